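"""Translation of C4 structural-haplotype dosages into gene copy-number dosages.

The complement component 4 locus carries a variable number of *C4A* and
*C4B* gene copies per chromosome, each copy in a "long" form (containing a
6.4-kb HERV-K insertion in intron 9) or a "short" form.  A structural
haplotype such as ``AL-BL`` is one chromosome carrying one long C4A and one
long C4B.  Given per-individual haplotype dosages (expected haplotype
counts, possibly fractional after probabilistic imputation) and a table of
per-haplotype gene contents, copy-number dosages of C4A, C4B, HERV-K, total
C4 and the four long/short forms are obtained by a pure linear map:

    cn_channel[i] = sum_h dosage[i, h] * count[h, channel]

When a haplotype's gene content is only known as isotype totals (number of
C4A, C4B and HERV-K copies), the split into long/short forms may be
ambiguous; it is then resolved by the population consensus that ~95% of C4A
copies are long (see :func:`decompose_long_short`).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HaplotypeComposition",
    "DEFAULT_COMPOSITIONS",
    "DEFAULT_FREQUENCIES",
    "load_composition",
    "decompose_long_short",
    "compute_cn_dosages",
    "haplotype_allele_correlation",
    "weighted_imputation_accuracy",
    "round_copy_number",
    "CN_CHANNELS",
    "FORM_CHANNELS",
    "A_LONG_CONSENSUS",
]

#: Fraction of C4A copies present in the long form (population consensus).
A_LONG_CONSENSUS = 0.95

#: The four long/short form channels, in canonical order.
FORM_CHANNELS = ("al", "as", "bl", "bs")

#: All copy-number channels produced by :func:`compute_cn_dosages`.
CN_CHANNELS = ("c4a", "c4b", "hervk", "c4_total") + FORM_CHANNELS


@dataclass(frozen=True)
class HaplotypeComposition:
    """Gene content of one structural haplotype.

    ``al``/``as_``/``bl``/``bs`` are copy counts of long/short C4A and C4B;
    they are fractional only when the long/short split was inferred from
    isotype totals via the 95% consensus rule.  ``frequency`` is an optional
    population haplotype frequency.
    """

    name: str
    al: float
    as_: float
    bl: float
    bs: float
    frequency: float | None = None

    def __post_init__(self) -> None:
        for ch in ("al", "as_", "bl", "bs"):
            if getattr(self, ch) < 0:
                raise ValueError(f"negative copy count {ch} in haplotype {self.name!r}")
        if self.al + self.as_ + self.bl + self.bs <= 0:
            raise ValueError(f"haplotype {self.name!r} carries no C4 gene copies")
        if self.frequency is not None and not (0 <= self.frequency <= 1):
            raise ValueError(f"frequency of {self.name!r} outside [0, 1]")

    @property
    def c4a(self) -> float:
        return self.al + self.as_

    @property
    def c4b(self) -> float:
        return self.bl + self.bs

    @property
    def hervk(self) -> float:
        return self.al + self.bl

    @property
    def c4_total(self) -> float:
        return self.c4a + self.c4b

    def channel(self, name: str) -> float:
        key = "as_" if name == "as" else name
        return getattr(self, key)


def decompose_long_short(
    a_total: float,
    b_total: float,
    herv_total: float,
    *,
    p_a_long: float = A_LONG_CONSENSUS,
) -> tuple[float, float, float, float]:
    """Split isotype totals into (al, as, bl, bs) copy counts.

    The marginal constraints ``al + as = a_total``, ``bl + bs = b_total`` and
    ``al + bl = herv_total`` (every long gene carries one HERV-K insertion)
    pin the split uniquely whenever one isotype is absent or HERV-K saturates
    or is absent.  Otherwise the assignment is ambiguous and the expected
    counts under the consensus prior P(A copy is long) = ``p_a_long`` are
    returned, still satisfying all three marginals exactly.

    Returns a tuple that is integral whenever the assignment is forced.
    """
    for v, label in ((a_total, "a_total"), (b_total, "b_total"), (herv_total, "herv_total")):
        if v < 0:
            raise ValueError(f"{label} must be non-negative, got {v}")
    if herv_total > a_total + b_total + 1e-12:
        raise ValueError(
            f"infeasible totals: {herv_total} HERV-K copies exceed "
            f"{a_total + b_total} gene copies"
        )
    # al ranges over [max(0, herv - b), min(a, herv)]; a single point means
    # the assignment is forced.
    lo = max(0.0, herv_total - b_total)
    hi = min(a_total, herv_total)
    if math.isclose(lo, hi, abs_tol=1e-12):
        al = lo
    else:
        # Expected AL count under the consensus prior, clipped to the
        # feasible interval so the marginals stay exact.
        al = min(max(p_a_long * a_total, lo), hi)
    as_ = a_total - al
    bl = herv_total - al
    bs = b_total - bl
    # trim float residue (e.g. 1 - 0.95) so consensus weights are exact
    return tuple(round(v, 12) + 0.0 for v in (al, as_, bl, bs))


def _default_table() -> tuple[list[HaplotypeComposition], dict[str, float]]:
    # Common European structural haplotypes.  Frequencies are configurable
    # defaults in the style of published European estimates, not values from
    # any single study population.
    rows = [
        # name, al, as, bl, bs, frequency
        ("BS", 0, 0, 0, 1, 0.09),
        ("AL-BS", 1, 0, 0, 1, 0.35),
        ("AL-BL", 1, 0, 1, 0, 0.43),
        ("AL-AL-BL", 2, 0, 1, 0, 0.08),
        ("AL-BL-BL", 1, 0, 2, 0, 0.02),
        ("AL-AL", 2, 0, 0, 0, 0.01),
        ("AL-AL-BS", 2, 0, 0, 1, 0.01),
        ("AL", 1, 0, 0, 0, 0.01),
    ]
    comps = [HaplotypeComposition(n, al, as_, bl, bs, f) for n, al, as_, bl, bs, f in rows]
    freqs = {c.name: c.frequency for c in comps}
    return comps, freqs


DEFAULT_COMPOSITIONS, DEFAULT_FREQUENCIES = _default_table()


def load_composition(
    source: str | io.TextIOBase | pd.DataFrame | None = None,
) -> list[HaplotypeComposition]:
    """Load a haplotype composition table.

    ``source`` may be a TSV path/handle, a DataFrame, or ``None`` for the
    built-in default table.  Accepted columns: ``name`` plus either explicit
    long/short counts (``al``, ``as``, ``bl``, ``bs``) or isotype totals
    (``c4a``, ``c4b``, ``hervk``) which are split with
    :func:`decompose_long_short`.  Explicit columns take precedence when both
    are present.  An optional ``frequency`` column is carried through.
    """
    if source is None:
        return list(DEFAULT_COMPOSITIONS)
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t")
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "name" not in df.columns:
        raise ValueError("composition table requires a 'name' column")
    if df["name"].duplicated().any():
        dups = sorted(df.loc[df["name"].duplicated(), "name"].unique())
        raise ValueError(f"duplicate haplotype names: {dups}")
    explicit = all(c in df.columns for c in FORM_CHANNELS)
    totals = all(c in df.columns for c in ("c4a", "c4b", "hervk"))
    if not explicit and not totals:
        raise ValueError(
            "composition table needs either columns al/as/bl/bs or c4a/c4b/hervk"
        )
    out: list[HaplotypeComposition] = []
    for _, row in df.iterrows():
        freq = float(row["frequency"]) if "frequency" in df.columns and pd.notna(row.get("frequency")) else None
        if explicit:
            al, as_, bl, bs = (float(row[c]) for c in FORM_CHANNELS)
        else:
            al, as_, bl, bs = decompose_long_short(
                float(row["c4a"]), float(row["c4b"]), float(row["hervk"])
            )
        out.append(HaplotypeComposition(str(row["name"]), al, as_, bl, bs, freq))
    return out


def compute_cn_dosages(
    hap_dosages: pd.DataFrame,
    compositions: Sequence[HaplotypeComposition] | None = None,
) -> pd.DataFrame:
    """Translate a haplotype dosage matrix into copy-number dosages.

    ``hap_dosages`` is individuals x haplotype-names.  Every column must have
    a composition entry.  Returns a DataFrame with columns
    ``c4a, c4b, hervk, c4_total, al, as, bl, bs`` indexed like the input.
    """
    comps = {c.name: c for c in (compositions or DEFAULT_COMPOSITIONS)}
    unknown = [h for h in hap_dosages.columns if h not in comps]
    if unknown:
        raise KeyError(f"no composition entry for haplotype column(s): {sorted(unknown)}")
    X = hap_dosages.to_numpy(dtype=float)
    # loading matrix: haplotypes x form channels
    L = np.array(
        [[comps[h].al, comps[h].as_, comps[h].bl, comps[h].bs] for h in hap_dosages.columns],
        dtype=float,
    ).reshape(len(hap_dosages.columns), 4)
    forms = X @ L if X.size else np.zeros((len(hap_dosages), 4))
    out = pd.DataFrame(forms, columns=list(FORM_CHANNELS), index=hap_dosages.index)
    out.insert(0, "c4a", out["al"] + out["as"])
    out.insert(1, "c4b", out["bl"] + out["bs"])
    out.insert(2, "hervk", out["al"] + out["bl"])
    out.insert(3, "c4_total", out["c4a"] + out["c4b"])
    return out


def round_copy_number(dosages: pd.Series | pd.DataFrame | np.ndarray):
    """Round imputed dosages to integer copy numbers (half-to-even).

    Used for plotting and for grouping individuals by rounded copy number;
    association models consume unrounded dosages.
    """
    if isinstance(dosages, (pd.Series, pd.DataFrame)):
        return dosages.round(0).astype(int)
    return np.rint(np.asarray(dosages)).astype(int)


def haplotype_allele_correlation(
    hap_dosages: pd.DataFrame, allele_dosages: pd.DataFrame
) -> pd.DataFrame:
    """Squared Pearson correlation between haplotype and allele dosages.

    Returns an r² matrix (haplotypes x alleles).  Pairs involving a
    zero-variance column are reported as NaN (undefined), never coerced to 0.
    """
    if len(hap_dosages) != len(allele_dosages):
        raise ValueError("haplotype and allele matrices must cover the same individuals")
    H = hap_dosages.to_numpy(dtype=float)
    A = allele_dosages.to_numpy(dtype=float)
    n = H.shape[0]
    Hc = H - H.mean(axis=0)
    Ac = A - A.mean(axis=0)
    sh = np.sqrt((Hc**2).sum(axis=0))
    sa = np.sqrt((Ac**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Hc.T @ Ac) / np.outer(sh, sa)
    r[:, sa == 0] = np.nan
    r[sh == 0, :] = np.nan
    if n < 2:
        r[:] = np.nan
    return pd.DataFrame(r**2, index=hap_dosages.columns, columns=allele_dosages.columns)


def weighted_imputation_accuracy(
    r2: Iterable[float] | Mapping[str, float],
    frequencies: Iterable[float] | Mapping[str, float],
) -> float:
    """Frequency-weighted mean imputation r²:  sum(f * r²) / sum(f)."""
    if isinstance(r2, Mapping) and isinstance(frequencies, Mapping):
        keys = list(r2)
        r2v = np.array([r2[k] for k in keys], dtype=float)
        fv = np.array([frequencies[k] for k in keys], dtype=float)
    else:
        r2v = np.asarray(list(r2), dtype=float)
        fv = np.asarray(list(frequencies), dtype=float)
    if len(r2v) != len(fv):
        raise ValueError("r2 and frequency vectors must have equal length")
    if np.any(fv < 0):
        raise ValueError("frequencies must be non-negative")
    total = fv.sum()
    if total <= 0:
        raise ValueError("frequencies sum to zero; weighted accuracy undefined")
    return float(np.dot(fv, r2v) / total)
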