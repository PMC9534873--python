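"""Conditional association scanning and forward selection across the MHC.

A conditional scan fits, per variant, a logistic model

    status ~ variant + base covariates + conditioning variables

and reports the variant term, revealing how much association survives once
a chosen summary of C4 structural variation is held fixed.  Eight
conditioning schemes are supported, from nothing (marginal scan) through
copy-number channels, risk scores, and forward-selected eQTL dosage sets.

Forward selection greedily adds, at each step, the candidate variant with
the smallest conditional p-value given the baseline covariates and the
variants already selected, stopping when no candidate reaches the stop
threshold.  Ties on p break on larger |beta|, then lexicographic id.
Candidates whose addition makes the design numerically singular (condition
number above 1e10) are skipped with a recorded reason.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import FitResult, SingularDesignError, fit_logistic

__all__ = [
    "GENOME_WIDE_P",
    "ScanResult",
    "SelectionTrace",
    "conditional_scan",
    "build_conditioning_set",
    "forward_select",
    "specific_eqtl_partition",
    "CONDITIONING_SCHEMES",
]

#: Genome-wide significance line drawn on Manhattan plots.
GENOME_WIDE_P = 5e-8

#: Condition-number ceiling beyond which a candidate is non-identifiable.
_COND_LIMIT = 1e10

CONDITIONING_SCHEMES = {
    1: "base covariates only",
    2: "SLE/SjS C4 risk score 2.3*C4A + C4B",
    3: "C4A, C4B and HERV-K copy-number channels",
    4: "composite risk score from the fitted interaction model",
    5: "forward-selected C4 eQTL dosages (all)",
    6: "forward-selected C4A-specific eQTL dosages",
    7: "forward-selected C4B-specific eQTL dosages",
    8: "expression-model eQTL dosages",
}


@dataclass
class ScanResult:
    """Per-variant association under one conditioning set."""

    table: pd.DataFrame  # id, pos, beta, se, z, p, reason
    scheme: str = "1"

    def manhattan_data(self) -> pd.DataFrame:
        """(pos, -log10 p) pairs for plotting."""
        ok = self.table.dropna(subset=["p"])
        return pd.DataFrame({"pos": ok["pos"], "neglog10p": -np.log10(ok["p"])})

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["scheme"] = self.scheme
        out.to_csv(path, sep="\t", index=False)


@dataclass
class SelectionTrace:
    """Ordered record of a forward-selection run."""

    selected: list[str] = field(default_factory=list)
    p_values: list[float] = field(default_factory=list)
    betas: list[float] = field(default_factory=list)
    candidate_filter_p: float = 1.0
    stop_p: float = 0.01
    baseline_terms: list[str] = field(default_factory=list)
    skipped: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.selected)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "selected": self.selected,
                    "p_values": self.p_values,
                    "betas": self.betas,
                    "candidate_filter_p": self.candidate_filter_p,
                    "stop_p": self.stop_p,
                    "baseline_terms": self.baseline_terms,
                    "skipped": self.skipped,
                },
                fh,
                indent=1,
            )


def _with_intercept(base: pd.DataFrame | None, index: pd.Index) -> pd.DataFrame:
    out = pd.DataFrame({"intercept": 1.0}, index=index)
    if base is not None and len(base.columns):
        out = pd.concat([out, base.astype(float)], axis=1)
    return out


def _condition_number(X: np.ndarray) -> float:
    norms = np.sqrt((X**2).sum(axis=0))
    if np.any(norms == 0):
        return np.inf
    return float(np.linalg.cond(X / norms))


def conditional_scan(
    variants: pd.DataFrame,
    outcome: pd.Series,
    base_covariates: pd.DataFrame | None = None,
    conditioning: pd.DataFrame | None = None,
    *,
    positions: Mapping[str, int] | pd.Series | None = None,
    scheme: str = "1",
) -> ScanResult:
    """Logistic association of each variant conditional on covariates.

    Only the variant term is reported.  A variant collinear with the
    conditioning set yields a missing p with reason "collinear"; a
    non-converged (separated) fit yields reason "not_converged".
    """
    idx = variants.index
    base = _with_intercept(base_covariates, idx)
    if conditioning is not None and len(conditioning.columns):
        base = pd.concat([base, conditioning.astype(float)], axis=1)
    y = np.asarray(outcome, dtype=float)
    Z = base.to_numpy(dtype=float)
    names = list(base.columns)
    rows = []
    for vid in variants.columns:
        v = variants[vid].to_numpy(dtype=float)
        X = np.column_stack([Z, v])
        pos = None
        if positions is not None:
            pos = int(positions[vid]) if vid in positions else None
        rec = {"id": vid, "pos": pos, "beta": np.nan, "se": np.nan, "z": np.nan, "p": np.nan, "reason": ""}
        try:
            fit = fit_logistic(X, y, term_names=names + [vid])
        except SingularDesignError:
            rec["reason"] = "collinear"
            rows.append(rec)
            continue
        if not fit.converged:
            rec["reason"] = "not_converged"
            rows.append(rec)
            continue
        rec.update(
            beta=fit.beta(vid), se=fit.se(vid),
            z=float(fit.table.loc[vid, "z"]), p=float(fit.table.loc[vid, "p"]),
        )
        rows.append(rec)
    return ScanResult(table=pd.DataFrame(rows), scheme=str(scheme))


def build_conditioning_set(
    scheme: int,
    cn_profile: pd.DataFrame | None = None,
    *,
    model_d_fit: FitResult | None = None,
    model_d_design: pd.DataFrame | None = None,
    eqtl_dosages: pd.DataFrame | None = None,
    eqtl_lists: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Covariate matrix for conditioning schemes 1-8.

    1: empty; 2: the SLE/SjS score 2.3*C4A + C4B; 3: the C4A/C4B/HERV-K
    channels; 4: the composite risk score from a fitted interaction model
    (linear predictor over its C4 terms); 5/6/7: forward-selected eQTL
    dosage columns (all / C4A-specific / C4B-specific); 8: expression-model
    eQTL dosage columns.  Schemes 5-8 read the id lists from ``eqtl_lists``
    keys "all", "c4a_specific", "c4b_specific", "expression".
    """
    if scheme not in CONDITIONING_SCHEMES:
        raise ValueError(f"unknown conditioning scheme {scheme}; expected 1-8")
    if scheme == 1:
        index = cn_profile.index if cn_profile is not None else pd.Index([])
        return pd.DataFrame(index=index)
    if scheme == 2:
        if cn_profile is None:
            raise ValueError("scheme 2 requires a copy-number profile")
        return pd.DataFrame(
            {"c4_sle_sjs_score": 2.3 * cn_profile["c4a"] + cn_profile["c4b"]}
        )
    if scheme == 3:
        if cn_profile is None:
            raise ValueError("scheme 3 requires a copy-number profile")
        return cn_profile[["c4a", "c4b", "hervk"]].copy()
    if scheme == 4:
        if model_d_fit is None or model_d_design is None:
            raise ValueError("scheme 4 requires the fitted interaction model and its design")
        betas = model_d_fit.betas()
        cn_terms = [
            t for t in betas
            if t in model_d_design.columns
            and t != "intercept"
            and not t.upper().startswith("PC")
            and not t.startswith("cohort[")
            and t != "sex"
        ]
        S = sum(betas[t] * model_d_design[t] for t in cn_terms)
        return pd.DataFrame({"c4_model_d_score": S})
    key = {5: "all", 6: "c4a_specific", 7: "c4b_specific", 8: "expression"}[scheme]
    if eqtl_dosages is None or eqtl_lists is None:
        raise ValueError(f"scheme {scheme} requires eQTL dosages and id lists")
    ids = list(eqtl_lists.get(key, []))
    missing = [i for i in ids if i not in eqtl_dosages.columns]
    if missing:
        raise KeyError(f"eQTL ids absent from dosage matrix: {missing}")
    return eqtl_dosages[ids].copy()


# ---------------------------------------------------------------------------
# forward selection


def _candidate_stat(
    Xbase: np.ndarray,
    names: list[str],
    cand: np.ndarray,
    cand_id: str,
    y: np.ndarray,
    family: str,
) -> tuple[float, float] | None:
    """(p, beta) for the candidate term added to the baseline, or None if
    non-identifiable."""
    X = np.column_stack([Xbase, cand])
    if _condition_number(X) > _COND_LIMIT:
        return None
    if family == "logistic":
        try:
            fit = fit_logistic(X, y, term_names=names + [cand_id])
        except SingularDesignError:
            return None
        if not fit.converged:
            return None
        return float(fit.table.loc[cand_id, "p"]), fit.beta(cand_id)
    # linear: OLS t test on the last coefficient
    n, p = X.shape
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p or n <= p:
        return None
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - p)
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * XtX_inv[-1, -1])
    if se == 0:
        return None
    t = beta[-1] / se
    pval = float(2 * stats.t.sf(abs(t), n - p))
    return pval, float(beta[-1])


def forward_select(
    candidates: pd.DataFrame,
    outcome: pd.Series,
    baseline_covariates: pd.DataFrame | None = None,
    *,
    candidate_filter_p: float = 1.0,
    stop_p: float = 0.01,
    family: str = "auto",
) -> SelectionTrace:
    """Greedy forward selection of candidate variants.

    ``family`` is "logistic", "linear" or "auto" (logistic iff the outcome
    is binary).  Candidates are first filtered by their marginal conditional
    p against the baseline alone (``candidate_filter_p``); selection then
    iterates until the best remaining conditional p is >= ``stop_p``.  An
    empty candidate set yields an empty trace.
    """
    for thr, label in ((candidate_filter_p, "candidate_filter_p"), (stop_p, "stop_p")):
        if not (0 < thr <= 1):
            raise ValueError(f"{label} must lie in (0, 1]")
    y = np.asarray(outcome, dtype=float)
    if family == "auto":
        family = "logistic" if set(np.unique(y)) <= {0.0, 1.0} else "linear"
    base = _with_intercept(baseline_covariates, candidates.index)
    names = list(base.columns)
    Xbase = base.to_numpy(dtype=float)
    trace = SelectionTrace(
        candidate_filter_p=candidate_filter_p, stop_p=stop_p, baseline_terms=names
    )
    if candidates.shape[1] == 0:
        return trace

    # pre-filter against the baseline
    remaining: list[str] = []
    for vid in candidates.columns:
        st = _candidate_stat(Xbase, names, candidates[vid].to_numpy(float), vid, y, family)
        if st is None:
            trace.skipped[vid] = "non_identifiable_at_filter"
        elif st[0] < candidate_filter_p:
            remaining.append(vid)
        else:
            trace.skipped[vid] = "filtered"

    while remaining:
        best: tuple[float, float, str] | None = None  # (p, -|beta|, id)
        stats_by_id: dict[str, tuple[float, float]] = {}
        unusable: list[str] = []
        for vid in remaining:
            st = _candidate_stat(Xbase, names, candidates[vid].to_numpy(float), vid, y, family)
            if st is None:
                unusable.append(vid)
                continue
            stats_by_id[vid] = st
            key = (st[0], -abs(st[1]), vid)
            if best is None or key < best:
                best = key
        for vid in unusable:
            remaining.remove(vid)
            trace.skipped[vid] = "non_identifiable"
        if best is None or best[0] >= stop_p:
            break
        vid = best[2]
        p_sel, beta_sel = stats_by_id[vid]
        trace.selected.append(vid)
        trace.p_values.append(p_sel)
        trace.betas.append(beta_sel)
        Xbase = np.column_stack([Xbase, candidates[vid].to_numpy(float)])
        names = names + [vid]
        remaining.remove(vid)
    return trace


def specific_eqtl_partition(
    eqtl_table: pd.DataFrame, *, p_threshold: float = 0.01
) -> tuple[list[str], list[str], list[str]]:
    """Partition eQTLs into (C4A-specific, C4B-specific, shared) id lists.

    An eQTL is C4A-specific iff it has a reported C4A association and no
    C4B association below ``p_threshold`` (missing counts as no evidence);
    symmetrically for C4B.  Everything else is shared.
    """
    df = eqtl_table.copy()
    df.columns = [str(c).lower() for c in df.columns]
    required = {"snp", "p_c4a", "p_c4b"}
    if not required <= set(df.columns):
        raise ValueError(f"eQTL table needs columns {sorted(required)}")
    if df["snp"].duplicated().any():
        raise ValueError("duplicate snp ids in eQTL table")
    a_specific, b_specific, shared = [], [], []
    for _, row in df.iterrows():
        has_a = pd.notna(row["p_c4a"])
        has_b = pd.notna(row["p_c4b"])
        a_evid = has_a
        b_evid = has_b
        if has_a and (not has_b or row["p_c4b"] >= p_threshold):
            a_specific.append(row["snp"])
        elif has_b and (not has_a or row["p_c4a"] >= p_threshold):
            b_specific.append(row["snp"])
        else:
            shared.append(row["snp"])
    return a_specific, b_specific, shared
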