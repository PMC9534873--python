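"""Variant quality control for pre- and post-imputation dosage matrices.

Pre-imputation stage drops variants with call rate < 0.98, minor allele
frequency < 0.01, or Hardy-Weinberg disequilibrium (chi-square p < 0.001 in
BOTH cases and controls).  Post-imputation stage drops imputation r² <= 0.3
(when provided), MAF <= 0.05 and the same HWE rule.  HWE uses a 1-df
Pearson chi-square on hard calls obtained by rounding dosages; filters are
evaluated jointly on the input matrix, so the surviving set is independent
of filter order.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["hwe_chisq_p", "qc_filter_variants"]


def hwe_chisq_p(n_ref: int, n_het: int, n_alt: int) -> float:
    """Pearson 1-df chi-square p-value against Hardy-Weinberg proportions."""
    n = n_ref + n_het + n_alt
    if n == 0:
        return 1.0
    p = (2 * n_alt + n_het) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    obs = np.array([n_ref, n_het, n_alt], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, df=1))


def _hard_calls(dosages: np.ndarray) -> np.ndarray:
    calls = np.rint(dosages)
    return np.clip(calls, 0, 2)


def _maf(col: np.ndarray) -> float:
    ok = ~np.isnan(col)
    if not ok.any():
        return np.nan
    af = float(col[ok].mean()) / 2
    return min(af, 1 - af)


def qc_filter_variants(
    dosages: pd.DataFrame,
    stage: str = "pre",
    outcome: pd.Series | None = None,
    *,
    imputation_r2: Mapping[str, float] | pd.Series | None = None,
    call_rate_min: float = 0.98,
    maf_min: float = 0.01,
    hwe_p_min: float = 0.001,
    post_maf_min: float = 0.05,
    post_r2_min: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply stage-appropriate variant filters to a dosage matrix.

    Returns (filtered matrix, report).  The report lists one row per
    removal with the variant id, the reason (``call_rate``, ``maf``,
    ``hwe``, ``imputation_r2``) and the offending value; a variant failing
    several filters appears once per reason.  Case/control HWE requires
    ``outcome``; omitting it raises.
    """
    if stage not in ("pre", "post"):
        raise ValueError(f"unknown QC stage {stage!r}")
    if outcome is None:
        raise ValueError("outcome is required for case/control HWE filtering")
    y = np.asarray(outcome, dtype=float)
    records: list[dict] = []
    drop: set[str] = set()
    maf_thr = maf_min if stage == "pre" else post_maf_min
    mat = dosages.to_numpy(dtype=float)
    for j, vid in enumerate(dosages.columns):
        col = mat[:, j]
        if stage == "pre":
            call_rate = float(np.mean(~np.isnan(col)))
            if call_rate < call_rate_min:
                records.append({"variant": vid, "reason": "call_rate", "value": call_rate})
                drop.add(vid)
        maf = _maf(col)
        if np.isnan(maf) or maf < maf_thr:
            records.append({"variant": vid, "reason": "maf", "value": maf})
            drop.add(vid)
        if stage == "post" and imputation_r2 is not None:
            r2 = float(imputation_r2[vid]) if vid in imputation_r2 else np.nan
            if np.isnan(r2) or r2 <= post_r2_min:
                records.append({"variant": vid, "reason": "imputation_r2", "value": r2})
                drop.add(vid)
        # HWE in cases and controls; removed only if violated in both
        ok = ~np.isnan(col)
        ps = []
        for grp in (1.0, 0.0):
            calls = _hard_calls(col[ok & (y == grp)])
            counts = [(calls == k).sum() for k in (0, 1, 2)]
            ps.append(hwe_chisq_p(*counts))
        if max(ps) < hwe_p_min:
            records.append({"variant": vid, "reason": "hwe", "value": max(ps)})
            drop.add(vid)
    report = pd.DataFrame(records, columns=["variant", "reason", "value"])
    kept = [v for v in dosages.columns if v not in drop]
    return dosages[kept], report
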