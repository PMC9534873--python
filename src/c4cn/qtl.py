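"""Quantitative-trait layer: expression residualization, variance explained,
copy-number prediction from eQTLs, serum-protein modelling and group tests.

Expression residualization mirrors a two-step pipeline: genetic principal
components are regressed out globally, then non-genetic structure is removed
per disease group by regressing out the leading principal components of the
inter-sample expression correlation matrix (computed within the group).

Variance explained uses ordinary least squares with the adjusted
coefficient of determination  r²_adj = 1 - (1 - r²)(n - 1)/(n - p - 1).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .assoc import FitResult

__all__ = [
    "residualize_expression",
    "model_variance_explained",
    "predict_cn_from_eqtls",
    "fit_protein_model",
    "compare_groups",
    "normalize_protein_centers",
    "protein_per_copy",
]


def _regress_out(Y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residual of each column of Y on [1, Z]."""
    X = np.column_stack([np.ones(len(Y)), Z]) if Z.size else np.ones((len(Y), 1))
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ coef


def residualize_expression(
    expression: pd.DataFrame,
    genetic_pcs: pd.DataFrame | None,
    groups: pd.Series,
    n_group_pcs: Mapping[str, int] | int,
    *,
    components: Mapping[str, np.ndarray] | None = None,
    return_components: bool = False,
):
    """Two-step residualization of a samples x genes expression matrix.

    Step 1 regresses the configured genetic PCs out of every gene globally;
    step 2 computes, within each group (e.g. cases and controls separately),
    the leading eigenvectors of the inter-sample correlation matrix and
    regresses the requested number out.  ``n_group_pcs`` is either one count
    for every group or a mapping group label -> count.  A group must contain
    more samples than requested PCs.

    Pass ``components`` (group label -> samples x k score matrix, as
    returned with ``return_components=True``) to reuse previously extracted
    components instead of recomputing them; re-applying the projection with
    the same components is a no-op.
    """
    if not expression.index.equals(groups.index):
        raise ValueError("expression and group labels must share the same samples")
    Y = expression.to_numpy(dtype=float)
    if genetic_pcs is not None and len(genetic_pcs.columns):
        Y = _regress_out(Y, genetic_pcs.loc[expression.index].to_numpy(dtype=float))
    else:
        Y = Y - Y.mean(axis=0)
    out = np.array(Y)
    used: dict = {}
    for g in pd.unique(groups):
        mask = (groups == g).to_numpy()
        k = n_group_pcs[g] if isinstance(n_group_pcs, Mapping) else int(n_group_pcs)
        if mask.sum() <= k:
            raise ValueError(
                f"group {g!r} has {int(mask.sum())} samples but {k} PCs were requested"
            )
        if k == 0:
            out[mask] = out[mask] - out[mask].mean(axis=0)
            used[g] = np.empty((int(mask.sum()), 0))
            continue
        sub = out[mask]
        if components is not None:
            scores = np.asarray(components[g])
        else:
            C = np.corrcoef(sub)  # inter-sample correlation across genes
            C = np.nan_to_num(C, nan=0.0)
            vals, vecs = np.linalg.eigh(C)
            scores = vecs[:, np.argsort(vals)[::-1][:k]]  # samples x k
        out[mask] = _regress_out(sub, scores)
        used[g] = scores
    result = pd.DataFrame(out, index=expression.index, columns=expression.columns)
    if return_components:
        return result, used
    return result


def model_variance_explained(
    trait: pd.Series,
    predictor_sets: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Adjusted r² of OLS models of one trait on named predictor sets.

    Supports cross-channel designs (e.g. C4B copy numbers inside the C4A
    expression model).  Returns a DataFrame indexed by model name with
    columns r2, r2_adj, n, p (model F-test p-value).
    """
    rows = {}
    y = pd.to_numeric(trait)
    for name, X in predictor_sets.items():
        Xa = sm.add_constant(X.loc[y.index].astype(float), has_constant="add")
        if len(y) <= Xa.shape[1]:
            raise ValueError(f"model {name!r}: n={len(y)} too small for {Xa.shape[1]} terms")
        res = sm.OLS(y, Xa).fit()
        rows[name] = {
            "r2": res.rsquared,
            "r2_adj": res.rsquared_adj,
            "n": int(res.nobs),
            "p": res.f_pvalue,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def predict_cn_from_eqtls(
    eqtl_dosages: pd.DataFrame, cn_channel: pd.Series
) -> tuple[sm.regression.linear_model.RegressionResultsWrapper, float]:
    """OLS prediction of one long/short copy-number channel from eQTL dosages.

    Returns the fitted model and its coefficient of determination.
    """
    if len(eqtl_dosages) != len(cn_channel):
        raise ValueError("eQTL dosages and copy-number channel must match individuals")
    X = sm.add_constant(eqtl_dosages.astype(float), has_constant="add")
    res = sm.OLS(pd.to_numeric(cn_channel), X).fit()
    return res, float(res.rsquared)


PROTEIN_MODEL_TERMS = ("disease", "sex", "age", "as", "al", "bs", "bl")


def fit_protein_model(
    protein: pd.Series,
    covariates: pd.DataFrame,
    cn_profile: pd.DataFrame,
    *,
    disease: pd.Series | None = None,
) -> tuple[FitResult, float]:
    """Linear model of serum C4 protein on disease, sex, age and the four
    long/short copy-number channels.

    Constant predictors are dropped with a warning.  Returns per-term
    estimates (FitResult with t-based p-values) and the model r².
    """
    df = pd.DataFrame(index=protein.index)
    source = covariates.copy()
    if disease is not None:
        source["disease"] = disease
    elif "status" in source.columns and "disease" not in source.columns:
        source["disease"] = source["status"]
    for term in PROTEIN_MODEL_TERMS:
        if term in source.columns:
            df[term] = pd.to_numeric(source[term])
        elif term in cn_profile.columns:
            df[term] = cn_profile[term]
        else:
            raise ValueError(f"protein model term {term!r} not found in inputs")
    keep = df.notna().all(axis=1) & protein.notna()
    df, y = df[keep], pd.to_numeric(protein[keep])
    dropped = [c for c in df.columns if df[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"dropping constant protein-model predictor(s): {dropped}", stacklevel=2)
        df = df.drop(columns=dropped)
    X = sm.add_constant(df, has_constant="add").rename(columns={"const": "intercept"})
    res = sm.OLS(y, X).fit()
    table = pd.DataFrame(
        {"beta": res.params, "se": res.bse, "z": res.tvalues, "p": res.pvalues}
    )
    table.index.name = "term"
    fit = FitResult(
        table=table, n_obs=int(res.nobs), converged=True, llf=float(res.llf), n_iter=1
    )
    return fit, float(res.rsquared)


def compare_groups(
    values: pd.Series | np.ndarray,
    labels: pd.Series | np.ndarray,
    *,
    tests: Sequence[str] = ("mann-whitney", "t"),
) -> pd.DataFrame:
    """Two-sided two-group comparison with the Mann-Whitney and t tests.

    The Mann-Whitney p uses exact enumeration for small tie-free samples and
    the tie-corrected, continuity-corrected normal approximation otherwise
    (the behaviour of R's ``wilcox.test``).  Returns a DataFrame indexed by
    test with columns statistic and p.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    uniq = pd.unique(lab)
    if len(uniq) != 2:
        raise ValueError(f"expected exactly two groups, got {list(uniq)}")
    a, b = v[lab == uniq[0]], v[lab == uniq[1]]
    if min(len(a), len(b)) < 2:
        raise ValueError("each group needs at least two values")
    rows = {}
    for t in tests:
        if t in ("mann-whitney", "mw", "wilcoxon"):
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
            rows["mann-whitney"] = {"statistic": float(res.statistic), "p": float(res.pvalue)}
        elif t == "t":
            res = stats.ttest_ind(a, b)
            rows["t"] = {"statistic": float(res.statistic), "p": float(res.pvalue)}
        else:
            raise ValueError(f"unknown test {t!r}")
    return pd.DataFrame.from_dict(rows, orient="index")


def normalize_protein_centers(
    protein: pd.Series,
    centers: pd.Series,
    controls: pd.Series | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Multiplicative per-center normalization of serum protein values.

    Each center's factor scales its control-sample median onto the pooled
    control median, preserving within-center rank order.  ``controls`` is a
    boolean mask (default: all samples are treated as the reference group).
    Centers without controls fall back to all their samples and are flagged.
    Returns (normalized values, per-center factor table).
    """
    if not protein.index.equals(centers.index):
        raise ValueError("protein values and center labels must share the same samples")
    if controls is None:
        controls = pd.Series(True, index=protein.index)
    ref = protein[controls.astype(bool)]
    if ref.empty:
        ref = protein
    pooled_median = float(ref.median())
    out = protein.astype(float).copy()
    rows = []
    for c in pd.unique(centers):
        mask = centers == c
        center_ref = protein[mask & controls.astype(bool)]
        flagged = center_ref.empty
        if flagged:
            center_ref = protein[mask]
        med = float(center_ref.median())
        factor = pooled_median / med if med != 0 else 1.0
        out[mask] = protein[mask] * factor
        rows.append({"center": c, "factor": factor, "n": int(mask.sum()), "no_controls": flagged})
    return out, pd.DataFrame(rows).set_index("center")


def protein_per_copy(
    protein: pd.Series, c4_total: pd.Series, *, floor: float = 0.5
) -> tuple[pd.Series, pd.Series]:
    """Copy-number-corrected protein: value / total C4 dosage.

    Dosages below ``floor`` are floored to avoid division blow-ups; the
    returned flag marks floored individuals.
    """
    denom = c4_total.astype(float).clip(lower=floor)
    flagged = c4_total < floor
    return protein / denom, flagged
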