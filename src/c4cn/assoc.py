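"""Logistic risk models for C4 copy number, risk scores and meta-analysis.

Implements the four nested case-control models used throughout the package
(copy-number dosages enter unrounded):

    a:  status ~ C4_total + HERV-K + PC1-5 + cohort + sex
    b:  status ~ C4A + C4B + HERV-K + PC1-5 + cohort + sex
    c:  status ~ AS + AL + BS + BL + PC1-5 + cohort + sex
    d:  model b + C4A:C4B + C4A:HERV-K + C4B:HERV-K + C4A:sex + C4B:sex

plus Wald odds ratios, composite risk scores (per-individual S = x'beta over
a chosen term subset, risk = logistic(S)), the max/min risk fold over
observed copy-number combinations, and fixed-effect inverse-variance
meta-analysis of per-cohort estimates.

The maximum-likelihood fit is iteratively reweighted least squares (Newton
with step-halving).  Wald standard errors come from the observed
information at the optimum; convergence requires max |score| < 1e-8 or a
relative log-likelihood change < 1e-10 within 100 iterations.  Perfect
separation is flagged (result marked non-converged) rather than raised; a
rank-deficient design raises :class:`SingularDesignError` naming the
collinear terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, special, stats

__all__ = [
    "ModelSpec",
    "FitResult",
    "MetaResult",
    "SingularDesignError",
    "build_design",
    "fit_logistic",
    "odds_ratio_ci",
    "composite_risk_score",
    "risk_fold_range",
    "meta_fixed_effect",
    "RISK_SCORE_PRESETS",
    "MODEL_MAIN_EFFECTS",
    "MODEL_INTERACTIONS",
]

logger = logging.getLogger(__name__)

MODEL_MAIN_EFFECTS: dict[str, tuple[str, ...]] = {
    "a": ("c4_total", "hervk"),
    "b": ("c4a", "c4b", "hervk"),
    "c": ("as", "al", "bs", "bl"),
    "d": ("c4a", "c4b", "hervk"),
}

MODEL_INTERACTIONS: dict[str, tuple[tuple[str, str], ...]] = {
    "a": (),
    "b": (),
    "c": (),
    "d": (("c4a", "c4b"), ("c4a", "hervk"), ("c4b", "hervk"), ("c4a", "sex"), ("c4b", "sex")),
}

#: Term subsets for the three composite-risk-score figure panels:
#: the C4A/C4B interaction view, the HERV-K view, and the male-risk view.
RISK_SCORE_PRESETS: dict[str, tuple[str, ...]] = {
    "c4a_c4b": ("c4a", "c4b", "c4a:c4b"),
    "hervk": ("c4a", "c4b", "hervk", "c4a:hervk", "c4b:hervk", "c4a:c4b"),
    "sex": ("sex", "c4a", "c4b", "c4a:sex", "c4b:sex", "c4a:c4b"),
}


class SingularDesignError(ValueError):
    """Raised when the design matrix is rank deficient."""


@dataclass(frozen=True)
class ModelSpec:
    """Terms of one case-control model.

    ``strata`` restricts the fit to one sex ("female"/"male"); stratified
    designs drop the sex column and any interaction involving sex.
    """

    model_id: str
    main_effects: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()
    strata: str = "all"
    include_pcs: bool = True
    include_cohort: bool = True
    include_sex: bool = True

    def __post_init__(self) -> None:
        mains = set(self.main_effects) | {"sex"}
        for a, b in self.interactions:
            if a not in mains or b not in mains:
                raise ValueError(f"interaction {a}:{b} references undeclared main effect")
        if self.strata not in ("all", "female", "male"):
            raise ValueError(f"unknown stratum {self.strata!r}")

    @classmethod
    def from_id(cls, model_id: str, strata: str = "all") -> "ModelSpec":
        if model_id not in MODEL_MAIN_EFFECTS:
            raise ValueError(f"unknown model id {model_id!r}; expected one of a, b, c, d")
        return cls(
            model_id=model_id,
            main_effects=MODEL_MAIN_EFFECTS[model_id],
            interactions=MODEL_INTERACTIONS[model_id],
            strata=strata,
        )


@dataclass
class FitResult:
    """Per-term estimates of one maximum-likelihood fit.

    ``table`` is indexed by term with columns beta, se, z, p.
    """

    table: pd.DataFrame
    n_obs: int
    converged: bool
    llf: float
    n_iter: int
    separated: bool = False
    n_dropped: int = 0

    def beta(self, term: str) -> float:
        return float(self.table.loc[term, "beta"])

    def se(self, term: str) -> float:
        return float(self.table.loc[term, "se"])

    def betas(self) -> dict[str, float]:
        return {t: float(b) for t, b in self.table["beta"].items()}

    def to_tsv(self, path) -> None:
        out = self.table.reset_index(names="term")
        out["n"] = self.n_obs
        out.to_csv(path, sep="\t", index=False)


@dataclass
class MetaResult:
    """Fixed-effect inverse-variance combination of per-cohort estimates."""

    beta: float
    se: float
    z: float
    p: float
    inputs: list[tuple[float, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# design construction


def build_design(
    spec: ModelSpec,
    cohort: pd.DataFrame,
    cn_profile: pd.DataFrame,
    outcome_col: str = "status",
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the design matrix and outcome for one model.

    ``cohort`` holds outcome, sex (0=female, 1=male), cohort label and
    genetic PCs (columns matching ``PC<k>``); ``cn_profile`` holds the
    copy-number channels.  Cohort labels expand to K-1 indicators against
    the lexicographically first level; interactions are elementwise products
    of their main-effect columns.  Rows with any missing value are excluded
    listwise (count logged).
    """
    if outcome_col not in cohort.columns:
        raise ValueError(f"cohort table lacks outcome column {outcome_col!r}")
    df = cohort.join(cn_profile, how="inner") if not cn_profile.empty else cohort.copy()
    if len(df) != len(cohort):
        raise ValueError("cohort table and copy-number profile index mismatch")

    if spec.strata != "all":
        if "sex" not in df.columns:
            raise ValueError("sex column required for stratified fits")
        df = df[df["sex"] == (1 if spec.strata == "male" else 0)]

    cols: dict[str, pd.Series] = {}
    for term in spec.main_effects:
        if term not in df.columns:
            raise ValueError(f"model term {term!r} missing from input tables")
        cols[term] = df[term]
    pc_cols = sorted(
        (c for c in df.columns if c.upper().startswith("PC") and c[2:].isdigit()),
        key=lambda c: int(c[2:]),
    )
    if spec.include_pcs:
        for c in pc_cols:
            cols[c] = df[c]
    if spec.include_cohort and "cohort" in df.columns:
        levels = sorted(df["cohort"].astype(str).unique())
        for lev in levels[1:]:  # first level is the reference
            cols[f"cohort[{lev}]"] = (df["cohort"].astype(str) == lev).astype(float)
    stratified = spec.strata != "all"
    if spec.include_sex and not stratified:
        if "sex" not in df.columns:
            raise ValueError("sex column missing")
        cols["sex"] = df["sex"]
    for a, b in spec.interactions:
        if stratified and ("sex" in (a, b)):
            continue  # constant within a sex stratum
        for t in (a, b):
            if t not in cols and t not in df.columns:
                raise ValueError(f"interaction component {t!r} missing")
        cols[f"{a}:{b}"] = (cols.get(a, df.get(a)) * cols.get(b, df.get(b)))

    design = pd.DataFrame(cols, index=df.index, dtype=float)
    design.insert(0, "intercept", 1.0)
    y = pd.to_numeric(df[outcome_col], errors="coerce")

    keep = design.notna().all(axis=1) & y.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("build_design: excluded %d rows with missing values", n_dropped)
    design, y = design[keep], y[keep]

    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(
            f"outcome has a single class ({classes.tolist()}) in stratum {spec.strata!r}"
        )
    design.attrs["n_dropped"] = n_dropped
    return design, y.astype(float)


# ---------------------------------------------------------------------------
# maximum likelihood


def _check_rank(X: np.ndarray, names: Sequence[str], tol: float = 1e-8) -> None:
    norms = np.sqrt((X**2).sum(axis=0))
    norms[norms == 0] = 1.0
    _, R, piv = linalg.qr(X / norms, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    ref = diag[0] if diag.size else 0.0
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] < tol * max(ref, 1.0)]
    zero = [names[j] for j in range(X.shape[1]) if not np.any(X[:, j])]
    bad = sorted(set(bad) | set(zero))
    if bad:
        raise SingularDesignError(f"design is rank deficient; collinear terms: {bad}")


def _loglik(y: np.ndarray, eta: np.ndarray, w: np.ndarray) -> float:
    # log L = sum w * (y*eta - log(1 + exp(eta))), numerically stable
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def fit_logistic(
    design: pd.DataFrame | np.ndarray,
    outcome: pd.Series | np.ndarray,
    *,
    weights: np.ndarray | None = None,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    ll_tol: float = 1e-10,
    term_names: Sequence[str] | None = None,
) -> FitResult:
    """Maximum-likelihood logistic regression via IRLS.

    ``weights`` are optional frequency weights (grouped data).  Diverging
    coefficients (perfect separation) leave the result flagged as
    non-converged with ``separated=True``; p-values should then not be
    interpreted.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        names = list(term_names) if term_names is not None else [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(outcome, dtype=float).ravel()
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float).ravel()
    n_obs = int(w.sum()) if weights is not None else len(y)
    if X.shape[0] != len(y):
        raise ValueError("design and outcome lengths differ")
    uy = np.unique(y)
    if not np.all(np.isin(uy, [0.0, 1.0])):
        raise ValueError("outcome must be binary 0/1")
    if n_obs <= X.shape[1]:
        raise ValueError("more model terms than observations")
    _check_rank(X * np.sqrt(w)[:, None], names)

    beta = np.zeros(X.shape[1])
    eta = X @ beta
    ll = _loglik(y, eta, w)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = special.expit(eta)
        score = X.T @ (w * (y - mu))
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        wls = np.clip(w * mu * (1 - mu), 1e-12, None)
        H = X.T @ (X * wls[:, None])
        try:
            step = linalg.solve(H, score, assume_a="pos")
        except linalg.LinAlgError:
            break
        # step-halving keeps the likelihood monotone
        new_ll = -np.inf
        for _ in range(30):
            cand = beta + step
            cand_eta = X @ cand
            new_ll = _loglik(y, cand_eta, w)
            if new_ll >= ll - 1e-12:
                break
            step = step / 2
        beta, eta = beta + step, X @ (beta + step)
        if new_ll - ll <= ll_tol * (abs(ll) + 1e-30) and new_ll >= ll:
            ll = new_ll
            converged = True
            break
        ll = new_ll

    mu = special.expit(eta)
    # diverging coefficients signal (quasi-)complete separation; the Wald
    # machinery is meaningless there even if the likelihood has plateaued
    separated = bool(np.max(np.abs(beta)) > 30)
    wls = np.clip(w * mu * (1 - mu), 1e-12, None)
    H = X.T @ (X * wls[:, None])
    try:
        cov = linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except linalg.LinAlgError:
        se = np.full_like(beta, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame({"beta": beta, "se": se, "z": z, "p": p}, index=pd.Index(names, name="term"))
    return FitResult(
        table=table,
        n_obs=n_obs,
        converged=converged and not separated,
        llf=ll,
        n_iter=it,
        separated=separated,
    )


# ---------------------------------------------------------------------------
# derived quantities


def odds_ratio_ci(beta: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """Odds ratio exp(beta) with a Wald confidence interval."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    z = stats.norm.ppf(0.5 + level / 2)
    return (float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se)))


def composite_risk_score(
    betas: Mapping[str, float],
    design: pd.DataFrame,
    terms: Sequence[str] | str,
) -> pd.DataFrame:
    """Per-individual composite risk: S_i = sum_t beta_t * x_it, risk = expit(S).

    ``terms`` is a subset of fitted terms or one of the named presets in
    :data:`RISK_SCORE_PRESETS` ("c4a_c4b", "hervk", "sex").
    """
    if isinstance(terms, str):
        try:
            terms = RISK_SCORE_PRESETS[terms]
        except KeyError:
            raise KeyError(
                f"unknown risk-score preset {terms!r}; options: {sorted(RISK_SCORE_PRESETS)}"
            ) from None
    missing = [t for t in terms if t not in betas]
    if missing:
        raise KeyError(f"terms without fitted beta: {missing}")
    missing_cols = [t for t in terms if t not in design.columns]
    if missing_cols:
        raise KeyError(f"terms missing from design: {missing_cols}")
    S = sum(betas[t] * design[t] for t in terms)
    return pd.DataFrame({"S": S, "risk": special.expit(S)}, index=design.index)


def risk_fold_range(risks: Iterable[float]) -> float:
    """Fold variation max(risk)/min(risk) over evaluated CN combinations."""
    r = np.asarray(list(risks), dtype=float)
    if r.size == 0:
        raise ValueError("no risk scores supplied")
    if np.min(r) <= 0:
        raise ValueError("risk scores must be strictly positive")
    return float(np.max(r) / np.min(r))


def meta_fixed_effect(estimates: Sequence[tuple[float, float]]) -> MetaResult:
    """Inverse-variance fixed-effect meta-analysis of (beta, se) pairs."""
    if len(estimates) == 0:
        raise ValueError("meta-analysis requires at least one cohort estimate")
    betas = np.array([b for b, _ in estimates], dtype=float)
    ses = np.array([s for _, s in estimates], dtype=float)
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    w = ses**-2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    return MetaResult(beta=beta, se=se, z=float(z), p=p, inputs=list(map(tuple, estimates)))
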