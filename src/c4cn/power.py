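"""Analytic power for case-control copy-number association tests.

Two calculations are provided, each with a Monte-Carlo simulation oracle:

* :func:`power_additive` — power of the 1-df allele-dosage (trend) test in
  a case-control design under an additive-on-relative-risk penetrance
  model constrained to a given disease prevalence, in the convention of
  standard GWAS power calculators.  Writing gamma for the per-allele
  genotype relative risk, penetrances are f1 = gamma*f0 and
  f2 = (2*gamma - 1)*f0 with f0 solved from the prevalence; expected case
  and control allele frequencies follow by Bayes' rule, and two-sided
  power uses the normal approximation of the two-proportion allele test
  with the variance evaluated at the alternative.

* :func:`power_interaction` — power of the 1-df Wald test of the
  gene-by-environment interaction coefficient in the logistic model
  outcome ~ G + E + G:E with binary carrier G and binary E (here: sex).
  With both factors binary the interaction MLE is a difference of log odds
  ratios whose variance is the sum of reciprocal expected counts over the
  eight case/control x G x E cells, so the non-centrality is available in
  closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .assoc import fit_logistic

__all__ = [
    "AdditivePowerSpec",
    "InteractionPowerSpec",
    "power_additive",
    "power_interaction",
    "simulate_power_additive",
    "simulate_power_interaction",
]


@dataclass(frozen=True)
class AdditivePowerSpec:
    """Parameters of the additive-model case-control power calculation."""

    allele_freq: float  # disease (risk) allele frequency
    grr: float  # genotype relative risk, additive: f1/f0
    prevalence: float
    n_cases: int
    n_controls: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.allele_freq < 1:
            raise ValueError("allele frequency must lie in (0, 1)")
        if self.grr <= 0:
            raise ValueError("genotype relative risk must be positive")
        if 2 * self.grr - 1 < 0:
            raise ValueError("additive model requires grr >= 0.5")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        if min(self.n_cases, self.n_controls) <= 0:
            raise ValueError("sample sizes must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class InteractionPowerSpec:
    """Parameters of the gene-by-environment interaction power calculation.

    ``p_gene`` is a binary carrier probability, ``p_env`` the environment
    (e.g. male sex) prevalence, ``or_ge`` the population G-E association
    odds ratio, ``case_fraction`` the fraction of cases among the total
    sample of size ``n``.  ``alpha1`` = 1 means single-stage testing of all
    markers (no screening).
    """

    prevalence: float
    p_gene: float
    p_env: float
    beta_g: float
    beta_e: float
    beta_ge: float
    or_ge: float = 1.0
    case_fraction: float = 0.5
    n: int = 10_000
    alpha: float = 0.05
    alpha1: float = 1.0

    def __post_init__(self) -> None:
        for name in ("prevalence", "p_gene", "p_env", "case_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.or_ge <= 0:
            raise ValueError("or_ge must be positive")
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0 < self.alpha < 1 or not 0 < self.alpha1 <= 1:
            raise ValueError("alpha levels must lie in (0, 1]")


# ---------------------------------------------------------------------------
# additive model


def _additive_genotype_dist(spec: AdditivePowerSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Genotype probabilities overall, in cases and in controls."""
    p, q = spec.allele_freq, 1 - spec.allele_freq
    g = np.array([q * q, 2 * p * q, p * p])  # risk-allele count 0, 1, 2
    rel = np.array([1.0, spec.grr, 2 * spec.grr - 1])
    f0 = spec.prevalence / float(g @ rel)
    f = f0 * rel
    if np.any(f > 1):
        raise ValueError(
            "penetrance exceeds 1: genotype relative risk and prevalence jointly infeasible"
        )
    p_case = f * g / spec.prevalence
    p_ctrl = (1 - f) * g / (1 - spec.prevalence)
    return g, p_case, p_ctrl


def power_additive(spec: AdditivePowerSpec) -> float:
    """Two-sided analytic power of the additive-model association test."""
    _, p_case, p_ctrl = _additive_genotype_dist(spec)
    pa_case = p_case[1] / 2 + p_case[2]
    pa_ctrl = p_ctrl[1] / 2 + p_ctrl[2]
    n1, n0 = 2 * spec.n_cases, 2 * spec.n_controls
    var = pa_case * (1 - pa_case) / n1 + pa_ctrl * (1 - pa_ctrl) / n0
    lam = (pa_case - pa_ctrl) / np.sqrt(var)
    za = stats.norm.ppf(1 - spec.alpha / 2)
    return float(stats.norm.cdf(-za + lam) + stats.norm.cdf(-za - lam))


def simulate_power_additive(
    spec: AdditivePowerSpec, n_reps: int = 2000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Monte-Carlo oracle: rejection rate of the Wald logistic test of the
    allele-dosage slope over simulated case-control replicates.

    Fits grouped logistic regressions (three genotype levels) per
    replicate.  Returns (power estimate, 95% binomial CI).
    """
    _, p_case, p_ctrl = _additive_genotype_dist(spec)
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(6), [0, 1, 2, 0, 1, 2]])
    y = np.array([1.0, 1, 1, 0, 0, 0])
    hits = 0
    for _ in range(n_reps):
        case_counts = rng.multinomial(spec.n_cases, p_case)
        ctrl_counts = rng.multinomial(spec.n_controls, p_ctrl)
        w = np.concatenate([case_counts, ctrl_counts]).astype(float)
        keep = w > 0
        fit = fit_logistic(X[keep], y[keep], weights=w[keep], term_names=["intercept", "dosage"])
        if fit.converged and fit.table.loc["dosage", "p"] < spec.alpha:
            hits += 1
    phat = hits / n_reps
    half = 1.96 * np.sqrt(phat * (1 - phat) / n_reps)
    return phat, (phat - half, phat + half)


# ---------------------------------------------------------------------------
# gene x environment interaction


def _joint_ge(p_gene: float, p_env: float, or_ge: float) -> np.ndarray:
    """P(G=g, E=e) with given margins and odds ratio; shape (2, 2) [g][e]."""
    if abs(or_ge - 1.0) < 1e-12:
        p11 = p_gene * p_env
    else:
        a = or_ge - 1.0
        b = -(or_ge * (p_gene + p_env) + (1 - p_gene - p_env))
        c = or_ge * p_gene * p_env
        disc = b * b - 4 * a * c
        p11 = (-b - np.sqrt(disc)) / (2 * a)
    pge = np.array(
        [[1 - p_gene - p_env + p11, p_env - p11], [p_gene - p11, p11]]
    )
    if np.any(pge <= 0):
        raise ValueError("G-E margins and odds ratio define an infeasible joint distribution")
    return pge


def _cell_distributions(spec: InteractionPowerSpec) -> tuple[np.ndarray, np.ndarray]:
    """(G, E) cell probabilities among cases and among controls."""
    pge = _joint_ge(spec.p_gene, spec.p_env, spec.or_ge)
    G = np.array([[0.0, 0.0], [1.0, 1.0]])
    E = np.array([[0.0, 1.0], [0.0, 1.0]])
    lp = spec.beta_g * G + spec.beta_e * E + spec.beta_ge * G * E

    def prev_gap(b0: float) -> float:
        return float(np.sum(pge * special.expit(b0 + lp))) - spec.prevalence

    b0 = optimize.brentq(prev_gap, -60, 60)
    pD = special.expit(b0 + lp)
    p_case = pD * pge / spec.prevalence
    p_ctrl = (1 - pD) * pge / (1 - spec.prevalence)
    return p_case, p_ctrl


def power_interaction(spec: InteractionPowerSpec) -> float:
    """Analytic power of the 1-df Wald test of the G:E interaction."""
    p_case, p_ctrl = _cell_distributions(spec)
    n_case = spec.n * spec.case_fraction
    n_ctrl = spec.n * (1 - spec.case_fraction)
    var = float(np.sum(1.0 / (n_case * p_case)) + np.sum(1.0 / (n_ctrl * p_ctrl)))
    lam = abs(spec.beta_ge) / np.sqrt(var)
    za = stats.norm.ppf(1 - spec.alpha / 2)
    return float(stats.norm.cdf(-za + lam) + stats.norm.cdf(-za - lam))


def simulate_power_interaction(
    spec: InteractionPowerSpec, n_reps: int = 2000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Monte-Carlo oracle: Wald-test rejection rate of the interaction term
    in grouped logistic fits of outcome ~ G + E + G:E."""
    p_case, p_ctrl = _cell_distributions(spec)
    n_case = int(round(spec.n * spec.case_fraction))
    n_ctrl = spec.n - n_case
    rng = np.random.default_rng(seed)
    # 8 covariate patterns: (case, ctrl) x (G, E) cells
    G = np.array([0, 0, 1, 1], dtype=float)
    E = np.array([0, 1, 0, 1], dtype=float)
    X = np.column_stack([np.ones(8), np.tile(G, 2), np.tile(E, 2), np.tile(G * E, 2)])
    y = np.array([1.0] * 4 + [0.0] * 4)
    names = ["intercept", "g", "e", "g:e"]
    hits = 0
    for _ in range(n_reps):
        cc = rng.multinomial(n_case, p_case.ravel())
        nc = rng.multinomial(n_ctrl, p_ctrl.ravel())
        w = np.concatenate([cc, nc]).astype(float)
        keep = w > 0
        try:
            fit = fit_logistic(X[keep], y[keep], weights=w[keep], term_names=names)
        except ValueError:
            continue
        if fit.converged and fit.table.loc["g:e", "p"] < spec.alpha:
            hits += 1
    phat = hits / n_reps
    half = 1.96 * np.sqrt(phat * (1 - phat) / n_reps)
    return phat, (phat - half, phat + half)
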