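"""Synthetic case-control cohorts with C4 structural-haplotype architecture.

The generator emulates the statistical structure the association analysis
assumes, with a full truth record for parameter-recovery testing:

* 2N structural haplotypes drawn i.i.d. from a configurable frequency
  table (defaults cover the common European haplotypes);
* SNP/HLA-style biallelic variants placed in tunable LD with a haplotype
  or a copy-number channel by copying the per-haplotype anchor indicator
  with a flip probability solved to hit a target r²;
* case status drawn from a logistic model over the copy-number channels
  and covariates, mirroring the most complex interaction risk model
  (C4A, C4B, HERV-K mains plus C4A:C4B, C4A:HERV-K, C4B:HERV-K,
  C4A:sex, C4B:sex);
* C4A/C4B expression linear in the long/short copy-number channels, and
  serum C4 protein linear in total C4, HERV-K, sex, age and disease, both
  with Gaussian noise.

Sex is coded female=0 / male=1; genetic PCs are standard normals
uncorrelated with genotype; the cohort label has no true effect unless
betas are configured for it.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from . import io as c4io
from .dosage import (
    CN_CHANNELS,
    DEFAULT_COMPOSITIONS,
    DEFAULT_FREQUENCIES,
    HaplotypeComposition,
    compute_cn_dosages,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SimulatedCohort",
    "DEFAULT_RISK_BETAS",
    "DEFAULT_EXPRESSION_COEFS",
    "DEFAULT_PROTEIN_COEFS",
    "DEFAULT_NOISE_SDS",
    "sample_cohort",
    "attach_linked_variants",
    "simulate_status",
    "simulate_quantitative",
    "simulate_cohort",
    "export_cohort",
    "load_truth",
]


#: Default generating log-odds for case status: the interaction risk model
#: with published effect sizes for the main and interaction terms.  The
#: intercept is calibrated so the default cohort shows roughly the study's
#: 34% case fraction given the default haplotype frequencies.
DEFAULT_RISK_BETAS: dict[str, float] = {
    "intercept": -0.05,
    "sex": -1.35,
    "c4a": -0.31,
    "c4b": -0.20,
    "hervk": 0.16,
    "c4a:c4b": -0.14,
    "c4a:hervk": 0.042,
    "c4b:hervk": 0.085,
    "c4a:sex": -0.17,
    "c4b:sex": 0.13,
}

#: Default expression effects per gene copy.  Short forms drive expression
#: harder than long forms (the HERV-K insertion suppresses its host gene),
#: and each isotype's model carries a small cross-channel contribution from
#: the other isotype's copies.
DEFAULT_EXPRESSION_COEFS: dict[str, dict[str, float]] = {
    "c4a_expr": {"intercept": 1.0, "al": 0.30, "as": 0.55, "bl": 0.08, "bs": 0.12},
    "c4b_expr": {"intercept": 1.0, "bl": 0.30, "bs": 0.55, "al": 0.08, "as": 0.12},
}

#: Default serum-protein effects: protein rises with total C4 copies, falls
#: with HERV-K copies and disease, is higher in males, and drifts with age.
DEFAULT_PROTEIN_COEFS: dict[str, float] = {
    "intercept": 0.6,
    "c4_total": 0.25,
    "hervk": -0.03,
    "sex": 0.04,
    "age": 0.001,
    "disease": -0.02,
}

#: Noise levels calibrated so copy number explains roughly a quarter of
#: expression variance and the protein model roughly an eighth of protein
#: variance under the default coefficients and haplotype frequencies.
DEFAULT_NOISE_SDS: dict[str, float] = {"c4a_expr": 0.35, "c4b_expr": 0.35, "protein": 0.4}


@dataclass
class SimulationConfig:
    """Generating parameters for one synthetic cohort."""

    n_individuals: int = 1000
    haplotype_freqs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FREQUENCIES))
    male_fraction: float = 0.306
    n_snps: int = 0
    #: (snp id, anchor, target r²); anchor is a haplotype name or CN channel.
    ld_targets: list[tuple[str, str, float]] = field(default_factory=list)
    risk_betas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RISK_BETAS))
    expression_coefs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EXPRESSION_COEFS.items()}
    )
    protein_coefs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PROTEIN_COEFS))
    noise_sds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SDS))
    n_cohorts: int = 1
    seed: int = 0
    #: optional imputed-style dosage noise: perturbs haplotype dosages and
    #: renormalizes rows to sum at most 2 (default off: rows sum exactly 2).
    dosage_noise_sd: float = 0.0
    compositions: list[HaplotypeComposition] = field(
        default_factory=lambda: list(DEFAULT_COMPOSITIONS)
    )

    def __post_init__(self) -> None:
        total = sum(self.haplotype_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total}, expected 1")
        if any(f < 0 for f in self.haplotype_freqs.values()):
            raise ValueError("haplotype frequencies must be non-negative")
        if not (0 <= self.male_fraction <= 1):
            raise ValueError("male_fraction must lie in [0, 1]")
        for vid, anchor, r2 in self.ld_targets:
            if not (0 <= r2 <= 1):
                raise ValueError(f"target r² for {vid} outside [0, 1]: {r2}")
        known = set(self.haplotype_freqs)
        have = {c.name for c in self.compositions}
        missing = known - have
        if missing:
            raise ValueError(f"haplotypes without composition entry: {sorted(missing)}")

    def rng(self, stream: int) -> np.random.Generator:
        # independent, order-insensitive stream per pipeline stage
        return np.random.default_rng([int(self.seed) % 2**31, stream])


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated cohort."""

    hap_pairs: np.ndarray  # (N, 2) haplotype names
    cn_profile: pd.DataFrame
    covariates: pd.DataFrame  # sex, age, cohort, PC1-5
    betas: dict[str, float] | None = None
    S: pd.Series | None = None  # linear predictor of the status model
    ld_info: pd.DataFrame | None = None  # variant, anchor, target_r2, flip_prob, realized_r2
    hap_alleles: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


@dataclass
class SimulatedCohort:
    """Bundle of all tables produced by :func:`simulate_cohort`."""

    hap_dosages: pd.DataFrame
    cohort: pd.DataFrame
    truth: SyntheticTruth
    variants: pd.DataFrame | None = None
    expression: pd.DataFrame | None = None
    protein: pd.DataFrame | None = None
    config: SimulationConfig | None = None


# ---------------------------------------------------------------------------
# sampling


def sample_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw 2N haplotypes and covariates; returns (dosages, cohort table, truth).

    Haplotype dosage rows sum to exactly 2 (unimputed data) unless the
    imputed-style ``dosage_noise_sd`` switch is on.  Sex ~ Bernoulli(male
    fraction), age ~ Uniform(18, 80), cohort label uniform over
    ``n_cohorts``, five genetic PCs ~ N(0, 1).
    """
    rng = config.rng(0)
    n = config.n_individuals
    names = sorted(config.haplotype_freqs)
    freqs = np.array([config.haplotype_freqs[h] for h in names], dtype=float)
    freqs = freqs / freqs.sum()
    draws = rng.choice(len(names), size=(n, 2), p=freqs)
    hap_pairs = np.array(names, dtype=object)[draws]
    counts = np.zeros((n, len(names)))
    for k in range(len(names)):
        counts[:, k] = (draws == k).sum(axis=1)
    index = pd.Index([f"S{i:06d}" for i in range(n)], name="sample_id")
    hap_dosages = pd.DataFrame(counts, index=index, columns=names)
    if config.dosage_noise_sd > 0:
        noisy = np.clip(counts + rng.normal(0, config.dosage_noise_sd, counts.shape), 0, None)
        target = 2.0 * (1 - np.abs(rng.normal(0, config.dosage_noise_sd / 2, n)))
        rowsum = noisy.sum(axis=1)
        rowsum[rowsum == 0] = 1.0
        hap_dosages = pd.DataFrame(
            noisy * (target / rowsum)[:, None], index=index, columns=names
        )

    sex = (rng.random(n) < config.male_fraction).astype(int)
    age = rng.uniform(18, 80, n)
    cohort_label = np.array([f"cohort{j + 1}" for j in rng.integers(0, config.n_cohorts, n)])
    pcs = rng.standard_normal((n, 5))
    covar = pd.DataFrame(
        {"sex": sex, "age": age, "cohort": cohort_label},
        index=index,
    )
    for j in range(5):
        covar[f"PC{j + 1}"] = pcs[:, j]
    cn = compute_cn_dosages(hap_dosages, config.compositions)
    truth = SyntheticTruth(hap_pairs=hap_pairs, cn_profile=cn, covariates=covar)
    return hap_dosages, covar.copy(), truth


# ---------------------------------------------------------------------------
# linked variants


def _anchor_indicator(
    hap_pairs: np.ndarray, anchor: str, compositions: Sequence[HaplotypeComposition]
) -> np.ndarray:
    """Per-haplotype 0/1 anchor indicator, shape (N, 2).

    A haplotype-name anchor marks chromosomes carrying that haplotype; a
    channel anchor (al/as/bl/bs/c4a/c4b/hervk/c4_total) marks chromosomes
    carrying at least one copy on that channel.
    """
    comps = {c.name: c for c in compositions}
    names = set(comps)
    if anchor in names:
        return (hap_pairs == anchor).astype(float)
    if anchor in CN_CHANNELS:
        carrier = {h: float(comps[h].channel(anchor) >= 1) for h in names}
        lut = np.vectorize(carrier.get)
        return lut(hap_pairs).astype(float)
    raise KeyError(f"unknown LD anchor {anchor!r}: not a haplotype name or CN channel")


def _solve_flip_prob(q: float, target_r2: float) -> float:
    """Flip probability giving squared correlation target_r2 with a
    Bernoulli(q) indicator under symmetric flipping."""
    if not 0 < q < 1:
        raise ValueError("anchor indicator is constant; LD target unattainable")
    target_r = float(np.sqrt(target_r2))

    def corr(eps: float) -> float:
        m = q * (1 - eps) + (1 - q) * eps
        denom = np.sqrt(q * (1 - q) * m * (1 - m))
        return (1 - 2 * eps) * q * (1 - q) / denom if denom > 0 else 0.0

    if target_r >= 1.0:
        return 0.0
    if target_r <= 0.0:
        return 0.5
    return float(optimize.brentq(lambda e: corr(e) - target_r, 0.0, 0.5, xtol=1e-12))


def attach_linked_variants(truth: SyntheticTruth, config: SimulationConfig) -> pd.DataFrame:
    """Generate biallelic variant dosages in configured LD with C4 anchors.

    Each LD-target variant copies its anchor's per-haplotype indicator with
    the flip probability that yields the target diploid r²; the realized r²
    is recorded in ``truth.ld_info``.  Variants beyond the LD targets (up to
    ``config.n_snps``) are independent Bernoulli draws at a random MAF in
    [0.05, 0.5].
    """
    rng = config.rng(1)
    n = len(truth.cn_profile)
    cols: dict[str, np.ndarray] = {}
    records = []
    for vid, anchor, r2 in config.ld_targets:
        ind = _anchor_indicator(truth.hap_pairs, anchor, config.compositions)
        q = float(ind.mean())
        anchor_count = ind.sum(axis=1)
        if r2 >= 1.0:
            alleles = ind
            eps = 0.0
        else:
            eps = _solve_flip_prob(q, r2)
            flips = rng.random(ind.shape) < eps
            alleles = np.where(flips, 1 - ind, ind)
        dosage = alleles.sum(axis=1)
        if np.std(dosage) > 0 and np.std(anchor_count) > 0:
            realized = float(np.corrcoef(dosage, anchor_count)[0, 1] ** 2)
        else:
            realized = np.nan
        cols[vid] = dosage
        truth.hap_alleles[vid] = alleles
        records.append(
            {"variant": vid, "anchor": anchor, "target_r2": r2, "flip_prob": eps, "realized_r2": realized}
        )
    n_extra = max(0, config.n_snps - len(config.ld_targets))
    for j in range(n_extra):
        maf = rng.uniform(0.05, 0.5)
        vid = f"snp{j + 1:05d}"
        cols[vid] = rng.binomial(1, maf, (n, 2)).sum(axis=1).astype(float)
        records.append(
            {"variant": vid, "anchor": None, "target_r2": np.nan, "flip_prob": np.nan, "realized_r2": np.nan}
        )
    truth.ld_info = pd.DataFrame(records)
    return pd.DataFrame(cols, index=truth.cn_profile.index, dtype=float)


# ---------------------------------------------------------------------------
# outcomes and quantitative traits


def _status_design_column(term: str, truth: SyntheticTruth) -> pd.Series:
    cn, cov = truth.cn_profile, truth.covariates
    if term == "intercept":
        return pd.Series(1.0, index=cn.index)
    if ":" in term:
        a, b = term.split(":", 1)
        return _status_design_column(a, truth) * _status_design_column(b, truth)
    if term in cn.columns:
        return cn[term]
    if term in cov.columns:
        return pd.to_numeric(cov[term])
    low = {c.lower(): c for c in cov.columns}
    if term.lower() in low:
        return pd.to_numeric(cov[low[term.lower()]])
    raise KeyError(f"no design column for risk term {term!r}")


def simulate_status(
    truth: SyntheticTruth,
    risk_betas: Mapping[str, float],
    *,
    rng: np.random.Generator | None = None,
    config: SimulationConfig | None = None,
) -> pd.Series:
    """Draw case status ~ Bernoulli(expit(S)), S = sum beta_t * x_t.

    Terms are keyed by channel/covariate name, with ``a:b`` denoting a
    product; ``intercept`` is required.  The realized linear predictor and
    betas are stored on the truth record.
    """
    if rng is None:
        rng = config.rng(2) if config is not None else np.random.default_rng(0)
    if "intercept" not in risk_betas:
        raise KeyError("risk_betas must include an 'intercept' term")
    S = pd.Series(0.0, index=truth.cn_profile.index)
    for term, beta in risk_betas.items():
        S = S + beta * _status_design_column(term, truth)
    prob = special.expit(S)
    status = pd.Series(
        (rng.random(len(S)) < prob).astype(int), index=S.index, name="status"
    )
    truth.S = S.rename("S")
    truth.betas = dict(risk_betas)
    return status


def _trait_column(term: str, truth: SyntheticTruth, status: pd.Series | None) -> pd.Series:
    if term == "intercept":
        return pd.Series(1.0, index=truth.cn_profile.index)
    if term == "disease":
        if status is None:
            raise KeyError("trait model references 'disease' but no status was simulated")
        return status.astype(float)
    return _status_design_column(term, truth)


def simulate_quantitative(
    truth: SyntheticTruth,
    expression_coefs: Mapping[str, Mapping[str, float]],
    protein_coefs: Mapping[str, float],
    noise_sds: Mapping[str, float],
    *,
    status: pd.Series | None = None,
    rng: np.random.Generator | None = None,
    config: SimulationConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate expression traits and serum protein as linear models + noise.

    Expression traits are linear in the long/short copy-number channels;
    protein is linear in total C4, HERV-K, sex, age and disease.  Noise is
    Gaussian with per-trait standard deviations from ``noise_sds`` (a trait
    absent from ``noise_sds`` is noiseless).
    """
    if rng is None:
        rng = config.rng(3) if config is not None else np.random.default_rng(0)
    idx = truth.cn_profile.index
    expr = pd.DataFrame(index=idx)
    for trait, coefs in expression_coefs.items():
        mean = pd.Series(0.0, index=idx)
        for term, c in coefs.items():
            mean = mean + c * _trait_column(term, truth, status)
        sd = float(noise_sds.get(trait, 0.0))
        expr[trait] = mean + (rng.normal(0, sd, len(idx)) if sd > 0 else 0.0)
    if {"c4a_expr", "c4b_expr"} <= set(expr.columns):
        expr["c4_total_expr"] = expr["c4a_expr"] + expr["c4b_expr"]

    mean = pd.Series(0.0, index=idx)
    for term, c in protein_coefs.items():
        mean = mean + c * _trait_column(term, truth, status)
    sd = float(noise_sds.get("protein", 0.0))
    protein = pd.DataFrame(
        {"protein": mean + (rng.normal(0, sd, len(idx)) if sd > 0 else 0.0)}, index=idx
    )
    return expr, protein


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Run the full generator: haplotypes, variants, status, traits."""
    hap_dosages, cohort, truth = sample_cohort(config)
    variants = None
    if config.n_snps > 0 or config.ld_targets:
        variants = attach_linked_variants(truth, config)
    status = simulate_status(truth, config.risk_betas, rng=config.rng(2))
    cohort.insert(0, "status", status)
    expression = protein = None
    if config.expression_coefs or config.protein_coefs:
        expression, protein = simulate_quantitative(
            truth,
            config.expression_coefs,
            config.protein_coefs,
            config.noise_sds,
            status=status,
            rng=config.rng(3),
        )
    return SimulatedCohort(
        hap_dosages=hap_dosages,
        cohort=cohort,
        truth=truth,
        variants=variants,
        expression=expression,
        protein=protein,
        config=config,
    )


# ---------------------------------------------------------------------------
# export / import


def export_cohort(
    sim: SimulatedCohort, out_dir: str | os.PathLike, *, fmt: str = "vcf"
) -> dict[str, Path]:
    """Write all cohort tables plus the truth record to ``out_dir``.

    Haplotype and variant dosages go to VCF (DS field; haplotypes as
    symbolic-ALT pseudo-variants) or TSV, phenotype/expression/protein to
    TSV, and the truth (betas, LD records, linear predictor) to JSON.
    Round-trips losslessly through the package readers.
    """
    if fmt not in ("vcf", "tsv"):
        raise ValueError(f"unknown export format {fmt!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if fmt == "vcf":
        paths["haplotypes"] = out / "haplotypes.vcf"
        c4io.write_dosage_vcf(paths["haplotypes"], sim.hap_dosages, symbolic_alt=True)
        if sim.variants is not None:
            paths["variants"] = out / "variants.vcf"
            c4io.write_dosage_vcf(paths["variants"], sim.variants, start_pos=28_510_120)
    else:
        paths["haplotypes"] = out / "haplotypes.tsv"
        c4io.write_matrix_tsv(paths["haplotypes"], sim.hap_dosages)
        if sim.variants is not None:
            paths["variants"] = out / "variants.tsv"
            c4io.write_matrix_tsv(paths["variants"], sim.variants)
    paths["phenotypes"] = out / "phenotypes.tsv"
    c4io.write_matrix_tsv(paths["phenotypes"], sim.cohort)
    if sim.expression is not None:
        paths["expression"] = out / "expression.tsv"
        c4io.write_matrix_tsv(paths["expression"], sim.expression)
    if sim.protein is not None:
        paths["protein"] = out / "protein.tsv"
        c4io.write_matrix_tsv(paths["protein"], sim.protein)

    truth = sim.truth
    record = {
        "betas": truth.betas,
        "hap_pairs": truth.hap_pairs.tolist(),
        "S": truth.S.tolist() if truth.S is not None else None,
        "ld_info": truth.ld_info.to_dict(orient="records") if truth.ld_info is not None else [],
        "seed": sim.config.seed if sim.config is not None else None,
    }
    paths["truth"] = out / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(record, fh, indent=1)
    return paths


def load_truth(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return json.load(fh)
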