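"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the study's ingredients at desk scale: an
LD-structured reference panel with AR(1)-style decay of r^2 along the
chromosome, two-sample GWAS summary statistics under a linear causal
model (outcome effect = theta x exposure effect + directional pleiotropy
+ sampling noise, the regime the IVW/Egger estimators assume, with
pleiotropy independent of instrument strength so InSIDE holds), gene
annotations with planted signal regions, and a cohort with a
liability-scale binary outcome modulated by a drug covariate.

Every generator is a pure function of its :class:`SimConfig`; the one
seed is split deterministically per sub-generator so adding a generator
does not perturb existing streams.  Summary statistics are drawn
directly from the effect/noise model rather than by regressing simulated
genotypes: estimator tests need exactly known betas, and the panel is
needed only for LD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import GeneRegion, GeneSelection, LDReference

# fixed stream ids so generator streams stay independent and stable
_STREAM_PANEL = 1
_STREAM_GWAS = 2
_STREAM_ANNOTATION = 3
_STREAM_COHORT = 4
_STREAM_WEIGHTS = 5

#: non-palindromic allele pairs assigned to simulated variants
_ALLELE_PAIRS = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]


@dataclass
class SimConfig:
    """All knobs for the synthetic study, with the default conditions the
    estimator checks are run under.

    Defaults: 50k-sample exposure and outcome GWAS, a true causal effect
    of 0.3 (log-odds per exposure unit), 20 strong instruments among 400
    variants, no pleiotropy, and a 20,000-person cohort whose binary
    outcome follows logit(p) = -1 + 0.4 x standardized PRS - 0.3 x drug.
    """

    seed: int
    n_variants: int = 400
    n_individuals_panel: int = 2000
    ld_decay: float = 0.8  # AR(1) rho between adjacent variants
    maf_range: tuple[float, float] = (0.05, 0.5)
    variant_spacing_bp: int = 10_000
    n_exposure: int = 50_000
    n_outcome: int = 50_000
    theta: float = 0.3
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    instrument_fraction: float = 0.05
    # lower bound chosen so per-instrument F = (beta/se)^2 exceeds ~30
    # at n = 50k even for the rarest allowed MAF (strong instruments)
    instrument_beta_range: tuple[float, float] = (0.08, 0.20)
    cohort_n: int = 20_000
    cohort_n_variants: int = 200
    cohort_n_chromosomes: int = 4
    cohort_missing_rate: float = 0.0
    intercept: float = -1.0
    prs_coef: float = 0.4
    drug_coef: float = -0.3
    drug_prevalence: float = 0.1
    drug_confounding: float = 0.0  # effect of the score on drug uptake

    def __post_init__(self):
        if not 0 <= self.ld_decay < 1:
            raise ValueError("ld_decay must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if not 0 < self.instrument_fraction <= 1:
            raise ValueError("instrument_fraction must be in (0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


@dataclass
class PanelData:
    """A simulated reference panel with its realized pairwise r^2."""

    dosages: np.ndarray  # individuals x variants, counts in {0, 1, 2}
    variant_map: pd.DataFrame  # variant_id, chromosome, position, maf, alleles
    r2: np.ndarray  # realized squared correlation, monomorphic rows zeroed

    def ld_reference(self) -> LDReference:
        return LDReference.from_matrix(
            self.r2, self.variant_map["variant_id"], self.variant_map["chromosome"]
        )


def _variant_map(config: SimConfig, mafs: np.ndarray) -> pd.DataFrame:
    m = config.n_variants
    pairs = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(m)]
    return pd.DataFrame(
        {
            "variant_id": [f"rs{i + 1}" for i in range(m)],
            "chromosome": "1",
            "position": (np.arange(m) + 1) * config.variant_spacing_bp,
            "maf": mafs,
            "effect_allele": [p[0] for p in pairs],
            "other_allele": [p[1] for p in pairs],
        }
    )


def simulate_panel(config: SimConfig) -> PanelData:
    """Simulate a dosage panel whose r^2 decays like rho^(2 x lag).

    Haplotypes come from a latent Gaussian AR(1) process thresholded at
    the per-variant allele frequency; dosage is the sum of two
    independent haplotypes.  The realized empirical r^2 matrix is
    returned so clumping can be tested against the exact LD the panel
    carries.
    """
    rng = config.rng(_STREAM_PANEL)
    n, m, rho = config.n_individuals_panel, config.n_variants, config.ld_decay
    # allele frequency varies smoothly along the chromosome: thresholding
    # a latent Gaussian attenuates correlation badly when adjacent
    # thresholds differ, so neighbouring variants get similar MAFs
    mafs = np.sort(rng.uniform(*config.maf_range, size=m))
    thresholds = stats.norm.ppf(mafs)

    def haplotypes() -> np.ndarray:
        eps = rng.standard_normal((n, m))
        z = np.empty((n, m))
        z[:, 0] = eps[:, 0]
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * eps[:, j]
        return (z < thresholds).astype(np.int8)

    dosages = (haplotypes() + haplotypes()).astype(np.int8)
    sd = dosages.std(axis=0)
    poly = sd > 0
    r2 = np.zeros((m, m))
    if poly.sum() >= 2:
        corr = np.corrcoef(dosages[:, poly].astype(float), rowvar=False)
        r2[np.ix_(poly, poly)] = corr**2
    np.fill_diagonal(r2, 1.0)
    return PanelData(dosages=dosages, variant_map=_variant_map(config, mafs), r2=r2)


def simulate_two_sample_gwas(
    config: SimConfig,
    panel: PanelData | None = None,
    instrument_indices: np.ndarray | list[int] | None = None,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
):
    """Two-sample GWAS summary statistics under the linear causal model.

    True exposure effects are positive (allele coding is free, so this is
    the oriented representation) and nonzero for ``instrument_fraction``
    of variants, or exactly at ``instrument_indices`` when given.  The
    true outcome effect is theta x true exposure effect plus a
    per-instrument pleiotropy term ~ N(pleiotropy_mean, pleiotropy_sd^2)
    drawn independently of instrument strength.  Observed statistics add
    sampling noise with per-variant standard errors
    1 / sqrt(2 maf (1-maf) N); p-values satisfy
    p = 2 (1 - Phi(|beta/se|)) exactly.

    Returns cleaned-format exposure and outcome record tables plus a
    truth record holding every latent quantity.
    """
    from .sumstats_io import SummaryStatsSet

    rng = config.rng(_STREAM_GWAS)
    if panel is not None:
        vmap = panel.variant_map
    else:
        mafs = rng.uniform(*config.maf_range, size=config.n_variants)
        vmap = _variant_map(config, mafs)
    m = len(vmap)
    mafs = vmap["maf"].to_numpy()

    if instrument_indices is None:
        k = max(1, round(config.instrument_fraction * m))
        instrument_indices = np.sort(rng.choice(m, size=k, replace=False))
    else:
        instrument_indices = np.sort(np.asarray(instrument_indices, dtype=int))
    is_inst = np.zeros(m, dtype=bool)
    is_inst[instrument_indices] = True

    bx_true = np.zeros(m)
    lo, hi = config.instrument_beta_range
    bx_true[is_inst] = rng.uniform(lo, hi, size=is_inst.sum())
    pleio = np.zeros(m)
    if config.pleiotropy_sd > 0 or config.pleiotropy_mean != 0:
        pleio[is_inst] = rng.normal(
            config.pleiotropy_mean, config.pleiotropy_sd, size=is_inst.sum()
        )
    by_true = config.theta * bx_true + pleio

    se_x = 1.0 / np.sqrt(2 * mafs * (1 - mafs) * config.n_exposure)
    se_y = 1.0 / np.sqrt(2 * mafs * (1 - mafs) * config.n_outcome)
    bx_obs = bx_true + rng.normal(0, se_x)
    by_obs = by_true + rng.normal(0, se_y)

    def make_set(name: str, beta, se, n: int) -> "SummaryStatsSet":
        p = 2 * stats.norm.sf(np.abs(beta / se))
        records = pd.DataFrame(
            {
                "variant_id": vmap["variant_id"],
                "chromosome": vmap["chromosome"],
                "position": vmap["position"],
                "effect_allele": vmap["effect_allele"],
                "other_allele": vmap["other_allele"],
                "eaf": mafs,
                "beta": beta,
                "se": se,
                "pvalue": np.clip(p, np.finfo(float).tiny, 1.0),
                "n": n,
            }
        )
        return SummaryStatsSet(trait_name=name, records=records, genome_build="simulated")

    exposure = make_set(exposure_name, bx_obs, se_x, config.n_exposure)
    # swap allele labels (and flip betas/EAF) for a random half of the
    # outcome's variants so harmonization is exercised on realistic input
    swap = rng.random(m) < 0.5
    out_records_beta = np.where(swap, -by_obs, by_obs)
    outcome = make_set(outcome_name, out_records_beta, se_y, config.n_outcome)
    outcome.records.loc[swap, ["effect_allele", "other_allele"]] = (
        outcome.records.loc[swap, ["other_allele", "effect_allele"]].to_numpy()
    )
    outcome.records.loc[swap, "eaf"] = 1 - outcome.records.loc[swap, "eaf"]

    truth = {
        "theta": config.theta,
        "instrument_indices": instrument_indices.tolist(),
        "instrument_ids": vmap.loc[is_inst, "variant_id"].tolist(),
        "beta_exposure_true": bx_true.tolist(),
        "beta_outcome_true": by_true.tolist(),
        "pleiotropy": pleio.tolist(),
        "label_swapped": swap.tolist(),
    }
    return exposure, outcome, truth


def simulate_gene_annotation(
    config: SimConfig,
    variant_map: pd.DataFrame,
    planted_genes: int = 2,
    flank: int = 0,
) -> tuple[list[GeneSelection], dict]:
    """Disjoint gene intervals over the variant map with known membership.

    The variant range is cut into ``planted_genes`` equal contiguous
    blocks separated by gaps wider than twice the flank, so a planted
    instrument block lands inside exactly one gene.  Returns one
    selection per gene plus an all-genes selection, and a truth record of
    each gene's variant indices.
    """
    if planted_genes < 1:
        raise ValueError("planted_genes must be >= 1")
    m = len(variant_map)
    positions = variant_map["position"].to_numpy()
    bounds = np.linspace(0, m, planted_genes + 1).astype(int)
    regions, gene_variants = [], {}
    for g in range(planted_genes):
        lo_i, hi_i = bounds[g], bounds[g + 1] - 1
        if hi_i < lo_i:
            raise ValueError("more genes than variants")
        name = f"GENE{g + 1}"
        # trim the interval so consecutive flanked genes stay disjoint
        start = int(positions[lo_i])
        end = int(positions[hi_i])
        if g > 0:
            start += flank + 1
            lo_i += int(np.searchsorted(positions[lo_i:hi_i + 1], start))
        regions.append(
            GeneRegion(gene_symbol=name, chromosome="1", start=start, end=end, flank=flank)
        )
        gene_variants[name] = list(range(lo_i, hi_i + 1))
    selections = [GeneSelection(name="all_genes", regions=list(regions))]
    selections += [GeneSelection(name=r.gene_symbol, regions=[r]) for r in regions]
    return selections, {"gene_variant_indices": gene_variants}


def simulate_weights(config: SimConfig, weight_sd: float = 0.05) -> pd.DataFrame:
    """A weight table over the cohort's variants (posterior-style effects)."""
    rng = config.rng(_STREAM_WEIGHTS)
    m = config.cohort_n_variants
    chroms = np.sort(np.arange(m) % config.cohort_n_chromosomes + 1).astype(str)
    pairs = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(m)]
    return pd.DataFrame(
        {
            "variant_id": [f"prs_rs{i + 1}" for i in range(m)],
            "chromosome": chroms,
            "effect_allele": [p[0] for p in pairs],
            "weight": rng.normal(0, weight_sd, size=m),
        }
    )


def simulate_prs_cohort(config: SimConfig, weights: pd.DataFrame):
    """A cohort of dosages, drug status and a PRS-driven binary outcome.

    Dosages are Binomial(2, maf); missing entries (NaN) appear at
    ``cohort_missing_rate``.  The true score is sum(dosage x weight) over
    all variants (complete data); the outcome is Bernoulli with
    logit(p) = intercept + prs_coef x standardized true score
    + drug_coef x drug_status.  Drug uptake is Bernoulli at
    ``drug_prevalence``, optionally tilted by the score
    (``drug_confounding``) for negative-control designs.

    Returns (dosages DataFrame with NaNs, phenotype DataFrame, truth).
    """
    rng = config.rng(_STREAM_COHORT)
    n = config.cohort_n
    m = len(weights)
    mafs = rng.uniform(*config.maf_range, size=m)
    full = rng.binomial(2, mafs, size=(n, m)).astype(float)

    w = weights["weight"].to_numpy()
    true_score = full @ w
    z = (true_score - true_score.mean()) / true_score.std(ddof=1)

    base = np.log(config.drug_prevalence / (1 - config.drug_prevalence))
    p_drug = 1 / (1 + np.exp(-(base + config.drug_confounding * z)))
    drug = rng.binomial(1, p_drug)

    lin = config.intercept + config.prs_coef * z + config.drug_coef * drug
    outcome = rng.binomial(1, 1 / (1 + np.exp(-lin)))

    dosages = full.copy()
    if config.cohort_missing_rate > 0:
        mask = rng.random((n, m)) < config.cohort_missing_rate
        dosages[mask] = np.nan

    ids = [f"ind{i + 1}" for i in range(n)]
    dosages_df = pd.DataFrame(dosages, index=ids, columns=list(weights["variant_id"]))
    pheno = pd.DataFrame(
        {"individual_id": ids, "outcome": outcome, "drug_status": drug}
    ).set_index("individual_id")
    truth = {
        "true_score": true_score.tolist(),
        "standardized_true_score": z.tolist(),
        "intercept": config.intercept,
        "prs_coef": config.prs_coef,
        "drug_coef": config.drug_coef,
        "maf": mafs.tolist(),
    }
    return dosages_df, pheno, truth
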