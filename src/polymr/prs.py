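"""Polygenic risk scoring and drug-adjusted logistic association.

Per-chromosome scores are the mean over scored variants of
dosage x weight; genome-wide scores aggregate them with
individual-level, per-chromosome variant counts as weights,

    PRS_j = sum_i PRS_ji K_ji / sum_i K_ji,

which makes the aggregation robust to within-chromosome missing
dosages (a variant missing for individual j drops out of both the
chromosome mean and K_ji for j only).  Scores are standardized and
entered, together with drug prescription status, into a logistic
regression for each binary outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import AssociationError, PolymrError
from .sumstats_io import COMPLEMENT

WEIGHT_COLUMNS = ["variant_id", "chromosome", "effect_allele", "weight"]


@dataclass
class PRSComponents:
    """Per-individual, per-chromosome score means and variant counts.

    Both frames are individuals x chromosomes; ``counts`` holds K_ji and
    ``scores`` is NaN wherever K_ji = 0.
    """

    scores: pd.DataFrame
    counts: pd.DataFrame


@dataclass
class AssociationModel:
    """A fitted logistic model for outcome ~ PRS + drug status (+ covariates)."""

    outcome_name: str
    table: pd.DataFrame  # predictor, coef, se, ci_low, ci_high, pvalue
    n_cases: int
    n_controls: int
    converged: bool
    n_iterations: int | None = None

    def coef(self, predictor: str) -> float:
        return float(self.table.set_index("predictor").loc[predictor, "coef"])


def _validate_weights(weights: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in WEIGHT_COLUMNS if c not in weights.columns]
    if missing:
        raise PolymrError(f"weight table missing columns: {missing}")
    if weights["variant_id"].duplicated().any():
        raise PolymrError("weight table has duplicated variant ids")
    if not np.isfinite(weights["weight"]).all():
        raise PolymrError("weight table has non-finite weights")
    return weights


def per_chromosome_scores(
    dosages: pd.DataFrame,
    weights: pd.DataFrame,
    dosage_alleles: Mapping[str, str] | None = None,
) -> PRSComponents:
    """Mean dosage-weighted score and variant count per chromosome.

    ``dosages`` is individuals x variants with effect-allele counts in
    [0, 2]; missing dosages are NaN (never 0).  ``dosage_alleles`` maps
    each variant to the allele its dosage column counts; when that allele
    is neither the weight's effect allele nor its strand complement the
    dosage is flipped to ``2 - d``.
    """
    weights = _validate_weights(weights)
    shared = [v for v in weights["variant_id"] if v in dosages.columns]
    if not shared:
        raise PolymrError("no variants shared between dosages and weight table")
    w = weights.set_index("variant_id").loc[shared]

    D = dosages[shared].astype(float).copy()
    if dosage_alleles is not None:
        for vid in shared:
            counted = dosage_alleles.get(vid)
            if counted is None:
                continue
            ea = w.loc[vid, "effect_allele"]
            if counted != ea and COMPLEMENT.get(counted) != ea:
                D[vid] = 2.0 - D[vid]

    contrib = D * w["weight"].to_numpy()
    chrom = w["chromosome"].astype(str)
    scores = {}
    counts = {}
    for c in sorted(chrom.unique()):
        cols = [v for v in shared if chrom[v] == c]
        k = D[cols].notna().sum(axis=1)
        s = contrib[cols].sum(axis=1, min_count=1) / k.replace(0, np.nan)
        scores[c] = s
        counts[c] = k
    return PRSComponents(scores=pd.DataFrame(scores), counts=pd.DataFrame(counts))


def aggregate_prs(components: PRSComponents) -> tuple[pd.Series, list]:
    """Genome-wide score as the K-weighted mean of per-chromosome scores.

    Individuals with no scored variant on any chromosome are dropped and
    returned in the second element.
    """
    k = components.counts
    s = components.scores
    total_k = k.sum(axis=1)
    numer = (s * k).sum(axis=1, min_count=1)
    keep = total_k > 0
    dropped = list(total_k.index[~keep])
    prs = numer[keep] / total_k[keep]
    prs.name = "prs"
    return prs, dropped


def standardize(scores: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Z-score with the sample (n-1) standard deviation."""
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise PolymrError("standardization requires at least 2 individuals")
    sd = x.std(ddof=1)
    if sd == 0:
        raise PolymrError("standardization undefined: scores have zero variance")
    z = (x - x.mean()) / sd
    if isinstance(scores, pd.Series):
        return pd.Series(z, index=scores.index, name=scores.name)
    return z


def fit_association(
    outcome: pd.Series | np.ndarray,
    prs: pd.Series | np.ndarray,
    drug_status: pd.Series | np.ndarray | None = None,
    covariates: pd.DataFrame | None = None,
    outcome_name: str = "outcome",
) -> AssociationModel:
    """Maximum-likelihood logistic fit of a binary outcome on the PRS,
    drug status and optional covariates (with intercept).

    Wald standard errors, 95% CIs and two-sided p-values per coefficient.
    Constant predictors, one-class outcomes, separation and
    non-convergence raise :class:`AssociationError` — no silent
    coefficients.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise AssociationError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise AssociationError("outcome has a single class; nothing to fit")

    X = pd.DataFrame({"prs": np.asarray(prs, dtype=float)})
    if drug_status is not None:
        X["drug_status"] = np.asarray(drug_status, dtype=float)
    if covariates is not None:
        for col in covariates.columns:
            X[col] = np.asarray(covariates[col], dtype=float)
    for col in X.columns:
        if X[col].nunique() < 2:
            raise AssociationError(f"predictor '{col}' is constant")

    design = sm.add_constant(X, prepend=True)
    try:
        fit = sm.Logit(y, design).fit(disp=False, maxiter=100)
    except Exception as exc:  # perfect separation, singular Hessian...
        raise AssociationError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise AssociationError("logistic fit did not converge")
    bse = np.asarray(fit.bse)
    if not np.all(np.isfinite(bse)):
        raise AssociationError("non-finite standard errors (possible separation)")

    ci = fit.conf_int()
    table = pd.DataFrame(
        {
            "predictor": design.columns,
            "coef": np.asarray(fit.params),
            "se": bse,
            "ci_low": np.asarray(ci)[:, 0],
            "ci_high": np.asarray(ci)[:, 1],
            "pvalue": np.asarray(fit.pvalues),
        }
    )
    return AssociationModel(
        outcome_name=outcome_name,
        table=table,
        n_cases=int(y.sum()),
        n_controls=int(len(y) - y.sum()),
        converged=True,
        n_iterations=fit.mle_retvals.get("iterations"),
    )
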