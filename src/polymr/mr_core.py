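"""Two-sample MR estimators: Wald ratio, IVW, MR-Egger, and the Rücker
model-selection ladder.

All estimators use first-order weights ``1 / se_outcome^2`` that ignore
exposure-side uncertainty.  Estimates are on the scale of the supplied
betas: log odds of the outcome per unit of exposure beta (per
effect-allele copy, or per 1 SD of the exposure if the exposure betas are
standardized).

P-value conventions, fixed to avoid silent cross-implementation drift:
normal for the Wald ratio and fixed-effect IVW; Student t with k-1 df for
multiplicative-random-effects IVW; t with k-2 df for both Egger variants.

Model selection follows the Rücker ladder on the heterogeneity statistics
Q (Cochran, IVW) and Q' (Rücker, Egger):

1. Q not significant against chi2(k-1)      -> fixed-effect IVW
2. Q - Q' not significant against chi2(1)   -> random-effects IVW
3. Q' not significant against chi2(k-2)     -> fixed-effect Egger
4. otherwise                                -> random-effects Egger

A single nominal level (default 0.05) is used for all three comparisons
and for the Egger-intercept pleiotropy flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateDesignError,
    InsufficientInstrumentsError,
    NoInstrumentsError,
    UndefinedRatioError,
)
from .instruments import InstrumentSet

Z95 = stats.norm.ppf(0.975)


@dataclass
class MRResult:
    """A causal-effect estimate with its selection and pleiotropy context."""

    method: str  # wald | ivw_fixed | ivw_random | egger_fixed | egger_random
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    q_ivw: float | None = None
    q_egger: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    pleiotropy_flag: bool = False
    decision_trace: list[dict] = field(default_factory=list)

    def to_row(self) -> dict:
        row = asdict(self)
        row["decision_trace"] = json.dumps(self.decision_trace)
        return row


def _extract(instruments) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(instruments, InstrumentSet):
        df = instruments.instruments
    elif isinstance(instruments, pd.DataFrame):
        df = instruments
    else:
        df = pd.DataFrame(instruments)
    bx = np.asarray(df["beta_exposure"], dtype=float)
    by = np.asarray(df["beta_outcome"], dtype=float)
    se = np.asarray(df["se_outcome"], dtype=float)
    return bx, by, se


def _ci(estimate: float, se: float, crit: float) -> tuple[float, float]:
    return estimate - crit * se, estimate + crit * se


def wald_ratio(instrument) -> MRResult:
    """Single-instrument estimate: beta_outcome / beta_exposure.

    The standard error is the first-order delta-method value
    ``se_outcome / |beta_exposure|`` (exposure uncertainty ignored).
    """
    bx, by, se = _extract(instrument if not isinstance(instrument, dict) else [instrument])
    if len(bx) != 1:
        raise ValueError("wald_ratio expects exactly one instrument")
    bx, by, se = float(bx[0]), float(by[0]), float(se[0])
    if bx == 0:
        raise UndefinedRatioError("Wald ratio undefined: exposure beta is zero")
    est = by / bx
    est_se = se / abs(bx)
    z = est / est_se
    lo, hi = _ci(est, est_se, Z95)
    return MRResult(
        method="wald",
        estimate=est,
        se=est_se,
        ci_low=lo,
        ci_high=hi,
        pvalue=float(2 * stats.norm.sf(abs(z))),
        n_snps=1,
    )


def ivw(instruments, random_effects: bool = False) -> MRResult:
    """Inverse-variance-weighted estimate (regression through the origin).

    Weighted least squares of beta_outcome on beta_exposure with weights
    1/se_outcome^2 and no intercept.  The multiplicative random-effects
    variant scales the fixed-effect variance by max(1, Q/(k-1)).
    """
    bx, by, se = _extract(instruments)
    k = len(bx)
    if k < 2:
        raise InsufficientInstrumentsError(f"IVW requires >= 2 instruments, got {k}")
    w = 1.0 / se**2
    denom = float(np.sum(w * bx**2))
    if denom == 0:
        raise DegenerateDesignError("all exposure betas are zero")
    est = float(np.sum(w * bx * by)) / denom
    se_fixed = np.sqrt(1.0 / denom)
    q = float(np.sum(w * (by - est * bx) ** 2))
    if random_effects:
        phi = max(1.0, q / (k - 1))
        est_se = se_fixed * np.sqrt(phi)
        crit = stats.t.ppf(0.975, df=k - 1)
        p = float(2 * stats.t.sf(abs(est / est_se), df=k - 1))
        method = "ivw_random"
    else:
        est_se = se_fixed
        crit = Z95
        p = float(2 * stats.norm.sf(abs(est / est_se)))
        method = "ivw_fixed"
    lo, hi = _ci(est, est_se, crit)
    return MRResult(
        method=method, estimate=est, se=float(est_se), ci_low=lo, ci_high=hi,
        pvalue=p, n_snps=k, q_ivw=q,
    )


def egger(instruments, random_effects: bool = False) -> MRResult:
    """MR-Egger: weighted regression with a free intercept.

    Instruments are oriented so every beta_exposure is non-negative
    (flipping beta_outcome in tandem) before fitting; the intercept then
    estimates average directional pleiotropy.  The slope is the causal
    estimate; Rücker's Q' is the weighted residual sum of squares.
    """
    bx, by, se = _extract(instruments)
    k = len(bx)
    if k < 3:
        raise InsufficientInstrumentsError(f"MR-Egger requires >= 3 instruments, got {k}")
    flip = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * flip, by * flip
    if np.ptp(bx) == 0:
        raise DegenerateDesignError("no variance in exposure betas after orientation")
    w = 1.0 / se**2
    X = np.column_stack([np.ones(k), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    cov_fixed = np.linalg.inv(xtwx)
    coef = cov_fixed @ xtwy
    resid = by - X @ coef
    q_prime = float(np.sum(w * resid**2))
    if random_effects:
        phi = max(1.0, q_prime / (k - 2))
        cov = cov_fixed * phi
        method = "egger_random"
    else:
        cov = cov_fixed
        method = "egger_fixed"
    slope, slope_se = float(coef[1]), float(np.sqrt(cov[1, 1]))
    icept, icept_se = float(coef[0]), float(np.sqrt(cov[0, 0]))
    df = k - 2
    crit = stats.t.ppf(0.975, df=df)
    lo, hi = _ci(slope, slope_se, crit)
    return MRResult(
        method=method,
        estimate=slope,
        se=slope_se,
        ci_low=lo,
        ci_high=hi,
        pvalue=float(2 * stats.t.sf(abs(slope / slope_se), df=df)),
        n_snps=k,
        q_egger=q_prime,
        egger_intercept=icept,
        egger_intercept_se=icept_se,
        egger_intercept_p=float(2 * stats.t.sf(abs(icept / icept_se), df=df)),
    )


def rucker_select(instruments, alpha: float = 0.05) -> MRResult:
    """Choose among the four IVW/Egger models via the Rücker ladder.

    Returns the selected model's result, annotated with both
    heterogeneity statistics, the Egger intercept test, a pleiotropy flag
    (intercept p < alpha) and a trace of every comparison made.
    """
    bx, _, _ = _extract(instruments)
    k = len(bx)
    if k < 3:
        raise InsufficientInstrumentsError(
            f"Rücker selection requires >= 3 instruments, got {k}"
        )
    ivw_fix = ivw(instruments, random_effects=False)
    egg_fix = egger(instruments, random_effects=False)
    q, q_prime = ivw_fix.q_ivw, egg_fix.q_egger

    trace: list[dict] = []

    def compare(name: str, statistic: float, df: int) -> bool:
        crit = float(stats.chi2.ppf(1 - alpha, df=df))
        significant = statistic > crit
        trace.append(
            {
                "comparison": name,
                "statistic": statistic,
                "df": df,
                "critical_value": crit,
                "significant": significant,
            }
        )
        return significant

    if not compare("Q vs chi2(k-1)", q, k - 1):
        chosen = ivw_fix
    elif not compare("Q - Q' vs chi2(1)", q - q_prime, 1):
        chosen = ivw(instruments, random_effects=True)
    elif not compare("Q' vs chi2(k-2)", q_prime, k - 2):
        chosen = egg_fix
    else:
        chosen = egger(instruments, random_effects=True)

    chosen.q_ivw = q
    chosen.q_egger = q_prime
    # pleiotropy test always from the random-effects Egger fit, so the
    # flag does not depend on which model the ladder picked
    egg_rand = egger(instruments, random_effects=True)
    chosen.egger_intercept = egg_rand.egger_intercept
    chosen.egger_intercept_se = egg_rand.egger_intercept_se
    chosen.egger_intercept_p = egg_rand.egger_intercept_p
    chosen.pleiotropy_flag = bool(chosen.egger_intercept_p < alpha)
    chosen.decision_trace = trace
    return chosen


def mr_analyze(instrument_set: InstrumentSet, alpha: float = 0.05) -> MRResult:
    """Dispatch by instrument count: 1 -> Wald, 2 -> IVW, >= 3 -> Rücker."""
    k = instrument_set.n_snps
    if k == 0:
        raise NoInstrumentsError(
            f"no instruments for '{instrument_set.trait_name}'"
            + (f" ({instrument_set.provenance.get('reason')})"
               if instrument_set.provenance.get("reason") else "")
        )
    if k == 1:
        return wald_ratio(instrument_set.instruments)
    if k == 2:
        return ivw(instrument_set.instruments, random_effects=False)
    return rucker_select(instrument_set.instruments, alpha=alpha)


#: column order for serialized MR result tables
RESULT_COLUMNS = [
    "method", "estimate", "se", "ci_low", "ci_high", "pvalue", "n_snps",
    "q_ivw", "q_egger", "egger_intercept", "egger_intercept_se",
    "egger_intercept_p", "pleiotropy_flag", "decision_trace",
]


def results_to_frame(results: dict[str, MRResult] | list[tuple[str, MRResult]]) -> pd.DataFrame:
    items = results.items() if isinstance(results, dict) else results
    rows = []
    for label, res in items:
        row = {"label": label}
        row.update(res.to_row())
        rows.append(row)
    return pd.DataFrame(rows, columns=["label", *RESULT_COLUMNS])
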