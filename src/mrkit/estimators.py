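"""Causal-effect estimators and heterogeneity diagnostics for two-sample MR.

All estimation happens on the log-odds scale (outcome log-odds per SD of
exposure); odds-ratio transforms are attached to each estimate for
reporting only.  The estimators operate on a harmonized
:class:`~mrkit.summary_data.InstrumentSet`:

* per-SNP Wald ratios and their delta-method standard errors;
* inverse-variance-weighted (IVW) pooling, fixed-effect or multiplicative
  random-effects (standard errors inflated by sqrt(max(1, Q/(J-1))));
* the weighted median estimator with a parametric-bootstrap standard error;
* MR-Egger regression (free intercept capturing average directional
  pleiotropy) with Rucker's Q' and multiplicative overdispersion;
* Cochran's Q / I^2 heterogeneity about the IVW fit, and I^2_GX, the
  no-measurement-error diagnostic that triggers SIMEX correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .summary_data import HarmonizedInstrument, InstrumentSet

__all__ = [
    "RatioEstimate",
    "MrEstimate",
    "HeterogeneityStats",
    "EggerResult",
    "EstimationError",
    "wald_ratio",
    "wald_ratios",
    "ivw",
    "cochran_q",
    "weighted_median",
    "weighted_median_point",
    "mr_egger",
    "i_squared_gx",
]


class EstimationError(ValueError):
    """Raised when an estimator's preconditions are not met."""


@dataclass(frozen=True)
class RatioEstimate:
    """Per-SNP Wald ratio: outcome log-odds per SD of exposure."""

    rsid: str
    theta: float
    se_theta: float

    @property
    def weight(self) -> float:
        return 1.0 / self.se_theta**2


@dataclass(frozen=True)
class MrEstimate:
    """A pooled causal-effect estimate on the log-odds scale.

    ``scale_factor_phi`` is the multiplicative overdispersion applied to
    the standard error (1 for fixed-effect inference).  ``or_scale`` holds
    the exponentiated (OR, CI) for reporting.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    scale_factor_phi: float = 1.0

    @property
    def or_scale(self) -> tuple[float, float, float]:
        return (np.exp(self.beta), np.exp(self.ci_low), np.exp(self.ci_high))

    def to_dict(self) -> dict:
        or_, lo, hi = self.or_scale
        return {
            "method": self.method,
            "n_snps": self.n_snps,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "or": or_,
            "or_ci_low": lo,
            "or_ci_high": hi,
            "scale_factor_phi": self.scale_factor_phi,
        }


@dataclass(frozen=True)
class HeterogeneityStats:
    """A Q-type heterogeneity statistic with df, p-value and I^2."""

    statistic_name: str
    q: float
    df: int
    pvalue: float
    i_squared: float
    i_squared_ci: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic_name,
            "q": self.q,
            "df": self.df,
            "pvalue": self.pvalue,
            "i_squared": self.i_squared,
            "i_squared_ci_low": self.i_squared_ci[0],
            "i_squared_ci_high": self.i_squared_ci[1],
        }


@dataclass(frozen=True)
class InterceptEstimate:
    """MR-Egger intercept: average directional pleiotropy per SNP."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float


@dataclass(frozen=True)
class EggerResult:
    slope: MrEstimate
    intercept: InterceptEstimate
    q_prime: HeterogeneityStats


def _two_sided_p(z: float, df: int | None = None) -> float:
    if df is None:
        return float(2.0 * stats.norm.sf(abs(z)))
    return float(2.0 * stats.t.sf(abs(z), df))


def _critical(df: int | None = None, level: float = 0.95) -> float:
    q = 0.5 + level / 2.0
    if df is None:
        return float(stats.norm.ppf(q))
    return float(stats.t.ppf(q, df))


def _make_estimate(
    method: str,
    beta: float,
    se: float,
    n_snps: int,
    phi: float = 1.0,
    df: int | None = None,
) -> MrEstimate:
    crit = _critical(df)
    return MrEstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - crit * se),
        ci_high=float(beta + crit * se),
        pvalue=_two_sided_p(beta / se, df) if se > 0 else (1.0 if beta == 0 else 0.0),
        n_snps=n_snps,
        scale_factor_phi=float(phi),
    )


def wald_ratio(inst: HarmonizedInstrument, second_order: bool = False) -> RatioEstimate:
    """Wald ratio for one instrument: beta_outcome / beta_exposure.

    The default standard error is the first-order delta method
    se_outcome/|beta_exposure|; ``second_order=True`` adds the term
    propagating the exposure-side sampling error,
    sqrt(se_Y^2/b_X^2 + b_Y^2 se_X^2 / b_X^4).
    """
    if inst.beta_exposure == 0:
        raise EstimationError(f"{inst.rsid}: Wald ratio undefined for zero exposure beta")
    theta = inst.beta_outcome / inst.beta_exposure
    if second_order:
        se = np.sqrt(
            inst.se_outcome**2 / inst.beta_exposure**2
            + inst.beta_outcome**2 * inst.se_exposure**2 / inst.beta_exposure**4
        )
    else:
        se = inst.se_outcome / abs(inst.beta_exposure)
    return RatioEstimate(rsid=inst.rsid, theta=float(theta), se_theta=float(se))


def wald_ratios(
    instruments: InstrumentSet, second_order: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Wald ratios and SEs over an instrument set."""
    bx, by = instruments.beta_exposure, instruments.beta_outcome
    sx, sy = instruments.se_exposure, instruments.se_outcome
    if np.any(bx == 0):
        bad = [r for r, b in zip(instruments.rsids, bx) if b == 0]
        raise EstimationError(f"zero exposure beta for {bad}")
    theta = by / bx
    if second_order:
        se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        se = sy / np.abs(bx)
    return theta, se


def _ivw_core(theta: np.ndarray, se: np.ndarray) -> tuple[float, float, float]:
    """Return (pooled beta, fixed-effect se, Cochran Q)."""
    w = 1.0 / se**2
    if not np.all(np.isfinite(w)) or np.sum(w) <= 0:
        raise EstimationError("non-finite or zero IVW weights")
    beta = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (theta - beta) ** 2))
    return beta, se_fixed, q


def ivw(
    instruments: InstrumentSet,
    model: str = "multiplicative_random",
    truncate_phi: bool = True,
    use_t: bool = False,
) -> MrEstimate:
    """Inverse-variance-weighted pooling of the per-SNP Wald ratios.

    With first-order ratio SEs this is identical to the weighted regression
    of outcome betas on exposure betas through the origin with weights
    1/se_outcome^2.  ``multiplicative_random`` inflates the fixed-effect
    standard error by sqrt(phi), phi = Q/(J-1) (truncated below at 1 by
    default), leaving the point estimate unchanged.
    """
    j = len(instruments)
    if model not in ("fixed", "multiplicative_random"):
        raise EstimationError(f"unknown IVW model {model!r}")
    if j < 1 or (model == "multiplicative_random" and j < 2):
        raise EstimationError(f"too few instruments (J={j}) for IVW {model}")
    theta, se = wald_ratios(instruments)
    beta, se_fixed, q = _ivw_core(theta, se)
    if model == "fixed":
        phi = 1.0
    else:
        phi = q / (j - 1)
        if truncate_phi:
            phi = max(1.0, phi)
    df = j - 1 if use_t else None
    return _make_estimate(
        f"ivw_{'fixed' if model == 'fixed' else 'mre'}",
        beta,
        se_fixed * np.sqrt(phi),
        j,
        phi=phi,
        df=df,
    )


def _i_squared_ci(q: float, df: int) -> tuple[float, float]:
    """Test-based confidence interval for I^2 (Higgins & Thompson).

    Works through H = sqrt(Q/df): a closed-form standard error of ln(H)
    gives an interval for H, mapped to I^2 = (H^2-1)/H^2 and clipped to
    [0, 1].
    """
    if df < 1:
        return (0.0, 1.0)
    if q > df + 1e-12:
        se_ln_h = 0.5 * (np.log(q) - np.log(df)) / (
            np.sqrt(2.0 * q) - np.sqrt(2.0 * df - 1.0)
        )
    elif df > 1:
        se_ln_h = np.sqrt(1.0 / (2.0 * (df - 1.0)) * (1.0 - 1.0 / (3.0 * (df - 1.0) ** 2)))
    else:
        return (0.0, 1.0)
    ln_h = 0.5 * max(0.0, np.log(q) - np.log(df)) if q > 0 else 0.0
    z = 1.959963984540054
    h_low = np.exp(ln_h - z * se_ln_h)
    h_high = np.exp(ln_h + z * se_ln_h)

    def h_to_i2(h: float) -> float:
        return max(0.0, (h**2 - 1.0) / h**2) if h > 0 else 0.0

    return (min(1.0, h_to_i2(h_low)), min(1.0, h_to_i2(h_high)))


def _het_stats(name: str, q: float, df: int) -> HeterogeneityStats:
    p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return HeterogeneityStats(
        statistic_name=name,
        q=float(q),
        df=df,
        pvalue=p,
        i_squared=float(i2),
        i_squared_ci=_i_squared_ci(q, df),
    )


def cochran_q(instruments: InstrumentSet) -> HeterogeneityStats:
    """Cochran's Q about the fixed-effect IVW fit, with I^2 and its CI."""
    j = len(instruments)
    if j < 2:
        raise EstimationError("Cochran's Q needs at least 2 instruments")
    theta, se = wald_ratios(instruments)
    _, _, q = _ivw_core(theta, se)
    return _het_stats("cochran_q", q, j - 1)


def weighted_median_point(theta: np.ndarray, weights: np.ndarray) -> float:
    """Weighted 50th percentile of the ordered ratios.

    Order statistics are placed at standardized cumulative weights
    (S_j - w_j/2)/sum(w) and the estimate interpolates linearly at 0.5;
    with equal weights this reduces to the interpolated sample median.
    Ties in theta are broken by the original index for determinism.
    """
    order = np.argsort(theta, kind="stable")
    th = np.asarray(theta, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if 0.5 <= cum[0]:
        return float(th[0])
    if 0.5 >= cum[-1]:
        return float(th[-1])
    return float(np.interp(0.5, cum, th))


def weighted_median(
    instruments: InstrumentSet,
    n_boot: int = 1000,
    seed: int = 0,
    min_instruments: int = 3,
    use_t: bool = False,
) -> MrEstimate:
    """Weighted median estimator with a parametric-bootstrap standard error.

    Consistent when instruments contributing more than half of the total
    inverse-variance weight are valid.  The SE resamples each instrument's
    (beta_exposure, beta_outcome) from normal sampling distributions,
    recomputes the weighted median ``n_boot`` times, and takes the SD.
    """
    j = len(instruments)
    if j < min_instruments:
        raise EstimationError(f"weighted median needs >= {min_instruments} instruments")
    if n_boot < 1:
        raise EstimationError("n_boot must be >= 1")
    theta, se = wald_ratios(instruments)
    w = 1.0 / se**2
    point = weighted_median_point(theta, w)

    rng = np.random.default_rng(seed)
    bx = instruments.beta_exposure
    by = instruments.beta_outcome
    sx = instruments.se_exposure
    sy = instruments.se_outcome
    bx_star = rng.normal(bx, sx, size=(n_boot, j))
    by_star = rng.normal(by, sy, size=(n_boot, j))
    # guard against resampled exposure betas crossing zero
    bx_star = np.where(np.abs(bx_star) < 1e-300, 1e-300, bx_star)
    theta_star = by_star / bx_star
    w_star = (bx_star / sy) ** 2
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = weighted_median_point(theta_star[b], w_star[b])
    se_boot = float(np.std(boots, ddof=1)) if n_boot > 1 else float("nan")
    df = j - 1 if use_t else None
    return _make_estimate("weighted_median", point, se_boot, j, df=df)


def wls_line(
    bx: np.ndarray, by: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form weighted least squares of ``by`` on ``bx`` with intercept.

    Accepts 1-D inputs or a 2-D batch of predictor rows (``bx`` shaped
    (B, J) against shared ``by``/``w``, or both 2-D).  Returns
    (slope, intercept, unit-variance of slope, unit-variance of intercept,
    weighted RSS); the unit variances are (X'WX)^-1 diagonals, i.e. the
    sampling variances under unit residual dispersion.
    """
    bx = np.atleast_2d(bx)
    by = np.broadcast_to(np.atleast_2d(by), bx.shape)
    w = np.broadcast_to(np.atleast_2d(w), bx.shape)
    sw = w.sum(axis=-1)
    swx = (w * bx).sum(axis=-1)
    swy = (w * by).sum(axis=-1)
    swxx = (w * bx * bx).sum(axis=-1)
    swxy = (w * bx * by).sum(axis=-1)
    denom = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / denom
    intercept = (swy - slope * swx) / sw
    resid = by - intercept[..., None] - slope[..., None] * bx
    rss = (w * resid**2).sum(axis=-1)
    var_slope = sw / denom
    var_intercept = swxx / denom
    return slope, intercept, var_slope, var_intercept, rss


def mr_egger(
    instruments: InstrumentSet,
    truncate_phi: bool = True,
    overdispersion: bool = True,
    use_t: bool = False,
) -> EggerResult:
    """MR-Egger regression: pleiotropy-robust slope and intercept test.

    Weighted regression of outcome betas on (non-negative, orientation
    enforced upstream) exposure betas with a free intercept and weights
    1/se_outcome^2.  A non-zero intercept estimates the average directional
    pleiotropic effect per SNP; the slope is a causal estimate valid under
    the InSIDE assumption.  Standard errors are inflated by
    sqrt(max(1, Q'/(J-2))) where Q' (Rucker's Q') is the weighted residual
    sum of squares; ``overdispersion=False`` disables the inflation.
    """
    j = len(instruments)
    if j < 3:
        raise EstimationError("MR-Egger needs at least 3 instruments")
    bx = instruments.beta_exposure
    by = instruments.beta_outcome
    if np.ptp(bx) == 0:
        raise EstimationError("degenerate design: all exposure betas equal")
    w = 1.0 / instruments.se_outcome**2
    slope, intercept, v_slope, v_int, rss = (x.item() for x in wls_line(bx, by, w))
    df_q = j - 2
    phi = rss / df_q
    if truncate_phi:
        phi = max(1.0, phi)
    if not overdispersion:
        phi = 1.0
    se_slope = np.sqrt(phi * v_slope)
    se_int = np.sqrt(phi * v_int)
    df = df_q if use_t else None
    crit = _critical(df)
    return EggerResult(
        slope=_make_estimate("egger_slope", slope, se_slope, j, phi=phi, df=df),
        intercept=InterceptEstimate(
            beta=float(intercept),
            se=float(se_int),
            ci_low=float(intercept - crit * se_int),
            ci_high=float(intercept + crit * se_int),
            pvalue=_two_sided_p(intercept / se_int, df),
        ),
        q_prime=_het_stats("rucker_q_prime", rss, df_q),
    )


def i_squared_gx(instruments: InstrumentSet) -> HeterogeneityStats:
    """I^2_GX — the no-measurement-error (NOME) diagnostic for MR-Egger.

    A fixed-effect meta-analysis of the exposure betas (weights
    1/se_exposure^2) yields Q_GX; I^2_GX = max(0, (Q_GX - (J-1))/Q_GX)
    measures how much of the spread in exposure betas is real signal
    rather than sampling noise.  Values below ~0.9 indicate regression
    dilution of the Egger slope, warranting SIMEX correction.
    """
    j = len(instruments)
    if j < 2:
        raise EstimationError("I^2_GX needs at least 2 instruments")
    bx = instruments.beta_exposure
    w = 1.0 / instruments.se_exposure**2
    mean = np.sum(w * bx) / np.sum(w)
    q_gx = float(np.sum(w * (bx - mean) ** 2))
    return _het_stats("q_gx", q_gx, j - 1)
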