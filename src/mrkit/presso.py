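"""MR-PRESSO: pleiotropy residual sum and outlier test.

Three stages, all built on the leave-one-out IVW fit with outcome-side
weights 1/se_outcome^2:

* a **global test** comparing the observed weighted residual sum of
  squares (RSS) against an RSS null distribution simulated under the
  no-pleiotropy model;
* a per-SNP **outlier test** comparing each observed residual against its
  simulated null counterparts, with Bonferroni control by default;
* an outlier-corrected IVW estimate plus a **distortion test** asking
  whether removing the flagged SNPs moved the estimate more than removing
  random subsets of the same size would.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import EstimationError, MrEstimate, ivw, wald_ratios
from .summary_data import InstrumentSet

__all__ = [
    "PressoConfig",
    "PressoResult",
    "presso_global_test",
    "presso_outlier_test",
    "presso_corrected_estimate",
    "run_presso",
]


@dataclass(frozen=True)
class PressoConfig:
    """MR-PRESSO settings.

    ``n_sim`` null draws feed both the global and the per-SNP tests;
    ``outlier_alpha`` is the per-test level, Bonferroni-adjusted over the
    number of instruments by default.
    """

    n_sim: int = 1000
    outlier_alpha: float = 0.05
    multiple_testing: str = "bonferroni"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sim < 100:
            raise EstimationError("PRESSO n_sim must be >= 100")
        if not (0.0 < self.outlier_alpha < 1.0):
            raise EstimationError("outlier_alpha must be in (0, 1)")
        if self.multiple_testing not in ("bonferroni", "none"):
            raise EstimationError(f"unknown multiple_testing {self.multiple_testing!r}")


@dataclass
class PressoResult:
    rss_observed: float
    global_pvalue: float
    outlier_pvalues: dict[str, float]
    outliers: list[str]
    estimate_raw: MrEstimate
    estimate_corrected: MrEstimate
    distortion_pvalue: float | None
    n_sim: int = 0

    def outlier_table(self) -> pd.DataFrame:
        rsids = list(self.outlier_pvalues)
        return pd.DataFrame(
            {
                "rsid": rsids,
                "pvalue": [self.outlier_pvalues[r] for r in rsids],
                "flagged": [r in set(self.outliers) for r in rsids],
            }
        )


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW slopes (origin regression form).

    Supports a batch: ``bx``/``by`` shaped (S, J) with shared weights.
    """
    sxy = (w * bx * by).sum(axis=-1, keepdims=True)
    sxx = (w * bx * bx).sum(axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def _residual_ss(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-SNP weighted squared leave-one-out residuals d_j."""
    theta_loo = _loo_slopes(bx, by, w)
    return w * (by - theta_loo * bx) ** 2


def _simulated_residuals(
    instruments: InstrumentSet, config: PressoConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Observed d_j and the (n_sim, J) matrix of simulated null d*_j."""
    bx = instruments.beta_exposure
    by = instruments.beta_outcome
    sx = instruments.se_exposure
    sy = instruments.se_outcome
    w = 1.0 / sy**2

    d_obs = _residual_ss(bx, by, w)
    theta_loo = _loo_slopes(bx, by, w).ravel()

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    shape = (config.n_sim, len(bx))
    bx_star = rng.normal(bx, sx, size=shape)
    by_star = rng.normal(theta_loo * bx, sy, size=shape)
    d_star = _residual_ss(bx_star, by_star, w)
    return d_obs, d_star


def presso_global_test(
    instruments: InstrumentSet, config: PressoConfig | None = None
) -> tuple[float, float]:
    """Global heterogeneity test; returns (rss_observed, empirical p).

    The observed RSS sums the weighted squared leave-one-out residuals; the
    null distribution re-simulates both beta vectors from their sampling
    distributions under the per-SNP leave-one-out slope and recomputes the
    RSS each time.  The p-value is the upper-tail proportion with a
    +1/(n_sim+1) continuity correction, so it lies in [1/(n_sim+1), 1].
    """
    config = config or PressoConfig()
    if len(instruments) < 4:
        raise EstimationError("MR-PRESSO needs at least 4 instruments")
    d_obs, d_star = _simulated_residuals(instruments, config)
    rss_obs = float(d_obs.sum())
    rss_star = d_star.sum(axis=1)
    p = float((1 + np.sum(rss_star >= rss_obs)) / (config.n_sim + 1))
    return rss_obs, p


def presso_outlier_test(
    instruments: InstrumentSet, config: PressoConfig | None = None
) -> tuple[dict[str, float], list[str]]:
    """Per-SNP outlier test; returns ({rsid: p}, flagged rsids).

    Each SNP's empirical p-value is the plain proportion of simulated null
    residuals exceeding the observed one (it may be exactly zero, as in the
    original MR-PRESSO implementation, so that Bonferroni correction over
    hundreds of SNPs remains able to flag).  A SNP is an outlier when its
    p-value falls below ``outlier_alpha`` after the configured adjustment.
    """
    config = config or PressoConfig()
    if len(instruments) < 4:
        raise EstimationError("MR-PRESSO needs at least 4 instruments")
    d_obs, d_star = _simulated_residuals(instruments, config)
    p_raw = (d_star >= d_obs).mean(axis=0)
    rsids = instruments.rsids
    j = len(rsids)
    threshold = config.outlier_alpha
    if config.multiple_testing == "bonferroni":
        threshold = config.outlier_alpha / j
    outliers = [r for r, p in zip(rsids, p_raw) if p < threshold]
    return dict(zip(rsids, (float(p) for p in p_raw))), outliers


def presso_corrected_estimate(
    instruments: InstrumentSet,
    outliers: list[str],
    config: PressoConfig | None = None,
) -> tuple[MrEstimate, MrEstimate, float | None]:
    """IVW before/after outlier removal plus the distortion test p-value.

    The corrected estimate is multiplicative random-effects IVW on the
    non-flagged instruments.  The distortion null removes ``|outliers|``
    random instruments (without replacement) ``n_sim`` times; the two-sided
    empirical p-value (continuity-corrected) asks whether the observed
    shift raw - corrected is larger than random removal explains.  With no
    outliers the corrected estimate equals the raw one and the p-value is
    None.
    """
    config = config or PressoConfig()
    j = len(instruments)
    estimate_raw = ivw(instruments, model="multiplicative_random")
    estimate_raw = _relabel(estimate_raw, "presso_raw")
    if not outliers:
        return estimate_raw, _relabel(estimate_raw, "presso_corrected"), None
    unknown = set(outliers) - set(instruments.rsids)
    if unknown:
        raise EstimationError(f"outliers not in instrument set: {sorted(unknown)}")
    if len(outliers) >= j:
        raise EstimationError("all instruments flagged as outliers; refusing to correct")
    kept = instruments.drop(outliers)
    estimate_corrected = _relabel(
        ivw(kept, model="multiplicative_random"), "presso_corrected"
    )
    observed_shift = estimate_raw.beta - estimate_corrected.beta

    # null shifts: IVW point estimates after removing random subsets of the
    # same size (the point estimate is weight-mean of ratios, identical for
    # fixed and multiplicative-random models, so this is computed directly)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    theta, se = wald_ratios(instruments)
    w = 1.0 / se**2
    k = len(outliers)
    shifts = np.empty(config.n_sim)
    for s in range(config.n_sim):
        drop = rng.choice(j, size=k, replace=False)
        keep_mask = np.ones(j, dtype=bool)
        keep_mask[drop] = False
        shifts[s] = estimate_raw.beta - np.sum(w[keep_mask] * theta[keep_mask]) / np.sum(
            w[keep_mask]
        )
    p = float(
        (1 + np.sum(np.abs(shifts) >= abs(observed_shift))) / (config.n_sim + 1)
    )
    return estimate_raw, estimate_corrected, p


def _relabel(est: MrEstimate, method: str) -> MrEstimate:
    return MrEstimate(
        method=method,
        beta=est.beta,
        se=est.se,
        ci_low=est.ci_low,
        ci_high=est.ci_high,
        pvalue=est.pvalue,
        n_snps=est.n_snps,
        scale_factor_phi=est.scale_factor_phi,
    )


def run_presso(
    instruments: InstrumentSet, config: PressoConfig | None = None
) -> PressoResult:
    """Full MR-PRESSO suite: global test, outlier test, corrected estimate.

    The global and per-SNP tests share one simulated null ensemble, exactly
    as calling the two test functions with the same config would.
    """
    config = config or PressoConfig()
    if len(instruments) < 4:
        raise EstimationError("MR-PRESSO needs at least 4 instruments")
    d_obs, d_star = _simulated_residuals(instruments, config)
    rss_obs = float(d_obs.sum())
    global_p = float(
        (1 + np.sum(d_star.sum(axis=1) >= rss_obs)) / (config.n_sim + 1)
    )
    p_raw = (d_star >= d_obs).mean(axis=0)
    rsids = instruments.rsids
    threshold = config.outlier_alpha
    if config.multiple_testing == "bonferroni":
        threshold = config.outlier_alpha / len(rsids)
    outliers = [r for r, p in zip(rsids, p_raw) if p < threshold]
    outlier_p = dict(zip(rsids, (float(p) for p in p_raw)))
    raw, corrected, distortion_p = presso_corrected_estimate(
        instruments, outliers, config
    )
    return PressoResult(
        rss_observed=rss_obs,
        global_pvalue=global_p,
        outlier_pvalues=outlier_p,
        outliers=outliers,
        estimate_raw=raw,
        estimate_corrected=corrected,
        distortion_pvalue=distortion_p,
        n_sim=config.n_sim,
    )
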