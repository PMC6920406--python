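"""Synthetic two-sample GWAS summary statistics.

Generates exposure/outcome association tables with the generative structure
the MR estimators assume:

    beta_outcome_j = theta * b_Xj + alpha_j + noise,

where ``b_Xj`` are true SNP-exposure effects, ``theta`` the causal effect
(log-odds per SD of exposure), and ``alpha_j`` optional horizontal
pleiotropy — none, balanced (zero-mean), or directional — optionally
correlated with instrument strength (an InSIDE violation).  Observed betas
add normal sampling error at configurable per-study levels; allele labels
include configurable fractions of palindromic variants and strand-flipped
outcome rows so the harmonization layer is exercised end to end.  Binary
outcome effects are generated directly on the log-odds scale, keeping the
ground truth analytic.

The default configuration mirrors a well-powered smoking-initiation /
type 2 diabetes style study: 377 tightly-clustered instruments with mean
F-statistic near 77, exposure-side signal-to-noise giving I^2_GX around
0.6, and balanced pleiotropy producing ratio heterogeneity with I^2 around
0.7 (see docs/methods.md for the calibration arithmetic).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .summary_data import SnpAssociation, complement_allele
from scipy import stats

__all__ = [
    "PleiotropySpec",
    "SimulationConfig",
    "SimulationTruth",
    "SimulatedStudy",
    "simulate_two_sample",
    "make_fixture",
    "FIXTURE_NAMES",
]

_NONPALINDROMIC_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))
_PALINDROMIC_PAIRS = (("A", "T"), ("G", "C"))


@dataclass(frozen=True)
class PleiotropySpec:
    """Horizontal-pleiotropy model: kind in {none, balanced, directional}.

    ``balanced`` draws alpha_j ~ N(0, sd^2); ``directional`` draws
    alpha_j ~ N(mean, sd^2).
    """

    kind: str = "none"
    mean: float = 0.0
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy kind {self.kind!r}")
        if self.kind == "balanced" and self.mean != 0.0:
            raise ValueError("balanced pleiotropy has zero mean by definition")
        if self.sd < 0:
            raise ValueError("pleiotropy sd must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults describe the emulated study: 377 genome-wide-significant,
    conditionally independent instruments for a behavioural exposure
    measured in SD units, against a large biobank-scale binary outcome.

    ``beta_x_dist`` is ``("abs_normal", scale)`` or
    ``("abs_normal", loc, scale)`` — absolute value of a normal, so true
    effects are oriented to the exposure-increasing allele.  ``se_x_level``
    / ``se_y_level`` are either a float (constant SE) or
    ``("gamma", shape, mean)`` for per-SNP gamma-distributed SEs.
    """

    n_snps: int = 377
    theta: float = 0.25
    beta_x_dist: tuple = ("abs_normal", 0.019, 0.0028)
    se_x_level: float | tuple = 0.0022
    se_y_level: float | tuple = 0.007
    pleiotropy: PleiotropySpec = field(default_factory=lambda: PleiotropySpec("balanced", 0.0, 0.0107))
    inside_violation: bool = False
    inside_strength: float = 0.3
    outlier_fraction: float = 0.0
    outlier_magnitude: float = 0.0
    outlier_sign: str = "random"
    palindromic_fraction: float = 10.0 / 377.0
    palindromic_high_maf_fraction: float = 1.0
    strand_flip_fraction: float = 0.0
    sampling_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        for name in (
            "outlier_fraction",
            "palindromic_fraction",
            "palindromic_high_maf_fraction",
            "strand_flip_fraction",
        ):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.outlier_sign not in ("random", "positive", "negative"):
            raise ValueError(f"invalid outlier_sign {self.outlier_sign!r}")
        for lv in (self.se_x_level, self.se_y_level):
            if isinstance(lv, (int, float)):
                if lv <= 0:
                    raise ValueError("SE levels must be > 0")
            elif not (isinstance(lv, tuple) and lv[0] == "gamma" and len(lv) == 3):
                raise ValueError(f"invalid SE level spec {lv!r}")
        if not (
            isinstance(self.beta_x_dist, tuple)
            and self.beta_x_dist[0] == "abs_normal"
            and len(self.beta_x_dist) in (2, 3)
        ):
            raise ValueError(f"invalid beta_x distribution spec {self.beta_x_dist!r}")


@dataclass
class SimulationTruth:
    """Ground truth behind a simulated study."""

    theta: float
    beta_x_true: np.ndarray
    pleiotropy: np.ndarray
    outlier_rsids: list[str]
    strand_flipped_rsids: list[str]

    def to_dict(self) -> dict:
        return {
            "theta": self.theta,
            "beta_x_true": [float(b) for b in self.beta_x_true],
            "pleiotropy": [float(a) for a in self.pleiotropy],
            "outlier_rsids": list(self.outlier_rsids),
            "strand_flipped_rsids": list(self.strand_flipped_rsids),
        }


@dataclass
class SimulatedStudy:
    exposure_table: list[SnpAssociation]
    outcome_table: list[SnpAssociation]
    truth: SimulationTruth
    config: SimulationConfig


def _draw_se(level, n: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(level, tuple):
        _, shape, mean = level
        return rng.gamma(shape, mean / shape, size=n)
    return np.full(n, float(level))


def _draw_beta_x(dist: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    if len(dist) == 2:
        loc, scale = 0.0, dist[1]
    else:
        loc, scale = dist[1], dist[2]
    return np.abs(rng.normal(loc, scale, size=n))


def simulate_two_sample(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Draw one two-sample summary-statistic study from the configured model.

    Returns exposure and outcome tables sharing rsids (ready for
    :func:`mrkit.summary_data.harmonize`) plus the generating truth.
    Identical configs (including seed) give bit-identical studies.
    """
    config = config or SimulationConfig()
    n = config.n_snps
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    rsids = [f"rs{100000 + i}" for i in range(n)]

    beta_x_true = _draw_beta_x(config.beta_x_dist, n, rng)
    se_x = _draw_se(config.se_x_level, n, rng)
    se_y = _draw_se(config.se_y_level, n, rng)

    pleio = config.pleiotropy
    if pleio.kind == "none":
        alpha = np.zeros(n)
    else:
        alpha = rng.normal(pleio.mean, pleio.sd, size=n)
    if config.inside_violation and pleio.kind != "none":
        # tie direct effects to instrument strength, breaking InSIDE
        alpha = alpha + config.inside_strength * (beta_x_true - beta_x_true.mean())

    # sampling_noise=False gives the infinite-sample limit: observed betas
    # equal their expectations while reported SEs keep their stated levels
    noise_scale = 1.0 if config.sampling_noise else 0.0
    beta_x_obs = rng.normal(beta_x_true, noise_scale * se_x)
    mean_y = config.theta * beta_x_true + alpha

    n_outliers = int(round(config.outlier_fraction * n))
    outlier_idx = (
        rng.choice(n, size=n_outliers, replace=False) if n_outliers else np.array([], int)
    )
    shift = np.zeros(n)
    if n_outliers:
        if config.outlier_sign == "random":
            signs = rng.choice((-1.0, 1.0), size=n_outliers)
        else:
            signs = np.full(n_outliers, 1.0 if config.outlier_sign == "positive" else -1.0)
        shift[outlier_idx] = signs * config.outlier_magnitude * se_y[outlier_idx]
    beta_y_obs = rng.normal(mean_y + shift, noise_scale * se_y)

    # allele labels and frequencies
    n_palin = int(round(config.palindromic_fraction * n))
    palin_idx = set(
        rng.choice(n, size=n_palin, replace=False).tolist() if n_palin else []
    )
    eaf = rng.uniform(0.05, 0.95, size=n)
    pairs: list[tuple[str, str]] = []
    for i in range(n):
        if i in palin_idx:
            pairs.append(_PALINDROMIC_PAIRS[int(rng.integers(2))])
            if rng.uniform() < config.palindromic_high_maf_fraction:
                eaf[i] = rng.uniform(0.45, 0.55)
        else:
            pairs.append(_NONPALINDROMIC_PAIRS[int(rng.integers(4))])

    p_x = np.maximum(2 * stats.norm.sf(np.abs(beta_x_obs / se_x)), 1e-300)
    p_y = np.maximum(2 * stats.norm.sf(np.abs(beta_y_obs / se_y)), 1e-300)
    eaf_out = np.clip(eaf + rng.normal(0, 0.01, size=n), 0.01, 0.99)

    exposure, outcome = [], []
    flip_rsids: list[str] = []
    for i, rsid in enumerate(rsids):
        ea, oa = pairs[i]
        exposure.append(
            SnpAssociation(
                rsid=rsid,
                effect_allele=ea,
                other_allele=oa,
                beta=float(beta_x_obs[i]),
                se=float(se_x[i]),
                eaf=float(eaf[i]),
                pvalue=float(p_x[i]),
            )
        )
        out = SnpAssociation(
            rsid=rsid,
            effect_allele=ea,
            other_allele=oa,
            beta=float(beta_y_obs[i]),
            se=float(se_y[i]),
            eaf=float(eaf_out[i]),
            pvalue=float(p_y[i]),
        )
        if (
            i not in palin_idx
            and rng.uniform() < config.strand_flip_fraction
        ):
            out = replace(
                out,
                effect_allele=complement_allele(out.effect_allele),
                other_allele=complement_allele(out.other_allele),
            )
            flip_rsids.append(rsid)
        outcome.append(out)

    truth = SimulationTruth(
        theta=config.theta,
        beta_x_true=beta_x_true,
        pleiotropy=alpha,
        outlier_rsids=[rsids[i] for i in sorted(outlier_idx.tolist())],
        strand_flipped_rsids=flip_rsids,
    )
    return SimulatedStudy(
        exposure_table=exposure, outcome_table=outcome, truth=truth, config=config
    )


#: deterministic named datasets used across the test suite and docs
FIXTURE_NAMES = ("study_like", "tiny", "outlier_demo")


def make_fixture(name: str) -> SimulatedStudy:
    """Named deterministic datasets.

    ``study_like``
        the default configuration at a fixed seed — ~377 SNPs with mean F
        near 77, ratio heterogeneity I^2 in the 0.6-0.8 band, a handful of
        high-MAF palindromic variants.
    ``tiny``
        5 strong SNPs with no pleiotropy and mild noise; small enough that
        IVW can be checked by hand.
    ``outlier_demo``
        50 homogeneous SNPs plus 2 planted outliers displaced by 10
        outcome SEs, for outlier-detection demonstrations.
    """
    if name == "study_like":
        return simulate_two_sample(SimulationConfig(seed=20190377))
    if name == "tiny":
        return simulate_two_sample(
            SimulationConfig(
                n_snps=5,
                theta=0.4,
                beta_x_dist=("abs_normal", 0.3, 0.1),
                se_x_level=0.01,
                se_y_level=0.05,
                pleiotropy=PleiotropySpec("none"),
                palindromic_fraction=0.0,
                seed=11,
            )
        )
    if name == "outlier_demo":
        return simulate_two_sample(
            SimulationConfig(
                n_snps=50,
                theta=0.25,
                beta_x_dist=("abs_normal", 0.019, 0.0028),
                pleiotropy=PleiotropySpec("none"),
                outlier_fraction=2.0 / 50.0,
                outlier_magnitude=10.0,
                palindromic_fraction=0.0,
                seed=42,
            )
        )
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
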