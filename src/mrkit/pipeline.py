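"""End-to-end orchestration of the two-sample MR analysis.

``run_full_analysis`` executes the published analysis sequence on a pair of
summary-statistic tables: harmonize, instrument-strength F, multiplicative
random-effects IVW (main analysis), Cochran's Q / I^2, weighted median,
MR-Egger with Rucker's Q', I^2_GX, SIMEX-corrected Egger when I^2_GX falls
below the configured trigger, and the MR-PRESSO suite.  The result is an
:class:`AnalysisReport` that serializes to JSON and per-table TSV, carries
a forest-table (one row per method, log-odds and OR scales) and the
per-SNP scatter data, and records provenance (config hash, seeds).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import estimators, presso as presso_mod, simex as simex_mod
from .summary_data import (
    InstrumentSet,
    SnpAssociation,
    harmonize,
    mean_f_statistic,
    read_summary_table,
)

__all__ = ["AnalysisConfig", "AnalysisReport", "run_full_analysis", "run_analysis", "compare_runs"]


@dataclass(frozen=True)
class AnalysisConfig:
    """All analysis-relevant settings for one pipeline run.

    ``simex_mode``: "auto" runs SIMEX only when I^2_GX < ``simex_trigger``
    (the published decision rule, trigger 0.90); "on"/"off" force it.
    Child seeds for every stochastic stage (weighted-median bootstrap,
    SIMEX, PRESSO) are derived deterministically from ``seed``.
    """

    palindromic_policy: str = "retain_same_strand"
    palindromic_maf_threshold: float = 0.45
    wm_n_boot: int = 1000
    simex_lambdas: tuple[float, ...] = simex_mod.DEFAULT_LAMBDAS
    simex_n_sim: int = 1000
    simex_trigger: float = 0.90
    simex_mode: str = "auto"
    presso_n_sim: int = 1000
    presso_alpha: float = 0.05
    presso_multiple_testing: str = "bonferroni"
    use_t: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simex_mode not in ("auto", "on", "off"):
            raise ValueError(f"simex_mode must be auto/on/off, got {self.simex_mode!r}")
        object.__setattr__(self, "simex_lambdas", tuple(float(x) for x in self.simex_lambdas))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simex_lambdas"] = list(d["simex_lambdas"])
        return d

    def config_hash(self) -> str:
        """Hash over every analysis-relevant setting (stable ordering)."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def child_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.seed).generate_state(3, dtype=np.uint64)
        names = ("weighted_median", "simex", "presso")
        return {name: int(s % (2**31)) for name, s in zip(names, state)}

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        """Load from a flat ``key: value`` YAML file.

        Keys may be dotted (``simex.n_sim``) or flat (``simex_n_sim``).
        """
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        mapping = {
            "harmonize.palindromic_policy": "palindromic_policy",
            "harmonize.maf_threshold": "palindromic_maf_threshold",
            "weighted_median.n_boot": "wm_n_boot",
            "simex.lambdas": "simex_lambdas",
            "simex.n_sim": "simex_n_sim",
            "simex.trigger": "simex_trigger",
            "simex.mode": "simex_mode",
            "presso.n_sim": "presso_n_sim",
            "presso.alpha": "presso_alpha",
            "presso.multiple_testing": "presso_multiple_testing",
        }
        kwargs = {}
        valid = set(cls.__dataclass_fields__)
        for key, value in raw.items():
            name = mapping.get(key, key.replace(".", "_"))
            if name not in valid:
                raise ValueError(f"unknown config key {key!r}")
            if name == "simex_lambdas":
                value = tuple(float(v) for v in value)
            kwargs[name] = value
        return cls(**kwargs)


@dataclass
class AnalysisReport:
    """Serializable record of one full analysis run."""

    instrument_summary: dict
    estimates: list[dict]
    egger_intercept: dict
    heterogeneity: list[dict]
    simex: dict
    presso: dict
    scatter_data: list[dict]
    provenance: dict

    def to_dict(self, include_timestamp: bool = True) -> dict:
        d = {
            "instrument_summary": self.instrument_summary,
            "estimates": self.estimates,
            "egger_intercept": self.egger_intercept,
            "heterogeneity": self.heterogeneity,
            "simex": self.simex,
            "presso": self.presso,
            "scatter_data": self.scatter_data,
            "provenance": dict(self.provenance),
        }
        if not include_timestamp:
            d["provenance"].pop("created", None)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)

    def canonical_json(self) -> str:
        """Deterministic serialization: identical runs give identical bytes."""
        return json.dumps(self.to_dict(include_timestamp=False), sort_keys=True)

    def forest_table(self) -> pd.DataFrame:
        """Figure-style per-method table (log-odds and OR scales)."""
        return pd.DataFrame(self.estimates)

    def scatter_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.scatter_data)

    def estimate(self, method: str) -> dict:
        for row in self.estimates:
            if row["method"] == method:
                return row
        raise KeyError(f"no estimate for method {method!r}")

    def summary_text(self) -> str:
        lines = [
            "Two-sample MR analysis",
            f"  instruments: {self.instrument_summary['n_instruments']}"
            f" (palindromic retained: {self.instrument_summary['n_palindromic_retained']},"
            f" dropped: {self.instrument_summary['n_dropped']})",
            f"  mean F-statistic: {self.instrument_summary['mean_f_statistic']:.1f}",
            "  method                OR (95% CI)          p",
        ]
        for row in self.estimates:
            lines.append(
                f"  {row['method']:<20}{row['or']:.2f} ({row['or_ci_low']:.2f},"
                f" {row['or_ci_high']:.2f})   {row['pvalue']:.3g}"
            )
        icpt = self.egger_intercept
        lines.append(
            f"  egger intercept      {icpt['beta']:.3f} ({icpt['ci_low']:.3f},"
            f" {icpt['ci_high']:.3f})   {icpt['pvalue']:.3g}"
        )
        for het in self.heterogeneity:
            lines.append(
                f"  {het['statistic']:<20}Q={het['q']:.1f} df={het['df']}"
                f" I2={100 * het['i_squared']:.0f}%"
            )
        lines.append(
            f"  presso: global p={self.presso['global_pvalue']:.3g},"
            f" outliers={self.presso['n_outliers']}"
        )
        return "\n".join(lines)


def run_analysis(
    exposure: Sequence[SnpAssociation],
    outcome: Sequence[SnpAssociation],
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Run the full analysis on in-memory association tables."""
    config = config or AnalysisConfig()
    seeds = config.child_seeds()

    instruments = harmonize(
        exposure,
        outcome,
        palindromic_maf_threshold=config.palindromic_maf_threshold,
        palindromic_policy=config.palindromic_policy,
    )
    mean_f = mean_f_statistic(instruments)

    est_ivw = estimators.ivw(instruments, model="multiplicative_random", use_t=config.use_t)
    het_q = estimators.cochran_q(instruments)
    est_wm = estimators.weighted_median(
        instruments, n_boot=config.wm_n_boot, seed=seeds["weighted_median"], use_t=config.use_t
    )
    egger = estimators.mr_egger(instruments, use_t=config.use_t)
    het_gx = estimators.i_squared_gx(instruments)

    run_simex = config.simex_mode == "on" or (
        config.simex_mode == "auto" and het_gx.i_squared < config.simex_trigger
    )
    simex_section: dict = {"ran": bool(run_simex), "trigger": config.simex_trigger,
                           "i_squared_gx": het_gx.i_squared}
    simex_result = None
    if run_simex:
        simex_result = simex_mod.simex_egger(
            instruments,
            simex_mod.SimexConfig(
                lambdas=config.simex_lambdas,
                n_sim=config.simex_n_sim,
                seed=seeds["simex"],
            ),
        )
        simex_section["per_lambda"] = simex_result.per_lambda_coefficients.to_dict("records")
        simex_section["extrapolation"] = simex_result.extrapolation_diagnostics
        simex_section["intercept"] = vars(simex_result.corrected.intercept)

    presso_result = presso_mod.run_presso(
        instruments,
        presso_mod.PressoConfig(
            n_sim=config.presso_n_sim,
            outlier_alpha=config.presso_alpha,
            multiple_testing=config.presso_multiple_testing,
            seed=seeds["presso"],
        ),
    )

    estimates = [est_ivw.to_dict(), est_wm.to_dict(), egger.slope.to_dict()]
    if simex_result is not None:
        estimates.append(simex_result.corrected.slope.to_dict())
    estimates += [
        presso_result.estimate_raw.to_dict(),
        presso_result.estimate_corrected.to_dict(),
    ]

    dropped = instruments.dropped_counts()
    report = AnalysisReport(
        instrument_summary={
            "n_exposure_snps": len(exposure),
            "n_shared_snps": len(exposure) - dropped["dropped_missing"],
            "n_instruments": len(instruments),
            "n_palindromic_retained": instruments.n_palindromic_retained,
            "n_dropped": instruments.n_dropped,
            "dropped_counts": dropped,
            "mean_f_statistic": mean_f,
        },
        estimates=estimates,
        egger_intercept=vars(egger.intercept),
        heterogeneity=[het_q.to_dict(), egger.q_prime.to_dict(), het_gx.to_dict()],
        simex=simex_section,
        presso={
            "rss_observed": presso_result.rss_observed,
            "global_pvalue": presso_result.global_pvalue,
            "n_outliers": len(presso_result.outliers),
            "outliers": presso_result.outliers,
            "distortion_pvalue": presso_result.distortion_pvalue,
            "n_sim": presso_result.n_sim,
        },
        scatter_data=[
            {
                "rsid": inst.rsid,
                "beta_exposure": inst.beta_exposure,
                "se_exposure": inst.se_exposure,
                "beta_outcome": inst.beta_outcome,
                "se_outcome": inst.se_outcome,
            }
            for inst in instruments
        ],
        provenance={
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "child_seeds": seeds,
            "created": datetime.now(timezone.utc).isoformat(),
        },
    )
    return report


def run_full_analysis(
    exposure_path,
    outcome_path,
    config: AnalysisConfig | None = None,
    column_map: dict | None = None,
) -> AnalysisReport:
    """Read the two summary tables from disk and run the full analysis."""
    exposure = read_summary_table(exposure_path, column_map=column_map)
    outcome = read_summary_table(outcome_path, column_map=column_map)
    return run_analysis(exposure, outcome, config)


def compare_runs(
    report_a: AnalysisReport, report_b: AnalysisReport, strict: bool = True
) -> pd.DataFrame:
    """Per-method deltas between two analysis reports.

    Returns one row per shared method with the log-odds betas, their
    difference, the SE difference, and whether the confidence intervals
    overlap.  With ``strict=True`` the two reports must carry the same
    method set.
    """
    methods_a = {row["method"]: row for row in report_a.estimates}
    methods_b = {row["method"]: row for row in report_b.estimates}
    if strict and set(methods_a) != set(methods_b):
        raise ValueError(
            f"mismatched methods: {sorted(set(methods_a) ^ set(methods_b))}"
        )
    shared = [m for m in methods_a if m in methods_b]
    if not shared:
        raise ValueError("no shared methods between reports")
    rows = []
    for m in shared:
        a, b = methods_a[m], methods_b[m]
        rows.append(
            {
                "method": m,
                "beta_a": a["beta"],
                "beta_b": b["beta"],
                "delta_beta": a["beta"] - b["beta"],
                "delta_se": a["se"] - b["se"],
                "ci_overlap": a["ci_low"] <= b["ci_high"] and b["ci_low"] <= a["ci_high"],
                "both_or_above_1": a["or"] > 1 and b["or"] > 1,
            }
        )
    return pd.DataFrame(rows)
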