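"""End-to-end analysis: select → proxy → harmonize → Steiger → stratify →
estimate → diagnose → report.

The primary analysis is the random-effects IVW estimate with Steiger and
biological-effect filtering; MR-Egger, weighted-median and penalized-
weighted-median estimates are run as pleiotropy-robust sensitivity analyses
on every instrument set (pooled and per stratum).  An IVW estimate is flagged
invalid when the MR-Egger intercept is significant at P < 0.05, and headline
significance calls use the Bonferroni family-wise threshold
alpha / (n_exposures × n_outcomes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from . import harmonize as hz
from . import filtering as flt
from . import models as mdl
from .harmonize import HarmonizedSet
from .models import MREstimate
from .sumstats import LDReference, read_ld_reference, read_sumstats

ESTIMATE_COLUMNS = [
    "stratum",
    "label",
    "method",
    "n_snps",
    "beta",
    "se",
    "pval",
    "Q",
    "Q_pval",
    "I2",
    "intercept",
    "intercept_se",
    "intercept_pval",
    "status",
    "ivw_invalid",
    "significant_fw",
]


@dataclass
class AnalysisConfig:
    """All inputs, thresholds and seeds for one pipeline run."""

    exposure_path: str
    indicator_path: str
    outcome_path: str
    ld_pairs_path: str | None = None
    ld_positions_path: str | None = None
    p_threshold: float = 5.0e-8
    r2_min: float = 0.7
    max_dist: int = 1_000_000
    palindrome_window: float = 0.08
    steiger: bool = True
    labels: Mapping[str, str] = field(
        default_factory=lambda: {"positive": "positive", "negative": "negative"}
    )
    random_effects: bool = True
    n_boot: int = 1000
    penalty_k: float = 20.0
    seed: int = 0
    alpha: float = 0.05
    n_exposures: int = 2
    n_outcomes: int = 2
    output_dir: str | None = None

    def validate(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ConfigurationError(f"p_threshold must be in (0, 1), got {self.p_threshold}")
        if not (0 <= self.r2_min <= 1):
            raise ConfigurationError(f"r2_min must be in [0, 1], got {self.r2_min}")
        if not (0 < self.alpha < 1):
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.max_dist < 0:
            raise ConfigurationError("max_dist must be >= 0")
        if self.n_boot < 100:
            raise ConfigurationError("n_boot must be >= 100")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown analysis config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PlotData:
    """Plot-ready datasets (points + per-method reference/fit lines)."""

    funnel_points: pd.DataFrame  # variant_id, ratio, precision
    funnel_lines: pd.DataFrame  # method, estimate
    dosage_points: pd.DataFrame  # variant_id, beta_x, beta_y, se_y
    dosage_lines: pd.DataFrame  # method, slope, intercept
    empty: bool = False


@dataclass
class ResultsReport:
    estimates: pd.DataFrame  # one row per stratum × method
    counts: dict[str, int]
    stratum_sizes: dict[str, int]
    provenance: pd.DataFrame
    steiger: pd.DataFrame
    strata: pd.DataFrame
    plot_data: dict[str, PlotData]
    fw_threshold: float
    validity: dict[str, dict]

    def write(self, outdir: str | Path) -> Path:
        """Write every report table as TSV plus a plain-text run log.

        Float formatting is fixed (repr), so identical reports serialize to
        identical bytes.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_tsv(self.estimates, outdir / "estimates.tsv")
        _write_tsv(self.provenance, outdir / "provenance.tsv")
        _write_tsv(self.steiger, outdir / "steiger.tsv")
        _write_tsv(self.strata, outdir / "strata.tsv")
        for name, pdta in self.plot_data.items():
            _write_tsv(pdta.funnel_points, outdir / f"funnel_points_{name}.tsv")
            _write_tsv(pdta.funnel_lines, outdir / f"funnel_lines_{name}.tsv")
            _write_tsv(pdta.dosage_points, outdir / f"dosage_points_{name}.tsv")
            _write_tsv(pdta.dosage_lines, outdir / f"dosage_lines_{name}.tsv")
        with open(outdir / "run_log.txt", "w") as fh:
            fh.write("stratmr run log\n")
            fh.write(f"family-wise significance threshold: {repr(self.fw_threshold)}\n")
            for k, v in self.counts.items():
                fh.write(f"count {k}: {v}\n")
            for k, v in self.stratum_sizes.items():
                fh.write(f"stratum {k}: {v}\n")
            for name, flags in self.validity.items():
                fh.write(f"validity {name}: {flags}\n")
        return outdir


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for row in df.itertuples(index=False):
            cells = []
            for v in row:
                if isinstance(v, (float, np.floating)):
                    cells.append("NA" if pd.isna(v) else repr(float(v)))
                elif isinstance(v, (bool, np.bool_)):
                    cells.append(str(bool(v)))
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")


def multiple_testing_threshold(alpha: float, n_exposures: int, n_outcomes: int) -> float:
    """Bonferroni family-wise threshold alpha / (n_exposures × n_outcomes)."""
    if not (0 < alpha < 1):
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    if n_exposures < 1 or n_outcomes < 1:
        raise ConfigurationError("exposure/outcome counts must be >= 1")
    return alpha / (n_exposures * n_outcomes)


def apply_validity_rule(estimates: Mapping[str, MREstimate], alpha: float = 0.05) -> dict:
    """Flag IVW invalid when the MR-Egger intercept is significant (strict <).

    When Egger was refused (too few instruments) the flag is
    ``egger-unavailable`` and IVW is *not* auto-invalidated.
    """
    egger = estimates.get("Egger")
    if egger is None or egger.status != "ok" or np.isnan(egger.intercept_pval):
        return {"ivw_invalid": False, "flag": "egger-unavailable"}
    invalid = egger.intercept_pval < alpha
    return {
        "ivw_invalid": bool(invalid),
        "flag": "egger-intercept-significant" if invalid else "",
        "intercept_pval": float(egger.intercept_pval),
    }


def diagnostic_plot_data(
    hset: HarmonizedSet, estimates: Mapping[str, MREstimate]
) -> PlotData:
    """Funnel and dosage datasets for one (filtered) instrument set.

    Funnel: per-instrument Wald ratio against precision (1/ratio se), with a
    vertical reference line at each computed method estimate.  Dosage:
    per-instrument (β_x, β_y) scatter with each method's fitted line (zero
    intercept except MR-Egger).
    """
    ratios = mdl.ratio_estimates(hset)
    ok = {m: e for m, e in estimates.items() if e.status == "ok" and not np.isnan(e.beta)}
    if not ratios:
        empty_cols = lambda cols: pd.DataFrame(columns=cols)  # noqa: E731
        return PlotData(
            funnel_points=empty_cols(["variant_id", "ratio", "precision"]),
            funnel_lines=empty_cols(["method", "estimate"]),
            dosage_points=empty_cols(["variant_id", "beta_x", "beta_y", "se_y"]),
            dosage_lines=empty_cols(["method", "slope", "intercept"]),
            empty=True,
        )
    funnel_points = pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in ratios],
            "ratio": [r.ratio for r in ratios],
            "precision": [1.0 / r.ratio_se for r in ratios],
        }
    )
    funnel_lines = pd.DataFrame(
        {"method": list(ok), "estimate": [e.beta for e in ok.values()]}
    )
    dosage_points = pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in hset.records],
            "beta_x": [r.beta_x for r in hset.records],
            "beta_y": [r.beta_y for r in hset.records],
            "se_y": [r.se_y for r in hset.records],
        }
    )
    dosage_lines = pd.DataFrame(
        {
            "method": list(ok),
            "slope": [e.beta for e in ok.values()],
            "intercept": [0.0 if np.isnan(e.intercept) else e.intercept for e in ok.values()],
        }
    )
    return PlotData(funnel_points, funnel_lines, dosage_points, dosage_lines)


def _estimate_rows(
    name: str,
    label: str,
    estimates: Mapping[str, MREstimate],
    validity: dict,
    fw_threshold: float,
) -> list[dict]:
    rows = []
    for method, est in estimates.items():
        significant = (
            est.status == "ok"
            and not np.isnan(est.pval)
            and est.pval < fw_threshold
            and not (method == "IVW" and validity.get("ivw_invalid", False))
        )
        rows.append(
            {
                "stratum": name,
                "label": label,
                "method": method,
                "n_snps": est.n_snps,
                "beta": est.beta,
                "se": est.se,
                "pval": est.pval,
                "Q": est.Q,
                "Q_pval": est.Q_pval,
                "I2": est.I2,
                "intercept": est.intercept,
                "intercept_se": est.intercept_se,
                "intercept_pval": est.intercept_pval,
                "status": est.status,
                "ivw_invalid": bool(validity.get("ivw_invalid", False)) if method == "IVW" else False,
                "significant_fw": bool(significant),
            }
        )
    return rows


def run_analysis(
    config: AnalysisConfig,
    tables: tuple | None = None,
    ld: LDReference | None = None,
) -> ResultsReport:
    """Execute the full stratified MR analysis.

    ``tables`` may carry pre-loaded ``(exposure, indicator, outcome)``
    :class:`SummaryStatsTable` objects (the paths in ``config`` are then
    ignored), which is how the simulator output is analysed in-process.
    Zero instruments at any point produce structured ``no-instruments``
    entries, never an exception.
    """
    config.validate()
    if tables is not None:
        exposure, indicator, outcome = tables
    else:
        exposure = read_sumstats(config.exposure_path, trait_name="exposure")
        indicator = read_sumstats(config.indicator_path, trait_name="indicator")
        outcome = read_sumstats(config.outcome_path, trait_name="outcome")
    if ld is None:
        if config.ld_pairs_path and config.ld_positions_path:
            ld = read_ld_reference(config.ld_pairs_path, config.ld_positions_path)
        else:
            ld = LDReference()

    hset = hz.build_instrument_set(
        exposure,
        indicator,
        outcome,
        ld,
        p_threshold=config.p_threshold,
        r2_min=config.r2_min,
        max_dist=config.max_dist,
        palindrome_window=config.palindrome_window,
    )
    n_selected = len(hset.provenance)
    n_harmonized = len(hset)

    if config.steiger:
        kept, steiger_results = flt.steiger_filter(hset)
    else:
        kept, steiger_results = hset, []
    steiger_df = flt.steiger_results_frame(steiger_results)
    n_steiger_removed = n_harmonized - len(kept)

    groups = flt.stratify_by_indicator(kept, labels=dict(config.labels))
    strata_df = groups.to_frame()

    fw_threshold = multiple_testing_threshold(
        config.alpha, config.n_exposures, config.n_outcomes
    )

    analysis_sets: dict[str, tuple[str, HarmonizedSet]] = {
        "all": ("all", kept),
        "positive": (groups.labels.get("positive", "positive"), HarmonizedSet(records=groups.positive)),
        "negative": (groups.labels.get("negative", "negative"), HarmonizedSet(records=groups.negative)),
    }

    rows: list[dict] = []
    validity: dict[str, dict] = {}
    plot_data: dict[str, PlotData] = {}
    for i, (name, (label, subset)) in enumerate(analysis_sets.items()):
        estimates = mdl.estimate_all(
            subset,
            random_effects=config.random_effects,
            n_boot=config.n_boot,
            seed=config.seed + i,
            penalty_k=config.penalty_k,
        )
        vflags = apply_validity_rule(estimates, alpha=0.05)
        validity[name] = vflags
        rows.extend(_estimate_rows(name, label, estimates, vflags, fw_threshold))
        plot_data[name] = diagnostic_plot_data(subset, estimates)

    estimates_df = pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)
    counts = {
        "selected": n_selected,
        "harmonized": n_harmonized,
        "dropped_harmonization": n_selected - n_harmonized,
        "steiger_removed": n_steiger_removed,
        "analyzed": len(kept),
    }
    report = ResultsReport(
        estimates=estimates_df,
        counts=counts,
        stratum_sizes=groups.sizes,
        provenance=hset.provenance,
        steiger=steiger_df,
        strata=strata_df,
        plot_data=plot_data,
        fw_threshold=fw_threshold,
        validity=validity,
    )
    if config.output_dir:
        report.write(config.output_dir)
    return report
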