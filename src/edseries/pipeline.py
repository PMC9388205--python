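"""Five-step analysis pipeline, cohort description, and reporting.

The pipeline runs the interrupted time-series analysis end to end:

1. regress the dependent weekly count on the contemporaneous control
   series (plain OLS via the transfer machinery with no ARMA terms);
2. identify residual autocorrelation and confirm the configured
   subset-AR noise spec;
3. re-estimate with the coded intervention indicator added;
4. check residual whiteness with a Ljung-Box test (failure is surfaced
   as a warning, not an error);
5. iteratively detect and adjust for AO/TC/LS outliers.

It accepts either encounter-level records (which are filtered and binned
first) or a pre-binned :class:`~edseries.ingest.SeriesPair`, and emits a
JSON-serializable :class:`AnalysisReport` containing both coefficient
tables, diagnostics, the outlier list, and effect translations under the
8- and 9-week duration conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date
from typing import Sequence

import numpy as np
import pandas as pd

from .arima import (
    DiagnosticsReport,
    FitResult,
    NoiseSpec,
    TransferModelSpec,
    acf_pacf,
    fit_transfer_model,
    identify_noise,
    ljung_box,
)
from .ingest import (
    EncounterRecord,
    FilterSpec,
    SeriesPair,
    bin_weekly,
    filter_encounters,
)
from .intervention import (
    InterventionSpec,
    effect_summary,
    magnitude_change,
    make_indicator,
)
from .outliers import OutlierConfig, OutlierRecord, detect_and_adjust, outliers_to_frame

logger = logging.getLogger("edseries")

REPORT_SCHEMA_VERSION = "1"

SENSITIVITY_VARIANTS = ("include_inpatient", "step_switch", "alternate_pair")

AGE_BAND_EDGES = ((18, 34), (35, 44), (45, 54), (55, 64), (65, None))
AGE_BAND_LABELS = ("18-34", "35-44", "45-55", "55-64", "65+")
PAYER_LABELS = {"restricted_medical": "Undocumented", "full_medical": "Medicaid", "other": "Other"}


def percent_share(n: float, total: float, digits: int = 2) -> float:
    """Percentage of ``total`` represented by ``n``, rounded for display."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * n / total, digits)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs: cohort filters, calendar span,
    intervention coding, noise structure, outlier settings, reporting."""

    filter: FilterSpec = FilterSpec()
    anchor_date: date = date(2018, 1, 5)
    n_weeks: int = 142
    intervention: InterventionSpec = InterventionSpec(
        kind="pulse", start_date=date(2020, 3, 13), series_length=142, n_weeks=9
    )
    noise: NoiseSpec = NoiseSpec(ar_lags=(1, 5))
    outliers: OutlierConfig = OutlierConfig()
    run_outlier_scan: bool = True
    burn_in_weeks: int = 6
    effect_durations: tuple[int, ...] = (8, 9)
    ljung_box_lags: int = 12
    identify_max_lag: int = 10
    ljung_box_alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.intervention.series_length != self.n_weeks:
            raise ValueError("intervention series_length must equal n_weeks")
        if self.n_weeks < 1:
            raise ValueError("n_weeks must be positive")


@dataclass
class AnalysisReport:
    """Assembled output of one pipeline run."""

    variant: str
    pair: SeriesPair
    initial_fit: FitResult
    adjusted_fit: FitResult | None
    diagnostics_initial: DiagnosticsReport
    diagnostics_adjusted: DiagnosticsReport | None
    outliers: list[OutlierRecord]
    outliers_in_intervention: list[int]
    effects: dict
    residuals: np.ndarray
    removed_by_filter: dict[str, int] | None
    descriptive: pd.DataFrame | None
    warnings: list[str] = field(default_factory=list)
    schema_version: str = REPORT_SCHEMA_VERSION

    def to_dict(self) -> dict:
        out = {
            "schema_version": self.schema_version,
            "variant": self.variant,
            "anchor_date": self.pair.anchor_date.isoformat(),
            "n_weeks": len(self.pair),
            "initial_model": self.initial_fit.to_dict(),
            "adjusted_model": self.adjusted_fit.to_dict() if self.adjusted_fit else None,
            "diagnostics_initial": self.diagnostics_initial.to_dict(),
            "diagnostics_adjusted": (
                self.diagnostics_adjusted.to_dict() if self.diagnostics_adjusted else None
            ),
            "outliers": [o.to_dict() for o in self.outliers],
            "outliers_in_intervention_window": list(self.outliers_in_intervention),
            "effects": self.effects,
            "residuals": self.residuals.tolist(),
            "removed_by_filter": self.removed_by_filter,
            "warnings": list(self.warnings),
        }
        if self.descriptive is not None:
            out["descriptive"] = self.descriptive.to_dict(orient="tight")
        return out

    def outlier_frame(self) -> pd.DataFrame:
        return outliers_to_frame(self.outliers, anchor_date=self.pair.anchor_date)


def split_pair_by_payer(
    records: Sequence[EncounterRecord],
    config: PipelineConfig,
    dependent_payer: str = "restricted_medical",
    control_payer: str = "full_medical",
) -> tuple[SeriesPair, dict[str, int]]:
    """Filter encounters and bin them into the dependent/control pair."""
    kept, removed = filter_encounters(records, config.filter)
    dep = bin_weekly(
        [r for r in kept if r.payer == dependent_payer],
        config.anchor_date,
        config.n_weeks,
        "dependent",
    )
    ctl = bin_weekly(
        [r for r in kept if r.payer == control_payer],
        config.anchor_date,
        config.n_weeks,
        "control",
    )
    return SeriesPair(dependent=dep, control=ctl), removed


def _diagnose(fit: FitResult, config: PipelineConfig) -> DiagnosticsReport:
    report = acf_pacf(fit.residuals, config.identify_max_lag)
    n_fitted = len(fit.phi) + len(fit.theta)
    stat, p = ljung_box(fit.residuals, config.ljung_box_lags, n_fitted)
    report.ljung_box_stat, report.ljung_box_p = stat, p
    return report


def _effects_block(
    initial_fit: FitResult,
    adjusted_fit: FitResult | None,
    weekly_mean: float,
    durations: tuple[int, ...],
) -> dict:
    block: dict = {"weekly_mean": weekly_mean, "models": {}}
    for label, fit in (("initial", initial_fit), ("outlier_adjusted", adjusted_fit)):
        if fit is None or fit.omega_intervention is None:
            continue
        block["models"][label] = {
            f"{d}_week": effect_summary(fit.omega_intervention, d, weekly_mean).to_dict()
            for d in durations
        }
    omega0 = initial_fit.omega_intervention
    if adjusted_fit is not None and omega0 not in (None, 0):
        block["magnitude_change_pct"] = magnitude_change(
            omega0, adjusted_fit.omega_intervention
        )
    return block


def run_pipeline(
    data: SeriesPair | Sequence[EncounterRecord],
    config: PipelineConfig,
    variant: str = "primary",
) -> AnalysisReport:
    """Execute the five analysis steps and assemble the report."""
    removed = None
    descriptive = None
    if isinstance(data, SeriesPair):
        pair = data
    else:
        pair, removed = split_pair_by_payer(data, config)
        descriptive = describe_cohort(list(data))
    if len(pair) != config.n_weeks:
        raise ValueError(f"series length {len(pair)} != configured n_weeks {config.n_weeks}")

    warnings: list[str] = []
    indicator = make_indicator(config.intervention, config.anchor_date)

    stage = "step1_control_regression"
    try:
        spec_ols = TransferModelSpec(
            noise=NoiseSpec(ar_lags=(), ma_lags=(), d=0),
            include_control=True,
            intervention=None,
            burn_in_weeks=0,
        )
        fit_ols = fit_transfer_model(pair, spec_ols)

        stage = "step2_noise_identification"
        suggestion = identify_noise(fit_ols.residuals_full, config.identify_max_lag)
        if set(suggestion.ar_lags) != set(config.noise.ar_lags):
            msg = (
                f"identified AR lags {suggestion.ar_lags} differ from configured "
                f"{config.noise.ar_lags}; using the configured spec"
            )
            logger.info(msg)
            warnings.append("noise_identification_mismatch")

        stage = "step3_intervention_fit"
        spec_full = TransferModelSpec(
            noise=config.noise,
            include_control=True,
            intervention=tuple(indicator),
            burn_in_weeks=config.burn_in_weeks,
        )
        initial_fit = fit_transfer_model(pair, spec_full)

        stage = "step4_residual_diagnostics"
        diag_initial = _diagnose(initial_fit, config)
        if diag_initial.ljung_box_p < config.ljung_box_alpha:
            warnings.append("residual_autocorrelation_detected")
            logger.warning(
                "Ljung-Box p=%.4f below %.2f: residuals show autocorrelation",
                diag_initial.ljung_box_p,
                config.ljung_box_alpha,
            )

        stage = "step5_outlier_scan"
        adjusted_fit = None
        diag_adjusted = None
        outlier_records: list[OutlierRecord] = []
        if config.run_outlier_scan:
            adjusted_fit, outlier_records = detect_and_adjust(
                pair, spec_full, config.outliers, initial_fit=initial_fit
            )
            diag_adjusted = _diagnose(adjusted_fit, config)
            warnings.extend(w for w in adjusted_fit.warnings if w not in warnings)
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    intervention_weeks = set(np.flatnonzero(indicator) + 1)
    flagged = sorted(r.week for r in outlier_records if r.week in intervention_weeks)
    if flagged:
        logger.warning("outliers inside the intervention window at weeks %s", flagged)

    weekly_mean = float(np.mean(pair.dependent.values))
    effects = _effects_block(initial_fit, adjusted_fit, weekly_mean, config.effect_durations)

    final_fit = adjusted_fit if adjusted_fit is not None else initial_fit
    return AnalysisReport(
        variant=variant,
        pair=pair,
        initial_fit=initial_fit,
        adjusted_fit=adjusted_fit,
        diagnostics_initial=diag_initial,
        diagnostics_adjusted=diag_adjusted,
        outliers=outlier_records,
        outliers_in_intervention=flagged,
        effects=effects,
        residuals=final_fit.residuals,
        removed_by_filter=removed,
        descriptive=descriptive,
        warnings=warnings,
    )


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for the CLI."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at {stage}: {cause}")
        self.stage = stage


# ---------------------------------------------------------------------------
# Cohort description


def _age_band(age: int) -> str:
    for (lo, hi), label in zip(AGE_BAND_EDGES, AGE_BAND_LABELS):
        if age >= lo and (hi is None or age <= hi):
            return label
    return "<18"


def describe_cohort(records: Sequence[EncounterRecord]) -> pd.DataFrame:
    """Descriptive table: counts and within-margin percentages by payer,
    sex, and age band, per calendar year and in total."""
    if not records:
        logger.warning("describe_cohort called with no records")
        return pd.DataFrame()
    frame = pd.DataFrame(
        {
            "year": [r.visit_date.year for r in records],
            "Insurance status": [PAYER_LABELS[r.payer] for r in records],
            "Sex": [r.sex.capitalize() for r in records],
            "Age": [_age_band(r.age_years) for r in records],
        }
    )
    years = sorted(frame["year"].unique())
    blocks = []
    for margin in ("Insurance status", "Sex", "Age"):
        counts = frame.groupby(margin).size().rename("N_total").to_frame()
        for y in years:
            sub = frame[frame["year"] == y]
            counts[f"N_{y}"] = sub.groupby(margin).size().reindex(counts.index).fillna(0).astype(int)
            counts[f"pct_{y}"] = (100.0 * counts[f"N_{y}"] / max(len(sub), 1)).round(2)
        counts["pct_total"] = (100.0 * counts["N_total"] / len(frame)).round(2)
        counts.insert(0, "margin", margin)
        blocks.append(counts)
    table = pd.concat(blocks)
    table.index.name = "level"
    cols = ["margin"] + [c for y in years for c in (f"N_{y}", f"pct_{y}")] + ["N_total", "pct_total"]
    return table[cols]


# ---------------------------------------------------------------------------
# Sensitivity variants


def run_sensitivity(
    records: Sequence[EncounterRecord],
    config: PipelineConfig,
    variant: str,
) -> AnalysisReport:
    """Re-run the pipeline under a named modification.

    ``include_inpatient`` widens the disposition filter; ``step_switch``
    recodes the intervention as a sustained step; ``alternate_pair``
    models Latino Medi-Cal counts against a non-Latino Medi-Cal control.
    """
    if variant not in SENSITIVITY_VARIANTS:
        raise ValueError(f"variant must be one of {SENSITIVITY_VARIANTS}")
    if variant == "include_inpatient":
        cfg = replace(config, filter=config.filter.with_inpatient())
        return run_pipeline(records, cfg, variant=variant)
    if variant == "step_switch":
        step = InterventionSpec(
            kind="step",
            start_date=config.intervention.start_date,
            series_length=config.n_weeks,
        )
        cfg = replace(config, intervention=step)
        return run_pipeline(records, cfg, variant=variant)

    # alternate_pair: Latino Medi-Cal becomes the dependent series,
    # non-Latino Medi-Cal the control
    if not any(r.ethnicity == "non_latino" for r in records):
        raise ValueError("alternate_pair requires non-Latino records")
    latino_filter = replace(config.filter, ethnicity_keep=frozenset({"latino"}))
    nonlatino_filter = replace(config.filter, ethnicity_keep=frozenset({"non_latino"}))
    kept_lat, _ = filter_encounters(records, latino_filter)
    kept_non, _ = filter_encounters(records, nonlatino_filter)
    dep = bin_weekly(
        [r for r in kept_lat if r.payer == "full_medical"],
        config.anchor_date,
        config.n_weeks,
        "latino_medical",
    )
    ctl = bin_weekly(
        [r for r in kept_non if r.payer == "full_medical"],
        config.anchor_date,
        config.n_weeks,
        "nonlatino_medical",
    )
    pair = SeriesPair(dependent=dep, control=ctl)
    return run_pipeline(pair, config, variant=variant)


# ---------------------------------------------------------------------------
# Rendering and plotting


def report_to_markdown(report: AnalysisReport) -> str:
    """Human-readable rendering of an analysis report."""
    lines = [f"# Interrupted time-series report ({report.variant})", ""]
    lines.append(f"Weeks: {len(report.pair)} starting {report.pair.anchor_date.isoformat()}")
    lines.append("")
    for label, fit in (
        ("Initial model", report.initial_fit),
        ("Outlier-adjusted model", report.adjusted_fit),
    ):
        if fit is None:
            continue
        lines.append(f"## {label}")
        lines.append("")
        lines.append("| Parameter | Estimate | SE | 95% CI | p |")
        lines.append("|---|---|---|---|---|")
        for entry in fit.to_dict()["parameters"]:
            lo, hi = entry["ci95"]
            lines.append(
                f"| {entry['label']} | {entry['estimate']:.2f} | {entry['se']:.2f} "
                f"| ({lo:.2f}, {hi:.2f}) | {entry['p_value']:.4f} |"
            )
        lines.append("")
    if report.outliers:
        lines.append("## Detected outliers")
        lines.append("")
        lines.append(report.outlier_frame().to_string(index=False))
        lines.append("")
    lines.append("## Effect translation")
    lines.append("")
    eff = report.effects
    lines.append(f"Weekly mean of the dependent series: {eff['weekly_mean']:.2f}")
    for model, durs in eff.get("models", {}).items():
        for dur, s in durs.items():
            lines.append(
                f"- {model}, {dur.replace('_', ' ')} window: "
                f"{s['avoided_visits']:.2f} visits avoided "
                f"(~{s['avoided_visits_rounded']}), "
                f"{s['pct_below_expected']:.2f}% below expected"
            )
    if "magnitude_change_pct" in eff:
        lines.append(
            f"- outlier adjustment changed |omega| by {eff['magnitude_change_pct']:.2f}%"
        )
    if report.warnings:
        lines.append("")
        lines.append("## Warnings")
        for w in report.warnings:
            lines.append(f"- {w}")
    return "\n".join(lines) + "\n"


def plot_report(report: AnalysisReport, path) -> None:
    """Two-panel figure: observed dependent counts and model residuals,
    with the intervention window marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pair = report.pair
    t = np.arange(1, len(pair) + 1)
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
    ax1.plot(t, pair.dependent.values, lw=1, color="black")
    ax1.set_ylabel("ED visits / week")
    ax1.set_title("Observed dependent series")
    burn = report.initial_fit.burn_in_weeks
    ax2.plot(t[burn:], report.residuals, lw=1, color="black")
    ax2.axhline(0, color="grey", lw=0.5)
    ax2.set_ylabel("Residual")
    ax2.set_xlabel("Week")
    ax2.set_title("Model residuals (post burn-in)")
    spec = report.initial_fit.spec
    if spec.intervention is not None:
        weeks = np.flatnonzero(np.asarray(spec.intervention)) + 1
        if len(weeks):
            for ax in (ax1, ax2):
                ax.axvline(weeks[0], ls=":", color="tab:red")
                ax.axvline(weeks[-1] + 1, ls=":", color="tab:red")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
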