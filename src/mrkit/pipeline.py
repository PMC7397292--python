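"""End-to-end analysis orchestration.

Runs the full two-sample MR workflow for every locus x outcome pair in a
configuration: read tables, optionally prune the instrument by stepwise LD
selection, harmonize alleles, estimate with IVW (which reduces to the
single-variant ratio when one variant remains) and, where the instrument
is large enough, the weighted-median and MR-Egger sensitivity analyses.
Emits a numeric report table and a per-pair run summary that accounts for
every input variant as used or dropped with a reason.

No multiple-testing correction is applied — significance is the raw
two-sided p < 0.05 — but the report carries an ``n_tests`` column so
readers can judge the burden themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import estimators, select, sumstats
from .exceptions import HarmonizationError, ParameterError
from .types import HarmonizedInstrument

log = logging.getLogger(__name__)

#: Minimum instrument size for the sensitivity analyses.
MIN_SENSITIVITY_VARIANTS = 3

REPORT_COLUMNS = [
    "locus",
    "outcome",
    "method",
    "n_variants",
    "estimate",
    "se",
    "ci_low",
    "ci_high",
    "pvalue",
    "odds_ratio",
    "or_ci_low",
    "or_ci_high",
    "egger_intercept",
    "egger_intercept_se",
    "egger_intercept_pvalue",
    "n_tests",
]


@dataclass(frozen=True)
class LocusSpec:
    """One exposure instrument: a label, its table, and pruning settings."""

    label: str
    exposure: str
    mode: str = "multi_variant"  # or "single_variant" (pre-specified instrument)
    ld: Optional[str] = None
    r2_threshold: float = select.DEFAULT_R2_THRESHOLD


@dataclass(frozen=True)
class OutcomeSpec:
    label: str
    path: str


@dataclass(frozen=True)
class AnalysisConfig:
    """Validated configuration for :func:`run_analysis`.

    ``methods`` chooses among ``ivw``, ``weighted_median`` and ``egger``;
    IVW always runs. A seed is mandatory whenever the weighted median (and
    its bootstrap) is requested. ``reprune_per_outcome`` re-applies the
    stepwise selection to the post-harmonization intersection (off by
    default: the instrument is pruned once on the exposure side).
    """

    loci: Sequence[LocusSpec]
    outcomes: Sequence[OutcomeSpec]
    methods: Sequence[str] = ("ivw", "weighted_median", "egger")
    effects_model: str = "fixed"
    delta_order: str = "first"
    palindromic_policy: str = "drop"
    n_boot: int = 1000
    seed: Optional[int] = None
    reprune_per_outcome: bool = False
    report_path: Optional[str] = None
    run_summary_path: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.loci:
            raise ParameterError("config must define at least one locus")
        if not self.outcomes:
            raise ParameterError("config must define at least one outcome")
        unknown = set(self.methods) - {"ivw", "weighted_median", "egger"}
        if unknown:
            raise ParameterError(f"unknown methods: {sorted(unknown)}")
        if "weighted_median" in self.methods and self.seed is None:
            raise ParameterError("a seed is required when weighted_median is requested")
        for locus in self.loci:
            if locus.mode not in {"single_variant", "multi_variant"}:
                raise ParameterError(f"{locus.label}: unknown mode {locus.mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            loci = tuple(
                LocusSpec(
                    label=entry["label"],
                    exposure=entry["exposure"],
                    mode=entry.get("mode", "multi_variant"),
                    ld=entry.get("ld"),
                    r2_threshold=float(
                        entry.get("r2_threshold", select.DEFAULT_R2_THRESHOLD)
                    ),
                )
                for entry in raw.get("loci", [])
            )
            outcomes = tuple(
                OutcomeSpec(label=entry["label"], path=entry["path"])
                for entry in raw.get("outcomes", [])
            )
        except KeyError as exc:
            raise ParameterError(f"config entry missing required key: {exc}") from exc
        output = raw.get("output", {}) or {}
        return cls(
            loci=loci,
            outcomes=outcomes,
            methods=tuple(raw.get("methods", ("ivw", "weighted_median", "egger"))),
            effects_model=raw.get("effects_model", "fixed"),
            delta_order=raw.get("delta_order", "first"),
            palindromic_policy=raw.get("palindromic_policy", "drop"),
            n_boot=int(raw.get("n_boot", 1000)),
            seed=raw.get("seed"),
            reprune_per_outcome=bool(raw.get("reprune_per_outcome", False)),
            report_path=output.get("report"),
            run_summary_path=output.get("run_summary"),
        )


def _estimate_rows(
    instrument: HarmonizedInstrument, config: AnalysisConfig, pair_seed: int
):
    """All method estimates for one harmonized locus x outcome pair."""
    rows = []
    skipped = []
    ivw = estimators.ivw_estimate(instrument, effects_model=config.effects_model)
    rows.append(_flatten(ivw))
    enough = instrument.n_variants >= MIN_SENSITIVITY_VARIANTS
    if "weighted_median" in config.methods:
        if enough:
            wm = estimators.weighted_median(
                instrument, n_boot=config.n_boot, seed=pair_seed
            )
            rows.append(_flatten(wm))
        else:
            skipped.append("weighted_median")
    if "egger" in config.methods:
        if enough:
            egger = estimators.egger_regression(instrument)
            row = _flatten(egger.slope)
            row["egger_intercept"] = egger.intercept_estimate
            row["egger_intercept_se"] = egger.intercept_se
            row["egger_intercept_pvalue"] = egger.intercept_pvalue
            rows.append(row)
        else:
            skipped.append("egger")
    if skipped:
        log.info(
            "sensitivity analyses skipped (%s): instrument has %d variant(s), "
            "fewer than %d",
            ", ".join(skipped),
            instrument.n_variants,
            MIN_SENSITIVITY_VARIANTS,
        )
    return rows, skipped


def _flatten(est) -> dict:
    return {
        "method": est.method,
        "n_variants": est.n_variants,
        "estimate": est.estimate,
        "se": est.se,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "pvalue": est.pvalue,
        "odds_ratio": est.odds_ratio,
        "or_ci_low": est.or_ci_low,
        "or_ci_high": est.or_ci_high,
        "egger_intercept": None,
        "egger_intercept_se": None,
        "egger_intercept_pvalue": None,
    }


def run_analysis(config: AnalysisConfig):
    """Execute the configured analysis.

    Returns
    -------
    (report, run_summary) : (pandas.DataFrame, pandas.DataFrame)
        ``report`` has one row per (locus, outcome, method) with log-odds
        and odds-scale columns; ``run_summary`` has one row per
        (locus, outcome) recording variant accounting and settings. A pair
        whose harmonization leaves no variants is recorded as failed in
        the summary and the run continues.

    Both tables are also written as TSV when the config names output
    paths. Re-running with the same config and seed is byte-identical.
    """
    report_rows = []
    summary_rows = []
    for locus_idx, locus in enumerate(config.loci):
        exposure = sumstats.read_associations(locus.exposure)
        selection_removed: dict = {}
        if locus.mode == "multi_variant" and locus.ld is not None:
            ld = sumstats.read_ld_matrix(locus.ld)
            result = select.stepwise_select(exposure, ld, locus.r2_threshold)
            selection_removed = dict(result.removed)
            chosen = set(result.selected)
            exposure_used = [v for v in exposure if v.rsid in chosen]
            log.info(
                "%s: stepwise pruning kept %d of %d candidates (r2 > %.2f removed)",
                locus.label,
                len(exposure_used),
                len(exposure),
                locus.r2_threshold,
            )
        else:
            exposure_used = exposure

        for outcome_idx, outcome in enumerate(config.outcomes):
            pair_seed = None
            if config.seed is not None:
                pair_seed = int(config.seed) + 1000 * locus_idx + outcome_idx
            outcome_assoc = sumstats.read_associations(outcome.path)
            base = {
                "locus": locus.label,
                "outcome": outcome.label,
                "n_candidates": len(exposure),
                "n_pruned": len(selection_removed),
                "n_exposure_used": len(exposure_used),
            }
            try:
                instrument = sumstats.harmonize(
                    exposure_used,
                    outcome_assoc,
                    palindromic_policy=config.palindromic_policy,
                )
            except HarmonizationError as exc:
                log.error("%s x %s: %s", locus.label, outcome.label, exc)
                summary_rows.append(
                    {
                        **base,
                        "n_harmonized": 0,
                        "n_dropped": len(exposure_used),
                        "drop_log": "all:harmonization_failed",
                        "methods_run": "",
                        "methods_skipped": ";".join(config.methods),
                        "status": "failed_empty_instrument",
                    }
                )
                continue
            rows, skipped = _estimate_rows(instrument, config, pair_seed)
            for row in rows:
                report_rows.append({"locus": locus.label, "outcome": outcome.label, **row})
            drop_entries = [f"{r}:{reason}" for r, reason in instrument.drop_log.items()]
            drop_entries += [f"{r}:pruned_by_{s}" for r, s in selection_removed.items()]
            summary_rows.append(
                {
                    **base,
                    "n_harmonized": instrument.n_variants,
                    "n_dropped": instrument.n_dropped,
                    "drop_log": ";".join(drop_entries),
                    "methods_run": ";".join(r["method"] for r in rows),
                    "methods_skipped": ";".join(skipped),
                    "status": "ok",
                }
            )

    report = pd.DataFrame(report_rows)
    if len(report):
        report["n_tests"] = len(report)
        report = report[REPORT_COLUMNS]
    summary = pd.DataFrame(summary_rows)
    if config.report_path:
        _write_tsv(report, config.report_path)
    if config.run_summary_path:
        _write_tsv(summary, config.run_summary_path)
    return report, summary


def _write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
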