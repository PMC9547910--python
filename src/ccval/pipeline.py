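"""End-to-end orchestration: data -> scores -> classes -> cohorts -> reports.

``run_pipeline`` executes the full criterion-validity analysis on an
interchange CSV bundle (real extracts or generator output):

1. score the GCPS items (``gcps_scores.csv``);
2. classify chronicity from the claims lookback (``cc_classes.csv``);
3. build the cohort cascade (``cohort_ledger.json``, ``cohort_flags.csv``);
4. compare predicted vs observed severity on the validation cohort and the
   sick-leave-insured subgroup, 3-level and dichotomised
   (``metrics.json``);
5. summarise CPI-adjusted costs by GCPS grade on the cost cohort
   (``cost_summary.csv``) plus a descriptive table by grade.

Stages are isolated: a failing stage is recorded in the result and the
remaining independent stages still run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier, cohort, costs, gcps, metrics
from .classifier import CcConfig
from .data_model import TableBundle, read_tables
from .generator import GeneratorConfig, generate

logger = logging.getLogger("ccval")


@dataclass
class PipelineConfig:
    """Where to read inputs, where to write outputs, and stage constants."""

    input_dir: str | Path | None = None
    output_dir: str | Path = "ccval_out"
    generator: GeneratorConfig | None = None
    cc_config: CcConfig = field(default_factory=CcConfig)
    cpi_table: dict[int, float] | None = None
    base_year: int = costs.DEFAULT_BASE_YEAR

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.generator is None):
            raise ValueError(
                "exactly one of input_dir (existing data) or generator "
                "(synthetic data) must be given"
            )


@dataclass
class PipelineResult:
    """Outputs of one run: per-stage artifacts and per-stage errors."""

    gcps_scores: pd.DataFrame | None = None
    cc_classes: pd.DataFrame | None = None
    cohorts: cohort.Cohorts | None = None
    validation: dict | None = None
    cost_summary: pd.DataFrame | None = None
    descriptive: pd.DataFrame | None = None
    manifest: dict | None = None
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult()

    if config.generator is not None:
        bundle, manifest = generate(config.generator, out_dir / "data")
        result.manifest = manifest
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    else:
        bundle, row_errors = read_tables(config.input_dir)
        if row_errors:
            logger.warning("%d malformed input rows dropped", len(row_errors))

    # --- stage: GCPS scoring
    try:
        scores = gcps.score_frame(bundle.gcps_items)
        scores.to_csv(out_dir / "gcps_scores.csv", index=False)
        result.gcps_scores = scores
        logger.info("scored %d GCPS responses", len(scores))
    except Exception as exc:  # noqa: BLE001 - stage isolation
        result.errors["gcps"] = str(exc)

    # --- stage: chronicity classification (index date = invitation for
    #     invited persons, enrolment for self-selected)
    try:
        enrol = bundle.enrolment
        if not len(enrol):
            raise ValueError("enrolment table is empty")
        index_dates = pd.Series(
            np.where(
                enrol["path"] == "invited",
                pd.to_datetime(enrol["invitation_date"]).to_numpy(),
                pd.to_datetime(enrol["enrolment_date"]).to_numpy(),
            ),
            index=enrol["person_id"].astype(str).to_numpy(),
        )
        classes = classifier.classify_table(
            bundle.diagnoses, bundle.prescriptions, bundle.sick_leave,
            index_dates, config.cc_config,
        )
        classes.to_csv(out_dir / "cc_classes.csv", index=False)
        result.cc_classes = classes
        logger.info("classified %d persons", len(classes))
    except Exception as exc:  # noqa: BLE001
        result.errors["classifier"] = str(exc)

    # --- stage: cohort cascade (without invoice data the availability
    #     exclusion cannot be applied; everyone passes it, with a warning)
    try:
        flags = cohort.build_flags(bundle.enrolment, bundle.invoices)
        if not len(bundle.invoices):
            logger.warning(
                "no invoice data: skipping the invoice-availability exclusion"
            )
            flags["has_any_invoice_12mo"] = True
        cohorts = cohort.select_cohorts(flags)
        flags.to_csv(out_dir / "cohort_flags.csv", index=False)
        (out_dir / "cohort_ledger.json").write_text(
            json.dumps(cohorts.ledger, indent=2)
        )
        result.cohorts = cohorts
        logger.info("cohort cascade: %s", cohorts.ledger)
    except Exception as exc:  # noqa: BLE001
        result.errors["cohort"] = str(exc)

    # --- stage: criterion validity
    if result.gcps_scores is not None and result.cc_classes is not None \
            and result.cohorts is not None:
        try:
            result.validation = _validation_stage(result, bundle)
            (out_dir / "metrics.json").write_text(
                json.dumps(result.validation, indent=2)
            )
        except Exception as exc:  # noqa: BLE001
            result.errors["validation"] = str(exc)

    # --- stage: costs by grade + descriptive table
    if result.gcps_scores is not None and result.cohorts is not None:
        try:
            result.cost_summary, result.descriptive = _cost_stage(
                result, bundle, config
            )
            result.cost_summary.to_csv(out_dir / "cost_summary.csv", index=False)
            result.descriptive.to_csv(out_dir / "descriptive_by_grade.csv",
                                      index=False)
        except Exception as exc:  # noqa: BLE001
            result.errors["costs"] = str(exc)

    for stage, message in result.errors.items():
        logger.error("stage %s failed: %s", stage, message)
    return result


def _merged_severity(result: PipelineResult, persons: list[str]) -> pd.DataFrame:
    scores = result.gcps_scores.set_index(
        result.gcps_scores["person_id"].astype(str)
    )
    classes = result.cc_classes.set_index(
        result.cc_classes["person_id"].astype(str)
    )
    keep = [p for p in persons if p in scores.index and p in classes.index]
    df = pd.DataFrame(
        {
            "cc": classes.loc[keep, "cc"],
            "grade3": scores.loc[keep, "grade3"],
            "severe_obs": scores.loc[keep, "severe"],
        }
    )
    df = df[df["cc"] != classifier.NOT_CLASSIFIABLE]
    df["cc"] = df["cc"].astype(int)
    df["severe_pred"] = df["cc"] == 3
    return df


def _binary_report(df: pd.DataFrame) -> metrics.MetricReport:
    tp = int((df["severe_pred"] & df["severe_obs"]).sum())
    fp = int((df["severe_pred"] & ~df["severe_obs"]).sum())
    fn = int((~df["severe_pred"] & df["severe_obs"]).sum())
    tn = int((~df["severe_pred"] & ~df["severe_obs"]).sum())
    return metrics.evaluate_binary(metrics.ConfusionMatrix.from_binary_counts(
        tp, fp, fn, tn
    ))


def _validation_stage(result: PipelineResult, bundle: TableBundle) -> dict:
    out: dict = {}
    for name, persons in (
        ("validation_cohort", result.cohorts.validation_cohort),
        ("sickleave_subgroup", result.cohorts.sickleave_subgroup),
    ):
        df = _merged_severity(result, persons)
        if not len(df):
            raise ValueError(f"{name} is empty after filtering")
        out[name] = {
            "n": int(len(df)),
            "binary": _binary_report(df).to_dict(),
            "three_level": metrics.evaluate_ordinal(
                df["cc"].tolist(), df["grade3"].tolist()
            ).to_dict(),
        }
    return out


def _cost_stage(
    result: PipelineResult, bundle: TableBundle, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    enrol = bundle.enrolment
    enrol_dates = pd.Series(
        pd.to_datetime(enrol["enrolment_date"]).to_numpy(),
        index=enrol["person_id"].astype(str).to_numpy(),
    )
    cohort_ids = result.cohorts.cost_cohort
    if not len(bundle.invoices):
        raise ValueError("invoices table is empty")
    vectors = costs.aggregate_costs(
        bundle.invoices, enrol_dates.loc[cohort_ids],
        config.cpi_table, config.base_year,
    )
    scores = result.gcps_scores.set_index(
        result.gcps_scores["person_id"].astype(str)
    )
    grades = scores["grade"].reindex(cohort_ids).dropna()
    table = costs.cost_table_by_group(vectors, grades)

    desc = _descriptive_by_grade(scores, grades)
    return table, desc


def _descriptive_by_grade(scores: pd.DataFrame, grades: pd.Series) -> pd.DataFrame:
    """Counts plus mean (SD) of the numeric scores per grade, overall first."""
    sub = scores.loc[grades.index]
    rows = []
    for label in ["overall", *gcps.GRADES]:
        grp = sub if label == "overall" else sub[sub["grade"] == label]
        if not len(grp):
            continue
        rows.append(
            {
                "group": label,
                "n": int(len(grp)),
                "pct": round(100 * len(grp) / len(sub), 1),
                "pain_intensity_mean": grp["pain_intensity"].mean(),
                "pain_intensity_sd": grp["pain_intensity"].std(ddof=1),
                "disability_score_mean": grp["disability_score"].mean(),
                "disability_score_sd": grp["disability_score"].std(ddof=1),
                "severe_pct": round(100 * grp["severe"].mean(), 1),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report rendering


def render_confusion_report(report: metrics.MetricReport, title: str = "") -> str:
    """Text rendering of a 2x2 severity comparison in the shape of the
    published evaluation tables, with metrics at the printed precision
    (proportions to one decimal percent, correlations to three decimals)."""
    tp, fp, fn, tn = report.matrix.binary_cells()
    lines = []
    if title:
        lines += [title, "=" * len(title)]
    width = max(7, max(len(f"{x:,}") for x in (tp, fp, fn, tn, report.matrix.n)) + 2)
    cell = f"{{:>{width},}}"
    head = f"{{:<24}}{{:>{width + 10}}}{{:>{width + 14}}}{{:>{width + 6}}}"
    lines += [
        head.format("Predicted severity", "Observed severe",
                    "Observed non-severe", "Total"),
        head.format("Severe (CC 3)", f"TP: {cell.format(tp)}",
                    f"FP: {cell.format(fp)}", cell.format(tp + fp)),
        head.format("Non-severe (CC 1&2)", f"FN: {cell.format(fn)}",
                    f"TN: {cell.format(tn)}", cell.format(fn + tn)),
        head.format("Total", cell.format(tp + fn), cell.format(fp + tn),
                    cell.format(report.matrix.n)),
        "",
        f"Sensitivity          {report.sensitivity * 100:.1f}%",
        f"Specificity          {report.specificity * 100:.1f}%",
        f"Correctly predicted  {report.correct * 100:.1f}%",
        f"MCC                  {report.mcc:.3f} ({report.bands.get('mcc', '')})",
    ]
    if report.kappa is not None:
        lo, hi = report.kappa_ci
        lines.append(
            f"Cohen's kappa        {report.kappa:.3f} "
            f"(95% CI: {lo:.3f}-{hi:.3f}, {report.bands.get('kappa', '')})"
        )
    return "\n".join(lines)
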