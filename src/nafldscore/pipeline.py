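"""End-to-end pipeline: descriptives -> coding selection -> weights ->
scoring -> association -> report bundle."""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .association import association_table
from .cohort import SCORE_SNP_IDS, Cohort, write_cohort_table
from .errors import DegenerateInputError, NafldScoreError
from .report import (
    association_report,
    covariate_frequency_table,
    fibrosis_split_table,
    genotype_distribution_table,
    score_distribution_table,
    weight_manifest,
    write_tables,
)
from .score import GeneticRiskScore

log = logging.getLogger("nafldscore")

#: The study's contrasts: case group first, reference group second.
DEFAULT_CONTRASTS = [
    ("cirrhosis", "nafld"),
    ("nafld", "healthy"),
    ("cirrhosis", "healthy"),
]

#: The contrast the coding selection and weights are derived on.
DERIVATION_CONTRAST = ("cirrhosis", "nafld")


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run."""

    outdir: Path
    score_snps: list[str] = field(default_factory=lambda: list(SCORE_SNP_IDS))
    contrasts: list[tuple] = field(default_factory=lambda: list(DEFAULT_CONTRASTS))
    derivation_contrast: tuple = DERIVATION_CONTRAST
    coding: str | dict = "aic"
    weight_mode: str = "joint"
    category_column: str = "category_abstract"
    precision: int = 2
    seed: int | None = None


def _setup_logging() -> None:
    if not log.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("event=%(levelname)s stage=%(name)s msg=%(message)s"))
        log.addHandler(h)
        log.setLevel(logging.INFO)


def run_pipeline(cohort: Cohort, config: PipelineConfig) -> dict[str, Path]:
    """Run every stage on a cohort and write the report bundle.

    Stages that cannot run on the given data (e.g. association with a
    single group) are skipped with a logged reason rather than failing the
    bundle.  Returns the written file paths keyed by report name.
    """
    _setup_logging()
    tables: dict[str, pd.DataFrame] = {}

    tables["population"] = covariate_frequency_table(cohort, config.precision)
    tables["genotype_distribution"] = genotype_distribution_table(cohort)
    has_fibrosis = (
        "fibrosis_stage" in cohort.data.columns
        and cohort.data["fibrosis_stage"].notna().any()
    )

    groups = cohort.groups()
    case, ref = config.derivation_contrast
    scores = None
    if case in groups and ref in groups:
        mask = cohort.data["group"].isin([case, ref])
        X = cohort.data.loc[mask, config.score_snps]
        y = (cohort.data.loc[mask, "group"] == case).astype(float)
        model = GeneticRiskScore(
            panel=cohort.panel,
            snp_ids=config.score_snps,
            coding=config.coding,
            weight_mode=config.weight_mode,
        ).fit(X, y)
        for sid, entry in model.coding_selection_.entries.items():
            log.info(
                "coding_selected snp=%s scheme=%s delta_aic=%.3f unavailable=%s",
                sid, entry.chosen, entry.delta_to_best, entry.unavailable,
            )
        if model.weights_.dropped:
            log.warning("snps_dropped_from_score %s", model.weights_.dropped)
        tables["weights"] = weight_manifest(model.coding_selection_, model.weights_)
        scores = model.score_frame(cohort)
        if scores.attrs["excluded"]:
            log.info(
                "subjects_excluded_from_score n=%d ids=%s",
                len(scores.attrs["excluded"]), scores.attrs["excluded"],
            )
        tables["scores"] = scores.drop(columns=[], errors="ignore")
        tables["score_distribution"] = score_distribution_table(scores)
    else:
        log.warning(
            "score stage skipped: derivation contrast %s needs both groups (have %s)",
            config.derivation_contrast, groups,
        )

    if has_fibrosis:
        tables["fibrosis_split"] = fibrosis_split_table(cohort, scores, config.precision)

    if scores is not None:
        runnable = [c in groups and r in groups for c, r in config.contrasts]
        contrasts = [ct for ct, ok in zip(config.contrasts, runnable) if ok]
        for ct, ok in zip(config.contrasts, runnable):
            if not ok:
                log.warning("association skipped for contrast %s: group absent", ct)
        if contrasts:
            try:
                results = association_table(
                    cohort, scores, contrasts, category_column=config.category_column
                )
                tables["association"] = association_report(results, config.precision)
            except (DegenerateInputError, NafldScoreError) as exc:
                log.warning("association stage failed: %s", exc)

    paths = write_tables(tables, config.outdir)
    write_cohort_table(cohort, Path(config.outdir) / "cohort.tsv")
    paths["cohort"] = Path(config.outdir) / "cohort.tsv"
    return paths
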