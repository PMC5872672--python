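"""Case-control association of the genetic score, unadjusted and adjusted.

Reproduces the study's model family: for each pairwise group contrast
(cirrhosis vs NAFLD, NAFLD vs healthy, cirrhosis vs healthy) a logistic
model of case membership on the score, entered either linearly (one OR per
score point) or categorically (one OR per score band against the band "0"),
optionally adjusted for age (years), sex (male = 1), BMI (kg/m2) and T2DM
(yes = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import DegenerateInputError, SeparationError
from .glm import ORwithCI, fit_logistic, wald_or_ci

ADJUSTMENT_COVARIATES = ["age", "sex", "bmi", "t2dm"]


@dataclass
class AssociationResult:
    """ORs for the score terms of one contrast/form/adjustment combination."""

    contrast: tuple[str, str]  # (case group, reference group)
    predictor_form: str  # "linear" or "categorical"
    adjusted: bool
    covariates: list = field(default_factory=list)
    terms: dict = field(default_factory=dict)  # term label -> ORwithCI
    unavailable: dict = field(default_factory=dict)  # term label -> reason
    n_used: int = 0
    n_excluded: int = 0
    dropped_covariates: list = field(default_factory=list)


def _covariate_matrix(df: pd.DataFrame) -> np.ndarray:
    age = pd.to_numeric(df["age"]).to_numpy(dtype=float)
    bmi = pd.to_numeric(df["bmi"]).to_numpy(dtype=float)
    sex = (df["sex"] == "male").to_numpy(dtype=float)
    t2dm = (df["t2dm"] == "yes").to_numpy(dtype=float)
    return np.column_stack([age, sex, bmi, t2dm])


def run_association_models(
    cohort: Cohort,
    scores: pd.DataFrame,
    contrast: tuple[str, str],
    form: str = "linear",
    adjust: bool = False,
    category_column: str = "category_abstract",
) -> AssociationResult:
    """Fit one score-association model and return its OR terms.

    ``scores`` is the per-subject frame from ``compute_scores`` (aligned to
    the cohort by subject_id).  In categorical form the score bands of
    ``category_column`` are dummy-coded against the band "0"; a band absent
    from the data is reported as unavailable rather than fitted.  Subjects
    with a null score — or, in adjusted models, a missing covariate — are
    excluded and counted.
    """
    case, ref = contrast
    if form not in ("linear", "categorical"):
        raise ValueError(f"unknown predictor form {form!r}")
    df = cohort.data.merge(
        scores[["subject_id", "score", category_column]], on="subject_id", how="left"
    )
    in_contrast = df["group"].isin([case, ref])
    n_total = int(in_contrast.sum())
    usable = in_contrast & df["score"].notna()
    if adjust:
        for cov in ADJUSTMENT_COVARIATES:
            usable &= df[cov].notna()
    sub = df.loc[usable]
    if not (sub["group"] == case).any() or not (sub["group"] == ref).any():
        raise DegenerateInputError(f"contrast {contrast}: a group is empty")
    y = (sub["group"] == case).to_numpy(dtype=float)

    result = AssociationResult(
        contrast=contrast,
        predictor_form=form,
        adjusted=adjust,
        covariates=list(ADJUSTMENT_COVARIATES) if adjust else [],
        n_used=len(sub),
        n_excluded=n_total - len(sub),
    )

    if form == "linear":
        cols = [sub["score"].to_numpy(dtype=float)]
        labels = ["score"]
    else:
        cats = sub[category_column].astype(str)
        levels = [c for c in _band_order(cats.unique()) if c != "0"]
        if not (cats == "0").any():
            raise DegenerateInputError(
                "categorical form needs a non-empty reference band '0'"
            )
        cols, labels = [], []
        for lvl in levels:
            ind = (cats == lvl).to_numpy(dtype=float)
            if ind.sum() == 0:
                result.unavailable[f"score={lvl}"] = "no subjects in this band"
                continue
            cols.append(ind)
            labels.append(f"score={lvl}")
    X = np.column_stack(cols)
    if adjust:
        cov = _covariate_matrix(sub)
        # a constant covariate is collinear with the intercept and carries no
        # adjustment information; drop it instead of failing the fit
        varying = np.ptp(cov, axis=0) > 0
        result.dropped_covariates = [
            c for c, keep in zip(ADJUSTMENT_COVARIATES, varying) if not keep
        ]
        X = np.column_stack([X, cov[:, varying]])
    design = np.column_stack([np.ones(len(sub)), X])
    try:
        fit = fit_logistic(design, y)
    except SeparationError as exc:
        sparse = _sparsest_term(sub, labels, form, category_column, y)
        raise SeparationError(f"{exc} (sparsest score term: {sparse})") from None
    for i, lab in enumerate(labels):
        result.terms[lab] = wald_or_ci(
            float(fit.coefficients[i + 1]), float(fit.standard_errors[i + 1])
        )
    result.fit_ = fit
    return result


def _band_order(levels) -> list[str]:
    def key(lbl: str):
        head = str(lbl).split("-")[0].rstrip("+")
        try:
            return (0, float(head))
        except ValueError:
            return (1, str(lbl))

    return sorted((str(l) for l in levels), key=key)


def _sparsest_term(sub, labels, form, category_column, y):
    if form == "linear":
        return "score"
    counts = {}
    for lab in labels:
        lvl = lab.split("=", 1)[1]
        mask = (sub[category_column].astype(str) == lvl).to_numpy()
        counts[lab] = min((y[mask] == 1).sum(), (y[mask] == 0).sum())
    return min(counts, key=counts.get) if counts else "score"


def association_table(
    cohort: Cohort,
    scores: pd.DataFrame,
    contrasts: list[tuple[str, str]],
    category_column: str = "category_abstract",
) -> list[AssociationResult]:
    """All linear + categorical, unadjusted + adjusted models for the contrasts."""
    results = []
    for contrast in contrasts:
        for form in ("linear", "categorical"):
            for adjust in (False, True):
                try:
                    results.append(
                        run_association_models(
                            cohort,
                            scores,
                            contrast,
                            form=form,
                            adjust=adjust,
                            category_column=category_column,
                        )
                    )
                except SeparationError as exc:
                    # one unstable model should not void the whole table;
                    # its cells are reported unavailable with the reason
                    res = AssociationResult(
                        contrast=contrast,
                        predictor_form=form,
                        adjusted=adjust,
                        covariates=list(ADJUSTMENT_COVARIATES) if adjust else [],
                    )
                    res.unavailable["score"] = f"separation: {exc}"
                    results.append(res)
    return results
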