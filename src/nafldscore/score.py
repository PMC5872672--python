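"""Construction of the integer genetic risk score.

The procedure, applied here to the PNPLA3/TM6SF2/KLF6 panel for NASH
cirrhosis versus noncirrhotic NAFLD:

1. For each SNP, choose the genotype coding (additive, dominant or
   recessive) whose univariable logistic model has the lowest AIC for the
   case-control contrast.  A recessive (or dominant) coding that is constant
   in the contrast — e.g. no minor-allele homozygotes at all — is marked
   unavailable rather than fitted.  AIC ties go to the additive coding, the
   least restrictive model for an ordinal genotype.
2. Fit one joint logistic model containing all encoded SNPs and take its
   coefficients as raw weights (a univariable per-SNP mode is available
   behind ``weight_mode``).
3. Standardize the raw coefficients by their mean and round to the nearest
   unit (halves away from zero) to obtain integer points per SNP; a SNP
   whose points round to 0 is dropped from the score with a warning.
4. Score each subject as the points-weighted sum of encoded genotypes.

With the study's coefficients (0.43, 0.39, 0.46) every SNP gets one point,
the PNPLA3 coding is additive and TM6SF2/KLF6 are dominant, so the score
runs from 0 to 4.

``GeneticRiskScore`` packages steps 1-4 as a scikit-learn transformer;
the module functions expose the individual steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import (
    DEFAULT_PANEL,
    SCHEMES,
    SCORE_SNP_IDS,
    Cohort,
    Panel,
    encode_series,
    max_code,
    MISSING,
)
from .errors import DegenerateInputError, SeparationError
from .glm import fit_logistic
from .util import round_half_away

#: Preference order used to break AIC ties.
_TIE_ORDER = ("additive", "dominant", "recessive")
_AIC_TIE_TOL = 1e-6


@dataclass(frozen=True)
class CodingEntry:
    """Per-SNP coding selection: candidate AICs and the chosen scheme."""

    snp_id: str
    aic: dict  # scheme -> AIC, or None when the scheme is unavailable
    chosen: str
    delta_to_best: float  # AIC margin to the best competing available scheme
    tied: bool = False

    @property
    def unavailable(self) -> list[str]:
        return [s for s, a in self.aic.items() if a is None]


@dataclass
class CodingSelection:
    """Chosen genotype coding per SNP."""

    entries: dict = field(default_factory=dict)  # snp_id -> CodingEntry

    def scheme(self, snp_id: str) -> str:
        return self.entries[snp_id].chosen

    @classmethod
    def fixed(cls, schemes: dict) -> "CodingSelection":
        """A selection imposed a priori (no AIC comparison)."""
        return cls(
            {sid: CodingEntry(sid, {}, sch, 0.0) for sid, sch in schemes.items()}
        )


#: The study's codings: additive PNPLA3, dominant TM6SF2 and KLF6.
PAPER_CODINGS = {
    "rs738409": "additive",
    "rs58542926": "dominant",
    "rs3750861": "dominant",
}


@dataclass(frozen=True)
class WeightSet:
    """Integer point weights derived from raw logistic coefficients."""

    raw: dict  # snp_id -> raw coefficient (log-odds)
    standardized: dict  # snp_id -> raw / mean(raw)
    points: dict  # snp_id -> integer points, included SNPs only
    dropped: dict  # snp_id -> reason, for SNPs excluded (points rounded to 0)

    @property
    def included_snps(self) -> list[str]:
        return list(self.points)

    def max_score(self, selection: CodingSelection) -> int:
        return sum(
            p * max_code(selection.scheme(sid)) for sid, p in self.points.items()
        )


def select_coding(
    cohort: Cohort,
    snp_id: str,
    contrast: tuple[str, str],
    candidate_schemes: tuple[str, ...] = SCHEMES,
) -> CodingEntry:
    """Choose the genotype coding for one SNP by AIC on a group contrast.

    Fits outcome ~ intercept + encoded genotype for each candidate scheme
    over subjects of the two contrast groups with a non-missing call at this
    SNP.  A scheme whose encoding is constant in that subset (e.g. recessive
    with no minor homozygote) is marked unavailable.  The minimal-AIC scheme
    wins; ties go to additive.
    """
    case, ref = contrast
    df = cohort.data
    in_contrast = df["group"].isin([case, ref]) & (df[snp_id] != MISSING)
    sub = df.loc[in_contrast]
    if not (sub["group"] == case).any() or not (sub["group"] == ref).any():
        raise DegenerateInputError(
            f"contrast {contrast} has an empty group after missing-genotype exclusion"
        )
    y = (sub["group"] == case).to_numpy(dtype=float)
    snp = cohort.panel[snp_id]
    x_by_scheme = {
        sch: encode_series(sub[snp_id], snp, sch).to_numpy()
        for sch in candidate_schemes
    }
    aics: dict[str, float | None] = {}
    for sch, x in x_by_scheme.items():
        if np.ptp(x) == 0:  # constant encoding: model unidentifiable, not an error
            aics[sch] = None
            continue
        design = np.column_stack([np.ones(len(x)), x])
        try:
            aics[sch] = fit_logistic(design, y).aic
        except SeparationError:
            # e.g. a lone minor homozygote that is a case: the MLE (and
            # hence the AIC) does not exist for this coding
            aics[sch] = None
    available = {s: a for s, a in aics.items() if a is not None}
    if not available:
        raise DegenerateInputError(
            f"{snp_id}: every candidate coding is constant in contrast {contrast}"
        )
    best = min(available.values())
    tied = [s for s in _TIE_ORDER if s in available and available[s] <= best + _AIC_TIE_TOL]
    chosen = tied[0]
    others = [a for s, a in available.items() if s != chosen]
    delta = float(min(others) - available[chosen]) if others else 0.0
    return CodingEntry(
        snp_id=snp_id,
        aic=aics,
        chosen=chosen,
        delta_to_best=delta,
        tied=len(tied) > 1,
    )


def derive_weights(raw_coefficients: dict) -> WeightSet:
    """Standardize raw log-odds coefficients by their mean and round to units.

    standardized_i = raw_i / mean(raw); points_i = round half away from zero.
    The coefficients must point in the risk-increasing direction on average
    (mean > 0).  SNPs whose points round to 0 are dropped with a warning —
    they would contribute nothing to an integer score.
    """
    if not raw_coefficients:
        raise DegenerateInputError("no coefficients to derive weights from")
    values = np.array(list(raw_coefficients.values()), dtype=float)
    if not np.isfinite(values).all():
        raise DegenerateInputError("non-finite coefficient in weight derivation")
    mean = float(values.mean())
    if mean <= 0:
        raise DegenerateInputError(
            f"mean coefficient {mean:.4f} <= 0; weights require a "
            "risk-increasing orientation"
        )
    standardized = {sid: float(v) / mean for sid, v in raw_coefficients.items()}
    points: dict[str, int] = {}
    dropped: dict[str, str] = {}
    for sid, s in standardized.items():
        pt = int(round_half_away(s, 0))
        if pt == 0:
            dropped[sid] = f"standardized weight {s:.3f} rounds to 0 points"
            warnings.warn(
                f"{sid} dropped from the score: {dropped[sid]}", stacklevel=2
            )
        else:
            points[sid] = pt
    return WeightSet(
        raw=dict(raw_coefficients),
        standardized=standardized,
        points=points,
        dropped=dropped,
    )


def compute_scores(
    cohort: Cohort,
    selection: CodingSelection,
    weights: WeightSet,
) -> pd.DataFrame:
    """Per-subject integer scores: sum of points x encoded genotype.

    Returns a frame with subject_id, group (and fibrosis_stage when
    present), score, and both category labellings.  Subjects missing a
    genotype at any included SNP get a null score (they are excluded from
    score analyses); ``attrs['excluded']`` lists their ids.
    """
    df = cohort.data
    max_score = weights.max_score(selection)
    score = np.zeros(len(df))
    complete = np.ones(len(df), dtype=bool)
    for sid, pts in weights.points.items():
        codes = encode_series(df[sid], cohort.panel[sid], selection.scheme(sid)).to_numpy()
        complete &= ~np.isnan(codes)
        score = score + pts * np.where(np.isnan(codes), 0.0, codes)
    out_cols = ["subject_id", "group"]
    if "fibrosis_stage" in df.columns:
        out_cols.append("fibrosis_stage")
    out = df[out_cols].copy()
    out["score"] = pd.array(
        [int(s) if ok else None for s, ok in zip(score, complete)], dtype="Int64"
    )
    out["category_abstract"] = [
        categorize_score(int(s), "abstract", max_score) if ok else None
        for s, ok in zip(score, complete)
    ]
    out["category_table"] = [
        categorize_score(int(s), "table", max_score) if ok else None
        for s, ok in zip(score, complete)
    ]
    out.attrs["excluded"] = df.loc[~complete, "subject_id"].tolist()
    out.attrs["max_score"] = max_score
    return out


def categorize_score(score: int, mode: str = "abstract", max_score: int = 4) -> str:
    """Band an integer score.

    ``abstract`` mode pools into {0, 1-2, 3-4}; ``table`` mode keeps single
    values with the top band pooled, {0, 1, 2, 3+}.
    """
    if not 0 <= score <= max_score:
        raise ValueError(f"score {score} outside [0, {max_score}]")
    if mode == "abstract":
        if score == 0:
            return "0"
        return "1-2" if score <= 2 else "3-4"
    if mode == "table":
        return str(score) if score < 3 else "3+"
    raise ValueError(f"unknown categorization mode {mode!r}")


def group_score_summary(
    scores: pd.DataFrame, grouping: str | pd.Series = "group"
) -> pd.DataFrame:
    """Per-group score mean, sample SD, n, and the score-value distribution.

    The distribution columns (``p0 .. p<max>``) give the fraction of scored
    subjects in the group at each score value — the per-group histogram of
    score prevalences.
    """
    if isinstance(grouping, str):
        grouping = scores[grouping]
    scored = scores["score"].notna()
    max_score = int(scores.attrs.get("max_score", scores.loc[scored, "score"].max()))
    rows = []
    for level in pd.unique(grouping.dropna()):
        vals = scores.loc[scored & (grouping == level), "score"].astype(float)
        if len(vals) == 0:
            raise DegenerateInputError(f"group {level!r} has no scored subjects")
        row = {
            "group": level,
            "n": len(vals),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        }
        for s in range(max_score + 1):
            row[f"p{s}"] = float((vals == s).mean())
        rows.append(row)
    return pd.DataFrame(rows)


class GeneticRiskScore(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer building an integer genetic risk score.

    ``fit`` takes a genotype frame (one canonical two-letter genotype string
    column per rsID) and a binary outcome (1 = case), selects a coding per
    SNP by AIC, derives integer point weights from a joint logistic fit, and
    ``transform`` maps genotypes to scores (NaN where a genotype is missing).

    Parameters
    ----------
    panel : SNP panel providing allele definitions (default: the five-locus
        study panel).
    snp_ids : SNPs entering the score (default: PNPLA3, TM6SF2, KLF6).
    coding : "aic" for data-driven selection, or a dict snp_id -> scheme to
        impose the codings a priori (e.g. ``PAPER_CODINGS``).
    weight_mode : "joint" (one multivariable fit, the default) or
        "univariable" (per-SNP fits).
    candidate_schemes : schemes considered during AIC selection.
    """

    def __init__(
        self,
        panel: Panel = DEFAULT_PANEL,
        snp_ids: list[str] | None = None,
        coding: str | dict = "aic",
        weight_mode: str = "joint",
        candidate_schemes: tuple[str, ...] = SCHEMES,
    ):
        self.panel = panel
        self.snp_ids = snp_ids
        self.coding = coding
        self.weight_mode = weight_mode
        self.candidate_schemes = candidate_schemes

    def _snps(self) -> list[str]:
        return list(self.snp_ids) if self.snp_ids is not None else list(SCORE_SNP_IDS)

    def _encode_frame(self, X: pd.DataFrame, selection: CodingSelection) -> pd.DataFrame:
        cols = {
            sid: encode_series(X[sid], self.panel[sid], selection.scheme(sid))
            for sid in selection.entries
            if sid in X.columns
        }
        return pd.DataFrame(cols, index=X.index, dtype=float)

    def fit(self, X: pd.DataFrame, y):
        snps = self._snps()
        y = np.asarray(y, dtype=float)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        if isinstance(self.coding, dict):
            self.coding_selection_ = CodingSelection.fixed(
                {sid: self.coding[sid] for sid in snps}
            )
        else:
            entries = {}
            for sid in snps:
                snp = self.panel[sid]
                aics: dict[str, float | None] = {}
                ok = (X[sid] != MISSING).to_numpy()
                for sch in self.candidate_schemes:
                    x = encode_series(X.loc[ok, sid], snp, sch).to_numpy()
                    if len(x) == 0 or np.ptp(x) == 0:
                        aics[sch] = None
                        continue
                    design = np.column_stack([np.ones(len(x)), x])
                    try:
                        aics[sch] = fit_logistic(design, y[ok]).aic
                    except SeparationError:
                        aics[sch] = None
                available = {s: a for s, a in aics.items() if a is not None}
                if not available:
                    raise DegenerateInputError(f"{sid}: all codings constant")
                best = min(available.values())
                tied = [
                    s
                    for s in _TIE_ORDER
                    if s in available and available[s] <= best + _AIC_TIE_TOL
                ]
                chosen = tied[0]
                others = [a for s, a in available.items() if s != chosen]
                entries[sid] = CodingEntry(
                    sid,
                    aics,
                    chosen,
                    float(min(others) - available[chosen]) if others else 0.0,
                    tied=len(tied) > 1,
                )
            self.coding_selection_ = CodingSelection(entries)

        encoded = self._encode_frame(X[snps], self.coding_selection_)
        complete = encoded.notna().all(axis=1).to_numpy()
        self.n_excluded_ = int((~complete).sum())
        enc = encoded.loc[complete].to_numpy()
        yy = y[complete]
        raw: dict[str, float] = {}
        if self.weight_mode == "joint":
            design = np.column_stack([np.ones(len(enc)), enc])
            fit = fit_logistic(design, yy)
            for i, sid in enumerate(snps):
                raw[sid] = float(fit.coefficients[i + 1])
            self.weight_fit_ = fit
        elif self.weight_mode == "univariable":
            for i, sid in enumerate(snps):
                design = np.column_stack([np.ones(len(enc)), enc[:, i]])
                raw[sid] = float(fit_logistic(design, yy).coefficients[1])
        else:
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")
        self.weights_ = derive_weights(raw)
        self.max_score_ = self.weights_.max_score(self.coding_selection_)
        self.n_features_in_ = len(snps)
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        """Integer scores as an (n, 1) float array; NaN where incomplete."""
        encoded = self._encode_frame(
            X[list(self.weights_.points)], self.coding_selection_
        )
        pts = np.array([self.weights_.points[s] for s in encoded.columns], dtype=float)
        return (encoded.to_numpy() @ pts)[:, None]

    def score_frame(self, cohort: Cohort) -> pd.DataFrame:
        """Convenience: full per-subject score table for a cohort."""
        return compute_scores(cohort, self.coding_selection_, self.weights_)
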