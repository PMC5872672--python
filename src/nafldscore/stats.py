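"""Descriptive and comparative statistics for case-control genotype data.

Allele/genotype frequencies, the Pearson chi-square test (no continuity
correction), Kruskal-Wallis, and the closed-form 2x2 odds ratio with Woolf
confidence interval.  The closed forms double as independent oracles for the
iteratively-reweighted-least-squares logistic fitter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import MISSING, Cohort, SNPDef, minor_allele_count
from .errors import DegenerateInputError
from .util import round_half_away

Z_95 = float(sps.norm.ppf(0.975))  # 1.959964...


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype class counts at one locus: ancestral hom / het / minor hom."""

    n_homozygous_ancestral: int
    n_heterozygous: int
    n_homozygous_minor: int

    def __post_init__(self) -> None:
        if min(self.as_tuple()) < 0:
            raise ValueError("genotype counts must be non-negative")

    def as_tuple(self) -> tuple[int, int, int]:
        return (
            self.n_homozygous_ancestral,
            self.n_heterozygous,
            self.n_homozygous_minor,
        )

    @property
    def total(self) -> int:
        return sum(self.as_tuple())


@dataclass(frozen=True)
class FreqResult:
    """Minor-allele frequency with the allele total it was computed from."""

    maf: float
    n_alleles: int

    @property
    def rounded(self) -> float:
        """MAF at the 2-decimal reporting precision of the frequency tables."""
        return round_half_away(self.maf, 2)


@dataclass(frozen=True)
class ContingencyResult:
    statistic: float
    df: int
    p_value: float
    min_expected: float

    @property
    def sparse(self) -> bool:
        """True when any expected cell count is below 5 (chi-square approximation weak)."""
        return self.min_expected < 5


def allele_frequency(counts: GenotypeCounts) -> FreqResult:
    """Minor-allele frequency (het + 2*minor hom) / (2*total)."""
    if counts.total == 0:
        raise DegenerateInputError("allele frequency undefined for empty counts")
    n_alleles = 2 * counts.total
    maf = (counts.n_heterozygous + 2 * counts.n_homozygous_minor) / n_alleles
    return FreqResult(maf=maf, n_alleles=n_alleles)


def genotype_counts(cohort: Cohort, snp: SNPDef | str, mask=None) -> GenotypeCounts:
    """Genotype class counts for one SNP over (a subset of) a cohort."""
    snp = cohort.panel[snp] if isinstance(snp, str) else snp
    col = cohort.data[snp.snp_id]
    if mask is not None:
        col = col[mask]
    col = col[col != MISSING]
    counts = [0, 0, 0]
    for g in col:
        counts[minor_allele_count(g, snp)] += 1
    return GenotypeCounts(*counts)


def genotype_count_table(
    cohort: Cohort,
    snp: SNPDef | str,
    grouping: pd.Series | str = "group",
    group_order: list[str] | None = None,
    dichotomize: bool = False,
) -> pd.DataFrame:
    """Genotype-class x group counts matrix for one SNP.

    Rows are the genotype classes (three, or two when ``dichotomize`` pools
    heterozygotes with minor homozygotes into a carrier row); columns are the
    grouping levels.  Missing genotypes are excluded.
    """
    snp = cohort.panel[snp] if isinstance(snp, str) else snp
    if isinstance(grouping, str):
        grouping = cohort.data[grouping]
    levels = group_order or [g for g in pd.unique(grouping.dropna())]
    if len(levels) < 2:
        raise DegenerateInputError("grouping must yield at least 2 groups")
    cols = {}
    for level in levels:
        mask = (grouping == level).to_numpy()
        if not mask.any():
            raise DegenerateInputError(f"group {level!r} is empty")
        c = genotype_counts(cohort, snp, mask=mask)
        cols[level] = list(c.as_tuple())
    aa, am, mm = snp.genotype_classes
    table = pd.DataFrame(cols, index=[aa, am, mm])
    if dichotomize:
        carrier = table.loc[[am, mm]].sum()
        table = pd.DataFrame(
            {lvl: [table.loc[aa, lvl], carrier[lvl]] for lvl in levels},
            index=[aa, f"{am}/{mm}"],
        )
    return table


def pearson_chi2(table) -> ContingencyResult:
    """Pearson chi-square test of independence on an r x c count table.

    Plain sum((O-E)^2/E) with no continuity correction, p from the chi-square
    distribution on (r-1)(c-1) degrees of freedom.  A warning is attached
    when any expected count falls below 5; the test is still computed (the
    frequency tables this reproduces use the plain statistic throughout).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DegenerateInputError("need an r x c table with r, c >= 2")
    if (obs < 0).any():
        raise DegenerateInputError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise DegenerateInputError("zero row/column margin: table is degenerate")
    expected = np.outer(row, col) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df))
    min_e = float(expected.min())
    if min_e < 5:
        warnings.warn(
            f"expected count {min_e:.2f} < 5; chi-square approximation may be poor",
            stacklevel=2,
        )
    return ContingencyResult(statistic=stat, df=df, p_value=p, min_expected=min_e)


def allele_count_chi2(c1: GenotypeCounts, c2: GenotypeCounts) -> ContingencyResult:
    """2x2 allele-count chi-square between two groups (pairwise frequency contrast)."""
    a1 = c1.n_heterozygous + 2 * c1.n_homozygous_minor
    a2 = c2.n_heterozygous + 2 * c2.n_homozygous_minor
    table = [[2 * c1.total - a1, a1], [2 * c2.total - a2, a2]]
    return pearson_chi2(table)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis rank test (tie-corrected H, chi-square p-value)."""
    if len(groups) < 2:
        raise DegenerateInputError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise DegenerateInputError("all groups must be non-empty")
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def odds_ratio_2x2(
    a: float, b: float, c: float, d: float, correction: bool = False
) -> tuple[float, float, float]:
    """Closed-form odds ratio ad/bc with Woolf 95% CI.

    Layout: a = exposed cases, b = exposed controls, c = unexposed cases,
    d = unexposed controls.  With ``correction`` and any zero cell, 0.5 is
    added to every cell (Haldane-Anscombe) before computing.
    """
    if min(a, b, c, d) < 0:
        raise DegenerateInputError("cell counts must be non-negative")
    if correction and 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b * c == 0 or a * d == 0:
        raise DegenerateInputError(
            "zero cell makes the odds ratio undefined/infinite; "
            "pass correction=True for the 0.5-adjusted estimate"
        )
    or_value = (a * d) / (b * c)
    se_log = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = float(or_value * np.exp(-Z_95 * se_log))
    hi = float(or_value * np.exp(Z_95 * se_log))
    return float(or_value), lo, hi
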