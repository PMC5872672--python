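"""TSV report writers mirroring the study's published tables.

All reports are tab-separated UTF-8 with a header row; odds-ratio cells are
formatted ``X.XX (L–U)``.  Logs never mix with data: writers only emit
tables.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .association import AssociationResult
from .cohort import Cohort
from .score import CodingSelection, WeightSet, group_score_summary
from .stats import (
    allele_frequency,
    genotype_count_table,
    genotype_counts,
    kruskal_wallis,
    pearson_chi2,
)
from .util import round_half_away

GROUP_ORDER = ["healthy", "nafld", "cirrhosis"]


def _fmt(x: float, precision: int) -> str:
    return f"{round_half_away(x, precision):.{precision}f}"


def format_or_cell(or_value: float, ci_low: float, ci_high: float, precision: int = 2) -> str:
    """Format an OR with its CI the way the association table prints it."""
    return (
        f"{_fmt(or_value, precision)} "
        f"({_fmt(ci_low, precision)}–{_fmt(ci_high, precision)})"
    )


def covariate_frequency_table(cohort: Cohort, precision: int = 2) -> pd.DataFrame:
    """Covariate summaries and per-group minor-allele frequencies
    (the study's population-description table)."""
    df = cohort.data
    groups = [g for g in GROUP_ORDER if (df["group"] == g).any()]
    rows = []

    def per_group(fn):
        out = {"all": fn(df)}
        for g in groups:
            out[g] = fn(df[df["group"] == g])
        return out

    rows.append({"variable": "n", **per_group(len)})
    age = per_group(lambda d: f"{d['age'].mean():.1f} ({d['age'].std(ddof=1):.1f})")
    rows.append({"variable": "age_years", **age})
    rows.append(
        {
            "variable": "sex_male_pct",
            **per_group(lambda d: _fmt(100 * (d["sex"] == "male").mean(), 1)),
        }
    )
    rows.append(
        {
            "variable": "bmi",
            **per_group(lambda d: f"{d['bmi'].mean():.1f} ({d['bmi'].std(ddof=1):.1f})"),
        }
    )
    rows.append(
        {
            "variable": "t2dm_pct",
            **per_group(lambda d: _fmt(100 * (d["t2dm"] == "yes").mean(), 1)),
        }
    )
    for snp in cohort.panel:
        def maf_of(d, snp=snp):
            sub = Cohort(cohort.panel, d.copy())
            return _fmt(allele_frequency(genotype_counts(sub, snp)).maf, precision)

        rows.append(
            {
                "variable": f"{snp.gene}_{snp.minor_allele}_allele_frequency",
                **per_group(maf_of),
            }
        )
    p_vals = {}
    if len(groups) >= 2:
        p_vals["age_years"] = kruskal_wallis(
            *[df.loc[df["group"] == g, "age"].to_numpy() for g in groups]
        )[1]
        p_vals["bmi"] = kruskal_wallis(
            *[df.loc[df["group"] == g, "bmi"].to_numpy() for g in groups]
        )[1]
        for var, col, level in (("sex_male_pct", "sex", "male"), ("t2dm_pct", "t2dm", "yes")):
            tab = [
                [
                    int(((df["group"] == g) & (df[col] == level)).sum()),
                    int(((df["group"] == g) & (df[col] != level)).sum()),
                ]
                for g in groups
            ]
            p_vals[var] = pearson_chi2(tab).p_value
    table = pd.DataFrame(rows)
    table["p_overall"] = table["variable"].map(
        lambda v: f"{p_vals[v]:.3g}" if v in p_vals else ""
    )
    return table


def genotype_distribution_table(cohort: Cohort, dichotomize_dominant: bool = True) -> pd.DataFrame:
    """Per-locus genotype counts with column percentages and the overall
    chi-square p, in the layout of the study's genotype table."""
    df = cohort.data
    groups = [g for g in GROUP_ORDER if (df["group"] == g).any()]

    def count_table(snp, dichot):
        if len(groups) >= 2:
            return genotype_count_table(cohort, snp, group_order=groups, dichotomize=dichot)
        c = genotype_counts(cohort, snp)
        aa, am, mm = snp.genotype_classes
        if dichot:
            return pd.DataFrame(
                {groups[0]: [c.n_homozygous_ancestral, c.n_heterozygous + c.n_homozygous_minor]},
                index=[aa, f"{am}/{mm}"],
            )
        return pd.DataFrame({groups[0]: list(c.as_tuple())}, index=[aa, am, mm])

    rows = []
    for snp in cohort.panel:
        variants = [(snp.gene, False)]
        counts3 = count_table(snp, False)
        if dichotomize_dominant and (counts3.iloc[2] == 0).any():
            variants.append((f"{snp.gene}_dichotomized", True))
        for label, dichot in variants:
            tab = count_table(snp, dichot)
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                try:
                    p = pearson_chi2(tab.to_numpy()).p_value
                except Exception:
                    p = float("nan")
            for i, (geno, row) in enumerate(tab.iterrows()):
                rec = {"locus": label, "genotype": geno}
                for g in groups:
                    n = int(row[g])
                    pct = 100 * n / tab[g].sum()
                    rec[g] = f"{n} ({_fmt(pct, 1)}%)"
                rec["p_overall"] = f"{p:.3g}" if i == 0 else ""
                rows.append(rec)
    return pd.DataFrame(rows)


def weight_manifest(selection: CodingSelection, weights: WeightSet) -> pd.DataFrame:
    """snp_id, chosen scheme, raw coefficient, standardized value, points."""
    rows = []
    for sid, raw in weights.raw.items():
        rows.append(
            {
                "snp_id": sid,
                "scheme": selection.scheme(sid),
                "raw_coefficient": f"{raw:.4f}",
                "standardized": f"{weights.standardized[sid]:.4f}",
                "points": weights.points.get(sid, 0),
                "included": sid in weights.points,
            }
        )
    return pd.DataFrame(rows)


def association_report(results: list[AssociationResult], precision: int = 2) -> pd.DataFrame:
    """Association-table layout: rows = score terms, one OR/aOR column pair
    per contrast, cells ``X.XX (L–U)``."""
    contrasts = []
    for r in results:
        if r.contrast not in contrasts:
            contrasts.append(r.contrast)
    term_labels: list[str] = []
    for r in results:
        for t in r.terms:
            if t not in term_labels:
                term_labels.append(t)
    if not term_labels:
        cols = ["term"]
        for c in contrasts:
            cols += [f"OR_{c[0]}_vs_{c[1]}", f"aOR_{c[0]}_vs_{c[1]}"]
        return pd.DataFrame(columns=cols)
    rows = []
    for term in term_labels:
        rec = {"term": term}
        for contrast in contrasts:
            for adjusted, col in ((False, "OR"), (True, "aOR")):
                label = f"{col}_{contrast[0]}_vs_{contrast[1]}"
                cell = ""
                for r in results:
                    if r.contrast == contrast and r.adjusted == adjusted:
                        if term in r.terms:
                            t = r.terms[term]
                            cell = format_or_cell(
                                t.or_value, t.ci_low, t.ci_high, precision
                            )
                        elif term in r.unavailable:
                            cell = f"NA ({r.unavailable[term]})"
                rec[label] = cell
        rows.append(rec)
    return pd.DataFrame(rows)


def score_distribution_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Fraction of subjects at each score value per group (the score
    prevalence histogram)."""
    return group_score_summary(scores, "group")


def fibrosis_split_table(cohort: Cohort, scores: pd.DataFrame | None = None, precision: int = 2) -> pd.DataFrame:
    """Covariates, allele frequencies and (optionally) score summary for the
    NAFLD group split into F0-1 versus F2-3 fibrosis."""
    df = cohort.data
    nafld = df[(df["group"] == "nafld") & df.get("fibrosis_stage").notna()]
    split = nafld["fibrosis_stage"].map(
        lambda s: "F0-1" if s in ("F0", "F1") else "F2-3"
    )
    rows = []
    levels = ["F0-1", "F2-3"]
    sub = {lvl: nafld[split == lvl] for lvl in levels}
    rows.append({"variable": "n", **{lvl: len(sub[lvl]) for lvl in levels}})
    rows.append(
        {
            "variable": "age_years",
            **{
                lvl: f"{sub[lvl]['age'].mean():.1f} ({sub[lvl]['age'].std(ddof=1):.1f})"
                for lvl in levels
            },
        }
    )
    rows.append(
        {
            "variable": "t2dm_pct",
            **{lvl: _fmt(100 * (sub[lvl]["t2dm"] == "yes").mean(), 1) for lvl in levels},
        }
    )
    for snp in cohort.panel:
        rec = {"variable": f"{snp.gene}_{snp.minor_allele}_allele_frequency"}
        for lvl in levels:
            c = genotype_counts(Cohort(cohort.panel, sub[lvl].copy()), snp)
            rec[lvl] = _fmt(allele_frequency(c).maf, precision)
        rows.append(rec)
    if scores is not None:
        merged = nafld[["subject_id"]].merge(scores, on="subject_id")
        merged_split = split.loc[nafld.index].to_numpy()
        rec = {"variable": "score_mean_sd"}
        for lvl in levels:
            vals = merged.loc[merged_split == lvl, "score"].dropna().astype(float)
            rec[lvl] = f"{vals.mean():.1f} ({vals.std(ddof=1):.1f})"
        rows.append(rec)
    return pd.DataFrame(rows)


def write_tables(tables: dict[str, pd.DataFrame], outdir) -> dict[str, Path]:
    """Write each named table as <name>.tsv under ``outdir``; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, table in tables.items():
        path = outdir / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False)
        paths[name] = path
    return paths
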