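"""Cohort data model: SNP panel, genotype canonicalization and encoding, TSV and VCF input.

A cohort is a table of subjects (group label, covariates, one genotype string
per panel SNP).  Genotypes are unphased diploid calls stored in canonical
order — ancestral allele before minor allele ("CG", never "GC") — so a
genotype maps unambiguously onto a minor-allele count of 0, 1 or 2.  The risk
(minor) allele of every locus is fixed by the panel definition, never
re-estimated from the data: frequency-based relabelling could flip codings in
small groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    CohortFormatError,
    GenotypeValidationError,
    PanelLookupError,
)

#: Marker used for missing genotype calls in cohort tables.
MISSING = "NA"

VALID_GROUPS = ("healthy", "nafld", "cirrhosis")
VALID_FIBROSIS = ("F0", "F1", "F2", "F3")

#: Encoding schemes for a biallelic genotype.
SCHEMES = ("additive", "dominant", "recessive")


@dataclass(frozen=True)
class SNPDef:
    """A biallelic SNP: rsID, gene symbol, ancestral and minor (risk) allele."""

    snp_id: str
    gene: str
    ancestral_allele: str
    minor_allele: str

    def __post_init__(self) -> None:
        for a in (self.ancestral_allele, self.minor_allele):
            if a not in "ACGT" or len(a) != 1:
                raise ValueError(f"{self.snp_id}: allele {a!r} is not a single nucleotide")
        if self.ancestral_allele == self.minor_allele:
            raise ValueError(f"{self.snp_id}: ancestral and minor allele are identical")

    @property
    def genotype_classes(self) -> tuple[str, str, str]:
        """Canonical genotype strings ordered by minor-allele count (0, 1, 2)."""
        a, m = self.ancestral_allele, self.minor_allele
        return (a + a, a + m, m + m)


class Panel(tuple):
    """An ordered, immutable collection of SNPDef with rsID lookup."""

    def __new__(cls, snps: Iterable[SNPDef]):
        snps = tuple(snps)
        ids = [s.snp_id for s in snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate rsIDs in panel")
        return super().__new__(cls, snps)

    def __getitem__(self, key):  # rsID or positional access
        if isinstance(key, str):
            for s in self:
                if s.snp_id == key:
                    return s
            raise PanelLookupError(f"SNP {key!r} not in panel")
        return super().__getitem__(key)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self]


#: The five loci genotyped in the study: PNPLA3 I148M, TM6SF2 E167K, and the
#: KLF6, SOD2 and LPIN1 variants.  C is ancestral at every locus; the risk
#: allele is G for PNPLA3 and T elsewhere.
DEFAULT_PANEL = Panel(
    [
        SNPDef("rs738409", "PNPLA3", "C", "G"),
        SNPDef("rs58542926", "TM6SF2", "C", "T"),
        SNPDef("rs3750861", "KLF6", "C", "T"),
        SNPDef("rs4880", "SOD2", "C", "T"),
        SNPDef("rs13412852", "LPIN1", "C", "T"),
    ]
)

#: The three loci the risk score is built from.
SCORE_SNP_IDS = ["rs738409", "rs58542926", "rs3750861"]

REQUIRED_COLUMNS = ["subject_id", "group", "age", "sex", "bmi", "t2dm"]


def normalize_genotype(raw: str, snp: SNPDef) -> str:
    """Canonicalize a two-character genotype string for ``snp``.

    The canonical form puts the ancestral allele first ("GC" -> "CG");
    the operation is idempotent and order-insensitive.  ``MISSING`` passes
    through unchanged.
    """
    if raw == MISSING:
        return MISSING
    if not isinstance(raw, str) or len(raw) != 2:
        raise GenotypeValidationError(
            f"{snp.snp_id}: genotype {raw!r} is not a two-character string"
        )
    raw = raw.upper()
    valid = {snp.ancestral_allele, snp.minor_allele}
    for ch in raw:
        if ch not in valid:
            raise GenotypeValidationError(
                f"{snp.snp_id}: {ch!r} is not an allele of this SNP "
                f"(expected {snp.ancestral_allele}/{snp.minor_allele})"
            )
    if raw[0] == snp.minor_allele and raw[1] == snp.ancestral_allele:
        return raw[1] + raw[0]
    return raw


def minor_allele_count(g: str, snp: SNPDef) -> int | None:
    """Number of minor alleles in genotype ``g`` (None when missing)."""
    if g == MISSING:
        return None
    g = normalize_genotype(g, snp)
    return sum(1 for ch in g if ch == snp.minor_allele)


def encode_genotype(g: str, snp: SNPDef, scheme: str) -> int | None:
    """Encode a genotype under an inheritance-model scheme.

    additive  -> minor-allele count 0/1/2
    dominant  -> 1 iff the subject carries at least one minor allele
    recessive -> 1 iff the subject is homozygous for the minor allele

    Missing genotypes propagate as None.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    count = minor_allele_count(g, snp)
    if count is None:
        return None
    if scheme == "additive":
        return count
    if scheme == "dominant":
        return int(count >= 1)
    return int(count == 2)


def _canon_map(snp: SNPDef) -> dict[str, str]:
    """All accepted raw spellings -> canonical form, for vectorized mapping."""
    aa, am, mm = snp.genotype_classes
    return {aa: aa, am: am, am[::-1]: am, mm: mm, MISSING: MISSING}


def encode_series(genotypes: pd.Series, snp: SNPDef, scheme: str) -> pd.Series:
    """Vectorized ``encode_genotype`` over a column of canonical genotypes
    (float result, NaN where missing)."""
    aa, am, mm = snp.genotype_classes
    codes = {
        "additive": {aa: 0.0, am: 1.0, mm: 2.0},
        "dominant": {aa: 0.0, am: 1.0, mm: 1.0},
        "recessive": {aa: 0.0, am: 0.0, mm: 1.0},
    }
    if scheme not in codes:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    return genotypes.map(codes[scheme])  # MISSING -> NaN


def max_code(scheme: str) -> int:
    """Largest value the encoding can take (2 additive, 1 otherwise)."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    return 2 if scheme == "additive" else 1


@dataclass
class Cohort:
    """A validated cohort: SNP panel plus one row per subject.

    ``data`` holds subject_id, group, age, sex, bmi, t2dm, optionally
    fibrosis_stage, and one column per panel rsID with canonical genotype
    strings (or ``MISSING``).
    """

    panel: Panel
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.data
        missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        missing_cols += [s for s in self.panel.snp_ids if s not in df.columns]
        if missing_cols:
            raise CohortFormatError(f"cohort table lacks columns: {missing_cols}")
        if df["subject_id"].duplicated().any():
            dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise CohortFormatError(f"duplicate subject_ids: {dupes}")
        bad_group = set(df["group"]) - set(VALID_GROUPS)
        if bad_group:
            raise CohortFormatError(f"unknown group labels: {sorted(bad_group)}")
        if "fibrosis_stage" in df.columns:
            staged = df["fibrosis_stage"].notna() & (df["fibrosis_stage"] != "")
            bad = df.loc[staged & (df["group"] != "nafld")]
            if len(bad):
                raise CohortFormatError(
                    "fibrosis_stage present for non-NAFLD subjects: "
                    f"{bad['subject_id'].tolist()}"
                )
            bad_stage = set(df.loc[staged, "fibrosis_stage"]) - set(VALID_FIBROSIS)
            if bad_stage:
                raise CohortFormatError(f"invalid fibrosis stages: {sorted(bad_stage)}")
        for snp in self.panel:
            col = df[snp.snp_id].astype("object")
            col = col.where(col.notna() & (col != ""), MISSING)
            canon = col.str.upper().map(_canon_map(snp))
            if canon.isna().any():
                # slow path only to produce a precise error message
                bad_idx = canon.index[canon.isna()][0]
                subject_id = df.loc[bad_idx, "subject_id"]
                try:
                    normalize_genotype(str(col.loc[bad_idx]), snp)
                except GenotypeValidationError as exc:
                    raise GenotypeValidationError(
                        f"subject {subject_id!r}: {exc}"
                    ) from None
                raise GenotypeValidationError(  # pragma: no cover
                    f"subject {subject_id!r}: invalid genotype {col.loc[bad_idx]!r} "
                    f"for {snp.snp_id}"
                )
            df[snp.snp_id] = canon

    @property
    def n(self) -> int:
        return len(self.data)

    def subset(self, mask) -> "Cohort":
        return Cohort(self.panel, self.data.loc[mask].copy())

    def groups(self) -> list[str]:
        return [g for g in VALID_GROUPS if (self.data["group"] == g).any()]

    def encoded(self, snp_id: str, scheme: str) -> pd.Series:
        """Encoded genotype column (float, NaN where missing)."""
        return encode_series(self.data[snp_id], self.panel[snp_id], scheme)


def _norm_sex(v: str) -> str:
    v = str(v).strip().lower()
    if v in {"male", "m"}:
        return "male"
    if v in {"female", "f"}:
        return "female"
    raise CohortFormatError(f"cannot interpret sex value {v!r}")


def _norm_yesno(v: str, column: str) -> str:
    v = str(v).strip().lower()
    if v in {"yes", "y", "1", "true"}:
        return "yes"
    if v in {"no", "n", "0", "false"}:
        return "no"
    raise CohortFormatError(f"cannot interpret {column} value {v!r}")


def read_cohort_table(path, panel: Panel = DEFAULT_PANEL) -> Cohort:
    """Read a tab-separated cohort table and validate it against ``panel``.

    The header must name subject_id, group, age, sex, bmi, t2dm and one
    column per panel rsID; fibrosis_stage is optional.  Empty genotype cells
    and ``NA`` become the missing marker.  Row order is preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS + panel.snp_ids if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: header lacks required columns {missing}")
    df["group"] = df["group"].str.strip().str.lower()
    df["sex"] = df["sex"].map(_norm_sex)
    df["t2dm"] = df["t2dm"].map(lambda v: _norm_yesno(v, "t2dm"))
    for col in ("age", "bmi"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    if "fibrosis_stage" in df.columns:
        df["fibrosis_stage"] = df["fibrosis_stage"].replace({"": None, "NA": None})
    for sid in panel.snp_ids:
        df[sid] = df[sid].replace({"": MISSING})
    return Cohort(panel, df)


def write_cohort_table(cohort: Cohort, path) -> None:
    """Write a cohort back to canonical TSV (round-trips with the reader)."""
    cols = REQUIRED_COLUMNS.copy()
    if "fibrosis_stage" in cohort.data.columns:
        cols.append("fibrosis_stage")
    cols += cohort.panel.snp_ids
    out = cohort.data[cols].copy()
    if "fibrosis_stage" in out.columns:
        out["fibrosis_stage"] = out["fibrosis_stage"].fillna("")
    out.to_csv(path, sep="\t", index=False)


def parse_vcf_genotypes(
    path,
    panel: Panel = DEFAULT_PANEL,
    id_map: Mapping[str, str] | None = None,
    snp_ids: Sequence[str] | None = None,
) -> dict[str, dict[str, str]]:
    """Extract panel genotypes from a VCF, keyed by subject then rsID.

    Panel SNPs are matched by rsID in the ID column; REF/ALT give the allele
    letters, so "0/1" (or phased "0|1") becomes the canonical heterozygote
    and "./." the missing marker.  ``id_map`` maps VCF sample names to
    subject ids (identity when omitted).  Multi-allelic records and
    non-diploid GT values are rejected; panel SNPs absent from the file
    raise a lookup error listing the missing rsIDs.
    """
    from cyvcf2 import VCF

    wanted = list(snp_ids) if snp_ids is not None else panel.snp_ids
    vcf = VCF(str(path))
    samples = vcf.samples
    if id_map is None:
        id_map = {s: s for s in samples}
    result: dict[str, dict[str, str]] = {id_map[s]: {} for s in samples if s in id_map}
    seen: set[str] = set()
    for variant in vcf:
        if variant.ID not in wanted:
            continue
        snp = panel[variant.ID]
        if len(variant.ALT) != 1:
            raise CohortFormatError(
                f"{variant.ID}: multi-allelic record (ALT={variant.ALT}); "
                "panel expects biallelic sites"
            )
        alleles = [variant.REF, variant.ALT[0]]
        seen.add(variant.ID)
        for sample, gt in zip(samples, variant.genotypes):
            if sample not in id_map:
                continue
            *calls, _phased = gt
            if len(calls) != 2:
                raise CohortFormatError(
                    f"{variant.ID} sample {sample}: non-diploid GT {calls}"
                )
            if -1 in calls:
                g = MISSING
            else:
                raw = alleles[calls[0]] + alleles[calls[1]]
                g = normalize_genotype(raw, snp)
            result[id_map[sample]][variant.ID] = g
    vcf.close()
    absent = sorted(set(wanted) - seen)
    if absent:
        raise PanelLookupError(f"panel SNPs absent from VCF: {absent}")
    return result
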