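"""Synthetic cohort generation with known truth.

Two generative modes:

* **margins mode** — reproduces published group-level marginal
  distributions: per-locus genotype counts (exactly, or as multinomial
  draws), truncated-normal age and BMI, Bernoulli sex and T2DM.  Loci are
  simulated independently — the five panel SNPs sit in different genes on
  different chromosomes, and the score treats them as independent
  contributors.  Because the group score mean depends only on the per-locus
  margins (linearity), an exact-count cohort reproduces published group
  means exactly whatever the joint arrangement.

* **liability mode** — draws genotypes from Hardy-Weinberg proportions at
  given allele frequencies and assigns case status from a logistic model
  with known per-SNP log-odds and covariate effects.  This is the
  generative model the score analysis presumes, and the ground truth for
  parameter-recovery and type-I-error experiments.

Scenario files are YAML mirrors of the spec dataclasses; a packaged default
scenario encodes the study's three groups (and the fibrosis subgroups) so
the demo pipeline runs with no external input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from scipy.stats import truncnorm

from .cohort import DEFAULT_PANEL, Cohort, Panel
from .errors import DegenerateInputError

#: Truncation bounds keeping simulated covariates physiologically possible.
AGE_MIN = 18.0
BMI_MIN = 15.0


@dataclass
class GroupSpec:
    """Marginal distributions for one simulated group (or subgroup).

    Genotypes come from ``genotype_counts`` (exact per-locus class counts,
    must sum to n) or ``genotype_probs`` (three-class probabilities) or
    ``maf`` (Hardy-Weinberg expansion of an allele frequency), checked in
    that order per SNP.
    """

    group: str
    n: int
    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    male_fraction: float
    t2dm_prevalence: float
    genotype_counts: dict = field(default_factory=dict)
    genotype_probs: dict = field(default_factory=dict)
    maf: dict = field(default_factory=dict)
    fibrosis_counts: dict = field(default_factory=dict)
    label: str | None = None  # id prefix; defaults to the group name

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise DegenerateInputError(f"group {self.group}: n must be positive")
        for sid, counts in self.genotype_counts.items():
            if len(counts) != 3 or min(counts) < 0 or sum(counts) != self.n:
                raise DegenerateInputError(
                    f"group {self.group} {sid}: genotype counts {counts} "
                    f"must be 3 non-negative integers summing to n={self.n}"
                )
        for sid, probs in self.genotype_probs.items():
            if len(probs) != 3 or min(probs) < 0 or abs(sum(probs) - 1.0) > 1e-9:
                raise DegenerateInputError(
                    f"group {self.group} {sid}: genotype probabilities {probs} "
                    "must be non-negative and sum to 1"
                )
        for sid, q in self.maf.items():
            if not 0.0 <= q <= 1.0:
                raise DegenerateInputError(f"group {self.group} {sid}: maf {q} not in [0,1]")
        if self.fibrosis_counts and sum(self.fibrosis_counts.values()) != self.n:
            raise DegenerateInputError(
                f"group {self.group}: fibrosis counts must sum to n"
            )

    def probs_for(self, snp_id: str) -> tuple[float, float, float]:
        if snp_id in self.genotype_counts:
            c = self.genotype_counts[snp_id]
            return tuple(x / self.n for x in c)
        if snp_id in self.genotype_probs:
            return tuple(self.genotype_probs[snp_id])
        if snp_id in self.maf:
            q = self.maf[snp_id]
            return ((1 - q) ** 2, 2 * q * (1 - q), q**2)
        raise DegenerateInputError(
            f"group {self.group}: no genotype distribution for {snp_id}"
        )


@dataclass
class LiabilitySpec:
    """Generative logistic model for case-control simulation.

    ``effects`` maps snp_id -> (scheme, log-odds per encoded unit); the
    linear predictor is intercept + sum of genotype terms + covariate terms
    (age, male sex, bmi, t2dm on their natural scales).
    """

    n: int
    maf: dict  # snp_id -> minor allele frequency (Hardy-Weinberg)
    effects: dict  # snp_id -> (scheme, beta)
    intercept: float = 0.0
    covariate_effects: dict = field(default_factory=dict)
    case_group: str = "cirrhosis"
    control_group: str = "nafld"
    age_mean: float = 55.0
    age_sd: float = 13.0
    bmi_mean: float = 29.0
    bmi_sd: float = 4.5
    male_fraction: float = 0.55
    t2dm_prevalence: float = 0.4

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise DegenerateInputError("n must be positive")
        betas = [self.intercept] + [b for _, b in self.effects.values()]
        betas += list(self.covariate_effects.values())
        if not np.all(np.isfinite(betas)):
            raise DegenerateInputError("non-finite coefficient in liability spec")


def _truncated_normal(rng, mean, sd, low, size):
    a = (low - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_genotypes(rng, snp, probs, n, exact):
    classes = np.array(snp.genotype_classes)
    if exact:
        counts = [int(round(p * n)) for p in probs]
        if sum(counts) != n:  # guard against rounding drift in probs-as-counts
            raise DegenerateInputError(
                f"{snp.snp_id}: exact-count mode needs integer counts summing to n"
            )
        idx = np.repeat([0, 1, 2], counts)
        rng.shuffle(idx)
    else:
        idx = rng.choice(3, size=n, p=probs)
    return classes[idx]


def simulate_cohort_margins(
    specs: Sequence[GroupSpec],
    seed: int,
    panel: Panel = DEFAULT_PANEL,
    exact_counts: bool = True,
) -> Cohort:
    """Simulate a cohort from group-level marginal distributions.

    With ``exact_counts`` (the default) every SNP whose spec gives integer
    class counts is assigned precisely those counts, independently shuffled
    across the group's subjects; otherwise genotypes are multinomial draws.
    Age and BMI are truncated normal (age >= 18 y, BMI >= 15 kg/m2); sex and
    T2DM are Bernoulli.  Fully reproducible from (specs, seed).
    """
    rng = np.random.default_rng(seed)
    frames = []
    for k, spec in enumerate(specs):
        prefix = spec.label or spec.group
        df = pd.DataFrame(
            {
                "subject_id": [f"{prefix}_{i:05d}" for i in range(spec.n)],
                "group": spec.group,
                "age": np.round(
                    _truncated_normal(rng, spec.age_mean, spec.age_sd, AGE_MIN, spec.n), 1
                ),
                "sex": np.where(
                    rng.random(spec.n) < spec.male_fraction, "male", "female"
                ),
                "bmi": np.round(
                    _truncated_normal(rng, spec.bmi_mean, spec.bmi_sd, BMI_MIN, spec.n), 1
                ),
                "t2dm": np.where(
                    rng.random(spec.n) < spec.t2dm_prevalence, "yes", "no"
                ),
            }
        )
        if spec.fibrosis_counts:
            stages = np.repeat(
                list(spec.fibrosis_counts.keys()),
                list(spec.fibrosis_counts.values()),
            )
            rng.shuffle(stages)
            df["fibrosis_stage"] = stages
        for snp in panel:
            probs = spec.probs_for(snp.snp_id)
            exact = exact_counts and snp.snp_id in spec.genotype_counts
            df[snp.snp_id] = _draw_genotypes(rng, snp, probs, spec.n, exact)
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    if "fibrosis_stage" in data.columns:
        data["fibrosis_stage"] = data["fibrosis_stage"].where(
            data["fibrosis_stage"].notna(), None
        )
    return Cohort(panel, data)


def simulate_cohort_liability(
    spec: LiabilitySpec, seed: int, panel: Panel = DEFAULT_PANEL
) -> Cohort:
    """Simulate a case-control cohort from a logistic liability model.

    Genotypes are Hardy-Weinberg at the spec's allele frequencies (loci
    independent); covariates as in margins mode; case status is Bernoulli
    with probability expit(linear predictor).  Cases get ``case_group`` as
    group label, controls ``control_group``.
    """
    from .cohort import encode_series

    rng = np.random.default_rng(seed)
    n = spec.n
    eta = np.full(n, float(spec.intercept))
    geno_cols: dict[str, np.ndarray] = {}
    for snp in panel:
        q = spec.maf.get(snp.snp_id)
        if q is None:
            continue
        probs = ((1 - q) ** 2, 2 * q * (1 - q), q * q)
        genos = _draw_genotypes(rng, snp, probs, n, exact=False)
        geno_cols[snp.snp_id] = genos
        if snp.snp_id in spec.effects:
            scheme, beta = spec.effects[snp.snp_id]
            codes = encode_series(pd.Series(genos), snp, scheme).to_numpy()
            eta += beta * codes
    age = _truncated_normal(rng, spec.age_mean, spec.age_sd, AGE_MIN, n)
    bmi = _truncated_normal(rng, spec.bmi_mean, spec.bmi_sd, BMI_MIN, n)
    male = (rng.random(n) < spec.male_fraction).astype(float)
    t2dm = (rng.random(n) < spec.t2dm_prevalence).astype(float)
    cov = {"age": age, "sex_male": male, "bmi": bmi, "t2dm": t2dm}
    for name, beta in spec.covariate_effects.items():
        eta += beta * cov[name]
    if not np.isfinite(eta).all():
        raise DegenerateInputError("non-finite linear predictor in liability model")
    y = rng.random(n) < expit(eta)
    df = pd.DataFrame(
        {
            "subject_id": [f"sim_{i:06d}" for i in range(n)],
            "group": np.where(y, spec.case_group, spec.control_group),
            "age": np.round(age, 1),
            "sex": np.where(male == 1.0, "male", "female"),
            "bmi": np.round(bmi, 1),
            "t2dm": np.where(t2dm == 1.0, "yes", "no"),
        }
    )
    for snp in panel:
        if snp.snp_id in geno_cols:
            df[snp.snp_id] = geno_cols[snp.snp_id]
        else:
            df[snp.snp_id] = snp.genotype_classes[0]
    return Cohort(panel, df)


def load_scenario(source) -> list[GroupSpec] | LiabilitySpec:
    """Load a YAML scenario file (margins -> list of GroupSpec, liability ->
    LiabilitySpec)."""
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    mode = doc.get("mode", "margins")
    if mode == "margins":
        specs = []
        for g in doc["groups"]:
            specs.append(
                GroupSpec(
                    group=g["group"],
                    n=int(g["n"]),
                    age_mean=float(g["age"]["mean"]),
                    age_sd=float(g["age"]["sd"]),
                    bmi_mean=float(g["bmi"]["mean"]),
                    bmi_sd=float(g["bmi"]["sd"]),
                    male_fraction=float(g["male_fraction"]),
                    t2dm_prevalence=float(g["t2dm_prevalence"]),
                    genotype_counts={
                        k: tuple(v) for k, v in (g.get("genotype_counts") or {}).items()
                    },
                    genotype_probs={
                        k: tuple(v) for k, v in (g.get("genotype_probs") or {}).items()
                    },
                    maf=dict(g.get("maf") or {}),
                    fibrosis_counts=dict(g.get("fibrosis_counts") or {}),
                    label=g.get("label"),
                )
            )
        return specs
    if mode == "liability":
        return LiabilitySpec(
            n=int(doc["n"]),
            maf=dict(doc["maf"]),
            effects={k: (v[0], float(v[1])) for k, v in doc["effects"].items()},
            intercept=float(doc.get("intercept", 0.0)),
            covariate_effects=dict(doc.get("covariate_effects") or {}),
            case_group=doc.get("case_group", "cirrhosis"),
            control_group=doc.get("control_group", "nafld"),
        )
    raise DegenerateInputError(f"unknown scenario mode {mode!r}")


def default_study_scenario() -> list[GroupSpec]:
    """The packaged margins scenario encoding the study's printed group
    distributions (healthy, NAFLD split by fibrosis, NASH cirrhosis)."""
    ref = resources.files("nafldscore.data").joinpath("study_margins.yaml")
    with ref.open("r") as fh:
        return load_scenario(fh)
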