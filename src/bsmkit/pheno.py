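"""Phenotypic characterization: Schaeffer live-weight estimation and
two-tailed t-test comparison of breed means with superscript letter groups.

Schaeffer's formula estimates live body weight from body length l and heart
girth g, both in inches: W = l * g^2 / 300, in pounds.  Breed means per
conformation parameter are compared with a two-tailed t-test (Welch by
default — safer at n = 4-5 with unequal spreads; Student's pooled variant is
available); breeds sharing a superscript letter do not differ at alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "KG_PER_LB",
    "PhenoRecord",
    "GroupComparison",
    "schaeffer_weight",
    "lbs_to_kg",
    "read_pheno_table",
    "compare_groups",
]

KG_PER_LB = 0.45359237  # international pound

MALE_PARAMETERS = (
    "weight", "stature", "chest_width", "body_depth", "length", "girth",
    "rump_width", "face_length", "scrotal_circumference",
)
FEMALE_PARAMETERS = (
    "weight", "stature", "chest_width", "body_depth", "length", "girth",
    "rump_width", "fore_teat_length", "rear_teat_length", "rear_udder_width",
    "teat_thickness",
)


@dataclass
class PhenoRecord:
    """One animal's measurements (length/girth in inches for the weight
    formula; other conformation parameters unit-free here)."""

    animal: str
    breed: str
    sex: str
    measurements: dict[str, float]

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male or female, got {self.sex!r}")
        schema = MALE_PARAMETERS if self.sex == "male" else FEMALE_PARAMETERS
        for name, value in self.measurements.items():
            if value < 0:
                raise ValueError(f"{self.animal}: negative measurement {name}={value}")
            if name not in schema:
                logger.warning("%s: parameter %r not in %s schema", self.animal, name, self.sex)


@dataclass
class GroupComparison:
    parameter: str
    breeds: tuple[str, str]
    means: tuple[float, float]
    sds: tuple[float, float]
    ns: tuple[int, int]
    t: float
    df: float
    p: float
    letters: tuple[str, str]
    alpha: float = 0.05


def schaeffer_weight(length_in: float, girth_in: float) -> float:
    """Live weight in pounds from length and heart girth in inches:
    W = l * g^2 / 300."""
    if length_in <= 0 or girth_in <= 0:
        raise ValueError("length and girth must be positive")
    return length_in * girth_in**2 / 300.0


def lbs_to_kg(w_lbs: float) -> float:
    """Pounds to kilograms (x 0.45359237)."""
    if w_lbs < 0:
        raise ValueError("weight must be non-negative")
    return w_lbs * KG_PER_LB


def kg_to_lbs(w_kg: float) -> float:
    return w_kg / KG_PER_LB


def read_pheno_table(path: str) -> list[PhenoRecord]:
    """Read a long-format TSV ``animal breed sex parameter value`` into
    per-animal records."""
    df = pd.read_csv(path, sep="\t", dtype={"animal": str, "breed": str, "sex": str})
    required = {"animal", "breed", "sex", "parameter", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"phenotype table must have columns {sorted(required)}")
    records: dict[str, PhenoRecord] = {}
    for row in df.itertuples(index=False):
        rec = records.get(row.animal)
        if rec is None:
            rec = PhenoRecord(row.animal, row.breed, row.sex, {})
            records[row.animal] = rec
        elif rec.breed != row.breed or rec.sex != row.sex:
            raise ValueError(f"animal {row.animal!r} has conflicting breed/sex rows")
        rec.measurements[row.parameter] = float(row.value)
    out = list(records.values())
    for rec in out:
        PhenoRecord(rec.animal, rec.breed, rec.sex, rec.measurements)  # re-validate
    return out


def compare_groups(
    records: list[PhenoRecord],
    parameter: str,
    breeds: tuple[str, str],
    variant: str = "welch",
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-tailed t-test of one parameter between two breeds.

    Welch-Satterthwaite degrees of freedom by default (``variant='student'``
    pools variances).  Letters: the breeds share a letter iff p >= alpha.
    Two zero-variance groups with equal means give p = 1 by convention.
    """
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown variant {variant!r}")
    groups = []
    for breed in breeds:
        vals = np.array([
            r.measurements[parameter]
            for r in records
            if r.breed == breed and parameter in r.measurements
        ])
        if len(vals) < 2:
            raise ValueError(f"breed {breed!r} has n < 2 for parameter {parameter!r}")
        groups.append(vals)
    a, b = groups
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            logger.info("both groups constant and equal; p = 1 by convention")
            t, df, p = 0.0, float(len(a) + len(b) - 2), 1.0
        else:
            t, df, p = np.inf if a.mean() > b.mean() else -np.inf, \
                float(len(a) + len(b) - 2), 0.0
    else:
        res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    letters = ("a", "a") if p >= alpha else ("a", "b")
    return GroupComparison(
        parameter=parameter,
        breeds=breeds,
        means=(float(a.mean()), float(b.mean())),
        sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        ns=(len(a), len(b)),
        t=t,
        df=df,
        p=p,
        letters=letters,
        alpha=alpha,
    )
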