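"""Anthropometrics (BMI, obesity class) and maternal-lineage bookkeeping.

BMI is weight (kg) divided by squared height (m), reported to one decimal
with round-half-away-from-zero. Obesity classes follow age/sex percentile
cutoffs supplied as a data file: above the 95th percentile is obese, above
the 99th severely obese (strict inequalities); an optional 85th-percentile
column marks overweight. Maternal-lineage summaries count the matriline of a
proband — the members reachable from the proband's founding matriarch through
mother links — since mtDNA is transmitted along exactly that path.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

from .reference import ValidationError

__all__ = [
    "SubjectRecord",
    "Pedigree",
    "BmiCutoffs",
    "bmi",
    "classify_obesity",
    "load_bmi_cutoffs",
    "read_subject_table",
    "read_pedigree",
    "matrilineal_summary",
]


def bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index in kg/m², rounded to 1 decimal (half away from zero)."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValidationError("weight and height must be positive")
    raw = weight_kg / (height_cm / 100.0) ** 2
    return float(Decimal(repr(raw)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SubjectRecord:
    id: str
    age: float
    sex: str
    height_cm: float
    weight_kg: float
    bmi: float
    obese_duration: Optional[str] = None
    carrier: bool = False

    def __post_init__(self) -> None:
        if self.height_cm <= 0 or self.weight_kg <= 0:
            raise ValidationError(f"{self.id}: non-positive height or weight")
        if self.sex not in ("M", "F"):
            raise ValidationError(f"{self.id}: sex must be M or F")
        recomputed = bmi(self.weight_kg, self.height_cm)
        if abs(recomputed - self.bmi) > 0.05 + 1e-9:
            raise ValidationError(
                f"{self.id}: stated BMI {self.bmi} inconsistent with "
                f"{self.weight_kg} kg / {self.height_cm} cm ({recomputed})"
            )


@dataclass(frozen=True)
class BmiCutoffs:
    """Age/sex percentile cutoff table; bands are [age_min, age_max)."""

    rows: tuple[tuple[str, float, float, Optional[float], float, float], ...]

    def lookup(self, age: float, sex: str):
        for row_sex, lo, hi, p85, p95, p99 in self.rows:
            if row_sex == sex and lo <= age < hi:
                return p85, p95, p99
        return None


def load_bmi_cutoffs(source) -> BmiCutoffs:
    close = False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        source = open(source, "rt")
        close = True
    try:
        reader = csv.DictReader(
            (ln for ln in source if not ln.startswith("#")), delimiter="\t"
        )
        rows = tuple(
            (
                r["sex"].strip(),
                float(r["age_min"]),
                float(r["age_max"]),
                float(r["p85"]) if r.get("p85") else None,
                float(r["p95"]),
                float(r["p99"]),
            )
            for r in reader
        )
    finally:
        if close:
            source.close()
    if not rows:
        raise ValidationError("empty BMI cutoff table")
    return BmiCutoffs(rows=rows)


def classify_obesity(
    bmi_value: float, age: float, sex: str, cutoffs: BmiCutoffs
) -> str:
    """Classify BMI against age/sex percentile cutoffs.

    Strictly above the 99th percentile is ``severe_obese``, above the 95th
    ``obese``, above the 85th (when supplied) ``overweight``, else ``normal``.
    A missing (age, sex) band returns ``unclassified`` — never a silent
    default.
    """
    row = cutoffs.lookup(age, sex)
    if row is None:
        return "unclassified"
    p85, p95, p99 = row
    if bmi_value > p99:
        return "severe_obese"
    if bmi_value > p95:
        return "obese"
    if p85 is not None and bmi_value > p85:
        return "overweight"
    return "normal"


def read_subject_table(source) -> list[SubjectRecord]:
    """Read the anthropometrics TSV (id, age, sex, height_cm, weight_kg, bmi, ...)."""
    close = False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        source = open(source, "rt")
        close = True
    try:
        reader = csv.DictReader(
            (ln for ln in source if not ln.startswith("#")), delimiter="\t"
        )
        subjects = [
            SubjectRecord(
                id=r["id"].strip(),
                age=float(r["age"]),
                sex=r["sex"].strip(),
                height_cm=float(r["height_cm"]),
                weight_kg=float(r["weight_kg"]),
                bmi=float(r["bmi"]),
                obese_duration=r.get("obese_duration") or None,
                carrier=r.get("carrier", "0").strip() in ("1", "true", "yes"),
            )
            for r in reader
        ]
    finally:
        if close:
            source.close()
    if not subjects:
        raise ValidationError("empty subject table")
    return subjects


@dataclass
class Pedigree:
    """Members with mother links and an affected set.

    Maternal links must be acyclic. When carrier flags are present, every
    carrier's in-pedigree mother must also be a carrier (homoplasmic mtDNA
    transmission is strictly maternal and deterministic).
    """

    members: list[str]
    mother_of: dict[str, str]
    affected: set[str] = field(default_factory=set)
    carriers: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        known = set(self.members)
        for child, mother in self.mother_of.items():
            if child not in known or mother not in known:
                raise ValidationError(f"link {child}->{mother} references unknown member")
        # cycle check by chain walking
        for m in self.members:
            seen = set()
            cur = m
            while cur in self.mother_of:
                if cur in seen:
                    raise ValidationError(f"cyclic maternal links at {cur}")
                seen.add(cur)
                cur = self.mother_of[cur]
        for c in self.carriers:
            mother = self.mother_of.get(c)
            if mother is not None and mother not in self.carriers:
                raise ValidationError(
                    f"carrier {c} has non-carrier mother {mother}: "
                    "violates strict maternal transmission"
                )

    def matriarch(self, member: str) -> str:
        cur = member
        while cur in self.mother_of:
            cur = self.mother_of[cur]
        return cur

    def matriline(self, proband: str) -> set[str]:
        """All members sharing the proband's matriline (incl. the matriarch)."""
        if proband not in self.members:
            raise ValidationError(f"unknown proband {proband!r}")
        root = self.matriarch(proband)
        return {m for m in self.members if self.matriarch(m) == root}


def read_pedigree(source) -> Pedigree:
    """Read a pedigree TSV (id, mother, affected[, carrier]); mother '-' = none."""
    close = False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        source = open(source, "rt")
        close = True
    try:
        reader = csv.DictReader(
            (ln for ln in source if not ln.startswith("#")), delimiter="\t"
        )
        members, mother_of, affected, carriers = [], {}, set(), set()
        for r in reader:
            mid = r["id"].strip()
            members.append(mid)
            mother = r.get("mother", "-").strip()
            if mother and mother != "-":
                mother_of[mid] = mother
            if r.get("affected", "0").strip() in ("1", "true", "yes"):
                affected.add(mid)
            if r.get("carrier", "0").strip() in ("1", "true", "yes"):
                carriers.add(mid)
    finally:
        if close:
            source.close()
    return Pedigree(members=members, mother_of=mother_of, affected=affected, carriers=carriers)


def matrilineal_summary(pedigree: Pedigree, proband: str) -> tuple[int, int, float]:
    """(affected, total, penetrance) over the proband's matriline."""
    line = pedigree.matriline(proband)
    affected = len(line & pedigree.affected)
    total = len(line)
    return affected, total, affected / total
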