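"""Drosophila melanogaster telomere complement, chromatin classes and reporting categories.

A diploid neuroblast karyotype is modelled at the unreplicated-chromosome
level: 16 telomere "slots" per cell (sister chromatids collapsed).  Each
telomere knows its chromosome, arm, homolog index and subtelomeric chromatin
class.  Reporting collapses telomeres into the five standard scoring
categories (A, XL, XR, Fourth, Y); the Eu group is {A, XL} and the Het group
is {XR, Fourth, Y}.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

__all__ = [
    "ChromatinClass",
    "Sex",
    "Variant",
    "TelomereID",
    "KaryotypeConfig",
    "KaryotypeError",
    "CATEGORIES",
    "EU_CATEGORIES",
    "HET_CATEGORIES",
    "DEFAULT_CHROMATIN",
    "build_karyotype",
    "karyotype_from_arms",
    "telomere_census",
]


class KaryotypeError(ValueError):
    """Raised for invalid karyotype configurations."""


class ChromatinClass(str, Enum):
    """Subtelomeric chromatin context of a terminus."""

    HETEROCHROMATIN = "heterochromatin"
    TAS = "TAS"
    FOURTH_TYPE = "fourth_type"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Variant(str, Enum):
    WILDTYPE = "wildtype"
    MARKED_Y = "marked_Y"


#: Canonical reporting categories, in fixed output order.
CATEGORIES: tuple[str, ...] = ("A", "XL", "XR", "Fourth", "Y")

#: Category-level euchromatic / heterochromatic grouping.
EU_CATEGORIES: tuple[str, ...] = ("A", "XL")
HET_CATEGORIES: tuple[str, ...] = ("XR", "Fourth", "Y")

#: Default chromatin class per chromosome arm.  4L abuts constitutive
#: heterochromatin while 4R carries its own distinct subtelomeric chromatin;
#: both are heterochromatin-associated for grouping/weighting purposes.
DEFAULT_CHROMATIN: dict[str, ChromatinClass] = {
    "XL": ChromatinClass.TAS,
    "XR": ChromatinClass.HETEROCHROMATIN,
    "YL": ChromatinClass.HETEROCHROMATIN,
    "YS": ChromatinClass.HETEROCHROMATIN,
    "2L": ChromatinClass.TAS,
    "2R": ChromatinClass.TAS,
    "3L": ChromatinClass.TAS,
    "3R": ChromatinClass.TAS,
    "4L": ChromatinClass.HETEROCHROMATIN,
    "4R": ChromatinClass.FOURTH_TYPE,
}

_CATEGORY_BY_ARM: dict[str, str] = {
    "XL": "XL",
    "XR": "XR",
    "YL": "Y",
    "YS": "Y",
    "2L": "A",
    "2R": "A",
    "3L": "A",
    "3R": "A",
    "4L": "Fourth",
    "4R": "Fourth",
}


@dataclass(frozen=True, order=True)
class TelomereID:
    """One chromosome-arm terminus of one homolog.

    Parameters
    ----------
    chromosome:
        Chromosome name: ``X``, ``Y``, ``2``, ``3`` or ``4``.
    arm:
        Arm letter (``L``, ``R``; the Y short arm is ``S``).
    homolog:
        1-based homolog index.  Single-copy chromosomes (the Y, the X in
        males) use index 1.
    chromatin_class:
        Subtelomeric chromatin context of this terminus.
    """

    chromosome: str
    arm: str
    homolog: int
    chromatin_class: ChromatinClass = field(compare=False)

    @property
    def arm_label(self) -> str:
        """Arm name such as ``XL`` or ``YS``."""
        return f"{self.chromosome}{self.arm}"

    @property
    def category(self) -> str:
        """Scoring category (A, XL, XR, Fourth or Y)."""
        return _CATEGORY_BY_ARM[self.arm_label]

    @property
    def het_associated(self) -> bool:
        """True for heterochromatin-associated termini (non-TAS classes)."""
        return self.chromatin_class is not ChromatinClass.TAS

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.arm_label}({self.homolog})"


@dataclass(frozen=True)
class KaryotypeConfig:
    """The full telomere complement for one sex/variant."""

    sex: Sex
    variant: Variant
    telomeres: tuple[TelomereID, ...]

    def __post_init__(self) -> None:
        keys = [(t.chromosome, t.arm, t.homolog) for t in self.telomeres]
        if len(set(keys)) != len(keys):
            raise KaryotypeError("duplicate (chromosome, arm, homolog) in karyotype")

    @property
    def total_telomeres(self) -> int:
        return len(self.telomeres)

    @property
    def categories(self) -> tuple[str, ...]:
        """Categories present, in canonical order."""
        present = {t.category for t in self.telomeres}
        return tuple(c for c in CATEGORIES if c in present)

    def has_chromosome(self, name: str) -> bool:
        return any(t.chromosome == name for t in self.telomeres)


_AUTOSOME_ARMS = ("2L", "2R", "3L", "3R", "4L", "4R")


def _parse_arm(arm_label: str) -> tuple[str, str]:
    chromosome, arm = arm_label[:-1], arm_label[-1]
    if arm_label not in _CATEGORY_BY_ARM:
        raise KaryotypeError(f"unknown chromosome arm {arm_label!r}")
    return chromosome, arm


def karyotype_from_arms(
    arm_counts: Mapping[str, int],
    *,
    sex: Sex = Sex.MALE,
    variant: Variant = Variant.WILDTYPE,
    chromatin: Mapping[str, ChromatinClass] | None = None,
) -> KaryotypeConfig:
    """Build an arbitrary (toy or variant) karyotype from per-arm copy numbers.

    ``arm_counts`` maps arm labels (``"2L"``, ``"YS"``, ...) to homolog
    counts; homolog indices are assigned 1..n.  ``chromatin`` overrides the
    default chromatin class per arm.
    """
    classes = dict(DEFAULT_CHROMATIN)
    if chromatin:
        for label, cls in chromatin.items():
            _parse_arm(label)
            classes[label] = ChromatinClass(cls)
    telomeres: list[TelomereID] = []
    for label in sorted(arm_counts):
        n = arm_counts[label]
        if n < 0:
            raise KaryotypeError(f"negative copy number for {label}")
        chromosome, arm = _parse_arm(label)
        for h in range(1, n + 1):
            telomeres.append(TelomereID(chromosome, arm, h, classes[label]))
    return KaryotypeConfig(sex=sex, variant=variant, telomeres=tuple(telomeres))


def build_karyotype(
    sex: Sex | str,
    variant: Variant | str = Variant.WILDTYPE,
    *,
    chromatin_overrides: Mapping[str, ChromatinClass | str] | None = None,
) -> KaryotypeConfig:
    """Construct the wildtype male/female complement (16 telomeres) or the
    marked-Y male variant.

    The marked-Y variant is the male complement with the YL terminus
    reclassified to a TAS-like euchromatic context (a euchromatic fragment
    appended to the YL end); its census is unchanged.

    Raises
    ------
    KaryotypeError
        If ``marked_Y`` is requested for a female karyotype.
    """
    sex = Sex(sex)
    variant = Variant(variant)
    if variant is Variant.MARKED_Y and sex is not Sex.MALE:
        raise KaryotypeError("marked_Y variant requires a male karyotype")

    counts: dict[str, int] = {label: 2 for label in _AUTOSOME_ARMS}
    if sex is Sex.MALE:
        counts.update({"XL": 1, "XR": 1, "YL": 1, "YS": 1})
    else:
        counts.update({"XL": 2, "XR": 2})

    chromatin: dict[str, ChromatinClass] = {}
    if variant is Variant.MARKED_Y:
        chromatin["YL"] = ChromatinClass.TAS
    if chromatin_overrides:
        for label, cls in chromatin_overrides.items():
            chromatin[label] = ChromatinClass(cls)
    return karyotype_from_arms(counts, sex=sex, variant=variant, chromatin=chromatin)


def telomere_census(karyotype: KaryotypeConfig) -> dict[str, int]:
    """Telomere slots per category, in canonical category order."""
    census: dict[str, int] = {c: 0 for c in karyotype.categories}
    for t in karyotype.telomeres:
        census[t.category] += 1
    return census
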