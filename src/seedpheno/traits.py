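"""Trait schema for seed-imaging exports.

A schema names the geometric traits the imaging system reports for each
organ (dried bean or whole cherry), maps display labels (as they appear
in exported spreadsheets) to stable trait ids, and records units:
cm^2 for areas, cm for diameters and perimeters, dimensionless ratios
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ORGANS = ("bean", "cherry")


@dataclass(frozen=True)
class Trait:
    """One measured geometric trait of one organ."""

    trait_id: str
    organ: str
    label: str
    unit: str = ""

    def __post_init__(self) -> None:
        if self.organ not in ORGANS:
            raise ValueError(f"organ must be one of {ORGANS}, got {self.organ!r}")


@dataclass(frozen=True)
class TraitSchema:
    """An ordered collection of traits with unique ids."""

    traits: tuple[Trait, ...]
    _by_id: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        ids = [t.trait_id for t in self.traits]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate trait ids: {dup}")
        object.__setattr__(self, "_by_id", {t.trait_id: t for t in self.traits})

    @property
    def ids(self) -> list[str]:
        return [t.trait_id for t in self.traits]

    @property
    def labels(self) -> dict[str, str]:
        return {t.label: t.trait_id for t in self.traits}

    def __contains__(self, trait_id: str) -> bool:
        return trait_id in self._by_id

    def __getitem__(self, trait_id: str) -> Trait:
        return self._by_id[trait_id]

    def organ_ids(self, organ: str) -> list[str]:
        return [t.trait_id for t in self.traits if t.organ == organ]

    def subset(self, trait_ids) -> "TraitSchema":
        return TraitSchema(tuple(self._by_id[i] for i in trait_ids))


DEFAULT_SCHEMA = TraitSchema(
    (
        Trait("b_area", "bean", "B. AREA", "cm^2"),
        Trait("b_circularity", "bean", "B. CIRCULARITY"),
        Trait("b_max_diameter", "bean", "B. MAX D.", "cm"),
        Trait("b_min_diameter", "bean", "B. MIN D.", "cm"),
        Trait("b_sphericity", "bean", "B. SPHERICITY"),
        Trait("b_rectangularity", "bean", "B. RECTANGULARITY"),
        Trait("b_irregularity", "bean", "B. IRREGULARITY"),
        Trait("b_n_corners", "bean", "B. N. CORNERS"),
        Trait("b_perimeter", "bean", "B. PERIMETER", "cm"),
        Trait("c_area", "cherry", "C. AREA", "cm^2"),
        Trait("c_circularity", "cherry", "C. CIRCULARITY"),
        Trait("c_max_diameter", "cherry", "C. MAX D.", "cm"),
        Trait("c_min_diameter", "cherry", "C. MIN D.", "cm"),
        Trait("c_sphericity", "cherry", "C. SPHERICITY"),
        Trait("c_rectangularity", "cherry", "C. RECTANGULARITY"),
        Trait("c_irregularity", "cherry", "C. IRREGULARITY"),
        Trait("c_perimeter", "cherry", "C. PERIMETER", "cm"),
    )
)

# Ten-trait subset conventionally used for the correlation analysis
# (five bean traits, five cherry traits).
DEFAULT_CORRELATION_TRAITS = [
    "b_area",
    "b_max_diameter",
    "b_min_diameter",
    "b_sphericity",
    "b_irregularity",
    "c_area",
    "c_circularity",
    "c_max_diameter",
    "c_min_diameter",
    "c_perimeter",
]
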