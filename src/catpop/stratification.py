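"""Municipal stratification and national baseline extrapolation.

Municipalities are classified on two independent axes:

* **habitat** — urban if the municipality has more than 20,000 inhabitants,
  rural otherwise (the boundary itself is rural);
* **reproductive potential** — the province-level class (L/M/H/VH) supplied
  as an input column (derived upstream from winter daylight/temperature; not
  recomputed here).

Together these give eight strata (UL..RVH) that index every demographic
parameter downstream.

Separately, five population-size classes carry the census ratios
(community cats per inhabitant, cats per colony) estimated from the
municipal sample.  Applying each municipality's size-class ratio to its
human population and aggregating by stratum yields the national baseline
table that seeds the projection model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from ._util import iround
from .reproduction import Habitat, Potential

__all__ = [
    "URBAN_THRESHOLD",
    "ScenarioKey",
    "SCENARIOS",
    "MunicipalityRecord",
    "SizeClass",
    "SIZE_CLASS_LABELS",
    "DEFAULT_SIZE_CLASSES",
    "size_class_label",
    "classify_municipality",
    "compute_stratum_ratios",
    "extrapolate_national",
    "BaselineTable",
    "read_municipalities_csv",
]

#: Municipalities with strictly more inhabitants are urban.
URBAN_THRESHOLD = 20_000


class ScenarioKey(NamedTuple):
    """One habitat x reproductive-potential stratum."""

    habitat: Habitat
    potential: Potential

    @property
    def code(self) -> str:
        return ("U" if self.habitat is Habitat.URBAN else "R") + self.potential.value

    @classmethod
    def from_code(cls, code: str) -> "ScenarioKey":
        code = code.strip().upper()
        if code[0] not in "UR" or code[1:] not in Potential.__members__:
            raise ValueError(f"unknown scenario code {code!r}")
        return cls(Habitat.URBAN if code[0] == "U" else Habitat.RURAL, Potential(code[1:]))


#: Canonical stratum order used throughout the package (urban first).
SCENARIOS: tuple[ScenarioKey, ...] = tuple(
    ScenarioKey(h, p)
    for h in (Habitat.URBAN, Habitat.RURAL)
    for p in (Potential.L, Potential.M, Potential.H, Potential.VH)
)

SCENARIO_CODES: tuple[str, ...] = tuple(k.code for k in SCENARIOS)


@dataclass(frozen=True)
class MunicipalityRecord:
    """One municipality row of the administrative census.

    ``counted_cats``/``counted_colonies`` are present only in the sampled
    municipalities that reported a verified colony census.
    """

    id: str
    inhabitants: int
    potential: Potential
    counted_cats: int | None = None
    counted_colonies: int | None = None

    def __post_init__(self):
        if self.inhabitants < 0:
            raise ValueError(f"{self.id}: inhabitants must be >= 0")
        for name in ("counted_cats", "counted_colonies"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{self.id}: {name} must be >= 0")


@dataclass(frozen=True)
class SizeClass:
    """A municipality-size class and its census ratios."""

    label: str
    cat_to_human: float
    cats_per_colony: float

    def __post_init__(self):
        if self.cat_to_human < 0 or self.cats_per_colony <= 0:
            raise ValueError(f"{self.label}: ratios must be positive")


# Right-open size bins; the printed class labels are ambiguous at the shared
# boundaries, so 5000 falls in "5000-10000", 50,000 in ">50000".
_SIZE_BIN_EDGES = np.array([0, 500, 5_000, 10_000, 50_000])
SIZE_CLASS_LABELS: tuple[str, ...] = (
    "<500",
    "500-5000",
    "5000-10000",
    "10000-50000",
    ">50000",
)

#: National default ratios per size class (cat-to-human, cats-per-colony).
DEFAULT_SIZE_CLASSES: dict[str, SizeClass] = {
    "<500": SizeClass("<500", 0.59, 15.68),
    "500-5000": SizeClass("500-5000", 0.12, 15.05),
    "5000-10000": SizeClass("5000-10000", 0.04, 13.29),
    "10000-50000": SizeClass("10000-50000", 0.03, 14.14),
    ">50000": SizeClass(">50000", 0.01, 12.64),
}


def size_class_label(inhabitants: int) -> str:
    """Size class a municipality belongs to."""
    if inhabitants < 0:
        raise ValueError("inhabitants must be >= 0")
    idx = int(np.searchsorted(_SIZE_BIN_EDGES, inhabitants, side="right")) - 1
    return SIZE_CLASS_LABELS[idx]


def classify_municipality(rec: MunicipalityRecord) -> ScenarioKey:
    """Assign a municipality to its habitat x potential stratum."""
    if rec.potential is None:
        raise ValueError(f"{rec.id}: missing province reproductive-potential class")
    habitat = Habitat.URBAN if rec.inhabitants > URBAN_THRESHOLD else Habitat.RURAL
    return ScenarioKey(habitat, Potential(rec.potential))


def compute_stratum_ratios(sample: Iterable[MunicipalityRecord]) -> dict[str, SizeClass]:
    """Pooled-ratio estimates of the two census ratios per size class.

    ``cat_to_human = sum(cats) / sum(inhabitants)`` and
    ``cats_per_colony = sum(cats) / sum(colonies)`` within each class — the
    pooled estimator weights municipalities by size and is robust to tiny
    denominators, unlike a mean of per-municipality ratios.
    """
    sums: dict[str, list[float]] = {lbl: [0.0, 0.0, 0.0] for lbl in SIZE_CLASS_LABELS}
    seen: dict[str, int] = {lbl: 0 for lbl in SIZE_CLASS_LABELS}
    for rec in sample:
        if rec.counted_cats is None:
            raise ValueError(f"{rec.id}: counted_cats required to estimate ratios")
        lbl = size_class_label(rec.inhabitants)
        sums[lbl][0] += rec.inhabitants
        sums[lbl][1] += rec.counted_cats
        sums[lbl][2] += rec.counted_colonies or 0
        seen[lbl] += 1

    out: dict[str, SizeClass] = {}
    for lbl in SIZE_CLASS_LABELS:
        inhab, cats, colonies = sums[lbl]
        if seen[lbl] == 0:
            raise ValueError(f"no sampled municipalities in size class {lbl!r}")
        if inhab == 0:
            raise ValueError(f"size class {lbl!r} has zero inhabitants in the sample")
        if colonies == 0 and cats > 0:
            raise ValueError(f"size class {lbl!r} reports cats but zero colonies")
        out[lbl] = SizeClass(
            lbl,
            cats / inhab,
            cats / colonies if colonies > 0 else float("nan"),
        )
    return out


@dataclass
class BaselineTable:
    """Per-stratum baseline cat population and colony counts.

    Integer counts are rounded half-up at the stratum aggregate; the raw
    (unrounded) stratum sums are kept for invariance checks.  Partition
    totals are sums of the rounded stratum values, so the eight strata
    always add up to the national total exactly.
    """

    cats: dict[str, int]
    colonies: dict[str, int]
    raw_cats: dict[str, float] = field(default_factory=dict)
    raw_colonies: dict[str, float] = field(default_factory=dict)

    @property
    def urban_total(self) -> int:
        return sum(v for k, v in self.cats.items() if k.startswith("U"))

    @property
    def rural_total(self) -> int:
        return sum(v for k, v in self.cats.items() if k.startswith("R"))

    @property
    def national_total(self) -> int:
        return self.urban_total + self.rural_total

    @property
    def rural_share(self) -> float:
        """Rural fraction of the national population (0..1)."""
        total = self.national_total
        return self.rural_total / total if total else 0.0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "scenario": list(SCENARIO_CODES),
                "cats": [self.cats.get(c, 0) for c in SCENARIO_CODES],
                "colonies": [self.colonies.get(c, 0) for c in SCENARIO_CODES],
            }
        )
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BaselineTable":
        cats = dict(zip(df["scenario"], df["cats"].astype(int)))
        colonies = dict(zip(df["scenario"], df["colonies"].astype(int)))
        return cls(cats=cats, colonies=colonies)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BaselineTable":
        return cls.from_frame(pd.read_csv(path))


def extrapolate_national(
    ratios: Mapping[str, SizeClass],
    census: Iterable[MunicipalityRecord],
) -> BaselineTable:
    """Extrapolate the national baseline from size-class ratios.

    Each municipality contributes ``inhabitants * cat_to_human`` cats and
    ``cats / cats_per_colony`` colonies (both real-valued); contributions are
    aggregated by stratum and rounded half-up only at the aggregate, to
    avoid the systematic bias of per-municipality rounding.
    """
    raw_cats = {c: 0.0 for c in SCENARIO_CODES}
    raw_colonies = {c: 0.0 for c in SCENARIO_CODES}
    missing: list[str] = []
    for rec in census:
        lbl = size_class_label(rec.inhabitants)
        if lbl not in ratios:
            missing.append(rec.id)
            continue
        sc = ratios[lbl]
        key = classify_municipality(rec).code
        cats = rec.inhabitants * sc.cat_to_human
        raw_cats[key] += cats
        raw_colonies[key] += cats / sc.cats_per_colony
    if missing:
        raise ValueError(f"municipalities with unmapped size class: {missing[:10]}")
    return BaselineTable(
        cats={c: iround(v) for c, v in raw_cats.items()},
        colonies={c: iround(v) for c, v in raw_colonies.items()},
        raw_cats=raw_cats,
        raw_colonies=raw_colonies,
    )


def read_municipalities_csv(path, with_counts: bool = False) -> list[MunicipalityRecord]:
    """Read a municipal CSV (id, inhabitants, potential[, cats, colonies])."""
    df = pd.read_csv(path, dtype={"id": str})
    records = []
    for row in df.itertuples(index=False):
        records.append(
            MunicipalityRecord(
                id=str(row.id),
                inhabitants=int(row.inhabitants),
                potential=Potential(str(row.potential)),
                counted_cats=int(row.cats) if with_counts else None,
                counted_colonies=int(row.colonies) if with_counts else None,
            )
        )
    return records
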