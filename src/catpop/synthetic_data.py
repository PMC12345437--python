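"""Synthetic municipal samples and national censuses.

Two generators make the whole pipeline testable without any external data:

* :func:`generate_sample` emulates the ~1128-municipality administrative
  sample that the size-class ratios are estimated from: municipality sizes
  drawn log-uniformly within each class, reported cat counts drawn
  negative-binomially around ``ratio * inhabitants`` (colony census counts
  are overdispersed), colony counts derived from the cats-per-colony ratio
  with mild lognormal noise.

* :func:`generate_census` deterministically constructs a full synthetic
  national census whose stratum-level extrapolation (with the default
  size-class ratios) reproduces a target baseline table *exactly*.  With the
  default targets this is the packaged fixture census: a synthetic stand-in
  for the real national municipal register, inverse-solved from the
  published stratum totals — a test artifact, not a claim about real
  administrative data.
"""

from __future__ import annotations

import math

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from ._util import iround, round_half_up
from .reproduction import Habitat, Potential
from .stratification import (
    DEFAULT_SIZE_CLASSES,
    SIZE_CLASS_LABELS,
    MunicipalityRecord,
    ScenarioKey,
    SizeClass,
)

__all__ = [
    "GeneratorSpec",
    "CensusSpec",
    "generate_sample",
    "generate_census",
    "table_baseline_census",
    "records_to_frame",
    "TABLE_STRATUM_POPULATIONS",
]

#: Default per-stratum baseline populations the fixture census reproduces.
TABLE_STRATUM_POPULATIONS: dict[str, int] = {
    "UL": 103_676,
    "UM": 160_648,
    "UH": 88_719,
    "UVH": 132_726,
    "RL": 700_056,
    "RM": 295_906,
    "RH": 153_003,
    "RVH": 179_202,
}

#: Sample composition by size class (counts in the 1128-municipality call).
_DEFAULT_CLASS_COUNTS = {
    "<500": 109,
    "500-5000": 477,
    "5000-10000": 186,
    "10000-50000": 278,
    ">50000": 78,
}

# inhabitant ranges per size class for sampling (log-uniform)
_CLASS_RANGES = {
    "<500": (50, 499),
    "500-5000": (500, 4_999),
    "5000-10000": (5_000, 9_999),
    "10000-50000": (10_000, 49_999),
    ">50000": (50_000, 800_000),
}

#: Default reproductive-potential mix by habitat, proportional to the
#: baseline stratum populations.
_POTENTIAL_MIX = {
    Habitat.URBAN: {"L": 0.213, "M": 0.331, "H": 0.183, "VH": 0.273},
    Habitat.RURAL: {"L": 0.527, "M": 0.223, "H": 0.115, "VH": 0.135},
}


class GeneratorSpec(BaseModel):
    """Configuration of the municipal-sample generator."""

    n_municipalities: int = Field(default=1128, ge=0)
    class_mix: dict[str, float] = Field(
        default_factory=lambda: {
            lbl: cnt / 1128 for lbl, cnt in _DEFAULT_CLASS_COUNTS.items()
        }
    )
    true_ratios: dict[str, SizeClass] = Field(
        default_factory=lambda: dict(DEFAULT_SIZE_CLASSES)
    )
    #: negative-binomial shape parameter; larger = closer to Poisson.
    overdispersion: float = Field(default=10.0, gt=0.0)
    colony_noise_sd: float = Field(default=0.10, ge=0.0)
    seed: int = 0

    model_config = {"arbitrary_types_allowed": True}

    @field_validator("class_mix")
    @classmethod
    def _check_mix(cls, v):
        if set(v) != set(SIZE_CLASS_LABELS):
            raise ValueError(f"class_mix must cover exactly {SIZE_CLASS_LABELS}")
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix fractions must sum to 1")
        if any(f < 0 for f in v.values()):
            raise ValueError("class_mix fractions must be >= 0")
        return v


def generate_sample(spec: GeneratorSpec) -> list[MunicipalityRecord]:
    """Draw a synthetic municipal sample with verified cat/colony counts."""
    rng = np.random.default_rng(spec.seed)
    counts = {
        lbl: int(round(frac * spec.n_municipalities)) for lbl, frac in spec.class_mix.items()
    }
    # reconcile rounding drift against the requested total
    drift = spec.n_municipalities - sum(counts.values())
    if drift:
        largest = max(counts, key=counts.get)
        counts[largest] += drift

    records: list[MunicipalityRecord] = []
    i = 0
    for lbl in SIZE_CLASS_LABELS:
        lo, hi = _CLASS_RANGES[lbl]
        ratios = spec.true_ratios[lbl]
        for _ in range(counts[lbl]):
            inhab = int(np.exp(rng.uniform(math.log(lo), math.log(hi + 1))))
            inhab = min(max(inhab, lo), hi)
            habitat = Habitat.URBAN if inhab > 20_000 else Habitat.RURAL
            mix = _POTENTIAL_MIX[habitat]
            potential = Potential(rng.choice(list(mix), p=list(mix.values())))
            mean_cats = ratios.cat_to_human * inhab
            # NB via gamma-Poisson mixture: var = m + m^2 / k
            lam = rng.gamma(spec.overdispersion, mean_cats / spec.overdispersion)
            cats = int(rng.poisson(lam))
            noise = rng.lognormal(0.0, spec.colony_noise_sd) if spec.colony_noise_sd else 1.0
            colonies = max(1, iround(cats / ratios.cats_per_colony * noise)) if cats else 0
            records.append(
                MunicipalityRecord(
                    id=f"S{i:05d}",
                    inhabitants=inhab,
                    potential=potential,
                    counted_cats=cats,
                    counted_colonies=colonies,
                )
            )
            i += 1
    return records


class CensusSpec(BaseModel):
    """Configuration of the deterministic synthetic national census."""

    stratum_populations: dict[str, int] = Field(
        default_factory=lambda: dict(TABLE_STRATUM_POPULATIONS)
    )
    ratios: dict[str, SizeClass] = Field(default_factory=lambda: dict(DEFAULT_SIZE_CLASSES))
    #: size classes used for rural / urban construction
    rural_class: str = "<500"
    urban_class: str = "10000-50000"

    model_config = {"arbitrary_types_allowed": True}

    @model_validator(mode="after")
    def _check(self):
        for code in self.stratum_populations:
            ScenarioKey.from_code(code)  # raises on bad code
        return self


def _solve_inhabitants(target: int, ratio: float) -> int:
    """Smallest-error total inhabitants H with round_half_up(ratio*H) == target."""
    h0 = int(round(target / ratio))
    for h in sorted(range(h0 - 3, h0 + 4), key=lambda h: abs(ratio * h - target)):
        if h >= 0 and int(round_half_up(ratio * h)) == target:
            return h
    raise ValueError(f"cannot hit target {target} with ratio {ratio}")


def generate_census(spec: CensusSpec | None = None) -> list[MunicipalityRecord]:
    """Deterministic synthetic national census hitting the stratum targets.

    For each stratum the total human population is inverse-solved from the
    size-class cat-to-human ratio, then split into municipalities that stay
    inside the size class (and on the right side of the urban threshold), so
    that extrapolation with the same ratios reproduces the target baseline
    exactly after aggregate half-up rounding.
    """
    if spec is None:
        spec = CensusSpec()
    records: list[MunicipalityRecord] = []
    for code, target in spec.stratum_populations.items():
        key = ScenarioKey.from_code(code)
        if target == 0:
            continue
        urban = key.habitat is Habitat.URBAN
        class_label = spec.urban_class if urban else spec.rural_class
        ratio = spec.ratios[class_label].cat_to_human
        total_inhab = _solve_inhabitants(target, ratio)
        lo, hi = _CLASS_RANGES[class_label]
        min_size = max(lo, 20_001) if urban else lo
        max_size = hi if urban else min(hi, 20_000)
        n = max(1, math.ceil(total_inhab / max_size))
        base, rem = divmod(total_inhab, n)
        if base < min_size:
            raise ValueError(
                f"stratum {code}: target {target} too small to build "
                f"municipalities inside class {class_label!r}"
            )
        for j in range(n):
            inhab = base + (1 if j < rem else 0)
            records.append(
                MunicipalityRecord(
                    id=f"C{code}{j:05d}",
                    inhabitants=inhab,
                    potential=key.potential,
                )
            )
    return records


def table_baseline_census() -> list[MunicipalityRecord]:
    """The packaged fixture census reproducing the default baseline table."""
    return generate_census(CensusSpec())


def records_to_frame(records: list[MunicipalityRecord], with_counts: bool = False):
    """Municipality records as a DataFrame (for CSV round-tripping)."""
    import pandas as pd

    data = {
        "id": [r.id for r in records],
        "inhabitants": [r.inhabitants for r in records],
        "potential": [r.potential.value for r in records],
    }
    if with_counts:
        data["cats"] = [r.counted_cats for r in records]
        data["colonies"] = [r.counted_colonies for r in records]
    return pd.DataFrame(data)
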