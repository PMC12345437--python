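"""Scenario-specific reproductive distributions for free-roaming cats.

The annual reproductive output of an unsterilized female is modelled in two
stages:

1. **Litter frequency.**  A female has up to ``n = 3`` fertile opportunities
   per year.  Each opportunity succeeds with probability
   ``p_modulated = p_base * RUR``, where ``p_base = 0.85`` is the biological
   per-attempt success probability and RUR (Reproductive Utilization Rate)
   is a territorial correction in [0, 1] expressing how many fertile periods
   actually result in pregnancy (photoperiod, winter temperature, stress,
   mate access).  The number of litters per year is therefore
   Binomial(3, p_modulated).

2. **Litter size.**  Kittens per litter follow a Gaussian shape truncated to
   the integer support 1..6 and renormalized:
   ``P(k) = exp(-(k - mu)^2 / (2 sigma^2)) / T`` with
   ``mu = 3.75, sigma = 1.2`` in urban habitats and ``mu = 4.75,
   sigma = 1.3`` in rural ones.  The Gaussian prefactor ``1/(sigma sqrt(2
   pi))`` cancels in the normalization and is omitted.

Applying the first-year mortality filter (65% kitten mortality) to the
product of the two stages yields the expected number of viable offspring per
female per year, the quantity the projection engine consumes.
"""

from __future__ import annotations

import enum
from functools import lru_cache

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import special

from ._util import round_half_up

__all__ = [
    "Potential",
    "Habitat",
    "RUR_BY_LEVEL",
    "LITTER_SIZE_PARAMS",
    "LITTER_SIZE_SUPPORT",
    "scenario_rur",
    "ReproductionParams",
    "MortalitySchedule",
    "modulated_success",
    "litter_count_pmf",
    "litter_size_pmf",
    "expected_litter_size",
    "expected_litters",
    "expected_viable_offspring",
    "litter_count_table",
    "litter_size_table",
]


class Potential(str, enum.Enum):
    """Provincial reproductive-potential class (winter daylight/temperature)."""

    L = "L"
    M = "M"
    H = "H"
    VH = "VH"


class Habitat(str, enum.Enum):
    URBAN = "urban"
    RURAL = "rural"


#: Default RUR for each reproductive-potential level (the four rows of the
#: litter-frequency table).
RUR_BY_LEVEL: dict[Potential, float] = {
    Potential.L: 0.55,
    Potential.M: 0.65,
    Potential.H: 0.75,
    Potential.VH: 0.85,
}

#: Litter-size Gaussian parameters (mean, sd) by habitat.
LITTER_SIZE_PARAMS: dict[Habitat, tuple[float, float]] = {
    Habitat.URBAN: (3.75, 1.2),
    Habitat.RURAL: (4.75, 1.3),
}

#: Integer litter sizes with non-zero probability.
LITTER_SIZE_SUPPORT = np.arange(1, 7)

#: Per-scenario RUR.  Rural strata take the level default; urban strata are
#: assigned one level higher (UL shares RM's value, UM shares RH's, and both
#: UH and UVH sit at the 0.85 ceiling), reflecting year-round food
#: availability and prolonged urban estrus.
_SCENARIO_RUR: dict[tuple[Habitat, Potential], float] = {
    (Habitat.RURAL, Potential.L): 0.55,
    (Habitat.RURAL, Potential.M): 0.65,
    (Habitat.RURAL, Potential.H): 0.75,
    (Habitat.RURAL, Potential.VH): 0.85,
    (Habitat.URBAN, Potential.L): 0.65,
    (Habitat.URBAN, Potential.M): 0.75,
    (Habitat.URBAN, Potential.H): 0.85,
    (Habitat.URBAN, Potential.VH): 0.85,
}


def scenario_rur(habitat: Habitat, potential: Potential) -> float:
    """RUR used by a habitat x potential stratum in the projection model."""
    return _SCENARIO_RUR[(Habitat(habitat), Potential(potential))]


class MortalitySchedule(BaseModel):
    """Annual age-specific mortality fractions."""

    kitten_mortality: float = Field(default=0.65, ge=0.0, le=1.0)
    adult_mortality: float = Field(default=0.15, ge=0.0, le=1.0)


class ReproductionParams(BaseModel):
    """Full parameter set for one stratum's reproductive model."""

    p_base: float = Field(default=0.85, ge=0.0, le=1.0)
    n_opportunities: int = Field(default=3, ge=1)
    rur: float = Field(default=1.0, ge=0.0, le=1.0)
    litter_mean: float = 3.75
    litter_sd: float = Field(default=1.2, gt=0.0)

    @model_validator(mode="after")
    def _check_modulated(self):
        if not 0.0 <= self.p_base * self.rur <= 1.0:
            raise ValueError("modulated success probability outside [0, 1]")
        return self

    @classmethod
    def for_scenario(cls, habitat: Habitat, potential: Potential) -> "ReproductionParams":
        mean, sd = LITTER_SIZE_PARAMS[Habitat(habitat)]
        return cls(rur=scenario_rur(habitat, potential), litter_mean=mean, litter_sd=sd)

    @property
    def p_modulated(self) -> float:
        return modulated_success(self.p_base, self.rur)


def modulated_success(p_base: float, rur: float) -> float:
    """Effective per-opportunity success probability, ``p_base * RUR``."""
    if not 0.0 <= p_base <= 1.0:
        raise ValueError(f"p_base must be in [0, 1], got {p_base}")
    if not 0.0 <= rur <= 1.0:
        raise ValueError(f"RUR must be in [0, 1], got {rur}")
    return p_base * rur


def litter_count_pmf(p_mod: float, n: int = 3) -> np.ndarray:
    """Binomial pmf over the number of litters per female per year.

    Returns an array of length ``n + 1`` indexed by k = 0..n litters,
    summing to 1.
    """
    if not 0.0 <= p_mod <= 1.0:
        raise ValueError(f"p_mod must be in [0, 1], got {p_mod}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    k = np.arange(n + 1)
    # explicit C(n,k) p^k (1-p)^(n-k): robust down to subnormal p, where
    # scipy's regularized-beta route can overflow
    with np.errstate(under="ignore"):
        return special.comb(n, k) * p_mod**k * (1.0 - p_mod) ** (n - k)


def litter_size_pmf(litter_mean: float, litter_sd: float) -> np.ndarray:
    """Truncated discrete-Gaussian pmf over litter sizes 1..6.

    The Gaussian density is evaluated at the integer support, then divided
    by its sum; the ``1/(sigma sqrt(2 pi))`` prefactor cancels.
    """
    if litter_sd <= 0:
        raise ValueError(f"litter_sd must be > 0, got {litter_sd}")
    w = np.exp(-((LITTER_SIZE_SUPPORT - litter_mean) ** 2) / (2.0 * litter_sd**2))
    return w / w.sum()


def expected_litters(params: ReproductionParams) -> float:
    """Mean litters per female per year, ``n * p_modulated``."""
    return params.n_opportunities * params.p_modulated


def expected_litter_size(params: ReproductionParams) -> float:
    pmf = litter_size_pmf(params.litter_mean, params.litter_sd)
    return float(pmf @ LITTER_SIZE_SUPPORT)


def expected_viable_offspring(
    params: ReproductionParams, mort: MortalitySchedule | None = None
) -> float:
    """Expected kittens per female per year surviving their first year.

    ``E[litters] * E[litter size] * (1 - kitten_mortality)``.
    """
    if mort is None:
        mort = MortalitySchedule()
    return expected_litters(params) * expected_litter_size(params) * (1.0 - mort.kitten_mortality)


@lru_cache(maxsize=None)
def _habitat_pmf(habitat: Habitat) -> tuple[float, ...]:
    mean, sd = LITTER_SIZE_PARAMS[habitat]
    return tuple(litter_size_pmf(mean, sd))


def habitat_litter_size_pmf(habitat: Habitat) -> np.ndarray:
    """Litter-size pmf for a habitat with the default parameters."""
    return np.array(_habitat_pmf(Habitat(habitat)))


def litter_count_table(p_base: float = 0.85, n: int = 3) -> pd.DataFrame:
    """Litter-frequency table: one row per RUR level, percent, 2 decimals."""
    rows = {}
    for level, rur in RUR_BY_LEVEL.items():
        pmf = litter_count_pmf(modulated_success(p_base, rur), n)
        rows[level.value] = round_half_up(pmf * 100.0, 2)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=[f"{k}_litters" for k in range(n + 1)])
    df.insert(0, "rur", [RUR_BY_LEVEL[Potential(lv)] for lv in df.index])
    df.index.name = "scenario"
    return df


def litter_size_table() -> pd.DataFrame:
    """Litter-size table: rows k = 1..6 kittens, urban/rural percent columns."""
    data = {
        hab.value: round_half_up(habitat_litter_size_pmf(hab) * 100.0, 2)
        for hab in (Habitat.URBAN, Habitat.RURAL)
    }
    df = pd.DataFrame(data, index=LITTER_SIZE_SUPPORT)
    df.index.name = "kittens_per_litter"
    return df
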