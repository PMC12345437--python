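"""Sterilization policy plans.

A :class:`PolicyPlan` maps each stratum to a target sterilization coverage —
the sterilized fraction of the living population to be reached (and then
maintained) by the annual TNR transfer.  The four built-in plans encode the
intervention scenarios analysed nationally:

* ``baseline20`` — the status quo: fragmented effort holding every stratum
  at the current ~20% coverage (an 80:20 unsterilized:sterilized ratio).
* ``enhanced40`` — doubled national effort, 40% everywhere.
* ``ideal80`` — the idealized 80% literature benchmark, everywhere.
* ``pacf`` — the differentiated national strategy: 50% in most strata,
  60% in urban very-high and rural high reproductive-potential areas, and
  70% in rural very-high areas.
"""

from __future__ import annotations

from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator

from .stratification import SCENARIO_CODES

__all__ = ["PolicyPlan", "builtin_plans", "get_plan"]


class PolicyPlan(BaseModel):
    """Per-stratum sterilization coverage targets, constant over years."""

    name: str
    coverage: dict[str, float]
    #: "maintain": the target is the post-transfer sterilized stock fraction,
    #: re-established every year.  "annual_rate": the target is instead the
    #: fraction of currently unsterilized individuals transferred each year
    #: (a campaign-effort reading, exposed for sensitivity analysis).
    mode: Literal["maintain", "annual_rate"] = "maintain"

    @field_validator("coverage")
    @classmethod
    def _check_coverage(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(SCENARIO_CODES)
        if unknown:
            raise ValueError(f"unknown scenario codes: {sorted(unknown)}")
        missing = set(SCENARIO_CODES) - set(v)
        if missing:
            raise ValueError(f"missing scenario codes: {sorted(missing)}")
        for code, frac in v.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"coverage for {code} must be in [0, 1], got {frac}")
        return v

    @classmethod
    def uniform(cls, name: str, target: float, mode: str = "maintain") -> "PolicyPlan":
        return cls(name=name, coverage={c: target for c in SCENARIO_CODES}, mode=mode)

    @classmethod
    def from_yaml(cls, path) -> "PolicyPlan":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


def builtin_plans() -> list[PolicyPlan]:
    """The four built-in intervention scenarios."""
    pacf_coverage = {
        "UL": 0.50,
        "UM": 0.50,
        "UH": 0.50,
        "UVH": 0.60,
        "RL": 0.50,
        "RM": 0.50,
        "RH": 0.60,
        "RVH": 0.70,
    }
    return [
        PolicyPlan.uniform("baseline20", 0.20),
        PolicyPlan.uniform("enhanced40", 0.40),
        PolicyPlan.uniform("ideal80", 0.80),
        PolicyPlan(name="pacf", coverage=pacf_coverage),
    ]


def get_plan(name: str) -> PolicyPlan:
    for plan in builtin_plans():
        if plan.name == name:
            return plan
    raise KeyError(f"no built-in plan named {name!r}")
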