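"""Annual-step stochastic metapopulation projection under TNR policies.

Each of the eight strata holds four cohorts — kittens/adults x
sterilized/unsterilized.  One simulated year applies, in order:

1. **births** — unsterilized adult females (50% of unsterilized adults)
   produce litters (Binomial(3, p_modulated) litters each, truncated-Gaussian
   litter sizes); kittens enter the unsterilized kitten cohort;
2. **catastrophe draw** — with 5% annual probability per stratum, this
   year's mortality rates rise by 30% (multiplicative by default);
3. **mortality** — 65% kitten / 15% adult annual mortality, binomial
   thinning in the stochastic engine;
4. **age up** — surviving kittens become adults;
5. **abandonment** — a constant national inflow (109,000/yr) of unsterilized
   cats, allocated across strata proportionally to the initial stratum
   populations, half kittens half adults;
6. **adoption** — a constant national harvest (52,000/yr) removed
   proportionally to current stratum sizes and cohort sizes, capped at
   availability;
7. **sterilization transfer** — unsterilized individuals are moved (never
   removed) to the sterilized cohorts until the policy's coverage target is
   met; because this runs after the flow steps, immigrants are covered too;
8. **carrying capacity** — if a stratum exceeds K (2.5x initial for rural,
   3x for urban by default), cohorts are scaled down proportionally so the
   total equals K exactly.

Two engines share this code path: the default stochastic engine keeps
integer counts and draws binomial/multinomial variates; the expected-value
engine propagates real-valued means deterministically (catastrophes enter
through the expected rate multiplier) and serves as a fast, bit-reproducible
oracle for the stochastic one.

Monte-Carlo iterations are vectorized: cohort arrays carry a leading
iteration axis and a single seeded generator drives the whole batch.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from ._util import iround, largest_remainder
from .policies import PolicyPlan
from .reproduction import (
    Habitat,
    LITTER_SIZE_SUPPORT,
    MortalitySchedule,
    ReproductionParams,
    expected_litter_size,
    habitat_litter_size_pmf,
)
from .stratification import SCENARIO_CODES, SCENARIOS, BaselineTable

__all__ = [
    "Cohort",
    "CatastropheSpec",
    "FlowSpec",
    "CapacitySpec",
    "SimConfig",
    "PopulationState",
    "YearLedger",
    "StratumParams",
    "default_stratum_params",
    "initialize_state",
    "births",
    "apply_mortality",
    "age_up",
    "apply_flows",
    "apply_sterilization",
    "enforce_capacity",
    "step_year",
    "run_scenario",
    "Trajectory",
    "SimulationResult",
]

N_STRATA = len(SCENARIOS)


class Cohort(enum.IntEnum):
    """Cohort axis layout of all count arrays."""

    KITTEN_UNSTERILIZED = 0
    KITTEN_STERILIZED = 1
    ADULT_UNSTERILIZED = 2
    ADULT_STERILIZED = 3


_KU, _KS, _AU, _AS = (int(c) for c in Cohort)

DEFAULT_EVENT_ORDER: tuple[str, ...] = (
    "births",
    "mortality",
    "age_up",
    "abandonment",
    "adoption",
    "sterilization",
    "capacity",
)


class CatastropheSpec(BaseModel):
    """Stochastic mass-mortality events (disease outbreaks, poisoning...)."""

    annual_probability: float = Field(default=0.05, ge=0.0, le=1.0)
    mortality_multiplier: float = Field(default=1.30, ge=1.0)
    #: multiplicative: rate -> rate * multiplier; additive: rate -> rate +
    #: (multiplier - 1).  Both capped at 1.
    mode: Literal["multiplicative", "additive"] = "multiplicative"


class FlowSpec(BaseModel):
    """Constant national abandonment inflow and adoption harvest."""

    national_abandonment: int = Field(default=109_000, ge=0)
    national_adoption: int = Field(default=52_000, ge=0)
    abandonment_kitten_fraction: float = Field(default=0.5, ge=0.0, le=1.0)


class CapacitySpec(BaseModel):
    """Carrying-capacity multipliers applied to initial stratum sizes."""

    rural_multiplier: float = 2.5
    urban_multiplier: float = 3.0
    #: optional per-stratum override, e.g. {"UM": 2.5}
    overrides: dict[str, float] = Field(default_factory=dict)

    def multipliers(self) -> np.ndarray:
        mult = np.array(
            [
                self.urban_multiplier if key.habitat is Habitat.URBAN else self.rural_multiplier
                for key in SCENARIOS
            ]
        )
        for code, value in self.overrides.items():
            mult[SCENARIO_CODES.index(code)] = value
        return mult


class SimConfig(BaseModel):
    """Run configuration for the projection engine."""

    horizon: int = Field(default=25, ge=0)
    iterations: int = Field(default=1000, ge=1)
    seed: int = 0
    engine: Literal["stochastic", "expected_value"] = "stochastic"
    initial_sterilized_fraction: float = Field(default=0.20, ge=0.0, le=1.0)
    initial_stage: Literal["adults", "stable"] = "adults"
    mortality: MortalitySchedule = Field(default_factory=MortalitySchedule)
    catastrophe: CatastropheSpec = Field(default_factory=CatastropheSpec)
    flows: FlowSpec = Field(default_factory=FlowSpec)
    capacity: CapacitySpec = Field(default_factory=CapacitySpec)
    event_order: tuple[str, ...] = DEFAULT_EVENT_ORDER

    @field_validator("event_order")
    @classmethod
    def _check_order(cls, v):
        if sorted(v) != sorted(DEFAULT_EVENT_ORDER):
            raise ValueError(f"event_order must be a permutation of {DEFAULT_EVENT_ORDER}")
        return tuple(v)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclasses.dataclass
class StratumParams:
    """Vectorized per-stratum demographic parameters."""

    p_mod: np.ndarray  # (8,) modulated per-opportunity success
    n_opportunities: int
    size_pmf: np.ndarray  # (8, 6) litter-size pmf rows
    mean_litter: np.ndarray  # (8,)


def default_stratum_params() -> StratumParams:
    p_mod = np.empty(N_STRATA)
    size_pmf = np.empty((N_STRATA, LITTER_SIZE_SUPPORT.size))
    mean_litter = np.empty(N_STRATA)
    n_opp = 3
    for i, key in enumerate(SCENARIOS):
        params = ReproductionParams.for_scenario(key.habitat, key.potential)
        p_mod[i] = params.p_modulated
        n_opp = params.n_opportunities
        size_pmf[i] = habitat_litter_size_pmf(key.habitat)
        mean_litter[i] = expected_litter_size(params)
    return StratumParams(p_mod=p_mod, n_opportunities=n_opp, size_pmf=size_pmf, mean_litter=mean_litter)


@dataclasses.dataclass
class PopulationState:
    """Cohort counts for all strata at one point in time.

    ``counts`` has shape ``(..., 8, 4)``; a leading axis, when present,
    indexes Monte-Carlo iterations.  The stochastic engine uses int64, the
    expected-value engine float64.
    """

    counts: np.ndarray
    year: int = 0

    def copy(self) -> "PopulationState":
        return PopulationState(self.counts.copy(), self.year)

    @property
    def stratum_totals(self) -> np.ndarray:
        return self.counts.sum(axis=-1)

    @property
    def total(self) -> np.ndarray:
        return self.counts.sum(axis=(-1, -2))

    @property
    def sterilized(self) -> np.ndarray:
        return self.counts[..., [_KS, _AS]].sum(axis=(-1, -2))

    @property
    def unsterilized(self) -> np.ndarray:
        return self.counts[..., [_KU, _AU]].sum(axis=(-1, -2))


@dataclasses.dataclass
class YearLedger:
    """Exact event bookkeeping for one simulated year (summed nationally)."""

    births: np.ndarray
    deaths: np.ndarray
    abandoned: np.ndarray
    adopted: np.ndarray
    capacity_removed: np.ndarray
    sterilized_transferred: np.ndarray


def initialize_state(
    baseline: BaselineTable,
    cfg: SimConfig,
    params: StratumParams | None = None,
) -> PopulationState:
    """Initial cohort counts from a baseline table.

    Each stratum's population is split half-up into sterilized/unsterilized.
    By default everyone starts adult; ``initial_stage="stable"`` instead
    seeds kittens at the stationary kitten share implied by the stratum's
    birth and survival rates (a sensitivity option).
    """
    if params is None:
        params = default_stratum_params()
    totals = np.array([baseline.cats.get(c, 0) for c in SCENARIO_CODES], dtype=np.int64)
    sterilized = iround(cfg.initial_sterilized_fraction * totals)
    unsterilized = totals - sterilized
    counts = np.zeros((N_STRATA, 4), dtype=np.int64)
    if cfg.initial_stage == "adults":
        counts[:, _AU] = unsterilized
        counts[:, _AS] = sterilized
    else:
        # stationary kitten share: births per adult b -> kittens/(adults+kittens)
        b = 0.5 * params.n_opportunities * params.p_mod * params.mean_litter
        kitten_share = b / (1.0 + b)
        ku = iround(kitten_share * unsterilized)
        counts[:, _KU] = ku
        counts[:, _AU] = unsterilized - ku
        counts[:, _AS] = sterilized
    return PopulationState(counts=counts, year=0)


def _is_stochastic(counts: np.ndarray) -> bool:
    return np.issubdtype(counts.dtype, np.integer)


def births(
    counts: np.ndarray,
    params: StratumParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Kittens produced this year per stratum (added by caller to KU).

    Breeding pool: 50% of unsterilized adults.  Stochastic: total litters
    over F females ~ Binomial(3F, p_mod); kittens = multinomial litter-size
    composition.  Expected-value: F * 3 p_mod * E[litter size].
    """
    adults_u = counts[..., _AU]
    if _is_stochastic(counts):
        if rng is None:
            raise ValueError("stochastic births require an rng")
        females = adults_u // 2
        litters = rng.binomial(params.n_opportunities * females, params.p_mod)
        kittens = np.zeros_like(adults_u)
        # two litter-size pmfs (urban rows 0..3, rural rows 4..7)
        for rows in (slice(0, 4), slice(4, 8)):
            comp = rng.multinomial(litters[..., rows], params.size_pmf[rows.start])
            kittens[..., rows] = comp @ LITTER_SIZE_SUPPORT
        return kittens
    females = adults_u / 2.0
    return females * params.n_opportunities * params.p_mod * params.mean_litter


def _effective_rates(
    mort: MortalitySchedule, cat: CatastropheSpec, active
) -> tuple[np.ndarray, np.ndarray]:
    """Per-stratum kitten/adult mortality rates given catastrophe activity.

    ``active`` is a boolean array (stochastic draw) or a float expectation
    (expected-value engine).
    """
    active = np.asarray(active, dtype=float)
    if cat.mode == "multiplicative":
        factor = 1.0 + active * (cat.mortality_multiplier - 1.0)
        kitten = np.minimum(mort.kitten_mortality * factor, 1.0)
        adult = np.minimum(mort.adult_mortality * factor, 1.0)
    else:
        bump = active * (cat.mortality_multiplier - 1.0)
        kitten = np.minimum(mort.kitten_mortality + bump, 1.0)
        adult = np.minimum(mort.adult_mortality + bump, 1.0)
    return kitten, adult


def apply_mortality(
    counts: np.ndarray,
    mort: MortalitySchedule,
    catastrophe: CatastropheSpec | None = None,
    catastrophe_active=False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Thin every cohort at its age-specific rate; returns (survivors, deaths)."""
    if catastrophe is None:
        catastrophe = CatastropheSpec()
    kitten_rate, adult_rate = _effective_rates(mort, catastrophe, catastrophe_active)
    surv = np.stack(
        [1.0 - kitten_rate, 1.0 - kitten_rate, 1.0 - adult_rate, 1.0 - adult_rate], axis=-1
    )
    surv = np.broadcast_to(surv, counts.shape)
    if _is_stochastic(counts):
        if rng is None:
            raise ValueError("stochastic mortality requires an rng")
        survivors = rng.binomial(counts, surv)
    else:
        survivors = counts * surv
    return survivors, counts - survivors


def age_up(counts: np.ndarray) -> np.ndarray:
    """Move surviving kittens into the adult cohorts; reset kitten cohorts."""
    out = counts.copy()
    out[..., _AU] = out[..., _AU] + out[..., _KU]
    out[..., _AS] = out[..., _AS] + out[..., _KS]
    out[..., _KU] = 0
    out[..., _KS] = 0
    return out


def abandonment_allocation(flows: FlowSpec, initial_totals: np.ndarray) -> np.ndarray:
    """Constant per-stratum abandonment additions, shape (8, 4).

    The national inflow is split across strata proportionally to the
    *initial* stratum populations (largest remainder), then half kittens /
    half adults, all unsterilized.
    """
    per_stratum = largest_remainder(initial_totals, flows.national_abandonment)
    kittens = iround(flows.abandonment_kitten_fraction * per_stratum)
    adults = per_stratum - kittens
    alloc = np.zeros((N_STRATA, 4), dtype=np.int64)
    alloc[:, _KU] = kittens
    alloc[:, _AU] = adults
    return alloc


def apply_flows(
    counts: np.ndarray,
    flows: FlowSpec,
    abandonment: np.ndarray | None = None,
    do_abandonment: bool = True,
    do_adoption: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Add the abandonment inflow and/or remove the adoption harvest.

    Returns ``(new_counts, abandoned_added, adopted_removed)`` where the
    flow arrays are summed over strata/cohorts per batch element.  Adoption
    is removed proportionally to current cohort sizes across all strata
    (largest remainder in the integer engine), capped at availability.
    """
    out = counts.copy()
    stochastic = _is_stochastic(counts)
    added = np.zeros(counts.shape[:-2], dtype=counts.dtype)
    removed = np.zeros(counts.shape[:-2], dtype=counts.dtype)

    if do_abandonment and flows.national_abandonment > 0:
        if abandonment is None:
            raise ValueError("abandonment allocation required (see abandonment_allocation)")
        out = out + abandonment.astype(out.dtype)
        added = added + abandonment.sum()

    if do_adoption and flows.national_adoption > 0:
        flat = out.reshape(out.shape[:-2] + (N_STRATA * 4,))
        total = flat.sum(axis=-1)
        harvest = np.minimum(total, flows.national_adoption)
        if stochastic:
            removals = largest_remainder(flat, harvest)
            flat = flat - removals
            removed = removed + harvest.astype(counts.dtype)
        else:
            total_safe = np.where(total > 0, total, 1.0)
            frac = harvest / total_safe
            removals = flat * frac[..., None]
            flat = flat - removals
            removed = removed + harvest
        out = flat.reshape(out.shape)

    return out, added, removed


def apply_sterilization(
    counts: np.ndarray,
    coverage_target,
    mode: str = "maintain",
) -> tuple[np.ndarray, np.ndarray]:
    """Transfer unsterilized individuals to the sterilized cohorts.

    ``maintain`` mode moves the minimum number needed so that
    sterilized/total >= target in each stratum; ``annual_rate`` mode instead
    moves ``target`` fraction of the currently unsterilized.  Individuals
    are moved, never removed; transfers are split between unsterilized
    kittens and adults proportionally (largest remainder).

    Returns ``(new_counts, transferred_total)``.
    """
    target = np.asarray(coverage_target, dtype=float)
    out = counts.copy()
    unst = out[..., [_KU, _AU]]
    available = unst.sum(axis=-1)
    if mode == "maintain":
        total = out.sum(axis=-1)
        sterilized = out[..., [_KS, _AS]].sum(axis=-1)
        # tiny epsilon guards against 0.2 * 1000 = 200.0000000000003 artifacts
        needed = np.ceil(target * total - sterilized - 1e-9)
        needed = np.maximum(needed, 0.0)
    elif mode == "annual_rate":
        needed = target * available
    else:
        raise ValueError(f"unknown sterilization mode {mode!r}")

    if _is_stochastic(counts):
        transfer = np.minimum(iround(np.ceil(needed)) if mode == "maintain" else iround(needed),
                              available)
        moved = largest_remainder(unst, transfer)
        out[..., _KU] -= moved[..., 0]
        out[..., _KS] += moved[..., 0]
        out[..., _AU] -= moved[..., 1]
        out[..., _AS] += moved[..., 1]
        total_moved = transfer.sum(axis=-1)
    else:
        transfer = np.minimum(needed, available)
        avail_safe = np.where(available > 0, available, 1.0)
        frac = transfer / avail_safe
        moved_k = out[..., _KU] * frac
        moved_a = out[..., _AU] * frac
        out[..., _KU] -= moved_k
        out[..., _KS] += moved_k
        out[..., _AU] -= moved_a
        out[..., _AS] += moved_a
        total_moved = transfer.sum(axis=-1)
    return out, total_moved


def enforce_capacity(counts: np.ndarray, capacity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale strata exceeding K down to exactly K, preserving proportions.

    Returns ``(new_counts, removed_total)``.
    """
    totals = counts.sum(axis=-1)
    over = totals > capacity
    if not np.any(over):
        return counts, np.zeros(counts.shape[:-2], dtype=counts.dtype)
    target = np.where(over, np.minimum(totals, capacity), totals)
    if _is_stochastic(counts):
        scaled = largest_remainder(counts, target)
        out = np.where(over[..., None], scaled, counts)
    else:
        totals_safe = np.where(totals > 0, totals, 1.0)
        factor = np.where(over, target / totals_safe, 1.0)
        out = counts * factor[..., None]
    removed = (totals - out.sum(axis=-1)).sum(axis=-1)
    return out, removed


@dataclasses.dataclass
class _RunContext:
    """Precomputed invariants shared by every simulated year."""

    params: StratumParams
    cfg: SimConfig
    coverage: np.ndarray  # (8,)
    coverage_mode: str
    capacity: np.ndarray  # (8,)
    abandonment: np.ndarray  # (8, 4)


def _draw_catastrophes(ctx: _RunContext, shape, rng: np.random.Generator | None, stochastic: bool):
    p = ctx.cfg.catastrophe.annual_probability
    if stochastic:
        return rng.random(shape) < p
    return np.full(shape, p)  # expectation enters the rate multiplier


def step_year(
    state: PopulationState,
    ctx: _RunContext,
    rng: np.random.Generator | None = None,
) -> tuple[PopulationState, YearLedger]:
    """Advance the population one year through the configured event order."""
    counts = state.counts
    stochastic = _is_stochastic(counts)
    batch_shape = counts.shape[:-2]
    zero = np.zeros(batch_shape, dtype=counts.dtype)
    ledger = YearLedger(zero, zero.copy(), zero.copy(), zero.copy(), zero.copy(), zero.copy())

    catastrophe_active = _draw_catastrophes(
        ctx, counts.shape[:-1], rng, stochastic
    )

    for event in ctx.cfg.event_order:
        if event == "births":
            new_kittens = births(counts, ctx.params, rng)
            counts = counts.copy()
            counts[..., _KU] = counts[..., _KU] + new_kittens
            ledger.births = ledger.births + new_kittens.sum(axis=-1)
        elif event == "mortality":
            counts, deaths = apply_mortality(
                counts,
                ctx.cfg.mortality,
                ctx.cfg.catastrophe,
                catastrophe_active,
                rng,
            )
            ledger.deaths = ledger.deaths + deaths.sum(axis=(-1, -2))
        elif event == "age_up":
            counts = age_up(counts)
        elif event == "abandonment":
            counts, added, _ = apply_flows(
                counts, ctx.cfg.flows, ctx.abandonment, do_adoption=False
            )
            ledger.abandoned = ledger.abandoned + added
        elif event == "adoption":
            counts, _, removed = apply_flows(
                counts, ctx.cfg.flows, do_abandonment=False
            )
            ledger.adopted = ledger.adopted + removed
        elif event == "sterilization":
            counts, moved = apply_sterilization(counts, ctx.coverage, ctx.coverage_mode)
            ledger.sterilized_transferred = ledger.sterilized_transferred + moved
        elif event == "capacity":
            counts, culled = enforce_capacity(counts, ctx.capacity)
            ledger.capacity_removed = ledger.capacity_removed + culled
        else:  # pragma: no cover - guarded by SimConfig validation
            raise ValueError(f"unknown event {event!r}")

    return PopulationState(counts, state.year + 1), ledger


@dataclasses.dataclass
class Trajectory:
    """Per-year Monte-Carlo summary of one population series."""

    years: np.ndarray
    mean: np.ndarray
    lo: np.ndarray  # 2.5th percentile
    hi: np.ndarray  # 97.5th percentile

    def to_frame(self, prefix: str = "total") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                f"{prefix}_mean": self.mean,
                f"{prefix}_lo": self.lo,
                f"{prefix}_hi": self.hi,
            }
        )


def _summarize(series: np.ndarray, years: np.ndarray) -> Trajectory:
    # series shape (iterations, years+1)
    return Trajectory(
        years=years,
        mean=series.mean(axis=0),
        lo=np.percentile(series, 2.5, axis=0),
        hi=np.percentile(series, 97.5, axis=0),
    )


@dataclasses.dataclass
class SimulationResult:
    """Raw Monte-Carlo arrays plus summaries for one scenario run."""

    config: SimConfig
    plan_name: str
    years: np.ndarray
    #: (iterations, years+1) national totals
    national_total: np.ndarray
    national_sterilized: np.ndarray
    national_unsterilized: np.ndarray
    #: (iterations, 8, years+1) per-stratum totals
    stratum_totals: np.ndarray
    ledgers: list[YearLedger]

    @property
    def national(self) -> Trajectory:
        return _summarize(self.national_total, self.years)

    @property
    def sterilized(self) -> Trajectory:
        return _summarize(self.national_sterilized, self.years)

    @property
    def unsterilized(self) -> Trajectory:
        return _summarize(self.national_unsterilized, self.years)

    def stratum(self, code: str) -> Trajectory:
        idx = SCENARIO_CODES.index(code)
        return _summarize(self.stratum_totals[:, idx, :], self.years)

    def national_frame(self) -> pd.DataFrame:
        df = self.national.to_frame("total")
        df = df.merge(self.sterilized.to_frame("sterilized"), on="year")
        df = df.merge(self.unsterilized.to_frame("unsterilized"), on="year")
        return df

    def stratum_frame(self, code: str) -> pd.DataFrame:
        return self.stratum(code).to_frame("total")


def build_context(
    baseline: BaselineTable,
    plan: PolicyPlan,
    cfg: SimConfig,
    params: StratumParams | None = None,
) -> _RunContext:
    if params is None:
        params = default_stratum_params()
    initial_totals = np.array([baseline.cats.get(c, 0) for c in SCENARIO_CODES], dtype=np.int64)
    capacity = iround(cfg.capacity.multipliers() * initial_totals)
    coverage = np.array([plan.coverage[c] for c in SCENARIO_CODES])
    abandonment = abandonment_allocation(cfg.flows, initial_totals)
    return _RunContext(
        params=params,
        cfg=cfg,
        coverage=coverage,
        coverage_mode=plan.mode,
        capacity=capacity,
        abandonment=abandonment,
    )


def run_scenario(
    baseline: BaselineTable,
    plan: PolicyPlan,
    cfg: SimConfig,
    params: StratumParams | None = None,
    check_conservation: bool = True,
) -> SimulationResult:
    """Project all eight strata over the horizon and aggregate nationally."""
    ctx = build_context(baseline, plan, cfg, params)
    state0 = initialize_state(baseline, cfg, ctx.params)

    stochastic = cfg.engine == "stochastic"
    n_iter = cfg.iterations if stochastic else 1
    if stochastic:
        counts = np.broadcast_to(state0.counts, (n_iter,) + state0.counts.shape).copy()
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    else:
        counts = state0.counts.astype(float)[None, ...]
        rng = None

    years = np.arange(cfg.horizon + 1)
    national_total = np.empty((n_iter, cfg.horizon + 1))
    national_ster = np.empty_like(national_total)
    national_unster = np.empty_like(national_total)
    stratum_totals = np.empty((n_iter, N_STRATA, cfg.horizon + 1))

    state = PopulationState(counts, 0)
    ledgers: list[YearLedger] = []

    def record(t: int, st: PopulationState) -> None:
        national_total[:, t] = st.total
        national_ster[:, t] = st.sterilized
        national_unster[:, t] = st.unsterilized
        stratum_totals[:, :, t] = st.stratum_totals

    record(0, state)
    for t in range(1, cfg.horizon + 1):
        before = state.total
        state, ledger = step_year(state, ctx, rng)
        ledgers.append(ledger)
        if check_conservation:
            after = state.total
            expected = (
                before
                + ledger.births
                + ledger.abandoned
                - ledger.deaths
                - ledger.adopted
                - ledger.capacity_removed
            )
            if stochastic:
                if not np.array_equal(after, expected):
                    raise AssertionError(f"conservation violated in year {t}")
            elif not np.allclose(after, expected, rtol=1e-9, atol=1e-6):
                raise AssertionError(f"conservation violated in year {t}")
        record(t, state)

    return SimulationResult(
        config=cfg,
        plan_name=plan.name,
        years=years,
        national_total=national_total,
        national_sterilized=national_ster,
        national_unsterilized=national_unster,
        stratum_totals=stratum_totals,
        ledgers=ledgers,
    )
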