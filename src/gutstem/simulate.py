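"""Agent-based forward simulator of killifish intestinal epithelium turnover.

The killifish gut mucosa is organised in fold units: a proliferative interfold
region (IFR, the functional analogue of the mammalian crypt) feeding two fold
flanks that act as conveyor belts.  All cycling cells sit in the IFR; slow-cycling
intestinal stem cells (ISCs) divide asymmetrically, producing transient-amplifying
(TA) progenitors that divide a fixed number of times, differentiate, and are
pushed onto a flank.  Every arrival at the fold base shifts the column upward;
cells pushed past the apex are shed by apoptosis.

A dual-pulse thymidine-analogue schedule (BrdU twice 2 h apart, a 6-day chase,
one EdU pulse, harvest 1 day later) marks cells in S phase during each pulse
window; label content is halved at every division, so fast-cycling TA cells
dilute the first label below detectability while slow-cycling ISCs retain it
(label-retaining cells, LRCs).  The simulator emits "section tables": ordered
per-cell records (DAPI/BrdU/EdU/PCNA flags plus a zone tag) that mimic scoring
a stained histological section, and an event log of divisions and apoptoses.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Pulse",
    "LabelingSchedule",
    "SimConfig",
    "SimResult",
    "scenario",
    "simulate",
    "simulate_cohort",
    "render_sections",
    "zone_of_position",
    "ZONES",
]

# cell states
ISC, TA, DIFF = 0, 1, 2
# cycle phases
G1, S, G2M, NONE = 0, 1, 2, 3

ZONES = ("IFR", "FOLD_LOWER", "FOLD_UPPER", "APEX")

SECTION_COLUMNS = (
    "animal_id",
    "section_id",
    "unit_id",
    "position_index",
    "zone",
    "dapi",
    "brdu",
    "edu",
    "pcna",
)


@dataclass(frozen=True)
class Pulse:
    """One intraperitoneal injection of a thymidine analogue.

    ``window`` is the bioavailability of the analogue after injection (hours):
    cells whose S phase overlaps [start, start + window) incorporate the label.
    """

    analog: str  # "BrdU" or "EdU"
    start: float  # hours
    window: float = 1.0  # hours

    def __post_init__(self):
        if self.analog not in ("BrdU", "EdU"):
            raise ValueError(f"unknown analog {self.analog!r}")
        if self.window <= 0:
            raise ValueError("pulse window must be positive")


@dataclass(frozen=True)
class LabelingSchedule:
    """Pulse times and the harvest time of the labeling experiment."""

    pulses: tuple[Pulse, ...]
    harvest_time: float  # hours after the first pulse's t=0 frame

    def __post_init__(self):
        if not self.pulses:
            raise ValueError("schedule needs at least one pulse")
        starts = [p.start for p in self.pulses]
        if sorted(starts) != starts:
            raise ValueError("pulses must be sorted by start time")
        if self.harvest_time <= max(starts):
            raise ValueError("harvest_time must fall after the last pulse")

    @classmethod
    def dual_pulse(cls, pulse_window: float = 1.0) -> "LabelingSchedule":
        """The LRC detection schedule: BrdU at 0 h and 2 h, EdU at 146 h,
        harvest at 170 h (one day after EdU)."""
        return cls(
            pulses=(
                Pulse("BrdU", 0.0, pulse_window),
                Pulse("BrdU", 2.0, pulse_window),
                Pulse("EdU", 146.0, pulse_window),
            ),
            harvest_time=170.0,
        )

    def windows(self, analog: str) -> list[tuple[float, float]]:
        """Merged (start, end) bioavailability windows for one analogue.

        Overlapping windows of the same analogue merge rather than error.
        """
        spans = sorted(
            (p.start, p.start + p.window) for p in self.pulses if p.analog == analog
        )
        merged: list[tuple[float, float]] = []
        for a, b in spans:
            if merged and a <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        return merged

    @property
    def inter_pulse_interval(self) -> float:
        """Effective Ti: time from the last first-analogue pulse to the first
        second-analogue pulse (144 h under the default schedule)."""
        brdu = [p.start for p in self.pulses if p.analog == "BrdU"]
        edu = [p.start for p in self.pulses if p.analog == "EdU"]
        if brdu and edu:
            return min(edu) - max(brdu)
        # single-analogue schedules: spacing of the two outermost pulses
        starts = [p.start for p in self.pulses]
        return max(starts) - min(starts)


@dataclass
class SimConfig:
    """Parameters of one simulated animal.

    Times are hours.  ``tc_isc``/``tc_ta`` may be ``inf`` (frozen tissue).
    ``dilution_threshold`` is the minimum label content (fraction of full
    incorporation) still scored positive; at the default 1/16, four halvings
    leave a label exactly at the detection boundary and a fifth erases it.
    """

    n_units: int = 20          # fold units per animal
    n_ifr: int = 24            # initial cells per IFR pool
    n_fold: int = 45           # positions per fold flank (conveyor length)
    n_isc: int = 5             # ISCs per IFR (constant under asymmetric division)
    tc_isc: float = 54.0       # ISC total cycle time
    tc_ta: float = 24.0       # TA total cycle time
    ts_frac: float = 0.3       # S-phase fraction of the cycle
    cv_phase: float = 0.15     # CV of Gamma-distributed phase durations
    d_max: int = 4             # TA divisions before forced differentiation
    pulse_window: float = 1.0  # analogue bioavailability per injection
    dilution_threshold: float = 1.0 / 16.0
    dt: float = 0.5            # integration timestep
    burn_in: float | None = None  # default 10 * tc_ta (finite) before t=0
    isc_daughter_isc_prob: float = 0.0  # >0 enables symmetric expansion
    g1_share: float = 0.7      # G1 share of the non-S cycle remainder
    cv_between_animal: float = 0.15  # CV of per-animal cycle-time multipliers

    def validate(self) -> None:
        if self.n_fold <= 0:
            raise ValueError("n_fold must be positive")
        if not (0 < self.n_isc <= self.n_ifr):
            raise ValueError("need 0 < n_isc <= n_ifr")
        if not (0.0 < self.ts_frac < 1.0):
            raise ValueError("ts_frac must lie in (0, 1)")
        if not (0.0 < self.dilution_threshold <= 1.0):
            raise ValueError("dilution_threshold must lie in (0, 1]")
        for name in ("tc_isc", "tc_ta", "pulse_window", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.d_max < 1:
            raise ValueError("d_max must be >= 1")
        if not (0.0 <= self.isc_daughter_isc_prob <= 1.0):
            raise ValueError("isc_daughter_isc_prob must lie in [0, 1]")

    @property
    def effective_burn_in(self) -> float:
        if self.burn_in is not None:
            return self.burn_in
        if math.isfinite(self.tc_ta):
            return 10.0 * self.tc_ta
        return 0.0

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


_SCENARIOS = {
    # ISC cycle times: adult ~54 h and old ~76 h match the measured ages W12/W20;
    # adolescent is a faster-cycling young scenario used in recovery experiments.
    "adolescent": dict(tc_isc=40.0),
    "adult": dict(tc_isc=54.0),
    "old": dict(tc_isc=76.0),
}


def scenario(name: str, **overrides) -> SimConfig:
    """Named age-scenario presets differing in ISC cycle time.

    Only the stem-cell compartment slows with age; TA kinetics stay fixed, so
    the conveyor slows through the reduced differentiation influx alone.
    """
    if name not in _SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(_SCENARIOS)}")
    kw = dict(_SCENARIOS[name])
    kw.update(overrides)
    return SimConfig(**kw)


def zone_of_position(pos: np.ndarray, n_fold: int) -> np.ndarray:
    """Zone labels for flank positions (-1 = IFR; top 10% of positions = APEX)."""
    pos = np.asarray(pos)
    out = np.full(pos.shape, "FOLD_UPPER", dtype=object)
    apex_start = n_fold - max(1, int(round(0.1 * n_fold)))
    out[pos >= apex_start] = "APEX"
    out[pos < n_fold / 2.0] = "FOLD_LOWER"
    out[pos < 0] = "IFR"
    return out


def _phase_fracs(cfg: SimConfig) -> np.ndarray:
    rest = 1.0 - cfg.ts_frac
    return np.array([cfg.g1_share * rest, cfg.ts_frac, (1.0 - cfg.g1_share) * rest])


def _phase_mean(cfg: SimConfig, state: np.ndarray, phase: np.ndarray) -> np.ndarray:
    tc = np.where(state == ISC, cfg.tc_isc, cfg.tc_ta)
    return tc * _phase_fracs(cfg)[np.minimum(phase, 2)]


def _draw_durations(rng: np.random.Generator, mean: np.ndarray, cv: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    out = np.array(mean, copy=True)
    finite = np.isfinite(mean) & (mean > 0)
    if cv > 0 and finite.any():
        shape = 1.0 / cv**2
        out[finite] = rng.gamma(shape, mean[finite] * cv**2)
    return out


@dataclass
class SimResult:
    """Final cell population plus the division/apoptosis event log."""

    config: SimConfig
    schedule: LabelingSchedule
    seed: int
    unit: np.ndarray
    pos: np.ndarray      # -1 for IFR pool, 0..n_fold-1 along a flank
    flank: np.ndarray    # -1 for IFR pool, 0/1 for the two flanks
    state: np.ndarray    # ISC / TA / DIFF
    phase: np.ndarray    # G1 / S / G2M / NONE
    brdu: np.ndarray     # label content in [0, 1]
    edu: np.ndarray
    ndiv: np.ndarray
    events: pd.DataFrame  # columns: time, event, unit_id
    n_initial: int

    @property
    def n_cells(self) -> int:
        return self.unit.size

    @property
    def n_divisions(self) -> int:
        return int((self.events["event"] == "division").sum())

    @property
    def n_apoptoses(self) -> int:
        return int((self.events["event"] == "apoptosis").sum())

    def label_flags(self, theta: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Binary BrdU/EdU detection flags at threshold theta."""
        theta = self.config.dilution_threshold if theta is None else theta
        return (self.brdu >= theta).astype(int), (self.edu >= theta).astype(int)

    def event_log_lines(self) -> list[str]:
        return [
            f"{t:.2f}\t{ev}\t{u}"
            for t, ev, u in self.events.itertuples(index=False)
        ]


def simulate(
    config: SimConfig,
    schedule: LabelingSchedule | None = None,
    seed: int = 0,
) -> SimResult:
    """Run the turnover simulation from burn-in through harvest.

    The population is initialised with ``n_isc`` ISCs and ``n_ifr - n_isc`` TA
    cells per IFR at random phase positions, equilibrated for ``burn_in`` hours
    (default 10 TA cycles) before the schedule's t=0, then stepped through the
    pulse-chase protocol to ``harvest_time``.
    """
    config.validate()
    if schedule is None:
        schedule = LabelingSchedule.dual_pulse(config.pulse_window)
    cfg = config
    rng = np.random.default_rng(seed)
    dt = cfg.dt

    n0 = cfg.n_units * cfg.n_ifr
    unit = np.repeat(np.arange(cfg.n_units), cfg.n_ifr)
    per_unit = np.array([ISC] * cfg.n_isc + [TA] * (cfg.n_ifr - cfg.n_isc), dtype=np.int8)
    state = np.tile(per_unit, cfg.n_units).astype(np.int8)
    pos = np.full(n0, -1, dtype=np.int32)
    flank = np.full(n0, -1, dtype=np.int8)
    ndiv = np.where(
        state == ISC, 0, rng.integers(0, cfg.d_max, size=n0)
    ).astype(np.int16)
    brdu = np.zeros(n0)
    edu = np.zeros(n0)

    # random initial phase, weighted by mean phase duration
    shares = np.array(
        [cfg.g1_share * (1 - cfg.ts_frac), cfg.ts_frac, (1 - cfg.g1_share) * (1 - cfg.ts_frac)]
    )
    phase = rng.choice(np.array([G1, S, G2M], dtype=np.int8), size=n0, p=shares)
    # non-proliferating (infinite cycle time) cells rest in G1, never in S
    frozen = ~np.isfinite(np.where(state == ISC, cfg.tc_isc, cfg.tc_ta))
    phase[frozen] = G1
    phase_dur = _draw_durations(rng, _phase_mean(cfg, state, phase), cfg.cv_phase)
    with np.errstate(invalid="ignore"):
        phase_age = np.where(np.isfinite(phase_dur), rng.uniform(0, 1, n0) * phase_dur, 0.0)

    brdu_windows = schedule.windows("BrdU")
    edu_windows = schedule.windows("EdU")

    ev_time: list[np.ndarray] = []
    ev_kind: list[np.ndarray] = []
    ev_unit: list[np.ndarray] = []

    # hot-path duration sampler: tc by state and phase fraction as lookups
    fracs = _phase_fracs(cfg)
    tc_by_state = np.array([cfg.tc_isc, cfg.tc_ta, np.inf])
    all_finite = math.isfinite(cfg.tc_isc) and math.isfinite(cfg.tc_ta)
    gamma_shape = 1.0 / cfg.cv_phase**2 if cfg.cv_phase > 0 else None

    def draw_dur(state_idx, phase_idx):
        mean = tc_by_state[state_idx] * fracs[phase_idx]
        if gamma_shape is None:
            return mean
        if all_finite:
            return rng.gamma(gamma_shape, mean * cfg.cv_phase**2)
        return _draw_durations(rng, mean, cfg.cv_phase)

    t = -cfg.effective_burn_in
    horizon = schedule.harvest_time
    while t < horizon - 1e-9:
        step_end = min(t + dt, horizon)
        # non-cycling cells carry an infinite phase_dur and a NONE phase, so
        # the unmasked update and completion check below cannot touch them
        phase_age += step_end - t

        # pulse labeling: any S-phase overlap with an active window marks the cell
        for windows, content in ((brdu_windows, brdu), (edu_windows, edu)):
            for a, b in windows:
                if a < step_end and b > t:
                    content[(state <= TA) & (phase == S)] = 1.0

        done_idx = np.flatnonzero(phase_age >= phase_dur)
        div_idx = done_idx[phase[done_idx] == G2M]
        adv_idx = done_idx[phase[done_idx] != G2M]

        if adv_idx.size:
            over = phase_age[adv_idx] - phase_dur[adv_idx]
            new_phase = phase[adv_idx] + 1
            phase[adv_idx] = new_phase
            phase_dur[adv_idx] = draw_dur(state[adv_idx], new_phase)
            phase_age[adv_idx] = over

        if div_idx.size:
            over = phase_age[div_idx] - phase_dur[div_idx]
            # label halving applies to both products of the division
            brdu[div_idx] *= 0.5
            edu[div_idx] *= 0.5

            mother_isc = state[div_idx] == ISC
            # daughters
            d_unit = unit[div_idx]
            d_state = np.full(div_idx.size, TA, dtype=np.int8)
            if cfg.isc_daughter_isc_prob > 0:
                sym = mother_isc & (
                    rng.uniform(size=div_idx.size) < cfg.isc_daughter_isc_prob
                )
                d_state[sym] = ISC
            d_ndiv = np.where(mother_isc, 0, ndiv[div_idx] + 1).astype(np.int16)
            d_ndiv[d_state == ISC] = 0
            ndiv[div_idx] += 1
            # mothers restart G1
            phase[div_idx] = G1
            phase_dur[div_idx] = draw_dur(state[div_idx], np.zeros(div_idx.size, dtype=np.int8))
            phase_age[div_idx] = over

            d_phase = np.full(div_idx.size, G1, dtype=np.int8)
            d_dur = draw_dur(d_state, d_phase)

            ev_time.append(np.full(div_idx.size, t))
            ev_kind.append(np.zeros(div_idx.size, dtype=np.int8))
            ev_unit.append(d_unit.astype(np.int32))

            n_before = unit.size
            unit = np.concatenate([unit, d_unit])
            pos = np.concatenate([pos, np.full(div_idx.size, -1, dtype=np.int32)])
            flank = np.concatenate([flank, np.full(div_idx.size, -1, dtype=np.int8)])
            state = np.concatenate([state, d_state])
            phase = np.concatenate([phase, d_phase])
            phase_dur = np.concatenate([phase_dur, d_dur])
            phase_age = np.concatenate([phase_age, over.copy()])
            brdu = np.concatenate([brdu, brdu[div_idx]])
            edu = np.concatenate([edu, edu[div_idx]])
            ndiv = np.concatenate([ndiv, d_ndiv])

            # forced differentiation of exhausted TA cells (mothers + daughters)
            cand = np.concatenate([div_idx, np.arange(n_before, unit.size)])
            newdiff = cand[(state[cand] == TA) & (ndiv[cand] >= cfg.d_max)]
            if newdiff.size:
                state[newdiff] = DIFF
                phase[newdiff] = NONE
                phase_dur[newdiff] = np.inf
                phase_age[newdiff] = 0.0
                ev_time.append(np.full(newdiff.size, t))
                ev_kind.append(np.full(newdiff.size, 2, dtype=np.int8))
                ev_unit.append(unit[newdiff].astype(np.int32))
                target_flank = rng.integers(0, 2, size=newdiff.size).astype(np.int8)
                key = unit[newdiff] * 2 + target_flank
                # shift every standing fold cell by the number of arrivals on
                # its flank, in one vectorized pass
                arrivals = np.bincount(key, minlength=cfg.n_units * 2)
                standing = pos >= 0
                pos[standing] += arrivals[unit[standing] * 2 + flank[standing]]
                # arrivals take base positions 0..c-1 in random within-flank order
                perm = np.lexsort((rng.random(newdiff.size), key))
                sorted_key = key[perm]
                group_start = np.flatnonzero(
                    np.r_[True, sorted_key[1:] != sorted_key[:-1]]
                )
                rank = np.arange(newdiff.size) - np.repeat(
                    group_start, np.diff(np.r_[group_start, newdiff.size])
                )
                pos[newdiff[perm]] = rank
                flank[newdiff] = target_flank

                # cells pushed past the apex are shed
                shed = pos >= cfg.n_fold
                if shed.any():
                    ev_time.append(np.full(int(shed.sum()), t))
                    ev_kind.append(np.ones(int(shed.sum()), dtype=np.int8))
                    ev_unit.append(unit[shed].astype(np.int32))
                    keep = ~shed
                    unit, pos, flank = unit[keep], pos[keep], flank[keep]
                    state, phase = state[keep], phase[keep]
                    phase_dur, phase_age = phase_dur[keep], phase_age[keep]
                    brdu, edu, ndiv = brdu[keep], edu[keep], ndiv[keep]

        t = step_end

    if ev_time:
        times = np.concatenate(ev_time)
        kinds = np.concatenate(ev_kind)
        units = np.concatenate(ev_unit)
    else:
        times = np.empty(0)
        kinds = np.empty(0, dtype=np.int8)
        units = np.empty(0, dtype=np.int32)
    kind_names = np.array(["division", "apoptosis", "differentiation"])
    events = pd.DataFrame(
        {"time": times, "event": kind_names[kinds], "unit_id": units}
    )

    return SimResult(
        config=cfg,
        schedule=schedule,
        seed=seed,
        unit=unit,
        pos=pos,
        flank=flank,
        state=state,
        phase=phase,
        brdu=brdu,
        edu=edu,
        ndiv=ndiv,
        events=events,
        n_initial=n0,
    )


def simulate_cohort(
    config: SimConfig,
    n_animals: int = 3,
    schedule: LabelingSchedule | None = None,
    seed: int = 0,
    n_sections: int = 8,
    units_per_section: int | None = None,
    cells_per_unit: int | None = None,
    animal_prefix: str = "A",
) -> pd.DataFrame:
    """Simulate and render a cohort of animals sharing one scenario.

    Real cohorts are not clones: each animal draws a lognormal multiplier of
    CV ``cv_between_animal`` applied to both its ISC and TA cycle times,
    emulating inter-individual variation in turnover rate around the scenario
    mean.  Returns the concatenated section tables of all animals.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for a in range(n_animals):
        if config.cv_between_animal > 0:
            sigma = math.sqrt(math.log(1.0 + config.cv_between_animal**2))
            mult = float(rng.lognormal(-0.5 * sigma**2, sigma))
        else:
            mult = 1.0
        cfg_a = config.replace(
            tc_isc=config.tc_isc * mult if math.isfinite(config.tc_isc) else config.tc_isc,
            tc_ta=config.tc_ta * mult if math.isfinite(config.tc_ta) else config.tc_ta,
        )
        sim_seed = int(rng.integers(0, 2**31 - 1))
        res = simulate(cfg_a, schedule, seed=sim_seed)
        frames.append(
            render_sections(
                res,
                n_sections=n_sections,
                units_per_section=units_per_section,
                cells_per_unit=cells_per_unit,
                seed=sim_seed,
                animal_id=f"{animal_prefix}{a}",
            )
        )
    return pd.concat(frames, ignore_index=True)


def render_sections(
    result: SimResult,
    n_sections: int = 1,
    units_per_section: int | None = None,
    cells_per_unit: int | None = None,
    seed: int = 0,
    animal_id: str = "A1",
) -> pd.DataFrame:
    """Emit section tables from a harvested simulation.

    Each section observes ``units_per_section`` fold units (all units when
    ``None``).  When the requested sections jointly need no more units than
    exist, units are partitioned without reuse (mimicking physically distinct
    sections); otherwise each section samples units independently.  Per unit the
    IFR pool is emitted first in randomised order (the pool has no internal
    geometry), followed by the two flanks base-to-apex; ``cells_per_unit``
    subsamples the unit's cells order-preservingly, as a thin section would.
    Deterministic under ``seed``.
    """
    cfg = result.config
    rng = np.random.default_rng(seed)
    brdu_flag, edu_flag = result.label_flags()
    pcna = (result.state <= TA).astype(int)

    unit_ids = np.arange(cfg.n_units)
    ups = cfg.n_units if units_per_section is None else units_per_section
    if ups > cfg.n_units:
        warnings.warn("requested more units per section than exist; clamping")
        ups = cfg.n_units

    if n_sections * ups <= cfg.n_units:
        shuffled = rng.permutation(unit_ids)
        section_units = [shuffled[i * ups : (i + 1) * ups] for i in range(n_sections)]
    else:
        section_units = [
            rng.choice(unit_ids, size=ups, replace=False) for _ in range(n_sections)
        ]

    # sort cells once: by unit, then IFR/flank block, then flank position
    order_all = np.lexsort((result.pos, result.flank, result.unit))
    u_sorted = result.unit[order_all]

    cols = {k: [] for k in ("section_id", "unit_id", "position_index", "idx")}
    for s_idx, units in enumerate(section_units):
        for u in units:
            lo, hi = np.searchsorted(u_sorted, [u, u + 1])
            block = order_all[lo:hi]
            if block.size == 0:
                continue
            n_ifr = int((result.pos[block] < 0).sum())
            ordered = np.concatenate(
                [rng.permutation(block[:n_ifr]), block[n_ifr:]]
            )
            if cells_per_unit is not None:
                if cells_per_unit > ordered.size:
                    warnings.warn("requested more cells than exist in unit; clamping")
                elif cells_per_unit < ordered.size:
                    take = np.sort(
                        rng.choice(ordered.size, size=cells_per_unit, replace=False)
                    )
                    ordered = ordered[take]
            cols["section_id"].append(np.full(ordered.size, s_idx, dtype=np.int64))
            cols["unit_id"].append(np.full(ordered.size, u, dtype=np.int64))
            cols["position_index"].append(np.arange(ordered.size, dtype=np.int64))
            cols["idx"].append(ordered)

    if not cols["idx"]:
        return pd.DataFrame(columns=list(SECTION_COLUMNS))
    idx = np.concatenate(cols["idx"])
    section_names = np.array([f"S{i}" for i in range(len(section_units))])
    out = pd.DataFrame(
        {
            "animal_id": animal_id,
            "section_id": section_names[np.concatenate(cols["section_id"])],
            "unit_id": np.concatenate(cols["unit_id"]),
            "position_index": np.concatenate(cols["position_index"]),
            "zone": zone_of_position(result.pos[idx], cfg.n_fold),
            "dapi": 1,
            "brdu": brdu_flag[idx],
            "edu": edu_flag[idx],
            "pcna": pcna[idx],
        }
    )
    return out[list(SECTION_COLUMNS)]
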