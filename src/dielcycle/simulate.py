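"""Synthetic light/dark-synchronized picocyanobacterial populations.

The generator emulates a *Prochlorococcus*-like population entrained by a
12 h/12 h modulated light cycle in the slow-growth regime: each cell performs
at most one G1 -> S -> G2 -> division traversal per 24 h.  Per day and per
cell, the time of entry into S is drawn around a mean clock hour
(``s_onset_clock``) with a between-cell spread (``sigma_sync``); S and G2
durations are drawn once per traversal; division replaces one G2 cell by two
G1 daughters.  A fraction of cells may skip division for a day
(``frac_arrested``), and a continuous-culture mode removes cells at a
constant dilution rate, uniformly at random.

Entry into S is gated by clock time (an entrainment model), not by the
instantaneous irradiance; the :class:`~dielcycle.schedule.LightSchedule`
carried by a scenario labels the light regime and drives nothing mechanistic.

A separate measurement model (:func:`measure_events`) turns a population
snapshot into SYBR-style DNA fluorescence events: signal proportional to DNA
content (1 genome equivalent in G1, 2 in G2, linear in between during S)
with multiplicative Gaussian noise and optional low-signal debris.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .schedule import E_MAX_PAR_HL, E_MAX_PAR_LL, E_MAX_UVA, E_MAX_UVB, LightSchedule
from .series import PhaseFractionSeries

__all__ = [
    "SimParams",
    "InstrumentModel",
    "EventSample",
    "CellCountSeries",
    "CellSnapshot",
    "PopulationHistory",
    "SimResult",
    "Scenario",
    "ExtinctionError",
    "simulate_population",
    "measure_events",
    "events_from_fractions",
    "default_scenarios",
    "simulate_scenario",
]

G1, S, G2 = 0, 1, 2
PHASE_NAMES = ("G1", "S", "G2")

#: Integration/step resolution used when a sub-hourly grid is needed (hours).
TIME_STEP_H = 0.1


class ExtinctionError(RuntimeError):
    """Raised when a continuous culture is diluted to extinction."""


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulated population.

    ``s_onset_clock`` is the *mean* clock hour at which cells enter S; the
    first cells of the wave appear roughly ``2 * sigma_sync`` earlier.  With
    the defaults (onset 16:00, T_S = T_G2 = 4 h, dusk at 18:00) the
    S-fraction peak falls at the light-to-dark transition and the G2 peak
    4 h later, the canonical high-light pattern.
    """

    n0: int = 10_000
    s_onset_clock: float = 16.0     # h, mean S-entry clock time
    sigma_sync: float = 1.0         # h, between-cell spread of S entry
    t_s: float = 4.0                # h, mean S duration
    t_g2: float = 4.0               # h, mean G2 duration
    jitter_s: float = 0.25          # h, per-cell SD of S duration
    jitter_g2: float = 0.25         # h, per-cell SD of G2 duration
    frac_arrested: float = 0.05     # fraction of cells skipping division per day
    mode: str = "batch"             # "batch" | "continuous"
    dilution_rate: float = 0.0      # d-1, continuous mode only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n0 < 1:
            raise ValueError("n0 must be >= 1")
        if self.t_s <= 0 or self.t_g2 <= 0:
            raise ValueError("t_s and t_g2 must be > 0")
        if self.sigma_sync < 0 or self.jitter_s < 0 or self.jitter_g2 < 0:
            raise ValueError("spreads must be >= 0")
        if not 0.0 <= self.frac_arrested < 1.0:
            raise ValueError("frac_arrested must be in [0, 1)")
        if self.mode not in ("batch", "continuous"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "continuous" and self.dilution_rate <= 0:
            raise ValueError("continuous mode requires dilution_rate > 0")


@dataclass(frozen=True)
class InstrumentModel:
    """Flow-cytometer measurement model for the DNA-stain channel.

    ``gain`` is the expected fluorescence (a.u.) of one genome equivalent;
    the expected G2 peak sits at exactly ``2 * gain``.  ``cv`` is the
    fractional coefficient of variation of the measured signal.
    """

    gain: float = 200.0
    cv: float = 0.03
    bead_position: Optional[float] = None   # a.u., internal reference beads
    debris_frac: float = 0.0                # fraction of low-signal noise events

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.cv <= 0:
            raise ValueError("cv must be > 0")
        if not 0.0 <= self.debris_frac < 1.0:
            raise ValueError("debris_frac must be in [0, 1)")


@dataclass
class EventSample:
    """Single-timepoint list of DNA-fluorescence events (a.u.)."""

    t: float                 # clock hours in [0, 24)
    events: np.ndarray
    day: int = 0
    condition: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        if not 0.0 <= self.t < 24.0:
            raise ValueError("t must be a clock hour in [0, 24)")
        if self.events.size and np.any(self.events <= 0):
            raise ValueError("all event values must be > 0")

    @property
    def t_abs(self) -> float:
        """Hours since the start of the experiment."""
        return 24.0 * self.day + self.t


@dataclass
class CellCountSeries:
    """Cell concentration time series (cells mL-1 at absolute hours)."""

    t: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if np.any(self.n <= 0):
            raise ValueError("cell counts must be > 0")


@dataclass
class CellSnapshot:
    """Per-cell states of the alive population at one sampling time."""

    t_abs: float
    phase: np.ndarray       # int8 codes: 0=G1, 1=S, 2=G2
    phase_age: np.ndarray   # hours in current phase
    dna: np.ndarray         # genome equivalents in [1, 2]

    @property
    def n_cells(self) -> int:
        return self.phase.size

    def fractions(self):
        n = self.n_cells
        return tuple(float(np.count_nonzero(self.phase == p)) / n for p in (G1, S, G2))


@dataclass
class PopulationHistory:
    """Full per-cell schedule records of a simulated population.

    Each cell is one record: its birth time, washout time (``inf`` in batch
    mode), S-entry time (``inf`` if it never entered), drawn S and G2
    durations, and death time (division or washout, ``inf`` if still alive at
    the end).  All times are absolute hours.
    """

    birth: np.ndarray
    entry: np.ndarray
    dur_s: np.ndarray
    dur_g2: np.ndarray
    death: np.ndarray
    divided: np.ndarray

    def alive_mask(self, t_abs: float) -> np.ndarray:
        return (self.birth <= t_abs) & (t_abs < self.death)

    def count(self, t_abs) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t_abs, dtype=float))
        return np.array([int(self.alive_mask(ti).sum()) for ti in t])

    def snapshot(self, t_abs: float) -> CellSnapshot:
        alive = self.alive_mask(t_abs)
        if not alive.any():
            raise ExtinctionError(f"population extinct at t = {t_abs:.2f} h")
        birth = self.birth[alive]
        entry = self.entry[alive]
        dur_s = self.dur_s[alive]
        s_end = entry + dur_s
        in_s = (entry <= t_abs) & (t_abs < s_end)
        in_g2 = np.isfinite(entry) & (t_abs >= s_end)
        phase = np.zeros(birth.size, dtype=np.int8)
        phase[in_s] = S
        phase[in_g2] = G2
        age = t_abs - birth
        age[in_s] = t_abs - entry[in_s]
        age[in_g2] = t_abs - s_end[in_g2]
        dna = np.ones(birth.size)
        dna[in_s] = 1.0 + (t_abs - entry[in_s]) / dur_s[in_s]
        dna[in_g2] = 2.0
        return CellSnapshot(t_abs=t_abs, phase=phase, phase_age=age, dna=dna)


@dataclass
class SimResult:
    truth: PhaseFractionSeries
    counts: CellCountSeries
    snapshots: list
    history: PopulationHistory


def _washout_times(rng, birth, rate_per_day):
    if rate_per_day <= 0:
        return np.full(birth.size, np.inf)
    return birth + rng.exponential(24.0 / rate_per_day, size=birth.size)


def simulate_population(
    params: SimParams,
    schedule: Optional[LightSchedule] = None,
    sample_times: Optional[Sequence[float]] = None,
    n_days: int = 2,
) -> SimResult:
    """Simulate a synchronized population and sample its true phase structure.

    Parameters
    ----------
    params : SimParams
    schedule : LightSchedule, optional
        Carried for scenario labeling; does not drive the cell cycle.
    sample_times : sequence of clock hours in [0, 24), optional
        Defaults to hourly sampling.  Expanded across ``n_days``.
    n_days : int
        Number of diel cycles simulated (>= 1).

    Returns
    -------
    SimResult
        Exact truth fractions, cell counts, per-cell snapshots at each
        sampling time, and the full population history.  All randomness
        derives from ``params.seed``; identical inputs give bit-identical
        outputs.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if sample_times is None:
        sample_times = np.arange(0.0, 24.0, 1.0)
    sample_times = np.asarray(sorted(sample_times), dtype=float)
    if np.any(sample_times < 0) or np.any(sample_times >= 24):
        raise ValueError("sample_times must be clock hours in [0, 24)")

    rng = np.random.default_rng(params.seed)
    rate = params.dilution_rate if params.mode == "continuous" else 0.0

    # growing record arrays
    birth = [np.zeros(params.n0)]
    entry = [np.full(params.n0, np.inf)]
    dur_s = [np.zeros(params.n0)]
    dur_g2 = [np.zeros(params.n0)]
    death = [_washout_times(rng, birth[0], rate)]
    divided = [np.zeros(params.n0, dtype=bool)]

    def _cat(chunks):
        return np.concatenate(chunks) if len(chunks) > 1 else chunks[0]

    # cells alive and not yet committed to a traversal
    pending = np.arange(params.n0)

    for day in range(n_days):
        if pending.size == 0:
            raise ExtinctionError(f"population extinct before day {day}")
        b = _cat(birth)
        w = _cat(death)  # for pending cells death currently equals washout time
        arrested = rng.random(pending.size) < params.frac_arrested
        act = pending[~arrested]

        e = 24.0 * day + rng.normal(params.s_onset_clock, params.sigma_sync, act.size)
        e = np.maximum(e, b[act] + 1e-9)
        ds = np.clip(rng.normal(params.t_s, params.jitter_s, act.size), 0.05, None)
        dg = np.clip(rng.normal(params.t_g2, params.jitter_g2, act.size), 0.05, None)
        div = e + ds + dg
        enters = e < w[act]          # washed out before entering S otherwise
        divides = enters & (div < w[act])

        # write the traversal into the records
        entry_full = _cat(entry)
        dur_s_full = _cat(dur_s)
        dur_g2_full = _cat(dur_g2)
        death_full = w
        divided_full = _cat(divided)
        sel = act[enters]
        entry_full[sel] = e[enters]
        dur_s_full[sel] = ds[enters]
        dur_g2_full[sel] = dg[enters]
        death_full[act[divides]] = div[divides]
        divided_full[act[divides]] = True
        entry, dur_s, dur_g2, death, divided = (
            [entry_full], [dur_s_full], [dur_g2_full], [death_full], [divided_full]
        )
        birth = [b]

        # daughters: two G1 cells per division
        n_new = 2 * int(divides.sum())
        child_birth = np.repeat(div[divides], 2)
        birth.append(child_birth)
        entry.append(np.full(n_new, np.inf))
        dur_s.append(np.zeros(n_new))
        dur_g2.append(np.zeros(n_new))
        death.append(_washout_times(rng, child_birth, rate))
        divided.append(np.zeros(n_new, dtype=bool))
        child_idx = b.size + np.arange(n_new)

        # survivors into the next day's wave: arrested cells not yet washed
        # out, plus the new daughters (their own washout is checked above).
        next_boundary = 24.0 * (day + 1)
        still = pending[arrested]
        still = still[death_full[still] > next_boundary]
        pending = np.concatenate([still, child_idx])

    history = PopulationHistory(
        birth=_cat(birth),
        entry=_cat(entry),
        dur_s=_cat(dur_s),
        dur_g2=_cat(dur_g2),
        death=_cat(death),
        divided=_cat(divided),
    )

    t_abs = np.concatenate([24.0 * d + sample_times for d in range(n_days)])
    snapshots = [history.snapshot(t) for t in t_abs]
    frac = np.array([snap.fractions() for snap in snapshots])
    truth = PhaseFractionSeries(
        t=t_abs, f_g1=frac[:, 0], f_s=frac[:, 1], f_g2=frac[:, 2]
    )
    counts = CellCountSeries(t=t_abs, n=history.count(t_abs).astype(float))
    return SimResult(truth=truth, counts=counts, snapshots=snapshots, history=history)


def measure_events(
    snapshot: CellSnapshot,
    instrument: InstrumentModel,
    n_events: int,
    seed,
    replace: bool = True,
    condition: str = "",
) -> EventSample:
    """Draw DNA-fluorescence events from a population snapshot.

    Cells are sampled uniformly (with replacement by default, mimicking
    subsampling of a large culture); each event is
    ``gain * dna_content * (1 + eps)`` with ``eps ~ Normal(0, cv)``, floored
    at a small positive value.  ``instrument.debris_frac`` appends
    exponentially distributed low-signal noise events below the G1 peak.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_cells = snapshot.n_cells
    if n_cells == 0:
        raise ValueError("empty population snapshot")
    if not replace and n_events > n_cells:
        raise ValueError(
            f"n_events ({n_events}) exceeds population ({n_cells}) "
            "and sampling without replacement was requested"
        )
    idx = rng.choice(n_cells, size=n_events, replace=replace)
    fl = instrument.gain * snapshot.dna[idx] * (
        1.0 + instrument.cv * rng.standard_normal(n_events)
    )
    if instrument.debris_frac > 0:
        n_debris = int(round(instrument.debris_frac * n_events))
        debris = rng.exponential(instrument.gain / 4.0, size=n_debris)
        fl = np.concatenate([fl, debris])
    fl = np.maximum(fl, 1e-6 * instrument.gain)
    return EventSample(
        t=snapshot.t_abs % 24.0,
        day=int(snapshot.t_abs // 24.0),
        events=fl,
        condition=condition,
    )


def events_from_fractions(
    fractions,
    n_events: int,
    instrument: InstrumentModel,
    seed,
    t: float = 0.0,
) -> EventSample:
    """Generate events directly from target (f_G1, f_S, f_G2) fractions.

    The oracle generator for histogram-fit recovery tests: G1 cells carry 1
    genome equivalent, G2 cells 2, S cells a DNA content uniform in (1, 2);
    the instrument model is applied as in :func:`measure_events`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f = np.asarray(fractions, dtype=float)
    if f.size != 3 or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be 3 non-negative values summing to 1")
    n_per = rng.multinomial(n_events, f)
    dna = np.concatenate([
        np.ones(n_per[0]),
        1.0 + rng.random(n_per[1]),
        np.full(n_per[2], 2.0),
    ])
    phase = np.concatenate([
        np.zeros(n_per[0], dtype=np.int8),
        np.ones(n_per[1], dtype=np.int8),
        np.full(n_per[2], 2, dtype=np.int8),
    ])
    snap = CellSnapshot(t_abs=t, phase=phase, phase_age=np.zeros(n_events), dna=dna)
    return measure_events(snap, instrument, n_events, rng, replace=False)


# ---------------------------------------------------------------------------
# Default scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """A named light regime plus the population parameters it entrains."""

    name: str
    schedule: LightSchedule
    params: SimParams


def default_scenarios() -> dict:
    """The three canonical acclimated light regimes.

    * ``HL``: high light; mean S entry 16:00, so the S-fraction peak falls at
      the 18:00 light-to-dark transition and the G2 peak 4 h later.
    * ``HL+UV``: the same population with the replication wave shifted 2 h
      later into the dark period (mean S entry 18:00, S peak 20:00).
    * ``LL``: low light; earlier S peak (17:00) and a slower division rate
      (about half of the population divides per day).
    """
    hl_sched = LightSchedule(e_max_par=E_MAX_PAR_HL)
    uv_sched = LightSchedule(
        e_max_par=E_MAX_PAR_HL, e_max_uva=E_MAX_UVA, e_max_uvb=E_MAX_UVB
    )
    ll_sched = LightSchedule(e_max_par=E_MAX_PAR_LL)
    hl = SimParams(s_onset_clock=16.0, t_s=4.0, t_g2=4.0, frac_arrested=0.05)
    uv = replace(hl, s_onset_clock=18.0)
    ll = SimParams(
        s_onset_clock=15.0, t_s=4.1, t_g2=3.9, frac_arrested=0.46, sigma_sync=1.2
    )
    return {
        "HL": Scenario("HL", hl_sched, hl),
        "HL+UV": Scenario("HL+UV", uv_sched, uv),
        "LL": Scenario("LL", ll_sched, ll),
    }


def simulate_scenario(
    scenario: Scenario,
    sample_times: Optional[Sequence[float]] = None,
    n_days: int = 2,
    instrument: Optional[InstrumentModel] = None,
    n_events: int = 100_000,
    seed: Optional[int] = None,
):
    """Run a scenario end to end: population, truth, counts and event samples.

    ``seed`` overrides ``scenario.params.seed`` when given; the measurement
    stream is seeded independently of the population stream via a
    ``SeedSequence`` spawn so that changing ``n_events`` does not perturb the
    population.
    """
    instrument = instrument or InstrumentModel()
    base_seed = scenario.params.seed if seed is None else seed
    pop_ss, meas_ss = np.random.SeedSequence(base_seed).spawn(2)
    pop_seed = int(pop_ss.generate_state(1)[0] % (2**31))
    params = replace(scenario.params, seed=pop_seed)
    result = simulate_population(
        params, scenario.schedule, sample_times=sample_times, n_days=n_days
    )
    meas_rng = np.random.default_rng(meas_ss)
    samples = [
        measure_events(s, instrument, n_events, meas_rng, condition=scenario.name)
        for s in result.snapshots
    ]
    result.truth.condition = scenario.name
    return result, samples
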