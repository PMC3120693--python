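"""Delayed stochastic simulation algorithm (delayed SSA).

An extension of Gillespie's SSA in which selected reaction products appear
only after a (possibly random) delay.  Delayed releases are kept on a
time-ordered waiting list; each event loop iteration either fires the next
SSA reaction or, if a queued release comes first, releases it.  The algorithm:

1. Set ``t = 0``, read the initial copy numbers and reactions, start with an
   empty waiting list.
2. Draw the next candidate reaction ``R1`` and its waiting time ``t1`` by a
   standard SSA step.
3. If ``t + t1`` precedes the earliest queued release, advance to ``t + t1``
   and perform ``R1``, queuing its delayed products.
4. Otherwise advance to the earliest release time and release that product
   (the drawn candidate is discarded; the exponential clock is memoryless).
5. Repeat while ``t < t_stop``.

Ties (``t + t1`` equal to the head release time) are resolved in favour of
the release; equal release times are served in insertion order.

Two execution paths exist: :func:`advance_one_event` is a straightforward
single-step reference in plain Python, and :func:`run_simulation` runs whole
trajectories through a numba-compiled kernel.  They consume different random
streams, so trajectories are not event-for-event identical across paths, but
both implement the same law and each path is deterministic for a fixed seed.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional

import numpy as np

from ._kernel import STATUS_NEGATIVE_COUNT, run_core
from .errors import ParameterError

__all__ = [
    "DelayKind",
    "DelaySpec",
    "Reaction",
    "ReactionSystem",
    "PendingRelease",
    "SimulationState",
    "SimResult",
    "sample_delay",
    "sample_delays",
    "advance_one_event",
    "run_simulation",
]


class DelayKind(str, Enum):
    ZERO = "zero"
    CONSTANT = "constant"
    GAMMA = "gamma"


@dataclass(frozen=True)
class DelaySpec:
    """Delay attached to a reaction product.

    ``zero`` products appear when the reaction fires; ``constant`` products a
    fixed number of seconds later; ``gamma`` products after a gamma-distributed
    time parameterised by its mean and standard deviation (moment matching:
    shape ``(mean/sd)**2``, scale ``sd**2/mean``).  The gamma is the natural
    waiting-time model for a multi-step process such as promoter open-complex
    formation, and the moment-matched shape may be far below 1 (a very
    fat-tailed distribution); sampling goes through numpy's gamma generator,
    which is valid in that regime.
    """

    kind: DelayKind = DelayKind.ZERO
    mean: float = 0.0
    sd: float = 0.0

    def __post_init__(self):
        kind = DelayKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if self.mean < 0 or self.sd < 0:
            raise ParameterError("delay mean and sd must be non-negative")
        if kind is DelayKind.ZERO and (self.mean != 0 or self.sd != 0):
            raise ParameterError("zero delay requires mean = sd = 0")
        if kind is DelayKind.CONSTANT and self.sd != 0:
            raise ParameterError("constant delay requires sd = 0")
        if kind is DelayKind.GAMMA and (self.mean <= 0 or self.sd <= 0):
            raise ParameterError("gamma delay requires mean > 0 and sd > 0")

    @classmethod
    def zero(cls) -> "DelaySpec":
        return cls(DelayKind.ZERO, 0.0, 0.0)

    @classmethod
    def constant(cls, mean: float) -> "DelaySpec":
        return cls(DelayKind.CONSTANT, float(mean), 0.0)

    @classmethod
    def gamma(cls, mean: float, sd: float) -> "DelaySpec":
        return cls(DelayKind.GAMMA, float(mean), float(sd))

    @property
    def gamma_shape_scale(self) -> tuple[float, float]:
        if self.kind is not DelayKind.GAMMA:
            raise ParameterError("shape/scale defined only for gamma delays")
        shape = (self.mean / self.sd) ** 2
        scale = self.sd ** 2 / self.mean
        return shape, scale


def sample_delay(spec: DelaySpec, rng: np.random.Generator) -> float:
    """Draw one delay (seconds, >= 0) from the spec's distribution."""
    if spec.kind is DelayKind.ZERO:
        return 0.0
    if spec.kind is DelayKind.CONSTANT:
        return spec.mean
    shape, scale = spec.gamma_shape_scale
    return float(rng.gamma(shape, scale))


def sample_delays(spec: DelaySpec, rng: np.random.Generator, size: int) -> np.ndarray:
    """Vectorised :func:`sample_delay`."""
    if spec.kind is DelayKind.ZERO:
        return np.zeros(size)
    if spec.kind is DelayKind.CONSTANT:
        return np.full(size, spec.mean)
    shape, scale = spec.gamma_shape_scale
    return rng.gamma(shape, scale, size=size)


@dataclass(frozen=True)
class Reaction:
    """Mass-action reaction, at most second order, with per-product delays.

    ``reactants`` is a sequence of ``(species, stoichiometry)``; ``products``
    of ``(species, stoichiometry, DelaySpec)``.  The propensity is the rate
    constant times the combinatorial count of reactant tuples
    (``x`` for stoichiometry 1, ``x (x - 1) / 2`` for 2).
    """

    reactants: tuple
    products: tuple
    rate_constant: float
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "reactants",
                           tuple((str(s), int(n)) for s, n in self.reactants))
        prods = []
        for entry in self.products:
            s, n, d = entry
            if not isinstance(d, DelaySpec):
                raise ParameterError("product delay must be a DelaySpec")
            prods.append((str(s), int(n), d))
        object.__setattr__(self, "products", tuple(prods))
        if self.rate_constant <= 0:
            raise ParameterError("rate constant must be positive")
        if any(n < 1 for _, n in self.reactants):
            raise ParameterError("reactant stoichiometry must be >= 1")
        if any(n < 1 for _, n, _ in self.products):
            raise ParameterError("product stoichiometry must be >= 1")
        if sum(n for _, n in self.reactants) > 2:
            raise ParameterError("reactions are at most second order")


@dataclass(frozen=True)
class ReactionSystem:
    species: tuple
    reactions: tuple
    initial_counts: Mapping[str, int]

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(str(s) for s in self.species))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        known = set(self.species)
        for rxn in self.reactions:
            for s, _ in rxn.reactants:
                if s not in known:
                    raise ParameterError(f"unknown reactant species {s!r}")
            for s, _, _ in rxn.products:
                if s not in known:
                    raise ParameterError(f"unknown product species {s!r}")
        counts = {s: int(self.initial_counts.get(s, 0)) for s in self.species}
        if any(c < 0 for c in counts.values()):
            raise ParameterError("initial counts must be non-negative")
        object.__setattr__(self, "initial_counts", counts)

    def species_index(self) -> dict:
        return {s: i for i, s in enumerate(self.species)}

    def to_arrays(self):
        """Flat array encoding consumed by the compiled kernel."""
        idx = self.species_index()
        n_r = len(self.reactions)
        re_idx = np.full((n_r, 2), -1, dtype=np.int64)
        re_sto = np.zeros((n_r, 2), dtype=np.int64)
        rates = np.empty(n_r)
        p_start = np.zeros(n_r, dtype=np.int64)
        p_count = np.zeros(n_r, dtype=np.int64)
        p_species, p_sto, d_kind, d_p1, d_p2 = [], [], [], [], []
        for r, rxn in enumerate(self.reactions):
            for k, (s, n) in enumerate(rxn.reactants):
                re_idx[r, k] = idx[s]
                re_sto[r, k] = n
            rates[r] = rxn.rate_constant
            p_start[r] = len(p_species)
            p_count[r] = len(rxn.products)
            for s, n, d in rxn.products:
                p_species.append(idx[s])
                p_sto.append(n)
                if d.kind is DelayKind.ZERO:
                    d_kind.append(0); d_p1.append(0.0); d_p2.append(0.0)
                elif d.kind is DelayKind.CONSTANT:
                    d_kind.append(1); d_p1.append(d.mean); d_p2.append(0.0)
                else:
                    shape, scale = d.gamma_shape_scale
                    d_kind.append(2); d_p1.append(shape); d_p2.append(scale)
        init = np.array([self.initial_counts[s] for s in self.species],
                        dtype=np.int64)
        return (re_idx, re_sto, rates,
                p_start, p_count,
                np.array(p_species, dtype=np.int64),
                np.array(p_sto, dtype=np.int64),
                np.array(d_kind, dtype=np.int64),
                np.array(d_p1), np.array(d_p2), init)


@dataclass(order=True)
class PendingRelease:
    """One queued delayed product (an element of the waiting list)."""
    release_time: float
    seq: int
    species: str = field(compare=False)
    count: int = field(compare=False, default=1)


@dataclass
class SimulationState:
    """Mutable state threaded through :func:`advance_one_event`."""
    time: float
    counts: dict
    waitlist: list          # heap of PendingRelease
    rng: np.random.Generator
    t_stop: float
    n_events: int = 0
    _seq: int = 0

    @classmethod
    def initial(cls, system: ReactionSystem, t_stop: float, seed) -> "SimulationState":
        return cls(time=0.0, counts=dict(system.initial_counts), waitlist=[],
                   rng=np.random.default_rng(seed), t_stop=float(t_stop))

    def enqueue(self, release_time: float, species: str, count: int = 1) -> None:
        heapq.heappush(self.waitlist,
                       PendingRelease(release_time, self._seq, species, count))
        self._seq += 1


def _propensity(rxn: Reaction, counts: Mapping[str, int]) -> float:
    a = rxn.rate_constant
    for s, n in rxn.reactants:
        x = counts[s]
        a *= x if n == 1 else x * (x - 1) / 2.0
    return a


def advance_one_event(state: SimulationState, system: ReactionSystem) -> SimulationState:
    """Advance the simulation by a single event (reference implementation).

    Performs one SSA draw and either fires the drawn reaction or releases the
    waiting-list head, whichever comes first (release wins ties).  With zero
    total propensity and an empty list, time jumps to ``t_stop``.
    """
    if state.time >= state.t_stop:
        raise ParameterError("simulation already at t_stop")
    props = [_propensity(r, state.counts) for r in system.reactions]
    a0 = sum(props)
    t_min = state.waitlist[0].release_time if state.waitlist else math.inf

    if a0 <= 0.0:
        t_event, fire = t_min, False
    else:
        t1 = state.rng.exponential(1.0 / a0)
        if state.time + t1 < t_min:
            t_event, fire = state.time + t1, True
        else:
            t_event, fire = t_min, False

    if t_event > state.t_stop:
        state.time = state.t_stop
        return state

    state.time = t_event
    if fire:
        u = state.rng.random() * a0
        acc = 0.0
        r1 = system.reactions[-1]
        for rxn, p in zip(system.reactions, props):
            acc += p
            if u < acc:
                r1 = rxn
                break
        for s, n in r1.reactants:
            state.counts[s] -= n
            if state.counts[s] < 0:
                raise RuntimeError(f"negative copy number for {s!r}")
        for s, n, d in r1.products:
            if d.kind is DelayKind.ZERO:
                state.counts[s] += n
            else:
                state.enqueue(t_event + sample_delay(d, state.rng), s, n)
    else:
        head = heapq.heappop(state.waitlist)
        state.counts[head.species] += head.count
    state.n_events += 1
    return state


@dataclass
class SimResult:
    """Trajectory endpoint and optional sampled time series.

    ``sampled_pending`` mirrors ``sampled_counts`` for copies still on the
    waiting list, letting conservation (free + pending) be audited.
    """
    t_stop: float
    final_counts: dict
    species: tuple
    n_events: int
    sample_times: Optional[np.ndarray] = None
    sampled_counts: Optional[np.ndarray] = None
    sampled_pending: Optional[np.ndarray] = None

    def series(self, species: str) -> np.ndarray:
        if self.sampled_counts is None:
            raise ParameterError("simulation was run without sampling")
        return self.sampled_counts[:, self.species.index(species)]

    def to_frame(self):
        import pandas as pd
        if self.sampled_counts is None:
            raise ParameterError("simulation was run without sampling")
        df = pd.DataFrame(self.sampled_counts, columns=list(self.species))
        df.insert(0, "time", self.sample_times)
        return df


def _normalize_seed(seed) -> int:
    if isinstance(seed, (int, np.integer)):
        if seed < 0:
            raise ParameterError("seed must be non-negative")
        return int(seed) % (2 ** 32)
    return int(np.random.SeedSequence(seed).generate_state(1)[0])


def run_simulation(system: ReactionSystem, t_stop: float, seed,
                   sampling: Optional[float] = None,
                   engine: str = "numba") -> SimResult:
    """Simulate from t = 0 to ``t_stop``.

    Parameters
    ----------
    sampling : float, optional
        If given, record counts every ``sampling`` seconds (left-limit state
        at each sample time), including t = 0 and ``t_stop``.
    engine : {"numba", "python"}
        Compiled kernel (default) or the plain-Python reference loop.
    """
    if t_stop < 0:
        raise ParameterError("t_stop must be non-negative")
    if sampling is not None:
        if sampling <= 0:
            raise ParameterError("sampling interval must be positive")
        sample_times = np.arange(0.0, t_stop + sampling / 2, sampling)
    else:
        sample_times = np.empty(0)

    if engine == "numba":
        arrays = system.to_arrays()
        final, samp, samp_pend, n_events, status = run_core(
            *arrays[:10], arrays[10], float(t_stop), sample_times,
            _normalize_seed(seed))
        if status == STATUS_NEGATIVE_COUNT:
            raise RuntimeError("negative copy number encountered")
        final_counts = {s: int(final[i]) for i, s in enumerate(system.species)}
    elif engine == "python":
        state = SimulationState.initial(system, t_stop, seed)
        n_sp = len(system.species)
        samp = np.zeros((len(sample_times), n_sp), dtype=np.int64)
        samp_pend = np.zeros((len(sample_times), n_sp), dtype=np.int64)
        si = 0
        while state.time < t_stop:
            t_before = dict(state.counts)
            pend_before = _pending_totals(state, system)
            prev_time = state.time
            advance_one_event(state, system)
            while si < len(sample_times) and prev_time <= sample_times[si] < state.time:
                for i, s in enumerate(system.species):
                    samp[si, i] = t_before[s]
                    samp_pend[si, i] = pend_before[s]
                si += 1
        while si < len(sample_times):
            for i, s in enumerate(system.species):
                samp[si, i] = state.counts[s]
                samp_pend[si, i] = _pending_totals(state, system)[s]
            si += 1
        final_counts = dict(state.counts)
        n_events = state.n_events
    else:
        raise ParameterError(f"unknown engine {engine!r}")

    return SimResult(
        t_stop=float(t_stop), final_counts=final_counts, species=system.species,
        n_events=int(n_events),
        sample_times=sample_times if sampling is not None else None,
        sampled_counts=samp if sampling is not None else None,
        sampled_pending=samp_pend if sampling is not None else None)


def _pending_totals(state: SimulationState, system: ReactionSystem) -> dict:
    totals = {s: 0 for s in system.species}
    for item in state.waitlist:
        totals[item.species] += item.count
    return totals
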