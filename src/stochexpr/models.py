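"""Delayed stochastic models of a tet-inducible gene expressing GFP.

The gene is modelled by four mass-action reactions with delayed products
(``X(tau)`` means X appears tau seconds after the reaction fires):

    1. Pro --k1--> Pro(tau1) + RBS(tau2)     transcription
    2. RBS --k2--> RBS + P(tau3)             translation
    3. RBS --k3--> 0                         RNA degradation
    4. P   --k4--> 0                         protein degradation

``Pro`` is the promoter, sequestered for ``tau1`` seconds after each
initiation while the open complex forms; ``RBS`` is the ribosome binding
site region of the transcript (the species ribosomes see, and what the
MS2-GFP assay counts); ``P`` is a GFP molecule.  Induction by
anhydrotetracycline (aTc) enters only through the initiation rate ``k1``:
aTc titrates the TetR repressor away from the promoter, and the model
absorbs the whole binding equilibrium into a per-condition ``k1`` tuned to
match mean expression.

Two model variants differ only in the law of ``tau1``:

* variant 1 — constant 19 s (the open complex takes the same time on every
  initiation);
* variant 2 — gamma-distributed with mean 19 s and a configurable standard
  deviation (default 400 s), a very fat-tailed distribution under which most
  initiations are nearly back-to-back while a few are separated by very long
  intervals.

Because the network is feedback-free, the stationary means have a closed
form used as an independent oracle: initiations form a renewal process with
mean interval ``1/k1 + E[tau1]``, so

    E[RNA] = (1/k1 + E[tau1])^-1 / k3,   E[P] = E[RNA] * k2 / k4.

The printed single-cell measurement summary (population size, mean/SD of
total GFP fluorescence per cell in arbitrary units, relative mean, Fano
factor) for the five aTc conditions is kept here as
``MEASURED_GFP_SUMMARY``; it is the fixed experimental input to the
calibration and model-fitting steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .delayed_ssa import (DelaySpec, Reaction, ReactionSystem, run_simulation,
                          sample_delays)
from .errors import ParameterError

__all__ = [
    "K2", "K3", "K4", "TAU1_MEAN", "TAU1_SD_DEFAULT", "TAU2", "TAU3",
    "ATC_CONDITIONS", "MEASURED_GFP_SUMMARY", "ModelParams",
    "gamma_moment_match", "build_model", "steady_state_oracle",
    "PopulationSample", "simulate_population", "cell_seed",
]

K2 = 0.19       # s^-1, translation (ribosome availability, RBS:P ~ 1:1000)
K3 = 0.004      # s^-1, RNA degradation
K4 = 0.0002     # s^-1, protein degradation (intermediate-lifetime GFP(AAV))
TAU1_MEAN = 19.0        # s, mean open-complex duration
TAU1_SD_DEFAULT = 400.0  # s, variant-2 default SD of the open-complex duration
TAU2 = 2.0      # s, delay until the nascent RBS is available
TAU3 = 420.0    # s, transcript+protein completion incl. GFP maturation

#: Induction conditions: aTc concentration (ng/ml) -> initiation rate k1 (s^-1),
#: tuned to match the measured mean expression at each concentration.
ATC_CONDITIONS = (
    (0.0, 1.5e-4),
    (0.1, 4.3e-4),
    (0.5, 1.4e-3),
    (1.0, 6.5e-3),
    (2.0, 2.8e-2),
)

#: Measured single-cell GFP summary per aTc condition (fluorescence, a.u.).
MEASURED_GFP_SUMMARY = pd.DataFrame(
    {
        "atc_ng_ml": [0.0, 0.1, 0.5, 1.0, 2.0],
        "n_cells": [245, 225, 88, 203, 299],
        "mean": [1841.54, 5526.12, 16948.61, 73338.24, 231836.5],
        "sd": [2414.88, 3901.75, 8781.03, 33388.72, 105391.2],
        "relative_mean": [0.01, 0.02, 0.07, 0.32, 1.0],
        "fano": [3166.72, 2754.85, 4549.43, 15200.89, 47909.94],
    }
)


def gamma_moment_match(mean: float, sd: float) -> tuple[float, float]:
    """Shape and scale of the gamma distribution with the given mean and SD.

    ``shape = (mean/sd)**2``, ``scale = sd**2/mean``; the moments round-trip
    exactly.  For the default open-complex delay (mean 19 s, SD 400 s) the
    shape is ~2.26e-3, i.e. far below 1.
    """
    if mean <= 0 or sd <= 0:
        raise ParameterError("gamma moment matching requires mean > 0 and sd > 0")
    return (mean / sd) ** 2, sd ** 2 / mean


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of one model variant at one induction level."""

    k1: float
    variant: int = 1
    tau1_mean: float = TAU1_MEAN
    tau1_sd: float = TAU1_SD_DEFAULT
    k2: float = K2
    k3: float = K3
    k4: float = K4
    tau2: float = TAU2
    tau3: float = TAU3

    def __post_init__(self):
        if min(self.k1, self.k2, self.k3, self.k4) <= 0:
            raise ParameterError("all rate constants must be positive")
        if self.variant not in (1, 2):
            raise ParameterError("variant must be 1 or 2")
        if self.tau1_mean <= 0:
            raise ParameterError("tau1 mean must be positive")
        if self.variant == 2 and self.tau1_sd <= 0:
            raise ParameterError("variant 2 requires tau1_sd > 0")

    @property
    def tau1(self) -> DelaySpec:
        if self.variant == 1:
            return DelaySpec.constant(self.tau1_mean)
        return DelaySpec.gamma(self.tau1_mean, self.tau1_sd)


def build_model(k1: float, variant: int = 1,
                tau1_sd: float = TAU1_SD_DEFAULT, *,
                params: Optional[ModelParams] = None) -> ReactionSystem:
    """Assemble the four-reaction system (initial state: Pro=1, RBS=0, P=0)."""
    p = params if params is not None else ModelParams(k1=k1, variant=variant,
                                                      tau1_sd=tau1_sd)
    reactions = (
        Reaction(reactants=(("Pro", 1),),
                 products=(("Pro", 1, p.tau1),
                           ("RBS", 1, DelaySpec.constant(p.tau2))),
                 rate_constant=p.k1, name="transcription"),
        Reaction(reactants=(("RBS", 1),),
                 products=(("RBS", 1, DelaySpec.zero()),
                           ("P", 1, DelaySpec.constant(p.tau3))),
                 rate_constant=p.k2, name="translation"),
        Reaction(reactants=(("RBS", 1),), products=(),
                 rate_constant=p.k3, name="rna_degradation"),
        Reaction(reactants=(("P", 1),), products=(),
                 rate_constant=p.k4, name="protein_degradation"),
    )
    return ReactionSystem(species=("Pro", "RBS", "P"), reactions=reactions,
                          initial_counts={"Pro": 1})


def steady_state_oracle(params: ModelParams) -> tuple[float, float]:
    """Closed-form stationary means (RNA, protein).

    Initiations are a renewal process with mean interval ``1/k1 + E[tau1]``
    (the promoter must both escape repression and complete the open complex),
    so only the delay's mean enters — the oracle holds for both variants.
    """
    rate = 1.0 / (1.0 / params.k1 + params.tau1_mean)
    mean_rna = rate / params.k3
    return mean_rna, mean_rna * params.k2 / params.k4


def cell_seed(master_seed, cell_index: int) -> int:
    """Per-cell kernel seed: one seedable stream per simulated cell."""
    return int(np.random.SeedSequence((master_seed, cell_index)).generate_state(1)[0])


@dataclass
class PopulationSample:
    """Per-cell molecule counts for one condition of one model variant."""

    condition: str
    rna: np.ndarray          # RBS copies per cell
    protein: np.ndarray      # P copies per cell
    t_sample: float
    master_seed: int
    params: ModelParams = field(repr=False, default=None)

    @property
    def n_cells(self) -> int:
        return len(self.protein)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": np.arange(self.n_cells),
            "condition": self.condition,
            "rna_count": self.rna,
            "protein_count": self.protein,
            "seed": [cell_seed(self.master_seed, i) for i in range(self.n_cells)],
        })


def _simulate_cell_direct(params: ModelParams, t_sample: float,
                          rng: np.random.Generator) -> tuple[int, int]:
    """Exact direct sampling of (RNA, protein) at ``t_sample`` for one cell.

    The network has no feedback, so its state at a fixed time can be sampled
    without an event loop: transcription initiations form a renewal process
    with interval ``Exp(1/k1) + tau1`` (the promoter is sequestered for
    ``tau1`` after each initiation); each transcript appears ``tau2`` later
    and lives ``Exp(1/k3)``; translations are a Poisson process of rate
    ``k2`` over the transcript's lifetime, each yielding a protein ``tau3``
    later that survives to ``t_sample`` with probability
    ``exp(-k4 (t_sample - appearance))``.  Products still inside their delay
    at ``t_sample`` are not counted, matching the event-loop engine.  The
    sampler draws from exactly the same law as the delayed SSA and is used
    where grid scans make whole-trajectory simulation needlessly expensive.
    """
    T = t_sample
    tau1 = params.tau1
    # Initiation times S_i: S_1 = e_1, S_i = S_{i-1} + tau_{i-1} + e_i, drawn
    # in blocks; with e + tau summed first, S = cumsum(e + tau) - tau.
    block = max(16, int(1.3 * T / (1.0 / params.k1 + params.tau1_mean)) + 16)
    e_parts, tau_parts, consumed = [], [], 0.0
    while True:
        e = rng.exponential(1.0 / params.k1, size=block)
        tau = sample_delays(tau1, rng, block)
        e_parts.append(e)
        tau_parts.append(tau)
        consumed += float(np.sum(e + tau))
        if consumed > T:
            break
        block *= 2
    e = np.concatenate(e_parts)
    tau = np.concatenate(tau_parts)
    s = np.cumsum(e + tau) - tau
    s = s[s <= T]
    if s.size == 0:
        return 0, 0
    appear = s + params.tau2
    appear = appear[appear <= T]
    if appear.size == 0:
        return 0, 0
    death = appear + rng.exponential(1.0 / params.k3, size=appear.size)
    n_rna = int(np.count_nonzero(death > T))

    # Translation windows clipped so the protein (born tau3 later) exists by T.
    win_hi = np.minimum(death, T - params.tau3)
    lengths = np.clip(win_hi - appear, 0.0, None)
    n_tr = rng.poisson(params.k2 * lengths)
    total = int(n_tr.sum())
    if total == 0:
        return n_rna, 0
    lo = np.repeat(appear, n_tr)
    hi = np.repeat(win_hi, n_tr)
    u = lo + (hi - lo) * rng.random(total)
    born = u + params.tau3
    alive = rng.random(total) < np.exp(-params.k4 * (T - born))
    return n_rna, int(np.count_nonzero(alive))


def simulate_population(params: ModelParams, n_cells: int, t_sample: float,
                        master_seed, condition: Optional[str] = None,
                        engine: str = "numba") -> PopulationSample:
    """Simulate ``n_cells`` independent cells and sample each at ``t_sample``.

    Every cell starts from Pro=1, RBS=0, P=0 and runs its own random stream
    derived from ``(master_seed, cell_index)``, so populations are
    reproducible and independent of execution order.  The default sampling
    time used throughout the package is 25 000 s (five protein lifetimes,
    quasi-steady state).

    ``engine="numba"`` (default) and ``"python"`` run the delayed-SSA event
    loop; ``"direct"`` uses the exact no-event-loop sampler
    (:func:`_simulate_cell_direct`), distribution-identical and much faster
    for parameter scans.
    """
    if n_cells < 0:
        raise ParameterError("n_cells must be non-negative")
    if t_sample < 0:
        raise ParameterError("t_sample must be non-negative")
    rna = np.zeros(n_cells, dtype=np.int64)
    protein = np.zeros(n_cells, dtype=np.int64)
    if engine == "direct":
        for i in range(n_cells):
            rng = np.random.default_rng(cell_seed(master_seed, i))
            rna[i], protein[i] = _simulate_cell_direct(params, t_sample, rng)
    else:
        system = build_model(params.k1, params.variant, params.tau1_sd,
                             params=params)
        for i in range(n_cells):
            res = run_simulation(system, t_sample, cell_seed(master_seed, i),
                                 engine=engine)
            rna[i] = res.final_counts["RBS"]
            protein[i] = res.final_counts["P"]
    label = condition if condition is not None else f"k1={params.k1:g}"
    return PopulationSample(condition=label, rna=rna, protein=protein,
                            t_sample=float(t_sample),
                            master_seed=int(np.asarray(master_seed).item())
                            if np.isscalar(master_seed) else master_seed,
                            params=params)
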