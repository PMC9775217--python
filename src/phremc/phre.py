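"""pH replica-exchange (pHRE) driver.

``n`` replicas run in parallel, each owning one pH value from an ordered
ladder; adjacent replicas periodically attempt to exchange pH values with
the Metropolis probability

    p = min(1, 10**((pH_m - pH_l) * (N_i - N_j)))

where ``x_i`` is the state currently at ``pH_m`` and ``N`` the bound-proton
count.  In gradient mode the interior bath pH is fixed (physiological, 7.2
by default) and only the exterior pH exchanges; interior-bath protons then
cancel exactly from the acceptance ratio, so ``N`` counts exterior-bath
protons only.

Conformational sampling is delegated to a pluggable propagator (the
:class:`Propagator` contract); each cycle interleaves a protonation MC
update, a short relaxation advance, and a production advance, with
exchange attempts phased halfway through the production segment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Protocol, Sequence

import numpy as np

from .mc import MCSettings, _CompiledSystem
from .titration import (
    BATH_OUT,
    BathAssignment,
    EnergyTerms,
    GradientSpec,
    Microstate,
    TitratableSite,
)

log = logging.getLogger(__name__)

__all__ = [
    "Schedule",
    "PHLadder",
    "ReplicaRecord",
    "Propagator",
    "TitrationSystem",
    "FixedConformationSystem",
    "FrozenPropagator",
    "exchange_probability",
    "attempt_exchanges",
    "run_phre",
]


class Propagator(Protocol):
    """Markovian conformational propagator.

    ``advance`` must, for a fixed microstate, preserve its declared
    conformational distribution.  ``initial`` supplies a starting
    conformation for a replica.
    """

    def initial(self, rng: np.random.Generator) -> Any: ...

    def advance(
        self, conformation: Any, microstate: Microstate, n_steps: int,
        rng: np.random.Generator,
    ) -> Any: ...

    def summary(self, conformation: Any) -> float:
        """Scalar summary of the conformation (tagged-group z, Angstrom)."""
        ...


class TitrationSystem(Protocol):
    """Titratable system whose energy terms may depend on the conformation."""

    @property
    def sites(self) -> list[TitratableSite]: ...

    def terms_for(self, conformation: Any) -> EnergyTerms: ...


@dataclass
class FixedConformationSystem:
    """A system whose energy terms do not depend on the conformation."""

    _sites: list[TitratableSite]
    terms: EnergyTerms

    @property
    def sites(self) -> list[TitratableSite]:
        return self._sites

    def terms_for(self, conformation: Any) -> EnergyTerms:
        return self.terms


class FrozenPropagator:
    """Trivial propagator: the conformation never changes."""

    def __init__(self, conformation: float = 0.0):
        self.conformation = conformation

    def initial(self, rng: np.random.Generator) -> float:
        return self.conformation

    def advance(self, conformation, microstate, n_steps, rng):
        return conformation

    def summary(self, conformation) -> float:
        return float(conformation)


@dataclass(frozen=True)
class Schedule:
    """Cycle structure of a pHRE run.

    ``tau_prot`` production propagator steps per cycle, ``tau_rlx``
    relaxation steps after each protonation update, and an exchange attempt
    every ``exchange_every`` cycles, phased halfway through the production
    segment.  ``mc_cycles_per_update`` is the length of the protonation MC
    chain run at each cycle.  The first ``burn_in_fraction`` of cycles is
    discarded from the emitted records.
    """

    n_cycles: int = 1000
    n_replicates: int = 1
    tau_prot: int = 20
    tau_rlx: int = 2
    exchange_every: int = 1
    mc_cycles_per_update: int = 50
    burn_in_fraction: float = 0.5

    def __post_init__(self) -> None:
        if min(self.n_cycles, self.n_replicates, self.tau_prot,
               self.exchange_every, self.mc_cycles_per_update) < 1:
            raise ValueError("schedule counts must be positive")
        if self.tau_rlx < 0:
            raise ValueError("tau_rlx must be >= 0")
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must be in [0, 1)")


@dataclass(frozen=True)
class PHLadder:
    """Ordered pH ladder; in gradient mode these are exterior (pH_out) values.

    In gradient mode the interior pH is held fixed at ``pH_in`` while the
    ladder values are exterior pH values.  ``pH_in=None`` in gradient mode
    makes the interior pH track the exterior one (a zero-gradient setup
    that must reproduce the nongradient run exactly).
    """

    values: tuple[float, ...] = (4.0, 5.0, 6.0, 7.0)
    gradient_mode: bool = False
    pH_in: float | None = 7.2

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(self.values))
        if len(self.values) < 2:
            raise ValueError("ladder needs at least 2 pH values")
        if any(b <= a for a, b in zip(self.values, self.values[1:])):
            raise ValueError("ladder must be strictly increasing")

    @property
    def fixed_interior(self) -> bool:
        """True when the interior bath pH does not follow the exchanged pH."""
        return self.gradient_mode and self.pH_in is not None

    def gradient_at(self, pH: float) -> GradientSpec:
        if self.fixed_interior:
            return GradientSpec(pH_in=self.pH_in, pH_out=pH)
        return GradientSpec(pH_in=pH, pH_out=pH)


@dataclass
class ReplicaRecord:
    """One post-burn-in sample: replica state at the end of a cycle."""

    replicate_id: int
    cycle: int
    pH: float  # ladder pH (pH_out in gradient mode)
    z: float  # tagged-group position along the membrane normal
    microstate: Microstate
    protonated: dict[str, int]  # binary occupancy per site


def exchange_probability(pH_m: float, pH_l: float, N_i: int, N_j: int) -> float:
    """Metropolis probability of swapping states between two pH values.

    ``x_i`` (with ``N_i`` bound protons) currently sits at ``pH_m`` and
    ``x_j`` at ``pH_l``; the semi-grand weight ratio of the swapped to the
    unswapped pair gives ``min(1, 10**((pH_m - pH_l)(N_i - N_j)))``.
    """
    if N_i < 0 or N_j < 0:
        raise ValueError("proton counts must be >= 0")
    e = (pH_m - pH_l) * (N_i - N_j)
    return 1.0 if e >= 0 else 10.0**e


class _Replica:
    """Internal mutable replica state inside run_phre."""

    __slots__ = ("pH", "conformation", "state", "comp")

    def __init__(self, pH, conformation, state, comp):
        self.pH = pH
        self.conformation = conformation
        self.state = state
        self.comp = comp


def attempt_exchanges(
    replicas: Sequence, parity: int, rng: np.random.Generator,
    exchange_proton_counts: Sequence[int],
) -> list[tuple[int, int, float, bool]]:
    """Attempt pH swaps between adjacent replicas of the given parity.

    ``replicas`` must be ordered by ladder position and expose a mutable
    ``pH`` attribute; ``exchange_proton_counts[k]`` is the proton count
    entering the acceptance ratio for replica ``k`` (total protons, or
    exterior-bath protons in gradient mode).  On acceptance the two pH
    labels are swapped (equivalent to swapping conformation+protonation).
    Returns a log of ``(k, k+1, probability, accepted)`` tuples.
    """
    swaps: list[tuple[int, int, float, bool]] = []
    for k in range(parity % 2, len(replicas) - 1, 2):
        a, b = replicas[k], replicas[k + 1]
        # x_i is the state at the higher pH of the pair
        if a.pH >= b.pH:
            p = exchange_probability(
                a.pH, b.pH, exchange_proton_counts[k], exchange_proton_counts[k + 1]
            )
        else:
            p = exchange_probability(
                b.pH, a.pH, exchange_proton_counts[k + 1], exchange_proton_counts[k]
            )
        accepted = bool(p >= 1.0 or rng.random() < p)
        if accepted:
            a.pH, b.pH = b.pH, a.pH
        swaps.append((k, k + 1, p, accepted))
    return swaps


def _exchange_count(comp: _CompiledSystem, state: list[int], out_only: bool) -> int:
    """Proton count entering the exchange ratio.

    Only sites whose bath pH actually changes on a swap contribute: under a
    fixed-interior gradient that is the exterior-bath sites (the identical
    interior terms cancel exactly from the ratio); otherwise all sites.
    """
    n = 0
    for i, t in enumerate(state):
        if out_only and comp.bath[i] != BATH_OUT:
            continue
        n += comp.nprot[i][t]
    return n


def run_phre(
    system: TitrationSystem,
    propagator: Propagator,
    ladder: PHLadder,
    baths: BathAssignment,
    schedule: Schedule,
    seeds: Sequence[int],
    pair_threshold: float = 2.0,
) -> list[ReplicaRecord]:
    """Run pH replica exchange and return post-burn-in replica records.

    One independent run per replicate seed.  Per cycle and replica:
    protonation MC update at the replica's bath pH(s), a relaxation advance
    of ``tau_rlx`` steps, then the production advance split around the
    exchange attempt.  Records are emitted per replica at the end of each
    post-burn-in cycle; the streams are keyed by ladder pH, not by walker,
    so marginals per pH are directly comparable across cycles.
    """
    if len(seeds) != schedule.n_replicates:
        raise ValueError(
            f"need one seed per replicate ({schedule.n_replicates}), got {len(seeds)}"
        )
    records: list[ReplicaRecord] = []
    burn_in = int(schedule.burn_in_fraction * schedule.n_cycles)
    for rep_id, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        replicas: list[_Replica] = []
        for pH in ladder.values:
            conf = propagator.initial(rng)
            grad = ladder.gradient_at(pH)
            comp = _CompiledSystem(
                system.sites, system.terms_for(conf), baths, grad, pair_threshold
            )
            replicas.append(_Replica(pH, conf, comp.random_state(rng), comp))
        parity = 0
        half = schedule.tau_prot // 2
        for cycle in range(schedule.n_cycles):
            for r in replicas:
                # refresh energy terms for the current conformation and pH
                grad = ladder.gradient_at(r.pH)
                r.comp = _CompiledSystem(
                    system.sites, system.terms_for(r.conformation), baths, grad,
                    pair_threshold,
                )
                for _ in range(schedule.mc_cycles_per_update):
                    r.comp.sweep(r.state, rng)
                x = r.comp.to_microstate(r.state)
                if schedule.tau_rlx:
                    r.conformation = propagator.advance(
                        r.conformation, x, schedule.tau_rlx, rng
                    )
                r.conformation = propagator.advance(r.conformation, x, half, rng)
            if cycle % schedule.exchange_every == 0:
                ordered = sorted(replicas, key=lambda r: r.pH)
                counts = [
                    _exchange_count(r.comp, r.state, ladder.fixed_interior)
                    for r in ordered
                ]
                swaps = attempt_exchanges(ordered, parity, rng, counts)
                parity ^= 1
                for k, kk, p, acc in swaps:
                    log.debug(
                        "rep=%d cycle=%d exchange %d<->%d p=%.3g accepted=%s",
                        rep_id, cycle, k, kk, p, acc,
                    )
            for r in replicas:
                x = r.comp.to_microstate(r.state)
                r.conformation = propagator.advance(
                    r.conformation, x, schedule.tau_prot - half, rng
                )
                if cycle >= burn_in:
                    records.append(
                        ReplicaRecord(
                            replicate_id=rep_id,
                            cycle=cycle,
                            pH=r.pH,
                            z=propagator.summary(r.conformation),
                            microstate=x,
                            protonated={
                                s.site_id: r.comp.is_prot[i][r.state[i]]
                                for i, s in enumerate(system.sites)
                            },
                        )
                    )
    records.sort(key=lambda rec: (rec.replicate_id, rec.pH, rec.cycle))
    return records
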