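"""Domain types for titratable systems under a transmembrane pH gradient.

A titratable site carries one or more tautomers (distinct proton-placement
forms).  A microstate assigns one tautomer to every site; its semi-grand
free energy combines conformation-specific intrinsic terms ``g`` (derived
externally, e.g. from a Poisson-Boltzmann solver), pairwise couplings ``W``,
and a chemical-potential term ``n_protons * pH`` per site, where the pH is
that of the proton bath the site is statically assigned to (inner or outer
monolayer side).

All energies are kept in pK (log10) units throughout: the statistical
weight of microstate ``x`` is ``10**(-G(x))``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

BATH_IN = "in"
BATH_OUT = "out"


@dataclass(frozen=True)
class Tautomer:
    """One proton-placement form of a titratable site."""

    label: str
    n_protons: int

    def __post_init__(self) -> None:
        if self.n_protons < 0:
            raise ValueError(f"n_protons must be >= 0, got {self.n_protons}")


@dataclass(frozen=True)
class TitratableSite:
    """A titratable group: its tautomer inventory and setup geometry.

    ``start_z`` is the position along the membrane normal (Angstrom) at
    setup time; it decides the proton-bath assignment unless
    ``bath_override`` is given.
    """

    site_id: str
    tautomers: tuple[Tautomer, ...]
    start_z: float = 0.0
    bath_override: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "tautomers", tuple(self.tautomers))
        labels = [t.label for t in self.tautomers]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate tautomer labels in site {self.site_id!r}")
        if not any(t.n_protons == 0 for t in self.tautomers):
            raise ValueError(f"site {self.site_id!r} has no deprotonated tautomer")
        if not any(t.n_protons >= 1 for t in self.tautomers):
            raise ValueError(f"site {self.site_id!r} has no protonated tautomer")
        if self.bath_override is not None and self.bath_override not in (BATH_IN, BATH_OUT):
            raise ValueError(f"bath_override must be 'in' or 'out', got {self.bath_override!r}")

    def tautomer(self, label: str) -> Tautomer:
        for t in self.tautomers:
            if t.label == label:
                return t
        raise KeyError(f"site {self.site_id!r} has no tautomer {label!r}")


def _canon_pair(key: tuple[str, str, str, str]) -> tuple[str, str, str, str]:
    i, ti, j, tj = key
    return (i, ti, j, tj) if (i, ti) <= (j, tj) else (j, tj, i, ti)


@dataclass
class EnergyTerms:
    """Conformation-specific energy terms in pK units.

    ``intrinsic`` maps (site_id, tautomer label) -> g, the per-tautomer
    intrinsic term; for a two-form site the intrinsic pK is
    ``pK_int = -g(prot) + g(deprot)``.  ``pairwise`` maps
    (site_i, tau_i, site_j, tau_j) -> W; it is stored symmetrically and
    missing pairs read as zero.
    """

    intrinsic: dict[tuple[str, str], float]
    pairwise: dict[tuple[str, str, str, str], float] = field(default_factory=dict)
    conformation_id: str = ""

    def __post_init__(self) -> None:
        for k, v in self.intrinsic.items():
            if not _finite(v):
                raise ValueError(f"non-finite intrinsic term for {k}: {v}")
        canon: dict[tuple[str, str, str, str], float] = {}
        for k, v in self.pairwise.items():
            if not _finite(v):
                raise ValueError(f"non-finite pairwise term for {k}: {v}")
            ck = _canon_pair(k)
            if ck in canon and canon[ck] != v:
                raise ValueError(f"conflicting pairwise entries for {ck}")
            canon[ck] = v
        self.pairwise = canon

    def g(self, site_id: str, tautomer: str) -> float:
        try:
            return self.intrinsic[(site_id, tautomer)]
        except KeyError:
            raise KeyError(f"no intrinsic term for site {site_id!r} tautomer {tautomer!r}") from None

    def w(self, site_i: str, tau_i: str, site_j: str, tau_j: str) -> float:
        return self.pairwise.get(_canon_pair((site_i, tau_i, site_j, tau_j)), 0.0)


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


@dataclass(frozen=True)
class GradientSpec:
    """Transmembrane pH gradient: bath pH values for the two monolayer sides.

    Convention: ``delta_pH = pH_in - pH_out`` (positive when the interior is
    more basic), and the midpoint pH is ``(pH_in + pH_out) / 2``.
    """

    pH_in: float
    pH_out: float

    @property
    def pH(self) -> float:
        return 0.5 * (self.pH_in + self.pH_out)

    @property
    def delta_pH(self) -> float:
        return self.pH_in - self.pH_out

    def bath_pH(self, bath: str) -> float:
        if bath == BATH_IN:
            return self.pH_in
        if bath == BATH_OUT:
            return self.pH_out
        raise ValueError(f"unknown bath {bath!r}")

    @property
    def is_gradient(self) -> bool:
        return self.pH_in != self.pH_out


def gradient_endpoints(pH: float, delta_pH: float) -> GradientSpec:
    """Build a :class:`GradientSpec` from midpoint pH and gradient magnitude.

    ``pH_in = pH + delta_pH/2`` and ``pH_out = pH - delta_pH/2``, so that
    ``delta_pH = pH_in - pH_out``.
    """
    return GradientSpec(pH_in=pH + 0.5 * delta_pH, pH_out=pH - 0.5 * delta_pH)


@dataclass(frozen=True)
class BathAssignment:
    """Static site -> proton-bath map ('in' or 'out'); total over all sites."""

    baths: Mapping[str, str]

    def __post_init__(self) -> None:
        for sid, b in self.baths.items():
            if b not in (BATH_IN, BATH_OUT):
                raise ValueError(f"site {sid!r} assigned to unknown bath {b!r}")

    def bath(self, site_id: str) -> str:
        try:
            return self.baths[site_id]
        except KeyError:
            raise KeyError(f"site {site_id!r} has no bath assignment") from None

    def __len__(self) -> int:
        return len(self.baths)


def assign_proton_baths(
    sites: Sequence[TitratableSite], membrane_center_z: float
) -> BathAssignment:
    """Assign each site to the inner or outer proton bath by its setup z.

    Sites starting above the membrane center go to the outer bath, sites
    below to the inner bath.  An explicit ``bath_override`` on the site wins
    and is logged.  A site exactly at the center (no override) is assigned
    to the outer bath with a warning.
    """
    if not _finite(membrane_center_z):
        raise ValueError(f"membrane_center_z must be finite, got {membrane_center_z}")
    baths: dict[str, str] = {}
    for s in sites:
        if s.bath_override is not None:
            log.info("site %s: bath override -> %s", s.site_id, s.bath_override)
            baths[s.site_id] = s.bath_override
        elif s.start_z > membrane_center_z:
            baths[s.site_id] = BATH_OUT
        elif s.start_z < membrane_center_z:
            baths[s.site_id] = BATH_IN
        else:
            warnings.warn(
                f"site {s.site_id!r} starts exactly at the membrane center; "
                "assigned to the outer bath",
                stacklevel=2,
            )
            baths[s.site_id] = BATH_OUT
    return BathAssignment(baths)


@dataclass(frozen=True)
class Microstate:
    """One tautomer label per site; ``N`` is the total bound-proton count."""

    assignment: Mapping[str, str]

    def tautomer(self, site_id: str) -> str:
        return self.assignment[site_id]

    def total_protons(self, sites: Sequence[TitratableSite]) -> int:
        return sum(s.tautomer(self.assignment[s.site_id]).n_protons for s in sites)


def microstate_free_energy(
    x: Microstate,
    sites: Sequence[TitratableSite],
    terms: EnergyTerms,
    baths: BathAssignment,
    grad: GradientSpec,
) -> float:
    """Semi-grand free energy of a microstate, in pK units.

    ``G(x) = sum_i [ g_i(tau_i) + n_protons(tau_i) * pH_{b(i)} ]
    + sum_{i<j} W_ij(tau_i, tau_j)``; the statistical weight of ``x`` is
    ``10**(-G(x))``.  For a single two-form site this reduces to the
    Henderson-Hasselbalch protonated fraction
    ``1 / (1 + 10**(pH - pK_int))`` with ``pK_int = -g(prot) + g(deprot)``.
    """
    G = 0.0
    chosen: list[tuple[str, str]] = []
    for s in sites:
        tau = x.assignment.get(s.site_id)
        if tau is None:
            raise KeyError(f"microstate lacks site {s.site_id!r}")
        t = s.tautomer(tau)
        G += terms.g(s.site_id, tau) + t.n_protons * grad.bath_pH(baths.bath(s.site_id))
        chosen.append((s.site_id, tau))
    for a in range(len(chosen)):
        for b in range(a + 1, len(chosen)):
            si, ti = chosen[a]
            sj, tj = chosen[b]
            G += terms.w(si, ti, sj, tj)
    return G


def make_two_form_site(
    site_id: str, pk_int: float, start_z: float = 0.0, bath_override: str | None = None
) -> tuple[TitratableSite, dict[tuple[str, str], float]]:
    """Convenience: a deprotonated/protonated site with intrinsic pK ``pk_int``.

    Returns the site and its intrinsic-term entries (g(deprot)=0,
    g(prot)=-pk_int).
    """
    site = TitratableSite(
        site_id=site_id,
        tautomers=(Tautomer("d", 0), Tautomer("p", 1)),
        start_z=start_z,
        bath_override=bath_override,
    )
    return site, {(site_id, "d"): 0.0, (site_id, "p"): -pk_int}


def sites_by_id(sites: Iterable[TitratableSite]) -> dict[str, TitratableSite]:
    out: dict[str, TitratableSite] = {}
    for s in sites:
        if s.site_id in out:
            raise ValueError(f"duplicate site_id {s.site_id!r}")
        out[s.site_id] = s
    return out
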