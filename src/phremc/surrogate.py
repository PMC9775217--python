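"""Synthetic stand-ins for atomistic constant-pH simulation data.

Three generators:

* a 1D peptide-membrane surrogate whose single key titratable site has a
  burial-dependent intrinsic pK — desolvation raises the pK sigmoidally as
  the group leaves the aqueous phase — together with a Metropolis
  propagator on the insertion coordinate ``z``;
* random interacting titration systems for sampler validation;
* synthetic membrane frames with a controlled Gaussian monolayer
  deformation centered on the peptide, for the geometry analyses.

The surrogate's joint ensemble couples protonation and insertion: the
protonated (neutral) form gains ``pK_int(z)`` of stabilisation when buried,
so it preferentially inserts, while the charged deprotonated form prefers
the aqueous side.  ``analytic_pka_profile`` returns the exact ground-truth
profile the analysis pipeline must recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import LOWER, UPPER, MembraneFrame
from .mc import TitrationResult
from .titration import EnergyTerms, Microstate, TitratableSite, Tautomer

KEY_SITE = "ASP"
PARTNER_SITE = "ARG"


@dataclass(frozen=True)
class SurrogateParams:
    """Ground-truth parameters of the 1D insertion surrogate.

    ``pK_mod``: solution (fully solvated) pK of the key site.
    ``dpK_desolv``: maximal desolvation-induced pK shift (>= 0), reached at
    deep burial.  ``z_mid``/``z_width``: midpoint and width (Angstrom) of
    the logistic burial switch.  ``conf_step``: half-width of the z
    random-walk proposal.  ``well_center``/``well_k``: harmonic
    conformational potential (pK units per Angstrom^2) confining z.
    ``w_partner``: optional coupling (pK units) between the protonated key
    site and a fixed basic partner site.
    """

    pK_mod: float = 5.5
    dpK_desolv: float = 2.0
    z_mid: float = 0.0
    z_width: float = 2.0
    conf_step: float = 1.5
    well_center: float = 0.0
    well_k: float = 0.02
    w_partner: float = 0.0

    def __post_init__(self) -> None:
        if self.z_width <= 0:
            raise ValueError("z_width must be > 0")
        if self.dpK_desolv < 0:
            raise ValueError("dpK_desolv must be >= 0")
        if self.conf_step <= 0 or self.well_k <= 0:
            raise ValueError("conf_step and well_k must be > 0")

    def pk_int(self, z: float) -> float:
        """Intrinsic pK of the key site at insertion z (burial raises it)."""
        u = (self.z_mid - z) / self.z_width
        return self.pK_mod + self.dpK_desolv / (1.0 + math.exp(-u))

    def potential(self, z: float) -> float:
        """Conformational potential U(z) in pK units."""
        dz = z - self.well_center
        return 0.5 * self.well_k * dz * dz


def analytic_pka_profile(params: SurrogateParams, z_grid) -> np.ndarray:
    """Ground-truth pKa(z) of the uncoupled surrogate, evaluated on a grid."""
    if params.w_partner != 0.0:
        raise ValueError("analytic profile is defined only without partner coupling")
    z = np.asarray(z_grid, float)
    u = (params.z_mid - z) / params.z_width
    return params.pK_mod + params.dpK_desolv / (1.0 + np.exp(-u))


class SurrogateSystem:
    """Titration system whose key-site intrinsic term tracks the z coordinate."""

    def __init__(self, params: SurrogateParams):
        self.params = params
        sites = [
            TitratableSite(
                KEY_SITE, (Tautomer("d", 0), Tautomer("p", 1)), start_z=5.0
            )
        ]
        if params.w_partner != 0.0:
            sites.append(
                TitratableSite(
                    PARTNER_SITE, (Tautomer("d", 0), Tautomer("p", 1)), start_z=5.0
                )
            )
        self._sites = sites

    @property
    def sites(self) -> list[TitratableSite]:
        return self._sites

    def terms_for(self, conformation: float) -> EnergyTerms:
        z = float(conformation)
        intrinsic = {
            (KEY_SITE, "d"): 0.0,
            (KEY_SITE, "p"): -self.params.pk_int(z),
        }
        pairwise = {}
        if self.params.w_partner != 0.0:
            # basic partner: strongly protonated over the working pH range
            intrinsic[(PARTNER_SITE, "d")] = 0.0
            intrinsic[(PARTNER_SITE, "p")] = -12.0
            pairwise[(KEY_SITE, "p", PARTNER_SITE, "p")] = self.params.w_partner
        return EnergyTerms(intrinsic, pairwise, conformation_id=f"z={z:.4f}")


class SurrogatePropagator:
    """Metropolis random walk on z, in equilibrium with the protonation state.

    For a fixed microstate the stationary density is
    ``10**-(U(z) + g_tau(z))``: the deprotonated form samples the bare well,
    the protonated form is biased toward burial by the desolvation term.
    """

    def __init__(self, params: SurrogateParams):
        self.params = params

    def _g_tau(self, tau: str, z: float) -> float:
        return -self.params.pk_int(z) if tau == "p" else 0.0

    def log10_density(self, tau: str, z) -> np.ndarray:
        """Unnormalised log10 conditional density of z given the key tautomer."""
        z = np.asarray(z, float)
        u = (self.params.z_mid - z) / self.params.z_width
        pk = self.params.pK_mod + self.params.dpK_desolv / (1.0 + np.exp(-u))
        g = -pk if tau == "p" else np.zeros_like(z)
        dz = z - self.params.well_center
        return -(0.5 * self.params.well_k * dz * dz + g)

    def initial(self, rng: np.random.Generator) -> float:
        sd = 1.0 / math.sqrt(self.params.well_k * math.log(10.0))
        return float(self.params.well_center + sd * rng.standard_normal())

    def advance(
        self, conformation: float, microstate: Microstate, n_steps: int,
        rng: np.random.Generator,
    ) -> float:
        z = float(conformation)
        tau = microstate.assignment[KEY_SITE]
        p = self.params
        e = p.potential(z) + self._g_tau(tau, z)
        if n_steps <= 0:
            return z
        steps = rng.uniform(-p.conf_step, p.conf_step, n_steps)
        us = rng.random(n_steps)
        for k in range(n_steps):
            z_new = z + steps[k]
            e_new = p.potential(z_new) + self._g_tau(tau, z_new)
            d = e_new - e
            if d <= 0.0 or us[k] < 10.0 ** (-d):
                z, e = z_new, e_new
        return z

    def summary(self, conformation: float) -> float:
        return float(conformation)


def make_surrogate_system(
    params: SurrogateParams | None = None, seed: int = 0
) -> tuple[SurrogateSystem, SurrogatePropagator]:
    """Build the surrogate system and its matching z propagator."""
    params = params or SurrogateParams()
    return SurrogateSystem(params), SurrogatePropagator(params)


def random_titration_system(
    rng: np.random.Generator,
    n_sites: int = 6,
    max_tautomers: int = 3,
    g_range: tuple[float, float] = (-9.0, -3.0),
    w_range: tuple[float, float] = (-3.0, 3.0),
    coupling_density: float = 0.4,
) -> tuple[list[TitratableSite], EnergyTerms]:
    """A random interacting titration system for sampler validation.

    Each site gets one deprotonated and 1..(max_tautomers-1) protonated
    tautomers, intrinsic terms drawn from ``g_range`` and sparse pairwise
    couplings from ``w_range``.  Site start_z values are drawn in
    [-20, 20] so bath assignments mix inner and outer.
    """
    sites: list[TitratableSite] = []
    intrinsic: dict[tuple[str, str], float] = {}
    pairwise: dict[tuple[str, str, str, str], float] = {}
    for i in range(n_sites):
        sid = f"S{i}"
        n_prot_forms = int(rng.integers(1, max_tautomers))
        tauts = [Tautomer("d", 0)] + [
            Tautomer(f"p{k}", 1) for k in range(n_prot_forms)
        ]
        z = float(rng.uniform(-20, 20))
        sites.append(TitratableSite(sid, tuple(tauts), start_z=z))
        intrinsic[(sid, "d")] = 0.0
        for k in range(n_prot_forms):
            intrinsic[(sid, f"p{k}")] = float(rng.uniform(*g_range))
    for a in range(n_sites):
        for b in range(a + 1, n_sites):
            if rng.random() >= coupling_density:
                continue
            for ta in sites[a].tautomers:
                for tb in sites[b].tautomers:
                    if ta.n_protons == 0 and tb.n_protons == 0:
                        continue
                    pairwise[(sites[a].site_id, ta.label, sites[b].site_id, tb.label)] = (
                        float(rng.uniform(*w_range))
                    )
    return sites, EnergyTerms(intrinsic, pairwise)


@dataclass(frozen=True)
class SyntheticFrameSpec:
    """Parameters of the synthetic membrane-frame generator.

    Phosphate sheets sit at ``z = +-(half_thickness_bulk +
    A * exp(-r^2 / (2 sigma^2)))`` plus Gaussian z noise, with the
    deformation centered on the peptide at the origin; ``A < 0`` dimples the
    monolayer toward the membrane interior.  Lipids are laid out on a
    jittered square grid (one P and two O atoms each).
    """

    n_lipids: int = 256
    half_thickness_bulk: float = 19.5
    amplitude: float = 0.0
    sigma: float = 3.0
    noise_sd: float = 0.5
    lipid_spacing: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.half_thickness_bulk <= 0 or self.sigma <= 0:
            raise ValueError("half_thickness_bulk and sigma must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def box_length(self) -> float:
        side = int(math.ceil(math.sqrt(self.n_lipids)))
        return side * self.lipid_spacing


def generate_membrane_frames(
    spec: SyntheticFrameSpec,
    n_frames: int,
    probe_z: float | np.ndarray = 15.0,
    probe_tag: str = "PRB",
) -> list[MembraneFrame]:
    """Synthetic frames with a known monolayer deformation.

    The peptide/probe marker sits on the z axis at ``probe_z`` (scalar, or
    one value per frame).  Surface z of each monolayer follows the closed
    form in :class:`SyntheticFrameSpec`, so analysis results can be checked
    against ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    probe_z = np.broadcast_to(np.asarray(probe_z, float), (n_frames,))
    side = int(math.ceil(math.sqrt(spec.n_lipids)))
    L = spec.box_length
    gx, gy = np.meshgrid(np.arange(side), np.arange(side))
    grid = (np.stack([gx.ravel(), gy.ravel()], axis=1)[: spec.n_lipids] + 0.5)
    grid = grid * spec.lipid_spacing
    frames: list[MembraneFrame] = []
    for fi in range(n_frames):
        atoms = []
        elements = []
        monos = []
        for mono_sign, mono_tag in ((1.0, UPPER), (-1.0, LOWER)):
            # full-cell jitter: stratified-uniform lipid positions, so every
            # radial bin around the peptide is populated on average
            xy = grid + rng.uniform(
                -spec.lipid_spacing / 2, spec.lipid_spacing / 2, grid.shape
            )
            xy %= L
            # deformation is centered on the peptide at the box center
            dxy = xy - L / 2.0
            dxy -= L * np.round(dxy / L)
            r2 = (dxy**2).sum(axis=1)
            z_surf = spec.half_thickness_bulk + spec.amplitude * np.exp(
                -r2 / (2.0 * spec.sigma**2)
            )
            for o_dx, element in ((0.0, "P"), (-0.6, "O"), (0.6, "O")):
                z = mono_sign * (z_surf + rng.normal(0.0, spec.noise_sd, len(xy)))
                pos = np.column_stack([xy[:, 0] + o_dx, xy[:, 1], z])
                atoms.append(pos)
                elements.extend([element] * len(xy))
                monos.extend([mono_tag] * len(xy))
        frames.append(
            MembraneFrame(
                phosphate_xyz=np.concatenate(atoms),
                phosphate_element=np.array(elements),
                phosphate_monolayer=np.array(monos),
                probes={
                    probe_tag: np.array([[L / 2.0, L / 2.0, probe_z[fi]]])
                },
                frame_index=fi,
                box=(L, L, 4.0 * spec.half_thickness_bulk),
            )
        )
    return frames


def expected_half_thickness(
    spec: SyntheticFrameSpec, bin_edges: np.ndarray, n_quad: int = 200
) -> np.ndarray:
    """Closed-form expected half thickness per radial bin of the generator.

    Averages ``half_thickness_bulk + A exp(-r^2/(2 sigma^2))`` over each bin
    with the radial measure ``r dr`` (atoms are uniform in the plane), which
    is the exact population mean the annulus analysis estimates.
    """
    edges = np.asarray(bin_edges, float)
    out = np.empty(len(edges) - 1)
    for k in range(len(out)):
        r = np.linspace(edges[k], edges[k + 1], n_quad)
        f = spec.half_thickness_bulk + spec.amplitude * np.exp(
            -(r**2) / (2.0 * spec.sigma**2)
        )
        out[k] = np.trapezoid(f * r, r) / np.trapezoid(r, r)
    return out


def exact_surrogate_averages(
    params: SurrogateParams, pH: float, z_lim: float = 40.0, n_quad: int = 4001
) -> TitrationResult:
    """Quadrature oracle for the uncoupled surrogate's joint ensemble.

    Integrates the joint weight over z for each protonation form and
    returns exact ensemble averages (protonated fraction and mean z are
    recoverable from the returned pieces).
    """
    if params.w_partner != 0.0:
        raise ValueError("oracle defined only without partner coupling")
    z = np.linspace(-z_lim, z_lim, n_quad)
    pk = analytic_pka_profile(params, z)
    u_conf = 0.5 * params.well_k * (z - params.well_center) ** 2
    log_wd = -u_conf * math.log(10.0)
    log_wp = (-(u_conf - pk + pH)) * math.log(10.0)
    m = max(log_wd.max(), log_wp.max())
    wd = np.exp(log_wd - m)
    wp = np.exp(log_wp - m)
    Zd = np.trapezoid(wd, z)
    Zp = np.trapezoid(wp, z)
    frac = Zp / (Zd + Zp)
    return TitrationResult(
        mean_protonation={KEY_SITE: float(frac)},
        se_protonation={KEY_SITE: 0.0},
        mean_protons={KEY_SITE: float(frac)},
        mean_N=float(frac),
        final_state=Microstate({KEY_SITE: "p" if frac > 0.5 else "d"}),
        n_cycles_run=0,
    )
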