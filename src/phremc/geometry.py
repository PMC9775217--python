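"""Membrane coordinate-frame analyses.

Works on per-frame snapshots carrying the lipid phosphate-group atoms (P
and O), tagged by monolayer, plus labelled probe groups (e.g. a titratable
residue).  Provides the membrane center, the local monolayer surface under
the probe, signed insertion depths (negative = membrane interior), and
peptide-centered annulus half-thickness / deformation profiles.

All xy proximity tests use minimum-image distances in the periodic xy
plane.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

log = logging.getLogger(__name__)

UPPER = 1
LOWER = -1


@dataclass
class MembraneFrame:
    """One coordinate snapshot of a peptide-membrane system (Angstrom).

    ``phosphate_xyz``: (N, 3) positions of lipid phosphate-group atoms;
    ``phosphate_element``: 'P' or 'O' per atom; ``phosphate_monolayer``:
    +1 (upper/outer) or -1 (lower/inner) per atom — an input tag assigned
    at setup, not re-derived per frame.  ``probes`` maps a residue tag to
    the (k, 3) positions of its atoms.  ``box`` holds the periodic box
    lengths (Lx, Ly[, Lz]); xy periodicity is honoured.
    """

    phosphate_xyz: np.ndarray
    phosphate_element: np.ndarray
    phosphate_monolayer: np.ndarray
    probes: dict[str, np.ndarray] = field(default_factory=dict)
    frame_index: int = 0
    box: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.phosphate_xyz = np.asarray(self.phosphate_xyz, float)
        self.phosphate_element = np.asarray(self.phosphate_element)
        self.phosphate_monolayer = np.asarray(self.phosphate_monolayer, int)
        if not np.isfinite(self.phosphate_xyz).all():
            raise ValueError("non-finite phosphate coordinates")
        for tag, xyz in self.probes.items():
            self.probes[tag] = np.atleast_2d(np.asarray(xyz, float))

    def monolayer_mask(self, monolayer: int) -> np.ndarray:
        return self.phosphate_monolayer == monolayer


@dataclass
class InsertionRecord:
    """Signed insertion of a probe group in one frame (negative = interior)."""

    frame_index: int
    residue_tag: str
    insertion: float
    monolayer: int
    n_atoms_surface: int


@dataclass
class ThicknessProfile:
    """Radial half-thickness profile per monolayer around the peptide."""

    bin_edges: np.ndarray  # (n_bins + 1,)
    mean: dict[int, np.ndarray]  # monolayer -> per-bin mean (NaN when empty)
    sem: dict[int, np.ndarray]
    count: dict[int, np.ndarray]
    # raw per-(group, bin) means used for SEM; groups are replicates when
    # given, frames otherwise
    _group_means: dict[int, np.ndarray] = field(default_factory=dict, repr=False)
    _bulk_values: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def bin_mid(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _min_image_dxy(dxy: np.ndarray, box: tuple[float, ...] | None) -> np.ndarray:
    if box is not None:
        L = np.asarray(box[:2], float)
        dxy = dxy - L * np.round(dxy / L)
    return dxy


def membrane_center(frame: MembraneFrame) -> float:
    """Mean z of all phosphorus atoms (the membrane normal origin)."""
    mask = frame.phosphate_element == "P"
    if not mask.any():
        raise ValueError("frame has no P atoms")
    return float(frame.phosphate_xyz[mask, 2].mean())


def local_surface_z(
    frame: MembraneFrame,
    probe_xy: Sequence[float],
    monolayer: int,
    radius: float = 6.0,
    min_atoms: int = 10,
) -> tuple[float, int]:
    """Local monolayer surface: mean z of nearby phosphate P/O atoms.

    Atoms of the given monolayer within ``radius`` (xy minimum-image) of
    the probe are averaged; when fewer than ``min_atoms`` qualify, the
    ``min_atoms`` nearest atoms in the xy plane are used regardless of the
    cutoff.
    """
    mask = frame.monolayer_mask(monolayer)
    xyz = frame.phosphate_xyz[mask]
    if len(xyz) < min_atoms:
        raise ValueError(
            f"monolayer {monolayer:+d} has only {len(xyz)} phosphate atoms "
            f"(< {min_atoms})"
        )
    dxy = _min_image_dxy(xyz[:, :2] - np.asarray(probe_xy, float), frame.box)
    d2 = (dxy**2).sum(axis=1)
    inside = d2 <= radius * radius
    if inside.sum() >= min_atoms:
        sel = inside
        n = int(inside.sum())
    else:
        order = np.argsort(d2, kind="stable")[:min_atoms]
        sel = order
        n = min_atoms
    return float(xyz[sel, 2].mean()), n


def insertion_series(
    frames: Sequence[MembraneFrame],
    residue_tag: str,
    reference: str = "centroid",
    radius: float = 6.0,
    min_atoms: int = 10,
) -> list[InsertionRecord]:
    """Signed insertion of a probe group relative to its local monolayer surface.

    The reference point is the probe-atom centroid (``reference='centroid'``)
    or the atom at a given index (``reference='atom:<k>'``).  The monolayer
    is picked by the side of the membrane center the reference sits on; the
    sign convention makes negative insertion always point to the membrane
    interior.  Frames missing the residue are skipped with a warning.
    """
    records: list[InsertionRecord] = []
    for frame in frames:
        xyz = frame.probes.get(residue_tag)
        if xyz is None or len(xyz) == 0:
            log.warning(
                "frame %d: residue %r absent, skipped", frame.frame_index, residue_tag
            )
            continue
        if reference == "centroid":
            ref = xyz.mean(axis=0)
        elif reference.startswith("atom:"):
            ref = xyz[int(reference.split(":", 1)[1])]
        else:
            raise ValueError(f"unknown reference rule {reference!r}")
        center = membrane_center(frame)
        mono = UPPER if ref[2] >= center else LOWER
        z_surf, n = local_surface_z(frame, ref[:2], mono, radius, min_atoms)
        sign = 1.0 if mono == UPPER else -1.0
        records.append(
            InsertionRecord(
                frame_index=frame.frame_index,
                residue_tag=residue_tag,
                insertion=float(sign * (ref[2] - z_surf)),
                monolayer=mono,
                n_atoms_surface=n,
            )
        )
    return records


def annulus_half_thickness(
    frames: Sequence[MembraneFrame],
    peptide_tag: str,
    bin_width: float = 1.0,
    r_max: float | None = None,
    replicates: Sequence[int] | None = None,
) -> ThicknessProfile:
    """Radial annulus scan of per-monolayer half thickness around the peptide.

    For each P/O atom the half thickness is ``|z_atom - membrane_center|``;
    atoms are binned by their xy minimum-image distance to the per-frame
    peptide centroid.  Bin means pool all atoms of all frames; SEM is taken
    across replicates when ``replicates`` labels are given, across frames
    otherwise.  Empty bins carry NaN means and zero counts.
    """
    if not frames:
        raise ValueError("no frames given")
    if replicates is not None and len(replicates) != len(frames):
        raise ValueError("replicates must align with frames")
    rs: list[np.ndarray] = []
    hs: list[np.ndarray] = []
    monos: list[np.ndarray] = []
    groups: list[np.ndarray] = []
    for fi, frame in enumerate(frames):
        pep = frame.probes.get(peptide_tag)
        if pep is None or len(pep) == 0:
            raise ValueError(f"frame {frame.frame_index}: peptide tag {peptide_tag!r} absent")
        center_xy = pep[:, :2].mean(axis=0)
        c = membrane_center(frame)
        dxy = _min_image_dxy(frame.phosphate_xyz[:, :2] - center_xy, frame.box)
        rs.append(np.sqrt((dxy**2).sum(axis=1)))
        hs.append(np.abs(frame.phosphate_xyz[:, 2] - c))
        monos.append(frame.phosphate_monolayer)
        gid = replicates[fi] if replicates is not None else fi
        groups.append(np.full(len(dxy), gid))
    r = np.concatenate(rs)
    h = np.concatenate(hs)
    mono = np.concatenate(monos)
    grp = np.concatenate(groups)
    if r_max is None:
        # stop at half the box: beyond it annuli are incomplete (corner-only)
        boxes = [f.box for f in frames if f.box is not None]
        if boxes:
            r_max = float(min(min(b[0], b[1]) for b in boxes)) / 2.0
        else:
            r_max = float(r.max())
    n_bins = max(1, int(math.ceil(r_max / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.floor(r / bin_width).astype(int)
    uniq_groups = np.unique(grp)
    mean: dict[int, np.ndarray] = {}
    sem: dict[int, np.ndarray] = {}
    count: dict[int, np.ndarray] = {}
    gmeans: dict[int, np.ndarray] = {}
    bulk_vals: dict[int, np.ndarray] = {}
    for m in (UPPER, LOWER):
        msel = mono == m
        cnt = np.bincount(idx[msel & (idx < n_bins)], minlength=n_bins)
        tot = np.bincount(
            idx[msel & (idx < n_bins)], weights=h[msel & (idx < n_bins)],
            minlength=n_bins,
        )
        with np.errstate(invalid="ignore"):
            mu = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
        gm = np.full((len(uniq_groups), n_bins), np.nan)
        for k, g in enumerate(uniq_groups):
            sel = msel & (grp == g) & (idx < n_bins)
            c_g = np.bincount(idx[sel], minlength=n_bins)
            t_g = np.bincount(idx[sel], weights=h[sel], minlength=n_bins)
            with np.errstate(invalid="ignore"):
                gm[k] = np.where(c_g > 0, t_g / np.maximum(c_g, 1), np.nan)
        n_g = (~np.isnan(gm)).sum(axis=0)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
            sd = np.nanstd(gm, axis=0, ddof=1)
        s = np.where(n_g > 1, sd / np.sqrt(np.maximum(n_g, 1)), np.nan)
        mean[m], sem[m], count[m], gmeans[m] = mu, s, cnt, gm
        bulk_vals[m] = np.stack([r[msel], h[msel]])
    return ThicknessProfile(
        bin_edges=edges, mean=mean, sem=sem, count=count,
        _group_means=gmeans, _bulk_values=bulk_vals,
    )


@dataclass
class DeformationProfile:
    """Local deformation (local minus bulk half thickness) per monolayer."""

    bin_edges: np.ndarray
    deformation: dict[int, np.ndarray]
    sem: dict[int, np.ndarray]
    bulk: dict[int, float]

    @property
    def bin_mid(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def local_deformation(
    profile: ThicknessProfile, bulk_cutoff: float = 15.0
) -> DeformationProfile:
    """Deformation profile: per-bin half thickness minus the bulk value.

    The bulk half thickness per monolayer comes from all P/O atoms beyond
    ``bulk_cutoff`` (xy distance to the peptide).
    """
    if profile.bin_edges[-1] <= bulk_cutoff:
        raise ValueError(
            f"profile extends only to {profile.bin_edges[-1]} A "
            f"(<= bulk cutoff {bulk_cutoff} A)"
        )
    deformation: dict[int, np.ndarray] = {}
    bulk: dict[int, float] = {}
    for m, mu in profile.mean.items():
        r, h = profile._bulk_values[m]
        far = r > bulk_cutoff
        if not far.any():
            raise ValueError(f"monolayer {m:+d}: no atoms beyond {bulk_cutoff} A")
        bulk[m] = float(h[far].mean())
        deformation[m] = mu - bulk[m]
    return DeformationProfile(
        bin_edges=profile.bin_edges,
        deformation=deformation,
        sem=dict(profile.sem),
        bulk=bulk,
    )
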