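"""Coordinate-frame reading and writing (GRO and PDB) via MDAnalysis.

Frames arrive as multi-model PDB files or as stacked GRO blocks (several
complete GRO frames concatenated in one file).  MDAnalysis parses the
formats; this module only maps atoms onto :class:`~phremc.geometry.MembraneFrame`
according to a small selection config and handles the nm/Angstrom
conversion implied by GRO (MDAnalysis already reports Angstrom
internally).

Monolayer membership is assigned once, from the first frame, by the side
of the membrane center each phosphate atom sits on, and reused for all
frames.
"""

from __future__ import annotations

import io as _io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda
    from MDAnalysis.lib.util import NamedStream

from .geometry import LOWER, UPPER, MembraneFrame
from .io import FormatError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    """Maps residue/atom names onto phosphate and probe groups.

    Atoms of residues in ``lipid_resnames`` whose name starts with 'P' or
    'O' are phosphate-group atoms; every other residue name becomes a
    probe tag (or only those listed in ``probe_resnames`` when given).
    """

    lipid_resnames: tuple[str, ...] = ("LIP", "POPC", "DMPC", "POPE")
    probe_resnames: tuple[str, ...] | None = None

    def is_lipid(self, resname: str) -> bool:
        return resname in self.lipid_resnames

    def probe_tag(self, resname: str) -> str | None:
        if self.probe_resnames is not None and resname not in self.probe_resnames:
            return None
        return resname


def _universe_frames(path: Path) -> list[mda.Universe]:
    """One single-frame Universe per frame, for GRO stacks or multi-model PDB."""
    suffix = path.suffix.lower()
    if suffix == ".gro":
        return _split_gro(path)
    if suffix == ".pdb":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
            out = []
            for ts in u.trajectory:
                sub = mda.Merge(u.atoms)
                sub.dimensions = ts.dimensions
                out.append(sub)
        return out
    raise FormatError(f"unknown coordinate format {suffix!r} (expected .gro or .pdb)")


def _split_gro(path: Path) -> list[mda.Universe]:
    lines = path.read_text().splitlines()
    out: list[mda.Universe] = []
    i = 0
    fi = 0
    while i < len(lines):
        if not lines[i].strip() and i == len(lines) - 1:
            break
        if i + 1 >= len(lines):
            raise FormatError(f"{path}: truncated frame {fi} (missing atom count)")
        try:
            natoms = int(lines[i + 1].strip())
        except ValueError:
            raise FormatError(
                f"{path}: frame {fi}: bad atom-count line {i + 2}"
            ) from None
        end = i + 2 + natoms + 1
        if end > len(lines):
            raise FormatError(f"{path}: truncated frame {fi}")
        block = "\n".join(lines[i:end]) + "\n"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out.append(mda.Universe(NamedStream(_io.StringIO(block), "frame.gro")))
        i = end
        fi += 1
    if not out:
        raise FormatError(f"{path}: no frames found")
    return out


def read_frames(
    path: str | Path, selection: SelectionConfig | None = None
) -> list[MembraneFrame]:
    """Read a GRO stack or multi-model PDB into membrane frames."""
    selection = selection or SelectionConfig()
    path = Path(path)
    universes = _universe_frames(path)
    frames: list[MembraneFrame] = []
    mono_tags: np.ndarray | None = None
    n_phos = None
    for fi, u in enumerate(universes):
        resnames = u.atoms.resnames
        names = u.atoms.names
        is_lipid = np.array([selection.is_lipid(r) for r in resnames])
        is_phos = is_lipid & np.array([n[:1] in ("P", "O") for n in names])
        if not is_phos.any():
            raise FormatError(f"{path}: frame {fi}: selection matched no phosphate atoms")
        xyz = u.atoms.positions.astype(float)
        if u.dimensions is None or not np.all(u.dimensions[:3] > 0):
            raise FormatError(f"{path}: frame {fi}: missing box dimensions")
        box = tuple(float(v) for v in u.dimensions[:3])
        phos_xyz = xyz[is_phos]
        elements = np.array([n[0] for n in names[is_phos]])
        if mono_tags is None:
            p_mask = elements == "P"
            if not p_mask.any():
                raise FormatError(f"{path}: no P atoms among phosphate selection")
            center = phos_xyz[p_mask, 2].mean()
            mono_tags = np.where(phos_xyz[:, 2] >= center, UPPER, LOWER)
            n_phos = int(is_phos.sum())
        elif int(is_phos.sum()) != n_phos:
            raise FormatError(
                f"{path}: frame {fi}: phosphate atom count changed "
                f"({int(is_phos.sum())} vs {n_phos})"
            )
        probes: dict[str, list[np.ndarray]] = {}
        for resname in np.unique(resnames[~is_lipid]):
            tag = selection.probe_tag(resname)
            if tag is None:
                continue
            sel = (~is_lipid) & (resnames == resname)
            probes[tag] = xyz[sel]
        frames.append(
            MembraneFrame(
                phosphate_xyz=phos_xyz,
                phosphate_element=elements,
                phosphate_monolayer=mono_tags.copy(),
                probes=probes,
                frame_index=fi,
                box=box,
            )
        )
    return frames


def _frame_to_universe(frame: MembraneFrame, lipid_resname: str = "LIP") -> mda.Universe:
    n_phos = len(frame.phosphate_xyz)
    probe_items = sorted(frame.probes.items())
    n_probe = sum(len(xyz) for _t, xyz in probe_items)
    n = n_phos + n_probe
    names = [str(e) for e in frame.phosphate_element]
    resnames = [lipid_resname] * n_phos
    positions = [frame.phosphate_xyz]
    for tag, xyz in probe_items:
        names.extend(["CA"] * len(xyz))
        resnames.extend([tag[:4]] * len(xyz))
        positions.append(xyz)
    u = mda.Universe.empty(
        n, n_residues=n, atom_resindex=np.arange(n), trajectory=True
    )
    u.add_TopologyAttr("name", names)
    u.add_TopologyAttr("resname", resnames)
    u.add_TopologyAttr("resid", (np.arange(n) % 99999) + 1)
    u.atoms.positions = np.concatenate(positions)
    box = frame.box or (0.0, 0.0, 0.0)
    lz = box[2] if len(box) > 2 else max(200.0, 4 * abs(frame.phosphate_xyz[:, 2]).max())
    u.dimensions = np.array([box[0], box[1], lz, 90.0, 90.0, 90.0])
    return u


def write_frames(
    frames: Sequence[MembraneFrame], path: str | Path, lipid_resname: str = "LIP"
) -> None:
    """Write frames as a GRO stack or multi-model PDB (by file extension)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".pdb":
        # one CRYST1 per MODEL so per-frame box dimensions survive a
        # round trip (a single shared CRYST1 is dropped on multi-model read)
        blocks: list[str] = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for k, frame in enumerate(frames, start=1):
                u = _frame_to_universe(frame, lipid_resname)
                stream = NamedStream(_io.StringIO(), "frame.pdb")
                with mda.Writer(stream, u.atoms.n_atoms) as w:
                    w.write(u.atoms)
                body = [
                    line
                    for line in stream.getvalue().splitlines()
                    if line[:6] in ("CRYST1", "ATOM  ", "HETATM", "TER   ")
                    or line[:3] == "TER"
                ]
                blocks.append(
                    "\n".join([f"MODEL     {k:>4d}", *body, "ENDMDL"])
                )
        path.write_text("\n".join(blocks) + "\nEND\n")
    elif suffix == ".gro":
        chunks = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for frame in frames:
                u = _frame_to_universe(frame, lipid_resname)
                stream = NamedStream(_io.StringIO(), "frame.gro")
                with mda.Writer(stream, u.atoms.n_atoms) as w:
                    w.write(u.atoms)
                chunks.append(stream.getvalue())
        path.write_text("".join(chunks))
    else:
        raise FormatError(f"unknown coordinate format {suffix!r} (expected .gro or .pdb)")
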