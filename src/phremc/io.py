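"""Tabular readers/writers: energy-term files, bath files, record CSVs.

Energy-term files are tab- or whitespace-separated, one file per
conformation, with two record kinds (``#`` starts a comment)::

    SITE  site_id  tautomer  n_protons  g
    PAIR  site_i  tau_i  site_j  tau_j  W

Units are pK (log10) throughout.  Bath files list ``site_id in|out``
overrides, one per line.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .mc import TitrationResult
from .phre import ReplicaRecord
from .titration import EnergyTerms, TitratableSite, Tautomer

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


def read_energy_terms(path: str | Path) -> tuple[list[TitratableSite], EnergyTerms]:
    """Parse an energy-term file into sites and :class:`EnergyTerms`.

    Site ``start_z`` is not part of the format and defaults to 0; callers
    set bath assignments separately (bath file or explicit map).
    """
    path = Path(path)
    site_tauts: dict[str, list[Tautomer]] = {}
    seen_site_lines: dict[tuple[str, str], int] = {}
    intrinsic: dict[tuple[str, str], float] = {}
    pairwise: dict[tuple[str, str, str, str], float] = {}
    seen_pair_lines: dict[tuple[str, str, str, str], int] = {}
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        kind = fields[0].upper()
        if kind == "SITE":
            if len(fields) != 5:
                raise FormatError(f"{path}:{ln}: SITE record needs 4 fields")
            _, sid, tau, n_str, g_str = fields
            key = (sid, tau)
            if key in seen_site_lines:
                raise FormatError(
                    f"{path}:{ln}: duplicate SITE {sid} {tau} "
                    f"(first at line {seen_site_lines[key]})"
                )
            seen_site_lines[key] = ln
            try:
                n = int(n_str)
                g = float(g_str)
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-numeric SITE fields: {exc}") from None
            site_tauts.setdefault(sid, []).append(Tautomer(tau, n))
            intrinsic[key] = g
        elif kind == "PAIR":
            if len(fields) != 6:
                raise FormatError(f"{path}:{ln}: PAIR record needs 5 fields")
            _, si, ti, sj, tj, w_str = fields
            key = (si, ti, sj, tj)
            if key in seen_pair_lines:
                raise FormatError(
                    f"{path}:{ln}: duplicate PAIR {' '.join(key)} "
                    f"(first at line {seen_pair_lines[key]})"
                )
            seen_pair_lines[key] = ln
            try:
                w = float(w_str)
            except ValueError:
                raise FormatError(f"{path}:{ln}: non-numeric W {w_str!r}") from None
            pairwise[key] = w
        else:
            raise FormatError(f"{path}:{ln}: unknown record kind {kind!r}")
    if not site_tauts:
        raise FormatError(f"{path}: no SITE records")
    sites = [
        TitratableSite(sid, tuple(tauts)) for sid, tauts in site_tauts.items()
    ]
    for si, ti, sj, tj in pairwise:
        for sid, tau in ((si, ti), (sj, tj)):
            if (sid, tau) not in intrinsic:
                raise FormatError(
                    f"{path}: PAIR references unknown site/tautomer {sid} {tau}"
                )
    return sites, EnergyTerms(intrinsic, pairwise, conformation_id=path.stem)


def write_energy_terms(
    path: str | Path,
    sites: Sequence[TitratableSite],
    terms: EnergyTerms,
    header: str = "",
) -> None:
    lines = []
    if header:
        lines.extend(f"# {h}" for h in header.splitlines())
    for s in sites:
        for t in s.tautomers:
            lines.append(
                f"SITE\t{s.site_id}\t{t.label}\t{t.n_protons}\t{terms.g(s.site_id, t.label):.10g}"
            )
    for (si, ti, sj, tj), w in sorted(terms.pairwise.items()):
        lines.append(f"PAIR\t{si}\t{ti}\t{sj}\t{tj}\t{w:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_bath_file(path: str | Path) -> dict[str, str]:
    """Read ``site_id in|out`` override lines."""
    out: dict[str, str] = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 2 or fields[1] not in ("in", "out"):
            raise FormatError(f"{path}:{ln}: expected 'site_id in|out'")
        if fields[0] in out:
            raise FormatError(f"{path}:{ln}: duplicate site {fields[0]!r}")
        out[fields[0]] = fields[1]
    return out


def titration_result_frame(result: TitrationResult) -> pd.DataFrame:
    """Per-site means as a tidy table (the `titrate` CSV)."""
    rows = [
        {
            "site_id": sid,
            "mean_protonation": result.mean_protonation[sid],
            "se": result.se_protonation[sid],
            "mean_protons": result.mean_protons[sid],
        }
        for sid in result.mean_protonation
    ]
    return pd.DataFrame(rows)


def records_to_frame(records: Iterable[ReplicaRecord]) -> pd.DataFrame:
    """Flatten replica records into the observation table profiles consume.

    One row per record and site: replicate, pH, frame (cycle), insertion
    (the tagged-group z), site_id, protonated.
    """
    rows = []
    for r in records:
        for sid, prot in r.protonated.items():
            rows.append(
                {
                    "replicate": r.replicate_id,
                    "pH": r.pH,
                    "frame": r.cycle,
                    "insertion": r.z,
                    "site_id": sid,
                    "protonated": prot,
                }
            )
    return pd.DataFrame(
        rows, columns=["replicate", "pH", "frame", "insertion", "site_id", "protonated"]
    )


FLOAT_FORMAT = "%.6g"


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """CSV writer with the package-wide float format (6 significant digits)."""
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
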