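"""Insertion-binned protonation and pKa profiles.

Protonation observations — (replicate, pH, frame, insertion, protonated)
tuples — are binned along the insertion coordinate, screened by three
robustness criteria, and each surviving bin's per-pH average protonations
are fitted to the Hill equation

    <prot>(pH) = 1 / (1 + 10**(n * (pH - pKa)))

to give a pKa-versus-insertion profile.  Errors come from a Bayesian
bootstrap: each replicate-level average-protonation sample receives a
flat-Dirichlet random weight, averages and criteria are recomputed, and
the fit is repeated per resample.

The screening criteria per insertion bin:

1. each (pH, replicate) cell needs at least ``min_conformations`` (10)
   conformations of *each* protonation state;
2. at least ``min_replicates`` (3) replicates must contribute at a pH for
   it to count, and at least two surviving pH values are required for a
   pKa fit;
3. moving up the surviving pH values, the pooled average protonation may
   not rise by more than ``monotonicity_tol`` (0.05) above the previous
   (lower-pH) average.

Protonation profiles need only criteria 1-2; pKa fits need all three.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

LN10 = math.log(10.0)

DEFAULT_MIN_CONFORMATIONS = 10
DEFAULT_MIN_REPLICATES = 3
DEFAULT_MIN_PHS = 2
DEFAULT_MONOTONICITY_TOL = 0.05


class HillFitError(RuntimeError):
    """Raised when a Hill fit is impossible or fails to converge."""


def _discard_burn_in(obs: pd.DataFrame, burn_in_fraction: float) -> pd.DataFrame:
    """Drop the first fraction of frames per (replicate, pH), by frame order."""
    df = obs.sort_values("frame", kind="stable")
    if burn_in_fraction <= 0:
        return df
    grp = df.groupby(["replicate", "pH"], sort=False)
    pos = grp.cumcount()
    size = grp["frame"].transform("size")
    return df[pos >= (burn_in_fraction * size).astype(int)]


@dataclass(frozen=True)
class HillCurve:
    """Fitted Hill titration curve: midpoint pKa and cooperativity n."""

    pKa: float
    n: float
    residual: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.n <= 10:
            raise ValueError(f"Hill n must be in (0, 10], got {self.n}")

    def predict(self, pH) -> np.ndarray:
        pH = np.asarray(pH, float)
        return 1.0 / (1.0 + 10.0 ** (self.n * (pH - self.pKa)))


# ---------------------------------------------------------------------------
# binning and criteria


def bin_observations(
    obs: pd.DataFrame,
    bin_width: float = 1.0,
    burn_in_fraction: float = 0.0,
) -> pd.DataFrame:
    """Tally protonation counts per (insertion bin, pH, replicate) cell.

    ``obs`` needs columns replicate, pH, frame, insertion, protonated.
    The first ``burn_in_fraction`` of frames (by frame order, per
    replicate and pH) is discarded.  Bins are half-open ``[k*w, (k+1)*w)``
    on a grid anchored at zero.
    """
    required = {"replicate", "pH", "frame", "insertion", "protonated"}
    missing = required - set(obs.columns)
    if missing:
        raise ValueError(f"observations lack columns: {sorted(missing)}")
    if len(obs) == 0:
        raise ValueError("no observations")
    if not 0.0 <= burn_in_fraction < 1.0:
        raise ValueError("burn_in_fraction must be in [0, 1)")
    df = _discard_burn_in(obs, burn_in_fraction)
    k = np.floor(df["insertion"].to_numpy(float) / bin_width).astype(int)
    df = df.assign(bin_low=k * bin_width, bin_high=(k + 1) * bin_width)
    prot = df["protonated"].astype(int)
    cells = (
        df.assign(n_prot=prot, n_deprot=1 - prot)
        .groupby(["bin_low", "bin_high", "pH", "replicate"], as_index=False)[
            ["n_prot", "n_deprot"]
        ]
        .sum()
    )
    return cells


def apply_bin_criteria(
    cells: pd.DataFrame,
    min_conformations: int = DEFAULT_MIN_CONFORMATIONS,
    min_replicates: int = DEFAULT_MIN_REPLICATES,
    min_phs: int = DEFAULT_MIN_PHS,
    monotonicity_tol: float = DEFAULT_MONOTONICITY_TOL,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen binned counts by the three robustness criteria.

    Returns ``(cells, bins)``: the input cells with a ``cell_valid`` column
    (criterion 1), and a per-(bin, pH) table with pooled averages over valid
    cells, ``pH_valid`` (criterion 2, replicate count), and per-bin flags
    ``profile_valid`` (criteria 1-2) and ``pka_valid`` (criteria 1-3).
    Pooled averages are unweighted means of replicate-level averages — the
    same samples the Bayesian bootstrap reweights.
    """
    cells = cells.copy()
    cells["cell_valid"] = (cells["n_prot"] >= min_conformations) & (
        cells["n_deprot"] >= min_conformations
    )
    cells["avg"] = cells["n_prot"] / (cells["n_prot"] + cells["n_deprot"])
    valid = cells[cells["cell_valid"]].copy()
    valid["n_total"] = valid["n_prot"] + valid["n_deprot"]
    per_ph = (
        valid.groupby(["bin_low", "bin_high", "pH"])
        .agg(
            avg=("avg", "mean"),
            n_replicates=("replicate", "nunique"),
            n_conformations=("n_total", "sum"),
        )
        .reset_index()
    )
    per_ph["pH_valid"] = per_ph["n_replicates"] >= min_replicates
    rows = []
    for (lo, hi), g in per_ph.groupby(["bin_low", "bin_high"]):
        surv = g[g["pH_valid"]].sort_values("pH")
        n_ph = len(surv)
        avgs = surv["avg"].to_numpy()
        mono = bool(
            np.all(avgs[1:] <= avgs[:-1] + monotonicity_tol)
        ) if n_ph >= 2 else n_ph == 1
        rows.append(
            {
                "bin_low": lo,
                "bin_high": hi,
                "n_pH": n_ph,
                "monotonic": mono,
                "profile_valid": n_ph >= 1,
                "pka_valid": (n_ph >= min_phs) and mono,
            }
        )
    bin_cols = [
        "bin_low", "bin_high", "n_pH", "monotonic", "profile_valid", "pka_valid",
    ]
    if per_ph.empty:
        out = per_ph.copy()
        for c in ("n_pH", "monotonic", "profile_valid", "pka_valid"):
            out[c] = pd.Series(dtype=bool if c != "n_pH" else int)
        return cells, out
    bins = pd.DataFrame(rows, columns=bin_cols)
    return cells, per_ph.merge(bins, on=["bin_low", "bin_high"], how="left")


# ---------------------------------------------------------------------------
# Hill fitting


def _hill_init(pH: np.ndarray, p: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted linear fit on the logit10 scale: exact for noiseless data."""
    q = np.clip(p, 1e-6, 1 - 1e-6)
    y = np.log10(q / (1.0 - q))  # y = n * (pKa - pH)
    sw = w.sum(axis=-1, keepdims=True)
    xm = (w * pH).sum(axis=-1, keepdims=True) / sw
    ym = (w * y).sum(axis=-1, keepdims=True) / sw
    sxx = (w * (pH - xm) ** 2).sum(axis=-1)
    sxy = (w * (pH - xm) * (y - ym)).sum(axis=-1)
    slope = np.where(sxx > 0, sxy / np.maximum(sxx, 1e-300), -1.0)
    n0 = np.clip(-slope, 1e-2, 10.0)
    pka0 = (ym.squeeze(-1) / n0) + xm.squeeze(-1)
    return pka0, n0


def _hill_fit_batch(
    pH: np.ndarray,
    p: np.ndarray,
    w: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Damped Gauss-Newton Hill fits, vectorised over the leading axis.

    ``pH``: (K,), ``p``/``w``: (B, K).  Returns (pKa, n, rss, ok); n is
    constrained to (0, 10].
    """
    p = np.atleast_2d(np.asarray(p, float))
    w = np.broadcast_to(np.asarray(w, float), p.shape).copy()
    pka, n = _hill_init(pH, p, w)
    lam = np.full(pka.shape, 1e-3)

    def rss_of(pka_, n_):
        f = 1.0 / (1.0 + 10.0 ** (n_[:, None] * (pH[None, :] - pka_[:, None])))
        r = p - f
        return (w * r * r).sum(axis=-1), f

    rss, f = rss_of(pka, n)
    for _ in range(max_iter):
        fp = f * (1.0 - f)
        # d f / d pKa = ln10 * n * f(1-f); d f / d n = -ln10 (pH - pKa) f(1-f)
        J1 = LN10 * n[:, None] * fp
        J2 = -LN10 * (pH[None, :] - pka[:, None]) * fp
        r = p - f
        a11 = (w * J1 * J1).sum(axis=-1) + 1e-300
        a12 = (w * J1 * J2).sum(axis=-1)
        a22 = (w * J2 * J2).sum(axis=-1) + 1e-300
        b1 = (w * J1 * r).sum(axis=-1)
        b2 = (w * J2 * r).sum(axis=-1)
        d11 = a11 * (1.0 + lam)
        d22 = a22 * (1.0 + lam)
        det = d11 * d22 - a12 * a12
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        s1 = (d22 * b1 - a12 * b2) / det
        s2 = (d11 * b2 - a12 * b1) / det
        pka_new = pka + s1
        n_new = np.clip(n + s2, 1e-3, 10.0)
        rss_new, f_new = rss_of(pka_new, n_new)
        better = rss_new <= rss + 1e-15
        pka = np.where(better, pka_new, pka)
        n = np.where(better, n_new, n)
        f = np.where(better[:, None], f_new, f)
        rss = np.where(better, rss_new, rss)
        lam = np.where(better, lam * 0.5, lam * 4.0)
        if np.all(np.abs(s1) + np.abs(s2) < tol):
            break
    ok = np.isfinite(pka) & np.isfinite(n)
    return pka, n, rss, ok


def hill_fit(points) -> HillCurve:
    """Weighted least-squares fit of the Hill equation.

    ``points`` is a sequence of (pH, average protonation[, weight]) tuples;
    weights default to 1 (callers typically pass the number of contributing
    conformations).  Needs >= 2 distinct pH values and averages that are not
    all pinned at 0 or 1.
    """
    pts = [tuple(t) for t in points]
    pH = np.array([t[0] for t in pts], float)
    p = np.array([t[1] for t in pts], float)
    w = np.array([t[2] if len(t) > 2 else 1.0 for t in pts], float)
    if len(np.unique(pH)) < 2:
        raise HillFitError("at least two distinct pH values are required for the fit")
    if np.any((p < 0) | (p > 1)):
        raise HillFitError("average protonations must lie in [0, 1]")
    if p.max() < 1e-4 or p.min() > 1 - 1e-4:
        raise HillFitError("titration curve is flat (all ~0 or all ~1); pKa not identifiable")
    pka, n, rss, ok = _hill_fit_batch(pH, p[None, :], w[None, :])
    if not ok[0]:
        raise HillFitError("Hill fit did not converge")
    return HillCurve(pKa=float(pka[0]), n=float(n[0]), residual=float(rss[0]))


# ---------------------------------------------------------------------------
# Bayesian bootstrap


@dataclass
class BootstrapResult:
    pKa: float
    error: float
    n_hill: float
    point_estimate: HillCurve
    fraction_failed: float
    n_bootstraps: int


def bayesian_bootstrap_pka(
    samples: dict[float, np.ndarray],
    B: int = 1000,
    seed: int = 0,
    weights: dict[float, float] | None = None,
    monotonicity_tol: float = DEFAULT_MONOTONICITY_TOL,
    max_fail_fraction: float = 0.5,
) -> BootstrapResult:
    """Bayesian-bootstrap pKa and error from replicate average protonations.

    ``samples`` maps pH -> per-replicate average protonations of one
    insertion bin (already criteria-screened).  Each bootstrap draws flat
    Dirichlet weights over every pH's replicate samples, recomputes the
    weighted per-pH averages, re-checks the monotonicity criterion on them,
    and refits the Hill curve.  The reported pKa and error are the mean and
    standard deviation over criteria-passing bootstraps; a bin where more
    than ``max_fail_fraction`` of bootstraps fail is rejected as unreliable.
    """
    phs = np.array(sorted(samples), float)
    if len(phs) < 2:
        raise HillFitError("at least two pH values are required")
    xs = [np.asarray(samples[ph], float).ravel() for ph in phs]
    w_fit = np.array(
        [1.0 if weights is None else float(weights[ph]) for ph in phs]
    )
    point = hill_fit(
        [(ph, float(x.mean()), wf) for ph, x, wf in zip(phs, xs, w_fit)]
    )
    rng = np.random.default_rng(seed)
    avg = np.empty((B, len(phs)))
    for k, x in enumerate(xs):
        if len(x) == 1:
            avg[:, k] = x[0]
            continue
        g = rng.gamma(1.0, size=(B, len(x)))
        avg[:, k] = (g * x[None, :]).sum(axis=1) / g.sum(axis=1)
    mono = np.all(avg[:, 1:] <= avg[:, :-1] + monotonicity_tol, axis=1)
    flat = (avg.max(axis=1) < 1e-4) | (avg.min(axis=1) > 1 - 1e-4)
    usable = mono & ~flat
    if usable.any():
        pka, n, _rss, ok = _hill_fit_batch(phs, avg[usable], w_fit[None, :])
        good = ok
    else:
        pka = np.empty(0)
        good = np.zeros(0, bool)
    n_good = int(good.sum())
    frac_failed = 1.0 - n_good / B
    log.info("bayesian bootstrap: %d/%d resamples usable", n_good, B)
    if frac_failed > max_fail_fraction:
        raise HillFitError(
            f"{frac_failed:.0%} of bootstraps failed the criteria; bin unreliable"
        )
    vals = pka[good]
    return BootstrapResult(
        pKa=float(vals.mean()),
        error=float(vals.std(ddof=1)) if n_good > 1 else 0.0,
        n_hill=point.n,
        point_estimate=point,
        fraction_failed=frac_failed,
        n_bootstraps=B,
    )


# ---------------------------------------------------------------------------
# full profile assembly


def pka_profile(
    obs: pd.DataFrame,
    bin_width: float = 1.0,
    burn_in_fraction: float = 0.0,
    B: int = 1000,
    seed: int = 0,
    min_conformations: int = DEFAULT_MIN_CONFORMATIONS,
    min_replicates: int = DEFAULT_MIN_REPLICATES,
    monotonicity_tol: float = DEFAULT_MONOTONICITY_TOL,
) -> pd.DataFrame:
    """Insertion-resolved pKa profile with Bayesian-bootstrap errors.

    Returns one row per criteria-passing bin: bin edges, bootstrap pKa and
    error, point-estimate pKa, Hill n, and the diagnostics (number of pH
    values, replicates, resample failure fraction).  Bins failing the
    criteria or the bootstrap-reliability check are omitted.
    """
    cells, per_ph = apply_bin_criteria(
        bin_observations(obs, bin_width, burn_in_fraction),
        min_conformations=min_conformations,
        min_replicates=min_replicates,
        monotonicity_tol=monotonicity_tol,
    )
    rows = []
    for (lo, hi), g in per_ph.groupby(["bin_low", "bin_high"]):
        if not g["pka_valid"].iloc[0]:
            continue
        surv = g[g["pH_valid"]].sort_values("pH")
        cell_sel = cells[
            (cells["bin_low"] == lo)
            & (cells["bin_high"] == hi)
            & cells["cell_valid"]
            & cells["pH"].isin(surv["pH"])
        ]
        samples = {
            ph: gg["avg"].to_numpy() for ph, gg in cell_sel.groupby("pH")
        }
        weights = dict(zip(surv["pH"], surv["n_conformations"].astype(float)))
        try:
            boot = bayesian_bootstrap_pka(
                samples, B=B, seed=seed, weights=weights,
                monotonicity_tol=monotonicity_tol,
            )
        except HillFitError as exc:
            log.warning("bin [%g, %g): %s", lo, hi, exc)
            continue
        rows.append(
            {
                "bin_low": lo,
                "bin_high": hi,
                "pKa": boot.pKa,
                "pKa_point": boot.point_estimate.pKa,
                "hill_n": boot.point_estimate.n,
                "error": boot.error,
                "n_pH": len(surv),
                "n_replicates": int(surv["n_replicates"].min()),
                "fraction_failed": boot.fraction_failed,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "bin_low", "bin_high", "pKa", "pKa_point", "hill_n", "error",
            "n_pH", "n_replicates", "fraction_failed",
        ],
    )


def protonation_profile(
    obs: pd.DataFrame,
    bin_width: float = 1.0,
    burn_in_fraction: float = 0.0,
    min_conformations: int = DEFAULT_MIN_CONFORMATIONS,
    min_replicates: int = DEFAULT_MIN_REPLICATES,
) -> pd.DataFrame:
    """Per-pH average protonation per insertion bin (criteria 1-2 only)."""
    _cells, per_ph = apply_bin_criteria(
        bin_observations(obs, bin_width, burn_in_fraction),
        min_conformations=min_conformations,
        min_replicates=min_replicates,
    )
    out = per_ph[per_ph["pH_valid"]][
        ["bin_low", "bin_high", "pH", "avg", "n_replicates", "n_conformations"]
    ].reset_index(drop=True)
    return out


def property_profile(
    obs: pd.DataFrame,
    value_column: str,
    bin_width: float = 1.0,
    burn_in_fraction: float = 0.0,
    min_count: int = DEFAULT_MIN_CONFORMATIONS,
    min_replicates: int = DEFAULT_MIN_REPLICATES,
) -> pd.DataFrame:
    """Generic scalar-vs-insertion profile (e.g. partner distances).

    Same binning and burn-in as the protonation machinery; the per-state
    count requirement becomes a plain >= ``min_count`` conformations per
    (bin, pH, replicate) cell, and >= ``min_replicates`` replicates per
    (bin, pH).  Returns per-bin per-pH means with replicate-level SEM.
    """
    required = {"replicate", "pH", "frame", "insertion", value_column}
    missing = required - set(obs.columns)
    if missing:
        raise ValueError(f"observations lack columns: {sorted(missing)}")
    vals = obs[value_column].to_numpy(float)
    if not np.isfinite(vals).all():
        raise ValueError(f"non-finite values in {value_column!r}")
    df = _discard_burn_in(obs, burn_in_fraction)
    k = np.floor(df["insertion"].to_numpy(float) / bin_width).astype(int)
    df = df.assign(bin_low=k * bin_width, bin_high=(k + 1) * bin_width)
    cell = (
        df.groupby(["bin_low", "bin_high", "pH", "replicate"])[value_column]
        .agg(["mean", "count"])
        .reset_index()
    )
    cell = cell[cell["count"] >= min_count]
    rows = []
    for (lo, hi, ph), g in cell.groupby(["bin_low", "bin_high", "pH"]):
        if g["replicate"].nunique() < min_replicates:
            continue
        m = g["mean"].to_numpy()
        rows.append(
            {
                "bin_low": lo,
                "bin_high": hi,
                "pH": ph,
                "mean": m.mean(),
                "sem": m.std(ddof=1) / math.sqrt(len(m)) if len(m) > 1 else 0.0,
                "n_replicates": len(m),
            }
        )
    return pd.DataFrame(
        rows, columns=["bin_low", "bin_high", "pH", "mean", "sem", "n_replicates"]
    )
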