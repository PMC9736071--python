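"""Free-energy profile along PCV-s: umbrella scheduling, WHAM, states.

Umbrella windows are laid out along the converged path with an average gap
of 0.5 in node-index units; each window restrains s harmonically and
records an s time series.  The windows are combined by the standard
self-consistent weighted-histogram (WHAM) iteration over bin probabilities
p_i and per-window free-energy constants g_k = ln Z_k:

    p_i  = sum_k n_{ki} / sum_k N_k exp(g_k - beta u_k(s_i))
    g_k  = -ln sum_i exp(-beta u_k(s_i)) p_i

iterated until max |delta g_k| < tol.  The profile is
f(s) = -(1/beta) ln p(s), shifted so its minimum is zero (k_BT units).

Transition states (TS, maxima) and intermediate states (IS, minima) are the
interior extrema of the profile with topographic prominence above a
threshold; the two profile endpoints always count as states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from .errors import (
    DisconnectedHistogramError,
    InputError,
    NonConvergenceError,
)
from .pcv import Path

__all__ = [
    "UmbrellaWindow",
    "FESProfile",
    "OverlapReport",
    "build_schedule",
    "check_overlap",
    "wham",
    "find_states",
    "delta_g",
]


@dataclass
class UmbrellaWindow:
    """One umbrella window: center, stiffness, sampled s series."""

    s_center: float
    k_umb: float
    s_series: np.ndarray
    n_equil_discard: int = 0

    def __post_init__(self):
        self.s_series = np.asarray(self.s_series, dtype=float).reshape(-1)
        if self.samples.size == 0:
            raise InputError(
                f"window at s={self.s_center}: no samples after discarding "
                f"{self.n_equil_discard}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise InputError(f"window at s={self.s_center}: non-finite samples")

    @property
    def samples(self) -> np.ndarray:
        return self.s_series[self.n_equil_discard :]


@dataclass
class FESProfile:
    """Free energy vs s with identified minima (IS) and maxima (TS)."""

    s_grid: np.ndarray
    f: np.ndarray  # k_BT, min-shifted to 0; NaN on unsampled bins
    minima: List[Tuple[float, float]] = field(default_factory=list)
    maxima: List[Tuple[float, float]] = field(default_factory=list)
    beta: float = 1.0


def build_schedule(path: Path, gap: float = 0.5) -> np.ndarray:
    """Window centers 1, 1+gap, ... N with the last center exactly N."""
    if gap <= 0:
        raise InputError("gap must be positive")
    n = path.n
    if gap >= n - 1:
        raise InputError(f"gap {gap} >= path span {n - 1}")
    centers = list(np.arange(1.0, float(n), gap))
    if abs(centers[-1] - n) > 1e-9:
        centers.append(float(n))
    else:
        centers[-1] = float(n)
    return np.asarray(centers)


@dataclass
class OverlapReport:
    """Adjacent-window histogram overlap diagnostics."""

    fractions: np.ndarray  # per adjacent pair
    passed: bool
    threshold: float
    proposed_centers: List[float]  # midpoints for failing pairs


def _hist_density(samples: np.ndarray, edges: np.ndarray) -> np.ndarray:
    h, _ = np.histogram(samples, bins=edges)
    return h / max(h.sum(), 1)


def check_overlap(
    windows: Sequence[UmbrellaWindow], threshold: float = 0.05, n_bins: int = 100
) -> OverlapReport:
    """Shared-support mass between adjacent s-histograms on a common grid."""
    if len(windows) < 2:
        raise InputError("need >=2 windows")
    ws = sorted(windows, key=lambda w: w.s_center)
    lo = min(w.samples.min() for w in ws)
    hi = max(w.samples.max() for w in ws)
    if hi <= lo:
        edges = np.linspace(lo - 0.5, lo + 0.5, n_bins + 1)
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    fracs = []
    proposed = []
    for a, b in zip(ws[:-1], ws[1:]):
        pa = _hist_density(a.samples, edges)
        pb = _hist_density(b.samples, edges)
        frac = float(np.minimum(pa, pb).sum())
        fracs.append(frac)
        if frac < threshold:
            proposed.append(0.5 * (a.s_center + b.s_center))
    fracs = np.asarray(fracs)
    return OverlapReport(
        fractions=fracs,
        passed=len(proposed) == 0,
        threshold=threshold,
        proposed_centers=proposed,
    )


def wham(
    windows: Sequence[UmbrellaWindow],
    beta: float = 1.0,
    n_bins: Optional[int] = None,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> FESProfile:
    """Self-consistent WHAM over the pooled window histograms.

    ``n_bins`` defaults to 10 bins per unit of s.  Bins with zero counts
    across all windows are masked (NaN), not imputed; if the masked bins
    split the sampled range into disconnected islands the window constants
    are only defined per island and a DisconnectedHistogramError is raised.
    """
    if len(windows) < 1:
        raise InputError("need >=1 window")
    samples = [w.samples for w in windows]
    lo = min(s.min() for s in samples)
    hi = max(s.max() for s in samples)
    if hi <= lo:
        raise InputError("all samples identical; no histogram support")
    if n_bins is None:
        n_bins = max(int(round(10 * (hi - lo))), 10)
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.stack([np.histogram(s, bins=edges)[0] for s in samples]).astype(float)
    n_k = counts.sum(axis=1)  # samples per window
    total = counts.sum(axis=0)  # per-bin totals
    occupied = total > 0

    # connectivity: islands of occupied bins separated by >=3 empty bins
    occ_idx = np.flatnonzero(occupied)
    gaps = np.diff(occ_idx)
    wide = np.flatnonzero(gaps >= 4)
    if wide.size:
        i = occ_idx[wide[0]]
        j = occ_idx[wide[0] + 1]
        raise DisconnectedHistogramError(
            f"no samples between s={centers[i]:.3f} and s={centers[j]:.3f}; "
            "add umbrella windows bridging the gap"
        )

    cb = centers[occupied]
    cnt = counts[:, occupied]
    tot = total[occupied]
    u = 0.5 * np.array([w.k_umb for w in windows])[:, None] * (
        cb[None, :] - np.array([w.s_center for w in windows])[:, None]
    ) ** 2
    log_c = -beta * u  # (K, B) log bias factors
    g = np.zeros(len(windows))
    log_nk = np.log(n_k)
    for _it in range(max_iter):
        # log denominator per bin: ln sum_k N_k exp(g_k - beta u_ki)
        a = log_nk[:, None] + g[:, None] + log_c
        amax = a.max(axis=0)
        denom = amax + np.log(np.exp(a - amax).sum(axis=0))
        log_p = np.log(tot) - denom
        log_p -= log_p.max()
        # g_k = -ln sum_i exp(log_c_ki + log_p_i)
        b = log_c + log_p[None, :]
        bmax = b.max(axis=1)
        g_new = -(bmax + np.log(np.exp(b - bmax[:, None]).sum(axis=1)))
        g_new -= g_new[0]  # gauge fix
        resid = float(np.abs(g_new - g).max())
        g = g_new
        if resid < tol:
            break
    else:
        raise NonConvergenceError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(last residual {resid:.3e})",
            residual=resid,
        )
    # normalize p over occupied bins
    p = np.exp(log_p)
    p /= p.sum()
    f_occ = -np.log(p) / beta
    f = np.full(n_bins, np.nan)
    f[occupied] = f_occ - f_occ.min()
    return FESProfile(s_grid=centers, f=f, beta=beta)


def _prominences(f: np.ndarray, kind: str) -> Tuple[np.ndarray, np.ndarray]:
    sig = f if kind == "max" else -f
    peaks, props = find_peaks(sig, prominence=0.0)
    return peaks, props["prominences"]


def find_states(profile: FESProfile, prominence: float = 0.5) -> FESProfile:
    """Populate minima (IS) and maxima (TS) with a prominence threshold.

    Works on the largest finite segment of the profile.  Interior extrema
    must clear ``prominence`` (k_BT); the segment endpoints always count as
    states (appended to the minima list as end states).  Alternation along s
    is enforced by discarding the lower-prominence violator.
    """
    finite = np.isfinite(profile.f)
    if not finite.any():
        raise InputError("profile has no finite bins")
    # largest finite run
    idx = np.flatnonzero(finite)
    splits = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, splits + 1)
    run = max(runs, key=len)
    s = profile.s_grid[run]
    f = profile.f[run]

    pk_max, prom_max = _prominences(f, "max")
    pk_min, prom_min = _prominences(f, "min")
    states = []  # (grid position, kind, prominence)
    for p, pr in zip(pk_max, prom_max):
        if pr >= prominence:
            states.append((int(p), "max", float(pr)))
    for p, pr in zip(pk_min, prom_min):
        if pr >= prominence:
            states.append((int(p), "min", float(pr)))
    states.sort()
    # enforce alternation among interior extrema: drop the lower-prominence
    # member of any same-kind neighbouring pair
    changed = True
    while changed:
        changed = False
        for i in range(len(states) - 1):
            if states[i][1] == states[i + 1][1]:
                drop = i if states[i][2] < states[i + 1][2] else i + 1
                del states[drop]
                changed = True
                break
    # the segment ends always count as states: they enter the end-state
    # (minima) list unless an interior minimum already flanks them, which
    # happens when the sampled range extends past the physical end state
    if not states or states[0][1] == "max":
        states.insert(0, (0, "min", np.inf))
    if states[-1][1] == "max" or len(states) == 1 and np.isinf(states[0][2]):
        states.append((len(f) - 1, "min", np.inf))
    minima = [(float(s[p]), float(f[p])) for p, kind, _ in states if kind == "min"]
    maxima = [(float(s[p]), float(f[p])) for p, kind, _ in states if kind == "max"]
    return replace(profile, minima=minima, maxima=maxima)


def delta_g(profile: FESProfile, state_a: float, state_b: float) -> float:
    """f(state_b) - f(state_a) in k_BT between two identified minima."""
    if not profile.minima:
        raise InputError("profile has no identified minima; run find_states first")
    if profile.s_grid.size > 1:
        half_bin = 0.5 * float(np.median(np.diff(profile.s_grid)))
    else:
        half_bin = 0.5

    def lookup(sv: float) -> float:
        for s, fv in profile.minima:
            if abs(s - sv) <= half_bin + 1e-9:
                return fv
        raise InputError(
            f"s={sv} is not an identified minimum "
            f"(minima at {[round(s, 3) for s, _ in profile.minima]})"
        )

    if state_a == state_b:
        return 0.0
    return lookup(state_b) - lookup(state_a)
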