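"""Desk-scale samplers: analytic potentials and overdamped Langevin dynamics.

The configurational sampling that a molecular-dynamics engine would provide
is replaced by Euler-Maruyama integration of overdamped (Brownian) Langevin
dynamics,

    x_{t+1} = x_t - D * beta * grad(U + U_bias) * dt + sqrt(2 D dt) * xi,

with xi standard normal per coordinate.  Path optimization only needs
equilibrium sampling in restrained ensembles, for which Brownian dynamics is
sufficient.  Energies are in k_BT at the default beta = 1, so free energies
read directly in k_BT.

Bundled potentials: the Mueller-Brown surface (standard coefficients), a 1D
double well whose inter-well offset is set by a smooth tanh step (the offset
then equals the well-depth difference essentially exactly), a 2D three-hole
surface, harmonic wells and a flat potential for null tests.

A nominal "ns" of sampling maps to integrator steps through
STEPS_PER_NS (default 1e5 steps/ns); the mapping is a bookkeeping constant,
not physics, and every step count is configurable directly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .errors import DivergedSimulationError, InputError, NonConvergenceError
from .geometry import EUCLIDEAN, Conformation, MetricSpec
from .pcv import Path, pcv_project_with_gradient

__all__ = [
    "STEPS_PER_NS",
    "Potential",
    "FlatPotential",
    "HarmonicPotential",
    "DoubleWellPotential",
    "MuellerBrownPotential",
    "ThreeHolePotential",
    "SimulationSettings",
    "Trajectory",
    "PathSRestraint",
    "CoordinateRestraint",
    "MovingTargetRestraint",
    "simulate",
    "restrained_sample_perpendicular",
    "targeted_path",
    "umbrella_run",
]

#: nominal sampling-time bookkeeping: integrator steps per "ns"
STEPS_PER_NS = 100_000


class Potential:
    """Analytic potential: energy (k_BT at beta=1), gradient, dimension."""

    dim: int = 1

    def energy(self, x: np.ndarray) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def stiffness(self) -> float:
        """Rough upper estimate of the largest curvature (for dt stability)."""
        return 1.0


class FlatPotential(Potential):
    """U = 0 everywhere; free diffusion null model."""

    def __init__(self, dim: int = 1):
        self.dim = dim

    def energy(self, x):
        return 0.0

    def gradient(self, x):
        return np.zeros_like(np.asarray(x, dtype=float))

    def stiffness(self):
        return 0.0


class HarmonicPotential(Potential):
    """U = 1/2 k |x - center|^2."""

    def __init__(self, k: float = 1.0, dim: int = 1, center: float = 0.0):
        if k <= 0:
            raise InputError("harmonic k must be positive")
        self.k = k
        self.dim = dim
        self.center = center

    def energy(self, x):
        d = np.asarray(x, dtype=float) - self.center
        return 0.5 * self.k * float(d @ d)

    def gradient(self, x):
        return self.k * (np.asarray(x, dtype=float) - self.center)

    def stiffness(self):
        return self.k


class DoubleWellPotential(Potential):
    """1D two-basin landscape with a configurable inter-well offset.

    U(x) = a (x^2 - 1)^2 + offset * sigma(x / width),  sigma = (1 + tanh)/2.

    The quartic part gives wells at x = +-1 with barrier height ``a`` (from
    the upper well); the smooth step raises the right well by ``offset``
    while leaving the stationary points at +-1 essentially untouched
    (tanh saturates well before |x| = 1 for the default width), so the
    configured offset IS the well free-energy offset at the minima, and the
    basin shapes are mirror images: at the default width the equilibrium
    occupancy ratio matches exp(-beta*offset) to within 2%.
    """

    dim = 1

    def __init__(self, a: float = 2.0, offset: float = 0.0, width: float = 0.1):
        if a <= 0 or width <= 0:
            raise InputError("a and width must be positive")
        self.a = a
        self.offset = offset
        self.width = width

    def well_offset(self) -> float:
        """Exact U(+1) - U(-1)."""
        return self.energy(np.array([1.0])) - self.energy(np.array([-1.0]))

    def energy(self, x):
        x = float(np.asarray(x).reshape(-1)[0])
        return self.a * (x * x - 1.0) ** 2 + self.offset * 0.5 * (
            1.0 + math.tanh(x / self.width)
        )

    def gradient(self, x):
        xv = float(np.asarray(x).reshape(-1)[0])
        g = 4.0 * self.a * xv * (xv * xv - 1.0)
        t = math.tanh(xv / self.width)
        g += self.offset * 0.5 * (1.0 - t * t) / self.width
        return np.array([g])

    def stiffness(self):
        # well curvature 8a plus the step's maximal |sigma''|
        return 8.0 * self.a + abs(self.offset) * 0.77 / self.width**2


class MuellerBrownPotential(Potential):
    """The standard 2D Mueller-Brown surface.

    U(x, y) = sum_k A_k exp(a_k (x-x_k)^2 + b_k (x-x_k)(y-y_k) + c_k (y-y_k)^2)

    with the canonical coefficients
    A = (-200, -100, -170, 15), a = (-1, -1, -6.5, 0.7),
    b = (0, 0, 11, 0.6), c = (-10, -10, -6.5, 0.7),
    x0 = (1, 0, -0.5, -1), y0 = (0, 0.5, 1.5, 1).

    ``scale`` multiplies the whole surface (scale=1 keeps the canonical,
    deep-well energies; at beta=1 this is effectively a low-temperature
    landscape, which is exactly what valley-floor path relaxation needs).
    """

    dim = 2
    A = np.array([-200.0, -100.0, -170.0, 15.0])
    a = np.array([-1.0, -1.0, -6.5, 0.7])
    b = np.array([0.0, 0.0, 11.0, 0.6])
    c = np.array([-10.0, -10.0, -6.5, 0.7])
    x0 = np.array([1.0, 0.0, -0.5, -1.0])
    y0 = np.array([0.0, 0.5, 1.5, 1.0])

    def __init__(self, scale: float = 1.0):
        self.scale = scale
        self._A = self.A * scale

    def energy(self, x):
        x = np.asarray(x, dtype=float).reshape(-1)
        dx = x[0] - self.x0
        dy = x[1] - self.y0
        e = self._A * np.exp(self.a * dx * dx + self.b * dx * dy + self.c * dy * dy)
        return float(e.sum())

    def gradient(self, x):
        x = np.asarray(x, dtype=float).reshape(-1)
        dx = x[0] - self.x0
        dy = x[1] - self.y0
        e = self._A * np.exp(self.a * dx * dx + self.b * dx * dy + self.c * dy * dy)
        gx = float(np.sum(e * (2.0 * self.a * dx + self.b * dy)))
        gy = float(np.sum(e * (self.b * dx + 2.0 * self.c * dy)))
        return np.array([gx, gy])

    def stiffness(self):
        # largest Hessian eigenvalue over the basin region is O(5e3) at scale 1
        return 6.0e3 * abs(self.scale)


class ThreeHolePotential(Potential):
    """2D three-hole surface: two deep side wells, one shallow upper well.

    U = 3 e^{-x^2-(y-1/3)^2} - 3 e^{-x^2-(y-5/3)^2}
        - 5 e^{-(x-1)^2-y^2} - 5 e^{-(x+1)^2-y^2}
        + 0.2 x^4 + 0.2 (y-1/3)^4
    """

    dim = 2

    def energy(self, x):
        x = np.asarray(x, dtype=float).reshape(-1)
        u, v = x[0], x[1]
        return float(
            3.0 * math.exp(-u * u - (v - 1.0 / 3.0) ** 2)
            - 3.0 * math.exp(-u * u - (v - 5.0 / 3.0) ** 2)
            - 5.0 * math.exp(-((u - 1.0) ** 2) - v * v)
            - 5.0 * math.exp(-((u + 1.0) ** 2) - v * v)
            + 0.2 * u**4
            + 0.2 * (v - 1.0 / 3.0) ** 4
        )

    def gradient(self, x):
        x = np.asarray(x, dtype=float).reshape(-1)
        u, v = x[0], x[1]
        e1 = 3.0 * math.exp(-u * u - (v - 1.0 / 3.0) ** 2)
        e2 = -3.0 * math.exp(-u * u - (v - 5.0 / 3.0) ** 2)
        e3 = -5.0 * math.exp(-((u - 1.0) ** 2) - v * v)
        e4 = -5.0 * math.exp(-((u + 1.0) ** 2) - v * v)
        gx = (
            e1 * (-2.0 * u)
            + e2 * (-2.0 * u)
            + e3 * (-2.0 * (u - 1.0))
            + e4 * (-2.0 * (u + 1.0))
            + 0.8 * u**3
        )
        gy = (
            e1 * (-2.0 * (v - 1.0 / 3.0))
            + e2 * (-2.0 * (v - 5.0 / 3.0))
            + e3 * (-2.0 * v)
            + e4 * (-2.0 * v)
            + 0.8 * (v - 1.0 / 3.0) ** 3
        )
        return np.array([gx, gy])

    def stiffness(self):
        return 30.0


@dataclass
class SimulationSettings:
    """Integrator controls: beta, diffusion D, step dt, length, seed."""

    dt: float
    n_steps: int
    seed: int
    beta: float = 1.0
    diffusion: float = 1.0
    record_every: int = 1

    def __post_init__(self):
        if self.dt <= 0 or self.diffusion <= 0 or self.beta <= 0:
            raise InputError("dt, diffusion and beta must be positive")
        if self.n_steps < 1 or self.record_every < 1:
            raise InputError("n_steps and record_every must be >= 1")

    def check_stability(self, stiffness: float):
        """Harmonic Euler stability bound: D * beta * k * dt < 2."""
        if stiffness > 0 and self.diffusion * self.beta * stiffness * self.dt >= 2.0:
            raise InputError(
                f"dt={self.dt} unstable for stiffness ~{stiffness:g} "
                f"(need D*beta*k*dt < 2)"
            )


@dataclass
class Trajectory:
    """Time-ordered configurations with optional per-frame (s, z) series."""

    positions: np.ndarray  # (n_frames, dof)
    settings: SimulationSettings
    cv_series: Optional[np.ndarray] = None  # (n_frames, 2): s, z

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def frames(self) -> List[Conformation]:
        return [Conformation.from_vector(p) for p in self.positions]

    @property
    def s_series(self) -> np.ndarray:
        if self.cv_series is None:
            raise InputError("trajectory carries no CV series")
        return self.cv_series[:, 0]

    @classmethod
    def from_conformations(
        cls, confs: Sequence[Conformation], settings: SimulationSettings
    ) -> "Trajectory":
        return cls(np.stack([c.vector for c in confs]), settings)


# ---------------------------------------------------------------------------
# bias potentials


class PathSRestraint:
    """Harmonic restraint on PCV-s: U_b = 1/2 k (s(x) - center)^2.

    z is deliberately left unrestrained: node sampling explores the
    hyperplane perpendicular to the path freely while s pins progress.
    """

    def __init__(self, path: Path, center: float, k: float):
        if k <= 0:
            raise InputError("restraint stiffness k must be positive")
        self.path = path
        self.center = float(center)
        self.k = float(k)
        # rough |ds/dx| scale for the stability gate: s advances one index
        # per typical node gap (a locally tight pair only steepens s there)
        gaps = np.linalg.norm(np.diff(path.node_matrix, axis=0), axis=1)
        self._dsdx_max = 2.0 / max(gaps.mean(), 1e-12)

    def energy(self, x, step=0):
        s, _, _ = pcv_project_with_gradient(x, self.path)
        return 0.5 * self.k * (s - self.center) ** 2

    def gradient(self, x, step=0):
        s, z, ds = pcv_project_with_gradient(x, self.path)
        self._last_cv = (s, z)
        return self.k * (s - self.center) * ds

    def cv(self, x):
        return self._last_cv

    def stiffness(self):
        return self.k * self._dsdx_max**2

    def check_gradient(self, x, eps: float = 1e-6) -> float:
        """Max relative mismatch of analytic vs central-difference bias force."""
        x = np.asarray(x, dtype=float)
        g = self.gradient(x)
        num = np.empty_like(g)
        for i in range(x.size):
            xp = x.copy()
            xm = x.copy()
            xp[i] += eps
            xm[i] -= eps
            num[i] = (self.energy(xp) - self.energy(xm)) / (2 * eps)
        scale = max(np.abs(num).max(), np.abs(g).max(), 1e-8)
        return float(np.abs(g - num).max() / scale)


class CoordinateRestraint:
    """Harmonic restraint on one bare coordinate component."""

    def __init__(self, k: float, center: float, component: int = 0):
        if k <= 0:
            raise InputError("restraint stiffness k must be positive")
        self.k = k
        self.center = center
        self.component = component

    def energy(self, x, step=0):
        return 0.5 * self.k * (float(x[self.component]) - self.center) ** 2

    def gradient(self, x, step=0):
        g = np.zeros_like(np.asarray(x, dtype=float))
        g[self.component] = self.k * (float(x[self.component]) - self.center)
        return g

    def cv(self, x):
        return (float(x[self.component]), 0.0)

    def stiffness(self):
        return self.k


class MovingTargetRestraint:
    """Shrinking distance restraint: U = 1/2 k (|x - target| - d0(step))^2."""

    def __init__(self, target: np.ndarray, k: float, d0_of_step):
        if k <= 0:
            raise InputError("restraint stiffness k must be positive")
        self.target = np.asarray(target, dtype=float)
        self.k = k
        self.d0_of_step = d0_of_step

    def _dist(self, x):
        return float(np.linalg.norm(np.asarray(x, dtype=float) - self.target))

    def energy(self, x, step=0):
        return 0.5 * self.k * (self._dist(x) - self.d0_of_step(step)) ** 2

    def gradient(self, x, step=0):
        x = np.asarray(x, dtype=float)
        diff = x - self.target
        d = float(np.linalg.norm(diff))
        if d < 1e-12:
            return np.zeros_like(diff)
        return self.k * (d - self.d0_of_step(step)) * diff / d

    def cv(self, x):
        return (self._dist(x), 0.0)

    def stiffness(self):
        return self.k


# ---------------------------------------------------------------------------
# integrator


def simulate(
    pot: Potential,
    x0,
    settings: SimulationSettings,
    bias=None,
) -> Trajectory:
    """Euler-Maruyama overdamped Langevin run; bit-reproducible per seed."""
    if isinstance(x0, Conformation):
        x = x0.vector.astype(float).copy()
    else:
        x = np.asarray(x0, dtype=float).reshape(-1).copy()
    if x.size != pot.dim:
        raise InputError(f"x0 has dim {x.size}, potential expects {pot.dim}")
    stiff = pot.stiffness() + (bias.stiffness() if bias is not None else 0.0)
    settings.check_stability(stiff)

    rng = np.random.default_rng(settings.seed)
    dt = settings.dt
    drift = settings.diffusion * settings.beta * dt
    sigma = math.sqrt(2.0 * settings.diffusion * dt)
    re = settings.record_every
    n_frames = settings.n_steps // re + 1
    out = np.empty((n_frames, x.size))
    cv_out = np.empty((n_frames, 2)) if bias is not None and hasattr(bias, "cv") else None

    def record(k, xcur):
        out[k] = xcur
        if cv_out is not None:
            cv_out[k] = bias.cv(xcur)

    if bias is not None:
        bias.gradient(x, 0)  # prime cached CV for frame 0
    record(0, x)
    k = 1
    chunk = 65536
    step = 0
    n_steps = settings.n_steps
    while step < n_steps:
        m = min(chunk, n_steps - step)
        noise = rng.standard_normal((m, x.size))
        for j in range(m):
            g = pot.gradient(x)
            if bias is not None:
                g = g + bias.gradient(x, step)
            x = x - drift * g + sigma * noise[j]
            step += 1
            if step % re == 0:
                if not np.all(np.isfinite(x)):
                    raise DivergedSimulationError(
                        f"non-finite state at step {step}", step=step
                    )
                record(k, x)
                k += 1
    if not np.all(np.isfinite(x)):
        raise DivergedSimulationError(
            f"non-finite state at step {n_steps}", step=n_steps
        )
    return Trajectory(positions=out, settings=settings, cv_series=cv_out)


def restrained_sample_perpendicular(
    pot: Potential,
    path: Path,
    node_index: int,
    k_s: float,
    settings: SimulationSettings,
) -> Trajectory:
    """Sample the hyperplane perpendicular to the path at one node.

    A harmonic restraint on PCV-s pins progress at ``node_index`` (1-based,
    node-index units); motion orthogonal to the path is unrestrained, so the
    samples trace out the local equilibrium density within the hyperplane.
    """
    if not (1 <= node_index <= path.n):
        raise InputError(
            f"node_index {node_index} outside 1..{path.n} (1-based node units)"
        )
    if k_s <= 0:
        raise InputError("k_s must be positive")
    bias = PathSRestraint(path, float(node_index), k_s)
    x0 = path.nodes[node_index - 1]
    traj = simulate(pot, x0, settings, bias=bias)
    mean_dev = float(np.abs(traj.s_series - node_index).mean())
    if mean_dev >= 0.5:
        warnings.warn(
            f"node {node_index}: mean |s - center| = {mean_dev:.2f} >= 0.5; "
            "restraint k_s may be too soft",
            stacklevel=2,
        )
    return traj


def targeted_path(
    pot: Potential,
    start: Conformation,
    target: Conformation,
    k_tmd: float,
    schedule_steps: int,
    settings: SimulationSettings,
    n_record: int,
    metric: MetricSpec = EUCLIDEAN,
    eps_target: Optional[float] = None,
) -> Path:
    """Generate an initial path by targeted (steered) dynamics.

    A harmonic restraint on the distance to ``target`` with a linearly
    shrinking set-point d0(t): d(start, target) -> 0 over ``schedule_steps``
    drags the walker to the target; the recorded frames are resampled
    uniformly in d0 into ``n_record`` path nodes.  Endpoints of the returned
    path are the exact input conformations.
    """
    if n_record < 2:
        raise InputError("n_record must be >= 2")
    if k_tmd <= 0:
        raise InputError("k_tmd must be positive")
    if settings.n_steps < schedule_steps:
        raise InputError("settings.n_steps must cover schedule_steps")
    sv = start.vector
    tv = target.vector
    d_start = float(np.linalg.norm(sv - tv))
    if d_start == 0.0:
        raise InputError("start and target coincide")

    def d0(step):
        return d_start * max(0.0, 1.0 - step / schedule_steps)

    bias = MovingTargetRestraint(tv, k_tmd, d0)
    traj = simulate(pot, start, settings, bias=bias)
    dists = np.linalg.norm(traj.positions - tv, axis=1)
    if eps_target is None:
        # restraint width plus a diffusion allowance
        eps_target = 3.0 * math.sqrt(1.0 / (settings.beta * k_tmd)) + 0.05 * d_start
    final_d = float(dists[-1])
    if final_d > eps_target:
        raise NonConvergenceError(
            f"targeted run ended {final_d:.4g} from target "
            f"(tolerance {eps_target:.4g})",
            residual=final_d,
        )
    levels = np.linspace(d_start, 0.0, n_record)
    frame_idx = [0]
    for lev in levels[1:-1]:
        frame_idx.append(int(np.argmin(np.abs(dists - lev))))
    frame_idx.append(traj.n_frames - 1)
    # connectivity repair: equal steps in d0 are not equal steps in arclength
    # on a curved route, so bridge oversized spatial gaps with recorded frames
    for _ in range(3 * n_record):
        pts = traj.positions[frame_idx]
        gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        mean_gap = gaps.mean()
        worst = int(np.argmax(gaps))
        if gaps[worst] < 2.0 * mean_gap or frame_idx[worst + 1] - frame_idx[worst] < 2:
            break
        lo, hi = frame_idx[worst], frame_idx[worst + 1]
        seg = traj.positions[lo + 1 : hi]
        span = np.maximum(
            np.linalg.norm(seg - traj.positions[lo], axis=1),
            np.linalg.norm(seg - traj.positions[hi], axis=1),
        )
        frame_idx.insert(worst + 1, lo + 1 + int(np.argmin(span)))
    vecs = [sv] + [traj.positions[i] for i in frame_idx[1:-1]] + [tv]
    # drop coincident consecutive frames (can happen for very short schedules)
    nodes: List[Conformation] = [start.copy()]
    for v in vecs[1:-1]:
        if np.linalg.norm(v - nodes[-1].vector) > 1e-12:
            nodes.append(Conformation.from_vector(v))
    if np.linalg.norm(tv - nodes[-1].vector) <= 1e-12:
        nodes.pop()
    nodes.append(target.copy())
    if len(nodes) < 2:
        nodes = [start.copy(), target.copy()]
    return Path(nodes, metric=metric)


def umbrella_run(
    pot: Potential,
    path: Path,
    s_center: float,
    k_umb: float,
    settings: SimulationSettings,
) -> Trajectory:
    """One umbrella window: harmonic bias on PCV-s centered at ``s_center``."""
    if not (1.0 <= s_center <= path.n):
        raise InputError(f"s_center {s_center} outside [1, {path.n}]")
    nearest = int(np.clip(round(s_center), 1, path.n))
    bias = PathSRestraint(path, s_center, k_umb)
    return simulate(pot, path.nodes[nearest - 1], settings, bias=bias)
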