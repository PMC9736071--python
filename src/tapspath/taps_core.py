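"""The TAPS optimization loop.

One iteration of travelling-salesman automated path searching:

1. sample the hyperplane perpendicular to the path at every interior node
   (harmonic restraint on PCV-s, z free);
2. pool the samples and pick candidate nodes as greedy density-peak medoids
   (density peaks approximate the local free-energy minima within the
   sampled hyperplanes -- paths other than the MFEP are unstable in the
   directions orthogonal to themselves, so samples accumulate on the
   valley floor);
3. reorder candidates between the fixed endpoints as the shortest open
   travelling-salesman tour (exact Held-Karp for small node counts,
   nearest-neighbour + 2-opt refinement otherwise);
4. reparametrize: insert metric midpoints into oversized gaps, delete the
   cheaper-to-remove node from undersized ones, keeping the geometric
   resolution of the path;
5. recompute lambda and monitor convergence through z_bar, the mean PCV-z
   of the new path's nodes projected on the previous (and initial) path.

Endpoints are never sampled, reordered, or deleted: the first and last node
of every iterate are bit-identical to the initial endpoint states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DivergedSimulationError, InputError, ResolutionConflictError
from .geometry import (
    Conformation,
    MetricSpec,
    distance,
    kabsch_superpose,
    pairwise_distances,
)
from .pcv import Path, path_z_distance
from .dynamics import (
    Potential,
    SimulationSettings,
    restrained_sample_perpendicular,
)

__all__ = [
    "TAPSConfig",
    "TAPSResult",
    "select_candidates",
    "tsp_reorder",
    "reparametrize",
    "taps_iteration",
    "taps_optimize",
    "mds_project",
]


@dataclass
class TAPSConfig:
    """Controls for the TAPS loop.

    ``target_resolution`` (desired mean inter-node gap) and
    ``convergence_tol`` (z_bar units, squared distance) default to values
    derived from the initial path: the initial mean gap, and 1% of the
    initial mean squared gap, respectively.
    """

    seed: int = 0
    k_s: float = 50.0
    samples_per_node: int = 400
    target_resolution: Optional[float] = None
    d_min_factor: float = 0.5
    d_max_factor: float = 1.5
    convergence_tol: Optional[float] = None
    convergence_window: int = 5
    max_iterations: int = 60
    # sampler controls
    dt: float = 1e-4
    beta: float = 1.0
    diffusion: float = 1.0
    record_every: int = 10
    burn_in_fraction: float = 0.2
    # candidate selection
    n_candidates: Optional[int] = None  # default: current interior node count
    density_radius: Optional[float] = None  # default: 0.8 * target_resolution
    max_pool: int = 4000
    archive_paths: bool = False

    def __post_init__(self):
        if not (0 < self.d_min_factor < 1 < self.d_max_factor):
            raise InputError("need d_min_factor < 1 < d_max_factor")
        if self.max_iterations < 1:
            raise InputError("max_iterations must be >= 1")
        if self.samples_per_node < 1:
            raise InputError("samples_per_node must be >= 1")
        if self.convergence_window < 1:
            raise InputError("convergence_window must be >= 1")


@dataclass
class TAPSResult:
    """Outcome of a TAPS optimization."""

    final_path: Path
    z_bar_history: List[dict]  # per-iteration {"vs_previous":, "vs_initial":}
    converged: bool
    accumulated_samples: int
    iteration_paths: Optional[List[Path]] = None


def select_candidates(
    samples, n_target: int, density_radius: float
) -> List[Conformation]:
    """Greedy density-peak medoids from pooled perpendicular samples.

    Repeatedly picks the sample with the most neighbours within
    ``density_radius`` (ties broken by lowest index), then suppresses every
    sample within that radius of the pick.  Returns at most ``n_target``
    medoids; if suppression exhausts the pool earlier a warning is issued and
    fewer are returned -- nodes are never fabricated.
    """
    if hasattr(samples, "__len__") and len(samples) and isinstance(samples[0], Conformation):
        pts = np.stack([c.vector for c in samples])
    else:
        pts = np.asarray(samples, dtype=float)
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise InputError("samples must be a non-empty (M, dof) pool")
    if pts.shape[0] < n_target:
        raise InputError(
            f"pooled sample count {pts.shape[0]} < n_target {n_target}"
        )
    if density_radius <= 0:
        raise InputError("density_radius must be positive")
    adj = cdist(pts, pts) <= density_radius
    active = np.ones(pts.shape[0], dtype=bool)
    picks: List[int] = []
    while len(picks) < n_target and active.any():
        counts = adj[:, active].sum(axis=1)
        counts[~active] = -1
        best = int(np.argmax(counts))  # argmax takes the lowest index on ties
        picks.append(best)
        active &= ~adj[best]
    if len(picks) < n_target:
        warnings.warn(
            f"only {len(picks)} candidates after suppression "
            f"(requested {n_target})",
            stacklevel=2,
        )
    return [Conformation.from_vector(pts[i]) for i in picks]


# ---------------------------------------------------------------------------
# travelling-salesman reordering

_HELD_KARP_MAX = 12


def _held_karp_path(dmat: np.ndarray) -> List[int]:
    """Exact shortest open path 0 -> n-1 visiting all nodes (Held-Karp DP)."""
    n = dmat.shape[0]
    interior = list(range(1, n - 1))
    m = len(interior)
    if m == 0:
        return [0, n - 1]
    # dp[(mask, j)] = (cost, parent) of best path 0 -> {mask} -> interior[j]
    dp = {}
    for j in range(m):
        dp[(1 << j, j)] = (dmat[0, interior[j]], -1)
    for mask in range(1, 1 << m):
        for j in range(m):
            if not mask & (1 << j) or (mask, j) not in dp:
                continue
            cost_j = dp[(mask, j)][0]
            for k in range(m):
                if mask & (1 << k):
                    continue
                nmask = mask | (1 << k)
                cand = cost_j + dmat[interior[j], interior[k]]
                cur = dp.get((nmask, k))
                if cur is None or cand < cur[0] - 1e-15:
                    dp[(nmask, k)] = (cand, j)
    full = (1 << m) - 1
    best_j, best_cost = -1, np.inf
    for j in range(m):
        c = dp[(full, j)][0] + dmat[interior[j], n - 1]
        if c < best_cost - 1e-15:
            best_cost, best_j = c, j
    order = [n - 1]
    mask, j = full, best_j
    while j != -1:
        order.append(interior[j])
        mask, j = mask ^ (1 << j), dp[(mask, j)][1]
    order.append(0)
    return order[::-1]


def _two_opt_path(dmat: np.ndarray, order: List[int]) -> List[int]:
    """Deterministic 2-opt on an open path with fixed endpoints."""
    n = len(order)
    improved = True
    while improved:
        improved = False
        for i in range(1, n - 2):
            for j in range(i + 1, n - 1):
                a, b = order[i - 1], order[i]
                c, d = order[j], order[j + 1]
                delta = dmat[a, c] + dmat[b, d] - dmat[a, b] - dmat[c, d]
                if delta < -1e-12:
                    order[i : j + 1] = order[i : j + 1][::-1]
                    improved = True
    return order


def tsp_reorder(
    candidates: Sequence[Conformation],
    start: Conformation,
    end: Conformation,
    metric: MetricSpec,
) -> List[Conformation]:
    """Order candidates into the shortest open tour from start to end.

    Exact Held-Karp dynamic programming for <= 12 interior nodes; a
    nearest-neighbour seed refined by 2-opt beyond that.  Ties break by
    lexicographic node index, so the result is deterministic.
    """
    nodes = [start, *candidates, end]
    dmat = pairwise_distances(nodes, metric)
    dups = [
        (i, j)
        for i in range(len(nodes))
        for j in range(i + 1, len(nodes))
        if dmat[i, j] == 0.0
    ]
    if dups:
        raise InputError(
            f"coincident nodes under metric at index pairs {dups}; "
            "merge duplicates before reordering"
        )
    m = len(candidates)
    if m <= _HELD_KARP_MAX:
        order = _held_karp_path(dmat)
    else:
        # nearest-neighbour seed from the start
        remaining = set(range(1, m + 1))
        order = [0]
        while remaining:
            last = order[-1]
            nxt = min(remaining, key=lambda j: (dmat[last, j], j))
            order.append(nxt)
            remaining.discard(nxt)
        order.append(m + 1)
        order = _two_opt_path(dmat, order)
    return [nodes[i] for i in order]


# ---------------------------------------------------------------------------
# geometric reparametrization


def _midpoint(a: Conformation, b: Conformation, metric: MetricSpec) -> Conformation:
    if metric.kind == "rmsd":
        _, _, b_on_a = kabsch_superpose(b, a, metric.align_idx)
        return Conformation((a.coords + b_on_a.coords) / 2.0,
                            list(a.atom_labels) if a.atom_labels is not None else None)
    return Conformation.from_vector((a.vector + b.vector) / 2.0)


def reparametrize(path: Path, config: TAPSConfig) -> Path:
    """Insert/delete nodes so all gaps fall inside the resolution band.

    While any consecutive gap exceeds d_max_factor * target_resolution the
    metric midpoint is inserted; then, while any gap is below
    d_min_factor * target_resolution, the flanking interior node whose
    removal least increases the total path length is deleted.  Deletion may
    reopen an oversized gap, so the two phases alternate (at most 10
    rounds).  Endpoints are never deleted and lambda is recomputed.
    """
    if config.target_resolution is None:
        raise InputError("config.target_resolution must be set before reparametrize")
    res = config.target_resolution
    d_max = config.d_max_factor * res
    d_min = config.d_min_factor * res
    nodes = list(path.nodes)
    metric = path.metric

    def gaps(ns):
        return [distance(ns[i], ns[i + 1], metric) for i in range(len(ns) - 1)]

    for _round in range(10):
        changed = False
        # insertion phase
        while True:
            g = gaps(nodes)
            over = [i for i, d in enumerate(g) if d > d_max]
            if not over:
                break
            i = over[0]
            nodes.insert(i + 1, _midpoint(nodes[i], nodes[i + 1], metric))
            changed = True
        # deletion phase
        while len(nodes) > 2:
            g = gaps(nodes)
            under = [(d, i) for i, d in enumerate(g) if d < d_min]
            if not under:
                break
            _, i = min(under)
            cands = [j for j in (i, i + 1) if 0 < j < len(nodes) - 1]
            if not cands:
                break  # endpoint-only violation: endpoints are never deleted
            def removal_cost(j):
                before = distance(nodes[j - 1], nodes[j], metric) + distance(
                    nodes[j], nodes[j + 1], metric
                )
                after = distance(nodes[j - 1], nodes[j + 1], metric)
                return after - before
            j = min(cands, key=lambda j: (removal_cost(j), j))
            del nodes[j]
            changed = True
        g = gaps(nodes)
        ok_max = all(d <= d_max for d in g)
        ok_min = all(d >= d_min for d in g) or len(nodes) == 2
        if ok_max and (ok_min or not changed):
            break
        if not changed:
            break
    else:
        raise ResolutionConflictError(
            "insertion/deletion oscillated for 10 rounds; widen the "
            "[d_min_factor, d_max_factor] band or change target_resolution"
        )
    return Path(nodes, metric=metric, endpoints_fixed=path.endpoints_fixed)


# ---------------------------------------------------------------------------
# the iteration and the outer loop


def _node_seed(config_seed: int, iteration: int, node: int) -> int:
    ss = np.random.SeedSequence([int(config_seed), int(iteration), int(node)])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def _resolved(config: TAPSConfig, path: Path) -> TAPSConfig:
    cfg = replace(config)
    if cfg.target_resolution is None:
        cfg.target_resolution = path.mean_gap()
    if cfg.convergence_tol is None:
        cfg.convergence_tol = 0.01 * path.mean_squared_gap()
    if cfg.density_radius is None:
        # comparable to the node spacing: one candidate per resolution element,
        # which keeps the TSP tour from zigzagging through perpendicular noise
        cfg.density_radius = 0.8 * cfg.target_resolution
    if cfg.n_candidates is None:
        # frozen at the interior count of the path seen at resolution time
        # (the initial path in taps_optimize); letting it track the current
        # node count feeds back into node-count inflation
        cfg.n_candidates = path.n - 2
    return cfg


def taps_iteration(
    pot: Potential, path: Path, config: TAPSConfig, iteration: int = 0
) -> Path:
    """One sampling -> selection -> reordering -> reparametrization cycle."""
    cfg = _resolved(config, path)
    n_interior = path.n - 2
    if n_interior < 1:
        raise InputError("path has no interior nodes to optimize")
    n_steps = cfg.samples_per_node * cfg.record_every
    pools = []
    kept_old: List[Conformation] = []
    for node_index in range(2, path.n):  # interior nodes, 1-based 2..N-1
        settings = SimulationSettings(
            dt=cfg.dt,
            n_steps=n_steps,
            seed=_node_seed(cfg.seed, iteration, node_index),
            beta=cfg.beta,
            diffusion=cfg.diffusion,
            record_every=cfg.record_every,
        )
        try:
            traj = restrained_sample_perpendicular(
                pot, path, node_index, cfg.k_s, settings
            )
        except DivergedSimulationError as exc:
            warnings.warn(
                f"node {node_index} sampling diverged ({exc}); keeping old node",
                stacklevel=2,
            )
            kept_old.append(path.nodes[node_index - 1])
            continue
        burn = int(cfg.burn_in_fraction * traj.n_frames)
        pools.append(traj.positions[burn:])
    if pools:
        pool = np.concatenate(pools, axis=0)
    else:
        pool = np.empty((0, path.node_matrix.shape[1]))
    if pool.shape[0] > cfg.max_pool:
        stride = int(np.ceil(pool.shape[0] / cfg.max_pool))
        pool = pool[::stride]
    n_target = cfg.n_candidates - len(kept_old)
    cand: List[Conformation] = []
    if n_target > 0 and pool.shape[0] > 0:
        cand = select_candidates(
            pool, min(n_target, pool.shape[0]), cfg.density_radius
        )
    cand.extend(kept_old)
    start, end = path.nodes[0], path.nodes[-1]
    # drop candidates that coincide with an endpoint or each other
    uniq: List[Conformation] = []
    anchors = [start.vector, end.vector]
    for c in cand:
        v = c.vector
        if all(np.linalg.norm(v - a) > 1e-9 for a in anchors):
            uniq.append(c)
            anchors.append(v)
    ordered = tsp_reorder(uniq, start, end, path.metric)
    new_path = Path(ordered, metric=path.metric, endpoints_fixed=True)
    return reparametrize(new_path, cfg)


def taps_optimize(
    pot: Potential, initial_path: Path, config: TAPSConfig
) -> TAPSResult:
    """Iterate TAPS until z_bar stabilizes or max_iterations is reached.

    Convergence is declared when z_bar(current, previous) stays below
    ``convergence_tol`` for ``convergence_window`` consecutive iterations.
    Running out of iterations returns a result with ``converged=False``
    rather than raising.
    """
    cfg = _resolved(config, initial_path)
    history: List[dict] = []
    archive: List[Path] = [initial_path] if cfg.archive_paths else []
    current = initial_path
    accumulated = 0
    converged = False
    streak = 0
    for it in range(1, cfg.max_iterations + 1):
        new = taps_iteration(pot, current, cfg, iteration=it)
        accumulated += cfg.samples_per_node * (current.n - 2)
        z_prev = path_z_distance(new, current)
        z_init = path_z_distance(new, initial_path)
        history.append(
            {"iteration": it, "vs_previous": z_prev, "vs_initial": z_init}
        )
        if cfg.archive_paths:
            archive.append(new)
        current = new
        streak = streak + 1 if z_prev < cfg.convergence_tol else 0
        if streak >= cfg.convergence_window:
            converged = True
            break
    return TAPSResult(
        final_path=current,
        z_bar_history=history,
        converged=converged,
        accumulated_samples=accumulated,
        iteration_paths=archive if cfg.archive_paths else None,
    )


# ---------------------------------------------------------------------------
# MDS diagnostics


def mds_project(
    paths: Sequence[Path], metric: MetricSpec, dim: int = 2
) -> List[np.ndarray]:
    """Classical (Torgerson) MDS embedding of all path nodes.

    Pools the nodes of every path, double-centers the squared distance
    matrix, and returns the top-``dim`` spectral coordinates split back per
    path.  When nodes genuinely live in a ``dim``-dimensional Euclidean
    space, embedded distances reproduce the inputs exactly (up to rotation).
    """
    if dim not in (2, 3):
        raise InputError("dim must be 2 or 3")
    if len(paths) < 1:
        raise InputError("need >=1 path")
    all_nodes = [node for p in paths for node in p.nodes]
    d = pairwise_distances(all_nodes, metric)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    neg_mass = float(np.sum(np.abs(evals[evals < 0])))
    total = float(np.sum(np.abs(evals)))
    if total > 0 and neg_mass > 0.10 * total:
        warnings.warn(
            f"non-Euclidean distances: negative eigenvalue mass "
            f"{neg_mass / total:.1%} of trace",
            stacklevel=2,
        )
    coords = evecs[:, :dim] * np.sqrt(np.clip(evals[:dim], 0.0, None))
    out = []
    ofs = 0
    for p in paths:
        out.append(coords[ofs : ofs + p.n])
        ofs += p.n
    return out
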