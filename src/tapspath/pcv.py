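"""Path collective variables (PCV).

A discretized transition path is an ordered list of N node conformations.
Any configuration x projects onto the path through Gaussian weights
``w_i = exp(-lambda * d(x, node_i)^2)``:

    s(x) = sum_i i * w_i / sum_i w_i            (progress, node-index units 1..N)
    z(x) = -(1/lambda) * ln sum_i w_i           (departure, squared-distance units)

with the smoothing constant set from the mean squared inter-node spacing,

    lambda = 2.3 * (N - 1) / sum_i d(node_i, node_{i+1})^2 .

``s`` is reported in node-index units (1..N), matching the umbrella-window
spacing convention used downstream (average gap 0.5 on s).  ``z`` carries
squared-distance units because the exponent uses d^2; in the large-lambda
limit z -> min_i d(x, node_i)^2, the squared distance to the nearest node.

Both sums run over i = 1..N.  All exponentials are evaluated after
subtracting the maximum exponent, so projections never underflow to 0/0.

The mean z of one path's nodes projected on a reference path,

    z_bar = (1/N) sum_i z(node_i | ref_path),

is the scalar convergence monitor used by the path optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .errors import DegeneratePathError, InputError
from .geometry import EUCLIDEAN, Conformation, MetricSpec, distance

__all__ = [
    "Path",
    "PathProjection",
    "compute_lambda",
    "pcv_project",
    "pcv_project_with_gradient",
    "path_z_distance",
]


@dataclass(frozen=True)
class PathProjection:
    """(s, z) projection of one configuration onto a path."""

    s: float
    z: float


def compute_lambda(path_nodes: Sequence[Conformation], metric: MetricSpec) -> float:
    """Smoothing constant lambda = 2.3 (N-1) / sum of squared node gaps."""
    n = len(path_nodes)
    if n < 2:
        raise InputError(f"path needs >=2 nodes, got {n}")
    gaps2 = []
    for i in range(n - 1):
        d = distance(path_nodes[i], path_nodes[i + 1], metric)
        if d == 0.0:
            raise DegeneratePathError(
                f"consecutive nodes {i} and {i + 1} coincide (zero gap)"
            )
        gaps2.append(d * d)
    return 2.3 * (n - 1) / float(np.sum(gaps2))


class Path:
    """Ordered node list with fixed endpoints and its lambda constant.

    lambda is recomputed from the nodes at construction; passing a stale
    value that disagrees with the nodes (relative error > 1e-12) is an error,
    so every path modification goes through a fresh ``Path``.
    """

    def __init__(
        self,
        nodes: Sequence[Conformation],
        metric: MetricSpec = EUCLIDEAN,
        lam: float | None = None,
        endpoints_fixed: bool = True,
    ):
        if len(nodes) < 2:
            raise InputError("path needs >=2 nodes")
        self.nodes: List[Conformation] = list(nodes)
        self.metric = metric
        derived = compute_lambda(self.nodes, metric)
        if lam is not None:
            if abs(lam - derived) > 1e-12 * max(abs(derived), 1.0):
                raise InputError(
                    f"stale lambda {lam!r}: nodes imply {derived!r} "
                    "(lambda must be recomputed after any path change)"
                )
        self.lam = derived
        self.endpoints_fixed = endpoints_fixed
        self._node_matrix: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def node_matrix(self) -> np.ndarray:
        """(N, dof) matrix of flattened node coordinates (euclidean fast path)."""
        if self._node_matrix is None:
            self._node_matrix = np.stack([c.vector for c in self.nodes])
        return self._node_matrix

    def mean_gap(self) -> float:
        gaps = [
            distance(self.nodes[i], self.nodes[i + 1], self.metric)
            for i in range(self.n - 1)
        ]
        return float(np.mean(gaps))

    def mean_squared_gap(self) -> float:
        # identical to 2.3 (N-1) / lambda / (N-1) but kept explicit
        gaps = [
            distance(self.nodes[i], self.nodes[i + 1], self.metric)
            for i in range(self.n - 1)
        ]
        return float(np.mean(np.square(gaps)))


def _sq_dists(x: Conformation, path: Path) -> np.ndarray:
    if path.metric.kind == "euclidean":
        diff = path.node_matrix - x.vector
        return np.einsum("ij,ij->i", diff, diff)
    return np.array(
        [distance(x, node, path.metric) ** 2 for node in path.nodes]
    )


def _project_from_d2(d2: np.ndarray, lam: float) -> PathProjection:
    a = -lam * d2  # log-weights
    m = a.max()
    w = np.exp(a - m)
    sw = w.sum()
    idx = np.arange(1, len(d2) + 1, dtype=float)
    s = float(np.dot(idx, w) / sw)
    z = float(-(m + np.log(sw)) / lam)
    return PathProjection(s=s, z=z)


def pcv_project(x: Conformation, path: Path, lam_scale: float = 1.0) -> PathProjection:
    """Project configuration ``x`` onto ``path`` -> (s, z).

    ``lam_scale`` multiplies the path's lambda; the derived lambda makes
    lambda * gap^2 = 2.3 regardless of coordinate scale, so sharp-weight
    (large-lambda) limit analyses must raise it explicitly.
    """
    if path.metric.kind == "euclidean" and x.vector.size != path.node_matrix.shape[1]:
        raise InputError(
            f"configuration dof {x.vector.size} incompatible with path dof "
            f"{path.node_matrix.shape[1]}"
        )
    if lam_scale <= 0:
        raise InputError("lam_scale must be positive")
    d2 = _sq_dists(x, path)
    return _project_from_d2(d2, path.lam * lam_scale)


def pcv_project_with_gradient(x_vec: np.ndarray, path: Path):
    """(s, z, ds/dx) for a flat state vector under a euclidean-metric path.

    The gradient is the exact chain-rule derivative of s through the Gaussian
    weights:  ds/dx = -2 lambda * sum_i (i - s) w~_i (x - node_i)  with
    normalized weights w~.  Only the euclidean metric supports analytic
    biased-dynamics forces; rmsd paths are projection-only.
    """
    if path.metric.kind != "euclidean":
        raise InputError("analytic s-gradient requires the euclidean metric")
    x_vec = np.asarray(x_vec, dtype=float)
    nodes = path.node_matrix
    diff = x_vec - nodes  # (N, dof)
    d2 = np.einsum("ij,ij->i", diff, diff)
    lam = path.lam
    a = -lam * d2
    m = a.max()
    w = np.exp(a - m)
    sw = w.sum()
    wn = w / sw
    idx = np.arange(1, len(d2) + 1, dtype=float)
    s = float(np.dot(idx, wn))
    z = float(-(m + np.log(sw)) / lam)
    grad = -2.0 * lam * ((idx - s) * wn) @ diff
    return s, z, grad


def path_z_distance(path_a: Path, ref_path: Path, lam_scale: float = 1.0) -> float:
    """Mean z of path_a's nodes projected on ref_path (z_bar monitor)."""
    if path_a.metric != ref_path.metric:
        raise InputError(
            f"metric mismatch: {path_a.metric} vs {ref_path.metric}"
        )
    zs = [pcv_project(node, ref_path, lam_scale).z for node in path_a.nodes]
    return float(np.mean(zs))
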