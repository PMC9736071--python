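"""Configurations and distance metrics.

A :class:`Conformation` is either a bare point in R^k (toy mode: one "atom"
holding the whole state vector) or an n_atoms x 3 coordinate set (molecular
mode).  Distances between conformations come in two flavours, selected by a
:class:`MetricSpec`:

* ``euclidean`` — plain Euclidean norm of the flattened coordinate difference
  (toy mode default, no alignment);
* ``rmsd`` — root-mean-square deviation over a *compute* atom set after
  optimal rigid-body (Kabsch) superposition on a possibly different *align*
  atom set.  Separating the two sets lets the aligned scaffold stay fixed
  while the deviation is measured only over the mobile region of interest.

RMSD is unweighted and reflections are excluded: the returned rotation is
always proper (det = +1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import DegenerateAlignmentError, InputError

__all__ = [
    "Conformation",
    "MetricSpec",
    "EUCLIDEAN",
    "kabsch_superpose",
    "distance",
    "pairwise_distances",
]


@dataclass
class Conformation:
    """One configuration: an ordered point set in R^k.

    ``coords`` has shape (n_points, k).  Toy-mode states are stored as a
    single point whose components are the full state vector.
    """

    coords: np.ndarray
    atom_labels: Optional[Sequence[str]] = None
    box: Optional[np.ndarray] = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 1:
            self.coords = self.coords.reshape(1, -1)
        if self.coords.ndim != 2 or self.coords.size == 0:
            raise InputError("coords must be a non-empty (n_points, k) array")
        if self.atom_labels is not None and len(self.atom_labels) != len(self.coords):
            raise InputError(
                f"atom_labels length {len(self.atom_labels)} != "
                f"{len(self.coords)} points"
            )

    @classmethod
    def from_vector(cls, vec) -> "Conformation":
        """Wrap a bare state vector as a single-point conformation."""
        return cls(np.asarray(vec, dtype=float).reshape(1, -1))

    @property
    def vector(self) -> np.ndarray:
        """Flattened coordinates (copy-free view where possible)."""
        return self.coords.reshape(-1)

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    def copy(self) -> "Conformation":
        return Conformation(
            self.coords.copy(),
            list(self.atom_labels) if self.atom_labels is not None else None,
            None if self.box is None else self.box.copy(),
        )


def _validate_idx(name: str, idx: Tuple[int, ...]):
    if len(idx) == 0:
        raise InputError(f"{name} must be non-empty for rmsd metric")
    arr = np.asarray(idx)
    if arr.min() < 0:
        raise InputError(f"{name} contains negative index (0-based indices in code)")
    if len(arr) > 1 and not np.all(np.diff(arr) > 0):
        raise InputError(f"{name} must be strictly increasing, got {list(idx)}")


@dataclass(frozen=True)
class MetricSpec:
    """Distance definition: ``euclidean`` or align/compute-set ``rmsd``."""

    kind: str = "euclidean"
    align_idx: Tuple[int, ...] = ()
    compute_idx: Tuple[int, ...] = ()

    def __post_init__(self):
        if self.kind not in ("euclidean", "rmsd"):
            raise InputError(f"unknown metric kind {self.kind!r}")
        object.__setattr__(self, "align_idx", tuple(self.align_idx))
        object.__setattr__(self, "compute_idx", tuple(self.compute_idx))
        if self.kind == "rmsd":
            _validate_idx("align_idx", self.align_idx)
            _validate_idx("compute_idx", self.compute_idx)

    def check_compatible(self, conf: Conformation):
        if self.kind == "rmsd":
            if conf.dim != 3:
                raise InputError("rmsd metric requires 3D coordinates")
            n = conf.n_points
            for name, idx in (("align_idx", self.align_idx), ("compute_idx", self.compute_idx)):
                if max(idx) >= n:
                    raise InputError(
                        f"{name} index {max(idx)} out of range for {n} atoms "
                        "(0-based indices in code)"
                    )


EUCLIDEAN = MetricSpec("euclidean")


def kabsch_superpose(
    mobile: Conformation, reference: Conformation, align_idx: Sequence[int]
) -> Tuple[np.ndarray, np.ndarray, Conformation]:
    """Optimal proper-rotation superposition of ``mobile`` onto ``reference``.

    The rotation/translation minimizing the RMSD over ``align_idx`` is found
    by SVD of the cross-covariance (Kabsch), with the usual sign correction on
    the smallest singular direction so that only proper rotations
    (det R = +1) are returned.  The whole mobile conformation is transformed,
    not just the alignment atoms.

    Returns ``(rotation, translation, aligned)`` with
    ``aligned = mobile @ R.T + t``.
    """
    idx = np.asarray(align_idx, dtype=int)
    if mobile.n_points != reference.n_points:
        raise InputError(
            f"atom count mismatch: mobile has {mobile.n_points}, "
            f"reference has {reference.n_points}"
        )
    if idx.size < 3:
        raise DegenerateAlignmentError(
            f"need >=3 alignment atoms for a unique rotation, got {idx.size}"
        )
    p = mobile.coords[idx]
    q = reference.coords[idx]
    pc = p.mean(axis=0)
    qc = q.mean(axis=0)
    p0 = p - pc
    q0 = q - qc
    # collinearity check: centered align set must span a plane
    sv = np.linalg.svd(p0, compute_uv=False)
    if sv[1] <= 1e-10 * max(sv[0], 1e-300):
        raise DegenerateAlignmentError(
            "alignment atoms are collinear: rotation about the line is undetermined"
        )
    h = p0.T @ q0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0] * (h.shape[0] - 1) + [d])
    rot = vt.T @ corr @ u.T
    trans = qc - rot @ pc
    aligned = Conformation(
        mobile.coords @ rot.T + trans,
        list(mobile.atom_labels) if mobile.atom_labels is not None else None,
    )
    return rot, trans, aligned


def distance(a: Conformation, b: Conformation, metric: MetricSpec = EUCLIDEAN) -> float:
    """Distance between two conformations under ``metric`` (length units)."""
    if a.coords.shape != b.coords.shape:
        raise InputError(
            f"incompatible shapes {a.coords.shape} vs {b.coords.shape}"
        )
    if metric.kind == "euclidean":
        return float(np.linalg.norm(a.vector - b.vector))
    metric.check_compatible(a)
    metric.check_compatible(b)
    _, _, aligned = kabsch_superpose(a, b, metric.align_idx)
    ci = np.asarray(metric.compute_idx, dtype=int)
    diff = aligned.coords[ci] - b.coords[ci]
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def pairwise_distances(
    confs: Sequence[Conformation], metric: MetricSpec = EUCLIDEAN
) -> np.ndarray:
    """Symmetric matrix of pairwise distances (zero diagonal)."""
    n = len(confs)
    if n < 2:
        raise InputError("need >=2 conformations")
    if metric.kind == "euclidean":
        x = np.stack([c.vector for c in confs])
        diff = x[:, None, :] - x[None, :, :]
        return np.sqrt(np.sum(diff * diff, axis=-1))
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                out[i, j] = out[j, i] = distance(confs[i], confs[j], metric)
            except InputError as exc:
                raise InputError(f"pair ({i}, {j}): {exc}") from exc
    return out
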