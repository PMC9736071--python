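"""File formats, trajectory analyses, fixtures and oracles.

Multi-frame XYZ is the canonical coordinate interchange; PDB is read-only.
CV series and free-energy profiles are tab-separated text with one header
line; path manifests are JSON.  Indices are 0-based in code and 1-based in
user-facing selections (PDB convention).

``make_fixture`` builds desk-scale benchmark bundles: analytic two-basin
landscapes with known well offsets, and the Mueller-Brown surface together
with an independent reference minimum-energy path obtained by the
zero-temperature string method (steepest-descent relaxation of a dense
path under the analytic gradient with equal-arclength reparametrization),
plus dense-grid located minima and saddle points.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import root

from .errors import EmptySelectionError, InputError, ParseError
from .geometry import EUCLIDEAN, Conformation, MetricSpec, distance
from .pcv import Path
from .dynamics import (
    DoubleWellPotential,
    MuellerBrownPotential,
    Potential,
    Trajectory,
)

__all__ = [
    "read_xyz",
    "write_xyz",
    "read_pdb_coords",
    "Selection",
    "ContactSpec",
    "contact_fraction",
    "rmsd_series_stats",
    "write_cv_table",
    "read_cv_table",
    "write_profile_table",
    "PathManifest",
    "write_path_manifest",
    "read_path_manifest",
    "zero_temperature_string",
    "locate_critical_points",
    "FixtureBundle",
    "make_fixture",
]


# ---------------------------------------------------------------------------
# XYZ


def write_xyz(confs: Sequence[Conformation], path: str, comment: str = ""):
    """Write multi-frame XYZ; points with <3 components are zero-padded."""
    with open(path, "w") as fh:
        for fi, conf in enumerate(confs):
            coords = conf.coords
            if coords.shape[1] < 3:
                pad = np.zeros((coords.shape[0], 3 - coords.shape[1]))
                coords = np.hstack([coords, pad])
            elif coords.shape[1] > 3:
                raise InputError("XYZ supports at most 3 components per point")
            labels = conf.atom_labels or ["X"] * conf.n_points
            fh.write(f"{conf.n_points}\n")
            fh.write(f"{comment} frame {fi}\n".strip() + "\n" if comment else f"frame {fi}\n")
            for lab, (x, y, z) in zip(labels, coords):
                fh.write(f"{lab} {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path: str, dim: int = 3) -> List[Conformation]:
    """Read multi-frame XYZ.  ``dim`` < 3 truncates padded toy coordinates."""
    confs: List[Conformation] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if lines[i].strip() == "":
            i += 1
            continue
        try:
            count = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise ParseError(
                f"line {i + 1}: expected atom count, got {lines[i].rstrip()!r}",
                line=i + 1,
            )
        if i + 1 + count >= n_lines + 1:
            raise ParseError(
                f"line {i + 1}: frame declares {count} atoms but file is truncated",
                line=i + 1,
            )
        labels = []
        coords = []
        for j in range(count):
            ln = i + 2 + j
            if ln >= n_lines:
                raise ParseError(
                    f"line {ln + 1}: truncated frame (expected {count} atom lines)",
                    line=ln + 1,
                )
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ParseError(
                    f"line {ln + 1}: expected 'element x y z', got {lines[ln].rstrip()!r}",
                    line=ln + 1,
                )
            labels.append(parts[0])
            try:
                coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError:
                raise ParseError(
                    f"line {ln + 1}: non-numeric coordinate in {lines[ln].rstrip()!r}",
                    line=ln + 1,
                )
        arr = np.asarray(coords)[:, :dim]
        confs.append(Conformation(arr, atom_labels=labels))
        i += 2 + count
    if not confs:
        raise ParseError("no frames found", line=1)
    return confs


# ---------------------------------------------------------------------------
# PDB (read-only, via biotite)


@dataclass(frozen=True)
class Selection:
    """Atom filter: 1-based residue ids and/or atom names; heavy = no H."""

    residues: Optional[Tuple[int, ...]] = None
    atom_names: Optional[Tuple[str, ...]] = None
    heavy_only: bool = False

    @classmethod
    def residue_range(cls, first: int, last: int, heavy_only: bool = False):
        return cls(residues=tuple(range(first, last + 1)), heavy_only=heavy_only)


def read_pdb_coords(path: str, selection: Optional[Selection] = None) -> Conformation:
    """First-model PDB coordinates (Angstrom) with an optional selection.

    Alternate locations keep the highest-occupancy conformer; insertion
    codes are rejected loudly.  Selections use 1-based residue numbers and
    PDB atom names.
    """
    import biotite.structure.io.pdb as pdb

    pf = pdb.PDBFile.read(path)
    atoms = pf.get_structure(model=1, altloc="occupancy", extra_fields=["occupancy"])
    if np.any(atoms.ins_code != ""):
        bad = sorted(set(atoms.res_id[atoms.ins_code != ""].tolist()))
        raise InputError(
            f"insertion codes present at residues {bad}; renumber the PDB first "
            "(1-based residue ids in selections)"
        )
    mask = np.ones(atoms.array_length(), dtype=bool)
    if selection is not None:
        if selection.residues is not None:
            mask &= np.isin(atoms.res_id, np.asarray(selection.residues))
        if selection.atom_names is not None:
            mask &= np.isin(atoms.atom_name, np.asarray(selection.atom_names))
        if selection.heavy_only:
            mask &= atoms.element != "H"
    if not mask.any():
        raise EmptySelectionError(
            f"selection {selection} matched no atoms "
            "(1-based residue ids, PDB atom names)"
        )
    sub = atoms[mask]
    labels = [
        f"{rid}:{rname.strip()}:{aname.strip()}"
        for rid, rname, aname in zip(sub.res_id, sub.res_name, sub.atom_name)
    ]
    return Conformation(np.asarray(sub.coord, dtype=float), atom_labels=labels)


# ---------------------------------------------------------------------------
# trajectory analyses


@dataclass(frozen=True)
class ContactSpec:
    """Distance-cutoff contact between two atom groups (0-based indices)."""

    group_a: Tuple[int, ...]
    group_b: Tuple[int, ...]
    cutoff: float

    def __post_init__(self):
        if self.cutoff <= 0:
            raise InputError("cutoff must be positive (Angstrom)")
        if not self.group_a or not self.group_b:
            raise InputError("contact groups must be non-empty")
        object.__setattr__(self, "group_a", tuple(self.group_a))
        object.__setattr__(self, "group_b", tuple(self.group_b))


def _frame_coords(traj: Trajectory, n_atoms: int) -> np.ndarray:
    dof = traj.positions.shape[1]
    if dof != 3 * n_atoms:
        raise InputError(
            f"trajectory dof {dof} incompatible with {n_atoms} atoms x 3"
        )
    return traj.positions.reshape(traj.n_frames, n_atoms, 3)


def contact_fraction(traj: Trajectory, spec: ContactSpec) -> float:
    """Percentage of frames with min inter-group distance <= cutoff."""
    max_idx = max(max(spec.group_a), max(spec.group_b))
    n_atoms = traj.positions.shape[1] // 3
    if traj.positions.shape[1] % 3 or max_idx >= n_atoms:
        raise InputError(
            f"contact index {max_idx} out of range for {n_atoms} atoms "
            "(0-based indices in code)"
        )
    coords = _frame_coords(traj, n_atoms)
    a = coords[:, list(spec.group_a)]  # (F, na, 3)
    b = coords[:, list(spec.group_b)]  # (F, nb, 3)
    diff = a[:, :, None, :] - b[:, None, :, :]
    dmin = np.sqrt(np.sum(diff * diff, axis=-1)).min(axis=(1, 2))
    return float(100.0 * np.mean(dmin <= spec.cutoff))


def rmsd_series_stats(
    traj: Trajectory, reference: Conformation, metric: MetricSpec
) -> Tuple[float, float]:
    """(mean, population SD) of per-frame RMSD to the reference."""
    if metric.kind != "rmsd":
        raise InputError("rmsd_series_stats requires an rmsd-kind metric")
    coords = _frame_coords(traj, reference.n_points)
    vals = []
    for fi in range(traj.n_frames):
        try:
            vals.append(distance(Conformation(coords[fi]), reference, metric))
        except InputError as exc:
            raise InputError(f"frame {fi}: {exc}") from exc
    vals = np.asarray(vals)
    return float(vals.mean()), float(vals.std())


# ---------------------------------------------------------------------------
# tab-separated tables


def write_cv_table(path: str, traj: Trajectory):
    """Tab-separated (step, s, z) series with one header line."""
    if traj.cv_series is None:
        raise InputError("trajectory carries no CV series")
    steps = np.arange(traj.n_frames) * traj.settings.record_every
    with open(path, "w") as fh:
        fh.write("step\ts\tz\n")
        for st, (s, z) in zip(steps, traj.cv_series):
            fh.write(f"{st}\t{s:.10g}\t{z:.10g}\n")


def read_cv_table(path: str) -> np.ndarray:
    """(n, 3) array of (step, s, z)."""
    data = np.loadtxt(path, skiprows=1)
    return np.atleast_2d(data)


def write_profile_table(path: str, profile) -> None:
    """Tab-separated (s, f) free-energy table with one header line."""
    with open(path, "w") as fh:
        fh.write("s\tf_kBT\n")
        for s, f in zip(profile.s_grid, profile.f):
            fh.write(f"{s:.10g}\t{f:.10g}\n")


# ---------------------------------------------------------------------------
# path manifests


MANIFEST_VERSION = "1"


@dataclass
class PathManifest:
    """Serialized description of a Path plus provenance."""

    version: str
    metric: dict
    lam: float
    node_file: str
    n_nodes: int
    config: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def write_path_manifest(
    directory: str,
    path_obj: Path,
    config: Optional[dict] = None,
    provenance: Optional[dict] = None,
    node_file: str = "nodes.xyz",
) -> PathManifest:
    import os

    os.makedirs(directory, exist_ok=True)
    write_xyz(path_obj.nodes, os.path.join(directory, node_file))
    manifest = PathManifest(
        version=MANIFEST_VERSION,
        metric={
            "kind": path_obj.metric.kind,
            "align_idx": list(path_obj.metric.align_idx),
            "compute_idx": list(path_obj.metric.compute_idx),
        },
        lam=path_obj.lam,
        node_file=node_file,
        n_nodes=path_obj.n,
        config=config or {},
        provenance=provenance or {"timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")},
    )
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest.__dict__, fh, indent=2, sort_keys=True)
    return manifest


def read_path_manifest(directory: str, dim: int = 3) -> Tuple[Path, PathManifest]:
    import os

    mf = os.path.join(directory, "manifest.json")
    if not os.path.exists(mf):
        raise InputError(f"no manifest.json in {directory}")
    with open(mf) as fh:
        raw = json.load(fh)
    manifest = PathManifest(**raw)
    metric = MetricSpec(
        kind=manifest.metric["kind"],
        align_idx=tuple(manifest.metric["align_idx"]),
        compute_idx=tuple(manifest.metric["compute_idx"]),
    )
    nodes = read_xyz(os.path.join(directory, manifest.node_file), dim=dim)
    if len(nodes) != manifest.n_nodes:
        raise InputError(
            f"manifest declares {manifest.n_nodes} nodes but "
            f"{manifest.node_file} has {len(nodes)} frames"
        )
    path_obj = Path(nodes, metric=metric)
    if abs(path_obj.lam - manifest.lam) > 1e-6 * max(abs(manifest.lam), 1.0):
        raise InputError(
            f"manifest lambda {manifest.lam} disagrees with nodes "
            f"({path_obj.lam}); manifest is stale"
        )
    return path_obj, manifest


# ---------------------------------------------------------------------------
# oracles: zero-temperature string method and critical-point location


def _central_tangents(x: np.ndarray) -> np.ndarray:
    tan = np.empty_like(x)
    tan[1:-1] = x[2:] - x[:-2]
    tan[0] = x[1] - x[0]
    tan[-1] = x[-1] - x[-2]
    return tan / np.linalg.norm(tan, axis=1, keepdims=True)


def _perp_residual(pot: Potential, x: np.ndarray) -> float:
    g = np.stack([pot.gradient(p) for p in x])
    tan = _central_tangents(x)
    g_perp = g - np.sum(g * tan, axis=1, keepdims=True) * tan
    return float(np.linalg.norm(g_perp[1:-1], axis=1).max())


def zero_temperature_string(
    pot: Potential,
    a: np.ndarray,
    b: np.ndarray,
    n_nodes: int = 101,
    string_iter: int = 2_000,
    refine_sweeps: int = 5_000,
    grad_tol: float = 1e-3,
    step_cap: float = 5e-3,
) -> np.ndarray:
    """Minimum-energy path by the zero-temperature string method.

    Phase 1: a dense path from ``a`` to ``b`` relaxes by capped steepest
    descent under the analytic gradient with equal-arclength cubic-spline
    reparametrization after every step (the classic string iteration).
    Phase 2: node positions are polished by Newton sweeps restricted to the
    direction perpendicular to the local (central-difference) tangent, which
    drives the perpendicular gradient of every interior node below
    ``grad_tol`` without letting nodes slide along the path.  Supports 2D
    potentials (perpendicular subspace is a line).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t = np.linspace(0.0, 1.0, n_nodes)[:, None]
    x = a + t * (b - a)
    alphas = np.linspace(0.0, 1.0, n_nodes)
    for _it in range(string_iter):
        g = np.stack([pot.gradient(p) for p in x])
        gmax = np.abs(g).max()
        eta = min(step_cap / max(gmax, 1e-12), 5e-4)
        x[1:-1] = x[1:-1] - eta * g[1:-1]
        seg = np.linalg.norm(np.diff(x, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        arc /= arc[-1]
        x = CubicSpline(arc, x, axis=0)(alphas)
        x[0], x[-1] = a, b
        if _it % 100 == 99 and _perp_residual(pot, x) < grad_tol:
            return x
    resid = np.inf
    for _sweep in range(refine_sweeps):
        tan = _central_tangents(x)
        nrm = np.stack([-tan[:, 1], tan[:, 0]], axis=1)  # 2D perpendicular
        moved = 0.0
        for i in range(1, n_nodes - 1):
            n_i = nrm[i]
            g_i = pot.gradient(x[i])
            a_i = float(g_i @ n_i)
            h = 1e-6
            c_i = float((pot.gradient(x[i] + h * n_i) - g_i) @ n_i / h)
            if c_i <= 1e-8:
                step = -np.sign(a_i) * min(abs(a_i) * 1e-4, 1e-4)
            else:
                step = -a_i / c_i
                step = float(np.clip(step, -0.01, 0.01))
            x[i] = x[i] + step * n_i
            moved = max(moved, abs(step))
        resid = _perp_residual(pot, x)
        if resid < grad_tol:
            return x
    from .errors import NonConvergenceError

    raise NonConvergenceError(
        f"string method residual {resid:.3e} after refinement",
        residual=resid,
    )


def locate_critical_points(
    pot: Potential,
    bounds: Sequence[Tuple[float, float]],
    n_grid: int = 200,
) -> Dict[str, List[dict]]:
    """Dense-grid location of minima and saddle points of a 2D potential.

    Grid points with locally minimal gradient norm seed Newton refinement of
    the stationary condition grad U = 0; converged roots are classified by
    the eigenvalues of a finite-difference Hessian and deduplicated.
    """
    (x0, x1), (y0, y1) = bounds
    xs = np.linspace(x0, x1, n_grid)
    ys = np.linspace(y0, y1, n_grid)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    gnorm = np.empty_like(gx)
    for i in range(n_grid):
        for j in range(n_grid):
            gnorm[i, j] = np.linalg.norm(pot.gradient(np.array([gx[i, j], gy[i, j]])))
    seeds = []
    for i in range(1, n_grid - 1):
        for j in range(1, n_grid - 1):
            window = gnorm[i - 1 : i + 2, j - 1 : j + 2]
            if gnorm[i, j] == window.min() and gnorm[i, j] < window.max():
                seeds.append((gx[i, j], gy[i, j]))
    found: Dict[str, List[dict]] = {"minima": [], "saddles": []}

    def hessian(p, h=1e-5):
        hess = np.empty((2, 2))
        for k in range(2):
            ek = np.zeros(2)
            ek[k] = h
            hess[:, k] = (pot.gradient(p + ek) - pot.gradient(p - ek)) / (2 * h)
        return 0.5 * (hess + hess.T)

    for seed in seeds:
        sol = root(pot.gradient, np.asarray(seed), tol=1e-12)
        if not sol.success:
            continue
        p = sol.x
        if np.linalg.norm(pot.gradient(p)) > 1e-8:
            continue  # runaway Newton root, not a stationary point
        if not (x0 - 0.1 <= p[0] <= x1 + 0.1 and y0 - 0.1 <= p[1] <= y1 + 0.1):
            continue
        evals = np.linalg.eigvalsh(hessian(p))
        kind = None
        if np.all(evals > 1e-8):
            kind = "minima"
        elif evals[0] < -1e-8 < 1e-8 < evals[1]:
            kind = "saddles"
        if kind is None:
            continue
        rec = {"x": p.copy(), "energy": pot.energy(p)}
        if all(np.linalg.norm(p - r["x"]) > 1e-4 for r in found[kind]):
            found[kind].append(rec)
    for kind in found:
        found[kind].sort(key=lambda r: r["energy"])
    return found


# ---------------------------------------------------------------------------
# fixtures


@dataclass
class FixtureBundle:
    """Desk-scale benchmark: potential, endpoints, oracle references."""

    kind: str
    seed: int
    potential: Potential
    start: Conformation
    end: Conformation
    oracle: dict  # kind-specific reference data
    oracle_path: Optional[Path] = None
    pdb_text: Optional[str] = None


def _mueller_brown_bundle(seed: int) -> FixtureBundle:
    pot = MuellerBrownPotential()
    crit = locate_critical_points(pot, [(-1.8, 1.3), (-0.4, 2.1)], n_grid=120)
    minima = crit["minima"]
    # the two deep wells: global minimum and the deep right-hand basin
    deep = minima[0]["x"]
    others = [m for m in minima[1:]]
    right = max(others, key=lambda m: m["x"][0])["x"]
    mfep = zero_temperature_string(pot, right, deep, n_nodes=101)
    oracle_nodes = [Conformation.from_vector(p) for p in mfep]
    oracle_path = Path(oracle_nodes, metric=EUCLIDEAN)
    energies = np.array([pot.energy(p) for p in mfep])
    return FixtureBundle(
        kind="mueller_brown_mfep",
        seed=seed,
        potential=pot,
        start=Conformation.from_vector(right),
        end=Conformation.from_vector(deep),
        oracle={
            "minima": crit["minima"],
            "saddles": crit["saddles"],
            "mfep_energies": energies,
        },
        oracle_path=oracle_path,
    )


def _double_well_bundle(seed: int, offset: float = 2.0) -> FixtureBundle:
    pot = DoubleWellPotential(a=2.0, offset=offset)
    start = Conformation.from_vector([-1.0])
    end = Conformation.from_vector([1.0])
    return FixtureBundle(
        kind="double_well",
        seed=seed,
        potential=pot,
        start=start,
        end=end,
        oracle={
            "delta_g": pot.well_offset(),
            "barrier_from_low_well": pot.energy(np.array([0.0]))
            - pot.energy(np.array([-1.0])),
        },
    )


class TwoBasin2D(Potential):
    """2D two-basin landscape: double well in x, harmonic confinement in y."""

    dim = 2

    def __init__(self, a: float = 2.0, offset: float = 2.0, ky: float = 8.0):
        self.well = DoubleWellPotential(a=a, offset=offset)
        self.ky = ky

    def energy(self, x):
        x = np.asarray(x, dtype=float).reshape(-1)
        return self.well.energy(x[:1]) + 0.5 * self.ky * x[1] ** 2

    def gradient(self, x):
        x = np.asarray(x, dtype=float).reshape(-1)
        gx = self.well.gradient(x[:1])[0]
        return np.array([gx, self.ky * x[1]])

    def stiffness(self):
        return max(self.well.stiffness(), self.ky)


def _two_basin_nd_bundle(seed: int, offset: float = 2.0) -> FixtureBundle:
    pot = TwoBasin2D(offset=offset)
    return FixtureBundle(
        kind="two_basin_nd",
        seed=seed,
        potential=pot,
        start=Conformation.from_vector([-1.0, 0.0]),
        end=Conformation.from_vector([1.0, 0.0]),
        oracle={"delta_g": pot.well.well_offset()},
    )


_PDB_RES = ["ALA", "GLY", "SER", "VAL", "LEU"]
_PDB_ATOMS = {
    "ALA": ["N", "CA", "C", "O", "CB"],
    "GLY": ["N", "CA", "C", "O"],
    "SER": ["N", "CA", "C", "O", "CB", "OG"],
    "VAL": ["N", "CA", "C", "O", "CB", "CG1", "CG2"],
    "LEU": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"],
}


def _pdb_line(serial, name, altloc, resname, chain, resid, xyz, occ, element):
    name_f = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {name_f}{altloc}{resname:>3s} {chain}{resid:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{0.0:6.2f}          "
        f"{element:>2s}"
    )


def _pdb_toy_bundle(seed: int) -> FixtureBundle:
    """Synthetic 5-residue PDB text with one altLoc pair (built, not downloaded)."""
    rng = np.random.default_rng(seed)
    lines = []
    serial = 1
    alt_kept = None
    for ri, rname in enumerate(_PDB_RES, start=1):
        base = np.array([3.8 * ri, 0.0, 0.0])
        for aname in _PDB_ATOMS[rname]:
            xyz = base + rng.normal(scale=0.8, size=3)
            if rname == "SER" and aname == "OG":
                # altLoc pair: conformer B has the higher occupancy
                alt_a = xyz + np.array([0.5, 0.0, 0.0])
                alt_b = xyz - np.array([0.5, 0.0, 0.0])
                alt_kept = alt_b
                lines.append(_pdb_line(serial, "OG", "A", rname, "A", ri, alt_a, 0.30, "O"))
                serial += 1
                lines.append(_pdb_line(serial, "OG", "B", rname, "A", ri, alt_b, 0.70, "O"))
                serial += 1
                continue
            lines.append(
                _pdb_line(serial, aname, " ", rname, "A", ri, xyz, 1.00, aname[0])
            )
            serial += 1
    lines.append("END")
    text = "\n".join(lines) + "\n"
    expected = {
        "n_atoms_total": sum(len(v) for v in _PDB_ATOMS.values()),
        "ca_count": len(_PDB_RES),
        "altloc_kept": alt_kept,
        "atoms_per_residue": {i + 1: len(_PDB_ATOMS[r]) for i, r in enumerate(_PDB_RES)},
    }
    return FixtureBundle(
        kind="pdb_toy",
        seed=seed,
        potential=DoubleWellPotential(),  # placeholder; unused for pdb fixtures
        start=Conformation.from_vector([0.0]),
        end=Conformation.from_vector([1.0]),
        oracle=expected,
        pdb_text=text,
    )


def make_fixture(kind: str, seed: int) -> FixtureBundle:
    """Build a named benchmark bundle; bit-reproducible per seed."""
    builders = {
        "mueller_brown_mfep": _mueller_brown_bundle,
        "double_well": _double_well_bundle,
        "two_basin_nd": _two_basin_nd_bundle,
        "pdb_toy": _pdb_toy_bundle,
    }
    if kind not in builders:
        raise InputError(
            f"unknown fixture kind {kind!r}; choose from {sorted(builders)}"
        )
    return builders[kind](seed)
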