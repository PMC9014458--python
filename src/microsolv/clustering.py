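"""Structural clustering of sampled configurations.

Frames are superposed with the Kabsch least-squares fit on solute
heavy atoms, equivalent waters are optionally relabeled by
minimum-cost assignment on oxygen-oxygen distances (waters are
physically indistinguishable), and the resulting pairwise RMSD matrix
is clustered with the Daura/GROMOS neighbor-count algorithm: the frame
with the most neighbors within the cutoff founds a cluster containing
itself and its neighbors, those frames are removed, and the procedure
repeats.  Founder frames are the cluster representatives.  All ties
break toward the lowest original frame index, so results are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .structures import Atom, Conformer, Ensemble


class GeometryError(ValueError):
    pass


def solute_heavy(atom: Atom) -> bool:
    """Default superposition selection: solute heavy atoms."""
    return atom.fragment_id == 0 and atom.is_heavy


def heavy(atom: Atom) -> bool:
    """Default RMSD selection: all heavy atoms (solute + water oxygens)."""
    return atom.is_heavy


def kabsch_superpose(
    reference: Conformer,
    mobile: Conformer,
    selection: Callable[[Atom], bool] = solute_heavy,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares optimal rigid superposition (Kabsch, via SVD).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile_selected @ rotation.T + translation`` best fits the
    reference selection; the rotation is proper (det = +1).  The RMSD
    is over the selected atoms.
    """
    idx_r = reference.atom_indices(selection)
    idx_m = mobile.atom_indices(selection)
    if len(idx_r) != len(idx_m):
        raise GeometryError("selections have different atom counts")
    if len(idx_r) < 3:
        raise GeometryError("need at least 3 selected atoms for superposition")
    p = reference.positions[idx_r]
    q = mobile.positions[idx_m]
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    # collinearity check: rank of the centered reference selection
    if np.linalg.matrix_rank(p0, tol=1e-8) < 2:
        raise GeometryError("selected atoms are collinear")
    h = q0.T @ p0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = pc - qc @ rot.T
    fitted = q @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - p) ** 2, axis=1))))
    return rot, trans, rmsd


def _match_waters(ref: Conformer, mob_pos: np.ndarray, mob: Conformer) -> dict[int, int]:
    """Match mobile water ids to reference water ids by O-O distance.

    Minimum-cost assignment (Hungarian algorithm) on the oxygen
    positions after the mobile frame has been superposed.
    """
    from scipy.optimize import linear_sum_assignment

    ref_ids = ref.water_fragment_ids()
    mob_ids = mob.water_fragment_ids()
    if len(ref_ids) != len(mob_ids):
        raise GeometryError("frames have different numbers of waters")
    if not ref_ids:
        return {}
    ref_o = np.array(
        [next(a.position for a in ref.water_atoms(f) if a.element == "O") for f in ref_ids]
    )
    mob_o_idx = [
        next(
            i
            for i, a in enumerate(mob.atoms)
            if a.fragment_id == f and a.element == "O"
        )
        for f in mob_ids
    ]
    mob_o = mob_pos[mob_o_idx]
    # squared distances: the assignment then minimizes the summed squared
    # deviation, i.e. exactly the RMSD contribution of the matched oxygens
    cost = np.sum((mob_o[:, None, :] - ref_o[None, :, :]) ** 2, axis=-1)
    rows, cols = linear_sum_assignment(cost)
    return {mob_ids[r]: ref_ids[c] for r, c in zip(rows, cols)}


def pair_rmsd(
    ref: Conformer,
    mob: Conformer,
    selection: Callable[[Atom], bool] = heavy,
    fit_selection: Callable[[Atom], bool] = solute_heavy,
    permutation_mode: str = "water_optimal",
) -> float:
    """Minimal RMSD between two frames after superposition.

    Fits on ``fit_selection`` (solute heavy atoms by default), measures
    RMSD over ``selection``.  In ``water_optimal`` mode water labels
    are matched by minimum-cost assignment on oxygen distances first.
    """
    rot, trans, _ = kabsch_superpose(ref, mob, fit_selection)
    mob_pos = mob.positions @ rot.T + trans

    if permutation_mode == "water_optimal":
        mapping = _match_waters(ref, mob_pos, mob)
    elif permutation_mode == "identity":
        mapping = {f: f for f in mob.water_fragment_ids()}
    else:
        raise ValueError(f"unknown permutation_mode {permutation_mode!r}")

    # reference coordinates keyed by (fragment, element, occurrence)
    def keyed(conf: Conformer, pos: np.ndarray, remap: dict[int, int] | None):
        out = {}
        seen: dict[tuple, int] = {}
        for i, a in enumerate(conf.atoms):
            if not selection(a):
                continue
            fid = a.fragment_id
            if remap is not None and fid >= 1:
                fid = remap[fid]
            key = (fid, a.element)
            k = seen.get(key, 0)
            seen[key] = k + 1
            out[(fid, a.element, k)] = pos[i]
        return out

    ref_map = keyed(ref, ref.positions, None)
    mob_map = keyed(mob, mob_pos, mapping)
    if set(ref_map) != set(mob_map):
        raise GeometryError(
            f"atom selections of frames {ref.label!r} and {mob.label!r} do not match"
        )
    diffs = np.array([ref_map[k] - mob_map[k] for k in ref_map])
    return float(np.sqrt(np.mean(np.sum(diffs**2, axis=1))))


@dataclass
class RmsdMatrix:
    values: np.ndarray
    frame_labels: list[str]
    selection: str = "heavy"
    permutation_mode: str = "water_optimal"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RMSD matrix must be square")
        if not np.allclose(v, v.T, atol=1e-8) or np.any(v < 0):
            raise ValueError("RMSD matrix must be symmetric and non-negative")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValueError("RMSD matrix diagonal must be zero")
        self.values = v


def rmsd_matrix(
    ensemble: Ensemble,
    selection: Callable[[Atom], bool] = heavy,
    permutation_mode: str = "water_optimal",
) -> RmsdMatrix:
    """Pairwise minimal-RMSD matrix over an ensemble."""
    n = len(ensemble)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                r = pair_rmsd(
                    ensemble[i], ensemble[j], selection, permutation_mode=permutation_mode
                )
            except GeometryError as exc:
                raise GeometryError(
                    f"frames {ensemble[i].label!r} / {ensemble[j].label!r}: {exc}"
                ) from exc
            m[i, j] = m[j, i] = r
    return RmsdMatrix(m, ensemble.labels, "heavy", permutation_mode)


@dataclass
class ClusterAssignment:
    """Partition of frames into clusters with founder representatives."""

    cluster_of: dict[int, int]
    representatives: list[int]  # frame index of each cluster's founder
    cutoff: float
    cluster_sizes: list[int]

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)

    def members(self, cluster: int) -> list[int]:
        return sorted(f for f, c in self.cluster_of.items() if c == cluster)


def cluster_daura(matrix: RmsdMatrix, cutoff: float = 1.0) -> ClusterAssignment:
    """Daura/GROMOS neighbor-count clustering of an RMSD matrix.

    Repeatedly the unassigned frame with the most unassigned neighbors
    within ``cutoff`` founds a cluster of itself plus those neighbors;
    ties break to the lowest frame index.  Clusters come out in
    non-increasing size order.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    v = matrix.values
    n = v.shape[0]
    if n == 0:
        raise ValueError("empty RMSD matrix")
    remaining = np.ones(n, dtype=bool)
    adj = v <= cutoff
    np.fill_diagonal(adj, False)

    cluster_of: dict[int, int] = {}
    representatives: list[int] = []
    sizes: list[int] = []
    while remaining.any():
        counts = (adj & remaining[None, :] & remaining[:, None]).sum(axis=1)
        counts = np.where(remaining, counts, -1)
        founder = int(np.argmax(counts))  # argmax takes the first (lowest) index on ties
        members = np.flatnonzero(adj[founder] & remaining).tolist()
        members = [founder] + members
        cid = len(representatives)
        for f in members:
            cluster_of[f] = cid
        remaining[members] = False
        representatives.append(founder)
        sizes.append(len(members))
    return ClusterAssignment(cluster_of, representatives, cutoff, sizes)


def select_representatives(
    assignment: ClusterAssignment, ensemble: Ensemble
) -> list[Conformer]:
    """Founder frames ordered by descending cluster size.

    Size ties keep discovery order (which itself breaks ties toward the
    lower original frame index).  Each returned conformer's label is
    suffixed with its cluster size and carries ``cluster_id`` /
    ``cluster_size`` metadata.
    """
    for f in assignment.representatives:
        if f >= len(ensemble):
            raise IndexError(f"representative frame {f} not in ensemble")
    order = sorted(
        range(assignment.n_clusters), key=lambda c: (-assignment.cluster_sizes[c], c)
    )
    out = []
    for c in order:
        frame = assignment.representatives[c]
        size = assignment.cluster_sizes[c]
        rep = ensemble[frame].copy(label=f"{ensemble[frame].label}|size={size}")
        rep.extra["cluster_id"] = str(c)
        rep.extra["cluster_size"] = str(size)
        out.append(rep)
    return out


def write_assignment_tsv(
    assignment: ClusterAssignment, ensemble: Ensemble, path: str | Path
) -> None:
    """Cluster membership as TSV: frame_label, cluster_id, is_representative."""
    lines = ["frame_label\tcluster_id\tis_representative"]
    reps = set(assignment.representatives)
    for f in range(len(ensemble)):
        lines.append(
            f"{ensemble[f].label}\t{assignment.cluster_of[f]}\t{int(f in reps)}"
        )
    Path(path).write_text("\n".join(lines) + "\n", newline="\n")
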