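"""Docking-pose post-processing.

After a peptide is docked against a receptor, the engine returns an
ensemble of poses in the receptor's coordinate frame.  This module
partitions the ensemble with k-medoids (PAM) on pairwise pose RMSD,
ranks clusters by occupancy and energy, measures the Cα–Cα contact
interface of a representative pose, and applies the selection rules of
the screen: more than 50 % of the peptide length in contact, cluster
occupancy above the ensemble average N/k, and coincidence of the most
populated with the lowest-energy cluster.

Pose RMSD is computed in the common receptor frame *without*
superposition — after docking all poses share that frame, and it is the
placement on the receptor, not the internal conformation, that
distinguishes binding modes.  Superposed RMSD is available as an option
for conformational comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import biotite.structure as struc
from scipy.spatial import cKDTree

AtomSelection = Literal["CA", "backbone", "heavy", "all"]

_BACKBONE_ATOMS = ("N", "CA", "C", "O")


def _selection_mask(atoms: struc.AtomArray, selection: AtomSelection) -> np.ndarray:
    if selection == "CA":
        return atoms.atom_name == "CA"
    if selection == "backbone":
        return np.isin(atoms.atom_name, _BACKBONE_ATOMS)
    if selection == "heavy":
        return atoms.element != "H"
    if selection == "all":
        return np.ones(atoms.array_length(), dtype=bool)
    raise ValueError(f"unknown atom selection {selection!r}")


@dataclass
class PoseEnsemble:
    """Receptor coordinates plus N peptide poses in the receptor frame."""

    receptor: struc.AtomArray
    poses: struc.AtomArrayStack
    energies: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.energies is not None:
            self.energies = np.asarray(self.energies, dtype=float)
            if len(self.energies) != self.n_poses:
                raise ValueError("one energy per pose required")

    @property
    def n_poses(self) -> int:
        return self.poses.stack_depth()

    def pose(self, i: int) -> struc.AtomArray:
        return self.poses[i]


@dataclass
class ClusterSet:
    """A k-medoids partition of a pose ensemble."""

    k: int
    labels: np.ndarray          # per-pose cluster id in 0..k-1
    medoids: np.ndarray         # pose index of each cluster's medoid
    occupancies: np.ndarray     # per-cluster pose counts
    cost: float                 # total within-cluster distance
    most_populated_cluster: int
    lowest_energy_cluster: Optional[int] = None
    energy_minima: Optional[np.ndarray] = None

    @property
    def mean_occupancy(self) -> float:
        return float(self.occupancies.sum()) / self.k

    @property
    def coincident(self) -> Optional[bool]:
        """Whether the most populated cluster is also the lowest-energy one."""
        if self.lowest_energy_cluster is None:
            return None
        return self.most_populated_cluster == self.lowest_energy_cluster


def pose_rmsd(
    a: struc.AtomArray,
    b: struc.AtomArray,
    atom_selection: AtomSelection = "CA",
    superpose: bool = False,
) -> float:
    """RMSD between two poses over an atom selection, in Å.

    By default no superposition is applied (both poses are taken in the
    shared receptor frame), so a rigid translation by ``t`` gives
    exactly ``|t|``.  With ``superpose=True`` the optimal rigid fit is
    removed first.
    """
    ma, mb = _selection_mask(a, atom_selection), _selection_mask(b, atom_selection)
    xa, xb = a.coord[ma], b.coord[mb]
    if xa.shape != xb.shape:
        raise ValueError(
            f"atom-count mismatch in selection {atom_selection!r}: "
            f"{xa.shape[0]} vs {xb.shape[0]}"
        )
    if superpose:
        xb = _superpose(xb, xa)
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


def _superpose(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Least-squares rigid fit of ``mobile`` onto ``ref`` (Kabsch)."""
    mc, rc = mobile.mean(axis=0), ref.mean(axis=0)
    H = (mobile - mc).T @ (ref - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return (mobile - mc) @ R.T + rc


def pairwise_rmsd_matrix(
    ensemble: PoseEnsemble, atom_selection: AtomSelection = "CA"
) -> np.ndarray:
    """Symmetric N×N matrix of unsuperposed pose RMSDs (vectorized)."""
    mask = _selection_mask(ensemble.poses[0], atom_selection)
    X = ensemble.poses.coord[:, mask, :]           # (N, m, 3)
    # ||xi - xj||^2 summed over atoms, via the Gram-matrix expansion
    sq = np.einsum("imk,imk->i", X, X)
    cross = np.einsum("imk,jmk->ij", X, X)
    d2 = (sq[:, None] + sq[None, :] - 2.0 * cross) / X.shape[1]
    np.clip(d2, 0.0, None, out=d2)
    m = np.sqrt(d2)
    np.fill_diagonal(m, 0.0)
    return m


# ---------------------------------------------------------------------------
# k-medoids (PAM: greedy BUILD + best-improvement SWAP)


def _pam(dist: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """PAM on a precomputed distance matrix; deterministic.

    BUILD greedily adds the medoid that most reduces total cost; SWAP
    repeatedly applies the single best (medoid, non-medoid) exchange
    until no exchange lowers the cost.  Ties are broken by lowest index.
    """
    n = dist.shape[0]
    first = int(np.argmin(dist.sum(axis=1)))
    medoids = [first]
    d_near = dist[first].copy()
    while len(medoids) < k:
        # gain of adding each candidate: sum of reductions of d_near
        gains = np.maximum(d_near[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        c = int(np.argmax(gains))
        medoids.append(c)
        d_near = np.minimum(d_near, dist[c])

    medoids = np.array(sorted(medoids))
    is_medoid = np.zeros(n, dtype=bool)
    is_medoid[medoids] = True
    while True:
        sub = dist[medoids]
        if k > 1:
            part = np.partition(sub, 1, axis=0)
            d1, d2 = part[0], part[1]       # nearest / second-nearest medoid
        else:
            d1, d2 = sub[0], np.full(n, np.inf)
        nearest = medoids[np.argmin(sub, axis=0)]
        base = d1.sum()
        best_delta, best_swap = -1e-9, None
        for mi, m in enumerate(medoids):
            d_keep = np.where(nearest == m, d2, d1)   # cost if m is removed
            # new cost for every candidate h at once: min(d_keep, dist[h])
            costs = np.minimum(d_keep[None, :], dist).sum(axis=1)
            costs[is_medoid] = np.inf
            h = int(np.argmin(costs))
            delta = costs[h] - base
            if delta < best_delta:
                best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        is_medoid[medoids[mi]] = False
        is_medoid[h] = True
        medoids[mi] = h
        medoids = np.array(sorted(medoids))
    cost = float(np.min(dist[medoids], axis=0).sum())
    return medoids, cost


def kmedoids_cluster(
    ensemble: PoseEnsemble,
    k: int,
    seed: int = 0,
    atom_selection: AtomSelection = "CA",
    dist: Optional[np.ndarray] = None,
) -> ClusterSet:
    """Partition a pose ensemble into k clusters by PAM k-medoids.

    The metric is unsuperposed pose RMSD (or a caller-supplied distance
    matrix).  PAM as implemented is deterministic, so ``seed`` is
    recorded for provenance but does not alter the result.  Occupancies
    sum to N; for N=1000 and k=10 the mean occupancy is 100.
    """
    n = ensemble.n_poses
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be in 1..{n}")
    if dist is None:
        dist = pairwise_rmsd_matrix(ensemble, atom_selection)
    medoids, cost = _pam(dist, k)
    labels = np.argmin(dist[medoids], axis=0)
    # stable tie-break: a medoid always belongs to its own cluster
    for j, m in enumerate(medoids):
        labels[m] = j
    occupancies = np.bincount(labels, minlength=k)
    most_pop = int(np.argmax(occupancies))
    lowest_cluster, minima = None, None
    if ensemble.energies is not None:
        minima = np.array([
            ensemble.energies[labels == j].min() if occupancies[j] else np.inf
            for j in range(k)
        ])
        lowest_cluster = int(np.argmin(minima))
    return ClusterSet(
        k=k, labels=labels, medoids=medoids, occupancies=occupancies,
        cost=cost, most_populated_cluster=most_pop,
        lowest_energy_cluster=lowest_cluster, energy_minima=minima,
    )


# ---------------------------------------------------------------------------
# Cα contact interface


@dataclass
class ContactReport:
    """Cα–Cα interface of one peptide pose against the receptor."""

    cutoff_A: float
    contact_residues: tuple[int, ...]   # peptide residue ids in contact
    length: int
    fraction_threshold_pct: float = 50.0

    @property
    def contacts(self) -> int:
        return len(self.contact_residues)

    @property
    def fraction_pct(self) -> float:
        return round(100.0 * self.contacts / self.length, 2)

    @property
    def selected(self) -> bool:
        """Strictly more than the threshold fraction of the length in contact."""
        return self.fraction_pct > self.fraction_threshold_pct


def contact_analysis(
    receptor: struc.AtomArray,
    pose: struc.AtomArray,
    cutoff_A: float = 10.0,
) -> ContactReport:
    """Count peptide residues whose Cα lies strictly within ``cutoff_A``
    of any receptor Cα.

    The fraction of the peptide length in contact is reported to two
    decimals, and a pose is flagged selected when it exceeds 50 %.
    """
    rec_ca = receptor[receptor.atom_name == "CA"]
    pep_ca = pose[pose.atom_name == "CA"]
    pep_res = np.unique(pose.res_id)
    if rec_ca.array_length() == 0 or pep_ca.array_length() != len(pep_res):
        missing = set(pep_res) - set(pep_ca.res_id)
        raise ValueError(
            f"missing C-alpha atoms (receptor CAs: {rec_ca.array_length()}, "
            f"peptide residues without CA: {sorted(missing)})"
        )
    tree = cKDTree(rec_ca.coord)
    dmin, _ = tree.query(pep_ca.coord)
    in_contact = tuple(int(r) for r, d in zip(pep_ca.res_id, dmin) if d < cutoff_A)
    return ContactReport(
        cutoff_A=cutoff_A, contact_residues=in_contact, length=len(pep_res)
    )


@dataclass
class SelectionResult:
    """Outcome of the Table-style selection rules for one peptide."""

    contact_selected: bool          # fraction > 50 % on a representative pose
    occupancy_selected: bool        # top-cluster occupancy strictly above N/k
    coincident: Optional[bool]      # most-populated == lowest-energy cluster
    occupancy: int
    report: ContactReport

    @property
    def selected(self) -> bool:
        ok = self.contact_selected and self.occupancy_selected
        if self.coincident is not None:
            ok = ok and self.coincident
        return ok


def select_candidates(
    clusters: ClusterSet,
    reports: Sequence[ContactReport],
) -> SelectionResult:
    """Apply the selection rules given per-cluster representative reports.

    A peptide passes when (i) the representative pose of its
    most-populated and/or lowest-energy cluster has more than 50 % of
    the peptide length in contact, (ii) the most-populated cluster's
    occupancy is strictly above the ensemble average N/k, and (iii) —
    when energies are available — the most populated cluster coincides
    with the lowest-energy one.
    """
    if len(reports) != clusters.k:
        raise ValueError("one contact report per cluster required")
    key_clusters = {clusters.most_populated_cluster}
    if clusters.lowest_energy_cluster is not None:
        key_clusters.add(clusters.lowest_energy_cluster)
    contact_ok = any(reports[j].selected for j in key_clusters)
    occ = int(clusters.occupancies[clusters.most_populated_cluster])
    occupancy_ok = occ > clusters.mean_occupancy
    return SelectionResult(
        contact_selected=contact_ok,
        occupancy_selected=occupancy_ok,
        coincident=clusters.coincident,
        occupancy=occ,
        report=reports[clusters.most_populated_cluster],
    )


# ---------------------------------------------------------------------------
# Multi-model PDB I/O


def read_pose_ensemble(
    path, receptor_chain: str = "A", peptide_chain: str = "B"
) -> PoseEnsemble:
    """Read a pose ensemble from a multi-model PDB file.

    The receptor (taken from the first model) and the peptide poses are
    distinguished by chain ID.
    """
    from biotite.structure.io.pdb import PDBFile

    stack = PDBFile.read(str(path)).get_structure()
    receptor = stack[0][stack[0].chain_id == receptor_chain]
    poses = stack[:, stack[0].chain_id == peptide_chain]
    if receptor.array_length() == 0 or poses.array_length() == 0:
        raise ValueError(
            f"chains {receptor_chain!r}/{peptide_chain!r} not found in {path}"
        )
    return PoseEnsemble(receptor=receptor, poses=poses)


def write_pose_ensemble(ensemble: PoseEnsemble, path) -> None:
    """Write receptor + poses as a multi-model PDB (receptor repeated)."""
    from biotite.structure.io.pdb import PDBFile

    n = ensemble.n_poses
    rec_stack = struc.stack([ensemble.receptor] * n)
    merged = struc.concatenate([rec_stack, ensemble.poses])
    f = PDBFile()
    f.set_structure(merged)
    f.write(str(path))
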