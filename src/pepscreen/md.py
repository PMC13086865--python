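"""Geometric descriptors of peptide–protein simulation trajectories.

Works on a trajectory held as a :class:`biotite.structure.AtomArrayStack`
(multi-model PDB or a plain per-frame coordinate table).  Descriptors:

* ``d`` — distance between the centers of mass of two selections
  (peptide vs. protein), in Å;
* ``theta`` — the inter-chain opening angle at a designated vertex Cα,
  formed by two other designated Cα atoms, in degrees;
* a three-state binding classification from ``d`` (bound / intermediate
  / unbound) with configurable thresholds;
* 2-D (d, theta) histograms on a uniform grid;
* quality-threshold conformational clustering of peptide frames under
  an RMSD cutoff, after aligning frames on the receptor;
* per-residue-pair contact lifetimes (fraction of analysed frames with
  minimum heavy-atom distance below a cutoff).

Trajectories from long production runs are analysed on a trailing
window (by default the last 70 % of frames, mirroring the practice of
discarding the approach/equilibration phase of a binding simulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc

from .poses import _superpose

# Average atomic masses (Da) for the elements of standard residues.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971,
}

BOUND_MAX_A = 45.0      # d at or below this is bound
UNBOUND_MIN_A = 50.0    # d strictly above this is unbound


def atom_masses(elements) -> np.ndarray:
    """Per-atom average masses from element symbols."""
    try:
        return np.array([ATOMIC_MASSES[el.upper()] for el in elements])
    except KeyError as exc:
        raise ValueError(f"unknown element {exc.args[0]!r}") from None


def center_of_mass(
    atoms, mask: Optional[np.ndarray] = None,
    mass_weighted: bool = True,
) -> np.ndarray:
    """Center of (mass | geometry) of a selection, in float64.

    ``atoms`` needs only ``coord`` and ``element`` arrays, so both
    :class:`biotite.structure.AtomArray` frames and plain coordinate
    holders work.
    """
    coord = np.asarray(atoms.coord, dtype=np.float64)
    elements = np.asarray(atoms.element)
    if mask is not None:
        coord, elements = coord[mask], elements[mask]
    if len(coord) == 0:
        raise ValueError("empty selection")
    if not mass_weighted:
        return coord.mean(axis=0)
    w = atom_masses(elements)
    return (coord * w[:, None]).sum(axis=0) / w.sum()


def com_distance(
    frame: struc.AtomArray,
    selection_a: np.ndarray,
    selection_b: np.ndarray,
    mass_weighted: bool = True,
) -> float:
    """Distance between the centers of mass of two selections, in Å.

    Invariant under any rigid motion applied jointly to all coordinates.
    """
    ca = center_of_mass(frame, selection_a, mass_weighted)
    cb = center_of_mass(frame, selection_b, mass_weighted)
    return float(np.linalg.norm(ca - cb))


def _resolve_atom(frame, spec) -> np.ndarray:
    """Resolve ``(chain, res_id, atom_name)`` or an index to coordinates."""
    if isinstance(spec, (int, np.integer)):
        return np.asarray(frame.coord[int(spec)], dtype=np.float64)
    chain, res_id, atom_name = spec
    mask = (
        (frame.chain_id == chain)
        & (frame.res_id == int(res_id))
        & (frame.atom_name == atom_name)
    )
    idx = np.flatnonzero(mask)
    if len(idx) != 1:
        raise ValueError(f"atom {chain}:{res_id}:{atom_name} resolved to {len(idx)} atoms")
    return np.asarray(frame.coord[idx[0]], dtype=np.float64)


def interchain_angle(frame: struc.AtomArray, atom1, vertex_atom, atom2) -> float:
    """Angle (degrees) at ``vertex_atom`` spanned by ``atom1`` and ``atom2``.

    Atoms are ``(chain, res_id, atom_name)`` triples or atom indices.
    Computed from the normalized dot product and clamped to [0, 180].
    """
    p1 = _resolve_atom(frame, atom1)
    pv = _resolve_atom(frame, vertex_atom)
    p2 = _resolve_atom(frame, atom2)
    v1, v2 = p1 - pv, p2 - pv
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("zero-length arm at the angle vertex")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def classify_binding(
    d: float, bound_max: float = BOUND_MAX_A, unbound_min: float = UNBOUND_MIN_A
) -> str:
    """Map a COM distance to bound / intermediate / unbound.

    ``d <= bound_max`` is bound, ``d > unbound_min`` is unbound; the
    band in between is an explicit intermediate state.  The two
    thresholds partition the non-negative axis, so every distance maps
    to exactly one state.
    """
    if bound_max > unbound_min:
        raise ValueError("bound_max must be <= unbound_min")
    if d <= bound_max:
        return "bound"
    if d > unbound_min:
        return "unbound"
    return "intermediate"


def descriptor_table(
    trajectory: struc.AtomArrayStack,
    selection_a: np.ndarray,
    selection_b: np.ndarray,
    angle_atoms: Optional[tuple] = None,
    bound_max: float = BOUND_MAX_A,
    unbound_min: float = UNBOUND_MIN_A,
    mass_weighted: bool = True,
) -> pd.DataFrame:
    """Per-frame descriptor table: frame index, d, theta, binding state.

    ``angle_atoms`` is the ``(atom1, vertex, atom2)`` triple defining
    the inter-chain angle; when omitted the theta column is NaN.
    """
    rows = []
    for i in range(trajectory.stack_depth()):
        frame = trajectory[i]
        d = com_distance(frame, selection_a, selection_b, mass_weighted)
        theta = (
            interchain_angle(frame, *angle_atoms) if angle_atoms is not None
            else np.nan
        )
        rows.append((i, d, theta, classify_binding(d, bound_max, unbound_min)))
    return pd.DataFrame(rows, columns=["frame", "d_A", "theta_deg", "state"])


def density_2d(
    d: Sequence[float],
    theta: Sequence[float],
    bins: int | tuple[int, int] = 151,
    ranges: Optional[tuple[tuple[float, float], tuple[float, float]]] = None,
):
    """2-D histogram of (d, theta) pairs on a uniform grid.

    Defaults to a 151 x 151 grid.  Counts sum exactly to the number of
    frames (values on the upper edge are included in the last bin).
    """
    d = np.asarray(d, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if d.size == 0:
        raise ValueError("at least one frame required")
    if ranges is not None:
        for lo, hi in ranges:
            if not hi > lo:
                raise ValueError(f"degenerate range ({lo}, {hi})")
    counts, d_edges, t_edges = np.histogram2d(d, theta, bins=bins, range=ranges)
    return counts, d_edges, t_edges


# ---------------------------------------------------------------------------
# Frame-window selection


def analysis_window(n_frames: int, discard_fraction: float = 0.3) -> slice:
    """Trailing analysis window: drop the first ``discard_fraction`` of frames.

    The default 0.3 keeps the last 70 % of each run (e.g. the last
    700 ns of a 1 microsecond replica).
    """
    if not 0.0 <= discard_fraction < 1.0:
        raise ValueError("discard_fraction must be in [0, 1)")
    start = int(np.ceil(n_frames * discard_fraction))
    if start >= n_frames:
        raise ValueError("analysis window is empty")
    return slice(start, n_frames)


# ---------------------------------------------------------------------------
# Quality-threshold conformational clustering


@dataclass
class FrameClusters:
    """QT clustering result: clusters of frame indices, largest first."""

    clusters: list          # list of np.ndarray of frame indices
    centers: list           # representative frame index per cluster
    rmsd_cutoff_A: float

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]


def qt_cluster(
    trajectory: struc.AtomArrayStack,
    atom_selection: np.ndarray,
    rmsd_cutoff_A: float = 20.0,
    align_selection: Optional[np.ndarray] = None,
) -> FrameClusters:
    """Quality-threshold (leader) clustering of trajectory frames.

    Frames are first aligned on ``align_selection`` (typically receptor
    Cα atoms) against the first frame; pairwise RMSD is then computed
    over ``atom_selection`` (typically the peptide backbone).
    Iteratively, the frame whose cutoff-neighbourhood is largest becomes
    a cluster center, its neighbourhood is removed, and the process
    repeats — so every member lies within the cutoff of its center and
    cluster sizes are non-increasing.  Ties go to the lowest frame index.
    """
    n = trajectory.stack_depth()
    if n == 0:
        raise ValueError("empty trajectory")
    coords = trajectory.coord.copy()
    if align_selection is not None:
        ref = coords[0][align_selection]
        for i in range(1, n):
            mob = coords[i][align_selection]
            mc, rc = mob.mean(axis=0), ref.mean(axis=0)
            H = (mob - mc).T @ (ref - rc)
            U, _, Vt = np.linalg.svd(H)
            dsign = np.sign(np.linalg.det(Vt.T @ U.T))
            R = Vt.T @ np.diag([1.0, 1.0, dsign]) @ U.T
            coords[i] = (coords[i] - mc) @ R.T + rc
    X = coords[:, atom_selection, :]
    sq = np.einsum("imk,imk->i", X, X)
    cross = np.einsum("imk,jmk->ij", X, X)
    d2 = (sq[:, None] + sq[None, :] - 2.0 * cross) / X.shape[1]
    np.clip(d2, 0.0, None, out=d2)
    rmsd = np.sqrt(d2)

    within = rmsd < rmsd_cutoff_A
    remaining = np.ones(n, dtype=bool)
    clusters, centers = [], []
    while remaining.any():
        counts = (within & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))     # argmax takes the lowest index on ties
        members = np.flatnonzero(within[center] & remaining)
        clusters.append(members)
        centers.append(center)
        remaining[members] = False
    order = sorted(
        range(len(clusters)), key=lambda i: (-len(clusters[i]), centers[i])
    )
    return FrameClusters(
        clusters=[clusters[i] for i in order],
        centers=[centers[i] for i in order],
        rmsd_cutoff_A=rmsd_cutoff_A,
    )


# ---------------------------------------------------------------------------
# Contact lifetimes


@dataclass
class ContactLifetimeMap:
    """Residue-pair contact lifetimes over the analysed frames.

    ``lifetimes`` maps ``((chain_a, res_a), (chain_b, res_b))`` to the
    fraction of analysed frames in which the pair's minimum heavy-atom
    distance is below the cutoff.  A pair is persistent when its
    lifetime reaches ``lifetime_threshold``.
    """

    lifetimes: dict
    cutoff_A: float
    lifetime_threshold: float
    n_frames: int

    @property
    def persistent(self) -> list:
        """Persistent pairs with lifetimes, sorted by lifetime (desc)."""
        pairs = [
            (pair, lam) for pair, lam in self.lifetimes.items()
            if lam >= self.lifetime_threshold
        ]
        return sorted(pairs, key=lambda t: (-t[1], t[0]))

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "chain_a": a[0], "res_a": a[1], "chain_b": b[0], "res_b": b[1],
                "lifetime": lam, "persistent": lam >= self.lifetime_threshold,
            }
            for (a, b), lam in sorted(
                self.lifetimes.items(), key=lambda t: (-t[1], t[0])
            )
        ]
        return pd.DataFrame(
            rows,
            columns=["chain_a", "res_a", "chain_b", "res_b", "lifetime", "persistent"],
        )


def contact_lifetimes(
    trajectory: struc.AtomArrayStack,
    group_a: np.ndarray,
    group_b: np.ndarray,
    heavy_cutoff_A: float = 5.0,
    lifetime_threshold: float = 0.5,
    frames: Optional[slice] = None,
) -> ContactLifetimeMap:
    """Per-residue-pair contact lifetimes between two atom groups.

    For each analysed frame, a residue pair (one residue from each
    group) is in contact when the minimum distance between their heavy
    (non-hydrogen) atoms is strictly below ``heavy_cutoff_A``.  The
    lifetime is the fraction of analysed frames in contact.
    """
    from scipy.spatial import cKDTree

    n = trajectory.stack_depth()
    frames = frames if frames is not None else slice(0, n)
    frame_idx = range(*frames.indices(n))
    n_frames = len(frame_idx)
    if n_frames == 0:
        raise ValueError("empty frame range")

    template = trajectory[0]
    heavy = template.element != "H"
    a_idx = np.flatnonzero(np.asarray(group_a) & heavy)
    b_idx = np.flatnonzero(np.asarray(group_b) & heavy)
    if len(a_idx) == 0 or len(b_idx) == 0:
        raise ValueError("a group has no heavy atoms")
    a_res = [
        (str(template.chain_id[i]), int(template.res_id[i])) for i in a_idx
    ]
    b_res = [
        (str(template.chain_id[i]), int(template.res_id[i])) for i in b_idx
    ]

    counts: dict = {}
    for fi in frame_idx:
        coord = trajectory.coord[fi]
        tree_b = cKDTree(coord[b_idx])
        hit_pairs = set()
        for ai, neighbours in enumerate(
            cKDTree(coord[a_idx]).query_ball_tree(tree_b, heavy_cutoff_A)
        ):
            for bi in neighbours:
                # query_ball_tree uses <=; enforce a strict cutoff
                if np.linalg.norm(coord[a_idx[ai]] - coord[b_idx[bi]]) < heavy_cutoff_A:
                    hit_pairs.add((a_res[ai], b_res[bi]))
        for pair in hit_pairs:
            counts[pair] = counts.get(pair, 0) + 1

    lifetimes = {pair: c / n_frames for pair, c in counts.items()}
    return ContactLifetimeMap(
        lifetimes=lifetimes, cutoff_A=heavy_cutoff_A,
        lifetime_threshold=lifetime_threshold, n_frames=n_frames,
    )


# ---------------------------------------------------------------------------
# Trajectory I/O


def read_trajectory_pdb(path) -> struc.AtomArrayStack:
    """Read a trajectory from a multi-model PDB file."""
    from biotite.structure.io.pdb import PDBFile

    return PDBFile.read(str(path)).get_structure()


def write_trajectory_pdb(trajectory: struc.AtomArrayStack, path) -> None:
    from biotite.structure.io.pdb import PDBFile

    f = PDBFile()
    f.set_structure(trajectory)
    f.write(str(path))


_TABLE_COLUMNS = ["frame", "chain", "res_id", "res_name", "atom_name", "element", "x", "y", "z"]


def write_trajectory_table(trajectory: struc.AtomArrayStack, path) -> None:
    """Write a trajectory as a plain whitespace-delimited coordinate table."""
    template = trajectory[0]
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for fi in range(trajectory.stack_depth()):
            coord = trajectory.coord[fi]
            for ai in range(template.array_length()):
                fh.write(
                    f"{fi}\t{template.chain_id[ai]}\t{template.res_id[ai]}\t"
                    f"{template.res_name[ai]}\t{template.atom_name[ai]}\t"
                    f"{template.element[ai]}\t"
                    f"{coord[ai, 0]:.4f}\t{coord[ai, 1]:.4f}\t{coord[ai, 2]:.4f}\n"
                )


def read_trajectory_table(path) -> struc.AtomArrayStack:
    """Read a trajectory written by :func:`write_trajectory_table`."""
    df = pd.read_csv(path, sep=r"\s+")
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns: {sorted(missing)}")
    frames = sorted(df["frame"].unique())
    first = df[df["frame"] == frames[0]]
    n_atoms = len(first)
    template = struc.AtomArray(n_atoms)
    template.chain_id = first["chain"].astype(str).to_numpy()
    template.res_id = first["res_id"].to_numpy()
    template.res_name = first["res_name"].astype(str).to_numpy()
    template.atom_name = first["atom_name"].astype(str).to_numpy()
    template.element = first["element"].astype(str).to_numpy()
    stack = struc.stack([template] * len(frames))
    for i, fi in enumerate(frames):
        sub = df[df["frame"] == fi]
        if len(sub) != n_atoms:
            raise ValueError(f"frame {fi} has {len(sub)} atoms, expected {n_atoms}")
        stack.coord[i] = sub[["x", "y", "z"]].to_numpy()
    return stack
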