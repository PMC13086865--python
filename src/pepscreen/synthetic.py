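"""Seeded synthetic-data generators with planted ground truth.

Every input the screening pipeline consumes — parent sequences, docked
pose ensembles, single poses with a planted contact interface, and MD
trajectories with planted binding states, inter-chain angles and
residue-pair contact lifetimes — can be generated here, deterministic
under a seed and emitted together with the planted truth.  The
generators stand in for external docking and simulation engines: the
structures are minimal Cα-level scaffolds that exercise the geometry
and the file formats, with no pretence of physical realism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import biotite.structure as struc

from .peptide_library import ParentProtein
from .peptides import KU2, KU3, KU1_NATIVE, PARENT_REGION
from .poses import PoseEnsemble

SCENARIOS = (
    "pose_blobs", "contact_plant", "trajectory_segments",
    "mutant_library", "parent_sequence",
)


@dataclass(frozen=True)
class GeneratorSpec:
    """A named scenario plus its parameters; identical specs give
    byte-identical outputs."""

    seed: int
    scenario: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; valid: {SCENARIOS}")


def generate(spec: GeneratorSpec):
    """Dispatch a generator spec to the matching generator function."""
    fns = {
        "pose_blobs": make_pose_blobs,
        "contact_plant": make_contact_pose,
        "trajectory_segments": make_trajectory,
        "mutant_library": _make_mutant_library,
        "parent_sequence": make_parent,
    }
    return fns[spec.scenario](seed=spec.seed, **spec.parameters)


def _make_mutant_library(seed: int = 0, reference: str = KU3.sequence,
                         n: int = 1000, max_mutations: int = 10):
    from .scoring import generate_mutants

    return generate_mutants(reference, n=n, max_mutations=max_mutations, seed=seed)


# ---------------------------------------------------------------------------
# Parent sequences


_FILLER = "GSTA"  # filler alphabet free of E/K: cannot create EEA-like motifs


def ku80_ct_scaffold() -> ParentProtein:
    """Synthetic stand-in for the 120-residue Ku80 C-terminal region.

    The published peptide segments are planted at their absolute
    positions (599-636 from Ku2/Ku4, 676-707 from Ku3/native Ku1); the
    unpublished stretches are deterministic G/S/T/A filler.  The result
    is a synthetic reconstruction suitable for enumeration, coordinate
    mapping and motif-location checks — it is NOT the database Ku80
    sequence.
    """
    lo, hi = PARENT_REGION
    seq = {}
    for pep in (KU2,):
        for i, aa in enumerate(pep.sequence):
            seq[pep.parent_start + i] = aa
    # Ku4 (607-636) extends the same block; consistency asserted below
    from .peptides import KU4
    for i, aa in enumerate(KU4.sequence):
        pos = KU4.parent_start + i
        assert seq.get(pos, aa) == aa, f"segment conflict at {pos}"
        seq[pos] = aa
    for pep in (KU3, KU1_NATIVE):
        for i, aa in enumerate(pep.sequence):
            pos = pep.parent_start + i
            assert seq.get(pos, aa) == aa, f"segment conflict at {pos}"
            seq[pos] = aa
    chars = []
    fill = 0
    for pos in range(lo, hi + 1):
        if pos in seq:
            chars.append(seq[pos])
        else:
            chars.append(_FILLER[fill % len(_FILLER)])
            fill += 1
    return ParentProtein(id="Ku80-Ct-synthetic", sequence="".join(chars),
                         numbering_offset=lo)


def make_parent(seed: int = 0, length: int = 120, offset: int = 1,
                id: str = "synthetic-parent") -> ParentProtein:
    """Random parent sequence over the 20 standard residues."""
    from .scoring import AMINO_ACIDS

    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    return ParentProtein(id=id, sequence=seq, numbering_offset=offset)


# ---------------------------------------------------------------------------
# Structure scaffolding helpers


def _ca_chain(chain_id: str, res_ids: Sequence[int], coords: np.ndarray,
              atom_name: str = "CA", element: str = "C",
              res_name: str = "ALA") -> struc.AtomArray:
    """Cα-only chain with valid PDB metadata."""
    n = len(res_ids)
    arr = struc.AtomArray(n)
    arr.chain_id = np.full(n, chain_id)
    arr.res_id = np.asarray(res_ids, dtype=int)
    arr.res_name = np.full(n, res_name)
    arr.atom_name = np.full(n, atom_name)
    arr.element = np.full(n, element)
    arr.hetero = np.zeros(n, dtype=bool)
    arr.coord = np.asarray(coords, dtype=np.float32).reshape(n, 3)
    return arr


def _receptor_scaffold(n_side: int = 4, spacing: float = 3.8,
                       chain_id: str = "A") -> struc.AtomArray:
    """Rigid dummy receptor: a Cα grid centred at the origin."""
    xs = (np.arange(n_side) - (n_side - 1) / 2) * spacing
    grid = np.array([(x, y, 0.0) for x in xs for y in xs])
    return _ca_chain(chain_id, np.arange(1, len(grid) + 1), grid)


def _peptide_template(length: int, chain_id: str = "B",
                      spacing: float = 3.8) -> struc.AtomArray:
    """Extended Cα-only peptide along x, centred at the origin."""
    xs = (np.arange(length) - (length - 1) / 2) * spacing
    coords = np.column_stack([xs, np.zeros(length), np.zeros(length)])
    return _ca_chain(chain_id, np.arange(1, length + 1), coords)


# ---------------------------------------------------------------------------
# Pose ensembles with planted cluster structure


def make_pose_blobs(
    seed: int = 0,
    n_poses: int = 1000,
    n_clusters: int = 10,
    peptide_length: int = 28,
    separation_A: float = 40.0,
    spread_A: float = 2.0,
    weights: Optional[Sequence[float]] = None,
    plant_energies: bool = False,
    lowest_energy_cluster: Optional[int] = None,
) -> tuple[PoseEnsemble, np.ndarray]:
    """Pose ensemble sampled around well-separated anchor placements.

    Each pose is the peptide template rigidly translated to one of
    ``n_clusters`` anchors plus isotropic Gaussian jitter of scale
    ``spread_A`` — so unsuperposed pose RMSD within a cluster is of
    order the jitter and between clusters of order ``separation_A``.
    Returns the ensemble together with the true cluster labels.  With
    ``plant_energies``, per-pose energies are drawn so that the stated
    cluster (default: the most populated) holds the global minimum.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if spread_A < 0:
        raise ValueError("spread must be non-negative")
    if separation_A < 4 * spread_A and spread_A > 0:
        warnings.warn(
            f"anchor separation {separation_A} < 4x spread {spread_A}: "
            "planted clusters may overlap", stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    receptor = _receptor_scaffold()
    template = _peptide_template(peptide_length)
    # anchors on a 3-D integer lattice scaled by the separation
    anchors = []
    g = int(np.ceil(n_clusters ** (1 / 3)))
    for ix in range(g):
        for iy in range(g):
            for iz in range(g):
                anchors.append((ix, iy, iz + 3))   # +z offset clears the receptor
    anchors = np.array(anchors[:n_clusters], dtype=float) * separation_A

    if weights is None:
        labels = rng.integers(n_clusters, size=n_poses)
    else:
        w = np.asarray(weights, dtype=float)
        labels = rng.choice(n_clusters, size=n_poses, p=w / w.sum())
    shifts = anchors[labels] + rng.normal(0.0, spread_A, size=(n_poses, 3))
    stack = struc.stack([template] * n_poses)
    stack.coord = stack.coord + shifts[:, None, :].astype(np.float32)

    energies = None
    if plant_energies:
        low = (int(np.argmax(np.bincount(labels, minlength=n_clusters)))
               if lowest_energy_cluster is None else lowest_energy_cluster)
        base = rng.uniform(-50.0, -30.0, size=n_clusters)
        base[low] = -100.0
        energies = base[labels] + rng.uniform(0.0, 5.0, size=n_poses)
    return PoseEnsemble(receptor=receptor, poses=stack, energies=energies), labels


def make_contact_pose(
    seed: int = 0,
    length: int = 28,
    planted_contacts: int = 18,
    cutoff: float = 10.0,
    margin: float = 2.0,
) -> tuple[struc.AtomArray, struc.AtomArray]:
    """Single pose with an exact planted Cα contact count.

    The first ``planted_contacts`` peptide residues sit strictly inside
    the cutoff of a receptor Cα; all others lie at least ``margin``
    beyond the cutoff from every receptor Cα.  Returns
    ``(receptor, pose)``.
    """
    if not 0 <= planted_contacts <= length:
        raise ValueError("planted_contacts must be in 0..length")
    receptor = _ca_chain("A", [1, 2, 3], np.array([
        [0.0, -3.8, 0.0], [0.0, 0.0, 0.0], [0.0, 3.8, 0.0],
    ]))
    rng = np.random.default_rng(seed)
    coords = np.zeros((length, 3))
    inner = 0.5 * cutoff
    for i in range(planted_contacts):
        # ring strictly inside the cutoff around the central receptor Cα
        phi = 2 * np.pi * i / max(planted_contacts, 1)
        coords[i] = (inner * np.cos(phi), inner * np.sin(phi) * 0.3, 2.0)
    far = cutoff + margin
    for j in range(planted_contacts, length):
        coords[j] = (far + 2.0 * (j - planted_contacts) + 1e-3, 0.0, 0.0)
    pose = _ca_chain("B", np.arange(1, length + 1), coords)
    return receptor, pose


def make_selection_ensemble(
    seed: int = 0,
    length: int = 28,
    planted_contacts: int = 18,
    n_poses: int = 100,
    n_clusters: int = 5,
    winner_weight: float = 3.0,
    jitter_A: float = 0.2,
    separation_A: float = 60.0,
    cutoff: float = 10.0,
) -> tuple[PoseEnsemble, np.ndarray, int]:
    """Pose ensemble with a planted winning cluster.

    Cluster 0 is built around a pose with exactly ``planted_contacts``
    Cα contacts (margins large against the jitter), carries
    ``winner_weight`` times the population of each other cluster, and
    holds the lowest energies — so it passes the contact-fraction,
    occupancy and coincidence selection rules by construction, and the
    other clusters (translated far from the receptor) fail the contact
    rule.  Returns ``(ensemble, true_labels, winner_label)``.
    """
    receptor, contact_pose = make_contact_pose(
        seed=seed, length=length, planted_contacts=planted_contacts,
        cutoff=cutoff, margin=2.0 + 4 * jitter_A,
    )
    rng = np.random.default_rng(seed)
    w = np.full(n_clusters, 1.0)
    w[0] = winner_weight
    labels = rng.choice(n_clusters, size=n_poses, p=w / w.sum())
    # guarantee the plant regardless of sampling noise: cluster 0 must be
    # strictly the most populated and strictly above the N/k average
    counts = np.bincount(labels, minlength=n_clusters)
    floor = max(int(counts[1:].max()) + 1 if n_clusters > 1 else 0,
                n_poses // n_clusters + 1)
    deficit = floor - int(counts[0])
    if deficit > 0:
        movable = np.flatnonzero(labels != 0)[:deficit]
        labels[movable] = 0
    anchors = np.zeros((n_clusters, 3))
    for j in range(1, n_clusters):
        anchors[j] = (0.0, 0.0, j * separation_A)
    stack = struc.stack([contact_pose] * n_poses)
    shifts = anchors[labels] + rng.normal(0.0, jitter_A, size=(n_poses, 3))
    stack.coord = stack.coord + shifts[:, None, :].astype(np.float32)
    energies = np.where(labels == 0,
                        rng.uniform(-100.0, -90.0, size=n_poses),
                        rng.uniform(-50.0, -30.0, size=n_poses))
    return PoseEnsemble(receptor=receptor, poses=stack, energies=energies), labels, 0


def make_planted_mutant_library(
    reference: str,
    n: int = 1000,
    conserved_positions: Sequence[int] = (),
    p_mutate: float = 0.6,
    seed: int = 0,
) -> tuple[list[str], set[int]]:
    """Substitution library with protected positions (never mutated).

    Each unprotected position mutates independently with probability
    ``p_mutate`` (substitution uniform over the 19 alternatives);
    protected 1-based ``conserved_positions`` always keep the reference
    residue.  With ``p_mutate > 0.5`` the expected reference-residue
    frequency at unprotected columns falls below one half, so a
    plurality-at-half consensus recovers exactly the protected
    positions (up to sampling noise).  Returns the member list and the
    protected-position set.
    """
    from .scoring import AMINO_ACIDS

    rng = np.random.default_rng(seed)
    L = len(reference)
    protected = set(int(p) for p in conserved_positions)
    if any(not 1 <= p <= L for p in protected):
        raise ValueError("conserved positions must be within the reference")
    alternatives = {
        aa: [b for b in AMINO_ACIDS if b != aa] for aa in AMINO_ACIDS
    }
    members = []
    for _ in range(n):
        seq = list(reference)
        for pos in range(1, L + 1):
            if pos in protected:
                continue
            if rng.random() < p_mutate:
                alts = alternatives[reference[pos - 1]]
                seq[pos - 1] = alts[int(rng.integers(len(alts)))]
        members.append("".join(seq))
    return members, protected


# ---------------------------------------------------------------------------
# Trajectories with planted states, angles and contact lifetimes


#: Default COM distance (Å) realised for each planted binding state.
STATE_DISTANCES = {"bound": 40.0, "intermediate": 47.5, "unbound": 60.0}


@dataclass
class TrajectoryTruth:
    """Planted ground truth emitted alongside a synthetic trajectory."""

    states: list                    # per-frame planted state
    d_A: np.ndarray                 # per-frame planted COM distance
    theta_deg: np.ndarray           # per-frame planted inter-chain angle
    contact_lifetimes: dict         # planted pair -> realised lifetime
    protein_mask: np.ndarray
    peptide_mask: np.ndarray
    angle_atoms: tuple


def make_trajectory(
    seed: int = 0,
    segments: Sequence[tuple[str, int]] = (("bound", 50), ("unbound", 50)),
    theta_deg: float | Sequence[float] = 120.0,
    planted_contacts: Sequence[tuple[int, int, float]] = (),
    state_distances: Optional[dict] = None,
    d_jitter_A: float = 1.0,
    contact_cutoff_A: float = 5.0,
) -> tuple[struc.AtomArrayStack, TrajectoryTruth]:
    """Trajectory with planted binding segments, angles and contacts.

    The system is a minimal dimer-plus-peptide scaffold: chain A carries
    Cα atoms for residues 95 and 214 (the angle arm and vertex), chain B
    the residue-95 Cα of the second protomer, and chain P the peptide.
    Per frame, the peptide's center of mass is placed at the planted
    distance ``d`` from the protein's center of mass (inside the
    interval of the segment's state), the chain-B arm realises the
    planted angle exactly, and planted peptide/protein residue contacts
    are toggled on a deterministic frame schedule to hit each target
    lifetime to within 1/n_frames.  ``planted_contacts`` entries are
    ``(peptide_res_id, protein_res_id, target_lifetime)`` with the
    protein residue on chain A.

    Contact toggling moves paired peptide atoms symmetrically about the
    peptide center of mass, so the planted ``d`` is preserved exactly.
    """
    from .md import classify_binding

    state_d = dict(STATE_DISTANCES)
    if state_distances:
        state_d.update(state_distances)
    segments = list(segments)
    n_frames = sum(n for _, n in segments)
    if n_frames == 0:
        raise ValueError("at least one frame required")
    thetas = (
        [float(theta_deg)] * len(segments)
        if np.isscalar(theta_deg) else [float(t) for t in theta_deg]
    )
    if len(thetas) != len(segments):
        raise ValueError("one theta per segment required")

    # protein scaffold: A:95 and A:214 (vertex) plus B:95 (mobile arm)
    arm = 15.0
    chain_a = _ca_chain("A", [95, 214], np.array([
        [arm, 0.0, 0.0], [0.0, 0.0, 0.0],
    ]))
    chain_b = _ca_chain("B", [95], np.array([[0.0, arm, 0.0]]))

    planted = list(planted_contacts)
    for pep_res, prot_res, lam in planted:
        if prot_res not in (95, 214):
            raise ValueError("planted protein residue must be 95 or 214 (chain A)")
        if not 0.0 <= lam <= 1.0:
            raise ValueError("target lifetime must be in [0, 1]")
    # peptide: one contact atom + one mirror atom per planted pair,
    # plus two anchor atoms; all carbons of equal mass
    contact_res = [p[0] for p in planted]
    if len(set(contact_res)) != len(contact_res):
        raise ValueError("planted peptide residues must be distinct")
    n_pep = 2 * len(planted) + 2
    pep_res_ids = []
    for r in contact_res:
        pep_res_ids.append(r)
    mirror_start = (max(contact_res) if contact_res else 0) + 1000
    for i in range(len(planted)):
        pep_res_ids.append(mirror_start + i)
    pep_res_ids += [mirror_start + len(planted), mirror_start + len(planted) + 1]
    peptide = _ca_chain("P", pep_res_ids, np.zeros((n_pep, 3)))

    frame0 = struc.concatenate([chain_a, chain_b, peptide])
    protein_mask = np.isin(frame0.chain_id, ["A", "B"])
    peptide_mask = frame0.chain_id == "P"
    prot_coord_idx = {95: 0, 214: 1}    # indices within chain A

    # deterministic contact schedule: ON in the first round(lam*n) frames
    on_counts = [int(round(lam * n_frames)) for _, _, lam in planted]

    rng = np.random.default_rng(seed)
    states, d_list = [], []
    theta_list = []
    stack = struc.stack([frame0] * n_frames)
    fi = 0
    for (state, n_seg), th in zip(segments, thetas):
        for _ in range(n_seg):
            d = state_d[state] + rng.uniform(-d_jitter_A, d_jitter_A)
            if state_distances is None and classify_binding(d) != state:
                raise ValueError(
                    f"d_jitter_A={d_jitter_A} pushes d outside the "
                    f"{state!r} interval"
                )
            coord = stack.coord[fi]
            # chain B arm realises theta exactly (rotation in the xy-plane)
            coord[2] = [arm * np.cos(np.radians(th)),
                        arm * np.sin(np.radians(th)), 0.0]
            prot_com = coord[:3].mean(axis=0)   # three equal-mass carbons
            pep_com = prot_com + np.array([0.0, 0.0, d])
            # base placement: all peptide atoms in a tight bundle at the COM
            base = pep_com + np.array([
                [0.4 * k - 0.2 * (n_pep - 1), 0.0, 0.0] for k in range(n_pep)
            ])
            for ci, (pep_res, prot_res, _lam) in enumerate(planted):
                if fi < on_counts[ci]:
                    target = coord[prot_coord_idx[prot_res]] + np.array([0.0, 0.0, 3.0])
                    disp = target - base[ci]
                    base[ci] += disp
                    base[len(planted) + ci] -= disp   # mirror keeps the COM
            coord[3:] = base
            stack.coord[fi] = coord
            states.append(state)
            d_list.append(d)
            theta_list.append(th)
            fi += 1

    lifetimes = {
        (("P", pep_res), ("A", prot_res)): on_counts[ci] / n_frames
        for ci, (pep_res, prot_res, _lam) in enumerate(planted)
    }
    truth = TrajectoryTruth(
        states=states,
        d_A=np.array(d_list),
        theta_deg=np.array(theta_list),
        contact_lifetimes=lifetimes,
        protein_mask=protein_mask,
        peptide_mask=peptide_mask,
        angle_atoms=(("A", 95, "CA"), ("A", 214, "CA"), ("B", 95, "CA")),
    )
    return stack, truth


def make_conformer_trajectory(
    seed: int = 0,
    family_sizes: Sequence[int] = (30, 20),
    separation_A: float = 100.0,
    spread_A: float = 1.0,
    peptide_length: int = 10,
) -> tuple[struc.AtomArrayStack, np.ndarray]:
    """Trajectory whose peptide hops between well-separated conformer
    families, for exercising quality-threshold clustering.

    Returns the stack (receptor chain A + peptide chain P) and the true
    per-frame family labels.  Frames of family ``j`` place the peptide
    at offset ``j * separation_A`` with Gaussian jitter ``spread_A``.
    """
    rng = np.random.default_rng(seed)
    receptor = _receptor_scaffold(chain_id="A")
    template = _peptide_template(peptide_length, chain_id="P")
    frame0 = struc.concatenate([receptor, template])
    n = sum(family_sizes)
    labels = np.concatenate([
        np.full(sz, j) for j, sz in enumerate(family_sizes)
    ])
    labels = labels[rng.permutation(n)]
    stack = struc.stack([frame0] * n)
    pep = frame0.chain_id == "P"
    for i in range(n):
        shift = np.array([0.0, 0.0, 10.0 + labels[i] * separation_A])
        jitter = rng.normal(0.0, spread_A, size=3)
        stack.coord[i, pep, :] += (shift + jitter).astype(np.float32)
    return stack, labels
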