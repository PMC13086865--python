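# pepscreen

**In-silico discovery pipeline for protein-derived inhibitory peptides.**

Short peptides cut from a protein that naturally binds a target can
inhibit that target by mimicking the native interface. `pepscreen`
implements the computational funnel behind one such screen — Ku80
C-terminal-domain (Ku80-Ct) peptides against the mitochondrial nuclease
Endonuclease G (EndoG), where the 28-mer "Ku3" emerged as the lead —
as a reusable, fully tested library and CLI for structural
bioinformaticians running peptide screens of their own:

1. **Library** — exhaustive enumeration of contiguous subpeptides of a
   parent region, with absolute-coordinate mapping and average masses
   (a 120-residue parent at minimum length 21 gives
   `(L−m+1)(L−m+2)/2 = 5050` candidates).
2. **Scoring** — pluggable peptide–target interaction scorers with
   reference-threshold filtering (keep candidates scoring above the
   parent) and a length cap; plus seeded substitution-mutant library
   generation (up to `max_mutations` per derivative).
3. **Poses** — docking-pose post-processing: pairwise unsuperposed
   RMSD, PAM k-medoids clustering (N poses into k clusters, occupancy
   `o_j` with `Σ o_j = N`), Cα contact interfaces (residue in contact
   iff its Cα is < 10 Å from any receptor Cα), and selection by
   contact fraction `100·contacts/length > 50 %`, occupancy `> N/k`,
   and most-populated/lowest-energy cluster coincidence.
4. **Motifs** — plurality consensus over an aligned mutant library
   (column conserved iff the unique top residue reaches half the
   entries), wildcard submotif scanning, and position-frequency-matrix
   export for logo tools.
5. **MD descriptors** — per-frame center-of-mass distance *d*,
   inter-chain angle *θ* at a designated vertex Cα, bound/unbound
   classification (*d* ≤ 45 Å bound, > 50 Å unbound), 151 × 151
   (d, θ) densities, quality-threshold conformational clustering, and
   residue-pair contact lifetimes λ (< 5 Å heavy-atom cutoff,
   persistent at λ ≥ 0.5).

Docking and simulation engines are import boundaries: the pipeline
reads their multi-model PDB output, and ships seeded synthetic
generators with planted ground truth (`pepscreen.synthetic`) standing
in for them, so everything runs and is verifiable offline. The shipped
interaction scorer and solubility flag are transparent baselines, not
the trained external predictors used in the original screen.

## Worked example

```python
import pepscreen as ps
from pepscreen.synthetic import ku80_ct_scaffold, make_pose_blobs

parent = ku80_ct_scaffold()                      # synthetic Ku80-Ct, residues 590-709
library = ps.enumerate_subpeptides(parent, min_len=21)
print(f"library size: {len(library)}")

ku3 = next(p for p in library if (p.parent_start, p.parent_end) == (676, 703))
print(f"Ku3 candidate: {ku3.name}  {ku3.sequence}")
print(f"mass: {ku3.mass_Da:.1f} Da  (printed: 2933)")
print(f"peptide position 14 -> Ku80 residue {ps.map_to_parent(ku3, 14)}")
print(f"TKEEASG located at: {ps.find_motif(ku3, 'TKEEASG')}")

ensemble, truth = make_pose_blobs(seed=0, n_poses=1000, n_clusters=10)
clusters = ps.kmedoids_cluster(ensemble, k=10, seed=0)
print(f"occupancies: {sorted(clusters.occupancies.tolist(), reverse=True)}")
print(f"mean occupancy: {clusters.mean_occupancy}")
```

prints

```
library size: 5050
Ku3 candidate: Ku80-Ct-synthetic/676-703  EIVVQDGITLITKEEASGSSVTAEEAKK
mass: 2933.2 Da  (printed: 2933)
peptide position 14 -> Ku80 residue 689
TKEEASG located at: [(12, 687)]
occupancies: [117, 107, 106, 105, 102, 99, 96, 96, 88, 84]
mean occupancy: 100.0
```

The 5050 candidates are every window of more than 20 residues in the
120-residue parent. The Ku3 window's average mass matches the
published candidate table to the printed integer; local position 14
maps to Ku80 residue E689 (a residue whose mutation abolishes
activity), and the conserved heptamer TKEEASG sits at Ku80 687–693.
Clustering 1000 synthetic docked poses into 10 clusters returns
occupancies summing to 1000 around the N/k = 100 average; a candidate
passes the occupancy rule when its top cluster exceeds that average.

The same stages are available from a shell:

```sh
pepscreen synth pose_blobs --seed 1 --param n_poses=1000 --out poses.pdb
pepscreen poses cluster --pdb poses.pdb --k 10 --seed 1 --cutoff 10.0
pepscreen motif --msa derivatives.fasta --freq-out pfm.tsv
pepscreen md descriptors --trajectory traj.pdb \
    --angle-atoms A:95:CA,A:214:CA,B:95:CA --bins 151 --out descriptors.tsv
pepscreen run --config screen.yaml
```

See `docs/methods.md` for the model, parameter defaults and the
boundary semantics of every threshold.

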