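# Methods

`pepscreen` re-implements, as a tested reusable pipeline, the in-silico
procedure used to discover short protein-derived inhibitory peptides —
concretely, Ku80-C-terminal (Ku80-Ct) peptides targeting the
mitochondrial nuclease Endonuclease G (EndoG). The pipeline covers five
stages: exhaustive subpeptide enumeration, interaction-score filtering,
docking-pose clustering with contact-fraction selection, consensus-motif
extraction from mutant libraries, and geometric descriptor analysis of
binding simulations. External engines (docking, molecular dynamics,
trained interaction/solubility predictors) are *import boundaries*:
the package consumes their outputs and ships seeded synthetic
generators with planted ground truth in their place, so every stage is
testable offline.

## Subpeptide libraries and coordinates

A parent region is a sequence plus a 1-based absolute numbering offset;
peptide-local position `i` of a candidate with span `[s, e]` maps to
absolute residue `s + i − 1`, and all spans are inclusive. The library
is every contiguous window with length in `[min_len, max_len]`; for a
parent of length `L` and unbounded maximum the count follows
`(L − m + 1)(L − m + 2)/2`. The default configuration (a 120-residue
region, minimum length 21) yields 5050 candidates. The equivalent
reading "L = 119, minimum 20" enumerates the same windows under an
off-by-one numbering and the same count; we anchor to the 120/21
parameterization.

Peptide masses are average (not monoisotopic) masses of unmodified
chains with free termini: the sum of average residue masses
(Biopython's IUPAC table) plus one water (18.0153 Da). This reproduces
the published candidate masses to the printed integer (e.g. the
28-mer EIVVQDGITLITKEEASGSSVTAEEAKK → 2933 Da; the synthesized 22-mer
G-variant ITKEEASGSSVTAEEAKKFLAG → 2253 Da). Mass is additive under
concatenation up to one water, which the suite verifies to 1e-6 Da.

The default parent is a **synthetic scaffold**: the published peptide
segments are planted at their absolute Ku80 positions (599–636 and
676–707) and the unpublished stretches are filled with a deterministic
G/S/T/A cycle, chosen to be free of E and K so it cannot create
spurious EEA-like motifs. Any real parent FASTA (header `id/start-end`)
can be substituted.

## Interaction scoring

Scoring is a pluggable registry of pure functions
`(peptide, target) → score`. The screen's original scorer is a trained
external predictor and is out of scope; the shipped `propensity`
baseline is the mean pairwise residue propensity over all
peptide × target residue pairs, with a 20×20 table
`M(a,b) = −q_a q_b + 0.2·(h_a/4.5)(h_b/4.5)` built from side-chain
charge `q` (K/R = +1, H = +0.5, D/E = −1) and Kyte–Doolittle
hydropathy `h`. It is symmetric, deterministic and finite, and it is
**not** a trained interaction model: absolute funnel counts obtained
with it are not comparable to published counts, and the package treats
them as scorer-dependent throughout. Filtering keeps candidates whose
score beats a calibrated reference-sequence score (strict `>` for the
parent-reference screen; `>=` for the derivative screen where the
reference belongs to the library); the length cap is inclusive
(`≤ 30` residues by default).

Mutant libraries are substitution-only: per member the number of
mutated positions is uniform on `{1..max_mutations}` (default 10),
positions are drawn without replacement, substitutions uniformly over
the 19 alternatives, duplicates rejected. The mutation-count
distribution is not specified by the source procedure; uniform was
chosen as the least-informative option and the per-position mutation
frequency is verified flat by a χ² test.

## Pose clustering and selection

Docked poses share the receptor's coordinate frame, so the clustering
metric is **unsuperposed** Cα RMSD: binding-site placement, not
internal conformation, distinguishes binding modes (superposed RMSD is
available as an option). Clustering is PAM k-medoids — greedy build
plus best-improvement swap to convergence, ties to the lowest pose
index — which is deterministic on a fixed distance matrix. With
N = 1000 poses and k = 10 the mean occupancy is N/k = 100.

The interface of a cluster representative (the medoid by default; the
lowest-energy member optionally, since the source procedure does not
say which member was measured) is the set of peptide residues whose Cα
lies **strictly** within 10 Å of any receptor Cα. The contact fraction
is `100·contacts/length` rounded to two decimals. Selection rules, all
strict per the stated wording: fraction > 50 % in the most-populated
and/or lowest-energy cluster's representative; most-populated-cluster
occupancy > N/k; and, when energies are present, coincidence of the
most-populated with the lowest-energy cluster. Without energies the
coincidence rule is undefined and only the other rules apply.

## Consensus motifs

Columns of an equal-length alignment are called conserved when the most
frequent symbol (i) reaches at least `threshold·n` (default one half,
comparison `≥`), (ii) is the unique maximizer (ties → wildcard; the
source rule is silent, so the conservative choice), and (iii) is not a
gap — gaps count toward `n` but never become consensus. Non-conserved
columns are emitted as `x`, so the motif has the alignment's width.
Raw-count plurality is implemented; the original extraction tool may
weight by a scoring matrix, so this is a documented interpretation.
Substitution-only libraries align columnwise with no external aligner;
gapped MSAs from external tools are accepted as FASTA/Clustal.
`submotif_scan` verifies published wildcard patterns literally
(pattern and motif wildcards both match anything) and reports maximal
conserved runs; the position frequency matrix is row-stochastic and
logo-tool compatible.

## Trajectory descriptors

* `d` — distance between centers of mass of the peptide and protein
  selections, mass-weighted by default (standard average atomic
  masses), geometric centroid optional.
* `θ` — angle at a designated vertex Cα (the middle atom of the
  configured triple, e.g. A:95 / **A:214** / B:95 — the middle-atom
  vertex is our convention, as the source lists three atoms without
  naming one) via the clamped normalized dot product.
* Binding states: `d ≤ 45 Å` bound, `d > 50 Å` unbound, the 45–50 Å
  band an explicit intermediate (the source leaves it undefined);
  thresholds configurable, and the three states partition the axis.
* (d, θ) densities on a uniform 151 × 151 grid; counts conserve the
  frame total exactly.
* Conformational clustering is quality-threshold/leader: frames are
  first aligned on receptor Cα (alignment before peptide RMSD is our
  choice; the source does not state it), then the frame with the
  largest 20 Å-RMSD neighbourhood over the peptide backbone founds a
  cluster, its members are removed, and the process repeats — sizes are
  non-increasing, clusters disjoint and exhaustive.
* Contact lifetimes: per residue pair across the two groups, the
  fraction λ of analysed frames whose minimum heavy-atom distance is
  strictly below 5 Å; pairs with λ ≥ 0.5 are persistent. Analysis uses
  a trailing window — by default the last 70 % of frames, by fraction
  rather than absolute time since time-step metadata may be absent
  (mirroring "last 700 ns of 1 μs" practice).

Geometric routines compute in float64; rigid-motion invariance of d and
θ holds to 1e-9 on float64 input. Structures stored as PDB/AtomArray
carry float32 coordinates, where ~1e-6 is the attainable bound.

## Synthetic generators

All generators are deterministic under a seed and emit their planted
truth. They emulate the *geometry and bookkeeping* of engine outputs,
not physics:

* **pose_blobs** — Cα-scaffold receptor plus poses translated to
  well-separated anchors with Gaussian jitter; true labels returned;
  with jitter ≪ separation, k-medoids recovers the plant exactly
  (ARI 1). Optional planted energies make a designated cluster the
  energy minimum.
* **contact_plant** — a single pose with an exact planted Cα contact
  count: contacts strictly inside the cutoff, the rest outside by a
  ≥ 2 Å margin. Drives the candidate-table arithmetic end-to-end
  ((22,18) → 81.82 %, (26,22) → 84.62 %, (28,18) → 64.29 %,
  (30,18) → 60.00 %).
* **selection ensembles** — a contact-planted winning cluster that is
  strictly most populated, above-average in occupancy and lowest in
  energy, with decoy clusters far from the receptor; used to verify the
  full selection logic and the end-to-end funnel.
* **trajectory_segments** — a minimal dimer-plus-peptide scaffold whose
  per-frame COM distance is placed inside the planted state's interval
  (bound 40 ± 1 Å, intermediate 47.5 ± 1 Å, unbound 60 ± 1 Å), whose
  angle arm realises the planted θ exactly, and whose planted contacts
  toggle on a deterministic schedule hitting each target lifetime to
  within 1/n_frames; contact toggling displaces mirrored atom pairs so
  the peptide COM — hence d — is untouched.
* **mutant libraries** — the uniform scheme above, plus a
  planted-conservation variant (protected positions never mutate,
  others mutate with probability 0.6 > ½) for consensus-recovery tests.

Because these inputs are geometric idealizations, passing tests
demonstrate the correctness of the bookkeeping, metrics and selection
logic — not the behaviour of real docked or simulated structures, which
have correlated noise, flexible conformations and ambiguous cluster
boundaries.

## Problem sizes and numerical choices

The test suite and the reproduction script use 100–1000 poses,
600–5000-member mutant libraries and 100-frame trajectories — sizes at
which every planted recovery is exact while the whole suite runs in
well under a minute; the algorithms scale to engine-sized inputs
(1000 × 1000 RMSD matrices are computed vectorized via the Gram
expansion, with negative squared distances clipped at zero before the
square root). Boundary semantics follow the stated wording everywhere:
strict `<` at the 10 Å contact cutoff and 5 Å heavy-atom cutoff,
strict `>` at the 50 % fraction and the N/k occupancy, `≥` at the
half-plurality and the 0.5 lifetime. k-medoids ties break to the lowest
index; a medoid always belongs to its own cluster.

## Known limitations

The propensity scorer and the GRAVY/charge solubility flag are
transparent stand-ins; published funnel counts that depend on the
trained predictors (5050 → 356 → 137 → 13; 100000 → 18960) are not
reproduction targets. Docking and MD are not run. Only the 20 standard
residues are supported (no PTMs, no non-standard residues); the
substitution-only mutant path has no indels, though externally aligned
gapped MSAs are accepted. Trajectory I/O is multi-model PDB or a plain
coordinate table; binary trajectory formats are expected to be
converted upstream.
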