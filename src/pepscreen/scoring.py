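"""Peptide–protein interaction scoring and substitution-mutant libraries.

Interaction scoring is pluggable: scorers are registered by name and must
be pure functions of (peptide sequence, target sequence), so that a
screen is reproducible and a trained external predictor can be dropped in
behind the same interface.  The shipped ``propensity`` scorer is a
deterministic sequence-level baseline — the mean pairwise residue
propensity between peptide and target — and is NOT a trained
interaction model; it exists so the whole funnel runs end-to-end and is
labelled as a baseline in every output.

The mutant-library generator produces seeded substitution-only
derivative libraries (no indels): for each member the number of mutated
positions is drawn uniformly on 1..max_mutations, positions are sampled
without replacement, and each substituted residue is drawn uniformly
over the 19 alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Callable, Iterable, Literal, Optional

import numpy as np

from .peptide_library import (
    STANDARD_RESIDUES,
    NonStandardResidueError,
    PeptideCandidate,
    _check_sequence,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Kyte–Doolittle hydropathy, normalized to [-1, 1] by dividing by 4.5.
_KD = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
    "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
    "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
    "W": -0.9, "Y": -1.3,
}
# Formal side-chain charge at neutral pH; His counted half-protonated.
_CHARGE = {aa: 0.0 for aa in AMINO_ACIDS}
_CHARGE.update({"K": 1.0, "R": 1.0, "H": 0.5, "D": -1.0, "E": -1.0})

#: 20x20 residue-pair propensity: electrostatic complementarity
#: (opposite charges attract, like charges repel) plus a weaker
#: hydrophobic-burial term.  Symmetric by construction.
PROPENSITY = {
    (a, b): -_CHARGE[a] * _CHARGE[b] + 0.2 * ((_KD[a] / 4.5) * (_KD[b] / 4.5))
    for a in AMINO_ACIDS
    for b in AMINO_ACIDS
}


def propensity_score(peptide: str, target: str) -> float:
    """Mean pairwise residue propensity between peptide and target.

    Averages :data:`PROPENSITY` over all ``|peptide| x |target|``
    residue pairs; a pure function of the two sequences, finite for any
    standard-residue input.
    """
    peptide = _check_sequence(peptide)
    target = _check_sequence(target)
    total = sum(PROPENSITY[(a, b)] for a in peptide for b in target)
    return total / (len(peptide) * len(target))


_SCORERS: dict[str, Callable[[str, str], float]] = {}


def register_scorer(name: str, fn: Callable[[str, str], float]) -> None:
    """Register a scorer callable (peptide, target) -> score under a name."""
    _SCORERS[name] = fn


def get_scorer(name: str) -> Callable[[str, str], float]:
    try:
        return _SCORERS[name]
    except KeyError:
        raise KeyError(
            f"unknown scorer {name!r}; registered: {sorted(_SCORERS)}"
        ) from None


register_scorer("propensity", propensity_score)


@dataclass
class ScorerSpec:
    """A named scorer plus the calibrated score of a reference sequence."""

    name: str = "propensity"
    parameters: dict = field(default_factory=dict)
    reference_score: Optional[float] = None

    def score(self, peptide: str, target: str) -> float:
        return get_scorer(self.name)(peptide, target)

    def calibrate(self, reference: str, target: str) -> float:
        """Score the reference sequence and store it as the filter threshold."""
        self.reference_score = self.score(reference, target)
        return self.reference_score


def score_peptides(
    library: Iterable[PeptideCandidate],
    target_sequence: str,
    scorer: ScorerSpec,
) -> list[PeptideCandidate]:
    """Fill the ``score`` field of every candidate; order preserved."""
    peps = list(library)
    fn = get_scorer(scorer.name)
    for pep in peps:
        s = float(fn(pep.sequence, target_sequence))
        if not np.isfinite(s):
            raise ValueError(f"scorer {scorer.name!r} returned non-finite score")
        pep.score = s
    return peps


def filter_by_reference(
    library: Iterable[PeptideCandidate],
    reference_score: float,
    mode: Literal["greater", "greater_equal"] = "greater",
) -> list[PeptideCandidate]:
    """Keep candidates whose score beats the reference.

    ``greater`` implements a strictly-better-than-parent screen;
    ``greater_equal`` the equal-or-better variant used when the
    reference itself belongs to the library.  Idempotent and
    order-preserving.
    """
    peps = list(library)
    missing = [p.name for p in peps if p.score is None]
    if missing:
        raise ValueError(f"unscored candidates: {missing[:5]}")
    if mode == "greater":
        return [p for p in peps if p.score > reference_score]
    if mode == "greater_equal":
        return [p for p in peps if p.score >= reference_score]
    raise ValueError(f"unknown mode {mode!r}")


def length_cap(
    library: Iterable[PeptideCandidate], max_len: int
) -> list[PeptideCandidate]:
    """Keep candidates with at most ``max_len`` residues (inclusive)."""
    return [p for p in library if p.length <= max_len]


@dataclass(frozen=True)
class MutantLibrary:
    reference: str
    members: tuple[str, ...]
    max_mutations: int
    seed: int

    def __len__(self) -> int:
        return len(self.members)


def _n_reachable(length: int, max_mutations: int) -> float:
    """Number of distinct sequences within Hamming distance 1..max_mutations."""
    return float(sum(comb(length, d) * 19**d for d in range(1, max_mutations + 1)))


def generate_mutants(
    reference: str,
    n: int,
    max_mutations: int = 10,
    seed: int = 0,
) -> MutantLibrary:
    """Seeded library of ``n`` unique substitution mutants of ``reference``.

    Sampling scheme per member: mutation count uniform on
    ``{1..max_mutations}``, positions without replacement, substitutions
    uniform over the 19 alternative residues.  Duplicates are rejected
    and redrawn, so members are unique sequences.
    """
    reference = _check_sequence(reference)
    L = len(reference)
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 1 <= max_mutations <= L:
        raise ValueError("max_mutations must be in 1..len(reference)")
    if n > _n_reachable(L, max_mutations):
        raise ValueError(
            f"n={n} exceeds the {_n_reachable(L, max_mutations):.0f} distinct "
            f"sequences reachable with <= {max_mutations} substitutions"
        )
    rng = np.random.default_rng(seed)
    alternatives = {
        aa: [b for b in AMINO_ACIDS if b != aa] for aa in AMINO_ACIDS
    }
    seen: set[str] = set()
    members: list[str] = []
    while len(members) < n:
        d = int(rng.integers(1, max_mutations + 1))
        positions = rng.choice(L, size=d, replace=False)
        seq = list(reference)
        for pos in positions:
            alts = alternatives[reference[pos]]
            seq[pos] = alts[int(rng.integers(len(alts)))]
        mutant = "".join(seq)
        if mutant not in seen:
            seen.add(mutant)
            members.append(mutant)
    return MutantLibrary(
        reference=reference, members=tuple(members),
        max_mutations=max_mutations, seed=seed,
    )


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))


def score_sequences(
    sequences: Iterable[str], target_sequence: str, scorer: ScorerSpec
) -> "np.ndarray":
    """Vector of scores for plain sequences (mutant-library screening)."""
    fn = get_scorer(scorer.name)
    return np.array([fn(s, target_sequence) for s in sequences], dtype=float)
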