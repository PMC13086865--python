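"""Parent-sequence handling and exhaustive subpeptide enumeration.

A peptide screen starts from a *parent* region of a protein (here the
C-terminal domain of Ku80, but any sequence works) carried with an
absolute residue-numbering offset, so that peptide-local positions can
always be mapped back to the parent protein's own numbering.  The module
provides the sliding-window library generator, local/absolute coordinate
mapping, average-mass calculation for unmodified peptides, motif search
with a wildcard, and longest-common-substring overlap between peptides.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional

from Bio.Data.IUPACData import protein_letters, protein_weights

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = frozenset(protein_letters)  # the 20 one-letter codes

#: Average mass of one water molecule in Da; released per peptide bond,
#: added back once for the free termini of an unmodified chain.
WATER_MASS_DA = 18.0153

#: Average residue (amino-acid minus water) masses in Da.
RESIDUE_MASSES_DA = {aa: protein_weights[aa] - WATER_MASS_DA for aa in STANDARD_RESIDUES}

SOLUBILITY_FLAGS = ("good", "poor", "unknown")


class NonStandardResidueError(ValueError):
    """A sequence contains a letter outside the 20 standard residues."""


def _check_sequence(sequence: str) -> str:
    sequence = sequence.upper()
    for ch in sequence:
        if ch not in STANDARD_RESIDUES:
            raise NonStandardResidueError(
                f"non-standard residue {ch!r} in sequence"
            )
    return sequence


@dataclass(frozen=True)
class ParentProtein:
    """A parent sequence with 1-based absolute residue numbering.

    ``numbering_offset`` is the absolute residue index of the first
    position of ``sequence``; position ``i`` (1-based) of the sequence
    is absolute residue ``numbering_offset + i - 1``.
    """

    id: str
    sequence: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("parent sequence must be non-empty")
        object.__setattr__(self, "sequence", _check_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def span(self) -> tuple[int, int]:
        """Absolute (first, last) residue indices, inclusive."""
        return self.numbering_offset, self.numbering_offset + len(self.sequence) - 1

    def subsequence(self, start: int, end: int) -> str:
        """Extract residues by absolute indices, inclusive on both ends."""
        lo, hi = self.span
        if not (lo <= start <= end <= hi):
            raise IndexError(
                f"span {start}-{end} outside parent {self.id} span {lo}-{hi}"
            )
        i = start - self.numbering_offset
        return self.sequence[i : i + (end - start + 1)]


@dataclass
class PeptideCandidate:
    """A contiguous subpeptide of a parent, plus screening annotations.

    ``parent_start``/``parent_end`` are absolute residue indices
    (inclusive).  The optional fields are filled in by downstream funnel
    stages: interaction ``score``, interface ``contacts`` and
    ``fraction_pct`` (percentage of the length in contact with the
    receptor), docking-cluster ``occupancy``, and a ``solubility_flag``.
    """

    sequence: str
    parent_id: str
    parent_start: int
    parent_end: int
    score: Optional[float] = None
    contacts: Optional[int] = None
    fraction_pct: Optional[float] = None
    occupancy: Optional[int] = None
    solubility_flag: str = "unknown"
    selected: Optional[bool] = None
    mass_Da: float = field(init=False)

    def __post_init__(self) -> None:
        self.sequence = _check_sequence(self.sequence)
        if self.parent_end - self.parent_start + 1 != len(self.sequence):
            raise ValueError(
                f"span {self.parent_start}-{self.parent_end} inconsistent with "
                f"sequence length {len(self.sequence)}"
            )
        if self.solubility_flag not in SOLUBILITY_FLAGS:
            raise ValueError(f"unknown solubility flag {self.solubility_flag!r}")
        self.mass_Da = average_mass(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def name(self) -> str:
        return f"{self.parent_id}/{self.parent_start}-{self.parent_end}"


def enumerate_subpeptides(
    parent: ParentProtein,
    min_len: int,
    max_len: Optional[int] = None,
) -> list[PeptideCandidate]:
    """Enumerate every contiguous subpeptide with length in [min_len, max_len].

    ``max_len=None`` means unbounded (capped by the parent length).  The
    output order is deterministic: by start position, then by length.
    For unbounded ``max_len`` the count follows the closed form
    ``(L - m + 1)(L - m + 2) / 2`` with ``L`` the parent length and
    ``m = min_len``; a 120-residue parent with ``min_len=21`` yields
    5050 peptides.
    """
    L = len(parent)
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if max_len is not None and max_len < min_len:
        raise ValueError("max_len must be >= min_len")
    if min_len > L:
        warnings.warn(
            f"min_len {min_len} exceeds parent length {L}; empty library",
            stacklevel=2,
        )
        logger.warning("min_len %d exceeds parent length %d", min_len, L)
        return []
    cap = L if max_len is None else min(max_len, L)
    out = []
    for start in range(L):  # 0-based position in the parent string
        for k in range(min_len, cap + 1):
            if start + k > L:
                break
            abs_start = parent.numbering_offset + start
            out.append(
                PeptideCandidate(
                    sequence=parent.sequence[start : start + k],
                    parent_id=parent.id,
                    parent_start=abs_start,
                    parent_end=abs_start + k - 1,
                )
            )
    return out


def subpeptide_count(L: int, min_len: int, max_len: Optional[int] = None) -> int:
    """Closed-form size of the library produced by :func:`enumerate_subpeptides`."""
    cap = L if max_len is None else min(max_len, L)
    return sum(L - k + 1 for k in range(min_len, cap + 1)) if min_len <= L else 0


def map_to_parent(pep: PeptideCandidate, peptide_pos: int) -> int:
    """Absolute parent residue index of 1-based peptide position."""
    if not 1 <= peptide_pos <= pep.length:
        raise IndexError(
            f"peptide position {peptide_pos} outside 1..{pep.length}"
        )
    return pep.parent_start + peptide_pos - 1


def map_from_parent(pep: PeptideCandidate, parent_index: int) -> int:
    """Inverse of :func:`map_to_parent`: absolute index -> 1-based peptide position."""
    pos = parent_index - pep.parent_start + 1
    if not 1 <= pos <= pep.length:
        raise IndexError(
            f"parent index {parent_index} outside span "
            f"{pep.parent_start}-{pep.parent_end}"
        )
    return pos


def average_mass(sequence: str) -> float:
    """Average molecular mass in Da of an unmodified peptide, free termini.

    Sum of average residue masses plus one water (18.0153 Da); the
    empty chain therefore weighs exactly one water.  Additive under
    concatenation up to one water: ``mass(a + b) = mass(a) + mass(b) -
    18.0153``.
    """
    sequence = _check_sequence(sequence)
    return sum(RESIDUE_MASSES_DA[aa] for aa in sequence) + WATER_MASS_DA


def find_motif(
    pep: PeptideCandidate, motif: str, wildcard: str = "x"
) -> list[tuple[int, int]]:
    """All occurrences of ``motif`` in the peptide, left to right.

    The wildcard letter matches any residue.  Returns pairs of
    ``(peptide_pos, parent_index)`` — the 1-based local position and the
    absolute parent index of the first matched residue.  Overlapping
    occurrences are all reported.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    motif = motif.upper().replace(wildcard.upper(), wildcard)
    seq = pep.sequence
    m = len(motif)
    hits = []
    for i in range(len(seq) - m + 1):
        if all(c == wildcard or c == seq[i + j] for j, c in enumerate(motif)):
            hits.append((i + 1, pep.parent_start + i))
    return hits


def longest_common_overlap(a: str, b: str) -> tuple[int, str]:
    """Longest common contiguous substring of two sequences.

    Ties are broken by the earliest start position in ``a``.  Dynamic
    programming over suffix matches, O(|a|·|b|).
    """
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    best_len, best_start = 0, 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best_len:
                    best_len = cur[j]
                    best_start = i - cur[j]
        prev = cur
    return best_len, a[best_start : best_start + best_len]


# ---------------------------------------------------------------------------
# FASTA / TSV interfaces


def read_parent_fasta(path) -> list[ParentProtein]:
    """Read parent proteins from FASTA.

    A description of the form ``id/start-end`` sets the numbering offset
    to ``start``; otherwise numbering starts at 1.
    """
    from Bio import SeqIO

    parents = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name, offset = rec.id, 1
        if "/" in rec.id:
            name, _, span = rec.id.rpartition("/")
            try:
                offset = int(span.split("-")[0])
            except ValueError:
                name, offset = rec.id, 1
        parents.append(ParentProtein(id=name, sequence=str(rec.seq), numbering_offset=offset))
    return parents


def write_library_fasta(peptides, path) -> None:
    """Write peptides as FASTA, span encoded in the header as id/start-end."""
    with open(path, "w") as fh:
        for pep in peptides:
            fh.write(f">{pep.name}\n{pep.sequence}\n")


def read_library_fasta(path) -> list[PeptideCandidate]:
    """Read a peptide library written by :func:`write_library_fasta`."""
    from Bio import SeqIO

    peptides = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parent_id, _, span = rec.id.rpartition("/")
        start, end = (int(x) for x in span.split("-"))
        peptides.append(
            PeptideCandidate(
                sequence=str(rec.seq), parent_id=parent_id,
                parent_start=start, parent_end=end,
            )
        )
    return peptides


REPORT_COLUMNS = [
    "peptide", "parent_span", "sequence", "mass_Da", "length",
    "contacts", "fraction_pct", "occupancy", "solubility", "selected",
]


def candidate_table(peptides):
    """Candidate report as a DataFrame with the standard report columns."""
    import pandas as pd

    rows = []
    for pep in peptides:
        rows.append({
            "peptide": pep.name,
            "parent_span": f"{pep.parent_start}-{pep.parent_end}",
            "sequence": pep.sequence,
            "mass_Da": round(pep.mass_Da),
            "length": pep.length,
            "contacts": pep.contacts,
            "fraction_pct": pep.fraction_pct,
            "occupancy": pep.occupancy,
            "solubility": pep.solubility_flag,
            "selected": pep.selected,
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
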