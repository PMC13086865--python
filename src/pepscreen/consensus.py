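"""Plurality-consensus motif extraction from aligned sequence libraries.

Given an alignment of accepted mutant peptides (columnwise for
substitution-only libraries, or an externally aligned gapped MSA), each
column's most frequent residue is accepted as the consensus when its
count reaches at least half of the entries (configurable threshold), is
the unique maximizer, and is not a gap; otherwise the column is written
as the wildcard ``x``.  The module also scans consensus motifs for
conserved runs and wildcard-tolerant submotifs and exports position
frequency matrices for sequence-logo tools.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

GAP_SYMBOLS = frozenset("-.")
WILDCARD = "x"


@dataclass(frozen=True)
class AlignmentColumnProfile:
    """Residue counts and consensus call for one alignment column."""

    position: int               # 1-based column index
    counts: dict
    n: int
    consensus_residue: str      # residue letter or the wildcard 'x'
    conserved: bool


def _check_alignment(msa) -> list[str]:
    rows = [s.upper() for s in msa]
    if not rows:
        raise ValueError("alignment must contain at least one sequence")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged alignment: all rows must have equal length")
    return rows


def consensus_from_alignment(
    msa, threshold_fraction: float = 0.5
) -> tuple[str, list[AlignmentColumnProfile]]:
    """Plurality consensus of an equal-length alignment.

    A column is conserved iff its most frequent symbol has count
    ``>= threshold_fraction * n``, is a unique maximizer, and is not a
    gap; gaps count toward ``n`` but can never become the consensus.
    Non-conserved columns are emitted as ``x``, so the motif string has
    exactly the alignment width.
    """
    rows = _check_alignment(msa)
    n = len(rows)
    profiles = []
    motif = []
    for col in range(len(rows[0])):
        counts = Counter(r[col] for r in rows)
        (top, top_count), = counts.most_common(1)
        unique = sum(1 for c in counts.values() if c == top_count) == 1
        conserved = (
            unique
            and top not in GAP_SYMBOLS
            and top_count >= threshold_fraction * n
        )
        residue = top if conserved else WILDCARD
        motif.append(residue)
        profiles.append(
            AlignmentColumnProfile(
                position=col + 1, counts=dict(counts), n=n,
                consensus_residue=residue, conserved=conserved,
            )
        )
    return "".join(motif), profiles


@dataclass(frozen=True)
class ConservedRun:
    """A maximal contiguous run of conserved positions in a motif."""

    start: int      # 1-based position of the first conserved residue
    end: int        # inclusive
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def conserved_runs(motif: str, window_min: int = 1) -> list[ConservedRun]:
    """Maximal runs of non-wildcard positions, at least ``window_min`` long."""
    runs = []
    start = None
    for i, ch in enumerate(motif + WILDCARD):
        if ch != WILDCARD and start is None:
            start = i
        elif ch == WILDCARD and start is not None:
            if i - start >= window_min:
                runs.append(ConservedRun(start + 1, i, motif[start:i]))
            start = None
    return runs


def submotif_scan(
    motif: str, pattern: str | None = None, window_min: int = 1,
    max_wildcard_fraction: float = 0.5,
) -> list:
    """Scan a consensus motif for submotifs.

    With ``pattern`` given (wildcards allowed on either side), returns
    1-based positions where the pattern matches the motif — a motif
    wildcard matches anything, and a pattern wildcard matches any motif
    symbol, so the printed decomposition of a motif into wildcard-
    tolerant fragments can be verified literally.  Without a pattern,
    returns maximal conserved segments bounded by conserved anchors
    whose wildcard density does not exceed ``max_wildcard_fraction``.
    """
    if pattern is not None:
        m = len(pattern)
        hits = []
        for i in range(len(motif) - m + 1):
            window = motif[i : i + m]
            if all(
                p == WILDCARD or w == WILDCARD or p == w
                for p, w in zip(pattern, window)
            ):
                hits.append(i + 1)
        return hits
    runs = conserved_runs(motif, window_min)
    segments = []
    # merge adjacent runs across wildcard gaps while density stays low
    for i, run in enumerate(runs):
        start, end = run.start, run.end
        for nxt in runs[i + 1 :]:
            cand = motif[start - 1 : nxt.end]
            if cand.count(WILDCARD) / len(cand) <= max_wildcard_fraction:
                end = nxt.end
            else:
                break
        seg = motif[start - 1 : end]
        if len(seg) >= window_min:
            segments.append(ConservedRun(start, end, seg))
    # drop segments nested in an earlier, longer one
    out = []
    for seg in segments:
        if not any(s.start <= seg.start and seg.end <= s.end for s in out):
            out.append(seg)
    return out


def frequency_matrix(msa, include_gaps: bool = True) -> pd.DataFrame:
    """Row-stochastic position × symbol frequency matrix.

    One row per alignment column (1-based ``position`` index), one
    column per symbol observed anywhere in the alignment; each row sums
    to exactly 1.  Suitable as TSV input to sequence-logo renderers.
    """
    rows = _check_alignment(msa)
    n = len(rows)
    alphabet = sorted({c for r in rows for c in r if include_gaps or c not in GAP_SYMBOLS})
    width = len(rows[0])
    mat = np.zeros((width, len(alphabet)))
    index = {c: j for j, c in enumerate(alphabet)}
    for r in rows:
        for i, c in enumerate(r):
            if c in index:
                mat[i, index[c]] += 1
    mat /= mat.sum(axis=1, keepdims=True)
    return pd.DataFrame(mat, columns=alphabet, index=pd.RangeIndex(1, width + 1, name="position"))


def read_msa(path, fmt: str = "fasta") -> list[str]:
    """Read an alignment (FASTA or Clustal) into a list of row strings."""
    from Bio import AlignIO

    aln = AlignIO.read(str(path), fmt)
    return [str(rec.seq) for rec in aln]
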