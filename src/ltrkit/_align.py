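"""Thin wrappers around Bio.Align.PairwiseAligner used across the package."""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices


def nt_local_aligner(match: float = 2.0, mismatch: float = -3.0,
                     gap_open: float = -8.0, gap_extend: float = -1.0) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = gap_open
    a.extend_gap_score = gap_extend
    return a


def nt_global_aligner(match: float = 2.0, mismatch: float = -1.0,
                      gap_open: float = -10.0, gap_extend: float = -0.5) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = gap_open
    a.extend_gap_score = gap_extend
    return a


def protein_local_aligner(gap_open: float = -11.0, gap_extend: float = -1.0) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = gap_open
    a.extend_gap_score = gap_extend
    return a


def protein_global_aligner(gap_open: float = -11.0, gap_extend: float = -1.0) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = gap_open
    a.extend_gap_score = gap_extend
    return a


@dataclass
class AlignmentStats:
    """Column-level statistics of one pairwise alignment."""

    identities: int
    mismatches: int
    gaps: int
    target_start: int
    target_end: int
    query_start: int
    query_end: int

    @property
    def columns(self) -> int:
        return self.identities + self.mismatches + self.gaps

    @property
    def identity(self) -> float:
        return self.identities / self.columns if self.columns else 0.0


def align_stats(aligner: Align.PairwiseAligner, target: str, query: str) -> AlignmentStats:
    """Best alignment of query against target with column statistics.

    The first optimal alignment is taken, which is deterministic for a
    fixed Biopython version and input pair.
    """
    aln = aligner.align(target, query)[0]
    counts = aln.counts()
    tblocks, qblocks = aln.aligned
    return AlignmentStats(
        identities=counts.identities,
        mismatches=counts.mismatches,
        gaps=counts.gaps,
        target_start=int(tblocks[0][0]),
        target_end=int(tblocks[-1][1]),
        query_start=int(qblocks[0][0]),
        query_end=int(qblocks[-1][1]),
    )
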