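"""Short-read mapping, redundancy (reads/kb) and solo-LTR ratio statistics.

Reads truncated to a constant length are assigned to the reference whose
best ungapped alignment covers at least a minimum fraction of the read
at a minimum identity; multireads (ties across references) are placed
uniformly at random from a seeded stream.  Redundancy is reported as
mapped reads per kb.  For solo-LTR screening each element is mapped with
its 3' LTR excluded, so an intact-only family has an expected
5'-LTR/inter-LTR coverage ratio of 2; solo-LTRs push the ratio above
that, and ratios > 2.5 flag solo-LTR-rich families.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .io import SequenceRecord, revcomp
from .detect import FullLengthRE

log = logging.getLogger("ltrkit")


@dataclass
class MapperParams:
    min_identity: float = 0.90
    min_length_fraction: float = 0.90
    read_truncate_len: int = 75
    kmer_len: int = 15
    solo_ratio_threshold: float = 2.5

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1 and 0 < self.min_length_fraction <= 1):
            raise ValueError("identity and length fraction must be in (0,1]")


@dataclass
class ReadAssignment:
    read_id: str
    reference_id: str
    position: int  # 0-based start on the reference
    strand: str
    identity: float


@dataclass
class RedundancyStat:
    reference_id: str
    mapped_reads: int
    reads_per_kb: float


@dataclass
class SoloLtrStat:
    element_id: str
    rpk_ltr: float
    rpk_inter: float
    ratio: float  # inf when the inter-LTR partition receives no reads
    solo_flag: bool


def truncate_reads(reads: list[SequenceRecord], length: int = 75) -> list[SequenceRecord]:
    """Cut every read down to its first ``length`` bases."""
    out = []
    for r in reads:
        if len(r.sequence) > length:
            out.append(replace(r, sequence=r.sequence[:length]))
        else:
            out.append(r)
    return out


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class _RefIndex:
    def __init__(self, references: list[SequenceRecord], k: int):
        self.refs = references
        self.k = k
        self.arrays = [_encode(r.sequence) for r in references]
        self.kmers: dict[str, list[tuple[int, int]]] = {}
        for ri, ref in enumerate(references):
            s = ref.sequence
            if len(s) < k:
                log.warning("reference %s shorter than k-mer length; skipped", ref.id)
                continue
            for i in range(len(s) - k + 1):
                self.kmers.setdefault(s[i : i + k], []).append((ri, i))


def _best_hits(seq: str, index: _RefIndex, params: MapperParams) -> list[tuple[int, int, int, str, float]]:
    """All best-scoring ungapped placements of one oriented read.

    Returns (matches, ref_index, ref_start, strand, identity) tuples for
    the top score over both orientations.
    """
    k = index.k
    L0 = len(seq)
    best_score = -1
    best: list[tuple[int, int, int, str, float]] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        arr = _encode(s)
        L = len(s)
        diags: set[tuple[int, int]] = set()
        for off in range(0, L - k + 1):
            for ri, p in index.kmers.get(s[off : off + k], ()):
                diags.add((ri, p - off))
        for ri, diag in diags:
            ref = index.arrays[ri]
            r_start = max(0, -diag)
            f_start = max(0, diag)
            ov = min(L - r_start, len(ref) - f_start)
            if ov < params.min_length_fraction * L0:
                continue
            matches = int(np.count_nonzero(arr[r_start : r_start + ov] == ref[f_start : f_start + ov]))
            if matches / ov < params.min_identity:
                continue
            if matches > best_score:
                best_score = matches
                best = [(matches, ri, f_start, strand, matches / ov)]
            elif matches == best_score:
                best.append((matches, ri, f_start, strand, matches / ov))
    return best


def map_reads(reads: list[SequenceRecord], references: list[SequenceRecord],
              params: MapperParams | None = None,
              rng: np.random.Generator | None = None) -> list[ReadAssignment]:
    """Assign each read to at most one reference.

    Acceptance requires the best ungapped placement to cover at least
    ``min_length_fraction`` of the read at ``min_identity`` or better;
    both orientations are tried and ties among best placements are broken
    uniformly at random from the supplied seeded stream.
    """
    params = params or MapperParams()
    rng = rng or np.random.default_rng(0)
    index = _RefIndex(references, params.kmer_len)
    out: list[ReadAssignment] = []
    for read in reads:
        hits = _best_hits(read.sequence, index, params)
        if not hits:
            continue
        pick = hits[0] if len(hits) == 1 else hits[int(rng.integers(len(hits)))]
        _, ri, pos, strand, ident = pick
        out.append(ReadAssignment(read.id, references[ri].id, pos, strand, ident))
    return out


def reads_per_kb(assignments: list[ReadAssignment],
                 references: list[SequenceRecord]) -> list[RedundancyStat]:
    """Mapped-read counts per reference normalized to reads per kb."""
    counts = {r.id: 0 for r in references}
    for a in assignments:
        counts[a.reference_id] += 1
    return [
        RedundancyStat(r.id, counts[r.id], counts[r.id] / (len(r.sequence) / 1000.0))
        for r in references
    ]


def effective_length(region_len: int, read_len: int, min_length_fraction: float) -> int:
    """Number of admissible read start positions over one copy of a region.

    A read of length T is accepted on a region flanked by non-reference
    sequence iff at least ceil(f*T) of its bases fall inside the region,
    so the admissible starts span L - 2*ceil(f*T) + T + 1 positions.
    Normalizing counts by this effective length (instead of the raw
    region length) removes the finite-read-length edge bias from
    coverage-ratio estimates.
    """
    m = math.ceil(min_length_fraction * read_len)
    return max(1, region_len - 2 * m + read_len + 1)


def ltr_ratio(element: FullLengthRE, reads: list[SequenceRecord],
              params: MapperParams | None = None,
              rng: np.random.Generator | None = None) -> SoloLtrStat:
    """5'-LTR vs inter-LTR coverage ratio of one element.

    The read set is mapped against two references — the 5' LTR sequence
    and the inter-LTR sequence; the 3' LTR is excluded so that reads from
    both genomic LTRs of every intact copy land on the single remaining
    LTR, which makes the intact-only expectation of the ratio equal 2.
    Per-partition reads/kb are normalized by the partition's effective
    (edge-corrected) length, which makes the ratio an unbiased estimate
    of (2N + S)/N for N intact copies and S solo-LTRs.
    """
    params = params or MapperParams()
    rng = rng or np.random.default_rng(0)
    ltr_len = element.five_ltr.length
    inter_len = element.three_ltr.start - element.five_ltr.end
    if inter_len <= 0:
        raise ValueError("element has no inter-LTR region")
    ltr_ref = SequenceRecord(f"{element.element_id or 'element'}|ltr5", element.five_ltr_seq())
    inter_ref = SequenceRecord(f"{element.element_id or 'element'}|inter", element.internal_seq())
    assignments = map_reads(reads, [ltr_ref, inter_ref], params, rng)
    n_ltr = sum(1 for a in assignments if a.reference_id == ltr_ref.id)
    n_inter = len(assignments) - n_ltr
    t_len = params.read_truncate_len
    rpk_ltr = n_ltr / (effective_length(ltr_len, t_len, params.min_length_fraction) / 1000.0)
    rpk_inter = n_inter / (effective_length(inter_len, t_len, params.min_length_fraction) / 1000.0)
    if rpk_inter == 0:
        ratio = math.inf if rpk_ltr > 0 else math.nan
        log.warning("element %s: inter-LTR partition received no reads", element.element_id)
    else:
        ratio = rpk_ltr / rpk_inter
    solo = bool(ratio > params.solo_ratio_threshold) if not math.isnan(ratio) else False
    return SoloLtrStat(element.element_id, rpk_ltr, rpk_inter, ratio, solo)
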