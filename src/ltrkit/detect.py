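"""De novo structural detection of full-length LTR retroelements.

A full-length element is two long terminal repeats (LTRs) flanking an
internal region, with up to four corroborating features: TG...CA termini,
a 4-6 nt target-site duplication (TSD), a primer-binding site (PBS)
complementary to a tRNA 3' end just inside the 5' LTR, and a polypurine
tract (PPT) just upstream of the 3' LTR.  Detection is a seeded
self-comparison of each contig: exact k-mer matches between distant
regions are chained on near-constant diagonals, extended by local
alignment into LTR-pair candidates, refined, and scored for features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .io import GenomicInterval, SequenceRecord, revcomp
from ._align import align_stats, nt_local_aligner

log = logging.getLogger("ltrkit")

PURINES = frozenset("AG")


@dataclass
class DetectorParams:
    """Structural-search thresholds.

    Length bounds bracket the LTR and element lengths typical of plant
    Copia/Gypsy elements (LTR means around 540-650 nt, elements around
    5.6-7.6 kb); all are configurable.
    """

    min_contig_len: int = 10_000
    min_ltr_len: int = 100
    max_ltr_len: int = 3_500
    min_elem_len: int = 1_000
    max_elem_len: int = 16_000
    min_ltr_similarity: float = 0.80
    seed_kmer_len: int = 13
    boundary_snap_window: int = 25
    missing_features_allowed: int = 1
    pbs_window: int = 30
    pbs_max_mismatches: int = 2
    ppt_window: int = 40
    ppt_min_purine: float = 0.80
    sw_match: float = 2.0
    sw_mismatch: float = -3.0
    sw_gap_open: float = -8.0
    sw_gap_extend: float = -1.0
    # chaining controls
    max_seed_occurrences: int = 64
    diagonal_tolerance: int = 20
    max_seed_gap: int = 300

    def __post_init__(self) -> None:
        if self.min_ltr_len >= self.max_ltr_len or self.min_elem_len >= self.max_elem_len:
            raise ValueError("min length bounds must be below max bounds")
        if not (0 < self.min_ltr_similarity <= 1):
            raise ValueError("min_ltr_similarity must be in (0,1]")


@dataclass
class LtrPairCandidate:
    contig_id: str
    five_ltr: GenomicInterval
    three_ltr: GenomicInterval
    ltr_identity: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.five_ltr.end > self.three_ltr.start:
            raise ValueError("5' LTR must precede 3' LTR")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.contig_id, self.five_ltr.start, self.three_ltr.end, self.strand)


@dataclass
class FullLengthRE:
    """A detected element plus its structural evidence."""

    contig_id: str
    five_ltr: GenomicInterval
    three_ltr: GenomicInterval
    ltr_identity: float
    strand: str
    element_sequence: str
    element_id: str
    tsd: str | None = None
    pbs: GenomicInterval | None = None
    ppt: GenomicInterval | None = None
    has_tg_ca: bool = False
    ppt_purine_fraction: float | None = None
    superfamily: str | None = None

    @property
    def start(self) -> int:
        return self.five_ltr.start

    @property
    def end(self) -> int:
        return self.three_ltr.end

    @property
    def length(self) -> int:
        return self.end - self.start

    def five_ltr_seq(self) -> str:
        off = self.five_ltr.start - self.start
        return self.element_sequence[off : off + self.five_ltr.length]

    def three_ltr_seq(self) -> str:
        off = self.three_ltr.start - self.start
        return self.element_sequence[off : off + self.three_ltr.length]

    def internal_seq(self) -> str:
        return self.element_sequence[
            self.five_ltr.end - self.start : self.three_ltr.start - self.start
        ]

    def missing_features(self) -> int:
        return sum(
            1
            for ok in (self.has_tg_ca, self.tsd is not None, self.pbs is not None, self.ppt is not None)
            if not ok
        )


# --------------------------------------------------------------------------
# candidate discovery
# --------------------------------------------------------------------------

def find_ltr_pairs(contig: SequenceRecord, params: DetectorParams | None = None) -> list[LtrPairCandidate]:
    """Find LTR-pair candidates by seeded self-comparison of one contig.

    Exact ``seed_kmer_len``-mers occurring twice at a spacing compatible
    with the element-length bounds are grouped by diagonal, chained into
    runs, and each run is verified/extended by Smith-Waterman between the
    two putative repeat neighbourhoods.  Overlapping candidates at the
    same locus are reduced to the highest-identity one.  Direct-repeat
    discovery is strand-symmetric, so the forward scan covers both strands.
    """
    params = params or DetectorParams()
    seq = contig.sequence
    n = len(seq)
    if n < params.min_contig_len:
        log.warning("contig %s shorter than %d nt; skipped", contig.id, params.min_contig_len)
        return []
    k = params.seed_kmer_len

    # k-mer -> positions
    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)

    d_min = max(params.min_ltr_len, params.min_elem_len - params.max_ltr_len)
    d_max = params.max_elem_len
    # (diagonal, position) seed pairs
    seeds: list[tuple[int, int]] = []
    for positions in index.values():
        m = len(positions)
        if m < 2 or m > params.max_seed_occurrences:
            continue
        for a in range(m - 1):
            pa = positions[a]
            for b in range(a + 1, m):
                d = positions[b] - pa
                if d < d_min:
                    continue
                if d > d_max:
                    break
                seeds.append((d, pa))
    if not seeds:
        return []

    # cluster seeds: same diagonal (within tolerance), contiguous positions
    seeds.sort()
    clusters: list[list[tuple[int, int]]] = []
    for d, p in seeds:
        placed = False
        for cl in reversed(clusters):
            ld, lp = cl[-1]
            if abs(d - ld) <= params.diagonal_tolerance and 0 <= p - lp <= params.max_seed_gap:
                cl.append((d, p))
                placed = True
                break
            if d - ld > params.diagonal_tolerance:
                break
        if not placed:
            clusters.append([(d, p)])

    aligner = nt_local_aligner(params.sw_match, params.sw_mismatch, params.sw_gap_open, params.sw_gap_extend)
    candidates: list[LtrPairCandidate] = []
    for cl in clusters:
        d_mean = round(sum(d for d, _ in cl) / len(cl))
        p_lo = min(p for _, p in cl)
        p_hi = max(p for _, p in cl) + k
        if p_hi - p_lo < params.min_ltr_len // 2:
            continue
        pad = max(100, (p_hi - p_lo) // 2)
        w5_lo, w5_hi = max(0, p_lo - pad), min(n, p_hi + pad)
        w3_lo, w3_hi = max(0, p_lo + d_mean - pad), min(n, p_hi + d_mean + pad)
        # keep windows disjoint so the local alignment pairs the two copies
        if w5_hi > w3_lo:
            mid = (w5_hi + w3_lo) // 2
            w5_hi, w3_lo = mid, mid
        if w5_hi - w5_lo < params.min_ltr_len or w3_hi - w3_lo < params.min_ltr_len:
            continue
        try:
            st = align_stats(aligner, seq[w5_lo:w5_hi], seq[w3_lo:w3_hi])
        except IndexError:  # empty alignment
            continue
        five = (w5_lo + st.target_start, w5_lo + st.target_end)
        three = (w3_lo + st.query_start, w3_lo + st.query_end)
        len5, len3 = five[1] - five[0], three[1] - three[0]
        if not (params.min_ltr_len <= len5 <= params.max_ltr_len):
            continue
        if not (params.min_ltr_len <= len3 <= params.max_ltr_len):
            continue
        if five[1] > three[0]:
            continue
        span = three[1] - five[0]
        if not (params.min_elem_len <= span <= params.max_elem_len):
            continue
        if st.identity < params.min_ltr_similarity:
            continue
        candidates.append(
            LtrPairCandidate(
                contig_id=contig.id,
                five_ltr=GenomicInterval(contig.id, five[0], five[1]),
                three_ltr=GenomicInterval(contig.id, three[0], three[1]),
                ltr_identity=st.identity,
            )
        )

    return _dedup_candidates(candidates)


def _overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _dedup_candidates(cands: list[LtrPairCandidate]) -> list[LtrPairCandidate]:
    """Reduce candidates sharing a locus (both LTRs overlapping) to the best."""
    cands = sorted(cands, key=lambda c: (-c.ltr_identity, c.five_ltr.start))
    kept: list[LtrPairCandidate] = []
    for c in cands:
        if any(
            _overlap(c.five_ltr, k.five_ltr) > 0 and _overlap(c.three_ltr, k.three_ltr) > 0
            for k in kept
        ):
            continue
        kept.append(c)
    kept.sort(key=lambda c: c.five_ltr.start)
    return kept


# --------------------------------------------------------------------------
# refinement and features
# --------------------------------------------------------------------------

def refine_boundaries(cand: LtrPairCandidate, contig: SequenceRecord,
                      params: DetectorParams | None = None) -> LtrPairCandidate:
    """Polish candidate boundaries and snap termini onto TG...CA.

    The two LTR neighbourhoods are re-aligned by Smith-Waterman; the
    termini are then snapped to the nearest offset (within
    ``boundary_snap_window``) at which *both* LTRs start with TG,
    respectively end with CA.  Refinement never discards a candidate.
    """
    params = params or DetectorParams()
    seq = contig.sequence
    n = len(seq)
    pad = params.boundary_snap_window + 10
    aligner = nt_local_aligner(params.sw_match, params.sw_mismatch, params.sw_gap_open, params.sw_gap_extend)

    w5_lo = max(0, cand.five_ltr.start - pad)
    w5_hi = min(n, cand.five_ltr.end + pad)
    w3_lo = max(0, cand.three_ltr.start - pad)
    w3_hi = min(n, cand.three_ltr.end + pad)
    if w5_hi > w3_lo:
        mid = (w5_hi + w3_lo) // 2
        w5_hi, w3_lo = mid, mid
    st = align_stats(aligner, seq[w5_lo:w5_hi], seq[w3_lo:w3_hi])
    f_start, f_end = w5_lo + st.target_start, w5_lo + st.target_end
    t_start, t_end = w3_lo + st.query_start, w3_lo + st.query_end
    identity = st.identity

    def _outside_diverges(a: int, b: int, anchor: str, min_mismatch: int = 1) -> bool:
        # a true terminus separates the repeat from non-repeat context, so
        # the sequence just outside it must differ between the two loci;
        # inside an identical LTR pair it would be identical (spurious snap)
        w = 6
        if anchor == "start":
            ua, ub = seq[max(0, a - w) : a], seq[max(0, b - w) : b]
        else:
            ua, ub = seq[a : a + w], seq[b : b + w]
        if len(ua) != len(ub) or not ua:
            return True  # contig edge: give the benefit of the doubt
        return sum(1 for x, y in zip(ua, ub) if x != y) >= min_mismatch

    def _inside_matches(a: int, b: int, anchor: str, max_mismatch: int = 2) -> bool:
        # just inside a true terminus both copies show the same (repeat)
        # sequence; a skewed pairing of motifs at unrelated repeat
        # positions does not
        w = 6
        if anchor == "start":
            ua, ub = seq[a : a + w], seq[b : b + w]
        else:
            ua, ub = seq[max(0, a - w) : a], seq[max(0, b - w) : b]
        if len(ua) != len(ub) or not ua:
            return True
        return sum(1 for x, y in zip(ua, ub) if x != y) <= max_mismatch

    def snap(pos5: int, pos3: int, motif: str, anchor: str) -> tuple[int, int] | None:
        # offsets may differ slightly between the two LTRs (alignment
        # wobble), but must stay length-compatible
        w = params.boundary_snap_window
        max_skew = 6

        def hits(pos: int) -> list[int]:
            found = []
            for off in sorted(range(-w, w + 1), key=lambda o: (abs(o), o)):
                p = pos + off
                if anchor == "start":
                    if 0 <= p and p + 2 <= n and seq[p : p + 2] == motif:
                        found.append(off)
                else:
                    if p - 2 >= 0 and p <= n and seq[p - 2 : p] == motif:
                        found.append(off)
            return found

        best: tuple[tuple[int, int, int], int, int] | None = None
        for o5 in hits(pos5):
            for o3 in hits(pos3):
                if abs(o5 - o3) > max_skew:
                    continue
                if not _outside_diverges(pos5 + o5, pos3 + o3, anchor):
                    continue
                if not _inside_matches(pos5 + o5, pos3 + o3, anchor):
                    continue
                key = (abs(o5) + abs(o3), abs(o5 - o3), o5)
                if best is None or key < best[0]:
                    best = (key, pos5 + o5, pos3 + o3)
        return None if best is None else (best[1], best[2])

    start_snap = snap(f_start, t_start, "TG", "start")
    end_snap = snap(f_end, t_end, "CA", "end")
    has_tg_ca = start_snap is not None and end_snap is not None
    if has_tg_ca:
        f_start, t_start = start_snap
        f_end, t_end = end_snap
    if f_end <= f_start or t_end <= t_start or f_end > t_start:
        # snapped geometry degenerate; keep alignment-derived coordinates
        f_start, f_end = w5_lo + st.target_start, w5_lo + st.target_end
        t_start, t_end = w3_lo + st.query_start, w3_lo + st.query_end
        has_tg_ca = False
    refined = LtrPairCandidate(
        contig_id=cand.contig_id,
        five_ltr=GenomicInterval(cand.contig_id, f_start, f_end),
        three_ltr=GenomicInterval(cand.contig_id, t_start, t_end),
        ltr_identity=identity,
        strand=cand.strand,
    )
    refined.has_tg_ca = has_tg_ca  # transient note consumed by scan_contigs
    return refined


def detect_tsd(contig: SequenceRecord, element: GenomicInterval) -> str | None:
    """Longest exact 4-6-mer shared by the immediate flanks, or None."""
    seq = contig.sequence
    if element.start < 4 or element.end + 4 > len(seq):
        log.warning("element at contig edge; TSD undetectable")
        return None
    max_len = min(6, element.start, len(seq) - element.end)
    for L in range(max_len, 3, -1):
        up = seq[element.start - L : element.start]
        down = seq[element.end : element.end + L]
        if up == down:
            return up
    return None


def detect_pbs(contig: SequenceRecord, five_ltr: GenomicInterval,
               trna_oligos: list[SequenceRecord],
               window: int = 30, max_mismatches: int = 2) -> GenomicInterval | None:
    """Find a 15-18 nt primer-binding site just 3' of the 5' LTR.

    The PBS is complementary to a tRNA 3' end, so the scan looks for a
    stretch matching the reverse complement of a library oligo (or its
    3'-terminal 15-17-mers) with at most ``max_mismatches`` mismatches.
    """
    if not trna_oligos:
        raise ValueError("tRNA oligo library is empty")
    seq = contig.sequence
    win_lo = five_ltr.end
    win_hi = min(len(seq), five_ltr.end + window)
    win = seq[win_lo:win_hi]
    best: tuple[int, int, int] | None = None  # (mismatches, offset, length)
    for oligo in trna_oligos:
        for L in range(18, 14, -1):
            if len(oligo.sequence) < L:
                continue
            probe = revcomp(oligo.sequence[-L:])
            for off in range(0, len(win) - L + 1):
                mm = sum(1 for x, y in zip(win[off : off + L], probe) if x != y)
                if mm <= max_mismatches:
                    key = (mm, off, -L)
                    if best is None or key < (best[0], best[1], -best[2]):
                        best = (mm, off, L)
    if best is None:
        return None
    _, off, L = best
    return GenomicInterval(contig.id, win_lo + off, win_lo + off + L)


def detect_ppt(contig: SequenceRecord, three_ltr: GenomicInterval,
               window: int = 40, min_purine: float = 0.80) -> GenomicInterval | None:
    """Highest-purine 20-25 nt window in the 40 nt upstream of the 3' LTR."""
    seq = contig.sequence
    win_lo = max(0, three_ltr.start - window)
    win = seq[win_lo : three_ltr.start]
    best: tuple[float, int, int] | None = None  # (fraction, -closeness, length)
    for L in range(20, 26):
        for off in range(0, len(win) - L + 1):
            sub = win[off : off + L]
            frac = sum(1 for c in sub if c in PURINES) / L
            if frac < min_purine:
                continue
            # prefer higher purity, then proximity to the LTR, then length
            key = (frac, off + L, L)
            if best is None or key > (best[0], best[1], best[2]):
                best = key
    if best is None:
        return None
    frac, end_off, L = best
    iv = GenomicInterval(contig.id, win_lo + end_off - L, win_lo + end_off)
    iv_frac = frac
    return iv


def _ppt_fraction(seq: str) -> float:
    return sum(1 for c in seq if c in PURINES) / len(seq) if seq else 0.0


def scan_contigs(contigs: list[SequenceRecord], params: DetectorParams | None = None,
                 trna_oligos: list[SequenceRecord] | None = None) -> list[FullLengthRE]:
    """Full structural scan: find, refine, and score features per contig.

    Candidates missing more than ``missing_features_allowed`` of
    {TG...CA, TSD, PBS, PPT} are dropped.  If the forward orientation of a
    candidate scores worse than its reverse complement, the element is
    reported on the minus strand.
    """
    params = params or DetectorParams()
    if trna_oligos is None:
        from .io import bundled_trna_oligos

        trna_oligos = bundled_trna_oligos()
    elements: list[FullLengthRE] = []
    for contig in contigs:
        if len(contig) < params.min_contig_len:
            log.warning("contig %s (%d nt) below length filter", contig.id, len(contig))
            continue
        for cand in find_ltr_pairs(contig, params):
            refined = refine_boundaries(cand, contig, params)
            fwd = _evaluate(refined, contig, params, trna_oligos, strand="+")
            best = fwd
            if fwd.missing_features() > params.missing_features_allowed:
                rc_contig = SequenceRecord(contig.id, revcomp(contig.sequence))
                mirrored = _mirror_candidate(refined, len(contig))
                rev = _evaluate(mirrored, rc_contig, params, trna_oligos, strand="-")
                if rev.missing_features() < fwd.missing_features():
                    best = _mirror_element(rev, len(contig))
            if best.missing_features() <= params.missing_features_allowed:
                elements.append(best)
    elements.sort(key=lambda e: (e.contig_id, e.start))
    for i, el in enumerate(elements, 1):
        el.element_id = f"RE_{el.contig_id}_{el.start + 1}"
    return elements


def _evaluate(cand: LtrPairCandidate, contig: SequenceRecord, params: DetectorParams,
              trna_oligos: list[SequenceRecord], strand: str) -> FullLengthRE:
    span = cand.span
    tsd = detect_tsd(contig, span)
    pbs = detect_pbs(contig, cand.five_ltr, trna_oligos, params.pbs_window, params.pbs_max_mismatches)
    ppt = detect_ppt(contig, cand.three_ltr, params.ppt_window, params.ppt_min_purine)
    seq = contig.sequence[span.start : span.end]
    ppt_frac = _ppt_fraction(contig.sequence[ppt.start : ppt.end]) if ppt else None
    return FullLengthRE(
        contig_id=cand.contig_id,
        five_ltr=cand.five_ltr,
        three_ltr=cand.three_ltr,
        ltr_identity=cand.ltr_identity,
        strand=strand,
        element_sequence=seq,
        element_id="",
        tsd=tsd,
        pbs=pbs,
        ppt=ppt,
        has_tg_ca=getattr(cand, "has_tg_ca", False),
        ppt_purine_fraction=ppt_frac,
    )


def elements_from_gff3(gff_path, contigs: list[SequenceRecord]) -> list[FullLengthRE]:
    """Rebuild FullLengthRE objects from a detector GFF3 plus the contigs."""
    from .io import read_gff3

    by_id = {c.id: c for c in contigs}
    feats = read_gff3(gff_path)
    spans = [f for f in feats if f["type"] == "LTR_retrotransposon"]
    children: dict[str, list[dict]] = {}
    for f in feats:
        parent = f["attributes"].get("Parent")
        if parent:
            children.setdefault(parent, []).append(f)
    elements = []
    for span in spans:
        eid = span["attributes"]["ID"]
        contig = by_id.get(span["contig_id"])
        if contig is None:
            raise ValueError(f"contig {span['contig_id']!r} not present in FASTA")
        ltrs = sorted(
            (f for f in children.get(eid, []) if f["type"] == "long_terminal_repeat"),
            key=lambda f: f["start"],
        )
        if len(ltrs) != 2:
            raise ValueError(f"element {eid} does not have two LTR children")
        pbs = next((f for f in children.get(eid, []) if f["type"] == "primer_binding_site"), None)
        ppt = next((f for f in children.get(eid, []) if f["type"] == "RR_tract"), None)
        tsds = [f for f in children.get(eid, []) if f["type"] == "target_site_duplication"]
        cid = span["contig_id"]
        elements.append(
            FullLengthRE(
                contig_id=cid,
                five_ltr=GenomicInterval(cid, ltrs[0]["start"], ltrs[0]["end"]),
                three_ltr=GenomicInterval(cid, ltrs[1]["start"], ltrs[1]["end"]),
                ltr_identity=float(span["attributes"].get("ltr_identity", "0")),
                strand=span["strand"],
                element_sequence=contig.sequence[span["start"] : span["end"]],
                element_id=eid,
                tsd=tsds[0]["attributes"].get("seq") if tsds else None,
                pbs=GenomicInterval(cid, pbs["start"], pbs["end"]) if pbs else None,
                ppt=GenomicInterval(cid, ppt["start"], ppt["end"]) if ppt else None,
                has_tg_ca=span["attributes"].get("has_tg_ca") == "true",
                superfamily=span["attributes"].get("superfamily"),
            )
        )
    return elements


def _mirror_interval(iv: GenomicInterval, contig_len: int) -> GenomicInterval:
    return GenomicInterval(iv.contig_id, contig_len - iv.end, contig_len - iv.start, iv.strand)


def _mirror_candidate(cand: LtrPairCandidate, contig_len: int) -> LtrPairCandidate:
    out = LtrPairCandidate(
        contig_id=cand.contig_id,
        five_ltr=_mirror_interval(cand.three_ltr, contig_len),
        three_ltr=_mirror_interval(cand.five_ltr, contig_len),
        ltr_identity=cand.ltr_identity,
        strand=cand.strand,
    )
    out.has_tg_ca = getattr(cand, "has_tg_ca", False)
    return out


def _mirror_element(el: FullLengthRE, contig_len: int) -> FullLengthRE:
    return replace(
        el,
        five_ltr=_mirror_interval(el.three_ltr, contig_len),
        three_ltr=_mirror_interval(el.five_ltr, contig_len),
        pbs=_mirror_interval(el.pbs, contig_len) if el.pbs else None,
        ppt=_mirror_interval(el.ppt, contig_len) if el.ppt else None,
    )
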