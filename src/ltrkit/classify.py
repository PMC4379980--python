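"""Superfamily classification from protein-domain order.

Copia and Gypsy elements encode the same polyprotein domains but in a
different order: integrase (INT) lies upstream of reverse transcriptase
(RT) in Copia and downstream of RNaseH (RH) in Gypsy; a chromodomain
(CHD) at the integrase C-terminus marks a Gypsy subgroup.  Domains are
located by translated Smith-Waterman search of the element's internal
region against a bundled protein library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Seq import Seq

from .io import GenomicInterval, SequenceRecord, revcomp
from ._align import align_stats, protein_local_aligner
from .detect import FullLengthRE

log = logging.getLogger("ltrkit")

DOMAIN_LABELS = ("GAG", "PR", "INT", "RT", "RH", "CHD")

FRAMES = (1, 2, 3, -1, -2, -3)


def six_frame_translate(dna: str) -> dict[int, str]:
    """Translate all six reading frames; stops are rendered as ``*``."""
    dna = dna.upper()
    if set(dna) - set("ACGTN"):
        raise ValueError("non-DNA characters in sequence")
    if len(dna) < 3:
        raise ValueError("sequence shorter than one codon")
    out: dict[int, str] = {}
    rc = revcomp(dna)
    for f in (1, 2, 3):
        for strand_seq, frame in ((dna, f), (rc, -f)):
            sub = strand_seq[f - 1 :]
            sub = sub[: len(sub) - len(sub) % 3]
            out[frame] = str(Seq(sub).translate()) if sub else ""
    return out


@dataclass
class DomainHit:
    """One protein-domain alignment on an element (element coordinates)."""

    label: str
    frame: int
    interval: GenomicInterval
    score: float


@dataclass
class SuperfamilyCall:
    superfamily: str  # Copia | Gypsy | Unknown
    chromodomain: bool
    evidence: list[DomainHit]


def _domain_label(ref_id: str) -> str:
    label = ref_id.split("_")[0].upper()
    if label not in DOMAIN_LABELS:
        raise ValueError(f"reference id {ref_id!r} does not start with a domain label")
    return label


def find_domains(element: FullLengthRE | str, reference_proteins: list[SequenceRecord],
                 score_min: float = 55.0) -> list[DomainHit]:
    """Locate protein domains in the element's internal region.

    Each library protein is aligned (local, BLOSUM62, gap open 11 /
    extend 1) against all six frame translations of the internal region;
    hits scoring below ``score_min`` are discarded and overlapping hits
    with the same label are merged keeping the best score.  Returned hits
    are sorted by position on the element.
    """
    if not reference_proteins:
        raise ValueError("reference protein library is empty")
    if isinstance(element, str):
        internal = element
        internal_off = 0
        contig_id = "element"
    else:
        internal = element.internal_seq()
        internal_off = element.five_ltr.end - element.start
        contig_id = element.element_id or element.contig_id
    if len(internal) < 3:
        return []
    frames = six_frame_translate(internal)
    aligner = protein_local_aligner()
    hits: list[DomainHit] = []
    n = len(internal)
    for frame, prot in frames.items():
        if not prot:
            continue
        for ref in reference_proteins:
            score = aligner.score(prot, ref.sequence)
            if score < score_min:
                continue
            st = align_stats(aligner, prot, ref.sequence)
            aa_start, aa_end = st.target_start, st.target_end
            if frame > 0:
                nt_start = (frame - 1) + 3 * aa_start
                nt_end = (frame - 1) + 3 * aa_end
            else:
                # frame translations of the reverse complement
                off = -frame - 1
                nt_end = n - off - 3 * aa_start
                nt_start = n - off - 3 * aa_end
            nt_start = max(0, nt_start)
            nt_end = min(n, nt_end)
            if nt_end <= nt_start:
                continue
            hits.append(
                DomainHit(
                    label=_domain_label(ref.id),
                    frame=frame,
                    interval=GenomicInterval(contig_id, internal_off + nt_start, internal_off + nt_end),
                    score=float(score),
                )
            )
    return _merge_hits(hits)


def _merge_hits(hits: list[DomainHit]) -> list[DomainHit]:
    hits.sort(key=lambda h: (h.label, -h.score))
    merged: list[DomainHit] = []
    for h in hits:
        clash = False
        for m in merged:
            if m.label == h.label and max(m.interval.start, h.interval.start) < min(m.interval.end, h.interval.end):
                clash = True
                break
        if not clash:
            merged.append(h)
    merged.sort(key=lambda h: h.interval.start)
    return merged


def classify_superfamily(hits: list[DomainHit]) -> SuperfamilyCall:
    """Call Copia/Gypsy/Unknown from the genomic order of domain hits.

    INT upstream of RT means Copia; INT downstream of RH (or of RT when
    no RH hit exists) means Gypsy.  Order is read along the coding strand
    (negative-frame hits reverse the genomic order), which makes the call
    invariant to the element's strand.  Without both an RT and an INT
    anchor the order is undecidable and the element stays Unknown.
    """
    by_label: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_label.setdefault(h.label, []).append(h)
    ints = by_label.get("INT", [])
    rts = by_label.get("RT", [])
    rhs = by_label.get("RH", [])
    chds = by_label.get("CHD", [])
    if not ints or not rts:
        if not ints and not rts:
            return SuperfamilyCall("Unknown", False, list(hits))
        log.warning("element has %s but not both INT and RT; order undecidable",
                    "INT" if ints else "RT")
        return SuperfamilyCall("Unknown", False, list(hits))
    # coding strand = score-weighted majority of hit frames
    minus = sum(h.score for h in hits if h.frame < 0)
    plus = sum(h.score for h in hits if h.frame > 0)

    def pos(h: DomainHit) -> int:
        return h.interval.start if plus >= minus else -h.interval.end

    rt_start = min(pos(h) for h in rts)
    rh_start = min(pos(h) for h in rhs) if rhs else rt_start
    int_before = any(pos(h) < rt_start for h in ints)
    int_after = any(pos(h) > rh_start for h in ints)
    if int_before and int_after:
        log.warning("contradictory INT placements; classified Unknown")
        return SuperfamilyCall("Unknown", False, list(hits))
    if int_before:
        return SuperfamilyCall("Copia", False, list(hits))
    if int_after:
        int_min = min(pos(h) for h in ints)
        chromo = any(pos(c) > int_min for c in chds)
        return SuperfamilyCall("Gypsy", chromo, list(hits))
    return SuperfamilyCall("Unknown", False, list(hits))


def classify_element(element: FullLengthRE, reference_proteins: list[SequenceRecord],
                     score_min: float = 55.0) -> SuperfamilyCall:
    call = classify_superfamily(find_domains(element, reference_proteins, score_min))
    element.superfamily = call.superfamily
    return call


def reclassify_unknowns(calls: dict[str, SuperfamilyCall], elements: list[FullLengthRE],
                        min_len: int = 400, min_identity: float = 0.80) -> dict[str, SuperfamilyCall]:
    """Second-pass nucleotide assignment of Unknown elements.

    An Unknown inherits the superfamily of its best classified nucleotide
    hit when the local alignment spans at least ``min_len`` nt at
    ``min_identity`` identity or better.
    """
    from ._align import nt_local_aligner

    aligner = nt_local_aligner()
    by_id = {el.element_id: el for el in elements}
    classified = [eid for eid, c in calls.items() if c.superfamily in ("Copia", "Gypsy")]
    for eid, call in calls.items():
        if call.superfamily != "Unknown":
            continue
        query = by_id[eid].element_sequence
        best: tuple[float, str] | None = None
        for other in classified:
            st = align_stats(aligner, by_id[other].element_sequence, query)
            if st.columns >= min_len and st.identity >= min_identity:
                if best is None or st.identity > best[0]:
                    best = (st.identity, other)
        if best is not None:
            inherited = calls[best[1]].superfamily
            calls[eid] = SuperfamilyCall(inherited, False, call.evidence)
            by_id[eid].superfamily = inherited
    return calls
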