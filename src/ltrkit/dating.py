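"""Insertion-age dating from sister-LTR divergence.

The two LTRs of a retroelement are identical at insertion and diverge
under a molecular clock afterwards.  Ages follow from three steps:

1. the LTR pair is globally aligned and gapped columns are removed
   (complete deletion), giving a proportion of mismatching sites p;
2. p is corrected for multiple hits with the one-parameter Jukes-Cantor
   model, K = -(3/4) ln(1 - (4/3) p);
3. K is divided by an LTR substitution rate calibrated from the mean
   synonymous divergence (Nei-Gojobori 1986 Ks, Jukes-Cantor corrected)
   of ortholog pairs spanning a known split time: r_syn = mean(Ks)/T and
   r_ltr = 2 r_syn, LTRs evolving about twice as fast as synonymous
   sites in genes.

The default age convention is ``age = K / r_ltr``; the alternative
``K / (2 r_ltr)`` reading is available via configuration.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._align import align_stats, nt_global_aligner

log = logging.getLogger("ltrkit")

STANDARD_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

BASES = "ACGT"


class SaturationError(ValueError):
    """Raised when a p-distance is at or beyond the Jukes-Cantor domain."""


# --------------------------------------------------------------------------
# LTR alignment
# --------------------------------------------------------------------------

@dataclass
class LtrAlignment:
    aligned_cols: int
    indel_free_cols: int
    mismatches: int

    def __post_init__(self) -> None:
        if not (self.mismatches <= self.indel_free_cols <= self.aligned_cols):
            raise ValueError("inconsistent alignment counts")

    @property
    def p_distance(self) -> float:
        if self.indel_free_cols == 0:
            raise ValueError("no indel-free columns to compare")
        return self.mismatches / self.indel_free_cols


def align_ltr_pair(five_ltr_seq: str, three_ltr_seq: str) -> LtrAlignment:
    """Global alignment of a sister-LTR pair with complete gap deletion.

    Needleman-Wunsch (match +2, mismatch -1, gap open -10, extend -0.5);
    every column containing a gap is discarded before the p-distance is
    computed.
    """
    if not five_ltr_seq or not three_ltr_seq:
        raise ValueError("empty LTR sequence")
    st = align_stats(nt_global_aligner(), five_ltr_seq.upper(), three_ltr_seq.upper())
    return LtrAlignment(
        aligned_cols=st.columns,
        indel_free_cols=st.identities + st.mismatches,
        mismatches=st.mismatches,
    )


def jc_distance(p: float) -> float:
    """Jukes-Cantor correction K = -(3/4) ln(1 - (4/3) p)."""
    if p < 0:
        raise ValueError("p-distance cannot be negative")
    if p >= 0.75:
        raise SaturationError(f"p = {p:.4f} is at or beyond JC saturation (0.75)")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


# --------------------------------------------------------------------------
# Nei-Gojobori 1986
# --------------------------------------------------------------------------

@dataclass
class NgCounts:
    """Synonymous/nonsynonymous site and difference counts (NG86)."""

    S: float
    N: float
    Sd: float
    Nd: float

    @property
    def ps(self) -> float:
        return self.Sd / self.S if self.S else 0.0

    @property
    def pn(self) -> float:
        return self.Nd / self.N if self.N else 0.0


def _codon_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one codon.

    Each position contributes (number of synonymous single-base changes)/3;
    changes to stop codons are never synonymous, so they count towards the
    nonsynonymous side (the original NG86 site definition, also used by
    the common implementations).
    """
    aa = STANDARD_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if STANDARD_TABLE[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def _codon_diff_counts(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous differences between two codons.

    Multi-difference codons average over all orderings of the single-base
    changes; pathways passing through a stop codon are excluded (all
    pathways are used if every one hits a stop).
    """
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    valid: list[tuple[float, float]] = []
    fallback: list[tuple[float, float]] = []
    for order in itertools.permutations(positions):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            aa1, aa2 = STANDARD_TABLE[cur], STANDARD_TABLE[nxt]
            if aa2 == "*" and nxt != c2:
                through_stop = True
            if aa1 == aa2:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (fallback if through_stop else valid).append((sd, nd))
    paths = valid or fallback
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def ng86_counts(seq1: str, seq2: str) -> NgCounts:
    """NG86 site and difference counts for a gap-free codon alignment."""
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2):
        raise ValueError("sequences must have equal length")
    if len(seq1) % 3:
        raise ValueError("sequence length must be a multiple of 3")
    if "-" in seq1 or "-" in seq2:
        raise ValueError("gapped codons must be removed before NG86 counting")
    S1 = S2 = Sd = Nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if STANDARD_TABLE[c1] == "*" or STANDARD_TABLE[c2] == "*":
            if i + 3 < len(seq1):
                raise ValueError(f"internal stop codon at nt {i}")
            continue  # terminal stop: excluded from counting
        s1, _ = _codon_site_counts(c1)
        s2, _ = _codon_site_counts(c2)
        S1 += s1
        S2 += s2
        sd, nd = _codon_diff_counts(c1, c2)
        Sd += sd
        Nd += nd
    S = (S1 + S2) / 2.0
    codons = sum(
        1
        for i in range(0, len(seq1), 3)
        if STANDARD_TABLE[seq1[i : i + 3]] != "*" and STANDARD_TABLE[seq2[i : i + 3]] != "*"
    )
    return NgCounts(S=S, N=3.0 * codons - S, Sd=Sd, Nd=Nd)


def ng86_ks(seq1: str, seq2: str) -> tuple[NgCounts, float]:
    """NG86 Ks with Jukes-Cantor correction for one codon-aligned pair."""
    counts = ng86_counts(seq1, seq2)
    ks = jc_distance(counts.ps)
    return counts, ks


# --------------------------------------------------------------------------
# rate calibration and ages
# --------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    ks_per_gene: list[float]
    split_time_years: float = 42.5e6

    @property
    def mean_ks(self) -> float:
        return float(np.mean(self.ks_per_gene))

    @property
    def r_syn(self) -> float:
        """Synonymous substitutions per site per year."""
        return self.mean_ks / self.split_time_years

    @property
    def r_ltr(self) -> float:
        """LTR substitution rate: twice the synonymous rate."""
        return 2.0 * self.r_syn


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting convention for rates)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def calibrate_rate(ortholog_pairs: list[tuple[str, str]], split_time_years: float = 42.5e6) -> CalibrationResult:
    """Per-gene NG86 Ks for each codon-aligned ortholog pair, then rates.

    Saturated pairs are dropped with a warning; if every pair saturates
    the calibration fails.
    """
    if not ortholog_pairs:
        raise ValueError("no ortholog pairs supplied")
    if split_time_years <= 0:
        raise ValueError("split time must be positive")
    ks_values: list[float] = []
    for a, b in ortholog_pairs:
        try:
            _, ks = ng86_ks(a, b)
        except SaturationError:
            log.warning("saturated ortholog pair skipped")
            continue
        ks_values.append(ks)
    if not ks_values:
        raise SaturationError("all ortholog pairs are saturated")
    result = CalibrationResult(ks_per_gene=ks_values, split_time_years=split_time_years)
    if result.mean_ks == 0:
        log.warning("mean Ks is zero; substitution rate is zero")
    return result


@dataclass
class AgeEstimate:
    K: float
    age_years: float
    zero_div_upper_bound_years: float | None
    convention: str = "K_over_r"

    @property
    def age_my(self) -> float:
        return self.age_years / 1e6


def estimate_age(alignment: LtrAlignment, rates: CalibrationResult,
                 convention: str = "K_over_r") -> AgeEstimate:
    """Insertion age from one sister-LTR alignment.

    ``K_over_r`` (default): age = K / r_ltr.  ``K_over_2r``: age =
    K / (2 r_ltr).  For identical LTRs (K = 0) the age is 0 and an upper
    bound corresponding to a single substitution across the aligned
    length is reported.
    """
    if convention not in ("K_over_r", "K_over_2r"):
        raise ValueError(f"unknown convention {convention!r}")
    if rates.r_ltr <= 0:
        raise ValueError("LTR substitution rate must be positive")
    denom = rates.r_ltr if convention == "K_over_r" else 2.0 * rates.r_ltr
    K = jc_distance(alignment.p_distance)
    age = K / denom
    bound = None
    if K == 0:
        bound = jc_distance(1.0 / alignment.indel_free_cols) / denom
    return AgeEstimate(K=K, age_years=age, zero_div_upper_bound_years=bound, convention=convention)


def batch_ages(ltr_pairs: dict[str, tuple[str, str]], rates: CalibrationResult,
               convention: str = "K_over_r",
               superfamilies: dict[str, str] | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Age every element and summarize mean +/- SE overall and per superfamily.

    ``ltr_pairs`` maps element id -> (5' LTR sequence, 3' LTR sequence).
    Returns (per-element table, summary table); ages in MY to 0.01.
    """
    if not ltr_pairs:
        raise ValueError("no elements to date")
    rows = []
    for eid, (l5, l3) in ltr_pairs.items():
        aln = align_ltr_pair(l5, l3)
        try:
            est = estimate_age(aln, rates, convention)
        except SaturationError:
            log.warning("element %s saturated; excluded from ages", eid)
            continue
        rows.append(
            {
                "element_id": eid,
                "superfamily": (superfamilies or {}).get(eid, "all"),
                "K": est.K,
                "age_MY": round(est.age_my, 2),
                "bound_MY": round(est.zero_div_upper_bound_years / 1e6, 3)
                if est.zero_div_upper_bound_years is not None
                else float("nan"),
            }
        )
    table = pd.DataFrame(rows)
    groups = [("all", table)]
    if superfamilies:
        groups += [(sf, g) for sf, g in table.groupby("superfamily")]
    summary_rows = []
    for name, g in groups:
        n = len(g)
        mean = g["age_MY"].mean() if n else float("nan")
        se = g["age_MY"].std(ddof=1) / math.sqrt(n) if n > 1 else 0.0
        summary_rows.append({"group": name, "n": n, "mean_age_MY": round(mean, 2), "se_MY": round(se, 2)})
    return table, pd.DataFrame(summary_rows)
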