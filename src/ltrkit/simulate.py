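"""Synthetic genomes, reads and calibration inputs with known ground truth.

The generator plants full-length LTR retroelements (TG...CA termini,
4-6 nt target-site duplications, PBS, PPT, domain-encoding ORFs in the
requested Copia/Gypsy order) and recombination-derived solo-LTRs into a
random background genome, diverges sister LTRs under a Jukes-Cantor
clock to prescribed ages, samples uniform-coverage shotgun reads with
i.i.d. substitution errors, and emits codon-aligned ortholog pairs with
a prescribed expected synonymous divergence.  Everything placed is
recorded in a truth manifest sufficient to score every downstream stage.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import SequenceRecord, revcomp, bundled_trna_oligos, bundled_domain_proteins
from .dating import STANDARD_TABLE, _codon_site_counts

log = logging.getLogger("ltrkit")

BASES = np.array(list("ACGT"))

# most-frequent plant codon per amino acid, used to back-translate the
# bundled domain proteins into detectable ORFs
PLANT_CODON = {
    "A": "GCT", "R": "AGA", "N": "AAC", "D": "GAT", "C": "TGC",
    "Q": "CAA", "E": "GAA", "G": "GGA", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAG", "M": "ATG", "F": "TTC", "P": "CCA",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAC", "V": "GTT",
    "*": "TAA",
}

DOMAIN_ORDERS = {
    "Copia": ("GAG", "PR", "INT", "RT", "RH"),
    "Gypsy": ("GAG", "PR", "RT", "RH", "INT"),
    "Gypsy+CHD": ("GAG", "PR", "RT", "RH", "INT", "CHD"),
}


@dataclass
class ElementTemplateSpec:
    """Blueprint of one element family."""

    family_id: str
    superfamily: str = "Copia"  # Copia | Gypsy | Gypsy+CHD
    ltr_len: int = 400
    internal_len: int | None = None  # None: sized to fit the ORF
    with_tg_ca: bool = True
    with_tsd: bool = True
    with_pbs: bool = True
    with_ppt: bool = True
    with_domains: bool = True
    domain_order: tuple[str, ...] | None = None


@dataclass
class ElementTemplate:
    spec: ElementTemplateSpec
    sequence: str  # 5' LTR + internal + 3' LTR (LTRs identical)
    ltr_len: int
    feature_map: dict


@dataclass
class PlantedCopy:
    family_id: str
    element_id: str
    start: int  # final-genome coordinates of the element proper
    end: int
    ltr_len: int
    age_years: float
    tsd: str
    solo: bool
    realized_k: float  # realized JC distance between the two LTRs (0 for solos)


@dataclass
class TruthManifest:
    genome_length: int
    copies: list[PlantedCopy] = field(default_factory=list)
    read_origins: list[dict] = field(default_factory=list)
    ortholog_ks: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        data = {
            "genome_length": self.genome_length,
            "copies": [asdict(c) for c in self.copies],
            "read_origins": self.read_origins,
            "ortholog_ks": self.ortholog_ks,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.4) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def back_translate(protein: str) -> str:
    return "".join(PLANT_CODON[aa] for aa in protein)


# --------------------------------------------------------------------------
# element templates
# --------------------------------------------------------------------------

def build_template(spec: ElementTemplateSpec, rng: np.random.Generator,
                   trna_oligos: list[SequenceRecord] | None = None,
                   domain_proteins: list[SequenceRecord] | None = None) -> ElementTemplate:
    """Construct one element template with the requested features.

    The LTR begins with TG and ends with CA (when enabled); the PBS is
    the reverse complement of a bundled tRNA 3'-end 18-mer placed 1 nt
    after the 5' LTR; the PPT is a 22-nt purine run directly upstream of
    the 3' LTR; the internal ORF encodes the superfamily's domain order
    in frame +1 via back-translation of the bundled domain proteins.
    """
    trna_oligos = trna_oligos or bundled_trna_oligos()
    domain_proteins = domain_proteins or bundled_domain_proteins()
    if not (100 <= spec.ltr_len <= 3500):
        raise ValueError("LTR length outside detector bounds")

    ltr = list(random_dna(rng, spec.ltr_len))
    if spec.with_tg_ca:
        ltr[0:2] = "TG"
        ltr[-2:] = "CA"
    else:
        # make sure the termini are NOT the canonical dinucleotides
        if "".join(ltr[0:2]) == "TG":
            ltr[0] = "A"
        if "".join(ltr[-2:]) == "CA":
            ltr[-1] = "T"
    ltr = "".join(ltr)

    parts: list[str] = []
    feature_map: dict = {"ltr_len": spec.ltr_len, "superfamily": spec.superfamily}
    if spec.with_pbs:
        oligo = trna_oligos[int(rng.integers(len(trna_oligos)))]
        pbs = revcomp(oligo.sequence[-18:])
        parts.append(random_dna(rng, 1) + pbs)
        feature_map["pbs_oligo"] = oligo.id
    orf = ""
    if spec.with_domains:
        order = spec.domain_order or DOMAIN_ORDERS[spec.superfamily]
        by_label: dict[str, SequenceRecord] = {}
        lineage = "gypsy" if spec.superfamily.startswith("Gypsy") else "copia"
        for p in domain_proteins:
            label = p.id.split("_")[0].upper()
            if label not in by_label or lineage in p.id.lower():
                by_label[label] = p
        missing = [lab for lab in order if lab not in by_label]
        if missing:
            raise ValueError(f"domain library lacks {missing}")
        protein = "M" + "GS".join(by_label[lab].sequence for lab in order)
        orf = back_translate(protein)
        feature_map["domain_order"] = list(order)
    parts.append(random_dna(rng, 30))
    parts.append(orf)
    internal = "".join(parts)
    if spec.internal_len is not None:
        if spec.internal_len < len(internal) + (52 if spec.with_ppt else 30):
            raise ValueError(
                f"internal_len {spec.internal_len} cannot hold the requested features "
                f"({len(internal)} nt minimum)"
            )
        pad = spec.internal_len - len(internal) - (22 if spec.with_ppt else 0)
        internal += random_dna(rng, pad)
    else:
        internal += random_dna(rng, 120)
    if spec.with_ppt:
        ppt = "".join(rng.choice(np.array(list("AG")), size=22, p=[0.45, 0.55]))
        internal += ppt
        feature_map["ppt_len"] = 22

    seq = ltr + internal + ltr
    feature_map["internal_len"] = len(internal)
    if 3500 < spec.ltr_len or not (1000 <= len(seq) <= 16000):
        log.warning("template %s length %d outside default detector bounds", spec.family_id, len(seq))
    return ElementTemplate(spec=spec, sequence=seq, ltr_len=spec.ltr_len, feature_map=feature_map)


# --------------------------------------------------------------------------
# LTR divergence clock
# --------------------------------------------------------------------------

def _jc_mutate(seq: str, p_site: float, rng: np.random.Generator) -> str:
    """Substitute each site with probability p_site, uniformly to another base."""
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < p_site
    idx = np.nonzero(hit)[0]
    for i in idx:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def age_ltrs(template: ElementTemplate, age_years: float, r_ltr: float,
             rng: np.random.Generator, convention: str = "K_over_r") -> tuple[str, float]:
    """Diverge the template's two LTRs to a prescribed age under JC69.

    Each LTR mutates independently at the per-LTR rate mu implied by the
    dating convention (mu = r_ltr/2 for ``K_over_r`` so that the expected
    between-LTR JC distance is r_ltr * age; mu = r_ltr for ``K_over_2r``).
    Returns the aged element sequence and the realized JC distance.
    """
    if age_years < 0:
        raise ValueError("age must be non-negative")
    mu = r_ltr / 2.0 if convention == "K_over_r" else r_ltr
    p_site = 0.75 * (1.0 - math.exp(-(4.0 / 3.0) * mu * age_years))
    L = template.ltr_len
    ltr5 = _jc_mutate(template.sequence[:L], p_site, rng)
    ltr3 = _jc_mutate(template.sequence[len(template.sequence) - L :], p_site, rng)
    internal = template.sequence[L : len(template.sequence) - L]
    seq = ltr5 + internal + ltr3
    mism = sum(1 for a, b in zip(ltr5, ltr3) if a != b)
    p = mism / L
    realized_k = -0.75 * math.log1p(-(4.0 / 3.0) * p) if p < 0.75 else float("inf")
    return seq, realized_k


# --------------------------------------------------------------------------
# genome assembly
# --------------------------------------------------------------------------

def plant_elements(genome: str, templates: list[ElementTemplate],
                   copies_per_family: int, solos_per_family: int,
                   ages_years: dict[str, float] | list[float] | float,
                   r_ltr: float, rng: np.random.Generator,
                   convention: str = "K_over_r",
                   min_spacing: int = 0) -> tuple[str, TruthManifest]:
    """Insert aged copies and solo-LTRs into a background genome.

    Every insertion duplicates a 4-6 nt target site around the inserted
    sequence; a solo insertion places a single LTR between one TSD pair,
    the signature left by unequal homologous recombination.  Insertion
    points are drawn uniformly without overlap (optionally with a
    minimum spacing); each full copy's LTR pair is aged independently.
    """
    jobs = []  # (template, solo?, age)
    for t in templates:
        if isinstance(ages_years, dict):
            age = ages_years[t.spec.family_id]
        elif isinstance(ages_years, (list, tuple)):
            age = None  # drawn per copy below
        else:
            age = float(ages_years)
        for _ in range(copies_per_family):
            a = age if age is not None else float(rng.choice(ages_years))
            jobs.append((t, False, a))
        for _ in range(solos_per_family):
            jobs.append((t, True, 0.0))

    n_sites = len(jobs)
    glen = len(genome)
    need = sum(len(t.sequence) for t, solo, _ in jobs)
    if glen < (min_spacing + 10) * n_sites + 20:
        raise ValueError("background genome too short for the requested insertions")
    # spaced uniform insertion points: draw in the shrunken interval and
    # re-expand, which guarantees the spacing without rejection sampling
    spacing = max(10, min_spacing)
    usable = glen - 20 - (n_sites - 1) * spacing
    if usable < n_sites:
        raise ValueError("could not place insertions with the requested spacing")
    base = np.sort(rng.integers(0, usable, size=n_sites))
    points = base + 10 + np.arange(n_sites) * spacing
    order = rng.permutation(n_sites)

    manifest = TruthManifest(genome_length=0)
    pieces: list[str] = []
    cursor = 0
    out_len = 0
    records: list[PlantedCopy] = []
    for site_idx, job_idx in enumerate(order):
        template, solo, age = jobs[job_idx]
        pos = int(points[site_idx])
        tsd_len = int(rng.integers(4, 7))
        tsd = genome[pos : pos + tsd_len]
        if solo:
            insert = template.sequence[: template.ltr_len]
            realized_k = 0.0
        else:
            insert, realized_k = age_ltrs(template, age, r_ltr, rng, convention)
        pieces.append(genome[cursor : pos + tsd_len])
        out_len += pos + tsd_len - cursor
        el_start = out_len
        pieces.append(insert)
        out_len += len(insert)
        el_end = out_len
        pieces.append(tsd)
        out_len += tsd_len
        cursor = pos + tsd_len
        records.append(
            PlantedCopy(
                family_id=template.spec.family_id,
                element_id=f"{template.spec.family_id}_{'solo' if solo else 'copy'}_{site_idx}",
                start=el_start,
                end=el_end,
                ltr_len=template.ltr_len,
                age_years=0.0 if solo else age,
                tsd=tsd,
                solo=solo,
                realized_k=realized_k,
            )
        )
    pieces.append(genome[cursor:])
    out_len += glen - cursor
    final = "".join(pieces)
    manifest.genome_length = len(final)
    manifest.copies = sorted(records, key=lambda c: c.start)
    return final, manifest


# --------------------------------------------------------------------------
# reads and orthologs
# --------------------------------------------------------------------------

def simulate_reads(genome: str, coverage: float, read_len: int, error_rate: float,
                   rng: np.random.Generator) -> tuple[list[SequenceRecord], list[dict]]:
    """Uniform shotgun reads from both strands with i.i.d. substitution errors."""
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if read_len > len(genome):
        raise ValueError("read length exceeds genome length")
    if not (0 <= error_rate < 0.1):
        raise ValueError("error rate must be in [0, 0.1)")
    n_reads = int(round(coverage * len(genome) / read_len))
    starts = rng.integers(0, len(genome) - read_len + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    reads: list[SequenceRecord] = []
    origins: list[dict] = []
    for i, (s, st) in enumerate(zip(starts, strands)):
        frag = genome[s : s + read_len]
        if st:
            frag = revcomp(frag)
        if error_rate > 0:
            frag = _jc_mutate(frag, error_rate, rng)
        rid = f"read_{i}"
        reads.append(SequenceRecord(rid, frag))
        origins.append({"read_id": rid, "start": int(s), "strand": "-" if st else "+"})
    return reads, origins


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = [c for c, aa in STANDARD_TABLE.items() if aa != "*" and aa != "M"]
    seq = ["ATG"] + [codons[int(rng.integers(len(codons)))] for _ in range(n_codons - 1)]
    return "".join(seq)


def simulate_orthologs(count: int, codon_len: int, target_ks: float,
                       rng: np.random.Generator) -> tuple[list[tuple[str, str]], list[float]]:
    """Codon-aligned ortholog pairs with expected NG86 Ks = ``target_ks``.

    The expected proportion of synonymous differences per synonymous site
    is ps = (3/4)(1 - exp(-(4/3) Ks)); each codon position with a
    synonymous mutational option is flipped to a random synonymous
    neighbour with probability ps * (synonymous fraction of the position),
    which makes E[Sd]/S = ps under NG86 counting.  Realized per-pair Ks
    values are returned alongside the pairs.
    """
    if not (0 <= target_ks < 1.0):
        # beyond Ks ~1 the per-pair estimator is close to saturation and
        # the single-flip generator can no longer hit the target
        raise ValueError("target Ks must be in [0, 1)")
    ps_target = 0.75 * (1.0 - math.exp(-(4.0 / 3.0) * target_ks))
    from .dating import ng86_ks

    pairs: list[tuple[str, str]] = []
    realized: list[float] = []
    for _ in range(count):
        a = _random_cds(rng, codon_len)
        b = list(a)
        for ci in range(codon_len):
            codon = a[3 * ci : 3 * ci + 3]
            if STANDARD_TABLE[codon] == "*":
                continue
            for pos in range(3):
                syn_opts = [
                    x
                    for x in "ACGT"
                    if x != codon[pos]
                    and STANDARD_TABLE[codon[:pos] + x + codon[pos + 1 :]] == STANDARD_TABLE[codon]
                ]
                if not syn_opts:
                    continue
                non_stop = [
                    x
                    for x in "ACGT"
                    if x != codon[pos]
                    and STANDARD_TABLE[codon[:pos] + x + codon[pos + 1 :]] != "*"
                ]
                frac = len(syn_opts) / len(non_stop)
                if rng.random() < ps_target * frac:
                    b[3 * ci + pos] = syn_opts[int(rng.integers(len(syn_opts)))]
        b = "".join(b)
        pairs.append((a, b))
        _, ks = ng86_ks(a, b)
        realized.append(ks)
    return pairs, realized
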