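"""Sequence/annotation readers and writers, run configuration, seeded RNG streams.

Internal coordinates are 0-based half-open throughout the package; GFF3 output
is 1-based inclusive as required by the format.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

log = logging.getLogger("ltrkit")

DNA_ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-tolerant)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named DNA or protein sequence."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record must have a non-empty id")
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named contig."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def shifted(self, offset: int) -> "GenomicInterval":
        return dataclasses.replace(self, start=self.start + offset, end=self.end + offset)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (order preserved, uppercased).

    Raises on missing files, duplicate ids and empty records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq), rec.description))
    return records


def read_reads(path: str | Path) -> list[SequenceRecord]:
    """Read short reads from FASTA or FASTQ (qualities are ignored)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), fmt):
        if rec.id in seen:
            raise ValueError(f"duplicate read id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq), rec.description))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def bundled_trna_oligos() -> list[SequenceRecord]:
    """tRNA 3'-end 18-mers used for PBS detection.

    The shipped set is a synthetic stand-in for a curated plant tRNA library
    and is user-replaceable with any FASTA of 3'-terminal oligos.
    """
    ref = resources.files("ltrkit.data") / "trna_oligos_synthetic.fasta"
    with resources.as_file(ref) as p:
        return read_fasta(p)


def bundled_domain_proteins() -> list[SequenceRecord]:
    """Reference protein domains (GAG/PR/INT/RT/RH/CHD) for superfamily calls.

    Synthetic stand-ins for a curated plant Copia/Gypsy domain library;
    record ids are ``<LABEL>_<lineage>_...`` and user-replaceable.
    """
    ref = resources.files("ltrkit.data") / "domain_proteins_synthetic.fasta"
    with resources.as_file(ref) as p:
        return read_fasta(p)


# --------------------------------------------------------------------------
# GFF3
# --------------------------------------------------------------------------

GFF_HEADER = "##gff-version 3"


def write_gff3(elements: Sequence, path: str | Path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write detected elements as GFF3 (1-based inclusive coordinates).

    Each element becomes an ``LTR_retrotransposon`` feature with
    ``long_terminal_repeat``, ``target_site_duplication``,
    ``primer_binding_site`` and ``RR_tract`` children linked via Parent.
    """
    lines = [GFF_HEADER]
    for el in elements:
        contig = el.contig_id
        if contig_lengths is not None:
            clen = contig_lengths.get(contig)
            if clen is not None and el.three_ltr.end > clen:
                raise ValueError(f"element {el.element_id} exceeds contig bounds")
        eid = el.element_id
        strand = el.strand
        attrs = [f"ID={eid}", f"ltr_identity={el.ltr_identity:.4f}"]
        if getattr(el, "superfamily", None):
            attrs.append(f"superfamily={el.superfamily}")
        attrs.append(f"has_tg_ca={'true' if el.has_tg_ca else 'false'}")
        lines.append(_gff_line(contig, "LTR_retrotransposon", el.five_ltr.start, el.three_ltr.end, strand, ";".join(attrs)))
        lines.append(_gff_line(contig, "long_terminal_repeat", el.five_ltr.start, el.five_ltr.end, strand, f"ID={eid}.ltr5;Parent={eid}"))
        lines.append(_gff_line(contig, "long_terminal_repeat", el.three_ltr.start, el.three_ltr.end, strand, f"ID={eid}.ltr3;Parent={eid}"))
        if el.tsd:
            up_start = el.five_ltr.start - len(el.tsd)
            if up_start >= 0:
                lines.append(_gff_line(contig, "target_site_duplication", up_start, el.five_ltr.start, strand, f"ID={eid}.tsd5;Parent={eid};seq={el.tsd}"))
            lines.append(_gff_line(contig, "target_site_duplication", el.three_ltr.end, el.three_ltr.end + len(el.tsd), strand, f"ID={eid}.tsd3;Parent={eid};seq={el.tsd}"))
        if el.pbs is not None:
            lines.append(_gff_line(contig, "primer_binding_site", el.pbs.start, el.pbs.end, strand, f"ID={eid}.pbs;Parent={eid}"))
        if el.ppt is not None:
            lines.append(_gff_line(contig, "RR_tract", el.ppt.start, el.ppt.end, strand, f"ID={eid}.ppt;Parent={eid}"))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _gff_line(contig: str, ftype: str, start0: int, end0: int, strand: str, attrs: str) -> str:
    # 0-based half-open -> 1-based inclusive
    return "\t".join([contig, "ltrkit", ftype, str(start0 + 1), str(end0), ".", strand, ".", attrs])


def read_gff3(path: str | Path) -> list[dict]:
    """Parse a GFF3 file into dicts with 0-based half-open coordinates."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = {}
            for kv in cols[8].split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    attrs[k] = v
            out.append(
                {
                    "contig_id": cols[0],
                    "type": cols[2],
                    "start": int(cols[3]) - 1,
                    "end": int(cols[4]),
                    "strand": cols[6],
                    "attributes": attrs,
                }
            )
    return out


# --------------------------------------------------------------------------
# Configuration and RNG streams
# --------------------------------------------------------------------------

# stable per-stage stream ids so stages are order-independent
_STAGE_IDS = {
    "simulate": 1,
    "detect": 2,
    "classify": 3,
    "calibrate": 4,
    "date": 5,
    "map": 6,
    "phylo": 7,
    "report": 8,
}


def rng_for(seed: int, stage: str) -> np.random.Generator:
    """A reproducible, stage-independent random stream."""
    return np.random.default_rng([int(seed), _STAGE_IDS[stage]])


@dataclass
class RunConfig:
    """Flat bag of every tunable parameter, serializable as key=value text."""

    seed: int = 0
    # detector
    min_contig_len: int = 10_000
    min_ltr_len: int = 100
    max_ltr_len: int = 3_500
    min_elem_len: int = 1_000
    max_elem_len: int = 16_000
    min_ltr_similarity: float = 0.80
    seed_kmer_len: int = 13
    boundary_snap_window: int = 25
    missing_features_allowed: int = 1
    pbs_max_mismatches: int = 2
    ppt_min_purine: float = 0.80
    # classifier
    domain_score_min: float = 55.0
    reclass_min_len: int = 400
    reclass_min_identity: float = 0.80
    # dating
    split_time_years: float = 42.5e6
    age_convention: str = "K_over_r"  # or "K_over_2r"
    # mapper
    min_identity: float = 0.90
    min_length_fraction: float = 0.90
    read_truncate_len: int = 75
    map_kmer_len: int = 15
    solo_ratio_threshold: float = 2.5
    # phylogeny
    min_rt_aa: int = 80
    family_cutoff: float = 0.25
    bootstrap_replicates: int = 100

    def validate(self) -> None:
        if not (0 < self.min_ltr_similarity <= 1):
            raise ValueError("min_ltr_similarity must be in (0,1]")
        if self.min_ltr_len >= self.max_ltr_len:
            raise ValueError("min_ltr_len must be < max_ltr_len")
        if self.min_elem_len >= self.max_elem_len:
            raise ValueError("min_elem_len must be < max_elem_len")
        if not (0 < self.min_identity <= 1 and 0 < self.min_length_fraction <= 1):
            raise ValueError("mapper fractions must be in (0,1]")
        if self.age_convention not in ("K_over_r", "K_over_2r"):
            raise ValueError(f"unknown age convention {self.age_convention!r}")

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in types:
                    raise ValueError(f"unknown config key {key!r}")
                current = getattr(defaults, key)
                kwargs[key] = type(current)(value) if not isinstance(current, str) else value
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg
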