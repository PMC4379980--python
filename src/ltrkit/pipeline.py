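"""End-to-end pipeline: detect -> classify -> calibrate -> date -> map -> phylo -> report.

All stage outputs are plain-text artifacts (GFF3, FASTA, TSV, newick)
written to one output directory; a fixed config+seed yields byte-identical
outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import classify, dating, detect, mapping, phylo, report
from .io import (
    RunConfig,
    SequenceRecord,
    bundled_domain_proteins,
    bundled_trna_oligos,
    read_fasta,
    read_reads,
    rng_for,
    write_fasta,
    write_gff3,
)

log = logging.getLogger("ltrkit")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig, contigs_path: str | Path,
                 reads_path: str | Path | None = None,
                 orthologs_path: str | Path | None = None,
                 outdir: str | Path = "ltrkit_out") -> dict:
    """Run every stage on the given inputs and write the report bundle.

    ``orthologs_path`` is a FASTA of codon-aligned ortholog pairs in
    consecutive record pairs; without it a default calibration
    (mean Ks 0.077 over a 42.5 MY split) is used for dating.
    Returns a dict of the in-memory artifacts.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    # ---- detect ----
    try:
        contigs = read_fasta(contigs_path)
        params = detect.DetectorParams(
            min_contig_len=config.min_contig_len,
            min_ltr_len=config.min_ltr_len,
            max_ltr_len=config.max_ltr_len,
            min_elem_len=config.min_elem_len,
            max_elem_len=config.max_elem_len,
            min_ltr_similarity=config.min_ltr_similarity,
            seed_kmer_len=config.seed_kmer_len,
            boundary_snap_window=config.boundary_snap_window,
            missing_features_allowed=config.missing_features_allowed,
            pbs_max_mismatches=config.pbs_max_mismatches,
            ppt_min_purine=config.ppt_min_purine,
        )
        trna = bundled_trna_oligos()
        elements = detect.scan_contigs(contigs, params, trna)
        if not elements:
            log.warning("no full-length elements detected")
        write_gff3(elements, outdir / "elements.gff3", {c.id: len(c) for c in contigs})
        write_fasta(
            [SequenceRecord(e.element_id, e.element_sequence) for e in elements],
            outdir / "elements.fasta",
        )
        evidence = pd.DataFrame(
            [
                {
                    "element_id": e.element_id,
                    "contig_id": e.contig_id,
                    "start": e.start,
                    "end": e.end,
                    "strand": e.strand,
                    "ltr5_len": e.five_ltr.length,
                    "ltr3_len": e.three_ltr.length,
                    "ltr_identity": round(e.ltr_identity, 4),
                    "has_tg_ca": e.has_tg_ca,
                    "tsd": e.tsd or ".",
                    "pbs_offset": (e.pbs.start - e.five_ltr.end) if e.pbs else -1,
                    "ppt_purine_fraction": round(e.ppt_purine_fraction, 3) if e.ppt_purine_fraction else -1,
                }
                for e in elements
            ]
        )
        _write_tsv(evidence, outdir / "evidence.tsv")
        artifacts["elements"] = elements
        artifacts["evidence"] = evidence
    except Exception as exc:  # noqa: BLE001
        raise StageError("detect", exc) from exc

    # ---- classify ----
    try:
        library = bundled_domain_proteins()
        calls: dict[str, classify.SuperfamilyCall] = {}
        for el in elements:
            calls[el.element_id] = classify.classify_element(el, library, config.domain_score_min)
        calls = classify.reclassify_unknowns(
            calls, elements, config.reclass_min_len, config.reclass_min_identity
        )
        cls_table = pd.DataFrame(
            [
                {
                    "element_id": eid,
                    "superfamily": c.superfamily,
                    "chromodomain": c.chromodomain,
                    "domain_order": "-".join(h.label for h in c.evidence) or ".",
                    "best_score": max((h.score for h in c.evidence), default=0.0),
                }
                for eid, c in calls.items()
            ]
        )
        _write_tsv(cls_table, outdir / "classification.tsv")
        artifacts["calls"] = calls
    except Exception as exc:  # noqa: BLE001
        raise StageError("classify", exc) from exc

    # ---- calibrate ----
    try:
        if orthologs_path is not None:
            recs = read_fasta(orthologs_path)
            if len(recs) % 2:
                raise ValueError("ortholog FASTA must contain an even number of records")
            pairs = [(recs[i].sequence, recs[i + 1].sequence) for i in range(0, len(recs), 2)]
            rates = dating.calibrate_rate(pairs, config.split_time_years)
        else:
            log.warning("no ortholog input; using default calibration (mean Ks 0.077)")
            rates = dating.CalibrationResult([0.077], config.split_time_years)
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "mean_ks": round(rates.mean_ks, 4),
                        "split_time_MY": rates.split_time_years / 1e6,
                        "r_syn": dating.round_sig(rates.r_syn, 2),
                        "r_ltr": dating.round_sig(rates.r_ltr, 2),
                    }
                ]
            ),
            outdir / "calibration.tsv",
        )
        artifacts["rates"] = rates
    except Exception as exc:  # noqa: BLE001
        raise StageError("calibrate", exc) from exc

    # ---- date ----
    try:
        ltr_pairs = {e.element_id: (e.five_ltr_seq(), e.three_ltr_seq()) for e in elements}
        superfams = {eid: c.superfamily for eid, c in calls.items()}
        if ltr_pairs:
            ages, age_summary = dating.batch_ages(ltr_pairs, rates, config.age_convention, superfams)
        else:
            ages = pd.DataFrame(columns=["element_id", "superfamily", "K", "age_MY", "bound_MY"])
            age_summary = pd.DataFrame(columns=["group", "n", "mean_age_MY", "se_MY"])
        _write_tsv(ages, outdir / "ages.tsv")
        _write_tsv(age_summary, outdir / "age_summary.tsv")
        artifacts["ages"] = ages
    except Exception as exc:  # noqa: BLE001
        raise StageError("date", exc) from exc

    # ---- map ----
    try:
        if reads_path is not None and elements:
            reads = mapping.truncate_reads(read_reads(reads_path), config.read_truncate_len)
            mp = mapping.MapperParams(
                min_identity=config.min_identity,
                min_length_fraction=config.min_length_fraction,
                read_truncate_len=config.read_truncate_len,
                kmer_len=config.map_kmer_len,
                solo_ratio_threshold=config.solo_ratio_threshold,
            )
            refs = [SequenceRecord(e.element_id, e.element_sequence) for e in elements]
            assignments = mapping.map_reads(reads, refs, mp, rng_for(config.seed, "map"))
            rpk = mapping.reads_per_kb(assignments, refs)
            solo_rows = []
            for el in elements:
                stat = mapping.ltr_ratio(el, reads, mp, rng_for(config.seed, "map"))
                solo_rows.append(
                    {
                        "element_id": stat.element_id,
                        "rpk_ltr": round(stat.rpk_ltr, 3),
                        "rpk_inter": round(stat.rpk_inter, 3),
                        "ratio": round(stat.ratio, 3),
                        "solo_flag": stat.solo_flag,
                    }
                )
            rpk_table = pd.DataFrame(
                [
                    {"element_id": s.reference_id, "mapped_reads": s.mapped_reads,
                     "reads_per_kb": round(s.reads_per_kb, 3)}
                    for s in rpk
                ]
            )
            _write_tsv(rpk_table, outdir / "redundancy.tsv")
            _write_tsv(pd.DataFrame(solo_rows), outdir / "solo_ltr.tsv")
            artifacts["redundancy"] = rpk_table
            artifacts["solo"] = pd.DataFrame(solo_rows)
        else:
            artifacts["redundancy"] = None
    except Exception as exc:  # noqa: BLE001
        raise StageError("map", exc) from exc

    # ---- phylo ----
    try:
        rt_seqs = phylo.extract_rt(elements, calls, config.min_rt_aa)
        if len(rt_seqs) >= 3:
            dm = phylo.protein_distances(rt_seqs)
            newick = phylo.nj_tree(dm)
            (outdir / "rt_tree.nwk").write_text(newick + "\n")
            fams = phylo.family_clusters(dm, config.family_cutoff)
            _write_tsv(
                pd.DataFrame(
                    [{"element_id": k, "family": v} for k, v in sorted(fams.items())]
                ),
                outdir / "families.tsv",
            )
            artifacts["tree"] = newick
        else:
            log.warning("fewer than 3 RT sequences; tree not built")
            artifacts["tree"] = None
    except Exception as exc:  # noqa: BLE001
        raise StageError("phylo", exc) from exc

    # ---- report ----
    try:
        rows = []
        rpk_by_id = {}
        if artifacts.get("redundancy") is not None:
            rpk_by_id = dict(
                zip(artifacts["redundancy"]["element_id"], artifacts["redundancy"]["reads_per_kb"])
            )
        age_by_id = dict(zip(artifacts["ages"]["element_id"], artifacts["ages"]["age_MY"])) if len(artifacts["ages"]) else {}
        for el in elements:
            rows.append(
                {
                    "element_id": el.element_id,
                    "superfamily": calls[el.element_id].superfamily,
                    "length": el.length,
                    "ltr5_len": el.five_ltr.length,
                    "ltr3_len": el.three_ltr.length,
                    "reads_per_kb": rpk_by_id.get(el.element_id, float("nan")),
                    "age_MY": age_by_id.get(el.element_id, float("nan")),
                }
            )
        el_table = pd.DataFrame(rows)
        if len(el_table):
            _write_tsv(report.superfamily_table(el_table), outdir / "superfamily_summary.tsv")
            hist = report.age_histogram(
                [a for a in el_table["age_MY"] if a == a],
                [sf for sf, a in zip(el_table["superfamily"], el_table["age_MY"]) if a == a],
            )
            _write_tsv(hist, outdir / "age_histogram.tsv")
        artifacts["element_table"] = el_table
    except Exception as exc:  # noqa: BLE001
        raise StageError("report", exc) from exc

    return artifacts
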