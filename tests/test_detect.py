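import numpy as np
import pytest

from ltrkit.detect import (
    DetectorParams,
    detect_pbs,
    detect_ppt,
    detect_tsd,
    find_ltr_pairs,
    refine_boundaries,
    scan_contigs,
)
from ltrkit.io import GenomicInterval, SequenceRecord, revcomp
from ltrkit.simulate import (
    ElementTemplateSpec,
    build_template,
    plant_elements,
    random_dna,
    _jc_mutate,
)


class TestFindLtrPairs:
    def test_planted_element_recovered_within_5nt(self, single_element_world):
        contig, manifest, _ = single_element_world
        truth = manifest.copies[0]
        cands = find_ltr_pairs(contig)
        assert len(cands) == 1
        c = cands[0]
        assert abs(c.five_ltr.start - truth.start) <= 5
        assert abs(c.three_ltr.end - truth.end) <= 5
        assert c.ltr_identity >= 0.99

    def test_random_contig_has_no_candidates(self):
        rng = np.random.default_rng(42)
        contig = SequenceRecord("rand", random_dna(rng, 50_000))
        assert find_ltr_pairs(contig) == []

    def test_low_identity_pair_rejected_at_default_threshold(self):
        # LTR copies mutated to ~70% identity fall below the 0.80 cut-off
        rng = np.random.default_rng(5)
        ltr = random_dna(rng, 400)
        ltr_far = _jc_mutate(ltr, 0.30, rng)
        contig_seq = (
            random_dna(rng, 6_000) + ltr + random_dna(rng, 3_000) + ltr_far + random_dna(rng, 6_000)
        )
        cands = find_ltr_pairs(SequenceRecord("c", contig_seq))
        assert cands == []

    def test_short_contig_warns_and_returns_empty(self, caplog):
        contig = SequenceRecord("tiny", "ACGT" * 500)
        with caplog.at_level("WARNING", logger="ltrkit"):
            assert find_ltr_pairs(contig) == []
        assert "shorter" in caplog.text

    def test_lowering_similarity_never_decreases_candidates(self):
        # monotonicity of the similarity threshold on a fixed input
        rng = np.random.default_rng(9)
        ltr = random_dna(rng, 400)
        ltr_mid = _jc_mutate(ltr, 0.12, rng)  # ~85% identity pair
        contig = SequenceRecord(
            "c", random_dna(rng, 6_000) + ltr + random_dna(rng, 3_000) + ltr_mid + random_dna(rng, 6_000)
        )
        counts = []
        for sim in (0.95, 0.85, 0.75):
            counts.append(len(find_ltr_pairs(contig, DetectorParams(min_ltr_similarity=sim))))
        assert counts == sorted(counts)
        assert counts[-1] >= 1

    def test_candidate_invariants_hold(self, single_element_world):
        contig, _, _ = single_element_world
        params = DetectorParams()
        for c in find_ltr_pairs(contig, params):
            assert params.min_ltr_len <= c.five_ltr.length <= params.max_ltr_len
            assert params.min_ltr_len <= c.three_ltr.length <= params.max_ltr_len
            assert params.min_elem_len <= c.span.length <= params.max_elem_len
            assert c.ltr_identity >= params.min_ltr_similarity
            assert c.five_ltr.end <= c.three_ltr.start

    def test_strand_symmetry(self, single_element_world):
        contig, _, _ = single_element_world
        fwd = find_ltr_pairs(contig)
        rev = find_ltr_pairs(SequenceRecord(contig.id, revcomp(contig.sequence)))
        n = len(contig.sequence)
        mirrored = {(n - c.three_ltr.end, n - c.five_ltr.start) for c in rev}
        assert {(c.five_ltr.start, c.three_ltr.end) for c in fwd} == mirrored


class TestRefineBoundaries:
    def test_offset_termini_snap_back_to_tg_ca(self, single_element_world):
        contig, manifest, _ = single_element_world
        truth = manifest.copies[0]
        cand = find_ltr_pairs(contig)[0]
        # perturb the raw candidate by +3 nt and refine
        from dataclasses import replace
        shifted = replace(
            cand,
            five_ltr=cand.five_ltr.shifted(3),
            three_ltr=cand.three_ltr.shifted(3),
        )
        refined = refine_boundaries(shifted, contig)
        assert refined.has_tg_ca
        assert refined.five_ltr.start == truth.start
        assert refined.three_ltr.end == truth.end

    def test_no_tg_ca_means_no_snap(self):
        rng = np.random.default_rng(11)
        t = build_template(
            ElementTemplateSpec(family_id="f", ltr_len=400, with_tg_ca=False), rng
        )
        genome, _ = plant_elements(
            random_dna(rng, 30_000), [t], 1, 0, 0.0, 3.6e-9, rng, min_spacing=5_000
        )
        contig = SequenceRecord("c", genome)
        cand = find_ltr_pairs(contig)[0]
        refined = refine_boundaries(cand, contig)
        assert not refined.has_tg_ca

    def test_refine_is_idempotent(self, single_element_world):
        contig, _, _ = single_element_world
        cand = find_ltr_pairs(contig)[0]
        once = refine_boundaries(cand, contig)
        twice = refine_boundaries(once, contig)
        assert (once.five_ltr, once.three_ltr) == (twice.five_ltr, twice.three_ltr)


class TestFeatures:
    def test_tsd_exact_4mer(self):
        seq = "T" * 20 + "GATC" + "A" * 100 + "GATC" + "T" * 20
        contig = SequenceRecord("c", seq)
        assert detect_tsd(contig, GenomicInterval("c", 24, 124)) == "GATC"

    def test_tsd_longest_wins(self):
        seq = "T" * 20 + "AACGTT" + "G" * 100 + "AACGTT" + "T" * 20
        contig = SequenceRecord("c", seq)
        assert detect_tsd(contig, GenomicInterval("c", 26, 126)) == "AACGTT"

    def test_tsd_absent_when_flanks_differ(self):
        rng = np.random.default_rng(3)
        seq = "ACGTACGTAC" + "G" * 100 + "TGCATTGCAT"
        contig = SequenceRecord("c", seq)
        assert detect_tsd(contig, GenomicInterval("c", 10, 110)) is None

    def test_pbs_planted_oligo_found(self, trna_oligos):
        from ltrkit.io import revcomp as rc

        oligo = trna_oligos[0]
        ltr = "TG" + "A" * 196 + "CA"
        seq = "T" * 50 + ltr + "G" + rc(oligo.sequence[-18:]) + "C" * 200
        contig = SequenceRecord("c", seq)
        pbs = detect_pbs(contig, GenomicInterval("c", 50, 250), trna_oligos)
        assert pbs is not None
        assert pbs.start == 251  # 1 nt after the LTR
        assert pbs.length == 18

    def test_pbs_absent_in_random_window(self, trna_oligos):
        rng = np.random.default_rng(7)
        seq = "T" * 50 + random_dna(rng, 300)
        contig = SequenceRecord("c", seq)
        # brute-force confirm no oligo matches this window within 2 mismatches
        window = seq[250:280]
        from ltrkit.io import revcomp as rc

        best_mm = min(
            sum(1 for x, y in zip(window[o : o + L], rc(t.sequence[-L:])) if x != y)
            for t in trna_oligos
            for L in (15, 16, 17, 18)
            for o in range(len(window) - L + 1)
        )
        assert best_mm > 2
        assert detect_pbs(contig, GenomicInterval("c", 50, 250), trna_oligos) is None

    def test_pbs_three_mismatches_rejected(self, trna_oligos):
        from ltrkit.io import revcomp as rc

        probe = list(rc(trna_oligos[0].sequence[-18:]))
        for i in (2, 7, 12):  # introduce 3 mismatches
            probe[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[probe[i]]
        seq = "T" * 250 + "".join(probe) + "T" * 30
        contig = SequenceRecord("c", seq)
        assert detect_pbs(contig, GenomicInterval("c", 50, 250), trna_oligos) is None

    def test_pbs_empty_library_raises(self):
        contig = SequenceRecord("c", "A" * 400)
        with pytest.raises(ValueError):
            detect_pbs(contig, GenomicInterval("c", 50, 250), [])

    def test_ppt_all_purine_window_found(self):
        ppt = "GAGAGAGGGGAGAGAGAGGG"  # 20 nt, purine fraction 1.0
        seq = "CT" * 100 + ppt + "G" * 300
        contig = SequenceRecord("c", seq)
        iv = detect_ppt(contig, GenomicInterval("c", 220, 520))
        assert iv is not None
        assert seq[iv.start : iv.end].strip("AG") == ""

    def test_ppt_absent_for_pyrimidine_window(self):
        seq = "CT" * 300
        contig = SequenceRecord("c", seq)
        assert detect_ppt(contig, GenomicInterval("c", 300, 590)) is None

    def test_ppt_below_purity_threshold_rejected(self):
        # 15 purines of 20 -> 0.75 < 0.80
        window = "GGGGGAGAGAGAGAGCTCTC"
        assert sum(1 for c in window if c in "AG") == 15
        seq = "CT" * 100 + window + "C" * 300
        contig = SequenceRecord("c", seq)
        assert detect_ppt(contig, GenomicInterval("c", 220, 520)) is None


class TestScanContigs:
    def test_clean_simulation_full_recall(self):
        # multiple families, identical LTRs, all features on: 100% recall,
        # boundary error <= 5 nt
        rng = np.random.default_rng(3)
        templates = [
            build_template(
                ElementTemplateSpec(
                    family_id=f"fam{i}", superfamily=("Copia", "Gypsy")[i % 2], ltr_len=350 + 50 * i
                ),
                rng,
            )
            for i in range(4)
        ]
        genome, manifest = plant_elements(
            random_dna(rng, 200_000), templates, 2, 0, 0.0, 3.6e-9, rng, min_spacing=17_000
        )
        elements = scan_contigs([SequenceRecord("c", genome)])
        truth = sorted((c.start, c.end) for c in manifest.copies)
        assert len(elements) == len(truth)
        for (ts, te), el in zip(truth, sorted(elements, key=lambda e: e.start)):
            assert abs(el.start - ts) <= 5 and abs(el.end - te) <= 5
            assert el.has_tg_ca and el.tsd and el.pbs and el.ppt

    def test_elements_without_tsd_retained_with_absent_evidence(self):
        rng = np.random.default_rng(8)
        t = build_template(ElementTemplateSpec(family_id="f", ltr_len=400), rng)
        genome, manifest = plant_elements(
            random_dna(rng, 40_000), [t], 1, 0, 0.0, 3.6e-9, rng, min_spacing=5_000
        )
        # destroy the downstream TSD copy
        c = manifest.copies[0]
        glist = list(genome)
        for i in range(c.end, c.end + len(c.tsd)):
            glist[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[glist[i]]
        elements = scan_contigs([SequenceRecord("c", "".join(glist))])
        assert len(elements) == 1
        assert elements[0].tsd is None
        assert elements[0].missing_features() == 1

    def test_contigs_below_10kb_are_skipped(self, caplog):
        rng = np.random.default_rng(2)
        t = build_template(ElementTemplateSpec(family_id="f", ltr_len=300), rng)
        genome, _ = plant_elements(
            random_dna(rng, 4_000), [t], 1, 0, 0.0, 3.6e-9, rng
        )
        assert len(genome) < 10_000
        with caplog.at_level("WARNING", logger="ltrkit"):
            assert scan_contigs([SequenceRecord("small", genome)]) == []
        assert "below length filter" in caplog.text
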