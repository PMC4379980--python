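import itertools
import math

import numpy as np
import pytest

from ltrkit.dating import (
    AgeEstimate,
    CalibrationResult,
    LtrAlignment,
    SaturationError,
    STANDARD_TABLE,
    align_ltr_pair,
    batch_ages,
    calibrate_rate,
    estimate_age,
    jc_distance,
    ng86_counts,
    ng86_ks,
    round_sig,
)
from ltrkit.simulate import _jc_mutate


# --------------------------------------------------------------------------
# independent NG86 oracle: naive enumeration, structured differently from
# the implementation (explicit per-pathway recursion, no shared helpers)
# --------------------------------------------------------------------------

def _oracle_sites(codon):
    aa = STANDARD_TABLE[codon]
    syn_sites = 0.0
    for i in range(3):
        syn = 0
        for b in "ACGT":
            if b == codon[i]:
                continue
            mutant = codon[:i] + b + codon[i + 1 :]
            syn += STANDARD_TABLE[mutant] == aa
        syn_sites += syn / 3
    return syn_sites


def _oracle_diffs(c1, c2):
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    clean, stopped = [], []
    for order in itertools.permutations(diff_pos):
        cur, sd, nd, via_stop = c1, 0, 0, False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if STANDARD_TABLE[nxt] == "*" and nxt != c2:
                via_stop = True
            if STANDARD_TABLE[nxt] == STANDARD_TABLE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (stopped if via_stop else clean).append((sd, nd))
    use = clean or stopped
    return (sum(x for x, _ in use) / len(use), sum(y for _, y in use) / len(use))


def oracle_ng86(seq1, seq2):
    S = Sd = Nd = 0.0
    ncod = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if STANDARD_TABLE[c1] == "*" or STANDARD_TABLE[c2] == "*":
            continue
        ncod += 1
        S += (_oracle_sites(c1) + _oracle_sites(c2)) / 2
        sd, nd = _oracle_diffs(c1, c2)
        Sd += sd
        Nd += nd
    return S, 3 * ncod - S, Sd, Nd


class TestJcDistance:
    @pytest.mark.parametrize("p,expected", [(0.0, 0.0), (0.10, 0.10732)])
    def test_closed_form_values(self, p, expected):
        assert jc_distance(p) == pytest.approx(expected, abs=1e-5)

    def test_saturation_boundary(self):
        with pytest.raises(SaturationError):
            jc_distance(0.75)

    def test_strictly_increasing_convex_and_above_p(self):
        grid = np.linspace(0.0, 0.70, 200)
        k = np.array([jc_distance(p) for p in grid])
        assert (np.diff(k) > 0).all()
        assert (np.diff(k, 2) > -1e-12).all()
        assert (k >= grid - 1e-12).all()


class TestAlignLtrPair:
    def test_identical_ltrs(self):
        seq = "ACGT" * 100
        aln = align_ltr_pair(seq, seq)
        assert aln.p_distance == 0.0
        assert aln.indel_free_cols == 400

    def test_forty_substitutions_give_p_010(self):
        rng = np.random.default_rng(1)
        a = "".join(rng.choice(list("ACGT"), 400))
        b = list(a)
        pos = rng.choice(400, size=40, replace=False)
        for i in pos:
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        aln = align_ltr_pair(a, "".join(b))
        assert aln.p_distance == pytest.approx(0.10)

    def test_deletion_columns_are_removed(self):
        rng = np.random.default_rng(2)
        a = "".join(rng.choice(list("ACGT"), 400))
        b = list(a)
        subs = rng.choice(np.r_[0:150, 160:400], size=40, replace=False)
        for i in subs:
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        del b[150:160]  # 10-nt deletion, no substitutions inside
        aln = align_ltr_pair(a, "".join(b))
        assert aln.indel_free_cols == 390
        assert aln.mismatches == 40

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_ltr_pair("", "ACGT")


class TestNg86:
    def test_identity_gives_zero(self):
        counts, ks = ng86_ks("AAAGGGTTT", "AAAGGGTTT")
        assert counts.Sd == 0 and ks == 0.0

    def test_worked_single_difference_example(self):
        # hand count: S = (1/3 + 1 + 1/3) per sequence, Sd = 1 (AAA->AAG)
        counts, ks = ng86_ks("AAAGGGTTT", "AAGGGGTTT")
        assert counts.S == pytest.approx(5 / 3)
        assert counts.Sd == 1.0
        assert counts.ps == pytest.approx(0.6)
        assert ks == pytest.approx(1.2071, abs=1e-4)

    def test_saturated_pair_raises(self):
        # GGG->GGA synonymous; S = 4/3, ps = 0.75 exactly
        with pytest.raises(SaturationError):
            ng86_ks("AAAGGG", "AAAGGA")

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            ng86_counts("TAAGGG", "TAAGGG")

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            ng86_counts("AAA", "AAAGGG")

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        codons = [c for c, aa in STANDARD_TABLE.items() if aa != "*"]
        for _ in range(25):
            a = "".join(rng.choice(codons, 6))
            b = "".join(rng.choice(codons, 6))
            ca = ng86_counts(a, b)
            cb = ng86_counts(b, a)
            assert ca.Sd == pytest.approx(cb.Sd)
            assert ca.S == pytest.approx(cb.S)

    def test_site_counts_partition_three_per_codon(self):
        rng = np.random.default_rng(8)
        codons = [c for c, aa in STANDARD_TABLE.items() if aa != "*"]
        for _ in range(20):
            n = int(rng.integers(2, 8))
            a = "".join(rng.choice(codons, n))
            b = "".join(rng.choice(codons, n))
            c = ng86_counts(a, b)
            assert c.S + c.N == pytest.approx(3 * n)

    def test_matches_enumeration_oracle_on_random_codon_pairs(self):
        rng = np.random.default_rng(11)
        codons = [c for c, aa in STANDARD_TABLE.items() if aa != "*"]
        for _ in range(60):
            n = int(rng.integers(1, 4))
            a = "".join(rng.choice(codons, n))
            b = "".join(rng.choice(codons, n))
            mine = ng86_counts(a, b)
            S, N, Sd, Nd = oracle_ng86(a, b)
            assert mine.S == pytest.approx(S)
            assert mine.N == pytest.approx(N)
            assert mine.Sd == pytest.approx(Sd)
            assert mine.Nd == pytest.approx(Nd)

    def test_matches_biopython_ng86_ks(self):
        # independent cross-check against Bio.codonalign cal_dn_ds
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        rng = np.random.default_rng(17)
        codons = [c for c, aa in STANDARD_TABLE.items() if aa != "*"]
        checked = 0
        while checked < 10:
            a = "".join(rng.choice(codons, 30))
            b = _jc_mutate(a, 0.03, rng)
            # restrict to single-difference codons: for multi-hit codons
            # Biopython averages pathways through stop codons while the
            # standard NG86 excludes them
            if any(
                sum(x != y for x, y in zip(a[i : i + 3], b[i : i + 3])) > 1
                for i in range(0, len(a), 3)
            ):
                continue
            try:
                _, ks = ng86_ks(a, b)
            except (SaturationError, ValueError):
                continue
            try:
                _, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
            except Exception:
                continue
            assert ks == pytest.approx(ds, abs=1e-6)
            checked += 1


class TestCalibration:
    def test_published_rate_chain(self):
        rates = CalibrationResult([0.077], split_time_years=42.5e6)
        assert round_sig(rates.r_syn, 2) == pytest.approx(1.8e-9)
        assert round_sig(rates.r_ltr, 2) == pytest.approx(3.6e-9)
        assert rates.r_ltr == 2 * rates.r_syn

    def test_mean_of_per_gene_ks(self):
        rates = CalibrationResult([0.05, 0.10, 0.09], split_time_years=40e6)
        assert rates.mean_ks == pytest.approx(0.08)

    def test_zero_ks_warns_and_gives_zero_rate(self, caplog):
        pairs = [("AAAGGGTTT", "AAAGGGTTT")]
        with caplog.at_level("WARNING", logger="ltrkit"):
            rates = calibrate_rate(pairs, 42.5e6)
        assert rates.r_syn == 0.0

    def test_all_saturated_raises(self):
        with pytest.raises(SaturationError):
            calibrate_rate([("AAAGGG", "AAAGGA")], 42.5e6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            calibrate_rate([], 42.5e6)


class TestEstimateAge:
    def _rates(self):
        return CalibrationResult([0.0765], split_time_years=42.5e6)

    def test_age_is_k_over_r_by_default(self):
        # K = 0.0646 at r_ltr = 3.6e-9 -> 17.94 MY
        rates = CalibrationResult([0.0765], split_time_years=42.5e6)
        r_ltr = rates.r_ltr
        aln = LtrAlignment(700, 700, 42)  # p = 0.06 -> K = 0.0646...
        est = estimate_age(aln, rates)
        assert est.K == pytest.approx(jc_distance(42 / 700))
        assert est.age_years == pytest.approx(est.K / r_ltr)

    def test_two_conventions_differ_by_factor_two(self):
        aln = LtrAlignment(700, 700, 42)
        a1 = estimate_age(aln, self._rates(), "K_over_r")
        a2 = estimate_age(aln, self._rates(), "K_over_2r")
        assert a1.age_years == pytest.approx(2 * a2.age_years)

    def test_identical_ltrs_have_zero_age_and_finite_bound(self):
        aln = LtrAlignment(718, 718, 0)
        est = estimate_age(aln, self._rates())
        assert est.age_years == 0.0
        assert est.zero_div_upper_bound_years is not None
        assert 0 < est.zero_div_upper_bound_years < 1e6

    def test_age_linear_in_k_and_halved_by_double_rate(self):
        aln = LtrAlignment(500, 500, 25)
        r1 = CalibrationResult([0.06], 40e6)
        r2 = CalibrationResult([0.12], 40e6)  # doubled rate
        assert estimate_age(aln, r1).age_years == pytest.approx(
            2 * estimate_age(aln, r2).age_years
        )


class TestBatchAges:
    def test_mean_and_se_hand_arithmetic(self):
        # ages 10, 20, 30 MY -> mean 20, SE 5.7735
        rates = CalibrationResult([0.0765], 42.5e6)
        r = rates.r_ltr
        pairs = {}
        rng = np.random.default_rng(0)
        for i, age in enumerate((10e6, 20e6, 30e6)):
            p = 0.75 * (1 - math.exp(-(4 / 3) * r * age))
            n = 6000  # long LTRs so realized p is essentially exact
            seq = "".join(rng.choice(list("ACGT"), n))
            k = round(p * n)
            mut = list(seq)
            # scatter substitutions evenly so no block can re-align as a gap
            for j in range(k):
                idx = j * n // k
                mut[idx] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mut[idx]]
            pairs[f"e{i}"] = (seq, "".join(mut))
        table, summary = batch_ages(pairs, rates)
        overall = summary[summary["group"] == "all"].iloc[0]
        assert overall["mean_age_MY"] == pytest.approx(20.0, abs=0.05)
        assert overall["se_MY"] == pytest.approx(5.77, abs=0.05)

    def test_parameter_recovery_from_simulated_pairs(self):
        # LTR pairs simulated under JC at a known age: the mean estimated
        # age must recover the truth within 3 standard errors
        rng = np.random.default_rng(99)
        rates = CalibrationResult([0.0765], 42.5e6)
        r = rates.r_ltr
        true_age = 15e6
        p_site = 0.75 * (1 - math.exp(-(4 / 3) * (r / 2) * true_age))
        pairs = {}
        for i in range(120):
            ltr = "".join(rng.choice(list("ACGT"), 600))
            pairs[f"e{i}"] = (_jc_mutate(ltr, p_site, rng), _jc_mutate(ltr, p_site, rng))
        table, summary = batch_ages(pairs, rates)
        overall = summary[summary["group"] == "all"].iloc[0]
        assert abs(overall["mean_age_MY"] - 15.0) <= 3 * max(overall["se_MY"], 1e-9)
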