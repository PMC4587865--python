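"""Bisulfite clone alignment, calling, QC and group comparisons."""

import numpy as np
import pytest
from scipy import stats

from methylmark import bisulfite as bs
from methylmark import cpgtools as cg
from methylmark import simulate as sim
from oracles import needleman_wunsch_affine


@pytest.fixture(scope="module")
def reference():
    # 110 bp with 8 CpGs and a healthy supply of non-CpG cytosines
    seq = ("ATCGATCCATTACGATTCCATACGATTACCATTCGATCCATTACGATTCCAT"
           "ACGATTACCATTCGATCCATTACGATTCCATACCATTACCATTACCATTA")
    offs = cg.cpg_offsets_of(seq)
    assert len(offs) == 8
    return bs.BisulfiteReference(seq, offs)


class TestReference:
    def test_converted_image_has_c_only_at_cpgs(self, reference):
        conv = reference.converted
        for i, c in enumerate(conv):
            if c == "C":
                assert i in reference.cpg_offsets
        # original CpG cytosines preserved
        for o in reference.cpg_offsets:
            assert conv[o] == "C"

    def test_non_cpg_offset_rejected(self):
        with pytest.raises(ValueError):
            bs.BisulfiteReference("ACCA", (1,))


class TestAlignClone:
    def test_fully_converted_clone(self, reference):
        # unmethylated molecule: every C (CpG or not) reads as T
        clone = reference.sequence.replace("C", "T")
        a = bs.align_clone(clone, reference, "c1")
        assert (a.calls == bs.UNMETHYLATED).all()
        assert a.conversion_rate == pytest.approx(1.0)
        assert a.identity == pytest.approx(1.0)

    def test_unconverted_clone(self, reference):
        a = bs.align_clone(reference.sequence, reference, "c1")
        assert (a.calls == bs.METHYLATED).all()
        assert a.conversion_rate == pytest.approx(0.0)
        assert a.identity == pytest.approx(1.0)

    def test_fully_methylated_clone(self, reference):
        # methylated molecule after perfect conversion: CpG Cs retained,
        # every other C converted
        spec = sim.BisulfiteSimSpec(
            cpg_positions=reference.cpg_offsets,
            per_cpg_meth_prob=tuple([1.0] * 8), n_clones=1, seed=1)
        clone = sim.gen_bisulfite_clones(spec, reference.sequence)[0]
        a = bs.align_clone(clone, reference, "c1")
        assert (a.calls == bs.METHYLATED).all()
        assert a.conversion_rate == pytest.approx(1.0)

    def test_deletion_spanning_cpg_called_missing(self, reference):
        target = reference.cpg_offsets[3]
        full = reference.sequence.replace("C", "T")
        clone = full[: target - 2] + full[target + 4:]
        a = bs.align_clone(clone, reference, "c1")
        assert a.calls[3] == bs.MISSING
        keep = np.delete(a.calls, 3)
        assert (keep == bs.UNMETHYLATED).all()

    def test_alignment_score_matches_gotoh_oracle(self, rng, reference):
        # implementation's optimal score equals a brute-force affine-gap DP
        for _ in range(5):
            clone = list(reference.converted)
            # random deletion + substitutions
            start = int(rng.integers(10, 80))
            del clone[start : start + int(rng.integers(1, 5))]
            for _ in range(2):
                i = int(rng.integers(0, len(clone)))
                clone[i] = "ACGT"[int(rng.integers(0, 4))]
            clone = "".join(clone)
            score = bs._ALIGNER.score(reference.sequence, clone)
            oracle = needleman_wunsch_affine(
                reference.sequence, clone, bisulfite=True)
            assert score == pytest.approx(oracle)

    def test_low_identity_rejected(self, reference):
        with pytest.raises(bs.LowIdentityError):
            bs.align_clone("G" * 100, reference, "junk")

    def test_empty_clone_rejected(self, reference):
        with pytest.raises(ValueError):
            bs.align_clone("", reference)


class TestQcFilter:
    def _aln(self, conv, ident, cid="c"):
        return bs.CloneAlignment(cid, np.array([1, 0]), conv, ident)

    def test_low_conversion_excluded(self):
        with pytest.warns(UserWarning, match="failed QC"):
            retained, report = bs.qc_filter([self._aln(0.80, 1.0)],
                                            min_conversion=0.95)
        assert retained == []
        assert report[0]["retained"] is False

    def test_all_pass_is_identity(self):
        alns = [self._aln(0.99, 0.98, f"c{i}") for i in range(5)]
        retained, _ = bs.qc_filter(alns)
        assert retained == alns

    def test_retained_calls_unchanged(self):
        a = self._aln(0.99, 0.99)
        calls_before = a.calls.copy()
        retained, _ = bs.qc_filter([a])
        assert (retained[0].calls == calls_before).all()

    def test_all_fail_warns(self):
        with pytest.warns(UserWarning):
            bs.qc_filter([self._aln(0.5, 1.0)])

    def test_exclusion_fraction_matches_binomial_tail(self, reference):
        # planted conversion failure rate 0.1; a clone passes QC only when
        # its observed failures keep conversion >= 0.95
        rate, min_conv, n_clones = 0.1, 0.95, 400
        spec = sim.BisulfiteSimSpec(
            cpg_positions=reference.cpg_offsets,
            per_cpg_meth_prob=tuple([0.5] * 8),
            n_clones=n_clones, conversion_failure_rate=rate, seed=11)
        clones = sim.gen_bisulfite_clones(spec, reference.sequence)
        alns = [bs.align_clone(c, reference, f"c{i}") for i, c in enumerate(clones)]
        retained, _ = bs.qc_filter(alns, min_conversion=min_conv)
        n_c = len(reference.non_cpg_c_offsets)
        max_failures = int(np.floor((1 - min_conv) * n_c))
        p_pass = stats.binom.cdf(max_failures, n_c, rate)
        excl_expected = 1 - p_pass
        excl_observed = 1 - len(retained) / n_clones
        ci = 3 * np.sqrt(excl_expected * (1 - excl_expected) / n_clones)
        assert abs(excl_observed - excl_expected) < ci


class TestSampleMethylation:
    def _sample(self, calls, group="tumor"):
        alns = [bs.CloneAlignment(f"c{i}", np.asarray(row), 1.0, 1.0)
                for i, row in enumerate(calls)]
        return bs.BisulfiteSample("s", group, alns)

    def test_all_unmethylated_is_zero(self):
        s = self._sample([[0] * 22] * 5)
        _, pct = bs.sample_methylation(s)
        assert pct == 0.0

    def test_pooled_percent_arithmetic(self, rng):
        # 110 calls, 66 methylated -> 60.0%
        flat = np.zeros(110, int)
        flat[rng.choice(110, 66, replace=False)] = 1
        s = self._sample(flat.reshape(5, 22))
        fractions, pct = bs.sample_methylation(s)
        assert pct == pytest.approx(60.0)
        assert fractions.shape == (22,)

    def test_invariant_to_clone_order(self, rng):
        calls = rng.integers(0, 2, size=(5, 10))
        s1 = self._sample(calls)
        s2 = self._sample(calls[::-1])
        assert s1.percent_methylation == s2.percent_methylation

    def test_missing_calls_excluded_from_denominator(self):
        s = self._sample([[1, -1, 0], [1, 1, -1]])
        fractions, pct = bs.sample_methylation(s)
        assert pct == pytest.approx(100 * 3 / 4)
        assert np.isnan(fractions).sum() == 0

    def test_no_clones_rejected(self):
        with pytest.raises(ValueError):
            bs.sample_methylation(bs.BisulfiteSample("s", "tumor", []))


def panel(reference, meth_prob, n_samples, group, seed0):
    samples = []
    for k in range(n_samples):
        spec = sim.BisulfiteSimSpec(
            cpg_positions=reference.cpg_offsets,
            per_cpg_meth_prob=tuple([meth_prob] * len(reference.cpg_offsets)),
            n_clones=5, seed=seed0 + k)
        clones = sim.gen_bisulfite_clones(spec, reference.sequence)
        alns = [bs.align_clone(c, reference, f"c{i}") for i, c in enumerate(clones)]
        samples.append(bs.BisulfiteSample(f"{group}{k}", group, alns))
    return samples


class TestGroupComparisons:
    def test_cancer_vs_control_panels_recover_generating_means(self, reference):
        # cancer-line panels generated at 56.5% methylation, controls at 3.2%
        bc = panel(reference, 0.565, 8, "BC", seed0=100)
        ntb = panel(reference, 0.032, 4, "NTB", seed0=200)
        mean_bc = np.mean([s.percent_methylation for s in bc])
        mean_ntb = np.mean([s.percent_methylation for s in ntb])
        # binomial CI: each sample pools 40 calls
        assert abs(mean_bc - 56.5) < 3 * 100 * np.sqrt(0.565 * 0.435 / (8 * 40))
        assert abs(mean_ntb - 3.2) < 3 * 100 * np.sqrt(0.032 * 0.968 / (4 * 40))

    def test_separated_panels_significant(self, reference):
        hits = 0
        for trial in range(20):
            bc = panel(reference, 0.565, 8, "BC", seed0=1000 + 10 * trial)
            ntb = panel(reference, 0.032, 2, "NTB", seed0=2000 + 10 * trial)
            hits += bs.compare_groups(bc, ntb).p_value < 0.05
        assert hits >= 19

    def test_identical_groups_not_significant(self, reference):
        a = panel(reference, 0.5, 3, "A", seed0=1)
        res = bs.compare_groups(a, a)
        assert res.p_value == pytest.approx(1.0, abs=0.01)

    def test_paired_identical_samples_p_one(self, reference):
        s = panel(reference, 0.5, 1, "T", seed0=5)[0]
        with pytest.warns(UserWarning):
            res = bs.compare_paired(s, s)
        assert res.p_value == 1.0

    def test_paired_uniform_shift_minimal_p(self):
        n_cpg = 22
        tumor = bs.BisulfiteSample("t", "tumor", [
            bs.CloneAlignment("c1", np.array([1] * n_cpg), 1.0, 1.0),
            bs.CloneAlignment("c2", np.array([1] * 11 + [0] * 11), 1.0, 1.0),
        ])
        normal = bs.BisulfiteSample("n", "normal", [
            bs.CloneAlignment("c1", np.array([0] * n_cpg), 1.0, 1.0),
            bs.CloneAlignment("c2", np.array([1] * 11 + [0] * 11), 1.0, 1.0),
        ])
        # tumor fraction exceeds normal by 0.5 at every CpG: most extreme
        # signed-rank statistic, exact two-sided p = 2 / 2^22
        res = bs.compare_paired(tumor, normal)
        assert res.p_value == pytest.approx(2 / 2 ** n_cpg)

    def test_mismatched_grids_rejected(self):
        t = bs.BisulfiteSample("t", "tumor",
                               [bs.CloneAlignment("c", np.ones(5, int), 1, 1)])
        n = bs.BisulfiteSample("n", "normal",
                               [bs.CloneAlignment("c", np.ones(6, int), 1, 1)])
        with pytest.raises(ValueError):
            bs.compare_paired(t, n)


class TestCorrelateExpression:
    def test_perfect_anticorrelation(self):
        res = bs.correlate_expression([10, 20, 30, 40, 50], [5, 4, 3, 2, 1])
        assert res.statistic == pytest.approx(-1.0)

    def test_strong_negative_association_regime(self, rng):
        # 10 cell lines, methylation strongly suppressing expression
        meth = np.sort(rng.uniform(0, 90, 10))
        expr = 8 - 0.08 * meth + rng.normal(0, 0.4, 10)
        res = bs.correlate_expression(meth, expr)
        assert res.statistic < -0.85
        assert res.p_value < 0.01

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            bs.correlate_expression([1, 2, 3], [3, 2, 1])
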