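"""HMM segmentation, mixture genotyping, component construction, rawcnv IO."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cnvsmoke.cnvcall import (
    CNVCall, HMMParams, build_components, genotype_median_lrr, parse_rawcnv,
    span_bp, viterbi_segment, write_rawcnv,
)
from cnvsmoke.simdata import ProbePanel, SimulationConfig, simulate_intensities
from oracles import brute_force_viterbi


def _panel(lrr, baf, chrom="chr1", start=1000, step=500, ids=None):
    lrr = np.atleast_2d(np.asarray(lrr, float))
    baf = np.atleast_2d(np.asarray(baf, float))
    pos = start + step * np.arange(lrr.shape[1])
    return ProbePanel(chrom=chrom, positions=pos, lrr=lrr, baf=baf,
                      subject_ids=ids or [f"S{i}" for i in range(lrr.shape[0])])


class TestSpan:
    @pytest.mark.parametrize("start,end,expected", [
        (6212573, 6214264, 1691),
        (6194430, 6214264, 19834),
        (100, 100, 0),
    ])
    def test_span_convention(self, start, end, expected):
        assert span_bp(start, end) == expected

    def test_reversed_rejected(self):
        with pytest.raises(ValueError):
            span_bp(10, 5)


class TestViterbi:
    def test_zero_noise_diploid_panel_has_no_calls(self):
        panel = _panel(np.zeros((3, 12)), np.full((3, 12), 0.5))
        assert viterbi_segment(panel) == []

    def test_planted_cn1_segment_recovered_exactly(self):
        """A 5-probe hemizygous segment at SNR >= 6 yields one exact call."""
        rng = np.random.default_rng(0)
        sd = 0.66 / 6
        lrr = rng.normal(0, sd, size=(1, 20))
        lrr[0, 8:13] += -0.66
        baf_centers = rng.choice([0.0, 0.5, 1.0], p=[0.25, 0.5, 0.25],
                                 size=(1, 20))
        baf_centers[0, 8:13] = rng.choice([0.0, 1.0], size=5)
        baf = np.clip(baf_centers + rng.normal(0, 0.02, size=(1, 20)), 0, 1)
        panel = _panel(lrr, baf)
        calls = viterbi_segment(panel, HMMParams(lrr_sd=sd, baf_sd=0.03))
        assert len(calls) == 1
        call = calls[0]
        assert call.copy_number == 1
        assert call.n_probes == 5
        assert call.start_bp == panel.positions[8]
        assert call.end_bp == panel.positions[12]
        assert call.confidence > 0

    def test_confidence_is_loglik_margin_over_diploid(self):
        lrr = np.zeros((1, 10))
        lrr[0, 3:6] = -0.66
        baf = np.full((1, 10), 0.5)
        baf[0, 3:6] = 0.0
        hmm = HMMParams(lrr_sd=0.1, baf_sd=0.05)
        calls = viterbi_segment(_panel(lrr, baf), hmm)
        from cnvsmoke.cnvcall import emission_loglik
        emis = emission_loglik(_panel(lrr, baf), hmm)[0]
        expected = float(np.sum(emis[3:6, 1] - emis[3:6, 2]))
        assert calls[0].confidence == pytest.approx(expected, abs=1e-10)

    def test_nonfinite_probes_are_skipped(self):
        lrr = np.zeros((1, 10))
        lrr[0, 4] = np.nan
        baf = np.full((1, 10), 0.5)
        assert viterbi_segment(_panel(lrr, baf)) == []

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=2, max_value=8), st.integers(0, 2 ** 31 - 1))
    def test_viterbi_matches_exhaustive_enumeration(self, n_probes, seed):
        rng = np.random.default_rng(seed)
        lrr = rng.normal(-0.5, 1.0, size=(1, n_probes))
        baf = rng.random((1, n_probes))
        panel = _panel(lrr, baf)
        hmm = HMMParams(lrr_sd=0.3, baf_sd=0.08, stay_prob=0.9)
        from cnvsmoke.cnvcall import viterbi_path, emission_loglik
        path = viterbi_path(emission_loglik(panel, hmm)[0], hmm)
        np.testing.assert_array_equal(path, brute_force_viterbi(panel, hmm))


class TestGenotypeMedianLRR:
    def _mixture_panel(self, counts, noise_sd=0.15, seed=0, n_probes=9):
        """Panel whose subjects split into CN0/CN1/CN2 classes of given sizes."""
        n = sum(counts)
        cn = np.repeat([0, 1, 2], counts)
        rng = np.random.default_rng(seed)
        cn = rng.permutation(cn)
        cfg = SimulationConfig(n_subjects=n, noise_sd_lrr=noise_sd, seed=seed,
                               n_components=0)
        panel = simulate_intensities(
            [f"S{i}" for i in range(n)], cn, ("chr3", 6_194_430, 6_214_264),
            n_probes, cfg, rng=rng)
        return panel, cn

    def test_all_diploid_single_class(self):
        panel, _ = self._mixture_panel([0, 0, 500], noise_sd=0.2, seed=1)
        cn_hat, summary = genotype_median_lrr(
            panel, ("chr3", 6_194_430, 6_214_264))
        assert np.all(cn_hat == 2)

    def test_replication_style_class_counts(self):
        """Class sizes 3 : 170 : 3037 recovered within +/-2 subjects each."""
        counts = [3, 170, 3037]
        panel, cn_true = self._mixture_panel(counts, noise_sd=0.15, seed=2)
        cn_hat, summary = genotype_median_lrr(
            panel, ("chr3", 6_194_430, 6_214_264))
        for state, expected in zip([0, 1, 2], counts):
            assert abs(int((cn_hat == state).sum()) - expected) <= 2

    def test_zero_noise_perfect_assignment(self):
        panel, cn_true = self._mixture_panel([5, 50, 445], noise_sd=0.0, seed=3)
        cn_hat, _ = genotype_median_lrr(panel, ("chr3", 6_194_430, 6_214_264))
        np.testing.assert_array_equal(cn_hat, cn_true)

    def test_too_few_probes_rejected(self):
        panel, _ = self._mixture_panel([0, 5, 45], n_probes=10)
        with pytest.raises(ValueError, match="at least 3"):
            genotype_median_lrr(panel, ("chr3", 6_194_430, 6_194_433))

    def test_agrees_with_viterbi_at_high_snr(self):
        """Carrier status from both callers agrees for >=99% of subjects."""
        counts = [0, 40, 460]
        panel, cn_true = self._mixture_panel(counts, noise_sd=0.66 / 4, seed=4)
        cn_mix, _ = genotype_median_lrr(panel, ("chr3", 6_194_430, 6_214_264))
        calls = viterbi_segment(panel, HMMParams(lrr_sd=0.66 / 4, baf_sd=0.05))
        hmm_carriers = {c.subject_id for c in calls}
        mix_carriers = {panel.subject_ids[i]
                        for i in np.flatnonzero(cn_mix != 2)}
        n = panel.n_subjects
        agree = n - len(hmm_carriers ^ mix_carriers)
        assert agree / n >= 0.99


class TestBuildComponents:
    def test_no_calls_no_components(self):
        assert build_components([], cohort_size=10) == []

    def test_by_hand_two_component_example(self):
        """Three carriers on a core interval, one extending further right."""
        calls = [
            CNVCall("A", "chr1", 100, 200, 1, 3),
            CNVCall("B", "chr1", 100, 200, 1, 3),
            CNVCall("C", "chr1", 100, 300, 1, 5),
        ]
        ids = ["A", "B", "C"] + [f"D{i}" for i in range(97)]
        comps = build_components(calls, cohort_size=100, min_frequency=0.0,
                                 subject_ids=ids)
        assert [(c.start_bp, c.end_bp, c.carrier_count) for c in comps] == \
            [(100, 200, 3), (201, 300, 1)]
        assert comps[0].frequency == pytest.approx(0.03)
        assert comps[1].frequency == pytest.approx(0.01)
        # strict > 1% retains only the core interval
        poly = build_components(calls, cohort_size=100, min_frequency=0.01,
                                subject_ids=ids)
        assert [(c.start_bp, c.end_bp) for c in poly] == [(100, 200)]

    def test_two_carrier_classes_at_study_counts(self):
        """77 large-deletion carriers and 40 short upstream carriers yield
        components with 77 and 117 carriers."""
        large = [CNVCall(f"L{i}", "chr3", 6_194_430, 6_214_264, 1, 30)
                 for i in range(77)]
        short = [CNVCall(f"U{i}", "chr3", 6_194_430, 6_212_572, 1, 25)
                 for i in range(40)]
        ids = ([c.subject_id for c in large + short]
               + [f"N{i}" for i in range(2889 - 117)])
        comps = build_components(large + short, cohort_size=2889,
                                 min_frequency=0.01, subject_ids=ids)
        counts = {(c.start_bp, c.end_bp): c.carrier_count for c in comps}
        assert counts == {(6_194_430, 6_212_572): 117,
                          (6_212_573, 6_214_264): 77}
        tail = next(c for c in comps if c.start_bp == 6_212_573)
        assert span_bp(tail.start_bp, tail.end_bp) == 1691

    def test_conflicting_overlap_names_subject(self):
        calls = [CNVCall("A", "chr1", 100, 200, 1, 3),
                 CNVCall("A", "chr1", 150, 250, 0, 3)]
        with pytest.raises(ValueError, match="A"):
            build_components(calls, cohort_size=10, subject_ids=None)

    def test_frequency_invariant_under_subject_permutation(self, rng):
        calls = [CNVCall(f"S{i}", "chr2", 500, 900, 1, 4)
                 for i in rng.choice(50, size=12, replace=False)]
        ids = [f"S{i}" for i in range(50)]
        shuffled = list(rng.permutation(ids))
        f1 = [c.frequency for c in build_components(calls, 50, 0.0, ids)]
        f2 = [c.frequency for c in build_components(calls, 50, 0.0, shuffled)]
        assert f1 == f2


class TestRawCNV:
    SAMPLE = ("chr3:6212573-6214264 numsnp=5 length=1,692 state2,cn=1 "
              "SAMPLE_ID startsnp=rsA endsnp=rsB conf=12.3\n")

    def test_parse_dialect_line(self):
        (call,) = parse_rawcnv([self.SAMPLE])
        assert call.chrom == "chr3"
        assert (call.start_bp, call.end_bp) == (6212573, 6214264)
        assert call.copy_number == 1
        assert call.subject_id == "SAMPLE_ID"
        assert call.n_probes == 5
        assert call.confidence == pytest.approx(12.3)

    def test_missing_conf_tolerated(self):
        (call,) = parse_rawcnv(["chr1:10-20 numsnp=2 length=11 state1,cn=0 X"])
        assert call.copy_number == 0
        assert np.isnan(call.confidence)

    def test_round_trip(self):
        calls = [CNVCall("S1", "chr3", 6212573, 6214264, 1, 5, 12.3),
                 CNVCall("S2", "chr7", 100, 900, 3, 4)]
        back = parse_rawcnv(write_rawcnv(calls).splitlines())
        for a, b in zip(calls, back):
            assert (a.subject_id, a.chrom, a.start_bp, a.end_bp,
                    a.copy_number, a.n_probes) == \
                (b.subject_id, b.chrom, b.start_bp, b.end_bp,
                 b.copy_number, b.n_probes)

    def test_diploid_call_rejected(self):
        with pytest.raises(ValueError):
            CNVCall("S", "chr1", 1, 2, 2, 1)
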