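"""Virtual spectratype histograms, Gaussian-ness scoring, classification."""

import math

import numpy as np
import pytest
from scipy.stats import binom, norm

from tcrrecon.io import Clonotype, build_sample, translate_junction
from tcrrecon.spectratype import (
    SpectratypeProfile,
    SpectratypeThresholds,
    FamilyProfile,
    cdr3_length_distribution,
    classify_spectratype,
    gaussianness_score,
    spectratype_profile,
)
from tcrrecon.simulate import (
    abnormal_spectratype_params,
    normal_spectratype_params,
    simulate_repertoire,
)


def clonotype_of_length(i, length, count, family="TRBV5"):
    n_mid = length // 3 - 2
    mids = ["GCA", "GCC", "GCG", "GCT", "ACA", "ACC", "ACG", "ACT"]
    nt = "TGT" + mids[i % len(mids)] * n_mid + "TTT"
    assert len(nt) == length
    return Clonotype(f"{family}-1*01", "TRBJ2-1", nt, count, cdr3_aa=translate_junction(nt))


class TestLengthDistribution:
    def test_single_length_single_peak(self):
        s = build_sample("s", [clonotype_of_length(i, 45, 2) for i in range(3)])
        p = cdr3_length_distribution(s)
        (fam,) = p.families
        assert fam.length_histogram == {45: pytest.approx(1.0)}
        assert fam.peak_count == 1

    def test_three_to_one_split(self):
        s = build_sample(
            "s", [clonotype_of_length(0, 45, 3), clonotype_of_length(1, 48, 1)]
        )
        p = cdr3_length_distribution(s)
        hist = p.families[0].length_histogram
        assert hist[45] == pytest.approx(0.75) and hist[48] == pytest.approx(0.25)

    def test_family_histograms_sum_to_aggregate(self):
        clonotypes = [
            clonotype_of_length(i, 39 + 3 * (i % 4), 1 + i, family=f"TRBV{5 + i % 3}")
            for i in range(12)
        ]
        s = build_sample("s", clonotypes)
        p = cdr3_length_distribution(s)
        agg = {}
        for f in p.families:
            assert sum(f.length_histogram.values()) == pytest.approx(f.total_frequency, abs=1e-12)
            for l, v in f.length_histogram.items():
                agg[l] = agg.get(l, 0.0) + v
        assert sum(agg.values()) == pytest.approx(1.0, abs=1e-12)
        for l, v in p.aggregate_histogram.items():
            assert agg[l] == pytest.approx(v, abs=1e-12)

    def test_unresolvable_v_call_binned_unassigned(self):
        c = Clonotype("oddgene", "J", "TGTGCATTT", 4, cdr3_aa="CAF")
        p = cdr3_length_distribution(build_sample("s", [c]))
        assert p.families[0].v_family == "unassigned"


class TestGaussianness:
    def test_histogram_equal_to_fitted_gaussian_scores_one(self):
        lengths = np.arange(30, 61, 3, dtype=float)
        w = norm.pdf(lengths, loc=45, scale=6)
        w /= w.sum()
        hist = dict(zip(lengths.astype(int), w))
        # the moment fit of this histogram is not exactly (45, 6) because the
        # support is truncated; feed the fit back so shapes match exactly
        mu = sum(l * p for l, p in hist.items())
        sd = math.sqrt(sum(p * (l - mu) ** 2 for l, p in hist.items()))
        refit = norm.pdf(lengths, loc=mu, scale=sd)
        refit /= refit.sum()
        hist_exact = dict(zip(lengths.astype(int), refit))
        # one more fixpoint pass is enough at this tolerance
        assert gaussianness_score(hist_exact) >= 0.99

    def test_single_spike_scores_zero(self):
        assert gaussianness_score({45: 1.0}) == 0.0

    def test_binomial_shape_matches_direct_l1_oracle(self):
        n = 7
        lengths = [36 + 3 * k for k in range(n + 1)]
        weights = binom.pmf(np.arange(n + 1), n, 0.5)
        hist = dict(zip(lengths, weights))
        # independent L1 computation against the moment-fitted Gaussian
        mu = sum(l * w for l, w in hist.items())
        sd = math.sqrt(sum(w * (l - mu) ** 2 for l, w in hist.items()))
        grid = np.arange(36, 36 + 3 * n + 1, 3)
        fit = norm.pdf(grid, mu, sd)
        fit /= fit.sum()
        expected = 1 - 0.5 * float(np.abs(np.asarray(list(weights)) - fit).sum())
        assert gaussianness_score(hist) == pytest.approx(expected, abs=1e-12)
        assert gaussianness_score(hist) > 0.9  # binomial(7) is near-Gaussian

    def test_two_spike_histogram_scores_low(self):
        assert gaussianness_score({30: 0.5, 60: 0.5}) < 0.5


def profile_with(median_peaks, gaussian_scores):
    families = [
        FamilyProfile(f"TRBV{i}", {45: 1.0}, peak_count=int(median_peaks), gaussian_score=g)
        for i, g in enumerate(gaussian_scores)
    ]
    return SpectratypeProfile(
        sample_id="s",
        families=families,
        aggregate_histogram={},
        median_peaks=float(median_peaks),
        n_gaussian_families=0,
        gaussian_fraction=0.0,
    )


class TestClassification:
    def test_exactly_at_thresholds_is_normal(self):
        # 8 peaks, 3/4 families Gaussian at exactly the 0.8 cut
        p = profile_with(8, [0.8, 0.8, 0.8, 0.1])
        assert classify_spectratype(p) == "Normal"

    def test_low_median_peaks_is_abnormal(self):
        p = profile_with(5, [0.9, 0.9, 0.9, 0.9])
        assert classify_spectratype(p) == "Abnormal"

    def test_intermediate_is_almost_normal(self):
        p = profile_with(7, [0.9, 0.9, 0.1, 0.1])  # fraction 0.5, peaks 7
        assert classify_spectratype(p) == "Almost_normal"

    def test_adding_clonal_mass_never_promotes_abnormal_to_normal(self):
        """Dumping extra mass into one length bin of an Abnormal profile can
        only sharpen spikes; the label must not become Normal."""
        s = simulate_repertoire(abnormal_spectratype_params(seed=0, total_reads=20_000))
        base = spectratype_profile(s)
        assert base.classification == "Abnormal"
        boosted = s.clonotypes[0]
        from dataclasses import replace

        clones = [replace(boosted, count=boosted.count + 50_000)] + s.clonotypes[1:]
        s2 = build_sample("boosted", clones)
        assert spectratype_profile(s2).classification != "Normal"

    def test_generator_label_recovery_smoke(self):
        """Normal and Abnormal generator presets recover their labels (the
        full 200-draw recovery rate is checked in the acceptance suite)."""
        for seed in range(5):
            n = simulate_repertoire(normal_spectratype_params(seed=seed, total_reads=50_000))
            a = simulate_repertoire(abnormal_spectratype_params(seed=seed, total_reads=20_000))
            assert spectratype_profile(n).classification == "Normal"
            assert spectratype_profile(a).classification == "Abnormal"

    def test_empty_profile_rejected(self):
        p = profile_with(8, [0.9])
        p.families = []
        with pytest.raises(ValueError):
            classify_spectratype(p)
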