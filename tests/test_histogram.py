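import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adcphantom import (
    build_shared_spec,
    compute_features,
    compute_histogram,
    mean_histogram,
)
from adcphantom.histogram import ADCHistogram, HistogramSpec
from adcphantom.voi import ADCSample


def sample(values):
    return ADCSample(values=np.asarray(values, dtype=float))


# ---------------------------------------------------------------------------
# independent oracles (plain-Python, no numpy shortcuts shared with the impl)
# ---------------------------------------------------------------------------

def percentile_type7(sorted_vals, q):
    n = len(sorted_vals)
    h = (n - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, n - 1)
    return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])


def feature_oracle(values, counts):
    v = sorted(values)
    n = len(v)
    mean = sum(v) / n
    var1 = sum((x - mean) ** 2 for x in v) / (n - 1)
    m2 = sum((x - mean) ** 2 for x in v) / n
    m3 = sum((x - mean) ** 3 for x in v) / n
    m4 = sum((x - mean) ** 4 for x in v) / n
    total = sum(counts)
    ent = -sum((c / total) * math.log2(c / total) for c in counts if c > 0)
    p = {q: percentile_type7(v, q / 100) for q in (10, 25, 50, 75, 90)}
    return {
        "mean": mean,
        "sd": math.sqrt(var1),
        "median": p[50],
        "iqr": p[75] - p[25],
        "p10": p[10],
        "p25": p[25],
        "p75": p[75],
        "p90": p[90],
        "kurtosis": m4 / m2**2,
        "skewness": m3 / m2**1.5,
        "entropy": ent,
    }


def histogram_oracle(values, spec):
    """O(n * bins) scan using explicit half-open edges (last bin closed)."""
    edges = [spec.x_min + i * spec.bin_width for i in range(spec.n_bins + 1)]
    counts = [0] * spec.n_bins
    for v in values:
        for k in range(spec.n_bins):
            last = k == spec.n_bins - 1
            if edges[k] <= v < edges[k + 1] or (last and v == edges[k + 1]):
                counts[k] += 1
                break
    return counts


class TestSharedSpec:
    def test_single_value(self):
        spec = build_shared_spec([sample([1.0e-3])], bin_width=5e-6)
        assert spec.n_bins == 1
        assert spec.x_min <= 1.0e-3 <= spec.x_max

    def test_two_bins_for_10um_range(self):
        spec = build_shared_spec([sample([1.000e-3, 1.010e-3])], bin_width=5e-6)
        assert spec.n_bins == 2

    def test_monotone_envelope(self):
        s1 = [sample([1.0e-3, 1.1e-3])]
        s2 = s1 + [sample([0.5e-3, 1.6e-3])]
        a = build_shared_spec(s1)
        b = build_shared_spec(s2)
        assert b.x_min <= a.x_min and b.x_max >= a.x_max

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_shared_spec([])

    def test_edges_aligned_to_width(self):
        spec = build_shared_spec([sample([1.2345e-3, 1.9999e-3])], bin_width=5e-6)
        assert spec.x_min / 5e-6 == pytest.approx(round(spec.x_min / 5e-6), abs=1e-6)


class TestHistogram:
    def test_identical_values_one_bin(self):
        spec = build_shared_spec([sample([1.0e-3] * 7)])
        h = compute_histogram(sample([1.0e-3] * 7), spec)
        assert h.counts.max() == 7
        assert h.total == 7

    def test_interior_edge_goes_up(self):
        spec = HistogramSpec(bin_width=1.0, x_min=0.0, x_max=3.0)
        h = compute_histogram(sample([1.0]), spec)
        np.testing.assert_array_equal(h.counts, [0, 1, 0])

    def test_last_edge_closed(self):
        spec = HistogramSpec(bin_width=1.0, x_min=0.0, x_max=3.0)
        h = compute_histogram(sample([3.0]), spec)
        np.testing.assert_array_equal(h.counts, [0, 0, 1])

    def test_matches_brute_force(self, rng):
        vals = rng.uniform(0.5e-3, 2.0e-3, size=300)
        spec = build_shared_spec([sample(vals)])
        h = compute_histogram(sample(vals), spec)
        np.testing.assert_array_equal(h.counts, histogram_oracle(vals, spec))
        assert h.total == vals.size

    def test_out_of_range_rejected(self):
        spec = HistogramSpec(bin_width=1.0, x_min=0.0, x_max=3.0)
        with pytest.raises(ValueError):
            compute_histogram(sample([5.0]), spec)


class TestMeanHistogram:
    def test_idempotent(self):
        spec = HistogramSpec(bin_width=1.0, x_min=0.0, x_max=2.0)
        h = ADCHistogram(spec=spec, counts=np.array([2.0, 1.0]))
        m = mean_histogram([h, h, h])
        np.testing.assert_array_equal(m.counts, h.counts)

    def test_two_histograms(self):
        spec = HistogramSpec(bin_width=1.0, x_min=0.0, x_max=2.0)
        h1 = ADCHistogram(spec=spec, counts=np.array([2.0, 0.0]))
        h2 = ADCHistogram(spec=spec, counts=np.array([0.0, 2.0]))
        np.testing.assert_array_equal(mean_histogram([h1, h2]).counts, [1.0, 1.0])

    def test_spec_mismatch(self):
        h1 = ADCHistogram(HistogramSpec(1.0, 0.0, 2.0), np.array([1.0, 0.0]))
        h2 = ADCHistogram(HistogramSpec(1.0, 0.0, 3.0), np.array([1.0, 0.0, 0.0]))
        with pytest.raises(ValueError):
            mean_histogram([h1, h2])


class TestFeatures:
    def test_uniform_four_bins_entropy_two_bits(self):
        vals = [1e-3, 2e-3, 3e-3, 4e-3]
        spec = HistogramSpec(bin_width=1e-3, x_min=0.5e-3, x_max=4.5e-3)
        fv = compute_features(sample(vals), spec)
        assert fv.entropy == pytest.approx(2.0, abs=1e-12)

    def test_single_bin_entropy_zero(self):
        vals = [1.0e-3] * 10
        spec = HistogramSpec(bin_width=5e-6, x_min=0.9975e-3, x_max=1.0025e-3)
        fv = compute_features(sample(vals), spec)
        assert fv.entropy == 0.0

    def test_symmetric_sample_zero_skewness(self):
        d = 2e-4
        vals = [1e-3 - d, 1e-3, 1e-3 + d]
        spec = build_shared_spec([sample(vals)])
        fv = compute_features(sample(vals), spec)
        assert abs(fv.skewness) <= 1e-12

    def test_matches_oracle_on_seeded_samples(self, rng):
        for _ in range(50):
            vals = rng.lognormal(math.log(1e-3), 0.2, size=rng.integers(50, 400))
            spec = build_shared_spec([sample(vals)])
            fv = compute_features(sample(vals), spec)
            h = compute_histogram(sample(vals), spec)
            expected = feature_oracle(vals.tolist(), h.counts.tolist())
            for name, want in expected.items():
                assert getattr(fv, name) == pytest.approx(want, rel=1e-10), name

    def test_constant_sample_flagged(self):
        vals = [1e-3] * 5
        spec = build_shared_spec([sample(vals)])
        fv = compute_features(sample(vals), spec)
        assert fv.sd == 0.0 and fv.iqr == 0.0
        assert math.isnan(fv.skewness) and math.isnan(fv.kurtosis)

    def test_empty_sample_rejected(self):
        spec = HistogramSpec(bin_width=1.0, x_min=0.0, x_max=1.0)
        with pytest.raises(ValueError):
            compute_features(sample([]), spec)

    def test_percentile_ordering_invariant(self, rng):
        vals = rng.uniform(0.5e-3, 2e-3, 100)
        spec = build_shared_spec([sample(vals)])
        fv = compute_features(sample(vals), spec)
        assert fv.p10 <= fv.p25 <= fv.median <= fv.p75 <= fv.p90
        assert fv.iqr == pytest.approx(fv.p75 - fv.p25, abs=1e-15)

    @given(shift=st.floats(min_value=0.0, max_value=5e-3))
    @settings(max_examples=25, deadline=None)
    def test_location_shift(self, shift):
        base = np.array([0.8e-3, 0.9e-3, 1.0e-3, 1.4e-3, 2.0e-3, 1.1e-3])
        spec0 = build_shared_spec([sample(base)])
        spec1 = HistogramSpec(spec0.bin_width, spec0.x_min + shift, spec0.x_max + shift)
        f0 = compute_features(sample(base), spec0)
        f1 = compute_features(sample(base + shift), spec1)
        for name in ("mean", "median", "p10", "p25", "p75", "p90"):
            assert getattr(f1, name) == pytest.approx(getattr(f0, name) + shift, rel=1e-9)
        for name in ("sd", "iqr", "skewness", "kurtosis", "entropy"):
            assert getattr(f1, name) == pytest.approx(getattr(f0, name), rel=1e-6, abs=1e-9)

    def test_normal_limit_kurtosis_three(self):
        g = np.random.default_rng(99).normal(1e-3, 1e-4, size=100_000)
        g = np.abs(g)
        spec = build_shared_spec([sample(g)])
        fv = compute_features(sample(g), spec)
        assert fv.kurtosis == pytest.approx(3.0, abs=0.1)
        assert fv.skewness == pytest.approx(0.0, abs=0.1)

    def test_entropy_upper_bound(self, rng):
        vals = rng.uniform(0.5e-3, 2e-3, 500)
        spec = build_shared_spec([sample(vals)])
        h = compute_histogram(sample(vals), spec)
        fv = compute_features(sample(vals), spec)
        nonzero = int((h.counts > 0).sum())
        assert fv.entropy <= math.log2(nonzero) + 1e-12
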