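"""Fixed-bin ADC histograms and first-order radiomic features.

All histograms that will be compared share one bin grid (the "Xvector"): a
uniform grid at a fixed bin width spanning the pooled min/max of every sample
in the comparison group.  Moment/percentile features are computed from raw
voxel values; entropy comes from the normalised fixed-bin histogram.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .voi import ADCSample

__all__ = [
    "DEFAULT_BIN_WIDTH",
    "HistogramSpec",
    "ADCHistogram",
    "FeatureVector",
    "FEATURE_NAMES",
    "build_shared_spec",
    "compute_histogram",
    "mean_histogram",
    "compute_features",
]

#: Fixed histogram bin width in mm^2/s.
DEFAULT_BIN_WIDTH = 5e-6

FEATURE_NAMES = (
    "mean",
    "sd",
    "median",
    "iqr",
    "p10",
    "p25",
    "p75",
    "p90",
    "kurtosis",
    "skewness",
    "entropy",
)


@dataclass(frozen=True)
class HistogramSpec:
    """Uniform bin grid shared by every histogram in a comparison group."""

    bin_width: float
    x_min: float
    x_max: float

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.x_max <= self.x_min:
            raise ValueError("x_max must exceed x_min")

    @property
    def n_bins(self) -> int:
        return int(round((self.x_max - self.x_min) / self.bin_width))

    @property
    def edges(self) -> np.ndarray:
        return self.x_min + self.bin_width * np.arange(self.n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        return self.x_min + self.bin_width * (np.arange(self.n_bins) + 0.5)


@dataclass
class ADCHistogram:
    spec: HistogramSpec
    counts: np.ndarray  # real-valued so mean histograms are representable
    provenance: dict | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.size != self.spec.n_bins:
            raise ValueError("counts length inconsistent with spec")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def build_shared_spec(
    samples: Iterable[ADCSample | np.ndarray],
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> HistogramSpec:
    """Bin grid spanning the pooled range of all samples, edge-aligned to the
    bin width (outward rounding)."""
    pools = []
    for s in samples:
        v = s.values if isinstance(s, ADCSample) else np.asarray(s, dtype=float)
        if v.size:
            pools.append(v)
    if not pools:
        raise ValueError("no non-empty samples supplied")
    lo = min(float(v.min()) for v in pools)
    hi = max(float(v.max()) for v in pools)
    x_min = np.floor(lo / bin_width + 1e-9) * bin_width
    if x_min > lo:  # guard against rounding up past the data
        x_min -= bin_width
    n = max(1, int(np.ceil((hi - x_min) / bin_width - 1e-9)))
    while x_min + n * bin_width < hi:
        n += 1
    return HistogramSpec(bin_width=bin_width, x_min=x_min, x_max=x_min + n * bin_width)


def compute_histogram(sample: ADCSample, spec: HistogramSpec) -> ADCHistogram:
    """Counts on the shared grid; bins are half-open [e_k, e_{k+1}), last closed."""
    v = sample.values
    if v.size == 0:
        raise ValueError("cannot histogram an empty sample")
    tol = 1e-9 * spec.bin_width
    if v.min() < spec.x_min - tol or v.max() > spec.x_max + tol:
        raise ValueError("sample values outside histogram spec range")
    counts, _ = np.histogram(np.clip(v, spec.x_min, spec.x_max), bins=spec.edges)
    return ADCHistogram(spec=spec, counts=counts.astype(float), provenance=sample.provenance)


def mean_histogram(histograms: Sequence[ADCHistogram]) -> ADCHistogram:
    """Binwise arithmetic mean of histograms sharing one spec."""
    if not histograms:
        raise ValueError("no histograms to average")
    spec = histograms[0].spec
    for h in histograms[1:]:
        if h.spec != spec:
            raise ValueError("histograms do not share a spec")
    counts = np.mean([h.counts for h in histograms], axis=0)
    return ADCHistogram(spec=spec, counts=counts)


def _entropy_bits(counts: np.ndarray) -> float:
    total = counts.sum()
    if total <= 0:
        raise ValueError("zero-mass histogram")
    p = counts[counts > 0] / total
    return float(-np.sum(p * np.log2(p)))


def compute_features(sample: ADCSample, spec: HistogramSpec) -> FeatureVector:
    """Eleven first-order features of one VOI sample.

    Moments and percentiles use the raw voxel values (sd with n-1; percentiles
    linearly interpolated; skewness m3/m2^1.5 and non-excess kurtosis m4/m2^2
    from 1/n central moments, so a normal population gives kurtosis ~= 3).
    Entropy is Shannon entropy in bits of the fixed-bin histogram.  A constant
    sample yields NaN skewness/kurtosis rather than an error.
    """
    v = sample.values
    if v.size == 0:
        raise ValueError("empty sample")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size >= 2 else float("nan")
    p10, p25, med, p75, p90 = (float(q) for q in np.percentile(v, [10, 25, 50, 75, 90]))
    d = v - mean
    m2 = float(np.mean(d**2))
    if m2 > 0:
        m3 = float(np.mean(d**3))
        m4 = float(np.mean(d**4))
        skew = m3 / m2**1.5
        kurt = m4 / m2**2
    else:
        skew = float("nan")
        kurt = float("nan")
    entropy = _entropy_bits(compute_histogram(sample, spec).counts)
    return FeatureVector(
        mean=mean,
        sd=sd,
        median=med,
        iqr=p75 - p25,
        p10=p10,
        p25=p25,
        p75=p75,
        p90=p90,
        kurtosis=kurt,
        skewness=skew,
        entropy=entropy,
    )


@dataclass(frozen=True)
class FeatureVector:
    mean: float
    sd: float
    median: float
    iqr: float
    p10: float
    p25: float
    p75: float
    p90: float
    kurtosis: float
    skewness: float
    entropy: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}
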