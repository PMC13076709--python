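"""Voxelwise apparent-diffusion-coefficient maps from multi-b magnitude stacks.

The fit is an unweighted ordinary least squares of ``ln S`` against ``b`` over
the b-values with positive signal; ``ADC = -slope`` and ``S0 = exp(intercept)``.
Negative fitted slopes are clamped to zero; voxels with too little usable
signal are marked missing (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import DWIStack

__all__ = ["SignalFit", "ADCMap", "fit_adc_signal", "fit_adc_map"]


@dataclass(frozen=True)
class SignalFit:
    """Result of one mono-exponential signal fit."""

    s0: float
    adc: float
    n_points_used: int
    clamped: bool = False

    @property
    def defined(self) -> bool:
        return self.n_points_used >= 2 and np.isfinite(self.adc)


@dataclass
class ADCMap:
    """3D ADC map (mm^2/s); NaN marks voxels where the fit is undefined."""

    values: np.ndarray
    pixel_mm: float
    slice_mm: float
    provenance: dict | None = None

    def __post_init__(self) -> None:
        if self.pixel_mm <= 0 or self.slice_mm <= 0:
            raise ValueError("voxel spacing must be positive")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and np.any(finite < 0):
            raise ValueError("defined ADC values must be non-negative")


def fit_adc_signal(signals, b_values) -> SignalFit:
    """Fit ``S(b) = S0 * exp(-b * ADC)`` to one voxel's b-series.

    Only strictly positive signals enter the log-linear regression.  With fewer
    than two usable points the fit is undefined (NaN ADC).  A negative fitted
    ADC is clamped to zero and flagged.
    """
    s = np.asarray(signals, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if s.shape != b.shape or s.ndim != 1:
        raise ValueError("signals and b_values must be 1D arrays of equal length")
    if s.size < 2:
        raise ValueError("need at least two b-values")
    pos = s > 0
    n = int(pos.sum())
    if n < 2:
        return SignalFit(s0=np.nan, adc=np.nan, n_points_used=n)
    x, y = b[pos], np.log(s[pos])
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    adc = -slope
    clamped = adc < 0
    if clamped:
        adc = 0.0
    return SignalFit(s0=float(np.exp(intercept)), adc=float(adc), n_points_used=n, clamped=clamped)


def fit_adc_map(stack: DWIStack, *, signal_floor: float | None = None) -> ADCMap:
    """Voxelwise mono-exponential fit over a whole stack (vectorised).

    Voxels whose b=0 signal falls below ``signal_floor`` (default: three times
    the protocol's single-average noise sigma) are marked missing, as are
    voxels with fewer than two positive signals.
    """
    proto = stack.protocol
    if signal_floor is None:
        signal_floor = 3.0 * proto.noise_sigma
    data = stack.data
    b = np.asarray(proto.b_values, dtype=float)

    pos = data > 0
    y = np.where(pos, np.log(np.where(pos, data, 1.0)), 0.0)
    w = pos.astype(float)

    n = w.sum(axis=-1)
    sx = (w * b).sum(axis=-1)
    sy = (w * y).sum(axis=-1)
    sxx = (w * b**2).sum(axis=-1)
    sxy = (w * b * y).sum(axis=-1)
    denom = n * sxx - sx**2

    valid = (n >= 2) & (denom > 0) & (data[..., 0] >= signal_floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (n * sxy - sx * sy) / denom
    adc = np.where(valid, np.clip(-slope, 0.0, None), np.nan)

    return ADCMap(
        values=adc,
        pixel_mm=proto.pixel_mm,
        slice_mm=proto.slice_mm,
        provenance={
            "sequence": proto.sequence,
            "session": stack.session_id,
            "repeat": stack.repeat_id,
            "level": stack.level,
        },
    )
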