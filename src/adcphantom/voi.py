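"""Cylindrical volumes of interest on the ADC-map grid.

VOIs are circles drawn on a few consecutive slices at each vial centre,
rasterised with a voxel-centre-in-circle rule, and reused bit-identically
across every reconstruction level and repeat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import ADCMap
from .phantom import AcquisitionProtocol, GeometryError, PhantomLayout

__all__ = [
    "PAPER_VOI_DIAMETER_MM",
    "VOISpec",
    "VOIMask",
    "ADCSample",
    "make_cylindrical_voi",
    "default_voi_specs",
    "extract_adc_sample",
]

#: VOI diameters used on the physical phantom (mm); the simulation pipeline
#: instead sizes VOIs as a fraction of the vial footprint so they always fit.
PAPER_VOI_DIAMETER_MM = {"fFOV": 25.0, "rFOV": 22.0}


@dataclass(frozen=True)
class VOISpec:
    label: str
    center_xy: tuple[float, float]
    diameter_mm: float
    n_slices: int = 3
    start_slice: int = 0

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")
        if self.n_slices < 1 or self.start_slice < 0:
            raise ValueError("invalid slice block")


@dataclass
class VOIMask:
    mask: np.ndarray  # 3D boolean
    spec: VOISpec

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class ADCSample:
    """Finite ADC values extracted from one VOI (missing voxels dropped)."""

    values: np.ndarray
    provenance: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (
            not np.all(np.isfinite(self.values)) or np.any(self.values < 0)
        ):
            raise ValueError("sample values must be finite and non-negative")

    def __len__(self) -> int:
        return int(self.values.size)


def make_cylindrical_voi(
    spec: VOISpec, shape: tuple[int, int, int], pixel_mm: float
) -> VOIMask:
    """Rasterise a cylindrical VOI on a grid.

    A voxel is included iff its centre lies strictly within ``diameter/2`` of
    the VOI axis in-plane, on ``n_slices`` consecutive slices starting at
    ``start_slice``.  Physical coordinates place the origin at the FOV centre
    with voxel centres at ``(i + 0.5) * pixel_mm`` from the corner.
    """
    nx, ny, nz = shape
    if nx != ny:
        raise ValueError("in-plane grid must be square")
    r = spec.diameter_mm / 2.0
    cx, cy = spec.center_xy
    half = nx * pixel_mm / 2.0
    if abs(cx) + r > half or abs(cy) + r > half:
        raise GeometryError(f"VOI {spec.label} exceeds in-plane grid bounds")
    if spec.start_slice + spec.n_slices > nz:
        raise GeometryError(f"VOI {spec.label} exceeds slice range")

    coords = (np.arange(nx) + 0.5) * pixel_mm - half
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    disc = (xx - cx) ** 2 + (yy - cy) ** 2 < r**2
    mask = np.zeros(shape, dtype=bool)
    for z in range(spec.start_slice, spec.start_slice + spec.n_slices):
        mask[:, :, z] = disc
    out = VOIMask(mask=mask, spec=spec)
    if out.voxel_count == 0:
        raise GeometryError(f"VOI {spec.label} contains no voxels")
    return out


def default_voi_specs(
    layout: PhantomLayout,
    protocol: AcquisitionProtocol,
    *,
    diameter_fraction: float = 0.8,
    n_slices: int = 3,
) -> list[VOISpec]:
    """Centred VOI per vial, sized as a fraction of the vial diameter.

    The slice block is centred on the middle slice.  ``diameter_fraction`` must
    stay below 1 so the VOI keeps a margin from the vial wall.
    """
    if not (0 < diameter_fraction < 1):
        raise ValueError("diameter_fraction must be in (0, 1)")
    n_slices = min(n_slices, protocol.n_slices)
    start = max(0, protocol.n_slices // 2 - n_slices // 2)
    return [
        VOISpec(
            label=v.label,
            center_xy=v.center_xy,
            diameter_mm=2.0 * v.radius_mm * diameter_fraction,
            n_slices=n_slices,
            start_slice=start,
        )
        for v in layout.vials
    ]


def extract_adc_sample(
    adc_map: ADCMap, voi: VOIMask, *, provenance: dict | None = None
) -> ADCSample:
    """Pull the VOI's ADC values out of a map, dropping missing voxels."""
    if adc_map.values.shape != voi.mask.shape:
        raise ValueError(
            f"grid mismatch: map {adc_map.values.shape} vs mask {voi.mask.shape}"
        )
    vals = adc_map.values[voi.mask]
    vals = vals[np.isfinite(vals)]
    prov = dict(adc_map.provenance or {})
    prov["vial"] = voi.spec.label
    if provenance:
        prov.update(provenance)
    return ADCSample(values=vals, provenance=prov)
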