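"""Synthetic diffusion phantom: vial geometry, nominal diffusivity model and
seeded multi-b DWI simulation with emulated reconstruction-stage denoising.

The simulated object mimics a commercial multi-vial diffusion phantom: a
cylindrical water bath holding vials of polymer solutions whose diffusivity
spans the free-water to restricted range.  Magnitude images follow the
mono-exponential decay ``S(b) = S0 * exp(-b * ADC)`` with Rician noise and
NEX-style magnitude averaging.  Denoising strength levels are emulated by
in-plane Gaussian smoothing of the magnitude b-images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "PVP_FRACTIONS",
    "VialSpec",
    "PhantomLayout",
    "AcquisitionProtocol",
    "NominalADCModel",
    "StudyDesign",
    "DWIStack",
    "build_phantom_layout",
    "default_protocol",
    "nominal_adc",
    "simulate_dwi_series",
    "emulate_dl_reconstruction",
    "simulate_study",
]

#: Polymer mass fractions available in the phantom (0% is the free-water vial).
PVP_FRACTIONS = (0.0, 0.10, 0.20, 0.30, 0.40, 0.50)

RINGS = ("central", "inner", "outer")

# Fixed physical geometry of the simulated phantom (mm).
VIAL_RADIUS_MM = 10.0
INNER_RING_MM = 21.0
OUTER_RING_MM = 42.0
BATH_RADIUS_MM = 53.0

#: Physical in-plane extent the default protocols are designed to cover (mm).
REFERENCE_FOV_MM = 110.08

#: Default denoising-level smoothing widths (level name -> Gaussian sigma, mm).
DEFAULT_LEVELS = (("OFF", 0.0), ("LOW", 0.4), ("MEDIUM", 0.8), ("HIGH", 1.2))

LEVEL_ORDER = tuple(name for name, _ in DEFAULT_LEVELS)


class GeometryError(ValueError):
    """Raised when a requested geometry is inconsistent (overlaps, out of grid)."""


@dataclass(frozen=True)
class VialSpec:
    """One cylindrical vial: label, polymer fraction, ring position and footprint."""

    label: str
    pvp_fraction: float
    ring: str
    center_xy: tuple[float, float]
    radius_mm: float = VIAL_RADIUS_MM

    def __post_init__(self) -> None:
        if self.ring not in RINGS:
            raise ValueError(f"unknown ring {self.ring!r}; expected one of {RINGS}")
        if not any(math.isclose(self.pvp_fraction, f, abs_tol=1e-9) for f in PVP_FRACTIONS):
            raise ValueError(
                f"pvp_fraction {self.pvp_fraction} not in supported set {PVP_FRACTIONS}"
            )
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")


@dataclass(frozen=True)
class PhantomLayout:
    """Arrangement of vials inside the water bath."""

    vials: tuple[VialSpec, ...]
    bath_adc: float = 2.0e-3
    bath_radius_mm: float = BATH_RADIUS_MM
    fov_mm: float = 2.0 * BATH_RADIUS_MM
    wall_mm: float = 1.5  # dark (signal-free) vial wall annulus thickness
    visible_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        labels = [v.label for v in self.vials]
        if len(set(labels)) != len(labels):
            raise ValueError("vial labels must be unique")
        for i, a in enumerate(self.vials):
            for b in self.vials[i + 1 :]:
                d = math.dist(a.center_xy, b.center_xy)
                if d < a.radius_mm + b.radius_mm - 1e-9:
                    raise GeometryError(f"vials {a.label} and {b.label} overlap")
        if not self.visible_labels:
            object.__setattr__(self, "visible_labels", tuple(labels))

    def vial(self, label: str) -> VialSpec:
        for v in self.vials:
            if v.label == label:
                return v
        raise KeyError(label)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Acquisition parameters of one DWI sequence variant."""

    sequence: str
    b_values: tuple[float, ...] = (0.0, 500.0, 1000.0, 1500.0, 2000.0)
    averages_per_b: tuple[int, ...] = (2, 2, 2, 2, 2)
    pixel_mm: float = 0.86
    slice_mm: float = 4.0
    matrix: int = 128
    n_slices: int = 25
    noise_sigma: float = 4.0
    s0: float = 1000.0

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        if b.size < 2 or b[0] != 0 or np.any(np.diff(b) <= 0):
            raise ValueError("b_values must be strictly increasing and start at 0")
        if len(self.averages_per_b) != len(self.b_values):
            raise ValueError("averages_per_b must align with b_values")
        if any(int(a) < 1 for a in self.averages_per_b):
            raise ValueError("averages must be positive integers")
        if self.pixel_mm <= 0 or self.slice_mm <= 0:
            raise ValueError("voxel spacing must be positive")
        if self.matrix < 2 or self.n_slices < 1:
            raise ValueError("matrix/n_slices too small")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0 (0 disables noise)")

    @property
    def fov_mm(self) -> float:
        return self.matrix * self.pixel_mm

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return (self.matrix, self.matrix, self.n_slices, len(self.b_values))


def default_protocol(
    sequence: str,
    *,
    matrix: int | None = None,
    n_slices: int | None = None,
    pixel_mm: float | None = None,
    noise_sigma: float = 4.0,
) -> AcquisitionProtocol:
    """Build the default protocol for a sequence variant.

    ``fFOV`` uses 0.86 mm pixels / 4 mm slices with 2 averages per b-value;
    ``rFOV`` uses 0.70 mm pixels / 3 mm slices with 2 averages at b=0 and 4 at
    the higher b-values.  When ``matrix`` is overridden without an explicit
    ``pixel_mm``, the pixel size is rescaled so the field of view still covers
    the fixed phantom footprint.
    """
    key = sequence.lower()
    if key == "ffov":
        base = AcquisitionProtocol(sequence="fFOV", noise_sigma=noise_sigma)
    elif key == "rfov":
        base = AcquisitionProtocol(
            sequence="rFOV",
            averages_per_b=(2, 4, 4, 4, 4),
            pixel_mm=0.70,
            slice_mm=3.0,
            matrix=160,
            n_slices=27,
            noise_sigma=noise_sigma,
        )
    else:
        raise ValueError(f"unknown sequence {sequence!r}; expected fFOV or rFOV")
    kwargs: dict = {}
    if matrix is not None:
        kwargs["matrix"] = int(matrix)
        if pixel_mm is None:
            kwargs["pixel_mm"] = REFERENCE_FOV_MM / int(matrix)
    if pixel_mm is not None:
        kwargs["pixel_mm"] = float(pixel_mm)
    if n_slices is not None:
        kwargs["n_slices"] = int(n_slices)
    return replace(base, **kwargs) if kwargs else base


def _ring_positions(radius: float, n: int, phase_deg: float) -> list[tuple[float, float]]:
    out = []
    for k in range(n):
        a = math.radians(phase_deg + k * 360.0 / n)
        out.append((radius * math.cos(a), radius * math.sin(a)))
    return out


def build_phantom_layout(
    sequence: str,
    *,
    vials: Sequence[VialSpec] | None = None,
    bath_adc: float = 2.0e-3,
) -> PhantomLayout:
    """Return the default vial layout for a sequence (or wrap explicit vials).

    The full-FOV layout holds 13 vials: one central free-water vial plus inner
    and outer rings of six concentrations each, labelled ``PVP{percent}_{C|I|O}``.
    The reduced-FOV layout keeps the 11 vials inside its narrower field of view
    (``PVP20_O`` and ``PVP50_O`` are cropped out).
    """
    key = sequence.lower()
    if key not in ("ffov", "rfov"):
        raise ValueError(f"unknown sequence {sequence!r}; expected fFOV or rFOV")
    if vials is not None:
        return PhantomLayout(vials=tuple(vials), bath_adc=bath_adc)

    specs: list[VialSpec] = [
        VialSpec(label="PVP0_C", pvp_fraction=0.0, ring="central", center_xy=(0.0, 0.0))
    ]
    inner = _ring_positions(INNER_RING_MM, 6, phase_deg=0.0)
    outer = _ring_positions(OUTER_RING_MM, 6, phase_deg=30.0)
    for frac, pos_i, pos_o in zip(PVP_FRACTIONS, inner, outer):
        pct = int(round(frac * 100))
        specs.append(
            VialSpec(label=f"PVP{pct}_I", pvp_fraction=frac, ring="inner", center_xy=pos_i)
        )
        specs.append(
            VialSpec(label=f"PVP{pct}_O", pvp_fraction=frac, ring="outer", center_xy=pos_o)
        )
    if key == "rfov":
        dropped = {"PVP20_O", "PVP50_O"}
        specs = [v for v in specs if v.label not in dropped]
    return PhantomLayout(vials=tuple(specs), bath_adc=bath_adc)


# ---------------------------------------------------------------------------
# Nominal diffusivity model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NominalADCModel:
    """Per-concentration second-order polynomial ``ADC(T) = a0 + a1*T + a2*T**2``.

    ``coefficients`` maps polymer mass fraction to ``(a0, a1, a2)`` with ADC in
    mm^2/s and temperature in degrees Celsius.  A calibration table supplied
    with a physical phantom can be loaded into this structure directly; the
    :meth:`default` model is a synthetic stand-in anchored so that the 0% vial
    reads 2.0e-3 mm^2/s and the 50% vial 0.3e-3 mm^2/s at 20 C, with
    intermediate concentrations log-linearly interpolated and a +2%/C linear
    temperature slope.
    """

    coefficients: Mapping[float, tuple[float, float, float]]
    valid_range: tuple[float, float] = (15.0, 24.0)

    @classmethod
    def default(cls) -> "NominalADCModel":
        adc_hi, adc_lo = 2.0e-3, 0.3e-3
        slope_per_c = 0.02
        coeffs = {}
        for frac in PVP_FRACTIONS:
            adc20 = adc_hi * (adc_lo / adc_hi) ** (frac / 0.5)
            a1 = adc20 * slope_per_c
            a0 = adc20 - a1 * 20.0
            coeffs[frac] = (a0, a1, 0.0)
        return cls(coefficients=coeffs)

    def adc(self, pvp_fraction: float, temperature_c: float) -> float:
        return nominal_adc(self, pvp_fraction, temperature_c)


def nominal_adc(model: NominalADCModel, pvp_fraction: float, temperature_c: float) -> float:
    """Evaluate the nominal ADC polynomial at a temperature (mm^2/s)."""
    lo, hi = model.valid_range
    if not (lo <= temperature_c <= hi):
        raise ValueError(
            f"temperature {temperature_c} C outside calibrated range [{lo}, {hi}]"
        )
    try:
        a0, a1, a2 = model.coefficients[pvp_fraction]
    except KeyError:
        for key, val in model.coefficients.items():
            if math.isclose(key, pvp_fraction, abs_tol=1e-9):
                a0, a1, a2 = val
                break
        else:
            raise KeyError(f"no coefficients for pvp_fraction={pvp_fraction}") from None
    value = a0 + a1 * temperature_c + a2 * temperature_c**2
    if value <= 0:
        raise ValueError("nominal ADC evaluated non-positive; bad coefficient table")
    return value


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


@dataclass
class DWIStack:
    """One simulated (or loaded) 4D magnitude acquisition, (x, y, slice, b)."""

    data: np.ndarray
    protocol: AcquisitionProtocol
    level: str = "OFF"
    repeat_id: str = "r1"
    session_id: str = "S1"
    ground_truth: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.data.shape != self.protocol.shape:
            raise ValueError(
                f"data shape {self.data.shape} inconsistent with protocol {self.protocol.shape}"
            )
        if np.any(self.data < 0):
            raise ValueError("magnitude data must be non-negative")


def _voxel_center_grid(protocol: AcquisitionProtocol) -> tuple[np.ndarray, np.ndarray]:
    # Physical coordinates with the origin at the FOV centre; voxel centres at
    # (i + 0.5) * pixel from the FOV corner.
    n, p = protocol.matrix, protocol.pixel_mm
    coords = (np.arange(n) + 0.5) * p - n * p / 2.0
    return np.meshgrid(coords, coords, indexing="ij")


def ground_truth_maps(
    layout: PhantomLayout,
    protocol: AcquisitionProtocol,
    model: NominalADCModel,
    temperature_c: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (adc, s0) 3D maps for the noiseless object.

    Voxels outside the bath carry zero signal.  Vial membership is decided by
    the in-plane voxel-centre distance to each vial axis; vials span all slices.
    """
    xx, yy = _voxel_center_grid(protocol)
    adc2d = np.zeros_like(xx)
    s0_2d = np.zeros_like(xx)
    bath = xx**2 + yy**2 <= layout.bath_radius_mm**2
    adc2d[bath] = layout.bath_adc
    s0_2d[bath] = protocol.s0
    for vial in layout.vials:
        cx, cy = vial.center_xy
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        wall = r2 <= (vial.radius_mm + layout.wall_mm) ** 2
        adc2d[wall] = 0.0
        s0_2d[wall] = 0.0  # signal-free plastic wall
        inside = r2 <= vial.radius_mm**2
        adc2d[inside] = nominal_adc(model, vial.pvp_fraction, temperature_c)
        s0_2d[inside] = protocol.s0
    adc = np.repeat(adc2d[:, :, None], protocol.n_slices, axis=2)
    s0 = np.repeat(s0_2d[:, :, None], protocol.n_slices, axis=2)
    return adc, s0


def simulate_dwi_series(
    layout: PhantomLayout,
    protocol: AcquisitionProtocol,
    model: NominalADCModel,
    temperature_c: float,
    seed: int,
    *,
    session_id: str = "S1",
    repeat_id: str = "r1",
) -> DWIStack:
    """Simulate one multi-b magnitude acquisition of the phantom.

    Each stored b-image is the arithmetic mean of ``averages_per_b`` independent
    Rician magnitude realisations: ``|S(b) + n_re + i*n_im|`` with real/imag
    noise drawn i.i.d. from ``N(0, noise_sigma)``.  ``noise_sigma == 0`` yields
    the exact noiseless decay.
    """
    adc, s0 = ground_truth_maps(layout, protocol, model, temperature_c)
    b = np.asarray(protocol.b_values, dtype=float)
    clean = s0[..., None] * np.exp(-adc[..., None] * b[None, None, None, :])

    sigma = protocol.noise_sigma
    if sigma == 0:
        data = clean
    else:
        rng = np.random.default_rng(seed)
        data = np.empty_like(clean)
        for bi, navg in enumerate(protocol.averages_per_b):
            acc = np.zeros(clean.shape[:3])
            for _ in range(int(navg)):
                re = clean[..., bi] + rng.normal(0.0, sigma, clean.shape[:3])
                im = rng.normal(0.0, sigma, clean.shape[:3])
                acc += np.hypot(re, im)
            data[..., bi] = acc / int(navg)

    truth = {
        v.label: nominal_adc(model, v.pvp_fraction, temperature_c) for v in layout.vials
    }
    truth["__bath__"] = layout.bath_adc
    return DWIStack(
        data=data,
        protocol=protocol,
        level="OFF",
        repeat_id=repeat_id,
        session_id=session_id,
        ground_truth=truth,
    )


def emulate_dl_reconstruction(
    stack: DWIStack,
    level: str,
    *,
    smoothing_mm: Mapping[str, float] | None = None,
) -> DWIStack:
    """Emulate a reconstruction-stage denoiser at a given strength level.

    ``OFF`` is the identity.  Other levels convolve every in-plane b-image with
    an isotropic Gaussian whose standard deviation (mm) is the level's
    smoothing parameter; means over interior regions are preserved by the
    normalised kernel.
    """
    table = dict(smoothing_mm) if smoothing_mm is not None else dict(DEFAULT_LEVELS)
    if level not in table:
        raise ValueError(f"unknown reconstruction level {level!r}")
    sigma_mm = float(table[level])
    out = stack.data.copy()
    if sigma_mm > 0:
        sigma_vox = sigma_mm / stack.protocol.pixel_mm
        # smooth in-plane only; 'nearest' keeps edge means from collapsing
        out = gaussian_filter(out, sigma=(sigma_vox, sigma_vox, 0, 0), mode="nearest")
        np.clip(out, 0.0, None, out=out)
    return DWIStack(
        data=out,
        protocol=stack.protocol,
        level=level,
        repeat_id=stack.repeat_id,
        session_id=stack.session_id,
        ground_truth=stack.ground_truth,
    )


@dataclass(frozen=True)
class StudyDesign:
    """Repeat/session/level structure of a phantom study."""

    levels: tuple[tuple[str, float], ...] = DEFAULT_LEVELS
    n_repeats: int = 5
    sessions: tuple[tuple[str, float], ...] = (("S1", 21.0), ("S2", 22.0))
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 2:
            raise ValueError("n_repeats must be >= 2")
        names = [n for n, _ in self.levels]
        sigmas = [s for _, s in self.levels]
        if names[0] != "OFF" or sigmas[0] != 0:
            raise ValueError("first level must be OFF with zero smoothing")
        if any(b <= a for a, b in zip(sigmas, sigmas[1:])):
            raise ValueError("smoothing parameters must increase strictly OFF->HIGH")
        if not self.sessions:
            raise ValueError("at least one session required")

    @property
    def level_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.levels)

    @property
    def smoothing_mm(self) -> dict[str, float]:
        return dict(self.levels)


def child_seed(base_seed: int, session_index: int, repeat_index: int) -> np.random.SeedSequence:
    """Deterministic per-acquisition seed derivation (stable across runs)."""
    return np.random.SeedSequence(entropy=base_seed, spawn_key=(session_index, repeat_index))


def simulate_study(
    design: StudyDesign,
    sequence: str,
    *,
    layout: PhantomLayout | None = None,
    protocol: AcquisitionProtocol | None = None,
    model: NominalADCModel | None = None,
) -> dict[tuple[str, str, str], DWIStack]:
    """Simulate a full repeat/session/level study for one sequence.

    One raw noisy acquisition is generated per (session, repeat); every
    reconstruction level is then applied to that same realisation, mirroring
    multiple reconstructions of one set of raw data (which is what makes the
    downstream paired comparisons meaningful).
    """
    layout = layout if layout is not None else build_phantom_layout(sequence)
    protocol = protocol if protocol is not None else default_protocol(sequence)
    model = model if model is not None else NominalADCModel.default()

    out: dict[tuple[str, str, str], DWIStack] = {}
    for s_idx, (session_id, temp_c) in enumerate(design.sessions):
        for r_idx in range(design.n_repeats):
            repeat_id = f"r{r_idx + 1}"
            ss = child_seed(design.base_seed, s_idx, r_idx)
            raw = simulate_dwi_series(
                layout,
                protocol,
                model,
                temp_c,
                seed=ss,
                session_id=session_id,
                repeat_id=repeat_id,
            )
            for level in design.level_names:
                out[(session_id, repeat_id, level)] = emulate_dl_reconstruction(
                    raw, level, smoothing_mm=design.smoothing_mm
                )
    return out
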