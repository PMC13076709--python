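"""NIfTI and sidecar I/O for simulated stacks, ADC maps and VOI masks."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .fitting import ADCMap
from .phantom import AcquisitionProtocol, DWIStack

__all__ = [
    "save_stack",
    "load_stack",
    "save_adc_map",
    "load_adc_map",
    "save_mask",
    "load_mask",
]


def _affine(pixel_mm: float, slice_mm: float) -> np.ndarray:
    return np.diag([pixel_mm, pixel_mm, slice_mm, 1.0])


def save_stack(stack: DWIStack, path: str | Path) -> Path:
    """Write a 4D stack as uncompressed NIfTI plus a JSON sidecar.

    The sidecar carries the b-values (ascending), averages, noise level and
    provenance needed to reload the stack without the originating objects.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    proto = stack.protocol
    img = nib.Nifti1Image(stack.data.astype(np.float64), _affine(proto.pixel_mm, proto.slice_mm))
    nib.save(img, str(path))
    sidecar = {
        "bvalues": list(map(float, proto.b_values)),
        "averages_per_b": list(map(int, proto.averages_per_b)),
        "sequence": proto.sequence,
        "pixel_mm": proto.pixel_mm,
        "slice_mm": proto.slice_mm,
        "noise_sigma": proto.noise_sigma,
        "s0": proto.s0,
        "level": stack.level,
        "session_id": stack.session_id,
        "repeat_id": stack.repeat_id,
        "ground_truth": stack.ground_truth,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def load_stack(path: str | Path) -> DWIStack:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    data = np.asarray(nib.load(str(path)).get_fdata())
    proto = AcquisitionProtocol(
        sequence=meta["sequence"],
        b_values=tuple(meta["bvalues"]),
        averages_per_b=tuple(meta["averages_per_b"]),
        pixel_mm=meta["pixel_mm"],
        slice_mm=meta["slice_mm"],
        matrix=data.shape[0],
        n_slices=data.shape[2],
        noise_sigma=meta["noise_sigma"],
        s0=meta.get("s0", 1000.0),
    )
    return DWIStack(
        data=data,
        protocol=proto,
        level=meta["level"],
        repeat_id=meta["repeat_id"],
        session_id=meta["session_id"],
        ground_truth=meta.get("ground_truth"),
    )


def save_adc_map(adc_map: ADCMap, path: str | Path, *, scale: float = 1.0) -> Path:
    """Write an ADC map as NIfTI; ``scale`` (e.g. 1e3) is recorded in the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(
        (adc_map.values * scale).astype(np.float64), _affine(adc_map.pixel_mm, adc_map.slice_mm)
    )
    img.header["descrip"] = f"ADC x{scale:g} mm2/s".encode()
    nib.save(img, str(path))
    if adc_map.provenance:
        path.with_suffix(".json").write_text(
            json.dumps({"scale": scale, **adc_map.provenance}, indent=2, sort_keys=True)
        )
    return path


def load_adc_map(path: str | Path) -> ADCMap:
    path = Path(path)
    img = nib.load(str(path))
    scale = 1.0
    prov = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        scale = float(meta.pop("scale", 1.0))
        prov = meta
    zooms = img.header.get_zooms()
    return ADCMap(
        values=np.asarray(img.get_fdata()) / scale,
        pixel_mm=float(zooms[0]),
        slice_mm=float(zooms[2]),
        provenance=prov,
    )


def save_mask(mask: np.ndarray, pixel_mm: float, slice_mm: float, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(mask.astype(np.uint8), _affine(pixel_mm, slice_mm))
    nib.save(img, str(path))
    return path


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata()) > 0.5
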