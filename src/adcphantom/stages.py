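"""Disk-based pipeline stages.

Each stage reads the previous stage's on-disk artifacts, so real scanner data
(NIfTI stacks with b-value sidecars, or precomputed ADC maps plus a VOI table)
can enter at the fit or extract stage.  Layout on disk, per sequence::

    <out>/<sequence>/stacks/<session>_<repeat>_<level>.nii (+ .json sidecar)
    <out>/<sequence>/adc/<session>_<repeat>_<level>.nii
    <out>/<sequence>/masks/<vial>.nii
    <out>/<sequence>/vois.csv
    <out>/<sequence>/nominal.json
    <out>/<sequence>/samples.csv
    <out>/*.csv                      (result tables)
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .fitting import fit_adc_map
from .io import load_adc_map, load_stack, save_adc_map, save_mask, save_stack
from .phantom import (
    NominalADCModel,
    StudyDesign,
    build_phantom_layout,
    default_protocol,
    nominal_adc,
    simulate_study,
)
from .pipeline import StudyResultSet, analyze_samples, render_report
from .repeatability import aggregate_sessions
from .voi import ADCSample, VOISpec, default_voi_specs, make_cylindrical_voi, extract_adc_sample

logger = logging.getLogger("adcphantom")

__all__ = [
    "stage_simulate",
    "stage_fit",
    "stage_extract",
    "stage_analyze",
    "stage_report",
]


def _design(config: PipelineConfig) -> StudyDesign:
    return StudyDesign(
        levels=config.levels,
        n_repeats=config.n_repeats,
        sessions=config.sessions,
        base_seed=config.seed,
    )


def stage_simulate(config: PipelineConfig, outdir: str | Path) -> None:
    outdir = Path(outdir)
    model = NominalADCModel.default()
    for sequence in config.sequences:
        layout = build_phantom_layout(sequence)
        protocol = default_protocol(
            sequence,
            matrix=config.matrix,
            n_slices=config.n_slices,
            pixel_mm=config.pixel_mm,
            noise_sigma=config.noise_sigma,
        )
        design = _design(config)
        seqdir = outdir / sequence
        stacks = simulate_study(design, sequence, layout=layout, protocol=protocol)
        for (session, repeat, level), stack in stacks.items():
            save_stack(stack, seqdir / "stacks" / f"{session}_{repeat}_{level}.nii")

        specs = default_voi_specs(
            layout,
            protocol,
            diameter_fraction=config.voi_diameter_fraction,
            n_slices=config.voi_n_slices,
        )
        pd.DataFrame(
            [
                {
                    "label": s.label,
                    "center_x_mm": s.center_xy[0],
                    "center_y_mm": s.center_xy[1],
                    "diameter_mm": s.diameter_mm,
                    "n_slices": s.n_slices,
                    "start_slice": s.start_slice,
                }
                for s in specs
            ]
        ).to_csv(seqdir / "vois.csv", index=False)

        nominal = {
            session: {
                "__temperature_c__": temp,
                **{v.label: nominal_adc(model, v.pvp_fraction, temp) for v in layout.vials},
            }
            for session, temp in design.sessions
        }
        (seqdir / "nominal.json").write_text(json.dumps(nominal, indent=2, sort_keys=True))
        logger.info("[simulate] %s: wrote %d stacks", sequence, len(stacks))


def stage_fit(config: PipelineConfig, outdir: str | Path) -> None:
    outdir = Path(outdir)
    for sequence in config.sequences:
        seqdir = outdir / sequence
        stack_paths = sorted((seqdir / "stacks").glob("*.nii"))
        if not stack_paths:
            raise FileNotFoundError(f"no stacks under {seqdir / 'stacks'}; run simulate first")
        for p in stack_paths:
            stack = load_stack(p)
            save_adc_map(fit_adc_map(stack), seqdir / "adc" / p.name)
        logger.info("[fit] %s: %d maps", sequence, len(stack_paths))


def _load_vois(seqdir: Path) -> list[VOISpec]:
    df = pd.read_csv(seqdir / "vois.csv")
    return [
        VOISpec(
            label=row.label,
            center_xy=(row.center_x_mm, row.center_y_mm),
            diameter_mm=row.diameter_mm,
            n_slices=int(row.n_slices),
            start_slice=int(row.start_slice),
        )
        for row in df.itertuples()
    ]


def stage_extract(config: PipelineConfig, outdir: str | Path) -> None:
    outdir = Path(outdir)
    for sequence in config.sequences:
        seqdir = outdir / sequence
        map_paths = sorted((seqdir / "adc").glob("*.nii"))
        if not map_paths:
            raise FileNotFoundError(f"no ADC maps under {seqdir / 'adc'}; run fit first")
        specs = _load_vois(seqdir)
        first = load_adc_map(map_paths[0])
        masks = {
            s.label: make_cylindrical_voi(s, first.values.shape, first.pixel_mm)
            for s in specs
        }
        for label, mask in masks.items():
            save_mask(mask.mask, first.pixel_mm, first.slice_mm, seqdir / "masks" / f"{label}.nii")
        rows = []
        for p in map_paths:
            adc_map = load_adc_map(p)
            session, repeat, level = p.stem.split("_")
            for label, mask in masks.items():
                sample = extract_adc_sample(adc_map, mask)
                rows.append(
                    pd.DataFrame(
                        {
                            "vial": label,
                            "session": session,
                            "repeat": repeat,
                            "level": level,
                            "adc": sample.values,
                        }
                    )
                )
        df = pd.concat(rows, ignore_index=True)
        df.to_csv(seqdir / "samples.csv", index=False)
        logger.info("[extract] %s: %d voxel rows", sequence, len(df))


def stage_analyze(config: PipelineConfig, outdir: str | Path) -> StudyResultSet:
    outdir = Path(outdir)
    design = _design(config)
    tables_per_seq = []
    for sequence in config.sequences:
        seqdir = outdir / sequence
        df = pd.read_csv(seqdir / "samples.csv")
        nominal_raw = json.loads((seqdir / "nominal.json").read_text())
        nominal = {
            session: {k: v for k, v in table.items() if not k.startswith("__")}
            for session, table in nominal_raw.items()
        }
        samples = {
            (vial, session, repeat, level): ADCSample(values=g["adc"].to_numpy())
            for (vial, session, repeat, level), g in df.groupby(
                ["vial", "session", "repeat", "level"], sort=True
            )
        }
        tables_per_seq.append(
            analyze_samples(
                samples,
                nominal,
                list(design.level_names),
                sequence=sequence,
                bin_width=config.bin_width,
            )
        )

    tables = {
        name: pd.concat([t[name] for t in tables_per_seq], ignore_index=True)
        for name in tables_per_seq[0]
    }
    pooled = {}
    if len(config.sessions) >= 2:
        pooled = aggregate_sessions(
            tables["accuracy_repeats"],
            tables["repeatability"],
            tables["wasserstein"],
            tables["percent_diff"],
        )
    results = StudyResultSet(
        tables=tables,
        pooled=pooled,
        manifest={"config": config.to_dict(), "config_hash": config.content_hash(), "seed": config.seed},
    )
    results.write(outdir)
    return results


def stage_report(config: PipelineConfig, outdir: str | Path) -> None:
    outdir = Path(outdir)
    tables = {}
    for name in ("features", "wilcoxon", "accuracy", "repeatability", "wasserstein"):
        p = outdir / f"{name}.csv"
        if p.exists():
            tables[name] = pd.read_csv(p)
    if not tables:
        raise FileNotFoundError(f"no result tables under {outdir}; run analyze first")
    render_report(StudyResultSet(tables=tables), outdir)
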