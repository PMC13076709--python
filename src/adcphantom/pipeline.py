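"""End-to-end orchestration: simulate -> fit -> extract -> analyze -> report.

Every stage can also run standalone against on-disk artifacts (NIfTI stacks
with b-value sidecars, ADC maps, a VOI table and tidy sample CSVs), so real
scanner data can enter the pipeline at the fit or extract stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .fitting import fit_adc_map
from .histogram import build_shared_spec, compute_features, compute_histogram, mean_histogram, FEATURE_NAMES
from .io import save_adc_map, save_mask, save_stack
from .phantom import (
    NominalADCModel,
    StudyDesign,
    build_phantom_layout,
    default_protocol,
    nominal_adc,
    simulate_study,
)
from .repeatability import (
    aggregate_sessions,
    coefficient_of_variation,
    max_percent_deviation,
    percent_deviation,
)
from .stats import (
    friedman_across_levels,
    percent_difference,
    wasserstein_distance,
    wilcoxon_paired,
)
from .voi import default_voi_specs, extract_adc_sample, make_cylindrical_voi, ADCSample

logger = logging.getLogger("adcphantom")

__all__ = ["StudyResultSet", "run_study", "render_report", "analyze_samples"]

TABLE_NAMES = (
    "features",
    "accuracy",
    "accuracy_repeats",
    "repeatability",
    "wasserstein",
    "friedman",
    "wilcoxon",
    "percent_diff",
)


@dataclass
class StudyResultSet:
    """All result tables of one study run, as tidy DataFrames."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    pooled: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in {**self.tables, **self.pooled}.items():
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            written.append(p)
        mp = outdir / "manifest.json"
        mp.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        written.append(mp)
        return written


def _sorted_df(rows: list[dict], order: list[str]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return df.sort_values(order, kind="mergesort").reset_index(drop=True)


def analyze_samples(
    samples: dict[tuple[str, str, str, str], ADCSample],
    nominal: dict[str, dict[str, float]],
    levels: list[str],
    *,
    sequence: str,
    bin_width: float,
) -> dict[str, pd.DataFrame]:
    """Compute every result table from per-VOI ADC samples.

    ``samples`` is keyed by (vial, session, repeat, level); ``nominal`` maps
    session -> vial -> reference ADC.  The histogram bin grid is shared per
    (vial, session) across all repeats and levels, and the level listed first
    is treated as the no-denoising baseline for the paired comparisons.
    """
    vials = sorted({k[0] for k in samples})
    sessions = sorted({k[1] for k in samples})
    repeats = sorted({k[2] for k in samples}, key=lambda r: (len(r), r))
    baseline = levels[0]

    feat_rows, acc_rows, accr_rows, rep_rows = [], [], [], []
    wd_rows, fr_rows, wx_rows, pd_rows = [], [], [], []
    features: dict[tuple[str, str, str, str], dict[str, float]] = {}

    for vial in vials:
        for session in sessions:
            group = {
                (r, l): samples[(vial, session, r, l)] for r in repeats for l in levels
            }
            spec = build_shared_spec(group.values(), bin_width=bin_width)

            for (r, l), sample in group.items():
                fv = compute_features(sample, spec)
                features[(vial, session, r, l)] = fv.as_dict()
                feat_rows.append(
                    {
                        "sequence": sequence,
                        "vial": vial,
                        "session": session,
                        "repeat": r,
                        "level": l,
                        "n_voxels": len(sample),
                        **fv.as_dict(),
                    }
                )

            # accuracy & repeatability from per-repeat VOI medians
            ref = nominal[session][vial]
            for level in levels:
                medians = [float(np.median(group[(r, level)].values)) for r in repeats]
                for r, m in zip(repeats, medians):
                    accr_rows.append(
                        {
                            "sequence": sequence,
                            "vial": vial,
                            "session": session,
                            "level": level,
                            "repeat": r,
                            "median_adc": m,
                            "deviation_percent": percent_deviation(m, ref),
                        }
                    )
                measured = float(np.mean(medians))
                acc_rows.append(
                    {
                        "sequence": sequence,
                        "vial": vial,
                        "session": session,
                        "level": level,
                        "measured_median": measured,
                        "nominal": ref,
                        "deviation_percent": percent_deviation(measured, ref),
                    }
                )
                neg, pos = max_percent_deviation(medians)
                rep_rows.append(
                    {
                        "sequence": sequence,
                        "vial": vial,
                        "session": session,
                        "level": level,
                        "cv_percent": coefficient_of_variation(medians),
                        "max_dev_percent_neg": neg,
                        "max_dev_percent_pos": pos,
                    }
                )

            # mean histograms per level and distances to baseline
            mean_by_level = {
                l: mean_histogram([compute_histogram(group[(r, l)], spec) for r in repeats])
                for l in levels
            }
            for level in levels[1:]:
                wd_rows.append(
                    {
                        "sequence": sequence,
                        "vial": vial,
                        "session": session,
                        "level": level,
                        "wasserstein": wasserstein_distance(
                            mean_by_level[baseline], mean_by_level[level]
                        ),
                    }
                )

            # Friedman across levels, voxels paired via the shared raw data
            pooled = {
                l: np.concatenate([group[(r, l)].values for r in repeats]) for l in levels
            }
            lengths = {l: v.size for l, v in pooled.items()}
            if len(set(lengths.values())) != 1:
                raise ValueError(f"level samples not paired for {vial}/{session}: {lengths}")
            fr = friedman_across_levels(*[pooled[l] for l in levels])
            fr_rows.append(
                {
                    "sequence": sequence,
                    "vial": vial,
                    "session": session,
                    "statistic": fr.statistic,
                    "p_value": fr.p_value,
                    "degenerate": fr.degenerate,
                }
            )

    # paired feature tests and percent differences (pairs = vial x repeat)
    for session in sessions:
        for level in levels[1:]:
            for feature in FEATURE_NAMES:
                x, y = [], []
                for vial in vials:
                    for r in repeats:
                        fx = features[(vial, session, r, baseline)][feature]
                        fy = features[(vial, session, r, level)][feature]
                        if np.isfinite(fx) and np.isfinite(fy):
                            x.append(fx)
                            y.append(fy)
                        pd_rows.append(
                            {
                                "sequence": sequence,
                                "session": session,
                                "feature": feature,
                                "level": level,
                                "vial": vial,
                                "repeat": r,
                                "percent_difference": percent_difference(fx, fy),
                            }
                        )
                res = wilcoxon_paired(x, y)
                wx_rows.append(
                    {
                        "sequence": sequence,
                        "session": session,
                        "feature": feature,
                        "level": level,
                        "n_pairs": len(x),
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                        "degenerate": res.degenerate,
                    }
                )

    return {
        "features": _sorted_df(feat_rows, ["sequence", "vial", "session", "repeat", "level"]),
        "accuracy": _sorted_df(acc_rows, ["sequence", "vial", "session", "level"]),
        "accuracy_repeats": _sorted_df(
            accr_rows, ["sequence", "vial", "session", "level", "repeat"]
        ),
        "repeatability": _sorted_df(rep_rows, ["sequence", "vial", "session", "level"]),
        "wasserstein": _sorted_df(wd_rows, ["sequence", "vial", "session", "level"]),
        "friedman": _sorted_df(fr_rows, ["sequence", "vial", "session"]),
        "wilcoxon": _sorted_df(wx_rows, ["sequence", "session", "feature", "level"]),
        "percent_diff": _sorted_df(
            pd_rows, ["sequence", "session", "feature", "level", "vial", "repeat"]
        ),
    }


def _design_from_config(config: PipelineConfig) -> StudyDesign:
    return StudyDesign(
        levels=config.levels,
        n_repeats=config.n_repeats,
        sessions=config.sessions,
        base_seed=config.seed,
    )


def run_sequence(
    config: PipelineConfig,
    sequence: str,
    *,
    model: NominalADCModel | None = None,
    outdir: Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Simulate, fit, extract and analyze one sequence in memory."""
    model = model if model is not None else NominalADCModel.default()
    layout = build_phantom_layout(sequence)
    protocol = default_protocol(
        sequence,
        matrix=config.matrix,
        n_slices=config.n_slices,
        pixel_mm=config.pixel_mm,
        noise_sigma=config.noise_sigma,
    )
    design = _design_from_config(config)
    logger.info("[simulate] %s: %d stacks", sequence, len(design.sessions) * design.n_repeats * len(design.levels))
    stacks = simulate_study(design, sequence, layout=layout, protocol=protocol, model=model)

    voi_specs = default_voi_specs(
        layout,
        protocol,
        diameter_fraction=config.voi_diameter_fraction,
        n_slices=config.voi_n_slices,
    )
    masks = {
        s.label: make_cylindrical_voi(s, protocol.shape[:3], protocol.pixel_mm)
        for s in voi_specs
    }

    samples: dict[tuple[str, str, str, str], ADCSample] = {}
    for (session, repeat, level), stack in stacks.items():
        adc_map = fit_adc_map(stack)
        if outdir is not None and config.keep_intermediates:
            save_stack(stack, outdir / sequence / "stacks" / f"{session}_{repeat}_{level}.nii")
            save_adc_map(adc_map, outdir / sequence / "adc" / f"{session}_{repeat}_{level}.nii")
        for label, mask in masks.items():
            samples[(label, session, repeat, level)] = extract_adc_sample(adc_map, mask)

    nominal = {
        session: {
            v.label: nominal_adc(model, v.pvp_fraction, temp) for v in layout.vials
        }
        for session, temp in design.sessions
    }
    if outdir is not None and config.keep_intermediates:
        for label, mask in masks.items():
            save_mask(mask.mask, protocol.pixel_mm, protocol.slice_mm, outdir / sequence / "masks" / f"{label}.nii")

    logger.info("[analyze] %s: %d VOI samples", sequence, len(samples))
    return analyze_samples(
        samples,
        nominal,
        list(design.level_names),
        sequence=sequence,
        bin_width=config.bin_width,
    )


def run_study(config: PipelineConfig, *, write: bool = True) -> StudyResultSet:
    """Run the configured study end to end; optionally write all CSV tables."""
    outdir = Path(config.output_dir)
    logger.info("run_study seed=%d config=%s", config.seed, config.content_hash())
    per_seq = [run_sequence(config, seq, outdir=outdir if write else None) for seq in config.sequences]

    tables: dict[str, pd.DataFrame] = {}
    for name in TABLE_NAMES:
        tables[name] = pd.concat([t[name] for t in per_seq], ignore_index=True)

    pooled: dict[str, pd.DataFrame] = {}
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
        manifest={
            "config": config.to_dict(),
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "version": __version__,
        },
    )
    if write:
        results.write(outdir)
        render_report(results, outdir)
    return results


def render_report(results: StudyResultSet, outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Write feature-trend tables and a Wilcoxon significance matrix.

    Trends are mean feature values across all inserts per level; the
    significance matrix is one row per feature with p-values per
    (sequence, session, level-pair) column, mirroring a heatmap layout.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict[str, pd.DataFrame] = {}

    feats = results.tables.get("features")
    if feats is not None and not feats.empty:
        trends = (
            feats.groupby(["sequence", "session", "level"], sort=True)[list(FEATURE_NAMES)]
            .mean()
            .reset_index()
        )
        trends.to_csv(outdir / "feature_trends.csv", index=False)
        out["feature_trends"] = trends

    wx = results.tables.get("wilcoxon")
    if wx is None or wx.empty:
        logger.info("[report] no feature tests; significance matrix omitted")
    else:
        matrix = wx.pivot_table(
            index="feature",
            columns=["sequence", "session", "level"],
            values="p_value",
        )
        matrix = matrix.reindex(list(FEATURE_NAMES))
        flat = matrix.copy()
        flat.columns = ["_".join(map(str, c)) for c in flat.columns]
        flat.reset_index().to_csv(outdir / "significance_matrix.csv", index=False)
        out["significance_matrix"] = matrix

    lines = ["study summary", "============="]
    acc = results.tables.get("accuracy")
    if acc is not None and not acc.empty:
        lines.append(
            f"accuracy deviation range: {acc.deviation_percent.min():+.2f}% .. "
            f"{acc.deviation_percent.max():+.2f}%"
        )
    rep = results.tables.get("repeatability")
    if rep is not None and not rep.empty:
        lines.append(
            f"CV range: {rep.cv_percent.min():.3f}% .. {rep.cv_percent.max():.3f}%"
        )
    wd = results.tables.get("wasserstein")
    if wd is not None and not wd.empty:
        top = wd.sort_values("wasserstein", ascending=False).iloc[0]
        lines.append(
            f"largest Wasserstein distance: {top.wasserstein:.2f} "
            f"({top.sequence} {top.vial} {top.session} OFF vs {top.level})"
        )
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    return out
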