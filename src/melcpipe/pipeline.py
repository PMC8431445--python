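"""End-to-end orchestration of the pipeline stages.

Stages (``simulate -> correct -> segment -> features -> normalize ->
evaluate -> atlas``) communicate exclusively through files under one output
directory, so any stage can be re-run from its predecessors' artifacts.  A
manifest records the configuration hash, the seed and stage completion; a
hash mismatch between stages aborts rather than silently mixing parameter
sets.  One global seed is fanned out to per-stage seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from melcpipe import io as mio
from melcpipe.atlas import (
    AtlasParams,
    cluster_profile_heatmap,
    composition_summary,
    embed_cells,
    gms_cluster,
)
from melcpipe.cluster_eval import ConsensusSpec, compute_mcs, run_consensus, stability_metrics
from melcpipe.correction import CalibrationImages, MelcCycle, MelcRun, correct_run
from melcpipe.features import build_feature_table
from melcpipe.normalization import (
    NormalizationConfig,
    apply_background_normalization,
    estimate_background_levels,
    nc_ratio_normalize,
)

from melcpipe.segmentation import (
    CellTable,
    LabelMask,
    apply_exclusions,
    reconcile_masks,
    segment_cells,
    segment_nuclei,
)
from melcpipe.synthetic import (
    SceneTruth,
    SyntheticParams,
    default_cell_types,
    default_panel,
    evaluate_recovery,
    make_scene,
    render_run,
)

logger = logging.getLogger(__name__)

STAGES = ["simulate", "correct", "segment", "features", "normalize", "evaluate", "atlas"]


class ValidationError(ValueError):
    """Configuration or input inconsistency detected before processing."""


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the global seed."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _manifest_path(outdir: Path) -> Path:
    return outdir / "manifest.json"


def _load_manifest(outdir: Path, config: dict) -> dict:
    path = _manifest_path(outdir)
    h = config_hash(config)
    if path.exists():
        manifest = json.loads(path.read_text())
        if manifest["config_hash"] != h:
            raise ValidationError(
                "config hash mismatch with existing output directory "
                f"({manifest['config_hash']} != {h}); refusing to mix parameter sets"
            )
        return manifest
    size = int(config.get("synthetic", {}).get("image_size", 512))
    px = float(config.get("synthetic", {}).get("pixel_size_um", 0.45))
    return {
        "config_hash": h,
        "seed": int(config.get("seed", 0)),
        "image_size_px": size,
        "pixel_size_um": px,
        "fov_physical_size_um": size * px,
        "stages": {},
    }


def _save_manifest(outdir: Path, manifest: dict, stage: str, info: dict | None = None) -> None:
    manifest["stages"][stage] = {"done": True, **(info or {})}
    _manifest_path(outdir).write_text(json.dumps(manifest, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# stage: simulate


def stage_simulate(config: dict, outdir: Path) -> SceneTruth:
    manifest = _load_manifest(outdir, config)
    syn = dict(config.get("synthetic", {}))
    n_cells = int(syn.pop("n_cells", 400))
    nc_pairs = syn.pop("nc_pairs", {"GD2": "NC1"})
    seed = stage_seed(int(config.get("seed", 0)), "simulate")
    params = SyntheticParams(seed=seed, **syn)
    types = default_cell_types()
    scene = make_scene(n_cells, types, [1.0 / len(types)] * len(types), params)
    panel = default_panel(scene, nc_pairs=nc_pairs)
    run = render_run(
        scene,
        panel,
        sample_id=config.get("sample_id", "synthetic"),
        fov_id=config.get("fov_id", "fov1"),
    )

    img_dir = outdir / "images"
    for cyc in run.cycles:
        base = f"{run.sample_id}_{run.fov_id}_c{cyc.index:02d}"
        mio.write_image(img_dir / f"{base}_tag.tif", cyc.tag_image)
        mio.write_image(img_dir / f"{base}_bleach.tif", cyc.postbleach_image)
        mio.write_image(img_dir / f"{base}_phase.tif", cyc.phase_image)
    mio.write_image(img_dir / "brightfield.tif", run.calibration.brightfield)
    mio.write_image(img_dir / "darkframe.tif", run.calibration.darkframe)

    cycles_meta = [
        {
            "index": c.index,
            "marker": c.marker,
            "is_negative_control": c.is_negative_control,
            "nc_partner": c.nc_partner,
        }
        for c in run.cycles
    ]
    mio.save_yaml(
        outdir / "run_meta.yaml",
        {
            "sample_id": run.sample_id,
            "fov_id": run.fov_id,
            "pixel_size_um": run.pixel_size_um,
            "cycles": cycles_meta,
        },
    )

    truth_dir = outdir / "truth"
    mio.write_label_mask(truth_dir / "nucleus_mask.tif", scene.true_nucleus_mask.labels)
    mio.write_label_mask(truth_dir / "cell_mask.tif", scene.true_cell_mask.labels)
    pd.DataFrame(
        {
            "cell_label": np.arange(1, scene.n_cells + 1),
            "x": scene.centers[:, 0] if scene.n_cells else [],
            "y": scene.centers[:, 1] if scene.n_cells else [],
            "type": scene.type_labels,
            "unspecific_factor": scene.unspecific_factors,
        }
    ).to_csv(truth_dir / "cells.csv", index=False)
    scene.true_expression.to_csv(truth_dir / "expression.csv")
    mio.save_yaml(truth_dir / "params.yaml", asdict(params))

    _save_manifest(outdir, manifest, "simulate", {"n_cells": scene.n_cells})
    return scene


def load_run(outdir: Path) -> MelcRun:
    meta = mio.load_yaml(outdir / "run_meta.yaml")
    img_dir = outdir / "images"
    cycles = []
    for c in meta["cycles"]:
        base = f"{meta['sample_id']}_{meta['fov_id']}_c{c['index']:02d}"
        cycles.append(
            MelcCycle(
                index=c["index"],
                marker=c["marker"],
                tag_image=mio.read_image(img_dir / f"{base}_tag.tif"),
                postbleach_image=mio.read_image(img_dir / f"{base}_bleach.tif"),
                phase_image=mio.read_image(img_dir / f"{base}_phase.tif"),
                is_negative_control=bool(c["is_negative_control"]),
                nc_partner=c["nc_partner"],
            )
        )
    calibration = CalibrationImages(
        brightfield=mio.read_image(img_dir / "brightfield.tif"),
        darkframe=mio.read_image(img_dir / "darkframe.tif"),
    )
    return MelcRun(
        cycles=cycles,
        calibration=calibration,
        pixel_size_um=float(meta["pixel_size_um"]),
        sample_id=meta["sample_id"],
        fov_id=meta["fov_id"],
    )


def load_scene(outdir: Path) -> SceneTruth:
    truth_dir = outdir / "truth"
    cells = pd.read_csv(truth_dir / "cells.csv")
    expression = pd.read_csv(truth_dir / "expression.csv", index_col=0)
    params = SyntheticParams(**mio.load_yaml(truth_dir / "params.yaml"))
    return SceneTruth(
        centers=cells[["x", "y"]].to_numpy() if len(cells) else np.empty((0, 2)),
        type_labels=list(cells["type"]),
        true_nucleus_mask=LabelMask(mio.read_label_mask(truth_dir / "nucleus_mask.tif")),
        true_cell_mask=LabelMask(mio.read_label_mask(truth_dir / "cell_mask.tif")),
        true_expression=expression,
        unspecific_factors=cells["unspecific_factor"].to_numpy(),
        params=params,
    )


# ---------------------------------------------------------------------------
# stage: correct


def stage_correct(config: dict, outdir: Path) -> MelcRun:
    manifest = _load_manifest(outdir, config)
    corr = dict(config.get("correction", {}))
    run = load_run(outdir)
    if corr.get("flat_field", True) and run.calibration is None:
        raise ValidationError("flat-field correction enabled but no calibration images")
    corrected, report = correct_run(
        run,
        register=corr.get("register", True),
        reference_cycle=int(corr.get("reference_cycle", 1)),
        max_shift=float(corr.get("max_shift", 50.0)),
        flat_field=corr.get("flat_field", True),
        vignetting=corr.get("vignetting", True),
        smoothing_scale=float(corr.get("smoothing_scale", 50.0)),
        min_images=int(corr.get("min_images", 8)),
    )
    cdir = outdir / "corrected"
    for cyc in corrected.cycles:
        mio.write_image(cdir / f"c{cyc.index:02d}_{_safe(cyc.marker)}.tif", cyc.tag_image)
        mio.write_image(cdir / f"c{cyc.index:02d}_{_safe(cyc.marker)}_phase.tif", cyc.phase_image)
    if report["shifts"] is not None:
        pd.DataFrame(report["shifts"]).to_csv(cdir / "shifts.csv", index=False)
    if report["gain"] is not None:
        mio.write_image(cdir / "gain.tif", report["gain"].gain)
    _save_manifest(outdir, manifest, "correct")
    return corrected


def _safe(marker: str) -> str:
    return marker.replace("/", "_")


def load_corrected(outdir: Path) -> MelcRun:
    meta = mio.load_yaml(outdir / "run_meta.yaml")
    cdir = outdir / "corrected"
    cycles = []
    for c in meta["cycles"]:
        tag_path = cdir / f"c{c['index']:02d}_{_safe(c['marker'])}.tif"
        if not tag_path.exists():  # cycle dropped during registration
            continue
        tag = mio.read_image(tag_path)
        cycles.append(
            MelcCycle(
                index=c["index"],
                marker=c["marker"],
                tag_image=tag,
                postbleach_image=np.zeros_like(tag),  # consumed during correction
                phase_image=mio.read_image(
                    cdir / f"c{c['index']:02d}_{_safe(c['marker'])}_phase.tif"
                ),
                is_negative_control=bool(c["is_negative_control"]),
                nc_partner=c["nc_partner"],
            )
        )
    return MelcRun(
        cycles=cycles,
        calibration=None,
        pixel_size_um=float(meta["pixel_size_um"]),
        sample_id=meta["sample_id"],
        fov_id=meta["fov_id"],
    )


# ---------------------------------------------------------------------------
# stage: segment


def stage_segment(config: dict, outdir: Path) -> CellTable:
    manifest = _load_manifest(outdir, config)
    seg = config.get("segmentation", {})
    run = load_corrected(outdir)
    nuclear_marker = config.get("nuclear_marker", "PI")
    pi_cycle = run.cycle_for(nuclear_marker)

    ext_nuc = seg.get("nucleus_mask_file")
    ext_cell = seg.get("cell_mask_file")
    if ext_nuc:
        nuc_mask = LabelMask(mio.read_label_mask(ext_nuc))
    else:
        nuc_mask = segment_nuclei(pi_cycle.tag_image, **seg.get("nucleus", {}))
    if ext_cell:
        cell_mask = LabelMask(mio.read_label_mask(ext_cell))
    else:
        cell_mask = segment_cells(pi_cycle.phase_image, **seg.get("cell", {}))

    table = reconcile_masks(cell_mask, nuc_mask)
    regions = seg.get("exclusion_regions") or []
    if isinstance(regions, str):
        regions = json.loads(Path(regions).read_text())
    table = apply_exclusions(table, [[tuple(p) for p in poly] for poly in regions])

    mdir = outdir / "masks"
    mio.write_label_mask(mdir / "nucleus_labels.tif", nuc_mask.labels)
    mio.write_label_mask(mdir / "cell_labels.tif", cell_mask.labels)
    table.records.to_csv(mdir / "cell_table.csv", index=False)
    _save_manifest(
        outdir,
        manifest,
        "segment",
        {
            "n_cells": len(table),
            "n_cells_dropped": table.n_cells_dropped,
            "n_nuclei_unassigned": table.n_nuclei_unassigned,
        },
    )
    return table


def load_cell_table(outdir: Path) -> CellTable:
    mdir = outdir / "masks"
    return CellTable(
        records=pd.read_csv(mdir / "cell_table.csv"),
        cell_mask=mio.read_label_mask(mdir / "cell_labels.tif"),
        nucleus_mask=mio.read_label_mask(mdir / "nucleus_labels.tif"),
    )


# ---------------------------------------------------------------------------
# stage: features


def stage_features(config: dict, outdir: Path) -> pd.DataFrame:
    manifest = _load_manifest(outdir, config)
    run = load_corrected(outdir)
    table = load_cell_table(outdir)
    features = build_feature_table(run, table)
    features.to_csv(outdir / "features.csv", index=False)
    _save_manifest(outdir, manifest, "features", {"n_columns": features.shape[1]})
    return features


# ---------------------------------------------------------------------------
# stage: normalize


def _norm_config(config: dict, outdir: Path) -> NormalizationConfig:
    norm = dict(config.get("normalization", {}))
    nc_pairs = norm.get("nc_pairs")
    if nc_pairs is None:  # derive from acquisition metadata
        meta = mio.load_yaml(outdir / "run_meta.yaml")
        nc_pairs = {
            c["marker"]: c["nc_partner"] for c in meta["cycles"] if c.get("nc_partner")
        }
    return NormalizationConfig(
        nc_pairs=nc_pairs,
        exclusive_pairs=norm.get("exclusive_pairs", {}),
        q_counterpart=float(norm.get("q_counterpart", 0.8)),
        q_background=float(norm.get("q_background", 0.95)),
        reference_stat=norm.get("reference_stat", "M20"),
        reference_compartment=norm.get("reference_compartment", "cytomem"),
        min_reference_cells=int(norm.get("min_reference_cells", 20)),
    )


def stage_normalize(config: dict, outdir: Path) -> pd.DataFrame:
    manifest = _load_manifest(outdir, config)
    features = pd.read_csv(outdir / "features.csv")
    ncfg = _norm_config(config, outdir)
    normalized = nc_ratio_normalize(features, ncfg)
    if ncfg.exclusive_pairs:
        levels = estimate_background_levels(normalized, ncfg)
        normalized = apply_background_normalization(normalized, levels)
        levels.levels.to_csv(outdir / "background_levels.csv", index=False)
    normalized.to_csv(outdir / "features_normalized.csv", index=False)
    mio.write_fcs(outdir / "features_normalized.fcs", normalized)
    _save_manifest(outdir, manifest, "normalize")
    return normalized


# ---------------------------------------------------------------------------
# stage: evaluate (consensus stability of feature variants)


def stage_evaluate(config: dict, outdir: Path) -> dict:
    manifest = _load_manifest(outdir, config)
    ev = config.get("evaluation", {})
    features = pd.read_csv(outdir / "features_normalized.csv")
    seed = stage_seed(int(config.get("seed", 0)), "evaluate")
    report = {}
    for variant in ev.get("variants", ["I", "V"]):
        spec = ConsensusSpec(
            feature_variant=variant,
            n_repeats=int(ev.get("n_repeats", 20)),
            subsample_rate=float(ev.get("subsample_rate", 0.8)),
            n_clusters=int(ev.get("n_clusters", 10)),
            perplexity=float(ev.get("perplexity", 30.0)),
            seed=seed,
        )
        result = run_consensus(features, spec)
        metrics = stability_metrics(result, spec)
        report[variant] = {
            "PAC": metrics.pac,
            "CON": metrics.con,
            "MSS": metrics.mss,
            "MCS": compute_mcs(metrics),
            "n_repeats": spec.n_repeats,
            "n_clusters": spec.n_clusters,
            "seed": spec.seed,
        }
        np.savetxt(
            outdir / f"consensus_{variant}.csv.gz", result.consensus_matrix, delimiter=","
        )
    (outdir / "stability.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    _save_manifest(outdir, manifest, "evaluate")
    return report


# ---------------------------------------------------------------------------
# stage: atlas


def stage_atlas(config: dict, outdir: Path) -> pd.DataFrame:
    manifest = _load_manifest(outdir, config)
    at = config.get("atlas", {})
    features = pd.read_csv(outdir / "features_normalized.csv")
    seed = stage_seed(int(config.get("seed", 0)), "atlas")
    params = AtlasParams(
        perplexity=float(at.get("perplexity", 30.0)),
        gms_bandwidth=at.get("gms_bandwidth"),
        mode_merge_tol=at.get("mode_merge_tol"),
        n_subclusters=int(at.get("n_subclusters", 30)),
        seed=seed,
    )
    emb = embed_cells(features, params)
    labels = gms_cluster(emb, params)
    out = pd.DataFrame(
        {
            "cell_id": features["cell_id"],
            "sample_id": features["sample_id"],
            "tsne_1": emb[:, 0],
            "tsne_2": emb[:, 1],
            "cluster": labels,
        }
    )
    out.to_csv(outdir / "atlas.csv", index=False)
    heat = cluster_profile_heatmap(features, labels)
    heat.to_csv(outdir / "cluster_profiles.csv")
    comp = composition_summary(labels, features["sample_id"].to_numpy())
    comp.to_csv(outdir / "composition.csv", index=False)
    mio.write_fcs(outdir / "atlas.fcs", pd.concat([features.select_dtypes("number"), out[["cluster"]]], axis=1))
    _save_manifest(outdir, manifest, "atlas", {"n_clusters": int(labels.max())})
    return out


def stage_recovery(config: dict, outdir: Path) -> dict:
    """Score the pipeline against the simulated ground truth, if present."""
    manifest = _load_manifest(outdir, config)
    scene = load_scene(outdir)
    table = load_cell_table(outdir)
    atlas = pd.read_csv(outdir / "atlas.csv")
    features = pd.read_csv(outdir / "features_normalized.csv")
    report = evaluate_recovery(
        scene,
        cell_table=table,
        cluster_labels=atlas["cluster"].to_numpy(),
        feature_table=features,
    )
    (outdir / "recovery.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    _save_manifest(outdir, manifest, "recovery")
    return report


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run every stage in order; returns the recovery report (if simulated)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_simulate(config, outdir)
    stage_correct(config, outdir)
    stage_segment(config, outdir)
    stage_features(config, outdir)
    stage_normalize(config, outdir)
    if config.get("evaluation", {}).get("enabled", False):
        stage_evaluate(config, outdir)
    stage_atlas(config, outdir)
    return stage_recovery(config, outdir)
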