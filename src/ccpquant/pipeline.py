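"""End-to-end orchestration: simulate/load -> detect -> track -> report.

Three entry points mirror the three experiment shapes:

* :func:`run_movie_analysis` — live-cell movies per condition: per-frame
  master detection, dependent slave measurement, linking, classification,
  lifetime/persistence/slave-positivity statistics, cohort traces and a
  condition-vs-condition Welch comparison;
* :func:`run_if_analysis` — fixed-cell stills: detection, slave measurement,
  per-cell PCC and the proportion-vs-intensity curve;
* :func:`run_binding_suite` — a folder of titration CSVs, each fit with the
  model its columns identify.

All intermediate artifacts are persisted as CSV, reports as JSON, and every
report carries a provenance block (config hash, seed, package version) so a
run regenerates identically from its configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bindingfit, colocalization, detection, synthgen, trackstats

__all__ = [
    "load_config",
    "config_hash",
    "run_movie_analysis",
    "run_if_analysis",
    "run_binding_suite",
    "analyze_movie_cell",
]

log = logging.getLogger("ccpquant")

DEFAULT_PIXEL_SIZE_UM = 0.0645  # 6.45 um camera pixel at 100x

DEFAULT_COHORT_BOUNDS = [(10.0, 20.0), (20.0, 40.0), (40.0, 60.0), (60.0, 120.0)]


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _jsonsafe(obj):
    """Recursively replace non-finite floats with None (strict JSON)."""
    if isinstance(obj, dict):
        return {k: _jsonsafe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonsafe(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _provenance(config: dict, seed: int) -> dict:
    from . import __version__
    return {"config_hash": config_hash(config), "seed": seed,
            "ccpquant_version": __version__}


def _detection_config(config: dict) -> detection.DetectionConfig:
    cfg = detection.DetectionConfig(**config.get("detection", {}))
    cfg.validate()
    return cfg


def analyze_movie_cell(stacks: dict[str, synthgen.FrameStack],
                       det_cfg: detection.DetectionConfig,
                       tracking: dict | None = None,
                       classification: dict | None = None,
                       pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                       noise_sd: float | None = None,
                       ) -> tuple[pd.DataFrame, list[trackstats.Track], dict]:
    """Analyze one cell's movie: detect, measure slaves, link, classify.

    Returns the detections table, the classified tracks, and a per-cell
    summary row.  ``noise_sd`` (per-pixel, at background) sets the bona fide
    intensity threshold as ``threshold_snr * noise_sd``; if None it is
    estimated from the median residual noise of the detections.
    """
    tracking = dict(tracking or {})
    classification = dict(classification or {})
    master = stacks["master"]
    slave = stacks.get("slave")
    n_frames = master.n_frames

    rows = []
    n_insig = 0
    for f in range(n_frames):
        masters = detection.detect_frame(master.data[f], det_cfg, frame_index=f,
                                         keep_insignificant=True)
        sig_masters = [d for d in masters if d.significant and d.valid]
        n_insig += len(masters) - len(sig_masters)
        slaves = (detection.measure_slave(sig_masters, slave.data[f], det_cfg,
                                          master_frame_shape=master.data[f].shape)
                  if slave is not None else None)
        for i, d in enumerate(sig_masters):
            row = {"frame": f, "x": d.x, "y": d.y, "amplitude": d.amplitude,
                   "background": d.background, "noise_sd": d.residual_noise_sd,
                   "p_value": d.p_value, "significant": d.significant}
            if slaves is not None:
                s = slaves[i]
                row["slave_amplitude"] = s.amplitude
                row["slave_significant"] = s.significant and s.valid
                row["slave_p_value"] = s.p_value
            rows.append(row)
    det_table = pd.DataFrame(rows)
    log.info("detections: %d significant kept, %d insignificant rejected",
             len(det_table), n_insig)

    extra = ("slave",) if slave is not None and len(det_table) else ()
    tracks = trackstats.link(
        det_table if len(det_table) else pd.DataFrame(
            columns=["frame", "x", "y", "amplitude"]),
        max_displacement=tracking.get("max_displacement", 3.0),
        max_gap=tracking.get("max_gap", 2),
        frame_interval=master.frame_interval,
        extra_channels=extra,
    )

    if noise_sd is None:
        noise_sd = float(det_table["noise_sd"].median()) if len(det_table) else 1.0
    threshold = classification.get(
        "intensity_threshold",
        classification.get("threshold_snr", 5.0) * noise_sd)
    trackstats.classify(tracks, n_frames, threshold,
                        min_frames=classification.get("min_frames", 4))

    min_frac = classification.get("min_significant_fraction", 0.3)
    for t in tracks:
        if "slave" in t.significant:
            trackstats.slave_positivity(t, min_frac)

    area_um2 = (master.data.shape[2] * pixel_size_um) * (
        master.data.shape[1] * pixel_size_um)
    n_bona = sum(t.category == "bona_fide" for t in tracks)
    n_pers = sum(t.category == "persistent" for t in tracks)
    with_slave = [t for t in tracks if t.slave_positive is not None]
    summary = {
        "n_tracks": len(tracks),
        "n_bona_fide": n_bona,
        "n_transient": sum(t.category == "transient" for t in tracks),
        "n_persistent": n_pers,
        "persistent_density_per_um2": trackstats.persistent_density(tracks, area_um2),
        "area_um2": area_um2,
        "slave_positive_pct": (100.0 * np.mean([t.slave_positive for t in with_slave])
                               if with_slave else np.nan),
    }
    bona = [t for t in tracks if t.category == "bona_fide"]
    if len(bona) >= 20:
        ls = trackstats.lifetime_stats(tracks)
        summary["mean_lifetime_s"] = ls.mean_s
        summary["p95_mean_lifetime_s"] = ls.p95_mean_s
    else:
        summary["mean_lifetime_s"] = np.nan
        summary["p95_mean_lifetime_s"] = np.nan
    return det_table, tracks, summary


def run_movie_analysis(config: dict, out_dir) -> dict:
    """Run the full movie pipeline for every condition/cell in the config.

    ``config["conditions"]`` maps condition names to movie-spec overrides;
    ``config["n_cells"]`` movies are simulated per condition (seeded
    deterministically from ``config["seed"]``), or per-condition
    ``inputs`` lists of ``{master: path, slave: path}`` are loaded instead.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    det_cfg = _detection_config(config)
    base_sim = dict(config.get("simulation", {}))
    n_cells = int(config.get("n_cells", 3))
    pixel = float(config.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM))
    cohort_bounds = [tuple(b) for b in config.get("cohort_bounds",
                                                  DEFAULT_COHORT_BOUNDS)]

    per_cell = []
    cohorts_rows = []
    for ci, (cond, overrides) in enumerate(config.get(
            "conditions", {"control": {}}).items()):
        inputs = (overrides or {}).pop("inputs", None) if isinstance(
            overrides, dict) else None
        for cell in range(n_cells if inputs is None else len(inputs)):
            cell_id = f"{cond}_{cell:02d}"
            log.info("stage=simulate/load cell=%s", cell_id)
            if inputs is None:
                spec = synthgen.MovieSpec(**{**base_sim, **(overrides or {})},
                                          seed=seed + 1000 * ci + cell)
                stacks, _ = synthgen.generate_movie(spec)
                noise_sd = spec.noise_sd
            else:
                entry = inputs[cell]
                fi = float(entry.get("frame_interval", 2.0))
                stacks = {"master": synthgen.read_movie(entry["master"], fi)}
                if "slave" in entry:
                    stacks["slave"] = synthgen.read_movie(entry["slave"], fi,
                                                          "slave")
                noise_sd = None
            try:
                det_table, tracks, summary = analyze_movie_cell(
                    stacks, det_cfg, config.get("tracking"),
                    config.get("classification"), pixel, noise_sd)
            except Exception as exc:
                raise RuntimeError(
                    f"stage=analyze cell={cell_id} failed: {exc}") from exc
            det_table.to_csv(out / f"detections_{cell_id}.csv", index=False)
            trackstats.tracks_to_frame(tracks).to_csv(
                out / f"tracks_{cell_id}.csv", index=False)
            summary.update({"condition": cond, "cell_id": cell_id})
            per_cell.append(summary)
            channels = ("master", "slave") if "slave" in stacks else ("master",)
            for cs in trackstats.cohort_traces(
                    [t for t in tracks if t.category == "bona_fide"],
                    cohort_bounds, channels=channels):
                for ch in cs.mean:
                    for i, tt in enumerate(cs.time_axis):
                        cohorts_rows.append({
                            "condition": cond, "cell_id": cell_id,
                            "cohort_lo_s": cs.lifetime_range[0],
                            "cohort_hi_s": cs.lifetime_range[1],
                            "n_tracks": cs.n_tracks, "channel": ch,
                            "t_norm": tt, "mean": cs.mean[ch][i],
                            "se": cs.se[ch][i],
                        })

    cells = pd.DataFrame(per_cell)
    cells.to_csv(out / "per_cell_summary.csv", index=False)
    if cohorts_rows:
        pd.DataFrame(cohorts_rows).to_csv(out / "cohort_traces.csv", index=False)

    report = {"provenance": _provenance(config, seed), "conditions": {}}
    metrics = ["persistent_density_per_um2", "slave_positive_pct",
               "mean_lifetime_s", "p95_mean_lifetime_s", "n_bona_fide"]
    for cond, grp in cells.groupby("condition"):
        report["conditions"][cond] = {
            m: {"mean": float(np.nanmean(grp[m])),
                "sd": float(np.nanstd(grp[m], ddof=1)) if len(grp) > 1 else 0.0,
                "n": int(grp[m].notna().sum())}
            for m in metrics
        }
    names = list(cells["condition"].unique())
    if len(names) >= 2:
        a = cells[cells["condition"] == names[0]]
        b = cells[cells["condition"] == names[1]]
        tests = {}
        for m in metrics:
            av, bv = a[m].dropna(), b[m].dropna()
            if len(av) >= 2 and len(bv) >= 2:
                tests[m] = colocalization.summarize_condition(av, bv)
        report["t_tests"] = {f"{names[0]}_vs_{names[1]}": tests}
    report = _jsonsafe(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def run_if_analysis(config: dict, out_dir) -> dict:
    """Fixed-cell still-image pipeline: detection, PCC, proportion curves."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    det_cfg = _detection_config(config)
    sim = dict(config.get("if_simulation", {}))
    n_cells = int(config.get("n_cells", 3))
    n_bins = int(config.get("n_bins", 10))

    per_cell = []
    curves = []
    for cell in range(n_cells):
        cell_id = f"cell_{cell:02d}"
        images, _ = synthgen.generate_if_image(seed=seed + cell, **sim)
        masters = detection.detect_frame(images["master"], det_cfg)
        row = {"cell_id": cell_id, "n_detections": len(masters)}
        for ch, img in images.items():
            if ch == "master":
                continue
            slaves = detection.measure_slave(masters, img, det_cfg, channel=ch,
                                             master_frame_shape=images["master"].shape)
            paired = colocalization.PairedMeasurements(
                [m.amplitude for m in masters],
                [s.amplitude for s in slaves],
                [s.significant and s.valid for s in slaves],
            )
            if len(paired) >= 2:
                try:
                    row[f"pcc_{ch}"] = colocalization.pearson(paired)
                except ValueError:
                    row[f"pcc_{ch}"] = np.nan
            if len(paired) >= 5 * n_bins:
                curve = colocalization.proportion_curve(paired, n_bins)
                cf = curve.to_frame()
                cf.insert(0, "channel", ch)
                cf.insert(0, "cell_id", cell_id)
                curves.append(cf)
                row[f"proportion_{ch}"] = float(curve.proportion_positive.mean())
        per_cell.append(row)

    cells = pd.DataFrame(per_cell)
    cells.to_csv(out / "if_per_cell.csv", index=False)
    if curves:
        pd.concat(curves).to_csv(out / "if_proportion_curves.csv", index=False)
    report = _jsonsafe({"provenance": _provenance(config, seed),
                        "per_cell": cells.to_dict(orient="records")})
    with open(out / "if_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _infer_titration_kind(df: pd.DataFrame) -> str:
    if "ligand_uM" in df.columns:
        return "anisotropy"
    if "time_s" in df.columns:
        return "spr_dissociation"
    if "injection_index" in df.columns:
        return "itc"
    raise ValueError("cannot infer titration kind from columns "
                     f"{list(df.columns)}")


def run_binding_suite(config: dict, out_dir) -> dict:
    """Fit every titration CSV in ``config['titration_dir']``.

    The x-column name identifies the model: ligand_uM -> anisotropy,
    time_s -> SPR biexponential dissociation, injection_index -> ITC (the
    ITC design must accompany the file in the config under ``itc_design``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    folder = Path(config["titration_dir"])
    results = {}
    for path in sorted(folder.glob("*.csv")):
        df = pd.read_csv(path)
        kind = _infer_titration_kind(df)
        if kind == "anisotropy":
            fit = bindingfit.fit_anisotropy(df["ligand_uM"], df["anisotropy"])
        elif kind == "spr_dissociation":
            fit = bindingfit.fit_dissociation(df["time_s"], df["response_RU"])
        else:
            design = config.get("itc_design", {})
            exp = bindingfit.ITCExperiment(
                cell_conc_M=design.get("cell_conc_M", 125e-6),
                syringe_conc_M=design.get("syringe_conc_M", 2.5e-3),
                cell_volume_L=design.get("cell_volume_L", 170e-6),
                injection_volumes_L=np.full(len(df), design.get(
                    "injection_volume_L", 2.43e-6)),
                heats_J=df["heat_uJ"].to_numpy() * 1e-6,
            )
            fit = bindingfit.fit_itc(exp)
        results[path.stem] = json.loads(fit.to_json())
    report = {"provenance": _provenance(config, int(config.get("seed", 0))),
              "fits": results}
    with open(out / "binding_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
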