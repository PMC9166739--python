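"""Pipeline orchestration: configuration, staging, provenance.

Stages run in the fixed order

    simulate -> detect -> quantify -> population -> associate -> proteome

and any contiguous subset can be requested.  Every artifact directory
gets a per-stage provenance JSON (parameters, seed, package version) from
which the stage can be reproduced exactly; all randomness flows from one
master seed split deterministically per stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import AssociationParams, PointSet, association_test
from .detection import DetectionParams, detect_frame
from .frames import ImageFrame
from .population import (classify_quadrants, estimate_gates, frame_proportions)
from .proteome import ScreenParams, screen
from .quantification import QuantParams, measure_event, read_cytofile, write_cytofile
from .synthetic import PeptideSpec, SceneSpec, make_peptide_table, make_point_sets, write_scene

__all__ = ["RunConfig", "run_pipeline", "STAGES", "PipelineError"]

STAGES = ["simulate", "detect", "quantify", "population", "associate", "proteome"]

log = logging.getLogger("synaptoscope")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """One reproducible run: paths, per-stage parameters, master seed."""

    out_dir: str = "synaptoscope_run"
    seed: int = 0
    n_frames: int = 4
    scene: dict = field(default_factory=dict)       # SceneSpec overrides
    points: dict = field(default_factory=lambda: {
        "n_A": 100, "n_B": 100, "field_um": (200.0, 200.0),
        "paired_fraction": 0.3, "offset_um": 0.3})
    peptides: dict = field(default_factory=dict)    # PeptideSpec overrides
    detection: dict = field(default_factory=dict)   # DetectionParams overrides
    quantification: dict = field(default_factory=dict)  # QuantParams overrides
    gates: dict | str = "auto"                      # or {channel: threshold}
    association: dict = field(default_factory=dict)  # AssociationParams overrides
    screen: dict = field(default_factory=dict)      # ScreenParams overrides
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage_seed(master: int, stage: str) -> int:
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=master, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _provenance(out: Path, stage: str, params: dict, seed: int,
                extra: dict | None = None) -> None:
    payload = {"stage": stage, "params": params, "seed": seed,
               "version": __version__}
    if extra:
        payload.update(extra)
    with open(out / f"provenance_{stage}.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, default=str)


def _as_tuple_fields(d: dict, keys: tuple[str, ...]) -> dict:
    out = dict(d)
    for k in keys:
        if k in out and isinstance(out[k], list):
            out[k] = tuple(out[k])
    return out


def _scene_spec(config: RunConfig, seed: int) -> SceneSpec:
    over = _as_tuple_fields(config.scene, ("field_px", "offset_um", "background"))
    if "intensity_law" in over:
        over["intensity_law"] = {k: tuple(v) for k, v in over["intensity_law"].items()}
    if "counts" in over:
        over["counts"] = dict(over["counts"])
    return SceneSpec(seed=seed, **over)


def stage_simulate(config: RunConfig, out: Path) -> None:
    seed = _stage_seed(config.seed, "simulate")
    frames_dir = out / "frames"
    truth_dir = out / "truth"
    frames_dir.mkdir(parents=True, exist_ok=True)
    truth_dir.mkdir(parents=True, exist_ok=True)
    for i in range(config.n_frames):
        spec = _scene_spec(config, seed + i)
        write_scene(spec, frames_dir / f"scene_{i:03d}.tif",
                    truth_dir / f"scene_{i:03d}.csv")
    log.info("simulate: wrote %d frames", config.n_frames)

    pts = _as_tuple_fields(config.points, ("field_um",))
    A, B = make_point_sets(seed=seed + 1000, **pts)
    for ps, name in ((A, "points_A.csv"), (B, "points_B.csv")):
        pd.DataFrame(ps.points, columns=["x_um", "y_um"]).to_csv(
            out / name, index=False)
    (out / "points_meta.json").write_text(
        json.dumps({"field_um": list(A.field_um), **config.points},
                   default=str), encoding="utf-8")

    pep_spec = PeptideSpec(seed=seed + 2000,
                           **_as_tuple_fields(config.peptides,
                                              ("peptides_per_protein",)))
    table, truth = make_peptide_table(pep_spec)
    table.to_csv(out / "peptides.csv", index=False)
    truth.to_csv(out / "peptide_truth.csv")
    _provenance(out, "simulate",
                {"scene": config.scene, "n_frames": config.n_frames,
                 "points": config.points, "peptides": config.peptides},
                seed)


def stage_detect(config: RunConfig, out: Path) -> None:
    det = DetectionParams(**config.detection)
    quant = QuantParams(**config.quantification)
    rows = []
    tiffs = sorted((out / "frames").glob("*.tif"))
    if not tiffs:
        raise PipelineError("detect: no frames found; run simulate first or "
                            "point the config at existing TIFFs")
    counts = {"accepted": 0, "rejected_border": 0, "rejected_competing": 0}
    for path in tiffs:
        frame = ImageFrame.from_tiff(path)
        events, _ = detect_frame(frame, det, outer_radius_px=quant.doughnut_outer_px)
        for j, e in enumerate(events):
            counts[e.qc_status] += 1
            rows.append({"frame_id": frame.frame_id, "event_id": j,
                         "x_px": e.x_px, "y_px": e.y_px,
                         "peak_value": e.merged_peak_value,
                         "qc_status": e.qc_status})
    pd.DataFrame(rows, columns=["frame_id", "event_id", "x_px", "y_px",
                                "peak_value", "qc_status"]).to_csv(
        out / "candidates.csv", index=False)
    log.info("detect: %d maxima (%s)", len(rows), counts)
    _provenance(out, "detect", dataclasses.asdict(det),
                _stage_seed(config.seed, "detect"), {"counts": counts})


def stage_quantify(config: RunConfig, out: Path) -> None:
    from .detection import CandidateEvent
    quant = QuantParams(**config.quantification)
    cand = pd.read_csv(out / "candidates.csv")
    measurements = []
    pixel_size = None
    channel_order = None
    for path in sorted((out / "frames").glob("*.tif")):
        frame = ImageFrame.from_tiff(path)
        pixel_size = frame.pixel_size_um
        channel_order = frame.channel_names
        sub = cand[(cand["frame_id"] == frame.frame_id)
                   & (cand["qc_status"] == "accepted")]
        for row in sub.itertuples():
            ev = CandidateEvent(row.x_px, row.y_px, row.peak_value, row.qc_status)
            measurements.append(measure_event(frame, ev, event_id=row.event_id,
                                              params=quant))
    if pixel_size is None:
        raise PipelineError("quantify: no frames found")
    write_cytofile(measurements, out / "Pooled_CytoFile.csv", pixel_size,
                   channel_order)
    (out / "Pooled_CytoFile.params.json").write_text(
        json.dumps({**dataclasses.asdict(quant), "pixel_size_um": pixel_size,
                    "channels": channel_order}), encoding="utf-8")
    log.info("quantify: %d events measured", len(measurements))
    _provenance(out, "quantify", dataclasses.asdict(quant),
                _stage_seed(config.seed, "quantify"),
                {"n_events": len(measurements)})


def stage_population(config: RunConfig, out: Path) -> None:
    df = read_cytofile(out / "Pooled_CytoFile.csv")
    if isinstance(config.gates, dict):
        gates = estimate_gates(
            {c: df[c].to_numpy() for c in ("intensity_ch1", "intensity_ch2")},
            overrides={k: float(v) for k, v in config.gates.items()})
    else:
        gates = estimate_gates(
            {c: df[c].to_numpy() for c in ("intensity_ch1", "intensity_ch2")})
    counts = classify_quadrants(df, gates)
    summary = frame_proportions(counts)
    summary.frame_percentages.to_csv(out / "population_frames.csv")
    headline = {
        "gates": gates.thresholds, "gate_method": gates.method,
        "n_frames": summary.n_frames,
        "mean_pct": summary.mean_pct.to_dict(),
        "sem_pct": summary.sem_pct.to_dict(),
        "sem_defined": summary.sem_defined,
        "conditional_pct_pp_of_A_positive": (
            100.0 * summary.mean_pct["pct_pp"]
            / (summary.mean_pct["pct_pp"] + summary.mean_pct["pct_pn"])
            if summary.mean_pct["pct_pp"] + summary.mean_pct["pct_pn"] > 0
            else None),
    }
    (out / "population_summary.json").write_text(
        json.dumps(headline, indent=2), encoding="utf-8")
    log.info("population: %d frames summarized", summary.n_frames)
    _provenance(out, "population", {"gates": config.gates},
                _stage_seed(config.seed, "population"))


def stage_associate(config: RunConfig, out: Path) -> None:
    seed = _stage_seed(config.seed, "associate")
    assoc_over = dict(config.association)
    assoc_over.setdefault("seed", seed)
    params = AssociationParams(**assoc_over)
    meta = json.loads((out / "points_meta.json").read_text(encoding="utf-8"))
    field_um = tuple(meta["field_um"])
    A = PointSet(pd.read_csv(out / "points_A.csv").to_numpy(), field_um, "A")
    B = PointSet(pd.read_csv(out / "points_B.csv").to_numpy(), field_um, "B")
    res = association_test(A, B, params)
    pd.DataFrame([{
        "label_A": "A", "label_B": "B", "n_A": res.n_A, "n_B": res.n_B,
        "field_w_um": field_um[0], "field_h_um": field_um[1],
        "d_um": res.d_um, "n_iterations": params.n_iterations,
        "observed_pct": res.observed_fraction,
        "random_mean_pct": res.random_mean,
        "empirical_p": res.empirical_p,
        "direction": res.direction, "seed": res.seed,
    }]).to_csv(out / "Pooled_RandomizationResults.csv", index=False)
    log.info("associate: observed %.2f%% vs random %.3f%% (p=%.4g)",
             res.observed_fraction, res.random_mean, res.empirical_p)
    _provenance(out, "associate", dataclasses.asdict(params), seed)


def stage_proteome(config: RunConfig, out: Path) -> None:
    params = ScreenParams(**config.screen)
    table = pd.read_csv(out / "peptides.csv")
    result = screen(table, params)
    result.to_csv(out / "protein_quant.csv")
    n_by_class = result["klass"].value_counts().to_dict()
    log.info("proteome: %s", n_by_class)
    _provenance(out, "proteome", dataclasses.asdict(params),
                _stage_seed(config.seed, "proteome"),
                {"classes": n_by_class, "background": result.attrs["background"]})


_STAGE_FN = {
    "simulate": stage_simulate,
    "detect": stage_detect,
    "quantify": stage_quantify,
    "population": stage_population,
    "associate": stage_associate,
    "proteome": stage_proteome,
}


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> Path:
    """Execute the requested (contiguous) stage subset; returns the out dir."""
    stages = stages or STAGES
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stage(s): {unknown}")
    idx = sorted(STAGES.index(s) for s in stages)
    if idx != list(range(idx[0], idx[-1] + 1)):
        raise PipelineError("stages must form a contiguous subset of "
                            f"{STAGES}")
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(
        json.dumps(config.to_dict(), indent=2, default=str), encoding="utf-8")
    for i in range(idx[0], idx[-1] + 1):
        name = STAGES[i]
        log.info("--- stage %s ---", name)
        try:
            _STAGE_FN[name](config, out)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
    return out
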