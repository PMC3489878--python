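"""End-to-end orchestration: simulate/load -> (extract) -> process -> states -> report.

A single validated config drives every stage; each stage writes its
artifact into the output directory and the run finishes with a manifest
recording the fully resolved parameters, per-stage timings and a SHA-256
checksum of every artifact, so a rerun with the same config and seed can be
verified byte-for-byte (the report and all intermediate files are
deterministic; only the timings differ).
"""

from __future__ import annotations

import hashlib
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__, io
from .imaging import detect_dual_view, extract_traces, register_views
from .kinetics import count_transitions, distance_from_efficiency, estimate_lifetime
from .mixture import assign_states, fit_mixture, pool_efficiencies, select_k
from .processing import compute_efficiency, estimate_gamma, select_fret_pairs
from .simulate import SimulationConfig, load_preset, simulate_traces
from .types import AnalysisError

__all__ = ["RunConfig", "StageError", "validate_config", "run_pipeline"]


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


class ImagingOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    psf_sigma_px: float = Field(1.2, gt=0)
    threshold_sd: float = Field(5.0, gt=0)
    max_pair_dist_px: float = Field(4.0, gt=0)
    frame_rate: float = Field(10.0, gt=0)
    detection_window_s: float = Field(2.0, gt=0, description="span averaged for spot detection")


class ProcessingOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    window_s: float = Field(1.0, gt=0, description="moving-average window, seconds")
    accept_k: float = Field(3.0, gt=0, description="step acceptance multiple of pooled sd")
    max_steps: int = Field(4, ge=1)
    gamma_window_s: float = Field(1.0, gt=0)
    bleach_frac: float = Field(0.25, gt=0, lt=1)
    background: float = 0.0
    gamma: Optional[float] = Field(None, gt=0, description="override; None = estimate from data")


class StatesOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    candidates: tuple[int, ...] = (2, 3)
    n_restarts: int = Field(20, ge=1)
    bin_width: float = Field(0.05, gt=0, lt=1)


class ReportOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    r0_nm: float = Field(5.1, gt=0)
    min_dwell_frames: int = Field(10, ge=1)


class RunConfig(BaseModel):
    """Validated configuration of a full pipeline run."""

    model_config = ConfigDict(extra="forbid")

    mode: Literal["simulate", "traces", "movie"]
    preset: Optional[str] = None
    simulation: Optional[dict] = None  # SimulationConfig fields / preset overrides
    traces_path: Optional[str] = None
    movie_path: Optional[str] = None
    seed: int = 0
    imaging: ImagingOptions = ImagingOptions()
    processing: ProcessingOptions = ProcessingOptions()
    states: StatesOptions = StatesOptions()
    report: ReportOptions = ReportOptions()

    @model_validator(mode="after")
    def _check_mode(self) -> "RunConfig":
        if self.mode == "simulate" and self.preset is None and self.simulation is None:
            raise ValueError("simulate mode needs 'preset' and/or 'simulation'")
        if self.mode == "traces" and not self.traces_path:
            raise ValueError("traces mode needs 'traces_path'")
        if self.mode == "movie" and not self.movie_path:
            raise ValueError("movie mode needs 'movie_path'")
        return self

    def resolve_simulation(self) -> SimulationConfig:
        overrides = dict(self.simulation or {})
        overrides.setdefault("seed", self.seed)
        if self.preset is not None:
            base = load_preset(self.preset).config.model_dump()
            base.update(overrides)
            return SimulationConfig(**base)
        return SimulationConfig(**overrides)


def validate_config(raw: dict) -> RunConfig:
    """Schema-check a raw config dict; unknown keys are rejected."""
    config = RunConfig(**raw)
    if config.mode == "simulate":
        config.resolve_simulation()  # surface field errors now, not mid-run
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: Path | str) -> dict:
    """Execute all stages and return the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    timings: dict[str, float] = {}
    manifest: dict = {
        "smfret_version": __version__,
        "seed": config.seed,
        "config": config.model_dump(mode="json"),
    }

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 4)
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc
                return False

        return _Timer()

    # ------------------------------------------------------------------ input
    frame_rate = config.imaging.frame_rate
    with stage("input"):
        if config.mode == "simulate":
            sim_cfg = config.resolve_simulation()
            frame_rate = sim_cfg.frame_rate
            traces, truth = simulate_traces(sim_cfg)
            artifacts["traces"] = io.write_traces_csv(traces, outdir / "traces.csv")
            artifacts["truth"] = io.write_truth_json(truth, outdir / "traces.truth.json")
            manifest["simulation"] = sim_cfg.model_dump(mode="json")
        elif config.mode == "traces":
            traces = io.read_traces_csv(config.traces_path, frame_rate=frame_rate)
        else:  # movie
            stack = io.read_movie_tiff(config.movie_path)
            n_det = max(1, int(round(config.imaging.detection_window_s * frame_rate)))
            detection_image = stack[: min(n_det, len(stack))].mean(axis=0)
            donor_spots, acceptor_spots = detect_dual_view(
                detection_image, config.imaging.threshold_sd, config.imaging.psf_sigma_px
            )
            half = stack.shape[2] // 2
            registration = register_views(
                donor_spots,
                acceptor_spots,
                config.imaging.max_pair_dist_px,
                nominal_offset_px=(half, 0.0),
            )
            traces = extract_traces(
                stack, registration, donor_spots, config.imaging.psf_sigma_px, frame_rate
            )
            artifacts["spots"] = io.write_spots_csv(
                donor_spots + acceptor_spots, outdir / "spots.csv"
            )
            artifacts["traces"] = io.write_traces_csv(traces, outdir / "traces.csv")
        if not traces:
            raise AnalysisError("no input traces")

    # ---------------------------------------------------------------- process
    with stage("process"):
        popt = config.processing
        selections, _events = select_fret_pairs(
            traces,
            background=popt.background,
            bleach_frac=popt.bleach_frac,
            accept_k=popt.accept_k,
            max_steps=popt.max_steps,
        )
        accepted = [s for s in selections if s.accepted]
        if not accepted:
            raise AnalysisError("no molecule passed FRET-pair selection")
        if popt.gamma is not None:
            gamma = popt.gamma
            gamma_source = "config"
            n_gamma = 0
        else:
            est = estimate_gamma(traces, selections, popt.gamma_window_s)
            gamma = est.gamma
            gamma_source = "estimated_median"
            n_gamma = est.n
        # Two efficiency tracks per molecule: raw frames are statistically
        # independent (used for model-order selection), smoothed frames are
        # variance-reduced (used for component fitting and state assignment).
        by_id = {tr.molecule_id: tr for tr in traces}
        fret_traces, fret_raw = [], []
        for s in accepted:
            smooth = compute_efficiency(
                by_id[s.molecule_id], gamma, s.acceptor_bleach_frame, popt.window_s
            )
            if smooth.n_valid == 0:
                continue
            fret_traces.append(smooth)
            fret_raw.append(
                compute_efficiency(by_id[s.molecule_id], gamma, s.acceptor_bleach_frame, None)
            )
        if not fret_traces:
            raise AnalysisError("no accepted molecule has valid frames")

        artifacts["fret"] = io.write_fret_csv(fret_traces, outdir / "fret.csv", raw=fret_raw)

        import pandas as pd

        mol_rows = pd.DataFrame(
            {
                "molecule_id": [s.molecule_id for s in selections],
                "accepted": [s.accepted for s in selections],
                "reason": [s.reason for s in selections],
                "acceptor_bleach_frame": [
                    -1 if s.acceptor_bleach_frame is None else s.acceptor_bleach_frame
                    for s in selections
                ],
            }
        )
        mean_e = {ft.molecule_id: ft.mean_efficiency for ft in fret_traces}
        mol_rows["mean_efficiency"] = [
            round(mean_e.get(m, float("nan")), 6) for m in mol_rows["molecule_id"]
        ]
        artifacts["molecules"] = outdir / "molecules.csv"
        mol_rows.to_csv(artifacts["molecules"], index=False)
        artifacts["process_summary"] = io.write_json(
            {
                "gamma": round(float(gamma), 6),
                "gamma_source": gamma_source,
                "n_gamma_molecules": n_gamma,
                "n_traces": len(traces),
                "n_accepted": len(accepted),
                "rejection_reasons": {
                    r: int(sum(1 for s in selections if s.reason == r))
                    for r in sorted({s.reason for s in selections if not s.accepted})
                },
            },
            outdir / "process_summary.json",
        )

    # ----------------------------------------------------------------- states
    with stage("states"):
        sample_raw, hist = pool_efficiencies(fret_raw, config.states.bin_width)
        sample, _ = pool_efficiencies(fret_traces, config.states.bin_width)
        selected = select_k(
            sample_raw,
            candidates=config.states.candidates,
            seed=config.seed,
            n_restarts=config.states.n_restarts,
        )
        model = fit_mixture(
            sample, selected.K, n_restarts=config.states.n_restarts, seed=config.seed
        )
        model.selection_score = selected.selection_score
        assignment = assign_states(fret_traces, model)
        artifacts["model"] = io.write_json(model.to_dict(), outdir / "states_model.json")
        artifacts["histogram"] = outdir / "histogram.csv"
        hist.to_csv(artifacts["histogram"], index=False)

        import pandas as pd

        assign_rows = []
        for mol, ft, labels in zip(
            assignment.molecule_ids, fret_traces, assignment.label_sequences()
        ):
            frames = np.flatnonzero(ft.valid_mask)
            assign_rows.append(
                pd.DataFrame({"molecule_id": mol, "frame": frames, "label": labels})
            )
        artifacts["assignments"] = outdir / "assignments.csv"
        pd.concat(assign_rows, ignore_index=True).to_csv(artifacts["assignments"], index=False)

    # ----------------------------------------------------------------- report
    with stage("report"):
        counts, n_with = count_transitions(assignment, config.report.min_dwell_frames)
        mean_obs_s = float(np.mean([ft.n_valid for ft in fret_traces])) / frame_rate
        # A transition only registers when both flanking runs last min_dwell
        # frames, so the window in which one is detectable is the span minus
        # its two edges; using the raw span would bias the lifetime upward.
        md = config.report.min_dwell_frames
        eff_obs_s = float(
            np.mean([max(0, ft.n_valid - (2 * md - 1)) for ft in fret_traces])
        ) / frame_rate
        kin = estimate_lifetime(n_with, len(fret_traces), max(eff_obs_s, 1e-9))
        mean_e_frames = float(np.mean(sample))
        mean_e_molecules = float(np.mean([ft.mean_efficiency for ft in fret_traces]))
        r0 = config.report.r0_nm

        def safe_distance(e: float):
            return round(distance_from_efficiency(e, r0), 4) if 0 < e < 1 else None

        report = {
            "gamma": round(float(gamma), 6),
            "K": model.K,
            "means": [round(float(m), 6) for m in model.means],
            "widths": [round(float(s), 6) for s in model.widths],
            "weights": [round(float(w), 6) for w in model.weights],
            "state_labels": model.state_labels,
            "state_fractions": {
                k: round(v, 6) for k, v in assignment.state_fractions.items()
            },
            "kinetics": {**kin.to_dict(), "mean_observation_raw_s": round(mean_obs_s, 6)},
            "mean_efficiency_frame_weighted": round(mean_e_frames, 6),
            "mean_efficiency_molecule_weighted": round(mean_e_molecules, 6),
            "r0_nm": r0,
            "distances_nm": {
                "per_state": {
                    lab: safe_distance(float(m))
                    for lab, m in zip(model.state_labels, model.means)
                },
                "mean_frame_weighted": safe_distance(mean_e_frames),
                "mean_molecule_weighted": safe_distance(mean_e_molecules),
            },
        }
        artifacts["report"] = io.write_json(report, outdir / "report.json")

    manifest["timings_s"] = timings
    manifest["artifacts"] = {
        name: {"path": str(p), "sha256": _sha256(Path(p))} for name, p in artifacts.items()
    }
    io.write_json(manifest, outdir / "manifest.json")
    return manifest
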