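"""Readers and writers for the on-disk formats the pipeline exchanges.

Traces travel as long-format CSV (molecule_id, frame, donor, acceptor) with
a JSON ground-truth sidecar when they come from the simulator; movies are
multi-page grayscale TIFF, one page per frame, dual view split at the
horizontal midline (left donor, right acceptor).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .simulate import GroundTruth
from .types import FretTrace, IntensityTrace, Spot

__all__ = [
    "traces_to_frame",
    "write_traces_csv",
    "read_traces_csv",
    "write_truth_json",
    "read_truth_json",
    "write_movie_tiff",
    "read_movie_tiff",
    "write_spots_csv",
    "write_json",
]


def traces_to_frame(traces: list[IntensityTrace]) -> pd.DataFrame:
    parts = [
        pd.DataFrame(
            {
                "molecule_id": tr.molecule_id,
                "frame": np.arange(len(tr)),
                "donor": tr.donor,
                "acceptor": tr.acceptor,
            }
        )
        for tr in traces
    ]
    if not parts:
        return pd.DataFrame(columns=["molecule_id", "frame", "donor", "acceptor"])
    return pd.concat(parts, ignore_index=True)


def write_traces_csv(traces: list[IntensityTrace], path: Path | str) -> Path:
    path = Path(path)
    df = traces_to_frame(traces)
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_traces_csv(path: Path | str, frame_rate: float = 10.0) -> list[IntensityTrace]:
    df = pd.read_csv(path)
    required = {"molecule_id", "frame", "donor", "acceptor"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("trace CSV contains no rows")
    traces = []
    for mol, grp in df.groupby("molecule_id", sort=True):
        grp = grp.sort_values("frame")
        traces.append(
            IntensityTrace(int(mol), frame_rate, grp["donor"].to_numpy(), grp["acceptor"].to_numpy())
        )
    return traces


def write_truth_json(truth: GroundTruth, path: Path | str) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth.to_dict(), sort_keys=True))
    return path


def read_truth_json(path: Path | str) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))


def write_movie_tiff(stack: np.ndarray, path: Path | str) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))
    return path


def read_movie_tiff(path: Path | str) -> np.ndarray:
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    return np.asarray(stack, dtype=float)


def write_spots_csv(spots: list[Spot], path: Path | str, molecule_ids: Optional[list[int]] = None) -> Path:
    path = Path(path)
    ids = molecule_ids if molecule_ids is not None else list(range(len(spots)))
    pd.DataFrame(
        {
            "molecule_id": ids,
            "x": [s.x for s in spots],
            "y": [s.y for s in spots],
            "view": [s.view for s in spots],
        }
    ).to_csv(path, index=False, float_format="%.4f")
    return path


def write_fret_csv(
    fret_traces: list[FretTrace], path: Path | str, raw: Optional[list[FretTrace]] = None
) -> Path:
    """Long-format efficiency table: one row per frame, NaN where invalid.

    ``efficiency`` holds the (smoothed) trace values; when ``raw`` supplies
    the matching unsmoothed traces an ``efficiency_raw`` column is added.
    """
    path = Path(path)
    parts = []
    for i, ft in enumerate(fret_traces):
        cols = {
            "molecule_id": ft.molecule_id,
            "frame": np.arange(len(ft.efficiency)),
            "efficiency": ft.efficiency,
            "valid": ft.valid_mask.astype(int),
            "gamma_used": ft.gamma_used,
            "frame_rate": ft.frame_rate,
        }
        if raw is not None:
            cols["efficiency_raw"] = raw[i].efficiency
        parts.append(pd.DataFrame(cols))
    df = (
        pd.concat(parts, ignore_index=True)
        if parts
        else pd.DataFrame(
            columns=["molecule_id", "frame", "efficiency", "valid", "gamma_used", "frame_rate"]
        )
    )
    df.to_csv(path, index=False, float_format="%.8f")
    return path


def read_fret_csv(path: Path | str, column: str = "efficiency") -> list[FretTrace]:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError("FRET CSV contains no rows")
    if column not in df.columns:
        raise ValueError(f"FRET CSV has no column {column!r}")
    out = []
    for mol, grp in df.groupby("molecule_id", sort=True):
        grp = grp.sort_values("frame")
        eff = grp[column].to_numpy()
        valid = grp["valid"].to_numpy().astype(bool)
        out.append(
            FretTrace(
                molecule_id=int(mol),
                frame_rate=float(grp["frame_rate"].iloc[0]),
                efficiency=eff,
                valid_mask=valid,
                gamma_used=float(grp["gamma_used"].iloc[0]),
                mean_efficiency=float(np.nanmean(eff[valid])) if valid.any() else float("nan"),
                clipped_mask=np.zeros(len(eff), dtype=bool),
            )
        )
    return out


def write_json(obj: dict, path: Path | str) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path
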