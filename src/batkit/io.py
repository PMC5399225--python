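"""Plain-text readers and writers for cohorts, feature tables and reports.

Everything on disk is CSV or JSON so that session archives diff cleanly
and need no binary device formats.  A cohort directory looks like::

    cohort/
      manifest.json             participants, sets, generator config
      ground_truth.csv          per-participant security scores
      p000_set1/
        ibi.csv                 t_ms, ibi_ms
        eda.csv                 t_ms, microsiemens
        frames.csv              t_ms, expression channels, gaze_away, head_size
        responses.csv           theme, h1h2, rd, liwc_* columns
        timeline.json           per-theme exposure/response/interstitial windows
      ...

Timestamps are 0-based integers-or-floats in ms.  Missing modalities are
simply absent files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cardiac import IbiSeries
from .eda import EdaTrace
from .sessions import (FeatureTable, Session, ThemeEvent, ThemeTimeline,
                       feature_schema)
from .simulate import CohortConfig, LatentTrait

__all__ = [
    "write_cohort", "read_cohort", "read_session",
    "write_feature_table", "read_feature_table",
    "write_timeline", "read_timeline",
]

log = logging.getLogger(__name__)


def write_timeline(timeline: ThemeTimeline, path: Path) -> None:
    events = [dict(theme_id=ev.theme_id, set_id=ev.set_id,
                   exposure=list(ev.exposure), response=list(ev.response),
                   interstitial=list(ev.interstitial))
              for ev in timeline]
    Path(path).write_text(json.dumps({"events": events}, indent=2))


def read_timeline(path: Path) -> ThemeTimeline:
    raw = json.loads(Path(path).read_text())
    events = tuple(ThemeEvent(theme_id=e["theme_id"], set_id=e["set_id"],
                              exposure=tuple(e["exposure"]),
                              response=tuple(e["response"]),
                              interstitial=tuple(e["interstitial"]))
                   for e in raw["events"])
    return ThemeTimeline(events=events)


def _session_dirname(participant_id: str, set_id: int) -> str:
    return f"{participant_id}_set{set_id}"


def write_cohort(sessions: Sequence[Session], traits: Sequence[LatentTrait],
                 ground_truth: pd.DataFrame, directory: Path,
                 config: Optional[CohortConfig] = None) -> Path:
    """Write a cohort as a session directory tree; returns the root path."""
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    manifest = {
        "participants": sorted({s.participant_id for s in sessions}),
        "sets": sorted({s.set_id for s in sessions}),
        "sessions": [],
    }
    if config is not None:
        cfgd = dataclasses.asdict(config)
        manifest["config"] = cfgd
    for s in sessions:
        d = root / _session_dirname(s.participant_id, s.set_id)
        d.mkdir(exist_ok=True)
        write_timeline(s.timeline, d / "timeline.json")
        if s.ibi is not None:
            pd.DataFrame({"t_ms": s.ibi.onsets, "ibi_ms": s.ibi.intervals}) \
                .to_csv(d / "ibi.csv", index=False)
        if s.eda is not None:
            pd.DataFrame({"t_ms": s.eda.times_ms,
                          "microsiemens": s.eda.values}) \
                .to_csv(d / "eda.csv", index=False)
        if s.frames is not None:
            s.frames.to_csv(d / "frames.csv", index=False)
        if s.responses is not None:
            s.responses.to_csv(d / "responses.csv", index=False)
        manifest["sessions"].append({"participant": s.participant_id,
                                     "set": s.set_id, "dir": d.name})
    if ground_truth is not None and len(ground_truth):
        ground_truth.to_csv(root / "ground_truth.csv")
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return root


def read_session(directory: Path, participant_id: str, set_id: int) -> Session:
    d = Path(directory)
    timeline = read_timeline(d / "timeline.json")
    ibi = eda = frames = responses = None
    if (d / "ibi.csv").exists():
        df = pd.read_csv(d / "ibi.csv")
        _require(df, ["t_ms", "ibi_ms"], d / "ibi.csv")
        ibi = IbiSeries(onsets=df["t_ms"].to_numpy(float),
                        intervals=df["ibi_ms"].to_numpy(float))
    if (d / "eda.csv").exists():
        df = pd.read_csv(d / "eda.csv")
        _require(df, ["t_ms", "microsiemens"], d / "eda.csv")
        t = df["t_ms"].to_numpy(float)
        if len(t) > 1:
            steps = np.diff(t)
            if not np.allclose(steps, steps[0], atol=1e-6):
                raise ValueError(f"{d/'eda.csv'}: sampling grid is not uniform")
            rate = 1000.0 / steps[0]
        else:
            rate = 1.0
        eda = EdaTrace(sample_rate=rate,
                       values=df["microsiemens"].to_numpy(float),
                       start=float(t[0]) if len(t) else 0.0)
    if (d / "frames.csv").exists():
        frames = pd.read_csv(d / "frames.csv")
        _require(frames, ["t_ms"], d / "frames.csv")
    if (d / "responses.csv").exists():
        responses = pd.read_csv(d / "responses.csv")
        _require(responses, ["theme"], d / "responses.csv")
    return Session(participant_id=participant_id, set_id=set_id,
                   timeline=timeline, ibi=ibi, eda=eda,
                   frames=frames, responses=responses)


def _require(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_cohort(directory: Path
                ) -> Tuple[List[Session], Optional[pd.DataFrame], dict]:
    """Read a cohort tree; returns (sessions, ground_truth, manifest)."""
    root = Path(directory)
    manifest = json.loads((root / "manifest.json").read_text())
    sessions = [read_session(root / e["dir"], e["participant"], e["set"])
                for e in manifest["sessions"]]
    gt = None
    if (root / "ground_truth.csv").exists():
        gt = pd.read_csv(root / "ground_truth.csv", index_col="participant")
    return sessions, gt, manifest


def write_feature_table(table: FeatureTable, csv_path: Path,
                        schema_path: Optional[Path] = None) -> None:
    table.data.to_csv(csv_path, index=False)
    if schema_path is not None:
        Path(schema_path).write_text(json.dumps(table.schema, indent=2))


def read_feature_table(csv_path: Path,
                       schema_path: Optional[Path] = None) -> FeatureTable:
    data = pd.read_csv(csv_path)
    schema = (json.loads(Path(schema_path).read_text())
              if schema_path and Path(schema_path).exists()
              else feature_schema())
    return FeatureTable(data, schema=schema)
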