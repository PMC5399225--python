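"""Session segmentation, per-theme feature aggregation, and score treatments.

A test session walks through a fixed sequence of *themes* (narrative
placeholders for rotating stimuli).  Each theme has an *exposure* phase
(the stimulus is on screen, default 15 s), a *response* phase (the
participant answers aloud, default 25 s) and a short interstitial (default
5 s) that is discarded.  Theme 1 is a neutral baseline.

This module segments raw streams by that timeline, aggregates behavioral /
paralinguistic / linguistic streams per (theme, phase), extracts cardiac
and electrodermal features per theme, and applies the two score
treatments:

* ``minus_baseline`` — theme k minus theme 1, individualizing scores to a
  participant's own resting level;
* ``minus_previous`` — theme k minus theme k-1, isolating the increment
  caused by the current theme from carry-over.

All windows are half-open ``[start, end)`` in 0-based ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .cardiac import IbiSeries, bayevsky_si, clean_ibi, hrv_freq, hrv_time
from .eda import EdaTrace, decompose_eda, detect_scr

__all__ = [
    "ThemeEvent",
    "ThemeTimeline",
    "Session",
    "FeatureTable",
    "EXPRESSION_CHANNELS",
    "WORD_CATEGORIES",
    "PARALINGUISTIC_FEATURES",
    "build_timeline",
    "segment",
    "aggregate_behavior",
    "extract_session_features",
    "subtract_baseline",
    "subtract_previous",
    "feature_schema",
]

# Facial-expression evidence channels (individual emotions plus the
# positive/negative composites produced by expression-recognition software).
EXPRESSION_CHANNELS = [
    "joy", "anger", "sadness", "fear", "disgust", "contempt", "surprise",
    "confusion", "frustration", "neutral", "positive", "negative",
]

# Word categories with an attachment-relevant signal in verbal responses.
WORD_CATEGORIES = [
    "we", "hearing", "leisure", "they", "inhibition", "tentative",
    "feeling", "past_tense", "discrepancy", "exclusion",
]

# Voice-quality features: h1h2 indexes a breathy (relaxed) voice,
# rd a tense one.
PARALINGUISTIC_FEATURES = ["h1h2", "rd"]

PHASES = ("exposure", "response", "whole")
VARIANTS = ("raw", "minus_baseline", "minus_previous")

KEY_COLS = ["participant", "set", "theme", "phase", "variant", "feature"]


@dataclass(frozen=True)
class ThemeEvent:
    theme_id: int
    set_id: int
    exposure: Tuple[float, float]      # ms, half-open
    response: Tuple[float, float]
    interstitial: Tuple[float, float]

    @property
    def whole(self) -> Tuple[float, float]:
        return (self.exposure[0], self.response[1])


@dataclass(frozen=True)
class ThemeTimeline:
    events: Tuple[ThemeEvent, ...]

    def __post_init__(self):
        object.__setattr__(self, "events", tuple(self.events))
        if not self.events:
            raise ValueError("timeline must contain at least one theme")
        if self.events[0].theme_id != 1:
            raise ValueError("theme 1 (baseline) must come first")
        prev_end = -np.inf
        for ev in self.events:
            for w in (ev.exposure, ev.response, ev.interstitial):
                if w[1] <= w[0]:
                    raise ValueError("windows must have positive duration")
                if w[0] < prev_end:
                    raise ValueError("windows must be ordered and non-overlapping")
                prev_end = w[1]

    @property
    def duration_ms(self) -> float:
        return self.events[-1].interstitial[1]

    def __iter__(self):
        return iter(self.events)

    def __len__(self):
        return len(self.events)


def build_timeline(n_themes: int = 14, set_id: int = 1,
                   exposure_s: float = 15.0, response_s: float = 25.0,
                   interstitial_s: float = 5.0, start_ms: float = 0.0) -> ThemeTimeline:
    if n_themes < 2:
        raise ValueError("n_themes must be >= 2 (theme 1 is the baseline)")
    events = []
    t = start_ms
    for theme in range(1, n_themes + 1):
        e0, e1 = t, t + exposure_s * 1000.0
        r1 = e1 + response_s * 1000.0
        i1 = r1 + interstitial_s * 1000.0
        events.append(ThemeEvent(theme_id=theme, set_id=set_id,
                                 exposure=(e0, e1), response=(e1, r1),
                                 interstitial=(r1, i1)))
        t = i1
    return ThemeTimeline(events=tuple(events))


@dataclass
class Session:
    """All recorded streams for one participant in one stimuli set.

    Any modality may be ``None`` (missing): downstream extraction emits no
    rows for it rather than failing.
    """

    participant_id: str
    set_id: int
    timeline: ThemeTimeline
    ibi: Optional[IbiSeries] = None
    eda: Optional[EdaTrace] = None
    # frames: t_ms + one column per expression channel + gaze_away + head_size
    frames: Optional[pd.DataFrame] = None
    # responses: one row per theme; h1h2, rd, word-category frequency columns
    responses: Optional[pd.DataFrame] = None


def segment(session: Session, timeline: Optional[ThemeTimeline] = None
            ) -> Dict[Tuple[int, str], pd.DataFrame]:
    """Slice the frame stream into per-(theme, phase) pieces.

    Returns a dict keyed by (theme_id, phase) for phases exposure and
    response; interstitial data is discarded.  A (theme, phase) whose
    window contains no frames maps to an empty DataFrame (missing).
    """
    tl = timeline or session.timeline
    out: Dict[Tuple[int, str], pd.DataFrame] = {}
    if session.frames is None:
        return out
    t = session.frames["t_ms"].to_numpy()
    for ev in tl:
        for phase, (lo, hi) in (("exposure", ev.exposure), ("response", ev.response)):
            mask = (t >= lo) & (t < hi)
            out[(ev.theme_id, phase)] = session.frames.loc[mask]
    return out


def aggregate_behavior(slices: Dict[Tuple[int, str], pd.DataFrame]
                       ) -> List[dict]:
    """Per-(theme, phase) means of expression evidence, gaze and head size."""
    rows: List[dict] = []
    for (theme, phase), df in slices.items():
        if df.empty:
            continue
        for ch in EXPRESSION_CHANNELS:
            if ch in df.columns:
                rows.append(dict(theme=theme, phase=phase,
                                 feature=f"expr_{ch}",
                                 value=float(df[ch].mean())))
        if "gaze_away" in df.columns:
            rows.append(dict(theme=theme, phase=phase, feature="gaze_away_frac",
                             value=float(df["gaze_away"].mean())))
        if "head_size" in df.columns:
            rows.append(dict(theme=theme, phase=phase, feature="head_size_mean",
                             value=float(df["head_size"].mean())))
    return rows


@dataclass
class FeatureTable:
    """Tidy participant x set x theme x phase x variant feature matrix.

    ``data`` has columns participant, set, theme, phase, variant, feature,
    value; ``schema`` maps feature name -> {modality, desirability}.
    Desirability marks the direction a *higher* value is expected to move
    with attachment security: ``desirable`` (up), ``undesirable`` (down),
    ``excluded`` (redundant with another feature), ``unsigned``.
    """

    data: pd.DataFrame
    schema: Dict[str, Dict[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in KEY_COLS + ["value"] if c not in self.data.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        if self.data.duplicated(KEY_COLS).any():
            raise ValueError("duplicate feature-table keys")

    def select(self, **kw) -> pd.DataFrame:
        df = self.data
        for col, val in kw.items():
            vals = val if isinstance(val, (list, tuple, set)) else [val]
            df = df[df[col].isin(vals)]
        return df

    def concat(self, other: "FeatureTable") -> "FeatureTable":
        schema = {**self.schema, **other.schema}
        return FeatureTable(pd.concat([self.data, other.data], ignore_index=True),
                            schema=schema)


def feature_schema() -> Dict[str, Dict[str, str]]:
    """Typed metadata for every feature this package computes."""
    s: Dict[str, Dict[str, str]] = {}

    def add(name, modality, desirability):
        s[name] = {"modality": modality, "desirability": desirability}

    add("hrv_mean_rr", "cardiac", "excluded")     # redundant with mean HR
    add("hrv_median_rr", "cardiac", "excluded")
    add("mean_hr", "cardiac", "undesirable")
    add("hrv_sdnn", "cardiac", "desirable")
    add("hrv_rmssd", "cardiac", "desirable")
    add("hrv_nn50", "cardiac", "desirable")
    add("hrv_pnn50", "cardiac", "desirable")
    add("hrv_hf_nu", "cardiac", "desirable")
    add("hrv_lf_nu", "cardiac", "excluded")       # = 100 - hf_nu
    add("hrv_lf_hf_ratio", "cardiac", "excluded")
    add("hrv_hf_pct", "cardiac", "excluded")      # hf_nu controls for VLF
    add("hrv_hf_power", "cardiac", "excluded")
    add("hrv_lf_pct", "cardiac", "unsigned")
    add("hrv_lf_power", "cardiac", "unsigned")
    add("hrv_vlf_power", "cardiac", "unsigned")
    add("bayevsky_si", "cardiac", "undesirable")
    add("scr_sum", "eda", "undesirable")
    add("scr_count", "eda", "unsigned")
    add("phasic_max", "eda", "excluded")          # redundant with scr_sum
    add("tonic_level", "eda", "excluded")         # needs long windows
    for ch in EXPRESSION_CHANNELS:
        # individual emotions live inside the two composites
        add(f"expr_{ch}", "face",
            {"positive": "desirable", "negative": "undesirable"}.get(ch, "excluded"))
    add("gaze_away_frac", "gaze", "undesirable")
    add("head_size_mean", "face", "desirable")
    add("h1h2", "voice", "desirable")             # breathy, relaxed voice
    add("rd", "voice", "undesirable")             # tense voice
    for cat in WORD_CATEGORIES:
        add(f"liwc_{cat}", "language", "unsigned")
    return s


def _aggregate_frames_fast(session: Session) -> List[dict]:
    """Vectorized equivalent of aggregate_behavior(segment(session)).

    Labels every frame with its (theme, phase) in one pass and computes
    all per-slice means with a single grouped reduction.
    """
    if session.frames is None or session.frames.empty:
        return []
    t = session.frames["t_ms"].to_numpy()
    bounds, labels = [], []
    for ev in session.timeline:
        bounds.append(ev.exposure[0]); labels.append((ev.theme_id, "exposure"))
        bounds.append(ev.response[0]); labels.append((ev.theme_id, "response"))
        bounds.append(ev.interstitial[0]); labels.append(None)
    bounds.append(session.timeline.events[-1].interstitial[1])
    idx = np.searchsorted(np.asarray(bounds), t, side="right") - 1
    valid = (idx >= 0) & (idx < len(labels))
    idx = np.where(valid, idx, 0)
    lab = [labels[i] if v else None for i, v in zip(idx, valid)]
    keep = np.array([l is not None for l in lab])
    if not keep.any():
        return []
    df = session.frames.loc[keep].copy()
    kept = [l for l in lab if l is not None]
    df["__theme"] = [l[0] for l in kept]
    df["__phase"] = [l[1] for l in kept]
    value_cols = [c for c in df.columns
                  if c in EXPRESSION_CHANNELS or c in ("gaze_away", "head_size")]
    grouped = df.groupby(["__theme", "__phase"])[value_cols].mean()
    rename = {ch: f"expr_{ch}" for ch in EXPRESSION_CHANNELS}
    rename.update({"gaze_away": "gaze_away_frac", "head_size": "head_size_mean"})
    rows = []
    for (theme, phase), vals in grouped.iterrows():
        for col, v in vals.items():
            if np.isfinite(v):
                rows.append(dict(theme=int(theme), phase=phase,
                                 feature=rename[col], value=float(v)))
    return rows


def _maybe(rows, theme, phase, feature, value):
    if value is not None and np.isfinite(value):
        rows.append(dict(theme=theme, phase=phase, feature=feature,
                         value=float(value)))


def extract_session_features(session: Session,
                             scr_min_amplitude: float = 0.01) -> pd.DataFrame:
    """Run the full per-session extraction; returns tidy raw-variant rows.

    Cardiac time-domain features are computed per phase and on the whole
    theme; spectral HRV and the Baevsky index need longer windows and are
    computed on the whole theme only (exposure + response, 40 s by
    default).  EDA features are computed per phase; voice and language
    features are per response.
    """
    rows: List[dict] = []
    tl = session.timeline

    if session.ibi is not None and len(session.ibi) > 0:
        ibi, _ = clean_ibi(session.ibi)
        for ev in tl:
            for phase, win in (("exposure", ev.exposure),
                               ("response", ev.response),
                               ("whole", ev.whole)):
                t = hrv_time(ibi, win)
                _maybe(rows, ev.theme_id, phase, "hrv_mean_rr", t.mean_rr)
                _maybe(rows, ev.theme_id, phase, "hrv_median_rr", t.median_rr)
                _maybe(rows, ev.theme_id, phase, "mean_hr", t.mean_hr)
                _maybe(rows, ev.theme_id, phase, "hrv_sdnn", t.sdnn)
                _maybe(rows, ev.theme_id, phase, "hrv_rmssd", t.rmssd)
                _maybe(rows, ev.theme_id, phase, "hrv_nn50", t.nn50)
                _maybe(rows, ev.theme_id, phase, "hrv_pnn50", t.pnn50)
            f = hrv_freq(ibi, ev.whole)
            for name, value in (("hrv_vlf_power", f.vlf_power),
                                ("hrv_lf_power", f.lf_power),
                                ("hrv_hf_power", f.hf_power),
                                ("hrv_lf_pct", f.lf_pct),
                                ("hrv_hf_pct", f.hf_pct),
                                ("hrv_lf_nu", f.lf_nu),
                                ("hrv_hf_nu", f.hf_nu),
                                ("hrv_lf_hf_ratio", f.lf_hf_ratio)):
                _maybe(rows, ev.theme_id, "whole", name, value)
            b = bayevsky_si(ibi, ev.whole)
            _maybe(rows, ev.theme_id, "whole", "bayevsky_si", b.si)

    if session.eda is not None and len(session.eda) > 0:
        tonic, phasic = decompose_eda(session.eda)
        for ev in tl:
            for phase, win in (("exposure", ev.exposure), ("response", ev.response)):
                e = detect_scr(phasic, win, min_amplitude=scr_min_amplitude,
                               tonic=tonic)
                _maybe(rows, ev.theme_id, phase, "scr_sum", e.scr_sum)
                _maybe(rows, ev.theme_id, phase, "scr_count", e.scr_count)
                _maybe(rows, ev.theme_id, phase, "phasic_max", e.phasic_max)
                _maybe(rows, ev.theme_id, phase, "tonic_level", e.tonic_level)

    rows.extend(_aggregate_frames_fast(session))

    if session.responses is not None and not session.responses.empty:
        resp = session.responses.set_index("theme") \
            if "theme" in session.responses.columns else session.responses
        for ev in tl:
            if ev.theme_id not in resp.index:
                continue
            row = resp.loc[ev.theme_id]
            for name in PARALINGUISTIC_FEATURES:
                if name in row.index:
                    _maybe(rows, ev.theme_id, "response", name, row[name])
            for cat in WORD_CATEGORIES:
                col = f"liwc_{cat}"
                if col in row.index:
                    _maybe(rows, ev.theme_id, "response", col, row[col])

    df = pd.DataFrame(rows, columns=["theme", "phase", "feature", "value"])
    df.insert(0, "participant", session.participant_id)
    df.insert(1, "set", session.set_id)
    df.insert(4, "variant", "raw")
    return df


def _treated(table: FeatureTable, kind: str) -> pd.DataFrame:
    raw = table.select(variant="raw")
    wide = raw.pivot_table(index=["participant", "set", "phase", "feature"],
                           columns="theme", values="value")
    if kind == "minus_baseline":
        if 1 not in wide.columns:
            return pd.DataFrame(columns=KEY_COLS + ["value"])
        treated = wide.sub(wide[1], axis=0).drop(columns=[1])
    elif kind == "minus_previous":
        # strictly consecutive: theme k minus theme k-1, both present
        cols = {cur: wide[cur] - wide[cur - 1]
                for cur in sorted(wide.columns)
                if cur >= 2 and (cur - 1) in wide.columns}
        if not cols:
            return pd.DataFrame(columns=KEY_COLS + ["value"])
        treated = pd.DataFrame(cols)
        treated.columns.name = "theme"
    else:  # pragma: no cover
        raise ValueError(kind)
    long = treated.stack().rename("value").reset_index()
    long["variant"] = kind
    return long[KEY_COLS + ["value"]]


def subtract_baseline(table: FeatureTable) -> FeatureTable:
    """Add minus_baseline rows: raw(theme k) - raw(theme 1), k >= 2.

    Rows are only emitted where both operands exist; theme 1 never carries
    treated variants.
    """
    extra = _treated(table, "minus_baseline")
    if extra.empty:
        return table
    return FeatureTable(pd.concat([table.data, extra], ignore_index=True),
                        schema=table.schema)


def subtract_previous(table: FeatureTable) -> FeatureTable:
    """Add minus_previous rows: raw(theme k) - raw(theme k-1), k >= 2."""
    extra = _treated(table, "minus_previous")
    if extra.empty:
        return table
    return FeatureTable(pd.concat([table.data, extra], ignore_index=True),
                        schema=table.schema)


def extract_cohort_features(sessions: Iterable[Session],
                            scr_min_amplitude: float = 0.01,
                            treatments: bool = True) -> FeatureTable:
    """Extract features for every session and apply both score treatments."""
    frames = [extract_session_features(s, scr_min_amplitude=scr_min_amplitude)
              for s in sessions]
    frames = [f for f in frames if not f.empty]
    data = (pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame(columns=KEY_COLS + ["value"]))
    table = FeatureTable(data, schema=feature_schema())
    if treatments and not data.empty:
        table = subtract_baseline(table)
        table = subtract_previous(table)
    return table
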