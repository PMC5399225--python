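"""The composite effects index: one number per participant.

Rather than multiplying hypothesis tests over hundreds of features, the
confirmatory analysis collapses them into a single index.  Each feature is
z-scored across participants (within a stimuli set), assigned to a
*desirable* group (markers of a soothing, parasympathetic response:
HF power of HRV in normalized units, SDNN, RMSSD, NN50, pNN50, breathy-
voice features, the positive-expression composite, head size) or an
*undesirable* group (Baevsky stress index, heart rate, gaze aversion,
tense-voice features, the negative-expression composite, SCR), summed over
the requested themes, available phases and score-treatment variants, and

    index = desirable_sum - undesirable_sum.

A higher index means a more desirable (secure-typical) reaction.
Mathematically redundant features (LF in normalized units, the LF/HF
ratio, HF in percent and absolute power, mean/median RR, individual
expression channels, phasic maximum, tonic level) are excluded so no
information is double counted; word-category features stay out because
they have no single desirable direction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .sessions import FeatureTable, KEY_COLS, feature_schema

__all__ = ["CompositeSchema", "CompositeResult", "default_schema",
           "zscore_features", "build_index", "correlate_index"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompositeSchema:
    """Grouping ledger: which features count as desirable / undesirable."""

    desirable: Tuple[str, ...]
    undesirable: Tuple[str, ...]
    excluded: Tuple[str, ...] = ()

    def __post_init__(self):
        overlap = set(self.desirable) & set(self.undesirable)
        if overlap:
            raise ValueError(f"features in both groups: {sorted(overlap)}")

    @classmethod
    def from_json(cls, path) -> "CompositeSchema":
        with open(path) as fh:
            d = json.load(fh)
        return cls(desirable=tuple(d["desirable"]),
                   undesirable=tuple(d["undesirable"]),
                   excluded=tuple(d.get("excluded", ())))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"desirable": list(self.desirable),
                       "undesirable": list(self.undesirable),
                       "excluded": list(self.excluded)}, fh, indent=2)


def default_schema() -> CompositeSchema:
    """Grouping derived from the package-wide feature schema."""
    s = feature_schema()
    return CompositeSchema(
        desirable=tuple(k for k, v in s.items() if v["desirability"] == "desirable"),
        undesirable=tuple(k for k, v in s.items() if v["desirability"] == "undesirable"),
        excluded=tuple(k for k, v in s.items()
                       if v["desirability"] in ("excluded", "unsigned")),
    )


@dataclass
class CompositeResult:
    """Per-participant index with full contribution provenance."""

    scores: pd.DataFrame        # index: participant; desirable_sum,
                                # undesirable_sum, index, n_missing
    provenance: pd.DataFrame    # participant, set, theme, phase, variant,
                                # feature, group, z


def zscore_features(table: FeatureTable, themes: Optional[Sequence[int]] = None,
                    min_participants: int = 3) -> pd.DataFrame:
    """z-score every feature cell across participants, within stimuli set.

    Returns tidy rows (participant, set, theme, phase, variant, feature, z).
    Cells observed for fewer than ``min_participants`` participants or with
    zero variance across them are dropped (logged).
    """
    df = table.data
    if themes is not None:
        df = df[df["theme"].isin(list(themes))]
    if df.empty:
        raise ValueError("no feature rows to z-score")
    if df["participant"].nunique() < min_participants:
        raise ValueError(
            f"z-scoring needs >= {min_participants} participants, "
            f"got {df['participant'].nunique()}")
    cell = ["set", "theme", "phase", "variant", "feature"]
    g = df.groupby(cell)["value"]
    stats = g.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count")
    merged = df.merge(stats, left_on=cell, right_index=True)
    bad = (merged["n"] < min_participants) | ~(merged["sd"] > 0)
    n_dropped = merged.loc[bad, cell].drop_duplicates().shape[0]
    if n_dropped:
        log.info("z-scoring dropped %d degenerate feature cells", n_dropped)
    merged = merged[~bad]
    out = merged[KEY_COLS].copy()
    out["z"] = (merged["value"] - merged["mean"]) / merged["sd"]
    return out.reset_index(drop=True)


def build_index(ztable: pd.DataFrame, schema: Optional[CompositeSchema] = None,
                themes: Optional[Sequence[int]] = None,
                variants: Optional[Sequence[str]] = None) -> CompositeResult:
    """Sum grouped z-scores into the composite effects index.

    Contributions are summed over the requested themes, all available
    phases and all available variants (``variants`` narrows the set; by
    default raw and both treatments enter when present).  A participant's
    missing contributions implicitly enter as 0 — the cohort mean — and
    are counted in ``n_missing``.
    """
    schema = schema or default_schema()
    df = ztable
    if themes is not None:
        df = df[df["theme"].isin(list(themes))]
    if variants is not None:
        df = df[df["variant"].isin(list(variants))]
    present = set(df["feature"].unique())
    group_of: Dict[str, str] = {}
    for f in schema.desirable:
        if f in present:
            group_of[f] = "desirable"
        else:
            log.warning("schema feature %r absent from table; skipped", f)
    for f in schema.undesirable:
        if f in present:
            group_of[f] = "undesirable"
        else:
            log.warning("schema feature %r absent from table; skipped", f)
    df = df[df["feature"].isin(group_of)].copy()
    if df.empty:
        raise ValueError("no schema features present in the z-table")
    df["group"] = df["feature"].map(group_of)

    participants = sorted(ztable["participant"].unique())
    sums = (df.groupby(["participant", "group"])["z"].sum()
            .unstack(fill_value=0.0)
            .reindex(participants, fill_value=0.0))
    for col in ("desirable", "undesirable"):
        if col not in sums.columns:
            sums[col] = 0.0
    # contributions a participant lacks relative to the densest coverage
    cell_count = df.groupby("participant").size().reindex(participants, fill_value=0)
    n_cells = int(df.groupby(["set", "theme", "phase", "variant", "feature"])
                  .ngroups)
    scores = pd.DataFrame({
        "desirable_sum": sums["desirable"],
        "undesirable_sum": sums["undesirable"],
        "index": sums["desirable"] - sums["undesirable"],
        "n_missing": n_cells - cell_count,
    })
    scores.index.name = "participant"
    prov = df[["participant", "set", "theme", "phase", "variant",
               "feature", "group", "z"]].reset_index(drop=True)
    return CompositeResult(scores=scores, provenance=prov)


def correlate_index(result: CompositeResult, ground_truth: pd.DataFrame,
                    measure: str) -> Tuple[float, float, int]:
    """Pearson correlation of the index with a ground-truth measure.

    Pairwise-complete over participants; returns (r, two-sided P, n).
    """
    if measure not in ground_truth.columns:
        raise KeyError(f"unknown ground-truth measure {measure!r}")
    joined = result.scores.join(ground_truth[measure], how="inner").dropna(
        subset=["index", measure])
    n = len(joined)
    if n < 3:
        raise ValueError(f"need >= 3 overlapping participants, got {n}")
    r, p = _stats.pearsonr(joined["index"], joined[measure])
    return float(r), float(p), n
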