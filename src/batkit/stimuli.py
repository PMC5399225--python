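"""Crowdsourced stimulus selection: fitness scoring and set assembly.

Candidate pictures for each theme are judged in a slider survey (each
slider opposes two traits, e.g. stressed vs relaxed, and is normalized to
[-100, 100] with 0 at the neutral center).  A per-theme composite fitness
formula sums the respondent-mean of its positive criteria and subtracts
the mean of its negative criteria; for the worked "attuned mother-child"
theme that is genuineness + attunement - child stress - mother stress.
Pictures below a minimum required fitness are gated out, the rest are
ranked, and three stimuli sets are assembled: set 1 takes each theme's
top-ranked picture, set 2 the runner-up, and set 3 holds each theme's
ranks 3-5 as a pool from which one picture is drawn at play time.

Music-clip selection reuses the same ranking: clips come with published
per-emotion scores and the top scorer for a theme's required emotion wins.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = ["ThemeFormula", "composite_fitness", "assemble_sets",
           "draw_from_pool", "rank_music", "ATTUNED_MOTHER_CHILD_FORMULA"]

log = logging.getLogger(__name__)

SLIDER_MIN, SLIDER_MAX = -100.0, 100.0


@dataclass(frozen=True)
class ThemeFormula:
    """Composite fitness formula for one theme's candidate pictures."""

    theme_id: int
    positive: Tuple[str, ...]
    negative: Tuple[str, ...] = ()
    min_required_score: float = 0.0

    def __post_init__(self):
        overlap = set(self.positive) & set(self.negative)
        if overlap:
            raise ValueError(f"criteria on both sides: {sorted(overlap)}")

    @classmethod
    def from_json(cls, path) -> Dict[int, "ThemeFormula"]:
        with open(path) as fh:
            raw = json.load(fh)
        return {int(k): cls(theme_id=int(k), positive=tuple(v["positive"]),
                            negative=tuple(v.get("negative", ())),
                            min_required_score=v.get("min_required_score", 0.0))
                for k, v in raw.items()}


# the one formula printed in full: genuineness + mother-child attunement
# minus the child's and the mother's perceived stress
ATTUNED_MOTHER_CHILD_FORMULA = ThemeFormula(
    theme_id=13,
    positive=("genuineness", "attunement"),
    negative=("child_stress", "mother_stress"),
)


def _validate_survey(survey: pd.DataFrame) -> pd.DataFrame:
    required = {"picture_id", "criterion", "respondent_id", "value"}
    missing = required - set(survey.columns)
    if missing:
        raise ValueError(f"survey table missing columns: {sorted(missing)}")
    vals = survey["value"]
    if ((vals < SLIDER_MIN) | (vals > SLIDER_MAX)).any():
        raise ValueError("slider values must lie in [-100, 100]")
    dup = survey.duplicated(["picture_id", "criterion", "respondent_id"])
    if dup.any():
        log.warning("dropping %d duplicate (picture, criterion, respondent) "
                    "judgments", int(dup.sum()))
        survey = survey[~dup]
    return survey


def composite_fitness(survey: pd.DataFrame, formula: ThemeFormula
                      ) -> pd.DataFrame:
    """Rank a theme's candidate pictures by composite fitness.

    score(picture) = sum of respondent-mean positive criteria minus sum of
    respondent-mean negative criteria.  Pictures scoring below the
    formula's ``min_required_score`` are excluded.  Returns a DataFrame
    (picture_id, score, rank) sorted by descending score, ties broken by
    picture_id.
    """
    survey = _validate_survey(survey)
    needed = set(formula.positive) | set(formula.negative)
    have = set(survey["criterion"].unique())
    absent = needed - have
    if absent:
        raise ValueError(f"survey lacks criteria: {sorted(absent)}")
    means = (survey[survey["criterion"].isin(needed)]
             .groupby(["picture_id", "criterion"])["value"].mean()
             .unstack("criterion"))
    score = means[list(formula.positive)].sum(axis=1)
    if formula.negative:
        score = score - means[list(formula.negative)].sum(axis=1)
    out = score.rename("score").reset_index()
    out = out[out["score"] >= formula.min_required_score]
    out = out.sort_values(["score", "picture_id"],
                          ascending=[False, True]).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def assemble_sets(rankings: Dict[int, pd.DataFrame]
                  ) -> Tuple[Dict[int, str], Dict[int, str], Dict[int, List[str]]]:
    """Assemble the two fixed sets and the rotating-pool third set.

    ``rankings`` maps theme_id -> output of :func:`composite_fitness`.
    Returns (set1, set2, set3_pool): set1/set2 map theme -> picture_id
    (ranks 1 and 2), set3_pool maps theme -> the rank 3-5 pictures.  A
    theme with fewer than 2 gated pictures is an error; a pool smaller
    than 3 is allowed but logged.
    """
    set1: Dict[int, str] = {}
    set2: Dict[int, str] = {}
    pool: Dict[int, List[str]] = {}
    for theme, ranked in rankings.items():
        ids = ranked.sort_values("rank")["picture_id"].tolist()
        if len(ids) < 2:
            raise ValueError(
                f"theme {theme}: need >= 2 gated pictures to build both "
                f"fixed sets, got {len(ids)}")
        set1[theme] = ids[0]
        set2[theme] = ids[1]
        pool[theme] = ids[2:5]
        if len(pool[theme]) < 3:
            log.warning("theme %d: rotating pool has only %d pictures",
                        theme, len(pool[theme]))
    return set1, set2, pool


def draw_from_pool(pool: Dict[int, List[str]], seed: int) -> Dict[int, str]:
    """Seeded play-time draw of one picture per theme from the set-3 pools."""
    rng = np.random.default_rng(seed)
    out = {}
    for theme in sorted(pool):
        choices = pool[theme]
        if not choices:
            continue
        out[theme] = choices[rng.integers(len(choices))]
    return out


def rank_music(emotion_scores: pd.DataFrame, emotion: str,
               n: int = 1) -> List[str]:
    """Pick the music clips scoring highest on the required emotion.

    ``emotion_scores`` has columns clip_id plus one column per emotion.
    """
    if emotion not in emotion_scores.columns:
        raise ValueError(f"no scores for emotion {emotion!r}")
    ranked = emotion_scores.sort_values([emotion, "clip_id"],
                                        ascending=[False, True])
    return ranked["clip_id"].head(n).tolist()
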