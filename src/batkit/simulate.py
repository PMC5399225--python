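"""Synthetic multimodal test cohorts with planted attachment-security effects.

Every downstream stage of the pipeline (cardiac, electrodermal,
behavioral, voice and language features; composite index; statistics) is
exercised on cohorts produced here, because no raw study recordings are
publicly deposited.  The generator emulates one full session per
participant per stimuli set: interbeat intervals, a sampled skin-
conductance trace, per-frame expression/gaze/head-size streams, and
per-response voice and word-category vectors, all spanning the theme
timeline (14 themes x 15 s exposure + 25 s response + 5 s interstitial by
default).

The planted effect works through a latent standard-normal *security*
trait z per participant.  For each modality m, an "expressed trait"
``u_m = r_m * z + sqrt(1 - r_m^2) * eps`` carries the signal, so the
population correlation between z and any feature driven by u_m is
approximately the configured per-modality ``effect_size`` r_m, regardless
of the modality's internal gain.  On the attachment-deactivating themes
(4, 7 and 13: reassuring, attuned-figure narratives) u_m shifts feature
means in the theory-consistent directions: more high-frequency HRV power
and less LF share, lower Baevsky stress index, lower heart rate, fewer and
smaller skin-conductance responses, more positive / fewer negative facial
expressions, less gaze aversion, a larger (closer) head, a breathier and
less tense voice, and attunement-flavoured word choices.  Ground-truth
security scores are linear functions of z plus noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .cardiac import IbiSeries
from .eda import EdaTrace
from .sessions import (EXPRESSION_CHANNELS, PARALINGUISTIC_FEATURES, Session,
                       ThemeTimeline, WORD_CATEGORIES, build_timeline)

__all__ = [
    "MODALITIES",
    "DEACTIVATING_THEMES",
    "CohortConfig",
    "LatentTrait",
    "SyntheticSession",
    "generate_cohort",
]

MODALITIES = ("cardiac", "eda", "face", "gaze", "voice", "language")

# Reassuring, attachment-deactivating themes (attuned father-child,
# attuned couple, attuned mother-child).
DEACTIVATING_THEMES = (4, 7, 13)

_POSITIVE_WORDS = {"we", "hearing", "leisure", "they", "past_tense", "exclusion"}
_NEGATIVE_WORDS = {"inhibition", "tentative", "feeling", "discrepancy"}

_DEF_NOISE = {"cardiac": 10.0,   # ms, beat-level RR noise
              "eda": 0.01,       # µS, sensor noise
              "face": 0.5,       # evidence units per frame
              "gaze": 0.0,       # gaze is Bernoulli; no extra noise
              "voice": 0.2,      # feature units per response
              "language": 0.0}   # Dirichlet sampling is the noise


def _per_modality(value: Union[float, Mapping[str, float]],
                  name: str) -> Dict[str, float]:
    if isinstance(value, Mapping):
        unknown = set(value) - set(MODALITIES)
        if unknown:
            raise ValueError(f"{name}: unknown modalities {sorted(unknown)}")
        return {m: float(value.get(m, 0.0)) for m in MODALITIES}
    return {m: float(value) for m in MODALITIES}


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    ``effect_size`` is on the correlation scale in [-1, 1], per modality
    or one number for all; ``missingness`` is the probability that a
    participant's modality recording failed in a given set.
    """

    n_participants: int
    n_themes: int = 14
    n_sets: int = 3
    seed: int = 0
    effect_size: Union[float, Mapping[str, float]] = 0.5
    noise_sd: Union[float, Mapping[str, float], None] = None
    missingness: Union[float, Mapping[str, float]] = 0.0
    sampling_rate_eda: float = 4.0   # Hz, wristband-class EDA rate
    frame_rate: float = 10.0         # Hz, video analysis frame rate
    exposure_s: float = 15.0
    response_s: float = 25.0
    interstitial_s: float = 5.0
    ammi_coverage: float = 0.4       # fraction of participants with AMMI scores

    def __post_init__(self):
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        if self.n_themes < 2:
            raise ValueError("n_themes must be >= 2 (theme 1 is the baseline)")
        if not 1 <= self.n_sets <= 3:
            raise ValueError("n_sets must be in 1..3")
        for d, nm in ((self.exposure_s, "exposure_s"),
                      (self.response_s, "response_s"),
                      (self.interstitial_s, "interstitial_s")):
            if d <= 0:
                raise ValueError(f"{nm} must be strictly positive")
        if self.sampling_rate_eda <= 0 or self.frame_rate <= 0:
            raise ValueError("sampling rates must be strictly positive")
        es = _per_modality(self.effect_size, "effect_size")
        if any(abs(v) > 1 for v in es.values()):
            raise ValueError("effect_size must lie in [-1, 1]")
        miss = _per_modality(self.missingness, "missingness")
        if any(not 0 <= v <= 1 for v in miss.values()):
            raise ValueError("missingness must lie in [0, 1]")
        if not 0 <= self.ammi_coverage <= 1:
            raise ValueError("ammi_coverage must lie in [0, 1]")

    @property
    def effect(self) -> Dict[str, float]:
        return _per_modality(self.effect_size, "effect_size")

    @property
    def noise(self) -> Dict[str, float]:
        if self.noise_sd is None:
            return dict(_DEF_NOISE)
        if isinstance(self.noise_sd, Mapping):
            out = dict(_DEF_NOISE)
            out.update({k: float(v) for k, v in self.noise_sd.items()})
            return out
        return {m: float(self.noise_sd) for m in MODALITIES}

    @property
    def miss(self) -> Dict[str, float]:
        return _per_modality(self.missingness, "missingness")

    def deactivating_themes(self) -> Tuple[int, ...]:
        return tuple(t for t in DEACTIVATING_THEMES if t <= self.n_themes)


@dataclass(frozen=True)
class LatentTrait:
    participant_id: str
    security: float  # standard-normal latent value, fixed across sets


# a Session produced by the generator carries exactly the Session contract
SyntheticSession = Session

# --- generator gains (feature units per unit of expressed trait) ---------
_RR_MEAN_MS = 800.0
_RR_MEAN_GAIN = 20.0     # secure -> slower heart
_A_LF_MS = 25.0
_A_HF_MS = 25.0
_HF_GAIN = 0.30          # relative A_HF increase per unit trait
_LF_GAIN = 0.15          # relative A_LF decrease per unit trait
_EDA_TONIC_US = 2.0
_EDA_DRIFT_US_PER_S = 1e-4
_SCR_RATE_HZ = 0.10
_SCR_AMP_US = 0.30
_SCR_GAIN = 0.30         # relative rate/amplitude decrease per unit trait
_SCR_RISE_S = 1.0
_SCR_DECAY_S = 4.0
_EXPR_GAIN = 0.5         # evidence-unit shift of the composites
_GAZE_BASE_P = 0.2
_GAZE_GAIN = 1.0         # logit shift
_HEAD_BASE = 100.0
_HEAD_GAIN = 0.05        # relative size increase per unit trait
_VOICE_GAIN = 0.5
_WORD_GAIN = 0.4         # log-alpha shift of Dirichlet weights


def _theme_of_ms(t_ms: np.ndarray, block_ms: float, n_themes: int) -> np.ndarray:
    idx = np.minimum((t_ms // block_ms).astype(int), n_themes - 1)
    return idx + 1


def _gen_ibi(rng: np.random.Generator, cfg: CohortConfig, u: float,
             duration_s: float, block_s: float) -> IbiSeries:
    deact = cfg.deactivating_themes()
    n_themes = cfg.n_themes
    sd = cfg.noise["cardiac"]
    mean_rr = np.full(n_themes, _RR_MEAN_MS)
    a_lf = np.full(n_themes, _A_LF_MS)
    a_hf = np.full(n_themes, _A_HF_MS)
    for th in deact:
        mean_rr[th - 1] = np.clip(_RR_MEAN_MS + _RR_MEAN_GAIN * u, 500.0, 1200.0)
        a_lf[th - 1] = max(_A_LF_MS * (1.0 - _LF_GAIN * u), 2.0)
        a_hf[th - 1] = max(_A_HF_MS * (1.0 + _HF_GAIN * u), 2.0)
    # beat-by-beat integration of RR(t)
    t = 0.0
    onsets: List[float] = []
    intervals: List[float] = []
    n_guess = int(duration_s * 1000.0 / (_RR_MEAN_MS - 60.0)) + 16
    noise = rng.normal(0.0, sd, size=n_guess)
    k = 0
    two_pi = 2.0 * np.pi
    while t < duration_s:
        th = min(int(t // block_s), n_themes - 1)
        rr = (mean_rr[th]
              + a_lf[th] * np.sin(two_pi * 0.1 * t)
              + a_hf[th] * np.sin(two_pi * 0.25 * t)
              + (noise[k] if k < n_guess else rng.normal(0.0, sd)))
        rr = max(rr, 300.0)
        t += rr / 1000.0
        onsets.append(t * 1000.0)
        intervals.append(rr)
        k += 1
    return IbiSeries(onsets=np.array(onsets), intervals=np.array(intervals))


def _gen_eda(rng: np.random.Generator, cfg: CohortConfig, u: float,
             duration_s: float, block_s: float) -> EdaTrace:
    fs = cfg.sampling_rate_eda
    n = int(duration_s * fs)
    t = np.arange(n) / fs
    x = _EDA_TONIC_US + _EDA_DRIFT_US_PER_S * t
    deact = set(cfg.deactivating_themes())
    peak_tau = (np.log(_SCR_DECAY_S / _SCR_RISE_S)
                / (1.0 / _SCR_RISE_S - 1.0 / _SCR_DECAY_S))
    peak_val = np.exp(-peak_tau / _SCR_DECAY_S) - np.exp(-peak_tau / _SCR_RISE_S)
    kernel_t = np.arange(0.0, 6.0 * _SCR_DECAY_S, 1.0 / fs)
    kernel = (np.exp(-kernel_t / _SCR_DECAY_S)
              - np.exp(-kernel_t / _SCR_RISE_S)) / peak_val
    for th in range(1, cfg.n_themes + 1):
        rate = _SCR_RATE_HZ
        amp = _SCR_AMP_US
        if th in deact:
            rate = max(_SCR_RATE_HZ * (1.0 - _SCR_GAIN * u), 0.01)
            amp = max(_SCR_AMP_US * (1.0 - _SCR_GAIN * u), 0.02)
        t0, t1 = (th - 1) * block_s, min(th * block_s, duration_s)
        n_ev = rng.poisson(rate * (t1 - t0))
        starts = np.sort(rng.uniform(t0, t1, size=n_ev))
        amps = amp * rng.lognormal(0.0, 0.4, size=n_ev)
        for s, a in zip(starts, amps):
            i0 = int(s * fs)
            seg = min(kernel.size, n - i0)
            if seg > 0:
                x[i0:i0 + seg] += a * kernel[:seg]
    x = x + rng.normal(0.0, cfg.noise["eda"], size=n)
    return EdaTrace(sample_rate=fs, values=np.maximum(x, 0.0), start=0.0)


def _gen_frames(rng: np.random.Generator, cfg: CohortConfig,
                u_face: float, u_gaze: float,
                duration_s: float, block_s: float) -> pd.DataFrame:
    fr = cfg.frame_rate
    n = int(duration_s * fr)
    t_ms = np.arange(n) * 1000.0 / fr
    theme = _theme_of_ms(t_ms, block_s * 1000.0, cfg.n_themes)
    deact = np.isin(theme, cfg.deactivating_themes())
    sd = cfg.noise["face"]
    shift = {ch: 0.0 for ch in EXPRESSION_CHANNELS}
    shift["positive"] = _EXPR_GAIN * u_face
    shift["joy"] = 0.8 * _EXPR_GAIN * u_face
    for ch in ("anger", "sadness", "fear", "disgust", "contempt"):
        shift[ch] = -0.5 * _EXPR_GAIN * u_face
    for ch in ("surprise", "confusion", "frustration"):
        shift[ch] = -0.3 * _EXPR_GAIN * u_face
    shift["negative"] = -_EXPR_GAIN * u_face
    cols = {"t_ms": t_ms}
    for ch in EXPRESSION_CHANNELS:
        cols[ch] = rng.normal(0.0, sd, size=n) + np.where(deact, shift[ch], 0.0)
    logit = np.log(_GAZE_BASE_P / (1.0 - _GAZE_BASE_P))
    p = 1.0 / (1.0 + np.exp(-(logit - np.where(deact, _GAZE_GAIN * u_gaze, 0.0))))
    cols["gaze_away"] = (rng.random(n) < p).astype(int)
    head = _HEAD_BASE * np.where(deact, 1.0 + _HEAD_GAIN * u_face, 1.0)
    cols["head_size"] = np.maximum(head + rng.normal(0.0, 2.0, size=n), 1.0)
    return pd.DataFrame(cols)


def _gen_responses(rng: np.random.Generator, cfg: CohortConfig,
                   u_voice: float, u_lang: float) -> pd.DataFrame:
    deact = set(cfg.deactivating_themes())
    sd = cfg.noise["voice"]
    rows = []
    base_alpha = np.full(len(WORD_CATEGORIES) + 1, 5.0)
    base_alpha[-1] = 30.0  # "all other words" bulk category
    for th in range(1, cfg.n_themes + 1):
        uv = u_voice if th in deact else 0.0
        ul = u_lang if th in deact else 0.0
        alpha = base_alpha.copy()
        for i, cat in enumerate(WORD_CATEGORIES):
            if cat in _POSITIVE_WORDS:
                alpha[i] *= np.exp(_WORD_GAIN * ul)
            elif cat in _NEGATIVE_WORDS:
                alpha[i] *= np.exp(-_WORD_GAIN * ul)
        freqs = rng.dirichlet(alpha)[:-1]
        row = {"theme": th,
               "h1h2": 1.0 + _VOICE_GAIN * uv + rng.normal(0.0, sd),
               "rd": 1.0 - _VOICE_GAIN * uv + rng.normal(0.0, sd)}
        row.update({f"liwc_{c}": f for c, f in zip(WORD_CATEGORIES, freqs)})
        rows.append(row)
    return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig
                    ) -> Tuple[List[Session], List[LatentTrait], pd.DataFrame]:
    """Generate (sessions, traits, ground_truth) for one synthetic cohort.

    ``sessions`` holds one Session per participant per set (missing
    modalities are None); ``ground_truth`` is a DataFrame indexed by
    participant with AAQ/AAP/AMMI-style security scores and the latent
    trait itself.  Deterministic given ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants
    ids = [f"p{i:03d}" for i in range(n)]
    z = rng.normal(size=n)
    traits = [LatentTrait(pid, float(zi)) for pid, zi in zip(ids, z)]

    effect = cfg.effect
    # per-modality expressed trait: corr(z, u_m) = effect_size_m
    u = {}
    for m in MODALITIES:
        r = effect[m]
        u[m] = r * z + np.sqrt(max(1.0 - r * r, 0.0)) * rng.normal(size=n)

    block_s = cfg.exposure_s + cfg.response_s + cfg.interstitial_s
    duration_s = block_s * cfg.n_themes
    miss = cfg.miss

    sessions: List[Session] = []
    for set_id in range(1, cfg.n_sets + 1):
        timeline = build_timeline(cfg.n_themes, set_id=set_id,
                                  exposure_s=cfg.exposure_s,
                                  response_s=cfg.response_s,
                                  interstitial_s=cfg.interstitial_s)
        for i, pid in enumerate(ids):
            drop = {m: rng.random() < miss[m] for m in MODALITIES}
            ibi = (None if drop["cardiac"] else
                   _gen_ibi(rng, cfg, u["cardiac"][i], duration_s, block_s))
            eda = (None if drop["eda"] else
                   _gen_eda(rng, cfg, u["eda"][i], duration_s, block_s))
            frames = (None if drop["face"] and drop["gaze"] else
                      _gen_frames(rng, cfg, u["face"][i], u["gaze"][i],
                                  duration_s, block_s))
            responses = (None if drop["voice"] and drop["language"] else
                         _gen_responses(rng, cfg, u["voice"][i], u["language"][i]))
            sessions.append(Session(participant_id=pid, set_id=set_id,
                                    timeline=timeline, ibi=ibi, eda=eda,
                                    frames=frames, responses=responses))

    # ground-truth instruments: linear in the latent trait plus noise
    def instrument():
        return 0.8 * z + 0.6 * rng.normal(size=n)

    gt = pd.DataFrame({
        "participant": ids,
        "aaq_security": instrument(),
        "aap_security": instrument(),
        "ammi_mother": instrument(),
        "ammi_father": instrument(),
        "ammi_partner": instrument(),
        "latent_security": z,
    }).set_index("participant")
    if cfg.ammi_coverage < 1.0 and n > 0:
        for col in ("ammi_mother", "ammi_father", "ammi_partner"):
            keep = rng.random(n) < cfg.ammi_coverage
            gt.loc[~keep, col] = np.nan
    return sessions, traits, gt
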