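"""The three study analyses: correlation screens, confirmatory index
correlation (see :mod:`batkit.composite`), and per-feature stability
checks across stimuli sets.

*Exploratory screen.*  Every feature is correlated with each ground-truth
attachment measure over the theme scope that matches the measure's target
relationship (partner questionnaire -> the attuned-couple theme; general
projective measure -> the mean over the three attuned themes; the
mother / father / partner interview models -> their matching themes).
Pearson is used for measures with enough assessed participants; Spearman
rank otherwise.  No multiple-testing correction is applied by default —
the confirmatory composite index exists precisely to handle the
multiplicity — but Bonferroni / Benjamini-Hochberg modes are available.

*Stability.*  A one-way within-subject (repeated-measures) ANOVA per
feature asks whether responses differ across the stimuli sets that rotate
behind the same themes.  Mauchly's test checks sphericity; when violated
(P < .05) both degrees of freedom are multiplied by the Greenhouse-Geisser
epsilon.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .sessions import FeatureTable

__all__ = [
    "AnovaResult",
    "spearman",
    "explore_correlations",
    "rm_anova",
    "rm_anova_by_feature",
    "stability_summary",
    "multiple_comparison_ledger",
    "DEFAULT_MEASURE_SCOPES",
]

#: ground-truth measure -> themes over which its features are averaged
DEFAULT_MEASURE_SCOPES: Dict[str, Tuple[int, ...]] = {
    "aaq_security": (7,),          # romantic partners -> attuned couple
    "aap_security": (4, 7, 13),    # attachment figures in general
    "ammi_mother": (13,),          # attuned mother-child
    "ammi_father": (4,),           # attuned father-child
    "ammi_partner": (7,),          # attuned couple
}

SMALL_N_SPEARMAN = 30      # below this many assessed participants, use ranks
_EXACT_SPEARMAN_N = 8      # full permutation enumeration up to 8! orderings


from functools import lru_cache


@lru_cache(maxsize=8)
def _exact_rho_null(n: int) -> np.ndarray:
    """|rho| over all n! tie-free rank orderings (universal for given n)."""
    ident = np.arange(n, dtype=float)
    ident -= ident.mean()
    denom = float((ident ** 2).sum())
    vals = np.empty(math.factorial(n))
    for i, perm in enumerate(itertools.permutations(range(n))):
        vals[i] = abs(float((ident[list(perm)] * ident).sum()) / denom)
    return vals


def spearman(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Spearman rho with an exact permutation P for very small samples.

    For n <= 8 the null distribution of rho is enumerated over all n!
    orderings (cached for tie-free ranks, enumerated directly with
    midranks otherwise); beyond that the usual t-approximation is
    returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    rho, p_asym = _stats.spearmanr(x, y)
    if n > _EXACT_SPEARMAN_N or not np.isfinite(rho):
        return float(rho), float(p_asym)
    rx = _stats.rankdata(x)
    ry = _stats.rankdata(y)
    rx = (rx - rx.mean())
    ry = (ry - ry.mean())
    denom = math.sqrt(float((rx ** 2).sum() * (ry ** 2).sum()))
    if denom == 0:
        return float(rho), 1.0
    obs = float((rx * ry).sum()) / denom
    tie_free = (np.unique(rx).size == n and np.unique(ry).size == n)
    if tie_free:
        null = _exact_rho_null(n)
        return float(rho), float(np.mean(null >= abs(obs) - 1e-12))
    count = total = 0
    for perm in itertools.permutations(range(n)):
        stat = float((rx[list(perm)] * ry).sum()) / denom
        if abs(stat) >= abs(obs) - 1e-12:
            count += 1
        total += 1
    return float(rho), count / total


def explore_correlations(table: FeatureTable, ground_truth: pd.DataFrame,
                         scopes: Optional[Dict[str, Sequence[int]]] = None,
                         expected_signs: Optional[Dict[str, int]] = None,
                         alpha: float = 0.05,
                         small_n_threshold: int = SMALL_N_SPEARMAN,
                         correction: Optional[str] = None) -> pd.DataFrame:
    """Correlation screen of every feature against every security measure.

    For each measure, features are first averaged over the measure's theme
    scope (keeping phase and variant separate), then correlated with the
    measure across participants, pairwise-complete.  ``expected_signs``
    maps feature name -> +1/-1; a significant correlation is tagged
    ``theory_consistent`` when its sign matches.  ``correction`` may be
    None (the default), "bonferroni" or "bh".
    """
    scopes = {k: tuple(v) for k, v in (scopes or DEFAULT_MEASURE_SCOPES).items()}
    expected_signs = expected_signs or {}
    rows: List[dict] = []
    df = table.data
    for measure, themes in scopes.items():
        if measure not in ground_truth.columns:
            continue
        gt = ground_truth[measure].dropna()
        method = "pearson" if len(gt) >= small_n_threshold else "spearman"
        sub = df[df["theme"].isin(themes)]
        if sub.empty:
            continue
        # mean over the theme scope, one value per participant per key
        agg = (sub.groupby(["participant", "set", "phase", "variant", "feature"])
               ["value"].mean().reset_index())
        for (s, phase, variant, feat), cell in agg.groupby(
                ["set", "phase", "variant", "feature"]):
            merged = cell.set_index("participant")["value"].to_frame() \
                .join(gt, how="inner").dropna()
            n = len(merged)
            if n < 3:
                continue
            x = merged["value"].to_numpy()
            y = merged[measure].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            if method == "pearson":
                r, p = _stats.pearsonr(x, y)
            else:
                r, p = spearman(x, y)
            exp = expected_signs.get(feat)
            rows.append(dict(measure=measure, themes=str(themes), set=s,
                             phase=phase, variant=variant, feature=feat,
                             method=method, r=float(r), p=float(p), n=n,
                             expected_sign=exp))
    report = pd.DataFrame(rows)
    if report.empty:
        return report
    if correction == "bonferroni":
        report["p_adj"] = np.minimum(report["p"] * len(report), 1.0)
    elif correction == "bh":
        order = np.argsort(report["p"].to_numpy())
        m = len(report)
        adj = np.empty(m)
        ranked = report["p"].to_numpy()[order] * m / (np.arange(m) + 1)
        adj[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        report["p_adj"] = np.minimum(adj, 1.0)
    else:
        report["p_adj"] = report["p"]
    sig = report["p_adj"] < alpha
    has_sign = report["expected_sign"].notna()
    tc = pd.Series(pd.NA, index=report.index, dtype="boolean")
    tc[sig & has_sign] = (np.sign(report.loc[sig & has_sign, "r"])
                          == report.loc[sig & has_sign, "expected_sign"])
    report["significant"] = sig
    report["theory_consistent"] = tc
    return report


@dataclass(frozen=True)
class AnovaResult:
    feature: str
    k: int
    n: int
    f: float
    df_num: float
    df_den: float
    p: float
    mauchly_w: float
    mauchly_p: float
    epsilon_gg: float
    corrected: bool


def _contrasts(k: int) -> np.ndarray:
    """Orthonormal contrasts of k conditions (k x (k-1))."""
    return np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, : k - 1]


def _gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the k x k condition covariance."""
    k = cov.shape[0]
    c = _contrasts(k)
    m = c.T @ cov @ c
    den = (k - 1) * np.trace(m @ m)
    if den <= 0:
        return 1.0
    return float(np.clip(np.trace(m) ** 2 / den, 1.0 / (k - 1), 1.0))


def _mauchly(y: np.ndarray) -> Tuple[float, float]:
    """Mauchly's sphericity test on an n x k within-subject matrix."""
    n, k = y.shape
    if k <= 2:
        return 1.0, 1.0
    c = _contrasts(k)
    e = (y - y.mean(axis=0)) @ c
    s = e.T @ e / (n - 1)
    eig = np.linalg.eigvalsh(s)
    eig = np.maximum(eig, 0.0)
    tr = eig.sum()
    if tr <= 0 or np.any(eig <= 0):
        return 0.0, 0.0
    d = k - 1
    w = float(np.prod(eig) / (tr / d) ** d)
    # second-order chi-square approximation (as in SPSS / ezANOVA)
    f = 1.0 - (2 * d * d + d + 2) / (6.0 * d * (n - 1))
    w2 = ((d + 2) * (d - 1) * (d - 2) * (2 * d ** 3 + 6 * d * d + 3 * k + 2)
          / (288.0 * ((n - 1) * d * f) ** 2))
    chi2 = -(n - 1) * f * math.log(max(w, 1e-300))
    ddf = d * (d + 1) // 2 - 1
    p1 = _stats.chi2.sf(chi2, ddf)
    p2 = _stats.chi2.sf(chi2, ddf + 4)
    p = float(p1 + w2 * (p2 - p1))
    return w, p


def rm_anova(y: np.ndarray, feature: str = "", alpha: float = 0.05) -> AnovaResult:
    """One-way repeated-measures ANOVA on an n x k complete-case matrix.

    When Mauchly's test rejects sphericity at ``alpha``, both degrees of
    freedom are multiplied by the Greenhouse-Geisser epsilon.  With k = 2
    sphericity holds trivially and epsilon is exactly 1.
    """
    y = np.asarray(y, dtype=float)
    n, k = y.shape
    if n < 3 or k < 2:
        raise ValueError("rm_anova needs >= 3 subjects and >= 2 conditions")
    grand = y.mean()
    ss_cond = n * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((y.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df_num = float(k - 1)
    df_den = float((n - 1) * (k - 1))
    ms_cond = ss_cond / df_num
    ms_err = ss_err / df_den if df_den > 0 else np.nan
    f = ms_cond / ms_err if ms_err > 0 else 0.0
    cov = np.cov(y, rowvar=False, ddof=1)
    eps = 1.0 if k == 2 else _gg_epsilon(np.atleast_2d(cov))
    w, mp = _mauchly(y)
    corrected = bool(k > 2 and mp < alpha)
    if corrected:
        df_num *= eps
        df_den *= eps
    p = float(_stats.f.sf(f, df_num, df_den)) if f > 0 else 1.0
    return AnovaResult(feature=feature, k=k, n=n, f=float(f),
                       df_num=df_num, df_den=df_den, p=p,
                       mauchly_w=w, mauchly_p=mp,
                       epsilon_gg=eps, corrected=corrected)


def rm_anova_by_feature(table: FeatureTable, features: Sequence[Tuple],
                        themes: Sequence[int] = (4, 7, 13),
                        alpha: float = 0.05) -> List[AnovaResult]:
    """RM-ANOVA across stimuli sets for each (phase, variant, feature) key.

    Feature values are first averaged over ``themes`` per participant per
    set; only participants observed in every set enter (complete cases).
    Features with fewer than 3 complete cases or fewer than 2 sets are
    skipped.
    """
    df = table.data
    df = df[df["theme"].isin(list(themes))]
    results: List[AnovaResult] = []
    for phase, variant, feat in features:
        sub = df[(df["phase"] == phase) & (df["variant"] == variant)
                 & (df["feature"] == feat)]
        if sub.empty:
            continue
        agg = (sub.groupby(["participant", "set"])["value"].mean()
               .unstack("set").dropna())
        if agg.shape[0] < 3 or agg.shape[1] < 2:
            continue
        name = f"{feat}|{phase}|{variant}"
        results.append(rm_anova(agg.to_numpy(), feature=name, alpha=alpha))
    return results


def stability_summary(results: Sequence[AnovaResult],
                      alpha: float = 0.05) -> Tuple[int, int, float]:
    """How many features differ across stimuli sets at ``alpha``.

    Returns (n_different, n_total, fraction).
    """
    if not results:
        raise ValueError("no ANOVA results to summarize")
    n_total = len(results)
    n_diff = sum(1 for r in results if r.p < alpha)
    return n_diff, n_total, n_diff / n_total


def multiple_comparison_ledger(n_features: int = 46, n_sets: int = 3,
                               alpha: float = 0.05) -> Dict[str, float]:
    """Bookkeeping behind the no-Bonferroni decision.

    Testing ``n_features`` features across ``n_sets`` stimuli sets amounts
    to n_features * n_sets F tests; a Bonferroni correction would divide
    ``alpha`` by that count.
    """
    n_tests = n_features * n_sets
    return {"n_features": n_features, "n_sets": n_sets, "n_tests": n_tests,
            "alpha": alpha, "bonferroni_alpha": alpha / n_tests}
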