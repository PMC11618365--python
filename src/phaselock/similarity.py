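"""Human-model behavioral similarity statistics and uncertainty machinery.

Similarity between condition-wise human and model scores is quantified two
ways: the Pearson correlation (relative performance across conditions) and
the RMS error after min-max normalizing with the *human* scale (absolute
performance, comparable across experiments with different units).
Uncertainty comes from bootstrapping over units (observers or network
architectures); significance of a manipulation comes from a Gaussian fit to
a bootstrapped null distribution, or from a within-unit permutation test
for the interaction between a between-unit factor and a two-level
within-unit factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SimilarityReport",
    "pearson_similarity",
    "minmax_rms",
    "bootstrap_stats",
    "reliability_corrected_r2",
    "permutation_interaction_test",
]


@dataclass
class SimilarityReport:
    """Bootstrap summary of a per-unit score distribution."""

    mean: float
    ci95: tuple[float, float]
    p_two_tailed: float | None
    n_boot: int
    seed: int | None

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.mean + 1e-12 and self.mean - 1e-12 <= hi):
            raise ValueError("CI must bracket the mean")


def pearson_similarity(human, model) -> float:
    """Pearson correlation between analogous human and model data points."""
    h = np.asarray(human, float)
    m = np.asarray(model, float)
    if h.shape != m.shape or h.size < 3:
        raise ValueError("need matched vectors of length >= 3")
    if not (np.all(np.isfinite(h)) and np.all(np.isfinite(m))):
        raise ValueError("inputs must be finite")
    if np.ptp(h) == 0 or np.ptp(m) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(h, m).statistic)


def minmax_rms(human, model, groups=None) -> float:
    """RMS error after min-max normalization with human-derived scaling.

    Within each scaling group, human data are rescaled to [0, 1]
    (subtracting the human minimum and dividing by the human range) and the
    *same* offset and scale are applied to the model data. Shared groups
    across related experiments stop null-effect experiments (flat human
    data within one experiment) from yielding an artificially zero error.
    """
    h = np.asarray(human, float)
    m = np.asarray(model, float)
    if h.shape != m.shape:
        raise ValueError("human and model must have matching shapes")
    if groups is None:
        groups = np.zeros(h.shape, dtype=int)
    groups = np.asarray(groups)
    hn = np.empty_like(h)
    mn = np.empty_like(m)
    for g in np.unique(groups):
        idx = groups == g
        lo, hi = h[idx].min(), h[idx].max()
        if hi == lo:
            raise ValueError(f"flat human data in scaling group {g!r}")
        hn[idx] = (h[idx] - lo) / (hi - lo)
        mn[idx] = (m[idx] - lo) / (hi - lo)
    return float(np.sqrt(np.mean((hn - mn) ** 2)))


def bootstrap_stats(
    values,
    n_boot: int = 1000,
    seed: int | None = None,
    null_values=None,
) -> SimilarityReport:
    """Bootstrap the mean of per-unit scores; optional Gaussian-null p-value.

    The 95% CI is the percentile interval of the resampled mean of
    ``values``. When ``null_values`` (scores of a reference condition) are
    given, their bootstrapped means are fitted with a Normal and a
    two-tailed p-value for mean(values) under that null is returned.
    """
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("need at least 2 units to bootstrap")
    rng = np.random.default_rng(seed)
    boots = rng.choice(v, size=(n_boot, v.size), replace=True).mean(axis=1)
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    mean = float(v.mean())
    p = None
    if null_values is not None:
        nv = np.asarray(null_values, float)
        if nv.size < 2:
            raise ValueError("need at least 2 null units")
        null_boots = rng.choice(nv, size=(n_boot, nv.size), replace=True).mean(axis=1)
        mu, sd = float(null_boots.mean()), float(null_boots.std(ddof=1))
        if sd == 0:
            p = 1.0 if np.isclose(mean, mu) else 0.0
        else:
            z = (mean - mu) / sd
            p = float(2 * stats.norm.sf(abs(z)))
    # clamp CI onto the mean for degenerate (all-equal) inputs
    ci = (min(ci[0], mean), max(ci[1], mean))
    return SimilarityReport(mean, ci, p, n_boot, seed)


def spearman_brown(r: float) -> float:
    """Split-half reliability corrected to full length: 2r / (1 + r)."""
    return 2.0 * r / (1.0 + r)


def reliability_corrected_r2(r: float, human_halves, model_halves) -> float:
    """Fraction of explainable variance explained.

    ``human_halves`` and ``model_halves`` are (half1, half2) pairs of
    condition-wise means computed from disjoint halves of the units. The
    split-half correlation of each side is Spearman-Brown corrected, and
    the human-model r^2 is divided by the product of the two reliabilities.
    """
    h1, h2 = (np.asarray(a, float) for a in human_halves)
    m1, m2 = (np.asarray(a, float) for a in model_halves)
    r_h = float(stats.pearsonr(h1, h2).statistic)
    r_m = float(stats.pearsonr(m1, m2).statistic)
    if r_h <= 0 or r_m <= 0:
        raise ValueError("non-positive split-half reliability")
    rel_h = spearman_brown(r_h)
    rel_m = spearman_brown(r_m)
    return float(r**2 / (rel_h * rel_m))


def _interaction_f(scores: np.ndarray, group_ids: np.ndarray) -> float:
    """F for the group x condition interaction with 2 within levels.

    With two within-unit conditions, the interaction F equals the one-way
    ANOVA F of the per-unit condition differences across groups.
    """
    d = scores[:, 1] - scores[:, 0]
    samples = [d[group_ids == g] for g in np.unique(group_ids)]
    return float(stats.f_oneway(*samples).statistic)


def permutation_interaction_test(
    scores,
    between_labels,
    n_perm: int = 10000,
    seed: int | None = None,
) -> dict:
    """Permutation test for a between x within interaction.

    ``scores`` is a [units x 2] table of within-condition values;
    ``between_labels`` assigns each unit to a between-unit group. The
    F-statistic of the interaction is recomputed ``n_perm`` times with the
    two within-condition labels independently swapped within each unit
    (exchangeable under the null of no within-factor effect), and the
    p-value is (1 + #{F_perm >= F_obs}) / (n_perm + 1).
    """
    s = np.asarray(scores, float)
    if s.ndim != 2 or s.shape[1] != 2:
        raise ValueError("scores must be [units x 2] (balanced 2-level within factor)")
    labels = np.asarray(between_labels)
    if labels.shape[0] != s.shape[0]:
        raise ValueError("one between-group label per unit")
    groups, counts = np.unique(labels, return_counts=True)
    if groups.size < 2 or np.any(counts < 2):
        raise ValueError("need >= 2 groups with >= 2 units each")
    f_obs = _interaction_f(s, labels)
    if not np.isfinite(f_obs):
        # zero variance in the within-unit differences: every permutation
        # reproduces the observed statistic exactly
        return {"f": f_obs, "p": 1.0, "n_perm": n_perm, "seed": seed}
    rng = np.random.default_rng(seed)
    n_units = s.shape[0]
    exceed = 0
    for _ in range(n_perm):
        flip = rng.random(n_units) < 0.5
        perm = s.copy()
        perm[flip] = perm[flip][:, ::-1]
        if _interaction_f(perm, labels) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return {"f": f_obs, "p": p, "n_perm": n_perm, "seed": seed}
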