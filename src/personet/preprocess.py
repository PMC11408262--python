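"""Expression preprocessing and profile group statistics.

The expression matrix is subjects x genes on the log2 scale.  Preprocessing
follows the standard microarray route: quantile normalization across
subjects, then selection of the most variable genes.  Group differences
between personality profiles are tested with one-way ANOVA, Tukey's HSD for
pairwise contrasts, a Bonferroni-corrected alpha, and point-biserial Pearson
correlations as effect sizes on the conventional scale where |r| of 0.20,
0.50 and 0.80 mark small, medium and large effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from ._util import ValidationError

PROFILE_ORDER = ("creative", "organized", "unregulated")


@dataclass
class PairwiseComparison:
    pair: tuple[str, str]
    tukey_p: float
    adjusted_p: float
    effect_size_r: float
    degenerate: bool = False


@dataclass
class GroupComparisonResult:
    """One-way ANOVA over profile groups plus pairwise follow-up."""

    F: float
    p: float
    pairwise: list[PairwiseComparison] = field(default_factory=list)
    bonferroni_alpha: float = 0.05
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "F": self.F,
            "p": self.p,
            "bonferroni_alpha": self.bonferroni_alpha,
            "degenerate": self.degenerate,
            "pairwise": [
                {"pair": list(c.pair), "tukey_p": c.tukey_p,
                 "adjusted_p": c.adjusted_p, "effect_size_r": c.effect_size_r,
                 "degenerate": c.degenerate}
                for c in self.pairwise
            ],
        }


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize subjects (rows) to the mean quantile vector.

    After normalization every subject's sorted expression vector equals the
    across-subject mean of the sorted vectors; tied values within a subject
    receive the average of the reference quantiles they span.
    """
    values = np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValidationError("quantile_normalize needs a 2-D matrix with >=2 subjects")
    if not np.isfinite(values).all():
        raise ValidationError("quantile_normalize: input contains non-finite values")
    n_genes = values.shape[1]
    reference = np.sort(values, axis=1).mean(axis=0)
    ranks = np.apply_along_axis(stats.rankdata, 1, values)  # average ranks, 1-based
    out = np.interp(ranks, np.arange(1, n_genes + 1), reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def select_variable_genes(matrix: pd.DataFrame, n: int,
                          between_profile: bool = False,
                          labels: dict | None = None) -> list[str]:
    """The ``n`` genes with the largest variance, most variable first.

    Variance is computed across all subjects pooled; ties are broken by
    ascending gene identifier.  With ``between_profile=True`` the ranking
    uses the variance of per-profile mean expression instead (requires
    ``labels``).
    """
    if n <= 0:
        raise ValidationError("select_variable_genes: n must be positive")
    if n > matrix.shape[1]:
        raise ValidationError(
            f"select_variable_genes: n={n} exceeds gene count {matrix.shape[1]}")
    if between_profile:
        if labels is None:
            raise ValidationError("between_profile ranking requires labels")
        groups = pd.Series(labels).reindex(matrix.index)
        variance = matrix.groupby(groups, observed=True).mean().var(axis=0, ddof=1)
    else:
        variance = matrix.var(axis=0, ddof=1)
    order = sorted(matrix.columns, key=lambda g: (-variance[g], str(g)))
    return order[:n]


def _group_arrays(values, labels) -> dict[str, np.ndarray]:
    if isinstance(values, pd.Series):
        s = values.astype(float)
        lab = pd.Series(labels).reindex(s.index)
    else:
        keys = list(labels.keys())
        s = pd.Series(np.asarray(values, dtype=float), index=keys)
        lab = pd.Series([labels[k] for k in keys], index=keys)
    return {g: s[lab == g].to_numpy() for g in pd.unique(lab.dropna())}


def profile_anova(values, labels, alpha: float = 0.05) -> GroupComparisonResult:
    """Classical one-way ANOVA plus Tukey HSD over all profile pairs.

    ``values`` is a per-subject vector (pd.Series indexed by subject, or an
    array ordered like ``labels``); ``labels`` maps subject -> profile.
    The Bonferroni-corrected alpha over the pairwise family is reported.
    """
    groups = _group_arrays(values, labels)
    if len(groups) < 2:
        raise ValidationError("profile_anova: need at least two groups")
    for g, arr in groups.items():
        if len(arr) < 2:
            raise ValidationError(f"profile_anova: group {g!r} has n < 2")
    arrays = list(groups.values())
    names = list(groups.keys())
    within_var = sum(a.var(ddof=1) for a in arrays)
    degenerate = within_var == 0.0
    if degenerate:
        means = [a.mean() for a in arrays]
        if max(means) == min(means):
            F, p = 0.0, 1.0
        else:
            F, p = np.inf, 0.0
    else:
        F, p = stats.f_oneway(*arrays)
    n_pairs = len(names) * (len(names) - 1) // 2
    bonferroni_alpha = alpha / max(n_pairs, 1)
    pairwise = []
    if not degenerate:
        flat = np.concatenate(arrays)
        flat_groups = np.concatenate([[g] * len(groups[g]) for g in names])
        tukey = pairwise_tukeyhsd(flat, flat_groups, alpha=alpha)
        uniq = [str(g) for g in tukey.groupsunique]
        for (a, b), tukey_p in zip(combinations(uniq, 2), tukey.pvalues):
            r, deg = pairwise_effect_size(
                np.concatenate([groups[a], groups[b]]),
                np.concatenate([np.zeros(len(groups[a])),
                                np.ones(len(groups[b]))]))
            pairwise.append(PairwiseComparison(
                pair=(a, b), tukey_p=float(tukey_p),
                adjusted_p=min(1.0, float(tukey_p) * n_pairs),
                effect_size_r=r, degenerate=deg))
    return GroupComparisonResult(F=float(F), p=float(p), pairwise=pairwise,
                                 bonferroni_alpha=bonferroni_alpha,
                                 degenerate=degenerate)


def pairwise_effect_size(values, group_indicator) -> tuple[float, bool]:
    """Point-biserial Pearson r between a 0/1 group indicator and values.

    Returns ``(r, degenerate)``; for constant values (or a constant
    indicator) r is undefined and reported as 0.0 with the degenerate flag
    set.  Sign convention: the group coded 0 comes first, so positive r means
    the group coded 1 has the larger mean.
    """
    x = np.asarray(group_indicator, dtype=float)
    y = np.asarray(values, dtype=float)
    if set(np.unique(x)) - {0.0, 1.0}:
        raise ValidationError("pairwise_effect_size: indicator must be 0/1")
    if len(np.unique(x)) < 2:
        return 0.0, True
    if np.ptp(y) == 0:
        return 0.0, True
    r = float(np.corrcoef(x, y)[0, 1])
    return r, False


@dataclass
class BootstrapAnovaResult:
    mean_F: float
    ci_low: float
    ci_high: float
    replicate_F: list[float]
    pairwise_r: dict[str, float]
    n_boot: int

    def to_dict(self) -> dict:
        return {"mean_F": self.mean_F, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "n_boot": self.n_boot,
                "pairwise_r": self.pairwise_r}


def bootstrap_profile_anova(matrix: pd.DataFrame, labels: dict,
                            n_boot: int = 100, seed: int = 0,
                            ci: float = 0.95) -> BootstrapAnovaResult:
    """Bootstrap ANOVA over selected genes averaged within profiles.

    Per replicate, subjects are resampled with replacement within each
    profile; each gene's within-profile mean expression is computed; and a
    one-way ANOVA is run with genes as observations and profiles as groups.
    F is aggregated over replicates, and pairwise point-biserial effect
    sizes between the per-gene profile means are averaged.
    """
    if n_boot < 1:
        raise ValidationError("bootstrap_profile_anova: n_boot must be >= 1")
    lab = pd.Series(labels).reindex(matrix.index)
    expected = set(labels.values())
    present = set(lab.dropna())
    missing = expected - present
    if missing:
        raise ValidationError(
            f"bootstrap_profile_anova: profile(s) empty after restriction to "
            f"the matrix subjects: {sorted(missing)}")
    profiles = [p for p in PROFILE_ORDER if p in present] or sorted(present)
    members = {p: np.flatnonzero((lab == p).to_numpy()) for p in profiles}
    values = np.asarray(matrix, dtype=float)
    rng = np.random.default_rng(seed)
    fs = []
    pair_rs: dict[str, list[float]] = {}
    for _ in range(n_boot):
        means = {}
        for p, idx in members.items():
            draw = rng.choice(idx, size=len(idx), replace=True)
            means[p] = values[draw].mean(axis=0)  # per-gene profile mean
        F, _ = stats.f_oneway(*means.values())
        fs.append(float(F))
        for i, a in enumerate(profiles):
            for b in profiles[i + 1:]:
                r, _ = pairwise_effect_size(
                    np.concatenate([means[a], means[b]]),
                    np.concatenate([np.zeros(len(means[a])),
                                    np.ones(len(means[b]))]))
                pair_rs.setdefault(f"{a}_vs_{b}", []).append(r)
    fs_arr = np.asarray(fs)
    tail = (1 - ci) / 2
    return BootstrapAnovaResult(
        mean_F=float(fs_arr.mean()),
        ci_low=float(np.quantile(fs_arr, tail)),
        ci_high=float(np.quantile(fs_arr, 1 - tail)),
        replicate_F=[float(f) for f in fs],
        pairwise_r={k: float(np.mean(v)) for k, v in pair_rs.items()},
        n_boot=n_boot)
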