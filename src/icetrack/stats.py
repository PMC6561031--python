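"""Statistical layer: Monte-Carlo Fisher's exact test on focus-count
distributions, proportional count scaling, and thin parametric wrappers.

The central piece is :func:`fisher_exact_mc`, a simulated-p-value Fisher's
exact test for general R x K contingency tables. The test statistic is the
probability of the table under the fixed-margin (multivariate hypergeometric)
null; ``B`` tables are sampled with the same margins and the p-value is

    p = (1 + #{simulated tables at least as extreme}) / (B + 1),

"as extreme" meaning a null probability less than or equal to the observed
one. The smallest attainable p is therefore 1/(B+1) -- 0.0005 at B = 2000.

Focus distributions from groups of different sizes are first scaled to a
common total with largest-remainder rounding (:func:`scale_distribution`), so
that percent-normalized distributions can be compared as integer counts.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "MCFisherResult",
    "scale_distribution",
    "fisher_exact_mc",
    "compare_groups",
    "ttest_one_sided",
    "anova_tukey",
    "basic_tests",
]


@dataclass(frozen=True)
class MCFisherResult:
    """Result of a Monte-Carlo Fisher's exact test."""

    p_value: float
    B: int
    log_prob_observed: float
    n_as_extreme: int
    seed: Optional[int]

    def __post_init__(self):
        lo = 1.0 / (self.B + 1)
        if not lo <= self.p_value <= 1.0:
            raise ValueError("p_value outside [1/(B+1), 1]")


def scale_distribution(counts: Sequence[int], target_n: int) -> np.ndarray:
    """Scale integer counts proportionally so they sum to ``target_n``.

    Uses largest-remainder rounding: floors of the scaled quantities are
    taken first and the remaining units go to the largest fractional parts
    (ties to the lower index), so the total is conserved exactly and scaling
    a distribution to its own total is the identity.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    total = counts.sum()
    if total == 0:
        raise ValueError("cannot scale an all-zero distribution")
    if target_n <= 0:
        raise ValueError("target_n must be positive")
    quotas = counts * (target_n / total)
    floors = np.floor(quotas).astype(int)
    remainder = target_n - floors.sum()
    if remainder > 0:
        frac = quotas - floors
        # argsort is stable, so equal fractions resolve to the lower index
        order = np.argsort(-frac, kind="stable")
        floors[order[:remainder]] += 1
    return floors


def _log_table_prob(table: np.ndarray) -> float:
    """Log-probability of a table under the fixed-margin null."""
    n = table.sum()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    return float(
        gammaln(rows + 1).sum()
        + gammaln(cols + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def _sample_fixed_margin(rng: np.random.Generator, rows: np.ndarray,
                         cols: np.ndarray) -> np.ndarray:
    """Sample one table with the given margins, uniformly over the
    multivariate hypergeometric null, by sequential column filling."""
    remaining = rows.copy()
    out = np.empty((rows.size, cols.size), dtype=np.int64)
    for j, c in enumerate(cols[:-1]):
        draw = rng.multivariate_hypergeometric(remaining, int(c))
        out[:, j] = draw
        remaining -= draw
    out[:, -1] = remaining
    return out


def fisher_exact_mc(table, B: int = 2000, seed: Optional[int] = None,
                    rng: Optional[np.random.Generator] = None) -> MCFisherResult:
    """Monte-Carlo Fisher's exact test for an R x K table.

    Parameters
    ----------
    table
        Nonnegative integer contingency table (groups x classes).
    B
        Number of simulated tables (>= 1); 2000 is the conventional setting.
    seed, rng
        Either a seed or an explicit generator; the seed is recorded in the
        result for reproducibility.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if np.any(table < 0):
        raise ValueError("table entries must be nonnegative")
    if B < 1:
        raise ValueError("B must be >= 1")
    cols = table.sum(axis=0)
    table = table[:, cols > 0]   # all-zero classes carry no information
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if np.any(rows == 0) or table.shape[1] < 2:
        raise ValueError("degenerate margins: a zero group or fewer than two "
                         "non-empty classes")
    if rng is None:
        rng = np.random.default_rng(seed)
    log_obs = _log_table_prob(table)
    # tolerance guards against float noise when a simulated table ties the
    # observed probability exactly
    tol = 1e-9 * max(1.0, abs(log_obs))
    n_extreme = 0
    for _ in range(B):
        sim = _sample_fixed_margin(rng, rows, cols)
        if _log_table_prob(sim) <= log_obs + tol:
            n_extreme += 1
    p = (1 + n_extreme) / (B + 1)
    return MCFisherResult(p_value=p, B=B, log_prob_observed=log_obs,
                          n_as_extreme=n_extreme, seed=seed)


def compare_groups(dist_a, dist_b, B: int = 2000,
                   seed: Optional[int] = None) -> MCFisherResult:
    """Compare two focus-count distributions by the MC Fisher test.

    ``dist_b`` is scaled to ``dist_a``'s total with largest-remainder
    rounding (percent normalization on a common integer total), the two are
    stacked into a 2 x K table, focus classes empty in both groups are
    dropped, and :func:`fisher_exact_mc` is run.

    The arguments may be :class:`~icetrack.lineage.FocusDistribution` objects
    or plain count sequences.
    """
    a = np.asarray(getattr(dist_a, "counts", dist_a), dtype=np.int64)
    b = np.asarray(getattr(dist_b, "counts", dist_b), dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError("distributions must cover the same focus classes")
    b_scaled = scale_distribution(b, int(a.sum()))
    stacked = np.vstack([a, b_scaled])
    keep = stacked.sum(axis=0) > 0
    return fisher_exact_mc(stacked[:, keep], B=B, seed=seed)


def ttest_one_sided(a, b, alternative: str = "greater") -> dict:
    """One-sided two-sample Welch t test (mean of ``a`` vs mean of ``b``)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    res = sps.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return {
        "t": float(res.statistic),
        "p_value": float(res.pvalue),
        "mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)),
        "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1)),
        "alternative": alternative,
    }


def anova_tukey(groups: dict, alpha: float = 0.05) -> dict:
    """One-way ANOVA with post hoc Tukey HSD pairwise contrasts.

    ``groups`` maps label -> 1-d samples. Returns the F statistic, ANOVA
    p-value, per-group summaries and the Tukey contrast table.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    labels = list(groups)
    samples = [np.asarray(groups[k], float) for k in labels]
    if len(samples) < 2 or any(s.size < 2 for s in samples):
        raise ValueError("need >= 2 groups with n >= 2 each")
    f_stat, p = sps.f_oneway(*samples)
    values = np.concatenate(samples)
    codes = np.concatenate([np.full(s.size, k) for s, k in zip(samples, labels)])
    tukey = pairwise_tukeyhsd(values, codes, alpha=alpha)
    from itertools import combinations

    pairs = list(combinations(tukey.groupsunique, 2))
    contrasts = [
        {
            "group1": str(g1), "group2": str(g2),
            "meandiff": float(md), "p_adj": float(pv),
            "reject": bool(rej),
        }
        for (g1, g2), md, pv, rej in zip(
            pairs, tukey.meandiffs, tukey.pvalues, tukey.reject
        )
    ]
    return {
        "F": float(f_stat),
        "p_value": float(p),
        "groups": {
            k: {"n": int(s.size), "mean": float(s.mean()), "sd": float(s.std(ddof=1))}
            for k, s in zip(labels, samples)
        },
        "tukey": contrasts,
    }


def basic_tests(groups: dict, alpha: float = 0.05) -> dict:
    """Standard comparisons used around the focus distributions: one-sided t
    test for two groups, ANOVA + Tukey for two or more."""
    out = {"anova": anova_tukey(groups, alpha=alpha)}
    if len(groups) == 2:
        a, b = (np.asarray(v, float) for v in groups.values())
        out["t_test"] = ttest_one_sided(a, b)
    return out
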