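"""tc / non-tc classification from eCherry fluorescence.

The transfer-competent (tc) subpopulation carries an active P_inR-eCherry
reporter and shows up as the upper tail of the single-cell eCherry
distribution, deviating from the quantile-quantile line of a single lognormal
population. The assay is one-sided by construction: we assume one dominant
dim (non-tc) population plus an optional bright tail, never a general
mixture.

Algorithm (on log-transformed values):

1. *Compression-aware QQ fit.* If a fraction ``f`` of cells belongs to the
   bright tail, the mixture order statistic at plotting position ``p`` (for
   ``p`` below the tail) sits at the non-tc quantile ``p / (1 - f)``, not at
   ``p`` -- fitting a normal to raw mixture quantiles is therefore biased as
   soon as ``f`` is non-negligible. We fit ``x_(p) = mu + sigma *
   Phi^-1(p / (1 - f))`` by least squares on the lower plotting band
   (default 5th-45th percentile, pure non-tc for any ``f < 0.55``) over a
   grid of candidate ``f``, profiling out ``mu`` and ``sigma``.
2. *Refit on the sub-threshold cells.* With the profiled fit, cells above
   ``mu + sigma * z_{1-alpha}`` are provisionally tc; the remaining cells are
   an essentially pure non-tc sample, on which a plain normal QQ fit is
   unbiased. One refit-and-rethreshold pass removes any residual dependence
   on the grid resolution.
3. *Tail count.* The tc fraction estimate is the fraction of cells above the
   final threshold, minus the expected non-tc false positives
   ``alpha * (1 - f)``.

Everything operates on ratios of the input values, so assignments are
invariant to rescaling the fluorescence units.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["QQResult", "qq_subpopulation", "classify_first_frame",
           "refine_by_offspring"]

MIN_CELLS = 50


@dataclass(frozen=True)
class QQResult:
    """Output of :func:`qq_subpopulation`."""

    tc_fraction: float           # corrected tail-fraction estimate
    n: int
    threshold: float             # on the original (linear) fluorescence scale
    mu_log: float                # fitted non-tc log-mean
    sigma_log: float             # fitted non-tc log-sd
    is_tc: np.ndarray            # provisional per-cell boolean, input order
    qq_residual: np.ndarray      # per-cell deviation from the fitted QQ line

    @property
    def classes(self) -> np.ndarray:
        return np.where(self.is_tc, "tc", "non_tc")


def _profile_fit(x_sorted: np.ndarray, band: tuple[float, float],
                 f_grid: np.ndarray) -> tuple[float, float, float]:
    """LS fit of sorted log values against Phi^-1(p/(1-f)) on the band,
    profiling over the tail fraction f. Returns (f, mu, sigma)."""
    n = x_sorted.size
    p = (np.arange(n) + 0.5) / n
    in_band = (p >= band[0]) & (p <= band[1])
    xb, pb = x_sorted[in_band], p[in_band]
    best = (np.inf, 0.0, 0.0, 1.0)
    for f in f_grid:
        q = pb / (1.0 - f)
        if q[-1] >= 0.999:
            continue
        z = norm.ppf(q)
        zc = z - z.mean()
        denom = float(zc @ zc)
        if denom <= 0:
            continue
        sigma = float(zc @ (xb - xb.mean())) / denom
        if sigma <= 0:
            continue
        mu = float(xb.mean() - sigma * z.mean())
        sse = float(np.sum((xb - mu - sigma * z) ** 2))
        if sse < best[0]:
            best = (sse, f, mu, sigma)
    if not np.isfinite(best[0]):
        raise RuntimeError("QQ profile fit failed on all candidate fractions")
    return best[1], best[2], best[3]


def qq_subpopulation(values, band: tuple[float, float] = (0.05, 0.45),
                     max_fraction: float = 0.6, tail_alpha: float = 2e-5,
                     grid_step: float = 0.005) -> QQResult:
    """Estimate the bright (tc) subpopulation fraction from eCherry values.

    Parameters
    ----------
    values
        Per-cell fluorescence, strictly positive, length >= 50.
    band
        Plotting-position band used for the non-tc normal fit; must stay
        below the smallest tail the caller wants to resolve.
    max_fraction
        Upper limit of the profiled tail fraction grid.
    tail_alpha
        Upper-tail mass of the fitted non-tc normal allowed above the
        classification threshold (``threshold = mu + sigma * z_{1-alpha}``).
    """
    values = np.asarray(values, dtype=float)
    if values.size < MIN_CELLS:
        raise ValueError(f"need at least {MIN_CELLS} cells, got {values.size}")
    if np.any(~np.isfinite(values)) or np.any(values <= 0):
        raise ValueError("fluorescence values must be finite and > 0")

    logx = np.log(values)
    order = np.argsort(logx, kind="stable")
    x_sorted = logx[order]
    n = x_sorted.size

    f_grid = np.arange(0.0, max_fraction + 1e-12, grid_step)
    _, mu, sigma = _profile_fit(x_sorted, band, f_grid)

    z_cut = norm.ppf(1.0 - tail_alpha)
    for _ in range(2):  # refit on the sub-threshold (essentially pure) sample
        thr = mu + sigma * z_cut
        non_tc = x_sorted[x_sorted <= thr]
        if non_tc.size < MIN_CELLS:
            break
        m = non_tc.size
        p = (np.arange(m) + 0.5) / m
        in_band = (p >= band[0]) & (p <= 0.90)
        z = norm.ppf(p[in_band])
        xb = non_tc[in_band]
        zc = z - z.mean()
        sigma_new = float(zc @ (xb - xb.mean())) / float(zc @ zc)
        if sigma_new <= 0:
            break
        mu, sigma = float(xb.mean() - sigma_new * z.mean()), sigma_new

    thr = mu + sigma * z_cut
    is_tc = logx > thr
    count = int(is_tc.sum())
    expected_fp = tail_alpha * (n - count)
    frac = max(0.0, (count - expected_fp) / n)

    p_all = (np.arange(n) + 0.5) / n
    resid_sorted = x_sorted - (mu + sigma * norm.ppf(p_all))
    residual = np.empty(n)
    residual[order] = resid_sorted

    return QQResult(tc_fraction=float(frac), n=n, threshold=float(np.exp(thr)),
                    mu_log=mu, sigma_log=sigma, is_tc=is_tc,
                    qq_residual=residual)


def classify_first_frame(cell_table: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Provisionally classify the first-frame (founder) cells of a movie.

    Returns a DataFrame with cell_id, echerry, class ('tc'/'non_tc') and
    qq_residual. Descendants inherit the founder's class downstream.
    """
    first = cell_table["frame"].min()
    founders = (cell_table[cell_table["frame"] == first]
                .drop_duplicates("cell_id").sort_values("cell_id"))
    res = qq_subpopulation(founders["echerry"].to_numpy(), **kwargs)
    return pd.DataFrame({
        "cell_id": founders["cell_id"].to_numpy(),
        "echerry": founders["echerry"].to_numpy(),
        "class": res.classes,
        "qq_residual": res.qq_residual,
    })


def refine_by_offspring(assignments: pd.DataFrame, lineage: pd.DataFrame,
                        min_offspring: int = 8) -> pd.DataFrame:
    """Exclude poorly regrowing provisional non-tc founders.

    Founders labelled non_tc whose final offspring count is below
    ``min_offspring`` (default 8 live descendants in the last frame) are
    relabelled ``excluded``: they may be tc cells with low eCherry. tc labels
    are never changed by this rule.
    """
    offspring = lineage.set_index("cell_id")["offspring_final"]
    missing = [c for c in assignments["cell_id"] if c not in offspring.index]
    if missing:
        raise ValueError(
            f"no lineage entry for classified founder(s): {missing[:10]}"
        )
    out = assignments.copy()
    counts = offspring.loc[out["cell_id"]].to_numpy()
    out["offspring_final"] = counts
    demote = (out["class"] == "non_tc") & (counts < min_offspring)
    out.loc[demote, "class"] = "excluded"
    return out
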