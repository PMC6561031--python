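"""Midcell-axis focus geometry: ploidy classes by cell length, CFP/YFP focus
pairing, and interfocal-distance summaries.

Cells of 0.8-1.8 um carry on average a single chromosome copy (oneX); cells
of 1.8-3.0 um are replicating and carry two (twoX). Interfocal distances are
full 2D displacements (axial plus transverse) reported in nanometers. In
twoX cells the two focus pairs are matched within the same cell half, a
geometric surrogate for "same replichore".
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

__all__ = ["FocusPair", "classify_ploidy", "project_foci", "pair_foci",
           "pair_foci_table", "interfocal_summary",
           "ONEX_RANGE", "TWOX_RANGE"]

ONEX_RANGE = (0.8, 1.8)   # um, lower-closed / upper-open
TWOX_RANGE = (1.8, 3.0)   # um, closed


@dataclass(frozen=True)
class FocusPair:
    cell_id: int
    cfp_axial: float          # um from the bottom pole
    yfp_axial: float
    distance_nm: float        # full 2D CFP-YFP displacement
    ploidy_class: str
    same_half: bool


def classify_ploidy(cell_length: float) -> str:
    """Chromosome-copy class from cell length (um).

    [0.8, 1.8) -> 'oneX'; [1.8, 3.0] -> 'twoX'; otherwise 'out_of_range'.
    The 1.8 um boundary belongs to twoX (lower-closed intervals).
    """
    if not np.isfinite(cell_length) or cell_length <= 0:
        raise ValueError(f"cell length must be positive, got {cell_length}")
    if ONEX_RANGE[0] <= cell_length < ONEX_RANGE[1]:
        return "oneX"
    if TWOX_RANGE[0] <= cell_length <= TWOX_RANGE[1]:
        return "twoX"
    return "out_of_range"


def project_foci(cell_length: float, axial_positions) -> np.ndarray:
    """Signed focus coordinates along the midcell axis.

    ``axial_positions`` are distances from the bottom pole in um; the result
    is relative to midcell (negative toward the bottom pole), ordered so the
    focus farthest from the bottom pole comes first (pair plotting
    convention).
    """
    pos = np.asarray(axial_positions, dtype=float)
    if np.any((pos < -1e-9) | (pos > cell_length + 1e-9)):
        raise ValueError("focus outside the cell outline")
    rel = pos - cell_length / 2.0
    return rel[np.argsort(-rel, kind="stable")]


def _pair_two(cfp, yfp):
    """Minimal-total-axial-distance matching of two foci per channel."""
    best = None
    for perm in permutations(range(2)):
        tot = sum(abs(cfp[i][0] - yfp[perm[i]][0]) for i in range(2))
        if best is None or tot < best[0]:
            best = (tot, perm)
    return best[1]


def pair_foci(cfp_foci: pd.DataFrame, yfp_foci: pd.DataFrame,
              cell_length: float, cell_id: int = -1) -> list[FocusPair]:
    """Pair CFP with YFP foci of one cell and compute 2D distances (nm).

    With one focus per channel the nearest (only) pairing is used. With two
    per channel, pairing is restricted within the same cell half where
    possible (the replichore surrogate); if a half does not contain exactly
    one focus of each channel, the assignment minimizing total axial distance
    is used and flagged ``same_half=False``. Channels with unequal or
    zero counts yield nearest-neighbour pairs for the smaller channel.
    """
    def rows(df):
        return [(float(a), float(t)) for a, t in
                zip(df["axial_um"], df["transverse_um"])]

    c, yv = rows(cfp_foci), rows(yfp_foci)
    if not c or not yv:
        return []
    mid = cell_length / 2.0

    def make(cf, yf, same_half):
        d_nm = 1000.0 * float(np.hypot(cf[0] - yf[0], cf[1] - yf[1]))
        return FocusPair(cell_id=cell_id, cfp_axial=cf[0], yfp_axial=yf[0],
                         distance_nm=d_nm,
                         ploidy_class=classify_ploidy(cell_length),
                         same_half=same_half)

    if len(c) == 1 and len(yv) == 1:
        return [make(c[0], yv[0], True)]

    if len(c) == 2 and len(yv) == 2:
        halves_ok = True
        pairs = []
        for half in (0, 1):
            in_half = lambda f: (f[0] >= mid) == (half == 0)
            ch = [f for f in c if in_half(f)]
            yh = [f for f in yv if in_half(f)]
            if len(ch) == 1 and len(yh) == 1:
                pairs.append(make(ch[0], yh[0], True))
            else:
                halves_ok = False
                break
        if halves_ok:
            return pairs
        perm = _pair_two(c, yv)
        return [make(c[i], yv[perm[i]], False) for i in range(2)]

    # unequal counts: nearest neighbour for each focus of the smaller channel
    small, large, flip = (c, yv, False) if len(c) <= len(yv) else (yv, c, True)
    out = []
    for f in small:
        g = min(large, key=lambda h: abs(h[0] - f[0]))
        cf, yf = (f, g) if not flip else (g, f)
        out.append(make(cf, yf, False))
    return out


def pair_foci_table(cells: pd.DataFrame, foci: pd.DataFrame) -> pd.DataFrame:
    """Run :func:`pair_foci` over a (single-frame) cell table.

    ``foci`` must carry ``channel`` in {CFP, YFP}. Returns one row per focus
    pair with the cell length and ploidy class attached.
    """
    lengths = cells.drop_duplicates("cell_id").set_index("cell_id")["length_um"]
    rows = []
    for cid, group in foci.groupby("cell_id"):
        L = float(lengths.loc[cid])
        pairs = pair_foci(group[group["channel"] == "CFP"],
                          group[group["channel"] == "YFP"], L, cell_id=int(cid))
        for p in pairs:
            rows.append({"cell_id": p.cell_id, "length_um": L,
                         "ploidy_class": p.ploidy_class,
                         "distance_nm": p.distance_nm,
                         "same_half": p.same_half})
    return pd.DataFrame(rows, columns=["cell_id", "length_um", "ploidy_class",
                                       "distance_nm", "same_half"])


def interfocal_summary(pairs: pd.DataFrame, classes: pd.Series,
                       min_pairs: int = 2) -> tuple[pd.DataFrame, dict]:
    """Per-(class, ploidy) interfocal-distance summaries in nm.

    ``classes`` maps cell_id -> class label. Groups with fewer than
    ``min_pairs`` pairs are excluded (reported with n but NaN summaries).
    Returns (summary table, dict of per-group distance arrays) — the latter
    feeds the ANOVA/Tukey comparisons.
    """
    if len(pairs) == 0:
        raise ValueError("no focus pairs supplied")
    tagged = pairs.copy()
    tagged["class"] = tagged["cell_id"].map(classes)
    tagged = tagged[tagged["class"].notna()
                    & (tagged["ploidy_class"] != "out_of_range")]
    rows, groups = [], {}
    for (cls, ploidy), g in tagged.groupby(["class", "ploidy_class"]):
        d = g["distance_nm"].to_numpy()
        key = f"{cls}_{ploidy}"
        if d.size >= min_pairs:
            groups[key] = d
            rows.append({"class": cls, "ploidy_class": ploidy, "n": d.size,
                         "mean_nm": float(d.mean()),
                         "sd_nm": float(d.std(ddof=1))})
        else:
            rows.append({"class": cls, "ploidy_class": ploidy, "n": d.size,
                         "mean_nm": np.nan, "sd_nm": np.nan})
    return pd.DataFrame(rows), groups
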