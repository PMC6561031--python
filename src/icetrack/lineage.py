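"""Genealogy construction and per-lifetime focus statistics.

A cell's identity ends at division: daughters are new cells whose birth frame
equals the mother's death frame. ``offspring_final`` counts the live
descendants of a cell in the last movie frame (a censored undivided cell
counts itself), which is the microcolony-size quantity behind the
"fewer than 8 offspring" exclusion rule.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FocusDistribution", "build_genealogy", "max_foci_per_lifetime",
           "focus_distribution"]

MAX_FOCI = 8


@dataclass(frozen=True)
class FocusDistribution:
    """Counts of cells by maximum lifetime focus number (0..8) for a group."""

    label: str
    counts: np.ndarray   # length 9, index = focus number

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (MAX_FOCI + 1,):
            raise ValueError("counts must cover focus numbers 0..8")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def percentages(self) -> np.ndarray:
        return 100.0 * self.counts / max(1, self.n)

    @property
    def zero_focus_proportion(self) -> float:
        """Share of cells with no detectable focus at any point."""
        return float(self.counts[0]) / max(1, self.n)

    def proportion_at_least(self, k: int) -> float:
        return float(self.counts[k:].sum()) / max(1, self.n)


def build_genealogy(cell_table: pd.DataFrame, movie_end: int | None = None
                    ) -> pd.DataFrame:
    """Derive one lineage record per cell from a per-(cell, frame) table.

    Expects ``cell_id``, ``frame`` and ``mother_id`` columns (mother -1 or
    NaN for roots). Returns a DataFrame with birth/death frames, mother and
    daughter links, fate ('divided', 'lysed', 'censored') and the final
    offspring count. A divided mother's death frame equals her daughters'
    birth frame.

    Raises on inconsistent links: a daughter appearing before its mother
    dies, unknown mothers, or link cycles.
    """
    g = cell_table.groupby("cell_id")["frame"]
    birth = g.min()
    last = g.max()
    ids = birth.index.to_numpy()
    if movie_end is None:
        movie_end = int(cell_table["frame"].max())

    mothers = (cell_table.drop_duplicates("cell_id")
               .set_index("cell_id")["mother_id"]
               .reindex(ids).fillna(-1).astype(np.int64))
    known = set(ids.tolist())
    bad = [int(m) for m in mothers.unique() if m != -1 and int(m) not in known]
    if bad:
        raise ValueError(f"mother id(s) not present as cells: {bad[:10]}")

    mother_consistency = cell_table.groupby("cell_id")["mother_id"].nunique()
    multi = mother_consistency[mother_consistency > 1]
    if len(multi):
        raise ValueError(f"cells with multiple mothers: {list(multi.index[:10])}")

    pos = {int(c): k for k, c in enumerate(ids)}
    birth_a = birth.to_numpy()
    last_a = last.to_numpy()
    mother_a = mothers.to_numpy()

    daughters: dict[int, list[int]] = {int(c): [] for c in ids}
    for cid, m in zip(ids, mother_a):
        if m != -1:
            if birth_a[pos[int(cid)]] <= birth_a[pos[int(m)]]:
                raise ValueError(
                    f"lineage cycle or inverted link at cell {int(cid)} "
                    f"(born no later than its mother {int(m)})")
            daughters[int(m)].append(int(cid))

    fate = np.empty(ids.size, dtype=object)
    death = np.empty(ids.size, dtype=np.int64)
    for k, cid in enumerate(ids):
        ds = daughters[int(cid)]
        if ds:
            if len(ds) != 2:
                raise ValueError(f"cell {int(cid)} has {len(ds)} daughters (expected 2)")
            db = {birth_a[pos[d]] for d in ds}
            if len(db) != 1:
                raise ValueError(f"daughters of cell {int(cid)} born in different frames")
            fate[k] = "divided"
            death[k] = db.pop()
        elif last_a[k] >= movie_end:
            fate[k] = "censored"
            death[k] = movie_end
        else:
            fate[k] = "lysed"
            death[k] = last_a[k] + 1

    # live descendants in the final frame, processed children-before-mothers
    offspring = np.where((fate == "censored"), 1, 0).astype(np.int64)
    order = np.argsort(-birth_a, kind="stable")
    for k in order:
        m = mother_a[k]
        if m != -1:
            offspring[pos[int(m)]] += offspring[k]

    return pd.DataFrame({
        "cell_id": ids,
        "birth_frame": birth_a,
        "death_frame": death,
        "mother_id": mother_a,
        "daughter_ids": [tuple(daughters[int(c)]) for c in ids],
        "fate": fate,
        "offspring_final": offspring,
    })


def max_foci_per_lifetime(cell_table: pd.DataFrame, foci: pd.DataFrame
                          ) -> pd.Series:
    """Maximum simultaneous focus count each cell shows across its frames.

    ``foci`` must already be thresholded. Cells present in ``cell_table``
    with no focus rows get 0; the maximum is per cell, never aggregated over
    descendants. Returns a Series indexed by cell_id.
    """
    universe = pd.Index(cell_table["cell_id"].unique(), name="cell_id")
    if len(universe) == 0:
        raise ValueError("cell table contains no cells")
    if len(foci):
        extra = set(foci["cell_id"].unique()) - set(universe)
        if extra:
            raise ValueError(f"foci reference cells without frames: {sorted(extra)[:10]}")
        per_frame = (foci.groupby(["cell_id", "frame"]).size()
                     .groupby("cell_id").max())
    else:
        per_frame = pd.Series(dtype=np.int64)
    out = per_frame.reindex(universe, fill_value=0).astype(np.int64)
    out.name = "max_foci"
    return out


def focus_distribution(maxima: pd.Series, classes: pd.Series, group: str,
                       label: str | None = None) -> FocusDistribution:
    """Histogram of per-cell lifetime maxima for the cells of one class.

    ``classes`` maps cell_id -> class label ('tc', 'non_tc', 'excluded',
    ...); every cell of the group must have a computed maximum.
    """
    members = classes.index[classes == group]
    if len(members) == 0:
        raise ValueError(f"no cells in group {group!r}")
    missing = members.difference(maxima.index)
    if len(missing):
        raise ValueError(f"cells without lifetime maxima: {list(missing[:10])}")
    vals = maxima.loc[members].to_numpy()
    if np.any(vals > MAX_FOCI):
        raise ValueError("maxima exceed the 8-focus cap; threshold foci first")
    counts = np.bincount(vals, minlength=MAX_FOCI + 1)[:MAX_FOCI + 1]
    return FocusDistribution(label=label or group, counts=counts)
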