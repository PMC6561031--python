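"""Conjugative transfer-event detection.

A transfer shows up as the first repressor-bound focus in an ICE-free
recipient cell adjacent to a transfer-competent donor, followed (3.5-10 h
later) by eCherry expression once the element integrates into the
recipient's conditional reporter trap. Foci that disappear again without
reporter onset are scored as aborted transfers; onsets outside the window
are flagged rather than counted.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from shapely.geometry import LineString
from shapely.strtree import STRtree

from .lineage import FocusDistribution, MAX_FOCI

__all__ = ["TransferEvent", "adjacency", "detect_transfer_events",
           "donor_distribution_vs_background", "ECHERRY_WINDOW_H"]

ECHERRY_WINDOW_H = (3.5, 10.0)   # integration-reporting delay window, hours


@dataclass(frozen=True)
class TransferEvent:
    donor_id: Optional[int]
    recipient_id: int
    focus_frame: int
    echerry_frame: Optional[int]
    donor_max_foci: Optional[int]
    status: str                   # 'integrated', 'aborted', 'outside_window'

    def __post_init__(self):
        if self.echerry_frame is not None and self.echerry_frame <= self.focus_frame:
            raise ValueError("reporter onset must follow the focus appearance")


def _capsule(x, y, length, width, angle):
    """Cell outline as a capsule (segment buffered by the half width)."""
    half = max(1e-6, (length - width) / 2.0)
    dx, dy = np.cos(angle) * half, np.sin(angle) * half
    return LineString([(x - dx, y - dy), (x + dx, y + dy)]).buffer(width / 2.0)


def adjacency(cell_table: pd.DataFrame, frame: int,
              tolerance: float = 0.2) -> set[tuple[int, int]]:
    """Contact pairs at one frame: cells whose outlines lie within
    ``tolerance`` um of each other. Returns a set of (id_low, id_high)."""
    rows = cell_table[cell_table["frame"] == frame]
    geoms, ids = [], []
    for _, r in rows.iterrows():
        geoms.append(_capsule(r["x_um"], r["y_um"], r["length_um"],
                              r["width_um"], r.get("angle_rad", 0.0)))
        ids.append(int(r["cell_id"]))
    if len(geoms) < 2:
        return set()
    tree = STRtree(geoms)
    pairs = set()
    for i, g in enumerate(geoms):
        for j in tree.query(g.buffer(tolerance)):
            j = int(j)
            if j <= i:
                continue
            if geoms[i].distance(geoms[j]) <= tolerance:
                pairs.add((min(ids[i], ids[j]), max(ids[i], ids[j])))
    return pairs


def _echerry_onset_threshold(recipients: pd.DataFrame) -> float:
    """Baseline + 3 robust sds of the recipient population's first-frame
    eCherry (the reporter is silent until integration)."""
    first = recipients.groupby("cell_id")["frame"].idxmin()
    base = recipients.loc[first, "echerry"].to_numpy()
    med = float(np.median(base))
    mad = 1.4826 * float(np.median(np.abs(base - med)))
    return med + 3.0 * max(mad, 1e-9 * med)


def detect_transfer_events(cell_table: pd.DataFrame, classes: pd.Series,
                           foci: pd.DataFrame, frame_interval_min: float = 30.0,
                           window_h: tuple[float, float] = ECHERRY_WINDOW_H,
                           contact_tolerance: float = 0.2,
                           maxima: Optional[pd.Series] = None):
    """Scan recipients for incoming-element foci and score the outcomes.

    Parameters
    ----------
    cell_table
        Per-(cell, frame) records including ``is_recipient``.
    classes
        cell_id -> class label; used to find adjacent tc donors.
    foci
        Thresholded focus table (donors' and recipients' CFP foci).
    maxima
        Optional precomputed per-cell lifetime focus maxima for donors.

    Returns ``(events, unassigned)``: lists of :class:`TransferEvent`;
    ``unassigned`` holds recipient foci without an adjacent tc donor.
    """
    recips = cell_table[cell_table["is_recipient"].astype(bool)]
    if len(recips) == 0:
        return [], []
    onset_thr = _echerry_onset_threshold(recips)
    fph = 60.0 / frame_interval_min

    rec_ids = set(recips["cell_id"].unique())
    rec_foci = foci[foci["cell_id"].isin(rec_ids)]
    if maxima is None:
        from .lineage import max_foci_per_lifetime
        maxima = max_foci_per_lifetime(cell_table, foci)
    per_frame_counts = foci.groupby(["cell_id", "frame"]).size()

    def donor_max_until(donor_id, frame):
        """Donor's lifetime maximum simultaneous focus count up to `frame`."""
        try:
            traj = per_frame_counts.loc[donor_id]
        except KeyError:
            return 0
        early = traj[traj.index <= frame]
        return int(early.max()) if len(early) else 0

    contact_cache: dict[int, set] = {}
    events, unassigned = [], []
    for rid, g in rec_foci.groupby("cell_id"):
        focus_frames = np.sort(g["frame"].unique())
        f0 = int(focus_frames[0])
        # donor search among adjacent tc cells at the focus frame
        if f0 not in contact_cache:
            contact_cache[f0] = adjacency(cell_table, f0,
                                          tolerance=contact_tolerance)
        contacts = contact_cache[f0]
        neighbours = [a if b == rid else b
                      for a, b in contacts if rid in (a, b)]
        tc_neighbours = [n for n in neighbours if classes.get(n) == "tc"]
        donor = None
        if tc_neighbours:
            donor = max(tc_neighbours,
                        key=lambda n: (donor_max_until(n, f0), -n))
        # reporter onset
        traj = (cell_table[(cell_table["cell_id"] == rid)
                           & (cell_table["frame"] > f0)]
                .sort_values("frame"))
        above = traj[traj["echerry"] > onset_thr]
        onset = int(above["frame"].iloc[0]) if len(above) else None

        donor_max = donor_max_until(donor, f0) if donor is not None else None
        if onset is not None:
            dt_h = (onset - f0) / fph
            status = "integrated" if window_h[0] <= dt_h <= window_h[1] \
                else "outside_window"
            ev = TransferEvent(donor, int(rid), f0, onset, donor_max, status)
        else:
            # focus gone again and reporter silent: aborted transfer
            last_focus = int(focus_frames[-1])
            last_seen = int(cell_table.loc[cell_table["cell_id"] == rid,
                                           "frame"].max())
            status = "aborted" if last_focus < last_seen else "censored"
            ev = TransferEvent(donor, int(rid), f0, None, donor_max, status)
        (events if donor is not None else unassigned).append(ev)
    return events, unassigned


def donor_distribution_vs_background(events: list[TransferEvent],
                                     tc_background: FocusDistribution
                                     ) -> tuple[FocusDistribution, FocusDistribution]:
    """Focus distribution of successfully transferring donors, paired with
    the tc background distribution, ready for the MC Fisher comparison."""
    integrated = [e for e in events if e.status == "integrated"
                  and e.donor_max_foci is not None]
    if not integrated:
        raise ValueError("no integrated transfer events")
    counts = np.bincount([min(e.donor_max_foci, MAX_FOCI) for e in integrated],
                         minlength=MAX_FOCI + 1)[:MAX_FOCI + 1]
    donors = FocusDistribution(label="transferring_donors", counts=counts)
    return donors, tc_background
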