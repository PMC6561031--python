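"""Ground-truthed synthetic single-cell time-lapse generator.

Emulates microcolony growth of *P. putida* seeded from a stationary-phase
culture: a small eCherry-bright transfer-competent (tc) subpopulation among
dim non-tc cells; exponential growth and division until the population
re-enters stationary phase (~12 h); impaired division and frequent lysis of
tc cells; chromosome-replication-driven 1-2 foci in non-tc cells; excision
plus transient replication of the mobile element (up to ``copy_cap`` foci)
in tc cells; and copy-number-dependent transfer to adjacent ICE-free
recipients with a delayed eCherry onset in the transconjugant.

Outputs are a per-(cell, frame) table of segmented-cell records plus
candidate foci (scored on the 1-7 threshold scale) and a parallel
:class:`GroundTruth` bundle against which every downstream stage can be
checked. Given identical ``(config, seed)`` the output is bit-identical.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import SimConfig

__all__ = ["GroundTruth", "generate_population", "generate_colabel_snapshot",
           "sample_echerry"]

CLASS_CODES = {0: "non_tc", 1: "tc", 2: "recipient"}

CELL_COLUMNS = ["cell_id", "frame", "mother_id", "length_um", "width_um",
                "x_um", "y_um", "angle_rad", "echerry", "is_recipient"]
FOCUS_COLUMNS = ["cell_id", "frame", "channel", "axial_um", "transverse_um",
                 "score", "intensity"]


@dataclass
class GroundTruth:
    """Per-cell / per-frame truth emitted alongside the observable tables."""

    cells: pd.DataFrame      # cell_id, frame, true_class, integrated/excised copies, visible_foci
    per_cell: pd.DataFrame   # cell_id, true_class, dim, mother_id, birth/death frame, fate
    foci: pd.DataFrame       # true focus positions (cell_id, frame, channel, axial, transverse)
    transfers: pd.DataFrame  # donor_id, recipient_id, focus_frame, integrated, echerry_frame


def sample_echerry(config: SimConfig, n: int, rng: np.random.Generator,
                   tc: Optional[np.ndarray] = None) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-cell eCherry base fluorescence for ``n`` founders.

    Returns ``(values, is_tc)``; the class indicator is drawn from
    ``config.tc_fraction`` unless supplied.
    """
    if tc is None:
        tc = rng.random(n) < config.tc_fraction
    mu = np.where(tc, config.echerry_tc[0], config.echerry_nontc[0])
    sd = np.where(tc, config.echerry_tc[1], config.echerry_nontc[1])
    return np.exp(rng.normal(mu, sd)), tc


def _founder_positions(n: int, spacing: float, rng: np.random.Generator):
    side = int(math.ceil(math.sqrt(n)))
    idx = np.arange(n)
    x = (idx % side) * spacing + rng.uniform(-1.0, 1.0, n)
    y = (idx // side) * spacing + rng.uniform(-1.0, 1.0, n)
    return x, y


def _draw_scores(n: int, dim: np.ndarray, rng: np.random.Generator):
    """Score / intensity bins (1-7) for true foci; dim cells stay below the
    conservative (6, 6) working threshold."""
    score = np.where(dim, rng.integers(3, 6, n), 6 + (rng.random(n) < 0.65))
    intensity = np.where(dim, rng.integers(3, 7, n), 6 + (rng.random(n) < 0.6))
    return score.astype(np.int64), intensity.astype(np.int64)


class _Recorder:
    """Column-chunk accumulator for the output tables."""

    def __init__(self):
        self.cells = {c: [] for c in CELL_COLUMNS}
        self.foci = {c: [] for c in FOCUS_COLUMNS}
        self.true_foci = {c: [] for c in FOCUS_COLUMNS if c not in ("score", "intensity")}
        self.truth = {c: [] for c in ["cell_id", "frame", "true_class",
                                      "integrated_copies", "excised_copies",
                                      "visible_foci"]}

    def frame_cells(self, **cols):
        for k, v in cols.items():
            self.cells[k].append(v)

    def to_frames(self):
        cells = pd.DataFrame({k: np.concatenate(v) if v else np.array([])
                              for k, v in self.cells.items()})
        foci = pd.DataFrame({k: (np.concatenate(v) if v else np.array([]))
                             for k, v in self.foci.items()})
        true_foci = pd.DataFrame({k: (np.concatenate(v) if v else np.array([]))
                                  for k, v in self.true_foci.items()})
        truth = pd.DataFrame({k: np.concatenate(v) if v else np.array([])
                              for k, v in self.truth.items()})
        for df, col in ((cells, "cell_id"), (foci, "cell_id"),
                        (true_foci, "cell_id"), (truth, "cell_id")):
            if len(df):
                df[col] = df[col].astype(np.int64)
                df["frame"] = df["frame"].astype(np.int64)
        return cells, foci, true_foci, truth


def generate_population(config: SimConfig, seed: Optional[int] = None):
    """Simulate a branching cell population and its candidate foci.

    Returns ``(cell_table, focus_table, truth)`` where ``cell_table`` is one
    row per (cell, frame), ``focus_table`` holds scored candidate foci in the
    CFP channel, and ``truth`` is a :class:`GroundTruth` bundle.
    """
    if config.initial_cells < 1:
        raise ValueError("initial_cells must be positive")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    n0 = config.initial_cells
    w = config.cell_width
    # class assignment: recipients first (transfer mixes), then tc among the rest
    cls = np.zeros(n0, dtype=np.int64)
    is_rec = rng.random(n0) < config.recipient_fraction
    cls[is_rec] = 2
    donors = ~is_rec
    cls[donors & (rng.random(n0) < config.tc_fraction)] = 1
    cls[(cls == 1) & is_rec] = 2  # unreachable; keep classes exclusive

    echerry_base = np.empty(n0)
    for code, spec in ((0, config.echerry_nontc), (1, config.echerry_tc),
                       (2, config.echerry_recipient)):
        m = cls == code
        echerry_base[m] = np.exp(rng.normal(spec[0], spec[1], int(m.sum())))

    x, y = _founder_positions(n0, config.colony_spacing, rng)

    # live-population state
    live = {
        "id": np.arange(n0, dtype=np.int64),
        "cls": cls,
        "mother": np.full(n0, -1, dtype=np.int64),
        "length": rng.uniform(*config.birth_length, n0),
        "x": x, "y": y,
        "angle": rng.uniform(0, np.pi, n0),
        "div_thresh": config.division_length
        * (1 + rng.uniform(-config.division_jitter, config.division_jitter, n0)),
        "echerry": echerry_base,
        "dim": np.where(cls == 1,
                        rng.random(n0) < config.dim_prob_tc,
                        rng.random(n0) < config.dim_prob_nontc),
        "excised": np.zeros(n0, dtype=bool),
        "copies": np.zeros(n0, dtype=np.int64),
        "exc_frame": np.full(n0, -1, dtype=np.int64),
        # recipient transfer state
        "r_start": np.full(n0, -1, dtype=np.int64),
        "r_end": np.full(n0, np.iinfo(np.int64).max, dtype=np.int64),
        "r_onset": np.full(n0, -1, dtype=np.int64),
        "r_bright": np.zeros(n0),
        "birth": np.zeros(n0, dtype=np.int64),
    }

    next_id = n0
    fates: dict[int, tuple[str, int]] = {}        # id -> (fate, death_frame)
    registry = {"cell_id": [], "true_class": [], "dim": [], "mother_id": [],
                "birth_frame": []}

    def register(ids, classes, dims, mothers, births):
        registry["cell_id"].extend(np.asarray(ids, dtype=np.int64))
        registry["true_class"].extend(np.asarray(classes, dtype=np.int64))
        registry["dim"].extend(np.asarray(dims, dtype=bool))
        registry["mother_id"].extend(np.asarray(mothers, dtype=np.int64))
        registry["birth_frame"].extend(np.asarray(births, dtype=np.int64))

    register(live["id"], live["cls"], live["dim"], live["mother"], live["birth"])

    transfers = {"donor_id": [], "recipient_id": [], "focus_frame": [],
                 "integrated": [], "echerry_frame": []}

    rec = _Recorder()
    p_exc = 1.0 - (1.0 - config.excision_prob) ** (1.0 / max(1, config.excision_window))
    vis = config.reporter_present and config.array_present
    contacts = None  # recipient adjacency, built at stationary entry

    for f in range(config.frames):
        n = live["id"].size
        if n == 0:
            break
        cls_l = live["cls"]
        L = live["length"]

        # ---- observable cell rows -------------------------------------------
        echerry_now = live["echerry"].copy()
        onset_passed = (cls_l == 2) & (live["r_onset"] >= 0) & (f >= live["r_onset"])
        echerry_now[onset_passed] = live["r_bright"][onset_passed]
        echerry_now = echerry_now * (1 + config.echerry_noise * rng.standard_normal(n))
        np.clip(echerry_now, 1e-6, None, out=echerry_now)
        rec.frame_cells(
            cell_id=live["id"], frame=np.full(n, f, dtype=np.int64),
            mother_id=live["mother"], length_um=L.copy(),
            width_um=np.full(n, w), x_um=live["x"].copy(), y_um=live["y"].copy(),
            angle_rad=live["angle"].copy(), echerry=echerry_now,
            is_recipient=(cls_l == 2).copy(),
        )

        # ---- true focus counts ----------------------------------------------
        chrom = 1 + (L >= config.replication_onset_length).astype(np.int64)
        count = np.where(cls_l == 1,
                         np.where(live["excised"], live["copies"], chrom),
                         chrom)
        rec_focus_on = (cls_l == 2) & (live["r_start"] >= 0) \
            & (f >= live["r_start"]) & (f < live["r_end"])
        count = np.where(cls_l == 2, rec_focus_on.astype(np.int64), count)

        integ = np.where(cls_l == 2,
                         (onset_passed).astype(np.int64),
                         np.where((cls_l == 1) & live["excised"], 0, chrom))
        excis = np.where(cls_l == 2,
                         (rec_focus_on & ~onset_passed).astype(np.int64),
                         np.where((cls_l == 1) & live["excised"], live["copies"], 0))

        visible = count.copy()
        if not vis:
            # no operator array or no fluorescent repressor in the donor strain;
            # recipients express their own LacI-CFP and keep transfer foci visible
            visible = np.where(cls_l == 2, count, 0)

        rec.truth["cell_id"].append(live["id"].copy())
        rec.truth["frame"].append(np.full(n, f, dtype=np.int64))
        rec.truth["true_class"].append(cls_l.copy())
        rec.truth["integrated_copies"].append(integ)
        rec.truth["excised_copies"].append(excis)
        rec.truth["visible_foci"].append(visible)

        # ---- candidate foci ---------------------------------------------------
        reps = visible
        if reps.sum() > 0:
            owner = np.repeat(np.arange(n), reps)
            m = owner.size
            Lr = L[owner]
            axial = rng.uniform(0.08, np.maximum(0.09, Lr - 0.08))
            transverse = np.clip(rng.normal(0, 0.08, m), -(w / 2 - 0.05), w / 2 - 0.05)
            score, intensity = _draw_scores(m, live["dim"][owner], rng)
            rec.foci["cell_id"].append(live["id"][owner])
            rec.foci["frame"].append(np.full(m, f, dtype=np.int64))
            rec.foci["channel"].append(np.full(m, "CFP"))
            rec.foci["axial_um"].append(axial)
            rec.foci["transverse_um"].append(transverse)
            rec.foci["score"].append(score)
            rec.foci["intensity"].append(intensity)
            rec.true_foci["cell_id"].append(live["id"][owner])
            rec.true_foci["frame"].append(np.full(m, f, dtype=np.int64))
            rec.true_foci["channel"].append(np.full(m, "CFP"))
            rec.true_foci["axial_um"].append(axial)
            rec.true_foci["transverse_um"].append(transverse)

        # spurious candidates: low-scoring everywhere; threshold-passing ones
        # only in array-carrying strains (reporter-system artifacts)
        for rate, lo_s, hi_s, lo_i, hi_i, gate, donors_only in (
            (config.spurious_rate, 1, 6, 1, 8, True, False),
            (config.spurious_pass_rate, 6, 8, 6, 8, config.array_present, True),
        ):
            if rate <= 0 or not gate:
                continue
            hit = rng.random(n) < rate
            if donors_only:
                # passing spurious foci are array-borne artifacts; recipients
                # carry no array until they receive the element
                hit &= cls_l != 2
            m = int(hit.sum())
            if m == 0:
                continue
            Lr = L[hit]
            rec.foci["cell_id"].append(live["id"][hit])
            rec.foci["frame"].append(np.full(m, f, dtype=np.int64))
            rec.foci["channel"].append(np.full(m, "CFP"))
            rec.foci["axial_um"].append(rng.uniform(0.08, np.maximum(0.09, Lr - 0.08)))
            rec.foci["transverse_um"].append(
                np.clip(rng.normal(0, 0.1, m), -(w / 2 - 0.05), w / 2 - 0.05))
            rec.foci["score"].append(rng.integers(lo_s, hi_s, m))
            rec.foci["intensity"].append(rng.integers(lo_i, hi_i, m))

        # ---- state updates -----------------------------------------------------
        # 1) tc lysis
        lyse = (cls_l == 1) & (rng.random(n) < config.tc_lysis_prob)
        if f == config.frames - 1:
            lyse[:] = False
        for cid in live["id"][lyse]:
            fates[int(cid)] = ("lysed", f + 1)

        # 2) excision and excised-copy replication (tc only)
        if config.excisable:
            eligible = (cls_l == 1) & ~live["excised"] & (f < config.excision_window)
            exc_now = eligible & (rng.random(n) < p_exc)
            live["excised"][exc_now] = True
            live["copies"][exc_now] = 1
            live["exc_frame"][exc_now] = f
        replicating = (live["excised"] & (live["copies"] < config.copy_cap)
                       & (f < live["exc_frame"] + config.copy_birth_window))
        born = replicating & (rng.random(n) < config.copy_birth_rate)
        live["copies"][born] += 1

        # 3) transfer from adjacent tc donors (static, stationary-phase colonies)
        if config.recipient_fraction > 0 and f >= config.stationary_frame:
            if contacts is None:
                contacts = _build_contacts(live, w)
            _transfer_step(config, rng, live, contacts, f, transfers)

        # 4) growth and division (exponential phase only)
        growing = f < config.stationary_frame
        div = np.zeros(n, dtype=bool)
        if growing:
            factor = np.where(cls_l == 1, config.growth_rate ** config.tc_growth_factor,
                              config.growth_rate)
            live["length"] = live["length"] * factor
            over = live["length"] >= live["div_thresh"]
            div = over & ~lyse
            tc_div_block = (cls_l == 1) & (rng.random(n) >= config.tc_division_deficit)
            div &= ~tc_div_block

        survivors = ~(lyse | div)
        new_cells = None
        if div.any():
            for cid in live["id"][div]:
                fates[int(cid)] = ("divided", f + 1)
            new_cells = _make_daughters(config, rng, live, div, f, next_id, w)
            next_id += 2 * int(div.sum())
            register(new_cells["id"], new_cells["cls"], new_cells["dim"],
                     new_cells["mother"], new_cells["birth"])

        for k in live:
            live[k] = live[k][survivors]
        if new_cells is not None:
            for k in live:
                live[k] = np.concatenate([live[k], new_cells[k]])

    # survivors at the end are censored
    for cid in live["id"]:
        fates.setdefault(int(cid), ("censored", config.frames - 1))

    cells, foci, true_foci, truth_cells = rec.to_frames()
    per_cell = pd.DataFrame(registry)
    per_cell["true_class"] = per_cell["true_class"].map(CLASS_CODES)
    fate_df = pd.DataFrame(
        [(cid, fat, dfr) for cid, (fat, dfr) in fates.items()],
        columns=["cell_id", "fate", "death_frame"],
    )
    per_cell = per_cell.merge(fate_df, on="cell_id", how="left")
    per_cell["fate"] = per_cell["fate"].fillna("censored")
    truth_cells["true_class"] = truth_cells["true_class"].map(CLASS_CODES)

    truth = GroundTruth(cells=truth_cells, per_cell=per_cell, foci=true_foci,
                        transfers=pd.DataFrame(transfers))
    return cells, foci, truth


def _make_daughters(config, rng, live, div, f, next_id, w):
    """Two daughters per divider, placed end to end along the mother axis."""
    idx = np.where(div)[0]
    k = idx.size
    ids = next_id + np.arange(2 * k, dtype=np.int64)
    rep = np.repeat(idx, 2)
    sign = np.tile([1.0, -1.0], k)
    newlen = live["length"][rep] / 2
    ang = live["angle"][rep] + rng.normal(0, 0.25, 2 * k)
    dx = np.cos(ang) * (newlen / 2 + 0.05) * sign
    dy = np.sin(ang) * (newlen / 2 + 0.05) * sign
    cls_rep = live["cls"][rep]
    # excised copies partition binomially between tc daughters
    copies = np.zeros(2 * k, dtype=np.int64)
    exc = np.zeros(2 * k, dtype=bool)
    for j, i in enumerate(idx):
        if live["excised"][i]:
            a = rng.binomial(int(live["copies"][i]), 0.5)
            copies[2 * j], copies[2 * j + 1] = a, live["copies"][i] - a
            exc[2 * j] = exc[2 * j + 1] = True
    return {
        "id": ids,
        "cls": cls_rep.copy(),
        "mother": live["id"][rep].copy(),
        "length": newlen,
        "x": live["x"][rep] + dx,
        "y": live["y"][rep] + dy,
        "angle": ang % np.pi,
        "div_thresh": config.division_length
        * (1 + rng.uniform(-config.division_jitter, config.division_jitter, 2 * k)),
        "echerry": live["echerry"][rep].copy(),
        "dim": live["dim"][rep].copy(),
        "excised": exc,
        "copies": copies,
        "exc_frame": live["exc_frame"][rep].copy(),
        "r_start": np.full(2 * k, -1, dtype=np.int64),
        "r_end": np.full(2 * k, np.iinfo(np.int64).max, dtype=np.int64),
        "r_onset": np.full(2 * k, -1, dtype=np.int64),
        "r_bright": np.zeros(2 * k),
        "birth": np.full(2 * k, f + 1, dtype=np.int64),
    }


def _build_contacts(live, width):
    """Donor-recipient contact pairs (by cell id) among the now-static
    cells; lysis later in the movie only removes pairs."""
    pts = np.column_stack([live["x"], live["y"]])
    tree = cKDTree(pts)
    reach = live["length"].max() + width + 0.2
    pairs = tree.query_pairs(reach, output_type="ndarray")
    contacts = []
    for i, j in pairs:
        d = np.hypot(*(pts[i] - pts[j]))
        if d <= (live["length"][i] + live["length"][j]) / 2 * 0.6 + width:
            contacts.append((int(live["id"][i]), int(live["id"][j])))
    return contacts


def _transfer_step(config, rng, live, contacts, f, transfers):
    if not contacts:
        return
    index_of = {int(cid): k for k, cid in enumerate(live["id"])}
    cls_l = live["cls"]
    for id_i, id_j in contacts:
        i, j = index_of.get(id_i), index_of.get(id_j)
        if i is None or j is None:
            continue
        for d, r in ((i, j), (j, i)):
            if cls_l[d] != 1 or cls_l[r] != 2:
                continue
            if live["r_start"][r] >= 0:       # already received
                continue
            c = live["copies"][d]
            if not live["excised"][d] or c < 2:
                continue
            p = min(0.9, config.transfer_rate * (c - 1))
            if rng.random() >= p:
                continue
            start = f + 1
            live["r_start"][r] = start
            integrated = rng.random() < config.integration_prob
            onset = -1
            if integrated:
                delay_h = rng.uniform(*config.echerry_delay)
                onset = start + int(round(delay_h * config.frames_per_hour))
                live["r_onset"][r] = onset
                live["r_bright"][r] = np.exp(
                    rng.normal(config.echerry_tc[0], config.echerry_tc[1]))
            else:
                live["r_end"][r] = start + config.abort_persistence
            transfers["donor_id"].append(int(live["id"][d]))
            transfers["recipient_id"].append(int(live["id"][r]))
            transfers["focus_frame"].append(start)
            transfers["integrated"].append(bool(integrated))
            transfers["echerry_frame"].append(int(onset))


# ---------------------------------------------------------------------------
# colabel (CFP + YFP) snapshot generator for interfocal-distance analysis
# ---------------------------------------------------------------------------

def _place_pair(rng, d_nm, lo, hi, t_span=0.26):
    """Place a CFP/YFP pair with 2D separation ``d_nm`` inside an axial
    window [lo, hi]; returns (a_cfp, t_cfp, a_yfp, t_yfp) or None."""
    d = d_nm / 1000.0
    span = hi - lo
    for _ in range(60):
        phi = rng.uniform(0, 2 * np.pi)
        da, dt = d * np.cos(phi), d * np.sin(phi)
        if abs(da) > span or abs(dt) > 2 * t_span:
            continue
        a_lo = lo + max(0.0, -da)
        a_hi = hi - max(0.0, da)
        a1 = rng.uniform(a_lo, a_hi)
        t_lo = max(-t_span, -t_span - dt)
        t_hi = min(t_span, t_span - dt)
        t1 = rng.uniform(t_lo, t_hi)
        return a1, t1, a1 + da, t1 + dt
    return None


def generate_colabel_snapshot(config: SimConfig, n_cells: int,
                              population: str = "mixed",
                              seed: Optional[int] = None):
    """Single-frame population with CFP (element) and YFP (chromosome) foci.

    Cells with the element integrated (non-tc) carry CFP/YFP displacements
    drawn from ``config.interfocal_integrated``; tc cells with an excised
    element from ``config.interfocal_excised`` (nm, gamma-distributed with
    the configured mean and sd, truncated to what fits inside the cell).
    Cells longer than 1.8 um carry two focus pairs, one per cell half.

    ``population`` is 'mixed' (classes drawn with ``tc_fraction``), 'tc' or
    'non_tc'.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    w = config.cell_width

    if population == "mixed":
        tc = rng.random(n_cells) < config.tc_fraction
    elif population == "tc":
        tc = np.ones(n_cells, dtype=bool)
    elif population == "non_tc":
        tc = np.zeros(n_cells, dtype=bool)
    else:
        raise ValueError("population must be 'mixed', 'tc' or 'non_tc'")

    echerry, _ = sample_echerry(config, n_cells, rng, tc=tc)
    lengths = rng.uniform(0.8, 2.99, n_cells)
    x, y = _founder_positions(n_cells, config.colony_spacing, rng)

    def gamma_params(mean, sd):
        shape = (mean / sd) ** 2
        return shape, mean / shape

    pi = gamma_params(*config.interfocal_integrated)
    pe = gamma_params(*config.interfocal_excised)

    foci = {c: [] for c in FOCUS_COLUMNS}
    truth_rows = []
    margin = 0.03
    for i in range(n_cells):
        L = lengths[i]
        shape, scale = pe if tc[i] else pi
        windows = ([(margin, L - margin)] if L < 1.8
                   else [(margin, L / 2 - 0.02), (L / 2 + 0.02, L - margin)])
        for lo, hi in windows:
            placed = None
            d = 0.0
            for _ in range(200):      # redraw d when it cannot fit (truncation)
                d = rng.gamma(shape, scale)
                placed = _place_pair(rng, d, lo, hi, t_span=w / 2 - 0.09)
                if placed is not None:
                    break
            if placed is None:
                continue
            a1, t1, a2, t2 = placed
            for ch, a, t in (("CFP", a1, t1), ("YFP", a2, t2)):
                foci["cell_id"].append(i)
                foci["frame"].append(0)
                foci["channel"].append(ch)
                foci["axial_um"].append(a)
                foci["transverse_um"].append(t)
                foci["score"].append(6 + int(rng.random() < 0.6))
                foci["intensity"].append(6 + int(rng.random() < 0.5))
            truth_rows.append((i, "tc" if tc[i] else "non_tc", d))

    cells = pd.DataFrame({
        "cell_id": np.arange(n_cells, dtype=np.int64),
        "frame": np.zeros(n_cells, dtype=np.int64),
        "mother_id": np.full(n_cells, -1, dtype=np.int64),
        "length_um": lengths,
        "width_um": np.full(n_cells, w),
        "x_um": x, "y_um": y,
        "angle_rad": rng.uniform(0, np.pi, n_cells),
        "echerry": echerry,
        "is_recipient": np.zeros(n_cells, dtype=bool),
    })
    focus_table = pd.DataFrame(foci)
    truth = pd.DataFrame(truth_rows,
                         columns=["cell_id", "true_class", "true_distance_nm"])
    return cells, focus_table, truth
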