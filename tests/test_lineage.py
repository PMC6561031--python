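"""Genealogy construction and per-lifetime focus statistics."""
import numpy as np
import pandas as pd
import pytest

from icetrack import preset
from icetrack.lineage import (FocusDistribution, build_genealogy,
                              focus_distribution, max_foci_per_lifetime)
from icetrack.simulate import generate_population
from icetrack.spots import apply_thresholds


def _table(rows):
    return pd.DataFrame(rows, columns=["cell_id", "frame", "mother_id",
                                       "length_um"])


def _cell(cid, frames, mother=-1, length=2.0):
    return [(cid, f, mother, length) for f in frames]


class TestBuildGenealogy:
    def test_single_censored_cell(self):
        lin = build_genealogy(_table(_cell(0, range(5))), movie_end=4)
        row = lin.iloc[0]
        assert row["fate"] == "censored"
        assert row["offspring_final"] == 1

    def test_three_synchronous_division_rounds(self):
        rows = _cell(0, [0, 1])
        nid = 1
        gen = [(0, 1)]
        for rnd in range(3):
            nxt = []
            for mother, death in gen:
                for _ in range(2):
                    birth = death + 1
                    rows += _cell(nid, range(birth, birth + 2), mother=mother)
                    nxt.append((nid, birth + 1))
                    nid += 1
            gen = nxt
        end = max(r[1] for r in rows)
        lin = build_genealogy(_table(rows), movie_end=end).set_index("cell_id")
        assert lin.loc[0, "offspring_final"] == 8
        assert lin.loc[0, "fate"] == "divided"
        # divided mothers die exactly when the daughters appear
        for cid, row in lin.iterrows():
            if row["fate"] == "divided":
                for d in row["daughter_ids"]:
                    assert lin.loc[d, "birth_frame"] == row["death_frame"]

    def test_lysed_cell_has_no_offspring(self):
        rows = _cell(0, range(3))      # ends at frame 2, movie runs to 6
        lin = build_genealogy(_table(rows), movie_end=6)
        assert lin.iloc[0]["fate"] == "lysed"
        assert lin.iloc[0]["offspring_final"] == 0

    def test_inconsistent_links_rejected(self):
        with pytest.raises(ValueError, match="mother"):
            build_genealogy(_table(_cell(0, [0, 1], mother=42)))
        bad = _table(_cell(0, [0, 1]) + _cell(1, [2, 3], mother=0))
        bad.loc[3, "mother_id"] = -1   # same cell, two different mothers
        with pytest.raises(ValueError, match="multiple mothers"):
            build_genealogy(bad)

    def test_generator_descendant_counts_match_truth(self, small_run):
        """Offspring computed from links equals live cells in the last frame."""
        cells, lineage = small_run["cells"], small_run["lineage"]
        last = cells["frame"].max()
        alive = set(cells.loc[cells["frame"] == last, "cell_id"])
        roots = lineage[lineage["mother_id"] == -1]
        assert roots["offspring_final"].sum() == len(alive)


class TestMaxFociPerLifetime:
    def _foci(self, counts_by_frame, cid=0):
        rows = []
        for f, k in counts_by_frame.items():
            for j in range(k):
                rows.append({"cell_id": cid, "frame": f, "channel": "CFP",
                             "axial_um": 0.2 + 0.1 * j, "transverse_um": 0.0,
                             "score": 7, "intensity": 7})
        return pd.DataFrame(rows, columns=["cell_id", "frame", "channel",
                                           "axial_um", "transverse_um",
                                           "score", "intensity"])

    @pytest.mark.parametrize("counts,expected", [
        ({0: 1, 1: 1, 2: 2, 3: 1}, 2),
        ({0: 1, 1: 2, 2: 6, 3: 4}, 6),
        ({}, 0),
    ])
    def test_lifetime_maximum(self, counts, expected):
        cells = _table(_cell(0, range(4)))
        assert max_foci_per_lifetime(cells, self._foci(counts))[0] == expected

    def test_invariant_to_frame_reordering(self):
        cells = _table(_cell(0, range(6)))
        foci = self._foci({0: 1, 2: 3, 5: 2})
        shuffled = foci.sample(frac=1.0, random_state=1)
        a = max_foci_per_lifetime(cells, foci)
        b = max_foci_per_lifetime(cells, shuffled)
        assert a.equals(b)

    def test_unknown_cells_rejected(self):
        cells = _table(_cell(0, range(3)))
        with pytest.raises(ValueError):
            max_foci_per_lifetime(cells, self._foci({0: 1}, cid=99))


class TestFocusDistribution:
    def test_simple_histogram(self):
        maxima = pd.Series([1] * 10, index=pd.Index(range(10), name="cell_id"))
        classes = pd.Series(["g"] * 10, index=maxima.index)
        dist = focus_distribution(maxima, classes, "g")
        assert dist.n == 10
        assert dist.counts[1] == 10
        assert dist.percentages[1] == pytest.approx(100.0)

    def test_empty_group_rejected(self):
        maxima = pd.Series([1], index=pd.Index([0], name="cell_id"))
        classes = pd.Series(["a"], index=maxima.index)
        with pytest.raises(ValueError):
            focus_distribution(maxima, classes, "zzz")

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            FocusDistribution("x", np.ones(5, dtype=int))

    def test_class_conservation_on_pipeline_run(self, small_run):
        """Class-wise totals add up to all classified, non-excluded cells."""
        classes = small_run["classes"]
        dists = small_run["distributions"]
        counted = sum(d.n for d in dists.values())
        assert counted == int(classes.isin(["tc", "non_tc"]).sum())

    def test_perfect_detection_matches_ground_truth(self):
        """Without spurious foci or dim cells, thresholded lifetime maxima
        equal the generator's visible-focus maxima exactly."""
        cfg = preset("wildtype", initial_cells=150, frames=40,
                     spurious_rate=0.0, spurious_pass_rate=0.0,
                     dim_prob_nontc=0.0, dim_prob_tc=0.0)
        cells, foci, truth = generate_population(cfg, seed=11)
        maxima = max_foci_per_lifetime(cells, apply_thresholds(foci))
        truth_max = (truth.cells.groupby("cell_id")["visible_foci"].max()
                     .reindex(maxima.index).fillna(0).astype(int))
        assert maxima.equals(truth_max.rename("max_foci"))
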