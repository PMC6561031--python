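"""Strain presets and the ground-truthed population generator."""
import numpy as np
import pandas as pd
import pytest

from icetrack import preset
from icetrack.presets import PRESET_NAMES
from icetrack.simulate import generate_colabel_snapshot, generate_population


class TestPresets:
    def test_subpopulation_fractions(self):
        assert preset("wildtype").tc_fraction == pytest.approx(0.045)
        assert preset("dmfsR").tc_fraction == pytest.approx(0.454)

    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(ValueError) as err:
            preset("dXyz")
        for name in PRESET_NAMES:
            assert name in str(err.value)

    def test_capability_switches(self):
        assert not preset("dattL").excisable
        assert not preset("dmfsR_dattL").excisable
        assert not preset("no_array").array_present
        assert not preset("no_lacI").reporter_present
        assert preset("dtraI").copy_birth_rate < preset("wildtype").copy_birth_rate
        assert preset("doriT2").copy_birth_rate == preset("wildtype").copy_birth_rate

    def test_config_validation(self):
        with pytest.raises(ValueError):
            preset("wildtype", tc_fraction=1.5)
        with pytest.raises(ValueError):
            preset("wildtype", copy_cap=9)
        with pytest.raises(ValueError):
            preset("wildtype", frame_interval=0)


class TestGeneratePopulation:
    def test_degenerate_tc_fraction(self):
        cfg = preset("wildtype", tc_fraction=0.0, initial_cells=200, frames=10)
        _, _, truth = generate_population(cfg, seed=0)
        assert (truth.per_cell["true_class"] != "tc").all()

    def test_founder_class_sampling(self):
        cfg = preset("wildtype", initial_cells=3000, frames=1)
        _, _, truth = generate_population(cfg, seed=1)
        frac = (truth.per_cell["true_class"] == "tc").mean()
        se = np.sqrt(0.045 * 0.955 / 3000)
        assert abs(frac - 0.045) <= 3 * se

    def test_determinism_same_seed(self):
        cfg = preset("wildtype", initial_cells=80, frames=25)
        c1, f1, t1 = generate_population(cfg, seed=9)
        c2, f2, t2 = generate_population(cfg, seed=9)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(f1, f2)
        pd.testing.assert_frame_equal(t1.cells, t2.cells)

    def test_lineage_closure_and_class_stability(self):
        cfg = preset("wildtype", initial_cells=120, frames=40)
        cells, _, truth = generate_population(cfg, seed=3)
        first = cells.groupby("cell_id")["frame"].min()
        last = cells.groupby("cell_id")["frame"].max()
        mothers = cells.drop_duplicates("cell_id").set_index("cell_id")["mother_id"]
        for cid, m in mothers.items():
            if m != -1:
                # daughters appear the frame after the mother's last record
                assert first[cid] == last[m] + 1
        # a cell's true class never changes within its lifetime
        assert (truth.cells.groupby("cell_id")["true_class"].nunique() == 1).all()

    def test_true_foci_inside_outline(self):
        cfg = preset("dmfsR", initial_cells=100, frames=30)
        cells, _, truth = generate_population(cfg, seed=4)
        lengths = cells.set_index(["cell_id", "frame"])["length_um"]
        foci = truth.foci.set_index(["cell_id", "frame"])
        L = lengths.loc[foci.index]
        assert (foci["axial_um"].to_numpy() >= 0).all()
        assert (foci["axial_um"].to_numpy() <= L.to_numpy()).all()
        assert (foci["transverse_um"].abs() <= cfg.cell_width / 2).all()

    def test_preset_monotonicity_in_tc_fraction(self):
        lo = generate_population(
            preset("wildtype", initial_cells=1500, frames=1), seed=5)[2]
        hi = generate_population(
            preset("dmfsR", initial_cells=1500, frames=1), seed=5)[2]
        assert ((hi.per_cell["true_class"] == "tc").sum()
                > (lo.per_cell["true_class"] == "tc").sum())

    def test_excision_locked_and_dark_presets(self):
        for name, check in [
            ("dattL", lambda t: t.cells["excised_copies"].max() == 0),
            ("no_array", lambda t: t.cells["visible_foci"].max() == 0),
            ("no_lacI", lambda t: t.cells["visible_foci"].max() == 0),
        ]:
            cfg = preset(name, initial_cells=150, frames=40)
            _, foci, truth = generate_population(cfg, seed=6)
            assert check(truth), name
        # excision-locked ground truth never exceeds two foci
        cfg = preset("dattL", initial_cells=300, frames=50)
        _, _, truth = generate_population(cfg, seed=7)
        assert truth.cells["visible_foci"].max() <= 2

    def test_copy_cap_respected(self):
        cfg = preset("dmfsR", initial_cells=200, frames=60)
        _, _, truth = generate_population(cfg, seed=8)
        assert truth.cells["excised_copies"].max() <= cfg.copy_cap
        tc_rows = truth.cells["true_class"] == "tc"
        assert (truth.cells.loc[~tc_rows
                & (truth.cells["true_class"] != "recipient"),
                "excised_copies"] == 0).all()

    def test_rejects_empty_population(self):
        with pytest.raises(ValueError):
            generate_population(preset("wildtype", initial_cells=0), seed=0)


class TestColabelSnapshot:
    def test_measured_distance_equals_truth(self):
        cfg = preset("wildtype")
        cells, foci, truth = generate_colabel_snapshot(cfg, 150,
                                                       population="tc", seed=1)
        from icetrack.geometry import pair_foci_table

        pairs = pair_foci_table(cells, foci)
        # each cell's measured pair distances match the generated displacements
        by_cell_meas = pairs.groupby("cell_id")["distance_nm"].sum()
        by_cell_true = truth.groupby("cell_id")["true_distance_nm"].sum()
        common = by_cell_meas.index.intersection(by_cell_true.index)
        np.testing.assert_allclose(by_cell_meas[common], by_cell_true[common],
                                   rtol=1e-9)

    def test_foci_inside_cells(self):
        cfg = preset("wildtype")
        cells, foci, _ = generate_colabel_snapshot(cfg, 200,
                                                   population="mixed", seed=2)
        lengths = cells.set_index("cell_id")["length_um"]
        L = lengths.loc[foci["cell_id"]].to_numpy()
        assert (foci["axial_um"].to_numpy() >= 0).all()
        assert (foci["axial_um"].to_numpy() <= L).all()

    def test_population_argument(self):
        cfg = preset("wildtype")
        with pytest.raises(ValueError):
            generate_colabel_snapshot(cfg, 50, population="weird", seed=0)
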