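"""Adjacency, transfer-event detection and the donor copy-number shift."""
import numpy as np
import pandas as pd
import pytest

from icetrack.lineage import FocusDistribution
from icetrack.pipeline import PipelineConfig, run_pipeline
from icetrack.transfer import (TransferEvent, adjacency,
                               detect_transfer_events,
                               donor_distribution_vs_background)


def _cells(rows, frame=0):
    return pd.DataFrame([{
        "cell_id": cid, "frame": frame, "mother_id": -1, "length_um": ln,
        "width_um": 0.7, "x_um": x, "y_um": y, "angle_rad": ang,
        "echerry": ech, "is_recipient": rec}
        for cid, x, y, ln, ang, ech, rec in rows])


class TestAdjacency:
    def test_far_cells_not_adjacent(self):
        cells = _cells([(0, 0, 0, 2.0, 0.0, 1, False),
                        (1, 5.0, 0, 2.0, 0.0, 1, False)])
        assert adjacency(cells, 0) == set()

    def test_touching_cells_adjacent(self):
        cells = _cells([(0, 0, 0, 2.0, 0.0, 1, False),
                        (1, 0, 0.75, 2.0, 0.0, 1, False)])
        assert adjacency(cells, 0) == {(0, 1)}

    def test_chain_yields_only_neighbour_pairs(self):
        cells = _cells([(0, 0.0, 0, 2.0, 0.0, 1, False),
                        (1, 2.15, 0, 2.0, 0.0, 1, False),
                        (2, 4.30, 0, 2.0, 0.0, 1, False)])
        assert adjacency(cells, 0) == {(0, 1), (1, 2)}


class TestTransferEvent:
    def test_ordering_invariant(self):
        with pytest.raises(ValueError):
            TransferEvent(donor_id=1, recipient_id=2, focus_frame=10,
                          echerry_frame=10, donor_max_foci=3,
                          status="integrated")


class TestDetectTransferEvents:
    def _scene(self, focus_frames, echerry_onset=None, n_frames=60):
        """A tc donor touching a recipient; baseline recipients around."""
        rows = []
        for f in range(n_frames):
            bright = (echerry_onset is not None and f >= echerry_onset)
            rows += [
                # donor (tc) at origin
                dict(cell_id=0, frame=f, mother_id=-1, length_um=2.0,
                     width_um=0.7, x_um=0.0, y_um=0.0, angle_rad=0.0,
                     echerry=2000.0, is_recipient=False),
                # recipient in contact
                dict(cell_id=1, frame=f, mother_id=-1, length_um=2.0,
                     width_um=0.7, x_um=0.0, y_um=0.75, angle_rad=0.0,
                     echerry=3000.0 if bright else 100.0, is_recipient=True),
            ]
            # a quiet recipient population fixing the onset baseline
            for k in range(2, 12):
                rows.append(dict(cell_id=k, frame=f, mother_id=-1,
                                 length_um=2.0, width_um=0.7, x_um=10.0 * k,
                                 y_um=0.0, angle_rad=0.0, echerry=100.0,
                                 is_recipient=True))
        cells = pd.DataFrame(rows)
        foci = pd.DataFrame([
            {"cell_id": 1, "frame": f, "channel": "CFP", "axial_um": 1.0,
             "transverse_um": 0.0, "score": 7, "intensity": 7}
            for f in focus_frames]
            + [{"cell_id": 0, "frame": f, "channel": "CFP", "axial_um": 0.5,
                "transverse_um": 0.0, "score": 7, "intensity": 7}
               for f in range(n_frames)])
        classes = pd.Series({0: "tc", **{k: "recipient" for k in range(1, 12)}})
        return cells, classes, foci

    def test_onset_within_window_is_integrated(self):
        # focus at frame 28, eCherry at frame 42: 7 h at 30-min frames
        cells, classes, foci = self._scene(range(28, 60), echerry_onset=42)
        events, unassigned = detect_transfer_events(cells, classes, foci)
        assert len(events) == 1 and not unassigned
        ev = events[0]
        assert ev.status == "integrated"
        assert ev.donor_id == 0
        assert ev.focus_frame == 28 and ev.echerry_frame == 42

    def test_vanishing_focus_without_onset_is_aborted(self):
        cells, classes, foci = self._scene([28, 29], echerry_onset=None)
        events, _ = detect_transfer_events(cells, classes, foci)
        assert events[0].status == "aborted"

    def test_onset_outside_window_flagged(self):
        # 12 h delay: outside the 3.5-10 h integration-reporting window
        cells, classes, foci = self._scene(range(20, 60), echerry_onset=44)
        events, _ = detect_transfer_events(cells, classes, foci)
        assert events[0].status == "outside_window"

    def test_recipient_without_tc_neighbour_reported_separately(self):
        cells, classes, foci = self._scene(range(28, 60), echerry_onset=42)
        classes[0] = "non_tc"
        events, unassigned = detect_transfer_events(cells, classes, foci)
        assert not events and len(unassigned) == 1


class TestDonorShift:
    def test_right_shifted_donor_distribution(self):
        events = [TransferEvent(0, k, 30, 44, 4, "integrated")
                  for k in range(5)]
        background = FocusDistribution(
            "tc", np.array([0, 50, 30, 10, 5, 0, 0, 0, 0]))
        donors, bg = donor_distribution_vs_background(events, background)
        assert donors.proportion_at_least(3) > bg.proportion_at_least(3)

    def test_no_integrated_events_rejected(self):
        background = FocusDistribution("tc", np.zeros(9, dtype=int))
        with pytest.raises(ValueError):
            donor_distribution_vs_background(
                [TransferEvent(0, 1, 5, None, 2, "aborted")], background)

    def test_generator_copy_number_mechanism(self):
        """Transfer proportional to excised copies makes transferring donors
        carry more foci than the tc background; event ordering holds."""
        ge3 = n_int = 0
        bg = []
        for seed in (5, 6):
            cfg = PipelineConfig(preset="dmfsR", seed=seed,
                                 overrides=dict(initial_cells=250,
                                                recipient_fraction=0.66,
                                                colony_spacing=2.5,
                                                frames=80))
            bundle = run_pipeline(cfg)
            events = bundle["transfer_events"] + bundle["transfer_unassigned"]
            for e in events:
                if e.status == "integrated":
                    assert e.echerry_frame > e.focus_frame
            ints = [e for e in bundle["transfer_events"]
                    if e.status == "integrated"]
            n_int += len(ints)
            ge3 += sum(1 for e in ints if e.donor_max_foci >= 3)
            bg.append(bundle["distributions"]["tc"].proportion_at_least(3))
        assert n_int >= 5
        assert ge3 / n_int > np.mean(bg)
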