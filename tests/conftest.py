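import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_run():
    """One shared wild-type pipeline run on a small population."""
    from icetrack.pipeline import PipelineConfig, run_pipeline

    cfg = PipelineConfig(preset="wildtype", seed=7,
                         overrides=dict(initial_cells=400, frames=60))
    return run_pipeline(cfg)


@pytest.fixture()
def single_cell_frame():
    """One cell, one frame, for rendering/detection fixtures."""
    return pd.DataFrame([{
        "cell_id": 0, "frame": 0, "mother_id": -1, "length_um": 2.5,
        "width_um": 0.7, "x_um": 5.0, "y_um": 5.0, "angle_rad": 0.3,
        "echerry": 100.0, "is_recipient": False,
    }])


def focus_row(cell_id=0, frame=0, channel="CFP", axial=0.5, transverse=0.0,
              score=7, intensity=7):
    return {"cell_id": cell_id, "frame": frame, "channel": channel,
            "axial_um": axial, "transverse_um": transverse,
            "score": score, "intensity": intensity}


@pytest.fixture()
def make_foci():
    def _make(rows):
        return pd.DataFrame([focus_row(**r) for r in rows],
                            columns=["cell_id", "frame", "channel",
                                     "axial_um", "transverse_um",
                                     "score", "intensity"])
    return _make
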