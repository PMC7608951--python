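import numpy as np
import pandas as pd
import pytest

from zgakit import synth
from zgakit.expression import ExpressionMatrix
from zgakit.schedule import CycleSchedule, default_schedule


@pytest.fixture(scope="session")
def sched() -> CycleSchedule:
    return default_schedule()


@pytest.fixture()
def simple_schedule() -> CycleSchedule:
    """One hand-sized schedule: cycle 13 interphase 15, mitosis 5, lag 4."""
    return CycleSchedule(cycles=((12, 12.5, 5.0), (13, 15.0, 5.0), (14, 65.0, 5.0)))


@pytest.fixture(scope="session")
def small_bundle() -> synth.StudyBundle:
    """A 400-gene synthetic study shared across tests (fixed seed)."""
    return synth.make_study(design=synth.EmbryoDesign(seed=7), n_genes=400)


@pytest.fixture()
def toy_counts() -> ExpressionMatrix:
    """3 genes x 4 samples with metadata covering two conditions."""
    values = pd.DataFrame(
        {
            "s1": [100.0, 900.0, 0.0],
            "s2": [200.0, 800.0, 0.0],
            "s3": [50.0, 940.0, 10.0],
            "s4": [60.0, 930.0, 10.0],
        },
        index=["gA", "gB", "gC"],
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "condition": ["control", "control", "arrested", "arrested"],
            "cycle_label": ["C12", "C12", "30", "30"],
            "minutes": [6.0, 6.0, 30.0, 30.0],
            "replicate": [1, 2, 1, 2],
        }
    )
    return ExpressionMatrix(values=values, stage="counts", meta=meta)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
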