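import numpy as np
import pytest

import periotag as pt


@pytest.fixture(scope="session")
def unsync_pattern():
    return pt.parse_pattern(pt.UNSYNCOPATED, 120.0)


@pytest.fixture(scope="session")
def sync_pattern():
    return pt.parse_pattern(pt.SYNCOPATED, 140.0)


@pytest.fixture(scope="session")
def listen_block(unsync_pattern):
    return pt.StimulusBlock(unsync_pattern, 6)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_electrodes(n_tracking: int, n_null: int) -> list:
    """A small right-hemisphere montage with the first channels tracking."""
    out = []
    for i in range(n_tracking):
        out.append(
            pt.ElectrodeMeta(f"T{i:03d}", "R", (30.0, 40.0, 20.0), True,
                             "R prefrontal")
        )
    for i in range(n_null):
        out.append(
            pt.ElectrodeMeta(f"N{i:03d}", "R", (40.0, -30.0, 30.0), False,
                             "R other")
        )
    return out


@pytest.fixture(scope="session")
def tiny_study_bundle():
    """A small but complete synthetic study with planted tracking electrodes."""
    design = pt.StudyDesign(
        n_participants=2, electrodes_left=2, electrodes_right=6,
        n_tracking=3, modulation_depth=0.8,
    )
    trials, truths, montages = pt.generate_study(design, seed=7)
    return design, trials, truths, montages
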