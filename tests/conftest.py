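"""Shared fixtures: a default plate map and a desk-scale simulated plate."""

import numpy as np
import pandas as pd
import pytest

import paintscope as ps


@pytest.fixture(scope="session")
def platemap():
    """Default JUMP-MOA-style layout (90 compounds / 47 MOAs / 4 reps)."""
    return ps.generate_jumpmoa_layout(seed=0)


@pytest.fixture(scope="session")
def registry():
    return ps.ChannelRegistry.five_channel(brightfield=True)


@pytest.fixture(scope="session")
def desk_cfg():
    return ps.desk_scale_config(seed=1)


@pytest.fixture(scope="session")
def desk_sim(desk_cfg):
    """(platemap, schema, library, cells) for one desk-scale plate."""
    return ps.simulate_experiment_plate(desk_cfg)


@pytest.fixture(scope="session")
def desk_profile(desk_sim):
    _, _, _, cells = desk_sim
    return ps.profile_pipeline(cells)


def toy_platemap():
    """Six-well plate: compounds A, B (shared MOA M1) and C (MOA M2)."""
    wells = pd.DataFrame(
        {
            "compound_id": ["A", "A", "B", "B", "C", "C"],
            "moa": ["M1", "M1", "M1", "M1", "M2", "M2"],
            "concentration_uM": 3.0,
            "role": "treatment",
        },
        index=pd.Index(["A01", "A02", "A03", "A04", "A05", "A06"],
                       name="well_position"),
    )
    return ps.PlateMap(plate_id="toy", wells=wells)


def toy_profile(seed=0, n_features=8):
    """Random well profiles matching :func:`toy_platemap`."""
    rng = np.random.default_rng(seed)
    pm = toy_platemap()
    df = pd.DataFrame(rng.standard_normal((6, n_features)),
                      columns=[f"Cells_Intensity_F{i}_DNA" for i in range(n_features)])
    df.insert(0, "Metadata_Plate", "toy")
    df.insert(1, "Metadata_Well", list(pm.wells.index))
    return pm, df
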