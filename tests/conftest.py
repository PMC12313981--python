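"""Shared fixtures: small synthetic plates and panels built at test time."""

import numpy as np
import pandas as pd
import pytest

from sarmap import io as sio
from sarmap import synthetic as syn


@pytest.fixture(scope="session")
def eleven_markers():
    return syn.default_markers()


@pytest.fixture(scope="session")
def eleven_panel(eleven_markers):
    return sio.PanelConfig(
        [sio.PanelMarker(m.name, m.name, m.cofactor) for m in eleven_markers]
    )


def make_marker_table(values: dict[str, np.ndarray], scale: str = "raw") -> sio.EventTable:
    """EventTable with only marker channels, from named value arrays."""
    data = pd.DataFrame(values)
    channels = [sio.Channel(name, sio.ROLE_MARKER) for name in values]
    return sio.EventTable(data, channels, scale)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_two_well_plate(eleven_markers):
    """Two vehicle wells of 5,200 cells with no debris/doublets/dead."""
    wells = [
        syn.WellSpec("A1", "vehicle", "veh-1"),
        syn.WellSpec("A2", "vehicle", "veh-2"),
    ]
    design = syn.PlateDesign(
        wells=wells,
        markers=eleven_markers,
        cells_per_well=5200,
        debris_fraction=0.0,
        doublet_fraction=0.0,
        dead_fraction=0.0,
        count_model="fixed",
        seed=11,
    )
    return syn.simulate_plate(design, [])
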