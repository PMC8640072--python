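import numpy as np
import pandas as pd
import pytest

from hepazone import SimulationConfig, SpotArray, generate_dataset


def make_spot_array(coords_px, scale=1.0, section_id="s1", sample_id="a"):
    """SpotArray from a list of (x_px, y_px) pairs."""
    coords_px = np.asarray(coords_px, float)
    df = pd.DataFrame(
        {
            "spot_id": [f"spot{i}" for i in range(len(coords_px))],
            "x_px": coords_px[:, 0],
            "y_px": coords_px[:, 1],
            "section_id": section_id,
            "sample_id": sample_id,
        }
    )
    return SpotArray(df, scale=scale)


def small_config(seed=42, **overrides):
    """A compact multi-sample study: 3 samples x 1 section, 3+3 veins, 2 ambiguous."""
    defaults = dict(
        frame_extent=(3000.0, 3200.0),
        n_samples=3,
        sections_per_sample=1,
        n_central=8,
        n_portal=8,
        n_ambiguous=2,
        vein_radius_um=60.0,
        min_separation_um=400.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_config())


@pytest.fixture(scope="session")
def marker_panel(small_dataset):
    """The 5+5 gradient marker genes used for vein classification."""
    return [g.gene_id for g in small_dataset.config.gene_panel if g.archetype.startswith("gradient")]
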