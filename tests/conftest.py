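import numpy as np
import pandas as pd
import pytest

from reefscape.habitat import PatchGrid, load_typology
from reefscape.raster import Raster


@pytest.fixture(scope="session")
def typology_l3():
    return load_typology(level="L3")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_grid(lons, lats, areas, class_id="fringing_s", N=None,
              resolution=0.25, sites=None):
    """Small hand-built patch grid."""
    index = pd.Index(range(len(lons)), name="patch_id")
    patches = pd.DataFrame(index=index)
    patches["lon"] = np.asarray(lons, dtype=float)
    patches["lat"] = np.asarray(lats, dtype=float)
    patches["N"] = np.asarray(N, dtype=float) if N is not None else np.nan
    patches["sampled_site_code"] = None
    if sites:
        for pid, code in sites.items():
            patches.loc[pid, "sampled_site_code"] = code
    class_areas = pd.DataFrame({class_id: np.asarray(areas, dtype=float)},
                               index=index)
    return PatchGrid(resolution=resolution, patches=patches,
                     class_areas=class_areas)


@pytest.fixture
def three_patch_grid():
    return make_grid(lons=[100.1, 100.4, 100.9], lats=[0.1, 0.1, 0.1],
                     areas=[10.0, 20.0, 30.0], N=[100.0, 200.0, 300.0])


def all_water_raster(nrows=10, ncols=10, west=0.0, south=0.0, resolution=0.1):
    return Raster(np.zeros((nrows, ncols), dtype=int), west=west, south=south,
                  resolution=resolution)


def genepop_text_toy():
    """Two pops x two loci, 3-digit dialect."""
    return (
        "toy data\n"
        "LocusA\n"
        "LocusB\n"
        "pop\n"
        "P1_01 , 001001 002003\n"
        "P1_02 , 001002 003003\n"
        "pop\n"
        "P2_01 , 002002 001003\n"
        "P2_02 , 001001 000000\n"
        "P2_03 , 001002 003002\n"
    )
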