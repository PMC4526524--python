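import numpy as np
import pandas as pd
import pytest

from mbddmr.model import CountMatrix, SampleInfo, SampleSheet
from mbddmr.pipeline import analyze_dataset
from mbddmr.synthio import CaptureModel, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def sim():
    """Shared synthetic dataset at default (scaled-down) study conditions."""
    return simulate_dataset(SimConfig(seed=11, target_pairs_per_sample=2000))


@pytest.fixture(scope="session")
def analysis(sim):
    """Full pipeline result on the shared dataset."""
    return analyze_dataset(sim.genome, sim.variants, sim.samples, sim.pairs_by_sample)


def two_group_sheet(n: int = 10) -> SampleSheet:
    return SampleSheet(
        [
            SampleInfo(f"s{i}", "A", "control" if i < n // 2 else "dehp")
            for i in range(n)
        ]
    )


def counts_from_array(Y, sheet=None, libsize=None) -> CountMatrix:
    Y = np.asarray(Y)
    sheet = sheet or two_group_sheet(Y.shape[1])
    ids = sheet.sample_ids
    values = pd.DataFrame(Y, index=[f"p{g}" for g in range(Y.shape[0])], columns=ids)
    if libsize is None:
        libsize = pd.Series(Y.sum(axis=0), index=ids)
    else:
        libsize = pd.Series(libsize, index=ids)
    return CountMatrix(values, sheet, libsize)


@pytest.fixture
def make_counts():
    return counts_from_array


@pytest.fixture
def factorial_sheet():
    def build(n_per_cell: int = 5, strains=("C57BL/6J", "FVB/N")):
        infos = []
        for s_i, strain in enumerate(strains):
            for treatment in ("control", "dehp"):
                for r in range(n_per_cell):
                    infos.append(
                        SampleInfo(f"st{s_i}_{treatment}_{r}", strain, treatment)
                    )
        return SampleSheet(infos)

    return build
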