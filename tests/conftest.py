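from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from socmix.compositional import CountTable
from socmix.pipeline import RunConfig, process_bundle, _load_inputs
from socmix.synthetic import (PopulationConfig, TransmissionParams,
                              build_population, simulate_dataset)

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_counts() -> CountTable:
    """12-taxon, 40-sample toy table with hand-designed totals/prevalences."""
    return CountTable.read_tsv(DATA / "toy_counts.tsv")


@pytest.fixture(scope="session")
def small_population():
    return build_population(PopulationConfig(n_groups=12, n_periods=2, seed=42))


@pytest.fixture(scope="session")
def small_dataset():
    cfg = PopulationConfig(n_groups=12, n_periods=2, seed=42)
    return simulate_dataset(cfg, TransmissionParams(), seed=42)


@pytest.fixture(scope="session")
def small_bundle():
    """Processed bundle of a 20-group simulation (all strata)."""
    cfg = RunConfig(seed=7, simulate={"population": {"n_groups": 20,
                                                     "n_periods": 2}})
    counts, annot, meta, rel, _ = _load_inputs(cfg)
    return process_bundle(counts, annot, meta, rel, cfg)
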