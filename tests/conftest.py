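import numpy as np
import pandas as pd
import pytest

from hrdscape import io as cio
from hrdscape.signatures import load_default_signatures
from hrdscape.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def signatures():
    return load_default_signatures()


@pytest.fixture(scope="session")
def test_chrom_map():
    """Two-chromosome toy genome used by hand-counted scar fixtures."""
    return cio.ChromosomeMap(pd.DataFrame([
        {"chrom": "T1", "length": 100_000_000,
         "centromere_start": 45_000_000, "centromere_end": 55_000_000},
        {"chrom": "T2", "length": 200_000_000,
         "centromere_start": 90_000_000, "centromere_end": 100_000_000},
    ]))


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """One shared small synthetic cohort (30 non-carriers, default carriers)."""
    outdir = tmp_path_factory.mktemp("cohort")
    cfg = GeneratorConfig(seed=11)
    cfg.n_noncarrier = 30
    files = generate_cohort(cfg, outdir)
    return files


@pytest.fixture(scope="session")
def small_truth(small_cohort):
    return pd.read_csv(small_cohort.ground_truth, sep="\t").set_index("sample_id")


def seg(sample, chrom, start, end, a, b):
    return cio.ASCNSegment(sample, chrom, int(start), int(end), a, b)


@pytest.fixture
def make_seg():
    return seg
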