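"""Generate a small synthetic PTV breast-tumour cohort with ground truth.

The generator emits every file the pipeline consumes (variants, ASCN
segments, expression, chromosome map, pathology table) plus a ground-truth
table for validation.  Here we shrink the non-carrier arm to keep the run
fast and show what was produced.
"""

import tempfile
from pathlib import Path

import pandas as pd

from hrdscape.simulate import GeneratorConfig, generate_cohort

config = GeneratorConfig(seed=7)
config.n_noncarrier = 50  # default is 500

with tempfile.TemporaryDirectory() as tmp:
    files = generate_cohort(config, tmp)
    truth = pd.read_csv(files.ground_truth, sep="\t")
    print("files written:", *(p.name for p in Path(tmp).iterdir()))
    print("\nsamples per carrier group / allelic status:")
    print(truth.groupby(["carrier_group", "allelic_status"]).size())
    bi = truth[truth.allelic_status == "biallelic"]
    nc = truth[truth.carrier_group == "non_carrier"]
    print(f"\nmedian somatic SNVs  biallelic: {bi.n_snv.median():.0f}   "
          f"non-carrier: {nc.n_snv.median():.0f}")
    print("(biallelic tumours carry the elevated mutation burden the "
          "cohort is constructed to show)")
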