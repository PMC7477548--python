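"""Full pipeline on a synthetic analogue library with one injected cliff.

A combinatorial library (3 lactam scaffolds x 6 substituents) is generated
with an additive potency surface, 15% of combinations withheld, and one
withheld combination carrying a 2-log substituent-driven cliff. The
pipeline rebuilds the matrix from structures alone and ranks the injected
cell as the top cliff candidate.
"""

import tempfile
from pathlib import Path

import pandas as pd

from sarmatrix import RunConfig, SimConfig, run_pipeline
from sarmatrix.synthetic_data import make_library

config = SimConfig(
    n_scaffolds=3, n_substituents=6, noise_sd=0.1, missing_frac=0.15,
    n_cliffs=1, cliff_magnitude=2.0, seed=11,
)
records, truth = make_library(config)
print(f"library: {len(records)} compounds, withheld {len(truth.withheld)}, "
      f"injected cliff at {truth.injected[0][1]} on scaffold "
      f"{truth.scaffolds.index(truth.injected[0][0]) + 1}")

workdir = Path(tempfile.mkdtemp())
csv = workdir / "library.csv"
pd.DataFrame(
    [
        {
            "compound_id": r.compound_id, "smiles": r.smiles, "value": r.value,
            "unit": r.unit, "type": r.activity_type, "relation": r.relation,
        }
        for r in records
    ]
).to_csv(csv, index=False)

summary = run_pipeline(RunConfig(input_path=str(csv), output_dir=str(workdir / "out")))
for stage, count in summary["counts"].items():
    print(f"  {stage}: {count}")

top = pd.read_csv(workdir / "out" / "cliffs.csv").iloc[0]
print("\ntop cliff candidate:")
print(f"  observed {top.observed_compound_id} (p {top.observed_p:.2f}) vs virtual "
      f"analogue predicted p {top.predicted_p:.2f}  (delta {top.delta:.2f})")
print(f"  proposed structure: {top.virtual_smiles}")
# delta ~2 log units: the injected substituent effect was learned from the
# observed analogues bearing that substituent and transferred to the
# withheld combination.
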