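"""Extract the nine quantitative features from one synthetic case.

Generates a single thymic-carcinoma phantom, writes it to disk as
NIfTI + sidecar the way real exported iodine maps would arrive, reads it
back, and prints the feature vector: seven first-order histogram statistics
of the enhanced-phase iodine density over the tumor VOI, the iodine effect
and the ECV.
"""

import tempfile
from pathlib import Path

import numpy as np

from iodect import (
    PhantomConfig,
    TumorGroup,
    case_qc,
    extract_feature_vector,
    generate_case,
    read_case,
    write_case,
)

config = PhantomConfig(seed=3)
case = generate_case(config, TumorGroup.THYMIC_CARCINOMA, np.random.default_rng(3))

with tempfile.TemporaryDirectory() as tmp:
    write_case(case, Path(tmp) / "case")
    case = read_case(Path(tmp) / "case")  # round trip is lossless

fv = extract_feature_vector(case)
qc = case_qc(case)
print(f"case {case.case_id}: hematocrit {case.hematocrit:.3f}, "
      f"VOI {qc['n_voxels']} voxels, aortic delta {qc['delta_aorta_mg_cc']:.2f} mg/cc")
for name, value in fv.as_dict().items():
    unit = {"skewness": "", "kurtosis": "", "ecv": " %"}.get(name, " mg/cc")
    print(f"  {name:>13}: {value:8.3f}{unit}")
print("\nminimum sits near the -2.9 mg/cc decomposition floor; ECV above ~21%")
print("is the operating range associated with carcinoma.")
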