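"""Generate the synthetic three-cancer-type metastatic cohort and look at
its composition.

The cohort mirrors a discovery study design: 63 metastatic pancreatic
adenocarcinomas (9 KRAS-wildtype), 14 cholangiocarcinomas and 63
colorectal adenocarcinomas, with mutation, copy-number, expression,
fusion, protein, and clinical layers that all carry planted, recoverable
structure.
"""

import pandas as pd

from kraswt.synthetic_data import SimConfig, generate_cohort

cohort = generate_cohort(SimConfig(seed=1))

types = pd.Series([s.cancer_type for s in cohort.samples]).value_counts()
print("samples per cancer type:")
print(types.to_string())

wt = [s for s in cohort.samples
      if s.cancer_type == "mPDAC" and s.kras_status == "wildtype"]
print(f"\nKRAS-wildtype mPDAC: {len(wt)} of 63")
print(f"variant calls: {len(cohort.variants)}")
print(f"copy segments: {len(cohort.segments)}")
print(f"expression matrix: {cohort.counts.values.shape} (genes x samples)")
print(f"planted signature genes: {len(cohort.truth.signature_up)} up, "
      f"{len(cohort.truth.signature_down)} down")
print(f"planted chr1q amplification carriers: "
      f"{len(cohort.truth.chr1q_carriers)}")
# The truth record is what downstream examples test recovery against.
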