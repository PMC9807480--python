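"""Clinical and clinico-molecular risk stratification.

Assigns each simulated patient a clinical stratum (SR/HR: resection,
metastasis, histology, age, MYC/MYCN status) and the integrated
clinico-molecular stratum, where subgroup VII or a WCA favorable-risk
phenotype demotes clinical SR to low risk, and subgroups II/III/V promote
clinical HR to very high risk.
"""

import pandas as pd

from mbrisk import (CohortConfig, MolecularCalls, assign_strata, generate_cohort)

cfg = CohortConfig(n_patients=400, seed=11)
patients, labels, truths = generate_cohort(cfg)

rows = []
for p, lab, t in zip(patients, labels, truths):
    chr7 = ("7p", "gain") in t.arm_aberrations
    chr8 = ("8p", "loss") in t.arm_aberrations
    chr11 = ("11p", "loss") in t.arm_aberrations
    calls = MolecularCalls(p.patient_id, {}, chr7, chr8, chr11, None,
                           t.myc_amp, t.mycn_amp)
    a = assign_strata(p, lab, calls)
    rows.append({"clinical": a.clinical, "cm": a.cm,
                 "first_reason": a.reasons[0]})
df = pd.DataFrame(rows)

print("clinical strata:")
print(df.clinical.value_counts().to_string())
print("\nclinico-molecular strata:")
print(df.cm.value_counts().to_string())
print("\nflow (clinical -> CM):")
print(pd.crosstab(df.clinical, df.cm).to_string())
# By construction clinical SR only flows to LR/SR and clinical HR only to
# HR/VHR; the audit trail records which rule fired first for each patient.
print("\nmost common triggers:")
print(df.first_reason.value_counts().head(5).to_string())
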