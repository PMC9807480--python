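# mbrisk

Clinico-molecular risk stratification for **non-WNT/non-SHH (Group 3/4)
medulloblastoma**: arm-level copy-number calling from methylation-array
log2-ratio profiles, the whole-chromosomal-aberration (WCA) phenotype,
rule-based clinical and clinico-molecular risk strata, and a survival-model
comparison framework with time-dependent Cox regression — exercised
end-to-end on a synthetic cohort generator.

## Who this is for

Biostatisticians and computational neuro-oncologists who need a
reproducible implementation of the Group 3/4 risk-stratification scheme:
given per-patient clinical covariates, methylation subgroup labels (I–VIII)
and binned copy-number data, assign each patient a risk stratum and
quantify how much prognostic information the molecular markers add.

## The method in brief

**Copy-number calls.** From a binned log2-ratio profile with per-sample
baseline $b$ (length-weighted autosomal median), an arm is *gained* when
bins with $\log_2 \ge b + 0.2$ cover $\ge 80\%$ of the profiled arm length
(*lost* analogously), *MYC*/*MYCN* are *amplified* when the length-weighted
locus median is $\ge b + 0.4$, and

- chr7 gain ⇔ 7p **and** 7q gained; chr8 loss ⇔ 8p and 8q lost;
  chr11 loss ⇔ 11p and 11q lost;
- **WCA-FR** (favorable risk) ⇔ at least 2 of {chr7 gain, chr8 loss, chr11 loss};
- **i17q** ⇔ 17p loss and 17q gain.

**Risk strata.** Clinical **SR** = R0 (residual < 1.5 cm²), M0,
non-anaplastic histology, age ≥ 4 years, no *MYC* amplification, no *MYCN*
amplification unless Group 4; otherwise clinical **HR**. Then

| clinical | modifier                        | CM stratum |
|----------|---------------------------------|------------|
| SR       | subgroup VII and/or WCA-FR      | **LR**     |
| SR       | otherwise                       | **SR**     |
| HR       | subgroup II, III or V           | **VHR**    |
| HR       | otherwise                       | **HR**     |

**Model comparison.** Cox proportional-hazards models on the counting
process $(\text{start}, \text{stop}]$ with craniospinal irradiation (CSI)
as a time-dependent 0/1 covariate, Efron tie handling. Models share the
clinical backbone (staging, CSI, *MYC*, *MYCN*) plus one biological block
(group | subgroup | WCA | combinations | CM stratum) and are ranked by the
integrated incident/dynamic ROC AUC for 5-year PFS; prediction accuracy is
measured by the IPCW (Graf) Brier curve, its integral (IBS), and the
concordance index, cross-validated by out-of-bag bootstrap.

**Synthetic cohorts.** Because patient-level data of this disease group are
not publicly deposited, the package ships a calibrated generator: subgroup
frequencies, metastasis/amplification/WCA rates per subgroup, and
exponential survival per CM stratum matched to published 5-year rates
(94% LR … 29% VHR PFS), with coupled progression/death times, independent
censoring, and CNV ground truth rendered as noisy 1 Mb bin profiles.

## Worked example

```bash
python examples/05_compare_models.py
```

prints (n = 1000 synthetic patients, B = 25 bootstrap):

```
              integrated_auc       aic  c_index    ibs  cv_ibs  cv_c_index
model
clinical               0.581  8309.568    0.583  0.168   0.170       0.574
group                  0.605  8292.815    0.609  0.165   0.167       0.605
wca                    0.606  8280.637    0.605  0.165   0.168       0.598
wca_subgroup           0.647  8226.430    0.646  0.159   0.163       0.637
cm                     0.639  8156.440    0.642  0.156   0.158       0.640

best model by integrated AUC: wca_subgroup
```

Reading it: every row is a Cox model on the same counting-process data;
`integrated_auc` is discrimination for 5-year PFS (0.5 = none), `cv_ibs`
the bootstrap out-of-bag prediction error (lower is better), `cv_c_index`
the cross-validated concordance. Adding WCA + subgroup — the combination
behind the CM strata — beats the purely clinical backbone on every metric.
`examples/04_survival_curves.py` shows the stratum-level view, e.g.
5-year PFS 91.2% ± 4.9% in CM-LR vs 27.2% ± 3.5% in CM-VHR with a log-rank
χ² of 140.5 (df 3) on 600 synthetic patients.

A thin CLI mirrors the stages (`mbrisk simulate | call-cnv | stratify |
survfit | compare-models | validate | run`); see `mbrisk --help`.

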