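"""Arm-level copy-number calling on a rendered profile.

Plants a chr7 gain, a chr11 loss and a MYC amplification, renders a noisy
binned log2-ratio profile (1 Mb bins, sd 0.1), and shows that the caller
recovers all three events: arm gains/losses need >= 0.2 log2 units over
>= 80% of the arm, amplifications >= 0.4 over the locus, and a WCA
favorable-risk phenotype needs at least two whole-chromosome events.
"""

from mbrisk import CohortConfig, call_sample, generate_cohort, load_default_genome, \
    render_profile

genome = load_default_genome()
cfg = CohortConfig(n_patients=1, seed=3, noise_sd=0.1)
_, _, truths = generate_cohort(cfg)
truth = truths[0]
truth.arm_aberrations = {("7p", "gain"), ("7q", "gain"),
                         ("11p", "loss"), ("11q", "loss")}
truth.myc_amp, truth.mycn_amp = True, False

profile = render_profile(truth, genome, cfg)
calls = call_sample(profile, genome)

print(f"profile: {len(profile.bins)} bins of {cfg.bin_size_bp // 10**6} Mb")
for arm in ("7p", "7q", "11p", "11q", "17p", "17q"):
    c = calls.arm_calls[arm]
    print(f"  {arm:>3}: {c.status:<8} gain_fraction={c.gain_fraction:.2f} "
          f"loss_fraction={c.loss_fraction:.2f}")
print(f"chr7 gain: {calls.chr7_gain}, chr11 loss: {calls.chr11_loss}, "
      f"chr8 loss: {calls.chr8_loss}")
print(f"WCA count: {calls.wca_count} -> phenotype {calls.wca_phenotype} "
      "(>= 2 markers = favorable risk)")
print(f"MYC amplified: {calls.myc_amp}, MYCN amplified: {calls.mycn_amp}")
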