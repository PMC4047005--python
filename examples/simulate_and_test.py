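"""Simulate one trial with opposite treatment effects and run the three tests.

The scenario: the treatment cuts the cancer-death hazard by 20%
(HR_CD = 0.8) but raises the non-cancer-death hazard by 25% (HR_NCD = 1.25),
the classic efficacy-vs-toxicity trade-off of adjuvant chemotherapy.
"""

from crtests import preset, run_all_tests, simulate_trial

config = preset("scenario4", rho=0.375, censor_target=0.25, seed=7)
trial = simulate_trial(config, rep_index=0)

deaths = (trial.status > 0).sum()
print(f"{trial.n} subjects, {deaths} deaths "
      f"({(trial.status == 1).sum()} cancer, {(trial.status == 2).sum()} other), "
      f"{(trial.status == 0).sum()} censored\n")

print(f"{'test':4s} {'cause':10s} {'X2':>7s} {'p':>8s} {'O-E':>8s} {'V':>8s}")
for (test, cause), r in sorted(run_all_tests(trial).items()):
    print(f"{test:4s} {cause:10s} {r.statistic:7.3f} {r.p_value:8.4f} "
          f"{r.observed_minus_expected:8.2f} {r.variance:8.2f}")

print("\nA negative O-E means fewer treated-arm events than expected under "
      "no effect;\nX2 = (O-E)^2/V is chi-square on 1 df. Expect a clear "
      "cancer-death benefit\nand an adverse non-cancer signal, sharpest for "
      "Gray's test, which keeps\ncompeting-event subjects in the risk set.")
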