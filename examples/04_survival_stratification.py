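"""Stratify a survival cohort by hub-gene alteration status.

Generates a 200-patient cohort in which 20% of patients carry upregulated
hub-gene expression and a 3x hazard, flags altered patients with the
z >= 1.96 all-genes rule, and compares the groups with Kaplan-Meier curves
and a log-rank test.
"""

import oncohub as oh

cfg = oh.SimConfig(seed=1)
study = oh.simulate_all(cfg)
truth = study.truth
cohort = study.survival.set_index("patient")
hubs = sorted(truth.hub_genes)

calls = oh.zscore_alteration(cohort, hubs, threshold=1.96)
flagged = set(calls.index[calls["altered"]])
print(f"patients flagged altered: {len(flagged)}/{len(calls)} "
      f"(planted: {len(truth.survival_altered_patients)}; "
      f"calls match truth: {flagged == truth.survival_altered_patients})")

groups = calls["altered"].map({True: "altered", False: "normal"})
stat, p = oh.logrank_test(cohort["time"], cohort["event"], groups)
print(f"log-rank chi-square = {stat:.2f}, p = {p:.3g}")

km = oh.km_estimate(cohort["time"], cohort["event"], groups)
for name, curve in km.items():
    half = curve[curve["survival"] <= 0.5]
    median = half["time"].iloc[0] if not half.empty else float("inf")
    print(f"  {name}: median survival = {median:.1f} months")
print("\nA small log-rank p with a shorter median in the altered group shows"
      "\nthe hub-gene signature separating good from poor prognosis.")
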