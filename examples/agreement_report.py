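"""Sex-stratified concurrent-validity report on a synthetic cohort.

Generates the headline scenario (101 athletes; simulated DEXA built from
the Durnin & Rahaman prediction plus a +0.8 point bias and 2.5-point
noise), runs the full agreement battery, and prints the whole-cohort
rows.  ICC (absolute agreement) near 1 with a tight CI means a system
tracks the criterion; the bias column is the mean of DEXA - prediction,
so a negative value flags systematic overestimation; the limits of
agreement bracket ~95 % of individual differences.
"""

from adipometry import paper_scenario, validity_report

cohort, truth = paper_scenario(seed=7)
report = validity_report(cohort)

table = report.table[report.table.stratum == "all"]
cols = ["equation", "n", "icc", "icc_ci_low", "icc_ci_high", "icc_class",
        "bias", "sd_diff", "loa_low", "loa_high"]
print(table[cols].round(3).to_string(index=False))

print("\ninjected / emergent bias per equation (ground truth):")
for eq, beta in truth.expected_bias.items():
    print(f"  {eq:<15s} {beta:+6.2f}")
print("\nOnly the Lohman system overestimates (negative bias); its offset is")
print("large enough to drag the absolute-agreement ICC into the poor band.")
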