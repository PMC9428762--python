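"""Loading-history effect: paired comparison of the two statuses.

Each leg is measured twice — after an hour of rest ("time zero") and
after 15 minutes of continuous weight bearing.  The paired analysis
asks, within each group, which properties shift under pre-compression.
"""

from heelpad import (
    generate_cohort,
    paired_status_table,
    properties_table,
    study_cohort_spec,
)

table = properties_table(generate_cohort(study_cohort_spec(), seed=2))
paired = paired_status_table(table)
print(paired.round({"mean_diff": 2, "statistic": 2, "p": 4}).to_string(index=False))

print()
print("mean_diff is time-zero minus post-loading: positive rows mean the")
print("property drops after sustained loading.  The generator couples the")
print("two statuses within each leg, so primary thickness and viscous")
print("modulus show the expected loading-history decline in both groups,")
print("tested with the paired t or signed-rank test as the difference")
print("distribution dictates.")
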