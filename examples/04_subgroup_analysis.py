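"""Three-group subgroup analysis with matched post-hoc tests.

Splits the diabetic group by disease course (<10 vs >=10 years) and
compares healthy / short-course / long-course primary thickness and
viscous modulus, routing to ANOVA, Brown-Forsythe or Kruskal-Wallis
with SNK-q, Tamhane T2 or Dunn post-hoc pairs.
"""

from heelpad import (
    compare_three_groups,
    generate_cohort,
    properties_table,
    study_cohort_spec,
)

table = properties_table(generate_cohort(study_cohort_spec(subgroups=True), seed=3))
tz = table[table["status"] == "time_zero"]
groups = ["healthy", "diabetesA", "diabetesB"]

for prop in ("h0_mm", "eta_kPa_s"):
    samples = [tz.loc[tz["group"] == g, prop].to_numpy() for g in groups]
    res = compare_three_groups(*samples, labels=groups)
    print(f"{prop}: {res.test_name}  statistic={res.statistic:.2f}  "
          f"p={res.p:.4f} {res.stars}")
    if res.posthoc is not None:
        print(res.posthoc.round({"statistic": 2, "p": 4}).to_string(index=False))
    print()

print("The omnibus test typically separates healthy heels from both diabetic")
print("subgroups while the two subgroups stay indistinguishable, mirroring")
print("a disease effect that does not scale simply with disease duration.")
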