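"""Per-subject microbiota plasticity and its comparison across outcomes.

Daily plasticity is the mean Bray-Curtis dissimilarity between a subject's
consecutive within-window samples; cross-period plasticity is the mean over
all pre-diet x ten-week sample pairs.  Very-successful (VS) and unsuccessful
(US) dieters are compared with a rank-sum test on the subject-level means.
"""

from plasticome import (
    classify_success,
    compare_plasticity_groups,
    fixture_small,
    plasticity_table,
)

table, metadata, tree, taxonomy, truth = fixture_small()

pt = plasticity_table(table, metadata, metrics=("braycurtis",))
daily = pt[pt.pairing == "BLvBL"]
cross = pt[pt.pairing == "BLvW10"]
print(f"mean daily (BL v. BL) plasticity:        {daily.value.mean():.3f}")
print(f"mean cross-period (BL v. 10wk) plasticity: {cross.value.mean():.3f}")

success = metadata.subjects["weight_loss_pct_12mo"].map(classify_success)
groups = success[success.isin(["US", "VS"])]
for diet in ("low-carb", "low-fat"):
    on_diet = metadata.subjects.index[metadata.subjects.diet == diet]
    u, p = compare_plasticity_groups(
        pt, groups, pairing="BLvBL", metric="braycurtis",
        subjects=[s for s in on_diet if s in groups.index],
    )
    print(f"{diet}: US vs VS daily plasticity, rank-sum U={u:.1f}, p={p:.3f}")
# A small p would indicate that daily gut-community turnover differs between
# subjects who went on to lose >10% vs <3% of their weight at 12 months.
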