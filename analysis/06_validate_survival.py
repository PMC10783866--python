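"""Validate the discovered subtypes against overall survival.

Kaplan-Meier curves per cluster, the log-rank test, a Cox fit of the
cluster-1 indicator, and agreement with the generator's hidden subtype
labels.  Writes results/km_cluster*.tsv.
"""

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from mutstrat import cox_fit, io, km_estimate, km_median, logrank_test

clinical = io.read_clinical("results/demo_data/clinical.tsv")
assignment = pd.read_csv("results/subtype_assignment.tsv", sep="\t", index_col=0)
labels = assignment["cluster"]

chi2, df, p = logrank_test(clinical, labels)
curves = km_estimate(clinical, labels)
for cluster, curve in curves.items():
    curve.to_csv(f"results/km_cluster{cluster}.tsv", sep="\t", index=False)
    median = km_median(clinical[labels == cluster])
    print(f"cluster {cluster}: n={int((labels == cluster).sum())}, "
          f"median OS {median:.1f} months")
print(f"log-rank: chi2={chi2:.2f} (df={df}), p={p:.2e}")

frame = clinical[["os_months", "os_event"]].copy()
frame["cluster1"] = (labels == 1).astype(float)
cox = cox_fit(frame, ["cluster1"])
s = cox.summary.loc["cluster1"]
print(f"Cox cluster-1 HR {s.hr:.2f} (95% CI {s.ci_low:.2f}-{s.ci_high:.2f}), p={s.p:.2e}")

if "subtype_true" in clinical.columns:
    ari = adjusted_rand_score(clinical["subtype_true"], labels)
    print(f"ARI vs planted subtypes: {ari:.3f}")
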