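"""Screen pathways for association with overall survival.

One univariate Cox proportional-hazards fit per pathway; pathways with
Wald p < 0.05 are retained (no multiplicity correction, by design), with
their hazard-ratio direction.  Writes results/prognostic_pathways.tsv.
"""

from mutstrat import io, screen_prognostic_pathways

activity = io.read_matrix("results/pathway_activity.tsv")
clinical = io.read_clinical("results/demo_data/clinical.tsv")

table = screen_prognostic_pathways(activity, clinical, alpha=0.05)
table.to_csv("results/prognostic_pathways.tsv", sep="\t")

n_risk = int((table["direction"] == "risk").sum())
print(f"retained {len(table)}/{activity.shape[1]} pathways at p < 0.05")
print(f"  {n_risk} risk (HR > 1), {len(table) - n_risk} protective (HR < 1)")
print(table.head(8).round(4))
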