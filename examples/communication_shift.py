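"""Score ligand-receptor communication and find treatment-shifted pathways.

Simulates a small single-cell cohort in which post-treatment fibroblasts
triple their NRG1 output, builds per-sample subpopulation communication
profiles, scores every (sender, receiver, LR pathway) triple with the
subpopulation-weighted expression product, and contrasts day 0 vs day 180.
"""

from tmecrosstalk.communication import (build_profiles, communication_network,
                                        communication_table, compare_pre_post,
                                        default_erbb_pairs)
from tmecrosstalk.synthetic import CohortConfig, generate_count_cohort

pairs = default_erbb_pairs()
cfg = CohortConfig(n_patients=5, n_cells_per_sample=150, n_genes=80, seed=7)
cohort = generate_count_cohort(
    cfg, lr_pairs=pairs,
    shift_spec=[{"cell_type": "fibroblast", "gene": "NRG1", "fold": 3.0}])

profiles = build_profiles(cohort.counts, cohort.cell_meta, pairs)
table = communication_table(profiles)
timepoints = cohort.cell_meta.groupby("sample")["t"].first()

tests = compare_pre_post(table, timepoints)
fib_to_cancer = tests[(tests.sender == "fibroblast") & (tests.receiver == "cancer")]
print("fibroblast -> cancer LR pathway shifts (fold change on the 1+C scale):")
print(fib_to_cancer.round(4).to_string(index=False))

G = communication_network(table, timepoints)
print("\ncell-type network edges into cancer (weight = mean log1p communication,")
print("fold_change = post/pre of within-tumor means):")
for S, R, d in G.edges(data=True):
    if R == "cancer":
        print(f"  {S:>11s} -> cancer   weight={d['weight']:.3f}  fold={d['fold_change']:.2f}")
print("\nThe NRG1 pathways from fibroblasts should show the largest fold changes;")
print("pathways whose ligand was not shifted stay near fold 1.")
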