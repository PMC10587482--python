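#!/usr/bin/env python
"""Mobility-profile classification of vesicle markers.

Runs the full pipeline on the synthetic eight-marker study (five
diffusive, two directed-rich, one pure-directed): pooled per-track
features → z-score + PCA → per-marker density shapes in PC space →
total-distance dissimilarity → average-linkage clustering cut at k = 3.
Writes scores, loadings, the dissimilarity matrix and group labels.
"""

from pathlib import Path

from vesikin import mobility_profile as mp

ROOT = Path(__file__).resolve().parent.parent / "results"
ROOT.mkdir(exist_ok=True)

table, truth = mp.synthetic_marker_study(seed=0)
scores, loadings, var = mp.pca_embed(table)
print(f"{len(table)} tracks from {table['marker'].nunique()} markers; "
      f"PC1/PC2 explain {100 * var[0]:.0f}%/{100 * var[1]:.0f}% of variance")

grid = mp.shared_grid(scores)
shapes = [mp.density_shape(scores, m, grid) for m in table["marker"].unique()]
dissim = mp.dissimilarity_matrix(shapes)
res = mp.cluster_markers(dissim, k=3)

scores.to_csv(ROOT / "profile_scores.csv", index=False)
loadings.to_csv(ROOT / "profile_loadings.csv")
dissim.to_csv(ROOT / "profile_dissimilarity.csv")
labels = res["labels"].to_frame()
labels["true_class"] = [truth[m] for m in labels.index]
labels.to_csv(ROOT / "profile_groups.csv")

print("\nmarker groups (cut at k = 3), leaf order "
      f"{res['leaf_order']}:")
print(labels.to_string())
ok = labels.groupby("group")["true_class"].nunique().max() == 1
print(f"\ngenerative classes recovered exactly: {ok}")
print(f"wrote profile_* tables to {ROOT}")
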