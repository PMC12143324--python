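"""Load a single-cell dataset, downsample it for display, and compute the
per-group statistics behind violin / dot / heatmap / metachart views.
"""

import os
import tempfile

import numpy as np

from omicview import stats
from omicview.sc import DownsampleSpec, downsample_cells, load_cell_dataset
from omicview.simulate import (
    SyntheticGenomeSpec, SyntheticSCSpec, make_assembly, simulate_sc,
)

work = tempfile.mkdtemp()
simulate_sc(SyntheticSCSpec(seed=0), work, make_assembly(SyntheticGenomeSpec()))
ds = load_cell_dataset(os.path.join(work, "rna.h5ad"))
print(f"{ds.n_cells} cells, modalities {sorted(ds.modalities)}, "
      f"embeddings {sorted(ds.embeddings)}")

# display downsampling: proportional per cluster, deterministic per seed
idx = downsample_cells(ds, DownsampleSpec("cluster", max_drawing_cells=200, seed=1))
labels = ds.metadata["cluster"].astype(str).to_numpy()
print(f"kept {len(idx)} of {ds.n_cells} cells for drawing; per-cluster:",
      {g: int((labels[idx] == g).sum()) for g in sorted(set(labels))})
# each cluster keeps its proportional share (+/- 1 cell from rounding)

# dot-plot statistics for a planted marker gene (computed on ALL cells)
for s in stats.group_feature_summary(ds, "rna", ["GENE0000"], "cluster"):
    print(f"  {s.group}: mean={s.mean:.2f}  pct_expressed={s.pct_expressed:.0%}  "
          f"median={s.quantiles[2]:.1f}  n={s.n}")
# GENE0000 is a cluster0 marker, so its cluster0 mean is ~4x the others

mat = stats.heatmap_matrix(ds, "rna", ["GENE0000", "GENE0002", "GENE0004"],
                           "cluster", scale="zscore_by_feature")
print("heatmap (z-scored across clusters):")
print(mat.round(2))

table = stats.metachart(ds, "sample", "cluster")
print("metachart fractions per sample:")
print(table.pivot(index="split", columns="category", values="fraction").round(3))
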