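"""Server-side statistics behind the comparative single-cell views.

Per-(group, feature) summaries feed violin/box/dot/heatmap plots; the
metachart is a cross-tabulation of category proportions within a
splitting variable; split views pair two overlays under one shared color
scale.  Everything here is computed on the *full* dataset — display
downsampling never feeds statistics — and is invariant to cell order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .sc.dataset import CellDataset, feature_vector

VIOLIN_BINS = 50  # fixed histogram instead of a kernel density: deterministic


@dataclass(frozen=True)
class GroupFeatureSummary:
    group: str
    feature: str
    n: int
    mean: float
    pct_expressed: float  # fraction of cells with value > 0
    quantiles: Tuple[float, float, float, float, float]  # q0,q25,q50,q75,q100
    histogram: Optional[Tuple] = None  # (bin_edges, counts)


def group_feature_summary(
    ds: CellDataset,
    assay: str,
    features: Sequence[str],
    group_column: str,
    histogram: bool = False,
) -> List[GroupFeatureSummary]:
    """Per-group mean / percent-expressed / quantiles of raw stored values."""
    if group_column not in ds.metadata.columns:
        raise KeyError(f"group column {group_column!r} not in metadata")
    labels = ds.metadata[group_column].astype(str).to_numpy()
    groups = sorted(set(labels))
    out = []
    for feat in features:
        v = feature_vector(ds, assay, feat)
        for g in groups:
            vals = v[labels == g]
            n = len(vals)
            if n == 0:
                out.append(
                    GroupFeatureSummary(g, feat, 0, np.nan, np.nan, (np.nan,) * 5)
                )
                continue
            q = tuple(np.quantile(vals, [0, 0.25, 0.5, 0.75, 1.0]).tolist())
            hist = None
            if histogram:
                counts, edges = np.histogram(vals, bins=VIOLIN_BINS)
                hist = (tuple(edges.tolist()), tuple(counts.tolist()))
            out.append(
                GroupFeatureSummary(
                    group=g,
                    feature=feat,
                    n=n,
                    mean=float(vals.mean()),
                    pct_expressed=float((vals > 0).sum()) / n,
                    quantiles=q,
                    histogram=hist,
                )
            )
    return out


def heatmap_matrix(
    ds: CellDataset,
    assay: str,
    features: Sequence[str],
    group_column: str,
    scale: str = "none",
) -> pd.DataFrame:
    """Groups x features matrix of group means, optionally z-scored
    across groups per feature (zero-variance features map to 0)."""
    if not features:
        raise ValueError("need at least one feature")
    if scale not in ("none", "zscore_by_feature"):
        raise ValueError(f"unknown scale {scale!r}")
    summaries = group_feature_summary(ds, assay, features, group_column)
    groups = sorted({s.group for s in summaries})
    mat = pd.DataFrame(index=groups, columns=list(features), dtype=float)
    for s in summaries:
        mat.loc[s.group, s.feature] = s.mean
    if scale == "zscore_by_feature":
        for f in features:
            col = mat[f].to_numpy(float)
            sd = col.std(ddof=0)
            mat[f] = 0.0 if sd == 0 else (col - col.mean()) / sd
    return mat


def metachart(ds: CellDataset, split_column: str, category_column: str) -> pd.DataFrame:
    """Counts and within-split fractions for every (split, category) pair.

    Returns a tidy frame with columns split / category / count / fraction,
    including explicit zero rows, fractions summing to 1 per split.
    """
    for col in (split_column, category_column):
        if col not in ds.metadata.columns:
            raise KeyError(f"column {col!r} not in metadata")
        s = ds.metadata[col]
        if not (isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object):
            raise TypeError(f"column {col!r} must be categorical")
    split = ds.metadata[split_column].astype(str)
    cat = ds.metadata[category_column].astype(str)
    tab = pd.crosstab(split, cat)  # includes zeros for observed label pairs
    rows = []
    for s in tab.index:
        total = int(tab.loc[s].sum())
        for c in tab.columns:
            count = int(tab.loc[s, c])
            rows.append(
                {
                    "split": s,
                    "category": c,
                    "count": count,
                    "fraction": count / total if total else 0.0,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# split view
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompareSpec:
    """What to put on each side of a split view.

    ``axis`` names the varying dimension; each selector is
    (dataset_key, assay, feature) for continuous overlays or
    (dataset_key, metadata column) for categorical ones.
    """

    axis: str  # feature | sample | modality | group
    left: tuple
    right: tuple

    def __post_init__(self):
        if self.axis not in ("feature", "sample", "modality", "group"):
            raise ValueError(f"unknown compare axis {self.axis!r}")


@dataclass
class ViewPayload:
    dataset_key: str
    overlay: np.ndarray  # per-cell values or label codes
    kind: str  # "continuous" | "categorical"
    scale: tuple  # (min, max) shared across the pair, or palette mapping
    embedding: Optional[np.ndarray] = None


def split_view(datasets: Dict[str, CellDataset], spec: CompareSpec,
               embedding: str = "umap") -> Tuple[ViewPayload, ViewPayload]:
    """Two aligned payloads under one shared color scale."""

    def resolve(sel):
        if len(sel) == 3:
            ds_key, assay, feature = sel
            ds = datasets[ds_key]
            return ds_key, ds, feature_vector(ds, assay, feature), "continuous"
        if len(sel) == 2:
            ds_key, column = sel
            ds = datasets[ds_key]
            if column not in ds.metadata.columns:
                raise KeyError(f"column {column!r} not in metadata")
            return ds_key, ds, ds.metadata[column].astype(str).to_numpy(), "categorical"
        raise ValueError(f"unresolvable selector {sel!r}")

    lk, lds, lv, lkind = resolve(spec.left)
    rk, rds, rv, rkind = resolve(spec.right)
    if lkind != rkind:
        raise ValueError("split view sides must both be continuous or both categorical")
    if spec.axis == "feature" and lkind == "categorical":
        raise ValueError("feature axis requires continuous overlays")

    if lkind == "continuous":
        lo = float(min(lv.min(), rv.min()))
        hi = float(max(lv.max(), rv.max()))
        scale = (lo, hi)
    else:
        cats = sorted(set(lv) | set(rv))
        scale = tuple(cats)  # shared palette order for shared categories

    def payload(key, ds, v):
        emb = ds.embeddings.get(embedding)
        return ViewPayload(key, np.asarray(v), lkind, scale, emb)

    return payload(lk, lds, lv), payload(rk, rds, rv)
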