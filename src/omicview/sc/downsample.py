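"""Proportional per-group random downsampling for display.

When a dataset holds more cells than the renderer can draw
(``MaxDrawingCells``), the kept cell count follows the piecewise rule

    N'' = N                 if N <= MaxDrawingCells
    N'' = MaxDrawingCells   if N >  MaxDrawingCells

and the kept cells are drawn *proportionally* from each cell group:
group ``g`` receives a quota ``MaxDrawingCells * n_g / N``, rounded by
largest remainder so the quotas sum exactly to the total, with every
non-empty group keeping at least one cell.  Sampling within a group is
uniform without replacement and fully determined by the seed.

Downsampling only ever feeds rendering; statistics are computed on the
full dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import CellDataset

DEFAULT_MAX_DRAWING_CELLS = 30_000


@dataclass(frozen=True)
class DownsampleSpec:
    group_column: str
    max_drawing_cells: int = DEFAULT_MAX_DRAWING_CELLS
    seed: int = 0

    def __post_init__(self):
        if self.max_drawing_cells < 1:
            raise ValueError("max_drawing_cells must be >= 1")


def proportional_quotas(group_sizes: dict, total: int) -> dict:
    """Largest-remainder quotas proportional to group size.

    Every non-empty group gets >= 1; quotas sum exactly to ``total``.
    Deterministic: remainders tie-break by larger group then name.
    """
    groups = {g: n for g, n in group_sizes.items() if n > 0}
    if total < len(groups):
        raise ValueError(
            f"max_drawing_cells ({total}) < number of non-empty groups ({len(groups)})"
        )
    N = sum(groups.values())
    ideal = {g: total * n / N for g, n in groups.items()}
    quota = {g: max(1, int(np.floor(x))) for g, x in ideal.items()}
    quota = {g: min(q, groups[g]) for g, q in quota.items()}

    def order(gs):
        # largest fractional remainder first; ties to bigger groups, then name
        return sorted(
            gs,
            key=lambda g: (-(ideal[g] - np.floor(ideal[g])), -groups[g], str(g)),
        )

    # pad or trim deterministically until the quotas hit the total exactly
    diff = total - sum(quota.values())
    guard = 0
    while diff != 0:
        guard += 1
        if guard > 10 * len(groups) + 10:  # pragma: no cover
            raise RuntimeError("quota adjustment failed to converge")
        if diff > 0:
            for g in order([g for g in groups if quota[g] < groups[g]]):
                quota[g] += 1
                diff -= 1
                if diff == 0:
                    break
        else:
            for g in order([g for g in groups if quota[g] > 1])[::-1]:
                quota[g] -= 1
                diff += 1
                if diff == 0:
                    break
    return quota


def downsample_cells(ds: CellDataset, spec: DownsampleSpec) -> np.ndarray:
    """Indices (ascending) of the cells to draw."""
    if spec.group_column not in ds.metadata.columns:
        raise KeyError(f"group column {spec.group_column!r} not in metadata")
    labels = ds.metadata[spec.group_column]
    if not (isinstance(labels.dtype, pd.CategoricalDtype) or labels.dtype == object):
        raise TypeError(f"group column {spec.group_column!r} must be categorical")
    labels = labels.astype(str).to_numpy()
    n = ds.n_cells
    if n <= spec.max_drawing_cells:
        return np.arange(n)

    sizes = pd.Series(labels).value_counts().to_dict()
    quotas = proportional_quotas(sizes, spec.max_drawing_cells)
    rng = np.random.default_rng(spec.seed)
    kept = []
    for g in sorted(quotas, key=str):  # fixed group order for determinism
        rows = np.where(labels == g)[0]
        take = rng.choice(rows, size=quotas[g], replace=False)
        kept.append(take)
    out = np.sort(np.concatenate(kept))
    assert len(out) == spec.max_drawing_cells
    return out
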