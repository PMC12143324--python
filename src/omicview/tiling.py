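"""Zoom-level selection and fixed-pixel-width block tiling.

The engine maps a view (pixel width + genomic range) to a discrete zoom
level and partitions the chromosome into grid-aligned blocks that are
fetched, aggregated and cached as units:

* ``realScale = ViewWidth / CurrentRange`` — true pixels per base pair of
  the current view.
* ``currentScale = findScale(realScale, desiredScales)`` — the member of a
  predefined descending scale set closest to ``realScale`` (absolute error;
  ties break toward the finer scale).
* ``blockBPs = BlockWidth / currentScale`` — bases covered by one block of
  ``BlockWidth`` pixels (default 1000), rounded up to an integer.
* block *i* spans ``[i * blockBPs, (i + 1) * blockBPs)``; the grid is
  anchored at chromosome position 0 so blocks are reusable across pans.

Signal blocks carry ``block_width`` per-pixel bins (min/max/mean/count of
the base-weighted signal); feature blocks carry the overlapping records,
thinned to a cap by descending score then span length; very dense feature
tracks fall back to per-bin record counts ("density" payloads).
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .genome.io import BedFeature, query_region
from .genome.types import (
    GenomicInterval,
    SignalPoint,
    TrackHandle,
    TrackKind,
)

#: Powers of ten from 10 px/bp (base-level detail) to 1e-7 px/bp
#: (whole-chromosome views); configurable per deployment.
DEFAULT_DESIRED_SCALES = tuple(10.0 ** -e for e in range(-1, 8))

DEFAULT_BLOCK_WIDTH = 1000
DEFAULT_MAX_RECORDS_PER_BLOCK = 2000


@dataclass(frozen=True)
class ViewState:
    """A view: its pixel width and the genomic range it displays."""

    view_width: int
    current_range: GenomicInterval

    def __post_init__(self):
        if self.view_width < 1:
            raise ValueError("view_width must be >= 1 pixel")


@dataclass(frozen=True)
class ZoomConfig:
    desired_scales: Sequence[float] = DEFAULT_DESIRED_SCALES
    block_width: int = DEFAULT_BLOCK_WIDTH
    max_records_per_block: int = DEFAULT_MAX_RECORDS_PER_BLOCK

    def __post_init__(self):
        ds = tuple(self.desired_scales)
        if any(s <= 0 for s in ds):
            raise ValueError("desired scales must be positive")
        if list(ds) != sorted(ds, reverse=True) or len(set(ds)) != len(ds):
            raise ValueError("desired scales must be strictly decreasing")
        if self.block_width < 1:
            raise ValueError("block_width must be >= 1")
        object.__setattr__(self, "desired_scales", ds)


@dataclass(frozen=True)
class BlockInfo:
    """One tile of the per-chromosome block grid."""

    index: int
    start_bp: int
    end_bp: int

    def __post_init__(self):
        if self.index < 0:
            raise ValueError("block index must be >= 0")
        if self.end_bp <= self.start_bp:
            raise ValueError("empty block")


@dataclass
class BlockData:
    """Aggregated payload of one (track, block, scale) unit."""

    block: BlockInfo
    track_id: str
    scale: float
    payload_kind: str  # "bins" | "records" | "density"
    bins: Optional[dict] = None  # arrays: min, max, mean, count, missing
    records: Optional[list] = None
    counts: Optional[np.ndarray] = None  # density payload


def compute_real_scale(view: ViewState) -> float:
    """True pixels-per-base of the view: view width over range length."""
    range_bp = len(view.current_range)
    if range_bp < 1:
        raise ValueError("current range must span at least 1 bp")
    return view.view_width / range_bp


def select_zoom_level(real_scale: float, config: ZoomConfig = ZoomConfig()) -> float:
    """Discrete zoom level: the desired scale with minimal absolute error.

    Ties break toward the larger (finer) scale, preferring detail.
    """
    scales = config.desired_scales
    if not scales:
        raise ValueError("desired_scales is empty")
    best = None
    best_err = None
    for s in scales:  # descending, so the first of a tied pair (finer) wins
        err = abs(s - real_scale)
        # ties are compared with a relative tolerance so that decimal inputs
        # whose errors are equal on paper tie in floating point too
        if best_err is None or err < best_err * (1 - 1e-9) - 1e-300:
            best, best_err = s, err
    return best


def block_bps(current_scale: float, config: ZoomConfig = ZoomConfig()) -> int:
    """Bases per block at a zoom level, rounded up to a whole base."""
    if current_scale <= 0:
        raise ValueError("current_scale must be positive")
    return max(1, int(np.ceil(config.block_width / current_scale)))


def partition_blocks(
    current_scale: float,
    current_range: GenomicInterval,
    config: ZoomConfig = ZoomConfig(),
) -> List[BlockInfo]:
    """Contiguous run of grid-aligned blocks covering the range."""
    bps = block_bps(current_scale, config)
    first = current_range.start // bps
    last = (current_range.end - 1) // bps
    return [BlockInfo(i, i * bps, (i + 1) * bps) for i in range(first, last + 1)]


def blocks_for_view(view: ViewState, config: ZoomConfig = ZoomConfig()):
    """Convenience: realScale -> currentScale -> block partition."""
    real = compute_real_scale(view)
    scale = select_zoom_level(real, config)
    return scale, partition_blocks(scale, view.current_range, config)


class BlockCache:
    """LRU cache keyed by (track_id, scale, block index)."""

    def __init__(self, max_blocks: int = 512):
        self.max_blocks = max_blocks
        self._store: OrderedDict = OrderedDict()
        self.hits = 0
        self.misses = 0

    def get(self, key):
        if key in self._store:
            self._store.move_to_end(key)
            self.hits += 1
            return self._store[key]
        self.misses += 1
        return None

    def put(self, key, value):
        self._store[key] = value
        self._store.move_to_end(key)
        while len(self._store) > self.max_blocks:
            self._store.popitem(last=False)

    def __len__(self):
        return len(self._store)


def _signal_bins(
    records: List[SignalPoint], block: BlockInfo, clip_end: int, block_width: int
) -> dict:
    """Per-pixel min/max/mean/count of a base-weighted step signal.

    Bin *j* of the block spans
    ``[start + j * span / W, start + (j + 1) * span / W)`` in bases (the
    terminal, clipped block keeps the full block's bin grid so bins stay
    aligned across zooms).  A bin with no covered base is flagged missing.
    """
    span = block.end_bp - block.start_bp
    W = block_width
    mins = np.full(W, np.inf)
    maxs = np.full(W, -np.inf)
    sums = np.zeros(W)
    counts = np.zeros(W)  # covered bases per bin

    edges = block.start_bp + np.arange(W + 1) * (span / W)
    for r in records:
        s = max(r.start, block.start_bp)
        e = min(r.end, min(block.end_bp, clip_end))
        if e <= s:
            continue
        j0 = int(np.searchsorted(edges, s, side="right")) - 1
        j1 = int(np.searchsorted(edges, e, side="left"))
        for j in range(max(j0, 0), min(j1, W)):
            lo = max(s, edges[j])
            hi = min(e, edges[j + 1])
            bases = hi - lo
            if bases <= 0:
                continue
            mins[j] = min(mins[j], r.value)
            maxs[j] = max(maxs[j], r.value)
            sums[j] += r.value * bases
            counts[j] += bases
    missing = counts == 0
    means = np.where(missing, np.nan, sums / np.where(missing, 1.0, counts))
    mins[missing] = np.nan
    maxs[missing] = np.nan
    return {
        "min": mins,
        "max": maxs,
        "mean": means,
        "count": counts,
        "missing": missing,
    }


def _record_sort_key(r):
    score = getattr(r, "score", None)
    if score is None:
        score = getattr(r, "value", 0.0) or 0.0
    length = r.end - r.start
    return (-float(score), -length, r.start)


def density_zoom_kind(
    handle: TrackHandle, current_scale: float, config: ZoomConfig = ZoomConfig()
) -> str:
    """"records" when the expected records per block fit under the cap,
    else "density" (per-bin record counts)."""
    bps = block_bps(current_scale, config)
    total_len = sum(l for _, l in handle.assembly.chromosomes)
    n = handle.record_count
    expected_per_block = n * bps / max(total_len, 1)
    return "records" if expected_per_block <= config.max_records_per_block else "density"


def fetch_block(
    handle: TrackHandle,
    block: BlockInfo,
    current_scale: float,
    chrom: str,
    cache: Optional[BlockCache] = None,
    config: ZoomConfig = ZoomConfig(),
) -> BlockData:
    """Fetch and aggregate one block of one track at one zoom level.

    The terminal block is clipped at the chromosome end.  Results are
    cache-transparent: with or without a cache the payload is identical.
    """
    resolved = handle.assembly.resolve_chrom(chrom)
    if resolved is None:
        raise KeyError(f"unknown chromosome {chrom!r}")
    key = (handle.track_id, resolved, current_scale, block.index)
    if cache is not None:
        hit = cache.get(key)
        if hit is not None:
            return hit

    chrom_len = handle.assembly.lengths[resolved]
    if block.start_bp >= chrom_len:
        raise ValueError(
            f"block [{block.start_bp}, {block.end_bp}) beyond {resolved} length {chrom_len}"
        )
    clip_end = min(block.end_bp, chrom_len)
    iv = GenomicInterval(resolved, block.start_bp, clip_end)
    records = query_region(handle, iv)

    if handle.kind is TrackKind.SIGNAL:
        bins = _signal_bins(records, block, chrom_len, config.block_width)
        data = BlockData(block, handle.track_id, current_scale, "bins", bins=bins)
    else:
        kind = density_zoom_kind(handle, current_scale, config)
        if kind == "records":
            if len(records) > config.max_records_per_block:
                records = sorted(records, key=_record_sort_key)[: config.max_records_per_block]
                records.sort(key=lambda r: (r.start, r.end))
            data = BlockData(block, handle.track_id, current_scale, "records", records=records)
        else:
            counts = _density_counts(records, block, config.block_width)
            data = BlockData(block, handle.track_id, current_scale, "density", counts=counts)

    if cache is not None:
        cache.put(key, data)
    return data


def _density_counts(records, block: BlockInfo, block_width: int) -> np.ndarray:
    """Per-pixel-bin record counts; a record increments every bin it overlaps."""
    span = block.end_bp - block.start_bp
    edges = block.start_bp + np.arange(block_width + 1) * (span / block_width)
    counts = np.zeros(block_width, dtype=np.int64)
    for r in records:
        j0 = int(np.searchsorted(edges, r.start, side="right")) - 1
        j1 = int(np.searchsorted(edges, r.end, side="left"))
        for j in range(max(j0, 0), min(j1, block_width)):
            if min(r.end, edges[j + 1]) > max(r.start, edges[j]):
                counts[j] += 1
    return counts
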