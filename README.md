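# omicview

A headless, multimodal genome-browser engine: the server-side machinery a
coordinated genomics + single-cell visualization client needs, packaged as a
Python library with a thin CLI and a small JSON/HTTP service. It is aimed at
groups building interactive viewers for epigenomics and single-cell/spatial
studies — scATAC accessibility next to gene models, Hi-C contacts across two
chromosomes, Visium slices next to embeddings — who need the data layer
(parsing, tiling, downsampling, statistics, cross-panel synchronization)
without any pixel rendering.

## What it computes

**Track tiling.** A view is a pixel width and a genomic range. The engine
computes the true resolution

    realScale = ViewWidth / CurrentRange        [px/bp]

snaps it to a discrete zoom level `currentScale = findScale(realScale,
desiredScales)` (the member of a descending scale set with minimal absolute
error; ties go to the finer scale), and partitions the chromosome into
fixed-pixel blocks of

    blockBPs = BlockWidth / currentScale        (BlockWidth = 1000 px)
    block_i  = [i * blockBPs, (i + 1) * blockBPs)

The grid is anchored at position 0, so blocks are cacheable across pans
(LRU, keyed by track x scale x block index). Signal blocks carry 1,000
per-pixel bins (min/max/mean/count of the base-weighted signal); feature
blocks carry overlapping records thinned by score, or per-bin densities when
a track is too dense to ship records.

**Single-cell serving.** Datasets load from `.h5ad`, `.h5mu` and Zarr into a
shared-cell-order store with embeddings (2-D/3-D), metadata, Visium-style
spatial slices and precomputed marker tables. When a dataset exceeds the
drawing budget `MaxDrawingCells` (default 30,000), the kept count follows

    N'' = N               if N <= MaxDrawingCells
    N'' = MaxDrawingCells if N >  MaxDrawingCells

sampled proportionally per cell group (largest-remainder rounding, >= 1 cell
per group, seed-deterministic). Spot coordinates map onto tissue images via
the 10x scale factors; 3-D groups get convex-hull surface meshes; expression
overlays get percentile-clipped linear opacity. Per-group means,
percent-expressed, quantiles and composition tables feed violin/dot/heatmap
and stacked-bar views — always computed on the full dataset, never on the
display subsample.

**Cross-panel linkage.** Genes, peaks and eQTLs act as anchors: resolving
one yields a padded genomic window (20% per side, +/- 50 kb for point
features) plus a highlight, delivered over an ordered, schema-checked
message bus. Dual-chromosome views get exactly the interaction records with
one anchor in each frame; cluster selections become scATAC pseudobulk
coverage tracks (CPM per group). A character-trigram index gives
typo-tolerant feature search, and `chrom:start-end` queries (1-based
inclusive, as users type them) parse straight to regions. Sessions
serialize to JSON and share via short store-backed URLs; projects, roles
and versioned co-annotation live in an embedded SQLite store.

## Worked example

```bash
python examples/tile_signal_track.py
```

prints

```
realScale  = 7.059e-04 px/bp   (1,200 px over 1.7 Mb)
zoom level = 1.000e-03 px/bp   (nearest member of the scale set)
blocks     = [(1, 1000000, 2000000), (2, 2000000, 3000000), (3, 3000000, 4000000)]
block 1: 1000 of 1000 pixel bins covered, mean signal 5.574
cache hits after refetch: 1  (identical payload, no recompute)
```

A 1.7 Mb view in a 1,200 px window has a true resolution of 7.06e-4 px/bp;
the engine snaps to the 1e-3 px/bp zoom level, so each 1,000 px block spans
1 Mb and the view is covered by blocks 1-3 of the chromosome grid. Every
pixel bin of block 1 is covered by the synthetic coverage track, and
refetching the block is served from the cache.

The other scripts in `examples/` each demonstrate one capability (format
parsing + region/contact queries, downsampling + plot statistics, anchors +
dual-frame links + pseudobulk, search + 3-D surfaces, collaboration +
session sharing) on synthetic fixtures generated at run time.

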