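# Methods

This note documents the models and procedures omicview implements, the
parameters that matter, what the synthetic fixtures do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Coordinates and track model

All in-memory coordinates are 0-based half-open `[start, end)`. Dialects
that are 1-based inclusive on disk (GFF3/GTF, VCF, methylC, the GWAS/eQTL
table, and `chrom:start-end` strings typed by users) convert at the I/O
boundary and convert back on write; round-trip tests check there is no
drift. Chromosome names are normalized against the declared assembly by
adding/stripping a `chr` prefix only — any other mismatch is an error that
lists the offending names, and parse failures cite the line number.

The region-query index keeps, per chromosome, records sorted by start with
a prefix running maximum of interval ends. A query binary-searches the
right boundary (start < query end) and walks left until the running
max-end proves no earlier record can still overlap. Worst case is linear
for pathologically nested tracks; typical genomic tracks terminate after a
handful of steps. The index is validated against a brute-force overlap
scan on randomized tracks and queries.

Interaction dialects follow public conventions because no schema is fixed
anywhere authoritative: longrange is `chrom start end chrom2:start2-end2,score`
and biginteract is the 18-column UCSC interact schema. The GWAS/eQTL table
is tab-delimited `chrom pos p_value score label group` with a header.
Hi-C input is dense text tiles (`#tile chrom_a chrom_b bin_size origin_a
origin_b` + matrix rows); values are raw counts, and contact queries slice
tiles by integer bin arithmetic, transposing when the pair is stored in
the other orientation. Matrix normalizations (KR/VC) are out of scope.

## Tiling

- `realScale = ViewWidth / CurrentRange` (px/bp).
- `currentScale` is the member of `desired_scales` minimizing the absolute
  error to `realScale`. The error metric is a choice — a relative metric
  would be equally defensible — and absolute error is used consistently.
  Ties prefer the finer (larger) scale: more detail over speed. Errors are
  compared with a 1e-9 relative tolerance so decimal scale sets whose
  errors tie on paper also tie in binary floating point.
- `desired_scales` defaults to powers of ten from 10 px/bp down to 1e-7
  px/bp, covering single-base detail to whole-chromosome views of the
  largest genomes; the set is configurable.
- `blockBPs = BlockWidth / currentScale`, rounded *up* to an integer base
  count so the block run always covers the view without gaps.
  `BlockWidth` is 1,000 px. The block grid is anchored at chromosome
  position 0 (not at the view start) so blocks are reusable across pans
  and shareable across users; the terminal block is clipped at the
  chromosome end rather than padded.
- Signal aggregation: each block is divided into `BlockWidth` pixel bins;
  a bin's min/max/mean/count aggregate the piecewise-constant signal
  weighted by the number of bases (fractional at bin edges) each record
  contributes. Bins with no covered base carry an explicit missing flag
  rather than a zero, so absence of data is distinguishable from zero
  signal. The oracle tests pin bins to a per-base recomputation at bin
  sizes that align on whole bases.
- Feature payloads: records are shipped as-is up to
  `max_records_per_block` (default 2,000), thinned by descending score,
  then longer span, so the most salient features survive; when the
  *expected* records per block (track density x block span) exceeds the
  cap, the payload switches to per-bin record counts. A record increments
  every bin it overlaps, once per bin.
- The cache is LRU over (track, chromosome, scale, block index), 512
  blocks by default; cache transparency (identical payloads with and
  without cache) is asserted in tests.

## Single-cell store

One dataset holds any number of modalities (matrices over a shared,
ordered cell list), embeddings of dimension 2 or 3, per-cell metadata,
optional spatial slices and an optional precomputed marker table. The
engine visualizes precomputed results: it never clusters, integrates, or
tests for markers.

On-disk mappings: `.h5ad` holds one modality (embeddings in
`obsm['X_<name>']`, slices in `obsm['spatial']` + `uns['spatial']`,
markers in `uns['markers']`); `.h5mu` and multimodal Zarr use the MuData
layout — per-modality AnnData groups under `mod/`, shared `obs`/`obsm` at
the root, written and read with anndata's element writers. Round-trips
are exact for matrices, embeddings, categorical metadata, scale factors
and marker tables.

Downsampling: the piecewise rule keeps everything up to
`MaxDrawingCells`, else exactly `MaxDrawingCells` cells. The default of
30,000 is the order of magnitude where WebGL-style scatter rendering
degrades; the parameter is exposed. Group quotas are proportional to
group size with largest-remainder rounding (ties to the larger group,
then name), a minimum of one cell per non-empty group, and deterministic
trimming/padding to hit the total exactly; within-group sampling is
uniform without replacement under a fixed seed. It is an error to ask for
fewer cells than there are non-empty groups. Statistics are always
computed on the full dataset — the subsample only ever feeds drawing, and
a test asserts summaries are unchanged by a preceding downsample.

Spatial mapping multiplies full-resolution spot coordinates and the spot
diameter by the per-image scale factor (`hires`/`lowres`), radius =
diameter x scalef / 2. Expression opacity clips at the 99th percentile —
using an observed value (numpy `method="higher"`) so short vectors keep
their maximum — then min-max scales to [0, 1]; constant vectors map to
full opacity.

Surfaces: a group's 3-D points are summarized by their convex hull,
re-oriented so all triangle normals point outward (checked against
qhull's facet equations), giving a closed, orientable mesh (every edge
shared by exactly two faces). An alpha-shape can be plugged in through
the `builder` hook for concave tissues; the hull is the default because
it is parameter-free and its containment/volume properties are exactly
testable. Meshes export to OFF and a minimal glTF-style JSON.

## View statistics

Per (group, feature): mean, fraction of cells with value strictly greater
than zero (the standard dot-plot convention), five quantiles, and an
optional 50-bin histogram for violins — a fixed histogram rather than a
kernel density so payloads are deterministic and estimator-free. The
heatmap is the groups x features matrix of means, optionally z-scored
across groups per feature with zero-variance features mapped to 0. The
metachart cross-tabulates two categorical columns into counts and
within-split fractions, including explicit zeros, with fractions summing
to 1 per split. Split views share one color scale: the joint min/max of
both sides for continuous overlays, one palette order over the union of
categories otherwise. All statistics are permutation-invariant in cell
order and are computed from raw stored values without re-normalization.

## Linkage

The message bus delivers events to per-topic listeners in emission order
with a global monotone sequence number; payloads are schema-checked at
emit time (known topics have required fields; all payloads must be
JSON-serializable) and an optional bearer-token set gates emission. HTTP
clients subscribe by polling `GET /bus/events?since=<sequence>`, which is
lossless given the sequence cursor.

Anchors resolve a feature name against gene, peak, or association tracks.
Interval features pad by 20% of their length per side; point features get
a fixed +/- 50 kb window — both clipped to the chromosome. The window
margins are engine choices (nothing canonical exists); the invariant that
matters, and is property-tested, is that re-querying the window always
re-finds the feature. Dual-frame links are exactly the interaction
records with one anchor overlapping each frame, in either anchor order.

Cluster pseudobulk bins scATAC fragments per group at a fixed bin size; a
fragment counts once in every bin it overlaps (fragment-overlap counting,
not per-base pileup — indistinguishable at browser bin sizes and much
cheaper). Normalization is counts per million fragments of the group, so
clusters of different size are comparable; raw counts are available and
sum, bin by bin, to the all-cells track.

Sessions serialize to canonical JSON with a schema version; unknown
versions fail naming the supported set. Share URLs use store-and-token
indirection (token in SQLite), keeping URLs far below the 2,048-character
limit regardless of session size; a compressed inline fragment form also
exists.

## Search

Names are lowercased, boundary-padded (`^name$`) and decomposed into
character trigrams. Scores are Jaccard overlap of gram sets plus +1.0 for
an exact case-insensitive match and +0.5 for a prefix match (range
[0, 2.5]); ties sort alphabetically. Queries shorter than the gram size
fall back to a prefix scan. `chrom:start-end` queries bypass the index
and return a region reference converted from 1-based inclusive to
half-open. Trigrams with Jaccard were chosen over a probabilistic n-gram
language model because ranking short gene symbols needs typo tolerance,
not sequence likelihood; self-retrieval (every vocabulary name ranks
itself first) is exhaustively tested.

## Collaboration service

SQLite backs projects, datasets, users, per-project roles (admin/editor/
viewer, every project keeps >= 1 admin), versioned annotations and session
tokens. Annotation synchronization is last-writer-wins with an immutable
revision history — simple, predictable, and sufficient without real-time
co-editing. Credentials are PBKDF2-salted hashes; authentication issues
bearer tokens. Batch track addition attempts each item independently and
reports per-item success/failure. Permission granularity is per-project.
The HTTP layer is a plain WSGI app on the standard library's server; the
endpoints, not the web framework, are the contract.

## Synthetic fixtures

The generators produce every input the engine consumes, deterministically
(byte-identical trees per seed, including the HDF5 containers), with a
JSON manifest recording ground truth so oracle tests never re-simulate.

Genome defaults: 2 chromosomes x 1 Mb, 50 genes/chromosome with 1-3 exon
transcripts, 2 piecewise-constant signal tracks (sine baseline + Gaussian
noise, ~500 bp steps), 200 variants and 300 methylation calls per
chromosome, 80 scored peaks, 100 interactions per chromosome pair in both
link dialects, 40 eQTLs with cell-type groups, and 10 kb contact tiles
built as rank-1 gamma outer products with 1/(1+d) distance decay and
Poisson noise, symmetrized exactly for intrachromosomal tiles.

Single-cell defaults: 600 cells, 200 genes, 3 clusters; negative-binomial
counts with mean 2 and dispersion 0.5 (variance mu + 0.5 mu^2), the
standard overdispersed scRNA stand-in; 2 planted markers per cluster at
2 log2-fold; Gaussian-blob embeddings in 2-D and 3-D with centers 6
blob-SDs apart (clusters separable, hulls disjoint); a 10x-style Visium
folder (positions CSV + scale-factors JSON); an ATAC modality over 100
peaks; and ~50 fragments per cell, 80% of them landing in the cell's own
cluster-specific peaks.

What the fixtures do *not* emulate: library-size variation, batch
effects, doublets, realistic gene structure or sequence context, Hi-C
compartment/TAD structure, or image content (image paths are carried as
references only). Passing tests therefore demonstrate the engine's
contracts — parsing, tiling arithmetic, proportionality, ordering,
round-trips — not biological fidelity of any analysis.

## Problem sizes and limitations

Tests and the acceptance script run on the fixture scales above (1 Mb
chromosomes, hundreds of cells), chosen so the full suite and the
acceptance run each finish in seconds on one CPU while still exercising
every code path, including the density fallback and cache eviction.

Known limitations: `.hic` binary input is not read (dense text tiles
stand in); Hi-C values are raw counts only; the in-memory track store
parses whole files rather than seeking with an on-disk index, which is
fine at fixture scale but would need tabix-style indexing for
multi-gigabyte tracks; the bus is in-process (the HTTP layer exposes it
by polling, not push); and co-annotation is last-writer-wins, not
conflict-free concurrent editing.
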