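"""Synthetic single-cell / spatial multimodal fixtures.

Emulates the structure (not the biology) of the datasets the engine
serves: negative-binomial RNA counts with planted per-cluster marker
genes, an ATAC modality over peak features, Gaussian-blob 2-D/3-D
embeddings, a Visium-style spatial folder with 10x scale factors, and a
barcode-tagged scATAC fragments file whose fragments fall preferentially
in cluster-specific peaks.  A JSON manifest records the planted truth
(marker assignments, effect sizes, peak regions, totals) for oracle tests.

Counts use the standard overdispersed scRNA stand-in: NB with variance
``mu + alpha * mu**2`` (``alpha`` = 0.5 by default).  What this generator
does *not* emulate: library-size variation between cells, batch effects,
dropout beyond NB sampling, or realistic genomic sequence context.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict
from typing import List, Optional

import numpy as np
import pandas as pd

from ..genome.types import GenomeAssembly
from ..sc.dataset import (
    CellDataset,
    Modality,
    ScaleFactors,
    SpatialSlice,
    save_cell_dataset,
)


@dataclass(frozen=True)
class SyntheticSCSpec:
    n_cells: int = 600
    n_genes: int = 200
    n_clusters: int = 3
    markers_per_cluster: int = 2
    marker_log2_fc: float = 2.0
    nb_mean: float = 2.0
    nb_dispersion: float = 0.5  # variance = mu + alpha * mu^2
    blob_sd: float = 1.0
    blob_separation_sd: float = 6.0  # center spacing in units of blob_sd
    embedding_3d: bool = True
    n_peaks: int = 100
    fragments_per_cell: int = 50
    peak_fragment_fraction: float = 0.8  # fragments landing in own-cluster peaks
    spatial_grid: int = 25  # spots per side of the Visium-like grid
    spot_spacing_px: float = 200.0  # full-resolution pixels between spots
    hires_scalef: float = 0.1
    lowres_scalef: float = 0.03
    spot_diameter_fullres: float = 130.0
    seed: int = 0


def _nb_counts(rng, mu, alpha, size):
    """NB draws with variance mu + alpha mu^2 (r = 1/alpha)."""
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p, size=size)


def _blob_embedding(rng, labels, n_clusters, sd, sep, dim):
    angles = 2 * np.pi * np.arange(n_clusters) / n_clusters
    centers = np.stack([np.cos(angles), np.sin(angles)], axis=1) * sep * sd / 2
    if dim == 3:
        z = np.linspace(-sep * sd / 2, sep * sd / 2, n_clusters)[:, None]
        centers = np.hstack([centers * 2, z * 2])  # widen so hulls stay disjoint
    coords = centers[labels] + rng.normal(0, sd, size=(len(labels), dim))
    return coords


def simulate_sc(spec: SyntheticSCSpec, out_dir: str,
                assembly: Optional[GenomeAssembly] = None) -> dict:
    """Write .h5ad / .h5mu / Visium folder / fragments file + manifest."""
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    n, g, k = spec.n_cells, spec.n_genes, spec.n_clusters
    cell_ids = [f"cell{i:05d}" for i in range(n)]
    gene_names = [f"GENE{j:04d}" for j in range(g)]
    labels = rng.integers(0, k, size=n)
    cluster_names = [f"cluster{c}" for c in range(k)]

    # planted markers: disjoint gene blocks per cluster
    markers = {}
    for c in range(k):
        lo = c * spec.markers_per_cluster
        markers[cluster_names[c]] = gene_names[lo : lo + spec.markers_per_cluster]

    mu = np.full((n, g), spec.nb_mean)
    fc = 2.0 ** spec.marker_log2_fc
    for c in range(k):
        rows = labels == c
        for gene in markers[cluster_names[c]]:
            mu[rows, gene_names.index(gene)] *= fc
    X = _nb_counts(rng, mu, spec.nb_dispersion, (n, g)).astype(float)

    emb2 = _blob_embedding(rng, labels, k, spec.blob_sd, spec.blob_separation_sd, 2)
    embeddings = {"umap": emb2}
    if spec.embedding_3d:
        embeddings["spatial3d"] = _blob_embedding(
            rng, labels, k, spec.blob_sd, spec.blob_separation_sd, 3
        )

    metadata = pd.DataFrame(
        {
            "cluster": pd.Categorical([cluster_names[c] for c in labels]),
            "sample": pd.Categorical(
                ["anterior" if i < n // 2 else "posterior" for i in range(n)]
            ),
            "n_counts": X.sum(axis=1),
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )

    # marker table from the planted truth (precomputed-results contract)
    marker_rows = []
    for c, genes in markers.items():
        for gene in genes:
            marker_rows.append(
                {"feature": gene, "group": c,
                 "p_value": 1e-6, "score": float(spec.marker_log2_fc)}
            )
    marker_table = pd.DataFrame(marker_rows)

    # Visium-style spatial slice on a grid
    side = spec.spatial_grid
    order = rng.permutation(n)
    coords = np.zeros((n, 2))
    array_rc = np.zeros((n, 2), dtype=int)
    for rank, i in enumerate(order):
        r, cc = divmod(rank % (side * side), side)
        jitter = rng.uniform(-10, 10, size=2)
        coords[i] = [cc * spec.spot_spacing_px + 500 + jitter[0],
                     r * spec.spot_spacing_px + 500 + jitter[1]]
        array_rc[i] = [r, cc]
    sf = ScaleFactors(spec.hires_scalef, spec.lowres_scalef, spec.spot_diameter_fullres)
    sl = SpatialSlice("slice1", sf, coords, np.arange(n))

    rna = Modality(X=X, var=pd.DataFrame(index=pd.Index(gene_names, name="feature")))

    # ATAC: peaks on the first assembly chromosome (or a nominal chr1)
    chrom = assembly.chromosomes[0][0] if assembly else "chr1"
    chrom_len = assembly.chromosomes[0][1] if assembly else 1_000_000
    peak_width = 600
    usable = chrom_len - peak_width - 1
    peak_starts = np.sort(
        rng.choice(usable // peak_width, size=spec.n_peaks, replace=False)
    ) * peak_width
    peak_names = [f"{chrom}:{s}-{s + peak_width}" for s in peak_starts]
    # cluster-specific peaks: contiguous block per cluster
    per = spec.n_peaks // k
    cluster_peaks = {
        cluster_names[c]: list(range(c * per, (c + 1) * per)) for c in range(k)
    }
    atac_mu = np.full((n, spec.n_peaks), 1.0)
    for c in range(k):
        atac_mu[np.ix_(labels == c, cluster_peaks[cluster_names[c]])] *= 3.0
    atac_X = _nb_counts(rng, atac_mu, spec.nb_dispersion, (n, spec.n_peaks)).astype(float)
    atac = Modality(
        X=atac_X, var=pd.DataFrame(index=pd.Index(peak_names, name="feature"))
    )

    ds_rna = CellDataset(
        cell_ids=cell_ids,
        modalities={"rna": rna},
        metadata=metadata.copy(),
        embeddings={k2: v.copy() for k2, v in embeddings.items()},
        spatial=[SpatialSlice("slice1", sf, coords.copy(), np.arange(n))],
        markers=marker_table.copy(),
    )
    ds_multi = CellDataset(
        cell_ids=cell_ids,
        modalities={"rna": Modality(X=X.copy(), var=rna.var.copy()), "atac": atac},
        metadata=metadata.copy(),
        embeddings={k2: v.copy() for k2, v in embeddings.items()},
        spatial=[SpatialSlice("slice1", sf, coords.copy(), np.arange(n))],
        markers=marker_table.copy(),
    )

    h5ad_path = os.path.join(out_dir, "rna.h5ad")
    h5mu_path = os.path.join(out_dir, "multi.h5mu")
    save_cell_dataset(ds_rna, h5ad_path)
    save_cell_dataset(ds_multi, h5mu_path)

    # Visium folder
    vis_dir = os.path.join(out_dir, "visium")
    os.makedirs(vis_dir, exist_ok=True)
    with open(os.path.join(vis_dir, "scalefactors_json.json"), "w") as fh:
        json.dump(
            {
                "tissue_hires_scalef": sf.tissue_hires_scalef,
                "tissue_lowres_scalef": sf.tissue_lowres_scalef,
                "spot_diameter_fullres": sf.spot_diameter_fullres,
            },
            fh, sort_keys=True,
        )
    with open(os.path.join(vis_dir, "tissue_positions.csv"), "w") as fh:
        fh.write("barcode,in_tissue,array_row,array_col,"
                 "pxl_row_in_fullres,pxl_col_in_fullres\n")
        for i, b in enumerate(cell_ids):
            fh.write(
                f"{b},1,{array_rc[i][0]},{array_rc[i][1]},"
                f"{float(coords[i][1])!r},{float(coords[i][0])!r}\n"
            )

    # fragments file: preferentially in own-cluster peaks
    frag_path = os.path.join(out_dir, "fragments.tsv")
    frags = []
    for i, b in enumerate(cell_ids):
        cname = cluster_names[labels[i]]
        own = cluster_peaks[cname]
        for _ in range(spec.fragments_per_cell):
            if rng.random() < spec.peak_fragment_fraction:
                p = int(rng.choice(own))
                s = int(peak_starts[p] + rng.integers(0, peak_width - 150))
            else:
                s = int(rng.integers(0, chrom_len - 300))
            e = s + int(rng.integers(100, 300))
            frags.append((chrom, s, min(e, chrom_len), b))
    frags.sort(key=lambda f: (f[0], f[1], f[2], f[3]))
    with open(frag_path, "w") as fh:
        for c, s, e, b in frags:
            fh.write(f"{c}\t{s}\t{e}\t{b}\n")

    manifest = {
        "spec": asdict(spec),
        "cell_ids_n": n,
        "cluster_of": {cell_ids[i]: cluster_names[labels[i]] for i in range(n)},
        "cluster_sizes": {
            cluster_names[c]: int((labels == c).sum()) for c in range(k)
        },
        "markers": markers,
        "peaks": {
            "chrom": chrom,
            "width": peak_width,
            "starts": [int(s) for s in peak_starts],
            "cluster_peaks": cluster_peaks,
        },
        "fragments_total": len(frags),
        "rna_sum": float(X.sum()),
        "atac_sum": float(atac_X.sum()),
        "files": {
            "h5ad": "rna.h5ad",
            "h5mu": "multi.h5mu",
            "visium": "visium",
            "fragments": "fragments.tsv",
        },
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, sort_keys=True)
    return manifest
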