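"""Deterministic synthetic genome-track fixtures with recorded ground truth.

One call writes a small genome's worth of every supported text format —
gene models, BED peaks, variants, bedGraph signal, methylC calls,
longrange + interact links, eQTL tables and dense Hi-C contact tiles —
plus a JSON manifest holding the generator's own record of what it wrote
(counts, per-track totals, and the raw records), so downstream tests can
check parsers and aggregation against ground truth without re-simulating.

Everything is drawn from a single seeded generator; equal specs and seeds
produce byte-identical directories.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import List, Optional

import numpy as np

from ..genome import io as gio
from ..genome.types import (
    AssociationRecord,
    ContactTile,
    GenomeAssembly,
    GenomicInterval,
    GeneModel,
    InteractionRecord,
    MethylationRecord,
    SignalPoint,
    Strand,
    Transcript,
)


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    genes_per_chrom: int = 50
    signal_tracks: int = 2
    signal_segment_bp: int = 500  # mean step length of the piecewise signal
    signal_noise_sd: float = 1.0
    variants_per_chrom: int = 200
    methylation_per_chrom: int = 300
    interactions_per_pair: int = 100
    peaks_per_chrom: int = 80
    eqtls_per_chrom: int = 40
    contact_bin_size: int = 10_000
    seed: int = 0


def _chrom_names(spec) -> List[str]:
    return [f"chr{i + 1}" for i in range(spec.n_chromosomes)]


def make_assembly(spec: SyntheticGenomeSpec) -> GenomeAssembly:
    return GenomeAssembly(
        name="synth1",
        chromosomes=tuple((c, spec.chrom_length) for c in _chrom_names(spec)),
    )


def _simulate_genes(rng, chrom, L, n) -> List[GeneModel]:
    genes = []
    slot = L // max(n, 1)
    for i in range(n):
        start = i * slot + int(rng.integers(0, max(slot // 4, 1)))
        length = int(rng.integers(2_000, max(min(slot // 2, 20_000), 2_001)))
        end = min(start + length, L)
        if end <= start + 100:
            end = start + 100
        strand = Strand.FORWARD if rng.random() < 0.5 else Strand.REVERSE
        gid = f"{chrom}g{i:04d}"
        n_ex = int(rng.integers(1, 4))
        cuts = np.sort(rng.integers(start, end, size=2 * n_ex))
        exons = []
        for k in range(n_ex):
            a, b = int(cuts[2 * k]), int(cuts[2 * k + 1])
            if b <= a:
                b = a + 1
            exons.append(GenomicInterval(chrom, a, min(b, end), strand))
        tx = Transcript(f"{gid}.t1", tuple(exons))
        genes.append(
            GeneModel(gid, f"GENE{chrom[3:]}_{i:04d}",
                      GenomicInterval(chrom, start, end, strand), (tx,))
        )
    return genes


def _simulate_signal(rng, chrom, L, seg_bp, noise_sd) -> List[SignalPoint]:
    """Piecewise-constant positive signal: sine baseline + Gaussian noise."""
    out = []
    pos = 0
    while pos < L:
        step = int(rng.integers(max(seg_bp // 2, 1), seg_bp * 2))
        end = min(pos + step, L)
        base = 5.0 + 4.0 * np.sin(2 * np.pi * pos / (L / 5))
        value = max(0.0, base + rng.normal(0, noise_sd))
        out.append(SignalPoint(GenomicInterval(chrom, pos, end), round(float(value), 6)))
        pos = end
    return out


def _simulate_contacts(rng, chrom_a, chrom_b, L, bin_size) -> ContactTile:
    """Rank-1 outer product + distance decay (intra) + Poisson noise."""
    n = int(np.ceil(L / bin_size))
    w_a = rng.gamma(2.0, 1.0, size=n)
    w_b = w_a if chrom_a == chrom_b else rng.gamma(2.0, 1.0, size=n)
    lam = np.outer(w_a, w_b)
    if chrom_a == chrom_b:
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        lam = lam * (1.0 / (1.0 + d))
        lam = (lam + lam.T) / 2
    m = rng.poisson(lam).astype(float)
    if chrom_a == chrom_b:
        m = np.triu(m) + np.triu(m, 1).T  # exactly symmetric
    return ContactTile(chrom_a, chrom_b, bin_size, 0, 0, m)


def simulate_genome(spec: SyntheticGenomeSpec, out_dir: str) -> dict:
    """Write the fixture tree and return the ground-truth manifest."""
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    assembly = make_assembly(spec)
    chroms = _chrom_names(spec)
    L = spec.chrom_length
    manifest = {"spec": asdict(spec), "assembly": {c: L for c in chroms}, "tracks": {}}

    # genes
    genes = []
    for c in chroms:
        genes.extend(_simulate_genes(rng, c, L, spec.genes_per_chrom))
    gio.write_gff3(genes, os.path.join(out_dir, "genes.gff3"))
    manifest["tracks"]["genes.gff3"] = {
        "format": "gff3",
        "n_records": len(genes),
        "records": [
            {"gene_id": g.gene_id, "gene_name": g.gene_name, "chrom": g.chrom,
             "start": g.start, "end": g.end}
            for g in genes
        ],
    }

    # peaks (BED)
    peaks = []
    for c in chroms:
        starts = np.sort(rng.integers(0, L - 1_000, size=spec.peaks_per_chrom))
        for i, s in enumerate(starts):
            width = int(rng.integers(200, 1_000))
            peaks.append(
                gio.BedFeature(
                    GenomicInterval(c, int(s), min(int(s) + width, L)),
                    name=f"{c}_peak{i:04d}",
                    score=round(float(rng.uniform(1, 1000)), 3),
                )
            )
    gio.write_bed(peaks, os.path.join(out_dir, "peaks.bed"))
    manifest["tracks"]["peaks.bed"] = {
        "format": "bed",
        "n_records": len(peaks),
        "records": [
            {"chrom": p.chrom, "start": p.start, "end": p.end, "name": p.name,
             "score": p.score}
            for p in peaks
        ],
    }

    # signal tracks
    for t in range(spec.signal_tracks):
        sig = []
        for c in chroms:
            sig.extend(_simulate_signal(rng, c, L, spec.signal_segment_bp, spec.signal_noise_sd))
        fname = f"signal_{t}.bedgraph"
        gio.write_bedgraph(sig, os.path.join(out_dir, fname))
        total = float(sum(r.value * (r.end - r.start) for r in sig))
        manifest["tracks"][fname] = {
            "format": "bedgraph",
            "n_records": len(sig),
            "value_sum": float(sum(r.value for r in sig)),
            "base_weighted_sum": total,
        }

    # variants
    variants = []
    bases = "ACGT"
    for c in chroms:
        pos = np.sort(rng.choice(L, size=spec.variants_per_chrom, replace=False))
        for i, p in enumerate(pos):
            ref = bases[int(rng.integers(0, 4))]
            alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
            variants.append(
                gio.Variant(c, int(p), ref, (alt,), variant_id=f"{c}v{i:04d}")
            )
    gio.write_vcf(variants, os.path.join(out_dir, "variants.vcf"), assembly)
    manifest["tracks"]["variants.vcf"] = {
        "format": "vcf",
        "n_records": len(variants),
        "records": [
            {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alts[0]}
            for v in variants
        ],
    }

    # methylation
    meth = []
    contexts = ["CG", "CHG", "CHH"]
    for c in chroms:
        pos = np.sort(rng.choice(L, size=spec.methylation_per_chrom, replace=False))
        for p in pos:
            ctx = contexts[int(rng.choice([0, 0, 0, 1, 2]))]  # CG-rich mix
            meth.append(
                MethylationRecord(
                    c, int(p),
                    Strand.FORWARD if rng.random() < 0.5 else Strand.REVERSE,
                    ctx,
                    round(float(rng.beta(2, 2)), 4),
                    int(rng.integers(1, 60)),
                )
            )
    gio.write_methylc(meth, os.path.join(out_dir, "methylation.tsv"))
    manifest["tracks"]["methylation.tsv"] = {
        "format": "methylc",
        "n_records": len(meth),
        "records": [
            {"chrom": m.chrom, "pos": m.pos, "context": m.context, "level": m.level}
            for m in meth
        ],
    }

    # interactions, both dialects, across all chrom pairs (incl. intra)
    inter = []
    pairs = [(a, b) for i, a in enumerate(chroms) for b in chroms[i:]]
    for ca, cb in pairs:
        for i in range(spec.interactions_per_pair):
            s1 = int(rng.integers(0, L - 5_000))
            s2 = int(rng.integers(0, L - 5_000))
            w1 = int(rng.integers(500, 5_000))
            w2 = int(rng.integers(500, 5_000))
            inter.append(
                InteractionRecord(
                    GenomicInterval(ca, s1, s1 + w1),
                    GenomicInterval(cb, s2, s2 + w2),
                    score=round(float(rng.uniform(1, 100)), 3),
                    name=f"{ca}_{cb}_link{i:04d}",
                )
            )
    gio.write_longrange(inter, os.path.join(out_dir, "links.longrange"))
    gio.write_biginteract(inter, os.path.join(out_dir, "links.interact"))
    link_records = [
        {"chrom1": r.anchor1.chrom, "start1": r.anchor1.start, "end1": r.anchor1.end,
         "chrom2": r.anchor2.chrom, "start2": r.anchor2.start, "end2": r.anchor2.end,
         "score": r.score}
        for r in inter
    ]
    manifest["tracks"]["links.longrange"] = {
        "format": "longrange", "n_records": len(inter), "records": link_records,
    }
    manifest["tracks"]["links.interact"] = {
        "format": "biginteract", "n_records": len(inter), "records": link_records,
    }

    # eQTL / GWAS associations
    assoc = []
    cell_types = ["Tcell", "Bcell", "Monocyte"]
    for c in chroms:
        pos = np.sort(rng.choice(L, size=spec.eqtls_per_chrom, replace=False))
        for i, p in enumerate(pos):
            assoc.append(
                AssociationRecord(
                    c, int(p),
                    score=round(float(rng.uniform(0, 30)), 3),
                    p_value=float(f"{rng.uniform(1e-12, 0.05):.3e}"),
                    label=f"{c}_eqtl{i:04d}",
                    group=cell_types[int(rng.integers(0, len(cell_types)))],
                )
            )
    gio.write_gwas(assoc, os.path.join(out_dir, "eqtl.tsv"))
    manifest["tracks"]["eqtl.tsv"] = {
        "format": "gwas",
        "n_records": len(assoc),
        "records": [
            {"chrom": a.chrom, "pos": a.pos, "label": a.label, "group": a.group}
            for a in assoc
        ],
    }

    # contact tiles
    tiles = [
        _simulate_contacts(rng, ca, cb, L, spec.contact_bin_size) for ca, cb in pairs
    ]
    gio.write_contact_tiles(tiles, os.path.join(out_dir, "contacts.txt"))
    manifest["tracks"]["contacts.txt"] = {
        "format": "contact",
        "n_tiles": len(tiles),
        "tile_sums": {f"{t.chrom_a}|{t.chrom_b}": float(t.matrix.sum()) for t in tiles},
    }

    with open(os.path.join(out_dir, "assembly.json"), "w") as fh:
        json.dump({"name": assembly.name, "chromosomes": [[c, L] for c in chroms]},
                  fh, sort_keys=True)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, sort_keys=True)
    return manifest


def load_assembly(path: str) -> GenomeAssembly:
    with open(path) as fh:
        d = json.load(fh)
    return GenomeAssembly(d["name"], tuple((c, int(l)) for c, l in d["chromosomes"]))
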