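"""Track parsing, coordinate conventions, region queries, contact tiles."""

import os

import numpy as np
import pytest

from omicview.genome import (
    GenomeAssembly,
    GenomicInterval,
    Strand,
    TrackParseError,
    open_track,
    query_contacts,
    query_region,
)
from omicview.genome import io as gio
from omicview.genome.index import TrackIndex
from omicview.genome.types import (
    AssociationRecord,
    ContactTile,
    MethylationRecord,
    SignalPoint,
    Variant,
)

ASM = GenomeAssembly("toy", (("chr1", 100_000), ("chr2", 100_000)))


# ---------------------------------------------------------------------------
# opening + counting + error reporting
# ---------------------------------------------------------------------------

def test_open_track_counts_match_generator(genome_dir, genome_manifest, assembly):
    for fname, info in genome_manifest["tracks"].items():
        if info["format"] == "contact":
            continue
        h = open_track(os.path.join(genome_dir, fname), info["format"], assembly)
        assert h.record_count == info["n_records"], fname


def test_three_gene_gff_fixture(tmp_path):
    path = tmp_path / "three.gff3"
    path.write_text(
        "##gff-version 3\n"
        "chr1\t.\tgene\t1001\t2000\t.\t+\t.\tID=g1;Name=ALPHA\n"
        "chr1\t.\tmRNA\t1001\t2000\t.\t+\t.\tID=g1.t1;Parent=g1\n"
        "chr1\t.\texon\t1001\t1500\t.\t+\t.\tParent=g1.t1\n"
        "chr1\t.\tgene\t3001\t4000\t.\t-\t.\tID=g2;Name=BETA\n"
        "chr2\t.\tgene\t501\t900\t.\t+\t.\tID=g3;Name=GAMMA\n"
    )
    h = open_track(str(path), "gff3", ASM)
    assert h.record_count == 3
    genes = h.index.all_records()
    g1 = [g for g in genes if g.gene_id == "g1"][0]
    # 1-based inclusive on disk -> 0-based half-open in memory
    assert (g1.start, g1.end) == (1000, 2000)
    assert g1.transcripts[0].exons[0].start == 1000


def test_bed_invalid_line_cites_line_number(tmp_path):
    lines = ["chr1\t%d\t%d\tok\n" % (i * 10, i * 10 + 5) for i in range(1, 7)]
    lines.append("chr1\t500\t400\tbad\n")  # line 7: end < start
    path = tmp_path / "bad.bed"
    path.write_text("".join(lines))
    with pytest.raises(TrackParseError, match=r":7"):
        open_track(str(path), "bed", ASM)


def test_unknown_chromosome_listed(tmp_path):
    path = tmp_path / "odd.bed"
    path.write_text("chrUn_x\t0\t10\n")
    with pytest.raises(TrackParseError, match="chrUn_x"):
        open_track(str(path), "bed", ASM)


def test_chr_prefix_normalization(tmp_path):
    path = tmp_path / "noprefix.bed"
    path.write_text("1\t10\t20\n2\t30\t40\n")
    h = open_track(str(path), "bed", ASM)
    assert sorted(h.index.chromosomes) == ["chr1", "chr2"]


def test_bedgraph_sum_matches_manifest(genome_dir, genome_manifest, assembly):
    info = genome_manifest["tracks"]["signal_0.bedgraph"]
    h = open_track(os.path.join(genome_dir, "signal_0.bedgraph"), "bedgraph", assembly)
    parsed_sum = sum(r.value for r in h.index.all_records())
    assert parsed_sum == pytest.approx(info["value_sum"], abs=1e-9)
    weighted = sum(r.value * (r.end - r.start) for r in h.index.all_records())
    assert weighted == pytest.approx(info["base_weighted_sum"], rel=1e-12)


# ---------------------------------------------------------------------------
# round-trips for every text dialect
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "fname,fmt",
    [
        ("genes.gff3", "gff3"),
        ("peaks.bed", "bed"),
        ("signal_0.bedgraph", "bedgraph"),
        ("variants.vcf", "vcf"),
        ("methylation.tsv", "methylc"),
        ("links.longrange", "longrange"),
        ("links.interact", "biginteract"),
        ("eqtl.tsv", "gwas"),
    ],
)
def test_write_read_round_trip(tmp_path, genome_dir, assembly, fname, fmt):
    h = open_track(os.path.join(genome_dir, fname), fmt, assembly)
    records = h.index.all_records()
    out = tmp_path / ("rt_" + fname)
    writer = {
        "gff3": gio.write_gff3,
        "bed": gio.write_bed,
        "bedgraph": gio.write_bedgraph,
        "vcf": lambda r, p: gio.write_vcf(r, p, assembly),
        "methylc": gio.write_methylc,
        "longrange": gio.write_longrange,
        "biginteract": gio.write_biginteract,
        "gwas": gio.write_gwas,
    }[fmt]
    writer(records, str(out))
    h2 = open_track(str(out), fmt, assembly)
    assert sorted(h2.index.all_records(), key=repr) == sorted(records, key=repr)


def test_bigwig_round_trip(tmp_path, genome_dir, assembly):
    h = open_track(os.path.join(genome_dir, "signal_0.bedgraph"), "bedgraph", assembly)
    records = h.index.all_records()
    path = str(tmp_path / "sig.bw")
    gio.write_bigwig(records, path, assembly)
    back = gio.read_bigwig(path)
    assert len(back) == len(records)
    a = sorted(records, key=lambda r: (r.chrom, r.start))
    b = sorted(back, key=lambda r: (r.chrom, r.start))
    for x, y in zip(a, b):
        assert (x.chrom, x.start, x.end) == (y.chrom, y.start, y.end)
        assert y.value == pytest.approx(x.value, rel=1e-6)  # bigWig stores float32


# ---------------------------------------------------------------------------
# region queries vs brute force
# ---------------------------------------------------------------------------

def brute_force_overlap(records, iv):
    return sorted(
        (r for r in records if r.chrom == iv.chrom and r.start < iv.end and iv.start < r.end),
        key=lambda r: (r.start, r.end),
    )


@pytest.mark.parametrize("fname,fmt", [
    ("peaks.bed", "bed"), ("genes.gff3", "gff3"),
    ("variants.vcf", "vcf"), ("methylation.tsv", "methylc"),
])
def test_query_region_equals_brute_force(genome_dir, assembly, fname, fmt):
    h = open_track(os.path.join(genome_dir, fname), fmt, assembly)
    all_records = h.index.all_records()
    rng = np.random.default_rng(5)
    L = assembly.lengths["chr1"]
    for _ in range(300):
        chrom = "chr1" if rng.random() < 0.5 else "chr2"
        a = int(rng.integers(0, L - 1))
        b = a + int(rng.integers(1, L // 4))
        iv = GenomicInterval(chrom, a, min(b, L))
        got = query_region(h, iv)
        want = brute_force_overlap(all_records, iv)
        assert [(r.start, r.end) for r in got] == [(r.start, r.end) for r in want]


def test_half_open_abutment_excluded():
    idx = TrackIndex.build([SignalPoint(GenomicInterval("chr1", 100, 200), 1.0)])
    assert idx.query(GenomicInterval("chr1", 200, 300)) == []
    assert len(idx.query(GenomicInterval("chr1", 199, 300))) == 1


def test_empty_region_returns_empty(genome_dir, assembly):
    h = open_track(os.path.join(genome_dir, "peaks.bed"), "bed", assembly)
    with pytest.raises(KeyError):
        query_region(h, GenomicInterval("chrMT", 0, 100))


def test_nested_intervals_query():
    # fully nested features exercise the max-end augmentation walk
    recs = [SignalPoint(GenomicInterval("chr1", 0, 10_000), 1.0)]
    recs += [SignalPoint(GenomicInterval("chr1", 100 * i, 100 * i + 10), float(i)) for i in range(1, 50)]
    idx = TrackIndex.build(recs)
    got = idx.query(GenomicInterval("chr1", 4999, 5001))
    want = brute_force_overlap(recs, GenomicInterval("chr1", 4999, 5001))
    assert [(r.start, r.end) for r in got] == [(r.start, r.end) for r in want]


# ---------------------------------------------------------------------------
# coordinate conventions of 1-based dialects
# ---------------------------------------------------------------------------

def test_vcf_methylc_gwas_one_based_conversion(tmp_path):
    vcf = tmp_path / "a.vcf"
    vcf.write_text("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
                   "chr1\t1\trs1\tA\tC\t.\t.\t.\n")
    v = gio.read_vcf(str(vcf))[0]
    assert v.pos == 0  # first base of the chromosome

    m = tmp_path / "m.tsv"
    m.write_text("chr1\t1\t+\tCG\t0.5\t10\n")
    assert gio.read_methylc(str(m))[0].pos == 0

    g = tmp_path / "g.tsv"
    g.write_text("chrom\tpos\tp_value\tscore\tlabel\tgroup\n"
                 "chr1\t1\t0.01\t5\tsnp1\tTcell\n")
    assert gio.read_gwas(str(g))[0].pos == 0


def test_methylation_level_validation(tmp_path):
    m = tmp_path / "m.tsv"
    m.write_text("chr1\t10\t+\tCG\t1.5\t10\n")
    with pytest.raises(TrackParseError, match=r":1"):
        gio.read_methylc(str(m))


# ---------------------------------------------------------------------------
# contact tiles
# ---------------------------------------------------------------------------

def test_contact_full_range_round_trip(genome_dir, genome_manifest, assembly):
    h = open_track(os.path.join(genome_dir, "contacts.txt"), "contact", assembly)
    L = assembly.lengths["chr1"]
    tile = query_contacts(
        h, GenomicInterval("chr1", 0, L), GenomicInterval("chr1", 0, L), 10_000
    )
    stored = [t for t in h.extra["tiles"] if t.chrom_a == "chr1" and t.chrom_b == "chr1"][0]
    assert np.array_equal(tile.matrix, stored.matrix)
    s = genome_manifest["tracks"]["contacts.txt"]["tile_sums"]["chr1|chr1"]
    assert tile.matrix.sum() == pytest.approx(s)


def test_intra_tile_symmetric(genome_dir, assembly):
    h = open_track(os.path.join(genome_dir, "contacts.txt"), "contact", assembly)
    iv = GenomicInterval("chr1", 100_000, 400_000)
    tile = query_contacts(h, iv, iv, 10_000)
    assert np.array_equal(tile.matrix, tile.matrix.T)


def test_sub_tile_equals_index_slicing(genome_dir, assembly):
    h = open_track(os.path.join(genome_dir, "contacts.txt"), "contact", assembly)
    full = [t for t in h.extra["tiles"] if (t.chrom_a, t.chrom_b) == ("chr1", "chr2")][0]
    a = GenomicInterval("chr1", 130_000, 370_000)
    b = GenomicInterval("chr2", 250_000, 610_000)
    tile = query_contacts(h, a, b, 10_000)
    # oracle: slice the full matrix by integer bin arithmetic
    ia0, ia1 = 130_000 // 10_000, -(-370_000 // 10_000)
    ib0, ib1 = 250_000 // 10_000, -(-610_000 // 10_000)
    assert np.array_equal(tile.matrix, full.matrix[ia0:ia1, ib0:ib1])
    assert tile.origin_a == ia0 * 10_000 and tile.origin_b == ib0 * 10_000


def test_unavailable_bin_size_lists_options(genome_dir, assembly):
    h = open_track(os.path.join(genome_dir, "contacts.txt"), "contact", assembly)
    iv = GenomicInterval("chr1", 0, 50_000)
    with pytest.raises(ValueError, match="10000"):
        query_contacts(h, iv, iv, 123)
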