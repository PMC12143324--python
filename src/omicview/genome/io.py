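"""Readers and writers for the supported track formats.

Supported text dialects: GFF3, GTF, BED3/6, bedGraph, VCF 4.x, methylC
(``chrom pos strand context level coverage``), longrange
(``chrom start end chrom2:start2-end2,score``), biginteract (UCSC interact
BED5+13), GWAS/eQTL tab (``chrom pos p_value score label group`` with
header), and dense Hi-C text tiles.  bigWig is read/written through pyBigWig.

Text dialects are parsed in-package rather than through pysam/cyvcf2: the
error contract (name the offending line number, list unknown chromosomes)
is part of the module surface and the library parsers do not expose it.
Only the columns the data model carries are interpreted; everything is
re-emitted losslessly by the paired writer for round-trip tests.
"""

from __future__ import annotations

import os
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, List, Optional

import numpy as np

from .index import TrackIndex
from .types import (
    AssociationRecord,
    ContactTile,
    GenomeAssembly,
    GenomicInterval,
    GeneModel,
    InteractionRecord,
    MethylationRecord,
    SignalPoint,
    Strand,
    TrackHandle,
    TrackKind,
    Transcript,
    Variant,
)


class TrackParseError(ValueError):
    """Raised when a track file fails to parse; carries the line number."""

    def __init__(self, path: str, line_no: Optional[int], message: str):
        self.path = path
        self.line_no = line_no
        where = f"{path}:{line_no}" if line_no is not None else path
        super().__init__(f"{where}: {message}")


def _split(line: str) -> List[str]:
    return line.rstrip("\n").split("\t")


def _parse_int(fields, i, path, ln, what):
    try:
        return int(fields[i])
    except (ValueError, IndexError):
        raise TrackParseError(path, ln, f"cannot parse {what} from column {i + 1}")


def _parse_float(fields, i, path, ln, what):
    try:
        return float(fields[i])
    except (ValueError, IndexError):
        raise TrackParseError(path, ln, f"cannot parse {what} from column {i + 1}")


def _iter_data_lines(path):
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track ") or line.startswith("browser "):
                continue
            yield ln, line


# ---------------------------------------------------------------------------
# BED family
# ---------------------------------------------------------------------------

def read_bed(path: str):
    """BED3/6 as bare intervals carried in SignalPoint(score) records."""
    records = []
    for ln, line in _iter_data_lines(path):
        f = _split(line)
        if len(f) < 3:
            raise TrackParseError(path, ln, f"BED needs >= 3 columns, got {len(f)}")
        chrom = f[0]
        start = _parse_int(f, 1, path, ln, "start")
        end = _parse_int(f, 2, path, ln, "end")
        if end <= start:
            raise TrackParseError(path, ln, f"end ({end}) must be > start ({start})")
        if start < 0:
            raise TrackParseError(path, ln, f"negative start {start}")
        score = _parse_float(f, 4, path, ln, "score") if len(f) >= 5 and f[4] != "." else 0.0
        strand = Strand.parse(f[5]) if len(f) >= 6 else Strand.UNSTRANDED
        name = f[3] if len(f) >= 4 else "."
        iv = GenomicInterval(chrom, start, end, strand)
        records.append(BedFeature(interval=iv, name=name, score=score))
    return records


@dataclass(frozen=True)
class BedFeature:
    """Generic BED feature (name + score)."""

    interval: GenomicInterval
    name: str = "."
    score: float = 0.0

    @property
    def chrom(self):
        return self.interval.chrom

    @property
    def start(self):
        return self.interval.start

    @property
    def end(self):
        return self.interval.end


def write_bed(records: Iterable[BedFeature], path: str):
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{_fmt(r.score)}\t{r.interval.strand.value}\n"
            )


def _fmt(x: float) -> str:
    """Stable float formatting for text round-trips."""
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(path: str) -> List[SignalPoint]:
    records = []
    for ln, line in _iter_data_lines(path):
        f = _split(line)
        if len(f) < 4:
            raise TrackParseError(path, ln, f"bedGraph needs 4 columns, got {len(f)}")
        start = _parse_int(f, 1, path, ln, "start")
        end = _parse_int(f, 2, path, ln, "end")
        if end <= start:
            raise TrackParseError(path, ln, f"end ({end}) must be > start ({start})")
        value = _parse_float(f, 3, path, ln, "value")
        records.append(SignalPoint(GenomicInterval(f[0], start, end), value))
    return records


def write_bedgraph(records: Iterable[SignalPoint], path: str):
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{_fmt(r.value)}\n")


# ---------------------------------------------------------------------------
# bigWig
# ---------------------------------------------------------------------------

def read_bigwig(path: str) -> List[SignalPoint]:
    import pyBigWig

    bw = pyBigWig.open(path)
    try:
        records = []
        for chrom in bw.chroms():
            for start, end, value in (bw.intervals(chrom) or []):
                records.append(SignalPoint(GenomicInterval(chrom, int(start), int(end)), float(value)))
        return records
    finally:
        bw.close()


def write_bigwig(records: Iterable[SignalPoint], path: str, assembly: GenomeAssembly):
    import pyBigWig

    by_chrom = defaultdict(list)
    for r in records:
        by_chrom[r.chrom].append(r)
    bw = pyBigWig.open(path, "w")
    header = [(c, int(l)) for c, l in assembly.chromosomes if c in by_chrom]
    bw.addHeader(header)
    for chrom, _ in header:
        rs = sorted(by_chrom[chrom], key=lambda r: r.start)
        bw.addEntries(
            [chrom] * len(rs),
            [r.start for r in rs],
            ends=[r.end for r in rs],
            values=[float(r.value) for r in rs],
        )
    bw.close()


# ---------------------------------------------------------------------------
# GFF3 / GTF gene models
# ---------------------------------------------------------------------------

def _gff_attrs(field: str) -> dict:
    out = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
        elif " " in part:  # GTF style: key "value"
            k, v = part.split(" ", 1)
            v = v.strip().strip('"')
        else:
            continue
        out[k.strip()] = v.strip()
    return out


def _read_gene_rows(path: str, dialect: str):
    rows = []
    for ln, line in _iter_data_lines(path):
        f = _split(line)
        if len(f) < 9:
            raise TrackParseError(path, ln, f"{dialect} needs 9 columns, got {len(f)}")
        start1 = _parse_int(f, 3, path, ln, "start")
        end1 = _parse_int(f, 4, path, ln, "end")
        if start1 < 1 or end1 < start1:
            raise TrackParseError(path, ln, f"bad 1-based span {start1}..{end1}")
        rows.append(
            dict(
                ln=ln,
                chrom=f[0],
                type=f[2],
                start=start1 - 1,  # to 0-based half-open
                end=end1,
                strand=Strand.parse(f[6]),
                attrs=_gff_attrs(f[8]),
            )
        )
    return rows


def read_gff3(path: str, dialect: str = "gff3") -> List[GeneModel]:
    """Assemble GeneModel records from gene/mRNA-transcript/exon/CDS rows."""
    rows = _read_gene_rows(path, dialect)
    genes = {}
    tx_rows = {}
    tx_parent = {}
    children = defaultdict(lambda: {"exons": [], "cds": []})

    for row in rows:
        t = row["type"].lower()
        a = row["attrs"]
        if dialect == "gtf":
            gid = a.get("gene_id")
            tid = a.get("transcript_id")
            if t == "gene" and gid:
                genes[gid] = row
            elif t in ("transcript", "mrna") and tid:
                tx_rows[tid] = row
                tx_parent[tid] = gid
            elif t in ("exon", "cds") and tid:
                tx_parent.setdefault(tid, gid)
                children[tid]["exons" if t == "exon" else "cds"].append(row)
        else:
            rid = a.get("ID")
            parent = a.get("Parent")
            if t == "gene":
                if rid is None:
                    raise TrackParseError(path, row["ln"], "gene row lacks ID attribute")
                genes[rid] = row
            elif t in ("mrna", "transcript"):
                if rid is None:
                    raise TrackParseError(path, row["ln"], "transcript row lacks ID attribute")
                tx_rows[rid] = row
                tx_parent[rid] = parent
            elif t in ("exon", "cds"):
                if parent is None:
                    raise TrackParseError(path, row["ln"], f"{t} row lacks Parent attribute")
                children[parent]["exons" if t == "exon" else "cds"].append(row)

    # synthesize gene rows for orphan transcripts (common in GTF exports)
    for tid, g in tx_parent.items():
        if g is not None and g not in genes and tid in tx_rows:
            row = dict(tx_rows[tid])
            row["attrs"] = {"ID": g, "Name": g}
            genes[g] = row

    models = []
    for gid, grow in genes.items():
        txs = []
        for tid, trow in tx_rows.items():
            if tx_parent.get(tid) != gid:
                continue
            ex = tuple(
                GenomicInterval(r["chrom"], r["start"], r["end"], r["strand"])
                for r in sorted(children[tid]["exons"], key=lambda r: r["start"])
            )
            cds = tuple(
                GenomicInterval(r["chrom"], r["start"], r["end"], r["strand"])
                for r in sorted(children[tid]["cds"], key=lambda r: r["start"])
            )
            txs.append(Transcript(tid, ex, cds))
        name = grow["attrs"].get("Name") or grow["attrs"].get("gene_name") or gid
        iv = GenomicInterval(grow["chrom"], grow["start"], grow["end"], grow["strand"])
        models.append(GeneModel(gid, name, iv, tuple(sorted(txs, key=lambda t: t.transcript_id))))
    models.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return models


def write_gff3(models: Iterable[GeneModel], path: str):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            s = g.interval.strand.value
            fh.write(
                f"{g.chrom}\t.\tgene\t{g.start + 1}\t{g.end}\t.\t{s}\t.\t"
                f"ID={g.gene_id};Name={g.gene_name}\n"
            )
            for t in g.transcripts:
                if t.exons:
                    tstart = min(e.start for e in t.exons)
                    tend = max(e.end for e in t.exons)
                else:
                    tstart, tend = g.start, g.end
                fh.write(
                    f"{g.chrom}\t.\tmRNA\t{tstart + 1}\t{tend}\t.\t{s}\t.\t"
                    f"ID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{g.chrom}\t.\texon\t{e.start + 1}\t{e.end}\t.\t{s}\t.\t"
                        f"Parent={t.transcript_id}\n"
                    )
                for c in t.cds:
                    fh.write(
                        f"{g.chrom}\t.\tCDS\t{c.start + 1}\t{c.end}\t.\t{s}\t0\t"
                        f"Parent={t.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str) -> List[Variant]:
    records = []
    for ln, line in _iter_data_lines(path):
        f = _split(line)
        if len(f) < 8:
            raise TrackParseError(path, ln, f"VCF needs 8 columns, got {len(f)}")
        pos1 = _parse_int(f, 1, path, ln, "POS")
        if pos1 < 1:
            raise TrackParseError(path, ln, f"POS must be >= 1, got {pos1}")
        alts = tuple(f[4].split(",")) if f[4] != "." else ()
        info = ()
        if f[7] != ".":
            kv = []
            for item in f[7].split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    kv.append((k, v))
                else:
                    kv.append((item, True))
            info = tuple(kv)
        records.append(Variant(f[0], pos1 - 1, f[3], alts, variant_id=f[2], info=info))
    return records


def write_vcf(records: Iterable[Variant], path: str, assembly: Optional[GenomeAssembly] = None):
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if assembly is not None:
            for c, l in assembly.chromosomes:
                fh.write(f"##contig=<ID={c},length={l}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            alt = ",".join(r.alts) if r.alts else "."
            info = (
                ";".join(k if v is True else f"{k}={v}" for k, v in r.info) if r.info else "."
            )
            fh.write(f"{r.chrom}\t{r.pos + 1}\t{r.variant_id}\t{r.ref}\t{alt}\t.\t.\t{info}\n")


# ---------------------------------------------------------------------------
# methylC
# ---------------------------------------------------------------------------

def read_methylc(path: str) -> List[MethylationRecord]:
    records = []
    for ln, line in _iter_data_lines(path):
        f = _split(line)
        if len(f) < 6:
            raise TrackParseError(path, ln, f"methylC needs 6 columns, got {len(f)}")
        pos1 = _parse_int(f, 1, path, ln, "pos")
        level = _parse_float(f, 4, path, ln, "level")
        cov = _parse_int(f, 5, path, ln, "coverage")
        try:
            records.append(
                MethylationRecord(f[0], pos1 - 1, Strand.parse(f[2]), f[3], level, cov)
            )
        except ValueError as e:
            raise TrackParseError(path, ln, str(e))
    return records


def write_methylc(records: Iterable[MethylationRecord], path: str):
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t{r.strand.value}\t{r.context}\t"
                f"{_fmt(r.level)}\t{r.coverage}\n"
            )


# ---------------------------------------------------------------------------
# longrange / biginteract
# ---------------------------------------------------------------------------

def read_longrange(path: str) -> List[InteractionRecord]:
    """WashU longrange: ``chrom start end chrom2:start2-end2,score``."""
    records = []
    for ln, line in _iter_data_lines(path):
        f = _split(line)
        if len(f) < 4:
            raise TrackParseError(path, ln, f"longrange needs 4 columns, got {len(f)}")
        start = _parse_int(f, 1, path, ln, "start")
        end = _parse_int(f, 2, path, ln, "end")
        target = f[3]
        try:
            loc, score_s = target.rsplit(",", 1)
            chrom2, span = loc.split(":")
            s2, e2 = span.split("-")
            a2 = GenomicInterval(chrom2, int(s2), int(e2))
            score = float(score_s)
        except (ValueError, IndexError):
            raise TrackParseError(path, ln, f"cannot parse longrange target {target!r}")
        records.append(InteractionRecord(GenomicInterval(f[0], start, end), a2, score))
    return records


def write_longrange(records: Iterable[InteractionRecord], path: str):
    with open(path, "w") as fh:
        for r in records:
            a2 = r.anchor2
            fh.write(
                f"{r.anchor1.chrom}\t{r.anchor1.start}\t{r.anchor1.end}\t"
                f"{a2.chrom}:{a2.start}-{a2.end},{_fmt(r.score)}\n"
            )


def read_biginteract(path: str) -> List[InteractionRecord]:
    """UCSC interact schema (BED5+13): anchors in columns 9-11 and 14-16."""
    records = []
    for ln, line in _iter_data_lines(path):
        f = _split(line)
        if len(f) < 18:
            raise TrackParseError(path, ln, f"interact needs 18 columns, got {len(f)}")
        score = _parse_float(f, 4, path, ln, "score")
        a1 = GenomicInterval(
            f[8], _parse_int(f, 9, path, ln, "sourceStart"), _parse_int(f, 10, path, ln, "sourceEnd")
        )
        a2 = GenomicInterval(
            f[13], _parse_int(f, 14, path, ln, "targetStart"), _parse_int(f, 15, path, ln, "targetEnd")
        )
        records.append(InteractionRecord(a1, a2, score, name=f[3]))
    return records


def write_biginteract(records: Iterable[InteractionRecord], path: str):
    with open(path, "w") as fh:
        for r in records:
            a1, a2 = r.anchor1, r.anchor2
            span_chrom = a1.chrom
            span_start = min(a1.start, a2.start) if a1.chrom == a2.chrom else a1.start
            span_end = max(a1.end, a2.end) if a1.chrom == a2.chrom else a1.end
            fh.write(
                "\t".join(
                    [
                        span_chrom,
                        str(span_start),
                        str(span_end),
                        r.name,
                        _fmt(r.score),
                        _fmt(r.score),
                        ".",
                        "0",
                        a1.chrom,
                        str(a1.start),
                        str(a1.end),
                        ".",
                        ".",
                        a2.chrom,
                        str(a2.start),
                        str(a2.end),
                        ".",
                        ".",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GWAS / eQTL tab
# ---------------------------------------------------------------------------

_GWAS_HEADER = ["chrom", "pos", "p_value", "score", "label", "group"]


def read_gwas(path: str) -> List[AssociationRecord]:
    records = []
    seen_header = False
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if not seen_header:
                if [c.strip().lower() for c in f[:6]] != _GWAS_HEADER:
                    raise TrackParseError(
                        path, ln, f"expected header {' '.join(_GWAS_HEADER)!r}"
                    )
                seen_header = True
                continue
            if len(f) < 6:
                raise TrackParseError(path, ln, f"needs 6 columns, got {len(f)}")
            pos1 = _parse_int(f, 1, path, ln, "pos")
            p = _parse_float(f, 2, path, ln, "p_value")
            score = _parse_float(f, 3, path, ln, "score")
            try:
                records.append(AssociationRecord(f[0], pos1 - 1, score, p, f[4], f[5]))
            except ValueError as e:
                raise TrackParseError(path, ln, str(e))
    return records


def write_gwas(records: Iterable[AssociationRecord], path: str):
    with open(path, "w") as fh:
        fh.write("\t".join(_GWAS_HEADER) + "\n")
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t{_fmt(r.p_value)}\t{_fmt(r.score)}\t"
                f"{r.label}\t{r.group}\n"
            )


# ---------------------------------------------------------------------------
# Dense Hi-C text tiles
# ---------------------------------------------------------------------------

def read_contact_tiles(path: str) -> List[ContactTile]:
    """Dense text tiles: ``#tile chrom_a chrom_b bin_size origin_a origin_b``
    header followed by one tab-separated matrix row per line."""
    tiles = []
    header = None
    rows: List[List[float]] = []

    def flush():
        if header is not None:
            tiles.append(
                ContactTile(
                    header[0], header[1], int(header[2]), int(header[3]), int(header[4]),
                    np.array(rows, dtype=float),
                )
            )

    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#tile"):
                flush()
                f = line.split("\t")
                if len(f) != 6:
                    raise TrackParseError(path, ln, "tile header needs 6 fields")
                header, rows = f[1:], []
            elif line.startswith("#"):
                continue
            else:
                if header is None:
                    raise TrackParseError(path, ln, "matrix row before any #tile header")
                try:
                    rows.append([float(x) for x in line.split("\t")])
                except ValueError:
                    raise TrackParseError(path, ln, "non-numeric matrix entry")
    flush()
    for t in tiles:
        if len({len(r) for r in t.matrix.tolist()} or {0}) > 1:
            raise TrackParseError(path, None, "ragged contact matrix")
    return tiles


def write_contact_tiles(tiles: Iterable[ContactTile], path: str):
    with open(path, "w") as fh:
        for t in tiles:
            fh.write(
                f"#tile\t{t.chrom_a}\t{t.chrom_b}\t{t.bin_size}\t{t.origin_a}\t{t.origin_b}\n"
            )
            for row in t.matrix:
                fh.write("\t".join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# open_track / query_region / query_contacts
# ---------------------------------------------------------------------------

_READERS = {
    "gff3": lambda p: read_gff3(p, "gff3"),
    "gtf": lambda p: read_gff3(p, "gtf"),
    "bed": read_bed,
    "bedgraph": read_bedgraph,
    "bigwig": read_bigwig,
    "vcf": read_vcf,
    "methylc": read_methylc,
    "longrange": read_longrange,
    "biginteract": read_biginteract,
    "gwas": read_gwas,
}

_KIND_BY_FORMAT = {
    "gff3": TrackKind.GENE,
    "gtf": TrackKind.GENE,
    "bed": TrackKind.FEATURE,
    "bedgraph": TrackKind.SIGNAL,
    "bigwig": TrackKind.SIGNAL,
    "vcf": TrackKind.VARIANT,
    "methylc": TrackKind.METHYLATION,
    "longrange": TrackKind.INTERACTION,
    "biginteract": TrackKind.INTERACTION,
    "gwas": TrackKind.ASSOCIATION,
    "contact": TrackKind.CONTACT,
}


def _normalize_chrom(record, assembly: GenomeAssembly):
    resolved = assembly.resolve_chrom(record.chrom)
    return resolved


def _with_chrom(record, chrom: str):
    """Return a copy of a record with its chromosome(s) renamed."""
    if isinstance(record, (SignalPoint, BedFeature)):
        return replace(record, interval=replace(record.interval, chrom=chrom))
    if isinstance(record, GeneModel):
        return replace(record, interval=replace(record.interval, chrom=chrom))
    if isinstance(record, InteractionRecord):
        return record  # handled anchor-by-anchor by caller
    return replace(record, chrom=chrom)


def open_track(
    path: str,
    format: str,
    assembly: GenomeAssembly,
    track_id: Optional[str] = None,
    group: Optional[str] = None,
) -> TrackHandle:
    """Parse a track file, validate it against the assembly, build its index."""
    fmt = format.lower()
    if fmt == "contact":
        return _open_contact(path, assembly, track_id, group)
    if fmt not in _READERS:
        raise ValueError(f"unsupported track format {format!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    records = _READERS[fmt](path)

    lengths = assembly.lengths
    unknown = set()
    normalized = []
    for r in records:
        if isinstance(r, InteractionRecord):
            c1 = assembly.resolve_chrom(r.anchor1.chrom)
            c2 = assembly.resolve_chrom(r.anchor2.chrom)
            if c1 is None:
                unknown.add(r.anchor1.chrom)
            if c2 is None:
                unknown.add(r.anchor2.chrom)
            if c1 is None or c2 is None:
                continue
            r = replace(
                r,
                anchor1=replace(r.anchor1, chrom=c1),
                anchor2=replace(r.anchor2, chrom=c2),
            )
            normalized.append(r)
            continue
        c = assembly.resolve_chrom(r.chrom)
        if c is None:
            unknown.add(r.chrom)
            continue
        if c != r.chrom:
            r = _with_chrom(r, c)
        if r.end > lengths[c]:
            raise TrackParseError(
                path, None, f"record [{r.start}, {r.end}) exceeds {c} length {lengths[c]}"
            )
        normalized.append(r)
    if unknown:
        raise TrackParseError(
            path, None,
            "chromosomes not in assembly "
            f"{assembly.name!r}: {', '.join(sorted(unknown))}",
        )

    handle = TrackHandle(
        track_id=track_id or os.path.basename(path),
        kind=_KIND_BY_FORMAT[fmt],
        format=fmt,
        path=path,
        assembly=assembly,
        index=TrackIndex.build(normalized),
        group=group,
    )
    return handle


def _open_contact(path, assembly, track_id, group) -> TrackHandle:
    tiles = read_contact_tiles(path)
    unknown = set()
    for t in tiles:
        for c in (t.chrom_a, t.chrom_b):
            if assembly.resolve_chrom(c) is None:
                unknown.add(c)
    if unknown:
        raise TrackParseError(
            path, None,
            f"chromosomes not in assembly {assembly.name!r}: {', '.join(sorted(unknown))}",
        )
    handle = TrackHandle(
        track_id=track_id or os.path.basename(path),
        kind=TrackKind.CONTACT,
        format="contact",
        path=path,
        assembly=assembly,
        index=TrackIndex.build([]),
        group=group,
        extra={"tiles": tiles},
    )
    return handle


def query_region(handle: TrackHandle, interval: GenomicInterval):
    """All records overlapping the half-open interval, ascending by start.

    Interaction tracks match on either anchor."""
    chrom = handle.assembly.resolve_chrom(interval.chrom)
    if chrom is None:
        raise KeyError(f"unknown chromosome {interval.chrom!r}")
    iv = GenomicInterval(chrom, interval.start, interval.end, interval.strand)
    if handle.kind is TrackKind.INTERACTION:
        out = [
            r
            for r in handle.index.all_records()
            if r.anchor1.overlaps(iv) or r.anchor2.overlaps(iv)
        ]
        out.sort(key=lambda r: (r.anchor1.chrom, r.anchor1.start, r.anchor2.start))
        return out
    return handle.index.query(iv)


def query_contacts(
    handle: TrackHandle,
    interval_a: GenomicInterval,
    interval_b: GenomicInterval,
    bin_size: int,
) -> ContactTile:
    """Slice the dense contact map covering two intervals at one bin size."""
    tiles = handle.extra.get("tiles", [])
    available = sorted({t.bin_size for t in tiles})
    ca = handle.assembly.resolve_chrom(interval_a.chrom)
    cb = handle.assembly.resolve_chrom(interval_b.chrom)
    if ca is None or cb is None:
        raise KeyError(f"unknown chromosome in {interval_a.chrom!r}/{interval_b.chrom!r}")

    match = None
    transpose = False
    for t in tiles:
        if t.bin_size != bin_size:
            continue
        if t.chrom_a == ca and t.chrom_b == cb:
            match = t
            break
        if t.chrom_a == cb and t.chrom_b == ca:
            match, transpose = t, True
            break
    if match is None:
        if bin_size not in available:
            raise ValueError(
                f"bin size {bin_size} unavailable; available: {available or 'none'}"
            )
        raise KeyError(f"no contact tile for pair ({ca}, {cb}) at bin size {bin_size}")

    m = match.matrix.T if transpose else match.matrix
    oa = match.origin_b if transpose else match.origin_a
    ob = match.origin_a if transpose else match.origin_b

    ia0 = (interval_a.start - oa) // bin_size
    ia1 = -(-(interval_a.end - oa) // bin_size)  # ceil
    ib0 = (interval_b.start - ob) // bin_size
    ib1 = -(-(interval_b.end - ob) // bin_size)
    ia0, ib0 = max(ia0, 0), max(ib0, 0)
    ia1, ib1 = min(ia1, m.shape[0]), min(ib1, m.shape[1])
    if ia1 <= ia0 or ib1 <= ib0:
        sub = np.zeros((0, 0))
        ia0, ib0 = 0, 0
    else:
        sub = m[ia0:ia1, ib0:ib1].copy()
    return ContactTile(ca, cb, bin_size, oa + ia0 * bin_size, ob + ib0 * bin_size, sub)
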