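"""Open every supported track format and run region + contact queries.

The numbers printed are record counts per format, the hits overlapping a
200 kb window, and the shape of a Hi-C contact sub-tile.
"""

import os
import tempfile

from omicview.genome import GenomicInterval, open_track, query_contacts, query_region
from omicview.simulate import SyntheticGenomeSpec, load_assembly, simulate_genome

work = tempfile.mkdtemp()
simulate_genome(SyntheticGenomeSpec(seed=0), work)
assembly = load_assembly(os.path.join(work, "assembly.json"))

formats = [
    ("genes.gff3", "gff3"), ("peaks.bed", "bed"), ("signal_0.bedgraph", "bedgraph"),
    ("variants.vcf", "vcf"), ("methylation.tsv", "methylc"),
    ("links.longrange", "longrange"), ("links.interact", "biginteract"),
    ("eqtl.tsv", "gwas"),
]
handles = {}
for fname, fmt in formats:
    h = open_track(os.path.join(work, fname), fmt, assembly)
    handles[fmt] = h
    print(f"{fmt:12s} {h.record_count:5d} records")

window = GenomicInterval("chr1", 400_000, 600_000)
for fmt in ("gff3", "bed", "vcf", "methylc"):
    hits = query_region(handles[fmt], window)
    print(f"{fmt:12s} {len(hits):4d} records overlap chr1:400,000-600,000")
# records are returned in ascending start order; the window is half-open,
# so a feature ending exactly at 400,000 is excluded

hic = open_track(os.path.join(work, "contacts.txt"), "contact", assembly)
tile = query_contacts(
    hic, GenomicInterval("chr1", 100_000, 500_000),
    GenomicInterval("chr2", 200_000, 800_000), bin_size=10_000,
)
print(f"contact tile {tile.chrom_a} x {tile.chrom_b}: {tile.matrix.shape} bins of "
      f"{tile.bin_size} bp, total {tile.matrix.sum():.0f} raw counts")
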