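"""Cross-panel linkage: anchors, dual-chromosome links, cluster pseudobulk.

A click on a gene in the single-cell panel becomes an anchor message the
genome browser navigates to; a dual-chromosome view shows interaction
links straddling the two frames; selecting clusters yields per-cluster
scATAC coverage tracks in CPM.
"""

import json
import os
import tempfile

import numpy as np

from omicview.genome import GenomicInterval, open_track
from omicview.linkage import (
    DualFrameState, MessageBus, cluster_coverage, cross_frame_links,
    read_fragments, resolve_anchor,
)
from omicview.simulate import (
    SyntheticGenomeSpec, SyntheticSCSpec, load_assembly, make_assembly,
    simulate_genome, simulate_sc,
)
from omicview.tiling import ViewState

work = tempfile.mkdtemp()
gspec = SyntheticGenomeSpec(seed=0)
simulate_genome(gspec, os.path.join(work, "g"))
simulate_sc(SyntheticSCSpec(seed=0), os.path.join(work, "s"), make_assembly(gspec))
assembly = load_assembly(os.path.join(work, "g/assembly.json"))
genes = open_track(os.path.join(work, "g/genes.gff3"), "gff3", assembly)

# 1. anchor: resolve a gene symbol to a padded, highlighted window
bus = MessageBus()
received = []
bus.register_listener("anchor", received.append)
gene = genes.index.all_records()[3]
msg = resolve_anchor([genes], gene.gene_name, "gene")
bus.emit("anchor", msg.to_payload())
print(f"anchor {gene.gene_name}: navigate to "
      f"{msg.target_region.chrom}:{msg.target_region.start}-{msg.target_region.end}, "
      f"highlight {msg.highlight.start}-{msg.highlight.end}")
print(f"bus delivered {len(received)} event(s), sequence {received[0].sequence}")
# the window pads the gene by 20% per side so flanking signal is visible

# 2. dual-chromosome mode: links with one anchor in each frame
links = open_track(os.path.join(work, "g/links.longrange"), "longrange", assembly)
dual = DualFrameState(
    ViewState(1000, GenomicInterval("chr1", 0, 500_000)),
    ViewState(1000, GenomicInterval("chr2", 0, 500_000)),
)
found = cross_frame_links(links, dual)
print(f"dual-frame chr1/chr2: {found.__len__()} links straddle the two frames")

# 3. cluster pseudobulk from fragments
man = json.load(open(os.path.join(work, "s/manifest.json")))
frags = read_fragments(os.path.join(work, "s/fragments.tsv"))
cov = cluster_coverage(frags, man["cluster_of"], sorted(man["cluster_sizes"]),
                       bin_size=50_000, assembly=assembly)
for g in sorted(cov):
    bins = cov[g]["chr1"]
    print(f"  {g}: peak bin {np.argmax(bins)} at {bins.max():,.0f} CPM")
# CPM normalization makes clusters of different size comparable
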