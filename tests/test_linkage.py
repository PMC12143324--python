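"""Message bus, anchor navigation, dual-frame links, pseudobulk, sessions."""

import os

import numpy as np
import pytest

from omicview.genome import GenomicInterval, open_track
from omicview.linkage import (
    AnchorMessage,
    DualFrameState,
    MessageBus,
    PayloadSchemaError,
    ViewSession,
    cluster_coverage,
    cross_frame_links,
    deserialize_session,
    read_fragments,
    resolve_anchor,
    serialize_session,
    session_from_url_fragment,
    session_to_url_fragment,
)
from omicview.genome.io import query_region
from omicview.tiling import ViewState


# ---------------------------------------------------------------------------
# bus
# ---------------------------------------------------------------------------

def test_bus_delivers_in_order_to_all_listeners():
    bus = MessageBus()
    seen_a, seen_b = [], []
    bus.register_listener("t", seen_a.append)
    bus.register_listener("t", seen_b.append)
    for i in range(3):
        bus.emit("t", {"i": i})
    assert [e.payload["i"] for e in seen_a] == [0, 1, 2]
    assert [e.payload["i"] for e in seen_b] == [0, 1, 2]
    assert len(seen_a) == 3 and len(seen_b) == 3


def test_emit_without_listeners_is_noop():
    bus = MessageBus()
    ev = bus.emit("silent", {"x": 1})
    assert ev.sequence == 1


def test_interleaved_topics_preserve_per_topic_order():
    bus = MessageBus()
    log = {"a": [], "b": []}
    bus.register_listener("a", lambda e: log["a"].append(e.sequence))
    bus.register_listener("b", lambda e: log["b"].append(e.sequence))
    rng = np.random.default_rng(0)
    for _ in range(100):
        bus.emit(rng.choice(["a", "b"]), {"x": 0})
    assert log["a"] == sorted(log["a"])
    assert log["b"] == sorted(log["b"])
    # global sequence strictly increasing and complete
    assert sorted(log["a"] + log["b"]) == list(range(1, 101))


def test_schema_validation_names_missing_field():
    bus = MessageBus()
    with pytest.raises(PayloadSchemaError, match="'end'"):
        bus.emit("highlight", {"chrom": "chr1", "start": 5})


def test_dropped_listener_stops_receiving():
    bus = MessageBus()
    seen = []
    listener = bus.register_listener("t", seen.append)
    bus.emit("t", {"x": 1})
    bus.drop_listener("t", listener)
    bus.emit("t", {"x": 2})
    assert len(seen) == 1


def test_bus_token_auth():
    bus = MessageBus(auth_tokens={"secret"})
    with pytest.raises(PermissionError):
        bus.emit("t", {"x": 1})
    assert bus.emit("t", {"x": 1}, token="secret").sequence == 1


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def gene_track(genome_dir, assembly):
    return open_track(os.path.join(genome_dir, "genes.gff3"), "gff3", assembly)


@pytest.fixture(scope="module")
def eqtl_track(genome_dir, assembly):
    return open_track(os.path.join(genome_dir, "eqtl.tsv"), "gwas", assembly)


def test_gene_anchor_padded_twenty_percent(tmp_path, assembly):
    path = tmp_path / "one.gff3"
    path.write_text("chr1\t.\tgene\t10001\t20000\t.\t+\t.\tID=g;Name=G\n")
    h = open_track(str(path), "gff3", assembly)
    msg = resolve_anchor([h], "G", "gene")
    assert msg.target_region == GenomicInterval("chr1", 8000, 22000)
    assert msg.highlight == GenomicInterval("chr1", 10000, 20000)


def test_point_anchor_window_clipped_at_zero(tmp_path, assembly):
    path = tmp_path / "e.tsv"
    path.write_text("chrom\tpos\tp_value\tscore\tlabel\tgroup\n"
                    "chr2\t10001\t0.001\t8\tSNP_A\tTcell\n")
    h = open_track(str(path), "gwas", assembly)
    msg = resolve_anchor([h], "SNP_A", "eqtl")
    assert msg.target_region.start == 0  # 10_000 - 50_000 clipped
    assert msg.target_region.end == 10_000 + 1 + 50_000


def test_anchor_round_trip_for_every_gene(gene_track):
    """resolve_anchor then query_region must re-find the feature."""
    for g in gene_track.index.all_records():
        msg = resolve_anchor([gene_track], g.gene_name, "gene")
        assert msg.target_region.contains(msg.highlight)
        hits = query_region(gene_track, msg.target_region)
        assert any(r.gene_id == g.gene_id for r in hits)


def test_anchor_sets_sc_overlay_when_feature_loaded(tmp_path, assembly):
    path = tmp_path / "one.gff3"
    path.write_text("chr1\t.\tgene\t1001\t2000\t.\t+\t.\tID=g;Name=SHARED\n")
    h = open_track(str(path), "gff3", assembly)
    msg = resolve_anchor([h], "SHARED", "gene", sc_features={"rna": ["SHARED", "OTHER"]})
    assert msg.sc_overlay == ("rna", "SHARED")


def test_unresolvable_anchor_errors(gene_track):
    with pytest.raises(KeyError):
        resolve_anchor([gene_track], "NO_SUCH_GENE", "gene")


def test_highlight_must_be_inside_region():
    with pytest.raises(ValueError):
        AnchorMessage(
            "p", "f", "gene",
            target_region=GenomicInterval("chr1", 100, 200),
            highlight=GenomicInterval("chr1", 150, 300),
        )


# ---------------------------------------------------------------------------
# dual-frame links
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def link_track(genome_dir, assembly):
    return open_track(os.path.join(genome_dir, "links.longrange"), "longrange", assembly)


def frame(chrom, start, end):
    return ViewState(1000, GenomicInterval(chrom, start, end))


def test_straddling_record_included_and_same_frame_excluded(tmp_path, assembly):
    path = tmp_path / "l.longrange"
    path.write_text(
        "chr1\t100\t200\tchr2\t300-400,5\n".replace("chr2\t300-400", "chr2:300-400")
        + "chr1\t500\t600\tchr1:700-800,3\n"
    )
    h = open_track(str(path), "longrange", assembly)
    dual = DualFrameState(frame("chr1", 0, 1000), frame("chr2", 0, 1000))
    links = cross_frame_links(h, dual)
    assert len(links) == 1 and links[0].anchor2.chrom == "chr2"
    # both anchors inside frame_a, frame_b elsewhere -> excluded
    dual2 = DualFrameState(frame("chr1", 0, 1000), frame("chr2", 900_000, 901_000))
    assert cross_frame_links(h, dual2) == []


def test_cross_frame_links_equal_double_overlap_scan(link_track, assembly):
    rng = np.random.default_rng(8)
    L = assembly.lengths["chr1"]
    records = link_track.index.all_records()
    for _ in range(200):
        ca, cb = rng.choice(["chr1", "chr2"], 2)
        a0 = int(rng.integers(0, L - 10)); a1 = a0 + int(rng.integers(10, L // 3))
        b0 = int(rng.integers(0, L - 10)); b1 = b0 + int(rng.integers(10, L // 3))
        dual = DualFrameState(frame(ca, a0, min(a1, L)), frame(cb, b0, min(b1, L)))
        got = cross_frame_links(link_track, dual)
        ra, rb = dual.frame_a.current_range, dual.frame_b.current_range
        want = [
            r for r in records
            if (r.anchor1.overlaps(ra) and r.anchor2.overlaps(rb))
            or (r.anchor1.overlaps(rb) and r.anchor2.overlaps(ra))
        ]
        assert {(r.anchor1.start, r.anchor2.start) for r in got} == {
            (r.anchor1.start, r.anchor2.start) for r in want
        }


# ---------------------------------------------------------------------------
# cluster pseudobulk
# ---------------------------------------------------------------------------

def test_single_fragment_cpm(assembly):
    frags = [("chr1", 0, 1000, "bc1")]
    cov = cluster_coverage(frags, {"bc1": "g"}, ["g"], 1000, assembly)
    bins = cov["g"]["chr1"]
    assert bins[0] == pytest.approx(1e6)
    assert bins[1:].sum() == 0


def test_fragment_straddling_two_bins_counted_in_each(assembly):
    frags = [("chr1", 900, 1100, "bc1")]
    cov = cluster_coverage(frags, {"bc1": "g"}, ["g"], 1000, assembly, normalize="raw")
    bins = cov["g"]["chr1"]
    assert bins[0] == 1 and bins[1] == 1 and bins[2:].sum() == 0


def test_empty_group_errors(assembly):
    with pytest.raises(ValueError, match="zero barcodes"):
        cluster_coverage([], {"bc1": "g"}, ["g", "h"], 1000, assembly)


def test_cluster_coverage_equals_brute_force_and_groups_sum(sc_dir, sc_manifest, assembly):
    frags = read_fragments(os.path.join(sc_dir, "fragments.tsv"))
    assert len(frags) == sc_manifest["fragments_total"]
    b2g = sc_manifest["cluster_of"]
    groups = sorted(sc_manifest["cluster_sizes"])
    bin_size = 50_000
    cov = cluster_coverage(frags, b2g, groups, bin_size, assembly, normalize="raw")
    # brute force per-bin overlap counting
    for g in groups:
        for chrom in ("chr1",):
            n_bins = len(cov[g][chrom])
            expect = np.zeros(n_bins)
            for c, s, e, bc in frags:
                if c != chrom or b2g[bc] != g:
                    continue
                for b in range(s // bin_size, min((e - 1) // bin_size, n_bins - 1) + 1):
                    expect[b] += 1
            assert np.array_equal(cov[g][chrom], expect), (g, chrom)
    # group-sum invariant: raw tracks sum to the all-cells track
    all_cov = cluster_coverage(frags, {b: "all" for b in b2g}, ["all"], bin_size,
                               assembly, normalize="raw")
    total = sum(cov[g]["chr1"] for g in groups)
    assert np.array_equal(total, all_cov["all"]["chr1"])


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------

def sample_session():
    return ViewSession(
        session_id="s-1",
        layout=[{"panel": "browser"}, {"panel": "sc"}],
        tracks=[{"track_id": "genes", "style": {"color": "#336699"}}],
        view_states=[{"chrom": "chr1", "start": 0, "end": 100000, "view_width": 1200}],
        sc_overlay={"assay": "rna", "feature": "GENE0001"},
    )


def test_session_round_trip_identity():
    s = sample_session()
    assert deserialize_session(serialize_session(s)) == s


def test_truncated_payload_rejected():
    text = serialize_session(sample_session())
    with pytest.raises(ValueError, match="corrupt"):
        deserialize_session(text[: len(text) // 2])


def test_unknown_version_names_supported():
    bad = serialize_session(sample_session()).replace('"version":1', '"version":99')
    with pytest.raises(ValueError, match="supported"):
        deserialize_session(bad)


def test_url_fragment_round_trip_and_length():
    s = sample_session()
    frag = session_to_url_fragment(s)
    assert len(frag) <= 2048
    assert session_from_url_fragment(frag) == s


def test_session_token_survives_store_restart(tmp_path):
    from omicview.collab import CollabStore

    db = str(tmp_path / "store.db")
    s = sample_session()
    store = CollabStore(db)
    token = store.store_session(serialize_session(s))
    store.close()
    store2 = CollabStore(db)
    assert deserialize_session(store2.fetch_session(token)) == s
    store2.close()
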