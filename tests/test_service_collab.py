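"""Collaboration store, authorization sweeps, HTTP endpoints, CLI."""

import io
import json
import os
import threading
import urllib.request

import numpy as np
import pytest
from click.testing import CliRunner

from omicview.cli import main as cli_main
from omicview.collab import AuthorizationError, CollabStore, ConflictError
from omicview.service import EngineContext, make_wsgi_app, serve


# ---------------------------------------------------------------------------
# collaboration store
# ---------------------------------------------------------------------------

@pytest.fixture()
def store(tmp_path):
    s = CollabStore(str(tmp_path / "c.db"))
    s.add_user("alice", "Alice", "pw-a")
    s.add_user("bob", "Bob", "pw-b")
    s.add_user("eve", "Eve", "pw-e")
    s.create_project("p1", "Project One", owner="alice", species="mouse")
    s.set_role("p1", "alice", "bob", "editor")
    s.set_role("p1", "alice", "eve", "viewer")
    yield s
    s.close()


def test_viewer_cannot_annotate(store):
    with pytest.raises(AuthorizationError):
        store.annotate("p1", "eve", "gene:G1", "feature_rename", "NEWNAME")


def test_role_endpoint_sweep(store):
    """Every mutating operation respects the role matrix."""
    cases = [
        ("annotate", lambda u: store.annotate("p1", u, "t", "comment", "hi"),
         {"alice", "bob"}),
        ("add_dataset", lambda u: store.add_dataset("p1", u, f"d-{u}-{np.random.randint(1e9)}", "track"),
         {"alice", "bob"}),
        ("set_role", lambda u: store.set_role("p1", u, "bob", "editor"), {"alice"}),
    ]
    for name, op, allowed in cases:
        for user in ("alice", "bob", "eve"):
            if user in allowed:
                op(user)
            else:
                with pytest.raises(AuthorizationError):
                    op(user)


def test_last_writer_wins_with_history(store):
    r1 = store.annotate("p1", "alice", "gene:G1", "feature_rename", "NAME_A")
    r2 = store.annotate("p1", "bob", "gene:G1", "feature_rename", "NAME_B")
    assert (r1, r2) == (1, 2)
    latest = store.latest_annotation("p1", "gene:G1", "feature_rename")
    assert latest.value == "NAME_B" and latest.revision == 2
    hist = store.annotation_history("p1", "gene:G1", "feature_rename")
    assert [a.revision for a in hist] == [1, 2]


def test_history_length_equals_write_count(store):
    rng = np.random.default_rng(0)
    for trial in range(20):
        target = f"cells:subset{trial}"
        n = int(rng.integers(1, 8))
        for i in range(n):
            store.annotate("p1", "alice", target, "cell_type_label", f"type{i}")
        assert len(store.annotation_history("p1", target, "cell_type_label")) == n


def test_duplicate_ids_conflict(store):
    with pytest.raises(ConflictError):
        store.create_project("p1", "again", owner="alice")
    store.add_dataset("p1", "alice", "ds1", "track")
    with pytest.raises(ConflictError):
        store.add_dataset("p1", "alice", "ds1", "track")


def test_last_admin_protected(store):
    with pytest.raises(ConflictError):
        store.set_role("p1", "alice", "alice", "viewer")


def test_delete_project_unresolves_datasets(store):
    store.add_dataset("p1", "alice", "dsX", "track")
    assert store.dataset_project("dsX") == "p1"
    store.delete_project("p1", "alice")
    assert store.dataset_project("dsX") is None
    assert store.list_projects() == []


def test_batch_add_reports_per_item(tmp_path, store, genome_dir, assembly):
    from omicview.genome.io import open_track

    bad = tmp_path / "corrupt.bed"
    bad.write_text("chr1\tnot_an_int\t5\n")
    items = [
        ("t1", "bed", os.path.join(genome_dir, "peaks.bed")),
        ("t2", "bedgraph", os.path.join(genome_dir, "signal_0.bedgraph")),
        ("t3", "gff3", os.path.join(genome_dir, "genes.gff3")),
        ("t4", "gwas", os.path.join(genome_dir, "eqtl.tsv")),
        ("t5", "bed", str(bad)),
    ]
    report = store.batch_add_tracks(
        "p1", "bob", items, opener=lambda p, f: open_track(p, f, assembly)
    )
    assert [r["ok"] for r in report] == [True, True, True, True, False]
    assert "corrupt.bed:1" in report[4]["error"]


def test_store_restart_preserves_everything(tmp_path):
    db = str(tmp_path / "persist.db")
    s = CollabStore(db)
    s.add_user("u", "U", "pw")
    s.create_project("p", "P", owner="u")
    s.annotate("p", "u", "t", "comment", "note")
    s.close()
    s2 = CollabStore(db)
    assert [p[0] for p in s2.list_projects()] == ["p"]
    assert s2.latest_annotation("p", "t", "comment").value == "note"
    assert s2.role_of("p", "u") == "admin"
    s2.close()


def test_authentication_tokens(store):
    token = store.authenticate("alice", "pw-a")
    assert store.user_for_token(token) == "alice"
    with pytest.raises(AuthorizationError):
        store.authenticate("alice", "wrong")
    with pytest.raises(AuthorizationError):
        store.user_for_token("nope")


# ---------------------------------------------------------------------------
# HTTP service (WSGI, no socket)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def engine(genome_dir, genome_manifest, assembly, sc_dir):
    from omicview.sc.dataset import load_cell_dataset

    ctx = EngineContext(assembly=assembly, store=CollabStore())
    for fname, info in genome_manifest["tracks"].items():
        ctx.add_track(os.path.join(genome_dir, fname), info["format"],
                      track_id=os.path.splitext(fname)[0])
    ctx.add_dataset("demo", load_cell_dataset(os.path.join(sc_dir, "rna.h5ad")))
    ctx.add_fragments("demo", os.path.join(sc_dir, "fragments.tsv"))
    return ctx


def call(app, method, path, qs="", body=None):
    env = {"REQUEST_METHOD": method, "PATH_INFO": path, "QUERY_STRING": qs}
    if body is not None:
        raw = json.dumps(body).encode()
        env["CONTENT_LENGTH"] = str(len(raw))
        env["wsgi.input"] = io.BytesIO(raw)
    out = {}
    resp = b"".join(app(env, lambda s, h: out.update(status=int(s.split()[0]))))
    return out["status"], json.loads(resp)


def test_http_health_and_blocks(engine):
    app = make_wsgi_app(engine)
    status, doc = call(app, "GET", "/health")
    assert status == 200 and doc["status"] == "ok"
    status, doc = call(app, "GET", "/track/signal_0/blocks",
                       "chrom=chr1&start=0&end=200000&view_width=1000")
    assert status == 200
    assert doc["blocks"][0]["payload_kind"] == "bins"
    assert len(doc["blocks"][0]["bins"]["mean"]) == 1000


def test_http_error_codes(engine):
    app = make_wsgi_app(engine)
    assert call(app, "GET", "/track/nope/blocks", "chrom=chr1&start=0&end=1&view_width=1")[0] == 404
    assert call(app, "GET", "/sc/demo/feature/rna/NOPE")[0] == 404
    assert call(app, "POST", "/bus/emit", body={"topic": "highlight", "payload": {}})[0] == 400
    assert call(app, "GET", "/no/such/route")[0] == 404


def test_http_anchor_and_search(engine):
    app = make_wsgi_app(engine)
    status, doc = call(app, "GET", "/search", "q=GENE0001&k=3")
    assert status == 200 and doc["hits"][0]["name"] == "GENE0001"
    gene = None
    for r in engine.tracks["genes"].index.all_records():
        gene = r.gene_name
        break
    status, doc = call(app, "GET", "/anchor", f"feature={gene}&kind=gene")
    assert status == 200 and doc["feature_id"] == gene
    assert doc["start"] <= doc["highlight"][0] <= doc["highlight"][1] <= doc["end"]


def test_http_session_token_round_trip(engine):
    app = make_wsgi_app(engine)
    session = {"session_id": "s9", "version": 1, "layout": [], "tracks": [],
               "view_states": [], "sc_overlay": None}
    status, doc = call(app, "POST", "/session", body=session)
    assert status == 200
    status, back = call(app, "GET", f"/s/{doc['token']}")
    assert status == 200 and back["session_id"] == "s9"


def test_http_bus_polling(engine):
    app = make_wsgi_app(engine)
    s0, d0 = call(app, "GET", "/bus/events")
    n0 = len(d0["events"])
    call(app, "POST", "/bus/emit",
         body={"topic": "view", "payload": {"chrom": "chr1", "start": 0, "end": 10,
                                            "view_width": 800}})
    s1, d1 = call(app, "GET", "/bus/events", "topic=view")
    assert len(d1["events"]) >= 1
    last = d1["events"][-1]["sequence"]
    s2, d2 = call(app, "GET", "/bus/events", f"since={last}")
    assert d2["events"] == []


def test_real_server_health_endpoint(engine):
    srv, port = serve(engine, port=0)
    t = threading.Thread(target=srv.serve_forever, daemon=True)
    t.start()
    try:
        with urllib.request.urlopen(f"http://127.0.0.1:{port}/health", timeout=5) as r:
            assert r.status == 200
            assert json.loads(r.read())["status"] == "ok"
    finally:
        srv.shutdown()
        t.join(timeout=5)


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def tree_bytes(root):
    import hashlib, pathlib

    h = hashlib.sha256()
    for p in sorted(pathlib.Path(root).rglob("*")):
        if p.is_file():
            h.update(str(p.relative_to(root)).encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def test_cli_simulate_deterministic(tmp_path):
    runner = CliRunner()
    d1, d2 = str(tmp_path / "a"), str(tmp_path / "b")
    for d in (d1, d2):
        res = runner.invoke(cli_main, ["simulate", "--seed", "7", "--out", d])
        assert res.exit_code == 0, res.output
    assert tree_bytes(d1) == tree_bytes(d2)


def test_cli_add_track_missing_file(tmp_path, genome_dir):
    runner = CliRunner()
    res = runner.invoke(cli_main, [
        "add-track", "--path", str(tmp_path / "missing.bed"), "--format", "bed",
        "--assembly", os.path.join(genome_dir, "assembly.json"),
    ])
    assert res.exit_code != 0
    assert "missing.bed" in res.output


def test_cli_add_track_and_sc(genome_dir, sc_dir):
    runner = CliRunner()
    res = runner.invoke(cli_main, [
        "add-track", "--path", os.path.join(genome_dir, "peaks.bed"),
        "--format", "bed", "--assembly", os.path.join(genome_dir, "assembly.json"),
    ])
    assert res.exit_code == 0
    assert json.loads(res.output)["n_records"] > 0
    res = runner.invoke(cli_main, ["add-sc", "--path", os.path.join(sc_dir, "rna.h5ad")])
    assert res.exit_code == 0
    assert json.loads(res.output)["n_cells"] == 600


def test_cli_convert_round_trip(tmp_path, sc_dir):
    from omicview.sc.dataset import load_cell_dataset

    runner = CliRunner()
    out = str(tmp_path / "converted.zarr")
    res = runner.invoke(cli_main, ["convert", "--path",
                                   os.path.join(sc_dir, "rna.h5ad"), "--out", out])
    assert res.exit_code == 0, res.output
    assert load_cell_dataset(out).equals(load_cell_dataset(os.path.join(sc_dir, "rna.h5ad")))


def test_cli_bad_flags_usage_exit_2():
    runner = CliRunner()
    res = runner.invoke(cli_main, ["add-track", "--no-such-flag"])
    assert res.exit_code == 2


def test_cli_session_export_round_trip(tmp_path):
    from omicview.linkage import ViewSession, serialize_session

    runner = CliRunner()
    src = tmp_path / "s.json"
    src.write_text(serialize_session(ViewSession(session_id="cli-s")))
    out = tmp_path / "out.json"
    res = runner.invoke(cli_main, ["session-export", "--session-json", str(src),
                                   "--out", str(out)])
    assert res.exit_code == 0
    assert json.loads(out.read_text())["session_id"] == "cli-s"
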