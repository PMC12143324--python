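"""Small JSON-over-HTTP service exposing the engine to clients.

A plain WSGI application (stdlib ``wsgiref`` serves it; any WSGI server
works) over an :class:`EngineContext` that holds the opened tracks,
loaded cell datasets, the message bus, the search index and the
collaboration store.  Event subscription is by polling
``GET /bus/events?since=<sequence>`` — every event carries a monotone
sequence number, so clients resume without loss.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Dict, Optional
from urllib.parse import parse_qs

import numpy as np

from . import stats
from .collab import AuthorizationError, CollabStore, ConflictError
from .genome.io import open_track, query_region
from .genome.types import GenomeAssembly, GenomicInterval, TrackHandle
from .linkage import (
    DualFrameState,
    MessageBus,
    PayloadSchemaError,
    deserialize_session,
    cross_frame_links,
    read_fragments,
    cluster_coverage,
    resolve_anchor,
    serialize_session,
)
from .sc.dataset import CellDataset, UnknownFeatureError, feature_vector, map_spots_to_image
from .search import NGramIndex, RegionHit, SearchHit, build_index, search
from .tiling import BlockCache, ViewState, ZoomConfig, blocks_for_view, fetch_block


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return [None if (isinstance(v, float) and np.isnan(v)) else v for v in x.tolist()]
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        v = float(x)
        return None if np.isnan(v) else v
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


@dataclass
class EngineContext:
    assembly: GenomeAssembly
    tracks: Dict[str, TrackHandle] = field(default_factory=dict)
    datasets: Dict[str, CellDataset] = field(default_factory=dict)
    fragments: Dict[str, list] = field(default_factory=dict)
    bus: MessageBus = field(default_factory=MessageBus)
    store: Optional[CollabStore] = None
    cache: BlockCache = field(default_factory=BlockCache)
    zoom: ZoomConfig = field(default_factory=ZoomConfig)
    _search_index: Optional[NGramIndex] = None

    def add_track(self, path: str, format: str, track_id: Optional[str] = None) -> TrackHandle:
        h = open_track(path, format, self.assembly, track_id=track_id)
        self.tracks[h.track_id] = h
        self._search_index = None
        return h

    def add_dataset(self, name: str, ds: CellDataset):
        self.datasets[name] = ds
        self._search_index = None

    def add_fragments(self, name: str, path: str):
        self.fragments[name] = read_fragments(path)

    @property
    def search_index(self) -> NGramIndex:
        if self._search_index is None:
            entries = []
            for tid, h in self.tracks.items():
                for r in h.index.all_records():
                    for attr in ("gene_name", "name", "label"):
                        n = getattr(r, attr, None)
                        if n and n != ".":
                            entries.append((n, tid, None))
                            break
            for dname, ds in self.datasets.items():
                for assay, mod in ds.modalities.items():
                    for fname in mod.feature_names:
                        entries.append((fname, f"{dname}/{assay}", None))
            self._search_index = build_index(entries)
        return self._search_index

    def sc_feature_names(self) -> Dict[str, list]:
        out: Dict[str, list] = {}
        for ds in self.datasets.values():
            for assay, mod in ds.modalities.items():
                out.setdefault(assay, []).extend(mod.feature_names)
        return out


class HTTPError(Exception):
    def __init__(self, status: int, message: str):
        self.status = status
        self.message = message


_ROUTES = []


def route(method, pattern):
    rx = re.compile("^" + pattern + "$")

    def deco(fn):
        _ROUTES.append((method, rx, fn))
        return fn

    return deco


@route("GET", r"/health")
def _health(ctx, m, q, body):
    return {"status": "ok", "tracks": len(ctx.tracks), "datasets": len(ctx.datasets)}


@route("GET", r"/track/(?P<tid>[^/]+)/blocks")
def _blocks(ctx, m, q, body):
    tid = m["tid"]
    if tid not in ctx.tracks:
        raise HTTPError(404, f"unknown track {tid!r}")
    try:
        chrom = q["chrom"][0]
        start, end = int(q["start"][0]), int(q["end"][0])
        view_width = int(q["view_width"][0])
    except (KeyError, ValueError):
        raise HTTPError(400, "need chrom, start, end, view_width")
    view = ViewState(view_width, GenomicInterval(chrom, start, end))
    scale, blocks = blocks_for_view(view, ctx.zoom)
    handle = ctx.tracks[tid]
    out = []
    for b in blocks:
        if b.start_bp >= ctx.assembly.length_of(chrom):
            continue
        bd = fetch_block(handle, b, scale, chrom, cache=ctx.cache, config=ctx.zoom)
        item = {
            "index": b.index, "start_bp": b.start_bp, "end_bp": b.end_bp,
            "scale": scale, "payload_kind": bd.payload_kind,
        }
        if bd.bins is not None:
            item["bins"] = {k: _jsonable(np.asarray(v)) for k, v in bd.bins.items()}
        if bd.records is not None:
            item["n_records"] = len(bd.records)
            item["records"] = [
                {"start": r.start, "end": r.end,
                 "name": getattr(r, "name", getattr(r, "gene_name", "."))}
                for r in bd.records
            ]
        if bd.counts is not None:
            item["counts"] = _jsonable(bd.counts)
        out.append(item)
    return {"track": tid, "current_scale": scale, "blocks": out}


@route("GET", r"/sc/(?P<ds>[^/]+)/embedding/(?P<name>[^/]+)")
def _embedding(ctx, m, q, body):
    ds = _get_ds(ctx, m["ds"])
    if m["name"] not in ds.embeddings:
        raise HTTPError(404, f"unknown embedding {m['name']!r}")
    return {"name": m["name"], "coords": _jsonable(ds.embeddings[m["name"]])}


@route("GET", r"/sc/(?P<ds>[^/]+)/feature/(?P<assay>[^/]+)/(?P<gene>[^/]+)")
def _feature(ctx, m, q, body):
    ds = _get_ds(ctx, m["ds"])
    try:
        v = feature_vector(ds, m["assay"], m["gene"])
    except UnknownFeatureError as e:
        raise HTTPError(404, str(e))
    except KeyError as e:
        raise HTTPError(404, str(e))
    return {"assay": m["assay"], "feature": m["gene"], "values": _jsonable(v)}


@route("GET", r"/sc/(?P<ds>[^/]+)/spatial/(?P<slice>[^/]+)")
def _spatial(ctx, m, q, body):
    ds = _get_ds(ctx, m["ds"])
    for sl in ds.spatial:
        if sl.slice_id == m["slice"]:
            res = q.get("resolution", ["hires"])[0]
            try:
                mapped = map_spots_to_image(sl, res)
            except ValueError as e:
                raise HTTPError(400, str(e))
            return {
                "slice": sl.slice_id,
                "resolution": res,
                "spots": _jsonable(mapped),
                "cell_index": _jsonable(sl.cell_index),
            }
    raise HTTPError(404, f"unknown slice {m['slice']!r}")


@route("GET", r"/sc/(?P<ds>[^/]+)/summary")
def _summary(ctx, m, q, body):
    ds = _get_ds(ctx, m["ds"])
    try:
        assay = q["assay"][0]
        features = q["features"][0].split(",")
        group = q["group"][0]
    except KeyError:
        raise HTTPError(400, "need assay, features, group")
    try:
        summaries = stats.group_feature_summary(ds, assay, features, group)
    except KeyError as e:
        raise HTTPError(404, str(e))
    return {
        "summaries": [
            {
                "group": s.group, "feature": s.feature, "n": s.n,
                "mean": _jsonable(np.float64(s.mean)),
                "pct_expressed": _jsonable(np.float64(s.pct_expressed)),
                "quantiles": _jsonable(np.asarray(s.quantiles)),
            }
            for s in summaries
        ]
    }


@route("GET", r"/sc/(?P<ds>[^/]+)/metachart")
def _metachart(ctx, m, q, body):
    ds = _get_ds(ctx, m["ds"])
    try:
        table = stats.metachart(ds, q["split"][0], q["category"][0])
    except KeyError as e:
        raise HTTPError(404, str(e))
    except TypeError as e:
        raise HTTPError(400, str(e))
    return {"rows": table.to_dict(orient="records")}


@route("POST", r"/compare/split")
def _compare(ctx, m, q, body):
    try:
        spec = stats.CompareSpec(
            axis=body["axis"], left=tuple(body["left"]), right=tuple(body["right"])
        )
        left, right = stats.split_view(ctx.datasets, spec)
    except (KeyError, ValueError) as e:
        raise HTTPError(400, str(e))

    def pay(p):
        return {
            "dataset": p.dataset_key, "kind": p.kind,
            "scale": _jsonable(p.scale), "overlay": _jsonable(np.asarray(p.overlay)),
        }

    return {"left": pay(left), "right": pay(right)}


@route("GET", r"/search")
def _search(ctx, m, q, body):
    query = q.get("q", [""])[0]
    k = int(q.get("k", ["10"])[0])
    try:
        hits = search(ctx.search_index, query, k)
    except ValueError as e:
        raise HTTPError(400, str(e))
    out = []
    for h in hits:
        if isinstance(h, RegionHit):
            out.append({"kind": "region", "chrom": h.interval.chrom,
                        "start": h.interval.start, "end": h.interval.end})
        else:
            out.append({"kind": "name", "name": h.name, "source": h.source,
                        "score": h.score})
    return {"hits": out}


@route("GET", r"/anchor")
def _anchor(ctx, m, q, body):
    try:
        feature, kind = q["feature"][0], q["kind"][0]
    except KeyError:
        raise HTTPError(400, "need feature and kind")
    try:
        msg = resolve_anchor(
            list(ctx.tracks.values()), feature, kind,
            sc_features=ctx.sc_feature_names(), search_index=ctx.search_index,
        )
    except KeyError as e:
        raise HTTPError(404, str(e))
    except ValueError as e:
        raise HTTPError(400, str(e))
    return msg.to_payload()


@route("GET", r"/links")
def _links(ctx, m, q, body):
    try:
        tid = q["track"][0]
        fa = q["framea"][0]
        fb = q["frameb"][0]
    except KeyError:
        raise HTTPError(400, "need track, framea, frameb (chrom:start-end)")
    if tid not in ctx.tracks:
        raise HTTPError(404, f"unknown track {tid!r}")

    def frame(s):
        from .search import parse_region_query

        iv = parse_region_query(s)
        if iv is None:
            raise HTTPError(400, f"bad frame {s!r}")
        return ViewState(1000, iv)

    dual = DualFrameState(frame(fa), frame(fb))
    links = cross_frame_links(ctx.tracks[tid], dual)
    return {
        "links": [
            {"chrom1": r.anchor1.chrom, "start1": r.anchor1.start, "end1": r.anchor1.end,
             "chrom2": r.anchor2.chrom, "start2": r.anchor2.start, "end2": r.anchor2.end,
             "score": r.score}
            for r in links
        ]
    }


@route("POST", r"/cluster-signal")
def _cluster_signal(ctx, m, q, body):
    try:
        frag_key = body["fragments"]
        groups = body["groups"]
        barcode_to_group = body["barcode_to_group"]
        bin_size = int(body["bin_size"])
    except (KeyError, TypeError, ValueError):
        raise HTTPError(400, "need fragments, groups, barcode_to_group, bin_size")
    if frag_key not in ctx.fragments:
        raise HTTPError(404, f"unknown fragments {frag_key!r}")
    try:
        cov = cluster_coverage(
            ctx.fragments[frag_key], barcode_to_group, groups, bin_size, ctx.assembly
        )
    except ValueError as e:
        raise HTTPError(400, str(e))
    return {g: {c: _jsonable(v) for c, v in per.items()} for g, per in cov.items()}


@route("POST", r"/bus/emit")
def _bus_emit(ctx, m, q, body):
    try:
        ev = ctx.bus.emit(body["topic"], body.get("payload", {}), token=body.get("token"))
    except PayloadSchemaError as e:
        raise HTTPError(400, str(e))
    except PermissionError as e:
        raise HTTPError(403, str(e))
    except (KeyError, TypeError):
        raise HTTPError(400, "need topic and payload")
    return {"sequence": ev.sequence}


@route("GET", r"/bus/events")
def _bus_events(ctx, m, q, body):
    since = int(q.get("since", ["0"])[0])
    topic = q.get("topic", [None])[0]
    return {
        "events": [
            {"topic": e.topic, "payload": e.payload, "sequence": e.sequence}
            for e in ctx.bus.events_since(since, topic)
        ]
    }


@route("POST", r"/session")
def _session_store(ctx, m, q, body):
    if ctx.store is None:
        raise HTTPError(503, "no collaboration store configured")
    try:
        payload = serialize_session(deserialize_session(json.dumps(body)))
    except ValueError as e:
        raise HTTPError(400, str(e))
    token = ctx.store.store_session(payload)
    return {"token": token, "url": f"/s/{token}"}


@route("GET", r"/s/(?P<token>[^/]+)")
def _session_fetch(ctx, m, q, body):
    if ctx.store is None:
        raise HTTPError(503, "no collaboration store configured")
    try:
        return json.loads(ctx.store.fetch_session(m["token"]))
    except KeyError as e:
        raise HTTPError(404, str(e))


def _get_ds(ctx, name) -> CellDataset:
    if name not in ctx.datasets:
        raise HTTPError(404, f"unknown dataset {name!r}")
    return ctx.datasets[name]


def make_wsgi_app(ctx: EngineContext):
    def app(environ, start_response):
        method = environ["REQUEST_METHOD"]
        path = environ.get("PATH_INFO", "/")
        q = parse_qs(environ.get("QUERY_STRING", ""))
        body = None
        if method == "POST":
            try:
                n = int(environ.get("CONTENT_LENGTH") or 0)
                body = json.loads(environ["wsgi.input"].read(n) or b"{}")
            except (ValueError, KeyError):
                body = {}
        for m_, rx, fn in _ROUTES:
            if m_ != method:
                continue
            match = rx.match(path)
            if match:
                try:
                    result = fn(ctx, match.groupdict(), q, body)
                    status, doc = "200 OK", result
                except HTTPError as e:
                    status, doc = f"{e.status} ERROR", {"error": e.message}
                except (AuthorizationError,) as e:
                    status, doc = "403 Forbidden", {"error": str(e)}
                except ConflictError as e:
                    status, doc = "409 Conflict", {"error": str(e)}
                payload = json.dumps(doc).encode()
                start_response(status, [("Content-Type", "application/json"),
                                        ("Content-Length", str(len(payload)))])
                return [payload]
        payload = json.dumps({"error": f"no route {method} {path}"}).encode()
        start_response("404 Not Found", [("Content-Type", "application/json"),
                                         ("Content-Length", str(len(payload)))])
        return [payload]

    return app


def serve(ctx: EngineContext, host: str = "127.0.0.1", port: int = 0):
    """Run the WSGI app on wsgiref; returns (server, bound_port)."""
    from wsgiref.simple_server import make_server, WSGIRequestHandler

    class QuietHandler(WSGIRequestHandler):
        def log_message(self, *a):  # structured logs go through `logging`
            pass

    srv = make_server(host, port, make_wsgi_app(ctx), handler_class=QuietHandler)
    return srv, srv.server_address[1]
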