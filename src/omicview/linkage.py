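"""Cross-panel communication: bus, anchors, dual-frame links, pseudobulk.

Panels (genome browser frames, single-cell views) talk through a small
in-process message bus with per-topic ordering and schema-checked
payloads.  Genomic features — genes, peaks, eQTLs — act as *anchors*: a
click in one panel resolves the feature to a padded genomic window that
the other panel navigates to, with the feature itself highlighted and,
when the feature exists in a loaded modality, a single-cell overlay
suggestion attached.

The dual-chromosome mode keeps two independent coordinate frames;
interaction records whose anchors straddle the two frames are the links
drawn between them.  Cluster selections in the single-cell panel become
pseudobulk accessibility tracks by binning scATAC fragments per group.
"""

from __future__ import annotations

import base64
import json
import zlib
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genome.io import query_region
from .genome.types import (
    GenomeAssembly,
    GenomicInterval,
    InteractionRecord,
    TrackHandle,
    TrackKind,
)
from .search import suggest
from .tiling import ViewState

#: Interval anchors are padded by this fraction of their length per side.
ANCHOR_PAD_FRACTION = 0.2
#: Point anchors (eQTL/variant positions) get a fixed window per side.
POINT_ANCHOR_PAD_BP = 50_000


# ---------------------------------------------------------------------------
# message bus
# ---------------------------------------------------------------------------

class PayloadSchemaError(ValueError):
    pass


@dataclass(frozen=True)
class BusEvent:
    topic: str
    payload: dict
    sequence: int


#: Required payload fields per topic; unknown topics only need a dict payload.
TOPIC_SCHEMAS: Dict[str, Tuple[str, ...]] = {
    "anchor": ("source", "feature_id", "feature_kind", "chrom", "start", "end"),
    "highlight": ("chrom", "start", "end"),
    "sc_overlay": ("assay", "feature"),
    "view": ("chrom", "start", "end", "view_width"),
}


class MessageBus:
    """In-process pub/sub with strict per-topic ordering.

    An optional token set realizes the engine's authentication: when
    configured, every emit must present a known bearer token.
    """

    def __init__(self, auth_tokens: Optional[set] = None):
        self._listeners: Dict[str, List[Callable]] = defaultdict(list)
        self._sequence = 0
        self._auth_tokens = auth_tokens
        self.log: List[BusEvent] = []

    def register_listener(self, topic: str, listener: Callable) -> Callable:
        self._listeners[topic].append(listener)
        return listener

    def drop_listener(self, topic: str, listener: Callable):
        self._listeners[topic].remove(listener)

    def validate(self, topic: str, payload: dict):
        if not isinstance(payload, dict):
            raise PayloadSchemaError("payload must be a mapping")
        try:
            json.dumps(payload)
        except (TypeError, ValueError) as e:
            raise PayloadSchemaError(f"payload not serializable: {e}")
        for field_name in TOPIC_SCHEMAS.get(topic, ()):
            if field_name not in payload:
                raise PayloadSchemaError(
                    f"topic {topic!r} payload missing field {field_name!r}"
                )

    def emit(self, topic: str, payload: dict, token: Optional[str] = None) -> BusEvent:
        if self._auth_tokens is not None and token not in self._auth_tokens:
            raise PermissionError("emit rejected: unknown or missing token")
        self.validate(topic, payload)
        self._sequence += 1
        event = BusEvent(topic, dict(payload), self._sequence)
        self.log.append(event)
        for listener in list(self._listeners.get(topic, [])):
            listener(event)
        return event

    def events_since(self, sequence: int, topic: Optional[str] = None) -> List[BusEvent]:
        return [
            e for e in self.log if e.sequence > sequence and (topic is None or e.topic == topic)
        ]


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnchorMessage:
    source: str
    feature_id: str
    feature_kind: str  # gene | peak | eqtl | region
    target_region: GenomicInterval
    highlight: Optional[GenomicInterval] = None
    sc_overlay: Optional[Tuple[str, str]] = None  # (assay, feature)

    def __post_init__(self):
        if self.highlight is not None and not self.target_region.contains(self.highlight):
            raise ValueError("highlight must lie within target_region")

    def to_payload(self, ) -> dict:
        return {
            "source": self.source,
            "feature_id": self.feature_id,
            "feature_kind": self.feature_kind,
            "chrom": self.target_region.chrom,
            "start": self.target_region.start,
            "end": self.target_region.end,
            "highlight": (
                [self.highlight.start, self.highlight.end] if self.highlight else None
            ),
            "sc_overlay": list(self.sc_overlay) if self.sc_overlay else None,
        }


class AnchorError(KeyError):
    def __init__(self, feature_id, kind, suggestions):
        self.suggestions = suggestions
        msg = f"cannot resolve {kind} {feature_id!r}"
        if suggestions:
            msg += f"; did you mean: {', '.join(suggestions)}?"
        super().__init__(msg)


def resolve_anchor(
    tracks: Sequence[TrackHandle],
    feature_id: str,
    feature_kind: str,
    source: str = "sc_panel",
    sc_features: Optional[Dict[str, Sequence[str]]] = None,
    search_index=None,
) -> AnchorMessage:
    """Resolve a clicked feature to a navigable genomic window.

    Interval features (genes, peaks) are padded by 20% of their length per
    side; point features (eQTLs) get a +/- 50 kb window.  The window is
    clipped to the chromosome; the feature itself becomes the highlight.
    """
    kind_to_track_kind = {
        "gene": TrackKind.GENE,
        "peak": TrackKind.FEATURE,
        "eqtl": TrackKind.ASSOCIATION,
    }
    if feature_kind not in kind_to_track_kind:
        raise ValueError(f"unknown feature kind {feature_kind!r}")
    want = kind_to_track_kind[feature_kind]

    found = None
    assembly = None
    for handle in tracks:
        if handle.kind is not want:
            continue
        assembly = handle.assembly
        for r in handle.index.all_records():
            name = _feature_name(r, feature_kind)
            if name == feature_id:
                found = r
                break
        if found:
            break
    if found is None:
        suggestions = suggest(search_index, feature_id, k=3) if search_index else []
        raise AnchorError(feature_id, feature_kind, suggestions)

    iv = GenomicInterval(found.chrom, found.start, found.end)  # strand-free window
    chrom_len = assembly.length_of(iv.chrom)
    if len(iv) == 1:  # point feature
        pad = POINT_ANCHOR_PAD_BP
        region = iv.padded(pad, pad, chrom_len)
    else:
        pad = int(round(ANCHOR_PAD_FRACTION * len(iv)))
        region = iv.padded(pad, pad, chrom_len)

    sc_overlay = None
    for assay, names in (sc_features or {}).items():
        if feature_id in names:
            sc_overlay = (assay, feature_id)
            break

    return AnchorMessage(
        source=source,
        feature_id=feature_id,
        feature_kind=feature_kind,
        target_region=region,
        highlight=GenomicInterval(iv.chrom, iv.start, iv.end),
        sc_overlay=sc_overlay,
    )


def _feature_name(record, kind: str) -> Optional[str]:
    if kind == "gene":
        return getattr(record, "gene_name", None) or getattr(record, "gene_id", None)
    if kind == "peak":
        return getattr(record, "name", None)
    if kind == "eqtl":
        return getattr(record, "label", None)
    return None


# ---------------------------------------------------------------------------
# dual-chromosome frames
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DualFrameState:
    frame_a: ViewState
    frame_b: ViewState


def cross_frame_links(
    handle: TrackHandle, dual: DualFrameState
) -> List[InteractionRecord]:
    """Interaction records with one anchor in each frame (either order)."""
    ra = dual.frame_a.current_range
    rb = dual.frame_b.current_range
    out = []
    for r in handle.index.all_records():
        if (r.anchor1.overlaps(ra) and r.anchor2.overlaps(rb)) or (
            r.anchor1.overlaps(rb) and r.anchor2.overlaps(ra)
        ):
            out.append(r)
    out.sort(key=lambda r: (r.anchor1.chrom, r.anchor1.start, r.anchor2.chrom, r.anchor2.start))
    return out


# ---------------------------------------------------------------------------
# cluster pseudobulk coverage
# ---------------------------------------------------------------------------

def read_fragments(path: str) -> List[Tuple[str, int, int, str]]:
    """scATAC fragments: BED-like ``chrom start end barcode [count]``."""
    out = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{ln}: fragments need 4 columns")
            out.append((f[0], int(f[1]), int(f[2]), f[3]))
    return out


def cluster_coverage(
    fragments: Sequence[Tuple[str, int, int, str]],
    barcode_to_group: Dict[str, str],
    groups: Sequence[str],
    bin_size: int,
    assembly: GenomeAssembly,
    normalize: str = "cpm",
) -> Dict[str, Dict[str, np.ndarray]]:
    """Per-group binned fragment coverage, as {group: {chrom: bins}}.

    A fragment increments every bin it overlaps, once per bin.  With
    ``normalize='cpm'`` bins are scaled to counts per million fragments of
    that group; ``'raw'`` leaves plain counts (summing raw tracks across
    groups reproduces the all-cells track bin-by-bin).
    """
    if normalize not in ("cpm", "raw"):
        raise ValueError(f"unknown normalization {normalize!r}")
    group_set = list(groups)
    members = {g: 0 for g in group_set}
    for b, g in barcode_to_group.items():
        if g in members:
            members[g] += 1
    empty = [g for g in group_set if members[g] == 0]
    if empty:
        raise ValueError(f"groups with zero barcodes: {', '.join(map(str, empty))}")

    lengths = assembly.lengths
    out = {
        g: {c: np.zeros(int(np.ceil(l / bin_size))) for c, l in lengths.items()}
        for g in group_set
    }
    totals = {g: 0 for g in group_set}
    for chrom, start, end, barcode in fragments:
        g = barcode_to_group.get(barcode)
        if g not in out:
            continue
        c = assembly.resolve_chrom(chrom)
        if c is None:
            continue
        totals[g] += 1
        bins = out[g][c]
        b0 = max(start // bin_size, 0)
        b1 = min((end - 1) // bin_size, len(bins) - 1)
        for b in range(b0, b1 + 1):
            bins[b] += 1
    if normalize == "cpm":
        for g in group_set:
            denom = max(totals[g], 1)
            for c in out[g]:
                out[g][c] = out[g][c] * (1e6 / denom)
    return out


# ---------------------------------------------------------------------------
# shareable sessions
# ---------------------------------------------------------------------------

SESSION_SCHEMA_VERSION = 1
SUPPORTED_SESSION_VERSIONS = (1,)
MAX_SHARE_URL_LEN = 2048


@dataclass
class ViewSession:
    """Serializable view state shared between users."""

    session_id: str
    layout: List[dict] = field(default_factory=list)  # ordered panel descriptors
    tracks: List[dict] = field(default_factory=list)  # track refs + style keys
    view_states: List[dict] = field(default_factory=list)
    sc_overlay: Optional[dict] = None
    version: int = SESSION_SCHEMA_VERSION

    def to_dict(self) -> dict:
        return {
            "session_id": self.session_id,
            "layout": self.layout,
            "tracks": self.tracks,
            "view_states": self.view_states,
            "sc_overlay": self.sc_overlay,
            "version": self.version,
        }


def serialize_session(session: ViewSession) -> str:
    return json.dumps(session.to_dict(), sort_keys=True, separators=(",", ":"))


def deserialize_session(text: str) -> ViewSession:
    try:
        d = json.loads(text)
    except json.JSONDecodeError as e:
        raise ValueError(f"corrupt session payload: {e}") from e
    version = d.get("version")
    if version not in SUPPORTED_SESSION_VERSIONS:
        raise ValueError(
            f"unsupported session version {version!r}; supported: "
            f"{list(SUPPORTED_SESSION_VERSIONS)}"
        )
    return ViewSession(
        session_id=d["session_id"],
        layout=d.get("layout", []),
        tracks=d.get("tracks", []),
        view_states=d.get("view_states", []),
        sc_overlay=d.get("sc_overlay"),
        version=version,
    )


def session_to_url_fragment(session: ViewSession) -> str:
    """Compressed inline form; falls back to token indirection when long."""
    raw = zlib.compress(serialize_session(session).encode(), 9)
    return base64.urlsafe_b64encode(raw).decode()


def session_from_url_fragment(fragment: str) -> ViewSession:
    raw = zlib.decompress(base64.urlsafe_b64decode(fragment.encode()))
    return deserialize_session(raw.decode())
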