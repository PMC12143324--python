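"""Typo-tolerant feature-name search via a character n-gram index.

Names are lowercased, wrapped in boundary symbols (``^name$``) and split
into overlapping character n-grams (trigrams by default).  A query is
scored against each candidate by Jaccard overlap of gram sets, plus a
+1.0 bonus for an exact (case-insensitive) match and +0.5 for a prefix
match, giving scores in [0, 2.5].  Queries of the form
``chrom:start-end`` (1-based inclusive, as users type them) bypass the
index and resolve to a region reference in internal half-open coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

from .genome.types import GenomicInterval

_REGION_RE = re.compile(r"^(?P<chrom>[\w.]+):(?P<start>[\d,]+)-(?P<end>[\d,]+)$")


def parse_region_query(query: str) -> Optional[GenomicInterval]:
    """``chr8:11300703-11611527`` -> half-open interval (start-1, end)."""
    m = _REGION_RE.match(query.strip())
    if not m:
        return None
    start1 = int(m.group("start").replace(",", ""))
    end1 = int(m.group("end").replace(",", ""))
    if start1 < 1 or end1 < start1:
        return None
    return GenomicInterval(m.group("chrom"), start1 - 1, end1)


def ngrams(name: str, n: int) -> Set[str]:
    """Boundary-padded lowercase character n-grams of a name."""
    s = "^" + name.strip().lower() + "$"
    if len(s) < n:
        return {s}
    return {s[i : i + n] for i in range(len(s) - n + 1)}


@dataclass(frozen=True)
class VocabEntry:
    name: str
    source: str  # track id or assay name
    ref: object = None  # interval / feature reference


@dataclass
class NGramIndex:
    n: int = 3
    vocabulary: List[VocabEntry] = field(default_factory=list)
    postings: Dict[str, Set[int]] = field(default_factory=dict)
    _grams: List[Set[str]] = field(default_factory=list)

    def add(self, entry: VocabEntry):
        key = (entry.name.strip().lower(), entry.source)
        for e in self.vocabulary:
            if (e.name.strip().lower(), e.source) == key:
                return  # one vocabulary entry per (name, source)
        vid = len(self.vocabulary)
        self.vocabulary.append(entry)
        grams = ngrams(entry.name, self.n)
        self._grams.append(grams)
        for g in grams:
            self.postings.setdefault(g, set()).add(vid)


def build_index(names_with_refs, n: int = 3) -> NGramIndex:
    """Build a deterministic n-gram index from (name, source, ref) triples."""
    if n < 2:
        raise ValueError("n must be >= 2")
    idx = NGramIndex(n=n)
    for item in names_with_refs:
        if isinstance(item, VocabEntry):
            idx.add(item)
        else:
            name, source, ref = (tuple(item) + (None,))[:3]
            if not name or not name.strip():
                continue
            idx.add(VocabEntry(name, source, ref))
    return idx


@dataclass(frozen=True)
class SearchHit:
    name: str
    source: str
    ref: object
    score: float


@dataclass(frozen=True)
class RegionHit:
    interval: GenomicInterval
    score: float = 2.5


def search(index: NGramIndex, query: str, k: int = 10):
    """Ranked candidates for a query; region syntax short-circuits the index."""
    if k < 1:
        raise ValueError("k must be >= 1")
    q = query.strip()
    if not q:
        raise ValueError("empty query")

    region = parse_region_query(q)
    if region is not None:
        return [RegionHit(region)]

    ql = q.lower()
    qgrams = ngrams(q, index.n)

    # short queries have too few grams to discriminate; prefix scan instead
    prefix_only = len(ql) < index.n

    candidates: Set[int] = set()
    if prefix_only:
        for vid, e in enumerate(index.vocabulary):
            if e.name.lower().startswith(ql):
                candidates.add(vid)
    else:
        for g in qgrams:
            candidates |= index.postings.get(g, set())

    hits = []
    for vid in candidates:
        e = index.vocabulary[vid]
        el = e.name.strip().lower()
        inter = len(qgrams & index._grams[vid])
        union = len(qgrams | index._grams[vid])
        score = inter / union if union else 0.0
        if el == ql:
            score += 1.0
        if el.startswith(ql):
            score += 0.5
        hits.append(SearchHit(e.name, e.source, e.ref, score))
    hits.sort(key=lambda h: (-h.score, h.name.lower(), h.source))
    return hits[:k]


def suggest(index: NGramIndex, query: str, k: int = 3) -> List[str]:
    """Nearest-name suggestions for error messages."""
    try:
        out = search(index, query, k)
    except ValueError:
        return []
    return [h.name for h in out if isinstance(h, SearchHit)]
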