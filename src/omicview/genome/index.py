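"""Interval index for region queries.

Per chromosome, records are kept sorted by start with a prefix running
maximum of ends ("max-end augmentation").  A query ``[qs, qe)`` binary-searches
the starts for the right boundary (start < qe) and walks left until the
running max-end guarantees no earlier record can still overlap.  Worst case is
linear (fully nested tracks) but typical genomic tracks terminate quickly.
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from typing import Dict, List

from .types import GenomicInterval, TrackRecord


class _ChromIndex:
    __slots__ = ("starts", "ends", "records", "max_end_prefix")

    def __init__(self, records: List[TrackRecord]):
        records = sorted(records, key=lambda r: (r.start, r.end))
        self.records = records
        self.starts = [r.start for r in records]
        self.ends = [r.end for r in records]
        self.max_end_prefix = []
        running = 0
        for e in self.ends:
            running = max(running, e)
            self.max_end_prefix.append(running)

    def query(self, qstart: int, qend: int) -> List[TrackRecord]:
        # rightmost record with start < qend
        hi = bisect.bisect_left(self.starts, qend)
        out = []
        i = hi - 1
        while i >= 0:
            if self.max_end_prefix[i] <= qstart:
                break  # no record at or before i can reach into the query
            if self.ends[i] > qstart:
                out.append(self.records[i])
            i -= 1
        out.reverse()
        return out


class TrackIndex:
    """Region-query index over a set of track records."""

    def __init__(self, records_by_chrom: Dict[str, List[TrackRecord]]):
        self._by_chrom = {c: _ChromIndex(rs) for c, rs in records_by_chrom.items()}
        self.record_count = sum(len(ci.records) for ci in self._by_chrom.values())

    @classmethod
    def build(cls, records) -> "TrackIndex":
        by_chrom = defaultdict(list)
        for r in records:
            by_chrom[r.chrom].append(r)
        return cls(by_chrom)

    @property
    def chromosomes(self):
        return list(self._by_chrom)

    def records_on(self, chrom: str) -> List[TrackRecord]:
        ci = self._by_chrom.get(chrom)
        return list(ci.records) if ci else []

    def all_records(self) -> List[TrackRecord]:
        out = []
        for c in self._by_chrom:
            out.extend(self._by_chrom[c].records)
        return out

    def query(self, interval: GenomicInterval) -> List[TrackRecord]:
        """Records overlapping the half-open interval, ascending by start."""
        ci = self._by_chrom.get(interval.chrom)
        if ci is None:
            return []
        return ci.query(interval.start, interval.end)
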