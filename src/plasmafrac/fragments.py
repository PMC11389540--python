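"""Reading aligned read pairs into DNA fragments.

A *fragment* is the sequenced insert reconstructed from a proper read pair:
the leftmost mate's start plus its positive template length.  Reads failing
the standard shallow-WGS filters (MAPQ < 5, PCR duplicates, secondary and
supplementary alignments, unmapped reads, improper pairs) are removed before
any downstream analysis; the filter statistics attribute every dropped pair
to the first failing rule in a fixed order.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from collections.abc import Iterable, Iterator
from typing import NamedTuple

import numpy as np
import pandas as pd
import pysam

#: Order in which filter rules are attributed when several fail at once.
DROP_ORDER = ("unmapped", "secondary", "supplementary", "duplicate", "low_mapq", "improper_pair")


class FragmentRecord(NamedTuple):
    contig: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    length: int
    mapq: int
    sample_id: str = ""


@dataclasses.dataclass(frozen=True)
class FilterPolicy:
    min_mapq: int = 5
    drop_duplicates: bool = True
    drop_secondary: bool = True
    drop_supplementary: bool = True
    drop_unmapped: bool = True
    require_proper_pair: bool = True

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")

    def read_reason(self, read: pysam.AlignedSegment) -> str | None:
        """First failing rule for one read, or None if it passes."""
        if self.drop_unmapped and read.is_unmapped:
            return "unmapped"
        if self.drop_secondary and read.is_secondary:
            return "secondary"
        if self.drop_supplementary and read.is_supplementary:
            return "supplementary"
        if self.drop_duplicates and read.is_duplicate:
            return "duplicate"
        if read.mapping_quality < self.min_mapq:
            return "low_mapq"
        if self.require_proper_pair and not read.is_proper_pair:
            return "improper_pair"
        return None


@dataclasses.dataclass
class FilterStats:
    """Pair-level filter bookkeeping: ``kept + sum(dropped) = total pairs``.

    ``extra_records`` counts records that do not form pairs (secondary and
    supplementary alignments, or mates whose partner never appears)."""

    kept: int = 0
    dropped: Counter = dataclasses.field(default_factory=Counter)
    extra_records: Counter = dataclasses.field(default_factory=Counter)

    @property
    def total_pairs(self) -> int:
        return self.kept + sum(self.dropped.values())

    def as_dict(self) -> dict:
        return {
            "kept": self.kept,
            **{reason: self.dropped.get(reason, 0) for reason in DROP_ORDER},
            "degenerate": self.dropped.get("degenerate", 0),
        }


class Fragments:
    """Columnar fragment set: contig indices, starts and lengths as arrays."""

    def __init__(self, contig_names, contig_idx, start, length, mapq=None, sample_id=""):
        self.contig_names = tuple(contig_names)
        self.contig_idx = np.asarray(contig_idx, dtype=np.int64)
        self.start = np.asarray(start, dtype=np.int64)
        self.length = np.asarray(length, dtype=np.int64)
        if mapq is None:
            mapq = np.full(len(self.start), 60, dtype=np.int64)
        self.mapq = np.asarray(mapq, dtype=np.int64)
        self.sample_id = sample_id
        if (self.length < 1).any():
            raise ValueError("fragment lengths must be >= 1")

    def __len__(self) -> int:
        return len(self.start)

    @property
    def end(self) -> np.ndarray:
        return self.start + self.length

    def subset(self, mask: np.ndarray) -> "Fragments":
        return Fragments(
            self.contig_names,
            self.contig_idx[mask],
            self.start[mask],
            self.length[mask],
            self.mapq[mask],
            self.sample_id,
        )

    def records(self) -> Iterator[FragmentRecord]:
        names = self.contig_names
        for ci, s, ln, mq in zip(self.contig_idx, self.start, self.length, self.mapq):
            yield FragmentRecord(names[ci], int(s), int(s + ln), int(ln), int(mq), self.sample_id)

    @classmethod
    def from_records(cls, records: Iterable[FragmentRecord], sample_id: str = "") -> "Fragments":
        records = list(records)
        names: list[str] = []
        index: dict[str, int] = {}
        ci, st, ln, mq = [], [], [], []
        for r in records:
            if r.contig not in index:
                index[r.contig] = len(names)
                names.append(r.contig)
            ci.append(index[r.contig])
            st.append(r.start)
            ln.append(r.length)
            mq.append(r.mapq)
            sample_id = sample_id or r.sample_id
        return cls(names, ci, st, ln, mq, sample_id)

    def to_frame(self) -> pd.DataFrame:
        names = np.array(self.contig_names, dtype=object)
        return pd.DataFrame(
            {
                "contig": names[self.contig_idx],
                "start": self.start,
                "end": self.end,
                "length": self.length,
                "mapq": self.mapq,
            }
        )

    def write_bed(self, path) -> None:
        """BED3+ table: contig, start, end, length, mapq."""
        self.to_frame().to_csv(path, sep="\t", header=False, index=False)


def as_fragments(fragments) -> Fragments:
    """Accept a Fragments object or any iterable of FragmentRecord."""
    if isinstance(fragments, Fragments):
        return fragments
    return Fragments.from_records(fragments)


def iter_fragments(path, policy: FilterPolicy | None = None, stats: FilterStats | None = None,
                   sample_id: str = "") -> Iterator[FragmentRecord]:
    """Stream passing fragments from a coordinate-sorted alignment file.

    Both mates of a pair must pass the read-level filters; the fragment is
    taken from the mate with positive template length.  If ``stats`` is
    given it is filled in place (complete once the iterator is exhausted).
    """
    policy = policy or FilterPolicy()
    stats = stats if stats is not None else FilterStats()
    pending: dict[str, tuple[str | None, str | None, int, int]] = {}
    with pysam.AlignmentFile(str(path)) as fh:
        for read in fh:
            if read.is_secondary:
                stats.extra_records["secondary"] += 1
                continue
            if read.is_supplementary:
                stats.extra_records["supplementary"] += 1
                continue
            reason = policy.read_reason(read)
            info = (
                reason,
                read.reference_name,
                read.reference_start if not read.is_unmapped else -1,
                read.template_length,
            )
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = info
                continue
            reasons = [r for r in (mate[0], info[0]) if r is not None]
            if reasons:
                stats.dropped[min(reasons, key=DROP_ORDER.index)] += 1
                continue
            left = mate if mate[3] > 0 else info
            if left[3] <= 0:
                stats.dropped["degenerate"] += 1
                continue
            stats.kept += 1
            yield FragmentRecord(left[1], left[2], left[2] + left[3], left[3], 0, sample_id)
    for reason, *_ in pending.values():
        stats.extra_records["unpaired" if reason is None else reason] += 1


def read_fragments(path, policy: FilterPolicy | None = None, sample_id: str = "") -> tuple[Fragments, FilterStats]:
    """Materialise all passing fragments from an alignment file."""
    stats = FilterStats()
    with pysam.AlignmentFile(str(path)) as fh:
        contig_names = tuple(fh.references)
    index = {n: i for i, n in enumerate(contig_names)}
    ci, st, ln = [], [], []
    for rec in iter_fragments(path, policy, stats, sample_id=sample_id):
        ci.append(index[rec.contig])
        st.append(rec.start)
        ln.append(rec.length)
    frags = Fragments(contig_names, np.array(ci, dtype=np.int64), np.array(st, dtype=np.int64),
                      np.array(ln, dtype=np.int64) if ln else np.array([], dtype=np.int64),
                      mapq=np.full(len(st), 60, dtype=np.int64), sample_id=sample_id)
    return frags, stats


def count_reads(path, policy: FilterPolicy | None = None) -> tuple[int, Counter]:
    """Read-level counts passing the policy: (total aligned reads, per-contig).

    Counts individual reads, not fragments, matching how mitochondrial-DNA
    fractions are computed from samtools-style read counts.
    """
    policy = policy or FilterPolicy()
    per_contig: Counter = Counter()
    total = 0
    with pysam.AlignmentFile(str(path)) as fh:
        for read in fh:
            if policy.read_reason(read) is None:
                total += 1
                per_contig[read.reference_name] += 1
    return total, per_contig
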