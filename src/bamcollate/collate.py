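"""Bounded-memory collation of alignment streams by read name.

Coordinate-sorted paired-end files keep the two mates of a template apart:
with mean depth d, mean template length t and read length l one expects
about (d/l)(t-l) alignments between the mates, so most pairs are close
together while a minority (split pairs, high-depth regions) are not.  The
engine exploits this: records stream through a fixed-size collisionless
hash table H keyed by read name; a colliding resident is displaced into a
fixed-size two-ended overflow list L; whenever L fills it is sorted by
name, freshly matched pairs are emitted, and the remainder is written to a
name-sorted temporary run on disk.  After the input is exhausted the runs
are k-way merged to recover the remaining pairs, orphans and singles.
Total main memory is bounded by the sizes chosen for H and L regardless of
input size.

The hash table is backed by a ring buffer R of serialized records, a slot
table P of offsets into R, and an ordered index B of live start offsets;
inserting may evict the ring-order successor of the write cursor until the
circular gap suffices.  The overflow list packs record bytes from the
front of its buffer and insertion-order pointer entries from the back.

For n records of which n_H resolve in the hash table and n_L transit the
overflow list, time is O(n_H + n_L log n_L); with a list of s_L bytes,
in-memory space is O(s_L) plus the fixed table.
"""

from __future__ import annotations

import heapq
import os
import struct
import tempfile
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Iterator, List, Optional, Tuple

from .records import (
    AlignmentRecord,
    SerializedRecord,
    deserialize,
    extract_name,
    extract_sort_key,
    serialize,
)


class CollationError(RuntimeError):
    """Raised on configuration or temp-file corruption errors."""


def expected_pair_gap(d: float, t: float, l: float) -> float:
    """Expected number of alignments between the mates of a template.

    In a coordinate-sorted file the mean number of read ends starting at
    each position on the forward strand is d/l, and the forward-strand
    start points of the two mates are t - l apart, so the expected in-file
    gap is (d/l) * (t - l).

    Parameters
    ----------
    d : mean sequencing depth (reads covering a position)
    t : mean absolute template length, bases
    l : mean read length, bases
    """
    if d <= 0 or l <= 0:
        raise ValueError("depth and read length must be positive")
    if t < l:
        raise ValueError("template length must be at least the read length")
    return (d / l) * (t - l)


def hash_name(name: str, h: int) -> int:
    """Deterministic slot index for a read name (FNV-1a 64-bit, mod h)."""
    x = 0xCBF29CE484222325
    for b in name.encode():
        x = ((x ^ b) * 0x100000001B3) & 0xFFFFFFFFFFFFFFFF
    return x % h


class Category(Enum):
    PAIR = "pair"
    ORPHAN = "orphan"
    SINGLE = "single"


@dataclass
class CollationOutput:
    """One collated emission: a mate pair, an orphan, or a single-end read.

    For PAIR, ``first`` carries the read1 flag and ``second`` read2,
    regardless of file order.  Secondary/supplementary records pass
    through as SINGLE without participating in pairing.
    """

    category: Category
    first: AlignmentRecord
    second: Optional[AlignmentRecord] = None


@dataclass
class CollationConfig:
    """Sizing of the collation data structures.

    h            number of slots in the hash table P
    r_capacity   ring buffer size, bytes (must hold the largest record)
    s_L          overflow list size, bytes
    tmp_dir      directory for temp runs (default: system tmp; the
                 BAMCOLLATE_TMPDIR environment variable overrides)
    k            merge passes; 1 merges all runs at once where the open-file
                 budget (fan_in) allows, extra passes happen automatically
                 when the run count exceeds fan_in
    """

    h: int = 1 << 16
    r_capacity: int = 16 << 20
    s_L: int = 32 << 20
    tmp_dir: Optional[str] = None
    k: int = 1
    fan_in: int = 256

    def __post_init__(self):
        if self.h < 1:
            raise CollationError("hash table needs at least one slot")
        if self.s_L < _ENTRY_SIZE + _LEN_SIZE + 1:
            raise CollationError("overflow list too small for any record")
        if self.tmp_dir is None:
            self.tmp_dir = os.environ.get("BAMCOLLATE_TMPDIR")


@dataclass
class CollationStats:
    """Counters of one collation run.

    n     records consumed
    n_H   records whose pair was resolved directly in the hash table
    n_L   records routed through the overflow list (including the final
          hash-table drain)
    runs  temporary name-sorted runs written

    peak_ring_bytes / peak_list_bytes record the instrumentation maxima of
    live bytes in the ring buffer and overflow-list occupancy.
    """

    n: int = 0
    n_H: int = 0
    n_L: int = 0
    runs: int = 0
    pairs: int = 0
    orphans: int = 0
    singles: int = 0
    peak_ring_bytes: int = 0
    peak_list_bytes: int = 0


_LEN_SIZE = 4
_LEN = struct.Struct("<I")
_ENTRY_SIZE = 8
_ENTRY = struct.Struct("<II")

_RUN_MAGIC = b"BCRUN1\n"


class CollationHashTable:
    """Fixed-size collisionless name-keyed record store.

    R is a circular byte buffer of serialized records (each stored with a
    4-byte length prefix, wrapping allowed); P maps hash slots to start
    offsets in R (-1 = empty); B is the ordered index of live start
    offsets; r is the insert cursor.
    """

    def __init__(self, h: int, r_capacity: int):
        self.h = h
        self.cap = r_capacity
        self.R = bytearray(r_capacity)
        self.P: List[int] = [-1] * h
        self.B: List[int] = []
        self.r = 0
        self.live_bytes = 0
        self.peak_live_bytes = 0

    def __len__(self) -> int:
        return len(self.B)

    # circular byte access ------------------------------------------------
    def _write_bytes(self, off: int, data: bytes) -> None:
        off %= self.cap
        end = off + len(data)
        if end <= self.cap:
            self.R[off:end] = data
        else:
            cut = self.cap - off
            self.R[off:] = data[:cut]
            self.R[: end - self.cap] = data[cut:]

    def _read_bytes(self, off: int, n: int) -> bytes:
        off %= self.cap
        end = off + n
        if end <= self.cap:
            return bytes(self.R[off:end])
        cut = self.cap - off
        return bytes(self.R[off:]) + bytes(self.R[: end - self.cap])

    def record_at(self, off: int) -> SerializedRecord:
        (ln,) = _LEN.unpack(self._read_bytes(off, _LEN_SIZE))
        return self._read_bytes(off + _LEN_SIZE, ln)

    # index maintenance ---------------------------------------------------
    def _free_at_cursor(self) -> int:
        """Contiguous circular free space from the cursor to the next live record."""
        if not self.B:
            return self.cap
        i = bisect_left(self.B, self.r)
        if i < len(self.B) and self.B[i] == self.r:
            return 0
        succ = self.B[i] if i < len(self.B) else self.B[0]
        return (succ - self.r) % self.cap

    def _cursor_successor(self) -> int:
        """Start offset of the live record next after the cursor in ring order."""
        i = bisect_left(self.B, self.r)
        return self.B[i] if i < len(self.B) else self.B[0]

    def slot_of(self, buf: SerializedRecord) -> int:
        return hash_name(extract_name(buf), self.h)

    def erase(self, slot: int) -> None:
        off = self.P[slot]
        if off < 0:
            return
        (ln,) = _LEN.unpack(self._read_bytes(off, _LEN_SIZE))
        self.B.remove(off)
        self.P[slot] = -1
        self.live_bytes -= _LEN_SIZE + ln

    def evict_oldest(self) -> SerializedRecord:
        """Remove the ring-order successor of the cursor and return its bytes."""
        off = self._cursor_successor()
        buf = self.record_at(off)
        slot = self.slot_of(buf)
        if self.P[slot] != off:  # pragma: no cover - structural corruption
            raise CollationError("hash table index out of sync")
        self.erase(slot)
        return buf

    def store(self, slot: int, buf: SerializedRecord, evicted: List[SerializedRecord]) -> None:
        """Place a serialized record into an empty slot, evicting ring-order
        successors into ``evicted`` until the circular gap at the cursor is
        large enough."""
        need = _LEN_SIZE + len(buf)
        if need > self.cap:
            raise CollationError(
                f"record {extract_name(buf)!r} ({need} bytes) exceeds ring "
                f"buffer capacity {self.cap}"
            )
        while self._free_at_cursor() < need:
            evicted.append(self.evict_oldest())
        off = self.r
        self._write_bytes(off, _LEN.pack(len(buf)))
        self._write_bytes((off + _LEN_SIZE) % self.cap, buf)
        insort(self.B, off)
        self.P[slot] = off
        self.r = (off + need) % self.cap
        self.live_bytes += need
        if self.live_bytes > self.peak_live_bytes:
            self.peak_live_bytes = self.live_bytes

    def drain(self) -> Iterator[SerializedRecord]:
        """Yield and remove every resident record (used at end of input)."""
        for slot in range(self.h):
            if self.P[slot] >= 0:
                buf = self.record_at(self.P[slot])
                self.erase(slot)
                yield buf


class OverflowList:
    """Fixed-size two-ended byte store for records awaiting external handling.

    Record bytes fill the buffer upward from offset 0; fixed-size
    (offset, length) pointer entries fill downward from the end.  Read
    back-to-front, the pointer entries enumerate records in insertion
    order.  The list is full when the next record plus its entry would
    make the two regions overlap.
    """

    def __init__(self, s_L: int):
        self.size = s_L
        self.buf = bytearray(s_L)
        self.front = 0
        self.back = s_L
        self.count = 0
        self.peak_bytes = 0

    def occupancy(self) -> int:
        return self.front + (self.size - self.back)

    def fits(self, buf: SerializedRecord) -> bool:
        return self.front + len(buf) + _ENTRY_SIZE <= self.back

    def append(self, buf: SerializedRecord) -> None:
        if not self.fits(buf):
            raise CollationError(
                f"record {extract_name(buf)!r} does not fit the overflow list "
                f"({len(buf) + _ENTRY_SIZE} bytes needed, size {self.size})"
            )
        ln = len(buf)
        self.buf[self.front : self.front + ln] = buf
        self.back -= _ENTRY_SIZE
        _ENTRY.pack_into(self.buf, self.back, self.front, ln)
        self.front += ln
        self.count += 1
        occ = self.occupancy()
        if occ > self.peak_bytes:
            self.peak_bytes = occ

    def entries(self) -> List[Tuple[int, int]]:
        """Pointer entries in insertion order (back of the buffer first)."""
        out = []
        off = self.size - _ENTRY_SIZE
        while off >= self.back:
            out.append(_ENTRY.unpack_from(self.buf, off))
            off -= _ENTRY_SIZE
        return out

    def record(self, entry: Tuple[int, int]) -> SerializedRecord:
        off, ln = entry
        return bytes(self.buf[off : off + ln])

    def sort_pointers(self) -> List[Tuple[int, int]]:
        """Sort the pointer entries in place by the record name comparator
        (record bytes stay put) and return them in sorted order."""
        ents = self.entries()
        ents.sort(key=lambda e: extract_sort_key(self.record(e)))
        off = self.size - _ENTRY_SIZE
        for e in ents:
            _ENTRY.pack_into(self.buf, off, *e)
            off -= _ENTRY_SIZE
        return ents

    def clear(self) -> None:
        self.front = 0
        self.back = self.size
        self.count = 0


@dataclass
class TempRun:
    """A temporary file of length-prefixed serialized records in
    nondecreasing name order, with no emit-eligible pair inside."""

    path: str
    count: int


def _write_run(payloads: Iterable[SerializedRecord], tmp_dir: Optional[str]) -> TempRun:
    fd, path = tempfile.mkstemp(prefix="bamcollate-run-", suffix=".tmp", dir=tmp_dir)
    count = 0
    with os.fdopen(fd, "wb") as fh:
        fh.write(_RUN_MAGIC)
        for buf in payloads:
            fh.write(_LEN.pack(len(buf)))
            fh.write(buf)
            count += 1
    return TempRun(path=path, count=count)


def _iter_run(run: TempRun) -> Iterator[SerializedRecord]:
    with open(run.path, "rb") as fh:
        magic = fh.read(len(_RUN_MAGIC))
        if magic != _RUN_MAGIC:
            raise CollationError(f"corrupt temp run {run.path}: bad magic")
        last_key = None
        while True:
            head = fh.read(_LEN_SIZE)
            if not head:
                break
            if len(head) < _LEN_SIZE:
                raise CollationError(f"corrupt temp run {run.path}: truncated")
            (ln,) = _LEN.unpack(head)
            buf = fh.read(ln)
            if len(buf) < ln:
                raise CollationError(f"corrupt temp run {run.path}: truncated")
            key = extract_sort_key(buf)
            if last_key is not None and key < last_key:
                raise CollationError(f"corrupt temp run {run.path}: not name-sorted")
            last_key = key
            yield buf


def _pair_ordered(a: AlignmentRecord, b: AlignmentRecord) -> CollationOutput:
    if a.is_read2 and b.is_read1:
        a, b = b, a
    return CollationOutput(Category.PAIR, a, b)


def _complementary(fa: int, fb: int) -> bool:
    # one carries read1, the other read2
    a, b = (fa >> 6) & 3, (fb >> 6) & 3
    return (a | b) == 3 and a != b


class NameCollator:
    """Driver object wiring hash table, overflow list and temp runs together.

    Use :func:`collate` for the one-call interface; the individual steps
    (``hash_insert``, ``list_insert``, ``flush_list``, ``finalize``,
    ``merge_runs``) are exposed for testing and instrumentation.
    """

    def __init__(self, config: Optional[CollationConfig] = None):
        self.config = config or CollationConfig()
        self.H = CollationHashTable(self.config.h, self.config.r_capacity)
        self.L = OverflowList(self.config.s_L)
        self.runs: List[TempRun] = []
        self.stats = CollationStats()
        self.pending: List[CollationOutput] = []

    # ------------------------------------------------------------------
    def hash_insert(self, rec: AlignmentRecord) -> None:
        """Insert one collation-eligible record into the hash table.

        Either the resident at the record's slot is its mate (pair emitted,
        slot cleared), or the resident collides and is displaced into the
        overflow list before the record is stored.
        """
        buf = serialize(rec)
        slot = hash_name(rec.name, self.H.h)
        off = self.H.P[slot]
        if off >= 0:
            resident = self.H.record_at(off)
            res_key = extract_sort_key(resident)
            if res_key[0] == rec.name.encode():
                res = deserialize(resident)
                if _complementary(res.flags, rec.flags):
                    self.H.erase(slot)
                    self.stats.n_H += 2
                    self.stats.pairs += 1
                    self.pending.append(_pair_ordered(res, rec))
                    return
            # collision (different name, or same name without complementary
            # read1/read2 flags): displace the resident
            self.H.erase(slot)
            self.list_insert(resident)
        evicted: List[SerializedRecord] = []
        self.H.store(slot, buf, evicted)
        for victim in evicted:
            self.list_insert(victim)
        if self.H.peak_live_bytes > self.stats.peak_ring_bytes:
            self.stats.peak_ring_bytes = self.H.peak_live_bytes

    def list_insert(self, buf: SerializedRecord) -> None:
        """Append a serialized record to the overflow list, flushing it to a
        temp run first if the record does not fit."""
        if not self.L.fits(buf):
            self.flush_list()
            if not self.L.fits(buf):
                raise CollationError(
                    f"record {extract_name(buf)!r} larger than overflow list"
                )
        self.L.append(buf)
        self.stats.n_L += 1
        if self.L.peak_bytes > self.stats.peak_list_bytes:
            self.stats.peak_list_bytes = self.L.peak_bytes

    def flush_list(self) -> Optional[TempRun]:
        """Sort the overflow list by name, emit freshly matched pairs, and
        write the remaining records to a new name-sorted temp run."""
        if self.L.count == 0:
            return None
        ents = self.L.sort_pointers()
        payloads = [self.L.record(e) for e in ents]
        leftovers = list(self._extract_pairs(payloads))
        self.L.clear()
        if not leftovers:
            return None
        run = _write_run(leftovers, self.config.tmp_dir)
        self.runs.append(run)
        self.stats.runs += 1
        return run

    def _extract_pairs(self, payloads: Iterable[SerializedRecord]) -> Iterator[SerializedRecord]:
        """Scan name-sorted payloads, emit complementary mates as PAIRs to
        the pending sink, and yield the unmatched records in order."""
        group: List[SerializedRecord] = []
        group_name: Optional[str] = None
        for buf in payloads:
            name = extract_name(buf)
            if name != group_name and group:
                yield from self._resolve_group(group)
                group = []
            group_name = name
            group.append(buf)
        if group:
            yield from self._resolve_group(group)

    def _resolve_group(self, group: List[SerializedRecord]) -> Iterator[SerializedRecord]:
        r1 = [b for b in group if extract_sort_key(b)[1] == 0]
        r2 = [b for b in group if extract_sort_key(b)[1] == 1]
        n_pairs = min(len(r1), len(r2))
        for a, b in zip(r1[:n_pairs], r2[:n_pairs]):
            self.stats.pairs += 1
            self.pending.append(_pair_ordered(deserialize(a), deserialize(b)))
        yield from r1[n_pairs:]
        yield from r2[n_pairs:]

    def finalize(self) -> None:
        """Drain the hash table into the overflow list and flush it; all
        unresolved records end up in the temp runs (or emit as pairs)."""
        for buf in self.H.drain():
            self.list_insert(buf)
        self.flush_list()

    def merge_runs(self) -> Iterator[CollationOutput]:
        """k-way merge of the name-sorted runs; same-name complementary
        mates emit as PAIR, leftover paired-flag records as ORPHAN, and
        unpaired records as SINGLE.  When the number of runs exceeds the
        configured fan-in, intermediate merge passes combine them first
        (pairs discovered early are emitted immediately)."""
        runs = list(self.runs)
        self.runs = []
        fan_in = max(2, self.config.fan_in)
        while len(runs) > fan_in:
            batch, runs = runs[:fan_in], runs[fan_in:]
            merged = heapq.merge(*map(_iter_run, batch), key=extract_sort_key)
            leftovers = self._extract_pairs(merged)
            newrun = _write_run(leftovers, self.config.tmp_dir)
            yield from self._drain_pending()
            for r in batch:
                os.unlink(r.path)
            runs.append(newrun)
        merged = heapq.merge(*map(_iter_run, runs), key=extract_sort_key)
        for buf in self._extract_pairs(merged):
            rec = deserialize(buf)
            if rec.is_paired:
                self.stats.orphans += 1
                yield CollationOutput(Category.ORPHAN, rec)
            else:  # pragma: no cover - singles normally bypass the engine
                self.stats.singles += 1
                yield CollationOutput(Category.SINGLE, rec)
            yield from self._drain_pending()
        yield from self._drain_pending()
        for r in runs:
            os.unlink(r.path)

    def _drain_pending(self) -> Iterator[CollationOutput]:
        if self.pending:
            out, self.pending = self.pending, []
            yield from out


def collate(
    records: Iterable[AlignmentRecord],
    config: Optional[CollationConfig] = None,
) -> Tuple[Iterator[CollationOutput], CollationStats]:
    """Collate an alignment stream by read name.

    Returns ``(outputs, stats)`` where ``outputs`` lazily yields
    :class:`CollationOutput` items (every eligible input record appears in
    exactly one) and ``stats`` is filled in as the stream is consumed.
    Input order is arbitrary; coordinate-sorted input is the fast path.

    Unpaired reads, and secondary/supplementary alignments (which would
    give a name more than two records), are passed through as SINGLE
    without entering the pairing machinery.
    """
    coll = NameCollator(config)
    stats = coll.stats

    def gen() -> Iterator[CollationOutput]:
        for rec in records:
            stats.n += 1
            if rec.is_secondary or rec.is_supplementary or not rec.is_paired:
                stats.singles += 1
                yield CollationOutput(Category.SINGLE, rec)
                continue
            coll.hash_insert(rec)
            yield from coll._drain_pending()
        coll.finalize()
        yield from coll._drain_pending()
        yield from coll.merge_runs()

    return gen(), stats
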