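"""Duplicate marking by 5' mapping coordinate over the collating reader.

Two reads (or read pairs) are duplicates when their 5' coordinates on the
reference coincide.  The 5' coordinate of a forward-strand read is its
leftmost reference position extrapolated through leading soft/hard clips;
for a reverse-strand read it is the rightmost aligned position
extrapolated through trailing clips — so PCR copies whose clipping
differs still collide.  Pairs are keyed by the lexicographically ordered
pair of end coordinates.

Within each coincidence class a single representant — the entry with the
highest score computed from the base qualities (sum of Phred values of at
least 15; ties broken towards the lowest source rank) — stays unmarked
and every other member has the duplicate flag (0x400) set.  Single-end
reads and orphans mapping to the same coordinate as one end of a mapped
pair are marked unconditionally; reads of mapped pairs are never marked
through the fragment list.

List building streams through the name collator; to bound memory the
per-coordinate lists are held in RAM only up to a configurable entry
threshold, above which the list with the lowest coordinate is flushed to
a disk run and that coordinate is handled externally from then on.  The
deduced rank set is applied in a second pass that rewrites the file with
only the duplicate flag changed.
"""

from __future__ import annotations

import os
import pickle
import tempfile
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Set, Tuple

from .collate import Category, CollationConfig, CollationOutput, collate
from .records import FDUP, AlignmentRecord, open_alignments, write_alignments

QUAL_CUTOFF = 15

# FragCoord: (ref_id, pos5, strand) with strand 0 = forward, 1 = reverse.
FragCoord = Tuple[int, int, int]
# PairCoord: (left FragCoord, right FragCoord), canonically ordered.
PairCoord = Tuple[FragCoord, FragCoord]


class MarkdupError(RuntimeError):
    pass


def _clips(cigar, leading: bool) -> int:
    ops = cigar if leading else tuple(reversed(cigar))
    n = 0
    for op, ln in ops:
        if op in (4, 5):  # S, H
            n += ln
        else:
            break
    return n


def frag_coord(rec: AlignmentRecord) -> FragCoord:
    """Unclipped 5' coordinate of a mapped record."""
    if rec.is_unmapped or rec.ref_id < 0:
        raise MarkdupError(f"record {rec.name!r} is unmapped; no 5' coordinate")
    if rec.is_reverse:
        pos5 = rec.pos + rec.reference_span() - 1 + _clips(rec.cigar, leading=False)
        return (rec.ref_id, pos5, 1)
    return (rec.ref_id, rec.pos - _clips(rec.cigar, leading=True), 0)


def frag_score(rec: AlignmentRecord) -> int:
    """Sum of base quality values of at least QUAL_CUTOFF; absent quals score 0."""
    return sum(q - 33 for q in rec.qual.encode() if q - 33 >= QUAL_CUTOFF)


def pair_score(a: AlignmentRecord, b: AlignmentRecord) -> int:
    return frag_score(a) + frag_score(b)


@dataclass(frozen=True)
class FragEntry:
    coord: FragCoord
    score: int
    rank: int
    is_pair_member: bool


@dataclass(frozen=True)
class PairEntry:
    coord: PairCoord
    score: int
    ranks: Tuple[int, int]


# ---------------------------------------------------------------------------
# marking operators (operate on coordinate-sorted flat entry lists)

def mark_fragment_duplicates(
    entries: Sequence[FragEntry], pair_end_coords: Set[FragCoord]
) -> Set[int]:
    """Ranks to mark from the coordinate-sorted fragment list.

    Entries of mapped pairs are never marked here.  A non-pair fragment at
    a coordinate that is also the end of a mapped pair is marked
    unconditionally; otherwise, within each equal-coordinate class all but
    the single highest-score entry (lowest rank on ties) are marked.
    """
    marked: Set[int] = set()
    i, n = 0, len(entries)
    prev: Optional[FragCoord] = None
    while i < n:
        coord = entries[i].coord
        if prev is not None and coord < prev:
            raise MarkdupError("fragment list is not coordinate-sorted")
        prev = coord
        j = i
        cls: List[FragEntry] = []
        while j < n and entries[j].coord == coord:
            cls.append(entries[j])
            j += 1
        frags = [e for e in cls if not e.is_pair_member]
        if frags:
            if coord in pair_end_coords:
                marked.update(e.rank for e in frags)
            elif len(frags) > 1:
                best = max(frags, key=lambda e: (e.score, -e.rank))
                marked.update(e.rank for e in frags if e is not best)
        i = j
    return marked


def mark_pair_duplicates(entries: Sequence[PairEntry]) -> Set[int]:
    """Ranks to mark from the lexicographically sorted pair list: per
    equal-coordinate class both ranks of every non-representant pair."""
    marked: Set[int] = set()
    i, n = 0, len(entries)
    prev: Optional[PairCoord] = None
    while i < n:
        coord = entries[i].coord
        if prev is not None and coord < prev:
            raise MarkdupError("pair list is not coordinate-sorted")
        prev = coord
        cls: List[PairEntry] = []
        j = i
        while j < n and entries[j].coord == coord:
            cls.append(entries[j])
            j += 1
        if len(cls) > 1:
            best = max(cls, key=lambda e: (e.score, -min(e.ranks)))
            for e in cls:
                if e is not best:
                    marked.update(e.ranks)
        i = j
    return marked


# ---------------------------------------------------------------------------
# hybrid in-memory / spilled list state

class DupListState:
    """Coordinate-keyed fragment and pair lists with bounded memory.

    In-memory entries are grouped per coordinate; when the total number of
    held entries exceeds ``threshold`` the coordinate class with the
    lowest key is appended to a disk run and recorded as spilled, and any
    later entry at a spilled coordinate bypasses memory straight to that
    run.  Each run therefore holds a single coordinate class and is
    trivially coordinate-sorted.  ``threshold`` None means unbounded
    (pure in-memory operation).
    """

    def __init__(self, threshold: Optional[int] = None, tmp_dir: Optional[str] = None):
        self.threshold = threshold
        self.tmp_dir = tmp_dir
        self.frag_mem: Dict[FragCoord, List[FragEntry]] = {}
        self.pair_mem: Dict[PairCoord, List[PairEntry]] = {}
        self.count = 0
        self.spill_paths: Dict[Tuple[str, tuple], str] = {}
        self.spilled_frag: Set[FragCoord] = set()
        self.spilled_pair: Set[PairCoord] = set()
        self.pair_end_coords: Set[FragCoord] = set()
        self.pairs_examined = 0

    # -- insertion ------------------------------------------------------
    def add_frag(self, entry: FragEntry) -> None:
        if entry.is_pair_member:
            self.pair_end_coords.add(entry.coord)
        if entry.coord in self.spilled_frag:
            self._append_run("frag", entry.coord, entry)
            return
        self.frag_mem.setdefault(entry.coord, []).append(entry)
        self.count += 1
        self._maybe_spill()

    def add_pair(self, entry: PairEntry) -> None:
        self.pairs_examined += 1
        if entry.coord in self.spilled_pair:
            self._append_run("pair", entry.coord, entry)
            return
        self.pair_mem.setdefault(entry.coord, []).append(entry)
        self.count += 1
        self._maybe_spill()

    # -- spilling -------------------------------------------------------
    @staticmethod
    def _global_key(kind: str, coord) -> tuple:
        # frags and pairs compete for the lowest coordinate; a pair is keyed
        # by its left end, sorting just after a fragment at the same spot
        if kind == "frag":
            return (coord[0], coord[1], coord[2], 0, ())
        left, right = coord
        return (left[0], left[1], left[2], 1, right)

    def _maybe_spill(self) -> None:
        while self.threshold is not None and self.count > self.threshold:
            self.spill_lowest()

    def spill_lowest(self) -> None:
        """Flush the in-memory coordinate class with the lowest key to disk
        and mark the coordinate for external handling."""
        candidates = [("frag", c) for c in self.frag_mem] + [
            ("pair", c) for c in self.pair_mem
        ]
        if not candidates:
            return
        kind, coord = min(candidates, key=lambda kc: self._global_key(*kc))
        if kind == "frag":
            entries = self.frag_mem.pop(coord)
            self.spilled_frag.add(coord)
        else:
            entries = self.pair_mem.pop(coord)
            self.spilled_pair.add(coord)
        self.count -= len(entries)
        for e in entries:
            self._append_run(kind, coord, e)

    def _append_run(self, kind: str, coord, entry) -> None:
        key = (kind, coord)
        path = self.spill_paths.get(key)
        if path is None:
            fd, path = tempfile.mkstemp(
                prefix="bamcollate-dup-", suffix=".tmp", dir=self.tmp_dir
            )
            os.close(fd)
            self.spill_paths[key] = path
        with open(path, "ab") as fh:
            pickle.dump(entry, fh)

    def _read_run(self, key) -> list:
        out = []
        with open(self.spill_paths[key], "rb") as fh:
            while True:
                try:
                    out.append(pickle.load(fh))
                except EOFError:
                    break
        return out

    # -- finalization ---------------------------------------------------
    def sorted_entries(self) -> Tuple[List[FragEntry], List[PairEntry]]:
        """Merge in-memory classes and spill runs into the two
        coordinate-sorted flat lists, deleting the runs."""
        frag_classes: Dict[FragCoord, List[FragEntry]] = dict(self.frag_mem)
        pair_classes: Dict[PairCoord, List[PairEntry]] = dict(self.pair_mem)
        for (kind, coord), _path in list(self.spill_paths.items()):
            entries = self._read_run((kind, coord))
            if kind == "frag":
                frag_classes.setdefault(coord, []).extend(entries)
            else:
                pair_classes.setdefault(coord, []).extend(entries)
            os.unlink(self.spill_paths.pop((kind, coord)))
        frags = [e for c in sorted(frag_classes) for e in frag_classes[c]]
        pairs = [e for c in sorted(pair_classes) for e in pair_classes[c]]
        return frags, pairs


def build_dup_lists(
    outputs: Iterable[CollationOutput], state: DupListState
) -> DupListState:
    """Populate the fragment and pair lists from a collating reader.

    Every mapped end of a both-ends-mapped pair contributes a pair-member
    fragment entry and the pair one pair entry; orphans (mate unmapped or
    absent) and unpaired singles contribute plain fragment entries.
    Secondary/supplementary records are excluded.
    """
    for out in outputs:
        if out.category is Category.PAIR:
            a, b = out.first, out.second
            a_mapped, b_mapped = not a.is_unmapped, not b.is_unmapped
            if a_mapped and b_mapped:
                ca, cb = frag_coord(a), frag_coord(b)
                score = pair_score(a, b)
                coord = (ca, cb) if ca <= cb else (cb, ca)
                state.add_frag(FragEntry(ca, frag_score(a), a.rank, True))
                state.add_frag(FragEntry(cb, frag_score(b), b.rank, True))
                state.add_pair(PairEntry(coord, score, (a.rank, b.rank)))
            else:
                for r in (a, b):
                    if not r.is_unmapped:
                        state.add_frag(FragEntry(frag_coord(r), frag_score(r), r.rank, False))
        else:
            rec = out.first
            if rec.is_secondary or rec.is_supplementary or rec.is_unmapped:
                continue
            state.add_frag(FragEntry(frag_coord(rec), frag_score(rec), rec.rank, False))
    return state


def deduce_duplicate_ranks(
    input_path: str,
    config: Optional[CollationConfig] = None,
    threshold: Optional[int] = None,
) -> Tuple[Set[int], Dict[str, int]]:
    """First pass: collate the file and deduce the set of ranks to mark."""
    config = config or CollationConfig()
    _, records = open_alignments(input_path, assign_ranks=True)
    outputs, stats = collate(records, config)
    state = DupListState(threshold=threshold, tmp_dir=config.tmp_dir)
    build_dup_lists(outputs, state)
    frags, pairs = state.sorted_entries()
    marked = mark_pair_duplicates(pairs)
    marked |= mark_fragment_duplicates(frags, state.pair_end_coords)
    names = stats.pairs + stats.orphans + stats.singles
    counts = {
        "templates": names,
        "pairs_examined": state.pairs_examined,
        "dup_reads_marked": len(marked),
    }
    return marked, counts


def mark_duplicates(
    input_path: str,
    output_path: str,
    config: Optional[CollationConfig] = None,
    threshold: Optional[int] = None,
    level: Optional[int] = None,
) -> Dict[str, int]:
    """Mark duplicate reads: rewrite ``input_path`` to ``output_path`` with
    flag 0x400 set on exactly the deduced ranks and cleared elsewhere; all
    other record content and the record order are preserved.

    ``threshold`` bounds the number of in-memory duplicate-list entries
    (None = unbounded).  Returns summary counts.
    """
    marked, counts = deduce_duplicate_ranks(input_path, config, threshold)
    header, records = open_alignments(input_path, assign_ranks=True)

    def rewritten():
        for rec in records:
            if rec.rank in marked:
                rec.flags |= FDUP
            else:
                rec.flags &= ~FDUP
            yield rec

    n = write_alignments(rewritten(), output_path, header, level=level)
    counts["records"] = n
    return counts
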