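"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's engine code paths: collation is
checked against a plain name-sort-and-group pass, and duplicate marking
against an all-pairs O(n^2) scan applying the 5'-coordinate rules
directly.  Five-prime coordinates and scores are recomputed here from
first principles rather than imported, so the two routes stay independent.
"""

from collections import Counter, defaultdict


def collation_partition(records):
    """Partition eligible records into pairs/orphans/singles by stable
    name-sort and grouping; returns comparable multisets."""
    singles = Counter()
    groups = defaultdict(list)
    for r in records:
        if r.is_secondary or r.is_supplementary or not r.is_paired:
            singles[(r.name, r.flags, r.rank)] += 1
        else:
            groups[r.name].append(r)
    pairs = Counter()
    orphans = Counter()
    for name, grp in groups.items():
        n1 = sum(1 for r in grp if r.is_read1 and not r.is_read2)
        n2 = sum(1 for r in grp if r.is_read2 and not r.is_read1)
        k = min(n1, n2)
        pairs[name] += k
        for _ in range(len(grp) - 2 * k):
            orphans[name] += 1
    return {"pairs": pairs, "orphans": orphans, "singles": singles}


def engine_partition(outputs):
    """Same multisets, collected from a stream of CollationOutput."""
    pairs = Counter()
    orphans = Counter()
    singles = Counter()
    for out in outputs:
        if out.category.value == "pair":
            assert out.first.name == out.second.name
            assert out.first.is_read1 and out.second.is_read2
            pairs[out.first.name] += 1
        elif out.category.value == "orphan":
            orphans[out.first.name] += 1
        else:
            r = out.first
            singles[(r.name, r.flags, r.rank)] += 1
    return {"pairs": pairs, "orphans": orphans, "singles": singles}


# ---------------------------------------------------------------------------
# duplicate marking

def _coord5(rec):
    """Unclipped 5' coordinate, recomputed from the CIGAR by hand."""
    lead = 0
    for op, ln in rec.cigar:
        if op in (4, 5):
            lead += ln
        else:
            break
    trail = 0
    for op, ln in reversed(rec.cigar):
        if op in (4, 5):
            trail += ln
        else:
            break
    span = sum(ln for op, ln in rec.cigar if op in (0, 2, 3, 7, 8))
    if rec.flags & 0x10:
        return (rec.ref_id, rec.pos + span - 1 + trail, 1)
    return (rec.ref_id, rec.pos - lead, 0)


def _score(rec):
    return sum(ord(c) - 33 for c in rec.qual if ord(c) - 33 >= 15)


def brute_force_duplicate_ranks(records):
    """All-pairs duplicate deduction: ranks that must carry flag 0x400."""
    by_name = defaultdict(list)
    for r in records:
        if r.flags & (0x100 | 0x800):
            continue
        by_name[r.name].append(r)

    pair_items = []   # (pair coord, score, (rank, rank))
    frag_items = []   # (frag coord, score, rank, belongs-to-mapped-pair)
    for grp in by_name.values():
        r1 = [r for r in grp if r.is_paired and r.is_read1]
        r2 = [r for r in grp if r.is_paired and r.is_read2]
        if (
            len(r1) == 1
            and len(r2) == 1
            and not r1[0].is_unmapped
            and not r2[0].is_unmapped
        ):
            a, b = r1[0], r2[0]
            ca, cb = _coord5(a), _coord5(b)
            pc = (ca, cb) if ca <= cb else (cb, ca)
            pair_items.append((pc, _score(a) + _score(b), (a.rank, b.rank)))
            frag_items.append((ca, _score(a), a.rank, True))
            frag_items.append((cb, _score(b), b.rank, True))
        else:
            for r in grp:
                if not r.is_unmapped:
                    frag_items.append((_coord5(r), _score(r), r.rank, False))

    marked = set()
    for i, (pc, sc, ranks) in enumerate(pair_items):
        for j, (qc, qs, qranks) in enumerate(pair_items):
            if i == j or qc != pc:
                continue
            if (qs, -min(qranks)) > (sc, -min(ranks)):
                marked.update(ranks)
                break
    pair_ends = {c for c, _s, _r, is_pair in frag_items if is_pair}
    for i, (c, sc, rank, is_pair) in enumerate(frag_items):
        if is_pair:
            continue
        if c in pair_ends:
            marked.add(rank)
            continue
        for j, (qc, qs, qrank, qpair) in enumerate(frag_items):
            if i == j or qpair or qc != c:
                continue
            if (qs, -qrank) > (sc, -rank):
                marked.add(rank)
                break
    return marked
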