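"""Synthetic coordinate-sorted paired-end alignment files with known truth.

The generator emulates the record-level features the collation and
duplicate-marking algorithms react to — mate gaps governed by depth,
template length and read length; planted PCR-duplicate clusters that are
exact coordinate clones with independently resampled base qualities;
split pairs (mates on different references); orphans (mate absent, flagged
mate-unmapped); unpaired single-end reads — while making no attempt at
sequence-level realism (no error model, no real reference, pure-match
CIGARs unless soft-clipping is requested).

Templates are placed uniformly on the reference; template lengths follow a
normal distribution truncated below at the read length.  The emitted
stream is coordinate-sorted and every read name appears in exactly one
truth row, so each downstream module can be tested against planted ground
truth without any external data.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .records import (
    FMATE_REVERSE,
    FMATE_UNMAPPED,
    FPAIRED,
    FPROPER,
    FREAD1,
    FREAD2,
    FREVERSE,
    AlignmentRecord,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def _revcomp(seq: str) -> str:
    return seq.encode().translate(_COMPLEMENT)[::-1].decode()


@dataclass
class SimProfile:
    """Study conditions for one simulated file.

    d, t_mean, l mirror the depth / template-length / read-length triple of
    the mate-gap model; default t_sd keeps templates comfortably above the
    read length.  Rates are fractions of templates assigned to each
    special category; duplicated templates get cluster sizes 1 + Poisson(dup_lambda).
    The seed fixes the full output.
    """

    genome_len: int = 100_000
    n_refs: int = 1
    d: float = 10.0
    t_mean: float = 300.0
    t_sd: float = 30.0
    l: int = 100
    dup_rate: float = 0.0
    dup_lambda: float = 1.0
    orphan_rate: float = 0.0
    split_rate: float = 0.0
    single_rate: float = 0.0
    clip_prob: float = 0.0
    clip_len: int = 5
    qual_lo: int = 20
    qual_hi: int = 41
    seed: int = 1
    name_prefix: str = "sim"

    def __post_init__(self):
        rates = (self.dup_rate, self.orphan_rate, self.split_rate, self.single_rate)
        if any(r < 0 or r > 1 for r in rates):
            raise ValueError("rates must lie in [0, 1]")
        if self.orphan_rate + self.split_rate + self.single_rate > 1:
            raise ValueError("special-case rates must sum to at most 1")
        if self.t_mean < self.l:
            raise ValueError("mean template length must be at least the read length")
        if self.split_rate > 0 and self.n_refs < 2:
            raise ValueError("split pairs require at least two references")

    @property
    def references(self) -> List[Tuple[str, int]]:
        return [(f"ref{i}", self.genome_len) for i in range(self.n_refs)]

    def n_templates(self) -> int:
        return int(round(self.d * self.genome_len * self.n_refs / (2 * self.l)))


@dataclass
class TruthRecord:
    """Planted truth for one template (one clone of a cluster)."""

    name: str
    category: str               # normal | orphan | split | single
    cluster_id: int             # founder template index; clones share it
    coord1: Optional[Tuple[int, int, int]]   # (ref_id, pos5, strand) of read1
    coord2: Optional[Tuple[int, int, int]]   # of read2; None if absent
    read1_seq: str = ""         # sequencing-orientation bases/quals, for
    read1_qual: str = ""        # round-trip checks; not serialized
    read2_seq: str = ""
    read2_qual: str = ""


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _random_qual(rng: np.random.Generator, n: int, lo: int, hi: int) -> str:
    return (rng.integers(lo, hi, n).astype(np.uint8) + 33).tobytes().decode()


def simulate_alignments(
    profile: SimProfile,
) -> Tuple[List[AlignmentRecord], List[TruthRecord]]:
    """Generate a coordinate-sorted record list and its truth table.

    Approximately d·genome_len·n_refs/(2l) templates are placed; ranks are
    assigned after coordinate sorting, so the records round-trip through
    the I/O layer unchanged.
    """
    rng = np.random.default_rng(profile.seed)
    l = profile.l
    records: List[AlignmentRecord] = []
    truth: List[TruthRecord] = []
    n_templates = profile.n_templates()

    for i in range(n_templates):
        u = rng.random()
        if u < profile.orphan_rate:
            category = "orphan"
        elif u < profile.orphan_rate + profile.split_rate:
            category = "split"
        elif u < profile.orphan_rate + profile.split_rate + profile.single_rate:
            category = "single"
        else:
            category = "normal"
        cluster = 1
        if category in ("normal", "single") and rng.random() < profile.dup_rate:
            cluster = 1 + int(rng.poisson(profile.dup_lambda))

        ref = int(rng.integers(0, profile.n_refs))
        t = int(round(rng.normal(profile.t_mean, profile.t_sd)))
        t = max(l, min(t, profile.genome_len))
        start = int(rng.integers(0, profile.genome_len - t + 1))
        read1_forward = bool(rng.integers(0, 2))

        for j in range(cluster):
            name = f"{profile.name_prefix}_{i:08d}" if j == 0 else f"{profile.name_prefix}_{i:08d}_d{j}"
            if category == "single":
                _emit_single(profile, rng, records, truth, name, i, ref, start, t)
            elif category == "orphan":
                _emit_orphan(profile, rng, records, truth, name, i, ref, start, t, read1_forward)
            elif category == "split":
                ref2 = int((ref + 1 + rng.integers(0, profile.n_refs - 1)) % profile.n_refs)
                pos2 = int(rng.integers(0, profile.genome_len - l + 1))
                _emit_split(profile, rng, records, truth, name, i, ref, start, ref2, pos2, read1_forward)
            else:
                _emit_pair(profile, rng, records, truth, name, i, ref, start, t, read1_forward)

    records.sort(key=lambda r: (r.ref_id, r.pos, r.name, r.flags))
    for rank, rec in enumerate(records):
        rec.rank = rank
    return records, truth


def _make_read(
    profile: SimProfile,
    rng: np.random.Generator,
    reverse: bool,
) -> Tuple[str, str, str, str, Tuple[Tuple[int, int], ...], int]:
    """Create one read: returns (orig_seq, orig_qual, stored_seq,
    stored_qual, cigar, pos_shift) where pos_shift adjusts the stored
    leftmost position for a leading soft clip."""
    l = profile.l
    orig_seq = _random_seq(rng, l)
    orig_qual = _random_qual(rng, l, profile.qual_lo, profile.qual_hi)
    if reverse:
        stored_seq, stored_qual = _revcomp(orig_seq), orig_qual[::-1]
    else:
        stored_seq, stored_qual = orig_seq, orig_qual
    cigar: Tuple[Tuple[int, int], ...] = ((0, l),)
    shift = 0
    if profile.clip_prob > 0 and rng.random() < profile.clip_prob:
        s = min(profile.clip_len, l - 1)
        if reverse:
            # clip at the 5' (right/trailing) end; unclipped 5' position unchanged
            cigar = ((0, l - s), (4, s))
        else:
            cigar = ((4, s), (0, l - s))
            shift = s
    return orig_seq, orig_qual, stored_seq, stored_qual, cigar, shift


def _emit_pair(profile, rng, records, truth, name, cluster_id, ref, start, t, read1_forward):
    l = profile.l
    pos_fwd = start
    pos_rev = start + t - l
    s1, q1, ss1, sq1, cig_f, sh_f = _make_read(profile, rng, reverse=False)
    s2, q2, ss2, sq2, cig_r, _ = _make_read(profile, rng, reverse=True)
    fwd_flags = FPAIRED | FPROPER | FMATE_REVERSE | (FREAD1 if read1_forward else FREAD2)
    rev_flags = FPAIRED | FPROPER | FREVERSE | (FREAD2 if read1_forward else FREAD1)
    fwd = AlignmentRecord(
        name=name, flags=fwd_flags, ref_id=ref, pos=pos_fwd + sh_f, mapq=60,
        cigar=cig_f, mate_ref_id=ref, mate_pos=pos_rev, tlen=t,
        seq=ss1, qual=sq1,
    )
    rev = AlignmentRecord(
        name=name, flags=rev_flags, ref_id=ref, pos=pos_rev, mapq=60,
        cigar=cig_r, mate_ref_id=ref, mate_pos=pos_fwd + sh_f, tlen=-t,
        seq=ss2, qual=sq2,
    )
    records.extend((fwd, rev))
    coord_fwd = (ref, start, 0)
    coord_rev = (ref, start + t - 1, 1)
    if read1_forward:
        truth.append(TruthRecord(name, "normal", cluster_id, coord_fwd, coord_rev,
                                 s1, q1, s2, q2))
    else:
        truth.append(TruthRecord(name, "normal", cluster_id, coord_rev, coord_fwd,
                                 s2, q2, s1, q1))


def _emit_orphan(profile, rng, records, truth, name, cluster_id, ref, start, t, read1_forward):
    # only one mate is emitted; it carries paired + mate-unmapped flags
    l = profile.l
    reverse = not read1_forward
    pos = start if not reverse else start + t - l
    s, q, ss, sq, cig, sh = _make_read(profile, rng, reverse=reverse)
    flags = FPAIRED | FMATE_UNMAPPED | FREAD1 | (FREVERSE if reverse else 0)
    rec = AlignmentRecord(
        name=name, flags=flags, ref_id=ref, pos=pos + (sh if not reverse else 0),
        mapq=60, cigar=cig, mate_ref_id=-1, mate_pos=-1, tlen=0, seq=ss, qual=sq,
    )
    records.append(rec)
    coord = (ref, start if not reverse else start + t - 1, int(reverse))
    truth.append(TruthRecord(name, "orphan", cluster_id, coord, None, s, q))


def _emit_split(profile, rng, records, truth, name, cluster_id, ref1, pos1, ref2, pos2, read1_forward):
    l = profile.l
    s1, q1, ss1, sq1, cig1, sh1 = _make_read(profile, rng, reverse=False)
    s2, q2, ss2, sq2, cig2, _ = _make_read(profile, rng, reverse=True)
    f1 = FPAIRED | FMATE_REVERSE | (FREAD1 if read1_forward else FREAD2)
    f2 = FPAIRED | FREVERSE | (FREAD2 if read1_forward else FREAD1)
    a = AlignmentRecord(name=name, flags=f1, ref_id=ref1, pos=pos1 + sh1, mapq=60,
                        cigar=cig1, mate_ref_id=ref2, mate_pos=pos2, tlen=0,
                        seq=ss1, qual=sq1)
    b = AlignmentRecord(name=name, flags=f2, ref_id=ref2, pos=pos2, mapq=60,
                        cigar=cig2, mate_ref_id=ref1, mate_pos=pos1 + sh1, tlen=0,
                        seq=ss2, qual=sq2)
    records.extend((a, b))
    c1 = (ref1, pos1, 0)
    c2 = (ref2, pos2 + l - 1, 1)
    if read1_forward:
        truth.append(TruthRecord(name, "split", cluster_id, c1, c2, s1, q1, s2, q2))
    else:
        truth.append(TruthRecord(name, "split", cluster_id, c2, c1, s2, q2, s1, q1))


def _emit_single(profile, rng, records, truth, name, cluster_id, ref, start, t):
    l = profile.l
    reverse = bool(rng.integers(0, 2))
    pos = start if not reverse else max(0, start + t - l)
    s, q, ss, sq, cig, sh = _make_read(profile, rng, reverse=reverse)
    flags = FREVERSE if reverse else 0
    rec = AlignmentRecord(name=name, flags=flags, ref_id=ref,
                          pos=pos + (sh if not reverse else 0), mapq=60,
                          cigar=cig, mate_ref_id=-1, mate_pos=-1, tlen=0,
                          seq=ss, qual=sq)
    records.append(rec)
    coord = (ref, pos if not reverse else pos + l - 1, int(reverse))
    truth.append(TruthRecord(name, "single", cluster_id, coord, None, s, q))


# ---------------------------------------------------------------------------

def empirical_mate_gap(records: Iterable[AlignmentRecord]) -> Tuple[float, float]:
    """Median and mean in-file record-count gap between mates.

    For every template with both mates present, mapped, and on the same
    reference, the gap is |rank2 - rank1| - 1.  Records must carry ranks.
    """
    ranks: Dict[str, List[int]] = {}
    for rec in records:
        if not rec.is_paired or rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        if rec.ref_id < 0 or rec.ref_id != rec.mate_ref_id:
            continue
        ranks.setdefault(rec.name, []).append(rec.rank)
    gaps = [abs(r[1] - r[0]) - 1 for r in ranks.values() if len(r) == 2]
    if not gaps:
        return float("nan"), float("nan")
    return float(statistics.median(gaps)), float(statistics.fmean(gaps))


# ---------------------------------------------------------------------------
# truth sidecar (plain TSV)

_TRUTH_HEADER = "name\tcategory\tcluster_id\tref1\tpos5_1\tstrand1\tref2\tpos5_2\tstrand2"


def write_truth(truth: Iterable[TruthRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_TRUTH_HEADER + "\n")
        for t in truth:
            c1 = t.coord1 if t.coord1 else ("", "", "")
            c2 = t.coord2 if t.coord2 else ("", "", "")
            fh.write(
                f"{t.name}\t{t.category}\t{t.cluster_id}\t"
                f"{c1[0]}\t{c1[1]}\t{c1[2]}\t{c2[0]}\t{c2[1]}\t{c2[2]}\n"
            )


def read_truth(path: str) -> List[TruthRecord]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != _TRUTH_HEADER.strip():
            raise ValueError(f"unrecognised truth file header in {path}")
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            c1 = (int(cols[3]), int(cols[4]), int(cols[5])) if cols[3] != "" else None
            c2 = (int(cols[6]), int(cols[7]), int(cols[8])) if cols[6] != "" else None
            out.append(TruthRecord(cols[0], cols[1], int(cols[2]), c1, c2))
    return out
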