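"""Alignment record model plus SAM/BAM readers/writers and a compact byte encoding.

Alignments live in two shapes here.  :class:`AlignmentRecord` is a light
dataclass carrying exactly the fields the collation and duplicate-marking
algorithms look at (name, flag bits, coordinates, CIGAR, sequence,
qualities, source rank).  Inside the fixed-size collation buffers the same
record is held as a flat byte string produced by :func:`serialize`; the
encoding stores the read name first so the pairing key — and the few bytes
needed as a sort key — can be read without decoding the whole entry.

File access goes through pysam/htslib; SAM and BAM are auto-detected on
read, and the dialect written is chosen from the output file extension.
Internal coordinates are 0-based (BAM convention); SAM text conversion is
handled by htslib.  Optional tags are carried as an opaque tab-separated
text blob and never interpreted.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, Tuple, Union

import pysam

# SAM flag bits
FPAIRED = 0x1
FPROPER = 0x2
FUNMAPPED = 0x4
FMATE_UNMAPPED = 0x8
FREVERSE = 0x10
FMATE_REVERSE = 0x20
FREAD1 = 0x40
FREAD2 = 0x80
FSECONDARY = 0x100
FQCFAIL = 0x200
FDUP = 0x400
FSUPPLEMENTARY = 0x800

#: CIGAR operation characters indexed by BAM op code.
CIGAR_OPS = "MIDNSHP=X"

#: Op codes that consume reference bases (M, D, N, =, X).
_REF_CONSUMING = frozenset((0, 2, 3, 7, 8))


class BamIOError(RuntimeError):
    """Raised for unreadable, malformed or truncated alignment files."""


@dataclass
class AlignmentRecord:
    """One SAM/BAM alignment line.

    ``rank`` is the 0-based line number of the record in the source file
    (-1 when unassigned); it is the identity used by duplicate marking to
    address records across the two passes.
    """

    name: str
    flags: int = 0
    ref_id: int = -1
    pos: int = -1
    mapq: int = 0
    cigar: Tuple[Tuple[int, int], ...] = ()
    mate_ref_id: int = -1
    mate_pos: int = -1
    tlen: int = 0
    seq: str = ""           # "" encodes the SAM "*" absent-sequence marker
    qual: str = ""          # Phred+33 text; "" when absent
    tags: str = ""          # opaque tab-separated optional fields
    rank: int = -1

    # -- flag helpers -------------------------------------------------
    @property
    def is_paired(self) -> bool:
        return bool(self.flags & FPAIRED)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flags & FUNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flags & FREVERSE)

    @property
    def is_read1(self) -> bool:
        return bool(self.flags & FREAD1)

    @property
    def is_read2(self) -> bool:
        return bool(self.flags & FREAD2)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flags & FSECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flags & FSUPPLEMENTARY)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flags & FDUP)

    @property
    def has_seq(self) -> bool:
        return self.seq != ""

    def reference_span(self) -> int:
        """Number of reference bases covered by the alignment."""
        return sum(n for op, n in self.cigar if op in _REF_CONSUMING)

    def cigar_string(self) -> str:
        if not self.cigar:
            return "*"
        return "".join(f"{n}{CIGAR_OPS[op]}" for op, n in self.cigar)


def parse_cigar(text: str) -> Tuple[Tuple[int, int], ...]:
    """Parse a SAM CIGAR string into (op-code, length) tuples."""
    if text == "*" or text == "":
        return ()
    out = []
    n = 0
    for ch in text:
        if ch.isdigit():
            n = n * 10 + ord(ch) - 48
        else:
            op = CIGAR_OPS.find(ch)
            if op < 0 or n == 0:
                raise BamIOError(f"malformed CIGAR string: {text!r}")
            out.append((op, n))
            n = 0
    if n:
        raise BamIOError(f"malformed CIGAR string: {text!r}")
    return tuple(out)


# ---------------------------------------------------------------------------
# headers

HeaderLike = Union[pysam.AlignmentHeader, dict, Sequence[Tuple[str, int]]]


def as_header(header: HeaderLike) -> pysam.AlignmentHeader:
    """Normalise a header given as pysam header, dict, or (name, length) list."""
    if isinstance(header, pysam.AlignmentHeader):
        return header
    if isinstance(header, dict):
        return pysam.AlignmentHeader.from_dict(header)
    names = [n for n, _ in header]
    lengths = [ln for _, ln in header]
    return pysam.AlignmentHeader.from_references(names, lengths)


def read_header(path: str) -> pysam.AlignmentHeader:
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        return fh.header


# ---------------------------------------------------------------------------
# reading / writing

def _record_from_segment(seg: pysam.AlignedSegment, rank: int) -> AlignmentRecord:
    cols = seg.to_string().split("\t", 11)
    seq = cols[9] if cols[9] != "*" else ""
    qual = cols[10] if cols[10] != "*" else ""
    tags = cols[11] if len(cols) > 11 else ""
    cig = tuple((op, ln) for op, ln in (seg.cigartuples or ()))
    return AlignmentRecord(
        name=seg.query_name or "",
        flags=seg.flag,
        ref_id=seg.reference_id,
        pos=seg.reference_start,
        mapq=seg.mapping_quality,
        cigar=cig,
        mate_ref_id=seg.next_reference_id,
        mate_pos=seg.next_reference_start,
        tlen=seg.template_length,
        seq=seq,
        qual=qual,
        tags=tags,
        rank=rank,
    )


def to_sam_line(rec: AlignmentRecord, ref_names: Sequence[str]) -> str:
    """Render a record as one SAM text line (1-based coordinates)."""
    rname = ref_names[rec.ref_id] if rec.ref_id >= 0 else "*"
    rnext = ref_names[rec.mate_ref_id] if rec.mate_ref_id >= 0 else "*"
    if rnext != "*" and rnext == rname:
        rnext = "="
    cols = [
        rec.name,
        str(rec.flags),
        rname,
        str(rec.pos + 1 if rec.pos >= 0 else 0),
        str(rec.mapq),
        rec.cigar_string(),
        rnext,
        str(rec.mate_pos + 1 if rec.mate_pos >= 0 else 0),
        str(rec.tlen),
        rec.seq if rec.seq else "*",
        rec.qual if rec.qual else "*",
    ]
    if rec.tags:
        cols.append(rec.tags)
    return "\t".join(cols)


def open_alignments(path: str, assign_ranks: bool = True):
    """Open a SAM/BAM file; return ``(header, record iterator)``.

    The iterator yields :class:`AlignmentRecord` in file order.  With
    ``assign_ranks`` the records get ranks 0, 1, 2, … in encounter order.
    """
    try:
        fh = pysam.AlignmentFile(str(path), check_sq=False)
    except (OSError, ValueError) as exc:
        raise BamIOError(f"cannot open alignment file {path}: {exc}") from exc

    def gen():
        idx = 0
        try:
            with fh:
                for seg in fh.fetch(until_eof=True):
                    yield _record_from_segment(seg, idx if assign_ranks else -1)
                    idx += 1
        except (OSError, ValueError) as exc:
            raise BamIOError(f"error reading {path} at record {idx}: {exc}") from exc

    return fh.header, gen()


def read_alignments(path: str, assign_ranks: bool = True) -> Iterator[AlignmentRecord]:
    """Stream records from a SAM or BAM file (auto-detected)."""
    _, it = open_alignments(path, assign_ranks=assign_ranks)
    return it


def write_alignments(
    records: Iterable[AlignmentRecord],
    path: str,
    header: HeaderLike,
    level: Optional[int] = None,
) -> int:
    """Write records as SAM or BAM (chosen by extension; default SAM).

    Returns the number of records written.  Every mapped record's ref_id
    must be valid in ``header``.
    """
    hdr = as_header(header)
    ref_names = list(hdr.references)
    path = str(path)
    if path.endswith(".bam"):
        mode = "wb" + (str(level) if level is not None else "")
    else:
        mode = "wh"
    count = 0
    with pysam.AlignmentFile(path, mode, header=hdr) as out:
        for rec in records:
            if rec.ref_id >= len(ref_names) or rec.mate_ref_id >= len(ref_names):
                raise BamIOError(
                    f"record {rec.name!r}: reference id out of range for header"
                )
            seg = pysam.AlignedSegment.fromstring(to_sam_line(rec, ref_names), hdr)
            out.write(seg)
            count += 1
    return count


# ---------------------------------------------------------------------------
# compact serialized form
#
# Layout (little endian), name first so it is extractable cheaply:
#   u16 name_len | name | u16 flags | i32 ref_id | i64 pos | u8 mapq
#   | u16 n_cigar | n_cigar * (u8 op, u32 len)
#   | i32 mate_ref_id | i64 mate_pos | i64 tlen
#   | u32 seq_len | seq | u32 qual_len | qual | u32 tags_len | tags
#   | i64 rank

SerializedRecord = bytes

_NAME = struct.Struct("<H")
_FIXED1 = struct.Struct("<HiqBH")
_CIG = struct.Struct("<BI")
_FIXED2 = struct.Struct("<iqq")
_U32 = struct.Struct("<I")
_RANK = struct.Struct("<q")


def serialize(rec: AlignmentRecord) -> SerializedRecord:
    name_b = rec.name.encode()
    parts = [
        _NAME.pack(len(name_b)),
        name_b,
        _FIXED1.pack(rec.flags, rec.ref_id, rec.pos, rec.mapq, len(rec.cigar)),
    ]
    for op, n in rec.cigar:
        parts.append(_CIG.pack(op, n))
    parts.append(_FIXED2.pack(rec.mate_ref_id, rec.mate_pos, rec.tlen))
    for text in (rec.seq, rec.qual, rec.tags):
        b = text.encode()
        parts.append(_U32.pack(len(b)))
        parts.append(b)
    parts.append(_RANK.pack(rec.rank))
    return b"".join(parts)


def deserialize(buf: SerializedRecord) -> AlignmentRecord:
    (name_len,) = _NAME.unpack_from(buf, 0)
    off = 2
    name = buf[off : off + name_len].decode()
    off += name_len
    flags, ref_id, pos, mapq, n_cigar = _FIXED1.unpack_from(buf, off)
    off += _FIXED1.size
    cig = []
    for _ in range(n_cigar):
        cig.append(_CIG.unpack_from(buf, off))
        off += _CIG.size
    mate_ref_id, mate_pos, tlen = _FIXED2.unpack_from(buf, off)
    off += _FIXED2.size
    texts = []
    for _ in range(3):
        (ln,) = _U32.unpack_from(buf, off)
        off += 4
        texts.append(buf[off : off + ln].decode())
        off += ln
    (rank,) = _RANK.unpack_from(buf, off)
    return AlignmentRecord(
        name=name,
        flags=flags,
        ref_id=ref_id,
        pos=pos,
        mapq=mapq,
        cigar=tuple(cig),
        mate_ref_id=mate_ref_id,
        mate_pos=mate_pos,
        tlen=tlen,
        seq=texts[0],
        qual=texts[1],
        tags=texts[2],
        rank=rank,
    )


def extract_name(buf: SerializedRecord) -> str:
    """Read name of a serialized record without full deserialization."""
    (name_len,) = _NAME.unpack_from(buf, 0)
    return buf[2 : 2 + name_len].decode()


def extract_sort_key(buf: SerializedRecord) -> Tuple[bytes, int, int]:
    """Canonical collation key of a serialized record, decoded cheaply.

    Keys order bytewise-lexicographically by name, then read1 before
    read2, then by source rank.
    """
    (name_len,) = _NAME.unpack_from(buf, 0)
    name_b = bytes(buf[2 : 2 + name_len])
    (flags,) = struct.unpack_from("<H", buf, 2 + name_len)
    (rank,) = _RANK.unpack_from(buf, len(buf) - 8)
    return (name_b, (flags >> 7) & 1, rank)
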