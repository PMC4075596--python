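"""BAM/SAM to FastQ conversion on top of the name collation engine.

Mapped reverse-strand records store the reverse complement of the
sequenced bases, so conversion restores the original sequencing
orientation (reverse complement the bases, reverse the qualities) before
writing.  Pairs are written index-aligned to two files; orphans (paired
reads whose mate never appears) and unpaired singles go to their own
files.  Secondary and supplementary alignments are skipped — they would
duplicate the primary record of the same read — as are records without
stored sequence, which FastQ cannot represent.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Dict, Optional

from .collate import Category, CollationConfig, CollationStats, collate
from .records import AlignmentRecord, read_alignments

# IUPAC nucleotide complements, upper and lower case
_COMP = "ACGTURYSWKMBDHVN"
_COMP_TO = "TGCAAYRSWMKVHDBN"
COMPLEMENT = bytes.maketrans(
    (_COMP + _COMP.lower()).encode(), (_COMP_TO + _COMP_TO.lower()).encode()
)


@dataclass
class FastqRecord:
    """One 4-line FastQ entry (Phred+33)."""

    id: str
    seq: str
    qual: str


def reverse_complement(seq: str) -> str:
    return seq.encode().translate(COMPLEMENT)[::-1].decode()


def to_original_orientation(rec: AlignmentRecord) -> tuple:
    """Bases and qualities of a record in sequencing orientation.

    Reverse-strand records come back reverse-complemented with the
    quality string reversed; forward-strand records are unchanged.
    """
    if rec.is_reverse:
        return reverse_complement(rec.seq), rec.qual[::-1]
    return rec.seq, rec.qual


def _open_out(path: str, gzip_out: bool):
    if gzip_out:
        return gzip.open(path, "wt")
    return open(path, "w")


class _FastqWriter:
    def __init__(self, path: str, gzip_out: bool, suffix: str = ""):
        self.fh = _open_out(path, gzip_out)
        self.suffix = suffix
        self.count = 0

    def write(self, rec: AlignmentRecord) -> None:
        seq, qual = to_original_orientation(rec)
        if not qual:
            qual = "!" * len(seq)
        self.fh.write(f"@{rec.name}{self.suffix}\n{seq}\n+\n{qual}\n")
        self.count += 1

    def close(self):
        self.fh.close()


def bam_to_fastq(
    input_path: str,
    pair1: str,
    pair2: str,
    orphans: str,
    singles: str,
    config: Optional[CollationConfig] = None,
    gzip_out: bool = False,
    mate_suffix: bool = False,
) -> Dict[str, int]:
    """Convert an alignment file to FastQ via name collation.

    Returns counts per category plus the number of records skipped for
    having no stored sequence or being secondary/supplementary.  The four
    output files are always created (empty if unused); with ``gzip_out``
    each is a gzip member stream.
    """
    outputs, stats = collate(read_alignments(input_path), config)
    w1 = _FastqWriter(pair1, gzip_out, "/1" if mate_suffix else "")
    w2 = _FastqWriter(pair2, gzip_out, "/2" if mate_suffix else "")
    wo = _FastqWriter(orphans, gzip_out)
    ws = _FastqWriter(singles, gzip_out)
    skipped_no_seq = 0
    skipped_secondary = 0
    try:
        for out in outputs:
            if out.category is Category.PAIR:
                a, b = out.first, out.second
                if not a.has_seq or not b.has_seq:
                    skipped_no_seq += (not a.has_seq) + (not b.has_seq)
                    # an unrepresentable mate demotes the survivor to orphan
                    for r in (a, b):
                        if r.has_seq:
                            wo.write(r)
                    continue
                w1.write(a)
                w2.write(b)
            else:
                rec = out.first
                if rec.is_secondary or rec.is_supplementary:
                    skipped_secondary += 1
                    continue
                if not rec.has_seq:
                    skipped_no_seq += 1
                    continue
                (wo if out.category is Category.ORPHAN else ws).write(rec)
    finally:
        for w in (w1, w2, wo, ws):
            w.close()
    return {
        "pairs": w1.count,
        "orphans": wo.count,
        "singles": ws.count,
        "skipped_no_seq": skipped_no_seq,
        "skipped_secondary": skipped_secondary,
        "records": stats.n,
        "stats": stats,
    }
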