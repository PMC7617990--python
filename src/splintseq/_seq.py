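"""Small sequence utilities shared across modules (FASTQ I/O via Biopython)."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHNacgtrykmbvdhn", "TGCAYRMKVBHDNtgcayrmkvbhdn")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware for the codes used in oligo specs)."""
    return seq.translate(_COMPLEMENT)[::-1]


def open_maybe_gzip(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, quality) from a FASTQ file (optionally gzipped)."""
    with open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            yield rec.id, str(rec.seq), qual


def write_fastq(records: Iterable[tuple[str, str, str]], path) -> None:
    with open_maybe_gzip(path, "wt") as fh:
        for rid, seq, qual in records:
            rec = SeqRecord(Seq(seq), id=rid, description="")
            rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
            SeqIO.write(rec, fh, "fastq")
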