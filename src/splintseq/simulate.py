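"""Synthetic long-read library generator with a ground-truth ledger.

Every downstream stage (QC, demultiplexing, UMI grouping, consensus,
counting) is testable against libraries produced here.  A simulated read
mimics the splint-ligated cDNA structure::

    [bottom splint: R2 + barcode + constant + UMI + constant + poly(T)]
    [transcript body]
    [TSO adaptor]

possibly reverse-complemented (strands are equally likely), truncated from
the TSO side (mimicking RNA degradation), and corrupted with independent
per-base substitution/insertion/deletion errors.  A fraction of reads are
concatemers carrying a second library molecule and hence an internal
adaptor.  Each molecule draws its UMI once; PCR duplicates share it
verbatim before errors.  The ledger records, per read: cell barcode,
molecule, duplicate index, true UMI, transcript, strand, and concatemer
status.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._seq import revcomp, write_fastq
from .oligo import TSO_DNA, SplintDesign, build_bottom_splint, sample_umis, synthetic_barcode_set

_BASE_TO_IDX = np.full(256, 0, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_IDX[_b] = _i
_IDX_TO_BYTE = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class TranscriptRecord:
    transcript_id: str
    sequence: str
    feature_class: str  # "gene" | "TE"
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class TranscriptPool:
    """A small transcript pool standing in for a transcriptome reference."""

    records: list[TranscriptRecord]

    def __post_init__(self):
        ids = [r.transcript_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise SimulationError("transcript ids must be unique")
        if any(not r.sequence for r in self.records):
            raise SimulationError("transcript sequences must be non-empty")

    def __len__(self):
        return len(self.records)

    def by_id(self, tid: str) -> TranscriptRecord:
        return next(r for r in self.records if r.transcript_id == tid)

    def loci_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "feature_id": r.transcript_id,
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "strand": r.strand,
                    "feature_class": r.feature_class,
                }
                for r in self.records
            ]
        )

    def write(self, fasta_path, bed_path) -> None:
        with open(fasta_path, "w") as fa:
            for r in self.records:
                fa.write(f">{r.transcript_id}\n{r.sequence}\n")
        with open(bed_path, "w") as bed:
            for r in self.records:
                bed.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.transcript_id}\t0\t{r.strand}\n"
                )

    @classmethod
    def read(cls, fasta_path, bed_path) -> "TranscriptPool":
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
        bed = pd.read_csv(
            bed_path,
            sep="\t",
            names=["chrom", "start", "end", "name", "score", "strand"],
        )
        records = [
            TranscriptRecord(
                transcript_id=row["name"],
                sequence=seqs[row["name"]],
                feature_class="TE" if str(row["name"]).startswith("TE") else "gene",
                chrom=row["chrom"],
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
            )
            for _, row in bed.iterrows()
        ]
        return cls(records)


def make_toy_pool(
    n_genes: int = 7,
    n_tes: int = 3,
    min_len: int = 500,
    max_len: int = 1500,
    seed: int = 0,
) -> TranscriptPool:
    """Random transcript pool on a toy chromosome with non-overlapping loci."""
    rng = np.random.default_rng(seed)
    records = []
    cursor = 1000
    for i in range(n_genes + n_tes):
        is_te = i >= n_genes
        length = int(rng.integers(min_len, max_len + 1))
        seq = "".join(np.array(list("ACGT"))[rng.integers(4, size=length)])
        tid = f"TE{i - n_genes + 1}" if is_te else f"gene{i + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        records.append(
            TranscriptRecord(tid, seq, "TE" if is_te else "gene",
                             "chrS", cursor, cursor + length, strand)
        )
        cursor += length + 500
    return TranscriptPool(records)


@dataclass
class SimConfig:
    """Study conditions for one simulated library.

    Defaults follow the protocol's stated conditions: 5 PCR duplicates per
    molecule, 50-nt R/Y/N UMIs (via the designs' UmiSpec), equally likely
    strands, and nanopore-like error rates (substitution 5%, insertion 1%,
    deletion 1%).  The seed is mandatory.
    """

    seed: int
    n_cells: int = 4
    molecules_per_cell: int = 10
    pcr_duplicates: int = 5
    substitution: float = 0.05
    insertion: float = 0.01
    deletion: float = 0.01
    truncation_prob: float = 0.05
    max_truncation_fraction: float = 0.5
    strand_flip_prob: float = 0.5
    concatemer_fraction: float = 0.0
    polyt_length: int = 25

    def __post_init__(self):
        for name in (
            "substitution", "insertion", "deletion", "truncation_prob",
            "max_truncation_fraction", "strand_flip_prob", "concatemer_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        if self.n_cells < 1 or self.molecules_per_cell < 1 or self.pcr_duplicates < 1:
            raise SimulationError("counts must be >= 1")


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    quality: str
    truth: dict = field(default_factory=dict)


def _inject(seq: str, sub: float, ins: float, dele: float,
            rng: np.random.Generator) -> str:
    """Independent per-base substitution/insertion/deletion errors."""
    if not seq or (sub == 0 and ins == 0 and dele == 0):
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    idx = _BASE_TO_IDX[arr]
    n = len(arr)
    keep = rng.random(n) >= dele
    subm = rng.random(n) < sub
    # substituted bases always change (shift 1..3 in base index, mod 4)
    idx = np.where(subm, (idx + rng.integers(1, 4, size=n)) % 4, idx)
    insm = rng.random(n) < ins
    ins_bases = rng.integers(0, 4, size=n)
    pair = np.full((n, 2), -1, dtype=np.int64)
    pair[keep, 0] = idx[keep]
    pair[insm, 1] = ins_bases[insm]
    flat = pair.ravel()
    flat = flat[flat >= 0]
    return _IDX_TO_BYTE[flat].tobytes().decode()


def inject_errors(sequence: str, rates: tuple[float, float, float], seed: int) -> str:
    """Mutate ``sequence`` with (substitution, insertion, deletion) rates.

    Deterministic under ``seed``; rate 0 on all channels is the identity.
    """
    sub, ins, dele = rates
    for v in rates:
        if not 0.0 <= v <= 1.0:
            raise SimulationError(f"rates must be in [0, 1], got {rates}")
    return _inject(sequence, sub, ins, dele, np.random.default_rng(seed))


def _phred_char(total_rate: float) -> str:
    q = int(min(40, round(-10 * np.log10(max(total_rate, 1e-4)))))
    return chr(33 + q)


def make_concatemer(reads: list[SimulatedRead]) -> SimulatedRead:
    """Join >=2 reads into one read with internal adaptor junctions."""
    if len(reads) < 2:
        raise SimulationError("a concatemer needs at least 2 reads")
    seq = "".join(r.sequence for r in reads)
    qual = "".join(r.quality for r in reads)
    truth = dict(reads[0].truth)
    truth["is_concatemer"] = True
    truth["concat_sources"] = ";".join(r.truth.get("molecule_id", r.read_id) for r in reads)
    return SimulatedRead(reads[0].read_id + "+concat", seq, qual, truth)


def simulate_library(
    config: SimConfig,
    pool: TranscriptPool,
    designs: list[SplintDesign] | None = None,
) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Simulate a library; returns (reads, ledger).

    Every emitted read has exactly one ledger row.  Concatemeric reads carry
    a copy of another read of the same library appended at their 3' end, so
    the per-cell molecule bookkeeping is unchanged and the flagged fraction
    is Bernoulli(config.concatemer_fraction) per read.
    """
    if len(pool) == 0:
        raise SimulationError("transcript pool is empty")
    if designs is None:
        designs = synthetic_barcode_set(config.n_cells)
    if len(designs) < config.n_cells:
        raise SimulationError("need at least n_cells barcode designs")
    designs = designs[: config.n_cells]
    rng = np.random.default_rng(config.seed)
    qchar = _phred_char(config.substitution + config.insertion + config.deletion)

    reads: list[SimulatedRead] = []
    rows: list[dict] = []
    counter = 0
    for ci, design in enumerate(designs):
        design = dataclasses.replace(design, dt_tail_length=config.polyt_length)
        umis = sample_umis(design.umi_spec, config.molecules_per_cell, rng)
        for mi in range(config.molecules_per_cell):
            molecule_id = f"{design.barcode_id}:m{mi}"
            tr = pool.records[rng.integers(len(pool))]
            splint, _ = build_bottom_splint(design, umis[mi])
            template = splint + tr.sequence + TSO_DNA
            for di in range(config.pcr_duplicates):
                seq = template
                if rng.random() < config.truncation_prob:
                    cut = int(rng.random() * config.max_truncation_fraction * len(seq))
                    if cut:
                        seq = seq[:-cut]  # degrade from the TSO (far) end
                seq = _inject(seq, config.substitution, config.insertion,
                              config.deletion, rng)
                strand = "-" if rng.random() < config.strand_flip_prob else "+"
                if strand == "-":
                    seq = revcomp(seq)
                rid = f"read{counter:06d}"
                counter += 1
                truth = {
                    "read_id": rid,
                    "barcode_id": design.barcode_id,
                    "molecule_id": molecule_id,
                    "duplicate_index": di,
                    "umi": umis[mi],
                    "transcript_id": tr.transcript_id,
                    "strand": strand,
                    "is_concatemer": False,
                    "concat_sources": "",
                }
                reads.append(SimulatedRead(rid, seq, qchar * len(seq), truth))

    # concatemer decoration: per-read Bernoulli; partner copied from library
    if config.concatemer_fraction > 0 and len(reads) >= 2:
        for i, r in enumerate(reads):
            if rng.random() < config.concatemer_fraction:
                j = int(rng.integers(len(reads) - 1))
                if j >= i:
                    j += 1
                partner = reads[j]
                r.sequence = r.sequence + partner.sequence
                r.quality = r.quality + partner.quality
                r.truth["is_concatemer"] = True
                r.truth["concat_sources"] = (
                    f"{r.truth['molecule_id']};{partner.truth['molecule_id']}"
                )

    for r in reads:
        row = dict(r.truth)
        row["read_id"] = r.read_id
        row["length"] = len(r.sequence)
        rows.append(row)
    ledger = pd.DataFrame(rows)
    return reads, ledger


def simulate_umi_grouping(
    n_molecules: int,
    duplicates: int = 5,
    umi_length: int = 50,
    seed: int = 0,
    n_features: int = 20,
    substitution: float = 0.05,
    insertion: float = 0.01,
    deletion: float = 0.01,
    pattern: str = "NRY",
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """UMI-level grouping simulation (no read bodies).

    Each molecule draws one R/Y/N UMI and a feature pre-group; every PCR
    duplicate observes an independently error-corrupted copy of that UMI.
    Returns (bins keyed by feature holding (read_id, observed_umi), ledger
    with read_id → molecule_id).  This is the harness behind the
    UMI-length / Levenshtein-threshold design comparisons.
    """
    from .oligo import UmiSpec

    rng = np.random.default_rng(seed)
    spec = UmiSpec(length=umi_length, pattern=pattern)
    umis = sample_umis(spec, n_molecules, rng)
    feats = rng.integers(n_features, size=n_molecules)
    bins: dict[str, list[tuple[str, str]]] = {}
    rows = []
    rid = 0
    for mi in range(n_molecules):
        for di in range(duplicates):
            obs = _inject(umis[mi], substitution, insertion, deletion, rng)
            name = f"r{rid:06d}"
            rid += 1
            bins.setdefault(f"f{feats[mi]}", []).append((name, obs))
            rows.append({"read_id": name, "molecule_id": f"m{mi}",
                         "umi": umis[mi], "feature_id": f"f{feats[mi]}",
                         "duplicate_index": di})
    return bins, pd.DataFrame(rows)


def write_library(reads: list[SimulatedRead], ledger: pd.DataFrame,
                  fastq_path, ledger_path) -> None:
    write_fastq(((r.read_id, r.sequence, r.quality) for r in reads), fastq_path)
    ledger.to_csv(ledger_path, sep="\t", index=False)


def read_ledger(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)
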