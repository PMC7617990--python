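"""Splint-oligo and UMI design.

The library adapter used here is a partially double-stranded "splint" oligo.
Its bottom strand carries, 5'→3': a Nextera R2 sequencing handle, a per-cell
barcode, a short constant region, a long UMI built on a cyclic R/Y/N pattern
(purine / pyrimidine / any base), a second constant region, and an oligo-dT
tail.  The top strand anneals to the post-UMI constant region and ends in an
inverted dT that blocks exonuclease degradation.

The R/Y/N pattern is the point of the design: because an R position can never
match a Y position, homopolymer runs inside the UMI body are bounded at two
bases, which sidesteps the weakness of nanopore basecalling on homopolymers.
Long UMIs (default 50 nt) shrink the chance that two cDNA molecules draw the
same tag and allow permissive Levenshtein grouping thresholds downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np

from ._seq import revcomp

#: Base classes of the UMI pattern alphabet.
CLASS_BASES = {"R": "AG", "Y": "CT", "N": "ACGT"}

# Published oligo sequences of the splint architecture.
NEXTERA_R1 = "CGTCGGCAGCGTCAGATGTGTATAAGAGACAG"
NEXTERA_R2 = "GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG"
CONSTANT_PRE_UMI = "AGTGGTATC"
TOP_SPLINT = "TAGCCGGATACCCTGCGGTGCGCTCGAACCCGCTACGCCATGTAAAACGACGGCCAGT"
#: Post-UMI constant region of the bottom splint; equals revcomp(TOP_SPLINT),
#: the annealing interface between the two splint strands.
CONSTANT_POST_UMI = revcomp(TOP_SPLINT)
#: DNA portion of the template-switch oligo (riboG tail and 3' amine omitted).
TSO_DNA = "TCGTCGGCAGCGTCAGATGTGTATAAGAGACAGGG"


class OligoConfigError(ValueError):
    """Raised for invalid UMI/splint configuration."""


@dataclass(frozen=True)
class UmiSpec:
    """A cyclic R/Y/N UMI pattern.

    Parameters
    ----------
    length : int
        UMI length in nt (default 50).  The printed bottom splint shows 17
        N-R-Y triplets (51 nt); the accompanying text states 50 nt, so the
        length is a free parameter here.
    pattern : str
        Cyclic pattern over {R, Y, N}; position ``i`` uses
        ``pattern[i % len(pattern)]``.  Default "NRY" (N-first, matching the
        printed splint context "...TATCNRYN...").
    """

    length: int = 50
    pattern: str = "NRY"

    def __post_init__(self):
        if self.length < 1:
            raise OligoConfigError(f"UMI length must be >= 1, got {self.length}")
        bad = set(self.pattern) - set(CLASS_BASES)
        if bad or not self.pattern:
            raise OligoConfigError(f"invalid pattern symbols: {sorted(bad)!r}")

    def symbol_at(self, i: int) -> str:
        return self.pattern[i % len(self.pattern)]

    def symbols(self) -> str:
        return "".join(self.symbol_at(i) for i in range(self.length))

    def space_size(self) -> int:
        """Number of distinct UMIs admitted by the pattern."""
        k = 1
        for sym in self.symbols():
            k *= len(CLASS_BASES[sym])
        return k

    def matches(self, umi: str) -> bool:
        return len(umi) == self.length and all(
            b in CLASS_BASES[self.symbol_at(i)] for i, b in enumerate(umi)
        )


def generate_umi(spec: UmiSpec, seed: int) -> str:
    """Sample one UMI from ``spec``; identical seeds give identical strings."""
    rng = np.random.default_rng(seed)
    return "".join(
        CLASS_BASES[spec.symbol_at(i)][rng.integers(len(CLASS_BASES[spec.symbol_at(i)]))]
        for i in range(spec.length)
    )


def sample_umis(spec: UmiSpec, n: int, rng: np.random.Generator) -> list[str]:
    """Vectorised sampling of ``n`` UMIs from an existing generator."""
    syms = spec.symbols()
    cols = []
    for sym in syms:
        bases = CLASS_BASES[sym]
        cols.append(np.array(list(bases))[rng.integers(len(bases), size=n)])
    mat = np.stack(cols, axis=1)
    return ["".join(row) for row in mat]


def umi_collision_probability(spec: UmiSpec, n_molecules: int) -> float:
    """Birthday-bound estimate that >=2 of ``n_molecules`` draw the same UMI.

    Uses 1 - exp(-n(n-1) / 2K) with K the UMI-space size; monotone
    increasing in n and decreasing in UMI length.
    """
    if n_molecules < 0:
        raise ValueError("n_molecules must be >= 0")
    if n_molecules < 2:
        return 0.0
    k = spec.space_size()
    return 1.0 - math.exp(-n_molecules * (n_molecules - 1) / (2.0 * k))


@dataclass(frozen=True)
class SplintDesign:
    """One barcode's splint architecture (bottom + top strand)."""

    barcode_id: str
    barcode_seq: str
    nextera_r2: str = NEXTERA_R2
    constant_pre_umi: str = CONSTANT_PRE_UMI
    umi_spec: UmiSpec = field(default_factory=UmiSpec)
    constant_post_umi: str = CONSTANT_POST_UMI
    dt_tail_length: int = 15
    top_splint_seq: str = TOP_SPLINT
    top_splint_inverted_dt: bool = True

    def __post_init__(self):
        if self.dt_tail_length < 0:
            raise OligoConfigError("dt_tail_length must be >= 0")
        if self.barcode_seq and self.umi_spec.length and not (
            self.constant_pre_umi
        ):
            raise OligoConfigError(
                "barcode and UMI must be separated by a non-empty constant region"
            )


def build_bottom_splint(
    design: SplintDesign, umi: str
) -> tuple[str, dict[str, tuple[int, int]]]:
    """Assemble the bottom splint and return (sequence, segment coordinates).

    Segments appear 5'→3' as nextera_r2, barcode, constant_pre_umi, umi,
    constant_post_umi, dt_tail.  Coordinates are 0-based half-open on the
    returned sequence, so the UMI is recoverable by slicing.
    """
    if not design.umi_spec.matches(umi):
        raise OligoConfigError(
            f"UMI {umi!r} violates the {design.umi_spec.pattern} pattern "
            f"(length {design.umi_spec.length})"
        )
    segments = [
        ("nextera_r2", design.nextera_r2),
        ("barcode", design.barcode_seq),
        ("constant_pre_umi", design.constant_pre_umi),
        ("umi", umi),
        ("constant_post_umi", design.constant_post_umi),
        ("dt_tail", "T" * design.dt_tail_length),
    ]
    coords: dict[str, tuple[int, int]] = {}
    pos = 0
    parts = []
    for name, seq in segments:
        coords[name] = (pos, pos + len(seq))
        parts.append(seq)
        pos += len(seq)
    return "".join(parts), coords


def synthetic_barcode_set(
    n: int = 96, length: int = 24, min_distance: int = 8, seed: int = 2024
) -> list[SplintDesign]:
    """Generate a synthetic, well-separated barcode panel.

    This is a stand-in for a commercial 96-barcode panel (whose sequences are
    proprietary and not bundled): random ``length``-mers are accepted greedily
    only if their edit distance to every accepted barcode is at least
    ``min_distance``.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    alphabet = np.array(list("ACGT"))
    while len(accepted) < n:
        cand = "".join(alphabet[rng.integers(4, size=length)])
        if all(
            edlib.align(cand, bc, k=min_distance - 1)["editDistance"] == -1
            for bc in accepted
        ):
            accepted.append(cand)
    return [
        SplintDesign(barcode_id=f"BC{i + 1:02d}", barcode_seq=bc)
        for i, bc in enumerate(accepted)
    ]


def write_oligo_fasta(
    designs: list[SplintDesign], umis: dict[str, str], fasta_path, sidecar_path
) -> None:
    """Write one bottom-splint record per barcode plus a TSV coordinate sidecar."""
    fasta_path, sidecar_path = Path(fasta_path), Path(sidecar_path)
    with open(fasta_path, "w") as fa, open(sidecar_path, "w") as tsv:
        tsv.write("barcode_id\tsegment\tstart\tend\n")
        for d in designs:
            seq, coords = build_bottom_splint(d, umis[d.barcode_id])
            fa.write(f">{d.barcode_id}\n{seq}\n")
            for seg, (s, e) in coords.items():
                tsv.write(f"{d.barcode_id}\t{seg}\t{s}\t{e}\n")
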