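"""Collapse UMI groups to single molecules.

Two modes mirror the pipeline's choice:

* ``error_correct`` -- multiple sequence alignment over the group (capped
  upstream at 50 reads) followed by per-column majority voting over
  {A, C, G, T, gap}; gap-majority columns are deleted.  The MSA backend is
  a star alignment: every read is globally aligned (edlib) to a backbone
  read of median length, and the pairwise paths are stacked into columns.
  The backend is deliberately pluggable -- any MSA producing columns can
  feed the same majority vote.
* ``deduplicate`` -- a seeded uniform choice of one representative read.

Reads must enter on a common strand (orientation comes from the adaptor
hit upstream).  Internally the group is canonicalised to the
lexicographically smaller of backbone/revcomp(backbone), which makes the
consensus exactly strand-covariant: reverse-complementing every input
reverse-complements the output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np
from Bio import Align

from ._seq import revcomp

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")
_GAP = 4
_BASE_ORDER = "ACGT-"
_BASE_IDX = {b: i for i, b in enumerate("ACGT")}

#: Backbone aligner for the star MSA.  Gap opening is costlier than two
#: mismatches, so equal-cost substitution-vs-indel-pair ambiguities between
#: noisy reads resolve to substitutions; genuine indels still align as gaps.
_CONS_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=0,
    mismatch_score=-1,
    open_gap_score=-2.5,
    extend_gap_score=-1,
)


class ConsensusError(ValueError):
    pass


@dataclass
class ConsensusResult:
    group_id: str
    mode: str  # "error_correct" | "deduplicate"
    sequence: str
    support: int
    agreement: list[float]  # per-kept-column majority fraction

    def quality_string(self) -> str:
        """Synthetic quality from per-column agreement (phred-like, capped 40)."""
        quals = []
        for a in self.agreement:
            err = max(1.0 - a, 1e-4)
            quals.append(chr(33 + int(min(40, round(-10 * np.log10(err))))))
        return "".join(quals)


def _median_length_backbone(reads: list[str]) -> int:
    # strand-invariant sort key, so the same read is picked for a group and
    # for its reverse-complemented counterpart
    order = sorted(
        range(len(reads)),
        key=lambda i: (len(reads[i]), min(reads[i], revcomp(reads[i]))),
    )
    return order[len(order) // 2]


def _star_columns(reads: list[str], backbone_i: int):
    """Stack pairwise read-vs-backbone alignments into MSA columns.

    Columns are keyed by (backbone_pos, insert_offset); insert_offset 0 is
    the backbone base itself, >0 are insertion columns after it.  Reads
    lacking an insertion vote gap there; reads deleted at a backbone
    position vote gap.
    """
    backbone = reads[backbone_i]
    n = len(reads)
    votes: dict[tuple[int, int], np.ndarray] = {}

    def col(key):
        if key not in votes:
            votes[key] = np.zeros(5, dtype=np.int64)
        return votes[key]

    # backbone's own votes
    for p, b in enumerate(backbone):
        col((p, 0))[_BASE_IDX[b]] += 1
    for ri, read in enumerate(reads):
        if ri == backbone_i:
            continue
        aln = _CONS_ALIGNER.align(backbone, read)[0]
        t_blocks, q_blocks = aln.aligned
        prev_t = prev_q = 0
        for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
            for p in range(prev_t, ts):  # backbone bases the read lacks
                col((p, 0))[_GAP] += 1
            for k, q in enumerate(range(prev_q, qs), start=1):  # read insertions
                col((ts - 1, k))[_BASE_IDX[read[q]]] += 1
            for p, q in zip(range(ts, te), range(qs, qe)):
                col((p, 0))[_BASE_IDX[read[q]]] += 1
            prev_t, prev_q = te, qe
        for p in range(prev_t, len(backbone)):  # trailing deletion
            col((p, 0))[_GAP] += 1
        for k, q in enumerate(range(prev_q, len(read)), start=1):  # trailing insertion
            col((len(backbone) - 1, k))[_BASE_IDX[read[q]]] += 1
    # insertion columns: reads without that insertion implicitly voted gap
    for key, v in votes.items():
        if key[1] > 0:
            v[_GAP] += n - int(v.sum())
    return votes


def _majority(vote: np.ndarray) -> tuple[str, float]:
    """Majority call with documented tie-breaking: ties on the top count
    resolve to a base over the gap, then lexicographically (A<C<G<T)."""
    top = vote.max()
    winners = [i for i in range(5) if vote[i] == top]
    bases = [i for i in winners if i != _GAP]
    call = _BASE_ORDER[bases[0]] if bases else "-"
    support = int(vote.sum())
    return call, top / support if support else 0.0


def error_correct(
    reads: list[str], seed: int = 0, group_id: str = "group"
) -> ConsensusResult:
    """MSA-based majority consensus of a UMI group (all reads same strand)."""
    if not reads:
        raise ConsensusError("empty group")
    if len(reads) == 1:
        return ConsensusResult(group_id, "error_correct", reads[0], 1,
                               [1.0] * len(reads[0]))
    backbone_i = _median_length_backbone(reads)
    backbone = reads[backbone_i]
    flipped = revcomp(backbone) < backbone
    if flipped:
        reads = [revcomp(r) for r in reads]
        backbone = reads[backbone_i]
    votes = _star_columns(reads, backbone_i)
    out = []
    agreement = []
    for key in sorted(votes):
        call, frac = _majority(votes[key])
        if call == "-":
            continue  # gap-majority columns are deleted
        out.append(call)
        agreement.append(frac)
    seq = "".join(out)
    if flipped:
        seq = revcomp(seq)
        agreement = agreement[::-1]
    return ConsensusResult(group_id, "error_correct", seq, len(reads), agreement)


def deduplicate(
    reads: list[str], seed: int = 0, group_id: str = "group"
) -> ConsensusResult:
    """Seeded uniform choice of one representative read."""
    if not reads:
        raise ConsensusError("empty group")
    rng = np.random.default_rng(seed)
    pick = int(rng.integers(len(reads)))
    return ConsensusResult(group_id, "deduplicate", reads[pick], len(reads),
                           [1.0] * len(reads[pick]))


def measure_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment length."""
    if a == b:
        return 1.0
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="path")
    matches = 0
    total = 0
    for m in _CIGAR_RE.finditer(res["cigar"]):
        ln, op = int(m.group(1)), m.group(2)
        total += ln
        if op == "=":
            matches += ln
    return matches / total if total else 0.0
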