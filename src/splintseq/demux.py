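"""Cell demultiplexing via barcode-slot alignment.

The splint adaptor places the cell barcode between two known constant
regions (the Nextera R2 handle and the pre-UMI constant).  Rather than
re-aligning every whole read against every barcode, the scaffold
``R2 + N...N + constant`` (the barcode slot as wildcards) is localised once
per read in the 250-bp end windows on both strands; the read subsequence
projected onto the slot is then scored against each candidate barcode by
pairwise alignment.  A read is binned only when its best barcode score
clears the score threshold AND the margin over the runner-up ("gap") clears
the gap threshold -- ties are inherently ambiguous (gap 0) and fail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import revcomp
from .oligo import SplintDesign
from .qc import DEFAULT_END_WINDOW, _make_aligner

_SCAFFOLD_ALIGNER = _make_aligner(wildcard="N")
_SLOT_ALIGNER = _make_aligner()


@dataclass
class BarcodeAssignment:
    read_id: str
    best_barcode: str
    best_score: float
    second_best_score: float
    passed: bool
    reason: str = ""
    strand: str = "+"

    @property
    def gap(self) -> float:
        return self.best_score - self.second_best_score


def _project(alignment, q_start: int, q_end: int) -> tuple[int, int] | None:
    """Map query interval [q_start, q_end) to target coordinates via the
    alignment path; returns None when the interval is outside the aligned
    region."""
    t_blocks, q_blocks = alignment.aligned
    r_start = r_end = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if r_start is None and qe > q_start:
            r_start = ts + max(0, q_start - qs)
        if qs < q_end:
            r_end = te - max(0, qe - q_end)
    if r_start is None or r_end is None or r_end <= r_start:
        return None
    return int(r_start), int(r_end)


def locate_slot(
    seq: str,
    scaffold: str,
    slot_start: int,
    slot_end: int,
    end_window: int = DEFAULT_END_WINDOW,
) -> tuple[str, float, str] | None:
    """Find the scaffold on either strand/end of ``seq`` and return the read
    subsequence under the wildcard slot: (slot_seq, scaffold_score, strand)."""
    best = None
    for strand in ("+", "-"):
        oriented = seq if strand == "+" else revcomp(seq)
        if len(oriented) <= 2 * end_window:
            segments = [(0, oriented)]
        else:
            segments = [
                (0, oriented[:end_window]),
                (len(oriented) - end_window, oriented[-end_window:]),
            ]
        for offset, segment in segments:
            if not segment:
                continue
            alns = _SCAFFOLD_ALIGNER.align(segment, scaffold)
            try:
                aln = alns[0]
            except IndexError:
                continue
            if best is not None and aln.score <= best[1]:
                continue
            span = _project(aln, slot_start, slot_end)
            if span is None:
                continue
            slot_seq = segment[span[0]: span[1]]
            best = (slot_seq, float(aln.score), strand)
    return best


def _score_barcode(slot: str, barcode: str) -> float:
    if not slot:
        return float("-inf")
    alns = _SLOT_ALIGNER.align(slot, barcode)
    try:
        return float(alns[0].score)
    except IndexError:
        return float("-inf")


def slot_score_null(slots: list[str], barcodes: list[str], seed: int) -> np.ndarray:
    """Null barcode scores: each extracted slot scored against a random
    permutation of a randomly chosen candidate barcode."""
    rng = np.random.default_rng(seed)
    scores = []
    for slot in slots:
        bc = barcodes[rng.integers(len(barcodes))]
        perm = "".join(np.array(list(bc))[rng.permutation(len(bc))])
        scores.append(_score_barcode(slot, perm))
    return np.asarray(scores, dtype=float)


def demultiplex(
    reads,
    designs: list[SplintDesign],
    score_threshold: float | None = None,
    gap_threshold: float = 1.0,
    end_window: int = DEFAULT_END_WINDOW,
    null_seed: int = 0,
    null_percentile: float = 99.0,
):
    """Assign reads to barcodes.

    Returns (bins, unassigned, table): per-barcode read lists (a partition
    together with the unassigned bin) and the assignment table.  When
    ``score_threshold`` is None it is derived as the ``null_percentile`` of
    the scrambled-barcode score null over the extracted slots.
    """
    if not designs:
        raise ValueError("need at least one barcode design")
    reads = list(reads)
    d0 = designs[0]
    bc_len = len(d0.barcode_seq)
    scaffold = d0.nextera_r2 + "N" * bc_len + d0.constant_pre_umi
    slot_start, slot_end = len(d0.nextera_r2), len(d0.nextera_r2) + bc_len
    barcodes = [d.barcode_seq for d in designs]
    ids = [d.barcode_id for d in designs]

    located: list[tuple[str, float, str] | None] = []
    for r in reads:
        seq = r.sequence if hasattr(r, "sequence") else r[1]
        located.append(locate_slot(seq, scaffold, slot_start, slot_end, end_window))

    if score_threshold is None:
        slots = [loc[0] for loc in located if loc is not None]
        if slots:
            null = slot_score_null(slots, barcodes, null_seed)
            score_threshold = float(np.percentile(null, null_percentile))
        else:
            score_threshold = 0.0

    bins: dict[str, list] = {bid: [] for bid in ids}
    unassigned: list = []
    rows = []
    for r, loc in zip(reads, located):
        rid = r.read_id if hasattr(r, "read_id") else r[0]
        if loc is None:
            unassigned.append(r)
            rows.append(dict(read_id=rid, best_barcode="", best_score=np.nan,
                             second_best_score=np.nan, gap=np.nan, passed=False,
                             reason="no_adaptor", strand=""))
            continue
        slot, _, strand = loc
        scores = np.array([_score_barcode(slot, bc) for bc in barcodes])
        order = np.argsort(scores)[::-1]
        best_i = int(order[0])
        best = float(scores[best_i])
        second = float(scores[order[1]]) if len(scores) > 1 else float("-inf")
        gap = best - second if np.isfinite(second) else float("inf")
        passed = best >= score_threshold and gap >= gap_threshold
        reason = ""
        if not passed:
            reason = "low_score" if best < score_threshold else "ambiguous"
        if passed:
            bins[ids[best_i]].append(r)
        else:
            unassigned.append(r)
        rows.append(dict(read_id=rid, best_barcode=ids[best_i], best_score=best,
                         second_best_score=second, gap=gap, passed=passed,
                         reason=reason, strand=strand))
    table = pd.DataFrame(rows)
    table.attrs["score_threshold"] = score_threshold
    table.attrs["gap_threshold"] = gap_threshold
    return bins, unassigned, table


def assignment_summary(table: pd.DataFrame) -> dict:
    """Per-barcode counts and the retention fraction (passed / total)."""
    if table.empty:
        return {"counts": {}, "retention": float("nan"), "n_reads": 0,
                "undefined": True}
    passed = table[table["passed"]]
    counts = passed["best_barcode"].value_counts().to_dict()
    return {
        "counts": counts,
        "retention": len(passed) / len(table),
        "n_reads": len(table),
        "undefined": False,
    }


def write_assignments(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_assignments(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)
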