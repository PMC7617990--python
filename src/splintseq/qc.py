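"""Read QC: length filtering, end-window adaptor alignment, internal-adaptor
detection with a scrambled-adaptor null, and chimeric read splitting.

Adaptors are located by local alignment (match +1, mismatch -1, gap opening
penalty 4, gap extension penalty 1), by default restricted to the 250-bp
windows at either read end where genuine adaptors occur.  Score thresholds
are derived empirically: each read is also scored against a random
permutation of the adaptor ("scrambled null") and the threshold defaults to
the null's 99th percentile.  A hit whose midpoint falls within 20%-80% of
the read length is classed internal -- the signature of concatenated
molecules -- and such reads can be split at the junctions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import Align

from ._seq import revcomp

logger = logging.getLogger(__name__)

#: Alignment scoring; the gap parameters follow the published pipeline call
#: (gapOpening=4, gapExtension=1), match/mismatch are this package's defaults.
MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.0
GAP_OPEN = 4.0
GAP_EXTEND = 1.0
DEFAULT_END_WINDOW = 250
INTERNAL_LO, INTERNAL_HI = 0.2, 0.8


def _make_aligner(wildcard: str | None = None) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=MATCH_SCORE,
        mismatch_score=MISMATCH_SCORE,
        open_gap_score=-GAP_OPEN,
        extend_gap_score=-GAP_EXTEND,
    )
    if wildcard:
        aligner.wildcard = wildcard
    return aligner


_ALIGNER = _make_aligner()


@dataclass
class AdaptorHit:
    read_id: str
    adaptor_id: str
    score: float
    start: int  # 0-based, half-open on the read as given
    end: int
    strand: str  # "+" adaptor as given, "-" its reverse complement
    location_class: str  # end5 | end3 | internal

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def classify_location(start: int, end: int, read_length: int) -> str:
    mid = (start + end) / 2.0
    if INTERNAL_LO * read_length <= mid <= INTERNAL_HI * read_length:
        return "internal"
    return "end5" if mid < INTERNAL_LO * read_length else "end3"


def filter_by_length(reads, max_len: int = 20000):
    """Partition reads into (kept, removed); removal is strictly > max_len."""
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    kept, removed = [], []
    for r in reads:
        seq = r.sequence if hasattr(r, "sequence") else r[1]
        (removed if len(seq) > max_len else kept).append(r)
    return kept, removed


def _best_local(aligner, segment: str, adaptor: str):
    """Best local alignment score and query interval, or None if no positive score."""
    if not segment:
        return None
    alns = aligner.align(segment, adaptor)
    try:
        best = alns[0]
    except IndexError:
        return None
    if best.score <= 0:
        return None
    blocks = best.aligned[0]
    return best.score, int(blocks[0][0]), int(blocks[-1][1])


def align_adaptor(
    read,
    adaptor: str,
    adaptor_id: str = "adaptor",
    end_window: int = DEFAULT_END_WINDOW,
    full_read: bool = False,
    aligner: Align.PairwiseAligner | None = None,
) -> AdaptorHit | None:
    """Best local hit of ``adaptor`` (either strand) on a read.

    By default only the ``end_window`` bp at either read end are scanned;
    set ``full_read=True`` for internal-adaptor detection.  Returns None if
    the read is shorter than the adaptor (logged) or nothing aligns.
    """
    if not adaptor:
        raise ValueError("adaptor must be non-empty")
    rid = read.read_id if hasattr(read, "read_id") else read[0]
    seq = read.sequence if hasattr(read, "sequence") else read[1]
    if len(seq) < len(adaptor):
        logger.debug("read %s shorter than adaptor %s; skipped", rid, adaptor_id)
        return None
    aligner = aligner or _ALIGNER
    if full_read or len(seq) <= 2 * end_window:
        segments = [(0, seq)]
    else:
        segments = [(0, seq[:end_window]), (len(seq) - end_window, seq[-end_window:])]
    best: AdaptorHit | None = None
    for strand, query in (("+", adaptor), ("-", revcomp(adaptor))):
        for offset, segment in segments:
            res = _best_local(aligner, segment, query)
            if res is None:
                continue
            score, s, e = res
            if best is None or score > best.score:
                best = AdaptorHit(
                    rid, adaptor_id, score, offset + s, offset + e, strand,
                    classify_location(offset + s, offset + e, len(seq)),
                )
    return best


def scrambled_null(
    adaptor: str,
    reads,
    seed: int,
    end_window: int = DEFAULT_END_WINDOW,
    full_read: bool = False,
) -> np.ndarray:
    """Per-read best score of a freshly permuted adaptor (empirical null).

    Used to pick score thresholds, e.g. the 99th percentile of this
    distribution.  Deterministic under ``seed``.
    """
    reads = list(reads)
    if not reads:
        raise ValueError("need at least one read")
    rng = np.random.default_rng(seed)
    letters = np.array(list(adaptor))
    scores = []
    for r in reads:
        scrambled = "".join(letters[rng.permutation(len(letters))])
        hit = align_adaptor(r, scrambled, "scrambled", end_window, full_read)
        scores.append(hit.score if hit else 0.0)
    return np.asarray(scores, dtype=float)


def null_threshold(scores: np.ndarray, percentile: float = 99.0) -> float:
    return float(np.percentile(scores, percentile))


def detect_internal(
    read,
    adaptors: dict[str, str],
    score_threshold: float,
    max_hits_per_adaptor: int = 10,
) -> list[AdaptorHit]:
    """All above-threshold hits whose midpoint lies in the internal window.

    The read is scanned iteratively: after each hit the matched interval is
    masked and the scan repeated, collecting every distinct occurrence on
    both strands.
    """
    if not adaptors:
        raise ValueError("adaptors must be non-empty")
    rid = read.read_id if hasattr(read, "read_id") else read[0]
    seq = read.sequence if hasattr(read, "sequence") else read[1]
    hits: list[AdaptorHit] = []
    for adaptor_id, adaptor in adaptors.items():
        masked = seq
        for _ in range(max_hits_per_adaptor):
            hit = align_adaptor((rid, masked), adaptor, adaptor_id, full_read=True)
            if hit is None or hit.score < score_threshold:
                break
            hit.location_class = classify_location(hit.start, hit.end, len(seq))
            if hit.location_class == "internal":
                hits.append(hit)
            masked = masked[: hit.start] + "X" * (hit.end - hit.start) + masked[hit.end:]
    hits.sort(key=lambda h: h.start)
    return hits


def merge_hit_intervals(hits: list[AdaptorHit]) -> list[tuple[int, int]]:
    """Merge overlapping hit intervals into cut regions."""
    intervals = sorted((h.start, h.end) for h in hits)
    merged: list[list[int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def split_at_internal_adaptors(read, hits: list[AdaptorHit]):
    """Cut a read at each internal junction.

    Adaptor bases are assigned to the downstream fragment's start, so
    re-concatenating the fragments reconstructs the original read exactly.
    Fragment ids derive from the parent id with /1, /2, ... suffixes.
    """
    rid = read.read_id if hasattr(read, "read_id") else read[0]
    seq = read.sequence if hasattr(read, "sequence") else read[1]
    qual = read.quality if hasattr(read, "quality") else (read[2] if len(read) > 2 else "I" * len(seq))
    if not hits:
        return [(rid, seq, qual)]
    cuts = [s for s, _ in merge_hit_intervals(hits) if 0 < s < len(seq)]
    bounds = [0] + cuts + [len(seq)]
    frags = []
    for k in range(len(bounds) - 1):
        s, e = bounds[k], bounds[k + 1]
        frags.append((f"{rid}/{k + 1}", seq[s:e], qual[s:e]))
    return frags


@dataclass
class QcReport:
    n_reads: int
    length_histogram: dict
    score_histograms: dict
    percent_internal: float
    percent_both_end_adaptors: float

    def to_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "length_histogram": self.length_histogram,
            "score_histograms": self.score_histograms,
            "percent_internal": self.percent_internal,
            "percent_both_end_adaptors": self.percent_both_end_adaptors,
        }


def qc_report(
    reads,
    adaptors: dict[str, str],
    seed: int = 0,
    end_window: int = DEFAULT_END_WINDOW,
    null_percentile: float = 99.0,
) -> QcReport:
    """Library-level QC: read lengths, real vs scrambled adaptor scores,
    the percentage of internal-adaptor reads, and the percentage of reads
    carrying both end adaptors."""
    reads = list(reads)
    n = len(reads)
    lengths = [len(r.sequence if hasattr(r, "sequence") else r[1]) for r in reads]
    counts, edges = np.histogram(lengths, bins=20) if n else (np.array([]), np.array([]))
    score_histograms = {}
    thresholds = {}
    for aid, adaptor in adaptors.items():
        real = np.array([
            (h.score if (h := align_adaptor(r, adaptor, aid, end_window)) else 0.0)
            for r in reads
        ])
        null = scrambled_null(adaptor, reads, seed, end_window) if n else np.array([])
        thresholds[aid] = null_threshold(null, null_percentile) if n else 0.0
        score_histograms[aid] = {
            "real": real.tolist(),
            "scrambled": null.tolist(),
            "threshold": thresholds[aid],
        }
    n_internal = 0
    n_both_ends = 0
    for r in reads:
        internal = detect_internal(
            r, adaptors, min(thresholds.values()) if thresholds else 0.0
        )
        if internal:
            n_internal += 1
        end_classes = set()
        for aid, adaptor in adaptors.items():
            h = align_adaptor(r, adaptor, aid, end_window)
            if h and h.score >= thresholds.get(aid, 0.0) and h.location_class != "internal":
                end_classes.add(h.location_class)
        if {"end5", "end3"} <= end_classes:
            n_both_ends += 1
    return QcReport(
        n_reads=n,
        length_histogram={"counts": counts.tolist(), "edges": edges.tolist()},
        score_histograms=score_histograms,
        percent_internal=100.0 * n_internal / n if n else 0.0,
        percent_both_end_adaptors=100.0 * n_both_ends / n if n else 0.0,
    )
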