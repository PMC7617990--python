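"""UMI extraction, feature pre-grouping, and Levenshtein-distance clustering.

Reads are first binned by their aligned transcript/repeat ("pre-grouping",
from an external aligner's SAM/BAM or a plain read→feature mapping), which
shrinks the UMI comparison space.  Within a bin, UMIs are clustered as the
connected components of the graph joining pairs at Levenshtein distance at
most a threshold.  With 50-nt R/Y/N UMIs the default threshold is 14 --
permissive enough to absorb nanopore errors on PCR duplicates of one
molecule, yet far below the typical distance (~25-30) between two
independently drawn UMIs; for 20-nt UMIs the literature threshold is 6.

Distances are computed with edlib, banded at the threshold; this is exact
(identical to full dynamic programming) for the <=threshold decisions the
clustering consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import networkx as nx
import numpy as np
import pandas as pd
import pysam

from ._seq import revcomp
from .oligo import SplintDesign
from .qc import DEFAULT_END_WINDOW, _make_aligner
from .demux import _project

_FLANK_ALIGNER = _make_aligner(wildcard="N")


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (symmetric; obeys the triangle inequality)."""
    if a == b:
        return 0
    if not a or not b:
        return len(a) or len(b)
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def within_distance(a: str, b: str, k: int) -> bool:
    """True iff levenshtein(a, b) <= k, using a banded computation."""
    if k < 0:
        return False
    if not a or not b:
        return (len(a) or len(b)) <= k
    return edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"] != -1


@dataclass
class GroupingParams:
    """Levenshtein threshold 14 is the 50-nt UMI default; 6 is the
    documented choice for 20-nt UMIs."""

    levenshtein_threshold: int = 14
    max_reads_per_group_for_msa: int = 50
    chunk_size: int = 1000

    def __post_init__(self):
        if self.levenshtein_threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.max_reads_per_group_for_msa < 1:
            raise ValueError("max_reads_per_group_for_msa must be >= 1")


@dataclass
class UmiGroup:
    group_id: str
    feature_id: str
    read_ids: list[str]
    umis: list[str]
    msa_read_ids: list[str] | None = None  # subsample used for consensus

    @property
    def size(self) -> int:
        return len(self.read_ids)


class UmiExtractionError(Exception):
    pass


def extract_umi(
    read_seq: str,
    design: SplintDesign,
    strand: str = "+",
    end_window: int = DEFAULT_END_WINDOW,
    min_flank_identity: float = 0.5,
) -> tuple[str, float]:
    """Extract the UMI between the projected constant-region flanks.

    The template ``constant_pre_umi + N*umi_len + constant_post_umi`` is
    aligned locally (N wildcard) near the barcode end of the read oriented
    by ``strand``; the read subsequence projected under the N block is the
    UMI (its length may deviate from the design length through indels).
    Confidence is the flank alignment score over the maximal flank score.
    Raises UmiExtractionError when the flanks do not align convincingly.
    """
    oriented = read_seq if strand == "+" else revcomp(read_seq)
    pre, post = design.constant_pre_umi, design.constant_post_umi
    umi_len = design.umi_spec.length
    template = pre + "N" * umi_len + post
    window = min(len(oriented), end_window + len(template))
    segment = oriented[:window]
    alns = _FLANK_ALIGNER.align(segment, template)
    try:
        aln = alns[0]
    except IndexError:
        raise UmiExtractionError("flanks_unaligned")
    max_flank = len(pre) + len(post)
    confidence = float(aln.score) / max_flank
    if confidence < min_flank_identity:
        raise UmiExtractionError("flanks_below_threshold")
    span = _project(aln, len(pre), len(pre) + umi_len)
    if span is None:
        raise UmiExtractionError("umi_slot_unprojected")
    return segment[span[0]: span[1]], confidence


def pregroup_by_feature(assignments) -> dict[str, list[str]]:
    """Bin read ids by assigned feature.

    Accepts a DataFrame/TSV path with columns (read_id, feature_id) or a
    SAM/BAM path, from which primary-alignment reference names are taken
    (secondary/supplementary/unmapped records are ignored).
    """
    if isinstance(assignments, (str,)) and assignments.endswith((".sam", ".bam")):
        bins: dict[str, list[str]] = {}
        with pysam.AlignmentFile(assignments, check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                bins.setdefault(rec.reference_name, []).append(rec.query_name)
        return bins
    if isinstance(assignments, str):
        assignments = pd.read_csv(assignments, sep="\t")
    bins = {}
    for _, row in assignments.iterrows():
        bins.setdefault(str(row["feature_id"]), []).append(str(row["read_id"]))
    return bins


def cluster_umis(
    umis: list[tuple[str, str]],
    params: GroupingParams,
    feature_id: str = "feature",
) -> list[UmiGroup]:
    """Cluster (read_id, umi) pairs of one feature bin.

    Groups are the connected components of the graph joining UMI pairs at
    Levenshtein distance <= threshold (single linkage).  Deterministic:
    each group is labelled by its smallest member read_id and groups are
    returned sorted by that label.
    """
    if not umis:
        raise ValueError("need at least one UMI")
    k = params.levenshtein_threshold
    g = nx.Graph()
    g.add_nodes_from(range(len(umis)))
    seqs = [u for _, u in umis]
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if within_distance(seqs[i], seqs[j], k):
                g.add_edge(i, j)
    groups = []
    for comp in nx.connected_components(g):
        members = sorted(comp, key=lambda ix: umis[ix][0])
        read_ids = [umis[ix][0] for ix in members]
        groups.append(
            UmiGroup(
                group_id=f"{feature_id}:{read_ids[0]}",
                feature_id=feature_id,
                read_ids=read_ids,
                umis=[umis[ix][1] for ix in members],
            )
        )
    groups.sort(key=lambda grp: grp.group_id)
    return groups


def chunk_groups(
    groups: list[UmiGroup], params: GroupingParams, seed: int = 0
) -> list[list[UmiGroup]]:
    """Cap group size for consensus and batch groups for parallel execution.

    Groups larger than ``max_reads_per_group_for_msa`` get a seeded uniform
    subsample recorded in ``msa_read_ids`` (the remaining members inherit
    the group consensus); membership itself is unchanged, so the final
    groups are independent of the batch boundaries.
    """
    rng = np.random.default_rng(seed)
    for grp in groups:
        cap = params.max_reads_per_group_for_msa
        if grp.size > cap:
            pick = rng.choice(grp.size, size=cap, replace=False)
            grp.msa_read_ids = [grp.read_ids[i] for i in sorted(pick)]
        else:
            grp.msa_read_ids = list(grp.read_ids)
    size = max(1, params.chunk_size)
    return [groups[i: i + size] for i in range(0, len(groups), size)]


def evaluate_grouping(
    groups: list[UmiGroup], ledger: pd.DataFrame
) -> dict:
    """Score groups against the simulation ledger.

    A read is counted correct when the majority ledger-molecule of its
    group equals its own.  Singleton groups are correct by this rule but
    cannot be error-corrected, so the fraction of reads left alone is
    reported separately as ``under_grouped_fraction``.
    """
    mol = ledger.set_index("read_id")["molecule_id"]
    n_reads = 0
    n_correct = 0
    n_singleton = 0
    sizes = []
    for grp in groups:
        sizes.append(grp.size)
        members = [mol[rid] for rid in grp.read_ids]
        majority = pd.Series(members).mode().iloc[0]
        n_reads += grp.size
        n_correct += sum(m == majority for m in members)
        if grp.size == 1:
            n_singleton += 1
    size_dist = pd.Series(sizes).value_counts().sort_index()
    return {
        "proportion_correct": n_correct / n_reads if n_reads else float("nan"),
        "under_grouped_fraction": n_singleton / n_reads if n_reads else float("nan"),
        "n_groups": len(groups),
        "size_distribution": size_dist,
        "modal_group_size": int(size_dist.idxmax()) if len(size_dist) else 0,
    }


def write_groups(groups: list[UmiGroup], path) -> None:
    rows = []
    for grp in groups:
        for rid, umi in zip(grp.read_ids, grp.umis):
            rows.append((rid, grp.feature_id, grp.group_id, umi))
    pd.DataFrame(rows, columns=["read_id", "feature_id", "group_id", "umi"]).to_csv(
        path, sep="\t", index=False
    )
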