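"""End-to-end orchestration with a run manifest.

Stage order is fixed: length filter → adaptor QC → internal-adaptor split
(optional) → demultiplex → feature pre-grouping (external alignment or
truth mapping ingested) → UMI extraction and Levenshtein grouping →
consensus/deduplication → counting.  Every stage appends a metrics block
to the manifest; seeds recorded there fully determine the stochastic
stages.  Group processing is chunked and merged in canonical group-id
order, so results are independent of the chunking.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import pandas as pd

from . import consensus as cons
from . import demux as dmx
from . import qc
from . import umi as umimod
from .oligo import SplintDesign
from .quantify import count_molecules


@dataclass
class PipelineConfig:
    seed: int
    mode: str = "error_correct"  # or "deduplicate"
    max_read_length: int = 20000
    levenshtein_threshold: int = 14
    max_reads_per_group_for_msa: int = 50
    chunk_size: int = 1000
    score_threshold: float | None = None
    gap_threshold: float = 1.0
    split_internal: bool = False
    internal_adaptors: dict[str, str] | None = None

    def __post_init__(self):
        if self.mode not in ("error_correct", "deduplicate"):
            raise ValueError(f"unknown mode {self.mode!r}")


def stage_report(name: str, n_in: int, n_out: int, **extra) -> dict:
    block = {
        "stage": name,
        "reads_in": n_in,
        "reads_out": n_out,
        "retention": n_out / n_in if n_in else 0.0,
    }
    block.update(extra)
    return block


def _checksum(items) -> str:
    h = hashlib.sha256()
    for it in items:
        h.update(str(it).encode())
    return h.hexdigest()[:16]


def run_pipeline(
    reads,
    designs: list[SplintDesign],
    feature_map,
    config: PipelineConfig,
):
    """Run all stages; returns (results dict, manifest dict).

    ``feature_map`` is a read→feature mapping (DataFrame/TSV with read_id,
    feature_id, or a SAM/BAM path) from an external aligner — spliced
    alignment itself is out of scope here.
    """
    manifest = {
        "config": dataclasses.asdict(config),
        "stages": [],
    }
    reads = list(reads)
    n0 = len(reads)

    # 1. length filter
    kept, removed = qc.filter_by_length(reads, config.max_read_length)
    manifest["stages"].append(
        stage_report("length_filter", n0, len(kept), removed=len(removed))
    )
    reads = kept

    # 2. internal-adaptor detection / split (optional)
    if config.split_internal:
        adaptors = config.internal_adaptors or {
            "splint_scaffold": designs[0].nextera_r2 + designs[0].constant_pre_umi
        }
        null = qc.scrambled_null(
            next(iter(adaptors.values())), reads, config.seed, full_read=True
        )
        thr = qc.null_threshold(null)
        split_reads = []
        n_internal = 0
        for r in reads:
            hits = qc.detect_internal(r, adaptors, thr)
            frags = qc.split_at_internal_adaptors(r, hits)
            if len(frags) > 1:
                n_internal += 1
            split_reads.extend(frags)
        manifest["stages"].append(
            stage_report("internal_split", len(reads), len(split_reads),
                         internal_adaptor_pct=100.0 * n_internal / len(reads)
                         if reads else 0.0)
        )
        reads = split_reads

    # 3. demultiplex
    bins, unassigned, table = dmx.demultiplex(
        reads, designs,
        score_threshold=config.score_threshold,
        gap_threshold=config.gap_threshold,
        null_seed=config.seed,
    )
    summary = dmx.assignment_summary(table)
    manifest["stages"].append(
        stage_report("demultiplex", len(reads),
                     len(reads) - len(unassigned),
                     per_barcode=summary["counts"],
                     retention=summary["retention"])
    )
    strand_of = table.set_index("read_id")["strand"].to_dict()

    # 4. pre-group by feature, per cell
    feature_bins = umimod.pregroup_by_feature(feature_map)
    read_feature = {
        rid: feat for feat, rids in feature_bins.items() for rid in rids
    }

    # 5. UMI extraction + grouping per (cell, feature)
    params = umimod.GroupingParams(
        levenshtein_threshold=config.levenshtein_threshold,
        max_reads_per_group_for_msa=config.max_reads_per_group_for_msa,
        chunk_size=config.chunk_size,
    )
    seq_of = {}
    all_groups: list[tuple[str, umimod.UmiGroup]] = []
    n_grouped = 0
    n_excluded = 0
    for barcode_id, cell_reads in bins.items():
        design = next(d for d in designs if d.barcode_id == barcode_id)
        per_feature: dict[str, list[tuple[str, str]]] = {}
        for r in cell_reads:
            rid = r.read_id if hasattr(r, "read_id") else r[0]
            seq = r.sequence if hasattr(r, "sequence") else r[1]
            seq_of[rid] = seq
            feat = read_feature.get(rid)
            if feat is None:
                n_excluded += 1
                continue
            try:
                extracted, _conf = umimod.extract_umi(
                    seq, design, strand=strand_of.get(rid, "+")
                )
            except umimod.UmiExtractionError:
                n_excluded += 1
                continue
            per_feature.setdefault(feat, []).append((rid, extracted))
        for feat in sorted(per_feature):
            groups = umimod.cluster_umis(per_feature[feat], params,
                                         feature_id=feat)
            for grp in groups:
                all_groups.append((barcode_id, grp))
            n_grouped += sum(g.size for g in groups)
    manifest["stages"].append(
        stage_report("umi_grouping", n_grouped + n_excluded, n_grouped,
                     n_groups=len(all_groups), excluded=n_excluded)
    )

    # 6. consensus / dedup, chunked with order-canonical merge
    umimod.chunk_groups([g for _, g in all_groups], params, seed=config.seed)
    all_groups.sort(key=lambda t: (t[0], t[1].group_id))
    chunks = [
        all_groups[i: i + max(1, config.chunk_size)]
        for i in range(0, len(all_groups), max(1, config.chunk_size))
    ]
    records = []
    for chunk in chunks:
        for barcode_id, grp in chunk:
            member_seqs = [seq_of[rid] for rid in grp.msa_read_ids]
            # orient members to a common strand using the demux call
            oriented = []
            for rid, s in zip(grp.msa_read_ids, member_seqs):
                if strand_of.get(rid, "+") == "-":
                    from ._seq import revcomp
                    s = revcomp(s)
                oriented.append(s)
            group_seed = int(
                hashlib.sha256(f"{config.seed}:{grp.group_id}".encode()).hexdigest()[:7],
                16,
            )
            if config.mode == "error_correct":
                res = cons.error_correct(oriented, seed=group_seed,
                                         group_id=grp.group_id)
            else:
                res = cons.deduplicate(oriented, seed=group_seed,
                                       group_id=grp.group_id)
            records.append({
                "cell": barcode_id,
                "feature_id": grp.feature_id,
                "group_id": grp.group_id,
                "sequence": res.sequence,
                "support": res.support,
                "mode": res.mode,
            })
    consensus_table = pd.DataFrame(
        records,
        columns=["cell", "feature_id", "group_id", "sequence", "support", "mode"],
    )
    manifest["stages"].append(
        stage_report("consensus", len(all_groups), len(consensus_table),
                     mode=config.mode)
    )

    # 7. counting
    counts = count_molecules(consensus_table, cells=[d.barcode_id for d in designs])
    manifest["stages"].append(
        stage_report("counting", len(consensus_table), int(counts.to_numpy().sum()))
    )
    manifest["checksums"] = {
        "consensus": _checksum(consensus_table["sequence"].tolist()),
        "counts": _checksum(counts.to_numpy().ravel().tolist()),
    }

    results = {
        "counts": counts,
        "consensus": consensus_table,
        "assignments": table,
        "groups": [g for _, g in all_groups],
    }
    return results, manifest


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
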