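"""UMI extraction and Levenshtein clustering, checked against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splintseq.oligo import UmiSpec, sample_umis
from splintseq.simulate import simulate_umi_grouping
from splintseq.umi import (
    GroupingParams,
    UmiExtractionError,
    chunk_groups,
    cluster_umis,
    evaluate_grouping,
    extract_umi,
    levenshtein,
    pregroup_by_feature,
    within_distance,
)


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance (independent oracle)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def oracle_cluster(umis, threshold):
    """Exhaustive all-pairs single-linkage clustering via union-find + DP."""
    parent = list(range(len(umis)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(umis)):
        for j in range(i + 1, len(umis)):
            if dp_levenshtein(umis[i][1], umis[j][1]) <= threshold:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(len(umis)):
        comps.setdefault(find(i), set()).add(umis[i][0])
    return {frozenset(c) for c in comps.values()}


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a,b,d",
        [("ACGT", "ACGT", 0), ("", "ACG", 3), ("ACGTT", "AGTT", 1)],
    )
    def test_known_distances(self, a, b, d):
        assert levenshtein(a, b) == d

    def test_matches_dp_oracle_on_random_pairs(self):
        rng = np.random.default_rng(4)
        bases = np.array(list("ACGT"))
        for _ in range(1000):
            la, lb = rng.integers(0, 60, size=2)
            a = "".join(bases[rng.integers(4, size=la)])
            b = "".join(bases[rng.integers(4, size=lb)])
            expected = dp_levenshtein(a, b)
            assert levenshtein(a, b) == expected
            assert within_distance(a, b, 14) == (expected <= 14)

    @settings(max_examples=200, derandomize=True)
    @given(
        a=st.text(alphabet="ACGT", max_size=40),
        b=st.text(alphabet="ACGT", max_size=40),
    )
    def test_agrees_with_dp_oracle_property(self, a, b):
        d = levenshtein(a, b)
        assert d == dp_levenshtein(a, b)
        assert d >= abs(len(a) - len(b))
        assert d <= max(len(a), len(b))

    def test_metric_properties(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        seqs = ["".join(bases[rng.integers(4, size=20)]) for _ in range(10)]
        for a in seqs:
            for b in seqs:
                assert levenshtein(a, b) == levenshtein(b, a)
                for c in seqs:
                    assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)


class TestExtractUmi:
    def test_error_free_extraction_recovers_ledger_umi(self, clean_library, designs):
        reads, ledger, _ = clean_library
        truth = ledger.set_index("read_id")
        for r in reads[:20]:
            row = truth.loc[r.read_id]
            design = next(d for d in designs if d.barcode_id == row["barcode_id"])
            umi, conf = extract_umi(r.sequence, design, strand=row["strand"])
            assert umi == row["umi"]
            assert conf == 1.0

    def test_substitutions_inside_umi_preserved_at_distance_two(
        self, clean_library, designs
    ):
        reads, ledger, _ = clean_library
        truth = ledger.set_index("read_id")
        r = reads[0]
        row = truth.loc[r.read_id]
        design = next(d for d in designs if d.barcode_id == row["barcode_id"])
        from splintseq._seq import revcomp

        # mutate two interior UMI bases on the oriented read
        seq = r.sequence if row["strand"] == "+" else revcomp(r.sequence)
        base_umi, _ = extract_umi(seq, design, strand="+")
        start = seq.find(base_umi)
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        mut = list(seq)
        for off in (10, 30):
            mut[start + off] = flip[mut[start + off]]
        umi, _ = extract_umi("".join(mut), design, strand="+")
        assert levenshtein(umi, row["umi"]) == 2

    def test_read_without_adaptor_excluded_with_reason(self, designs):
        rng = np.random.default_rng(1)
        junk = "".join(np.array(list("ACGT"))[rng.integers(4, size=400)])
        with pytest.raises(UmiExtractionError):
            extract_umi(junk, designs[0], min_flank_identity=0.8)


class TestPregroup:
    def test_truth_mapping_bins_match_ledger(self, clean_library):
        _, ledger, _ = clean_library
        mapping = ledger[["read_id", "transcript_id"]].rename(
            columns={"transcript_id": "feature_id"}
        )
        bins = pregroup_by_feature(mapping)
        assert sum(len(v) for v in bins.values()) == len(ledger)
        for feat, rids in bins.items():
            assert set(ledger[ledger["transcript_id"] == feat]["read_id"]) == set(rids)

    def test_bins_are_disjoint(self, clean_library):
        _, ledger, _ = clean_library
        mapping = ledger[["read_id", "transcript_id"]].rename(
            columns={"transcript_id": "feature_id"}
        )
        bins = pregroup_by_feature(mapping)
        all_ids = [r for v in bins.values() for r in v]
        assert len(all_ids) == len(set(all_ids))

    def test_sam_input_uses_primary_alignments_only(self, tmp_path):
        sam = tmp_path / "toy.sam"
        sam.write_text(
            "@HD\tVN:1.6\n"
            "@SQ\tSN:gene1\tLN:1000\n"
            "@SQ\tSN:TE1\tLN:1000\n"
            "r1\t0\tgene1\t1\t60\t10M\t*\t0\t0\tACGTACGTAC\t*\n"
            "r1\t256\tTE1\t1\t0\t10M\t*\t0\t0\tACGTACGTAC\t*\n"  # secondary
            "r2\t16\tTE1\t5\t60\t10M\t*\t0\t0\tACGTACGTAC\t*\n"
            "r3\t4\t*\t0\t0\t*\t*\t0\t0\tACGTACGTAC\t*\n"  # unmapped
        )
        bins = pregroup_by_feature(str(sam))
        assert bins == {"gene1": ["r1"], "TE1": ["r2"]}


class TestClusterUmis:
    def test_threshold_zero_distinct_umis_singletons(self):
        umis = [("r1", "AAAA"), ("r2", "CCCC"), ("r3", "GGGG")]
        groups = cluster_umis(umis, GroupingParams(levenshtein_threshold=0))
        assert len(groups) == 3
        assert all(g.size == 1 for g in groups)

    def test_threshold_at_umi_length_single_group(self):
        umis = [("r1", "AAAA"), ("r2", "CCCC"), ("r3", "GGGG")]
        groups = cluster_umis(umis, GroupingParams(levenshtein_threshold=4))
        assert len(groups) == 1
        assert groups[0].size == 3

    def test_matches_exhaustive_oracle_on_200_reads(self):
        bins, ledger = simulate_umi_grouping(
            n_molecules=40, duplicates=5, umi_length=50, seed=8, n_features=1
        )
        umis = bins["f0"]
        assert len(umis) == 200
        for threshold in (0, 6, 14):
            groups = cluster_umis(umis, GroupingParams(levenshtein_threshold=threshold))
            ours = {frozenset(g.read_ids) for g in groups}
            assert ours == oracle_cluster(umis, threshold)

    def test_noisy_duplicates_regroup_to_molecules(self):
        bins, ledger = simulate_umi_grouping(
            n_molecules=20, duplicates=5, umi_length=50, seed=9, n_features=1
        )
        groups = cluster_umis(bins["f0"], GroupingParams(levenshtein_threshold=14))
        assert len(groups) == 20
        mol = ledger.set_index("read_id")["molecule_id"]
        for g in groups:
            assert len({mol[r] for r in g.read_ids}) == 1

    def test_group_count_monotone_nonincreasing_in_threshold(self):
        bins, _ = simulate_umi_grouping(
            n_molecules=30, duplicates=3, umi_length=20, seed=10, n_features=1
        )
        counts = [
            len(cluster_umis(bins["f0"], GroupingParams(levenshtein_threshold=t)))
            for t in (0, 2, 4, 8, 12, 20)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_deterministic_labels(self):
        rng = np.random.default_rng(11)
        umis = [(f"r{i}", u) for i, u in enumerate(sample_umis(UmiSpec(), 30, rng))]
        a = cluster_umis(umis, GroupingParams())
        b = cluster_umis(umis, GroupingParams())
        assert [g.group_id for g in a] == [g.group_id for g in b]


class TestChunking:
    def test_small_group_unchanged(self):
        umis = [("r1", "AAAA"), ("r2", "AAAT"), ("r3", "AATA")]
        groups = cluster_umis(umis, GroupingParams(levenshtein_threshold=4))
        chunk_groups(groups, GroupingParams(), seed=0)
        assert groups[0].msa_read_ids == groups[0].read_ids

    def test_large_group_subsampled_to_cap(self):
        umis = [(f"r{i:03d}", "AAAA") for i in range(120)]
        groups = cluster_umis(umis, GroupingParams(levenshtein_threshold=0))
        assert groups[0].size == 120
        chunk_groups(groups, GroupingParams(max_reads_per_group_for_msa=50), seed=1)
        assert len(groups[0].msa_read_ids) == 50
        assert set(groups[0].msa_read_ids) <= set(groups[0].read_ids)
        # seeded draw is reproducible
        again = cluster_umis(umis, GroupingParams(levenshtein_threshold=0))
        chunk_groups(again, GroupingParams(max_reads_per_group_for_msa=50), seed=1)
        assert again[0].msa_read_ids == groups[0].msa_read_ids

    def test_batch_boundaries_do_not_change_groups(self):
        bins, _ = simulate_umi_grouping(
            n_molecules=25, duplicates=4, umi_length=50, seed=12, n_features=1
        )
        g1 = cluster_umis(bins["f0"], GroupingParams(chunk_size=1))
        g2 = cluster_umis(bins["f0"], GroupingParams(chunk_size=1000))
        batches1 = chunk_groups(g1, GroupingParams(chunk_size=1), seed=0)
        batches2 = chunk_groups(g2, GroupingParams(chunk_size=1000), seed=0)
        flat1 = [g for b in batches1 for g in b]
        flat2 = [g for b in batches2 for g in b]
        assert [g.read_ids for g in flat1] == [g.read_ids for g in flat2]


class TestEvaluateGrouping:
    def test_perfect_grouping_scores_one(self):
        bins, ledger = simulate_umi_grouping(
            n_molecules=10, duplicates=5, umi_length=50, seed=13, n_features=1,
            substitution=0, insertion=0, deletion=0,
        )
        groups = cluster_umis(bins["f0"], GroupingParams(levenshtein_threshold=0))
        ev = evaluate_grouping(groups, ledger)
        assert ev["proportion_correct"] == 1.0
        assert ev["modal_group_size"] == 5
        assert set(ev["size_distribution"].index) == {5}

    def test_overly_strict_threshold_flags_undergrouping(self):
        bins, ledger = simulate_umi_grouping(
            n_molecules=10, duplicates=5, umi_length=50, seed=14, n_features=1
        )
        groups = cluster_umis(bins["f0"], GroupingParams(levenshtein_threshold=0))
        ev = evaluate_grouping(groups, ledger)
        assert ev["proportion_correct"] == 1.0  # singletons count correct...
        assert ev["under_grouped_fraction"] > 0.5  # ...but are flagged

    def test_long_umis_tolerate_threshold_14_better_than_short(self):
        results = {}
        for length in (20, 50):
            bins, ledger = simulate_umi_grouping(
                n_molecules=60, duplicates=5, umi_length=length, seed=15,
                n_features=1,
            )
            groups = cluster_umis(bins["f0"], GroupingParams(levenshtein_threshold=14))
            ev = evaluate_grouping(groups, ledger)
            results[length] = ev["proportion_correct"]
        assert results[50] >= results[20]
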