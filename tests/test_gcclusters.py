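"""GC-rich region scanning, cluster classification, tandem arrays,
count tables, ANOVA, conservation, M4 pairing, and k-mer scans."""
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from conftest import random_dna
from mitopop.diversity import MultipleAlignment
from mitopop.gcclusters import (AnovaResult, ConsensusEntry, ConsensusTable,
                                anova_by_population, classify_clusters,
                                cluster_count_table, conserved_positions,
                                default_consensus_table, gc_rich_regions,
                                instantiate_consensus, kmer_repeat_scan,
                                m4_pairing, scan_genome, tandem_arrays,
                                unclassified_regions)
from mitopop.io import AnnotatedGenome, ValidationError, reverse_complement


def brute_force_regions(seq, window=30, threshold=0.60):
    """Mark every GC-rich window explicitly, union the intervals."""
    marked = []
    for i in range(len(seq) - window + 1):
        w = seq[i:i + window]
        if (w.count("G") + w.count("C")) / window > threshold:
            marked.append((i, i + window))
    merged = []
    for s, e in marked:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


class TestGcRichRegions:
    def test_all_at_sequence_empty(self):
        assert gc_rich_regions("AT" * 200) == []

    def test_single_gc_block_matches_oracle(self):
        rng = np.random.default_rng(0)
        seq = random_dna(rng, 500, gc=0.1) + "G" * 20 + "C" * 20 + \
            random_dna(rng, 480, gc=0.1)
        regions = [(r.start, r.end) for r in gc_rich_regions(seq)]
        assert regions == brute_force_regions(seq)
        assert len(regions) == 1
        s, e = regions[0]
        assert s <= 500 and e >= 540

    def test_two_separated_blocks_two_regions(self):
        rng = np.random.default_rng(1)
        block = "GC" * 18
        seq = ("AT" * 100) + block + ("AT" * 100) + block + ("AT" * 100)
        regions = gc_rich_regions(seq)
        assert len(regions) == 2
        assert [(r.start, r.end) for r in regions] == brute_force_regions(seq)

    def test_window_longer_than_sequence_warns_empty(self):
        assert gc_rich_regions("ACGT", window=30) == []

    def test_matches_brute_force_on_random_sequences(self):
        """Every-window oracle over 1000 random sequences."""
        rng = np.random.default_rng(2)
        for _ in range(1000):
            n = int(rng.integers(40, 260))
            gc = float(rng.uniform(0.2, 0.7))
            seq = random_dna(rng, n, gc=gc)
            got = [(r.start, r.end) for r in gc_rich_regions(seq)]
            assert got == brute_force_regions(seq)

    def test_region_gc_recomputed_over_merged_interval(self):
        seq = "AT" * 50 + "G" * 40 + "AT" * 50
        (r,) = gc_rich_regions(seq)
        assert r.gc == pytest.approx(
            (seq[r.start:r.end].count("G") + seq[r.start:r.end].count("C"))
            / (r.end - r.start))

    def test_circular_rotation_invariance(self):
        rng = np.random.default_rng(3)
        seq = random_dna(rng, 600, gc=0.1) + "GC" * 25 + random_dna(rng, 600, gc=0.1)
        base = len(gc_rich_regions(seq, circular=True))
        for shift in (13, 300, 625, 1100):
            rot = seq[shift:] + seq[:shift]
            assert len(gc_rich_regions(rot, circular=True)) == base


class TestClassifyClusters:
    def test_exact_instance_identity_one(self):
        rng = np.random.default_rng(4)
        table = default_consensus_table()
        inst = instantiate_consensus(table.get("M1").consensus, rng)
        seq = random_dna(rng, 800, gc=0.1) + inst + random_dna(rng, 800, gc=0.1)
        hits = classify_clusters(seq, gc_rich_regions(seq), table)
        assert [h.label for h in hits] == ["M1"]
        assert hits[0].identity == 1.0 and hits[0].coverage == 1.0

    def test_reverse_strand_instance_found(self):
        rng = np.random.default_rng(5)
        table = default_consensus_table()
        inst = reverse_complement(instantiate_consensus(table.get("M2").consensus, rng))
        seq = random_dna(rng, 500, gc=0.1) + inst + random_dna(rng, 500, gc=0.1)
        hits = classify_clusters(seq, gc_rich_regions(seq), table)
        assert [(h.label, h.strand) for h in hits] == [("M2", "-")]

    def test_empty_region_list(self):
        table = default_consensus_table()
        assert classify_clusters("ACGT" * 100, [], table) == []

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            ConsensusTable([])

    def test_degraded_instance_below_threshold_unclassified(self):
        rng = np.random.default_rng(6)
        table = default_consensus_table()
        inst = list(instantiate_consensus(table.get("M1").consensus, rng))
        # mutate 30 % of positions (to the other GC base or an AT base)
        flip = {"A": "T", "T": "A", "G": "C", "C": "G"}
        for p in rng.choice(len(inst), size=int(0.3 * len(inst)), replace=False):
            inst[p] = flip[inst[p]]
        seq = random_dna(rng, 500, gc=0.1) + "".join(inst) + random_dna(rng, 500, gc=0.1)
        regions = gc_rich_regions(seq)
        assert regions, "degraded instance should still be GC-rich"
        hits = classify_clusters(seq, regions, table)
        assert [h for h in hits if h.label == "M1"] == []
        assert unclassified_regions(regions, hits) == regions

    def test_no_false_positives_on_random_at_genomes(self):
        rng = np.random.default_rng(7)
        table = default_consensus_table()
        for _ in range(100):
            seq = random_dna(rng, 2000, gc=0.16)
            regions = gc_rich_regions(seq)
            hits = classify_clusters(seq, regions, table)
            assert hits == []


class TestTandemArraysAndPairing:
    def _scan_with_planted_pair(self, seed=8):
        rng = np.random.default_rng(seed)
        table = default_consensus_table()
        m4 = instantiate_consensus(table.get("M4").consensus, rng)
        m1 = instantiate_consensus(table.get("M1").consensus, rng)
        seq = random_dna(rng, 700, gc=0.1) + m4 + m1 + random_dna(rng, 700, gc=0.1)
        regions = gc_rich_regions(seq)
        hits = classify_clusters(seq, regions, table)
        return regions, hits

    def test_single_hit_no_array(self):
        rng = np.random.default_rng(9)
        table = default_consensus_table()
        inst = instantiate_consensus(table.get("M3").consensus, rng)
        seq = random_dna(rng, 400, gc=0.1) + inst + random_dna(rng, 400, gc=0.1)
        regions = gc_rich_regions(seq)
        hits = classify_clusters(seq, regions, table)
        arrays, n = tandem_arrays(regions, hits)
        assert n == 0 and hits[0].array_id is None

    def test_m4_m1_pair_forms_one_array(self):
        regions, hits = self._scan_with_planted_pair()
        assert Counter(h.label for h in hits) == {"M4": 1, "M1": 1}
        arrays, n = tandem_arrays(regions, hits)
        assert n == 1 and len(arrays[0][1]) == 2

    def test_three_overlapping_hits_one_array(self):
        rng = np.random.default_rng(10)
        table = default_consensus_table()
        seqs = [instantiate_consensus(table.get(l).consensus, rng)
                for l in ("M2", "M3", "M2''")]
        seq = random_dna(rng, 600, gc=0.1) + "".join(seqs) + random_dna(rng, 600, gc=0.1)
        regions = gc_rich_regions(seq)
        hits = classify_clusters(seq, regions, table)
        arrays, n = tandem_arrays(regions, hits)
        assert n == 1 and len(arrays[0][1]) == 3

    def test_m4_pairing_orientation_counts(self):
        regions, hits = self._scan_with_planted_pair()
        arrays, _ = tandem_arrays(regions, hits)
        assert m4_pairing(hits, arrays) == (1, 1, 0, 0)

    def test_no_m4_hits(self):
        assert m4_pairing([], []) == (0, 0, 0, 0)

    def test_22_pairs_with_one_reversed(self):
        """22 M4-M1 arrays, 21 with M4 upstream and 1 reversed, counted as
        (22, 21, 1, 0)."""
        from mitopop.gcclusters import GCClusterHit, GCRichRegion
        hits, regions = [], []
        for i in range(22):
            base = 1000 * i
            if i < 21:
                m4 = GCClusterHit("M4", base + 100, base + 133, "+", 1.0, 1.0)
                m1 = GCClusterHit("M1", base + 133, base + 179, "+", 1.0, 1.0)
            else:
                m1 = GCClusterHit("M1", base + 100, base + 146, "+", 1.0, 1.0)
                m4 = GCClusterHit("M4", base + 146, base + 179, "+", 1.0, 1.0)
            hits += [m4, m1]
            regions.append(GCRichRegion(base + 95, base + 185, 0.8))
        arrays, n = tandem_arrays(regions, hits)
        assert n == 22
        assert m4_pairing(hits, arrays) == (22, 21, 1, 0)

    def test_unpaired_m4_counted(self):
        rng = np.random.default_rng(11)
        table = default_consensus_table()
        inst = instantiate_consensus(table.get("M4").consensus, rng)
        seq = random_dna(rng, 400, gc=0.1) + inst + random_dna(rng, 400, gc=0.1)
        regions = gc_rich_regions(seq)
        hits = classify_clusters(seq, regions, table)
        arrays, _ = tandem_arrays(regions, hits)
        assert m4_pairing(hits, arrays) == (1, 0, 0, 1)


class TestCountTable:
    def test_nothing_planted_all_zero(self):
        rng = np.random.default_rng(12)
        g = AnnotatedGenome("s", random_dna(rng, 3000, gc=0.16))
        counts = cluster_count_table([g])
        assert counts.loc["s"].sum() == 0

    def test_planted_counts_recovered_exactly(self, small_sim):
        cfg, genomes, truth = small_sim
        counts = cluster_count_table(genomes, cfg.consensus_table)
        for g in genomes:
            planted = Counter(c.label for c in truth.clusters[g.strain_id])
            for label in cfg.consensus_table.labels:
                assert counts.loc[g.strain_id, label] == planted.get(label, 0), \
                    (g.strain_id, label)
            assert counts.loc[g.strain_id, "total"] == sum(planted.values())


def anova_oracle(groups):
    """One-way F from explicit sums of squares."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = len(allv) - len(groups)
    return (ssb / dfb) / (ssw / dfw)


class TestAnova:
    def _frame(self, groups):
        rows, pops = [], {}
        for gi, g in enumerate(groups):
            for vi, v in enumerate(g):
                s = f"p{gi}_s{vi}"
                rows.append({"X": v})
                pops[s] = f"p{gi}"
        counts = pd.DataFrame(rows, index=list(pops))
        return counts, pops

    def test_equal_means_f_zero_is_not_forced(self):
        counts, pops = self._frame([[2.0, 4.0], [2.0, 4.0]])
        (res,) = anova_by_population(counts, pops, n_classes_for_bonferroni=1)
        assert res.F == pytest.approx(0.0)

    def test_hand_computed_f_eight(self):
        counts, pops = self._frame([[2.0, 4.0], [6.0, 8.0]])
        (res,) = anova_by_population(counts, pops, n_classes_for_bonferroni=1)
        assert res.F == pytest.approx(8.0)

    def test_all_identical_counts(self):
        counts, pops = self._frame([[5.0, 5.0], [5.0, 5.0]])
        (res,) = anova_by_population(counts, pops)
        assert res.F == 0.0 and res.p == 1.0

    def test_matches_ss_oracle_on_random_tables(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            k = int(rng.integers(2, 5))
            groups = [rng.normal(rng.uniform(0, 10), 1 + rng.random(),
                                 size=int(rng.integers(3, 12)))
                      for _ in range(k)]
            counts, pops = self._frame(groups)
            (res,) = anova_by_population(counts, pops,
                                         n_classes_for_bonferroni=1)
            assert res.F == pytest.approx(anova_oracle(groups), abs=1e-10)

    def test_bonferroni_capped_at_one(self):
        counts, pops = self._frame([[2.0, 4.0], [2.1, 4.1]])
        (res,) = anova_by_population(counts, pops, n_classes_for_bonferroni=50)
        assert res.p_bonferroni <= 1.0

    def test_singleton_population_excluded(self):
        counts, pops = self._frame([[2.0, 4.0], [6.0, 8.0]])
        counts.loc["solo"] = 5.0
        pops["solo"] = "loner"
        (res,) = anova_by_population(counts, pops, n_classes_for_bonferroni=1)
        assert set(res.group_means) == {"p0", "p1"}

    def test_planted_population_effect_detected(self):
        """M4-like effect (means 18 vs 2, sd 3, n=20/group) is Bonferroni
        significant in >= 99 % of seeds."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            groups = [np.round(rng.normal(18, 3, 20)),
                      np.round(rng.normal(2, 3, 20)).clip(0)]
            counts, pops = self._frame(groups)
            (res,) = anova_by_population(counts, pops,
                                         n_classes_for_bonferroni=11)
            hits += res.p_bonferroni <= 0.05
        assert hits >= 99


class TestConservedPositions:
    def test_shared_cluster_is_single_conserved_interval(self):
        rng = np.random.default_rng(14)
        left = random_dna(rng, 200, gc=0.1)
        right = random_dna(rng, 200, gc=0.1)
        block = "GC" * 20
        rows = [left + block + right] * 3
        aln = MultipleAlignment(["a", "b", "c"], rows)
        regions = {t: gc_rich_regions(rows[0]) for t in "abc"}
        conserved = conserved_positions(aln, regions)
        assert len(conserved) == 1
        s, e = conserved[0]
        assert s <= 200 and e >= 240

    def test_cluster_absent_in_one_strain_not_conserved(self):
        rng = np.random.default_rng(15)
        left = random_dna(rng, 200, gc=0.1)
        right = random_dna(rng, 200, gc=0.1)
        block = "GC" * 20
        with_block = left + block + right
        without = left + "-" * len(block) + right
        aln = MultipleAlignment(["a", "b", "c"],
                                [with_block, with_block, without])
        regions = {"a": gc_rich_regions(with_block),
                   "b": gc_rich_regions(with_block),
                   "c": gc_rich_regions(without.replace("-", ""))}
        assert conserved_positions(aln, regions) == []


def kmer_oracle(seq, k, min_count):
    counts = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        canon = min(kmer, reverse_complement(kmer))
        counts[canon] = counts.get(canon, 0) + 1
    return {k_: v for k_, v in counts.items() if v >= min_count}


class TestKmerScan:
    def test_dinucleotide_repeat_dominates_15mers(self):
        seq = "AT" * 50
        out = kmer_repeat_scan(seq, 15, min_count=5)
        oracle = kmer_oracle(seq, 15, 5)
        assert {k: c for k, c, _ in out} == oracle
        assert out[0][1] == max(oracle.values())

    def test_random_sequence_no_repeated_100mers(self):
        rng = np.random.default_rng(16)
        assert kmer_repeat_scan(random_dna(rng, 5000), 100, min_count=5) == []

    def test_planted_element_counted_at_k30(self):
        rng = np.random.default_rng(17)
        element = random_dna(rng, 60)
        seq = "".join(random_dna(rng, 120) + element for _ in range(6)) \
            + random_dna(rng, 200)
        out = kmer_repeat_scan(seq, 30, min_count=5)
        assert {k: c for k, c, _ in out} == kmer_oracle(seq, 30, 5)
        counts = {k: c for k, c, _ in out}
        internal = {min(element[i:i + 30],
                        reverse_complement(element[i:i + 30]))
                    for i in range(len(element) - 29)}
        assert all(counts.get(k) == 6 for k in internal)

    def test_k_larger_than_sequence_rejected(self):
        with pytest.raises(ValidationError):
            kmer_repeat_scan("ACGT", 10)
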