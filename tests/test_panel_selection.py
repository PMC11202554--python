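"""Selection criteria against brute-force oracles and planted truth."""

from collections import Counter

import numpy as np
import pytest

from snppanel import (
    ColonyScenario,
    PanelSelectionError,
    SelectionConfig,
    VariantSite,
    annotation_density_rank,
    complete_linkage_prune,
    flank_uniqueness_filter,
    frequency_filter,
    optimize_panel,
    select_panel,
    simulate_colonies,
    spacing_select,
)


def snp(scaffold, pos, classification="Other", **kw):
    base = dict(ref="A", alt="G", qd=10.0, fs=1.0, mq=60.0, dp=30.0)
    base.update(kw)
    return VariantSite(scaffold, pos, classification=classification, **base)


def dosage_of(n_hom_ref, n_het, n_hom_alt):
    return np.array([0] * n_hom_ref + [1] * n_het + [2] * n_hom_alt, dtype=np.int8)


class TestFrequencyFilter:
    def run(self, dos, cfg=SelectionConfig()):
        s = snp("s", 1)
        kept, rejected = frequency_filter([s], {s.key: dos}, cfg)
        return bool(kept), rejected

    def test_balanced_passes(self):
        assert self.run(dosage_of(10, 20, 10))[0]

    def test_p_020_fails(self):
        assert not self.run(dosage_of(26, 12, 2))[0]  # p_alt = 16/80 = 0.2

    def test_het_plus_balanced_homs_passes(self):
        # 40 animals: 28 het + 6/6 homozygotes -> p = 0.5
        assert self.run(dosage_of(6, 28, 6))[0]

    def test_monomorphic_fails(self):
        assert not self.run(dosage_of(40, 0, 0))[0]

    def test_uncalled_counted_separately(self):
        ok, rejected = self.run(np.full(40, -1, dtype=np.int8))
        assert not ok and rejected["uncalled"] == 1

    def test_maf_floor_is_strict(self):
        # p = 0.275: inside [0.25, 0.75] but not above the 0.3 floor
        dos = dosage_of(22, 14, 4)
        assert not self.run(dos)[0]
        assert self.run(dos, SelectionConfig(maf_floor=None))[0]


class TestFlankUniqueness:
    def test_neighbor_at_150_removes(self):
        cand = snp("s", 1000)
        assert flank_uniqueness_filter([cand], [cand, snp("s", 1150)]) == []

    def test_neighbor_at_exactly_200_removes(self):
        cand = snp("s", 1000)
        assert flank_uniqueness_filter([cand], [cand, snp("s", 1200)]) == []

    def test_neighbor_at_201_retains(self):
        cand = snp("s", 1000)
        assert flank_uniqueness_filter([cand], [cand, snp("s", 1201)]) == [cand]

    def test_planted_indel_neighbors(self):
        """30 candidates, 7 with an indel within 200 bp -> 23 retained."""
        candidates = [snp("s", 10_000 * (i + 1)) for i in range(30)]
        extras = [
            VariantSite("s", 10_000 * (i + 1) + 120, "AT", "A", qd=1.0)
            for i in range(7)
        ]
        kept = flank_uniqueness_filter(candidates, candidates + extras)
        assert kept == candidates[7:]

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(21)
        allv = [snp(f"c{rng.integers(3)}", int(p))
                for p in rng.choice(np.arange(1, 50_000), size=300, replace=False)]
        candidates = allv[:80]
        kept = flank_uniqueness_filter(candidates, allv)
        oracle = [
            c for c in candidates
            if not any(
                v is not c and v.scaffold == c.scaffold and abs(v.pos - c.pos) <= 200
                for v in allv
            )
        ]
        assert kept == oracle


class TestDensityRank:
    def test_isolated_candidate_scores_self_only(self):
        cand = snp("s", 1000, "Missense_Mutation")
        ranked = annotation_density_rank([cand], [cand])
        assert ranked == [(cand, 1)]

    def test_richer_window_ranks_first(self):
        a = snp("s1", 1000, "Intron")
        b = snp("s2", 1000, "Missense_Mutation")
        extras = [
            snp("s2", 2000, "Missense_Mutation"),
            snp("s2", 3000, "Nonsense_Mutation"),
            snp("s1", 2000, "Missense_Mutation"),
        ]
        ranked = annotation_density_rank([a, b], [a, b] + extras)
        assert [(s.scaffold, score) for s, score in ranked] == [("s2", 3), ("s1", 1)]

    def test_matches_brute_force_window_count(self):
        rng = np.random.default_rng(9)
        classes = ["Missense_Mutation", "Nonsense_Mutation", "Intron", "Other"]
        allv = [
            snp(f"c{rng.integers(2)}", int(rng.integers(1, 500_000)),
                classes[rng.integers(4)])
            for _ in range(400)
        ]
        candidates = allv[:60]
        cfg = SelectionConfig()
        ranked = annotation_density_rank(candidates, allv, cfg)
        for cand, score in ranked:
            brute = sum(
                1 for v in allv
                if v.scaffold == cand.scaffold
                and abs(v.pos - cand.pos) <= cfg.density_window_bp
                and v.classification in cfg.prefer_classes
            )
            assert score == brute
        scores = [s for _, s in ranked]
        assert scores == sorted(scores, reverse=True)


class TestSpacingSelect:
    def test_close_same_scaffold_pair_keeps_higher_rank(self):
        a, b = snp("s", 100_000), snp("s", 400_000)
        assert spacing_select([a, b]) == [a]

    def test_published_pair_734kb_apart_both_retained(self):
        # two panel loci on one scaffold, ~734 kb apart, at default spacing
        a = snp("NW_018657888.1", 735_326)
        b = snp("NW_018657888.1", 1_469_235)
        assert spacing_select([a, b]) == [a, b]

    def test_distinct_scaffolds_never_conflict(self):
        a, b = snp("s1", 100), snp("s2", 101)
        assert spacing_select([a, b]) == [a, b]

    def test_greedy_result_is_subset_with_spacing_property(self):
        rng = np.random.default_rng(33)
        cands = [snp(f"c{rng.integers(4)}", int(rng.integers(1, 3_000_000)))
                 for _ in range(120)]
        cfg = SelectionConfig()
        accepted = spacing_select(cands, cfg)
        keys = {c.key for c in cands}
        assert all(a.key in keys for a in accepted)
        for i, a in enumerate(accepted):
            for b in accepted[i + 1:]:
                if a.scaffold == b.scaffold:
                    assert abs(a.pos - b.pos) >= cfg.min_spacing_bp


class TestCompleteLinkagePrune:
    def prune(self, cols, positions=None):
        sites = [snp("s", (positions or range(1, len(cols) + 1))[i])
                 for i in range(len(cols))]
        dosages = {s.key: np.asarray(c, dtype=np.int8) for s, c in zip(sites, cols)}
        return sites, complete_linkage_prune(sites, dosages)

    def test_duplicated_column_pruned(self):
        col = [0, 1, 2, 1, 0, 2]
        _, (kept, removed) = self.prune([col, col, [0, 0, 1, 2, 2, 1]])
        assert len(kept) == 2 and len(removed) == 1

    def test_complementary_column_detected(self):
        col = np.array([0, 1, 2, 1, 0])
        _, (kept, removed) = self.prune([col, 2 - col])
        assert len(kept) == 1 and len(removed) == 1

    def test_tie_keeps_smallest_coordinate(self):
        col = [0, 1, 2, 1]
        sites, (kept, _) = self.prune([col, col], positions=[500, 100])
        assert kept == [sites[1]]

    def test_higher_maf_wins(self):
        a = [0, 1, 2, 1, 0, 1]          # maf 5/12
        b = [0, 1, 2, 1, 0, 1]
        c = [0, 0, 1, 0, 0, 0]          # unlinked, low maf
        sites, (kept, removed) = self.prune([a, b, c])
        assert sites[2] in kept and len(kept) == 2

    def test_matches_brute_force_all_pairs_scan(self):
        """Pruning agrees with an O(L^2) r^2 = 1 scan on random matrices."""
        rng = np.random.default_rng(17)
        n_samples, n_loci = 12, 30
        cols = rng.integers(0, 3, size=(n_loci, n_samples))
        cols[5] = cols[2]
        cols[11] = 2 - cols[7]
        cols[20] = cols[2]
        sites, (kept, removed) = self.prune([list(c) for c in cols])

        def linked(x, y):
            if np.all(x == x[0]) or np.all(y == y[0]):
                return False
            return np.array_equal(x, y) or np.array_equal(x, 2 - y)

        brute_pairs = {
            (i, j)
            for i in range(n_loci)
            for j in range(i + 1, n_loci)
            if linked(cols[i], cols[j])
        }
        # exactly one survivor per brute-force connected component
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(n_loci))
        g.add_edges_from(brute_pairs)
        kept_idx = {sites.index(s) for s in kept}
        for comp in nx.connected_components(g):
            assert len(comp & kept_idx) == 1

    def test_sparse_overlap_left_unpruned(self):
        _, (kept, removed) = self.prune([[0, -1, -1], [0, -1, -1]])
        assert len(kept) == 2 and removed == []


class TestSelectPanel:
    def test_planted_recovery_is_exact(self, variant_sim):
        """20 planted perfect loci among 100 one-fault decoys: 20/20, 0/100."""
        panel, log = select_panel(variant_sim.sites, variant_sim.dosages)
        truth = {tuple(k) for k in variant_sim.truth["perfect"]}
        assert {e.key for e in panel} == truth
        assert len(panel) == 20
        assert log.n_after_linkage == 20

    def test_order_stability(self, variant_sim):
        rng = np.random.default_rng(1)
        shuffled = list(variant_sim.sites)
        rng.shuffle(shuffled)
        a, _ = select_panel(variant_sim.sites, variant_sim.dosages)
        b, _ = select_panel(shuffled, variant_sim.dosages)
        assert [e.key for e in a] == [e.key for e in b]
        assert a.loci == b.loci

    def test_monotone_shrinking(self, variant_sim):
        _, log = select_panel(variant_sim.sites, variant_sim.dosages)
        stages = [log.n_input, log.n_after_qc, log.n_after_frequency,
                  log.n_after_flank, log.n_after_spacing, log.n_after_linkage]
        assert stages == sorted(stages, reverse=True)

    def test_all_monomorphic_raises(self):
        sites = [snp("s", 10_000 * (i + 1)) for i in range(5)]
        dosages = {s.key: dosage_of(40, 0, 0) for s in sites}
        with pytest.raises(PanelSelectionError, match="no loci met criteria"):
            select_panel(sites, dosages)


class TestOptimizePanel:
    def test_planted_failure_modes_all_deleted(self, genotyping_sim):
        sim = genotyping_sim
        final, deletions = optimize_panel(sim.panel, sim.matrix, sim.mapq)
        assert len(final) == 206
        by_rule = Counter(rule for _, rule in deletions)
        assert by_rule == {"MAPQ": 3, "monomorphic": 7, "linked": 3}
        deleted = {l for l, _ in deletions}
        assert set(sim.truth["low_mapq"]) <= deleted
        assert set(sim.truth["monomorphic"]) <= deleted
        # exactly one member of each linked pair is deleted
        for src, twin in sim.truth["linked"]:
            assert (src in deleted) != (twin in deleted)

    def test_bookkeeping_partitions_deletions(self, genotyping_sim):
        sim = genotyping_sim
        final, deletions = optimize_panel(sim.panel, sim.matrix, sim.mapq)
        assert len(final) + len(deletions) == len(sim.panel)
        assert len({l for l, _ in deletions}) == len(deletions)

    def test_clean_panel_unchanged(self):
        sim = simulate_colonies(ColonyScenario(n_loci=40, seed=5))
        final, deletions = optimize_panel(sim.panel, sim.matrix, sim.mapq)
        assert deletions == [] and final.loci == sim.panel.loci

    def test_final_ids_keep_original_numbering(self, genotyping_sim):
        sim = genotyping_sim
        final, _ = optimize_panel(sim.panel, sim.matrix, sim.mapq)
        assert set(final.loci) <= set(sim.panel.loci)
        order = {l: i for i, l in enumerate(sim.panel.loci)}
        idx = [order[l] for l in final.loci]
        assert idx == sorted(idx)
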