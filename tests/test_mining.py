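import pytest

from acrmine import (
    DomainAnnotation,
    HomologyHit,
    MarkerSet,
    MinerParams,
    SimConfig,
    accept_all_validator,
    build_association_graph,
    build_context,
    classify_aca,
    classify_acr_candidate,
    detect_fusion,
    generate_genomes,
    generate_hit_table,
    map_hits_to_genes,
    mine_candidates,
    reject_all_validator,
    search_validation_loop,
)
from acrmine.mining import audit_all
from acrmine.records import GeneRecord, GenomeAnnotation

from oracles import brute_candidates, brute_labels

PARAMS = MinerParams()


def _gene(gid, i, strand="+", aa=100, rid="r1"):
    s = 1000 * i + 1
    return GeneRecord(rid, gid, s, s + 3 * (aa + 1) - 1, strand, aa)


def _hit(fam, gid, evalue=1e-20, cov=0.95):
    return HomologyHit(fam, gid, 80.0, evalue, cov, 1, 90)


class TestMapHits:
    def _genome(self):
        return [GenomeAnnotation("r1", [_gene("g1", 0), _gene("g2", 1)])]

    def test_passing_hit_labels_gene(self):
        labels = map_hits_to_genes([_hit("F", "g1", 1e-6, 0.9)], self._genome())
        assert set(labels) == {"g1"} and set(labels["g1"]) == {"F"}

    @pytest.mark.parametrize("evalue,cov,labeled", [
        (1e-6, 0.9, True),
        (1e-3, 0.9, False),   # E-value boundary is strict
        (1e-6, 0.70, False),  # coverage boundary is strict
        (9.9e-4, 0.701, True),
    ])
    def test_strict_thresholds(self, evalue, cov, labeled):
        labels = map_hits_to_genes([_hit("F", "g1", evalue, cov)], self._genome())
        assert ("g1" in labels) is labeled

    def test_unknown_gene_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            labels = map_hits_to_genes([_hit("F", "ghost")], self._genome())
        assert labels == {}
        assert "unknown" in caplog.text

    def test_matches_brute_force_row_filter(self, default_corpus):
        _, genomes, _, _, hits, _, _ = default_corpus
        labels = map_hits_to_genes(hits, genomes)
        got = {g: set(fams) for g, fams in labels.items()}
        assert got == brute_labels(hits)


class TestBuildContext:
    def test_replicon_edge_truncates_upstream(self):
        genome = GenomeAnnotation("r1", [_gene("g1", 0), _gene("g2", 1)])
        ctx = build_context(genome.gene("g1"), genome)
        assert ctx.upstream == []
        assert [n.gene.gene_id for n in ctx.downstream] == ["g2"]

    def test_window_limits_neighbors(self):
        genome = GenomeAnnotation("r1", [_gene(f"g{i}", i) for i in range(5)])
        ctx = build_context(genome.gene("g2"), genome, window_genes=1)
        assert len(ctx.neighbors) == 2
        ctx = build_context(genome.gene("g2"), genome, window_genes=2,
                            max_intergenic_bp=10_000)
        assert len(ctx.neighbors) == 4

    def test_distant_neighbors_excluded(self):
        far = GeneRecord("r1", "g2", 50_000, 50_300, "+", 99)
        genome = GenomeAnnotation("r1", [_gene("g1", 0), far])
        ctx = build_context(genome.gene("g1"), genome, max_intergenic_bp=1000)
        assert ctx.neighbors == []

    def test_matches_exhaustive_scan(self):
        """Contexts equal a brute-force scan over the sorted gene list."""
        import numpy as np

        rng = np.random.default_rng(42)
        genes = []
        pos = 1
        for i in range(30):
            aa = int(rng.integers(50, 300))
            genes.append(GeneRecord("r1", f"g{i:02d}", pos,
                                    pos + 3 * aa - 1,
                                    "+" if rng.random() < 0.5 else "-", aa - 1))
            pos += 3 * aa + int(rng.integers(10, 2500))
        genome = GenomeAnnotation("r1", genes)
        for g in genome:
            ctx = build_context(g, genome, window_genes=2, max_intergenic_bp=1000)
            got = sorted(n.gene.gene_id for n in ctx.neighbors)
            i = genome.index_of(g.gene_id)
            want = []
            for j, other in enumerate(genome.genes):
                if j == i or abs(j - i) > 2:
                    continue
                gap = (other.start - g.end - 1) if other.start > g.end \
                    else (g.start - other.end - 1)
                if gap <= 1000:
                    want.append(other.gene_id)
            assert got == sorted(want)


class TestClassifiers:
    def _aca_setting(self, strand="+"):
        genes = [_gene("acr1", 0, "+"), _gene("aca1", 1, strand)]
        genome = GenomeAnnotation("r1", genes)
        labels = {"acr1": {"A1": [_hit("A1", "acr1")]},
                  "aca1": {"B": [_hit("B", "aca1")]}}
        domains = [DomainAnnotation("aca1", "HTH", 0.95, 5, 55)]
        graph = build_association_graph([genome], labels, {"A1"}, PARAMS)
        # corpus-wide association: pretend family B was also seen next to two
        # other Acr families at other loci
        graph.add("B", "A2", "elsewhere1")
        graph.add("B", "A3", "elsewhere2")
        ctx = build_context(genome.gene("aca1"), genome, labels=labels)
        return genome, labels, domains, graph, ctx

    def test_aca_with_all_three_criteria(self):
        genome, labels, domains, graph, ctx = self._aca_setting()
        cand = classify_aca(genome.gene("aca1"), ctx, domains, graph,
                            frozenset({"A1"}), {"B"}, PARAMS)
        assert cand is not None
        assert cand.candidate_class == "aca_candidate"
        assert cand.association_count == 3  # 3 > 2 satisfies "more than two"
        assert cand.adjacent_marker == "A1"

    def test_aca_opposite_strand_rejected(self):
        genome, labels, domains, graph, _ = self._aca_setting(strand="-")
        ctx = build_context(genome.gene("aca1"), genome, labels=labels)
        cand = classify_aca(genome.gene("aca1"), ctx, domains, graph,
                            frozenset({"A1"}), {"B"}, PARAMS)
        assert cand is None

    def test_aca_needs_more_than_two_distinct_families(self):
        genome, labels, domains, graph, ctx = self._aca_setting()
        small = build_association_graph([genome], labels, {"A1"}, PARAMS)
        assert small.distinct_acr_families("B") == 1
        cand = classify_aca(genome.gene("aca1"), ctx, domains, small,
                            frozenset({"A1"}), {"B"}, PARAMS)
        assert cand is None

    def test_acr_candidate_standard_tier(self):
        genes = [_gene("aca1", 0), _gene("cand", 1, aa=120)]
        genome = GenomeAnnotation("r1", genes)
        labels = {"aca1": {"B": [_hit("B", "aca1")]}}
        ctx = build_context(genome.gene("cand"), genome, labels=labels)
        cand = classify_acr_candidate(genome.gene("cand"), ctx, None,
                                      frozenset({"B"}), PARAMS)
        assert cand is not None and cand.confidence_tier == "standard"
        assert cand.size_ok

    def test_acr_size_boundary_strict(self):
        genes = [_gene("aca1", 0), _gene("cand", 1, aa=300)]
        genome = GenomeAnnotation("r1", genes)
        labels = {"aca1": {"B": [_hit("B", "aca1")]}}
        ctx = build_context(genome.gene("cand"), genome, labels=labels)
        assert classify_acr_candidate(genome.gene("cand"), ctx, None,
                                      frozenset({"B"}), PARAMS) is None

    def test_fusion_gives_boosted_tier(self, default_corpus):
        _, genomes, _, ledger, hits, domains, markers = default_corpus
        candidates, _ = mine_candidates(genomes, hits, domains, markers)
        boosted = {c.gene_id for c in candidates
                   if c.confidence_tier == "fusion_boosted"}
        assert boosted == {e.gene_id for e in ledger.by_class("fusion")}


class TestDetectFusion:
    def test_n_terminal_geometry(self):
        gene = GeneRecord("r1", "g1", 1, 603, "+", 200)
        call = detect_fusion(gene, [(5, 60)], PARAMS)
        assert call is not None
        assert call.terminal_side == "N"
        assert call.acr_remainder_length == 140

    def test_midpoint_straddling_interval_rejected(self):
        gene = GeneRecord("r1", "g1", 1, 603, "+", 200)
        assert detect_fusion(gene, [(60, 140)], PARAMS) is None

    def test_c_terminal_geometry(self):
        gene = GeneRecord("r1", "g1", 1, 603, "+", 200)
        call = detect_fusion(gene, [(150, 195)], PARAMS)
        assert call is not None
        assert call.terminal_side == "C"
        assert call.acr_remainder_length == 149

    def test_short_remainder_rejected(self):
        gene = GeneRecord("r1", "g1", 1, 303, "+", 100)
        # interval in N-terminal 40 aa but remainder only 30 aa
        assert detect_fusion(gene, [(5, 70)], PARAMS) is None

    def test_planted_fusions_recovered_without_false_calls(self):
        """Across seeded corpora, every planted fusion is called and no
        non-fusion gene receives a call."""
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_replicons=6, n_planted_operons=4,
                            n_fusions=2,
                            decoy_spec={"oversize": 1, "wrong_strand": 1,
                                        "non_adjacent": 1, "no_domain_aca": 0,
                                        "low_association_aca": 0})
            genomes, _, ledger = generate_genomes(cfg)
            hits = generate_hit_table(ledger, seed=seed + 1)
            labels = map_hits_to_genes(hits, genomes)
            aca_fams = frozenset(cfg.aca_families)
            called = set()
            for genome in genomes:
                for gene in genome:
                    ivs = [(h.subject_start, h.subject_end)
                           for fam, hs in labels.get(gene.gene_id, {}).items()
                           if fam in aca_fams for h in hs]
                    if detect_fusion(gene, ivs, PARAMS):
                        called.add(gene.gene_id)
            assert called == {e.gene_id for e in ledger.by_class("fusion")}


class TestAssociationGraph:
    def test_single_locus_counts_one(self):
        genome = GenomeAnnotation("r1", [_gene("a", 0), _gene("b", 1)])
        labels = {"a": {"A1": [_hit("A1", "a")]}, "b": {"B": [_hit("B", "b")]}}
        graph = build_association_graph([genome], labels, {"A1"}, PARAMS)
        assert graph.distinct_acr_families("B") == 1
        assert graph.partners("B") == {"A1": 1}

    def test_three_loci_three_distinct(self, chain_fixture):
        genomes, hits, domains, seeds = chain_fixture
        labels = map_hits_to_genes(hits, genomes)
        graph = build_association_graph(genomes, labels,
                                        {"A1", "A2", "A3"}, PARAMS)
        assert graph.distinct_acr_families("B") == 3

    def test_matches_brute_force_pair_enumeration(self, default_corpus):
        _, genomes, _, _, hits, _, markers = default_corpus
        labels = map_hits_to_genes(hits, genomes)
        graph = build_association_graph(genomes, labels, markers.acr_families,
                                        PARAMS)
        # independent enumeration
        from oracles import brute_candidates  # noqa: F401  (same module family)
        lab = brute_labels(hits)
        want: dict[str, set] = {}
        for genome in genomes:
            genes = sorted(genome.genes, key=lambda g: g.start)
            for i, g in enumerate(genes):
                own = lab.get(g.gene_id, set()) - set(markers.acr_families)
                if not own:
                    continue
                for j in (i - 1, i + 1):
                    if not (0 <= j < len(genes)):
                        continue
                    nb = genes[j]
                    gap = (nb.start - g.end - 1) if nb.start > g.end \
                        else (g.start - nb.end - 1)
                    if gap > PARAMS.max_intergenic_bp or nb.strand != g.strand:
                        continue
                    for af in lab.get(nb.gene_id, set()) & set(markers.acr_families):
                        for fam in own:
                            want.setdefault(fam, set()).add(af)
        got = {fam: set(graph.partners(fam)) for fam in graph.families()}
        assert got == want


class TestMineCandidates:
    def test_oracle_equivalence_on_random_corpora(self):
        """Miner output equals the brute-force checker of the six criteria on
        randomized noisy corpora."""
        from conftest import small_corpus

        for seed in range(15):
            cfg, genomes, ledger, hits, domains, markers = small_corpus(seed)
            candidates, _ = mine_candidates(genomes, hits, domains, markers)
            got = {(c.gene_id, c.candidate_class) for c in candidates}
            want = brute_candidates(genomes, hits, domains,
                                    cfg.acr_families, cfg.aca_families, PARAMS)
            assert got == want, f"seed {seed}"

    def test_planted_recovery_and_zero_decoys(self, default_corpus):
        _, genomes, _, ledger, hits, domains, markers = default_corpus
        candidates, _ = mine_candidates(genomes, hits, domains, markers)
        found = {(c.gene_id, c.candidate_class) for c in candidates}
        for e in ledger:
            if e.true_class in ("acr", "fusion"):
                assert (e.gene_id, "acr_candidate") in found
            elif e.true_class == "aca":
                assert (e.gene_id, "aca_candidate") in found
        reported_ids = {g for g, _ in found}
        assert not reported_ids & {e.gene_id for e in ledger.decoys()}

    def test_decoys_fail_exactly_their_tagged_criterion(self, default_corpus):
        _, genomes, _, ledger, hits, domains, markers = default_corpus
        audit = audit_all(genomes, hits, domains, markers)
        checks = {
            # tag -> (failed flag, flags that must still hold)
            "decoy:size": ("size_ok",
                           ["adjacent_any_marker", "orientation_ok_any"]),
            "decoy:strand": ("orientation_ok_any",
                             ["size_ok", "adjacent_any_marker"]),
            "decoy:adjacency": ("adjacent_any_marker", ["size_ok"]),
            "decoy:no_domain": ("has_dna_binding_domain",
                                ["adjacent_acr_marker", "orientation_ok_acr"]),
        }
        for e in ledger.decoys():
            a = audit[e.gene_id]
            if e.true_class == "decoy:low_association":
                assert a["association_count"] <= 2
                assert a["has_dna_binding_domain"]
                assert a["adjacent_acr_marker"] and a["orientation_ok_acr"]
                continue
            failed, held = checks[e.true_class]
            assert not a[failed], (e.true_class, a)
            for flag in held:
                assert a[flag], (e.true_class, flag, a)
            if e.true_class == "decoy:no_domain":
                assert a["association_count"] > 2

    def test_strand_symmetry(self, default_corpus):
        """Reverse-complementing every replicon leaves the candidate set
        invariant."""
        _, genomes, _, _, hits, domains, markers = default_corpus
        c1, _ = mine_candidates(genomes, hits, domains, markers)
        flipped = [g.reverse_complement() for g in genomes]
        c2, _ = mine_candidates(flipped, hits, domains, markers)
        as_set = lambda cs: {(c.gene_id, c.candidate_class) for c in cs}
        assert as_set(c1) == as_set(c2)


class TestSearchValidationLoop:
    def test_reject_all_halts_after_first_iteration(self, chain_fixture):
        genomes, hits, domains, seeds = chain_fixture
        markers, ledger, audit = search_validation_loop(
            seeds, genomes, hits, domains, reject_all_validator)
        assert len(audit) == 1
        assert markers.families == seeds.families

    def test_two_hop_chain_adopts_second_family_at_iteration_two(
            self, chain_fixture):
        genomes, hits, domains, seeds = chain_fixture
        markers, ledger, audit = search_validation_loop(
            seeds, genomes, hits, domains, accept_all_validator)
        assert "B" in markers.aca_families
        assert markers.iteration_of("B") == 1
        assert "A4" in markers.acr_families
        assert markers.iteration_of("A4") == 2

    def test_marker_growth_is_monotone(self, chain_fixture):
        genomes, hits, domains, seeds = chain_fixture
        _, _, audit = search_validation_loop(
            seeds, genomes, hits, domains, accept_all_validator)
        counts = [a["marker_count"] for a in audit]
        assert counts == sorted(counts)

    def test_empty_seed_rejected(self, chain_fixture):
        genomes, hits, domains, _ = chain_fixture
        with pytest.raises(ValueError):
            search_validation_loop(MarkerSet(), genomes, hits, domains,
                                   accept_all_validator)

    def test_truth_validator_blocks_background(self, default_corpus):
        """With the truth-ledger validator, adopted families never come from
        decoy or background genes."""
        from acrmine import truth_ledger_validator

        cfg, genomes, _, ledger, hits, domains, _ = default_corpus
        seeds = MarkerSet.from_families(acr=cfg.acr_families[:3])
        markers, cands, audit = search_validation_loop(
            seeds, genomes, hits, domains, truth_ledger_validator(ledger))
        planted_fams = {e.family for e in ledger if e.family} | {
            e.acr_family for e in ledger.by_class("fusion")} | {
            e.aca_family for e in ledger.by_class("fusion")}
        assert markers.families <= {f for f in planted_fams if f and "+" not in f}
        assert not markers.families & {"acaND01", "acaLOW01"}
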