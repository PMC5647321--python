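"""Anchor loading, chain DP (with exhaustive oracle) and block aggregation."""

import itertools

import numpy as np
import pytest

from paleoploid.simulate import DivergenceEvent, SimulationConfig, build_genome_set
from paleoploid.synteny import (
    Anchor,
    ChainParams,
    SyntenicBlock,
    block_4dtv,
    chain_all,
    chain_anchors,
    gene_ranks_from_gff,
    load_hits,
)

PARAMS = ChainParams(max_gap=3, min_anchors=3, gap_penalty=1.0, anchor_score=10.0)


def mk_anchors(pairs, chrom_a="a1", chrom_b="b1"):
    return [Anchor(f"ga{ra}", f"gb{rb}", chrom_a, chrom_b, ra, rb) for ra, rb in pairs]


def brute_force_best_score(anchors, params):
    """Exhaustive maximum chain score over all ordered anchor subsets."""
    best = 0.0
    order = sorted(anchors, key=lambda a: (a.rank_a, a.rank_b))
    n = len(order)
    for size in range(1, n + 1):
        for subset in itertools.combinations(range(n), size):
            for sign in (1, -1):
                chain = [order[i] for i in subset]
                ok = True
                score = params.anchor_score
                for x, y in zip(chain, chain[1:]):
                    da = y.rank_a - x.rank_a
                    db = sign * (y.rank_b - x.rank_b)
                    if da < 1 or db < 1 or da - 1 > params.max_gap or db - 1 > params.max_gap:
                        ok = False
                        break
                    score += params.anchor_score - params.gap_penalty * ((da - 1) + (db - 1))
                if ok:
                    best = max(best, score)
    return best


class TestLoadHits:
    @pytest.fixture()
    def annotated_pair(self, tmp_path):
        gff_a = tmp_path / "a.gff3"
        gff_a.write_text("##gff-version 3\n" + "\n".join(
            f"chrA\tx\tgene\t{100 * i + 1}\t{100 * i + 50}\t.\t+\t.\tID=a{i}"
            for i in range(1, 4)) + "\n")
        gff_b = tmp_path / "b.gff3"
        gff_b.write_text("##gff-version 3\n" + "\n".join(
            f"chrB\tx\tgene\t{100 * i + 1}\t{100 * i + 50}\t.\t+\t.\tID=b{i}"
            for i in range(1, 4)) + "\n")
        return gff_a, gff_b

    def write_hits(self, tmp_path, rows):
        path = tmp_path / "hits.tsv"
        header = "qid\tsid\tpident\tlength\tqchrom\tqstart\tqend\tschrom\tsstart\tsend\n"
        path.write_text(header + "".join(
            f"{q}\t{s}\t{p}\t50\tchrA\t1\t50\tchrB\t1\t50\n" for q, s, p in rows))
        return path

    def test_ranks_follow_coordinate_order(self, tmp_path, annotated_pair):
        gff_a, gff_b = annotated_pair
        hits = self.write_hits(tmp_path, [("a1", "b1", 90), ("a2", "b2", 91),
                                          ("a3", "b3", 92)])
        anchors = sorted(load_hits(hits, gff_a, gff_b), key=lambda a: a.rank_a)
        assert [(a.rank_a, a.rank_b) for a in anchors] == [(0, 0), (1, 1), (2, 2)]

    def test_duplicate_rows_keep_best_score(self, tmp_path, annotated_pair):
        gff_a, gff_b = annotated_pair
        hits = self.write_hits(tmp_path, [("a1", "b1", 80), ("a1", "b1", 95)])
        anchors = load_hits(hits, gff_a, gff_b)
        assert len(anchors) == 1
        assert anchors[0].score == 95

    def test_unknown_id_raises_with_name(self, tmp_path, annotated_pair):
        gff_a, gff_b = annotated_pair
        hits = self.write_hits(tmp_path, [("a1", "nope", 80)])
        with pytest.raises(ValueError, match="nope"):
            load_hits(hits, gff_a, gff_b)

    def test_gene_ranks_reset_per_chromosome(self, tmp_path):
        gff = tmp_path / "two_chrom.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "c1\tx\tgene\t1\t50\t.\t+\t.\tID=g1\n"
            "c1\tx\tgene\t100\t150\t.\t+\t.\tID=g2\n"
            "c2\tx\tgene\t1\t50\t.\t+\t.\tID=g3\n"
        )
        ranks = gene_ranks_from_gff(gff)
        assert ranks == {"g1": ("c1", 0), "g2": ("c1", 1), "g3": ("c2", 0)}


class TestChaining:
    def test_perfect_collinear_run(self):
        blocks = chain_anchors(mk_anchors([(i, i) for i in range(1, 6)]), PARAMS)
        assert len(blocks) == 1
        assert len(blocks[0]) == 5
        assert blocks[0].orientation == "same"

    def test_inverted_block(self):
        blocks = chain_anchors(mk_anchors([(i, 10 - i) for i in range(1, 6)]), PARAMS)
        assert len(blocks) == 1
        assert len(blocks[0]) == 5
        assert blocks[0].orientation == "inverted"

    def test_outlier_anchor_excluded(self):
        # (4,10) breaks collinearity beyond max_gap; best chain skips it
        anchors = mk_anchors([(1, 1), (2, 2), (3, 3), (4, 10), (5, 4)])
        blocks = chain_anchors(anchors, PARAMS)
        assert len(blocks) == 1
        got = [(a.rank_a, a.rank_b) for a in blocks[0].anchors]
        assert got == [(1, 1), (2, 2), (3, 3), (5, 4)]
        assert blocks[0].block_score == brute_force_best_score(anchors, PARAMS) == 39.0

    def test_empty_input(self):
        assert chain_anchors([], PARAMS) == []

    def test_min_anchors_filters_short_chains(self):
        blocks = chain_anchors(mk_anchors([(1, 1), (2, 2)]), PARAMS)
        assert blocks == []

    def test_first_chain_matches_exhaustive_optimum(self):
        # ranks unique on both axes, matching the post-collapse anchor sets
        # the DP actually operates on
        rng = np.random.default_rng(20)
        params = ChainParams(max_gap=4, min_anchors=2, gap_penalty=1.0, anchor_score=10.0)
        for _ in range(40):
            n = int(rng.integers(3, 11))
            ra = rng.choice(14, size=n, replace=False)
            rb = rng.choice(14, size=n, replace=False)
            anchors = mk_anchors(sorted(zip(ra.tolist(), rb.tolist())))
            blocks = chain_anchors(anchors, params)
            best = brute_force_best_score(anchors, params)
            if blocks:
                assert blocks[0].block_score == pytest.approx(best)
            else:
                # only chains below min_anchors existed; their score must not
                # beat a single anchor pair's baseline
                assert best <= 2 * params.anchor_score

    def test_antisymmetry_under_genome_swap(self):
        rng = np.random.default_rng(7)
        pairs = sorted({(int(rng.integers(0, 20)), int(rng.integers(0, 20)))
                        for _ in range(15)})
        fwd = chain_anchors(mk_anchors(pairs), PARAMS)
        swapped = [Anchor(a.gene_b, a.gene_a, a.chrom_b, a.chrom_a,
                          a.rank_b, a.rank_a, a.score)
                   for a in mk_anchors(pairs)]
        rev = chain_anchors(swapped, PARAMS)
        fwd_sets = sorted(frozenset((x.rank_a, x.rank_b) for x in b.anchors)
                          for b in fwd)
        rev_sets = sorted(frozenset((x.rank_b, x.rank_a) for x in b.anchors)
                          for b in rev)
        assert fwd_sets == rev_sets

    def test_single_chromosome_pair_enforced(self):
        anchors = mk_anchors([(1, 1)]) + mk_anchors([(2, 2)], chrom_a="a2")
        with pytest.raises(ValueError):
            chain_anchors(anchors, PARAMS)


class TestOnSimulatedGenomes:
    def test_lossfree_wgd_yields_one_block_per_chromosome_pair(self, single_wgd_config):
        gs = build_genome_set(single_wgd_config)
        anchors = _anchors_from_genome_set(gs)
        blocks = chain_all(anchors, ChainParams())
        # 10 chromosomes per subgenome copy, one block per homologous pair
        assert len(blocks) == 10
        assert all(len(b) == 10 for b in blocks)
        covered = {(a.gene_a, a.gene_b) for b in blocks for a in b.anchors}
        assert len(covered) == 100

    def test_decoy_hits_do_not_break_anchor_recovery(self):
        cfg = SimulationConfig(
            n_genes=200, codons_per_gene=10, loss_prob=0.0, seed=21,
            genes_per_chromosome=20, events=(DivergenceEvent("wgd", 0.05),),
            decoys=True,
        )
        gs = build_genome_set(cfg)
        truth_pairs = {tuple(sorted((r.gene_a, r.gene_b)))
                       for r in gs.truth.pairs.itertuples(index=False)}
        anchors = _anchors_from_genome_set(gs)
        blocks = chain_all(anchors, ChainParams())
        in_blocks = {tuple(sorted((a.gene_a, a.gene_b)))
                     for b in blocks for a in b.anchors}
        recovered = len(truth_pairs & in_blocks) / len(truth_pairs)
        assert recovered >= 0.95


class TestBlockAggregation:
    def mk_block(self, n):
        return SyntenicBlock(
            anchors=tuple(Anchor(f"a{i}", f"b{i}", "c1", "c2", i, i)
                          for i in range(n)),
            orientation="same", chrom_a="c1", chrom_b="c2", block_score=10.0 * n,
        )

    def test_median_of_odd_count(self):
        b = block_4dtv(self.mk_block(3), {("a0", "b0"): 0.1, ("a1", "b1"): 0.2,
                                          ("a2", "b2"): 0.3})
        assert b.block_4dtv == pytest.approx(0.2)

    def test_single_value(self):
        b = block_4dtv(self.mk_block(1), {("a0", "b0"): 0.042})
        assert b.block_4dtv == pytest.approx(0.042)

    def test_even_count_median_interpolates(self):
        vals = {(f"a{i}", f"b{i}"): v for i, v in enumerate([0.1, 0.2, 0.3, 0.4])}
        b = block_4dtv(self.mk_block(4), vals)
        assert b.block_4dtv == pytest.approx(0.25)

    def test_reversed_key_order_is_found(self):
        b = block_4dtv(self.mk_block(1), {("b0", "a0"): 0.07})
        assert b.block_4dtv == pytest.approx(0.07)

    def test_no_defined_values_flags_block(self):
        b = block_4dtv(self.mk_block(2), {("a0", "b0"): float("nan")})
        assert b.block_4dtv is None

    def test_mean_aggregate_option(self):
        vals = {(f"a{i}", f"b{i}"): v for i, v in enumerate([0.0, 0.1, 0.5])}
        b = block_4dtv(self.mk_block(3), vals, aggregate="mean")
        assert b.block_4dtv == pytest.approx(0.2)


def _anchors_from_genome_set(gs):
    """Rank-bearing anchors straight from simulator output (no files)."""
    ranks = {}
    for recs in gs.genes.values():
        per_chrom = {}
        for r in recs:
            per_chrom.setdefault(r.chrom, []).append(r)
        for chrom, group in per_chrom.items():
            for i, r in enumerate(sorted(group, key=lambda g: g.start)):
                ranks[r.gene_id] = (chrom, i)
    return [
        Anchor(t.qid, t.sid, ranks[t.qid][0], ranks[t.sid][0],
               ranks[t.qid][1], ranks[t.sid][1], score=t.pident)
        for t in gs.hits.itertuples(index=False)
    ]
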