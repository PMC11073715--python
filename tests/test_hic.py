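"""Hi-C graph, compartments, target regions and comparison statistics."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from lnct3d import hic
from oracles import fisher_two_oracle, hop_counts_oracle


def _hic_row(chrom, a, b, pairs, q):
    return dict(chrom=chrom, bin_i_start=a, bin_j_start=b,
                read_pairs=pairs, q_value=q)


class TestFilterHic:
    def test_threshold_boundaries(self):
        df = pd.DataFrame([
            _hic_row("chr1", 0, 10_000, 4, 0.001),    # too few pairs
            _hic_row("chr1", 0, 20_000, 5, 0.05),     # inclusive keep
            _hic_row("chr1", 0, 30_000, 50, 0.051),   # q too high
        ])
        g = hic.filter_hic(df)
        assert set(g.edges) == {(("chr1", 0), ("chr1", 20_000))}

    def test_duplicates_collapsed_by_summing_before_filter(self):
        df = pd.DataFrame([
            _hic_row("chr1", 0, 10_000, 3, 0.01),
            _hic_row("chr1", 10_000, 0, 3, 0.02),  # same unordered pair
        ])
        g = hic.filter_hic(df)
        assert g.number_of_edges() == 1
        e = g.edges[("chr1", 0), ("chr1", 10_000)]
        assert e["read_pairs"] == 6 and e["q_value"] == 0.01

    def test_self_loops_dropped(self):
        df = pd.DataFrame([_hic_row("chr1", 0, 0, 50, 0.001)])
        assert hic.filter_hic(df).number_of_edges() == 0

    def test_malformed_rows_reported_with_lines(self):
        df = pd.DataFrame([
            _hic_row("chr1", 0, 10_000, 9, 0.01),
            _hic_row("chr1", -5, 10_000, 9, 0.01),
        ])
        with pytest.raises(hic.MalformedTableError, match="3"):
            hic.filter_hic(df)
        with pytest.raises(hic.MalformedTableError, match="missing"):
            hic.filter_hic(df.drop(columns=["q_value"]))

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(4)
        rows = [
            _hic_row("chr1", int(a) * 10_000, int(b) * 10_000,
                     int(rng.integers(1, 12)), float(rng.uniform(0, 0.2)))
            for a, b in rng.integers(0, 30, size=(300, 2)) if a != b
        ]
        df = pd.DataFrame(rows)
        g = hic.filter_hic(df)
        # brute force: aggregate then filter
        agg: dict = {}
        for r in rows:
            key = ("chr1", min(r["bin_i_start"], r["bin_j_start"]),
                   max(r["bin_i_start"], r["bin_j_start"]))
            pairs, q = agg.get(key, (0, 1.0))
            agg[key] = (pairs + r["read_pairs"], min(q, r["q_value"]))
        want = {
            (("chr1", a), ("chr1", b))
            for (_, a, b), (pairs, q) in agg.items()
            if pairs >= 5 and q <= 0.05
        }
        got = {tuple(sorted(e)) for e in g.edges}
        assert got == {tuple(sorted(e)) for e in want}


class TestReassignCompartments:
    def _eigs(self, values, chrom="chr1"):
        return pd.DataFrame([
            (chrom, i * 1_000_000, (i + 1) * 1_000_000, v)
            for i, v in enumerate(values)
        ], columns=["chrom", "start", "end", "eigenvalue"])

    def test_consistent_signs_unchanged(self):
        eigs = self._eigs([1.0, -1.0])
        expr = {("chr1", 0): 10.0, ("chr1", 1_000_000): 2.0}
        cm = hic.reassign_compartments(eigs, expr)
        assert cm.segments.label.tolist() == ["A", "B"]
        assert cm.segments.eigenvalue.tolist() == [1.0, -1.0]

    def test_flip_when_negative_side_outexpresses(self):
        eigs = self._eigs([1.0, -1.0])
        expr = {("chr1", 0): 2.0, ("chr1", 1_000_000): 10.0}
        cm = hic.reassign_compartments(eigs, expr)
        assert cm.segments.label.tolist() == ["B", "A"]
        assert cm.segments.eigenvalue.tolist() == [-1.0, 1.0]

    def test_idempotent(self):
        eigs = self._eigs([0.5, -2.0, 1.5])
        expr = {("chr1", 0): 1.0, ("chr1", 1_000_000): 9.0,
                ("chr1", 2_000_000): 2.0}
        cm1 = hic.reassign_compartments(eigs, expr)
        cm2 = hic.reassign_compartments(cm1.segments.drop(columns="label"),
                                        expr)
        pd.testing.assert_frame_equal(cm1.segments, cm2.segments)

    def test_post_condition_a_expression_at_least_b(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            vals = rng.normal(size=6)
            eigs = self._eigs(list(vals))
            expr = {("chr1", i * 1_000_000): float(rng.uniform(0, 10))
                    for i in range(6)}
            cm = hic.reassign_compartments(eigs, expr)
            seg = cm.segments
            mean_a = np.mean([expr[("chr1", s)] for s in
                              seg[seg.label == "A"].start]) \
                if (seg.label == "A").any() else 0.0
            mean_b = np.mean([expr[("chr1", s)] for s in
                              seg[seg.label == "B"].start]) \
                if (seg.label == "B").any() else 0.0
            assert mean_a >= mean_b

    def test_all_zero_chromosome_undefined(self):
        cm = hic.reassign_compartments(self._eigs([0.0, 0.0]), {})
        assert set(cm.segments.label) == {"undefined"}
        assert cm.compartment_interval("chr1", 500) is None

    def test_compartment_interval_merges_contiguous_runs(self):
        eigs = self._eigs([1.0, 2.0, -1.0, 3.0])
        cm = hic.reassign_compartments(
            eigs, {("chr1", i * 1_000_000): 5.0 - i for i in range(4)}
        )
        assert cm.compartment_interval("chr1", 1_500_000) == (0, 2_000_000)
        assert cm.compartment_interval("chr1", 3_100_000) == \
            (3_000_000, 4_000_000)


class TestDegreeOfSeparation:
    def test_source_is_degree_zero(self):
        g = nx.Graph()
        g.add_edge(("chr1", 0), ("chr1", 10_000))
        assert hic.degree_of_separation(g, ("chr1", 0), ("chr1", 0)) == 0

    def test_direct_edge_is_one(self):
        g = nx.Graph()
        g.add_edge(("chr1", 0), ("chr1", 10_000))
        assert hic.degree_of_separation(g, ("chr1", 0), ("chr1", 10_000)) == 1

    def test_cap_and_unreachable(self):
        g = nx.path_graph([("chr1", i * 10_000) for i in range(6)])
        assert hic.degree_of_separation(
            g, ("chr1", 0), ("chr1", 50_000), max_k=3
        ) == hic.UNREACHABLE
        assert hic.degree_of_separation(
            g, ("chr1", 0), ("chr1", 50_000), max_k=5
        ) == 5

    def test_matches_bfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(6)
        for trial in range(100):
            n = int(rng.integers(5, 50))
            nodes = [("chr1", i * 10_000) for i in range(n)]
            edges = [
                (nodes[int(a)], nodes[int(b)])
                for a, b in rng.integers(0, n, size=(2 * n, 2)) if a != b
            ]
            g = nx.Graph(edges)
            src = nodes[int(rng.integers(0, n))]
            want = hop_counts_oracle(edges, src, max_k=4)
            for t in nodes:
                got = hic.degree_of_separation(g, src, t, max_k=4)
                expect = want.get(t, hic.UNREACHABLE) if t != src else 0
                assert got == expect

    def test_metric_properties_on_component(self):
        rng = np.random.default_rng(7)
        n = 30
        nodes = [("chr1", i * 10_000) for i in range(n)]
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b in rng.integers(0, n, size=(60, 2)):
            if a != b:
                g.add_edge(nodes[int(a)], nodes[int(b)])
        comp = max(nx.connected_components(g), key=len)
        comp = sorted(comp)[:8]
        K = len(comp) + 2
        for u in comp:
            for v in comp:
                duv = hic.degree_of_separation(g, u, v, max_k=K)
                dvu = hic.degree_of_separation(g, v, u, max_k=K)
                assert duv == dvu  # symmetry
                for w in comp:  # triangle inequality
                    duw = hic.degree_of_separation(g, u, w, max_k=K)
                    dwv = hic.degree_of_separation(g, w, v, max_k=K)
                    assert duv <= duw + dwv


class TestDefineTargetRegions:
    def _compartments(self):
        eigs = pd.DataFrame([
            ("chr1", 0, 1_000_000, 1.0),
            ("chr1", 1_000_000, 2_000_000, -1.0),
        ], columns=["chrom", "start", "end", "eigenvalue"])
        return hic.reassign_compartments(
            eigs, {("chr1", 0): 9.0, ("chr1", 1_000_000): 1.0}
        )

    def test_k_zero_is_empty(self):
        g = nx.Graph()
        g.add_edge(("chr1", 0), ("chr1", 10_000))
        regions = hic.define_target_regions(
            "L1", ("chr1", 500), g, self._compartments(), k=0
        )
        assert regions.bins == set()

    def test_reference_bin_excluded(self):
        g = nx.Graph()
        g.add_edge(("chr1", 0), ("chr1", 10_000))
        g.add_edge(("chr1", 10_000), ("chr1", 0))
        regions = hic.define_target_regions(
            "L1", ("chr1", 500), g, self._compartments()
        )
        assert ("chr1", 0) not in regions.bins
        assert regions.bin_degrees[("chr1", 10_000)] == 1

    def test_path_constraint_blocks_leakage_through_outside_bins(self):
        # ref(0) -- outside(1.5 Mb, in B) -- inside(20 kb): the inside bin
        # is only reachable through excluded territory
        g = nx.Graph()
        g.add_edge(("chr1", 0), ("chr1", 1_500_000))
        g.add_edge(("chr1", 1_500_000), ("chr1", 20_000))
        cm = self._compartments()
        path = hic.define_target_regions("L1", ("chr1", 500), g, cm,
                                         constrain="path")
        assert path.bins == set()
        ends = hic.define_target_regions("L1", ("chr1", 500), g, cm,
                                         constrain="endpoints")
        assert ends.bins == {("chr1", 20_000)}

    def test_padding_admits_bins_just_outside_compartment(self):
        g = nx.Graph()
        # compartment A = [0, 1 Mb); pad 100 kb admits bins < 1.1 Mb
        g.add_edge(("chr1", 0), ("chr1", 1_050_000))
        g.add_edge(("chr1", 0), ("chr1", 1_200_000))
        regions = hic.define_target_regions(
            "L1", ("chr1", 500), g, self._compartments()
        )
        assert regions.bins == {("chr1", 1_050_000)}
        assert regions.compartment_interval == (-100_000, 1_100_000)

    def test_unlabeled_compartment_raises(self):
        eigs = pd.DataFrame(
            [("chr1", 0, 1_000_000, 0.0)],
            columns=["chrom", "start", "end", "eigenvalue"],
        )
        cm = hic.reassign_compartments(eigs, {})
        with pytest.raises(hic.UnlabeledCompartmentError):
            hic.define_target_regions("L1", ("chr1", 500), nx.Graph(), cm)

    def test_recovers_planted_scaffold(self, world, hic_table):
        from lnct3d.hic import (
            filter_hic,
            reassign_compartments,
            segment_expression_from_promoters,
        )

        g = filter_hic(hic_table)
        prom_pos = {p.promoter_id: (p.chrom, p.pos)
                    for gm in world.genes for p in gm.promoters}
        seg_expr = segment_expression_from_promoters(
            world.expression, prom_pos
        )
        cm = reassign_compartments(world.eigenvalues, seg_expr)
        strongest = world.strongest_promoters()
        for gid, bins in world.planted_target_bins.items():
            p = strongest[gid]
            regions = hic.define_target_regions(
                gid, (p.chrom, p.pos), g, cm
            )
            assert bins <= regions.bins

    def test_invariant_to_edge_insertion_order(self):
        rng = np.random.default_rng(8)
        edges = [
            (("chr1", int(a) * 10_000), ("chr1", int(b) * 10_000))
            for a, b in rng.integers(0, 80, size=(120, 2)) if a != b
        ]
        cm = self._compartments()
        g1 = nx.Graph(edges)
        g2 = nx.Graph(edges[::-1])
        r1 = hic.define_target_regions("L1", ("chr1", 500), g1, cm)
        r2 = hic.define_target_regions("L1", ("chr1", 500), g2, cm)
        assert r1.bin_degrees == r2.bin_degrees


class TestMapTargetGenes:
    def _regions(self, bins):
        return hic.TargetRegionSet(
            "L1", ("chr1", 0), (0, 1_000_000),
            {b: 1 for b in bins},
        )

    def test_counts_each_feature_in_bin(self):
        regions = self._regions({("chr1", 50_000)})
        promoters = {"gA": ("chr1", 51_000), "gB": ("chr1", 52_000),
                     "gC": ("chr1", 70_000)}
        enh = pd.DataFrame(
            [("e1", "chr1", 55_000, 55_400), ("e2", "chr1", 95_000, 95_400)],
            columns=["enhancer_id", "chrom", "start", "end"],
        )
        genes, enhancers = hic.map_target_genes(regions, promoters, enh)
        assert genes == ["gA", "gB"] and enhancers == ["e1"]

    def test_empty_region_set(self):
        genes, enhancers = hic.map_target_genes(
            self._regions(set()), {"gA": ("chr1", 0)},
            pd.DataFrame(columns=["enhancer_id", "chrom", "start", "end"]),
        )
        assert genes == [] and enhancers == []

    def test_enhancer_straddling_bin_boundary_counted(self):
        regions = self._regions({("chr1", 10_000)})
        enh = pd.DataFrame([("e1", "chr1", 9_900, 10_100)],
                           columns=["enhancer_id", "chrom", "start", "end"])
        _, enhancers = hic.map_target_genes(regions, {}, enh)
        assert enhancers == ["e1"]


class TestComparisonStatistics:
    def _chain(self, n=6):
        return nx.path_graph([("chr1", i * 10_000) for i in range(n)])

    def test_degree_cdf_monotone_with_unreachable_residual(self):
        g = self._chain()
        sig = {"L1": {("chr1", 10_000), ("chr1", 30_000), ("chr2", 0)}}
        refs = {"L1": ("chr1", 0)}
        cdf = hic.degree_cdf(sig, refs, g, max_k=4)
        vals = cdf[cdf.degree >= 0].cumulative_fraction.tolist()
        assert vals == sorted(vals)
        assert cdf[cdf.degree == 3].cumulative_fraction.iloc[0] == \
            pytest.approx(2 / 3)
        unreach = cdf[cdf.degree == hic.UNREACHABLE]
        assert unreach.cumulative_fraction.iloc[0] == pytest.approx(1 / 3)

    def test_degree_cdf_empty_inputs(self):
        out = hic.degree_cdf({}, {}, nx.Graph())
        assert out.empty

    def test_sens_spec_confusion_matrix_oracle(self):
        rng = np.random.default_rng(9)
        n = 40
        nodes = [("chr1", i * 10_000) for i in range(n)]
        g = nx.Graph(
            (nodes[int(a)], nodes[int(b)])
            for a, b in rng.integers(0, n, size=(70, 2)) if a != b
        )
        universe = set(nodes)
        sig = set(rng.choice(n, size=10, replace=False))
        sig = {nodes[i] for i in sig}
        ref = nodes[0]
        out = hic.sensitivity_specificity_by_degree(sig, ref, g, universe,
                                                    max_k=3)
        reach = hop_counts_oracle(list(g.edges), ref, 3)
        for r in out.itertuples():
            within = {b for b in universe
                      if reach.get(b, 99) <= r.degree}
            tp = len(sig & within)
            fp = len((universe - sig) & within)
            assert r.sensitivity == pytest.approx(tp / len(sig))
            assert r.one_minus_specificity == pytest.approx(
                fp / len(universe - sig)
            )

    def test_sens_spec_requires_universe_superset(self):
        g = self._chain()
        with pytest.raises(ValueError):
            hic.sensitivity_specificity_by_degree(
                {("chr1", 0)}, ("chr1", 0), g, set(), max_k=1
            )

    def test_enrichment_planted_signal_and_randomization(self, world,
                                                         hic_table, called):
        _, _, sig = called
        g = hic.filter_hic(hic_table)
        strongest = world.strongest_promoters()
        gid = sorted(world.planted_target_bins)[0]
        p = strongest[gid]
        ref = (p.chrom, (p.pos // 10_000) * 10_000)
        bins = {(s.chrom, s.bin_start) for s in sig if s.gene_id == gid}
        universe = {n for n in g.nodes if n[0] == p.chrom} | bins
        res = hic.hic_support_enrichment(bins, ref, g, universe, k=2)
        assert res.odds_ratio > 1 and res.p_value < 0.01
        rnd = hic.hic_support_enrichment(bins, ref, g, universe, k=2,
                                         randomize=True, seed=0)
        assert rnd.p_value > res.p_value

    def test_enrichment_matches_exact_fisher_oracle(self):
        g = self._chain()
        universe = set(g.nodes)
        sig = {("chr1", 10_000), ("chr1", 20_000)}
        res = hic.hic_support_enrichment(sig, ("chr1", 0), g, universe, k=2)
        (a, b), (c, d) = res.table
        assert res.p_value == pytest.approx(fisher_two_oracle(a, b, c, d),
                                            rel=1e-9)

    def test_enrichment_degenerate_table(self):
        g = self._chain()
        universe = set(g.nodes)
        res = hic.hic_support_enrichment(set(), ("chr1", 0), g, universe)
        assert math.isnan(res.odds_ratio) and res.p_value == 1.0

    def test_linear_distances_and_compartment_flags(self):
        eigs = pd.DataFrame([
            ("chr1", 0, 1_000_000, 1.0),
            ("chr1", 1_000_000, 2_000_000, -1.0),
            ("chr1", 2_000_000, 3_000_000, 1.0),
            ("chr1", 3_000_000, 4_000_000, -1.0),
        ], columns=["chrom", "start", "end", "eigenvalue"])
        cm = hic.reassign_compartments(
            eigs, {("chr1", 0): 9, ("chr1", 1_000_000): 1,
                   ("chr1", 2_000_000): 8, ("chr1", 3_000_000): 2}
        )
        out = hic.linear_distance_stats(
            [("L1", ("chr1", 3_000_000)), ("L1", ("chr1", 2_000_000)),
             ("L1", ("chr1", 0))],
            {"L1": ("chr1", 1_005_000)}, cm,
        )
        by_bin = out.set_index("bin_start")
        # midpoint convention: |3,005,000 - 1,005,000|
        assert by_bin.loc[3_000_000, "distance_bp"] == 2_000_000
        # promoter (1.005 Mb) sits in B; 3.005 Mb is B, 2.005 Mb and 5 kb are A
        assert bool(by_bin.loc[3_000_000, "same_compartment"])
        assert not by_bin.loc[2_000_000, "same_compartment"]
        assert not by_bin.loc[0, "same_compartment"]

    def test_distance_within_bin_is_small(self):
        eigs = pd.DataFrame([("chr1", 0, 1_000_000, 1.0)],
                            columns=["chrom", "start", "end", "eigenvalue"])
        cm = hic.reassign_compartments(eigs, {("chr1", 0): 1.0})
        out = hic.linear_distance_stats(
            [("L1", ("chr1", 40_000))], {"L1": ("chr1", 42_000)}, cm
        )
        assert out.distance_bp.iloc[0] < 10_000


def test_differential_hic_filter_thresholds():
    df = pd.DataFrame({
        "log2fc": [1.0, -1.2, 0.9, 2.0],
        "fdr": [0.1, 0.05, 0.01, 0.2],
    })
    out = hic.apply_differential_hic_filter(df)
    assert out.log2fc.tolist() == [1.0, -1.2]
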