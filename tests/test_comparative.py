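import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tomoevo import comparative as comp
from tomoevo.io_formats import ValidationError
from tomoevo.spatial import RegionProfile

from conftest import hit_frame


def exact_fisher_two_sided(a, b, c, d):
    """Independent oracle: exact-integer probability-ordering enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {x: math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)}
    obs = weights[a]
    total = sum(weights.values())
    return sum(w for w in weights.values() if w <= obs * (1 + 1e-7)) / total


class TestFisherExact:
    @pytest.mark.parametrize("table,expected", [
        ([[0, 0], [0, 0]], 1.0),
        ([[1, 1], [1, 1]], 1.0),
        ([[3, 0], [0, 3]], 0.1),  # 2 of the C(6,3)=20 equally-margined tables
    ])
    def test_known_values(self, table, expected):
        _, p = comp.fisher_exact_2x2(table)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_matches_enumeration_oracle(self):
        _, p = comp.fisher_exact_2x2([[2, 7], [8, 2]])
        assert p == pytest.approx(exact_fisher_two_sided(2, 7, 8, 2), abs=1e-12)

    @given(st.tuples(*[st.integers(0, 25)] * 4))
    @settings(max_examples=200, deadline=None)
    def test_random_tables_match_oracle(self, cells):
        a, b, c, d = cells
        _, p = comp.fisher_exact_2x2([[a, b], [c, d]])
        assert p == pytest.approx(exact_fisher_two_sided(a, b, c, d), abs=1e-12)

    @given(st.tuples(*[st.integers(0, 40)] * 4))
    @settings(max_examples=100, deadline=None)
    def test_matches_scipy(self, cells):
        from scipy.stats import fisher_exact
        a, b, c, d = cells
        _, p = comp.fisher_exact_2x2([[a, b], [c, d]])
        assert p == pytest.approx(fisher_exact([[a, b], [c, d]])[1], rel=1e-7, abs=1e-12)

    def test_one_sided_greater(self):
        from scipy.stats import fisher_exact
        _, p = comp.fisher_exact_2x2([[8, 2], [3, 9]], alternative="greater")
        assert p == pytest.approx(
            fisher_exact([[8, 2], [3, 9]], alternative="greater")[1], rel=1e-9)

    def test_odds_ratio_conventions(self):
        odds, _ = comp.fisher_exact_2x2([[2, 4], [1, 8]])
        assert odds == pytest.approx(4.0)
        assert comp.fisher_exact_2x2([[2, 0], [0, 3]])[0] == np.inf
        assert comp.fisher_exact_2x2([[0, 2], [3, 0]])[0] == 0.0

    def test_negative_entries_rejected(self):
        with pytest.raises(ValidationError):
            comp.fisher_exact_2x2([[1, -1], [0, 2]])


def direct_bh(p):
    """Oracle: literal step-up definition, O(m^2)."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


class TestBhFdr:
    def test_hand_example(self):
        np.testing.assert_allclose(comp.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_all_ones(self):
        assert comp.bh_fdr([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(comp.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50))
    @settings(max_examples=200, deadline=None)
    def test_matches_direct_step_up(self, p):
        np.testing.assert_allclose(comp.bh_fdr(p), direct_bh(p), atol=1e-12)

    def test_permutation_stable(self):
        rng = np.random.default_rng(0)
        p = rng.random(30)
        q = comp.bh_fdr(p)
        perm = rng.permutation(30)
        np.testing.assert_allclose(comp.bh_fdr(p[perm]), q[perm], atol=1e-12)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(1)
        p = rng.random(40)
        q = comp.bh_fdr(p)
        assert (np.diff(q[np.argsort(p)]) >= -1e-12).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(2)
        p = rng.random(25)
        np.testing.assert_allclose(
            comp.bh_fdr(p), multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            comp.bh_fdr([0.5, 1.5])


def brute_force_rbh(hits, taxon_a, taxon_b, max_evalue=1e-3, reject_within=True):
    """O(n^2) oracle: explicit best-hit scan with the documented tie rules."""
    rows = [r for _, r in hits.iterrows()
            if r.query_id != r.target_id and r.evalue < max_evalue
            and r.query_taxon in (taxon_a, taxon_b) and r.target_taxon in (taxon_a, taxon_b)]

    def best(q, cross):
        cand = [r for r in rows if r.query_id == q and
                ((r.query_taxon != r.target_taxon) == cross)]
        if not cand:
            return None
        return min(cand, key=lambda r: (r.evalue, -r.bitscore, r.target_id))

    queries = {r.query_id: r.query_taxon for r in rows if r.query_taxon != r.target_taxon}
    bests = {}
    for q in queries:
        bc = best(q, True)
        if bc is None:
            continue
        if reject_within:
            bw = best(q, False)
            if bw is not None and (bw.evalue, -bw.bitscore) < (bc.evalue, -bc.bitscore):
                continue
        bests[q] = bc.target_id
    out = set()
    for q, t in bests.items():
        if queries.get(q) == taxon_a and bests.get(t) == q:
            out.add((q, t))
    return out


def random_hits(rng, n_a=15, n_b=15, n_hits=60):
    rows = []
    ga = [f"A_{i}" for i in range(n_a)]
    gb = [f"B_{i}" for i in range(n_b)]
    pool = ga + gb
    for _ in range(n_hits):
        q = pool[rng.integers(len(pool))]
        t = pool[rng.integers(len(pool))]
        rows.append((q, t, "ta" if q.startswith("A_") else "tb",
                     "ta" if t.startswith("A_") else "tb",
                     10.0 ** -rng.integers(0, 12), float(rng.integers(10, 50))))
    return hit_frame(rows)


class TestRbhOrthologs:
    def test_reciprocal_pair_called(self):
        hits = hit_frame([
            ("a1", "b1", "ta", "tb", 1e-10, 100),
            ("b1", "a1", "tb", "ta", 1e-10, 100),
        ])
        omap = comp.call_rbh_orthologs(hits, "ta", "tb")
        assert omap.pairs == [("a1", "b1")]

    def test_non_reciprocal_unpaired(self):
        hits = hit_frame([
            ("a1", "b1", "ta", "tb", 1e-20, 100),
            ("a2", "b1", "ta", "tb", 1e-10, 100),
            ("b1", "a1", "tb", "ta", 1e-20, 100),
        ])
        omap = comp.call_rbh_orthologs(hits, "ta", "tb")
        assert omap.pairs == [("a1", "b1")]  # a2's best is b1, but not reciprocal

    def test_equal_evalue_higher_bitscore_wins(self):
        hits = hit_frame([
            ("a1", "b1", "ta", "tb", 1e-10, 100),
            ("a1", "b2", "ta", "tb", 1e-10, 150),
            ("b2", "a1", "tb", "ta", 1e-10, 150),
        ])
        omap = comp.call_rbh_orthologs(hits, "ta", "tb")
        assert omap.pairs == [("a1", "b2")]

    def test_inparalog_rejection_flag(self):
        hits = hit_frame([
            ("a1", "a2", "ta", "ta", 1e-40, 300),  # stronger within-species hit
            ("a1", "b1", "ta", "tb", 1e-10, 100),
            ("b1", "a1", "tb", "ta", 1e-10, 100),
        ])
        assert comp.call_rbh_orthologs(hits, "ta", "tb").pairs == []
        kept = comp.call_rbh_orthologs(hits, "ta", "tb",
                                       reject_if_within_species_hit_better=False)
        assert kept.pairs == [("a1", "b1")]

    def test_evalue_threshold_strict(self):
        hits = hit_frame([
            ("a1", "b1", "ta", "tb", 1e-3, 100),
            ("b1", "a1", "tb", "ta", 1e-3, 100),
        ])
        assert comp.call_rbh_orthologs(hits, "ta", "tb", max_evalue=1e-3).pairs == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        hits = random_hits(rng)
        omap = comp.call_rbh_orthologs(hits, "ta", "tb")
        assert set(omap.pairs) == brute_force_rbh(hits, "ta", "tb")
        swapped = comp.call_rbh_orthologs(hits, "tb", "ta")
        assert {(a, b) for a, b in omap.pairs} == {(b, a) for a, b in swapped.pairs}


def _profile(genes, regions, regional, expressed=None, median_norm=None):
    n, m = len(genes), len(regions)
    regional = np.asarray(regional, bool)
    expressed = np.ones((n, m), bool) if expressed is None else np.asarray(expressed, bool)
    mn = np.full((n, m), 0.5) if median_norm is None else np.asarray(median_norm, float)
    mz = np.where(regional, 2.0, 0.0)
    return RegionProfile(genes, regions, mz, mn, expressed, regional)


class TestOverlapTests:
    def test_self_overlap_equals_regional_count(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(40)]
        regional = rng.random((40, 3)) < 0.3
        rp = _profile(genes, ["r1", "r2", "r3"], regional)
        df = comp.within_species_overlap_tests(rp).set_index(["region_a", "region_b"])
        for j, r in enumerate(["r1", "r2", "r3"]):
            assert df.loc[(r, r), "k"] == regional[:, j].sum()

    def test_cross_species_planted_overlap(self):
        genes_a = [f"a{i}" for i in range(30)]
        genes_b = [f"b{i}" for i in range(30)]
        reg_a = np.zeros((30, 2), bool)
        reg_b = np.zeros((30, 2), bool)
        reg_a[:10, 0] = True   # same 10 ortholog pairs regional in r1 of both
        reg_b[:10, 0] = True
        omap = comp.OrthologMap("ta", "tb", list(zip(genes_a, genes_b)))
        df = comp.region_overlap_tests(_profile(genes_a, ["r1", "r2"], reg_a),
                                       _profile(genes_b, ["r1", "r2"], reg_b), omap)
        df = df.set_index(["region_a", "region_b"])
        assert df.loc[("r1", "r1"), "k"] == 10
        assert df.loc[("r1", "r1"), "q"] == df["q"].min()

    def test_empty_margin_gives_p_one(self):
        genes_a, genes_b = ["a0"], ["b0"]
        omap = comp.OrthologMap("ta", "tb", [("a0", "b0")])
        df = comp.region_overlap_tests(_profile(genes_a, ["r1"], [[False]]),
                                       _profile(genes_b, ["r1"], [[False]]), omap)
        assert (df["p"] == 1.0).all()
        assert (df["odds_ratio"] == 0.0).all()


class TestDomainEnrichment:
    def test_nested_domain_significant(self):
        n = 5000
        genes = [f"g{i}" for i in range(n)]
        regional = np.zeros((n, 2), bool)
        regional[:50, 0] = True
        rp = _profile(genes, ["r1", "r2"], regional)
        domains = pd.DataFrame({"gene_id": genes[:5], "domain_id": "DUF1"})
        df = comp.domain_enrichment(rp, domains).set_index(["region", "domain"])
        row = df.loc[("r1", "DUF1")]
        assert (row["k"], row["K"], row["n"], row["N"]) == (5, 50, 5, 5000)
        assert row["q"] < 0.05
        assert row["p"] == pytest.approx(exact_fisher_two_sided(5, 45, 0, 4950), rel=1e-9)

    def test_single_member_domain_not_significant(self):
        n = 200
        genes = [f"g{i}" for i in range(n)]
        regional = np.zeros((n, 1), bool)
        regional[:20, 0] = True
        rp = _profile(genes, ["r1"], regional)
        domains = pd.DataFrame({"gene_id": [genes[0]], "domain_id": ["D1"]})
        df = comp.domain_enrichment(rp, domains)
        assert (df["p"] >= 0.1).all()

    def test_empty_regional_set_all_p_one(self):
        genes = [f"g{i}" for i in range(30)]
        rp = _profile(genes, ["r1"], np.zeros((30, 1), bool))
        domains = pd.DataFrame({"gene_id": genes[:6], "domain_id": "D1"})
        df = comp.domain_enrichment(rp, domains)
        assert (df["p"] == 1.0).all()

    def test_cumulative_expression_sums_members(self):
        genes = [f"g{i}" for i in range(10)]
        regional = np.zeros((10, 1), bool)
        regional[:4, 0] = True
        mn = np.arange(10, dtype=float).reshape(10, 1) + 1
        rp = _profile(genes, ["r1"], regional, median_norm=mn)
        domains = pd.DataFrame({"gene_id": genes[:2] + genes[5:6], "domain_id": "D1"})
        df = comp.domain_enrichment(rp, domains)
        # members intersect regional set: g0 (1.0) + g1 (2.0)
        assert df.iloc[0]["cumulative_expression"] == pytest.approx(3.0)


class TestOrthologMap:
    def test_duplicate_gene_rejected(self):
        with pytest.raises(ValidationError):
            comp.OrthologMap("ta", "tb", [("a1", "b1"), ("a1", "b2")])

    def test_mappings(self):
        omap = comp.OrthologMap("ta", "tb", [("a2", "b2"), ("a1", "b1")])
        assert omap.a_to_b() == {"a1": "b1", "a2": "b2"}
        assert omap.b_to_a() == {"b1": "a1", "b2": "a2"}
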