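import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from peroclock.enrichment import (
    build_regulatory_domains,
    binomial_region_test,
    enrich,
    hypergeometric_gene_test,
    map_cpgs_to_genes,
    select_foreground,
)
from peroclock.simulate import generate_gene_annotation, generate_gene_sets

from helpers import binom_tail_sum, hypergeom_tail_enum


def gene_table(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand"])


class TestRegulatoryDomains:
    def test_basal_interval_plus_strand(self):
        [d] = build_regulatory_domains(gene_table([("gA", "chr1", 2_000_000, "+")]))
        assert (d.basal_start, d.basal_end) == (1_950_000, 2_001_000)

    def test_basal_interval_minus_strand_mirrored(self):
        [d] = build_regulatory_domains(gene_table([("gA", "chr1", 2_000_000, "-")]))
        assert (d.basal_start, d.basal_end) == (1_999_000, 2_050_000)

    def test_isolated_gene_extends_full_megabase(self):
        [d] = build_regulatory_domains(gene_table([("gA", "chr1", 2_000_000, "+")]))
        assert d.ext_start == 1_000_000
        assert d.ext_end == 3_000_000

    def test_neighbors_cap_extension_at_each_other_basal(self):
        a, b = build_regulatory_domains(
            gene_table([("gA", "chr1", 2_000_000, "+"), ("gB", "chr1", 2_200_000, "+")])
        )
        # gB basal starts at 2,150,000; gA's right extension stops just before it
        assert a.ext_end == b.basal_start - 1
        assert b.ext_start == a.basal_end + 1

    def test_overlapping_basals_leave_no_extension(self):
        # 10 kb apart: the neighbor's basal already overlaps, extension collapses
        a, b = build_regulatory_domains(
            gene_table([("gA", "chr1", 2_000_000, "+"), ("gB", "chr1", 2_010_000, "+")])
        )
        assert a.ext_end == a.basal_end
        assert b.ext_start == b.basal_start

    def test_basal_always_inside_extended(self):
        genes = generate_gene_annotation(50, seed=3, n_chrom=4, spacing=80_000)
        for d in build_regulatory_domains(genes):
            assert d.ext_start <= d.basal_start <= d.basal_end <= d.ext_end
            assert d.basal_start >= 1

    def test_missing_strand_warns_and_defaults_plus(self):
        table = pd.DataFrame({"gene": ["gA"], "chrom": ["chr1"], "tss": [2_000_000],
                              "strand": [None]})
        with pytest.warns(UserWarning, match="strand"):
            [d] = build_regulatory_domains(table)
        assert (d.basal_start, d.basal_end) == (1_950_000, 2_001_000)


class TestMapCpgs:
    def test_single_basal_hit(self):
        domains = build_regulatory_domains(gene_table([("gA", "chr1", 2_000_000, "+")]))
        cpgs = pd.DataFrame({"cpg_id": ["c1"], "chrom": ["chr1"], "pos": [1_990_000]})
        assert map_cpgs_to_genes(cpgs, domains)["c1"] == frozenset({"gA"})

    def test_overlapping_extended_domains_give_both_genes(self):
        domains = build_regulatory_domains(
            gene_table([("gA", "chr1", 2_000_000, "+"), ("gB", "chr1", 2_400_000, "+")])
        )
        # extensions may overlap each other (only basal domains block them):
        # c1 sits in both genes' extended domains, c2 only in gB's basal side,
        # c3 is far intergenic
        mapping = map_cpgs_to_genes(
            pd.DataFrame(
                {"cpg_id": ["c1", "c2", "c3"], "chrom": ["chr1"] * 3,
                 "pos": [2_100_000, 2_360_000, 9_000_000]}
            ),
            domains,
        )
        assert mapping["c1"] == frozenset({"gA", "gB"})
        assert mapping["c2"] == frozenset({"gB"})
        assert mapping["c3"] == frozenset()

    def test_unknown_chromosome_unmapped(self):
        domains = build_regulatory_domains(gene_table([("gA", "chr1", 2_000_000, "+")]))
        cpgs = pd.DataFrame({"cpg_id": ["c1"], "chrom": ["chrU"], "pos": [2_000_000]})
        assert map_cpgs_to_genes(cpgs, domains)["c1"] == frozenset()

    def test_matches_brute_force_interval_scan(self):
        rng = np.random.default_rng(0)
        genes = generate_gene_annotation(40, seed=1, n_chrom=3, spacing=60_000)
        domains = build_regulatory_domains(genes)
        cpgs = pd.DataFrame(
            {
                "cpg_id": [f"c{i}" for i in range(100)],
                "chrom": rng.choice(["chr1", "chr2", "chr3"], 100),
                "pos": rng.integers(1, 1_200_000, 100),
            }
        )
        mapping = map_cpgs_to_genes(cpgs, domains)
        for row in cpgs.itertuples(index=False):
            expected = frozenset(
                d.gene
                for d in domains
                if d.chrom == row.chrom and d.ext_start <= row.pos <= d.ext_end
            )
            assert mapping[row.cpg_id] == expected


def toy_universe(n_bg=50, genes_per_cpg=1):
    """Background of n_bg CpGs, each mapping to its own gene g1..g{n_bg}."""
    background = [f"c{i}" for i in range(n_bg)]
    mapping = {f"c{i}": frozenset({f"g{i}"}) for i in range(n_bg)}
    return background, mapping


class TestHypergeometricGeneTest:
    def test_worked_example(self):
        # 5 foreground genes, 3 inside a 10-gene set, 50-gene universe
        background, mapping = toy_universe(50)
        foreground = [f"c{i}" for i in range(5)]
        gene_sets = {"setA": {f"g{i}" for i in range(3)} | {f"g{i}" for i in range(40, 47)}}
        result = hypergeometric_gene_test(
            foreground, background, mapping, gene_sets, size_bounds=(1, 3000)
        )
        assert result.loc["setA", "n_fg_hits"] == 3
        assert result.loc["setA", "p_hypergeometric"] == pytest.approx(
            102252 / 2118760, abs=1e-9
        )

    def test_disjoint_set_has_p_one(self):
        background, mapping = toy_universe(30)
        gene_sets = {"far": {f"g{i}" for i in range(20, 30)}}
        result = hypergeometric_gene_test(
            [f"c{i}" for i in range(5)], background, mapping, gene_sets, size_bounds=(1, 3000)
        )
        assert result.loc["far", "p_hypergeometric"] == 1.0

    def test_foreground_equal_background_saturates(self):
        background, mapping = toy_universe(30)
        gene_sets = {"any": {f"g{i}" for i in range(10)}}
        result = hypergeometric_gene_test(
            background, background, mapping, gene_sets, size_bounds=(1, 3000)
        )
        assert result.loc["any", "p_hypergeometric"] == 1.0

    def test_foreground_must_be_subset(self):
        background, mapping = toy_universe(10)
        with pytest.raises(ValueError, match="subset"):
            hypergeometric_gene_test(
                ["c99"], background, mapping, {"s": {"g1"} | {f"g{i}" for i in range(9)}},
                size_bounds=(1, 3000),
            )

    def test_size_bounds_filter(self):
        background, mapping = toy_universe(50)
        gene_sets = {"tiny": {"g1"}, "ok": {f"g{i}" for i in range(12)}}
        result = hypergeometric_gene_test(
            [f"c{i}" for i in range(5)], background, mapping, gene_sets,
            size_bounds=(10, 3000),
        )
        assert list(result.index) == ["ok"]

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_universe = int(rng.integers(10, 61))
        background, mapping = toy_universe(n_universe)
        n_fg = int(rng.integers(1, n_universe))
        n_set = int(rng.integers(1, n_universe))
        foreground = [f"c{i}" for i in rng.choice(n_universe, n_fg, replace=False)]
        members = {f"g{i}" for i in rng.choice(n_universe, n_set, replace=False)}
        result = hypergeometric_gene_test(
            foreground, background, mapping, {"s": members}, size_bounds=(1, 3000)
        )
        k = int(result.loc["s", "n_fg_hits"])
        expected = hypergeom_tail_enum(k, n_universe, n_set, n_fg)
        assert result.loc["s", "p_hypergeometric"] == pytest.approx(expected, abs=1e-9)

    def test_adjustments_monotone_and_bounded(self):
        background, mapping = toy_universe(50)
        rng = np.random.default_rng(1)
        gene_sets = {
            f"s{j}": {f"g{i}" for i in rng.choice(50, 12, replace=False)} for j in range(20)
        }
        result = hypergeometric_gene_test(
            [f"c{i}" for i in range(8)], background, mapping, gene_sets,
            size_bounds=(1, 3000),
        )
        assert (result["p_bonferroni"] >= result["p_hypergeometric"] - 1e-15).all()
        ordered = result.sort_values("p_hypergeometric")
        assert (np.diff(ordered["q_bh"]) >= -1e-12).all()
        assert (result["q_bh"] <= 1).all()


class TestBinomialRegionTest:
    def test_zero_hits_give_p_one(self):
        background, mapping = toy_universe(40)
        gene_sets = {"s": {f"g{i}" for i in range(30, 40)}}
        result = binomial_region_test(
            [f"c{i}" for i in range(5)], background, mapping, gene_sets,
            size_bounds=(1, 3000),
        )
        assert result.loc["s", "p_binomial"] == 1.0

    def test_reference_tail_value(self):
        assert float(sps.binom.sf(49, 500, 0.1)) == pytest.approx(0.520, abs=5e-3)

    def test_matches_direct_tail_sum(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(5, 200))
            p0 = float(rng.uniform(0.02, 0.6))
            k = int(rng.integers(0, n + 1))
            if k == 0:
                continue
            assert float(sps.binom.sf(k - 1, n, p0)) == pytest.approx(
                binom_tail_sum(k, n, p0), abs=1e-9
            )

    def test_degenerate_flag_false_on_regular_inputs(self):
        # with foreground inside the background and a shared mapping, hits in
        # the foreground imply p0 > 0, so the flag stays off
        background, mapping = toy_universe(40)
        gene_sets = {"s": {f"g{i}" for i in range(15)}}
        result = binomial_region_test(
            [f"c{i}" for i in range(8)], background, mapping, gene_sets,
            size_bounds=(1, 3000),
        )
        assert not bool(result.loc["s", "degenerate"])
        assert 0 < result.loc["s", "p_binomial"] <= 1

    def test_uniform_foreground_is_calibrated(self):
        """Foreground drawn uniformly from the background gives a null p."""
        rng = np.random.default_rng(3)
        genes = generate_gene_annotation(60, seed=4, n_chrom=5, spacing=70_000)
        domains = build_regulatory_domains(genes)
        positions = rng.integers(1, 900_000, 800)
        cpgs = pd.DataFrame(
            {
                "cpg_id": [f"c{i}" for i in range(800)],
                "chrom": rng.choice([f"chr{i}" for i in range(1, 6)], 800),
                "pos": positions,
            }
        )
        mapping = map_cpgs_to_genes(cpgs, domains)
        background = list(cpgs["cpg_id"])
        gene_sets = generate_gene_sets(list(genes["gene"]), n_sets=20,
                                       size_range=(10, 30), seed=5)
        pvals = []
        for seed in range(20):
            fg = list(np.random.default_rng(seed).choice(background, 100, replace=False))
            result = binomial_region_test(fg, background, mapping, gene_sets,
                                          size_bounds=(5, 3000))
            pvals.append(result["p_binomial"].to_numpy())
        p = np.concatenate(pvals)
        # discrete and correlated across sets, so only a coarse calibration check
        assert 0.2 < (p < 0.5).mean() < 0.8
        assert (p < 0.01).mean() < 0.05


class TestSelectForeground:
    def make_table(self, n=30):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {"p": rng.uniform(size=n), "effect": rng.normal(size=n)},
            index=[f"c{i}" for i in range(n)],
        )

    def test_direction_split_boundary(self):
        table = self.make_table()
        n_pos = int((table["effect"] > 0).sum())
        increased, decreased = select_foreground(table, n_per_direction=500)
        assert len(increased) == n_pos
        assert len(decreased) == len(table) - n_pos

    def test_tie_break_is_deterministic(self):
        table = pd.DataFrame(
            {"p": [0.5] * 4, "effect": [1.0] * 4}, index=["cB", "cA", "cD", "cC"]
        )
        increased, _ = select_foreground(table, n_per_direction=2)
        assert increased == ["cA", "cB"]

    def test_planted_directional_effects_dominate_selection(self):
        from peroclock.ewas import group_ewas
        from peroclock.simulate import generate_dataset
        from test_ewas import TestGroupEwas

        dataset, truth = generate_dataset(TestGroupEwas.contrast_config())
        table = group_ewas(dataset, "altitude", "high").table
        planted = truth.group_cpgs["altitude"]
        up = {c for c, e in planted.items() if e > 0}
        down = {c for c, e in planted.items() if e < 0}
        increased, decreased = select_foreground(table, n_per_direction=len(up))
        assert len(set(increased) & up) / len(up) >= 0.9
        decreased = decreased[: len(down)]
        assert len(set(decreased) & down) / len(down) >= 0.9


def test_enrich_end_to_end_detects_planted_set():
    """A gene set enriched among the foreground genes gets a small hypergeometric p."""
    rng = np.random.default_rng(6)
    genes = generate_gene_annotation(100, seed=7, n_chrom=10, spacing=120_000)
    domains = build_regulatory_domains(genes)
    gene_names = list(genes["gene"])
    # CpGs: one per gene basal region, plus intergenic extras
    rows, stats_rows = [], []
    target = set(gene_names[:15])
    for i, g in genes.iterrows():
        rows.append({"cpg_id": f"c{i}", "chrom": g["chrom"], "pos": g["tss"] + 100,
                     "adjacent_gene": g["gene"], "region_class": "promoter",
                     "tss_distance": 100})
        in_target = g["gene"] in target
        stats_rows.append(
            {"cpg_id": f"c{i}",
             "p": 1e-8 if in_target else rng.uniform(0.05, 1.0),
             "effect": 0.5 if in_target else rng.normal() * 0.1}
        )
    manifest = pd.DataFrame(rows)
    stats_table = pd.DataFrame(stats_rows).set_index("cpg_id")
    gene_sets = generate_gene_sets(gene_names, n_sets=10, size_range=(10, 25), seed=8,
                                   planted={"planted": sorted(target)})
    results = enrich(stats_table, manifest, genes, gene_sets, n_per_direction=15,
                     size_bounds=(5, 3000))
    increased = results["increased"]
    assert increased.loc["planted", "p_hypergeometric"] < 1e-6
    assert increased.loc["planted", "p_hypergeometric"] == increased["p_hypergeometric"].min()
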