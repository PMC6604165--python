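import numpy as np
import pandas as pd
import pytest

from nuclize import codes as cd
from nuclize.intervals import NucleosomeMap
from nuclize.multivalent import join_marks


def make_map(n=50, spacing=200, width=147, offset=100, chrom="chr1"):
    starts = offset + spacing * np.arange(n)
    return NucleosomeMap.from_intervals(
        pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": starts + width,
             "dyad": starts + width // 2}
        )
    )


def gene(gene_id, tss, strand, chrom="chr1"):
    return pd.DataFrame(
        {"gene_id": [gene_id], "chrom": [chrom], "tss": [tss], "strand": [strand]}
    )


class TestExtractCodes:
    def test_plus_strand_example(self, tiled_map):
        # TSS 2000; marked dyads at 1573 ("A", upstream) and 2373 ("T", down)
        calls = join_marks(
            {"H3K4me3": {7, 11}, "H3K9ac": {11}, "H3K27ac": {11}}, tiled_map
        )
        code = cd.extract_codes(calls, tiled_map, gene("g", 2000, "+"), 500)[0]
        # window [1500, 2500] holds 5 dyads; unmarked slots stay explicit
        marked = tuple(s for s in code.slots if s != cd.UNMARKED)
        assert marked == ("A", "T")
        assert code.count("T") == (0, 1, 1)
        assert code.count("A") == (1, 0, 1)
        assert (code.n_upstream, code.n_downstream) == (3, 2)

    def test_minus_strand_mirror_gives_identical_code(self, tiled_map):
        # mirrored layout on the minus strand: A at tss+427, T at tss-373
        calls = join_marks(
            {"H3K4me3": {7, 11}, "H3K9ac": {7}, "H3K27ac": {7}}, tiled_map
        )
        code = cd.extract_codes(calls, tiled_map, gene("g", 2000, "-"), 500)[0]
        marked = tuple(s for s in code.slots if s != cd.UNMARKED)
        assert marked == ("A", "T")
        assert code.count("T") == (0, 1, 1)

    def test_dyad_at_tss_counts_downstream(self, tiled_map):
        # nucleosome 10 dyad = 2173
        calls = join_marks({"H3K4me3": {10}}, tiled_map)
        for strand in "+-":
            code = cd.extract_codes(
                calls, tiled_map, gene("g", 2173, strand), 300
            )[0]
            assert code.count("A") == (0, 1, 1)

    def test_unmarked_slots_are_explicit(self, tiled_map):
        calls = join_marks({"H3K4me3": {10}}, tiled_map)
        code = cd.extract_codes(calls, tiled_map, gene("g", 2100, "+"), 500)[0]
        assert cd.UNMARKED in code.slots
        assert len(code.slots) == code.n_upstream + code.n_downstream

    def test_missing_chromosome_flagged(self, tiled_map):
        code = cd.extract_codes(
            join_marks({}, tiled_map), tiled_map, gene("g", 100, "+", "chrX"), 500
        )[0]
        assert code.missing_chrom
        assert code.slots == ()

    def test_translation_invariance(self):
        m1 = make_map(offset=100)
        m2 = make_map(offset=100 + 50_000)
        calls1 = join_marks({"H3K4me3": {3, 8}}, m1)
        calls2 = join_marks({"H3K4me3": {3, 8}}, m2)
        c1 = cd.extract_codes(calls1, m1, gene("g", 1100, "+"), 1000)[0]
        c2 = cd.extract_codes(calls2, m2, gene("g", 51_100, "+"), 1000)[0]
        assert c1.slots == c2.slots
        assert c1.counts == c2.counts

    def test_strand_flip_swaps_up_down(self, tiled_map):
        calls = join_marks({"H3K4me3": {8, 12}}, tiled_map)
        plus = cd.extract_codes(calls, tiled_map, gene("g", 2100, "+"), 1000)[0]
        minus = cd.extract_codes(calls, tiled_map, gene("g", 2100, "-"), 1000)[0]
        pu, pdn, _ = plus.count("A")
        mu, mdn, _ = minus.count("A")
        # dyads strictly off the TSS swap sides when the strand flips
        assert (pu, pdn) == (mdn, mu)

    def test_matches_brute_force_per_gene_scan(self, tiny_sim):
        sim = tiny_sim
        truth_calls = join_marks(
            {
                mark: set(ids)
                for mark, ids in sim.truth.marked.items()
            },
            sim.nucmap,
        )
        genes = sim.truth.genes
        w = 2000
        out = cd.extract_codes(truth_calls, sim.nucmap, genes, w)
        cat_by_id = dict(
            zip(truth_calls["nucleosome_id"], truth_calls["category"])
        )
        tab = sim.nucmap.table
        for code, g in zip(out, genes.itertuples(index=False)):
            rows = tab[
                (tab["chrom"] == g.chrom)
                & (tab["dyad"] >= g.tss - w)
                & (tab["dyad"] <= g.tss + w)
            ].sort_values("dyad")
            cats = [cat_by_id.get(int(i), cd.UNMARKED)
                    for i in rows["nucleosome_id"]]
            if g.strand == "-":
                cats = cats[::-1]
            assert list(code.slots) == cats


class TestCodeMatrix:
    def test_gene_without_nucleosomes_is_all_absent(self, tiled_map):
        code = cd.extract_codes(
            join_marks({}, tiled_map), tiled_map, gene("g", 100, "+", "chrX"), 500
        )
        X, gene_ids, cols = cd.build_code_matrix(code, slots_per_side=5)
        assert gene_ids == ["g"]
        absent_cols = [i for i, c in enumerate(cols) if c.endswith(cd.ABSENT)]
        assert X[0].sum() == 10
        assert X[0, absent_cols].sum() == 10

    def test_identical_codes_identical_rows(self, tiled_map):
        calls = join_marks({"H3K4me3": {5, 25}}, tiled_map)
        genes = pd.concat(
            [gene("g1", 1173, "+"), gene("g2", 5173, "+")], ignore_index=True
        )
        code_list = cd.extract_codes(calls, tiled_map, genes, 600)
        X, _, _ = cd.build_code_matrix(code_list, slots_per_side=4)
        assert np.array_equal(X[0], X[1])

    def test_one_hot_block_sums(self, tiny_sim):
        sim = tiny_sim
        calls = join_marks(
            {m: set(v) for m, v in sim.truth.marked.items()}, sim.nucmap
        )
        code_list = cd.extract_codes(calls, sim.nucmap, sim.truth.genes, 2000)
        X, _, cols = cd.build_code_matrix(code_list, slots_per_side=15)
        n_cat = len(set(c.split(":", 1)[1] for c in cols))
        blocks = X.reshape(len(code_list), -1, n_cat)
        assert np.all(blocks.sum(axis=2) == 1)


class TestClustering:
    def test_two_archetypes_recovered_exactly(self):
        a = np.tile([1.0, 0, 0, 1, 0, 0], (10, 1))
        b = np.tile([0.0, 1, 1, 0, 1, 1], (8, 1))
        X = np.vstack([a, b])
        labels = cd.cluster_codes(X, k=2, seed=0)
        # size-ordered labels: larger group gets label 1
        assert set(labels[:10]) == {1}
        assert set(labels[10:]) == {2}

    def test_duplicate_rows_same_cluster(self, rng):
        X = rng.uniform(size=(12, 6))
        X[7] = X[3]
        labels = cd.cluster_codes(X, k=3, seed=1)
        assert labels[7] == labels[3]

    def test_fixed_seed_reproducible(self, rng):
        X = rng.uniform(size=(30, 8))
        a = cd.cluster_codes(X, k=4, seed=11)
        b = cd.cluster_codes(X, k=4, seed=11)
        assert np.array_equal(a, b)

    def test_k_beyond_distinct_rows_raises(self):
        X = np.tile([1.0, 0.0], (10, 1))
        with pytest.raises(ValueError, match="distinct"):
            cd.cluster_codes(X, k=3, seed=0)


class TestExpression:
    @staticmethod
    def _codes_with_t_counts(t_down_counts, tiled):
        """One gene per requested downstream-T count."""
        genes = []
        code_list = []
        for i, t in enumerate(t_down_counts):
            ids = set(range(11, 11 + t))  # dyads 2373.. downstream of 2200
            calls = join_marks(
                {"H3K4me3": ids, "H3K9ac": ids, "H3K27ac": ids}, tiled
            )
            g = gene(f"g{i}", 2200, "+")
            code_list.extend(cd.extract_codes(calls, tiled, g, 2000))
        return code_list

    def test_monotone_design_gives_rho_one(self, tiled_map):
        t_counts = [0, 1, 2, 3, 4, 5]
        code_list = self._codes_with_t_counts(t_counts, tiled_map)
        expression = {f"g{i}": 10.0 * t for i, t in enumerate(t_counts)}
        clusters = {f"g{i}": i + 1 for i in range(len(t_counts))}
        per_gene, per_cluster, corr = cd.count_marks_vs_expression(
            code_list, expression, clusters=clusters
        )
        rho = corr.set_index("feature").loc["T_down", "spearman_rho"]
        assert rho == pytest.approx(1.0)

    def test_all_zero_expression_reports_nan(self, tiled_map):
        code_list = self._codes_with_t_counts([0, 1, 2], tiled_map)
        expression = {f"g{i}": 0.0 for i in range(3)}
        clusters = {f"g{i}": i + 1 for i in range(3)}
        _, _, corr = cd.count_marks_vs_expression(
            code_list, expression, clusters=clusters
        )
        assert corr["spearman_rho"].isna().all()

    def test_missing_expression_excluded_and_counted(self, tiled_map):
        code_list = self._codes_with_t_counts([1, 2, 3], tiled_map)
        expression = {"g0": 1.0, "g2": 5.0}  # g1 missing
        per_gene, _, _ = cd.count_marks_vs_expression(code_list, expression)
        assert set(per_gene["gene_id"]) == {"g0", "g2"}
        assert per_gene.attrs["n_missing_expression"] == 1

    def test_scatter_plot_writes_file(self, tiled_map, tmp_path):
        code_list = self._codes_with_t_counts([0, 2, 4], tiled_map)
        expression = {f"g{i}": 10.0 * i for i in range(3)}
        per_gene, _, _ = cd.count_marks_vs_expression(code_list, expression)
        out = cd.plot_expression_vs_counts(per_gene, tmp_path / "t.png")
        assert out.stat().st_size > 0

    def test_cluster_medians_match_sort_and_middle_oracle(self, tiled_map, rng):
        code_list = self._codes_with_t_counts([0, 1, 2, 3, 4, 5], tiled_map)
        expression = {f"g{i}": float(v) for i, v in
                      enumerate(rng.uniform(0, 50, size=6))}
        clusters = {f"g{i}": 1 if i < 3 else 2 for i in range(6)}
        _, per_cluster, _ = cd.count_marks_vs_expression(
            code_list, expression, clusters=clusters
        )

        def middle(vals):
            s = sorted(vals)
            n = len(s)
            return s[n // 2] if n % 2 else 0.5 * (s[n // 2 - 1] + s[n // 2])

        for cl, members in ((1, range(3)), (2, range(3, 6))):
            expect = middle([expression[f"g{i}"] for i in members])
            got = per_cluster.set_index("cluster").loc[cl, "rpkm"]
            assert got == pytest.approx(expect)
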