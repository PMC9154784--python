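import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fmtx import profile
from fmtx.io import ValidationError
from conftest import make_count_table


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

class TestAlphaDiversity:
    def test_bias_corrected_chao1_hand_case(self):
        # counts 1, 1, 2: observed 3, F1=2, F2=1 -> 3 + 2*1/(2*2) = 3.5
        res = profile.alpha_diversity(make_count_table([[1], [1], [2]]))
        row = res.iloc[0]
        assert row["observed"] == 3
        assert row["F1"] == 2 and row["F2"] == 1
        assert row["chao1"] == pytest.approx(3.5)

    def test_uniform_community_closed_forms(self):
        res = profile.alpha_diversity(make_count_table([[25]] * 4))
        row = res.iloc[0]
        assert row["shannon"] == pytest.approx(np.log(4))
        assert row["inv_simpson"] == pytest.approx(4.0)

    def test_chao1_equals_observed_without_singletons(self):
        res = profile.alpha_diversity(make_count_table([[5], [9], [2]]))
        assert res.iloc[0]["F1"] == 0
        assert res.iloc[0]["chao1"] == res.iloc[0]["observed"]

    def test_matches_reference_implementation(self, rng):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        counts = rng.integers(0, 40, size=(25, 6))
        counts[0] += 1  # keep samples nonzero
        table = make_count_table(counts)
        res = profile.alpha_diversity(table)
        for j, s in enumerate(table.sample_ids):
            x = counts[:, j]
            assert res.loc[s, "chao1"] == pytest.approx(
                skbio_alpha.chao1(x, bias_corrected=True))
            assert res.loc[s, "shannon"] == pytest.approx(
                skbio_alpha.shannon(x, base=np.e))
            assert res.loc[s, "inv_simpson"] == pytest.approx(
                skbio_alpha.enspie(x), rel=1e-9)

    def test_invariants_chao1_bounds(self, rng):
        counts = rng.integers(0, 15, size=(40, 8))
        counts[0] += 1
        res = profile.alpha_diversity(make_count_table(counts))
        assert (res["chao1"] >= res["observed"]).all()
        assert (res["inv_simpson"] <= res["observed"]).all()
        assert (res["shannon"] <= np.log(res["observed"]) + 1e-12).all()

    def test_zero_sample_is_an_error(self):
        table = make_count_table([[1, 1], [1, 2]])
        table.data.loc[:, "s1"] = 0
        with pytest.raises(ValidationError):
            profile.alpha_diversity(table)


# ---------------------------------------------------------------------------
# genus collapsing
# ---------------------------------------------------------------------------

def taxonomy_frame(rows):
    cols = list(profile.RANKS)
    return pd.DataFrame(
        [dict(zip(cols, r + [""] * (len(cols) - len(r)))) for r in rows],
        index=[f"f{i}" for i in range(len(rows))],
    )


class TestCollapseGenus:
    def test_same_genus_rows_are_summed(self):
        counts = make_count_table([[3], [5]])
        tax = taxonomy_frame([
            ["Bacteria", "P1", "C1", "O1", "F1", "G1"],
            ["Bacteria", "P1", "C1", "O1", "F1", "G1"],
        ])
        out = profile.collapse_genus(counts, tax)
        assert out.data.shape[0] == 1
        assert out.data.iloc[0, 0] == 8

    def test_distinct_genera_only_relabel(self):
        counts = make_count_table([[3], [5]])
        tax = taxonomy_frame([
            ["Bacteria", "P1", "C1", "O1", "F1", "G1"],
            ["Bacteria", "P1", "C1", "O1", "F1", "G2"],
        ])
        out = profile.collapse_genus(counts, tax)
        assert sorted(out.data.iloc[:, 0]) == [3, 5]

    def test_unassigned_genus_grouped_by_finest_rank(self):
        counts = make_count_table([[2], [4]])
        tax = taxonomy_frame([
            ["Bacteria", "P1", "C1", "O1", "F9"],
            ["Bacteria", "P1", "C1", "O1", "F9"],
        ])
        out = profile.collapse_genus(counts, tax)
        assert list(out.data.index)[0].endswith("unclassified_F9")
        assert out.data.iloc[0, 0] == 6

    def test_column_sums_conserved_on_random_tables(self, rng):
        counts = make_count_table(rng.integers(0, 30, size=(30, 5)))
        genera = rng.integers(0, 6, size=30)
        tax = taxonomy_frame([
            ["Bacteria", "P1", "C1", "O1", f"F{g % 3}", f"G{g}"] for g in genera])
        tax.index = counts.feature_ids
        out = profile.collapse_genus(counts, tax)
        assert np.array_equal(out.data.sum(axis=0), counts.data.sum(axis=0))

    def test_missing_taxonomy_row_names_the_asv(self):
        counts = make_count_table([[1], [1]])
        tax = taxonomy_frame([["Bacteria", "P1", "C1", "O1", "F1", "G1"]])
        with pytest.raises(ValidationError, match="f1"):
            profile.collapse_genus(counts, tax)


# ---------------------------------------------------------------------------
# cumulative sum scaling
# ---------------------------------------------------------------------------

class TestCssNormalize:
    def test_uniform_sample_hand_case(self):
        res = profile.css_normalize(make_count_table([[10], [10], [10], [10]]),
                                    quantile=0.5)
        assert np.allclose(res.normalized.iloc[:, 0], 250.0)
        assert res.scaling_factors.iloc[0] == 40

    def test_dominant_taxon_hand_case(self):
        res = profile.css_normalize(make_count_table([[97], [1], [1], [1]]),
                                    quantile=0.5)
        assert res.scaling_factors.iloc[0] == 3
        assert res.normalized.iloc[0, 0] == pytest.approx(97 / 3 * 1000)

    def test_scale_invariance_at_fixed_quantile(self, rng):
        counts = rng.integers(1, 50, size=(20, 3))
        a = profile.css_normalize(make_count_table(counts), quantile=0.5)
        doubled = counts.copy()
        doubled[:, 1] *= 2
        b = profile.css_normalize(make_count_table(doubled), quantile=0.5)
        assert np.allclose(a.normalized.to_numpy(), b.normalized.to_numpy())

    def test_log2_flag(self):
        res = profile.css_normalize(make_count_table([[10], [10], [10], [10]]),
                                    quantile=0.5, log2=True)
        assert np.allclose(res.normalized.iloc[:, 0], np.log2(251.0))

    def test_degenerate_sample_is_an_error(self):
        with pytest.raises(ValidationError):
            profile.css_normalize(make_count_table([[5], [0], [0]]))


# ---------------------------------------------------------------------------
# paired differential abundance + BH
# ---------------------------------------------------------------------------

def paired_meta(n_pairs, genotype="WT"):
    rows = []
    for i in range(n_pairs):
        rows.append({"sample": f"pre{i}", "genotype": genotype,
                     "treatment": "control", "pair_id": f"p{i}"})
        rows.append({"sample": f"post{i}", "genotype": genotype,
                     "treatment": "FMT", "pair_id": f"p{i}"})
    return pd.DataFrame(rows).set_index("sample")


class TestDiffAbundancePaired:
    def test_identical_pre_post_gives_na(self):
        meta = paired_meta(4)
        ab = pd.DataFrame(
            [[5.0] * 8], index=["t1"],
            columns=[f"pre{i}" for i in range(4)] + [f"post{i}" for i in range(4)])
        out = profile.diff_abundance_paired(ab, meta)
        assert np.isnan(out.loc["t1", "p"])

    def test_uniform_shift_exact_signed_rank_p(self):
        # 6 pairs all shifted upward: minimal W, exact two-sided p = 2/2^6
        meta = paired_meta(6)
        pre = np.array([1.0, 2, 3, 4, 5, 6])
        ab = pd.DataFrame(
            [np.concatenate([pre, pre + 10])], index=["t1"],
            columns=[f"pre{i}" for i in range(6)] + [f"post{i}" for i in range(6)])
        out = profile.diff_abundance_paired(ab, meta)
        assert out.loc["t1", "p"] == pytest.approx(0.03125)
        assert out.loc["t1", "median_lfc_proxy"] > 0

    def test_bh_step_up_hand_case(self):
        padj = profile.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(padj, 0.04)

    def test_bh_monotone_and_order_equivariant(self, rng):
        p = rng.uniform(size=50)
        padj = profile.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(padj[order]) >= -1e-12).all()
        assert (padj >= p - 1e-12).all()
        # pure function of the multiset of p-values: permuting the input
        # permutes the output identically
        perm = rng.permutation(50)
        assert np.allclose(profile.bh_adjust(p[perm]), padj[perm])
        # matches the step-up definition: padj_i = min_{j>=i} p_(j) * m / j
        sorted_p = np.sort(p)
        expected = np.minimum.accumulate(
            (sorted_p * 50 / np.arange(1, 51))[::-1])[::-1]
        assert np.allclose(np.sort(padj), expected)


# ---------------------------------------------------------------------------
# LDA effect size scan
# ---------------------------------------------------------------------------

class TestLefseLite:
    def make_meta(self, n=10):
        rows = [{"sample": f"a{i}", "genotype": "WT", "treatment": "control"}
                for i in range(n)]
        rows += [{"sample": f"b{i}", "genotype": "WT", "treatment": "FMT"}
                 for i in range(n)]
        return pd.DataFrame(rows).set_index("sample")

    def test_forced_effect_passes_with_enrichment_side(self, rng):
        meta = self.make_meta()
        cols = list(meta.index)
        clades = pd.DataFrame(
            [np.concatenate([rng.normal(500, 20, 10), np.zeros(10)])],
            index=["g__X"], columns=cols)
        out = profile.lefse_lite(clades, meta, "treatment", seed=1)
        assert out.loc["g__X", "kw_p"] < 1e-3
        assert out.loc["g__X", "lda_score"] >= 2.0
        assert out.loc["g__X", "passes"]
        assert out.loc["g__X", "enriched_class"] == "FMT" or \
            out.loc["g__X", "enriched_class"] == "control"
        # class a (= control here) holds the 500 permil abundance
        assert out.loc["g__X", "enriched_class"] == "control"

    def test_identical_distribution_fails_gate(self):
        meta = self.make_meta()
        clades = pd.DataFrame([[100.0] * 20], index=["g__Y"], columns=list(meta.index))
        out = profile.lefse_lite(clades, meta, "treatment", seed=1)
        assert not out.loc["g__Y", "passes"]
        assert np.isnan(out.loc["g__Y", "lda_score"])

    def test_global_null_passing_rate_at_most_alpha(self, rng):
        """Permuted labels: the expected fraction of passing clades stays below
        the Kruskal-Wallis level (the LDA gate only removes more)."""
        meta = self.make_meta(8)
        passing = total = 0
        for rep in range(60):
            clades = pd.DataFrame(rng.lognormal(3, 1, size=(10, 16)),
                                  index=[f"g__{i}" for i in range(10)],
                                  columns=list(meta.index))
            out = profile.lefse_lite(clades, meta, "treatment", seed=rep)
            passing += out["passes"].sum()
            total += len(out)
        assert passing / total <= 0.05 + 0.03

    def test_small_class_is_an_error(self):
        meta = self.make_meta(2)
        clades = pd.DataFrame([[1.0] * 4], index=["g__Z"], columns=list(meta.index))
        with pytest.raises(ValidationError):
            profile.lefse_lite(clades, meta, "treatment")


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def euclidean_distance(points):
    from scipy.spatial.distance import pdist, squareform
    ids = [f"s{i}" for i in range(len(points))]
    return pd.DataFrame(squareform(pdist(np.atleast_2d(points).T
                                         if np.ndim(points) == 1 else points)),
                        index=ids, columns=ids)


def two_group_meta(n_a, n_b):
    rows = [{"sample": f"s{i}", "genotype": "WT" if i < n_a else "KO",
             "treatment": "control"} for i in range(n_a + n_b)]
    return pd.DataFrame(rows).set_index("sample")


class TestPermanova:
    def test_separated_groups_hit_permutation_floor(self, rng):
        pts = np.concatenate([rng.normal(0, 0.1, (6, 2)), rng.normal(50, 0.1, (6, 2))])
        res = profile.permanova(euclidean_distance(pts), two_group_meta(6, 6),
                                ["genotype"], n_perm=199, seed=1)
        assert res.loc["genotype", "p_perm"] == pytest.approx(1 / 200)
        assert res.loc["genotype", "R2"] > 0.99

    def test_pseudo_f_equals_classical_anova_on_1d_euclidean(self, rng):
        x = rng.normal(0, 1, 10)
        x[5:] += 1.5
        res = profile.permanova(euclidean_distance(x), two_group_meta(5, 5),
                                ["genotype"], n_perm=49, seed=2)
        f_classic = stats.f_oneway(x[:5], x[5:]).statistic
        assert res.loc["genotype", "pseudo_F"] == pytest.approx(f_classic, rel=1e-9)

    def test_agrees_with_reference_single_factor(self, rng):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        pts = rng.normal(0, 1, (12, 4))
        pts[6:] += 0.8
        dist = euclidean_distance(pts)
        res = profile.permanova(dist, two_group_meta(6, 6), ["genotype"],
                                n_perm=99, seed=3)
        dm = skbio_distance.DistanceMatrix(dist.to_numpy(), ids=list(dist.index))
        ref = skbio_distance.permanova(dm, ["a"] * 6 + ["b"] * 6, permutations=99)
        assert res.loc["genotype", "pseudo_F"] == pytest.approx(
            ref["test statistic"], rel=1e-9)

    def test_malformed_matrix_rejected(self):
        bad = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
        with pytest.raises(ValidationError):
            profile.permanova(bad, two_group_meta(2, 1), ["genotype"], n_perm=9)


class TestRdaConstrained:
    def make_inputs(self, rng, effect="genotype"):
        n = 16
        meta = pd.DataFrame({
            "genotype": ["WT"] * 8 + ["KO"] * 8,
            "treatment": (["control"] * 4 + ["FMT"] * 4) * 2,
        }, index=[f"s{i}" for i in range(n)])
        signal = (meta["genotype"] == "KO").to_numpy(float)
        y = np.outer(np.ones(10), signal) * 5.0
        if effect == "none":
            y = rng.normal(size=(10, n))
        ab = pd.DataFrame(y, index=[f"t{i}" for i in range(10)], columns=meta.index)
        return ab, meta

    def test_pure_genotype_response_is_fully_explained(self, rng):
        ab, meta = self.make_inputs(rng)
        res = profile.rda_constrained(ab, meta, ["genotype", "treatment"],
                                      n_perm=99, seed=1)
        assert res.constrained_variance_fractions["genotype"] == pytest.approx(1.0)
        assert res.constrained_variance_fractions["treatment"] == pytest.approx(0.0, abs=1e-9)

    def test_total_inertia_decomposition(self, rng):
        ab, meta = self.make_inputs(rng, effect="none")
        res = profile.rda_constrained(ab, meta, ["genotype", "treatment"],
                                      n_perm=49, seed=1)
        explained = sum(res.constrained_variance_fractions.values())
        assert 0 <= explained <= 1
        assert res.constrained_inertia == pytest.approx(
            explained * res.total_inertia, abs=1e-8)

    def test_collinear_design_names_the_factor(self, rng):
        ab, meta = self.make_inputs(rng)
        meta = meta.copy()
        meta["treatment"] = np.where(meta["genotype"] == "WT", "control", "FMT")
        with pytest.raises(ValidationError, match="treatment"):
            profile.rda_constrained(ab, meta, ["genotype", "treatment"], n_perm=9)
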