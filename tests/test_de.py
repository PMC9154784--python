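import math

import numpy as np
import pandas as pd
import pytest

from fmtx import de
from fmtx.io import ValidationError
from conftest import make_count_table


def group_meta(n_a=6, n_b=6, groups=("KO", "KO_FMT")):
    rows = []
    for i in range(n_a):
        rows.append({"sample": f"a{i}", "group": groups[0]})
    for i in range(n_b):
        rows.append({"sample": f"b{i}", "group": groups[1]})
    return pd.DataFrame(rows).set_index("sample")


def nb_table(rng, n_genes, mu, alpha, n_samples, lfc_log2=None, sf=None):
    """NB count table; optional per-gene log2 effect applied to second half."""
    sf = np.ones(n_samples) if sf is None else sf
    means = np.tile(mu[:, None], (1, n_samples)) * sf[None, :]
    if lfc_log2 is not None:
        means[:, n_samples // 2:] *= 2.0 ** lfc_log2[:, None]
    counts = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * means))
    samples = [f"a{i}" for i in range(n_samples // 2)] + \
              [f"b{i}" for i in range(n_samples - n_samples // 2)]
    return make_count_table(counts, features=[f"g{i}" for i in range(n_genes)],
                            samples=samples)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        table = make_count_table([[10, 10], [3, 3], [7, 7]])
        sf = de.size_factors(table)
        assert np.allclose(sf, 1.0)

    def test_doubled_sample_has_doubled_factor(self):
        base = np.array([[10], [3], [7], [100]])
        table = make_count_table(np.hstack([base, base * 2]))
        sf = de.size_factors(table)
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)

    def test_matches_brute_force_median_of_ratios(self, rng):
        counts = rng.negative_binomial(5, 0.05, size=(200, 6)) + 1
        table = make_count_table(counts)
        sf = de.size_factors(table)
        # independent recomputation straight from the definition
        log_geo = np.log(counts).mean(axis=1)
        for j in range(6):
            expected = np.exp(np.median(np.log(counts[:, j]) - log_geo))
            assert sf.iloc[j] == pytest.approx(expected)

    def test_equivariance_multiplying_a_sample(self, rng):
        # factors are defined up to a global constant, so the *relative*
        # factor of the scaled sample grows by exactly c
        counts = rng.negative_binomial(5, 0.05, size=(100, 4)) + 1
        sf_a = de.size_factors(make_count_table(counts))
        scaled = counts.copy()
        scaled[:, 2] *= 3
        sf_b = de.size_factors(make_count_table(scaled))
        rel_a = sf_a.iloc[2] / sf_a.iloc[0]
        rel_b = sf_b.iloc[2] / sf_b.iloc[0]
        assert rel_b / rel_a == pytest.approx(3.0)


class TestEstimateDispersion:
    def test_poisson_data_shrinks_to_zero(self, rng):
        mu = rng.lognormal(5, 1, size=2000)
        counts = rng.poisson(np.tile(mu[:, None], (1, 12)))
        table = make_count_table(counts, samples=[f"a{i}" for i in range(6)]
                                 + [f"b{i}" for i in range(6)])
        sf = de.size_factors(table)
        disp = de.estimate_dispersion(table, sf, group_meta())
        assert disp.table["final_alpha"].median() <= 0.01

    def test_nb_dispersion_recovered(self, rng):
        mu = rng.lognormal(5, 1, size=2000)
        table = nb_table(rng, 2000, mu, 0.2, 12)
        sf = de.size_factors(table)
        disp = de.estimate_dispersion(table, sf, group_meta())
        assert 0.1 <= disp.table["final_alpha"].median() <= 0.4

    def test_underdispersed_gene_clamps_to_trend(self):
        # variance < mean for the first gene: raw alpha floored at 0
        counts = np.array([[50, 50, 51, 49, 50, 50, 50, 50, 51, 49, 50, 50]])
        counts = np.vstack([counts, np.random.default_rng(0).poisson(
            30, size=(30, 12)) + 1])
        table = make_count_table(counts, samples=[f"a{i}" for i in range(6)]
                                 + [f"b{i}" for i in range(6)])
        sf = pd.Series(1.0, index=table.sample_ids)
        disp = de.estimate_dispersion(table, sf, group_meta())
        assert disp.table["raw_alpha"].iloc[0] == 0.0
        assert disp.table["final_alpha"].iloc[0] > 0

    def test_single_replicate_design_is_an_error(self):
        table = make_count_table([[5, 6]], samples=["a0", "b0"])
        meta = pd.DataFrame({"group": ["KO", "KO_FMT"]}, index=["a0", "b0"])
        sf = pd.Series(1.0, index=table.sample_ids)
        with pytest.raises(ValidationError):
            de.estimate_dispersion(table, sf, meta)


class TestNbWaldTest:
    def run(self, table, meta, contrast=("KO", "KO_FMT")):
        sf = de.size_factors(table)
        disp = de.estimate_dispersion(table, sf, meta)
        return de.nb_wald_test(table, sf, disp, meta, contrast)

    def test_identical_groups_give_zero_lfc(self, rng):
        counts = rng.poisson(100, size=(50, 6))
        counts = np.hstack([counts, counts])
        table = make_count_table(counts, samples=[f"a{i}" for i in range(6)]
                                 + [f"b{i}" for i in range(6)])
        res = self.run(table, group_meta())
        assert np.allclose(res["log2FC"], 0.0, atol=1e-8)
        assert (res["p"] > 0.99).all()

    def test_sign_convention_and_antisymmetry(self, rng):
        # balanced planted effects on 20% of genes keep median-of-ratios honest
        mu = rng.lognormal(5, 0.8, size=300)
        lfc = np.zeros(300)
        lfc[240:270] = 1.0
        lfc[270:] = -1.0
        table = nb_table(rng, 300, mu, 0.1, 12, lfc_log2=lfc)
        meta = group_meta()
        sf = de.size_factors(table)
        disp = de.estimate_dispersion(table, sf, meta)
        fwd = de.nb_wald_test(table, sf, disp, meta, ("KO", "KO_FMT"))
        rev = de.nb_wald_test(table, sf, disp, meta, ("KO_FMT", "KO"))
        assert np.allclose(fwd["log2FC"], -rev["log2FC"], atol=1e-10)
        assert np.allclose(fwd["wald_z"], -rev["wald_z"], atol=1e-10)
        assert np.allclose(fwd["p"], rev["p"], atol=1e-10)
        assert np.sign(fwd["log2FC"]).equals(np.sign(fwd["wald_z"]))
        # planted positive effects point in the +lfc direction of the test group
        assert fwd["log2FC"].iloc[240:270].median() == pytest.approx(1.0, abs=0.15)

    def test_lfc_invariant_to_sample_scaling(self, rng):
        mu = rng.lognormal(5, 0.8, size=200)
        table = nb_table(rng, 200, mu, 0.1, 12)
        res_a = self.run(table, group_meta())
        scaled = table.data.copy()
        scaled.iloc[:, 0] = (scaled.iloc[:, 0] * 4).astype(int)
        res_b = self.run(make_count_table(scaled.to_numpy(),
                                          samples=table.sample_ids), group_meta())
        assert np.corrcoef(res_a["log2FC"], res_b["log2FC"])[0, 1] > 0.99

    def test_unknown_contrast_group_is_an_error(self, rng):
        table = nb_table(rng, 20, np.full(20, 50.0), 0.1, 12)
        with pytest.raises(ValidationError):
            self.run(table, group_meta(), contrast=("KO", "nope"))

    def test_agrees_with_reference_nb_wald_engine(self, rng):
        """Independent cross-check: log2FC agrees closely and p-values rank
        consistently with an established NB-Wald DE implementation."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        mu = rng.lognormal(5, 0.7, size=300)
        lfc = np.zeros(300)
        lfc[::5] = rng.choice([-1.5, 1.5], size=60)
        table = nb_table(rng, 300, mu, 0.15, 12, lfc_log2=lfc)
        meta = group_meta()
        res = self.run(table, meta)

        adata_meta = pd.DataFrame({"condition": ["A"] * 6 + ["B"] * 6},
                                  index=table.sample_ids)
        dds = DeseqDataSet(counts=table.data.T, metadata=adata_meta,
                           design="~condition", quiet=True)
        dds.deseq2()
        stat = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
        stat.summary()
        ref = stat.results_df
        shared = res.index.intersection(ref.index)
        r = np.corrcoef(res.loc[shared, "log2FC"],
                        ref.loc[shared, "log2FoldChange"])[0, 1]
        assert r > 0.98
        planted = [f"g{i}" for i in range(0, 300, 5)]
        assert np.corrcoef(res.loc[planted, "log2FC"],
                           ref.loc[planted, "log2FoldChange"])[0, 1] > 0.98


class TestOraEnrichment:
    def test_expected_count_and_exact_tail(self):
        universe = [f"g{i}" for i in range(100)]
        gene_set = universe[:10]
        de_genes = universe[8:28]  # overlap = 2
        out = de.ora_enrichment(de_genes, {"S": gene_set}, universe)
        row = out.loc["S"]
        assert row["overlap"] == 2
        assert row["expected"] == pytest.approx(2.0)
        # independent brute-force hypergeometric tail
        def hyper_tail(k_min, n, k_set, k_de):
            total = math.comb(n, k_de)
            return sum(math.comb(k_set, k) * math.comb(n - k_set, k_de - k)
                       for k in range(k_min, min(k_set, k_de) + 1)) / total
        assert row["p_hyper"] == pytest.approx(hyper_tail(2, 100, 10, 20), rel=1e-9)
        assert 0.6 < row["p_hyper"] < 0.75

    def test_saturated_overlap_trivial(self):
        universe = [f"g{i}" for i in range(12)]
        out = de.ora_enrichment(universe, {"S": universe}, universe)
        assert out.loc["S", "p_hyper"] == pytest.approx(1.0)
        assert out.loc["S", "expected"] == pytest.approx(12.0)

    def test_strong_overlap_is_extreme(self):
        universe = [f"g{i}" for i in range(100)]
        gene_set = universe[:10]
        de_genes = universe[:9] + universe[50:61]
        out = de.ora_enrichment(de_genes, {"S": gene_set}, universe)
        assert out.loc["S", "overlap"] == 9
        assert out.loc["S", "p_hyper"] < 1e-5

    def test_matches_enumeration_on_tiny_universes(self, rng):
        """Exhaustive check for universes <= 25 against combinatorial sums."""
        for trial in range(10):
            n = int(rng.integers(5, 26))
            universe = [f"g{i}" for i in range(n)]
            k_set = int(rng.integers(1, n + 1))
            k_de = int(rng.integers(1, n + 1))
            gene_set = list(rng.choice(universe, size=k_set, replace=False))
            de_genes = list(rng.choice(universe, size=k_de, replace=False))
            out = de.ora_enrichment(de_genes, {"S": gene_set}, universe)
            overlap = len(set(gene_set) & set(de_genes))
            total = math.comb(n, k_de)
            tail = sum(
                math.comb(k_set, k) * math.comb(n - k_set, k_de - k)
                for k in range(overlap, min(k_set, k_de) + 1)) / total
            assert out.loc["S", "p_hyper"] == pytest.approx(tail, rel=1e-9)

    def test_empty_universe_is_an_error(self):
        with pytest.raises(ValidationError):
            de.ora_enrichment(["g1"], {"S": ["g1"]}, [])
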