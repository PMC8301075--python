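"""Signed-Z combination, heterogeneity, and the three-criterion filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from t21meta.de import run_de
from t21meta.exceptions import ContractError, DataError
from t21meta.harmonize import harmonize_study
from t21meta.meta import combine_stouffer, heterogeneity_test, run_meta, signed_z
from t21meta.simulate import simulate_studies, small_config


class TestSignedZ:
    def test_p_one_gives_zero(self):
        assert signed_z(1.0, 0.8) == pytest.approx(0.0)
        assert signed_z(1.0, -2.0) == pytest.approx(0.0)

    def test_quantile_oracle_and_antisymmetry(self):
        # Phi^-1(1 - 0.05/2) = 1.959964...
        assert signed_z(0.05, 0.8) == pytest.approx(1.959964, abs=1e-5)
        assert signed_z(0.05, -0.8) == pytest.approx(-1.959964, abs=1e-5)

    def test_zero_lfc_gives_zero_z(self):
        assert signed_z(0.001, 0.0) == 0.0

    def test_out_of_range_p_raises(self):
        with pytest.raises(DataError):
            signed_z(0.0, 1.0)
        with pytest.raises(DataError):
            signed_z(1.5, 1.0)

    @given(
        st.floats(1e-10, 1.0),
        st.floats(-5, 5).filter(lambda x: abs(x) > 1e-6),
    )
    @settings(max_examples=100, deadline=None)
    def test_roundtrip_through_p(self, p, lfc):
        """For a nonzero fold change, |Z| converts back to the two-sided p."""
        z = signed_z(p, lfc)
        back = 2 * stats.norm.sf(abs(z))
        assert back == pytest.approx(p, rel=1e-7, abs=1e-12)


class TestCombineStouffer:
    def test_single_study_identity(self):
        z, p = combine_stouffer([1.7], [9])
        assert z == pytest.approx(1.7)
        assert p == pytest.approx(2 * stats.norm.sf(1.7))

    def test_symmetric_cancellation(self):
        z, p = combine_stouffer([1.96, -1.96], [10, 10])
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # w = (3, 4): Z = (3*2 + 4*1)/sqrt(9+16) = 2.0
        z, p = combine_stouffer([2.0, 1.0], [9, 16])
        assert z == pytest.approx(2.0)
        assert p == pytest.approx(0.0455, abs=2e-4)

    def test_order_invariance(self, rng):
        zs = rng.normal(size=6)
        ns = rng.integers(3, 40, size=6)
        z1, _ = combine_stouffer(zs, ns)
        perm = rng.permutation(6)
        z2, _ = combine_stouffer(zs[perm], ns[perm])
        assert z1 == pytest.approx(z2, rel=1e-12)

    def test_weight_scale_invariance(self, rng):
        zs = rng.normal(size=4)
        ns = np.array([9, 7, 27, 6])
        z1, _ = combine_stouffer(zs, ns)
        z2, _ = combine_stouffer(zs, ns * 17)
        assert z1 == pytest.approx(z2, rel=1e-12)

    def test_matches_p_transform_oracle(self, rng):
        """Equals an oracle that routes every study through (p, sign) pairs."""
        for _ in range(50):
            k = rng.integers(1, 6)
            zs = rng.normal(size=k) * 2
            ns = rng.integers(2, 50, size=k)
            p_in = 2 * stats.norm.sf(np.abs(zs))
            z_back = np.sign(zs) * stats.norm.isf(p_in / 2)
            w = np.sqrt(ns)
            oracle = np.sum(w * z_back) / np.sqrt(np.sum(w**2))
            z, _ = combine_stouffer(zs, ns)
            assert z == pytest.approx(oracle, abs=1e-10)

    def test_empty_input_raises(self):
        with pytest.raises(ContractError):
            combine_stouffer([], [])


class TestHeterogeneity:
    def test_identical_z_gives_zero_q(self):
        q, het_p = heterogeneity_test([1.3, 1.3, 1.3])
        assert q == pytest.approx(0.0, abs=1e-12)
        assert het_p == pytest.approx(1.0)

    def test_opposite_z_chi2_oracle(self):
        # Z=(2,-2): Q = (2-0)^2 + (-2-0)^2 = 8; HetP = P(chi2_1 >= 8)
        q, het_p = heterogeneity_test([2.0, -2.0])
        assert q == pytest.approx(8.0)
        assert het_p == pytest.approx(stats.chi2.sf(8.0, 1), rel=1e-12)
        assert het_p == pytest.approx(0.00468, abs=5e-5)

    def test_continuity_in_perturbation(self):
        for eps in (1e-2, 1e-4, 1e-6):
            q, het_p = heterogeneity_test([1.0, 1.0, 1.0, 1.0 + eps])
            assert q == pytest.approx(0.75 * eps**2, rel=1e-6)
        assert heterogeneity_test([1.0, 1.0, 1.0, 1.0 + 1e-9])[1] > 0.999999

    def test_single_study_convention(self):
        assert heterogeneity_test([2.2]) == (0.0, 1.0)

    def test_weighted_form_reduces_to_plain_for_equal_weights(self, rng):
        zs = rng.normal(size=5)
        q_plain, _ = heterogeneity_test(zs)
        q_w, _ = heterogeneity_test(zs, weights=np.full(5, 3.3))
        assert q_plain == pytest.approx(q_w, rel=1e-10)

    def test_weighted_form_central_under_proportional_means(self, rng):
        """Q stays chi2_{k-1} when E[Z_i] is proportional to the weights."""
        w = np.sqrt(np.array([9.0, 7.0, 27.0, 6.0]))
        qs = []
        for _ in range(2000):
            zs = 0.9 * w + rng.normal(size=4)
            qs.append(heterogeneity_test(zs, weights=w)[0])
        # mean of chi2_3 is 3
        assert np.mean(qs) == pytest.approx(3.0, abs=0.2)


def _de_table(study_id, genes, lfc, p, n_case, n_control):
    n = len(genes)
    return pd.DataFrame(
        {
            "study_id": study_id,
            "gene": genes,
            "log2fc": lfc,
            "p": p,
            "n_case": n_case,
            "n_control": n_control,
            "n_total": n_case + n_control,
        }
    )


class TestRunMeta:
    def test_three_criterion_filter(self):
        """Strong concordant gene included; single-study gene excluded."""
        # geneA: significant in 3 equal-size studies, concordant, k=3
        # geneB: significant in 1 study only (k=1)
        # geneC: measured twice, null
        tables = [
            _de_table("s1", ["geneA", "geneB", "geneC"],
                      [1.0, 2.0, 0.01], [1e-8, 1e-9, 0.9], 5, 5),
            _de_table("s2", ["geneA", "geneC"], [0.9, -0.02], [1e-7, 0.8], 5, 5),
            _de_table("s3", ["geneA"], [1.1], [1e-6], 5, 5),
        ]
        rec, summary = run_meta(tables)
        rec = rec.set_index("gene")
        assert bool(rec.loc["geneA", "included"])
        assert rec.loc["geneA", "direction"] == "up"
        assert not rec.loc["geneB", "included"]
        assert "fewer than two datasets" in rec.loc["geneB", "reason_excluded"]
        assert not rec.loc["geneC", "included"]
        assert summary["genes_entered"] == 3
        assert summary["included"] == summary["up"] + summary["down"] == 1

    def test_discordant_gene_fails_heterogeneity(self):
        tables = [
            _de_table("s1", ["g"], [2.0], [1e-12], 10, 10),
            _de_table("s2", ["g"], [-2.0], [1e-12], 10, 10),
        ]
        rec, _ = run_meta(tables)
        row = rec.iloc[0]
        assert not row["included"]
        assert "HetP" in row["reason_excluded"]

    def test_duplicate_study_gene_raises(self):
        t = _de_table("s1", ["g", "g"], [1.0, 1.0], [0.01, 0.01], 3, 3)
        with pytest.raises(ContractError):
            run_meta([t])

    def test_up_plus_down_equals_included(self):
        studies, maps, _ = simulate_studies(small_config(seed=21))
        harm = [harmonize_study(s, pm) for s, pm in zip(studies, maps)]
        rec, summary = run_meta([run_de(s) for s in harm])
        inc = rec[rec["included"]]
        assert summary["included"] == len(inc)
        assert summary["up"] + summary["down"] == summary["included"]
        assert (inc.loc[inc["direction"] == "up", "z_meta"] > 0).all()
        assert (inc.loc[inc["direction"] == "down", "z_meta"] < 0).all()
        # included implies all three criteria
        assert (inc["q_meta"] <= 0.01).all()
        assert (inc["k"] >= 2).all()
        assert (inc["het_p"] > 0.05).all()

    def test_null_z_meta_standard_normal(self):
        cfg = small_config(seed=31, cis_fraction=0.0, trans_fraction=0.0)
        studies, maps, _ = simulate_studies(cfg)
        harm = [harmonize_study(s, pm) for s, pm in zip(studies, maps)]
        rec, _ = run_meta([run_de(s) for s in harm])
        assert len(rec) >= 1900
        ks = stats.kstest(rec["z_meta"], "norm")
        assert ks.pvalue > 0.01

    def test_cis_recovery_on_default_shapes(self):
        """Scaled-down trisomy design: >=90% of cis genes with k>=2 recovered."""
        cfg = small_config(seed=42, cis_fraction=0.05)
        studies, maps, truth = simulate_studies(cfg)
        harm = [harmonize_study(s, pm) for s, pm in zip(studies, maps)]
        rec, _ = run_meta([run_de(s) for s in harm])
        cis = rec[rec["gene"].isin(truth.cis_genes) & (rec["k"] >= 2)]
        assert len(cis) > 50
        assert cis["included"].mean() >= 0.9
        assert (cis.loc[cis["included"], "direction"] == "up").all()
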