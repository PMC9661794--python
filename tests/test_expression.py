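"""FPKM, DEG calling, TOM and module detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from nbsevolve import expression, synthetic
from nbsevolve.expression import (
    bh_adjust,
    call_degs,
    compute_fpkm,
    detect_modules,
    module_eigengene,
    module_trait_correlation,
    soft_adjacency,
    tom_similarity,
)


def _fpkm_frame(values, samples=None):
    arr = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                        columns=samples)


class TestFPKM:
    def test_closed_form(self):
        counts = pd.DataFrame({"s1": [10]}, index=["g1"])
        fpkm = compute_fpkm(counts, pd.Series({"g1": 2000}),
                            library_sizes=pd.Series({"s1": 1e6}))
        assert fpkm.loc["g1", "s1"] == pytest.approx(5.0)

    def test_zero_count_zero_fpkm(self):
        counts = pd.DataFrame({"s1": [0, 100]}, index=["g1", "g2"])
        fpkm = compute_fpkm(counts, pd.Series({"g1": 1000, "g2": 1000}))
        assert fpkm.loc["g1", "s1"] == 0.0

    def test_doubling_library_halves_fpkm(self):
        counts = pd.DataFrame({"s1": [10, 30]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 500, "g2": 1500})
        a = compute_fpkm(counts, lengths, pd.Series({"s1": 1e6}))
        b = compute_fpkm(counts, lengths, pd.Series({"s1": 2e6}))
        assert np.allclose(a.values, 2 * b.values)

    def test_scaling_all_counts_leaves_fpkm_unchanged(self):
        counts = pd.DataFrame({"s1": [10, 30], "s2": [5, 80]},
                              index=["g1", "g2"])
        lengths = pd.Series({"g1": 500, "g2": 1500})
        assert np.allclose(
            compute_fpkm(counts, lengths).values,
            compute_fpkm(counts * 7, lengths).values,
        )

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"s1": [0]}, index=["g1"])
        with pytest.raises(ValueError, match="zero library"):
            compute_fpkm(counts, pd.Series({"g1": 1000}))


class TestBHAdjust:
    def test_hand_stepped_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=100)
        assert (bh_adjust(p) >= p - 1e-15).all()

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


class TestCallDEGs:
    def _design(self, nt=3, nc=3):
        names = [f"T{i}" for i in range(nt)] + [f"C{i}" for i in range(nc)]
        return pd.Series(["treated"] * nt + ["control"] * nc, index=names)

    def test_strict_fold_change_threshold(self):
        """A gene at exactly 1.5-fold is not called up."""
        fpkm = _fpkm_frame(
            [[150, 150, 150, 100, 100, 100]],
            samples=list(self._design().index),
        )
        # remove pseudo-count distortion: FC = (150+.01)/(100+.01) > 1.49994
        (rec,) = call_degs(fpkm, self._design())
        assert rec.fold_change < 1.5 or rec.status != "up"
        assert rec.status == "ns"

    def test_up_requires_both_criteria(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(50, 60, (30, 6))
        base[0, :3] *= 4.0  # strong planted effect
        fpkm = _fpkm_frame(base, samples=list(self._design().index))
        recs = {r.gene_id: r for r in call_degs(fpkm, self._design())}
        assert recs["g0"].status == "up"
        assert recs["g0"].fold_change > 1.5 and recs["g0"].p_adj < 0.05

    def test_down_mirrors_up(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(50, 60, (30, 6))
        base[0, :3] /= 4.0
        fpkm = _fpkm_frame(base, samples=list(self._design().index))
        recs = {r.gene_id: r for r in call_degs(fpkm, self._design())}
        assert recs["g0"].status == "down"

    def test_insufficient_replicates_rejected(self):
        fpkm = _fpkm_frame([[1, 2, 3]], samples=["T0", "C0", "C1"])
        design = pd.Series(["treated", "control", "control"],
                           index=["T0", "C0", "C1"])
        with pytest.raises(ValueError, match="replicates"):
            call_degs(fpkm, design)

    def test_padj_at_least_praw(self):
        rng = np.random.default_rng(4)
        fpkm = _fpkm_frame(rng.uniform(10, 100, (50, 6)),
                           samples=list(self._design().index))
        for r in call_degs(fpkm, self._design()):
            assert r.p_adj >= r.p_raw - 1e-15

    def test_status_monotone_in_padj(self):
        """Raising the significance bar never turns ns into up."""
        counts, lengths, design, truth = synthetic.generate_expression(
            synthetic.preset_deg_calibration(), 11
        )
        fpkm = compute_fpkm(counts, lengths)
        strict = {r.gene_id: r.status for r in call_degs(fpkm, design, p_adj_max=0.01)}
        loose = {r.gene_id: r.status for r in call_degs(fpkm, design, p_adj_max=0.05)}
        for g, s in strict.items():
            if s == "up":
                assert loose[g] == "up"


class TestAdjacency:
    def test_perfect_correlation_any_beta(self):
        fpkm = _fpkm_frame([[1, 2, 3, 4], [2, 4, 6, 8]])
        for beta in (1, 2, 6):
            a = soft_adjacency(fpkm, beta)
            assert a.iloc[0, 1] == pytest.approx(1.0)
            assert a.iloc[0, 0] == 0.0

    def test_orthogonal_vectors_zero(self):
        fpkm = _fpkm_frame([[1, -1, 1, -1], [1, 1, -1, -1]])
        assert soft_adjacency(fpkm, 2).iloc[0, 1] == pytest.approx(0.0)

    def test_negative_half_squared(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 1.0])
        r = np.corrcoef(x, y)[0, 1]
        a = soft_adjacency(_fpkm_frame([x, y]), 2)
        assert a.iloc[0, 1] == pytest.approx(r**2)

    def test_constant_row_rejected(self):
        fpkm = _fpkm_frame([[5, 5, 5, 5], [1, 2, 3, 4]])
        with pytest.raises(ValueError, match="constant"):
            soft_adjacency(fpkm)


class TestTOM:
    def test_complete_graph(self):
        a = np.ones((3, 3)) - np.eye(3)
        tom = tom_similarity(a)
        assert np.allclose(tom, 1.0)

    def test_empty_graph(self):
        tom = tom_similarity(np.zeros((4, 4)))
        assert np.allclose(tom[np.triu_indices(4, 1)], 0.0)
        assert np.allclose(np.diag(tom), 1.0)

    def test_three_node_path(self):
        a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        tom = tom_similarity(a)
        assert tom[0, 2] == pytest.approx(0.5)
        assert tom[0, 1] == pytest.approx((0 + 1) / (1 + 1 - 1))

    def test_asymmetric_rejected(self):
        a = np.array([[0, 0.5], [0.4, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(a)

    @given(
        arrays(
            float,
            st.integers(min_value=2, max_value=12).map(lambda n: (n, n)),
            elements=st.floats(min_value=0, max_value=1),
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_range_and_symmetry_on_random_adjacency(self, raw):
        a = (raw + raw.T) / 2.0
        np.fill_diagonal(a, 0.0)
        tom = tom_similarity(a)
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0.0 and tom.max() <= 1.0


class TestModules:
    def test_single_tight_block(self):
        a = np.full((40, 40), 0.9)
        np.fill_diagonal(a, 0.0)
        labels = detect_modules(tom_similarity(a), min_module_size=30)
        assert set(labels) == {"turquoise"}

    def test_small_input_all_grey(self):
        a = np.full((20, 20), 0.9)
        np.fill_diagonal(a, 0.0)
        labels = detect_modules(tom_similarity(a), min_module_size=30)
        assert set(labels) == {"grey"}

    def test_planted_two_block_design_recovered(self):
        counts, lengths, design, truth = synthetic.generate_expression(
            synthetic.preset_module_design(), 1
        )
        lg = np.log2(compute_fpkm(counts, lengths) + 1)
        tom = tom_similarity(soft_adjacency(lg).values)
        labels = detect_modules(tom, genes=lg.index)
        nongrey = sorted(set(labels) - {"grey"})
        assert len(nongrey) == 2
        for members in truth.module_blocks.values():
            counts_in = labels.loc[members].value_counts()
            assert counts_in.index[0] != "grey"
            assert counts_in.iloc[0] / len(members) >= 0.95


class TestEigengene:
    def test_shared_profile_recovered(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0])
        fpkm = _fpkm_frame([profile * c for c in (1, 2, 5)])
        eig = module_eigengene(fpkm, fpkm.index)
        z = (profile - profile.mean()) / profile.std()
        r = np.corrcoef(eig.values, z)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)
        assert r > 0  # orientation follows the members' mean profile

    def test_orientation_is_deterministic_under_global_sign_flip(self):
        """Flipping every member row flips the mean profile, so the oriented
        eigengene flips with it — the module axis itself is unchanged."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=(10, 6))
        a = module_eigengene(_fpkm_frame(x), [f"g{i}" for i in range(10)])
        b = module_eigengene(_fpkm_frame(-x), [f"g{i}" for i in range(10)])
        assert np.allclose(a.values, -b.values)
        assert abs(np.corrcoef(a.values, b.values)[0, 1]) == pytest.approx(1.0)

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            module_eigengene(_fpkm_frame([[1, 2, 3]]), [])

    def test_planted_factor_recovered_under_noise(self):
        rng = np.random.default_rng(6)
        factor = rng.normal(size=12)
        x = np.outer(rng.uniform(0.5, 2.0, 30), factor) + rng.normal(0, 0.1, (30, 12))
        eig = module_eigengene(_fpkm_frame(x), [f"g{i}" for i in range(30)])
        assert abs(np.corrcoef(eig.values, factor)[0, 1]) >= 0.95


class TestTraitCorrelation:
    def test_indicator_itself(self):
        eig = pd.Series([0.5, 0.5, -0.5, -0.5], index=list("abcd"))
        r, _ = module_trait_correlation(eig, pd.Series([1, 1, 0, 0], index=list("abcd")))
        assert r == pytest.approx(1.0)

    def test_orthogonal_trait(self):
        eig = pd.Series([1.0, -1.0, 1.0, -1.0], index=list("abcd"))
        r, _ = module_trait_correlation(eig, pd.Series([1, 1, 0, 0], index=list("abcd")))
        assert r == pytest.approx(0.0)

    def test_treatment_module_ranks_first_from_planted_membership(self):
        """3v3 design: the treatment-driven block's eigengene out-correlates
        the latent block's in at least 18 of 20 seeds."""
        wins = 0
        cfg = synthetic.ExpressionConfig(
            n_treated=3, n_control=3, n_up=0, dispersion=0.02,
            module_blocks=(
                synthetic.ModuleBlockSpec(40, "treatment", 1.2),
                synthetic.ModuleBlockSpec(40, "latent", 0.6),
            ),
        )
        for seed in range(1, 21):
            counts, lengths, design, truth = synthetic.generate_expression(cfg, seed)
            lg = np.log2(compute_fpkm(counts, lengths) + 1)
            trait = (design == "treated").astype(float)
            scores = {}
            for label, members in truth.module_blocks.items():
                eig = module_eigengene(lg, members)
                r, _ = module_trait_correlation(eig, trait)
                scores[label.split(":")[1]] = abs(r)
            wins += scores["treatment"] > scores["latent"]
        assert wins >= 18
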