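"""Design construction, OLS fitting, and Holm-Bonferroni voxel selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from laminarbold.glm import (
    build_design,
    fit_glm,
    holm_select,
    orthogonalize_confounds,
)
from laminarbold.synth import Block, GasProtocol, make_motion_params, make_protocol


def _nuisance(protocol, seed=0):
    rng = np.random.default_rng(seed)
    cols = make_motion_params(protocol, seed=seed)
    cols["rvt"] = rng.normal(0.5, 0.1, protocol.n_volumes)
    cols["bpm"] = rng.normal(65.0, 2.0, protocol.n_volumes)
    return cols


class TestDesign:
    def test_default_column_count(self, protocol):
        design = build_design(protocol, _nuisance(protocol))
        # intercept + 3 gas conditions + 8 nuisance
        assert design.matrix.shape == (820, 12)
        assert design.names[0] == "intercept"
        assert design.condition_names == ["hc+5", "hc+10", "ho+350"]

    def test_condition_columns_are_binary_block_indicators(self, protocol):
        design = build_design(protocol, None)
        col = design.column("hc+10")
        assert set(np.unique(col)) == {0.0, 1.0}
        assert abs(col.sum() - 120.0 / 0.85) <= 1.0
        np.testing.assert_array_equal(col.astype(bool), protocol.volumes_in("hc+10"))

    def test_condition_columns_disjoint(self, protocol):
        design = build_design(protocol, None)
        cols = [design.column(c) for c in design.condition_names]
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                assert cols[i] @ cols[j] == 0.0

    def test_nuisance_mean_centred(self, protocol):
        design = build_design(protocol, _nuisance(protocol))
        np.testing.assert_allclose(design.column("rvt").mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(design.column("bpm").mean(), 0.0, atol=1e-12)

    def test_overlapping_blocks_rejected(self):
        class Overlapping(GasProtocol):
            # forge a protocol whose condition indicators coincide in time
            def volumes_in(self, label):
                return np.ones(self.n_volumes, bool)

        proto = Overlapping(blocks=(
            Block("hc+5", 120.0, dpetco2=5.0),
            Block("hc+10", 120.0, dpetco2=10.0),
        ))
        with pytest.raises(ValueError, match="overlap"):
            build_design(proto, None)

    def test_length_mismatch_rejected(self, protocol):
        with pytest.raises(ValueError, match="sample count"):
            build_design(protocol, np.zeros((10, 8)))


class TestFit:
    def test_noiseless_betas_recovered_exactly(self, protocol, rng):
        design = build_design(protocol, _nuisance(protocol))
        beta_true = rng.normal(size=(design.matrix.shape[1], 7))
        data = design.matrix @ beta_true
        result = fit_glm(data, design)
        np.testing.assert_allclose(result.beta.T, beta_true, atol=1e-9)

    def test_matches_bruteforce_normal_equations(self, protocol, rng):
        """OLS beta/se/t agree with an explicit normal-equations oracle < 1e-10."""
        design = build_design(protocol, _nuisance(protocol))
        X = design.matrix
        data = rng.normal(size=(820, 5)) + X @ rng.normal(size=(X.shape[1], 5))
        result = fit_glm(data, design)

        xtx_inv = np.linalg.inv(X.T @ X)
        for v in range(5):
            beta = xtx_inv @ X.T @ data[:, v]
            resid = data[:, v] - X @ beta
            dof = X.shape[0] - X.shape[1]
            sigma2 = resid @ resid / dof
            se = np.sqrt(sigma2 * np.diag(xtx_inv))
            np.testing.assert_allclose(result.beta[v], beta, atol=1e-10)
            np.testing.assert_allclose(result.se[v], se, atol=1e-10)
            np.testing.assert_allclose(result.t[v], beta / se, atol=1e-10)

    def test_matches_statsmodels_reference(self, protocol, rng):
        sm = pytest.importorskip("statsmodels.api")
        design = build_design(protocol, _nuisance(protocol))
        y = rng.normal(size=820) + 0.5 * design.column("hc+10")
        ref = sm.OLS(y, design.matrix).fit()
        result = fit_glm(y, design)
        np.testing.assert_allclose(result.beta[0], ref.params, atol=1e-10)
        np.testing.assert_allclose(result.t[0], ref.tvalues, atol=1e-8)
        np.testing.assert_allclose(result.p[0], ref.pvalues, atol=1e-10)
        f_ref = ref.f_test(np.eye(len(design.names))[
            [design.names.index(c) for c in design.condition_names]
        ])
        np.testing.assert_allclose(result.f_stat[0], float(f_ref.fvalue), rtol=1e-8)
        np.testing.assert_allclose(result.f_p[0], float(f_ref.pvalue), atol=1e-12)

    def test_voxel_permutation_equivariance(self, protocol, rng):
        design = build_design(protocol, None)
        data = rng.normal(size=(820, 20))
        perm = rng.permutation(20)
        a = fit_glm(data, design)
        b = fit_glm(data[:, perm], design)
        np.testing.assert_allclose(b.beta, a.beta[perm], atol=1e-12)

    def test_rank_deficiency_names_columns(self, protocol):
        design = build_design(protocol, None)
        dup = design.with_confounds(design.column("hc+5")[:, None], ["hc+5_copy"])
        with pytest.raises(ValueError, match="hc\\+5"):
            fit_glm(np.zeros(820), dup)

    def test_nan_voxels_propagate_not_poison(self, protocol, rng):
        design = build_design(protocol, None)
        data = rng.normal(size=(820, 3))
        data[:, 1] = np.nan
        result = fit_glm(data, design)
        assert np.isnan(result.beta[1]).all()
        assert np.isfinite(result.beta[[0, 2]]).all()

    def test_confound_orthogonalization_leaves_task_betas(self, protocol, rng):
        """Orthogonalised confounds cannot change condition estimates."""
        design = build_design(protocol, None)
        data = rng.normal(size=(820, 4)) + design.matrix @ rng.normal(size=(4, 4))
        conf = rng.normal(size=(820, 5))
        plain = fit_glm(data, design)
        orth = orthogonalize_confounds(conf, design.matrix)
        with_conf = fit_glm(data, design.with_confounds(orth, [f"c{k}" for k in range(orth.shape[1])]))
        for c in design.condition_names:
            np.testing.assert_allclose(with_conf.coef(c), plain.coef(c), atol=1e-10)


class TestHolm:
    def test_hand_worked_example(self):
        # thresholds 0.05/3, 0.05/2, 0.05: all three rejected
        assert holm_select([0.001, 0.02, 0.04], alpha=0.05).tolist() == [True] * 3

    def test_step_down_stops_at_first_failure(self):
        # 0.001 <= 0.05/3 rejected; 0.03 > 0.05/2 stops; 0.04 not tested
        assert holm_select([0.001, 0.03, 0.04], alpha=0.05).tolist() == [True, False, False]

    def test_all_ones_rejects_none(self):
        assert not holm_select(np.ones(10)).any()

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            holm_select([])

    def test_matches_statsmodels_on_random_families(self, rng):
        """Identical rejection sets to the reference step-down implementation."""
        from statsmodels.stats.multitest import multipletests

        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.uniform(size=m) ** rng.uniform(0.5, 3.0)
            mine = holm_select(p, alpha=0.05)
            ref = multipletests(p, alpha=0.05, method="holm")[0]
            np.testing.assert_array_equal(mine, ref)

    def test_at_least_as_powerful_as_bonferroni(self, rng):
        for _ in range(200):
            p = rng.uniform(size=25)
            holm = holm_select(p, alpha=0.05)
            bonf = p <= 0.05 / p.size
            assert (holm | bonf).tolist() == holm.tolist()  # holm superset

    def test_nan_entries_excluded(self):
        p = np.array([0.001, np.nan, 0.2])
        sel = holm_select(p, alpha=0.05)
        assert sel.tolist() == [True, False, False]
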