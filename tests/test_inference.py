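import itertools
from collections import deque

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reactfc import (
    DesignSpec,
    ModelSpec,
    SyntheticConfig,
    TFCEParams,
    build_design,
    fit_glm_voxelwise,
    freedman_lane_draw,
    generate_cohort,
    gpd_tail_pvalue,
    mask_bold,
    permutation_fwe,
    react,
    run_models,
    tfce_transform,
)


def brute_force_tfce(stat, h_power=2.0, e_power=2.0, n_steps=100):
    """Independent oracle: BFS component labeling at every threshold."""
    pos = np.where(stat > 0, stat, 0.0)
    vmax = pos.max()
    out = np.zeros_like(pos)
    if vmax <= 0:
        return out
    dh = vmax / n_steps
    shape = pos.shape
    for i in range(1, n_steps + 1):
        h = (i - 0.5) * dh
        mask = pos >= h
        if not mask.any():
            break
        seen = np.zeros(shape, bool)
        for start in zip(*np.nonzero(mask)):
            if seen[start]:
                continue
            comp = []
            queue = deque([start])
            seen[start] = True
            while queue:
                x, y, z = queue.popleft()
                comp.append((x, y, z))
                for dx, dy, dz in (
                    (1, 0, 0), (-1, 0, 0), (0, 1, 0),
                    (0, -1, 0), (0, 0, 1), (0, 0, -1),
                ):
                    xx, yy, zz = x + dx, y + dy, z + dz
                    if (
                        0 <= xx < shape[0] and 0 <= yy < shape[1]
                        and 0 <= zz < shape[2]
                        and mask[xx, yy, zz] and not seen[xx, yy, zz]
                    ):
                        seen[xx, yy, zz] = True
                        queue.append((xx, yy, zz))
            inc = (len(comp) ** e_power) * (h ** h_power) * dh
            for vox in comp:
                out[vox] += inc
    return out


def _group_design(groups):
    n = len(groups)
    design = np.column_stack([np.ones(n), np.asarray(groups, float)])
    return DesignSpec(design=design, contrast=np.array([0.0, 1.0]), nuisance_idx=(0,))


class TestGLM:
    def test_equals_two_sample_t(self, rng):
        g = np.array([0] * 9 + [1] * 11)
        y = rng.normal(size=(20, 30)) + g[:, None] * 0.4
        t = fit_glm_voxelwise(y, _group_design(g))
        ref = stats.ttest_ind(y[g == 1], y[g == 0], equal_var=True)
        assert np.allclose(t, ref.statistic, rtol=1e-10)

    def test_orthogonal_response_gives_zero_t(self, rng):
        g = np.array([0.0] * 5 + [1.0] * 5)
        y = np.tile(np.r_[np.ones(5), np.ones(5)], (3, 1)).T
        t = fit_glm_voxelwise(y + 0.0, _group_design(g))
        assert np.allclose(t, 0.0)

    def test_matches_algebraic_oracle(self):
        rng = np.random.default_rng(5)
        N, P, V = 20, 4, 15
        X = np.column_stack([np.ones(N), rng.normal(size=(N, P - 1))])
        c = np.array([0.0, 1.0, 0.0, 0.0])
        Y = rng.normal(size=(N, V))
        spec = DesignSpec(design=X, contrast=c, nuisance_idx=(0, 2, 3))
        t = fit_glm_voxelwise(Y, spec)
        xtx_inv = np.linalg.inv(X.T @ X)
        for v in range(V):
            beta = xtx_inv @ X.T @ Y[:, v]
            resid = Y[:, v] - X @ beta
            sigma2 = resid @ resid / (N - P)
            oracle = (c @ beta) / np.sqrt(sigma2 * (c @ xtx_inv @ c))
            assert t[v] == pytest.approx(oracle, rel=1e-8)

    def test_design_validation(self, rng):
        X = np.column_stack([np.ones(6), np.arange(6.0)])
        with pytest.raises(ValueError, match="nonzero"):
            DesignSpec(design=X, contrast=np.zeros(2))
        with pytest.raises(ValueError, match="rank"):
            DesignSpec(
                design=np.column_stack([X, X[:, 1]]), contrast=np.array([0, 0, 1.0])
            )
        with pytest.raises(ValueError, match="nuisance"):
            DesignSpec(design=X, contrast=np.array([0, 1.0]), nuisance_idx=(0, 1))
        tiny = DesignSpec(
            design=np.column_stack([np.ones(3), [0.0, 1, 2], [0.0, 1, 4]]),
            contrast=np.array([0, 1.0, 0]),
        )
        with pytest.raises(ValueError, match="N > P"):
            fit_glm_voxelwise(rng.normal(size=(3, 5)), tiny)


class TestTFCE:
    def test_zero_map(self):
        assert np.all(tfce_transform(np.zeros((4, 4, 4))) == 0)

    def test_all_negative_map_is_zero_not_error(self):
        assert np.all(tfce_transform(-np.ones((3, 3, 3))) == 0)

    def test_single_voxel_closed_form(self):
        vol = np.zeros((5, 5, 5))
        vol[2, 2, 2] = 3.0
        out = tfce_transform(vol, TFCEParams(h=2.0, e=2.0, n_steps=100))
        # integral of 1^2 * h^2 from 0 to 3 = 9.0
        assert out[2, 2, 2] == pytest.approx(9.0, rel=0.01)
        assert np.all(out[vol == 0] == 0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(8, 8, 8))
        out = tfce_transform(x, TFCEParams(h=2.0, e=2.0, connectivity=6))
        assert np.allclose(out, brute_force_tfce(x), rtol=1e-10, atol=1e-12)

    def test_monotone_in_voxel_height(self):
        rng = np.random.default_rng(14)
        x = np.abs(rng.normal(size=(6, 6, 6)))
        base = tfce_transform(x, TFCEParams(dh=0.05))
        bumped = x.copy()
        bumped[3, 3, 3] += 0.5
        out = tfce_transform(bumped, TFCEParams(dh=0.05))
        assert np.all(out >= base - 1e-12)

    def test_connectivity_changes_components(self):
        vol = np.zeros((4, 4, 4))
        vol[0, 0, 0] = vol[1, 1, 0] = 2.0  # diagonal pair: joined at C=18+
        c6 = tfce_transform(vol, TFCEParams(connectivity=6, dh=0.5))
        c18 = tfce_transform(vol, TFCEParams(connectivity=18, dh=0.5))
        assert c18[0, 0, 0] > c6[0, 0, 0]


class TestFreedmanLane:
    def test_identity_permutation_reproduces_observed(self, rng):
        N, V = 12, 40
        X = np.column_stack([np.ones(N), rng.normal(size=(N, 2))])
        spec = DesignSpec(
            design=X, contrast=np.array([0, 1.0, 0]), nuisance_idx=(0, 2)
        )
        Y = rng.normal(size=(N, V))
        obs = fit_glm_voxelwise(Y, spec)
        perm = freedman_lane_draw(Y, spec, perm=np.arange(N))
        assert np.allclose(perm, obs, rtol=1e-10)

    def test_no_nuisance_reduces_to_permuting_rows(self, rng):
        N, V = 10, 25
        X = np.arange(N, dtype=float)[:, None]
        spec = DesignSpec(design=X, contrast=np.array([1.0]))
        Y = rng.normal(size=(N, V))
        p = rng.permutation(N)
        a = freedman_lane_draw(Y, spec, perm=p)
        b = fit_glm_voxelwise(Y[p], spec)
        assert np.allclose(a, b, rtol=1e-10)

    def test_exhaustive_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        N = 6
        x = rng.normal(size=N)
        y = 0.8 * x + rng.normal(size=N)
        maps = y[:, None, None, None].reshape(N, 1, 1, 1)
        spec = DesignSpec(
            design=np.column_stack([np.ones(N), x]),
            contrast=np.array([0, 1.0]),
            nuisance_idx=(0,),
        )
        res = permutation_fwe(maps, spec, exhaustive=True)
        # independent oracle: enumerate correlation-based t over all 720 orders
        def tstat(yy):
            r = np.corrcoef(x, yy)[0, 1]
            return r * np.sqrt((N - 2) / (1 - r**2))

        t_obs = tstat(y)
        null = [tstat(np.asarray(p)) for p in itertools.permutations(y)]
        # TFCE of a single positive voxel is monotone in t, so ordering is
        # preserved and p-values coincide
        p_oracle = np.mean([tn >= t_obs - 1e-12 for tn in null])
        assert res.pmap.ravel()[0] == pytest.approx(p_oracle, abs=1e-12)
        assert res.n_permutations == 720


class TestPermutationFWE:
    def test_min_attainable_p(self, rng):
        N, shape = 10, (4, 4, 4)
        x = np.linspace(-1, 1, N)
        maps = (
            5.0 * x[:, None, None, None] * np.ones(shape)[None]
            + 0.01 * rng.normal(size=(N, *shape))
        )
        spec = DesignSpec(
            design=np.column_stack([np.ones(N), x]),
            contrast=np.array([0, 1.0]),
            nuisance_idx=(0,),
        )
        res = permutation_fwe(maps, spec, n_perm=99, seed=1)
        assert res.min_p == pytest.approx(1.0 / 100.0)

    def test_seed_determinism(self, rng):
        N, shape = 8, (5, 5, 5)
        maps = rng.normal(size=(N, *shape))
        x = rng.normal(size=N)
        spec = DesignSpec(
            design=np.column_stack([np.ones(N), x]),
            contrast=np.array([0, 1.0]),
            nuisance_idx=(0,),
        )
        a = permutation_fwe(maps, spec, n_perm=50, seed=42)
        b = permutation_fwe(maps, spec, n_perm=50, seed=42)
        assert np.array_equal(a.pmap, b.pmap)
        assert np.array_equal(a.null_max, b.null_max)

    def test_seed_required(self, rng):
        maps = rng.normal(size=(6, 3, 3, 3))
        spec = DesignSpec(
            design=np.column_stack([np.ones(6), rng.normal(size=6)]),
            contrast=np.array([0, 1.0]),
        )
        with pytest.raises(ValueError, match="seed"):
            permutation_fwe(maps, spec, n_perm=10)

    def test_pvalues_in_unit_interval(self, rng):
        maps = rng.normal(size=(9, 4, 4, 4))
        x = rng.normal(size=9)
        spec = DesignSpec(
            design=np.column_stack([np.ones(9), x]), contrast=np.array([0, 1.0]),
            nuisance_idx=(0,),
        )
        res = permutation_fwe(maps, spec, n_perm=30, seed=3)
        assert np.all(res.pmap > 0) and np.all(res.pmap <= 1)
        assert res.null_max.size == 30


class TestGPDTail:
    def test_fallback_below_refinement_region(self):
        rng = np.random.default_rng(1)
        null = rng.normal(size=200)
        obs = float(np.quantile(null, 0.5))
        emp = (1 + (null >= obs).sum()) / 201
        assert gpd_tail_pvalue(null, obs) == pytest.approx(emp)

    def test_exponential_tail_recovered(self):
        # a zero-shape GPD is an exponential tail; the fitted tail p at the
        # true 99.9th percentile is within a factor 2 of 0.001 for a typical
        # sample (median over seeds to damp tail-sampling noise)
        true_q = -np.log(1e-3)  # 99.9th percentile of Exp(1)
        ps = []
        for seed in range(1, 10):
            null = np.random.default_rng(seed).exponential(size=1000)
            ps.append(gpd_tail_pvalue(null, true_q))
        assert 0.0005 < np.median(ps) < 0.002

    def test_far_beyond_null_is_positive_and_small(self):
        rng = np.random.default_rng(4)
        null = rng.exponential(size=500)
        p = gpd_tail_pvalue(null, null.max() * 3)
        assert 0 < p < 1.0 / 501.0

    def test_small_null_errors(self):
        with pytest.raises(ValueError, match="at least 50"):
            gpd_tail_pvalue(np.arange(10.0), 5.0)

    def test_degenerate_null_warns_and_falls_back(self):
        null = np.ones(100)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            p = gpd_tail_pvalue(null, 2.0)
        assert p == pytest.approx(1.0 / 101.0)


@pytest.fixture(scope="module")
def planted():
    cfg = SyntheticConfig(
        grid_dims=(10, 10, 10), n_systems=3, n_subjects=24, n_timepoints=60,
        noise_sigma=0.4, effect_beta=-0.9, effect_system=1, seed=23,
    )
    cohort = generate_cohort(cfg)
    mask = np.ones(cfg.grid_dims, bool)
    M = cohort.truth_templates.reshape(3, -1).T
    stacks = {
        name: np.stack(
            [
                react(mask_bold(cohort.bold[s], mask), M)[0].volume(k)
                for s in range(cfg.n_subjects)
            ]
        )
        for k, name in enumerate(cohort.system_names)
    }
    return cohort, stacks


class TestRunModels:
    def test_planted_negative_effect_found_only_in_negative_contrast(self, planted):
        cohort, stacks = planted
        models = [ModelSpec("fss~age+gender", "fss", ("age", "gender"))]
        results = run_models(
            {"NET": stacks["NET"]}, cohort.covariates, models, n_perm=200, seed=5
        )
        cell = results["NET"]["fss~age+gender"]
        assert cell["negative"].min_p < 0.05
        assert cell["positive"].min_p > 0.05

    def test_aes_nuisance_leaves_planted_cluster_significant(self, planted):
        cohort, stacks = planted
        models = [ModelSpec("fss+aes", "fss", ("age", "gender", "aes"))]
        results = run_models(
            {"NET": stacks["NET"]}, cohort.covariates, models, n_perm=200, seed=6
        )
        assert results["NET"]["fss+aes"]["negative"].min_p < 0.05

    def test_missing_covariates_error(self, planted):
        cohort, stacks = planted
        cov = cohort.covariates.copy()
        cov.loc[3, "age"] = np.nan
        with pytest.raises(ValueError, match="subjects"):
            run_models(
                {"NET": stacks["NET"]},
                cov,
                [ModelSpec("m", "fss", ("age",))],
                n_perm=10,
                seed=1,
            )


class TestBuildDesign:
    def test_centering_and_contrast(self):
        cov = pd.DataFrame(
            {"fss": [1.0, 2, 3, 4], "age": [52.0, 61, 58, 80], "gender": [0.0, 1, 0, 1]}
        )
        spec = build_design(cov, "fss", ("age", "gender"), sign=-1)
        assert spec.design.shape == (4, 4)
        assert np.allclose(spec.design[:, 1].mean(), 0)  # centered predictor
        assert set(np.unique(spec.design[:, 3])) == {0.0, 1.0}  # binary kept
        assert spec.contrast[1] == -1.0
        assert spec.nuisance_idx == (0, 2, 3)
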