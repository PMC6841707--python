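import numpy as np
import pandas as pd
import pytest

from floodnet.core import EnvTable, SampleHierarchy, ValidationError
from floodnet.scales import (
    build_dbmem,
    forward_select_rda,
    rda_adj_r2,
    varpart,
    vca,
)

MAIN = ["riffle", "run", "pool", "confluence", "shoreline"]


def balanced_hierarchy(n_biome=2, n_fp=4, n_hab=4, n_rep=3):
    """Balanced nested design: biome / floodplain / zone / habitat / replicate."""
    rows = []
    biomes = ["montane", "grassland"][:n_biome]
    offs = ["backwater", "side-channel", "parafluvial-springbrook", "orthofluvial-springbrook", "pond"]
    for b in biomes:
        for f in range(n_fp):
            fp = f"{b[:1]}{f}"
            for zone, habs in (("main-channel", MAIN), ("off-channel", offs)):
                for h in habs[:n_hab]:
                    for r in range(n_rep):
                        rows.append(
                            {
                                "sample_id": f"{fp}-{h}-{r}",
                                "biome": b,
                                "floodplain": fp,
                                "zone": zone,
                                "habitat": h,
                                "x": 0.0,
                                "y": 0.0,
                            }
                        )
    return SampleHierarchy(pd.DataFrame(rows).set_index("sample_id"))


def nested_data(h: SampleHierarchy, variances, seed):
    """Gaussian response with the given (biome, fp, zone, habitat, resid) variances."""
    rng = np.random.default_rng(seed)
    t = h.table
    y = np.zeros(len(t))
    path = None
    for sd2, level in zip(variances[:4], ("biome", "floodplain", "zone", "habitat")):
        labels = t[level].astype(str)
        path = labels if path is None else path + "/" + labels
        codes = pd.factorize(path)[0]
        eff = rng.normal(0, np.sqrt(sd2), codes.max() + 1)
        y = y + eff[codes]
    y = y + rng.normal(0, np.sqrt(variances[4]), len(t))
    return y


def ems_oracle(h: SampleHierarchy, y: np.ndarray) -> np.ndarray:
    """Method-of-moments (expected-mean-squares) estimator for the balanced design."""
    t = h.table.assign(y=y)
    sizes = []
    means = []
    path_cols = []
    path = None
    for level in ("biome", "floodplain", "zone", "habitat"):
        labels = t[level].astype(str)
        path = labels if path is None else path + "/" + labels
        col = f"_p_{level}"
        t[col] = path
        path_cols.append(col)
        sizes.append(t.groupby(col).size().iloc[0])
        means.append(t.groupby(col)["y"].transform("mean"))
    grand = t["y"].mean()
    n = len(t)
    n_units = [t[c].nunique() for c in path_cols]
    ss = []
    prev_mean = pd.Series(grand, index=t.index)
    for m in means:
        ss.append(((m - prev_mean) ** 2).sum())
        prev_mean = m
    ss_resid = ((t["y"] - means[-1]) ** 2).sum()
    df = [n_units[0] - 1]
    for i in range(1, 4):
        df.append(n_units[i] - n_units[i - 1])
    df_resid = n - n_units[3]
    ms = [s / d for s, d in zip(ss, df)] + [ss_resid / df_resid]
    k = sizes + [1]  # observations per unit at each level
    est = [ms[4]]
    for lvl in (3, 2, 1, 0):
        est.insert(0, (ms[lvl] - ms[lvl + 1]) / k[lvl])
    return np.array(est)


class TestVCA:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_reml_matches_ems_on_balanced_design(self, seed):
        """REML equals the EMS/ANOVA estimator on balanced data (interior optimum)."""
        h = balanced_hierarchy(n_fp=5, n_hab=4, n_rep=3)
        truth = (4.0, 1.0, 0.4, 0.6, 0.8)  # large biome variance keeps df=1 level interior
        y = nested_data(h, truth, seed=seed)
        env = EnvTable(pd.DataFrame({"v": np.exp(y)}, index=h.sample_ids))
        res = vca(env, h, "v")
        oracle = ems_oracle(h, y)
        assert (oracle > 0).all(), "oracle estimates must be interior for equivalence"
        np.testing.assert_allclose(res.variances.to_numpy(), oracle, atol=1e-6)

    def test_percentages_sum_to_100(self):
        h = balanced_hierarchy(n_fp=3, n_hab=3, n_rep=2)
        y = nested_data(h, (0.1, 0.5, 0.2, 0.3, 0.5), seed=1)
        env = EnvTable(pd.DataFrame({"v": np.exp(y)}, index=h.sample_ids))
        res = vca(env, h, "v")
        assert res.percents.sum() == pytest.approx(100.0, abs=1e-6)
        assert (res.variances >= 0).all()

    def test_null_data_small_structural_components(self):
        """Residual-only data: structural variance shares stay small.

        Levels with many units (biome, floodplain, zone) stay under 5%; the
        habitat level, estimated from 3 replicates per unit, has wider
        truncation noise and is held under 10%.
        """
        h = balanced_hierarchy(n_fp=4, n_hab=4, n_rep=3)
        good_upper, good_hab = 0, 0
        for s in range(10):
            y = nested_data(h, (0, 0, 0, 0, 1.0), seed=100 + s)
            env = EnvTable(pd.DataFrame({"v": np.exp(y)}, index=h.sample_ids))
            res = vca(env, h, "v")
            good_upper += bool((res.percents[["biome", "floodplain", "zone"]] < 5.0).all())
            good_hab += bool(res.percents["habitat"] < 10.0)
        assert good_upper >= 8 and good_hab >= 8

    def test_low_replication_flag(self):
        h = balanced_hierarchy(n_fp=3, n_hab=3, n_rep=2)
        y = nested_data(h, (0.1, 0.5, 0.2, 0.3, 0.5), seed=2)
        env = EnvTable(pd.DataFrame({"v": np.exp(y)}, index=h.sample_ids))
        assert "biome" in vca(env, h, "v").low_replication


class TestDbMEM:
    def test_orthonormal_and_centered(self, rng):
        coords = rng.random((25, 2)) * 1000
        mem = build_dbmem(coords)
        v = mem.vectors.to_numpy()
        assert np.allclose(v.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-10)
        assert (mem.eigenvalues > 0).all()

    def test_collinear_points_match_pcoa_oracle(self):
        """3 equidistant collinear points: truncation keeps all, plain PCoA applies."""
        coords = np.array([[0.0, 0], [1, 0], [2, 0]])
        mem = build_dbmem(coords)
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        t = 1.0  # MST longest edge
        dt = np.where(d > t, 4 * t, d)
        J = np.eye(3) - np.ones((3, 3)) / 3
        B = -0.5 * J @ dt**2 @ J
        vals, vecs = np.linalg.eigh(B)
        keep = vals > 1e-9 * abs(vals).max()
        assert mem.vectors.shape[1] == keep.sum()
        assert mem.truncation == pytest.approx(1.0)
        # subspace agreement
        v_o = vecs[:, keep]
        v_m = mem.vectors.to_numpy()
        proj = v_o @ np.linalg.lstsq(v_o, v_m, rcond=None)[0]
        assert np.allclose(proj, v_m, atol=1e-8)

    def test_transect_wavelength_ordering(self):
        """On a regular transect the leading MEM has the fewest sign changes."""
        coords = np.column_stack([np.arange(20.0), np.zeros(20)])
        mem = build_dbmem(coords)
        signs = np.sign(mem.vectors.to_numpy())
        changes = [(np.diff(signs[:, a]) != 0).sum() for a in range(min(4, signs.shape[1]))]
        assert changes == sorted(changes)

    def test_identical_sites_error(self):
        with pytest.raises(ValidationError):
            build_dbmem(np.zeros((4, 2)))


class TestForwardSelection:
    def test_signal_predictor_selected_first(self, rng):
        n = 40
        X = pd.DataFrame(rng.standard_normal((n, 4)), columns=list("wxyz"))
        Y = np.outer(X["x"], rng.random(5)) + 0.1 * rng.standard_normal((n, 5))
        sel = forward_select_rda(Y, X, n_perm=99, seed=0)
        assert sel and sel[0] == "x"

    def test_pure_noise_mostly_empty(self, rng):
        import warnings

        empty = 0
        for s in range(20):
            X = pd.DataFrame(rng.standard_normal((25, 3)), columns=list("abc"))
            Y = rng.standard_normal((25, 4))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if not forward_select_rda(Y, X, n_perm=99, seed=s):
                    empty += 1
        assert empty >= 16  # ~95% nominal; generous floor for 20 draws

    def test_adjusted_r2_matches_closed_form(self, rng):
        """Simple RDA with one predictor: adjusted R2 from the regression identity."""
        n = 30
        x = rng.standard_normal(n)
        Y = np.outer(x, [1.0, -0.5]) + 0.3 * rng.standard_normal((n, 2))
        r2_cols = []
        xc = x - x.mean()
        Yc = Y - Y.mean(axis=0)
        fit = np.outer(xc, (xc @ Yc) / (xc @ xc))
        r2 = (fit**2).sum() / (Yc**2).sum()
        expected = 1 - (1 - r2) * (n - 1) / (n - 2)
        assert rda_adj_r2(Y, x.reshape(-1, 1)) == pytest.approx(expected, abs=1e-12)
        del r2_cols


class TestVarpart:
    def test_identities(self, rng):
        Y = rng.standard_normal((30, 4))
        E = rng.standard_normal((30, 2))
        S = rng.standard_normal((30, 2))
        p = varpart(Y, E, S)
        assert p.env_unique + p.shared == pytest.approx(p.adj_r2_env, abs=1e-9)
        assert p.shared + p.space_unique == pytest.approx(p.adj_r2_space, abs=1e-9)
        assert p.env_unique + p.shared + p.space_unique + p.residual == pytest.approx(1.0, abs=1e-9)
        assert p.residual == pytest.approx(1 - p.adj_r2_full, abs=1e-12)

    def test_env_only_signal_orthogonal_predictors(self, rng):
        n = 60
        E = rng.standard_normal((n, 2))
        S = rng.standard_normal((n, 2))
        Y = E @ rng.random((2, 5)) + 0.2 * rng.standard_normal((n, 5))
        p = varpart(Y, E, S)
        assert abs(p.space_unique) < 0.02
        assert abs(p.shared) < 0.05
        assert p.env_unique > 0.5

    def test_duplicated_predictors_all_shared(self, rng):
        n = 40
        X = rng.standard_normal((n, 2))
        Y = X @ rng.random((2, 3)) + 0.3 * rng.standard_normal((n, 3))
        p = varpart(Y, X, X.copy())
        assert abs(p.env_unique) < 1e-9 and abs(p.space_unique) < 1e-9
        assert p.shared == pytest.approx(p.adj_r2_env, abs=1e-9)

    def test_rank_deficient_errors(self, rng):
        Y = rng.standard_normal((6, 2))
        E = rng.standard_normal((6, 3))
        S = rng.standard_normal((6, 3))
        with pytest.raises(ValidationError, match="rank"):
            varpart(Y, E, S)
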