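"""V test, rm-ANOVA (GG), permutation ANOVA, mixed model, planned contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tempopred import stats as tps


def long_table(y, factors_levels, subject_prefix="s"):
    """Build a long-format table from a (subjects x cells) matrix."""
    import itertools

    cells = list(itertools.product(*factors_levels.values()))
    rows = []
    for i, row in enumerate(y):
        for cell, val in zip(cells, row):
            d = {f: lv for f, lv in zip(factors_levels, cell)}
            d.update(subject=f"{subject_prefix}{i}", dv=val)
            rows.append(d)
    return pd.DataFrame(rows)


class TestVTest:
    def test_all_angles_at_theta0(self):
        res = tps.v_test(np.full(12, 0.5), 0.5)
        assert res.v == pytest.approx(12.0)

    def test_equally_spaced_angles(self):
        res = tps.v_test(np.linspace(0, 2 * np.pi, 10, endpoint=False), 0.0)
        assert res.v == pytest.approx(0.0, abs=1e-10)

    def test_against_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        a = rng.vonmises(0.3, 1.0, size=19)
        res = tps.v_test(a, 0.3)
        v_ref, p_ref = pingouin.circ_vtest(a, dir=0.3)
        assert res.v == pytest.approx(v_ref, abs=1e-9)
        assert res.p == pytest.approx(p_ref, abs=1e-6)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(7)
        angles = rng.uniform(-np.pi, np.pi, size=(2000, 20))
        v = np.cos(angles).sum(axis=1)
        p = sps.norm.sf(v * np.sqrt(2 / 20))
        assert sps.kstest(p, "uniform").pvalue > 0.01

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tps.v_test(np.array([]))


class TestRmAnova:
    def test_two_level_factor_equals_paired_t(self, rng):
        y = rng.normal(0, 1, size=(14, 2))
        y[:, 1] += 0.7
        tab = long_table(y, {"cond": ["a", "b"]})
        res = tps.rm_anova(tab, "dv", "subject", ["cond"])
        d = y[:, 1] - y[:, 0]
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert res.F[0] == pytest.approx(t**2, rel=1e-9)
        assert res.eps_gg[0] == 1.0

    def test_against_pingouin_two_way(self, rng):
        pingouin = pytest.importorskip("pingouin")
        y = rng.normal(0, 1, size=(16, 6))
        y[:, :3] += np.array([0.2, 0.5, 0.9])
        tab = long_table(y, {"A": ["a1", "a2"], "B": ["b1", "b2", "b3"]})
        ours = tps.rm_anova(tab, "dv", "subject", ["A", "B"]).set_index("effect")
        ref = pingouin.rm_anova(
            data=tab, dv="dv", within=["A", "B"], subject="subject", detailed=True
        ).set_index("Source")
        for eff, key in [("A", "A"), ("B", "B"), ("A x B", "A * B")]:
            assert ours.loc[eff, "F"] == pytest.approx(ref.loc[key, "F"], rel=1e-8)
            if ref.loc[key, "eps"] is not None and not np.isnan(ref.loc[key, "eps"]):
                assert ours.loc[eff, "eps_gg"] == pytest.approx(ref.loc[key, "eps"], rel=1e-6)

    def test_sphericity_violation_shrinks_epsilon(self, rng):
        # heterogeneous difference variances violate sphericity -> eps < 1
        n = 40
        base = rng.normal(0, 1.0, size=(n, 1))
        y = np.hstack([
            base + rng.normal(0, 0.05, (n, 1)),
            base + rng.normal(0, 0.05, (n, 1)),
            base + rng.normal(0, 3.0, (n, 1)),
        ])
        tab = long_table(y, {"cond": ["a", "b", "c"]})
        res = tps.rm_anova(tab, "dv", "subject", ["cond"])
        assert res.eps_gg[0] < 0.75

    def test_missing_cells_rejected(self, rng):
        tab = long_table(rng.normal(size=(6, 2)), {"cond": ["a", "b"]})
        with pytest.raises(ValueError, match="incomplete"):
            tps.rm_anova(tab.iloc[:-1], "dv", "subject", ["cond"])


class TestPermAnova:
    def test_type_one_error_near_nominal(self):
        """Exchangeable null data: rejection rate compatible with alpha=0.05."""
        rng = np.random.default_rng(3)
        rejections = 0
        n_sim = 300
        for _ in range(n_sim):
            y = rng.normal(size=(10, 3))
            tab = long_table(y, {"cond": ["a", "b", "c"]})
            res = tps.perm_anova(tab, "dv", "subject", ["cond"], n_perm=101, rng=rng)
            rejections += res.effects.p_perm[0] <= 0.05
        rate = rejections / n_sim
        lo, hi = sps.binom.ppf([0.005, 0.995], n_sim, 0.05) / n_sim
        assert lo <= rate <= hi

    def test_large_effect_hits_p_floor(self, rng):
        y = rng.normal(size=(12, 2))
        y[:, 1] += 50.0
        tab = long_table(y, {"cond": ["a", "b"]})
        res = tps.perm_anova(tab, "dv", "subject", ["cond"], n_perm=199, rng=rng)
        assert res.effects.p_perm[0] == pytest.approx(1 / 200)

    def test_invariant_to_level_relabeling(self, rng):
        y = rng.normal(size=(9, 2))
        y[:, 0] += 0.8
        t1 = long_table(y, {"cond": ["a", "b"]})
        t2 = t1.replace({"cond": {"a": "z", "b": "y"}})
        r1 = tps.perm_anova(t1, "dv", "subject", ["cond"], 200, np.random.default_rng(5))
        r2 = tps.perm_anova(t2, "dv", "subject", ["cond"], 200, np.random.default_rng(5))
        assert r1.effects.F[0] == pytest.approx(r2.effects.F[0])
        assert r1.effects.p_perm[0] == r2.effects.p_perm[0]


def simulate_phase_rt(n_subjects, n_trials, coupling, rng, angle_spread=0.0,
                      soa_angle_shift=0.0):
    rows = []
    for s in range(n_subjects):
        theta = angle_spread * rng.standard_normal()
        for _ in range(n_trials):
            ph = rng.uniform(-np.pi, np.pi)
            soa = rng.integers(0, 2)
            t = theta + soa_angle_shift * (soa - 0.5)
            rt = 400 - coupling * np.cos(ph - t) + 10 * soa + rng.normal(0, 50)
            rows.append(dict(subject=f"s{s}", rt_ms=rt, phase=ph, soa=soa))
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_common_angle_recovered(self):
        rng = np.random.default_rng(11)
        df = simulate_phase_rt(12, 120, coupling=40.0, rng=rng)
        # all subjects share optimal angle 0
        res = tps.phase_rt_mixed_model(df)
        assert abs(res.optimal_angle - 0.0) < 0.25
        assert res.lrt_fixed_phase[2] < 0.01

    def test_fixed_phase_type_one_near_nominal(self):
        """Uncoupled generator: the 2-df phase LRT rejects at ~alpha."""
        rng = np.random.default_rng(21)
        n_sim, rej = 120, 0
        for _ in range(n_sim):
            df = simulate_phase_rt(8, 40, coupling=0.0, rng=rng)
            res = tps.phase_rt_mixed_model(df)
            rej += res.lrt_fixed_phase[2] <= 0.05
        rate = rej / n_sim
        lo, hi = sps.binom.ppf([0.005, 0.995], n_sim, 0.05) / n_sim
        assert lo <= rate <= hi + 0.01

    def test_dispersed_angles_detected_by_random_slope_lrt(self):
        rng = np.random.default_rng(31)
        df = simulate_phase_rt(19, 150, coupling=45.0, rng=rng, angle_spread=1.2)
        res = tps.phase_rt_mixed_model(df)
        assert res.lrt_random_slopes[2] < 0.05
        assert res.lrt_random_slopes[1] == 5 or res.fallback is not None

    def test_soa_angle_shift_has_one_df(self):
        rng = np.random.default_rng(41)
        df = simulate_phase_rt(10, 80, coupling=40.0, rng=rng)
        res = tps.phase_rt_mixed_model(df)
        assert res.lrt_soa_by_phase[1] == 1
        assert res.lrt_soa_by_phase[2] > 0.001  # no shift planted


class TestValidityContrasts:
    def _rt_table(self, rng, rhythmic_penalty=0.0, n=19):
        rows = []
        for s in range(n):
            subj_off = rng.normal(0, 15)
            for cond, base in [("Rhythmic", 330), ("RepeatedInterval", 330), ("Random", 360)]:
                for val in ("valid", "invalid"):
                    extra = rhythmic_penalty if (cond == "Rhythmic" and val == "invalid") else 0.0
                    for _ in range(20):
                        rows.append(dict(
                            subject=s, condition=cond, validity=val,
                            rt_ms=base + extra + subj_off + rng.normal(0, 40),
                        ))
        return pd.DataFrame(rows)

    def test_identical_conditions_give_zero(self, rng):
        df = self._rt_table(rng)
        df["rt_ms"] = 400.0
        out = tps.validity_contrasts(df)
        assert np.allclose(out.t, 0.0) and np.allclose(out.cohens_d, 0.0)

    def test_equal_benefit_ci_covers_zero(self):
        rng = np.random.default_rng(8)
        covered = 0
        for _ in range(20):
            out = tps.validity_contrasts(self._rt_table(rng))
            row = out[(out.contrast == "Rhythmic - RepeatedInterval") & (out.validity == "valid")]
            lo, hi = row.ci95.iloc[0]
            covered += lo <= 0 <= hi
        assert covered >= 18

    def test_rhythmic_only_penalty_detected(self):
        rng = np.random.default_rng(9)
        out = tps.validity_contrasts(self._rt_table(rng, rhythmic_penalty=30.0))
        row = out[(out.contrast == "Rhythmic - RepeatedInterval") & (out.validity == "invalid")]
        assert row.p.iloc[0] < 0.05
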