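import itertools
import math
import subprocess
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rbcdeform as r
from rbcdeform.stats import groupwise_mann_whitney


class TestShapiroWilk:
    def test_constant_input_error(self):
        with pytest.raises(ValueError):
            r.shapiro_wilk(np.full(20, 3.0))

    def test_uniform_sample_decisively_non_normal(self):
        rng = np.random.default_rng(0)
        _, p = r.shapiro_wilk(rng.uniform(0, 1, 500))
        assert p < 0.01

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(1)
        rejections = sum(
            r.shapiro_wilk(rng.standard_normal(50))[1] < 0.05 for _ in range(1000)
        )
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_size_limits(self):
        with pytest.raises(ValueError):
            r.shapiro_wilk([1.0, 2.0])


def mann_whitney_enumeration(a, b):
    """Full enumeration of the exact two-sided Mann-Whitney p (oracle)."""
    a, b = list(a), list(b)
    pool = a + b
    na = len(a)

    def u_stat(idx_a):
        xs = [pool[i] for i in idx_a]
        ys = [pool[i] for i in range(len(pool)) if i not in idx_a]
        return sum(x > y for x in xs for y in ys)

    u_obs = sum(x > y for x in a for y in b)
    dist = Counter(
        u_stat(set(idx)) for idx in itertools.combinations(range(len(pool)), na)
    )
    total = sum(dist.values())
    cdf = sum(c for u, c in dist.items() if u <= u_obs) / total
    sf = sum(c for u, c in dist.items() if u >= u_obs) / total
    return u_obs, min(1.0, 2.0 * min(cdf, sf))


class TestMannWhitney:
    def test_separated_groups_exact(self):
        u, p = r.mann_whitney([1, 2, 3], [4, 5, 6])
        u_o, p_o = mann_whitney_enumeration([1, 2, 3], [4, 5, 6])
        assert (u, p) == (u_o, p_o) == (0.0, 0.1)

    def test_identical_groups_p_one(self):
        _, p = r.mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_swap_symmetry(self):
        a, b = [0.3, 1.7, 2.2, 5.0], [0.9, 1.1, 4.2]
        u1, p1 = r.mann_whitney(a, b)
        u2, p2 = r.mann_whitney(b, a)
        assert p1 == pytest.approx(p2)
        assert u2 == pytest.approx(len(a) * len(b) - u1)

    def test_exact_path_matches_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            na, nb = rng.integers(2, 7), rng.integers(2, 7)
            a = rng.uniform(0, 1, na).tolist()
            b = rng.uniform(0, 1, nb).tolist()
            u, p = r.mann_whitney(a, b)
            u_o, p_o = mann_whitney_enumeration(a, b)
            assert u == pytest.approx(u_o)
            assert p == pytest.approx(p_o, abs=1e-12)

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            r.mann_whitney([], [1.0])

    def test_groupwise_with_holm(self):
        model = r.CohortModel(n_donors={"healthy": 6, "cll": 6})
        cohort = r.generate_cohort(model, seed=2)
        out = groupwise_mann_whitney(cohort, holm=True)
        assert len(out) == 7
        assert (out["p_holm"] >= out["p"] - 1e-15).all()


class TestPartialEtaSquared:
    @pytest.mark.parametrize(
        "F,df1,df2,expected",
        [
            (93.56, 1, 20, 0.82),     # group effect, ellipse-fit pipeline
            (35.22, 6, 120, 0.64),    # shear effect
            (8.488, 6, 120, 0.30),    # interaction
            (49.38, 6, 119.2, 0.71),  # shear effect, farthest-point pipeline
            (2.86, 6, 119.2, 0.13),   # interaction
        ],
    )
    def test_reported_effect_sizes(self, F, df1, df2, expected):
        assert round(r.partial_eta_squared(F, df1, df2), 2) == expected

    def test_zero_effect(self):
        assert r.partial_eta_squared(0.0, 3, 50) == 0.0

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            r.partial_eta_squared(1.0, 0, 10)


class TestPearson:
    def test_exact_linearity(self):
        x = np.array([0.1, 0.5, 2.0, 3.3])
        assert r.pearson(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert r.pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # r = 3 / sqrt(2 * 14/3)
        rho, _ = r.pearson([1, 2, 3], [1, 2, 4])
        assert rho == pytest.approx(3 / math.sqrt(2 * 14 / 3), abs=1e-10)

    @given(
        st.floats(0.1, 10), st.floats(-5, 5), st.floats(0.1, 10), st.floats(-5, 5)
    )
    def test_invariance_to_positive_affine_maps(self, a1, b1, a2, b2):
        x = np.array([0.0, 1.0, 3.0, 4.5, 7.0])
        y = np.array([2.0, 1.0, 4.0, 3.5, 6.0])
        base, _ = r.pearson(x, y)
        mapped, _ = r.pearson(a1 * x + b1, a2 * y + b2)
        assert mapped == pytest.approx(base, abs=1e-9)

    def test_constant_input_error(self):
        with pytest.raises(ValueError):
            r.pearson([1, 1, 1], [1, 2, 3])


class TestBlandAltman:
    def test_identical_series(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        ba = r.bland_altman(x, x)
        assert ba.bias == 0.0
        assert ba.loa_low == ba.loa_high == 0.0
        assert ba.prop_bias_slope == 0.0
        assert ba.pct_within == 1.0

    def test_constant_shift(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        ba = r.bland_altman(x + 0.1, x)
        assert ba.bias == pytest.approx(0.1)
        assert ba.loa_low == pytest.approx(0.1)
        assert ba.loa_high == pytest.approx(0.1)

    def test_hand_computed_example(self):
        ba = r.bland_altman([0.20, 0.25, 0.31, 0.40], [0.15, 0.18, 0.25, 0.30])
        d = np.array([0.05, 0.07, 0.06, 0.10])
        assert ba.bias == pytest.approx(0.07)
        assert ba.loa_low == pytest.approx(0.07 - 1.96 * d.std(ddof=1))
        assert ba.loa_high == pytest.approx(0.07 + 1.96 * d.std(ddof=1))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            r.bland_altman([1, 2, 3], [1, 2])


class TestMixedModel:
    def test_large_group_effect_detected(self):
        model = r.CohortModel(
            di_max={"healthy": 0.41, "cll": 0.30},
            tau_half={"healthy": 0.4, "cll": 0.4},
            donor_sd=0.01, residual_sd=0.01,
            n_donors={"healthy": 10, "cll": 10},
        )
        res = r.fit_mixed_model(r.generate_cohort(model, seed=7))
        eff = res.effects["group"]
        assert eff.p < 0.001
        assert eff.eta2p > 0.5
        # eta2p invariant
        for e in res.effects.values():
            assert e.eta2p == pytest.approx(
                e.F * e.df1 / (e.F * e.df1 + e.df2), abs=1e-9
            )

    def test_balanced_design_satterthwaite_matches_split_plot_df(self):
        # balanced two-group repeated-measures design: Satterthwaite df
        # reduce to the classical values N-2 and (N-2)(s-1)
        model = r.CohortModel(n_donors={"healthy": 8, "cll": 8})
        res = r.fit_mixed_model(r.generate_cohort(model, seed=4))
        assert res.effects["group"].df2 == pytest.approx(14.0, abs=0.1)
        assert res.effects["shear"].df2 == pytest.approx(84.0, abs=0.1)
        assert res.effects["group:shear"].df2 == pytest.approx(84.0, abs=0.1)
        assert res.effects["shear"].df1 == 6

    def test_single_donor_group_rejected(self):
        model = r.CohortModel(n_donors={"healthy": 5, "cll": 1})
        with pytest.raises(ValueError):
            r.fit_mixed_model(r.generate_cohort(model, seed=0))

    def test_matches_lmerTest_reference(self, tmp_path):
        # independent oracle: lmerTest's Satterthwaite Type III table
        model = r.CohortModel(
            di_max={"healthy": 0.41, "cll": 0.30},
            tau_half={"healthy": 0.4, "cll": 0.4},
            donor_sd=0.01, residual_sd=0.012,
            n_donors={"healthy": 7, "cll": 5},  # unbalanced on purpose
        )
        cohort = r.generate_cohort(model, seed=21)
        csv = tmp_path / "cohort.csv"
        cohort.to_csv(csv, index=False)
        script = tmp_path / "lmm.R"
        script.write_text(
            'suppressMessages(library(lmerTest))\n'
            f'd <- read.csv("{csv}")\n'
            "d$group <- factor(d$group); d$shear <- factor(d$stress_dyn_cm2)\n"
            "contrasts(d$group) <- contr.sum(2); contrasts(d$shear) <- contr.sum(7)\n"
            "fit <- lmer(di_mean ~ group*shear + (1|donor_id), data=d, REML=TRUE)\n"
            'a <- anova(fit, type=3, ddf="Satterthwaite")\n'
            'cat(sprintf("%s %.6f %.6f\\n", rownames(a), a$DenDF, a$"F value"))\n'
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        ).stdout
        reference = {}
        for line in out.strip().splitlines():
            name, dendf, fval = line.split()
            reference[name] = (float(dendf), float(fval))
        res = r.fit_mixed_model(cohort)
        mapping = {"group": "group", "shear": "shear", "group:shear": "group:shear"}
        for ours, theirs in mapping.items():
            df2_ref, f_ref = reference[theirs]
            assert res.effects[ours].F == pytest.approx(f_ref, rel=1e-3)
            assert res.effects[ours].df2 == pytest.approx(df2_ref, abs=0.1)

    def test_recovers_group_offset_within_two_se(self):
        # parameter recovery: the fitted group coefficient is within 2 SE
        # of the generating offset in >= 90% of simulated cohorts
        model = r.CohortModel(
            di_max={"healthy": 0.41, "cll": 0.36},
            tau_half={"healthy": 0.4, "cll": 0.4},
            donor_sd=0.01, residual_sd=0.01,
            n_donors={"healthy": 10, "cll": 10},
        )
        stresses = np.array(model.stresses_dyn_cm2)
        mu = {
            g: np.mean([r.expected_di(t, model, g) for t in stresses])
            for g in ("healthy", "cll")
        }
        true_coef = (mu["cll"] - mu["healthy"]) / 2  # sum coding, cll = +1
        hits = 0
        for i in range(100):
            res = r.fit_mixed_model(r.generate_cohort(model, seed=3000 + i))
            est = res.fixed_effects["group"]
            se = res.fixed_effects_se["group"]
            hits += abs(est - true_coef) <= 2 * se
        assert hits >= 90
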