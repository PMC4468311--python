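import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methylaging import (
    compute_acceleration,
    fit_reference_model,
    group_compare_kruskal,
    pearson_cor,
    replicate_concordance,
    tissue_summary,
)
from methylaging.acceleration import AgeModelFit


def _table(ages, dnam, tissue="cortex", subject_prefix="s"):
    n = len(ages)
    return pd.DataFrame(
        {
            "sample_id": [f"{subject_prefix}{i}" for i in range(n)],
            "subject_id": [f"{subject_prefix}{i}" for i in range(n)],
            "tissue": tissue,
            "age": ages,
            "dnam_age": dnam,
            "replicate": 1,
        }
    )


class TestReferenceFit:
    def test_identity_line(self):
        t = _table([10.0, 20.0, 30.0], [10.0, 20.0, 30.0])
        fit = fit_reference_model(t)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)
        assert fit.slope == pytest.approx(1.0)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-10)

    def test_duplicated_point(self):
        t = _table([10.0, 30.0, 30.0], [15.0, 45.0, 45.0])
        fit = fit_reference_model(t)
        assert fit.slope == pytest.approx(1.5)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(10, 90, 20)
        y = 0.8 * x + 4 + rng.normal(0, 3, 20)
        fit = fit_reference_model(_table(x, y))
        X = np.column_stack([np.ones(20), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)  # closed-form oracle
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)

    def test_reference_filter_excludes_tissue(self):
        t = pd.concat(
            [
                _table([10.0, 50.0, 90.0], [10.0, 50.0, 90.0]),
                _table([10.0, 50.0, 90.0], [5.0, 25.0, 45.0], tissue="cerebellum",
                       subject_prefix="c"),
            ],
            ignore_index=True,
        )
        fit = fit_reference_model(t, exclude_tissues=["cerebellum"])
        assert fit.slope == pytest.approx(1.0)
        assert len(fit.reference_sample_ids) == 3

    def test_degenerate_designs(self):
        with pytest.raises(ValueError, match="3 reference"):
            fit_reference_model(_table([10.0, 20.0], [10.0, 20.0]))
        with pytest.raises(ValueError, match="degenerate"):
            fit_reference_model(_table([10.0, 10.0, 10.0], [1.0, 2.0, 3.0]))


class TestAcceleration:
    def test_residual_examples(self):
        fit = AgeModelFit(0.0, 1.0, [], 0.0)
        t = _table([40.0, 40.0], [40.0, 45.0])
        acc = compute_acceleration(fit, t)
        np.testing.assert_allclose(acc.acceleration, [0.0, 5.0])

    def test_reference_residuals_sum_to_zero(self):
        rng = np.random.default_rng(1)
        t = _table(rng.uniform(20, 100, 30), rng.uniform(20, 100, 30))
        fit = fit_reference_model(t)
        acc = compute_acceleration(fit, t)
        assert acc.acceleration.sum() == pytest.approx(0.0, abs=1e-8)

    @given(c=st.floats(-30, 30))
    @settings(max_examples=25, derandomize=True)
    def test_constant_shift_absorbed_by_fit(self, c):
        """Adding c years to every DNAm age leaves all residuals unchanged."""
        rng = np.random.default_rng(2)
        t = _table(rng.uniform(20, 100, 15), rng.uniform(20, 100, 15))
        acc0 = compute_acceleration(fit_reference_model(t), t)
        t2 = t.assign(dnam_age=t.dnam_age + c)
        acc1 = compute_acceleration(fit_reference_model(t2), t2)
        np.testing.assert_allclose(
            acc0.acceleration, acc1.acceleration, atol=1e-8
        )

    def test_synth_cerebellum_negative(self, noiseless_cohort):
        from methylaging import predict_dnam_age

        truth, beta, sheet = noiseless_cohort
        pred = predict_dnam_age(beta, truth.clock)
        t = sheet.merge(pred.reset_index(), on="sample_id")
        fit = fit_reference_model(t, exclude_tissues=["cerebellum"])
        acc = compute_acceleration(fit, t)
        cb = acc[(acc.tissue == "cerebellum") & (acc.age > 40)]
        expected = 0.6 * cb.age - fit.predict(cb.age)
        np.testing.assert_allclose(cb.acceleration, expected, atol=1e-8)
        assert (cb.acceleration < 0).all()


class TestKruskal:
    def test_hand_computed_h(self):
        t = pd.concat(
            [
                _table([50] * 3, [0.0, 0.0, 0.0]).assign(
                    acceleration=[1.0, 2.0, 3.0], tissue="a"
                ),
                _table([50] * 3, [0.0, 0.0, 0.0], subject_prefix="t").assign(
                    acceleration=[4.0, 5.0, 6.0], tissue="b"
                ),
            ],
            ignore_index=True,
        )
        h, p, degen = group_compare_kruskal(t)
        assert h == pytest.approx(27.0 / 7.0)  # tie-free closed form 3.857...
        assert not degen
        assert p == pytest.approx(stats.chi2.sf(27.0 / 7.0, 1))

    def test_identical_groups_h_zero(self):
        t = pd.concat(
            [
                _table([50] * 3, [0.0] * 3).assign(acceleration=[1.0, 2.0, 3.0],
                                                   tissue="a"),
                _table([50] * 3, [0.0] * 3, subject_prefix="t").assign(
                    acceleration=[1.0, 2.0, 3.0], tissue="b"
                ),
            ],
            ignore_index=True,
        )
        h, _, degen = group_compare_kruskal(t)
        assert h == pytest.approx(0.0)
        assert not degen

    def test_all_equal_flagged(self):
        t = pd.concat(
            [
                _table([50] * 2, [0.0] * 2).assign(acceleration=1.0, tissue="a"),
                _table([50] * 2, [0.0] * 2, subject_prefix="t").assign(
                    acceleration=1.0, tissue="b"
                ),
            ],
            ignore_index=True,
        )
        h, p, degen = group_compare_kruskal(t)
        assert (h, p, degen) == (0.0, 1.0, True)

    def test_single_group_rejected(self):
        t = _table([50] * 3, [0.0] * 3).assign(acceleration=[1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="2 non-empty groups"):
            group_compare_kruskal(t)

    def test_exact_permutation_oracle_small_n(self):
        """Chi-square p within 0.1 of the exhaustive permutation p at n=8."""
        a = np.array([1.0, 3.0, 5.0, 6.0])
        b = np.array([2.0, 7.0, 8.0, 9.0])
        h_obs, p_asym = stats.kruskal(a, b)
        pooled = np.concatenate([a, b])
        count = total = 0
        for idx in itertools.combinations(range(8), 4):
            mask = np.zeros(8, bool)
            mask[list(idx)] = True
            h, _ = stats.kruskal(pooled[mask], pooled[~mask])
            count += h >= h_obs - 1e-12
            total += 1
        p_exact = count / total
        assert abs(p_exact - p_asym) < 0.1

    @pytest.mark.parametrize("f", [np.exp, lambda v: v**3, lambda v: 5 * v - 2])
    def test_invariant_under_monotone_transform(self, f):
        rng = np.random.default_rng(3)
        t = _table(rng.uniform(20, 90, 12), np.zeros(12)).assign(
            acceleration=rng.normal(0, 2, 12),
            tissue=np.repeat(["a", "b", "c"], 4),
        )
        h0, _, _ = group_compare_kruskal(t)
        t2 = t.assign(acceleration=f(t.acceleration.to_numpy()))
        h1, _, _ = group_compare_kruskal(t2)
        assert h1 == pytest.approx(h0, rel=1e-12)


class TestPearson:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, _ = pearson_cor(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = pearson_cor(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r, _ = pearson_cor(x, y)
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert r == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_cor([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestTissueSummary:
    def test_single_sample_flagged(self):
        t = _table([85.0], [90.0]).assign(acceleration=2.0)
        out = tissue_summary(t)
        assert out.loc[0, "se_undefined"] and out.loc[0, "se"] == 0.0

    def test_replicates_averaged_first(self):
        t = pd.DataFrame(
            {
                "sample_id": ["a1", "a2"],
                "subject_id": ["s1", "s1"],
                "tissue": "cortex",
                "age": [85.0, 85.0],
                "dnam_age": [82.0, 84.0],
                "replicate": [1, 2],
                "acceleration": [-3.0, -1.0],
            }
        )
        out = tissue_summary(t)
        assert out.loc[0, "mean"] == pytest.approx(-2.0)
        assert out.loc[0, "n"] == 1


class TestReplicateConcordance:
    def _acc(self, reps):
        rows = []
        for i, (a, b) in enumerate(reps):
            rows.append((f"s{i}_r1", f"s{i}", "cortex", 80.0, a, 1, 0.0))
            rows.append((f"s{i}_r2", f"s{i}", "cortex", 80.0, b, 2, 0.0))
        return pd.DataFrame(
            rows,
            columns=["sample_id", "subject_id", "tissue", "age", "dnam_age",
                     "replicate", "acceleration"],
        )

    def test_identical_replicates(self):
        acc = self._acc([(70.0, 70.0), (80.0, 80.0), (90.0, 90.0)])
        r, n = replicate_concordance(acc)
        assert r == pytest.approx(1.0)
        assert n == 3

    def test_no_pairs_rejected(self):
        acc = self._acc([(70.0, 70.0)])
        with pytest.raises(ValueError, match="replicate pairs"):
            replicate_concordance(acc)

    def test_calibrated_noise_concordance_window(self):
        """Fig-4-style design: one very old subject, 30 tissues, 2 replicates.

        With the default beta-scale noise the replicate DNAm-age correlation
        should land in the plausible reproducibility window around the
        reported 0.71.
        """
        from methylaging import (
            SimulationTruth,
            compute_acceleration,
            make_clock,
            predict_dnam_age,
            simulate_methylation,
        )
        from methylaging.acceleration import AgeModelFit

        rng = np.random.default_rng(10)
        rates = {f"tissue{i:02d}": float(r)
                 for i, r in enumerate(rng.normal(1.0, 0.05, 30))}
        clock = make_clock(353, seed=10)
        truth = SimulationTruth(clock=clock, tissue_rate=rates, seed=10)
        beta, sheet = simulate_methylation(
            truth, [(112.0, list(rates), 2)], n_filler_cpgs=10
        )
        pred = predict_dnam_age(beta, clock)
        t = sheet.merge(pred.reset_index(), on="sample_id")
        acc = compute_acceleration(AgeModelFit(0.0, 1.0, [], 0.0), t)
        r, n = replicate_concordance(acc)
        assert n == 30
        assert 0.5 < r < 0.9
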