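"""FEE fitting and lattice-based community-function prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import phylofee as pf
from phylofee.fee import (
    CommunityDataset,
    FEEParams,
    additive_from_dataset,
    additive_predict,
    canon,
    community_function,
    evaluate_predictions,
    fit_all_fees,
    fit_fee,
    functional_effect,
    key_str,
    predict_function,
    read_fees,
    write_fees,
)

from conftest import lattice_objective


class TestCommunityFunction:
    def test_half_consumed(self):
        assert community_function(200.0, 100.0) == pytest.approx(0.5)

    def test_all_consumed_and_none(self):
        assert community_function(200.0, 0.0) == 1.0
        assert community_function(200.0, 200.0) == 0.0

    def test_slight_overshoot_clipped_to_zero(self):
        assert community_function(200.0, 205.0) == 0.0

    def test_large_overshoot_is_error(self):
        with pytest.raises(ValueError, match="exceed"):
            community_function(200.0, 250.0)


class TestCanon:
    def test_sorts_and_accepts_strings(self):
        assert canon(["b", "a"]) == ("a", "b")
        assert canon("b;a") == ("a", "b")
        assert key_str(["b", "a"]) == "a;b"

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            canon(["a", "a"])


@pytest.fixture
def small_ds():
    recs = []
    for f in (0.1, 0.2, 0.3):
        recs.append((("b1",), f"r{f}", f))            # mean 0.2
    for f in (0.4, 0.5, 0.6):
        recs.append((("b1", "z"), f"r{f}", f))        # mean 0.5
    return CommunityDataset.from_records(recs)


class TestDataset:
    def test_replicate_aggregation(self, small_ds):
        assert small_ds.mean_F(("b1",)) == pytest.approx(0.2)
        assert small_ds.n_replicates(("b1",)) == 3
        assert small_ds.sd_F(("b1",)) == pytest.approx(0.1)

    def test_empty_community_anchor(self, small_ds):
        assert small_ds.mean_F(()) == 0.0
        assert small_ds.is_measured(())

    def test_out_of_range_function_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            CommunityDataset.from_records([(("a",), 1, 1.4)])

    def test_unmeasured_lookup_is_keyerror(self, small_ds):
        with pytest.raises(KeyError):
            small_ds.mean_F(("nope",))

    def test_csv_round_trip(self, small_ds, tmp_path):
        p = tmp_path / "m.csv"
        small_ds.to_csv(p)
        again = CommunityDataset.read_csv(p)
        assert again.mean_F(("b1", "z")) == pytest.approx(0.5)
        assert again.strains == ["b1", "z"]


class TestFunctionalEffect:
    def test_value_and_sd_propagation(self, small_ds):
        dF, sd = functional_effect(small_ds, "z", ("b1",))
        assert dF == pytest.approx(0.3)
        # independent-sample propagation: sqrt(0.1^2/3 + 0.1^2/3)
        assert sd == pytest.approx(np.sqrt(0.02 / 3))

    def test_strain_already_present_is_error(self, small_ds):
        with pytest.raises(ValueError, match="already"):
            functional_effect(small_ds, "z", ("b1", "z"))

    def test_unmeasured_pair_is_keyerror(self, small_ds):
        with pytest.raises(KeyError):
            functional_effect(small_ds, "q", ("b1",))


def _linear_dataset(a, b, xs, noise=None, strain="z"):
    """Backgrounds {g_j} with F = x_j; adding `strain` gives x_j + a + b x_j."""
    recs = []
    for j, x in enumerate(xs):
        dF = a + b * x + (noise[j] if noise is not None else 0.0)
        recs.append(((f"g{j:02d}",), 1, x))
        recs.append(((f"g{j:02d}", strain), 1, x + dF))
    return CommunityDataset.from_records(recs)


class TestFitFee:
    def test_noiseless_exact_recovery(self):
        ds = _linear_dataset(0.25, -0.6, [0.1, 0.3, 0.5, 0.7, 0.9])
        fee = fit_fee(ds, "z")
        assert fee.a == pytest.approx(0.25, abs=1e-12)
        assert fee.b == pytest.approx(-0.6, abs=1e-12)
        assert fee.sigma2 == pytest.approx(1e-4)  # floor, not 0
        assert fee.r2 == pytest.approx(1.0)
        assert fee.n_points == 5

    def test_perfect_consumer(self):
        """A strain that always drives the community to F = 1 has the FEE
        dF = 1 - F(B), i.e. a = 1, b = -1."""
        recs = []
        for j, x in enumerate([0.2, 0.5, 0.8]):
            recs.append(((f"g{j}",), 1, x))
            recs.append(((f"g{j}", "sc"), 1, 1.0))
        fee = fit_fee(CommunityDataset.from_records(recs), "sc")
        assert fee.a == pytest.approx(1.0, abs=1e-12)
        assert fee.b == pytest.approx(-1.0, abs=1e-12)

    def test_monoculture_pair_uses_empty_anchor(self):
        """The (empty, monoculture) pair contributes a point at F(B) = 0."""
        ds = _linear_dataset(0.3, -0.5, [0.4, 0.6])
        recs = list(zip(
            [("z",), ("g00",), ("g00", "z"), ("g01",), ("g01", "z")],
            range(5),
            [0.3, 0.4, 0.4 + 0.3 - 0.5 * 0.4, 0.6, 0.6 + 0.3 - 0.5 * 0.6],
        ))
        fee = fit_fee(CommunityDataset.from_records(recs), "z")
        assert fee.n_points == 3
        assert fee.a == pytest.approx(0.3, abs=1e-12)
        assert fee.b == pytest.approx(-0.5, abs=1e-12)

    def test_too_few_pairs_is_error(self):
        ds = _linear_dataset(0.2, -0.3, [0.4, 0.6])
        with pytest.raises(ValueError, match="pairs"):
            fit_fee(ds, "z")

    def test_degenerate_design_is_error(self):
        ds = _linear_dataset(0.2, -0.3, [0.5, 0.5, 0.5])
        with pytest.raises(ValueError, match="degenerate"):
            fit_fee(ds, "z")

    def test_three_se_coverage(self):
        """Over 200 noisy replicates, the true (a, b) lie within 3 standard
        errors of the OLS estimates in >= 95% of fits."""
        a_true, b_true, sd = 0.3, -0.5, 0.02
        rng = np.random.default_rng(77)
        n, hits = 20, 0
        for _ in range(200):
            xs = rng.uniform(0.2, 0.9, size=n)
            noise = rng.normal(0.0, sd, size=n)
            fee = fit_fee(_linear_dataset(a_true, b_true, xs, noise), "z")
            x = fee.residuals["F_B"].to_numpy()
            s2 = float(fee.residuals["residual"].pow(2).sum()) / (n - 2)
            sxx = float(((x - x.mean()) ** 2).sum())
            se_b = np.sqrt(s2 / sxx)
            se_a = np.sqrt(s2 * (1 / n + x.mean() ** 2 / sxx))
            if abs(fee.a - a_true) <= 3 * se_a and abs(fee.b - b_true) <= 3 * se_b:
                hits += 1
        assert hits >= 190

    def test_fit_all_records_failures(self):
        ds = _linear_dataset(0.2, -0.4, [0.1, 0.5, 0.9])
        fees = fit_all_fees(ds)
        assert "z" in fees
        # background strains each appear in only one pair -> recorded failures
        assert set(fit_all_fees.failures) == {"g00", "g01", "g02"}

    def test_json_round_trip(self, tmp_path):
        ds = _linear_dataset(0.2, -0.4, [0.1, 0.5, 0.9])
        fees = {"z": fit_fee(ds, "z")}
        p = tmp_path / "fees.json"
        write_fees(fees, p)
        back = read_fees(p)
        assert back["z"].a == pytest.approx(fees["z"].a)
        assert back["z"].sigma2 == pytest.approx(fees["z"].sigma2)


def _toy_fees(params):
    return {
        s: FEEParams(s, a, b, sigma2, 5, 1.0) for s, (a, b, sigma2) in params.items()
    }


class TestPredict:
    def test_in_sample_target_returns_observed_mean(self, small_ds):
        res = predict_function(("b1", "z"), small_ds, {})
        assert res.F_pred == pytest.approx(0.5)
        assert res.anchors == [("b1", "z")]

    def test_single_addition_closed_form(self):
        """One missing strain: prediction = F(c0) + a + b F(c0), Eq (2)."""
        ds = CommunityDataset.from_records(
            [(("a",), 1, 0.3), (("b",), 1, 0.2), (("a", "b"), 1, 0.4)]
        )
        fees = _toy_fees({"c": (0.15, -0.3, 0.01)})
        res = predict_function(("a", "b", "c"), ds, fees)
        f0 = 0.4
        assert res.F_pred_raw == pytest.approx(f0 + 0.15 - 0.3 * f0, abs=1e-12)
        assert ("a", "b") in res.anchors

    def test_anchor_tie_break_prefers_more_replicates(self):
        ds = CommunityDataset.from_records(
            [(("a", "b"), 1, 0.4), (("a", "c"), 1, 0.5), (("a", "c"), 2, 0.5)]
        )
        fees = _toy_fees({"b": (0.1, -0.2, 0.01), "c": (0.1, -0.2, 0.01),
                          "d": (0.1, -0.2, 0.01)})
        res = predict_function(("a", "b", "c", "d"), ds, fees)
        # c0 must be ('a','c'): same size as ('a','b') but two replicates
        assert res.anchors[-1] != res.target
        # the lattice interval starts at ('a','c'): node ('a','c','d') exists
        assert res.lattice_nodes >= 6

    def test_missing_fee_is_error(self):
        ds = CommunityDataset.from_records([(("a",), 1, 0.3)])
        with pytest.raises(ValueError, match="no fitted FEE"):
            predict_function(("a", "q"), ds, {})

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        ds = CommunityDataset.from_records(
            [(("a",), 1, 0.3), (("b",), 1, 0.2), (("c",), 1, 0.25),
             (("a", "b"), 1, 0.45)]
        )
        fees = _toy_fees({
            "c": (0.15, -0.3, 0.01), "d": (0.05, -0.1, 0.02), "e": (0.2, -0.4, 0.015),
        })
        members = ["a", "b", "c", "d", "e"]
        ref = predict_function(members, ds, fees).F_pred_raw
        for _ in range(20):
            perm = list(rng.permutation(members))
            assert predict_function(perm, ds, fees).F_pred_raw == pytest.approx(
                ref, abs=1e-9
            )

    def test_matches_numerical_minimizer(self):
        """Two latent intermediates + latent target: the sparse WLS solution
        matches scipy.optimize on the same weighted edge objective."""
        ds = CommunityDataset.from_records(
            [(("a",), 1, 0.3), (("b",), 1, 0.2), (("c",), 1, 0.25),
             (("d",), 1, 0.15), (("a", "b"), 1, 0.45)]
        )
        fees = _toy_fees({
            "a": (0.1, -0.2, 0.02), "b": (0.08, -0.15, 0.03),
            "c": (0.15, -0.3, 0.01), "d": (0.05, -0.1, 0.04),
        })
        target = ("a", "b", "c", "d")
        res = predict_function(target, ds, fees)
        # fixed nodes and the latent interval above c0 = ('a','b')
        fixed = {(): 0.0, ("a",): 0.3, ("b",): 0.2, ("c",): 0.25,
                 ("d",): 0.15, ("a", "b"): 0.45}
        latent = [("a", "b", "c"), ("a", "b", "d"), ("a", "b", "c", "d")]

        def obj(v):
            values = dict(fixed)
            values.update(dict(zip(latent, v)))
            return lattice_objective(values, fees)

        best = optimize.minimize(obj, x0=np.full(3, 0.4), method="Nelder-Mead",
                                 options={"xatol": 1e-10, "fatol": 1e-14,
                                          "maxiter": 20000})
        assert res.F_pred_raw == pytest.approx(best.x[2], abs=1e-6)

    def test_powerset_scope_runs_and_clips(self):
        ds = CommunityDataset.from_records([(("a",), 1, 0.9)])
        fees = _toy_fees({"b": (0.9, 0.1, 0.01)})
        res = predict_function(("a", "b"), ds, fees, scope="powerset")
        assert res.clipped
        assert res.F_pred == 1.0
        with pytest.raises(ValueError, match="scope"):
            predict_function(("a", "b"), ds, fees, scope="chain")


class TestAdditive:
    def test_hand_example(self):
        pred, raw = additive_predict(["x", "y"], 0.6, {"x": 0.1, "y": -0.05})
        assert raw == pytest.approx(0.65)
        assert pred == pytest.approx(0.65)

    def test_clipping_and_missing_effect(self):
        pred, raw = additive_predict(["x"], 0.9, {"x": 0.4})
        assert raw == pytest.approx(1.3)
        assert pred == 1.0
        with pytest.raises(KeyError):
            additive_predict(["q"], 0.5, {})

    def test_from_dataset(self):
        ds = CommunityDataset.from_records(
            [(("sc",), 1, 0.6), (("x",), 1, 0.2),
             (("sc", "x"), 1, 0.7), (("y",), 1, 0.1), (("sc", "y"), 1, 0.55)]
        )
        pred, raw = additive_from_dataset(ds, ("sc", "x", "y"), "sc")
        # F_sc + (0.7-0.6) + (0.55-0.6)
        assert raw == pytest.approx(0.65)
        with pytest.raises(ValueError, match="focal"):
            additive_from_dataset(ds, ("x", "y"), "sc")


class TestEvaluate:
    def test_hand_rmse_and_r(self):
        preds = pd.Series({"a;b": 0.5, "a;c": 0.8})
        obs = pd.Series({"a;b": 0.6, "a;c": 1.0, "a;d": 0.3})
        ev = evaluate_predictions(preds, obs)
        assert ev["n"] == 2
        assert ev["rmse"] == pytest.approx(np.sqrt((0.01 + 0.04) / 2))
        assert ev["r"] == pytest.approx(1.0)
        assert ev["rmse_by_richness"].loc[2] == pytest.approx(np.sqrt(0.025))

    def test_richness_grouping(self):
        preds = pd.Series({"a;b": 0.5, "a;b;c": 0.5})
        obs = pd.Series({"a;b": 0.6, "a;b;c": 0.7})
        ev = evaluate_predictions(preds, obs)
        assert ev["rmse_by_richness"].loc[2] == pytest.approx(0.1)
        assert ev["rmse_by_richness"].loc[3] == pytest.approx(0.2)

    def test_disjoint_is_error(self):
        with pytest.raises(ValueError, match="common"):
            evaluate_predictions(pd.Series({"a": 0.1}), pd.Series({"b": 0.2}))
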