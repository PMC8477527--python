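"""Fitting, Rhat diagnostics, posterior summaries, diagnostics export."""

import arviz as az
import numpy as np
import pandas as pd
import pytest

from hurdlema import (
    ModelSpec,
    SamplerConfig,
    compute_rhat,
    diagnostics_export,
    fit,
    summarize_posterior,
)
from hurdlema.inference import PosteriorDraws


def _draws_from(values, names=("a",), seed=0):
    values = np.asarray(values)
    cfg = SamplerConfig(n_chains=values.shape[0], n_iter=2 * values.shape[1],
                        n_warmup=values.shape[1], seed=seed)
    return PosteriorDraws(values=values, parameter_names=list(names), config=cfg)


class TestRhat:
    def test_well_mixed_chains_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 4000))
        assert compute_rhat(x) == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_much_greater_than_one(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 1000))
        x[1] += 10.0
        r = compute_rhat(x)
        assert r > 3.0

    def test_matches_arviz_split_rhat(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((4, 500)).cumsum(axis=1) * 0.01 \
            + rng.standard_normal((4, 500))
        ours = compute_rhat(x)
        theirs = float(np.asarray(
            az.rhat(az.convert_to_dataset(x), method="split")["x"]).ravel()[0])
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_constant_chain_flagged_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            r = compute_rhat(np.ones((2, 100)))
        assert np.isnan(r)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((3, 400))
        assert compute_rhat(3.5 * x - 7.0) == pytest.approx(compute_rhat(x),
                                                            rel=1e-12)

    def test_requires_multiple_chains_and_draws(self):
        with pytest.raises(ValueError):
            compute_rhat(np.ones((1, 100)))
        with pytest.raises(ValueError):
            compute_rhat(np.ones((2, 3)))


class TestSummaries:
    def test_constant_draws(self):
        d = _draws_from(np.full((2, 50, 1), 3.25))
        with pytest.warns(UserWarning):
            s = summarize_posterior(d)
        row = s["a"]
        assert row["mean"] == 3.25 and row["sd"] == 0
        assert row["ci_low"] == row["ci_high"] == 3.25

    def test_small_mean(self):
        d = _draws_from(np.array([1.0, 2, 3, 4]).reshape(2, 2, 1))
        s = summarize_posterior(d)
        assert s["a"]["mean"] == 2.5

    def test_normal_draws_ci_matches_quantiles(self):
        rng = np.random.default_rng(5)
        d = _draws_from(rng.standard_normal((4, 50000, 1)))
        s = summarize_posterior(d)
        assert s["a"]["ci_low"] == pytest.approx(-1.96, abs=0.03)
        assert s["a"]["ci_high"] == pytest.approx(1.96, abs=0.03)

    def test_ci_monotone_in_level(self):
        rng = np.random.default_rng(6)
        d = _draws_from(rng.standard_normal((2, 2000, 1)))
        widths = []
        for level in (0.5, 0.8, 0.95, 0.99):
            s = summarize_posterior(d, level=level)
            widths.append(s["a"]["ci_high"] - s["a"]["ci_low"])
        assert np.all(np.diff(widths) > 0)

    def test_long_csv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(7)
        d = _draws_from(rng.standard_normal((2, 10, 2)), names=("a", "b"))
        d.save_csv(tmp_path / "draws.csv")
        back = pd.read_csv(tmp_path / "draws.csv")
        assert len(back) == 2 * 10 * 2
        assert set(back["parameter"]) == {"a", "b"}


class TestDiagnosticsExport:
    def test_trace_shapes_and_density(self):
        rng = np.random.default_rng(8)
        d = _draws_from(rng.standard_normal((4, 1000, 1)))
        out = diagnostics_export(d)
        trace = out["a"]["trace"]
        assert len(trace) == 4000
        assert trace["chain"].nunique() == 4
        assert not out["a"]["degenerate"]
        dens = out["a"]["density"]
        assert (dens["density"] >= 0).all()

    def test_unimodal_density_single_mode(self):
        rng = np.random.default_rng(9)
        d = _draws_from(rng.standard_normal((2, 4000, 1)))
        dens = diagnostics_export(d)["a"]["density"]
        y = dens["density"].to_numpy()
        interior_max = (np.diff(np.sign(np.diff(y))) < 0).sum()
        assert interior_max == 1

    def test_constant_chain_flagged(self):
        d = _draws_from(np.full((2, 100, 1), 1.0))
        out = diagnostics_export(d)
        assert out["a"]["degenerate"]


class TestFit:
    def test_seed_reproducibility_bitwise(self, tiny_dataset):
        data, _ = tiny_dataset
        cfg = SamplerConfig(n_chains=2, n_iter=80, n_warmup=40, seed=99)
        d1 = fit(data, ModelSpec(), cfg)
        d2 = fit(data, ModelSpec(), cfg)
        np.testing.assert_array_equal(d1.values, d2.values)

    def test_different_seeds_differ(self, tiny_dataset):
        data, _ = tiny_dataset
        d1 = fit(data, ModelSpec(), SamplerConfig(n_chains=2, n_iter=80,
                                                  n_warmup=40, seed=1))
        d2 = fit(data, ModelSpec(), SamplerConfig(n_chains=2, n_iter=80,
                                                  n_warmup=40, seed=2))
        assert not np.array_equal(d1.values, d2.values)

    def test_reported_parameters_and_support(self, tiny_dataset):
        data, _ = tiny_dataset
        cfg = SamplerConfig(n_chains=2, n_iter=120, n_warmup=60, seed=7)
        draws = fit(data, ModelSpec(), cfg)
        assert draws.parameter_names == [
            "b_zero_Intercept", "b_gamma_Intercept", "sd_zero_Intercept",
            "sd_gamma_Intercept", "cor_zero_Intercept_gamma_Intercept", "shape"]
        assert draws.values.shape == (2, 60, 6)
        assert (draws.get("sd_zero_Intercept") >= 0).all()
        assert (draws.get("shape") > 0).all()
        cor = draws.get("cor_zero_Intercept_gamma_Intercept")
        assert (np.abs(cor) <= 1).all()

    def test_keep_random_effects_adds_person_draws(self, tiny_dataset):
        data, _ = tiny_dataset
        cfg = SamplerConfig(n_chains=2, n_iter=40, n_warmup=20, seed=3)
        draws = fit(data, ModelSpec(), cfg, keep_random_effects=True)
        J = data.n_participants
        assert draws.values.shape[-1] == 6 + 2 * J

    def test_empty_dataset_rejected(self, tiny_dataset):
        from hurdlema.data import EmaDataset
        data, _ = tiny_dataset
        empty = EmaDataset(data.table.iloc[:0].copy())
        with pytest.raises(ValueError):
            fit(empty, ModelSpec())
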