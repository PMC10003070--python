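"""Objective function, normalization profiling and the fit driver."""

import numpy as np
import pytest

from pyrdyn import (SteadyStateDataset, default_parameters, fit_parameters,
                    objective, read_datasets_csv, synth, write_datasets_csv)
from pyrdyn.fit import compare_datasets
from pyrdyn.params import ExternalPools


@pytest.fixture(scope="module")
def clean_data(p_default):
    return synth.make_steady_datasets(p_default, noise_cv=0.0,
                                      scale_factors=(1.0, 1.0), seed=0)


class TestObjective:
    def test_zero_at_generating_parameters(self, p_default, clean_data):
        # limited only by the steady-state refinement tolerance
        assert objective(p_default, clean_data) == pytest.approx(0.0, abs=1e-9)

    def test_single_observation_off_by_e_contributes_one(self, p_default,
                                                         clean_data):
        ds = clean_data[0]
        bumped = SteadyStateDataset(
            dataset_id=ds.dataset_id,
            concentrations={m: (c * np.e if m == "ump" else c)
                            for m, c in ds.concentrations.items()},
            pools=ds.pools)
        # fix the coefficient at 1 so the residual is not profiled away
        val = objective(p_default, [bumped], norms={ds.dataset_id: 1.0})
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_profiled_norms_recover_scale_ratio(self, p_default):
        data = synth.make_steady_datasets(p_default, noise_cv=0.0,
                                          scale_factors=(1.0, 2.0), seed=0)
        obj, norms = objective(p_default, data, return_norms=True)
        assert obj == pytest.approx(0.0, abs=1e-9)
        ids = [d.dataset_id for d in data]
        assert norms[ids[0]] == 1.0
        assert norms[ids[1]] == pytest.approx(2.0, rel=1e-5)

    def test_dataset_order_invariance(self, p_default):
        data = synth.make_steady_datasets(p_default, noise_cv=0.1, seed=3)
        fixed = {d.dataset_id: 1.3 for d in data}
        a = objective(p_default, data, norms=fixed)
        b = objective(p_default, list(reversed(data)), norms=fixed)
        assert a == pytest.approx(b, rel=1e-12)

    def test_infinite_penalty_without_steady_state(self, clean_data):
        p_osc = synth.make_oscillatory_base()
        assert objective(p_osc, clean_data) == np.inf

    def test_validation(self, p_default):
        with pytest.raises(ValueError):
            objective(p_default, [])
        with pytest.raises(ValueError, match="unknown metabolite"):
            SteadyStateDataset("x", {"nadph": 1.0}, ExternalPools())
        with pytest.raises(ValueError, match="must be > 0"):
            SteadyStateDataset("x", {"ump": 0.0}, ExternalPools())


class TestFitParameters:
    def test_empty_free_params_evaluates_once(self, p_default, clean_data):
        res = fit_parameters(clean_data, [], seed=0)
        assert res.nfev == 1
        assert res.objective == pytest.approx(0.0, abs=1e-9)
        assert res.params.to_dict() == p_default.to_dict()

    def test_missing_bounds_rejected(self, clean_data):
        with pytest.raises(ValueError, match="bounds required"):
            fit_parameters(clean_data, ["k9"], bounds=None)
        with pytest.raises(KeyError):
            fit_parameters(clean_data, ["k99"], bounds={"k99": (0.1, 1.0)})

    def test_seed_reproducibility(self, p_default):
        data = synth.make_steady_datasets(p_default, noise_cv=0.1, seed=5)
        kw = dict(bounds={"k9": (p_default.k9 / 5, p_default.k9 * 5)},
                  maxiter=10, popsize=6, polish=False)
        a = fit_parameters(data, ["k9"], seed=11, **kw)
        b = fit_parameters(data, ["k9"], seed=11, **kw)
        assert a.params.k9 == b.params.k9
        assert a.objective == b.objective
        assert a.trace == b.trace

    def test_noise_free_k9_recovery_tight(self, p_default, clean_data):
        res = fit_parameters(clean_data, ["k9"],
                             bounds={"k9": (p_default.k9 / 10,
                                            p_default.k9 * 10)},
                             seed=1, maxiter=40, popsize=8)
        assert res.success
        err = abs(res.params.k9 - p_default.k9) / p_default.k9
        assert err < 0.01

    def test_result_serialization(self, p_default, clean_data, tmp_path):
        res = fit_parameters(clean_data, [], seed=0)
        path = tmp_path / "fit.json"
        res.to_json(path)
        import json
        doc = json.loads(path.read_text())
        assert doc["objective"] == pytest.approx(0.0, abs=1e-9)
        assert doc["params_digest"] == p_default.digest()


class TestDatasetIO:
    def test_csv_round_trip(self, tmp_path, p_default):
        data = synth.make_steady_datasets(p_default, noise_cv=0.1, seed=2)
        path = tmp_path / "datasets.csv"
        write_datasets_csv(data, path)
        back = read_datasets_csv(path)
        assert len(back) == len(data)
        for a, b in zip(data, back):
            assert a.dataset_id == b.dataset_id
            assert a.pools == b.pools
            for m in a.concentrations:
                assert b.concentrations[m] == pytest.approx(
                    a.concentrations[m], rel=1e-12)

    def test_reader_rejects_missing_columns(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="need columns"):
            read_datasets_csv(path)


def test_between_dataset_scale_shift_is_detectable(p_default):
    """The location test flags a systematic 2x scale between the tables."""
    data = synth.make_steady_datasets(p_default, noise_cv=0.0,
                                      scale_factors=(1.0, 2.0), seed=0,
                                      pools=(synth.DEFAULT_POOLS[0],
                                             synth.DEFAULT_POOLS[0]))
    t, pv = compare_datasets(data[0], data[1])
    assert pv < 0.05
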