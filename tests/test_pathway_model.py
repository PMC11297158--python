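"""Branched-pathway ODE model: programs, equilibrium, sampling, fitting."""

import numpy as np
import pytest

from combisig.pathway_model import (DISTRIBUTED_PARAMS, MODULE_PARAMS,
                                    PathwayParameters, PopulationSpec,
                                    equilibrate, fit_representative,
                                    mass_conservation_error,
                                    sample_parameters, simulate_cell,
                                    stimulus_program)


def test_stimulus_program_dose_scaling_and_mock():
    full = stimulus_program("TNF", 100.0)
    half = stimulus_program("TNF", 1.0)   # half_dose for TNF is 1.0
    t = np.linspace(0, 120, 50)
    ratio = half.ikk_curve(t)[10:] / full.ikk_curve(t)[10:]
    # dose saturation dose/(dose+half), normalized at the reference dose
    expected = (1.0 / 2.0) / (100.0 / 101.0)
    assert np.allclose(ratio, expected, rtol=1e-6)
    mock = stimulus_program("mock", 100.0)
    assert not mock.ikk_curve(t).any() and not mock.tak1_curve(t).any()
    zero_dose = stimulus_program("LPS", 0.0)
    assert not zero_dose.ikk_curve(t).any()
    with pytest.raises(ValueError):
        stimulus_program("IL6", 10.0)


def test_input_curves_zero_before_stimulus_and_bounded():
    prog = stimulus_program("LPS", 100.0)
    t = np.linspace(-60, 480, 500)
    y = prog.ikk_curve(t)
    assert not y[t < 0].any()
    assert y.min() >= 0.0 and y.max() <= 1.0


def test_parameter_validation():
    with pytest.raises(ValueError):
        PathwayParameters(p38_tot=-1.0)
    with pytest.raises(ValueError):
        PathwayParameters(n_mkk6=20.0)  # Hill coefficient outside [0.1, 10]
    with pytest.raises(ValueError):
        PathwayParameters().updated(no_such_rate=1.0)
    p2 = PathwayParameters().updated(p38_tot=0.8)
    assert p2.p38_tot == 0.8 and PathwayParameters().p38_tot != 0.8


def test_resting_equilibrium_is_quiescent():
    from combisig.pathway_model import SPECIES
    p = PathwayParameters()
    named = dict(zip(SPECIES, equilibrate(p)))
    assert named["p38_pp"] == pytest.approx(0.0, abs=1e-9)
    assert named["nfkb_n"] == pytest.approx(0.0, abs=1e-9)
    assert named["nfkb_ikb"] == pytest.approx(p.NFkB_tot, rel=1e-6)


def test_mock_simulation_is_exactly_flat():
    sim = simulate_cell(PathwayParameters(), stimulus_program("mock", 0.0))
    assert np.allclose(sim.trajectory.p38, 0.0, atol=1e-9)
    assert np.allclose(sim.trajectory.nfkb, 0.0, atol=1e-9)


def test_stimulus_phenomenology():
    """TNF transient and weakest; LPS sustained with biphasic branch order."""
    p = PathwayParameters()
    sims = {s: simulate_cell(p, stimulus_program(s, 100.0))
            for s in ("TNF", "LPS", "P3C4")}
    maxima = {s: sims[s].trajectory.p38.max() for s in sims}
    assert maxima["TNF"] < maxima["LPS"] and maxima["TNF"] < maxima["P3C4"]
    t = sims["LPS"].trajectory.time_min
    late = t >= 300
    assert sims["LPS"].trajectory.p38[late].max() > 5 * sims["TNF"].trajectory.p38[late].max()
    # conservation holds for every stimulus
    for sim in sims.values():
        assert mass_conservation_error(sim) < 1e-6


def test_sample_parameters_median_and_denoise_stream():
    rep = PathwayParameters()
    spec = PopulationSpec(n_cells=4000, seed=3)
    table = sample_parameters(spec, rep)
    assert list(table.columns) == list(DISTRIBUTED_PARAMS)
    for name in DISTRIBUTED_PARAMS:
        med = np.median(table[name])
        assert med == pytest.approx(getattr(rep, name), rel=0.05)
    # denoising one module pins its params without shifting other streams
    spec_d = PopulationSpec(n_cells=4000, seed=3,
                            denoise=frozenset({"p38_module"}))
    table_d = sample_parameters(spec_d, rep)
    for name in MODULE_PARAMS["p38_module"]:
        assert (table_d[name] == getattr(rep, name)).all()
    for name in MODULE_PARAMS["nfkb_module"] + MODULE_PARAMS["receptor"]:
        np.testing.assert_array_equal(table[name], table_d[name])
    with pytest.raises(ValueError):
        sample_parameters(PopulationSpec(n_cells=2, distributed_params=("bogus",)),
                          rep)


def test_baseline_frames_are_zero_activity():
    sim = simulate_cell(PathwayParameters(), stimulus_program("TNF", 100.0))
    tr = sim.trajectory
    assert np.allclose(tr.p38[tr.baseline_mask], 0.0, atol=1e-9)
    assert np.allclose(tr.nfkb[tr.baseline_mask], 0.0, atol=1e-9)


def test_fit_representative_recovers_perturbed_total():
    true = PathwayParameters().updated(p38_tot=0.6)
    target = simulate_cell(true, stimulus_program("TNF", 100.0)).trajectory
    res = fit_representative(PathwayParameters(), {"TNF": target},
                             free_params=("p38_tot",), max_nfev=40)
    assert res.params.p38_tot == pytest.approx(0.6, rel=0.05)
    assert res.objective < 1e-4
    with pytest.raises(ValueError):
        fit_representative(PathwayParameters(), {})
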