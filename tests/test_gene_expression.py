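"""AND-gate gene model and expression-distribution statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from combisig.gene_expression import (SAMPLE_TIMES_H, GeneModelParameters,
                                      _hill_act, _hill_rep,
                                      bimodality_coefficient, fano_factor,
                                      permutation_test_mean_diff,
                                      population_expression, simulate_mrna)
from combisig.trajectories import ActivityTrajectory, default_grid


def _flat_traj(p38, nfkb, grid=None):
    grid = default_grid() if grid is None else grid
    return ActivityTrajectory(cell_id="c", stimulus="toy", dose=0.0,
                              time_min=grid, p38=np.full_like(grid, p38),
                              nfkb=np.full_like(grid, nfkb), units="model_uM")


def test_parameter_validation():
    with pytest.raises(ValueError):
        GeneModelParameters(k_syn_max=-1.0)
    with pytest.raises(ValueError):
        GeneModelParameters(mode="OR")


def test_simulate_mrna_requires_model_units():
    traj = _flat_traj(0.0, 0.1)
    traj.units = "AU"
    with pytest.raises(ValueError, match="model units"):
        simulate_mrna(GeneModelParameters(), traj)


def test_p38_represses_degradation():
    """Higher p38 stabilizes the transcript: more mRNA at equal NFkB drive."""
    low = simulate_mrna(GeneModelParameters(), _flat_traj(0.0, 0.2))
    high = simulate_mrna(GeneModelParameters(), _flat_traj(0.2, 0.2))
    assert high[-1] > low[-1]
    # NFkB_only mode ignores p38 entirely
    p = GeneModelParameters(mode="NFkB_only")
    a = simulate_mrna(p, _flat_traj(0.0, 0.2))
    b = simulate_mrna(p, _flat_traj(0.5, 0.2))
    np.testing.assert_array_equal(a, b)


def test_no_nfkb_no_transcription():
    m = simulate_mrna(GeneModelParameters(), _flat_traj(0.1, 0.0))
    assert np.allclose(m, 0.0, atol=1e-12)


def test_steady_state_closed_form_scaling():
    params = GeneModelParameters(k_deg_max=0.3)
    m = simulate_mrna(params, _flat_traj(0.03, 0.15))
    expected = (params.k_syn_max * _hill_act(0.15, params.K_d_NFkB, params.n_nfkb)
                / (params.k_deg_max * _hill_rep(0.03, params.K_d_p38, params.n_p38)))
    assert m[-1] == pytest.approx(expected, rel=1e-6)


def test_population_expression_summary_schema():
    trajs = [_flat_traj(0.02 * i, 0.05 + 0.05 * i) for i in range(5)]
    dist = population_expression(trajs)
    assert set(dist.values) == {"AND", "NFkB_only"}
    assert dist.values["AND"].shape == (5, len(SAMPLE_TIMES_H))
    summ = dist.summary()
    assert set(summ.columns) >= {"mode", "time_h", "mean", "fano", "bimodality"}
    assert len(summ) == 2 * len(SAMPLE_TIMES_H)


def test_fano_factor_closed_forms_and_errors():
    rng = np.random.default_rng(0)
    assert fano_factor(rng.poisson(5, 50_000)) == pytest.approx(1.0, abs=0.03)
    # a scaled Poisson has Fano equal to the scale
    assert fano_factor(3.0 * rng.poisson(5, 50_000)) == pytest.approx(3.0, abs=0.1)
    with pytest.raises(ValueError):
        fano_factor(np.zeros(10))


@settings(max_examples=25, deadline=None)
@given(scale=st.floats(0.1, 50.0))
def test_fano_scaling_property(scale):
    rng = np.random.default_rng(1)
    x = rng.poisson(8, 2000).astype(float)
    assert fano_factor(scale * x) == pytest.approx(scale * fano_factor(x),
                                                   rel=1e-9)


def test_bimodality_coefficient_forms():
    rng = np.random.default_rng(2)
    assert bimodality_coefficient(rng.normal(size=50_000)) == pytest.approx(
        1 / 3, abs=0.03)
    two = np.concatenate([np.zeros(5000), np.ones(5000)])
    assert bimodality_coefficient(two) == pytest.approx(1.0, abs=0.01)
    # nonzero_only drops the zero spike before computing the statistic
    spike = np.concatenate([np.zeros(5000), rng.normal(10, 1, 5000)])
    assert (bimodality_coefficient(spike, nonzero_only=True)
            == pytest.approx(1 / 3, abs=0.05))
    with pytest.raises(ValueError):
        bimodality_coefficient(np.arange(3))


def test_permutation_test_detects_shift_and_validates():
    rng = np.random.default_rng(3)
    a = rng.normal(0, 1, 40)
    b = rng.normal(2, 1, 40)
    assert permutation_test_mean_diff(a, b, n_perm=500, seed=0) < 0.01
    same = permutation_test_mean_diff(a, a + 0.0, n_perm=500, seed=0)
    assert same > 0.5
    with pytest.raises(ValueError):
        permutation_test_mean_diff(a, b, n_perm=50)
    with pytest.raises(ValueError):
        permutation_test_mean_diff(a, np.array([]))
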