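"""AND-gate mRNA kinetics driven by paired activity trajectories, plus
expression-distribution statistics.

The gene model couples the two pathways sequentially: NFkB activates the
promoter (synthesis) while p38 stabilizes the transcript (represses
degradation):

    d[mRNA]/dt = k_syn_max * NFkB^n_nfkb / (K_d_NFkB^n_nfkb + NFkB^n_nfkb)
               - k_deg_max * K_d_p38^n_p38 / (K_d_p38^n_p38 + p38^n_p38) * [mRNA]

The NFkB-only variant fixes the degradation Hill factor at 1 (degradation at
full k_deg_max), which is also the exact p38 = 0 limit of the AND gate.
Distribution statistics: Fano factor (sample variance / mean), the
bimodality coefficient

    BC = (g1^2 + 1) / (g2 + 3 (n-1)^2 / ((n-2)(n-3)))

with g1 the sample skewness and g2 the sample excess kurtosis (BC = 1/3 for
a normal sample, > 5/9 suggests bimodality), and a two-sided permutation
test for differences in group means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import solve_ivp

from .trajectories import ActivityTrajectory

#: mRNA collection times, hours after stimulation
SAMPLE_TIMES_H = (0.25, 1.0, 3.0, 8.0)


@dataclass
class GeneModelParameters:
    """AND-gate gene model constants.

    Defaults place both K_d values mid-range of the simulated pathway
    activities (model uM scale) with cooperative (n = 2) Hill terms; the
    synthesis and degradation maxima set the output scale and the ~50-min
    response time of the transcript.
    """
    k_syn_max: float = 1.0      # mRNA/min
    k_deg_max: float = 0.02     # 1/min
    K_d_NFkB: float = 0.1       # uM
    K_d_p38: float = 0.04       # uM
    n_nfkb: float = 2.0
    n_p38: float = 2.0
    mode: str = "AND"           # "AND" or "NFkB_only"

    def __post_init__(self):
        for name in ("k_syn_max", "k_deg_max", "K_d_NFkB", "K_d_p38",
                     "n_nfkb", "n_p38"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mode not in ("AND", "NFkB_only"):
            raise ValueError("mode must be 'AND' or 'NFkB_only'")


def _hill_act(x, kd, n):
    xn = x ** n
    return xn / (kd ** n + xn)


def _hill_rep(x, kd, n):
    kdn = kd ** n
    return kdn / (kdn + x ** n)


def simulate_mrna(params: GeneModelParameters, traj: ActivityTrajectory) -> np.ndarray:
    """Integrate the mRNA ODE on the trajectory's post-stimulus grid.

    The activity inputs (model units, uM) are linearly interpolated between
    frames and clamped at 0 (baseline noise can dip below zero); initial
    mRNA is 0 at stimulus onset.
    """
    if traj.units != "model_uM":
        raise ValueError("trajectory must be in model units (apply rescale_units)")
    post = traj.post_mask
    t = traj.time_min[post]
    nfkb = np.clip(traj.nfkb[post], 0.0, None)
    p38 = np.clip(traj.p38[post], 0.0, None)

    def rhs(tt, m):
        nf = np.interp(tt, t, nfkb)
        pp = np.interp(tt, t, p38)
        syn = params.k_syn_max * _hill_act(nf, params.K_d_NFkB, params.n_nfkb)
        if params.mode == "AND":
            deg = params.k_deg_max * _hill_rep(pp, params.K_d_p38, params.n_p38)
        else:
            deg = params.k_deg_max
        return syn - deg * m[0]

    sol = solve_ivp(rhs, (t[0], t[-1]), [0.0], t_eval=t, method="LSODA",
                    rtol=1e-8, atol=1e-10, max_step=traj.frame_min)
    if not sol.success:
        raise RuntimeError(f"mRNA integration failed at t = "
                           f"{sol.t[-1] if sol.t.size else t[0]:.1f} min: {sol.message}")
    return sol.y[0]


@dataclass
class ExpressionDistribution:
    """Per-cell mRNA levels at the sampling times, per regulatory mode."""
    sample_times_h: tuple
    values: dict                      # mode -> (n_cells x n_times) array
    cell_ids: list = field(default_factory=list)
    condition: str = ""

    def summary(self) -> pd.DataFrame:
        rows = []
        for mode, mat in self.values.items():
            for j, th in enumerate(self.sample_times_h):
                col = mat[:, j]
                rows.append({
                    "mode": mode, "time_h": th, "mean": float(col.mean()),
                    "fano": fano_factor(col) if col.mean() > 0 else np.nan,
                    "bimodality": (bimodality_coefficient(col, nonzero_only=True)
                                   if np.count_nonzero(col) >= 4 else np.nan),
                })
        return pd.DataFrame(rows)


def population_expression(trajs: list[ActivityTrajectory],
                          params: GeneModelParameters | None = None,
                          modes: tuple = ("AND", "NFkB_only"),
                          sample_times_h: tuple = SAMPLE_TIMES_H) -> ExpressionDistribution:
    """One mRNA trace per cell per mode, sampled at the collection times."""
    if params is None:
        params = GeneModelParameters()
    values = {}
    times_min = np.asarray(sample_times_h, float) * 60.0
    for mode in modes:
        p = GeneModelParameters(**{**params.__dict__, "mode": mode})
        mat = np.empty((len(trajs), times_min.size))
        for i, traj in enumerate(trajs):
            m = simulate_mrna(p, traj)
            t = traj.time_min[traj.post_mask]
            mat[i] = np.interp(times_min, t, m)
        values[mode] = mat
    return ExpressionDistribution(
        sample_times_h=tuple(sample_times_h), values=values,
        cell_ids=[t.cell_id for t in trajs],
        condition=trajs[0].stimulus if trajs else "")


# ---------------------------------------------------------------------------
# distribution statistics
# ---------------------------------------------------------------------------

def fano_factor(values) -> float:
    """Sample variance divided by the mean (1 for a Poisson sample)."""
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    if mean <= 0:
        raise ValueError("Fano factor requires a positive mean")
    if values.size < 2:
        return 0.0
    return float(values.var(ddof=1) / mean)


def bimodality_coefficient(values, nonzero_only: bool = False) -> float:
    """Sarle's bimodality coefficient on a sample (optionally zeros dropped)."""
    values = np.asarray(values, dtype=float)
    if nonzero_only:
        values = values[values != 0]
    n = values.size
    if n < 4:
        raise ValueError("need at least 4 values")
    g1 = stats.skew(values, bias=False)
    g2 = stats.kurtosis(values, fisher=True, bias=False)
    return float((g1 ** 2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


def permutation_test_mean_diff(group_a, group_b, n_perm: int = 10_000,
                               seed: int = 0) -> float:
    """Two-sided permutation p-value for a difference in group means.

    p = (1 + #{|delta_perm| >= |delta_obs|}) / (n_perm + 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    obs = abs(a.mean() - b.mean())
    n_a = a.size
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[:n_a].mean() - perm[n_a:].mean()) >= obs:
            count += 1
    return (1 + count) / (n_perm + 1)
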