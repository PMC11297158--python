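"""Responder-fraction dose-response curves and four-parameter Hill fits.

The response model is

    A(conc) = maxA * conc^HillC / (halfA_conc^HillC + conc^HillC) + intersect

fit by bounded nonlinear least squares with HillC in [0.1, 10], halfA_conc in
[min dose, max dose], maxA in [0, 1] and intersect in [0, 0.9].  Mock
stimulation enters the (logarithmic) dose axis at 100x below the lowest
nonzero dose.  The p38-vs-NFkB differential activation threshold is the
ratio of the two pathways' half-maximum concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .trajectories import ActivityTrajectory
from .trajectory_features import responder_fraction

HILLC_BOUNDS = (0.1, 10.0)
MAXA_BOUNDS = (0.0, 1.0)
INTERSECT_BOUNDS = (0.0, 0.9)
MOCK_DOSE_FACTOR = 100.0


@dataclass
class DoseResponse:
    stimulus: str
    doses: np.ndarray                 # strictly increasing; mock encoded low
    fractions: dict = field(default_factory=dict)  # pathway -> responder fractions

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        for pw, fr in self.fractions.items():
            fr = np.asarray(fr, dtype=float)
            if fr.shape != self.doses.shape:
                raise ValueError(f"{pw}: fraction vector length mismatch")
            if np.any((fr < 0) | (fr > 1)):
                raise ValueError(f"{pw}: responder fractions must lie in [0, 1]")
            self.fractions[pw] = fr


@dataclass
class HillFit:
    maxA: float
    halfA_conc: float
    HillC: float
    intersect: float
    residual: float
    identifiable: bool = True

    def predict(self, conc):
        conc = np.asarray(conc, dtype=float)
        ch = conc ** self.HillC
        return self.maxA * ch / (self.halfA_conc ** self.HillC + ch) + self.intersect

    def summary(self) -> dict:
        return {"maxA": self.maxA, "halfA_conc": self.halfA_conc,
                "HillC": self.HillC, "intersect": self.intersect,
                "residual": self.residual, "identifiable": self.identifiable}


def build_dose_response(traj_sets: dict[float, list[ActivityTrajectory]],
                        pathways: tuple = ("p38", "nfkb"),
                        stimulus: str | None = None, **responder_kwargs) -> DoseResponse:
    """Responder fractions per dose per pathway.

    ``traj_sets`` maps dose -> trajectory list; dose 0 (mock) is re-encoded
    at 1/100 of the lowest nonzero dose for the logarithmic axis.
    """
    for dose, trajs in traj_sets.items():
        if not trajs:
            raise ValueError(f"dose {dose} has zero cells")
    doses = np.array(sorted(traj_sets), dtype=float)
    nonzero = doses[doses > 0]
    if nonzero.size == 0:
        raise ValueError("need at least one nonzero dose")
    axis = np.where(doses == 0, nonzero.min() / MOCK_DOSE_FACTOR, doses)
    if stimulus is None:
        stimulus = next(t.stimulus for d in sorted(traj_sets) if d > 0
                        for t in traj_sets[d][:1])
    fractions = {
        pw: np.array([responder_fraction(traj_sets[d], pw, **responder_kwargs)
                      for d in sorted(traj_sets)])
        for pw in pathways}
    return DoseResponse(stimulus=stimulus, doses=axis, fractions=fractions)


def _hill_model(x, conc):
    maxA, half, hc, inter = x
    ch = conc ** hc
    return maxA * ch / (half ** hc + ch) + inter


def fit_hill(dr: DoseResponse, pathway: str) -> HillFit:
    """Bounded least-squares Hill fit from 5 deterministic multistarts.

    Starting points span the box bounds; the best final residual wins, ties
    resolved by start index.  A flat response leaves halfA_conc
    unidentifiable, flagged in the result.
    """
    conc = dr.doses
    y = dr.fractions[pathway]
    if conc.size < 4:
        raise ValueError("need at least 4 dose points")
    lo = np.array([MAXA_BOUNDS[0], conc.min(), HILLC_BOUNDS[0], INTERSECT_BOUNDS[0]])
    hi = np.array([MAXA_BOUNDS[1], conc.max(), HILLC_BOUNDS[1], INTERSECT_BOUNDS[1]])

    log_mid = 10 ** ((np.log10(conc.min()) + np.log10(conc.max())) / 2)
    starts = [
        np.array([0.9, log_mid, 1.0, 0.05]),
        np.array([0.5, conc.min() * 2, 2.0, 0.0]),
        np.array([1.0, conc.max() / 2, 0.5, 0.1]),
        np.array([max(y.max() - y.min(), 0.05), log_mid, 4.0, min(y.min(), 0.9)]),
        np.array([0.2, log_mid, 8.0, 0.4]),
    ]
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        sol = least_squares(lambda x: _hill_model(x, conc) - y, x0,
                            bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        cost = float(np.sum(sol.fun ** 2))
        if best is None or cost < best[0] - 1e-15:
            best = (cost, sol)
    cost, sol = best
    # an evaluation-capped run that already reached a negligible residual is
    # converged for practical purposes (tolerances are set near machine eps)
    if not sol.success and cost > 1e-10:
        raise RuntimeError(f"Hill fit did not converge: {sol.message}; residual {cost:.3g}")
    maxA, half, hc, inter = sol.x
    # a flat curve (maxA ~ 0) carries no information about halfA_conc
    identifiable = maxA > 1e-3 * max(1.0, y.max())
    return HillFit(maxA=float(maxA), halfA_conc=float(half), HillC=float(hc),
                   intersect=float(inter), residual=cost, identifiable=identifiable)


def half_max_fold_difference(fit_p38: HillFit, fit_nfkb: HillFit) -> float:
    """halfA_conc(p38) / halfA_conc(NFkB): the differential activation threshold."""
    if not (fit_p38.identifiable and fit_nfkb.identifiable):
        raise ValueError("halfA_conc unidentifiable in at least one fit")
    return fit_p38.halfA_conc / fit_nfkb.halfA_conc
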