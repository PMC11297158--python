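"""Branched p38 / NFkB pathway ODE model and synthetic-population generator.

The model couples two kinase branches that converge on p38 to a reduced
IkB--NFkB negative-feedback module, all driven by shared receptor-proximal
input curves:

* **IKK/Tpl2 -> MKK3/6 branch.**  IKK activity degrades the Tpl2 inhibitor
  p105 and activates Tpl2, which drives two-step (mono-, then di-)
  phosphorylation of MKK6 via Hill kinetics.
* **TAK1 -> MKK4 branch.**  TAK1 activity drives two-step phosphorylation of
  MKK4 with its own kinetic parameters (slower by default, extending p38
  activity to later times).
* **p38.**  Doubly phosphorylated MKK6 and MKK4 each catalyze two-step
  phosphorylation of p38; pp-p38 is the reported p38 activity.
* **IkB--NFkB module.**  IKK degrades IkB in the cytoplasmic NFkB:IkB
  complex, freeing NFkB to enter the nucleus where it induces IkB mRNA;
  newly translated IkB re-captures nuclear and cytoplasmic NFkB, closing the
  negative feedback.  Nuclear NFkB is the reported NFkB activity.

Receptor-level biochemistry is abstracted into stimulus-specific parametric
IKK and TAK1 activity curves (difference of exponentials, with an optional
delayed second phase for the TRIF arm of LPS signaling).

Cell-to-cell heterogeneity is generated by sampling ten parameters (three
kinase totals, the receptor-curve amplitude, and six NFkB-module
parameters) from lognormal distributions whose median is the representative
cell and whose shape places 99% of the mass within twofold of the median.
"Denoising" a module replaces its sampled parameters by the representative
values, localizing the source of heterogeneity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .trajectories import ActivityTrajectory, default_grid

__all__ = [
    "StimulusProgram", "PathwayParameters", "PopulationSpec", "CellSimulation",
    "FitResult", "FitError", "SIGMA_TWOFOLD_99", "DISTRIBUTED_PARAMS",
    "MODULE_PARAMS", "stimulus_program", "simulate_cell", "sample_parameters",
    "simulate_population", "fit_representative", "mass_conservation_error",
]

#: lognormal shape placing exactly 99% of mass within twofold of the median:
#: sigma = ln(2) / PhiInverse(0.995)
SIGMA_TWOFOLD_99 = math.log(2.0) / 2.5758293035489004

STIMULI = ("P3C4", "CpG", "LPS", "TNF", "mock")

SPECIES = (
    "p105", "tpl2a",
    "mkk6", "mkk6_p", "mkk6_pp",
    "mkk4", "mkk4_p", "mkk4_pp",
    "p38", "p38_p", "p38_pp",
    "nfkb_ikb", "nfkb_c", "nfkb_n", "ikb", "ikb_mrna",
)
_IX = {name: i for i, name in enumerate(SPECIES)}


# ---------------------------------------------------------------------------
# stimulus input curves
# ---------------------------------------------------------------------------

def _pulse(t: np.ndarray | float, amplitude: float, tau_rise: float,
           tau_decay: float) -> np.ndarray | float:
    """Difference-of-exponentials pulse normalized to peak ``amplitude``."""
    if amplitude == 0.0:
        return 0.0 * np.asarray(t, float)
    a, b = float(tau_decay), float(tau_rise)
    if a <= b:
        a = b * 1.0001  # degenerate: near-alpha-function
    t = np.asarray(t, float)
    t_peak = a * b / (a - b) * math.log(a / b)
    peak = math.exp(-t_peak / a) - math.exp(-t_peak / b)
    g = np.exp(-np.clip(t, 0, None) / a) - np.exp(-np.clip(t, 0, None) / b)
    g = np.where(t < 0, 0.0, g)
    return amplitude * g / peak


@dataclass
class InputCurve:
    """One receptor-proximal activity curve (IKK or TAK1), in [0, 1]."""
    amplitude: float = 0.0
    tau_rise: float = 5.0       # min
    tau_decay: float = 40.0     # min
    amplitude2: float = 0.0     # delayed second phase (TRIF-like)
    delay2: float = 60.0        # min
    tau_rise2: float = 20.0
    tau_decay2: float = 120.0

    def __call__(self, t):
        y = _pulse(t, self.amplitude, self.tau_rise, self.tau_decay)
        if self.amplitude2 > 0:
            y = y + _pulse(np.asarray(t, float) - self.delay2, self.amplitude2,
                           self.tau_rise2, self.tau_decay2)
        return np.clip(y, 0.0, 1.0)


@dataclass
class StimulusProgram:
    """Stimulus identity, dose, and the IKK/TAK1 activity curves it drives."""
    stimulus: str
    dose: float
    ikk_curve: InputCurve = field(default_factory=InputCurve)
    tak1_curve: InputCurve = field(default_factory=InputCurve)

    def __post_init__(self):
        if self.stimulus not in STIMULI:
            raise ValueError(f"unknown stimulus {self.stimulus!r}; expected one of {STIMULI}")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if self.stimulus == "mock" or self.dose == 0.0:
            self.stimulus, self.dose = "mock", 0.0
            self.ikk_curve = InputCurve(amplitude=0.0)
            self.tak1_curve = InputCurve(amplitude=0.0)


# Shapes calibrated so the four high-dose stimuli reproduce the observed
# stimulus-specific p38 dynamics: TNF fast/transient/low-amplitude, LPS
# high/sustained/biphasic (delayed TRIF phase, slow TAK1 branch), CpG slower
# and moderate, P3C4 high amplitude with moderate width.
_PROGRAM_SHAPES: dict[str, dict] = {
    "TNF": dict(ikk=InputCurve(0.9, 1.5, 12.0), tak1=InputCurve(0.45, 1.5, 10.0),
                half_dose=1.0, high_dose=100.0),
    "LPS": dict(ikk=InputCurve(0.75, 5.0, 45.0, amplitude2=0.35, delay2=60.0),
                tak1=InputCurve(0.95, 30.0, 170.0),
                half_dose=1.0, high_dose=100.0),
    "P3C4": dict(ikk=InputCurve(1.0, 4.0, 55.0), tak1=InputCurve(0.75, 10.0, 70.0),
                 half_dose=1.0, high_dose=100.0),
    "CpG": dict(ikk=InputCurve(0.5, 22.0, 90.0), tak1=InputCurve(0.45, 28.0, 110.0),
                half_dose=30.0, high_dose=1000.0),
}


def stimulus_program(stimulus: str, dose: float) -> StimulusProgram:
    """Build the default input program for a stimulus at a given dose.

    Curve amplitudes saturate with dose as ``dose / (dose + half_dose)``,
    normalized to 1 at the stimulus' reference high dose, so the shipped
    high-dose programs match the calibrated shapes exactly.
    """
    if stimulus == "mock" or dose == 0.0:
        return StimulusProgram("mock", 0.0)
    if stimulus not in _PROGRAM_SHAPES:
        raise ValueError(f"unknown stimulus {stimulus!r}; expected one of "
                         f"{sorted(_PROGRAM_SHAPES) + ['mock']}")
    shapes = _PROGRAM_SHAPES[stimulus]
    k = shapes["half_dose"]
    ref = shapes["high_dose"]
    scale = (dose / (dose + k)) / (ref / (ref + k))
    ikk = replace(shapes["ikk"])
    tak1 = replace(shapes["tak1"])
    ikk.amplitude = min(1.0, ikk.amplitude * scale)
    ikk.amplitude2 = min(1.0, ikk.amplitude2 * scale)
    tak1.amplitude = min(1.0, tak1.amplitude * scale)
    return StimulusProgram(stimulus, dose, ikk, tak1)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class PathwayParameters:
    """Rate constants and totals of the representative cell (uM, 1/min).

    Defaults are the package's calibration of the p38 module to the four
    stimulus-specific response shapes (``fit_representative`` refits them
    against user-supplied target trajectories).
    """
    # totals, uM
    p38_tot: float = 0.4
    MKK4_tot: float = 0.2
    MKK6_tot: float = 0.2
    NFkB_tot: float = 0.35
    # shared receptor input scale (per-cell heterogeneity hook)
    receptor_amplitude: float = 1.0
    # p105 / Tpl2
    k_p105_basal: float = 0.05    # p105 re-synthesis toward resting level
    k_p105_deg: float = 0.5       # IKK-driven p105 degradation rate scale
    k_tpl2_act: float = 0.4       # Tpl2 activation rate
    k_tpl2_inact: float = 0.15
    # MKK6 two-step phosphorylation by IKK/Tpl2
    v_mkk6: float = 0.22
    Km_mkk6: float = 0.3
    n_mkk6: float = 1.0
    kd_mkk6_p: float = 0.08
    kd_mkk6_pp: float = 0.08
    # MKK4 two-step phosphorylation by TAK1 (slower, sustained branch)
    v_mkk4: float = 0.1
    Km_mkk4: float = 0.3
    n_mkk4: float = 1.0
    kd_mkk4_p: float = 0.03
    kd_mkk4_pp: float = 0.03
    # p38 phosphorylation by MKK6-pp and MKK4-pp
    v_p38_6: float = 0.5
    Km_p38_6: float = 0.6
    n_p38_6: float = 1.0
    v_p38_4: float = 0.5
    Km_p38_4: float = 0.6
    n_p38_4: float = 1.0
    kd_p38_p: float = 0.2
    kd_p38_pp: float = 0.2
    # IkB--NFkB module
    k_c_deg: float = 0.05         # IKK-driven IkB degradation in the complex
    k_imp: float = 1.5            # NFkB nuclear import
    k_exp: float = 4.0            # IkB-mediated nuclear export, /uM/min
    k_ass: float = 8.0            # cytoplasmic NFkB:IkB association, /uM/min
    k_tx: float = 0.02            # NFkB-induced IkB mRNA synthesis, uM/min
    K_tx: float = 0.1
    n_tx: float = 2.0
    k_tl: float = 0.04            # IkB translation
    k_mdeg: float = 0.04          # IkB mRNA turnover
    k_ikb_deg_ikk: float = 0.2    # IKK-driven free-IkB degradation
    k_ikb_basal: float = 0.004

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if v <= 0:
                raise ValueError(f"parameter {f.name} must be > 0, got {v}")
        for n in ("n_mkk6", "n_mkk4", "n_p38_6", "n_p38_4", "n_tx"):
            h = getattr(self, n)
            if not (0.1 <= h <= 10.0):
                raise ValueError(f"Hill coefficient {n} must lie in [0.1, 10], got {h}")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def updated(self, **kwargs) -> "PathwayParameters":
        unknown = set(kwargs) - {f.name for f in fields(self)}
        if unknown:
            raise ValueError(f"unknown parameter(s) {sorted(unknown)}; "
                             f"valid names: {[f.name for f in fields(self)]}")
        return replace(self, **kwargs)


#: parameters distributed across cells, by module
MODULE_PARAMS = {
    "p38_module": ("p38_tot", "MKK4_tot", "MKK6_tot"),
    "receptor": ("receptor_amplitude",),
    "nfkb_module": ("NFkB_tot", "k_tx", "k_tl", "k_ikb_deg_ikk", "k_imp", "k_exp"),
}
DISTRIBUTED_PARAMS = tuple(p for ps in MODULE_PARAMS.values() for p in ps)


@dataclass
class PopulationSpec:
    """How to draw a heterogeneous cell population."""
    n_cells: int
    distributed_params: tuple = DISTRIBUTED_PARAMS
    sigma_log: float | dict = SIGMA_TWOFOLD_99
    denoise: frozenset = frozenset()   # subset of MODULE_PARAMS keys
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        self.denoise = frozenset(self.denoise)
        bad = self.denoise - set(MODULE_PARAMS)
        if bad:
            raise ValueError(f"unknown denoise flag(s) {sorted(bad)}")
        sigmas = (self.sigma_log.values() if isinstance(self.sigma_log, dict)
                  else [self.sigma_log])
        if any(s < 0 for s in sigmas):
            raise ValueError("sigma_log must be >= 0")

    def sigma_for(self, name: str) -> float:
        if isinstance(self.sigma_log, dict):
            return float(self.sigma_log.get(name, SIGMA_TWOFOLD_99))
        return float(self.sigma_log)


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

def _hill(s, km, n):
    sn = s ** n if s > 0 else 0.0
    return sn / (km ** n + sn)


def _rhs(t, y, p: PathwayParameters, ikk_fn, tak1_fn):
    (p105, tpl2a, mkk6, mkk6_p, mkk6_pp, mkk4, mkk4_p, mkk4_pp,
     p38, p38_p, p38_pp, c, nc, nn, ikb, mrna) = y

    scale = p.receptor_amplitude
    ikk = scale * float(ikk_fn(t))
    tak1 = scale * float(tak1_fn(t))

    # p105 / Tpl2 relay of IKK activity
    d_p105 = p.k_p105_basal * (1.0 - p105) - p.k_p105_deg * ikk * p105
    d_tpl2a = p.k_tpl2_act * ikk * p105 * (1.0 - tpl2a) - p.k_tpl2_inact * tpl2a

    # MKK6 branch (IKK/Tpl2)
    r6_1 = p.v_mkk6 * tpl2a * _hill(mkk6, p.Km_mkk6, p.n_mkk6)
    r6_2 = p.v_mkk6 * tpl2a * _hill(mkk6_p, p.Km_mkk6, p.n_mkk6)
    d_mkk6 = -r6_1 + p.kd_mkk6_p * mkk6_p
    d_mkk6_pp = r6_2 - p.kd_mkk6_pp * mkk6_pp
    d_mkk6_p = r6_1 - r6_2 - p.kd_mkk6_p * mkk6_p + p.kd_mkk6_pp * mkk6_pp

    # MKK4 branch (TAK1)
    r4_1 = p.v_mkk4 * tak1 * _hill(mkk4, p.Km_mkk4, p.n_mkk4)
    r4_2 = p.v_mkk4 * tak1 * _hill(mkk4_p, p.Km_mkk4, p.n_mkk4)
    d_mkk4 = -r4_1 + p.kd_mkk4_p * mkk4_p
    d_mkk4_pp = r4_2 - p.kd_mkk4_pp * mkk4_pp
    d_mkk4_p = r4_1 - r4_2 - p.kd_mkk4_p * mkk4_p + p.kd_mkk4_pp * mkk4_pp

    # p38 double phosphorylation by both branches
    kin1 = (p.v_p38_6 * mkk6_pp * _hill(p38, p.Km_p38_6, p.n_p38_6)
            + p.v_p38_4 * mkk4_pp * _hill(p38, p.Km_p38_4, p.n_p38_4))
    kin2 = (p.v_p38_6 * mkk6_pp * _hill(p38_p, p.Km_p38_6, p.n_p38_6)
            + p.v_p38_4 * mkk4_pp * _hill(p38_p, p.Km_p38_4, p.n_p38_4))
    d_p38 = -kin1 + p.kd_p38_p * p38_p
    d_p38_pp = kin2 - p.kd_p38_pp * p38_pp
    d_p38_p = kin1 - kin2 - p.kd_p38_p * p38_p + p.kd_p38_pp * p38_pp

    # IkB--NFkB negative feedback
    r_rel = p.k_c_deg * ikk * c                  # IKK degrades complexed IkB
    r_ass = p.k_ass * nc * ikb                   # cytoplasmic recapture
    r_exp = p.k_exp * nn * ikb                   # IkB-mediated nuclear export
    r_imp = p.k_imp * nc
    r_tx = p.k_tx * _hill(nn, p.K_tx, p.n_tx)
    d_c = r_ass + r_exp - r_rel
    d_nc = r_rel - r_imp - r_ass
    d_nn = r_imp - r_exp
    d_ikb = (p.k_tl * mrna - (p.k_ikb_deg_ikk * ikk + p.k_ikb_basal) * ikb
             - r_ass - r_exp)
    d_mrna = r_tx - p.k_mdeg * mrna

    return (d_p105, d_tpl2a, d_mkk6, d_mkk6_p, d_mkk6_pp,
            d_mkk4, d_mkk4_p, d_mkk4_pp, d_p38, d_p38_p, d_p38_pp,
            d_c, d_nc, d_nn, d_ikb, d_mrna)


def _resting_state(p: PathwayParameters) -> np.ndarray:
    y0 = np.zeros(len(SPECIES))
    y0[_IX["p105"]] = 1.0
    y0[_IX["mkk6"]] = p.MKK6_tot
    y0[_IX["mkk4"]] = p.MKK4_tot
    y0[_IX["p38"]] = p.p38_tot
    y0[_IX["nfkb_ikb"]] = p.NFkB_tot
    return y0


class EquilibrationError(RuntimeError):
    pass


class IntegrationError(RuntimeError):
    pass


_ZERO = lambda t: 0.0


def equilibrate(p: PathwayParameters, y0: np.ndarray | None = None,
                tol: float = 1e-9, t_max: float = 5000.0) -> np.ndarray:
    """Relax the unstimulated system to rest (max |dy/dt| < ``tol`` uM/min).

    Raises :class:`EquilibrationError` naming the worst species if the
    system does not settle within ``t_max`` minutes.
    """
    y = _resting_state(p) if y0 is None else np.asarray(y0, float)
    t = 0.0
    while True:
        dy = np.abs(_rhs(0.0, y, p, _ZERO, _ZERO))
        if dy.max() < tol:
            return y
        if t >= t_max:
            worst = SPECIES[int(np.argmax(dy))]
            raise EquilibrationError(
                f"no pre-stimulus equilibrium within {t_max:g} min: "
                f"|d[{worst}]/dt| = {dy.max():.3e} uM/min")
        chunk = min(1000.0, t_max - t)
        sol = solve_ivp(_rhs, (0.0, chunk), y, args=(p, _ZERO, _ZERO),
                        method="LSODA", rtol=1e-8, atol=1e-12)
        if not sol.success:
            raise EquilibrationError(f"equilibration integrator failed: {sol.message}")
        y = sol.y[:, -1]
        t += chunk


@dataclass
class CellSimulation:
    """Full output of one single-cell simulation."""
    trajectory: ActivityTrajectory
    time_min: np.ndarray
    states: dict          # species name -> series over the full grid
    params: PathwayParameters
    program: StimulusProgram


def simulate_cell(params: PathwayParameters, program: StimulusProgram,
                  grid: np.ndarray | None = None,
                  cell_id: str = "cell") -> CellSimulation:
    """Equilibrate, stimulate at t = 0, and report baseline-deducted
    pp-p38 and nuclear NFkB on the grid, plus the full state trace."""
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, float)
    y_eq = equilibrate(params)

    post = grid[grid >= 0]
    t_end = float(post[-1]) if post.size else 0.0
    sol = solve_ivp(_rhs, (0.0, t_end), y_eq,
                    args=(params, program.ikk_curve, program.tak1_curve),
                    method="LSODA", rtol=1e-6, atol=1e-9,
                    t_eval=post, max_step=5.0)
    if not sol.success:
        raise IntegrationError(
            f"integration failed at t = {sol.t[-1] if sol.t.size else 0:.1f} min: {sol.message}")

    n_base = int(np.sum(grid < 0))
    full = np.empty((len(SPECIES), grid.size))
    full[:, :n_base] = y_eq[:, None]
    full[:, n_base:] = sol.y
    states = {name: full[i] for i, name in enumerate(SPECIES)}

    p38_act = states["p38_pp"] - y_eq[_IX["p38_pp"]]
    nfkb_act = states["nfkb_n"] - y_eq[_IX["nfkb_n"]]
    traj = ActivityTrajectory(cell_id=cell_id, stimulus=program.stimulus,
                              dose=program.dose, time_min=grid,
                              p38=p38_act, nfkb=nfkb_act, units="model_uM")
    return CellSimulation(traj, grid, states, params, program)


def mass_conservation_error(sim: CellSimulation) -> float:
    """Largest relative drift of any conserved kinase family or total NFkB."""
    s, p = sim.states, sim.params
    errs = [
        np.abs(s["mkk6"] + s["mkk6_p"] + s["mkk6_pp"] - p.MKK6_tot) / p.MKK6_tot,
        np.abs(s["mkk4"] + s["mkk4_p"] + s["mkk4_pp"] - p.MKK4_tot) / p.MKK4_tot,
        np.abs(s["p38"] + s["p38_p"] + s["p38_pp"] - p.p38_tot) / p.p38_tot,
        np.abs(s["nfkb_ikb"] + s["nfkb_c"] + s["nfkb_n"] - p.NFkB_tot) / p.NFkB_tot,
    ]
    return float(max(e.max() for e in errs))


# ---------------------------------------------------------------------------
# heterogeneous populations
# ---------------------------------------------------------------------------

def sample_parameters(spec: PopulationSpec,
                      representative: PathwayParameters) -> pd.DataFrame:
    """Draw the per-cell parameter table (n_cells x distributed names).

    Each distributed parameter is lognormal with median equal to the
    representative value; parameters of denoised modules are held constant.
    """
    valid = {f.name for f in fields(representative)}
    unknown = set(spec.distributed_params) - valid
    if unknown:
        raise ValueError(f"unknown parameter name(s) {sorted(unknown)}; "
                         f"valid names: {sorted(valid)}")
    denoised = {name for mod in spec.denoise for name in MODULE_PARAMS[mod]}
    rng = np.random.default_rng(spec.seed)
    cols = {}
    for name in spec.distributed_params:
        rep = getattr(representative, name)
        # draw in a fixed order so denoising one module does not shift the
        # random stream of the others
        z = rng.standard_normal(spec.n_cells)
        if name in denoised:
            cols[name] = np.full(spec.n_cells, rep)
        else:
            cols[name] = rep * np.exp(spec.sigma_for(name) * z)
    return pd.DataFrame(cols)


def simulate_population(spec: PopulationSpec, program: StimulusProgram,
                        representative: PathwayParameters,
                        grid: np.ndarray | None = None) -> list[ActivityTrajectory]:
    """One paired p38/NFkB trajectory per sampled cell."""
    table = sample_parameters(spec, representative)
    out = []
    for i in range(spec.n_cells):
        cell_params = representative.updated(**{k: float(table[k].iloc[i]) for k in table})
        try:
            sim = simulate_cell(cell_params, program, grid, cell_id=f"cell_{i:04d}")
        except (EquilibrationError, IntegrationError) as exc:
            raise type(exc)(f"cell {i}: {exc}") from exc
        out.append(sim.trajectory)
    return out


# ---------------------------------------------------------------------------
# representative-cell fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    params: PathwayParameters
    objective: float
    n_evals: int
    message: str


class FitError(RuntimeError):
    def __init__(self, message, params=None, objective=None):
        super().__init__(message)
        self.params = params
        self.objective = objective


def fit_representative(initial: PathwayParameters,
                       targets: dict[str, ActivityTrajectory],
                       free_params: tuple = ("p38_tot", "MKK4_tot", "MKK6_tot"),
                       bounds_decades: float = 1.0,
                       max_nfev: int = 120) -> FitResult:
    """Refit selected parameters against stimulus-labeled pp-p38 targets.

    Minimizes the summed squared error between simulated and target p38
    activity (model units) across all supplied stimuli.  Optimization runs
    in log10 parameter space within ``bounds_decades`` of the initial point.
    """
    from scipy.optimize import least_squares

    if not targets:
        raise ValueError("need at least one target trajectory")
    if all(np.max(np.abs(t.p38)) == 0 for t in targets.values()):
        raise ValueError("degenerate fit: all target p38 traces are zero")
    for t in targets.values():
        if t.units != "model_uM":
            raise ValueError("targets must be in model units (apply rescale_units)")

    programs = {s: stimulus_program(t.stimulus, t.dose) for s, t in targets.items()}
    x0 = np.log10([getattr(initial, n) for n in free_params])

    def residuals(x):
        p = initial.updated(**{n: 10.0 ** v for n, v in zip(free_params, x)})
        res = []
        for key, target in targets.items():
            sim = simulate_cell(p, programs[key], target.time_min)
            res.append(sim.trajectory.p38 - target.p38)
        return np.concatenate(res)

    sol = least_squares(residuals, x0, bounds=(x0 - bounds_decades, x0 + bounds_decades),
                        xtol=1e-10, ftol=1e-10, gtol=1e-10,
                        diff_step=1e-4, max_nfev=max_nfev)
    fitted = initial.updated(**{n: 10.0 ** v for n, v in zip(free_params, sol.x)})
    objective = float(np.sum(sol.fun ** 2))
    if sol.status <= 0:
        raise FitError(f"optimizer did not converge: {sol.message}",
                       params=fitted, objective=objective)
    return FitResult(params=fitted, objective=objective,
                     n_evals=int(sol.nfev), message=sol.message)
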