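"""Paired single-cell activity trajectories.

The central in-memory object of the pipeline is :class:`ActivityTrajectory`:
one cell's p38 and NFkB activity series on a shared, uniformly spaced time
grid (minutes), with a labeled pre-stimulus baseline window at negative
times.  Activities are either baseline-deducted arbitrary units (microscopy
scale) or micromolar concentrations (model scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: frame interval of the live-cell acquisition, minutes
FRAME_MIN = 5.0

#: arbitrary-unit -> micromolar factors (p38: 0.08 uM / 0.73 A.U.;
#: NFkB: nuclear concentration calibration)
DEFAULT_RESCALE_FACTORS = {"p38": 0.1096, "nfkb": 0.0383}


def default_grid(n_baseline: int = 6, n_post: int = 97,
                 frame_min: float = FRAME_MIN) -> np.ndarray:
    """Uniform time grid: ``n_baseline`` frames before stimulus (negative
    times) and ``n_post`` frames from t = 0 on, at ``frame_min`` spacing.
    The default covers a 30-min baseline window and 0-480 min (8 h) of
    post-stimulus acquisition."""
    if n_baseline < 0 or n_post < 1:
        raise ValueError("need n_baseline >= 0 and n_post >= 1")
    return frame_min * np.arange(-n_baseline, n_post, dtype=float)


@dataclass
class ActivityTrajectory:
    """Paired p38/NFkB activity of one cell on a uniform time grid."""

    cell_id: str
    stimulus: str
    dose: float
    time_min: np.ndarray
    p38: np.ndarray
    nfkb: np.ndarray
    units: str = "AU"  # "AU" or "model_uM"
    replicate: int = 1

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.p38 = np.asarray(self.p38, dtype=float)
        self.nfkb = np.asarray(self.nfkb, dtype=float)
        n = self.time_min.size
        if self.p38.size != n or self.nfkb.size != n:
            raise ValueError("activity series must match the time grid length")
        if n >= 2:
            dt = np.diff(self.time_min)
            if not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
                raise ValueError("time grid must be uniformly spaced")
        if self.units not in ("AU", "model_uM"):
            raise ValueError(f"unknown units flag {self.units!r}")

    # -- masks -----------------------------------------------------------
    @property
    def baseline_mask(self) -> np.ndarray:
        return self.time_min < 0

    @property
    def post_mask(self) -> np.ndarray:
        return self.time_min >= 0

    @property
    def frame_min(self) -> float:
        return float(self.time_min[1] - self.time_min[0])

    def channel(self, pathway: str) -> np.ndarray:
        if pathway == "p38":
            return self.p38
        if pathway == "nfkb":
            return self.nfkb
        raise ValueError(f"unknown pathway {pathway!r} (expected 'p38' or 'nfkb')")

    def with_channels(self, p38: np.ndarray, nfkb: np.ndarray) -> "ActivityTrajectory":
        return replace(self, p38=np.asarray(p38, float), nfkb=np.asarray(nfkb, float))


def rescale_units(traj: ActivityTrajectory, direction: str,
                  factors: dict | None = None) -> ActivityTrajectory:
    """Convert a trajectory between microscopy (A.U.) and model (uM) scales.

    ``direction`` is ``"AU->model"`` or ``"model->AU"``.  Each channel is
    multiplied (or divided) by its calibration factor; the round trip is an
    identity to floating-point precision.
    """
    factors = dict(DEFAULT_RESCALE_FACTORS if factors is None else factors)
    for name, f in factors.items():
        if f <= 0:
            raise ValueError(f"rescale factor for {name!r} must be positive, got {f}")
    if direction == "AU->model":
        if traj.units != "AU":
            raise ValueError("trajectory is not in A.U.")
        out = traj.with_channels(traj.p38 * factors["p38"], traj.nfkb * factors["nfkb"])
        out.units = "model_uM"
    elif direction == "model->AU":
        if traj.units != "model_uM":
            raise ValueError("trajectory is not in model units")
        out = traj.with_channels(traj.p38 / factors["p38"], traj.nfkb / factors["nfkb"])
        out.units = "AU"
    else:
        raise ValueError("direction must be 'AU->model' or 'model->AU'")
    return out


def make_toy_trajectory(shape: str, amplitude: float = 1.0, t_peak: float = 60.0,
                        width: float = 120.0, period: float = 90.0,
                        noise_sd: float = 0.0, seed: int = 0,
                        grid: np.ndarray | None = None,
                        channel: str = "both",
                        cell_id: str = "toy") -> ActivityTrajectory:
    """Parametric pulse fixture with analytically known dynamic features.

    Shapes: ``flat`` (identically ``amplitude``, zero for amplitude 0),
    ``step`` (0 before ``t_peak``, ``amplitude`` for ``width`` minutes),
    ``triangle`` (linear rise to ``amplitude`` at ``t_peak``, symmetric fall,
    base ``width``), ``damped_oscillation``
    (``amplitude * exp(-t/(3*period)) * sin^2(pi t / period)``, period of the
    squared sine envelope equal to ``period``).
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, float)
    t = np.clip(grid, 0.0, None)
    span = grid[-1]
    if shape in ("triangle", "step") and t_peak + (width if shape == "step" else width / 2) > span:
        raise ValueError("pulse extends beyond the time grid")
    if shape == "damped_oscillation" and period > span:
        raise ValueError("oscillation period exceeds the grid span")

    if shape == "flat":
        y = np.full_like(t, float(amplitude))
        y[grid < 0] = 0.0
    elif shape == "step":
        y = np.where((grid >= t_peak) & (grid < t_peak + width), float(amplitude), 0.0)
    elif shape == "triangle":
        half = width / 2.0
        y = amplitude * np.clip(1.0 - np.abs(grid - t_peak) / half, 0.0, None)
    elif shape == "damped_oscillation":
        y = amplitude * np.exp(-t / (3.0 * period)) * np.sin(np.pi * t / period) ** 2
        y[grid < 0] = 0.0
    else:
        raise ValueError(f"unknown toy shape {shape!r}")

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.size)

    zeros = np.zeros_like(y)
    p38 = y if channel in ("p38", "both") else zeros
    nfkb = y if channel in ("nfkb", "both") else zeros
    return ActivityTrajectory(cell_id=cell_id, stimulus="toy", dose=0.0,
                              time_min=grid, p38=p38, nfkb=nfkb, units="AU")
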