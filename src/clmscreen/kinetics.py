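"""Deterministic kinetics of the coupled ketone-reduction / alcohol-oxidation system.

The model is the three-species closed system

    ketone K  --k_red_R-->  (R)-alcohol R
    ketone K  --k_red_S-->  (S)-alcohol S
    R  --phi * k_ox_R-->  K        (usually k_ox_R = 0)
    S  --phi * k_ox_S-->  K

with all steps first order and ``phi`` an oxygen-availability factor in
[0, 1] multiplying the oxidation rates (``phi = 0`` is strict anaerobiosis,
under which an oxidase-driven oxidation is silent).  Amounts are normalized
fractions of the initial material, so ``K + R + S = 1`` along every
trajectory.

Two parallel reduction channels (to (R)- and to (S)-alcohol) cover both a
single poorly selective dehydrogenase and two dehydrogenases of opposite
enantiotoposelectivity — the observable kinetics are identical.

The system is linear with constant coefficients, so trajectories are computed
exactly via the matrix exponential; the generator's columns sum to zero, so
mass conservation holds to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import least_squares

__all__ = [
    "KineticState",
    "RedoxParams",
    "Trajectory",
    "TrajectoryObservation",
    "RedoxFit",
    "rate_matrix",
    "simulate_redox",
    "anaerobic_alcohol_ee",
    "oxygen_factor_from_biomass",
    "fit_redox_params",
]

_MASS_TOL = 1e-6


@dataclass(frozen=True)
class KineticState:
    """Normalized amounts (ketone, (R)-alcohol, (S)-alcohol) at time ``t``."""

    K: float
    R: float
    S: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if min(self.K, self.R, self.S) < -_MASS_TOL:
            raise ValueError(f"negative amount in state {self}")
        total = self.K + self.R + self.S
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"state not normalized: K+R+S = {total}")

    def as_array(self) -> np.ndarray:
        return np.array([self.K, self.R, self.S], dtype=float)


@dataclass(frozen=True)
class RedoxParams:
    """First-order rate constants (h^-1) and the oxygen factor phi.

    ``oxygen_factor = 0`` reproduces anaerobic conditions exactly; 1 is fully
    aerobic.  ``k_ox_R`` defaults to 0 (strictly S-selective oxidation).
    """

    k_red_R: float = 0.0
    k_red_S: float = 0.0
    k_ox_S: float = 0.0
    k_ox_R: float = 0.0
    oxygen_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_red_R", "k_red_S", "k_ox_S", "k_ox_R"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.oxygen_factor <= 1.0:
            raise ValueError(
                f"oxygen_factor must be in [0, 1], got {self.oxygen_factor}"
            )


def rate_matrix(p: RedoxParams) -> np.ndarray:
    """Generator A of the linear system d/dt (K, R, S) = A @ (K, R, S)."""
    phi = p.oxygen_factor
    return np.array(
        [
            [-(p.k_red_R + p.k_red_S), phi * p.k_ox_R, phi * p.k_ox_S],
            [p.k_red_R, -phi * p.k_ox_R, 0.0],
            [p.k_red_S, 0.0, -phi * p.k_ox_S],
        ]
    )


@dataclass(frozen=True)
class Trajectory:
    """Solution of the redox system sampled at ``times`` (hours)."""

    times: np.ndarray
    y: np.ndarray  # shape (len(times), 3): columns K, R, S

    @property
    def K(self) -> np.ndarray:
        return self.y[:, 0]

    @property
    def R(self) -> np.ndarray:
        return self.y[:, 1]

    @property
    def S(self) -> np.ndarray:
        return self.y[:, 2]

    def alcohol_ee(self) -> np.ndarray:
        """Signed ee of the alcohol pool, nan where no alcohol is present."""
        total = self.R + self.S
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, (self.R - self.S) / total, np.nan)

    def states(self) -> list[KineticState]:
        return [
            KineticState(K=k, R=r, S=s, t=t)
            for t, (k, r, s) in zip(self.times, self.y)
        ]


def simulate_redox(
    p: RedoxParams, y0: KineticState, times: Sequence[float]
) -> Trajectory:
    """Exact trajectory of the redox system from ``y0`` at the given times.

    ``times`` must be sorted and non-negative.  The matrix exponential of the
    (constant) generator is used, so the result is exact up to floating-point
    rounding and conserves ``K + R + S`` by construction.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted")
    if t[0] < 0:
        raise ValueError("times must be >= 0")
    A = rate_matrix(p)
    v0 = y0.as_array()
    y = np.empty((t.size, 3))
    for i, ti in enumerate(t):
        y[i] = expm(A * ti) @ v0
    np.clip(y, 0.0, None, out=y)
    return Trajectory(times=t, y=y)


def anaerobic_alcohol_ee(p: RedoxParams) -> float:
    """Alcohol ee fixed by the reduction-rate ratio, ``(kR - kS)/(kR + kS)``.

    Without oxidation (phi = 0) the two alcohols accumulate in constant
    proportion to their formation rates, so a trajectory started from pure
    ketone shows this ee at *every* time point.  This is why anaerobic
    incubations report a concentration-independent, modest ee: it is the
    intrinsic selectivity of the reduction step alone.
    """
    total = p.k_red_R + p.k_red_S
    if total <= 0:
        raise ValueError("anaerobic ee undefined: both reduction rates are zero")
    return (p.k_red_R - p.k_red_S) / total


def oxygen_factor_from_biomass(biomass: float, half_saturation: float) -> float:
    """Oxygen availability factor ``h / (h + biomass)``, in (0, 1].

    Models the competition between respiration and the oxidase for dissolved
    oxygen: dense cell suspensions (biomass in g wet weight / L) consume
    oxygen for maintenance, starving the oxidation.  Hyperbolic in biomass,
    equal to 1 at zero biomass and to 0.5 at ``biomass == half_saturation``;
    strictly decreasing.  The functional form is a modelling choice — only
    the direction of the effect is constrained by observation.
    """
    if biomass < 0:
        raise ValueError(f"biomass must be >= 0, got {biomass}")
    if half_saturation <= 0:
        raise ValueError(f"half_saturation must be > 0, got {half_saturation}")
    return half_saturation / (half_saturation + biomass)


@dataclass(frozen=True)
class TrajectoryObservation:
    """One observed time course under a fixed, known oxygen factor.

    ``y`` has shape (n_times, 3) with columns K, R, S (noisy, normalized).
    ``y0`` is the known initial state; if None, the first row of ``y`` is
    used as-is.
    """

    times: np.ndarray
    y: np.ndarray
    oxygen_factor: float
    y0: KineticState | None = None


@dataclass(frozen=True)
class RedoxFit:
    params: RedoxParams
    residual_norm: float
    k_ox_identifiable: bool
    jacobian_rank: int
    n_observations: int
    message: str = ""


def fit_redox_params(
    observations: Sequence[TrajectoryObservation],
    initial_guess: RedoxParams | None = None,
) -> RedoxFit:
    """Least-squares recovery of the four rate constants from time courses.

    Each observation is simulated with its own (fixed, known) oxygen factor
    and the concatenated residuals over all species and time points are
    minimized with ``scipy.optimize.least_squares`` under non-negativity
    bounds.  Full identifiability of the oxidation rates needs at least one
    observation with ``oxygen_factor > 0``; with anaerobic data only, the fit
    proceeds but ``k_ox_identifiable`` is False and the oxidation rates are
    meaningless.  ``jacobian_rank`` (numerical rank of the residual Jacobian
    at the solution) below 4 signals a flat direction in parameter space.
    """
    if not observations:
        raise ValueError("no observations")
    total_pts = sum(len(o.times) for o in observations)
    informative = sum(int(np.count_nonzero(np.asarray(o.times) > 0)) for o in observations)
    if informative == 0:
        raise ValueError("degenerate input: all observations at t = 0")
    if total_pts < 4:
        raise ValueError(f"need >= 4 observations for 4 rates, got {total_pts}")

    # reference state and time: a known y0 anchors at t = 0; otherwise the
    # first observed row anchors at its own sampling time
    y0s: list[tuple[np.ndarray, float]] = []
    for o in observations:
        if o.y0 is not None:
            y0s.append((o.y0.as_array(), 0.0))
        else:
            v = np.asarray(o.y[0], dtype=float)
            y0s.append((v / v.sum(), float(o.times[0])))

    def residuals(x: np.ndarray) -> np.ndarray:
        res = []
        for o, (v0, t_ref) in zip(observations, y0s):
            A = np.array(
                [
                    [-(x[0] + x[1]), o.oxygen_factor * x[3], o.oxygen_factor * x[2]],
                    [x[0], -o.oxygen_factor * x[3], 0.0],
                    [x[1], 0.0, -o.oxygen_factor * x[2]],
                ]
            )
            for ti, yi in zip(o.times, o.y):
                res.append(expm(A * (float(ti) - t_ref)) @ v0 - yi)
        return np.concatenate(res)

    g = initial_guess or RedoxParams(0.1, 0.1, 0.1, 0.01)
    x0 = np.array([g.k_red_R, g.k_red_S, g.k_ox_S, g.k_ox_R])
    sol = least_squares(residuals, x0, bounds=(0.0, np.inf), xtol=1e-12, ftol=1e-12)

    sv = np.linalg.svd(sol.jac, compute_uv=False)
    rank = int(np.sum(sv > sv[0] * 1e-7)) if sv.size else 0
    any_aerobic = any(o.oxygen_factor > 0 for o in observations)
    params = RedoxParams(
        k_red_R=float(sol.x[0]),
        k_red_S=float(sol.x[1]),
        k_ox_S=float(sol.x[2]),
        k_ox_R=float(sol.x[3]),
    )
    return RedoxFit(
        params=params,
        residual_norm=float(np.linalg.norm(sol.fun)),
        k_ox_identifiable=bool(any_aerobic and rank >= 4),
        jacobian_rank=rank,
        n_observations=total_pts,
        message=sol.message,
    )
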