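"""Synthetic strain libraries and pooled-incubation simulation.

This module generates everything the downstream stages consume: per-strain
kinetic profiles (reduction of a ketone to each alcohol enantiomer, selective
oxidation of the (S)-alcohol, oxygen dependence), and tidy assay readout
tables for pooled batches and single-strain controls sampled at a few time
points, with multiplicative measurement noise.

Pooling model: strains in a batch act as parallel first-order catalysts, so
the batch's effective rate for each step is the *sum* of its members' rates
(each strain contributes its own cells at full density; resuspension volumes
scale with the number of batches a strain joins).

One deliberate departure from time-invariant kinetics: a strain's reduction
rates may decay exponentially (``reduction_decay``, h^-1), emulating resting
cells exhausting their pool of reducing equivalents.  With constant rates the
alcohol fraction of a closed ketone-start system is provably monotone
non-decreasing, so the experimentally familiar pattern — high alcohol early,
much less later because an oxygen-driven oxidase keeps running after the
reductions stall — requires exactly this kind of non-stationarity.  With all
decays zero the dynamics reduce to the constant-coefficient model of
:mod:`clmscreen.kinetics` and are integrated exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .design import PoolDesign, build_design
from .kinetics import KineticState, RedoxParams, simulate_redox

__all__ = [
    "SubstrateKinetics",
    "StrainProfile",
    "ProfilePriors",
    "StudyFixture",
    "MixtureChannel",
    "READOUT_COLUMNS",
    "generate_strain_profiles",
    "simulate_assay",
    "make_study_fixture",
    "simulate_study",
]

READOUT_COLUMNS = (
    "batch_or_strain",
    "substrate",
    "time_h",
    "conversion",
    "alcohol_ee",
    "aeration",
    "mode",
)

#: Amount below which the alcohol pool is treated as absent and ee reported nan.
_EE_SENTINEL_THRESHOLD = 1e-9


@dataclass(frozen=True)
class SubstrateKinetics:
    """First-order rate constants (h^-1) of one strain toward one substrate."""

    k_red_R: float = 0.0
    k_red_S: float = 0.0
    k_ox_S: float = 0.0
    k_ox_R: float = 0.0
    #: exponential decay rate of the reduction capacity (0 = stable activity)
    reduction_decay: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_red_R", "k_red_S", "k_ox_S", "k_ox_R", "reduction_decay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class StrainProfile:
    """Kinetic identity of one strain: per-substrate rates plus cell traits.

    ``oxygen_dependent_oxidation`` gates *all* this strain's oxidation rates:
    under anaerobic incubation they are exactly zero (oxidase activity needs
    molecular oxygen); dehydrogenase-type oxidation (flag False) runs under
    both aerations.  ``biomass`` is the cell density (g wet weight / L) of
    the strain's suspension.
    """

    strain_id: str
    substrates: Mapping[str, SubstrateKinetics] = field(default_factory=dict)
    oxygen_dependent_oxidation: bool = True
    biomass: float = 100.0

    def __post_init__(self) -> None:
        if self.biomass < 0:
            raise ValueError("biomass must be >= 0")

    def kinetics_for(self, substrate: str) -> SubstrateKinetics:
        return self.substrates.get(substrate, SubstrateKinetics())

    def is_inactive(self, tol: float = 1e-12) -> bool:
        return all(
            max(k.k_red_R, k.k_red_S, k.k_ox_S, k.k_ox_R) <= tol
            for k in self.substrates.values()
        )


@dataclass(frozen=True)
class ProfilePriors:
    """Sampling ranges for random strain libraries.

    Defaults describe a realistic screening library: most strains show no
    useful activity toward a given substrate, active reducers span an
    order of magnitude in rate, a minority of strains carry an
    (S)-selective oxidase, usually oxygen dependent.
    """

    k_red_range: tuple[float, float] = (0.02, 0.5)
    k_ox_range: tuple[float, float] = (0.1, 0.6)
    p_inactive: float = 0.6
    p_oxidizer: float = 0.1
    p_oxygen_dependent: float = 0.9
    biomass_range: tuple[float, float] = (50.0, 150.0)

    def __post_init__(self) -> None:
        for name in ("k_red_range", "k_ox_range", "biomass_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid range {name}={lo, hi}")
        for name in ("p_inactive", "p_oxidizer", "p_oxygen_dependent"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")


def generate_strain_profiles(
    n: int,
    priors: ProfilePriors | None = None,
    seed: int | None = None,
    substrates: Sequence[str] = ("ketone",),
    strain_ids: Sequence[str] | None = None,
) -> list[StrainProfile]:
    """Draw ``n`` random strain profiles, reproducibly under ``seed``.

    For each strain x substrate pair, the strain is inactive with probability
    ``p_inactive``; otherwise a total reduction rate is drawn log-uniformly
    from ``k_red_range`` and split between the (R) and (S) channels by a
    uniformly random enantioselectivity.  With probability ``p_oxidizer`` the
    strain additionally carries an (S)-selective oxidase.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    priors = priors or ProfilePriors()
    rng = np.random.default_rng(seed)
    ids = list(strain_ids) if strain_ids is not None else [f"s{i+1:02d}" for i in range(n)]
    if len(ids) != n:
        raise ValueError("strain_ids length must equal n")

    profiles = []
    for sid in ids:
        per_substrate: dict[str, SubstrateKinetics] = {}
        oxygen_dep = bool(rng.random() < priors.p_oxygen_dependent)
        for sub in substrates:
            kin = SubstrateKinetics()
            if rng.random() >= priors.p_inactive:
                lo, hi = priors.k_red_range
                if hi > 0:
                    lo_ = max(lo, 1e-6 * hi)
                    k_tot = float(np.exp(rng.uniform(np.log(lo_), np.log(hi))))
                else:
                    k_tot = 0.0
                ee = float(rng.uniform(-1.0, 1.0))  # intrinsic reduction ee
                kin = replace(
                    kin,
                    k_red_R=k_tot * (1.0 + ee) / 2.0,
                    k_red_S=k_tot * (1.0 - ee) / 2.0,
                )
            if rng.random() < priors.p_oxidizer:
                kin = replace(kin, k_ox_S=float(rng.uniform(*priors.k_ox_range)))
            per_substrate[sub] = kin
        profiles.append(
            StrainProfile(
                strain_id=sid,
                substrates=per_substrate,
                oxygen_dependent_oxidation=oxygen_dep,
                biomass=float(rng.uniform(*priors.biomass_range)),
            )
        )
    return profiles


def _pooled_terms(
    members: Sequence[StrainProfile],
    substrate: str,
    aeration: str,
    inhibition_factor: float,
) -> tuple[list[tuple[float, float, float]], float, float]:
    """Per-member reduction terms and summed effective oxidation rates."""
    if aeration not in ("aerobic", "anaerobic"):
        raise ValueError(f"aeration must be 'aerobic' or 'anaerobic', got {aeration!r}")
    red_terms = []  # (k_red_R, k_red_S, decay)
    k_ox_S = k_ox_R = 0.0
    for m in members:
        kin = m.kinetics_for(substrate)
        red_terms.append(
            (
                kin.k_red_R * inhibition_factor,
                kin.k_red_S * inhibition_factor,
                kin.reduction_decay,
            )
        )
        gate = 0.0 if (aeration == "anaerobic" and m.oxygen_dependent_oxidation) else 1.0
        k_ox_S += gate * kin.k_ox_S
        k_ox_R += gate * kin.k_ox_R
    return red_terms, k_ox_S, k_ox_R


def _integrate_pool(
    red_terms: Sequence[tuple[float, float, float]],
    k_ox_S: float,
    k_ox_R: float,
    y0: np.ndarray,
    times: np.ndarray,
) -> np.ndarray:
    """Trajectory (len(times), 3) of the pooled system, exact when stationary."""
    if all(d == 0.0 for _, _, d in red_terms) or not red_terms:
        kR = sum(t[0] for t in red_terms)
        kS = sum(t[1] for t in red_terms)
        p = RedoxParams(k_red_R=kR, k_red_S=kS, k_ox_S=k_ox_S, k_ox_R=k_ox_R)
        total = y0.sum()
        state = KineticState(K=y0[0] / total, R=y0[1] / total, S=y0[2] / total)
        return simulate_redox(p, state, times).y * total

    terms = np.asarray(red_terms, dtype=float)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        w = np.exp(-terms[:, 2] * t)
        kR = float(terms[:, 0] @ w)
        kS = float(terms[:, 1] @ w)
        dK = -(kR + kS) * y[0] + k_ox_S * y[2] + k_ox_R * y[1]
        dR = kR * y[0] - k_ox_R * y[1]
        dS = kS * y[0] - k_ox_S * y[2]
        return np.array([dK, dR, dS])

    t_span = (0.0, float(times[-1]) if times[-1] > 0 else 1e-12)
    sol = solve_ivp(
        rhs, t_span, y0, t_eval=times, method="LSODA", rtol=1e-9, atol=1e-12
    )
    if not sol.success:  # pragma: no cover - LSODA on a smooth bounded system
        raise RuntimeError(f"integration failed: {sol.message}")
    return np.clip(sol.y.T, 0.0, None)


def simulate_assay(
    members: Sequence[StrainProfile],
    substrate: str,
    times: Sequence[float],
    aeration: str = "aerobic",
    noise_sd: float = 0.0,
    seed: int | None = None,
    y0: tuple[float, float, float] = (1.0, 0.0, 0.0),
    mode: str = "pooled",
    batch_or_strain: str | None = None,
    inhibition_factor: float = 1.0,
) -> pd.DataFrame:
    """Simulate one incubation (pooled batch or single-strain control).

    Parameters
    ----------
    members
        Strains present; an empty pool is valid and transforms nothing.
    substrate
        Label looked up in each member's kinetic table.
    times
        Sampling times in hours, sorted, >= 0.
    y0
        Initial ``(ketone, R-alcohol, S-alcohol)`` amounts; normalized
        internally.  A ketone start reports conversion as the fraction of
        ketone consumed; an alcohol start (ketone = 0) as the fraction of
        alcohol oxidized.
    noise_sd
        Multiplicative Gaussian noise applied to conversion
        (``c * (1 + eps)``), then clipped to [0, 1].  ee is reported
        noise-free, nan when the alcohol pool is empty.
    inhibition_factor
        Scales all reduction rates; models suppression of a reduction by a
        co-substrate (1.0 = no interaction).

    Returns a tidy readout table with columns :data:`READOUT_COLUMNS`.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0 or np.any(np.diff(t) < 0) or (t.size and t[0] < 0):
        raise ValueError("times must be non-empty, sorted and >= 0")
    v0 = np.asarray(y0, dtype=float)
    if v0.min() < 0 or v0.sum() <= 0:
        raise ValueError("initial amounts must be >= 0 with positive total")
    if not 0.0 <= inhibition_factor:
        raise ValueError("inhibition_factor must be >= 0")

    red_terms, k_ox_S, k_ox_R = _pooled_terms(
        members, substrate, aeration, inhibition_factor
    )
    total = v0.sum()
    traj = _integrate_pool(red_terms, k_ox_S, k_ox_R, v0 / total, t)

    K0 = v0[0] / total
    alcohol0 = (v0[1] + v0[2]) / total
    ketone_assay = K0 >= alcohol0
    if ketone_assay:
        conversion = (K0 - traj[:, 0]) / K0 if K0 > 0 else np.zeros_like(t)
    else:
        conversion = (traj[:, 0] - K0) / alcohol0
    conversion = np.clip(conversion, 0.0, 1.0)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        conversion = np.clip(
            conversion * (1.0 + rng.normal(0.0, noise_sd, size=conversion.shape)),
            0.0,
            1.0,
        )

    alcohol = traj[:, 1] + traj[:, 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        ee = np.where(
            alcohol > _EE_SENTINEL_THRESHOLD,
            (traj[:, 1] - traj[:, 2]) / alcohol,
            np.nan,
        )

    label = batch_or_strain or (
        members[0].strain_id if len(members) == 1 else "pool"
    )
    return pd.DataFrame(
        {
            "batch_or_strain": label,
            "substrate": substrate,
            "time_h": t,
            "conversion": conversion,
            "alcohol_ee": ee,
            "aeration": aeration,
            "mode": mode,
        }
    )


@dataclass(frozen=True)
class MixtureChannel:
    """One substrate mixture incubated with one library's batches."""

    name: str
    substrates: tuple[str, str]
    library: str  # "CLM-1" or "CLM-2"


@dataclass(frozen=True)
class StudyFixture:
    """Complete synthetic reconstruction of the two-library screening study.

    The incidence matrices are a *synthetic* reconstruction: the published
    batch-composition table is not reproduced in the source text, so the
    matrices here are built to satisfy every stated constraint (two 12-strain
    libraries in batches A-D and E-H, pool size 5, eight strains in two
    batches and four in one, and the signatures of all strains discussed by
    name: the fast aliphatic reducer exclusive to D, the two aromatic
    reducers sharing {A, D}, the suspected oxidizer exclusive to B, the fast
    3-octanone reducer exclusive to E, and the two acetophenone transformers
    sharing {E, F}, one of which is the oxygen-dependent (S)-oxidizer).
    """

    clm1: PoolDesign
    clm2: PoolDesign
    profiles: dict[str, StrainProfile]
    mixtures: tuple[MixtureChannel, ...]
    truth: dict[str, tuple[str, ...]]
    cross_inhibition: dict[tuple[str, str], float]
    batch_b_mechanism: str

    @property
    def substrates(self) -> tuple[str, ...]:
        seen: list[str] = []
        for m in self.mixtures:
            for s in m.substrates:
                if s not in seen:
                    seen.append(s)
        return tuple(seen)

    def design_for(self, channel: MixtureChannel) -> PoolDesign:
        return self.clm1 if channel.library == "CLM-1" else self.clm2


# Incidence of the two 12-strain libraries (rows = strains, cols = batches).
# Synthetic reconstruction; see StudyFixture docstring.
_CLM1_ROWS: dict[str, tuple[int, int, int, int]] = {  # columns A, B, C, D
    "s01": (0, 0, 0, 1),  # fast aliphatic reducer, exclusive to D
    "s02": (1, 0, 0, 1),  # aromatic reducer, signature {A, D}
    "s03": (1, 0, 0, 1),  # aromatic reducer, signature {A, D}
    "s04": (0, 1, 0, 0),  # suspected oxidizer/inhibitor, exclusive to B
    "s05": (1, 1, 0, 0),
    "s06": (1, 0, 1, 0),
    "s07": (0, 1, 1, 0),
    "s08": (0, 1, 0, 1),
    "s09": (0, 0, 1, 1),
    "s10": (1, 0, 1, 0),
    "s11": (0, 1, 0, 0),  # competent 3-octanone reducer in B
    "s12": (0, 0, 1, 0),
}
_CLM2_ROWS: dict[str, tuple[int, int, int, int]] = {  # columns E, F, G, H
    "s13": (1, 0, 0, 0),  # very fast 3-octanone reducer, exclusive to E
    "s14": (1, 1, 0, 0),  # acetophenone reducer, signature {E, F}
    "s15": (1, 1, 0, 0),  # oxygen-dependent (S)-oxidizer + reducer, {E, F}
    "s16": (1, 0, 1, 0),
    "s17": (1, 0, 0, 1),
    "s18": (0, 1, 1, 0),
    "s19": (0, 1, 0, 1),
    "s20": (0, 1, 0, 0),
    "s21": (0, 0, 1, 1),
    "s22": (0, 0, 1, 0),
    "s23": (0, 0, 1, 1),
    "s24": (0, 0, 0, 1),
}


def _fixture_design(rows: dict[str, tuple[int, ...]], batch_ids: tuple[str, ...]) -> PoolDesign:
    M = np.array(list(rows.values()), dtype=int)
    return PoolDesign(
        n_strains=len(rows),
        n_batches=len(batch_ids),
        incidence=M,
        pool_size=int(M.sum(axis=0)[0]),
        strain_ids=tuple(rows),
        batch_ids=batch_ids,
    )


def make_study_fixture(batch_b_mechanism: str = "oxidation") -> StudyFixture:
    """The screening scenario: two 12-strain libraries, three ketone mixtures.

    Channels: CLM-1 (batches A-D) incubated with 2-octanone + acetonaphthone
    and with 3-octanone + propiophenone; CLM-2 (batches E-H) with 3-octanone
    + acetophenone.  Ground-truth activities (see ``truth``) reproduce the
    decoding situations of interest: a unique hit set {D}, a two-candidate
    hit set {A, D}, a fast 4 h hit in E, the tandem reduction/oxidation
    anomaly in E and F, and a suppressed reduction in batch B.

    ``batch_b_mechanism`` selects between the two rival explanations of the
    weak batch-B aromatic chemistry — ``"oxidation"`` (the B-exclusive strain
    oxidizes the product alcohols) or ``"inhibition"`` (it suppresses its
    batch-mates' reductions); the fixture asserts neither as true.
    """
    if batch_b_mechanism not in ("oxidation", "inhibition"):
        raise ValueError("batch_b_mechanism must be 'oxidation' or 'inhibition'")

    clm1 = _fixture_design(_CLM1_ROWS, ("A", "B", "C", "D"))
    clm2 = _fixture_design(_CLM2_ROWS, ("E", "F", "G", "H"))

    def kin(**kw: float) -> SubstrateKinetics:
        return SubstrateKinetics(**kw)

    weak = kin(k_red_R=0.0008, k_red_S=0.0012)  # background low activity

    profiles: dict[str, StrainProfile] = {}

    def add(sid: str, subs: dict[str, SubstrateKinetics], oxygen_dep: bool = True,
            biomass: float = 100.0) -> None:
        profiles[sid] = StrainProfile(
            strain_id=sid,
            substrates=subs,
            oxygen_dependent_oxidation=oxygen_dep,
            biomass=biomass,
        )

    # --- CLM-1 strains -----------------------------------------------------
    # s01: fast reducer of both aliphatic ketones, only strain in D alone.
    add("s01", {
        "2-octanone": kin(k_red_R=0.07, k_red_S=0.03),
        "3-octanone": kin(k_red_R=0.08, k_red_S=0.04),
    })
    # s02/s03: strong (S)-selective reducers of the aromatic ketones (> 99% ee).
    aromatic = {
        "propiophenone": kin(k_red_R=0.0008, k_red_S=0.20),
        "acetonaphthone": kin(k_red_R=0.0006, k_red_S=0.16),
    }
    add("s02", dict(aromatic))
    add("s03", {k: replace(v, k_red_S=v.k_red_S * 0.9) for k, v in aromatic.items()})
    # s04: B-exclusive strain; under the oxidation hypothesis it destroys the
    # aromatic alcohols, under the inhibition hypothesis it is kinetically inert
    # and the suppression is carried by the cross_inhibition table instead.
    if batch_b_mechanism == "oxidation":
        add("s04", {
            "propiophenone": kin(k_ox_S=0.30, k_ox_R=0.25),
            "acetonaphthone": kin(k_ox_S=0.30, k_ox_R=0.25),
        })
    else:
        add("s04", {})
    # s11: reduces 3-octanone well (the batch-B control activity).
    add("s11", {"3-octanone": kin(k_red_R=0.055, k_red_S=0.045)})
    for sid in ("s05", "s06", "s07", "s08", "s09", "s10", "s12"):
        add(sid, {s: weak for s in ("2-octanone", "3-octanone",
                                    "propiophenone", "acetonaphthone")})

    # --- CLM-2 strains -----------------------------------------------------
    # s13: very fast 3-octanone reducer (>= 85% conversion by 4 h).
    add("s13", {"3-octanone": kin(k_red_R=0.30, k_red_S=0.18)})
    # s14: fast, strongly (S)-selective acetophenone reducer whose activity
    # decays (resting cells); no oxidation — the analog that leaves the
    # product alcohol untouched.
    add("s14", {"acetophenone": kin(k_red_R=0.08, k_red_S=1.40, reduction_decay=0.6)})
    # s15: the tandem strain — (S)-leaning reduction plus a strictly
    # (S)-selective, oxygen-dependent oxidation; the same rates apply whether
    # the incubation starts from the ketone or from added racemic alcohol.
    s15_kin = kin(k_red_R=0.12, k_red_S=0.48, k_ox_S=0.30, reduction_decay=0.2)
    add("s15", {"acetophenone": s15_kin, "phenylethanol": s15_kin}, oxygen_dep=True)
    for sid in ("s16", "s17", "s18", "s19", "s20", "s21", "s22", "s23", "s24"):
        add(sid, {s: weak for s in ("3-octanone", "acetophenone")})

    mixtures = (
        MixtureChannel("mixture-1", ("2-octanone", "acetonaphthone"), "CLM-1"),
        MixtureChannel("mixture-2", ("3-octanone", "propiophenone"), "CLM-1"),
        MixtureChannel("mixture-3", ("3-octanone", "acetophenone"), "CLM-2"),
    )
    truth = {
        "fast_aliphatic_reducer_D": ("s01",),
        "aromatic_reducers_AD": ("s02", "s03"),
        "suspected_oxidizer_B": ("s04",),
        "fast_octanone_reducer_E": ("s13",),
        "acetophenone_transformers_EF": ("s14", "s15"),
        "oxygen_dependent_S_oxidizer": ("s15",),
    }
    # Suppression of the 3-octanone reduction in batch B when propiophenone is
    # present (mixture assays only, not single-ketone controls).
    cross_inhibition = {("B", "3-octanone"): 0.3}
    return StudyFixture(
        clm1=clm1,
        clm2=clm2,
        profiles=profiles,
        mixtures=mixtures,
        truth=truth,
        cross_inhibition=cross_inhibition,
        batch_b_mechanism=batch_b_mechanism,
    )


def simulate_study(
    fixture: StudyFixture,
    times: Sequence[float] = (4.0, 24.0),
    noise_sd: float = 0.03,
    seed: int | None = None,
    aeration: str = "aerobic",
) -> pd.DataFrame:
    """Readout table for the whole study: pooled assays plus controls.

    For every mixture channel and every batch of its library, each substrate
    of the mixture is incubated twice: in the mixture ("pooled" mode, where
    cross-substrate inhibition factors apply) and alone ("control" mode).
    Substrates transform independently otherwise.  Seeded noise is drawn
    independently per incubation; identical seeds give identical tables.
    """
    rng = np.random.default_rng(seed)
    frames: list[pd.DataFrame] = []
    for channel in fixture.mixtures:
        design = fixture.design_for(channel)
        for batch in design.batch_ids:
            members = [fixture.profiles[s] for s in design.members(batch)]
            for substrate in channel.substrates:
                for mode in ("pooled", "control"):
                    factor = (
                        fixture.cross_inhibition.get((batch, substrate), 1.0)
                        if mode == "pooled"
                        else 1.0
                    )
                    frames.append(
                        simulate_assay(
                            members,
                            substrate,
                            times,
                            aeration=aeration,
                            noise_sd=noise_sd,
                            seed=int(rng.integers(0, 2**31 - 1)),
                            mode=mode,
                            batch_or_strain=batch,
                            inhibition_factor=factor,
                        )
                    )
    return pd.concat(frames, ignore_index=True)
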