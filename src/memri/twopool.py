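"""Two-pool longitudinal magnetization dynamics.

The tissue is modelled as two exchanging proton pools: free water (f) and
macromolecular protons (m), coupled by magnetization transfer with rates
k_fm (free -> macromolecular) and k_mf (macromolecular -> free).  Detailed
balance ties the rates to the pool size ratio PSR = k_fm / k_mf =
M_inf_m / M_inf_f.  After a hard inversion pulse that selectively inverts
the free pool, the coupled longitudinal system recovers bi-exponentially,

    M_z,f(t) / M_inf,f = bf+ exp(-R1+ t) + bf- exp(-R1- t) + 1,

with the fast/slow apparent rates R1+/- and amplitudes bf+/- closed-form
functions of the pool parameters and of the post-pulse state
(delta_f, delta_m) = (M_z,f(0)/M_inf,f, M_z,m(0)/M_inf,m).

All quantities are carried internally in seconds and Hz; conversion to the
millisecond conventions of acquisition protocols happens at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DomainError, IntegrationError

__all__ = [
    "TwoPoolParams",
    "InversionState",
    "SequenceParams",
    "BiexpComponents",
    "simulate_inversion_pulse",
    "rates_from_twopool",
    "biexp_recovery_signal",
]


@dataclass(frozen=True)
class TwoPoolParams:
    """Biophysical state of the two-pool system.

    Parameters
    ----------
    r1f, r1m : float
        Longitudinal relaxation rates of the free and macromolecular pools
        in the absence of cross-relaxation (Hz).
    kmf : float
        Magnetization-transfer rate from the macromolecular to the free
        pool (Hz).
    psr : float
        Pool size ratio, macromolecular over free proton population
        (dimensionless).  The reverse rate k_fm = psr * kmf is always
        derived, never stored.
    t2f, t2m : float
        Transverse relaxation times of the two pools (seconds).  t2m is of
        order 10 microseconds for semisolid protons.
    m_inf_f, m_inf_m : float
        Equilibrium longitudinal magnetizations (arbitrary units).  When
        m_inf_m is not given it defaults to psr * m_inf_f.
    """

    r1f: float
    r1m: float
    kmf: float
    psr: float
    t2f: float = 60e-3
    t2m: float = 10e-6
    m_inf_f: float = 1.0
    m_inf_m: float | None = None

    def __post_init__(self):
        for name in ("r1f", "r1m", "kmf", "psr", "t2f", "t2m", "m_inf_f"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be strictly positive")
        if self.m_inf_m is None:
            object.__setattr__(self, "m_inf_m", self.psr * self.m_inf_f)
        elif not math.isclose(self.m_inf_m / self.m_inf_f, self.psr,
                              rel_tol=1e-6):
            raise DomainError(
                "m_inf_m / m_inf_f must equal psr (detailed balance)")

    @property
    def kfm(self) -> float:
        """Free -> macromolecular transfer rate, psr * kmf (Hz)."""
        return self.psr * self.kmf


@dataclass(frozen=True)
class InversionState:
    """Longitudinal state immediately after the inversion pulse,
    expressed as fractions of the respective equilibrium magnetizations."""

    delta_f: float
    delta_m: float

    def __post_init__(self):
        for name in ("delta_f", "delta_m"):
            v = getattr(self, name)
            if not -1.0 - 1e-9 <= v <= 1.0 + 1e-9:
                raise DomainError(f"{name} must lie in [-1, 1], got {v}")


@dataclass(frozen=True)
class SequenceParams:
    """Timing of a spin-echo acquisition.

    te_list and ti_list are in seconds and strictly increasing;
    refocusing_angles are in degrees, one per echo (broadcast from a
    scalar).
    """

    te_list: np.ndarray | None = None
    ti_list: np.ndarray | None = None
    echo_spacing: float | None = None
    n_echoes_per_ti: int = 1
    refocusing_angles: np.ndarray | float = 180.0
    inversion_pulse_duration: float = 1e-3
    inversion_flip: float = 180.0

    def __post_init__(self):
        for name in ("te_list", "ti_list"):
            v = getattr(self, name)
            if v is None:
                continue
            v = np.asarray(v, dtype=float)
            if v.ndim != 1 or v.size == 0:
                raise DomainError(f"{name} must be a non-empty 1-d array")
            if np.any(v <= 0) or np.any(np.diff(v) <= 0):
                raise DomainError(f"{name} must be positive and strictly "
                                  "increasing")
            object.__setattr__(self, name, v)
        if self.n_echoes_per_ti < 1:
            raise DomainError("n_echoes_per_ti must be >= 1")
        ang = np.atleast_1d(np.asarray(self.refocusing_angles, dtype=float))
        if np.any(ang <= 0) or np.any(ang > 180):
            raise DomainError("refocusing angles must lie in (0, 180]")
        object.__setattr__(self, "refocusing_angles", ang)


@dataclass(frozen=True)
class BiexpComponents:
    """Rates and amplitudes of the bi-exponential inversion recovery.

    r1_plus >= r1_minus > 0; the recovery starts at
    delta_f = 1 + bf_plus + bf_minus which must lie in [-1, 1].
    """

    r1_plus: float
    r1_minus: float
    bf_plus: float
    bf_minus: float

    def __post_init__(self):
        if not self.r1_minus > 0:
            raise DomainError("r1_minus must be strictly positive")
        if self.r1_plus < self.r1_minus:
            raise DomainError("r1_plus must be >= r1_minus")
        d0 = 1.0 + self.bf_plus + self.bf_minus
        if not -1.0 - 1e-6 <= d0 <= 1.0 + 1e-6:
            raise DomainError(
                f"1 + bf_plus + bf_minus = {d0} outside [-1, 1]")

    @property
    def delta_f(self) -> float:
        """Value of the normalized recovery at t = 0."""
        return 1.0 + self.bf_plus + self.bf_minus


def _pulse_decay(t2: float, duration: float, flip_deg: float,
                 rtol: float = 1e-9) -> float:
    """Longitudinal fraction M_z(tau)/M_z(0-) after an on-resonance
    constant-amplitude pulse, by numerical Bloch integration.

    During the (short) pulse longitudinal relaxation is negligible but
    transverse relaxation is not: for very short T2 the rotation is
    quenched and the pulse saturates rather than inverts.  With B1 along
    x only (My, Mz) evolve:

        dMy/dt = w1 Mz - My/T2,    dMz/dt = -w1 My.
    """
    w1 = math.radians(flip_deg) / duration

    def rhs(_t, y):
        my, mz = y
        return [w1 * mz - my / t2, -w1 * my]

    sol = solve_ivp(rhs, (0.0, duration), [0.0, 1.0], method="LSODA",
                    rtol=rtol, atol=1e-12)
    if not sol.success:
        raise IntegrationError(f"Bloch integration failed: {sol.message}")
    return float(sol.y[1, -1])


def simulate_inversion_pulse(params: TwoPoolParams,
                             pulse_duration: float = 1e-3,
                             flip: float = 180.0) -> InversionState:
    """Post-pulse longitudinal state of both pools for a hard pulse.

    A hard on-resonance pulse of the given duration and nominal flip angle
    is applied to each pool independently, integrating the Bloch equations
    with the pool's own T2 (Lorentzian line).  The free pool (T2 of tens
    of milliseconds) is essentially fully inverted; the macromolecular
    pool (T2 of tens of microseconds) is only partially saturated, which
    is exactly the selectivity the inversion-recovery MT experiment relies
    on.

    Returns
    -------
    InversionState with delta_f, delta_m in [-1, 1].
    """
    if not pulse_duration > 0:
        raise DomainError("pulse_duration must be positive")
    if not 0.0 < flip < 360.0:
        raise DomainError("flip must lie in (0, 360) degrees")
    delta_f = _pulse_decay(params.t2f, pulse_duration, flip)
    delta_m = _pulse_decay(params.t2m, pulse_duration, flip)
    clip = lambda v: float(np.clip(v, -1.0, 1.0))
    return InversionState(delta_f=clip(delta_f), delta_m=clip(delta_m))


def rates_from_twopool(params: TwoPoolParams,
                       inv: InversionState) -> BiexpComponents:
    """Map pool parameters and post-pulse state to the bi-exponential
    components (R1+, R1-, bf+, bf-).

    The apparent rates are the eigenvalues of the coupled longitudinal
    relaxation matrix,

        2 R1+/- = R1f + R1m + kfm + kmf
                  +/- sqrt((R1f - R1m + kfm - kmf)^2 + 4 kfm kmf),

    and the amplitudes follow from projecting the initial state onto the
    eigenvectors,

        bf+/- = +/- [ (R1f - R1-/+)(delta_f - 1)
                      + kfm (delta_f - delta_m) ] / (R1+ - R1-).
    """
    r1f, r1m = params.r1f, params.r1m
    kfm, kmf = params.kfm, params.kmf
    disc = math.sqrt((r1f - r1m + kfm - kmf) ** 2 + 4.0 * kfm * kmf)
    r1_plus = 0.5 * (r1f + r1m + kfm + kmf + disc)
    r1_minus = 0.5 * (r1f + r1m + kfm + kmf - disc)
    df1 = inv.delta_f - 1.0
    dfm = inv.delta_f - inv.delta_m
    gap = r1_plus - r1_minus
    bf_plus = ((r1f - r1_minus) * df1 + kfm * dfm) / gap
    bf_minus = -((r1f - r1_plus) * df1 + kfm * dfm) / gap
    return BiexpComponents(r1_plus=r1_plus, r1_minus=r1_minus,
                           bf_plus=bf_plus, bf_minus=bf_minus)


def biexp_recovery_signal(comp: BiexpComponents,
                          ti_list: np.ndarray) -> np.ndarray:
    """Normalized free-pool recovery M_z,f(t)/M_inf,f at the given times.

    Evaluates bf+ exp(-R1+ t) + bf- exp(-R1- t) + 1 elementwise; the
    result is signed (negative shortly after inversion).
    """
    t = np.asarray(ti_list, dtype=float)
    if np.any(t < 0):
        raise DomainError("recovery times must be nonnegative")
    return (comp.bf_plus * np.exp(-comp.r1_plus * t)
            + comp.bf_minus * np.exp(-comp.r1_minus * t) + 1.0)
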