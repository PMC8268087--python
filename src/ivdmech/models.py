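"""Core data types for ramp-hold spherical indentation analysis.

Units at the API boundary are the instrument's: time in seconds,
displacement in micrometres, force in micronewtons, moduli in kilopascals.
Conversions to SI happen inside the numerical routines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

__all__ = [
    "IndentProfile",
    "SLSParams",
    "IndentationRecord",
    "ContactPoint",
    "SLSFit",
    "ValidityReport",
    "InvalidSpecError",
    "NoContactError",
    "AmbiguousContactError",
    "InsufficientDataError",
]


class InvalidSpecError(ValueError):
    """A generator or analysis specification violates its invariants."""


class NoContactError(RuntimeError):
    """The force signal never exceeds the contact threshold."""


class AmbiguousContactError(RuntimeError):
    """The curve starts above the contact threshold; no baseline exists."""


class InsufficientDataError(RuntimeError):
    """Too few post-contact samples to constrain the viscoelastic fit."""


@dataclass(frozen=True)
class IndentProfile:
    """Trapezoidal displacement-controlled indentation profile.

    Default values are the study protocol: load at 2 um/s to a 2 um depth,
    hold for 10 s, unload at 2 um/s.

    Attributes
    ----------
    v_load : float
        Loading ramp speed, um/s.
    h_max : float
        Maximum indentation depth, um.
    t_hold : float
        Hold duration at constant displacement, s.
    v_unload : float
        Unloading ramp speed, um/s.
    """

    v_load: float = 2.0
    h_max: float = 2.0
    t_hold: float = 10.0
    v_unload: float = 2.0

    def __post_init__(self) -> None:
        for name in ("v_load", "h_max", "t_hold", "v_unload"):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be strictly positive")

    @property
    def t_ramp(self) -> float:
        """Ramp duration h_max / v_load, s."""
        return self.h_max / self.v_load

    @property
    def t_unload(self) -> float:
        return self.h_max / self.v_unload

    @property
    def t_total(self) -> float:
        return self.t_ramp + self.t_hold + self.t_unload

    def displacement(self, t: np.ndarray) -> np.ndarray:
        """Commanded indentation depth h(t) in um (0 before t=0, 0 after unload)."""
        t = np.asarray(t, dtype=float)
        h = np.zeros_like(t)
        ramp = (t >= 0) & (t < self.t_ramp)
        hold = (t >= self.t_ramp) & (t < self.t_ramp + self.t_hold)
        unload = (t >= self.t_ramp + self.t_hold) & (t <= self.t_total)
        h[ramp] = self.v_load * t[ramp]
        h[hold] = self.h_max
        h[unload] = np.maximum(
            self.h_max - self.v_unload * (t[unload] - self.t_ramp - self.t_hold), 0.0
        )
        return h


@dataclass(frozen=True)
class SLSParams:
    """Standard-linear-solid relaxation parameters.

    A spring E0 in parallel with a Maxwell arm (spring E1 in series with a
    dashpot of time constant tau1); relaxation modulus
    G(t) = E0 + E1 * exp(-t / tau1).

    Attributes
    ----------
    E0 : float
        Equilibrium spring modulus, kPa.
    E1 : float
        Maxwell-arm spring modulus, kPa.
    tau1 : float
        Maxwell relaxation time, s.
    """

    E0: float
    E1: float
    tau1: float

    def __post_init__(self) -> None:
        if self.E0 < 0 or self.E1 < 0:
            raise InvalidSpecError("moduli must be non-negative")
        if self.tau1 <= 0:
            raise InvalidSpecError("tau1 must be strictly positive")

    @property
    def E_ins(self) -> float:
        """Instantaneous modulus G(0) = E0 + E1, kPa."""
        return self.E0 + self.E1

    @property
    def E_eq(self) -> float:
        """Equilibrium modulus G(inf) = E0, kPa."""
        return self.E0

    @property
    def f(self) -> float:
        """Elastic fraction E_eq / E_ins in [0, 1]; 1 = purely elastic."""
        if self.E_ins == 0:
            raise ZeroDivisionError("elastic fraction undefined for E0 + E1 = 0")
        return self.E0 / self.E_ins

    @classmethod
    def from_moduli(cls, E_ins: float, f: float, tau1: float) -> "SLSParams":
        """Build from instantaneous modulus and elastic fraction."""
        if not 0.0 <= f <= 1.0:
            raise InvalidSpecError("elastic fraction must lie in [0, 1]")
        return cls(E0=f * E_ins, E1=(1.0 - f) * E_ins, tau1=tau1)


@dataclass
class IndentationRecord:
    """One indent's sampled time, displacement and force series.

    Attributes
    ----------
    t : ndarray
        Time, s; strictly increasing.
    h : ndarray
        Displacement, um (probe position; may include a pre-contact approach).
    P : ndarray
        Force, uN.
    tip_radius : float
        Spherical tip radius R, um.
    poisson_ratio : float
        Poisson's ratio nu; 0.5 (incompressible) by default.
    spring_constant : float | None
        Cantilever stiffness, N/m; metadata only, not used in analysis.
    metadata : dict
        Free-form provenance: group, specimen, structure, vertebral level,
        stage, and (for synthetic records) ground truth.
    """

    t: np.ndarray
    h: np.ndarray
    P: np.ndarray
    tip_radius: float = 42.0
    poisson_ratio: float = 0.5
    spring_constant: float | None = 0.48
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if not (self.t.shape == self.h.shape == self.P.shape):
            raise ValueError("t, h, P must have equal length")
        if self.t.ndim != 1 or self.t.size < 2:
            raise ValueError("series must be 1-D with at least 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.tip_radius <= 0:
            raise ValueError("tip radius must be positive")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson ratio must lie in [0, 0.5]")

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class ContactPoint:
    """Detected tip-sample contact with offsets zeroing the indentation phase.

    Subtracting (t0, h0, P0) from the series makes the post-contact segment
    start at the origin of the force-indentation plane.
    """

    index: int
    t0: float
    h0: float
    P0: float
    threshold_used: float

    def zeroed(self, record: IndentationRecord) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Post-contact (t, h, P) with offsets removed."""
        sl = slice(self.index, None)
        return (
            record.t[sl] - self.t0,
            record.h[sl] - self.h0,
            record.P[sl] - self.P0,
        )


@dataclass(frozen=True)
class SLSFit:
    """Fitted SLS parameters with derived moduli and fit diagnostics."""

    params: SLSParams
    E_ins: float
    E_eq: float
    f: float
    rmse: float
    r_squared: float
    t_ramp_end: float
    t_hold_end: float
    converged: bool
    at_bounds: bool = False
    n_points: int = 0

    @staticmethod
    def from_params(
        params: SLSParams,
        *,
        rmse: float,
        r_squared: float,
        t_ramp_end: float,
        t_hold_end: float,
        converged: bool,
        at_bounds: bool = False,
        n_points: int = 0,
    ) -> "SLSFit":
        return SLSFit(
            params=params,
            E_ins=params.E_ins,
            E_eq=params.E_eq,
            f=params.f,
            rmse=rmse,
            r_squared=r_squared,
            t_ramp_end=t_ramp_end,
            t_hold_end=t_hold_end,
            converged=converged,
            at_bounds=at_bounds,
            n_points=n_points,
        )


@dataclass(frozen=True)
class ValidityReport:
    """Measurement-validity flags for one indent.

    The representative contact strain uses Tabor's convention 0.2*a/R with
    contact radius a = sqrt(R * h_max); the substrate criterion compares the
    indentation depth with the section thickness.
    """

    representative_strain: float
    depth_to_thickness: float
    strain_ok: bool
    substrate_ok: bool

    STRAIN_LIMIT = 0.05
    DEPTH_RATIO_LIMIT = 0.10

    @property
    def ok(self) -> bool:
        return self.strain_ok and self.substrate_ok
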