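"""Closed-form two-step irreversible binding kinetics.

An irreversible covalent inhibitor I binds its target E in two steps: a
reversible, affinity-driven association (k_on, k_off) forming the non-covalent
encounter complex EI, followed by irreversible bond formation (k_inact)
yielding the covalent adduct EI*::

    E + I  <==[k_on/k_off]==>  EI  --[k_inact]-->  EI*

Under the steady-state approximation for EI and pseudo-first-order conditions
([I] >> [E]_0, no inhibitor depletion), the occupancy [EI*]/[E]_0 follows a
single-exponential approach to 1 with apparent rate

    k_obs([I]) = k_inact * [I] / (K_I + [I]),    K_I = (k_off + k_inact)/k_on

The second-order inactivation efficiency k_eff = k_inact/K_I is the standard
potency metric for irreversible inhibitors. This module holds the shared
domain types and the closed-form expressions; everything else in the package
builds on them.

Units are strictly SI throughout the package internals: concentrations in M,
times in s, first-order rates in s^-1 and second-order rates in M^-1 s^-1.
Occupancies are fractions in [0, 1]; percent appears only in reports. I/O
layers convert from nM/uM/min at the boundary.

The closed form is exact only without inhibitor depletion; the ODE simulator
(`kinact.simulate`) integrates the full mass-action system and quantifies the
divergence when [I] approaches [E]_0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "KineticParams",
    "MicroRates",
    "OccupancyPoint",
    "RatePoint",
    "kobs_from_params",
    "occupancy_closed_form",
    "keff",
    "ki_from_micro_rates",
]


@dataclass(frozen=True)
class KineticParams:
    """Macroscopic two-step kinetic parameters of one inhibitor-target pair.

    Parameters
    ----------
    k_inact : float
        First-order rate constant of the covalent bond-forming step (s^-1).
        Zero is allowed and denotes an inactive compound (occupancy stays 0).
    K_I : float
        Two-step inactivation constant (k_off + k_inact)/k_on (M), > 0.
    """

    k_inact: float
    K_I: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.k_inact) or self.k_inact < 0:
            raise ValueError(f"k_inact must be finite and >= 0, got {self.k_inact}")
        if not np.isfinite(self.K_I) or self.K_I <= 0:
            raise ValueError(f"K_I must be finite and > 0, got {self.K_I}")

    @property
    def k_eff(self) -> float:
        """Inactivation efficiency k_inact/K_I (M^-1 s^-1)."""
        return self.k_inact / self.K_I


@dataclass(frozen=True)
class MicroRates:
    """Microscopic rate constants and initial conditions for the simulator.

    Fields: k_on (M^-1 s^-1), k_off (s^-1), k_inact (s^-1), initial free
    target E0 (M, > 0) and initial free inhibitor I0 (M, >= 0).
    """

    k_on: float
    k_off: float
    k_inact: float
    E0: float
    I0: float

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_inact", "I0"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not np.isfinite(self.E0) or self.E0 <= 0:
            raise ValueError(f"E0 must be finite and > 0, got {self.E0}")

    @property
    def K_I(self) -> float:
        return ki_from_micro_rates(self)

    @property
    def params(self) -> KineticParams:
        """The implied macroscopic (k_inact, K_I) pair."""
        return KineticParams(k_inact=self.k_inact, K_I=self.K_I)

    def with_inhibitor(self, I0: float) -> "MicroRates":
        """Same rates at a different initial inhibitor concentration."""
        return MicroRates(self.k_on, self.k_off, self.k_inact, self.E0, I0)

    @classmethod
    def from_macroscopic(
        cls,
        k_inact: float,
        K_I: float,
        k_on: float,
        E0: float,
        I0: float = 0.0,
    ) -> "MicroRates":
        """Construct micro rates realizing a target (k_inact, K_I) pair.

        k_on is the caller's choice; k_off = K_I*k_on - k_inact is implied and
        must be nonnegative, i.e. k_on >= k_inact/K_I.
        """
        k_off = K_I * k_on - k_inact
        if k_off < 0:
            raise ValueError(
                f"k_on={k_on} too small for k_inact={k_inact}, K_I={K_I}: "
                f"implied k_off={k_off} < 0 (need k_on >= k_inact/K_I)"
            )
        return cls(k_on=k_on, k_off=k_off, k_inact=k_inact, E0=E0, I0=I0)


@dataclass(frozen=True)
class OccupancyPoint:
    """One covalent-occupancy observation: ([I] in M, t in s, fraction)."""

    conc: float
    time: float
    occupancy: float
    replicate: str = ""

    def __post_init__(self) -> None:
        if self.conc < 0:
            raise ValueError(f"conc must be >= 0, got {self.conc}")
        if self.time < 0:
            raise ValueError(f"time must be >= 0, got {self.time}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(
                f"occupancy must lie in [0, 1] after clamping, got {self.occupancy}"
            )


@dataclass(frozen=True)
class RatePoint:
    """One ([I], k_obs) observation feeding the Michaelis-Menten stage."""

    conc: float
    k_obs: float
    stderr: Optional[float] = None
    replicate: str = ""
    flag: str = ""

    def __post_init__(self) -> None:
        if self.conc < 0:
            raise ValueError(f"conc must be >= 0, got {self.conc}")
        if self.k_obs < 0:
            raise ValueError(f"k_obs must be >= 0, got {self.k_obs}")


def kobs_from_params(params: KineticParams, conc):
    """Apparent pseudo-first-order inactivation rate at concentration `conc`.

    k_obs = k_inact * conc / (K_I + conc); accepts scalars or arrays.
    Bounded above by k_inact, concave and nondecreasing in conc.
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("conc must be >= 0")
    out = params.k_inact * conc / (params.K_I + conc)
    return out if out.ndim else float(out)


def occupancy_closed_form(params: KineticParams, conc, time):
    """Covalent occupancy [EI*]/[E]_0 = 1 - exp(-k_obs(conc) * t).

    Exact under pseudo-first-order conditions (no inhibitor depletion) and
    the steady-state approximation for the non-covalent complex.
    """
    time = np.asarray(time, dtype=float)
    if np.any(time < 0):
        raise ValueError("time must be >= 0")
    k = kobs_from_params(params, conc)
    out = -np.expm1(-np.asarray(k) * time)
    return out if out.ndim else float(out)


def keff(params: KineticParams) -> float:
    """Inactivation efficiency k_inact/K_I (M^-1 s^-1)."""
    return params.k_eff


def ki_from_micro_rates(rates: MicroRates) -> float:
    """K_I = (k_off + k_inact)/k_on from microscopic rates."""
    if rates.k_on <= 0:
        raise ValueError("k_on must be > 0 to define K_I")
    return (rates.k_off + rates.k_inact) / rates.k_on
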