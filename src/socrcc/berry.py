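"""Single rate-controlled Berry bienzymatic oscillator.

The Berry model describes the remodelling of extracellular matrix ``m`` from
soluble filaments ``f`` by an antagonistic pair of enzymes: a proteinase ``p``
that degrades matrix into filaments, and a transglutaminase ``g`` that
cross-links filaments back into matrix.  Matrix is supplied by neighbouring
cells at a rate ``r_im``, the bifurcation parameter; for a window of ``r_im``
values the model is chaotic.

Rate Control of Chaos (RCC) multiplies the production terms of the two
enzymes by a control factor

    sigma(q) = f_s * exp(xi * q),        q = f / (f + mu_f),

where the rate quotient ``q`` is a bounded (0 <= q < 1) measure of the
instantaneous filament level.  With negative ``xi`` the enzyme production is
slowed when ``f`` grows, which is enough to steer the chaotic oscillator onto
a stable periodic orbit using only local, instantaneous information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BerryParams",
    "RCCParams",
    "OscillatorState",
    "CHAOTIC_R_IM",
    "rate_quotient",
    "control_sigma",
    "berry_derivatives",
]

#: A value of the matrix-supply bifurcation parameter inside the chaotic
#: window of the uncontrolled model.  Located by scanning the largest
#: Lyapunov exponent over r_im in [0.002, 0.1]: weak chaos (LE ~ +3e-4)
#: appears for r_im in roughly [0.012, 0.025].  At 0.012 the chaos is a
#: long chaotic transient (lifetime of order 5e4 time units from
#: attractor-adjacent states before locking onto a periodic orbit; the
#: coupled, perturbed network re-excites it continually), and the
#: RCC-controlled system settles onto a period-2 orbit - the stabilisation
#: showcase.  Persistent single-unit chaos lives around r_im ~ 0.014-0.015.
CHAOTIC_R_IM = 0.012


@dataclass(frozen=True)
class BerryParams:
    """Kinetic constants of the Berry bienzymatic matrix-remodelling model.

    ``k_a`` (the proteinase autocatalytic decay rate) defaults to the exact
    quotient ``k_deg / K_deg`` (~0.04545); the commonly quoted 0.0455 is that
    quotient rounded.
    """

    gamma: float = 0.026
    beta: float = 0.00075
    K_R: float = 4.5
    K_S: float = 1.0
    K_G: float = 0.1
    K_deg: float = 1.1
    k_g: float = 0.05
    k_deg: float = 0.05
    k_a: float = field(default=None)  # type: ignore[assignment]
    hill_n: int = 4
    hill_l: int = 4

    def __post_init__(self) -> None:
        if self.k_a is None:
            object.__setattr__(self, "k_a", self.k_deg / self.K_deg)
        for name in ("gamma", "beta", "K_R", "K_S", "K_G", "K_deg",
                     "k_g", "k_deg", "k_a"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"BerryParams.{name} must be finite and > 0, got {v}")
        if self.hill_n < 1 or self.hill_l < 1:
            raise ValueError("Hill exponents must be >= 1")

    def as_vector(self) -> np.ndarray:
        """Flat float64 vector used by the compiled integration kernel."""
        return np.array(
            [self.gamma, self.beta, self.K_R, self.K_S, self.K_G, self.K_deg,
             self.k_g, self.k_deg, self.k_a,
             float(self.hill_n), float(self.hill_l)],
            dtype=np.float64,
        )


@dataclass(frozen=True)
class RCCParams:
    """Rate-control parameters: quotient scale mu_f, exponents xi, prefactors f_p/f_g."""

    mu_f: float = 2.0
    xi_p: float = -1.0
    xi_g: float = -1.0
    f_p: float = 1.0
    f_g: float = 1.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu_f) and self.mu_f > 0):
            raise ValueError("mu_f must be finite and > 0")

    def disabled(self) -> "RCCParams":
        return replace(self, enabled=False)

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.mu_f, self.xi_p, self.xi_g, self.f_p, self.f_g,
             1.0 if self.enabled else 0.0],
            dtype=np.float64,
        )


@dataclass(frozen=True)
class OscillatorState:
    """Concentrations of one Berry unit: matrix m, filament f, proteinase p, transglutaminase g."""

    m: float
    f: float
    p: float
    g: float

    def as_array(self) -> np.ndarray:
        return np.array([self.m, self.f, self.p, self.g], dtype=np.float64)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "OscillatorState":
        m, f, p, g = np.asarray(y, dtype=float)
        return cls(m, f, p, g)

    def is_finite(self) -> bool:
        return bool(np.all(np.isfinite(self.as_array())))

    def is_nonnegative(self) -> bool:
        return bool(np.all(self.as_array() >= 0.0))


def rate_quotient(f, mu_f: float):
    """Bounded rate quotient q = f / (f + mu_f), in [0, 1) for f >= 0.

    Accepts scalars or arrays of filament concentrations.
    """
    f = np.asarray(f, dtype=float)
    if not np.all(np.isfinite(f)) or np.any(f < 0):
        raise ValueError("rate_quotient requires finite, non-negative f")
    if not (np.isfinite(mu_f) and mu_f > 0):
        raise ValueError("rate_quotient requires mu_f > 0")
    q = f / (f + mu_f)
    return float(q) if q.ndim == 0 else q


def control_sigma(q, f_scale: float = 1.0, xi: float = -1.0):
    """Exponential control factor sigma = f_scale * exp(xi * q).

    Equals ``f_scale`` at q = 0 and is strictly positive; for xi < 0 it is
    monotone decreasing in q, bounded in [f_scale*e^xi, f_scale] on [0, 1].
    """
    q = np.asarray(q, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("control_sigma requires finite q")
    s = f_scale * np.exp(xi * q)
    return float(s) if s.ndim == 0 else s


def _int_pow(x: float, n: int) -> float:
    out = 1.0
    for _ in range(n):
        out *= x
    return out


def berry_derivatives(
    state: OscillatorState,
    bp: BerryParams,
    rcc: RCCParams,
    r_im: float,
) -> OscillatorState:
    """Vector field of one (optionally RCC-controlled) Berry oscillator.

    Returns the time derivatives (dm/dt, df/dt, dp/dt, dg/dt) as an
    :class:`OscillatorState`.  With ``rcc.enabled`` false the control factors
    reduce to the constant prefactors f_p, f_g (= 1 in the uncontrolled
    convention), recovering the plain Berry model.
    """
    if not state.is_finite() or not math.isfinite(r_im):
        raise ValueError("berry_derivatives requires finite state and r_im")
    m, f, p, g = state.m, state.f, state.p, state.g
    if rcc.enabled:
        q = f / (f + rcc.mu_f)
        sigma_p = rcc.f_p * math.exp(rcc.xi_p * q)
        sigma_g = rcc.f_g * math.exp(rcc.xi_g * q)
    else:
        sigma_p = rcc.f_p
        sigma_g = rcc.f_g

    exchange = bp.k_g * f * g / (bp.K_G + f)   # transglutaminase: filament -> matrix
    hydrolysis = m * p / (1.0 + m)             # proteinase: matrix -> filament
    fn = _int_pow(f, bp.hill_n)
    fl = _int_pow(f, bp.hill_l)

    dm = exchange - hydrolysis + r_im
    df = -exchange + hydrolysis - f * p / (1.0 + f)
    dp = sigma_p * bp.gamma * fn / (_int_pow(bp.K_R, bp.hill_n) + fn) - bp.k_a * p * p
    dg = sigma_g * bp.beta * fl / (_int_pow(bp.K_S, bp.hill_l) + fl) \
        - bp.k_deg * g * p / (bp.K_deg + g)
    return OscillatorState(dm, df, dp, dg)
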