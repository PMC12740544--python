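"""Sum-of-exponentials (SOEF) kidney kinetics and analytic time-integrated activity.

The structural model describes the fraction of injected activity in both
kidneys after administration of a 177Lu-labelled radiopharmaceutical as a
six-parameter sum of exponentials,

    f(t) = A1 e^{-(l1+lp) t} + A2 e^{-(l2+lp) t} - A3 e^{-(l3+lp) t}
           - (A1 + A2 - A3) e^{-(lbc+lp) t},

where ``A1..A3`` are dimensionless prefactors, ``l1..l3`` biological
uptake/clearance rates (1/h), ``lp`` the fixed physical decay constant of
177Lu and ``lbc`` the fast blood-circulation uptake rate (half-life one
minute).  The tied fourth prefactor forces ``f(0) = 0``.

The time-integrated activity (TIA) over [0, inf) has the closed form

    TIA = A1/(l1+lp) + A2/(l2+lp) - A3/(l3+lp) - (A1+A2-A3)/(lbc+lp),

in units of (fraction of injected activity) x hours.  TIA uncertainty is
propagated from a parameter covariance matrix with the delta method using
the analytic gradient of the integral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LN2",
    "PARAM_NAMES",
    "DEFAULT_CONSTANTS",
    "PhysicalConstants",
    "SOEFParameters",
    "decay_constant",
    "soef_eval",
    "soef_eval_array",
    "soef_tia",
    "soef_tia_array",
    "tia_gradient",
    "tia_gradient_array",
    "tia_sd_delta",
]

LN2 = float(np.log(2.0))

#: canonical parameter ordering used by every array-valued interface
PARAM_NAMES = ("A1", "A2", "A3", "lambda1", "lambda2", "lambda3")


def decay_constant(half_life_h: float) -> float:
    """Decay rate ln(2)/T1/2 in 1/h for a half-life given in hours."""
    half_life_h = float(half_life_h)
    if not np.isfinite(half_life_h) or half_life_h <= 0.0:
        raise ValueError(f"half-life must be positive and finite, got {half_life_h!r}")
    return LN2 / half_life_h


@dataclass(frozen=True)
class PhysicalConstants:
    """Fixed decay/uptake rates of the kinetic model.

    Parameters
    ----------
    t_half_phys_d:
        Physical half-life of the radionuclide in days (177Lu: 6.6443 d).
    t_half_bc_min:
        Half-life of the fast blood-circulation uptake phase in minutes.
    """

    t_half_phys_d: float = 6.6443
    t_half_bc_min: float = 1.0

    def __post_init__(self) -> None:
        if self.t_half_phys_d <= 0 or self.t_half_bc_min <= 0:
            raise ValueError("half-lives must be positive")

    @property
    def t_half_phys_h(self) -> float:
        return self.t_half_phys_d * 24.0

    @property
    def t_half_bc_h(self) -> float:
        return self.t_half_bc_min / 60.0

    @property
    def lambda_phys(self) -> float:
        """Physical decay constant in 1/h."""
        return decay_constant(self.t_half_phys_h)

    @property
    def lambda_bc(self) -> float:
        """Blood-circulation uptake rate in 1/h."""
        return decay_constant(self.t_half_bc_h)


DEFAULT_CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class SOEFParameters:
    """Structural kinetic parameters of one subject's kidney curve.

    All six values must be strictly positive.  The implied fourth prefactor
    ``A1 + A2 - A3`` is unconstrained; a negative value makes the curve rise
    above its multi-exponential envelope in the first minutes, which is
    physically unusual but not forbidden.
    """

    A1: float
    A2: float
    A3: float
    lambda1: float
    lambda2: float
    lambda3: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0.0:
                raise ValueError(f"SOEF parameter {name} must be > 0, got {v!r}")

    @property
    def tail_prefactor(self) -> float:
        """The tied fourth prefactor A1 + A2 - A3."""
        return self.A1 + self.A2 - self.A3

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.A1, self.A2, self.A3, self.lambda1, self.lambda2, self.lambda3],
            dtype=float,
        )

    @classmethod
    def from_array(cls, p: np.ndarray) -> "SOEFParameters":
        p = np.asarray(p, dtype=float)
        if p.shape != (6,):
            raise ValueError(f"expected 6 parameters, got shape {p.shape}")
        return cls(*p.tolist())

    def warn_if_negative_tail(self) -> None:
        if self.tail_prefactor < 0:
            warnings.warn(
                f"tied prefactor A1+A2-A3 = {self.tail_prefactor:.3g} < 0; "
                "the curve is not guaranteed nonnegative near t=0",
                stacklevel=2,
            )


def _check_times(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    return t


def soef_eval_array(
    p: np.ndarray, t: np.ndarray, consts: PhysicalConstants = DEFAULT_CONSTANTS
) -> np.ndarray:
    """Evaluate the SOEF for a raw parameter vector (A1,A2,A3,l1,l2,l3)."""
    p = np.asarray(p, dtype=float)
    t = _check_times(t)
    lp = consts.lambda_phys
    a1, a2, a3, l1, l2, l3 = p
    tail = a1 + a2 - a3
    return (
        a1 * np.exp(-(l1 + lp) * t)
        + a2 * np.exp(-(l2 + lp) * t)
        - a3 * np.exp(-(l3 + lp) * t)
        - tail * np.exp(-(consts.lambda_bc + lp) * t)
    )


def soef_eval(
    params: SOEFParameters, t, consts: PhysicalConstants = DEFAULT_CONSTANTS
):
    """Fraction of injected activity at time(s) ``t`` (hours post-injection)."""
    out = soef_eval_array(params.as_array(), t, consts)
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out)
    return out


def soef_tia_array(
    p: np.ndarray, consts: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    a1, a2, a3, l1, l2, l3 = np.asarray(p, dtype=float)
    lp = consts.lambda_phys
    tail = a1 + a2 - a3
    return float(
        a1 / (l1 + lp)
        + a2 / (l2 + lp)
        - a3 / (l3 + lp)
        - tail / (consts.lambda_bc + lp)
    )


def soef_tia(
    params: SOEFParameters, consts: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Analytic time-integrated activity over [0, inf), in hours."""
    return soef_tia_array(params.as_array(), consts)


def tia_gradient_array(
    p: np.ndarray, consts: PhysicalConstants = DEFAULT_CONSTANTS
) -> np.ndarray:
    """Gradient of the analytic TIA w.r.t. (A1, A2, A3, l1, l2, l3)."""
    a1, a2, a3, l1, l2, l3 = np.asarray(p, dtype=float)
    lp = consts.lambda_phys
    dbc = 1.0 / (consts.lambda_bc + lp)
    return np.array(
        [
            1.0 / (l1 + lp) - dbc,
            1.0 / (l2 + lp) - dbc,
            -1.0 / (l3 + lp) + dbc,
            -a1 / (l1 + lp) ** 2,
            -a2 / (l2 + lp) ** 2,
            a3 / (l3 + lp) ** 2,
        ]
    )


def tia_gradient(
    params: SOEFParameters, consts: PhysicalConstants = DEFAULT_CONSTANTS
) -> np.ndarray:
    return tia_gradient_array(params.as_array(), consts)


def tia_sd_delta(
    params: SOEFParameters,
    param_cov: np.ndarray,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Delta-method SD of the TIA from a 6x6 parameter covariance matrix.

    SD = sqrt(g' C g) with g the analytic gradient of the TIA integral.
    ``param_cov`` must be symmetric with shape (6, 6).
    """
    c = np.asarray(param_cov, dtype=float)
    if c.shape != (6, 6):
        raise ValueError(f"param_cov must have shape (6, 6), got {c.shape}")
    if not np.allclose(c, c.T, rtol=1e-8, atol=1e-12):
        raise ValueError("param_cov must be symmetric")
    g = tia_gradient(params, consts)
    var = float(g @ c @ g)
    # tiny negative values can arise from roundoff in near-singular matrices
    return float(np.sqrt(max(var, 0.0)))
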