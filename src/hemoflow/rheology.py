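"""Blood constitutive laws: generalized Cross viscosity and the Oldroyd-B split.

Four constitutive cases are supported, distinguished by the solvent
(Newtonian) viscosity and the presence of an elastic extra stress:

==================  =======================  ==========
case                solvent viscosity mu_n   sigma_v
==================  =======================  ==========
``newtonian``       mu_inf (constant)        absent
``gen_newtonian``   mu(gamma_dot) (Cross)    absent
``oldroyd_b``       mu_inf (constant)        active
``gen_oldroyd_b``   mu(gamma_dot) (Cross)    active
==================  =======================  ==========

The total viscosity is mu = mu_n + mu_v and the retardation/relaxation ratio
lam_d/lam_x = mu_n/(mu_n + mu_v) is maintained as a derived quantity.  The
shear rate is gamma_dot = sqrt(2 V:V), which reduces to |dU/dy| in simple
shear.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CrossParams",
    "OldroydParams",
    "CaseConfig",
    "CASES",
    "strain_rate_tensor",
    "shear_rate",
    "cross_viscosity",
    "viscosity_split",
]

CASES = ("newtonian", "gen_newtonian", "oldroyd_b", "gen_oldroyd_b")

#: short aliases accepted on the command line / in configs
CASE_ALIASES = {
    "n": "newtonian",
    "gn": "gen_newtonian",
    "od": "oldroyd_b",
    "gd": "gen_oldroyd_b",
}


def canonical_case(tag: str) -> str:
    tag = tag.strip().lower().replace("-", "_")
    tag = CASE_ALIASES.get(tag, tag)
    if tag not in CASES:
        raise ValueError(f"unknown constitutive case {tag!r}; expected one of {CASES}")
    return tag


@dataclass(frozen=True)
class CrossParams:
    """Generalized Cross model mu(g) = mu_inf + (mu0 - mu_inf)/(1 + (lam*g)^b)^a.

    Defaults are the whole-blood parameter set used throughout: zero-shear
    viscosity 0.16 Pa s, infinite-shear viscosity 0.0036 Pa s, time constant
    8.2 s, exponents a = 1.23, b = 0.64.
    """

    mu0: float = 0.16
    mu_inf: float = 0.0036
    lam: float = 8.2
    a: float = 1.23
    b: float = 0.64

    def __post_init__(self):
        if not (self.mu0 >= self.mu_inf > 0):
            raise ValueError("require mu0 >= mu_inf > 0")
        if self.lam <= 0 or self.a <= 0 or self.b <= 0:
            raise ValueError("require lam, a, b > 0")


@dataclass(frozen=True)
class OldroydParams:
    """Oldroyd-B viscosity split: solvent mu_n, elastic mu_v, relaxation lam_x.

    The retardation time is derived, lam_d = lam_x * mu_n/(mu_n + mu_v), so
    the constraint lam_d/lam_x = mu_n/(mu_n + mu_v) holds by construction.
    """

    mu_n: float = 0.0036
    mu_v: float = 0.0036
    lam_x: float = 8.2

    def __post_init__(self):
        if self.mu_n < 0 or self.mu_v < 0:
            raise ValueError("viscosities must be non-negative")
        if self.mu_n + self.mu_v <= 0:
            raise ValueError("total viscosity must be positive")
        if self.lam_x <= 0:
            raise ValueError("relaxation time must be positive")

    @property
    def mu_total(self) -> float:
        return self.mu_n + self.mu_v

    @property
    def beta(self) -> float:
        """Solvent fraction mu_n/(mu_n + mu_v) (= lam_d/lam_x)."""
        return self.mu_n / self.mu_total

    @property
    def lam_d(self) -> float:
        return self.lam_x * self.beta


@dataclass(frozen=True)
class CaseConfig:
    """Constitutive case selector bundling Cross and Oldroyd-B parameters."""

    case: str = "gen_oldroyd_b"
    cross: CrossParams = field(default_factory=CrossParams)
    oldroyd: OldroydParams = field(default_factory=OldroydParams)

    def __post_init__(self):
        object.__setattr__(self, "case", canonical_case(self.case))

    @property
    def is_viscoelastic(self) -> bool:
        return self.case in ("oldroyd_b", "gen_oldroyd_b") and self.oldroyd.mu_v > 0

    @property
    def is_shear_thinning(self) -> bool:
        return self.case in ("gen_newtonian", "gen_oldroyd_b")

    @property
    def mu_v(self) -> float:
        return self.oldroyd.mu_v if self.case in ("oldroyd_b", "gen_oldroyd_b") else 0.0

    def solvent_viscosity(self, gamma_dot):
        """Dimensional solvent viscosity mu_n, constant or Cross."""
        if self.is_shear_thinning:
            return cross_viscosity(gamma_dot, self.cross)
        return np.full_like(np.asarray(gamma_dot, dtype=float), self.cross.mu_inf)


def strain_rate_tensor(grad_u: np.ndarray) -> np.ndarray:
    """Symmetric part V = (grad u + grad u^T)/2 of a velocity gradient.

    Accepts any array of shape (..., 2, 2); the antisymmetric (rotation)
    part is discarded and trace(V) equals the divergence.
    """
    grad_u = np.asarray(grad_u, dtype=float)
    if not np.all(np.isfinite(grad_u)):
        raise ValueError("velocity gradient must be finite")
    return 0.5 * (grad_u + np.swapaxes(grad_u, -1, -2))


def shear_rate(V: np.ndarray) -> np.ndarray:
    """Scalar shear rate gamma_dot = sqrt(2 V:V) of a strain-rate tensor."""
    V = np.asarray(V, dtype=float)
    vv = np.einsum("...ij,...ij->...", V, V)
    return np.sqrt(2.0 * vv)


def cross_viscosity(gamma_dot, p: CrossParams):
    """Generalized Cross viscosity; monotone from mu0 (g=0) down to mu_inf."""
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rate must be non-negative")
    mu = p.mu_inf + (p.mu0 - p.mu_inf) / (1.0 + (p.lam * g) ** p.b) ** p.a
    return mu if mu.shape else float(mu)


def cross_viscosity_derivative(gamma_dot, p: CrossParams):
    """d mu/d gamma_dot of the Cross law (<= 0); used by the Newton Jacobian."""
    g = np.asarray(gamma_dot, dtype=float)
    lg = p.lam * g
    lgb = lg**p.b
    dmu = (
        -(p.mu0 - p.mu_inf)
        * p.a
        * p.b
        * lgb
        / np.where(g > 0, g, 1.0)
        / (1.0 + lgb) ** (p.a + 1.0)
    )
    return np.where(g > 0, dmu, 0.0)


def viscosity_split(case: CaseConfig, gamma_dot):
    """Solvent/elastic viscosity split at a given shear rate.

    Returns ``(mu_n_eff, mu_v, beta)`` where ``mu_n_eff`` multiplies the
    momentum Laplacian, ``mu_v`` feeds the extra-stress transport equation
    and ``beta = mu_n_eff/(mu_n_eff + mu_v)`` is the solvent fraction
    (identically 1 for the inelastic cases).
    """
    mu_n_eff = case.solvent_viscosity(gamma_dot)
    mu_v = case.mu_v
    beta = mu_n_eff / (mu_n_eff + mu_v)
    return mu_n_eff, mu_v, beta


@dataclass(frozen=True)
class DimensionlessRheology:
    """Dimensionless viscosity functions fed to the solver.

    Viscosities are normalised by the infinite-shear value ``mu_inf``, so the
    Newtonian solvent has unit dimensionless viscosity and the zero-shear
    plateau sits at ``mu0/mu_inf``.  The Cross time constant is scaled with
    the reference velocity/length pair (``lam_nd = lam * U_ref / L_ref``),
    which converts dimensionless shear rates back to 1/s inside the Cross
    law.  Defaults ``U_ref = 1 m/s``, ``L_ref = 6.2 mm`` follow the
    code-validation parameter set (see docs/methods.md).
    """

    case: CaseConfig
    U_ref: float = 1.0
    L_ref: float = 0.0062

    @property
    def lam_nd(self) -> float:
        return self.case.cross.lam * self.U_ref / self.L_ref

    @property
    def nu_ratio(self) -> float:
        return self.case.cross.mu0 / self.case.cross.mu_inf

    @property
    def nu_v(self) -> float:
        """Dimensionless elastic viscosity mu_v/mu_inf."""
        return self.case.mu_v / self.case.cross.mu_inf

    def nu_s(self, gamma_dot_nd):
        """Dimensionless solvent viscosity at dimensionless shear rate."""
        g = np.asarray(gamma_dot_nd, dtype=float)
        if not self.case.is_shear_thinning:
            return np.ones_like(g)
        scaled = replace(self.case.cross, lam=self.lam_nd)
        return cross_viscosity(g, scaled) / self.case.cross.mu_inf

    def nu_s_derivative(self, gamma_dot_nd):
        g = np.asarray(gamma_dot_nd, dtype=float)
        if not self.case.is_shear_thinning:
            return np.zeros_like(g)
        scaled = replace(self.case.cross, lam=self.lam_nd)
        return cross_viscosity_derivative(g, scaled) / self.case.cross.mu_inf
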