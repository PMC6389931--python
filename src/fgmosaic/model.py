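"""Forest-grassland mosaic model with human feedback.

The ecosystem is described by the forest fraction ``f`` (grassland is
``g = 1 - f``) and the fraction ``x`` of the population that prefers forest.
Fire-mediated recruitment turns grassland into forest at a rate ``w(f)`` that
switches on sharply once the landscape is forested enough; natural conversion
removes forest at rate ``nu``; society adds or removes forest through the
opinion-dependent feedback ``J(x) = h (1 - 2 x)``.  Opinions evolve by
imitation at social learning rate ``s``, weighted by the perceived relative
value ``u(f)`` of forest over grassland::

    df/dt = w(f) f (1 - f) - nu * f - J(x)
    dx/dt = s * x (1 - x) * u(f)

    w(f) = c / (1 + exp(-k * f/(1-f) + b))
    u(f) = r (1 - f)**m - q * f**n        (defaults give u = 1 - 2 f)

All derivatives of the vector field up to third order are available in closed
form; they feed the Hopf normal-form computation, where third-order accuracy
decides the sign of the first Lyapunov coefficient near Bautin points.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields, replace

import numpy as np
from scipy.special import expit

__all__ = [
    "ParameterSet",
    "DerivativeBundle",
    "F_DOMAIN_MAX",
    "recruitment_rate",
    "recruitment_rate_derivs",
    "perceived_value",
    "perceived_value_derivs",
    "human_feedback",
    "rhs",
    "forest_only_rhs",
    "jacobian",
    "derivatives",
]

#: Upper guard for the forest fraction: w(f) involves f/(1-f), which diverges
#: as f -> 1.  Values at or above this bound raise a domain error.
F_DOMAIN_MAX = 1.0 - 1e-9


@dataclass(frozen=True)
class ParameterSet:
    """Model constants.

    b : sharpness offset of the recruitment switch (dimensionless)
    c : maximum forest recruitment rate (per year)
    k : fire-mediated activation steepness (dimensionless)
    nu : natural forest-to-grassland conversion rate (per year)
    s : social learning rate (per year)
    h : magnitude of human influence (per year)
    r, q : gains for the perceived value of forest / grassland
    m, n : shape exponents of the perceived-value function
    """

    b: float = 11.0
    c: float = 1.0
    k: float = 10.0
    nu: float = 1.0
    s: float = 10.0
    h: float = 2.0
    r: float = 1.0
    q: float = 1.0
    m: float = 1.0
    n: float = 1.0

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError(f"c must be positive, got {self.c}")
        if not self.k > 0:
            raise ValueError(f"k must be positive, got {self.k}")
        if self.nu < 0:
            raise ValueError(f"nu must be non-negative, got {self.nu}")
        if self.s < 0:
            raise ValueError(f"s must be non-negative, got {self.s}")
        if self.h < 0:
            raise ValueError(f"h must be non-negative, got {self.h}")
        if self.r < 0 or self.q < 0:
            raise ValueError(f"r, q must be non-negative, got r={self.r}, q={self.q}")
        if self.m < 1 or self.n < 1:
            raise ValueError(f"m, n must be >= 1, got m={self.m}, n={self.n}")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def from_file(cls, path) -> "ParameterSet":
        """Load from a flat JSON or YAML mapping."""
        text = open(path).read()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ValueError("parameter file must contain a flat mapping")
        return cls.from_dict(data)

    def with_(self, **kw) -> "ParameterSet":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)

    @property
    def symmetric_preference(self) -> bool:
        """True when u(1/2) = 0, i.e. the interior equilibrium family is f = 1/2."""
        return abs(self.r * 0.5**self.m - self.q * 0.5**self.n) < 1e-14


def _check_f(f: float) -> None:
    if not 0.0 <= f < F_DOMAIN_MAX:
        raise ValueError(f"forest fraction f={f!r} outside the domain [0, 1)")


def recruitment_rate(f: float, p: ParameterSet) -> float:
    """Fire-mediated grassland-to-forest recruitment rate w(f).

    ``w(f) = c / (1 + exp(-k f/(1-f) + b))`` — a sharp sigmoidal switch from
    near 0 (sparse forest, fire kills recruits) to c (dense forest shades out
    fire-prone grass).
    """
    _check_f(f)
    phi = f / (1.0 - f)
    return p.c * expit(p.k * phi - p.b)


def recruitment_rate_derivs(f: float, p: ParameterSet) -> tuple[float, float, float, float]:
    """w(f) and its first three derivatives with respect to f.

    Chain rule through a = k*f/(1-f) - b and the logistic sigma(a):
    sigma' = sigma(1-sigma), sigma'' = sigma'(1-2 sigma),
    sigma''' = sigma'(1 - 6 sigma + 6 sigma^2).
    """
    _check_f(f)
    one = 1.0 - f
    phi1 = 1.0 / one**2
    phi2 = 2.0 / one**3
    phi3 = 6.0 / one**4
    a1 = p.k * phi1
    a2 = p.k * phi2
    a3 = p.k * phi3
    sig = expit(p.k * (f / one) - p.b)
    s1 = sig * (1.0 - sig)
    s2 = s1 * (1.0 - 2.0 * sig)
    s3 = s1 * (1.0 - 6.0 * sig + 6.0 * sig * sig)
    w0 = p.c * sig
    w1 = p.c * s1 * a1
    w2 = p.c * (s2 * a1 * a1 + s1 * a2)
    w3 = p.c * (s3 * a1**3 + 3.0 * s2 * a1 * a2 + s1 * a3)
    return w0, w1, w2, w3


def perceived_value(f: float, p: ParameterSet) -> float:
    """Perceived value of forest relative to grassland, u(f) = r(1-f)^m - q f^n."""
    return p.r * (1.0 - f) ** p.m - p.q * f**p.n


def _pow_derivs(base: float, e: float) -> tuple[float, float, float, float]:
    # base**e and derivatives w.r.t. base; guards 0**negative for low exponents
    v0 = base**e
    v1 = e * base ** (e - 1) if e >= 1 else 0.0
    v2 = e * (e - 1) * base ** (e - 2) if e >= 2 or base > 0 else 0.0
    v3 = e * (e - 1) * (e - 2) * base ** (e - 3) if e >= 3 or base > 0 else 0.0
    if e == 1:
        v2 = v3 = 0.0
    elif e == 2:
        v3 = 0.0
    return v0, v1, v2, v3


def perceived_value_derivs(f: float, p: ParameterSet) -> tuple[float, float, float, float]:
    """u(f) and its first three derivatives with respect to f."""
    g0, g1, g2, g3 = _pow_derivs(1.0 - f, p.m)
    h0, h1, h2, h3 = _pow_derivs(f, p.n)
    return (
        p.r * g0 - p.q * h0,
        -p.r * g1 - p.q * h1,
        p.r * g2 - p.q * h2,
        -p.r * g3 - p.q * h3,
    )


def human_feedback(x: float, p: ParameterSet) -> float:
    """Opinion-driven feedback J(x) = h (1 - 2 x).

    The forest equation carries ``-J(x)``: a forest-preferring majority
    (x > 1/2) reforests, a grassland-preferring majority deforests.
    """
    return p.h * (1.0 - 2.0 * x)


def rhs(state, p: ParameterSet) -> np.ndarray:
    """Time derivatives (df/dt, dx/dt) of the coupled model."""
    f, x = state
    w = recruitment_rate(f, p)
    df = w * (1.0 - f) * f - p.nu * f - human_feedback(x, p)
    dx = p.s * x * (1.0 - x) * perceived_value(f, p)
    return np.array([df, dx])


def _rhs_unchecked(state, p: ParameterSet) -> np.ndarray:
    """rhs without the lower domain guard, for integrator trial steps.

    The recruitment formula is regular for any f < 1; f >= 0 is a physical
    constraint enforced by the integration events, not by the formula.
    """
    f, x = state
    f = min(f, F_DOMAIN_MAX)
    w = p.c * expit(p.k * (f / (1.0 - f)) - p.b)
    df = w * (1.0 - f) * f - p.nu * f - p.h * (1.0 - 2.0 * x)
    dx = p.s * x * (1.0 - x) * perceived_value(f, p)
    return np.array([df, dx])


def forest_only_rhs(f: float, p: ParameterSet) -> float:
    """Uncoupled 1D forest dynamics w(f) f (1-f) - nu f (no human term)."""
    return recruitment_rate(f, p) * f * (1.0 - f) - p.nu * f


def jacobian(state, p: ParameterSet) -> np.ndarray:
    """Analytic Jacobian of the vector field at ``state``."""
    f, x = state
    w0, w1, _, _ = recruitment_rate_derivs(f, p)
    u0, u1, _, _ = perceived_value_derivs(f, p)
    ff = f * (1.0 - f)
    return np.array(
        [
            [w1 * ff + w0 * (1.0 - 2.0 * f) - p.nu, 2.0 * p.h],
            [p.s * x * (1.0 - x) * u1, p.s * (1.0 - 2.0 * x) * u0],
        ]
    )


@dataclass(frozen=True)
class DerivativeBundle:
    """Value, Jacobian and the symmetric second/third derivative tensors.

    ``second_order[i, j, k]`` is d^2 F_i / dy_j dy_k; ``third_order`` adds one
    index.  ``B`` and ``C`` contract the tensors with vectors (complex allowed),
    as needed for the Hopf normal-form coefficients.
    """

    value: np.ndarray
    jacobian: np.ndarray
    second_order: np.ndarray
    third_order: np.ndarray

    def B(self, u, v) -> np.ndarray:
        return np.einsum("ijk,j,k->i", self.second_order, u, v)

    def C(self, u, v, w) -> np.ndarray:
        return np.einsum("ijkl,j,k,l->i", self.third_order, u, v, w)


def derivatives(state, p: ParameterSet) -> DerivativeBundle:
    """Closed-form derivative tensors of the vector field up to third order.

    The forest equation is nonlinear in f only (x enters linearly through J),
    so its mixed partials with x vanish.  The opinion equation is the product
    s * x(1-x) * u(f), bilinear in the factors.
    """
    f, x = state
    w0, w1, w2, w3 = recruitment_rate_derivs(f, p)
    u0, u1, u2, u3 = perceived_value_derivs(f, p)
    ff = f * (1.0 - f)
    # F(f) = w(f) f (1-f) derivatives
    F1 = w1 * ff + w0 * (1.0 - 2.0 * f)
    F2 = w2 * ff + 2.0 * w1 * (1.0 - 2.0 * f) - 2.0 * w0
    F3 = w3 * ff + 3.0 * w2 * (1.0 - 2.0 * f) - 6.0 * w1
    xx = x * (1.0 - x)
    x1 = 1.0 - 2.0 * x

    B = np.zeros((2, 2, 2))
    B[0, 0, 0] = F2
    B[1, 0, 0] = p.s * xx * u2
    B[1, 0, 1] = B[1, 1, 0] = p.s * x1 * u1
    B[1, 1, 1] = -2.0 * p.s * u0

    C = np.zeros((2, 2, 2, 2))
    C[0, 0, 0, 0] = F3
    C[1, 0, 0, 0] = p.s * xx * u3
    C[1, 0, 0, 1] = C[1, 0, 1, 0] = C[1, 1, 0, 0] = p.s * x1 * u2
    C[1, 0, 1, 1] = C[1, 1, 0, 1] = C[1, 1, 1, 0] = -2.0 * p.s * u1

    val = np.array([w0 * ff - p.nu * f - human_feedback(x, p), p.s * xx * u0])
    jac = np.array([[F1 - p.nu, 2.0 * p.h], [p.s * xx * u1, p.s * x1 * u0]])
    return DerivativeBundle(value=val, jacobian=jac, second_order=B, third_order=C)
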