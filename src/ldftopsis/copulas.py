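"""Archimedean copula generators and the extended copula / co-copula.

An Archimedean copula is C(x, y) = theta_inv(theta(x) + theta(y)) for a strict
generator theta: (0, 1] -> [0, +inf], strictly decreasing with theta(1) = 0.
The pseudo-inverse clamps arguments beyond theta(0) to 0, which makes the
boundary condition C(x, 0) = 0 exact even for non-strict generators.  The
co-copula is the dual C*(x, y) = 1 - C(1-x, 1-y); it aggregates the
membership-side components in the LDFN operational laws while C handles the
non-membership side.

Five one-parameter families are supported (``family`` 1-5):

1. Gumbel        theta(x) = (-ln x)^lam,                lam >= 1
2. Clayton       theta(x) = (x^-lam - 1)/lam,           lam >= -1, lam != 0
3. Frank         theta(x) = -ln((e^-lam*x - 1)/(e^-lam - 1)),  lam != 0
4. Ali-Mikhail-Haq  theta(x) = ln((1 - lam(1-x))/x),    lam in [-1, 1)
5. Joe           theta(x) = -ln(1 - (1-x)^lam),         lam >= 1

The Clayton generator carries the conventional 1/lam factor: for lam > 0 this
is a positive rescaling (the induced copula is identical, since generators are
only defined up to a positive constant), and for lam in [-1, 0) it is what
makes theta decreasing and non-negative at all.  Frank carries the leading
minus sign for the same reason, and degrades gracefully to the independence
(product) copula for |lam| < 1e-5, where the closed form becomes 0/0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

_INF = math.inf

#: below this |lam| the Frank family is evaluated in its lam -> 0 limit,
#: the independence copula with generator -ln(x)
_FRANK_SWITCH = 1e-5

_FAMILY_NAMES = {1: "Gumbel", 2: "Clayton", 3: "Frank", 4: "Ali-Mikhail-Haq", 5: "Joe"}


@dataclass(frozen=True)
class CopulaSpec:
    """A generator family (1-5) with its parameter lam.

    Parameter domains: 1: lam >= 1; 2: lam >= -1, lam != 0; 3: lam != 0;
    4: lam in [-1, 1); 5: lam >= 1.  Violations raise ValueError at
    construction, and the generator is spot-checked to be strictly decreasing
    with theta(1) = 0.
    """

    family: int
    lam: float

    def __post_init__(self) -> None:
        fam, lam = self.family, self.lam
        if fam not in _FAMILY_NAMES:
            raise ValueError(f"family must be in 1..5, got {fam!r}")
        ok = {
            1: lam >= 1.0,
            2: lam >= -1.0 and lam != 0.0,
            3: lam != 0.0,
            4: -1.0 <= lam < 1.0,
            5: lam >= 1.0,
        }[fam]
        if not ok:
            raise ValueError(
                f"lam = {lam!r} outside the domain of family {fam} "
                f"({_FAMILY_NAMES[fam]})"
            )
        # numeric spot-check: strictly decreasing on a coarse grid, theta(1)=0
        if abs(generator(self, 1.0)) > 1e-12:
            raise ValueError(f"generator of {self} does not vanish at 1")
        grid = [0.1, 0.3, 0.5, 0.7, 0.9, 1.0]
        vals = [generator(self, x) for x in grid]
        if any(a <= b for a, b in zip(vals, vals[1:])):
            raise ValueError(f"generator of {self} is not strictly decreasing")

    @property
    def name(self) -> str:
        return _FAMILY_NAMES[self.family]


def generator(spec: CopulaSpec, x: float) -> float:
    """The additive generator theta(x) for x in (0, 1].

    Returns +inf where the limit diverges (x = 0 for strict generators).
    Raises for x < 0 or x > 1.
    """
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"generator argument {x!r} outside [0, 1]")
    lam = spec.lam
    fam = spec.family
    if fam == 1:
        if x == 0.0:
            return _INF
        return (-math.log(x)) ** lam
    if fam == 2:
        if x == 0.0:
            return _INF if lam > 0 else -1.0 / lam
        return (x**-lam - 1.0) / lam
    if fam == 3:
        if abs(lam) < _FRANK_SWITCH:
            return _INF if x == 0.0 else -math.log(x)
        if x == 0.0:
            return _INF
        num = math.expm1(-lam * x)
        den = math.expm1(-lam)
        return -math.log(num / den)
    if fam == 4:
        if x == 0.0:
            return _INF
        return math.log((1.0 - lam * (1.0 - x)) / x)
    # fam == 5
    if x == 0.0:
        return _INF
    inner = 1.0 - (1.0 - x) ** lam
    if inner <= 0.0:
        return _INF
    return -math.log(inner)


def generator_inv(spec: CopulaSpec, s: float) -> float:
    """The pseudo-inverse: theta^{-1}(s) for s <= theta(0), else 0.

    Raises for s < 0.  generator_inv(spec, 0) = 1 for every family.
    """
    if s < 0.0:
        raise ValueError(f"generator_inv argument {s!r} negative")
    if s == 0.0:
        return 1.0
    lam = spec.lam
    fam = spec.family
    if math.isinf(s):
        return 0.0
    if fam == 1:
        return math.exp(-(s ** (1.0 / lam)))
    if fam == 2:
        base = 1.0 + lam * s
        if base <= 0.0:  # beyond theta(0) for lam < 0
            return 0.0
        return base ** (-1.0 / lam)
    if fam == 3:
        if abs(lam) < _FRANK_SWITCH:
            return math.exp(-s)
        inner = math.exp(-s) * math.expm1(-lam)
        return -math.log1p(inner) / lam
    if fam == 4:
        return (1.0 - lam) / (math.exp(s) - lam)
    # fam == 5
    return 1.0 - (-math.expm1(-s)) ** (1.0 / lam)


def copula(spec: CopulaSpec, x: float, y: float) -> float:
    """C(x, y) = theta_inv(theta(x) + theta(y)); satisfies C(x, 1) = x,
    C(x, 0) = 0 and the 2-increasing rectangle inequality."""
    if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
        raise ValueError(f"copula arguments ({x!r}, {y!r}) outside [0, 1]^2")
    if x == 0.0 or y == 0.0:
        return 0.0
    if x == 1.0:
        return y
    if y == 1.0:
        return x
    value = generator_inv(spec, generator(spec, x) + generator(spec, y))
    return min(1.0, max(0.0, value))


def co_copula(spec: CopulaSpec, x: float, y: float) -> float:
    """C*(x, y) = 1 - C(1-x, 1-y) — the dual used on membership components;
    satisfies C*(x, 0) = x and C*(x, y) >= max(x, y)."""
    return 1.0 - copula(spec, 1.0 - x, 1.0 - y)


def scaled_generator_inv(spec: CopulaSpec, weight: float, x: float) -> float:
    """theta_inv(weight * theta(x)) with careful 0 * inf handling.

    By convention a zero weight annihilates the term (returns 1, the additive
    neutral under the generator), even when theta(x) = +inf; this is what makes
    zero-weight inputs vanish from weighted aggregations.
    """
    if weight == 0.0:
        return 1.0
    return generator_inv(spec, weight * generator(spec, x))
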