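"""The linear Diophantine fuzzy number (LDFN) value type.

An LDFN is a quadruple (mem, nonmem, ref_mem, ref_nonmem) of values in [0, 1]
together with an integer exponent ``q >= 1``, subject to

    ref_mem**q + ref_nonmem**q <= 1
    mem * ref_mem**q + nonmem * ref_nonmem**q <= 1

The reference parameters (ref_mem, ref_nonmem) weight the grades in the mixed
constraint, which is what lets both grades exceed the intuitionistic bound
mem + nonmem <= 1: e.g. (0.8, 0.9) is a valid pair of grades whenever the
references are small enough.  Classical intuitionistic / Pythagorean /
q-rung-orthopair values are the special cases with fixed references.

This module also provides the classical (product t-norm) algebra on LDFNs and
the score/accuracy comparison used for ideal-solution selection downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

TOL = 1e-9


class ConstraintError(ValueError):
    """An LDFN validity constraint is violated; the message names the
    inequality and its slack."""


@dataclass(frozen=True)
class LDFN:
    """A validated linear Diophantine fuzzy number.

    Construct via :func:`make_ldfn` (or :func:`from_pair`), which validate the
    defining inequalities; direct construction skips validation.
    """

    mem: float
    nonmem: float
    ref_mem: float
    ref_nonmem: float
    power: int = 1

    def as_tuple(self) -> Tuple[float, float, float, float]:
        return (self.mem, self.nonmem, self.ref_mem, self.ref_nonmem)


def _clamp_unit(value: float, name: str) -> float:
    """Clamp to [0,1] when within TOL of the boundary; reject otherwise."""
    if -TOL <= value < 0.0:
        return 0.0
    if 1.0 < value <= 1.0 + TOL:
        return 1.0
    if not (0.0 <= value <= 1.0):
        raise ConstraintError(
            f"{name} = {value!r} outside [0, 1] by more than tolerance {TOL}"
        )
    return float(value)


def make_ldfn(
    mem: float,
    nonmem: float,
    ref_mem: float,
    ref_nonmem: float,
    power: int = 1,
) -> LDFN:
    """Validate and construct an LDFN.

    Raises
    ------
    ConstraintError
        If a component lies outside [0, 1] (beyond 1e-9 tolerance), or one of
        the two defining inequalities fails; the message names the violated
        inequality and its slack.
    """
    if not isinstance(power, int) or isinstance(power, bool) or power < 1:
        raise ConstraintError(f"power must be an integer >= 1, got {power!r}")
    mem = _clamp_unit(float(mem), "mem")
    nonmem = _clamp_unit(float(nonmem), "nonmem")
    ref_mem = _clamp_unit(float(ref_mem), "ref_mem")
    ref_nonmem = _clamp_unit(float(ref_nonmem), "ref_nonmem")

    ref_sum = ref_mem**power + ref_nonmem**power
    if ref_sum > 1.0 + TOL:
        raise ConstraintError(
            "reference constraint ref_mem^q + ref_nonmem^q <= 1 violated: "
            f"{ref_sum:.12g} exceeds 1 by {ref_sum - 1.0:.3g}"
        )
    mixed = mem * ref_mem**power + nonmem * ref_nonmem**power
    if mixed > 1.0 + TOL:
        raise ConstraintError(
            "mixed constraint mem*ref_mem^q + nonmem*ref_nonmem^q <= 1 violated: "
            f"{mixed:.12g} exceeds 1 by {mixed - 1.0:.3g}"
        )
    return LDFN(mem, nonmem, ref_mem, ref_nonmem, power)


def from_pair(
    mem: float,
    nonmem: float,
    default_refs: Tuple[float, float] = (0.5, 0.5),
    power: int = 1,
) -> LDFN:
    """Lift a bare (mem, nonmem) grade pair to a full LDFN using configured
    default reference parameters.

    Expert elicitation often records only the grade pair; the references then
    come from a panel-wide convention.  The default (0.5, 0.5) admits every
    grade pair in [0,1]^2 at q = 1.
    """
    rho0, sigma0 = default_refs
    return make_ldfn(mem, nonmem, rho0, sigma0, power)


def complement(value: LDFN) -> LDFN:
    """The LDFN complement: grades swapped and references swapped.

    (mem, nonmem, ref_mem, ref_nonmem)^c = (nonmem, mem, ref_nonmem, ref_mem).
    An involution; it maps the crisp "full membership" value (1,0,1,0) to the
    anti-crisp (0,1,0,1), and preserves both validity constraints.
    """
    return LDFN(value.nonmem, value.mem, value.ref_nonmem, value.ref_mem, value.power)


def score(value: LDFN) -> float:
    """Score in [-1, 1]: ((mem - nonmem) + (ref_mem^q - ref_nonmem^q)) / 2.

    The grade difference and the reference difference contribute equally, so a
    value can only attain score 1 (resp. -1) when it is crisp (anti-crisp).
    """
    q = value.power
    return 0.5 * ((value.mem - value.nonmem) + (value.ref_mem**q - value.ref_nonmem**q))


def accuracy(value: LDFN) -> float:
    """Accuracy ((mem + nonmem) + (ref_mem^q + ref_nonmem^q)) / 2 — the total
    information content, used to break score ties."""
    q = value.power
    return 0.5 * ((value.mem + value.nonmem) + (value.ref_mem**q + value.ref_nonmem**q))


def compare(a: LDFN, b: LDFN) -> int:
    """Total order on LDFNs: by score, then accuracy, then lexicographically
    on (mem, nonmem, ref_mem, ref_nonmem).  Returns -1, 0 or 1."""
    for ka, kb in (
        (score(a), score(b)),
        (accuracy(a), accuracy(b)),
        (a.as_tuple(), b.as_tuple()),
    ):
        if ka < kb:
            return -1
        if ka > kb:
            return 1
    return 0


def _require_same_q(a: LDFN, b: LDFN) -> int:
    if a.power != b.power:
        raise ConstraintError(
            f"mixed exponents q = {a.power} and q = {b.power}; LDFN arithmetic "
            "requires a common q"
        )
    return a.power


def alg_add(a: LDFN, b: LDFN) -> LDFN:
    """Classical LDFN sum (probabilistic sum on mem/ref_mem, product on
    nonmem/ref_nonmem)."""
    q = _require_same_q(a, b)
    return make_ldfn(
        a.mem + b.mem - a.mem * b.mem,
        a.nonmem * b.nonmem,
        a.ref_mem + b.ref_mem - a.ref_mem * b.ref_mem,
        a.ref_nonmem * b.ref_nonmem,
        q,
    )


def alg_mult(a: LDFN, b: LDFN) -> LDFN:
    """Classical LDFN product — the dual of :func:`alg_add`."""
    q = _require_same_q(a, b)
    return make_ldfn(
        a.mem * b.mem,
        a.nonmem + b.nonmem - a.nonmem * b.nonmem,
        a.ref_mem * b.ref_mem,
        a.ref_nonmem + b.ref_nonmem - a.ref_nonmem * b.ref_nonmem,
        q,
    )


def alg_scalar(gamma: float, value: LDFN) -> LDFN:
    """Scalar multiple gamma * L for gamma > 0 in the classical algebra:
    1 - (1-x)^gamma on mem/ref_mem, x^gamma on nonmem/ref_nonmem."""
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma!r}")
    return make_ldfn(
        1.0 - (1.0 - value.mem) ** gamma,
        value.nonmem**gamma,
        1.0 - (1.0 - value.ref_mem) ** gamma,
        value.ref_nonmem**gamma,
        value.power,
    )


def alg_power(value: LDFN, gamma: float) -> LDFN:
    """Power L^gamma for gamma > 0 — the dual of :func:`alg_scalar`."""
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma!r}")
    return make_ldfn(
        value.mem**gamma,
        1.0 - (1.0 - value.nonmem) ** gamma,
        value.ref_mem**gamma,
        1.0 - (1.0 - value.ref_nonmem) ** gamma,
        value.power,
    )


def hesitancy(value: LDFN) -> float:
    """Hesitancy pi = 1 - (mem*ref_mem^q + nonmem*ref_nonmem^q) — the slack of
    the mixed constraint, guaranteed in [0, 1] for every valid LDFN and
    invariant under complement."""
    q = value.power
    pi = 1.0 - (value.mem * value.ref_mem**q + value.nonmem * value.ref_nonmem**q)
    return min(1.0, max(0.0, pi))
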