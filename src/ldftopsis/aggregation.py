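"""Copula operational laws on LDFNs and weighted copula aggregation operators.

The extended operational laws replace the product t-norm/t-conorm of the
classical LDFN algebra with an Archimedean copula C and its co-copula C*:
addition applies C* to the membership-side components and C to the
non-membership side; multiplication is the dual.  Iterating the addition law n
times collapses, through the additive generator, to

    n*L = (1 - th_inv(n*th(1-mem)), th_inv(n*th(nonmem)),
           1 - th_inv(n*th(1-ref_mem)), th_inv(n*th(ref_nonmem)))

and the weighted aggregation operator LDFWCA generalizes this with convex
weights inside the generator sums.  With the product copula (Gumbel lam = 1)
LDFWCA coincides with the classical weighted-averaging operator
(1 - prod(1-mem_i)^w_i, prod(nonmem_i)^w_i, ...).

Crisp components are absorbing: a 0 or 1 entering a generator sum with
positive weight contributes +inf, and the pseudo-inverse clamp returns the
corresponding crisp output.
"""

from __future__ import annotations

import math
from typing import Sequence

from .copulas import CopulaSpec, generator, generator_inv
from .ldfn import LDFN, ConstraintError, compare, make_ldfn

WEIGHT_TOL = 1e-9


def validate_weights(weights: Sequence[float], n: int | None = None) -> list[float]:
    """Check a weight vector: non-negative entries summing to 1 within 1e-9
    (and of length ``n`` when given).  Returns the weights as floats."""
    w = [float(x) for x in weights]
    if n is not None and len(w) != n:
        raise ValueError(f"expected {n} weights, got {len(w)}")
    if len(w) < 1:
        raise ValueError("weight vector must be non-empty")
    if any(x < 0.0 for x in w):
        raise ValueError(f"negative weight in {w}")
    total = math.fsum(w)
    if abs(total - 1.0) > WEIGHT_TOL:
        raise ValueError(f"weights sum to {total!r}, expected 1 within {WEIGHT_TOL}")
    return w


def _require_same_q(values: Sequence[LDFN]) -> int:
    qs = {v.power for v in values}
    if len(qs) != 1:
        raise ConstraintError(f"mixed exponents q in aggregation: {sorted(qs)}")
    return qs.pop()


def _wsum_inv(spec: CopulaSpec, pairs: Sequence[tuple[float, float]]) -> float:
    """theta_inv(sum w*theta(x)) over (w, x) pairs, skipping zero weights so
    that 0 * inf never poisons the sum."""
    total = 0.0
    for w, x in pairs:
        if w == 0.0:
            continue
        g = generator(spec, x)
        if math.isinf(g):
            return 0.0
        total += w * g
    return generator_inv(spec, total)


def cop_add(a: LDFN, b: LDFN, spec: CopulaSpec) -> LDFN:
    """Copula sum: C* on (mem, ref_mem), C on (nonmem, ref_nonmem).

    (0, 1, 0, 1) is the neutral element.  Reduces to the classical sum under
    the product copula.
    """
    q = _require_same_q([a, b])
    return make_ldfn(
        1.0 - _wsum_inv(spec, [(1.0, 1.0 - a.mem), (1.0, 1.0 - b.mem)]),
        _wsum_inv(spec, [(1.0, a.nonmem), (1.0, b.nonmem)]),
        1.0 - _wsum_inv(spec, [(1.0, 1.0 - a.ref_mem), (1.0, 1.0 - b.ref_mem)]),
        _wsum_inv(spec, [(1.0, a.ref_nonmem), (1.0, b.ref_nonmem)]),
        q,
    )


def cop_mult(a: LDFN, b: LDFN, spec: CopulaSpec) -> LDFN:
    """Copula product — the dual of :func:`cop_add`; (1, 0, 1, 0) is neutral."""
    q = _require_same_q([a, b])
    return make_ldfn(
        _wsum_inv(spec, [(1.0, a.mem), (1.0, b.mem)]),
        1.0 - _wsum_inv(spec, [(1.0, 1.0 - a.nonmem), (1.0, 1.0 - b.nonmem)]),
        _wsum_inv(spec, [(1.0, a.ref_mem), (1.0, b.ref_mem)]),
        1.0 - _wsum_inv(spec, [(1.0, 1.0 - a.ref_nonmem), (1.0, 1.0 - b.ref_nonmem)]),
        q,
    )


def cop_scalar(alpha: float, value: LDFN, spec: CopulaSpec) -> LDFN:
    """alpha * L for real alpha > 0 through the generator:

        (1 - th_inv(a*th(1-mem)), th_inv(a*th(nonmem)),
         1 - th_inv(a*th(1-ref_mem)), th_inv(a*th(ref_nonmem)))

    Agrees with the n-fold :func:`cop_add` chain at integer alpha and is
    additive: (a+b)L = aL + bL.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha!r}")
    return make_ldfn(
        1.0 - _wsum_inv(spec, [(alpha, 1.0 - value.mem)]),
        _wsum_inv(spec, [(alpha, value.nonmem)]),
        1.0 - _wsum_inv(spec, [(alpha, 1.0 - value.ref_mem)]),
        _wsum_inv(spec, [(alpha, value.ref_nonmem)]),
        value.power,
    )


def cop_power(value: LDFN, alpha: float, spec: CopulaSpec) -> LDFN:
    """L^alpha for real alpha > 0 — the dual of :func:`cop_scalar`."""
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha!r}")
    return make_ldfn(
        _wsum_inv(spec, [(alpha, value.mem)]),
        1.0 - _wsum_inv(spec, [(alpha, 1.0 - value.nonmem)]),
        _wsum_inv(spec, [(alpha, value.ref_mem)]),
        1.0 - _wsum_inv(spec, [(alpha, 1.0 - value.ref_nonmem)]),
        value.power,
    )


def ldfwca(
    values: Sequence[LDFN], weights: Sequence[float], spec: CopulaSpec
) -> LDFN:
    """Linear Diophantine fuzzy weighted copula aggregation.

    mem = 1 - th_inv(sum w_i th(1-mem_i)); nonmem = th_inv(sum w_i th(nonmem_i));
    references analogously.  Idempotent, bounded and monotone in each
    membership argument.
    """
    if len(values) == 0:
        raise ValueError("cannot aggregate an empty sequence")
    w = validate_weights(weights, n=len(values))
    q = _require_same_q(values)
    return make_ldfn(
        1.0 - _wsum_inv(spec, [(wi, 1.0 - v.mem) for wi, v in zip(w, values)]),
        _wsum_inv(spec, [(wi, v.nonmem) for wi, v in zip(w, values)]),
        1.0 - _wsum_inv(spec, [(wi, 1.0 - v.ref_mem) for wi, v in zip(w, values)]),
        _wsum_inv(spec, [(wi, v.ref_nonmem) for wi, v in zip(w, values)]),
        q,
    )


def ldfwoca(
    values: Sequence[LDFN], weights: Sequence[float], spec: CopulaSpec
) -> LDFN:
    """Ordered variant: inputs are sorted by descending score (ties by
    accuracy, then lexicographically) before the position weights apply, so
    the result is invariant under permutation of the input list."""
    import functools

    ordered = sorted(values, key=functools.cmp_to_key(compare), reverse=True)
    return ldfwca(ordered, weights, spec)


def ldfwhca(
    values: Sequence[LDFN],
    weights: Sequence[float],
    order_weights: Sequence[float],
    spec: CopulaSpec,
) -> LDFN:
    """Hybrid variant: each input is first rescaled by cop_scalar(n * w_i),
    then the ordered operator is applied with the position weights.  With
    uniform weights the rescaling is the identity and the hybrid reduces to
    the ordered operator."""
    w = validate_weights(weights, n=len(values))
    n = len(values)
    # a zero weight rescales to the additive neutral (0, 1, 0, 1)
    rescaled = [
        cop_scalar(n * wi, v, spec) if n * wi > 0 else LDFN(0.0, 1.0, 0.0, 1.0, v.power)
        for wi, v in zip(w, values)
    ]
    return ldfwoca(rescaled, order_weights, spec)
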