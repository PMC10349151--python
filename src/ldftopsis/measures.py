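"""Distance and entropy measures on LDF collections.

The generalized distance of exponent Upsilon (> 0, or inf for Chebyshev)
between two equal-length LDFN sequences averages the component-wise absolute
differences of all four components:

    d(A, B) = ( (1/(4n)) sum_i |d_mem|^U + |d_nonmem|^U + |d_refm|^U
                + |d_refnm|^U )^(1/U)

Upsilon = 1 is the Hamming distance, 2 the Euclidean, inf the Chebyshev
(max component difference).  The weighted variant places convex weights w_i
inside the sum; by default it keeps the literal 1/(4n) prefactor alongside
the weights (``strict``), which double-normalizes relative to the
conventional 1/4-only form available via ``strict=False``.  Under the
conventional form uniform weights recover the unweighted distance exactly.

The entropy of a collection averages, per element,

    (1 - d(I, I^c)) * (1 + pi) / 2

where d is the single-element Hamming distance to the complement and pi is
the hesitancy (the slack of the mixed validity constraint).  Crisp elements
have entropy 0; the maximally fuzzy value (0.5, 0.5, 0.5, 0.5) has 0.75; the
measure is invariant under complement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .ldfn import LDFN, complement, hesitancy


@dataclass(frozen=True)
class DistanceSpec:
    """Distance configuration: exponent Upsilon > 0 (math.inf = Chebyshev),
    optional weights, and the normalization convention for the weighted form."""

    exponent: float = 1.0
    weights: tuple[float, ...] | None = None
    strict: bool = True

    def __post_init__(self) -> None:
        if not (self.exponent > 0.0):
            raise ValueError(f"exponent must be positive, got {self.exponent!r}")


def _component_diffs(a: LDFN, b: LDFN) -> tuple[float, float, float, float]:
    return (
        abs(a.mem - b.mem),
        abs(a.nonmem - b.nonmem),
        abs(a.ref_mem - b.ref_mem),
        abs(a.ref_nonmem - b.ref_nonmem),
    )


def gdm(a: Sequence[LDFN], b: Sequence[LDFN], spec: DistanceSpec | None = None) -> float:
    """Generalized distance between equal-length LDFN sequences, in [0, 1].

    Zero iff the sequences are componentwise equal; symmetric; monotone in
    each component difference.
    """
    spec = spec or DistanceSpec()
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("distance of empty sequences is undefined")
    u = spec.exponent
    if math.isinf(u):
        return max(max(_component_diffs(x, y)) for x, y in zip(a, b))
    n = len(a)
    total = math.fsum(
        d**u for x, y in zip(a, b) for d in _component_diffs(x, y)
    )
    return (total / (4.0 * n)) ** (1.0 / u)


def wgdm(a: Sequence[LDFN], b: Sequence[LDFN], spec: DistanceSpec) -> float:
    """Weighted generalized distance with convex weights per position.

    ``spec.strict`` keeps the 1/(4n) prefactor together with the weights
    (the literal definition); ``strict=False`` uses the conventional 1/4
    prefactor, under which uniform weights reduce to :func:`gdm`.
    """
    from .aggregation import validate_weights

    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if spec.weights is None:
        raise ValueError("wgdm requires spec.weights")
    w = validate_weights(spec.weights, n=len(a))
    u = spec.exponent
    if math.isinf(u):
        return max(
            max(_component_diffs(x, y)) for wi, (x, y) in zip(w, zip(a, b)) if wi > 0
        )
    prefactor = 1.0 / (4.0 * len(a)) if spec.strict else 0.25
    total = math.fsum(
        wi * d**u
        for wi, (x, y) in zip(w, zip(a, b))
        for d in _component_diffs(x, y)
    )
    return (prefactor * total) ** (1.0 / u)


def element_entropy(value: LDFN) -> float:
    """Entropy of a single LDFN: (1 - d(I, I^c)) * (1 + pi)/2 with the
    single-element Hamming distance and pi the mixed-constraint slack."""
    d = gdm([value], [complement(value)], DistanceSpec(exponent=1.0))
    return (1.0 - d) * (1.0 + hesitancy(value)) / 2.0


def entropy(collection: Sequence[LDFN]) -> float:
    """Mean per-element entropy of a non-empty LDFN collection, in [0, 1]."""
    if len(collection) == 0:
        raise ValueError("entropy of an empty collection is undefined")
    return math.fsum(element_entropy(v) for v in collection) / len(collection)
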