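"""Embedded benchmark data and the seeded random-panel generator.

The benchmark is an EEG classifier-selection case study: three decision
experts rate five classifier alternatives (k-NN, GMM, decision tree, naive
Bayes, probabilistic neural network) against five entropy-feature criteria
(sample, spectral, bispectrum, approximate and Renyi entropy), all benefit
criteria, as bare membership/non-membership pairs.  No EEG signals are
processed here — the entropies are criterion labels only.

:func:`eeg_case_reference` carries the reported intermediate values of the
case study that are arithmetically consistent with one another (closeness
indices of the experts, the per-expert distances of each alternative to the
positive/negative ideals, and the per-expert relative closeness); they serve
as inputs for cross-checking the closing arithmetic of the pipeline.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .ldfn import from_pair, make_ldfn, LDFN
from .topsis import DecisionMatrix, ExpertPanel, Sense

ALTERNATIVES = ("P1", "P2", "P3", "P4", "P5")
ALTERNATIVE_NAMES = {
    "P1": "k-nearest neighbour",
    "P2": "Gaussian mixture model",
    "P3": "decision tree",
    "P4": "naive Bayes classifier",
    "P5": "probabilistic neural network",
}
CRITERIA = ("C1", "C2", "C3", "C4", "C5")
CRITERION_NAMES = {
    "C1": "sample entropy",
    "C2": "spectral entropy",
    "C3": "bispectrum entropy",
    "C4": "approximate entropy",
    "C5": "Renyi entropy",
}

# grade pairs per expert, rows = P1..P5, columns = C1..C5
_EXPERT_PAIRS = (
    (  # expert 1
        ((0.8, 0.9), (0.8, 0.9), (0.1, 0.1), (0.9, 0.1), (0.9, 0.1)),
        ((0.3, 0.9), (0.3, 0.2), (0.9, 0.5), (0.7, 0.9), (0.9, 0.1)),
        ((0.2, 0.1), (0.2, 0.9), (0.3, 0.7), (0.4, 0.2), (0.2, 0.9)),
        ((0.7, 0.6), (0.8, 0.3), (0.5, 0.8), (0.4, 0.4), (0.8, 0.9)),
        ((0.6, 0.7), (0.1, 0.3), (0.6, 0.1), (0.8, 0.7), (0.9, 0.1)),
    ),
    (  # expert 2
        ((0.7, 0.7), (0.9, 0.1), (0.9, 0.8), (0.9, 0.1), (0.8, 0.9)),
        ((0.5, 0.6), (0.2, 0.9), (0.3, 0.1), (0.2, 0.9), (0.4, 0.9)),
        ((0.2, 0.9), (0.5, 0.3), (0.5, 0.2), (0.3, 0.3), (0.5, 0.6)),
        ((0.1, 0.5), (0.8, 0.9), (0.9, 0.8), (0.9, 0.9), (0.7, 0.8)),
        ((0.3, 0.6), (0.9, 1.0), (0.9, 0.8), (0.6, 0.9), (0.2, 0.9)),
    ),
    (  # expert 3
        ((0.2, 0.8), (0.3, 0.8), (0.2, 0.5), (0.8, 0.8), (0.7, 0.9)),
        ((0.7, 0.8), (0.4, 0.9), (0.1, 0.5), (0.9, 0.9), (0.2, 0.1)),
        ((0.3, 0.6), (0.6, 0.4), (0.3, 0.6), (0.4, 0.9), (0.8, 0.3)),
        ((0.2, 0.9), (0.7, 0.8), (0.8, 0.9), (0.9, 0.4), (0.7, 0.6)),
        ((0.5, 0.4), (0.2, 0.9), (0.8, 0.9), (0.9, 0.4), (0.6, 0.7)),
    ),
)


def eeg_classifier_panel(
    default_refs: tuple[float, float] = (0.5, 0.5), power: int = 1
) -> ExpertPanel:
    """The three-expert, 5x5, all-benefit EEG classifier-selection panel.

    Pair-only cells are lifted to full LDFNs with the given default reference
    parameters (every cell is valid under the default (0.5, 0.5) at q = 1).
    """
    criteria = tuple((c, "benefit") for c in CRITERIA)
    matrices = tuple(
        DecisionMatrix(
            ALTERNATIVES,
            criteria,
            tuple(
                tuple(from_pair(mem, nonmem, default_refs, power) for mem, nonmem in row)
                for row in expert
            ),
        )
        for expert in _EXPERT_PAIRS
    )
    return ExpertPanel(matrices)


def eeg_case_reference() -> dict:
    """Reported intermediate values of the case study used as cross-check
    inputs: expert closeness indices and the (rounded) expert weights derived
    from them, per-expert DIS+/DIS- per alternative, and per-expert relative
    closeness.  Distance/closeness blocks are indexed [expert][alternative]."""
    return {
        "closeness_indices": [0.613, 0.728, 0.707],
        "expert_weights": [0.2995, 0.3553, 0.3452],
        "dis_plus": [
            [0.1018, 0.2190, 0.1941, 0.1700, 0.1029],
            [0.0955, 0.2290, 0.1339, 0.1675, 0.1741],
            [0.1927, 0.1823, 0.1631, 0.0749, 0.0828],
        ],
        "dis_minus": [
            [0.2343, 0.1013, 0.1519, 0.1541, 0.2038],
            [0.2175, 0.0514, 0.1709, 0.1511, 0.1537],
            [0.0856, 0.1933, 0.1877, 0.1592, 0.1547],
        ],
        "rci": [
            [0.697, 0.316, 0.439, 0.575, 0.664],
            [0.695, 0.183, 0.561, 0.474, 0.469],
            [0.308, 0.515, 0.535, 0.680, 0.651],
        ],
    }


def random_panel(
    seed: int,
    n: int = 5,
    m: int = 5,
    e: int = 3,
    q: int = 1,
    all_benefit: bool = False,
) -> ExpertPanel:
    """A reproducible random valid panel: n alternatives, m criteria, e
    experts, common exponent q.

    Reference pairs are drawn uniformly from the region ref_mem^q +
    ref_nonmem^q <= 1 and grades uniformly subject to the mixed constraint,
    both by rejection sampling; criterion senses are random unless
    ``all_benefit``.
    """
    if n < 2 or m < 1 or e < 1:
        raise ValueError(f"need n >= 2, m >= 1, e >= 1, got {(n, m, e)}")
    rng = np.random.default_rng(seed)

    def sample_cell() -> LDFN:
        while True:
            rho, sigma = rng.uniform(size=2)
            if rho**q + sigma**q <= 1.0:
                break
        while True:
            mem, nonmem = rng.uniform(size=2)
            if mem * rho**q + nonmem * sigma**q <= 1.0:
                break
        return make_ldfn(mem, nonmem, rho, sigma, q)

    alternatives = tuple(f"A{i + 1}" for i in range(n))
    senses: tuple[Sense, ...] = tuple(
        "benefit" if all_benefit or rng.uniform() < 0.5 else "cost" for _ in range(m)
    )
    criteria = tuple((f"G{j + 1}", s) for j, s in zip(range(m), senses))
    matrices = tuple(
        DecisionMatrix(
            alternatives,
            criteria,
            tuple(tuple(sample_cell() for _ in range(m)) for _ in range(n)),
        )
        for _ in range(e)
    )
    return ExpertPanel(matrices)
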