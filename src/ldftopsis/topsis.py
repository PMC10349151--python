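"""Three-phase extended TOPSIS for multi-expert LDF decision panels.

Given one LDFN decision matrix per expert (rows = alternatives, columns =
criteria with benefit/cost senses), the algorithm derives both the expert
weights and the criterion weights from the data before ranking:

Phase 1 — expert weights.  Cost columns are complemented (normalization);
the expert matrices are aggregated cell-wise by the weighted copula operator
into a group decision ideal solution (GDIS), and the per-cell score-max /
score-min expert opinions form the right and left ideal solutions (GRIS /
GLIS).  Each expert's matrix is scored by its generalized distance to the
three ideals: close to the extremes and far from the consensus means a
distinctive, informative expert.  The closeness index

    CI_k = (D_GRIS + D_GLIS) / (D_GDIS + D_GRIS + D_GLIS)

normalized over experts gives the expert weights w_k.

Phase 2 — criterion weights.  The matrices are re-aggregated with the expert
weights (RGDIS); each column's mean cell entropy E(C_j) measures how fuzzy
that criterion's assessments are, and the entropy-weight method

    gamma_j = (1 - E(C_j)) / (m - sum_j E(C_j))

gives sharper criteria more weight.

Phase 3 — ranking.  Per expert, cells are rescaled by cop_scalar(gamma_j);
the per-column score-max/min cells are the positive/negative ideal solutions
(PIS/NIS); each alternative's weighted distances to them give the relative
closeness RCI = DIS- / (DIS+ + DIS-), and the final closeness is the
expert-weighted mean FC(A_i) = sum_k w_k RCI_k(A_i), ranked descending.
A ``collective_phase3`` variant instead merges the experts into one matrix
(weighted by w_k) before phase 3, in which case FC is that single matrix's
RCI.
"""

from __future__ import annotations

import functools
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .aggregation import ldfwca, cop_scalar, validate_weights
from .copulas import CopulaSpec
from .ldfn import LDFN, ConstraintError, compare, complement as ldfn_complement
from .measures import DistanceSpec, element_entropy, gdm, wgdm

Sense = Literal["benefit", "cost"]


@dataclass(frozen=True)
class DecisionMatrix:
    """An alternatives x criteria grid of LDFNs with criterion senses."""

    alternatives: tuple[str, ...]
    criteria: tuple[tuple[str, Sense], ...]
    cells: tuple[tuple[LDFN, ...], ...]

    def __post_init__(self) -> None:
        n, m = len(self.alternatives), len(self.criteria)
        if n < 2 or m < 1:
            raise ValueError(f"need >= 2 alternatives and >= 1 criterion, got {n}x{m}")
        if len(self.cells) != n or any(len(row) != m for row in self.cells):
            raise ValueError("cell grid shape does not match labels")
        for label, sense in self.criteria:
            if sense not in ("benefit", "cost"):
                raise ValueError(f"criterion {label!r} has invalid sense {sense!r}")
        qs = {cell.power for row in self.cells for cell in row}
        if len(qs) != 1:
            raise ConstraintError(f"mixed exponents q within a matrix: {sorted(qs)}")

    @property
    def n_alternatives(self) -> int:
        return len(self.alternatives)

    @property
    def n_criteria(self) -> int:
        return len(self.criteria)

    def row(self, i: int) -> tuple[LDFN, ...]:
        return self.cells[i]

    def column(self, j: int) -> tuple[LDFN, ...]:
        return tuple(row[j] for row in self.cells)

    def map_cells(self, fn) -> "DecisionMatrix":
        return DecisionMatrix(
            self.alternatives,
            self.criteria,
            tuple(tuple(fn(cell, i, j) for j, cell in enumerate(row))
                  for i, row in enumerate(self.cells)),
        )


@dataclass(frozen=True)
class ExpertPanel:
    """One DecisionMatrix per expert (congruent shapes and labels) plus the
    within-panel aggregation weights (default uniform)."""

    matrices: tuple[DecisionMatrix, ...]
    agg_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.matrices) < 1:
            raise ValueError("panel needs at least one expert")
        first = self.matrices[0]
        for k, mat in enumerate(self.matrices[1:], start=2):
            if (mat.alternatives != first.alternatives
                    or mat.criteria != first.criteria):
                raise ValueError(f"expert {k} matrix labels/senses differ from expert 1")
        if self.agg_weights is not None:
            validate_weights(self.agg_weights, n=len(self.matrices))

    @property
    def n_experts(self) -> int:
        return len(self.matrices)

    def weights(self) -> list[float]:
        if self.agg_weights is not None:
            return list(self.agg_weights)
        e = self.n_experts
        return [1.0 / e] * e


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the pipeline.

    family/lam pick the Archimedean copula (default Clayton, lam = 1 — the
    family whose closed form the aggregation steps are stated in); upsilon is
    the distance exponent (default 1, Hamming); q the LDFN exponent;
    default_refs lifts pair-only inputs to quadruples; strict_eq13 selects the
    literal weighted-distance normalization; collective_phase3 switches phase
    3 to the single merged-matrix variant; digits_weights/digits_closeness
    control report rounding only.
    """

    family: int = 2
    lam: float = 1.0
    upsilon: float = 1.0
    q: int = 1
    default_refs: tuple[float, float] = (0.5, 0.5)
    strict_eq13: bool = True
    collective_phase3: bool = False
    digits_weights: int = 4
    digits_closeness: int = 3
    seed: int | None = None

    def copula_spec(self) -> CopulaSpec:
        return CopulaSpec(self.family, self.lam)

    def distance_spec(self, weights: Sequence[float] | None = None) -> DistanceSpec:
        w = tuple(float(x) for x in weights) if weights is not None else None
        return DistanceSpec(exponent=self.upsilon, weights=w, strict=self.strict_eq13)


@dataclass
class TopsisTrace:
    """Every intermediate artifact of a pipeline run."""

    config: PipelineConfig
    panel: ExpertPanel
    normalized: tuple[DecisionMatrix, ...] = ()
    gdis: DecisionMatrix | None = None
    gris: DecisionMatrix | None = None
    glis: DecisionMatrix | None = None
    dgdis: list[list[float]] = field(default_factory=list)  # expert x alternative
    dgris: list[list[float]] = field(default_factory=list)
    dglis: list[list[float]] = field(default_factory=list)
    closeness_indices: list[float] = field(default_factory=list)
    expert_weights: list[float] = field(default_factory=list)
    rgdis: DecisionMatrix | None = None
    criterion_entropies: list[float] = field(default_factory=list)
    criterion_weights: list[float] = field(default_factory=list)
    weighted_matrices: tuple[DecisionMatrix, ...] = ()
    pis: list[list[LDFN]] = field(default_factory=list)  # per expert: m cells
    nis: list[list[LDFN]] = field(default_factory=list)
    dis_plus: list[list[float]] = field(default_factory=list)  # expert x alternative
    dis_minus: list[list[float]] = field(default_factory=list)
    rci: list[list[float]] = field(default_factory=list)
    final_closeness: list[float] = field(default_factory=list)
    ranking: list[str] = field(default_factory=list)


def normalize(panel: ExpertPanel) -> ExpertPanel:
    """Benefit cells unchanged; cost cells replaced by the LDFN complement.
    The criterion labels keep their senses (already accounted for)."""
    def norm_matrix(mat: DecisionMatrix) -> DecisionMatrix:
        return mat.map_cells(
            lambda cell, i, j: ldfn_complement(cell)
            if mat.criteria[j][1] == "cost" else cell
        )

    return ExpertPanel(tuple(norm_matrix(m) for m in panel.matrices),
                       panel.agg_weights)


def _argmax_cell(cands: Sequence[LDFN]) -> LDFN:
    return max(cands, key=functools.cmp_to_key(compare))


def _argmin_cell(cands: Sequence[LDFN]) -> LDFN:
    return min(cands, key=functools.cmp_to_key(compare))


def group_ideals(
    panel: ExpertPanel, spec: CopulaSpec
) -> tuple[DecisionMatrix, DecisionMatrix, DecisionMatrix]:
    """Cell-wise aggregation and extreme selection over experts.

    GDIS aggregates each cell across experts with the panel weights via
    LDFWCA; GRIS/GLIS pick the score-maximal/minimal expert opinion per cell.
    """
    w = panel.weights()
    first = panel.matrices[0]

    def agg(cell, i, j):
        return ldfwca([m.cells[i][j] for m in panel.matrices], w, spec)

    gdis = first.map_cells(agg)
    gris = first.map_cells(
        lambda cell, i, j: _argmax_cell([m.cells[i][j] for m in panel.matrices])
    )
    glis = first.map_cells(
        lambda cell, i, j: _argmin_cell([m.cells[i][j] for m in panel.matrices])
    )
    return gdis, gris, glis


def expert_weights(
    panel: ExpertPanel,
    ideals: tuple[DecisionMatrix, DecisionMatrix, DecisionMatrix],
    dspec: DistanceSpec,
) -> tuple[list[list[float]], list[list[float]], list[list[float]],
           list[float], list[float]]:
    """Per-alternative distances to the three ideals, closeness indices and
    the resulting expert weights.

    Returns (dgdis, dgris, dglis, closeness_indices, weights), the distance
    blocks indexed [expert][alternative].
    """
    gdis, gris, glis = ideals
    plain = DistanceSpec(exponent=dspec.exponent)
    dgdis, dgris, dglis, cis = [], [], [], []
    for mat in panel.matrices:
        row_d = [gdm(mat.row(i), gdis.row(i), plain) for i in range(mat.n_alternatives)]
        row_r = [gdm(mat.row(i), gris.row(i), plain) for i in range(mat.n_alternatives)]
        row_l = [gdm(mat.row(i), glis.row(i), plain) for i in range(mat.n_alternatives)]
        dgdis.append(row_d)
        dgris.append(row_r)
        dglis.append(row_l)
        denom = math.fsum(row_d) + math.fsum(row_r) + math.fsum(row_l)
        if denom <= 1e-9:
            # the expert coincides with all three ideals (e.g. a panel of
            # identical matrices): equally close to everything
            warnings.warn(
                "expert matrix coincides with all three ideal solutions; "
                "closeness index set to 0.5",
                stacklevel=2,
            )
            cis.append(0.5)
        else:
            cis.append((math.fsum(row_r) + math.fsum(row_l)) / denom)
    return dgdis, dgris, dglis, cis, weights_from_closeness(cis)


def weights_from_closeness(closeness_indices: Sequence[float]) -> list[float]:
    """Normalize closeness indices to weights: w_k = CI_k / sum(CI)."""
    total = math.fsum(closeness_indices)
    if total <= 0.0:
        raise ValueError("all closeness indices are zero; weights undefined")
    return [ci / total for ci in closeness_indices]


def criteria_weights(
    panel: ExpertPanel, w_experts: Sequence[float], spec: CopulaSpec
) -> tuple[DecisionMatrix, list[float], list[float]]:
    """Entropy-weight method on the expert-weighted aggregate.

    RGDIS re-aggregates cells across experts with the expert weights; each
    criterion's entropy is the mean per-cell entropy of its column, and the
    weights are gamma_j = (1 - E_j) / (m - sum E).
    """
    w = validate_weights(w_experts, n=panel.n_experts)
    first = panel.matrices[0]
    rgdis = first.map_cells(
        lambda cell, i, j: ldfwca([m.cells[i][j] for m in panel.matrices], w, spec)
    )
    m = rgdis.n_criteria
    entropies = [
        math.fsum(element_entropy(c) for c in rgdis.column(j)) / rgdis.n_alternatives
        for j in range(m)
    ]
    denom = m - math.fsum(entropies)
    if denom <= 0.0:
        raise ValueError("all criterion entropies are 1; weights undefined")
    gammas = [(1.0 - e) / denom for e in entropies]
    return rgdis, entropies, gammas


def _phase3_single(
    mat: DecisionMatrix,
    gammas: Sequence[float],
    spec: CopulaSpec,
    dspec: DistanceSpec,
) -> tuple[DecisionMatrix, list[LDFN], list[LDFN], list[float], list[float], list[float]]:
    """Weighted-normalized matrix, PIS/NIS rows, DIS+/-, RCI for one matrix."""
    weighted = mat.map_cells(lambda cell, i, j: cop_scalar(gammas[j], cell, spec))
    pis = [_argmax_cell(weighted.column(j)) for j in range(mat.n_criteria)]
    nis = [_argmin_cell(weighted.column(j)) for j in range(mat.n_criteria)]
    wspec = DistanceSpec(
        exponent=dspec.exponent, weights=tuple(gammas), strict=dspec.strict
    )
    dis_plus, dis_minus, rci = [], [], []
    for i in range(mat.n_alternatives):
        dp = wgdm(weighted.row(i), pis, wspec)
        dm = wgdm(weighted.row(i), nis, wspec)
        dis_plus.append(dp)
        dis_minus.append(dm)
        if dp + dm == 0.0:
            warnings.warn(
                f"alternative {mat.alternatives[i]!r} equidistant (0) from PIS "
                "and NIS; relative closeness set to 0.5",
                stacklevel=3,
            )
            rci.append(0.5)
        else:
            rci.append(dm / (dp + dm))
    return weighted, pis, nis, dis_plus, dis_minus, rci


def per_expert_closeness(
    panel: ExpertPanel,
    gammas: Sequence[float],
    spec: CopulaSpec,
    dspec: DistanceSpec,
) -> tuple[tuple[DecisionMatrix, ...], list[list[LDFN]], list[list[LDFN]],
           list[list[float]], list[list[float]], list[list[float]]]:
    """Phase 3 run independently per expert; returns per-expert weighted
    matrices, PIS/NIS rows, DIS+/-, and RCI (all indexed [expert])."""
    gammas = validate_weights(gammas, n=panel.matrices[0].n_criteria)
    weighted, pis, nis, dplus, dminus, rcis = [], [], [], [], [], []
    for mat in panel.matrices:
        wmat, p, n_, dp, dm, rci = _phase3_single(mat, gammas, spec, dspec)
        weighted.append(wmat)
        pis.append(p)
        nis.append(n_)
        dplus.append(dp)
        dminus.append(dm)
        rcis.append(rci)
    return tuple(weighted), pis, nis, dplus, dminus, rcis


def finalize(
    rci: Sequence[Sequence[float]],
    w_experts: Sequence[float],
    alternatives: Sequence[str],
) -> tuple[list[float], list[str]]:
    """Final closeness FC(A_i) = sum_k w_k RCI_k(A_i) and the descending
    ranking; ties broken by label order with a warning."""
    w = validate_weights(w_experts, n=len(rci))
    n_alt = len(alternatives)
    fc = [
        math.fsum(w[k] * rci[k][i] for k in range(len(w)))
        for i in range(n_alt)
    ]
    order = sorted(range(n_alt), key=lambda i: (-fc[i], alternatives[i]))
    for a, b in zip(order, order[1:]):
        if fc[a] == fc[b]:
            warnings.warn(
                f"final closeness tie between {alternatives[a]!r} and "
                f"{alternatives[b]!r}; broken by label order",
                stacklevel=2,
            )
    return fc, [alternatives[i] for i in order]


def run(panel: ExpertPanel, config: PipelineConfig | None = None) -> TopsisTrace:
    """Execute the full three-phase algorithm, recording every intermediate."""
    config = config or PipelineConfig()
    spec = config.copula_spec()
    dspec = config.distance_spec()
    trace = TopsisTrace(config=config, panel=panel)

    normalized = normalize(panel)
    trace.normalized = normalized.matrices

    ideals = group_ideals(normalized, spec)
    trace.gdis, trace.gris, trace.glis = ideals

    (trace.dgdis, trace.dgris, trace.dglis,
     trace.closeness_indices, trace.expert_weights) = expert_weights(
        normalized, ideals, dspec
    )

    trace.rgdis, trace.criterion_entropies, trace.criterion_weights = (
        criteria_weights(normalized, trace.expert_weights, spec)
    )

    alternatives = list(panel.matrices[0].alternatives)
    if config.collective_phase3:
        collective = trace.rgdis
        wmat, pis, nis, dp, dm, rci = _phase3_single(
            collective, trace.criterion_weights, spec, dspec
        )
        trace.weighted_matrices = (wmat,)
        trace.pis, trace.nis = [pis], [nis]
        trace.dis_plus, trace.dis_minus = [dp], [dm]
        trace.rci = [rci]
        trace.final_closeness, trace.ranking = finalize([rci], [1.0], alternatives)
    else:
        (trace.weighted_matrices, trace.pis, trace.nis,
         trace.dis_plus, trace.dis_minus, trace.rci) = per_expert_closeness(
            normalized, trace.criterion_weights, spec, dspec
        )
        trace.final_closeness, trace.ranking = finalize(
            trace.rci, trace.expert_weights, alternatives
        )
    return trace
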