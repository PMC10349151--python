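"""The three-phase extended TOPSIS pipeline."""

import math
import warnings

import numpy as np
import pytest

from ldftopsis import (
    CopulaSpec,
    DecisionMatrix,
    DistanceSpec,
    ExpertPanel,
    LDFN,
    PipelineConfig,
    criteria_weights,
    eeg_classifier_panel,
    expert_weights,
    finalize,
    from_pair,
    group_ideals,
    make_ldfn,
    normalize,
    per_expert_closeness,
    random_panel,
    run,
    weights_from_closeness,
)
from ldftopsis.ldfn import complement

CLAYTON = CopulaSpec(2, 1.0)
HAMMING = DistanceSpec(exponent=1.0)


def pair_matrix(grid, senses=None, alternatives=None):
    n, m = len(grid), len(grid[0])
    alternatives = alternatives or tuple(f"A{i+1}" for i in range(n))
    senses = senses or ("benefit",) * m
    criteria = tuple((f"G{j+1}", s) for j, s in enumerate(senses))
    cells = tuple(tuple(from_pair(*c) for c in row) for row in grid)
    return DecisionMatrix(tuple(alternatives), criteria, cells)


class TestStructures:
    def test_matrix_shape_validation(self):
        with pytest.raises(ValueError):
            pair_matrix([[(0.5, 0.5)]])  # single alternative
        with pytest.raises(ValueError):
            DecisionMatrix(("A1", "A2"), (("G1", "benefit"),),
                           ((from_pair(0.5, 0.5),),))

    def test_panel_congruence(self):
        a = pair_matrix([[(0.5, 0.5)], [(0.4, 0.4)]])
        b = pair_matrix([[(0.5, 0.5)], [(0.4, 0.4)]], senses=("cost",))
        with pytest.raises(ValueError, match="expert 2"):
            ExpertPanel((a, b))


class TestNormalize:
    def test_benefit_panel_unchanged(self):
        panel = eeg_classifier_panel()
        assert normalize(panel).matrices == panel.matrices

    def test_cost_columns_are_complemented(self):
        mat = pair_matrix([[(0.6, 0.2), (0.3, 0.4)], [(0.1, 0.8), (0.9, 0.05)]],
                          senses=("benefit", "cost"))
        out = normalize(ExpertPanel((mat,))).matrices[0]
        assert out.cells[0][0] == mat.cells[0][0]
        assert out.cells[0][1] == complement(mat.cells[0][1])

    def test_involution_on_all_cost_panel(self):
        mat = pair_matrix([[(0.6, 0.2)], [(0.1, 0.8)]], senses=("cost",))
        panel = ExpertPanel((mat,))
        assert normalize(normalize(panel)).matrices == panel.matrices


class TestGroupIdeals:
    def test_identical_experts_collapse(self):
        mat = pair_matrix([[(0.6, 0.2)], [(0.1, 0.8)]])
        panel = ExpertPanel((mat, mat, mat))
        gdis, gris, glis = group_ideals(panel, CLAYTON)
        for ideal in (gdis, gris, glis):
            for row_a, row_b in zip(ideal.cells, mat.cells):
                for a, b in zip(row_a, row_b):
                    assert a.as_tuple() == pytest.approx(b.as_tuple(), abs=1e-9)

    def test_benchmark_extreme_picks_at_first_cell(self):
        # candidates (0.8,0.9), (0.7,0.7), (0.2,0.8) under equal references
        panel = eeg_classifier_panel()
        _, gris, glis = group_ideals(panel, CLAYTON)
        assert gris.cells[0][0].as_tuple()[:2] == (0.7, 0.7)
        assert glis.cells[0][0].as_tuple()[:2] == (0.2, 0.8)

    def test_two_expert_clayton_aggregate_membership(self):
        a = pair_matrix([[(0.2, 0.5)], [(0.5, 0.5)]])
        b = pair_matrix([[(0.8, 0.5)], [(0.5, 0.5)]])
        gdis, _, _ = group_ideals(ExpertPanel((a, b)), CLAYTON)
        assert gdis.cells[0][0].mem == pytest.approx(0.68)


class TestExpertWeights:
    def test_single_expert_gets_unit_weight(self):
        mat = pair_matrix([[(0.6, 0.2)], [(0.1, 0.8)]])
        panel = ExpertPanel((mat,))
        ideals = group_ideals(panel, CLAYTON)
        *_, cis, w = expert_weights(panel, ideals, HAMMING)
        assert w == [1.0]

    def test_weights_normalize_and_order_follows_closeness(self):
        panel = eeg_classifier_panel()
        ideals = group_ideals(panel, CLAYTON)
        *_, cis, w = expert_weights(panel, ideals, HAMMING)
        assert math.fsum(w) == pytest.approx(1.0, abs=1e-9)
        assert np.argsort(cis).tolist() == np.argsort(w).tolist()

    def test_weights_from_closeness_arithmetic(self):
        w = weights_from_closeness([0.2, 0.3, 0.5])
        assert w == pytest.approx([0.2, 0.3, 0.5])
        with pytest.raises(ValueError):
            weights_from_closeness([0.0, 0.0])

    def test_identical_matrices_yield_uniform_weights(self):
        mat = pair_matrix([[(0.6, 0.2)], [(0.1, 0.8)]])
        panel = ExpertPanel((mat, mat, mat))
        ideals = group_ideals(panel, CLAYTON)
        with pytest.warns(UserWarning, match="coincides"):
            *_, w = expert_weights(panel, ideals, HAMMING)
        assert w == pytest.approx([1 / 3] * 3)


class TestCriteriaWeights:
    def test_identical_columns_share_weight_equally(self):
        grid = [[(0.6, 0.2), (0.6, 0.2)], [(0.1, 0.8), (0.1, 0.8)]]
        panel = ExpertPanel((pair_matrix(grid), pair_matrix(grid)))
        _, entropies, gammas = criteria_weights(panel, [0.5, 0.5], CLAYTON)
        assert gammas == pytest.approx([0.5, 0.5])

    def test_crisp_column_gets_largest_weight(self):
        crisp = (1.0, 0.0, 1.0, 0.0)
        fuzzy = (0.5, 0.5)
        mat = DecisionMatrix(
            ("A1", "A2"),
            (("G1", "benefit"), ("G2", "benefit")),
            (
                (make_ldfn(*crisp), from_pair(*fuzzy)),
                (make_ldfn(*crisp), from_pair(*fuzzy)),
            ),
        )
        panel = ExpertPanel((mat,))
        _, entropies, gammas = criteria_weights(panel, [1.0], CLAYTON)
        assert entropies[0] == pytest.approx(0.0)
        assert gammas[0] > gammas[1]

    def test_weights_sum_to_one_on_random_panels(self):
        for seed in range(5):
            panel = normalize(random_panel(seed, n=4, m=3, e=2))
            ideals = group_ideals(panel, CLAYTON)
            *_, w = expert_weights(panel, ideals, HAMMING)
            _, _, gammas = criteria_weights(panel, w, CLAYTON)
            assert math.fsum(gammas) == pytest.approx(1.0, abs=1e-9)


class TestClosenessAndFinalize:
    def test_dominant_alternative_reaches_unit_closeness(self):
        grid = [[(0.9, 0.1), (0.9, 0.1)], [(0.3, 0.6), (0.2, 0.7)],
                [(0.5, 0.4), (0.4, 0.5)]]
        panel = ExpertPanel((pair_matrix(grid),))
        _, _, _, dplus, dminus, rci = per_expert_closeness(
            panel, [0.5, 0.5], CLAYTON, HAMMING)
        assert dplus[0][0] == pytest.approx(0.0, abs=1e-12)
        assert rci[0][0] == pytest.approx(1.0)

    def test_rci_bounded_on_random_panels(self):
        for seed, spec, u in [(0, CLAYTON, 1.0), (1, CopulaSpec(1, 2.0), 2.0),
                              (2, CopulaSpec(5, 1.5), math.inf)]:
            panel = normalize(random_panel(seed, n=4, m=4, e=2))
            gammas = [0.25] * 4
            *_, rci = per_expert_closeness(
                panel, gammas, spec, DistanceSpec(exponent=u))
            assert all(0.0 <= r <= 1.0 for row in rci for r in row)

    def test_finalize_weighted_mean_and_ranking(self):
        rci = [[0.697, 0.316], [0.695, 0.183], [0.308, 0.515]]
        w = [0.2995, 0.3553, 0.3452]
        fc, ranking = finalize(rci, w, ["P1", "P2"])
        assert fc[0] == pytest.approx(0.562, abs=5e-4)
        assert ranking == ["P1", "P2"]

    def test_single_expert_final_closeness_is_its_rci(self):
        fc, _ = finalize([[0.3, 0.9]], [1.0], ["A1", "A2"])
        assert fc == [0.3, 0.9]

    def test_tie_broken_by_label_with_warning(self):
        with pytest.warns(UserWarning, match="tie"):
            _, ranking = finalize([[0.5, 0.5]], [1.0], ["B", "A"])
        assert ranking == ["A", "B"]


class TestRun:
    def test_benchmark_trace_is_complete_and_normalized(self):
        trace = run(eeg_classifier_panel())
        assert math.fsum(trace.expert_weights) == pytest.approx(1.0, abs=1e-9)
        assert math.fsum(trace.criterion_weights) == pytest.approx(1.0, abs=1e-9)
        assert sorted(trace.ranking) == ["P1", "P2", "P3", "P4", "P5"]
        assert all(0.0 <= x <= 1.0 for x in trace.final_closeness)
        assert len(trace.rci) == 3 and len(trace.weighted_matrices) == 3

    def test_alternative_permutation_equivariance(self):
        panel = eeg_classifier_panel()
        perm = [2, 0, 4, 1, 3]
        permuted = ExpertPanel(tuple(
            DecisionMatrix(
                tuple(mat.alternatives[i] for i in perm),
                mat.criteria,
                tuple(mat.cells[i] for i in perm),
            )
            for mat in panel.matrices
        ))
        base = run(panel)
        moved = run(permuted)
        for pos, i in enumerate(perm):
            assert moved.final_closeness[pos] == pytest.approx(
                base.final_closeness[i], abs=1e-12)
        assert moved.ranking == base.ranking

    def test_collective_phase3_variant(self):
        trace = run(eeg_classifier_panel(),
                    PipelineConfig(collective_phase3=True))
        assert len(trace.rci) == 1
        assert trace.final_closeness == trace.rci[0]
        assert sorted(trace.ranking) == ["P1", "P2", "P3", "P4", "P5"]

    def test_raising_memberships_does_not_lower_final_closeness(self):
        config = PipelineConfig(family=1, lam=1.0)
        panel = random_panel(7, n=4, m=3, e=2, all_benefit=True)
        target = 1  # boost alternative A2 in every expert matrix

        def boost(mat):
            rows = list(mat.cells)
            rows[target] = tuple(
                LDFN(min(1.0, c.mem + 0.3 * (1 - c.mem)), c.nonmem,
                     c.ref_mem, c.ref_nonmem, c.power)
                for c in rows[target]
            )
            return DecisionMatrix(mat.alternatives, mat.criteria, tuple(rows))

        boosted = ExpertPanel(tuple(boost(m) for m in panel.matrices))
        before = run(panel, config).final_closeness[target]
        after = run(boosted, config).final_closeness[target]
        assert after >= before - 1e-9
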