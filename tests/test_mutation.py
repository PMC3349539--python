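"""Mutation protocol, transition matrices, robustness and evolvability."""

import dataclasses

import numpy as np
import pytest
import scipy.stats

from fflscape import (
    MOTIF_IDS,
    MutationConfig,
    evolvability,
    get_motif,
    mutate,
    robustness,
    sample_parameters,
    transition_matrices,
)
from fflscape.mutation import MUTABLE_FIELDS

SMALL = dict(n_parameter_sets=12, max_rounds=15, convergence_window=10**9)


def small_cfg(**kw):
    merged = {**SMALL, **kw}
    return MutationConfig(**merged)


class TestMutate:
    def _fields_changed(self, a, b):
        return [
            f.name
            for f in dataclasses.fields(a)
            if getattr(a, f.name) != getattr(b, f.name)
        ]

    def test_changes_exactly_one_field(self):
        topo = get_motif("I4")
        rng = np.random.default_rng(3)
        (params,) = sample_parameters(topo, 1, seed=8)
        for _ in range(200):
            mutant = mutate(params, topo, rng)
            assert len(self._fields_changed(params, mutant)) == 1

    def test_c1_sign_constraints_preserved(self):
        topo = get_motif("C1")
        rng = np.random.default_rng(4)
        params = sample_parameters(topo, 1, seed=2)[0]
        for _ in range(500):
            params = mutate(params, topo, rng)
            assert params.alpha_x > 1 and params.beta_x > 1 and params.beta_y > 1
            params.check_signs(topo)

    def test_parameter_choice_uniform_chi_square(self):
        """10,000 mutations of one circuit select each parameter uniformly."""
        topo = get_motif("C1")
        rng = np.random.default_rng(12)
        (params,) = sample_parameters(topo, 1, seed=0)
        counts = {f: 0 for f in MUTABLE_FIELDS}
        for _ in range(10_000):
            mutant = mutate(params, topo, rng)
            (changed,) = self._fields_changed(params, mutant)
            counts[changed] += 1
        stat, pvalue = scipy.stats.chisquare(list(counts.values()))
        assert pvalue > 1e-4

    def test_multimerization_stays_in_range(self):
        topo = get_motif("C1")
        rng = np.random.default_rng(6)
        params = sample_parameters(topo, 1, seed=4)[0]
        for _ in range(300):
            params = mutate(params, topo, rng)
            assert 1 <= params.n <= 4 and 1 <= params.m <= 4


class TestTransitionMatrices:
    def test_seeded_rerun_is_bit_reproducible(self):
        topo = get_motif("C1")
        cfg = small_cfg(seed=21)
        s1, a1 = transition_matrices(topo, cfg)
        s2, a2 = transition_matrices(topo, cfg)
        assert s1.values.equals(s2.values)
        assert a1.values.equals(a2.values)

    def test_diagonal_dominates_for_c1(self):
        """Most single mutations leave the class unchanged (cf. the reference
        matrices, where the C1 diagonal carries ~0.95 of the mass)."""
        single, accum = transition_matrices(get_motif("C1"), small_cfg(seed=21))
        assert robustness(single) > 0.5
        assert single.values.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert accum.values.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_vanishing_kernel_puts_all_mass_on_diagonal(self):
        cfg = small_cfg(n_parameter_sets=6, max_rounds=4, kernel_scale=0.0, seed=9)
        single, accum = transition_matrices(get_motif("I2"), cfg)
        assert robustness(single) == pytest.approx(1.0)
        assert robustness(accum) == pytest.approx(1.0)
        assert evolvability(single, accum) == pytest.approx(0.0)

    def test_zero_rounds_give_empty_matrix(self):
        cfg = small_cfg(n_parameter_sets=4, max_rounds=0, seed=1)
        single, accum = transition_matrices(get_motif("C1"), cfg)
        assert (single.values.values == 0).all()
        assert (accum.values.values == 0).all()


class TestReferenceMatrices:
    def test_printed_spot_values(self, reference_transitions):
        c1 = reference_transitions[("C1", "single")]
        assert c1.values.loc["G+", "P+T+"] == pytest.approx(0.008)
        assert (c1.values.loc["P-T+"] == 0).all()
        i1 = reference_transitions[("I1", "accumulated")]
        assert i1.values.loc["P+T+", "P+T+"] == pytest.approx(0.229)

    def test_entries_nonnegative_and_totals_near_one(self, reference_transitions):
        for (mid, regime), tm in reference_transitions.items():
            assert (tm.values.values >= 0).all()
            total = tm.values.values.sum()
            if (mid, regime) == ("C3", "single"):
                # this printed block totals 1.106 in the source table
                assert total == pytest.approx(1.106, abs=1e-9)
            else:
                assert total == pytest.approx(1.0, abs=0.02)

    def test_c1_single_robustness_from_printed_diagonal(self, reference_transitions):
        assert robustness(reference_transitions[("C1", "single")]) == pytest.approx(
            0.948, abs=1e-9
        )

    def test_i3_single_robustness_from_printed_diagonal(self, reference_transitions):
        assert robustness(reference_transitions[("I3", "single")]) == pytest.approx(
            0.818, abs=1e-9
        )

    def test_identity_like_matrix_has_unit_robustness(self, reference_transitions):
        tm = reference_transitions[("C1", "single")]
        ident = dataclasses.replace(
            tm, values=tm.values * 0 + np.eye(6) / 6
        )
        assert robustness(ident) == pytest.approx(1.0)


class TestEvolvability:
    def test_equal_regimes_give_zero(self, reference_transitions):
        tm = reference_transitions[("C2", "single")]
        assert evolvability(tm, tm) == 0.0

    def test_c1_from_printed_diagonals(self, reference_evolvability):
        assert reference_evolvability["C1"] == pytest.approx(1 - 0.649 / 0.948, abs=1e-9)
        assert reference_evolvability["C1"] == pytest.approx(0.315, abs=5e-3)

    def test_i1_from_printed_diagonals(self, reference_evolvability):
        assert reference_evolvability["I1"] == pytest.approx(1 - 0.546 / 0.930, abs=1e-9)
        assert reference_evolvability["I1"] == pytest.approx(0.413, abs=5e-3)

    def test_all_motifs_in_unit_interval(self, reference_evolvability):
        assert ((reference_evolvability >= 0) & (reference_evolvability <= 1)).all()

    def test_most_abundant_motifs_have_top_two_evolvability(
        self, reference_evolvability
    ):
        top2 = set(reference_evolvability.sort_values(ascending=False).index[:2])
        assert top2 == {"C1", "I1"}
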