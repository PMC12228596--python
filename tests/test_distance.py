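"""Amplitude embedding, SWAP test, quantum Euclidean distance, ranking."""

import math

import numpy as np
import pytest

from qdock import (
    DEFAULT_RANGES,
    EmbeddedVector,
    InteractionSite,
    MoleculeChain,
    PlantSpec,
    build_phi,
    build_psi,
    classical_euclidean,
    distance_from_p0,
    encode_chain_amplitude,
    plant_site,
    quantum_distance,
    random_chain,
    rank_candidates,
    swap_test_p0,
)
from qdock.errors import DegenerateInputError, SizeError


class TestClassicalOracle:
    def test_identical_vectors(self):
        assert classical_euclidean([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_orthogonal_units(self):
        assert classical_euclidean([1, 0], [0, 1]) == pytest.approx(math.sqrt(2))

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(2, 8))
        brute = math.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)))
        assert classical_euclidean(x, y) == pytest.approx(brute, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(SizeError):
            classical_euclidean([1, 2], [1, 2, 3])


class TestStatePreparation:
    def test_phi_unit_norms(self):
        A = EmbeddedVector.from_raw([1.0, 0.0])
        B = EmbeddedVector.from_raw([0.0, 1.0])
        phi, Z = build_phi(A, B)
        assert Z == pytest.approx(2.0)
        np.testing.assert_allclose(phi, [1 / math.sqrt(2), -1 / math.sqrt(2)])

    def test_phi_arbitrary_norms(self):
        A = EmbeddedVector.from_raw([3.0, 0.0])
        B = EmbeddedVector.from_raw([0.0, 4.0])
        phi, Z = build_phi(A, B)
        assert Z == pytest.approx(25.0)
        np.testing.assert_allclose(phi, [0.6, -0.8])

    def test_phi_zero_norm_side(self):
        A = EmbeddedVector.from_raw([2.0, 0.0])
        B = EmbeddedVector.from_raw([0.0, 0.0])
        phi, Z = build_phi(A, B)
        np.testing.assert_allclose(phi, [1.0, 0.0])
        assert Z == pytest.approx(4.0)

    def test_phi_both_zero_rejected(self):
        zero = EmbeddedVector.from_raw([0.0, 0.0])
        with pytest.raises(DegenerateInputError):
            build_phi(zero, zero)

    def test_psi_equal_states_is_product_with_balanced_ancilla(self):
        A = EmbeddedVector.from_raw([0.6, 0.8])
        psi = build_psi(A, A)
        expected = np.kron(A.unit_state, [1 / math.sqrt(2), 1 / math.sqrt(2)])
        np.testing.assert_allclose(psi, expected, atol=1e-12)

    def test_psi_orthogonal_states_maximally_entangle_ancilla(self):
        A = EmbeddedVector.from_raw([1.0, 0.0])
        B = EmbeddedVector.from_raw([0.0, 1.0])
        psi = build_psi(A, B)
        rho = psi.reshape(2, 2)  # (register, ancilla)
        red = rho.T @ rho  # reduced ancilla density matrix
        np.testing.assert_allclose(np.linalg.eigvalsh(red), [0.5, 0.5], atol=1e-12)

    def test_psi_norm_on_random_inputs(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            A = EmbeddedVector.from_raw(rng.normal(size=8))
            B = EmbeddedVector.from_raw(rng.normal(size=8))
            psi = build_psi(A, B)
            assert float(psi @ psi) == pytest.approx(1.0, abs=1e-12)


class TestSwapTest:
    def test_identical_states_give_half(self):
        A = EmbeddedVector.from_raw([0.6, 0.8])
        phi, _ = build_phi(A, A)
        assert swap_test_p0(build_psi(A, A), phi) == pytest.approx(0.5, abs=1e-12)

    def test_orthogonal_units_give_three_quarters(self):
        A = EmbeddedVector.from_raw([1.0, 0.0])
        B = EmbeddedVector.from_raw([0.0, 1.0])
        phi, _ = build_phi(A, B)
        assert swap_test_p0(build_psi(A, B), phi) == pytest.approx(0.75, abs=1e-12)

    def test_p0_always_in_upper_half(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            A = EmbeddedVector.from_raw(rng.normal(size=4))
            B = EmbeddedVector.from_raw(rng.normal(size=4))
            phi, _ = build_phi(A, B)
            p0 = swap_test_p0(build_psi(A, B), phi)
            assert 0.5 - 1e-12 <= p0 <= 1.0 + 1e-12

    def test_circuit_matches_contraction_identity(self):
        """Simulated circuit p0 equals 1/2 + 1/2 ||<phi|psi>||^2 with the bra
        contracting psi's ancilla — the form that reproduces D = |A - B|."""
        rng = np.random.default_rng(23)
        for _ in range(10):
            A = EmbeddedVector.from_raw(rng.normal(size=8))
            B = EmbeddedVector.from_raw(rng.normal(size=8))
            phi, _ = build_phi(A, B)
            psi = build_psi(A, B)
            contracted = psi.reshape(-1, 2) @ phi
            identity_p0 = 0.5 + 0.5 * float(contracted @ contracted)
            assert swap_test_p0(psi, phi) == pytest.approx(identity_p0, abs=1e-12)


class TestDistance:
    @pytest.mark.parametrize(
        "p0, Z, expected", [(0.5, 2.0, 0.0), (0.75, 2.0, math.sqrt(2)), (1.0, 2.0, 2.0)]
    )
    def test_distance_formula(self, p0, Z, expected):
        assert distance_from_p0(p0, Z).distance == pytest.approx(expected, abs=1e-12)

    def test_shot_noise_below_half_clamps_to_zero(self):
        res = distance_from_p0(0.4997, 2.0)
        assert res.distance == 0.0 and res.clamped

    @pytest.mark.parametrize("dim", [2, 4, 16])
    def test_exact_quantum_equals_classical_euclidean(self, dim):
        rng = np.random.default_rng(dim)
        for _ in range(50):
            a = rng.normal(size=dim)
            b = rng.normal(size=dim)
            assert quantum_distance(a, b).distance == pytest.approx(
                classical_euclidean(a, b), abs=1e-9
            )

    def test_symmetry(self):
        rng = np.random.default_rng(29)
        a, b = rng.normal(size=(2, 8))
        assert quantum_distance(a, b).distance == pytest.approx(
            quantum_distance(b, a).distance, abs=1e-12
        )

    def test_sampled_distance_converges(self):
        rng = np.random.default_rng(31)
        a, b = rng.normal(size=(2, 4))
        exact = quantum_distance(a, b).distance
        est = quantum_distance(a, b, backend="sampling", shots=100_000, seed=7).distance
        assert est == pytest.approx(exact, rel=0.05)


class TestRanking:
    def test_exact_continuous_plant_ranks_first_with_zero_distance(self):
        lig = random_chain(2, seed=41, role="ligand")
        prot = plant_site(
            random_chain(10, seed=42), lig,
            PlantSpec(offset=4, mode="exact-continuous"),
        )
        ranked = rank_candidates(lig, [0, 4, 7], prot, DEFAULT_RANGES)
        assert ranked[0].start_offset == 4
        assert ranked[0].rank == 1
        assert ranked[0].distance == pytest.approx(0.0, abs=1e-9)

    def test_single_site_perturbation_ranks_second(self):
        lig = MoleculeChain(
            (InteractionSite(0.3, 0.7), InteractionSite(0.6, 0.2)), role="ligand"
        )
        exact = plant_site(
            random_chain(8, seed=43), lig, PlantSpec(offset=0, mode="exact-continuous")
        )
        # second candidate differs from the ligand in one site value
        perturbed_sites = list(exact.sites)
        perturbed_sites[4] = InteractionSite(0.3, 0.7)
        perturbed_sites[5] = InteractionSite(0.6, 0.35)
        prot = MoleculeChain(tuple(perturbed_sites))
        ranked = rank_candidates(lig, [0, 4], prot, DEFAULT_RANGES)
        assert [c.start_offset for c in ranked] == [0, 4]
        assert ranked[0].distance < ranked[1].distance

    def test_ranking_invariant_under_input_permutation(self):
        lig = random_chain(2, seed=44, role="ligand")
        prot = random_chain(12, seed=45)
        r1 = rank_candidates(lig, [0, 3, 6, 9], prot, DEFAULT_RANGES)
        r2 = rank_candidates(lig, [9, 0, 6, 3], prot, DEFAULT_RANGES)
        assert [(c.start_offset, c.rank) for c in r1] == [
            (c.start_offset, c.rank) for c in r2
        ]

    def test_distances_equal_classical_on_encoded_states(self):
        lig = random_chain(2, seed=46, role="ligand")
        prot = random_chain(10, seed=47)
        lig_state = encode_chain_amplitude(lig, DEFAULT_RANGES)
        for cand in rank_candidates(lig, [0, 2, 5], prot, DEFAULT_RANGES):
            chunk_state = encode_chain_amplitude(
                prot.slice(cand.start_offset, 2), DEFAULT_RANGES
            )
            assert cand.distance == pytest.approx(
                classical_euclidean(lig_state, chunk_state), abs=1e-9
            )
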