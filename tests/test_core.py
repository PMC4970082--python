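import numpy as np
import pytest
from hypothesis import given, strategies as st

from ahnet.core import (
    Compound,
    MoleculeParams,
    Mixture,
    TrainingConfig,
    bounds_from_distances,
    compound_values,
    evaluate_compound,
    evaluate_mixture,
    evaluate_molecule,
    fit_molecule,
    interval_energy,
    train_compound,
    update_distances,
)
from ahnet.errors import (
    DegenerateDomainError,
    EmptyIntervalError,
    InsufficientDataError,
    InvalidInputError,
)
from ahnet.synthetic import gen_piecewise


def _horner(coeffs, z):
    acc = 0.0
    for c in coeffs:
        acc = acc * z + c
    return acc


def _make_compound(const_a=1.0, const_b=5.0, bounds=(0.0, 1.0, 2.0)):
    ma = MoleculeParams.from_coefficients([const_a], degree=3)
    mb = MoleculeParams.from_coefficients([const_b], degree=3)
    return Compound((ma, mb), bounds)


class TestMolecule:
    @pytest.mark.parametrize(
        "sigma, roots, z, expected",
        [(2.0, (1.0, -1.0), 0.0, -2.0), (1.0, (1.0, 2.0, 3.0), 4.0, 6.0)],
    )
    def test_root_product_form(self, sigma, roots, z, expected):
        mol = MoleculeParams.from_roots(sigma, roots)
        assert evaluate_molecule(mol, z) == pytest.approx(expected, abs=1e-9)

    def test_root_and_coefficient_forms_agree(self, rng):
        """Root-product evaluation equals Horner evaluation of the same
        coefficients on random degree-3 molecules."""
        for _ in range(50):
            coeffs = rng.uniform(-3, 3, size=4)
            coeffs[0] = coeffs[0] or 1.0
            mol = MoleculeParams.from_coefficients(coeffs, degree=3)
            for z in rng.uniform(-5, 5, size=50):
                expected = _horner(coeffs, z)
                assert evaluate_molecule(mol, z) == pytest.approx(expected, abs=1e-9 * max(1, abs(expected)))

    def test_hydrogens_closed_under_conjugation(self):
        # z^2 + 1 has roots +/- i
        mol = MoleculeParams.from_coefficients([1.0, 0.0, 1.0], degree=2)
        hs = mol.hydrogens
        assert sorted(h.imag for h in hs) == pytest.approx([-1.0, 1.0])
        assert evaluate_molecule(mol, 2.0) == pytest.approx(5.0)

    def test_valence_and_input_validation(self):
        with pytest.raises(InvalidInputError):
            MoleculeParams((1.0, 0.0, 0.0, 0.0, 0.0, 0.0), degree=5)
        mol = MoleculeParams.from_roots(1.0, (0.0,))
        with pytest.raises(InvalidInputError):
            evaluate_molecule(mol, float("nan"))


class TestCompound:
    def test_interval_dispatch_half_open(self):
        comp = _make_compound()
        assert evaluate_compound(comp, 0.5) == 1.0  # molecule 1
        assert evaluate_compound(comp, 1.0) == 5.0  # molecule 2: half-open left intervals
        assert evaluate_compound(comp, 2.0) == 5.0  # last interval closed on the right

    def test_out_of_range_extrapolates_with_end_molecules(self):
        comp = _make_compound()
        assert evaluate_compound(comp, -0.5) == 1.0
        assert evaluate_compound(comp, 7.0) == 5.0

    def test_structural_invariants_enforced(self):
        ch2 = MoleculeParams.from_coefficients([1.0], degree=2)
        ch3 = MoleculeParams.from_coefficients([1.0], degree=3)
        with pytest.raises(InvalidInputError):
            Compound((ch2, ch3), (0.0, 1.0, 2.0))  # outer molecule must be CH3
        with pytest.raises(InvalidInputError):
            Compound((ch3, ch3), (0.0, 1.0, 0.5))  # bounds must increase
        with pytest.raises(InvalidInputError):
            Compound((ch3,), (0.0, 1.0))  # n >= 2

    def test_partition_completeness(self, rng):
        """Every z maps to exactly one molecule interval."""
        comp = _make_compound(bounds=(0.0, 0.3, 2.0))
        zs = rng.uniform(0.0, 2.0, size=200)
        vals = compound_values(comp, zs)
        assert np.all((vals == 1.0) | (vals == 5.0))
        assert np.all(vals[zs < 0.3] == 1.0)
        assert np.all(vals[zs >= 0.3] == 5.0)


class TestBoundsFromDistances:
    @pytest.mark.parametrize(
        "distances, lo, hi, expected",
        [((1, 1), 0, 10, (0, 5, 10)), ((1, 3), 0, 8, (0, 2, 8))],
    )
    def test_shares_map_to_bounds(self, distances, lo, hi, expected):
        assert bounds_from_distances(distances, lo, hi) == pytest.approx(expected)

    @given(
        st.lists(st.floats(0.01, 100.0), min_size=2, max_size=8),
        st.floats(1.001, 50.0),
    )
    def test_scaling_invariance(self, distances, factor):
        a = bounds_from_distances(distances, -2.0, 3.0)
        b = bounds_from_distances(np.asarray(distances) * factor, -2.0, 3.0)
        assert a == pytest.approx(b, abs=1e-9)

    def test_degenerate_domain_rejected(self):
        with pytest.raises(DegenerateDomainError):
            bounds_from_distances((1, 1), 1.0, 1.0)


class TestFitMolecule:
    def test_exact_cubic_interpolation(self):
        zs = np.linspace(-1, 5, 10)
        ys = (zs - 1) * (zs - 2) * (zs - 3)
        mol = fit_molecule(zs, ys, degree=3)
        assert mol.carbon_value == pytest.approx(1.0, abs=1e-8)
        assert [h.real for h in mol.hydrogens] == pytest.approx([1.0, 2.0, 3.0], abs=1e-8)
        assert max(abs(h.imag) for h in mol.hydrogens) < 1e-8

    def test_matches_normal_equations(self, rng):
        zs = rng.uniform(-2, 2, size=20)
        ys = 0.5 * zs**2 - zs + 3 + rng.normal(0, 0.3, size=20)
        mol = fit_molecule(zs, ys, degree=2)
        A = np.vander(zs, 3)
        expected = np.linalg.solve(A.T @ A, A.T @ ys)
        assert mol.coefficients == pytest.approx(tuple(expected), abs=1e-9)

    def test_degree_reduction_on_thin_data(self):
        mol = fit_molecule([0.0, 1.0], [0.0, 2.0], degree=3)
        assert mol.effective_degree == 1
        assert mol.degree == 3

    def test_empty_interval_rejected(self):
        with pytest.raises(EmptyIntervalError):
            fit_molecule([], [], degree=2)


class TestIntervalEnergy:
    def test_perfect_fit_is_zero(self):
        mol = fit_molecule([0, 1, 2], [1, 2, 3], degree=1)
        assert interval_energy(mol, [0, 1, 2], [1, 2, 3]) == pytest.approx(0.0, abs=1e-20)

    def test_mse_arithmetic(self):
        mol = MoleculeParams.from_coefficients([0.0], degree=2)
        assert interval_energy(mol, [0.0, 1.0], [1.0, 1.0]) == 1.0
        assert interval_energy(mol, [], []) == 0.0

    def test_matches_loop_oracle(self, rng):
        mol = MoleculeParams.from_coefficients(rng.uniform(-1, 1, 3), degree=2)
        zs = rng.uniform(-3, 3, 40)
        ys = rng.uniform(-3, 3, 40)
        expected = sum((y - _horner(mol.coefficients, z)) ** 2 for z, y in zip(zs, ys)) / 40
        assert interval_energy(mol, zs, ys) == pytest.approx(expected, abs=1e-12)


class TestUpdateDistances:
    def test_boundary_moves_into_worse_interval(self):
        # pair energies (2, 1): the worse left interval shrinks by eta*(E1-E2)
        out = update_distances([1.0, 1.0], [2.0, 1.0], eta=0.1, min_distance_fraction=1e-3)
        assert out == pytest.approx([0.9, 1.1])

    def test_equal_energies_leave_distances_unchanged(self):
        out = update_distances([0.4, 1.0, 0.8], [3.0, 3.0, 3.0], eta=0.2, min_distance_fraction=1e-3)
        assert out == pytest.approx([0.4, 1.0, 0.8])

    def test_collapsing_width_clamped_to_floor(self):
        out = update_distances([1.0, 1.0], [0.0, 100.0], eta=0.5, min_distance_fraction=1e-3)
        floor = 1e-3 * 2.0
        assert out[1] == pytest.approx(floor)
        assert np.all(out >= floor)

    @given(st.lists(st.floats(0.0, 10.0), min_size=2, max_size=6))
    def test_total_width_roughly_preserved(self, energies):
        r0 = np.ones(len(energies))
        out = update_distances(r0, energies, eta=0.1, min_distance_fraction=1e-3)
        assert out.sum() == pytest.approx(r0.sum(), rel=1e-2)
        assert np.all(out >= 1e-3 * r0.sum() * (1 - 1e-9))

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            update_distances([1.0, 1.0], [1.0], eta=0.1, min_distance_fraction=1e-3)


class TestTrainCompound:
    def test_single_cubic_fits_exactly(self, rng):
        zs = rng.uniform(0, 1, 200)
        ys = 2 * zs**3 - zs + 0.5
        comp, trace = train_compound(zs, ys, TrainingConfig(n_molecules=2, seed=0))
        assert trace.best_rmse <= 1e-6

    def test_recovers_known_pieces_with_fixed_bounds(self, piecewise_spec):
        zs, ys = gen_piecewise(piecewise_spec, 600, seed=3)
        comp, trace = train_compound(
            zs, ys, TrainingConfig(n_molecules=3, seed=0), fixed_bounds=piecewise_spec.bounds
        )
        assert trace.best_rmse <= 1e-6
        for mol, true_coeffs in zip(comp.molecules, piecewise_spec.coefficients):
            assert mol.coefficients == pytest.approx(true_coeffs, abs=1e-6)

    def test_learns_breakpoints_on_noiseless_data(self, piecewise_spec):
        zs, ys = gen_piecewise(piecewise_spec, 600, seed=3)
        cfg = TrainingConfig(n_molecules=3, seed=42, max_iterations=2000)
        comp, trace = train_compound(zs, ys, cfg)
        assert trace.best_rmse <= 1e-3
        assert comp.bounds[1] == pytest.approx(1.0, abs=0.05)
        assert comp.bounds[2] == pytest.approx(2.0, abs=0.05)

    def test_seed_determinism_and_best_tracking(self, piecewise_spec):
        zs, ys = gen_piecewise(piecewise_spec, 300, seed=7)
        cfg = TrainingConfig(n_molecules=3, seed=42, max_iterations=50)
        c1, t1 = train_compound(zs, ys, cfg)
        c2, t2 = train_compound(zs, ys, cfg)
        assert c1 == c2
        assert t1.errors == t2.errors
        # returned compound is the best encountered: no worse than iteration 0
        returned_rmse = float(np.sqrt(np.mean((ys - compound_values(c1, zs)) ** 2)))
        assert returned_rmse <= t1.errors[0] + 1e-15
        assert min(t1.errors) == pytest.approx(t1.best_rmse)

    def test_bounds_strictly_increasing_every_iteration(self, piecewise_spec):
        zs, ys = gen_piecewise(piecewise_spec, 300, seed=7)
        _, trace = train_compound(zs, ys, TrainingConfig(n_molecules=4, seed=1, max_iterations=40))
        for rec in trace.records:
            assert np.all(np.diff(rec.bounds) > 0)

    def test_error_conditions(self):
        with pytest.raises(InsufficientDataError):
            train_compound([0.0], [1.0], TrainingConfig(n_molecules=2))
        with pytest.raises(DegenerateDomainError):
            train_compound([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], TrainingConfig(n_molecules=2))


class TestMixture:
    def test_single_compound_mixture_is_identity(self):
        comp = _make_compound()
        mix = Mixture((comp,), (1.0,))
        assert evaluate_mixture(mix, 0.5) == evaluate_compound(comp, 0.5)

    def test_convex_blend_of_identical_compounds(self):
        comp = _make_compound()
        mix = Mixture((comp, comp), (0.5, 0.5))
        assert evaluate_mixture(mix, 1.7) == pytest.approx(evaluate_compound(comp, 1.7))

    def test_matches_weighted_sum_oracle(self, rng):
        comps = [_make_compound(rng.uniform(-2, 2), rng.uniform(-2, 2)) for _ in range(4)]
        alphas = rng.uniform(-1, 1, 4)
        mix = Mixture(tuple(comps), tuple(alphas))
        for z in rng.uniform(-1, 3, 20):
            expected = sum(a * evaluate_compound(c, z) for a, c in zip(alphas, comps))
            assert evaluate_mixture(mix, z) == pytest.approx(expected, abs=1e-12)
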