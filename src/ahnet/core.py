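"""Artificial hydrocarbon network (AHN) learning machinery.

An AHN models a scalar relationship ``y = f(z)`` with a *compound*: a
saturated linear chain of CH-molecules CH3-CH2-...-CH2-CH3.  Each molecule
carries a polynomial behaviour

    phi(z) = sigma * prod_i (z - H_i)

where ``sigma`` is the *carbon value* (leading coefficient), the ``H_i`` are
*hydrogen values* (the polynomial roots, possibly complex in conjugate
pairs) and ``k <= 4`` is the number of hydrogens.  The compound behaviour
``psi`` is piecewise: molecule ``j`` acts on the interval ``[L_{j-1}, L_j)``
of the input axis (the last interval is closed on both ends).  Interval
widths are *intermolecular distances* learned by gradient descent on the
adjacent molecules' *energies* (here: per-interval mean squared error),
while each molecule's polynomial is refitted by least squares every
iteration.

The canonical parameterisation of a molecule is its real coefficient
vector; carbon value and hydrogens are derived views (roots may be complex,
which the model permits).
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateDomainError,
    EmptyIntervalError,
    InsufficientDataError,
    InvalidInputError,
)

logger = logging.getLogger(__name__)

#: Valence constraint: a carbon binds at most four hydrogens.
MAX_HYDROGENS = 4


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MoleculeParams:
    """One CH-molecule: a polynomial of structural degree ``k`` (2 or 3).

    Parameters
    ----------
    coefficients
        Real coefficient vector in descending powers, trimmed so the
        leading entry is nonzero (unless the polynomial is identically
        zero).  Its length is ``effective_degree + 1``, which may be less
        than ``degree + 1`` when the molecule was fitted on degenerate
        (thin) data.
    degree
        Structural number of hydrogens ``k`` (3 for the outer CH3
        molecules, 2 for inner CH2 molecules).
    """

    coefficients: tuple[float, ...]
    degree: int

    def __post_init__(self):
        if not (1 <= self.degree <= MAX_HYDROGENS):
            raise InvalidInputError(f"degree must be in [1, {MAX_HYDROGENS}], got {self.degree}")
        coeffs = tuple(float(c) for c in self.coefficients)
        if len(coeffs) == 0 or len(coeffs) > self.degree + 1:
            raise InvalidInputError("coefficient vector length must be in [1, degree+1]")
        if not all(math.isfinite(c) for c in coeffs):
            raise InvalidInputError("coefficients must be finite")
        object.__setattr__(self, "coefficients", coeffs)

    @classmethod
    def from_coefficients(cls, coefficients, degree: int) -> "MoleculeParams":
        """Build from a coefficient vector, trimming leading zeros."""
        arr = np.atleast_1d(np.asarray(coefficients, dtype=float))
        nz = np.flatnonzero(arr)
        arr = arr[nz[0]:] if nz.size else arr[-1:]
        return cls(tuple(arr), degree)

    @classmethod
    def from_roots(cls, carbon_value: float, hydrogens, degree: int | None = None) -> "MoleculeParams":
        """Build from the root-product form ``sigma * prod (z - H_i)``.

        The hydrogens must be closed under complex conjugation so the
        expanded coefficients are real.
        """
        roots = np.atleast_1d(np.asarray(hydrogens, dtype=complex))
        coeffs = float(carbon_value) * np.poly(roots) if roots.size else np.array([float(carbon_value)])
        if np.max(np.abs(coeffs.imag)) > 1e-9 * max(1.0, np.max(np.abs(coeffs))):
            raise InvalidInputError("hydrogens are not closed under conjugation")
        return cls.from_coefficients(coeffs.real, degree if degree is not None else max(roots.size, 1))

    @property
    def effective_degree(self) -> int:
        return len(self.coefficients) - 1

    @property
    def carbon_value(self) -> float:
        """Leading coefficient sigma."""
        return self.coefficients[0]

    @property
    def hydrogens(self) -> tuple[complex, ...]:
        """Polynomial roots, sorted by (real, imag) for determinism."""
        if self.effective_degree == 0 or self.carbon_value == 0.0:
            return ()
        roots = np.roots(self.coefficients)
        return tuple(sorted((complex(r) for r in roots), key=lambda c: (c.real, c.imag)))


@dataclass(frozen=True)
class Compound:
    """A saturated linear chain of molecules with its interval bounds.

    ``molecules[j]`` acts on ``[bounds[j], bounds[j+1])`` (last interval
    closed); outer molecules are CH3 (degree 3), inner CH2 (degree 2).
    """

    molecules: tuple[MoleculeParams, ...]
    bounds: tuple[float, ...]

    def __post_init__(self):
        mols = tuple(self.molecules)
        bnds = tuple(float(b) for b in self.bounds)
        if len(mols) < 2:
            raise InvalidInputError("a compound needs at least two molecules")
        if len(bnds) != len(mols) + 1:
            raise InvalidInputError("bounds length must be n_molecules + 1")
        if not all(b0 < b1 for b0, b1 in zip(bnds, bnds[1:])):
            raise InvalidInputError("bounds must be strictly increasing")
        if mols[0].degree != 3 or mols[-1].degree != 3:
            raise InvalidInputError("outer molecules must be CH3 (degree 3)")
        if any(m.degree != 2 for m in mols[1:-1]):
            raise InvalidInputError("inner molecules must be CH2 (degree 2)")
        object.__setattr__(self, "molecules", mols)
        object.__setattr__(self, "bounds", bnds)

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)


@dataclass(frozen=True)
class TrainingConfig:
    """Hyper-parameters of the AHN training loop.

    ``n_molecules`` is the number of intervals/molecules ``n``;
    ``learning_rate`` is the gradient step ``eta`` on intermolecular
    distances; training stops when the RMSE drops to ``tolerance`` or
    after ``max_iterations`` sweeps.  ``min_distance_fraction`` is the
    width-collapse floor, as a fraction of the domain span.
    """

    n_molecules: int
    learning_rate: float = 0.1
    tolerance: float = 1e-4
    max_iterations: int = 200
    seed: int = 0
    min_samples_per_interval: int = 1
    min_distance_fraction: float = 1e-3

    def __post_init__(self):
        if self.n_molecules < 2:
            raise InvalidInputError("n_molecules must be >= 2")
        if not (0.0 < self.learning_rate < 1.0):
            raise InvalidInputError("learning_rate must be in (0, 1)")
        if self.tolerance <= 0:
            raise InvalidInputError("tolerance must be > 0")
        if self.max_iterations < 1:
            raise InvalidInputError("max_iterations must be >= 1")
        if self.min_samples_per_interval < 1:
            raise InvalidInputError("min_samples_per_interval must be >= 1")
        if self.min_distance_fraction <= 0:
            raise InvalidInputError("min_distance_fraction must be > 0")


@dataclass
class IterationRecord:
    """Per-iteration training trace entry."""

    iteration: int
    rmse: float
    energies: tuple[float, ...]
    bounds: tuple[float, ...]

    def log_line(self) -> str:
        energies = " ".join(f"{e:.6g}" for e in self.energies)
        bounds = " ".join(f"{b:.6g}" for b in self.bounds)
        return f"iter={self.iteration} rmse={self.rmse:.8g} energies=[{energies}] bounds=[{bounds}]"


@dataclass
class TrainingTrace:
    """Full training trace plus provenance of the best compound found."""

    records: list[IterationRecord] = field(default_factory=list)
    best_iteration: int = -1
    best_rmse: float = math.inf

    @property
    def errors(self) -> list[float]:
        return [r.rmse for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class Mixture:
    """A weighted blend of compounds, ``S(z) = sum_i alpha_i psi_i(z)``.

    The weights ``alpha_i`` are the stoichiometric coefficients.  This
    work trains a single compound (c = 1); the mixture exists so the
    general model surface is exercisable.
    """

    compounds: tuple[Compound, ...]
    coefficients: tuple[float, ...]

    def __post_init__(self):
        comps = tuple(self.compounds)
        alphas = tuple(float(a) for a in self.coefficients)
        if len(comps) < 1:
            raise InvalidInputError("a mixture needs at least one compound")
        if len(comps) != len(alphas):
            raise InvalidInputError("compounds and coefficients lengths differ")
        object.__setattr__(self, "compounds", comps)
        object.__setattr__(self, "coefficients", alphas)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def evaluate_molecule(molecule: MoleculeParams, z: float) -> float:
    """Evaluate the root-product form ``sigma * prod (z - H_i)`` at real z.

    Equals Horner evaluation of the coefficient vector to within numerical
    round-off; any imaginary residue (from complex-conjugate hydrogens) is
    discarded.
    """
    z = float(z)
    if not math.isfinite(z):
        raise InvalidInputError("z must be finite")
    value = complex(molecule.carbon_value)
    for h in molecule.hydrogens:
        value *= z - h
    return value.real


def molecule_values(molecule: MoleculeParams, zs: np.ndarray) -> np.ndarray:
    """Vectorised coefficient-form (Horner) evaluation."""
    return np.polyval(molecule.coefficients, np.asarray(zs, dtype=float))


def _interval_index(bounds: np.ndarray, zs: np.ndarray) -> np.ndarray:
    """Dispatch z to its molecule: half-open intervals, last closed,
    out-of-range z extrapolates with the nearest end molecule."""
    idx = np.searchsorted(bounds, zs, side="right") - 1
    return np.clip(idx, 0, len(bounds) - 2)


def evaluate_compound(compound: Compound, z: float) -> float:
    """Piecewise behaviour psi(z): dispatch to the owning molecule."""
    z = float(z)
    if not math.isfinite(z):
        raise InvalidInputError("z must be finite")
    j = int(_interval_index(np.asarray(compound.bounds), np.asarray([z]))[0])
    return float(molecule_values(compound.molecules[j], np.asarray([z]))[0])


def compound_values(compound: Compound, zs) -> np.ndarray:
    """Vectorised psi over an array of inputs."""
    zs = np.asarray(zs, dtype=float)
    bounds = np.asarray(compound.bounds)
    idx = _interval_index(bounds, zs)
    out = np.empty_like(zs)
    for j, mol in enumerate(compound.molecules):
        sel = idx == j
        if np.any(sel):
            out[sel] = molecule_values(mol, zs[sel])
    return out


def evaluate_mixture(mixture: Mixture, z: float) -> float:
    """``S(z) = sum_i alpha_i psi_i(z)``."""
    return float(sum(a * evaluate_compound(c, z) for a, c in zip(mixture.coefficients, mixture.compounds)))


# ---------------------------------------------------------------------------
# fitting primitives
# ---------------------------------------------------------------------------


def bounds_from_distances(distances, z_min: float, z_max: float) -> np.ndarray:
    """Map positive width shares r_1..r_n onto bounds L_0..L_n in
    [z_min, z_max].

    L_t = z_min + (z_max - z_min) * cumulative share; any positive
    rescaling of the distances yields identical bounds.
    """
    distances = np.asarray(distances, dtype=float)
    if z_min >= z_max:
        raise DegenerateDomainError(f"degenerate domain [{z_min}, {z_max}]")
    if distances.ndim != 1 or distances.size < 1 or np.any(distances <= 0):
        raise InvalidInputError("distances must be a vector of positive reals")
    shares = np.concatenate(([0.0], np.cumsum(distances))) / distances.sum()
    bounds = z_min + (z_max - z_min) * shares
    bounds[0], bounds[-1] = z_min, z_max  # exact endpoints
    if not np.all(np.diff(bounds) > 0):
        raise InvalidInputError("distances produce non-increasing bounds")
    return bounds


def fit_molecule(zs, ys, degree: int) -> MoleculeParams:
    """Least-squares polynomial fit of degree ``min(degree, m-1)``.

    With m samples the fitted degree is reduced to ``m - 1`` so the system
    stays determined; the carbon value is the leading coefficient and the
    hydrogens are the fitted polynomial's roots.
    """
    zs = np.asarray(zs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if zs.shape != ys.shape or zs.ndim != 1:
        raise InvalidInputError("zs and ys must be equal-length vectors")
    m = zs.size
    if m == 0:
        raise EmptyIntervalError("cannot fit a molecule on an empty interval")
    d = min(int(degree), m - 1)
    coeffs, *_ = np.linalg.lstsq(np.vander(zs, d + 1), ys, rcond=None)
    return MoleculeParams.from_coefficients(coeffs, degree)


def interval_energy(molecule: MoleculeParams, zs, ys) -> float:
    """Molecule energy: mean squared error of phi on its interval samples
    (0 for an empty interval)."""
    zs = np.asarray(zs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if zs.shape != ys.shape:
        raise InvalidInputError("zs and ys must have equal length")
    if zs.size == 0:
        return 0.0
    resid = ys - molecule_values(molecule, zs)
    return float(np.mean(resid**2))


def update_distances(distances, energies, eta: float, min_distance_fraction: float) -> np.ndarray:
    """Gradient step on interval widths from adjacent molecule energies.

    For every adjacent pair (t-1, t) the width of the left interval
    changes by ``-eta * (E_{t-1} - E_t)`` and, symmetrically, the width of
    the right interval by the opposite amount: the shared boundary hands
    territory from the worse-fitting molecule to the better-fitting one,
    and equal energies leave the partition untouched.  Net per-interval
    step: ``r_t <- r_t - eta * ((E_t - E_{t-1}) + (E_t - E_{t+1}))`` with
    one-sided terms at the chain ends.  Widths are then clamped to the
    collapse floor and rescaled so the total is preserved.
    """
    r = np.asarray(distances, dtype=float).copy()
    e = np.asarray(energies, dtype=float)
    if r.shape != e.shape or r.ndim != 1:
        raise InvalidInputError("distances and energies must be equal-length vectors")
    if not (0.0 < eta < 1.0):
        raise InvalidInputError("eta must be in (0, 1)")
    total = r.sum()
    pair = e[:-1] - e[1:]  # E_{t-1} - E_t for each adjacent pair
    grad = np.zeros_like(r)
    grad[:-1] += pair      # left interval of the pair: -eta * (E_{t-1} - E_t)
    grad[1:] -= pair       # right interval: the symmetric counterpart
    r -= eta * grad
    floor = min_distance_fraction * total
    r = np.maximum(r, floor)
    r *= total / r.sum()
    return np.maximum(r, floor)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def _molecule_degrees(n: int) -> list[int]:
    return [3] + [2] * (n - 2) + [3]


def _fit_interval_molecules(zs, ys, bounds, degrees, previous):
    """Fit one molecule per interval; empty intervals inherit their
    previous parameters, or on the first sweep a constant equal to the
    nearest fitted neighbour's value at the shared boundary."""
    idx = _interval_index(bounds, zs)
    n = len(degrees)
    molecules: list[MoleculeParams | None] = [None] * n
    occupied = []
    for j in range(n):
        sel = idx == j
        if np.any(sel):
            molecules[j] = fit_molecule(zs[sel], ys[sel], degrees[j])
            occupied.append(j)
    for j in range(n):
        if molecules[j] is not None:
            continue
        if previous is not None:
            molecules[j] = previous[j]
            continue
        nearest = min(occupied, key=lambda o: (abs(o - j), o))
        edge = bounds[j] if nearest < j else bounds[j + 1]
        value = float(molecule_values(molecules[nearest], np.asarray([edge]))[0])
        molecules[j] = MoleculeParams.from_coefficients([value], degrees[j])
    return molecules, idx


def train_compound(
    zs,
    ys,
    config: TrainingConfig,
    *,
    fixed_bounds=None,
) -> tuple[Compound, TrainingTrace]:
    """Train a saturated linear compound on scalar data.

    Each sweep: derive bounds from the intermolecular distances, refit one
    polynomial per interval by least squares, assemble the compound,
    measure the per-molecule energies and the global RMSE, and take a
    gradient step on the distances.  Stops when RMSE <= tolerance or after
    ``max_iterations`` sweeps; the best compound encountered is returned
    together with the full trace.  Identical (data, config) give
    bit-identical results.

    ``fixed_bounds`` pins the partition (no distance updates), which is
    useful for recovery studies on data with known breakpoints.
    """
    zs = np.asarray(zs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if zs.shape != ys.shape or zs.ndim != 1:
        raise InvalidInputError("zs and ys must be equal-length vectors")
    n = config.n_molecules
    if zs.size < n * config.min_samples_per_interval:
        raise InsufficientDataError(
            f"need at least {n * config.min_samples_per_interval} samples, got {zs.size}"
        )
    z_min, z_max = float(zs.min()), float(zs.max())
    if z_min >= z_max:
        raise DegenerateDomainError("all z values are equal")

    degrees = _molecule_degrees(n)
    rng = np.random.default_rng(config.seed)
    distances = rng.uniform(0.5, 1.5, size=n)

    trace = TrainingTrace()
    best_compound: Compound | None = None
    previous = None
    for iteration in range(config.max_iterations):
        if fixed_bounds is not None:
            bounds = np.asarray(fixed_bounds, dtype=float)
        else:
            bounds = bounds_from_distances(distances, z_min, z_max)
        molecules, idx = _fit_interval_molecules(zs, ys, bounds, degrees, previous)
        energies = tuple(
            interval_energy(molecules[j], zs[idx == j], ys[idx == j]) for j in range(n)
        )
        compound = Compound(tuple(molecules), tuple(bounds))
        rmse = float(np.sqrt(np.mean((ys - compound_values(compound, zs)) ** 2)))
        record = IterationRecord(iteration, rmse, energies, tuple(bounds))
        trace.records.append(record)
        logger.debug("%s", record.log_line())
        if rmse < trace.best_rmse:
            trace.best_rmse = rmse
            trace.best_iteration = iteration
            best_compound = copy.deepcopy(compound)
        if rmse <= config.tolerance:
            break
        if fixed_bounds is None:
            distances = update_distances(
                distances, energies, config.learning_rate, config.min_distance_fraction
            )
        previous = molecules

    assert best_compound is not None
    return best_compound, trace
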