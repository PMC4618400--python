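"""Taylor in-state spin-orbit analysis of low-spin d5 EPR g values.

A low-spin Fe(III) site has a single hole in the t2g manifold
{d_yz, d_xz, d_xy}.  The rhombic ligand field splits these orbitals by a
tetragonal parameter ``Delta`` (d_xy relative to the {d_xz, d_yz} pair)
and a rhombic parameter ``V`` (d_xz relative to d_yz), while the in-state
spin-orbit coupling ``zeta * L.S`` mixes them.  The ground Kramers
doublet is then

    |psi>    = a |yz, -> + b |xz, -> + c |xy, +>
    |psibar> = -a |yz, +> + b |xz, +> + c |xy, ->        (time reversal)

with real mixing coefficients (a, b, c), and the principal g values are
exact closed forms in those coefficients:

    g_x = 2 [a^2 - (b + c)^2]
    g_y = 2 [(a + c)^2 - b^2]
    g_z = 2 [(a + b)^2 - c^2]

Because the three-orbital problem is exactly soluble, the map can be
inverted: the signed g values give the coefficient ratios

    a : b : c = (g_z + g_y) : (g_z - g_x) : (g_y - g_x)

and the orbital splittings in units of zeta

    V / zeta     = g_x / (g_z + g_y) + g_y / (g_z - g_x)
    Delta / zeta = g_x / (g_z + g_y) + g_z / (g_y - g_x) - V / (2 zeta)

The dimensionless rhombicity |V / 2 Delta| ranges from 0 (axial) to 1/3
(rhombic limit, equal t2g gaps) under the proper-axis convention and is
independent of zeta.  A negative Delta places d_xy as the half-occupied
orbital (c dominant).

Only the magnitudes |g| are measured; :func:`assign_g_tensor` enumerates
axis permutations and sign patterns and ranks them by self-consistency.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import ZETA_DEFAULT_CM
from .exceptions import DegenerateAssignmentError, NormalizationError, OrderingError

__all__ = [
    "SignedGTensor",
    "HoleCoefficients",
    "LigandFieldParameters",
    "TransitionPair",
    "AssignmentCandidate",
    "g_from_coefficients",
    "coefficients_from_g",
    "ligand_field_from_g",
    "predicted_transitions",
    "soc_ground_doublet",
    "doublet_g_values",
    "assign_g_tensor",
]

#: Numerators below this magnitude are treated as degenerate.
_DEGENERATE_TOL = 1e-10


@dataclass(frozen=True)
class SignedGTensor:
    """Principal g values with Taylor signs and an axis-assignment label."""

    g_x: float
    g_y: float
    g_z: float
    axis_convention: str = ""

    def __post_init__(self) -> None:
        g = np.array([self.g_x, self.g_y, self.g_z])
        if np.all(g == 0):
            raise ValueError("all three g values are zero")
        if np.any(np.abs(g) >= 4.0):
            raise ValueError(f"|g| must lie in (0, 4); got {tuple(g)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.g_x, self.g_y, self.g_z], dtype=float)


@dataclass(frozen=True)
class HoleCoefficients:
    """Weights (a, b, c) of d_yz, d_xz, d_xy in the ground-doublet hole.

    Stored fully normalized (a^2 + b^2 + c^2 = 1).  Under the canonical
    phase all three are non-negative; the overall Kramers sign is fixed
    by c >= 0.
    """

    a: float
    b: float
    c: float

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c], dtype=float)

    @classmethod
    def from_unnormalized(cls, a: float, b: float, c: float) -> "HoleCoefficients":
        v = np.array([a, b, c], dtype=float)
        n = np.linalg.norm(v)
        if n == 0:
            raise NormalizationError("zero coefficient vector")
        v = v / n
        if v[2] < 0:  # canonical Kramers phase
            v = -v
        return cls(*v)

    def table_scaled(self) -> tuple[float, float, float]:
        """Coefficients rescaled so the largest equals 1.00.

        This is the conventional way splitting tables report the hole
        composition; comparisons to published tables use this scaling.
        """
        v = self.as_array()
        return tuple(v / np.max(np.abs(v)))


@dataclass(frozen=True)
class LigandFieldParameters:
    """t2g splitting parameters in cm^-1 plus the derived rhombicity."""

    delta: float
    v: float
    zeta: float
    rhombicity: float = field(init=False)

    def __post_init__(self) -> None:
        if self.zeta <= 0:
            raise ValueError("zeta must be positive")
        if self.delta != 0:
            rh = abs(self.v) / (2 * abs(self.delta))
        else:
            rh = 0.0 if self.v == 0 else np.inf  # fully degenerate / no unique axis
        object.__setattr__(self, "rhombicity", rh)


@dataclass(frozen=True)
class TransitionPair:
    """The two intra-t2g (dpi -> dpi) transition energies, cm^-1."""

    trans1: float
    trans2: float

    def __post_init__(self) -> None:
        if not (0 <= self.trans1 <= self.trans2):
            raise OrderingError(
                f"require 0 <= trans1 <= trans2, got ({self.trans1}, {self.trans2})"
            )


@dataclass(frozen=True)
class AssignmentCandidate:
    """One axis-permutation/sign hypothesis for experimental |g| values."""

    permutation: tuple[str, str, str]
    signs: tuple[int, int, int]
    residual: float
    parameters: LigandFieldParameters | None
    coefficients: HoleCoefficients
    g: SignedGTensor


def _check_normalized(a: float, b: float, c: float, tol: float = 1e-9) -> None:
    n2 = a * a + b * b + c * c
    if abs(n2 - 1.0) > tol:
        raise NormalizationError(
            f"coefficients not normalized: a^2+b^2+c^2 = {n2:.12f}; "
            "use HoleCoefficients.from_unnormalized"
        )


def g_from_coefficients(coeffs: HoleCoefficients) -> SignedGTensor:
    """Signed principal g values from normalized hole coefficients.

    Invariant under the overall Kramers phase (flipping the sign of all
    three coefficients), since each closed form is quadratic.
    """
    a, b, c = coeffs.a, coeffs.b, coeffs.c
    _check_normalized(a, b, c)
    return SignedGTensor(
        g_x=2 * (a * a - (b + c) ** 2),
        g_y=2 * ((a + c) ** 2 - b * b),
        g_z=2 * ((a + b) ** 2 - c * c),
    )


def _ratio_numerators(g: SignedGTensor) -> np.ndarray:
    return np.array([g.g_z + g.g_y, g.g_z - g.g_x, g.g_y - g.g_x])


def coefficients_from_g(g: SignedGTensor) -> HoleCoefficients:
    """Invert the closed forms: coefficient ratios from signed g values.

    Exact because g_z + g_y = 4a(a+b+c), g_z - g_x = 4b(a+b+c) and
    g_y - g_x = 4c(a+b+c) under the closed forms, so the ratio triple is
    proportional to (a, b, c) itself.
    """
    num = _ratio_numerators(g)
    if np.all(np.abs(num) < _DEGENERATE_TOL):
        raise DegenerateAssignmentError(
            "all three coefficient numerators vanish; the g tensor is "
            "isotropic-degenerate and the hole composition is unresolvable"
        )
    return HoleCoefficients.from_unnormalized(*num)


def ligand_field_from_g(
    g: SignedGTensor, zeta: float = ZETA_DEFAULT_CM
) -> LigandFieldParameters:
    """Tetragonal and rhombic t2g splittings from signed g values.

    The rhombicity |V/2Delta| is independent of ``zeta`` (both splittings
    scale linearly with it); the absolute splittings require the one-hole
    spin-orbit constant, default 380 cm^-1.
    """
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    num = _ratio_numerators(g)
    if np.any(np.abs(num) < _DEGENERATE_TOL):
        raise DegenerateAssignmentError(
            f"degenerate denominators {tuple(num)}; the inversion requires "
            "g_z+g_y, g_z-g_x and g_y-g_x all nonzero"
        )
    v_over_zeta = g.g_x / num[0] + g.g_y / num[1]
    delta_over_zeta = g.g_x / num[0] + g.g_z / num[2] - v_over_zeta / 2
    return LigandFieldParameters(
        delta=delta_over_zeta * zeta, v=v_over_zeta * zeta, zeta=zeta
    )


def predicted_transitions(params: LigandFieldParameters) -> TransitionPair:
    """Predicted dpi -> dpi transition energies from the orbital splittings.

    With the hole in the orbital |Delta| below the {d_xz, d_yz} pair
    split by |V|, the two intra-t2g excitations sit at |Delta| -/+ |V|/2,
    so their separation is exactly |V|.
    """
    d, v = abs(params.delta), abs(params.v)
    if d < v / 2:
        raise OrderingError(
            f"|Delta| = {d:g} < |V|/2 = {v / 2:g}: the tetragonal axis is "
            "not the unique axis under the proper-axis convention"
        )
    return TransitionPair(trans1=d - v / 2, trans2=d + v / 2)


# ---------------------------------------------------------------------------
# Full one-hole spin-orbit Hamiltonian (forward model)
# ---------------------------------------------------------------------------

# Orbital angular momentum within t2g in the real basis (yz, xz, xy),
# from L = -i r x grad acting on the orbital polynomials yz, xz, xy.
# The set behaves as an effective l = 1 with inverted sign:
# [L_x, L_y] = -i L_z.
_LX = np.array([[0, 0, 0], [0, 0, 1j], [0, -1j, 0]])
_LY = np.array([[0, 0, -1j], [0, 0, 0], [1j, 0, 0]])
_LZ = np.array([[0, 1j, 0], [-1j, 0, 0], [0, 0, 0]])
_SX = np.array([[0, 1], [1, 0]]) / 2.0
_SY = np.array([[0, -1j], [1j, 0]]) / 2.0
_SZ = np.diag([1.0, -1.0]) / 2.0
_I2 = np.eye(2)
_I3 = np.eye(3)


def _hole_hamiltonian(delta: float, v: float, zeta: float) -> np.ndarray:
    """6x6 one-hole Hamiltonian on {yz, xz, xy} x {up, down}.

    Hole orbital energies (-V/2, +V/2, Delta) and spin-orbit term
    -zeta L.S; the sign of the coupling for a hole is opposite to the
    one-electron convention.  This fixes the calibration: negative Delta
    puts the hole in d_xy, and the resulting g values carry the Taylor
    sign pattern.
    """
    e_orb = np.diag([-v / 2.0, v / 2.0, delta]).astype(complex)
    h_soc = np.kron(_LX, _SX) + np.kron(_LY, _SY) + np.kron(_LZ, _SZ)
    h = np.kron(e_orb, _I2) - zeta * h_soc
    if not np.allclose(h, h.conj().T):
        raise AssertionError("Hamiltonian construction is not Hermitian")
    return h


def _ground_state(delta: float, v: float, zeta: float):
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    w, vec = np.linalg.eigh(_hole_hamiltonian(delta, v, zeta))
    return w, vec


def soc_ground_doublet(
    delta: float, v: float, zeta: float
) -> tuple[HoleCoefficients, tuple[float, float, float]]:
    """Diagonalize the one-hole t2g + spin-orbit problem.

    Returns the ground Kramers doublet's orbital coefficients (phases
    absorbed so a, b, c are real and non-negative) and the three doublet
    energies in cm^-1, ascending.  In the zeta -> 0 limit the doublet
    gaps reduce to the pure orbital splittings (|Delta| -/+ |V|/2 for
    negative Delta).
    """
    w, vec = _ground_state(delta, v, zeta)
    psi = vec[:, 0]
    amps = psi.reshape(3, 2)
    coef = np.sqrt((np.abs(amps) ** 2).sum(axis=1))
    energies = (w[0], w[2], w[4])  # one per Kramers pair
    return HoleCoefficients.from_unnormalized(*coef), energies


def _time_reversal(psi: np.ndarray) -> np.ndarray:
    """T = -i sigma_y K applied to each orbital's spin pair."""
    amps = psi.reshape(3, 2)
    tamps = np.stack([-np.conj(amps[:, 1]), np.conj(amps[:, 0])], axis=1)
    return tamps.reshape(6)


def doublet_g_values(delta: float, v: float, zeta: float) -> SignedGTensor:
    """Signed g values directly from magnetic-moment matrix elements.

    Independent of the closed-form route: builds the ground doublet
    {psi, T psi}, evaluates the 2x2 blocks of mu_k = L_k + 2 S_k and
    collects their Pauli coefficients into the 3x3 matrix B with
    B_kj = 2 tr(M_k sigma_j)/2.  In the molecular (principal) frame
    B = diag(g) R^T for a pseudo-spin gauge rotation R, so |g_k| is the
    k-th row norm of B and the sign is carried by B_kk once the gauge is
    anchored.  The Taylor sign convention corresponds to the doublet
    member from the spin-down d_xy sector with that amplitude real
    positive (pure d_xy hole: mu_z diagonal = 2S_z = -1, giving the
    conventional g_z = -2).  Agrees with
    ``g_from_coefficients(soc_ground_doublet(...)[0])`` to machine
    precision; the two routes cross-validate each other.
    """
    _, vec = _ground_state(delta, v, zeta)
    psi = vec[:, 0]
    partner = _time_reversal(psi)
    # the Hamiltonian is block-diagonal in the sectors {yz-,xz-,xy+} and
    # {yz+,xz+,xy-}; canonicalize to the spin-down d_xy member
    if abs(psi[5]) < abs(partner[5]):
        psi = partner
    if abs(psi[5]) > 1e-12:
        psi = psi * np.conj(psi[5]) / abs(psi[5])
    psibar = _time_reversal(psi)
    b = np.zeros((3, 3))
    for k, (lk, sk) in enumerate(((_LX, _SX), (_LY, _SY), (_LZ, _SZ))):
        mu = np.kron(lk, _I2) + 2 * np.kron(_I3, sk)
        off = psi.conj() @ mu @ psibar
        diag = (psi.conj() @ mu @ psi).real
        b[k] = 2 * np.array([off.real, -off.imag, diag])
    # principal magnitudes: B B^T must be diagonal in the principal frame
    gram = b @ b.T
    if np.abs(gram - np.diag(np.diag(gram))).max() > 1e-8:
        raise AssertionError("moment matrix not diagonal in the molecular frame")
    mags = np.sqrt(np.diag(gram))
    return SignedGTensor(*(np.sign(np.diag(b)) * mags))


# ---------------------------------------------------------------------------
# Assignment search over permutations and signs
# ---------------------------------------------------------------------------

_AXES = ("x", "y", "z")


def assign_g_tensor(
    magnitudes: tuple[float, float, float],
    zeta: float = ZETA_DEFAULT_CM,
    residual_threshold: float = 0.1,
) -> list[AssignmentCandidate]:
    """Rank axis/sign assignments of experimental |g| magnitudes.

    EPR measures only |g|.  The Taylor inversion needs signed values on
    labelled axes, so every axis permutation and sign pattern (modulo
    the overall Kramers sign, fixed by taking g_y > 0) is tried: the
    coefficients are computed from the hypothesised signed triple, g is
    re-predicted from them, and the Euclidean distance between input and
    re-prediction is the consistency residual.  Candidates violating the
    proper-axis convention (rhombicity > 1/3, or V < 0) are dropped; the
    remainder are sorted by residual with rhombicity as tie-break.

    The V >= 0 filter removes an exact relabelling degeneracy: swapping
    the x and y magnitudes (with the matching signs) swaps a with b and
    flips the sign of V while describing the same physical site, so only
    the representative with d_yz below d_xz is kept.
    """
    mags = np.asarray(magnitudes, dtype=float)
    if mags.shape != (3,) or np.any(mags <= 0):
        raise ValueError("need three positive |g| magnitudes")

    candidates: list[AssignmentCandidate] = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            if signs[1] < 0:  # Kramers degeneracy: fix overall sign via g_y > 0
                continue
            gvals = np.array([signs[i] * mags[perm[i]] for i in range(3)])
            g = SignedGTensor(
                *gvals,
                axis_convention="|g|[{}]->x, |g|[{}]->y, |g|[{}]->z".format(*perm),
            )
            try:
                coeffs = coefficients_from_g(g)
                gpred = g_from_coefficients(coeffs)
            except (DegenerateAssignmentError, ValueError):
                # unresolvable ratios, or a re-predicted g outside (0, 4)
                continue
            residual = float(np.linalg.norm(gpred.as_array() - gvals))
            try:
                params = ligand_field_from_g(g, zeta=zeta)
            except DegenerateAssignmentError:
                params = None
            if params is not None and (
                params.rhombicity > 1 / 3 + 1e-9 or params.v < 0
            ):
                continue
            candidates.append(
                AssignmentCandidate(
                    permutation=tuple(_AXES[i] for i in perm),
                    signs=signs,
                    residual=residual,
                    parameters=params,
                    coefficients=coeffs,
                    g=g,
                )
            )
    candidates.sort(
        key=lambda c: (
            c.residual,
            c.parameters.rhombicity if c.parameters else np.inf,
        )
    )
    if not candidates or candidates[0].residual > residual_threshold:
        warnings.warn(
            "no assignment candidate below the consistency threshold "
            f"({residual_threshold}); returning all candidates",
            stacklevel=2,
        )
    return candidates
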