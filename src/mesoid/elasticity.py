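"""Kelvin-form elasticity tensor algebra.

Fourth-order elasticity and compliance tensors are stored as symmetric
positive-definite matrices in Kelvin (normalized Voigt / Mandel) form: 6x6 in
3D, 3x3 for the in-plane reduction used under the plane-stress assumption.
The Kelvin convention puts a factor sqrt(2) on the shear rows/columns so that
the Frobenius norm of the matrix equals the Frobenius norm of the underlying
fourth-order tensor, and a strain/stress vector contraction reproduces the
tensor double contraction exactly.  All internal math in the package is
Kelvin; engineering (Voigt) components appear only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ElasticTensor",
    "IsotropicModuli",
    "isotropic_stiffness",
    "isotropic_compliance",
    "engineering_constants",
    "moduli_from_engineering",
    "plane_stress_reduce",
    "frobenius_distance",
    "kelvin_to_tensor",
    "tensor_to_kelvin",
    "n_correlation_lengths",
]

_SQRT2 = np.sqrt(2.0)

# Kelvin index -> (i, j) pairs of the fourth-order tensor, 0-based.
_PAIRS_3D = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]
_PAIRS_2D = [(0, 0), (1, 1), (0, 1)]

# in-plane sub-block of a 6x6 Kelvin matrix: components 11, 22, 12
PLANE_IDX = np.array([0, 1, 5])


@dataclass
class IsotropicModuli:
    """Isotropic elastic moduli: bulk modulus ``kappa`` and shear modulus
    ``mu``, both in GPa."""

    kappa: float
    mu: float

    def __post_init__(self) -> None:
        if not (self.kappa > 0 and self.mu > 0):
            raise ValueError(
                f"moduli must be positive, got kappa={self.kappa}, mu={self.mu}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.kappa, self.mu])


@dataclass
class ElasticTensor:
    """A stiffness or compliance tensor in Kelvin matrix form.

    Parameters
    ----------
    kelvin : ndarray
        Symmetric positive-definite matrix, 6x6 (``form='full3d'``) or 3x3
        (``form='plane2d'``). Units GPa for stiffness, 1/GPa for compliance.
    kind : {'stiffness', 'compliance'}
    form : {'full3d', 'plane2d'}
    """

    kelvin: np.ndarray
    kind: str = "stiffness"
    form: str = "full3d"
    _validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.kelvin = np.asarray(self.kelvin, dtype=float)
        if self.kind not in ("stiffness", "compliance"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.form not in ("full3d", "plane2d"):
            raise ValueError(f"unknown form {self.form!r}")
        n = {"full3d": 6, "plane2d": 3}[self.form]
        if self.kelvin.shape != (n, n):
            raise ValueError(f"expected {n}x{n} matrix for form {self.form!r}")
        if self._validate:
            sym_err = np.linalg.norm(self.kelvin - self.kelvin.T)
            if sym_err > 1e-12 * max(np.linalg.norm(self.kelvin), 1.0):
                raise ValueError("Kelvin matrix is not symmetric")
            if np.linalg.eigvalsh(self.kelvin).min() <= 0:
                raise ValueError("Kelvin matrix is not positive definite")

    @property
    def n(self) -> int:
        return self.kelvin.shape[0]

    def inverse(self) -> "ElasticTensor":
        """Inverse tensor: stiffness <-> compliance."""
        other = "compliance" if self.kind == "stiffness" else "stiffness"
        inv = np.linalg.inv(self.kelvin)
        return ElasticTensor(0.5 * (inv + inv.T), kind=other, form=self.form,
                             _validate=False)

    def norm(self) -> float:
        return float(np.linalg.norm(self.kelvin))


def n_correlation_lengths(d: int = 3) -> int:
    """Number of possibly distinct spatial correlation lengths of a
    matrix-valued random field in dimension ``d``: d * n(n+1)/2 with
    n = d(d+1)/2 (63 for d=3)."""
    n = d * (d + 1) // 2
    return d * n * (n + 1) // 2


def isotropic_stiffness(m: IsotropicModuli, form: str = "full3d") -> ElasticTensor:
    """Isotropic stiffness tensor from bulk/shear moduli.

    ``full3d`` returns the classical 3D isotropic stiffness
    C = 3*kappa*P_vol + 2*mu*P_dev in Kelvin form.  ``plane2d`` returns the
    plane-stress stiffness consistent with the 3D moduli, i.e. the inverse of
    the in-plane sub-block of the 3D compliance.
    """
    c3 = _isotropic_kelvin(3.0 * m.kappa, 2.0 * m.mu)
    if form == "full3d":
        return ElasticTensor(c3, kind="stiffness", form="full3d", _validate=False)
    if form == "plane2d":
        s3 = isotropic_compliance(m, form="full3d")
        return plane_stress_reduce(s3).inverse()
    raise ValueError(f"unknown form {form!r}")


def isotropic_compliance(m: IsotropicModuli, form: str = "full3d") -> ElasticTensor:
    """Isotropic compliance tensor, inverse of :func:`isotropic_stiffness`."""
    s3 = _isotropic_kelvin(1.0 / (3.0 * m.kappa), 1.0 / (2.0 * m.mu))
    if form == "full3d":
        return ElasticTensor(s3, kind="compliance", form="full3d", _validate=False)
    if form == "plane2d":
        full = ElasticTensor(s3, kind="compliance", form="full3d", _validate=False)
        return plane_stress_reduce(full)
    raise ValueError(f"unknown form {form!r}")


def _isotropic_kelvin(three_kappa: float, two_mu: float) -> np.ndarray:
    # C = a*P_vol + b*P_dev with P_vol = m m^T / 3, m = (1,1,1,0,0,0)
    m = np.zeros(6)
    m[:3] = 1.0
    p_vol = np.outer(m, m) / 3.0
    p_dev = np.eye(6) - p_vol
    return three_kappa * p_vol + two_mu * p_dev


def engineering_constants(m: IsotropicModuli) -> tuple[float, float]:
    """Young's modulus and Poisson ratio from bulk/shear moduli:
    E = 9*kappa*mu/(3*kappa + mu), nu = (3*kappa - 2*mu)/(2*(3*kappa + mu))."""
    denom = 3.0 * m.kappa + m.mu
    e = 9.0 * m.kappa * m.mu / denom
    nu = (3.0 * m.kappa - 2.0 * m.mu) / (2.0 * denom)
    return float(e), float(nu)


def moduli_from_engineering(e: float, nu: float) -> IsotropicModuli:
    """Inverse of :func:`engineering_constants`."""
    kappa = e / (3.0 * (1.0 - 2.0 * nu))
    mu = e / (2.0 * (1.0 + nu))
    return IsotropicModuli(kappa, mu)


def plane_stress_reduce(s: ElasticTensor) -> ElasticTensor:
    """In-plane restriction of a 3D compliance tensor.

    Under plane stress only the components {S}_ijkh with i,j,k,h in {1,2}
    enter the 2D constitutive law; in Kelvin form this is the [11, 22, 12]
    sub-block of the 6x6 matrix.  The inverse of the result is the 2D
    plane-stress stiffness.
    """
    if s.form != "full3d" or s.kind != "compliance":
        raise ValueError("plane_stress_reduce expects a 3D compliance tensor")
    sub = s.kelvin[np.ix_(PLANE_IDX, PLANE_IDX)]
    if abs(np.linalg.det(sub)) < 1e-300:
        raise ValueError("singular in-plane compliance sub-block")
    return ElasticTensor(sub, kind="compliance", form="plane2d", _validate=False)


def reduce_kelvin_matrices(s6: np.ndarray) -> np.ndarray:
    """Vectorized in-plane sub-block extraction: (..., 6, 6) -> (..., 3, 3)."""
    return s6[..., PLANE_IDX[:, None], PLANE_IDX[None, :]]


def frobenius_distance(a: ElasticTensor, b: ElasticTensor) -> float:
    """Frobenius distance between two tensors of the same kind and form.

    Thanks to the Kelvin normalization this equals the component-wise
    fourth-order tensor distance.
    """
    if a.form != b.form or a.kind != b.kind:
        raise ValueError("tensors must share form and kind")
    return float(np.linalg.norm(a.kelvin - b.kelvin))


def tensor_to_kelvin(c: np.ndarray) -> np.ndarray:
    """Fourth-order tensor (3,3,3,3) or (2,2,2,2) with minor/major symmetries
    to its Kelvin matrix."""
    d = c.shape[0]
    pairs = _PAIRS_3D if d == 3 else _PAIRS_2D
    n = len(pairs)
    out = np.empty((n, n))
    for a_idx, (i, j) in enumerate(pairs):
        for b_idx, (k, h) in enumerate(pairs):
            fac = (1.0 if i == j else _SQRT2) * (1.0 if k == h else _SQRT2)
            out[a_idx, b_idx] = fac * c[i, j, k, h]
    return out


def kelvin_to_tensor(m: np.ndarray) -> np.ndarray:
    """Kelvin matrix back to the full fourth-order tensor (inverse of
    :func:`tensor_to_kelvin`)."""
    n = m.shape[0]
    pairs = _PAIRS_3D if n == 6 else _PAIRS_2D
    d = 3 if n == 6 else 2
    out = np.zeros((d, d, d, d))
    for a_idx, (i, j) in enumerate(pairs):
        for b_idx, (k, h) in enumerate(pairs):
            fac = (1.0 if i == j else _SQRT2) * (1.0 if k == h else _SQRT2)
            val = m[a_idx, b_idx] / fac
            for (p, q) in {(i, j), (j, i)}:
                for (r, s) in {(k, h), (h, k)}:
                    out[p, q, r, s] = val
    return out


def strain_tensor_to_kelvin(eps: np.ndarray) -> np.ndarray:
    """Symmetric second-order tensor -> Kelvin vector (last two axes)."""
    d = eps.shape[-1]
    pairs = _PAIRS_3D if d == 3 else _PAIRS_2D
    comps = []
    for (i, j) in pairs:
        fac = 1.0 if i == j else _SQRT2
        comps.append(fac * eps[..., i, j])
    return np.stack(comps, axis=-1)
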