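"""Torsional-energy evaluation and Fourier <-> Ryckaert-Bellemans conversion.

The fitted potential per dihedral is ``sum_j k^j (1 + cos(j phi))``; MD
engines commonly store the equivalent Ryckaert-Bellemans polynomial
``sum_n C_n cos^n(psi)`` with ``psi = phi - 180 deg``.  Because
``cos(phi) = -cos(psi)``, expanding each harmonic with the Chebyshev
identities

    cos 2phi = 2 cos^2 phi - 1
    cos 3phi = 4 cos^3 phi - 3 cos phi
    cos 4phi = 8 cos^4 phi - 8 cos^2 phi + 1

gives the exact linear map (c = cos psi):

    C0 = k1 + k3 + 2 k4
    C1 = -k1 + 3 k3
    C2 = 2 k2 - 8 k4
    C3 = -4 k3
    C4 = 8 k4
    C5 = 0

The constant term is preserved, so the two representations agree to
machine precision at every angle, not merely up to an additive shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .algebraic_fit import FourierParams
from .scan_model import DihedralTyping

__all__ = ["RBParams", "fourier_energy", "fourier_to_rb", "rb_energy"]


@dataclass(frozen=True)
class RBParams:
    """Ryckaert-Bellemans coefficients ``C0..C5`` per dihedral type, kJ/mol."""

    C: np.ndarray

    def __post_init__(self) -> None:
        C = np.atleast_2d(np.asarray(self.C, dtype=float))
        object.__setattr__(self, "C", C)
        if C.shape[1] != 6:
            raise ValueError(f"expected 6 RB coefficients per type, got {C.shape[1]}")
        if not np.all(np.isfinite(C)):
            raise ValueError("coefficients must be finite")

    @property
    def n_types(self) -> int:
        return self.C.shape[0]


def _per_instance_coeffs(params_matrix: np.ndarray, typing: DihedralTyping) -> np.ndarray:
    return params_matrix[np.asarray(typing.type_of)]


def fourier_energy(
    params: FourierParams,
    angles: np.ndarray,
    typing: DihedralTyping,
) -> float | np.ndarray:
    """Total torsional energy of conformer(s) under Fourier coefficients.

    Parameters
    ----------
    angles
        Dihedral angles in degrees, shape (n_dihedrals,) for one conformer
        or (n_conformers, n_dihedrals) for a batch.

    Returns
    -------
    Energy in kJ/mol (scalar or per-conformer vector), including the fitted
    offset when the parameter set carries one.
    """
    if params.n_types != typing.n_types:
        raise ValueError(
            f"parameter set has {params.n_types} types, typing has {typing.n_types}"
        )
    arr = np.asarray(angles, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != typing.n_dihedrals:
        raise ValueError(
            f"angle vector length {arr.shape[1]} does not match "
            f"{typing.n_dihedrals} dihedrals"
        )
    phi = np.deg2rad(arr)  # (K, I)
    js = np.arange(1, params.n_terms + 1)
    basis = 1.0 + np.cos(phi[:, :, None] * js)  # (K, I, J)
    k_inst = _per_instance_coeffs(params.k, typing)  # (I, J)
    e = np.einsum("kij,ij->k", basis, k_inst)
    if params.offset is not None:
        e = e + params.offset
    return float(e[0]) if single else e


def fourier_to_rb(params: FourierParams) -> RBParams:
    """Exact conversion of 1+cos(j phi) coefficients to RB polynomials.

    Three-term parameter sets are zero-padded (``k4 = 0``) so a single
    conversion path serves both fits.  The fitted offset, being a dataset
    artifact rather than a force-field parameter, is dropped.
    """
    if params.n_terms > 4:
        raise ValueError("conversion supports at most 4 Fourier terms")
    k = params.k
    if params.n_terms < 4:
        k = np.hstack([k, np.zeros((params.n_types, 4 - params.n_terms))])
    k1, k2, k3, k4 = k.T
    C = np.column_stack([
        k1 + k3 + 2 * k4,
        -k1 + 3 * k3,
        2 * k2 - 8 * k4,
        -4 * k3,
        8 * k4,
        np.zeros_like(k1),
    ])
    return RBParams(C=C)


def rb_energy(
    params: RBParams,
    angles: np.ndarray,
    typing: DihedralTyping,
) -> float | np.ndarray:
    """Total torsional energy under Ryckaert-Bellemans coefficients.

    Evaluates ``sum_n C_n cos^n(phi - 180 deg)`` per instance and sums over
    the molecule; angles in degrees, energy in kJ/mol.
    """
    if params.n_types != typing.n_types:
        raise ValueError(
            f"parameter set has {params.n_types} types, typing has {typing.n_types}"
        )
    arr = np.asarray(angles, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != typing.n_dihedrals:
        raise ValueError(
            f"angle vector length {arr.shape[1]} does not match "
            f"{typing.n_dihedrals} dihedrals"
        )
    c = np.cos(np.deg2rad(arr - 180.0))  # (K, I)
    powers = c[:, :, None] ** np.arange(6)  # (K, I, 6)
    C_inst = _per_instance_coeffs(params.C, typing)  # (I, 6)
    e = np.einsum("kin,in->k", powers, C_inst)
    return float(e[0]) if single else e
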