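"""Domain types for dihedral-scan datasets and design-matrix assembly.

A molecule's torsional potential is a sum over dihedral instances of a
truncated cosine series ``sum_j k_g^j * (1 + cos(j * phi))`` where the
coefficients ``k_g^j`` are shared by all instances of the same dihedral
*type* (the equivalence class of atom-type quadruples).  A conformer scan
records the value of *every* dihedral in every conformer, because a
constrained rotation of one dihedral relaxes all the others.  The fitting
problem is therefore a single linear least-squares system whose columns
aggregate the basis functions of all same-type instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DihedralTyping",
    "ConformerRecord",
    "ScanDataset",
    "DesignSystem",
    "build_design_system",
]

#: Half-open angle domain, degrees.  +180 is identified with -180.
ANGLE_MIN, ANGLE_MAX = -180.0, 180.0


def wrap_angle(angle: float | np.ndarray) -> float | np.ndarray:
    """Normalize angle(s) in degrees into the half-open interval [-180, 180)."""
    return ((np.asarray(angle, dtype=float) + 180.0) % 360.0) - 180.0


@dataclass(frozen=True)
class DihedralTyping:
    """Partition of a molecule's dihedral instances into shared-coefficient types.

    Parameters
    ----------
    type_of
        ``type_of[i]`` is the 0-based type index of dihedral instance ``i``.
        Every type index up to ``max(type_of)`` must occur at least once.
    type_labels
        Optional atom-type quadruple strings per type, e.g. ``"CT-OS-P-OS"``.
    """

    type_of: tuple[int, ...]
    type_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        type_of = tuple(int(t) for t in self.type_of)
        object.__setattr__(self, "type_of", type_of)
        if not type_of:
            raise ValueError("typing must contain at least one dihedral instance")
        if min(type_of) < 0:
            raise ValueError("type indices must be non-negative")
        n_types = max(type_of) + 1
        used = set(type_of)
        missing = sorted(set(range(n_types)) - used)
        if missing:
            raise ValueError(f"type indices {missing} are unused; types must be 0..n_types-1 with no gaps")
        if self.type_labels is not None:
            labels = tuple(str(s) for s in self.type_labels)
            object.__setattr__(self, "type_labels", labels)
            if len(labels) != n_types:
                raise ValueError(
                    f"expected {n_types} type labels, got {len(labels)}"
                )

    @property
    def n_dihedrals(self) -> int:
        return len(self.type_of)

    @property
    def n_types(self) -> int:
        return max(self.type_of) + 1

    @property
    def multiplicities(self) -> tuple[int, ...]:
        """Number of dihedral instances per type."""
        counts = np.bincount(np.asarray(self.type_of), minlength=self.n_types)
        return tuple(int(c) for c in counts)

    def members(self, type_index: int) -> tuple[int, ...]:
        """Instance indices belonging to ``type_index``."""
        return tuple(i for i, t in enumerate(self.type_of) if t == type_index)


@dataclass(frozen=True)
class ConformerRecord:
    """One conformer of a scan: all dihedral values plus its torsional target.

    ``e_target`` is the torsional energy left after subtracting the
    zero-torsion molecular-mechanics energy from the quantum-reference total,
    in kJ/mol.  ``angles`` holds every dihedral of the molecule in degrees;
    ``scanned_dihedral`` names the instance that was constrained to
    ``scan_angle`` when this conformer was generated.
    """

    conformer_id: str
    scanned_dihedral: int
    scan_angle: float
    angles: tuple[float, ...]
    e_target: float

    def __post_init__(self) -> None:
        angles = tuple(float(a) for a in self.angles)
        object.__setattr__(self, "angles", angles)
        object.__setattr__(self, "scan_angle", float(self.scan_angle))
        object.__setattr__(self, "e_target", float(self.e_target))
        if not 0 <= self.scanned_dihedral < len(angles):
            raise ValueError(
                f"record {self.conformer_id!r}: scanned_dihedral "
                f"{self.scanned_dihedral} outside 0..{len(angles) - 1}"
            )
        for i, a in enumerate(angles):
            if not (ANGLE_MIN <= a < ANGLE_MAX):
                raise ValueError(
                    f"record {self.conformer_id!r}: angle phi_{i}={a} outside "
                    f"[{ANGLE_MIN}, {ANGLE_MAX})"
                )
        if abs(angles[self.scanned_dihedral] - self.scan_angle) > 1e-6:
            raise ValueError(
                f"record {self.conformer_id!r}: scan_angle {self.scan_angle} does "
                f"not match angles[{self.scanned_dihedral}]="
                f"{angles[self.scanned_dihedral]}"
            )
        if not np.isfinite(self.e_target):
            raise ValueError(f"record {self.conformer_id!r}: non-finite e_target")


@dataclass(frozen=True)
class ScanDataset:
    """A full multi-dihedral scan: typing plus an ordered list of conformers."""

    typing: DihedralTyping
    records: tuple[ConformerRecord, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        records = tuple(self.records)
        object.__setattr__(self, "records", records)
        n = self.typing.n_dihedrals
        seen: set[str] = set()
        for rec in records:
            if len(rec.angles) != n:
                raise ValueError(
                    f"record {rec.conformer_id!r} has {len(rec.angles)} angles, "
                    f"typing declares {n} dihedrals"
                )
            if rec.conformer_id in seen:
                raise ValueError(f"duplicate conformer_id {rec.conformer_id!r}")
            seen.add(rec.conformer_id)

    def __len__(self) -> int:
        return len(self.records)

    def angles_matrix(self) -> np.ndarray:
        """All dihedral angles as an (n_conformers, n_dihedrals) array, degrees."""
        return np.array([r.angles for r in self.records], dtype=float)

    def targets(self) -> np.ndarray:
        return np.array([r.e_target for r in self.records], dtype=float)


@dataclass(frozen=True)
class DesignSystem:
    """Linear system ``B @ K ~ y`` for the shared-coefficient torsion fit.

    Column order is type-major then term-minor: ``(g=0, j=1..n_terms),
    (g=1, j=1..n_terms), ...``, with an optional trailing all-ones column
    absorbing the arbitrary additive constant between the quantum and
    molecular-mechanics energy zeros.  Entry ``B[k, (g, j)]`` is
    ``sum over instances i of type g of (1 + cos(j * phi_ik))``.
    """

    B: np.ndarray
    y: np.ndarray
    n_types: int
    n_terms: int
    has_offset: bool

    @property
    def n_coeffs(self) -> int:
        """Number of shared torsion coefficients (excludes the offset column)."""
        return self.n_types * self.n_terms

    def column_index(self, type_index: int, term: int) -> int:
        """Column of coefficient ``k_g^j`` (``term`` is j, counted from 1)."""
        if not 1 <= term <= self.n_terms:
            raise ValueError(f"term must be in 1..{self.n_terms}")
        return type_index * self.n_terms + (term - 1)


def basis_matrix(
    angles_deg: np.ndarray, typing: DihedralTyping, n_terms: int
) -> np.ndarray:
    """Aggregated cosine-basis matrix for a block of conformers.

    ``angles_deg`` has shape (n_conformers, n_dihedrals); the result has
    shape (n_conformers, n_types * n_terms), type-major / term-minor.
    """
    angles_deg = np.atleast_2d(np.asarray(angles_deg, dtype=float))
    phi = np.deg2rad(angles_deg)  # (K, I)
    n_conf = phi.shape[0]
    n_types = typing.n_types
    out = np.zeros((n_conf, n_types * n_terms))
    js = np.arange(1, n_terms + 1)
    # A[k, i, j] = 1 + cos(j * phi_ik); sum instances within each type
    A = 1.0 + np.cos(phi[:, :, None] * js[None, None, :])
    for g in range(n_types):
        idx = list(typing.members(g))
        out[:, g * n_terms : (g + 1) * n_terms] = A[:, idx, :].sum(axis=1)
    return out


def build_design_system(
    dataset: ScanDataset, n_terms: int = 4, include_offset: bool = True
) -> DesignSystem:
    """Assemble the least-squares system for a scan dataset.

    Parameters
    ----------
    dataset
        Conformers with their full dihedral-angle vectors and torsional
        energy targets (kJ/mol).
    n_terms
        Number of cosine terms per dihedral type, 3 or 4.
    include_offset
        Append a trailing all-ones column so the fit can absorb the
        arbitrary constant offset of the target energies (default on).

    Returns
    -------
    DesignSystem
        ``B`` of shape (n_conformers, n_types*n_terms [+1]) and target ``y``.
    """
    if n_terms not in (3, 4):
        raise ValueError(f"n_terms must be 3 or 4, got {n_terms}")
    if len(dataset) == 0:
        raise ValueError("cannot build a design system from an empty dataset")
    B = basis_matrix(dataset.angles_matrix(), dataset.typing, n_terms)
    if include_offset:
        B = np.hstack([B, np.ones((B.shape[0], 1))])
    return DesignSystem(
        B=B,
        y=dataset.targets(),
        n_types=dataset.typing.n_types,
        n_terms=n_terms,
        has_offset=include_offset,
    )
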