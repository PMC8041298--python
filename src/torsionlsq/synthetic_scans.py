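"""Synthetic dihedral-scan generator with known ground-truth coefficients.

Emulates the structure of a relaxed quantum-mechanical torsion scan: every
dihedral instance is driven over a half-open angular grid (default
-180..170 deg in 10-deg steps, 36 points) while the remaining, unscanned
dihedrals respond.  In a real relaxed scan the off-scan angles shift
because the molecule re-optimizes at each constrained point; here that
coupling is imitated by deterministic smooth functions of the scan angle
(or fixed / random alternatives).  Targets are exact torsional energies of
a known coefficient set plus optional Gaussian noise, so solvers and
metrics can be validated by round trip with no external data.
"""

from __future__ import annotations

import warnings

import numpy as np

from .algebraic_fit import FourierParams
from .potential_convert import fourier_energy
from .scan_model import (
    ConformerRecord,
    DihedralTyping,
    ScanDataset,
    basis_matrix,
    wrap_angle,
)

__all__ = ["generate_dataset", "dmph_typing", "random_params", "scan_grid"]

#: Atom-type quadruples of the six dihedral types of dimethyl phosphoric
#: acid (DMPH), the canonical small model molecule for phosphate torsions.
DMPH_TYPE_LABELS = (
    "CT-OS-P-OS",
    "CT-OS-P-O2",
    "CT-OS-P-OH",
    "HC-CT-OS-P",
    "HO-OH-P-O2",
    "HO-OH-P-OS",
)

#: Instances per type in DMPH: 15 dihedrals grouped as [2, 2, 2, 6, 1, 2].
DMPH_MULTIPLICITIES = (2, 2, 2, 6, 1, 2)


def dmph_typing() -> DihedralTyping:
    """Typing of the 15 dihedral instances of dimethyl phosphoric acid."""
    type_of: list[int] = []
    for g, m in enumerate(DMPH_MULTIPLICITIES):
        type_of.extend([g] * m)
    return DihedralTyping(type_of=tuple(type_of), type_labels=DMPH_TYPE_LABELS)


def scan_grid(grid_step: float = 10.0) -> np.ndarray:
    """Half-open scan grid [-180, 180) in degrees; 36 points at 10-deg step."""
    if grid_step <= 0 or abs(360.0 / grid_step - round(360.0 / grid_step)) > 1e-9:
        raise ValueError(f"grid_step must evenly divide 360, got {grid_step}")
    return np.arange(-180.0, 180.0 - 1e-9, grid_step)


def random_params(
    typing: DihedralTyping,
    n_terms: int = 4,
    scale: float = 5.0,
    offset: float | None = 0.0,
    seed: int = 0,
) -> FourierParams:
    """Random ground-truth coefficient set, uniform in [-scale, scale] kJ/mol.

    The default scale of 5 kJ/mol matches the magnitude of torsion
    coefficients typical of organophosphate force fields.
    """
    rng = np.random.default_rng(seed)
    k = rng.uniform(-scale, scale, size=(typing.n_types, n_terms))
    return FourierParams(k=k, offset=offset)


def _off_scan_angles(
    typing: DihedralTyping,
    coupling: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-instance baseline, coupling amplitude (deg) and phase (rad)."""
    n = typing.n_dihedrals
    base = rng.uniform(-180.0, 180.0, size=n)
    if coupling == "fixed":
        amp = np.zeros(n)
        phase = np.zeros(n)
    elif coupling == "smooth":
        # modest relaxation response: off-scan dihedrals swing by up to
        # ~40 deg as a smooth function of the driven angle
        amp = rng.uniform(15.0, 40.0, size=n)
        phase = rng.uniform(0.0, 2 * np.pi, size=n)
    else:
        raise ValueError(f"unknown coupling mode {coupling!r}")
    return base, amp, phase


def generate_dataset(
    typing: DihedralTyping,
    true_params: FourierParams,
    grid_step: float = 10.0,
    coupling: str = "smooth",
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline_angles: np.ndarray | None = None,
) -> ScanDataset:
    """Generate a full multi-dihedral scan dataset from known coefficients.

    One record is emitted per (dihedral instance, grid angle) pair; for the
    canonical 15-dihedral molecule at a 10-deg step this yields
    15 x 36 = 540 conformers.  Off-scan angles follow the ``coupling`` mode:

    ``"smooth"`` (default)
        Per-instance baseline plus a deterministic sinusoid of the scan
        angle, imitating a relaxed scan in which every profile is
        conjugated with the others.
    ``"fixed"``
        Off-scan angles frozen at per-instance baselines (can leave the
        design rank-deficient; a warning is emitted if so).
    ``"random"``
        Off-scan angles drawn uniformly per conformer.

    Targets are ``fourier_energy(true_params, angles)`` plus
    ``N(0, noise_sd)`` noise, kJ/mol.  Fully reproducible under ``seed``.
    ``baseline_angles`` overrides the per-instance baselines of the
    ``fixed``/``smooth`` modes (degrees, length ``n_dihedrals``).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    grid = scan_grid(grid_step)
    rng = np.random.default_rng(seed)
    n = typing.n_dihedrals

    if coupling == "random":
        base = amp = phase = None
    else:
        base, amp, phase = _off_scan_angles(typing, coupling, rng)
        if baseline_angles is not None:
            base = np.asarray(baseline_angles, dtype=float)
            if base.shape != (n,):
                raise ValueError(f"baseline_angles must have shape ({n},)")

    records: list[ConformerRecord] = []
    all_angles: list[np.ndarray] = []
    for d in range(n):
        for a in grid:
            if coupling == "random":
                angles = rng.uniform(-180.0, 180.0, size=n)
            else:
                angles = wrap_angle(base + amp * np.sin(np.deg2rad(a) + phase))
            angles[d] = a
            all_angles.append(angles.copy())
    angles_mat = np.array(all_angles)
    energies = np.asarray(fourier_energy(true_params, angles_mat, typing), dtype=float)
    if noise_sd > 0:
        energies = energies + rng.normal(0.0, noise_sd, size=energies.size)

    idx = 0
    for d in range(n):
        for a in grid:
            records.append(
                ConformerRecord(
                    conformer_id=f"d{d:02d}_a{int(round(a)):+04d}",
                    scanned_dihedral=d,
                    scan_angle=float(a),
                    angles=tuple(angles_mat[idx]),
                    e_target=float(energies[idx]),
                )
            )
            idx += 1
    dataset = ScanDataset(typing=typing, records=tuple(records))

    # warn when the emitted geometry cannot identify all coefficients
    B = basis_matrix(angles_mat, typing, true_params.n_terms)
    rank = int(np.linalg.matrix_rank(B.T @ B))
    if rank < B.shape[1]:
        warnings.warn(
            f"generated design is rank-deficient (rank {rank} < {B.shape[1]}); "
            "some coefficients will not be identifiable from this dataset",
            stacklevel=2,
        )
    return dataset
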