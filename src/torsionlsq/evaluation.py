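"""RMSD scoring of fitted torsional profiles against reference scans.

A fitted parameter set is judged by how well the model torsional energy
reproduces the reference (QM-derived) profile of each scanned dihedral.
Profiles are minimum-aligned by default — each is shifted so its minimum
is zero — because the quantum and molecular-mechanics energy zeros differ
by an arbitrary constant that carries no physical content.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .algebraic_fit import FitResult
from .potential_convert import fourier_energy
from .scan_model import ScanDataset

__all__ = ["profile_rmsd", "scan_report"]


def profile_rmsd(
    fitted: np.ndarray, reference: np.ndarray, align: bool = True
) -> float:
    """Root-mean-square deviation between two energy profiles, kJ/mol.

    With ``align`` each profile is first shifted so its minimum is zero,
    making the score invariant to constant offsets between the two energy
    scales.
    """
    fitted = np.asarray(fitted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fitted.shape != reference.shape or fitted.ndim != 1:
        raise ValueError(
            f"profiles must be 1-D of equal length, got {fitted.shape} vs "
            f"{reference.shape}"
        )
    if fitted.size < 2:
        raise ValueError("profiles must contain at least 2 points")
    if align:
        fitted = fitted - fitted.min()
        reference = reference - reference.min()
    return float(np.sqrt(np.mean((fitted - reference) ** 2)))


def scan_report(
    dataset: ScanDataset, fit: FitResult, align: bool = True
) -> pd.DataFrame:
    """Per-scanned-dihedral RMSD table for a fitted parameter set.

    Groups the dataset's conformers by the dihedral that was scanned,
    evaluates the fitted torsional energy for each conformer, and scores
    each scan's profile against the recorded targets.  The returned frame
    has one row per scanned dihedral (columns ``scanned_dihedral``,
    ``type_index``, ``type_label``, ``n_points``, ``rmsd_kj_mol``) plus its
    unweighted mean in ``frame.attrs["average_rmsd"]``.
    """
    typing = dataset.typing
    if fit.params.n_types != typing.n_types:
        raise ValueError(
            f"fit has {fit.params.n_types} types, dataset typing has "
            f"{typing.n_types}"
        )
    model_e = np.asarray(
        fourier_energy(fit.params, dataset.angles_matrix(), typing)
    )
    target_e = dataset.targets()
    scanned = np.array([r.scanned_dihedral for r in dataset.records])

    rows = []
    for d in sorted(set(scanned.tolist())):
        mask = scanned == d
        g = typing.type_of[d]
        label = typing.type_labels[g] if typing.type_labels else f"type{g}"
        rows.append(
            {
                "scanned_dihedral": d,
                "type_index": g,
                "type_label": label,
                "n_points": int(mask.sum()),
                "rmsd_kj_mol": profile_rmsd(model_e[mask], target_e[mask], align=align),
            }
        )
    report = pd.DataFrame(rows)
    report.attrs["average_rmsd"] = float(report["rmsd_kj_mol"].mean())
    return report
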