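"""File formats: scan/typing CSV, parameter YAML, and GROMACS .itp export.

Scan CSV layout (one row per conformer)::

    conformer_id,scanned_dihedral,scan_angle,e_target,phi_0,...,phi_{n-1}

with angles in degrees and energies in kJ/mol.  The typing CSV maps each
dihedral instance to its shared-coefficient type::

    dihedral_index,type_index,type_label
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .algebraic_fit import FourierParams
from .potential_convert import RBParams, fourier_to_rb
from .scan_model import ConformerRecord, DihedralTyping, ScanDataset

__all__ = [
    "read_scan_csv",
    "write_scan_csv",
    "read_typing_csv",
    "write_typing_csv",
    "write_itp",
    "read_itp",
    "write_params_yaml",
    "read_params_yaml",
]

_SCAN_FIXED_COLS = ["conformer_id", "scanned_dihedral", "scan_angle", "e_target"]


class ParseError(ValueError):
    """A structured input file failed validation."""


def write_typing_csv(typing: DihedralTyping, path: str | Path) -> None:
    labels = typing.type_labels or tuple(f"type{g}" for g in range(typing.n_types))
    df = pd.DataFrame(
        {
            "dihedral_index": range(typing.n_dihedrals),
            "type_index": list(typing.type_of),
            "type_label": [labels[g] for g in typing.type_of],
        }
    )
    df.to_csv(path, index=False)


def read_typing_csv(path: str | Path) -> DihedralTyping:
    df = pd.read_csv(path)
    for col in ("dihedral_index", "type_index"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    df = df.sort_values("dihedral_index")
    if list(df["dihedral_index"]) != list(range(len(df))):
        raise ParseError(f"{path}: dihedral_index must cover 0..{len(df) - 1}")
    type_of = tuple(int(t) for t in df["type_index"])
    labels = None
    if "type_label" in df.columns:
        n_types = max(type_of) + 1
        labels_arr = [""] * n_types
        for g, lab in zip(df["type_index"], df["type_label"]):
            labels_arr[int(g)] = str(lab)
        labels = tuple(labels_arr)
    return DihedralTyping(type_of=type_of, type_labels=labels)


def write_scan_csv(dataset: ScanDataset, path: str | Path) -> None:
    n = dataset.typing.n_dihedrals
    cols = {c: [] for c in _SCAN_FIXED_COLS}
    for rec in dataset.records:
        cols["conformer_id"].append(rec.conformer_id)
        cols["scanned_dihedral"].append(rec.scanned_dihedral)
        cols["scan_angle"].append(rec.scan_angle)
        cols["e_target"].append(rec.e_target)
    df = pd.DataFrame(cols)
    angles = dataset.angles_matrix()
    for i in range(n):
        df[f"phi_{i}"] = angles[:, i]
    df.to_csv(path, index=False, float_format="%.12g")


def read_scan_csv(path: str | Path, typing: DihedralTyping) -> ScanDataset:
    """Read a scan CSV and validate it against a typing.

    Raises :class:`ParseError` naming the offending column or line on
    missing columns, non-numeric fields or duplicate conformer ids.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    for col in _SCAN_FIXED_COLS:
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    n = typing.n_dihedrals
    phi_cols = [f"phi_{i}" for i in range(n)]
    for col in phi_cols:
        if col not in df.columns:
            raise ParseError(f"{path}: missing angle column {col!r}")
    for col in ["scanned_dihedral", "scan_angle", "e_target", *phi_cols]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if df[col].isna().any() or bad.any():
            row = int((df[col].isna() | bad).idxmax())
            raise ParseError(
                f"{path}: non-numeric or missing value in column {col!r} "
                f"(line {row + 2})"
            )
    dup = df["conformer_id"].duplicated()
    if dup.any():
        row = int(dup.idxmax())
        raise ParseError(
            f"{path}: duplicate conformer_id "
            f"{df['conformer_id'][row]!r} (line {row + 2})"
        )
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                ConformerRecord(
                    conformer_id=str(row["conformer_id"]),
                    scanned_dihedral=int(row["scanned_dihedral"]),
                    scan_angle=float(row["scan_angle"]),
                    angles=tuple(float(row[c]) for c in phi_cols),
                    e_target=float(row["e_target"]),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: line {int(idx) + 2}: {exc}") from exc
    return ScanDataset(typing=typing, records=tuple(records))


# --- GROMACS topology fragment -------------------------------------------

_ITP_HEADER = "[ dihedraltypes ]"


def _split_label(label: str) -> tuple[str, str, str, str]:
    parts = re.split(r"[-\s]+", label.strip())
    if len(parts) != 4:
        raise ValueError(
            f"type label {label!r} is not an atom-type quadruple like 'CT-OS-P-OS'"
        )
    return tuple(parts)  # type: ignore[return-value]


def write_itp(
    params: FourierParams | RBParams,
    typing: DihedralTyping,
    path: str | Path,
    style: str = "rb_func3",
) -> None:
    """Write a GROMACS ``[ dihedraltypes ]`` fragment.

    ``style="rb_func3"`` emits Ryckaert-Bellemans lines (function type 3,
    C0..C5); Fourier parameter sets are converted exactly first.
    ``style="fourier_func5"`` emits function type 5 with the four fitted
    coefficients of the ``1 + cos(j phi)`` basis (3-term sets are padded
    with a zero).  The fitted offset, when present, is recorded as a
    comment only.  Output is fixed-width 6-decimal and byte-stable.
    """
    if typing.type_labels is None:
        raise ValueError("typing has no atom-type labels; cannot write .itp")
    if style not in ("rb_func3", "fourier_func5"):
        raise ValueError(f"unknown style {style!r}")

    offset = None
    if style == "rb_func3":
        if isinstance(params, FourierParams):
            offset = params.offset
            rb = fourier_to_rb(params)
        else:
            rb = params
        coeff_rows = rb.C
        func = 3
    else:
        if not isinstance(params, FourierParams):
            raise ValueError("fourier_func5 export requires Fourier parameters")
        offset = params.offset
        k = params.k
        if params.n_terms < 4:
            k = np.hstack([k, np.zeros((params.n_types, 4 - params.n_terms))])
        coeff_rows = k
        func = 5

    if coeff_rows.shape[0] != typing.n_types:
        raise ValueError("parameter set and typing disagree on the type count")
    coeff_rows = coeff_rows + 0.0  # normalize -0.0 so output is byte-stable

    lines = [_ITP_HEADER]
    if func == 3:
        lines.append("; ai    aj    ak    al  func        C0        C1        C2        C3        C4        C5")
    else:
        lines.append("; ai    aj    ak    al  func        k1        k2        k3        k4   ; basis k*(1+cos(j*phi))")
    if offset is not None:
        lines.append(f"; fitted global energy offset (not a parameter): {offset:.6f} kJ/mol")
    for g in range(typing.n_types):
        a1, a2, a3, a4 = _split_label(typing.type_labels[g])
        coeffs = "  ".join(f"{c:10.6f}" for c in coeff_rows[g])
        lines.append(f"{a1:>4}  {a2:>4}  {a3:>4}  {a4:>4}  {func:4d}  {coeffs}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_itp(path: str | Path) -> tuple[DihedralTyping, np.ndarray, int]:
    """Parse a ``[ dihedraltypes ]`` fragment written by :func:`write_itp`.

    Returns a one-instance-per-type :class:`DihedralTyping`, the
    coefficient matrix (one row per type) and the GROMACS function type.
    """
    func_seen: set[int] = set()
    labels: list[str] = []
    rows: list[list[float]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split(";")[0].strip()
        if not line or line.startswith("["):
            continue
        parts = line.split()
        if len(parts) < 6:
            raise ParseError(f"{path}: malformed dihedraltypes line: {raw!r}")
        labels.append("-".join(parts[:4]))
        func_seen.add(int(parts[4]))
        rows.append([float(p) for p in parts[5:]])
    if not rows:
        raise ParseError(f"{path}: no dihedraltypes entries found")
    if len(func_seen) != 1:
        raise ParseError(f"{path}: mixed function types {sorted(func_seen)}")
    typing = DihedralTyping(
        type_of=tuple(range(len(labels))), type_labels=tuple(labels)
    )
    return typing, np.array(rows), func_seen.pop()


# --- parameter YAML -------------------------------------------------------

def write_params_yaml(params: FourierParams | RBParams, path: str | Path) -> None:
    if isinstance(params, FourierParams):
        doc = {
            "basis": "fourier",
            "k": [[float(v) for v in row] for row in params.k],
        }
        if params.offset is not None:
            doc["offset"] = float(params.offset)
    else:
        doc = {
            "basis": "ryckaert_bellemans",
            "C": [[float(v) for v in row] for row in params.C],
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_params_yaml(path: str | Path) -> FourierParams | RBParams:
    doc = yaml.safe_load(Path(path).read_text())
    basis = doc.get("basis")
    if basis == "fourier":
        return FourierParams(k=np.array(doc["k"]), offset=doc.get("offset"))
    if basis == "ryckaert_bellemans":
        return RBParams(C=np.array(doc["C"]))
    raise ParseError(f"{path}: unknown basis {basis!r}")
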