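"""Read and write the file formats the pipeline touches.

Multi-model PDB/PDBQT ligand pose files (MODEL/ENDMDL blocks, one file
per ligand, optional ``REMARK VINA RESULT`` score lines), delimited
residue-interaction tables, and TSV serializations of symmetric RMSD
matrices. PDBQT is treated as PDB columns plus ignorable extra fields;
the AutoDock atom-type column is translated back to an element symbol.
"""
from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyInputError, PoseFormatError, VocabularyError
from .model import Atom, InteractionRecord, LigandPose, PoseSet, RmsdMatrix

#: AutoDock/PDBQT atom types that differ from plain element symbols.
_PDBQT_TYPES = {
    "A": "C", "OA": "O", "NA": "N", "SA": "S",
    "HD": "H", "HS": "H", "NS": "N", "CL": "Cl", "BR": "Br",
}

_VINA_REMARK = re.compile(r"REMARK\s+VINA\s+RESULT:\s*(-?\d+(?:\.\d+)?)")

_INTERACTION_COLUMNS = [
    "ligand_id", "model_index", "chain", "resnum", "resname",
    "interaction_class",
]


def _element_from_name(name: str) -> str:
    """Infer the element from a PDB atom name (fallback when column 77-78
    is absent). Two-letter elements like Cl must occupy column 13."""
    stripped = name.strip()
    if not stripped:
        raise ValueError("empty atom name")
    head = stripped.lstrip("0123456789")
    if head[:2].capitalize() in ("Cl", "Br"):
        return head[:2].capitalize()
    return head[0].upper()


def _parse_atom_line(line: str, path, lineno: int, dialect: str) -> Atom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PoseFormatError(path, lineno, f"bad ATOM/HETATM record: {exc}")
    element_field = line[76:78].strip() if len(line) > 76 else ""
    try:
        if dialect == "pdbqt":
            # last whitespace token is the AutoDock atom type
            token = line[77:].split()[-1] if len(line) > 77 else element_field
            element = _PDBQT_TYPES.get(token.upper(), token.capitalize())
        elif element_field:
            element = element_field.capitalize()
        else:
            element = _element_from_name(name)
        return Atom(serial=serial, name=name, element=element, coords=(x, y, z))
    except (ValueError, IndexError) as exc:
        raise PoseFormatError(path, lineno, str(exc))


def read_pose_file(path, dialect: str | None = None, ligand_id: str | None = None):
    """Parse a multi-model PDB or PDBQT file into a list of LigandPose.

    One pose per MODEL block, in file order; a file without MODEL records
    but with ATOM/HETATM lines is read as a single model. The docking
    score is taken from a ``REMARK VINA RESULT`` line inside the block
    when present. Hydrogens are kept (they are flagged by element so
    scaffold extraction can exclude them).

    Parameters
    ----------
    dialect:
        ``"pdb"`` or ``"pdbqt"``; inferred from the file suffix if None.
    ligand_id:
        Defaults to the file stem.
    """
    path = Path(path)
    if dialect is None:
        dialect = "pdbqt" if path.suffix.lower() == ".pdbqt" else "pdb"
    if dialect not in ("pdb", "pdbqt"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if ligand_id is None:
        ligand_id = path.stem

    poses = []
    atoms: list | None = None
    score = None
    saw_model = False
    model_index = 0

    def close_model(lineno):
        nonlocal atoms, score
        if atoms is not None:
            if not atoms:
                raise PoseFormatError(path, lineno, "MODEL block with no atoms")
            poses.append(LigandPose(ligand_id, len(poses) + 1, atoms, score))
        atoms, score = None, None

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6].strip()
            if record == "MODEL":
                saw_model = True
                close_model(lineno)
                atoms = []
                try:
                    model_index = int(line.split()[1])
                except (IndexError, ValueError):
                    model_index = len(poses) + 1
                if model_index != len(poses) + 1:
                    raise PoseFormatError(
                        path, lineno,
                        f"MODEL {model_index} out of sequence "
                        f"(expected {len(poses) + 1})",
                    )
            elif record == "ENDMDL":
                close_model(lineno)
            elif record in ("ATOM", "HETATM"):
                if atoms is None:
                    if saw_model:
                        raise PoseFormatError(
                            path, lineno, "ATOM record outside MODEL block"
                        )
                    atoms = []  # single-model file without MODEL records
                atoms.append(_parse_atom_line(line, path, lineno, dialect))
            elif record == "REMARK" and atoms is not None:
                m = _VINA_REMARK.search(line)
                if m:
                    score = float(m.group(1))
        close_model("EOF")

    if not poses:
        raise EmptyInputError(f"{path}: no models found")
    return poses


def write_pose_file(path, poses, dialect: str = "pdb"):
    """Write poses as a multi-model PDB/PDBQT file (HETATM records)."""
    path = Path(path)
    lines = []
    for pose in poses:
        lines.append(f"MODEL {pose.model_index:8d}")
        if pose.docking_score is not None:
            lines.append(
                f"REMARK VINA RESULT: {pose.docking_score:9.1f}"
                f" {0.0:10.3f} {0.0:10.3f}"
            )
        for atom in pose.atoms:
            x, y, z = atom.coords
            element = atom.element
            type_field = element.upper() if dialect == "pdbqt" else element.rjust(2)
            lines.append(
                f"HETATM{atom.serial:5d} {atom.name:<4s}"
                f"{'LIG':>4s} A   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {type_field:<2s}"
            )
        lines.append("ENDMDL")
    path.write_text("\n".join(lines) + "\n")
    return path


def load_pose_dir(directory, dialect: str | None = None) -> PoseSet:
    """Read every .pdb/.pdbqt file in a directory into one PoseSet.

    Files are taken in sorted name order; the file stem is the ligand id.
    """
    directory = Path(directory)
    files = sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in (".pdb", ".pdbqt")
    )
    if not files:
        raise EmptyInputError(f"no pose files in {directory}")
    return PoseSet({p.stem: read_pose_file(p, dialect=dialect) for p in files})


def read_interaction_table(path):
    """Read a CSV/TSV residue-interaction table into InteractionRecords.

    The header must name the columns ligand_id, model_index, chain,
    resnum, resname and interaction_class; the delimiter is sniffed.
    An interaction class outside the closed vocabulary raises
    VocabularyError naming the offending value.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: empty interaction table")
    missing = [c for c in _INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise EmptyInputError(f"{path}: missing column(s) {missing}")
    records = []
    for row in df.itertuples(index=False):
        cls = str(row.interaction_class).strip()
        try:
            records.append(InteractionRecord(
                ligand_id=str(row.ligand_id).strip(),
                model_index=int(row.model_index),
                chain=str(row.chain).strip(),
                resnum=int(row.resnum),
                resname=str(row.resname).strip(),
                interaction_class=cls,
            ))
        except VocabularyError:
            raise VocabularyError(
                f"{path}: interaction class {cls!r} is not in the vocabulary"
            )
    return records


def write_interaction_table(path, records, sep: str = ","):
    df = pd.DataFrame(
        [(r.ligand_id, r.model_index, r.chain, r.resnum, r.resname,
          r.interaction_class) for r in records],
        columns=_INTERACTION_COLUMNS,
    )
    df.to_csv(path, sep=sep, index=False)
    return Path(path)


def write_matrix(matrix: RmsdMatrix, path):
    """Serialize a symmetric RMSD matrix as TSV, values to 3 decimals.

    Row/column labels are ``ligand_id/model_index``. Symmetry is
    validated by the RmsdMatrix container itself; re-reading the file
    reproduces the matrix at the printed precision.
    """
    path = Path(path)
    if not isinstance(matrix, RmsdMatrix):
        # (labels, values) pair: validation (square, symmetric, zero
        # diagonal) happens in the RmsdMatrix constructor
        labels_in, values_in = matrix
        matrix = RmsdMatrix(labels_in, values_in)
    labels = [f"{lig}/{mi}" for lig, mi in matrix.labels]
    with open(path, "w") as fh:
        fh.write("\t".join([""] + labels) + "\n")
        for lab, row in zip(labels, matrix.values):
            fh.write("\t".join([lab] + [f"{v:.3f}" for v in row]) + "\n")
    return path


def read_matrix(path) -> RmsdMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = []
    for lab in df.index:
        lig, _, mi = str(lab).rpartition("/")
        labels.append((lig, int(mi)))
    values = df.to_numpy(dtype=float)
    # exact symmetry can be lost to 3-decimal rounding; restore it
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    return RmsdMatrix(labels, values)
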