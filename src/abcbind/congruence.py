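"""Scaffold RMSD in the shared receptor frame and the all-vs-all matrix.

All poses come from docking into one fixed receptor model, so they live
in a common coordinate frame and the deviation between two poses is
measured directly, **without** superposition:

    RMSD(A, B) = sqrt( sum_i ||A_i - B_i||^2 / N )

over the N corresponding scaffold atoms (hydrogens excluded upstream).
An optional Kabsch superposition exists for diagnostic use but is off by
default, because superposing would discard exactly the placement
information the congruence analysis is about.

The same statistic over a named atom subset serves as the redocking
validation metric: a redocked pose is congruent with its reference when
the RMSD falls below a threshold, 4 Angstrom by default.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CoreCoordinates, LigandPose, RmsdMatrix

#: Default redocking congruence threshold, Angstrom.
CONGRUENCE_THRESHOLD = 4.0


def _as_points(x):
    if isinstance(x, CoreCoordinates):
        return x.points
    return np.asarray(x, dtype=float)


def _kabsch_superpose(moving: np.ndarray, fixed: np.ndarray) -> np.ndarray:
    mc, fc = moving.mean(axis=0), fixed.mean(axis=0)
    m, f = moving - mc, fixed - fc
    u, _, vt = np.linalg.svd(m.T @ f)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return m @ rot + fc


def core_rmsd(a, b, superpose: bool = False) -> float:
    """Scaffold RMSD between two poses over corresponding atoms.

    Parameters
    ----------
    a, b:
        CoreCoordinates (or plain (N, 3) arrays) in identical template
        order, sharing the receptor frame.
    superpose:
        If True, optimally superpose ``a`` onto ``b`` first (diagnostic
        only; the congruence analysis uses the raw frame).
    """
    pa, pb = _as_points(a), _as_points(b)
    if pa.shape != pb.shape:
        raise ValueError(
            f"core length mismatch: {pa.shape[0]} vs {pb.shape[0]} atoms"
        )
    if pa.shape[0] < 1:
        raise ValueError("need at least one atom")
    if superpose:
        pa = _kabsch_superpose(pa, pb)
    return float(np.sqrt(np.sum((pa - pb) ** 2) / pa.shape[0]))


def pairwise_matrix(cores: list) -> RmsdMatrix:
    """All-vs-all scaffold RMSD over a list of CoreCoordinates.

    Labels preserve input order (ligands grouped, models ascending when
    the input comes from a PoseSet). All cores must have the same atom
    count; mixing templates of different dimension is an error.
    """
    if not cores:
        raise ValueError("no cores given")
    sizes = {c.n_atoms for c in cores}
    if len(sizes) != 1:
        raise ValueError(f"mixed core sizes {sorted(sizes)}; same template required")
    coords = np.stack([c.points for c in cores])          # (P, N, 3)
    diff = coords[:, None, :, :] - coords[None, :, :, :]  # (P, P, N, 3)
    msd = np.mean(np.sum(diff * diff, axis=-1), axis=-1)
    values = np.sqrt(msd)
    np.fill_diagonal(values, 0.0)
    values = 0.5 * (values + values.T)  # exact symmetry against fp jitter
    labels = [(c.ligand_id, c.model_index) for c in cores]
    return RmsdMatrix(labels, values)


@dataclass(frozen=True)
class RedockResult:
    """Redocking validation outcome for one model."""

    rmsd: float
    congruent: bool
    threshold: float


def redock_rmsd(
    model: LigandPose,
    reference: LigandPose,
    atom_subset: list | None = None,
    threshold: float = CONGRUENCE_THRESHOLD,
) -> RedockResult:
    """Raw-frame RMSD of a redocked model to its reference position.

    Atoms are matched by name over ``atom_subset`` (all shared heavy
    atom names when None); hydrogens are always excluded. The companion
    predicate flags the model congruent when RMSD < threshold.
    """
    ref_atoms = {a.name: a for a in reference.heavy_atoms}
    mod_atoms = {a.name: a for a in model.heavy_atoms}
    if atom_subset is None:
        atom_subset = [a.name for a in reference.heavy_atoms if a.name in mod_atoms]
        if not atom_subset:
            raise ValueError("poses share no heavy atom names")
    missing = [n for n in atom_subset if n not in ref_atoms or n not in mod_atoms]
    if missing:
        raise ValueError(f"atom(s) {missing} missing from one of the poses")
    ref = np.array([ref_atoms[n].coords for n in atom_subset])
    mod = np.array([mod_atoms[n].coords for n in atom_subset])
    rmsd = core_rmsd(mod, ref)
    return RedockResult(rmsd=rmsd, congruent=rmsd < threshold, threshold=threshold)


def plot_heatmap(matrix: RmsdMatrix, path, cmap: str = "viridis"):
    """Render the convergence heat map as PNG (visualization only)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [f"{lig}/{mi}" for lig, mi in matrix.labels]
    fig, ax = plt.subplots(figsize=(0.25 * len(labels) + 2,) * 2)
    im = ax.imshow(matrix.values, cmap=cmap)
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=6)
    ax.set_yticks(range(len(labels)), labels, fontsize=6)
    fig.colorbar(im, ax=ax, label="scaffold RMSD [$\\AA$]")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
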