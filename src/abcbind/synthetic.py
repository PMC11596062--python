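"""Synthetic inputs with known ground truth.

Emulates the study design the pipeline consumes: five cardenolide
ligands docked into one receptor frame with nine models each (one
"planted" pose per ligand tightly clustered at a common binding site,
the rest decoys displaced elsewhere), residue-interaction tables that
are consistent with that geometry (shared binding-site residues appear
only on planted poses), and noisy paired +-vanadate Michaelis-Menten
dose-response data over the 0-800 uM assay range.

Docking scores are deliberately decoupled from the geometry — the
planted pose is never the best-scored model of its ligand — so that any
consensus recovery demonstrated on this data must come from scaffold
congruence plus interaction similarity, never from score ranking.

All generators are pure functions of their parameters and seed:
regeneration with the same arguments is byte-identical.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import pose_io
from .model import Atom, DoseResponse, InteractionRecord, LigandPose, PoseSet
from .scaffold import (
    CARDENOLIDE_LIGANDS,
    ScaffoldTemplate,
    default_cardenolide_template,
    template_geometry,
)

#: Binding-site residue pool used for shared interaction keys: the
#: lysine/glutamine H-bond donors to the lactone carbonyl and the
#: alanine/phenylalanine/valine hydrophobic contacts to the steroid core
#: that typify cardenolide-transporter interfaces.
BINDING_SITE_RESIDUES = (
    ("A", 214, "LYS", "conventional_hbond"),
    ("A", 880, "GLN", "conventional_hbond"),
    ("A", 888, "ALA", "pi_alkyl"),
    ("A", 361, "PHE", "pi_alkyl"),
    ("A", 943, "PHE", "alkyl"),
    ("A", 955, "GLN", "carbon_hbond"),
    ("A", 213, "VAL", "alkyl"),
    ("A", 737, "LYS", "conventional_hbond"),
)

_NOISE_CLASSES = (
    "van_der_waals", "alkyl", "pi_alkyl", "carbon_hbond",
    "conventional_hbond", "pi_pi", "salt_bridge", "unfavorable",
)

_NOISE_RESNAMES = ("LEU", "ILE", "MET", "SER", "THR", "TYR", "TRP", "GLY")

#: Default dose-response concentration grid, uM.
MM_GRID = (0.0, 1.0, 5.0, 10.0, 25.0, 50.0, 100.0, 200.0, 400.0, 800.0)


@dataclass
class SyntheticTruth:
    """Ground truth of a generated workspace; determines regeneration."""

    planted: dict                     # ligand_id -> model_index
    centroid: np.ndarray
    sigma_in: float
    decoy_shift: tuple
    seed: int
    shared_keys: list = field(default_factory=list)
    kinetics: dict = field(default_factory=dict)  # substrate -> (vmax, km)


def _random_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian, sign-fixed)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def generate_pose_set(
    n_ligands: int = 5,
    n_models: int = 9,
    sigma_in: float = 0.5,
    decoy_shift: tuple = (5.0, 20.0),
    seed: int = 0,
    template: ScaffoldTemplate | None = None,
    ligand_ids: tuple | None = None,
    outdir=None,
):
    """Pose sets with one planted consensus pose per ligand.

    Per ligand, the planted model is the scaffold template placed at a
    shared centroid with per-coordinate Gaussian jitter of ``sigma_in``
    Angstrom; the other ``n_models - 1`` models are decoys, randomly
    rotated about their own centroid and displaced by a uniformly drawn
    distance in ``decoy_shift``. Scores are drawn from U(-11, -7) and
    assigned so the planted pose sits mid-field, never first.

    Returns (PoseSet, SyntheticTruth); with ``outdir`` set, one
    multi-model PDB file per ligand is also written.
    """
    if n_ligands < 2 or n_models < 1:
        raise ValueError("need >= 2 ligands and >= 1 model per ligand")
    if template is None:
        template = default_cardenolide_template()
    if ligand_ids is None:
        ligand_ids = tuple(CARDENOLIDE_LIGANDS[:n_ligands]) + tuple(
            f"ligand{i}" for i in range(len(CARDENOLIDE_LIGANDS), n_ligands)
        )
    rng = np.random.default_rng(seed)
    base = np.asarray(template_geometry(template))
    centroid = np.zeros(3)
    elements = [elem for _, elem in template.atoms]
    labels = list(template.labels)

    ligands = {}
    planted = {}
    for lig in ligand_ids:
        planted_index = int(rng.integers(1, n_models + 1))
        planted[lig] = planted_index
        # scores: planted never best (most negative); median rank instead
        draws = np.sort(rng.uniform(-11.0, -7.0, size=n_models))
        decoy_scores = list(np.delete(draws, n_models // 2))
        rng.shuffle(decoy_scores)
        poses = []
        for mi in range(1, n_models + 1):
            if mi == planted_index:
                coords = base + centroid + rng.normal(0.0, sigma_in, base.shape)
                score = float(draws[n_models // 2])
            else:
                rot = _random_rotation(rng)
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                shift = rng.uniform(*decoy_shift)
                coords = (base @ rot.T) + centroid + shift * direction
                coords = coords + rng.normal(0.0, sigma_in, base.shape)
                score = float(decoy_scores.pop())
            atoms = [
                Atom(serial=i + 1, name=labels[i], element=elements[i],
                     coords=coords[i])
                for i in range(len(labels))
            ]
            poses.append(LigandPose(lig, mi, atoms, docking_score=score))
        ligands[lig] = poses

    pose_set = PoseSet(ligands)
    truth = SyntheticTruth(
        planted=planted, centroid=centroid, sigma_in=sigma_in,
        decoy_shift=tuple(decoy_shift), seed=seed,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for lig, poses in ligands.items():
            pose_io.write_pose_file(outdir / f"{lig}.pdb", poses)
    return pose_set, truth


def generate_interactions(
    pose_set: PoseSet,
    truth: SyntheticTruth,
    shared_site_keys: int = 4,
    noise_keys: int = 2,
    seed: int = 0,
    path=None,
):
    """Residue-interaction records consistent with the planted geometry.

    Planted poses receive all ``shared_site_keys`` binding-site residue
    keys (hence each shared key occurs in every ligand) plus
    ``noise_keys`` private keys; decoy poses receive only private keys.
    Private residue numbers are globally unique, so they can never
    recur across ligands.
    """
    if shared_site_keys > len(BINDING_SITE_RESIDUES):
        raise ValueError(
            f"at most {len(BINDING_SITE_RESIDUES)} shared site keys available"
        )
    rng = np.random.default_rng(seed)
    shared = list(BINDING_SITE_RESIDUES[:shared_site_keys])
    truth.shared_keys = [
        ((chain, resnum, resname), cls) for chain, resnum, resname, cls in shared
    ]
    records = []
    private_resnum = 2000  # far above any binding-site residue number
    for pose in pose_set.poses():
        if truth.planted[pose.ligand_id] == pose.model_index:
            for chain, resnum, resname, cls in shared:
                records.append(InteractionRecord(
                    pose.ligand_id, pose.model_index, chain, resnum, resname, cls
                ))
        for _ in range(noise_keys):
            private_resnum += 1
            records.append(InteractionRecord(
                pose.ligand_id, pose.model_index, "A", private_resnum,
                _NOISE_RESNAMES[int(rng.integers(len(_NOISE_RESNAMES)))],
                _NOISE_CLASSES[int(rng.integers(len(_NOISE_CLASSES)))],
            ))
    if path is not None:
        pose_io.write_interaction_table(path, records)
    return records


def generate_mm_data(
    vmax: float,
    km: float,
    grid: tuple = MM_GRID,
    replicates: int = 5,
    sigma_frac: float = 0.05,
    baseline: float = 5.0,
    seed: int = 0,
    substrate_id: str = "digoxin",
    path=None,
) -> DoseResponse:
    """Noisy paired +-vanadate dose-response data for one substrate.

    The no-vanadate arm is baseline + Vmax*S/(Km+S) + Gaussian noise of
    ``sigma_frac * vmax``; the vanadate arm models complete transporter
    inhibition: baseline + noise only. Their difference therefore
    recovers the Michaelis-Menten curve exactly in expectation.
    """
    if vmax <= 0 or km <= 0:
        raise ValueError("Vmax and Km must be positive")
    rng = np.random.default_rng(seed)
    sigma = sigma_frac * vmax
    rows = []
    for rep in range(1, replicates + 1):
        for s in grid:
            signal = vmax * s / (km + s)
            no_van = baseline + signal + (rng.normal(0.0, sigma) if sigma else 0.0)
            with_van = baseline + (rng.normal(0.0, sigma) if sigma else 0.0)
            rows.append((s, rep, no_van, with_van))
    data = pd.DataFrame(rows, columns=[
        "concentration_uM", "replicate", "activity_no_vanadate",
        "activity_vanadate",
    ])
    d = DoseResponse(
        substrate_id=substrate_id,
        data=data,
        metadata={"vanadate_uM": 500.0, "dmso_percent": 2.0,
                  "truth_vmax": vmax, "truth_km": km, "seed": seed},
    )
    if path is not None:
        df = data.copy()
        df.insert(0, "substrate", substrate_id)
        df.to_csv(path, index=False)
    return d


#: Realistic kinetic magnitudes per transporter/substrate for the demo
#: workspace (Vmax in nmol Pi/mg protein/min, Km in uM).
DEMO_KINETICS = {
    "transporter1": {"digoxin": (21.08, 33.73), "ouabain": (11.78, 48.56)},
    "transporter2": {"digoxin": (12.54, 9.33), "ouabain": (13.30, 7.05)},
}


def make_demo_workspace(outdir, seed: int = 0, sigma_in: float = 0.5):
    """Materialize a complete two-transporter demo workspace.

    Per transporter: five 9-model ligand pose files, an interaction
    table, and a paired dose-response CSV for the two assayable
    substrates. Returns {transporter: (PoseSet, SyntheticTruth)}.
    """
    outdir = Path(outdir)
    out = {}
    for t_index, (transporter, kinetics) in enumerate(DEMO_KINETICS.items()):
        tdir = outdir / transporter
        pose_set, truth = generate_pose_set(
            seed=seed + 101 * t_index, sigma_in=sigma_in,
            outdir=tdir / "poses",
        )
        generate_interactions(
            pose_set, truth, seed=seed + 101 * t_index + 1,
            path=tdir / "interactions.csv",
        )
        truth.kinetics = dict(kinetics)
        responses = [
            generate_mm_data(
                vmax, km, seed=seed + 101 * t_index + 2 + i,
                substrate_id=substrate,
            )
            for i, (substrate, (vmax, km)) in enumerate(kinetics.items())
        ]
        from .kinetics import write_dose_response

        write_dose_response(tdir / "dose_response.csv", responses)
        out[transporter] = (pose_set, truth)
    return out
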