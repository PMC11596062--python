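import numpy as np
import pytest

from abcbind.congruence import pairwise_matrix
from abcbind.model import Atom, CoreCoordinates, LigandPose, PoseSet
from abcbind.scaffold import default_cardenolide_template, template_geometry


@pytest.fixture(scope="session")
def template():
    return default_cardenolide_template()


@pytest.fixture(scope="session")
def core_geometry(template):
    """Fixed 3-D embedding of the 25-atom scaffold, template order."""
    return np.asarray(template_geometry(template))


def make_pose(
    coords,
    ligand_id="lig",
    model_index=1,
    names=None,
    elements=None,
    score=None,
    serial_start=1,
):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if names is None:
        names = [f"C{i + 1}" for i in range(n)]
    if elements is None:
        elements = ["C"] * n
    atoms = [
        Atom(serial=serial_start + i, name=names[i], element=elements[i],
             coords=coords[i])
        for i in range(n)
    ]
    return LigandPose(ligand_id, model_index, atoms, docking_score=score)


def scaffold_pose(geometry, template, ligand_id="lig", model_index=1,
                  score=None, offset=(0.0, 0.0, 0.0)):
    """A pose whose atoms are the scaffold template at a given offset."""
    return make_pose(
        np.asarray(geometry) + np.asarray(offset, dtype=float),
        ligand_id=ligand_id,
        model_index=model_index,
        names=list(template.labels),
        elements=[e for _, e in template.atoms],
        score=score,
    )


def point_pose_set(positions: dict):
    """PoseSet of single-carbon poses plus its cores and RMSD matrix.

    ``positions`` maps ligand_id -> list of 3-vectors (one per model);
    with one atom per pose, the pairwise scaffold RMSD is simply the
    Euclidean distance between the points, making expected values easy
    to state by hand.
    """
    ligands = {}
    cores = []
    for lig, pts in positions.items():
        poses = []
        for mi, p in enumerate(pts, start=1):
            poses.append(make_pose([p], ligand_id=lig, model_index=mi))
            cores.append(CoreCoordinates(lig, mi, [p]))
        ligands[lig] = poses
    pose_set = PoseSet(ligands)
    return pose_set, cores, pairwise_matrix(cores)
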