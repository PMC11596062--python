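"""Domain types shared across the pipeline.

Coordinates are Angstrom throughout, docking scores kcal/mol (more
negative = more favorable), ATPase activities nmol Pi/mg protein/min and
substrate concentrations uM. No unit conversion happens anywhere in the
package.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Closed vocabulary of protein-ligand interaction classes, following the
#: categories reported by interaction-diagram software for docking poses.
INTERACTION_CLASSES = frozenset({
    "conventional_hbond",   # conventional hydrogen bond
    "carbon_hbond",         # carbon-hydrogen bond
    "salt_bridge",          # salt bridge / attractive charge
    "pi_pi",                # pi-pi or amide-pi stacking
    "pi_alkyl",
    "alkyl",
    "van_der_waals",
    "unfavorable",
})

#: Interaction classes counted as hydrogen bonds in the H-bond/alkyl ratio.
HBOND_CLASSES = frozenset({"conventional_hbond", "carbon_hbond"})
#: Interaction classes counted as alkyl-type in the H-bond/alkyl ratio.
ALKYL_CLASSES = frozenset({"alkyl", "pi_alkyl"})

_KNOWN_ELEMENTS = frozenset({
    "H", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I", "B", "Se", "Mg",
    "Na", "K", "Ca", "Zn", "Fe", "Mn", "Cu",
})


@dataclass
class Atom:
    """One atom of a docked ligand pose."""

    serial: int
    name: str
    element: str
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"atom {self.name}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if self.element not in _KNOWN_ELEMENTS:
            raise ValueError(f"atom {self.name}: unknown element {self.element!r}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class LigandPose:
    """One docked conformation (MODEL block) of one ligand."""

    ligand_id: str
    model_index: int
    atoms: list
    docking_score: Optional[float] = None

    def __post_init__(self):
        if self.model_index < 1:
            raise ValueError("model_index must be >= 1")
        if not any(not a.is_hydrogen for a in self.atoms):
            raise ValueError(
                f"{self.ligand_id}/{self.model_index}: pose has no heavy atoms"
            )

    @property
    def heavy_atoms(self) -> list:
        return [a for a in self.atoms if not a.is_hydrogen]

    @property
    def label(self) -> str:
        return f"{self.ligand_id}/{self.model_index}"


class PoseSet:
    """All poses of a docking run, grouped by ligand in input order."""

    def __init__(self, ligands: dict):
        if not ligands:
            raise ValueError("PoseSet needs at least one ligand")
        for lig, poses in ligands.items():
            if not poses:
                raise ValueError(f"ligand {lig!r} has no poses")
            seen = [p.model_index for p in poses]
            if len(set(seen)) != len(seen):
                raise ValueError(f"ligand {lig!r}: duplicate model_index")
        self.ligands = dict(ligands)

    @property
    def ligand_ids(self) -> list:
        return list(self.ligands)

    @property
    def n_poses(self) -> int:
        return sum(len(p) for p in self.ligands.values())

    def poses(self):
        """Iterate poses grouped by ligand, models in stored order."""
        for poses in self.ligands.values():
            yield from poses

    def get(self, ligand_id: str, model_index: int) -> LigandPose:
        for pose in self.ligands[ligand_id]:
            if pose.model_index == model_index:
                return pose
        raise KeyError(f"{ligand_id}/{model_index} not in pose set")

    def labels(self) -> list:
        return [(p.ligand_id, p.model_index) for p in self.poses()]


@dataclass(frozen=True)
class InteractionRecord:
    """One residue-level protein-ligand interaction of one pose."""

    ligand_id: str
    model_index: int
    chain: str
    resnum: int
    resname: str
    interaction_class: str

    def __post_init__(self):
        if self.interaction_class not in INTERACTION_CLASSES:
            from .errors import VocabularyError

            raise VocabularyError(
                f"unknown interaction class {self.interaction_class!r}; "
                f"expected one of {sorted(INTERACTION_CLASSES)}"
            )

    @property
    def residue(self) -> tuple:
        return (self.chain, self.resnum, self.resname)


@dataclass
class CoreCoordinates:
    """Scaffold-atom coordinates of a pose, in template atom order."""

    ligand_id: str
    model_index: int
    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite core coordinates")

    @property
    def n_atoms(self) -> int:
        return self.points.shape[0]

    @property
    def label(self) -> str:
        return f"{self.ligand_id}/{self.model_index}"


class RmsdMatrix:
    """Symmetric all-vs-all scaffold RMSD matrix with pose labels."""

    def __init__(self, labels: list, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("RMSD matrix must be square")
        if len(labels) != values.shape[0]:
            raise ValueError("label count does not match matrix size")
        if not np.allclose(values, values.T, atol=1e-9):
            raise ValueError("RMSD matrix must be symmetric")
        if np.any(values < 0):
            raise ValueError("RMSD values must be >= 0")
        if not np.allclose(np.diag(values), 0.0, atol=1e-9):
            raise ValueError("RMSD matrix diagonal must be zero")
        self.labels = [(str(l), int(m)) for l, m in labels]
        self.values = values
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self):
        return len(self.labels)

    def index_of(self, ligand_id: str, model_index: int) -> int:
        return self._index[(ligand_id, int(model_index))]

    def rmsd(self, a: tuple, b: tuple) -> float:
        return float(self.values[self._index[a], self._index[b]])


@dataclass(frozen=True)
class Constellation:
    """One pose per ligand, with the mean pairwise scaffold RMSD."""

    members: tuple            # ((ligand_id, model_index), ...) in ligand order
    mean_rmsd: float
    index: int                # 1-based rank under the canonical sort

    @property
    def members_dict(self) -> dict:
        return dict(self.members)


@dataclass(frozen=True)
class SimilarityResult:
    """Interaction similarity of a constellation: counts and factor Sf."""

    b_total: int
    b_similar: int
    sf: float

    def __post_init__(self):
        if not (0 <= self.b_similar <= self.b_total):
            raise ValueError("need 0 <= b_similar <= b_total")
        if not (0.0 <= self.sf <= 1.0):
            raise ValueError("sf must lie in [0, 1]")


@dataclass
class BondClassSummary:
    """Per-class interaction counts and the H-bond/alkyl ratio."""

    counts: dict
    hb_alkyl_ratio: Optional[float]

    @property
    def n_records(self) -> int:
        return sum(self.counts.values())


@dataclass
class KineticFit:
    """Michaelis-Menten fit: Vmax +- SE, Km +- SE, fit diagnostics."""

    vmax: float
    vmax_se: float
    km: float
    km_se: float
    rss: float
    n_points: int

    def __post_init__(self):
        if self.vmax <= 0 or self.km <= 0:
            raise ValueError("converged Vmax and Km must be positive")
        if self.vmax_se < 0 or self.km_se < 0:
            raise ValueError("standard errors must be >= 0")

    def velocity(self, s):
        """Fitted velocity v = Vmax * S / (Km + S)."""
        s = np.asarray(s, dtype=float)
        return self.vmax * s / (self.km + s)


@dataclass
class DoseResponse:
    """Paired +-vanadate ATPase dose-response measurements.

    ``data`` columns: concentration_uM, replicate, activity_no_vanadate,
    activity_vanadate. Metadata records assay conditions (vanadate 500 uM,
    2% DMSO) without entering any computation.
    """

    substrate_id: str
    data: "pandas.DataFrame"  # noqa: F821 - forward name only
    metadata: dict = field(default_factory=dict)


@dataclass
class CurveComparison:
    """Extra-sum-of-squares F comparison of two Michaelis-Menten fits."""

    f_statistic: float
    df_num: int
    df_den: int
    p_value: float


@dataclass
class SelectionReport:
    """Outcome of the two-step consensus constellation selection."""

    chosen: Constellation
    similarity: Optional[SimilarityResult]
    member_scores: dict                   # ligand_id -> docking score or None
    candidates: list                      # [(Constellation, SimilarityResult|None)]
    warnings: list = field(default_factory=list)
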