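"""Scaffold templates and pose-to-template atom correspondence.

Different cardenolides share the aglycone: a tetracyclic steroid nucleus
(rings A-D, carbons C1-C17 plus the angular methyls C18/C19) carrying a
butenolide (unsaturated five-membered lactone) at C17. Scaffold RMSD
between poses of *different* cardenolides is only meaningful over
corresponding atoms of this common core, ignoring sugar residues and
substituents, so every pose must first be mapped onto a shared ordered
template. Two mapping modes are provided:

``by_name``
    Look template atom labels up in the pose via a per-ligand name map
    (identity by default). Deterministic and auditable; the default.
``by_graph``
    Perceive pose connectivity from interatomic distances (covalent
    radii + 0.45 Angstrom tolerance) and find the template graph as an
    element-matched induced subgraph. Fallback for arbitrary inputs
    whose atom names do not follow the template convention.

The shipped 25-atom composition (17 ring carbons, C18, C19, butenolide
carbons C20-C23, the lactone ring oxygen and its carbonyl oxygen) is a
reconstructed convention for the "steroid structure plus lactone ring"
core and is replaceable via configuration.
"""
from __future__ import annotations

import functools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import yaml

from .errors import AmbiguousMappingError, UnmappedAtomError
from .model import CoreCoordinates, LigandPose

log = logging.getLogger(__name__)

#: Single-bond covalent radii, Angstrom (Cordero et al. consensus values).
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}

#: Extra slack on the sum of covalent radii when perceiving bonds.
BOND_TOLERANCE = 0.45

#: The five cardenolide ligands studied; synthetic pose files for these
#: use template atom labels directly, so the shipped name maps are
#: identity maps. Real exports with other naming conventions supply
#: their own maps via load_name_maps().
CARDENOLIDE_LIGANDS = ("cymarin", "digoxin", "frugoside", "oleandrin", "ouabain")


@dataclass(frozen=True)
class ScaffoldTemplate:
    """Named, ordered scaffold atom list with its bond graph."""

    name: str
    atoms: tuple      # ((label, element), ...) -- order fixes RMSD order
    bonds: tuple      # ((label_a, label_b), ...)

    def __post_init__(self):
        labels = [lab for lab, _ in self.atoms]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate template atom labels")
        known = set(labels)
        for a, b in self.bonds:
            if a not in known or b not in known:
                raise ValueError(f"bond ({a}, {b}) references unknown atom")
        if not nx.is_connected(self.graph()):
            raise ValueError("template graph must be connected")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def labels(self) -> tuple:
        return tuple(lab for lab, _ in self.atoms)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for lab, elem in self.atoms:
            g.add_node(lab, element=elem)
        g.add_edges_from(self.bonds)
        return g


def default_cardenolide_template() -> ScaffoldTemplate:
    """The 25-atom cardenolide aglycone core.

    Gonane numbering: rings A (C1-C5, C10), B (C5-C10), C (C8, C9,
    C11-C14), D (C13-C17); angular methyls C18 (on C13) and C19 (on
    C10); butenolide C20-C23 attached at C17, closed by the ring oxygen
    O21 (between C21 and C23) with the carbonyl oxygen O23 on C23.
    23 carbons + 2 oxygens = 25 heavy atoms.
    """
    carbons = [(f"C{i}", "C") for i in range(1, 24)]
    atoms = tuple(carbons + [("O21", "O"), ("O23", "O")])
    bonds = (
        # ring A
        ("C1", "C2"), ("C2", "C3"), ("C3", "C4"), ("C4", "C5"),
        ("C5", "C10"), ("C10", "C1"),
        # ring B
        ("C5", "C6"), ("C6", "C7"), ("C7", "C8"), ("C8", "C9"),
        ("C9", "C10"),
        # ring C
        ("C8", "C14"), ("C9", "C11"), ("C11", "C12"), ("C12", "C13"),
        ("C13", "C14"),
        # ring D
        ("C13", "C17"), ("C14", "C15"), ("C15", "C16"), ("C16", "C17"),
        # angular methyls
        ("C13", "C18"), ("C10", "C19"),
        # butenolide (lactone) ring and carbonyl
        ("C17", "C20"), ("C20", "C21"), ("C21", "O21"), ("O21", "C23"),
        ("C23", "C22"), ("C22", "C20"), ("C23", "O23"),
    )
    return ScaffoldTemplate(name="cardenolide-core-25", atoms=atoms, bonds=bonds)


@functools.lru_cache(maxsize=None)
def template_geometry(template: ScaffoldTemplate, seed: int = 20240901) -> np.ndarray:
    """A fixed, chemically plausible 3-D embedding of a template.

    Uses RDKit distance-geometry embedding (ETKDG, seeded, hence
    deterministic) on the template bond graph and returns coordinates in
    template atom order, centered on the origin. Used by the synthetic
    pose generator and by geometry fixtures.
    """
    from rdkit import Chem, RDLogger
    from rdkit.Chem import AllChem

    RDLogger.DisableLog("rdApp.warning")  # bare heavy-atom graph is intended
    rw = Chem.RWMol()
    index = {}
    for lab, elem in template.atoms:
        index[lab] = rw.AddAtom(Chem.Atom(elem))
    for a, b in template.bonds:
        rw.AddBond(index[a], index[b], Chem.BondType.SINGLE)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError(f"could not embed template {template.name}")
    conf = mol.GetConformer()
    coords = np.array(
        [list(conf.GetAtomPosition(index[lab])) for lab in template.labels]
    )
    coords -= coords.mean(axis=0)
    coords.setflags(write=False)
    return coords


def default_name_maps() -> dict:
    """Identity name maps for the five shipped cardenolide ligands."""
    template = default_cardenolide_template()
    identity = {lab: lab for lab in template.labels}
    return {lig: dict(identity) for lig in CARDENOLIDE_LIGANDS}


def load_name_maps(path) -> dict:
    """Load per-ligand template-label -> pose-atom-name maps from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {
        str(lig): {str(k): str(v) for k, v in mapping.items()}
        for lig, mapping in raw.items()
    }


def perceive_bonds(atoms) -> nx.Graph:
    """Distance-based connectivity over heavy atoms.

    Two atoms are bonded when their distance is below the sum of their
    covalent radii plus BOND_TOLERANCE.
    """
    heavy = [a for a in atoms if not a.is_hydrogen]
    g = nx.Graph()
    for i, a in enumerate(heavy):
        g.add_node(i, element=a.element, atom=a)
    coords = np.array([a.coords for a in heavy])
    radii = np.array([COVALENT_RADII.get(a.element, 0.76) for a in heavy])
    for i in range(len(heavy)):
        d = np.linalg.norm(coords[i + 1:] - coords[i], axis=1)
        cutoff = radii[i] + radii[i + 1:] + BOND_TOLERANCE
        for off in np.nonzero(d < cutoff)[0]:
            g.add_edge(i, int(i + 1 + off))
    return g


def _resolve_by_name(pose, template, name_map):
    if name_map is None:
        name_map = {lab: lab for lab in template.labels}
    missing = [lab for lab in template.labels if lab not in name_map]
    if missing:
        raise UnmappedAtomError(
            f"name_map does not cover template atom(s) {missing}"
        )
    by_name = {}
    for atom in pose.heavy_atoms:
        by_name.setdefault(atom.name, atom)
    points = []
    for lab in template.labels:
        atom = by_name.get(name_map[lab])
        if atom is None:
            raise UnmappedAtomError(
                f"{pose.label}: no atom named {name_map[lab]!r} "
                f"for template atom {lab}"
            )
        points.append(atom.coords)
    return np.array(points)


def _resolve_by_graph(pose, template):
    pose_graph = perceive_bonds(pose.atoms)
    matcher = nx.isomorphism.GraphMatcher(
        pose_graph, template.graph(),
        node_match=lambda pa, ta: pa["element"] == ta["element"],
    )
    embeddings = []
    for mapping in matcher.subgraph_isomorphisms_iter():
        inverse = {tlab: pose_graph.nodes[pi]["atom"] for pi, tlab in mapping.items()}
        embeddings.append(inverse)
    if not embeddings:
        raise UnmappedAtomError(
            f"{pose.label}: template {template.name} is not an "
            f"element-matched subgraph of the pose connectivity"
        )
    coord_sets = [
        np.array([emb[lab].coords for lab in template.labels])
        for emb in embeddings
    ]
    distinct = any(
        not np.allclose(coord_sets[0], cs, atol=1e-6) for cs in coord_sets[1:]
    )
    if distinct:
        listing = [
            tuple(int(emb[lab].serial) for lab in template.labels)
            for emb in embeddings
        ]
        raise AmbiguousMappingError(
            listing,
            f"{pose.label}: {len(embeddings)} geometrically distinct "
            f"template embeddings",
        )
    if len(embeddings) > 1:
        log.warning(
            "%s: %d symmetry-equivalent embeddings; choosing the one with "
            "lexicographically smallest atom serials", pose.label,
            len(embeddings),
        )
    # deterministic tie-break on pose atom serial sequence
    best = min(
        range(len(embeddings)),
        key=lambda i: tuple(
            int(embeddings[i][lab].serial) for lab in template.labels
        ),
    )
    return coord_sets[best]


def resolve_correspondence(
    pose: LigandPose,
    template: ScaffoldTemplate,
    mode: str = "by_name",
    name_map: dict | None = None,
) -> CoreCoordinates:
    """Map a pose onto the scaffold template, returning ordered core
    coordinates (hydrogens and non-core atoms, e.g. sugars, excluded).

    The mapping is a bijection from template atoms to pose atoms and is
    deterministic for a given input; an unmapped template atom raises
    UnmappedAtomError naming the label, and geometrically distinct
    graph embeddings raise AmbiguousMappingError.
    """
    if mode == "by_name":
        points = _resolve_by_name(pose, template, name_map)
    elif mode == "by_graph":
        points = _resolve_by_graph(pose, template)
    else:
        raise ValueError(f"unknown correspondence mode {mode!r}")
    return CoreCoordinates(pose.ligand_id, pose.model_index, points)


def extract_cores(
    pose_set,
    template: ScaffoldTemplate | None = None,
    mode: str = "by_name",
    name_maps: dict | None = None,
) -> list:
    """Resolve correspondences for every pose of a set, in set order."""
    if template is None:
        template = default_cardenolide_template()
    cores = []
    for pose in pose_set.poses():
        name_map = None if name_maps is None else name_maps.get(pose.ligand_id)
        cores.append(resolve_correspondence(pose, template, mode, name_map))
    return cores
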