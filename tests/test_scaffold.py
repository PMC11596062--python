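from collections import Counter

import numpy as np
import pytest

from abcbind.errors import AmbiguousMappingError, UnmappedAtomError
from abcbind.model import Atom, LigandPose
from abcbind.scaffold import (
    ScaffoldTemplate,
    default_cardenolide_template,
    default_name_maps,
    perceive_bonds,
    resolve_correspondence,
)

from conftest import make_pose, scaffold_pose


class TestDefaultTemplate:
    def test_has_25_atoms(self, template):
        assert template.n_atoms == 25

    def test_element_multiset_is_23_carbon_2_oxygen(self, template):
        counts = Counter(elem for _, elem in template.atoms)
        assert counts == {"C": 23, "O": 2}

    def test_graph_is_connected_and_rigid(self, template):
        import networkx as nx

        g = template.graph()
        assert nx.is_connected(g)
        # exactly one element-preserving automorphism: graph matching
        # of a pose onto the template can never be symmetry-ambiguous
        gm = nx.isomorphism.GraphMatcher(
            g, g, node_match=lambda a, b: a["element"] == b["element"]
        )
        assert sum(1 for _ in gm.isomorphisms_iter()) == 1

    def test_bond_endpoints_validated(self):
        with pytest.raises(ValueError, match="unknown atom"):
            ScaffoldTemplate("bad", (("C1", "C"),), (("C1", "C2"),))

    def test_disconnected_template_rejected(self):
        with pytest.raises(ValueError, match="connected"):
            ScaffoldTemplate("bad", (("C1", "C"), ("C2", "C")), ())

    def test_shipped_name_maps_cover_all_template_labels(self, template):
        maps = default_name_maps()
        assert set(maps) == {
            "cymarin", "digoxin", "frugoside", "oleandrin", "ouabain"
        }
        for mapping in maps.values():
            assert set(mapping) == set(template.labels)


def brute_force_embeddings(pose_graph, template):
    """Independent recursive subgraph matcher (oracle for by_graph).

    Maps template atoms one at a time onto pose graph nodes, enforcing
    element equality and exact adjacency (induced) consistency.
    """
    tgraph = template.graph()
    labels = list(template.labels)
    results = []

    def extend(assignment):
        if len(assignment) == len(labels):
            results.append(dict(assignment))
            return
        lab = labels[len(assignment)]
        want_elem = tgraph.nodes[lab]["element"]
        used = set(assignment.values())
        for node in pose_graph.nodes:
            if node in used:
                continue
            if pose_graph.nodes[node]["element"] != want_elem:
                continue
            ok = True
            for prev_lab, prev_node in assignment.items():
                bonded_t = tgraph.has_edge(lab, prev_lab)
                bonded_p = pose_graph.has_edge(node, prev_node)
                if bonded_t != bonded_p:
                    ok = False
                    break
            if ok:
                extend({**assignment, lab: node})

    extend({})
    return results


class TestResolveCorrespondence:
    def test_by_name_identity_returns_template_order(self, template,
                                                     core_geometry):
        pose = scaffold_pose(core_geometry, template)
        core = resolve_correspondence(pose, template, mode="by_name")
        np.testing.assert_allclose(core.points, core_geometry)

    def test_invariant_to_atom_order_permutation(self, template,
                                                 core_geometry):
        rng = np.random.default_rng(7)
        perm = rng.permutation(25)
        atoms = [
            Atom(serial=i + 1, name=template.labels[j],
                 element=template.atoms[j][1], coords=core_geometry[j])
            for i, j in enumerate(perm)
        ]
        pose = LigandPose("lig", 1, atoms)
        core = resolve_correspondence(pose, template, mode="by_name")
        np.testing.assert_allclose(core.points, core_geometry)

    def test_sugar_atoms_excluded_from_core(self, template, core_geometry):
        # digoxin-like pose: scaffold plus a glycone appended far away
        sugar_names = ["C1'", "C2'", "O5'"]
        sugar_coords = core_geometry.mean(axis=0) + np.array(
            [[8.0, 0, 0], [9.5, 0, 0], [8.7, 1.3, 0]]
        )
        coords = np.vstack([core_geometry, sugar_coords])
        names = list(template.labels) + sugar_names
        elements = [e for _, e in template.atoms] + ["C", "C", "O"]
        pose = make_pose(coords, "digoxin", 1, names=names, elements=elements)
        core = resolve_correspondence(pose, template, mode="by_name")
        assert core.n_atoms == 25
        # hand-built index list: scaffold atoms are exactly the first 25
        np.testing.assert_allclose(core.points, coords[:25])

    def test_hydrogens_never_enter_core(self, template, core_geometry):
        coords = np.vstack([core_geometry, [[0.0, 0.0, 9.9]]])
        names = list(template.labels) + ["C1"]  # H sharing a core name
        elements = [e for _, e in template.atoms] + ["H"]
        pose = make_pose(coords, "lig", 1, names=names, elements=elements)
        core = resolve_correspondence(pose, template, mode="by_name")
        np.testing.assert_allclose(core.points, core_geometry)

    def test_unmapped_template_atom_names_the_label(self, template,
                                                    core_geometry):
        pose = scaffold_pose(core_geometry, template)
        pose.atoms[0].name = "XX"  # C1 disappears
        with pytest.raises(UnmappedAtomError, match="C1"):
            resolve_correspondence(pose, template, mode="by_name")

    def test_by_graph_equals_by_name_on_relabeled_geometry(self, template,
                                                           core_geometry):
        named = scaffold_pose(core_geometry, template)
        relabeled = make_pose(
            core_geometry, "lig", 1,
            names=[f"X{i}" for i in range(25)],
            elements=[e for _, e in template.atoms],
        )
        by_name = resolve_correspondence(named, template, mode="by_name")
        by_graph = resolve_correspondence(relabeled, template, mode="by_graph")
        np.testing.assert_allclose(by_graph.points, by_name.points)

    def test_by_graph_agrees_with_brute_force_oracle(self, template,
                                                     core_geometry):
        pose = make_pose(
            core_geometry, "lig", 1,
            names=[f"X{i}" for i in range(25)],
            elements=[e for _, e in template.atoms],
        )
        embeddings = brute_force_embeddings(perceive_bonds(pose.atoms), template)
        assert len(embeddings) == 1
        oracle_points = np.array([
            core_geometry[embeddings[0][lab]] for lab in template.labels
        ])
        core = resolve_correspondence(pose, template, mode="by_graph")
        np.testing.assert_allclose(core.points, oracle_points)

    def test_by_graph_sugar_pose_still_finds_core(self, template,
                                                  core_geometry):
        # append a two-carbon substituent bonded to C3 (1.5 A steps)
        c3 = core_geometry[2]
        away = c3 / np.linalg.norm(c3)
        extra = np.array([c3 + 1.5 * away, c3 + 3.0 * away])
        coords = np.vstack([core_geometry, extra])
        pose = make_pose(
            coords, "lig", 1,
            names=[f"X{i}" for i in range(27)],
            elements=[e for _, e in template.atoms] + ["C", "C"],
        )
        core = resolve_correspondence(pose, template, mode="by_graph")
        np.testing.assert_allclose(core.points, core_geometry)

    def test_symmetric_molecule_raises_ambiguity(self):
        chain = ScaffoldTemplate(
            "c3-chain", (("A1", "C"), ("A2", "C"), ("A3", "C")),
            (("A1", "A2"), ("A2", "A3")),
        )
        pose = make_pose(
            [[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0]], names=["P1", "P2", "P3"]
        )
        with pytest.raises(AmbiguousMappingError):
            resolve_correspondence(pose, chain, mode="by_graph")

    def test_name_map_must_cover_template(self, template, core_geometry):
        pose = scaffold_pose(core_geometry, template)
        with pytest.raises(UnmappedAtomError, match="O23"):
            resolve_correspondence(
                pose, template, mode="by_name",
                name_map={lab: lab for lab in template.labels[:-1]},
            )
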