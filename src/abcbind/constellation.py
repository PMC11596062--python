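"""Enumerate and rank one-pose-per-ligand constellations.

A constellation picks exactly one docked model per ligand; its score is
the arithmetic mean of the scaffold RMSDs over all C(L, 2) member
pairs. Low mean RMSD means the chosen models of the different
cardenolides occupy the same region of the receptor — step 1 of the
two-step consensus binding-region search (step 2, interaction
similarity, lives in :mod:`abcbind.similarity`).

Full enumeration is the default (9^5 = 59,049 combinations for the
5-ligand x 9-model study design is trivial); a beam search over ligands
is available for larger pose sets and is validated against full
enumeration. Constellation indices are 1-based ranks under the
canonical sort (ascending mean RMSD, ties by lexicographic member
tuple) — a deterministic convention of this package.
"""
from __future__ import annotations

import itertools

import numpy as np

from .errors import EnumerationCapError
from .model import Constellation, PoseSet, RmsdMatrix

#: Largest number of combinations full enumeration will attempt.
FULL_ENUMERATION_CAP = 10 ** 6


def mean_rmsd(members, matrix: RmsdMatrix) -> float:
    """Mean pairwise scaffold RMSD over all unordered member pairs.

    ``members`` maps ligand_id -> model_index and must cover >= 2
    ligands.
    """
    items = list(members.items() if isinstance(members, dict) else members)
    if len(items) < 2:
        raise ValueError("mean RMSD needs at least 2 ligands")
    idx = [matrix.index_of(lig, mi) for lig, mi in items]
    total = 0.0
    for i, j in itertools.combinations(idx, 2):
        total += matrix.values[i, j]
    return total / (len(idx) * (len(idx) - 1) / 2)


def _finalize(member_tuples, sums, n_pairs, ligand_ids, matrix):
    """Canonical sort and 1-based rank assignment."""
    order = sorted(
        range(len(member_tuples)),
        key=lambda i: (sums[i], member_tuples[i]),
    )
    out = []
    for rank, i in enumerate(order, start=1):
        members = tuple(
            (lig, matrix.labels[j][1])
            for lig, j in zip(ligand_ids, member_tuples[i])
        )
        out.append(Constellation(
            members=members,
            mean_rmsd=float(sums[i] / n_pairs),
            index=rank,
        ))
    return out


def _enumerate_full(index_lists, matrix):
    grids = np.meshgrid(*[np.asarray(ix) for ix in index_lists], indexing="ij")
    combos = np.stack([g.ravel() for g in grids], axis=1)   # (K, L)
    L = combos.shape[1]
    sums = np.zeros(combos.shape[0])
    for i, j in itertools.combinations(range(L), 2):
        sums += matrix.values[combos[:, i], combos[:, j]]
    return [tuple(int(v) for v in row) for row in combos], sums


def _enumerate_beam(index_lists, matrix, beam_width):
    # states: (partial pair-RMSD sum, tuple of chosen matrix indices)
    states = [(0.0, ())]
    for ix_list in index_lists:
        extended = []
        for total, chosen in states:
            for j in ix_list:
                add = sum(matrix.values[c, j] for c in chosen)
                extended.append((total + add, chosen + (j,)))
        extended.sort(key=lambda s: (s[0], s[1]))
        states = extended[:beam_width]
    member_tuples = [chosen for _, chosen in states]
    # recompute final sums in the canonical pair order (same float
    # addition sequence as full enumeration) so both modes agree exactly
    sums = np.zeros(len(member_tuples))
    L = len(index_lists)
    for i, j in itertools.combinations(range(L), 2):
        sums += np.array([
            matrix.values[c[i], c[j]] for c in member_tuples
        ])
    return member_tuples, sums


def enumerate_constellations(
    pose_set: PoseSet,
    matrix: RmsdMatrix,
    mode: str = "full",
    beam_width: int = 50,
    cap: int = FULL_ENUMERATION_CAP,
) -> list:
    """All (or beam-retained) constellations, canonically sorted.

    Returns Constellation objects sorted ascending by mean pairwise
    RMSD, ties broken by the lexicographic member tuple; ``index`` is
    the 1-based rank after sorting. Full mode refuses to enumerate more
    than ``cap`` combinations.
    """
    ligand_ids = pose_set.ligand_ids
    if len(ligand_ids) < 2:
        raise ValueError("constellation enumeration needs >= 2 ligands")
    index_lists = [
        [matrix.index_of(lig, p.model_index) for p in pose_set.ligands[lig]]
        for lig in ligand_ids
    ]
    n_pairs = len(ligand_ids) * (len(ligand_ids) - 1) / 2
    if mode == "full":
        n_combos = int(np.prod([len(ix) for ix in index_lists], dtype=np.int64))
        if n_combos > cap:
            raise EnumerationCapError(
                f"{n_combos} combinations exceed the full-enumeration cap "
                f"({cap}); use beam mode"
            )
        member_tuples, sums = _enumerate_full(index_lists, matrix)
    elif mode == "beam":
        if beam_width < 1:
            raise ValueError("beam_width must be >= 1")
        member_tuples, sums = _enumerate_beam(index_lists, matrix, beam_width)
    else:
        raise ValueError(f"unknown enumeration mode {mode!r}")
    return _finalize(member_tuples, sums, n_pairs, ligand_ids, matrix)


def top_k(constellations: list, k: int = 15) -> list:
    """First k constellations of the canonical order (all, if fewer)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return list(constellations[:k])
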