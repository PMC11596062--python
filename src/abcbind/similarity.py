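"""Interaction similarity of a constellation (the similarity factor Sf).

Step 2 of the consensus search compares the residue-level protein-
ligand interactions of a constellation's member poses. With

    B_total   = number of interaction records of the member poses,
    B_similar = number of those records whose key (residue identity,
                plus interaction class in the default key mode) also
                occurs in the member pose of at least one *other*
                ligand,

the similarity factor is

    Sf = B_similar / B_total,

a dimensionless fraction in [0, 1]: the share of a constellation's
interactions that recur across ligands, i.e. evidence that the ligands
bind one common region through shared residues. "Recurs" is read as
"appears in >= 2 distinct ligands' member poses"; each record counts
once in B_total and once in B_similar when its key qualifies.

Reported values are rounded to 2 decimals half-up; full precision is
retained internally.
"""
from __future__ import annotations

import logging
from collections import Counter
from decimal import ROUND_HALF_UP, Decimal

from .model import (
    ALKYL_CLASSES,
    HBOND_CLASSES,
    BondClassSummary,
    Constellation,
    INTERACTION_CLASSES,
    SimilarityResult,
)

log = logging.getLogger(__name__)

KEY_MODES = ("residue_and_class", "residue_only")


def sf_from_counts(b_similar: int, b_total: int) -> float:
    """Similarity factor from raw counts: Sf = B_similar / B_total."""
    if b_total == 0:
        raise ValueError("Sf is undefined for zero total interactions")
    if not 0 <= b_similar <= b_total:
        raise ValueError(
            f"need 0 <= b_similar <= b_total, got ({b_similar}, {b_total})"
        )
    return b_similar / b_total


def round_report(value: float, ndigits: int = 2) -> float:
    """Half-up rounding used for report tables (0.625 -> 0.63)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _record_key(record, key_mode: str):
    if key_mode == "residue_and_class":
        return (record.residue, record.interaction_class)
    if key_mode == "residue_only":
        return record.residue
    raise ValueError(f"unknown key_mode {key_mode!r}; expected {KEY_MODES}")


def constellation_similarity(
    c: Constellation,
    records: list,
    key_mode: str = "residue_and_class",
) -> SimilarityResult:
    """Sf of a constellation given the full interaction record list.

    Records are restricted to the member poses; a member pose with no
    records contributes zero and is logged. A record is similar iff its
    key occurs in the member poses of >= 2 distinct ligands.
    """
    members = set(c.members)
    member_records = [
        r for r in records if (r.ligand_id, r.model_index) in members
    ]
    covered = {(r.ligand_id, r.model_index) for r in member_records}
    for member in sorted(members - covered):
        log.warning("constellation %d: member %s/%s has no interaction "
                    "records", c.index, *member)

    b_total = len(member_records)
    if b_total == 0:
        raise ValueError(
            f"constellation {c.index}: no interaction records for any member"
        )
    ligands_per_key: dict = {}
    for r in member_records:
        ligands_per_key.setdefault(_record_key(r, key_mode), set()).add(r.ligand_id)
    b_similar = sum(
        1 for r in member_records
        if len(ligands_per_key[_record_key(r, key_mode)]) >= 2
    )
    return SimilarityResult(
        b_total=b_total,
        b_similar=b_similar,
        sf=sf_from_counts(b_similar, b_total),
    )


def bond_class_summary(records: list) -> BondClassSummary:
    """Per-class interaction counts and the H-bond/alkyl ratio.

    The ratio is (conventional + carbon H-bonds) / (alkyl + pi-alkyl)
    and is None when the denominator is zero.
    """
    if not records:
        raise ValueError("bond class summary needs at least one record")
    counts = Counter(r.interaction_class for r in records)
    counts = {cls: counts.get(cls, 0) for cls in sorted(INTERACTION_CLASSES)}
    hbonds = sum(counts[c] for c in HBOND_CLASSES)
    alkyl = sum(counts[c] for c in ALKYL_CLASSES)
    ratio = hbonds / alkyl if alkyl > 0 else None
    return BondClassSummary(counts=counts, hb_alkyl_ratio=ratio)
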