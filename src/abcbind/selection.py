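"""Step-2 selection of the consensus binding-region constellation.

Among the top-k constellations by steric congruence (lowest mean
pairwise scaffold RMSD), pick the one with the highest similarity
factor. Sf takes priority over RMSD rank: a sterically slightly worse
constellation wins when its interactions recur more strongly across
ligands. Ties on Sf fall back to lower mean RMSD, then lower index.
The selection is strictly rule-based — Sf maximum, not a weighted
composite — and never consults docking scores; scores are only echoed
in the report.
"""
from __future__ import annotations

import logging
from pathlib import Path

from .constellation import enumerate_constellations, top_k
from .model import PoseSet, RmsdMatrix, SelectionReport, SimilarityResult
from .similarity import constellation_similarity, round_report

log = logging.getLogger(__name__)


def select_constellation(
    pose_set: PoseSet,
    matrix: RmsdMatrix,
    records: list,
    k: int = 15,
    key_mode: str = "residue_and_class",
    mode: str = "full",
    beam_width: int = 50,
) -> SelectionReport:
    """Two-step consensus selection over a pose set.

    Step 1: rank all one-pose-per-ligand constellations by mean pairwise
    scaffold RMSD and keep the top k (default 15). Step 2: compute Sf
    for each candidate and choose the Sf maximum (ties: lower mean
    RMSD, then lower index). With no interaction records at all the
    selection degenerates to the congruence rank-1 constellation, with
    a logged warning.
    """
    warnings = []
    ranked = enumerate_constellations(
        pose_set, matrix, mode=mode, beam_width=beam_width
    )
    candidates = top_k(ranked, k=k)

    scored = []
    for cand in candidates:
        if records:
            member_keys = set(cand.members)
            if any((r.ligand_id, r.model_index) in member_keys for r in records):
                sim = constellation_similarity(cand, records, key_mode)
            else:
                # fully record-less candidate: zero interactions to share
                log.warning("constellation %d has no interaction records",
                            cand.index)
                sim = SimilarityResult(b_total=0, b_similar=0, sf=0.0)
            scored.append((cand, sim))
        else:
            scored.append((cand, None))

    if not records:
        msg = ("no interaction records: degenerating to the congruence "
               "rank-1 constellation")
        log.warning(msg)
        warnings.append(msg)
        chosen, similarity = scored[0]
    else:
        chosen, similarity = min(
            scored, key=lambda cs: (-cs[1].sf, cs[0].mean_rmsd, cs[0].index)
        )

    member_scores = {
        lig: pose_set.get(lig, mi).docking_score for lig, mi in chosen.members
    }
    return SelectionReport(
        chosen=chosen,
        similarity=similarity,
        member_scores=member_scores,
        candidates=scored,
        warnings=warnings,
    )


def write_selection_report(
    report: SelectionReport,
    out_dir,
    stem: str = "selection",
    pose_set: PoseSet | None = None,
):
    """Write the candidate table (TSV) and a text summary.

    The TSV mirrors the similarity-report layout: index, members, mean
    RMSD, total and similar bond counts, Sf (2 decimals, half-up) and
    per-ligand docking scores (per candidate when a pose_set is given).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ligands = [lig for lig, _ in report.chosen.members]

    tsv = out_dir / f"{stem}.tsv"
    header = (
        ["index", "mean_rmsd", "bonds_total", "bonds_similar", "sf"]
        + [f"score_{lig}" for lig in ligands]
        + [f"model_{lig}" for lig in ligands]
    )
    with open(tsv, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for cand, sim in report.candidates:
            members = dict(cand.members)
            row = [
                str(cand.index),
                f"{cand.mean_rmsd:.3f}",
                str(sim.b_total) if sim else "",
                str(sim.b_similar) if sim else "",
                f"{round_report(sim.sf):.2f}" if sim else "",
            ]
            for lig in ligands:
                if pose_set is not None:
                    score = pose_set.get(lig, members[lig]).docking_score
                elif cand is report.chosen:
                    score = report.member_scores.get(lig)
                else:
                    score = None
                row.append("" if score is None else f"{score:.1f}")
            row += [str(members[lig]) for lig in ligands]
            fh.write("\t".join(row) + "\n")

    summary = out_dir / f"{stem}.txt"
    lines = [
        f"chosen constellation: index {report.chosen.index}",
        f"mean scaffold RMSD: {report.chosen.mean_rmsd:.3f} A",
    ]
    if report.similarity:
        lines.append(
            f"interactions: {report.similarity.b_similar} similar of "
            f"{report.similarity.b_total} total, "
            f"Sf = {round_report(report.similarity.sf):.2f}"
        )
    for lig, mi in report.chosen.members:
        score = report.member_scores.get(lig)
        score_txt = "n/a" if score is None else f"{score:.1f} kcal/mol"
        lines.append(f"  {lig}: model {mi}, docking score {score_txt}")
    lines.extend(f"warning: {w}" for w in report.warnings)
    summary.write_text("\n".join(lines) + "\n")
    return tsv, summary
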