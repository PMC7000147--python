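"""Tissue-specificity scoring of splice junctions.

For each tissue T a binary table records, per junction, every pairwise
comparison T versus another tissue: 1 if dPSI (oriented psi_T - psi_other)
meets the differential threshold, 0 otherwise.  Summing a tissue's table
rows gives that tissue's score — the number of comparisons in which the
junction was more included in T.  With five tissues the maximum score is 4.
A junction is labelled with the tissue holding a strict maximum score;
ties at the maximum, or all-zero scores, give NA (not specific).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import JunctionKey
from .splice_quant import DpsiRecord, PsiEstimate, delta_psi

logger = logging.getLogger("splicescope")

NA_LABEL = "NA"


@dataclass
class TissueScore:
    """Per-junction pairwise-comparison wins per tissue plus the label."""

    key: JunctionKey
    scores: dict[str, int] = field(default_factory=dict)
    n_scorable: dict[str, int] = field(default_factory=dict)
    label: str = NA_LABEL


def pairwise_dpsi(
    psi_by_tissue: Mapping[str, Mapping[JunctionKey, PsiEstimate]],
) -> list[DpsiRecord]:
    """All oriented pairwise dPSI records, tissue A minus tissue B.

    Every ordered pair of distinct tissues contributes a record per
    junction quantifiable in both; junctions unquantifiable on either side
    produce no record (missing, not zero).
    """
    records: list[DpsiRecord] = []
    tissues = list(psi_by_tissue)
    for a in tissues:
        for b in tissues:
            if a == b:
                continue
            for key, est_a in psi_by_tissue[a].items():
                est_b = psi_by_tissue[b].get(key)
                if est_b is not None:
                    records.append(delta_psi(est_a, est_b))
    return records


def build_tissue_tables(
    records: Iterable[DpsiRecord], threshold: float = 0.2
) -> dict[str, dict[JunctionKey, dict[str, int]]]:
    """Per-tissue binary inclusion tables.

    ``tables[T][junction][other] = 1`` iff the record oriented psi_T -
    psi_other meets the threshold (inclusive), else 0.  A comparison with
    no record stays absent rather than scoring 0, so NA-by-missing-data is
    distinguishable from NA-by-tie downstream.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    tables: dict[str, dict[JunctionKey, dict[str, int]]] = defaultdict(
        lambda: defaultdict(dict))
    for rec in records:
        tables[rec.condition_a][rec.key][rec.condition_b] = int(
            rec.dpsi >= threshold)
    return {t: dict(v) for t, v in tables.items()}


def score_junctions(
    tables: Mapping[str, Mapping[JunctionKey, Mapping[str, int]]],
) -> dict[JunctionKey, TissueScore]:
    """Sum each tissue's table entries into an overall tissue score."""
    tissues = sorted(tables)
    scores: dict[JunctionKey, TissueScore] = {}
    for tissue in tissues:
        for key, entries in tables[tissue].items():
            ts = scores.setdefault(key, TissueScore(key))
            ts.scores[tissue] = sum(entries.values())
            ts.n_scorable[tissue] = len(entries)
    for ts in scores.values():
        for tissue in tissues:
            ts.scores.setdefault(tissue, 0)
            ts.n_scorable.setdefault(tissue, 0)
        ts.label = assign_specificity(ts)
    return scores


def assign_specificity(score: TissueScore) -> str:
    """Tissue label for a junction, or NA.

    The highest-scoring tissue wins only with a strict maximum; two or more
    tied top scores, an all-zero score vector, or no scorable comparison at
    all give NA.
    """
    if not score.scores or sum(score.n_scorable.values()) == 0:
        if sum(score.n_scorable.values()) == 0:
            logger.debug("junction %s has no scorable comparison", score.key)
        return NA_LABEL
    best = max(score.scores.values())
    if best == 0:
        return NA_LABEL
    winners = [t for t, s in score.scores.items() if s == best]
    return winners[0] if len(winners) == 1 else NA_LABEL


def tally_by_tissue(
    scores: Mapping[JunctionKey, TissueScore],
    ne_junctions: Iterable[JunctionKey] = (),
    tissues: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Counts of tissue-specific junctions per tissue, split NE / non-NE.

    Rows are tissues plus NA; columns ``ne``, ``non_ne`` and ``total``.
    The column totals sum to the number of scored junctions.
    """
    ne_set = set(ne_junctions)
    if tissues is None:
        tissues = sorted({t for ts in scores.values() for t in ts.scores})
    rows = {t: {"ne": 0, "non_ne": 0} for t in list(tissues) + [NA_LABEL]}
    for key, ts in scores.items():
        group = "ne" if key in ne_set else "non_ne"
        rows.setdefault(ts.label, {"ne": 0, "non_ne": 0})[group] += 1
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "tissue"
    df["total"] = df["ne"] + df["non_ne"]
    return df


def scores_to_frame(scores: Mapping[JunctionKey, TissueScore]) -> pd.DataFrame:
    """Score table: one row per junction, one column per tissue, plus label."""
    tissues = sorted({t for ts in scores.values() for t in ts.scores})
    rows = []
    for key, ts in scores.items():
        row = {"junction": f"{key[0]}:{key[1]}-{key[2]}({key[3]})"}
        row.update({t: ts.scores.get(t, 0) for t in tissues})
        row["label"] = ts.label
        rows.append(row)
    return pd.DataFrame(rows, columns=["junction", *tissues, "label"])
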