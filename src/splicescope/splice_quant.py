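"""Junction filtering and empirical PSI / dPSI estimation.

PSI (percent spliced in) is estimated empirically at the junction level:
the read support of a target junction divided by the summed support of the
target plus every junction competing for one of its splice sites.
Replicates are pooled by summing counts before the ratio is taken.  This is
a deliberate stand-in for Bayesian posterior E(PSI) machinery — junction
(rather than isoform) quantification sidesteps the known difficulty of
reconstructing full transcripts from short reads.

For a cassette exon screened manually, PSI is computed from the novel exon
inclusion junction (NEIJ) and canonical exclusion junction (CEJ) counts as
``NEIJ / (2*CEJ + NEIJ)``; the factor 2 balances the two inclusion
junctions flanking a cassette exon against the single skipping junction.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import JunctionKey, SpliceJunction, keys_match


class UnquantifiableError(ValueError):
    """No reads support the event, so PSI carries no signal."""


@dataclass(frozen=True)
class PsiEstimate:
    """Empirical PSI of one junction in one condition.

    ``supporting_reads`` is the denominator: pooled reads over the target
    and all junctions sharing one of its splice sites.
    """

    key: JunctionKey
    condition: str
    psi: float
    supporting_reads: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.psi <= 1.0:
            raise ValueError(f"psi {self.psi} outside [0, 1]")


@dataclass(frozen=True)
class DpsiRecord:
    """Signed PSI difference, oriented ``psi_A - psi_B``."""

    key: JunctionKey
    condition_a: str
    condition_b: str
    dpsi: float

    def __post_init__(self) -> None:
        if abs(self.dpsi) > 1.0 + 1e-12:
            raise ValueError(f"|dpsi| {self.dpsi} exceeds 1")


# ---------------------------------------------------------------------------
# filtering, union, intersection
# ---------------------------------------------------------------------------

def filter_junctions(
    junctions: Sequence[SpliceJunction],
    min_reads: int = 6,
    min_intron: int = 60,
) -> list[SpliceJunction]:
    """Drop weakly supported and implausibly short junctions.

    A junction is retained iff ``unique_reads >= min_reads`` (removing
    junctions supported by fewer than 6 reads by default) and the intron is
    at least ``min_intron`` nucleotides (very few genuine introns are
    shorter than 60 nt).  Input order is preserved.
    """
    if min_reads < 0 or min_intron < 0:
        raise ValueError("thresholds must be non-negative")
    return [
        j for j in junctions
        if j.unique_reads >= min_reads and j.intron_length >= min_intron
    ]


def union_junctions(
    tables: Sequence[Sequence[SpliceJunction]],
) -> dict[JunctionKey, SpliceJunction]:
    """Union of junction tables keyed by (chrom, start, end, strand).

    Read support is aggregated by summing, the annotated flag by OR, and
    the maximum overhang by max — the union of all junctions detected
    across replicates.
    """
    if not tables:
        raise ValueError("need at least one table")
    merged: dict[JunctionKey, SpliceJunction] = {}
    for table in tables:
        for j in table:
            cur = merged.get(j.key)
            if cur is None:
                merged[j.key] = SpliceJunction(
                    j.chrom, j.intron_start, j.intron_end, j.strand,
                    j.unique_reads, j.multi_reads, j.max_overhang, j.annotated)
            else:
                cur.unique_reads += j.unique_reads
                cur.multi_reads += j.multi_reads
                cur.max_overhang = max(cur.max_overhang, j.max_overhang)
                cur.annotated = cur.annotated or j.annotated
    return merged


def intersect_novel(
    set_a: Iterable[JunctionKey],
    set_b: Iterable[JunctionKey],
    annotation: Iterable[JunctionKey],
) -> set[JunctionKey]:
    """Novel junctions seen in both datasets (high-confidence set).

    Matching is strand-blind whenever either side's strand is '.': one
    dataset may be unstranded, and requiring strand agreement there would
    discard every cross-dataset match.  Returned keys are those of
    ``set_a``.
    """
    def coord_index(keys: Iterable[JunctionKey]) -> dict:
        idx: dict[tuple[str, int, int], set[str]] = defaultdict(set)
        for k in keys:
            idx[k[:3]].add(k[3])
        return idx

    b_idx = coord_index(set_b)
    ann_idx = coord_index(annotation)

    def present(key: JunctionKey, idx: dict) -> bool:
        strands = idx.get(key[:3])
        if not strands:
            return False
        return key[3] in strands or key[3] == "." or "." in strands

    return {
        k for k in set_a
        if present(k, b_idx) and not present(k, ann_idx)
    }


# ---------------------------------------------------------------------------
# PSI
# ---------------------------------------------------------------------------

def compute_novel_exon_psi(neij: int, cej: int) -> float:
    """Cassette-exon PSI from inclusion (NEIJ) and exclusion (CEJ) reads.

    ``psi = NEIJ / (2*CEJ + NEIJ)``.  Raises :class:`UnquantifiableError`
    when both counts are zero — absence of signal is not PSI 0.
    """
    if neij < 0 or cej < 0:
        raise ValueError("read counts must be non-negative")
    if neij == 0 and cej == 0:
        raise UnquantifiableError("no reads support inclusion or exclusion")
    return neij / (2 * cej + neij)


def pool_replicates(
    tables: Sequence[Sequence[SpliceJunction]], method: str = "sum"
) -> dict[JunctionKey, float]:
    """Pool replicate junction tables into one count per junction.

    ``sum`` (default) adds counts across replicates; ``mean`` averages,
    treating a junction absent from a replicate as zero reads there.
    """
    if method not in {"sum", "mean"}:
        raise ValueError("method must be 'sum' or 'mean'")
    totals: dict[JunctionKey, float] = defaultdict(float)
    for table in tables:
        for j in table:
            totals[j.key] += j.unique_reads
    if method == "mean":
        n = len(tables)
        totals = {k: v / n for k, v in totals.items()}
    return dict(totals)


def find_competitors(
    target: JunctionKey, keys: Iterable[JunctionKey]
) -> list[JunctionKey]:
    """Junctions competing with ``target`` for either of its splice sites.

    A competitor shares the target's chromosome and its intron start or
    intron end, with '.' matching either strand.
    """
    out = []
    for k in keys:
        if k == target or k[0] != target[0]:
            continue
        if k[3] != target[3] and "." not in (k[3], target[3]):
            continue
        if k[1] == target[1] or k[2] == target[2]:
            out.append(k)
    return out


def compute_junction_psi(
    target: JunctionKey,
    counts: Mapping[JunctionKey, float],
    condition: str = "",
) -> PsiEstimate | None:
    """Empirical PSI of ``target`` against its splice-site competitors.

    ``counts`` maps junction keys to pooled read counts for one condition.
    Returns ``None`` when target and competitors carry no reads at all
    (the junction is not quantifiable in this condition).
    """
    competitors = find_competitors(target, counts.keys())
    total = counts.get(target, 0.0) + sum(counts[c] for c in competitors)
    if total <= 0:
        return None
    return PsiEstimate(target, condition, counts.get(target, 0.0) / total,
                       int(round(total)))


def quantify_conditions(
    tables_by_condition: Mapping[str, Sequence[Sequence[SpliceJunction]]],
    targets: Iterable[JunctionKey] | None = None,
    pool: str = "sum",
) -> dict[str, dict[JunctionKey, PsiEstimate]]:
    """PSI per junction per condition, pooling replicates first.

    ``tables_by_condition`` maps a condition (tissue) name to its replicate
    junction tables.  When ``targets`` is given only those junctions are
    quantified; otherwise every junction seen in the condition is.
    """
    out: dict[str, dict[JunctionKey, PsiEstimate]] = {}
    for condition, tables in tables_by_condition.items():
        counts = pool_replicates(tables, method=pool)
        keys = list(targets) if targets is not None else list(counts)
        estimates: dict[JunctionKey, PsiEstimate] = {}
        for key in keys:
            est = compute_junction_psi(key, counts, condition)
            if est is not None:
                estimates[key] = est
        out[condition] = estimates
    return out


def delta_psi(psi_a: PsiEstimate, psi_b: PsiEstimate) -> DpsiRecord:
    """Signed difference ``psi_A - psi_B`` for one junction."""
    if psi_a.key != psi_b.key:
        raise ValueError("dPSI requires the same junction on both sides")
    return DpsiRecord(psi_a.key, psi_a.condition, psi_b.condition,
                      psi_a.psi - psi_b.psi)


def call_differential(dpsi: float | DpsiRecord, threshold: float = 0.2) -> bool:
    """Differential-splicing call: inclusion higher in A by >= threshold.

    The threshold is inclusive — a change of exactly 0.2 is called.
    """
    value = dpsi.dpsi if isinstance(dpsi, DpsiRecord) else dpsi
    return value >= threshold
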