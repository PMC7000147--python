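"""Post-processing of MS protein-identification tables.

Identification filtering (>= 2 peptides and/or >= 13 spectral counts, read
as an inclusive OR), target-decoy FDR at the protein and spectral levels,
distributed normalized spectral abundance factors (dNSAF), and the report
of identified peptides that span a splice junction.

dNSAF follows the standard distributed definition: spectra of peptides
shared between proteins are apportioned in proportion to each sharer's
unique spectral counts, the distributed count is length-normalized, and
the factors are rescaled to sum to 1.  Subset proteins are deliberately
not removed by parsimony — a junction peptide is interesting precisely
when its protein is otherwise a subset of an annotated one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .junction_peptides import DECOY_PREFIX, DatabaseEntry


@dataclass
class ProteinIdentification:
    """One identified protein with its peptide and spectral evidence."""

    accession: str
    length: int
    peptides: set[str] = field(default_factory=set)
    spectral_count: int = 0
    unique_spectral_count: int = 0
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if self.spectral_count < self.unique_spectral_count or \
                self.unique_spectral_count < 0:
            raise ValueError(
                "require spectral_count >= unique_spectral_count >= 0")
        if self.accession.startswith(DECOY_PREFIX) != self.is_decoy:
            raise ValueError(
                f"decoy flag inconsistent with accession {self.accession!r}")


@dataclass
class FdrReport:
    """Target-decoy FDR at the protein and spectral levels (percent)."""

    protein_fdr: float
    spectral_fdr: float
    n_target_proteins: int
    n_decoy_proteins: int
    n_target_spectra: int
    n_decoy_spectra: int


def filter_identifications(
    ids: Sequence[ProteinIdentification],
    min_peptides: int = 2,
    min_spectra: int = 13,
) -> list[ProteinIdentification]:
    """Keep proteins with >= 2 peptides and/or >= 13 spectral counts.

    "and/or" is an inclusive OR: one criterion suffices (a single-peptide
    protein with 13 spectra is kept).
    """
    return [
        p for p in ids
        if len(p.peptides) >= min_peptides or p.spectral_count >= min_spectra
    ]


def estimate_fdr(
    ids: Sequence[ProteinIdentification],
    denominator: str = "targets",
) -> FdrReport:
    """Target-decoy FDR of a retained identification set.

    ``protein_fdr = 100 * decoy_proteins / target_proteins`` and likewise
    for spectra (DTASelect-style, targets-only denominator); pass
    ``denominator='all'`` to divide by targets + decoys instead.
    """
    if denominator not in {"targets", "all"}:
        raise ValueError("denominator must be 'targets' or 'all'")
    tp = sum(1 for p in ids if not p.is_decoy)
    dp = sum(1 for p in ids if p.is_decoy)
    ts = sum(p.spectral_count for p in ids if not p.is_decoy)
    ds = sum(p.spectral_count for p in ids if p.is_decoy)
    if tp == 0 or ts == 0:
        raise ValueError("no target identifications; FDR undefined")
    pden = tp + dp if denominator == "all" else tp
    sden = ts + ds if denominator == "all" else ts
    return FdrReport(100.0 * dp / pden, 100.0 * ds / sden, tp, dp, ts, ds)


def compute_dnsaf(
    ids: Sequence[ProteinIdentification],
    peptide_spectra: Mapping[str, int] | None = None,
) -> dict[str, float]:
    """Distributed normalized spectral abundance factor per protein.

    Unique spectra count fully toward their protein.  When
    ``peptide_spectra`` maps peptide sequence -> spectral count, spectra of
    peptides claimed by several proteins are distributed in proportion to
    the sharers' unique spectral counts (equally if none has unique
    evidence).  Without a peptide map, each protein's own
    ``spectral_count`` is taken as already distributed.  The factors sum
    to 1.
    """
    if not ids:
        raise ValueError("no identifications")
    for p in ids:
        if p.length <= 0:
            raise ValueError(f"protein {p.accession} has non-positive length")

    dist: dict[str, float] = {p.accession: float(p.unique_spectral_count)
                              for p in ids}
    if peptide_spectra is None:
        dist = {p.accession: float(p.spectral_count) for p in ids}
    else:
        claims: dict[str, list[ProteinIdentification]] = {}
        for p in ids:
            for pep in p.peptides:
                claims.setdefault(pep, []).append(p)
        for pep, count in peptide_spectra.items():
            owners = claims.get(pep, [])
            if len(owners) <= 1:
                if owners:
                    # unique peptide: already inside unique_spectral_count
                    continue
                continue
            total_unique = sum(o.unique_spectral_count for o in owners)
            for o in owners:
                share = (o.unique_spectral_count / total_unique
                         if total_unique > 0 else 1.0 / len(owners))
                dist[o.accession] += count * share

    dsaf = {p.accession: dist[p.accession] / p.length for p in ids}
    total = sum(dsaf.values())
    if total == 0:
        raise ValueError("all distributed spectral counts are zero")
    return {acc: v / total for acc, v in dsaf.items()}


def shared_spectra_distribution(
    ids: Sequence[ProteinIdentification],
    shared_count: int,
) -> dict[str, float]:
    """Distribute one shared peptide's spectra across its owner proteins,
    in proportion to each owner's unique spectral counts."""
    total_unique = sum(p.unique_spectral_count for p in ids)
    if total_unique == 0:
        return {p.accession: shared_count / len(ids) for p in ids}
    return {p.accession: shared_count * p.unique_spectral_count / total_unique
            for p in ids}


# ---------------------------------------------------------------------------
# junction-spanning peptide report
# ---------------------------------------------------------------------------

def _parse_junction_accession(accession: str) -> dict[str, str] | None:
    if not accession.startswith("jnc|"):
        return None
    parts = accession.split("|")
    meta = {"location": parts[1]}
    for p in parts[2:]:
        if "=" in p:
            k, v = p.split("=", 1)
            meta[k] = v
    return meta


def find_junction_peptides(
    peptides: Iterable[str],
    entries: Sequence[DatabaseEntry],
) -> pd.DataFrame:
    """Map identified peptides onto junction database entries.

    A peptide supports a junction iff it occurs in a junction entry's
    sequence overlapping the splice boundary with at least one residue on
    each side.  Peptides matching several junction entries are flagged
    ambiguous; peptides matching none are listed as unmatched.
    """
    junction_entries = []
    for e in entries:
        meta = _parse_junction_accession(e.accession)
        if meta is None or e.category != "junction":
            continue
        off = meta.get("off", "NA")
        if off == "NA":
            continue
        junction_entries.append((e, meta["location"],
                                 meta.get("kind", ""), int(off)))

    rows = []
    for pep in peptides:
        hits = []
        for entry, loc, kind, off in junction_entries:
            start = entry.sequence.find(pep)
            while start != -1:
                if start < off < start + len(pep):
                    hits.append((entry.accession, loc, kind))
                    break
                start = entry.sequence.find(pep, start + 1)
        if not hits:
            rows.append((pep, "", "", "", False, False))
        else:
            for acc, loc, kind in hits:
                rows.append((pep, acc, loc, kind, True, len(hits) > 1))
    return pd.DataFrame(
        rows,
        columns=["peptide", "accession", "junction", "kind",
                 "matched", "ambiguous"],
    )


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_identifications(path: str | Path) -> list[ProteinIdentification]:
    """Read an identification TSV with columns accession, length, peptides
    (semicolon-separated), spectral_count, unique_spectral_count."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        peps = set(str(row.peptides).split(";")) if str(row.peptides) else set()
        peps.discard("")
        out.append(ProteinIdentification(
            accession=str(row.accession),
            length=int(row.length),
            peptides=peps,
            spectral_count=int(row.spectral_count),
            unique_spectral_count=int(row.unique_spectral_count),
            is_decoy=str(row.accession).startswith(DECOY_PREFIX),
        ))
    return out


def write_identifications(
    ids: Sequence[ProteinIdentification], path: str | Path
) -> None:
    pd.DataFrame(
        [(p.accession, p.length, ";".join(sorted(p.peptides)),
          p.spectral_count, p.unique_spectral_count) for p in ids],
        columns=["accession", "length", "peptides", "spectral_count",
                 "unique_spectral_count"],
    ).to_csv(path, sep="\t", index=False)
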