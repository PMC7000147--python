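"""Construction of the junction-peptide proteogenomics search database.

Each retained splice junction is extended 66 nt into its flanking exonic
sequence on both sides; the 132-nt window is translated in three frames in
the direction of the host gene (six frames over both strands when no gene
orientation is known).  A frame is discarded if a stop codon falls at or
before the codon containing the splice boundary; stops after the boundary
truncate the peptide.  Surviving peptides (~44 aa for a full window) must
still genuinely span the junction: the boundary has to sit no more than 22
residues from the start and at least 22 residues from the end.  Novel-exon
and intron-retention sequences are translated the same way and kept when at
least 7 aa long.  Targets (reference proteome + contaminants + junction and
novel-region peptides) are de-duplicated and paired one-to-one with shuffled
decoys of identical length and residue composition for FDR estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .io_formats import JunctionKey, SequenceRecord, SpliceJunction

logger = logging.getLogger("splicescope")

DEFAULT_FLANK = 66
MAX_START_DISTANCE = 22  # junction must start within this many aa ...
MIN_END_DISTANCE = 22    # ... and have at least this many aa after it

CATEGORIES = ("reference", "contaminant", "junction", "novel-region", "decoy")
DECOY_PREFIX = "decoy_"


@dataclass
class JunctionWindow:
    """Genomic sequence around a junction, in transcription order.

    ``upstream_flank`` is the exonic sequence 5' of the intron and
    ``downstream_flank`` the exonic sequence 3' of it, both already oriented
    with the gene; ``window`` is their concatenation and
    ``junction_offset_nt = len(upstream_flank)`` marks the splice boundary.
    ``clipped`` is set when a chromosome end shortened either flank.
    """

    key: JunctionKey
    upstream_flank: str
    downstream_flank: str
    strand: str
    clipped: bool = False

    @property
    def window(self) -> str:
        return self.upstream_flank + self.downstream_flank

    @property
    def junction_offset_nt(self) -> int:
        return len(self.upstream_flank)


@dataclass
class JunctionPeptide:
    """One translated junction-window frame.

    ``junction_offset_aa`` counts residues before the splice boundary; it is
    ``None`` for novel-region peptides, which have no internal junction.
    """

    sequence: str
    frame: int
    source: JunctionKey | str
    kind: str = "novel-junction"
    junction_offset_aa: int | None = None

    def __post_init__(self) -> None:
        if "*" in self.sequence:
            raise ValueError("peptide contains an internal stop character")


@dataclass
class DatabaseEntry:
    """One searchable sequence of the target-decoy database."""

    accession: str
    sequence: str
    category: str
    paired_target: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def genome_dict(records: Iterable[SequenceRecord]) -> dict[str, str]:
    """Chromosome name -> sequence mapping from FASTA records."""
    return {r.id: r.residues for r in records}


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def extract_window(
    junction: SpliceJunction | JunctionKey,
    genome: Mapping[str, str],
    gene_strand: str,
    flank: int = DEFAULT_FLANK,
) -> JunctionWindow:
    """Extend a junction ``flank`` nt into both flanking exonic sequences.

    Flanks are raw genomic sequence adjacent to the intron — novel
    junctions have no reliable exon annotation to walk.  On '-' strand
    genes the window is reverse-complemented so it reads in transcription
    order; flanks truncated by a chromosome end set ``clipped``.
    """
    key = junction.key if isinstance(junction, SpliceJunction) else junction
    chrom, istart, iend, _ = key
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} absent from genome")
    seq = genome[chrom]
    left = seq[max(0, istart - 1 - flank): istart - 1]
    right = seq[iend: iend + flank]
    clipped = len(left) < flank or len(right) < flank
    if gene_strand == "-":
        up, down = _revcomp(right), _revcomp(left)
    else:
        up, down = left, right
    return JunctionWindow(key, up, down, gene_strand, clipped)


def windows_for_junction(
    junction: SpliceJunction | JunctionKey,
    genome: Mapping[str, str],
    gene_strand: str | None = None,
    flank: int = DEFAULT_FLANK,
) -> list[JunctionWindow]:
    """Windows to translate for one junction.

    With a known gene orientation there is a single window; for unstranded
    junctions with no overlapping gene ('.') both strand readings are
    returned, giving six translation frames overall.
    """
    key = junction.key if isinstance(junction, SpliceJunction) else junction
    strand = gene_strand if gene_strand is not None else key[3]
    if strand in {"+", "-"}:
        return [extract_window(junction, genome, strand, flank)]
    return [
        extract_window(junction, genome, "+", flank),
        extract_window(junction, genome, "-", flank),
    ]


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------

def _translate(nt: str) -> str:
    """Standard-code translation of whole codons; N-containing codons -> X."""
    nt = nt[: len(nt) - len(nt) % 3]
    if not nt:
        return ""
    return str(Seq(nt).translate())


def translate_window(
    window: JunctionWindow, kind: str = "novel-junction"
) -> list[JunctionPeptide]:
    """Three-frame translation of a junction window.

    Frame *f* translates ``window[f:]``.  A frame is dropped when any stop
    codon lies at or before the codon containing the splice boundary;
    the first stop after the boundary truncates the peptide (truncated
    peptides must still pass the junction-position check downstream).
    ``junction_offset_aa = (junction_offset_nt - f) // 3``.
    """
    seq = window.window
    if len(seq) < 3:
        logger.warning("window for %s shorter than one codon", window.key)
        return []
    out: list[JunctionPeptide] = []
    j_nt = window.junction_offset_nt
    for frame in range(3):
        aa = _translate(seq[frame:])
        if not aa:
            continue
        boundary_codon = (j_nt - frame - 1) // 3
        stop = aa.find("*")
        if stop != -1 and stop <= boundary_codon:
            continue
        peptide = aa if stop == -1 else aa[:stop]
        if not peptide:
            continue
        out.append(JunctionPeptide(
            sequence=peptide,
            frame=frame,
            source=window.key,
            kind=kind,
            junction_offset_aa=max((j_nt - frame) // 3, 0),
        ))
    return out


def translate_novel_region(
    sequence: str,
    strand: str = "+",
    min_len: int = 7,
    source: str = "",
    kind: str = "novel-exon",
) -> list[JunctionPeptide]:
    """Three-frame translation of a novel exon or retained intron.

    Each frame is truncated at its first stop codon; translations shorter
    than ``min_len`` residues (default 7) are discarded.
    """
    nt = _revcomp(sequence) if strand == "-" else sequence
    out: list[JunctionPeptide] = []
    for frame in range(3):
        aa = _translate(nt[frame:])
        stop = aa.find("*")
        peptide = aa if stop == -1 else aa[:stop]
        if len(peptide) >= min_len:
            out.append(JunctionPeptide(peptide, frame, source or sequence[:12],
                                       kind=kind, junction_offset_aa=None))
    return out


def validate_junction_peptide(
    peptide: JunctionPeptide,
    window: JunctionWindow | None = None,
) -> bool:
    """Check that a peptide genuinely crosses its splice boundary.

    Pass iff the junction starts at most 22 residues from the peptide start
    (and not at position 0 — that would leave nothing upstream) and at
    least 22 residues remain after it.
    """
    off = peptide.junction_offset_aa
    if off is None or off < 1:
        return False
    if off > MAX_START_DISTANCE:
        return False
    return len(peptide.sequence) - off >= MIN_END_DISTANCE


def peptide_accession(peptide: JunctionPeptide) -> str:
    """Stable FASTA accession for a junction/novel-region peptide."""
    if isinstance(peptide.source, tuple):
        chrom, s, e, strand = peptide.source
        loc = f"{chrom}:{s}-{e}({strand})"
    else:
        loc = str(peptide.source)
    off = "NA" if peptide.junction_offset_aa is None else peptide.junction_offset_aa
    return f"jnc|{loc}|frame={peptide.frame}|off={off}|kind={peptide.kind}"


def build_junction_entries(
    junctions: Iterable[SpliceJunction],
    genome: Mapping[str, str],
    strand_of: Mapping[JunctionKey, str] | None = None,
    flank: int = DEFAULT_FLANK,
) -> list[DatabaseEntry]:
    """Window extraction, translation and junction-position validation.

    ``strand_of`` optionally maps junction keys to a host-gene strand,
    overriding the junction's own strand call.  Every returned entry has
    passed :func:`validate_junction_peptide`.
    """
    entries: list[DatabaseEntry] = []
    for j in junctions:
        strand = (strand_of or {}).get(j.key, j.strand)
        kind = "annotated-junction" if j.annotated else "novel-junction"
        for window in windows_for_junction(j, genome, strand, flank):
            for pep in translate_window(window, kind=kind):
                if validate_junction_peptide(pep, window):
                    entries.append(DatabaseEntry(
                        peptide_accession(pep), pep.sequence, "junction"))
                else:
                    logger.debug("peptide for %s frame %d fails the "
                                 "junction-position check", j.key, pep.frame)
    return entries


# ---------------------------------------------------------------------------
# database assembly
# ---------------------------------------------------------------------------

def dedupe_entries(entries: Sequence[DatabaseEntry]) -> list[DatabaseEntry]:
    """Collapse exact sequence duplicates, keeping the first-seen entry."""
    seen: set[str] = set()
    out: list[DatabaseEntry] = []
    for e in entries:
        if e.sequence not in seen:
            seen.add(e.sequence)
            out.append(e)
    return out


def make_decoys(
    entries: Sequence[DatabaseEntry], seed: int | np.random.Generator = 0
) -> list[DatabaseEntry]:
    """One shuffled decoy per target, same length and residue composition."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    decoys = []
    for e in entries:
        shuffled = "".join(rng.permutation(list(e.sequence)))
        decoys.append(DatabaseEntry(DECOY_PREFIX + e.accession, shuffled,
                                    "decoy", paired_target=e.accession))
    return decoys


def assemble_database(
    reference: Sequence[DatabaseEntry],
    contaminants: Sequence[DatabaseEntry] = (),
    junction_entries: Sequence[DatabaseEntry] = (),
    novel_region_entries: Sequence[DatabaseEntry] = (),
    seed: int = 0,
) -> tuple[list[DatabaseEntry], dict[str, int]]:
    """Final target+decoy database and a per-category summary.

    Targets are de-duplicated across all categories before decoy
    generation, so the decoy count equals the final target count and the
    database holds exactly twice as many sequences as targets.
    """
    targets = dedupe_entries([*reference, *contaminants, *junction_entries,
                              *novel_region_entries])
    if not targets:
        raise ValueError("empty target set")
    decoys = make_decoys(targets, seed)
    summary = {cat: 0 for cat in CATEGORIES}
    for e in targets:
        summary[e.category] += 1
    summary["decoy"] = len(decoys)
    summary["targets"] = len(targets)
    summary["total"] = len(targets) + len(decoys)
    return [*targets, *decoys], summary


def entries_from_records(
    records: Iterable[SequenceRecord], category: str
) -> list[DatabaseEntry]:
    """Wrap FASTA records (reference proteome, contaminants) as entries."""
    return [DatabaseEntry(r.id, r.residues, category) for r in records]


def entries_from_peptides(
    peptides: Iterable[JunctionPeptide], category: str = "novel-region"
) -> list[DatabaseEntry]:
    return [DatabaseEntry(peptide_accession(p), p.sequence, category)
            for p in peptides]


def database_to_records(entries: Iterable[DatabaseEntry]) -> list[SequenceRecord]:
    return [SequenceRecord(e.accession, e.sequence) for e in entries]


def manifest_frame(entries: Sequence[DatabaseEntry]):
    """TSV-ready manifest: accession, category, length, paired target."""
    import pandas as pd

    return pd.DataFrame(
        [(e.accession, e.category, len(e.sequence), e.paired_target or "")
         for e in entries],
        columns=["accession", "category", "length", "paired_target"],
    )
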