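"""Readers and writers for the formats the pipeline touches.

All genomic coordinates held in memory are 1-based inclusive, matching both
the STAR ``SJ.out.tab`` layout and GTF.  A splice junction is represented by
its intron: ``intron_start`` is the first intronic base and ``intron_end``
the last.  The only place a different convention appears is the BED6 export,
which converts to 0-based half-open explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("splicescope")

STRAND_CODES = {"0": ".", "1": "+", "2": "-"}
STRAND_TO_CODE = {v: k for k, v in STRAND_CODES.items()}

#: junction identity key: (chrom, intron_start, intron_end, strand)
JunctionKey = tuple[str, int, int, str]


class ParseError(ValueError):
    """A malformed record in an input file; the message names the line."""


@dataclass
class SpliceJunction:
    """One intron call from a splice-aware aligner.

    ``intron_start``/``intron_end`` are the 1-based first and last intronic
    bases.  ``unique_reads`` is the uniquely-mapping read support used for
    all filtering; ``annotated`` marks presence in the supplied annotation.
    """

    chrom: str
    intron_start: int
    intron_end: int
    strand: str
    unique_reads: int = 0
    multi_reads: int = 0
    max_overhang: int = 0
    annotated: bool = False

    def __post_init__(self) -> None:
        if self.intron_start > self.intron_end:
            raise ValueError(
                f"intron_start {self.intron_start} > intron_end {self.intron_end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")
        if min(self.unique_reads, self.multi_reads, self.max_overhang) < 0:
            raise ValueError("read counts and overhang must be non-negative")

    @property
    def key(self) -> JunctionKey:
        return (self.chrom, self.intron_start, self.intron_end, self.strand)

    @property
    def intron_length(self) -> int:
        return self.intron_end - self.intron_start + 1


@dataclass
class GeneModel:
    """A gene: one exon list per transcript, 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    is_ne: bool = False

    def max_exon_count(self) -> int:
        """Exon count of the transcript with the most exons (0 if none)."""
        if not self.transcripts:
            return 0
        return max(len(exons) for exons in self.transcripts.values())

    def junctions(self) -> list[tuple[int, int]]:
        """Intron (start, end) pairs implied by consecutive exons."""
        out: set[tuple[int, int]] = set()
        for exons in self.transcripts.values():
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                out.add((e1 + 1, s2 - 1))
        return sorted(out)


@dataclass
class SequenceRecord:
    """A named nucleotide or amino-acid sequence."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for record {self.id!r}")


def keys_match(a: JunctionKey, b: JunctionKey, strand_blind_dot: bool = True) -> bool:
    """Whether two junction keys denote the same junction.

    When either strand is '.' (unstranded data) the strands are not compared,
    so an unstranded call can match a stranded one at the same coordinates.
    """
    if a[:3] != b[:3]:
        return False
    if a[3] == b[3]:
        return True
    return strand_blind_dot and "." in (a[3], b[3])


def canonical_key(key: JunctionKey) -> tuple[str, int, int]:
    """Coordinate-only key used for strand-blind set operations."""
    return key[:3]


# ---------------------------------------------------------------------------
# STAR SJ.out.tab
# ---------------------------------------------------------------------------

def read_star_sj(path: str | Path) -> list[SpliceJunction]:
    """Read a STAR ``SJ.out.tab`` junction table.

    Columns: chrom, intron start (1-based), intron end (1-based), strand
    code (0 undefined / 1 '+' / 2 '-'), intron motif, annotated (0/1),
    unique reads, multi-mapping reads, maximum spliced overhang.
    """
    junctions: list[SpliceJunction] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(
                    f"{path}:{lineno}: expected >=9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                strand = STRAND_CODES[fields[3]]
                annotated = fields[5] == "1"
                uniq, multi, overhang = (int(f) for f in fields[6:9])
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed row ({exc})") from exc
            if min(uniq, multi, overhang) < 0:
                raise ParseError(f"{path}:{lineno}: negative count")
            junctions.append(
                SpliceJunction(chrom, start, end, strand, uniq, multi,
                               overhang, annotated)
            )
    return junctions


def write_star_sj(junctions: Iterable[SpliceJunction], path: str | Path) -> None:
    """Write junctions in the 9-column SJ.out.tab layout (motif written 0)."""
    with open(path, "w") as fh:
        for j in junctions:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        j.chrom, j.intron_start, j.intron_end,
                        STRAND_TO_CODE[j.strand], 0, int(j.annotated),
                        j.unique_reads, j.multi_reads, j.max_overhang,
                    )
                )
                + "\n"
            )


def junctions_to_bed(junctions: Iterable[SpliceJunction], path: str | Path) -> None:
    """Export junction introns as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for j in junctions:
            name = f"{j.chrom}:{j.intron_start}-{j.intron_end}({j.strand})"
            fh.write(
                f"{j.chrom}\t{j.intron_start - 1}\t{j.intron_end}\t"
                f"{name}\t{j.unique_reads}\t{j.strand}\n"
            )


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path: str | Path, ne_genes: set[str] | None = None) -> list[GeneModel]:
    """Read gene models from a GTF file, grouping exons by transcript.

    Only ``exon`` features are consulted; gene/transcript parent features are
    neither required nor inferred.  ``ne_genes`` flags the nuclear-envelope
    subset on the returned models.
    """
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    ne_genes = ne_genes or set()
    models: dict[str, GeneModel] = {}
    n_exons = 0
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        n_exons += 1
        gene_id = feat.attributes.get("gene_id", [None])[0]
        tx_id = feat.attributes.get("transcript_id", [None])[0]
        if gene_id is None or tx_id is None:
            raise ParseError(
                f"{path}: exon at {feat.seqid}:{feat.start}-{feat.end} lacks "
                "gene_id/transcript_id"
            )
        model = models.setdefault(
            gene_id,
            GeneModel(gene_id, feat.seqid, feat.strand, is_ne=gene_id in ne_genes),
        )
        model.transcripts.setdefault(tx_id, []).append((feat.start, feat.end))
    # genes present only as non-exon features still yield (empty) models
    for feat in db.all_features():
        gene_id = feat.attributes.get("gene_id", [None])[0]
        if gene_id is not None and gene_id not in models:
            logger.warning("gene %s has no exon features", gene_id)
            models[gene_id] = GeneModel(
                gene_id, feat.seqid, feat.strand, is_ne=gene_id in ne_genes
            )
    if n_exons == 0:
        logger.warning("%s contains no exon features", path)
    for model in models.values():
        for exons in model.transcripts.values():
            exons.sort()
    return list(models.values())


def write_gtf(models: Iterable[GeneModel], path: str | Path,
              source: str = "splicescope") -> None:
    """Write gene models as exon-only GTF."""
    with open(path, "w") as fh:
        for m in models:
            for tx_id, exons in m.transcripts.items():
                for start, end in exons:
                    attrs = f'gene_id "{m.gene_id}"; transcript_id "{tx_id}";'
                    fh.write(
                        f"{m.chrom}\t{source}\texon\t{start}\t{end}\t.\t"
                        f"{m.strand}\t.\t{attrs}\n"
                    )


def read_gene_list(path: str | Path) -> set[str]:
    """Read a plain-text gene list, one id per line; '#' lines are comments."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA; duplicate ids are an error (they break decoy pairing)."""
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seen[rec.id] = seen.get(rec.id, 0) + 1
        records.append(SequenceRecord(rec.id, str(rec.seq), rec.description))
    dups = sorted(k for k, n in seen.items() if n > 1)
    if dups:
        raise ParseError(f"{path}: duplicate FASTA ids: {', '.join(dups)}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.residues), id=r.id,
                  description=r.description if r.description != r.id else "")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")
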