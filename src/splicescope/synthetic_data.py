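"""Synthetic inputs with known ground truth.

Every downstream stage of the pipeline is exercised against data generated
here: multi-exon gene models with a flagged nuclear-envelope (NE) subset,
per-tissue junction tables with planted tissue-specific cassette events,
bimodal expressed/unexpressed count matrices, and per-residue disorder
tracks.  Generators are pure functions of (config, seed): the same
:class:`SimConfig` always yields byte-identical output.

The default design mirrors a five-tissue body-map experiment (brain, heart,
liver, muscle, testes) observed by two independent junction datasets
("dsA", "dsB") so that cross-dataset intersection logic is exercisable.
Junction read counts are negative binomial (Gamma-Poisson): for a planted
cassette event in tissue *t*, inclusion reads have mean ``depth * psi_t``
and the competing exclusion-junction reads mean ``depth * (1 - psi_t)``,
with ``psi_t = psi_high`` in the labelled tissue and ``psi_low`` elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GeneModel, JunctionKey, SequenceRecord, SpliceJunction

DEFAULT_TISSUES = ("brain", "heart", "liver", "muscle", "testes")
DATASETS = ("dsA", "dsB")


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    ``dispersion`` is the NB overdispersion (variance = m + dispersion*m^2);
    the default 0.01 reflects the modest extra-Poisson variability of
    junction counts across replicates of the same tissue.  ``psi_high`` /
    ``psi_low`` set the inclusion level of planted junctions in their
    labelled tissue versus everywhere else.
    """

    n_tissues: int = 5
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    n_replicates: int = 3
    n_genes: int = 60
    fraction_ne: float = 0.2
    n_planted_specific: int = 4
    psi_high: float = 0.8
    psi_low: float = 0.05
    mean_depth: float = 100.0
    dispersion: float = 0.01
    n_noise_junctions: int = 30
    exon_count_mean: float = 8.0
    ne_exon_boost: float = 4.0
    exon_len_range: tuple[int, int] = (90, 300)
    intron_len_range: tuple[int, int] = (200, 600)
    # count-matrix mixture
    n_samples: int = 4
    expressed_fraction: float = 0.7
    unexpressed_mean: float = 0.1
    expressed_log2_mean: float = 6.0
    expressed_log2_sd: float = 1.5
    # disorder tracks
    disordered_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.psi_low < self.psi_high <= 1.0:
            raise ValueError("require 0 <= psi_low < psi_high <= 1")
        if len(self.tissues) != self.n_tissues:
            if self.tissues == DEFAULT_TISSUES:
                self.tissues = tuple(f"tissue{i + 1}" for i in range(self.n_tissues))
            else:
                raise ValueError("len(tissues) must equal n_tissues")
        for name in ("n_tissues", "n_replicates", "n_genes", "n_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if self.dispersion < 0 or self.mean_depth <= 0:
            raise ValueError("mean_depth > 0 and dispersion >= 0 required")


@dataclass
class SimTruth:
    """Planted ground truth for recovery tests."""

    junction_tissue: dict[JunctionKey, str] = field(default_factory=dict)
    expressed_genes: set[str] = field(default_factory=set)
    disordered_proteins: set[str] = field(default_factory=set)
    decoy_accessions: set[str] = field(default_factory=set)


def _nb_sample(rng: np.random.Generator, mean: float, dispersion: float,
               size: int | None = None):
    """Negative binomial with mean ``mean`` and var ``mean + disp*mean^2``."""
    if mean <= 0:
        return np.zeros(size or 1, dtype=int) if size else 0
    if dispersion <= 0:
        return rng.poisson(mean, size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size)


# ---------------------------------------------------------------------------
# gene models and genome
# ---------------------------------------------------------------------------

def simulate_gene_models(
    config: SimConfig,
) -> tuple[list[SequenceRecord], list[GeneModel], set[str]]:
    """Generate a random genome, multi-exon gene models and an NE gene list.

    Exon counts per gene are ``2 + Poisson(exon_count_mean - 2)``; NE genes
    receive an extra ``ne_exon_boost`` on the Poisson mean, so that the
    NE-versus-rest exon-count comparison has a planted signal (boost 0 gives
    the null).  Genes with >= 3 exons may carry a second, exon-skipping
    transcript.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n_ne = int(round(config.fraction_ne * config.n_genes))
    ne_idx = set(rng.choice(config.n_genes, size=n_ne, replace=False).tolist())

    models: list[GeneModel] = []
    chrom = "chr1"
    pos = 1000
    for gi in range(config.n_genes):
        gene_id = f"gene{gi + 1:04d}"
        is_ne = gi in ne_idx
        mean = config.exon_count_mean + (config.ne_exon_boost if is_ne else 0.0)
        n_exons = 2 + int(rng.poisson(max(mean - 2.0, 0.0)))
        exons: list[tuple[int, int]] = []
        cur = pos
        for _ in range(n_exons):
            elen = int(rng.integers(*config.exon_len_range))
            exons.append((cur, cur + elen - 1))
            ilen = int(rng.integers(*config.intron_len_range))
            cur = cur + elen + ilen
        strand = "+" if rng.random() < 0.5 else "-"
        model = GeneModel(gene_id, chrom, strand, is_ne=is_ne)
        model.transcripts[f"{gene_id}.t1"] = exons
        if n_exons >= 3 and rng.random() < 0.5:
            skip = int(rng.integers(1, n_exons - 1))
            model.transcripts[f"{gene_id}.t2"] = (
                exons[:skip] + exons[skip + 1:]
            )
        models.append(model)
        pos = cur + int(rng.integers(500, 2000))

    genome_len = pos + 5000
    seq = "".join(rng.choice(list("ACGT"), size=genome_len))
    genome = [SequenceRecord(chrom, seq, "synthetic chromosome")]
    ne_genes = {m.gene_id for m in models if m.is_ne}
    return genome, models, ne_genes


# ---------------------------------------------------------------------------
# junction tables
# ---------------------------------------------------------------------------

def simulate_junction_tables(
    models: list[GeneModel], config: SimConfig
) -> tuple[dict[tuple[str, str, int], list[SpliceJunction]], SimTruth]:
    """Per-(dataset, tissue, replicate) SJ tables with planted events.

    Each planted event converts one annotated intron into a cassette: a
    novel inclusion junction shares the annotated junction's donor site and
    lands inside the intron.  The inclusion junction is written into every
    replicate of both datasets; per-table noise junctions carry fewer than 6
    reads so they are removed by the read-support filter.
    """
    rng = np.random.default_rng(config.seed + 1)
    truth = SimTruth()

    # choose host genes for planted events, one tissue label per junction
    eligible = [m for m in models
                if len(m.transcripts[f"{m.gene_id}.t1"]) >= 2]
    needed = config.n_planted_specific * config.n_tissues
    if len(eligible) < needed:
        raise ValueError(
            f"need {needed} multi-exon genes for planted events, "
            f"have {len(eligible)}"
        )
    hosts = rng.choice(len(eligible), size=needed, replace=False)
    planted: list[tuple[SpliceJunction, SpliceJunction, str]] = []
    for k, hi in enumerate(hosts):
        model = eligible[int(hi)]
        tissue = config.tissues[k % config.n_tissues]
        exons = model.transcripts[f"{model.gene_id}.t1"]
        ji = int(rng.integers(0, len(exons) - 1))
        istart, iend = exons[ji][1] + 1, exons[ji + 1][0] - 1
        # novel acceptor inside the intron; keep the novel intron >= 60 nt
        novel_end = istart + 60 + int(rng.integers(0, max(iend - istart - 90, 1)))
        excl = SpliceJunction(model.chrom, istart, iend, model.strand,
                              annotated=True)
        incl = SpliceJunction(model.chrom, istart, novel_end, model.strand,
                              annotated=False)
        planted.append((incl, excl, tissue))
        truth.junction_tissue[incl.key] = tissue

    # constitutive junctions (constant inclusion across tissues)
    event_keys = {j.key for incl, excl, _ in planted for j in (incl, excl)}
    constitutive: list[SpliceJunction] = []
    for m in models:
        for istart, iend in m.junctions():
            j = SpliceJunction(m.chrom, istart, iend, m.strand, annotated=True)
            if j.key not in event_keys:
                constitutive.append(j)

    chrom_span = max(
        e for m in models for ex in m.transcripts.values() for _, e in ex
    ) + 4000
    tables: dict[tuple[str, str, int], list[SpliceJunction]] = {}
    for dataset in DATASETS:
        for tissue in config.tissues:
            for rep in range(config.n_replicates):
                rows: list[SpliceJunction] = []
                for j in constitutive:
                    reads = int(_nb_sample(rng, config.mean_depth,
                                           config.dispersion))
                    rows.append(SpliceJunction(
                        j.chrom, j.intron_start, j.intron_end, j.strand,
                        unique_reads=reads, max_overhang=50, annotated=True))
                for incl, excl, label in planted:
                    psi = config.psi_high if tissue == label else config.psi_low
                    inc_reads = int(_nb_sample(
                        rng, config.mean_depth * psi, config.dispersion))
                    exc_reads = int(_nb_sample(
                        rng, config.mean_depth * (1.0 - psi), config.dispersion))
                    rows.append(SpliceJunction(
                        incl.chrom, incl.intron_start, incl.intron_end,
                        incl.strand, unique_reads=inc_reads, max_overhang=50))
                    rows.append(SpliceJunction(
                        excl.chrom, excl.intron_start, excl.intron_end,
                        excl.strand, unique_reads=exc_reads, max_overhang=50,
                        annotated=True))
                for _ in range(config.n_noise_junctions):
                    s = int(rng.integers(1, chrom_span - 200))
                    e = s + 60 + int(rng.integers(0, 500))
                    rows.append(SpliceJunction(
                        "chr1", s, e, rng.choice(["+", "-", "."]),
                        unique_reads=int(rng.integers(1, 6)), max_overhang=20))
                rows.sort(key=lambda j: (j.chrom, j.intron_start, j.intron_end))
                tables[(dataset, tissue, rep)] = rows
    return tables, truth


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def simulate_counts(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.Series, set[str]]:
    """Gene-level count matrix from a two-component expressed mixture.

    Unexpressed genes draw Poisson counts with mean ``unexpressed_mean``
    (mostly zeros); expressed genes draw Poisson counts around a log-normal
    gene mean.  The log-scale gap between the two components gives the
    retained-genes-versus-cutoff calibration curve its knee.  Returns the
    counts (genes x samples), gene lengths in nt, and the expressed truth.
    """
    rng = np.random.default_rng(config.seed + 2)
    genes = [f"gene{gi + 1:04d}" for gi in range(config.n_genes)]
    samples = [f"sample{si + 1}" for si in range(config.n_samples)]
    expressed = rng.random(config.n_genes) < config.expressed_fraction
    if not expressed.any():
        expressed[int(rng.integers(config.n_genes))] = True
    means = np.where(
        expressed,
        2.0 ** rng.normal(config.expressed_log2_mean,
                          config.expressed_log2_sd, config.n_genes),
        config.unexpressed_mean,
    )
    counts = rng.poisson(means[:, None], size=(config.n_genes, config.n_samples))
    lengths = pd.Series(rng.integers(500, 3000, config.n_genes),
                        index=genes, name="length")
    df = pd.DataFrame(counts, index=genes, columns=samples)
    truth = {g for g, e in zip(genes, expressed) if e}
    return df, lengths, truth


# ---------------------------------------------------------------------------
# disorder tracks
# ---------------------------------------------------------------------------

def simulate_disorder_tracks(
    proteins: list[tuple[str, int]], config: SimConfig
) -> tuple[dict[str, np.ndarray], set[str]]:
    """Per-residue disorder scores in [0, 1] with planted disordered proteins.

    ``proteins`` is a list of (id, length) pairs.  A planted disordered
    protein carries one contiguous stretch of >= 20 residues scoring above
    0.5; all other residues (and all residues of ordered proteins) score
    below 0.5, so both the total-count and consecutive-stretch readings of
    the disorder call agree with the truth flags.
    """
    rng = np.random.default_rng(config.seed + 3)
    tracks: dict[str, np.ndarray] = {}
    flagged: set[str] = set()
    for pid, length in proteins:
        scores = rng.uniform(0.0, 0.45, size=length)
        if length >= 20 and rng.random() < config.disordered_fraction:
            run = int(rng.integers(20, min(41, length + 1)))
            start = int(rng.integers(0, length - run + 1))
            scores[start:start + run] = rng.uniform(0.55, 0.95, size=run)
            flagged.add(pid)
        tracks[pid] = scores
    return tracks, flagged


def disorder_tracks_to_frame(tracks: dict[str, np.ndarray]) -> pd.DataFrame:
    """Long-format (protein, position, score) table for TSV export."""
    rows = [
        (pid, i + 1, float(s))
        for pid, scores in tracks.items()
        for i, s in enumerate(scores)
    ]
    return pd.DataFrame(rows, columns=["protein", "position", "score"])
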