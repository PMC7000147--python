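"""Expression thresholds and nuclear-envelope enrichment statistics.

Covers TPM computation, the calibration-curve expression cutoff, expressed
gene-set unions, the NE-versus-rest splicing enrichment comparison
(two-sample Kolmogorov-Smirnov over per-comparison proportions), the
max-exon-count comparison, and intrinsic-disorder calls with their Fisher
exact test.

The calibration cutoff exploits the bimodality of transformed expression
values: sweeping a cutoff across the value range, the retained-gene count
drops sharply while crossing the unexpressed mode and then plateaus; the
cutoff is placed at the upper edge of the single grid step with the largest
drop.  The transform is a plug-in (default: log2 of median-of-ratios
size-factor-normalized counts + 1); the cutoff procedure, not the
transform, is the interesting part.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneModel

logger = logging.getLogger("splicescope")


@dataclass
class EnrichmentResult:
    """Outcome of an NE-enrichment comparison."""

    statistic: float
    p_value: float
    proportions_a: tuple[float, ...] = ()
    proportions_b: tuple[float, ...] = ()
    odds_ratio: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    table: tuple[tuple[int, int], tuple[int, int]] | None = None


# ---------------------------------------------------------------------------
# TPM and expression cutoffs
# ---------------------------------------------------------------------------

def count_to_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: ``1e6 * (N_i/L_i) / sum_j (N_j/L_j)``.

    ``counts`` is genes x samples; ``lengths`` gives each gene's length in
    nucleotides.  Every column of the result sums to 1e6.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"genes without length: {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (counts < 0).to_numpy().any():
        raise ValueError("counts must be non-negative")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    zero = denom[denom == 0]
    if len(zero):
        raise ValueError(f"sample(s) with all-zero counts: {list(zero.index)}")
    return 1e6 * rate.div(denom, axis=1)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (genes with any zero are skipped)."""
    log_counts = np.log(counts.where(counts > 0))
    log_means = log_counts.mean(axis=1)
    usable = log_means.notna()
    if not usable.any():
        return pd.Series(1.0, index=counts.columns)
    ratios = log_counts.loc[usable].sub(log_means[usable], axis=0)
    return np.exp(ratios.median(axis=0)).fillna(1.0)


def default_transform(counts: pd.DataFrame) -> pd.Series:
    """Per-gene expression value: log2(mean size-factor-normalized count + 1)."""
    norm = counts.div(size_factors(counts), axis=1)
    return np.log2(norm.mean(axis=1) + 1.0)


def calibration_cutoff(
    values: Sequence[float] | pd.Series,
    grid_size: int = 200,
    gap_fraction: float = 0.05,
) -> float:
    """Expression cutoff from the retained-genes-versus-cutoff curve.

    Retained(c) = number of genes with value >= c is evaluated on a
    ``grid_size``-step grid between the minimum and maximum value.  With
    bimodal data this curve falls steeply while c crosses the unexpressed
    mode and then plateaus until the expressed mode begins.  The cutoff is
    the upper edge of the last falling step of the region containing the
    maximum single-step drop: falling steps separated by short flat runs
    (up to ``gap_fraction`` of the grid) belong to the same region, and the
    first longer plateau ends it.  Because the rule only looks at the drop
    region around the unexpressed mode, it is insensitive to extra genes
    far above the cutoff.  A degenerate (constant) value vector yields that
    value with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no expression values")
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        logger.warning("degenerate calibration curve: all values equal %g", lo)
        return lo
    grid = np.linspace(lo, hi, grid_size + 1)
    retained = (v[None, :] >= grid[:, None]).sum(axis=1)
    drops = retained[:-1] - retained[1:]
    start = int(np.argmax(drops))
    max_gap = max(1, int(round(gap_fraction * grid_size)))
    last_fall = start
    flat_run = 0
    for k in range(start + 1, len(drops)):
        if drops[k] > 0:
            last_fall = k
            flat_run = 0
        else:
            flat_run += 1
            if flat_run >= max_gap:
                break
    return float(grid[last_fall + 1])


def calibration_curve(
    values: Sequence[float] | pd.Series, grid_size: int = 200
) -> pd.DataFrame:
    """Retained-gene count at each candidate cutoff (for inspection/plots)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no expression values")
    grid = np.linspace(v.min(), v.max(), grid_size + 1)
    retained = (v[None, :] >= grid[:, None]).sum(axis=1)
    return pd.DataFrame({"cutoff": grid, "retained": retained})


def expressed_genes(
    counts: pd.DataFrame,
    transform: Callable[[pd.DataFrame], pd.Series] = default_transform,
    cutoff: float | None = None,
    tpm_min: float | None = None,
    lengths: pd.Series | None = None,
) -> set[str]:
    """Genes called expressed, by calibration cutoff or a TPM floor.

    Default path: apply ``transform`` and the calibration cutoff.  With
    ``tpm_min`` (e.g. 1.0) and gene lengths, a gene is instead expressed
    when its mean TPM reaches the floor.
    """
    if tpm_min is not None:
        if lengths is None:
            raise ValueError("tpm_min requires gene lengths")
        tpm = count_to_tpm(counts, lengths)
        return set(tpm.index[tpm.mean(axis=1) >= tpm_min])
    values = transform(counts)
    if cutoff is None:
        cutoff = calibration_cutoff(values)
    return set(values.index[values >= cutoff])


def expressed_union(set_a: Iterable[str], set_b: Iterable[str]) -> set[str]:
    """Union of the genes expressed in either of two conditions."""
    return set(set_a) | set(set_b)


# ---------------------------------------------------------------------------
# splicing enrichment (KS over per-comparison proportions)
# ---------------------------------------------------------------------------

def ne_proportion(genes: Iterable[str], ne_genes: set[str]) -> float:
    genes = set(genes)
    if not genes:
        raise ValueError("empty gene set")
    return len(genes & ne_genes) / len(genes)


def splicing_enrichment(
    comparisons: Sequence[tuple[Iterable[str], Iterable[str]]],
    ne_genes: set[str],
) -> EnrichmentResult:
    """NE over-representation among differentially spliced genes.

    ``comparisons`` holds, per condition pair, the expressed gene union and
    the spliced gene set (genes with at least one junction at dPSI >= 0.2
    in that comparison).  The NE fraction of each collection is computed
    per comparison and the two proportion collections are compared with a
    two-sample Kolmogorov-Smirnov test.
    """
    if len(comparisons) < 2:
        raise ValueError("KS test needs at least 2 comparisons")
    p_expr = [ne_proportion(expr, ne_genes) for expr, _ in comparisons]
    p_spl = [ne_proportion(spl, ne_genes) for _, spl in comparisons]
    stat, p = stats.ks_2samp(p_expr, p_spl)
    return EnrichmentResult(
        statistic=float(stat), p_value=float(p),
        proportions_a=tuple(p_expr), proportions_b=tuple(p_spl),
    )


def max_exons_per_gene(
    models: Sequence[GeneModel],
    expressed: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per expressed gene, the exon count of its exon-richest transcript.

    Restricting to expressed genes avoids skew from the mass of
    low-exon-count genes that are simply silent.  Genes without any
    transcript are excluded (logged).
    """
    expressed_set = set(expressed) if expressed is not None else None
    rows = []
    for m in models:
        if expressed_set is not None and m.gene_id not in expressed_set:
            continue
        if not m.transcripts:
            logger.warning("gene %s has no transcripts; excluded", m.gene_id)
            continue
        rows.append((m.gene_id, m.max_exon_count(), m.is_ne))
    return pd.DataFrame(rows, columns=["gene_id", "max_exons", "is_ne"])


def compare_exon_counts(exon_table: pd.DataFrame) -> EnrichmentResult:
    """NE versus non-NE max-exon-count distributions (two-sample KS)."""
    ne = exon_table.loc[exon_table.is_ne, "max_exons"]
    rest = exon_table.loc[~exon_table.is_ne, "max_exons"]
    if ne.empty or rest.empty:
        raise ValueError("need both NE and non-NE genes")
    stat, p = stats.ks_2samp(ne, rest)
    return EnrichmentResult(statistic=float(stat), p_value=float(p),
                            proportions_a=(float(ne.median()),),
                            proportions_b=(float(rest.median()),))


# ---------------------------------------------------------------------------
# intrinsic disorder
# ---------------------------------------------------------------------------

def disorder_call(
    scores: Sequence[float] | np.ndarray,
    threshold: float = 0.5,
    min_residues: int = 20,
    consecutive: bool = False,
) -> bool:
    """Whether a protein counts as intrinsically disordered.

    Default: at least ``min_residues`` residues anywhere score above
    ``threshold``.  With ``consecutive=True`` the residues must form one
    contiguous stretch — a stricter reading appropriate when disorder is
    expected as discrete disordered regions.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty disorder track")
    above = s > threshold
    if not consecutive:
        return int(above.sum()) >= min_residues
    best = run = 0
    for flag in above:
        run = run + 1 if flag else 0
        best = max(best, run)
    return best >= min_residues


def odds_ratio_ci(
    table: Sequence[Sequence[int]], alpha: float = 0.05
) -> tuple[float, float, float]:
    """Sample odds ratio with a Woolf (log) confidence interval.

    A 0.5 Haldane correction is applied to every cell for the interval
    whenever any cell is zero.
    """
    (a, b), (c, d) = table
    orr = np.inf if b * c == 0 and a * d > 0 else (
        np.nan if b * c == 0 else (a * d) / (b * c))
    aa, bb, cc, dd = (
        (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if 0 in (a, b, c, d)
        else (a, b, c, d)
    )
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = stats.norm.ppf(1 - alpha / 2)
    log_or = np.log((aa * dd) / (bb * cc))
    return float(orr), float(np.exp(log_or - z * se)), \
        float(np.exp(log_or + z * se))


def disorder_enrichment(
    calls: Mapping[str, bool],
    ne_genes: set[str],
) -> EnrichmentResult:
    """Fisher exact test of disorder against NE membership.

    Builds the 2x2 table (NE / non-NE) x (disordered / not), tests the
    two-sided alternative that the odds ratio differs from 1, and reports
    the sample odds ratio with its 95% Woolf interval.
    """
    if not calls:
        raise ValueError("no disorder calls")
    a = sum(1 for g, dis in calls.items() if g in ne_genes and dis)
    b = sum(1 for g, dis in calls.items() if g in ne_genes and not dis)
    c = sum(1 for g, dis in calls.items() if g not in ne_genes and dis)
    d = sum(1 for g, dis in calls.items() if g not in ne_genes and not dis)
    table = ((a, b), (c, d))
    _, p = stats.fisher_exact(table, alternative="two-sided")
    orr, lo, hi = odds_ratio_ci(table)
    n_ne, n_rest = a + b, c + d
    return EnrichmentResult(
        statistic=float(orr) if np.isfinite(orr) else np.nan,
        p_value=float(p),
        proportions_a=(a / n_ne,) if n_ne else (),
        proportions_b=(c / n_rest,) if n_rest else (),
        odds_ratio=orr, ci_low=lo, ci_high=hi, table=table,
    )
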