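"""Independent oracles and simulation helpers used by the test suite."""

from math import comb


def fisher_exact_bruteforce(table):
    """Two-sided Fisher exact p-value by full hypergeometric enumeration.

    Fixes the margins of the 2x2 table, enumerates every admissible
    upper-left cell value, computes each table's hypergeometric probability
    from binomial coefficients, and sums the probabilities no larger than
    the observed one (with a tiny relative slack on the tie comparison).
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    denom = comb(n, c1)

    def pmf(k):
        return comb(r1, k) * comb(r2, c1 - k) / denom

    p_obs = pmf(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(p for k in range(lo, hi + 1)
               if (p := pmf(k)) <= p_obs * (1 + 1e-7))


def canonical_table(a, b, c, d):
    """Representative of a 2x2 table's orbit under row swap, column swap
    and transposition — operations that leave the two-sided Fisher exact
    p-value unchanged."""
    return min(
        (a, b, c, d), (b, a, d, c), (c, d, a, b), (d, c, b, a),
        (a, c, b, d), (c, a, d, b), (b, d, a, c), (d, b, c, a),
    )


def enumerate_ne_proportion_sets(rng, n_comparisons, set_size, p_expr, p_spl):
    """Gene sets for a splicing-enrichment simulation.

    Builds, per comparison, an expressed gene set and a spliced gene set of
    equal size whose members are NE with probabilities ``p_expr`` and
    ``p_spl``; returns (comparisons, ne_genes) in the form
    ``splicing_enrichment`` accepts.  Equal sizes keep the two proportion
    collections identically distributed under the null (p_expr == p_spl).
    """
    comparisons = []
    ne_genes = set()
    uid = 0
    for _ in range(n_comparisons):
        sets = []
        for p in (p_expr, p_spl):
            ids = range(uid, uid + set_size)
            uid += set_size
            flags = rng.random(set_size) < p
            ne_genes.update(g for g, f in zip(ids, flags) if f)
            sets.append(set(ids))
        comparisons.append((sets[0], sets[1]))
    return comparisons, ne_genes
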