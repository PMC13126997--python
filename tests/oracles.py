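"""Independent brute-force oracles, kept deliberately naive and separate
from the implementation paths they check."""

import numpy as np


def bh_stepup(p):
    """Literal Benjamini-Hochberg step-up: sort, scale by m/rank, running min
    from the largest rank down, clip at 1, map back to input order."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def median_of_ratios(counts):
    """Size factors recomputed gene by gene with explicit loops."""
    counts = np.asarray(counts, dtype=float)
    n_genes, n_samples = counts.shape
    geomeans = []
    for gi in range(n_genes):
        row = counts[gi]
        if (row > 0).all():
            geomeans.append((gi, np.exp(np.mean(np.log(row)))))
    factors = []
    for si in range(n_samples):
        ratios = [counts[gi, si] / gm for gi, gm in geomeans]
        factors.append(np.median(ratios))
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


def lr_pairs_by_two_memberships(pair_rows, deg_genes):
    """Pair list filtered by two independent DEG-membership lookups.

    ``pair_rows`` is an iterable of (pair_id, ligand, receptor);
    ``deg_genes`` the set of genes passing thresholds in the contrast.
    """
    kept = []
    for pid, lig, rec in pair_rows:
        if lig in deg_genes and rec in deg_genes:
            kept.append(pid)
    return sorted(kept)


def pooled_t(a, b):
    """Closed-form pooled-variance two-sample t statistic."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
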