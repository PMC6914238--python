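"""Independent brute-force oracles used by the test suite."""

import numpy as np


def pearson_oracle(x, y):
    """Textbook Pearson correlation, written out longhand."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    mx, my = x.sum() / n, y.sum() / n
    num = ((x - mx) * (y - my)).sum()
    den = np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den


def average_ranks(values):
    """Average ranks with tie handling, by explicit enumeration."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Brute-force Spearman: average ranks then longhand Pearson."""
    return pearson_oracle(average_ranks(x), average_ranks(y))


def ipf_oracle_2x2(counts, row_targets, col_targets, n_iter=500):
    """Independent iterative proportional fitting on a 2x2 contingency
    table of weighted masses (total mass 1)."""
    m = np.asarray(counts, dtype=float)
    m = m / m.sum()
    r = np.asarray(row_targets, dtype=float)
    c = np.asarray(col_targets, dtype=float)
    for _ in range(n_iter):
        m *= (r / m.sum(axis=1))[:, None]
        m *= c / m.sum(axis=0)
    return m
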