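"""Independent naive reference implementations used as test oracles.

Everything here is written as plain loops over Python floats, deliberately
sharing no code path with the package's vectorised implementations.
"""

import math

import numpy as np


def naive_size_factors(values):
    """Median-of-ratios, gene by gene: values is a genes x samples array."""
    n_genes, n_samples = values.shape
    geomeans = []
    for i in range(n_genes):
        row = values[i]
        if all(v > 0 for v in row):
            geomeans.append(math.exp(sum(math.log(v) for v in row) / n_samples))
        else:
            geomeans.append(0.0)
    factors = []
    for j in range(n_samples):
        ratios = [values[i, j] / geomeans[i] for i in range(n_genes) if geomeans[i] > 0]
        factors.append(float(np.median(ratios)))
    return factors


def naive_average_ranks(vector):
    """Average ranks (1-based) with ties, by explicit grouping."""
    order = sorted(range(len(vector)), key=lambda i: vector[i])
    ranks = [0.0] * len(vector)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and vector[order[j + 1]] == vector[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def naive_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def naive_spearman(x, y):
    return naive_pearson(naive_average_ranks(list(x)), naive_average_ranks(list(y)))


def naive_iqr(vector):
    q1 = float(np.percentile(vector, 25, method="linear"))
    q3 = float(np.percentile(vector, 75, method="linear"))
    return q3 - q1


def naive_top_k_by_iqr(values, gene_ids, k):
    """Stable descending sort on per-gene IQR; ties keep input order."""
    iqrs = [naive_iqr(values[i]) for i in range(len(gene_ids))]
    order = sorted(range(len(gene_ids)), key=lambda i: (-iqrs[i], i))
    return [gene_ids[i] for i in order[:k]]


def naive_expression_filter(values, gene_ids, threshold, min_samples):
    kept = []
    for i, g in enumerate(gene_ids):
        hits = sum(1 for v in values[i] if v > threshold)
        if hits >= min_samples:
            kept.append(g)
    return kept


def naive_group_means(rows, groups):
    """rows: dict name -> list of floats; groups: dict name -> group label."""
    out = {}
    for name, label in groups.items():
        out.setdefault(label, []).append(rows[name])
    return {
        label: [sum(col) / len(col) for col in zip(*members)]
        for label, members in out.items()
    }


def naive_marker_r2(gmfi, tpm, exclude_zeros=True):
    pairs = [
        (math.log10(t), math.log10(g))
        for g, t in zip(gmfi, tpm)
        if not exclude_zeros or (g > 0 and t > 0)
    ]
    xs = [p[0] for p in pairs]
    ys = [p[1] for p in pairs]
    return naive_pearson(xs, ys) ** 2
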