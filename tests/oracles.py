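"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the package's internal code paths: plain Python
loops, explicit pair counting and exhaustive enumeration only.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def brute_correct_barcode(observed, quals, abundances, threshold=0.975):
    """Scan every whitelist member; score exact Hamming-1 hits."""
    if observed in abundances:
        return observed
    scored = []
    for member, abundance in abundances.items():
        if hamming(member, observed) != 1:
            continue
        pos = next(i for i, (x, y) in enumerate(zip(member, observed)) if x != y)
        scored.append((member, abundance * 10.0 ** (-quals[pos] / 10.0)))
    total = sum(w for _, w in scored)
    if not scored or total <= 0:
        return None
    best, weight = max(scored, key=lambda s: s[1])
    return best if weight / total >= threshold else None


def brute_correct_umis(umi_reads: dict[str, int]) -> dict[str, int]:
    """Merge UMIs into strictly-more-prolific Hamming-1 UMIs of one gene.

    Same contract as the implementation (single pass, descending pre-merge
    support, lexicographic ties) but computed with a separate explicit loop.
    """
    original = dict(umi_reads)
    order = sorted(original, key=lambda u: (-original[u], u))
    merged = dict(original)
    gone: set[str] = set()
    for u in order:
        if u in gone:
            continue
        for v in order:
            if v is u or v in gone:
                continue
            if original[v] < original[u] and hamming(u, v) == 1:
                merged[u] += merged.pop(v)
                gone.add(v)
    return merged


def brute_demux(reads, abundances, threshold=0.975):
    """Full pure-python demultiplex: returns {(barcode, gene): umi_count}.

    reads: iterable of (barcode, barcode_quals, umi, umi_quals, gene) with
    quality strings in offset-33 ASCII.
    """
    kept = []
    for bc, bq, umi, uq, gene in reads:
        quals = [ord(c) - 33 for c in bq]
        corrected = brute_correct_barcode(bc, quals, abundances, threshold)
        if corrected is None:
            continue
        uquals = [ord(c) - 33 for c in uq]
        if len(set(umi)) <= 1 or min(uquals) <= 10:
            continue
        kept.append((corrected, umi, gene))
    support = Counter(kept)
    # within-gene UMI merging per barcode
    molecules: dict[tuple[str, str, str], int] = {}
    by_bc_gene: dict[tuple[str, str], dict[str, int]] = {}
    for (bc, umi, gene), n in support.items():
        by_bc_gene.setdefault((bc, gene), {})[umi] = n
    for (bc, gene), umi_reads in by_bc_gene.items():
        for umi, n in brute_correct_umis(umi_reads).items():
            molecules[(bc, umi, gene)] = n
    # multi-gene (barcode, umi) collisions: max support wins, ties dropped
    by_pair: dict[tuple[str, str], list[tuple[str, int]]] = {}
    for (bc, umi, gene), n in molecules.items():
        by_pair.setdefault((bc, umi), []).append((gene, n))
    counts: Counter = Counter()
    for (bc, umi), genes in by_pair.items():
        top = max(n for _, n in genes)
        winners = [g for g, n in genes if n == top]
        if len(winners) == 1:
            counts[(bc, winners[0])] += 1
    return dict(counts)


def brute_call_cells(totals: dict[str, int], expected_cells: int):
    """Explicit nearest-rank percentile cell calling."""
    nonzero = sorted((t for t in totals.values() if t > 0), reverse=True)
    assert nonzero, "no candidate cells"
    top = nonzero[: min(expected_cells, len(nonzero))]
    asc = sorted(top)
    rank = max(1, math.ceil(0.99 * len(asc)))
    robust_max = asc[rank - 1]
    threshold = robust_max / 10.0
    return {b for b, t in totals.items() if t >= threshold}, robust_max, threshold


def median(xs):
    s = sorted(xs)
    n = len(s)
    return s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2.0


def brute_mad_flags(columns: dict[str, list[float]], k: float = 3.0) -> list[bool]:
    """Two-sided raw-MAD outlier flags over any number of metric columns."""
    n = len(next(iter(columns.values())))
    flags = [False] * n
    for xs in columns.values():
        med = median(xs)
        mad = median([abs(x - med) for x in xs])
        for i, x in enumerate(xs):
            if abs(x - med) > k * mad:
                flags[i] = True
    return flags


def brute_hard_flags(pct_mito, pct_ribo, mito_cap=20.0, ribo_cap=50.0):
    return [m > mito_cap or r > ribo_cap for m, r in zip(pct_mito, pct_ribo)]


def brute_gene_keep(detection_counts, n_cells, min_fraction=0.01):
    return [c / n_cells >= min_fraction for c in detection_counts]


def brute_u_statistic(x, y) -> float:
    """U by explicit pair counting: #(x_i < y_j) + 0.5 * #(x_i == y_j)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi < yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def brute_mw_exact_p(x, y, alternative="two_sided") -> float:
    """Exact p by enumerating all C(m+n, m) group assignments."""
    pooled = list(x) + list(y)
    m = len(x)
    u_obs = brute_u_statistic(x, y)
    us = []
    for combo in itertools.combinations(range(len(pooled)), m):
        gx = [pooled[i] for i in combo]
        gy = [pooled[i] for i in range(len(pooled)) if i not in combo]
        us.append(brute_u_statistic(gx, gy))
    eps = 1e-9
    p_ge = sum(u >= u_obs - eps for u in us) / len(us)
    p_le = sum(u <= u_obs + eps for u in us) / len(us)
    if alternative == "less":
        return p_ge
    if alternative == "greater":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


def midranks(xs):
    order = sorted(range(len(xs)), key=lambda i: xs[i])
    ranks = [0.0] * len(xs)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and xs[order[j + 1]] == xs[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def pearson(a, b) -> float:
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    num = sum((ai - ma) * (bi - mb) for ai, bi in zip(a, b))
    den = math.sqrt(sum((ai - ma) ** 2 for ai in a) * sum((bi - mb) ** 2 for bi in b))
    return num / den


def brute_spearman(x, y):
    """(rho, exact two-sided permutation p) via full enumeration."""
    rx, ry = midranks(x), midranks(y)
    rho = pearson(rx, ry)
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(pearson(rx, list(perm))) >= abs(rho) - 1e-9:
            count += 1
    return rho, count / total
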