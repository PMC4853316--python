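"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: explicit loops and
naive enumeration, so they can serve as oracles for the optimized
implementations.
"""

from collections import OrderedDict

from txprofiler.genetics import AA_TO_CODONS, AMINO_ACIDS


def brute_n50(lengths):
    """Try every observed length from the largest down; return the first L
    such that the contigs of length >= L hold at least half the bases."""
    total = sum(lengths)
    for L in sorted(set(lengths), reverse=True):
        if sum(l for l in lengths if l >= L) >= total / 2:
            return L
    raise AssertionError("unreachable for non-empty input")


def brute_rscu(counts):
    """Per-amino-acid loops over the standard code, straight off the formula."""
    out = {}
    for aa in AMINO_ACIDS:
        codons = AA_TO_CODONS[aa]
        total = 0
        for c in codons:
            total += counts[c]
        for c in codons:
            if total == 0:
                out[c] = None
            else:
                mean = total / len(codons)
                out[c] = counts[c] / mean
    return out


def brute_best_hits(hits, cutoff):
    """Scan all (query, hit) pairs; keep max bitscore, ties min evalue,
    then earliest position in the input."""
    queries = []
    for h in hits:
        if h.query_id not in queries:
            queries.append(h.query_id)
    best = OrderedDict()
    for q in queries:
        candidates = [
            (i, h) for i, h in enumerate(hits)
            if h.query_id == q and h.evalue <= cutoff
        ]
        if not candidates:
            continue
        candidates.sort(key=lambda ih: (-ih[1].bitscore, ih[1].evalue, ih[0]))
        best[q] = candidates[0][1]
    return dict(best)


def brute_bins(coverages, bin_width):
    """Assign each value by explicitly testing every bin interval."""
    n_bins = 100 // bin_width
    edges = [(i * bin_width, (i + 1) * bin_width) for i in range(n_bins)]
    counts = [0] * n_bins
    for v in coverages:
        pct = 100.0 * v
        if pct == 0.0:
            counts[0] += 1
            continue
        for i, (lo, hi) in enumerate(edges):
            if lo < pct <= hi:
                counts[i] += 1
                break
    cumulative = []
    for i in range(n_bins):
        cumulative.append(sum(counts[i:]))
    return [(float(lo), float(hi), c, cum)
            for (lo, hi), c, cum in zip(edges, counts, cumulative)]


def brute_exn50(id_length_tpm, x):
    """Enumerate prefixes of the (tpm desc, length desc, id asc) ranking
    until the cumulative TPM reaches x% of the total; N50 of that prefix."""
    rows = sorted(id_length_tpm, key=lambda r: (-r[2], -r[1], r[0]))
    total = sum(r[2] for r in rows)
    running = 0.0
    for k, row in enumerate(rows):
        running += row[2]
        if running >= total * x / 100.0 or k == len(rows) - 1:
            subset = rows[: k + 1]
            return (
                brute_n50([r[1] for r in subset]),
                len(subset),
                subset[-1][2],
            )
    raise AssertionError("unreachable")
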