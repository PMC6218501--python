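"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive — position-by-position scans, explicit
tail sums, union-find, per-target argmax loops — and shares no code with the
package paths it checks.
"""

from __future__ import annotations

from math import comb, log10

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
         "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper()))


def naive_match(seq: str, motif: str, pos: int) -> bool:
    if pos < 0 or pos + len(motif) > len(seq):
        return False
    for i, letter in enumerate(motif.upper()):
        if seq[pos + i] not in IUPAC_SETS[letter]:
            return False
    return True


def naive_scan(seq: str, motif: str, offset: int = 0) -> list[tuple[int, str]]:
    """All (position, strand) occurrences; palindromic spans keep + only.

    ``offset`` is the TSS-relative coordinate of seq[0].  A − strand hit at
    left end i is reported at its own 5'-most base, i + len(motif) − 1.
    """
    motif = motif.upper()
    hits = []
    rcm = rc(motif)
    for i in range(len(seq) - len(motif) + 1):
        fwd = naive_match(seq, motif, i)
        rev = naive_match(seq, rcm, i)
        if fwd:
            hits.append((offset + i, "+"))
        if rev and not fwd:
            hits.append((offset + i + len(motif) - 1, "-"))
    return hits


def hypergeom_tail(k: int, big_n: int, big_k: int, n: int) -> float:
    """P(X >= k) for a hypergeometric draw of n from N with K successes."""
    if k <= 0:
        return 1.0
    total = comb(big_n, n)
    acc = 0
    for x in range(k, min(big_k, n) + 1):
        if big_n - big_k >= n - x:
            acc += comb(big_k, x) * comb(big_n - big_k, n - x)
    return acc / total


def median_of_ratios(counts: list[list[float]]) -> list[float]:
    """Size factors: median over all-positive genes of count / geometric mean."""
    import statistics

    n_samples = len(counts[0])
    refs = []
    for row in counts:
        if all(v > 0 for v in row):
            gm = 1.0
            for v in row:
                gm *= v
            refs.append((row, gm ** (1.0 / n_samples)))
    factors = []
    for j in range(n_samples):
        factors.append(statistics.median(row[j] / ref for row, ref in refs))
    gm = 1.0
    for f in factors:
        gm *= f
    gm **= 1.0 / n_samples
    return [f / gm for f in factors]


def union_find_components(nodes: list[str], edges: list[tuple[str, str]]) -> int:
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    return len({find(n) for n in nodes})


def bfs_depths(nodes: list[str], edges: list[tuple[str, str]], source: str) -> dict[str, int]:
    adj = {n: [] for n in nodes}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    depths = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in depths:
                    depths[v] = depths[u] + 1
                    nxt.append(v)
        frontier = nxt
    return depths


def best_hit_bruteforce(hits):
    """argmax by (length, identity, smallest target) via explicit sort."""
    ordered = sorted(hits, key=lambda h: (-h.aln_length, -h.identity, h.target_id))
    return ordered[0]


def resolve_bruteforce(pairs):
    """Per-target argmax by (stability, length, smallest locus_a)."""
    out = {}
    for p in pairs:
        out.setdefault(p.locus_b, []).append(p)
    kept = []
    for claimants in out.values():
        kept.append(
            sorted(claimants, key=lambda p: (-p.stability, -p.aln_length, p.locus_a))[0]
        )
    return sorted(kept, key=lambda p: p.locus_a)


def classify_oracle(log2fcs, ps, lfc=2.0, p_thr=0.01) -> str:
    """Exhaustive rule: best significant event by |log2fc| decides the class."""
    best = None
    for l, p in zip(log2fcs, ps):
        if p < p_thr and abs(l) > lfc:
            if best is None or abs(l) > abs(best):
                best = l
    if best is None:
        return "unchanged"
    return "up" if best > 0 else "down"
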