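"""Independent brute-force oracles used to validate the library implementations.

Each oracle is deliberately written by direct enumeration of the defining
quantity (haplotype pair counting, exhaustive subinterval enumeration,
per-locus moment formulas), sharing no code with the implementation it checks.
"""

from collections import Counter

import numpy as np

from popscan.rohscan import ROHParams


# ---------------------------------------------------------------------------
# EHHS by O(n^2 m) pair comparison
# ---------------------------------------------------------------------------

def ehhs_brute(haps: np.ndarray, core: int, variant: str) -> np.ndarray:
    """EHHS at every marker by counting identical haplotype pairs directly."""
    n, m = haps.shape
    vals = np.empty(m)
    for t in range(m):
        if t == core:
            vals[t] = 1.0
            continue
        lo, hi = min(core, t), max(core, t)
        classes = Counter(tuple(int(x) for x in h[lo:hi + 1]) for h in haps)
        pairs = sum(c * (c - 1) for c in classes.values())
        if variant == "tang":
            core_classes = Counter(int(h[core]) for h in haps)
            denom = sum(c * (c - 1) for c in core_classes.values())
        elif variant == "sabeti":
            denom = n * (n - 1)
        else:
            raise ValueError(variant)
        vals[t] = pairs / denom if denom else np.nan
    return vals


def ies_brute(bp: np.ndarray, ehhs: np.ndarray, core_pos: int, cutoff: float = 0.05,
              discard_at_border: bool = True) -> float:
    """Truncated trapezoidal iES by explicit summation over each side."""
    total = 0.0
    for direction in (-1, +1):
        idx = core_pos
        prev_v, prev_x = ehhs[idx], float(bp[idx])
        side = 0.0
        hit_cutoff = False
        while True:
            idx += direction
            if idx < 0 or idx >= len(ehhs):
                break
            v, x = ehhs[idx], float(bp[idx])
            side += 0.5 * (v + prev_v) * abs(x - prev_x)
            if v < cutoff:
                hit_cutoff = True
                break
            prev_v, prev_x = v, x
        if discard_at_border and not hit_cutoff:
            return float("nan")
        total += side
    return total


# ---------------------------------------------------------------------------
# ROH by exhaustive subinterval enumeration
# ---------------------------------------------------------------------------

def _roh_ok(pos, het, mis, a, b, p: ROHParams) -> bool:
    n = b - a + 1
    if n < p.min_snps:
        return False
    span = pos[b] - pos[a] + 1
    if span < p.min_length_bp:
        return False
    if span / n > p.max_bp_per_snp:
        return False
    if sum(het[a:b + 1]) > p.max_het:
        return False
    if sum(mis[a:b + 1]) > p.max_missing:
        return False
    for i in range(a, b):
        if pos[i + 1] - pos[i] > p.max_gap_bp:
            return False
    return True


def roh_brute(pos, het, mis, params: ROHParams) -> list[tuple[int, int]]:
    """All maximal qualifying intervals, then the overlap-resolution rule:
    merge overlapping intervals into the union when the union qualifies, else
    keep the longer span (tie: leftmost), scanning left to right."""
    pos = list(pos)
    het = list(het)
    mis = list(mis)
    m = len(pos)
    quals = [(a, b) for a in range(m) for b in range(a, m)
             if _roh_ok(pos, het, mis, a, b, params)]
    maximal = [
        (a, b) for (a, b) in quals
        if not any(c <= a and d >= b and (c, d) != (a, b) for (c, d) in quals)
    ]
    maximal.sort()
    if not maximal:
        return []
    out = []
    cur = maximal[0]
    for nxt in maximal[1:]:
        if nxt[0] <= cur[1]:
            union = (min(cur[0], nxt[0]), max(cur[1], nxt[1]))
            if _roh_ok(pos, het, mis, union[0], union[1], params):
                cur = union
            elif pos[nxt[1]] - pos[nxt[0]] > pos[cur[1]] - pos[cur[0]]:
                cur = nxt
        else:
            out.append(cur)
            cur = nxt
    out.append(cur)
    return out


# ---------------------------------------------------------------------------
# Weir–Cockerham theta by per-locus scalar arithmetic
# ---------------------------------------------------------------------------

def wc_theta_brute(geno: np.ndarray, labels: np.ndarray) -> float:
    """Two-population Weir–Cockerham theta, ratio of summed components,
    computed locus by locus with scalar arithmetic (missing = -1)."""
    num = den = 0.0
    r = 2
    for j in range(geno.shape[1]):
        ns, ps, hs = [], [], []
        skip = False
        for k in (0, 1):
            g = geno[labels == k, j]
            g = g[g >= 0]
            if len(g) < 2:
                skip = True
                break
            ns.append(len(g))
            ps.append(g.sum() / (2 * len(g)))
            hs.append((g == 1).sum() / len(g))
        if skip:
            continue
        nbar = sum(ns) / r
        nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
        pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den if den else float("nan")
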