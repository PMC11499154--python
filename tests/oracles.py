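"""Independent brute-force oracles used by the test suite only."""

from __future__ import annotations

import numpy as np


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def collapse_oracle(counts: dict[str, int]) -> dict[str, int]:
    """Exhaustive Hamming-1 graph collapse of one UMI group.

    Repeatedly enumerates every eligible (child, parent) pair — parent at
    Hamming distance 1 with reads(parent) >= 2*reads(child) - 1, equal-read
    pairs merging only toward the smaller UMI — and applies the merge for
    the globally smallest (reads, umi) child, parent chosen by most reads
    then smallest UMI, until no pair is eligible.
    """
    counts = dict(counts)
    while True:
        pairs = []
        for u, ru in counts.items():
            for v, rv in counts.items():
                if u == v or hamming(u, v) != 1:
                    continue
                if rv >= 2 * ru - 1 and (rv > ru or (rv == ru and v < u)):
                    pairs.append((u, v))
        if not pairs:
            return counts
        child = min({u for u, _ in pairs}, key=lambda u: (counts[u], u))
        parent = min(
            [v for u, v in pairs if u == child], key=lambda v: (-counts[v], v)
        )
        counts[parent] += counts[child]
        del counts[child]


def knee_by_largest_drop(totals: np.ndarray) -> int:
    """1-based rank of the largest adjacent log-log drop in sorted totals."""
    t = np.sort(np.asarray(totals, dtype=float))[::-1]
    drops = np.log10(t[:-1]) - np.log10(t[1:])
    return int(np.argmax(drops)) + 1


def random_umi_group(rng: np.random.Generator, max_umis: int = 6, length: int = 4):
    """Random small UMI group biased toward Hamming-1 neighbours."""
    bases = "ACGT"
    n = int(rng.integers(1, max_umis + 1))
    umis: set[str] = set()
    while len(umis) < n:
        if umis and rng.random() < 0.6:
            # mutate an existing UMI at one position to force H1 structure
            u = sorted(umis)[int(rng.integers(0, len(umis)))]
            p = int(rng.integers(0, length))
            c = bases[int(rng.integers(0, 4))]
            umis.add(u[:p] + c + u[p + 1 :])
        else:
            umis.add("".join(bases[i] for i in rng.integers(0, 4, size=length)))
    return {u: int(rng.integers(1, 21)) for u in sorted(umis)}
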