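"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive — quadratic scans, exhaustive subset
enumeration — and shares no code with the package's own algorithms.
"""

from __future__ import annotations

import itertools
from collections import Counter

from recoil.encoder import GainModel, MemMatch


def brute_force_mems(source: str, dest: str, k: int) -> set[MemMatch]:
    """All maximal exact matches of length >= k by O(n*m) position scanning."""
    out: set[MemMatch] = set()
    for i in range(len(source)):
        for j in range(len(dest)):
            if source[i] != dest[j]:
                continue
            if i > 0 and j > 0 and source[i - 1] == dest[j - 1]:
                continue  # not left-maximal: covered by an earlier start
            length = 0
            while i + length < len(source) and j + length < len(dest) and source[i + length] == dest[j + length]:
                length += 1
            if length >= k:
                out.add(MemMatch(i, j, length))
    return out


def exhaustive_chain_gain(mems: list[MemMatch], model: GainModel) -> int:
    """Best total gain over every subset of MEMs, with left-trimming on overlap.

    Mirrors the chain semantics: members are applied in (dest, source, length)
    order; each is trimmed from the left until it clears its predecessor in
    both strings, and a member trimmed to nothing is skipped.
    """
    order = sorted(mems, key=lambda m: (m.start_in_dest, m.start_in_source, m.length))
    best = 0
    for mask in range(1 << len(order)):
        gain = 0
        prev_send = prev_dend = 0
        for i, mem in enumerate(order):
            if not mask >> i & 1:
                continue
            trim = max(0, prev_dend - mem.start_in_dest, prev_send - mem.start_in_source)
            length = mem.length - trim
            if length < 1:
                continue
            gain += model.gain(length)
            prev_send = mem.start_in_source + mem.length
            prev_dend = mem.start_in_dest + mem.length
        best = max(best, gain)
    return best


def brute_force_anchor_counts(seed_occurrences: dict[int, Counter]) -> Counter:
    """Expected uncapped anchor multiset.

    ``seed_occurrences`` maps read id -> Counter of selected k-mer values
    (with occurrence multiplicity).  With no cap, a value occurring a times in
    one read and b times in another contributes a*b anchors to that pair.
    """
    counts: Counter = Counter()
    for a, b in itertools.combinations(sorted(seed_occurrences), 2):
        total = sum(
            seed_occurrences[a][v] * seed_occurrences[b][v]
            for v in seed_occurrences[a].keys() & seed_occurrences[b].keys()
        )
        if total:
            counts[(a, b)] = total
    return counts


def brute_force_max_spanning_weight(n: int, edges: list[tuple[int, int, int]]) -> int:
    """Maximum spanning-tree weight by enumerating all edge subsets of size n-1."""
    best = None
    for combo in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for u, v, _w in combo:
            ru, rv = find(u), find(v)
            if ru == rv:
                ok = False
                break
            parent[ru] = rv
        if ok:
            weight = sum(w for _u, _v, w in combo)
            best = weight if best is None else max(best, weight)
    if best is None:
        raise ValueError("graph is disconnected")
    return best
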