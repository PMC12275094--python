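"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive pure Python: per-offset Hamming scans
and O(n^2) pairwise clustering, sharing no code with the package paths they
verify.
"""

from chiapet_loops.linker import reverse_complement


def brute_force_linker_scan(read, linker):
    """Exhaustive best-hit scan: every query, every offset, partials included.

    Returns (offset, orientation, mismatches, match_len) or None, under the
    same selection rule as the production scanner: fewest mismatches, then
    smallest offset, then query priority.
    """
    queries = [
        ("forward", linker.forward_seq),
        ("reverse", linker.reverse_seq),
        ("forward_rc", reverse_complement(linker.forward_seq)),
        ("reverse_rc", reverse_complement(linker.reverse_seq)),
    ]
    n = len(read)
    best = None
    for prio, (orientation, query) in enumerate(queries):
        m = len(query)
        for off in range(n - m + 1):
            mm = 0
            for a, b in zip(read[off : off + m], query):
                if a != b:
                    mm += 1
            if mm <= linker.max_mismatches:
                key = (mm, off, prio)
                if best is None or key < best[0]:
                    best = (key, (off, orientation, mm, m))
        for length in range(min(m - 1, n), linker.min_overlap - 1, -1):
            off = n - length
            mm = sum(a != b for a, b in zip(read[off:], query[:length]))
            if mm <= (linker.max_mismatches * length) // m:
                key = (mm, off, prio)
                if best is None or key < best[0]:
                    best = (key, (off, orientation, mm, length))
    return best[1] if best else None


def brute_force_cluster(pets, extension):
    """O(n^2) union-find over all pairwise both-anchor overlap tests.

    Returns the partition as a frozenset of frozensets of input indices.
    """

    def intervals(pet):
        a = pet.tag1.occupied()
        b = pet.tag2.occupied()
        if (a.start, a.end) > (b.start, b.end):
            a, b = b, a
        return (
            (max(0, a.start - extension), a.end + extension),
            (max(0, b.start - extension), b.end + extension),
        )

    ivs = [intervals(p) for p in pets]
    parent = list(range(len(pets)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(len(pets)):
        for j in range(i + 1, len(pets)):
            (l1, l2), (r1, r2) = ivs[i], ivs[j]
            left_overlap = r1[0] < l1[1] and l1[0] < r1[1]
            right_overlap = r2[0] < l2[1] and l2[0] < r2[1]
            if left_overlap and right_overlap:
                parent[find(j)] = find(i)

    groups = {}
    for i in range(len(pets)):
        groups.setdefault(find(i), []).append(i)
    return frozenset(frozenset(g) for g in groups.values())
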