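"""Independent brute-force oracles used to validate the fast implementations.

Everything here enumerates exhaustively and is deliberately naive; none of
it shares code with the library paths it checks.
"""

from __future__ import annotations

from itertools import product

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def hairpin_oracle(seq, min_stem, min_loop, max_loop, allow_gu=False):
    """Best (stem_pairs, loop_len, start) by full enumeration of
    (start, stem, loop) triples; None when nothing qualifies."""
    s = seq.upper().replace("U", "T")
    n = len(s)

    def pairs(x, y):
        if _COMP.get(x) == y:
            return True
        return allow_gu and {x, y} == {"G", "T"}

    best = None
    for start in range(n):
        for stem in range(min_stem, n):
            for loop in range(min_loop, max_loop + 1):
                end = start + 2 * stem + loop  # exclusive
                if end > n:
                    break
                if all(pairs(s[start + t], s[end - 1 - t]) for t in range(stem)):
                    # reject non-maximal stems (the next inward pair also pairs)
                    if loop >= min_loop + 2 and pairs(s[start + stem], s[end - 1 - stem]):
                        continue
                    key = (stem, -loop, -start)
                    if best is None or key > best[0]:
                        best = (key, (stem, loop, start + 1))
    return None if best is None else best[1]


def _substrings(labels, circular):
    """All contiguous runs (as tuples) of length >= 1, honouring the wrap."""
    n = len(labels)
    out = set()
    limit = n if circular else n
    for i in range(n):
        max_len = n if circular else n - i
        for length in range(1, max_len + 1):
            out.add(tuple(labels[(i + k) % n] for k in range(length)))
    return out


def shared_blocks_oracle(a_labels, b_labels, min_len=2, circular=False):
    """Maximal common contiguous runs by enumerating every substring of
    ``a`` and testing membership among substrings of ``b`` (same direction
    only, matching the unsigned comparison)."""
    subs_b = _substrings(b_labels, circular)
    common = [
        s
        for s in _substrings(a_labels, circular)
        if len(s) >= min_len and s in subs_b and len(set(s)) == len(s)
    ]
    # keep only maximal runs: not a proper infix of another common run
    def is_infix(small, big):
        if len(small) >= len(big):
            return False
        return any(
            big[i : i + len(small)] == small for i in range(len(big) - len(small) + 1)
        )

    maximal = {s for s in common if not any(is_infix(s, t) for t in common if t != s)}
    return sorted(maximal, key=lambda s: (-len(s), s))


def breakpoint_oracle(a_labels, b_labels, circular=False):
    """Adjacencies of a absent from b, pairs unordered."""

    def adj(labels):
        n = len(labels)
        last = n if circular else n - 1
        return {frozenset((labels[i], labels[(i + 1) % n])) for i in range(last)}

    return len(adj(a_labels) - adj(b_labels))


def rscu_oracle(counts_by_family):
    """RSCU per codon from an explicit {family: {codon: count}} mapping."""
    out = {}
    for codons in counts_by_family.values():
        total = sum(codons.values())
        for c, n in codons.items():
            out[c] = None if total == 0 else n * len(codons) / total
    return out
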