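"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: entropy sums are
written out with math.log2 over explicit contingency counts, and the
maximum base-pairing count is found by enumerating every legal
non-crossing structure recursively.
"""

import math

ORACLE_PAIRS = {"AU", "UA", "GC", "CG", "GU", "UG"}
ORACLE_MIN_LOOP = 3


def brute_force_information_gain(bin_ids, labels) -> float:
    """IG from the raw contingency table, base-2 logs, no numpy."""
    n = len(labels)
    assert n == len(bin_ids)

    def entropy(counts):
        total = sum(counts)
        h = 0.0
        for c in counts:
            if c > 0:
                p = c / total
                h -= p * math.log2(p)
        return h

    classes = sorted(set(labels))
    h_y = entropy([sum(1 for y in labels if y == c) for c in classes])
    cond = 0.0
    for b in sorted(set(bin_ids)):
        members = [y for bid, y in zip(bin_ids, labels) if bid == b]
        cond += len(members) / n * entropy(
            [sum(1 for y in members if y == c) for c in classes]
        )
    return h_y - cond


def brute_force_max_pairs(seq: str) -> int:
    """Max base pairs over all legal non-crossing structures, by enumeration.

    Recursion on the leftmost position: leave it unpaired, or pair it
    with every admissible partner and recurse into the two independent
    sub-intervals.  Exponential, fine for length <= 12.
    """

    def best(i: int, j: int) -> int:
        if j - i <= ORACLE_MIN_LOOP:
            return 0
        score = best(i + 1, j)  # i unpaired
        for k in range(i + ORACLE_MIN_LOOP + 1, j + 1):
            if seq[i] + seq[k] in ORACLE_PAIRS:
                score = max(score, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return score

    return best(0, len(seq) - 1)
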