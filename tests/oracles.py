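"""Independent brute-force oracles used only by tests.

Deliberately written without reference to the package internals: a
memoized exhaustive search over all alignments for the semiglobal affine
score, and a window-by-window IUPAC scanner for target sites.
"""

from functools import lru_cache

NEG = -(10**9)

ORACLE_IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
    "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_rc(seq):
    return "".join(_RC[c] for c in reversed(seq))


def oracle_semiglobal_score(read, ref, match=1, mismatch=1,
                            gap_open=2, gap_extend=1):
    """Best score over ALL alignments of the full read within the
    reference, free reference end gaps, gap cost open + extend * L."""
    m, n = len(read), len(ref)
    open_cost = gap_open + gap_extend

    @lru_cache(maxsize=None)
    def rec(i, j, state):
        if i == m:
            return 0  # remaining reference is a free end gap
        best = NEG
        if j < n:
            hit = read[i] == ref[j] and read[i] != "N"
            best = max(best, (match if hit else -mismatch)
                       + rec(i + 1, j + 1, "M"))
            cost = gap_extend if state == "D" else open_cost
            best = max(best, -cost + rec(i, j + 1, "D"))
        cost = gap_extend if state == "I" else open_cost
        best = max(best, -cost + rec(i + 1, j, "I"))
        return best

    result = max(rec(0, j0, "M") for j0 in range(n + 1))
    rec.cache_clear()
    return result


def oracle_scan(sequence, pattern, spacer_len):
    """Naive window-by-window scan; returns a set of
    (strand, pam_start, pam_end, proto_start, proto_end) tuples."""
    seq = sequence.upper()
    plen = len(pattern)
    hits = set()

    def matches(window):
        return all(c in ORACLE_IUPAC[p] for c, p in zip(window, pattern))

    for i in range(len(seq) - plen + 1):
        window = seq[i : i + plen]
        if "N" in window:
            continue
        if matches(window) and i + plen + spacer_len <= len(seq):
            hits.add(("+", i, i + plen, i + plen, i + plen + spacer_len))
        if matches(oracle_rc(window)) and i - spacer_len >= 0:
            hits.add(("-", i, i + plen, i - spacer_len, i))
    return hits
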