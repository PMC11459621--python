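"""Independent brute-force oracles used to validate the implementation.

These deliberately share no code with gpseq: plain-Python textbook DP for
local alignment, and an exhaustive dinucleotide scan for the Read2
treatment boundary.
"""

from __future__ import annotations


def sw_score_oracle(
    query: str,
    target: str,
    mode: str = "off",
    match: int = 5,
    mismatch: int = 0,
    gap: int = 6,
) -> int:
    """Textbook O(nm) Smith-Waterman best local score (linear gaps)."""
    n, m = len(query), len(target)
    prev = [0] * (m + 1)
    best = 0
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        qc = query[i - 1]
        for j in range(1, m + 1):
            tc = target[j - 1]
            ok = qc == tc and qc != "N"
            if mode == "CT" and tc == "C" and qc == "T":
                ok = True
            if mode == "GA" and tc == "G" and qc == "A":
                ok = True
            if tc == "N":
                ok = False
            s = match if ok else mismatch
            cur[j] = max(0, prev[j - 1] + s, prev[j] - gap, cur[j - 1] - gap)
            if cur[j] > best:
                best = cur[j]
        prev = cur
    return best


def boundary_oracle(seq: str) -> int | None:
    """Exhaustive scan: one past the last G preceded by A/T/G, else None."""
    candidates = [
        i + 1
        for i in range(1, len(seq))
        if seq[i] == "G" and seq[i - 1] in "ATG"
    ]
    return candidates[-1] if candidates else None
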