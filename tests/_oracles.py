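"""Independent oracles used by the test suite.

These deliberately re-derive expectations by brute force (exhaustive
substring comparison, direct formula evaluation) without touching the
implementation paths they check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

_COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_exact_matches(query: str, element_seq: str, min_len: int):
    """All maximal exact common substrings >= min_len, one strand.

    Returns a set of (qstart, qend) query intervals, computed per diagonal
    with a plain match/mismatch scan.
    """
    out = set()
    qn, en = len(query), len(element_seq)
    qa = np.frombuffer(query.encode(), dtype="S1")
    ea = np.frombuffer(element_seq.encode(), dtype="S1")
    for diag in range(-en + 1, qn):
        qlo = max(0, diag)
        qhi = min(qn, diag + en)
        if qhi - qlo < min_len:
            continue
        m = qa[qlo:qhi] == ea[qlo - diag:qhi - diag]
        i = 0
        L = len(m)
        while i < L:
            if m[i]:
                j = i
                while j < L and m[j]:
                    j += 1
                if j - i >= min_len:
                    out.add((qlo + i, qlo + j))
                i = j
            else:
                i += 1
    return out


def oracle_match_set(query: str, library, min_len: int):
    """Exact-match oracle over a whole library, both strands, with the same
    containment rule the matcher applies (drop intervals strictly contained
    in a longer match to the same element+strand)."""
    raw = []
    for el in library:
        for strand, seq in (("+", el.sequence), ("-", rc(el.sequence))):
            for qstart, qend in brute_force_exact_matches(query, seq, min_len):
                raw.append((el.id, strand, qstart, qend))
    kept = set()
    for mid, strand, qs, qe in raw:
        contained = any(
            m2 == mid and s2 == strand and qs2 <= qs and qe <= qe2
            and (qs2, qe2) != (qs, qe)
            for m2, s2, qs2, qe2 in raw
        )
        if not contained:
            kept.add((mid, strand, qs, qe))
    return kept


def hand_pooled_t_p(x, y) -> float:
    """Two-sided pooled-variance two-sample t-test from first principles."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return 2 * stats.t.sf(abs(t), n1 + n2 - 2)


def count_substring_occurrences(haystacks, needle: str) -> int:
    """Direct both-strand overlapping occurrence count of one needle."""
    total = 0
    for strand_seq in (needle, rc(needle)):
        for hay in haystacks:
            start = 0
            while True:
                i = hay.find(strand_seq, start)
                if i < 0:
                    break
                total += 1
                start = i + 1
    if needle == rc(needle):
        total //= 2
    return total
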