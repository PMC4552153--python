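"""Repeat-junction detection and classification.

A repeat junction is the boundary between a sequence matching a classed
repeat library and something else — either unmatched (genic / low-copy /
not-in-library) sequence or a different repeat element.  Junctions are found
with a self-contained k-mer-seeded ungapped extender against the repeat
library, so no external aligner is required; thresholds (seed length,
minimum match length, minimum identity) play the role an E-value cutoff
would in a BLAST-based screen.

Detected junctions are classified into the canonical categories formed by
the unordered pair of flanking classes: retrotransposon-unknown,
dna_transposon-unknown, retrotransposon-retrotransposon,
dna_transposon-dna_transposon and dna_transposon-retrotransposon.  An
unknown-unknown pair is not a repeat junction and is rejected.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seq import revcomp, validate_dna
from .synthdata import DNA_TE, RETRO, UNKNOWN

#: a crossed mismatch must be followed by at least this many matches for the
#: ungapped extension to continue; stops drift into random flanking sequence
MIN_EXTEND_RUN = 8

#: two matches whose edges are within this many bases are treated as abutting
GAP_TOLERANCE = 5

CATEGORIES = (
    "retrotransposon-unknown",
    "dna_transposon-unknown",
    "retrotransposon-retrotransposon",
    "dna_transposon-dna_transposon",
    "dna_transposon-retrotransposon",
)

_CATEGORY_BY_PAIR = {
    frozenset({RETRO, UNKNOWN}): "retrotransposon-unknown",
    frozenset({DNA_TE, UNKNOWN}): "dna_transposon-unknown",
    frozenset({RETRO}): "retrotransposon-retrotransposon",
    frozenset({DNA_TE}): "dna_transposon-dna_transposon",
    frozenset({RETRO, DNA_TE}): "dna_transposon-retrotransposon",
}


@dataclass(frozen=True)
class RepeatMatch:
    """An ungapped alignment of a query interval to a library element."""

    query_id: str
    qstart: int
    qend: int
    element_id: str
    element_class: str
    strand: str
    identity: float

    def __post_init__(self) -> None:
        if not (0 <= self.qstart < self.qend):
            raise ValueError("bad match interval")

    @property
    def length(self) -> int:
        return self.qend - self.qstart


@dataclass(frozen=True)
class DetectedJunction:
    """A classified junction at ``midpoint`` (0-based boundary) in the query."""

    query_id: str
    midpoint: int
    left_class: str
    right_class: str
    category: str
    flank_left: int
    flank_right: int


def classify_junction(left_class: str, right_class: str) -> str:
    """Order-insensitive canonical category label for a pair of classes."""
    for c in (left_class, right_class):
        if c not in (RETRO, DNA_TE, UNKNOWN):
            raise ValueError(f"unknown class {c!r}")
    if left_class == UNKNOWN and right_class == UNKNOWN:
        raise ValueError("an unknown-unknown boundary is not a repeat junction")
    return _CATEGORY_BY_PAIR[frozenset({left_class, right_class})]


class RepeatMatcher:
    """k-mer index over a repeat library (both strands), reusable across queries."""

    def __init__(self, library, k: int = 16):
        if k < 4:
            raise ValueError("seed length k must be >= 4")
        self.k = k
        self.library = library
        # kmer -> list of (element index, strand, element-oriented sequence offset)
        self.index: dict[str, list[tuple[int, str, int]]] = defaultdict(list)
        self.oriented: dict[tuple[int, str], str] = {}
        for ei, el in enumerate(library):
            for strand in "+-":
                seq = el.sequence if strand == "+" else revcomp(el.sequence)
                self.oriented[(ei, strand)] = seq
                for off in range(len(seq) - k + 1):
                    self.index[seq[off:off + k]].append((ei, strand, off))

    # -- extension ---------------------------------------------------------

    @staticmethod
    def _extend(m: np.ndarray, s: int, e: int, min_identity: float) -> tuple[int, int, int]:
        """Grow an all-match run [s, e) across isolated mismatches.

        Each step consumes one mismatch plus the following match run; it is
        accepted only if that run has >= MIN_EXTEND_RUN matches and the
        segment identity stays >= min_identity.  With min_identity == 1.0 no
        step is ever accepted, so segments are exactly maximal exact runs.
        """
        mis = 0
        n = len(m)
        while True:
            grew = False
            # rightwards: m[e] is a mismatch (or e == n)
            if e < n:
                j = e + 1
                while j < n and m[j]:
                    j += 1
                run = j - (e + 1)
                length = j - s
                if run >= MIN_EXTEND_RUN and (length - (mis + 1)) / length >= min_identity:
                    e, mis = j, mis + 1
                    grew = True
            # leftwards: m[s-1] is a mismatch (or s == 0)
            if s > 0:
                j = s - 2
                while j >= 0 and m[j]:
                    j -= 1
                run = (s - 1) - (j + 1)
                length = e - (j + 1)
                if run >= MIN_EXTEND_RUN and (length - (mis + 1)) / length >= min_identity:
                    s, mis = j + 1, mis + 1
                    grew = True
            if not grew:
                return s, e, mis

    def find(
        self,
        query: str,
        min_match_len: int = 30,
        min_identity: float = 0.9,
        query_id: str = "query",
    ) -> list[RepeatMatch]:
        k = self.k
        validate_dna(query, "query")
        if k > min_match_len:
            raise ValueError("seed length k must not exceed min_match_len")
        if len(query) < min_match_len:
            raise ValueError("query shorter than min_match_len")
        qarr = np.frombuffer(query.encode(), dtype="S1")

        seeds: dict[tuple[int, str, int], list[int]] = defaultdict(list)
        for qpos in range(len(query) - k + 1):
            for ei, strand, off in self.index.get(query[qpos:qpos + k], ()):
                seeds[(ei, strand, qpos - off)].append(qpos)

        raw: list[RepeatMatch] = []
        for (ei, strand, diag), qposs in seeds.items():
            eseq = self.oriented[(ei, strand)]
            qlo = max(0, diag)
            qhi = min(len(query), diag + len(eseq))
            if qhi - qlo < min_match_len:
                continue
            earr = np.frombuffer(eseq.encode(), dtype="S1")
            m = qarr[qlo:qhi] == earr[qlo - diag:qhi - diag]
            claimed: list[tuple[int, int]] = []
            for qpos in sorted(qposs):
                rel = qpos - qlo
                if any(s <= rel < e for s, e in claimed):
                    continue
                # maximal exact run containing this seed
                s = rel
                while s > 0 and m[s - 1]:
                    s -= 1
                e = rel
                while e < len(m) and m[e]:
                    e += 1
                s, e, mis = self._extend(m, s, e, min_identity)
                claimed.append((s, e))
                length = e - s
                identity = (length - mis) / length
                if length >= min_match_len and identity >= min_identity:
                    el = self.library.elements[ei]
                    raw.append(
                        RepeatMatch(query_id, qlo + s, qlo + e, el.id,
                                    el.repeat_class, strand, identity)
                    )

        # dedupe identical intervals, then drop matches strictly contained in a
        # longer match to the same element+strand ("overlapping matches merged")
        uniq = {}
        for mt in raw:
            key = (mt.element_id, mt.strand, mt.qstart, mt.qend)
            if key not in uniq or mt.identity > uniq[key].identity:
                uniq[key] = mt
        matches = sorted(uniq.values(), key=lambda x: (x.qstart, -(x.qend)))
        kept: list[RepeatMatch] = []
        for mt in matches:
            contained = any(
                o.element_id == mt.element_id and o.strand == mt.strand
                and o.qstart <= mt.qstart and mt.qend <= o.qend
                and (o.qstart, o.qend) != (mt.qstart, mt.qend)
                for o in matches
            )
            if not contained:
                kept.append(mt)
        return kept


def find_repeat_matches(
    query: str,
    library,
    min_match_len: int = 30,
    min_identity: float = 0.9,
    k: int = 16,
    query_id: str = "query",
) -> list[RepeatMatch]:
    """One-shot matcher; build a :class:`RepeatMatcher` for bulk scanning."""
    if len(library) == 0:
        validate_dna(query, "query")
        return []
    return RepeatMatcher(library, k=k).find(
        query, min_match_len=min_match_len, min_identity=min_identity,
        query_id=query_id,
    )


def detect_junctions(
    query_id: str,
    matches: Sequence[RepeatMatch],
    query_length: int,
    min_flank: int = 25,
) -> list[DetectedJunction]:
    """Junctions at qualifying match edges.

    A lone match edge becomes a (element, unknown) junction when the match
    and the sequence beyond the edge each provide at least *min_flank* bases
    of support.  Two matches whose facing edges are within GAP_TOLERANCE
    bases collapse into a single element-element junction at the midpoint of
    the two edges (rounded down).
    """
    if min_flank < 1:
        raise ValueError("min_flank must be >= 1")
    for mt in matches:
        if mt.query_id != query_id:
            raise ValueError("match does not belong to this query")
    ms = sorted(matches, key=lambda x: (x.qstart, x.qend))
    paired_left: set[int] = set()   # indices whose left edge is in a pair
    paired_right: set[int] = set()
    out: list[DetectedJunction] = []
    for i in range(len(ms) - 1):
        a, b = ms[i], ms[i + 1]
        gap = b.qstart - a.qend
        if abs(gap) <= GAP_TOLERANCE:
            mid = (a.qend + b.qstart) // 2
            if a.length >= min_flank and b.length >= min_flank and 0 < mid < query_length:
                out.append(
                    DetectedJunction(
                        query_id, mid, a.element_class, b.element_class,
                        classify_junction(a.element_class, b.element_class),
                        a.length, b.length,
                    )
                )
            paired_right.add(i)
            paired_left.add(i + 1)
    for i, mt in enumerate(ms):
        if i not in paired_left:
            flank = mt.qstart
            if flank >= min_flank and mt.length >= min_flank and 0 < mt.qstart < query_length:
                out.append(
                    DetectedJunction(
                        query_id, mt.qstart, UNKNOWN, mt.element_class,
                        classify_junction(UNKNOWN, mt.element_class),
                        flank, mt.length,
                    )
                )
        if i not in paired_right:
            flank = query_length - mt.qend
            if flank >= min_flank and mt.length >= min_flank and 0 < mt.qend < query_length:
                out.append(
                    DetectedJunction(
                        query_id, mt.qend, mt.element_class, UNKNOWN,
                        classify_junction(mt.element_class, UNKNOWN),
                        mt.length, flank,
                    )
                )
    out.sort(key=lambda j: j.midpoint)
    return out


def scan_reads(
    reads,
    library,
    min_match_len: int = 30,
    min_identity: float = 0.9,
    k: int = 16,
    min_flank: int = 25,
) -> list[DetectedJunction]:
    """Detect junctions in every read of a ReadSet (or iterable of reads)."""
    if len(library) == 0:
        return []
    matcher = RepeatMatcher(library, k=k)
    out: list[DetectedJunction] = []
    reads_iter = reads.reads if hasattr(reads, "reads") else reads
    for r in reads_iter:
        if len(r.sequence) < min_match_len:
            continue
        ms = matcher.find(r.sequence, min_match_len=min_match_len,
                          min_identity=min_identity, query_id=r.id)
        out.extend(detect_junctions(r.id, ms, len(r.sequence), min_flank=min_flank))
    return out


def tabulate_categories(junctions: Iterable[DetectedJunction]) -> pd.Series:
    """Counts per canonical category; always indexed by all five labels."""
    counts = pd.Series(0, index=list(CATEGORIES), dtype=int, name="count")
    for j in junctions:
        counts[j.category] += 1
    return counts
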