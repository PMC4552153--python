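"""52-mer probe extraction and the four-step filter cascade.

Junction probes are fixed-length windows with the repeat junction at the
midpoint.  Candidates then pass through, in order:

1. homopolymer screen (no single-base run longer than ``max_run``),
2. deep-read validation (the exact 52-mer must occur in high-coverage
   validation reads, removing windows carrying sequencing errors),
3. copy-number screen against target-genome shotgun reads (more than
   ``max_hits`` exact occurrences means multi-copy; zero occurrences means
   the junction is absent from the target genome — both fail),
4. thermodynamic screen (GC content and salt-adjusted melting temperature
   inside fixed windows, so all probes hybridize comparably).

Gene probes are picked left-to-right along each gene, non-overlapping, and
by default skip the read-based screens (genes are expected in homeologous
copies).  Accounting charges every rejected candidate to the first failing
step, so candidate = selected + sum(rejections) always holds.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .seq import revcomp, validate_dna

PROBE_LENGTH = 52

FILTERS = ("homopolymer", "read_validation", "copy_number", "thermo")

PASS, FAIL, NOT_RUN = "pass", "fail", "not_run"


@dataclass
class DesignConfig:
    probe_length: int = PROBE_LENGTH
    max_run: int = 3
    min_support: int = 2
    max_hits: int = 5
    gc_range: tuple[float, float] = (50.0, 65.0)
    tm_range: tuple[float, float] = (76.0, 83.0)
    na_molar: float = 0.165
    max_gene_probes: int = 3
    gene_spacing: int = 10
    gene_read_validation: bool = False
    gene_copy_number: bool = False


@dataclass
class Probe:
    """A designed probe with per-filter verdicts.

    ``source`` is (query or gene id, 0-based window start within it);
    ``genome_coords`` holds truth coordinates when known (simulation).
    """

    id: str
    sequence: str
    probe_type: str                      # "rjm" | "gene"
    source: tuple[str, int]
    gc_percent: float
    tm_celsius: float
    verdicts: dict[str, str] = field(default_factory=lambda: dict.fromkeys(FILTERS, NOT_RUN))
    genome_coords: list[tuple[str, int]] | None = None
    multi_copy: bool = False

    @classmethod
    def build(cls, probe_id: str, sequence: str, probe_type: str,
              source: tuple[str, int], na_molar: float = 0.165) -> "Probe":
        validate_dna(sequence, f"probe {probe_id}")
        return cls(
            probe_id, sequence, probe_type, source,
            gc_percent=gc_content(sequence),
            tm_celsius=melting_temp(sequence, na_molar=na_molar),
        )

    @property
    def selected(self) -> bool:
        """A probe is selected iff every filter that ran passed."""
        return all(v != FAIL for v in self.verdicts.values())

    def first_failure(self) -> str | None:
        for f in FILTERS:
            if self.verdicts[f] == FAIL:
                return f
        return None


@dataclass
class ProbeSet:
    probes: list[Probe]
    accounting: dict[str, int]

    def selected_probes(self) -> list[Probe]:
        return [p for p in self.probes if p.selected]

    def check_accounting(self) -> None:
        acc = self.accounting
        total = acc["selected"] + sum(
            v for k, v in acc.items() if k not in ("candidates", "selected")
        )
        if total != acc["candidates"]:
            raise AssertionError(f"accounting does not balance: {acc}")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def extract_window(sequence: str, junction_midpoint: int, length: int = PROBE_LENGTH):
    """The [mid - L/2, mid + L/2) window, or ``None`` when it leaves the sequence."""
    if length % 2 != 0:
        raise ValueError("probe length must be even")
    half = length // 2
    start = junction_midpoint - half
    end = junction_midpoint + half
    if start < 0 or end > len(sequence):
        return None
    return start, sequence[start:end]


def homopolymer_filter(sequence: str, max_run: int = 3) -> bool:
    """True (pass) unless any single-base run exceeds *max_run*."""
    return re.search(r"(A{%d,}|C{%d,}|G{%d,}|T{%d,})" % ((max_run + 1,) * 4),
                     sequence) is None


def gc_content(sequence: str) -> float:
    """GC percentage of a sequence."""
    if not sequence:
        raise ValueError("empty sequence")
    return 100.0 * (sequence.count("G") + sequence.count("C")) / len(sequence)


def melting_temp(sequence: str, na_molar: float = 0.165) -> float:
    """Salt-adjusted long-oligo melting temperature (degrees C).

    Tm = 81.5 + 16.6 log10([Na+]) + 0.41 GC% - 600/N, the standard formula
    for oligos of ~50 bases where nearest-neighbour models are unnecessary.
    """
    if na_molar <= 0:
        raise ValueError("sodium concentration must be positive")
    n = len(sequence)
    if n < 14:
        raise ValueError("formula requires length >= 14")
    return 81.5 + 16.6 * math.log10(na_molar) + 0.41 * gc_content(sequence) - 600.0 / n


def thermo_filter(
    sequence: str,
    gc_range: tuple[float, float] = (50.0, 65.0),
    tm_range: tuple[float, float] = (76.0, 83.0),
    na_molar: float = 0.165,
) -> bool:
    """Pass iff GC% and Tm both fall inside their (inclusive) windows."""
    if gc_range[0] > gc_range[1] or tm_range[0] > tm_range[1]:
        raise ValueError("filter ranges must be non-empty")
    gc = gc_content(sequence)
    tm = melting_temp(sequence, na_molar=na_molar)
    return gc_range[0] <= gc <= gc_range[1] and tm_range[0] <= tm <= tm_range[1]


def count_exact_occurrences(
    sequences: Iterable[str], queries: Sequence[str]
) -> dict[str, int]:
    """Exact, full-length, both-strand occurrence counts of each query.

    One sweep over *sequences* with a hash lookup per window keeps the cost
    independent of the number of queries.  All queries must share one length.
    """
    counts = {q: 0 for q in queries}
    if not counts:
        return counts
    lengths = {len(q) for q in counts}
    if len(lengths) != 1:
        raise ValueError("all queries must have the same length")
    L = lengths.pop()
    targets: dict[str, list[str]] = {}
    for q in counts:
        targets.setdefault(q, []).append(q)
        rc = revcomp(q)
        if rc != q:
            targets.setdefault(rc, []).append(q)
    for seq in sequences:
        for i in range(len(seq) - L + 1):
            hit = targets.get(seq[i:i + L])
            if hit:
                for q in hit:
                    counts[q] += 1
    return counts


def validate_with_deep_reads(probe: Probe, support_count: int, min_support: int = 2) -> bool:
    """Pass iff the probe's exact sequence has >= *min_support* read occurrences."""
    return support_count >= min_support


def copy_number_filter(probe: Probe, hit_count: int, max_hits: int = 5) -> bool:
    """Pass iff 1 <= hits <= max_hits.

    More than *max_hits* exact occurrences in ~max_hits-fold coverage reads
    implies more than one genomic copy; zero occurrences implies the locus is
    absent from the target genome.  Both fail.
    """
    return 0 < hit_count <= max_hits


# ---------------------------------------------------------------------------
# gene probes
# ---------------------------------------------------------------------------

def design_gene_probes(
    gene_sequence: str,
    gene_id: str = "gene",
    max_probes: int = 3,
    spacing: int = 10,
    config: DesignConfig | None = None,
) -> list[Probe]:
    """Up to *max_probes* non-overlapping windows passing the sequence filters.

    Windows are scanned left to right with at least *spacing* bases between
    chosen probes; each must clear the homopolymer and thermodynamic screens.
    """
    cfg = config or DesignConfig()
    L = cfg.probe_length
    out: list[Probe] = []
    pos = 0
    while pos + L <= len(gene_sequence) and len(out) < max_probes:
        window = gene_sequence[pos:pos + L]
        if homopolymer_filter(window, cfg.max_run) and thermo_filter(
            window, cfg.gc_range, cfg.tm_range, cfg.na_molar
        ):
            p = Probe.build(f"GENE_{gene_id}_{len(out) + 1}", window, "gene",
                            source=(gene_id, pos), na_molar=cfg.na_molar)
            p.verdicts["homopolymer"] = PASS
            p.verdicts["thermo"] = PASS
            out.append(p)
            pos += L + spacing
        else:
            pos += 1
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_design_pipeline(
    junctions: Sequence,
    discovery_seqs: Mapping[str, str],
    validation_reads,
    target_reads,
    genes: Sequence[tuple[str, str]] = (),
    config: DesignConfig | None = None,
) -> ProbeSet:
    """Full cascade: extract -> homopolymer -> read validation -> copy number -> thermo.

    *junctions* are detected junctions carrying ``query_id`` and ``midpoint``;
    *discovery_seqs* maps query id to its sequence.  Every filter verdict is
    evaluated for every candidate (so the selected set is independent of
    filter order); accounting charges each rejected probe to the first
    failing step in the canonical order.
    """
    cfg = config or DesignConfig()
    acc = {
        "candidates": 0, "selected": 0, "edge": 0, "duplicate": 0,
        "homopolymer": 0, "read_validation": 0, "copy_number": 0, "thermo": 0,
    }
    probes: list[Probe] = []
    seen: set[str] = set()
    n_rjm = 0
    for j in junctions:
        acc["candidates"] += 1
        seq = discovery_seqs[j.query_id]
        w = extract_window(seq, j.midpoint, cfg.probe_length)
        if w is None:
            acc["edge"] += 1
            continue
        start, window = w
        if window in seen:
            acc["duplicate"] += 1
            continue
        seen.add(window)
        n_rjm += 1
        probes.append(
            Probe.build(f"RJM_{n_rjm:06d}", window, "rjm",
                        source=(j.query_id, start), na_molar=cfg.na_molar)
        )

    for gene_id, gseq in genes:
        for p in design_gene_probes(gseq, gene_id=gene_id,
                                    max_probes=cfg.max_gene_probes,
                                    spacing=cfg.gene_spacing, config=cfg):
            acc["candidates"] += 1
            if p.sequence in seen:
                acc["duplicate"] += 1
                continue
            seen.add(p.sequence)
            probes.append(p)

    needs_validation = [
        p for p in probes
        if p.probe_type == "rjm" or cfg.gene_read_validation
    ]
    needs_copy = [
        p for p in probes
        if p.probe_type == "rjm" or cfg.gene_copy_number
    ]
    val_counts = count_exact_occurrences(
        _read_seqs(validation_reads), [p.sequence for p in needs_validation]
    )
    tgt_counts = count_exact_occurrences(
        _read_seqs(target_reads), [p.sequence for p in needs_copy]
    )

    for p in probes:
        v = p.verdicts
        v["homopolymer"] = (
            PASS if homopolymer_filter(p.sequence, cfg.max_run) else FAIL
        )
        if p.sequence in val_counts:
            ok = validate_with_deep_reads(p, val_counts[p.sequence], cfg.min_support)
            v["read_validation"] = PASS if ok else FAIL
        if p.sequence in tgt_counts:
            ok = copy_number_filter(p, tgt_counts[p.sequence], cfg.max_hits)
            v["copy_number"] = PASS if ok else FAIL
        v["thermo"] = (
            PASS if thermo_filter(p.sequence, cfg.gc_range, cfg.tm_range,
                                  cfg.na_molar) else FAIL
        )
        fail = p.first_failure()
        if fail is None:
            acc["selected"] += 1
        else:
            acc[fail] += 1

    ps = ProbeSet(probes, acc)
    ps.check_accounting()
    return ps


def _read_seqs(reads) -> Iterable[str]:
    if reads is None:
        return ()
    if hasattr(reads, "sequences"):
        return reads.sequences()
    if hasattr(reads, "reads"):
        return [r.sequence for r in reads.reads]
    return [getattr(r, "sequence", r) for r in reads]
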