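"""Synthetic genomes, aneuploid line panels, shotgun reads and hybridization signals.

This module generates every input the marker pipeline consumes, with full
ground truth attached, so that junction detection, probe filtering, and
chromosome/bin assignment can be validated end to end on data whose answer
is known by construction:

* a classed repeat library (retrotransposons and DNA transposons),
* multi-chromosome genomes with nested transposable-element insertions,
  genes, and an exact enumeration of every repeat-junction boundary,
* aneuploid line panels (one euploid control, one nullisomic line per
  chromosome, terminal-deletion lines defined by fraction-length
  breakpoints, and optionally a line missing the whole genome, standing in
  for an alternative-ploidy relative),
* fixed-length single-end shotgun reads with substitution errors,
* two-channel (test/reference) hybridization intensity matrices with
  replicated spots and arrays, dosage-dependent means, lognormal
  multiplicative noise and spot dropout.

Coordinates are 0-based, half-open throughout.  A junction "position" is the
index of the first base to the right of the boundary.  Fraction length (FL)
on a chromosome arm runs from 0 at the centromere to 1 at the telomere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seq import random_seq, revcomp, validate_dna

RETRO = "retrotransposon"
DNA_TE = "dna_transposon"
UNKNOWN = "unknown"

REPEAT_CLASSES = (RETRO, DNA_TE)

#: minimum distance kept between an insertion point and any existing segment
#: boundary, so that truth junctions are separated and flanks are detectable
INSERTION_MARGIN = 60


# ---------------------------------------------------------------------------
# repeat library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatElement:
    """A classed repeat sequence (one library entry)."""

    id: str
    repeat_class: str
    sequence: str

    def __post_init__(self) -> None:
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat class: {self.repeat_class!r}")
        validate_dna(self.sequence, f"repeat element {self.id}")


class RepeatLibrary:
    """An ordered collection of :class:`RepeatElement` with unique ids."""

    def __init__(self, elements: Iterable[RepeatElement] = ()):
        self.elements: list[RepeatElement] = list(elements)
        self.by_id: dict[str, RepeatElement] = {}
        for el in self.elements:
            if el.id in self.by_id:
                raise ValueError(f"duplicate element id {el.id!r}")
            self.by_id[el.id] = el

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    def class_of(self, element_id: str) -> str:
        return self.by_id[element_id].repeat_class


def build_repeat_library(
    n_retro: int,
    n_dna: int,
    length_range: tuple[int, int],
    seed: int,
) -> RepeatLibrary:
    """Uniform-random repeat library with ``n_retro + n_dna`` elements."""
    lo, hi = int(length_range[0]), int(length_range[1])
    if lo <= 0 or hi <= 0:
        raise ValueError("element lengths must be positive")
    if lo < 50:
        raise ValueError("minimum element length must be >= 50")
    if hi < lo:
        raise ValueError("length_range must be (min, max) with min <= max")
    if n_retro < 0 or n_dna < 0:
        raise ValueError("element counts must be >= 0")
    rng = np.random.default_rng(seed)
    elements = []
    for i in range(n_retro):
        n = int(rng.integers(lo, hi + 1))
        elements.append(RepeatElement(f"RLX_{i:03d}", RETRO, random_seq(rng, n)))
    for i in range(n_dna):
        n = int(rng.integers(lo, hi + 1))
        elements.append(RepeatElement(f"DTX_{i:03d}", DNA_TE, random_seq(rng, n)))
    return RepeatLibrary(elements)


# ---------------------------------------------------------------------------
# genome model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatJunctionTruth:
    """One true boundary between an inserted element and its neighbour."""

    chromosome: str
    position: int
    left_class: str
    right_class: str


@dataclass
class _Segment:
    origin: str      # "bg:<chrom>", "te:<k>" or "gene:<id>"
    el_class: str    # repeat class, or "unknown" for background/genic
    seq: str


@dataclass
class Line:
    """One stock of the aneuploid panel."""

    name: str
    kind: str                   # control | nulli_tetrasomic | deletion | alt_genome
    chromosome: str = ""
    arm: str = ""               # S | L | ""
    breakpoint_fl: float | None = None


class LinePanel:
    """Aneuploid line panel: one control plus nulli/deletion/alt lines."""

    def __init__(self, lines: Sequence[Line]):
        self.lines = list(lines)
        controls = [l for l in self.lines if l.kind == "control"]
        if len(controls) != 1:
            raise ValueError("panel must contain exactly one control line")
        for l in self.lines:
            if l.kind == "deletion":
                if not (l.chromosome and l.arm in ("S", "L")):
                    raise ValueError(f"deletion line {l.name} needs chromosome and arm")
                if l.breakpoint_fl is None or not (0.0 < l.breakpoint_fl < 1.0):
                    raise ValueError(f"deletion line {l.name} needs breakpoint in (0,1)")
            elif l.kind == "nulli_tetrasomic" and not l.chromosome:
                raise ValueError(f"nulli line {l.name} needs a target chromosome")
        names = [l.name for l in self.lines]
        if len(set(names)) != len(names):
            raise ValueError("line names must be unique")
        self.by_name = {l.name: l for l in self.lines}

    def __len__(self) -> int:
        return len(self.lines)

    @property
    def control(self) -> Line:
        return next(l for l in self.lines if l.kind == "control")

    @property
    def nulli_lines(self) -> list[Line]:
        return [l for l in self.lines if l.kind == "nulli_tetrasomic"]

    def deletion_lines(self, chromosome: str | None = None) -> list[Line]:
        out = [l for l in self.lines if l.kind == "deletion"]
        if chromosome is not None:
            out = [l for l in out if l.chromosome == chromosome]
        return out

    def breakpoints(self, chromosome: str) -> dict[str, list[float]]:
        """Sorted deletion breakpoints of *chromosome*, keyed by arm."""
        out: dict[str, list[float]] = {}
        for l in self.deletion_lines(chromosome):
            out.setdefault(l.arm, []).append(float(l.breakpoint_fl))
        for arm in out:
            out[arm] = sorted(out[arm])
        return out


class GenomeModel:
    """A simulated genome with full insertion/gene/junction ground truth.

    ``chromosomes`` holds ``(name, arm_fraction, sequence)`` triples; the
    centromere of a chromosome of length L sits at ``arm_fraction * L``
    (short arm = [0, centromere), long arm = [centromere, L)).
    """

    def __init__(
        self,
        chromosomes: list[tuple[str, float, str]],
        te_insertions: list[tuple[str, int, str, str]],
        genes: list[tuple[str, tuple[int, int], str]],
        junction_truth: list[RepeatJunctionTruth],
        n_nested: int = 0,
    ):
        self.chromosomes = chromosomes
        self.te_insertions = te_insertions
        self.genes = genes
        self.junction_truth = junction_truth
        self.n_nested = n_nested
        self.sequences = {name: seq for name, _, seq in chromosomes}
        self.arm_fractions = {name: af for name, af, _ in chromosomes}
        for j in junction_truth:
            if not (0 < j.position < len(self.sequences[j.chromosome])):
                raise ValueError("truth junction outside chromosome")

    @property
    def chrom_names(self) -> list[str]:
        return [name for name, _, _ in self.chromosomes]

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def arm_position(self, chrom: str, pos: int) -> tuple[str, float]:
        """Map a 0-based coordinate to ``(arm, fraction length)``.

        FL runs from 0 at the centromere to 1 at the telomere on each arm.
        """
        L = self.length(chrom)
        if not (0 <= pos < L):
            raise ValueError(f"position {pos} outside {chrom}")
        cen = self.arm_fractions[chrom] * L
        if pos < cen:
            return "S", (cen - pos) / cen
        return "L", (pos - cen) / (L - cen)

    def copy_number(self, line: Line, chrom: str, pos: int) -> int:
        """Copy count of the locus ``(chrom, pos)`` in *line* (control = 1)."""
        if line.kind == "control":
            return 1
        if line.kind == "alt_genome":
            return 0
        if line.kind == "nulli_tetrasomic":
            return 0 if chrom == line.chromosome else 1
        if line.kind == "deletion":
            if chrom != line.chromosome:
                return 1
            arm, fl = self.arm_position(chrom, pos)
            # the line retains the proximal fraction [0, b] of its arm
            return 0 if (arm == line.arm and fl > line.breakpoint_fl) else 1
        raise ValueError(f"unknown line kind {line.kind!r}")

    def gene_sequence(self, gene_id: str) -> str:
        for chrom, (start, end), gid in self.genes:
            if gid == gene_id:
                return self.sequences[chrom][start:end]
        raise KeyError(gene_id)


def simulate_genome(
    library: RepeatLibrary,
    chrom_specs: Sequence[tuple[str, int, float]],
    te_count: int = 0,
    nesting_prob: float = 0.0,
    gene_count: int = 0,
    seed: int = 0,
    gene_length_range: tuple[int, int] = (300, 900),
    gene_gc: float = 0.55,
) -> GenomeModel:
    """Assemble chromosomes with nested TE insertions and genes.

    Each insertion splits a host segment (background, or a previously
    inserted element when nesting) and the boundary bookkeeping enumerates
    every junction this creates: 2 per non-nested insertion, 4 per nested
    one, provided insertions never abut (guaranteed by an internal margin).
    Genes are spliced into TE-free background with a slightly elevated GC
    content typical of genic sequence.
    """
    if not (0.0 <= nesting_prob <= 1.0):
        raise ValueError("nesting_prob must be in [0,1]")
    if te_count < 0 or gene_count < 0:
        raise ValueError("counts must be >= 0")
    if te_count > 0 and len(library) == 0:
        raise ValueError("cannot place insertions from an empty library")
    rng = np.random.default_rng(seed)

    segs: dict[str, list[_Segment]] = {}
    for name, length, arm_fraction in chrom_specs:
        if length < 10_000:
            raise ValueError(f"chromosome {name}: length must be >= 10 kb")
        if not (0.0 < arm_fraction < 1.0):
            raise ValueError(f"chromosome {name}: arm fraction must be in (0,1)")
        segs[name] = [_Segment(f"bg:{name}", UNKNOWN, random_seq(rng, length))]

    m = INSERTION_MARGIN
    n_nested = 0
    for i in range(te_count):
        el = library.elements[int(rng.integers(len(library)))]
        strand = "+" if rng.random() < 0.5 else "-"
        ins_seq = el.sequence if strand == "+" else revcomp(el.sequence)
        want_nested = bool(rng.random() < nesting_prob)

        def _eligible(te: bool) -> list[tuple[str, int, int]]:
            # (chrom, segment index, usable length)
            out = []
            for name, slist in segs.items():
                for j, s in enumerate(slist):
                    if s.origin.startswith("te:") != te:
                        continue
                    usable = len(s.seq) - 2 * m
                    if usable > 0:
                        out.append((name, j, usable))
            return out

        cand = _eligible(True) if want_nested else _eligible(False)
        if want_nested and not cand:
            cand = _eligible(False)  # nothing to nest into yet
        if not cand:
            raise ValueError(
                "genome too small to host the requested insertions "
                f"(placed {i} of {te_count})"
            )
        weights = np.array([c[2] for c in cand], dtype=float)
        pick = int(rng.choice(len(cand), p=weights / weights.sum()))
        name, j, usable = cand[pick]
        host = segs[name][j]
        point = int(rng.integers(m, len(host.seq) - m + 1))
        if host.origin.startswith("te:"):
            n_nested += 1
        left = _Segment(host.origin, host.el_class, host.seq[:point])
        right = _Segment(host.origin, host.el_class, host.seq[point:])
        mid = _Segment(f"te:{i}|{el.id}|{strand}", el.repeat_class, ins_seq)
        segs[name][j:j + 1] = [left, mid, right]

    # genes go into TE-free background, away from any boundary
    glo, ghi = gene_length_range
    for g in range(gene_count):
        glen = int(rng.integers(glo, ghi + 1))
        cand = []
        for name, slist in segs.items():
            for j, s in enumerate(slist):
                if not s.origin.startswith("bg:"):
                    continue
                usable = len(s.seq) - glen - 2 * m
                if usable > 0:
                    cand.append((name, j, usable))
        if not cand:
            raise ValueError(f"no room left for gene {g} of {gene_count}")
        weights = np.array([c[2] for c in cand], dtype=float)
        pick = int(rng.choice(len(cand), p=weights / weights.sum()))
        name, j, usable = cand[pick]
        host = segs[name][j]
        off = int(rng.integers(m, len(host.seq) - glen - m + 1))
        gid = f"gene_{g:04d}"
        left = _Segment(host.origin, UNKNOWN, host.seq[:off])
        mid = _Segment(f"gene:{gid}", UNKNOWN, random_seq(rng, glen, gc=gene_gc))
        right = _Segment(host.origin, UNKNOWN, host.seq[off + glen:])
        segs[name][j:j + 1] = [left, mid, right]

    # final walk: coordinates, insertion records, gene records, junction truth
    chromosomes: list[tuple[str, float, str]] = []
    te_insertions: list[tuple[str, int, str, str]] = []
    genes: list[tuple[str, tuple[int, int], str]] = []
    truth: list[RepeatJunctionTruth] = []
    for name, _, af in chrom_specs:
        pos = 0
        seen_te: set[str] = set()
        parts = []
        slist = segs[name]
        for idx, s in enumerate(slist):
            if s.origin.startswith("te:") and s.origin not in seen_te:
                seen_te.add(s.origin)
                _, el_id, strand = s.origin.split("|")
                te_insertions.append((name, pos, el_id, strand))
            if s.origin.startswith("gene:"):
                genes.append((name, (pos, pos + len(s.seq)), s.origin[5:]))
            if idx > 0:
                prev = slist[idx - 1]
                if prev.origin != s.origin and (
                    prev.origin.startswith("te:") or s.origin.startswith("te:")
                ):
                    truth.append(
                        RepeatJunctionTruth(name, pos, prev.el_class, s.el_class)
                    )
            parts.append(s.seq)
            pos += len(s.seq)
        chromosomes.append((name, af, "".join(parts)))
    genes.sort(key=lambda g: (g[0], g[1][0]))
    return GenomeModel(chromosomes, te_insertions, genes, truth, n_nested=n_nested)


# ---------------------------------------------------------------------------
# line panel
# ---------------------------------------------------------------------------

def build_line_panel(
    genome: GenomeModel,
    deletion_fls: Mapping[str, Mapping[str, Sequence[float]]] | None = None,
    control_name: str = "CTRL",
    alt_genome_name: str | None = None,
) -> LinePanel:
    """Control + one nulli line per chromosome + one deletion line per breakpoint.

    ``deletion_fls`` maps chromosome -> arm -> sorted breakpoints in (0,1).
    A deletion line with breakpoint ``b`` on arm ``A`` retains the proximal
    fraction [0, b] of that arm and all other chromatin.  When
    *alt_genome_name* is given, a line lacking every chromosome is appended
    (used by the genome-specificity screen).
    """
    lines = [Line(control_name, "control")]
    for chrom in genome.chrom_names:
        lines.append(Line(f"N{chrom}", "nulli_tetrasomic", chromosome=chrom))
    deletion_fls = deletion_fls or {}
    for chrom, arms in deletion_fls.items():
        if chrom not in genome.sequences:
            raise ValueError(f"unknown chromosome {chrom!r} in deletion spec")
        for arm, bps in arms.items():
            if arm not in ("S", "L"):
                raise ValueError(f"arm must be 'S' or 'L', got {arm!r}")
            bps = [float(b) for b in bps]
            if len(set(bps)) != len(bps):
                raise ValueError(f"duplicate breakpoints on {chrom}{arm}")
            if sorted(bps) != bps:
                raise ValueError(f"breakpoints on {chrom}{arm} must be ascending")
            for b in bps:
                if not (0.0 < b < 1.0):
                    raise ValueError("breakpoints must lie strictly in (0,1)")
                lines.append(
                    Line(
                        f"{chrom}{arm}-{int(round(100 * b)):02d}",
                        "deletion",
                        chromosome=chrom,
                        arm=arm,
                        breakpoint_fl=b,
                    )
                )
    if alt_genome_name:
        lines.append(Line(alt_genome_name, "alt_genome"))
    return LinePanel(lines)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Read:
    id: str
    sequence: str
    chromosome: str
    start: int
    strand: str


@dataclass
class ReadSet:
    reads: list[Read]
    nominal_coverage: float

    def __len__(self) -> int:
        return len(self.reads)

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.reads]


def simulate_reads(
    genome: GenomeModel,
    coverage: float,
    read_length: int,
    substitution_rate: float = 0.0,
    seed: int = 0,
) -> ReadSet:
    """Uniform single-end reads at the requested nominal coverage.

    The read count is ``round(coverage * genome_length / read_length)``;
    origins are uniform over valid start positions, strands random, and
    substitution errors are injected independently per base.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not (0.0 <= substitution_rate < 1.0):
        raise ValueError("substitution_rate must be in [0,1)")
    shortest = min(genome.length(c) for c in genome.chrom_names)
    if read_length >= shortest:
        raise ValueError("read length must be shorter than the shortest chromosome")
    rng = np.random.default_rng(seed)
    total = genome.total_length
    n_reads = int(round(coverage * total / read_length))
    chroms = genome.chrom_names
    weights = np.array([genome.length(c) for c in chroms], dtype=float)
    weights /= weights.sum()
    picks = rng.choice(len(chroms), size=n_reads, p=weights)
    reads: list[Read] = []
    subs = "ACGT"
    for i in range(n_reads):
        chrom = chroms[int(picks[i])]
        start = int(rng.integers(0, genome.length(chrom) - read_length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        s = genome.sequences[chrom][start:start + read_length]
        if strand == "-":
            s = revcomp(s)
        if substitution_rate > 0:
            n_err = rng.binomial(read_length, substitution_rate)
            if n_err:
                seq = list(s)
                for p in rng.choice(read_length, size=n_err, replace=False):
                    cur = seq[p]
                    seq[p] = subs[(subs.index(cur) + int(rng.integers(1, 4))) % 4]
                s = "".join(seq)
        reads.append(Read(f"read_{i:07d}", s, chrom, start, strand))
    return ReadSet(reads, coverage)


def tile_reads(genome: GenomeModel, coverage: float, read_length: int) -> ReadSet:
    """Deterministic, error-free tiling reads at ~*coverage* depth.

    Forward-strand reads start every ``round(read_length / coverage)`` bases,
    so every internal k-mer is covered a fixed number of times.  Used where a
    coverage-based filter needs a noise-free occupancy signal.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    step = max(1, int(round(read_length / coverage)))
    reads = []
    i = 0
    for chrom in genome.chrom_names:
        L = genome.length(chrom)
        for start in range(0, L - read_length + 1, step):
            reads.append(
                Read(f"tile_{i:07d}", genome.sequences[chrom][start:start + read_length],
                     chrom, start, "+")
            )
            i += 1
    return ReadSet(reads, coverage)


# ---------------------------------------------------------------------------
# hybridization signals
# ---------------------------------------------------------------------------

@dataclass
class SignalModel:
    """Dosage-response model for two-channel hybridization intensities.

    ``base_intensity`` is the single-copy expectation scale; each additional
    copy multiplies the mean by ``copy_gain``.  A zero-copy locus yields no
    signal for junction probes and ``cross_hyb * base_intensity`` for gene
    probes (homeologous background).  ``lognormal_sd`` is the sd of the
    multiplicative log-normal noise; ``dropout_rate`` replaces individual
    spot measurements with near-background values.
    """

    base_intensity: float = 1000.0
    copy_gain: float = 2.0
    lognormal_sd: float = 0.15
    dropout_rate: float = 0.02
    cross_hyb: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_intensity <= 0:
            raise ValueError("base_intensity must be positive")
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ValueError("dropout_rate must be in [0,1]")
        if not (0.0 <= self.cross_hyb <= 1.0):
            raise ValueError("cross_hyb must be in [0,1]")
        if self.lognormal_sd < 0:
            raise ValueError("lognormal_sd must be >= 0")

    def expected_intensity(self, copies: int, probe_type: str) -> float:
        """Noise-free mean intensity for a locus present in *copies* doses.

        One copy hybridizes at ``base_intensity``; each extra copy
        multiplies by ``copy_gain``.  At zero copies a junction probe sees
        nothing while a gene probe keeps the homeologous background, so the
        noise-free loss of a deleted single-copy locus is exactly 1 for
        junction probes and ``1 - cross_hyb`` for gene probes.
        """
        if copies > 0:
            return self.base_intensity * self.copy_gain ** (copies - 1)
        if probe_type == "gene":
            return self.base_intensity * self.cross_hyb
        return 0.0


@dataclass
class SignalMatrix:
    """Per-probe two-channel intensities; columns ``line.array.spot.channel``."""

    data: pd.DataFrame

    @staticmethod
    def column_name(line: str, array_rep: int, spot_rep: int, channel: str) -> str:
        return f"{line}.{array_rep}.{spot_rep}.{channel}"

    @staticmethod
    def parse_column(name: str) -> tuple[str, int, int, str]:
        line, a, s, channel = name.rsplit(".", 3)
        if channel not in ("test", "ref"):
            raise ValueError(f"bad channel in column {name!r}")
        return line, int(a), int(s), channel

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    def lines(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.data.columns:
            seen.setdefault(self.parse_column(c)[0])
        return list(seen)


def probe_copy_number(probe, genome: GenomeModel, line: Line) -> int:
    """Summed copy number over a probe's truth loci in *line*."""
    coords = getattr(probe, "genome_coords", None)
    if not coords:
        if getattr(probe, "multi_copy", False):
            return 0
        raise ValueError(f"probe {probe.id} has no truth coordinate and is not flagged")
    return sum(genome.copy_number(line, chrom, pos) for chrom, pos in coords)


def simulate_hybridization(
    panel: LinePanel,
    probes: Sequence,
    genome: GenomeModel,
    model: SignalModel,
    n_arrays: int = 2,
    n_spots: int = 3,
) -> SignalMatrix:
    """Two-channel replicated intensities for every probe x line.

    The reference channel is always the euploid control genome (copy 1 at
    every locus); the test channel uses the line's copy number at the probe's
    truth coordinates.  Noise-free (``lognormal_sd=0, dropout_rate=0``)
    ratios are an exact function of copy number, e.g. a single-copy locus
    deleted in a line gives ``test/ref = expected(0)/expected(1)``.
    """
    if n_arrays < 1 or n_spots < 1:
        raise ValueError("need at least one array and one spot replicate")
    rng = np.random.default_rng(model.seed)
    probe_ids = [p.id for p in probes]
    ptypes = [getattr(p, "probe_type", "rjm") for p in probes]

    # copies[probe, line]
    copies = np.zeros((len(probes), len(panel.lines)), dtype=int)
    for j, line in enumerate(panel.lines):
        for i, p in enumerate(probes):
            copies[i, j] = probe_copy_number(p, genome, line)
    ref_copies = np.array(
        [probe_copy_number(p, genome, panel.control) for p in probes]
    )

    mu = np.empty_like(copies, dtype=float)
    mu_ref = np.empty(len(probes), dtype=float)
    for i, pt in enumerate(ptypes):
        mu_ref[i] = model.expected_intensity(int(ref_copies[i]), pt)
        for j in range(len(panel.lines)):
            mu[i, j] = model.expected_intensity(int(copies[i, j]), pt)

    cols: dict[str, np.ndarray] = {}
    n = len(probes)
    for j, line in enumerate(panel.lines):
        for a in range(1, n_arrays + 1):
            for s in range(1, n_spots + 1):
                for channel, base in (("test", mu[:, j]), ("ref", mu_ref)):
                    if model.lognormal_sd > 0:
                        noise = np.exp(rng.normal(0.0, model.lognormal_sd, size=n))
                    else:
                        noise = np.ones(n)
                    vals = base * noise
                    if model.dropout_rate > 0:
                        drop = rng.random(n) < model.dropout_rate
                        if drop.any():
                            bg = model.base_intensity * 0.01
                            vals = np.where(
                                drop,
                                bg * np.exp(rng.normal(0.0, 0.5, size=n)),
                                vals,
                            )
                    cols[SignalMatrix.column_name(line.name, a, s, channel)] = vals
    df = pd.DataFrame(cols, index=pd.Index(probe_ids, name="probe_id"))
    return SignalMatrix(df)


# ---------------------------------------------------------------------------
# array content from ground truth
# ---------------------------------------------------------------------------

def locate_probes(probes: Sequence, genome: GenomeModel) -> None:
    """Attach truth coordinates to probes by exact full-length genome search.

    Sets ``probe.genome_coords`` to the list of (chromosome, window start)
    occurrences (either strand) and ``probe.multi_copy`` when there is more
    than one.  A single sweep over the genome keeps this linear in genome
    size regardless of probe count.
    """
    if not probes:
        return
    L = len(probes[0].sequence)
    targets: dict[str, list] = {}
    for p in probes:
        if len(p.sequence) != L:
            raise ValueError("all probes must share one length")
        targets.setdefault(p.sequence, []).append(p)
        rc = revcomp(p.sequence)
        if rc != p.sequence:
            targets.setdefault(rc, []).append(p)
    hits: dict[int, list[tuple[str, int]]] = {id(p): [] for p in probes}
    for chrom, seq in genome.sequences.items():
        for i in range(len(seq) - L + 1):
            sub = seq[i:i + L]
            if sub in targets:
                for p in targets[sub]:
                    hits[id(p)].append((chrom, i))
    for p in probes:
        h = hits[id(p)]
        p.genome_coords = h
        p.multi_copy = len(h) > 1


def probes_from_truth(
    genome: GenomeModel,
    n_rjm: int | None = None,
    n_gene_probes: int | None = None,
    max_gene_probes: int = 3,
    probe_length: int = 52,
    seed: int = 0,
):
    """Array content straight from genome truth (no read pipeline).

    Junction probes are the *probe_length* windows centred on truth
    junctions; gene probes come from the gene intervals via the standard
    gene-probe designer.  Probes whose sequence is not single-copy in the
    genome are discarded.  Returns a list of :class:`~rjmap.probedesign.Probe`
    with ``genome_coords`` set.
    """
    from . import probedesign as pdx

    rng = np.random.default_rng(seed)
    half = probe_length // 2
    candidates = []
    order = rng.permutation(len(genome.junction_truth))
    for k in order:
        j = genome.junction_truth[int(k)]
        start = j.position - half
        end = j.position + half
        if start < 0 or end > genome.length(j.chromosome):
            continue
        seq = genome.sequences[j.chromosome][start:end]
        p = pdx.Probe.build(
            f"RJM_{j.chromosome}_{j.position}", seq, "rjm",
            source=(j.chromosome, start),
        )
        p.genome_coords = [(j.chromosome, start)]
        candidates.append(p)
        if n_rjm is not None and len(candidates) >= n_rjm:
            break
    n_rjm_got = len(candidates)

    gene_probes = []
    gorder = rng.permutation(len(genome.genes))
    for k in gorder:
        chrom, (gstart, gend), gid = genome.genes[int(k)]
        gseq = genome.sequences[chrom][gstart:gend]
        for p in pdx.design_gene_probes(gseq, gene_id=gid, max_probes=max_gene_probes):
            off = p.source[1]
            p.genome_coords = [(chrom, gstart + off)]
            gene_probes.append(p)
        if n_gene_probes is not None and len(gene_probes) >= n_gene_probes:
            break
    if n_gene_probes is not None:
        gene_probes = gene_probes[:n_gene_probes]
    probes = candidates + gene_probes

    counts = pdx.count_exact_occurrences(
        genome.sequences.values(), [p.sequence for p in probes]
    )
    unique = [p for p in probes if counts[p.sequence] == 1]
    for p in unique:
        p.multi_copy = False
    return unique


def simulate_genetic_map(
    genome: GenomeModel,
    marker_positions: Mapping[str, tuple[str, int]],
    chrom_cm_length: float = 150.0,
    suppression_power: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Monotone genetic map with centromeric recombination suppression.

    The cM coordinate grows with physical position but the local rate scales
    like ``fl ** suppression_power`` on each arm, so proximal markers
    cluster while distal markers spread out, as in real cereal maps.
    Returns a DataFrame with columns marker, chromosome, cm.
    """
    rows = []
    half = chrom_cm_length / 2.0
    for marker, (chrom, pos) in marker_positions.items():
        arm, fl = genome.arm_position(chrom, pos)
        # integral of rate ~ fl^p from centromere out
        dist = half * fl ** (suppression_power + 1)
        cm = half - dist if arm == "S" else half + dist
        rows.append((marker, chrom, float(cm)))
    df = pd.DataFrame(rows, columns=["marker", "chromosome", "cm"])
    return df.sort_values(["chromosome", "cm"], kind="stable").reset_index(drop=True)
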