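"""Deletion-bin bookkeeping and genetic/physical map integration.

A deletion bin is the chromosome segment between the fraction-length (FL)
breakpoints of two deletion lines; its physical length is the FL span times
the cytogenetic arm length.  The proximal residue of both arms plus the
centromere — the region no deletion line assays — forms a pericentromeric
composite bin whose marker count is obtained by subtraction: markers
assigned to the chromosome by the nullisomic panel minus markers placed in
assayed bins.

Markers inside a bin carry no order of their own; where a genetic map is
available the within-bin order is inferred from cM positions, and markers
whose cM position is inconsistent with the bin (it falls outside the bin's
own cM range but inside a neighbouring bin's) are flagged discordant and
excluded from the ordered list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

TERMINAL = "terminal"
INTERSTITIAL = "interstitial"
PERICENTROMERIC_KIND = "pericentromeric"


@dataclass(frozen=True)
class DeletionBin:
    chromosome: str
    arm: str                      # S | L | C (pericentromeric composite)
    fl_interval: tuple[float, float]   # (a, b], FL units
    physical_length_mb: float
    kind: str
    label: str

    def __post_init__(self) -> None:
        a, b = self.fl_interval
        if not (0.0 <= a < b <= 1.0):
            raise ValueError(f"bad FL interval {self.fl_interval}")
        if self.physical_length_mb < 0:
            raise ValueError("negative physical length")
        if self.kind == TERMINAL and b != 1.0:
            raise ValueError("terminal bin must end at FL 1.0")


# ---------------------------------------------------------------------------
# elementary ops
# ---------------------------------------------------------------------------

def estimate_bin_length(arm_length_mb: float, fl_interval: tuple[float, float]) -> float:
    """Physical bin length: (b - a) x arm length, in Mb."""
    a, b = fl_interval
    if arm_length_mb <= 0:
        raise ValueError("arm length must be positive")
    if a >= b:
        raise ValueError("FL interval must have a < b")
    return (b - a) * arm_length_mb


def pericentromeric_by_subtraction(chromosome_total: int, bin_counts: Sequence[int]) -> int:
    """Markers in the unassayed pericentromeric composite, by subtraction."""
    s = int(sum(bin_counts))
    total = int(chromosome_total)
    if s > total:
        raise ValueError(
            f"bin counts sum to {s}, exceeding the chromosome total {total}; "
            "the subtraction identity is violated"
        )
    return total - s


def marker_density(n_markers: int, span_mb: float) -> tuple[float, float]:
    """(markers per Mb, kb per marker)."""
    if n_markers <= 0 or span_mb <= 0:
        raise ValueError("marker count and span must be positive")
    return n_markers / span_mb, 1000.0 * span_mb / n_markers


def summarize_bins(bin_counts: Sequence[int]) -> dict[str, float]:
    """Mean/min/max unique markers per bin."""
    if not bin_counts:
        raise ValueError("need at least one bin")
    arr = np.asarray(bin_counts)
    return {
        "n_bins": len(arr),
        "total": int(arr.sum()),
        "mean": float(arr.mean()),
        "min": int(arr.min()),
        "max": int(arr.max()),
    }


def coverage_fraction(
    assayed_mb: float, genome_size_range_mb: tuple[float, float]
) -> tuple[float, float]:
    """Percent of the genome assayed, as a (low, high) range."""
    low, high = genome_size_range_mb
    if assayed_mb <= 0 or low <= 0 or high <= 0:
        raise ValueError("sizes must be positive")
    return 100.0 * assayed_mb / high, 100.0 * assayed_mb / low


def bin_genetic_length(cm_positions: Sequence[float]) -> float:
    """cM span of a bin's concordant markers (0 for a single marker)."""
    if len(cm_positions) == 0:
        raise ValueError("need at least one mapped marker")
    return float(max(cm_positions) - min(cm_positions))


def length_correlation(
    physical_mb: Sequence[float], genetic_cm: Sequence[float]
) -> dict[str, float]:
    """Pearson (primary) and Spearman correlation of bin physical vs genetic length."""
    x = np.asarray(physical_mb, dtype=float)
    y = np.asarray(genetic_cm, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired bins")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"pearson_r": float("nan"), "pearson_p": float("nan"),
                "spearman_r": float("nan"), "spearman_p": float("nan")}
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return {
        "pearson_r": float(pr.statistic), "pearson_p": float(pr.pvalue),
        "spearman_r": float(sr.statistic), "spearman_p": float(sr.pvalue),
    }


def order_markers_in_bin(
    markers_cm: Mapping[str, float],
    prev_interval: tuple[float, float] | None = None,
    next_interval: tuple[float, float] | None = None,
) -> tuple[list[str], list[str]]:
    """Sort a bin's markers by cM and flag discordant ones.

    A marker is discordant when its cM position falls outside the interval
    spanned by the bin's remaining markers *and* inside a neighbouring bin's
    cM interval — i.e. the genetic map places it in the adjacent bin.
    Returns (ordered concordant ids, discordant ids); together they
    partition the input.
    """
    ids = list(markers_cm)
    discordant: list[str] = []
    if len(ids) >= 2:
        for m in ids:
            rest = [markers_cm[x] for x in ids if x != m]
            lo, hi = min(rest), max(rest)
            cm = markers_cm[m]
            if lo <= cm <= hi:
                continue
            for iv in (prev_interval, next_interval):
                if iv is not None and iv[0] <= cm <= iv[1]:
                    discordant.append(m)
                    break
    ordered = sorted(
        (m for m in ids if m not in discordant), key=lambda m: markers_cm[m]
    )
    return ordered, discordant


# ---------------------------------------------------------------------------
# bin map container
# ---------------------------------------------------------------------------

class BinMap:
    """Assayed bins + pericentromeric composites with per-bin marker sets."""

    def __init__(
        self,
        bins: list[DeletionBin],
        markers: Mapping[str, list[str]],          # bin label -> marker ids
        marker_types: Mapping[str, str],           # marker id -> rjm | gene
        chromosome_totals: Mapping[str, Mapping[str, int]],  # chrom -> type -> n
    ):
        self.bins = list(bins)
        self.markers = {k: list(v) for k, v in markers.items()}
        self.marker_types = dict(marker_types)
        self.chromosome_totals = {c: dict(t) for c, t in chromosome_totals.items()}
        seen: set[str] = set()
        for label, ms in self.markers.items():
            dup = seen.intersection(ms)
            if dup:
                raise ValueError(f"markers in more than one bin: {sorted(dup)[:5]}")
            seen.update(ms)

    def bin_count(self, label: str, probe_type: str | None = None) -> int:
        ms = self.markers.get(label, [])
        if probe_type is None:
            return len(ms)
        return sum(1 for m in ms if self.marker_types.get(m) == probe_type)

    def pericentromeric_count(self, chromosome: str, probe_type: str) -> int:
        total = self.chromosome_totals.get(chromosome, {}).get(probe_type, 0)
        assayed = sum(
            self.bin_count(b.label, probe_type)
            for b in self.bins
            if b.chromosome == chromosome and b.kind != PERICENTROMERIC_KIND
        )
        return pericentromeric_by_subtraction(total, [assayed])

    def summary(self) -> pd.DataFrame:
        rows = []
        for b in self.bins:
            if b.kind == PERICENTROMERIC_KIND:
                n_rjm = self.pericentromeric_count(b.chromosome, "rjm")
                n_gene = self.pericentromeric_count(b.chromosome, "gene")
            else:
                n_rjm = self.bin_count(b.label, "rjm")
                n_gene = self.bin_count(b.label, "gene")
            rows.append(
                (b.label, b.chromosome, b.arm, b.kind, b.fl_interval[0],
                 b.fl_interval[1], b.physical_length_mb, n_gene, n_rjm)
            )
        return pd.DataFrame(
            rows,
            columns=["label", "chromosome", "arm", "kind", "fl_lo", "fl_hi",
                     "length_mb", "n_gene", "n_rjm"],
        )


def bins_from_breakpoints(
    breakpoints: Mapping[str, Mapping[str, Sequence[float]]],
    arm_lengths_mb: Mapping[tuple[str, str], float],
    chromosome_lengths_mb: Mapping[str, float] | None = None,
) -> list[DeletionBin]:
    """Assayed bins between consecutive breakpoints plus terminal bins.

    The proximal region (0, b_min] of each arm is not assayed by any line
    and is folded into the chromosome's pericentromeric composite, whose
    physical length is the chromosome length minus the assayed bins (when
    chromosome lengths are supplied).
    """
    from .cgh import bin_label

    out: list[DeletionBin] = []
    for chrom, arms in breakpoints.items():
        assayed = 0.0
        for arm, bps in arms.items():
            bps = sorted(float(b) for b in bps)
            arm_len = arm_lengths_mb[(chrom, arm)]
            edges = bps + [1.0]
            for lo, hi in zip(edges[:-1], edges[1:]):
                if lo == hi:
                    continue
                kind = TERMINAL if hi == 1.0 else INTERSTITIAL
                length = estimate_bin_length(arm_len, (lo, hi))
                assayed += length
                out.append(
                    DeletionBin(chrom, arm, (lo, hi), length, kind,
                                bin_label(chrom, arm, lo, hi))
                )
        if chromosome_lengths_mb is not None:
            peri_len = max(chromosome_lengths_mb[chrom] - assayed, 0.0)
            out.append(
                DeletionBin(chrom, "C", (0.0, 1.0), peri_len,
                            PERICENTROMERIC_KIND, f"{chrom}-pericentromeric")
            )
    return out


def build_bin_map(
    assignments: pd.DataFrame,
    probe_types: Mapping[str, str],
    bins: list[DeletionBin],
) -> BinMap:
    """Assemble a BinMap from CGH assignments.

    *assignments* is the frame produced by :func:`rjmap.cgh.assign_probes`
    (columns chromosome, bin).  Chromosome totals count every
    chromosome-assigned probe; bin membership uses the bin column; the
    pericentromeric composites absorb the remainder by subtraction.
    """
    from .cgh import UNASSIGNED

    markers: dict[str, list[str]] = {}
    totals: dict[str, dict[str, int]] = {}
    labels = {b.label for b in bins}
    for probe_id, row in assignments.iterrows():
        chrom = row["chromosome"]
        if chrom == UNASSIGNED:
            continue
        ptype = probe_types.get(probe_id, "rjm")
        totals.setdefault(chrom, {}).setdefault(ptype, 0)
        totals[chrom][ptype] += 1
        label = row["bin"]
        if label in labels:
            markers.setdefault(label, []).append(probe_id)
    return BinMap(bins, markers, dict(probe_types), totals)


def true_bin_of(
    arm: str, fl: float, arm_breakpoints: Mapping[str, Sequence[float]],
    chromosome: str,
) -> str:
    """Ground-truth bin label for a locus at (arm, FL) given the breakpoints.

    Loci proximal to every breakpoint of their arm (or on an arm with no
    deletion lines) belong to the pericentromeric composite.
    """
    from .cgh import PERICENTROMERIC, bin_label

    bps = sorted(arm_breakpoints.get(arm, []))
    if not bps or fl <= bps[0]:
        return PERICENTROMERIC
    edges = bps + [1.0]
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo < fl <= hi:
            return bin_label(chromosome, arm, lo, hi)
    raise AssertionError("unreachable: FL in (0,1]")


# ---------------------------------------------------------------------------
# ordering against a genetic map
# ---------------------------------------------------------------------------

def order_bins_along_chromosome(bins: Sequence[DeletionBin]) -> list[DeletionBin]:
    """Bins in physical order: S telomere -> centromere -> L telomere."""
    s = sorted((b for b in bins if b.arm == "S"), key=lambda b: -b.fl_interval[0])
    c = [b for b in bins if b.arm == "C"]
    l = sorted((b for b in bins if b.arm == "L"), key=lambda b: b.fl_interval[0])
    return s + c + l


def order_within_bins(
    binmap: BinMap, genetic_map: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-bin marker order from the genetic map, with discordance flags.

    Returns (ordered, bin_stats): *ordered* has one row per mapped marker
    (marker, bin, chromosome, cm, discordant); *bin_stats* one row per bin
    with its concordant marker count and cM span.  Also provides the data
    for a genetic-vs-physical dot plot (bin physical midpoints).
    """
    cm_of = dict(zip(genetic_map["marker"], genetic_map["cm"]))
    rows = []
    stat_rows = []
    by_chrom: dict[str, list[DeletionBin]] = {}
    for b in binmap.bins:
        by_chrom.setdefault(b.chromosome, []).append(b)
    for chrom, bins in by_chrom.items():
        ordered_bins = order_bins_along_chromosome(bins)
        intervals: list[tuple[float, float] | None] = []
        mapped: list[dict[str, float]] = []
        for b in ordered_bins:
            ms = {
                m: float(cm_of[m])
                for m in binmap.markers.get(b.label, [])
                if m in cm_of
            }
            mapped.append(ms)
            intervals.append((min(ms.values()), max(ms.values())) if ms else None)
        offset = 0.0
        for i, b in enumerate(ordered_bins):
            prev_iv = intervals[i - 1] if i > 0 else None
            next_iv = intervals[i + 1] if i + 1 < len(ordered_bins) else None
            ordered, discordant = order_markers_in_bin(mapped[i], prev_iv, next_iv)
            midpoint_mb = offset + b.physical_length_mb / 2.0
            offset += b.physical_length_mb
            for m in ordered:
                rows.append((m, b.label, chrom, mapped[i][m], False, midpoint_mb))
            for m in discordant:
                rows.append((m, b.label, chrom, mapped[i][m], True, midpoint_mb))
            stat_rows.append(
                (b.label, chrom, len(ordered), len(discordant),
                 bin_genetic_length([mapped[i][m] for m in ordered]) if ordered else 0.0,
                 b.physical_length_mb)
            )
    ordered_df = pd.DataFrame(
        rows, columns=["marker", "bin", "chromosome", "cm", "discordant",
                       "bin_midpoint_mb"],
    )
    stats_df = pd.DataFrame(
        stat_rows, columns=["bin", "chromosome", "n_ordered", "n_discordant",
                            "genetic_span_cm", "length_mb"],
    )
    return ordered_df, stats_df


# ---------------------------------------------------------------------------
# report arithmetic
# ---------------------------------------------------------------------------

def summarize_chromosomes(table: pd.DataFrame) -> dict[str, float]:
    """Whole-genome accounting from a per-chromosome count table.

    *table* needs columns ``rjm``, ``gene_probes``, ``unique_genes`` and
    ``size_mb`` (one row per chromosome).  Returns probe totals, the
    marker total (RJMs + unique genes) and its genome-wide density.
    """
    for col in ("rjm", "gene_probes", "unique_genes", "size_mb"):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    rjm = int(table["rjm"].sum())
    gene_probes = int(table["gene_probes"].sum())
    unique_genes = int(table["unique_genes"].sum())
    total_probes = rjm + gene_probes
    total_markers = rjm + unique_genes
    size = float(table["size_mb"].sum())
    per_mb, kb_per = marker_density(total_markers, size)
    return {
        "rjm_total": rjm,
        "gene_probe_total": gene_probes,
        "unique_gene_total": unique_genes,
        "probes_assigned": total_probes,
        "markers_assigned": total_markers,
        "size_mb": size,
        "markers_per_mb": per_mb,
        "kb_per_marker": kb_per,
    }


def bin_mapping_summary(
    gene_probes_on_chromosomes: int,
    rjm_on_chromosomes: int,
    gene_probes_in_bins: int,
    rjm_in_bins: int,
    unique_gene_markers_in_bins: int,
    n_bins: int,
) -> dict[str, float]:
    """Accounting of the deletion-bin stage relative to the chromosome stage."""
    probes_in_bins = gene_probes_in_bins + rjm_in_bins
    unique_loci = unique_gene_markers_in_bins + rjm_in_bins
    return {
        "gene_probes_unbinned": gene_probes_on_chromosomes - gene_probes_in_bins,
        "pct_gene_probes_binned": 100.0 * gene_probes_in_bins / gene_probes_on_chromosomes,
        "pct_rjm_binned": 100.0 * rjm_in_bins / rjm_on_chromosomes,
        "probes_in_bins": probes_in_bins,
        "unique_loci_in_bins": unique_loci,
        "mean_loci_per_bin": unique_loci / n_bins,
    }
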