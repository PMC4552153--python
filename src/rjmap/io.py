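"""Readers and writers for the pipeline's file formats.

FASTA/FASTQ go through Biopython; tables are tab-separated with explicit,
schema-checked column sets; genomic features are emitted as 0-based
half-open BED.  Sequences are normalized to upper case on read.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .probedesign import FILTERS, Probe, ProbeSet
from .synthdata import (
    GenomeModel,
    Line,
    LinePanel,
    Read,
    ReadSet,
    RepeatElement,
    RepeatJunctionTruth,
    RepeatLibrary,
    SignalMatrix,
)

FASTA_WRAP = 80


class SchemaError(ValueError):
    """A table is missing required columns."""


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """(id, uppercase sequence) pairs; raises on malformed records."""
    out = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            out.append((rec.id, str(rec.seq).upper()))
    return out


def write_fasta(path, records: Iterable[tuple[str, str]],
                descriptions: Mapping[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    recs = [
        SeqRecord(Seq(seq), id=rid, description=descriptions.get(rid, ""))
        for rid, seq in records
    ]
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=FASTA_WRAP).write_file(recs)


def write_fastq(path, reads: ReadSet, quality: int = 40) -> None:
    """Reads as FASTQ with a flat dummy quality."""
    with open(path, "w") as fh:
        for r in reads.reads:
            rec = SeqRecord(
                Seq(r.sequence), id=r.id,
                description=f"{r.chromosome}:{r.start}:{r.strand}",
            )
            rec.letter_annotations["phred_quality"] = [quality] * len(r.sequence)
            SeqIO.write(rec, fh, "fastq")


def read_reads(path) -> ReadSet:
    """Reads back from FASTA or FASTQ (origin parsed from the description)."""
    fmt = "fastq" if str(path).endswith((".fastq", ".fq")) else "fasta"
    reads = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            parts = rec.description.split()
            chrom, start, strand = "", 0, "+"
            if len(parts) > 1 and parts[-1].count(":") == 2:
                chrom, s, strand = parts[-1].rsplit(":", 2)
                start = int(s)
            reads.append(Read(rec.id, str(rec.seq).upper(), chrom, start, strand))
    return ReadSet(reads, nominal_coverage=0.0)


def write_library_fasta(path, library: RepeatLibrary) -> None:
    write_fasta(
        path,
        [(el.id, el.sequence) for el in library],
        descriptions={el.id: f"class={el.repeat_class}" for el in library},
    )


def read_library_fasta(path) -> RepeatLibrary:
    elements = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            cls = None
            for token in rec.description.split():
                if token.startswith("class="):
                    cls = token[6:]
            if cls is None:
                raise ValueError(f"element {rec.id}: description lacks class=...")
            elements.append(RepeatElement(rec.id, cls, str(rec.seq).upper()))
    return RepeatLibrary(elements)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def write_genome(prefix: Path, genome: GenomeModel) -> None:
    """genome.fasta + genome_meta.json + truth/TE BED + genes.fasta."""
    prefix = Path(prefix)
    write_fasta(prefix / "genome.fasta",
                [(name, seq) for name, _, seq in genome.chromosomes])
    meta = {
        "chromosomes": [
            {"name": name, "arm_fraction": af, "length": len(seq)}
            for name, af, seq in genome.chromosomes
        ],
        "n_nested": genome.n_nested,
    }
    (prefix / "genome_meta.json").write_text(json.dumps(meta, indent=1))
    write_junction_bed(prefix / "truth_junctions.bed", genome.junction_truth)
    with open(prefix / "te_insertions.bed", "w") as fh:
        for chrom, start, el_id, strand in genome.te_insertions:
            fh.write(f"{chrom}\t{start}\t{start + 1}\t{el_id}\t0\t{strand}\n")
    write_fasta(
        prefix / "genes.fasta",
        [(gid, genome.sequences[chrom][a:b]) for chrom, (a, b), gid in genome.genes],
    )


def read_genome(prefix: Path) -> GenomeModel:
    """Rebuild a GenomeModel (sequence + arm splits + truth) from disk."""
    prefix = Path(prefix)
    meta = json.loads((prefix / "genome_meta.json").read_text())
    seqs = dict(read_fasta(prefix / "genome.fasta"))
    chromosomes = [
        (c["name"], c["arm_fraction"], seqs[c["name"]]) for c in meta["chromosomes"]
    ]
    truth = []
    bed = prefix / "truth_junctions.bed"
    if bed.exists():
        for line in bed.read_text().splitlines():
            chrom, start, _end, name = line.split("\t")[:4]
            left, right = name.split("|")
            truth.append(RepeatJunctionTruth(chrom, int(start) + 1, left, right))
    return GenomeModel(chromosomes, [], [], truth,
                       n_nested=meta.get("n_nested", 0))


def write_junction_bed(path, junctions: Iterable[RepeatJunctionTruth]) -> None:
    """Truth junction at position p -> BED interval [p-1, p+1) flanking it."""
    with open(path, "w") as fh:
        for j in junctions:
            fh.write(
                f"{j.chromosome}\t{j.position - 1}\t{j.position + 1}"
                f"\t{j.left_class}|{j.right_class}\n"
            )


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

PANEL_COLUMNS = ["name", "kind", "chromosome", "arm", "breakpoint_FL"]


def write_panel_tsv(path, panel: LinePanel) -> None:
    rows = [
        (l.name, l.kind, l.chromosome, l.arm,
         "" if l.breakpoint_fl is None else l.breakpoint_fl)
        for l in panel.lines
    ]
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_panel_tsv(path) -> LinePanel:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "arm": str})
    _require_columns(df, PANEL_COLUMNS, "line panel")
    lines = []
    for _, r in df.iterrows():
        b = r["breakpoint_FL"]
        lines.append(
            Line(
                str(r["name"]), str(r["kind"]),
                "" if pd.isna(r["chromosome"]) else str(r["chromosome"]),
                "" if pd.isna(r["arm"]) else str(r["arm"]),
                None if pd.isna(b) else float(b),
            )
        )
    return LinePanel(lines)


def write_signals_tsv(path, matrix: SignalMatrix) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="probe_id")


def read_signals_tsv(path) -> SignalMatrix:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    for c in df.columns:
        SignalMatrix.parse_column(c)  # validates the line.array.spot.channel scheme
    sm = SignalMatrix(df)
    have = {SignalMatrix.parse_column(c)[:3] for c in df.columns}
    for line, a, s, channel in (SignalMatrix.parse_column(c) for c in df.columns):
        other = "ref" if channel == "test" else "test"
        if f"{line}.{a}.{s}.{other}" not in df.columns:
            raise SchemaError(f"signal matrix: {line}.{a}.{s} lacks the {other} channel")
    return sm


PROBE_COLUMNS = ["probe_id", "probe_type", "sequence", "source_id",
                 "source_start", "gc_percent", "tm_celsius", "selected",
                 *FILTERS]


def write_probes_tsv(path, probeset: ProbeSet) -> None:
    rows = []
    for p in probeset.probes:
        rows.append(
            (p.id, p.probe_type, p.sequence, p.source[0], p.source[1],
             round(p.gc_percent, 2), round(p.tm_celsius, 2), p.selected,
             *[p.verdicts[f] for f in FILTERS])
        )
    pd.DataFrame(rows, columns=PROBE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_probes_tsv(path) -> ProbeSet:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, PROBE_COLUMNS, "probe table")
    probes = []
    for _, r in df.iterrows():
        p = Probe.build(str(r["probe_id"]), str(r["sequence"]),
                        str(r["probe_type"]),
                        (str(r["source_id"]), int(r["source_start"])))
        for f in FILTERS:
            p.verdicts[f] = str(r[f])
        probes.append(p)
    acc = {"candidates": len(probes),
           "selected": sum(1 for p in probes if p.selected)}
    return ProbeSet(probes, acc)


def write_accounting_tsv(path, accounting: Mapping[str, int]) -> None:
    pd.DataFrame(
        sorted(accounting.items()), columns=["stage", "count"]
    ).to_csv(path, sep="\t", index=False)


ASSIGNMENT_COLUMNS = ["probe_id", "chromosome", "bin", "stringency_level",
                      "loss_fraction", "p_value"]


def write_assignments_tsv(path, assignments: pd.DataFrame) -> None:
    assignments.to_csv(path, sep="\t", index_label="probe_id")


def read_assignments_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ASSIGNMENT_COLUMNS, "assignment table")
    return df.set_index("probe_id")


def write_concordance_tsv(path, results: Mapping[str, tuple[int, int, float]]) -> None:
    """Concordance report: one row per comparison (level -> n, agree, %)."""
    rows = [
        (level, n, agree, round(pct, 2))
        for level, (n, agree, pct) in results.items()
    ]
    pd.DataFrame(
        rows, columns=["level", "n_compared", "n_agree", "percent"]
    ).to_csv(path, sep="\t", index=False)


GENETIC_MAP_COLUMNS = ["marker", "chromosome", "cm"]


def read_genetic_map_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, GENETIC_MAP_COLUMNS, "genetic map")
    if (df["cm"] < 0).any():
        raise ValueError("genetic map: negative cM positions")
    return df


def write_genetic_map_tsv(path, gmap: pd.DataFrame) -> None:
    _require_columns(gmap, GENETIC_MAP_COLUMNS, "genetic map")
    gmap.to_csv(path, sep="\t", index=False)


def write_manifest(path, command: str, parameters: Mapping, inputs: Sequence[str],
                   outputs: Sequence[str], seed: int | None) -> None:
    """Reproducibility manifest; deliberately timestamp-free so identical
    runs produce byte-identical output trees."""
    from . import __version__

    manifest = {
        "command": command,
        "package_version": __version__,
        "seed": seed,
        "parameters": parameters,
        # basenames only: identical runs into different directories must
        # produce byte-identical manifests
        "inputs": sorted(Path(p).name for p in inputs if str(p)),
        "outputs": sorted(Path(p).name for p in outputs if str(p)),
    }
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
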