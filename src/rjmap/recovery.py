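"""Parameter-recovery experiments on fully synthetic panels.

The headline mapping experiment (tens of thousands of probes hybridized to
real aneuploid stocks) cannot be reproduced computationally, so the
package's accuracy claim is a recovery experiment: simulate a genome whose
probe locations are known, push hybridization signals through the exact
assignment pipeline, and score the chromosome and bin calls against truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from . import binmap as bm
from . import cgh
from . import synthdata as sd

#: deletion-line breakpoints emulating a multi-chromosome bin framework
#: (twelve lines across seven chromosomes)
DEFAULT_DELETIONS: dict[str, dict[str, list[float]]] = {
    "1D": {"S": [0.5], "L": [0.3, 0.7]},
    "2D": {"L": [0.4, 0.75]},
    "3D": {"S": [0.6]},
    "4D": {"L": [0.5]},
    "5D": {"S": [0.4, 0.7]},
    "6D": {"L": [0.35]},
    "7D": {"S": [0.55], "L": [0.6]},
}


@dataclass
class RecoveryResult:
    n_probes: int
    chromosome_recovery_pct: float
    bin_recovery_pct: float
    n_chromosome_assigned: int
    n_bin_assigned: int


def run_recovery(
    lognormal_sd: float,
    dropout_rate: float,
    n_chromosomes: int = 7,
    chrom_length: int = 1_000_000,
    te_count: int = 300,
    gene_count: int = 500,
    deletions: Mapping[str, Mapping[str, list[float]]] | None = None,
    n_probes: int | None = 2000,
    cross_hyb: float = 0.3,
    seed: int = 0,
) -> RecoveryResult:
    """Simulate, assign, and score one recovery experiment.

    Array content comes straight from genome truth (junction-centred 52-mers
    plus gene probes), bypassing the read pipeline: this experiment isolates
    the signal-analysis stage.  Chromosome recovery is the fraction of
    probes whose assigned chromosome equals truth; bin recovery additionally
    requires the assigned bin to be the one containing the probe's true
    fraction-length position (or the pericentromeric inference for proximal
    loci).
    """
    deletions = dict(deletions if deletions is not None else DEFAULT_DELETIONS)
    library = sd.build_repeat_library(6, 4, (300, 900), seed=seed)
    chrom_names = [f"{i}D" for i in range(1, n_chromosomes + 1)]
    genome = sd.simulate_genome(
        library,
        [(c, chrom_length, 0.45) for c in chrom_names],
        te_count=te_count,
        nesting_prob=0.2,
        gene_count=gene_count,
        seed=seed + 1,
    )
    deletions = {c: a for c, a in deletions.items() if c in genome.sequences}
    panel = sd.build_line_panel(genome, deletions)
    probes = sd.probes_from_truth(genome, seed=seed + 2)
    if n_probes is not None:
        probes = probes[:n_probes]
    model = sd.SignalModel(
        lognormal_sd=lognormal_sd,
        dropout_rate=dropout_rate,
        cross_hyb=cross_hyb,
        seed=seed + 3,
    )
    matrix = sd.simulate_hybridization(panel, probes, genome, model)
    result = cgh.assign_probes(matrix, panel)

    ok_chrom = ok_bin = 0
    for p in probes:
        chrom, start = p.genome_coords[0]
        arm, fl = genome.arm_position(chrom, start + len(p.sequence) // 2)
        row = result.loc[p.id]
        if row["chromosome"] == chrom:
            ok_chrom += 1
            if row["bin"] == bm.true_bin_of(arm, fl, deletions.get(chrom, {}), chrom):
                ok_bin += 1
    n = len(probes)
    return RecoveryResult(
        n_probes=n,
        chromosome_recovery_pct=100.0 * ok_chrom / n,
        bin_recovery_pct=100.0 * ok_bin / n,
        n_chromosome_assigned=int((result["chromosome"] != cgh.UNASSIGNED).sum()),
        n_bin_assigned=int(
            result["bin"].isin(
                [b for b in result["bin"].unique()
                 if b not in (cgh.UNASSIGNED, cgh.PERICENTROMERIC)]
            ).sum()
        ),
    )
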