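"""Published wheat D-genome deletion-bin reference data.

These tables transcribe the published Chinese Spring / *Aegilops tauschii*
D-genome marker resource: the NimbleGen array content, the per-chromosome
marker counts from the nullisomic-tetrasomic assignment, and the deletion
bin framework (fraction-length intervals, cytogenetically estimated bin
sizes, and per-bin marker counts).  They serve two purposes: they are the
worked-example inputs for the report arithmetic (totals, percentages,
pericentromeric subtraction, densities), and they provide a realistic bin
framework for configuring simulations.

A few cells of the published tables are internally inconsistent (the 4D
pericentromeric gene count and the 7D pericentromeric RJM count do not
equal the subtraction of their bin rows from the chromosome totals); the
printed values are kept verbatim here and flagged in ``INCONSISTENT_CELLS``.
"""

from __future__ import annotations

import pandas as pd

#: probes fabricated on the mapping array
ARRAY_CONTENT = {
    "rjm_probes": 31205,
    "gene_probes": 15016,
    "genes_represented": 6348,
}

#: per-chromosome counts from the nullisomic-tetrasomic assignment
#: columns: chromosome size (Mb), RJM probes, gene probes, unique genes
_CHROM_ROWS = [
    ("1D", 604, 3921, 1561, 743),
    ("2D", 727, 4146, 1923, 923),
    ("3D", 770, 4453, 2153, 1031),
    ("4D", 648, 4366, 1412, 672),
    ("5D", 748, 4491, 2062, 982),
    ("6D", 712, 3551, 1298, 618),
    ("7D", 727, 4265, 2008, 956),
]

CHROMOSOME_TABLE = pd.DataFrame(
    _CHROM_ROWS,
    columns=["chromosome", "size_mb", "rjm", "gene_probes", "unique_genes"],
).set_index("chromosome")

#: estimated D-genome size used for the genome-wide density figure (Mb)
D_GENOME_SIZE_MB = 4900.0

#: published estimate range for the whole D genome (Mb)
D_GENOME_SIZE_RANGE_MB = (4020.0, 4950.0)

#: deletion-bin framework: label, chromosome, arm, FL interval, kind,
#: estimated length (Mb), unique gene markers, RJMs
_BIN_ROWS = [
    ("1DS5-0.70-1.00", "1D", "S", 0.70, 1.00, "terminal", 67.20, 98, 67),
    ("1DS1-0.59-0.70", "1D", "S", 0.59, 0.70, "interstitial", 24.64, 47, 113),
    ("1DL4-0.18-0.41", "1D", "L", 0.18, 0.41, "interstitial", 87.63, 174, 273),
    ("1DL2-0.41-1.00", "1D", "L", 0.41, 1.00, "terminal", 224.79, 366, 247),
    ("2DS5-0.47-1.00", "2D", "S", 0.47, 1.00, "terminal", 167.48, 82, 96),
    ("2DS1-0.33-0.47", "2D", "S", 0.33, 0.47, "interstitial", 44.24, 286, 203),
    ("2DL3-0.49-0.76", "2D", "L", 0.49, 0.76, "interstitial", 110.97, 259, 139),
    ("2DL9-0.76-1.00", "2D", "L", 0.76, 1.00, "terminal", 98.64, 231, 75),
    ("3DS6-0.55-1.00", "3D", "S", 0.55, 1.00, "terminal", 144.45, 240, 246),
    ("3DS3-0.24-0.55", "3D", "S", 0.24, 0.55, "interstitial", 99.51, 130, 146),
    ("3DL2-0.27-0.81", "3D", "L", 0.27, 0.81, "interstitial", 242.46, 301, 216),
    ("3DL3-0.81-1.00", "3D", "L", 0.81, 1.00, "terminal", 85.31, 152, 149),
    ("4DS2-0.81-1.00", "4D", "S", 0.81, 1.00, "terminal", 43.89, 105, 115),
    ("4DS3-0.67-0.81", "4D", "S", 0.67, 0.81, "interstitial", 32.34, 69, 117),
    ("4DS1-0.53-0.67", "4D", "S", 0.53, 0.67, "interstitial", 32.34, 78, 113),
    ("4DL9-0.31-0.56", "4D", "L", 0.31, 0.56, "interstitial", 104.00, 16, 59),
    ("4DL13-0.56-0.71", "4D", "L", 0.56, 0.71, "interstitial", 62.41, 71, 191),
    ("4DL12-0.71-1.00", "4D", "L", 0.71, 1.00, "terminal", 120.64, 116, 93),
    ("5DS2-0.78-1.00", "5D", "S", 0.78, 1.00, "terminal", 56.76, 116, 212),
    ("5DS5-0.67-0.78", "5D", "S", 0.67, 0.78, "interstitial", 28.38, 136, 120),
    ("5DS1-0.63-0.67", "5D", "S", 0.63, 0.67, "interstitial", 10.32, 74, 234),
    ("5DL1-0.60-0.74", "5D", "L", 0.60, 0.74, "interstitial", 68.60, 99, 116),
    ("5DL9-0.74-0.76", "5D", "L", 0.74, 0.76, "interstitial", 9.80, 9, 17),
    ("5DL5-0.76-1.00", "5D", "L", 0.76, 1.00, "terminal", 117.62, 266, 283),
    ("6DS6-0.99-1.00", "6D", "S", 0.99, 1.00, "terminal", 3.24, 62, 51),
    ("6DS4-0.79-0.99", "6D", "S", 0.79, 0.99, "interstitial", 64.80, 41, 58),
    ("6DS2-0.45-0.79", "6D", "S", 0.45, 0.79, "interstitial", 110.16, 115, 135),
    ("6DL6-0.29-0.47", "6D", "L", 0.29, 0.47, "interstitial", 70.02, 139, 158),
    ("6DL1-0.47-0.68", "6D", "L", 0.47, 0.68, "interstitial", 81.69, 36, 18),
    ("6DL12-0.68-0.74", "6D", "L", 0.68, 0.74, "interstitial", 23.34, 38, 68),
    ("6DL11-0.74-0.80", "6D", "L", 0.74, 0.80, "interstitial", 23.34, 168, 206),
    ("7DS4-0.61-1.00", "7D", "S", 0.61, 1.00, "terminal", 148.59, 285, 255),
    ("7DS5-0.36-0.61", "7D", "S", 0.36, 0.61, "interstitial", 95.25, 159, 125),
    ("7DL5-0.30-0.61", "7D", "L", 0.30, 0.61, "interstitial", 107.26, 125, 171),
    ("7DL2-0.61-0.82", "7D", "L", 0.61, 0.82, "interstitial", 72.66, 131, 129),
    ("7DL3-0.82-1.00", "7D", "L", 0.82, 1.00, "terminal", 62.28, 150, 157),
]

BIN_TABLE = pd.DataFrame(
    _BIN_ROWS,
    columns=["label", "chromosome", "arm", "fl_lo", "fl_hi", "kind",
             "length_mb", "gene_markers", "rjm"],
).set_index("label")

#: published pericentromeric composite cells: length (Mb), gene markers, RJMs
PERICENTROMERIC_TABLE = pd.DataFrame(
    [
        ("1D", 200.74, 58, 3221),
        ("2D", 305.67, 65, 3633),
        ("3D", 198.27, 208, 3696),
        ("4D", 251.39, 117, 3678),
        ("5D", 456.54, 282, 3509),
        ("6D", 258.61, 19, 2857),
        ("7D", 240.96, 106, 3394),
    ],
    columns=["chromosome", "length_mb", "gene_markers", "rjm"],
).set_index("chromosome")

#: pericentromeric cells whose printed value does not equal the subtraction
#: of the bin rows from the chromosome total
INCONSISTENT_CELLS = (("4D", "gene_markers"), ("7D", "rjm"))

#: deletion-bin stage totals as published
BIN_STAGE = {
    "gene_probes_in_bins": 10892,
    "rjm_in_bins": 5171,
    "unique_gene_markers_in_bins": 5070,
    "n_bins": 40,
    "assayed_mb": 2500.0,
}

#: cytogenetic arm lengths (Mb) consistent with the 1D bin sizes
ARM_LENGTHS_MB = {("1D", "S"): 224.0, ("1D", "L"): 381.0}


def chromosome_total(chromosome: str, probe_type: str) -> int:
    """Nulli-stage total for one chromosome: RJM probes or unique genes."""
    col = "rjm" if probe_type == "rjm" else "unique_genes"
    return int(CHROMOSOME_TABLE.loc[chromosome, col])


def bin_counts(chromosome: str, probe_type: str) -> list[int]:
    """Per-bin published counts for one chromosome (assayed bins only)."""
    col = "rjm" if probe_type == "rjm" else "gene_markers"
    sub = BIN_TABLE[BIN_TABLE["chromosome"] == chromosome]
    return [int(v) for v in sub[col]]
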