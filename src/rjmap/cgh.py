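"""Comparative-hybridization signal analysis: normalization, loss calling,
stringency ladder, chromosome/bin assignment and concordance.

The analysis contract mirrors a two-channel aneuploid mapping experiment:

* intensities are quantile normalized across arrays (every column ends up
  with the identical sorted value vector; a median-scaling alternative is
  available behind a switch),
* each spot's test-channel value is divided by its same-spot reference
  value, and ratios are normalized by the control line's median ratio,
* per line, spot-level ratios are compared to the control line's ratios
  with a two-sided pooled-variance Student's t-test; a probe is *flagged*
  in a line when the signal loss (1 - mean(test)/mean(ref)) reaches the
  active threshold and p < alpha,
* a stringency ladder evaluates thresholds from strict (50% loss) to
  lenient (20%): the first level at which a probe shows a clean pattern —
  exactly one nullisomic line flagged and a monotone deletion-line prefix —
  fixes its chromosome, deletion bin and stringency level.

A probe flagged distal to every breakpoint of an arm lands in the terminal
bin; one flagged in no deletion line is placed in the pericentromeric
composite by inference; non-monotone or cross-arm patterns stay unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthdata import LinePanel, SignalMatrix

DEFAULT_THRESHOLDS = (0.5, 0.4, 0.3, 0.2)

PERICENTROMERIC = "pericentromeric-inferred"
UNASSIGNED = "unassigned"

#: reference-channel spots below this fraction of the probe's median
#: reference intensity are masked as dropouts before ratios are formed
REF_FLOOR_FRACTION = 0.05


@dataclass
class LossTestResult:
    probe_id: str
    line: str
    loss_fraction: float
    p_value: float
    flagged: bool


@dataclass
class Assignment:
    probe_id: str
    chromosome: str = UNASSIGNED
    bin_label: str = UNASSIGNED
    stringency_level: float = float("nan")
    loss_fraction: float = float("nan")
    p_value: float = float("nan")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: SignalMatrix | pd.DataFrame) -> SignalMatrix | pd.DataFrame:
    """Full quantile normalization (rank mean) across columns.

    After normalization every column shares the identical sorted value
    vector: the per-rank mean of the input columns.  Tied entries receive
    the mean of their tied ranks' reference values (average-rank rule).
    """
    df = matrix.data if isinstance(matrix, SignalMatrix) else matrix
    if df.shape[1] < 2:
        raise ValueError("need at least two columns to normalize")
    if (df.values < 0).any():
        raise ValueError("negative intensities")
    n = df.shape[0]
    ref = np.sort(df.values, axis=0).mean(axis=1)
    ranks = df.rank(method="average").values
    out = np.interp(ranks, np.arange(1, n + 1), ref)
    res = pd.DataFrame(out, index=df.index, columns=df.columns)
    return SignalMatrix(res) if isinstance(matrix, SignalMatrix) else res


def median_scale(matrix: SignalMatrix | pd.DataFrame) -> SignalMatrix | pd.DataFrame:
    """Alternative normalization: scale each column to the global median."""
    df = matrix.data if isinstance(matrix, SignalMatrix) else matrix
    med = df.median(axis=0)
    target = float(np.median(df.values))
    res = df / med * target
    return SignalMatrix(res) if isinstance(matrix, SignalMatrix) else res


def average_replicates(matrix: SignalMatrix | pd.DataFrame) -> pd.DataFrame:
    """Spot-replicate means per (probe, line, array, channel), NaN-tolerant.

    Returns a tidy frame with one row per (line, array, channel) group and
    one column per probe; spot-level values remain in the input matrix for
    the t-test, this is the reporting/averaging view.
    """
    df = matrix.data if isinstance(matrix, SignalMatrix) else matrix
    meta = [SignalMatrix.parse_column(c) for c in df.columns]
    groups: dict[tuple[str, int, str], list[str]] = {}
    for col, (line, a, s, channel) in zip(df.columns, meta):
        groups.setdefault((line, a, channel), []).append(col)
    lines_seen = {line for line, _, _ in groups}
    for line in lines_seen:
        channels = {ch for (l, _, ch) in groups if l == line}
        if channels != {"test", "ref"}:
            raise ValueError(f"line {line!r} is missing a channel")
    rows = []
    idx = []
    for (line, a, channel), cols in groups.items():
        rows.append(np.nanmean(df[cols].values, axis=1))
        idx.append((line, a, channel))
    out = pd.DataFrame(
        rows, columns=df.index,
        index=pd.MultiIndex.from_tuples(idx, names=["line", "array", "channel"]),
    )
    return out.sort_index()


# ---------------------------------------------------------------------------
# ratios and loss testing
# ---------------------------------------------------------------------------

def spot_ratios(
    matrix: SignalMatrix | pd.DataFrame,
    panel: LinePanel,
    ref_floor_frac: float = REF_FLOOR_FRACTION,
) -> pd.DataFrame:
    """Per-spot test/reference ratios, normalized by the control line.

    Reference-channel dropouts (values below ``ref_floor_frac`` of the
    probe's median reference intensity) are masked to NaN: the reference
    genome carries every locus, so a near-background reference spot can only
    be a failed measurement, and leaving it in would corrupt the ratio mean.
    Columns are a MultiIndex (line, array, spot).
    """
    df = matrix.data if isinstance(matrix, SignalMatrix) else matrix
    test_cols: dict[tuple[str, int, int], str] = {}
    ref_cols: dict[tuple[str, int, int], str] = {}
    for c in df.columns:
        line, a, s, channel = SignalMatrix.parse_column(c)
        (test_cols if channel == "test" else ref_cols)[(line, a, s)] = c
    if set(test_cols) != set(ref_cols):
        raise ValueError("every (line, array, spot) needs both channels")
    keys = sorted(test_cols)
    ref = df[[ref_cols[k] for k in keys]].values.astype(float)
    test = df[[test_cols[k] for k in keys]].values.astype(float)
    if ref_floor_frac > 0:
        floor = np.nanmedian(ref, axis=1, keepdims=True) * ref_floor_frac
        ref = np.where(ref < floor, np.nan, ref)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = test / ref
    out = pd.DataFrame(
        ratios, index=df.index,
        columns=pd.MultiIndex.from_tuples(keys, names=["line", "array", "spot"]),
    )
    ctrl = out[panel.control.name]
    ctrl_med = np.nanmedian(ctrl.values, axis=1)
    ctrl_med[ctrl_med == 0] = np.nan
    return out.div(ctrl_med, axis=0)


def _pooled_t_p(m1, v1, n1, m2, v2, n2):
    """Two-sided pooled-variance t-test p-value, vectorized.

    Degenerate zero-variance comparisons resolve to p=0 when the means
    differ and p=1 when they agree (the noise-free simulation limit).
    """
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / np.maximum(df, 1)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
    zero_var = sp2 == 0
    p = np.where(zero_var & (m1 != m2), 0.0, p)
    p = np.where(zero_var & (m1 == m2), 1.0, p)
    p = np.where((n1 < 2) | (n2 < 2) | (df < 1), np.nan, p)
    return p


def loss_test(
    test_values: Sequence[float],
    ref_values: Sequence[float],
    threshold: float = 0.2,
    alpha: float = 0.05,
    probe_id: str = "",
    line: str = "",
) -> LossTestResult:
    """Loss fraction and Student's t-test for one probe in one line.

    ``loss = 1 - mean(test)/mean(ref)``; the t-test is two-sample,
    two-sided, pooled variance, on the replicate values.  NaN replicates
    (masked dropouts) are ignored.
    """
    t = np.asarray(test_values, dtype=float)
    r = np.asarray(ref_values, dtype=float)
    t = t[~np.isnan(t)]
    r = r[~np.isnan(r)]
    if len(t) < 2 or len(r) < 2:
        raise ValueError("need at least two replicate values per side")
    if r.mean() == 0:
        raise ZeroDivisionError("reference mean is zero; loss ratio undefined")
    loss = 1.0 - t.mean() / r.mean()
    p = float(
        _pooled_t_p(
            t.mean(), t.var(ddof=1), len(t), r.mean(), r.var(ddof=1), len(r)
        )
    )
    flagged = bool(loss >= threshold - 1e-12 and p < alpha)
    return LossTestResult(probe_id, line, float(loss), p, flagged)


def loss_table(
    ratios: pd.DataFrame, panel: LinePanel
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorized loss fractions and p-values, probes x non-control lines."""
    ctrl = ratios[panel.control.name].values
    m_ref = np.nanmean(ctrl, axis=1)
    v_ref = _nanvar1(ctrl)
    n_ref = np.sum(~np.isnan(ctrl), axis=1)
    losses = {}
    pvals = {}
    for line in panel.lines:
        if line.kind == "control":
            continue
        vals = ratios[line.name].values
        m = np.nanmean(vals, axis=1)
        v = _nanvar1(vals)
        n = np.sum(~np.isnan(vals), axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            losses[line.name] = 1.0 - m / m_ref
        pvals[line.name] = _pooled_t_p(m, v, n, m_ref, v_ref, n_ref)
    loss_df = pd.DataFrame(losses, index=ratios.index)
    p_df = pd.DataFrame(pvals, index=ratios.index)
    return loss_df, p_df


def _nanvar1(a: np.ndarray) -> np.ndarray:
    n = np.sum(~np.isnan(a), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.nanvar(a, axis=1) * n / np.maximum(n - 1, 1)
    return np.where(n >= 2, v, np.nan)


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

def assign_chromosome(nulli_flags: Mapping[str, bool]) -> str:
    """Chromosome of the single flagged nullisomic line, else unassigned."""
    flagged = [chrom for chrom, f in nulli_flags.items() if f]
    return flagged[0] if len(flagged) == 1 else UNASSIGNED


def bin_label(chromosome: str, arm: str, lo: float, hi: float) -> str:
    return f"{chromosome}{arm}-{lo:.2f}-{hi:.2f}"


def assign_bin(
    chromosome: str,
    deletion_flags: Mapping[tuple[str, float], bool],
) -> str:
    """Bin from the deletion-line flag pattern of one chromosome.

    A deletion line with breakpoint ``b`` on arm ``A`` flags a probe iff the
    probe lies distal to ``b`` on that arm, so on the true arm the flagged
    lines are exactly those with the smallest breakpoints.  Valid patterns:

    * flags on one arm forming an ascending prefix -> the bin bounded by the
      largest flagged and smallest unflagged breakpoints,
    * every line of an arm flagged -> the terminal bin (b_max, 1.0],
    * no line flagged anywhere -> pericentromeric (inferred),
    * anything else (cross-arm, non-monotone) -> unassigned.
    """
    by_arm: dict[str, list[tuple[float, bool]]] = {}
    for (arm, b), f in deletion_flags.items():
        by_arm.setdefault(arm, []).append((float(b), bool(f)))
    flagged_arms = [a for a, items in by_arm.items() if any(f for _, f in items)]
    if not flagged_arms:
        return PERICENTROMERIC
    if len(flagged_arms) > 1:
        return UNASSIGNED
    arm = flagged_arms[0]
    items = sorted(by_arm[arm])
    flags = [f for _, f in items]
    k = sum(flags)
    if flags != [True] * k + [False] * (len(flags) - k):
        return UNASSIGNED
    if k == len(flags):
        return bin_label(chromosome, arm, items[-1][0], 1.0)
    return bin_label(chromosome, arm, items[k - 1][0], items[k][0])


def stringency_ladder(
    loss_df: pd.DataFrame,
    p_df: pd.DataFrame,
    panel: LinePanel,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    alpha: float = 0.05,
) -> list[Assignment]:
    """Assignments at the strictest clean threshold per probe.

    A level is *clean* when exactly one nullisomic line is flagged and the
    deletion-line pattern on that chromosome is valid (a monotone prefix,
    all-flagged, or empty -> pericentromeric).  A probe whose chromosome
    call is clean at some level but whose deletion pattern never is gets a
    chromosome-only assignment at its first chromosome-clean level.
    """
    ths = list(thresholds)
    if any(b >= a for a, b in zip(ths, ths[1:])):
        raise ValueError("thresholds must be strictly decreasing")
    nulli = panel.nulli_lines
    out: list[Assignment] = []
    loss_v = loss_df.values
    p_v = p_df.values
    col_of = {c: i for i, c in enumerate(loss_df.columns)}
    nulli_cols = [(l.chromosome, col_of[l.name]) for l in nulli]
    del_cols: dict[str, list[tuple[str, float, int]]] = {}
    for l in panel.deletion_lines():
        del_cols.setdefault(l.chromosome, []).append(
            (l.arm, float(l.breakpoint_fl), col_of[l.name])
        )
    for i, probe_id in enumerate(loss_df.index):
        fallback: Assignment | None = None
        result: Assignment | None = None
        for t in ths:
            flags = {}
            for chrom, c in nulli_cols:
                flags[chrom] = bool(
                    loss_v[i, c] >= t - 1e-12 and p_v[i, c] < alpha
                )
            chrom = assign_chromosome(flags)
            if chrom == UNASSIGNED:
                continue
            nl = next(l for l in nulli if l.chromosome == chrom)
            a = Assignment(
                probe_id, chromosome=chrom, stringency_level=t,
                loss_fraction=float(loss_v[i, col_of[nl.name]]),
                p_value=float(p_v[i, col_of[nl.name]]),
            )
            dflags = {
                (arm, b): bool(loss_v[i, c] >= t - 1e-12 and p_v[i, c] < alpha)
                for arm, b, c in del_cols.get(chrom, [])
            }
            a.bin_label = assign_bin(chrom, dflags) if dflags else UNASSIGNED
            if a.bin_label != UNASSIGNED:
                result = a
                break
            if fallback is None:
                fallback = a
        out.append(result or fallback or Assignment(probe_id))
    return out


def assign_probes(
    matrix: SignalMatrix | pd.DataFrame,
    panel: LinePanel,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    alpha: float = 0.05,
    normalize: str = "median",
    ref_floor_frac: float = REF_FLOOR_FRACTION,
) -> pd.DataFrame:
    """End-to-end assignment: normalize, ratio, loss-test, ladder.

    Median scaling is the default normalization: in an aneuploid dosage
    design a sizeable fraction of probes genuinely drops to background in
    each line, and forcing identical column distributions (full quantile
    normalization) compresses exactly the losses being tested, while the
    column median — dominated by the unaffected majority — is invariant to
    them.  Pass ``normalize="quantile"`` for rank-mean normalization.

    Returns a DataFrame indexed by probe id with columns chromosome,
    bin, stringency_level, loss_fraction, p_value.
    """
    if normalize == "quantile":
        matrix = quantile_normalize(matrix)
    elif normalize == "median":
        matrix = median_scale(matrix)
    elif normalize != "none":
        raise ValueError(f"unknown normalization {normalize!r}")
    ratios = spot_ratios(matrix, panel, ref_floor_frac=ref_floor_frac)
    loss_df, p_df = loss_table(ratios, panel)
    assignments = stringency_ladder(loss_df, p_df, panel, thresholds, alpha)
    return pd.DataFrame(
        {
            "chromosome": [a.chromosome for a in assignments],
            "bin": [a.bin_label for a in assignments],
            "stringency_level": [a.stringency_level for a in assignments],
            "loss_fraction": [a.loss_fraction for a in assignments],
            "p_value": [a.p_value for a in assignments],
        },
        index=pd.Index([a.probe_id for a in assignments], name="probe_id"),
    )


# ---------------------------------------------------------------------------
# genome-specificity screen and concordance
# ---------------------------------------------------------------------------

def screen_genome_specific(
    matrix: SignalMatrix | pd.DataFrame,
    panel: LinePanel,
    alt_line: str,
    threshold: float = 0.2,
    alpha: float = 0.05,
    ref_floor_frac: float = REF_FLOOR_FRACTION,
) -> pd.Series:
    """Keep probes losing >= *threshold* signal in the alternative genome.

    A probe that keeps its signal when the whole target genome is absent is
    hybridizing to something else (homeologs, other subgenomes) and is not
    genome specific; it is dropped.
    """
    ratios = spot_ratios(matrix, panel, ref_floor_frac=ref_floor_frac)
    ctrl = ratios[panel.control.name]
    alt = ratios[alt_line]
    keep = {}
    for probe_id in ratios.index:
        res = loss_test(
            alt.loc[probe_id].values, ctrl.loc[probe_id].values,
            threshold=threshold, alpha=alpha, probe_id=probe_id, line=alt_line,
        )
        keep[probe_id] = res.flagged
    return pd.Series(keep, name="genome_specific")


def concordance(
    assignment_a: Mapping[str, str],
    assignment_b: Mapping[str, str],
) -> tuple[int, int, float]:
    """Agreement between two assignment sources on their shared probes.

    Probes assigned (not ``unassigned``) in both define the comparison set;
    returns (n_compared, n_agree, percent).  An empty comparison set yields
    percent NaN.
    """
    shared = [
        k for k in assignment_a
        if k in assignment_b
        and assignment_a[k] != UNASSIGNED
        and assignment_b[k] != UNASSIGNED
    ]
    n = len(shared)
    agree = sum(1 for k in shared if assignment_a[k] == assignment_b[k])
    pct = 100.0 * agree / n if n else float("nan")
    return n, agree, pct
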