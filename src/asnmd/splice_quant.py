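"""Exon inclusion (PSI) quantification and differential-inclusion statistics.

The inclusion rate of a cassette exon is estimated from splice-junction
read counts as ``psi = inc / (inc + 2 * exc)``, where ``inc`` counts reads
on the two flanking (inclusion) junctions and ``exc`` counts reads on
junctions that skip the exon. The factor 2 reflects that every included
molecule contributes two inclusion junctions while every skipped molecule
contributes one exclusion junction. Estimates with denominator
``inc + 2 * exc`` below 20 are discarded as unreliable.

Differential inclusion between a knockdown and its control is the
difference of inclusion rates (``dpsi``), corrected for the expression
confound (inclusion rates drift with local read depth) by taking residuals
of an OLS fit of dpsi on log10 of the denominator fold change.
Significance comes from per-depth-bin z-scores: records are binned by
log10 of the mean denominator, each bin's mean/SD of dpsi is estimated
excluding exact zeros, and one-tailed normal probabilities are assigned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

JUNCTION_COLUMNS = ["chrom", "intron_start", "intron_end", "strand", "count"]

MIN_DENOMINATOR = 20


# ---------------------------------------------------------------------------
# junction count tables
# ---------------------------------------------------------------------------

def read_junction_counts(path: str) -> pd.DataFrame:
    """Read a per-sample junction count TSV.

    Columns: chrom, intron_start (0-based first intronic base), intron_end
    (exclusive), strand, count. Duplicate keys are summed.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    missing = [c for c in JUNCTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[JUNCTION_COLUMNS]
    bad = df.index[~np.isfinite(df["count"]) | (df["count"] < 0)]
    if len(bad):
        raise ValueError(f"{path}: negative or non-finite count at row {bad[0] + 2}")
    df["count"] = df["count"].astype(np.int64)
    return (
        df.groupby(["chrom", "intron_start", "intron_end", "strand"], as_index=False)[
            "count"
        ]
        .sum()
        .sort_values(["chrom", "intron_start", "intron_end", "strand"], ignore_index=True)
    )


def pool_counts(*tables: pd.DataFrame) -> pd.DataFrame:
    """Pool bioreplicate tables by summing counts per junction key."""
    df = pd.concat(tables, ignore_index=True)
    return (
        df.groupby(["chrom", "intron_start", "intron_end", "strand"], as_index=False)[
            "count"
        ]
        .sum()
        .sort_values(["chrom", "intron_start", "intron_end", "strand"], ignore_index=True)
    )


def counts_to_dict(table: pd.DataFrame) -> dict[tuple[str, int, int, str], int]:
    return {
        (r.chrom, int(r.intron_start), int(r.intron_end), r.strand): int(r.count)
        for r in table.itertuples(index=False)
    }


def exon_support_counts(
    exon: tuple[str, int, int, str],
    gene_introns: Iterable[tuple[int, int]],
    counts: Mapping[tuple[str, int, int, str], int],
) -> tuple[int, int]:
    """(inc, exc) read support for a cassette exon.

    ``inc`` sums counts of annotated introns abutting the exon (ending at
    its acceptor or starting at its donor); ``exc`` sums counts of annotated
    introns spanning the exon entirely. Absent junctions count zero.
    """
    chrom, x, y, strand = exon
    inc = exc = 0
    for a, b in gene_introns:
        c = counts.get((chrom, a, b, strand), 0)
        if b == x or a == y:
            inc += c
        elif a < x and b > y:
            exc += c
    return inc, exc


def competing_junction_pairs(
    introns: Iterable[tuple[int, int]],
) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Pairs of introns sharing exactly one boundary.

    Two introns with a common donor but different acceptors (or vice versa)
    discriminate alternative 5'/3' splice-site usage; the inclusion-rate
    bookkeeping extends to such pairs with the competing junction's reads
    acting as exclusion support (see ``competing_site_psi``).
    """
    out = []
    ivs = sorted(set(introns))
    for i, a in enumerate(ivs):
        for b in ivs[i + 1 :]:
            if (a[0] == b[0]) != (a[1] == b[1]):
                out.append((a, b))
    return out


def competing_site_psi(
    count_primary: int, count_competing: int, min_denominator: int = MIN_DENOMINATOR
) -> float:
    """Inclusion rate of the primary junction against its competing partner.

    Applies the same psi = inc/(inc + 2*exc) bookkeeping used for cassette
    exons, with the competing junction's count as the exclusion support,
    and the same reliability threshold on the denominator.
    """
    return compute_psi(count_primary, count_competing, min_denominator)


def compute_psi(inc: int, exc: int, min_denominator: int = MIN_DENOMINATOR) -> float:
    """psi = inc / (inc + 2*exc); NaN when the denominator is below threshold."""
    if inc < 0 or exc < 0:
        raise ValueError("negative read counts")
    denom = inc + 2 * exc
    if denom < min_denominator:
        return float("nan")
    return inc / denom


def delta_psi(psi_kd: float, psi_ctrl: float) -> float:
    """Difference of inclusion rates; NaN propagates."""
    return psi_kd - psi_ctrl


# ---------------------------------------------------------------------------
# per-contrast quantification
# ---------------------------------------------------------------------------

def quantify_exons(
    exon_table: pd.DataFrame,
    introns_by_gene: Mapping[str, list[tuple[int, int]]],
    counts_kd: pd.DataFrame,
    counts_ctrl: pd.DataFrame,
    min_denominator: int = MIN_DENOMINATOR,
    fc_mode: str = "denominator",
) -> pd.DataFrame:
    """Per-exon inc/exc, psi and raw dpsi for one KD-vs-control contrast.

    ``exon_table`` must carry exon_id, chrom, start, end, strand, gene_id
    (cassette exons). ``fc_mode`` selects the fold-change proxy for the
    expression confound: "denominator" uses inc + 2*exc (the psi
    denominator, consistent with the binning variable), "total" uses
    inc + exc.
    """
    if fc_mode not in {"denominator", "total"}:
        raise ValueError(f"unknown fc_mode {fc_mode!r}")
    kd = counts_to_dict(counts_kd)
    ctrl = counts_to_dict(counts_ctrl)
    rows = []
    for r in exon_table.itertuples(index=False):
        exon = (r.chrom, int(r.start), int(r.end), r.strand)
        introns = introns_by_gene.get(r.gene_id, [])
        inc_k, exc_k = exon_support_counts(exon, introns, kd)
        inc_c, exc_c = exon_support_counts(exon, introns, ctrl)
        psi_k = compute_psi(inc_k, exc_k, min_denominator)
        psi_c = compute_psi(inc_c, exc_c, min_denominator)
        den_k, den_c = inc_k + 2 * exc_k, inc_c + 2 * exc_c
        if fc_mode == "denominator":
            num, den = den_k, den_c
        else:
            num, den = inc_k + exc_k, inc_c + exc_c
        log10_fc = np.log10(num / den) if num > 0 and den > 0 else np.nan
        rows.append(
            {
                "exon_id": r.exon_id,
                "gene_id": r.gene_id,
                "inc_kd": inc_k,
                "exc_kd": exc_k,
                "inc_ctrl": inc_c,
                "exc_ctrl": exc_c,
                "psi_kd": psi_k,
                "psi_ctrl": psi_c,
                "dpsi_raw": delta_psi(psi_k, psi_c),
                "log10_fc": log10_fc,
                "mean_count": (den_k + den_c) / 2.0,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RegressionFit:
    """OLS fit of dpsi on log10 fold change (expression confound)."""

    beta0: float
    beta1: float
    n: int


def residualize_expression(
    records: pd.DataFrame, min_records: int = 10
) -> tuple[pd.DataFrame, RegressionFit | None]:
    """Replace dpsi by its residual in the model dpsi ~ log10_fc.

    The fit uses records with dpsi_raw != 0 and finite log10_fc, as the
    confound is only identifiable on exons that moved. Records with
    dpsi_raw == 0 keep dpsi_corrected == 0; missing dpsi stays missing.
    """
    df = records.copy()
    mask = (
        df["dpsi_raw"].notna()
        & (df["dpsi_raw"] != 0)
        & np.isfinite(df["log10_fc"].to_numpy(dtype=float))
    )
    df["dpsi_corrected"] = df["dpsi_raw"]
    x = df.loc[mask, "log10_fc"].to_numpy(dtype=float)
    y = df.loc[mask, "dpsi_raw"].to_numpy(dtype=float)
    if mask.sum() < min_records or np.ptp(x) == 0:
        warnings.warn(
            "expression correction skipped: too few records or degenerate fold changes"
        )
        return df, None
    model = sm.OLS(y, sm.add_constant(x)).fit()
    df.loc[mask, "dpsi_corrected"] = model.resid
    fit = RegressionFit(beta0=float(model.params[0]), beta1=float(model.params[1]), n=int(mask.sum()))
    return df, fit


def _merge_small_bins(labels: np.ndarray, centers_width: float, min_records: int) -> np.ndarray:
    """Merge depth bins with fewer than ``min_records`` into their nearest neighbor.

    ``labels`` are integer bin indices; returns remapped labels. Groups are
    contiguous runs of original bins; a small group merges with whichever
    adjacent group has the nearer center (ties toward the lower group).
    """
    uniq, counts = np.unique(labels, return_counts=True)
    groups = [[int(u), int(u), int(c)] for u, c in zip(uniq, counts)]  # lo, hi, n
    while len(groups) > 1 and min(g[2] for g in groups) < min_records:
        i = min(range(len(groups)), key=lambda j: (groups[j][2], groups[j][0]))
        if groups[i][2] >= min_records:
            break
        center = (groups[i][0] + groups[i][1]) / 2.0
        cand = []
        if i > 0:
            cand.append((abs(center - (groups[i - 1][0] + groups[i - 1][1]) / 2.0), i - 1))
        if i < len(groups) - 1:
            cand.append((abs(center - (groups[i + 1][0] + groups[i + 1][1]) / 2.0), i + 1))
        _, j = min(cand)
        lo, hi = min(i, j), max(i, j)
        groups[lo] = [groups[lo][0], groups[hi][1], groups[lo][2] + groups[hi][2]]
        del groups[hi]
    remap = {}
    for gi, (lo, hi, _) in enumerate(groups):
        for u in uniq[(uniq >= lo) & (uniq <= hi)]:
            remap[int(u)] = gi
    return np.array([remap[int(u)] for u in labels], dtype=int)


def binned_z_test(
    records: pd.DataFrame,
    bin_width: float = 0.25,
    min_bin_records: int = 100,
    min_nonzero: int = 3,
) -> pd.DataFrame:
    """Assign depth-binned z-scores and one-tailed normal probabilities.

    Bins are fixed-width in log10(mean_count); bins with fewer than
    ``min_bin_records`` records are merged with the nearest neighbor. Per
    bin, the mean and sample SD of dpsi_corrected are estimated excluding
    exact zeros; z is assigned to every record in the bin.

    Output columns: ``bin`` (merged-bin index), ``z``, ``p`` (tail
    probability in the direction of the observed sign of z, <= 0.5), and
    ``p_up`` (fixed-direction upper tail, uniform under the null; the lower
    tail is 1 - p_up). Bins with fewer than ``min_nonzero`` nonzero values
    are untestable (z and p missing).
    """
    df = records.copy()
    df["bin"] = np.nan
    df["z"] = np.nan
    df["p"] = np.nan
    df["p_up"] = np.nan
    ok = df["dpsi_corrected"].notna() & (df["mean_count"] > 0)
    if not ok.any():
        return df
    logc = np.log10(df.loc[ok, "mean_count"].to_numpy(dtype=float))
    labels = np.floor(logc / bin_width).astype(int)
    merged = _merge_small_bins(labels, bin_width, min_bin_records)
    df.loc[ok, "bin"] = merged
    for b in np.unique(merged):
        sel = ok.copy()
        sel.loc[ok] = merged == b
        vals = df.loc[sel, "dpsi_corrected"].to_numpy(dtype=float)
        nonzero = vals[vals != 0]
        if len(nonzero) < min_nonzero:
            continue
        mu = float(np.mean(nonzero))
        sd = float(np.std(nonzero, ddof=1))
        if sd == 0:
            continue
        z = (vals - mu) / sd
        df.loc[sel, "z"] = z
        df.loc[sel, "p_up"] = sps.norm.sf(z)
        df.loc[sel, "p"] = sps.norm.sf(np.abs(z))
    return df


def to_qvalues(
    pvalues: np.ndarray | pd.Series,
    n_tests: int | None = None,
    method: str = "bh",
) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values over ``n_tests`` hypotheses.

    ``n_tests`` defaults to the number of finite p-values and may be larger
    (the paper-style correction "for the total number of exons in the
    respective test"). ``method="storey"`` additionally multiplies by a
    pi0 estimate (fraction of nulls, lambda = 0.5).
    """
    p = np.asarray(pvalues, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values outside [0, 1]")
    m = int(finite.sum())
    if n_tests is None:
        n_tests = m
    if n_tests < m:
        raise ValueError("n_tests smaller than the number of p-values")
    q = np.full_like(p, np.nan, dtype=float)
    if m == 0:
        return q
    idx = np.where(finite)[0]
    order = idx[np.argsort(p[idx], kind="mergesort")]
    ranked = p[order] * n_tests / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.minimum(ranked, 1.0)
    if method == "storey":
        pi0 = min(1.0, float(np.mean(p[finite] > 0.5)) * 2.0)
        qs = np.minimum(qs * pi0, 1.0)
    elif method != "bh":
        raise ValueError(f"unknown method {method!r}")
    q[order] = qs
    return q


def run_contrast(
    exon_table: pd.DataFrame,
    introns_by_gene: Mapping[str, list[tuple[int, int]]],
    counts_kd: pd.DataFrame,
    counts_ctrl: pd.DataFrame,
    min_denominator: int = MIN_DENOMINATOR,
    bin_width: float = 0.25,
    min_bin_records: int = 100,
    n_tests: int | None = None,
) -> tuple[pd.DataFrame, RegressionFit | None]:
    """Quantify -> residualize -> binned z -> q for one contrast."""
    df = quantify_exons(exon_table, introns_by_gene, counts_kd, counts_ctrl, min_denominator)
    df, fit = residualize_expression(df)
    df = binned_z_test(df, bin_width=bin_width, min_bin_records=min_bin_records)
    df["q"] = to_qvalues(df["p"].to_numpy(), n_tests=n_tests or len(df))
    return df, fit


def average_nmd_contrasts(
    upf1: pd.DataFrame,
    smg6: pd.DataFrame,
    require_both: bool = True,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Average the two NMD-inactivation contrasts treated as replicates.

    dpsi_nmd is the per-exon mean of corrected dpsi; combined significance
    uses the more conservative (larger) of the two one-tailed p-values,
    re-adjusted to q. With ``require_both`` (default) exons missing from
    either contrast are dropped; otherwise the available value is used.
    """
    a = upf1.set_index("exon_id")
    b = smg6.set_index("exon_id")
    idx = a.index.union(b.index, sort=True)
    d1 = a["dpsi_corrected"].reindex(idx)
    d2 = b["dpsi_corrected"].reindex(idx)
    p1 = a["p"].reindex(idx)
    p2 = b["p"].reindex(idx)
    if require_both:
        dpsi = (d1 + d2) / 2.0
        p = np.maximum(p1, p2)
    else:
        dpsi = pd.concat([d1, d2], axis=1).mean(axis=1)
        p = pd.concat([p1, p2], axis=1).max(axis=1)
    out = pd.DataFrame(
        {
            "exon_id": idx,
            "dpsi_upf1": d1.to_numpy(),
            "dpsi_smg6": d2.to_numpy(),
            "dpsi_nmd": dpsi.to_numpy(),
            "p_nmd": np.asarray(p, dtype=float),
        }
    )
    out["q_nmd"] = to_qvalues(out["p_nmd"].to_numpy(), n_tests=n_tests or len(out))
    return out
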