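"""Bin-based, context-specific differential methylation calling.

The genome is tiled in fixed-size bins (default 100 bp). Per bin and
context, methylated/unmethylated counts are pooled over cytosines covered
at least ``min_cov`` times in *both* samples, levels are compared with a
Fisher exact test on the pooled 2x2 table, and BH correction is applied
within each context. Significant bins (level difference above the
context threshold AND q below the cutoff, both strict) are joined into
regions when no more than ``join_gap`` bp apart, never across contexts or
directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CONTEXTS, GenomeIndex
from .stats import bh_adjust, fisher_exact_many

log = logging.getLogger(__name__)

#: level-difference thresholds per context (strict inequalities)
DEFAULT_THRESHOLDS = {"CG": 0.4, "CHG": 0.2, "CHH": 0.1}

#: threshold for the experimental all-context pooled ("total C") mode
TOTAL_C_THRESHOLD = {"C": 0.1}


@dataclass(frozen=True)
class DmrParams:
    """Caller parameters with the published defaults."""

    bin_size: int = 100
    min_cov: int = 4
    min_sites: int = 1
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    q_cutoff: float = 0.05
    join_gap: int = 200


def bin_methylation(
    wt: pd.DataFrame,
    mut: pd.DataFrame,
    genome: GenomeIndex,
    bin_size: int = 100,
    min_cov: int = 4,
    min_sites: int = 1,
    collapse_contexts: bool = False,
) -> pd.DataFrame:
    """Pool cytosine counts into per-bin, per-context methylation tables.

    A cytosine is informative iff its coverage (meth + unmeth) is at least
    ``min_cov`` in *both* samples; bins with fewer than ``min_sites``
    informative cytosines for a context are untestable and omitted. The
    terminal bin of a chromosome may be shorter than ``bin_size`` and is
    retained.

    With ``collapse_contexts=True`` all contexts are pooled into a single
    pseudo-context ``"C"`` (experimental "total C" mode).

    Returns one row per (chrom, bin, context) with pooled counts, per-sample
    levels and ``diff = level_mut - level_wt``.
    """
    for name, df in (("wt", wt), ("mut", mut)):
        unknown = set(df["chrom"].unique()) - set(genome.names)
        if unknown:
            raise ValueError(f"{name} sample has chromosomes not in genome: {sorted(unknown)}")
    merged = wt.merge(
        mut,
        on=["chrom", "pos", "strand", "context"],
        how="inner",
        suffixes=("_wt", "_mut"),
    )
    cov_wt = merged["meth_wt"] + merged["unmeth_wt"]
    cov_mut = merged["meth_mut"] + merged["unmeth_mut"]
    informative = (cov_wt >= min_cov) & (cov_mut >= min_cov)
    merged = merged.loc[informative]
    log.info(
        "bin_methylation: %d shared cytosines, %d informative (min_cov=%d)",
        informative.size,
        len(merged),
        min_cov,
    )
    if merged.empty:
        return _empty_bins()
    merged = merged.copy()
    merged["bin"] = merged["pos"] // bin_size
    if collapse_contexts:
        merged["context"] = "C"
    grouped = (
        merged.groupby(["chrom", "context", "bin"], sort=False, observed=True)
        .agg(
            n_sites=("pos", "size"),
            meth_wt=("meth_wt", "sum"),
            unmeth_wt=("unmeth_wt", "sum"),
            meth_mut=("meth_mut", "sum"),
            unmeth_mut=("unmeth_mut", "sum"),
        )
        .reset_index()
    )
    grouped = grouped.loc[grouped["n_sites"] >= min_sites].copy()
    grouped["start"] = grouped["bin"] * bin_size
    chrom_len = grouped["chrom"].map(genome.lengths)
    grouped["end"] = np.minimum(grouped["start"] + bin_size, chrom_len)
    grouped["level_wt"] = grouped["meth_wt"] / (grouped["meth_wt"] + grouped["unmeth_wt"])
    grouped["level_mut"] = grouped["meth_mut"] / (grouped["meth_mut"] + grouped["unmeth_mut"])
    grouped["diff"] = grouped["level_mut"] - grouped["level_wt"]
    chrom_order = {n: i for i, n in enumerate(genome.names)}
    grouped["_c"] = grouped["chrom"].map(chrom_order)
    grouped = grouped.sort_values(["_c", "start", "context"], kind="stable").drop(
        columns=["_c", "bin"]
    )
    cols = [
        "chrom",
        "start",
        "end",
        "context",
        "n_sites",
        "meth_wt",
        "unmeth_wt",
        "meth_mut",
        "unmeth_mut",
        "level_wt",
        "level_mut",
        "diff",
    ]
    return grouped[cols].reset_index(drop=True)


def _empty_bins() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "chrom",
            "start",
            "end",
            "context",
            "n_sites",
            "meth_wt",
            "unmeth_wt",
            "meth_mut",
            "unmeth_mut",
            "level_wt",
            "level_mut",
            "diff",
        ]
    )


def test_bins(
    bins: pd.DataFrame,
    thresholds: dict | None = None,
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Fisher-test each bin and flag significant ones.

    p-values come from the pooled 2x2 table (meth/unmeth x WT/mutant); BH
    adjustment is applied separately within each context. A bin is
    significant iff ``|diff| > threshold[context]`` and ``q < q_cutoff``
    (both strict). ``direction`` is ``hypo`` for negative diff (mutant
    lower), ``hyper`` otherwise.
    """
    thresholds = dict(DEFAULT_THRESHOLDS) if thresholds is None else thresholds
    out = bins.copy()
    if out.empty:
        out["p"] = out["q"] = out["significant"] = out["direction"] = []
        return out
    out["p"] = fisher_exact_many(
        out["meth_wt"].to_numpy(),
        out["unmeth_wt"].to_numpy(),
        out["meth_mut"].to_numpy(),
        out["unmeth_mut"].to_numpy(),
    )
    out["q"] = np.nan
    for ctx, idx in out.groupby("context", sort=False, observed=True).groups.items():
        out.loc[idx, "q"] = bh_adjust(out.loc[idx, "p"].to_numpy())
    thr = out["context"].map(thresholds).astype(float)
    out["direction"] = np.where(out["diff"] < 0, "hypo", "hyper")
    out["significant"] = (out["diff"].abs() > thr) & (out["q"] < q_cutoff)
    n_sig = int(out["significant"].sum())
    log.info("test_bins: %d/%d bins significant (q<%g)", n_sig, len(out), q_cutoff)
    return out


def call_dmrs(sig_bins: pd.DataFrame, join_gap: int = 200) -> pd.DataFrame:
    """Join significant bins into regions.

    Within one (chrom, context, direction) stream sorted by start,
    consecutive bins whose gap (next start minus previous end) is at most
    ``join_gap`` merge into one region. Directions and contexts never merge.

    Returns one row per region with ``n_bins``, ``mean_diff`` (unweighted
    mean of member-bin diffs) and ``min_q``.
    """
    cols = ["chrom", "start", "end", "context", "direction", "n_bins", "mean_diff", "min_q"]
    if "significant" in sig_bins.columns:
        sig_bins = sig_bins.loc[sig_bins["significant"]]
    if sig_bins.empty:
        return pd.DataFrame(columns=cols)
    rows = []
    for (chrom, ctx, direction), sub in sig_bins.groupby(
        ["chrom", "context", "direction"], sort=True, observed=True
    ):
        sub = sub.sort_values("start", kind="stable")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        gaps = starts[1:] - ends[:-1]
        breaks = np.concatenate([[0], np.nonzero(gaps > join_gap)[0] + 1, [len(sub)]])
        for i, j in zip(breaks[:-1], breaks[1:]):
            chunk = sub.iloc[i:j]
            rows.append(
                (
                    chrom,
                    int(starts[i]),
                    int(ends[j - 1]),
                    ctx,
                    direction,
                    int(j - i),
                    float(chunk["diff"].mean()),
                    float(chunk["q"].min()),
                )
            )
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["chrom", "start", "context", "direction"], kind="stable").reset_index(
        drop=True
    )


def dmr_stats(dmrs: pd.DataFrame, digits: int | None = None) -> dict:
    """Count, mean length and total length (bp) of a region set."""
    n = len(dmrs)
    if n == 0:
        return {"n": 0, "mean_length": 0.0, "total_length_bp": 0}
    lengths = (dmrs["end"] - dmrs["start"]).to_numpy()
    mean_len = float(lengths.mean())
    if digits is not None:
        mean_len = round(mean_len, digits)
    return {"n": n, "mean_length": mean_len, "total_length_bp": int(lengths.sum())}


def call_dmr_pipeline(
    wt: pd.DataFrame,
    mut: pd.DataFrame,
    genome: GenomeIndex,
    params: DmrParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: bin, test and join; returns (tested bins, DMRs)."""
    params = params or DmrParams()
    bins = bin_methylation(
        wt, mut, genome, params.bin_size, params.min_cov, params.min_sites
    )
    tested = test_bins(bins, params.thresholds, params.q_cutoff)
    dmrs = call_dmrs(tested, params.join_gap)
    return tested, dmrs
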