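"""24-nt small-RNA differential-region calling and differential expression.

Reads are filtered (size selection, structural-RNA mask, unique mappers),
assigned to fixed-size bins by their 5' end, normalised to reads per ten
million (RPTM), and compared between two libraries with an exact
conditional binomial rate test. The same test drives per-feature
differential expression.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import intervals
from .io_formats import FormatError, GenomeIndex
from .stats import bh_adjust, conditional_binomial_many

log = logging.getLogger(__name__)

RPTM_SCALE = 1e7

READ_COLUMNS = ["chrom", "start", "end", "length", "n_hits", "strand"]


# ---------------------------------------------------------------------------
# Per-read BED dialect: BED6 with name = "<length>:<n_hits>"

def read_srna_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "name": str},
    )
    split = df["name"].str.split(":", n=1, expand=True)
    if split.shape[1] < 2 or split[0].isna().any() or split[1].isna().any():
        raise FormatError("sRNA BED name field must be '<length>:<n_hits>'")
    try:
        df["length"] = split[0].astype(int)
        df["n_hits"] = split[1].astype(int)
    except ValueError as exc:
        raise FormatError(f"bad length/multiplicity in sRNA BED name field: {exc}") from exc
    return df[READ_COLUMNS]


def write_srna_bed(reads: pd.DataFrame, path) -> None:
    df = reads.sort_values(["chrom", "start", "end"], kind="stable")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": df["length"].astype(str) + ":" + df["n_hits"].astype(str),
            "score": 0,
            "strand": df["strand"] if "strand" in df else "+",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Filtering and binning

def filter_srna_reads(
    reads: pd.DataFrame,
    structural_mask: pd.DataFrame | None = None,
    len_range: tuple = (18, 30),
    unique_only: bool = True,
) -> tuple[pd.DataFrame, int]:
    """Apply size selection, structural-RNA masking and unique-mapper filters.

    Returns ``(filtered reads, total_mapped)`` where ``total_mapped`` counts
    every retained read in ``len_range`` (the RPTM denominator); downstream
    binning then restricts to the length of interest.
    """
    if "length" not in reads.columns:
        raise FormatError("read table lacks a 'length' column")
    keep = reads["length"].between(len_range[0], len_range[1])
    if unique_only:
        keep &= reads["n_hits"] == 1
    out = reads.loc[keep]
    if structural_mask is not None and len(structural_mask):
        drop = np.zeros(len(out), dtype=bool)
        for chrom, mask_sub in structural_mask.groupby("chrom", sort=False):
            sel = out["chrom"] == chrom
            if not sel.any():
                continue
            ms, me = intervals.merge(
                mask_sub["start"].to_numpy(), mask_sub["end"].to_numpy()
            )
            ov = intervals.coverage(
                out.loc[sel, "start"].to_numpy(), out.loc[sel, "end"].to_numpy(), ms, me
            )
            drop[np.nonzero(sel.to_numpy())[0]] = ov > 0
        out = out.loc[~drop]
    log.info(
        "filter_srna_reads: %d/%d reads retained (len %d-%d, unique_only=%s)",
        len(out),
        len(reads),
        len_range[0],
        len_range[1],
        unique_only,
    )
    return out.reset_index(drop=True), len(out)


def bin_and_normalize(
    reads: pd.DataFrame,
    genome: GenomeIndex,
    total_mapped: int,
    bin_size: int = 100,
    keep_len: int = 24,
    assign: str = "five_prime",
) -> pd.DataFrame:
    """Count ``keep_len``-nt reads per bin and normalise to RPTM.

    Each read is assigned to the single bin containing its 5' end (the
    start for plus-strand reads, ``end - 1`` for minus-strand); a
    ``midpoint`` mode is available. Bins with zero count are omitted.
    """
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    sel = reads.loc[reads["length"] == keep_len]
    if assign == "five_prime":
        if "strand" in sel.columns:
            pos = np.where(sel["strand"] == "-", sel["end"] - 1, sel["start"])
        else:
            pos = sel["start"].to_numpy()
    elif assign == "midpoint":
        pos = ((sel["start"] + sel["end"]) // 2).to_numpy()
    else:
        raise ValueError(f"unknown assignment mode {assign!r}")
    pos = np.asarray(pos)
    for chrom, sub_idx in sel.groupby("chrom", sort=False).groups.items():
        if chrom not in genome:
            raise FormatError(f"read on unknown chromosome {chrom}")
        loc = sel.index.get_indexer(sub_idx)
        if (pos[loc] < 0).any() or (pos[loc] >= genome.lengths[chrom]).any():
            raise FormatError(f"read beyond chromosome end on {chrom}")
    tab = pd.DataFrame({"chrom": sel["chrom"].to_numpy(), "bin": pos // bin_size})
    counts = tab.groupby(["chrom", "bin"], sort=False).size().rename("count").reset_index()
    counts["start"] = counts["bin"] * bin_size
    chrom_len = counts["chrom"].map(genome.lengths)
    counts["end"] = np.minimum(counts["start"] + bin_size, chrom_len)
    counts["rptm"] = counts["count"] * RPTM_SCALE / total_mapped
    chrom_order = {n: i for i, n in enumerate(genome.names)}
    counts["_c"] = counts["chrom"].map(chrom_order)
    counts = counts.sort_values(["_c", "start"], kind="stable").drop(columns=["_c", "bin"])
    return counts[["chrom", "start", "end", "count", "rptm"]].reset_index(drop=True)


def read_bin_table(path) -> tuple[pd.DataFrame, int]:
    """Read a per-bin count TSV; total_mapped is read from a header comment."""
    total = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# total_mapped="):
            total = int(first.strip().split("=", 1)[1])
    df = pd.read_csv(path, sep="\t", comment="#")
    if total is None:
        raise FormatError("bin table lacks '# total_mapped=' header")
    return df, total


def write_bin_table(bins: pd.DataFrame, total_mapped: int, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# total_mapped={total_mapped}\n")
        bins.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Differential siRNA regions

def call_dsrs(
    wt_bins: pd.DataFrame,
    mut_bins: pd.DataFrame,
    total_wt: int,
    total_mut: int,
    min_rptm: float = 5.0,
    fdr: float = 0.01,
    bin_size: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call differential regions between two binned libraries.

    Bins are retained iff RPTM strictly exceeds ``min_rptm`` in either
    sample; retained bins are tested with the conditional binomial test, BH
    adjusted, and bins with ``q < fdr`` are significant. Adjacent (touching)
    significant bins of the same direction merge into one region.

    Returns ``(tested bin table, DSR table)``.
    """
    if total_wt <= 0 or total_mut <= 0:
        raise ValueError("library totals must be positive")
    merged = wt_bins.merge(
        mut_bins,
        on=["chrom", "start", "end"],
        how="outer",
        suffixes=("_wt", "_mut"),
    )
    for col in ("count_wt", "count_mut"):
        merged[col] = pd.to_numeric(merged[col], errors="coerce").fillna(0).astype(np.int64)
    merged["rptm_wt"] = merged["count_wt"] * RPTM_SCALE / total_wt
    merged["rptm_mut"] = merged["count_mut"] * RPTM_SCALE / total_mut
    merged = merged.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    retained = merged.loc[
        (merged["rptm_wt"] > min_rptm) | (merged["rptm_mut"] > min_rptm)
    ].copy()
    log.info("call_dsrs: %d/%d bins retained (RPTM > %g)", len(retained), len(merged), min_rptm)
    dsr_cols = ["chrom", "start", "end", "direction", "n_bins", "logFC", "p", "q"]
    if retained.empty:
        return retained, pd.DataFrame(columns=dsr_cols)
    retained["p"] = conditional_binomial_many(
        retained["count_wt"].to_numpy(),
        retained["count_mut"].to_numpy(),
        float(total_wt),
        float(total_mut),
    )
    retained["q"] = bh_adjust(retained["p"].to_numpy())
    retained["direction"] = np.where(
        retained["rptm_mut"] >= retained["rptm_wt"], "up", "down"
    )
    retained["significant"] = retained["q"] < fdr
    sig = retained.loc[retained["significant"]]
    rows = []
    for (chrom, direction), sub in sig.groupby(["chrom", "direction"], sort=True):
        sub = sub.sort_values("start", kind="stable")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        gaps = starts[1:] - ends[:-1]
        breaks = np.concatenate([[0], np.nonzero(gaps > 0)[0] + 1, [len(sub)]])
        for i, j in zip(breaks[:-1], breaks[1:]):
            chunk = sub.iloc[i:j]
            rptm_w = chunk["rptm_wt"].sum()
            rptm_m = chunk["rptm_mut"].sum()
            logfc = float(np.log2((rptm_m + 1e-9) / (rptm_w + 1e-9)))
            rows.append(
                (
                    chrom,
                    int(starts[i]),
                    int(ends[j - 1]),
                    direction,
                    int(j - i),
                    logfc,
                    float(chunk["p"].min()),
                    float(chunk["q"].min()),
                )
            )
    dsrs = pd.DataFrame(rows, columns=dsr_cols)
    dsrs = dsrs.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return retained, dsrs


# ---------------------------------------------------------------------------
# Differential expression

def call_degs(
    counts: pd.DataFrame,
    fdr: float = 0.05,
    fc: float = 2.0,
    wt_col: str = "count_wt",
    mut_col: str = "count_mut",
) -> pd.DataFrame:
    """Per-feature differential expression between two libraries.

    Library sizes are the column sums. Features with zero total count are
    left untested (``status='ns'``, NaN p). Status is ``up``/``down`` iff
    ``q < fdr`` and the normalised fold change is at least ``fc`` in that
    direction.
    """
    out = counts.copy()
    n_wt = int(out[wt_col].sum())
    n_mut = int(out[mut_col].sum())
    out["p"] = np.nan
    out["q"] = np.nan
    out["fold_change"] = np.nan
    out["status"] = "ns"
    if n_wt == 0 or n_mut == 0:
        return out
    testable = (out[wt_col] + out[mut_col]) > 0
    rate_wt = out.loc[testable, wt_col].to_numpy() / n_wt
    rate_mut = out.loc[testable, mut_col].to_numpy() / n_mut
    with np.errstate(divide="ignore"):
        fold = np.where(
            rate_mut >= rate_wt,
            np.divide(rate_mut, rate_wt, out=np.full(rate_wt.shape, np.inf), where=rate_wt > 0),
            np.divide(rate_wt, rate_mut, out=np.full(rate_wt.shape, np.inf), where=rate_mut > 0),
        )
    out.loc[testable, "fold_change"] = fold
    out.loc[testable, "p"] = conditional_binomial_many(
        out.loc[testable, wt_col].to_numpy(),
        out.loc[testable, mut_col].to_numpy(),
        float(n_wt),
        float(n_mut),
    )
    out.loc[testable, "q"] = bh_adjust(out.loc[testable, "p"].to_numpy())
    sig = testable & (out["q"] < fdr) & (out["fold_change"] >= fc)
    up = sig & (out[mut_col] / n_mut > out[wt_col] / n_wt)
    out.loc[up, "status"] = "up"
    out.loc[sig & ~up, "status"] = "down"
    log.info(
        "call_degs: %d up, %d down of %d testable features",
        int((out["status"] == "up").sum()),
        int((out["status"] == "down").sum()),
        int(testable.sum()),
    )
    return out


# ---------------------------------------------------------------------------
# Joint siRNA / methylation deltas

def delta_scatter(
    regions: pd.DataFrame,
    wt_cx: pd.DataFrame,
    mut_cx: pd.DataFrame,
    wt_bins: pd.DataFrame,
    mut_bins: pd.DataFrame,
    total_wt: int,
    total_mut: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-region siRNA and methylation level changes plus correlations.

    For each region the siRNA delta is the difference of ``log10(RPTM + 1)``
    (pooled counts over the region) and the methylation delta per context is
    the difference of pooled-count levels. Regions without any covered
    cytosine in a context are flagged (``ok_<ctx> = False``) and excluded
    from that context's correlation.

    Returns ``(per-region table, correlation table)``; a correlation row is
    emitted only when it is defined (>= 2 complete rows and non-constant
    inputs).
    """
    from scipy.stats import pearsonr, spearmanr

    regions = regions.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    rows = []
    for _, reg in regions.iterrows():
        chrom, start, end = reg["chrom"], reg["start"], reg["end"]
        rec = {"chrom": chrom, "start": start, "end": end}
        cnt = {}
        for label, bins, total in (
            ("wt", wt_bins, total_wt),
            ("mut", mut_bins, total_mut),
        ):
            sub = bins.loc[
                (bins["chrom"] == chrom) & (bins["start"] < end) & (bins["end"] > start)
            ]
            cnt[label] = sub["count"].sum() * RPTM_SCALE / total
        rec["delta_log_rptm"] = float(
            np.log10(cnt["mut"] + 1) - np.log10(cnt["wt"] + 1)
        )
        for ctx in ("CG", "CHG", "CHH"):
            levels = {}
            for label, cx in (("wt", wt_cx), ("mut", mut_cx)):
                sub = cx.loc[
                    (cx["chrom"] == chrom)
                    & (cx["pos"] >= start)
                    & (cx["pos"] < end)
                    & (cx["context"] == ctx)
                ]
                tot = sub["meth"].sum() + sub["unmeth"].sum()
                levels[label] = sub["meth"].sum() / tot if tot > 0 else np.nan
            ok = not (np.isnan(levels["wt"]) or np.isnan(levels["mut"]))
            rec[f"delta_{ctx}"] = levels["mut"] - levels["wt"] if ok else np.nan
            rec[f"ok_{ctx}"] = ok
        rows.append(rec)
    table = pd.DataFrame(rows)
    corr_rows = []
    for ctx in ("CG", "CHG", "CHH"):
        if table.empty:
            break
        sub = table.loc[table[f"ok_{ctx}"]]
        x = sub["delta_log_rptm"].to_numpy()
        y = sub[f"delta_{ctx}"].to_numpy()
        if len(sub) < 2 or np.allclose(x, x[0]) or np.allclose(y, y[0]):
            continue
        rho, _ = spearmanr(x, y)
        r, _ = pearsonr(x, y)
        corr_rows.append({"context": ctx, "spearman": rho, "pearson": r, "n": len(sub)})
    corr = pd.DataFrame(corr_rows, columns=["context", "spearman", "pearson", "n"])
    return table, corr
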