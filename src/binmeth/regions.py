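"""Region-level analyses: feature partition, overlap accounting, flank
association, promoter methylation and chromatin-state enrichment.

All region arguments are DataFrames with at least ``chrom``, ``start``,
``end`` columns (0-based half-open).
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import binom

from . import intervals
from .io_formats import GenomeIndex
from .stats import bh_adjust

log = logging.getLogger(__name__)

PARTITION_CLASSES = ("gene", "TE", "gene/TE", "intergenic")


def _per_chrom(df: pd.DataFrame):
    for chrom, sub in df.groupby("chrom", sort=False):
        yield chrom, sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)


def _merged_by_chrom(df: pd.DataFrame) -> dict:
    return {
        chrom: intervals.merge(s, e) for chrom, s, e in _per_chrom(df)
    }


def _frame(chrom_map: dict) -> pd.DataFrame:
    rows = []
    for chrom, (s, e) in chrom_map.items():
        for a, b in zip(s, e):
            rows.append((chrom, int(a), int(b)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def merged_total_bp(regions: pd.DataFrame) -> int:
    return int(
        sum(np.sum(e - s) for _, (s, e) in _merged_by_chrom(regions).items())
    )


def _check_within_genome(regions: pd.DataFrame, genome: GenomeIndex, what: str) -> None:
    for chrom, s, e in _per_chrom(regions):
        if chrom not in genome:
            raise ValueError(f"{what} on unknown chromosome {chrom}")
        if s.min(initial=0) < 0 or e.max(initial=0) > genome.lengths[chrom]:
            raise ValueError(f"{what} outside chromosome bounds on {chrom}")


# ---------------------------------------------------------------------------
# Feature partition

def build_partition(features: pd.DataFrame, genome: GenomeIndex) -> dict:
    """Partition every genome bp into gene / TE / gene/TE / intergenic.

    Classes are pairwise disjoint and tile the genome exactly.
    """
    _check_within_genome(features, genome, "feature")
    genes = features.loc[features["kind"] == "gene"]
    tes = features.loc[features["kind"] == "TE"]
    g = _merged_by_chrom(genes)
    t = _merged_by_chrom(tes)
    empty = (np.array([], dtype=np.int64), np.array([], dtype=np.int64))
    out = {cls: {} for cls in PARTITION_CLASSES}
    for chrom in genome.names:
        gs, ge = g.get(chrom, empty)
        ts, te = t.get(chrom, empty)
        both = intervals.intersect(gs, ge, ts, te)
        gene_only = intervals.subtract(gs, ge, ts, te)
        te_only = intervals.subtract(ts, te, gs, ge)
        union_s = np.concatenate([gs, ts])
        union_e = np.concatenate([ge, te])
        inter = intervals.complement(union_s, union_e, genome.lengths[chrom])
        out["gene"][chrom] = gene_only
        out["TE"][chrom] = te_only
        out["gene/TE"][chrom] = both
        out["intergenic"][chrom] = inter
    return {cls: _frame(m) for cls, m in out.items()}


def distribute_regions(regions: pd.DataFrame, partition: dict) -> tuple:
    """bp-weighted fraction of a region set falling in each partition class.

    Returns ``(fractions, n_regions)``; an empty region set yields all-zero
    fractions with ``n_regions == 0``.
    """
    n = len(regions)
    fractions = {cls: 0.0 for cls in partition}
    if n == 0:
        return fractions, 0
    merged = _merged_by_chrom(regions)
    total = sum(int(np.sum(e - s)) for s, e in merged.values())
    for cls, cls_frame in partition.items():
        cls_map = _merged_by_chrom(cls_frame)
        bp = 0
        for chrom, (s, e) in merged.items():
            if chrom not in cls_map:
                continue
            cs, ce = cls_map[chrom]
            bp += int(np.sum(intervals.coverage(s, e, cs, ce)))
        fractions[cls] = bp / total
    return fractions, n


# ---------------------------------------------------------------------------
# Overlap accounting

def overlap_sets(a: pd.DataFrame, b: pd.DataFrame, min_bp: int = 1) -> dict:
    """Overlap summary between two region sets.

    ``n_a_overlapping_b`` counts regions of ``a`` intersecting any region of
    ``b`` by at least ``min_bp`` bp; ``overlap_bp`` is the bp intersection
    of the two merged sets; ``jaccard_bp`` = overlap / union.
    """
    n_a_overlap = 0
    n_b_overlap = 0
    n_pairs = 0
    overlap_bp = 0
    chroms = sorted(set(a["chrom"]) | set(b["chrom"]))
    for chrom in chroms:
        sub_a = a.loc[a["chrom"] == chrom]
        sub_b = b.loc[b["chrom"] == chrom]
        if len(sub_a) and len(sub_b):
            ia, ib = intervals.overlapping_pairs(
                sub_a["start"].to_numpy(),
                sub_a["end"].to_numpy(),
                sub_b["start"].to_numpy(),
                sub_b["end"].to_numpy(),
                min_bp=min_bp,
            )
            n_pairs += ia.size
            n_a_overlap += np.unique(ia).size
            n_b_overlap += np.unique(ib).size
            is_, ie_ = intervals.intersect(
                sub_a["start"].to_numpy(),
                sub_a["end"].to_numpy(),
                sub_b["start"].to_numpy(),
                sub_b["end"].to_numpy(),
            )
            overlap_bp += int(np.sum(ie_ - is_))
    total_a = merged_total_bp(a) if len(a) else 0
    total_b = merged_total_bp(b) if len(b) else 0
    union_bp = total_a + total_b - overlap_bp
    return {
        "n_a_overlapping_b": int(n_a_overlap),
        "n_b_overlapping_a": int(n_b_overlap),
        "n_shared_pairs": int(n_pairs),
        "overlap_bp": int(overlap_bp),
        "total_bp_a": int(total_a),
        "total_bp_b": int(total_b),
        "jaccard_bp": overlap_bp / union_bp if union_bp > 0 else 0.0,
    }


def percent_overlap(numerator, denominator, digits: int = 1) -> float:
    """``100 * numerator / denominator`` rounded half-up to ``digits``."""
    if denominator == 0:
        raise ValueError("percent_overlap undefined for zero denominator")
    value = Decimal(str(numerator)) * 100 / Decimal(str(denominator))
    exp = Decimal(1).scaleb(-digits)
    return float(value.quantize(exp, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Flank association and promoter methylation

def flank_associate(
    features: pd.DataFrame,
    regions: pd.DataFrame,
    flank: int = 1000,
    genome: GenomeIndex | None = None,
) -> tuple:
    """Pair features with regions intersecting their flanked span.

    The span is ``[start - flank, end + flank)`` clipped to the chromosome.
    Returns ``(pairs, summary)`` where summary reports the pair count and
    the distinct feature / region counts.
    """
    feats = features.reset_index(drop=True).copy()
    regs = regions.reset_index(drop=True).copy()
    feats["_fs"] = (feats["start"] - flank).clip(lower=0)
    feats["_fe"] = feats["end"] + flank
    if genome is not None:
        feats["_fe"] = np.minimum(feats["_fe"], feats["chrom"].map(genome.lengths))
    pair_rows = []
    for chrom in sorted(set(feats["chrom"]) & set(regs["chrom"])):
        fsub = feats.loc[feats["chrom"] == chrom]
        rsub = regs.loc[regs["chrom"] == chrom]
        ia, ib = intervals.overlapping_pairs(
            fsub["_fs"].to_numpy(),
            fsub["_fe"].to_numpy(),
            rsub["start"].to_numpy(),
            rsub["end"].to_numpy(),
        )
        for i, j in zip(ia, ib):
            frow = fsub.iloc[i]
            rrow = rsub.iloc[j]
            pair_rows.append(
                {
                    "feature_id": frow.get("id", f"feature_{frow.name}"),
                    "feature_index": int(frow.name),
                    "region_index": int(rrow.name),
                    "chrom": chrom,
                    "feature_start": int(frow["start"]),
                    "feature_end": int(frow["end"]),
                    "region_start": int(rrow["start"]),
                    "region_end": int(rrow["end"]),
                }
            )
    pairs = pd.DataFrame(
        pair_rows,
        columns=[
            "feature_id",
            "feature_index",
            "region_index",
            "chrom",
            "feature_start",
            "feature_end",
            "region_start",
            "region_end",
        ],
    )
    summary = {
        "n_pairs": len(pairs),
        "n_features": pairs["feature_index"].nunique() if len(pairs) else 0,
        "n_regions": pairs["region_index"].nunique() if len(pairs) else 0,
    }
    return pairs, summary


def promoter_methylation(
    features: pd.DataFrame,
    cx_by_sample: dict,
    flank: int = 1000,
    genome: GenomeIndex | None = None,
) -> pd.DataFrame:
    """Pooled methylation level in the strand-aware upstream flank.

    The promoter of a plus-strand feature ``[s, e)`` is ``[s - flank, s)``;
    of a minus-strand feature, ``[e, e + flank)``. One long-format row per
    (feature, sample, context); features without informative cytosines in a
    context get ``informative = False`` and NaN level.
    """
    if "strand" not in features.columns or features["strand"].isin([".", ""]).any():
        raise ValueError("promoter_methylation requires stranded features")
    rows = []
    for _, feat in features.iterrows():
        if feat["strand"] == "+":
            ps, pe = max(0, feat["start"] - flank), feat["start"]
        else:
            ps, pe = feat["end"], feat["end"] + flank
        if genome is not None:
            pe = min(pe, genome.lengths[feat["chrom"]])
        for sample, cx in cx_by_sample.items():
            sub = cx.loc[
                (cx["chrom"] == feat["chrom"]) & (cx["pos"] >= ps) & (cx["pos"] < pe)
            ]
            for ctx, ctx_sub in sub.groupby("context", sort=True, observed=True):
                meth = int(ctx_sub["meth"].sum())
                tot = meth + int(ctx_sub["unmeth"].sum())
                rows.append(
                    {
                        "feature_id": feat["id"],
                        "sample": sample,
                        "context": ctx,
                        "promoter_start": int(ps),
                        "promoter_end": int(pe),
                        "meth": meth,
                        "total": tot,
                        "level": meth / tot if tot > 0 else np.nan,
                        "informative": tot > 0,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id",
            "sample",
            "context",
            "promoter_start",
            "promoter_end",
            "meth",
            "total",
            "level",
            "informative",
        ],
    )


# ---------------------------------------------------------------------------
# Chromatin-state enrichment

def state_distribution(
    regions: pd.DataFrame, states: pd.DataFrame, genome: GenomeIndex
) -> pd.DataFrame:
    """Fraction of region bp (and of genome bp) per chromatin state."""
    merged = _merged_by_chrom(regions)
    total_region = sum(int(np.sum(e - s)) for s, e in merged.values()) or 0
    rows = []
    for state in range(1, 10):
        st = states.loc[states["state"] == state]
        st_map = _merged_by_chrom(st)
        state_bp = sum(int(np.sum(e - s)) for s, e in st_map.values())
        obs = 0
        for chrom, (s, e) in merged.items():
            if chrom in st_map:
                cs, ce = st_map[chrom]
                obs += int(np.sum(intervals.coverage(s, e, cs, ce)))
        rows.append(
            {
                "state": state,
                "region_bp": obs,
                "region_fraction": obs / total_region if total_region else 0.0,
                "genome_bp": state_bp,
                "genome_fraction": state_bp / genome.total_bp,
            }
        )
    return pd.DataFrame(rows)


def state_enrichment(
    region_sets,
    states: pd.DataFrame,
    genome: GenomeIndex,
    unit: int = 100,
) -> pd.DataFrame:
    """Enrichment of region sets in each chromatin state.

    ``region_sets`` is a single region DataFrame or a ``{name: regions}``
    dict; q-values are BH-adjusted across all (set, state) tests together.
    The p-value is a one-sided binomial tail on ``unit``-bp units
    (``n = region bp / unit``, success probability = genome fraction of the
    state), in the direction of the observed deviation.
    """
    if isinstance(region_sets, pd.DataFrame):
        region_sets = {"regions": region_sets}
    rows = []
    for name, regions in region_sets.items():
        dist = state_distribution(regions, states, genome)
        region_bp = merged_total_bp(regions) if len(regions) else 0
        n_units = max(1, int(round(region_bp / unit)))
        for rec in dist.itertuples(index=False):
            frac = rec.genome_fraction
            if frac <= 0:
                rows.append(
                    {
                        "set": name,
                        "state": rec.state,
                        "observed_bp": rec.region_bp,
                        "expected_bp": 0.0,
                        "fold": np.nan,
                        "p": np.nan,
                    }
                )
                continue
            expected_bp = region_bp * frac
            obs_units = int(np.clip(round(rec.region_bp / unit), 0, n_units))
            if rec.region_bp >= expected_bp:
                p = float(binom.sf(obs_units - 1, n_units, frac))
            else:
                p = float(binom.cdf(obs_units, n_units, frac))
            rows.append(
                {
                    "set": name,
                    "state": rec.state,
                    "observed_bp": rec.region_bp,
                    "expected_bp": expected_bp,
                    "fold": rec.region_bp / expected_bp if expected_bp > 0 else np.nan,
                    "p": p,
                }
            )
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    with np.errstate(divide="ignore"):
        out["neg_log10_q"] = -np.log10(out["q"])
    return out


def shuffle_enrichment_pvalue(
    regions: pd.DataFrame,
    states: pd.DataFrame,
    genome: GenomeIndex,
    state: int,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation cross-check: P(shuffled overlap >= observed) within chromosomes."""
    rng = np.random.default_rng(seed)
    st = states.loc[states["state"] == state]
    st_map = _merged_by_chrom(st)

    def observed_bp(regs):
        obs = 0
        for chrom, s, e in _per_chrom(regs):
            if chrom in st_map:
                cs, ce = st_map[chrom]
                obs += int(np.sum(intervals.coverage(s, e, cs, ce)))
        return obs

    obs = observed_bp(regions)
    hits = 0
    lengths = (regions["end"] - regions["start"]).to_numpy()
    chroms = regions["chrom"].to_numpy()
    for _ in range(n_perm):
        new_starts = np.empty(len(regions), dtype=np.int64)
        for chrom in np.unique(chroms):
            sel = chroms == chrom
            max_start = genome.lengths[chrom] - lengths[sel]
            new_starts[sel] = rng.integers(0, np.maximum(max_start, 1))
        shuffled = pd.DataFrame(
            {"chrom": chroms, "start": new_starts, "end": new_starts + lengths}
        )
        if observed_bp(shuffled) >= obs:
            hits += 1
    return (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Planted-truth recovery

def recovery_metrics(
    called: pd.DataFrame, truth: pd.DataFrame, min_frac: float = 0.5
) -> dict:
    """Region-level sensitivity and precision against planted intervals.

    A truth interval is recovered if at least ``min_frac`` of its length is
    covered by called regions; a called region is a true positive if at
    least ``min_frac`` of its length lies within truth intervals.
    """
    def frac_covered(queries: pd.DataFrame, reference: pd.DataFrame) -> np.ndarray:
        ref_map = _merged_by_chrom(reference) if len(reference) else {}
        fracs = np.zeros(len(queries))
        offset = 0
        for chrom, s, e in _per_chrom(queries):
            if chrom in ref_map:
                rs, re = ref_map[chrom]
                fracs[offset : offset + s.size] = intervals.coverage(s, e, rs, re) / (e - s)
            offset += s.size
        return fracs

    n_truth = len(truth)
    n_called = len(called)
    sens = float(np.mean(frac_covered(truth, called) >= min_frac)) if n_truth else np.nan
    prec = float(np.mean(frac_covered(called, truth) >= min_frac)) if n_called else np.nan
    return {
        "sensitivity": sens,
        "precision": prec,
        "n_truth": n_truth,
        "n_called": n_called,
    }
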