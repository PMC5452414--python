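"""Planted-truth simulator: genomes, annotations, paired methylomes,
24-nt sRNA libraries and expression counts.

Every generator is deterministic given ``(config, seed)``. The truth table
records, per planted locus and genotype, the methylation level in each
context and the expected per-bin sRNA abundance, so every downstream caller
can be scored against known ground truth.

Site-level heterogeneity is part of the *truth*: each cytosine carries a
fixed latent quantile (drawn once from the truth seed) that is mapped
through a Beta distribution around its locus level. Replicate methylomes of
the same genotype therefore share per-site true levels and differ only in
sampling noise, which keeps WT-vs-WT comparisons honestly null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .io_formats import GenomeIndex, derive_contexts, genome_index

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for unsatisfiable simulation configurations."""


#: per-class WT methylation levels; tuples are per-locus uniform ranges
_CLASS_LEVELS = {
    "RdDM": {"CG": 0.8, "CHG": (0.2, 0.6), "CHH": (0.35, 0.42)},
    "RdDM_low": {"CG": 0.10, "CHG": 0.05, "CHH": 0.03},
    "heterochromatin": {"CG": 0.9, "CHG": 0.7, "CHH": 0.08},
    "gene": {"CG": 0.25, "CHG": 0.01, "CHH": 0.005},
    "structural": {"CG": 0.02, "CHG": 0.01, "CHH": 0.005},
}

BACKGROUND_LEVELS = {"CG": 0.02, "CHG": 0.01, "CHH": 0.005}

#: per-bin expected RPTM of 24-nt reads
_BASAL_SRNA = 1.0
_BACKGROUND_SRNA = 0.5


@dataclass(frozen=True)
class SimConfig:
    """Desk-scale defaults: 2 Mb, one chromosome, 200 RdDM loci, 20x, 2e7/10 reads."""

    genome_size: int = 2_000_000
    n_chroms: int = 1
    seed: int = 0
    n_rddm_loci: int = 200
    n_het_loci: int = 60
    n_genes: int = 150
    n_structural: int = 10
    rddm_len: tuple = (300, 800)
    het_len: tuple = (500, 1500)
    gene_len: tuple = (1000, 2500)
    structural_len: tuple = (200, 400)
    min_spacing: int = 400
    coverage_mean: float = 20.0
    srna_library_size: int = 2_000_000
    beta_concentration: float = 50.0
    # large dispersion size => near-Poisson counts (the exact conditional
    # test assumes Poisson sampling; lower values exercise overdispersion)
    srna_dispersion: float = 1000.0
    expr_dispersion: float = 100.0
    genotypes: tuple = ("WT", "pkl", "nrpd1", "nrpe1")
    pkl_hypo_fraction: float = 0.6
    pkl_delta_chh: float = 0.3
    pkl_delta_chg: float = 0.25
    pkl_delta_cg: float = 0.2
    pkl_hyper_fraction: float = 0.15
    pkl_hyper_delta_chh: float = 0.27
    srna_fold: float = 5.0
    rddm_srna_rptm: tuple = (150.0, 400.0)
    low_rddm_srna_rptm: float = 30.0
    n_de_genes: int = 30
    n_derepressed_te: int = 10
    expr_fold: float = 4.0
    te_derepression_fold: float = 10.0
    background_levels: dict = field(default_factory=lambda: dict(BACKGROUND_LEVELS))

    def __post_init__(self):
        for name in (
            "genome_size",
            "n_chroms",
            "n_rddm_loci",
            "n_het_loci",
            "n_genes",
            "n_structural",
        ):
            if getattr(self, name) < 0 or (name in ("genome_size", "n_chroms") and getattr(self, name) <= 0):
                raise ConfigError(f"{name} must be non-negative (positive for sizes)")
        for gt in ("WT", "pkl", "nrpd1", "nrpe1"):
            if gt not in self.genotypes:
                raise ConfigError(f"genotype table must include {gt}")


@dataclass
class TruthSet:
    """Planted loci plus everything needed to draw data from them."""

    loci: pd.DataFrame
    features: pd.DataFrame
    expression: pd.DataFrame
    sequences: dict
    genome: GenomeIndex
    config: SimConfig
    seed: int
    _sites: pd.DataFrame | None = None

    @property
    def sites(self) -> pd.DataFrame:
        """All cytosines with context and trinucleotide (cached)."""
        if self._sites is None:
            self._sites = derive_contexts(self.sequences, with_trinucleotides=True)
        return self._sites

    def loci_to_tsv(self, path) -> None:
        self.loci.to_csv(path, sep="\t", index=False)

    def effect_loci(
        self, genotype: str, context: str, direction: str, min_delta: float = 0.05
    ) -> pd.DataFrame:
        """Planted intervals whose true level changes by > ``min_delta``."""
        delta = (
            self.loci[f"level_{context}_{genotype}"] - self.loci[f"level_{context}_WT"]
        )
        if direction == "hypo":
            sel = delta < -min_delta
        elif direction == "hyper":
            sel = delta > min_delta
        else:
            raise ValueError(f"unknown direction {direction!r}")
        return self.loci.loc[sel, ["chrom", "start", "end", "class", "locus_id"]].copy()

    def srna_effect_loci(
        self, genotype: str, direction: str, min_fold: float = 2.0
    ) -> pd.DataFrame:
        """Planted intervals whose sRNA rate changes by >= ``min_fold``."""
        wt = self.loci["srna_WT"]
        mut = self.loci[f"srna_{genotype}"]
        if direction == "down":
            sel = (wt > 0) & (wt / np.maximum(mut, 1e-9) >= min_fold)
        elif direction == "up":
            sel = (mut > 0) & (mut / np.maximum(wt, 1e-9) >= min_fold)
        else:
            raise ValueError(f"unknown direction {direction!r}")
        return self.loci.loc[sel, ["chrom", "start", "end", "class", "locus_id"]].copy()


def _draw_lengths(rng, n, lo_hi):
    lo, hi = lo_hi
    return rng.integers(lo, hi + 1, size=n)


def _place_loci(rng, chrom_lengths: dict, lengths: np.ndarray, spacing: int):
    """Distribute loci over chromosomes; non-overlapping with min spacing."""
    order = rng.permutation(len(lengths))
    lengths = lengths[order]
    total = sum(chrom_lengths.values())
    quotas = {}
    remaining = len(lengths)
    names = list(chrom_lengths)
    for i, name in enumerate(names):
        if i == len(names) - 1:
            quotas[name] = remaining
        else:
            q = int(round(len(lengths) * chrom_lengths[name] / total))
            q = min(q, remaining)
            quotas[name] = q
            remaining -= q
    placements = []
    idx = 0
    for name in names:
        q = quotas[name]
        lens = lengths[idx : idx + q]
        idx += q
        clen = chrom_lengths[name]
        need = int(lens.sum()) + spacing * (q + 1)
        if need > clen:
            raise ConfigError(
                f"cannot place {q} loci ({need} bp incl. spacing) on {name} ({clen} bp)"
            )
        slack = clen - need
        extra = rng.multinomial(slack, np.full(q + 1, 1.0 / (q + 1))) if q else []
        pos = spacing
        for k in range(q):
            pos += int(extra[k])
            placements.append((name, pos, pos + int(lens[k]), order[idx - q + k]))
            pos += int(lens[k]) + spacing
    placements.sort(key=lambda t: t[3])
    return [(c, s, e) for c, s, e, _ in placements]


def _random_sequence(rng, length: int) -> str:
    arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length)
    return arr.tobytes().decode("ascii")


def simulate_genome(config: SimConfig) -> TruthSet:
    """Generate sequences, features and the planted-effect truth table."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    per_chrom = config.genome_size // config.n_chroms
    chrom_lengths = {f"chr{i + 1}": per_chrom for i in range(config.n_chroms)}
    sequences = {n: _random_sequence(rng, L) for n, L in chrom_lengths.items()}

    n_low = int(round(config.n_rddm_loci * config.pkl_hyper_fraction))
    n_normal = config.n_rddm_loci - n_low
    classes = (
        ["RdDM"] * n_normal
        + ["RdDM_low"] * n_low
        + ["heterochromatin"] * config.n_het_loci
        + ["gene"] * config.n_genes
        + ["structural"] * config.n_structural
    )
    len_ranges = {
        "RdDM": config.rddm_len,
        "RdDM_low": config.rddm_len,
        "heterochromatin": config.het_len,
        "gene": config.gene_len,
        "structural": config.structural_len,
    }
    lengths = np.array(
        [int(_draw_lengths(rng, 1, len_ranges[c])[0]) for c in classes], dtype=np.int64
    )
    coords = _place_loci(rng, chrom_lengths, lengths, config.min_spacing)

    loci = pd.DataFrame(coords, columns=["chrom", "start", "end"])
    loci["class"] = classes
    loci["locus_id"] = [f"L{i:05d}" for i in range(len(loci))]

    # WT methylation levels per locus
    for ctx in ("CG", "CHG", "CHH"):
        vals = np.empty(len(loci))
        for i, cls in enumerate(classes):
            spec = _CLASS_LEVELS[cls][ctx]
            vals[i] = rng.uniform(*spec) if isinstance(spec, tuple) else spec
        loci[f"level_{ctx}_WT"] = vals

    # WT sRNA rates (expected RPTM per 100-bp bin)
    srna_wt = np.zeros(len(loci))
    is_rddm = loci["class"] == "RdDM"
    is_low = loci["class"] == "RdDM_low"
    srna_wt[is_rddm] = rng.uniform(*config.rddm_srna_rptm, size=int(is_rddm.sum()))
    srna_wt[is_low] = config.low_rddm_srna_rptm
    loci["srna_WT"] = srna_wt

    # pkl effect assignment: partial losses at a fraction of normal RdDM
    # loci, partial gains at the disjoint low-methylation subset
    normal_idx = np.nonzero(is_rddm.to_numpy())[0]
    n_hypo = int(round(len(normal_idx) * config.pkl_hypo_fraction))
    hypo_idx = rng.choice(normal_idx, size=n_hypo, replace=False)
    effect = np.array(["none"] * len(loci), dtype=object)
    effect[hypo_idx] = "hypo"
    effect[is_low.to_numpy()] = "hyper"
    loci["pkl_effect"] = effect

    for gt in config.genotypes:
        if gt == "WT":
            continue
        for ctx in ("CG", "CHG", "CHH"):
            loci[f"level_{ctx}_{gt}"] = loci[f"level_{ctx}_WT"].copy()
        loci[f"srna_{gt}"] = loci["srna_WT"].copy()

    rddm_like = (is_rddm | is_low).to_numpy()
    for gt in ("nrpd1", "nrpe1"):
        # siRNA-pathway mutants: CHH eliminated, CHG severely reduced,
        # siRNAs at basal levels at every RdDM-like locus
        loci.loc[rddm_like, f"level_CHH_{gt}"] = 0.01
        loci.loc[rddm_like, f"level_CHG_{gt}"] = np.minimum(
            loci.loc[rddm_like, "level_CHG_WT"], 0.05
        )
        loci.loc[rddm_like, f"srna_{gt}"] = _BASAL_SRNA

    hypo = effect == "hypo"
    loci.loc[hypo, "level_CHH_pkl"] = np.maximum(
        loci.loc[hypo, "level_CHH_WT"] - config.pkl_delta_chh, 0.01
    )
    loci.loc[hypo, "level_CHG_pkl"] = np.maximum(
        loci.loc[hypo, "level_CHG_WT"] - config.pkl_delta_chg, 0.01
    )
    loci.loc[hypo, "level_CG_pkl"] = np.maximum(
        loci.loc[hypo, "level_CG_WT"] - config.pkl_delta_cg, 0.05
    )
    loci.loc[hypo, "srna_pkl"] = loci.loc[hypo, "srna_WT"] / config.srna_fold
    hyper = effect == "hyper"
    loci.loc[hyper, "level_CHH_pkl"] = (
        loci.loc[hyper, "level_CHH_WT"] + config.pkl_hyper_delta_chh
    )
    loci.loc[hyper, "level_CHG_pkl"] = loci.loc[hyper, "level_CHG_WT"] + 0.15
    loci.loc[hyper, "srna_pkl"] = loci.loc[hyper, "srna_WT"] * config.srna_fold

    # features: genes keep their class; every RdDM-like or heterochromatic
    # locus is annotated as a TE
    feat_rows = []
    strands = rng.choice(["+", "-"], size=len(loci))
    for i, row in enumerate(loci.itertuples(index=False)):
        if row[3] == "gene":
            feat_rows.append((row[0], row[1], row[2], strands[i], "gene", row[4]))
        elif row[3] in ("RdDM", "RdDM_low", "heterochromatin"):
            feat_rows.append((row[0], row[1], row[2], strands[i], "TE", row[4]))
    features = pd.DataFrame(
        feat_rows, columns=["chrom", "start", "end", "strand", "kind", "id"]
    )

    expression = _build_expression_truth(rng, loci, features, config)

    genome = genome_index(sequences)
    log.info(
        "simulate_genome: %d bp, %d loci (%d RdDM, %d low, %d het, %d genes)",
        config.genome_size,
        len(loci),
        n_normal,
        n_low,
        config.n_het_loci,
        config.n_genes,
    )
    return TruthSet(
        loci=loci,
        features=features,
        expression=expression,
        sequences=sequences,
        genome=genome,
        config=config,
        seed=config.seed,
    )


def _build_expression_truth(rng, loci, features, config: SimConfig) -> pd.DataFrame:
    feats = features.copy()
    rates = np.empty(len(feats))
    is_gene = (feats["kind"] == "gene").to_numpy()
    rates[is_gene] = np.exp(rng.normal(5.0, 1.0, size=int(is_gene.sum())))
    rates[~is_gene] = rng.uniform(2.0, 5.0, size=int((~is_gene).sum()))
    expr = pd.DataFrame(
        {"feature_id": feats["id"], "kind": feats["kind"], "rate_WT": rates}
    )
    for gt in config.genotypes:
        if gt != "WT":
            expr[f"rate_{gt}"] = expr["rate_WT"].copy()

    # plant expression effects only on genes with enough baseline signal
    # for a two-library exact test to have power
    gene_idx = np.nonzero(is_gene & (rates >= 30.0))[0]
    n_de = min(config.n_de_genes, gene_idx.size)
    de_idx = rng.choice(gene_idx, size=n_de, replace=False)
    half = n_de // 2
    expr.loc[de_idx[:half], "rate_pkl"] *= config.expr_fold
    expr.loc[de_idx[half:], "rate_pkl"] /= config.expr_fold

    # derepressed TEs in pkl: drawn from TEs at pkl-hypomethylated loci
    effect_by_id = dict(zip(loci["locus_id"], loci["pkl_effect"]))
    te_idx = np.array(
        [
            i
            for i in np.nonzero(~is_gene)[0]
            if effect_by_id.get(feats["id"].iloc[i]) == "hypo"
        ]
    )
    n_dere = min(config.n_derepressed_te, te_idx.size)
    dere_idx = rng.choice(te_idx, size=n_dere, replace=False) if n_dere else []
    expr.loc[dere_idx, "rate_pkl"] *= config.te_derepression_fold
    # a small shared subset also derepressed in the siRNA-pathway mutants
    n_shared = min(3, n_dere)
    for gt in ("nrpd1", "nrpe1"):
        expr.loc[dere_idx[:n_shared], f"rate_{gt}"] *= config.te_derepression_fold
    expr["de_status_pkl"] = "none"
    expr.loc[de_idx[:half], "de_status_pkl"] = "up"
    expr.loc[de_idx[half:], "de_status_pkl"] = "down"
    expr.loc[dere_idx, "de_status_pkl"] = "up"
    return expr


# ---------------------------------------------------------------------------
# Methylomes

def _site_base_levels(truth: TruthSet, genotype: str) -> np.ndarray:
    """Per-site true mean level for a genotype (locus overlay on background)."""
    if genotype not in truth.config.genotypes:
        raise ConfigError(f"unknown genotype {genotype!r}")
    sites = truth.sites
    bg = truth.config.background_levels
    levels = (
        sites["context"].map(bg).to_numpy(dtype=float)
        if len(sites)
        else np.empty(0)
    )
    for chrom, sub in truth.loci.groupby("chrom", sort=False):
        sub = sub.sort_values("start")  # searchsorted needs coordinate order
        sel = (sites["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        pos = sites.loc[sel, "pos"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.maximum(idx, 0)])
        rows = np.nonzero(sel)[0][inside]
        locus_rows = idx[inside]
        for ctx in ("CG", "CHG", "CHH"):
            ctx_levels = sub[f"level_{ctx}_{genotype}"].to_numpy()
            ctx_sel = sites["context"].to_numpy()[rows] == ctx
            levels[rows[ctx_sel]] = ctx_levels[locus_rows[ctx_sel]]
    return levels


def _site_levels(truth: TruthSet, genotype: str) -> np.ndarray:
    """Latent per-site levels: Beta heterogeneity around the base levels.

    The latent quantile per site is drawn once from the truth seed, so
    replicates of one genotype share true site levels.
    """
    base = _site_base_levels(truth, genotype)
    conc = truth.config.beta_concentration
    if conc <= 0 or base.size == 0:
        return base
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 2]))
    u = rng.random(base.size)
    clipped = np.clip(base, 1e-4, 1 - 1e-4)
    return beta_dist.ppf(u, conc * clipped, conc * (1 - clipped))


def simulate_methylome(
    truth: TruthSet,
    genotype: str,
    coverage_mean: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a CX-style per-cytosine count table for one genotype.

    Coverage is Poisson(``coverage_mean``) per site; methylated counts are
    Binomial(coverage, site level). ``coverage_mean = 0`` yields an empty
    report.
    """
    if coverage_mean is None:
        coverage_mean = truth.config.coverage_mean
    sites = truth.sites
    cols = ["chrom", "pos", "strand", "context", "meth", "unmeth", "trinuc"]
    if coverage_mean <= 0 or len(sites) == 0:
        return pd.DataFrame(columns=cols)
    levels = _site_levels(truth, genotype)
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 3, seed]))
    coverage = rng.poisson(coverage_mean, size=len(sites))
    meth = rng.binomial(coverage, levels)
    out = sites[["chrom", "pos", "strand", "context", "trinuc"]].copy()
    out["meth"] = meth
    out["unmeth"] = coverage - meth
    return out[cols]


# ---------------------------------------------------------------------------
# Small RNA

def _negbin(rng, mean: np.ndarray, size_param: float) -> np.ndarray:
    """Gamma-Poisson draw; large ``size_param`` approaches Poisson."""
    mean = np.asarray(mean, dtype=float)
    lam = np.where(mean > 0, rng.gamma(size_param, 1.0, size=mean.shape) * mean / size_param, 0.0)
    return rng.poisson(lam)


def _bin_frame(genome: GenomeIndex, bin_size: int) -> pd.DataFrame:
    frames = []
    for chrom in genome.names:
        L = genome.lengths[chrom]
        starts = np.arange(0, L, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, L)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(frames, ignore_index=True)


def _bin_srna_means(
    truth: TruthSet, genotype: str, library_size: int, bin_size: int, include_structural: bool
) -> pd.DataFrame:
    if genotype not in truth.config.genotypes:
        raise ConfigError(f"unknown genotype {genotype!r}")
    bins = _bin_frame(truth.genome, bin_size)
    rptm = np.full(len(bins), _BACKGROUND_SRNA)
    loci = truth.loci
    if not include_structural:
        loci = loci.loc[loci["class"] != "structural"]
    for chrom, sub in loci.groupby("chrom", sort=False):
        sel = (bins["chrom"] == chrom).to_numpy()
        b_start = bins.loc[sel, "start"].to_numpy()
        b_end = bins.loc[sel, "end"].to_numpy()
        for row in sub.itertuples(index=False):
            rate = getattr(row, f"srna_{genotype}")
            if row[3] == "structural":
                rate = 500.0  # heavy contamination in all genotypes
            ov = np.minimum(b_end, row[2]) - np.maximum(b_start, row[1])
            frac = np.clip(ov, 0, None) / (b_end - b_start)
            idx = np.nonzero(frac > 0)[0]
            base = np.nonzero(sel)[0][idx]
            rptm[base] = rptm[base] + frac[idx] * rate
    bins["mean_count"] = rptm * library_size / 1e7
    return bins


def simulate_srna_library(
    truth: TruthSet,
    genotype: str,
    library_size: int | None = None,
    seed: int = 0,
    bin_size: int = 100,
) -> tuple[pd.DataFrame, int]:
    """Draw per-bin 24-nt counts directly (post-filtering abundances).

    Structural-RNA loci are excluded (their reads would be removed by the
    mask in a read-level pipeline). Returns ``(bins, total_mapped)`` where
    ``total_mapped`` is the configured library size used as the RPTM
    denominator.
    """
    if library_size is None:
        library_size = truth.config.srna_library_size
    if library_size <= 0:
        raise ConfigError("library_size must be positive")
    bins = _bin_srna_means(truth, genotype, library_size, bin_size, include_structural=False)
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 4, seed]))
    counts = _negbin(rng, bins["mean_count"].to_numpy(), truth.config.srna_dispersion)
    bins = bins.drop(columns="mean_count")
    bins["count"] = counts
    bins = bins.loc[bins["count"] > 0].reset_index(drop=True)
    bins["rptm"] = bins["count"] * 1e7 / library_size
    return bins, library_size


def simulate_srna_reads(
    truth: TruthSet,
    genotype: str,
    library_size: int = 100_000,
    seed: int = 0,
    bin_size: int = 100,
    off_size_fraction: float = 0.10,
    multi_fraction: float = 0.05,
) -> pd.DataFrame:
    """Per-read table exercising all filters.

    Emits 24-nt uniquely-mapped reads drawn from the planted rates
    (including structural loci), plus off-size (18-23/25-30 nt) reads and a
    multimapped fraction scattered genome-wide.
    """
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 5, seed]))
    bins = _bin_srna_means(truth, genotype, library_size, bin_size, include_structural=True)
    counts = _negbin(rng, bins["mean_count"].to_numpy(), truth.config.srna_dispersion)
    reads = []
    nz = np.nonzero(counts)[0]
    chrom_arr = bins["chrom"].to_numpy()
    start_arr = bins["start"].to_numpy()
    for i in nz:
        n = counts[i]
        starts = start_arr[i] + rng.integers(0, bin_size, size=n)
        reads.append(
            pd.DataFrame(
                {
                    "chrom": chrom_arr[i],
                    "start": starts,
                    "length": 24,
                }
            )
        )
    df = (
        pd.concat(reads, ignore_index=True)
        if reads
        else pd.DataFrame(columns=["chrom", "start", "length"])
    )
    n_off = int(round(len(df) * off_size_fraction))
    if n_off:
        off_lengths = rng.choice([18, 19, 20, 21, 22, 23, 25, 26, 28, 30], size=n_off)
        chroms = rng.choice(truth.genome.names, size=n_off)
        starts = np.array(
            [rng.integers(0, truth.genome.lengths[c] - 30) for c in chroms]
        )
        df = pd.concat(
            [df, pd.DataFrame({"chrom": chroms, "start": starts, "length": off_lengths})],
            ignore_index=True,
        )
    df["n_hits"] = 1
    n_multi = int(round(len(df) * multi_fraction))
    if n_multi:
        multi_rows = rng.choice(len(df), size=n_multi, replace=False)
        df.loc[multi_rows, "n_hits"] = rng.integers(2, 10, size=n_multi)
    df["strand"] = rng.choice(["+", "-"], size=len(df))
    df["end"] = np.minimum(
        df["start"] + df["length"], df["chrom"].map(truth.genome.lengths)
    )
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return df[["chrom", "start", "end", "length", "n_hits", "strand"]]


def structural_mask(truth: TruthSet) -> pd.DataFrame:
    sub = truth.loci.loc[truth.loci["class"] == "structural"]
    return sub[["chrom", "start", "end"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Expression

def simulate_expression(truth: TruthSet, genotype: str, seed: int = 0) -> pd.DataFrame:
    """Draw per-feature counts for one genotype from the planted rates."""
    if genotype not in truth.config.genotypes:
        raise ConfigError(f"unknown genotype {genotype!r}")
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 6, seed]))
    rates = truth.expression[f"rate_{genotype}"].to_numpy()
    counts = _negbin(rng, rates, truth.config.expr_dispersion)
    return pd.DataFrame(
        {
            "feature_id": truth.expression["feature_id"],
            "kind": truth.expression["kind"],
            "count": counts,
        }
    )


# ---------------------------------------------------------------------------
# Chromatin states (synthetic segmentation for the enrichment stage)

def simulate_states(truth: TruthSet, tile: int = 2000) -> pd.DataFrame:
    """A deterministic 9-state segmentation of the simulated genome.

    Heterochromatic and RdDM-like loci map to state 8 (with some state 4),
    genes to states 1-3, and the remainder to random tiles of the other
    states — enough structure for enrichment analyses to have signal.
    """
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 8]))
    rows = []
    for chrom in truth.genome.names:
        L = truth.genome.lengths[chrom]
        loci = truth.loci.loc[truth.loci["chrom"] == chrom].sort_values("start")
        cursor = 0
        for row in loci.itertuples(index=False):
            if row[1] > cursor:
                rows.extend(_random_tiles(rng, chrom, cursor, row[1], tile))
            if row[3] in ("RdDM", "RdDM_low", "heterochromatin"):
                state = 8 if rng.random() < 0.8 else 4
            elif row[3] == "gene":
                state = int(rng.integers(1, 4))
            else:
                state = int(rng.integers(1, 10))
            rows.append((chrom, row[1], row[2], state))
            cursor = row[2]
        if cursor < L:
            rows.extend(_random_tiles(rng, chrom, cursor, L, tile))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


def _random_tiles(rng, chrom, start, end, tile):
    out = []
    pos = start
    while pos < end:
        nxt = min(pos + tile, end)
        out.append((chrom, pos, nxt, int(rng.integers(1, 10))))
        pos = nxt
    return out
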