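"""Configuration-driven orchestration: simulate -> dmr -> dsr -> deg ->
annotate -> enrich -> report.

A single YAML-style config (every key optional, defaults below) drives the
whole run; every stage writes TSV outputs plus a machine-readable manifest
recording parameters, seeds and input checksums. Reruns with the same seed
are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dmr as dmr_mod
from . import regions as regions_mod
from . import simulate as sim_mod
from . import srna as srna_mod
from .dmr import DmrParams
from .io_formats import (
    write_cx_report,
    write_fasta,
    write_gff3,
    write_regions_bed,
    write_states_bed,
)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclasses.dataclass
class RunConfig:
    """All caller parameters, with the published defaults."""

    seed: int = 0
    outdir: str = "binmeth_out"
    genotype_pairs: tuple = (("WT", "pkl"), ("WT", "nrpd1"), ("WT", "nrpe1"))
    # simulate
    simulate: dict = dataclasses.field(default_factory=dict)
    # dmr
    bin_size: int = 100
    min_cov: int = 4
    min_sites: int = 1
    thresholds: dict = dataclasses.field(
        default_factory=lambda: dict(dmr_mod.DEFAULT_THRESHOLDS)
    )
    dmr_q: float = 0.05
    join_gap: int = 200
    # dsr
    rptm_min: float = 5.0
    dsr_fdr: float = 0.01
    # deg
    deg_fdr: float = 0.05
    deg_fc: float = 2.0
    # annotation
    flank: int = 1000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "genotype_pairs" in raw:
            raw["genotype_pairs"] = tuple(tuple(p) for p in raw["genotype_pairs"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 0 < self.dmr_q <= 1 or not 0 < self.dsr_fdr <= 1 or not 0 < self.deg_fdr <= 1:
            raise ValueError("cutoffs must lie in (0, 1]")
        if self.bin_size <= 0 or self.min_cov < 0 or self.join_gap < 0 or self.flank < 0:
            raise ValueError("sizes and gaps must be non-negative (bin_size positive)")

    def dmr_params(self) -> DmrParams:
        return DmrParams(
            bin_size=self.bin_size,
            min_cov=self.min_cov,
            min_sites=self.min_sites,
            thresholds=dict(self.thresholds),
            q_cutoff=self.dmr_q,
            join_gap=self.join_gap,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir=None) -> dict:
    """Run the full synthetic pipeline; returns the manifest dict."""
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": dataclasses.asdict(config),
        "seed": config.seed,
        "outputs": [],
        "checksums": {},
    }
    summary_rows = []

    # ---- simulate ---------------------------------------------------------
    sim_kwargs = dict(config.simulate)
    sim_kwargs.setdefault("seed", config.seed)
    try:
        sim_config = sim_mod.SimConfig(**sim_kwargs)
    except TypeError as exc:
        raise PipelineError("simulate", f"bad simulate config: {exc}") from exc
    truth = sim_mod.simulate_genome(sim_config)
    write_fasta(truth.sequences, out / "genome.fa")
    write_gff3(truth.features, out / "features.gff3")
    truth.loci_to_tsv(out / "truth_loci.tsv")
    states = sim_mod.simulate_states(truth)
    write_states_bed(states, out / "states.bed")

    genotypes = sorted({g for pair in config.genotype_pairs for g in pair})
    methylomes, srna_bins, srna_totals, expr = {}, {}, {}, {}
    for i, gt in enumerate(genotypes):
        methylomes[gt] = sim_mod.simulate_methylome(truth, gt, seed=i)
        write_cx_report(methylomes[gt], out / f"meth_{gt}.cx")
        srna_bins[gt], srna_totals[gt] = sim_mod.simulate_srna_library(truth, gt, seed=i)
        srna_mod.write_bin_table(srna_bins[gt], srna_totals[gt], out / f"srna_{gt}.tsv")
        expr[gt] = sim_mod.simulate_expression(truth, gt, seed=i)
    expr_matrix = expr[genotypes[0]][["feature_id", "kind"]].copy()
    for gt in genotypes:
        expr_matrix[gt] = expr[gt]["count"]
    expr_matrix.to_csv(out / "expression.tsv", sep="\t", index=False)
    summary_rows.append(("simulate", "n_loci", len(truth.loci)))

    # ---- dmr / dsr / deg per genotype pair -------------------------------
    dmrs_by_pair = {}
    dsrs_by_pair = {}
    degs_by_pair = {}
    tested_bins = {}
    for ref, alt in config.genotype_pairs:
        pair = f"{alt}_vs_{ref}"
        for gt in (ref, alt):
            if gt not in methylomes:
                raise PipelineError("dmr", f"no methylome for genotype {gt}")
        tested, dmrs = dmr_mod.call_dmr_pipeline(
            methylomes[ref], methylomes[alt], truth.genome, config.dmr_params()
        )
        tested_bins[pair] = tested
        dmrs_by_pair[pair] = dmrs
        tested.to_csv(out / f"bins_{pair}.tsv", sep="\t", index=False)
        dmrs.to_csv(out / f"dmrs_{pair}.tsv", sep="\t", index=False)
        if len(dmrs):
            write_regions_bed(dmrs, out / f"dmrs_{pair}.bed")
        for ctx in ("CG", "CHG", "CHH"):
            for direction in ("hypo", "hyper"):
                sub = dmrs.loc[(dmrs["context"] == ctx) & (dmrs["direction"] == direction)]
                stats = dmr_mod.dmr_stats(sub)
                summary_rows.append((f"dmr/{pair}", f"n_{ctx}_{direction}", stats["n"]))
                summary_rows.append(
                    (f"dmr/{pair}", f"total_bp_{ctx}_{direction}", stats["total_length_bp"])
                )

        bin_table, dsrs = srna_mod.call_dsrs(
            srna_bins[ref],
            srna_bins[alt],
            srna_totals[ref],
            srna_totals[alt],
            min_rptm=config.rptm_min,
            fdr=config.dsr_fdr,
            bin_size=config.bin_size,
        )
        dsrs_by_pair[pair] = dsrs
        dsrs.to_csv(out / f"dsrs_{pair}.tsv", sep="\t", index=False)
        summary_rows.append((f"dsr/{pair}", "n_dsrs", len(dsrs)))
        summary_rows.append(
            (f"dsr/{pair}", "n_up", int((dsrs["direction"] == "up").sum()) if len(dsrs) else 0)
        )

        counts = expr_matrix[["feature_id", "kind"]].copy()
        counts["count_wt"] = expr_matrix[ref]
        counts["count_mut"] = expr_matrix[alt]
        degs = srna_mod.call_degs(counts, fdr=config.deg_fdr, fc=config.deg_fc)
        degs_by_pair[pair] = degs
        degs.to_csv(out / f"degs_{pair}.tsv", sep="\t", index=False)
        summary_rows.append(
            (f"deg/{pair}", "n_up", int((degs["status"] == "up").sum()))
        )
        summary_rows.append(
            (f"deg/{pair}", "n_down", int((degs["status"] == "down").sum()))
        )

    # ---- annotate ---------------------------------------------------------
    partition = regions_mod.build_partition(truth.features, truth.genome)
    pairs = list(dmrs_by_pair)
    for pair in pairs:
        dmrs = dmrs_by_pair[pair]
        for direction in ("hypo", "hyper"):
            sub = dmrs.loc[(dmrs["context"] == "CHH") & (dmrs["direction"] == direction)]
            fractions, n = regions_mod.distribute_regions(sub, partition)
            for cls, frac in fractions.items():
                summary_rows.append(
                    (f"annotate/{pair}", f"CHH_{direction}_frac_{cls}", round(frac, 4))
                )
    # pairwise CHH hypoDMR overlap between mutants
    for i, p1 in enumerate(pairs):
        for p2 in pairs[i + 1 :]:
            a = dmrs_by_pair[p1]
            b = dmrs_by_pair[p2]
            a = a.loc[(a["context"] == "CHH") & (a["direction"] == "hypo")]
            b = b.loc[(b["context"] == "CHH") & (b["direction"] == "hypo")]
            ov = regions_mod.overlap_sets(a, b)
            summary_rows.append(
                (f"overlap/{p1}|{p2}", "n_a_overlapping_b", ov["n_a_overlapping_b"])
            )
            summary_rows.append((f"overlap/{p1}|{p2}", "overlap_bp", ov["overlap_bp"]))
            if len(a):
                summary_rows.append(
                    (
                        f"overlap/{p1}|{p2}",
                        "pct_a_overlapping_b",
                        regions_mod.percent_overlap(ov["n_a_overlapping_b"], len(a)),
                    )
                )
    # DEG-DMR flank association per pair
    for pair in pairs:
        degs = degs_by_pair[pair]
        up_ids = set(degs.loc[degs["status"] == "up", "feature_id"])
        up_feats = truth.features.loc[truth.features["id"].isin(up_ids)]
        hypo = dmrs_by_pair[pair]
        hypo = hypo.loc[hypo["direction"] == "hypo"]
        _, assoc = regions_mod.flank_associate(
            up_feats, hypo, flank=config.flank, genome=truth.genome
        )
        summary_rows.append((f"flank/{pair}", "n_up_features_with_hypoDMR", assoc["n_features"]))
        summary_rows.append((f"flank/{pair}", "n_hypoDMRs_near_up_features", assoc["n_regions"]))

    # siRNA/methylation delta table for the first pair
    ref, alt = config.genotype_pairs[0]
    pair = f"{alt}_vs_{ref}"
    table, corr = srna_mod.delta_scatter(
        dsrs_by_pair[pair],
        methylomes[ref],
        methylomes[alt],
        srna_bins[ref],
        srna_bins[alt],
        srna_totals[ref],
        srna_totals[alt],
    )
    table.to_csv(out / f"delta_{pair}.tsv", sep="\t", index=False)
    corr.to_csv(out / f"delta_corr_{pair}.tsv", sep="\t", index=False)
    for row in corr.itertuples(index=False):
        summary_rows.append((f"delta/{pair}", f"spearman_{row.context}", round(row.spearman, 4)))

    # ---- enrich -----------------------------------------------------------
    region_sets = {}
    for pair in pairs:
        dmrs = dmrs_by_pair[pair]
        for direction in ("hypo", "hyper"):
            sub = dmrs.loc[(dmrs["context"] == "CHH") & (dmrs["direction"] == direction)]
            if len(sub):
                region_sets[f"{pair}_CHH_{direction}"] = sub
    if region_sets:
        enr = regions_mod.state_enrichment(region_sets, states, truth.genome)
        enr.to_csv(out / "state_enrichment.tsv", sep="\t", index=False)
        for row in enr.loc[enr["state"] == 8].itertuples(index=False):
            summary_rows.append(("enrich/state8", row[0], round(float(row.fold), 3)))

    # ---- heatmap-ready matrices ------------------------------------------
    pair0 = pairs[0]
    chh_hypo = dmrs_by_pair[pair0]
    chh_hypo = chh_hypo.loc[
        (chh_hypo["context"] == "CHH") & (chh_hypo["direction"] == "hypo")
    ]
    matrix = export_matrices(chh_hypo, methylomes)
    matrix.to_csv(out / f"matrix_CHH_hypo_{pair0}.tsv", sep="\t", index=False)

    # ---- report -----------------------------------------------------------
    summary = pd.DataFrame(summary_rows, columns=["stage", "key", "value"])
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)

    for path in sorted(out.iterdir()):
        if path.name == "manifest.json":
            continue
        manifest["outputs"].append(path.name)
        manifest["checksums"][path.name] = _sha256(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("run_pipeline: wrote %d outputs to %s", len(manifest["outputs"]), out)
    return manifest


def export_matrices(regions: pd.DataFrame, cx_by_sample: dict) -> pd.DataFrame:
    """Per-region methylation level matrix (rows: regions, cols: sample x context).

    Rows are sorted by coordinates; values are pooled levels in [0, 1] (NaN
    when a region has no covered cytosine of a context).
    """
    regions = regions.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    out_cols = {
        "chrom": regions["chrom"],
        "start": regions["start"],
        "end": regions["end"],
    }
    for sample, cx in cx_by_sample.items():
        for ctx in ("CG", "CHG", "CHH"):
            vals = []
            sub_ctx = cx.loc[cx["context"] == ctx]
            for reg in regions.itertuples(index=False):
                sel = sub_ctx.loc[
                    (sub_ctx["chrom"] == reg.chrom)
                    & (sub_ctx["pos"] >= reg.start)
                    & (sub_ctx["pos"] < reg.end)
                ]
                tot = sel["meth"].sum() + sel["unmeth"].sum()
                vals.append(sel["meth"].sum() / tot if tot > 0 else np.nan)
            out_cols[f"{sample}_{ctx}"] = vals
    return pd.DataFrame(out_cols)
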