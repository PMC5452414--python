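"""Readers/writers for the pipeline's file formats and cytosine-context derivation.

Formats handled: genome FASTA, per-cytosine methylation reports (7-column
CX dialect: chrom, 1-based position, strand, methylated count, unmethylated
count, context, trinucleotide), GFF3 / BED feature annotation, chromatin
state BED, and region BED output.

Internal coordinates are 0-based half-open everywhere; 1-based conventions
(CX reports, GFF3) are converted only at the file boundary. CG sites are
kept strand-separate; symmetric positions are never pooled here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")

_IUPAC = set("ACGTURYSWKMBDHVN")


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered chromosome names with lengths (the coordinate frame)."""

    names: tuple
    lengths: dict

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise FormatError("duplicate chromosome names")
        for name in self.names:
            if self.lengths[name] <= 0:
                raise FormatError(f"non-positive length for {name}")

    @property
    def total_bp(self) -> int:
        return sum(self.lengths[n] for n in self.names)

    def __contains__(self, name) -> bool:
        return name in self.lengths


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path):
    """Read a genome FASTA; returns ``(GenomeIndex, {name: sequence})``.

    Sequences are upper-cased. Duplicate headers and non-IUPAC characters
    are format errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    seqs = {}
    for rec in records:
        if rec.id in seqs:
            raise FormatError(f"duplicate FASTA header: {rec.id}")
        s = str(rec.seq).upper()
        if not s:
            raise FormatError(f"empty sequence for {rec.id}")
        bad = set(s) - _IUPAC
        if bad:
            raise FormatError(f"non-IUPAC characters in {rec.id}: {sorted(bad)}")
        seqs[rec.id] = s
    genome = GenomeIndex(tuple(seqs), {n: len(s) for n, s in seqs.items()})
    return genome, seqs


def write_fasta(sequences: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def genome_index(sequences: dict) -> GenomeIndex:
    return GenomeIndex(tuple(sequences), {n: len(s) for n, s in sequences.items()})


# ---------------------------------------------------------------------------
# Context derivation

_A, _C, _G, _T, _N = (ord(x) for x in "ACGTN")
_COMP = np.full(256, _N, dtype=np.uint8)
for _x, _y in zip("ACGT", "TGCA"):
    _COMP[ord(_x)] = ord(_y)

_CTX_NAMES = np.array(["", "CG", "CHG", "CHH"])


def _is_h(arr: np.ndarray) -> np.ndarray:
    return (arr == _A) | (arr == _C) | (arr == _T)


def _tri_strings(c0, c1, c2) -> np.ndarray:
    flat = np.empty(3 * c0.size, dtype=np.uint8)
    flat[0::3], flat[1::3], flat[2::3] = c0, c1, c2
    return np.frombuffer(flat.tobytes(), dtype="S3").astype("U3")


def derive_contexts(sequences: dict, with_trinucleotides: bool = False) -> pd.DataFrame:
    """Assign CG/CHG/CHH contexts to every cytosine on both strands.

    Context rules, reading 5'->3' on the cytosine's own strand: a following
    G makes CG (a complete dinucleotide suffices); otherwise a complete
    trinucleotide is required and C-H-G is CHG, C-H-H is CHH (H = A/C/T).
    Cytosines whose context cannot be completed (chromosome end or N) are
    skipped.

    Returns a DataFrame with columns ``chrom, pos, strand, context``
    (plus ``trinuc`` if requested), sorted by chromosome order and position.
    """
    frames = []
    n_skipped = 0
    for chrom, seq in sequences.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        # normalise ambiguity codes other than ACGT to N
        known = (arr == _A) | (arr == _C) | (arr == _G) | (arr == _T)
        arr[~known] = _N
        L = arr.size
        nxt1 = np.concatenate([arr[1:], [_N]])
        nxt2 = np.concatenate([arr[2:], [_N, _N]])
        prv1 = np.concatenate([[_N], arr[:-1]])
        prv2 = np.concatenate([[_N, _N], arr[:-2]])

        plus_ctx = np.zeros(L, dtype=np.uint8)
        c_mask = arr == _C
        plus_ctx[c_mask & (nxt1 == _G)] = 1
        h1 = _is_h(nxt1)
        plus_ctx[c_mask & h1 & (nxt2 == _G)] = 2
        plus_ctx[c_mask & h1 & _is_h(nxt2)] = 3
        n_skipped += int(np.sum(c_mask & (plus_ctx == 0)))

        minus_ctx = np.zeros(L, dtype=np.uint8)
        g_mask = arr == _G
        minus_ctx[g_mask & (prv1 == _C)] = 1
        # H on the minus strand corresponds to T/G/A on the plus strand
        hc1 = (prv1 == _T) | (prv1 == _G) | (prv1 == _A)
        minus_ctx[g_mask & hc1 & (prv2 == _C)] = 2
        hc2 = (prv2 == _T) | (prv2 == _G) | (prv2 == _A)
        minus_ctx[g_mask & hc1 & hc2] = 3
        n_skipped += int(np.sum(g_mask & (minus_ctx == 0)))

        for strand, ctx in (("+", plus_ctx), ("-", minus_ctx)):
            pos = np.nonzero(ctx)[0]
            if pos.size == 0:
                continue
            cols = {
                "chrom": chrom,
                "pos": pos,
                "strand": strand,
                "context": _CTX_NAMES[ctx[pos]],
            }
            if with_trinucleotides:
                if strand == "+":
                    cols["trinuc"] = _tri_strings(arr[pos], nxt1[pos], nxt2[pos])
                else:
                    cols["trinuc"] = _tri_strings(
                        _COMP[arr[pos]], _COMP[prv1[pos]], _COMP[prv2[pos]]
                    )
            frames.append(pd.DataFrame(cols))
    if n_skipped:
        log.debug("derive_contexts: skipped %d cytosines without context", n_skipped)
    if not frames:
        cols = ["chrom", "pos", "strand", "context"]
        if with_trinucleotides:
            cols.append("trinuc")
        return pd.DataFrame(columns=cols)
    out = pd.concat(frames, ignore_index=True)
    chrom_order = {n: i for i, n in enumerate(sequences)}
    out["_c"] = out["chrom"].map(chrom_order)
    out = out.sort_values(["_c", "pos", "strand"], kind="stable").drop(columns="_c")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# CX methylation reports

_CX_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth", "context", "trinuc"]


def read_cx_report(path, genome: GenomeIndex) -> pd.DataFrame:
    """Read a 7-column CX report; positions become 0-based.

    Zero-coverage records are retained. Unknown context tokens, out-of-range
    positions and bad strands are format errors.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        names=_CX_COLUMNS,
        dtype={
            "chrom": str,
            "pos": np.int64,
            "strand": str,
            "meth": np.int64,
            "unmeth": np.int64,
            "context": str,
            "trinuc": str,
        },
        header=None,
    )
    if not df["context"].isin(CONTEXTS).all():
        bad = sorted(set(df["context"]) - set(CONTEXTS))
        raise FormatError(f"unknown context token(s): {bad}")
    if not df["strand"].isin(["+", "-"]).all():
        raise FormatError("strand must be '+' or '-'")
    if (df["meth"] < 0).any() or (df["unmeth"] < 0).any():
        raise FormatError("negative counts in CX report")
    df["pos"] = df["pos"] - 1
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in genome:
            raise FormatError(f"unknown chromosome in CX report: {chrom}")
        if (sub["pos"] < 0).any() or (sub["pos"] >= genome.lengths[chrom]).any():
            raise FormatError(f"position out of range on {chrom}")
    return df


def write_cx_report(records: pd.DataFrame, path) -> None:
    """Write records as a 7-column CX report (1-based positions, sorted)."""
    df = records.copy()
    if "trinuc" not in df.columns:
        df["trinuc"] = "NNN"
    df = df.sort_values(["chrom", "pos", "strand"], kind="stable")
    out = df[["chrom", "pos", "strand", "meth", "unmeth", "context", "trinuc"]].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Features (GFF3 / BED)

_GFF_KINDS = {
    "gene": "gene",
    "transposable_element": "TE",
    "transposable_element_gene": "TE",
    "transposon": "TE",
    "TE": "TE",
}


def read_gff3(path) -> pd.DataFrame:
    """Read gene/TE features from GFF3 (1-based closed -> 0-based half-open)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{ln}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype not in _GFF_KINDS:
                continue
            start0, end0 = int(start) - 1, int(end)
            if end0 <= start0:
                raise FormatError(f"{path}:{ln}: end <= start")
            fid = ""
            for field in attrs.split(";"):
                if field.startswith("ID="):
                    fid = field[3:]
                    break
                if field.startswith("Name=") and not fid:
                    fid = field[5:]
            if not fid:
                fid = f"{ftype}_{ln}"
            rows.append((chrom, start0, end0, strand, _GFF_KINDS[ftype], fid))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "kind", "id"]
    )


def write_gff3(features: pd.DataFrame, path) -> None:
    kind_to_type = {"gene": "gene", "TE": "transposable_element"}
    df = features.sort_values(["chrom", "start"], kind="stable")
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in df.itertuples(index=False):
            fh.write(
                "\t".join(
                    [
                        row.chrom,
                        "binmeth",
                        kind_to_type[row.kind],
                        str(row.start + 1),
                        str(row.end),
                        ".",
                        row.strand,
                        ".",
                        f"ID={row.id}",
                    ]
                )
                + "\n"
            )


def read_features(path) -> pd.DataFrame:
    """Read features from GFF3 (``.gff``/``.gff3``) or BED6(+kind) files."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return read_gff3(path)
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{ln}: feature BED needs >= 6 columns")
            chrom, start, end, name, _score, strand = parts[:6]
            kind = parts[6] if len(parts) > 6 else "gene"
            if kind not in ("gene", "TE"):
                raise FormatError(f"{path}:{ln}: unknown feature kind {kind!r}")
            s, e = int(start), int(end)
            if e <= s:
                raise FormatError(f"{path}:{ln}: end <= start")
            rows.append((chrom, s, e, strand, kind, name))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "kind", "id"]
    )


# ---------------------------------------------------------------------------
# Chromatin states

def read_states_bed(path) -> pd.DataFrame:
    """Read chromatin-state segments (BED4, name = state 1..9).

    Segments must be non-overlapping within a chromosome.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "state"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    df["state"] = df["state"].astype(int)
    if (df["end"] <= df["start"]).any():
        raise FormatError("state segment with end <= start")
    if not df["state"].between(1, 9).all():
        raise FormatError("chromatin state outside 1..9")
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        if (sub["start"].values[1:] < sub["end"].values[:-1]).any():
            raise FormatError(f"overlapping state segments on {chrom}")
    return df.reset_index(drop=True)


def write_states_bed(states: pd.DataFrame, path) -> None:
    df = states.sort_values(["chrom", "start"], kind="stable")
    df[["chrom", "start", "end", "state"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# Region BED (DMRs / DSRs)

def _q_to_score(q: float) -> int:
    if not np.isfinite(q) or q <= 0:
        return 1000
    return int(min(1000, round(-10.0 * math.log10(q))))


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    """Write regions as BED6: name = ``direction|context``, score = -10*log10(q).

    Missing direction/context fields are written as ``.``; the score is
    capped at 1000.
    """
    df = regions.copy().sort_values(["chrom", "start"], kind="stable")
    direction = df["direction"] if "direction" in df else pd.Series(".", index=df.index)
    context = df["context"] if "context" in df else pd.Series(".", index=df.index)
    if "min_q" in df:
        qv = df["min_q"]
    elif "q" in df:
        qv = df["q"]
    else:
        qv = pd.Series(np.nan, index=df.index)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": direction.astype(str) + "|" + context.astype(str),
            "score": [0 if not np.isfinite(q) else _q_to_score(q) for q in qv],
            "strand": ".",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_regions_bed(path) -> pd.DataFrame:
    """Read a region BED6 written by :func:`write_regions_bed`."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "name": str},
    )
    if (df["end"] <= df["start"]).any():
        raise FormatError("region with end <= start")
    split = df["name"].str.split("|", n=1, expand=True)
    df["direction"] = split[0]
    df["context"] = split[1] if split.shape[1] > 1 else "."
    return df[["chrom", "start", "end", "direction", "context", "score"]]
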