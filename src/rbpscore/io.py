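"""Readers for the standard input formats.

narrowPeak/BED are parsed with pandas, gene models with pyranges
(1-based GTF converted to 0-based half-open on read), variant panels
with pysam (VCF POS converted to 0-based). Only single-nucleotide
substitutions enter a panel; indels and multi-allelic ALTs are dropped
with a warning, since the scoring model is defined per substituted base.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Tuple

import numpy as np
import pandas as pd
import pysam

from .intervals import IntervalSet

logger = logging.getLogger("rbpscore")

NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signalValue", "pValue", "qValue", "peak",
]


class ParseError(ValueError):
    """Malformed input line; message names the file and line number."""


def read_narrowpeak(path: str | Path) -> pd.DataFrame:
    """Read a narrowPeak / BED6+ file into a peak table.

    Returns columns chrom, start, end, name, score, strand. Lines with
    fewer than 6 fields, non-numeric coordinates or start >= end raise
    :class:`ParseError` identifying the offending line.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"{path}:{lineno}: expected >=6 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                score = float(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if start >= end or start < 0:
                raise ParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            strand = fields[5] if fields[5] in {"+", "-", "."} else "."
            rows.append((fields[0], start, end, fields[3], score, strand))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


def read_bed3(path: str | Path) -> IntervalSet:
    """Read a BED3(+) file as a merged interval set."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >=3 fields, got {len(fields)}"
                )
            try:
                rows.append((fields[0], int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        return IntervalSet.empty()
    return IntervalSet.from_intervals(rows)


def read_gtf(path: str | Path) -> pd.DataFrame:
    """Read a GTF into a 0-based half-open feature table via pyranges."""
    import pyranges as pr

    df = pr.read_gtf(str(path)).df
    if df.empty:
        raise ParseError(f"{path}: no features parsed")
    df = df.rename(
        columns={"Chromosome": "chrom", "Start": "start", "End": "end",
                 "Strand": "strand", "Feature": "feature"}
    )
    df["chrom"] = df["chrom"].astype(str)
    return df


def cds_footprint(annotation: pd.DataFrame) -> IntervalSet:
    """Projected CDS footprint (union over all transcripts)."""
    cds = annotation[annotation["feature"] == "CDS"]
    if cds.empty:
        raise ValueError(
            "annotation contains no CDS features; a gene model with CDS "
            "records is required to partition the regulome into coding "
            "and noncoding bases"
        )
    return IntervalSet.from_intervals(
        cds[["chrom", "start", "end"]].itertuples(index=False)
    )


def transcript_spans(annotation: pd.DataFrame) -> pd.DataFrame:
    """Transcript spans (exons+introns) with gene ids, for peak-gene links."""
    tx = annotation[annotation["feature"] == "transcript"]
    if tx.empty:
        raise ValueError("annotation contains no transcript features")
    cols = ["chrom", "start", "end", "strand", "gene_id"]
    if "transcript_id" in tx.columns:
        cols.append("transcript_id")
    return tx[cols].reset_index(drop=True)


def read_panel_vcf(
    path: str | Path, af_info_key: str = "AF"
) -> pd.DataFrame:
    """Read a population VCF into a panel table.

    Returns columns chrom, pos0 (0-based), ref, alt, daf. Non-SNV records
    and records lacking the frequency field are skipped with a warning.
    """
    rows = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref == alt:
                skipped += 1
                continue
            af = rec.info.get(af_info_key)
            if af is None:
                skipped += 1
                continue
            if isinstance(af, tuple):
                af = af[0]
            daf = float(af)
            if not (0.0 <= daf <= 1.0):
                skipped += 1
                continue
            rows.append((rec.chrom, rec.pos - 1, ref, alt, daf))
    if skipped:
        warnings.warn(
            f"{path}: skipped {skipped} non-SNV or frequency-less records"
        )
    return pd.DataFrame(rows, columns=["chrom", "pos0", "ref", "alt", "daf"])


def read_snv_vcf(path: str | Path) -> pd.DataFrame:
    """Read query/somatic SNVs: columns chrom, pos0, ref, alt."""
    rows = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None:
                skipped += 1
                continue
            for alt in rec.alts:
                if len(rec.ref) != 1 or len(alt) != 1 or rec.ref == alt:
                    skipped += 1
                    continue
                rows.append((rec.chrom, rec.pos - 1, rec.ref, alt))
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} non-SNV allele records")
    return pd.DataFrame(rows, columns=["chrom", "pos0", "ref", "alt"])


def read_bedgraph(path: str | Path) -> dict:
    """Read a bedGraph (or 2-column position/value TSV) of per-base values.

    Returns ``{chrom: (starts, ends, values)}`` with sorted, disjoint steps.
    A 2-column file is interpreted as (0-based position, value) on a single
    unnamed chromosome and is rejected — per-base tracks must name their
    chromosome; use 4-column bedGraph.
    """
    path = Path(path)
    chroms: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(
                    f"{path}:{lineno}: bedGraph needs 4 columns, "
                    f"got {len(fields)}"
                )
            try:
                rec = (int(fields[1]), int(fields[2]), float(fields[3]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            chroms.setdefault(fields[0], []).append(rec)
    out = {}
    for chrom, recs in chroms.items():
        arr = sorted(recs)
        starts = np.array([r[0] for r in arr], dtype=np.int64)
        ends = np.array([r[1] for r in arr], dtype=np.int64)
        values = np.array([r[2] for r in arr], dtype=float)
        out[chrom] = (starts, ends, values)
    return out


def read_kd_table(
    path: str | Path, log2: bool = False
) -> pd.DataFrame:
    """Knockdown fold-change TSV: rbp_id, gene_id, fold_change.

    With ``log2=True`` the third column is a log2 fold change and is
    exponentiated on read.
    """
    df = pd.read_csv(
        path, sep="\t", header=0,
        names=["rbp_id", "gene_id", "fold_change"],
        dtype={"rbp_id": str, "gene_id": str},
    )
    if log2:
        df["fold_change"] = 2.0 ** df["fold_change"].astype(float)
    df["fold_change"] = df["fold_change"].astype(float)
    if (df["fold_change"] <= 0).any() or not np.isfinite(df["fold_change"]).all():
        raise ValueError(f"{path}: fold changes must be finite and positive")
    return df


def read_gene_list(path: str | Path) -> set:
    """One gene id per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def read_de_table(path: str | Path, q_threshold: float = 0.05) -> pd.DataFrame:
    """Differential-expression TSV: gene_id plus either q_value or status.

    Returns columns gene_id, status (binary) and, when present, q_value.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise ParseError(f"{path}: missing gene_id column")
    if "status" in df.columns:
        df["status"] = df["status"].astype(int)
    elif "q_value" in df.columns:
        df["status"] = (df["q_value"].astype(float) < q_threshold).astype(int)
    else:
        raise ParseError(f"{path}: need a q_value or status column")
    return df


def gc_fraction(seq: str) -> float:
    """G+C fraction of a sequence, ignoring Ns."""
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt
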