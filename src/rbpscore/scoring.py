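"""Per-variant score assembly and the end-to-end annotate-and-rank workflow.

The universal score of a variant inside the regulome is the sum of six
nonnegative components::

    universal = s_popcons + s_hub + s_gerp + s_structure + s_kd + s_motif

and the total adds the tissue-specific category count (0-3). Variants
outside every peak score 0 across the board (flagged) unless the
genome-wide baseline switch is on, in which case the position-level
cross-species and structure components are still reported.

A :class:`DataContext` is the frozen bundle of everything scoring needs;
it can be serialized to a directory of TSV/BED/FASTA files plus a JSON
manifest with parameters and checksums, so scoring runs reproduce
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .config import Config
from .context import (
    GCBackground, PartitionedRegulome, RBPPeakCollection, VariantPanel,
    build_gc_background, build_hub_track, load_peaks, partition_by_coding,
)
from .conservation import (
    ConservationTable, GerpTransform, HubPartitionTable, HubScoreTable,
    ValueTrack, build_conservation_table, build_hub_score_table,
    gerp_component, structure_component,
)
from .intervals import HubRuns, IntervalSet
from .kd import KnockdownTable, PeakGeneLink, kd_component, link_peaks_to_genes
from .motif import (
    PWM, DscoreBackgroundCDF, binding_rbps_at, build_dscore_cdf,
    motif_component, parse_meme, variant_disruption, write_meme,
)
from .tissue import (
    BurdenResult, burdened_peaks, key_regulators, peak_burden_test,
    regulatory_potential, connectivity_vector, tissue_component,
)
from . import io as rio

logger = logging.getLogger("rbpscore")

COMPONENTS = ("s_popcons", "s_hub", "s_gerp", "s_structure", "s_kd", "s_motif")


@dataclass
class ScoreBreakdown:
    chrom: str
    pos0: int
    ref: str
    alt: str
    s_popcons: float = 0.0
    s_hub: float = 0.0
    s_gerp: float = 0.0
    s_structure: float = 0.0
    s_kd: float = 0.0
    s_motif: float = 0.0
    s_tissue: int = 0
    flags: Tuple[str, ...] = ()
    provenance: Dict[str, object] = field(default_factory=dict)

    @property
    def universal(self) -> float:
        return (self.s_popcons + self.s_hub + self.s_gerp
                + self.s_structure + self.s_kd + self.s_motif)

    @property
    def total(self) -> float:
        return self.universal + self.s_tissue


@dataclass
class DataContext:
    """The frozen bundle of precomputed tables consumed at scoring time."""

    genome: object
    genome_id: str
    collections: Dict[str, RBPPeakCollection]
    partitioned: PartitionedRegulome
    transcripts: pd.DataFrame
    hub: HubRuns
    hub_table: HubScoreTable
    cons_table: ConservationTable
    background: GCBackground
    gerp: ValueTrack
    gerp_transform: GerpTransform
    structure: IntervalSet
    pwms_by_rbp: Dict[str, List[PWM]]
    dscore_cdf: DscoreBackgroundCDF
    links: List[PeakGeneLink]
    kd_table: KnockdownTable
    config: Config
    manifest: Dict[str, object] = field(default_factory=dict)

    @property
    def rbp_ids(self) -> List[str]:
        return sorted(self.collections)


@dataclass
class TissueContext:
    """Precomputed user-specific evidence sets."""

    key_rbps: Set[str] = field(default_factory=set)
    burdened: Set[Tuple[str, str, int, int]] = field(default_factory=set)
    key_genes: Set[str] = field(default_factory=set)
    potentials: List = field(default_factory=list)
    burden_results: List[BurdenResult] = field(default_factory=list)


# ---------------------------------------------------------------------------
# context construction

def build_context(
    genome,
    genome_id: str,
    collections: Dict[str, RBPPeakCollection],
    annotation: pd.DataFrame,
    panel: VariantPanel,
    gerp: ValueTrack,
    structure: IntervalSet,
    pwms: Sequence[PWM],
    kd_table: KnockdownTable,
    config: Config | None = None,
) -> DataContext:
    """Assemble every precomputed table from in-memory inputs."""
    config = config or Config()
    cds = rio.cds_footprint(annotation)
    transcripts = rio.transcript_spans(annotation)
    partitioned = partition_by_coding(collections, cds)
    hub = build_hub_track(collections)
    background = build_gc_background(
        genome, panel, config.gc_bin_size, config.gc_min_bins_per_group
    )
    cons_table = build_conservation_table(partitioned, panel, background, genome)
    hub_table = build_hub_score_table(
        hub, partitioned, panel, background, genome,
        config.hub_hot_quantile, config.hub_ultra_quantile,
        config.hub_smoother_bandwidth,
    )
    pwms_by_rbp: Dict[str, List[PWM]] = {}
    for pwm in pwms:
        pwms_by_rbp.setdefault(pwm.rbp_id, []).append(pwm)
    union = partitioned.union
    in_reg = panel.in_regions(union)
    panel_in = panel.table[in_reg]
    cdf = build_dscore_cdf(
        panel_in[["chrom", "pos0", "ref", "alt"]].itertuples(index=False),
        collections, pwms_by_rbp, genome,
        config.p_ref_gate, config.p_ref_gate_direction,
    )
    links = link_peaks_to_genes(collections, transcripts)
    gerp_tf = GerpTransform(config.gerp_midpoint, config.gerp_steepness)
    manifest = {
        "genome_id": genome_id,
        "n_rbps": len(collections),
        "regulome_bp": union.total_length,
        "panel_size": len(panel),
        "config": config.to_dict(),
    }
    return DataContext(
        genome=genome, genome_id=genome_id, collections=collections,
        partitioned=partitioned, transcripts=transcripts, hub=hub,
        hub_table=hub_table, cons_table=cons_table, background=background,
        gerp=gerp, gerp_transform=gerp_tf, structure=structure,
        pwms_by_rbp=pwms_by_rbp, dscore_cdf=cdf, links=links,
        kd_table=kd_table, config=config, manifest=manifest,
    )


def build_context_from_files(
    genome_fasta: str | Path,
    peak_files: Sequence,
    annotation_gtf: str | Path,
    panel_vcf: str | Path,
    gerp_bedgraph: str | Path,
    structure_bed: str | Path,
    motif_meme: str | Path,
    kd_tsv: str | Path,
    blacklist_bed: str | Path | None = None,
    config: Config | None = None,
    genome_id: str | None = None,
) -> DataContext:
    """File-based front end to :func:`build_context`."""
    import pyfaidx

    config = config or Config()
    genome = pyfaidx.Fasta(str(genome_fasta))
    blacklist = rio.read_bed3(blacklist_bed) if blacklist_bed else None
    collections = load_peaks(
        list(peak_files), config.min_peak_score, blacklist,
        config.peak_score_exact, config.merge_cell_lines,
    )
    annotation = rio.read_gtf(annotation_gtf)
    panel = VariantPanel.from_vcf(
        panel_vcf, config.af_info_key, config.daf_threshold
    )
    gerp = ValueTrack.from_bedgraph(gerp_bedgraph)
    structure = rio.read_bed3(structure_bed)
    pwms = parse_meme(motif_meme)
    for pwm in pwms:
        pwm.pseudocount = config.pwm_pseudocount
    kd_table = KnockdownTable(rio.read_kd_table(kd_tsv))
    return build_context(
        genome, genome_id or Path(genome_fasta).stem, collections,
        annotation, panel, gerp, structure, pwms, kd_table, config,
    )


def prepare_tissue(
    ctx: DataContext,
    de_tables: Dict[str, pd.DataFrame] | None = None,
    somatic: pd.DataFrame | None = None,
    prior_genes: Set[str] | None = None,
    chrom_lengths: Dict[str, int] | None = None,
) -> TissueContext:
    """Precompute the three tissue evidence sets from user inputs.

    ``de_tables`` maps condition name to a gene_id/status table; the key
    gene set is the union of the prior list and DE genes of every
    condition.
    """
    cfg = ctx.config
    tc = TissueContext()
    if prior_genes:
        tc.key_genes |= set(prior_genes)
    if de_tables:
        all_genes = sorted({
            g for df in de_tables.values() for g in df["gene_id"]
        })
        for cond, df in sorted(de_tables.items()):
            status = df.set_index("gene_id")["status"]
            y = np.array([int(status.get(g, 0)) for g in all_genes])
            tc.key_genes |= set(df.loc[df["status"] == 1, "gene_id"])
            for rbp in ctx.rbp_ids:
                x = connectivity_vector(ctx.links, rbp, all_genes)
                tc.potentials.append(
                    regulatory_potential(x, y, rbp, cond)
                )
        tc.key_rbps = key_regulators(
            tc.potentials, cfg.beta_p_threshold, cfg.beta_bh_adjust
        )
    if somatic is not None and len(somatic):
        tc.burden_results = peak_burden_test(
            ctx.collections, somatic, cfg.burden_window_bp, chrom_lengths,
            cfg.burden_q_threshold,
        )
        tc.burdened = burdened_peaks(tc.burden_results, cfg.burden_q_threshold)
    return tc


# ---------------------------------------------------------------------------
# per-variant scoring

def universal_score(
    chrom: str, pos0: int, ref: str, alt: str, ctx: DataContext,
) -> ScoreBreakdown:
    """Component-wise universal score of one SNV."""
    cfg = ctx.config
    flags: List[str] = []
    prov: Dict[str, object] = {}
    inside = ctx.partitioned.union.contains(chrom, pos0)
    bd = ScoreBreakdown(chrom, pos0, ref, alt)
    if not inside:
        flags.append("outside_regulome")
        if cfg.score_outside_regulome:
            val = ctx.gerp.value_at(chrom, pos0)
            bd.s_gerp, missing = gerp_component(val, ctx.gerp_transform)
            if missing:
                flags.append("gerp_missing")
            bd.s_structure = float(
                structure_component(chrom, pos0, ctx.structure)
            )
        bd.flags = tuple(flags)
        return bd

    s_popcons, pc_rbp = ctx.cons_table.score_at(chrom, pos0)
    s_hub, h = ctx.hub_table.score_at(chrom, pos0)
    val = ctx.gerp.value_at(chrom, pos0)
    s_gerp, missing = gerp_component(val, ctx.gerp_transform)
    if missing:
        flags.append("gerp_missing")
    s_structure = float(structure_component(chrom, pos0, ctx.structure))

    binding = binding_rbps_at(ctx.collections, chrom, pos0)
    dis = variant_disruption(
        chrom, pos0, ref, alt, binding, ctx.pwms_by_rbp, ctx.genome,
        cfg.p_ref_gate, cfg.p_ref_gate_direction,
    )
    s_motif = motif_component(
        dis.max_d, ctx.dscore_cdf, s_popcons, cfg.d_score_threshold
    )
    s_kd = float(kd_component(
        chrom, pos0, ctx.links, ctx.kd_table, dis.per_rbp,
        cfg.kd_fold_change, cfg.d_score_threshold, cfg.kd_two_sided,
    ))
    prov.update({
        "popcons_rbp": pc_rbp, "hub_H": h,
        "motif_pwm": dis.best_pwm,
        "max_d": dis.max_d if dis.max_d is not None else "",
        "binding_rbps": ",".join(sorted(binding)),
    })
    bd.s_popcons, bd.s_hub, bd.s_gerp = s_popcons, s_hub, s_gerp
    bd.s_structure, bd.s_kd, bd.s_motif = s_structure, s_kd, s_motif
    bd.flags, bd.provenance = tuple(flags), prov
    return bd


def full_score(
    chrom: str, pos0: int, ref: str, alt: str,
    ctx: DataContext, tissue_ctx: TissueContext | None = None,
) -> ScoreBreakdown:
    """Universal score plus the tissue category count."""
    bd = universal_score(chrom, pos0, ref, alt, ctx)
    if tissue_ctx is None or "outside_regulome" in bd.flags:
        return bd
    binding = sorted(binding_rbps_at(ctx.collections, chrom, pos0))
    containing = []
    for rbp in binding:
        for row in ctx.collections[rbp].peaks_at(chrom, pos0).itertuples():
            containing.append((rbp, chrom, int(row.start), int(row.end)))
    s_tissue, cats = tissue_component(
        chrom, pos0, binding, containing, ctx.links,
        tissue_ctx.key_rbps, tissue_ctx.burdened, tissue_ctx.key_genes,
    )
    bd.s_tissue = s_tissue
    bd.provenance["tissue_categories"] = ",".join(
        k for k, v in sorted(cats.items()) if v
    )
    return bd


def score_variants(
    variants: pd.DataFrame,
    ctx: DataContext,
    tissue_ctx: TissueContext | None = None,
) -> pd.DataFrame:
    """Score and rank a table of SNVs (columns chrom, pos0, ref, alt).

    Returns one row per variant ordered by total score (ties broken by
    universal score, then genomic coordinate); per-record failures are
    logged and skipped, and more than 10% failures raises.
    """
    rows = []
    failures = 0
    for rec in variants.itertuples(index=False):
        try:
            bd = full_score(
                str(rec.chrom), int(rec.pos0), str(rec.ref), str(rec.alt),
                ctx, tissue_ctx,
            )
        except Exception as exc:  # noqa: BLE001 - per-record isolation
            failures += 1
            logger.warning(
                "failed to score %s:%s %s>%s: %s",
                rec.chrom, rec.pos0, rec.ref, rec.alt, exc,
            )
            continue
        rows.append({
            "chrom": bd.chrom, "pos": bd.pos0 + 1,
            "ref": bd.ref, "alt": bd.alt,
            **{c: getattr(bd, c) for c in COMPONENTS},
            "universal": bd.universal, "tissue": bd.s_tissue,
            "total": bd.total,
            "flags": ";".join(bd.flags),
            "provenance": json.dumps(bd.provenance, sort_keys=True),
        })
    if len(variants) and failures > 0.1 * len(variants):
        raise RuntimeError(
            f"{failures}/{len(variants)} variants failed to score"
        )
    df = pd.DataFrame(rows, columns=[
        "chrom", "pos", "ref", "alt", *COMPONENTS,
        "universal", "tissue", "total", "flags", "provenance",
    ])
    if df.empty:
        df["rank"] = pd.Series(dtype=int)
        return df
    df = df.sort_values(
        by=["total", "universal", "chrom", "pos"],
        ascending=[False, False, True, True],
        kind="mergesort", ignore_index=True,
    )
    df.insert(df.columns.get_loc("total") + 1, "rank", np.arange(1, len(df) + 1))
    return df


# ---------------------------------------------------------------------------
# context serialization

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def save_context(ctx: DataContext, outdir: str | Path) -> Path:
    """Serialize a context to a directory of typed text files + manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    # genome
    with open(out / "genome.fa", "w") as fh:
        keys = sorted(ctx.genome.keys() if hasattr(ctx.genome, "keys")
                      else ctx.genome)
        for chrom in keys:
            fh.write(f">{chrom}\n")
            seq = str(ctx.genome[chrom][:])
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")

    peaks = pd.concat(
        [ctx.collections[r].peaks.assign(rbp_id=r) for r in ctx.rbp_ids],
        ignore_index=True,
    )
    _write_tsv(peaks[["rbp_id", "chrom", "start", "end", "strand", "score"]],
               out / "peaks.tsv")

    cds_rows = list(ctx.partitioned.cds.intervals())
    _write_tsv(pd.DataFrame(cds_rows, columns=["chrom", "start", "end"]),
               out / "cds.tsv")
    _write_tsv(ctx.transcripts, out / "transcripts.tsv")
    _write_tsv(pd.DataFrame(list(ctx.structure.intervals()),
                            columns=["chrom", "start", "end"]),
               out / "structure.tsv")

    hub_rows = []
    for chrom in sorted(ctx.hub.runs):
        s, e, c = ctx.hub.runs[chrom]
        for a, b, h in zip(s, e, c):
            hub_rows.append((chrom, int(a), int(b), int(h)))
    _write_tsv(pd.DataFrame(hub_rows, columns=["chrom", "start", "end", "H"]),
               out / "hub_runs.tsv")

    _write_tsv(ctx.background.to_frame(), out / "gc_background.tsv")
    _write_tsv(ctx.cons_table.table, out / "conservation.tsv")
    for part, tab in ctx.hub_table.partitions.items():
        _write_tsv(tab.table, out / f"hub_table_{part}.tsv")
    _write_tsv(pd.DataFrame({"d_score": ctx.dscore_cdf.scores}),
               out / "dscore_cdf.tsv")
    _write_tsv(pd.DataFrame(
        [dataclasses.asdict(ln) for ln in ctx.links]
    ), out / "links.tsv")
    _write_tsv(ctx.kd_table.table, out / "kd_table.tsv")

    gerp_rows = []
    for chrom in sorted(ctx.gerp.steps):
        s, e, v = ctx.gerp.steps[chrom]
        for a, b, x in zip(s, e, v):
            gerp_rows.append((chrom, int(a), int(b), float(x)))
    _write_tsv(pd.DataFrame(
        gerp_rows, columns=["chrom", "start", "end", "value"]
    ), out / "gerp.tsv")

    all_pwms = [p for r in sorted(ctx.pwms_by_rbp) for p in ctx.pwms_by_rbp[r]]
    write_meme(all_pwms, out / "motifs.meme")
    (out / "pwm_rbps.json").write_text(json.dumps(
        {p.motif_id: p.rbp_id for p in all_pwms}, sort_keys=True, indent=1,
    ))

    manifest = dict(ctx.manifest)
    manifest["hub_thresholds"] = {
        part: {"h_hot": t.h_hot, "h_ultra": t.h_ultra,
               "plateau": t.plateau, "bandwidth": t.bandwidth}
        for part, t in ctx.hub_table.partitions.items()
    }
    manifest["config"] = ctx.config.to_dict()
    files = sorted(p.name for p in out.iterdir()
                   if p.name != "manifest.json")
    manifest["checksums"] = {name: _sha256(out / name) for name in files}
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1) + "\n"
    )
    return out


def load_context(ctxdir: str | Path) -> DataContext:
    """Load a serialized context; verifies manifest checksums."""
    import pyfaidx

    d = Path(ctxdir)
    manifest = json.loads((d / "manifest.json").read_text())
    for name, digest in manifest["checksums"].items():
        path = d / name
        if not path.exists() or (
            path.suffix != ".fai" and _sha256(path) != digest
        ):
            raise ValueError(f"context checksum mismatch for {name}")
    config = Config.from_dict(manifest["config"])
    genome = pyfaidx.Fasta(str(d / "genome.fa"))

    peaks = pd.read_csv(d / "peaks.tsv", sep="\t",
                        dtype={"chrom": str, "rbp_id": str})
    collections = {}
    for rbp, grp in peaks.groupby("rbp_id", sort=True):
        collections[str(rbp)] = RBPPeakCollection(
            rbp_id=str(rbp), cell_lines=(),
            peaks=grp[["chrom", "start", "end", "strand", "score"]]
            .reset_index(drop=True),
        )
    cds_df = pd.read_csv(d / "cds.tsv", sep="\t", dtype={"chrom": str})
    cds = (IntervalSet.from_intervals(cds_df.itertuples(index=False))
           if len(cds_df) else IntervalSet.empty())
    transcripts = pd.read_csv(d / "transcripts.tsv", sep="\t",
                              dtype={"chrom": str, "gene_id": str})
    partitioned = partition_by_coding(collections, cds)
    hub = build_hub_track(collections)

    bg_df = pd.read_csv(d / "gc_background.tsv", sep="\t")
    background = GCBackground.from_frame(bg_df, config.gc_bin_size)
    cons = ConservationTable(
        pd.read_csv(d / "conservation.tsv", sep="\t",
                    dtype={"rbp_id": str, "partition": str}),
        partitioned,
    )
    parts = {}
    thr = manifest["hub_thresholds"]
    for part in ("coding", "noncoding"):
        f = d / f"hub_table_{part}.tsv"
        if f.exists():
            parts[part] = HubPartitionTable(
                table=pd.read_csv(f, sep="\t"),
                h_hot=int(thr[part]["h_hot"]),
                h_ultra=int(thr[part]["h_ultra"]),
                plateau=float(thr[part]["plateau"]),
                bandwidth=float(thr[part]["bandwidth"]),
            )
    hub_table = HubScoreTable(parts, hub, cds)

    structure_df = pd.read_csv(d / "structure.tsv", sep="\t",
                               dtype={"chrom": str})
    structure = (IntervalSet.from_intervals(structure_df.itertuples(index=False))
                 if len(structure_df) else IntervalSet.empty())
    gerp_df = pd.read_csv(d / "gerp.tsv", sep="\t", dtype={"chrom": str})
    steps = {}
    for chrom, grp in gerp_df.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        steps[str(chrom)] = (
            grp["start"].to_numpy(np.int64), grp["end"].to_numpy(np.int64),
            grp["value"].to_numpy(float),
        )
    gerp = ValueTrack(steps)

    rbp_map = json.loads((d / "pwm_rbps.json").read_text())
    # probabilities were pseudocount-normalized before saving; don't re-smooth
    pwms = parse_meme(d / "motifs.meme", pseudocount=0.0,
                      granularity=config.pwm_granularity)
    pwms_by_rbp: Dict[str, List[PWM]] = {}
    for p in pwms:
        p.rbp_id = rbp_map[p.motif_id]
        pwms_by_rbp.setdefault(p.rbp_id, []).append(p)

    cdf = DscoreBackgroundCDF(
        pd.read_csv(d / "dscore_cdf.tsv", sep="\t")["d_score"].to_numpy(float)
    )
    links_df = pd.read_csv(d / "links.tsv", sep="\t",
                           dtype={"rbp_id": str, "chrom": str, "gene_id": str})
    links = [
        PeakGeneLink(r.rbp_id, r.chrom, int(r.start), int(r.end), r.gene_id)
        for r in links_df.itertuples()
    ]
    kd_table = KnockdownTable(
        pd.read_csv(d / "kd_table.tsv", sep="\t",
                    dtype={"rbp_id": str, "gene_id": str})
    )
    return DataContext(
        genome=genome, genome_id=manifest["genome_id"],
        collections=collections, partitioned=partitioned,
        transcripts=transcripts, hub=hub, hub_table=hub_table,
        cons_table=cons, background=background, gerp=gerp,
        gerp_transform=GerpTransform(config.gerp_midpoint,
                                     config.gerp_steepness),
        structure=structure, pwms_by_rbp=pwms_by_rbp, dscore_cdf=cdf,
        links=links, kd_table=kd_table, config=config, manifest=manifest,
    )
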