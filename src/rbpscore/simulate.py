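"""Seeded synthetic test worlds with known planted parameters.

Every generator is deterministic given a seed and emits exactly the
formats the context builder consumes (FASTA, narrowPeak, VCF, bedGraph,
BED, MEME-minimal PWMs, TSV), so ``simulate -> build-context -> score``
is a closed round trip. A ground-truth JSON records what was planted
(rare-variant boost per RBP, hub hotspots, key regulators, burdened
peaks), sufficient to compute the expected value of every estimator
without re-reading the fixture files.

Rare/common panel status is drawn directly (Bernoulli per variant, with
a region-dependent rate for planted enrichment) rather than through a
population-genetic simulator: the scoring maths consumes only the
rare/common dichotomy. The genome's GC profile is blockwise so GC-group
stratification is exercised with several distinct groups.

Lightweight samplers (:func:`sample_calibration_rho_adj`,
:func:`sample_connectivity_de`, :func:`sample_burden_world`) reproduce
the statistical structure of single estimators at scale without building
a full world; the statistical tests use them for replicated runs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .config import Config
from .context import (
    GCBackground, RBPPeakCollection, VariantPanel, _merge_stranded,
    build_gc_background,
)
from .conservation import ValueTrack, entropy_weight
from .intervals import IntervalSet
from .kd import KnockdownTable
from .motif import PWM, BASES, write_meme

BASE_ARR = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# fixture specification

@dataclass
class GenomeSpec:
    n_chroms: int = 1
    length_bp: int = 200_000
    gc_levels: Tuple[float, ...] = (0.30, 0.35, 0.40, 0.45, 0.50, 0.55, 0.60)
    block_bp: int = 2_000


@dataclass
class RBPSpec:
    count: int = 8
    peaks_per_rbp: int = 25
    peak_length: Tuple[int, int] = (100, 160)
    hub_enrichment: float = 0.5   # fraction of peaks placed at shared hotspots
    n_hotspots: int = 5
    decoy_fraction: float = 0.08  # sub-threshold peaks written to files


@dataclass
class PanelSpec:
    n_variants: int = 10_000
    rare_fraction_background: float = 0.30
    rare_fraction_boost_in_peaks: float = 1.15
    boosted_rbps: Tuple[str, ...] = ("R01",)


@dataclass
class MotifSpec:
    length_range: Tuple[int, int] = (5, 7)
    consensus_prob: float = 0.85
    plant_fraction: float = 0.5   # fraction of peaks seeded with the consensus


@dataclass
class KDSpec:
    fraction_responsive: float = 0.30
    responsive_fc: Tuple[float, float] = (2.5, 6.0)
    neutral_fc: Tuple[float, float] = (0.7, 1.4)


@dataclass
class TissueSpec:
    de_prob_target: float = 0.40
    de_prob_nontarget: float = 0.10
    n_key_rbps: int = 3
    burden_rate_per_bp: float = 5e-5
    burden_multiplier: float = 10.0
    n_burdened_peaks: int = 20


@dataclass
class FixtureSpec:
    seed: int
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    rbps: RBPSpec = field(default_factory=RBPSpec)
    panel: PanelSpec = field(default_factory=PanelSpec)
    motifs: MotifSpec = field(default_factory=MotifSpec)
    kd: KDSpec = field(default_factory=KDSpec)
    tissue: TissueSpec = field(default_factory=TissueSpec)


# ---------------------------------------------------------------------------
# world (in-memory fixture set)

@dataclass
class World:
    spec: FixtureSpec
    genome: Dict[str, str]
    raw_peaks: Dict[str, pd.DataFrame]     # per RBP, pre-filter (with decoys)
    collections: Dict[str, RBPPeakCollection]
    blacklist: IntervalSet
    annotation: pd.DataFrame
    panel: pd.DataFrame
    gerp: ValueTrack
    structure: IntervalSet
    pwms: List[PWM]
    kd_table: pd.DataFrame
    de_table: pd.DataFrame
    somatic: pd.DataFrame
    prior_genes: Set[str]
    truth: Dict[str, object]


def _draw_sequence(rng: np.random.Generator, length: int,
                   gc_levels: Sequence[float], block_bp: int) -> np.ndarray:
    """Blockwise-GC random sequence as an S1 array."""
    out = np.empty(length, dtype="S1")
    pos = 0
    while pos < length:
        gc = rng.choice(gc_levels)
        n = min(block_bp, length - pos)
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        out[pos:pos + n] = BASE_ARR[rng.choice(4, size=n, p=p)]
        pos += n
    return out


def _make_annotation(length: int, chrom: str) -> pd.DataFrame:
    """Genes tiled along the chromosome: span 4 kb, 2 kb intergenic,
    CDS at [start+500, start+1500)."""
    rows = []
    gid = 0
    start = 1_000
    while start + 4_000 < length - 1_000:
        gid += 1
        g = f"G{gid:04d}"
        t = f"{g}.t1"
        rows.append((chrom, start, start + 4_000, "+", "gene", g, t))
        rows.append((chrom, start, start + 4_000, "+", "transcript", g, t))
        rows.append((chrom, start + 500, start + 1_500, "+", "CDS", g, t))
        start += 6_000
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "feature",
                       "gene_id", "transcript_id"]
    )


def _random_pwm(rng: np.random.Generator, motif_id: str, rbp_id: str,
                length: int, consensus_prob: float) -> PWM:
    cons = rng.integers(0, 4, size=length)
    probs = np.full((length, 4), (1 - consensus_prob) / 3)
    probs[np.arange(length), cons] = consensus_prob
    return PWM(motif_id=motif_id, probs=probs, rbp_id=rbp_id, source="invitro")


def simulate_world(spec: FixtureSpec) -> World:
    """Generate the full in-memory fixture set for a spec (deterministic)."""
    rng = np.random.default_rng(spec.seed)
    gs, rs, ps, ms, ks, ts = (spec.genome, spec.rbps, spec.panel,
                              spec.motifs, spec.kd, spec.tissue)
    L = gs.length_bp
    if rs.peak_length[1] > L:
        raise ValueError("peaks longer than the genome are infeasible")
    if ps.n_variants > L:
        raise ValueError("more panel variants than genome positions")
    chroms = [f"chr{i + 1}" for i in range(gs.n_chroms)]
    seqs = {
        c: _draw_sequence(rng, L, gs.gc_levels, gs.block_bp) for c in chroms
    }
    chrom = chroms[0]  # peaks/genes concentrate on the first chromosome

    rbp_ids = [f"R{i + 1:02d}" for i in range(rs.count)]
    # motifs first, so consensus sites can be planted into the genome
    pwms = []
    for rbp in rbp_ids:
        length = int(rng.integers(ms.length_range[0], ms.length_range[1] + 1))
        pwms.append(_random_pwm(rng, f"{rbp}_invitro", rbp, length,
                                ms.consensus_prob))
    pwm_by_rbp = {p.rbp_id: p for p in pwms}

    blacklist = IntervalSet.from_intervals([
        (chrom, L - 5_000, L - 4_500), (chrom, L - 3_000, L - 2_600),
    ])
    hotspots = np.sort(rng.integers(2_000, L - 2_000, size=rs.n_hotspots))

    raw_peaks: Dict[str, pd.DataFrame] = {}
    collections: Dict[str, RBPPeakCollection] = {}
    for rbp in rbp_ids:
        rows = []
        for _ in range(rs.peaks_per_rbp):
            plen = int(rng.integers(rs.peak_length[0], rs.peak_length[1] + 1))
            if rng.random() < rs.hub_enrichment:
                centre = int(rng.choice(hotspots) + rng.normal(0, 100))
            else:
                centre = int(rng.integers(1_000, L - 1_000))
            start = max(0, min(centre - plen // 2, L - plen))
            strand = "+" if rng.random() < 0.5 else "-"
            score = 500.0 if rng.random() < rs.decoy_fraction else 1000.0
            rows.append((chrom, start, start + plen, f"{rbp}_pk", score, strand))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                         "score", "strand"])
        raw_peaks[rbp] = df
        kept = df[df["score"] == 1000.0].copy()
        # drop blacklist-overlapping peaks, as the loader would
        drop = [
            i for i in kept.index
            if blacklist.intersect(IntervalSet.from_intervals(
                [(chrom, kept.at[i, "start"], kept.at[i, "end"])]
            )).total_length > 0
        ]
        kept = kept.drop(index=drop)
        merged = _merge_stranded(
            kept[["chrom", "start", "end", "strand", "score"]]
        )
        collections[rbp] = RBPPeakCollection(
            rbp_id=rbp, cell_lines=("SIM",), peaks=merged,
        )
        # plant the RBP's consensus at the centre of a fraction of its peaks
        pwm = pwm_by_rbp[rbp]
        site = pwm.consensus.encode()
        for row in merged.itertuples():
            if rng.random() < ms.plant_fraction:
                mid = (row.start + row.end) // 2
                s = mid - len(site) // 2
                if 0 <= s and s + len(site) <= L:
                    seqs[str(row.chrom)][s:s + len(site)] = np.frombuffer(
                        site, dtype="S1"
                    )

    genome = {c: seqs[c].tobytes().decode() for c in chroms}
    annotation = _make_annotation(L, chrom)

    union = IntervalSet.empty()
    boosted = IntervalSet.empty()
    for rbp, coll in collections.items():
        union = union.union(coll.footprint)
        if rbp in ps.boosted_rbps:
            boosted = boosted.union(coll.footprint)

    # panel: uniform positions; rare status Bernoulli with boosted rate
    # inside the designated RBPs' footprints
    positions = np.sort(rng.choice(L, size=ps.n_variants, replace=False))
    in_boost = boosted.contains_points(chrom, positions)
    rate = np.where(
        in_boost,
        np.clip(ps.rare_fraction_background * ps.rare_fraction_boost_in_peaks,
                0, 1),
        ps.rare_fraction_background,
    )
    is_rare = rng.random(ps.n_variants) < rate
    seq0 = seqs[chrom]
    refs = seq0[positions].astype("U1")
    alt_off = rng.integers(1, 4, size=ps.n_variants)
    base_idx = {b: i for i, b in enumerate(BASES)}
    alts = np.array([
        BASES[(base_idx[r] + o) % 4] for r, o in zip(refs, alt_off)
    ])
    dafs = np.where(
        is_rare,
        rng.uniform(1e-4, 0.005, ps.n_variants),
        rng.uniform(0.0101, 0.5, ps.n_variants),
    )
    panel = pd.DataFrame({
        "chrom": chrom, "pos0": positions, "ref": refs, "alt": alts,
        "daf": np.round(dafs, 6),
    })

    # cross-species values: 100-bp blocks, background N(0,1), a conserved
    # minority N(3, 0.5)
    n_blocks = L // 100
    conserved = rng.random(n_blocks) < 0.10
    values = np.where(
        conserved, rng.normal(3.0, 0.5, n_blocks), rng.normal(0.0, 1.0, n_blocks)
    )
    gerp = ValueTrack({chrom: (
        np.arange(n_blocks, dtype=np.int64) * 100,
        (np.arange(n_blocks, dtype=np.int64) + 1) * 100,
        np.round(values, 4),
    )})

    struct_starts = np.sort(rng.choice(L - 200, size=20, replace=False))
    structure = IntervalSet.from_intervals(
        [(chrom, int(s), int(s) + 100) for s in struct_starts]
    )

    # knockdown fold changes over (rbp, gene) pairs
    genes = annotation.loc[annotation["feature"] == "gene", "gene_id"].tolist()
    kd_rows = []
    for rbp in rbp_ids:
        for g in genes:
            if rng.random() < ks.fraction_responsive:
                fc = float(rng.uniform(*ks.responsive_fc))
                if rng.random() < 0.5:
                    fc = 1.0 / fc
            else:
                fc = float(rng.uniform(*ks.neutral_fc))
            kd_rows.append((rbp, g, round(fc, 4)))
    kd_table = pd.DataFrame(kd_rows,
                            columns=["rbp_id", "gene_id", "fold_change"])

    # tissue: DE prob depends on connectivity to the planted key RBPs
    key_rbps = rbp_ids[:ts.n_key_rbps]
    gene_rows = annotation[annotation["feature"] == "gene"]
    gene_iv = {
        r.gene_id: (r.start, r.end) for r in gene_rows.itertuples()
    }
    key_union = IntervalSet.empty()
    for rbp in key_rbps:
        key_union = key_union.union(collections[rbp].footprint)
    de_rows = []
    for g in genes:
        s, e = gene_iv[g]
        target = key_union.intersect(
            IntervalSet.from_intervals([(chrom, s, e)])
        ).total_length > 0
        p = ts.de_prob_target if target else ts.de_prob_nontarget
        de_rows.append((g, int(rng.random() < p)))
    de_table = pd.DataFrame(de_rows, columns=["gene_id", "status"])

    # somatic mutations: uniform background plus extra hits in designated peaks
    all_peaks = [
        (rbp, str(r.chrom), int(r.start), int(r.end))
        for rbp in rbp_ids for r in collections[rbp].peaks.itertuples()
    ]
    n_burd = min(ts.n_burdened_peaks, len(all_peaks))
    burd_idx = rng.choice(len(all_peaks), size=n_burd, replace=False)
    burdened = [all_peaks[i] for i in sorted(burd_idx)]
    n_bg = rng.poisson(ts.burden_rate_per_bp * L)
    som_pos = list(rng.integers(0, L, size=n_bg))
    for _, _, s, e in burdened:
        extra = rng.poisson(
            (ts.burden_multiplier - 1.0) * ts.burden_rate_per_bp * (e - s)
        )
        som_pos.extend(rng.integers(s, e, size=extra))
    som_pos = np.sort(np.asarray(som_pos, dtype=np.int64))
    som_ref = seq0[som_pos].astype("U1")
    som_alt = np.array([
        BASES[(base_idx[r] + 1) % 4] for r in som_ref
    ])
    somatic = pd.DataFrame({
        "chrom": chrom, "pos0": som_pos, "ref": som_ref, "alt": som_alt,
    })

    prior_genes = set(genes[:3])
    truth = {
        "seed": spec.seed,
        "rho_boost": {
            r: (ps.rare_fraction_boost_in_peaks if r in ps.boosted_rbps
                else 1.0)
            for r in rbp_ids
        },
        "rare_fraction_background": ps.rare_fraction_background,
        "hotspots": [int(h) for h in hotspots],
        "key_rbps": key_rbps,
        "de_prob_target": ts.de_prob_target,
        "de_prob_nontarget": ts.de_prob_nontarget,
        "burdened_peaks": [list(p) for p in burdened],
        "burden_multiplier": ts.burden_multiplier,
        "burden_rate_per_bp": ts.burden_rate_per_bp,
        "regulome_bp": union.total_length,
        "genome_bp": L * gs.n_chroms,
    }
    return World(
        spec=spec, genome=genome, raw_peaks=raw_peaks,
        collections=collections, blacklist=blacklist, annotation=annotation,
        panel=panel, gerp=gerp, structure=structure, pwms=pwms,
        kd_table=kd_table, de_table=de_table, somatic=somatic,
        prior_genes=prior_genes, truth=truth,
    )


# ---------------------------------------------------------------------------
# file emission

def _write_fasta(genome: Dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def _write_vcf(df: pd.DataFrame, path: Path, contigs: Dict[str, int],
               with_af: bool) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if with_af:
            fh.write('##INFO=<ID=AF,Number=A,Type=Float,'
                     'Description="Derived allele frequency">\n')
        for c in sorted(contigs):
            fh.write(f"##contig=<ID={c},length={contigs[c]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        df = df.sort_values(["chrom", "pos0"])
        for r in df.itertuples():
            info = f"AF={r.daf:.6g}" if with_af else "."
            fh.write(f"{r.chrom}\t{r.pos0 + 1}\t.\t{r.ref}\t{r.alt}\t.\t.\t"
                     f"{info}\n")


def _write_bed(regions: IntervalSet, path: Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in regions.intervals():
            fh.write(f"{chrom}\t{s}\t{e}\n")


def simulate_context(spec: FixtureSpec, outdir: str | Path) -> World:
    """Write the complete fixture set for ``spec`` under ``outdir``.

    Emits genome.fa, <RBP>_SIM_rep1.narrowPeak, blacklist.bed, genes.gtf,
    panel.vcf, gerp.bedgraph, structure.bed, motifs.meme, kd.tsv, de.tsv,
    somatic.vcf, prior_genes.tsv and ground_truth.json. Byte-identical
    for identical (spec, seed).
    """
    world = simulate_world(spec)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    L = spec.genome.length_bp
    contigs = {c: L for c in world.genome}

    _write_fasta(world.genome, out / "genome.fa")
    for rbp in sorted(world.raw_peaks):
        df = world.raw_peaks[rbp].sort_values(["chrom", "start"])
        with open(out / f"{rbp}_SIM_rep1.narrowPeak", "w") as fh:
            for r in df.itertuples():
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score:g}\t"
                    f"{r.strand}\t0\t-1\t-1\t-1\n"
                )
    _write_bed(world.blacklist, out / "blacklist.bed")
    with open(out / "genes.gtf", "w") as fh:
        for r in world.annotation.itertuples():
            attrs = (f'gene_id "{r.gene_id}"; '
                     f'transcript_id "{r.transcript_id}";')
            fh.write(
                f"{r.chrom}\tsim\t{r.feature}\t{r.start + 1}\t{r.end}\t.\t"
                f"{r.strand}\t.\t{attrs}\n"
            )
    _write_vcf(world.panel, out / "panel.vcf", contigs, with_af=True)
    with open(out / "gerp.bedgraph", "w") as fh:
        for chrom in sorted(world.gerp.steps):
            s, e, v = world.gerp.steps[chrom]
            for a, b, x in zip(s, e, v):
                fh.write(f"{chrom}\t{a}\t{b}\t{x:g}\n")
    _write_bed(world.structure, out / "structure.bed")
    write_meme(world.pwms, out / "motifs.meme")
    world.kd_table.to_csv(out / "kd.tsv", sep="\t", index=False)
    world.de_table.to_csv(out / "de.tsv", sep="\t", index=False)
    som = world.somatic.assign(daf=0.0)
    _write_vcf(som, out / "somatic.vcf", contigs, with_af=False)
    (out / "prior_genes.tsv").write_text(
        "\n".join(sorted(world.prior_genes)) + "\n"
    )
    (out / "ground_truth.json").write_text(
        json.dumps(world.truth, sort_keys=True, indent=1) + "\n"
    )
    return world


# ---------------------------------------------------------------------------
# lightweight statistical samplers

def sample_calibration_rho_adj(
    seed: int,
    n_variants: int = 10_000,
    n_bins: int = 400,
    bin_size: int = 500,
    region_bin_fraction: float = 0.5,
    rare_rate: float = 0.30,
    boost: float = 1.0,
    gc_levels: Sequence[float] = (0.45,),
    min_bins_per_group: Optional[int] = None,
) -> float:
    """One replicate of the GC-adjusted enrichment estimator.

    Builds a GC-homogeneous genome of ``n_bins`` bins (matched GC: the
    region's GC distribution equals the background's, so after group
    merging the adjustment is against the pooled panel), draws a uniform
    panel whose rare status is Bernoulli(``rare_rate``) outside and
    Bernoulli(``rare_rate * boost``) inside a random half of the bins
    (the "peak" region), then runs the pipeline's background builder and
    enrichment estimator on the region. Returns the estimated rho_adj;
    under boost=1 it is calibrated around 1.
    """
    rng = np.random.default_rng(seed)
    from .context import build_gc_background  # pipeline path under test
    from .conservation import gc_adjusted_enrichment, rare_fraction

    if min_bins_per_group is None:
        min_bins_per_group = n_bins  # merge to one matched-GC group
    L = n_bins * bin_size
    seq = _draw_sequence(rng, L, gc_levels, bin_size)
    genome = {"chr1": seq.tobytes().decode()}
    region_bins = np.sort(rng.choice(
        n_bins, size=int(n_bins * region_bin_fraction), replace=False
    ))
    region = IntervalSet.from_intervals([
        ("chr1", int(b) * bin_size, (int(b) + 1) * bin_size)
        for b in region_bins
    ])
    positions = np.sort(rng.choice(L, size=n_variants, replace=False))
    inside = region.contains_points("chr1", positions)
    rate = np.where(inside, min(rare_rate * boost, 1.0), rare_rate)
    is_rare = rng.random(n_variants) < rate
    daf = np.where(is_rare, 0.001, 0.1)
    panel = VariantPanel(pd.DataFrame({
        "chrom": "chr1", "pos0": positions,
        "ref": "A", "alt": "C", "daf": daf,
    }))
    background = build_gc_background(genome, panel, bin_size,
                                     min_bins_per_group=min_bins_per_group)
    stats = rare_fraction(panel, region, genome)
    return gc_adjusted_enrichment(stats, background)


def sample_connectivity_de(
    seed: int,
    n_genes: int = 2_000,
    target_fraction: float = 0.30,
    de_prob_target: float = 0.40,
    de_prob_nontarget: float = 0.10,
) -> Tuple[np.ndarray, np.ndarray]:
    """Binary connectivity x and DE status y with planted slope
    ``de_prob_target - de_prob_nontarget``."""
    rng = np.random.default_rng(seed)
    x = (rng.random(n_genes) < target_fraction).astype(int)
    p = np.where(x == 1, de_prob_target, de_prob_nontarget)
    y = (rng.random(n_genes) < p).astype(int)
    return x, y


def sample_burden_world(
    seed: int,
    n_peaks: int = 100,
    peak_length: int = 200,
    n_burdened: int = 0,
    rate_per_bp: float = 5e-5,
    multiplier: float = 10.0,
    genome_bp: int = 2_000_000,
) -> Tuple[Dict[str, RBPPeakCollection], pd.DataFrame, List[int]]:
    """Peaks plus somatic mutations with a planted burden in the first
    ``n_burdened`` peaks; returns (collections, somatic, burdened idx)."""
    rng = np.random.default_rng(seed)
    starts = np.sort(rng.choice(
        np.arange(0, genome_bp - peak_length, peak_length * 2),
        size=n_peaks, replace=False,
    ))
    peaks = pd.DataFrame({
        "chrom": "chr1", "start": starts, "end": starts + peak_length,
        "strand": "+", "score": 1000.0,
    })
    colls = {"RBPX": RBPPeakCollection("RBPX", ("SIM",), peaks)}
    n_bg = rng.poisson(rate_per_bp * genome_bp)
    pos = list(rng.integers(0, genome_bp, size=n_bg))
    burd = list(range(n_burdened))
    for i in burd:
        s, e = int(starts[i]), int(starts[i]) + peak_length
        extra = rng.poisson((multiplier - 1.0) * rate_per_bp * peak_length)
        pos.extend(rng.integers(s, e, size=extra))
    somatic = pd.DataFrame({
        "chrom": "chr1", "pos0": np.sort(np.asarray(pos, dtype=np.int64)),
    })
    return colls, somatic, burd


# ---------------------------------------------------------------------------
# worked example

@dataclass
class WorkedExample:
    """A <=10 kb hand-checkable world with frozen expected scores.

    ``expected`` holds component values derived by explicit arithmetic
    from the definitions (see :func:`worked_example` for the full
    derivation); ``variants`` are the documented query SNVs.
    """

    genome: Dict[str, str]
    collections: Dict[str, RBPPeakCollection]
    annotation: pd.DataFrame
    panel: pd.DataFrame
    gerp: ValueTrack
    structure: IntervalSet
    pwms: List[PWM]
    kd_table: pd.DataFrame
    de_table: pd.DataFrame
    somatic: pd.DataFrame
    prior_genes: Set[str]
    config: Config
    variants: pd.DataFrame
    expected: Dict[str, Dict[str, float]]


def worked_example() -> WorkedExample:
    """Build the tiny documented world and its hand-computed scores.

    Construction (all coordinates 0-based half-open on a 10 kb chr1 made
    of the GC-balanced repeat AACCGGTT, so every 500-bp bin and every
    footprint has integer GC percentage 50 and the GC background is a
    single group):

    * RBPA peaks [1000,1200)+ and [6100,6200)+; RBPB peak [1100,1300)+.
    * CDS footprint [1150,1250); gene G1 spans [900,1400), G2 [6000,6500),
      G3..G10 elsewhere without peak overlap.
    * Panel of 20 SNVs (12 rare at DAF 0.001, 8 common at DAF 0.1):

      ===================  =======  ==========
      region               n (r/c)  positions
      ===================  =======  ==========
      [1000,1100) A-only    4 (3/1)  1010r 1020r 1030r 1040c
      [1100,1150) overlap   4 (2/2)  1102r 1104r 1106c 1108c
      [1150,1200) coding    4 (3/1)  1155r 1160r 1170r 1180c
      [1200,1250) B-coding  2 (1/1)  1210r 1220c
      [1250,1300) B-noncod  2 (2/0)  1260r 1270r
      outside               4 (1/3)  4000r 5000c 6000c 7000c
      ===================  =======  ==========

      Background rho_b = 12/20 = 0.6.

    * A 6-mer motif ACGTAC (column probability 0.85 on the consensus
      base) is planted at [1117,1123); the repeat background contains no
      other full-score window, so only reference windows containing the
      intact site pass the 5e-4 match gate. In particular every panel
      variant fails the gate, the disruption background CDF is all -inf,
      and f(v, D) = 0 for the documented variant: its motif entropy is
      exactly 1 and the motif component equals its population score.
    * Cross-species values: 3.0 on [1100,1200) (logistic -> 19/20), absent
      elsewhere; conserved structure on [1100,1150).
    * Knockdown: (RBPA, G1) fold change 3.0 >= 2.5.

    Documented variants:

    * v1 = chr1:1120 T>G (inside the motif, both peaks, noncoding, H=2):
      s_popcons = max over RBPs = RBPB noncoding = ((4/6)/0.6) * S(0.3),
      s_hub = plateau of noncoding H=2 stratum = ((2/4)/0.6) * S(0.2)
      (hot and ultra-hot coincide at H=2 on this tiny track, so the
      stratum takes its raw value), s_gerp = 19/20, s_structure = 1,
      s_kd = 1 (D > 3 since p_ref = 4^-6 and every word within one
      mismatch of the consensus has p > 19/4096), s_motif = s_popcons.
    * v2 = chr1:5000 (outside the regulome): all components 0.
    * v1 with tissue inputs: key regulator (RBPA slope 0.875, p~0.01),
      burdened peak (30 of the 40 somatic mutations in [1000,1200)),
      and key gene G1 -> tissue = 3, total = universal + 3.
    """
    L = 10_000
    seq = ("AACCGGTT" * (L // 8 + 1))[:L]
    site = "ACGTAC"
    seq = seq[:1117] + site + seq[1123:]
    genome = {"chr1": seq}

    def peaks_df(rows):
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "strand", "score"]
        )

    collections = {
        "RBPA": RBPPeakCollection("RBPA", ("HAND",), peaks_df([
            ("chr1", 1000, 1200, "+", 1000.0),
            ("chr1", 6100, 6200, "+", 1000.0),
        ])),
        "RBPB": RBPPeakCollection("RBPB", ("HAND",), peaks_df([
            ("chr1", 1100, 1300, "+", 1000.0),
        ])),
    }

    gene_spans = {
        "G01": (900, 1400), "G02": (6000, 6500), "G03": (2000, 2400),
        "G04": (2500, 2900), "G05": (3000, 3400), "G06": (3500, 3900),
        "G07": (4000, 4400), "G08": (4500, 4900), "G09": (7000, 7400),
        "G10": (8000, 8400),
    }
    ann_rows = []
    for g, (s, e) in sorted(gene_spans.items()):
        ann_rows.append(("chr1", s, e, "+", "gene", g, f"{g}.t1"))
        ann_rows.append(("chr1", s, e, "+", "transcript", g, f"{g}.t1"))
    ann_rows.append(("chr1", 1150, 1250, "+", "CDS", "G01", "G01.t1"))
    annotation = pd.DataFrame(ann_rows, columns=[
        "chrom", "start", "end", "strand", "feature", "gene_id",
        "transcript_id",
    ])

    rare_pos = [1010, 1020, 1030, 1102, 1104, 1155, 1160, 1170, 1210,
                1260, 1270, 4000]
    common_pos = [1040, 1106, 1108, 1180, 1220, 5000, 6000, 7000]
    prows = []
    for p in sorted(rare_pos + common_pos):
        ref = seq[p]
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref]
        prows.append(("chr1", p, ref, alt, 0.001 if p in rare_pos else 0.1))
    panel = pd.DataFrame(
        prows, columns=["chrom", "pos0", "ref", "alt", "daf"]
    )

    gerp = ValueTrack({"chr1": (
        np.array([1100], dtype=np.int64), np.array([1200], dtype=np.int64),
        np.array([3.0]),
    )})
    structure = IntervalSet.from_intervals([("chr1", 1100, 1150)])

    probs = np.full((6, 4), 0.05)
    for i, b in enumerate(site):
        probs[i, BASES.index(b)] = 0.85
    pwms = [PWM(motif_id="RBPA_invitro", probs=probs, rbp_id="RBPA")]

    kd_table = pd.DataFrame(
        [("RBPA", "G01", 3.0), ("RBPA", "G02", 1.0), ("RBPB", "G01", 1.1)],
        columns=["rbp_id", "gene_id", "fold_change"],
    )
    de_table = pd.DataFrame(
        [(g, 1 if g in {"G01", "G02", "G03"} else 0)
         for g in sorted(gene_spans)],
        columns=["gene_id", "status"],
    )
    som_pos = [1000 + 6 * i for i in range(1, 31)] + list(
        range(3000, 10000, 700)
    )
    somatic = pd.DataFrame({
        "chrom": "chr1",
        "pos0": np.sort(np.asarray(som_pos, dtype=np.int64)),
    })

    variants = pd.DataFrame(
        [("chr1", 1120, "T", "G"), ("chr1", 5000, seq[5000],
                                    {"A": "C", "C": "G", "G": "T",
                                     "T": "A"}[seq[5000]])],
        columns=["chrom", "pos0", "ref", "alt"],
    )

    # --- hand computation, straight from the definitions ------------------
    def S(f):
        return 1.0 + f * math.log2(f) + (1.0 - f) * math.log2(1.0 - f)

    rho_b = 12 / 20
    s_pop = ((4 / 6) / rho_b) * S(6 / 20)        # RBPB noncoding, the max
    s_hub = ((2 / 4) / rho_b) * S(4 / 20)        # noncoding H=2 stratum
    s_gerp = 1.0 / (1.0 + math.exp(-math.log(19.0) * (3.0 - 2.0)))
    expected = {
        "v1": {
            "s_popcons": s_pop, "s_hub": s_hub, "s_gerp": s_gerp,
            "s_structure": 1.0, "s_kd": 1.0, "s_motif": s_pop,
            "universal": s_pop + s_hub + s_gerp + 1.0 + 1.0 + s_pop,
        },
        "v2": {
            "s_popcons": 0.0, "s_hub": 0.0, "s_gerp": 0.0,
            "s_structure": 0.0, "s_kd": 0.0, "s_motif": 0.0,
            "universal": 0.0,
        },
        "v1_tissue": {
            "s_tissue": 3.0,
            "total": s_pop + s_hub + s_gerp + 2.0 + s_pop + 3.0,
        },
    }
    return WorkedExample(
        genome=genome, collections=collections, annotation=annotation,
        panel=panel, gerp=gerp, structure=structure, pwms=pwms,
        kd_table=kd_table, de_table=de_table, somatic=somatic,
        prior_genes={"G01"}, config=Config(), variants=variants,
        expected=expected,
    )


def build_world_context(world, config: Config | None = None):
    """Assemble a scoring context straight from an in-memory world."""
    from .scoring import build_context

    config = config or Config()
    kd = KnockdownTable(world.kd_table)
    return build_context(
        genome=world.genome, genome_id="synthetic",
        collections=world.collections, annotation=world.annotation,
        panel=VariantPanel(world.panel, config.daf_threshold),
        gerp=world.gerp, structure=world.structure, pwms=world.pwms,
        kd_table=kd, config=config,
    )
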