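"""Orchestration of the two scan presets (domestication scan, breed scan)
and the diversity/load report, with config handling and provenance headers.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .genotypes import (
    GenotypeMatrix,
    GenotypeError,
    PopulationMap,
    filter_maf,
    ld_prune,
    make_windows,
    read_popmap,
    read_vcf,
)
from . import diversity as dv
from . import polarize as pz
from . import fstats as fs
from . import sweepscan as sw

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run_diversity_report",
    "run_domestication_scan",
    "run_breed_scan",
    "run_fstats",
]


@dataclass
class RunConfig:
    """All file paths, population groupings and stage parameters for a run."""

    vcf: str = ""
    popmap: str = ""
    gerp: str | None = None
    exons_bed: str | None = None
    genes_gff3: str | None = None
    out_dir: str = "out"
    seed: int = 1

    # windowing
    window_width: int = 10_000
    window_step: int = 10_000

    # MAF cutoffs: SNP-mode scans drop MAF <= maf_snp, window-mode scans
    # drop MAF < maf_window
    maf_snp: float = 0.05
    maf_window: float = 0.10

    # PCA scan
    pca_k: int = 2
    top_fraction_pca: float = 0.001
    n_sample_snps: int = 100_000

    # SNP-mode PBS
    top_fraction_pbs: float = 0.005

    # window-mode thresholds
    top_fraction_window: float = 0.01
    n_sample_windows: int = 10_000

    # ROH
    roh_min_length: int = 1_000_000
    roh_min_snp: int = 15
    roh_max_het: int = 0
    roh_max_miss: int = 1
    roh_max_gap: int = 1_000_000
    roh_use_pruned: bool = True

    # LD decay
    ld_max_dist: int = 100_000
    ld_n_bins: int = 20
    ld_max_pairs: int = 200_000

    # domestication-scan grouping
    control_pop: str = ""  # wild control population
    background_pops: list[str] = field(default_factory=list)
    daf_exclude: list[str] = field(default_factory=list)

    # breed-scan grouping
    breed_target: str = ""
    breed_control: str = ""

    # LD pruning parameters
    prune_window_snps: int = 50
    prune_step_snps: int = 10
    prune_r2_max: float = 0.2

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise GenotypeError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        # out_dir excluded so reruns into different directories stay
        # byte-identical
        d = asdict(self)
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(cfg: RunConfig) -> str:
    return (
        f"# hgfscan {__version__} cfg={cfg.digest()} seed={cfg.seed} "
        f"estimators=hudson_fst,composite_r2_corrected\n"
    )


def _fmt(x) -> str:
    if isinstance(x, float):
        if math.isinf(x):
            return "inf" if x > 0 else "-inf"
        return f"{x:.6g}"
    return str(x)


def _write_tsv(path: Path, cfg: RunConfig, header: Sequence[str], rows) -> Path:
    with open(path, "w") as fh:
        fh.write(_provenance(cfg))
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")
    return path


def _load_inputs(cfg: RunConfig) -> tuple[GenotypeMatrix, PopulationMap]:
    if not cfg.vcf or not cfg.popmap:
        raise GenotypeError("config must set vcf and popmap paths")
    gm = read_vcf(cfg.vcf)
    pm = read_popmap(cfg.popmap)
    pm.check_against(gm)
    return gm, pm


def _contig_lengths(gm: GenotypeMatrix) -> dict[str, int]:
    out = {}
    for ctg in dict.fromkeys(gm.contig):
        out[str(ctg)] = int(gm.pos[gm.contig == ctg].max())
    return out


def _hgf_pops(pm: PopulationMap) -> list[str]:
    return [p for p in pm.populations if pm.role_of(p) != "outgroup"]


# ---------------------------------------------------------------------------
# Diversity / load report
# ---------------------------------------------------------------------------

def run_diversity_report(cfg: RunConfig) -> dict[str, Path]:
    """Windowed pi, singletons, LD decay, ROH summaries and (when the score
    and exon tracks are present) mutational load, one TSV per panel."""
    gm, pm = _load_inputs(cfg)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pops = _hgf_pops(pm)
    windows = make_windows(_contig_lengths(gm), cfg.window_width, cfg.window_step)
    paths: dict[str, Path] = {}

    rows = []
    for pop in pops:
        for rec in dv.nucleotide_diversity(gm, pm.samples_of(pop), windows, pop):
            w = rec.window
            rows.append((pop, w.contig, w.start, w.end, rec.pi, rec.n_sites))
    paths["pi"] = _write_tsv(
        out_dir / "pi_windows.tsv",
        cfg,
        ("pop", "contig", "start", "end", "pi", "n_sites"),
        rows,
    )

    rows = []
    for pop in pops:
        for sample, n in dv.count_singletons(gm, pm.samples_of(pop)).items():
            rows.append((sample, pop, n))
    paths["singletons"] = _write_tsv(
        out_dir / "singletons.tsv", cfg, ("sample", "pop", "n_singletons"), rows
    )

    rows = []
    for pop in pops:
        gmp = filter_maf(gm.take_samples(pm.samples_of(pop)), cfg.maf_snp)
        if gmp.n_variants < 2:
            logger.warning("ld_decay: no usable sites for %s", pop)
            continue
        for b in dv.ld_decay(
            gmp,
            gmp.sample_ids,
            max_dist=cfg.ld_max_dist,
            n_bins=cfg.ld_n_bins,
            max_pairs=cfg.ld_max_pairs,
            seed=cfg.seed,
        ):
            rows.append(
                (pop, b.bin_lo, b.bin_hi, b.r2_naive, b.r2_corrected, b.n_pairs)
            )
    paths["ld"] = _write_tsv(
        out_dir / "ld_decay.tsv",
        cfg,
        ("pop", "bin_lo", "bin_hi", "r2_naive", "r2_corrected", "n_pairs"),
        rows,
    )

    roh_input = (
        ld_prune(gm, cfg.prune_window_snps, cfg.prune_step_snps, cfg.prune_r2_max)
        if cfg.roh_use_pruned
        else gm
    )
    segments = []
    hgf_samples = pm.samples_of(*pops)
    for sample in hgf_samples:
        segments.extend(
            dv.detect_roh(
                roh_input,
                sample,
                min_length=cfg.roh_min_length,
                min_snp=cfg.roh_min_snp,
                max_het=cfg.roh_max_het,
                max_miss=cfg.roh_max_miss,
                max_gap=cfg.roh_max_gap,
            )
        )
    paths["roh_segments"] = _write_tsv(
        out_dir / "roh_segments.tsv",
        cfg,
        ("sample", "contig", "start", "end", "n_snps"),
        [(s.sample, s.contig, s.start, s.end, s.n_snps) for s in segments],
    )
    summary = dv.summarize_roh(segments, pm, hgf_samples)
    paths["roh_summary"] = _write_tsv(
        out_dir / "roh_summary.tsv",
        cfg,
        ("pop", "mean_n_roh", "mean_total_length"),
        [(p, c, t) for p, (c, t) in summary.items()],
    )

    outgroup_pops = pm.pops_with_role("outgroup")
    if cfg.gerp and cfg.exons_bed and outgroup_pops:
        anc = pz.assign_ancestral(gm, pm.samples_of(*outgroup_pops))
        records, log = pz.mutational_load(
            gm,
            anc,
            pz.read_gerp(cfg.gerp),
            pz.read_bed(cfg.exons_bed),
            pm,
        )
        logger.info("mutational_load reconciliation: %s", log)
        paths["load"] = _write_tsv(
            out_dir / "load.tsv",
            cfg,
            ("sample", "pop", "n_hom_derived", "n_het", "n_sites"),
            [
                (r.sample, r.population, r.n_hom_derived, r.n_het, r.n_sites_qualifying)
                for r in records
            ],
        )
    else:
        logger.warning(
            "load panel skipped: needs gerp + exons_bed tracks and an outgroup"
        )
    return paths


# ---------------------------------------------------------------------------
# Domestication scan: PCA outliers (top 0.1%) x SNP-PBS (top 0.5%)
# ---------------------------------------------------------------------------

def domestication_scan_core(gm: GenotypeMatrix, pm: PopulationMap, cfg: RunConfig) -> dict:
    """PCA-outlier x SNP-PBS consensus scan on in-memory data."""
    hgf_pops = _hgf_pops(pm)
    dom_pops = [p for p in hgf_pops if pm.role_of(p) == "domestic"]
    wild_pops = [p for p in hgf_pops if pm.role_of(p) == "wild"]
    if not dom_pops or not wild_pops:
        raise GenotypeError("scan needs both wild and domestic populations")
    control = cfg.control_pop or wild_pops[0]
    background = cfg.background_pops or [p for p in wild_pops if p != control]
    if not background:
        raise GenotypeError("no background populations available")

    hgf = gm.take_samples(pm.samples_of(*hgf_pops))
    pca_records, _ = sw.pca_outlier_scan(hgf, cfg.pca_k, maf_min=cfg.maf_snp)
    pca_thr = sw.empirical_threshold(
        [r.value for r in pca_records],
        cfg.n_sample_snps,
        cfg.top_fraction_pca,
        seed=cfg.seed,
        statistic="PCA_STAT",
    )
    pca_records = sw.apply_threshold(pca_records, pca_thr)

    groups = {
        "target": dom_pops,
        "control": [control],
        "background": background,
    }
    ft = fs.build_freq_table(filter_maf(gm, cfg.maf_snp), pm, groups)
    pbs_records = sw.pbs(ft, "target", "control", "background")
    pbs_thr = sw.empirical_threshold(
        [r.value for r in pbs_records],
        cfg.n_sample_snps,
        cfg.top_fraction_pbs,
        seed=cfg.seed,
        statistic="PBS",
    )
    pbs_records = sw.apply_threshold(pbs_records, pbs_thr)

    consensus = sw.overlap_calls(pca_records, pbs_records, mode="site")

    genes: dict[str, list] = {}
    if cfg.genes_gff3:
        genes = sw.annotate_genes(consensus, sw.read_gff3_genes(cfg.genes_gff3))

    daf = []
    outgroup_pops = pm.pops_with_role("outgroup")
    if outgroup_pops:
        anc = pz.assign_ancestral(gm, pm.samples_of(*outgroup_pops))
        pos_to_idx = {
            (str(gm.contig[j]), int(gm.pos[j])): j for j in range(gm.n_variants)
        }
        sites = [
            pos_to_idx[(c, s)] for c, s, _ in consensus if (c, s) in pos_to_idx
        ]
        daf = pz.daf_contrast(
            gm,
            anc,
            pm,
            wild_pops,
            dom_pops,
            np.array(sites, dtype=int),
            exclude_from_fixation=cfg.daf_exclude,
        )
    else:
        logger.warning("no outgroup: DAF contrast omitted")

    return {
        "pca": pca_records,
        "pbs": pbs_records,
        "pca_threshold": pca_thr,
        "pbs_threshold": pbs_thr,
        "consensus": consensus,
        "genes": genes,
        "daf": daf,
    }


def run_domestication_scan(cfg: RunConfig) -> dict:
    gm, pm = _load_inputs(cfg)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    res = domestication_scan_core(gm, pm, cfg)
    for name, records, thr in (
        ("pca_scan", res["pca"], res["pca_threshold"]),
        ("pbs_snp_scan", res["pbs"], res["pbs_threshold"]),
    ):
        _write_tsv(
            out_dir / f"{name}.tsv",
            cfg,
            ("contig", "pos", "stat", "value", "outlier"),
            [
                (r.contig, r.start, r.statistic, r.value, int(r.outlier))
                for r in records
            ],
        )
        _write_threshold(out_dir / f"{name}.threshold.tsv", cfg, thr)
    _write_tsv(
        out_dir / "consensus_sites.tsv",
        cfg,
        ("contig", "pos"),
        [(c, s) for c, s, _ in res["consensus"]],
    )
    _write_tsv(
        out_dir / "consensus_genes.tsv",
        cfg,
        ("gene_id", "n_support", "loci"),
        [
            (gid, len(loci), ",".join(f"{c}:{s}" for c, s, _ in loci))
            for gid, loci in sorted(res["genes"].items())
        ],
    )
    if res["daf"]:
        _write_tsv(
            out_dir / "daf_contrast.tsv",
            cfg,
            ("contig", "pos", "delta_daf", "fixed_in_domestic"),
            [
                (d["contig"], d["pos"], d["delta_daf"], int(d["fixed_in_domestic"]))
                for d in res["daf"]
            ],
        )
    return res


def _write_threshold(path: Path, cfg: RunConfig, thr: sw.Threshold) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(cfg))
        fh.write("stat\tquantile\tcutoff\tn_sampled\tseed\n")
        fh.write(
            f"{thr.statistic}\t{thr.quantile}\t{_fmt(thr.cutoff)}"
            f"\t{thr.n_sampled}\t{thr.seed}\n"
        )


# ---------------------------------------------------------------------------
# Breed scan: window-PBS x Pi-ratio (top 1% each)
# ---------------------------------------------------------------------------

def breed_scan_core(gm: GenotypeMatrix, pm: PopulationMap, cfg: RunConfig) -> dict:
    """Window-PBS x Pi-ratio overlap scan on in-memory data."""
    if not cfg.breed_target or not cfg.breed_control:
        raise GenotypeError("breed scan needs breed_target and breed_control")
    wild_pops = cfg.background_pops or [
        p for p in _hgf_pops(pm) if pm.role_of(p) == "wild"
    ]
    if not wild_pops:
        raise GenotypeError("breed scan needs background populations")

    # the window-mode filter drops MAF < maf_window (boundary exclusive),
    # realized as MAF <= just-below cutoff
    gmf = filter_maf(gm, cfg.maf_window - 1e-12)
    windows = make_windows(_contig_lengths(gm), cfg.window_width, cfg.window_step)
    groups = {
        "target": [cfg.breed_target],
        "control": [cfg.breed_control],
        "background": wild_pops,
    }
    ft = fs.build_freq_table(gmf, pm, groups)
    pbs_records = sw.pbs(ft, "target", "control", "background", windows=windows)
    pi_bg = dv.nucleotide_diversity(
        gmf, pm.samples_of(*wild_pops), windows, "background"
    )
    pi_tg = dv.nucleotide_diversity(
        gmf, pm.samples_of(cfg.breed_target), windows, "target"
    )
    ratio_records = sw.pi_ratio(pi_bg, pi_tg)

    pbs_thr = sw.empirical_threshold(
        [r.value for r in pbs_records],
        cfg.n_sample_windows,
        cfg.top_fraction_window,
        seed=cfg.seed,
        statistic="PBS",
    )
    finite_ratio = [r.value for r in ratio_records if math.isfinite(r.value)]
    ratio_thr = sw.empirical_threshold(
        finite_ratio if finite_ratio else [r.value for r in ratio_records],
        cfg.n_sample_windows,
        cfg.top_fraction_window,
        seed=cfg.seed,
        statistic="PI_RATIO",
    )
    pbs_records = sw.apply_threshold(pbs_records, pbs_thr)
    ratio_records = sw.apply_threshold(ratio_records, ratio_thr)

    consensus = sw.overlap_calls(pbs_records, ratio_records, mode="window")
    genes: dict[str, list] = {}
    if cfg.genes_gff3:
        genes = sw.annotate_genes(consensus, sw.read_gff3_genes(cfg.genes_gff3))
    return {
        "pbs": pbs_records,
        "pi_ratio": ratio_records,
        "pbs_threshold": pbs_thr,
        "ratio_threshold": ratio_thr,
        "consensus": consensus,
        "genes": genes,
    }


def run_breed_scan(cfg: RunConfig, ld_profile_region: tuple | None = None) -> dict:
    gm, pm = _load_inputs(cfg)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    res = breed_scan_core(gm, pm, cfg)
    pbs_records = res["pbs"]
    ratio_records = res["pi_ratio"]
    pbs_thr = res["pbs_threshold"]
    ratio_thr = res["ratio_threshold"]
    consensus = res["consensus"]
    genes = res["genes"]

    gmf = filter_maf(gm, cfg.maf_window - 1e-12)
    ld_profile = None
    if ld_profile_region is not None:
        ctg, start, end = ld_profile_region
        pos, mat, extent = sw.ld_block_profile(
            gmf, pm.samples_of(cfg.breed_target), ctg, start, end
        )
        ld_profile = (pos, mat, extent)
        _write_tsv(
            out_dir / "ld_block_profile.tsv",
            cfg,
            ["pos"] + [str(p) for p in pos],
            [[pos[i]] + list(mat[i]) for i in range(len(pos))],
        )

    for name, records, thr in (
        ("pbs_window_scan", pbs_records, pbs_thr),
        ("pi_ratio_scan", ratio_records, ratio_thr),
    ):
        _write_tsv(
            out_dir / f"{name}.tsv",
            cfg,
            ("contig", "start", "end", "stat", "value", "outlier"),
            [
                (r.contig, r.start, r.end, r.statistic, r.value, int(r.outlier))
                for r in records
            ],
        )
        _write_threshold(out_dir / f"{name}.threshold.tsv", cfg, thr)
    _write_tsv(
        out_dir / "consensus_windows.tsv",
        cfg,
        ("contig", "start", "end"),
        list(consensus),
    )
    _write_tsv(
        out_dir / "breed_genes.tsv",
        cfg,
        ("gene_id", "n_support", "loci"),
        [
            (gid, len(loci), ",".join(f"{c}:{s}-{e}" for c, s, e in loci))
            for gid, loci in sorted(genes.items())
        ],
    )
    res["ld_profile"] = ld_profile
    return res


# ---------------------------------------------------------------------------
# f-statistics report
# ---------------------------------------------------------------------------

def run_fstats(cfg: RunConfig, block_size: int = 1000) -> dict:
    """Outgroup-f3 for every (domestic, wild) pair and D statistics for every
    ordered (domestic-vs-domestic; wild) configuration."""
    gm, pm = _load_inputs(cfg)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outgroup_pops = pm.pops_with_role("outgroup")
    if not outgroup_pops:
        raise GenotypeError("f-statistics need an outgroup population")
    dom = [p for p in pm.populations if pm.role_of(p) == "domestic"]
    wild = [p for p in pm.populations if pm.role_of(p) == "wild"]
    groups = {p: [p] for p in dom + wild}
    groups["__outgroup__"] = outgroup_pops
    ft = fs.build_freq_table(gm, pm, groups)
    results = []
    for d in dom:
        for w in wild:
            results.append(fs.outgroup_f3(ft, "__outgroup__", d, w, block_size))
    for i, d1 in enumerate(dom):
        for d2 in dom[i + 1 :]:
            for w in wild:
                results.append(fs.d_stat(ft, d1, d2, w, "__outgroup__", block_size))
    _write_tsv(
        Path(cfg.out_dir) / "fstats.tsv",
        cfg,
        ("stat", "pops", "estimate", "SE", "Z", "n_sites", "n_blocks"),
        [
            (
                r.statistic,
                ",".join(r.populations),
                r.estimate,
                r.se,
                r.z,
                r.n_sites,
                r.n_blocks,
            )
            for r in results
        ],
    )
    return {"results": results}
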