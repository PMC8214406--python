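"""Coalescent synthetic-data generation.

Produces genotype matrices under a configurable split/pulse demography (the
default template: four guinea-fowl-like populations plus a deep outgroup,
with a 12-fold domestication bottleneck and two admixture pulses), plus
companion annotation tracks (exons, genes, per-site conservation scores) and
a deterministic sweep-injection distortion for benchmarking scan methods.

All times are entered in years before present and converted to generations
via ``generation_time_years``; the simulated ancestral allele is written as
REF so truth polarization is known downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .genotypes import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "DemographyConfig",
    "TruthRecord",
    "default_hgf_demography",
    "simulate_genotypes",
    "inject_sweep",
    "simulate_tracks",
    "write_bed",
    "write_gff3",
    "write_gerp",
]

CM_PER_MB_TO_PER_BP = 1e-8  # 1 cM/Mb == 1e-8 crossovers / bp / generation


class SimulationError(ValueError):
    pass


@dataclass
class DemographyConfig:
    """Populations, split tree, pulses and rates for the coalescent engine.

    ``splits`` are ``(child, parent, time_years_bp)`` triples: looking
    backward the child population merges into the parent.  ``pulses`` are
    ``(source, dest, time_years_bp, fraction)`` in *forward-time* direction:
    at that time a fraction of ``dest`` ancestry is replaced by ``source``.
    """

    populations: dict[str, dict]  # name -> {"role": str, "ne": float}
    splits: list[tuple[str, str, float]]
    pulses: list[tuple[str, str, float, float]] = field(default_factory=list)
    mutation_rate: float = 1.91e-9  # per site per year
    recombination_cm_per_mb: float = 1.7
    generation_time_years: float = 1.0
    contig_length: int = 5_000_000
    contig_name: str = "contig1"
    samples_per_pop: dict[str, int] = field(default_factory=dict)
    seed: int = 1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.mutation_rate <= 0 or self.recombination_cm_per_mb < 0:
            raise SimulationError("rates must be positive")
        if self.generation_time_years <= 0:
            raise SimulationError("generation_time_years must be positive")
        if self.contig_length < 10_000:
            raise SimulationError("contig_length must be >= 10 kb")
        names = set(self.populations)
        for child, parent, t in self.splits:
            if child not in names or parent not in names:
                raise SimulationError(f"split references unknown population: {child}->{parent}")
            if t <= 0:
                raise SimulationError("split times must be positive")
        for src, dst, t, m in self.pulses:
            if src not in names or dst not in names:
                raise SimulationError(f"pulse references unknown population: {src}->{dst}")
            if not 0 < m < 1:
                raise SimulationError(f"pulse fraction must be in (0,1), got {m}")
            if t <= 0:
                raise SimulationError("pulse times must be positive")
        # child must still exist (not yet merged away, looking backward) at
        # each event involving it
        merged_at = {c: t for c, _, t in self.splits}
        for src, dst, t, _m in self.pulses:
            for p in (src, dst):
                if p in merged_at and t >= merged_at[p]:
                    raise SimulationError(
                        f"pulse at {t} BP involves {p} after it merged at {merged_at[p]} BP"
                    )
        for child, parent, t in self.splits:
            if parent in merged_at and t > merged_at[parent]:
                raise SimulationError(
                    f"{child} splits from {parent} at {t} BP but {parent} "
                    f"already merged at {merged_at[parent]} BP"
                )

    @property
    def recombination_rate(self) -> float:
        """Per-bp per-generation crossover rate."""
        return self.recombination_cm_per_mb * CM_PER_MB_TO_PER_BP

    @property
    def mutation_rate_per_generation(self) -> float:
        return self.mutation_rate * self.generation_time_years

    def sample_size(self, pop: str) -> int:
        return int(self.samples_per_pop.get(pop, 8))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class TruthRecord:
    """Ground truth for a simulated dataset: parameters and injected sweeps."""

    seed: int
    config: dict
    sweeps: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        return cls(seed=d["seed"], config=d["config"], sweeps=d["sweeps"])


# Template population labels
WILD_SUDAN = "wild_sudan"
WILD_NIGERIA = "wild_nigeria"
DOM_NIGERIA = "dom_nigeria"
DOM_SUDAN = "dom_sudan"
OUTGROUP = "outgroup"

DOMESTICATION_SPLIT_YBP = 5452.0
DOM_DOM_SPLIT_YBP = 1261.0
PULSE_WILD_TO_WILD = (WILD_SUDAN, WILD_NIGERIA, 1448.0, 0.093)
PULSE_WILD_TO_DOM = (WILD_SUDAN, DOM_SUDAN, 154.0, 0.054)
BOTTLENECK_FOLD = 12.0


def default_hgf_demography(
    wild_ne: float = 20_000.0,
    wild_split_ybp: float = 25_000.0,
    outgroup_split_ybp: float = 3_000_000.0,
    outgroup_ne: float = 20_000.0,
    contig_length: int = 5_000_000,
    samples_per_pop: int = 8,
    outgroup_samples: int = 6,
    seed: int = 1,
) -> DemographyConfig:
    """Template demography: two wild + two domestic populations + outgroup.

    The domestic branch splits from wild Nigeria at 5,452 years BP with its
    Ne reduced 12-fold relative to the wild Ne; the two domestic populations
    split at 1,261 years BP; pulses wild Sudan -> wild Nigeria (9.3%, 1,448
    BP) and wild Sudan -> domestic Sudan (5.4%, 154 BP).  The wild-wild split
    and the outgroup divergence are free parameters (defaults 25 kya and 3
    Mya) chosen to be illustrative, not estimates.
    """
    dom_ne = wild_ne / BOTTLENECK_FOLD
    pops = {
        WILD_SUDAN: {"role": "wild", "ne": wild_ne},
        WILD_NIGERIA: {"role": "wild", "ne": wild_ne},
        DOM_NIGERIA: {"role": "domestic", "ne": dom_ne},
        DOM_SUDAN: {"role": "domestic", "ne": dom_ne},
        OUTGROUP: {"role": "outgroup", "ne": outgroup_ne},
    }
    splits = [
        (DOM_SUDAN, DOM_NIGERIA, DOM_DOM_SPLIT_YBP),
        (DOM_NIGERIA, WILD_NIGERIA, DOMESTICATION_SPLIT_YBP),
        (WILD_NIGERIA, WILD_SUDAN, wild_split_ybp),
        (WILD_SUDAN, OUTGROUP, outgroup_split_ybp),
    ]
    samples = {p: samples_per_pop for p in pops}
    samples[OUTGROUP] = outgroup_samples
    return DemographyConfig(
        populations=pops,
        splits=splits,
        pulses=[PULSE_WILD_TO_WILD, PULSE_WILD_TO_DOM],
        contig_length=contig_length,
        samples_per_pop=samples,
        seed=seed,
    )


def _build_msprime_demography(cfg: DemographyConfig):
    import msprime

    gen = cfg.generation_time_years
    dem = msprime.Demography()
    for name, spec in cfg.populations.items():
        dem.add_population(name=name, initial_size=float(spec["ne"]))
    # Forward pulse source->dest means, backward in time, lineages now in
    # dest jump into source with the pulse probability.
    for src, dst, t, m in cfg.pulses:
        dem.add_mass_migration(time=t / gen, source=dst, dest=src, proportion=m)
    for child, parent, t in cfg.splits:
        dem.add_mass_migration(time=t / gen, source=child, dest=parent, proportion=1.0)
    dem.sort_events()
    return dem


def simulate_genotypes(
    cfg: DemographyConfig,
) -> tuple[GenotypeMatrix, PopulationMap, TruthRecord]:
    """Neutral coalescent simulation under ``cfg``.

    Returns biallelic SNPs only (sites hit by recurrent mutation are
    dropped); REF is the simulated ancestral allele.  Deterministic for a
    fixed config (the seed feeds both ancestry and mutations).
    """
    import msprime

    dem = _build_msprime_demography(cfg)
    samples = {p: cfg.sample_size(p) for p in cfg.populations}
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        sequence_length=cfg.contig_length,
        recombination_rate=cfg.recombination_rate,
        random_seed=cfg.seed,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=cfg.mutation_rate_per_generation,
        random_seed=cfg.seed + 7_919,
    )

    pop_of_node = {}
    sample_ids: list[str] = []
    sample_nodes: list[tuple[int, int]] = []
    pm_assign: dict[str, str] = {}
    counters: dict[str, int] = {}
    for ind in ts.individuals():
        nodes = ind.nodes
        pop = ts.population(ts.node(nodes[0]).population).metadata["name"]
        counters[pop] = counters.get(pop, 0) + 1
        sid = f"{pop}_{counters[pop]:02d}"
        sample_ids.append(sid)
        sample_nodes.append((nodes[0], nodes[1]))
        pm_assign[sid] = pop

    contigs, pos, ref, alt, cols = [], [], [], [], []
    node_a = np.array([n for n, _ in sample_nodes])
    node_b = np.array([n for _, n in sample_nodes])
    for var in ts.variants():
        alleles = [a for a in var.alleles if a is not None]
        if len(alleles) != 2:
            continue
        g = var.genotypes
        dosage = (g[node_a] > 0).astype(np.int8) + (g[node_b] > 0).astype(np.int8)
        p = int(var.site.position) + 1  # 1-based VCF position
        if pos and p == pos[-1]:
            continue
        contigs.append(cfg.contig_name)
        pos.append(p)
        ref.append(alleles[0])
        alt.append(alleles[1])
        cols.append(dosage)

    if cols:
        gm = GenotypeMatrix(
            sample_ids=sample_ids,
            contig=np.array(contigs, dtype=object),
            pos=np.array(pos, dtype=np.int64),
            ref=np.array(ref, dtype=object),
            alt=np.array(alt, dtype=object),
            gt=np.vstack(cols).T,
        )
    else:  # pragma: no cover - degenerate tiny simulations
        gm = GenotypeMatrix.empty(sample_ids)
    roles = {p: spec["role"] for p, spec in cfg.populations.items()}
    pm = PopulationMap(assignments=pm_assign, roles=roles)
    truth = TruthRecord(seed=cfg.seed, config=json.loads(json.dumps(asdict(cfg))))
    return gm, pm, truth


def inject_sweep(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    contig: str,
    position: int,
    sweep_pops: Sequence[str],
    intensity: float,
    radius: int = 100_000,
    truth: TruthRecord | None = None,
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Deterministic haplotype-copying sweep distortion.

    Within ``radius`` of ``position`` a donor haplotype (the first haplotype
    of the first sample in ``sweep_pops``) is copied over the first
    ``intensity`` fraction of sweep-population haplotypes; between ``radius``
    and ``2*radius`` the copied fraction decays linearly to zero.  With
    ``intensity == 1`` every genotype inside the core radius becomes
    homozygous for the donor allele (local diversity is wiped out).
    """
    if not 0 <= intensity <= 1:
        raise SimulationError(f"intensity must be in [0, 1], got {intensity}")
    on_contig = gm.contig == contig
    if not on_contig.any():
        raise SimulationError(f"no variants on contig {contig!r}")
    max_pos = int(gm.pos[on_contig].max())
    if not 1 <= position <= max_pos:
        raise SimulationError(
            f"position {position} outside simulated contig [1, {max_pos}]"
        )
    if truth is None:
        truth = TruthRecord(seed=-1, config={})
    new_truth = TruthRecord(
        seed=truth.seed, config=truth.config, sweeps=list(truth.sweeps)
    )
    new_truth.sweeps.append(
        {
            "contig": contig,
            "position": int(position),
            "intensity": float(intensity),
            "radius": int(radius),
            "populations": list(sweep_pops),
        }
    )
    if intensity == 0:
        return gm, new_truth

    rows = gm.sample_indices(pm.samples_of(*sweep_pops))
    dist = np.abs(gm.pos - position)
    sel = on_contig & (dist <= 2 * radius)
    sites = np.flatnonzero(sel)
    gt = gm.gt.copy()
    n_hap = 2 * len(rows)
    donor_row = rows[0]
    for j in sites:
        d = dist[j]
        frac = intensity if d <= radius else intensity * (2 - d / radius)
        k = int(round(frac * n_hap))
        if k <= 0:
            continue
        donor_g = gt[donor_row, j]
        if donor_g == MISSING:
            continue
        donor_allele = 1 if donor_g >= 1 else 0
        g = gt[rows, j]
        h1 = (g >= 1).astype(np.int8)
        h2 = (g == 2).astype(np.int8)
        h1[g == MISSING] = 0
        h2[g == MISSING] = 0
        haps = np.empty(n_hap, dtype=np.int8)
        haps[0::2] = h1
        haps[1::2] = h2
        haps[:k] = donor_allele
        newg = haps[0::2] + haps[1::2]
        # genotypes untouched by the copy keep their missingness
        untouched = np.arange(len(rows)) * 2 >= k
        miss = (g == MISSING) & untouched
        newg[miss] = MISSING
        gt[rows, j] = newg
    out = GenotypeMatrix(
        sample_ids=list(gm.sample_ids),
        contig=gm.contig,
        pos=gm.pos,
        ref=gm.ref,
        alt=gm.alt,
        gt=gt,
    )
    return out, new_truth


# ---------------------------------------------------------------------------
# Companion tracks
# ---------------------------------------------------------------------------

def simulate_tracks(
    gm: GenotypeMatrix,
    contig_length: int,
    exon_fraction: float = 0.1,
    gene_count: int = 20,
    p_high_gerp: float = 0.3,
    seed: int = 1,
    contig: str | None = None,
):
    """Generate exon intervals (BED-style), gene models, and per-site GERP scores.

    Returns ``(exons, genes, gerp)`` where ``exons`` is a list of 0-based
    half-open ``(contig, start, end)`` tuples covering ~``exon_fraction`` of
    the contig, ``genes`` is a list of ``(contig, start_1based, end_1based,
    gene_id)`` and ``gerp`` is a list of ``(contig, pos_1based, score)`` for
    every variant in ``gm``.  Exonic sites get score > 2 with probability
    exactly ``p_high_gerp`` (high and low mixture components lie strictly
    above/below 2).
    """
    if not 0 < exon_fraction < 1:
        raise SimulationError("exon_fraction must be in (0,1)")
    if not 0 < p_high_gerp < 1:
        raise SimulationError("p_high_gerp must be in (0,1)")
    if contig is None:
        contig = str(gm.contig[0]) if gm.n_variants else "contig1"
    rng = np.random.default_rng(seed)

    # exons: fixed-length blocks on a regular grid covering ~exon_fraction
    exon_len = max(int(contig_length * exon_fraction / max(gene_count * 5, 1)), 50)
    n_exons = max(int(round(contig_length * exon_fraction / exon_len)), 1)
    spacing = contig_length / n_exons
    exons = []
    for i in range(n_exons):
        lo = int(i * spacing)
        hi = int(min(lo + exon_len, contig_length))
        jitter = int(rng.integers(0, max(int(spacing - exon_len), 1)))
        start = min(lo + jitter, contig_length - exon_len)
        exons.append((contig, start, start + exon_len))
    exons.sort(key=lambda e: e[1])
    # de-overlap defensively
    cleaned = []
    for ctg, s, e in exons:
        if cleaned and s < cleaned[-1][2]:
            s = cleaned[-1][2]
            if s >= e:
                continue
        cleaned.append((ctg, s, e))
    exons = cleaned

    # genes: tile the contig into gene_count slots
    genes = []
    slot = contig_length / gene_count
    for i in range(gene_count):
        lo = int(i * slot)
        span = int(slot * rng.uniform(0.5, 0.9))
        start0 = lo + int(rng.integers(0, max(int(slot) - span, 1)))
        genes.append((contig, start0 + 1, start0 + span, f"gene{i + 1:04d}"))

    # GERP scores at variant positions
    starts = np.array([s for _, s, _ in exons])
    ends = np.array([e for _, _, e in exons])
    scores = []
    for j in range(gm.n_variants):
        if str(gm.contig[j]) != contig:
            continue
        p0 = int(gm.pos[j]) - 1
        k = np.searchsorted(starts, p0, side="right") - 1
        exonic = k >= 0 and p0 < ends[k]
        if exonic and rng.random() < p_high_gerp:
            score = 2.0 + abs(rng.normal(1.0, 0.5)) + 1e-6
        else:
            score = 2.0 - abs(rng.normal(1.5, 1.0)) - 1e-6
        scores.append((contig, int(gm.pos[j]), float(score)))
    return exons, genes, scores


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for ctg, start, end in intervals:
            fh.write(f"{ctg}\t{start}\t{end}\n")


def write_gff3(genes, path) -> None:
    """Write gene records; coordinates are 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ctg, start, end, gid in genes:
            fh.write(
                f"{ctg}\thgfscan\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}\n"
            )


def write_gerp(scores, path) -> None:
    with open(path, "w") as fh:
        fh.write("#contig\tpos\tscore\n")
        for ctg, pos, score in scores:
            fh.write(f"{ctg}\t{pos}\t{score:.6f}\n")
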