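"""Diploid genotype matrices, population metadata, and the variant filters
shared by all downstream statistics.

Genotypes are stored as alt-allele dosages in ``{0, 1, 2}`` with ``-1`` for
missing calls.  Variant positions are kept 1-based (as in VCF); genomic
windows and BED-style intervals use 0-based half-open coordinates, converted
only at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "PopulationMap",
    "GenomicWindow",
    "read_vcf",
    "write_vcf",
    "read_popmap",
    "filter_maf",
    "ld_prune",
    "make_windows",
]

logger = logging.getLogger(__name__)

MISSING: int = -1

_VALID_ROLES = frozenset({"wild", "domestic", "outgroup"})
_BASES = frozenset("ACGT")


class GenotypeError(ValueError):
    """Raised on malformed genotype data or inconsistent metadata."""


@dataclass(frozen=True)
class GenomicWindow:
    """Half-open 0-based interval ``[start, end)`` on a contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise GenotypeError(
                f"window start must be < end, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def contains_pos(self, pos_1based: int) -> bool:
        return self.start < pos_1based <= self.end


@dataclass
class GenotypeMatrix:
    """Samples x variants alt-dosage matrix for biallelic SNPs.

    Attributes
    ----------
    sample_ids
        Unique ordered sample identifiers.
    contig, pos, ref, alt
        Per-variant arrays; ``pos`` is 1-based as in VCF and strictly
        increasing within each contig.
    gt
        ``int8`` array of shape ``(n_samples, n_variants)`` holding alt-allele
        dosages, ``MISSING`` (-1) for no-calls.
    """

    sample_ids: list[str]
    contig: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    gt: np.ndarray

    def __post_init__(self) -> None:
        self.contig = np.asarray(self.contig, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        self.validate()

    # -- basic shape -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    def validate(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise GenotypeError("duplicate sample ids")
        if self.gt.shape != (self.n_samples, self.n_variants):
            raise GenotypeError(
                f"gt shape {self.gt.shape} inconsistent with "
                f"{self.n_samples} samples x {self.n_variants} variants"
            )
        if self.n_variants:
            bad = ~np.isin(self.gt, (0, 1, 2, MISSING))
            if bad.any():
                raise GenotypeError("genotype values outside {0,1,2,MISSING}")
            for arr, name in ((self.ref, "ref"), (self.alt, "alt")):
                if any(len(a) != 1 or a not in _BASES for a in arr):
                    raise GenotypeError(f"non-SNP {name} allele present")
            if any(r == a for r, a in zip(self.ref, self.alt)):
                raise GenotypeError("ref == alt at some variant")
            for ctg in dict.fromkeys(self.contig):
                p = self.pos[self.contig == ctg]
                if np.any(np.diff(p) <= 0):
                    raise GenotypeError(
                        f"positions not strictly increasing on {ctg}"
                    )

    @classmethod
    def empty(cls, sample_ids: Sequence[str] = ()) -> "GenotypeMatrix":
        n = len(sample_ids)
        return cls(
            sample_ids=list(sample_ids),
            contig=np.empty(0, dtype=object),
            pos=np.empty(0, dtype=np.int64),
            ref=np.empty(0, dtype=object),
            alt=np.empty(0, dtype=object),
            gt=np.empty((n, 0), dtype=np.int8),
        )

    # -- subsetting --------------------------------------------------------
    def take_variants(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            contig=self.contig[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            gt=self.gt[:, idx],
        )

    def take_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise GenotypeError(f"samples absent from matrix: {missing}")
        rows = [lookup[s] for s in sample_ids]
        return GenotypeMatrix(
            sample_ids=list(sample_ids),
            contig=self.contig,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            gt=self.gt[rows, :],
        )

    def sample_indices(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise GenotypeError(f"samples absent from matrix: {missing}")
        return np.array([lookup[s] for s in sample_ids], dtype=np.intp)

    # -- allele counting ---------------------------------------------------
    def allele_counts(self, rows: np.ndarray | None = None):
        """Return ``(alt_count, called_alleles)`` per variant over ``rows``."""
        g = self.gt if rows is None else self.gt[rows, :]
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=0).astype(np.int64)
        an = 2 * called.sum(axis=0).astype(np.int64)
        return alt, an

    def alt_freq(self, rows: np.ndarray | None = None) -> np.ndarray:
        alt, an = self.allele_counts(rows)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(an > 0, alt / np.maximum(an, 1), np.nan)


@dataclass
class PopulationMap:
    """Sample -> population assignments plus population -> role declarations."""

    assignments: dict[str, str]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {p: r for p, r in self.roles.items() if r not in _VALID_ROLES}
        if bad:
            raise GenotypeError(f"invalid roles {bad}; must be in {sorted(_VALID_ROLES)}")

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.assignments.values()))

    def samples_of(self, *pops: str) -> list[str]:
        wanted = set(pops)
        unknown = wanted - set(self.populations)
        if unknown:
            raise GenotypeError(f"unknown populations: {sorted(unknown)}")
        return [s for s, p in self.assignments.items() if p in wanted]

    def pops_with_role(self, role: str) -> list[str]:
        return [p for p in self.populations if self.roles.get(p) == role]

    def role_of(self, pop: str) -> str:
        return self.roles.get(pop, "domestic")

    def check_against(self, gm: GenotypeMatrix) -> None:
        missing = [s for s in gm.sample_ids if s not in self.assignments]
        if missing:
            raise GenotypeError(
                f"samples without population assignment: {missing}"
            )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_vcf(path, region: str | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF (4.x, plain or bgzipped).

    Multiallelic records, indels, and symbolic alleles are dropped (count is
    logged).  Diploid GTs are decoded to alt dosage; half-calls and
    non-diploid calls become :data:`MISSING`.  ``region`` restricts output to
    one contig.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True, strict_gt=True)
    except Exception as exc:  # pragma: no cover - htslib error text varies
        raise GenotypeError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    contigs, pos, ref, alt = [], [], [], []
    gts = []
    n_dropped = 0
    for v in vcf:
        if region is not None and v.CHROM != region:
            continue
        if (
            len(v.ALT) != 1
            or len(v.REF) != 1
            or len(v.ALT[0]) != 1
            or v.REF not in _BASES
            or v.ALT[0] not in _BASES
        ):
            n_dropped += 1
            continue
        g = v.gt_types.astype(np.int8)  # 0/1/2, 3 == unknown
        g[g == 3] = MISSING
        contigs.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        gts.append(g)
    vcf.close()
    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic-SNP records", n_dropped)
    if not pos:
        return GenotypeMatrix.empty(samples)
    return GenotypeMatrix(
        sample_ids=samples,
        contig=np.array(contigs, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        gt=np.vstack(gts).T,
    )


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path, contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write a VCF 4.2 file with unphased GT calls."""
    path = Path(path)
    lengths: dict[str, int] = {}
    for ctg in dict.fromkeys(gm.contig):
        lengths[str(ctg)] = int(gm.pos[gm.contig == ctg].max())
    if contig_lengths:
        for ctg, ln in contig_lengths.items():
            lengths[str(ctg)] = max(int(ln), lengths.get(str(ctg), 0))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hgfscan\n")
        for ctg, ln in lengths.items():
            fh.write(f"##contig=<ID={ctg},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j in range(gm.n_variants):
            calls = "\t".join(_GT_STR[int(g)] for g in gm.gt[:, j])
            fh.write(
                f"{gm.contig[j]}\t{gm.pos[j]}\t.\t{gm.ref[j]}\t{gm.alt[j]}"
                f"\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_popmap(path) -> PopulationMap:
    """Read a ``sample<TAB>population[<TAB>role]`` TSV."""
    assignments: dict[str, str] = {}
    roles: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise GenotypeError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated columns"
                )
            sample, pop = parts[0], parts[1]
            if sample in assignments:
                raise GenotypeError(f"{path}:{lineno}: duplicate sample {sample!r}")
            assignments[sample] = pop
            if len(parts) == 3:
                prev = roles.get(pop)
                if prev is not None and prev != parts[2]:
                    raise GenotypeError(
                        f"{path}:{lineno}: conflicting role for population {pop!r}"
                    )
                roles[pop] = parts[2]
    return PopulationMap(assignments=assignments, roles=roles)


def write_popmap(pm: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        for sample, pop in pm.assignments.items():
            role = pm.roles.get(pop)
            if role is None:
                fh.write(f"{sample}\t{pop}\n")
            else:
                fh.write(f"{sample}\t{pop}\t{role}\n")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_maf(gm: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Drop SNPs with minor allele frequency <= ``min_maf``.

    Frequencies use non-missing calls only.  Monomorphic sites (including
    all-missing) are always removed.  The boundary is inclusive on the
    removal side: MAF exactly equal to ``min_maf`` is filtered out.
    """
    if not 0 <= min_maf <= 0.5:
        raise GenotypeError(f"min_maf must be in [0, 0.5], got {min_maf}")
    alt, an = gm.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(an > 0, alt / np.maximum(an, 1), 0.0)
    maf = np.minimum(p, 1 - p)
    keep = (alt > 0) & (alt < an) & (maf > min_maf)
    if gm.n_variants and not keep.any():
        logger.warning("filter_maf: all %d SNPs removed", gm.n_variants)
    return gm.take_variants(np.flatnonzero(keep))


def _window_r2(g: np.ndarray) -> np.ndarray:
    """Pairwise composite r^2 of dosage columns with pairwise-complete calls."""
    if (g == MISSING).any():
        m = np.ma.masked_equal(g.astype(float), MISSING)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.ma.corrcoef(m, rowvar=False)
        r2 = np.square(np.ma.filled(r, 0.0))
    else:
        gf = g.astype(float)
        sd = gf.std(axis=0)
        sd[sd == 0] = np.nan
        z = (gf - gf.mean(axis=0)) / sd
        with np.errstate(invalid="ignore"):
            r2 = np.square(z.T @ z / len(gf))
        r2 = np.nan_to_num(r2, nan=0.0)
    np.fill_diagonal(r2, 0.0)
    return r2


def ld_prune(
    gm: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 10,
    r2_max: float = 0.2,
) -> GenotypeMatrix:
    """Greedy in-window LD pruning of dosage-correlated SNP pairs.

    Sliding windows of ``window_snps`` SNPs advance by ``step_snps``; within a
    window, whenever a retained pair has r^2 > ``r2_max`` the later-positioned
    SNP is removed.  Passes repeat until a fixed point so that the pruned
    output itself contains no in-window pair above the cutoff (pruning is
    idempotent).
    """
    if not (window_snps > step_snps > 0):
        raise GenotypeError("require window_snps > step_snps > 0")
    if not 0 < r2_max <= 1:
        raise GenotypeError("r2_max must be in (0, 1]")
    current = gm
    while True:
        keep = np.ones(current.n_variants, dtype=bool)
        for ctg in dict.fromkeys(current.contig):
            idx = np.flatnonzero(current.contig == ctg)
            for start in range(0, max(len(idx) - 1, 1), step_snps):
                win = idx[start : start + window_snps]
                if len(win) < 2:
                    continue
                r2 = _window_r2(current.gt[:, win])
                for a in range(len(win)):
                    if not keep[win[a]]:
                        continue
                    for b in range(a + 1, len(win)):
                        if keep[win[b]] and r2[a, b] > r2_max:
                            keep[win[b]] = False
        if keep.all():
            return current
        current = current.take_variants(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def make_windows(
    contig_lengths: Mapping[str, int], width: int, step: int | None = None
) -> list[GenomicWindow]:
    """Tile contigs with ``[start, start+width)`` windows anchored at 0."""
    if step is None:
        step = width
    if width <= 0 or step <= 0:
        raise GenotypeError("window width and step must be positive")
    out: list[GenomicWindow] = []
    for ctg, length in contig_lengths.items():
        for start in range(0, int(length), step):
            out.append(GenomicWindow(str(ctg), start, min(start + width, int(length))))
    return out
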