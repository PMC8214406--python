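"""Selective-sweep scan machinery: Hudson FST and the population branch
statistic (SNP and window modes), windowed Pi-ratio, a PCA-based outlier
scan, empirical resampling thresholds, outlier overlap, gene annotation of
outlier loci, and dense regional LD profiles."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genotypes import (
    MISSING,
    GenomicWindow,
    GenotypeMatrix,
    GenotypeError,
    PopulationMap,
)
from .diversity import corrected_r2
from .fstats import FreqTable

__all__ = [
    "ScanRecord",
    "Threshold",
    "hudson_fst",
    "pbs",
    "pi_ratio",
    "pca_outlier_scan",
    "empirical_threshold",
    "apply_threshold",
    "overlap_calls",
    "annotate_genes",
    "read_gff3_genes",
    "ld_block_profile",
    "FST_CLAMP_HI",
]

FST_CLAMP_HI = 1.0 - 1e-6


@dataclass
class ScanRecord:
    """One statistic value at one locus (site or window)."""

    contig: str
    start: int  # site: 1-based position; window: 0-based start
    end: int  # site: == start; window: exclusive end
    statistic: str
    value: float
    outlier: bool = False
    pc: int | None = None

    @property
    def is_window(self) -> bool:
        return self.end > self.start

    def key(self):
        return (self.contig, self.start, self.end)


@dataclass(frozen=True)
class Threshold:
    statistic: str
    quantile: float
    cutoff: float
    n_sampled: int
    seed: int


# ---------------------------------------------------------------------------
# FST / PBS
# ---------------------------------------------------------------------------

def _hudson_components(ft: FreqTable, pop_a: str, pop_b: str):
    """Per-site Hudson numerator/denominator; NaN where undefined."""
    for p in (pop_a, pop_b):
        if p not in ft.freqs:
            raise GenotypeError(f"population {p!r} not in frequency table")
    pa, pb = ft.freqs[pop_a], ft.freqs[pop_b]
    na, nb = ft.sizes[pop_a].astype(float), ft.sizes[pop_b].astype(float)
    ok = np.isfinite(pa) & np.isfinite(pb) & (na >= 4) & (nb >= 4)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (
            (pa - pb) ** 2
            - pa * (1 - pa) / (na - 1)
            - pb * (1 - pb) / (nb - 1)
        )
        den = pa * (1 - pb) + pb * (1 - pa)
    num = np.where(ok, num, np.nan)
    den = np.where(ok, den, np.nan)
    return num, den


def hudson_fst(
    ft: FreqTable,
    pop_a: str,
    pop_b: str,
    windows: Sequence[GenomicWindow] | None = None,
) -> list[ScanRecord]:
    """Hudson FST per site, or ratio-of-averages per window if ``windows``.

    Sites where both populations are fixed for the same allele (zero
    denominator) are skipped; windows with no usable site are skipped.
    """
    num, den = _hudson_components(ft, pop_a, pop_b)
    if windows is None:
        out = []
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = num / den
        for j in np.flatnonzero(np.isfinite(fst)):
            out.append(
                ScanRecord(
                    contig=str(ft.contig[j]),
                    start=int(ft.pos[j]),
                    end=int(ft.pos[j]),
                    statistic="FST",
                    value=float(fst[j]),
                )
            )
        return out
    out = []
    usable = np.isfinite(num) & np.isfinite(den)
    for w in windows:
        sel = (
            (ft.contig == w.contig)
            & (ft.pos > w.start)
            & (ft.pos <= w.end)
            & usable
        )
        d = den[sel].sum()
        if not sel.any() or d == 0:
            continue
        out.append(
            ScanRecord(
                contig=w.contig,
                start=w.start,
                end=w.end,
                statistic="FST",
                value=float(num[sel].sum() / d),
            )
        )
    return out


def _branch_length(fst: np.ndarray) -> np.ndarray:
    """T = -ln(1 - FST) with FST clamped into [0, 1 - 1e-6]."""
    clamped = np.clip(fst, 0.0, FST_CLAMP_HI)
    return -np.log(1.0 - clamped)


def pbs(
    ft: FreqTable,
    target: str,
    control: str,
    background: str,
    windows: Sequence[GenomicWindow] | None = None,
) -> list[ScanRecord]:
    """Population branch statistic for ``target``.

    ``PBS = (T_tc + T_tb - T_cb) / 2`` with ``T = -ln(1 - FST)``; per-site
    Hudson FST in SNP mode, ratio-of-averages windowed FST in window mode.
    Loci where any pairwise FST is undefined are skipped.
    """
    pairs = [(target, control), (target, background), (control, background)]
    if windows is None:
        fsts = []
        for a, b in pairs:
            num, den = _hudson_components(ft, a, b)
            with np.errstate(invalid="ignore", divide="ignore"):
                fsts.append(num / den)
        ok = np.isfinite(fsts[0]) & np.isfinite(fsts[1]) & np.isfinite(fsts[2])
        t = [_branch_length(f[ok]) for f in fsts]
        values = (t[0] + t[1] - t[2]) / 2.0
        idx = np.flatnonzero(ok)
        return [
            ScanRecord(
                contig=str(ft.contig[j]),
                start=int(ft.pos[j]),
                end=int(ft.pos[j]),
                statistic="PBS",
                value=float(v),
            )
            for j, v in zip(idx, values)
        ]
    per_pair = {
        (a, b): {r.key(): r.value for r in hudson_fst(ft, a, b, windows)}
        for a, b in pairs
    }
    out = []
    for w in windows:
        key = (w.contig, w.start, w.end)
        try:
            f = [per_pair[p][key] for p in pairs]
        except KeyError:
            continue
        t = _branch_length(np.array(f))
        out.append(
            ScanRecord(
                contig=w.contig,
                start=w.start,
                end=w.end,
                statistic="PBS",
                value=float((t[0] + t[1] - t[2]) / 2.0),
            )
        )
    return out


def pi_ratio(
    pi_background: Sequence,
    pi_target: Sequence,
) -> list[ScanRecord]:
    """Windowed pi(background) / pi(target) on an identical tiling.

    Windows where the target has zero diversity but the background does not
    get ``+inf`` (the strongest sweep signal); windows with both zero are
    excluded.
    """
    if len(pi_background) != len(pi_target):
        raise GenotypeError("pi tracks have different window counts")
    out = []
    for rb, rt in zip(pi_background, pi_target):
        if rb.window != rt.window:
            raise GenotypeError(
                f"mismatched tilings: {rb.window} vs {rt.window}"
            )
        if rt.pi == 0 and rb.pi == 0:
            continue
        value = math.inf if rt.pi == 0 else rb.pi / rt.pi
        w = rb.window
        out.append(
            ScanRecord(
                contig=w.contig,
                start=w.start,
                end=w.end,
                statistic="PI_RATIO",
                value=value,
            )
        )
    return out


# ---------------------------------------------------------------------------
# PCA outlier scan
# ---------------------------------------------------------------------------

def pca_outlier_scan(
    gm: GenotypeMatrix,
    k: int,
    maf_min: float = 0.05,
) -> tuple[list[ScanRecord], np.ndarray]:
    """PCA-based per-SNP outlier statistic with genomic-inflation rescaling.

    Dosages are MAF-filtered, mean-imputed and standardized by
    ``sqrt(2 p (1-p))``; per-SNP z-scores come from regressing the
    standardized genotype on the top ``k`` orthonormal PCs; the test
    statistic is the Mahalanobis distance of the z-vector, rescaled so its
    median matches the chi-square(k) median.  Returns the records plus the
    per-SNP PC assignment (largest squared loading).
    """
    from .genotypes import filter_maf

    if k <= 0:
        raise GenotypeError(f"k must be >= 1, got {k}")
    gmf = filter_maf(gm, maf_min)
    n, m = gmf.n_samples, gmf.n_variants
    if k >= min(n, m):
        raise GenotypeError(f"k={k} must be < min(samples, SNPs)={min(n, m)}")
    g = gmf.gt.astype(float)
    g[g == MISSING] = np.nan
    p_hat = np.nanmean(g, axis=0) / 2.0
    col_mean = 2.0 * p_hat
    g = np.where(np.isnan(g), col_mean, g)
    scale = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    nonzero = scale > 0
    gmf = gmf.take_variants(np.flatnonzero(nonzero))
    g = (g[:, nonzero] - col_mean[nonzero]) / scale[nonzero]
    m = g.shape[1]

    u, s, vt = np.linalg.svd(g, full_matrices=False)
    u_k = u[:, :k]  # orthonormal sample-space PCs

    beta = u_k.T @ g  # (k, m) regression coefficients
    resid = g - u_k @ beta
    dof = max(n - k, 1)
    sigma = np.sqrt((resid ** 2).sum(axis=0) / dof)
    sigma[sigma == 0] = np.nan
    z = beta / sigma  # (k, m)
    z = np.nan_to_num(z, nan=0.0, posinf=0.0, neginf=0.0)

    zc = z - z.mean(axis=1, keepdims=True)
    cov = np.cov(zc)
    cov = np.atleast_2d(cov)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate fixtures
        cov_inv = np.linalg.pinv(cov)
    d2 = np.einsum("km,kl,lm->m", zc, cov_inv, zc)

    from scipy.stats import chi2

    gif = np.median(d2) / chi2.ppf(0.5, df=k)
    stat = d2 / gif if gif > 0 else d2
    pc_assign = np.argmax(z ** 2, axis=0) + 1  # 1-based PC index

    records = [
        ScanRecord(
            contig=str(gmf.contig[j]),
            start=int(gmf.pos[j]),
            end=int(gmf.pos[j]),
            statistic="PCA_STAT",
            value=float(stat[j]),
            pc=int(pc_assign[j]),
        )
        for j in range(m)
    ]
    return records, pc_assign


# ---------------------------------------------------------------------------
# Thresholds and overlaps
# ---------------------------------------------------------------------------

def empirical_threshold(
    scores: Sequence[float],
    n_sample: int,
    top_fraction: float,
    seed: int = 0,
    statistic: str = "",
) -> Threshold:
    """Empirical outlier cutoff from a random subsample of scores.

    Samples ``n_sample`` scores without replacement (or uses all scores if
    fewer are available) and returns the empirical ``1 - top_fraction``
    quantile as the cutoff; a locus is an outlier iff its score is strictly
    greater than the cutoff.  Infinite scores are kept (they exceed any
    finite cutoff).
    """
    scores = np.asarray(scores, dtype=float)
    scores = scores[~np.isnan(scores)]
    if len(scores) == 0:
        raise GenotypeError("no scores supplied")
    if not 0 < top_fraction < 1:
        raise GenotypeError("top_fraction must be in (0, 1)")
    if n_sample < len(scores):
        rng = np.random.default_rng(seed)
        sample = rng.choice(scores, size=n_sample, replace=False)
    else:
        sample = scores
    m = len(sample)
    rank = math.ceil((1.0 - top_fraction) * m)
    if rank < 1 or rank > m:
        raise GenotypeError(
            f"cannot take {1 - top_fraction} quantile of {m} scores"
        )
    cutoff = float(np.sort(sample)[rank - 1])
    return Threshold(
        statistic=statistic,
        quantile=1.0 - top_fraction,
        cutoff=cutoff,
        n_sampled=m,
        seed=seed,
    )


def apply_threshold(records: Sequence[ScanRecord], thr: Threshold) -> list[ScanRecord]:
    """Flag records with value strictly above the cutoff (returns new list)."""
    return [
        ScanRecord(
            contig=r.contig,
            start=r.start,
            end=r.end,
            statistic=r.statistic,
            value=r.value,
            outlier=bool(r.value > thr.cutoff),
            pc=r.pc,
        )
        for r in records
    ]


def overlap_calls(
    calls_a: Sequence[ScanRecord],
    calls_b: Sequence[ScanRecord],
    mode: str = "site",
) -> list[tuple]:
    """Consensus loci flagged as outliers in both scans.

    ``mode='site'`` and ``mode='window'`` intersect identical loci; when one
    scan is per-site and the other windowed, a site matches any window
    containing it.
    """
    a_out = [r for r in calls_a if r.outlier]
    b_out = [r for r in calls_b if r.outlier]
    a_windows = any(r.is_window for r in a_out)
    b_windows = any(r.is_window for r in b_out)
    if a_windows == b_windows:
        keys_b = {r.key() for r in b_out}
        return sorted({r.key() for r in a_out} & keys_b)
    sites = a_out if b_windows else b_out
    wins = b_out if b_windows else a_out
    hits = set()
    for s in sites:
        for w in wins:
            if w.contig == s.contig and w.start < s.start <= w.end:
                hits.add(s.key())
    return sorted(hits)


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def read_gff3_genes(path) -> list[tuple[str, int, int, str]]:
    """Extract gene features as (contig, start_1based, end_1based, gene_id)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise GenotypeError(
                    f"{path}:{lineno}: malformed GFF3 line "
                    f"({len(parts)} columns, expected 9)"
                )
            if parts[2] != "gene":
                continue
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise GenotypeError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            gid = None
            for kv in parts[8].split(";"):
                if kv.startswith("ID="):
                    gid = kv[3:]
                    break
            if gid is None:
                gid = f"{parts[0]}:{start}-{end}"
            genes.append((parts[0], start, end, gid))
    return genes


def annotate_genes(
    loci: Sequence[tuple],
    genes: Sequence[tuple[str, int, int, str]],
) -> dict[str, list[tuple]]:
    """Map loci to the genes they support.

    ``loci`` are ``(contig, start, end)`` keys as produced by
    :func:`overlap_calls` (sites have ``start == end`` holding the 1-based
    position; windows are 0-based half-open).  A site supports a gene when
    it lies within the gene span; a window supports every gene it overlaps.
    """
    support: dict[str, list[tuple]] = {}
    for locus in loci:
        ctg, start, end = locus[0], int(locus[1]), int(locus[2])
        for g_ctg, g_start, g_end, gid in genes:
            if g_ctg != ctg:
                continue
            if start == end:  # site, 1-based
                hit = g_start <= start <= g_end
            else:  # window, 0-based half-open vs 1-based inclusive gene
                hit = start < g_end and g_start <= end
            if hit:
                support.setdefault(gid, []).append(locus)
    return support


# ---------------------------------------------------------------------------
# Regional LD profile
# ---------------------------------------------------------------------------

def ld_block_profile(
    gm: GenotypeMatrix,
    samples: Sequence[str],
    contig: str,
    start: int,
    end: int,
    max_snps: int = 2000,
    block_r2_cutoff: float = 0.5,
):
    """Dense corrected-r^2 matrix over the SNPs of a region.

    Returns ``(positions, matrix, block_extent)`` where ``block_extent`` is
    the longest run of consecutive SNPs whose median pairwise r^2 exceeds
    ``block_r2_cutoff``, reported as ``(start_pos, end_pos, n_snps)`` or
    ``None``.
    """
    sel = (gm.contig == contig) & (gm.pos > start) & (gm.pos <= end)
    idx = np.flatnonzero(sel)
    if len(idx) > max_snps:
        raise GenotypeError(
            f"region holds {len(idx)} SNPs (> cap {max_snps}); thin the "
            "region or raise max_snps"
        )
    rows = gm.sample_indices(samples)
    g = gm.gt[np.ix_(rows, idx)].astype(float)
    g[g == MISSING] = np.nan
    n_snp = g.shape[1]
    r2 = np.ones((n_snp, n_snp))
    ncomp = np.full((n_snp, n_snp), float(len(rows)))
    if np.isnan(g).any():
        for a in range(n_snp):
            for b in range(a + 1, n_snp):
                x, y = g[:, a], g[:, b]
                ok = ~(np.isnan(x) | np.isnan(y))
                n = int(ok.sum())
                ncomp[a, b] = ncomp[b, a] = n
                if n < 2 or x[ok].std() == 0 or y[ok].std() == 0:
                    r2[a, b] = r2[b, a] = np.nan
                    continue
                r = np.corrcoef(x[ok], y[ok])[0, 1]
                r2[a, b] = r2[b, a] = r * r
    else:
        sd = g.std(axis=0)
        z = (g - g.mean(axis=0)) / np.where(sd == 0, np.nan, sd)
        c = z.T @ z / len(rows)
        r2 = np.square(np.nan_to_num(c, nan=0.0))
        np.fill_diagonal(r2, 1.0)
    mat = corrected_r2(r2, ncomp)
    np.fill_diagonal(mat, 1.0)

    extent = None
    if n_snp >= 2:
        off_diag = mat.copy()
        np.fill_diagonal(off_diag, np.nan)
        med = np.nanmedian(off_diag, axis=1)
        above = med > block_r2_cutoff
        best = (0, -1)
        run_start = None
        for i in range(n_snp + 1):
            if i < n_snp and above[i]:
                if run_start is None:
                    run_start = i
            elif run_start is not None:
                if i - run_start > best[1] - best[0] + 1 or best[1] < best[0]:
                    best = (run_start, i - 1)
                run_start = None
        if best[1] >= best[0] and best[1] > best[0]:
            pos = gm.pos[idx]
            extent = (int(pos[best[0]]), int(pos[best[1]]), best[1] - best[0] + 1)
    return gm.pos[idx].copy(), mat, extent
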