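"""Ancestral-allele polarization from outgroup genotypes, derived-allele
frequencies, and conservation-weighted mutational-load accounting.

A site is polarized only when the outgroup samples agree on a homozygous
genotype; polarized sites yield derived-allele frequencies and, combined
with a per-site conservation-score track and exon intervals, per-individual
counts of homozygous-derived genotypes at constrained exonic sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genotypes import MISSING, GenotypeMatrix, GenotypeError, PopulationMap

__all__ = [
    "ANC_REF",
    "ANC_ALT",
    "UNASSIGNED",
    "AncestralAssignment",
    "LoadRecord",
    "assign_ancestral",
    "derived_freq",
    "daf_contrast",
    "mutational_load",
    "read_gerp",
    "read_bed",
]

ANC_REF = 0
ANC_ALT = 1
UNASSIGNED = -1


@dataclass
class AncestralAssignment:
    """Per-variant ancestral state: ANC_REF, ANC_ALT or UNASSIGNED."""

    state: np.ndarray  # int8 per variant
    n_informative: np.ndarray  # outgroup genotypes used per variant

    @property
    def assigned(self) -> np.ndarray:
        return self.state != UNASSIGNED


@dataclass(frozen=True)
class LoadRecord:
    sample: str
    population: str
    n_hom_derived: int
    n_het: int
    n_hom_ancestral: int
    n_missing: int
    n_sites_qualifying: int

    @property
    def rate_per_covered_site(self) -> float:
        covered = self.n_sites_qualifying - self.n_missing
        return self.n_hom_derived / covered if covered else float("nan")


def assign_ancestral(
    gm: GenotypeMatrix,
    outgroup_samples: Sequence[str],
    strict: bool = True,
    min_informative: int = 1,
) -> AncestralAssignment:
    """Polarize each variant from outgroup homozygous consensus.

    In strict mode (default) every outgroup sample must be called and carry
    the same homozygous genotype; relaxed mode requires at least
    ``min_informative`` called outgroups, unanimous among non-missing calls.
    Any heterozygote or disagreement leaves the site unassigned.
    """
    if not outgroup_samples:
        raise GenotypeError("no outgroup samples supplied")
    rows = gm.sample_indices(outgroup_samples)
    g = gm.gt[rows, :]
    called = g != MISSING
    n_called = called.sum(axis=0)
    any_het = (g == 1).any(axis=0)
    all_ref = np.logical_and(called, g == 0).sum(axis=0) == n_called
    all_alt = np.logical_and(called, g == 2).sum(axis=0) == n_called
    if strict:
        informative_ok = n_called == len(rows)
    else:
        informative_ok = n_called >= min_informative
    state = np.full(gm.n_variants, UNASSIGNED, dtype=np.int8)
    ok = informative_ok & ~any_het & (n_called > 0)
    state[ok & all_ref] = ANC_REF
    state[ok & all_alt] = ANC_ALT
    return AncestralAssignment(state=state, n_informative=n_called.astype(np.int64))


def derived_freq(
    gm: GenotypeMatrix,
    anc: AncestralAssignment,
    samples: Sequence[str],
) -> np.ndarray:
    """Per-site derived-allele frequency in ``samples``; NaN where unassigned
    or uncalled."""
    rows = gm.sample_indices(samples)
    alt, an = gm.allele_counts(rows)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(an > 0, alt / np.maximum(an, 1), np.nan)
    daf = np.where(anc.state == ANC_REF, p_alt, 1.0 - p_alt)
    daf[anc.state == UNASSIGNED] = np.nan
    return daf


def daf_contrast(
    gm: GenotypeMatrix,
    anc: AncestralAssignment,
    pm: PopulationMap,
    wild_pops: Sequence[str],
    domestic_pops: Sequence[str],
    sites: np.ndarray,
    exclude_from_fixation: Sequence[str] = (),
) -> list[dict]:
    """Per-site derived-allele-frequency contrast at selected sites.

    For each site index in ``sites`` reports the pooled wild vs pooled
    domestic |dDAF| and whether the derived allele is fixed (frequency 1) in
    every listed domestic population not in ``exclude_from_fixation``.
    """
    wild_rows = pm.samples_of(*wild_pops)
    dom_rows = pm.samples_of(*domestic_pops)
    daf_wild = derived_freq(gm, anc, wild_rows)
    daf_dom = derived_freq(gm, anc, dom_rows)
    checked = [p for p in domestic_pops if p not in set(exclude_from_fixation)]
    per_pop = {p: derived_freq(gm, anc, pm.samples_of(p)) for p in checked}
    out = []
    for j in sites:
        j = int(j)
        fixed = bool(checked) and all(
            np.isfinite(per_pop[p][j]) and per_pop[p][j] == 1.0 for p in checked
        )
        delta = (
            abs(daf_wild[j] - daf_dom[j])
            if np.isfinite(daf_wild[j]) and np.isfinite(daf_dom[j])
            else float("nan")
        )
        out.append(
            {
                "site": j,
                "contig": str(gm.contig[j]),
                "pos": int(gm.pos[j]),
                "delta_daf": delta,
                "fixed_in_domestic": fixed,
                "assigned": bool(anc.state[j] != UNASSIGNED),
            }
        )
    return out


def read_gerp(path) -> dict[tuple[str, int], float]:
    """Read a ``contig<TAB>pos(1-based)<TAB>score`` table."""
    out: dict[tuple[str, int], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GenotypeError(f"{path}:{lineno}: expected 3 columns")
            out[(parts[0], int(parts[1]))] = float(parts[2])
    return out


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read 0-based half-open intervals from a BED file."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GenotypeError(f"{path}:{lineno}: expected >= 3 columns")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def _in_intervals(
    contig: np.ndarray, pos: np.ndarray, intervals: Sequence[tuple[str, int, int]]
) -> np.ndarray:
    """Membership of 1-based positions in 0-based half-open intervals."""
    mask = np.zeros(len(pos), dtype=bool)
    by_ctg: dict[str, list[tuple[int, int]]] = {}
    for ctg, s, e in intervals:
        by_ctg.setdefault(ctg, []).append((s, e))
    for ctg, ivs in by_ctg.items():
        ivs.sort()
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        sel = np.flatnonzero(contig == ctg)
        p0 = pos[sel] - 1
        k = np.searchsorted(starts, p0, side="right") - 1
        ok = (k >= 0) & (p0 < ends[np.clip(k, 0, len(ends) - 1)])
        mask[sel[ok]] = True
    return mask


def mutational_load(
    gm: GenotypeMatrix,
    anc: AncestralAssignment,
    gerp: Mapping[tuple[str, int], float],
    exons: Sequence[tuple[str, int, int]],
    pm: PopulationMap,
    gerp_min: float = 2.0,
    samples: Sequence[str] | None = None,
) -> tuple[list[LoadRecord], dict]:
    """Homozygous-derived genotype counts at constrained exonic sites.

    A site qualifies iff it is polarized, its conservation score is strictly
    greater than ``gerp_min``, it falls in an exon interval, and it is
    polymorphic within the union of non-outgroup samples.  Returns one
    record per analyzed individual plus a reconciliation log (sites missing
    from the score table etc.).
    """
    if samples is None:
        out_pops = set(pm.pops_with_role("outgroup"))
        samples = [
            s for s in gm.sample_ids if pm.assignments.get(s) not in out_pops
        ]
    rows = gm.sample_indices(samples)

    scores = np.full(gm.n_variants, np.nan)
    n_absent = 0
    for j in range(gm.n_variants):
        key = (str(gm.contig[j]), int(gm.pos[j]))
        if key in gerp:
            scores[j] = gerp[key]
        else:
            n_absent += 1
    exonic = _in_intervals(gm.contig, gm.pos, exons)
    alt, an = gm.allele_counts(rows)
    polymorphic = (alt > 0) & (alt < an)
    with np.errstate(invalid="ignore"):
        qualifying = anc.assigned & (scores > gerp_min) & exonic & polymorphic
    q_idx = np.flatnonzero(qualifying)

    g = gm.gt[np.ix_(rows, q_idx)]
    state = anc.state[q_idx]
    derived_dosage = np.where(state == ANC_REF, g, 2 - g)
    derived_dosage[g == MISSING] = MISSING

    records = []
    for i, s in enumerate(samples):
        d = derived_dosage[i]
        records.append(
            LoadRecord(
                sample=s,
                population=pm.assignments.get(s, ""),
                n_hom_derived=int((d == 2).sum()),
                n_het=int((d == 1).sum()),
                n_hom_ancestral=int((d == 0).sum()),
                n_missing=int((d == MISSING).sum()),
                n_sites_qualifying=len(q_idx),
            )
        )
    log = {
        "n_sites_total": gm.n_variants,
        "n_sites_no_score": n_absent,
        "n_sites_qualifying": len(q_idx),
        "n_sites_unassigned": int((~anc.assigned).sum()),
        "n_sites_nonexonic": int((~exonic).sum()),
    }
    return records, log
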