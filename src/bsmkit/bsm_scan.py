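"""Breed-specific marker (BSM) scan.

The core algorithm: a (site, allele) pair is a breed-specific marker for a
target breed when the allele is carried by every target sample except a
relaxation budget of at most ``r`` (non-carriers and missing calls both draw
from the budget), and by zero samples of the pooled comparison panel (every
other breed in the cohort).  The default relaxation r = 1 accommodates a
single deviating animal per breed, e.g. one that clusters with a sibling
breed; r = 0 gives the strict scan.

Two interpretations of breed-privateness are offered:

* ``allele`` mode (default): the private allele may be carried het or hom —
  the standard private-allele notion in population genetics.
* ``genotype`` mode: all target samples share one unordered genotype that no
  comparison sample has.

Missing comparison-panel calls do not disqualify a site by default
(``permissive``); ``strict`` mode requires fully observed absence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .io_breeds import BreedMap, Cohort, VariantSite, write_vcf

__all__ = [
    "ScanConfig",
    "BsmRecord",
    "carriers",
    "scan_breed",
    "brute_force_scan",
    "scan_all",
]


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of one breed scan."""

    target_breed: str
    relaxation: int = 1
    mode: Literal["allele", "genotype"] = "allele"
    outgroup_missing_policy: Literal["permissive", "strict"] = "permissive"
    allow_ref_allele: bool = True

    def __post_init__(self) -> None:
        if self.relaxation < 0:
            raise ValueError("relaxation must be non-negative")
        if self.mode not in ("allele", "genotype"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.outgroup_missing_policy not in ("permissive", "strict"):
            raise ValueError(f"unknown policy {self.outgroup_missing_policy!r}")


@dataclass(frozen=True)
class BsmRecord:
    """One discovered marker: a (site, allele, breed) hit with its evidence."""

    site: VariantSite
    allele_index: int
    breed: str
    target_carriers: int
    target_noncarriers: int
    target_missing: int
    outgroup_carriers: int
    outgroup_missing: int
    genotype: tuple[int, int] | None = None  # set in genotype mode only

    def sort_key(self):
        return (
            self.site.chrom,
            self.site.pos,
            self.allele_index,
            self.genotype if self.genotype is not None else (-1, -1),
        )

    def key(self):
        """Identity key matching simulator truth-table rows."""
        return (self.site.chrom, self.site.pos, self.allele_index, self.breed)


def carriers(
    genotypes: np.ndarray,
    allele_index: int,
    n_alleles: int,
    mode: str = "allele",
    target_genotype: tuple[int, int] | None = None,
) -> tuple[int, int, int]:
    """Count (carriers, non-carriers, missing) over a sample set at one site.

    ``genotypes`` is an ``(n_samples, 2)`` slice of allele indices with -1 for
    missing.  In ``allele`` mode a sample carries iff its call contains
    ``allele_index`` at least once; in ``genotype`` mode iff its unordered
    genotype equals ``target_genotype``.  The three counts sum to the sample
    count.
    """
    if not (0 <= allele_index < n_alleles):
        raise ValueError(f"allele index {allele_index} out of range for {n_alleles} alleles")
    g = np.asarray(genotypes)
    missing = (g < 0).any(axis=1)
    if mode == "allele":
        carry = (~missing) & ((g[:, 0] == allele_index) | (g[:, 1] == allele_index))
    elif mode == "genotype":
        if target_genotype is None:
            raise ValueError("genotype mode requires a target genotype")
        lo, hi = sorted(target_genotype)
        gl = np.minimum(g[:, 0], g[:, 1])
        gh = np.maximum(g[:, 0], g[:, 1])
        carry = (~missing) & (gl == lo) & (gh == hi)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n_carry = int(carry.sum())
    n_miss = int(missing.sum())
    return n_carry, len(g) - n_carry - n_miss, n_miss


def _partition(cohort: Cohort, breed_map: BreedMap, target: str) -> tuple[np.ndarray, np.ndarray]:
    breed_map.validate_cohort(cohort)
    tgt = np.array([breed_map.assignments[s] == target for s in cohort.samples])
    if tgt.sum() < 2:
        raise ValueError(f"target breed {target!r} has fewer than 2 samples in the cohort")
    if (~tgt).sum() == 0:
        raise ValueError("empty comparison panel: cohort contains only the target breed")
    return np.where(tgt)[0], np.where(~tgt)[0]


def scan_breed(cohort: Cohort, breed_map: BreedMap, config: ScanConfig) -> list[BsmRecord]:
    """Scan every (site, allele) pair for markers private to one breed.

    Vectorized over samples; output strictly sorted by (chrom, pos,
    allele_index) and independent of input sample order.
    """
    tgt_idx, out_idx = _partition(cohort, breed_map, config.target_breed)
    if config.relaxation >= len(tgt_idx):
        raise ValueError(
            f"relaxation {config.relaxation} >= target sample count {len(tgt_idx)}"
        )
    records: list[BsmRecord] = []
    G = cohort.genotypes
    for i, site in enumerate(cohort.sites):
        gt_t = G[i, tgt_idx]
        gt_o = G[i, out_idx]
        miss_o = int((gt_o < 0).any(axis=1).sum())
        if config.outgroup_missing_policy == "strict" and miss_o > 0:
            continue
        if config.mode == "allele":
            first = 0 if config.allow_ref_allele else 1
            for a in range(first, site.n_alleles):
                c_t, nc_t, m_t = carriers(gt_t, a, site.n_alleles)
                if nc_t + m_t > config.relaxation:
                    continue
                c_o, _, _ = carriers(gt_o, a, site.n_alleles)
                if c_o:
                    continue
                records.append(
                    BsmRecord(site, a, config.target_breed, c_t, nc_t, m_t, 0, miss_o)
                )
        else:
            # candidate genotypes: those observed among target samples
            obs = gt_t[(gt_t >= 0).all(axis=1)]
            cands = sorted({(int(min(a, b)), int(max(a, b))) for a, b in obs})
            for geno in cands:
                if not config.allow_ref_allele and geno == (0, 0):
                    continue
                c_t, nc_t, m_t = carriers(
                    gt_t, geno[0], site.n_alleles, mode="genotype", target_genotype=geno
                )
                if nc_t + m_t > config.relaxation:
                    continue
                c_o, _, _ = carriers(
                    gt_o, geno[0], site.n_alleles, mode="genotype", target_genotype=geno
                )
                if c_o:
                    continue
                records.append(
                    BsmRecord(
                        site, geno[0], config.target_breed, c_t, nc_t, m_t, 0, miss_o,
                        genotype=geno,
                    )
                )
    records.sort(key=BsmRecord.sort_key)
    return records


def brute_force_scan(cohort: Cohort, breed_map: BreedMap, config: ScanConfig) -> list[BsmRecord]:
    """Naive reference scan: plain Python loops over sites, alleles, samples.

    Shares no counting code with :func:`scan_breed`; intended for tests and
    oracle adjudication on small cohorts.
    """
    breed_map.validate_cohort(cohort)
    targets = [s for s in cohort.samples if breed_map.assignments[s] == config.target_breed]
    others = [s for s in cohort.samples if breed_map.assignments[s] != config.target_breed]
    if len(targets) < 2:
        raise ValueError(f"target breed {config.target_breed!r} has fewer than 2 samples")
    if not others:
        raise ValueError("empty comparison panel")
    if config.relaxation >= len(targets):
        raise ValueError("relaxation >= target sample count")

    col = {s: j for j, s in enumerate(cohort.samples)}

    def call_of(i: int, name: str):
        j = col[name]
        a, b = cohort.genotypes[i, j]
        if a < 0 or b < 0:
            return None
        return (int(a), int(b))

    records: list[BsmRecord] = []
    for i, site in enumerate(cohort.sites):
        out_calls = [call_of(i, s) for s in others]
        out_missing = sum(1 for c in out_calls if c is None)
        if config.outgroup_missing_policy == "strict" and out_missing > 0:
            continue
        tgt_calls = [call_of(i, s) for s in targets]
        if config.mode == "allele":
            alleles = range(0 if config.allow_ref_allele else 1, site.n_alleles)
            for a in alleles:
                n_carry = n_non = n_miss = 0
                for c in tgt_calls:
                    if c is None:
                        n_miss += 1
                    elif a in c:
                        n_carry += 1
                    else:
                        n_non += 1
                if n_non + n_miss > config.relaxation:
                    continue
                if any(c is not None and a in c for c in out_calls):
                    continue
                records.append(
                    BsmRecord(site, a, config.target_breed, n_carry, n_non, n_miss, 0, out_missing)
                )
        else:
            cands = sorted({tuple(sorted(c)) for c in tgt_calls if c is not None})
            for geno in cands:
                if not config.allow_ref_allele and geno == (0, 0):
                    continue
                n_carry = n_non = n_miss = 0
                for c in tgt_calls:
                    if c is None:
                        n_miss += 1
                    elif tuple(sorted(c)) == geno:
                        n_carry += 1
                    else:
                        n_non += 1
                if n_non + n_miss > config.relaxation:
                    continue
                if any(c is not None and tuple(sorted(c)) == geno for c in out_calls):
                    continue
                records.append(
                    BsmRecord(
                        site, geno[0], config.target_breed, n_carry, n_non, n_miss,
                        0, out_missing, genotype=geno,
                    )
                )
    records.sort(key=BsmRecord.sort_key)
    return records


def scan_all(
    cohort: Cohort,
    breed_map: BreedMap,
    breeds: list[str],
    config: ScanConfig | None = None,
    out_dir: str | None = None,
) -> dict[str, list[BsmRecord]]:
    """Run :func:`scan_breed` for each breed against the shared panel.

    If ``out_dir`` is given, writes one ``{breed}_bsm.vcf`` per breed plus a
    ``bsm_summary.tsv`` with per-breed marker counts.
    """
    if not breeds:
        raise ValueError("breeds list is empty")
    template = config or ScanConfig(target_breed="")
    results: dict[str, list[BsmRecord]] = {}
    for breed in breeds:
        results[breed] = scan_breed(cohort, breed_map, replace(template, target_breed=breed))
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        site_pos = {id(s): i for i, s in enumerate(cohort.sites)}
        lines = ["breed\tn_markers\tn_sites_tested\trelaxation\tmode"]
        for breed, recs in results.items():
            idx = sorted({site_pos[id(r.site)] for r in recs})
            safe = breed.replace("/", "_").replace(" ", "_")
            write_vcf(cohort, os.path.join(out_dir, f"{safe}_bsm.vcf"), subset=idx)
            lines.append(
                f"{breed}\t{len(recs)}\t{cohort.n_sites}\t{template.relaxation}\t{template.mode}"
            )
        with open(os.path.join(out_dir, "bsm_summary.tsv"), "w") as fh:
            fh.write("\n".join(lines) + "\n")
    return results
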