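"""VCF and breed-map IO and the core cohort containers.

A :class:`Cohort` is the dense genotype container every analysis consumes:
an ordered sample list, an ordered (chrom, pos)-sorted site list, and a
``(n_sites, n_samples, 2)`` array of allele indices with ``-1`` marking a
missing allele.  Genotypes are strictly diploid; half-missing calls such as
``./1`` are treated as fully missing so that carrier logic downstream has an
unambiguous carrier / non-carrier / unknown trichotomy.

Coordinates are 1-based inclusive (VCF convention) everywhere in the public
API; interval arithmetic elsewhere converts to 0-based half-open at the
boundary.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

MISSING = -1
"""Sentinel allele index for a missing call (never a valid allele index)."""

_ALLELE_RE = re.compile(r"^[ACGTN]+$", re.IGNORECASE)

__all__ = [
    "MISSING",
    "VariantSite",
    "GenotypeCall",
    "Cohort",
    "BreedMap",
    "VcfFormatError",
    "read_vcf",
    "write_vcf",
    "read_breed_map",
]


class VcfFormatError(ValueError):
    """Raised for malformed VCF or breed-map input."""


@dataclass(frozen=True)
class VariantSite:
    """One variant locus: chromosome, 1-based position, REF and ALT alleles."""

    chrom: str
    pos: int
    id: str | None
    ref: str
    alts: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VcfFormatError(f"position must be >= 1, got {self.pos}")
        if not self.alts:
            raise VcfFormatError(f"{self.chrom}:{self.pos}: no ALT alleles")
        for allele in (self.ref, *self.alts):
            if not _ALLELE_RE.match(allele):
                raise VcfFormatError(
                    f"{self.chrom}:{self.pos}: unsupported allele {allele!r} "
                    "(symbolic/breakend alleles are rejected)"
                )

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alts)

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    def allele(self, index: int) -> str:
        return self.ref if index == 0 else self.alts[index - 1]


@dataclass(frozen=True)
class GenotypeCall:
    """An unordered diploid call: pair of allele indices, or missing.

    ``phased`` is retained from the input but ignored by every computation.
    """

    alleles: tuple[int, int] | None
    phased: bool = False

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    def dosage(self, allele_index: int = 1) -> int | None:
        """Count of ``allele_index`` in the call, or None if missing."""
        if self.alleles is None:
            return None
        return sum(1 for a in self.alleles if a == allele_index)

    def carries(self, allele_index: int) -> bool | None:
        if self.alleles is None:
            return None
        return allele_index in self.alleles


@dataclass
class Cohort:
    """Samples x sites genotype table.

    ``genotypes`` has shape ``(n_sites, n_samples, 2)`` (allele indices,
    ``MISSING`` = -1 in both slots for a missing call); ``phased`` has shape
    ``(n_sites, n_samples)``.
    """

    samples: list[str]
    sites: list[VariantSite]
    genotypes: np.ndarray
    phased: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise VcfFormatError("duplicate sample names")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
        if self.genotypes.shape != (len(self.sites), len(self.samples), 2):
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        if self.phased is None:
            self.phased = np.zeros(self.genotypes.shape[:2], dtype=bool)
        prev: tuple[str, int] | None = None
        seen_chroms: set[str] = set()
        for s in self.sites:
            if prev is not None and s.chrom == prev[0] and s.pos < prev[1]:
                raise VcfFormatError(
                    f"unsorted positions: {s.chrom}:{s.pos} after {prev[0]}:{prev[1]}"
                )
            if prev is not None and s.chrom != prev[0] and s.chrom in seen_chroms:
                raise VcfFormatError(f"chromosome {s.chrom} occurs in two blocks")
            seen_chroms.add(s.chrom)
            prev = (s.chrom, s.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def missing_mask(self) -> np.ndarray:
        """(n_sites, n_samples) boolean mask, True where the call is missing."""
        return (self.genotypes < 0).any(axis=2)

    def call(self, site_index: int, sample_index: int) -> GenotypeCall:
        a, b = self.genotypes[site_index, sample_index]
        if a < 0 or b < 0:
            return GenotypeCall(None)
        return GenotypeCall((int(a), int(b)), bool(self.phased[site_index, sample_index]))

    def sample_index(self, names: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not in cohort") from None

    def subset_sites(self, indices: Sequence[int]) -> "Cohort":
        idx = list(indices)
        return Cohort(
            samples=list(self.samples),
            sites=[self.sites[i] for i in idx],
            genotypes=self.genotypes[idx].copy(),
            phased=self.phased[idx].copy(),
        )


@dataclass
class BreedMap:
    """Sample -> breed assignment plus breed -> {river, swamp} type."""

    assignments: dict[str, str]
    breed_type: dict[str, str]

    VALID_TYPES = ("river", "swamp")

    def __post_init__(self) -> None:
        for breed, btype in self.breed_type.items():
            if btype not in self.VALID_TYPES:
                raise ValueError(f"unknown breed type {btype!r} for breed {breed!r}")
        for sample, breed in self.assignments.items():
            if breed not in self.breed_type:
                raise ValueError(f"sample {sample!r} assigned to untyped breed {breed!r}")

    @property
    def breeds(self) -> list[str]:
        return sorted(self.breed_type)

    def samples_of(self, breed: str) -> list[str]:
        return [s for s, b in self.assignments.items() if b == breed]

    def breed_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {b: 0 for b in self.breed_type}
        for breed in self.assignments.values():
            sizes[breed] += 1
        return sizes

    def type_sizes(self) -> dict[str, int]:
        sizes = {t: 0 for t in self.VALID_TYPES}
        for breed in self.assignments.values():
            sizes[self.breed_type[breed]] += 1
        return sizes

    def validate_cohort(self, cohort: Cohort) -> None:
        unmapped = [s for s in cohort.samples if s not in self.assignments]
        if unmapped:
            raise ValueError(f"samples not in breed map: {unmapped}")


def _parse_region(region: str) -> tuple[str, int, int]:
    m = re.match(r"^(.+):(\d+)-(\d+)$", region)
    if not m:
        raise ValueError(f"region {region!r} not of the form chrom:start-end")
    return m.group(1), int(m.group(2)), int(m.group(3))


def read_vcf(path: str, region: str | None = None) -> Cohort:
    """Read a VCF 4.x file (plain or bgzipped) into a :class:`Cohort`.

    Every record must carry a GT FORMAT field.  ``./.``, ``.`` and
    half-missing calls map to MISSING; ``/`` and ``|`` separators are both
    accepted, with phase recorded but unused.  ``region`` is a 1-based
    inclusive ``chrom:start-end`` filter applied while streaming (no index
    required).  Haploid or polyploid calls are a hard error.
    """
    want = _parse_region(region) if region else None
    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise VcfFormatError(f"duplicate sample names in {path}")

    sites: list[VariantSite] = []
    geno_rows: list[np.ndarray] = []
    phase_rows: list[np.ndarray] = []
    prev: tuple[str, int] | None = None
    for v in vcf:
        if v.FORMAT is None or "GT" not in v.FORMAT:
            raise VcfFormatError(f"{v.CHROM}:{v.POS}: record has no GT field")
        if prev is not None and v.CHROM == prev[0] and v.POS < prev[1]:
            raise VcfFormatError(
                f"unsorted VCF: {v.CHROM}:{v.POS} after position {prev[1]}"
            )
        prev = (v.CHROM, v.POS)
        if want is not None:
            chrom, lo, hi = want
            if v.CHROM != chrom or not (lo <= v.POS <= hi):
                continue
        site = VariantSite(
            chrom=v.CHROM,
            pos=v.POS,
            id=v.ID,
            ref=v.REF,
            alts=tuple(v.ALT),
        )
        row = np.full((len(samples), 2), MISSING, dtype=np.int16)
        prow = np.zeros(len(samples), dtype=bool)
        for j, g in enumerate(v.genotypes):
            # cyvcf2 genotype entry: allele indices then a phased flag
            alleles, phased_flag = g[:-1], g[-1]
            if len(alleles) == 1 and int(alleles[0]) < 0:
                # a bare "." call: fully missing, not haploid
                continue
            if len(alleles) != 2:
                raise VcfFormatError(
                    f"{v.CHROM}:{v.POS} sample {samples[j]}: "
                    f"non-diploid genotype of ploidy {len(alleles)}"
                )
            a, b = int(alleles[0]), int(alleles[1])
            if a < 0 or b < 0:
                a = b = MISSING
            elif max(a, b) > len(site.alts):
                raise VcfFormatError(
                    f"{v.CHROM}:{v.POS} sample {samples[j]}: allele index out of range"
                )
            row[j] = (a, b)
            prow[j] = bool(phased_flag)
        sites.append(site)
        geno_rows.append(row)
        phase_rows.append(prow)
    vcf.close()

    genotypes = (
        np.stack(geno_rows) if geno_rows else np.empty((0, len(samples), 2), dtype=np.int16)
    )
    phased = np.stack(phase_rows) if phase_rows else np.empty((0, len(samples)), dtype=bool)
    return Cohort(samples=samples, sites=sites, genotypes=genotypes, phased=phased)


def _format_call(alleles: np.ndarray, phased: bool) -> str:
    a, b = int(alleles[0]), int(alleles[1])
    sep = "|" if phased else "/"
    if a < 0 or b < 0:
        return f".{sep}."
    return f"{a}{sep}{b}"


def write_vcf(cohort: Cohort, path: str, subset: Iterable[int] | None = None) -> None:
    """Write a GT-only VCF 4.2 file; byte-stable for identical inputs.

    ``subset`` selects site indices (any order; output stays sorted because
    cohort sites are).  An empty subset yields a header-only VCF with all
    sample columns.
    """
    indices = sorted(subset) if subset is not None else range(cohort.n_sites)
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bsmkit\n")
        seen: list[str] = []
        for s in cohort.sites:
            if s.chrom not in seen:
                seen.append(s.chrom)
        for chrom in seen:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.samples)
            + "\n"
        )
        for i in indices:
            s = cohort.sites[i]
            calls = "\t".join(
                _format_call(cohort.genotypes[i, j], bool(cohort.phased[i, j]))
                for j in range(cohort.n_samples)
            )
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.id or '.'}\t{s.ref}\t{','.join(s.alts)}"
                f"\t.\t.\t.\tGT\t{calls}\n"
            )


def read_breed_map(path: str) -> BreedMap:
    """Read a TSV with columns ``sample``, ``breed``, ``type`` into a BreedMap.

    A sample listed twice with conflicting breed is an error; an empty file is
    an error, not an empty map.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"breed map {path} is empty") from None
    required = {"sample", "breed", "type"}
    if not required.issubset(df.columns):
        raise ValueError(f"breed map must have columns {sorted(required)}")
    if df.empty:
        raise ValueError(f"breed map {path} has no rows")

    assignments: dict[str, str] = {}
    breed_type: dict[str, str] = {}
    for row in df.itertuples(index=False):
        sample, breed, btype = row.sample, row.breed, row.type
        if btype not in BreedMap.VALID_TYPES:
            raise ValueError(f"unknown type {btype!r} for sample {sample!r}")
        if sample in assignments and assignments[sample] != breed:
            raise ValueError(
                f"sample {sample!r} listed with conflicting breeds "
                f"{assignments[sample]!r} and {breed!r}"
            )
        if breed in breed_type and breed_type[breed] != btype:
            raise ValueError(f"breed {breed!r} listed with conflicting types")
        assignments[sample] = breed
        breed_type[breed] = btype
    return BreedMap(assignments=assignments, breed_type=breed_type)
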