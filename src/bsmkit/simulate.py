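"""Synthetic cohort generator with planted breed-specific markers.

Emulates the statistical shape of a multi-breed resequencing panel: a small
target group per breed (4-5 animals), larger comparison panels, breed-level
drift, missing calls, and — the ground truth for the scan — alleles planted
to be private to one breed with a configurable number of dropout samples.

Drift follows the Balding-Nichols model: given ancestral frequency p and
differentiation F (Fst), each breed's site frequency is drawn from
Beta(p(1-F)/F, (1-p)(1-F)/F); genotypes are then Binomial(2, p_breed).
Planted sites overwrite the background: the private ALT allele is given
(homozygous) to all target samples except the configured dropout count, and
to no other sample.  Missingness is i.i.d. per cell but never erodes a
planted site's target carriers.  Everything is driven by one integer seed;
identical configs give byte-identical output.

Linked cohorts for LD work are generated from two ancestral haplotypes per
block: along a block, each of a sample's two haplotypes keeps its ancestral
assignment between adjacent sites with probability (1-c)^distance (c =
per-bp recombination), so c = 0 yields complete within-block LD and c = 1
free recombination.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from .io_breeds import BreedMap, Cohort, VariantSite, write_vcf

__all__ = ["SimConfig", "TruthRow", "TruthTable", "simulate_cohort",
           "simulate_linked", "emit_fixture", "load_config"]

_NUCS = np.array(list("ACGT"))
CHROM_LENGTH = 10_000_000  # single synthetic chromosome, bp


@dataclass
class SimConfig:
    """Generator parameters; ``seed`` is mandatory (no silent entropy)."""

    breeds: list[tuple[str, int]]
    n_sites: int = 500
    fst: float = 0.1
    ancestral_freq_dist: tuple[float, float] | float = (1.0, 1.0)  # Beta(a, b) or fixed p
    missing_rate: float = 0.0
    planted: dict[str, tuple[int, int]] = field(default_factory=dict)  # breed -> (count, dropout)
    linkage: tuple[int, float] | None = None  # (block_length bp, recomb_per_bp)
    n_chromosomes: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.breeds or any(n <= 0 for _, n in self.breeds):
            raise ValueError("each breed needs a positive sample count")
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")
        if not (0 <= self.fst < 1):
            raise ValueError("fst must be in [0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        total_planted = sum(c for c, _ in self.planted.values())
        if total_planted > self.n_sites:
            raise ValueError("planted count exceeds n_sites")
        for breed, (count, dropout) in self.planted.items():
            sizes = dict(self.breeds)
            if breed not in sizes:
                raise ValueError(f"planted breed {breed!r} not in breeds")
            if dropout >= sizes[breed]:
                raise ValueError(f"dropout must be < breed size for {breed!r}")
        if self.linkage is not None:
            block, c = self.linkage
            if block <= 0:
                raise ValueError("block_length must be positive")
            if not (0 <= c <= 1):
                raise ValueError("recomb_per_bp must be in [0, 1]")


@dataclass(frozen=True)
class TruthRow:
    chrom: str
    pos: int
    allele_index: int
    breed: str
    n_carrier_targets: int
    n_dropout_targets: int

    def key(self):
        return (self.chrom, self.pos, self.allele_index, self.breed)


@dataclass
class TruthTable:
    rows: list[TruthRow]

    def keys(self) -> set:
        return {r.key() for r in self.rows}

    def for_breed(self, breed: str) -> list[TruthRow]:
        return [r for r in self.rows if r.breed == breed]


def _draw_sites(rng: np.random.Generator, n_sites: int, n_chromosomes: int):
    """Sorted positions on one or more synthetic chromosomes with random
    REF/ALT nucleotides."""
    per = np.array_split(np.arange(n_sites), n_chromosomes)
    sites = []
    for ci, chunk in enumerate(per):
        k = len(chunk)
        pos = np.sort(rng.choice(CHROM_LENGTH, size=k, replace=False) + 1)
        for p in pos:
            ref, alt = rng.choice(4, size=2, replace=False)
            sites.append(VariantSite(
                chrom=f"chr{ci + 1}", pos=int(p), id=None,
                ref=str(_NUCS[ref]), alts=(str(_NUCS[alt]),),
            ))
    return sites


def _breed_freqs(rng: np.random.Generator, p: np.ndarray, fst: float, n_breeds: int):
    """Balding-Nichols per-breed frequencies around ancestral p."""
    if fst == 0:
        return np.tile(p, (n_breeds, 1))
    a = p * (1 - fst) / fst
    b = (1 - p) * (1 - fst) / fst
    # guard against zero shape parameters at p in {0, 1}
    a = np.clip(a, 1e-9, None)
    b = np.clip(b, 1e-9, None)
    return rng.beta(a[None, :], b[None, :], size=(n_breeds, len(p)))


def simulate_cohort(config: SimConfig) -> tuple[Cohort, BreedMap, TruthTable]:
    """Generate a drifted multi-breed cohort with planted private markers.

    Returns the cohort, the breed map (breeds alternate river/swamp types for
    plumbing purposes) and the planted-marker truth table.
    """
    rng = np.random.default_rng(config.seed)
    sites = _draw_sites(rng, config.n_sites, config.n_chromosomes)
    n_sites = len(sites)

    samples: list[str] = []
    breed_of: dict[str, str] = {}
    for breed, n in config.breeds:
        for i in range(n):
            name = f"{breed}_{i + 1}"
            samples.append(name)
            breed_of[name] = breed
    n_samples = len(samples)

    if isinstance(config.ancestral_freq_dist, (int, float)):
        anc = np.full(n_sites, float(config.ancestral_freq_dist))
    else:
        a, b = config.ancestral_freq_dist
        anc = rng.beta(a, b, size=n_sites)
    freqs = _breed_freqs(rng, anc, config.fst, len(config.breeds))

    genotypes = np.empty((n_sites, n_samples, 2), dtype=np.int16)
    col = 0
    for bi, (breed, n) in enumerate(config.breeds):
        hap = rng.random((n_sites, n, 2)) < freqs[bi][:, None, None]
        genotypes[:, col:col + n] = np.sort(hap.astype(np.int16), axis=2)
        col += n

    # plant private markers on disjoint site sets, one breed at a time
    truth_rows: list[TruthRow] = []
    available = list(range(n_sites))
    protected = np.zeros((n_sites, n_samples), dtype=bool)
    sizes = dict(config.breeds)
    for breed in sorted(config.planted):
        count, dropout = config.planted[breed]
        chosen = rng.choice(len(available), size=count, replace=False)
        chosen_sites = sorted(available[i] for i in chosen)
        available = [s for s in available if s not in set(chosen_sites)]
        tgt_cols = np.array([j for j, s in enumerate(samples) if breed_of[s] == breed])
        for si in chosen_sites:
            genotypes[si, :, :] = 0
            drop = rng.choice(len(tgt_cols), size=dropout, replace=False) if dropout else []
            carrier_cols = np.array([c for i, c in enumerate(tgt_cols) if i not in set(np.atleast_1d(drop))])
            genotypes[si, carrier_cols, :] = 1
            protected[si, carrier_cols] = True
            truth_rows.append(TruthRow(
                chrom=sites[si].chrom, pos=sites[si].pos, allele_index=1,
                breed=breed, n_carrier_targets=len(carrier_cols),
                n_dropout_targets=dropout,
            ))

    if config.missing_rate > 0:
        miss = rng.random((n_sites, n_samples)) < config.missing_rate
        miss &= ~protected  # never erode a planted site's target carriers
        genotypes[miss] = -1

    breed_type = {
        breed: ("river" if i % 2 == 0 else "swamp")
        for i, (breed, _) in enumerate(config.breeds)
    }
    breed_map = BreedMap(assignments=breed_of, breed_type=breed_type)
    cohort = Cohort(samples=samples, sites=sites, genotypes=genotypes)
    truth_rows.sort(key=lambda r: (r.chrom, r.pos, r.breed))
    return cohort, breed_map, TruthTable(rows=truth_rows)


def simulate_linked(config: SimConfig) -> tuple[Cohort, BreedMap]:
    """Generate a cohort of linked loci from two ancestral haplotypes per block.

    Site positions are laid out every 100 bp; blocks of ``block_length`` bp
    partition them.  Along a block each haplotype's ancestral assignment
    persists between adjacent sites with probability (1-c)^distance.
    """
    if config.linkage is None:
        raise ValueError("config.linkage must be set")
    block_length, c = config.linkage
    rng = np.random.default_rng(config.seed)

    n_sites = config.n_sites
    spacing = 100
    pos = np.arange(1, n_sites + 1) * spacing
    sites = []
    for p in pos:
        ref, alt = rng.choice(4, size=2, replace=False)
        sites.append(VariantSite(
            chrom="chr1", pos=int(p), id=None, ref=str(_NUCS[ref]), alts=(str(_NUCS[alt]),),
        ))

    samples: list[str] = []
    breed_of: dict[str, str] = {}
    for breed, n in config.breeds:
        for i in range(n):
            name = f"{breed}_{i + 1}"
            samples.append(name)
            breed_of[name] = breed
    n_samples = len(samples)

    if isinstance(config.ancestral_freq_dist, (int, float)):
        anc = np.full(n_sites, float(config.ancestral_freq_dist))
    else:
        a, b = config.ancestral_freq_dist
        anc = rng.beta(a, b, size=n_sites)

    genotypes = np.empty((n_sites, n_samples, 2), dtype=np.int16)
    block_id = (pos - 1) // block_length
    col = 0
    for breed, n in config.breeds:
        # two ancestral haplotypes per site for this breed
        anc_hap = (rng.random((2, n_sites)) < anc[None, :]).astype(np.int16)
        hap_alleles = np.empty((n_sites, 2 * n), dtype=np.int16)
        assign = rng.integers(0, 2, size=2 * n)
        for s in range(n_sites):
            if s > 0:
                if block_id[s] != block_id[s - 1]:
                    assign = rng.integers(0, 2, size=2 * n)
                else:
                    d = int(pos[s] - pos[s - 1])
                    keep = rng.random(2 * n) < (1 - c) ** d
                    fresh = rng.integers(0, 2, size=2 * n)
                    assign = np.where(keep, assign, fresh)
            hap_alleles[s] = anc_hap[assign, s]
        g = np.stack([hap_alleles[:, 0::2], hap_alleles[:, 1::2]], axis=2)
        genotypes[:, col:col + n] = np.sort(g, axis=2)
        col += n

    breed_type = {
        breed: ("river" if i % 2 == 0 else "swamp")
        for i, (breed, _) in enumerate(config.breeds)
    }
    cohort = Cohort(samples=samples, sites=sites, genotypes=genotypes)
    return cohort, BreedMap(assignments=breed_of, breed_type=breed_type)


def _config_to_dict(config: SimConfig) -> dict:
    return {
        "breeds": [[b, n] for b, n in config.breeds],
        "n_sites": config.n_sites,
        "fst": config.fst,
        "ancestral_freq_dist": (
            list(config.ancestral_freq_dist)
            if isinstance(config.ancestral_freq_dist, tuple)
            else config.ancestral_freq_dist
        ),
        "missing_rate": config.missing_rate,
        "planted": {b: [c, d] for b, (c, d) in config.planted.items()},
        "linkage": list(config.linkage) if config.linkage else None,
        "n_chromosomes": config.n_chromosomes,
        "seed": config.seed,
    }


def load_config(path: str) -> SimConfig:
    """Load a SimConfig from the YAML schema written by :func:`emit_fixture`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return SimConfig(
        breeds=[(b, int(n)) for b, n in raw["breeds"]],
        n_sites=int(raw.get("n_sites", 500)),
        fst=float(raw.get("fst", 0.1)),
        ancestral_freq_dist=(
            tuple(raw["ancestral_freq_dist"])
            if isinstance(raw.get("ancestral_freq_dist", [1.0, 1.0]), list)
            else float(raw["ancestral_freq_dist"])
        ),
        missing_rate=float(raw.get("missing_rate", 0.0)),
        planted={b: (int(c), int(d)) for b, (c, d) in raw.get("planted", {}).items()},
        linkage=tuple(raw["linkage"]) if raw.get("linkage") else None,
        n_chromosomes=int(raw.get("n_chromosomes", 1)),
        seed=int(raw["seed"]),
    )


def emit_fixture(config: SimConfig, out_dir: str) -> dict[str, str]:
    """Write the canonical fixture file set: cohort VCF, breed map TSV,
    truth TSV and the config as YAML.  Regenerating from the emitted YAML
    reproduces identical files."""
    os.makedirs(out_dir, exist_ok=True)
    cohort, breed_map, truth = simulate_cohort(config)
    paths = {
        "vcf": os.path.join(out_dir, "cohort.vcf"),
        "breeds": os.path.join(out_dir, "breeds.tsv"),
        "truth": os.path.join(out_dir, "truth.tsv"),
        "config": os.path.join(out_dir, "sim_config.yaml"),
    }
    write_vcf(cohort, paths["vcf"])
    with open(paths["breeds"], "w") as fh:
        fh.write("sample\tbreed\ttype\n")
        for s in cohort.samples:
            b = breed_map.assignments[s]
            fh.write(f"{s}\t{b}\t{breed_map.breed_type[b]}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("chrom\tpos\tallele_index\tbreed\tn_carrier_targets\tn_dropout_targets\n")
        for r in truth.rows:
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.allele_index}\t{r.breed}\t"
                f"{r.n_carrier_targets}\t{r.n_dropout_targets}\n"
            )
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=True)
    return paths
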