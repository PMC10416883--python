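"""Shared fixtures: hand-built cohorts, random cohort factory, toy GFF3."""

from __future__ import annotations

import numpy as np
import pytest

from bsmkit.io_breeds import BreedMap, Cohort, VariantSite
from bsmkit.simulate import SimConfig, simulate_cohort

NUCS = "ACGT"


def make_cohort(samples, records):
    """Build a Cohort from [(chrom, pos, ref, alts, [call, ...]), ...] where a
    call is (a, b) or None for missing."""
    sites = []
    geno = np.full((len(records), len(samples), 2), -1, dtype=np.int16)
    for i, (chrom, pos, ref, alts, calls) in enumerate(records):
        sites.append(VariantSite(chrom, pos, None, ref, tuple(alts)))
        for j, c in enumerate(calls):
            if c is not None:
                geno[i, j] = c
    return Cohort(samples=list(samples), sites=sites, genotypes=geno)


def random_cohort(rng: np.random.Generator, n_sites: int = 200,
                  multiallelic_frac: float = 0.15, missing_rate: float = 0.05):
    """Random 4-breed cohort (4-5 samples each) with mixed multi-allelic
    sites and missing calls, for oracle-equivalence testing."""
    breeds = [("B1", 4), ("B2", 4), ("B3", 5), ("B4", 5)]
    samples, assign = [], {}
    for b, n in breeds:
        for i in range(n):
            s = f"{b}_{i}"
            samples.append(s)
            assign[s] = b
    pos = np.sort(rng.choice(10_000_000, size=n_sites, replace=False) + 1)
    sites, rows = [], []
    for p in pos:
        n_alts = 2 if rng.random() < multiallelic_frac else 1
        alleles = rng.permutation(4)[: n_alts + 1]
        sites.append(VariantSite("chr1", int(p), None, NUCS[alleles[0]],
                                 tuple(NUCS[a] for a in alleles[1:])))
        n_all = n_alts + 1
        row = rng.integers(0, n_all, size=(len(samples), 2)).astype(np.int16)
        miss = rng.random(len(samples)) < missing_rate
        row[miss] = -1
        rows.append(np.sort(row, axis=1))
    cohort = Cohort(samples=samples, sites=sites, genotypes=np.stack(rows))
    bm = BreedMap(assignments=assign,
                  breed_type={"B1": "river", "B2": "river", "B3": "swamp", "B4": "swamp"})
    return cohort, bm


# canonical planted-marker fixture: four small target breeds shaped like the
# Pakistani panel (4, 4, 5, 5 animals) plus two larger comparison panels
CANONICAL_SIM = SimConfig(
    breeds=[("Nili", 4), ("NiliRavi", 4), ("Azakheli", 5), ("Kundi", 5),
            ("RiverPanel", 15), ("SwampPanel", 15)],
    n_sites=600,
    fst=0.1,
    planted={"Nili": (50, 1), "NiliRavi": (50, 0), "Azakheli": (50, 0), "Kundi": (50, 1)},
    missing_rate=0.02,
    seed=20230807,
)


@pytest.fixture(scope="session")
def canonical_fixture():
    return simulate_cohort(CANONICAL_SIM)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


TOY_GFF = """\
##gff-version 3
chr1\ttoy\tgene\t1000\t5000\t.\t+\t.\tID=gene1
chr1\ttoy\tmRNA\t1000\t5000\t.\t+\t.\tID=mrna1;Parent=gene1
chr1\ttoy\texon\t1000\t2000\t.\t+\t.\tID=exon1;Parent=mrna1
chr1\ttoy\texon\t3000\t5000\t.\t+\t.\tID=exon2;Parent=mrna1
chr1\ttoy\tCDS\t1200\t1800\t.\t+\t.\tID=cds1;Parent=mrna1
chr1\ttoy\tgene\t20000\t25000\t.\t-\t.\tID=gene2
chr1\ttoy\tmRNA\t20000\t25000\t.\t-\t.\tID=mrna2;Parent=gene2
chr1\ttoy\texon\t20000\t21000\t.\t-\t.\tID=exon3;Parent=mrna2
chr1\ttoy\texon\t24000\t25000\t.\t-\t.\tID=exon4;Parent=mrna2
chr1\ttoy\tCDS\t24100\t24900\t.\t-\t.\tID=cds2;Parent=mrna2
chr1\ttoy\tgene\t40000\t41000\t.\t+\t.\tID=gene3
chr1\ttoy\tmRNA\t40000\t41000\t.\t+\t.\tID=mrna3;Parent=gene3
chr1\ttoy\texon\t40000\t41000\t.\t+\t.\tID=exon5;Parent=mrna3
"""


@pytest.fixture(scope="session")
def toy_gff(tmp_path_factory):
    p = tmp_path_factory.mktemp("gff") / "toy.gff3"
    p.write_text(TOY_GFF)
    return str(p)
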