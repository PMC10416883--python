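"""The marker scan: carrier counting, oracle equivalence, relaxation logic."""

import numpy as np
import pytest

from bsmkit.bsm_scan import ScanConfig, brute_force_scan, carriers, scan_all, scan_breed
from bsmkit.io_breeds import BreedMap
from conftest import make_cohort, random_cohort


def keys(records):
    return [(r.site.chrom, r.site.pos, r.allele_index, r.genotype) for r in records]


def small_panel(target_calls, outgroup_calls, alts=("G",)):
    """4 target samples + outgroup samples at a single site."""
    n_out = len(outgroup_calls)
    samples = [f"t{i}" for i in range(len(target_calls))] + [f"o{i}" for i in range(n_out)]
    assign = {s: ("T" if s.startswith("t") else "O") for s in samples}
    bm = BreedMap(assignments=assign, breed_type={"T": "river", "O": "swamp"})
    cohort = make_cohort(samples, [("chr1", 100, "A", list(alts),
                                    list(target_calls) + list(outgroup_calls))])
    return cohort, bm


class TestCarriers:
    def test_allele_counting(self):
        calls = np.array([[0, 1], [1, 1], [0, 0], [-1, -1]])
        assert carriers(calls, 1, 2) == (2, 1, 1)

    def test_all_hom_carriers(self):
        calls = np.ones((6, 2), dtype=int)
        assert carriers(calls, 1, 2) == (6, 0, 0)

    def test_genotype_mode_equality(self):
        calls = np.array([[1, 1], [0, 1]])
        assert carriers(calls, 1, 2, mode="genotype", target_genotype=(1, 1)) == (1, 1, 0)

    def test_out_of_range_allele(self):
        with pytest.raises(ValueError):
            carriers(np.zeros((2, 2), dtype=int), 3, 2)


class TestScanBreed:
    def test_private_hom_alt_reported(self):
        cohort, bm = small_panel([(1, 1)] * 4, [(0, 0)] * 20)
        recs = scan_breed(cohort, bm, ScanConfig("T", relaxation=0))
        assert [(r.allele_index, r.target_carriers) for r in recs] == [(1, 4)]

    def test_single_outgroup_carrier_disqualifies(self):
        cohort, bm = small_panel([(1, 1)] * 4, [(0, 0)] * 19 + [(0, 1)])
        recs = scan_breed(cohort, bm, ScanConfig("T", relaxation=0))
        assert recs == []

    def test_relaxation_admits_one_noncarrier(self):
        cohort, bm = small_panel([(1, 1), (0, 0), (1, 1), (1, 1)], [(0, 0)] * 20)
        hit_r1 = scan_breed(cohort, bm, ScanConfig("T", relaxation=1))
        assert any(r.allele_index == 1 and r.target_noncarriers == 1 for r in hit_r1)
        hit_r0 = scan_breed(cohort, bm, ScanConfig("T", relaxation=0))
        assert not any(r.allele_index == 1 for r in hit_r0)

    def test_ref_allele_private_and_flag(self):
        # outgroup fixed hom ALT: REF is the target-private allele
        cohort, bm = small_panel([(0, 0)] * 4, [(1, 1)] * 10)
        recs = scan_breed(cohort, bm, ScanConfig("T", relaxation=0))
        assert [r.allele_index for r in recs] == [0]
        recs = scan_breed(cohort, bm, ScanConfig("T", relaxation=0, allow_ref_allele=False))
        assert recs == []

    def test_strict_outgroup_missing_policy(self):
        cohort, bm = small_panel([(1, 1)] * 4, [(0, 0)] * 9 + [None])
        permissive = scan_breed(cohort, bm, ScanConfig("T", relaxation=0))
        assert any(r.allele_index == 1 for r in permissive)
        strict = scan_breed(
            cohort, bm, ScanConfig("T", relaxation=0, outgroup_missing_policy="strict"))
        assert strict == []

    def test_relaxation_budget_covers_missing(self):
        cohort, bm = small_panel([(1, 1), None, (1, 1), (1, 1)], [(0, 0)] * 10)
        r1 = scan_breed(cohort, bm, ScanConfig("T", relaxation=1))
        assert any(r.allele_index == 1 and r.target_missing == 1 for r in r1)
        assert not any(r.allele_index == 1
                       for r in scan_breed(cohort, bm, ScanConfig("T", relaxation=0)))

    def test_relaxation_ge_target_count_is_error(self):
        cohort, bm = small_panel([(1, 1)] * 4, [(0, 0)] * 4)
        with pytest.raises(ValueError, match="relaxation"):
            scan_breed(cohort, bm, ScanConfig("T", relaxation=4))

    def test_empty_outgroup_is_error(self):
        cohort, bm = small_panel([(1, 1)] * 4, [(0, 0)] * 4)
        only_t = BreedMap(assignments={s: "T" for s in cohort.samples},
                          breed_type={"T": "river"})
        with pytest.raises(ValueError, match="comparison panel|outgroup"):
            scan_breed(cohort, only_t, ScanConfig("T", relaxation=0))

    def test_genotype_mode_shared_het(self):
        # all targets het 0/1; outgroup carries the same alleles but never that genotype
        cohort, bm = small_panel([(0, 1)] * 4, [(0, 0), (1, 1)] * 5)
        allele = scan_breed(cohort, bm, ScanConfig("T", relaxation=0, mode="allele"))
        assert allele == []  # both alleles occur in the outgroup
        geno = scan_breed(cohort, bm, ScanConfig("T", relaxation=0, mode="genotype"))
        assert [r.genotype for r in geno] == [(0, 1)]


class TestOracleEquivalence:
    @pytest.mark.parametrize("mode", ["allele", "genotype"])
    @pytest.mark.parametrize("r", [0, 1, 2])
    def test_matches_brute_force(self, mode, r):
        rng = np.random.default_rng(1000 + r)
        for _ in range(5):
            cohort, bm = random_cohort(rng, n_sites=60)
            for breed in ["B1", "B3"]:
                cfg = ScanConfig(breed, relaxation=r, mode=mode)
                assert keys(scan_breed(cohort, bm, cfg)) == \
                    keys(brute_force_scan(cohort, bm, cfg))

    def test_full_record_fields_match(self):
        rng = np.random.default_rng(77)
        cohort, bm = random_cohort(rng, n_sites=80)
        cfg = ScanConfig("B2", relaxation=1)
        assert scan_breed(cohort, bm, cfg) == brute_force_scan(cohort, bm, cfg)


class TestInvariants:
    def test_monotone_in_relaxation(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            cohort, bm = random_cohort(rng, n_sites=40)
            prev = None
            for r in (0, 1, 2):
                cur = set(keys(scan_breed(cohort, bm, ScanConfig("B1", relaxation=r))))
                if prev is not None:
                    assert prev <= cur
                prev = cur

    def test_adding_outgroup_sample_never_adds_record(self):
        rng = np.random.default_rng(6)
        cohort, bm = random_cohort(rng, n_sites=60)
        full = set(keys(scan_breed(cohort, bm, ScanConfig("B1", relaxation=1))))
        # drop the last outgroup sample
        keep = [j for j, s in enumerate(cohort.samples) if s != "B4_4"]
        sub = make_sub(cohort, keep)
        reduced = set(keys(scan_breed(sub, bm, ScanConfig("B1", relaxation=1))))
        assert full <= reduced

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(7)
        cohort, bm = random_cohort(rng, n_sites=50)
        perm = rng.permutation(cohort.n_samples)
        shuffled = make_sub(cohort, list(perm))
        cfg = ScanConfig("B2", relaxation=1)
        assert keys(scan_breed(cohort, bm, cfg)) == keys(scan_breed(shuffled, bm, cfg))

    def test_monomorphic_shared_site_yields_nothing(self):
        cohort, bm = small_panel([(0, 0)] * 4, [(0, 0)] * 10)
        assert scan_breed(cohort, bm, ScanConfig("T", relaxation=1)) == []


def make_sub(cohort, cols):
    from bsmkit.io_breeds import Cohort
    return Cohort(
        samples=[cohort.samples[j] for j in cols],
        sites=list(cohort.sites),
        genotypes=cohort.genotypes[:, cols].copy(),
        phased=cohort.phased[:, cols].copy(),
    )


class TestScanAll:
    def test_planted_counts_and_outputs(self, tmp_path, canonical_fixture):
        cohort, bm, truth = canonical_fixture
        results = scan_all(cohort, bm, ["Nili", "NiliRavi", "Azakheli", "Kundi"],
                           ScanConfig("", relaxation=1), out_dir=str(tmp_path))
        for breed, recs in results.items():
            planted = {t.key() for t in truth.for_breed(breed)}
            found = {r.key() for r in recs}
            assert planted <= found
        assert (tmp_path / "bsm_summary.tsv").exists()
        assert (tmp_path / "Nili_bsm.vcf").exists()

    def test_empty_breed_list_is_error(self, canonical_fixture):
        cohort, bm, _ = canonical_fixture
        with pytest.raises(ValueError):
            scan_all(cohort, bm, [], ScanConfig("", relaxation=1))
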