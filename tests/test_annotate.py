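"""GFF3 region classification and hypergeometric enrichment."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from bsmkit.annotate import (
    classify_variant,
    enrich,
    load_gff,
    read_pathway_map,
    summarize_regions,
)
from bsmkit.io_breeds import VariantSite


def site(pos, chrom="chr1"):
    return VariantSite(chrom, pos, None, "A", ("C",))


class TestLoadGff:
    def test_containment_queries(self, toy_gff):
        idx = load_gff(toy_gff)
        assert idx.cds_genes_at("chr1", 1500) == ["gene1"]
        assert idx.exon_genes_at("chr1", 1900) == ["gene1"]
        assert [g.gene_id for g in idx.genes_at("chr1", 2500)] == ["gene1"]

    def test_feature_midpoint_self_query(self, toy_gff):
        idx = load_gff(toy_gff)
        for gene in idx.genes.values():
            mid = (gene.start + gene.end) // 2 + 1  # back to 1-based
            assert gene.gene_id in [g.gene_id for g in idx.genes_at(gene.chrom, mid)]

    def test_no_genes_is_error(self, tmp_path):
        p = tmp_path / "empty.gff3"
        p.write_text("##gff-version 3\nchr1\tx\tregion\t1\t100\t.\t.\t.\tID=r1\n")
        with pytest.raises(ValueError, match="no gene"):
            load_gff(str(p))


class TestClassifyVariant:
    @pytest.mark.parametrize("pos,region,gene,dist", [
        (1500, "CDS", "gene1", 0),
        (1900, "exon_noncoding", "gene1", 0),
        (2500, "intron", "gene1", 0),
        (500, "upstream", "gene1", 500),
        (5500, "downstream", "gene1", 500),
        (26000, "upstream", "gene2", 1000),   # gene2 is minus-strand
        (19000, "downstream", "gene2", 1000),
        (24500, "CDS", "gene2", 0),
    ])
    def test_precedence_and_strand(self, toy_gff, pos, region, gene, dist):
        idx = load_gff(toy_gff)
        a = classify_variant(site(pos), idx)
        assert (a.region, a.gene, a.distance) == (region, gene, dist)

    def test_flank_boundary(self, toy_gff):
        idx = load_gff(toy_gff)
        # gene3 spans 40000-41000; 5000 bp past the end is downstream, 5001 intergenic
        assert classify_variant(site(46000), idx).region == "downstream"
        assert classify_variant(site(46001), idx).region == "intergenic"

    def test_absent_chromosome_intergenic_null_gene(self, toy_gff):
        idx = load_gff(toy_gff)
        a = classify_variant(site(100, "chrUn"), idx)
        assert a.region == "intergenic" and a.gene is None

    def test_negative_flank_is_error(self, toy_gff):
        idx = load_gff(toy_gff)
        with pytest.raises(ValueError):
            classify_variant(site(100), idx, flank=-1)

    def test_matches_naive_feature_scan(self, toy_gff, rng):
        """Random positions classified identically to a brute-force scan over
        every feature interval parsed independently of the index."""
        idx = load_gff(toy_gff)
        features = []  # (type, start0, end, gene, strand)
        with open(toy_gff) as fh:
            genes = {}
            parent_gene = {}
            for line in fh:
                if line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                attrs = dict(kv.split("=") for kv in f[8].split(";"))
                if f[2] == "gene":
                    genes[attrs["ID"]] = (int(f[3]) - 1, int(f[4]), f[6])
                    parent_gene[attrs["ID"]] = attrs["ID"]
                else:
                    parent_gene[attrs["ID"]] = parent_gene[attrs["Parent"]]
                features.append((f[2], int(f[3]) - 1, int(f[4]),
                                 parent_gene[attrs["ID"]], f[6]))

        def naive(pos, flank=5000):
            point = pos - 1
            for want in ("CDS", "exon"):
                for (t, s, e, g, _) in features:
                    if t == want and s <= point < e:
                        if want == "CDS":
                            return ("CDS", g)
                        in_cds = any(t2 == "CDS" and s2 <= point < e2
                                     for (t2, s2, e2, _, _) in features)
                        return ("CDS" if in_cds else "exon_noncoding", g)
            for gid, (s, e, _) in genes.items():
                if s <= point < e:
                    return ("intron", gid)
            best = min(
                ((max(s - point, point - e + 1, 0), s, gid)
                 for gid, (s, e, _) in genes.items()),
                key=lambda t: t,
            )
            dist, _, gid = best
            s, e, strand = genes[gid]
            if dist <= flank:
                before = point < s
                up = before if strand == "+" else not before
                return ("upstream" if up else "downstream", gid)
            return ("intergenic", gid)

        for _ in range(50):
            pos = int(rng.integers(1, 60000))
            a = classify_variant(site(pos), idx)
            assert (a.region, a.gene) == naive(pos), f"at pos {pos}"


class TestSummarizeRegions:
    def test_empty_input(self):
        s = summarize_regions([])
        assert s["total"] == 0 and all(v == 0 for v in s["counts"].values())

    def test_counts_sum_and_gene_list(self, toy_gff):
        idx = load_gff(toy_gff)
        anns = [classify_variant(site(p), idx)
                for p in (1500, 1500, 1500, 100000, 150000)]
        s = summarize_regions(anns)
        assert s["counts"]["CDS"] == 3 and s["counts"]["intergenic"] == 2
        assert sum(s["counts"].values()) == 5
        assert s["genes"] == ["gene1"]


class TestEnrich:
    def test_closed_form_hypergeometric(self):
        pmap = {"P1": ("pathway one", {f"g{i}" for i in range(1, 6)})}
        universe = {f"g{i}" for i in range(1, 11)}
        res = enrich({"g1", "g2", "g3", "g4"}, pmap, universe)
        assert res[0].p == pytest.approx(5 / 210, abs=1e-12)

    def test_zero_overlap_p_is_one(self):
        pmap = {"P1": ("p", {"g1", "g2"})}
        res = enrich({"g5", "g6"}, pmap, {f"g{i}" for i in range(1, 11)})
        assert res[0].p == pytest.approx(1.0)

    def test_single_pathway_q_equals_p(self):
        pmap = {"P1": ("p", {"g1", "g2", "g3"})}
        res = enrich({"g1", "g2"}, pmap, {f"g{i}" for i in range(1, 8)})
        assert res[0].q == pytest.approx(res[0].p)

    def test_exact_rational_pmf_sums(self, rng):
        """p-values equal exact rational sums of hypergeometric PMF terms."""
        for _ in range(10):
            N = int(rng.integers(8, 30))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            universe = {f"g{i}" for i in range(N)}
            pathway = {f"g{i}" for i in range(K)}
            query = set(rng.choice(sorted(universe), size=n, replace=False))
            k = len(query & pathway)
            exact = sum(
                Fraction(comb(K, x) * comb(N - K, n - x), comb(N, n))
                for x in range(k, min(K, n) + 1)
            )
            res = enrich(query, {"P": ("p", pathway)}, universe)
            assert res[0].k == k
            assert res[0].p == pytest.approx(float(exact), rel=1e-12)

    def test_bh_step_up_rule(self, rng):
        """Rejections at q <= alpha reproduce the step-up rule on raw p."""
        m = 12
        universe = {f"g{i}" for i in range(25)}
        pmap = {}
        for t in range(m):
            genes = set(rng.choice(sorted(universe), size=int(rng.integers(3, 12)),
                                   replace=False))
            pmap[f"P{t:02d}"] = (f"path{t}", genes)
        query = set(rng.choice(sorted(universe), size=8, replace=False))
        res = enrich(query, pmap, universe)
        ps = np.array([r.p for r in res])  # ascending
        alpha = 0.25
        thresh = ps <= alpha * (np.arange(1, len(ps) + 1)) / len(ps)
        n_reject_stepup = 0 if not thresh.any() else int(np.max(np.where(thresh)[0])) + 1
        n_reject_q = int(sum(r.q <= alpha for r in res))
        assert n_reject_q == n_reject_stepup
        # q non-decreasing with p-rank
        qs = [r.q for r in res]
        assert qs == sorted(qs)

    def test_query_outside_universe_dropped(self):
        pmap = {"P1": ("p", {"g1", "g2"})}
        res = enrich({"g1", "gX"}, pmap, {"g1", "g2", "g3", "g4"})
        assert res[0].n == 1  # gX dropped

    def test_empty_universe_is_error(self):
        with pytest.raises(ValueError):
            enrich({"g1"}, {"P": ("p", {"g1"})}, set())


class TestPathwayMap:
    def test_round_trip(self, tmp_path):
        p = tmp_path / "path.tsv"
        p.write_text("pathway_id\tpathway_name\tgene_id\n"
                     "P1\tGlycolysis\tg1\nP1\tGlycolysis\tg2\nP2\tTCA\tg2\n")
        pmap = read_pathway_map(str(p))
        assert pmap["P1"] == ("Glycolysis", {"g1", "g2"})
        assert pmap["P2"][1] == {"g2"}
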