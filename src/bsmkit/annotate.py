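"""Region-level variant annotation against GFF3 gene models and
hypergeometric pathway over-representation.

A marker is classified by where it falls relative to gene models, with
precedence CDS > non-coding exon > intron > upstream/downstream (within a
strand-aware flank, default 5 kb) > intergenic.  The genic/intergenic split
and the gene lists it yields feed the enrichment step: an upper-tail
hypergeometric test per pathway on a user-supplied pathway -> gene map, with
Benjamini-Hochberg adjustment across pathways.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import gffutils
import numpy as np
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_breeds import VariantSite

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModelIndex",
    "RegionAnnotation",
    "EnrichmentResult",
    "REGION_CLASSES",
    "load_gff",
    "classify_variant",
    "summarize_regions",
    "enrich",
]

REGION_CLASSES = ("CDS", "exon_noncoding", "intron", "upstream", "downstream", "intergenic")


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open internally
    end: int
    strand: str


@dataclass
class GeneModelIndex:
    """Per-chromosome interval trees over gene, exon and CDS features.

    Intervals are stored 0-based half-open; public queries take 1-based
    positions and convert at the boundary.
    """

    genes: dict[str, Gene]
    gene_trees: dict[str, IntervalTree]
    exon_trees: dict[str, IntervalTree]
    cds_trees: dict[str, IntervalTree]

    def genes_at(self, chrom: str, pos: int) -> list[Gene]:
        tree = self.gene_trees.get(chrom)
        if tree is None:
            return []
        return sorted(
            (self.genes[iv.data] for iv in tree[pos - 1]),
            key=lambda g: (g.start, g.gene_id),
        )

    def _hits(self, trees: dict[str, IntervalTree], chrom: str, pos: int) -> list[str]:
        tree = trees.get(chrom)
        return sorted(iv.data for iv in tree[pos - 1]) if tree is not None else []

    def exon_genes_at(self, chrom: str, pos: int) -> list[str]:
        return self._hits(self.exon_trees, chrom, pos)

    def cds_genes_at(self, chrom: str, pos: int) -> list[str]:
        return self._hits(self.cds_trees, chrom, pos)

    def all_gene_ids(self) -> set[str]:
        return set(self.genes)


@dataclass(frozen=True)
class RegionAnnotation:
    site: VariantSite
    region: str
    gene: str | None
    distance: int  # bp to the assigned gene edge; 0 if inside


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    pathway_name: str
    k: int  # overlap
    K: int  # pathway size within universe
    n: int  # query size
    N: int  # universe size
    p: float
    q: float


def _gene_of(db: gffutils.FeatureDB, feature) -> str | None:
    """Walk Parent links up to the enclosing gene; None if broken."""
    node = feature
    for _ in range(8):
        if node.featuretype == "gene":
            return node.id
        parents = list(db.parents(node, level=1))
        if not parents:
            return None
        node = parents[0]
    return None


def load_gff(path: str) -> GeneModelIndex:
    """Index a GFF3 file of gene/mRNA/exon/CDS features for point queries.

    Uses an in-memory gffutils database; exon/CDS features whose Parent chain
    does not reach a gene are logged and skipped.
    """
    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: dict[str, Gene] = {}
    gene_trees: dict[str, IntervalTree] = {}
    for g in db.features_of_type("gene"):
        gene = Gene(
            gene_id=g.id,
            chrom=g.seqid,
            start=g.start - 1,
            end=g.end,
            strand=g.strand if g.strand in ("+", "-") else "+",
        )
        genes[g.id] = gene
        gene_trees.setdefault(g.seqid, IntervalTree()).addi(gene.start, gene.end, g.id)
    if not genes:
        raise ValueError(f"{path}: no gene features found")

    exon_trees: dict[str, IntervalTree] = {}
    cds_trees: dict[str, IntervalTree] = {}
    for ftype, trees in (("exon", exon_trees), ("CDS", cds_trees)):
        for f in db.features_of_type(ftype):
            gid = _gene_of(db, f)
            if gid is None:
                logger.warning("%s feature %s has no gene parent; skipped", ftype, f.id)
                continue
            trees.setdefault(f.seqid, IntervalTree()).addi(f.start - 1, f.end, gid)
    return GeneModelIndex(
        genes=genes, gene_trees=gene_trees, exon_trees=exon_trees, cds_trees=cds_trees
    )


def classify_variant(
    site: VariantSite, index: GeneModelIndex, flank: int = 5000
) -> RegionAnnotation:
    """Assign a region class to a variant position.

    Precedence: CDS > non-coding exon > intron > upstream/downstream (within
    ``flank`` bp of the nearest gene, strand-aware) > intergenic.  The
    nearest gene is chosen by minimal edge distance, ties broken by smaller
    start then lexicographic id.  A chromosome absent from the index yields
    intergenic with a null gene.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    chrom, pos = site.chrom, site.pos
    if chrom not in index.gene_trees:
        logger.info("chromosome %s absent from gene index", chrom)
        return RegionAnnotation(site, "intergenic", None, -1)

    cds = index.cds_genes_at(chrom, pos)
    if cds:
        return RegionAnnotation(site, "CDS", cds[0], 0)
    exon = index.exon_genes_at(chrom, pos)
    if exon:
        return RegionAnnotation(site, "exon_noncoding", exon[0], 0)
    containing = index.genes_at(chrom, pos)
    if containing:
        return RegionAnnotation(site, "intron", containing[0].gene_id, 0)

    # nearest gene on this chromosome by edge distance (0-based point = pos-1)
    point = pos - 1
    best: tuple[int, int, str] | None = None
    for gene in index.genes.values():
        if gene.chrom != chrom:
            continue
        if point < gene.start:
            dist = gene.start - point
        elif point >= gene.end:
            dist = point - gene.end + 1
        else:
            dist = 0
        key = (dist, gene.start, gene.gene_id)
        if best is None or key < best:
            best = key
    assert best is not None
    dist, _, gid = best
    if dist <= flank:
        gene = index.genes[gid]
        before_start = point < gene.start
        if gene.strand == "+":
            region = "upstream" if before_start else "downstream"
        else:
            region = "downstream" if before_start else "upstream"
        return RegionAnnotation(site, region, gid, dist)
    return RegionAnnotation(site, "intergenic", gid, dist)


def summarize_regions(annotations: list[RegionAnnotation]) -> dict:
    """Counts per region class plus the distinct gene list of non-intergenic hits."""
    counts = Counter(a.region for a in annotations)
    table = {r: counts.get(r, 0) for r in REGION_CLASSES}
    genes = sorted({a.gene for a in annotations if a.region != "intergenic" and a.gene})
    return {"counts": table, "genes": genes, "total": len(annotations)}


def read_pathway_map(path: str) -> dict[str, tuple[str, set[str]]]:
    """Read a TSV ``pathway_id<TAB>pathway_name<TAB>gene_id`` into
    {pathway_id: (name, gene set)}."""
    pathways: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{line_no}: expected 3 tab-separated columns")
            pid, name, gene = parts
            if pid == "pathway_id":
                continue  # optional header
            if pid not in pathways:
                pathways[pid] = (name, set())
            pathways[pid][1].add(gene)
    if not pathways:
        raise ValueError(f"{path}: no pathway rows")
    return pathways


def enrich(
    query_genes: set[str],
    pathway_map: dict[str, tuple[str, set[str]]],
    universe: set[str],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of query genes per pathway.

    p = P(X >= k) for X ~ Hypergeom(N, K, n) with N the universe size, K the
    pathway size within the universe, n the query size and k the overlap;
    q values are Benjamini-Hochberg adjusted across the tested pathways.
    Query genes outside the universe are logged and dropped.
    """
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes) & universe
    dropped = set(query_genes) - universe
    if dropped:
        logger.warning("enrich: %d query genes outside universe dropped", len(dropped))
    if not query:
        raise ValueError("empty query after intersecting with universe")

    N, n = len(universe), len(query)
    rows: list[tuple[str, str, int, int, float]] = []
    for pid in sorted(pathway_map):
        name, genes = pathway_map[pid]
        pk = genes & universe
        K = len(pk)
        if K == 0:
            continue
        k = len(pk & query)
        p = float(hypergeom.sf(k - 1, N, K, n))  # upper tail P(X >= k)
        rows.append((pid, name, k, K, min(p, 1.0)))
    if not rows:
        raise ValueError("no pathway overlaps the universe")
    pvals = np.array([r[4] for r in rows])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(pid, name, k, K, n, N, p, float(q))
        for (pid, name, k, K, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.p, r.pathway_id))
    return results
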