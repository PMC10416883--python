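"""Linkage-disequilibrium decay within a distance window.

LD between two sites is the squared Pearson correlation of genotype dosages
(r^2) over pairwise-complete samples — the genotypic, phase-free r^2, which
matches unphased diploid calls.  Per breed, every same-chromosome site pair
closer than the window (default 0.1 Mb) is binned by distance and the
per-bin mean r^2 forms the decay curve; slower decay (larger area under the
curve) indicates a more uniform, more drifted breed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_breeds import BreedMap, Cohort
from .structure import dosage_matrix

logger = logging.getLogger(__name__)

__all__ = ["LdCurve", "pairwise_r2", "ld_decay", "compare_decay"]


@dataclass
class LdCurve:
    """Distance-binned mean r^2 for one breed.

    ``bins`` rows are (lo, hi, mean_r2, n_pairs) over half-open [lo, hi)
    intervals, except the final bin which closes at ``max_dist``; bins with
    zero pairs carry ``None`` means.
    """

    breed: str
    bins: list[tuple[int, int, float | None, int]]
    max_dist: int
    bin_width: int
    maf_min: float
    n_skipped_pairs: int = 0  # pairs with <3 complete entries or undefined r^2

    def area(self) -> float:
        """Trapezoidal area under the curve over bins with defined means,
        using bin midpoints as abscissae."""
        pts = [((lo + hi) / 2.0, m) for lo, hi, m, _ in self.bins if m is not None]
        if len(pts) < 2:
            raise ValueError(f"curve for {self.breed!r} has <2 defined bins")
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        return float(np.trapezoid(y, x))


def pairwise_r2(g1: np.ndarray, g2: np.ndarray) -> float | None:
    """Squared Pearson correlation of two dosage vectors.

    NaN entries are dropped pairwise; requires >= 3 complete entries and both
    vectors non-constant on the complete subset, else returns None.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("dosage vectors differ in length")
    ok = ~(np.isnan(g1) | np.isnan(g2))
    if ok.sum() < 3:
        return None
    a, b = g1[ok], g2[ok]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    r = np.corrcoef(a, b)[0, 1]
    return float(min(r * r, 1.0))


def ld_decay(
    cohort: Cohort,
    breed_map: BreedMap,
    breed: str,
    max_dist: int = 100_000,
    bin_width: int = 1_000,
    maf_min: float = 0.05,
) -> LdCurve:
    """Distance-binned LD decay curve for one breed.

    Restricts to the breed's samples, filters sites by within-breed MAF,
    computes r^2 for every same-chromosome pair with 0 < distance <=
    ``max_dist`` and averages within ``bin_width`` bins.  Pairs at exactly
    ``max_dist`` fall in the final (closed-top) bin.
    """
    if max_dist <= 0 or bin_width <= 0:
        raise ValueError("max_dist and bin_width must be positive")
    names = breed_map.samples_of(breed)
    names = [s for s in names if s in cohort.samples]
    if len(names) < 3:
        raise ValueError(f"breed {breed!r} has fewer than 3 cohort samples")
    cols = cohort.sample_index(names)
    sub = Cohort(
        samples=names,
        sites=list(cohort.sites),
        genotypes=cohort.genotypes[:, cols],
        phased=cohort.phased[:, cols],
    )
    dm = dosage_matrix(sub, biallelic_only=True, maf_min=maf_min, impute=False)
    X = np.where(dm.mask, np.nan, dm.values)        # samples x sites
    kept = dm.site_indices
    chroms = np.array([cohort.sites[i].chrom for i in kept])
    pos = np.array([cohort.sites[i].pos for i in kept])

    n_bins = int(np.ceil(max_dist / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    skipped = 0
    m = len(kept)
    for i in range(m):
        for j in range(i + 1, m):
            if chroms[j] != chroms[i]:
                continue
            dist = abs(int(pos[j]) - int(pos[i]))
            if dist == 0 or dist > max_dist:
                continue
            r2 = pairwise_r2(X[:, i], X[:, j])
            if r2 is None:
                skipped += 1
                continue
            # half-open [lo, hi) bins; distance == max_dist goes to the last bin
            b = n_bins - 1 if dist == max_dist else dist // bin_width
            sums[b] += r2
            counts[b] += 1
    if counts.sum() == 0:
        raise ValueError(f"no qualifying site pairs for breed {breed!r}")
    bins: list[tuple[int, int, float | None, int]] = []
    for b in range(n_bins):
        lo, hi = b * bin_width, min((b + 1) * bin_width, max_dist)
        mean = float(sums[b] / counts[b]) if counts[b] else None
        bins.append((lo, hi, mean, int(counts[b])))
    if skipped:
        logger.info("ld_decay(%s): skipped %d undefined pairs", breed, skipped)
    return LdCurve(
        breed=breed, bins=bins, max_dist=max_dist, bin_width=bin_width,
        maf_min=maf_min, n_skipped_pairs=skipped,
    )


def compare_decay(curves: list[LdCurve]) -> list[tuple[str, float]]:
    """Rank breeds by area under the decay curve, most extensive LD first.

    Areas are computed over the bins where every curve has a defined mean so
    the comparison is like-for-like; curves must share binning parameters.
    """
    if not curves:
        raise ValueError("no curves")
    ref = curves[0]
    for c in curves[1:]:
        if (c.max_dist, c.bin_width) != (ref.max_dist, ref.bin_width):
            raise ValueError("curves have mismatched binning parameters")
    shared = [
        b for b in range(len(ref.bins))
        if all(c.bins[b][2] is not None for c in curves)
    ]
    if len(shared) < 2:
        raise ValueError("fewer than 2 bins defined across all curves")
    ranking = []
    for c in curves:
        x = np.array([(c.bins[b][0] + c.bins[b][1]) / 2.0 for b in shared])
        y = np.array([c.bins[b][2] for b in shared])
        ranking.append((c.breed, float(np.trapezoid(y, x))))
    ranking.sort(key=lambda t: (-t[1], t[0]))
    return ranking
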