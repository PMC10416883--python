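"""Population structure: dosage matrix, variance-standardized PCA, IBS
distances and classical multidimensional scaling.

PCA follows the variance-standardized relationship-matrix convention: each
site column of the dosage matrix is centred by 2p and scaled by
sqrt(2p(1-p)) with p the observed alternate-allele frequency, then the
sample x sample covariance is eigendecomposed.  Missing dosages are mean
imputed (2p) beforehand, which keeps the covariance positive semi-definite
and the result deterministic.

IBS distance between two samples is one minus the mean per-site
allele-sharing fraction 1 - |d_i - d_j|/2 over pairwise-complete sites;
classical (Torgerson) MDS on that matrix gives the Cartesian embedding used
to cross-check PCA clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_breeds import Cohort

logger = logging.getLogger(__name__)

__all__ = ["DosageMatrix", "PcaResult", "DistanceMatrix", "dosage_matrix", "pca",
           "ibs_distance", "mds"]


@dataclass
class DosageMatrix:
    """Samples x sites ALT-dosage table with per-site frequencies and mask."""

    samples: list[str]
    values: np.ndarray          # (n_samples, n_sites), float; imputed cells = 2p
    site_freqs: np.ndarray      # per-site ALT frequency p from observed calls
    mask: np.ndarray            # (n_samples, n_sites) True where original call missing
    site_indices: np.ndarray    # indices of retained sites in the source cohort

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    def monomorphic(self) -> np.ndarray:
        return (self.site_freqs <= 0) | (self.site_freqs >= 1)


@dataclass
class PcaResult:
    samples: list[str]
    scores: np.ndarray            # (n_samples, k)
    eigenvalues: np.ndarray       # k values, descending
    explained_fraction: np.ndarray

    @property
    def k(self) -> int:
        return self.scores.shape[1]


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        self.d = d


def dosage_matrix(
    cohort: Cohort,
    biallelic_only: bool = True,
    maf_min: float = 0.0,
    impute: bool = False,
) -> DosageMatrix:
    """Build the ALT-dosage matrix (count of allele index 1 per call).

    Sites failing the biallelic or minor-allele-frequency filters are dropped
    and logged.  With ``impute``, missing cells are replaced by the site mean
    dosage 2p computed from observed calls.
    """
    if cohort.n_sites == 0 or cohort.n_samples == 0:
        raise ValueError("empty cohort")
    G = cohort.genotypes
    missing = cohort.missing_mask()                     # (sites, samples)
    dos = (G == 1).sum(axis=2).astype(float)            # (sites, samples)
    dos[missing] = np.nan

    keep = np.ones(cohort.n_sites, dtype=bool)
    if biallelic_only:
        keep &= np.array([len(s.alts) == 1 for s in cohort.sites])
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dos, axis=1) / 2.0
    p = np.where(np.isnan(p), 0.0, p)
    if maf_min > 0:
        maf = np.minimum(p, 1 - p)
        keep &= maf >= maf_min
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dosage_matrix: dropped %d of %d sites", n_dropped, cohort.n_sites)
    if not keep.any():
        raise ValueError("all sites removed by biallelic/MAF filters")

    dos = dos[keep].T                                   # (samples, sites)
    mask = missing[keep].T
    p = p[keep]
    if impute:
        fill = np.broadcast_to(2 * p, dos.shape)
        dos = np.where(mask, fill, dos)
    return DosageMatrix(
        samples=list(cohort.samples),
        values=dos,
        site_freqs=p,
        mask=mask,
        site_indices=np.where(keep)[0],
    )


def _fix_signs(scores: np.ndarray, loadings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # sign convention: the loading of largest magnitude is positive
    for c in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    return scores, loadings


def pca(dm: DosageMatrix, k: int) -> PcaResult:
    """Variance-standardized genotype PCA.

    Sites are centred by 2p and scaled by sqrt(2p(1-p)); monomorphic sites
    are excluded.  Eigenvalues are those of the sample covariance
    Z Z^T / n_sites; scores are the sample projections onto the top-k
    principal axes; the total variance (trace) backs ``explained_fraction``.
    """
    if dm.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if not (1 <= k <= dm.n_samples - 1):
        raise ValueError(f"k must be in [1, {dm.n_samples - 1}], got {k}")
    poly = ~dm.monomorphic()
    if not poly.any():
        raise ValueError("no polymorphic sites for PCA")
    X = dm.values[:, poly]
    if np.isnan(X).any():
        raise ValueError("dosage matrix contains missing cells; build with impute=True")
    p = dm.site_freqs[poly]
    Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    m = Z.shape[1]
    if not np.any(Z):
        raise ValueError("standardized matrix is identically zero")

    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    eigvals = S**2 / m                       # eigenvalues of Z Z^T / m, descending
    total = float(np.trace(Z @ Z.T)) / m
    scores = U[:, :k] * S[:k]
    loadings = Vt[:k].T
    scores, _ = _fix_signs(scores, loadings)
    return PcaResult(
        samples=list(dm.samples),
        scores=scores,
        eigenvalues=eigvals[:k],
        explained_fraction=eigvals[:k] / total,
    )


def ibs_distance(dm: DosageMatrix) -> DistanceMatrix:
    """Pairwise identity-by-state distance 1 - mean allele-sharing fraction.

    Pairwise-complete over the missingness mask; a pair with no shared
    observed site is an error naming the pair.
    """
    if dm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = np.where(dm.mask, np.nan, dm.values)
    n = dm.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(np.isnan(X[i]) | np.isnan(X[j]))
            if not ok.any():
                raise ValueError(
                    f"samples {dm.samples[i]!r} and {dm.samples[j]!r} share no "
                    "observed sites"
                )
            share = 1.0 - np.abs(X[i, ok] - X[j, ok]) / 2.0
            d[i, j] = d[j, i] = 1.0 - float(share.mean())
    return DistanceMatrix(labels=list(dm.samples), d=d)


def mds(dmat: DistanceMatrix, k: int) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling.

    Double-centres the squared-distance matrix, takes the top-k eigenpairs
    and scales eigenvectors by sqrt(eigenvalue).  Negative eigenvalues
    (non-Euclidean input) are truncated to zero with a logged warning.
    """
    n = len(dmat.labels)
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    D2 = dmat.d**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    top = eigvals[:k].copy()
    if np.any(top < -1e-9 * max(1.0, abs(eigvals[0]))):
        logger.warning("mds: %d negative eigenvalues truncated to zero", int((top < 0).sum()))
    top = np.clip(top, 0.0, None)
    coords = eigvecs[:, :k] * np.sqrt(top)
    coords, _ = _fix_signs(coords, coords.copy())
    return coords
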