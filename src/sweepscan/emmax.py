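"""Expedited mixed-model association (EMMAX-style).

The phenotype is modeled as ``y ~ N(Xβ, σ_g² K + σ_e² I)`` with K a
genome-wide kinship matrix. Variance components are estimated ONCE by REML
under the null (no SNP) via a single spectral decomposition of K and a
one-dimensional search over δ = σ_e²/σ_g²; they are then held fixed while
every marker is tested by generalized least squares in the decorrelated
(eigenvector-rotated) space. This is the expedited approximation: exact
per-marker REML refits are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .eigengwas import AssociationTrack
from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "VarianceComponents",
    "compute_kinship",
    "reml_fit",
    "emmax_scan",
]


@dataclass
class KinshipMatrix:
    """Symmetric PSD sample relatedness matrix."""

    samples: list[str]
    K: np.ndarray

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=np.float64)
        n = len(self.samples)
        if self.K.shape != (n, n):
            raise ValueError("K must be n×n for n samples")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("K must be symmetric")

    def check_psd(self, tol: float = 1e-8) -> None:
        vals = np.linalg.eigvalsh(self.K)
        if vals.min() < -tol:
            raise ValueError(f"K not PSD (min eigenvalue {vals.min():.3g})")

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(self.K, index=self.samples, columns=self.samples).to_csv(
            path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str) -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(samples=[str(s) for s in df.index], K=df.to_numpy())


def compute_kinship(g: GenotypeMatrix, method: str = "ibs") -> KinshipMatrix:
    """Genome-wide kinship.

    ``ibs``: mean identity-by-state proportion (1 − |d_i − d_j|/2) over
    sites non-missing in both samples. ``standardized``: cross-product of
    centered, scaled dosages divided by the SNP count (diagonal ≈ 1 +
    inbreeding).
    """
    D = g.dosages.astype(np.float64)
    obs = g.dosages != MISSING
    D[~obs] = np.nan
    maf = g.maf()
    poly = maf > 0
    if not poly.any():
        raise ValueError("no polymorphic SNPs for kinship")
    n = g.n_samples
    if method == "ibs":
        K = np.empty((n, n))
        for i in range(n):
            diff = np.abs(D[i] - D[i:])           # (n-i, m) with NaN at missing
            sim = 1.0 - diff / 2.0
            K[i, i:] = np.nanmean(sim, axis=1)
            K[i:, i] = K[i, i:]
        return KinshipMatrix(samples=list(g.samples), K=K)
    if method == "standardized":
        X = D[:, poly]
        mu = np.nanmean(X, axis=0)
        nan_mask = np.isnan(X)
        X[nan_mask] = np.take(mu, np.where(nan_mask)[1])
        X -= mu
        sd = X.std(axis=0)
        nz = sd > 0
        X = X[:, nz] / sd[nz]
        K = X @ X.T / X.shape[1]
        return KinshipMatrix(samples=list(g.samples), K=K)
    raise ValueError(f"unknown kinship method: {method!r}")


@dataclass
class VarianceComponents:
    """REML estimates under the null model."""

    sigma_g2: float
    sigma_e2: float
    reml_loglik: float

    @property
    def delta(self) -> float:
        """σ_e²/σ_g² (inf when σ_g² = 0)."""
        return self.sigma_e2 / self.sigma_g2 if self.sigma_g2 > 0 else np.inf

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


def _reml_loglik(log_delta: float, S: np.ndarray, yt: np.ndarray,
                 Xt: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    """Restricted log-likelihood at δ = exp(log_delta); returns (ll, σ_g²)."""
    delta = np.exp(log_delta)
    n, q = X.shape
    w = 1.0 / (S + delta)
    XtW = Xt * w[:, None]
    A = Xt.T @ XtW
    b = XtW.T @ yt
    beta = np.linalg.solve(A, b)
    r = yt - Xt @ beta
    rss = float(r @ (w * r))
    sg2 = rss / (n - q)
    sign, logdet_A = np.linalg.slogdet(A)
    _, logdet_XX = np.linalg.slogdet(X.T @ X)
    ll = -0.5 * ((n - q) * (np.log(2 * np.pi * sg2) + 1.0)
                 + np.sum(np.log(S + delta)) + logdet_A - logdet_XX)
    return ll, sg2


def reml_fit(y: np.ndarray, kinship: KinshipMatrix,
             X: np.ndarray | None = None,
             n_grid: int = 100,
             log10_delta_range: tuple[float, float] = (-5.0, 5.0),
             ) -> VarianceComponents:
    """One-time REML fit of ``y ~ N(Xβ, σ_g²K + σ_e²I)``.

    Uses a single spectral decomposition of K, a ``n_grid``-point log-spaced
    grid over δ, then golden-section refinement between the bracketing grid
    points. Deterministic, no randomness. ``X`` defaults to an intercept.
    """
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype")
    S, U = np.linalg.eigh(kinship.K)
    if S.min() < -1e-8:
        raise ValueError("kinship matrix is not PSD")
    S = np.clip(S, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    lo, hi = log10_delta_range
    grid = np.log(10.0) * np.linspace(lo, hi, n_grid)
    lls = np.array([_reml_loglik(ld, S, yt, Xt, X)[0] for ld in grid])
    i = int(np.argmax(lls))
    a = grid[max(0, i - 1)]
    b = grid[min(n_grid - 1, i + 1)]
    # golden-section maximization on [a, b]
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    c, d = b - gr * (b - a), a + gr * (b - a)
    fc = _reml_loglik(c, S, yt, Xt, X)[0]
    fd = _reml_loglik(d, S, yt, Xt, X)[0]
    for _ in range(60):
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = _reml_loglik(c, S, yt, Xt, X)[0]
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = _reml_loglik(d, S, yt, Xt, X)[0]
        if b - a < 1e-8:
            break
    best = (a + b) / 2.0
    ll, sg2 = _reml_loglik(best, S, yt, Xt, X)
    delta = float(np.exp(best))
    # collapse to the boundary when the optimum sits at a grid edge
    if i == 0 and lls[0] >= ll:
        ll, sg2 = _reml_loglik(grid[0], S, yt, Xt, X)
        delta = float(np.exp(grid[0]))
    elif i == n_grid - 1 and lls[-1] >= ll:
        ll, sg2 = _reml_loglik(grid[-1], S, yt, Xt, X)
        delta = float(np.exp(grid[-1]))
    return VarianceComponents(sigma_g2=float(sg2), sigma_e2=float(sg2 * delta),
                              reml_loglik=float(ll))


def emmax_scan(g: GenotypeMatrix, y: np.ndarray, kinship: KinshipMatrix,
               vc: VarianceComponents, phenotype_id: str = "",
               ) -> AssociationTrack:
    """Per-marker GLS tests under the fixed covariance σ_g²K + σ_e²I.

    With σ_g² = 0 the weights are uniform and the scan reduces exactly to
    the OLS single-marker scan. Wald chi-square with per-marker residual
    variance on n − 2 df; monomorphic SNPs untested.
    """
    y = np.asarray(y, dtype=np.float64)
    n = g.n_samples
    if len(y) != n or kinship.K.shape[0] != n:
        raise ValueError("dimension mismatch between genotypes, y and K")
    S, U = np.linalg.eigh(kinship.K)
    S = np.clip(S, 0.0, None)
    var_diag = vc.sigma_g2 * S + vc.sigma_e2
    if (var_diag <= 0).all():
        raise ValueError("degenerate variance components")
    w = 1.0 / np.maximum(var_diag, 1e-12)

    X = g.dosages.astype(np.float64)
    X[g.dosages == MISSING] = np.nan
    mu = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(mu, np.where(nan_mask)[1])
    tested = X.std(axis=0) > 0

    yt = U.T @ y
    Xt = U.T @ X            # n × m
    ones_t = U.T @ np.ones(n)

    a11 = float(np.sum(w * ones_t ** 2))
    a12 = (w * ones_t) @ Xt
    a22 = np.sum(w[:, None] * Xt ** 2, axis=0)
    b1 = float(np.sum(w * ones_t * yt))
    b2 = (w * yt) @ Xt
    det = a11 * a22 - a12 ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (a11 * b2 - a12 * b1) / det
        beta0 = (a22 * b1 - a12 * b2) / det
        yy = float(np.sum(w * yt ** 2))
        rss = yy - (beta0 * b1 + beta * b2)
        s2 = rss / (n - 2)
        var_beta = s2 * a11 / det
        chi2 = beta ** 2 / var_beta
    beta = np.where(tested, beta, np.nan)
    chi2 = np.where(tested, chi2, np.nan)
    se = np.sqrt(np.where(tested, var_beta, np.nan))
    p = stats.chi2.sf(chi2, df=1)
    return AssociationTrack(chrom=g.chrom, positions=g.pos, beta=beta, se=se,
                            chi2=chi2, p_raw=p, tested=tested,
                            phenotype_id=phenotype_id)
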