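"""Population structure: PCA of the pooled genotype matrix and LD decay.

PCA follows the population-genetics norm: dosages are centered and scaled
per variant, the sample × sample covariance is decomposed, and eigenvalues
are reported in descending order with variance-explained fractions. LD is
summarized as the squared genotype correlation r² between intra-chromosomal
SNP pairs, binned by distance, with per-bin means averaged across
chromosomes (each chromosome weighted equally by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "EigenResult",
    "LDDecayCurve",
    "compute_pca",
    "pairwise_r2",
    "ld_decay_curve",
    "ld_extent",
]


@dataclass
class EigenResult:
    """Eigen-decomposition of the sample covariance of standardized dosages."""

    eigenvalues: np.ndarray      # descending, non-negative
    eigenvectors: np.ndarray     # (n_samples, k) sample scores
    var_explained: np.ndarray    # eigenvalue_i / trace
    samples: list[str]

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample": self.samples})
        for k in range(self.n_components):
            df[f"EV{k + 1}"] = self.eigenvectors[:, k]
        return df


def _standardized_dosages(g: GenotypeMatrix, scale: bool) -> np.ndarray:
    """Mean-impute missing calls per variant, center, optionally scale.

    Zero-variance (monomorphic) columns are left as all-zero after centering.
    """
    X = g.dosages.astype(np.float64)
    X[g.dosages == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    X -= col_mean
    if scale:
        sd = X.std(axis=0)
        nz = sd > 0
        X[:, nz] /= sd[nz]
    return X


def compute_pca(g: GenotypeMatrix, k: int, scale: bool = True) -> EigenResult:
    """PCA of the pooled genotype matrix; returns the top-``k`` components.

    ``k`` must not exceed ``min(n_samples - 1, n_variants)``. Missing dosages
    are mean-imputed per variant (PCA only — the scans have their own rules).
    """
    n, m = g.n_samples, g.n_variants
    if k > min(n - 1, m):
        raise ValueError(f"k={k} exceeds min(n_samples-1, n_variants)="
                         f"{min(n - 1, m)}")
    X = _standardized_dosages(g, scale)
    if not (X != 0).any():
        raise ValueError("monomorphic-only input: PCA undefined")
    cov = X @ X.T / m
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    trace = vals.sum()
    return EigenResult(eigenvalues=vals[:k], eigenvectors=vecs[:, :k],
                       var_explained=vals[:k] / trace, samples=list(g.samples))


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def pairwise_r2(g: GenotypeMatrix, max_distance_bp: int = 1_000_000,
                ) -> tuple[pd.DataFrame, int]:
    """Squared genotype correlation r² for all intra-chromosomal SNP pairs
    within ``max_distance_bp``.

    LD is population-specific: pass a per-population matrix (e.g. from
    :func:`~sweepscan.genotype_io.split_by_population`). With missing calls,
    each pair is correlated over samples non-missing at both sites.
    Zero-variance pairs are skipped; the skip tally is returned alongside
    the records ``(chrom, pos_i, pos_j, distance, r2)``.
    """
    rows = []
    n_skipped = 0
    has_missing = (g.dosages == MISSING).any()
    for chrom in pd.unique(g.chrom):
        idx = np.where(g.chrom == chrom)[0]
        pos = g.pos[idx]
        D = g.dosages[:, idx].astype(np.float64)
        mc = len(idx)
        if not has_missing:
            mu = D.mean(axis=0)
            Z = D - mu
            sd = Z.std(axis=0)
            n = Z.shape[0]
            for a in range(mc):
                hi = np.searchsorted(pos, pos[a] + max_distance_bp, side="right")
                if hi <= a + 1:
                    continue
                bs = np.arange(a + 1, hi)
                if sd[a] == 0:
                    n_skipped += len(bs)
                    continue
                ok = sd[bs] > 0
                n_skipped += int((~ok).sum())
                bs = bs[ok]
                if not len(bs):
                    continue
                r = (Z[:, a] @ Z[:, bs]) / (n * sd[a] * sd[bs])
                for b, rv in zip(bs, r):
                    rows.append((chrom, pos[a], pos[b], pos[b] - pos[a],
                                 rv * rv))
        else:
            M = g.dosages[:, idx] != MISSING
            for a in range(mc):
                hi = np.searchsorted(pos, pos[a] + max_distance_bp, side="right")
                for b in range(a + 1, hi):
                    ok = M[:, a] & M[:, b]
                    x, y = D[ok, a], D[ok, b]
                    if len(x) < 2 or x.std() == 0 or y.std() == 0:
                        n_skipped += 1
                        continue
                    r = np.corrcoef(x, y)[0, 1]
                    rows.append((chrom, pos[a], pos[b], pos[b] - pos[a], r * r))
    df = pd.DataFrame(rows, columns=["chrom", "pos_i", "pos_j", "distance", "r2"])
    return df, n_skipped


@dataclass
class LDDecayCurve:
    """Mean r² per distance bin (bins contiguous from 0)."""

    bin_edges: np.ndarray    # length n_bins + 1, bp
    mean_r2: np.ndarray      # NaN for empty bins
    n_pairs: np.ndarray      # total pairs per bin
    population: str | None = None

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_start": self.bin_edges[:-1].astype(int),
                             "bin_end": self.bin_edges[1:].astype(int),
                             "mean_r2": self.mean_r2, "n_pairs": self.n_pairs})


def ld_decay_curve(records: pd.DataFrame, bin_width_bp: int = 10_000,
                   max_distance_bp: int | None = None,
                   pair_weighted: bool = False,
                   population: str | None = None) -> LDDecayCurve:
    """Bin r² records by distance and average across chromosomes.

    By default each chromosome contributes its own per-bin mean and the curve
    is the unweighted mean of those ("means across all chromosomes");
    ``pair_weighted=True`` pools all pairs instead.
    """
    if len(records) == 0:
        raise ValueError("no LD records to bin")
    if max_distance_bp is None:
        max_distance_bp = int(records["distance"].max())
    n_bins = max(1, int(np.ceil(max_distance_bp / bin_width_bp)))
    edges = np.arange(n_bins + 1, dtype=np.float64) * bin_width_bp
    rec = records[records["distance"] <= edges[-1]]
    bin_idx = np.minimum((rec["distance"].to_numpy() // bin_width_bp).astype(int),
                         n_bins - 1)
    n_pairs = np.bincount(bin_idx, minlength=n_bins)
    if pair_weighted:
        sums = np.bincount(bin_idx, weights=rec["r2"].to_numpy(), minlength=n_bins)
        with np.errstate(invalid="ignore"):
            mean_r2 = np.where(n_pairs > 0, sums / np.maximum(n_pairs, 1), np.nan)
    else:
        per_chrom = []
        for _, grp in rec.groupby("chrom", sort=False):
            bi = np.minimum((grp["distance"].to_numpy() // bin_width_bp).astype(int),
                            n_bins - 1)
            cnt = np.bincount(bi, minlength=n_bins)
            s = np.bincount(bi, weights=grp["r2"].to_numpy(), minlength=n_bins)
            with np.errstate(invalid="ignore"):
                per_chrom.append(np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan))
        stack = np.vstack(per_chrom)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_r2 = np.nanmean(stack, axis=0)
    return LDDecayCurve(bin_edges=edges, mean_r2=mean_r2, n_pairs=n_pairs,
                        population=population)


def ld_extent(curve: LDDecayCurve, threshold: float = 0.3) -> float | None:
    """Distance (bp) at which mean r² first decays to ``threshold``.

    Linear interpolation between the centers of the bracketing bins; 0 if
    the curve already starts below the threshold; ``None`` when the curve
    never reaches it within range ("beyond range").
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    ok = ~np.isnan(curve.mean_r2)
    centers = curve.bin_centers[ok]
    means = curve.mean_r2[ok]
    if len(means) < 2:
        raise ValueError("curve needs at least two non-empty bins")
    if means[0] < threshold:
        return 0.0
    for i in range(len(means) - 1):
        if means[i] >= threshold and means[i + 1] < threshold:
            frac = (means[i] - threshold) / (means[i] - means[i + 1])
            return float(centers[i] + frac * (centers[i + 1] - centers[i]))
    return None
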