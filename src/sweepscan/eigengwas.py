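"""EigenGWAS: single-marker regression of eigenvector phenotypes on dosages.

The phenotype is an eigenvector of the genotype data itself, so SNPs that
drive population structure (large between-population frequency differences)
show the strongest association. Drift inflates the test statistic
genome-wide; the genomic-control correction divides every chi-square by
``lambda_GC = median(chi²) / 0.4549364`` (the 1-df chi-square median) before
recomputing p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix
from .popstruct import EigenResult

__all__ = [
    "CHI2_1DF_MEDIAN",
    "AssociationTrack",
    "single_marker_scan",
    "eigengwas_scan",
    "genomic_control",
]

#: Median of the chi-square distribution with 1 degree of freedom.
CHI2_1DF_MEDIAN: float = 0.4549364231195724


@dataclass
class AssociationTrack:
    """Per-SNP association results for one phenotype."""

    chrom: np.ndarray
    positions: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    chi2: np.ndarray
    p_raw: np.ndarray
    tested: np.ndarray                  # bool; monomorphic SNPs are not tested
    phenotype_id: str = ""
    lambda_gc: float | None = None
    p_gc: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "pos": self.positions,
                           "beta": self.beta, "se": self.se, "chi2": self.chi2,
                           "p_raw": self.p_raw, "tested": self.tested})
        if self.p_gc is not None:
            df["p_gc"] = self.p_gc
        return df


def _imputed_dosages(g: GenotypeMatrix) -> np.ndarray:
    X = g.dosages.astype(np.float64)
    X[g.dosages == MISSING] = np.nan
    mu = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(mu, np.where(nan_mask)[1])
    return X


def single_marker_scan(g: GenotypeMatrix, y: np.ndarray,
                       phenotype_id: str = "") -> AssociationTrack:
    """OLS of phenotype ``y`` on each SNP dosage (with intercept).

    Wald chi-square on 1 df with per-marker residual variance (n − 2 df);
    missing dosages are mean-imputed per SNP; monomorphic SNPs are reported
    untested.
    """
    y = np.asarray(y, dtype=np.float64)
    n = g.n_samples
    if len(y) != n:
        raise ValueError("phenotype length != n_samples")
    if n < 3:
        raise ValueError("need at least 3 samples")
    X = _imputed_dosages(g)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc ** 2).sum(axis=0)
    tested = sxx > 0
    syy = float((yc ** 2).sum())
    sxy = xc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(tested, sxy / sxx, np.nan)
        rss = syy - np.where(tested, beta * sxy, 0.0)
        s2 = rss / (n - 2)
        se = np.sqrt(np.where(tested, s2 / sxx, np.nan))
        chi2 = (beta / se) ** 2
    p = stats.chi2.sf(chi2, df=1)
    p[~tested] = np.nan
    return AssociationTrack(chrom=g.chrom, positions=g.pos, beta=beta, se=se,
                            chi2=chi2, p_raw=p, tested=tested,
                            phenotype_id=phenotype_id)


def eigengwas_scan(g: GenotypeMatrix,
                   evec: EigenResult | pd.DataFrame,
                   which: tuple[int, ...] = (2, 3, 4, 5),
                   gc_correct: bool = True) -> list[AssociationTrack]:
    """Scan each requested eigenvector (1-based component indices).

    ``evec`` may be an :class:`~sweepscan.popstruct.EigenResult` computed on
    the same samples or an external phenotype table with one column per
    eigenvector (``EV1``, ``EV2``, ... plus an optional ``sample`` column).
    Genomic control is applied to each scan unless ``gc_correct=False``.
    """
    tracks = []
    for k in which:
        if isinstance(evec, EigenResult):
            if evec.samples != g.samples:
                raise ValueError("eigenvectors computed on different samples")
            if not 1 <= k <= evec.n_components:
                raise IndexError(f"component {k} out of range")
            y = evec.eigenvectors[:, k - 1]
        else:
            col = f"EV{k}"
            if col not in evec.columns:
                raise IndexError(f"column {col} missing from phenotype table")
            if "sample" in evec.columns:
                tbl = evec.set_index("sample").reindex(g.samples)
                if tbl[col].isna().any():
                    raise ValueError("phenotype table missing some samples")
                y = tbl[col].to_numpy(np.float64)
            else:
                y = evec[col].to_numpy(np.float64)
        track = single_marker_scan(g, y, phenotype_id=f"EV{k}")
        if gc_correct:
            track = genomic_control(track)
        tracks.append(track)
    return tracks


def genomic_control(track: AssociationTrack) -> AssociationTrack:
    """Divide chi-squares by lambda_GC = median(chi²)/0.4549364 and refill p."""
    chi2 = track.chi2[track.tested]
    if len(chi2) < 20:
        raise ValueError("need >= 20 tested SNPs for genomic control")
    med = float(np.median(chi2))
    if med == 0:
        raise ValueError("zero median chi-square")
    track.lambda_gc = med / CHI2_1DF_MEDIAN
    p_gc = stats.chi2.sf(track.chi2 / track.lambda_gc, df=1)
    p_gc[~track.tested] = np.nan
    track.p_gc = p_gc
    return track
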