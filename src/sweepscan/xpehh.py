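"""Cross-population extended haplotype homozygosity (XP-EHH) scan.

EHH at distance x from a core SNP is the probability that two haplotypes
drawn at random from the sample are identical at every marker between the
core and x. The cross-population statistic integrates EHH over physical
distance on both sides of the core in an observed (A) and a reference (B)
population and reports ``ln(I_A / I_B)``; positive values indicate longer
haplotype homozygosity — recent selection — in the observed population.

Conventions used here (all configurable where it matters):

* EHH is unconditional on the core allele and the core column itself is
  excluded from the identity check, so EHH is exactly 1 at distance 0 (the
  empty marker set) and non-increasing outward.
* The integration boundary is shared between populations: both integrals
  stop where EHH computed on the POOLED (observed + reference) panel first
  drops below ``ehh_cutoff`` (default 0.05). Without a shared boundary the
  log-ratio would not be comparable across sites.
* Distance is physical (bp). A constant recombination rate would make
  genetic distance proportional, and the constant cancels in the log ratio.
* Raw scores are normalized genome-wide to mean 0 / SD 1 and converted to
  two-sided standard-normal p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import HaplotypePanel

__all__ = [
    "EHHCurve",
    "ScoreTrack",
    "ehh_curve",
    "integrate_ehh",
    "xpehh_scan",
    "normalize_scores",
    "scores_to_pvalues",
]


@dataclass
class EHHCurve:
    """One-sided EHH decay curve from a core SNP."""

    core_index: int
    side: str                 # "left" | "right"
    distances: np.ndarray     # bp offsets from the core, starting at 0
    ehh: np.ndarray           # values in [0, 1], ehh[0] == 1, non-increasing

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=np.float64)
        self.ehh = np.asarray(self.ehh, dtype=np.float64)
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if len(self.distances) != len(self.ehh):
            raise ValueError("distances and ehh must align")
        if len(self.ehh) and self.ehh[0] != 1.0:
            raise ValueError("EHH must start at 1 at distance 0")


def _relabel(labels: np.ndarray, column: np.ndarray) -> np.ndarray:
    """Refine a haplotype partition with one more marker column."""
    _, new = np.unique(labels * 2 + column, return_inverse=True)
    return new


def _ehh_from_labels(labels: np.ndarray, n: int) -> float:
    counts = np.bincount(labels)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ehh_curve(panel: HaplotypePanel, core_index: int, side: str,
              stop_cutoff: float = 0.0,
              max_distance_bp: float | None = None) -> EHHCurve:
    """EHH decay on one side of a core SNP.

    Stepping outward marker by marker, EHH is the fraction of haplotype
    pairs identical over all markers strictly between the core and the
    current marker, inclusive of the current marker. The walk stops when EHH
    drops below ``stop_cutoff`` (that marker is still recorded), when
    ``max_distance_bp`` is exceeded, or at the chromosome end.
    """
    n = panel.n_haplotypes
    if n < 2:
        raise ValueError("need at least 2 haplotypes for EHH")
    H = panel.haplotypes
    pos = panel.positions
    step = -1 if side == "left" else 1
    j = core_index + step
    labels = np.zeros(n, dtype=np.int64)
    distances = [0.0]
    ehh = [1.0]
    while 0 <= j < panel.n_sites:
        d = abs(float(pos[j] - pos[core_index]))
        if max_distance_bp is not None and d > max_distance_bp:
            break
        labels = _relabel(labels, H[:, j])
        e = _ehh_from_labels(labels, n)
        distances.append(d)
        ehh.append(e)
        if e < stop_cutoff:
            break
        j += step
    return EHHCurve(core_index=core_index, side=side,
                    distances=np.asarray(distances), ehh=np.asarray(ehh))


def integrate_ehh(left: EHHCurve, right: EHHCurve) -> float:
    """Trapezoid-rule integral of EHH over physical distance, both sides
    summed (units: bp · homozygosity). A single-point side contributes 0."""
    if left.core_index != right.core_index:
        raise ValueError("sides come from different cores")
    total = 0.0
    for c in (left, right):
        if len(c.distances) > 1:
            total += float(np.trapezoid(c.ehh, c.distances))
    return total


# ---------------------------------------------------------------------------
# score track
# ---------------------------------------------------------------------------

@dataclass
class ScoreTrack:
    """Per-SNP XP-EHH statistic track (raw, normalized, p-value)."""

    chrom: np.ndarray
    positions: np.ndarray
    raw: np.ndarray            # NaN where unscorable
    z: np.ndarray
    p: np.ndarray
    truncated: np.ndarray      # bool: integration hit a chromosome end
    scorable: np.ndarray       # bool
    obs_label: str = "observed"
    ref_label: str = "reference"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "pos": self.positions,
                             "raw": self.raw, "z": self.z, "p": self.p,
                             "truncated": self.truncated,
                             "scorable": self.scorable})

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, obs_label: str = "observed",
                       ref_label: str = "reference") -> "ScoreTrack":
        return cls(chrom=df["chrom"].to_numpy(dtype=object),
                   positions=df["pos"].to_numpy(np.int64),
                   raw=df["raw"].to_numpy(float), z=df["z"].to_numpy(float),
                   p=df["p"].to_numpy(float),
                   truncated=df["truncated"].to_numpy(bool),
                   scorable=df["scorable"].to_numpy(bool),
                   obs_label=obs_label, ref_label=ref_label)


def _scan_one_chrom(panel_obs: HaplotypePanel, panel_ref: HaplotypePanel,
                    ehh_cutoff: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw XP-EHH per core on one chromosome.

    A single partition of the pooled haplotypes drives all three EHH values:
    restricting the partition's group counts to one population's rows gives
    that population's EHH, so the integration boundary (pooled EHH < cutoff)
    is shared exactly.
    """
    if not np.array_equal(panel_obs.positions, panel_ref.positions):
        raise ValueError("observed and reference panels must share positions")
    H = np.vstack([panel_obs.haplotypes, panel_ref.haplotypes]).astype(np.int64)
    n_obs = panel_obs.n_haplotypes
    n_ref = panel_ref.n_haplotypes
    n_all = n_obs + n_ref
    pos = panel_obs.positions.astype(np.float64)
    m = len(pos)
    raw = np.full(m, np.nan)
    truncated = np.zeros(m, dtype=bool)
    scorable = np.zeros(m, dtype=bool)
    pair_obs = n_obs * (n_obs - 1)
    pair_ref = n_ref * (n_ref - 1)
    pair_all = n_all * (n_all - 1)

    for core in range(m):
        I_obs = I_ref = 0.0
        reached = [False, False]
        hit_end = [False, False]
        for s, step in enumerate((-1, 1)):
            labels = np.zeros(n_all, dtype=np.int64)
            e_obs_prev = e_ref_prev = 1.0
            d_prev = 0.0
            j = core + step
            while 0 <= j < m:
                labels = _relabel(labels, H[:, j])
                counts_all = np.bincount(labels)
                counts_obs = np.bincount(labels[:n_obs],
                                         minlength=len(counts_all))
                counts_ref = counts_all - counts_obs
                e_all = (counts_all * (counts_all - 1)).sum() / pair_all
                e_obs = (counts_obs * (counts_obs - 1)).sum() / pair_obs
                e_ref = (counts_ref * (counts_ref - 1)).sum() / pair_ref
                d = abs(pos[j] - pos[core])
                I_obs += 0.5 * (e_obs_prev + e_obs) * (d - d_prev)
                I_ref += 0.5 * (e_ref_prev + e_ref) * (d - d_prev)
                e_obs_prev, e_ref_prev, d_prev = e_obs, e_ref, d
                if e_all < ehh_cutoff:
                    reached[s] = True
                    break
                j += step
            else:
                hit_end[s] = True
        if not (reached[0] or reached[1]):
            continue  # boundary reached on neither side -> unscorable
        if I_obs > 0 and I_ref > 0:
            # log difference, not log of the quotient: swapping the two
            # populations then negates every raw score bit-for-bit
            raw[core] = np.log(I_obs) - np.log(I_ref)
            scorable[core] = True
            truncated[core] = hit_end[0] or hit_end[1]
    return raw, truncated, scorable


def xpehh_scan(panels_obs: HaplotypePanel | list[HaplotypePanel],
               panels_ref: HaplotypePanel | list[HaplotypePanel],
               ehh_cutoff: float = 0.05, strict: bool = False,
               obs_label: str = "observed",
               ref_label: str = "reference") -> ScoreTrack:
    """Raw XP-EHH = ln(I_obs / I_ref) at every scorable core SNP.

    ``strict=True`` additionally marks chromosome-end-truncated sites
    unscorable instead of merely flagging them. Run
    :func:`normalize_scores` and :func:`scores_to_pvalues` afterwards.
    """
    if isinstance(panels_obs, HaplotypePanel):
        panels_obs = [panels_obs]
    if isinstance(panels_ref, HaplotypePanel):
        panels_ref = [panels_ref]
    if len(panels_obs) != len(panels_ref):
        raise ValueError("panel lists differ in length")
    chroms, poss, raws, truncs, scors = [], [], [], [], []
    for po, pr in zip(panels_obs, panels_ref):
        raw, trunc, scor = _scan_one_chrom(po, pr, ehh_cutoff)
        chroms.append(np.full(len(raw), po.chrom, dtype=object))
        poss.append(po.positions)
        raws.append(raw)
        truncs.append(trunc)
        scors.append(scor)
    raw = np.concatenate(raws)
    truncated = np.concatenate(truncs)
    scorable = np.concatenate(scors)
    if strict:
        scorable = scorable & ~truncated
        raw = np.where(scorable, raw, np.nan)
    if not scorable.any():
        raise ValueError("all sites unscorable")
    nan = np.full(len(raw), np.nan)
    return ScoreTrack(chrom=np.concatenate(chroms), positions=np.concatenate(poss),
                      raw=raw, z=nan.copy(), p=nan.copy(), truncated=truncated,
                      scorable=scorable, obs_label=obs_label, ref_label=ref_label)


def normalize_scores(track: ScoreTrack) -> ScoreTrack:
    """Genome-wide normalization: z = (raw − mean) / SD over scorable sites."""
    vals = track.raw[track.scorable]
    if len(vals) < 2:
        raise ValueError("need at least 2 scorable sites to normalize")
    sd = vals.std()
    if sd == 0:
        raise ValueError("zero variance of raw scores")
    track.z = (track.raw - vals.mean()) / sd
    track.z[~track.scorable] = np.nan
    return track


def scores_to_pvalues(track: ScoreTrack) -> ScoreTrack:
    """Two-sided standard-normal p-values: p = 2·(1 − Φ(|z|))."""
    if np.isnan(track.z[track.scorable]).any():
        raise ValueError("normalize scores before computing p-values")
    track.p = 2.0 * stats.norm.sf(np.abs(track.z))
    track.p[~track.scorable] = np.nan
    return track
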