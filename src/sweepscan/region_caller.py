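"""Outlier calling and potentially-selected-region (PSR) construction.

SNPs with two-sided p < alpha (default 0.01) are outlier loci, split by the
sign of their normalized score (positive: selection in the observed
population; negative: the reference). Same-sign outliers closer than a gap
(default 10 kb, strict <) merge transitively into sections; sections are
extended by a flank (default 10 kb) on both sides, clipped to the
chromosome, to give PSRs. Interval length is ``end − start`` bp, which makes
every single-SNP PSR exactly 20 kb long with the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .xpehh import ScoreTrack

__all__ = [
    "OutlierSet",
    "Section",
    "PSR",
    "PSRSet",
    "PSRSummary",
    "call_outliers",
    "merge_outliers",
    "extend_sections",
    "summarize_regions",
    "call_psrs",
]


@dataclass
class OutlierSet:
    """Outlier loci (p < alpha) with their sign."""

    loci: pd.DataFrame       # columns: chrom, pos, z, p, sign
    alpha: float

    def __len__(self) -> int:
        return len(self.loci)

    def by_sign(self, sign: str) -> "OutlierSet":
        return OutlierSet(self.loci[self.loci["sign"] == sign].reset_index(drop=True),
                          self.alpha)


@dataclass(frozen=True)
class Section:
    """A merged run of same-sign outlier loci (span of member positions)."""

    chrom: str
    start: int
    end: int
    sign: str
    member_loci: tuple[int, ...]


@dataclass(frozen=True)
class PSR:
    """A flank-extended section; length = end − start bp."""

    chrom: str
    start: int
    end: int
    sign: str
    member_loci: tuple[int, ...]

    @property
    def n_snps(self) -> int:
        return len(self.member_loci)

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    def distance_to(self, pos: int) -> int:
        """0 if ``pos`` is inside the region, else bp to the nearest edge."""
        if self.start <= pos <= self.end:
            return 0
        return min(abs(pos - self.start), abs(pos - self.end))


@dataclass
class PSRSet:
    regions: list[PSR]

    def __len__(self) -> int:
        return len(self.regions)

    def by_sign(self, sign: str) -> list[PSR]:
        return [r for r in self.regions if r.sign == sign]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"chrom": r.chrom, "start": r.start, "end": r.end, "sign": r.sign,
              "n_snps": r.n_snps, "length_kb": r.length_bp / 1_000.0}
             for r in self.regions])


def call_outliers(track: ScoreTrack, alpha: float = 0.01) -> OutlierSet:
    """Outlier loci with strict p < alpha, signed by z."""
    if np.isnan(track.p[track.scorable]).any():
        raise ValueError("p-values must be filled before calling outliers")
    mask = track.scorable & (track.p < alpha)
    sign = np.where(track.z > 0, "positive", "negative")
    loci = pd.DataFrame({"chrom": track.chrom[mask], "pos": track.positions[mask],
                         "z": track.z[mask], "p": track.p[mask],
                         "sign": sign[mask]})
    loci = loci.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return OutlierSet(loci=loci, alpha=alpha)


def merge_outliers(outliers: OutlierSet, gap_bp: int = 10_000) -> list[Section]:
    """Transitively merge same-sign outliers with inter-position distance
    strictly < ``gap_bp`` into sections (one sign at a time)."""
    signs = set(outliers.loci["sign"])
    if len(signs) > 1:
        raise ValueError("merge one sign at a time (use OutlierSet.by_sign)")
    sections: list[Section] = []
    df = outliers.loci.sort_values(["chrom", "pos"])
    for chrom, grp in df.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy(np.int64)
        sign = grp["sign"].iloc[0]
        run = [int(pos[0])]
        for p in pos[1:]:
            if p - run[-1] < gap_bp:
                run.append(int(p))
            else:
                sections.append(Section(str(chrom), run[0], run[-1], sign,
                                        tuple(run)))
                run = [int(p)]
        sections.append(Section(str(chrom), run[0], run[-1], sign, tuple(run)))
    return sections


def extend_sections(sections: list[Section], flank_bp: int = 10_000,
                    chrom_sizes: dict[str, int] | None = None,
                    merge_touching: bool = True) -> PSRSet:
    """Extend each section by ``flank_bp`` on both sides, clipped to
    [1, chromosome length].

    When extension makes same-sign PSRs touch or overlap, a post-pass merges
    them (default on). Opposite signs are never merged.
    """
    psrs: list[PSR] = []
    for s in sections:
        if chrom_sizes is not None:
            if s.chrom not in chrom_sizes:
                raise KeyError(f"chromosome {s.chrom!r} missing from sizes table")
            limit = chrom_sizes[s.chrom]
        else:
            limit = None
        start = max(1, s.start - flank_bp)
        end = s.end + flank_bp if limit is None else min(limit, s.end + flank_bp)
        psrs.append(PSR(s.chrom, start, end, s.sign, s.member_loci))
    if merge_touching:
        psrs = _merge_overlapping(psrs)
    psrs.sort(key=lambda r: (r.chrom, r.start, r.sign))
    return PSRSet(regions=psrs)


def _merge_overlapping(psrs: list[PSR]) -> list[PSR]:
    out: list[PSR] = []
    key = lambda r: (r.chrom, r.sign, r.start)
    for r in sorted(psrs, key=key):
        if out and out[-1].chrom == r.chrom and out[-1].sign == r.sign \
                and r.start <= out[-1].end:
            prev = out.pop()
            out.append(PSR(prev.chrom, prev.start, max(prev.end, r.end), prev.sign,
                           tuple(sorted(set(prev.member_loci + r.member_loci)))))
        else:
            out.append(r)
    return out


@dataclass
class PSRSummary:
    """Per-chromosome, per-sign PSR counts and kb lengths plus grand totals
    (the layout of a per-chromosome summary table; lengths in kb)."""

    table: pd.DataFrame           # one row per chromosome + a Total row
    genome_fraction: dict[str, float] | None   # sign -> fraction of genome

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.3f")


def summarize_regions(psrs: PSRSet, chrom_sizes: dict[str, int] | None = None,
                      ) -> PSRSummary:
    """Per-chromosome counts of outlier SNPs and PSRs with total/mean kb
    lengths for each sign, plus grand totals and genome fractions."""
    chroms = sorted({r.chrom for r in psrs.regions},
                    key=lambda c: (len(c), c))
    if chrom_sizes is not None:
        chroms = sorted(set(chroms) | set(chrom_sizes),
                        key=lambda c: (len(c), c))
    rows = []
    for chrom in chroms + ["Total"]:
        row: dict[str, object] = {"chrom": chrom}
        for sign, tag in (("positive", "pos"), ("negative", "neg")):
            if chrom == "Total":
                regs = psrs.by_sign(sign)
            else:
                regs = [r for r in psrs.by_sign(sign) if r.chrom == chrom]
            lengths = np.array([r.length_bp for r in regs], dtype=float)
            row[f"n_snps_{tag}"] = int(sum(r.n_snps for r in regs))
            row[f"n_regions_{tag}"] = len(regs)
            row[f"total_length_kb_{tag}"] = lengths.sum() / 1_000.0
            row[f"mean_length_kb_{tag}"] = (lengths.mean() / 1_000.0
                                            if len(regs) else 0.0)
        row["n_snps_total"] = row["n_snps_pos"] + row["n_snps_neg"]  # type: ignore
        rows.append(row)
    table = pd.DataFrame(rows)
    genome_fraction = None
    if chrom_sizes is not None:
        genome = float(sum(chrom_sizes.values()))
        genome_fraction = {
            sign: sum(r.length_bp for r in psrs.by_sign(sign)) / genome
            for sign in ("positive", "negative")}
    return PSRSummary(table=table, genome_fraction=genome_fraction)


def call_psrs(track: ScoreTrack, alpha: float = 0.01, gap_bp: int = 10_000,
              flank_bp: int = 10_000,
              chrom_sizes: dict[str, int] | None = None,
              merge_touching: bool = True) -> PSRSet:
    """Full pipeline: outliers → merged sections (per sign) → extended PSRs."""
    outliers = call_outliers(track, alpha)
    sections: list[Section] = []
    for sign in ("positive", "negative"):
        sub = outliers.by_sign(sign)
        if len(sub):
            sections.extend(merge_outliers(sub, gap_bp))
    return extend_sections(sections, flank_bp, chrom_sizes, merge_touching)
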