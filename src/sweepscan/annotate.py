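"""Gene/QTL annotation of PSRs and hypergeometric term enrichment.

Two different overlap rules, on purpose: genes are assigned to a region on
ANY overlap (≥1 shared bp, 1-based inclusive intervals), whereas QTL
matching requires full containment in either direction (the QTL inside the
region, or the region inside the QTL) — partial QTL overlaps do not count.
QTL intervals are cleaned first: those longer than 1 Mb are dropped and
pairs overlapping by more than half (of the shorter interval, by default)
are merged into their union, iterated to a fixed point.

Term enrichment is an upper-tail hypergeometric test at a raw 0.05
threshold; a Benjamini–Hochberg column is emitted for information only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .region_caller import PSR, PSRSet

__all__ = [
    "GeneRecord",
    "QTLRecord",
    "OverlapReport",
    "EnrichmentResult",
    "read_genes",
    "read_qtl_table",
    "read_term_map",
    "genes_in_regions",
    "prepare_qtl",
    "qtl_overlap",
    "enrichment_test",
]

TRAIT_CLASSES = ("healthy", "production", "physiological", "other")


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    name: str
    chrom: str
    start: int      # 1-based inclusive
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


@dataclass(frozen=True)
class QTLRecord:
    qtl_id: str
    trait: str
    trait_class: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"QTL {self.qtl_id}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_genes(path: str) -> list[GeneRecord]:
    """Gene records from BED6 (0-based half-open) or GFF3 (gene features)."""
    genes: list[GeneRecord] = []
    with open(path) as fh:
        first = fh.readline()
        is_gff = first.startswith("##gff") or len(first.split("\t")) == 9
        fh.seek(0)
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if is_gff:
                if f[2] != "gene":
                    continue
                attrs = dict(re.findall(r"(\w+)=([^;]+)", f[8]))
                gid = attrs.get("ID", f"{f[0]}:{f[3]}")
                genes.append(GeneRecord(gid, attrs.get("Name", gid), f[0],
                                        int(f[3]), int(f[4]), f[6]))
            else:
                name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}"
                strand = f[5] if len(f) > 5 else "."
                genes.append(GeneRecord(name, name, f[0],
                                        int(f[1]) + 1, int(f[2]), strand))
    return genes


def read_qtl_table(path: str) -> list[QTLRecord]:
    """TSV with header: qtl_id, trait, trait_class, chrom, start, end."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [QTLRecord(str(r.qtl_id), str(r.trait), str(r.trait_class),
                      str(r.chrom), int(r.start), int(r.end))
            for r in df.itertuples()]


def read_term_map(path: str) -> dict[str, set[str]]:
    """Two-column TSV (term_id, gene_id) → term → gene-set mapping."""
    df = pd.read_csv(path, sep="\t")
    terms: dict[str, set[str]] = {}
    for t, gid in zip(df.iloc[:, 0], df.iloc[:, 1]):
        terms.setdefault(str(t), set()).add(str(gid))
    return terms


# ---------------------------------------------------------------------------
# gene mapping
# ---------------------------------------------------------------------------

def _any_overlap(s1: int, e1: int, s2: int, e2: int) -> bool:
    """1-based inclusive intervals share at least one bp."""
    return max(s1, s2) <= min(e1, e2)


def genes_in_regions(psrs: PSRSet, genes: list[GeneRecord],
                     ) -> dict[PSR, list[GeneRecord]]:
    """Assign genes to PSRs on any-overlap; raises if the two inputs share
    no chromosome names at all (coordinate-system mismatch guard)."""
    psr_chroms = {r.chrom for r in psrs.regions}
    gene_chroms = {g.chrom for g in genes}
    if psrs.regions and genes and not (psr_chroms & gene_chroms):
        raise ValueError(
            "no shared chromosome names between regions and genes; "
            f"regions: {sorted(psr_chroms)}, genes: {sorted(gene_chroms)}")
    out: dict[PSR, list[GeneRecord]] = {}
    for r in psrs.regions:
        out[r] = [g for g in genes
                  if g.chrom == r.chrom and _any_overlap(r.start, r.end,
                                                         g.start, g.end)]
    return out


# ---------------------------------------------------------------------------
# QTL preparation and matching
# ---------------------------------------------------------------------------

def prepare_qtl(qtls: list[QTLRecord], max_len_bp: int = 1_000_000,
                merge_frac: float = 0.5,
                reciprocal: bool = False) -> list[QTLRecord]:
    """Drop QTL longer than ``max_len_bp`` (strict >), then iteratively merge
    pairs overlapping by more than ``merge_frac`` of the shorter interval
    (or of BOTH intervals with ``reciprocal=True``) into their union until no
    pair qualifies. Idempotent: re-running on its own output is a no-op."""
    kept = [q for q in qtls if q.length <= max_len_bp]
    changed = True
    while changed:
        changed = False
        merged: list[QTLRecord] = []
        used = [False] * len(kept)
        for i, a in enumerate(kept):
            if used[i]:
                continue
            cur = a
            for j in range(i + 1, len(kept)):
                if used[j]:
                    continue
                b = kept[j]
                if b.chrom != cur.chrom:
                    continue
                ov = min(cur.end, b.end) - max(cur.start, b.start)
                if ov <= 0:
                    continue
                shorter = min(cur.length, b.length)
                if reciprocal:
                    qualifies = (shorter > 0 and ov > merge_frac * cur.length
                                 and ov > merge_frac * b.length)
                else:
                    qualifies = shorter > 0 and ov > merge_frac * shorter
                if qualifies:
                    traits = sorted({*cur.trait.split(";"), *b.trait.split(";")})
                    classes = sorted({*cur.trait_class.split(";"),
                                      *b.trait_class.split(";")})
                    cur = QTLRecord(f"{cur.qtl_id}+{b.qtl_id}", ";".join(traits),
                                    ";".join(classes), cur.chrom,
                                    min(cur.start, b.start), max(cur.end, b.end))
                    used[j] = True
                    changed = True
            merged.append(cur)
            used[i] = True
        kept = merged
    return kept


@dataclass
class OverlapReport:
    """Per-PSR QTL matches and per-trait-class PSR counts."""

    per_psr: dict[PSR, list[QTLRecord]]
    class_counts: dict[str, int]    # trait class -> # PSRs with >=1 overlap
    n_psr_with_overlap: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for psr, hits in self.per_psr.items():
            rows.append({"chrom": psr.chrom, "start": psr.start, "end": psr.end,
                         "sign": psr.sign,
                         "qtl_ids": ";".join(q.qtl_id for q in hits),
                         "trait_classes": ";".join(sorted(
                             {c for q in hits for c in q.trait_class.split(";")}))})
        return pd.DataFrame(rows)


def _contains(s1: int, e1: int, s2: int, e2: int) -> bool:
    return s1 <= s2 and e2 <= e1


def qtl_overlap(psrs: PSRSet, qtls: list[QTLRecord]) -> OverlapReport:
    """Containment-rule matching: a QTL counts iff it lies fully inside the
    PSR or the PSR lies fully inside the QTL. Partial overlaps do not."""
    per_psr: dict[PSR, list[QTLRecord]] = {}
    for r in psrs.regions:
        per_psr[r] = [q for q in qtls if q.chrom == r.chrom
                      and (_contains(r.start, r.end, q.start, q.end)
                           or _contains(q.start, q.end, r.start, r.end))]
    class_counts = {c: 0 for c in TRAIT_CLASSES}
    for hits in per_psr.values():
        classes = {c for q in hits for c in q.trait_class.split(";")}
        for c in classes:
            class_counts[c] = class_counts.get(c, 0) + 1
    n_with = sum(1 for hits in per_psr.values() if hits)
    return OverlapReport(per_psr=per_psr, class_counts=class_counts,
                         n_psr_with_overlap=n_with)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int          # selected genes with the term
    K: int          # background genes with the term
    n: int          # selected genes
    N: int          # background genes
    p: float
    p_bh: float = float("nan")   # informational only; raw p drives significance
    significant: bool = False


def enrichment_test(selected_genes: set[str], background_genes: set[str],
                    term_map: dict[str, set[str]],
                    alpha: float = 0.05) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of each term in the selected set.

    ``p = P(X >= k)`` for X hypergeometric(N, K, n); the tail includes k, so
    k = 0 gives p = 1. Results are sorted by ascending p with a raw-alpha
    significance flag and an informational Benjamini–Hochberg column.
    """
    if not selected_genes:
        raise ValueError("empty selected gene set")
    if not selected_genes <= background_genes:
        raise ValueError("selected genes must be a subset of the background")
    N = len(background_genes)
    n = len(selected_genes)
    results = []
    for term, members in term_map.items():
        K = len(members & background_genes)
        if K == 0:
            continue
        k = len(members & selected_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(term_id=term, k=k, K=K, n=n, N=N,
                                        p=min(p, 1.0)))
    results.sort(key=lambda r: (r.p, r.term_id))
    m = len(results)
    if m:
        ps = np.array([r.p for r in results])
        bh = np.minimum.accumulate((ps * m / np.arange(1, m + 1))[::-1])[::-1]
        results = [replace(r, p_bh=float(min(b, 1.0)), significant=r.p < alpha)
                   for r, b in zip(results, bh)]
    return results
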