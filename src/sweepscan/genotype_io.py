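"""Genotype and haplotype containers plus readers/writers for the scan pipeline.

Genotypes are stored as alt-allele dosages in {0, 1, 2} with an explicit
``MISSING`` sentinel (-1) that is never conflated with dosage 0. Coordinates
are 1-based inclusive throughout the package and positions are required to be
strictly increasing within a chromosome.

Supported on-disk formats:

* VCF 4.x (via :mod:`cyvcf2`); phased ``|`` genotypes are required when the
  file is read as a haplotype panel.
* PLINK binary (``.bed``/``.bim``/``.fam``, SNP-major), read-only.
* Plain tab-separated genotype / haplotype tables with a header line.

Population labels come from a two-column sample→label file (or a mapping);
this study design has exactly two populations, but the containers do not
enforce that until an operation needs it.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "VariantRecord",
    "GenotypeMatrix",
    "HaplotypePanel",
    "VariantFilterSpec",
    "FilterReport",
    "read_genotypes",
    "read_haplotypes",
    "write_genotypes",
    "write_phased_vcf",
    "apply_variant_filters",
    "split_by_population",
    "read_population_labels",
    "read_chrom_sizes",
]

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1


@dataclass(frozen=True)
class VariantRecord:
    """A single biallelic SNP."""

    chrom: str
    pos: int  # 1-based physical position (bp)
    ref_allele: str
    alt_allele: str
    qual: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt allele identical at {self.chrom}:{self.pos}")


class GenotypeMatrixError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Samples × variants alt-allele dosage matrix with variant metadata.

    Attributes
    ----------
    chrom, pos, ref, alt : per-variant arrays (pos 1-based, strictly
        increasing within each chromosome).
    qual : per-variant quality (Phred-like); NaN where absent.
    samples : ordered sample ids.
    pop_labels : one population label per sample.
    dosages : (n_samples, n_variants) int8, values in {0, 1, 2, MISSING}.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    qual: np.ndarray
    samples: list[str]
    pop_labels: np.ndarray
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.qual = np.asarray(self.qual, dtype=np.float64)
        self.pop_labels = np.asarray(self.pop_labels, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.validate()

    # ------------------------------------------------------------------ basic
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    def validate(self) -> None:
        m = self.n_variants
        for name, arr in (("chrom", self.chrom), ("ref", self.ref),
                          ("alt", self.alt), ("qual", self.qual)):
            if len(arr) != m:
                raise GenotypeMatrixError(f"{name} length {len(arr)} != n_variants {m}")
        if self.dosages.shape != (self.n_samples, m):
            raise GenotypeMatrixError(
                f"dosage shape {self.dosages.shape} != ({self.n_samples}, {m})")
        if len(self.pop_labels) != self.n_samples:
            raise GenotypeMatrixError("every sample needs a population label")
        if len(set(self.samples)) != len(self.samples):
            raise GenotypeMatrixError("duplicate sample ids")
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            raise GenotypeMatrixError("dosages must be in {0,1,2} or MISSING")
        # per-chromosome sorted, strictly increasing positions
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise GenotypeMatrixError(
                    f"positions on chromosome {c} not strictly increasing")
        if (np.asarray(self.ref) == np.asarray(self.alt)).any():
            raise GenotypeMatrixError("ref == alt at some variant")

    def variant_records(self) -> Iterator[VariantRecord]:
        for i in range(self.n_variants):
            q = self.qual[i]
            yield VariantRecord(str(self.chrom[i]), int(self.pos[i]),
                                str(self.ref[i]), str(self.alt[i]),
                                None if np.isnan(q) else float(q))

    def variants_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "pos": self.pos,
                             "ref": self.ref, "alt": self.alt, "qual": self.qual})

    # ------------------------------------------------------------- statistics
    def call_rate(self) -> np.ndarray:
        """Per-variant fraction of non-missing calls."""
        return (self.dosages != MISSING).mean(axis=0)

    def alt_freq(self) -> np.ndarray:
        """Per-variant alt-allele frequency over non-missing calls (NaN if none)."""
        d = self.dosages.astype(np.float64)
        d[self.dosages == MISSING] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    # ------------------------------------------------------------- subsetting
    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.chrom[index], self.pos[index], self.ref[index],
                              self.alt[index], self.qual[index], list(self.samples),
                              self.pop_labels.copy(), self.dosages[:, index])

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(self.chrom, self.pos, self.ref, self.alt, self.qual,
                              [self.samples[i] for i in index],
                              self.pop_labels[index], self.dosages[index, :])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        qual_eq = np.array_equal(self.qual, other.qual, equal_nan=True)
        return (qual_eq
                and self.samples == other.samples
                and np.array_equal(self.pop_labels, other.pop_labels)
                and np.array_equal(self.chrom, other.chrom)
                and np.array_equal(self.pos, other.pos)
                and np.array_equal(self.ref, other.ref)
                and np.array_equal(self.alt, other.alt)
                and np.array_equal(self.dosages, other.dosages))


@dataclass
class HaplotypePanel:
    """Fully phased binary haplotypes for one chromosome (2N rows × M sites)."""

    chrom: str
    positions: np.ndarray          # increasing 1-based bp
    haplotypes: np.ndarray         # (2N, M) uint8 in {0,1}
    sample_of_haplotype: list[str]  # row -> sample id (each sample twice)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[1] != len(self.positions):
            raise ValueError("haplotype column count != number of positions")
        if len(self.sample_of_haplotype) != self.haplotypes.shape[0]:
            raise ValueError("sample_of_haplotype length != number of rows")
        if self.haplotypes.shape[0] % 2 != 0:
            raise ValueError("haplotype rows must pair up per sample")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("panel must be fully phased: alleles in {0,1} only")
        if len(self.positions) > 1 and not (np.diff(self.positions) > 0).all():
            raise ValueError("positions must be strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def samples(self) -> list[str]:
        return self.sample_of_haplotype[::2]

    def to_dosages(self) -> np.ndarray:
        """Collapse haplotype pairs to per-sample dosages (N × M)."""
        h = self.haplotypes
        return (h[0::2, :] + h[1::2, :]).astype(np.int8)

    def subset_samples(self, sample_ids: Sequence[str]) -> "HaplotypePanel":
        wanted = set(sample_ids)
        rows = [i for i, s in enumerate(self.sample_of_haplotype) if s in wanted]
        return HaplotypePanel(self.chrom, self.positions, self.haplotypes[rows, :],
                              [self.sample_of_haplotype[i] for i in rows])


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantFilterSpec:
    """SNP filter thresholds: call rate >= 90%, MAF >= 5%, QUAL >= 20, and a
    fixed set of allowed (assembled) chromosomes. All bounds are inclusive."""

    min_call_rate: float = 0.90
    min_maf: float = 0.05
    min_qual: float = 20.0
    allowed_chroms: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_call_rate <= 1.0:
            raise ValueError("min_call_rate must be in [0, 1]")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")


@dataclass
class FilterReport:
    """Counts of variants dropped per rule (first-failing-rule attribution,
    order: qual, chrom, call_rate, maf)."""

    n_input: int = 0
    n_failed_qual: int = 0
    n_failed_chrom: int = 0
    n_failed_call_rate: int = 0
    n_failed_maf: int = 0
    n_passed: int = 0

    def check(self) -> None:
        total = (self.n_failed_qual + self.n_failed_chrom + self.n_failed_call_rate
                 + self.n_failed_maf + self.n_passed)
        assert total == self.n_input, "filter report counts do not add up"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rule": ["input", "failed_qual", "failed_chrom", "failed_call_rate",
                      "failed_maf", "passed"],
             "count": [self.n_input, self.n_failed_qual, self.n_failed_chrom,
                       self.n_failed_call_rate, self.n_failed_maf, self.n_passed]})


def apply_variant_filters(g: GenotypeMatrix,
                          spec: VariantFilterSpec) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the four SNP filters; MAF is pooled over both populations.

    Each dropped variant is attributed to the FIRST failing rule in the fixed
    order qual, chrom, call_rate, maf so report counts are deterministic.
    An empty result warns rather than failing.
    """
    report = FilterReport(n_input=g.n_variants)
    qual_fail = (~np.isnan(g.qual)) & (g.qual < spec.min_qual)
    if spec.allowed_chroms is not None:
        chrom_fail = ~np.isin(g.chrom.astype(str), sorted(spec.allowed_chroms))
    else:
        chrom_fail = np.zeros(g.n_variants, dtype=bool)
    cr_fail = g.call_rate() < spec.min_call_rate
    maf = g.maf()
    maf_fail = np.isnan(maf) | (maf < spec.min_maf)

    first = np.full(g.n_variants, "pass", dtype=object)
    for name, mask in (("maf", maf_fail), ("call_rate", cr_fail),
                       ("chrom", chrom_fail), ("qual", qual_fail)):
        first[mask] = name  # later assignments win -> qual has highest priority

    report.n_failed_qual = int((first == "qual").sum())
    report.n_failed_chrom = int((first == "chrom").sum())
    report.n_failed_call_rate = int((first == "call_rate").sum())
    report.n_failed_maf = int((first == "maf").sum())
    keep = first == "pass"
    report.n_passed = int(keep.sum())
    report.check()
    if report.n_passed == 0:
        warnings.warn("no variants passed the filters", UserWarning, stacklevel=2)
    return g.take_variants(np.where(keep)[0]), report


def split_by_population(g: GenotypeMatrix) -> dict[str, GenotypeMatrix]:
    """Partition samples by population label; the variant set is shared."""
    out: dict[str, GenotypeMatrix] = {}
    for label in pd.unique(g.pop_labels):
        idx = np.where(g.pop_labels == label)[0]
        if len(idx) < 2:
            raise GenotypeMatrixError(
                f"population {label!r} has fewer than 2 samples")
        out[str(label)] = g.take_samples(idx)
    return out


# ---------------------------------------------------------------------------
# sidecar files
# ---------------------------------------------------------------------------

def read_population_labels(path: str | os.PathLike) -> dict[str, str]:
    """Two-column whitespace/tab file: sample_id, population label."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["sample", "label"], dtype=str)
    return dict(zip(df["sample"], df["label"]))


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    """Two-column file: chromosome name, length in bp."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["chrom", "length"], dtype={"chrom": str})
    return {c: int(l) for c, l in zip(df["chrom"], df["length"])}


def _resolve_labels(samples: Sequence[str],
                    pops: Mapping[str, str] | str | os.PathLike | None) -> np.ndarray:
    if pops is None:
        raise GenotypeMatrixError(
            "population labels required: pass a mapping or a sample→label file")
    if not isinstance(pops, Mapping):
        pops = read_population_labels(pops)
    missing = [s for s in samples if s not in pops]
    if missing:
        raise GenotypeMatrixError(f"samples without population label: {missing[:5]}")
    return np.asarray([pops[s] for s in samples], dtype=object)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_genotypes(path: str | os.PathLike, format_name: str, *,
                   pops: Mapping[str, str] | str | os.PathLike | None = None,
                   multiallelic: str = "reject") -> GenotypeMatrix:
    """Read a genotype file into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    format_name : one of ``vcf``, ``plink``, ``table``.
    pops : sample→population mapping or path to a two-column label file.
    multiallelic : ``reject`` (default, raise) or ``drop`` sites with more
        than one ALT allele.
    """
    path = os.fspath(path)
    if not os.path.exists(path if format_name != "plink" else path + ".bed"):
        raise FileNotFoundError(path)
    if format_name == "vcf":
        return _read_vcf_genotypes(path, pops, multiallelic)
    if format_name == "plink":
        return _read_plink(path, pops)
    if format_name == "table":
        return _read_table_genotypes(path, pops)
    raise ValueError(f"unknown genotype format: {format_name!r}")


def _read_vcf_genotypes(path: str, pops, multiallelic: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    chroms, poss, refs, alts, quals, rows = [], [], [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            if multiallelic == "drop":
                continue
            raise GenotypeMatrixError(
                f"multi-allelic site at {v.CHROM}:{v.POS} (policy=reject)")
        gts = v.genotypes  # [a0, a1, phased]
        dos = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(gts):
            a = gt[:-1]
            if any(x < 0 for x in a):
                dos[i] = MISSING
            else:
                dos[i] = sum(1 for x in a if x == 1)
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        quals.append(np.nan if v.QUAL is None else float(v.QUAL))
        rows.append(dos)
    vcf.close()
    dosages = (np.vstack(rows).T if rows
               else np.zeros((len(samples), 0), dtype=np.int8))
    return GenotypeMatrix(np.asarray(chroms, dtype=object), np.asarray(poss),
                          np.asarray(refs, dtype=object), np.asarray(alts, dtype=object),
                          np.asarray(quals, dtype=float), samples,
                          _resolve_labels(samples, pops), dosages)


def _read_table_genotypes(path: str, pops) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta = ["chrom", "pos", "ref", "alt", "qual"]
    samples = [c for c in df.columns if c not in meta]
    dos = df[samples].to_numpy(dtype=float)
    dos = np.where(np.isnan(dos), MISSING, dos).astype(np.int8).T
    return GenotypeMatrix(df["chrom"].to_numpy(dtype=object), df["pos"].to_numpy(),
                          df["ref"].to_numpy(dtype=object), df["alt"].to_numpy(dtype=object),
                          df["qual"].to_numpy(dtype=float), samples,
                          _resolve_labels(samples, pops), dos)


_PLINK_MAGIC = b"\x6c\x1b\x01"
# 2-bit codes in SNP-major .bed: 00 hom A1, 01 missing, 10 het, 11 hom A2.
# A1 is counted as the alt allele, so dosage = number of A1 copies.
_BED_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)


def _read_plink(prefix: str, pops) -> GenotypeMatrix:
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str})
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"],
                      dtype=str)
    samples = fam["iid"].tolist()
    n, m = len(samples), len(bim)
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _PLINK_MAGIC:
            raise GenotypeMatrixError(
                ".bed magic bytes wrong or not SNP-major; cannot read")
        data = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_snp = (n + 3) // 4
    if len(data) != bytes_per_snp * m:
        raise GenotypeMatrixError(".bed size inconsistent with .bim/.fam")
    data = data.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.stack([(data >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2)
    codes = codes.reshape(m, -1)[:, :n]
    dosages = _BED_CODE_TO_DOSAGE[codes].T  # -> samples × variants
    order = np.lexsort((bim["pos"].to_numpy(), bim["chrom"].to_numpy()))
    bim = bim.iloc[order]
    dosages = dosages[:, order]
    return GenotypeMatrix(bim["chrom"].to_numpy(dtype=object), bim["pos"].to_numpy(),
                          bim["a2"].to_numpy(dtype=object), bim["a1"].to_numpy(dtype=object),
                          np.full(m, np.nan), samples,
                          _resolve_labels(samples, pops), dosages)


class PhasingError(ValueError):
    pass


def read_haplotypes(path: str | os.PathLike, format_name: str = "vcf",
                    ) -> list[HaplotypePanel]:
    """Read fully phased haplotypes, one panel per chromosome.

    Heterozygous genotypes must use the phased ``|`` separator; an unphased
    het (``0/1``) raises :class:`PhasingError`. Unphased homozygotes are
    accepted since their haplotypes are unambiguous.
    """
    path = os.fspath(path)
    if format_name == "vcf":
        return _read_vcf_haplotypes(path)
    if format_name == "table":
        return _read_table_haplotypes(path)
    raise ValueError(f"unknown haplotype format: {format_name!r}")


def _read_vcf_haplotypes(path: str) -> list[HaplotypePanel]:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    per_chrom: dict[str, tuple[list[int], list[np.ndarray]]] = {}
    for v in vcf:
        if len(v.ALT) != 1:
            raise GenotypeMatrixError(f"multi-allelic site at {v.CHROM}:{v.POS}")
        col = np.empty(2 * len(samples), dtype=np.uint8)
        for i, gt in enumerate(v.genotypes):
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if a0 < 0 or a1 < 0:
                raise PhasingError(
                    f"missing allele in phased record at {v.CHROM}:{v.POS}")
            if a0 != a1 and not phased:
                raise PhasingError(
                    f"unphased heterozygote at {v.CHROM}:{v.POS} sample {samples[i]}")
            col[2 * i] = a0
            col[2 * i + 1] = a1
        pos_list, cols = per_chrom.setdefault(v.CHROM, ([], []))
        pos_list.append(v.POS)
        cols.append(col)
    vcf.close()
    sample_of_hap = [s for s in samples for _ in range(2)]
    return [HaplotypePanel(chrom, np.asarray(pos), np.column_stack(cols), sample_of_hap)
            for chrom, (pos, cols) in per_chrom.items()]


def _read_table_haplotypes(path: str) -> list[HaplotypePanel]:
    """Header: chrom, pos, then <sample>_h1 / <sample>_h2 column pairs."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    hap_cols = [c for c in df.columns if c not in ("chrom", "pos")]
    samples_of_hap = []
    for c in hap_cols:
        if not (c.endswith("_h1") or c.endswith("_h2")):
            raise GenotypeMatrixError(f"haplotype column {c!r} must end in _h1/_h2")
        samples_of_hap.append(c[:-3])
    panels = []
    for chrom, grp in df.groupby("chrom", sort=False):
        H = grp[hap_cols].to_numpy(dtype=np.uint8).T
        panels.append(HaplotypePanel(str(chrom), grp["pos"].to_numpy(), H,
                                     samples_of_hap))
    return panels


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_genotypes(g: GenotypeMatrix, path: str | os.PathLike,
                    format_name: str = "vcf") -> None:
    """Write genotypes as (unphased) VCF or a tab-separated table.

    Output is re-readable by :func:`read_genotypes`; MISSING becomes ``./.``
    in VCF and an empty cell in the table.
    """
    path = os.fspath(path)
    if format_name == "vcf":
        _write_vcf(g, path, phased=False)
    elif format_name == "table":
        df = g.variants_dataframe()
        dos = g.dosages.astype(float).T
        dos[dos == MISSING] = np.nan
        for j, s in enumerate(g.samples):
            df[s] = dos[:, j]
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    else:
        raise ValueError(f"unknown genotype output format: {format_name!r}")


_GT_UNPHASED = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_vcf(g: GenotypeMatrix, path: str, phased: bool) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(g.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        for i in range(g.n_variants):
            q = g.qual[i]
            qs = "." if np.isnan(q) else f"{q:g}"
            gts = "\t".join(_GT_UNPHASED[int(d)] for d in g.dosages[:, i])
            fh.write(f"{g.chrom[i]}\t{g.pos[i]}\t.\t{g.ref[i]}\t{g.alt[i]}\t"
                     f"{qs}\tPASS\t.\tGT\t{gts}\n")


def write_phased_vcf(panels: Iterable[HaplotypePanel], path: str | os.PathLike,
                     ref: str = "A", alt: str = "G",
                     qual: float | None = 100.0) -> None:
    """Write phased haplotype panels to a VCF with ``|`` genotype separators.

    All panels must carry the same samples in the same order. Constant
    ref/alt alleles are written (the panel stores binary alleles only).
    """
    panels = list(panels)
    samples = panels[0].samples
    qs = "." if qual is None else f"{qual:g}"
    with open(os.fspath(path), "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for p in panels:
            fh.write(f"##contig=<ID={p.chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for p in panels:
            if p.samples != samples:
                raise GenotypeMatrixError("panels disagree on samples")
            H = p.haplotypes
            for j, pos in enumerate(p.positions):
                gts = "\t".join(f"{H[2*i, j]}|{H[2*i+1, j]}"
                                for i in range(len(samples)))
                fh.write(f"{p.chrom}\t{pos}\t.\t{ref}\t{alt}\t{qs}\tPASS\t.\tGT\t{gts}\n")
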