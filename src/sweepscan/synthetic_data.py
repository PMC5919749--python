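"""Two-population synthetic genotype generator with optional hard sweep.

The generator produces the structure the scans consume, at desk scale:

1. Ancestral allele frequencies ``p ~ Uniform(maf_floor, 1 - maf_floor)``.
2. Population frequencies drawn from the Balding–Nichols distribution
   ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` with ``F`` the target F_ST.
3. Per population, ``n_founders`` founder haplotypes drawn site-wise from
   the population frequencies.
4. Each sample haplotype is a Markov mosaic of the founders (Li–Stephens
   flavored copying): at each inter-SNP gap the copied founder switches with
   probability ``1 - exp(-copy_switch_rate * gap_bp)``. Fewer founders and
   lower switch rates mean stronger, longer-range LD.

A hard sweep is emulated by overwriting a fraction of one population's
haplotypes with a single "sweep haplotype" over an interval around the focal
site whose flanks shrink by recombination erosion (Exponential lengths per
carrier).

Everything is deterministic given ``SyntheticConfig.seed`` (one global
``numpy.random.Generator`` per run).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .genotype_io import (MISSING, GenotypeMatrix, HaplotypePanel,
                          write_phased_vcf)

__all__ = [
    "SweepConfig",
    "SyntheticConfig",
    "TruthSet",
    "SimResult",
    "simulate_two_populations",
    "insert_sweep",
    "hudson_fst",
    "write_fixture",
    "make_annotation_fixture",
]


@dataclass(frozen=True)
class SweepConfig:
    """Hard-sweep parameters: which population carries it, where, how complete
    it is, and how eroded the swept haplotype flanks are."""

    population: str = "WHITE"
    chrom_index: int = 0
    focal_pos: int = 2_500_000
    carrier_fraction: float = 0.9
    erosion_mean_bp: float = 200_000.0

    def __post_init__(self) -> None:
        if not 0.0 < self.carrier_fraction <= 1.0:
            raise ValueError("carrier_fraction must be in (0, 1]")
        if self.erosion_mean_bp <= 0:
            raise ValueError("erosion_mean_bp must be positive")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-scale defaults: two populations of 50 diploid samples, two
    5-Mb chromosomes with 2,000 SNPs each, F_ST 0.2 between the breeds."""

    n_samples: int = 50                 # per population
    n_chrom: int = 2
    chrom_length_bp: int = 5_000_000
    n_snps: int = 2_000                 # per chromosome
    fst_target: float = 0.2
    n_founders: int = 30                # per population; controls LD strength
    copy_switch_rate: float = 1e-5      # per bp; controls LD decay
    sweep: SweepConfig | None = None
    maf_floor: float = 0.05
    pop_labels: tuple[str, str] = ("WHITE", "GREEN")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_chrom", "chrom_length_bp", "n_snps",
                     "n_founders"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.fst_target < 1.0:
            raise ValueError("fst_target must be in (0, 1)")
        if not 0.0 <= self.maf_floor < 0.5:
            raise ValueError("maf_floor must be in [0, 0.5)")
        if self.copy_switch_rate < 0:
            raise ValueError("copy_switch_rate must be >= 0")

    @property
    def chrom_names(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chrom)]

    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.chrom_length_bp for c in self.chrom_names}


@dataclass
class TruthSet:
    """Ground truth of a simulation run, for power/recovery tests."""

    config: SyntheticConfig
    fst_per_snp: dict[str, np.ndarray]           # chrom -> per-SNP Hudson F_ST
    founders: dict[str, dict[str, np.ndarray]]   # pop -> chrom -> founder alleles
    founder_paths: dict[str, dict[str, np.ndarray]]  # pop -> chrom -> hap×site ids
    sweep: SweepConfig | None = None
    sweep_carriers: np.ndarray | None = None     # haplotype row indices in the pop panel

    @property
    def mean_fst(self) -> float:
        vals = np.concatenate([v[np.isfinite(v)] for v in self.fst_per_snp.values()])
        return float(vals.mean())


@dataclass
class SimResult:
    genotypes: GenotypeMatrix
    panels: dict[str, list[HaplotypePanel]]   # pop label -> one panel per chromosome
    truth: TruthSet

    def pooled_panels(self) -> list[HaplotypePanel]:
        """Panels with both populations' haplotypes stacked (obs first)."""
        labels = list(self.panels)
        out = []
        for i in range(len(self.panels[labels[0]])):
            parts = [self.panels[lab][i] for lab in labels]
            out.append(HaplotypePanel(
                parts[0].chrom, parts[0].positions,
                np.vstack([p.haplotypes for p in parts]),
                sum((p.sample_of_haplotype for p in parts), [])))
        return out


def hudson_fst(h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
    """Per-SNP Hudson F_ST estimator from two haplotype matrices (rows = haps).

    Returns NaN where the between-population heterozygosity denominator is 0.
    """
    n1, n2 = h1.shape[0], h2.shape[0]
    p1 = h1.mean(axis=0)
    p2 = h2.mean(axis=0)
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / (n1 - 1)
           - p2 * (1 - p2) / (n2 - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(den > 0, num / den, np.nan)
    return fst


def _copy_haplotypes(founders: np.ndarray, n_hap: int, positions: np.ndarray,
                     switch_rate: float, rng: np.random.Generator,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Markov founder-copying: returns (haplotypes, founder_path)."""
    n_f, m = founders.shape
    path = np.empty((n_hap, m), dtype=np.int32)
    idx = rng.integers(0, n_f, size=n_hap)
    path[:, 0] = idx
    gaps = np.diff(positions)
    p_switch = 1.0 - np.exp(-switch_rate * gaps)
    for j in range(1, m):
        sw = rng.random(n_hap) < p_switch[j - 1]
        if sw.any():
            idx = np.where(sw, rng.integers(0, n_f, size=n_hap), idx)
        path[:, j] = idx
    haps = founders[path, np.arange(m)[None, :]].astype(np.uint8)
    return haps, path


def simulate_two_populations(cfg: SyntheticConfig) -> SimResult:
    """Simulate the two-population dataset; see module docstring for the model."""
    rng = np.random.default_rng(cfg.seed)
    labels = cfg.pop_labels
    F = cfg.fst_target
    panels: dict[str, list[HaplotypePanel]] = {lab: [] for lab in labels}
    founders_t: dict[str, dict[str, np.ndarray]] = {lab: {} for lab in labels}
    paths_t: dict[str, dict[str, np.ndarray]] = {lab: {} for lab in labels}
    n_hap = 2 * cfg.n_samples
    sample_ids = {lab: [f"{lab}_{i:03d}" for i in range(cfg.n_samples)]
                  for lab in labels}

    for chrom in cfg.chrom_names:
        positions = np.sort(rng.choice(
            np.arange(1, cfg.chrom_length_bp + 1), size=cfg.n_snps, replace=False))
        p_anc = rng.uniform(cfg.maf_floor, 1.0 - cfg.maf_floor, size=cfg.n_snps)
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        for lab in labels:
            p_pop = rng.beta(a, b)
            founders = (rng.random((cfg.n_founders, cfg.n_snps)) < p_pop
                        ).astype(np.uint8)
            haps, path = _copy_haplotypes(founders, n_hap, positions,
                                          cfg.copy_switch_rate, rng)
            sample_of_hap = [s for s in sample_ids[lab] for _ in range(2)]
            panels[lab].append(HaplotypePanel(chrom, positions, haps, sample_of_hap))
            founders_t[lab][chrom] = founders
            paths_t[lab][chrom] = path

    truth = TruthSet(config=cfg, fst_per_snp={}, founders=founders_t,
                     founder_paths=paths_t)
    if cfg.sweep is not None:
        insert_sweep(panels, truth, cfg.sweep, rng)

    for i, chrom in enumerate(cfg.chrom_names):
        truth.fst_per_snp[chrom] = hudson_fst(panels[labels[0]][i].haplotypes,
                                              panels[labels[1]][i].haplotypes)

    genotypes = _genotypes_from_panels(panels, labels)
    return SimResult(genotypes=genotypes, panels=panels, truth=truth)


def insert_sweep(panels: dict[str, list[HaplotypePanel]], truth: TruthSet,
                 sweep: SweepConfig, rng: np.random.Generator) -> None:
    """Overwrite a carrier fraction of one population with the sweep haplotype.

    The sweep haplotype is founder 0's site-wise sequence. Each carrier copies
    it over ``[focal - L, focal + R]`` with ``L, R ~ Exponential(erosion_mean_bp)``
    drawn independently per carrier, emulating recombination erosion of the
    swept haplotype's flanks. Panels and truth are modified in place.
    """
    if sweep.population not in panels:
        raise ValueError(f"sweep population {sweep.population!r} not simulated")
    panel = panels[sweep.population][sweep.chrom_index]
    if not 1 <= sweep.focal_pos <= panel.positions[-1] + 1:
        pass  # focal may sit between SNPs; only require it inside the chromosome
    chrom = panel.chrom
    sweep_hap = truth.founders[sweep.population][chrom][0]
    n_hap = panel.n_haplotypes
    n_carriers = int(round(sweep.carrier_fraction * n_hap))
    carriers = rng.choice(n_hap, size=n_carriers, replace=False)
    L = rng.exponential(sweep.erosion_mean_bp, size=n_carriers)
    R = rng.exponential(sweep.erosion_mean_bp, size=n_carriers)
    pos = panel.positions
    for c, l, r in zip(carriers, L, R):
        in_win = (pos >= sweep.focal_pos - l) & (pos <= sweep.focal_pos + r)
        panel.haplotypes[c, in_win] = sweep_hap[in_win]
    truth.sweep = sweep
    truth.sweep_carriers = np.sort(carriers)


def _genotypes_from_panels(panels: dict[str, list[HaplotypePanel]],
                           labels: Sequence[str]) -> GenotypeMatrix:
    chroms, poss, dos_cols = [], [], []
    samples: list[str] = []
    pop_labels: list[str] = []
    for lab in labels:
        samples.extend(panels[lab][0].samples)
        pop_labels.extend([lab] * len(panels[lab][0].samples))
    for i in range(len(panels[labels[0]])):
        parts = [panels[lab][i] for lab in labels]
        chroms.append(np.full(parts[0].n_sites, parts[0].chrom, dtype=object))
        poss.append(parts[0].positions)
        dos_cols.append(np.vstack([p.to_dosages() for p in parts]))
    chrom = np.concatenate(chroms)
    pos = np.concatenate(poss)
    m = len(pos)
    return GenotypeMatrix(chrom, pos, np.full(m, "A", dtype=object),
                          np.full(m, "G", dtype=object), np.full(m, 100.0),
                          samples, np.asarray(pop_labels, dtype=object),
                          np.hstack(dos_cols))


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def write_fixture(sim: SimResult, outdir: str | os.PathLike) -> dict[str, str]:
    """Write a phased VCF, population labels, chromosome sizes, and truth JSON.

    Returns a name -> path mapping of everything written.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    cfg = sim.truth.config
    paths = {
        "vcf": os.path.join(outdir, "genotypes.vcf"),
        "pops": os.path.join(outdir, "pops.tsv"),
        "chrom_sizes": os.path.join(outdir, "chrom_sizes.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_phased_vcf(sim.pooled_panels(), paths["vcf"])
    with open(paths["pops"], "w") as fh:
        for s, lab in zip(sim.genotypes.samples, sim.genotypes.pop_labels):
            fh.write(f"{s}\t{lab}\n")
    with open(paths["chrom_sizes"], "w") as fh:
        for c, ln in cfg.chrom_sizes().items():
            fh.write(f"{c}\t{ln}\n")
    truth_json = {
        "fst_target": cfg.fst_target,
        "realized_mean_fst": sim.truth.mean_fst,
        "seed": cfg.seed,
        "sweep": None if sim.truth.sweep is None else {
            "population": sim.truth.sweep.population,
            "chrom": cfg.chrom_names[sim.truth.sweep.chrom_index],
            "focal_pos": sim.truth.sweep.focal_pos,
            "carrier_fraction": sim.truth.sweep.carrier_fraction,
            "erosion_mean_bp": sim.truth.sweep.erosion_mean_bp,
        },
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_json, fh, indent=2)
    return paths


def make_annotation_fixture(cfg: SyntheticConfig, outdir: str | os.PathLike,
                            seed: int = 0, n_genes_per_chrom: int = 40,
                            n_qtl_per_chrom: int = 15,
                            n_terms: int = 8) -> dict[str, str]:
    """Emit coherent toy gene/QTL/term files over the simulated coordinates.

    The QTL table deliberately plants one interval longer than 1 Mb (which the
    QTL preparation step must drop) and one pair overlapping by >50% of the
    shorter interval (which it must merge).
    """
    rng = np.random.default_rng(seed)
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genes": os.path.join(outdir, "genes.gff3"),
        "qtl": os.path.join(outdir, "qtl.tsv"),
        "terms": os.path.join(outdir, "terms.tsv"),
    }
    gene_ids = []
    with open(paths["genes"], "w") as fh:
        fh.write("##gff-version 3\n")
        k = 0
        for chrom in cfg.chrom_names:
            starts = np.sort(rng.choice(
                np.arange(1, cfg.chrom_length_bp - 60_000), size=n_genes_per_chrom,
                replace=False))
            for s in starts:
                k += 1
                gid = f"GENE{k:04d}"
                gene_ids.append(gid)
                e = int(s) + int(rng.integers(5_000, 60_000))
                strand = "+" if rng.random() < 0.5 else "-"
                fh.write(f"{chrom}\tsynthetic\tgene\t{int(s)}\t{e}\t.\t{strand}\t.\t"
                         f"ID={gid};Name={gid}\n")
    classes = ["healthy", "production", "physiological", "other"]
    with open(paths["qtl"], "w") as fh:
        fh.write("qtl_id\ttrait\ttrait_class\tchrom\tstart\tend\n")
        q = 0
        chrom0 = cfg.chrom_names[0]
        # planted cases: one >1 Mb (dropped), one 83%-overlap pair (merged)
        fh.write(f"QTL_LONG\tbig_interval\tother\t{chrom0}\t100000\t1300000\n")
        fh.write(f"QTL_OVL_A\tbody_weight\tproduction\t{chrom0}\t1500000\t1600000\n")
        fh.write(f"QTL_OVL_B\tbody_weight\tproduction\t{chrom0}\t1550000\t1610000\n")
        for chrom in cfg.chrom_names:
            for _ in range(n_qtl_per_chrom):
                q += 1
                s = int(rng.integers(1, cfg.chrom_length_bp - 900_000))
                e = s + int(rng.integers(20_000, 900_000))
                cls = classes[int(rng.integers(0, len(classes)))]
                fh.write(f"QTL{q:04d}\ttrait_{q}\t{cls}\t{chrom}\t{s}\t{e}\n")
    with open(paths["terms"], "w") as fh:
        fh.write("term_id\tgene_id\n")
        for t in range(n_terms):
            members = rng.choice(gene_ids, size=int(rng.integers(5, 20)),
                                 replace=False)
            for gid in members:
                fh.write(f"TERM{t:03d}\t{gid}\n")
    return paths
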