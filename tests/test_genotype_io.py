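import numpy as np
import pytest

import sweepscan as sw
from sweepscan.genotype_io import MISSING, GenotypeMatrixError, PhasingError


VCF_SMALL = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS0\tS1\tS2
1\t100\t.\tA\tG\t50\tPASS\t.\tGT\t0/0\t0/1\t1/1
1\t200\t.\tC\tT\t30\tPASS\t.\tGT\t./.\t0/0\t0/1
"""

POPS3 = {"S0": "A", "S1": "A", "S2": "B"}


@pytest.fixture
def small_vcf(tmp_path):
    p = tmp_path / "small.vcf"
    p.write_text(VCF_SMALL)
    return str(p)


def test_vcf_dosage_coding_and_missing(small_vcf):
    g = sw.read_genotypes(small_vcf, "vcf", pops=POPS3)
    assert g.samples == ["S0", "S1", "S2"]
    assert list(g.dosages[:, 0]) == [0, 1, 2]
    assert g.dosages[0, 1] == MISSING
    assert g.dosages[1, 1] == 0  # missing is never conflated with 0
    assert g.qual[0] == 50


def test_sample_without_label_rejected(small_vcf):
    with pytest.raises(GenotypeMatrixError, match="without population label"):
        sw.read_genotypes(small_vcf, "vcf", pops={"S0": "A", "S1": "A"})


def test_unknown_format(small_vcf):
    with pytest.raises(ValueError, match="unknown genotype format"):
        sw.read_genotypes(small_vcf, "bogus", pops=POPS3)


@pytest.mark.parametrize("fmt", ["vcf", "table"])
def test_write_read_round_trip(fmt, tmp_path, rng):
    n, m = 6, 30
    dosages = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    dosages[rng.random((n, m)) < 0.1] = MISSING
    pos = np.sort(rng.choice(np.arange(1, 10_000), size=m, replace=False))
    g = sw.GenotypeMatrix(
        chrom=np.array(["1"] * (m // 2) + ["2"] * (m - m // 2), dtype=object),
        pos=np.concatenate([pos[:m // 2], pos[:m - m // 2]]),
        ref=np.full(m, "A", dtype=object), alt=np.full(m, "C", dtype=object),
        qual=np.full(m, 42.0), samples=[f"S{i}" for i in range(n)],
        pop_labels=np.array(["A"] * 3 + ["B"] * 3, dtype=object),
        dosages=dosages)
    path = tmp_path / f"out.{fmt}"
    sw.write_genotypes(g, path, fmt)
    g2 = sw.read_genotypes(path, fmt, pops={f"S{i}": "A" if i < 3 else "B"
                                            for i in range(n)})
    assert g2 == g


def test_vcf_writer_emits_missing_as_dot_slash_dot(tmp_path):
    g = sw.GenotypeMatrix(chrom=np.array(["1"]), pos=np.array([10]),
                          ref=np.array(["A"]), alt=np.array(["T"]),
                          qual=np.array([np.nan]), samples=["X", "Y"],
                          pop_labels=np.array(["A", "B"]),
                          dosages=np.array([[MISSING], [1]], dtype=np.int8))
    path = tmp_path / "m.vcf"
    sw.write_genotypes(g, path, "vcf")
    body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
    assert "./." in body[0] and "0/1" in body[0]


def test_empty_variant_matrix_round_trips(tmp_path):
    g = sw.GenotypeMatrix(chrom=np.array([], dtype=object), pos=np.array([], int),
                          ref=np.array([], dtype=object), alt=np.array([], dtype=object),
                          qual=np.array([], float), samples=["X", "Y"],
                          pop_labels=np.array(["A", "B"]),
                          dosages=np.zeros((2, 0), dtype=np.int8))
    path = tmp_path / "empty.vcf"
    sw.write_genotypes(g, path, "vcf")
    g2 = sw.read_genotypes(path, "vcf", pops={"X": "A", "Y": "B"})
    assert g2.n_variants == 0 and g2.samples == ["X", "Y"]


PHASED_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS0\tS1
1\t100\t.\tA\tG\t50\tPASS\t.\tGT\t0|1\t1|1
"""


def test_read_phased_haplotypes(tmp_path):
    p = tmp_path / "p.vcf"
    p.write_text(PHASED_VCF)
    panels = sw.read_haplotypes(p, "vcf")
    assert len(panels) == 1
    assert panels[0].haplotypes.shape == (4, 1)
    assert list(panels[0].haplotypes[:, 0]) == [0, 1, 1, 1]


def test_unphased_het_rejected(tmp_path):
    p = tmp_path / "u.vcf"
    p.write_text(PHASED_VCF.replace("0|1", "0/1"))
    with pytest.raises(PhasingError, match="unphased het"):
        sw.read_haplotypes(p, "vcf")


def test_haplotype_and_genotype_readers_agree(neutral_sim, tmp_path):
    paths = sw.write_fixture(neutral_sim, tmp_path / "fix")
    panels = sw.read_haplotypes(paths["vcf"], "vcf")
    g = sw.read_genotypes(paths["vcf"], "vcf", pops=paths["pops"])
    for panel in panels:
        cols = np.where(g.chrom == panel.chrom)[0]
        np.testing.assert_array_equal(panel.to_dosages(), g.dosages[:, cols])


def test_haplotype_table_round_trip(tmp_path):
    H = np.array([[0, 1, 1], [1, 1, 0], [0, 0, 0], [1, 0, 1]], dtype=np.uint8)
    lines = ["chrom\tpos\tS0_h1\tS0_h2\tS1_h1\tS1_h2"]
    for j, pos in enumerate((10, 20, 30)):
        lines.append("1\t%d\t%d\t%d\t%d\t%d" % (pos, *H[:, j]))
    p = tmp_path / "h.tsv"
    p.write_text("\n".join(lines) + "\n")
    (panel,) = sw.read_haplotypes(p, "table")
    np.testing.assert_array_equal(panel.haplotypes, H)
    assert panel.samples == ["S0", "S1"]


def test_plink_bed_reader(tmp_path):
    # 3 samples × 2 SNPs, hand-packed SNP-major 2-bit codes:
    # SNP1 codes (s0,s1,s2) = homA1, het, homA2 -> dosages 2,1,0
    # SNP2 codes = missing, homA1, het -> MISSING,2,1
    # LSB-first within a byte: s0 bits 0-1, s1 bits 2-3, s2 bits 4-5
    snp1 = (0b00) | (0b10 << 2) | (0b11 << 4)   # 2,1,0
    snp2 = (0b01) | (0b00 << 2) | (0b10 << 4)   # MISSING,2,1
    (tmp_path / "toy.bed").write_bytes(bytes([0x6C, 0x1B, 0x01, snp1, snp2]))
    (tmp_path / "toy.bim").write_text("1\trs1\t0\t100\tG\tA\n1\trs2\t0\t200\tT\tC\n")
    (tmp_path / "toy.fam").write_text("F\tS0\t0\t0\t0\t-9\nF\tS1\t0\t0\t0\t-9\nF\tS2\t0\t0\t0\t-9\n")
    g = sw.read_genotypes(tmp_path / "toy", "plink", pops=POPS3)
    assert list(g.dosages[:, 0]) == [2, 1, 0]
    assert list(g.dosages[:, 1]) == [MISSING, 2, 1]
    assert g.alt[0] == "G" and g.ref[0] == "A"


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def _matrix_from_columns(cols, quals=None, chroms=None, n_samples=None):
    dos = np.array(cols, dtype=np.int8).T
    n, m = dos.shape
    quals = np.full(m, 99.0) if quals is None else np.asarray(quals, float)
    chroms = np.full(m, "1", dtype=object) if chroms is None else np.asarray(chroms, dtype=object)
    # positions must increase within each chromosome
    pos = np.zeros(m, dtype=np.int64)
    for c in set(chroms):
        idx = np.where(chroms == c)[0]
        pos[idx] = (np.arange(len(idx)) + 1) * 100
    return sw.GenotypeMatrix(chroms, pos, np.full(m, "A", dtype=object),
                             np.full(m, "G", dtype=object), quals,
                             [f"S{i}" for i in range(n)],
                             np.array(["A"] * (n // 2) + ["B"] * (n - n // 2),
                                      dtype=object), dos)


def test_call_rate_filter_drops_low_call_variant():
    col = [0, 1, 2, 1, 0, 1, 2, 0, MISSING, MISSING]  # call rate 0.8
    g = _matrix_from_columns([col])
    out, rep = sw.apply_variant_filters(g, sw.VariantFilterSpec(min_call_rate=0.9))
    assert out.n_variants == 0
    assert rep.n_failed_call_rate == 1


def test_maf_threshold_is_inclusive():
    col = [1] + [0] * 9  # alt count 1 of 20 alleles -> MAF 0.05 exactly
    g = _matrix_from_columns([col])
    out, rep = sw.apply_variant_filters(
        g, sw.VariantFilterSpec(min_maf=0.05, min_call_rate=0.0))
    assert out.n_variants == 1 and rep.n_failed_maf == 0


def test_filter_report_matches_hand_enumeration():
    # six variants over 10 samples, one planted failure per rule
    ok = [0, 1, 2, 1, 0, 1, 2, 0, 1, 1]
    low_maf = [1] + [0] * 9              # MAF 0.05 < 0.10 below
    low_cr = ok[:7] + [MISSING] * 3      # call rate 0.7
    cols = [ok, low_maf, low_cr, ok, ok, ok]
    quals = [99, 99, 99, 10, 99, 99]          # variant 3 fails qual
    chroms = ["1", "1", "1", "1", "scaffold_7", "1"]  # variant 4 fails chrom
    g = _matrix_from_columns(cols, quals=quals, chroms=chroms)
    spec = sw.VariantFilterSpec(min_call_rate=0.9, min_maf=0.10, min_qual=20,
                                allowed_chroms=frozenset({"1"}))
    out, rep = sw.apply_variant_filters(g, spec)
    assert (rep.n_input, rep.n_passed) == (6, 2)
    assert rep.n_failed_qual == 1
    assert rep.n_failed_chrom == 1
    assert rep.n_failed_call_rate == 1
    assert rep.n_failed_maf == 1


def test_first_failing_rule_attribution_order():
    # variant fails qual AND maf -> attributed to qual only
    col = [1] + [0] * 9
    g = _matrix_from_columns([col], quals=[5.0])
    _, rep = sw.apply_variant_filters(g, sw.VariantFilterSpec(min_maf=0.10))
    assert rep.n_failed_qual == 1 and rep.n_failed_maf == 0


def test_filter_idempotence(neutral_sim):
    spec = sw.VariantFilterSpec(min_maf=0.10)
    once, _ = sw.apply_variant_filters(neutral_sim.genotypes, spec)
    twice, rep = sw.apply_variant_filters(once, spec)
    assert twice == once and rep.n_passed == rep.n_input


def test_all_missing_variant_fails_call_rate():
    g = _matrix_from_columns([[MISSING] * 10])
    with pytest.warns(UserWarning, match="no variants passed"):
        _, rep = sw.apply_variant_filters(g, sw.VariantFilterSpec())
    assert rep.n_failed_call_rate == 1


# ---------------------------------------------------------------------------
# population split
# ---------------------------------------------------------------------------

def test_split_partitions_samples(neutral_sim):
    split = sw.split_by_population(neutral_sim.genotypes)
    assert set(split) == {"WHITE", "GREEN"}
    all_samples = sorted(s for g in split.values() for s in g.samples)
    assert all_samples == sorted(neutral_sim.genotypes.samples)
    for sub in split.values():
        np.testing.assert_array_equal(sub.pos, neutral_sim.genotypes.pos)


def test_split_stratified_maf_matches_masked_computation(neutral_sim):
    g = neutral_sim.genotypes
    split = sw.split_by_population(g)
    for label, sub in split.items():
        mask = g.pop_labels == label
        direct = np.minimum(g.dosages[mask].mean(axis=0) / 2,
                            1 - g.dosages[mask].mean(axis=0) / 2)
        np.testing.assert_allclose(sub.maf(), direct, atol=1e-12)


def test_split_rejects_singleton_population():
    col = [0, 1, 2]
    g = _matrix_from_columns([col])
    g.pop_labels = np.array(["A", "A", "B"], dtype=object)
    with pytest.raises(GenotypeMatrixError, match="fewer than 2"):
        sw.split_by_population(g)


def test_unsorted_positions_rejected():
    with pytest.raises(GenotypeMatrixError, match="strictly increasing"):
        sw.GenotypeMatrix(np.array(["1", "1"], dtype=object), np.array([200, 100]),
                          np.array(["A", "A"], dtype=object),
                          np.array(["G", "G"], dtype=object),
                          np.array([np.nan, np.nan]), ["X", "Y"],
                          np.array(["A", "B"]),
                          np.zeros((2, 2), dtype=np.int8))
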