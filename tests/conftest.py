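import numpy as np
import pytest

import sweepscan as sw


@pytest.fixture(scope="session")
def neutral_sim() -> sw.SimResult:
    """Small neutral two-population dataset shared across tests."""
    cfg = sw.SyntheticConfig(n_samples=20, n_chrom=2, n_snps=300,
                             chrom_length_bp=1_000_000, fst_target=0.2,
                             seed=11)
    return sw.simulate_two_populations(cfg)


@pytest.fixture(scope="session")
def sweep_sim() -> sw.SimResult:
    """Dataset with a hard sweep in the WHITE (observed) population."""
    cfg = sw.SyntheticConfig(n_samples=25, n_chrom=2, n_snps=600,
                             chrom_length_bp=2_000_000, fst_target=0.2,
                             seed=7,
                             sweep=sw.SweepConfig(population="WHITE",
                                                  chrom_index=0,
                                                  focal_pos=1_000_000,
                                                  carrier_fraction=0.9,
                                                  erosion_mean_bp=200_000))
    return sw.simulate_two_populations(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20171129)


def make_panel(haps, positions=None, chrom="1", sample_prefix="S"):
    """Build a HaplotypePanel from a list/array of binary haplotype rows."""
    H = np.asarray(haps, dtype=np.uint8)
    if positions is None:
        positions = np.arange(1, H.shape[1] + 1) * 1_000
    n_samp = H.shape[0] // 2
    soh = [f"{sample_prefix}{i}" for i in range(n_samp) for _ in range(2)]
    return sw.HaplotypePanel(chrom, np.asarray(positions), H, soh)


def brute_force_ehh(H: np.ndarray, core: int, side: str) -> tuple[np.ndarray, np.ndarray]:
    """Independent EHH oracle: explicit pairwise-identity counting.

    For each marker stepping outward from the core (core column excluded),
    counts haplotype pairs identical at every marker between the core and
    that marker, divided by C(n, 2). Returns (distances, ehh) including the
    distance-0 point at EHH = 1.
    """
    H = np.asarray(H)
    n, m = H.shape
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if side == "left":
        cols = list(range(core - 1, -1, -1))
    else:
        cols = list(range(core + 1, m))
    dists = [0.0]
    ehh = [1.0]
    for stop_idx, j in enumerate(cols):
        window = cols[:stop_idx + 1]
        ident = sum(1 for a, b in pairs
                    if all(H[a, c] == H[b, c] for c in window))
        dists.append(abs(float(j - core)))
        ehh.append(ident / len(pairs))
    return np.asarray(dists), np.asarray(ehh)
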