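import numpy as np
import pytest
from scipy import stats

import sweepscan as sw
from conftest import brute_force_ehh, make_panel


# ---------------------------------------------------------------------------
# EHH curves
# ---------------------------------------------------------------------------

def test_ehh_identical_haplotypes_stay_at_one():
    panel = make_panel(np.zeros((4, 9), dtype=np.uint8))
    curve = sw.ehh_curve(panel, 4, "right")
    np.testing.assert_array_equal(curve.ehh, np.ones(5))


def test_ehh_two_groups_of_two_gives_one_third():
    # past the core (column 2), haplotypes split into two identical pairs
    H = np.array([[0, 0, 0, 0, 0],
                  [0, 0, 0, 0, 0],
                  [0, 0, 0, 1, 1],
                  [0, 0, 0, 1, 1]], dtype=np.uint8)
    curve = sw.ehh_curve(make_panel(H), 2, "right")
    # 2 * C(2,2) / C(4,2) = 1/3
    np.testing.assert_allclose(curve.ehh, [1.0, 1 / 3, 1 / 3])


def test_ehh_all_distinct_drops_to_zero():
    H = np.array([[0, 0, 0, 0],
                  [0, 0, 0, 1],
                  [0, 0, 1, 0],
                  [0, 0, 1, 1]], dtype=np.uint8)
    curve = sw.ehh_curve(make_panel(H), 1, "right")
    assert curve.ehh[-1] == 0.0


def test_ehh_needs_two_haplotypes():
    panel = make_panel(np.zeros((2, 4), dtype=np.uint8))
    # a 1-row panel cannot form pairs; odd row counts fail at construction
    with pytest.raises(ValueError):
        bad = sw.HaplotypePanel("1", panel.positions, panel.haplotypes[:1],
                                panel.sample_of_haplotype[:1])
        sw.ehh_curve(bad, 1, "right")


def test_ehh_matches_brute_force_on_random_panels(rng):
    for _ in range(25):
        n = int(rng.integers(4, 17)) * 2
        m = int(rng.integers(5, 40))
        H = (rng.random((n, m)) < rng.uniform(0.2, 0.8)).astype(np.uint8)
        panel = make_panel(H)
        core = int(rng.integers(0, m))
        for side in ("left", "right"):
            curve = sw.ehh_curve(panel, core, side)
            _, expected = brute_force_ehh(H, core, side)
            assert np.array_equal(curve.ehh, expected)  # exact


def test_ehh_monotone_non_increasing(rng):
    for _ in range(10):
        H = (rng.random((12, 30)) < 0.5).astype(np.uint8)
        panel = make_panel(H)
        for side in ("left", "right"):
            curve = sw.ehh_curve(panel, 15, side)
            assert (np.diff(curve.ehh) <= 1e-15).all()


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _flat_curve(side, dist, value=1.0, core=0):
    return sw.EHHCurve(core, side, np.array([0.0, dist]),
                       np.array([1.0, value]))


def test_integral_of_constant_one():
    left = _flat_curve("left", 10_000)
    right = _flat_curve("right", 10_000)
    assert sw.integrate_ehh(left, right) == pytest.approx(20_000)


def test_integral_single_trapezoid():
    left = sw.EHHCurve(0, "left", np.array([0.0]), np.array([1.0]))
    right = sw.EHHCurve(0, "right", np.array([0.0, 1000.0]),
                        np.array([1.0, 0.5]))
    assert sw.integrate_ehh(left, right) == pytest.approx(750.0)


def test_integral_matches_fine_grid_riemann_oracle(rng):
    d = np.concatenate([[0.0], np.sort(rng.uniform(10, 5_000, size=12))])
    e = np.concatenate([[1.0], np.sort(rng.uniform(0, 1, size=12))[::-1]])
    curve = sw.EHHCurve(0, "right", d, e)
    other = sw.EHHCurve(0, "left", np.array([0.0]), np.array([1.0]))
    # fine-grid Riemann sum over the piecewise-linear interpolant
    grid = np.linspace(d[0], d[-1], 2_000_001)
    vals = np.interp(grid, d, e)
    riemann = float(vals[:-1].sum() * (grid[1] - grid[0]))
    got = sw.integrate_ehh(other, curve)
    assert got == pytest.approx(riemann, rel=1e-5)


def test_degenerate_single_point_side_contributes_zero():
    left = sw.EHHCurve(0, "left", np.array([0.0]), np.array([1.0]))
    right = _flat_curve("right", 2_000)
    assert sw.integrate_ehh(left, right) == pytest.approx(2_000)


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

def test_identical_panels_score_zero(rng):
    H = (rng.random((12, 60)) < 0.5).astype(np.uint8)
    panel = make_panel(H)
    other = make_panel(H, sample_prefix="T")
    track = sw.xpehh_scan(panel, other, ehh_cutoff=0.05)
    assert np.allclose(track.raw[track.scorable], 0.0)


def test_swap_negates_scores_exactly(sweep_sim):
    obs = sweep_sim.panels["WHITE"]
    ref = sweep_sim.panels["GREEN"]
    fwd = sw.xpehh_scan(obs, ref)
    rev = sw.xpehh_scan(ref, obs)
    np.testing.assert_array_equal(fwd.scorable, rev.scorable)
    np.testing.assert_allclose(fwd.raw[fwd.scorable], -rev.raw[rev.scorable],
                               rtol=0, atol=0)


def test_sign_convention_homogeneous_obs_is_positive(rng):
    # obs haplotypes identical around the core (diverse outside, so the
    # pooled-EHH boundary is still reached); ref maximally diverse
    m = 41
    mid = m // 2
    H_obs = (rng.random((8, m)) < 0.5).astype(np.uint8)
    H_obs[:, mid - 6:mid + 7] = np.tile((rng.random(13) < 0.5).astype(np.uint8),
                                        (8, 1))
    H_ref = (rng.random((8, m)) < 0.5).astype(np.uint8)
    track = sw.xpehh_scan(make_panel(H_obs), make_panel(H_ref, sample_prefix="T"),
                          ehh_cutoff=0.05)
    assert track.scorable[mid]
    assert track.raw[mid] > 0


def test_scan_matches_longhand_hand_computation():
    """End-to-end oracle on 8-haplotype hand-built panels.

    The expected raw score at the central SNP is recomputed here from
    scratch: brute-force EHH curves for each population, the pooled-panel
    stop rule, and trapezoid integrals — all long-hand.
    """
    rng = np.random.default_rng(99)
    m = 31
    H_obs = (rng.random((8, m)) < 0.5).astype(np.uint8)
    H_ref = (rng.random((8, m)) < 0.5).astype(np.uint8)
    positions = np.cumsum(rng.integers(200, 2_000, size=m)) + 1
    p_obs = make_panel(H_obs, positions)
    p_ref = make_panel(H_ref, positions, sample_prefix="T")
    cutoff = 0.05
    core = m // 2

    H_all = np.vstack([H_obs, H_ref])
    I = {"obs": 0.0, "ref": 0.0}
    for side in ("left", "right"):
        _, e_all = brute_force_ehh(H_all, core, side)
        _, e_obs = brute_force_ehh(H_obs, core, side)
        _, e_ref = brute_force_ehh(H_ref, core, side)
        if side == "left":
            idx = np.arange(core - 1, -1, -1)
        else:
            idx = np.arange(core + 1, m)
        dist = np.concatenate([[0.0], np.abs(positions[idx] - positions[core])])
        # stop at the first marker where pooled EHH < cutoff (inclusive)
        stop = len(dist)
        for t in range(1, len(e_all)):
            if e_all[t] < cutoff:
                stop = t + 1
                break
        I["obs"] += np.trapezoid(e_obs[:stop], dist[:stop])
        I["ref"] += np.trapezoid(e_ref[:stop], dist[:stop])
    expected = np.log(I["obs"] / I["ref"])

    track = sw.xpehh_scan(p_obs, p_ref, ehh_cutoff=cutoff)
    assert track.scorable[core]
    assert track.raw[core] == pytest.approx(expected, abs=1e-12)


def test_mismatched_positions_rejected():
    H = np.zeros((4, 5), dtype=np.uint8)
    a = make_panel(H, positions=[10, 20, 30, 40, 50])
    b = make_panel(H, positions=[10, 20, 30, 40, 60], sample_prefix="T")
    with pytest.raises(ValueError, match="share positions"):
        sw.xpehh_scan(a, b)


def test_all_unscorable_raises():
    # 4 identical haplotypes in both pops: pooled EHH never decays
    H = np.zeros((4, 6), dtype=np.uint8)
    with pytest.raises(ValueError, match="unscorable"):
        sw.xpehh_scan(make_panel(H), make_panel(H, sample_prefix="T"))


def test_strict_mode_drops_truncated_sites(sweep_sim):
    lax = sw.xpehh_scan(sweep_sim.panels["WHITE"], sweep_sim.panels["GREEN"])
    if not lax.truncated.any():
        pytest.skip("no truncated sites in this fixture")
    strict = sw.xpehh_scan(sweep_sim.panels["WHITE"], sweep_sim.panels["GREEN"],
                           strict=True)
    assert not (strict.scorable & strict.truncated).any()
    assert strict.scorable.sum() == (lax.scorable & ~lax.truncated).sum()


# ---------------------------------------------------------------------------
# normalization and p-values
# ---------------------------------------------------------------------------

def _track(raw):
    raw = np.asarray(raw, dtype=float)
    n = len(raw)
    return sw.ScoreTrack(chrom=np.full(n, "1", dtype=object),
                         positions=np.arange(1, n + 1) * 100,
                         raw=raw, z=np.full(n, np.nan), p=np.full(n, np.nan),
                         truncated=np.zeros(n, bool),
                         scorable=~np.isnan(raw))


def test_normalization_of_three_points():
    track = sw.normalize_scores(_track([-1.0, 0.0, 1.0]))
    np.testing.assert_allclose(track.z, [-1.224744871, 0.0, 1.224744871],
                               atol=1e-9)


def test_normalized_scores_have_zero_mean_unit_sd(rng):
    track = sw.normalize_scores(_track(rng.normal(3.0, 2.0, size=500)))
    assert track.z.mean() == pytest.approx(0.0, abs=1e-6)
    assert track.z.std() == pytest.approx(1.0, abs=1e-6)


def test_normalization_affine_invariance(rng):
    raw = rng.normal(size=200)
    z1 = sw.normalize_scores(_track(raw)).z
    z2 = sw.normalize_scores(_track(2.5 * raw - 7.0)).z
    np.testing.assert_allclose(z1, z2, atol=1e-10)


def test_pvalue_center_and_outlier_threshold():
    track = _track([0.0, 1.0, -1.0])
    track.z = np.array([0.0, stats.norm.ppf(0.995), -stats.norm.ppf(0.995)])
    sw.scores_to_pvalues(track)
    assert track.p[0] == pytest.approx(1.0)
    assert track.p[1] == pytest.approx(0.01, abs=1e-12)
    assert track.p[1] == track.p[2]  # two-sided symmetry
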