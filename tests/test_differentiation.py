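"""Windowed statistics, pairwise matrices and the Mantel IBD test."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_dataset, make_popmap, make_sites
from popdiv.differentiation import (
    PairwiseMatrix,
    genomewide_statistic,
    great_circle_km,
    mantel_ibd,
    mantel_test,
    pairwise_matrix,
    windowed_dxy,
    windowed_fst,
    windowed_pi,
)
from popdiv.io import MISSING
from popdiv.simulate import (
    PopulationSpec,
    SimulationConfig,
    simulate_allele_frequencies,
    simulate_genotypes,
)


def _two_pop(dosage_a, dosage_b, **kw):
    dosage = np.vstack([dosage_a, dosage_b])
    ds = make_dataset(dosage, **kw)
    na = len(dosage_a)
    pm = make_popmap(
        {
            f"ind{i}": ("A" if i < na else "B")
            for i in range(len(dosage))
        },
        coords={"A": (115.0, -20.0), "B": (125.0, -15.0)},
    )
    return ds, pm


def _bn_pair(f, n=50, n_loci=5000, seed=17):
    cfg = SimulationConfig(
        seed=seed, n_loci=n_loci, invariant_sites_per_locus=0,
        stratum_f={"S": 0.0},
        populations=[PopulationSpec("A", "S", f, n), PopulationSpec("B", "S", f, n)],
        missing_rate=0.0, replicate_pairs=0,
    )
    return simulate_genotypes(simulate_allele_frequencies(cfg), cfg)[:2]


def test_windowed_pi_examples():
    # window of invariant sites only -> pi = 0
    ds = make_dataset(np.zeros((3, 0), dtype=np.int8), n_invariant=5)
    pm = make_popmap({i: "A" for i in ds.individual_ids})
    out = windowed_pi(ds, pm, "A")
    assert out["value"].tolist() == [0.0]
    # single site with 2 ref / 2 alt copies -> 4/6
    ds2, pm2 = _two_pop([[1], [1]], np.zeros((0, 1), dtype=int))
    out2 = windowed_pi(ds2, pm2, "A")
    assert out2["value"].iloc[0] == pytest.approx(4 / 6)


def test_window_concatenation_is_exact():
    """Ratio-of-sums makes the union of two windows equal their pooled value."""
    rng = np.random.default_rng(0)
    dosage = rng.integers(0, 3, size=(10, 40)).astype(np.int8)
    dosage[rng.random(dosage.shape) < 0.1] = MISSING
    sites = make_sites(40, spacing=700)  # spans several 10 kb windows
    ds = make_dataset(dosage, sites=sites)
    pm = make_popmap({i: "A" for i in ds.individual_ids})
    win = windowed_pi(ds, pm, "A", window_bp=10_000)
    assert len(win) > 2
    pooled = win["num"].sum() / win["den"].sum()
    assert genomewide_statistic(ds, pm, "pi", "A") == pytest.approx(pooled)


def test_dxy_examples():
    # fixed difference -> 1.0
    ds, pm = _two_pop([[2], [2]], [[0], [0]])
    assert windowed_dxy(ds, pm, "A", "B")["value"].iloc[0] == 1.0
    # identical monomorphic populations -> 0
    ds0, pm0 = _two_pop([[0], [0]], [[0], [0]])
    assert windowed_dxy(ds0, pm0, "A", "B")["value"].iloc[0] == 0.0
    # p_A = 0.5 (k=4), p_B = 0 (k=2): (2*2 + 2*0) / (4*2) = 0.5
    ds5, pm5 = _two_pop([[1], [1]], [[0]])
    assert windowed_dxy(ds5, pm5, "A", "B")["value"].iloc[0] == pytest.approx(0.5)


def test_dxy_of_duplicated_population_equals_pi():
    """D_XY(A, copy-of-A) equals within-population pi of A under
    ratio-of-sums (checked to 1e-12 on a constructed duplicate)."""
    rng = np.random.default_rng(1)
    block = rng.integers(0, 3, size=(8, 200)).astype(np.int8)
    ds, pm = _two_pop(block, block.copy(), n_invariant=20)
    dxy = genomewide_statistic(ds, pm, "dxy", "A", "B")
    # cross-copy comparisons pair every copy of every allele, so the exact
    # identity is with the plug-in (with-replacement) diversity 2pq of A
    alt = block.sum(axis=0)
    k = 2 * block.shape[0]
    p = np.concatenate([alt / k, np.zeros(20)])
    expected = np.mean(2 * p * (1 - p))
    assert dxy == pytest.approx(expected, abs=1e-12)


def test_fst_trivial_and_recovery():
    # identical frequencies, equal n -> ~0 across 10^4 simulated sites
    ds0, pm0 = _bn_pair(0.0, n=50, n_loci=10_000)
    for est in ("wc84", "hudson"):
        assert abs(genomewide_statistic(ds0, pm0, "fst", "A", "B", estimator=est)) < 0.02
    # fixed difference, large n -> -> 1
    dsf, pmf = _two_pop([[2]] * 30, [[0]] * 30)
    assert genomewide_statistic(dsf, pmf, "fst", "A", "B") > 0.95
    # generative F = 0.2 recovered within [0.17, 0.23]
    ds, pm = _bn_pair(0.2)
    for est in ("wc84", "hudson"):
        v = genomewide_statistic(ds, pm, "fst", "A", "B", estimator=est)
        assert 0.17 <= v <= 0.23


def test_wc84_matches_independent_per_site_oracle():
    """Window WC84 equals a direct textbook computation of the variance
    components on raw genotype counts (independent re-derivation)."""
    ds, pm = _bn_pair(0.2, n=12, n_loci=60, seed=3)
    mine = genomewide_statistic(ds, pm, "fst", "A", "B", estimator="wc84")

    dosA = ds.dosage[:12].astype(float)
    dosB = ds.dosage[12:].astype(float)
    num = den = 0.0
    r = 2
    for j in range(ds.n_sites):
        gA, gB = dosA[:, j], dosB[:, j]
        n1, n2 = len(gA), len(gB)
        p1, p2 = gA.mean() / 2, gB.mean() / 2
        h1, h2 = (gA == 1).mean(), (gB == 1).mean()
        nbar = (n1 + n2) / 2
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    assert mine == pytest.approx(num / den, abs=1e-12)


def test_hudson_close_to_wc84_on_balanced_designs():
    for f in (0.05, 0.2, 0.5):
        ds, pm = _bn_pair(f, n=40, n_loci=3000, seed=int(f * 100))
        wc = genomewide_statistic(ds, pm, "fst", "A", "B", estimator="wc84")
        hu = genomewide_statistic(ds, pm, "fst", "A", "B", estimator="hudson")
        assert abs(wc - hu) < 0.03


def test_dxy_decreases_with_invariant_sites():
    rng = np.random.default_rng(2)
    block = rng.integers(0, 3, size=(12, 100)).astype(np.int8)
    ds_v, pm = _two_pop(block[:6], block[6:])
    ds_all, _ = _two_pop(block[:6], block[6:], n_invariant=100)
    v = genomewide_statistic(ds_v, pm, "dxy", "A", "B")
    a = genomewide_statistic(ds_all, pm, "dxy", "A", "B")
    assert a < v


def test_windowed_fst_empty_window_flagged_missing():
    # one window holds only invariant sites -> NaN, not 0
    sites = pd.concat(
        [make_sites(1, 0, start=1), make_sites(0, 3, start=20_001)]
    ).reset_index(drop=True)
    dosage = np.array([[1, 0, 0, 0], [1, 0, 0, 0], [0, 0, 0, 0], [2, 0, 0, 0]])
    ds = make_dataset(dosage, sites=sites)
    pm = make_popmap({f"ind{i}": ("A" if i < 2 else "B") for i in range(4)})
    out = windowed_fst(ds, pm, "A", "B")
    assert np.isnan(out["value"].iloc[1])


def test_pairwise_matrix_rules(small_system):
    ds, pm, _ = small_system
    fst = pairwise_matrix(ds, pm, metric="fst", min_n=6)
    # populations under the size floor are absent
    small = [p for p in pm.populations if len(pm.individuals_of(p)) < 6]
    assert not set(small) & set(fst.populations)
    np.testing.assert_allclose(fst.values, fst.values.T)
    # duplicated population -> off-diagonal ~ 0 (slightly negative is the
    # known finite-sample behavior: the unbiased within-heterozygosity
    # exceeds the plug-in between-copy heterozygosity by a 1/(k-1) factor)
    rng = np.random.default_rng(4)
    p = rng.uniform(0.1, 0.9, 500)
    block = rng.binomial(2, p, size=(30, 500)).astype(np.int8)
    dsd, pmd = _two_pop(block, block.copy())
    d = pairwise_matrix(dsd, pmd, metric="fst", min_n=6)
    assert abs(d.values[0, 1]) < 0.03


def test_mantel_properties():
    rng = np.random.default_rng(5)
    base = rng.random((8, 8))
    base = (base + base.T) / 2
    np.fill_diagonal(base, 0)
    # identical matrices up to positive scaling -> r = 1, p = 1/(perm+1)
    r, p = mantel_test(base, 3.0 * base, permutations=99, seed=0)
    assert r == pytest.approx(1.0)
    assert p == pytest.approx(1 / 100)
    # permutation count honored in the p denominator
    _, p999 = mantel_test(base, 3.0 * base, permutations=999, seed=0)
    assert p999 == pytest.approx(1 / 1000)


def test_mantel_matches_scikit_bio():
    """Cross-check r and one-sided permutation p against the independent
    scikit-bio implementation on the same matrices."""
    from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

    rng = np.random.default_rng(6)
    n = 12
    pts = rng.random((n, 2))
    d1 = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    d2 = d1 + rng.normal(0, 0.05, size=d1.shape)
    d2 = (d2 + d2.T) / 2
    np.fill_diagonal(d2, 0)
    r_mine, _ = mantel_test(d1, d2, permutations=999, seed=0)
    r_ref, p_ref, _ = skbio_mantel(
        DistanceMatrix(d1), DistanceMatrix(d2), method="pearson",
        permutations=999, alternative="greater",
    )
    assert r_mine == pytest.approx(r_ref, abs=1e-12)
    _, p_mine = mantel_test(d1, d2, permutations=999, seed=0)
    assert abs(p_mine - p_ref) < 0.05  # both tiny for a strong signal


def test_mantel_ibd_wiring(small_system):
    ds, pm, _ = small_system
    fst = pairwise_matrix(ds, pm, metric="fst", min_n=6)
    out = mantel_ibd(fst, pm.coordinates(), permutations=99, seed=0)
    assert -1 <= out["r"] <= 1 and 0 < out["p"] <= 1
    # F_ST = 1 cannot be linearized
    bad = PairwiseMatrix(["X", "Y"], np.array([[0.0, 1.0], [1.0, 0.0]]), "fst")
    coords = pd.DataFrame(
        {"lon": [1.0, 2.0], "lat": [0.0, 0.0]}, index=["X", "Y"]
    )
    with pytest.raises(ValueError, match="linearized"):
        mantel_ibd(bad, coords)


def test_great_circle_distance_known_value():
    coords = pd.DataFrame({"lon": [0.0, 0.0], "lat": [0.0, 1.0]}, index=["a", "b"])
    d = great_circle_km(coords)
    assert d[0, 1] == pytest.approx(111.19, rel=1e-3)  # one degree of latitude
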