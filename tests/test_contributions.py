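"""Gene/allelic diversity partitions, leave-one-out and optimal pools."""

import numpy as np
import pandas as pd
import pytest
from itertools import product

from conftest import make_dataset, make_popmap
from popdiv.io import AlleleTable, allele_counts
from popdiv.contributions import (
    diversity_partition,
    leave_one_out_contributions,
    optimal_pool_contributions,
    pooled_gene_diversity,
    subsample_average,
)


def _table(alt, n_typed, pops=None):
    """AlleleTable from per-(pop, locus) alt copies and typed counts."""
    alt = np.asarray(alt)
    n_typed = np.asarray(n_typed)
    n_pops, n_loci = alt.shape
    ds = make_dataset(np.zeros((1, n_loci), dtype=np.int8))
    return AlleleTable(
        populations=pops or [f"P{i}" for i in range(n_pops)],
        sites=ds.sites,
        alt_copies=alt,
        n_typed=n_typed,
        n_het=np.zeros_like(alt),
    )


def test_gene_partition_fixed_difference():
    # two populations fixed for alternative alleles, equal weights
    t = _table([[4, 4], [0, 0]], [[2, 2], [2, 2]])
    part = diversity_partition(t, "equal")
    assert part.H_S == 0.0
    assert part.D_G == pytest.approx(0.5)
    assert part.H_T == pytest.approx(0.5)
    # equals pooled-frequency heterozygosity
    assert part.H_T == pytest.approx(pooled_gene_diversity(t, "equal"))
    # allelic side: A_S = 1, D_A = 0.5, A_T = 1.5
    assert part.A_S == 1.0 and part.D_A == pytest.approx(0.5)
    assert part.A_T == pytest.approx(1.5)


def test_identical_populations_have_zero_between_terms():
    t = _table([[3, 1], [3, 1]], [[5, 5], [5, 5]])
    part = diversity_partition(t, "equal")
    assert part.D_G == pytest.approx(0.0, abs=1e-15)
    assert part.D_A == 0.0


def test_pooling_identity_on_random_tables():
    """H_T equals the gene diversity of the weight-pooled frequencies for
    random allele tables and random simplex weights."""
    rng = np.random.default_rng(0)
    for _ in range(20):
        n_pops, n_loci = rng.integers(2, 6), rng.integers(3, 30)
        n_typed = rng.integers(2, 20, size=(n_pops, n_loci))
        alt = rng.integers(0, 2 * n_typed + 1)
        w = rng.dirichlet(np.ones(n_pops))
        t = _table(alt, n_typed)
        part = diversity_partition(t, w)
        assert part.H_T == pytest.approx(pooled_gene_diversity(t, w), abs=1e-12)
        assert part.H_T == pytest.approx(part.H_S + part.D_G, abs=1e-14)
        assert part.A_T == pytest.approx(part.A_S + part.D_A, abs=1e-14)


def test_allelic_total_equals_average_pairwise_union():
    """A_T reproduces the mean allele count of pairwise population unions
    (enumeration oracle over ordered pairs including self-pairs)."""
    rng = np.random.default_rng(1)
    for _ in range(10):
        n_pops, n_loci = rng.integers(2, 5), rng.integers(2, 15)
        n_typed = rng.integers(1, 10, size=(n_pops, n_loci))
        alt = rng.integers(0, 2 * n_typed + 1)
        t = _table(alt, n_typed)
        part = diversity_partition(t, "equal")
        ref = 2 * n_typed - alt
        union_sum = 0.0
        for i, j in product(range(n_pops), repeat=2):
            per_locus = (
                ((alt[i] > 0) | (alt[j] > 0)).astype(float)
                + ((ref[i] > 0) | (ref[j] > 0)).astype(float)
            )
            union_sum += per_locus.mean()
        assert part.A_T == pytest.approx(union_sum / n_pops**2, abs=1e-12)


def test_leave_one_out_contributions():
    # three populations: two maximally diverged + a clone of the second
    t = _table([[4, 4], [0, 0], [0, 0]], np.full((3, 2), 2))
    loo = leave_one_out_contributions(t, "equal")
    loo = loo.set_index("population_id")
    # removing the clone cannot lose between-population alleles
    assert loo.loc["P2", "D_A"] <= 0
    # contributions equal recomputed deltas by definition
    full = diversity_partition(t, "equal").as_dict()
    sub = diversity_partition(t.subset_populations(["P1", "P2"]), "equal").as_dict()
    want = 100 * (full["H_T"] - sub["H_T"]) / full["H_T"]
    assert loo.loc["P0", "H_T"] == pytest.approx(want)
    with pytest.raises(ValueError, match="at least 3"):
        leave_one_out_contributions(t.subset_populations(["P0", "P1"]))


def test_removing_one_of_two_diverged_populations_drops_all_ht():
    """With only two populations fixed for alternative alleles, H_T goes
    0.5 -> 0 when either is removed (the 100% contribution case)."""
    t = _table([[4, 4], [0, 0]], np.full((2, 2), 2))
    full = diversity_partition(t, "equal")
    solo = diversity_partition(t.subset_populations(["P1"]), [1.0])
    assert full.H_T == pytest.approx(0.5) and solo.H_T == 0.0


def test_duplicate_populations_have_equal_contributions():
    t = _table([[4, 1], [0, 3], [0, 3]], np.full((3, 2), 3))
    loo = leave_one_out_contributions(t, "equal").set_index("population_id")
    for c in ("A_T", "H_T", "H_S"):
        assert loo.loc["P1", c] == pytest.approx(loo.loc["P2", c], abs=1e-10)


def test_optimal_pool_symmetric_case_and_grid_oracle():
    # two populations fixed for alternative alleles -> w = (1/2, 1/2), H = 1/2
    t = _table([[4, 4], [0, 0]], np.full((2, 2), 2))
    out = optimal_pool_contributions(t, objective="H", seed=0)
    np.testing.assert_allclose(out["weight"], [0.5, 0.5], atol=1e-6)
    assert out["objective_value"].iloc[0] == pytest.approx(0.5, abs=1e-9)

    # 3-population random instance vs brute-force simplex grid (step 0.01)
    rng = np.random.default_rng(2)
    n_typed = np.full((3, 12), 10)
    alt = rng.integers(0, 21, size=(3, 12))
    t3 = _table(alt, n_typed)
    p = alt / 20
    for objective in ("H", "k"):
        out = optimal_pool_contributions(t3, objective=objective, seed=1)
        best = -np.inf
        copies = 2000
        for i in range(101):
            for j in range(101 - i):
                w = np.array([i, j, 100 - i - j]) / 100
                pbar = w @ p
                if objective == "H":
                    v = (2 * pbar * (1 - pbar)).mean()
                else:
                    v = ((1 - (1 - pbar) ** copies) + (1 - pbar**copies)).mean()
                best = max(best, v)
        assert out["objective_value"].iloc[0] >= best - 1e-4


def test_optimum_at_least_equal_weights():
    rng = np.random.default_rng(3)
    n_typed = np.full((4, 30), 8)
    alt = rng.integers(0, 17, size=(4, 30))
    t = _table(alt, n_typed)
    p = alt / 16
    out = optimal_pool_contributions(t, objective="H", seed=0)
    eq = np.full(4, 0.25)
    pbar = eq @ p
    assert out["objective_value"].iloc[0] >= (2 * pbar * (1 - pbar)).mean() - 1e-12


def test_dominating_population_takes_all_weight():
    # one population already at p = 0.5 everywhere dominates
    t = _table([[10, 10], [0, 20]], np.full((2, 2), 10))
    out = optimal_pool_contributions(t, objective="H", seed=0)
    assert out.set_index("population_id").loc["P0", "weight"] > 0.999


def test_subsample_average_protocol(small_system):
    ds, pm, _ = small_system

    def analysis(table):
        part = diversity_partition(table, "equal")
        return pd.DataFrame(
            {"population_id": table.populations, "H_S": part.H_S}
        )

    m1, s1 = subsample_average(analysis, ds, pm, n=6, reps=4, seed=5)
    m2, _ = subsample_average(analysis, ds, pm, n=6, reps=4, seed=5)
    pd.testing.assert_frame_equal(m1, m2)  # same seed -> identical
    assert (s1["H_S"].dropna() >= 0).all()
    # n = population size, reps = 1 reduces to the direct analysis
    tiny_pops = {p: len(pm.individuals_of(p)) for p in pm.populations}
    n_all = min(tiny_pops.values())
    m3, _ = subsample_average(analysis, ds, pm, n=n_all, reps=1, seed=0)
    assert len(m3) > 0


def test_subsample_sd_shrinks_with_reps(small_system):
    """Mean over reps stabilizes ~ 1/sqrt(reps): the SD of rep-means over
    many draws is smaller for larger reps."""
    ds, pm, _ = small_system

    def analysis(table):
        part = diversity_partition(table, "equal")
        return pd.DataFrame({"population_id": table.populations[:1],
                             "H_S": part.H_S})

    means_small = [
        subsample_average(analysis, ds, pm, n=6, reps=2, seed=s)[0]["H_S"].iloc[0]
        for s in range(12)
    ]
    means_big = [
        subsample_average(analysis, ds, pm, n=6, reps=8, seed=s)[0]["H_S"].iloc[0]
        for s in range(12)
    ]
    assert np.std(means_big) < np.std(means_small)
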