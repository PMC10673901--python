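"""Filtering-cascade behavior: boundary semantics, kinship, idempotence."""

import numpy as np
import pytest

from conftest import make_dataset, make_popmap, make_sites
from popdiv.io import MISSING, allele_counts
from popdiv.filtering import (
    allsites_filter,
    filter_allelic_depth,
    filter_mac,
    filter_max_het,
    filter_replicate_reproducibility,
    filter_site_presence,
    iterative_call_rate_filter,
    kinship_beta_dosage,
    prune_one_snp_per_locus,
    remove_related,
    run_cascade,
)


def _uniform_popmap(ds, pop="P1"):
    return make_popmap({i: pop for i in ds.individual_ids})


def test_site_presence_boundary():
    # 10 individuals; site 0 typed in 4 (40%), site 1 typed in exactly 5
    dosage = np.zeros((10, 2), dtype=np.int8)
    dosage[4:, 0] = MISSING
    dosage[5:, 1] = MISSING
    dosage[0, :] = 1
    ds = make_dataset(dosage)
    pm = _uniform_popmap(ds)
    out, report = filter_site_presence(ds, pm, min_sample_fraction=0.5)
    assert out.n_sites == 1  # 40% removed, exactly ceil(0.5*10)=5 retained
    assert out.sites.iloc[0]["pos"] == ds.sites.iloc[1]["pos"]
    # threshold 0 is the identity
    out0, _ = filter_site_presence(ds, pm, min_sample_fraction=0.0)
    assert out0.n_sites == ds.n_sites
    with pytest.raises(ValueError):
        filter_site_presence(ds, pm, min_sample_fraction=1.5)


def test_max_het_strictly_greater():
    # site 0: 3/4 het (0.75) -> removed; site 1: 0 het -> kept;
    # site 2: exactly 0.70 het (7/10) -> kept
    col0 = [1, 1, 1, 0] + [MISSING] * 6
    col1 = [0, 2, 0, 2] + [MISSING] * 6
    col2 = [1] * 7 + [0, 0, 2]
    ds = make_dataset(np.array([col0, col1, col2]).T)
    out, _ = filter_max_het(ds, max_ho=0.70)
    kept = out.sites["pos"].tolist()
    assert kept == [11, 21]


def test_prune_one_snp_per_locus_rule():
    sites = make_sites(3, locus_per_site=False)
    dosage = np.array([[0, 1, 1], [MISSING, 0, 2], [1, MISSING, 0]])
    ds = make_dataset(dosage, sites=sites)
    out = prune_one_snp_per_locus(ds)
    # site 2 has the max call rate (3/3)
    assert out.n_sites == 1 and out.sites.iloc[0]["pos"] == 21
    # tie on call rate -> smallest position wins
    ds2 = make_dataset(np.array([[0, 1, 1]]), sites=sites)
    out2 = prune_one_snp_per_locus(ds2)
    assert out2.sites.iloc[0]["pos"] == 1
    # single-SNP locus unchanged
    single = make_dataset(np.array([[1]]))
    assert prune_one_snp_per_locus(single).n_sites == 1


def test_allelic_depth_filter():
    # 3 sites: mean AD 2.0 (removed), balanced het (kept), 10-vs-1 het (removed)
    dosage = np.array([[1, 1, 1], [1, 1, 1]])
    ref = np.array([[1, 10, 10], [1, 10, 10]])
    alt = np.array([[1, 10, 1], [1, 10, 1]])
    ds = make_dataset(dosage, ref_depth=ref, alt_depth=alt)
    out, _ = filter_allelic_depth(ds)
    assert out.sites["pos"].tolist() == [11]
    nodepth = make_dataset(dosage)
    with pytest.raises(ValueError, match="no AD"):
        filter_allelic_depth(nodepth)


def test_iterative_call_rate_reaches_final_thresholds():
    rng = np.random.default_rng(0)
    dosage = rng.integers(0, 3, size=(40, 300)).astype(np.int8)
    miss = rng.random(dosage.shape) < 0.2
    dosage[miss] = MISSING
    ds = make_dataset(dosage)
    out, report = iterative_call_rate_filter(ds)
    assert out.n_sites > 0 and out.n_individuals > 0
    assert (out.site_call_rate() >= 0.95).all()
    assert (out.sample_call_rate() >= 0.90).all()
    # fully typed data is untouched
    full = make_dataset(np.ones((5, 5), dtype=np.int8))
    same, _ = iterative_call_rate_filter(full)
    assert same.n_sites == 5 and same.n_individuals == 5
    with pytest.raises(ValueError, match="equal length"):
        iterative_call_rate_filter(ds, sample_targets=[0.9], snp_targets=[0.5, 0.95])
    with pytest.raises(ValueError, match="schedule"):
        iterative_call_rate_filter(ds, sample_targets=[0.9, 0.5], snp_targets=[0.5, 0.95])


def test_one_shot_vs_scheduled_can_differ():
    """A single-pass filter at the final thresholds need not retain the same
    set as the scheduled run; both must satisfy the final thresholds."""
    rng = np.random.default_rng(3)
    dosage = rng.integers(0, 3, size=(30, 200)).astype(np.int8)
    # concentrate missingness in a few samples so order matters
    dosage[:5, :120] = MISSING
    dosage[5:, rng.integers(0, 200, 40)] = MISSING
    ds = make_dataset(dosage)
    scheduled, _ = iterative_call_rate_filter(ds)
    oneshot, _ = iterative_call_rate_filter(
        ds, sample_targets=[0.90], snp_targets=[0.95]
    )
    for out in (scheduled, oneshot):
        assert (out.site_call_rate() >= 0.95).all()
        assert (out.sample_call_rate() >= 0.90).all()


def test_mac_boundaries():
    # MAC 2 removed, MAC 3 kept, monomorphic removed
    cols = {
        "mac2": [1, 1, 0, 0, 0, 0],
        "mac3": [1, 1, 1, 0, 0, 0],
        "mono": [0, 0, 0, 0, 0, 0],
    }
    ds = make_dataset(np.array(list(cols.values())).T)
    out, _ = filter_mac(ds, min_mac=3)
    assert out.sites["pos"].tolist() == [11]


def test_replicate_reproducibility_rules():
    # pair (ind0, ind1): disagree at site 0, one-missing at site 1, agree at 2
    dosage = np.array(
        [
            [0, 1, 2],
            [1, MISSING, 2],
            [2, 2, 0],
        ]
    )
    ds = make_dataset(dosage, replicate_pairs=[("ind0", "ind1")])
    out, _ = filter_replicate_reproducibility(ds)
    assert out.sites["pos"].tolist() == [11, 21]  # mismatch site dropped
    # one pair member dropped, the higher-call-rate one kept (ind0 full)
    assert "ind0" in out.individual_ids and "ind1" not in out.individual_ids
    # no declared pairs -> warning, no-op
    ds2 = make_dataset(dosage)
    with pytest.warns(UserWarning, match="no replicate"):
        out2, _ = filter_replicate_reproducibility(ds2)
    assert out2.n_sites == 3


def test_kinship_identity_and_centering():
    rng = np.random.default_rng(1)
    dosage = (2 * rng.integers(0, 2, size=(6, 500))).astype(np.int8)
    dosage[1] = dosage[0]  # identical fully homozygous genomes
    ds = make_dataset(dosage)
    kin = kinship_beta_dosage(ds)
    assert kin.values[0, 1] == pytest.approx(1.0)
    assert kin.off_diagonal().mean() == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        kinship_beta_dosage(make_dataset(np.array([[1, 0]])))


def test_kinship_recovers_full_sibs():
    """Simulated full sibs among unrelated individuals sit near beta 0.25."""
    from popdiv.simulate import (
        PopulationSpec,
        SimulationConfig,
        simulate_allele_frequencies,
        simulate_genotypes,
    )

    cfg = SimulationConfig(
        seed=5, n_loci=6000, invariant_sites_per_locus=0,
        stratum_f={"S": 0.0},
        populations=[PopulationSpec("p", "S", 0.0, 40)],
        missing_rate=0.0, replicate_pairs=0, full_sib_pairs=3,
    )
    ds, _, truth = simulate_genotypes(simulate_allele_frequencies(cfg), cfg)
    kin = kinship_beta_dosage(ds)
    idx = {v: i for i, v in enumerate(ds.individual_ids)}
    sib_vals = [kin.values[idx[a], idx[b]] for a, b in truth["sib_pairs"]]
    assert 0.2 <= np.mean(sib_vals) <= 0.3


def test_remove_related_examples():
    rng = np.random.default_rng(2)
    ds = make_dataset(rng.integers(0, 3, size=(4, 50)).astype(np.int8))
    base = np.zeros((4, 4))
    # one pair over threshold -> exactly one removal
    k = base.copy()
    k[0, 1] = k[1, 0] = 0.3
    from popdiv.filtering import KinshipMatrix

    out, _ = remove_related(ds, KinshipMatrix(ds.individual_ids, k))
    assert out.n_individuals == 3
    # all pairs at the threshold (not above) -> identity
    k2 = np.full((4, 4), 0.25)
    np.fill_diagonal(k2, 0.5)
    out2, _ = remove_related(ds, KinshipMatrix(ds.individual_ids, k2))
    assert out2.n_individuals == 4
    # triangle of 3 related individuals -> two removals (minimal vertex cover)
    k3 = base.copy()
    for a, b in [(0, 1), (0, 2), (1, 2)]:
        k3[a, b] = k3[b, a] = 0.4
    out3, _ = remove_related(ds, KinshipMatrix(ds.individual_ids, k3))
    assert out3.n_individuals == 2


def test_allsites_filter_inclusive_bounds():
    dosage = np.zeros((2, 4), dtype=np.int8)
    ds = make_dataset(
        dosage,
        ref_depth=np.array([[4, 5, 100, 101]] * 2),
        alt_depth=np.zeros((2, 4), dtype=int),
    )
    out, _ = allsites_filter(ds)
    assert out.sites["pos"].tolist() == [11, 21]  # 5 and 100 inclusive
    # call-rate bound
    dosage2 = np.array([[0] * 10, [MISSING] * 2 + [0] * 8]).astype(np.int8)
    ds2 = make_dataset(
        dosage2,
        ref_depth=np.full((2, 10), 50),
        alt_depth=np.zeros((2, 10), dtype=int),
    )
    out2, _ = allsites_filter(ds2)
    assert out2.n_sites == 8  # the two half-missing sites fail 0.9 call rate


@pytest.mark.parametrize(
    "apply",
    [
        lambda ds, pm: filter_max_het(ds)[0],
        lambda ds, pm: filter_mac(ds)[0],
        lambda ds, pm: prune_one_snp_per_locus(ds),
        lambda ds, pm: filter_site_presence(ds, pm)[0],
        lambda ds, pm: allsites_filter(ds)[0],
        lambda ds, pm: iterative_call_rate_filter(ds)[0],
    ],
    ids=["max_het", "mac", "prune", "presence", "allsites", "call_rate"],
)
def test_filters_are_idempotent(small_system, apply):
    ds, pm, _ = small_system
    once = apply(ds, pm)
    twice = apply(once, pm.restrict_to(once.individual_ids))
    assert twice.n_sites == once.n_sites
    assert twice.individual_ids == once.individual_ids
    np.testing.assert_array_equal(twice.dosage, once.dosage)


def test_cascade_report_reconciles(small_system):
    ds, pm, _ = small_system
    out, report = run_cascade(ds, pm)
    frame = report.to_frame()
    # chained counts match: each step starts where the previous ended
    for prev, nxt in zip(report.steps, report.steps[1:]):
        assert nxt["sites_before"] == prev["sites_after"]
        assert nxt["individuals_before"] == prev["individuals_after"]
    assert frame.iloc[-1]["sites_after"] == out.n_sites
    assert frame.iloc[-1]["individuals_after"] == out.n_individuals
    # monotone non-increasing along both axes
    assert (frame["sites_after"] <= frame["sites_before"]).all()
    assert (frame["individuals_after"] <= frame["individuals_before"]).all()
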