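"""Shared fixtures: tiny hand-built datasets and a small simulated system."""

import numpy as np
import pandas as pd
import pytest

from popdiv.io import (
    MISSING,
    POPMAP_COLUMNS,
    SITE_COLUMNS,
    GenotypeDataset,
    PopulationMap,
)


def make_sites(n_variant, n_invariant=0, chrom="chr1", locus_per_site=True,
               start=1, spacing=10):
    """Site table with ``n_variant`` SNPs then ``n_invariant`` invariant sites."""
    rows = []
    pos = start
    for i in range(n_variant):
        locus = f"L{i:04d}" if locus_per_site else "L0000"
        rows.append((chrom, pos, locus, "A", "T", "variant"))
        pos += spacing
    for i in range(n_invariant):
        rows.append((chrom, pos, f"I{i:04d}", "A", None, "invariant"))
        pos += spacing
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def make_dataset(dosage, n_invariant=0, individual_ids=None, sites=None,
                 ref_depth=None, alt_depth=None, replicate_pairs=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n_ind, n_var = dosage.shape
    if n_invariant:
        pad = np.zeros((n_ind, n_invariant), dtype=np.int8)
        dosage = np.concatenate([dosage, pad], axis=1)
    if individual_ids is None:
        individual_ids = [f"ind{i}" for i in range(n_ind)]
    if sites is None:
        sites = make_sites(n_var, n_invariant)
    return GenotypeDataset(
        individual_ids=individual_ids,
        sites=sites,
        dosage=dosage,
        ref_depth=None if ref_depth is None else np.asarray(ref_depth),
        alt_depth=None if alt_depth is None else np.asarray(alt_depth),
        replicate_pairs=replicate_pairs or [],
    )


def make_popmap(assignment, strata=None, coords=None, status=None, sources=None,
                replicate_groups=None):
    """assignment: dict individual -> population."""
    strata = strata or {}
    rows = []
    for i, (ind, pop) in enumerate(assignment.items()):
        lon, lat = (coords or {}).get(pop, (100.0 + i, -20.0))
        rows.append(
            (
                ind, pop, strata.get(pop, "S"),
                lon, lat,
                (status or {}).get(pop, "natural"),
                (sources or {}).get(pop),
                (replicate_groups or {}).get(ind),
            )
        )
    return PopulationMap(pd.DataFrame(rows, columns=POPMAP_COLUMNS))


@pytest.fixture(scope="session")
def small_system():
    """A small but realistic simulated metapopulation (shared across tests)."""
    from popdiv.simulate import simulate_dataset

    return simulate_dataset(seed=7, n_loci=400)


@pytest.fixture()
def two_pop_dataset():
    """Two populations of 3, complete data, 4 variant + 2 invariant sites."""
    dosage = np.array(
        [
            [0, 1, 2, 0],
            [1, 1, 0, 0],
            [2, 0, 1, 0],
            [0, 2, 2, 1],
            [0, 2, 1, 1],
            [1, 2, 0, 2],
        ]
    )
    ds = make_dataset(dosage, n_invariant=2)
    pm = make_popmap(
        {f"ind{i}": ("P1" if i < 3 else "P2") for i in range(6)},
        strata={"P1": "S1", "P2": "S2"},
        coords={"P1": (115.0, -21.0), "P2": (125.0, -15.0)},
    )
    return ds, pm
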