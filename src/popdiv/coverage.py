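"""Allele-coverage population prioritization (systematic conservation planning).

Each (locus, allele) pair observed in a population's subsample is a feature;
each population is a planning unit with unit cost.  For scenario sizes
k = 1..P the maximum-coverage problem asks which k populations jointly carry
the most alleles.  P is small in this domain, so the exact solver enumerates
subsets; a greedy solver (with the classical 1 - 1/e guarantee) is provided
for larger instances.  The resampling protocol rebuilds the feature matrix
from a fresh subsample of n individuals per population each iteration,
solves exactly for every k, and tallies how often each configuration wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io import GenotypeDataset, PopulationMap, allele_counts

EXACT_ENUMERATION_LIMIT = 25


@dataclass
class FeatureMatrix:
    """Populations x features boolean presence matrix."""

    populations: list[str]
    presence: np.ndarray  # (n_pops, n_features) bool
    feature_labels: list[str] | None = None

    def __post_init__(self) -> None:
        pres = np.asarray(self.presence, dtype=bool)
        if pres.ndim != 2 or pres.shape[0] != len(self.populations):
            raise ValueError("presence matrix shape mismatch")
        # only keep features observed somewhere
        self.presence = pres

    @property
    def n_features(self) -> int:
        return self.presence.shape[1]

    def total_features(self) -> int:
        return int(self.presence.any(axis=0).sum())


@dataclass
class CoverageSolution:
    k: int
    selected: tuple[str, ...]
    covered: int
    proportion: float
    solver: str
    iteration: int = 0


def build_feature_matrix(
    dataset: GenotypeDataset,
    popmap: PopulationMap,
    subsample_n: int = 6,
    seed: int = 0,
) -> FeatureMatrix:
    """Feature presence from a random subsample of ``subsample_n``
    individuals per population; populations with fewer individuals are
    excluded with a warning.  Features are both alleles of every variant site
    plus the (single) allele of invariant sites, so a fixed-everywhere allele
    counts toward the total."""
    rng = np.random.default_rng(seed)
    present_ids = set(dataset.individual_ids)
    chosen: list[str] = []
    kept_pops: list[str] = []
    excluded = []
    for p in popmap.populations:
        inds = [i for i in popmap.individuals_of(p) if i in present_ids]
        if len(inds) < subsample_n:
            excluded.append(p)
            continue
        pick = rng.choice(len(inds), size=subsample_n, replace=False)
        chosen.extend(inds[i] for i in pick)
        kept_pops.append(p)
    if excluded:
        warnings.warn(f"populations below n={subsample_n} excluded: {excluded}")
    if not kept_pops:
        raise ValueError("no population meets the subsample size")
    sub = dataset.subset_individuals(chosen)
    table = allele_counts(sub, popmap.restrict_to(chosen))
    order = [table.pop_index(p) for p in kept_pops]
    ref_present = table.ref_copies[order] > 0
    alt_present = table.alt_copies[order] > 0
    presence = np.concatenate([ref_present, alt_present], axis=1)
    labels = [f"{lid}:{al}" for al in ("ref", "alt") for lid in table.sites["locus_id"]]
    observed = presence.any(axis=0)
    return FeatureMatrix(
        populations=kept_pops,
        presence=presence[:, observed],
        feature_labels=[l for l, o in zip(labels, observed) if o],
    )


def solve_max_coverage(
    matrix: FeatureMatrix, k: int, method: str = "exact"
) -> CoverageSolution:
    """Choose ``k`` populations maximizing the union of covered features.

    ``exact`` enumerates all C(P, k) subsets (P <= 25 enforced); ``greedy``
    adds the largest-marginal-gain population at each step.  Ties break to
    the lexicographically smallest population-id tuple, so results are
    deterministic."""
    pops = matrix.populations
    n_pops = len(pops)
    if not 1 <= k <= n_pops:
        raise ValueError(f"k must be in [1, {n_pops}]")
    if matrix.n_features == 0:
        raise ValueError("empty feature matrix")
    total = matrix.total_features()
    order = np.argsort(pops)  # lexicographic candidate order for tie-breaks
    pres = matrix.presence
    if method == "exact":
        if n_pops > EXACT_ENUMERATION_LIMIT:
            raise ValueError(
                f"exact enumeration limited to {EXACT_ENUMERATION_LIMIT} populations"
            )
        best_cov, best_set = -1, None
        for combo in combinations(order, k):
            cov = int(pres[list(combo)].any(axis=0).sum())
            names = tuple(sorted(pops[i] for i in combo))
            if cov > best_cov or (cov == best_cov and names < best_set):
                best_cov, best_set = cov, names
        return CoverageSolution(
            k=k, selected=best_set, covered=best_cov,
            proportion=best_cov / total, solver="exact",
        )
    if method == "greedy":
        covered = np.zeros(matrix.n_features, dtype=bool)
        chosen: list[str] = []
        remaining = list(order)
        for _ in range(k):
            gains = [(int((pres[i] & ~covered).sum()), pops[i], i) for i in remaining]
            gains.sort(key=lambda t: (-t[0], t[1]))
            _, name, idx = gains[0]
            chosen.append(name)
            covered |= pres[idx]
            remaining.remove(idx)
        cov = int(covered.sum())
        return CoverageSolution(
            k=k, selected=tuple(sorted(chosen)), covered=cov,
            proportion=cov / total, solver="greedy",
        )
    raise ValueError(f"unknown method: {method}")


def prioritization_protocol(
    dataset: GenotypeDataset,
    popmap: PopulationMap,
    k_range=None,
    iterations: int = 100,
    subsample_n: int = 6,
    seed: int = 0,
    method: str = "exact",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Resampled prioritization: per iteration, rebuild the feature matrix
    from a fresh subsample and solve for every scenario size k.

    Returns ``(summary, tallies)``: per-k mean/min/max proportion of total
    alleles covered, and per-k counts of each winning configuration.
    """
    rng = np.random.default_rng(seed)
    solutions: list[CoverageSolution] = []
    for it in range(iterations):
        matrix = build_feature_matrix(
            dataset, popmap, subsample_n=subsample_n, seed=int(rng.integers(2**31))
        )
        ks = k_range if k_range is not None else range(1, len(matrix.populations) + 1)
        for k in ks:
            sol = solve_max_coverage(matrix, k, method=method)
            sol.iteration = it
            solutions.append(sol)
    frame = pd.DataFrame(
        {
            "iteration": [s.iteration for s in solutions],
            "k": [s.k for s in solutions],
            "configuration": ["+".join(s.selected) for s in solutions],
            "covered": [s.covered for s in solutions],
            "proportion": [s.proportion for s in solutions],
        }
    )
    summary = (
        frame.groupby("k")["proportion"]
        .agg(mean="mean", min="min", max="max")
        .reset_index()
    )
    tallies = (
        frame.groupby(["k", "configuration"])
        .size()
        .rename("count")
        .reset_index()
        .sort_values(["k", "count"], ascending=[True, False])
        .reset_index(drop=True)
    )
    return summary, tallies
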