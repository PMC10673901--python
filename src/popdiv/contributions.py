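"""Metapopulation partitions of gene and allelic diversity and population
contributions.

Gene diversity splits as ``H_T = H_S + D_G``: the weighted mean
within-population gene diversity plus the weighted mean Nei minimum distance
over all ordered population pairs (self-distance 0).  Under any weight
vector w on the simplex, H_T equals the gene diversity of the w-pooled allele
frequencies.  Allelic diversity splits analogously as ``A_T = A_S + D_A``,
where A_S is the mean number of alleles per locus within a population and
D_A averages the one-way allele-absence counts over ordered pairs; A_T then
equals the average pairwise-union allele count.

A population's contribution to a component X is the relative change
``100 (X_all - X_without) / X_all`` when it is removed and weights are
renormalized (positive = diversity is lost when the population is removed).

``optimal_pool_contributions`` finds the weight vector on the simplex
maximizing either pooled expected heterozygosity (H) or the expected number
of distinct alleles in a finite synthetic pool (k).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .io import AlleleTable, GenotypeDataset, PopulationMap, allele_counts

COMPONENTS = ["A_S", "D_A", "A_T", "H_S", "D_G", "H_T"]


@dataclass
class DiversityPartition:
    populations: list[str]
    weights: np.ndarray
    H_S: float
    D_G: float
    H_T: float
    A_S: float
    D_A: float
    A_T: float

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in COMPONENTS}


def _freq_arrays(table: AlleleTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(alt frequency, alt presence, ref presence) per (population, variant site);
    loci untyped in some population are masked out of every population so all
    per-locus means run over a common locus set."""
    variant = table.variant_mask
    typed = table.n_typed[:, variant]
    common = (typed > 0).all(axis=0)
    if not common.any():
        raise ValueError("no variant loci typed in every population")
    alt = table.alt_copies[:, variant][:, common].astype(float)
    copies = 2.0 * typed[:, common]
    p = alt / copies
    alt_present = alt > 0
    ref_present = (copies - alt) > 0
    return p, alt_present, ref_present


def _weights(n_pops: int, sizes: np.ndarray, mode) -> np.ndarray:
    if isinstance(mode, (list, np.ndarray)):
        w = np.asarray(mode, dtype=float)
    elif mode == "equal":
        w = np.full(n_pops, 1.0 / n_pops)
    elif mode == "size":
        w = sizes / sizes.sum()
    else:
        raise ValueError(f"unknown weights: {mode}")
    if len(w) != n_pops or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be a simplex vector over populations")
    return w


def diversity_partition(table: AlleleTable, weights="equal") -> DiversityPartition:
    """Both partitions (gene H side and allelic A side) in one pass."""
    p, alt_present, ref_present = _freq_arrays(table)
    n_pops = len(table.populations)
    sizes = table.n_typed.max(axis=1).astype(float)
    w = _weights(n_pops, sizes, weights)

    # gene diversity side
    h_i = (2 * p * (1 - p)).mean(axis=1)  # per-pop expected heterozygosity
    H_S = float(w @ h_i)
    # Nei minimum distance per ordered pair, per-locus mean
    # d_ij = (sum p_i^2 + sum p_j^2)/2 - sum p_i p_j  (biallelic: over both alleles)
    sq = p**2 + (1 - p) ** 2  # (pop, locus) sum of squared freqs
    n_loci = p.shape[1]
    cross = (p @ p.T + (1 - p) @ (1 - p).T) / n_loci  # mean_l sum_a p_ia p_ja
    sqm = sq.mean(axis=1)
    d = (sqm[:, None] + sqm[None, :]) / 2.0 - cross
    np.fill_diagonal(d, 0.0)
    D_G = float(w @ d @ w)

    # allelic side
    n_alleles = alt_present.astype(float) + ref_present.astype(float)
    a_i = n_alleles.mean(axis=1)
    A_S = float(w @ a_i)
    # m_ij = mean count of alleles present in i and absent in j
    m = np.zeros((n_pops, n_pops))
    for pres in (alt_present, ref_present):
        pres_f = pres.astype(float)
        # alleles present in i: pres_f[i]; absent in j: 1 - pres_f[j]
        m += pres_f @ (1.0 - pres_f.T) / n_loci
    np.fill_diagonal(m, 0.0)
    D_A = float(w @ m @ w)

    return DiversityPartition(
        populations=list(table.populations),
        weights=w,
        H_S=H_S,
        D_G=D_G,
        H_T=H_S + D_G,
        A_S=A_S,
        D_A=D_A,
        A_T=A_S + D_A,
    )


def gene_diversity_partition(table: AlleleTable, weights="equal") -> DiversityPartition:
    return diversity_partition(table, weights)


def allelic_diversity_partition(table: AlleleTable, weights="equal") -> DiversityPartition:
    return diversity_partition(table, weights)


def pooled_gene_diversity(table: AlleleTable, weights="equal") -> float:
    """Gene diversity of the w-pooled allele frequencies (equals H_T)."""
    p, _, _ = _freq_arrays(table)
    sizes = table.n_typed.max(axis=1).astype(float)
    w = _weights(len(table.populations), sizes, weights)
    pbar = w @ p
    return float((1.0 - pbar**2 - (1.0 - pbar) ** 2).mean())


def leave_one_out_contributions(table: AlleleTable, weights="equal") -> pd.DataFrame:
    """Percent change of every partition component when one population is
    removed (positive = that component shrinks without the population)."""
    pops = list(table.populations)
    if len(pops) < 3:
        raise ValueError("leave-one-out needs at least 3 populations")
    full = diversity_partition(table, weights).as_dict()
    rows = []
    for k, pop in enumerate(pops):
        rest = [p for p in pops if p != pop]
        sub = table.subset_populations(rest)
        if isinstance(weights, (list, np.ndarray)):
            w = np.delete(np.asarray(weights, dtype=float), k)
            w = w / w.sum()
        else:
            w = weights
        part = diversity_partition(sub, w).as_dict()
        row = {"population_id": pop}
        for c in COMPONENTS:
            row[c] = (
                100.0 * (full[c] - part[c]) / full[c] if full[c] != 0 else np.nan
            )
            row[f"delta_{c}"] = full[c] - part[c]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Optimal contributions to a synthetic pool
# ---------------------------------------------------------------------------

def _pool_objective(p: np.ndarray, objective: str, pool_individuals: int):
    """Return f(w) (to maximize) and its gradient for the pooled frequencies."""
    n_loci = p.shape[1]
    copies = 2 * pool_individuals

    if objective == "H":

        def f(w):
            pbar = w @ p
            return float((2 * pbar * (1 - pbar)).mean())

        def grad(w):
            pbar = w @ p
            return (p * (2 - 4 * pbar)).mean(axis=1)

    elif objective == "k":
        # expected distinct alleles among `copies` pool gene copies:
        # sum_a [1 - (1 - pbar_a)^copies], per-locus mean over both alleles
        def f(w):
            pbar = w @ p
            kept = (1 - (1 - pbar) ** copies) + (1 - pbar**copies)
            return float(kept.mean())

        def grad(w):
            pbar = w @ p
            term = copies * ((1 - pbar) ** (copies - 1) - pbar ** (copies - 1))
            return (p * term).mean(axis=1)

    else:
        raise ValueError(f"unknown objective: {objective}")
    return f, grad


def optimal_pool_contributions(
    table: AlleleTable,
    objective: str = "H",
    pool_individuals: int = 1000,
    n_starts: int = 8,
    seed: int = 0,
    tol: float = 1e-10,
) -> pd.DataFrame:
    """Optimal per-population weight in a synthetic pool of
    ``pool_individuals`` individuals, maximizing pooled heterozygosity (H)
    or the expected number of distinct alleles (k).

    Solved with SLSQP on the simplex from multiple seeded starts (the H
    objective is concave, so multi-start is belt-and-braces; the k objective
    is also concave in w for copies >= 1).
    """
    p, _, _ = _freq_arrays(table)
    n_pops = p.shape[0]
    if n_pops == 0:
        raise ValueError("no populations")
    f, grad = _pool_objective(p, objective, pool_individuals)
    rng = np.random.default_rng(seed)
    starts = [np.full(n_pops, 1.0 / n_pops)]
    starts += [rng.dirichlet(np.ones(n_pops)) for _ in range(n_starts - 1)]
    best_w, best_v = None, -np.inf
    constraints = [{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                    "jac": lambda w: np.ones_like(w)}]
    bounds = [(0.0, 1.0)] * n_pops
    for w0 in starts:
        res = minimize(
            lambda w: -f(w),
            w0,
            jac=lambda w: -grad(w),
            method="SLSQP",
            bounds=bounds,
            constraints=constraints,
            options={"maxiter": 500, "ftol": tol},
        )
        if res.success and -res.fun > best_v:
            best_v, best_w = -res.fun, res.x
    if best_w is None:
        raise RuntimeError("optimal-pool optimization failed from every start")
    w = np.clip(best_w, 0.0, None)
    w = w / w.sum()
    return pd.DataFrame(
        {
            "population_id": table.populations,
            "weight": w,
            "percent": 100.0 * w,
            "objective": objective,
            "objective_value": f(w),
        }
    )


# ---------------------------------------------------------------------------
# Subsample-and-average protocol
# ---------------------------------------------------------------------------

def subsample_average(
    analysis,
    dataset: GenotypeDataset,
    popmap: PopulationMap,
    n: int = 6,
    reps: int = 50,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run ``analysis(AlleleTable) -> DataFrame`` on ``reps`` random
    subsamples of ``n`` individuals per population and return (mean, sd).

    Populations with fewer than ``n`` individuals are excluded (with a
    warning via the returned frame's attrs).  The analysis frame must carry a
    ``population_id`` column; numeric columns are averaged elementwise.
    """
    import warnings

    rng = np.random.default_rng(seed)
    eligible, excluded = [], []
    for p in popmap.populations:
        inds = [i for i in popmap.individuals_of(p) if i in set(dataset.individual_ids)]
        (eligible if len(inds) >= n else excluded).append(p)
    if excluded:
        warnings.warn(f"populations below n={n} excluded: {excluded}")
    results = []
    for _ in range(reps):
        chosen: list[str] = []
        for p in eligible:
            inds = [
                i for i in popmap.individuals_of(p) if i in set(dataset.individual_ids)
            ]
            pick = rng.choice(len(inds), size=n, replace=False)
            chosen.extend(inds[i] for i in pick)
        sub = dataset.subset_individuals(chosen)
        sub_map = popmap.restrict_to(chosen)
        frame = analysis(allele_counts(sub, sub_map))
        results.append(frame.set_index("population_id"))
    stacked = pd.concat(results, keys=range(reps))
    numeric = stacked.select_dtypes(include=[np.number])
    mean = numeric.groupby(level=1, sort=False).mean().reset_index()
    sd = numeric.groupby(level=1, sort=False).std(ddof=1).reset_index()
    mean.attrs["excluded"] = excluded
    mean.attrs["reps"] = reps
    mean.attrs["n"] = n
    return mean, sd
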