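"""Hierarchical partitioning of genetic diversity via Rao's quadratic entropy.

Each individual is a point in dosage space; the squared genetic distance
between two individuals is the per-locus mean of half the squared dosage
difference (the AMOVA convention for codominant data, which makes the
distances squared-Euclidean and therefore guarantees non-negative
among-group components under size weighting).  The quadratic entropy Q of a
set is the mean squared distance between two members drawn uniformly with
replacement.

Q partitions down a population hierarchy into a "diversity cascade":
total gamma, among-strata delta, within-stratum sigma, among-population beta
(within each stratum) and within-population alpha, with exact additivity
``gamma = delta + sum_r w_r sigma_r`` and
``sigma_r = beta_r + sum_p w_(p|r) alpha_p``.

Homogeneity of components across groups is screened with Bartlett's test,
treating each component as a variance estimate with its group degrees of
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeDataset, PopulationMap


@dataclass
class DiversityCascade:
    gamma: float
    delta: float
    sigma: dict[str, float]
    beta: dict[str, float]
    alpha: dict[str, float]  # population -> Q
    weight_mode: str
    df_sigma: dict[str, int]
    df_alpha: dict[str, int]
    bartlett_p_sigma: float
    bartlett_p_beta: float
    bartlett_p_alpha: dict[str, float]
    notes: list[str] = field(default_factory=list)

    def to_frame(self, popmap: PopulationMap) -> pd.DataFrame:
        """Long-format cascade table: parameter / stratum / population / value / p."""
        rows = [
            {"parameter": "gamma", "stratum": "", "population": "", "value": self.gamma,
             "p_bartlett": np.nan},
            {"parameter": "delta", "stratum": "", "population": "", "value": self.delta,
             "p_bartlett": np.nan},
        ]
        for i, (s, v) in enumerate(self.sigma.items()):
            rows.append({"parameter": "sigma", "stratum": s, "population": "",
                         "value": v,
                         "p_bartlett": self.bartlett_p_sigma if i == 0 else np.nan})
        for i, (s, v) in enumerate(self.beta.items()):
            rows.append({"parameter": "beta", "stratum": s, "population": "",
                         "value": v,
                         "p_bartlett": self.bartlett_p_beta if i == 0 else np.nan})
        for pop, v in self.alpha.items():
            stratum = popmap.stratum_of(pop)
            rows.append({"parameter": "alpha", "stratum": stratum, "population": pop,
                         "value": v,
                         "p_bartlett": self.bartlett_p_alpha.get(stratum, np.nan)})
        return pd.DataFrame(rows)


def complete_snp_subset(dataset: GenotypeDataset) -> GenotypeDataset:
    """The 100%-SNP-call-rate dataset the cascade requires.

    Iteratively filters samples (to >= 90% call rate) and SNPs up to a final
    SNP call rate of 100%, then keeps variant sites only.
    """
    from .filtering import iterative_call_rate_filter

    out, _ = iterative_call_rate_filter(
        dataset, sample_targets=(0.90, 0.90), snp_targets=(0.95, 1.0)
    )
    return out.take_sites(out.variant_mask)


def genotype_distance_matrix(dataset: GenotypeDataset) -> np.ndarray:
    """Squared genetic distance between individuals:
    ``d2_ij = (1/L) sum_l (x_il - x_jl)^2 / 2`` over variant loci.

    Requires complete data (run the 100%-call-rate filter first); any missing
    call raises with the offending individuals named.
    """
    variant = dataset.variant_mask
    dos = dataset.dosage[:, variant].astype(float)
    if dos.shape[1] == 0:
        raise ValueError("no variant sites")
    missing_rows = np.flatnonzero((dos == MISSING).any(axis=1))
    if missing_rows.size:
        names = [dataset.individual_ids[i] for i in missing_rows[:10]]
        raise ValueError(
            f"missing genotype calls are not allowed; offending individuals: {names}"
        )
    sq = (dos**2).sum(axis=1)
    cross = dos @ dos.T
    d2 = (sq[:, None] + sq[None, :] - 2 * cross) / (2.0 * dos.shape[1])
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


def quadratic_entropy(d2: np.ndarray, members: np.ndarray | None = None) -> float:
    """Rao's Q: mean of d2 over all ordered member pairs (self-pairs are 0)."""
    if members is not None:
        members = np.asarray(members)
        d2 = d2[np.ix_(members, members)]
    n = d2.shape[0]
    if n == 0:
        raise ValueError("empty member set")
    return float(d2.sum() / (n * n))


def bartlett_homogeneity(components: np.ndarray, dfs: np.ndarray) -> float:
    """Bartlett's homogeneity-of-variances p-value for variance-like
    components with known degrees of freedom."""
    s2 = np.asarray(components, dtype=float)
    df = np.asarray(dfs, dtype=float)
    if np.any(s2 <= 0):
        raise ValueError("Bartlett's test requires strictly positive components")
    if np.any(df < 1):
        raise ValueError("Bartlett's test requires df >= 1")
    k = len(s2)
    if k < 2:
        raise ValueError("need at least two components")
    df_tot = df.sum()
    sp2 = (df * s2).sum() / df_tot
    stat = df_tot * np.log(sp2) - (df * np.log(s2)).sum()
    correction = 1.0 + ((1.0 / df).sum() - 1.0 / df_tot) / (3.0 * (k - 1))
    return float(stats.chi2.sf(stat / correction, k - 1))


def _weights(sizes: np.ndarray, mode: str) -> np.ndarray:
    sizes = np.asarray(sizes, dtype=float)
    if mode == "size":
        return sizes / sizes.sum()
    if mode == "equal":
        return np.full(len(sizes), 1.0 / len(sizes))
    raise ValueError(f"unknown weight_mode: {mode}")


def diversity_cascade(
    dataset: GenotypeDataset,
    popmap: PopulationMap,
    weight_mode: str = "size",
) -> DiversityCascade:
    """Full gamma/delta/sigma/beta/alpha decomposition of Rao's Q.

    ``weight_mode='size'`` weights groups by member counts (the ANOVA
    decomposition: all components are then non-negative); ``'equal'`` weights
    groups uniformly (components remain exactly additive by construction but
    among-group terms may go negative when group sizes are very unequal).
    """
    d2 = genotype_distance_matrix(dataset)
    pop_of = popmap.population_of()
    idx_of_pop: dict[str, list[int]] = {}
    for i, ind in enumerate(dataset.individual_ids):
        if ind not in pop_of:
            raise ValueError(f"individual {ind} missing from population map")
        idx_of_pop.setdefault(pop_of[ind], []).append(i)
    pops = [p for p in popmap.populations if p in idx_of_pop]
    strata = list(dict.fromkeys(popmap.stratum_of(p) for p in pops))
    pops_of_stratum = {
        s: [p for p in pops if popmap.stratum_of(p) == s] for s in strata
    }
    notes: list[str] = []

    alpha = {p: quadratic_entropy(d2, np.array(idx_of_pop[p])) for p in pops}
    sigma: dict[str, float] = {}
    beta: dict[str, float] = {}
    df_sigma: dict[str, int] = {}
    df_alpha: dict[str, int] = {}
    for s in strata:
        members = np.concatenate([idx_of_pop[p] for p in pops_of_stratum[s]])
        sigma[s] = quadratic_entropy(d2, members)
        df_sigma[s] = len(members) - 1
        sizes = np.array([len(idx_of_pop[p]) for p in pops_of_stratum[s]])
        w = _weights(sizes, weight_mode)
        beta[s] = sigma[s] - float(
            sum(w_i * alpha[p] for w_i, p in zip(w, pops_of_stratum[s]))
        )
        if len(pops_of_stratum[s]) == 1:
            beta[s] = 0.0
            notes.append(f"stratum {s} has a single population; beta set to 0")
    for p in pops:
        df_alpha[p] = len(idx_of_pop[p]) - 1
        if df_alpha[p] == 0:
            notes.append(f"population {p} has a single individual; alpha = 0")

    gamma = quadratic_entropy(d2)
    stratum_sizes = np.array(
        [sum(len(idx_of_pop[p]) for p in pops_of_stratum[s]) for s in strata]
    )
    w_r = _weights(stratum_sizes, weight_mode)
    delta = gamma - float(sum(w * sigma[s] for w, s in zip(w_r, strata)))

    def safe_bartlett(values, dfs):
        values = np.asarray(values, dtype=float)
        dfs = np.asarray(dfs, dtype=float)
        ok = (values > 0) & (dfs >= 1)
        if ok.sum() < 2:
            return float("nan")
        return bartlett_homogeneity(values[ok], dfs[ok])

    bart_sigma = safe_bartlett(
        [sigma[s] for s in strata], [df_sigma[s] for s in strata]
    )
    bart_beta = safe_bartlett(
        [beta[s] for s in strata],
        [len(pops_of_stratum[s]) - 1 for s in strata],
    )
    bart_alpha = {
        s: safe_bartlett(
            [alpha[p] for p in pops_of_stratum[s]],
            [df_alpha[p] for p in pops_of_stratum[s]],
        )
        for s in strata
    }
    return DiversityCascade(
        gamma=gamma,
        delta=delta,
        sigma=sigma,
        beta=beta,
        alpha=alpha,
        weight_mode=weight_mode,
        df_sigma=df_sigma,
        df_alpha=df_alpha,
        bartlett_p_sigma=bart_sigma,
        bartlett_p_beta=bart_beta,
        bartlett_p_alpha=bart_alpha,
        notes=notes,
    )
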