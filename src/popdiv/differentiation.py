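"""Windowed and genome-wide population differentiation with invariant sites.

All windowed statistics use ratio-of-sums aggregation (pairwise-difference
counts and comparison counts are summed across sites before division), the
convention used by all-sites summary-statistic tools: it is unbiased under
missing data and makes window concatenation exact.  Windows are half-open
``[start, start + size)`` intervals in 1-based coordinates.

Two F_ST estimators are provided: Weir & Cockerham's (1984) variance
components (the default; window estimate sum(a)/sum(a+b+c)) and the Hudson
estimator in the ratio-of-sums form of Bhatia et al.

Isolation by distance is tested with a Mantel permutation test on linearized
F_ST/(1 - F_ST) against great-circle distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AlleleTable, GenotypeDataset, PopulationMap, allele_counts

EARTH_RADIUS_KM = 6371.0


@dataclass
class PairwiseMatrix:
    """Symmetric population x population matrix of a differentiation metric."""

    populations: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, equal_nan=True):
            raise ValueError("diagonal must be zero")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.populations, columns=self.populations
        )


# ---------------------------------------------------------------------------
# Per-site numerator/denominator pairs
# ---------------------------------------------------------------------------

def _pi_counts(table: AlleleTable, pop: str) -> tuple[np.ndarray, np.ndarray]:
    k = table.pop_index(pop)
    copies = table.total_copies[k].astype(float)
    alt = table.alt_copies[k].astype(float)
    diffs = (copies - alt) * alt
    comps = copies * (copies - 1.0) / 2.0
    return diffs, comps


def _dxy_counts(table: AlleleTable, a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    ka, kb = table.pop_index(a), table.pop_index(b)
    ca, cb = table.total_copies[ka].astype(float), table.total_copies[kb].astype(float)
    aa, ab = table.alt_copies[ka].astype(float), table.alt_copies[kb].astype(float)
    diffs = aa * (cb - ab) + (ca - aa) * ab
    comps = ca * cb
    return diffs, comps


def _hudson_counts(table: AlleleTable, a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (numerator, denominator) of the Hudson estimator:
    num = Hb - Hw, den = Hb, with unbiased within-population heterozygosity."""
    ka, kb = table.pop_index(a), table.pop_index(b)
    hw = np.zeros(len(table.sites))
    ok = np.ones(len(table.sites), dtype=bool)
    for k in (ka, kb):
        copies = table.total_copies[k].astype(float)
        alt = table.alt_copies[k].astype(float)
        ok &= copies >= 2
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(copies > 0, alt / copies, 0.0)
            h = np.where(
                copies > 1, copies / (copies - 1.0) * 2.0 * p * (1.0 - p), 0.0
            )
        hw += 0.5 * h
    pa = _freq(table, ka)
    pb = _freq(table, kb)
    hb = pa * (1 - pb) + pb * (1 - pa)
    num = np.where(ok, hb - hw, 0.0)
    den = np.where(ok, hb, 0.0)
    return num, den


def _freq(table: AlleleTable, k: int) -> np.ndarray:
    copies = table.total_copies[k].astype(float)
    alt = table.alt_copies[k].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(copies > 0, alt / copies, np.nan)


def _wc84_counts(table: AlleleTable, a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Weir-Cockerham variance components for two populations:
    returns (a, a+b+c) arrays; sites without >= 2 typed individuals in both
    populations contribute zero to both sums."""
    ka, kb = table.pop_index(a), table.pop_index(b)
    r = 2.0
    n1 = table.n_typed[ka].astype(float)
    n2 = table.n_typed[kb].astype(float)
    ok = (n1 >= 2) & (n2 >= 2)
    n1 = np.where(ok, n1, 2.0)
    n2 = np.where(ok, n2, 2.0)
    p1 = np.where(n1 > 0, table.alt_copies[ka] / (2 * n1), 0.0)
    p2 = np.where(n2 > 0, table.alt_copies[kb] / (2 * n2), 0.0)
    h1 = np.where(n1 > 0, table.n_het[ka] / n1, 0.0)
    h2 = np.where(n2 > 0, table.n_het[kb] / n2, 0.0)
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a_comp = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b_comp = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - ((r - 1) / r) * s2
            - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
    c_comp = hbar / 2.0
    a_comp = np.where(ok, a_comp, 0.0)
    total = np.where(ok, a_comp + b_comp + c_comp, 0.0)
    return a_comp, total


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

def _window_frame(
    table: AlleleTable,
    num: np.ndarray,
    den: np.ndarray,
    used: np.ndarray,
    window_bp: int,
    label: dict,
) -> pd.DataFrame:
    sites = table.sites
    win = ((sites["pos"].to_numpy() - 1) // window_bp) * window_bp + 1
    df = pd.DataFrame(
        {
            "chromosome": sites["chrom"].to_numpy(),
            "window_pos_1": win,
            "num": num,
            "den": den,
            "used": used.astype(int),
        }
    )
    grouped = df.groupby(["chromosome", "window_pos_1"], sort=True).sum().reset_index()
    grouped["window_pos_2"] = grouped["window_pos_1"] + window_bp - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        grouped["value"] = np.where(
            grouped["den"] > 0, grouped["num"] / grouped["den"], np.nan
        )
    grouped["n_sites"] = grouped["used"]
    for k, v in label.items():
        grouped[k] = v
    cols = list(label) + [
        "chromosome", "window_pos_1", "window_pos_2", "n_sites", "num", "den", "value",
    ]
    return grouped[cols]


def windowed_pi(
    dataset: GenotypeDataset,
    popmap: PopulationMap,
    population: str,
    window_bp: int = 10_000,
) -> pd.DataFrame:
    """Within-population nucleotide diversity per window (ratio-of-sums)."""
    table = allele_counts(dataset, popmap)
    num, den = _pi_counts(table, population)
    used = den > 0
    return _window_frame(
        table, num, den, used, window_bp, {"pop": population, "stat": "pi"}
    )


def windowed_dxy(
    dataset: GenotypeDataset,
    popmap: PopulationMap,
    pop_a: str,
    pop_b: str,
    window_bp: int = 10_000,
) -> pd.DataFrame:
    """Between-population divergence D_XY per window (ratio-of-sums)."""
    table = allele_counts(dataset, popmap)
    num, den = _dxy_counts(table, pop_a, pop_b)
    used = den > 0
    return _window_frame(
        table, num, den, used, window_bp,
        {"pop1": pop_a, "pop2": pop_b, "stat": "dxy"},
    )


def windowed_fst(
    dataset: GenotypeDataset,
    popmap: PopulationMap,
    pop_a: str,
    pop_b: str,
    window_bp: int = 10_000,
    estimator: str = "wc84",
) -> pd.DataFrame:
    """Pairwise F_ST per window; windows with no informative site get NaN."""
    table = allele_counts(dataset, popmap)
    if estimator == "wc84":
        num, den = _wc84_counts(table, pop_a, pop_b)
    elif estimator == "hudson":
        num, den = _hudson_counts(table, pop_a, pop_b)
    else:
        raise ValueError(f"unknown estimator: {estimator}")
    variant = table.variant_mask
    num = np.where(variant, num, 0.0)
    den = np.where(variant, den, 0.0)
    used = variant & (den != 0)
    return _window_frame(
        table, num, den, used, window_bp,
        {"pop1": pop_a, "pop2": pop_b, "stat": f"fst_{estimator}"},
    )


def genomewide_statistic(
    dataset: GenotypeDataset,
    popmap: PopulationMap,
    metric: str,
    pop_a: str,
    pop_b: str | None = None,
    estimator: str = "wc84",
) -> float:
    """Genome-wide ratio-of-sums value of pi, dxy or fst."""
    table = allele_counts(dataset, popmap)
    if metric == "pi":
        num, den = _pi_counts(table, pop_a)
    elif metric == "dxy":
        num, den = _dxy_counts(table, pop_a, pop_b)
    elif metric == "fst":
        if estimator == "wc84":
            num, den = _wc84_counts(table, pop_a, pop_b)
        else:
            num, den = _hudson_counts(table, pop_a, pop_b)
        variant = table.variant_mask
        num, den = np.where(variant, num, 0.0), np.where(variant, den, 0.0)
    else:
        raise ValueError(f"unknown metric: {metric}")
    total = den.sum()
    return float(num.sum() / total) if total != 0 else float("nan")


def pairwise_matrix(
    dataset: GenotypeDataset,
    popmap: PopulationMap,
    metric: str = "fst",
    min_n: int = 6,
    estimator: str = "wc84",
) -> PairwiseMatrix:
    """Genome-wide pairwise matrix over populations with >= ``min_n`` samples."""
    present = [
        p for p in popmap.populations
        if sum(i in set(dataset.individual_ids) for i in popmap.individuals_of(p)) >= min_n
    ]
    n = len(present)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = genomewide_statistic(
                dataset, popmap, metric, present[i], present[j], estimator=estimator
            )
            values[i, j] = values[j, i] = v
    label = metric if metric != "fst" else f"fst_{estimator}"
    return PairwiseMatrix(populations=present, values=values, metric=label)


# ---------------------------------------------------------------------------
# Isolation by distance
# ---------------------------------------------------------------------------

def great_circle_km(coords: pd.DataFrame) -> np.ndarray:
    """Haversine distance matrix (km) from per-population (lon, lat) degrees."""
    lon = np.radians(coords["lon"].to_numpy())
    lat = np.radians(coords["lat"].to_numpy())
    dlon = lon[:, None] - lon[None, :]
    dlat = lat[:, None] - lat[None, :]
    h = (
        np.sin(dlat / 2) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def mantel_test(
    x: np.ndarray, y: np.ndarray, permutations: int = 999, seed: int = 0
) -> tuple[float, float]:
    """One-sided Mantel permutation test of matrix association.

    r is the Pearson correlation of the off-diagonal upper-triangle entries;
    the permutation distribution shuffles rows and columns of ``y``
    simultaneously; p = (# permuted r >= observed + 1) / (permutations + 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.shape[0] != x.shape[1]:
        raise ValueError("mantel test needs two square matrices of equal shape")
    n = x.shape[0]
    iu = np.triu_indices(n, k=1)
    xv = x[iu]

    def corr(mat):
        yv = mat[iu]
        return np.corrcoef(xv, yv)[0, 1]

    r_obs = corr(y)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        if corr(y[np.ix_(perm, perm)]) >= r_obs:
            hits += 1
    p = (hits + 1) / (permutations + 1)
    return float(r_obs), float(p)


def mantel_ibd(
    fst: PairwiseMatrix,
    coords: pd.DataFrame,
    permutations: int = 999,
    seed: int = 0,
    log_distance: bool = True,
) -> dict:
    """Isolation-by-distance Mantel test on linearized F_ST.

    F_ST is linearized as F_ST/(1 - F_ST) (Rousset); distance is great-circle
    km, natural-log transformed by default (the two-dimensional expectation).
    An F_ST of exactly 1 cannot be linearized and must be excluded upstream.
    """
    vals = fst.values
    if np.any(vals >= 1.0):
        raise ValueError(
            "F_ST = 1 entries cannot be linearized; exclude those pairs first"
        )
    lin = vals / (1.0 - vals)
    coords = coords.loc[fst.populations]
    dist = great_circle_km(coords)
    if log_distance:
        off = ~np.eye(len(dist), dtype=bool)
        if np.any(dist[off] <= 0):
            raise ValueError("coincident populations: log-distance undefined")
        dmat = np.zeros_like(dist)
        dmat[off] = np.log(dist[off])
    else:
        dmat = dist
    r, p = mantel_test(dmat, lin, permutations=permutations, seed=seed)
    return {
        "r": r,
        "p": p,
        "permutations": permutations,
        "log_distance": log_distance,
        "n_populations": len(fst.populations),
    }
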