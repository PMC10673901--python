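"""Per-population diversity statistics.

Observed/expected heterozygosity and nucleotide diversity are computed from
the allele-count table with either a variant-only or an all-sites denominator
(the latter includes invariant sites, as produced by an all-sites caller, and
is the scale on which per-site diversity of reduced-representation data is
comparable across populations).  Allelic richness uses Hurlbert rarefaction
to a common number of gene copies; private alleles are counted raw and
standardized by Monte-Carlo subsampling to a common number of individuals.

``per_population_recall`` emulates the recommended protocol of re-calling
variants independently within each population: keep individuals with <10%
missing data, demand complete genotyping across them, and re-class sites that
are monomorphic within the population as invariant for denominator purposes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import AlleleTable, GenotypeDataset, PopulationMap, allele_counts


@dataclass
class PopulationDiversity:
    population_id: str
    n: int
    ho_variant: float
    ho_all_sites: float
    he_variant: float
    he_all_sites: float
    pi_variant: float
    pi_all_sites: float
    allelic_richness: float
    private_alleles: int
    private_alleles_std: float
    variant_sites: int
    total_sites: int


def _site_set(table: AlleleTable, denominator: str) -> np.ndarray:
    if denominator == "variant":
        return table.variant_mask
    if denominator == "all_sites":
        return np.ones(len(table.sites), dtype=bool)
    raise ValueError(f"unknown denominator: {denominator}")


def observed_heterozygosity(
    table: AlleleTable, population_id: str, denominator: str = "variant"
) -> float:
    """Sum of heterozygotes over sum of typed individuals across the site set."""
    k = table.pop_index(population_id)
    sel = _site_set(table, denominator)
    typed = table.n_typed[k, sel]
    het = table.n_het[k, sel]
    total = typed.sum()
    return float(het.sum() / total) if total > 0 else 0.0


def _per_site_unbiased_het(table: AlleleTable, k: int) -> np.ndarray:
    """Unbiased gene diversity h = k/(k-1) (1 - sum p^2) per site; 0 where
    fewer than 2 gene copies."""
    copies = table.total_copies[k].astype(float)
    alt = table.alt_copies[k].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(copies > 0, alt / copies, 0.0)
        raw = 1.0 - (p**2 + (1.0 - p) ** 2)
        h = np.where(copies > 1, copies / (copies - 1.0) * raw, 0.0)
    return h


def _per_site_pi(table: AlleleTable, k: int) -> np.ndarray:
    """Per-site pi = (# differing allele-copy pairs) / C(copies, 2)."""
    copies = table.total_copies[k].astype(float)
    alt = table.alt_copies[k].astype(float)
    ref = copies - alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pairs = copies * (copies - 1.0) / 2.0
        diff = ref * alt
        return np.where(pairs > 0, diff / pairs, 0.0)


def expected_heterozygosity(
    table: AlleleTable, population_id: str, denominator: str = "variant"
) -> float:
    k = table.pop_index(population_id)
    sel = _site_set(table, denominator) & (table.n_typed[k] > 0)
    h = _per_site_unbiased_het(table, k)[sel]
    return float(h.mean()) if h.size else 0.0


def nucleotide_diversity(
    table: AlleleTable, population_id: str, denominator: str = "variant"
) -> float:
    k = table.pop_index(population_id)
    sel = _site_set(table, denominator) & (table.n_typed[k] > 0)
    pi = _per_site_pi(table, k)[sel]
    return float(pi.mean()) if pi.size else 0.0


# ---------------------------------------------------------------------------
# Allelic richness (Hurlbert rarefaction)
# ---------------------------------------------------------------------------

def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    """log C(n, k) with -inf where n < k."""
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore"):
        out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where(n >= k, out, -np.inf)


def rarefied_allelic_richness(
    table: AlleleTable, population_id: str, g: int | None = None
) -> float:
    """Mean per-locus expected allele count in a subsample of ``g`` gene copies.

    Hurlbert rarefaction: per locus, ``sum_a [1 - C(N - N_a, g) / C(N, g)]``.
    ``g`` defaults to the smallest per-population typed-copy minimum so all
    populations are standardized to the same sample size.  Loci with fewer
    than ``g`` typed copies in this population are skipped.
    """
    if g is None:
        g = auto_rarefaction_g(table)
    k = table.pop_index(population_id)
    variant = table.variant_mask
    copies = table.total_copies[k][variant].astype(float)
    alt = table.alt_copies[k][variant].astype(float)
    ref = copies - alt
    usable = copies >= g
    if not usable.any():
        raise ValueError(f"no loci with >= {g} copies in {population_id}")
    copies, alt, ref = copies[usable], alt[usable], ref[usable]
    log_cn = _log_comb(copies, g)
    contrib = np.zeros_like(copies)
    for counts in (ref, alt):
        with np.errstate(invalid="ignore"):
            term = 1.0 - np.exp(_log_comb(copies - counts, g) - log_cn)
        contrib += np.where(counts > 0, term, 0.0)
    return float(contrib.mean())


def auto_rarefaction_g(table: AlleleTable) -> int:
    """Default rarefaction size: min over populations of their smallest
    positive per-locus typed-copy count."""
    variant = table.variant_mask
    copies = table.total_copies[:, variant]
    mins = []
    for k in range(len(table.populations)):
        pos = copies[k][copies[k] > 0]
        if pos.size:
            mins.append(pos.min())
    if not mins:
        raise ValueError("no typed variant loci in any population")
    return int(min(mins))


# ---------------------------------------------------------------------------
# Private alleles
# ---------------------------------------------------------------------------

def private_alleles_raw(table: AlleleTable) -> pd.Series:
    """Count of alleles observed in exactly one population, per population."""
    variant = table.variant_mask
    counts = {}
    alt_present = table.alt_copies[:, variant] > 0
    ref_present = table.ref_copies[:, variant] > 0
    for present in (alt_present, ref_present):
        only_one = present.sum(axis=0) == 1
        for k, pop in enumerate(table.populations):
            counts[pop] = counts.get(pop, 0) + int(
                (present[k] & only_one).sum()
            )
    return pd.Series(counts).reindex(table.populations)


def private_alleles(
    dataset: GenotypeDataset,
    popmap: PopulationMap,
    standardize_n: int = 6,
    reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Raw and sample-size-standardized private allele counts.

    Standardization subsamples ``standardize_n`` individuals per population
    (populations with fewer individuals are excluded) ``reps`` times and
    averages the raw private counts.
    """
    table = allele_counts(dataset, popmap)
    raw = private_alleles_raw(table)
    rng = np.random.default_rng(seed)
    eligible = [
        p for p in popmap.populations
        if len(popmap.individuals_of(p)) >= standardize_n
    ]
    acc = pd.Series(0.0, index=eligible)
    for _ in range(reps):
        chosen: list[str] = []
        for p in eligible:
            inds = popmap.individuals_of(p)
            pick = rng.choice(len(inds), size=standardize_n, replace=False)
            chosen.extend(inds[i] for i in pick)
        sub = dataset.subset_individuals(chosen)
        sub_table = allele_counts(sub, popmap.restrict_to(chosen))
        acc = acc.add(private_alleles_raw(sub_table).reindex(eligible), fill_value=0.0)
    std = acc / reps
    return pd.DataFrame(
        {"private_alleles": raw, "private_alleles_std": std.reindex(raw.index)}
    )


# ---------------------------------------------------------------------------
# Per-population independent recall
# ---------------------------------------------------------------------------

def per_population_recall(
    dataset: GenotypeDataset,
    popmap: PopulationMap,
    population_id: str,
    max_individual_missing: float = 0.10,
) -> GenotypeDataset:
    """Population-private complete-data subset for unbiased heterozygosity.

    Keeps this population's individuals with less than
    ``max_individual_missing`` missing data, then keeps only sites fully
    genotyped across them; sites monomorphic within the subset are re-classed
    invariant so the all-sites denominator reflects what an independent
    per-population variant call would report.
    """
    inds = popmap.individuals_of(population_id)
    if not inds:
        raise KeyError(f"unknown or empty population: {population_id}")
    sub = dataset.subset_individuals(inds)
    keep = sub.sample_call_rate() > 1.0 - max_individual_missing
    if not keep.any():
        raise ValueError(
            f"no individuals of {population_id} pass the missing-data filter"
        )
    sub = sub.take_individuals(keep)
    sub = sub.take_sites(sub.called.all(axis=0))
    alt = (sub.dosage.sum(axis=0)).astype(int)
    mono = (alt == 0) | (alt == 2 * sub.n_individuals)
    sites = sub.sites.copy()
    reclass = mono & (sites["site_class"] == "variant").to_numpy()
    sites.loc[reclass, "site_class"] = "invariant"
    sites.loc[reclass, "alt"] = None
    # alt-fixed sites: recode dosage relative to the (new) monomorphic state
    fixed_alt = reclass & (alt == 2 * sub.n_individuals)
    dosage = sub.dosage.copy()
    dosage[:, fixed_alt] = 0
    return GenotypeDataset(
        individual_ids=sub.individual_ids,
        sites=sites,
        dosage=dosage,
        ref_depth=sub.ref_depth,
        alt_depth=sub.alt_depth,
        replicate_pairs=sub.replicate_pairs,
    )


# ---------------------------------------------------------------------------
# Table-1-style summary
# ---------------------------------------------------------------------------

def population_diversity(
    dataset: GenotypeDataset,
    popmap: PopulationMap,
    rarefaction_g: int | None = None,
    standardize_n: int = 6,
    reps: int = 100,
    seed: int = 0,
    recall: bool = True,
    min_n: int = 1,
) -> pd.DataFrame:
    """One row of diversity statistics per population.

    With ``recall=True``, H_O/H_E/pi for each population are computed on its
    independently re-called (complete-data) subset; A_R and private alleles
    always come from the joint dataset so alleles are compared on common loci.
    """
    joint = allele_counts(dataset, popmap)
    g = rarefaction_g if rarefaction_g is not None else auto_rarefaction_g(joint)
    pa = private_alleles(
        dataset, popmap, standardize_n=standardize_n, reps=reps, seed=seed
    )
    rows = []
    for pop in popmap.populations:
        inds = popmap.individuals_of(pop)
        if len(inds) < min_n:
            continue
        if recall:
            sub = per_population_recall(dataset, popmap, pop)
            sub_map = popmap.restrict_to(sub.individual_ids)
            tab = allele_counts(sub, sub_map)
        else:
            tab = joint
        variant_sites = int(
            (tab.n_typed[tab.pop_index(pop)][tab.variant_mask] > 0).sum()
        )
        total_sites = int((tab.n_typed[tab.pop_index(pop)] > 0).sum())
        try:
            ar = rarefied_allelic_richness(joint, pop, g=g)
        except ValueError:
            ar = float("nan")
        rows.append(
            PopulationDiversity(
                population_id=pop,
                n=len(inds),
                ho_variant=observed_heterozygosity(tab, pop, "variant"),
                ho_all_sites=observed_heterozygosity(tab, pop, "all_sites"),
                he_variant=expected_heterozygosity(tab, pop, "variant"),
                he_all_sites=expected_heterozygosity(tab, pop, "all_sites"),
                pi_variant=nucleotide_diversity(tab, pop, "variant"),
                pi_all_sites=nucleotide_diversity(tab, pop, "all_sites"),
                allelic_richness=ar,
                private_alleles=int(pa["private_alleles"].get(pop, 0)),
                private_alleles_std=float(
                    pa["private_alleles_std"].get(pop, float("nan"))
                ),
                variant_sites=variant_sites,
                total_sites=total_sites,
            ).__dict__
        )
    return pd.DataFrame(rows)


def temporal_diversity(
    dataset: GenotypeDataset,
    popmap: PopulationMap,
    time_labels: dict[str, str],
    **kwargs,
) -> pd.DataFrame:
    """Diversity per (population, period): individuals are re-labelled into
    ``population|period`` pseudo-populations and summarized as usual."""
    table = popmap.table.copy()
    periods = table["individual_id"].map(time_labels)
    if periods.isna().any():
        missing = table.loc[periods.isna(), "individual_id"].tolist()
        raise ValueError(f"individuals without a time label: {missing}")
    table["population_id"] = table["population_id"] + "|" + periods
    # provenance is irrelevant for per-period summaries and would dangle
    # after relabelling, so the pseudo-map is all-natural
    table["status"] = "natural"
    table["source_population_id"] = None
    split_map = PopulationMap(table)
    out = population_diversity(dataset, split_map, **kwargs)
    out[["population_id", "period"]] = out["population_id"].str.rsplit(
        "|", n=1, expand=True
    )
    return out
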