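"""Post-assembly SNP and sample filtering cascade for RAD-style genotype data.

The cascade mirrors standard practice for reduced-representation datasets:
locus-presence thresholds, an observed-heterozygosity cap (paralog screen),
one SNP per RAD locus, allelic-depth and allele-balance screens, iterative
sample/SNP call-rate filtering to joint final targets, a minor-allele-count
floor, technical-replicate reproducibility, allele-sharing kinship (the
"beta-dosage" moment estimator) with greedy pruning of close kin, and the
all-sites missingness/mean-depth filter applied ahead of windowed statistics.

Every step returns the filtered dataset together with a :class:`FilterReport`
row so the whole cascade reconciles exactly with dataset shapes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, AlleleTable, GenotypeDataset, PopulationMap, allele_counts

DEFAULT_SAMPLE_SCHEDULE = (0.5, 0.7, 0.90)
DEFAULT_SNP_SCHEDULE = (0.5, 0.7, 0.95)


@dataclass
class FilterReport:
    """Ordered log of filtering steps with before/after counts."""

    steps: list[dict] = field(default_factory=list)

    def record(self, name: str, before: GenotypeDataset, after: GenotypeDataset,
               **params) -> None:
        if after.n_sites > before.n_sites or after.n_individuals > before.n_individuals:
            raise ValueError(f"filter step {name} increased dataset size")
        self.steps.append(
            {
                "step": name,
                "sites_before": before.n_sites,
                "sites_after": after.n_sites,
                "individuals_before": before.n_individuals,
                "individuals_after": after.n_individuals,
                "params": dict(params),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            row = {k: v for k, v in s.items() if k != "params"}
            row["params"] = ";".join(f"{k}={v}" for k, v in s["params"].items())
            rows.append(row)
        return pd.DataFrame(rows)

    def extend(self, other: "FilterReport") -> None:
        self.steps.extend(other.steps)


@dataclass
class KinshipMatrix:
    """Symmetric matrix of allele-sharing kinship estimates (beta-hat)."""

    individual_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.individual_ids)
        if v.shape != (n, n):
            raise ValueError("kinship matrix shape mismatch")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("kinship matrix must be symmetric")
        self.values = v

    def off_diagonal(self) -> np.ndarray:
        mask = ~np.eye(len(self.individual_ids), dtype=bool)
        return self.values[mask]


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


# ---------------------------------------------------------------------------
# Site filters
# ---------------------------------------------------------------------------

def filter_site_presence(
    dataset: GenotypeDataset,
    popmap: PopulationMap,
    min_pop_fraction: float = 0.0,
    min_sample_fraction: float = 0.5,
    min_populations: int | None = 1,
) -> tuple[GenotypeDataset, FilterReport]:
    """Keep sites typed in enough samples overall and present in enough populations.

    A site is retained when called in at least ``ceil(min_sample_fraction * N)``
    individuals and present (>= 1 typed individual) in at least
    ``min_populations`` populations (or ``ceil(min_pop_fraction * P)`` when
    ``min_populations`` is None).
    """
    _check_fraction("min_sample_fraction", min_sample_fraction)
    _check_fraction("min_pop_fraction", min_pop_fraction)
    table = allele_counts(dataset, popmap)
    n_required = int(np.ceil(min_sample_fraction * dataset.n_individuals))
    typed_total = table.n_typed.sum(axis=0)
    if min_populations is None:
        min_populations = int(np.ceil(min_pop_fraction * len(table.populations)))
    pops_present = (table.n_typed > 0).sum(axis=0)
    keep = (typed_total >= n_required) & (pops_present >= min_populations)
    out = dataset.take_sites(keep)
    report = FilterReport()
    report.record(
        "site_presence", dataset, out,
        min_sample_fraction=min_sample_fraction, min_populations=min_populations,
    )
    return out, report


def filter_max_het(
    dataset: GenotypeDataset, max_ho: float = 0.70
) -> tuple[GenotypeDataset, FilterReport]:
    """Drop variant sites whose pooled observed heterozygosity exceeds ``max_ho``.

    Removal is strictly greater-than, so a site at exactly the threshold is
    kept.  Excess heterozygosity flags collapsed paralogous RAD loci.
    """
    _check_fraction("max_ho", max_ho)
    het = (dataset.dosage == 1).sum(axis=0)
    typed = dataset.called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(typed > 0, het / typed, 0.0)
    keep = ~dataset.variant_mask | (ho <= max_ho)
    out = dataset.take_sites(keep)
    report = FilterReport()
    report.record("max_het", dataset, out, max_ho=max_ho)
    return out, report


def prune_one_snp_per_locus(dataset: GenotypeDataset) -> GenotypeDataset:
    """Retain a single SNP per RAD locus (short-range LD pruning).

    The SNP with the highest call rate wins; ties break to the smallest
    position.  Invariant sites are untouched.
    """
    call_rate = dataset.site_call_rate()
    variant = dataset.variant_mask
    order = pd.DataFrame(
        {
            "locus": dataset.sites["locus_id"].to_numpy(),
            "pos": dataset.sites["pos"].to_numpy(),
            "call_rate": call_rate,
            "idx": np.arange(dataset.n_sites),
            "variant": variant,
        }
    )
    snps = order[order["variant"]]
    best = (
        snps.sort_values(["locus", "call_rate", "pos"], ascending=[True, False, True])
        .groupby("locus", sort=False)
        .head(1)["idx"]
        .to_numpy()
    )
    keep = np.zeros(dataset.n_sites, dtype=bool)
    keep[best] = True
    keep |= ~variant
    return dataset.take_sites(keep)


def filter_allelic_depth(
    dataset: GenotypeDataset,
    min_mean_ad: float = 2.5,
    max_balance_diff: float = 0.80,
) -> tuple[GenotypeDataset, FilterReport]:
    """Screen variant sites on mean allelic depth and het allele balance.

    Sites are removed when the mean per-genotype total allelic depth (over
    called genotypes) is <= ``min_mean_ad``, or when the relative difference
    between mean ref and alt depth across heterozygous genotypes,
    ``|r - a| / max(r, a)``, is >= ``max_balance_diff``.
    """
    if not dataset.has_depth:
        raise ValueError("no AD data: dataset has no allelic-depth layer")
    called = dataset.called
    total = (dataset.ref_depth + dataset.alt_depth).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_ad = np.where(
            called.sum(axis=0) > 0,
            np.where(called, total, 0.0).sum(axis=0) / called.sum(axis=0),
            np.inf,
        )
    het = dataset.dosage == 1
    n_het = het.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ref_mean = np.where(n_het > 0, np.where(het, dataset.ref_depth, 0).sum(axis=0) / n_het, 0.0)
        alt_mean = np.where(n_het > 0, np.where(het, dataset.alt_depth, 0).sum(axis=0) / n_het, 0.0)
        peak = np.maximum(ref_mean, alt_mean)
        balance = np.where(peak > 0, np.abs(ref_mean - alt_mean) / np.where(peak > 0, peak, 1.0), 0.0)
    keep = ~dataset.variant_mask | ((mean_ad > min_mean_ad) & (balance < max_balance_diff))
    out = dataset.take_sites(keep)
    report = FilterReport()
    report.record(
        "allelic_depth", dataset, out,
        min_mean_ad=min_mean_ad, max_balance_diff=max_balance_diff,
    )
    return out, report


def iterative_call_rate_filter(
    dataset: GenotypeDataset,
    sample_targets=DEFAULT_SAMPLE_SCHEDULE,
    snp_targets=DEFAULT_SNP_SCHEDULE,
) -> tuple[GenotypeDataset, FilterReport]:
    """Alternate SNP and sample call-rate filters over ascending schedules.

    Each round drops sites below the round's SNP target, then individuals
    below the round's sample target.  After the final round, both final
    thresholds are re-applied until the dataset satisfies them jointly.
    """
    sample_targets = list(sample_targets)
    snp_targets = list(snp_targets)
    if len(sample_targets) != len(snp_targets):
        raise ValueError("sample and SNP schedules must have equal length")
    for sched, name in ((sample_targets, "sample"), (snp_targets, "snp")):
        if any(b < a for a, b in zip(sched, sched[1:])):
            raise ValueError(f"{name} schedule must be non-descending")
        for v in sched:
            _check_fraction(f"{name} target", v)
    if dataset.n_sites == 0 or dataset.n_individuals == 0:
        raise ValueError("empty dataset")
    report = FilterReport()
    current = dataset
    for round_i, (snp_t, sample_t) in enumerate(zip(snp_targets, sample_targets)):
        before = current
        current = current.take_sites(current.site_call_rate() >= snp_t)
        current = current.take_individuals(current.sample_call_rate() >= sample_t)
        report.record(
            f"call_rate_round_{round_i + 1}", before, current,
            snp_target=snp_t, sample_target=sample_t,
        )
    # converge on the joint final thresholds
    after_rounds = current
    while True:
        site_ok = current.site_call_rate() >= snp_targets[-1]
        if not site_ok.all():
            current = current.take_sites(site_ok)
            continue
        sample_ok = current.sample_call_rate() >= sample_targets[-1]
        if not sample_ok.all():
            current = current.take_individuals(sample_ok)
            continue
        break
    report.record(
        "call_rate_final", after_rounds, current,
        snp_target=snp_targets[-1], sample_target=sample_targets[-1],
    )
    return current, report


def filter_mac(
    dataset: GenotypeDataset, min_mac: int = 3
) -> tuple[GenotypeDataset, FilterReport]:
    """Drop variant sites with minor allele count below ``min_mac`` copies."""
    called = dataset.called
    alt = np.where(called, dataset.dosage, 0).sum(axis=0)
    total = 2 * called.sum(axis=0)
    mac = np.minimum(alt, total - alt)
    keep = ~dataset.variant_mask | (mac >= min_mac)
    out = dataset.take_sites(keep)
    report = FilterReport()
    report.record("mac", dataset, out, min_mac=min_mac)
    return out, report


def filter_replicate_reproducibility(
    dataset: GenotypeDataset,
) -> tuple[GenotypeDataset, FilterReport]:
    """Drop sites at which any technical replicate pair disagrees, then
    collapse each pair to its higher-call-rate member.

    A comparison with a missing call on either side is not a mismatch.
    """
    report = FilterReport()
    if not dataset.replicate_pairs:
        warnings.warn("no replicate pairs declared; reproducibility filter is a no-op")
        report.record("replicate_reproducibility", dataset, dataset, pairs=0)
        return dataset, report
    bad = np.zeros(dataset.n_sites, dtype=bool)
    idx = {v: i for i, v in enumerate(dataset.individual_ids)}
    for a, b in dataset.replicate_pairs:
        da, db = dataset.dosage[idx[a]], dataset.dosage[idx[b]]
        both = (da != MISSING) & (db != MISSING)
        bad |= both & (da != db)
    out = dataset.take_sites(~bad | ~dataset.variant_mask)
    # drop the lower-call-rate member of each pair
    rates = out.sample_call_rate()
    ridx = {v: i for i, v in enumerate(out.individual_ids)}
    drop = set()
    for a, b in dataset.replicate_pairs:
        if a in ridx and b in ridx:
            drop.add(a if rates[ridx[a]] < rates[ridx[b]] else b)
    keep_ind = [i for i, v in enumerate(out.individual_ids) if v not in drop]
    out = out.take_individuals(np.array(keep_ind, dtype=int))
    report.record(
        "replicate_reproducibility", dataset, out, pairs=len(dataset.replicate_pairs)
    )
    return out, report


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

def kinship_beta_dosage(dataset: GenotypeDataset) -> KinshipMatrix:
    """Allele-sharing kinship (beta-hat) from alt-allele dosages.

    Per pair, the matching proportion is the mean over co-typed loci of
    ``x_i x_j + (1 - x_i)(1 - x_j)`` with half-dosages ``x in {0, 1/2, 1}``
    (self-pairs use the same form, giving 1 for homozygotes and 1/2 for
    heterozygotes).  Estimates are centred on the mean off-diagonal matching:
    ``beta = (M - Mbar) / (1 - Mbar)``, so the off-diagonal average is zero by
    construction.  Pairs sharing no co-typed loci get NaN.
    """
    variant = dataset.variant_mask
    dos = dataset.dosage[:, variant].astype(float)
    if dataset.n_individuals < 2:
        raise ValueError("kinship requires at least 2 individuals")
    called = dos != MISSING
    x = np.where(called, dos / 2.0, 0.0)
    y = np.where(called, 1.0 - dos / 2.0, 0.0)
    w = called.astype(float)
    num = x @ x.T + y @ y.T
    den = w @ w.T
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(den > 0, num / den, np.nan)
    off = ~np.eye(len(m), dtype=bool)
    mbar = np.nanmean(m[off])
    beta = (m - mbar) / (1.0 - mbar)
    return KinshipMatrix(individual_ids=list(dataset.individual_ids), values=beta)


def remove_related(
    dataset: GenotypeDataset,
    kinship: KinshipMatrix,
    threshold: float = 0.25,
) -> tuple[GenotypeDataset, FilterReport]:
    """Greedily prune individuals until no pair's kinship exceeds ``threshold``.

    At each step the individual involved in the most above-threshold pairs is
    removed (ties break to the lower call rate, then input order).
    """
    if kinship.individual_ids != dataset.individual_ids:
        raise ValueError("kinship matrix does not match dataset individuals")
    values = kinship.values.copy()
    np.fill_diagonal(values, -np.inf)
    active = np.ones(dataset.n_individuals, dtype=bool)
    call_rate = dataset.sample_call_rate()
    with np.errstate(invalid="ignore"):
        over = np.nan_to_num(values, nan=-np.inf) > threshold
    while True:
        deg = (over & active[None, :] & active[:, None]).sum(axis=1)
        deg[~active] = 0
        if deg.max() == 0:
            break
        worst = deg == deg.max()
        candidates = np.flatnonzero(worst)
        candidates = candidates[np.argsort(call_rate[candidates], kind="stable")]
        active[candidates[0]] = False
    out = dataset.take_individuals(np.flatnonzero(active))
    report = FilterReport()
    report.record("kinship", dataset, out, threshold=threshold)
    return out, report


# ---------------------------------------------------------------------------
# All-sites filter (ahead of windowed pi / dxy / FST)
# ---------------------------------------------------------------------------

def allsites_filter(
    dataset: GenotypeDataset,
    max_missing: float = 0.9,
    min_mean_dp: float = 5.0,
    max_mean_dp: float = 100.0,
) -> tuple[GenotypeDataset, FilterReport]:
    """Call-rate and mean-depth site filter applied to variant and invariant
    sites jointly (VCFtools ``--max-missing/--min-meanDP/--max-meanDP``
    semantics: call rate >= ``max_missing``; depth bounds inclusive)."""
    _check_fraction("max_missing", max_missing)
    if not dataset.has_depth:
        raise ValueError("no AD data: all-sites filter needs the depth layer")
    rate = dataset.site_call_rate()
    called = dataset.called
    total = (dataset.ref_depth + dataset.alt_depth).astype(float)
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_dp = np.where(
            n_called > 0, np.where(called, total, 0.0).sum(axis=0) / n_called, 0.0
        )
    keep = (rate >= max_missing) & (mean_dp >= min_mean_dp) & (mean_dp <= max_mean_dp)
    out = dataset.take_sites(keep)
    report = FilterReport()
    report.record(
        "allsites", dataset, out,
        max_missing=max_missing, min_mean_dp=min_mean_dp, max_mean_dp=max_mean_dp,
    )
    return out, report


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

def run_cascade(
    dataset: GenotypeDataset,
    popmap: PopulationMap,
    min_sample_fraction: float = 0.5,
    max_ho: float = 0.70,
    min_mean_ad: float = 2.5,
    max_balance_diff: float = 0.80,
    sample_targets=DEFAULT_SAMPLE_SCHEDULE,
    snp_targets=DEFAULT_SNP_SCHEDULE,
    min_mac: int = 3,
    kinship_threshold: float = 0.25,
) -> tuple[GenotypeDataset, FilterReport]:
    """The full SNP filtering cascade in its fixed order: presence -> max-het
    -> one-SNP-per-locus -> allelic depth -> iterative call rate -> MAC ->
    replicate reproducibility -> kinship pruning."""
    report = FilterReport()
    ds, r = filter_site_presence(
        dataset, popmap, min_sample_fraction=min_sample_fraction
    )
    report.extend(r)
    ds, r = filter_max_het(ds, max_ho=max_ho)
    report.extend(r)
    before = ds
    ds = prune_one_snp_per_locus(ds)
    report.record("one_snp_per_locus", before, ds)
    if ds.has_depth:
        ds, r = filter_allelic_depth(
            ds, min_mean_ad=min_mean_ad, max_balance_diff=max_balance_diff
        )
        report.extend(r)
    ds, r = iterative_call_rate_filter(
        ds, sample_targets=sample_targets, snp_targets=snp_targets
    )
    report.extend(r)
    ds, r = filter_mac(ds, min_mac=min_mac)
    report.extend(r)
    if ds.replicate_pairs:
        ds, r = filter_replicate_reproducibility(ds)
        report.extend(r)
    # Close-kin pruning is done within populations: the beta-hat estimator is
    # centred on the mean allele sharing of its input sample, so across a
    # strongly drift-structured dataset every within-population pair of an
    # isolated population looks "related" relative to the global average.
    before = ds
    pmap = popmap.restrict_to(ds.individual_ids)
    drop: set[str] = set()
    for pop in pmap.populations:
        inds = [i for i in pmap.individuals_of(pop) if i in set(ds.individual_ids)]
        if len(inds) < 2:
            continue
        sub = ds.subset_individuals(inds)
        kin = kinship_beta_dosage(sub)
        pruned, _ = remove_related(sub, kin, threshold=kinship_threshold)
        drop |= set(sub.individual_ids) - set(pruned.individual_ids)
    if drop:
        keep = [i for i, v in enumerate(ds.individual_ids) if v not in drop]
        ds = ds.take_individuals(np.array(keep, dtype=int))
    report.record("kinship", before, ds, threshold=kinship_threshold, scope="within-population")
    return ds, report
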