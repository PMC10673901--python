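"""Synthetic structured-population genotype data.

The generator emulates the statistical structure of a reduced-representation
(RAD) study of a drift-structured metapopulation: short loci carrying one or a
few SNPs plus invariant sites, several population strata (e.g. subspecies)
each holding island-like populations with strong drift, translocated
populations founded from a natural source, per-genotype allelic depths,
missingness, technical replicate pairs and full-sib pairs.

Allele frequencies follow a hierarchical Balding-Nichols model: for ancestral
frequency p0 and drift intensity F, a descendant frequency is drawn from
``Beta(p0 (1-F)/F, (1-p0)(1-F)/F)`` so that ``E[p] = p0`` and
``Var(p) = F p0 (1-p0)``.  Stratum frequencies drift from the ancestral pool
with ``F_stratum``; population frequencies drift from their stratum with
``F_pop``.  Translocations are modelled mechanistically: binomial founder
sampling of ``2 n_founders`` gene copies followed by ``g`` generations of
binomial drift at effective size ``Ne``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    MISSING,
    POPMAP_COLUMNS,
    SITE_COLUMNS,
    GenotypeDataset,
    PopulationMap,
)


@dataclass
class PopulationSpec:
    """One simulated population."""

    name: str
    stratum: str
    f_pop: float = 0.1
    n: int = 20
    status: str = "natural"
    source: str | None = None
    n_founders: int = 100
    generations: int = 3
    ne: int = 500
    lon: float = 0.0
    lat: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_pop < 1.0:
            raise ValueError(f"f_pop must be in [0, 1): {self.f_pop}")
        if self.status == "translocated":
            if self.source is None:
                raise ValueError(f"translocated population {self.name} needs a source")
            if self.n_founders > 2 * self.ne:
                raise ValueError("n_founders cannot exceed 2 * Ne")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study system.

    Defaults describe a desk-scale version of the target system: 2000 RAD
    loci of 125 bp with one SNP and 20 invariant sites each, ancestral
    frequencies uniform on (0.05, 0.95), three strata with mild shared drift,
    and per-population drift intensities spanning weak (mainland) to strong
    (long-isolated island) differentiation.
    """

    seed: int = 0
    n_loci: int = 2000
    snps_per_locus: int = 1
    locus_length: int = 125
    invariant_sites_per_locus: int = 20
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    stratum_f: dict[str, float] = field(default_factory=dict)
    populations: list[PopulationSpec] = field(default_factory=list)
    missing_rate: float = 0.05
    mean_depth: float = 20.0
    depth_dispersion: float = 5.0
    genotype_error_rate: float = 0.0
    replicate_pairs: int = 0
    full_sib_pairs: int = 0

    def __post_init__(self) -> None:
        for name, f in self.stratum_f.items():
            if not 0.0 <= f < 1.0:
                raise ValueError(f"stratum {name} F must be in [0, 1)")
        for p in (self.missing_rate, self.genotype_error_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        for pop in self.populations:
            if pop.stratum not in self.stratum_f:
                raise ValueError(f"population {pop.name} references unknown stratum")
            if pop.source is not None:
                names = {q.name for q in self.populations}
                if pop.source not in names:
                    raise ValueError(f"unknown source population {pop.source}")

    @property
    def n_snps(self) -> int:
        return self.n_loci * self.snps_per_locus


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default study system: 3 strata, 9 natural and 3 translocated
    populations, drift intensities spanning F ~ 0.05-0.6 so that pairwise
    differentiation covers the strong-drift regime (F_ST roughly 0.1-0.6)."""
    pops = [
        # stratum A: one large well-connected mainland-like region
        PopulationSpec("mainland_1", "A", 0.05, 24, lon=125.0, lat=-16.0),
        PopulationSpec("mainland_2", "A", 0.08, 20, lon=126.0, lat=-15.5),
        PopulationSpec("mainland_3", "A", 0.10, 18, lon=125.5, lat=-14.8),
        PopulationSpec("island_A1", "A", 0.35, 14, lon=124.5, lat=-15.2),
        # stratum B: moderately drifted island group with translocations
        PopulationSpec("island_B1", "B", 0.20, 30, lon=115.4, lat=-20.8),
        PopulationSpec(
            "island_B2", "B", 0.20, 12, status="translocated", source="island_B1",
            n_founders=120, generations=4, ne=400, lon=115.5, lat=-21.5,
        ),
        PopulationSpec(
            "island_B3", "B", 0.20, 12, status="translocated", source="island_B1",
            n_founders=100, generations=3, ne=400, lon=114.9, lat=-21.0,
        ),
        PopulationSpec(
            "refuge_B4", "B", 0.20, 14, status="translocated", source="island_B1",
            n_founders=160, generations=5, ne=600, lon=122.2, lat=-26.2,
        ),
        # stratum C: small, long-isolated, strongly drifted islands
        PopulationSpec("island_C1", "C", 0.55, 18, lon=136.4, lat=-11.2),
        PopulationSpec("island_C2", "C", 0.60, 8, lon=136.6, lat=-11.6),
        PopulationSpec("island_C3", "C", 0.50, 12, lon=136.2, lat=-11.9),
        PopulationSpec("island_A2", "A", 0.45, 10, lon=125.8, lat=-15.9),
    ]
    cfg = dict(
        seed=seed,
        stratum_f={"A": 0.05, "B": 0.10, "C": 0.15},
        populations=pops,
        missing_rate=0.05,
        mean_depth=20.0,
        depth_dispersion=5.0,
        replicate_pairs=2,
        full_sib_pairs=0,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------

def _balding_nichols(rng, p0: np.ndarray, f: float) -> np.ndarray:
    """Draw descendant frequencies for drift intensity ``f`` (f=0 copies p0)."""
    if f == 0.0:
        return p0.copy()
    a = p0 * (1.0 - f) / f
    b = (1.0 - p0) * (1.0 - f) / f
    return rng.beta(a, b)


def simulate_allele_frequencies(config: SimulationConfig) -> pd.DataFrame:
    """Latent per-population alt-allele frequencies at every SNP.

    Returns a DataFrame with one column per population plus ``ancestral`` and
    per-stratum columns; rows are SNPs in genome order.  Translocated
    populations are founded from their source population's frequencies.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_snps
    p0 = rng.uniform(config.ancestral_low, config.ancestral_high, size=n)
    freqs = pd.DataFrame({"ancestral": p0})
    for stratum, f_s in config.stratum_f.items():
        freqs[f"stratum:{stratum}"] = _balding_nichols(rng, p0, f_s)
    # natural populations first (sources must exist before translocations)
    for pop in config.populations:
        if pop.status != "translocated":
            ps = freqs[f"stratum:{pop.stratum}"].to_numpy()
            freqs[pop.name] = _balding_nichols(rng, ps, pop.f_pop)
    for pop in config.populations:
        if pop.status == "translocated":
            src = freqs[pop.source].to_numpy()
            freqs[pop.name] = simulate_translocation(
                src, pop.n_founders, pop.generations, pop.ne,
                seed=rng.integers(2**31),
            )
    return freqs


def simulate_translocation(
    source_freqs: np.ndarray,
    n_founders: int,
    generations: int,
    ne: int,
    seed: int | None = None,
) -> np.ndarray:
    """Founder-event frequencies: binomial sampling of ``2 n_founders`` gene
    copies from the source, then ``generations`` rounds of binomial drift at
    ``2 Ne`` copies."""
    rng = np.random.default_rng(seed)
    p = rng.binomial(2 * n_founders, source_freqs) / (2.0 * n_founders)
    for _ in range(generations):
        p = rng.binomial(2 * ne, p) / (2.0 * ne)
    return p


def expected_fst(
    f_pop_a: float,
    f_pop_b: float,
    f_stratum_a: float = 0.0,
    f_stratum_b: float | None = None,
    same_stratum: bool = True,
) -> float:
    """Hudson-type expectation for a population pair under the nested model.

    Drift accumulates multiplicatively in heterozygosity: a population with
    stratum drift F_s and population drift F_p has total drift
    ``F_tot = F_s + (1 - F_s) F_p`` relative to the ancestral pool.  For a
    pair, the ratio-of-expectations Hudson F_ST is the mean of the two total
    drifts measured relative to their most recent shared pool: the stratum
    for a within-stratum pair, the ancestral pool otherwise.
    """
    if same_stratum:
        return 0.5 * (f_pop_a + f_pop_b)
    if f_stratum_b is None:
        f_stratum_b = f_stratum_a
    ta = f_stratum_a + (1 - f_stratum_a) * f_pop_a
    tb = f_stratum_b + (1 - f_stratum_b) * f_pop_b
    return 0.5 * (ta + tb)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _site_table(config: SimulationConfig, rng) -> pd.DataFrame:
    """Lay RAD loci end-to-end on one synthetic chromosome; SNP positions and
    invariant positions are drawn without replacement within each locus."""
    rows = []
    per_locus = config.snps_per_locus + config.invariant_sites_per_locus
    if per_locus > config.locus_length:
        raise ValueError("more sites per locus than locus length")
    for li in range(config.n_loci):
        start = li * config.locus_length + 1
        offsets = rng.choice(config.locus_length, size=per_locus, replace=False)
        offsets.sort()
        snp_offsets = set(
            rng.choice(offsets, size=config.snps_per_locus, replace=False)
        )
        for off in offsets:
            is_snp = off in snp_offsets
            rows.append(
                (
                    "chr1",
                    start + int(off),
                    f"locus_{li:06d}",
                    "A",
                    "T" if is_snp else None,
                    "variant" if is_snp else "invariant",
                )
            )
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def simulate_genotypes(
    freqs: pd.DataFrame, config: SimulationConfig
) -> tuple[GenotypeDataset, PopulationMap, dict]:
    """Draw Hardy-Weinberg genotypes plus sequencing artifacts.

    Returns the dataset (SNPs and invariant sites in genome order), the
    matching population map and a truth record holding every latent
    parameter.  Total depth is negative-binomial with the configured mean and
    dispersion; heterozygote allelic depths are binomial(depth, 1/2);
    missingness is completely at random; technical replicates duplicate a
    genotype vector and flip each call with the genotype error rate;
    full-sib pairs are drawn by Mendelian inheritance from two simulated
    parents.
    """
    rng = np.random.default_rng(config.seed + 1)
    sites = _site_table(config, rng)
    variant = (sites["site_class"] == "variant").to_numpy()
    n_sites = len(sites)
    snp_col = np.flatnonzero(variant)

    individual_ids: list[str] = []
    pop_rows = []
    genotype_blocks = []
    sib_pairs: list[tuple[str, str]] = []
    for pop in config.populations:
        p = freqs[pop.name].to_numpy()
        n_sibs = min(config.full_sib_pairs, pop.n // 2 - 1) if config.full_sib_pairs else 0
        n_indep = pop.n - 2 * n_sibs
        block = rng.binomial(2, p, size=(n_indep, config.n_snps)).astype(np.int8)
        rowsets = [block]
        for s in range(n_sibs):
            parents = rng.binomial(1, p, size=(2, 2, config.n_snps))  # parent x allele
            kids = []
            for _ in range(2):
                pick = rng.integers(2, size=(2, config.n_snps))
                kid = np.take_along_axis(parents[0], pick[:1], axis=0)[0] + \
                    np.take_along_axis(parents[1], pick[1:], axis=0)[0]
                kids.append(kid.astype(np.int8))
            rowsets.append(np.stack(kids))
        block = np.vstack(rowsets)
        ids = [f"{pop.name}_{i:03d}" for i in range(pop.n)]
        for s in range(n_sibs):
            sib_pairs.append((ids[n_indep + 2 * s], ids[n_indep + 2 * s + 1]))
        individual_ids.extend(ids)
        genotype_blocks.append(block)
        for ind in ids:
            pop_rows.append(
                (
                    ind, pop.name, pop.stratum,
                    pop.lon + rng.normal(0, 0.01), pop.lat + rng.normal(0, 0.01),
                    pop.status, pop.source, None,
                )
            )
    snp_dosage = np.vstack(genotype_blocks)

    # technical replicates: duplicate the first individual of the first
    # config.replicate_pairs populations, with per-call genotype errors
    replicate_pairs: list[tuple[str, str]] = []
    for r in range(config.replicate_pairs):
        if r >= len(config.populations):
            break
        src_pop = config.populations[r]
        src_id = f"{src_pop.name}_000"
        i = individual_ids.index(src_id)
        dup = snp_dosage[i].copy()
        if config.genotype_error_rate > 0:
            flip = rng.random(config.n_snps) < config.genotype_error_rate
            dup[flip] = rng.integers(0, 3, size=flip.sum())
        rep_id = f"{src_id}_rep"
        individual_ids.append(rep_id)
        snp_dosage = np.vstack([snp_dosage, dup[None, :]])
        src_row = pop_rows[i]
        pop_rows.append((rep_id,) + src_row[1:7] + (f"repgrp_{r}",))
        pop_rows[i] = src_row[:7] + (f"repgrp_{r}",)
        replicate_pairs.append((src_id, rep_id))

    n_ind = len(individual_ids)
    dosage = np.zeros((n_ind, n_sites), dtype=np.int8)
    dosage[:, snp_col] = snp_dosage

    # depth layer: negative-binomial total depth everywhere
    mu, k = config.mean_depth, config.depth_dispersion
    total_depth = rng.negative_binomial(k, k / (k + mu), size=(n_ind, n_sites))
    alt_depth = np.zeros_like(total_depth)
    het = dosage == 1
    alt_depth[het] = rng.binomial(total_depth[het], 0.5)
    hom_alt = dosage == 2
    alt_depth[hom_alt] = total_depth[hom_alt]
    ref_depth = total_depth - alt_depth

    # Missingness is missing-at-random given per-individual and per-site
    # propensities: real RAD missingness concentrates in low-quality samples
    # and dropout-prone loci, which is what leaves a usable 100%-call-rate
    # subset after filtering.  Individual effects ~ Gamma (mean 0.4 * rate);
    # half the sites are dropout-free, the rest ~ Exponential (mean
    # 1.2 * rate), so the overall expected rate is the configured one.
    if config.missing_rate > 0:
        rate = config.missing_rate
        ind_eff = rng.gamma(2.0, rate * 0.2, size=n_ind)
        site_eff = np.where(
            rng.random(n_sites) < 0.5,
            0.0,
            rng.exponential(rate * 1.2, size=n_sites),
        )
        p_miss = np.clip(ind_eff[:, None] + site_eff[None, :], 0.0, 0.95)
        miss = rng.random((n_ind, n_sites)) < p_miss
        dosage[miss] = MISSING
        ref_depth[miss] = 0
        alt_depth[miss] = 0

    dataset = GenotypeDataset(
        individual_ids=individual_ids,
        sites=sites,
        dosage=dosage,
        ref_depth=ref_depth.astype(np.int32),
        alt_depth=alt_depth.astype(np.int32),
        replicate_pairs=replicate_pairs,
    )
    popmap = PopulationMap(pd.DataFrame(pop_rows, columns=POPMAP_COLUMNS))
    truth = {
        "config": config,
        "frequencies": freqs,
        "sib_pairs": sib_pairs,
        "replicate_pairs": replicate_pairs,
    }
    return dataset, popmap, truth


def simulate_dataset(
    config: SimulationConfig | None = None, seed: int = 0, **overrides
) -> tuple[GenotypeDataset, PopulationMap, dict]:
    """One-call convenience: default study system -> frequencies -> genotypes."""
    if config is None:
        config = default_config(seed=seed, **overrides)
    freqs = simulate_allele_frequencies(config)
    return simulate_genotypes(freqs, config)
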