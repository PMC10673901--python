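"""Genotype and population-metadata containers and their file formats.

The central object is :class:`GenotypeDataset`, an individuals x sites matrix
of diploid alt-allele dosages (0/1/2, with -1 for missing) plus site metadata
and an optional per-genotype allelic-depth layer.  Population membership lives
in :class:`PopulationMap`, and :class:`AlleleTable` holds the per-population
allele-count sufficient statistics that nearly all downstream diversity and
differentiation math consumes.

VCF reading goes through cyvcf2; writing produces plain VCF v4.2 text with GT
(and AD when the depth layer is present).  Invariant sites are encoded with
``ALT=.`` as produced by all-sites variant callers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

SITE_COLUMNS = ["chrom", "pos", "locus_id", "ref", "alt", "site_class"]

POPMAP_COLUMNS = [
    "individual_id",
    "population_id",
    "stratum_id",
    "lon",
    "lat",
    "status",
    "source_population_id",
    "replicate_group",
]


class VCFParseError(ValueError):
    """Raised when a VCF cannot be interpreted as diploid biallelic genotypes."""


@dataclass
class GenotypeDataset:
    """Diploid genotypes for a set of individuals at a set of sites.

    Parameters
    ----------
    individual_ids
        Ordered unique individual labels.
    sites
        DataFrame with columns ``chrom, pos, locus_id, ref, alt, site_class``;
        positions are 1-based; ``site_class`` is ``variant`` or ``invariant``
        (invariant sites have ``alt`` = None).
    dosage
        ``(n_individuals, n_sites)`` int8 array of alt-allele counts in
        {0, 1, 2}, with :data:`MISSING` (-1) for uncalled genotypes.
    ref_depth, alt_depth
        Optional per-genotype allelic depth layer (same shape as ``dosage``).
    replicate_pairs
        Pairs of individual ids flagged as technical replicates.
    """

    individual_ids: list[str]
    sites: pd.DataFrame
    dosage: np.ndarray
    ref_depth: np.ndarray | None = None
    alt_depth: np.ndarray | None = None
    replicate_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if len(self.individual_ids) != len(set(self.individual_ids)):
            raise ValueError("individual_ids must be unique")
        if self.dosage.shape != (len(self.individual_ids), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.sites)} sites"
            )
        key = self.sites[["chrom", "pos"]].apply(tuple, axis=1)
        if key.duplicated().any():
            raise ValueError("duplicate (chrom, pos) in site table")
        inv = (self.sites["site_class"] == "invariant").to_numpy()
        if inv.any():
            bad = self.dosage[:, inv]
            if np.any((bad != 0) & (bad != MISSING)):
                raise ValueError("invariant sites must have dosage 0 or missing")
        for layer in (self.ref_depth, self.alt_depth):
            if layer is not None and np.any(layer < 0):
                raise ValueError("depths must be non-negative")

    # -- basic accessors -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def has_depth(self) -> bool:
        return self.ref_depth is not None and self.alt_depth is not None

    @property
    def variant_mask(self) -> np.ndarray:
        return (self.sites["site_class"] == "variant").to_numpy()

    @property
    def called(self) -> np.ndarray:
        """Boolean matrix of non-missing genotype calls."""
        return self.dosage != MISSING

    def individual_index(self, ids) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.individual_ids)}
        missing = [i for i in ids if i not in lookup]
        if missing:
            raise KeyError(f"individuals not in dataset: {missing}")
        return np.array([lookup[i] for i in ids], dtype=int)

    def sample_call_rate(self) -> np.ndarray:
        """Per-individual fraction of called genotypes."""
        if self.n_sites == 0:
            return np.ones(self.n_individuals)
        return self.called.mean(axis=1)

    def site_call_rate(self) -> np.ndarray:
        """Per-site fraction of called genotypes."""
        if self.n_individuals == 0:
            return np.ones(self.n_sites)
        return self.called.mean(axis=0)

    # -- subsetting ------------------------------------------------------
    def take_sites(self, index: np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            sites=self.sites.iloc[index],
            dosage=self.dosage[:, index],
            ref_depth=None if self.ref_depth is None else self.ref_depth[:, index],
            alt_depth=None if self.alt_depth is None else self.alt_depth[:, index],
        )

    def take_individuals(self, index: np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        kept = [self.individual_ids[i] for i in index]
        kept_set = set(kept)
        pairs = [p for p in self.replicate_pairs if p[0] in kept_set and p[1] in kept_set]
        return replace(
            self,
            individual_ids=kept,
            dosage=self.dosage[index],
            ref_depth=None if self.ref_depth is None else self.ref_depth[index],
            alt_depth=None if self.alt_depth is None else self.alt_depth[index],
            replicate_pairs=pairs,
        )

    def subset_individuals(self, ids) -> "GenotypeDataset":
        return self.take_individuals(self.individual_index(ids))


@dataclass
class PopulationMap:
    """Individual -> population -> stratum assignment with provenance.

    Wraps a DataFrame with columns ``individual_id, population_id, stratum_id,
    lon, lat, status, source_population_id, replicate_group``.  Status is
    ``natural`` or ``translocated``; translocated populations must name an
    existing source population.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True).copy()
        missing_cols = [c for c in POPMAP_COLUMNS if c not in t.columns]
        if missing_cols:
            raise ValueError(f"population map missing columns: {missing_cols}")
        if t["individual_id"].duplicated().any():
            dups = t.loc[t["individual_id"].duplicated(), "individual_id"].tolist()
            raise ValueError(f"duplicate individuals in population map: {dups}")
        t["lon"] = pd.to_numeric(t["lon"], errors="raise")
        t["lat"] = pd.to_numeric(t["lat"], errors="raise")
        bad_status = set(t["status"]) - {"natural", "translocated"}
        if bad_status:
            raise ValueError(f"unknown status values: {sorted(bad_status)}")
        # one stratum per population
        strata = t.groupby("population_id")["stratum_id"].nunique()
        if (strata > 1).any():
            raise ValueError(
                f"populations span multiple strata: {strata[strata > 1].index.tolist()}"
            )
        pops = set(t["population_id"])
        for _, row in t.iterrows():
            src = row["source_population_id"]
            has_src = isinstance(src, str) and src != ""
            if row["status"] == "translocated" and not has_src:
                raise ValueError(
                    f"translocated population {row['population_id']} lacks a source"
                )
            if row["status"] == "natural" and has_src:
                raise ValueError(
                    f"natural individual {row['individual_id']} names a source population"
                )
            if has_src and src not in pops:
                raise ValueError(f"unknown source population: {src}")
        self.table = t

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.table["population_id"]))

    @property
    def strata(self) -> list[str]:
        return list(dict.fromkeys(self.table["stratum_id"]))

    def stratum_of(self, population_id: str) -> str:
        rows = self.table.loc[self.table["population_id"] == population_id, "stratum_id"]
        if rows.empty:
            raise KeyError(f"unknown population: {population_id}")
        return rows.iloc[0]

    def individuals_of(self, population_id: str) -> list[str]:
        return self.table.loc[
            self.table["population_id"] == population_id, "individual_id"
        ].tolist()

    def population_of(self) -> dict[str, str]:
        return dict(zip(self.table["individual_id"], self.table["population_id"]))

    def coordinates(self) -> pd.DataFrame:
        """Per-population mean (lon, lat)."""
        return self.table.groupby("population_id")[["lon", "lat"]].mean()

    def replicate_pairs(self) -> list[tuple[str, str]]:
        """Technical replicate pairs declared via a shared replicate_group."""
        pairs = []
        groups = self.table.dropna(subset=["replicate_group"])
        groups = groups[groups["replicate_group"].astype(str) != ""]
        for _, grp in groups.groupby("replicate_group"):
            ids = grp["individual_id"].tolist()
            if len(ids) < 2:
                continue
            anchor = ids[0]
            pairs.extend((anchor, other) for other in ids[1:])
        return pairs

    def restrict_to(self, individual_ids) -> "PopulationMap":
        """Sub-map for a subset of individuals.

        Sources pointing at populations that drop out of the subset are kept
        as free-text provenance but re-validated leniently (set to None) so a
        sub-map of a valid map is always valid.
        """
        keep = self.table["individual_id"].isin(set(individual_ids))
        sub = self.table[keep].copy()
        pops = set(sub["population_id"])
        dangling = ~sub["source_population_id"].isin(pops) & sub[
            "source_population_id"
        ].notna()
        if dangling.any():
            sub.loc[dangling, "source_population_id"] = None
            sub.loc[dangling, "status"] = "natural"
        return PopulationMap(sub)


@dataclass
class AlleleTable:
    """Per-(population, site) allele-count sufficient statistics.

    For every population (rows) and site of the source dataset (columns):
    ``alt_copies`` (alt-allele copies among typed individuals), ``n_typed``
    (individuals with a called genotype) and ``n_het`` (called heterozygotes).
    Ref copies follow as ``2 * n_typed - alt_copies``.  Site metadata is shared
    with the source dataset, so variant and invariant (all-sites denominator)
    sites can be distinguished.
    """

    populations: list[str]
    sites: pd.DataFrame
    alt_copies: np.ndarray  # (n_pops, n_sites)
    n_typed: np.ndarray
    n_het: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.n_het > self.n_typed):
            raise ValueError("n_het cannot exceed n_typed")
        if np.any(self.alt_copies > 2 * self.n_typed):
            raise ValueError("allele copies exceed 2 * n_typed")
        if np.any(self.alt_copies < 0) or np.any(self.n_typed < 0):
            raise ValueError("counts must be non-negative")

    @property
    def ref_copies(self) -> np.ndarray:
        return 2 * self.n_typed - self.alt_copies

    @property
    def total_copies(self) -> np.ndarray:
        return 2 * self.n_typed

    @property
    def variant_mask(self) -> np.ndarray:
        return (self.sites["site_class"] == "variant").to_numpy()

    def pop_index(self, population_id: str) -> int:
        try:
            return self.populations.index(population_id)
        except ValueError:
            raise KeyError(f"unknown population: {population_id}") from None

    def frequencies(self) -> np.ndarray:
        """Alt-allele frequency per (population, site); NaN where untyped."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.n_typed > 0, self.alt_copies / (2.0 * self.n_typed), np.nan
            )

    def invariant_site_counts(self) -> pd.Series:
        """Per-population number of invariant sites genotyped in >= 1 individual."""
        inv = ~self.variant_mask
        return pd.Series(
            (self.n_typed[:, inv] > 0).sum(axis=1), index=self.populations
        )

    def subset_populations(self, keep: list[str]) -> "AlleleTable":
        idx = [self.pop_index(p) for p in keep]
        return AlleleTable(
            populations=list(keep),
            sites=self.sites,
            alt_copies=self.alt_copies[idx],
            n_typed=self.n_typed[idx],
            n_het=self.n_het[idx],
        )


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

def read_vcf(path, include_invariant: bool = True) -> GenotypeDataset:
    """Read a diploid VCF into a :class:`GenotypeDataset`.

    Multi-allelic sites are skipped with a warning (study-grade data are
    biallelic after filtering); a counter of skipped sites is attached as the
    ``n_multiallelic_skipped`` attribute of the returned dataset. Sites without
    an ALT allele are retained as ``invariant`` when ``include_invariant``.
    Non-diploid genotypes raise :class:`VCFParseError`.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise VCFParseError(f"cannot open VCF {path}: {exc}") from exc

    individual_ids = list(vcf.samples)
    n = len(individual_ids)
    rows = []
    dosages = []
    refs = []
    alts = []
    has_ad = False
    n_multi = 0
    locus_counter = 0
    for var in vcf:
        if len(var.ALT) > 1:
            n_multi += 1
            continue
        is_invariant = len(var.ALT) == 0 or var.ALT[0] in (".", "")
        if is_invariant and not include_invariant:
            continue
        gt = var.genotype.array()
        if gt.shape[1] - 1 != 2:  # last column is the phasing flag
            raise VCFParseError(
                f"non-diploid genotype at {var.CHROM}:{var.POS}"
            )
        alleles = gt[:, :2]
        miss = (alleles < 0).any(axis=1)
        if not is_invariant and np.any(alleles > 1):
            raise VCFParseError(
                f"allele index out of range at {var.CHROM}:{var.POS}"
            )
        dos = alleles.sum(axis=1).astype(np.int8)
        dos[miss] = MISSING
        locus = var.ID if var.ID not in (None, ".") else None
        if locus is None:
            locus = f"{var.CHROM}:{var.POS}"
            locus_counter += 1
        rows.append(
            (
                var.CHROM,
                var.POS,
                locus,
                var.REF,
                None if is_invariant else var.ALT[0],
                "invariant" if is_invariant else "variant",
            )
        )
        dosages.append(dos)
        try:
            ad = var.format("AD")
        except KeyError:  # AD absent from the header
            ad = None
        if ad is not None and ad.shape[1] >= 1:
            has_ad = True
            ref_d = np.maximum(ad[:, 0], 0)
            alt_d = np.maximum(ad[:, 1], 0) if ad.shape[1] > 1 else np.zeros(n, int)
            refs.append(ref_d)
            alts.append(alt_d)
        else:
            refs.append(np.zeros(n, dtype=np.int32))
            alts.append(np.zeros(n, dtype=np.int32))
    vcf.close()
    if n_multi:
        warnings.warn(f"skipped {n_multi} multi-allelic sites", stacklevel=2)
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    dosage = (
        np.stack(dosages, axis=1) if dosages else np.zeros((n, 0), dtype=np.int8)
    )
    ds = GenotypeDataset(
        individual_ids=individual_ids,
        sites=sites,
        dosage=dosage,
        ref_depth=np.stack(refs, axis=1).astype(np.int32) if has_ad else None,
        alt_depth=np.stack(alts, axis=1).astype(np.int32) if has_ad else None,
    )
    ds.n_multiallelic_skipped = n_multi
    return ds


def write_vcf(dataset: GenotypeDataset, path) -> None:
    """Write a dataset as VCF v4.2 text with GT (and AD when depths exist)."""
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if dataset.has_depth:
            fh.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,'
                'Description="Allelic depths">\n'
            )
        for chrom in dict.fromkeys(dataset.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "FORMAT"]
        fh.write("\t".join(header[:-1] + ["INFO", "FORMAT"] + dataset.individual_ids))
        fh.write("\n")
        fmt = "GT:AD" if dataset.has_depth else "GT"
        for j in range(dataset.n_sites):
            site = dataset.sites.iloc[j]
            alt = site["alt"] if site["site_class"] == "variant" else "."
            fields = [
                str(site["chrom"]),
                str(int(site["pos"])),
                str(site["locus_id"]),
                str(site["ref"]),
                str(alt),
                ".",
                "PASS",
                ".",
                fmt,
            ]
            calls = []
            for i in range(dataset.n_individuals):
                gt = gt_codes[int(dataset.dosage[i, j])]
                if dataset.has_depth:
                    gt += f":{int(dataset.ref_depth[i, j])},{int(dataset.alt_depth[i, j])}"
                calls.append(gt)
            fh.write("\t".join(fields + calls) + "\n")


def read_population_map(path) -> PopulationMap:
    """Read a tab-separated population map (see :data:`POPMAP_COLUMNS`)."""
    table = pd.read_csv(
        path,
        sep="\t",
        dtype={"individual_id": str, "population_id": str, "stratum_id": str},
        keep_default_na=False,
        na_values=[],
    )
    for col in ("source_population_id", "replicate_group"):
        if col in table.columns:
            table[col] = table[col].replace({"": None, "NA": None, ".": None})
    return PopulationMap(table)


def write_population_map(popmap: PopulationMap, path) -> None:
    popmap.table.to_csv(path, sep="\t", index=False)


def allele_counts(dataset: GenotypeDataset, popmap: PopulationMap) -> AlleleTable:
    """Tabulate per-population allele counts for every site.

    Every individual in the dataset must appear in the population map;
    missing genotypes do not count toward ``n_typed``.
    """
    mapped = set(popmap.table["individual_id"])
    absent = [i for i in dataset.individual_ids if i not in mapped]
    if absent:
        raise ValueError(f"individuals absent from population map: {absent}")
    pops = popmap.populations
    n_pops = len(pops)
    alt = np.zeros((n_pops, dataset.n_sites), dtype=np.int64)
    typed = np.zeros_like(alt)
    het = np.zeros_like(alt)
    pop_of = popmap.population_of()
    pop_idx = {p: k for k, p in enumerate(pops)}
    rows_by_pop: dict[int, list[int]] = {}
    for i, ind in enumerate(dataset.individual_ids):
        rows_by_pop.setdefault(pop_idx[pop_of[ind]], []).append(i)
    for k, rows in rows_by_pop.items():
        block = dataset.dosage[rows]
        called = block != MISSING
        typed[k] = called.sum(axis=0)
        alt[k] = np.where(called, block, 0).sum(axis=0)
        het[k] = (block == 1).sum(axis=0)
    return AlleleTable(
        populations=pops, sites=dataset.sites, alt_copies=alt, n_typed=typed, n_het=het
    )
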