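"""Metapopulation contributions to gene and allelic diversity.

Leave-one-out percent contributions to A_S/D_A/A_T and H_S/D_G/H_T,
averaged over 50 subsamples of six individuals per population, plus the
optimal per-population contribution to a synthetic pool of 1000 individuals
under heterozygosity (H) and allele-count (k) objectives.
"""

from _common import FILTERED_POPMAP, FILTERED_VCF, RESULTS, SEED, ensure_dirs, load

from popdiv.contributions import (
    leave_one_out_contributions,
    optimal_pool_contributions,
    subsample_average,
)
from popdiv.io import allele_counts


def main() -> None:
    ensure_dirs()
    dataset, popmap = load(FILTERED_VCF, FILTERED_POPMAP)
    mean, sd = subsample_average(
        leave_one_out_contributions, dataset, popmap, n=6, reps=50, seed=SEED
    )
    mean.to_csv(RESULTS / "contributions_mean.tsv", sep="\t", index=False)
    sd.to_csv(RESULTS / "contributions_sd.tsv", sep="\t", index=False)
    cols = ["population_id", "A_S", "D_A", "A_T", "H_S", "D_G", "H_T"]
    print(mean[cols].round(2).to_string(index=False))
    best = mean.loc[mean["H_T"].idxmax(), "population_id"]
    print(f"\nlargest contribution to total gene diversity: {best}")

    table = allele_counts(dataset, popmap)
    for objective in ("H", "k"):
        pool = optimal_pool_contributions(table, objective=objective, seed=SEED)
        pool.to_csv(RESULTS / f"optimal_pool_{objective}.tsv", sep="\t", index=False)
        tops = pool.sort_values("percent", ascending=False).head(3)
        desc = ", ".join(
            f"{r.population_id} {r.percent:.0f}%" for r in tops.itertuples()
        )
        print(f"optimal pool ({objective}): {desc}")


if __name__ == "__main__":
    main()
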