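"""Shared paths and loaders for the numbered analysis drivers."""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

SIM_VCF = SCRATCH / "simulated.vcf"
SIM_POPMAP = SCRATCH / "simulated_popmap.tsv"
FILTERED_VCF = SCRATCH / "filtered.vcf"
FILTERED_POPMAP = SCRATCH / "filtered_popmap.tsv"

SEED = 20


def ensure_dirs() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)


def load(vcf_path, popmap_path):
    from popdiv.io import read_population_map, read_vcf

    if not Path(vcf_path).exists():
        raise SystemExit(
            f"{vcf_path} missing - run the earlier numbered scripts first"
        )
    dataset = read_vcf(vcf_path)
    popmap = read_population_map(popmap_path)
    dataset.replicate_pairs = popmap.replicate_pairs()
    return dataset, popmap
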