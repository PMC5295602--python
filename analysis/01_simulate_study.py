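#!/usr/bin/env python
"""Simulate the twelve-library pooled exon-capture study.

Four collection sites; two of them (pk10, thailand) contribute dual
replicate pools per sex of 12 mosquitoes each, the other two (kaolack,
mexico) dual mixed-sex replicate pools of 14 and 22 mosquitoes.
Populations diverge at Balding-Nichols theta = 0.2; sexes within a
population share the population's allele frequencies. Writes the toy
genome, GTF annotation, capture BED, twelve readcount TSVs and the
true-frequency table under scratch/study/, and a YAML run configuration
for the downstream scripts.
"""

import sys
from pathlib import Path

import yaml

from poolfst.simulate import SimulationConfig, simulate_study

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "study"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 2016


def main() -> None:
    config = SimulationConfig(seed=SEED, n_genes=120, gene_length_bp=450, theta=0.2)
    fixture = simulate_study(config, SCRATCH)
    print(f"simulated {fixture.sites.n_sites} sites "
          f"({int(fixture.sites.segregating.sum())} segregating) "
          f"across {len(fixture.reference.genes)} genes, "
          f"{len(fixture.readcounts)} libraries -> {SCRATCH}")

    # Whole-collection sets pool all of a site's libraries as replicates
    # (female + male pools where sexes were separated), mirroring the
    # 28/44/48-individual collection totals.
    lib = {k: str(v.relative_to(SCRATCH)) for k, v in fixture.readcounts.items()}
    run_cfg = {
        "collections": {
            "pk10": {
                "replicates": [lib["pk10_female_rep1"], lib["pk10_female_rep2"],
                               lib["pk10_male_rep1"], lib["pk10_male_rep2"]],
                "n_individuals_per_replicate": 12,
            },
            "thailand": {
                "replicates": [lib["thailand_female_rep1"], lib["thailand_female_rep2"],
                               lib["thailand_male_rep1"], lib["thailand_male_rep2"]],
                "n_individuals_per_replicate": 12,
            },
            "kaolack": {
                "replicates": [lib["kaolack_rep1"], lib["kaolack_rep2"]],
                "n_individuals_per_replicate": 14,
            },
            "mexico": {
                "replicates": [lib["mexico_rep1"], lib["mexico_rep2"]],
                "n_individuals_per_replicate": 22,
            },
        },
        "gtf": "annotation.gtf",
        "fasta": "genome.fasta",
        "bed": "capture.bed",
        "comparisons": [
            ["mexico", "thailand"], ["pk10", "kaolack"], ["pk10", "mexico"],
            ["pk10", "thailand"], ["kaolack", "mexico"], ["kaolack", "thailand"],
        ],
        "output_dir": str(ROOT / "scratch" / "run"),
        "seed": SEED,
    }
    with open(SCRATCH / "run.yaml", "w") as fh:
        yaml.safe_dump(run_cfg, fh, sort_keys=False)
    print(f"wrote run configuration {SCRATCH / 'run.yaml'}")


if __name__ == "__main__":
    main()
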