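"""Self-contained simulation studies built on the pipeline.

These are the package's calibration experiments: simulate pooled
libraries under a known Balding-Nichols divergence, run the full filter +
estimation cascade on the written readcount files, and measure how well
the per-gene F_ST distribution recovers the planted structure. The
analysis drivers and the acceptance checks both run them.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .distributions import bin_statistic, lod_profile
from .pipeline import CollectionConfig, ComparisonResult, RunConfig, build_collection, compare_collections
from .annotation import Annotator
from .simulate import CollectionSpec, SimulationConfig, simulate_study


def _pipeline_comparison(
    fixture, name_i: str, name_j: str, n_per_rep_i: int, n_per_rep_j: int
) -> tuple[ComparisonResult, list]:
    annotator = Annotator(fixture.gtf, fixture.fasta)
    run_cfg = RunConfig(
        collections={
            name_i: CollectionConfig(
                name_i,
                [str(fixture.readcounts[f"{name_i}_rep{r}"]) for r in (1, 2)],
                n_per_rep_i,
            ),
            name_j: CollectionConfig(
                name_j,
                [str(fixture.readcounts[f"{name_j}_rep{r}"]) for r in (1, 2)],
                n_per_rep_j,
            ),
        },
        gtf=str(fixture.gtf),
        fasta=str(fixture.fasta),
        comparisons=[(name_i, name_j)],
    )
    set_i = build_collection(run_cfg.collections[name_i], annotator, run_cfg)
    set_j = build_collection(run_cfg.collections[name_j], annotator, run_cfg)
    comp = compare_collections(set_i, set_j, annotator)
    tallies = set_i.tallies + set_j.tallies
    return comp, tallies


@dataclass
class ThetaRecovery:
    theta: float
    median_gene_fst: float
    mean_gene_fst: float
    n_genes: int
    n_snps: int
    concordance_pass_rate: float


def theta_recovery_study(
    seed: int,
    thetas: tuple[float, ...] = (0.05, 0.1, 0.2, 0.4),
    n_genes: int = 60,
    gene_length_bp: int = 300,
    n_individuals_per_replicate: int = 12,
    coverage_mean: float = 100.0,
    error_rate: float = 0.001,
    polymorphic_fraction: float = 0.08,
    workdir: Path | str | None = None,
) -> list[ThetaRecovery]:
    """Two populations, dual 12-mosquito replicate pools each (24
    mosquitoes per collection pool), simulated at each divergence theta
    and pushed through the full pipeline from the written readcount
    files. Returns the per-theta median/mean per-gene F_ST.

    The genome-wide median per-gene F_ST should be a monotone increasing
    function of theta and land near theta itself.
    """
    results = []
    base = Path(workdir) if workdir is not None else None
    for k, theta in enumerate(thetas):
        cfg = SimulationConfig(
            seed=seed + 1000 * k,
            n_genes=n_genes,
            gene_length_bp=gene_length_bp,
            theta=theta,
            collections=(
                CollectionSpec("popA", n_individuals_per_replicate, 2),
                CollectionSpec("popB", n_individuals_per_replicate, 2),
            ),
            coverage_mean=coverage_mean,
            error_rate=error_rate,
            polymorphic_fraction=polymorphic_fraction,
        )
        with tempfile.TemporaryDirectory() as tmp:
            outdir = (base / f"theta_{theta:g}") if base is not None else Path(tmp)
            fixture = simulate_study(cfg, outdir)
            comp, tallies = _pipeline_comparison(fixture, "popA", "popB", n_individuals_per_replicate, n_individuals_per_replicate)
        inter = [t for t in tallies if t.stage.startswith("intersect")]
        tested = sum(t.n_in - t.n_discarded_empty for t in inter)
        passed = sum(t.n_retained for t in inter)
        results.append(
            ThetaRecovery(
                theta=theta,
                median_gene_fst=float(comp.gene_df["fst"].median()),
                mean_gene_fst=float(comp.gene_df["fst"].mean()),
                n_genes=len(comp.gene_df),
                n_snps=len(comp.snp_df),
                concordance_pass_rate=passed / tested if tested else float("nan"),
            )
        )
    return results


@dataclass
class SexDivergenceStudy:
    gene_df: pd.DataFrame  # per-gene F_ST with chromosome assignment
    snp_df: pd.DataFrame
    lod_all_chromosomes: pd.DataFrame  # 3 x 2 heterogeneity test per bin
    lod_null_chromosomes: pd.DataFrame  # chromosome 2 vs 3 only
    median_fst_by_chromosome: dict[str, float]
    max_lod_all: float
    max_lod_null: float


def sex_divergence_study(
    seed: int,
    sex_theta_chr1: float = 0.3,
    n_genes: int = 600,
    gene_length_bp: int = 150,
    coverage_mean: float = 100.0,
    polymorphic_fraction: float = 0.05,
    workdir: Path | str | None = None,
) -> SexDivergenceStudy:
    """Female and male pools of one population with divergence planted on
    chromosome 1 only (theta_1 = 0.3, theta_2 = theta_3 = 0).

    The chromosome-1 per-gene F_ST distribution should shift right with
    per-0.01-bin heterogeneity LOD > 3 against chromosomes 2-3, while the
    chromosome-2 vs chromosome-3 comparison stays below the cutoff.
    """
    cfg = SimulationConfig(
        seed=seed,
        n_genes=n_genes,
        gene_length_bp=gene_length_bp,
        theta=0.0,
        collections=(
            CollectionSpec("females", 12, 2, "female", population="colony"),
            CollectionSpec("males", 12, 2, "male", population="colony"),
        ),
        coverage_mean=coverage_mean,
        polymorphic_fraction=polymorphic_fraction,
        sex_theta_by_chromosome={"1": sex_theta_chr1},
        chromosome_cycle=("1", "2", "3"),
    )
    with tempfile.TemporaryDirectory() as tmp:
        outdir = Path(workdir) if workdir is not None else Path(tmp)
        fixture = simulate_study(cfg, outdir)
        comp, _ = _pipeline_comparison(fixture, "females", "males", 12, 12)

    gene = comp.gene_df
    by_chrom = {str(c): g["fst"].to_numpy() for c, g in gene.groupby("chromosome")}
    hists = [bin_statistic(by_chrom[c], "fst", label=f"chr{c}") for c in ("1", "2", "3")]
    lod_all = lod_profile(hists)
    lod_null = lod_profile([h for h in hists if h.label in ("chr2", "chr3")])
    return SexDivergenceStudy(
        gene_df=gene,
        snp_df=comp.snp_df,
        lod_all_chromosomes=lod_all,
        lod_null_chromosomes=lod_null,
        median_fst_by_chromosome={c: float(np.median(v)) for c, v in by_chrom.items()},
        max_lod_all=float(lod_all["lod"].max()),
        max_lod_null=float(lod_null["lod"].max()),
    )
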