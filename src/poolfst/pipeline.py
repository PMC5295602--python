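"""End-to-end orchestration: configuration, the filter cascade, pairwise
comparisons, and Table-1/2/3-style report frames.

Stages per collection: read each replicate's readcount TSV, trim (< 15
reads removed, > 2000 treated as repetitive), intersect replicates with
the heterogeneity chi-square concordance filter, and sum replicate
counts. Stages per comparison: intersect the two collections' SNP sets,
pick the alternate allele (second most common pooled allele), annotate
each SNP (gene region, codon position, mutation type, consequence), and
compute per-SNP a_s/b_s/F_ST plus per-gene ratio-of-sums F_ST and mean
H_exp. All randomness lives in the simulator; this path is deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import popgen
from .annotation import Annotator, GeneModel, classify_mutation
from .distributions import (
    bin_statistic,
    cooccurrence_tally,
    distribution_summary,
    extract_tails,
    lod_profile,
)
from .readcounts import (
    _TABLE_COLS,
    DEFAULT_ALPHA,
    MAX_COVERAGE,
    MIN_COVERAGE,
    FilterTally,
    LibraryTable,
    intersect_collections_table,
    intersect_replicates_table,
    read_readcounts_table,
    trim_table,
)

log = logging.getLogger(__name__)

_NUC_COLS = ["A", "C", "G", "T"]


@dataclass
class CollectionConfig:
    name: str
    replicates: list[str]  # readcount TSV paths
    n_individuals_per_replicate: int
    sex: str = "mixed"

    @property
    def n_individuals_total(self) -> int:
        return self.n_individuals_per_replicate * len(self.replicates)


@dataclass
class RunConfig:
    """A run: collections, annotation inputs, thresholds, comparisons."""

    collections: dict[str, CollectionConfig]
    gtf: str
    fasta: str
    comparisons: list[tuple[str, str]]
    bed: str | None = None
    min_cov: int = MIN_COVERAGE
    max_cov: int = MAX_COVERAGE
    alpha: float = DEFAULT_ALPHA
    cap_policy: str = "exclude"
    output_dir: str = "poolfst_out"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.min_cov < self.max_cov):
            raise ValueError("need 0 < min_cov < max_cov")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        for a, b in self.comparisons:
            for name in (a, b):
                if name not in self.collections:
                    raise ValueError(f"comparison references undefined collection {name!r}")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        colls = {}
        for name, c in raw["collections"].items():
            colls[name] = CollectionConfig(
                name=name,
                replicates=[str((base / p)) for p in c["replicates"]],
                n_individuals_per_replicate=int(c["n_individuals_per_replicate"]),
                sex=c.get("sex", "mixed"),
            )
        return cls(
            collections=colls,
            gtf=str(base / raw["gtf"]),
            fasta=str(base / raw["fasta"]),
            bed=str(base / raw["bed"]) if raw.get("bed") else None,
            comparisons=[tuple(pair) for pair in raw["comparisons"]],
            min_cov=int(raw.get("min_cov", MIN_COVERAGE)),
            max_cov=int(raw.get("max_cov", MAX_COVERAGE)),
            alpha=float(raw.get("alpha", DEFAULT_ALPHA)),
            cap_policy=raw.get("cap_policy", "exclude"),
            output_dir=str(raw.get("output_dir", "poolfst_out")),
            seed=raw.get("seed"),
        )


@dataclass
class CollectionSet:
    """A collection's replicate-intersected, concordance-filtered SNP set
    with replicate-summed counts, SNPIDs and gene assignments attached."""

    name: str
    n_individuals: int
    sex: str
    table: pd.DataFrame  # summed counts + snpid, gene_id, chromosome
    replicate_tables: list[pd.DataFrame]
    tallies: list[FilterTally] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.table)

    def polymorphism_tally(self) -> dict:
        """Table-1-style row: counts of sites by number of segregating
        nucleotides/indels (nid) and the percent polymorphic."""
        counts = self.table[_TABLE_COLS].to_numpy()
        nid = (counts > 0).sum(axis=1)
        total = len(nid)
        mono = int((nid == 1).sum())
        by_nid = {int(k): int(v) for k, v in zip(*np.unique(nid, return_counts=True))}
        return {
            "collection": self.name,
            "monomorphic": mono,
            **{f"nid_{m}": by_nid.get(m, 0) for m in range(2, 7)},
            "total": total,
            "percent_polymorphic": popgen.percent_polymorphic(mono, total) if total else float("nan"),
        }


def _assign_gene_windows(df: pd.DataFrame, annotator: Annotator) -> pd.DataFrame:
    """Attach snpid / gene_id / chromosome to a site table; sites outside
    every gene window are untracked and dropped; sites in two genes'
    windows are duplicated, once per gene."""
    pieces = []
    pos0 = df["position"].to_numpy() - 1
    contigs = df["contig"].to_numpy()
    order = np.lexsort((pos0, contigs))
    sorted_contig = contigs[order]
    sorted_pos = pos0[order]
    bounds: dict[str, tuple[int, int]] = {}
    uniq, starts = np.unique(sorted_contig, return_index=True)
    starts = list(starts) + [len(sorted_contig)]
    for i, ctg in enumerate(uniq):
        bounds[ctg] = (starts[i], starts[i + 1])
    for model in annotator.models:
        if model.contig not in bounds:
            continue
        lo, hi = bounds[model.contig]
        w0, w1 = model.window
        left = lo + np.searchsorted(sorted_pos[lo:hi], w0, side="left")
        right = lo + np.searchsorted(sorted_pos[lo:hi], w1, side="left")
        if right <= left:
            continue
        idx = order[left:right]
        sub = df.iloc[idx].copy()
        sub["snpid"] = (
            annotator.index._rank[model.transcript_id] + 1
        ) * 10**6 + (sorted_pos[left:right] - w0)
        sub["gene_id"] = model.gene_id
        sub["chromosome"] = model.chromosome
        pieces.append(sub)
    if not pieces:
        out = df.iloc[0:0].copy()
        out["snpid"] = pd.Series(dtype=np.int64)
        out["gene_id"] = pd.Series(dtype=object)
        out["chromosome"] = pd.Series(dtype=object)
        return out
    return pd.concat(pieces, ignore_index=True).sort_values("snpid", kind="mergesort").reset_index(drop=True)


def build_collection(cfg: CollectionConfig, annotator: Annotator, run: RunConfig) -> CollectionSet:
    tallies: list[FilterTally] = []
    trimmed: list[LibraryTable] = []
    for path in cfg.replicates:
        lib = read_readcounts_table(path)
        t = trim_table(lib, run.min_cov, run.max_cov, run.cap_policy)
        tallies.append(FilterTally(f"trim[{Path(path).name}]", n_in=lib.n_sites, n_retained=t.n_sites))
        trimmed.append(t)
    summed, aligned, tally = intersect_replicates_table(trimmed, alpha=run.alpha)
    tally.stage = f"intersect_replicates[{cfg.name}]"
    tallies.append(tally)
    table = _assign_gene_windows(summed.df, annotator)
    reps = [a.df for a in aligned]  # replicate rows kept for contingency output
    for t in tallies:
        t.log()
    return CollectionSet(
        name=cfg.name,
        n_individuals=cfg.n_individuals_total,
        sex=cfg.sex,
        table=table,
        replicate_tables=reps,
        tallies=tallies,
    )


def collection_gene_hexp(cset: CollectionSet) -> pd.Series:
    """Per-gene mean expected heterozygosity of one collection over its
    own retained sites. The tracked frequency is the reference allele
    over reference + alternate coverage, the alternate being the
    collection's own second most common allele; monomorphic sites
    contribute alpha = 0 to the gene mean."""
    counts = cset.table[_TABLE_COLS].to_numpy()
    col_index = {c: k for k, c in enumerate(_TABLE_COLS)}
    ref_cols = np.array([col_index.get(r, 0) for r in cset.table["ref"]])
    rows = np.arange(len(counts))
    masked = counts.copy()
    masked[rows, ref_cols] = -1
    alt_cols = np.argmax(masked, axis=1)
    ref_n = counts[rows, ref_cols].astype(float)
    alt_n = counts[rows, alt_cols].astype(float)
    tot = ref_n + alt_n
    p = np.where(tot > 0, ref_n / np.maximum(tot, 1.0), np.nan)
    alpha = 2.0 * p * (1.0 - p)
    df = pd.DataFrame({"gene_id": cset.table["gene_id"], "alpha": alpha}).dropna()
    return df.groupby("gene_id")["alpha"].mean().rename("hexp")


# ---------------------------------------------------------------------------
# Pairwise comparison


@dataclass
class ComparisonResult:
    name: str
    collection_i: str
    collection_j: str
    snp_df: pd.DataFrame  # per-SNP statistics (polymorphic sites)
    gene_df: pd.DataFrame  # per-gene fst + hexp per collection
    n_common_sites: int
    sites_per_gene: pd.Series

    def summary(self):
        return distribution_summary(
            self.gene_df["fst"].to_numpy(), "fst", n_snps=int(self.snp_df.shape[0])
        )


def _alt_columns(counts_i: np.ndarray, counts_j: np.ndarray, ref_cols: np.ndarray) -> np.ndarray:
    """Column index of the alternate allele: the most common pooled
    non-reference allele (= second most common overall when the reference
    is major); ties resolved to the lower column index, i.e. the
    lexicographically smallest of A,C,G,T then insertion then deletion."""
    pooled = (counts_i + counts_j).astype(np.int64)
    masked = pooled.copy()
    masked[np.arange(len(masked)), ref_cols] = -1
    return np.argmax(masked, axis=1)


def compare_collections(
    set_i: CollectionSet, set_j: CollectionSet, annotator: Annotator, name: str | None = None
) -> ComparisonResult:
    """All per-SNP and per-gene statistics for one pair of collections."""
    merged = set_i.table.merge(
        set_j.table[["snpid"] + _TABLE_COLS],
        on="snpid",
        how="inner",
        suffixes=("_i", "_j"),
    )
    ci = merged[[f"{c}_i" for c in _TABLE_COLS]].to_numpy()
    cj = merged[[f"{c}_j" for c in _TABLE_COLS]].to_numpy()
    n_common = len(merged)
    sites_per_gene = merged.groupby("gene_id").size()

    col_index = {c: k for k, c in enumerate(_TABLE_COLS)}
    ref_cols = np.array([col_index.get(r, 0) for r in merged["ref"]])
    alt_cols = _alt_columns(ci, cj, ref_cols)

    rows = np.arange(n_common)
    ref_i, ref_j = ci[rows, ref_cols], cj[rows, ref_cols]
    alt_i, alt_j = ci[rows, alt_cols], cj[rows, alt_cols]
    polymorphic = (alt_i + alt_j) > 0

    snp = merged.loc[polymorphic, ["snpid", "contig", "position", "ref", "gene_id", "chromosome"]].copy()
    ref_i, ref_j = ref_i[polymorphic], ref_j[polymorphic]
    alt_i, alt_j = alt_i[polymorphic], alt_j[polymorphic]
    alt_cols_p = alt_cols[polymorphic]

    # Bi-allelic reduction: p = reference-allele frequency among
    # reference + alternate coverage; other alleles stay in nid only.
    tot_i, tot_j = ref_i + alt_i, ref_j + alt_j
    usable = (tot_i > 0) & (tot_j > 0)
    p_i = np.where(tot_i > 0, ref_i / np.maximum(tot_i, 1), np.nan)
    p_j = np.where(tot_j > 0, ref_j / np.maximum(tot_j, 1), np.nan)
    p_bar = np.where(usable, (ref_i + ref_j) / np.maximum(tot_i + tot_j, 1), np.nan)

    a, b, fst, alpha_i, alpha_j = popgen.site_fst_arrays(
        p_i, p_j, p_bar, set_i.n_individuals, set_j.n_individuals
    )
    a[~usable] = np.nan
    b[~usable] = np.nan
    fst[~usable] = np.nan

    indel_token_i = merged.loc[polymorphic, "indel_token"].to_numpy()
    alt_alleles, mutation_types, regions, consequences = _annotate_rows(
        snp, alt_cols_p, indel_token_i, annotator
    )
    snp["alt"] = alt_alleles
    snp["mutation_type"] = mutation_types
    snp["region"] = regions
    snp["consequence"] = consequences
    snp["p_i"], snp["p_j"], snp["p_bar"] = p_i, p_j, p_bar
    snp["a"], snp["b"], snp["fst"] = a, b, fst
    snp["alpha_i"], snp["alpha_j"] = alpha_i, alpha_j
    counts_pooled = (ci + cj)[polymorphic]
    snp["nid"] = (counts_pooled > 0).sum(axis=1)

    gene = popgen.gene_fst(snp.dropna(subset=["a", "b"]))
    hex_i = popgen.gene_hexp(
        snp.rename(columns={"alpha_i": "alpha"}), sites_per_gene, alpha_col="alpha"
    )
    hex_j = popgen.gene_hexp(
        snp.rename(columns={"alpha_j": "alpha"}), sites_per_gene, alpha_col="alpha"
    )
    gene = gene.set_index("gene_id")
    gene["hexp_i"] = hex_i
    gene["hexp_j"] = hex_j
    chrom = (
        merged.loc[:, ["gene_id", "chromosome"]].drop_duplicates("gene_id").set_index("gene_id")
    )
    gene["chromosome"] = chrom["chromosome"]
    gene = gene.reset_index()

    label = name or f"{set_i.name}_vs_{set_j.name}"
    return ComparisonResult(
        name=label,
        collection_i=set_i.name,
        collection_j=set_j.name,
        snp_df=snp.reset_index(drop=True),
        gene_df=gene,
        n_common_sites=n_common,
        sites_per_gene=sites_per_gene,
    )


def _annotate_rows(
    snp: pd.DataFrame,
    alt_cols: np.ndarray,
    indel_tokens: np.ndarray,
    annotator: Annotator,
) -> tuple[list, list, list, list]:
    models: dict[str, GeneModel] = {m.gene_id: m for m in annotator.models}
    alt_alleles: list[str] = []
    mutation_types: list[str] = []
    regions: list[str] = []
    consequences: list[str] = []
    for row, acol in zip(snp.itertuples(index=False), alt_cols):
        if acol < 4:
            alt = _NUC_COLS[acol]
        elif acol == 4:
            alt = indel_tokens[len(alt_alleles)] or "+N"
            if not alt.startswith("+"):
                alt = "+N"
        else:
            alt = indel_tokens[len(alt_alleles)] or "-N"
            if not alt.startswith("-"):
                alt = "-N"
        model = models.get(row.gene_id)
        if model is None or row.ref == alt:
            alt_alleles.append(alt)
            mutation_types.append("")
            regions.append("")
            consequences.append("not_applicable")
            continue
        ann = model.annotate_site(int(row.position) - 1, row.ref, alt, annotator.genome)
        alt_alleles.append(alt)
        mutation_types.append(ann.mutation_type)
        regions.append(ann.region)
        consequences.append(ann.consequence)
    return alt_alleles, mutation_types, regions, consequences


# ---------------------------------------------------------------------------
# Report tables


def table1_style(sets: Sequence[CollectionSet]) -> pd.DataFrame:
    """Per-collection polymorphism tallies (monomorphic sites, counts by
    number of segregating alleles, percent polymorphic)."""
    return pd.DataFrame([s.polymorphism_tally() for s in sets])


def table2_style(comparisons: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Gene-wise H_exp comparisons: for each pair, counts of genes where
    collection 1 exceeds collection 2, whole-percent share, mean
    difference, and the paired t-test."""
    rows = []
    for comp in comparisons:
        g = comp.gene_df.set_index("gene_id")
        res = popgen.genewise_comparison(g["hexp_i"], g["hexp_j"])
        rows.append(
            {
                "comparison": f"(1) {comp.collection_i} vs (2) {comp.collection_j}",
                "n_genes": res.n_genes,
                "n_hexp1_gt_hexp2": res.n_greater,
                "n_hexp1_lt_hexp2": res.n_lesser,
                "percent_greater": res.percent_greater,
                "mean_difference": res.mean_difference,
                "t": res.t,
                "df": res.df,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)


def table3_style(comparisons: Sequence[ComparisonResult]) -> pd.DataFrame:
    """F_ST distribution summaries per comparison (gene and SNP counts,
    mean, median, modal bin midpoint, SD, 5% and 95% cutoffs)."""
    rows = []
    for comp in comparisons:
        s = comp.summary()
        rows.append(
            {
                "comparison": comp.name,
                "n_genes": s.n_genes,
                "n_snps": s.n_snps,
                "mean": s.mean,
                "median": s.median,
                "mode": s.mode,
                "sd": s.sd,
                "low5": s.low5,
                "high95": s.high95,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full run


@dataclass
class RunResult:
    config: RunConfig
    sets: dict[str, CollectionSet]
    comparisons: list[ComparisonResult]
    outdir: Path


def run(config: RunConfig, outdir: Path | str | None = None) -> RunResult:
    """Execute the full pipeline and write the output bundle: per-site and
    per-gene TSVs per comparison, Table-1/2/3-style summaries, histogram
    and LOD tables, 1% tail gene lists, and a machine-readable manifest.
    Identical inputs produce byte-identical outputs."""
    outdir = Path(outdir if outdir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotator = Annotator(config.gtf, config.fasta)

    needed = sorted({n for pair in config.comparisons for n in pair})
    sets = {name: build_collection(config.collections[name], annotator, config) for name in needed}

    comparisons = []
    for a, b in config.comparisons:
        comp = compare_collections(sets[a], sets[b], annotator)
        if comp.gene_df.empty:
            log.warning("comparison %s: empty SNP intersection; zero-gene summaries emitted", comp.name)
        comparisons.append(comp)
        comp.snp_df.to_csv(outdir / f"{comp.name}.sites.tsv", sep="\t", index=False, float_format="%.6g")
        comp.gene_df.to_csv(outdir / f"{comp.name}.genes.tsv", sep="\t", index=False, float_format="%.6g")

    table1_style(list(sets.values())).to_csv(outdir / "table1_polymorphism.tsv", sep="\t", index=False)
    table2_style(comparisons).to_csv(
        outdir / "table2_hexp_genewise.tsv", sep="\t", index=False, float_format="%.6g"
    )
    nonempty = [c for c in comparisons if len(c.gene_df)]
    table3_style(nonempty).to_csv(
        outdir / "table3_fst_summaries.tsv", sep="\t", index=False, float_format="%.6g"
    )

    if len(nonempty) >= 2:
        hists = [bin_statistic(c.gene_df["fst"].to_numpy(), "fst", label=c.name) for c in nonempty]
        lod_profile(hists).to_csv(outdir / "fst_lod_profile.tsv", sep="\t", index=False, float_format="%.6g")

    tails = []
    for comp in nonempty:
        vals = comp.gene_df.set_index("gene_id")["fst"]
        for direction in ("lower", "upper"):
            t = extract_tails(vals, comp.name, direction)
            tails.append(t)
            pd.Series(t.genes, name="gene_id").to_csv(
                outdir / f"{comp.name}.tail_{direction}.tsv", sep="\t", index=False
            )
    for direction in ("lower", "upper"):
        sets_dir = [t for t in tails if t.direction == direction and len(t)]
        if len(sets_dir) >= 2:
            tally = cooccurrence_tally(sets_dir)
            with open(outdir / f"tail_{direction}_cooccurrence.json", "w") as fh:
                json.dump(dataclasses.asdict(tally), fh, indent=2, sort_keys=True)
                fh.write("\n")

    manifest = {
        "collections": {
            name: {
                "n_sites": s.n_sites,
                "n_individuals": s.n_individuals,
                "tallies": [dataclasses.asdict(t) for t in s.tallies],
            }
            for name, s in sets.items()
        },
        "comparisons": [
            {"name": c.name, "n_common_sites": c.n_common_sites, "n_snps": len(c.snp_df), "n_genes": len(c.gene_df)}
            for c in comparisons
        ],
        "thresholds": {
            "min_cov": config.min_cov,
            "max_cov": config.max_cov,
            "alpha": config.alpha,
            "cap_policy": config.cap_policy,
        },
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return RunResult(config=config, sets=sets, comparisons=comparisons, outdir=outdir)
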