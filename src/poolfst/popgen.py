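"""Expected heterozygosity, percent polymorphism, and the per-SNP /
per-gene F_ST estimator for pooled allele-frequency data.

The estimator decomposes variance at SNP *s* between collections *i* and
*j* into a between-collection component a_s and a within-collection
component b_s::

    alpha(i,s) = 2 p_i (1 - p_i)            (expected heterozygosity)
    b_s = [n_i alpha(i,s) + n_j alpha(j,s)] / (n_i + n_j - 1)
    a_s = [4 n_i (p_i - pbar)^2 + 4 n_j (p_j - pbar)^2 - b_s]
          / (2 [2 n_i n_j / (n_i + n_j)])
    F_ST(s) = a_s / (a_s + b_s)

where p_i is the coverage of the tracked (reference) allele divided by
total tracked coverage in collection *i*, pbar is the pooled
coverage-weighted frequency over both collections, and n_i, n_j are the
numbers of mosquitoes pooled. A gene with m SNPs gets the ratio of sums
F_ST(g) = sum(a_s) / sum(a_s + b_s), never the mean of per-SNP ratios.

At a fixed difference (p_i=1, p_j=0) b_s = 0 and F_ST = 1; at identical
intermediate frequencies a_s < 0 and F_ST <= 0, which is why the
histograms downstream start at -0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "hexp",
    "percent_polymorphic",
    "SiteFrequencies",
    "SiteFst",
    "site_fst",
    "site_fst_arrays",
    "gene_fst",
    "gene_hexp",
    "GenewiseComparison",
    "genewise_comparison",
    "sexwise_fst",
    "stratified_fst_means",
]


def hexp(p: float | np.ndarray) -> float | np.ndarray:
    """Expected heterozygosity alpha = 2 p (1 - p) of a tracked-allele
    frequency; maximal (0.5) at p = 0.5, zero at fixation."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    out = 2.0 * p * (1.0 - p)
    return float(out) if out.ndim == 0 else out


def percent_polymorphic(monomorphic: int, total: int) -> float:
    """Percentage of analyzed sites that are polymorphic,
    100 x [1 - (monomorphic / total)], reported to two decimals."""
    if not (0 <= monomorphic <= total) or total == 0:
        raise ValueError("need 0 <= monomorphic <= total with total > 0")
    return round(100.0 * (1.0 - monomorphic / total), 2)


@dataclass(frozen=True)
class SiteFrequencies:
    """Tracked-allele frequencies of one SNP in two collections.

    ``p_bar`` is pooled coverage-weighted; pass it explicitly when built
    from read counts, otherwise it defaults to the coverage-agnostic
    midpoint implied by equal coverage.
    """

    p_i: float
    p_j: float
    n_i: int
    n_j: int
    p_bar: float | None = None

    def __post_init__(self) -> None:
        for p in (self.p_i, self.p_j):
            if not (0.0 <= p <= 1.0):
                raise ValueError("frequencies must lie in [0, 1]")
        if self.n_i + self.n_j <= 1:
            raise ValueError("need n_i + n_j > 1 mosquitoes")

    @property
    def pbar(self) -> float:
        if self.p_bar is not None:
            return self.p_bar
        return 0.5 * (self.p_i + self.p_j)


@dataclass(frozen=True)
class SiteFst:
    a: float
    b: float
    fst: float | None  # None where a + b == 0 (undefined)
    alpha_i: float
    alpha_j: float


def site_fst(freqs: SiteFrequencies) -> SiteFst:
    a, b, fst, ai, aj = site_fst_arrays(
        np.array([freqs.p_i]),
        np.array([freqs.p_j]),
        np.array([freqs.pbar]),
        freqs.n_i,
        freqs.n_j,
    )
    f = None if np.isnan(fst[0]) else float(fst[0])
    return SiteFst(float(a[0]), float(b[0]), f, float(ai[0]), float(aj[0]))


def site_fst_arrays(
    p_i: np.ndarray,
    p_j: np.ndarray,
    p_bar: np.ndarray,
    n_i: float | np.ndarray,
    n_j: float | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized a_s, b_s, F_ST and per-collection alpha; F_ST is NaN
    where a_s + b_s = 0 (such sites are excluded from gene sums)."""
    p_i = np.asarray(p_i, dtype=float)
    p_j = np.asarray(p_j, dtype=float)
    p_bar = np.asarray(p_bar, dtype=float)
    alpha_i = 2.0 * p_i * (1.0 - p_i)
    alpha_j = 2.0 * p_j * (1.0 - p_j)
    b = (n_i * alpha_i + n_j * alpha_j) / (n_i + n_j - 1.0)
    nh = 2.0 * n_i * n_j / (n_i + n_j)  # harmonic-mean sample size term
    a = (4.0 * n_i * (p_i - p_bar) ** 2 + 4.0 * n_j * (p_j - p_bar) ** 2 - b) / (2.0 * nh)
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(denom != 0.0, a / np.where(denom != 0.0, denom, 1.0), np.nan)
    return a, b, fst, alpha_i, alpha_j


def gene_fst(site_df: pd.DataFrame, gene_col: str = "gene_id") -> pd.DataFrame:
    """Ratio-of-sums gene F_ST over a per-site frame with columns
    ``gene_id``, ``a``, ``b`` (sites with a + b = 0 are dropped first).

    Returns a frame with gene_id, m (SNPs used), sum_a, sum_ab, fst.
    """
    valid = site_df[(site_df["a"] + site_df["b"]) != 0.0]
    tmp = valid[[gene_col, "a"]].copy()
    tmp["ab"] = valid["a"].to_numpy() + valid["b"].to_numpy()
    out = tmp.groupby(gene_col, sort=True).agg(
        m=("a", "size"), sum_a=("a", "sum"), sum_ab=("ab", "sum")
    )
    out["fst"] = out["sum_a"] / out["sum_ab"]
    return out.reset_index()


def gene_hexp(
    alpha_by_site: pd.DataFrame,
    sites_per_gene: pd.Series | None = None,
    alpha_col: str = "alpha",
    gene_col: str = "gene_id",
    polymorphic_only: bool = False,
) -> pd.Series:
    """Mean expected heterozygosity per gene.

    By default the mean runs over ALL retained sites of the gene
    (monomorphic sites contribute alpha = 0 through ``sites_per_gene``,
    the per-gene retained-site totals); with ``polymorphic_only`` the
    denominator is the polymorphic sites present in ``alpha_by_site``.
    """
    sums = alpha_by_site.groupby(gene_col)[alpha_col].sum()
    if polymorphic_only or sites_per_gene is None:
        denom = alpha_by_site.groupby(gene_col)[alpha_col].size()
        return (sums / denom).rename("hexp")
    out = sums.reindex(sites_per_gene.index, fill_value=0.0) / sites_per_gene
    return out.rename("hexp")


@dataclass(frozen=True)
class GenewiseComparison:
    n_genes: int
    n_greater: int
    n_lesser: int
    percent_greater: int  # whole percent, Table-2 style
    mean_difference: float
    t: float
    df: int
    p: float


def genewise_comparison(x: pd.Series, y: pd.Series) -> GenewiseComparison:
    """Paired gene-wise comparison of two per-gene statistics over their
    shared genes: counts of genes where x > y and x < y, the whole-percent
    share, the mean difference, and a two-sided paired t-test with
    (shared genes - 1) degrees of freedom."""
    common = x.index.intersection(y.index)
    if len(common) < 2:
        raise ValueError("need >= 2 shared genes")
    xv = x.loc[common].to_numpy(dtype=float)
    yv = y.loc[common].to_numpy(dtype=float)
    d = xv - yv
    n = len(d)
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        t_stat = 0.0 if mean_d == 0.0 else np.inf * np.sign(mean_d)
        p = 1.0 if mean_d == 0.0 else 0.0
    else:
        t_stat = mean_d / (sd / np.sqrt(n))
        p = float(2.0 * stats.t.sf(abs(t_stat), n - 1))
    n_gt = int((d > 0).sum())
    n_lt = int((d < 0).sum())
    return GenewiseComparison(
        n_genes=n,
        n_greater=n_gt,
        n_lesser=n_lt,
        percent_greater=round(100.0 * n_gt / n),
        mean_difference=mean_d,
        t=float(t_stat),
        df=n - 1,
        p=p,
    )


def sexwise_fst(gene_df: pd.DataFrame, chromosome_col: str = "chromosome") -> dict[str, pd.DataFrame]:
    """Split a per-gene female-vs-male F_ST frame by chromosome
    assignment. The frame comes from running the standard two-collection
    comparison with i = female pool and j = male pool; this helper only
    stratifies it for chromosome-level maps and distribution tests."""
    if chromosome_col not in gene_df:
        raise ValueError(f"gene frame lacks a {chromosome_col!r} column")
    return {str(ch): sub.reset_index(drop=True) for ch, sub in gene_df.groupby(chromosome_col)}


def stratified_fst_means(snp_df: pd.DataFrame, stratum: str, by_chromosome: bool = True) -> pd.DataFrame:
    """Mean per-SNP F_ST within each stratum (gene region, mutation type
    or coding consequence), optionally crossed with chromosome. Strata
    with no sites are absent from the output, not reported as zero."""
    if stratum not in snp_df:
        raise ValueError(f"unknown stratum column {stratum!r}")
    df = snp_df.dropna(subset=["fst", stratum])
    keys = [stratum, "chromosome"] if by_chromosome else [stratum]
    out = df.groupby(keys, sort=True)["fst"].agg(mean_fst="mean", n_snps="size")
    return out.reset_index()
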