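"""Histogramming, heterogeneity chi-square LOD profiles, 1% tails and
cross-collection co-occurrence tallies for per-gene statistics.

Distributions of per-gene F_ST are binned at width 0.01 from -0.05 to 1.0
(F_ST estimates can be slightly negative); H_exp from 0 to 1.0. Two or
more distributions are compared bin by bin: each 0.01 bin yields a k x 2
table (genes in the bin vs genes elsewhere) tested with a Pearson
heterogeneity chi-square on k - 1 degrees of freedom, summarized as
LOD = -log10(p); LOD = 3 serves as a stringent cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

BIN_WIDTH = 0.01
FST_RANGE = (-0.05, 1.0)
HEXP_RANGE = (0.0, 1.0)
LOD_CUTOFF = 3.0
#: p-values are floored here before taking -log10, bounding reportable LOD.
_MIN_P = 1e-300


def bin_edges(kind: str) -> np.ndarray:
    lo, hi = FST_RANGE if kind == "fst" else HEXP_RANGE if kind == "hexp" else (None, None)
    if lo is None:
        raise ValueError("kind must be 'fst' or 'hexp'")
    n = int(round((hi - lo) / BIN_WIDTH))
    return np.round(lo + BIN_WIDTH * np.arange(n + 1), 10)


@dataclass
class Histogram:
    """Per-gene statistic histogram: left-closed right-open 0.01 bins."""

    kind: str  # 'fst' | 'hexp'
    edges: np.ndarray
    counts: np.ndarray
    total: int
    label: str = ""

    @property
    def midpoints(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_left": self.edges[:-1], "bin_mid": self.midpoints, "count": self.counts}
        )


def bin_statistic(values: Sequence[float] | np.ndarray, kind: str, label: str = "") -> Histogram:
    """Bin per-gene values; out-of-range values are clamped into the end
    bins with a warning so the total is conserved."""
    edges = bin_edges(kind)
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    lo, hi = edges[0], edges[-1]
    n_out = int(((v < lo) | (v >= hi)).sum())
    if n_out:
        warnings.warn(f"{n_out} values outside [{lo}, {hi}) clamped into end bins")
        v = np.clip(v, lo, np.nextafter(hi, -np.inf))
    # np.histogram closes the last bin on the right; after clamping to
    # just-below hi every value falls in a left-closed right-open bin.
    counts, _ = np.histogram(v, bins=edges)
    return Histogram(kind=kind, edges=edges, counts=counts.astype(int), total=int(len(v)), label=label)


def _pearson_k_by_2(in_bin: np.ndarray, totals: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square of a k x 2 (in-bin / out-of-bin) table with
    df = k - 1; returns (chi2, df, p)."""
    table = np.stack([in_bin, totals - in_bin], axis=1).astype(float)
    col = table.sum(axis=0)
    df = len(in_bin) - 1
    if col[0] == 0 or col[1] == 0 or totals.sum() == 0:
        return 0.0, df, 1.0
    expected = np.outer(totals, col) / totals.sum()
    chi2 = float(((table - expected) ** 2 / expected).sum())
    p = float(chi2_dist.sf(chi2, df))
    return chi2, df, p


def lod_profile(histograms: Sequence[Histogram]) -> pd.DataFrame:
    """Per-bin heterogeneity chi-square across k >= 2 histograms.

    Returns a frame with bin_left, bin_mid, per-histogram counts, chi2,
    df, p, lod and a ``crosses_cutoff`` flag at LOD = 3. Bins empty in
    every distribution get LOD = 0 by convention.
    """
    if len(histograms) < 2:
        raise ValueError("need >= 2 histograms")
    edges = histograms[0].edges
    for h in histograms[1:]:
        if h.kind != histograms[0].kind or not np.array_equal(h.edges, edges):
            raise ValueError("histograms must share kind and bin edges")
    totals = np.array([h.total for h in histograms])
    counts = np.stack([h.counts for h in histograms])  # (k, B)

    rows = []
    for b in range(counts.shape[1]):
        chi2, df, p = _pearson_k_by_2(counts[:, b], totals)
        lod = -np.log10(max(p, _MIN_P)) if p < 1.0 else 0.0
        rows.append((edges[b], chi2, df, p, lod))
    out = pd.DataFrame(rows, columns=["bin_left", "chi2", "df", "p", "lod"])
    out.insert(1, "bin_mid", np.round(out["bin_left"] + BIN_WIDTH / 2, 10))
    for k, h in enumerate(histograms):
        out[f"count_{h.label or k}"] = counts[k]
    out["crosses_cutoff"] = out["lod"] > LOD_CUTOFF
    return out


@dataclass(frozen=True)
class TailSet:
    """Genes in the extreme 1% of a ranked per-gene statistic."""

    collection: str
    direction: str  # 'lower' | 'upper'
    genes: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.genes)


def extract_tails(
    values: Mapping[str, float] | pd.Series,
    collection: str,
    direction: str,
    fraction: float = 0.01,
) -> TailSet:
    """The extreme ``fraction`` of genes by ranked value (floor sizing;
    ties at the cutoff broken by gene id). Fewer than 1/fraction genes
    yield an empty tail with a warning."""
    if direction not in ("lower", "upper"):
        raise ValueError("direction must be 'lower' or 'upper'")
    s = pd.Series(values).dropna()
    size = int(np.floor(fraction * len(s)))
    if size == 0:
        warnings.warn(f"{collection}: {len(s)} genes give an empty {direction} {fraction:.0%} tail")
        return TailSet(collection, direction, ())
    ascending = direction == "lower"
    ranked = s.reset_index()
    ranked.columns = ["gene", "value"]
    ranked = ranked.sort_values(
        ["value", "gene"], ascending=[ascending, True], kind="mergesort"
    )
    genes = tuple(ranked["gene"].head(size))
    return TailSet(collection, direction, genes)


@dataclass(frozen=True)
class CooccurrenceTally:
    """How often tail genes recur across collections (Venn-style)."""

    direction: str
    k: int
    by_multiplicity: dict[int, int]  # m -> number of genes in exactly m collections
    union_size: int
    percent_unique: int  # whole percent of union genes in exactly one collection

    @property
    def counts_vector(self) -> tuple[int, ...]:
        return tuple(self.by_multiplicity.get(m, 0) for m in range(1, self.k + 1))


def cooccurrence_tally(tail_sets: Sequence[TailSet]) -> CooccurrenceTally:
    if len(tail_sets) < 2:
        raise ValueError("need >= 2 tail sets")
    directions = {t.direction for t in tail_sets}
    if len(directions) != 1:
        raise ValueError("tail sets mix directions")
    k = len(tail_sets)
    mult: dict[str, int] = {}
    for t in tail_sets:
        for g in set(t.genes):
            mult[g] = mult.get(g, 0) + 1
    by_m: dict[int, int] = {}
    for m in mult.values():
        by_m[m] = by_m.get(m, 0) + 1
    union = len(mult)
    pct = round(100.0 * by_m.get(1, 0) / union) if union else 0
    return CooccurrenceTally(
        direction=directions.pop(), k=k, by_multiplicity=by_m, union_size=union, percent_unique=pct
    )


@dataclass(frozen=True)
class DistributionSummary:
    """Table-3-style location/scale summary of a per-gene F_ST (or H_exp)
    distribution. The mode is the midpoint of the most populated 0.01 bin
    (a continuous statistic has no exact mode); quantiles use linear
    interpolation, or nearest-rank by flag."""

    n_genes: int
    n_snps: int | None
    mean: float
    sd: float
    median: float
    mode: float
    low5: float
    high95: float


def distribution_summary(
    values: Sequence[float] | np.ndarray,
    kind: str = "fst",
    n_snps: int | None = None,
    quantile_method: str = "linear",
) -> DistributionSummary:
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) == 0:
        raise ValueError("need >= 1 value")
    if quantile_method not in ("linear", "nearest"):
        raise ValueError("quantile_method must be 'linear' or 'nearest'")
    hist = bin_statistic(v, kind)
    mode = float(hist.midpoints[int(np.argmax(hist.counts))])
    q5, q95 = np.quantile(v, [0.05, 0.95], method=quantile_method)
    return DistributionSummary(
        n_genes=int(len(v)),
        n_snps=n_snps,
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if len(v) > 1 else 0.0,
        median=float(np.median(v)),
        mode=mode,
        low5=float(q5),
        high95=float(q95),
    )
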