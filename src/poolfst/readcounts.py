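"""Per-site readcount tables: parsing, trimming, replicate concordance,
and the replicate / collection intersection stages.

The readcount dialect is a TSV with header
``contig  position  ref  depth  counts...`` where each remaining column is
an ``allele:coverage`` pair; alleles are A/C/G/T or indel tokens
(``+SEQ`` insertion, ``-SEQ`` deletion). Positions are 1-based.

Two equivalent implementations coexist: per-site :class:`SiteCounts`
functions (the reference semantics, convenient for small inputs and
tests) and a vectorized :class:`LibraryTable` path used by the pipeline
on multi-million-site tables. Their agreement is asserted in the test
suite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

log = logging.getLogger(__name__)

NUCLEOTIDES = ("A", "C", "G", "T")
#: Default coverage thresholds: sites under 15 reads in a library are
#: removed, and sites above 2000 reads are treated as putative repetitive
#: DNA (excluded by default; proportional truncation by flag).
MIN_COVERAGE = 15
MAX_COVERAGE = 2000
DEFAULT_ALPHA = 0.05


def _valid_allele(token: str) -> bool:
    if token in NUCLEOTIDES or token == "N":
        return True
    if len(token) >= 2 and token[0] in "+-":
        return all(b in "ACGTN" for b in token[1:])
    return False


@dataclass
class SiteCounts:
    """One genomic site's per-allele coverages in one library."""

    contig: str
    position: int  # 1-based
    ref: str
    counts: dict[str, int]
    snpid: int | None = None
    gene_id: str | None = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def nid(self) -> int:
        """Number of nucleotides/indels segregating at the site."""
        return sum(1 for v in self.counts.values() if v > 0)

    @property
    def alleles(self) -> list[str]:
        return [a for a, v in self.counts.items() if v > 0]

    @property
    def key(self) -> tuple[str, int]:
        return (self.contig, self.position)


def read_readcounts(path: Path | str) -> Iterator[SiteCounts]:
    """Stream one SiteCounts per data line; malformed lines raise with the
    line number, unknown allele tokens raise naming the token, and a
    depth/column-sum mismatch warns (the summed value wins)."""
    with open(path) as fh:
        header = fh.readline()
        if header and not header.startswith("contig"):
            raise ValueError(f"{path}: missing readcount header line")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: malformed line (need >=4 columns)")
            contig, pos_s, ref, depth_s = fields[:4]
            try:
                position, depth = int(pos_s), int(depth_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line ({exc})") from None
            counts: dict[str, int] = {}
            for pair in fields[4:]:
                if not pair:
                    continue
                allele, _, count_s = pair.rpartition(":")
                if not allele or not _valid_allele(allele):
                    raise ValueError(f"{path}:{lineno}: unknown allele token {pair.split(':')[0]!r}")
                try:
                    counts[allele] = counts.get(allele, 0) + int(count_s)
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: malformed count in {pair!r}") from None
            site = SiteCounts(contig, position, ref, counts)
            if depth != site.total:
                warnings.warn(
                    f"{path}:{lineno}: depth column ({depth}) != summed allele coverage "
                    f"({site.total}); using the sum",
                    stacklevel=2,
                )
            yield site


def write_readcounts(sites: Iterable[SiteCounts], path: Path | str) -> None:
    """Bit-exact writer of the readcount dialect (nucleotides in A,C,G,T
    order, then indel tokens lexicographically; zero-coverage alleles
    omitted)."""
    with open(path, "w") as fh:
        fh.write("contig\tposition\tref\tdepth\tcounts\n")
        for s in sites:
            pairs = [f"{a}:{s.counts[a]}" for a in NUCLEOTIDES if s.counts.get(a, 0) > 0]
            pairs += sorted(
                f"{a}:{v}" for a, v in s.counts.items() if v > 0 and a not in NUCLEOTIDES
            )
            fh.write(f"{s.contig}\t{s.position}\t{s.ref}\t{s.total}\t" + "\t".join(pairs) + "\n")


# ---------------------------------------------------------------------------
# Trim / cap filter


def _truncate_counts(counts: dict[str, int], cap: int) -> dict[str, int]:
    """Scale counts proportionally to sum exactly ``cap`` (largest
    remainder rounding)."""
    total = sum(counts.values())
    items = [(a, v) for a, v in counts.items() if v > 0]
    scaled = [(a, v * cap / total) for a, v in items]
    floors = {a: int(x) for a, x in scaled}
    short = cap - sum(floors.values())
    for a, _ in sorted(scaled, key=lambda t: (-(t[1] - int(t[1])), t[0]))[:short]:
        floors[a] += 1
    return floors


def trim_sites(
    sites: Iterable[SiteCounts],
    min_cov: int = MIN_COVERAGE,
    max_cov: int = MAX_COVERAGE,
    cap_policy: str = "exclude",
) -> Iterator[SiteCounts]:
    """Remove sites with < ``min_cov`` total reads; sites over ``max_cov``
    (putative repetitive DNA) are excluded by default, or proportionally
    truncated to ``max_cov`` under ``cap_policy='truncate'``."""
    if not (0 < min_cov < max_cov):
        raise ValueError("need 0 < min_cov < max_cov")
    if cap_policy not in ("exclude", "truncate"):
        raise ValueError("cap_policy must be 'exclude' or 'truncate'")
    for s in sites:
        total = s.total
        if total < min_cov:
            continue
        if total > max_cov:
            if cap_policy == "exclude":
                continue
            s = replace(s, counts=_truncate_counts(s.counts, max_cov))
        yield s


# ---------------------------------------------------------------------------
# Replicate concordance


@dataclass(frozen=True)
class ConcordanceResult:
    retain: bool
    chi2: float
    df: int
    p: float
    reason: str = ""  # '', 'empty replicate', 'low expected counts'


def replicate_concordance(
    replicates: Sequence[SiteCounts], alpha: float = DEFAULT_ALPHA
) -> ConcordanceResult:
    """Heterogeneity chi-square across replicate libraries at one site.

    The k x nid table of allele coverages (alleles pooled over the
    replicates, nid of them nonzero) is tested with a plain Pearson
    statistic on (k-1)(nid-1) degrees of freedom -- nid-1 for the usual
    replicate pair. Sites where frequencies differ at level ``alpha`` are
    discarded. Monomorphic pooled sites (nid = 1, df = 0) are trivially
    retained; a zero-coverage replicate discards the site; tables with any
    expected cell below 1 are retained with a flag rather than tested.
    """
    if len(replicates) < 2:
        raise ValueError("concordance requires >= 2 replicate rows")
    keys = {r.key for r in replicates}
    if len(keys) != 1:
        raise ValueError(f"replicate rows refer to different sites: {sorted(keys)}")
    alleles = sorted({a for r in replicates for a in r.alleles})
    table = np.array([[r.counts.get(a, 0) for a in alleles] for r in replicates], dtype=float)
    row_tot = table.sum(axis=1)
    if (row_tot == 0).any():
        return ConcordanceResult(False, float("nan"), 0, float("nan"), "empty replicate")
    nid = len(alleles)
    df = (len(replicates) - 1) * (nid - 1)
    if df == 0:
        return ConcordanceResult(True, 0.0, 0, 1.0, "")
    col_tot = table.sum(axis=0)
    expected = np.outer(row_tot, col_tot) / row_tot.sum()
    if expected.min() < 1.0:
        return ConcordanceResult(True, float("nan"), df, float("nan"), "low expected counts")
    chi2 = float(((table - expected) ** 2 / expected).sum())
    p = float(chi2_dist.sf(chi2, df))
    return ConcordanceResult(p >= alpha, chi2, df, p, "")


# ---------------------------------------------------------------------------
# Intersections


@dataclass
class FilterTally:
    """Per-stage record counts, so no site is lost silently."""

    stage: str
    n_in: int = 0
    n_retained: int = 0
    n_discarded_concordance: int = 0
    n_discarded_empty: int = 0
    n_flagged_low_expected: int = 0

    def log(self) -> None:
        log.info(
            "%s: %d in, %d retained, %d discordant, %d empty-replicate, %d low-expected flagged",
            self.stage,
            self.n_in,
            self.n_retained,
            self.n_discarded_concordance,
            self.n_discarded_empty,
            self.n_flagged_low_expected,
        )


def _sum_counts(replicates: Sequence[SiteCounts]) -> SiteCounts:
    counts: dict[str, int] = {}
    for r in replicates:
        for a, v in r.counts.items():
            counts[a] = counts.get(a, 0) + v
    first = replicates[0]
    return SiteCounts(first.contig, first.position, first.ref, counts, first.snpid, first.gene_id)


def intersect_replicates(
    *replicate_maps: Mapping[tuple[str, int], SiteCounts],
    alpha: float = DEFAULT_ALPHA,
) -> tuple[dict[tuple[str, int], SiteCounts], FilterTally]:
    """SNPs present in every replicate of a collection, concordance-tested
    and replicate-summed (the "2 x 2" stage)."""
    if len(replicate_maps) < 2:
        raise ValueError("need >= 2 replicate maps")
    common = set(replicate_maps[0])
    for m in replicate_maps[1:]:
        common &= set(m)
    tally = FilterTally("intersect_replicates", n_in=len(common))
    out: dict[tuple[str, int], SiteCounts] = {}
    for key in sorted(common):
        rows = [m[key] for m in replicate_maps]
        res = replicate_concordance(rows, alpha=alpha)
        if res.reason == "empty replicate":
            tally.n_discarded_empty += 1
            continue
        if res.reason == "low expected counts":
            tally.n_flagged_low_expected += 1
        if not res.retain:
            tally.n_discarded_concordance += 1
            continue
        out[key] = _sum_counts(rows)
    tally.n_retained = len(out)
    return out, tally


def intersect_collections(
    set_i: Mapping[tuple[str, int], SiteCounts],
    set_j: Mapping[tuple[str, int], SiteCounts],
) -> list[tuple[str, int]]:
    """SNP keys common to two collections (the "2 x 2 x 2" stage)."""
    return sorted(set(set_i) & set(set_j))


def pooled_alt_allele(rows: Sequence[SiteCounts], ref: str) -> str | None:
    """Second most common allele over all pooled coverage ("the minor
    allele"); ties broken by the lexicographically smallest allele. None
    when only the reference allele is observed."""
    pooled: dict[str, int] = {}
    for r in rows:
        for a, v in r.counts.items():
            if v > 0:
                pooled[a] = pooled.get(a, 0) + v
    ranked = sorted(pooled.items(), key=lambda t: (-t[1], t[0]))
    for allele, _ in ranked:
        if allele != ref:
            # alt is the top non-reference allele == second most common
            # overall whenever ref is the major allele.
            return allele
    return None


@dataclass
class SnpContingency:
    """Per-library allele coverages for one SNP common to two collections."""

    key: tuple[str, int]
    ref: str
    alt: str | None
    rows: list[tuple[str, SiteCounts]]  # (library/collection label, counts)
    snpid: int | None = None
    gene_id: str | None = None

    def collection_counts(self, label: str) -> SiteCounts:
        rows = [r for lab, r in self.rows if lab == label]
        if not rows:
            raise KeyError(label)
        return _sum_counts(rows)


def build_contingency(
    key: tuple[str, int],
    rows_i: Sequence[tuple[str, SiteCounts]],
    rows_j: Sequence[tuple[str, SiteCounts]],
) -> SnpContingency:
    all_rows = list(rows_i) + list(rows_j)
    ref = all_rows[0][1].ref
    alt = pooled_alt_allele([r for _, r in all_rows], ref)
    first = all_rows[0][1]
    return SnpContingency(
        key=key, ref=ref, alt=alt, rows=all_rows, snpid=first.snpid, gene_id=first.gene_id
    )


# ---------------------------------------------------------------------------
# Vectorized path


_TABLE_COLS = ["A", "C", "G", "T", "INS", "DEL"]


@dataclass
class LibraryTable:
    """A whole library as a DataFrame: columns contig, position (1-based),
    ref, A, C, G, T, INS, DEL, indel_token. At most one insertion and one
    deletion token per site are representable; the per-site API has no
    such limit."""

    df: pd.DataFrame

    @property
    def n_sites(self) -> int:
        return len(self.df)

    def counts_matrix(self) -> np.ndarray:
        return self.df[_TABLE_COLS].to_numpy()

    def to_sites(self) -> Iterator[SiteCounts]:
        for row in self.df.itertuples(index=False):
            counts = {}
            for a in NUCLEOTIDES:
                v = getattr(row, a)
                if v:
                    counts[a] = int(v)
            if row.INS:
                counts[row.indel_token if str(row.indel_token).startswith("+") else "+N"] = int(row.INS)
            if row.DEL:
                tok = row.indel_token if str(row.indel_token).startswith("-") else "-N"
                counts[tok] = int(row.DEL)
            yield SiteCounts(row.contig, int(row.position), row.ref, counts)


def read_readcounts_table(path: Path | str) -> LibraryTable:
    """Vectorized reader of the readcount dialect."""
    contigs: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    data = {c: [] for c in _TABLE_COLS}
    tokens: list[str] = []
    n_mismatch = 0
    with open(path) as fh:
        header = fh.readline()
        if header and not header.startswith("contig"):
            raise ValueError(f"{path}: missing readcount header line")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                if line.strip() == "":
                    continue
                raise ValueError(f"{path}:{lineno}: malformed line")
            contigs.append(fields[0])
            positions.append(int(fields[1]))
            refs.append(fields[2])
            a = c = g = t = ins = dele = 0
            tok = ""
            for pair in fields[4:]:
                if not pair:
                    continue
                allele, _, count_s = pair.rpartition(":")
                v = int(count_s)
                if allele == "A":
                    a += v
                elif allele == "C":
                    c += v
                elif allele == "G":
                    g += v
                elif allele == "T":
                    t += v
                elif allele and allele[0] == "+":
                    ins += v
                    tok = allele
                elif allele and allele[0] == "-":
                    dele += v
                    tok = tok or allele
                elif allele == "N":
                    pass  # uninformative calls carry no allele identity
                else:
                    raise ValueError(f"{path}:{lineno}: unknown allele token {allele!r}")
            if int(fields[3]) != a + c + g + t + ins + dele:
                n_mismatch += 1
            data["A"].append(a)
            data["C"].append(c)
            data["G"].append(g)
            data["T"].append(t)
            data["INS"].append(ins)
            data["DEL"].append(dele)
            tokens.append(tok)
    if n_mismatch:
        warnings.warn(f"{path}: {n_mismatch} lines with depth != summed allele coverage")
    df = pd.DataFrame(
        {
            "contig": np.asarray(contigs, dtype=object),
            "position": np.asarray(positions, dtype=np.int64),
            "ref": np.asarray(refs, dtype=object),
            **{c: np.asarray(v, dtype=np.int64) for c, v in data.items()},
            "indel_token": np.asarray(tokens, dtype=object),
        }
    )
    return LibraryTable(df)


def trim_table(
    table: LibraryTable,
    min_cov: int = MIN_COVERAGE,
    max_cov: int = MAX_COVERAGE,
    cap_policy: str = "exclude",
) -> LibraryTable:
    if not (0 < min_cov < max_cov):
        raise ValueError("need 0 < min_cov < max_cov")
    counts = table.counts_matrix()
    total = counts.sum(axis=1)
    keep = total >= min_cov
    over = total > max_cov
    if cap_policy == "exclude":
        keep &= ~over
        return LibraryTable(table.df.loc[keep].reset_index(drop=True))
    if cap_policy != "truncate":
        raise ValueError("cap_policy must be 'exclude' or 'truncate'")
    df = table.df.loc[keep].reset_index(drop=True)
    counts = df[_TABLE_COLS].to_numpy().astype(float)
    total = counts.sum(axis=1)
    over = total > max_cov
    if over.any():
        scaled = counts[over] * (max_cov / total[over, None])
        floors = np.floor(scaled).astype(np.int64)
        remainder = scaled - floors
        short = (max_cov - floors.sum(axis=1)).astype(int)
        order = np.argsort(-remainder, axis=1, kind="stable")
        for r in range(len(floors)):
            for j in order[r, : short[r]]:
                floors[r, j] += 1
        out = df[_TABLE_COLS].to_numpy()
        out[np.flatnonzero(over)] = floors
        df[_TABLE_COLS] = out
    return LibraryTable(df)


def intersect_replicates_table(
    replicates: Sequence[LibraryTable], alpha: float = DEFAULT_ALPHA
) -> tuple[LibraryTable, list[LibraryTable], FilterTally]:
    """Vectorized "2 x 2" stage: key intersection across replicates,
    heterogeneity chi-square, replicate summing. Returns the summed
    collection table, the aligned per-replicate tables (for contingency
    rows), and the stage tally."""
    if len(replicates) < 2:
        raise ValueError("need >= 2 replicates")
    merged = replicates[0].df[["contig", "position", "ref", "indel_token"]]
    for k, rep in enumerate(replicates):
        cols = rep.df[["contig", "position"] + _TABLE_COLS].rename(
            columns={c: f"{c}_{k}" for c in _TABLE_COLS}
        )
        merged = merged.merge(cols, on=["contig", "position"], how="inner")
    n_in = len(merged)

    k_rep = len(replicates)
    mats = np.stack(
        [merged[[f"{c}_{k}" for c in _TABLE_COLS]].to_numpy() for k in range(k_rep)]
    )  # (k, n, 6)
    pooled = mats.sum(axis=0)
    row_tot = mats.sum(axis=2)  # (k, n)
    grand = row_tot.sum(axis=0)  # (n,)
    nz = pooled > 0
    nid = nz.sum(axis=1)
    df_test = (k_rep - 1) * (nid - 1)

    empty = (row_tot == 0).any(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = row_tot[:, :, None] * pooled[None, :, :] / grand[None, :, None]
        contrib = (mats - expected) ** 2 / expected
        contrib = np.where(np.broadcast_to(nz[None, :, :], contrib.shape), contrib, 0.0)
        chi2 = np.nansum(contrib, axis=(0, 2))
        min_exp = np.where(
            np.broadcast_to(nz[None, :, :], expected.shape), expected, np.inf
        ).min(axis=(0, 2))
    low_expected = (min_exp < 1.0) & (df_test > 0) & ~empty
    p = np.ones(len(merged))
    testable = (df_test > 0) & ~low_expected & ~empty
    p[testable] = chi2_dist.sf(chi2[testable], df_test[testable])
    discordant = testable & (p < alpha)
    keep = ~empty & ~discordant

    tally = FilterTally(
        "intersect_replicates",
        n_in=n_in,
        n_retained=int(keep.sum()),
        n_discarded_concordance=int(discordant.sum()),
        n_discarded_empty=int(empty.sum()),
        n_flagged_low_expected=int(low_expected.sum()),
    )

    base = merged.loc[keep, ["contig", "position", "ref", "indel_token"]].reset_index(drop=True)
    summed = base.copy()
    summed[_TABLE_COLS] = pooled[keep]
    summed = summed[["contig", "position", "ref"] + _TABLE_COLS + ["indel_token"]]
    aligned = []
    for k in range(k_rep):
        rep_df = base.copy()
        rep_df[_TABLE_COLS] = mats[k][keep]
        aligned.append(LibraryTable(rep_df[["contig", "position", "ref"] + _TABLE_COLS + ["indel_token"]]))
    return LibraryTable(summed), aligned, tally


def intersect_collections_table(
    set_i: LibraryTable, set_j: LibraryTable, suffixes: tuple[str, str] = ("_i", "_j")
) -> pd.DataFrame:
    """Vectorized "2 x 2 x 2" stage: inner join of two collection tables on
    (contig, position), counts suffixed per collection."""
    left = set_i.df.rename(columns={c: f"{c}{suffixes[0]}" for c in _TABLE_COLS + ["indel_token"]})
    right = set_j.df.drop(columns=["ref"]).rename(
        columns={c: f"{c}{suffixes[1]}" for c in _TABLE_COLS + ["indel_token"]}
    )
    return left.merge(right, on=["contig", "position"], how="inner")
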