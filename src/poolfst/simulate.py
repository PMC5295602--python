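"""Synthetic pooled exon-capture data with known population structure.

Generates a toy genome, gene annotation and replicate pooled readcount
tables whose statistical structure matches what the downstream pipeline
assumes: two-stage pool sampling (mosquito chromosomes, then reads),
Balding-Nichols divergence between collections with a known target F_ST,
negative-binomial coverage with occasional repetitive-region spikes,
sequencing miscalls, and segregating indel alleles.

All randomness derives from a single integer seed through a fixed
``SeedSequence`` split scheme (reference -> frequencies -> one stream per
library, in declared order), so every output file is byte-identical on
re-run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

NUCLEOTIDES = ("A", "C", "G", "T")

#: 600 bp non-transcribed cis windows flanking each transcript.
NTR_LENGTH = 600

#: Gap left between consecutive transcript spans on a contig, chosen so the
#: +/-600 bp gene windows of neighbouring genes never overlap.
_GENE_GAP = 1300
_CONTIG_MARGIN = 650
_GENES_PER_CONTIG = 4


@dataclass(frozen=True)
class CollectionSpec:
    """One pooled collection: replicate libraries of pooled mosquitoes.

    ``population`` groups collections that sample the same underlying gene
    pool (e.g. the female and male pools of one collection site); it
    defaults to the collection name, i.e. an independent population.
    """

    name: str
    n_individuals_per_replicate: int
    n_replicates: int = 2
    sex: str = "mixed"  # female | male | mixed
    population: str | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError(
                f"collection {self.name!r}: n_replicates must be >= 2 "
                "(the replicate-concordance filter requires pairs)"
            )
        if self.n_individuals_per_replicate < 1:
            raise ValueError(f"collection {self.name!r}: need >= 1 individual per replicate")
        if self.sex not in ("female", "male", "mixed"):
            raise ValueError(f"collection {self.name!r}: sex must be female/male/mixed")

    @property
    def population_key(self) -> str:
        return self.population if self.population is not None else self.name

    @property
    def n_individuals_total(self) -> int:
        return self.n_individuals_per_replicate * self.n_replicates

    def library_names(self) -> list[str]:
        return [f"{self.name}_rep{r + 1}" for r in range(self.n_replicates)]


def default_collections() -> tuple[CollectionSpec, ...]:
    """The twelve-library design: four collection sites, two of them with
    sex-separated dual replicate pools (12 mosquitoes each), the other two
    with mixed-sex dual replicate pools of 14 and 22 mosquitoes."""
    return (
        CollectionSpec("pk10_female", 12, 2, "female", population="pk10"),
        CollectionSpec("pk10_male", 12, 2, "male", population="pk10"),
        CollectionSpec("thailand_female", 12, 2, "female", population="thailand"),
        CollectionSpec("thailand_male", 12, 2, "male", population="thailand"),
        CollectionSpec("kaolack", 14, 2, "mixed"),
        CollectionSpec("mexico", 22, 2, "mixed"),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    theta is the Balding-Nichols divergence among *populations*;
    ``sex_theta_by_chromosome`` optionally plants an additional
    within-population divergence between sexed pools of one population,
    keyed by chromosome ("1", "2", "3", "unmapped").
    """

    seed: int = 0
    n_genes: int = 24
    gene_length_bp: int = 600
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    theta: float = 0.2
    collections: tuple[CollectionSpec, ...] = field(default_factory=default_collections)
    coverage_mean: float = 100.0
    coverage_dispersion: float = 5.0  # NB size k; variance = mu + mu^2/k
    error_rate: float = 0.001
    indel_rate: float = 0.05
    repeat_fraction: float = 0.01
    polymorphic_fraction: float = 0.05
    sex_theta_by_chromosome: Mapping[str, float] | None = None
    chromosome_cycle: tuple[str, ...] = ("1", "2", "3", "unmapped")

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta < 1.0):
            raise ValueError("theta must lie in [0, 1)")
        if self.coverage_mean < 1:
            raise ValueError("coverage_mean must be >= 1")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral_maf_range must satisfy 0 < lo <= hi < 1")
        for name, rate in (
            ("error_rate", self.error_rate),
            ("indel_rate", self.indel_rate),
            ("repeat_fraction", self.repeat_fraction),
            ("polymorphic_fraction", self.polymorphic_fraction),
        ):
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.coverage_dispersion <= 0:
            raise ValueError("coverage_dispersion must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.n_genes > 0 and self.gene_length_bp < 150:
            raise ValueError(
                "gene_length_bp too small: a transcript needs 5'UTR + >=30 bp CDS "
                "+ 3'UTR (minimum 150 bp)"
            )
        if self.sex_theta_by_chromosome is not None:
            for theta in self.sex_theta_by_chromosome.values():
                if not (0.0 <= theta < 1.0):
                    raise ValueError("sex_theta values must lie in [0, 1)")
        names = [c.name for c in self.collections]
        if len(set(names)) != len(names):
            raise ValueError("collection names must be unique")

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["collections"] = [dataclasses.asdict(c) for c in self.collections]
        if self.sex_theta_by_chromosome is not None:
            d["sex_theta_by_chromosome"] = dict(self.sex_theta_by_chromosome)
        return d


@dataclass
class SimGene:
    gene_id: str
    transcript_id: str
    contig: str
    chromosome: str
    strand: str
    tx_start: int  # 0-based half-open, genomic
    tx_end: int
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int, int]]  # (start, end, frame)

    @property
    def window(self) -> tuple[int, int]:
        return max(0, self.tx_start - NTR_LENGTH), self.tx_end + NTR_LENGTH


@dataclass
class Reference:
    genome: dict[str, str]  # contig -> sequence
    genes: list[SimGene]
    capture: list[tuple[str, int, int]]  # CDS intervals, 0-based half-open

    @property
    def contig_order(self) -> list[str]:
        return list(self.genome)


def _gene_structure(gene_length: int) -> list[tuple[str, int]]:
    """Transcript layout in coding-strand order: (kind, length) segments."""
    u5, u3 = 60, 60
    coding_span = gene_length - u5 - u3
    if coding_span < 30:
        raise ValueError("gene_length_bp leaves <30 bp for the CDS")
    if coding_span >= 300:
        intron = 90
        cds_total = coding_span - intron
        rem = cds_total % 3
        cds_total -= rem
        u3 += rem
        c1 = max(3, (cds_total // 2) // 3 * 3)
        c2 = cds_total - c1
        return [("UTR5", u5), ("CDS", c1), ("intron", intron), ("CDS", c2), ("UTR3", u3)]
    rem = coding_span % 3
    return [("UTR5", u5), ("CDS", coding_span - rem), ("UTR3", u3 + rem)]


def simulate_reference(config: SimulationConfig, rng: np.random.Generator | None = None) -> Reference:
    """Lay out ``n_genes`` transcripts on supercontigs assigned to
    chromosomes 1/2/3/unmapped, with both strands represented, and draw a
    random genome sequence.

    Contig names encode the physical chromosome assignment
    (``sc0001_chr1`` ... ``sc0007_chrU``), mirroring a supercontig build
    where only part of the assembly is placed on chromosomes.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    structure = _gene_structure(config.gene_length_bp) if config.n_genes else []
    tx_len = sum(length for _, length in structure)

    genome: dict[str, str] = {}
    genes: list[SimGene] = []
    capture: list[tuple[str, int, int]] = []

    n_contigs = (config.n_genes + _GENES_PER_CONTIG - 1) // _GENES_PER_CONTIG
    gene_no = 0
    for ci in range(n_contigs):
        chrom = config.chromosome_cycle[ci % len(config.chromosome_cycle)]
        suffix = "chrU" if chrom == "unmapped" else f"chr{chrom}"
        contig = f"sc{ci + 1:04d}_{suffix}"
        n_here = min(_GENES_PER_CONTIG, config.n_genes - ci * _GENES_PER_CONTIG)
        contig_len = _CONTIG_MARGIN * 2 + n_here * tx_len + (n_here - 1) * _GENE_GAP
        seq = rng.integers(0, 4, size=contig_len)
        genome[contig] = "".join(NUCLEOTIDES[i] for i in seq)

        pos = _CONTIG_MARGIN
        for gi in range(n_here):
            gene_no += 1
            gene_id = f"GENE{gene_no:05d}"
            strand = "+" if gene_no % 2 else "-"
            tx_start, tx_end = pos, pos + tx_len

            # Allocate segments along the genome; for '-' strand the
            # coding-strand order runs from high to low genomic coordinate.
            segs = []
            cursor = tx_start if strand == "+" else tx_end
            cds_before = 0
            for kind, length in structure:
                if strand == "+":
                    s, e = cursor, cursor + length
                    cursor = e
                else:
                    s, e = cursor - length, cursor
                    cursor = s
                frame = (3 - cds_before % 3) % 3 if kind == "CDS" else None
                segs.append((kind, s, e, frame))
                if kind == "CDS":
                    cds_before += length
            cds = sorted((s, e, f) for kind, s, e, f in segs if kind == "CDS")
            # exons = transcribed segments minus introns, merged where contiguous
            tx_segs = sorted((s, e) for kind, s, e, _ in segs if kind != "intron")
            exons: list[tuple[int, int]] = []
            for s, e in tx_segs:
                if exons and exons[-1][1] == s:
                    exons[-1] = (exons[-1][0], e)
                else:
                    exons.append((s, e))
            genes.append(
                SimGene(gene_id, f"{gene_id}-RA", contig, chrom, strand, tx_start, tx_end, exons, cds)
            )
            capture.extend((contig, s, e) for s, e, _ in cds)
            pos = tx_end + _GENE_GAP
    return Reference(genome=genome, genes=genes, capture=capture)


def write_fasta(ref: Reference, path: Path) -> None:
    with open(path, "w") as fh:
        for contig, seq in ref.genome.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_gtf(ref: Reference, path: Path) -> None:
    """GTF, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for g in ref.genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.transcript_id}";'

            def line(kind: str, s: int, e: int, frame: int | None = None) -> str:
                fr = "." if frame is None else str(frame)
                return (
                    f"{g.contig}\tpoolfst\t{kind}\t{s + 1}\t{e}\t.\t{g.strand}\t{fr}\t{attrs}\n"
                )

            fh.write(line("transcript", g.tx_start, g.tx_end))
            for s, e in g.exons:
                fh.write(line("exon", s, e))
            for s, e, f in g.cds:
                fh.write(line("CDS", s, e, f))


def write_capture_bed(ref: Reference, path: Path) -> None:
    """BED, 0-based half-open, covering CDS only (the capture design)."""
    with open(path, "w") as fh:
        for contig, s, e in ref.capture:
            fh.write(f"{contig}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# Site frequencies


@dataclass
class SiteTable:
    """One row per genomic position inside a gene window.

    ``alt_freq[name]`` is the alternate-allele frequency in collection
    ``name`` (0 for sites that do not segregate). These true frequencies
    are retained for parameter-recovery checks.
    """

    contig: np.ndarray  # object array of contig names
    pos: np.ndarray  # 0-based genomic position
    ref_base: np.ndarray  # object array, 'A'..'T'
    gene_id: np.ndarray
    chromosome: np.ndarray
    segregating: np.ndarray  # bool
    alt_allele: np.ndarray  # object; '' for non-segregating
    ancestral_freq: np.ndarray
    alt_freq: dict[str, np.ndarray]
    repeat_multiplier: np.ndarray  # coverage inflation factor (1 outside repeats)

    @property
    def n_sites(self) -> int:
        return len(self.pos)


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Draw descendant allele frequencies: Beta(p(1-t)/t, (1-p)(1-t)/t),
    reducing to p where theta == 0."""
    out = p.copy()
    t = np.broadcast_to(np.asarray(theta, dtype=float), p.shape)
    mask = t > 0
    if mask.any():
        ratio = (1.0 - t[mask]) / t[mask]
        out[mask] = rng.beta(p[mask] * ratio, (1.0 - p[mask]) * ratio)
    return out


def simulate_pool_frequencies(
    config: SimulationConfig,
    reference: Reference,
    rng: np.random.Generator | None = None,
) -> SiteTable:
    """Draw per-site true allele frequencies for every collection.

    Ancestral alternate frequencies are uniform on ``ancestral_maf_range``
    at a ``polymorphic_fraction`` subset of sites. Each population then
    receives a Balding-Nichols draw at divergence ``theta``; sexed pools
    within one population receive a second split at
    ``sex_theta_by_chromosome`` (default: none, sexes share the
    population frequency).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[1])

    contigs, poss, refs, gids, chroms = [], [], [], [], []
    for g in reference.genes:
        w0, w1 = g.window
        w1 = min(w1, len(reference.genome[g.contig]))
        n = w1 - w0
        contigs.append(np.full(n, g.contig, dtype=object))
        poss.append(np.arange(w0, w1))
        seq = reference.genome[g.contig][w0:w1]
        refs.append(np.array(list(seq), dtype=object))
        gids.append(np.full(n, g.gene_id, dtype=object))
        chroms.append(np.full(n, g.chromosome, dtype=object))

    if contigs:
        contig = np.concatenate(contigs)
        pos = np.concatenate(poss)
        ref_base = np.concatenate(refs)
        gene_id = np.concatenate(gids)
        chromosome = np.concatenate(chroms)
    else:
        contig = pos = ref_base = gene_id = chromosome = np.array([], dtype=object)
        pos = np.array([], dtype=int)
    n = len(pos)

    segregating = rng.random(n) < config.polymorphic_fraction
    lo, hi = config.ancestral_maf_range
    p_anc = np.zeros(n)
    p_anc[segregating] = rng.uniform(lo, hi, size=int(segregating.sum()))

    # Alternate allele: a different nucleotide, or an indel token at indel_rate.
    alt = np.full(n, "", dtype=object)
    seg_idx = np.flatnonzero(segregating)
    is_indel = rng.random(len(seg_idx)) < config.indel_rate
    base_pick = rng.integers(0, 3, size=len(seg_idx))
    ins_or_del = rng.integers(0, 2, size=len(seg_idx))
    ins_base = rng.integers(0, 4, size=len(seg_idx))
    for k, i in enumerate(seg_idx):
        if is_indel[k]:
            alt[i] = ("+" if ins_or_del[k] else "-") + NUCLEOTIDES[ins_base[k]]
        else:
            others = [b for b in NUCLEOTIDES if b != ref_base[i]]
            alt[i] = others[base_pick[k]]

    repeat_multiplier = np.ones(n)
    rep = rng.random(n) < config.repeat_fraction
    repeat_multiplier[rep] = rng.uniform(10.0, 100.0, size=int(rep.sum()))

    # Population-level divergence, then optional sex split within population.
    sex_theta = dict(config.sex_theta_by_chromosome or {})
    theta_site = np.full(n, config.theta)
    pop_freqs: dict[str, np.ndarray] = {}
    alt_freq: dict[str, np.ndarray] = {}
    populations: dict[str, list[CollectionSpec]] = {}
    for spec in config.collections:
        populations.setdefault(spec.population_key, []).append(spec)
    for pop_key in populations:
        q = np.zeros(n)
        q[segregating] = _balding_nichols(rng, p_anc[segregating], theta_site[segregating])
        pop_freqs[pop_key] = q
    for pop_key, members in populations.items():
        split = len(members) > 1 and sex_theta
        if split:
            ts = np.array([sex_theta.get(c, 0.0) for c in chromosome[segregating]])
        for spec in members:
            if split:
                q = np.zeros(n)
                q[segregating] = _balding_nichols(rng, pop_freqs[pop_key][segregating], ts)
            else:
                q = pop_freqs[pop_key].copy()
            alt_freq[spec.name] = q

    return SiteTable(
        contig=contig,
        pos=pos,
        ref_base=ref_base,
        gene_id=gene_id,
        chromosome=chromosome,
        segregating=segregating,
        alt_allele=alt,
        ancestral_freq=p_anc,
        alt_freq=alt_freq,
        repeat_multiplier=repeat_multiplier,
    )


# ---------------------------------------------------------------------------
# Readcount tables


def _negative_binomial_depth(
    rng: np.random.Generator, mean: float, dispersion: float, size: int
) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


_BASE_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}


def _library_counts(
    rng: np.random.Generator,
    sites: SiteTable,
    pool_freq: np.ndarray,
    config: SimulationConfig,
) -> np.ndarray:
    """Counts matrix (n_sites x 5): columns A,C,G,T,indel."""
    n = sites.n_sites
    depth = _negative_binomial_depth(rng, config.coverage_mean, config.coverage_dispersion, n)
    depth = np.round(depth * sites.repeat_multiplier).astype(np.int64)

    alt_reads = rng.binomial(depth, pool_freq)
    ref_reads = depth - alt_reads

    counts = np.zeros((n, 5), dtype=np.int64)
    ref_col = np.array([_BASE_INDEX[b] for b in sites.ref_base], dtype=np.intp)
    alt_is_indel = np.array(
        [a.startswith(("+", "-")) for a in sites.alt_allele], dtype=bool
    )
    alt_col = np.array(
        [4 if (not a or a.startswith(("+", "-"))) else _BASE_INDEX[a] for a in sites.alt_allele],
        dtype=np.intp,
    )

    # Sequencing miscalls apply to nucleotide reads only: each miscalled
    # read is reassigned uniformly to one of the three other nucleotides.
    def scatter(true_col_arr: np.ndarray, reads: np.ndarray, active: np.ndarray) -> None:
        if config.error_rate > 0:
            errs = rng.binomial(reads, config.error_rate)
        else:
            errs = np.zeros_like(reads)
        np.add.at(counts, (np.arange(n)[active], true_col_arr[active]), (reads - errs)[active])
        for col in range(4):
            m = active & (true_col_arr == col) & (errs > 0)
            if not m.any():
                continue
            others = [c for c in range(4) if c != col]
            spread = rng.multinomial(errs[m], [1 / 3] * 3)
            for k, oc in enumerate(others):
                counts[np.flatnonzero(m), oc] += spread[:, k]

    scatter(ref_col, ref_reads, np.ones(n, dtype=bool))
    nuc_alt = ~alt_is_indel & (sites.alt_allele != "")
    scatter(alt_col, alt_reads, nuc_alt)
    indel_alt = alt_is_indel
    counts[indel_alt, 4] = alt_reads[indel_alt]
    return counts


def simulate_readcounts(
    config: SimulationConfig,
    reference: Reference,
    sites: SiteTable,
    outdir: Path,
    rng: np.random.Generator | None = None,
) -> dict[str, Path]:
    """Write one readcount TSV per replicate library.

    Replicates of a collection sample reads from the same physical pool:
    the pool allele count is one binomial draw of 2 x (total mosquitoes in
    the collection) chromosomes from the collection's true frequency, and
    each replicate then samples reads from that pool at negative-binomial
    coverage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])

    paths: dict[str, Path] = {}
    for spec in config.collections:
        k_chrom = 2 * spec.n_individuals_total
        pool_count = rng.binomial(k_chrom, sites.alt_freq[spec.name])
        pool_freq = pool_count / k_chrom
        for lib in spec.library_names():
            counts = _library_counts(rng, sites, pool_freq, config)
            path = outdir / f"{lib}.readcounts.tsv"
            _write_readcount_tsv(path, sites, counts)
            paths[lib] = path
    return paths


def _write_readcount_tsv(path: Path, sites: SiteTable, counts: np.ndarray) -> None:
    tokens = list(NUCLEOTIDES)
    lines = ["contig\tposition\tref\tdepth\tcounts\n"]
    totals = counts.sum(axis=1)
    for i in range(sites.n_sites):
        tot = totals[i]
        if tot == 0:
            continue
        pairs = []
        for c in range(4):
            if counts[i, c]:
                pairs.append(f"{tokens[c]}:{counts[i, c]}")
        if counts[i, 4]:
            pairs.append(f"{sites.alt_allele[i]}:{counts[i, 4]}")
        lines.append(
            f"{sites.contig[i]}\t{sites.pos[i] + 1}\t{sites.ref_base[i]}\t{tot}\t"
            + "\t".join(pairs)
            + "\n"
        )
    with open(path, "w") as fh:
        fh.writelines(lines)


# ---------------------------------------------------------------------------
# One-call study fixture


@dataclass
class StudyFixture:
    root: Path
    fasta: Path
    gtf: Path
    bed: Path
    readcounts: dict[str, Path]
    truth: Path
    manifest: Path
    config: SimulationConfig
    reference: Reference
    sites: SiteTable


def simulate_study(config: SimulationConfig, outdir: Path | str) -> StudyFixture:
    """Generate the full fixture directory: genome FASTA, annotation GTF,
    capture BED, per-library readcount TSVs, a true-frequency table, and a
    JSON manifest of all parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed).spawn(3)
    reference = simulate_reference(config, np.random.default_rng(ss[0]))
    sites = simulate_pool_frequencies(config, reference, np.random.default_rng(ss[1]))
    readcounts = simulate_readcounts(
        config, reference, sites, outdir / "readcounts", np.random.default_rng(ss[2])
    )

    fasta, gtf, bed = outdir / "genome.fasta", outdir / "annotation.gtf", outdir / "capture.bed"
    write_fasta(reference, fasta)
    write_gtf(reference, gtf)
    write_capture_bed(reference, bed)

    truth = outdir / "true_frequencies.tsv"
    with open(truth, "w") as fh:
        names = [c.name for c in config.collections]
        fh.write("contig\tposition\tgene_id\tchromosome\tref\talt\tancestral_freq\t")
        fh.write("\t".join(f"freq_{n}" for n in names) + "\n")
        for i in np.flatnonzero(sites.segregating):
            freqs = "\t".join(f"{sites.alt_freq[n][i]:.6f}" for n in names)
            fh.write(
                f"{sites.contig[i]}\t{sites.pos[i] + 1}\t{sites.gene_id[i]}\t"
                f"{sites.chromosome[i]}\t{sites.ref_base[i]}\t{sites.alt_allele[i]}\t"
                f"{sites.ancestral_freq[i]:.6f}\t{freqs}\n"
            )

    manifest = outdir / "manifest.json"
    with open(manifest, "w") as fh:
        json.dump(
            {
                "config": config.to_manifest(),
                "n_sites": int(sites.n_sites),
                "n_segregating": int(sites.segregating.sum()),
                "libraries": {k: str(v.relative_to(outdir)) for k, v in readcounts.items()},
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return StudyFixture(
        root=outdir,
        fasta=fasta,
        gtf=gtf,
        bed=bed,
        readcounts=readcounts,
        truth=truth,
        manifest=manifest,
        config=config,
        reference=reference,
        sites=sites,
    )
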