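"""Gene models, hierarchical SNPID coordinates and site classification.

Builds transcript models from a GTF + FASTA pair, derives introns, UTRs
and the 600 bp non-transcribed (NTR) cis windows flanking each transcript,
and classifies any genomic position by gene region (5'NTR, 5'UTR, codon
1/2/3, intron, 3'UTR, 3'NTR), mutation type (transition / transversion /
insertion / deletion) and coding consequence (silent / replacement).

Coordinates: GTF input is 1-based inclusive; everything internal is
0-based half-open; conversion happens only at the I/O boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio.Seq import Seq
from Bio import SeqIO
from intervaltree import IntervalTree

NTR_LENGTH = 600

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
NUCLEOTIDES = frozenset("ACGT")

REGIONS = ("NTR5", "UTR5", "codon1", "codon2", "codon3", "intron", "UTR3", "NTR3")

_CHROM_RANK = {"1": 0, "2": 1, "3": 2, "unmapped": 3}
_CONTIG_RE = re.compile(r"^sc(\d+)_chr(1|2|3|U)$")


def chromosome_of_contig(contig: str) -> str:
    """Physical chromosome assignment encoded in the supercontig name
    (``sc0012_chr2`` -> "2"); anything else is unmapped."""
    m = _CONTIG_RE.match(contig)
    if m is None or m.group(2) == "U":
        return "unmapped"
    return m.group(2)


def supercontig_order(contig: str) -> tuple:
    m = _CONTIG_RE.match(contig)
    if m:
        return (0, int(m.group(1)))
    return (1, contig)


@dataclass(frozen=True)
class Feature:
    kind: str  # NTR5 | UTR5 | CDS | intron | UTR3 | NTR3
    start: int  # 0-based half-open, genomic
    end: int
    frame: int | None = None  # CDS only


@dataclass
class GeneModel:
    """One transcript's located features on a strand.

    ``features`` are in genomic coordinate order and partition the gene
    window (transcript span +/- 600 bp NTRs, truncated at contig edges).
    ``cds_incomplete`` flags transcripts whose CDS length is not a
    multiple of 3 or whose GTF frames are inconsistent; they keep region
    calls but are excluded from consequence calls.
    """

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    chromosome: str
    tx_start: int
    tx_end: int
    features: list[Feature]
    cds_incomplete: bool = False
    ntr_truncated: bool = False
    contig_length: int = 0
    _cds_seq: str | None = field(default=None, repr=False)

    @property
    def window(self) -> tuple[int, int]:
        return self.features[0].start, self.features[-1].end

    @property
    def cds_segments(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "CDS"]

    @property
    def cds_length(self) -> int:
        return sum(f.end - f.start for f in self.cds_segments)

    def contains(self, pos: int) -> bool:
        w0, w1 = self.window
        return w0 <= pos < w1

    # -- coding-strand arithmetic ------------------------------------------

    def coding_offset(self, pos: int) -> int | None:
        """0-based offset of a genomic position along the coding strand of
        the concatenated CDS, or None if the position is not in a CDS."""
        segs = self.cds_segments
        if self.strand == "+":
            before = 0
            for f in segs:
                if f.start <= pos < f.end:
                    return before + (pos - f.start)
                before += f.end - f.start
        else:
            before = 0
            for f in reversed(segs):
                if f.start <= pos < f.end:
                    return before + (f.end - 1 - pos)
                before += f.end - f.start
        return None

    def classify_region(self, pos: int) -> str:
        """Region of a position inside the gene window; CDS positions are
        resolved to their codon position on the coding strand."""
        if not self.contains(pos):
            raise ValueError(
                f"position {pos} outside window {self.window} of {self.transcript_id}"
            )
        for f in self.features:
            if f.start <= pos < f.end:
                if f.kind != "CDS":
                    return f.kind
                off = self.coding_offset(pos)
                return f"codon{off % 3 + 1}"
        raise AssertionError("window not fully partitioned")  # pragma: no cover

    def cds_sequence(self, genome: dict[str, str]) -> str:
        if self._cds_seq is None:
            parts = [genome[self.contig][f.start : f.end] for f in self.cds_segments]
            seq = "".join(parts)
            if self.strand == "-":
                seq = str(Seq(seq).reverse_complement())
            self._cds_seq = seq
        return self._cds_seq

    def annotate_site(self, pos: int, ref: str, alt: str, genome: dict[str, str]) -> "SiteAnnotation":
        """Full descriptor of a variant at a genomic position (0-based)."""
        mutation = classify_mutation(ref, alt)
        region = self.classify_region(pos)
        consequence = "not_applicable"
        if region.startswith("codon") and mutation in ("transition", "transversion"):
            if self.cds_incomplete:
                region = "codon?"
            else:
                off = self.coding_offset(pos)
                codon_pos = off % 3 + 1
                cds = self.cds_sequence(genome)
                codon = cds[off - (codon_pos - 1) : off - (codon_pos - 1) + 3]
                alt_coding = alt if self.strand == "+" else str(Seq(alt).complement())
                consequence = classify_consequence(codon, codon_pos, alt_coding)
        return SiteAnnotation(region=region, consequence=consequence, mutation_type=mutation)


@dataclass(frozen=True)
class SiteAnnotation:
    region: str
    consequence: str  # silent | replacement | not_applicable
    mutation_type: str  # transition | transversion | insertion | deletion


# ---------------------------------------------------------------------------
# Classification primitives


def classify_mutation(ref: str, alt: str) -> str:
    """Transition (purine<->purine or pyrimidine<->pyrimidine),
    transversion, or insertion/deletion for +SEQ / -SEQ tokens."""
    if alt.startswith("+"):
        return "insertion"
    if alt.startswith("-"):
        return "deletion"
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError(f"not a variant: ref == alt == {ref!r}")
    if ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
        raise ValueError(f"unrecognized alleles {ref!r} -> {alt!r}")
    if (ref in PURINES) == (alt in PURINES):
        return "transition"
    return "transversion"


def classify_consequence(codon: str, codon_position: int, alt: str) -> str:
    """Silent vs replacement under the standard genetic code; a nonsense
    change counts as replacement. Codons containing N are not callable."""
    codon = codon.upper()
    if codon_position not in (1, 2, 3):
        raise ValueError("codon_position must be 1, 2 or 3")
    if len(codon) != 3 or any(b not in NUCLEOTIDES for b in codon):
        return "not_applicable"
    alt = alt.upper()
    if alt not in NUCLEOTIDES:
        return "not_applicable"
    mutated = codon[: codon_position - 1] + alt + codon[codon_position:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    return "silent" if aa_ref == aa_alt else "replacement"


# ---------------------------------------------------------------------------
# Model construction


def _frames_consistent(cds: list[tuple[int, int, int | None]], strand: str) -> bool:
    order = cds if strand == "+" else list(reversed(cds))
    before = 0
    for s, e, frame in order:
        expected = (3 - before % 3) % 3
        if frame is not None and frame != expected:
            return False
        before += e - s
    return True


def build_gene_models(gtf_path: Path | str, fasta_path: Path | str) -> list[GeneModel]:
    """Read a GTF + FASTA pair into GeneModels, one per transcript.

    Introns are derived as gaps between exons; UTRs as exonic sequence
    outside the CDS; NTRs as 600 bp flanks of the transcript span,
    truncated (and flagged) at contig edges. CDS frame inconsistencies or
    a total CDS length not divisible by 3 flag the transcript incomplete.
    """
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    transcripts: dict[str, dict] = {}
    for feat in db.all_features():
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            continue
        rec = transcripts.setdefault(
            tid,
            {
                "gene_id": feat.attributes.get("gene_id", [tid])[0],
                "contig": feat.seqid,
                "strand": feat.strand,
                "exons": [],
                "cds": [],
                "span": None,
            },
        )
        start0, end0 = feat.start - 1, feat.end  # 1-based inclusive -> half-open
        if feat.featuretype == "transcript":
            rec["span"] = (start0, end0)
        elif feat.featuretype == "exon":
            rec["exons"].append((start0, end0))
        elif feat.featuretype == "CDS":
            frame = None if feat.frame in (None, ".") else int(feat.frame)
            rec["cds"].append((start0, end0, frame))

    models: list[GeneModel] = []
    for tid, rec in transcripts.items():
        contig = rec["contig"]
        if contig not in genome:
            raise ValueError(f"transcript {tid} references contig {contig!r} absent from FASTA")
        contig_len = len(genome[contig])
        exons = sorted(rec["exons"])
        cds = sorted(rec["cds"])
        if not exons:
            exons = [(s, e) for s, e, _ in cds]
        span = rec["span"] or (exons[0][0], exons[-1][1])
        tx_start, tx_end = span
        strand = rec["strand"]

        incomplete = False
        if cds:
            total = sum(e - s for s, e, _ in cds)
            if total % 3 != 0 or not _frames_consistent(cds, strand):
                incomplete = True
            # Fill frames where the GTF omitted them.
            order = cds if strand == "+" else list(reversed(cds))
            before, filled = 0, []
            for s, e, frame in order:
                filled.append((s, e, frame if frame is not None else (3 - before % 3) % 3))
                before += e - s
            cds = sorted(filled)

        features = _assemble_features(tx_start, tx_end, exons, cds, strand, contig_len)
        ntr_trunc = features[0].start > tx_start - NTR_LENGTH or features[-1].end < tx_end + NTR_LENGTH
        models.append(
            GeneModel(
                gene_id=rec["gene_id"],
                transcript_id=tid,
                contig=contig,
                strand=strand,
                chromosome=chromosome_of_contig(contig),
                tx_start=tx_start,
                tx_end=tx_end,
                features=features,
                cds_incomplete=incomplete,
                ntr_truncated=ntr_trunc,
                contig_length=contig_len,
            )
        )
    models.sort(key=lambda m: (_CHROM_RANK[m.chromosome], supercontig_order(m.contig), m.tx_start, m.transcript_id))
    return models


def _assemble_features(
    tx_start: int,
    tx_end: int,
    exons: list[tuple[int, int]],
    cds: list[tuple[int, int, int]],
    strand: str,
    contig_len: int,
) -> list[Feature]:
    feats: list[Feature] = []
    ntr_left = Feature("NTR5" if strand == "+" else "NTR3", max(0, tx_start - NTR_LENGTH), tx_start)
    ntr_right = Feature(
        "NTR3" if strand == "+" else "NTR5", tx_end, min(contig_len, tx_end + NTR_LENGTH)
    )

    cds_lo = min((s for s, _, _ in cds), default=None)
    cds_hi = max((e for _, e, _ in cds), default=None)

    # Exonic pieces split into UTR5 / CDS / UTR3 by position relative to the CDS span.
    pieces: list[Feature] = []
    for es, ee in exons:
        cursor = es
        for s, e, frame in cds:
            if e <= es or s >= ee:
                continue
            if s > cursor:
                pieces.append(Feature(_utr_kind(cursor, cds_lo, strand), cursor, s))
            pieces.append(Feature("CDS", s, e, frame))
            cursor = e
        if cursor < ee:
            kind = _utr_kind(cursor, cds_lo, strand) if cds else ("UTR5" if strand == "+" else "UTR3")
            pieces.append(Feature(kind, cursor, ee))
    pieces.sort(key=lambda f: f.start)

    # Introns fill the gaps between exons.
    feats.append(ntr_left)
    cursor = tx_start
    for es, ee in exons:
        if es > cursor:
            feats.append(Feature("intron", cursor, es))
        cursor = ee
    feats.extend(pieces)
    feats.append(ntr_right)
    feats = [f for f in feats if f.end > f.start]
    feats.sort(key=lambda f: f.start)
    return feats


def _utr_kind(pos: int, cds_lo: int | None, strand: str) -> str:
    if cds_lo is None:
        return "UTR5" if strand == "+" else "UTR3"
    upstream = pos < cds_lo
    if strand == "+":
        return "UTR5" if upstream else "UTR3"
    return "UTR3" if upstream else "UTR5"


# ---------------------------------------------------------------------------
# SNPID assignment


#: Within-gene offsets occupy the low digits of a SNPID; gene rank the high
#: digits, giving a total order (chromosome, supercontig, gene, offset).
SNPID_OFFSET_BASE = 10**6


class GeneIndex:
    """Hierarchical SNP coordinates over a set of gene models.

    Genes are ranked by (chromosome assignment, supercontig order,
    position in supercontig); a position maps to
    ``(rank + 1) * 10^6 + offset-in-window``. Positions in no gene window
    are untracked (lookup returns an empty list); positions inside two
    genes' windows are tracked once per gene.
    """

    def __init__(self, models: list[GeneModel]):
        self.models = models  # already sorted by build_gene_models
        self._rank = {m.transcript_id: i for i, m in enumerate(models)}
        self._trees: dict[str, IntervalTree] = {}
        for m in models:
            w0, w1 = m.window
            if w1 - w0 >= SNPID_OFFSET_BASE:
                raise ValueError(f"gene window of {m.transcript_id} too large for SNPID scheme")
            self._trees.setdefault(m.contig, IntervalTree()).addi(w0, w1, m)

    def snpid(self, model: GeneModel, pos: int) -> int:
        w0, _ = model.window
        if not model.contains(pos):
            raise ValueError(f"position {pos} not in window of {model.transcript_id}")
        return (self._rank[model.transcript_id] + 1) * SNPID_OFFSET_BASE + (pos - w0)

    def lookup(self, contig: str, pos: int) -> list[tuple[GeneModel, int]]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        hits = sorted(tree[pos], key=lambda iv: self._rank[iv.data.transcript_id])
        return [(iv.data, self.snpid(iv.data, pos)) for iv in hits]


def canonical_models(models: list[GeneModel]) -> list[GeneModel]:
    """One model per gene: the longest complete-CDS transcript, falling
    back to the longest transcript if none is complete."""
    by_gene: dict[str, list[GeneModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    out = []
    for gid, ms in by_gene.items():
        complete = [m for m in ms if not m.cds_incomplete and m.cds_segments]
        pool = complete or ms
        out.append(max(pool, key=lambda m: (m.cds_length, m.tx_end - m.tx_start, m.transcript_id)))
    out.sort(key=lambda m: (_CHROM_RANK[m.chromosome], supercontig_order(m.contig), m.tx_start))
    return out


class Annotator:
    """Convenience facade: gene models + genome + SNPID index."""

    def __init__(self, gtf_path: Path | str, fasta_path: Path | str, canonical: bool = True):
        all_models = build_gene_models(gtf_path, fasta_path)
        self.genome = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
        }
        self.models = canonical_models(all_models) if canonical else all_models
        self.index = GeneIndex(self.models)

    def annotate(
        self, contig: str, pos: int, ref: str, alt: str
    ) -> list[tuple[GeneModel, int, SiteAnnotation]]:
        """All gene-level records for a variant at a 0-based position."""
        out = []
        for model, snpid in self.index.lookup(contig, pos):
            out.append((model, snpid, model.annotate_site(pos, ref, alt, self.genome)))
        return out
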