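"""Gene models, SNPID ordering, region / codon-position / consequence
classification, including brute-force translation oracles."""

import numpy as np
import pytest
from Bio.Seq import Seq

from poolfst import annotation
from poolfst.annotation import (
    Annotator,
    GeneIndex,
    build_gene_models,
    canonical_models,
    classify_consequence,
    classify_mutation,
)
from poolfst.simulate import simulate_reference, simulate_study, write_fasta, write_gtf

from conftest import two_pop_config


def _write_toy(tmp_path, genome: dict[str, str], gtf_lines: list[str]):
    fasta = tmp_path / "toy.fasta"
    with open(fasta, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n{seq}\n")
    gtf = tmp_path / "toy.gtf"
    gtf.write_text("".join(line + "\n" for line in gtf_lines))
    return gtf, fasta


@pytest.fixture()
def plus_gene(tmp_path):
    """+ strand, two exons 101-150 and 201-250 (1-based), CDS 121-150 +
    201-230, on a 2000 bp contig."""
    rng = np.random.default_rng(0)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
    attrs = 'gene_id "gA"; transcript_id "gA-RA";'
    lines = [
        f"ctg\tx\ttranscript\t101\t250\t.\t+\t.\t{attrs}",
        f"ctg\tx\texon\t101\t150\t.\t+\t.\t{attrs}",
        f"ctg\tx\texon\t201\t250\t.\t+\t.\t{attrs}",
        f"ctg\tx\tCDS\t121\t150\t.\t+\t0\t{attrs}",
        f"ctg\tx\tCDS\t201\t230\t.\t+\t0\t{attrs}",
    ]
    gtf, fasta = _write_toy(tmp_path, {"ctg": seq}, lines)
    models = build_gene_models(gtf, fasta)
    return models[0], seq


class TestGeneModelConstruction:
    def test_intron_derived_from_exon_gap(self, plus_gene):
        model, _ = plus_gene
        introns = [(f.start, f.end) for f in model.features if f.kind == "intron"]
        assert introns == [(150, 200)]  # 1-based 151..200

    def test_ntr_windows_flank_transcript(self, plus_gene):
        model, _ = plus_gene
        kinds = [f.kind for f in model.features]
        assert kinds[0] == "NTR5" and kinds[-1] == "NTR3"
        assert model.features[0].end - model.features[0].start == 100  # truncated at contig start
        assert model.ntr_truncated

    def test_region_partition_covers_window_exactly(self, plus_gene):
        model, _ = plus_gene
        w0, w1 = model.window
        covered = sum(f.end - f.start for f in model.features)
        assert covered == w1 - w0
        regions = [model.classify_region(p) for p in range(w0, w1)]
        assert all(r in ("NTR5", "UTR5", "codon1", "codon2", "codon3", "intron", "UTR3", "NTR3")
                   for r in regions)

    def test_minus_strand_ntr5_at_higher_coordinates(self, tmp_path):
        rng = np.random.default_rng(1)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        attrs = 'gene_id "gB"; transcript_id "gB-RA";'
        lines = [
            f"ctg\tx\ttranscript\t1001\t1090\t.\t-\t.\t{attrs}",
            f"ctg\tx\texon\t1001\t1090\t.\t-\t.\t{attrs}",
            f"ctg\tx\tCDS\t1001\t1090\t.\t-\t0\t{attrs}",
        ]
        gtf, fasta = _write_toy(tmp_path, {"ctg": seq}, lines)
        model = build_gene_models(gtf, fasta)[0]
        ntr5 = [f for f in model.features if f.kind == "NTR5"][0]
        assert ntr5.start == 1090 and ntr5.end == 1690  # upstream on coding strand
        # first coding base (codon position 1) is the highest genomic CDS coordinate
        assert model.classify_region(1089) == "codon1"

    def test_incomplete_cds_flagged_but_regions_kept(self, tmp_path):
        seq = "A" * 1000
        attrs = 'gene_id "gC"; transcript_id "gC-RA";'
        lines = [
            f"ctg\tx\ttranscript\t301\t400\t.\t+\t.\t{attrs}",
            f"ctg\tx\texon\t301\t400\t.\t+\t.\t{attrs}",
            f"ctg\tx\tCDS\t301\t400\t.\t+\t0\t{attrs}",  # 100 bp, not divisible by 3
        ]
        gtf, fasta = _write_toy(tmp_path, {"ctg": seq}, lines)
        model = build_gene_models(gtf, fasta)[0]
        assert model.cds_incomplete
        ann = model.annotate_site(310, "A", "G", {"ctg": seq})
        assert ann.region == "codon?"
        assert ann.consequence == "not_applicable"


class TestCodonPosition:
    def test_plus_strand_frame0_positions(self, tmp_path):
        seq = "A" * 1000
        attrs = 'gene_id "gD"; transcript_id "gD-RA";'
        lines = [
            f"ctg\tx\ttranscript\t101\t190\t.\t+\t.\t{attrs}",
            f"ctg\tx\texon\t101\t190\t.\t+\t.\t{attrs}",
            f"ctg\tx\tCDS\t101\t190\t.\t+\t0\t{attrs}",
        ]
        gtf, fasta = _write_toy(tmp_path, {"ctg": seq}, lines)
        model = build_gene_models(gtf, fasta)[0]
        # 1-based genomic 101,102,103 are codon positions 1,2,3
        assert model.classify_region(100) == "codon1"
        assert model.classify_region(101) == "codon2"
        assert model.classify_region(102) == "codon3"

    def test_minus_strand_end_is_codon1(self, tmp_path):
        """- strand CDS 101-190 frame 0: genomic position 190 (1-based) is
        the first coding base. Verified by brute-force enumeration of
        coding-strand offsets."""
        seq = "A" * 1000
        attrs = 'gene_id "gE"; transcript_id "gE-RA";'
        lines = [
            f"ctg\tx\ttranscript\t101\t190\t.\t-\t.\t{attrs}",
            f"ctg\tx\texon\t101\t190\t.\t-\t.\t{attrs}",
            f"ctg\tx\tCDS\t101\t190\t.\t-\t0\t{attrs}",
        ]
        gtf, fasta = _write_toy(tmp_path, {"ctg": seq}, lines)
        model = build_gene_models(gtf, fasta)[0]
        assert model.classify_region(189) == "codon1"
        # brute force: offset k from the 3'-most genomic base
        for pos in range(100, 190):
            offset = 189 - pos
            expected = f"codon{offset % 3 + 1}"
            assert model.classify_region(pos) == expected


class TestMutationClassification:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("A", "G", "transition"),
            ("C", "T", "transition"),
            ("A", "T", "transversion"),
            ("G", "C", "transversion"),
            ("A", "+AG", "insertion"),
            ("A", "-T", "deletion"),
        ],
    )
    def test_examples(self, ref, alt, expected):
        assert classify_mutation(ref, alt) == expected

    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError, match="not a variant"):
            classify_mutation("A", "A")


class TestConsequence:
    @pytest.mark.parametrize(
        "codon,pos,alt,expected",
        [
            ("GGA", 3, "G", "silent"),  # Gly -> Gly
            ("AAA", 1, "G", "replacement"),  # Lys -> Glu
            ("TGG", 3, "A", "replacement"),  # Trp -> stop (nonsense = replacement)
        ],
    )
    def test_examples(self, codon, pos, alt, expected):
        assert classify_consequence(codon, pos, alt) == expected

    def test_codon_with_n_not_callable(self):
        assert classify_consequence("GNA", 3, "G") == "not_applicable"

    def test_agrees_with_full_cds_translation(self, tmp_path):
        """Oracle: mutate the whole CDS, translate both proteins with
        biopython, and compare; must match the per-codon call at every
        coding position of random toy transcripts."""
        fx = simulate_study(two_pop_config(seed=21, n_genes=6), tmp_path)
        ann = Annotator(fx.gtf, fx.fasta)
        checked = 0
        for model in ann.models:
            cds = model.cds_sequence(ann.genome)
            protein = str(Seq(cds).translate())
            for f in model.cds_segments:
                for pos in range(f.start, f.end):
                    ref = ann.genome[model.contig][pos]
                    alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref]
                    result = model.annotate_site(pos, ref, alt, ann.genome)
                    off = model.coding_offset(pos)
                    alt_coding = alt if model.strand == "+" else str(Seq(alt).complement())
                    mutated = cds[:off] + alt_coding + cds[off + 1 :]
                    expected = (
                        "silent"
                        if str(Seq(mutated).translate()) == protein
                        else "replacement"
                    )
                    assert result.consequence == expected
                    checked += 1
        assert checked > 500

    def test_strand_involution(self, tmp_path):
        """Reverse-complementing the genome and flipping strands leaves
        every consequence call unchanged."""
        fx = simulate_study(two_pop_config(seed=22, n_genes=4), tmp_path / "fwd")
        ann = Annotator(fx.gtf, fx.fasta)

        # Build the mirrored reference: coordinates x -> L - x.
        rc_dir = tmp_path / "rc"
        rc_dir.mkdir()
        genome_rc = {c: str(Seq(s).reverse_complement()) for c, s in ann.genome.items()}
        fasta_rc = rc_dir / "genome.fasta"
        with open(fasta_rc, "w") as fh:
            for c, s in genome_rc.items():
                fh.write(f">{c}\n{s}\n")
        gtf_rc = rc_dir / "annotation.gtf"
        with open(fx.gtf) as fh, open(gtf_rc, "w") as out:
            for line in fh:
                f = line.rstrip("\n").split("\t")
                L = len(ann.genome[f[0]])
                s, e = int(f[3]), int(f[4])
                f[3], f[4] = str(L - e + 1), str(L - s + 1)
                f[6] = "-" if f[6] == "+" else "+"
                out.write("\t".join(f) + "\n")
        ann_rc = Annotator(gtf_rc, fasta_rc)
        models_rc = {m.transcript_id: m for m in ann_rc.models}

        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        checked = 0
        for model in ann.models:
            L = len(ann.genome[model.contig])
            mirror = models_rc[model.transcript_id]
            for f in model.cds_segments:
                for pos in range(f.start, f.end, 7):
                    ref = ann.genome[model.contig][pos]
                    alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref]
                    fwd = model.annotate_site(pos, ref, alt, ann.genome)
                    pos_rc = L - pos - 1
                    rc = mirror.annotate_site(pos_rc, comp[ref], comp[alt], ann_rc.genome)
                    assert fwd.consequence == rc.consequence
                    assert fwd.region == rc.region
                    checked += 1
        assert checked > 100


@pytest.fixture(scope="module")
def annotator(tmp_path_factory):
    fx = simulate_study(two_pop_config(seed=23, n_genes=10), tmp_path_factory.mktemp("ann"))
    return Annotator(fx.gtf, fx.fasta)


class TestSnpIdOrdering:
    def test_within_gene_offsets_order(self, annotator):
        m = annotator.models[0]
        w0, _ = m.window
        assert annotator.index.snpid(m, w0 + 5) < annotator.index.snpid(m, w0 + 9)

    def test_gene_order_dominates(self, annotator):
        m1, m2 = annotator.models[0], annotator.models[1]
        last_of_first = annotator.index.snpid(m1, m1.window[1] - 1)
        first_of_second = annotator.index.snpid(m2, m2.window[0])
        assert last_of_first < first_of_second

    def test_chromosome_rank_dominates_contig(self, annotator):
        ranks = [( {"1": 0, "2": 1, "3": 2, "unmapped": 3}[m.chromosome]) for m in annotator.models]
        assert ranks == sorted(ranks)

    def test_lookup_deterministic_and_intergenic_untracked(self, annotator):
        m = annotator.models[0]
        pos = m.window[0] + 3
        first = annotator.index.lookup(m.contig, pos)
        second = annotator.index.lookup(m.contig, pos)
        assert [(mm.transcript_id, sid) for mm, sid in first] == [
            (mm.transcript_id, sid) for mm, sid in second
        ]
        assert annotator.index.lookup("nope", 5) == []

    def test_canonical_prefers_complete_cds(self, tmp_path):
        seq = "A" * 2000
        a1 = 'gene_id "g"; transcript_id "g-RA";'
        a2 = 'gene_id "g"; transcript_id "g-RB";'
        lines = [
            f"ctg\tx\ttranscript\t101\t200\t.\t+\t.\t{a1}",
            f"ctg\tx\texon\t101\t200\t.\t+\t.\t{a1}",
            f"ctg\tx\tCDS\t101\t200\t.\t+\t0\t{a1}",  # 100 bp -> incomplete
            f"ctg\tx\ttranscript\t101\t190\t.\t+\t.\t{a2}",
            f"ctg\tx\texon\t101\t190\t.\t+\t.\t{a2}",
            f"ctg\tx\tCDS\t101\t190\t.\t+\t0\t{a2}",  # 90 bp -> complete
        ]
        gtf, fasta = _write_toy(tmp_path, {"ctg": seq}, lines)
        models = build_gene_models(gtf, fasta)
        canon = canonical_models(models)
        assert len(canon) == 1 and canon[0].transcript_id == "g-RB"
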