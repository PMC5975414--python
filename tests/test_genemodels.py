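import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicevis.genemodels import (
    FeatureIDError,
    GenomicInterval,
    GeneModel,
    GTFParseError,
    TranscriptModel,
    annotate_features,
    feature_interval,
    parse_feature_id,
    read_gene_models,
    resolve_gene,
    to_bed12,
    write_gtf,
)


def _gtf(tmp_path, text, name="test.gtf"):
    p = tmp_path / name
    p.write_text(text)
    return p


GTF_ONE_TX = (
    'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
    'chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
)


class TestReadGeneModels:
    def test_coordinates_converted_to_zero_based_half_open(self, tmp_path):
        genes = read_gene_models(_gtf(tmp_path, GTF_ONE_TX))
        (gene,) = genes
        (tx,) = gene.transcripts
        assert [(e.start, e.end) for e in tx.exons] == [(100, 200), (300, 400)]
        assert tx.span.start == 100 and tx.span.end == 400

    def test_empty_file_gives_empty_list(self, tmp_path):
        assert read_gene_models(_gtf(tmp_path, "")) == []

    def test_fixture_gtf_matches_manifest(self, multigene_cohort):
        _cfg, manifest = multigene_cohort
        genes = read_gene_models(manifest["models"]["gtf"])
        expected = manifest["models"]["genes"]
        assert len(genes) == len(expected) == 3
        assert sum(len(g.transcripts) for g in genes) == 6
        by_id = {g.gene_id: g for g in genes}
        for entry in expected:
            gene = by_id[entry["gene_id"]]
            assert gene.symbol == entry["symbol"]
            got = {t.transcript_id: len(t.exons) for t in gene.transcripts}
            want = {t["transcript_id"]: t["n_exons"] for t in entry["transcripts"]}
            assert got == want

    def test_malformed_line_error_names_line_number(self, tmp_path):
        bad = GTF_ONE_TX + "chr1\tbroken line without nine fields\n"
        with pytest.raises(GTFParseError, match="line 3"):
            read_gene_models(_gtf(tmp_path, bad))

    def test_non_integer_coordinates_rejected(self, tmp_path):
        bad = 'chr1\tsrc\texon\tabc\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        with pytest.raises(GTFParseError, match="line 1"):
            read_gene_models(_gtf(tmp_path, bad))

    def test_exonless_transcript_skipped_with_warning(self, tmp_path):
        text = (
            'chr1\tsrc\ttranscript\t1\t500\t.\t+\t.\tgene_id "g1"; transcript_id "t9";\n'
            + GTF_ONE_TX
        )
        with pytest.warns(UserWarning, match="t9"):
            genes = read_gene_models(_gtf(tmp_path, text))
        assert [t.transcript_id for t in genes[0].transcripts] == ["t1"]

    def test_transcript_shared_by_two_genes_is_error(self, tmp_path):
        text = (
            GTF_ONE_TX
            + 'chr1\tsrc\texon\t501\t600\t.\t+\t.\tgene_id "g2"; transcript_id "t1";\n'
        )
        with pytest.raises(GTFParseError, match="t1"):
            read_gene_models(_gtf(tmp_path, text))

    def test_bookended_and_duplicate_exons_merged(self, tmp_path):
        text = (
            'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\tsrc\texon\t201\t300\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        genes = read_gene_models(_gtf(tmp_path, text))
        (tx,) = genes[0].transcripts
        assert [(e.start, e.end) for e in tx.exons] == [(100, 300)]

    def test_roundtrip_through_gtf_dialect(self, tmp_path, multigene_cohort):
        _cfg, manifest = multigene_cohort
        genes = read_gene_models(manifest["models"]["gtf"])
        out = tmp_path / "roundtrip.gtf"
        write_gtf(genes, out)
        again = read_gene_models(out)
        assert again == genes

    def test_bed12_has_one_line_per_transcript(self, multigene_cohort):
        _cfg, manifest = multigene_cohort
        genes = read_gene_models(manifest["models"]["gtf"])
        lines = to_bed12(genes).strip().split("\n")
        assert len(lines) == sum(len(g.transcripts) for g in genes)
        first = lines[0].split("\t")
        assert len(first) == 12 and first[0] == "chr1"


class TestFeatureIDGrammar:
    @pytest.mark.parametrize(
        "fid, kind, coords",
        [
            ("chr1:1000-1099:+", "exon", [(999, 1099)]),
            ("chr7:6414154-6414183:+", "exon", [(6414153, 6414183)]),
            ("chrX:5-5:-", "exon", [(4, 5)]),
            ("chr1:1099:+,chr1:2000:+", "junction", [(1098, 1099), (1999, 2000)]),
        ],
    )
    def test_valid_ids(self, fid, kind, coords):
        got_kind, parts = parse_feature_id(fid)
        assert got_kind == kind
        assert [(p.start, p.end) for p in parts] == coords

    @pytest.mark.parametrize(
        "fid",
        ["chr1:banana", "chr1:10-5:+", "chr1:100:+", "chr1:1:+,chr1:2:+,chr1:3:+", ""],
    )
    def test_invalid_ids_error_with_grammar(self, fid):
        with pytest.raises(FeatureIDError, match="grammar|end precedes"):
            parse_feature_id(fid)


def _gene_two_tx():
    t1 = TranscriptModel(
        "t1", "g", (GenomicInterval("chr1", 100, 200, "+"), GenomicInterval("chr1", 400, 500, "+"))
    )
    t2 = TranscriptModel("t2", "g", (GenomicInterval("chr1", 450, 800, "+"),))
    return GeneModel("g", "G", (t1, t2))


class TestAnnotateFeatures:
    def test_exon_inside_one_span_only(self):
        gene = _gene_two_tx()
        feats = [("f", "exon", (GenomicInterval("chr1", 150, 180, "+"),))]
        (ann,) = annotate_features(feats, gene)
        assert ann.gene_id == "g" and ann.transcript_ids == ("t1",)

    def test_exon_outside_all_spans_unassigned(self):
        gene = _gene_two_tx()
        feats = [("f", "exon", (GenomicInterval("chr1", 900, 950, "+"),))]
        (ann,) = annotate_features(feats, gene)
        assert ann.gene_id is None and ann.transcript_ids == ()

    def test_wrong_chromosome_is_unassigned_not_error(self):
        gene = _gene_two_tx()
        feats = [("f", "exon", (GenomicInterval("chr2", 150, 180, "+"),))]
        (ann,) = annotate_features(feats, gene)
        assert ann.gene_id is None

    def test_strand_mismatch_excludes_known_vs_known(self):
        gene = _gene_two_tx()
        minus = [("f", "exon", (GenomicInterval("chr1", 150, 180, "-"),))]
        unknown = [("f", "exon", (GenomicInterval("chr1", 150, 180, "."),))]
        assert annotate_features(minus, gene)[0].gene_id is None
        assert annotate_features(unknown, gene)[0].transcript_ids == ("t1",)

    def test_junction_requires_both_anchors_in_span(self):
        gene = _gene_two_tx()
        inside = [
            ("j1", "junction",
             (GenomicInterval("chr1", 199, 200, "+"), GenomicInterval("chr1", 400, 401, "+"))),
        ]
        half_out = [
            ("j2", "junction",
             (GenomicInterval("chr1", 199, 200, "+"), GenomicInterval("chr1", 600, 601, "+"))),
        ]
        assert annotate_features(inside, gene)[0].transcript_ids == ("t1",)
        # donor in t1 only, acceptor in t2 only: no transcript holds both
        assert annotate_features(half_out, gene)[0].gene_id is None

    def test_output_order_matches_input_order(self):
        gene = _gene_two_tx()
        feats = [
            ("b", "exon", (GenomicInterval("chr1", 460, 470, "+"),)),
            ("a", "exon", (GenomicInterval("chr1", 110, 120, "+"),)),
        ]
        anns = annotate_features(feats, gene)
        assert [a.feature_id for a in anns] == ["b", "a"]


def _brute_force(features, gene):
    """All-pairs overlap oracle mirroring the documented assignment rule."""
    out = []
    for _fid, kind, parts in features:
        iv = feature_interval(kind, parts)
        hits = []
        for tx in gene.transcripts:
            span = tx.span
            if iv.chrom != span.chrom or not span.strands_compatible(iv):
                continue
            if kind == "exon":
                ok = iv.start < span.end and span.start < iv.end
            else:
                ok = all(
                    span.start <= a.start and a.end <= span.end for a in parts
                )
            if ok:
                hits.append(tx.transcript_id)
        out.append(tuple(hits))
    return out


@st.composite
def _random_case(draw):
    n_tx = draw(st.integers(1, 5))
    txs = []
    for i in range(n_tx):
        start = draw(st.integers(0, 500))
        length = draw(st.integers(10, 400))
        strand = draw(st.sampled_from(["+", "-"]))
        txs.append(
            TranscriptModel(
                f"t{i}", "g", (GenomicInterval("chr1", start, start + length, strand),)
            )
        )
    gene = GeneModel("g", "G", tuple(txs))
    feats = []
    for i in range(draw(st.integers(1, 50))):
        strand = draw(st.sampled_from(["+", "-", "."]))
        if draw(st.booleans()):
            s = draw(st.integers(0, 900))
            e = s + draw(st.integers(1, 200))
            feats.append((f"f{i}", "exon", (GenomicInterval("chr1", s, e, strand),)))
        else:
            a = draw(st.integers(0, 900))
            b = a + draw(st.integers(1, 300))
            feats.append(
                (
                    f"f{i}",
                    "junction",
                    (
                        GenomicInterval("chr1", a, a + 1, strand),
                        GenomicInterval("chr1", b, b + 1, strand),
                    ),
                )
            )
    return feats, gene


class TestAnnotationProperties:
    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(_random_case())
    def test_matches_brute_force_all_pairs_oracle(self, case):
        feats, gene = case
        anns = annotate_features(feats, gene)
        assert [a.transcript_ids for a in anns] == [
            tuple(h) for h in _brute_force(feats, gene)
        ]

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(_random_case(), st.integers(1, 50), st.integers(1, 50))
    def test_enlarging_an_exon_feature_never_shrinks_assignment(
        self, case, grow_left, grow_right
    ):
        feats, gene = case
        exons = [f for f in feats if f[1] == "exon"]
        if not exons:
            return
        fid, kind, (iv,) = exons[0]
        bigger = GenomicInterval(
            iv.chrom, max(0, iv.start - grow_left), iv.end + grow_right, iv.strand
        )
        before = set(annotate_features([(fid, kind, (iv,))], gene)[0].transcript_ids)
        after = set(annotate_features([(fid, kind, (bigger,))], gene)[0].transcript_ids)
        assert before <= after


class TestResolveGene:
    def _genes(self, multigene_cohort):
        _cfg, manifest = multigene_cohort
        return read_gene_models(manifest["models"]["gtf"])

    def test_symbol_id_and_alias_paths_agree(self, multigene_cohort):
        genes = self._genes(multigene_cohort)
        assert (
            resolve_gene(genes, "GENE2")
            is resolve_gene(genes, "1002")
            is resolve_gene(genes, "gene2")
            is resolve_gene(genes, "SYN2")
        )

    def test_unknown_symbol_lists_nearest(self, multigene_cohort):
        genes = self._genes(multigene_cohort)
        with pytest.raises(KeyError, match="GENE"):
            resolve_gene(genes, "NOSUCH")


class TestIntervalInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"chrom": "", "start": 0, "end": 1},
            {"chrom": "chr1", "start": -1, "end": 5},
            {"chrom": "chr1", "start": 5, "end": 5},
            {"chrom": "chr1", "start": 0, "end": 1, "strand": "?"},
        ],
    )
    def test_invalid_intervals_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GenomicInterval(**kwargs)

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            TranscriptModel(
                "t",
                "g",
                (
                    GenomicInterval("chr1", 0, 100),
                    GenomicInterval("chr1", 50, 150),
                ),
            )
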