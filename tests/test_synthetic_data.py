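import json

import numpy as np
import pytest

from mirduplex import (
    SiteSpec,
    align_duplex,
    filter_by_expression,
    gen_expression,
    gen_library,
    gen_transcriptome,
    read_gff3_exons,
    search_targets,
    write_transcriptome,
)
from mirduplex.sequences import MIR396A
from types import SimpleNamespace


class TestTranscriptome:
    def test_same_seed_reproduces_byte_identical_output(self, mir396a):
        specs = [SiteSpec(), SiteSpec(mismatches=2)]
        a, ta = gen_transcriptome(mir396a, 3, specs, seed=7, transcript_length=120)
        b, tb = gen_transcriptome(mir396a, 3, specs, seed=7, transcript_length=120)
        assert [t.spliced_seq for t in a] == [t.spliced_seq for t in b]
        assert ta.data["sites"] == tb.data["sites"]

    def test_different_seed_changes_background(self, mir396a):
        a, _ = gen_transcriptome(mir396a, 2, [], seed=1, transcript_length=120)
        b, _ = gen_transcriptome(mir396a, 2, [], seed=2, transcript_length=120)
        assert a[0].spliced_seq.seq != b[0].spliced_seq.seq

    def test_planted_sites_realize_their_closed_form_scores(self, mir396a):
        specs = [SiteSpec(), SiteSpec(mismatches=2, wobbles=1),
                 SiteSpec(mismatches=1, bulge="target")]
        txs, truth = gen_transcriptome(mir396a, 3, specs, seed=13,
                                       transcript_length=120)
        for planted, spec in zip(truth.data["sites"], specs):
            assert planted.score == spec.expected_score()
            tx = next(t for t in txs if t.id == planted.transcript_id)
            window = tx.spliced_seq.seq[planted.start - 1: planted.end]
            assert align_duplex(mir396a, window).score == spec.expected_score()

    def test_grf2_style_spec_reproduces_the_bulge_architecture(self, mir396a):
        specs = [SiteSpec(bulge="target", bulge_position=(7, 8))]
        _, truth = gen_transcriptome(mir396a, 1, specs, seed=3,
                                     transcript_length=120)
        assert truth.data["sites"][0].bulge_positions == (("target", 7),)

    def test_decoys_leave_no_window_under_the_cap(self, mir396a):
        specs = [SiteSpec(mismatches=6, decoy=True)]
        txs, truth = gen_transcriptome(mir396a, 1, specs, seed=21,
                                       transcript_length=120)
        assert truth.data["sites"] == []
        assert search_targets(mir396a, txs) == []

    def test_junction_spec_records_boundary_inside_site(self, mir396a):
        specs = [SiteSpec(junction_split=10)]
        txs, truth = gen_transcriptome(mir396a, 1, specs, seed=2,
                                       transcript_length=120)
        planted = truth.data["sites"][0]
        (junction,) = txs[0].junctions
        assert planted.start - 1 < junction < planted.end
        assert planted.spans_junction

    def test_more_specs_than_transcripts_rejected(self, mir396a):
        with pytest.raises(ValueError, match="more site specs"):
            gen_transcriptome(mir396a, 1, [SiteSpec(), SiteSpec()], seed=0)

    def test_gff3_roundtrip_reproduces_spliced_sequences(self, mir396a, tmp_path):
        specs = [SiteSpec(junction_split=14), SiteSpec()]
        txs, truth = gen_transcriptome(mir396a, 2, specs, seed=4,
                                       transcript_length=120)
        paths = write_transcriptome(txs, truth, tmp_path, seed=4)
        models = read_gff3_exons(paths["gff"], paths["genome"])
        by_id = {m.id: m for m in models}
        for t in txs:
            if len(t.exon_lengths) > 1:
                assert by_id[t.id].spliced_seq.seq == t.spliced_seq.seq
                assert by_id[t.id].junctions == t.junctions
        assert json.loads(paths["truth"].read_text())["kind"] == "transcriptome"


class TestExpression:
    def test_zero_noise_puts_true_targets_exactly_at_their_fold(self):
        expr, truth = gen_expression(["a", "b", "c"], ["b"], noise_sd=0.0, seed=5)
        fold = truth.data["folds"]["b"]["hyl1"]
        assert expr.table.loc["b"].tolist() == [fold] * 3
        assert expr.table.loc["a"].tolist() == [1.0] * 3

    def test_fold_range_below_threshold_passes_nothing(self):
        expr, _ = gen_expression([f"g{i}" for i in range(10)], ["g1"],
                                 fold_range=(1.05, 1.25), seed=0)
        sites = [SimpleNamespace(transcript_id=g) for g in expr.genes]
        assert not any(t.passes for t in filter_by_expression(sites, expr))

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            gen_expression(["a"], [], noise_sd=-0.1)

    def test_unknown_true_target_rejected(self):
        with pytest.raises(ValueError, match="not in gene list"):
            gen_expression(["a"], ["zzz"])

    def test_realized_true_folds_lie_inside_the_range(self):
        expr, truth = gen_expression([f"g{i}" for i in range(17)], ["g0", "g8"],
                                     seed=99)
        for gene in ("g0", "g8"):
            assert all(1.3 <= fc <= 2.0 for fc in expr.table.loc[gene])


class TestLibrary:
    def test_single_variant_proportions(self):
        reads, _ = gen_library([MIR396A], [1.0], 50, seed=0)
        assert len(reads) == 50
        assert {r.seq for r in reads} == {MIR396A}

    def test_all_zero_trim_profile_gives_exact_lengths(self):
        reads, _ = gen_library([MIR396A], [1.0], 30, {0: 1.0}, seed=1)
        assert {len(r.seq) for r in reads} == {len(MIR396A)}

    def test_trim_profile_produces_length_heterogeneity(self):
        reads, _ = gen_library([MIR396A], [1.0], 200,
                               {0: 0.5, -1: 0.25, 1: 0.25}, seed=1)
        lengths = {len(r.seq) for r in reads}
        assert lengths == {len(MIR396A) - 1, len(MIR396A), len(MIR396A) + 1}

    def test_negative_proportion_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            gen_library([MIR396A, MIR396A], [1.5, -0.5], 10)

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            gen_library([MIR396A], [0.8], 10)

    def test_multinomial_recovery_within_three_standard_errors(self):
        from mirduplex import RnaSequence, count_variant_reads
        from mirduplex.sequences import MIR396B_7AG, MIR396_78INSG

        variants = [RnaSequence("a", MIR396A), RnaSequence("i", MIR396_78INSG),
                    RnaSequence("s", MIR396B_7AG)]
        props = [0.70, 0.25, 0.05]
        depth = 10_000
        reads, truth = gen_library(variants, props, depth,
                                   {0: 0.7, -1: 0.15, -2: 0.05, 1: 0.1}, seed=8)
        res = count_variant_reads(reads, variants)
        ab = {c.variant_id: c.abundance for c in res}
        for v, p in zip(variants, props):
            se = np.sqrt(p * (1 - p) / depth)
            assert abs(ab[v.id] - p) <= 3 * se
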