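"""Window extraction, structural classification and stability surrogates."""

import pytest

from g4snv.io_formats import SNV, GenomeSequence, revcomp
from g4snv.g4_detection import scan_genome
from g4snv.variant_effects import (
    NullBackend,
    SurrogateBackend,
    WindowPair,
    analyze_variants,
    classify_structural,
    compute_stability,
    extract_windows,
    surrogate_fold,
)

MOTIF = "GGGAGGGTGGGCGGG"


def _genome_with(insert, offset=40, total=300):
    seq = "ATTA" * (offset // 4) + insert
    seq = seq + "TAAT" * ((total - len(seq)) // 4 + 1)
    return GenomeSequence(["chr1"], {"chr1": seq[:total]})


class TestExtractWindows:
    genome = GenomeSequence(["chr1"], {"chr1": "ACGT" * 75})

    def test_untruncated(self):
        snv = SNV("chr1", 100, "A", "G")
        pair = extract_windows(self.genome, snv)
        assert len(pair.ref_window) == 61
        assert pair.variant_offset == 30
        assert not (pair.truncated_left or pair.truncated_right)
        assert pair.alt_window[30] == "G" and pair.ref_window[30] == "A"
        assert sum(a != b for a, b in zip(pair.ref_window, pair.alt_window)) == 1

    def test_left_truncation(self):
        snv = SNV("chr1", 10, "G", "T")
        pair = extract_windows(self.genome, snv)
        assert len(pair.ref_window) == 41
        assert pair.variant_offset == 10
        assert pair.truncated_left and not pair.truncated_right

    def test_ref_mismatch_errors(self):
        with pytest.raises(ValueError, match="ref mismatch"):
            extract_windows(self.genome, SNV("chr1", 100, "G", "T"))

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            extract_windows(self.genome, SNV("chr1", 400, "A", "G"))


class TestClassifyStructural:
    def test_tract_break_is_loss(self):
        genome = _genome_with(MOTIF)
        # middle G of the second tract (offset 40+5)
        snv = SNV("chr1", 45, "G", "A")
        cls = classify_structural(extract_windows(genome, snv))
        assert cls.value == "loss"
        assert (cls.strand_state_before, cls.strand_state_after) == ("+", "0")

    def test_fourth_tract_completion_is_gain(self):
        genome = _genome_with("GGGAGGGTGGGCGTG")
        snv = SNV("chr1", 53, "T", "G")  # the T of the defective GTG tract
        cls = classify_structural(extract_windows(genome, snv))
        assert cls.value == "gain"
        assert (cls.strand_state_before, cls.strand_state_after) == ("0", "+")

    def test_loop_substitution_is_retained(self):
        genome = _genome_with(MOTIF)
        snv = SNV("chr1", 43, "A", "T")  # the loop A between tracts 1 and 2
        cls = classify_structural(extract_windows(genome, snv))
        assert cls.value == "retained"
        assert (cls.strand_state_before, cls.strand_state_after) == ("+", "+")

    def test_minus_strand_loss(self):
        genome = _genome_with(revcomp(MOTIF))
        # break a C-tract: any C in the plus-strand sequence center
        pos = 40 + revcomp(MOTIF).index("CCC") + 1
        snv = SNV("chr1", pos, "C", "T")
        cls = classify_structural(extract_windows(genome, snv))
        assert cls.value == "loss"
        assert cls.strand_state_before == "-"

    def test_reverse_complement_symmetry(self):
        genome = _genome_with(MOTIF)
        snv = SNV("chr1", 45, "G", "A")
        pair = extract_windows(genome, snv)
        mirrored = WindowPair(
            chrom=pair.chrom,
            start=pair.start,
            ref_window=revcomp(pair.ref_window),
            alt_window=revcomp(pair.alt_window),
            variant_offset=len(pair.ref_window) - 1 - pair.variant_offset,
        )
        fwd, rev = classify_structural(pair), classify_structural(mirrored)
        swap = {"+": "-", "-": "+", "0": "0", "+-": "+-"}
        assert rev.value == fwd.value
        assert rev.strand_state_before == swap[fwd.strand_state_before]
        assert rev.strand_state_after == swap[fwd.strand_state_after]


@pytest.mark.parametrize(
    "seq,expected",
    [("AAAA", (0.0, 0)), ("GGGG", (-8.0, 1)), ("GGGAGGG", (-9.0, 2))],
)
def test_surrogate_fold_examples(seq, expected):
    assert surrogate_fold(seq) == expected


def test_surrogate_fold_uses_g_rich_orientation():
    # C-rich input is scored on its reverse complement
    assert surrogate_fold("CCCC") == surrogate_fold("GGGG")


def test_surrogate_fold_empty_errors():
    with pytest.raises(ValueError):
        surrogate_fold("")


class TestComputeStability:
    def test_null_backend_no_change(self):
        genome = _genome_with(MOTIF)
        pair = extract_windows(genome, SNV("chr1", 45, "G", "A"))
        result = compute_stability(pair, NullBackend())
        assert result.delta_mfe == 0.0
        assert result.stability_class == "no_change"

    def test_loss_destabilizes_under_surrogate(self):
        genome = _genome_with(MOTIF)
        pair = extract_windows(genome, SNV("chr1", 45, "G", "A"))
        result = compute_stability(pair, SurrogateBackend())
        assert result.delta_mfe > 0
        assert result.stability_class == "destabilized"

    def test_gain_stabilizes_under_surrogate(self):
        genome = _genome_with("GGGAGGGTGGGCGTG")
        pair = extract_windows(genome, SNV("chr1", 53, "T", "G"))
        result = compute_stability(pair, SurrogateBackend())
        assert result.delta_mfe < 0
        assert result.stability_class == "further_stabilized"

    def test_backend_failure_flags_unscored(self):
        class Broken:
            def fold(self, seq):
                raise RuntimeError("boom")

        genome = _genome_with(MOTIF)
        pair = extract_windows(genome, SNV("chr1", 45, "G", "A"))
        assert compute_stability(pair, Broken()).stability_class == "unscored"


class TestAnalyzeVariants:
    def test_three_planted_classes(self):
        genome = _genome_with(MOTIF + "T" * 30 + "GGGAGGGTGGGCGTG", offset=40, total=400)
        regions = scan_genome(genome)
        snvs = [
            SNV("chr1", 45, "G", "A", id="loss1"),
            SNV("chr1", 43, "A", "T", id="neut1"),
            SNV("chr1", 40 + 45 + 13, "T", "G", id="gain1"),
        ]
        effects, counts = analyze_variants(genome, snvs, regions, backend=SurrogateBackend())
        by_id = {e.snv.id: e for e in effects}
        assert by_id["loss1"].structural.value == "loss"
        assert by_id["neut1"].structural.value == "retained"
        assert by_id["gain1"].structural.value == "gain"
        assert counts["loss"] + counts["gain"] + counts["retained"] == len(effects)
        # the gained region is reported where the new motif sits
        g = by_id["gain1"].g4
        assert g.source == "predicted_alt" and g.start == 40 + 45

    def test_empty_snv_list(self):
        genome = _genome_with(MOTIF)
        effects, counts = analyze_variants(genome, [], scan_genome(genome))
        assert effects == [] and counts["snvs_total"] == 0

    def test_distant_non_g_snv_emits_nothing(self):
        genome = _genome_with(MOTIF, total=400)
        snvs = [SNV("chr1", 300, genome["chr1"][300], "T" if genome["chr1"][300] != "T" else "A")]
        effects, _ = analyze_variants(genome, snvs, scan_genome(genome))
        assert effects == []

    def test_unknown_chromosome_counted(self):
        genome = _genome_with(MOTIF)
        effects, counts = analyze_variants(
            genome, [SNV("chrX", 10, "A", "G")], scan_genome(genome)
        )
        assert effects == [] and counts["snvs_skipped_unknown_chrom"] == 1

    def test_idempotent_output(self, tmp_path):
        from g4snv.io_formats import write_effects_table

        genome = _genome_with(MOTIF, total=400)
        regions = scan_genome(genome)
        snvs = [SNV("chr1", 45, "G", "A"), SNV("chr1", 43, "A", "T")]
        p1, p2 = tmp_path / "1.tsv", tmp_path / "2.tsv"
        for p in (p1, p2):
            effects, _ = analyze_variants(genome, snvs, regions, backend=SurrogateBackend())
            write_effects_table(effects, str(p))
        assert p1.read_bytes() == p2.read_bytes()
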