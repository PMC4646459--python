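"""Feature annotation: CpG statistics, motif/PWM scanning, repeats, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dmrscan.features import (FeatureCatalog, FeatureSpec, GenomeSequence,
                              GenomicWindow, RepeatAnnotation, count_cpg,
                              count_motif_hits, count_pwm_hits,
                              count_repeat_overlaps, cpg_density,
                              default_catalog, extract_feature_matrix,
                              extract_features, pwm_log_odds,
                              read_feature_matrix, reverse_complement,
                              write_feature_matrix)

DNA = st.text(alphabet="ACGTacgtN", min_size=0, max_size=200)


def one_hot_pwm(pattern):
    pwm = np.zeros((4, len(pattern)))
    for j, base in enumerate(pattern):
        pwm["ACGT".index(base), j] = 1.0
    return pwm


class TestCpG:
    @pytest.mark.parametrize("seq,expected", [
        ("ACGT", 1), ("CGCGCG", 3), ("AAAA", 0), ("", 0),
        ("acgt", 1), ("CNG", 0), ("CGCG", 2),
    ])
    def test_count(self, seq, expected):
        assert count_cpg(seq) == expected

    @pytest.mark.parametrize("seq,expected", [
        ("CG", 50.0), ("CG" * 5 + "A" * 90, 5.0),
        ("A" * 990 + "CG" * 5, 0.5),
    ])
    def test_density(self, seq, expected):
        assert cpg_density(seq) == pytest.approx(expected)

    def test_density_empty_is_degenerate(self):
        with pytest.raises(ValueError):
            cpg_density("")

    @given(seq=DNA.filter(lambda s: len(s) > 0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_density_bounded(self, seq):
        # a CG dinucleotide occupies 2 bp, so density cannot exceed 50/100bp
        assert 0.0 <= cpg_density(seq) <= 50.0


class TestMotif:
    @pytest.mark.parametrize("seq,pattern,both,expected", [
        ("CCGGCCGG", "CCGG", False, 2),
        ("ACCGGT", "CCGG", True, 1),     # palindromic: no double count
        ("GAATTC", "TCGG", True, 0),
        ("AAAA", "AA", False, 3),        # overlapping starts all counted
        ("ACGTACGT", "RCGY", False, 2),  # degenerate IUPAC symbols
        ("CCGA", "TCGG", True, 1),       # reverse-complement strand hit
        ("ANAA", "AA", False, 1),        # N never matches
    ])
    def test_counts(self, seq, pattern, both, expected):
        assert count_motif_hits(seq, pattern, both) == expected

    def test_invalid_symbol(self):
        with pytest.raises(ValueError):
            count_motif_hits("ACGT", "AXG")

    @given(seq=DNA)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_palindrome_no_double_count(self, seq):
        for pattern in ("CCGG", "GCGC", "ACGT"):
            assert (count_motif_hits(seq, pattern, True)
                    == count_motif_hits(seq, pattern, False))

    def test_reverse_complement_involution(self):
        for pattern in ("CCGG", "TCGG", "RYSWKM", "NNAC"):
            assert reverse_complement(reverse_complement(pattern)) == pattern


class TestPWM:
    def test_one_hot_exact_match(self):
        pwm = one_hot_pwm("CCGG")
        assert count_pwm_hits("CCGG", pwm, 1.0) == 1
        assert count_pwm_hits("AAAA", pwm, 1.0) == 0

    def test_one_hot_equals_exact_pattern_scan(self, rng):
        # threshold 1.0 one-hot PWM scanning reduces to exact IUPAC counts
        for _ in range(200):
            pattern = "".join(rng.choice(list("ACGT"),
                                         size=rng.integers(3, 7)))
            seq = "".join(rng.choice(list("ACGT"), size=60))
            assert (count_pwm_hits(seq, one_hot_pwm(pattern), 1.0)
                    == count_motif_hits(seq, pattern, True))

    def test_matches_bruteforce_scoring(self, rng):
        # independent oracle: score every offset on both strands explicitly
        for trial in range(20):
            pwm = rng.random((4, 3)) + 0.01
            seq = "".join(rng.choice(list("ACGT"), size=50))
            frac = 0.8
            lo = pwm_log_odds(pwm)
            smin, smax = lo.min(axis=0).sum(), lo.max(axis=0).sum()
            thr = smin + frac * (smax - smin)

            def hits(matrix):
                lodds = pwm_log_odds(matrix)
                count = 0
                for off in range(len(seq) - matrix.shape[1] + 1):
                    score = sum(lodds["ACGT".index(seq[off + j]), j]
                                for j in range(matrix.shape[1]))
                    count += score >= thr - 1e-12
                return count

            rc = pwm[::-1, ::-1]
            expected = hits(pwm)
            if not np.allclose(rc, pwm):
                expected += hits(rc)
            assert count_pwm_hits(seq, pwm, frac) == expected

    def test_short_sequence_zero_hits(self):
        assert count_pwm_hits("AC", one_hot_pwm("CCGG"), 0.5) == 0

    def test_malformed_matrix(self):
        with pytest.raises(ValueError):
            count_pwm_hits("ACGT", np.ones((3, 4)))
        with pytest.raises(ValueError):
            count_pwm_hits("ACGT", -np.ones((4, 2)))


class TestRepeats:
    def make_annotation(self):
        ann = RepeatAnnotation()
        ann.add("chr1", 500, 600, "famX")
        ann.add("chr1", 900, 1200, "famY")
        ann.add("chr1", 950, 980, "famY")
        return ann

    def test_overlap_counting(self):
        ann = self.make_annotation()
        w = GenomicWindow("chr1", 0, 1000)
        assert count_repeat_overlaps(w, ann, "famX") == 1
        assert count_repeat_overlaps(w, ann, "famY") == 2
        assert count_repeat_overlaps(w, ann, "absent") == 0

    def test_half_open_no_touching_overlap(self):
        ann = RepeatAnnotation()
        ann.add("chr1", 1000, 1100, "famX")
        assert count_repeat_overlaps(GenomicWindow("chr1", 0, 1000),
                                     ann, "famX") == 0
        assert count_repeat_overlaps(GenomicWindow("chr1", 0, 1001),
                                     ann, "famX") == 1


class TestCatalogAndExtraction:
    def test_default_catalog_is_834_features(self):
        catalog = default_catalog()
        assert len(catalog) == 834
        assert catalog.subgroup_sizes == {
            "cpg_info": 3, "repeat_element": 216,
            "transcription_factor": 207, "sequence_motif": 60,
            "mammalian_motif": 348}

    def test_full_vector_length(self):
        catalog = default_catalog()
        genome = GenomeSequence({"chr1": "ACGT" * 2000})
        vec = extract_features(GenomicWindow("chr1", 3000, 4000), genome,
                               RepeatAnnotation(), catalog)
        assert vec.shape == (834,)
        assert np.all(np.isfinite(vec)) and np.all(vec >= 0)

    def test_toy_catalog_known_values(self):
        # 1000 bp of CCGG repeats: 250 CG dinucleotides, 250 CCGG starts
        genome = GenomeSequence({"chr1": "CCGG" * 250})
        catalog = FeatureCatalog([
            FeatureSpec("cpg_density", "cpg_info", "base", "cpg_density"),
            FeatureSpec("ccgg", "sequence_motif", "base", "CCGG")])
        vec = extract_features(GenomicWindow("chr1", 0, 1000), genome,
                               RepeatAnnotation(), catalog)
        assert tuple(vec) == (25.0, 250.0)

    def test_clipped_upstream_flank_is_zero(self):
        genome = GenomeSequence({"chr1": "ACGT" * 1000})
        catalog = FeatureCatalog([
            FeatureSpec("m", "sequence_motif", "up1k", "ACGT"),
            FeatureSpec("m", "sequence_motif", "dn1k", "ACGT")])
        vec = extract_features(GenomicWindow("chr1", 0, 1000), genome,
                               RepeatAnnotation(), catalog)
        assert vec[0] == 0.0          # upstream flank fully clipped
        assert vec[1] > 0.0

    def test_extraction_deterministic(self, small_genome, small_catalog):
        genome, repeats, _ = small_genome
        w = GenomicWindow("chr1", 10_000, 11_000)
        v1 = extract_features(w, genome, repeats, small_catalog)
        v2 = extract_features(w, genome, repeats, small_catalog)
        assert np.array_equal(v1, v2)

    def test_window_outside_genome_errors(self, small_genome,
                                          small_catalog):
        genome, repeats, _ = small_genome
        with pytest.raises(ValueError):
            extract_features(GenomicWindow("chr1", 399_500, 400_500),
                             genome, repeats, small_catalog)

    def test_catalog_tsv_roundtrip(self, tmp_path):
        catalog = default_catalog(subgroup_sizes={
            "repeat_element": 7, "transcription_factor": 5,
            "sequence_motif": 4, "mammalian_motif": 6})
        path = tmp_path / "catalog.tsv"
        catalog.to_tsv(path)
        loaded = FeatureCatalog.from_tsv(path)
        assert [s for s in loaded] == [s for s in catalog]
        for name in catalog.pwms:
            assert np.allclose(loaded.pwms[name], catalog.pwms[name],
                               atol=1e-6)


class TestIO:
    def test_fasta_roundtrip(self, tmp_path):
        genome = GenomeSequence({"chr1": "ACGTN" * 30, "chr2": "GGCC" * 10})
        path = tmp_path / "g.fa"
        genome.to_fasta(path)
        loaded = GenomeSequence.from_fasta(path)
        assert loaded.lengths == genome.lengths
        assert loaded.sequence("chr1", 0, 150) == genome.sequence(
            "chr1", 0, 150)

    def test_repeatmasker_roundtrip(self, tmp_path):
        ann = RepeatAnnotation()
        ann.add("chr1", 10, 50, "L1_Rn")
        ann.add("chr2", 0, 7, "B1_Mur")
        path = tmp_path / "r.out"
        ann.to_repeatmasker(path)
        assert RepeatAnnotation.from_repeatmasker(path).records() == \
            ann.records()

    def test_feature_matrix_roundtrip(self, tmp_path, small_genome,
                                      small_catalog):
        genome, repeats, _ = small_genome
        windows = [GenomicWindow("chr1", s, s + 1000)
                   for s in range(0, 5000, 1000)]
        df = extract_feature_matrix(windows, genome, repeats, small_catalog)
        path = tmp_path / "X.tsv"
        write_feature_matrix(df, path)
        loaded = read_feature_matrix(path)
        assert np.allclose(loaded.to_numpy(), df.to_numpy())
        assert list(loaded.columns) == list(df.columns)
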