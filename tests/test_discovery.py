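import pytest

from pinemap.discovery import (
    detect_polymorphisms,
    haplotype_r2,
    mask_low_quality,
    select_for_array,
    surrogate_design_score,
)
from pinemap.formats import AlignedFragment, FormatError, MarkerMeta
from pinemap.simulate import simulate_fragments


def frag(seqs, quals=None, fid="f1"):
    return AlignedFragment(fid, seqs, quals)


class TestMasking:
    def test_score_below_threshold_masked(self):
        f = frag(["ACGT"], [[40, 29, 40, 40]])
        assert mask_low_quality(f).sequences[0] == "ANGT"

    def test_score_at_threshold_retained(self):
        f = frag(["ACGT"], [[40, 30, 40, 40]])
        assert mask_low_quality(f).sequences[0] == "ACGT"

    def test_high_quality_untouched(self):
        f = frag(["ACGT", "ACGT"], [[40] * 4, [40] * 4])
        assert mask_low_quality(f).sequences == ["ACGT", "ACGT"]

    def test_gap_cells_untouched(self):
        f = frag(["A-GT"], [[40, -1, 40, 40]])
        assert mask_low_quality(f).sequences[0] == "A-GT"

    def test_missing_qualities_rejected(self):
        with pytest.raises(FormatError):
            mask_low_quality(frag(["ACGT"]))


class TestDetection:
    def test_singleton_discarded(self):
        f = frag(["A", "A", "A", "G"])
        assert detect_polymorphisms(f) == []

    def test_two_by_two_snp(self):
        f = frag(["A", "A", "G", "G"])
        (rec,) = detect_polymorphisms(f)
        assert rec.type == "SNP"
        assert rec.maf == pytest.approx(0.5)
        assert rec.detection_depth == 4

    def test_depth_below_minimum_rejected(self):
        f = frag(["A", "A", "G", "N"])
        assert detect_polymorphisms(f) == []

    def test_mutation_free_alignment_empty(self):
        f = frag(["ACGTACGT"] * 6)
        assert detect_polymorphisms(f) == []

    def test_three_alleles_skipped(self):
        f = frag(["A", "A", "G", "G", "C", "C"])
        assert detect_polymorphisms(f) == []

    def test_indel_detected(self):
        f = frag(["ACGTACGT", "AC--ACGT", "AC--ACGT", "ACGTACGT"])
        (rec,) = detect_polymorphisms(f)
        assert rec.type == "indel"
        assert rec.column == 2
        assert rec.indel_length == 2

    def test_long_indel_skipped(self):
        f = frag(["ACGTACGTA", "A-------A", "A-------A", "ACGTACGTA"])
        assert detect_polymorphisms(f) == []

    def test_planted_snps_recovered(self):
        frags, truth = simulate_fragments(seed=3, n_fragments=4, low_quality_rate=0.0)
        for f in frags:
            cols = [r.column for r in detect_polymorphisms(f)]
            assert cols == truth[f.fragment_id]


def _meta(records, scores):
    return {
        r.marker_id: MarkerMeta(
            marker_id=r.marker_id,
            contig_id=r.fragment_id,
            designability_score=scores.get(r.marker_id, 1.0),
            position_in_fragment=r.column,
        )
        for r in records
    }


def _two_snp_fragment(gap_nt, correlated=True):
    """Fragment of 10 haplotypes with two planted SNPs gap_nt apart.

    First SNP (column 10) is carried by sequences 0-3 (MAF 0.4).  The
    second is carried by the same sequences when *correlated* (r² = 1)
    or by sequences 0-1 only otherwise (MAF 0.2, partial LD).
    """
    L = gap_nt + 80
    seqs = []
    for i in range(10):
        s = ["A"] * L
        if i < 4:
            s[10] = "G"
        second_carriers = 4 if correlated else 2
        if i < second_carriers:
            s[10 + gap_nt] = "T"
        seqs.append("".join(s))
    return AlignedFragment("f1", seqs)


class TestSelection:
    def test_spacing_keeps_higher_maf(self):
        f = _two_snp_fragment(45)
        records = detect_polymorphisms(f)
        assert len(records) == 2
        meta = _meta(records, {})
        kept, rejected = select_for_array(records, meta, fragments={"f1": f})
        # both SNPs have MAF 0.4 here (correlated); force differing MAF
        f2 = _two_snp_fragment(45, correlated=False)
        recs = detect_polymorphisms(f2)
        mafs = sorted(r.maf for r in recs)
        kept, rejected = select_for_array(recs, _meta(recs, {}), fragments={"f1": f2})
        assert len(kept) == 1
        assert kept[0].maf == max(mafs)
        assert rejected[0].rule == "spacing"

    def test_low_score_rejected(self):
        f = _two_snp_fragment(200, correlated=False)
        recs = detect_polymorphisms(f)
        scores = {recs[0].marker_id: 0.39}
        kept, rejected = select_for_array(recs, _meta(recs, scores), fragments={"f1": f})
        rules = {rej.record.marker_id: rej.rule for rej in rejected}
        assert rules[recs[0].marker_id] == "score"

    def test_perfect_ld_rejected(self):
        f = _two_snp_fragment(200, correlated=True)  # same carriers: r^2 = 1
        recs = detect_polymorphisms(f)
        assert haplotype_r2(f, recs[0].column, recs[1].column) == pytest.approx(1.0)
        kept, rejected = select_for_array(
            recs, _meta(recs, {}), fragments={"f1": f}, ld_threshold=0.9
        )
        assert len(kept) == 1
        assert rejected[0].rule == "LD"

    def test_uncorrelated_distant_snps_both_kept(self):
        f = _two_snp_fragment(200, correlated=False)
        recs = detect_polymorphisms(f)
        assert haplotype_r2(f, recs[0].column, recs[1].column) < 0.9
        kept, _ = select_for_array(recs, _meta(recs, {}), fragments={"f1": f})
        assert len(kept) == 2

    def test_per_gene_cap(self):
        frags, _ = simulate_fragments(seed=9, n_fragments=3, n_snps_per_fragment=5,
                                      low_quality_rate=0.0, length=800)
        all_recs, metas, fmap = [], {}, {}
        for f in frags:
            recs = detect_polymorphisms(f)
            all_recs.extend(recs)
            metas.update(_meta(recs, {}))
            fmap[f.fragment_id] = f
        kept, rejected = select_for_array(
            all_recs, metas, fragments=fmap, per_gene_cap=2, ld_threshold=1.0
        )
        per_frag = {}
        for r in kept:
            per_frag[r.fragment_id] = per_frag.get(r.fragment_id, 0) + 1
        assert all(v <= 2 for v in per_frag.values())

    def test_selection_invariants(self):
        """Selected sets always satisfy spacing, score and cap constraints."""
        frags, _ = simulate_fragments(seed=4, n_fragments=6, n_snps_per_fragment=4,
                                      low_quality_rate=0.0, length=500)
        all_recs, metas, fmap = [], {}, {}
        for f in frags:
            recs = detect_polymorphisms(f)
            all_recs.extend(recs)
            metas.update(
                {
                    r.marker_id: MarkerMeta(
                        r.marker_id, f.fragment_id,
                        designability_score=surrogate_design_score(f, r.column),
                        position_in_fragment=r.column,
                    )
                    for r in recs
                }
            )
            fmap[f.fragment_id] = f
        kept, rejected = select_for_array(all_recs, metas, fragments=fmap,
                                          min_score=0.4, min_spacing_nt=60,
                                          per_gene_cap=2)
        assert len(kept) + len(rejected) == len(all_recs)
        by_frag = {}
        for r in kept:
            assert metas[r.marker_id].designability_score >= 0.4
            by_frag.setdefault(r.fragment_id, []).append(r.column)
        for cols in by_frag.values():
            assert len(cols) <= 2
            cols = sorted(cols)
            assert all(b - a >= 60 for a, b in zip(cols, cols[1:]))

    def test_unknown_fragment_metadata(self):
        f = frag(["A", "A", "G", "G"])
        recs = detect_polymorphisms(f)
        with pytest.raises(KeyError):
            select_for_array(recs, {})
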