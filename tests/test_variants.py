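"""ORF finding, pairwise alignment, variant calling, effects, motifs."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scentvar.variants import (
    DEFAULT_MOTIFS,
    IsoformGroupLabel,
    OrfNotFound,
    SequenceRecord,
    Variant,
    VariantError,
    align_pair,
    annotate_effect,
    apply_variants,
    assign_isoform_group,
    call_variants,
    find_orf,
    make_aligner,
    scan_motifs,
)

ALIGNER = make_aligner()


class TestFindOrf:
    def test_minimal_orf(self):
        orf = find_orf(SequenceRecord("r", "ATGAAATGA"))
        assert len(orf.seq) == 9 and orf.protein == "MK"

    def test_longest_wins(self):
        # 30-nt ORF then a 60-nt ORF downstream
        short = "ATG" + "AAA" * 8 + "TAA"
        long = "ATG" + "CCC" * 18 + "TGA"
        orf = find_orf(SequenceRecord("r", "TT" + short + "GG" + long))
        assert len(orf.seq) == 60 and orf.protein.startswith("MP")

    def test_leftmost_on_tie(self):
        a = "ATG" + "AAA" * 3 + "TAA"
        b = "ATG" + "CCC" * 3 + "TAA"
        orf = find_orf(SequenceRecord("r", a + "T" + b))
        assert orf.start == 1 and orf.protein == "MKKK"

    def test_no_orf_raises_with_record_name(self):
        with pytest.raises(OrfNotFound, match="rec7"):
            find_orf(SequenceRecord("rec7", "ATGCCCCCC"))

    def test_protein_length_law_on_isoforms(self, locus):
        # nt/3 - 1 across the three isoform ORF lengths
        for name, nt, aa in (("canonical", 1761, 586), ("alt5", 1773, 590), ("alt3", 1647, 548)):
            orf = find_orf(locus.cdnas[name])
            assert len(orf.seq) == nt
            assert len(orf.protein) == nt // 3 - 1 == aa


def brute_force_best_score(a: str, b: str, match=2.0, mismatch=-3.0, open_=-10.0, ext=-0.5):
    """Enumerate all global alignments of two short strings; return the best
    affine-gap score.  Independent of any dynamic-programming code path."""
    best = [-np.inf]

    def rec(i, j, score, prev_gap):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, score + s, None)
        if i < len(a):
            gap = ext if prev_gap == "a" else open_
            rec(i + 1, j, score + gap, "a")
        if j < len(b):
            gap = ext if prev_gap == "b" else open_
            rec(i, j + 1, score + gap, "b")

    rec(0, 0, 0.0, None)
    return best[0]


class TestAlignPair:
    def test_identical_no_gaps(self):
        gr, gq = align_pair("ACGTACGT", "ACGTACGT", ALIGNER)
        assert gr == gq == "ACGTACGT"

    def test_single_deletion_single_gap(self):
        gr, gq = align_pair("ACGTACGT", "ACGACGT", ALIGNER)
        assert gr.replace("-", "") == "ACGTACGT"
        assert gq.count("-") == 1 and gr.count("-") == 0

    def test_block_insertion_single_gap_run(self, locus, ref_orf):
        ref = ref_orf.seq
        ins = locus.alt5_insertion
        query = ref[:229] + ins + ref[229:]
        gr, gq = align_pair(ref, query, ALIGNER)
        runs = [len(list(g)) for k, g in itertools.groupby(gr) if k == "-"]
        assert runs == [12]

    @pytest.mark.parametrize("seed", range(6))
    def test_score_matches_exhaustive_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        a = "".join(bases[rng.integers(0, 4, 8)])
        b = "".join(bases[rng.integers(0, 4, int(rng.integers(5, 9)))])
        expected = brute_force_best_score(a, b)
        assert ALIGNER.score(a, b) == pytest.approx(expected)


def mutate(rng, ref: str, snp_rate=0.01, with_indel=True) -> str:
    bases = "ACGT"
    seq = list(ref)
    for i in range(len(seq)):
        if rng.random() < snp_rate:
            seq[i] = bases[(bases.index(seq[i]) + rng.integers(1, 4)) % 4]
    q = "".join(seq)
    if with_indel:
        p = int(rng.integers(5, len(q) - 20))
        length = int(rng.integers(1, 16))
        if rng.random() < 0.5:
            q = q[:p] + q[p + length :]
        else:
            ins = "".join(bases[k] for k in rng.integers(0, 4, length))
            q = q[:p] + ins + q[p:]
    return q


class TestCallVariants:
    def test_identical_empty(self):
        assert call_variants("ACGT" * 30, "ACGT" * 30, aligner=ALIGNER) == []

    def test_single_substitution_position(self):
        ref = "ACGT" * 50
        query = ref[:99] + ("G" if ref[99] != "G" else "C") + ref[100:]
        (v,) = call_variants(ref, query, aligner=ALIGNER)
        assert (v.pos, v.kind, v.ref_allele) == (100, "SNP", ref[99])

    @pytest.mark.parametrize("seed", range(25))
    def test_round_trip_random_mutants(self, seed):
        rng = np.random.default_rng(1000 + seed)
        ref = "".join("ACGT"[k] for k in rng.integers(0, 4, 150))
        query = mutate(rng, ref)
        variants = call_variants(ref, query, aligner=ALIGNER)
        assert apply_variants(ref, variants) == query

    def test_left_normalization_in_repeat(self):
        # deleting any single A of a homopolymer run yields one canonical record
        ref = "CCGT" + "AAAAAA" + "GTCC" + "ACGT" * 20
        seen = set()
        for k in range(6):
            query = ref[: 4 + k] + ref[5 + k :]
            (v,) = call_variants(ref, query, aligner=ALIGNER)
            seen.add((v.pos, v.kind, v.ref_allele, v.alt_allele))
        assert seen == {(5, "deletion", "A", "")}

    def test_renormalization_is_stable(self):
        ref = "CCGT" + "AGAGAGAG" + "TTCC" + "ACGT" * 20
        query = ref[:6] + ref[8:]  # drop one AG unit mid-repeat
        first = [v.key() for v in call_variants(ref, query, aligner=ALIGNER)]
        again = [v.key() for v in call_variants(ref, query, aligner=ALIGNER)]
        assert first == again and first[0][1] == "deletion"
        assert first[0][0] == 5  # shifted to the 5'-most equivalent position

    def test_n_sites_excluded_from_catalogue(self):
        ref = "ATGAAACCCGGGTTTTGA"
        query = ref[:3] + "N" + ref[4:]
        assert call_variants(ref, query, aligner=ALIGNER) == []


class TestAnnotateEffect:
    def test_third_position_silent(self):
        # CTT -> CTC is Leu -> Leu
        assert annotate_effect(
            make_orf_with("CTT"), Variant("r", 6, "SNP", "T", "C")
        ) == "synonymous"

    def test_met_to_ile(self):
        assert annotate_effect(
            make_orf_with("ATG"), Variant("r", 6, "SNP", "G", "A")
        ) == "nonsynonymous"

    @pytest.mark.parametrize("length, expected", [(12, "inframe_indel"), (114, "inframe_indel"), (5, "frameshift")])
    def test_indel_frame(self, length, expected):
        orf = make_orf_with("AAA")
        ins = Variant("r", 4, "insertion", "", "A" * length)
        assert annotate_effect(orf, ins) == expected

    def test_outside_orf_rejected(self):
        with pytest.raises(VariantError):
            annotate_effect(make_orf_with("AAA"), Variant("r", 99, "SNP", "A", "G"))

    def test_effect_partition_on_panel(self, ref_orf, panel):
        from scentvar.variants import catalogue_panel

        catalogue, _, _ = catalogue_panel(ref_orf, panel.records(with_indel=False)[:8])
        snps = [v for v in catalogue if v.kind == "SNP"]
        assert all(v.effect in ("synonymous", "nonsynonymous") for v in snps)
        syn = sum(v.effect == "synonymous" for v in snps)
        nonsyn = sum(v.effect == "nonsynonymous" for v in snps)
        assert syn + nonsyn == len(snps)


def make_orf_with(codon2: str):
    """Tiny valid ORF whose second codon is ``codon2`` (variant target)."""
    from scentvar.variants import Orf
    from Bio.Seq import Seq

    seq = "ATG" + codon2 + "TGA"
    return Orf(1, len(seq), seq, str(Seq(seq[:-3]).translate()))


class TestAssignIsoformGroup:
    def test_no_indels_is_group_one(self):
        assert assign_isoform_group([]).label == "LTPS-1"

    def test_twelve_bp_insertion_is_group_two(self):
        v = Variant("r", 230, "insertion", "", "G" * 12)
        lab = assign_isoform_group([v])
        assert lab.label == "LTPS-2" and lab.evidence == [v]

    def test_114_bp_deletion_is_group_three(self):
        v = Variant("r", 873, "deletion", "A" * 114, "")
        assert assign_isoform_group([v]).label == "LTPS-3"

    def test_conflicting_signature_raises(self):
        vs = [
            Variant("r", 230, "insertion", "", "G" * 12),
            Variant("r", 873, "deletion", "A" * 114, ""),
        ]
        with pytest.raises(VariantError, match="conflict"):
            assign_isoform_group(vs)


class TestScanMotifs:
    def test_rr_x8_w_by_construction(self):
        hits = scan_motifs("AAARRACDEFGHIWAAA")
        rr = [h for h in hits if h.motif_name == "RRX8W"]
        assert len(rr) == 1 and (rr[0].start, rr[0].end) == (4, 14)

    def test_ddxxd(self):
        hits = scan_motifs("DDAAD")
        dd = [h for h in hits if h.motif_name == "DDXXD"]
        assert len(dd) == 1 and (dd[0].start, dd[0].end) == (1, 5)

    def test_malformed_pattern_is_config_error(self):
        with pytest.raises(ValueError):
            scan_motifs("MKV", [{"name": "bad", "pattern": "[unclosed"}])

    def test_isoform_motif_layout(self, locus):
        """The short isoform loses RX8W with its deleted block; the core
        catalytic motifs survive in all three translations."""
        names = {}
        for iso in ("canonical", "alt5", "alt3"):
            protein = find_orf(locus.cdnas[iso]).protein
            names[iso] = {h.motif_name for h in scan_motifs(protein)}
        for iso in ("canonical", "alt5"):
            assert {"RRX8W", "RX8W", "DDXXD", "NSE/DTE", "transit_region"} <= names[iso]
        assert "RX8W" not in names["alt3"]
        assert {"RRX8W", "DDXXD", "NSE/DTE"} <= names["alt3"]


@given(
    data=st.data(),
)
def test_round_trip_property(data):
    """Applying called variants to the reference reconstructs the query."""
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    ref = "".join("ACGT"[k] for k in rng.integers(0, 4, int(rng.integers(40, 120))))
    query = mutate(rng, ref, snp_rate=0.05, with_indel=bool(rng.integers(0, 2)))
    if not query:
        return
    variants = call_variants(ref, query, aligner=ALIGNER)
    assert apply_variants(ref, variants) == query
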