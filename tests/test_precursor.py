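"""Signal peptides, cleavage sites, excision, PTMs, disulfide bookkeeping."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import oracles
from npmine.precursor import (
    CleavageRules,
    CleavageSite,
    ContractViolation,
    PeptideFragment,
    PtmRules,
    RenderingParseError,
    SignalConfig,
    SignalPeptidePrediction,
    annotate_precursor,
    apply_ptm,
    count_cysteines,
    enumerate_disulfide_pairings,
    excise_fragments,
    find_cleavage_sites,
    invert_rendering,
    mature_from_rendered,
    predict_signal_peptide,
    render,
    signal_score,
    validate_pairing,
)
from npmine.seq_io import ProteinRecord

ALP_MATURE = "WRSCIRRGGACDHRPNDCCYNSSCRCNLWGTNCRCQRMGIFQQW"
TRISSIN_MATURE = "STVSCDSCGPECQTACGTKNFRACCFNFL"


class TestSignalPeptide:
    def test_constructed_positive_cleaves_near_18(self):
        p = ProteinRecord("x", "MKTLLVLAVLALFSVSSA" + "DNTEQPDNTEQP" * 5)
        pred = predict_signal_peptide(p)
        assert pred.span is not None
        assert pred.span[0] == 1
        assert abs(pred.span[1] - 18) <= 2
        assert 0 <= pred.score <= 1

    def test_poly_aspartate_n_terminus_is_absent(self):
        p = ProteinRecord("y", "M" + "D" * 40 + "NTEQP" * 8)
        pred = predict_signal_peptide(p)
        assert pred.span is None

    def test_short_protein_absent_with_score_zero(self):
        pred = predict_signal_peptide(ProteinRecord("s", "MKTLLVLAVLA"))
        assert pred.span is None and pred.score == 0.0

    def test_external_override_returned_verbatim(self):
        cfg = SignalConfig(external={"ccap_like": (1, 30)})
        p = ProteinRecord("ccap_like", "M" + "A" * 140)
        pred = predict_signal_peptide(p, cfg)
        assert pred.span == (1, 30) and pred.method == "external"

    def test_three_region_scorer_matches_direct_computation(self):
        # verify the weighted combination against hand-computed components
        seq = "MKTLLVLAVLALFSVSSA" + "DNTEQP" * 10
        cfg = SignalConfig()
        from npmine.precursor import KYTE_DOOLITTLE, _signal_component_scores

        cut = 18
        n, h, c = _signal_component_scores(seq, cut, cfg)
        assert n == 1.0  # K at position 2
        # best 8-residue hydropathy window inside [3, cut-3], by direct sum
        best = max(
            sum(KYTE_DOOLITTLE[a] for a in seq[s : s + 8]) / 8
            for s in range(2, cut - 3 - 8 + 2)
        )
        assert h == pytest.approx(min(best / cfg.h_saturation, 1.0))
        assert c == 1.0  # A at -1 and S at -3
        assert signal_score(seq, cut, cfg) == pytest.approx(0.2 * n + 0.5 * h + 0.3 * c)


class TestCleavageSites:
    def test_single_dibasic_site(self):
        p = ProteinRecord("p", "AAAKRAAA")
        rules = CleavageRules(tribasic=frozenset(), terminal_monobasic=False)
        sites = find_cleavage_sites(p, rules)
        assert [(s.start, s.basic_run, s.kind, s.cut_after) for s in sites] == [
            (4, "KR", "dibasic", 5)
        ]

    def test_tribasic_and_dibasic_in_one_scan(self):
        p = ProteinRecord("p", "AAKRAARKRAA")
        sites = find_cleavage_sites(p, CleavageRules(terminal_monobasic=False))
        assert [(s.start, s.basic_run) for s in sites] == [(3, "KR"), (7, "RKR")]

    def test_terminal_monobasic_k(self):
        p = ProteinRecord("p", "AAAAAQQWK")
        sites = find_cleavage_sites(p, CleavageRules())
        assert [(s.start, s.basic_run, s.kind) for s in sites] == [(9, "K", "monobasic")]

    def test_interior_monobasic_requires_flag(self):
        p = ProteinRecord("p", "AAARAAAAAAAA")
        assert find_cleavage_sites(p, CleavageRules()) == []
        rules = CleavageRules(interior_monobasic=frozenset("R"))
        assert [(s.start, s.basic_run) for s in find_cleavage_sites(p, rules)] == [(4, "R")]

    def test_sites_inside_signal_excluded(self):
        p = ProteinRecord("p", "MKRAAAAAKRAAA")
        signal = SignalPeptidePrediction(span=(1, 5), score=1.0)
        sites = find_cleavage_sites(p, CleavageRules(terminal_monobasic=False), signal)
        assert [(s.start, s.basic_run) for s in sites] == [(9, "KR")]

    @pytest.mark.parametrize(
        "dibasic,tribasic,interior,terminal",
        [
            (frozenset({"KR", "RR", "KK", "RK"}), frozenset({"KKR", "RKR"}), frozenset(), True),
            (frozenset({"KR"}), frozenset(), frozenset(), False),
            (frozenset({"KR", "KK"}), frozenset({"RKR"}), frozenset("R"), True),
            (frozenset(), frozenset(), frozenset("KR"), False),
        ],
    )
    def test_matches_regex_scan_oracle(self, dibasic, tribasic, interior, terminal):
        rng = np.random.default_rng(
            1000 + 7 * len(dibasic) + 3 * len(tribasic) + len(interior) + terminal
        )
        rules = CleavageRules(
            dibasic=dibasic, tribasic=tribasic,
            interior_monobasic=interior, terminal_monobasic=terminal,
        )
        for _ in range(150):
            seq = "".join(
                rng.choice(list("AKRSTDEQ"), size=int(rng.integers(5, 80)))
            )
            p = ProteinRecord("p", seq)
            got = [(s.start, s.basic_run) for s in find_cleavage_sites(p, rules)]
            exp = oracles.regex_scan_cleavage(
                seq, dibasic, tribasic, interior, terminal
            )
            assert got == exp, seq


class TestExcision:
    def test_no_signal_no_sites_whole_protein(self):
        p = ProteinRecord("p", "ADTNEQSPY")
        frags = excise_fragments(p, None, [])
        assert len(frags) == 1
        assert frags[0].span == (1, 9) and frags[0].seq == p.seq

    def test_myosuppressin_style_excision(self):
        # 100-aa precursor, 24-aa signal, dibasic run at 85-86, monobasic at 97
        rng = np.random.default_rng(0)
        seq = list("A" * 100)
        seq[84], seq[85], seq[96] = "K", "R", "R"
        p = ProteinRecord("myo", "".join(seq))
        signal = SignalPeptidePrediction(span=(1, 24), score=1.0)
        sites = [CleavageSite(85, "KR", "dibasic"), CleavageSite(97, "R", "monobasic")]
        frags = excise_fragments(p, signal, sites)
        assert [f.span for f in frags] == [(25, 84), (87, 96), (98, 100)]

    def test_overlapping_sites_rejected(self):
        p = ProteinRecord("p", "AAAKRRAA")
        with pytest.raises(ContractViolation):
            excise_fragments(
                p, None, [CleavageSite(4, "KR", "dibasic"), CleavageSite(5, "RR", "dibasic")]
            )

    def test_tiling_reassembly_on_random_precursors(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=int(rng.integers(20, 200))))
            p = ProteinRecord("p", seq)
            sites = find_cleavage_sites(p, CleavageRules())
            frags = excise_fragments(p, None, sites)
            # signal + basic runs + fragments partition the precursor
            covered = {}
            for s in sites:
                for i in range(s.start, s.cut_after + 1):
                    assert i not in covered
                    covered[i] = seq[i - 1]
            for f in frags:
                assert f.seq == seq[f.span[0] - 1 : f.span[1]]
                for i, ch in zip(range(f.span[0], f.span[1] + 1), f.seq):
                    assert i not in covered
                    covered[i] = ch
            assert "".join(covered[i] for i in sorted(covered)) == seq

    def test_all_basic_precursor_yields_no_fragments_with_warning(self):
        p = ProteinRecord("p", "KRKRKRKR")
        ann = annotate_precursor(p)
        assert ann.fragments == []
        assert any("no fragments" in w for w in ann.warnings)


class TestPtm:
    @pytest.mark.parametrize(
        "frag,rendered,amidated,pyroglu",
        [
            ("QITFSRSWVPQG", "pQITFSRSWVPQamide", True, True),
            ("PFCNAFTGCG", "PFCNAFTGCamide", True, False),
            ("RYLPT", "RYLPT", False, False),
            ("QLNFSPGWG", "pQLNFSPGWamide", True, True),
        ],
    )
    def test_worked_examples(self, frag, rendered, amidated, pyroglu):
        m = apply_ptm(PeptideFragment((1, len(frag)), frag))
        assert m.rendered == rendered
        assert m.amidated is amidated and m.pyroglu is pyroglu

    def test_trailing_basics_stripped_before_amidation(self):
        m = apply_ptm(PeptideFragment((1, 8), "ADTNEQGK"))
        assert m.seq == "ADTNEQ" and m.amidated

    def test_pyroglu_from_e_only_when_enabled(self):
        f = PeptideFragment((1, 5), "EDTNE")
        assert not apply_ptm(f).pyroglu
        assert apply_ptm(f, PtmRules(pyroglu_from_e=True)).pyroglu
        assert apply_ptm(f, PtmRules(pyroglu_from_e=True)).rendered == "pEDTNE"

    def test_invert_rendering_examples(self):
        assert invert_rendering("pQLNFSPGWamide") == "QLNFSPGWG"
        assert invert_rendering("RYLPT") == "RYLPT"
        with pytest.raises(RenderingParseError):
            invert_rendering("pQ+bogus!")

    @given(
        st.text(alphabet="ACDEFGHILMNPQSTVWYG", min_size=1, max_size=40).filter(
            lambda s: s != "G"
        )
    )
    def test_roundtrip_identity_on_valid_fragments(self, frag):
        m = apply_ptm(PeptideFragment((1, len(frag)), frag))
        assert invert_rendering(m.rendered) == frag

    def test_mature_from_rendered_rebuilds_flags(self):
        m = mature_from_rendered("pQDLDHVFLRFamide")
        assert m.seq == "QDLDHVFLRF" and m.amidated and m.pyroglu


class TestDisulfides:
    def test_cysteine_counts_of_printed_matures(self):
        alp = apply_ptm(PeptideFragment((1, 45), ALP_MATURE + "G"))
        assert count_cysteines(alp) == 8
        trissin = apply_ptm(PeptideFragment((1, 29), TRISSIN_MATURE))
        assert count_cysteines(trissin) == 6
        assert count_cysteines(apply_ptm(PeptideFragment((1, 4), "AAAA"))) == 0

    def test_bridge_and_matching_counts(self):
        plan6 = enumerate_disulfide_pairings(6)
        assert plan6.bridge_count == 3 and plan6.n_matchings == 15
        assert len(plan6.matchings) == 15
        plan0 = enumerate_disulfide_pairings(0)
        assert plan0.bridge_count == 0 and plan0.n_matchings == 1
        assert plan0.matchings == [[]]
        assert enumerate_disulfide_pairings(8).bridge_count == 4

    @pytest.mark.parametrize("n", [2, 4, 6, 8, 10])
    def test_matching_count_equals_bruteforce_enumeration(self, n):
        plan = enumerate_disulfide_pairings(n)
        assert plan.n_matchings == oracles.count_perfect_matchings(n)
        if plan.matchings is not None:
            canon = {
                frozenset(frozenset(p) for p in matching)
                for matching in plan.matchings
            }
            assert len(canon) == plan.n_matchings

    def test_odd_count_flags_unpaired_cysteine(self):
        plan = enumerate_disulfide_pairings(7)
        assert plan.bridge_count == 3
        assert "unpaired" in plan.warning

    def test_validate_reported_pairings(self):
        gpa2 = [(1, 10), (2, 8), (3, 5), (4, 9), (6, 7)]
        assert validate_pairing(gpa2, 10)[0]
        gpb5 = [(1, 10), (2, 5), (3, 4), (6, 8), (7, 9)]
        assert validate_pairing(gpb5, 10)[0]
        trissin = [(1, 6), (2, 4), (3, 5)]
        assert validate_pairing(trissin, 6)[0]

    def test_invalid_pairings_rejected_with_reason(self):
        ok, reason = validate_pairing([(1, 2), (1, 3)], 4)
        assert not ok and "more than once" in reason
        ok, reason = validate_pairing([(1, 7)], 6)
        assert not ok and "out of range" in reason
        ok, reason = validate_pairing([(1, 2)], 4)
        assert not ok and "unpaired" in reason
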