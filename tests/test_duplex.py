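import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirduplex import (
    EnergyParams,
    PairState,
    ScoringParams,
    align_duplex,
    delta_delta_g,
    duplex_delta_g,
    render_duplex,
    score_alignment,
)
from mirduplex.duplex import min_penalty_capped
from mirduplex.sequences import (
    BHLH74_SITE,
    GRF2_SITE,
    MIR396A,
    MIR396B,
    MIR396B_7AG,
    MIR396_78INSG,
    reverse_complement,
)

from _brute import brute_force_optima

EP = EnergyParams()


def _random_pair(rng, m_lo=4, m_hi=10, n_cap=13):
    m = int(rng.integers(m_lo, m_hi + 1))
    n = int(np.clip(m + rng.integers(-3, 4), 2, n_cap))
    mir = "".join("ACGU"[c] for c in rng.integers(0, 4, m))
    win = "".join("ACGU"[c] for c in rng.integers(0, 4, n))
    return mir, win


class TestAlignment:
    def test_perfect_complement_scores_zero(self):
        mir = "UUCCACAG"
        aln = align_duplex(mir, reverse_complement(mir))
        assert aln.score == 0
        assert all(c.state is PairState.WATSON_CRICK for c in aln.columns)

    def test_grf2_duplex_has_single_target_bulge_between_7_and_8(self, mir396a):
        aln = align_duplex(mir396a, GRF2_SITE)
        assert aln.score == 1.0
        assert aln.bulge_positions() == [("target", 7)]
        counts = aln.counts()
        assert counts[PairState.MISMATCH] == 0
        assert counts[PairState.BULGE_MIRNA] == 0
        assert counts[PairState.WATSON_CRICK] == len(MIR396A)

    def test_insg_on_bhlh74_site_bulges_the_mirna_side(self):
        aln = align_duplex(MIR396_78INSG, BHLH74_SITE)
        assert [side for side, _ in aln.bulge_positions()] == ["mirna"]
        assert aln.counts()[PairState.BULGE_TARGET] == 0

    def test_score_census_two_mismatch_one_wobble_one_bulge(self):
        # build the partner strand by hand: mismatches at miRNA pos 4 and 16,
        # a G:U wobble at pos 12, one bulged target base between pos 18/19
        partners = [{"A": "U", "U": "A", "C": "G", "G": "C"}[b] for b in MIR396A]
        partners[3] = "A"    # C:A mismatch
        partners[15] = "A"   # G:A mismatch
        partners[11] = "G"   # U:G wobble
        partners.insert(18, "A")  # bulged target base (pairs neither A18 nor C19)
        window = "".join(reversed(partners))
        aln = align_duplex(MIR396A, window)
        assert aln.score == 2 * 1.0 + 0.5 + 1.0
        assert score_alignment(aln) == aln.score
        c = aln.counts()
        assert (c[PairState.MISMATCH], c[PairState.GU_WOBBLE],
                c[PairState.BULGE_TARGET]) == (2, 1, 1)

    def test_window_length_outside_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            align_duplex(MIR396A, "ACGU" * 10)

    def test_unpairable_cleavage_site_yields_no_site_sentinel(self):
        # miRNA positions 10-11 are U,U; an all-C window cannot pair them
        aln = align_duplex(MIR396A, "C" * 21)
        assert not aln.is_site
        assert aln.score == math.inf

    def test_relaxed_pairing_constraint_restores_alignment(self):
        relaxed = ScoringParams(require_paired_10_11=False)
        aln = align_duplex(MIR396A, "C" * 21, relaxed)
        assert aln.is_site

    def test_render_has_three_lines_and_gap_dash(self, mir396a):
        text = render_duplex(align_duplex(mir396a, GRF2_SITE))
        lines = text.splitlines()
        assert len(lines) == 3
        assert "-" in lines[2]  # target bulge leaves a dash on the miRNA line


class TestEnergies:
    def test_two_pair_helix_is_initiation_plus_one_stack(self):
        aln = align_duplex("GC", reverse_complement("GC"),
                           ScoringParams(require_paired_10_11=False))
        # 5'-GC-3' / 3'-CG-5'
        assert duplex_delta_g(aln, EP) == pytest.approx(
            EP.duplex_initiation + EP.stack("G", "C", "C", "G"))

    def test_single_bulge_insertion_changes_dg_by_bulge_initiation(self, mir396a):
        # the 1-nt bulge keeps its closing stack, so the hand-computed delta
        # between the perfect duplex and the bulged one is the initiation term
        perfect = align_duplex(mir396a, reverse_complement(MIR396A))
        bulged = align_duplex(mir396a, GRF2_SITE)
        assert (duplex_delta_g(bulged, EP) - duplex_delta_g(perfect, EP)
                == pytest.approx(EP.bulge(1)))

    def test_bulge_free_monocot_variant_binds_grf2_more_strongly(self, mir396a):
        a = align_duplex(mir396a, GRF2_SITE)
        b = align_duplex(MIR396_78INSG, GRF2_SITE)
        assert duplex_delta_g(b, EP) < duplex_delta_g(a, EP)

    def test_ddg_identity_and_window_check(self, mir396a):
        a = align_duplex(mir396a, GRF2_SITE)
        assert delta_delta_g(a, a) == 0.0
        other = align_duplex(mir396a, reverse_complement(MIR396A))
        with pytest.raises(ValueError, match="window"):
            delta_delta_g(a, other)

    def test_dg_requires_two_paired_columns(self):
        aln = align_duplex("AAAA", "AAAA", ScoringParams(require_paired_10_11=False))
        with pytest.raises(ValueError, match="two paired"):
            duplex_delta_g(aln, EP)

    def test_dg_invariant_under_strand_role_swap(self, mir396a):
        relaxed = ScoringParams(require_paired_10_11=False)
        fwd = align_duplex(MIR396A, GRF2_SITE, relaxed)
        rev = align_duplex(GRF2_SITE, MIR396A, relaxed)
        assert duplex_delta_g(fwd, EP) == pytest.approx(duplex_delta_g(rev, EP))

    def test_viennarna_crosscheck_on_bulge_removal(self):
        # independent implementation of the same published parameter set;
        # dangling-end handling differs, but the ΔΔG of bulge removal shares
        # identical termini and must agree closely
        import RNA

        ours = delta_delta_g(align_duplex(MIR396A, GRF2_SITE),
                             align_duplex(MIR396_78INSG, GRF2_SITE))
        vienna = (RNA.duplexfold(MIR396_78INSG, GRF2_SITE).energy
                  - RNA.duplexfold(MIR396A, GRF2_SITE).energy)
        assert ours == pytest.approx(vienna, abs=0.5)


class TestProperties:
    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25)
    def test_dp_score_and_energy_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        mir, win = _random_pair(rng, m_hi=8, n_cap=11)
        if not (len(mir) - 3 <= len(win) <= len(mir) + 3):
            return
        brute_score, brute_dg = brute_force_optima(mir, win)
        aln = align_duplex(mir, win)
        assert aln.score == pytest.approx(brute_score)
        e = align_duplex(mir, win, objective="energy")
        dg = (e.delta_g if e.is_site and len(e.paired_columns()) >= 2
              else math.inf)
        if isinstance(dg, float) and math.isnan(dg):
            dg = math.inf
        assert dg == pytest.approx(brute_dg)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25)
    def test_capped_scan_agrees_with_full_alignment(self, seed):
        rng = np.random.default_rng(seed)
        mir, win = _random_pair(rng, m_lo=6, m_hi=21, n_cap=24)
        if not (len(mir) - 3 <= len(win) <= len(mir) + 3):
            return
        full = align_duplex(mir, win).score
        capped = min_penalty_capped(mir, win)
        if full <= 5:
            assert capped == pytest.approx(full)
        else:
            assert capped == math.inf

    @given(st.integers(1, 21), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25)
    def test_mutating_a_paired_base_never_lowers_the_score(self, pos, seed):
        rng = np.random.default_rng(seed)
        site = list(reverse_complement(MIR396A))
        idx = len(site) - pos  # base paired to miRNA position pos
        wc = site[idx]
        alternatives = [b for b in "ACGU" if b != wc]
        mutated = site.copy()
        mutated[idx] = alternatives[int(rng.integers(0, 3))]
        base = align_duplex(MIR396A, "".join(site),
                            ScoringParams(require_paired_10_11=False))
        worse = align_duplex(MIR396A, "".join(mutated),
                             ScoringParams(require_paired_10_11=False))
        assert worse.score >= base.score
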