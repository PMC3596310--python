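"""Fragment generation, binomial ion scoring, site localization and the
Monte-Carlo behaviour of the score under noise-only spectra."""

import numpy as np
import pytest

from phosphopmf import (
    PHOSPHO,
    SULFO,
    ModifiedPeptide,
    PredictionParams,
    make_peaklist,
    score_placement,
    theoretical_fragments,
    validate,
)
from phosphopmf.digestion import TheoreticalPeptide
from phosphopmf.peaklist import Peak
from phosphopmf.prediction import PhosphoCandidate


class TestTheoreticalFragments:
    def test_y1_of_cterminal_arginine(self):
        ions = theoretical_fragments(ModifiedPeptide("GGR"))
        y1 = next(i for i in ions if i.series == "y" and i.index == 1)
        assert y1.mz == pytest.approx(175.1190, abs=1e-3)

    def test_b2_of_ynqllr(self):
        ions = theoretical_fragments(ModifiedPeptide("YNQLLR"))
        b2 = next(i for i in ions if i.series == "b" and i.index == 2)
        assert b2.mz == pytest.approx(278.1135, abs=1e-3)

    @pytest.mark.parametrize("seq", ["GR", "YNQLLR", "AAVPSGASTGIYEALELR"])
    def test_unmodified_ladder_has_2n_minus_2_ions(self, seq):
        ions = theoretical_fragments(ModifiedPeptide(seq))
        assert len(ions) == 2 * (len(seq) - 1)
        assert all(i.neutral_loss == "none" for i in ions)

    def test_neutral_loss_ions_only_for_fragments_containing_pst(self):
        placed = ModifiedPeptide("ASGR", ((2, PHOSPHO),))
        ions = theoretical_fragments(placed, include_neutral_loss=True)
        nl = [(i.series, i.index) for i in ions if i.neutral_loss == "H3PO4"]
        # pS at 2: b2,b3 contain it; y3 contains it (y1=R, y2=GR do not)
        assert set(nl) == {("b", 2), ("b", 3), ("y", 3)}
        base = {(i.series, i.index): i.mz for i in ions if i.neutral_loss == "none"}
        for series, idx in nl:
            lost = next(
                i.mz for i in ions if (i.series, i.index) == (series, idx) and i.neutral_loss == "H3PO4"
            )
            assert base[(series, idx)] - lost == pytest.approx(97.9769, abs=1e-3)

    def test_phospho_tyrosine_sheds_no_neutral_loss(self):
        placed = ModifiedPeptide("AYGR", ((2, PHOSPHO),))
        ions = theoretical_fragments(placed, include_neutral_loss=True)
        assert all(i.neutral_loss == "none" for i in ions)


class TestScorePlacement:
    def test_perfect_ladder_matches_all_ions(self):
        placed = ModifiedPeptide("YNQLLR", ((1, PHOSPHO),))
        ions = theoretical_fragments(placed, include_neutral_loss=True)
        msms = make_peaklist(
            "s", [(i.mz, 10.0) for i in ions], kind="MSMS", precursor_mz=886.4885
        )
        score = score_placement(msms, placed)
        assert score.n_matched == score.n_theoretical
        assert score.ion_score > 15

    def test_empty_spectrum_scores_zero_with_warning(self):
        placed = ModifiedPeptide("YNQLLR", ((1, PHOSPHO),))
        msms = make_peaklist("s", [], kind="MSMS", precursor_mz=886.4885)
        with pytest.warns(UserWarning):
            score = score_placement(msms, placed)
        assert score.ion_score == 0.0

    def test_noise_only_spectra_rarely_exceed_threshold(self):
        """Monte-Carlo null: 50 uniform peaks over 100-1000 Da exceed
        ion score 15 in at most 5% of 200 seeded replicates, matching
        the p<0.1 reading of the >15 acceptance threshold."""
        placed = ModifiedPeptide("LSAMPLEKDGYR", ((2, PHOSPHO),))
        exceed = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            mzs = np.sort(rng.uniform(100, 1000, size=50))
            msms = make_peaklist(
                "s",
                [(float(m), 1.0) for m in mzs],
                kind="MSMS",
                precursor_mz=1500.0,
            )
            if score_placement(msms, placed).ion_score > 15:
                exceed += 1
        assert exceed <= 10  # 5% of 200

    def test_true_site_outscores_alternative_on_discriminating_ladder(self):
        """Two candidate sites share ions below the site and differ
        above: the planted placement must score strictly higher."""
        true_site = ModifiedPeptide("TAAAAASR", ((7, PHOSPHO),))
        wrong_site = ModifiedPeptide("TAAAAASR", ((1, PHOSPHO),))
        ions = theoretical_fragments(true_site, include_neutral_loss=True)
        msms = make_peaklist(
            "s", [(i.mz, 5.0) for i in ions], kind="MSMS", precursor_mz=900.0
        )
        s_true = score_placement(msms, true_site, msms_tolerance=0.2)
        s_wrong = score_placement(msms, wrong_site, msms_tolerance=0.2)
        assert s_true.ion_score > s_wrong.ion_score

    def test_score_monotone_in_matched_count(self):
        """Adding matched ions (same spectrum density) never lowers the
        binomial tail score."""
        placed = ModifiedPeptide("YNQLLR", ((1, PHOSPHO),))
        ions = theoretical_fragments(placed, include_neutral_loss=True)
        scores = []
        rng = np.random.default_rng(0)
        decoys = sorted(float(x) for x in rng.uniform(1000, 2000, size=len(ions)))
        for k in range(1, len(ions) + 1):
            pairs = [(i.mz, 1.0) for i in ions[:k]]
            pairs += [(d, 1.0) for d in decoys[k:]]  # keep |peaks| constant
            msms = make_peaklist("s", pairs, kind="MSMS", precursor_mz=886.4885)
            scores.append(score_placement(msms, placed).n_matched)
        assert scores == sorted(scores)

    def test_neutral_loss_evidence_prefers_phospho_over_sulfo(self):
        """On a spectrum containing -98 loss ions, scoring the +80 site
        as phospho (with neutral-loss ions) beats scoring it as sulfo."""
        phospho_form = ModifiedPeptide("ASGLLTR", ((2, PHOSPHO),))
        sulfo_form = ModifiedPeptide("ASGLLTR", ((2, SULFO),))
        ions = theoretical_fragments(phospho_form, include_neutral_loss=True)
        msms = make_peaklist(
            "s", [(i.mz, 5.0) for i in ions], kind="MSMS", precursor_mz=800.0
        )
        s_phos = score_placement(msms, phospho_form, msms_tolerance=0.2)
        s_sulf = score_placement(msms, sulfo_form, msms_tolerance=0.2)
        assert s_phos.n_matched > s_sulf.n_matched
        assert s_phos.ion_score > s_sulf.ion_score


def _candidate(sequence, start, sites, phospho_mz, accession="P1"):
    pep = TheoreticalPeptide(sequence, start, start + len(sequence) - 1, 0, accession)
    return PhosphoCandidate(
        peptide=pep,
        modification="Phospho",
        candidate_sites=sites,
        phospho_peak=Peak(phospho_mz, 10.0),
        parent_mh=phospho_mz - PHOSPHO.delta,
        mass_error=0.0,
    )


class TestValidate:
    def test_enolase_fixture_localizes_y417_above_threshold(self, enolase_example):
        from phosphopmf import filter_by_parent, match_unmodified, predict_phospho
        from phosphopmf.intensity_filter import retained_candidates

        ex = enolase_example
        _, unmatched = match_unmodified(ex["pmf"], ex["peptides"], ex["params"])
        cands = predict_phospho(unmatched, ex["peptides"], ex["params"])
        retained = retained_candidates(filter_by_parent(cands, ex["pmf"], ex["params"]))
        validated, diagnostics = validate("spot135", retained, [ex["msms"]], ex["params"])
        assert diagnostics == []
        [v] = validated
        assert (v.best_site, v.residue) == (417, "Y")
        assert v.ion_score > 15
        assert v.ambiguous_sites == frozenset()

    def test_single_eligible_residue_forces_site(self):
        placed = ModifiedPeptide("YNQLLR", ((1, PHOSPHO),))
        ions = theoretical_fragments(placed, include_neutral_loss=True)
        msms = make_peaklist(
            "s", [(i.mz, 5.0) for i in ions], kind="MSMS", precursor_mz=886.4885
        )
        cand = _candidate("YNQLLR", 417, (417,), 886.4885)
        validated, _ = validate("s", [cand], [msms], PredictionParams())
        [v] = validated
        assert v.best_site == 417 and v.ambiguous_sites == frozenset()

    def test_noise_only_spectrum_fails_threshold(self):
        rng = np.random.default_rng(42)
        mzs = np.sort(rng.uniform(100, 1000, size=50))
        msms = make_peaklist(
            "s", [(float(m), 1.0) for m in mzs], kind="MSMS", precursor_mz=886.4885
        )
        cand = _candidate("YNQLLR", 417, (417,), 886.4885)
        validated, diagnostics = validate("s", [cand], [msms], PredictionParams())
        assert validated == []
        assert len(diagnostics) == 1 and "threshold" in diagnostics[0][1]

    def test_precursor_mismatch_reported_unvalidatable(self):
        msms = make_peaklist("s", [(175.119, 1.0)], kind="MSMS", precursor_mz=1200.0)
        cand = _candidate("YNQLLR", 417, (417,), 886.4885)
        validated, diagnostics = validate("s", [cand], [msms], PredictionParams())
        assert validated == []
        assert "precursor" in diagnostics[0][1]
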