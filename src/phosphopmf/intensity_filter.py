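"""Coexistence/intensity plausibility filter for predicted phosphopeptides.

In MALDI PMF spectra a genuine phosphopeptide ion coexists with its
unmodified parent ion and is weaker than it: phosphorylation is
sub-stoichiometric and phosphopeptides ionize poorly.  A predicted
phosphopeptide whose parent peak is absent, or which out-shines its
parent, is therefore treated as a false prediction (typically a peptide
of a co-migrated protein that happens to land +80 Da from something).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .peaklist import Peak, PeakList
from .prediction import PhosphoCandidate, PredictionParams

Verdict = Literal["retained", "rejected_no_parent", "rejected_intensity"]


@dataclass(frozen=True)
class FilterDecision:
    candidate: PhosphoCandidate
    parent_peak: Peak | None
    verdict: Verdict
    intensity_ratio: float | None  # phospho / parent, when parent present

    def __post_init__(self) -> None:
        if self.verdict == "retained":
            if self.parent_peak is None:
                raise ValueError("retained decision requires a parent peak")
            if self.intensity_ratio is None or not self.intensity_ratio < 1 + 1e-12:
                raise ValueError("retained decision requires phospho weaker than parent")


def filter_by_parent(
    candidates: list[PhosphoCandidate],
    pl: PeakList,
    params: PredictionParams = PredictionParams(),
    max_ratio: float = 1.0,
) -> list[FilterDecision]:
    """One decision per candidate: retained iff a parent peak exists within
    the PMF tolerance of the candidate's unmodified mass and the phospho
    peak is weaker than it.

    ``max_ratio`` tightens "weaker": retained requires
    phospho/parent < max_ratio (default 1.0 = any weaker).  When several
    peaks fall in the parent window the most intense one is taken as the
    parent, which favours retention.  ``pl`` must be the same
    contaminant-filtered PMF spectrum the candidates were predicted from.
    """
    decisions = []
    for cand in candidates:
        in_window = [
            p for p in pl.peaks if abs(p.mz - cand.parent_mh) <= params.pmf_tolerance
        ]
        if not in_window:
            decisions.append(FilterDecision(cand, None, "rejected_no_parent", None))
            continue
        parent = max(in_window, key=lambda p: p.intensity)
        if parent.intensity <= 0:
            decisions.append(FilterDecision(cand, parent, "rejected_intensity", None))
            continue
        ratio = cand.phospho_peak.intensity / parent.intensity
        if ratio < max_ratio:
            decisions.append(FilterDecision(cand, parent, "retained", ratio))
        else:
            decisions.append(FilterDecision(cand, parent, "rejected_intensity", ratio))
    return decisions


def retained_candidates(decisions: list[FilterDecision]) -> list[PhosphoCandidate]:
    return [d.candidate for d in decisions if d.verdict == "retained"]


def decision_report_rows(spot_id: str, decisions: list[FilterDecision]) -> list[dict]:
    return [
        {
            "spot_id": spot_id,
            "peptide": d.candidate.peptide.sequence,
            "observed_mz": round(d.candidate.phospho_peak.mz, 4),
            "parent_mz": round(d.parent_peak.mz, 4) if d.parent_peak else "",
            "verdict": d.verdict,
            "intensity_ratio": round(d.intensity_ratio, 4) if d.intensity_ratio is not None else "",
        }
        for d in decisions
    ]
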