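"""FindMod-style phosphopeptide prediction from PMF data.

Observed PMF peaks are first matched to unmodified theoretical tryptic
peptides (carrying fixed modifications).  Peaks left unmatched are then
scanned for a single variable-modification mass shift — in practice
the +80 Da phospho/sulfo class — against every peptide containing an
eligible residue.  Site localization is *not* attempted here: a
candidate carries every eligible S/T/Y position and is handed to the
MS/MS stage.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

from .constants import CARBAMIDOMETHYL, PHOSPHO, ModificationSpec
from .digestion import TheoreticalPeptide
from .masses import ModifiedPeptide, apply_fixed_modifications, peptide_mh
from .peaklist import Peak, PeakList


@dataclass(frozen=True)
class PredictionParams:
    """Knobs of the PMF prediction stage.

    Defaults mirror a standard FindMod run on MALDI data: ±0.1 Da
    tolerance on [M+H]+ monoisotopic masses, tryptic digest with one
    missed cleavage, fixed Cys carbamidomethylation and at most one
    variable modification per peptide, peptides considered in the
    700–4500 Da MALDI PMF window.
    """

    pmf_tolerance: float = 0.1
    max_missed: int = 1
    max_variable_mods: int = 1
    variable_specs: tuple[ModificationSpec, ...] = (PHOSPHO,)
    fixed_specs: tuple[ModificationSpec, ...] = (CARBAMIDOMETHYL,)
    mass_window: tuple[float, float] = (700.0, 4500.0)

    def __post_init__(self) -> None:
        if self.pmf_tolerance <= 0:
            raise ValueError("pmf_tolerance must be positive")
        if self.mass_window[0] >= self.mass_window[1]:
            raise ValueError("mass_window must be (min, max) with min < max")


@dataclass(frozen=True)
class PeptideMatch:
    peak: Peak
    peptide: TheoreticalPeptide
    theoretical_mh: float
    ambiguous: bool = False

    @property
    def mass_error(self) -> float:
        return self.peak.mz - self.theoretical_mh


@dataclass(frozen=True)
class PhosphoCandidate:
    """A PMF peak explained as peptide + one +80-class modification.

    ``candidate_sites`` lists every eligible residue position (1-based
    protein coordinates); localization is deferred to MS/MS scoring.
    """

    peptide: TheoreticalPeptide
    modification: str
    candidate_sites: tuple[int, ...]
    phospho_peak: Peak
    parent_mh: float  # theoretical unmodified (fixed mods only) [M+H]+
    mass_error: float  # observed - (parent_mh + delta)

    def __post_init__(self) -> None:
        if not self.candidate_sites:
            raise ValueError("candidate must have at least one eligible site")
        for pos in self.candidate_sites:
            if not self.peptide.start <= pos <= self.peptide.end:
                raise ValueError("candidate site outside peptide span")


def _base_mh(peptide: TheoreticalPeptide, params: PredictionParams) -> float:
    mods = apply_fixed_modifications(peptide.sequence, params.fixed_specs)
    return peptide_mh(ModifiedPeptide(peptide.sequence, mods))


def _windowed(
    peptides: list[TheoreticalPeptide], params: PredictionParams
) -> list[tuple[float, TheoreticalPeptide]]:
    lo, hi = params.mass_window
    out = []
    for pep in peptides:
        mh = _base_mh(pep, params)
        if lo <= mh <= hi:
            out.append((mh, pep))
    out.sort(key=lambda t: (t[0], t[1].start, t[1].end))
    return out


def _hits(
    index: list[tuple[float, TheoreticalPeptide]], target: float, tol: float
) -> list[tuple[float, TheoreticalPeptide]]:
    masses = [m for m, _ in index]
    lo = bisect.bisect_left(masses, target - tol)
    hi = bisect.bisect_right(masses, target + tol)
    return index[lo:hi]


def match_unmodified(
    pl: PeakList,
    peptides: list[TheoreticalPeptide],
    params: PredictionParams = PredictionParams(),
) -> tuple[list[PeptideMatch], list[Peak]]:
    """Assign PMF peaks to unmodified theoretical peptides.

    A peak matches when |observed − theoretical [M+H]+| ≤ tolerance;
    with several peptides in tolerance the nearest-mass one wins, and
    an exact tie reports every tied peptide flagged ambiguous.  Returns
    the matches and the peaks that matched nothing (the input to
    :func:`predict_phospho`).
    """
    index = _windowed(peptides, params)
    matched: list[PeptideMatch] = []
    unmatched: list[Peak] = []
    for peak in pl.peaks:
        hits = _hits(index, peak.mz, params.pmf_tolerance)
        if not hits:
            unmatched.append(peak)
            continue
        best = min(abs(mh - peak.mz) for mh, _ in hits)
        winners = [(mh, pep) for mh, pep in hits if abs(abs(mh - peak.mz) - best) < 1e-12]
        ambiguous = len(winners) > 1
        for mh, pep in winners:
            matched.append(PeptideMatch(peak, pep, mh, ambiguous=ambiguous))
    return matched, unmatched


def eligible_sites(peptide: TheoreticalPeptide, spec: ModificationSpec) -> tuple[int, ...]:
    """Protein positions (1-based) of residues the spec can modify."""
    return tuple(
        peptide.start + i
        for i, aa in enumerate(peptide.sequence)
        if aa in spec.targets
    )


def predict_phospho(
    unmatched_peaks: list[Peak],
    peptides: list[TheoreticalPeptide],
    params: PredictionParams = PredictionParams(),
) -> list[PhosphoCandidate]:
    """Scan unmatched PMF peaks for peptide + variable-mod mass matches.

    Emits one candidate per (peak, peptide, spec) triple satisfying
    |peak − (unmodified [M+H]+ + delta)| ≤ tolerance on a peptide with
    at least one eligible residue.  A peak may yield several candidates
    (different peptides); all are carried to the MS/MS stage.
    """
    index = _windowed(peptides, params)
    candidates: list[PhosphoCandidate] = []
    for peak in unmatched_peaks:
        for spec in params.variable_specs:
            for mh, pep in _hits(index, peak.mz - spec.delta, params.pmf_tolerance):
                sites = eligible_sites(pep, spec)
                if not sites:
                    continue
                candidates.append(
                    PhosphoCandidate(
                        peptide=pep,
                        modification=spec.name,
                        candidate_sites=sites,
                        phospho_peak=peak,
                        parent_mh=mh,
                        mass_error=peak.mz - (mh + spec.delta),
                    )
                )
    return candidates


def candidate_report_rows(spot_id: str, candidates: list[PhosphoCandidate]) -> list[dict]:
    """Flat dict rows for the TSV candidate report.  Counting convention:
    one row per (peak, peptide, modification) candidate, so a peak
    explained by several peptides contributes several rows."""
    return [
        {
            "spot_id": spot_id,
            "peptide": c.peptide.sequence,
            "protein": c.peptide.parent_id,
            "start": c.peptide.start,
            "end": c.peptide.end,
            "modification": c.modification,
            "observed_mz": round(c.phospho_peak.mz, 4),
            "theoretical_mz": round(c.parent_mh, 4),
            "error_mda": round(c.mass_error * 1000, 1),
        }
        for c in candidates
    ]
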