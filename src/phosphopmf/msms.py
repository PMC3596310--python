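"""Fragment-ion validation and phosphosite localization.

For every retained candidate, each eligible S/T/Y placement is turned
into a theoretical singly-charged b/y ladder (optionally with the
−98 Da H3PO4 neutral-loss ions diagnostic of pSer/pThr), matched
against the spot's MS/MS spectrum and scored.  The score is a binomial
ion score of this package's own design: with p the chance a random
spectrum peak lands in one fragment's match window,

    ion_score = −10·log10 P[X ≥ n_matched],   X ~ Binomial(n_theoretical, p)

which keeps the familiar −10·log10 scale and the >15 acceptance
threshold (p < 0.1 reading) of search-engine ion scores without
reproducing any particular engine's probability model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

from scipy import stats

from .constants import PROTON, WATER, ModificationSpec
from .masses import ModifiedPeptide, apply_fixed_modifications
from .peaklist import PeakList
from .prediction import PhosphoCandidate, PredictionParams


@dataclass(frozen=True)
class FragmentIon:
    series: Literal["b", "y"]
    index: int
    mz: float  # singly charged
    neutral_loss: Literal["none", "H3PO4"] = "none"

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("fragment index must be >= 1")
        if self.mz <= 0:
            raise ValueError("fragment m/z must be positive")


@dataclass(frozen=True)
class SitePlacementScore:
    site: int  # 1-based protein position
    n_theoretical: int
    n_matched: int
    ion_score: float  # -10*log10 P units

    def __post_init__(self) -> None:
        if not 0 <= self.n_matched <= self.n_theoretical:
            raise ValueError("matched ion count out of range")
        if self.ion_score < 0:
            raise ValueError("ion score must be non-negative")


@dataclass(frozen=True)
class ValidatedPhosphopeptide:
    spot_id: str
    candidate: PhosphoCandidate
    best_site: int  # 1-based protein position
    residue: Literal["S", "T", "Y"]
    ion_score: float
    ambiguous_sites: frozenset[int]
    placements: tuple[SitePlacementScore, ...] = ()

    def __post_init__(self) -> None:
        if self.best_site not in self.candidate.candidate_sites:
            raise ValueError("localized site is not among the candidate sites")


@dataclass(frozen=True)
class ValidationParams:
    msms_tolerance: float = 0.5  # Da, fragment matching
    score_threshold: float = 15.0  # accept strictly above
    include_neutral_loss: bool = True
    precursor_tolerance: float = 0.1  # Da, linking candidate peak to MS/MS precursor


def _residue_masses_with_mods(peptide: ModifiedPeptide) -> list[float]:
    from .constants import MASS_TABLE

    masses = [MASS_TABLE.residues[aa] for aa in peptide.sequence]
    for pos, spec in peptide.modifications:
        masses[pos - 1] += spec.delta
    return masses


def _loss_positions(peptide: ModifiedPeptide) -> list[tuple[int, float]]:
    """(position, loss mass) for modified residues that shed a neutral."""
    out = []
    for pos, spec in peptide.modifications:
        if spec.neutral_loss is not None and peptide.sequence[pos - 1] in spec.neutral_loss_targets:
            out.append((pos, spec.neutral_loss))
    return out


def theoretical_fragments(
    peptide: ModifiedPeptide, include_neutral_loss: bool = False
) -> list[FragmentIon]:
    """Singly-charged b and y ions of a modified peptide.

    For a peptide of length n the plain ladder holds 2(n−1) ions.  With
    ``include_neutral_loss`` every fragment containing a neutral-loss-
    capable modified residue (pS/pT) adds an ion at mz − 97.9769.
    """
    n = len(peptide.sequence)
    if n < 2:
        raise ValueError("fragmentation requires peptide length >= 2")
    masses = _residue_masses_with_mods(peptide)
    losses = _loss_positions(peptide)
    ions: list[FragmentIon] = []
    prefix = 0.0
    for i in range(1, n):
        prefix += masses[i - 1]
        mz = prefix + PROTON
        ions.append(FragmentIon("b", i, mz))
        if include_neutral_loss:
            for pos, loss in losses:
                if pos <= i:
                    ions.append(FragmentIon("b", i, mz - loss, neutral_loss="H3PO4"))
    suffix = 0.0
    for i in range(1, n):
        suffix += masses[n - i]
        mz = suffix + WATER + PROTON
        ions.append(FragmentIon("y", i, mz))
        if include_neutral_loss:
            for pos, loss in losses:
                if pos > n - i:
                    ions.append(FragmentIon("y", i, mz - loss, neutral_loss="H3PO4"))
    return ions


def score_placement(
    msms: PeakList,
    peptide: ModifiedPeptide,
    msms_tolerance: float = 0.5,
    include_neutral_loss: bool = True,
    site: int = 0,
) -> SitePlacementScore:
    """Match a placement's theoretical ions to a spectrum and score it.

    Each theoretical ion counts at most one match (the presence of any
    spectrum peak within tolerance), so dense noise cannot inflate the
    matched count beyond the ladder size.  The random-match probability
    p is estimated from the spectrum's peak density:
    p = min(1, 2·tol·|peaks| / (max mz − min mz)).
    """
    if msms.kind != "MSMS":
        raise ValueError("score_placement requires an MS/MS peak list")
    ions = theoretical_fragments(peptide, include_neutral_loss=include_neutral_loss)
    n_theoretical = len(ions)
    if len(msms.peaks) == 0:
        warnings.warn(f"empty MS/MS spectrum for spot {msms.spot_id}; score 0")
        return SitePlacementScore(site, n_theoretical, 0, 0.0)
    mzs = msms.mzs
    n_matched = sum(
        1 for ion in ions if any(abs(mz - ion.mz) <= msms_tolerance for mz in mzs)
    )
    if n_matched == 0:
        return SitePlacementScore(site, n_theoretical, 0, 0.0)
    span = mzs[-1] - mzs[0]
    p = 1.0 if span <= 0 else min(1.0, 2 * msms_tolerance * len(mzs) / span)
    tail = stats.binom.sf(n_matched - 1, n_theoretical, p)  # P[X >= n_matched]
    if tail <= 0:
        tail = 5e-324  # smallest positive float; caps the score
    import math

    score = max(0.0, -10.0 * math.log10(tail))
    return SitePlacementScore(site, n_theoretical, n_matched, score)


def placement_for_site(
    candidate: PhosphoCandidate,
    site: int,
    params: PredictionParams,
    spec: ModificationSpec,
) -> ModifiedPeptide:
    """The candidate's peptide with fixed mods plus the variable mod at a
    given protein position."""
    pep = candidate.peptide
    base = apply_fixed_modifications(pep.sequence, params.fixed_specs)
    local = site - pep.start + 1
    return ModifiedPeptide(pep.sequence, base + ((local, spec),))


def validate(
    spot_id: str,
    candidates: Sequence[PhosphoCandidate],
    msms_spectra: Sequence[PeakList],
    params: PredictionParams = PredictionParams(),
    vparams: ValidationParams = ValidationParams(),
) -> tuple[list[ValidatedPhosphopeptide], list[tuple[PhosphoCandidate, str]]]:
    """Score every site placement of every candidate against the matching
    MS/MS spectrum; localize and threshold.

    The matching spectrum is the one whose precursor lies within
    ``vparams.precursor_tolerance`` of the candidate's phospho peak
    (nearest wins).  Candidates with no such spectrum are returned in
    the diagnostics list as unvalidatable; placements are scored for
    the rest, the argmax site is reported, ties (score difference
    < 1e-9) are listed as ambiguous, and the peptide is emitted only if
    the best score exceeds the threshold.
    """
    spec_by_name = {s.name: s for s in params.variable_specs}
    validated: list[ValidatedPhosphopeptide] = []
    diagnostics: list[tuple[PhosphoCandidate, str]] = []
    for cand in candidates:
        matching = [
            s
            for s in msms_spectra
            if s.kind == "MSMS"
            and s.precursor_mz is not None
            and abs(s.precursor_mz - cand.phospho_peak.mz) <= vparams.precursor_tolerance
        ]
        if not matching:
            diagnostics.append((cand, "no MS/MS spectrum with matching precursor"))
            continue
        spectrum = min(matching, key=lambda s: abs(s.precursor_mz - cand.phospho_peak.mz))
        spec = spec_by_name[cand.modification]
        placements = tuple(
            score_placement(
                spectrum,
                placement_for_site(cand, site, params, spec),
                msms_tolerance=vparams.msms_tolerance,
                include_neutral_loss=vparams.include_neutral_loss,
                site=site,
            )
            for site in cand.candidate_sites
        )
        best = max(placements, key=lambda s: s.ion_score)
        if not best.ion_score > vparams.score_threshold:
            diagnostics.append((cand, f"best ion score {best.ion_score:.2f} <= threshold"))
            continue
        ties = frozenset(
            s.site for s in placements if abs(s.ion_score - best.ion_score) < 1e-9
        )
        residue = cand.peptide.sequence[best.site - cand.peptide.start]
        validated.append(
            ValidatedPhosphopeptide(
                spot_id=spot_id,
                candidate=cand,
                best_site=best.site,
                residue=residue,  # type: ignore[arg-type]
                ion_score=best.ion_score,
                ambiguous_sites=ties - {best.site},
                placements=placements,
            )
        )
    return validated, diagnostics


def validation_report_rows(validated: Sequence[ValidatedPhosphopeptide]) -> list[dict]:
    """TSV rows mirroring a site-inventory table: spot, protein, peptide
    with the localized site annotated, ion score, position range."""
    rows = []
    for v in validated:
        pep = v.candidate.peptide
        local = v.best_site - pep.start + 1
        annotated = "".join(
            aa + ("^P" if i == local else "") for i, aa in enumerate(pep.sequence, start=1)
        )
        rows.append(
            {
                "spot_id": v.spot_id,
                "protein": pep.parent_id,
                "peptide": annotated,
                "ion_score": round(v.ion_score, 2),
                "position": f"{pep.start}-{pep.end}",
                "site": v.best_site,
                "residue": v.residue,
                "ambiguous_sites": ";".join(map(str, sorted(v.ambiguous_sites))),
            }
        )
    return rows
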