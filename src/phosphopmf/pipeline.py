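"""End-to-end orchestration: spectra in, validated phosphosites out.

Stages, in order: contaminant erasure → unmodified-peptide matching →
+80 Da candidate prediction → parent coexistence/intensity filter →
MS/MS fragment validation with site localization → site-level
deduplication.  Each stage can only shrink the candidate set, so the
funnel counts are monotone non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .digestion import TheoreticalPeptide, digest
from .intensity_filter import FilterDecision, filter_by_parent, retained_candidates
from .msms import ValidatedPhosphopeptide, ValidationParams, validate
from .peaklist import ContaminantList, Peak, PeakList, filter_contaminants, read_contaminant_list
from .prediction import PhosphoCandidate, PredictionParams, match_unmodified, predict_phospho
from .summary import PhosphoSite, deduplicate_sites


@dataclass(frozen=True)
class FunnelCounts:
    """Spectrum/candidate counts through the pipeline stages."""

    raw_peaks: int
    contaminant_peaks_removed: int
    predicted_candidates: int
    retained_after_intensity_filter: int
    validated_peptides: int
    unique_sites: int

    def is_monotone(self) -> bool:
        return (
            self.raw_peaks
            >= self.raw_peaks - self.contaminant_peaks_removed
            and self.predicted_candidates
            >= self.retained_after_intensity_filter
            >= self.validated_peptides
            >= self.unique_sites
            >= 0
        )


@dataclass(frozen=True)
class SpotResult:
    spot_id: str
    filtered_pmf: PeakList
    removed_contaminants: tuple[tuple[Peak, str], ...]
    candidates: tuple[PhosphoCandidate, ...]
    decisions: tuple[FilterDecision, ...]
    validated: tuple[ValidatedPhosphopeptide, ...]
    diagnostics: tuple[tuple[PhosphoCandidate, str], ...]


@dataclass(frozen=True)
class PipelineResult:
    spots: dict[str, SpotResult]
    sites: tuple[PhosphoSite, ...]
    funnel: FunnelCounts

    @property
    def validated(self) -> list[ValidatedPhosphopeptide]:
        return [v for r in self.spots.values() for v in r.validated]


def run_pipeline(
    proteins: Mapping[str, str],
    pmf_by_spot: Mapping[str, PeakList],
    msms_by_spot: Mapping[str, Sequence[PeakList]],
    spot_to_protein: Mapping[str, str],
    contaminants: ContaminantList | None = None,
    params: PredictionParams = PredictionParams(),
    vparams: ValidationParams = ValidationParams(),
) -> PipelineResult:
    """Run every stage for every spot and collapse to unique sites.

    Each spot's PMF is matched against the digest of the protein the
    spot was assigned to (``spot_to_protein``); spots mapping to a
    protein absent from ``proteins`` raise.
    """
    if contaminants is None:
        contaminants = read_contaminant_list(tolerance=params.pmf_tolerance)
    digests: dict[str, list[TheoreticalPeptide]] = {}
    spot_results: dict[str, SpotResult] = {}
    raw_peaks = removed_total = predicted = retained_n = validated_n = 0
    for spot, pmf in pmf_by_spot.items():
        acc = spot_to_protein.get(spot)
        if acc is None or acc not in proteins:
            raise KeyError(f"spot {spot!r} has no protein sequence assigned")
        if acc not in digests:
            digests[acc] = digest(proteins[acc], acc, max_missed=params.max_missed)
        peptides = digests[acc]
        filtered, removed = filter_contaminants(pmf, contaminants)
        _, unmatched = match_unmodified(filtered, peptides, params)
        candidates = predict_phospho(unmatched, peptides, params)
        decisions = filter_by_parent(candidates, filtered, params)
        retained = retained_candidates(decisions)
        validated, diagnostics = validate(
            spot, retained, list(msms_by_spot.get(spot, ())), params, vparams
        )
        spot_results[spot] = SpotResult(
            spot_id=spot,
            filtered_pmf=filtered,
            removed_contaminants=tuple(removed),
            candidates=tuple(candidates),
            decisions=tuple(decisions),
            validated=tuple(validated),
            diagnostics=tuple(diagnostics),
        )
        raw_peaks += len(pmf)
        removed_total += len(removed)
        predicted += len(candidates)
        retained_n += len(retained)
        validated_n += len(validated)
    all_validated = [v for r in spot_results.values() for v in r.validated]
    sites = deduplicate_sites(all_validated)
    funnel = FunnelCounts(
        raw_peaks=raw_peaks,
        contaminant_peaks_removed=removed_total,
        predicted_candidates=predicted,
        retained_after_intensity_filter=retained_n,
        validated_peptides=validated_n,
        unique_sites=len(sites),
    )
    return PipelineResult(spots=spot_results, sites=tuple(sites), funnel=funnel)


@dataclass(frozen=True)
class RecoveryReport:
    """Planted-truth recovery of a pipeline run on a synthetic study."""

    n_planted: int
    n_recovered: int
    n_false: int

    @property
    def sensitivity(self) -> float:
        return self.n_recovered / self.n_planted if self.n_planted else float("nan")

    @property
    def fdr(self) -> float:
        found = self.n_recovered + self.n_false
        return self.n_false / found if found else 0.0


def evaluate_recovery(result: PipelineResult, truth_keys: set[tuple[str, int, str]]) -> RecoveryReport:
    found = {(s.accession, s.position, s.residue) for s in result.sites}
    return RecoveryReport(
        n_planted=len(truth_keys),
        n_recovered=len(found & truth_keys),
        n_false=len(found - truth_keys),
    )


def run_on_study(study, params: PredictionParams = PredictionParams(), vparams: ValidationParams = ValidationParams()) -> PipelineResult:
    """Convenience: run the pipeline on a generated synthetic study, using
    the study's own contaminant erasure list."""
    return run_pipeline(
        proteins=study.proteins,
        pmf_by_spot=study.pmf,
        msms_by_spot={k: list(v) for k, v in study.msms.items()},
        spot_to_protein=study.spot_to_protein,
        contaminants=study.contaminants,
        params=params,
        vparams=vparams,
    )
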