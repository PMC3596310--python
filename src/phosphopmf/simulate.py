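"""Synthetic 2-DE/MALDI study generator with planted ground truth.

Emulates the statistical structure the pipeline assumes: per-spot PMF
spectra containing every tryptic peptide of one protein with log-normal
intensities and Gaussian m/z error; sub-stoichiometric phosphopeptide
peaks at a fraction of their unmodified parent's intensity; injected
trypsin/keratin contaminant peaks; uniform chemical-noise peaks; and,
for every planted phosphopeptide, an MS/MS spectrum of its true b/y
ladder (optionally with H3PO4 neutral losses) plus noise.  Every peak
carries a provenance label so recovery can be scored exactly.

Deliberately not modelled: gel-level effects (pI/Mw shifts, staining),
isotope envelopes, multiply charged ions, co-migration (available as an
option), detector saturation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np

from .constants import PHOSPHO
from .digestion import TheoreticalPeptide, digest
from .masses import ModifiedPeptide, apply_fixed_modifications, peptide_mh
from .msms import theoretical_fragments
from .peaklist import ContaminantList, PeakList, make_peaklist, read_contaminant_list
from .prediction import PredictionParams

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-generation knobs.

    Defaults describe a plausible MALDI-TOF PMF experiment: external
    calibration mass error around 0.02 Da (well inside the ±0.1 Da
    matching tolerance), a few dozen chemical-noise peaks per spectrum,
    phosphopeptide peaks at 5–50% of their parent's intensity
    (phosphorylation is sub-stoichiometric and phosphopeptides ionize
    poorly), and log-normal peak intensities.
    """

    n_proteins: int = 20
    protein_length: tuple[int, int] = (150, 400)
    n_sites: int = 10
    phospho_intensity_fraction: tuple[float, float] = (0.05, 0.5)
    mz_sigma: float = 0.02
    n_noise_peaks: int = 30
    contaminant_rate: float = 0.2
    intensity_lognormal: tuple[float, float] = (3.0, 0.8)
    msms_n_noise_peaks: int = 20
    msms_mz_sigma: float = 0.02
    include_neutral_loss: bool = True
    comigration_rate: float = 0.0  # chance a spot also carries a second protein's peptides
    comigration_intensity: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.phospho_intensity_fraction
        if not (0 < lo <= hi < 1):
            raise ValueError("phospho_intensity_fraction must lie inside (0, 1)")
        for name in ("n_proteins", "n_sites", "n_noise_peaks", "msms_n_noise_peaks"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SimPeak:
    mz: float
    intensity: float
    provenance: str  # "peptide:...", "phospho:...", "contaminant:...", "noise"


@dataclass(frozen=True)
class PlantedSite:
    accession: str
    position: int  # 1-based protein coordinate
    residue: str
    spot_id: str
    peptide: TheoreticalPeptide  # fully cleaved carrier peptide


@dataclass(frozen=True)
class StudyTruth:
    planted_sites: tuple[PlantedSite, ...]
    provenance: dict[str, tuple[SimPeak, ...]]  # spot_id -> PMF peaks with labels

    def site_keys(self) -> set[tuple[str, int, str]]:
        return {(s.accession, s.position, s.residue) for s in self.planted_sites}


@dataclass(frozen=True)
class Study:
    config: SimulationConfig
    proteins: dict[str, str]
    spot_to_protein: dict[str, str]
    pmf: dict[str, PeakList]
    msms: dict[str, tuple[PeakList, ...]]
    truth: StudyTruth
    # the erasure list that belongs to this study: the injected list, or
    # empty when no contaminants were injected
    contaminants: ContaminantList = ContaminantList(entries=(), tolerance=0.1)


def _peptide_mh_fixed(pep: TheoreticalPeptide, params: PredictionParams) -> float:
    mods = apply_fixed_modifications(pep.sequence, params.fixed_specs)
    return peptide_mh(ModifiedPeptide(pep.sequence, mods))


def _draw_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def generate_study(
    config: SimulationConfig,
    params: PredictionParams = PredictionParams(),
    contaminants: ContaminantList | None = None,
) -> Study:
    """Generate proteins, planted sites, PMF and MS/MS spectra.

    One protein per spot.  Each planted site lies on an S/T/Y of a fully
    cleaved tryptic peptide whose unmodified mass falls in the PMF mass
    window, so its parent peak is present by construction.  Identical
    seeds give identical studies.
    """
    rng = np.random.default_rng(config.seed)
    if contaminants is None:
        contaminants = read_contaminant_list(tolerance=params.pmf_tolerance)
    mu, sigma = config.intensity_lognormal
    lo_mass, hi_mass = params.mass_window

    proteins: dict[str, str] = {}
    spot_to_protein: dict[str, str] = {}
    for i in range(config.n_proteins):
        length = int(rng.integers(config.protein_length[0], config.protein_length[1] + 1))
        acc = f"SYN{i:03d}"
        proteins[acc] = _draw_protein(rng, length)
        spot_to_protein[f"spot{i:03d}"] = acc

    digests = {acc: digest(seq, acc, max_missed=0) for acc, seq in proteins.items()}
    windowed = {
        acc: [p for p in peps if lo_mass <= _peptide_mh_fixed(p, params) <= hi_mass]
        for acc, peps in digests.items()
    }
    # theoretical masses the matching stage will consider (incl. missed
    # cleavages); used to keep planted sites mass-resolvable
    match_masses = {
        acc: sorted(
            mh
            for p in digest(seq, acc, max_missed=params.max_missed)
            if lo_mass <= (mh := _peptide_mh_fixed(p, params)) <= hi_mass
        )
        for acc, seq in proteins.items()
    }
    active_contaminants = (
        [mz for _, mz in contaminants.entries] if config.contaminant_rate > 0 else []
    )
    spots = sorted(spot_to_protein)

    # plant sites on eligible residues of windowed peptides
    planted: list[PlantedSite] = []
    taken: set[tuple[str, int]] = set()
    attempts = 0
    spec = PHOSPHO
    while len(planted) < config.n_sites:
        attempts += 1
        if attempts > 1000 * max(1, config.n_sites):
            raise RuntimeError(
                "could not plant the requested number of sites; "
                "proteins offer too few eligible S/T/Y residues in the mass window"
            )
        spot = spots[int(rng.integers(len(spots)))]
        acc = spot_to_protein[spot]
        peps = windowed[acc]
        if not peps:
            continue
        pep = peps[int(rng.integers(len(peps)))]
        eligible = [
            pep.start + j for j, aa in enumerate(pep.sequence) if aa in spec.targets
        ]
        if not eligible:
            continue
        pos = eligible[int(rng.integers(len(eligible)))]
        if (acc, pos) in taken:
            continue
        # a valid plant must be detectable in principle: its +80 peak must
        # not be isobaric with any theoretical peptide the matching stage
        # knows, its parent mass must be unique among the protein's
        # theoretical masses (no surrogate parents), and neither mass may
        # coincide with the active contaminant-erasure list.  Margin of
        # 2x tolerance absorbs the m/z jitter.
        mh_parent = _peptide_mh_fixed(pep, params)
        mh_phospho = mh_parent + spec.delta
        margin = 2 * params.pmf_tolerance
        if any(abs(mh_phospho - m) <= margin for m in match_masses[acc]):
            continue
        if any(
            abs(mh_parent - m) <= margin and abs(m - mh_parent) > 1e-9
            for m in match_masses[acc]
        ):
            continue
        if any(
            abs(mh_parent - c) <= margin or abs(mh_phospho - c) <= margin
            for c in active_contaminants
        ):
            continue
        taken.add((acc, pos))
        planted.append(
            PlantedSite(
                accession=acc,
                position=pos,
                residue=proteins[acc][pos - 1],
                spot_id=spot,
                peptide=pep,
            )
        )

    planted_by_spot: dict[str, list[PlantedSite]] = {}
    for s in planted:
        planted_by_spot.setdefault(s.spot_id, []).append(s)

    pmf: dict[str, PeakList] = {}
    msms: dict[str, tuple[PeakList, ...]] = {}
    provenance: dict[str, tuple[SimPeak, ...]] = {}
    for spot in spots:
        acc = spot_to_protein[spot]
        peaks: list[SimPeak] = []
        parent_obs: dict[tuple[int, int], tuple[float, float]] = {}
        for pep in windowed[acc]:
            mh = _peptide_mh_fixed(pep, params)
            obs = mh + rng.normal(0.0, config.mz_sigma) if config.mz_sigma > 0 else mh
            inten = float(rng.lognormal(mu, sigma))
            peaks.append(SimPeak(obs, inten, f"peptide:{acc}:{pep.start}-{pep.end}"))
            parent_obs[(pep.start, pep.end)] = (obs, inten)
        spot_msms: list[PeakList] = []
        for site in planted_by_spot.get(spot, []):
            pep = site.peptide
            _, parent_inten = parent_obs[(pep.start, pep.end)]
            frac = float(rng.uniform(*config.phospho_intensity_fraction))
            mh_phospho = _peptide_mh_fixed(pep, params) + spec.delta
            obs = (
                mh_phospho + rng.normal(0.0, config.mz_sigma)
                if config.mz_sigma > 0
                else mh_phospho
            )
            peaks.append(
                SimPeak(obs, parent_inten * frac, f"phospho:{acc}:{site.position}")
            )
            spot_msms.append(
                _msms_spectrum(rng, config, params, site, precursor=obs)
            )
        if config.comigration_rate > 0 and rng.random() < config.comigration_rate:
            others = [a for a in proteins if a != acc]
            if others:
                other = others[int(rng.integers(len(others)))]
                for pep in windowed[other]:
                    mh = _peptide_mh_fixed(pep, params)
                    obs = mh + rng.normal(0.0, config.mz_sigma) if config.mz_sigma > 0 else mh
                    inten = float(rng.lognormal(mu, sigma)) * config.comigration_intensity
                    peaks.append(
                        SimPeak(obs, inten, f"comigrated:{other}:{pep.start}-{pep.end}")
                    )
        for label, cmz in contaminants.entries:
            if rng.random() < config.contaminant_rate:
                obs = cmz + rng.normal(0.0, config.mz_sigma) if config.mz_sigma > 0 else cmz
                peaks.append(
                    SimPeak(obs, float(rng.lognormal(mu, sigma)), f"contaminant:{label}")
                )
        for _ in range(config.n_noise_peaks):
            peaks.append(
                SimPeak(
                    float(rng.uniform(lo_mass, hi_mass)),
                    float(rng.lognormal(mu, sigma)) * 0.2,
                    "noise",
                )
            )
        provenance[spot] = tuple(sorted(peaks, key=lambda p: p.mz))
        pmf[spot] = make_peaklist(spot, [(p.mz, p.intensity) for p in peaks], kind="PMF")
        msms[spot] = tuple(spot_msms)

    return Study(
        config=config,
        proteins=proteins,
        spot_to_protein=spot_to_protein,
        pmf=pmf,
        msms=msms,
        truth=StudyTruth(planted_sites=tuple(planted), provenance=provenance),
        contaminants=(
            contaminants
            if config.contaminant_rate > 0
            else ContaminantList(entries=(), tolerance=params.pmf_tolerance)
        ),
    )


def _msms_spectrum(
    rng: np.random.Generator,
    config: SimulationConfig,
    params: PredictionParams,
    site: PlantedSite,
    precursor: float,
) -> PeakList:
    pep = site.peptide
    base = apply_fixed_modifications(pep.sequence, params.fixed_specs)
    local = site.position - pep.start + 1
    placed = ModifiedPeptide(pep.sequence, base + ((local, PHOSPHO),))
    ions = theoretical_fragments(placed, include_neutral_loss=config.include_neutral_loss)
    pairs = []
    for ion in ions:
        obs = (
            ion.mz + rng.normal(0.0, config.msms_mz_sigma)
            if config.msms_mz_sigma > 0
            else ion.mz
        )
        pairs.append((obs, float(rng.lognormal(*config.intensity_lognormal))))
    lo = min(100.0, min(p[0] for p in pairs))
    for _ in range(config.msms_n_noise_peaks):
        pairs.append(
            (
                float(rng.uniform(lo, precursor)),
                float(rng.lognormal(*config.intensity_lognormal)) * 0.2,
            )
        )
    return make_peaklist(
        f"{site.spot_id} prec={precursor:.4f}",
        pairs,
        kind="MSMS",
        precursor_mz=precursor,
    )


DegradeOption = Literal["delete_parent", "swap_intensity", "noise_msms"]


def degrade_study(study: Study, option: DegradeOption, seed: int = 0) -> Study:
    """Targeted corruptions for negative tests.

    delete_parent   — remove every planted phosphopeptide's parent peak
                      (candidates must become rejected_no_parent);
    swap_intensity  — make every planted phospho peak more intense than
                      its parent (must become rejected_intensity);
    noise_msms      — replace MS/MS ladders with uniform noise of the
                      same size (validation must fail the threshold).
    """
    rng = np.random.default_rng(seed)
    parents = {
        (s.spot_id, f"peptide:{s.accession}:{s.peptide.start}-{s.peptide.end}")
        for s in study.truth.planted_sites
    }
    new_prov: dict[str, tuple[SimPeak, ...]] = {}
    new_pmf: dict[str, PeakList] = {}
    new_msms = dict(study.msms)
    for spot, peaks in study.truth.provenance.items():
        if option == "delete_parent":
            kept = tuple(p for p in peaks if (spot, p.provenance) not in parents)
        elif option == "swap_intensity":
            by_label = {p.provenance: p for p in peaks}
            out = []
            for p in peaks:
                if p.provenance.startswith("phospho:"):
                    acc, pos = p.provenance.split(":")[1:]
                    site = next(
                        s
                        for s in study.truth.planted_sites
                        if s.accession == acc and s.position == int(pos)
                    )
                    parent = by_label[
                        f"peptide:{acc}:{site.peptide.start}-{site.peptide.end}"
                    ]
                    # strictly out-shine the parent
                    out.append(replace(p, intensity=parent.intensity * 2.0))
                else:
                    out.append(p)
            kept = tuple(out)
        elif option == "noise_msms":
            kept = peaks
        else:
            raise ValueError(f"unknown degrade option {option!r}")
        new_prov[spot] = kept
        new_pmf[spot] = make_peaklist(spot, [(p.mz, p.intensity) for p in kept], kind="PMF")
    if option == "noise_msms":
        for spot, spectra in study.msms.items():
            noisy = []
            for spec in spectra:
                n = len(spec.peaks)
                lo = spec.peaks[0].mz if n else 100.0
                hi = spec.precursor_mz or (spec.peaks[-1].mz if n else 1000.0)
                pairs = [
                    (float(rng.uniform(lo, hi)), float(rng.lognormal(3.0, 0.8)))
                    for _ in range(n)
                ]
                noisy.append(
                    make_peaklist(spec.spot_id, pairs, kind="MSMS", precursor_mz=spec.precursor_mz)
                )
            new_msms[spot] = tuple(noisy)
    return replace(
        study,
        pmf=new_pmf,
        msms=new_msms,
        truth=replace(study.truth, provenance=new_prov),
    )


def write_study(study: Study, outdir: str | Path) -> None:
    """Write FASTA + two-column PMF + MGF MS/MS + truth TSV."""
    from .peaklist import write_mgf, write_two_column

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "proteins.fasta", "w") as fh:
        for acc, seq in study.proteins.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    for spot, pl in study.pmf.items():
        write_two_column(outdir / f"{spot}.pmf.txt", pl)
    all_msms = [s for spectra in study.msms.values() for s in spectra]
    if all_msms:
        write_mgf(outdir / "msms.mgf", all_msms)
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("accession\tposition\tresidue\tspot_id\tpeptide\tstart\tend\n")
        for s in study.truth.planted_sites:
            fh.write(
                f"{s.accession}\t{s.position}\t{s.residue}\t{s.spot_id}\t"
                f"{s.peptide.sequence}\t{s.peptide.start}\t{s.peptide.end}\n"
            )
    with open(outdir / "spots.tsv", "w") as fh:
        fh.write("spot_id\taccession\n")
        for spot, acc in sorted(study.spot_to_protein.items()):
            fh.write(f"{spot}\t{acc}\n")
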