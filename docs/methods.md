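# Methods

## Problem and approach

Protein spots resolved on two-dimensional gels are routinely identified
by peptide mass fingerprinting (PMF): the spot is digested with trypsin
and the observed MALDI [M+H]+ masses are matched against the theoretical
digest of the identified protein. The same PMF data can be mined for
phosphorylation: a peptide carrying one phosphate appears 79.9663 Da
above its unmodified mass. `phosphopmf` implements that mining as a
five-stage pipeline:

1. **Contaminant erasure.** Peaks within a mass tolerance of a
   configurable list of trypsin-autolysis and keratin masses are removed
   before any matching. The shipped list is configuration, not code —
   the masses appropriate to a given instrument/lab must be curated
   locally, and the packaged keratin set is a curated stand-in.
2. **Unmodified matching.** Remaining peaks are matched to the spot
   protein's theoretical tryptic peptides (cleavage C-terminal to K/R
   except before proline, up to 1 missed cleavage, fixed Cys
   carbamidomethylation) within ±0.1 Da. Ties go to the nearest mass;
   exact ties are reported for both peptides and flagged ambiguous.
3. **+80 Da scanning.** Peaks that matched nothing are tested against
   every peptide containing S/T/Y for a single +80-class shift.
   Phosphorylation (+79.9663) and sulfation (+79.9568) differ by less
   than 0.01 Da, far inside the PMF tolerance, so prediction treats
   them as one class; the MS/MS stage is what can favour phospho, via
   the −98 Da H3PO4 neutral loss that pSer/pThr shed and sulfo does
   not. A peak may yield several candidates (different peptides); all
   are carried forward.
4. **Coexistence/intensity filter.** Phosphorylation is
   sub-stoichiometric and phosphopeptides ionize poorly, so a genuine
   phosphopeptide ion coexists with its unmodified parent ion and is
   weaker. Candidates whose parent peak is absent from the spectrum,
   or whose peak is at least as intense as the parent's, are discarded.
   "Weaker" is implemented as strict inequality (ratio < 1); a
   `max_ratio` knob allows a stricter cutoff, since the qualitative
   observation ("much weaker") fixes no ratio. When several peaks fall
   in the parent window the most intense is taken as the parent, which
   favours retention. Raw peak heights are compared, not
   signal-to-noise.
5. **MS/MS validation and localization.** Every eligible S/T/Y
   placement of a retained candidate is expanded into its singly
   charged b/y ladder (plus neutral-loss ions when enabled) and matched
   against the spot's MS/MS spectrum at ±0.5 Da. The placement scores
   are compared; the argmax localizes the site, ties (score difference
   < 1e-9) are reported as ambiguous rather than broken arbitrarily,
   and the peptide is accepted only if the best score exceeds 15.

Validated peptides are collapsed to unique (accession, position,
residue) sites; repeated detections across spots become supporting
peptides of one site. Site-level outputs are the residue distribution,
a −6..+6 motif count matrix (gap-padded at termini; full protein
sequence context preferred, longest supporting peptide otherwise), a
novelty flag, and a per-protein isoform table.

## The ion score

The score is this package's own simplification of search-engine ion
scores. With `n_theoretical` ladder ions, of which `n_matched` have at
least one spectrum peak within the MS/MS tolerance `t`, and a
random-match probability estimated from the spectrum's peak density

    p = min(1, 2·t·|peaks| / (max m/z − min m/z)),

the score is `−10·log10 P[X ≥ n_matched]` with `X ~ Binomial(n_theoretical, p)`,
and 0 when nothing matches. Each theoretical ion can contribute at most
one match, so dense noise cannot inflate the count beyond the ladder
size. The −10·log10 scale keeps the conventional acceptance threshold
of 15 (tail probability ≈ 0.0316 < 0.1) meaningful: on pure-noise
spectra (50 uniform peaks over 100–1000 Da) the score exceeds 15 in
about 2% of replicates, consistent with the p < 0.1 reading of the
threshold. The score is monotone in `n_matched` at fixed ladder size
and density. It is *not* comparable numerically to MASCOT ion scores;
only the thresholding behaviour is retained.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| PMF tolerance | 0.1 | Da | standard FindMod-style PMF window for externally calibrated MALDI-TOF |
| missed cleavages | 1 | — | typical tryptic digest completeness |
| variable mods per peptide | 1 | — | single-modification scanning; more placements explode ambiguity at PMF resolution |
| fixed modification | Cam (+57.021464 on C) | Da | iodoacetamide treatment |
| +80 class | +79.966331 (phospho), +79.956815 (sulfo) | Da | Unimod monoisotopic deltas |
| mass window | 700–4500 | Da | typical MALDI PMF acquisition range |
| MS/MS tolerance | 0.5 | Da | TOF/TOF fragment accuracy |
| score threshold | 15 | −10·log10 P | p < 0.1 significance reading |
| Met oxidation | off at PMF stage | — | an MS/MS-stage variable mod; enabling it at PMF scanning is one `PredictionParams` change |

All mass constants live in `src/phosphopmf/data/monoisotopic_constants.txt`
(key=value text, overridable via `load_constants(path)`) so tests pin
exact values. I and L are distinct letters with identical mass;
ambiguity codes (B/J/X/Z) are rejected because candidate masses must be
exact.

## Synthetic studies

`generate_study` emulates the statistical structure the pipeline
assumes, one protein per gel spot: i.i.d. uniform-residue proteins
(150–400 aa), a PMF containing every fully cleaved tryptic peptide in
the mass window with log-normal intensities (log-mean 3, log-sd 0.8,
unitless — only ratios matter) and Gaussian m/z error (σ = 0.02 Da),
planted phosphopeptide peaks at 5–50% of their parent's intensity,
contaminant peaks injected with probability 0.2 per list entry, 30
uniform noise peaks per spectrum, and per planted site an MS/MS
spectrum of the true fragment ladder plus noise. Defaults are plausible
conditions for an externally calibrated MALDI-TOF instrument; a
co-migration option injects a second protein's peptides at low
intensity to exercise the false-prediction pathway.

Planted ground truth must be *detectable in principle* to be valid
truth: the generator re-draws a plant whose +80 mass is isobaric
(within twice the PMF tolerance) with any theoretical peptide of the
protein (such a peak is absorbed by unmodified matching), whose parent
mass is not unique among the protein's theoretical masses (a
surrogate parent would mask parent-deletion), or whose masses collide
with the active erasure list. Without this invariant a planted site can
be unrecoverable for reasons unrelated to noise, and recovery metrics
would conflate method behaviour with degenerate truth.

`degrade_study` applies targeted corruptions — delete parent peaks,
make phospho peaks out-shine parents, replace MS/MS ladders with noise
— each of which must trip exactly one rejection pathway.

Passing tests on these studies show the pipeline's logic and its
statistical behaviour under controlled error models. They do not show
robustness to what the generator omits: isotope envelopes, multiply
charged ions, detector saturation, correlated chemical noise, ionization
suppression beyond a fixed intensity fraction, gel-level artifacts, or
real co-migration complexity.

## Numerical and design choices

- Matching uses a mass-sorted index with binary search; tests assert
  the contract (set equality with an exhaustive triple-loop oracle),
  not the mechanism.
- Peak lists are sorted, with duplicate m/z within 1e-6 merged on
  construction and rejected on direct instantiation.
- Empty spectra score 0 with a warning rather than raising.
- Novelty is an exact lookup of (supporting peptide sequence, site
  offset) in a user-supplied known-site table. The original
  database-BLAST novelty determination is irreproducible offline and
  version-dependent; the reduction is deliberate and documented. With
  no table supplied, novelty is `undetermined`.
- Functional classification is consumed as an annotation column of the
  packaged inventory, never computed.
- The packaged 48-row phosphopeptide inventory carries peptide-level
  position ranges but not full protein sequences, so motif context for
  it uses peptide-context mode with gap padding.

## Limitations

- The ion score is a stand-in: its absolute values are not comparable
  to any search engine's, so published scores cannot be reproduced
  numerically — only site identities and threshold behaviour.
- Singly charged b/y ions only; no a/c/z series, no 2+ fragments, no
  isotope envelopes.
- The +80 class is reported as phosphorylation when neutral-loss
  evidence or a pY-only site supports it; a true sulfopeptide with no
  discriminating ions would be indistinguishable.
- Contaminant erasure can remove genuine peptide peaks that happen to
  be isobaric with a list entry; erasure is reported per peak so such
  losses are auditable.
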