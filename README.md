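# phosphopmf

Identification of in vivo phosphorylation sites directly from the
peptide mass fingerprints (PMF) of protein spots on two-dimensional
gels.

2-DE-based proteomics leaves behind large archives of MALDI PMF
spectra for identified, differentially expressed protein spots. Those
spectra already contain phosphorylation information: a peptide carrying
one phosphate shows up 79.9663 Da above its unmodified mass.
`phosphopmf` turns that observation into a tested pipeline for
proteomics researchers who want to mine existing 2-DE/MS archives for
phosphosites without running a new enrichment-based phosphoproteomics
experiment:

1. erase trypsin-autolysis and keratin contaminant peaks from the PMF;
2. match remaining peaks to the spot protein's theoretical tryptic
   digest (±0.1 Da, ≤1 missed cleavage, fixed Cys carbamidomethylation);
3. scan unmatched peaks for a +80 Da phospho-class shift
   (phospho +79.9663 and sulfo +79.9568 are indistinguishable at PMF
   tolerance and are treated as one class);
4. keep only candidates whose unmodified parent peak coexists in the
   spectrum and is more intense (phosphorylation is sub-stoichiometric
   and phosphopeptides ionize poorly);
5. validate retained candidates against MS/MS spectra by singly charged
   b/y fragment matching, localize the site by scoring every candidate
   S/T/Y placement with a binomial ion score
   (−10·log₁₀ P[X ≥ n_matched], X ~ Binomial(n_theoretical, p); accept
   above 15), then collapse validated peptides into unique
   (protein, position, residue) phosphosites with residue statistics,
   −6..+6 motif counts, novelty flags and per-protein isoform tables.

A synthetic-study generator (`generate_study`) plants phosphosites in
random proteins and emits PMF + MS/MS spectra with full per-peak
provenance, so every stage is testable against known ground truth; a
48-row phosphopeptide inventory of cotton-fiber proteins is packaged as
a reference fixture. See `docs/methods.md` for the model, parameter
rationale and limitations.

## Worked example

A spot-135 PMF shows the unmodified enolase peptide YNQLLR at 806.4639
and a weaker peak at 886.4885. The theoretical [M+H]+ of YNQLLR is
806.4519 (within ±0.1 Da of the observed peak) and its phospho form is
886.4182 (within ±0.1 Da of the second peak), so the +80 scan predicts
a phosphopeptide whose only eligible residue is the tyrosine at protein
position 417:

```python
from phosphopmf import (PredictionParams, digest, make_peaklist, run_pipeline,
                        ModifiedPeptide, PHOSPHO, theoretical_fragments)

protein = ("ADEFGHILMNPQVW" * 40)[:415] + "K" + "YNQLLR"   # YNQLLR at 417-422
pmf = make_peaklist("spot135", [(806.4639, 100.0), (886.4885, 18.0)])
ladder = theoretical_fragments(ModifiedPeptide("YNQLLR", ((1, PHOSPHO),)),
                               include_neutral_loss=True)
msms = make_peaklist("spot135", [(i.mz, 50.0) for i in ladder],
                     kind="MSMS", precursor_mz=886.4885)
result = run_pipeline({"ENO": protein}, {"spot135": pmf}, {"spot135": [msms]},
                      {"spot135": "ENO"})
print(result.funnel)
site = result.sites[0]
print(site.accession, site.position, site.residue,
      round(result.validated[0].ion_score, 2))
```

prints

```
FunnelCounts(raw_peaks=2, contaminant_peaks_removed=0, predicted_candidates=1, retained_after_intensity_filter=1, validated_peptides=1, unique_sites=1)
ENO 417 Y 173.01
```

i.e. the 886.4885 peak is predicted as phosphorylated YNQLLR, survives
the parent-intensity filter (18 < 100), and the pY placement matches
the full fragment ladder, localizing the site to Tyr-417 far above the
acceptance threshold of 15.

The packaged inventory reproduces the expected site-level statistics:

```sh
$ phosphopmf inventory-summary
peptide rows: 48
unique sites: 40
repeat detections: 13 rows in 5 groups
residue distribution: S=22 T=14 Y=4
distinct spots: 40
```

A full synthetic round trip:

```sh
phosphopmf simulate --seed 1 --n-proteins 5 --n-sites 3 --outdir study/
phosphopmf run --fasta study/proteins.fasta --pmf-dir study/ \
    --mgf study/msms.mgf --spots study/spots.tsv --outdir out/
```

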