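"""Shared fixtures: the packaged site-inventory records and a synthetic
enolase-like worked example (YNQLLR at protein positions 417-422)."""

from __future__ import annotations

import pytest

from phosphopmf import (
    PHOSPHO,
    ModifiedPeptide,
    PredictionParams,
    digest,
    load_site_inventory,
    make_peaklist,
    theoretical_fragments,
)

# printed PMF peak values of the unmodified and phosphorylated YNQLLR ions
YNQLLR_PARENT_PEAK = 806.4639
YNQLLR_PHOSPHO_PEAK = 886.4885


@pytest.fixture(scope="session")
def inventory_records():
    return load_site_inventory()


@pytest.fixture(scope="session")
def enolase_example():
    """A 422-residue protein whose tryptic digest places YNQLLR at
    417-422, with a PMF holding the two printed peaks and an MS/MS
    spectrum of the pY-NQLLR fragment ladder."""
    filler = ("ADEFGHILMNPQVW" * 40)[:415]  # no K/R/S/T/Y/C
    protein = filler + "K" + "YNQLLR"
    assert protein[416:422] == "YNQLLR"
    params = PredictionParams()
    peptides = digest(protein, "ENO_SYN", max_missed=params.max_missed)
    pmf = make_peaklist(
        "spot135", [(YNQLLR_PARENT_PEAK, 100.0), (YNQLLR_PHOSPHO_PEAK, 18.0)]
    )
    placed = ModifiedPeptide("YNQLLR", ((1, PHOSPHO),))
    ladder = theoretical_fragments(placed, include_neutral_loss=True)
    msms = make_peaklist(
        "spot135",
        [(ion.mz, 50.0) for ion in ladder],
        kind="MSMS",
        precursor_mz=YNQLLR_PHOSPHO_PEAK,
    )
    return {
        "protein": protein,
        "accession": "ENO_SYN",
        "peptides": peptides,
        "pmf": pmf,
        "msms": msms,
        "params": params,
    }
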