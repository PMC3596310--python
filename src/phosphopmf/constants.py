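"""Monoisotopic mass constants and modification specifications.

All masses in the package are monoisotopic and all peptide ions are
singly protonated ([M+H]+), matching MALDI-TOF peptide mass
fingerprinting conventions.  The numeric values live in a key=value
text file shipped with the package (``data/monoisotopic_constants.txt``)
so they can be pinned by tests and overridden from configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal


@dataclass(frozen=True)
class ResidueMassTable:
    """Monoisotopic residue masses plus the water and proton constants.

    ``residues`` maps one-letter amino acid codes to residue masses
    (the amino acid minus water, in Da).  A peptide's neutral mass is
    the sum of its residue masses plus one water; [M+H]+ adds a proton.
    """

    residues: dict[str, float]
    water_mass: float
    proton_mass: float

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.residues)
        if missing:
            raise ValueError(f"residue mass table incomplete, missing {sorted(missing)}")
        if any(m <= 0 for m in self.residues.values()):
            raise ValueError("residue masses must be positive")
        if self.water_mass <= 0 or self.proton_mass <= 0:
            raise ValueError("water and proton masses must be positive")


@dataclass(frozen=True)
class ModificationSpec:
    """A covalent modification: a mass delta on a set of target residues.

    ``mode`` distinguishes fixed modifications (applied unconditionally,
    e.g. carbamidomethylation of Cys after iodoacetamide treatment) from
    variable ones (enumerated placements, e.g. phosphorylation of
    S/T/Y).  ``max_per_peptide`` caps variable placements per peptide.
    """

    name: str
    delta: float
    targets: frozenset[str]
    mode: Literal["fixed", "variable"] = "variable"
    max_per_peptide: int = 1
    # Neutral loss observed from modified residues under CID, e.g. the
    # -98 Da H3PO4 loss diagnostic of pSer/pThr.  None disables it.
    neutral_loss: float | None = None
    neutral_loss_targets: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"modification {self.name!r} has no target residues")
        if self.max_per_peptide < 0:
            raise ValueError("max_per_peptide must be >= 0")
        import math

        if not math.isfinite(self.delta):
            raise ValueError("modification delta must be finite")


def _parse_constants(text: str) -> dict[str, float]:
    values: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"constants file line {lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        values[key.strip()] = float(val)
    return values


def load_constants(path: str | Path | None = None) -> tuple[ResidueMassTable, dict[str, float], dict[str, float]]:
    """Load the constants file; returns (mass table, mod deltas, neutral losses).

    ``path=None`` reads the packaged default table.
    """
    if path is None:
        text = (resources.files("phosphopmf.data") / "monoisotopic_constants.txt").read_text()
    else:
        text = Path(path).read_text()
    values = _parse_constants(text)
    residues = {k.split(".", 1)[1]: v for k, v in values.items() if k.startswith("residue.")}
    mods = {k.split(".", 1)[1]: v for k, v in values.items() if k.startswith("mod.")}
    losses = {k.split(".", 1)[1]: v for k, v in values.items() if k.startswith("neutral_loss.")}
    table = ResidueMassTable(residues=residues, water_mass=values["water"], proton_mass=values["proton"])
    return table, mods, losses


MASS_TABLE, _MOD_DELTAS, _NEUTRAL_LOSSES = load_constants()

WATER = MASS_TABLE.water_mass
PROTON = MASS_TABLE.proton_mass
H3PO4 = _NEUTRAL_LOSSES["H3PO4"]

CARBAMIDOMETHYL = ModificationSpec(
    name="Carbamidomethyl",
    delta=_MOD_DELTAS["Carbamidomethyl"],
    targets=frozenset("C"),
    mode="fixed",
)

OXIDATION = ModificationSpec(
    name="Oxidation",
    delta=_MOD_DELTAS["Oxidation"],
    targets=frozenset("M"),
)

# Phosphorylation and sulfation are near-isobaric (Δ < 0.01 Da): at the
# ±0.1 Da PMF tolerance every +80 mass match is ambiguous between them.
# Prediction therefore treats them as one "+80 class" carried under the
# Phospho spec; MS/MS neutral-loss evidence is what favours phospho.
PHOSPHO = ModificationSpec(
    name="Phospho",
    delta=_MOD_DELTAS["Phospho"],
    targets=frozenset("STY"),
    neutral_loss=H3PO4,
    neutral_loss_targets=frozenset("ST"),
)

SULFO = ModificationSpec(
    name="Sulfo",
    delta=_MOD_DELTAS["Sulfo"],
    targets=frozenset("STY"),
)

STANDARD_MODS = {m.name: m for m in (CARBAMIDOMETHYL, OXIDATION, PHOSPHO, SULFO)}
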