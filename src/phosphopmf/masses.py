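"""Peptide mass arithmetic: [M+H]+ of modified peptides and variable-mod
enumeration.

Everything downstream (digest matching, +80 scanning, fragment ions)
reduces to :func:`peptide_mh`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .constants import MASS_TABLE, ModificationSpec, ResidueMassTable


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence with positioned modifications.

    ``modifications`` holds ``(position, spec)`` pairs with 1-based
    positions inside the peptide.  Invariants (positions in range,
    residue eligibility, variable-mod cap) are checked on construction.
    """

    sequence: str
    modifications: tuple[tuple[int, ModificationSpec], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        var_counts: dict[str, int] = {}
        for pos, spec in self.modifications:
            if not 1 <= pos <= n:
                raise ValueError(f"modification position {pos} outside peptide of length {n}")
            residue = self.sequence[pos - 1]
            if residue not in spec.targets:
                raise ValueError(
                    f"residue {residue!r} at position {pos} is not a target of {spec.name}"
                )
            if spec.mode == "variable":
                var_counts[spec.name] = var_counts.get(spec.name, 0) + 1
                if var_counts[spec.name] > spec.max_per_peptide:
                    raise ValueError(
                        f"more than {spec.max_per_peptide} {spec.name} placements on one peptide"
                    )

    @property
    def variable_modifications(self) -> tuple[tuple[int, ModificationSpec], ...]:
        return tuple((p, s) for p, s in self.modifications if s.mode == "variable")

    def annotated(self) -> str:
        """Annotated string with ``^<name-abbrev>`` after modified residues,
        e.g. ``Y^PNQLLR`` for N-terminally phosphorylated YNQLLR."""
        marks = {pos: spec for pos, spec in self.modifications}
        out = []
        for i, aa in enumerate(self.sequence, start=1):
            out.append(aa)
            if i in marks:
                name = marks[i].name
                abbrev = {"Phospho": "P", "Carbamidomethyl": "Cam", "Oxidation": "Ox", "Sulfo": "S80"}.get(name, name)
                out.append(f"^{abbrev}")
        return "".join(out)


def residue_mass_sum(sequence: str, table: ResidueMassTable = MASS_TABLE) -> float:
    total = 0.0
    for i, aa in enumerate(sequence, start=1):
        try:
            total += table.residues[aa]
        except KeyError:
            raise ValueError(
                f"unknown residue code {aa!r} at position {i}; only the 20 standard one-letter codes are accepted"
            ) from None
    return total


def peptide_mh(peptide: ModifiedPeptide | str, table: ResidueMassTable = MASS_TABLE) -> float:
    """Monoisotopic [M+H]+ mass of a (possibly modified) peptide, in Da.

    Sum of residue masses + water + proton + modification deltas.
    """
    if isinstance(peptide, str):
        peptide = ModifiedPeptide(peptide)
    if not peptide.sequence:
        raise ValueError("peptide sequence is empty")
    mass = residue_mass_sum(peptide.sequence, table) + table.water_mass + table.proton_mass
    for _, spec in peptide.modifications:
        mass += spec.delta
    return mass


def apply_fixed_modifications(
    sequence: str, fixed_specs: Sequence[ModificationSpec]
) -> tuple[tuple[int, ModificationSpec], ...]:
    """Placements of every fixed spec on every eligible residue."""
    placements = []
    for pos, aa in enumerate(sequence, start=1):
        for spec in fixed_specs:
            if spec.mode == "fixed" and aa in spec.targets:
                placements.append((pos, spec))
    return tuple(placements)


def enumerate_variable_modifications(
    sequence: str,
    specs: Iterable[ModificationSpec],
) -> list[ModifiedPeptide]:
    """All modification states of ``sequence`` with at most one variable
    modification placed (the unmodified state first).

    Fixed specs in ``specs`` are applied to every form unconditionally;
    each variable spec contributes one form per eligible residue.  With
    ``max_per_peptide=1`` (the default used throughout) the output size
    is ``1 + number of eligible residues`` per variable spec.
    """
    specs = list(specs)
    fixed = [s for s in specs if s.mode == "fixed"]
    variable = [s for s in specs if s.mode == "variable"]
    base = apply_fixed_modifications(sequence, fixed)
    forms = [ModifiedPeptide(sequence, base)]
    for spec in variable:
        if spec.max_per_peptide < 1:
            continue
        for pos, aa in enumerate(sequence, start=1):
            if aa in spec.targets:
                forms.append(ModifiedPeptide(sequence, base + ((pos, spec),)))
    return forms
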