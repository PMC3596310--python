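"""Site-level summaries: deduplication, residue distribution, motif
context, novelty flags and per-protein isoform tables.

Validated phosphopeptides are collapsed to unique (accession, position,
residue) sites; repeated detections of the same site across gel spots
become supporting peptides of one site.  The packaged site-inventory
fixture (48 annotated phosphopeptide rows of cotton-fiber proteins) is
loaded through :func:`load_site_inventory`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .msms import ValidatedPhosphopeptide

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

# marker names are a closed set; longest-first so ^Cam is not read as ^C+"am"
_ANNOT = re.compile(r"\^(Cam|Ox|S80|P)")


def parse_annotated_peptide(annotated: str) -> tuple[str, list[tuple[int, str]]]:
    """Split e.g. ``Y^PNQLLR`` into (``YNQLLR``, [(1, 'P')]).

    Markers like ``^P`` / ``^Cam`` follow the modified residue; the
    returned positions are 1-based in the plain sequence.
    """
    sequence: list[str] = []
    mods: list[tuple[int, str]] = []
    i = 0
    while i < len(annotated):
        ch = annotated[i]
        if ch == "^":
            m = _ANNOT.match(annotated, i)
            if m is None or not sequence:
                raise ValueError(f"dangling modification marker in {annotated!r}")
            mods.append((len(sequence), m.group(1)))
            i = m.end()
        else:
            if ch.upper() not in AMINO_ACIDS:
                raise ValueError(f"unexpected character {ch!r} in {annotated!r}")
            sequence.append(ch.upper())
            i += 1
    return "".join(sequence), mods


@dataclass(frozen=True)
class PeptideSiteRecord:
    """One validated phosphopeptide observation with a localized site."""

    spot_id: str
    accession: str
    peptide: str  # plain sequence
    start: int  # 1-based inclusive protein coordinates
    end: int
    site: int  # 1-based protein position of the phosphosite
    residue: Literal["S", "T", "Y"]
    ion_score: float
    protein_name: str = ""
    category: str = ""
    known_flag: bool | None = None  # external database annotation, if any

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.peptide):
            raise ValueError("position range inconsistent with peptide length")
        if not self.start <= self.site <= self.end:
            raise ValueError("phosphosite outside the peptide's position range")
        if self.peptide[self.site - self.start] != self.residue:
            raise ValueError("annotated residue disagrees with peptide sequence")

    @property
    def site_offset(self) -> int:
        """1-based offset of the site within the peptide."""
        return self.site - self.start + 1


def record_from_validated(v: ValidatedPhosphopeptide) -> PeptideSiteRecord:
    pep = v.candidate.peptide
    return PeptideSiteRecord(
        spot_id=v.spot_id,
        accession=pep.parent_id,
        peptide=pep.sequence,
        start=pep.start,
        end=pep.end,
        site=v.best_site,
        residue=v.residue,
        ion_score=v.ion_score,
    )


def load_site_inventory(path: str | Path | None = None) -> list[PeptideSiteRecord]:
    """The packaged 48-row phosphopeptide inventory (annotated peptides
    with protein position ranges, ion scores and database-known flags)."""
    if path is None:
        source = resources.files("phosphopmf.data") / "cotton_fiber_phosphopeptides.tsv"
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", dtype={"spot": str})
    else:
        df = pd.read_csv(path, sep="\t", dtype={"spot": str})
    records = []
    for row in df.itertuples(index=False):
        sequence, mods = parse_annotated_peptide(row.peptide)
        phospho = [pos for pos, name in mods if name == "P"]
        if len(phospho) != 1:
            raise ValueError(f"expected exactly one ^P marker in {row.peptide!r}")
        offset = phospho[0]
        site = int(row.start) + offset - 1
        records.append(
            PeptideSiteRecord(
                spot_id=str(row.spot),
                accession=row.accession,
                peptide=sequence,
                start=int(row.start),
                end=int(row.end),
                site=site,
                residue=sequence[offset - 1],  # type: ignore[arg-type]
                ion_score=float(row.ion_score),
                protein_name=row.protein_name,
                category=row.category,
                known_flag=bool(row.p3db_known),
            )
        )
    return records


@dataclass(frozen=True)
class PhosphoSite:
    """A unique phosphosite after deduplication across spots/peptides."""

    accession: str
    position: int
    residue: Literal["S", "T", "Y"]
    supporting_peptides: tuple[PeptideSiteRecord, ...]
    novelty: Literal["known", "new", "undetermined"] = "undetermined"

    def __post_init__(self) -> None:
        if not self.supporting_peptides:
            raise ValueError("a site needs at least one supporting peptide")


def deduplicate_sites(
    records: Sequence[PeptideSiteRecord | ValidatedPhosphopeptide],
) -> list[PhosphoSite]:
    """Group records by (accession, position, residue) → unique sites.

    Conflicting residue claims at one (accession, position) indicate
    corrupt input and raise.  Idempotent: re-deduplicating the
    supporting peptides of the output reproduces it.
    """
    recs = [
        r if isinstance(r, PeptideSiteRecord) else record_from_validated(r)
        for r in records
    ]
    by_pos: dict[tuple[str, int], str] = {}
    groups: dict[tuple[str, int, str], list[PeptideSiteRecord]] = {}
    for r in recs:
        key_pos = (r.accession, r.site)
        if key_pos in by_pos and by_pos[key_pos] != r.residue:
            raise ValueError(
                f"conflicting residues {by_pos[key_pos]}/{r.residue} at {r.accession}:{r.site}"
            )
        by_pos[key_pos] = r.residue
        groups.setdefault((r.accession, r.site, r.residue), []).append(r)
    sites = []
    for (acc, pos, res), members in groups.items():
        uniq: list[PeptideSiteRecord] = []
        for m in members:
            if m not in uniq:
                uniq.append(m)
        sites.append(
            PhosphoSite(accession=acc, position=pos, residue=res, supporting_peptides=tuple(uniq))  # type: ignore[arg-type]
        )
    sites.sort(key=lambda s: (s.accession, s.position))
    return sites


def repeat_statistics(sites: Sequence[PhosphoSite]) -> tuple[int, int]:
    """(rows in multi-peptide groups, number of multi-peptide groups)."""
    multi = [s for s in sites if len(s.supporting_peptides) > 1]
    return sum(len(s.supporting_peptides) for s in multi), len(multi)


def residue_distribution(sites: Sequence[PhosphoSite]) -> dict[str, int]:
    counts = {"S": 0, "T": 0, "Y": 0}
    for s in sites:
        counts[s.residue] += 1
    return counts


@dataclass(frozen=True)
class MotifMatrix:
    """Residue counts around phosphosites, positions −flank..+flank.

    ``counts`` is a DataFrame indexed by residue (20 amino acids plus a
    gap row for context beyond the protein/peptide termini), one column
    per relative position; every column sums to the number of
    contributing sites.
    """

    counts: pd.DataFrame
    n_sites: int

    def frequencies(self, include_gaps: bool = False) -> pd.DataFrame:
        df = self.counts if include_gaps else self.counts.drop(index=GAP)
        return df / self.counts.sum(axis=0)


def _site_context(
    site: PhosphoSite, sequences: Mapping[str, str] | None, flank: int
) -> str:
    """Flanking residues around the site, gap-padded to 2*flank+1."""
    if sequences is not None and site.accession in sequences:
        seq = sequences[site.accession]
        if not 1 <= site.position <= len(seq):
            raise ValueError(
                f"site position {site.position} outside supplied sequence for {site.accession}"
            )
        center = site.position
        window = []
        for off in range(-flank, flank + 1):
            p = center + off
            window.append(seq[p - 1] if 1 <= p <= len(seq) else GAP)
        return "".join(window)
    # peptide-context mode: take the longest supporting peptide
    rec = max(site.supporting_peptides, key=lambda r: len(r.peptide))
    window = []
    for off in range(-flank, flank + 1):
        p = rec.site_offset + off
        window.append(rec.peptide[p - 1] if 1 <= p <= len(rec.peptide) else GAP)
    return "".join(window)


def motif_matrix(
    sites: Sequence[PhosphoSite],
    protein_sequences: Mapping[str, str] | None = None,
    flank: int = 6,
) -> MotifMatrix:
    """Count residues at positions −flank..+flank around each site.

    Context is read from the full protein sequence when available,
    otherwise from the longest supporting peptide with gap-padding
    outside it.  Position 0 is the phosphosite itself.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    positions = list(range(-flank, flank + 1))
    counts = pd.DataFrame(0, index=list(AMINO_ACIDS) + [GAP], columns=positions)
    for site in sites:
        context = _site_context(site, protein_sequences, flank)
        for pos, aa in zip(positions, context):
            counts.loc[aa, pos] += 1
    return MotifMatrix(counts=counts, n_sites=len(sites))


def annotate_novelty(
    sites: Sequence[PhosphoSite],
    known_sites: Iterable[tuple[str, int]] | None,
) -> list[PhosphoSite]:
    """Flag sites as known/new by exact lookup of (peptide sequence,
    1-based site offset) in a user-supplied known-site table; with no
    table every site is undetermined."""
    if known_sites is None:
        return [replace(s, novelty="undetermined") for s in sites]
    known = {(pep, int(off)) for pep, off in known_sites}
    out = []
    for s in sites:
        hit = any((r.peptide, r.site_offset) in known for r in s.supporting_peptides)
        out.append(replace(s, novelty="known" if hit else "new"))
    return out


def group_isoforms(
    records: Sequence[PeptideSiteRecord | ValidatedPhosphopeptide],
    spot_to_protein: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-protein isoform table: which gel spots of each protein carry
    which phosphosites.

    ``spot_to_protein`` may extend the table with spots of the same
    proteins that had no validated phosphopeptide (unphosphorylated
    isoforms); spots mapping to no accession are listed under
    ``unmapped``.  Returns one row per (accession, spot).
    """
    recs = [
        r if isinstance(r, PeptideSiteRecord) else record_from_validated(r)
        for r in records
    ]
    rows: dict[tuple[str, str], set[int]] = {}
    for r in recs:
        rows.setdefault((r.accession, r.spot_id), set()).add(r.site)
    if spot_to_protein is not None:
        seen_spots = {spot for _, spot in rows}
        for spot, acc in spot_to_protein.items():
            if spot not in seen_spots:
                rows.setdefault((acc or "unmapped", spot), set())
    table = pd.DataFrame(
        [
            {
                "accession": acc,
                "spot_id": spot,
                "phosphorylated": bool(sites),
                "n_sites": len(sites),
                "sites": ";".join(map(str, sorted(sites))),
            }
            for (acc, spot), sites in sorted(rows.items())
        ]
    )
    return table


def sites_table(sites: Sequence[PhosphoSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "accession": s.accession,
                "position": s.position,
                "residue": s.residue,
                "n_supporting_peptides": len(s.supporting_peptides),
                "spots": ";".join(sorted({r.spot_id for r in s.supporting_peptides})),
                "max_ion_score": max(r.ion_score for r in s.supporting_peptides),
                "novelty": s.novelty,
            }
            for s in sites
        ]
    )
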