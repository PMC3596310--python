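"""Spectrum containers, peak-list I/O and contaminant-peak erasure.

PMF spectra arrive either as simple two-column text (m/z, intensity)
or as MGF; MS/MS spectra as MGF.  Contaminant erasure removes peaks
within a mass tolerance of a configurable list of trypsin-autolysis
and keratin masses before any modification scanning, emulating the
Peakeraser step of the workflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

from pyteomics import mgf as _mgf


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass(frozen=True)
class PeakList:
    """One spot's spectrum: sorted (m/z, intensity) pairs.

    ``kind`` distinguishes MS1 fingerprints (PMF) from MS/MS spectra;
    the latter carry the precursor [M+H]+ in ``precursor_mz``.
    """

    spot_id: str
    kind: Literal["PMF", "MSMS"]
    peaks: tuple[Peak, ...]
    precursor_mz: float | None = None

    def __post_init__(self) -> None:
        mzs = [p.mz for p in self.peaks]
        if mzs != sorted(mzs):
            raise ValueError("peaks must be sorted ascending by m/z")
        for a, b in zip(mzs, mzs[1:]):
            if abs(a - b) < 1e-6:
                raise ValueError(f"duplicate m/z {a} within 1e-6 tolerance")
        if self.kind == "MSMS" and self.precursor_mz is None:
            raise ValueError("MS/MS peak list requires a precursor m/z")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mzs(self) -> list[float]:
        return [p.mz for p in self.peaks]


def make_peaklist(
    spot_id: str,
    pairs: Iterable[tuple[float, float]],
    kind: Literal["PMF", "MSMS"] = "PMF",
    precursor_mz: float | None = None,
) -> PeakList:
    """Build a PeakList from unsorted (m/z, intensity) pairs, merging
    duplicate m/z values (within 1e-6) by summing intensities."""
    ordered = sorted(pairs)
    merged: list[list[float]] = []
    for mz, inten in ordered:
        if merged and abs(mz - merged[-1][0]) < 1e-6:
            merged[-1][1] += inten
        else:
            merged.append([mz, inten])
    return PeakList(
        spot_id=spot_id,
        kind=kind,
        peaks=tuple(Peak(mz, inten) for mz, inten in merged),
        precursor_mz=precursor_mz,
    )


@dataclass(frozen=True)
class ContaminantList:
    entries: tuple[tuple[str, float], ...]
    tolerance: float = 0.1  # Da; defaults to the PMF matching tolerance

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("contaminant tolerance must be positive")


def read_peaklist(
    path: str | Path,
    dialect: Literal["two-column", "MGF"] = "two-column",
    spot_id: str | None = None,
) -> PeakList:
    """Read one spectrum from a two-column text file or a 1-spectrum MGF."""
    path = Path(path)
    if dialect == "two-column":
        pairs = []
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'm/z intensity', got {raw!r}")
            try:
                mz, inten = float(fields[0]), float(fields[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric field in {raw!r}") from None
            pairs.append((mz, inten))
        if not pairs:
            warnings.warn(f"empty spectrum in {path}")
        return make_peaklist(spot_id or path.stem, pairs, kind="PMF")
    if dialect == "MGF":
        spectra = read_mgf(path)
        if not spectra:
            warnings.warn(f"empty MGF file {path}")
            return make_peaklist(spot_id or path.stem, [], kind="PMF")
        if len(spectra) > 1:
            raise ValueError(f"{path} holds {len(spectra)} spectra; use read_mgf for multi-spectrum files")
        return spectra[0]
    raise ValueError(f"unknown dialect {dialect!r}")


def read_mgf(path: str | Path) -> list[PeakList]:
    """All spectra of an MGF file.  TITLE is the spot id (an optional
    ``spot=...`` token inside TITLE wins); PEPMASS is the precursor."""
    spectra = []
    with _mgf.read(str(path), use_index=False) as reader:
        for spec in reader:
            params = spec.get("params", {})
            title = str(params.get("title", "")).strip()
            spot = title
            for token in title.split():
                if token.startswith("spot="):
                    spot = token[len("spot="):]
            pepmass = params.get("pepmass")
            precursor = float(pepmass[0]) if pepmass else None
            pairs = list(zip(spec["m/z array"], spec["intensity array"]))
            spectra.append(
                make_peaklist(
                    spot or Path(path).stem,
                    [(float(mz), float(i)) for mz, i in pairs],
                    kind="MSMS" if precursor is not None else "PMF",
                    precursor_mz=precursor,
                )
            )
    return spectra


def write_mgf(path: str | Path, spectra: Sequence[PeakList]) -> None:
    entries = []
    for pl in spectra:
        params = {"title": pl.spot_id}
        if pl.precursor_mz is not None:
            params["pepmass"] = pl.precursor_mz
        entries.append(
            {
                "params": params,
                "m/z array": [p.mz for p in pl.peaks],
                "intensity array": [p.intensity for p in pl.peaks],
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def write_two_column(path: str | Path, pl: PeakList) -> None:
    lines = [f"{p.mz:.4f} {p.intensity:.4f}" for p in pl.peaks]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_contaminant_list(path: str | Path | None = None, tolerance: float = 0.1) -> ContaminantList:
    """Load a contaminant mass list (label, m/z per line); ``None`` loads
    the packaged trypsin-autolysis + keratin default."""
    if path is None:
        text = (resources.files("phosphopmf.data") / "contaminants.txt").read_text()
    else:
        text = Path(path).read_text()
    entries = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 2:
            raise ValueError(f"contaminant list line {lineno}: expected 'label m/z', got {raw!r}")
        entries.append((fields[0], float(fields[1])))
    return ContaminantList(entries=tuple(entries), tolerance=tolerance)


def filter_contaminants(
    pl: PeakList, cl: ContaminantList
) -> tuple[PeakList, list[tuple[Peak, str]]]:
    """Erase contaminant peaks from a PMF spectrum.

    A peak within ``cl.tolerance`` of any contaminant mass is removed
    and reported with the label of the nearest entry; all other peaks
    pass through unchanged, so removed and retained partition the input.
    """
    if pl.kind != "PMF":
        raise ValueError("contaminant filtering applies to PMF spectra")
    kept: list[Peak] = []
    removed: list[tuple[Peak, str]] = []
    for peak in pl.peaks:
        best: tuple[float, str] | None = None
        for label, mz in cl.entries:
            d = abs(peak.mz - mz)
            if d <= cl.tolerance and (best is None or d < best[0]):
                best = (d, label)
        if best is None:
            kept.append(peak)
        else:
            removed.append((peak, best[1]))
    return replace(pl, peaks=tuple(kept)), removed
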