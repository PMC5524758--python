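"""MS/MS spectrum container and plain-text I/O (MGF and a simple CSV dialect)."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

__all__ = ["MsmsSpectrum", "read_mgf", "write_mgf", "read_spectrum_csv", "write_spectrum_csv"]


@dataclass
class MsmsSpectrum:
    precursor_mz: float
    peaks: np.ndarray  # (n, 2) array of (mz, intensity), sorted by mz
    polarity: str = "negative"
    retention_time: float | None = None
    title: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if np.any(self.peaks[:, 1] < 0):
            raise ValueError("peak intensities must be non-negative")
        order = np.argsort(self.peaks[:, 0], kind="stable")
        self.peaks = self.peaks[order]

    @property
    def mz(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def intensity(self) -> np.ndarray:
        return self.peaks[:, 1]

    def __len__(self) -> int:
        return len(self.peaks)


def write_mgf(spectra: Iterable[MsmsSpectrum], path: str | Path) -> None:
    """Write spectra as MGF with negative charge (CHARGE=1-)."""
    with open(path, "w") as fh:
        for spec in spectra:
            fh.write("BEGIN IONS\n")
            if spec.title:
                fh.write(f"TITLE={spec.title}\n")
            fh.write(f"PEPMASS={spec.precursor_mz:.6f}\n")
            fh.write("CHARGE=1-\n")
            if spec.retention_time is not None:
                fh.write(f"RTINSECONDS={spec.retention_time * 60.0:.3f}\n")
            for mz, inten in spec.peaks:
                fh.write(f"{mz:.6f} {inten:.4f}\n")
            fh.write("END IONS\n")


def read_mgf(path: str | Path) -> Iterator[MsmsSpectrum]:
    """Parse an MGF file (the small subset this package writes)."""
    title = ""
    pepmass = None
    rt = None
    charge = ""
    peaks: list[tuple[float, float]] = []
    in_block = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line == "BEGIN IONS":
                in_block, title, pepmass, rt, charge, peaks = True, "", None, None, "", []
            elif line == "END IONS":
                if pepmass is None:
                    raise ValueError("MGF block without PEPMASS")
                yield MsmsSpectrum(
                    precursor_mz=pepmass,
                    peaks=np.array(peaks).reshape(-1, 2),
                    polarity="negative" if "-" in charge else "positive",
                    retention_time=rt,
                    title=title,
                )
                in_block = False
            elif in_block and "=" in line:
                key, _, value = line.partition("=")
                if key == "TITLE":
                    title = value
                elif key == "PEPMASS":
                    pepmass = float(value.split()[0])
                elif key == "RTINSECONDS":
                    rt = float(value) / 60.0
                elif key == "CHARGE":
                    charge = value
            elif in_block:
                parts = line.split()
                peaks.append((float(parts[0]), float(parts[1]) if len(parts) > 1 else 0.0))


def write_spectrum_csv(spec: MsmsSpectrum, path: str | Path) -> None:
    """One spectrum as CSV: header row carries the precursor, then mz,intensity."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["precursor_mz", spec.precursor_mz])
        writer.writerow(["polarity", spec.polarity])
        writer.writerow(["mz", "intensity"])
        for mz, inten in spec.peaks:
            writer.writerow([f"{mz:.6f}", f"{inten:.4f}"])


def read_spectrum_csv(path: str | Path) -> MsmsSpectrum:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    header = {row[0]: row[1] for row in rows[:2]}
    peaks = [(float(mz), float(inten)) for mz, inten in rows[3:]]
    return MsmsSpectrum(
        precursor_mz=float(header["precursor_mz"]),
        peaks=np.array(peaks).reshape(-1, 2),
        polarity=header.get("polarity", "negative"),
    )
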