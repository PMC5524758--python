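"""Rule-based structural annotation of negative-mode phospholipid MS/MS spectra.

Head groups are classified from diagnostic neutral losses/fragments, acyl
chains from carboxylate anions, PC ether chains from their reported
diagnostic ions; chain combinations are then screened against the
precursor mass (|error| < 0.05 Da) and the best-matching candidate wins.
Spectra that fire no rule are reported with head group "unknown".
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Iterable

import numpy as np

from . import masses
from .nomenclature import Chain, format_lipid_name, primary_id
from .spectra import MsmsSpectrum

__all__ = ["LipidAnnotation", "annotate", "annotate_many", "write_annotations_csv"]

PRECURSOR_TOLERANCE = 0.05  # Da, the accepted-annotation mass-error bound

# chain search grid for carboxylate matching
_CHAIN_GRID = [(c, d) for c in range(12, 27) for d in range(0, 7)]

_ADDUCTS = (masses.ADDUCT_M_MINUS_H, masses.ADDUCT_M_PLUS_FORMATE)

# head-group diagnostic -> candidate lipid classes
_CLASSES_FOR_HEADGROUP = {
    "PC": ("PC", "LPC"),
    "PE": ("PE", "LPE"),
    "PI": ("PI",),
    "PS": ("PS", "LPS"),
}


@dataclass
class LipidAnnotation:
    head_group: str  # PC/PE/PI/PS/LPC/LPE/LPS/FA/unknown
    chains: tuple[Chain, ...]
    adduct: str | None
    theoretical_mz: float | None
    mass_error: float | None
    name: str

    @property
    def is_identified(self) -> bool:
        return self.head_group != "unknown"


def _match_peak(spectrum: MsmsSpectrum, target: float, tolerance: float) -> bool:
    return bool(np.any(np.abs(spectrum.mz - target) <= tolerance))


def _matched_chains(
    spectrum: MsmsSpectrum, tolerance: float
) -> tuple[list[Chain], list[Chain]]:
    """Acyl chains (carboxylate anions) and PC ether chains seen in the spectrum."""
    acyl = [
        Chain("acyl", c, d)
        for c, d in _CHAIN_GRID
        if _match_peak(spectrum, masses.fa_anion_mz(c, d), tolerance)
    ]
    ether = [
        Chain("ether", c, d)
        for (c, d), mz in masses.ETHER_FRAGMENT_MZ.items()
        if _match_peak(spectrum, mz, tolerance)
    ]
    return acyl, ether


def _fired_headgroups(spectrum: MsmsSpectrum, tolerance: float) -> list[str]:
    fired = []
    for hg, rule in masses.headgroup_diagnostics().items():
        target = (
            spectrum.precursor_mz - float(rule["mass"])
            if rule["kind"] == "loss"
            else float(rule["mass"])
        )
        if _match_peak(spectrum, target, tolerance):
            fired.append(hg)
    return fired


def _candidate_combos(
    lipid_class: str, acyl: list[Chain], ether: list[Chain]
) -> Iterable[tuple[Chain, ...]]:
    lyso = lipid_class.startswith("L")
    if lyso:
        for chain in acyl:
            yield (chain,)
        return
    for pair in combinations_with_replacement(sorted(acyl, key=lambda c: c.sort_key), 2):
        yield pair
    if lipid_class == "PC":
        for e in ether:
            for a in acyl:
                yield (e, a)


def _unknown() -> LipidAnnotation:
    return LipidAnnotation("unknown", (), None, None, None, "unknown")


def annotate(spectrum: MsmsSpectrum, tolerance: float = 0.01) -> LipidAnnotation:
    """Annotate one negative-mode spectrum; returns "unknown" when no rule fires.

    ``tolerance`` is the fragment match tolerance (Da); the precursor match
    bound is the fixed 0.05 Da accepted-annotation limit.
    """
    if spectrum.polarity != "negative":
        raise ValueError(f"only negative-mode spectra are supported, got {spectrum.polarity!r}")
    if spectrum.precursor_mz <= 0:
        raise ValueError("spectrum has no valid precursor m/z")

    acyl, ether = _matched_chains(spectrum, tolerance)
    candidates: list[LipidAnnotation] = []

    for hg in _fired_headgroups(spectrum, tolerance):
        for lipid_class in _CLASSES_FOR_HEADGROUP[hg]:
            for combo in _candidate_combos(lipid_class, acyl, ether):
                try:
                    neutral = masses.lipid_neutral_mass(
                        lipid_class, [(c.linkage, c.carbons, c.double_bonds) for c in combo]
                    )
                except ValueError:
                    continue
                for adduct in _ADDUCTS:
                    theory = masses.adduct_mz(neutral, adduct)
                    err = theory - spectrum.precursor_mz
                    if abs(err) < PRECURSOR_TOLERANCE:
                        candidates.append(
                            LipidAnnotation(
                                lipid_class,
                                tuple(sorted(combo, key=lambda c: c.sort_key)),
                                adduct,
                                theory,
                                err,
                                format_lipid_name(lipid_class, list(combo)),
                            )
                        )

    # free fatty acid: the precursor itself is a carboxylate anion
    for c, d in _CHAIN_GRID:
        theory = masses.fa_anion_mz(c, d)
        err = theory - spectrum.precursor_mz
        if abs(err) < tolerance:
            candidates.append(
                LipidAnnotation(
                    "FA",
                    (Chain("acyl", c, d),),
                    masses.ADDUCT_M_MINUS_H,
                    theory,
                    err,
                    format_lipid_name("FA", [Chain("acyl", c, d)]),
                )
            )

    if not candidates:
        return _unknown()
    return min(candidates, key=lambda a: abs(a.mass_error))


def annotate_many(
    spectra: Iterable[MsmsSpectrum], tolerance: float = 0.01
) -> list[tuple[MsmsSpectrum, LipidAnnotation]]:
    return [(spec, annotate(spec, tolerance)) for spec in spectra]


def write_annotations_csv(
    results: Iterable[tuple[MsmsSpectrum, LipidAnnotation]], path: str | Path
) -> None:
    """CSV of primary id, common name, adduct, theoretical m/z, mass error."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["primary_id", "common_name", "adduct", "theoretical_mz", "mass_error"])
        for spec, ann in results:
            rt = spec.retention_time if spec.retention_time is not None else 0.0
            writer.writerow(
                [
                    primary_id(rt, spec.precursor_mz),
                    ann.name,
                    ann.adduct or "",
                    f"{ann.theoretical_mz:.4f}" if ann.theoretical_mz is not None else "",
                    f"{ann.mass_error:+.4f}" if ann.mass_error is not None else "",
                ]
            )
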