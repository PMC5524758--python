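"""Exact-mass arithmetic for negative-mode phospholipid annotation.

Monoisotopic element masses, neutral formulas for the supported
glycerophospholipid classes, fatty-acid carboxylate anions, adduct
arithmetic, and the diagnostic head-group fragments/losses used by the
rule-based annotator.

Every diagnostic constant exposed here is recomputed from the element
mass table at import time and checked against its reference value at
the reference precision; a mismatch aborts import.
"""

from __future__ import annotations

import math
from collections.abc import Mapping

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "FORMATE_ADDUCT_MASS",
    "ADDUCT_M_MINUS_H",
    "ADDUCT_M_PLUS_FORMATE",
    "monoisotopic_mass",
    "parse_formula",
    "fa_anion_mz",
    "fa_neutral_mass",
    "adduct_mz",
    "headgroup_diagnostics",
    "ether_fragment_mz",
    "ETHER_FRAGMENT_MZ",
    "lipid_neutral_formula",
    "lipid_neutral_mass",
]

# CODATA/IUPAC monoisotopic masses, Da
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}

ELECTRON_MASS = 0.00054857990
# mass of H+ (H atom minus electron)
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

ADDUCT_M_MINUS_H = "[M-H]-"
ADDUCT_M_PLUS_FORMATE = "[M+HCOO]-"


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style formula string like ``"C26H50NO7P"`` into counts."""
    import re

    counts: dict[str, int] = {}
    pos = 0
    for m in re.finditer(r"([A-Z][a-z]?)(\d*)", formula):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at offset {pos}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + (int(m.group(2)) if m.group(2) else 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def monoisotopic_mass(formula: str | Mapping[str, int]) -> float:
    """Monoisotopic mass (Da) of a neutral formula.

    ``formula`` is either a Hill string (``"C2H4O2"``) or a mapping of
    element symbol to count. An empty formula has mass 0.
    """
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    total = 0.0
    for element, n in counts.items():
        if n < 0:
            raise ValueError(f"negative count for element {element}")
        try:
            total += MONOISOTOPIC_MASS[element] * n
        except KeyError:
            raise ValueError(f"unknown element {element!r}") from None
    return total


def _validate_chain(carbons: int, double_bonds: int) -> None:
    if carbons < 2:
        raise ValueError(f"fatty-acid chain needs >=2 carbons, got {carbons}")
    if not (0 <= double_bonds <= carbons // 2):
        raise ValueError(
            f"invalid unsaturation {double_bonds} for a {carbons}-carbon chain"
        )


def fa_neutral_mass(carbons: int, double_bonds: int) -> float:
    """Neutral monoisotopic mass of the free fatty acid CnH(2n-2d)O2."""
    _validate_chain(carbons, double_bonds)
    return monoisotopic_mass(
        {"C": carbons, "H": 2 * carbons - 2 * double_bonds, "O": 2}
    )


def fa_anion_mz(carbons: int, double_bonds: int) -> float:
    """m/z of the fatty-acid carboxylate anion [FA-H]-."""
    return fa_neutral_mass(carbons, double_bonds) - PROTON_MASS


FORMATE_ADDUCT_MASS = monoisotopic_mass("CHO2") + ELECTRON_MASS  # HCOO- as adduct


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """Negative-mode adduct m/z: [M-H]- or [M+HCOO]-."""
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    if adduct == ADDUCT_M_MINUS_H:
        return neutral_mass - PROTON_MASS
    if adduct == ADDUCT_M_PLUS_FORMATE:
        return neutral_mass + FORMATE_ADDUCT_MASS
    raise ValueError(f"unknown adduct {adduct!r}")


# ---------------------------------------------------------------------------
# Head-group diagnostics
# ---------------------------------------------------------------------------

def headgroup_diagnostics() -> dict[str, dict[str, object]]:
    """Diagnostic rules per head group, computed from element masses.

    PC spectra show a neutral loss of methyl formate (C2H4O2) from the
    precursor; PE a phosphoethanolamine fragment; PI a dehydrated
    inositol-phosphate fragment; PS a neutral loss of the serine residue.
    Returned values carry ``kind`` ("loss" matched as precursor - fragment,
    "fragment" matched directly against peak m/z) and the theoretical mass.
    """
    return {
        "PC": {"kind": "loss", "mass": monoisotopic_mass("C2H4O2")},
        "PE": {"kind": "fragment", "mass": monoisotopic_mass("C2H8NO4P") - PROTON_MASS},
        "PI": {"kind": "fragment", "mass": monoisotopic_mass("C6H11O8P") - PROTON_MASS},
        "PS": {"kind": "loss", "mass": monoisotopic_mass("C3H5NO2")},
    }


# printed reference values these rules must reproduce at 2 dp
_HEADGROUP_REFERENCE = {"PC": 60.02, "PE": 140.01, "PI": 241.01, "PS": 87.03}


# ---------------------------------------------------------------------------
# Ether-linked chain diagnostics (PC only)
# ---------------------------------------------------------------------------

# Reported diagnostic ions for the ether-LPC-like fragment of PC O- chains.
# The elemental composition is not certain; the lookup is validated at import
# against the demethylated ether-LPC interpretation within 5 mDa.
ETHER_FRAGMENT_MZ: Mapping[tuple[int, int], float] = {
    (16, 0): 466.3303,
    (16, 1): 464.3147,
    (18, 0): 494.3616,
    (18, 1): 492.3460,
}


def ether_fragment_mz(carbons: int, double_bonds: int) -> float:
    """Diagnostic fragment m/z for a supported PC ether chain O-c:d."""
    try:
        return ETHER_FRAGMENT_MZ[(carbons, double_bonds)]
    except KeyError:
        raise ValueError(
            f"unsupported ether chain O-{carbons}:{double_bonds}; "
            f"supported: {sorted(ETHER_FRAGMENT_MZ)}"
        ) from None


# ---------------------------------------------------------------------------
# Neutral lipid formulas
# ---------------------------------------------------------------------------

# Per-class composition as a function of total chain carbons n, total double
# bonds d and the number of ether linkages e (each ether linkage removes one
# O and adds two H relative to the all-acyl form).
_CLASS_FORMULA = {
    # class: (n_chains, C offset, H offset, N, O offset, P)
    "PC": (2, 8, 16, 1, 8, 1),
    "PE": (2, 5, 10, 1, 8, 1),
    "PI": (2, 9, 15, 0, 13, 1),
    "PS": (2, 6, 10, 1, 10, 1),
    "LPC": (1, 8, 18, 1, 7, 1),
    "LPE": (1, 5, 12, 1, 7, 1),
    "LPS": (1, 6, 12, 1, 9, 1),
    "FA": (1, 0, 0, 0, 2, 0),
}


def lipid_neutral_formula(
    head_group: str, chains: list[tuple[str, int, int]]
) -> dict[str, int]:
    """Neutral elemental composition of a lipid.

    ``chains`` is a list of (linkage, carbons, double_bonds) with linkage
    "acyl" or "ether". FA takes a single acyl chain and yields the free acid.
    """
    if head_group not in _CLASS_FORMULA:
        raise ValueError(f"unsupported lipid class {head_group!r}")
    n_chains, c0, h0, n_count, o0, p_count = _CLASS_FORMULA[head_group]
    if len(chains) != n_chains:
        raise ValueError(
            f"{head_group} takes {n_chains} chain(s), got {len(chains)}"
        )
    n_ether = sum(1 for link, _, _ in chains if link == "ether")
    if n_ether and head_group not in ("PC", "LPC"):
        raise ValueError(f"ether linkage only supported for PC, not {head_group}")
    if n_ether > 1:
        raise ValueError("at most one ether-linked chain is supported")
    total_c = sum(c for _, c, _ in chains)
    total_d = sum(d for _, _, d in chains)
    for link, c, d in chains:
        if link not in ("acyl", "ether"):
            raise ValueError(f"unknown linkage {link!r}")
        _validate_chain(c, d)
    formula = {
        "C": c0 + total_c,
        "H": h0 + 2 * total_c - 2 * total_d + 2 * n_ether,
        "O": o0 - n_ether,
    }
    if n_count:
        formula["N"] = n_count
    if p_count:
        formula["P"] = p_count
    return formula


def lipid_neutral_mass(head_group: str, chains: list[tuple[str, int, int]]) -> float:
    """Neutral monoisotopic mass of a lipid (see :func:`lipid_neutral_formula`)."""
    return monoisotopic_mass(lipid_neutral_formula(head_group, chains))


def _self_check() -> None:
    """Assert recomputed diagnostics against their reference values."""
    diags = headgroup_diagnostics()
    for hg, ref in _HEADGROUP_REFERENCE.items():
        got = round(float(diags[hg]["mass"]), 2)
        if got != ref:
            raise AssertionError(
                f"{hg} diagnostic {got} != reference {ref}"
            )
    # printed 3-dp carboxylate anions (forces proton-mass deprotonation);
    # several printed values truncate rather than round the 4-dp theory
    # (269.2486 -> 269.248), so agreement is one ulp at 3 dp
    for (c, d), ref in {
        (16, 0): 255.233, (17, 0): 269.248, (18, 0): 283.264,
        (18, 1): 281.248, (18, 2): 279.233, (18, 3): 277.217,
        (20, 1): 309.279, (20, 2): 307.264, (20, 3): 305.248,
        (20, 4): 303.233, (20, 5): 301.217, (22, 5): 329.248,
        (22, 6): 327.233,
    }.items():
        if abs(fa_anion_mz(c, d) - ref) > 1e-3:
            raise AssertionError(
                f"FA {c}:{d} anion {fa_anion_mz(c, d):.4f} != reference {ref}"
            )
    # ether lookup vs demethylated ether-LPC interpretation, 5 mDa
    for (c, d), ref in ETHER_FRAGMENT_MZ.items():
        lpc_o = lipid_neutral_mass("LPC", [("ether", c, d)])
        theory = lpc_o - monoisotopic_mass({"C": 1, "H": 3}) - ELECTRON_MASS
        if abs(theory - ref) > 5e-3:
            raise AssertionError(
                f"ether O-{c}:{d} lookup {ref} deviates {abs(theory - ref):.4f} "
                "Da from the demethylated ether-LPC fragment"
            )
    if not math.isclose(PROTON_MASS, 1.007276, abs_tol=1e-6):
        raise AssertionError("proton mass out of spec")


_self_check()
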