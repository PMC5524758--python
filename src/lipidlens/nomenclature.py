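"""Lipid shorthand names and feature ("primary id") labels.

Shorthand names use the "_" chain separator because sn-positions are
never determined by the method; chain order inside the name is
canonical (ether chains first, then acyl chains by carbons then double
bonds).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["Chain", "LipidName", "parse_lipid_name", "format_lipid_name", "primary_id", "parse_primary_id"]

SUPPORTED_CLASSES = ("PC", "PE", "PI", "PS", "LPC", "LPE", "LPS", "FA")

_NAME_RE = re.compile(r"^(?P<cls>L?P[CEIS]|FA)\((?P<chains>[^)]+)\)$")
_CHAIN_RE = re.compile(r"^(?P<ether>O-)?(?P<c>\d+):(?P<d>\d+)$")


@dataclass(frozen=True, order=True)
class Chain:
    linkage: str  # "acyl" | "ether"
    carbons: int
    double_bonds: int

    def __str__(self) -> str:
        prefix = "O-" if self.linkage == "ether" else ""
        return f"{prefix}{self.carbons}:{self.double_bonds}"

    @property
    def sort_key(self) -> tuple[int, int, int]:
        return (0 if self.linkage == "ether" else 1, self.carbons, self.double_bonds)


@dataclass(frozen=True)
class LipidName:
    head_group: str
    chains: tuple[Chain, ...]

    def __str__(self) -> str:
        return format_lipid_name(self.head_group, list(self.chains))

    @property
    def chain_tuples(self) -> list[tuple[str, int, int]]:
        return [(c.linkage, c.carbons, c.double_bonds) for c in self.chains]


def parse_lipid_name(name: str) -> LipidName:
    """Parse shorthand like ``"PC(18:0_18:2)"`` or ``"LPC(O-16:0)"``.

    Raises ``ValueError`` for anything outside the supported grammar.
    """
    m = _NAME_RE.match(name.strip())
    if m is None:
        raise ValueError(f"cannot parse lipid name {name!r}")
    cls = m.group("cls")
    chains = []
    for part in m.group("chains").split("_"):
        cm = _CHAIN_RE.match(part.strip())
        if cm is None:
            raise ValueError(f"cannot parse chain {part!r} in {name!r}")
        chains.append(
            Chain(
                "ether" if cm.group("ether") else "acyl",
                int(cm.group("c")),
                int(cm.group("d")),
            )
        )
    expected = 1 if cls.startswith("L") or cls == "FA" else 2
    if len(chains) != expected:
        raise ValueError(f"{cls} takes {expected} chain(s), got {len(chains)} in {name!r}")
    return LipidName(cls, tuple(chains))


def format_lipid_name(head_group: str, chains: list[Chain | tuple[str, int, int]]) -> str:
    """Canonical shorthand: ether chains first, acyl chains sorted, '_' joined."""
    normalized = [c if isinstance(c, Chain) else Chain(*c) for c in chains]
    ordered = sorted(normalized, key=lambda c: c.sort_key)
    return f"{head_group}({'_'.join(str(c) for c in ordered)})"


def primary_id(retention_time: float, mz: float) -> str:
    """Feature label ``X<rt 2dp>_<mz 4dp>``, e.g. ``X1.17_564.3289``."""
    if retention_time < 0:
        raise ValueError("retention time must be non-negative")
    return f"X{retention_time:.2f}_{mz:.4f}"


_PRIMARY_RE = re.compile(r"^X(?P<rt>\d+(?:\.\d+)?)_(?P<mz>\d+(?:\.\d+)?)$")


def parse_primary_id(label: str) -> tuple[float, float]:
    """Inverse of :func:`primary_id`: returns (retention_time, mz)."""
    m = _PRIMARY_RE.match(label.strip())
    if m is None:
        raise ValueError(f"not a primary id: {label!r}")
    return float(m.group("rt")), float(m.group("mz"))
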