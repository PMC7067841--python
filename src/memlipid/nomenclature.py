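"""Parsing and rendering of shotgun-lipidomics species names.

Species are annotated as ``[class]-[carbons]:[double bonds];[hydroxyls]``
(e.g. ``SM-32:2;1``), optionally chain-resolved with one such composition
block per acyl chain (e.g. ``PC-18:1;0-24:2;0``).  Cholesterol carries no
composition block.  The class vocabulary is the Lipotype sum-composition
set covering glycerophospholipids, their lyso and ether variants,
sphingolipids, sterols and storage lipids.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "AcylChain",
    "LipidClass",
    "LipidSpecies",
    "LipidParseError",
    "CLASS_VOCABULARY",
    "parse_species",
    "render_species",
    "chains_of",
]


class LipidParseError(ValueError):
    """Raised when a species name cannot be parsed."""


@dataclass(frozen=True, order=True)
class AcylChain:
    """A single fatty acyl (or long-chain-base) moiety.

    ``carbons`` and ``double_bonds`` follow the C:D;H shorthand;
    ``hydroxyls`` defaults to 0 when a source omits the ``;H`` field.
    """

    carbons: int
    double_bonds: int
    hydroxyls: int = 0

    def __post_init__(self) -> None:
        if self.carbons < 1:
            raise ValueError(f"chain needs >=1 carbon, got {self.carbons}")
        if self.double_bonds < 0 or self.hydroxyls < 0:
            raise ValueError("double_bonds and hydroxyls must be >= 0")
        if self.double_bonds > self.carbons:
            raise ValueError(
                f"{self.double_bonds} double bonds impossible on "
                f"{self.carbons} carbons"
            )

    @property
    def signature(self) -> tuple[int, int]:
        """(carbons, double_bonds) pair used by fatty-acid set membership."""
        return (self.carbons, self.double_bonds)

    def __str__(self) -> str:
        return f"{self.carbons}:{self.double_bonds};{self.hydroxyls}"


@dataclass(frozen=True)
class LipidClass:
    """A lipid class from the controlled vocabulary with its category flags."""

    name: str
    expected_chain_count: int
    is_storage: bool = False
    is_glycerophospholipid: bool = False
    is_lyso: bool = False
    is_ether: bool = False

    @property
    def has_composition(self) -> bool:
        return self.expected_chain_count > 0


def _cls(name, n, storage=False, gpl=False, lyso=False, ether=False):
    return LipidClass(name, n, storage, gpl, lyso, ether)


#: Controlled vocabulary.  Chain counts: 0 sterol, 1 lyso/SE, 2 diacyl
#: (and ceramide-backbone classes, long-chain base + one FA), 3 TAG, 4 CL.
CLASS_VOCABULARY: dict[str, LipidClass] = {
    c.name: c
    for c in [
        _cls("CL", 4, gpl=True),
        _cls("Cer", 2),
        _cls("DAG", 2),
        _cls("DiHexCer", 2),
        _cls("HexCer", 2),
        _cls("SE", 1, storage=True),
        _cls("TAG", 3, storage=True),
        _cls("PA", 2, gpl=True),
        _cls("PC", 2, gpl=True),
        _cls("PE", 2, gpl=True),
        _cls("PG", 2, gpl=True),
        _cls("PI", 2, gpl=True),
        _cls("PS", 2, gpl=True),
        _cls("LPA", 1, gpl=True, lyso=True),
        _cls("LPC", 1, gpl=True, lyso=True),
        _cls("LPE", 1, gpl=True, lyso=True),
        _cls("LPI", 1, gpl=True, lyso=True),
        _cls("LPS", 1, gpl=True, lyso=True),
        _cls("PC O-", 2, gpl=True, ether=True),
        _cls("PE O-", 2, gpl=True, ether=True),
        _cls("LPC O-", 1, gpl=True, lyso=True, ether=True),
        _cls("LPE O-", 1, gpl=True, lyso=True, ether=True),
        _cls("SM", 2),
        _cls("Chol", 0),
    ]
}


@dataclass(frozen=True)
class LipidSpecies:
    """One annotated lipid species (sum-composition or chain-resolved)."""

    lipid_class: LipidClass
    total_carbons: int = 0
    total_double_bonds: int = 0
    total_hydroxyls: int = 0
    chains: Optional[tuple[AcylChain, ...]] = None
    raw_name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.chains is not None and len(self.chains) > 0:
            n = self.lipid_class.expected_chain_count
            if len(self.chains) != n:
                raise ValueError(
                    f"{self.lipid_class.name} expects {n} chains, "
                    f"got {len(self.chains)}"
                )
            sums = (
                sum(c.carbons for c in self.chains),
                sum(c.double_bonds for c in self.chains),
                sum(c.hydroxyls for c in self.chains),
            )
            totals = (self.total_carbons, self.total_double_bonds, self.total_hydroxyls)
            if sums != totals:
                raise ValueError(f"chain sums {sums} != totals {totals}")
        if not self.lipid_class.has_composition and self.total_carbons != 0:
            raise ValueError(f"{self.lipid_class.name} carries no composition")

    @property
    def name(self) -> str:
        return render_species(self)

    def __str__(self) -> str:
        return render_species(self)


_COMP_RE = re.compile(r"^(\d+):(\d+)(?:;(\d+))?$")


def _parse_block(block: str, name: str, pos: int) -> tuple[int, int, int]:
    m = _COMP_RE.match(block)
    if not m:
        raise LipidParseError(
            f"malformed composition {block!r} at position {pos} in {name!r}"
        )
    return int(m.group(1)), int(m.group(2)), int(m.group(3) or 0)


# Longest-first so "PC O-" wins over "PC", "LPC O-" over "LPC".
_CLASS_TOKENS = sorted(CLASS_VOCABULARY, key=len, reverse=True)


def parse_species(
    name: str, vocabulary: Optional[dict[str, LipidClass]] = None
) -> LipidSpecies:
    """Parse a species name into a :class:`LipidSpecies`.

    Accepts both hyphen- and space-separated dialects (``SM-32:2;1`` and
    ``SM 32:2;1``); the hydroxyl field may be omitted (defaults to 0).
    Chain-resolved names (``PC-18:1;0-24:2;0``) populate ``chains`` and
    derive the totals from the chain sums.

    Raises :class:`LipidParseError` for unknown class tokens or malformed
    composition blocks.
    """
    vocab = CLASS_VOCABULARY if vocabulary is None else vocabulary
    raw = name
    name = name.strip()
    if not name:
        raise LipidParseError("empty species name")

    # Isotope-labelled cholesterol standards collapse onto Chol.
    if re.fullmatch(r"Chol[- ]?D\d+", name):
        warnings.warn(f"stripping isotope label from {name!r}; treating as Chol")
        name = "Chol"

    tokens = vocab if vocabulary is not None else _CLASS_TOKENS
    tokens = sorted(tokens, key=len, reverse=True)
    cls = None
    rest = ""
    for tok in tokens:
        if name == tok:
            cls, rest = vocab[tok], ""
            break
        if name.startswith(tok):
            tail = name[len(tok):]
            if tok.endswith("-"):
                # ether classes: composition follows directly or after a separator
                cls, rest = vocab[tok], tail.lstrip("- ")
                break
            if tail[0] in "- ":
                cls, rest = vocab[tok], tail[1:]
                break
    if cls is None:
        head = re.split(r"[\d]", name, maxsplit=1)[0].strip(" -")
        raise LipidParseError(f"unknown lipid class {head or name!r} in {raw!r}")

    if not cls.has_composition:
        if rest:
            raise LipidParseError(f"{cls.name} takes no composition, got {rest!r}")
        return LipidSpecies(cls, raw_name=raw)
    if not rest:
        raise LipidParseError(f"missing composition for class {cls.name} in {raw!r}")

    blocks = re.split(r"[- ]", rest)
    pos = len(name) - len(rest)
    parsed = [_parse_block(b, raw, pos + i) for i, b in enumerate(blocks)]
    chains = None
    if len(parsed) == 1:
        tc, td, th = parsed[0]
    elif len(parsed) == cls.expected_chain_count:
        chains = tuple(AcylChain(*p) for p in parsed)
        tc = sum(c.carbons for c in chains)
        td = sum(c.double_bonds for c in chains)
        th = sum(c.hydroxyls for c in chains)
    else:
        raise LipidParseError(
            f"{cls.name} expects 1 (sum) or {cls.expected_chain_count} "
            f"(resolved) composition blocks, got {len(parsed)} in {raw!r}"
        )
    try:
        return LipidSpecies(cls, tc, td, th, chains, raw_name=raw)
    except ValueError as e:
        raise LipidParseError(f"invalid composition in {raw!r}: {e}") from e


def render_species(species: LipidSpecies) -> str:
    """Render the canonical hyphen-separated name of a species."""
    cls = species.lipid_class
    if not cls.has_composition:
        return cls.name
    sep = "" if cls.name.endswith("-") else "-"
    if species.chains:
        comp = "-".join(str(c) for c in species.chains)
    else:
        comp = (
            f"{species.total_carbons}:{species.total_double_bonds}"
            f";{species.total_hydroxyls}"
        )
    return f"{cls.name}{sep}{comp}"


def chains_of(species: LipidSpecies) -> Optional[list[AcylChain]]:
    """Uniform chain access.

    Returns resolved chains when present; for sum-only single-chain classes
    (lyso species, SE) the one chain implied by the totals; an empty list
    for Chol; ``None`` when the chain split is underdetermined.
    """
    if not species.lipid_class.has_composition:
        return []
    if species.chains:
        return list(species.chains)
    if species.lipid_class.expected_chain_count == 1:
        return [
            AcylChain(
                species.total_carbons,
                species.total_double_bonds,
                species.total_hydroxyls,
            )
        ]
    return None
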