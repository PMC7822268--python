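"""HELM-style monomer notation for chemically modified oligos.

Each nucleotide monomer is a (sugar, base, 3'-linker) triple from a
closed registry: sugars dR (DNA), R (RNA), LR (LNA), mR (2'-O-methyl);
bases A, C, G, T, U, 5mC; linkers P (phosphodiester), sP
(phosphorothioate).  The last monomer of a strand has no 3' linker.

The canonical string form is ``<strand_id>{unit.unit...}$$$$`` where a
unit is ``sugar(base)linker``; single-letter tokens are bare,
multi-character tokens bracketed, e.g.::

    RNA1{[dR](A)P.[dR](C)P.[dR](G)}$$$$

Besides the HELM string, two plain-text renderings mirror common
notebook conventions: a sequence view (DNA lowercase, RNA uppercase,
LNA "+X", 2'OMe "mX", phosphorothioate "*") and a fixed-width block
view emphasising the modification pattern.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

from .errors import NotationError

__all__ = ["Monomer", "ModifiedOligo", "helm_write", "helm_parse",
           "render_sequence", "render_blocks", "gapmer"]


def _load_registry() -> dict[str, tuple[str, ...]]:
    text = resources.files("oligopipe.data").joinpath("monomers.tsv").read_text()
    kinds: dict[str, list[str]] = {"sugar": [], "base": [], "linker": []}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("token\t"):
            continue
        token, kind = line.split("\t")[:2]
        kinds[kind].append(token)
    return {k: tuple(v) for k, v in kinds.items()}


_REGISTRY = _load_registry()
SUGARS = _REGISTRY["sugar"]
BASES = _REGISTRY["base"]
LINKERS = _REGISTRY["linker"] + ("none",)

_BASE_LETTER = {"A": "A", "C": "C", "G": "G", "T": "T", "U": "U", "5mC": "C"}
_SUGAR_BLOCK = {"dR": "[d]", "R": "[R]", "LR": "[L]", "mR": "[m]"}


@dataclass(frozen=True)
class Monomer:
    """One nucleotide unit: sugar, base, and the linker to the next unit."""

    sugar: str
    base: str
    linker3: str = "P"

    def __post_init__(self) -> None:
        if self.sugar not in SUGARS:
            raise NotationError(f"unknown sugar token {self.sugar!r}")
        if self.base not in BASES:
            raise NotationError(f"unknown base token {self.base!r}")
        if self.linker3 not in LINKERS:
            raise NotationError(f"unknown linker token {self.linker3!r}")


@dataclass
class ModifiedOligo:
    """An ordered 5'->3' strand of monomers.

    Exactly the last monomer has ``linker3 == "none"``.
    """

    strand_id: str = "RNA1"
    monomers: list[Monomer] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.monomers:
            raise NotationError("a strand needs at least one monomer")
        for i, m in enumerate(self.monomers):
            terminal = i == len(self.monomers) - 1
            if terminal != (m.linker3 == "none"):
                raise NotationError(
                    f"monomer {i}: only the terminal monomer may (and must) "
                    f"have linker3 = none"
                )


def _token(tok: str) -> str:
    return tok if len(tok) == 1 else f"[{tok}]"


def helm_write(o: ModifiedOligo) -> str:
    """Canonical HELM-dialect string of *o* (deterministic)."""
    units = []
    for m in o.monomers:
        unit = f"{_token(m.sugar)}({_token(m.base)})"
        if m.linker3 != "none":
            unit += _token(m.linker3)
        units.append(unit)
    return f"{o.strand_id}{{{'.'.join(units)}}}$$$$"


_HELM_RE = re.compile(r"^([A-Za-z0-9_]+)\{(.*)\}\$\$\$\$$")
_UNIT_RE = re.compile(
    r"(\[([A-Za-z0-9]{2,})\]|([A-Za-z]))"        # sugar
    r"\((\[([A-Za-z0-9]{2,})\]|([A-Za-z]))\)"    # base
    r"(\[([A-Za-z0-9]{2,})\]|([A-Za-z]))?"       # optional linker
    r"$"
)


def helm_parse(s: str) -> ModifiedOligo:
    """Inverse of :func:`helm_write`; errors carry a character offset."""
    m = _HELM_RE.match(s)
    if not m:
        raise NotationError(
            f"not a valid strand string (offset 0): {s[:40]!r}"
        )
    strand_id, body = m.group(1), m.group(2)
    if not body:
        raise NotationError(f"empty monomer list at offset {len(strand_id) + 1}")
    monomers: list[Monomer] = []
    offset = len(strand_id) + 1
    units = body.split(".")
    for i, unit in enumerate(units):
        um = _UNIT_RE.match(unit)
        if not um:
            raise NotationError(
                f"malformed monomer unit {unit!r} at offset {offset}"
            )
        sugar = um.group(2) or um.group(3)
        base = um.group(5) or um.group(6)
        linker = um.group(8) or um.group(9) or "none"
        terminal = i == len(units) - 1
        if terminal and linker != "none":
            raise NotationError(
                f"terminal monomer must not carry a 3' linker (offset {offset})"
            )
        if not terminal and linker == "none":
            raise NotationError(
                f"internal monomer lacks a 3' linker (offset {offset})"
            )
        for tok, kind in ((sugar, SUGARS), (base, BASES), (linker, LINKERS)):
            if tok not in kind:
                raise NotationError(
                    f"unknown monomer token {tok!r} at offset {offset}"
                )
        monomers.append(Monomer(sugar, base, linker))
        offset += len(unit) + 1
    return ModifiedOligo(strand_id=strand_id, monomers=monomers)


def render_sequence(o: ModifiedOligo) -> str:
    """Sequence view: DNA lowercase, RNA uppercase, LNA ``+X``,
    2'OMe ``mX``; phosphorothioate linkers rendered ``*``."""
    out = []
    for i, m in enumerate(o.monomers):
        letter = _BASE_LETTER[m.base]
        if m.sugar == "dR":
            out.append(letter.lower())
        elif m.sugar == "R":
            out.append(letter.upper())
        elif m.sugar == "LR":
            out.append("+" + letter.upper())
        else:  # mR
            out.append("m" + letter.upper())
        if m.linker3 == "sP":
            out.append("*")
    return "".join(out)


def render_blocks(o: ModifiedOligo) -> str:
    """Block view: three fixed-width lines (sugar class, base, linker mark).

    One 3-character column per monomer; distinct chemistries yield
    distinct sugar lines.
    """
    sugars = [_SUGAR_BLOCK[m.sugar] for m in o.monomers]
    bases = [_BASE_LETTER[m.base].center(3) for m in o.monomers]
    linkers = [
        (" * " if m.linker3 == "sP" else "   ") for m in o.monomers
    ]
    return "\n".join("".join(line) for line in (sugars, bases, linkers))


def gapmer(sequence: str, wing: int = 3, wing_sugar: str = "LR",
           linker: str = "sP", strand_id: str = "RNA1") -> ModifiedOligo:
    """Build a gapmer: *wing* modified sugars at each end flanking a DNA
    gap, with a uniform backbone linker (default fully phosphorothioate)."""
    seq = sequence.upper()
    n = len(seq)
    if n < 2 * wing + 1:
        raise NotationError(
            f"sequence of length {n} too short for {wing}-nt wings"
        )
    monomers = []
    for i, base in enumerate(seq):
        sugar = wing_sugar if (i < wing or i >= n - wing) else "dR"
        linker3 = "none" if i == n - 1 else linker
        monomers.append(Monomer(sugar, base, linker3))
    return ModifiedOligo(strand_id=strand_id, monomers=monomers)
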