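"""Nearest-neighbor duplex thermodynamics and simple structure screens.

Duplex stability is modeled as the standard nearest-neighbor sum: an
initiation term, one stack term per dinucleotide step of the oligo
strand (perfect Watson-Crick complement assumed), and, where the
parameter set defines them, per-end terminal-pair corrections.  Two
parameter sets ship as TSV data files:

* ``dna_dna`` — unified DNA:DNA set with terminal A·T / G·C terms;
* ``dna_rna`` — DNA:RNA hybrid set keyed by the DNA (oligo) strand,
  with a single initiation term (used for ASO:mRNA duplexes).

All free energies are ΔG at 37 °C (310.15 K) in kcal/mol; ΔH in
kcal/mol, ΔS in cal/(mol·K); R = 1.987 cal/(mol·K).

The intra/inter-molecular screens are deliberately simple, exhaustively
enumerable surrogates for partition-function structure calculations:
``self_dimer_dg`` scores the best ungapped antiparallel self-duplex and
``hairpin_screen`` reports the longest inverted-repeat stem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .core import reverse_complement
from .errors import EmptyInputError, InvalidSequenceError

R_GAS = 1.987  # cal/(mol K)
T37 = 310.15  # K

__all__ = [
    "NNParameterSet",
    "ThermoProfile",
    "load_params",
    "nn_duplex_dg",
    "nn_duplex_tm",
    "self_dimer_dg",
    "hairpin_screen",
    "thermo_profile",
]

_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class NNParameterSet:
    """A nearest-neighbor table: per-stack (dH, dS, dG37) plus init terms."""

    name: str
    stacks: dict[str, tuple[float, float, float]]
    init: tuple[float, float, float] = (0.0, 0.0, 0.0)
    term_at: tuple[float, float, float] | None = None
    term_gc: tuple[float, float, float] | None = None

    def check_consistency(self, tol: float = 0.05) -> None:
        """Verify dG37 == dH - T37*dS/1000 within *tol* for every entry."""
        entries = dict(self.stacks)
        entries["init"] = self.init
        if self.term_at:
            entries["term_AT"] = self.term_at
        if self.term_gc:
            entries["term_GC"] = self.term_gc
        for key, (dh, ds, dg) in entries.items():
            derived = dh - T37 * ds / 1000.0
            if abs(derived - dg) > tol:
                raise ValueError(
                    f"{self.name}: entry {key}: dG37 {dg} inconsistent with "
                    f"dH/dS-derived {derived:.3f}"
                )


@dataclass
class ThermoProfile:
    """The thermodynamic properties attached to each candidate."""

    duplex_dg37: float
    duplex_tm: float
    self_dimer_dg37: float
    hairpin_stem_max: int


def _parse_params(text: str, name: str) -> NNParameterSet:
    stacks: dict[str, tuple[float, float, float]] = {}
    init = (0.0, 0.0, 0.0)
    term_at = term_gc = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("dimer"):
            continue
        key, dh, ds, dg = line.split("\t")
        entry = (float(dh), float(ds), float(dg))
        if key == "init":
            init = entry
        elif key == "term_AT":
            term_at = entry
        elif key == "term_GC":
            term_gc = entry
        else:
            stacks[key] = entry
    params = NNParameterSet(name, stacks, init, term_at, term_gc)
    params.check_consistency()
    return params


def load_params(name_or_path: str) -> NNParameterSet:
    """Load a shipped parameter set (``dna_dna``, ``dna_rna``) or a TSV path."""
    if name_or_path in ("dna_dna", "dna_rna"):
        text = (
            resources.files("oligopipe.data")
            .joinpath(f"nn_{name_or_path}.tsv")
            .read_text()
        )
        return _parse_params(text, name_or_path)
    path = Path(name_or_path)
    return _parse_params(path.read_text(), path.stem)


def _check_acgt(seq: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in "ACGT":
            raise InvalidSequenceError(
                f"ambiguous or invalid base {ch!r} at position {i}; "
                f"thermodynamics requires A,C,G,T only"
            )


def _nn_sums(seq: str, params: NNParameterSet) -> tuple[float, float, float]:
    """(dH, dS, dG37) of the perfect duplex of *seq* with its complement."""
    _check_acgt(seq)
    if len(seq) < 2:
        raise EmptyInputError("duplex thermodynamics needs length >= 2")
    dh, ds, dg = params.init
    for i in range(len(seq) - 1):
        h, s, g = params.stacks[seq[i:i + 2]]
        dh, ds, dg = dh + h, ds + s, dg + g
    for terminal in (seq[0], seq[-1]):
        term = params.term_at if terminal in "AT" else params.term_gc
        if term is not None:
            dh, ds, dg = dh + term[0], ds + term[1], dg + term[2]
    return dh, ds, dg


def nn_duplex_dg(seq: str, params: NNParameterSet) -> float:
    """ΔG37 (kcal/mol) of *seq* duplexed with its perfect complement."""
    return _nn_sums(seq, params)[2]


def nn_duplex_tm(seq: str, params: NNParameterSet, oligo_conc: float = 1e-6,
                 na_conc: float = 1.0) -> float:
    """Two-state melting temperature in °C.

    Tm = ΔH·1000 / (ΔS + R·ln(CT/4)) − 273.15, with the 16.6·log10([Na+])
    salt correction applied when the sodium concentration is not 1 M.
    """
    if oligo_conc <= 0 or na_conc <= 0:
        raise ValueError("concentrations must be positive")
    dh, ds, _ = _nn_sums(seq, params)
    tm = dh * 1000.0 / (ds + R_GAS * math.log(oligo_conc / 4.0)) - 273.15
    if na_conc != 1.0:
        tm += 16.6 * math.log10(na_conc)
    return tm


def self_dimer_dg(seq: str, params: NNParameterSet) -> float:
    """ΔG37 of the best ungapped antiparallel self-duplex, never positive.

    All relative offsets of the sequence against a second copy of itself
    (antiparallel) are scanned; within each offset, every maximal run of
    >= 2 consecutive Watson-Crick complementary positions is scored as a
    standalone nearest-neighbor duplex.  Returns 0.0 when no such run
    exists or when no run is stabilising.
    """
    _check_acgt(seq)
    n = len(seq)
    best = 0.0
    # antiparallel alignment: position i of copy 1 faces position j of
    # copy 2 with i + j == const; const indexes the offset.
    for const in range(2 * n - 1):
        run_start = None
        i_lo = max(0, const - n + 1)
        i_hi = min(n - 1, const)
        for i in range(i_lo, i_hi + 2):  # +1 past end flushes the last run
            j = const - i
            paired = (
                i <= i_hi and 0 <= j < n and _PAIR[seq[i]] == seq[j]
            )
            if paired and run_start is None:
                run_start = i
            elif not paired and run_start is not None:
                run_len = i - run_start
                if run_len >= 2:
                    dg = nn_duplex_dg(seq[run_start:i], params)
                    best = min(best, dg)
                run_start = None
    return best


def hairpin_screen(seq: str, min_stem: int = 4, min_loop: int = 3) -> int:
    """Longest contiguous inverted-repeat stem with loop >= *min_loop*.

    Exhaustive scan over all stem placements; returns 0 when the longest
    stem is shorter than *min_stem*.
    """
    _check_acgt(seq)
    n = len(seq)
    best = 0
    for i in range(n):
        # j is the 0-based position pairing with i (j > i); loop between.
        for j in range(i + min_loop + 1, n):
            if _PAIR[seq[i]] != seq[j]:
                continue
            # extend stem outward-in: (i+d, j-d) pairs while loop holds
            d = 1
            while (
                i + d < j - d
                and (j - d) - (i + d) - 1 >= min_loop
                and _PAIR[seq[i + d]] == seq[j - d]
            ):
                d += 1
            best = max(best, d)
    return best if best >= min_stem else 0


def thermo_profile(oligo_seq: str, params: NNParameterSet,
                   oligo_conc: float = 1e-6,
                   na_conc: float = 1.0) -> ThermoProfile:
    """Full :class:`ThermoProfile` of an oligo sequence against its target."""
    return ThermoProfile(
        duplex_dg37=nn_duplex_dg(oligo_seq, params),
        duplex_tm=nn_duplex_tm(oligo_seq, params, oligo_conc, na_conc),
        self_dimer_dg37=self_dimer_dg(oligo_seq, params),
        hairpin_stem_max=hairpin_screen(oligo_seq),
    )
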