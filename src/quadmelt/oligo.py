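"""Sequence-level utilities for melting-experiment oligonucleotides.

Covers the bookkeeping around a melting study: strand representation,
260 nm extinction coefficients by monomer additivity, Watson-Crick pairing
and mismatch counting, and scanning for putative G-quadruplex (PQS) and
i-motif forming tracts.

Coordinates are 0-based half-open internally and in BED output; the TSV
writer in :mod:`quadmelt.io` emits 1-based inclusive columns for human
consumption.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

from .exceptions import AlphabetError, PairingError, ValidationError

_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Classical nucleoside-5'-monophosphate molar extinction coefficients at
#: 260 nm, mM^-1 cm^-1. Strand coefficients are the plain additive sum of
#: these; see docs/methods.md for the accuracy of that approximation on
#: G-run-rich strands.
DEFAULT_MONOMER_EPSILON = {"A": 15.4, "C": 7.4, "G": 11.5, "T": 8.7}

_WC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")})


def _check_sequence(seq: str, *, allow_empty: bool = False) -> str:
    if not isinstance(seq, str):
        raise AlphabetError(f"sequence must be a string, got {type(seq).__name__}")
    seq = seq.upper()
    if not seq and not allow_empty:
        raise AlphabetError("empty sequence")
    bad = set(seq) - _ALPHABET
    if bad:
        raise AlphabetError(
            f"sequence contains non-ACGT characters {sorted(bad)}; "
            "U and IUPAC ambiguity codes are not accepted"
        )
    return seq


@dataclass(frozen=True)
class Oligo:
    """A DNA oligonucleotide, written 5'→3'.

    ``extinction_260`` (mM^-1 cm^-1) is computed from the monomer table
    when not supplied.
    """

    name: str
    sequence: str
    extinction_260: float | None = None

    def __post_init__(self):
        if not self.name:
            raise ValidationError("oligo name must be non-empty")
        object.__setattr__(self, "sequence", _check_sequence(self.sequence))
        if self.extinction_260 is None:
            object.__setattr__(
                self, "extinction_260", extinction_coefficient(self.sequence)
            )
        elif not self.extinction_260 > 0:
            raise ValidationError("extinction_260 must be positive")

    def __len__(self) -> int:
        return len(self.sequence)


class OligoRegistry:
    """Name-unique collection of oligos."""

    def __init__(self, oligos: Iterable[Oligo] = ()):
        self._by_name: dict[str, Oligo] = {}
        for o in oligos:
            self.add(o)

    def add(self, oligo: Oligo) -> None:
        if oligo.name in self._by_name:
            raise ValidationError(f"duplicate oligo name {oligo.name!r}")
        self._by_name[oligo.name] = oligo

    def __getitem__(self, name: str) -> Oligo:
        try:
            return self._by_name[name]
        except KeyError:
            raise ValidationError(f"unknown oligo {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)


@dataclass(frozen=True)
class MotifHit:
    """One putative quadruplex- or i-motif-forming tract on the given strand.

    ``start``/``end`` are 0-based half-open; ``runs`` holds the
    (start, length) of each G- or C-run, ``loop_lengths`` the gaps between
    consecutive runs.
    """

    motif_class: str  # "G4" or "IM"
    start: int
    end: int
    runs: tuple[tuple[int, int], ...]
    loop_lengths: tuple[int, ...] = field(default=())

    def __post_init__(self):
        if self.motif_class not in ("G4", "IM"):
            raise ValidationError("motif_class must be 'G4' or 'IM'")
        if not self.end > self.start:
            raise ValidationError("motif end must exceed start")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement (an involution on ACGT strings)."""
    return _check_sequence(seq).translate(_COMPLEMENT)[::-1]


def count_mismatches(top: str, bottom: str) -> int:
    """Number of non-Watson-Crick pairs when two strands anneal.

    Both strands are given 5'→3'; ``bottom`` is reversed for pairing so
    that ``bottom[0]`` faces the last base of ``top``. Strands must have
    equal length — for overhang constructs pass the paired region only.
    """
    top = _check_sequence(top)
    bottom = _check_sequence(bottom)
    if len(top) != len(bottom):
        raise PairingError(
            f"cannot pair strands of different length ({len(top)} vs {len(bottom)}); "
            "pass the duplex-forming region only"
        )
    paired = bottom[::-1]
    return sum(1 for a, b in zip(top, paired) if (a, b) not in _WC_PAIRS)


def extinction_coefficient(
    seq: str, monomer_table: dict[str, float] | None = None
) -> float:
    """Additive 260 nm extinction coefficient, mM^-1 cm^-1.

    The strand coefficient is the sum of monomer coefficients over the
    sequence, which makes it exactly additive under concatenation. The
    default table holds classical nucleoside-5'-monophosphate values.
    """
    seq = _check_sequence(seq)
    table = DEFAULT_MONOMER_EPSILON if monomer_table is None else monomer_table
    missing = set(seq) - set(table)
    if missing:
        raise ValidationError(f"monomer table lacks entries for {sorted(missing)}")
    return sum(table[base] for base in seq)


def concentration_from_absorbance(
    a260: float, epsilon: float, pathlength: float = 1.0
) -> float:
    """Beer-Lambert strand concentration, mM.

    ``c = A / (ε · l)`` with ε in mM^-1 cm^-1 and l in cm.
    """
    if not epsilon > 0:
        raise ValidationError("epsilon must be positive")
    if not pathlength > 0:
        raise ValidationError("pathlength must be positive")
    if a260 < 0:
        raise ValidationError("absorbance must be non-negative")
    return a260 / (epsilon * pathlength)


def _maximal_runs(seq: str, base: str) -> list[tuple[int, int]]:
    """(start, length) of every maximal run of ``base``."""
    return [(m.start(), m.end() - m.start()) for m in re.finditer(f"{base}+", seq)]


def count_base_runs(seq: str, base: str, min_len: int) -> int:
    """Number of maximal runs of ``base`` with length >= ``min_len``."""
    seq = _check_sequence(seq, allow_empty=True)
    if base not in _ALPHABET:
        raise AlphabetError(f"base must be one of ACGT, got {base!r}")
    if min_len < 1:
        raise ValidationError("min_len must be >= 1")
    return sum(1 for _, length in _maximal_runs(seq, base) if length >= min_len)


def _scan_runs(
    seq: str,
    base: str,
    motif_class: str,
    min_run: int,
    loop_min: int,
    loop_max: int,
    n_runs: int,
    all_overlaps: bool,
) -> list[MotifHit]:
    seq = _check_sequence(seq, allow_empty=True)
    if min_run < 1 or n_runs < 2 or loop_min < 1:
        raise ValidationError("min_run, loop_min must be >= 1 and n_runs >= 2")
    if loop_min > loop_max:
        raise ValidationError("loop_min must not exceed loop_max")

    runs = [(s, l) for s, l in _maximal_runs(seq, base) if l >= min_run]
    hits: list[MotifHit] = []
    i = 0
    while i + n_runs <= len(runs):
        window = runs[i : i + n_runs]
        loops = [
            window[j + 1][0] - (window[j][0] + window[j][1])
            for j in range(n_runs - 1)
        ]
        if all(loop_min <= L <= loop_max for L in loops):
            start = window[0][0]
            end = window[-1][0] + window[-1][1]
            hits.append(
                MotifHit(
                    motif_class=motif_class,
                    start=start,
                    end=end,
                    runs=tuple(window),
                    loop_lengths=tuple(loops),
                )
            )
            if not all_overlaps:
                # non-overlapping, leftmost-first: resume past this hit
                while i < len(runs) and runs[i][0] < end:
                    i += 1
                continue
        i += 1
    return hits


def scan_quadruplex(
    seq: str,
    min_run: int = 3,
    loop_min: int = 1,
    loop_max: int = 7,
    n_runs: int = 4,
    all_overlaps: bool = False,
) -> list[MotifHit]:
    """Putative G-quadruplex-forming tracts on the given strand.

    Canonical PQS grammar: ``n_runs`` maximal G-runs of length >=
    ``min_run`` separated by loops of ``loop_min``–``loop_max`` nt.
    Default output is maximal, non-overlapping, leftmost-first;
    ``all_overlaps=True`` enumerates every qualifying run window. The
    complementary strand is never scanned implicitly.
    """
    return _scan_runs(seq, "G", "G4", min_run, loop_min, loop_max, n_runs, all_overlaps)


def scan_imotif(
    seq: str,
    min_run: int = 3,
    loop_min: int = 1,
    loop_max: int = 7,
    n_runs: int = 4,
    all_overlaps: bool = False,
) -> list[MotifHit]:
    """Putative i-motif-forming tracts: the C-run mirror of the PQS scan."""
    return _scan_runs(seq, "C", "IM", min_run, loop_min, loop_max, n_runs, all_overlaps)
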