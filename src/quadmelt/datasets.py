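"""Benchmark oligonucleotides and melting thermodynamics.

A curated set of published UV-melting results for duplexes derived from a
c-kit promoter fragment, with G-quadruplex-forming (human/Tetrahymena
telomeric repeat) or i-motif-forming (bcl-2 Py39WT) tracts appended to one
strand. These serve as reference inputs: sequences with their reported
260 nm extinction coefficients, and replicate-mean thermodynamic summaries
(Tm, ΔH, ΔS, ΔG° ± 1σ, n = 3 measurements at 3 µM/strand, i.e.
c_total = 6 µM) used to validate the package's arithmetic and to seed
realistic simulations.
"""

from __future__ import annotations

from .compare import ThermoSummary, Uncertain
from .oligo import Oligo, OligoRegistry

GQ1_OVERHANG = "GGGTT" * 3 + "GGG"  # (G3T2)3G3, human telomeric repeat variant
GQ2_OVERHANG = "GGGGTT" * 3 + "GGGG"  # (G4T2)3G4, Tetrahymena telomeric repeat
IM_OVERHANG = "CAGCCCCGCTCCCGCCCCCTTCCTCCCGCGCCCGCCCCT"  # bcl-2 Py39WT, 6 C-runs

_SEQUENCES: list[tuple[str, str, float]] = [
    ("top1", "GGCGCGCAGA", 108.9),
    ("top1::GQ1", "GGCGCGCAGA" + GQ1_OVERHANG, 292.3),
    ("top1::GQ2", "GGCGCGCAGA" + GQ2_OVERHANG, 335.7),
    ("top1::poly(T)1", "GGCGCGCAGA" + "T" * 22, 303.5),
    ("top1::poly(T)2", "GGCGCGCAGA" + "T" * 10, 197.5),
    ("top1::poly(T)3", "GGCGCGCAGA" + "T" * 27, 347.7),
    ("bottom1", "TCTGCGCGCC", 88.8),
    ("bottom1-1MM", "ACTGCGCGCC", 95.7),
    ("bottom1-2MM", "ATTGCGCGCC", 96.9),
    ("bottom1-3MM", "ATAGCGCGCC", 103.8),
    ("top2", "GGCGCGCATAAAA", 154.2),
    ("top2::GQ2", "GGCGCGCATAAAA" + GQ2_OVERHANG, 380.9),
    ("top2::IM", "GGCGCGCATAAAA" + IM_OVERHANG, 487.5),
    ("bottom2", "TTTTATGCGCGCC", 123.4),
    ("bottom2-1MM", "ATTTATGCGCGCC", 130.3),
    ("bottom2-2MM", "AATTATGCGCGCC", 137.2),
    ("bottom2-3MM", "AAATATGCGCGCC", 144.1),
    ("bottom2-4MM", "AAAAATGCGCGCC", 151.0),
    ("bottom2-5MM", "AAAATTGCGCGCC", 144.1),
    ("bottom2-6MM", "AAAATAGCGCGCC", 151.0),
    ("GQ2::bottom2", GQ2_OVERHANG + "TTTTATGCGCGCC", 350.2),
    ("IM::bottom2", "TCCCCGCCCGCGCCCTCCTTCCCCCGCCCTCGCCCCGAC" + "TTTTATGCGCGCC", 456.8),
]

#: Total single-strand concentration of the benchmark experiments, mol/L
#: (3 µM per strand, two strands).
C_TOTAL_BENCHMARK = 6e-6


def load_benchmark_oligos() -> OligoRegistry:
    """Registry of the benchmark strands with their reported ε260 values."""
    return OligoRegistry(
        Oligo(name, seq, extinction_260=eps) for name, seq, eps in _SEQUENCES
    )


def _row(pair, ph, tm, dh, ds, dg) -> ThermoSummary:
    return ThermoSummary(
        pair=pair,
        ph=ph,
        n=3,
        tm_c=Uncertain(*tm),
        delta_H=Uncertain(*dh),
        delta_S=Uncertain(*ds),
        delta_G=Uncertain(*dg),
    )


def load_benchmark_summaries() -> dict[str, ThermoSummary]:
    """Reported replicate-mean melting thermodynamics, keyed by pair label.

    Units: Tm °C, ΔH kJ/mol, ΔS J/(K mol), ΔG° kJ/mol at 298.15 K; all
    uncertainties 1σ over >= 3 measurements.

    .. note::
       The ``top1::GQ1, bottom1`` row is internally inconsistent as
       reported (its ΔH and ΔS imply ΔG° ≈ −77.8 kJ/mol, not the listed
       −52.7): it is retained verbatim for the ΔΔG°/ΔTm bookkeeping, which
       uses the listed ΔG° and σ directly, but must be excluded from
       ΔG° = ΔH − T·ΔS consistency checks.
    """
    rows = [
        _row("top1, bottom1", 7.4, (58.6, 0.7), (-336.4, 11.5), (-902.0, 32.9), (-67.5, 1.7)),
        _row("top1::GQ1, bottom1", 7.4, (52.7, 2.5), (-252.2, 56.6), (-585.0, 98.2), (-52.7, 3.4)),
        _row("top1::GQ2, bottom1", 7.4, (51.4, 1.8), (-213.8, 11.0), (-547.0, 34.8), (-50.7, 1.3)),
        _row("top1::poly(T)1, bottom1", 7.4, (56.9, 0.7), (-332.8, 12.1), (-896.7, 36.4), (-65.5, 1.4)),
        _row("top2, bottom2", 7.4, (54.3, 0.5), (-381.2, 7.4), (-1052.3, 23.5), (-67.5, 0.6)),
        _row("top2::GQ2, bottom2", 7.4, (49.9, 0.3), (-245.7, 14.6), (-648.8, 44.8), (-52.3, 1.2)),
        _row("top2, bottom2 (pH 4.0)", 4.0, (39.4, 0.9), (-254.9, 16.5), (-703.9, 51.9), (-45.1, 1.2)),
        _row("top2::IM, bottom2 (pH 4.0)", 4.0, (35.2, 0.8), (-254.0, 2.1), (-720.7, 4.3), (-39.0, 1.0)),
    ]
    return {r.pair: r for r in rows}


#: Reported absolute destabilizations ΔΔG° (kJ/mol ± 1σ) of the
#: top2::GQ2/bottom2 duplex across the pH series, and of top2::IM/bottom2
#: at low pH, against the matching duplex-alone reference at the same pH.
PH_SERIES_DDG = {
    ("top2::GQ2, bottom2", 4.0): Uncertain(9.6, 1.3),
    ("top2::GQ2, bottom2", 4.4): Uncertain(12.8, 1.4),
    ("top2::GQ2, bottom2", 5.0): Uncertain(16.1, 1.3),
    ("top2::GQ2, bottom2", 5.4): Uncertain(17.5, 1.5),
    ("top2::GQ2, bottom2", 5.9): Uncertain(15.5, 1.3),
    ("top2::GQ2, bottom2", 7.4): Uncertain(15.2, 1.4),
    ("top2::IM, bottom2", 4.0): Uncertain(6.0, 1.6),
    ("top2::IM, bottom2", 4.4): Uncertain(3.8, 2.2),
}

#: Duplex-alone reference ΔG° (kJ/mol ± 1σ) per pH for the relative
#: destabilization ratios of the pH series.
PH_SERIES_REFERENCE_DG = {
    4.0: Uncertain(-45.1, 1.2),
    7.4: Uncertain(-67.5, 0.6),
}
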