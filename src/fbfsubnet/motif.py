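"""FBF binding element (FBE) scanning.

The FBE is the octamer UGUNNNAU. Two "optimal" refinements are carried as
independent flags on each match rather than reconciled into one definition:

* relaxed optimal — UGUDHHAU (D = A/U/G, H = A/U/C);
* strict optimal — the nonamer UGURCCAUR (R = A/G) preceded by a cytosine.

Cytosines one or two bases upstream of the octamer (-1C / -2C) enhance FBF
affinity and are flagged separately. Scanning is sense-strand only: a
reverse-complement hit is not a binding element.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "T",
    "N": "ACGT", "D": "AGT", "H": "ACT", "R": "AG",
}

_VALID_INPUT = re.compile(r"^[ACGTUNRYSWKMBDHVacgtunryswkmbdhv]*$")


def _pattern_to_regex(pattern: str) -> re.Pattern[str]:
    return re.compile("".join(
        c if len(c) == 1 else f"[{c}]"
        for c in (_IUPAC[p] for p in pattern)
    ))


@dataclass(frozen=True)
class FBEPattern:
    """The FBE pattern family; defaults are the field's standard definitions."""

    canonical: str = "UGUNNNAU"
    relaxed_optimal: str = "UGUDHHAU"
    strict_optimal: str = "UGURCCAUR"  # nonamer; requires an upstream C too

    def __post_init__(self) -> None:
        for p in (self.canonical, self.relaxed_optimal, self.strict_optimal):
            if any(c not in _IUPAC for c in p):
                raise ValueError(f"pattern {p!r} uses unsupported symbols")


DEFAULT_PATTERN = FBEPattern()


@dataclass(frozen=True)
class FBEMatch:
    """One FBE occurrence; offsets are 0-based in the scanned sequence."""

    start: int
    octamer: str
    is_canonical: bool
    is_relaxed_optimal: bool
    is_strict_optimal: bool
    minus1C: bool
    minus2C: bool


def scan_fbe(sequence: str, pattern_set: FBEPattern = DEFAULT_PATTERN) -> list[FBEMatch]:
    """All canonical FBE octamer positions in ``sequence`` with their flags.

    T and U are equivalent; overlapping matches are all reported, sorted by
    start offset. Raises ValueError on characters outside the IUPAC alphabet.
    """
    if not _VALID_INPUT.match(sequence):
        bad = sorted(set(re.sub(r"[ACGTUNacgtun]", "", sequence)))
        raise ValueError(f"sequence contains non-IUPAC characters: {bad}")
    dna = sequence.upper().replace("U", "T")
    canon = _pattern_to_regex(pattern_set.canonical)
    relaxed = _pattern_to_regex(pattern_set.relaxed_optimal)
    strict = _pattern_to_regex(pattern_set.strict_optimal)

    matches: list[FBEMatch] = []
    pos = 0
    while True:
        m = canon.search(dna, pos)
        if m is None:
            break
        i = m.start()
        oct_rna = dna[i:i + 8].replace("T", "U")
        up1 = dna[i - 1] if i >= 1 else ""
        up2 = dna[i - 2] if i >= 2 else ""
        nonamer = dna[i:i + 9]
        is_strict = bool(
            len(nonamer) == 9
            and strict.fullmatch(nonamer)
            and up1 == "C"
        )
        matches.append(FBEMatch(
            start=i,
            octamer=oct_rna,
            is_canonical=True,
            is_relaxed_optimal=bool(relaxed.fullmatch(dna[i:i + 8])),
            is_strict_optimal=is_strict,
            minus1C=up1 == "C",
            minus2C=up2 == "C",
        ))
        pos = i + 1
    return matches


def peak_fbe_fraction(peaks, top_n: int | None = None) -> float:
    """Fraction of peaks whose window holds >=1 canonical FBE.

    ``peaks`` are Peak records carrying ``fbe`` match lists and ``rank``;
    ``top_n`` restricts to the highest-ranked peaks (by per-million height).
    A ``top_n`` larger than the peak list falls back to all peaks.
    """
    ranked = sorted(peaks, key=lambda p: p.rank)
    if top_n is not None and top_n <= len(ranked):
        ranked = ranked[:top_n]
    if not ranked:
        return float("nan")
    return sum(1 for p in ranked if p.fbe) / len(ranked)
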