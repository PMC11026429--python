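"""Pairwise Ks/Ka estimation by NG86 counting with Jukes–Cantor correction.

The estimator works on in-frame codon alignments: codon columns containing
gaps, ambiguous bases or stop codons in either sequence are skipped pairwise,
site counts are averaged across the two sequences, differences are
pathway-averaged, and the resulting proportions are corrected for multiple
hits with d = -(3/4)·ln(1 - 4p/3).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from . import codon as _codon

#: p-distance at which the Jukes–Cantor correction diverges.
SATURATION_P = 0.75

_VALID = set("ACGT")


@dataclass(frozen=True)
class CodonAlignmentPair:
    """Two aligned in-frame coding sequences.

    Sequences must be the same length, divisible by 3, over {A,C,G,T,-,N}
    (case-insensitive; other ambiguity codes are normalized to N).
    """

    seq1: str
    seq2: str
    id1: str = "seq1"
    id2: str = "seq2"

    def __post_init__(self):
        s1 = _normalize(self.seq1)
        s2 = _normalize(self.seq2)
        if len(s1) != len(s2):
            raise ValueError(
                f"aligned sequences differ in length: {len(s1)} vs {len(s2)}"
            )
        if len(s1) % 3 != 0:
            raise ValueError(f"alignment length {len(s1)} not divisible by 3")
        object.__setattr__(self, "seq1", s1)
        object.__setattr__(self, "seq2", s2)

    def codon_columns(self) -> Iterable[tuple[str, str]]:
        for i in range(0, len(self.seq1), 3):
            yield self.seq1[i : i + 3], self.seq2[i : i + 3]


def _normalize(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    return "".join(c if c in _VALID or c == "-" else "N" for c in seq)


@dataclass
class KsRecord:
    """Per-pair NG86 estimate.

    S/N are pair-averaged site counts, Sd/Nd pathway-averaged difference
    counts, pS/pN the proportions and Ks/Ka the Jukes–Cantor corrected
    rates.  ``flag`` is one of ok / saturated / too_short / undefined.
    """

    id1: str = "seq1"
    id2: str = "seq2"
    codons_used: int = 0
    S: float = float("nan")
    N: float = float("nan")
    Sd: float = float("nan")
    Nd: float = float("nan")
    pS: float = float("nan")
    pN: float = float("nan")
    Ka: float = float("nan")
    Ks: float = float("nan")
    flag: str = "ok"
    skipped_stop_columns: int = field(default=0, repr=False)


def jc_correct(p: float) -> float:
    """Jukes–Cantor multiple-hit correction d = -(3/4)·ln(1 - 4p/3).

    Defined for 0 <= p < 0.75; returns inf at or beyond saturation.
    """
    if p < 0:
        raise ValueError(f"proportion must be non-negative, got {p}")
    if p >= SATURATION_P:
        return math.inf
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _usable(c1: str, c2: str) -> bool:
    return _codon.is_sense_codon(c1) and _codon.is_sense_codon(c2)


def estimate_ks(pair: CodonAlignmentPair, strict_stops: bool = False) -> KsRecord:
    """NG86 Ks/Ka estimate for one aligned pair.

    Codon columns with gaps or Ns in either sequence are skipped; columns
    with an internal stop codon are skipped with a warning (or rejected when
    ``strict_stops``).  Columns whose every mutational pathway crosses a stop
    are likewise skipped.
    """
    rec = KsRecord(id1=pair.id1, id2=pair.id2)
    s1_sites = s2_sites = 0.0
    sd = nd = 0.0
    used = 0
    for c1, c2 in pair.codon_columns():
        if "-" in c1 or "-" in c2 or "N" in c1 or "N" in c2:
            continue
        if c1 in _codon.STOP_CODONS or c2 in _codon.STOP_CODONS:
            if strict_stops:
                raise ValueError(
                    f"internal stop codon in pair ({pair.id1}, {pair.id2})"
                )
            rec.skipped_stop_columns += 1
            continue
        try:
            col_sd, col_nd = _codon.count_differences(c1, c2)
        except ValueError:
            rec.skipped_stop_columns += 1
            continue
        a1, _ = _codon.count_sites(c1)
        a2, _ = _codon.count_sites(c2)
        s1_sites += a1
        s2_sites += a2
        sd += col_sd
        nd += col_nd
        used += 1
    if rec.skipped_stop_columns:
        warnings.warn(
            f"skipped {rec.skipped_stop_columns} stop-containing codon column(s) "
            f"in pair ({pair.id1}, {pair.id2})",
            stacklevel=2,
        )
    rec.codons_used = used
    if used == 0:
        rec.flag = "too_short"
        return rec
    S = 0.5 * (s1_sites + s2_sites)
    N = 3.0 * used - S
    rec.S, rec.N, rec.Sd, rec.Nd = S, N, sd, nd
    if S <= 0.0:
        rec.flag = "undefined"
        return rec
    rec.pS = sd / S
    rec.pN = nd / N if N > 0 else 0.0
    rec.Ka = jc_correct(rec.pN)
    if rec.pS >= SATURATION_P:
        rec.Ks = math.inf
        rec.flag = "saturated"
    else:
        rec.Ks = jc_correct(rec.pS)
    return rec


_TSV_COLUMNS = [
    "gene1", "gene2", "codons_used",
    "S", "N", "Sd", "Nd", "pS", "pN", "Ka", "Ks", "flag",
]


def batch_ks(
    pairs: Sequence[CodonAlignmentPair], strict_stops: bool = False
) -> pd.DataFrame:
    """Estimate Ks for a collection of pairs; one row per pair, in order.

    Per-pair failures are recorded in the ``flag`` column and never abort
    the batch.
    """
    rows = []
    for pair in pairs:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rec = estimate_ks(pair, strict_stops=strict_stops)
        except ValueError:
            rec = KsRecord(id1=pair.id1, id2=pair.id2, flag="undefined")
        rows.append(
            {
                "gene1": rec.id1,
                "gene2": rec.id2,
                "codons_used": rec.codons_used,
                "S": rec.S,
                "N": rec.N,
                "Sd": rec.Sd,
                "Nd": rec.Nd,
                "pS": rec.pS,
                "pN": rec.pN,
                "Ka": rec.Ka,
                "Ks": rec.Ks,
                "flag": rec.flag,
            }
        )
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)
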