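"""Position-wise nucleotide misincorporation profiles.

Cytosine deamination leaves an excess of C->T substitutions at the 5' ends
of degraded reads that declines roughly exponentially inwards (with the
mirrored G->A excess at the 3' end in double-stranded libraries). Profiles
here count, for each position from either read end, every ref->read base
change conditional on the reference base at that position — the convention
that makes the frequencies independent of depth and base composition. The
headline authenticity statistic is the percentage of C->T at the first 5'
base.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from ._seq import BASES, encode
from .alignments_io import ReadAlignment

FIVE_PRIME = "5p"
THREE_PRIME = "3p"


@dataclass
class MisincProfile:
    """Substitution counts by end, position (1-based from that end) and type.

    ``counts[end][p-1, ref, read]`` counts read base `read` where the
    reference base is `ref` at position p from the given end. Frequencies
    are conditional on the reference base; cells with a zero denominator
    are reported as NaN.
    """

    counts: dict[str, np.ndarray]  # end -> (P, 4, 4) int64
    P: int
    n_reads: int

    def denominator(self, end: str, position: int, ref_base: str) -> int:
        return int(self.counts[end][position - 1, BASES.index(ref_base)].sum())

    def freq(self, end: str, position: int, ref_base: str, read_base: str) -> float:
        if not 1 <= position <= self.P:
            raise ValueError(f"position must be in [1, {self.P}]")
        row = self.counts[end][position - 1, BASES.index(ref_base)]
        denom = row.sum()
        if denom == 0:
            return float("nan")
        return float(row[BASES.index(read_base)] / denom)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table of the 12 substitution types per end and position."""
        rows = []
        for end, arr in self.counts.items():
            for p in range(1, self.P + 1):
                for ri, ref in enumerate(BASES):
                    denom = arr[p - 1, ri].sum()
                    for qi, alt in enumerate(BASES):
                        if ref == alt:
                            continue
                        rows.append(
                            {
                                "end": end,
                                "position": p,
                                "substitution": f"{ref}>{alt}",
                                "count": int(arr[p - 1, ri, qi]),
                                "denominator": int(denom),
                                "frequency": arr[p - 1, ri, qi] / denom
                                if denom
                                else np.nan,
                            }
                        )
        return pd.DataFrame(rows)

    def ct_5p_table(self) -> pd.DataFrame:
        """5' C->T frequency by position (5pCtoT-style two-column table)."""
        rows = []
        for p in range(1, self.P + 1):
            rows.append({"position": p, "frequency": self.freq(FIVE_PRIME, p, "C", "T")})
        return pd.DataFrame(rows)


@dataclass
class DeaminationStat:
    """Percentage of C->T at the first 5' base (the deamination proxy)."""

    ct_first_pct: float
    denominator: int


def misincorporation_profile(
    reads: Iterable[ReadAlignment], P: int = 25
) -> MisincProfile:
    """Count ref->read substitutions by position from the 5' and 3' ends.

    Reads shorter than P contribute only to positions up to their length
    from each end; 'N' (or any non-ACGT character) in read or reference is
    skipped. All columns are match columns by construction (indel/clipped
    reads are filtered out upstream).
    """
    ref5_parts, read5_parts = [], []
    ref3_parts, read3_parts = [], []
    len5 = []
    n = 0
    for r in reads:
        n += 1
        m = min(len(r.read_bases), P)
        len5.append(m)
        ref5_parts.append(r.ref_bases[:m])
        read5_parts.append(r.read_bases[:m])
        ref3_parts.append(r.ref_bases[-m:][::-1])
        read3_parts.append(r.read_bases[-m:][::-1])
    if n == 0:
        raise ValueError("no reads: cannot build a misincorporation profile")
    counts = {
        FIVE_PRIME: np.zeros((P, 4, 4), dtype=np.int64),
        THREE_PRIME: np.zeros((P, 4, 4), dtype=np.int64),
    }
    lens = np.array(len5, dtype=np.int64)
    total = int(lens.sum())
    pos = np.arange(total) - np.repeat(np.cumsum(lens) - lens, lens)
    for end, ref_parts, read_parts in (
        (FIVE_PRIME, ref5_parts, read5_parts),
        (THREE_PRIME, ref3_parts, read3_parts),
    ):
        ref = encode("".join(ref_parts))
        read = encode("".join(read_parts))
        valid = (ref < 4) & (read < 4)
        np.add.at(counts[end], (pos[valid], ref[valid], read[valid]), 1)
    return MisincProfile(counts=counts, P=P, n_reads=n)


def first_base_ct(profile: MisincProfile) -> DeaminationStat:
    """Percentage (0-100) of C->T substitutions at 5' position 1."""
    denom = profile.denominator(FIVE_PRIME, 1, "C")
    if denom == 0:
        raise ValueError(
            "no reads with reference C at 5' position 1: "
            "first-base C->T percentage undefined"
        )
    f = profile.freq(FIVE_PRIME, 1, "C", "T")
    return DeaminationStat(ct_first_pct=100.0 * f, denominator=denom)
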