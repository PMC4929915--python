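"""Genomic base composition upstream of 5' read ends (break-point analysis).

Depurination creates abasic sites whose backbone subsequently breaks, so
strand breaks fall preferentially just 3' of a purine: in mapped historic
reads the reference base at position -1 (immediately 5' of the read start,
in read orientation) is enriched for A and G relative to the genomic
background. The enrichment statistic is the fold ratio of a base's
frequency at -1 over its frequency at -5, the background position far
enough from the break to be unaffected.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from ._seq import BASES, encode
from .alignments_io import CONTEXT_SIZE, ReadAlignment


@dataclass
class CompositionProfile:
    """Base frequencies at positions -10..-1 upstream of the 5' read end.

    ``counts[i, b]`` counts base b at position -(10-i); reads with non-ACGT
    context at a position are excluded from that position's tally.
    """

    counts: np.ndarray  # (CONTEXT_SIZE, 4) int64
    n_reads_used: int

    def freq(self, position: int, base: str) -> float:
        row = self.counts[self._row(position)]
        total = row.sum()
        if total == 0:
            raise ValueError(f"no counts at position {position}")
        return float(row[BASES.index(base)] / total)

    def frequencies(self) -> pd.DataFrame:
        """Long-format table: position, base, frequency, count."""
        rows = []
        for i in range(CONTEXT_SIZE):
            pos = i - CONTEXT_SIZE
            total = self.counts[i].sum()
            for b, cnt in zip(BASES, self.counts[i]):
                rows.append(
                    {
                        "position": pos,
                        "base": b,
                        "count": int(cnt),
                        "frequency": cnt / total if total else np.nan,
                    }
                )
        return pd.DataFrame(rows)

    @staticmethod
    def _row(position: int) -> int:
        if not -CONTEXT_SIZE <= position <= -1:
            raise ValueError(f"position must be in [-{CONTEXT_SIZE}, -1]")
        return position + CONTEXT_SIZE


@dataclass
class EnrichmentStat:
    """Fold enrichment of one purine at -1 versus the -5 background."""

    base: str
    fold: float
    se_fold: float  # delta-method SE of the binomial frequency ratio
    count_minus1: int
    count_minus5: int
    n_minus1: int
    n_minus5: int


def composition_profile(reads: Iterable[ReadAlignment]) -> CompositionProfile:
    """Tally upstream-context base frequencies over all context-complete reads.

    Context-truncated reads (too close to a contig edge to supply 10
    upstream bases) are skipped entirely; non-ACGT characters are skipped
    per position.
    """
    contexts = []
    for r in reads:
        if r.context_truncated or len(r.upstream_context) < CONTEXT_SIZE:
            continue
        contexts.append(r.upstream_context)
    if not contexts:
        raise ValueError("all reads are context-truncated; no profile possible")
    mat = encode("".join(contexts)).reshape(len(contexts), CONTEXT_SIZE)
    counts = np.zeros((CONTEXT_SIZE, 4), dtype=np.int64)
    for i in range(CONTEXT_SIZE):
        col = mat[:, i]
        counts[i] = np.bincount(col[col < 4], minlength=4)
    return CompositionProfile(counts=counts, n_reads_used=len(contexts))


def purine_enrichment(
    profile: CompositionProfile, background_position: int = -5
) -> dict[str, EnrichmentStat]:
    """Fold enrichment of A and of G at -1 relative to the background position.

    The standard error of the ratio of two independent binomial frequencies
    is obtained by the delta method on the log ratio:
    var(ln fold) ~= (1-p1)/(n1 p1) + (1-p5)/(n5 p5).
    """
    out = {}
    row1 = profile.counts[profile._row(-1)]
    row5 = profile.counts[profile._row(background_position)]
    n1, n5 = int(row1.sum()), int(row5.sum())
    for base in ("A", "G"):
        b = BASES.index(base)
        c1, c5 = int(row1[b]), int(row5[b])
        if c5 == 0 or n5 == 0:
            raise ValueError(
                f"frequency of {base} at background position "
                f"{background_position} is zero; fold ratio undefined"
            )
        p1, p5 = c1 / n1, c5 / n5
        fold = p1 / p5
        var_log = 0.0
        if c1 > 0:
            var_log = (1 - p1) / (n1 * p1) + (1 - p5) / (n5 * p5)
        out[base] = EnrichmentStat(
            base=base,
            fold=fold,
            se_fold=fold * float(np.sqrt(var_log)),
            count_minus1=c1,
            count_minus5=c5,
            n_minus1=n1,
            n_minus5=n5,
        )
    return out
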