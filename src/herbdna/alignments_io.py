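"""Alignment and metadata I/O for damage profiling.

Reads mapped merged reads (SAM/BAM) together with their reference FASTA and
produces oriented per-read records: for every read we keep the aligned
read/reference base pairs in *read orientation* (minus-strand records are
reverse-complemented) plus the reference context immediately 5' of the
read's first base, which is what break-point composition profiling needs.

Coordinates are 0-based half-open internally; SAM's 1-based convention is
handled at the file boundary by pysam. Position -1 denotes the reference
base immediately 5' of the first read base in read orientation; read
positions are 1-based from the 5' end.
"""
from __future__ import annotations

import collections
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import pysam
from pyfaidx import Fasta

from ._seq import revcomp

CONTEXT_SIZE = 10

NUCLEAR = "nuclear"
ORGANELLE = "organelle"

#: CIGAR operations treated as aligned match columns (M, =, X)
_MATCH_OPS = frozenset({0, 7, 8})


@dataclass(slots=True)
class ReadAlignment:
    """One mapped merged read, reported in read orientation.

    ``start``/``end`` are the 0-based half-open reference interval on the
    forward strand; ``read_bases``/``ref_bases`` are the aligned sequences in
    read (5'->3') orientation, so for minus-strand reads both are
    reverse-complemented relative to the reference forward strand.
    ``upstream_context`` holds up to ``CONTEXT_SIZE`` reference bases
    immediately 5' of the read's first base, also in read orientation; its
    last character is position -1.
    """

    contig: str
    start: int
    end: int
    strand: str  # '+' or '-'
    read_bases: str
    ref_bases: str
    upstream_context: str
    mapq: int = 60
    context_truncated: bool = False
    cluster_size: int = 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SampleMeta:
    """Identity and covariates of one sequencing library/sample."""

    sample_id: str
    collection_year: int
    age: float
    factors: dict[str, str] = field(default_factory=dict)
    compartment_of_contig: dict[str, str] = field(default_factory=dict)
    alignment_path: str | None = None

    def compartment(self, contig: str) -> str:
        return self.compartment_of_contig.get(contig, NUCLEAR)


@dataclass
class FilterStats:
    """Counts of records surviving/dropped by each alignment filter."""

    total: int = 0
    unmapped: int = 0
    secondary_supplementary: int = 0
    below_mapq: int = 0
    indel_or_clip: int = 0
    kept: int = 0


def load_reference(fasta_path: str | Path) -> dict[str, str]:
    """Load all contig sequences into memory as upper-case strings."""
    fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def load_alignments(
    alignment_path: str | Path,
    fasta_path: str | Path | dict[str, str],
    min_mapq: int = 25,
    compartment_filter: str | None = None,
    compartment_of_contig: dict[str, str] | None = None,
    stats: FilterStats | None = None,
) -> Iterator[ReadAlignment]:
    """Stream filtered, oriented read records from a SAM/BAM file.

    Unmapped, secondary, supplementary and below-``min_mapq`` records are
    dropped, as are reads whose CIGAR contains indels or clips (damage
    profiles are positionally indexed from the read ends and assume
    end-anchored match-only alignments). When ``compartment_filter`` is
    given, only reads from contigs of that compartment are yielded.
    """
    if isinstance(fasta_path, dict):
        ref = fasta_path
    else:
        ref = load_reference(fasta_path)
    compartments = compartment_of_contig or {}
    if stats is None:
        stats = FilterStats()

    any_seen = False
    with pysam.AlignmentFile(str(alignment_path), check_sq=False) as af:
        for rec in af:
            stats.total += 1
            if rec.is_unmapped:
                stats.unmapped += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                stats.secondary_supplementary += 1
                continue
            if rec.mapping_quality < min_mapq:
                stats.below_mapq += 1
                continue
            cig = rec.cigartuples
            if cig is None or any(op not in _MATCH_OPS for op, _ in cig):
                stats.indel_or_clip += 1
                continue
            contig = rec.reference_name
            if contig not in ref:
                raise KeyError(
                    f"contig {contig!r} in {alignment_path} absent from reference FASTA"
                )
            if compartment_filter is not None:
                if compartments.get(contig, NUCLEAR) != compartment_filter:
                    continue
            seq = ref[contig]
            start = rec.reference_start
            end = rec.reference_end
            read_fwd = rec.query_sequence  # reference-forward orientation
            ref_fwd = seq[start:end]
            if rec.is_reverse:
                read_bases = revcomp(read_fwd)
                ref_bases = revcomp(ref_fwd)
                ctx_fwd = seq[end : min(end + CONTEXT_SIZE, len(seq))]
                context = revcomp(ctx_fwd)
            else:
                read_bases = read_fwd
                ref_bases = ref_fwd
                context = seq[max(0, start - CONTEXT_SIZE) : start]
            stats.kept += 1
            any_seen = True
            yield ReadAlignment(
                contig=contig,
                start=start,
                end=end,
                strand="-" if rec.is_reverse else "+",
                read_bases=read_bases,
                ref_bases=ref_bases,
                upstream_context=context,
                mapq=rec.mapping_quality,
                context_truncated=len(context) < CONTEXT_SIZE,
            )
    if not any_seen:
        warnings.warn(
            f"no alignments passed filters in {alignment_path}", stacklevel=2
        )


def _consensus(cluster: list[ReadAlignment]) -> ReadAlignment:
    if len(cluster) == 1:
        return cluster[0]
    first = cluster[0]
    length = len(first.read_bases)
    cols = []
    for i in range(length):
        counts = collections.Counter(r.read_bases[i] for r in cluster)
        (top_base, top_n), *rest = counts.most_common()
        if rest and rest[0][1] == top_n:
            cols.append("N")  # tie between majority bases
        else:
            cols.append(top_base)
    return ReadAlignment(
        contig=first.contig,
        start=first.start,
        end=first.end,
        strand=first.strand,
        read_bases="".join(cols),
        ref_bases=first.ref_bases,
        upstream_context=first.upstream_context,
        mapq=max(r.mapq for r in cluster),
        context_truncated=first.context_truncated,
        cluster_size=len(cluster),
    )


def deduplicate(reads: Iterable[ReadAlignment]) -> list[ReadAlignment]:
    """Collapse PCR duplicates, identified by start and end coordinates.

    All reads sharing (contig, start, end, strand) form one cluster and are
    replaced by a consensus read: the majority base at each position, with
    ties reported as 'N'. The cluster size is recorded on the consensus
    record. Idempotent; empty input yields empty output.
    """
    clusters: dict[tuple, list[ReadAlignment]] = {}
    for r in reads:
        clusters.setdefault((r.contig, r.start, r.end, r.strand), []).append(r)
    return [_consensus(c) for c in clusters.values()]


def split_by_compartment(
    reads: Iterable[ReadAlignment], compartment_of_contig: dict[str, str]
) -> dict[str, list[ReadAlignment]]:
    """Partition reads by the compartment label of their contig.

    Contigs missing from the map default to nuclear.
    """
    out: dict[str, list[ReadAlignment]] = {}
    for r in reads:
        out.setdefault(compartment_of_contig.get(r.contig, NUCLEAR), []).append(r)
    return out


def load_compartment_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (contig, compartment) into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["contig", "compartment"],
                     dtype=str, comment="#")
    bad = set(df["compartment"]) - {NUCLEAR, ORGANELLE}
    if bad:
        raise ValueError(f"unknown compartment labels: {sorted(bad)}")
    return dict(zip(df["contig"], df["compartment"]))


def load_sample_table(
    tsv_path: str | Path, reference_year: int
) -> list[SampleMeta]:
    """Load per-sample metadata; derive age = reference_year - collection_year.

    Required columns: ``sample_id``, ``collection_year``. Optional:
    ``path`` (alignment file), ``compartment_file`` (contig->compartment TSV,
    default: every contig nuclear). Any further column becomes a factor
    label usable in ANCOVA (e.g. extraction_method, infection status).
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    required = {"sample_id", "collection_year"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dup}")
    base = Path(tsv_path).parent
    reserved = {"sample_id", "collection_year", "path", "compartment_file"}
    metas: list[SampleMeta] = []
    for _, row in df.iterrows():
        if pd.isna(row["collection_year"]) or str(row["collection_year"]).strip() == "":
            raise ValueError(f"sample {row['sample_id']}: missing collection year")
        year = int(row["collection_year"])
        if year > reference_year:
            raise ValueError(
                f"sample {row['sample_id']}: collection year {year} is after "
                f"reference year {reference_year}"
            )
        age = reference_year - year
        if age == 0:
            warnings.warn(
                f"sample {row['sample_id']} has age 0; it will be excluded "
                "from the decay regression",
                stacklevel=2,
            )
        comp: dict[str, str] = {}
        if "compartment_file" in df.columns and not pd.isna(row.get("compartment_file")):
            p = Path(str(row["compartment_file"]))
            comp = load_compartment_map(p if p.is_absolute() else base / p)
        path = None
        if "path" in df.columns and not pd.isna(row.get("path")):
            p = Path(str(row["path"]))
            path = str(p if p.is_absolute() else base / p)
        factors = {
            c: str(row[c]) for c in df.columns if c not in reserved and not pd.isna(row[c])
        }
        metas.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                collection_year=year,
                age=float(age),
                factors=factors,
                compartment_of_contig=comp,
                alignment_path=path,
            )
        )
    return metas
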