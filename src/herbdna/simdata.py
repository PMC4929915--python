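"""Synthetic damaged-read simulator with known ground truth.

Emulates the data-generating process that post-mortem DNA decay inference
assumes: per-bond i.i.d. breakage gives geometric fragment lengths with
per-bond break probability lambda = k * age; depurination biases break
points so that the genomic base immediately 5' of each fragment end is
preferentially a purine; cytosine deamination near the 5' end produces
C->T miscoding that declines geometrically inwards and grows linearly with
age (with a mirrored G->A signal at the 3' end, as in double-stranded
libraries); a logistic length-dependent recovery filter reshapes the short
end of the length distribution into the moded, lognormal-looking body seen
in real libraries while leaving the right tail exponential.

All randomness flows from one integer seed; each sample uses a substream
derived from (seed, stable hash of sample id), so cohorts are reproducible
read-for-read regardless of simulation order.
"""
from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam

from ._seq import A, C, G, T, decode, encode, revcomp
from .alignments_io import NUCLEAR, ORGANELLE, ReadAlignment, CONTEXT_SIZE

_MAX_BATCHES = 200


@dataclass
class SimulationConfig:
    """Study conditions for a simulated cohort.

    Defaults describe a plant herbarium-like setting: Arabidopsis-like GC
    content, a per-site per-year breakage rate of 1.66e-4, first-base
    deamination growing by 2e-4 per year of age and halving with every base
    from the 5' end, a two-fold purine preference at break points, and a
    logistic recovery filter centred at 35 bp.
    """

    ages: Sequence[float] = (50.0, 150.0, 278.0)
    n_reads: int = 50_000
    reference_length: int = 100_000
    contig_compartments: Mapping[str, str] = field(
        default_factory=lambda: {"chr1": NUCLEAR}
    )
    gc_content: float = 0.36
    k_true: float = 1.66e-4
    purine_break_weight: float = 2.0
    deam_rate_per_year: float = 2.0e-4
    deam_decline: float = 0.5
    deam_offset_organelle: float = -0.005
    seq_error: float = 1.0e-3
    min_len: int = 25
    max_len: int = 500
    recovery_L50: float = 35.0
    recovery_scale: float = 5.0
    reference_year: int = 2015
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference_length < 10_000:
            raise ValueError("reference_length must be >= 10 kb per contig")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")
        for name, val in [
            ("deam_rate_per_year", self.deam_rate_per_year),
            ("deam_decline", self.deam_decline),
            ("seq_error", self.seq_error),
        ]:
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.purine_break_weight < 0:
            raise ValueError("purine_break_weight must be >= 0")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.max_len <= self.min_len:
            raise ValueError("max_len must exceed min_len")
        if not self.ages:
            raise ValueError("at least one sample age required")
        if min(self.ages) <= 0:
            raise ValueError("ages must be > 0 (lambda = 0 is degenerate)")
        if self.k_true * max(self.ages) >= 1.0:
            raise ValueError("k_true * max(age) must be < 1 (lambda is a probability)")
        bad = set(self.contig_compartments.values()) - {NUCLEAR, ORGANELLE}
        if bad:
            raise ValueError(f"unknown compartment labels: {sorted(bad)}")


@dataclass
class SampleTruth:
    """Ground-truth parameters of one simulated sample, for recovery tests."""

    sample_id: str
    age: float
    lambda_true: float
    deam_first_base_true: dict[str, float]
    purine_break_weight: float

    def __post_init__(self) -> None:
        if not 0.0 < self.lambda_true < 1.0:
            raise ValueError("lambda_true must lie in (0, 1)")


class Reference:
    """Simulated reference: contig sequences plus compartment labels."""

    def __init__(self, sequences: dict[str, str], compartments: dict[str, str]):
        self.sequences = sequences
        self.compartments = compartments
        self.contig_names = list(sequences)
        self._codes = {name: encode(seq) for name, seq in sequences.items()}
        self._lengths = np.array([len(sequences[c]) for c in self.contig_names])

    def codes(self, contig: str) -> np.ndarray:
        return self._codes[contig]

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def generate_reference(config: SimulationConfig) -> Reference:
    """Draw i.i.d. reference sequences at the configured GC content.

    Deterministic for a fixed config seed (the reference uses its own
    substream so that changing cohort layout does not change the genome).
    """
    rng = np.random.default_rng([config.seed, 0x5EF])
    p_gc = config.gc_content
    probs = np.array([(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2])
    seqs, comps = {}, {}
    for name, comp in config.contig_compartments.items():
        codes = rng.choice(4, size=config.reference_length, p=probs).astype(np.uint8)
        seqs[name] = decode(codes)
        comps[name] = comp
    return Reference(seqs, comps)


def sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    """Per-sample substream: seeded by (cohort seed, CRC32 of sample id)."""
    return np.random.default_rng([seed, zlib.crc32(sample_id.encode())])


def _truncated_geometric(
    rng: np.random.Generator, lam: float, lo: int, hi: int, size: int
) -> np.ndarray:
    """Inverse-CDF sample of geometric(p=lam) conditioned on lo <= L <= hi."""
    q = 1.0 - lam
    top = q ** (lo - 1)
    span = top - q**hi
    u = rng.random(size)
    L = np.ceil(np.log(top - u * span) / np.log(q)).astype(np.int64)
    return np.clip(L, lo, hi)


def truncated_geometric_mean(lam: float, lo: int, hi: int) -> float:
    """Mean of geometric(p=lam) conditioned on [lo, hi], by direct summation."""
    L = np.arange(lo, hi + 1, dtype=float)
    w = (1.0 - lam) ** (L - 1.0)
    return float(np.sum(L * w) / np.sum(w))


def _first_base_deam(config: SimulationConfig, age: float) -> dict[str, float]:
    d1 = age * config.deam_rate_per_year
    out = {NUCLEAR: min(max(d1, 0.0), 1.0)}
    if any(c == ORGANELLE for c in config.contig_compartments.values()):
        out[ORGANELLE] = min(max(d1 + config.deam_offset_organelle, 0.0), 1.0)
    return out


def make_truth(config: SimulationConfig, sample_id: str, age: float) -> SampleTruth:
    return SampleTruth(
        sample_id=sample_id,
        age=age,
        lambda_true=config.k_true * age,
        deam_first_base_true=_first_base_deam(config, age),
        purine_break_weight=config.purine_break_weight,
    )


def simulate_sample(
    reference: Reference,
    truth: SampleTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    disable_recovery: bool = False,
) -> list[ReadAlignment]:
    """Simulate ``config.n_reads`` damaged mapped reads for one sample.

    Candidate fragments are drawn with truncated-geometric lengths, placed
    uniformly, thinned by the logistic recovery filter, and accepted with
    probability proportional to the break-point weight of the base 5' of
    each fragment end (w_pur for purines, 1 for pyrimidines; the 3' flank is
    assessed on the complementary strand). Accepted fragments then receive
    position-dependent deamination and uniform sequencing error, and a
    uniformly random strand of origin.
    """
    if rng is None:
        rng = sample_rng(config.seed, truth.sample_id)
    lam = truth.lambda_true
    if not 0.0 < lam < 1.0:
        raise ValueError("lambda_true must lie in (0, 1)")
    n_target = config.n_reads
    w_pur = config.purine_break_weight
    w_max = max(w_pur, 1.0)

    genome = np.concatenate([reference.codes(c) for c in reference.contig_names])
    contig_lens = np.array(
        [len(reference.sequences[c]) for c in reference.contig_names], dtype=np.int64
    )
    offsets = np.concatenate([[0], np.cumsum(contig_lens)[:-1]])
    p_contig = contig_lens / contig_lens.sum()
    is_organelle = np.array(
        [reference.compartments[c] == ORGANELLE for c in reference.contig_names]
    )
    d1_nuc = truth.deam_first_base_true.get(NUCLEAR, 0.0)
    d1_org = truth.deam_first_base_true.get(ORGANELLE, d1_nuc)

    acc_contig: list[np.ndarray] = []
    acc_start: list[np.ndarray] = []
    acc_len: list[np.ndarray] = []
    n_have = 0
    for _ in range(_MAX_BATCHES):
        if n_have >= n_target:
            break
        m = max(2048, int((n_target - n_have) * 2.5))
        L = _truncated_geometric(rng, lam, config.min_len, config.max_len, m)
        if not disable_recovery:
            p_rec = 1.0 / (1.0 + np.exp(-(L - config.recovery_L50) / config.recovery_scale))
            keep = rng.random(m) < p_rec
            L = L[keep]
        m = L.size
        if m == 0:
            continue
        ci = rng.choice(len(contig_lens), size=m, p=p_contig)
        room = contig_lens[ci] - L - 1
        ok = room >= 1
        ci, L, room = ci[ok], L[ok], room[ok]
        # start in [1, contig_len - L - 1] so both flanking bases exist
        start = 1 + (rng.random(L.size) * room).astype(np.int64)
        gstart = offsets[ci] + start
        left = genome[gstart - 1]
        right = genome[gstart + L]  # its complement flanks the minus-strand 5' end
        w_left = np.where((left == A) | (left == G), w_pur, 1.0)
        # complement of right flank is a purine iff the plus-strand base is C/T
        w_right = np.where((right == C) | (right == T), w_pur, 1.0)
        accept = rng.random(L.size) < (w_left * w_right) / (w_max * w_max)
        if accept.any():
            acc_contig.append(ci[accept])
            acc_start.append(start[accept])
            acc_len.append(L[accept])
            n_have += int(accept.sum())
    if n_have < n_target:
        raise RuntimeError(
            f"could not draw {n_target} acceptable fragments for "
            f"{truth.sample_id} within {_MAX_BATCHES} batches (check "
            "purine_break_weight against reference composition)"
        )
    ci = np.concatenate(acc_contig)[:n_target]
    start = np.concatenate(acc_start)[:n_target]
    L = np.concatenate(acc_len)[:n_target]
    minus = rng.random(n_target) < 0.5

    # flat per-base arrays across all reads, in read orientation
    total = int(L.sum())
    read_idx = np.repeat(np.arange(n_target), L)
    within = np.arange(total) - np.repeat(np.cumsum(L) - L, L)
    gstart = offsets[ci] + start
    pos = np.where(
        np.repeat(minus, L),
        np.repeat(gstart + L - 1, L) - within,
        np.repeat(gstart, L) + within,
    )
    codes = genome[pos].astype(np.int16)
    codes = np.where(np.repeat(minus, L), 3 - codes, codes)

    # deamination: C->T with prob d1*r^i from 5', G->A with prob d1*r^j from 3'
    d1 = np.where(is_organelle[ci], d1_org, d1_nuc)
    d1_flat = np.repeat(d1, L)
    r = config.deam_decline
    dist3 = np.repeat(L, L) - 1 - within
    u = rng.random(total)
    deam5 = (codes == C) & (u < d1_flat * r**within)
    deam3 = (codes == G) & (u < d1_flat * r**dist3)
    codes[deam5] = T
    codes[deam3] = A

    # uniform sequencing miscalls, applied last
    if config.seq_error > 0:
        err = rng.random(total) < config.seq_error
        n_err = int(err.sum())
        if n_err:
            codes[err] = (codes[err] + rng.integers(1, 4, size=n_err)) % 4

    bounds = np.concatenate([[0], np.cumsum(L)])
    flat = decode(codes.astype(np.uint8))
    reads: list[ReadAlignment] = []
    for i in range(n_target):
        contig = reference.contig_names[ci[i]]
        seq = reference.sequences[contig]
        s, e = int(start[i]), int(start[i] + L[i])
        read_bases = flat[bounds[i] : bounds[i + 1]]
        if minus[i]:
            ref_bases = revcomp(seq[s:e])
            context = revcomp(seq[e : min(e + CONTEXT_SIZE, len(seq))])
        else:
            ref_bases = seq[s:e]
            context = seq[max(0, s - CONTEXT_SIZE) : s]
        reads.append(
            ReadAlignment(
                contig=contig,
                start=s,
                end=e,
                strand="-" if minus[i] else "+",
                read_bases=read_bases,
                ref_bases=ref_bases,
                upstream_context=context,
                mapq=60,
                context_truncated=len(context) < CONTEXT_SIZE,
            )
        )
    return reads


def write_sam(
    reads: list[ReadAlignment],
    reference: Reference,
    path: str | Path,
    sample_id: str,
) -> None:
    """Write reads as a coordinate-sorted SAM file (match-only CIGARs)."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": name, "LN": len(reference.sequences[name])}
            for name in reference.contig_names
        ],
        "RG": [{"ID": sample_id, "SM": sample_id}],
    }
    tid = {name: i for i, name in enumerate(reference.contig_names)}
    order = sorted(range(len(reads)), key=lambda i: (tid[reads[i].contig], reads[i].start))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rank, i in enumerate(order):
            r = reads[i]
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"{sample_id}:{rank}"
            a.flag = 16 if r.strand == "-" else 0
            a.reference_id = tid[r.contig]
            a.reference_start = r.start
            a.mapping_quality = r.mapq
            a.cigartuples = [(0, r.length)]
            # SEQ is stored in reference-forward orientation
            a.query_sequence = revcomp(r.read_bases) if r.strand == "-" else r.read_bases
            out.write(a)


@dataclass
class CohortManifest:
    """Paths and ground truth of a written simulated cohort."""

    fasta: str
    sample_table: str
    compartment_file: str
    truth_json: str
    alignments: dict[str, str]
    truths: list[SampleTruth]


def simulate_cohort(config: SimulationConfig, outdir: str | Path) -> CohortManifest:
    """Simulate one sample per configured age and write the full artifact set.

    Writes the reference FASTA, one coordinate-sorted SAM per sample, a
    sample table TSV (sample_id, collection_year, path, compartment_file),
    the contig->compartment map, and a ground-truth JSON for recovery tests.
    Sample ids are S01..Snn in the order the ages are given; collection
    year is reference_year - age.
    """
    if len(set(config.ages)) < 2:
        raise ValueError("a cohort needs >= 2 distinct ages")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = generate_reference(config)
    fasta = outdir / "reference.fa"
    reference.write_fasta(fasta)

    comp_path = outdir / "compartments.tsv"
    with open(comp_path, "w") as fh:
        for name, comp in reference.compartments.items():
            fh.write(f"{name}\t{comp}\n")

    ids = [f"S{i + 1:02d}" for i in range(len(config.ages))]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    truths, alignments, rows = [], {}, []
    for sid, age in zip(ids, config.ages):
        truth = make_truth(config, sid, float(age))
        reads = simulate_sample(reference, truth, config)
        sam = outdir / f"{sid}.sam"
        write_sam(reads, reference, sam, sid)
        truths.append(truth)
        alignments[sid] = str(sam)
        rows.append(
            (sid, config.reference_year - int(round(age)), sam.name, comp_path.name)
        )

    table = outdir / "samples.tsv"
    with open(table, "w") as fh:
        fh.write("sample_id\tcollection_year\tpath\tcompartment_file\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    truth_json = outdir / "truth.json"
    with open(truth_json, "w") as fh:
        json.dump([asdict(t) for t in truths], fh, indent=1)

    return CohortManifest(
        fasta=str(fasta),
        sample_table=str(table),
        compartment_file=str(comp_path),
        truth_json=str(truth_json),
        alignments=alignments,
        truths=truths,
    )
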