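"""Shared fixtures: tiny hand-built alignment files and simulated samples."""
from __future__ import annotations

import textwrap
from pathlib import Path

import pytest

from herbdna import SimulationConfig, generate_reference, simulate_sample
from herbdna.simdata import make_truth

# 60 bp toy contig used by the hand-checked coordinate-convention tests.
TOY_REF = "ACGTACGTTTGATTACAGGCATGCATGCAAACCCGGGTTTAAAGGGCCCATATATATGCA"


@pytest.fixture(scope="session")
def toy_fasta(tmp_path_factory) -> Path:
    d = tmp_path_factory.mktemp("toy")
    path = d / "toy.fa"
    path.write_text(">chrT\n" + TOY_REF + "\n")
    return path


def write_sam_text(path: Path, records: list[str], contig: str = "chrT",
                   length: int = 60) -> Path:
    """Write a minimal SAM file from raw record lines."""
    header = f"@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:{contig}\tLN:{length}\n"
    path.write_text(header + "".join(r + "\n" for r in records))
    return path


def sam_line(qname: str, flag: int, pos1: int, seq: str, contig: str = "chrT",
             mapq: int = 60, cigar: str | None = None) -> str:
    cigar = cigar or f"{len(seq)}M"
    return "\t".join(
        [qname, str(flag), contig, str(pos1), str(mapq), cigar, "*", "0", "0",
         seq, "*"]
    )


@pytest.fixture(scope="session")
def small_sim():
    """One simulated sample on a uniform-composition genome, error-free.

    Moderate depth; used by profile-shape tests that only need the damage
    signals to be clearly measurable.
    """
    cfg = SimulationConfig(
        ages=[100.0],
        n_reads=30_000,
        reference_length=60_000,
        gc_content=0.5,
        k_true=1.0e-4,
        deam_rate_per_year=2.0e-3,  # first-base C->T 0.2 at age 100
        seq_error=0.0,
        seed=11,
    )
    ref = generate_reference(cfg)
    truth = make_truth(cfg, "SIM1", 100.0)
    reads = simulate_sample(ref, truth, cfg)
    return cfg, ref, truth, reads
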