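"""Parameter-recovery experiments for the simulator-driven pipeline.

Every estimator in the package can be checked by simulating data with known
ground truth and measuring how well the truth is recovered. This module
bundles those experiments so that the test suite and reporting scripts run
them under identical conditions: single-sample lambda recovery, cohort-level
decay-rate (k) and deamination-slope recovery, the rejection-sampling oracle
for purine break-point enrichment, and the ANCOVA calibration studies.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import alignments_io, kinetics
from ._seq import A, C, G, T
from .breakpoints import composition_profile, purine_enrichment
from .fraglen import fit_decay, length_distribution
from .kinetics import DecayRateEstimate, RegressionResult, ancova, regress
from .misinc import first_base_ct, misincorporation_profile
from .simdata import (
    Reference,
    SimulationConfig,
    generate_reference,
    make_truth,
    simulate_cohort,
    simulate_sample,
)

#: published per-site per-year decay rates used by the worked rate-ratio example
K_HERBARIUM = 1.66e-4
K_BONE = 2.71e-5


def decay_rate_ratio(k_bone: float = K_BONE) -> tuple[float, float]:
    """Worked example: herbarium decay rate over the ancient-bone rate.

    k is re-derived by the package's own through-origin regression on a
    cohort whose lambda values sit exactly on lambda = K_HERBARIUM * age,
    then divided by the bone rate. Returns (k_hat, ratio).
    """
    ages = [50.0, 150.0, 278.0]
    est = kinetics.estimate_decay_rate([(a, K_HERBARIUM * a) for a in ages])
    return est.k, est.k / k_bone


@dataclass
class LambdaRecovery:
    lambda_true: float
    lambda_hat: float
    window: tuple[int, int]
    n_reads: int

    @property
    def rel_err(self) -> float:
        return abs(self.lambda_hat - self.lambda_true) / self.lambda_true


def lambda_recovery(
    seed: int,
    lambda_true: float = 0.01,
    n_reads: int = 200_000,
    reference_length: int = 200_000,
) -> LambdaRecovery:
    """Single-sample recovery of the damage fraction from the length tail."""
    age = 100.0
    cfg = SimulationConfig(
        ages=[age],
        n_reads=n_reads,
        reference_length=reference_length,
        k_true=lambda_true / age,
        seed=seed,
    )
    ref = generate_reference(cfg)
    reads = simulate_sample(ref, make_truth(cfg, "L1", age), cfg)
    fit = fit_decay(length_distribution(reads))
    return LambdaRecovery(
        lambda_true=lambda_true,
        lambda_hat=fit.lambda_hat,
        window=fit.window,
        n_reads=n_reads,
    )


@dataclass
class CohortRecovery:
    table: pd.DataFrame  # per-sample age, lambda_hat, ct_first_pct
    decay: DecayRateEstimate
    k_true: float
    deam_regression: RegressionResult  # ct_first_pct ~ age
    deam_slope_true_pct: float  # expected slope on the percentage scale

    @property
    def k_rel_err(self) -> float:
        return abs(self.decay.k - self.k_true) / self.k_true


def cohort_recovery(
    seed: int,
    n_samples: int = 30,
    age_range: tuple[float, float] = (20.0, 278.0),
    k_true: float = K_HERBARIUM,
    n_reads: int = 50_000,
    reference_length: int = 100_000,
    deam_rate_per_year: float = 2.0e-4,
    workdir: str | Path | None = None,
) -> CohortRecovery:
    """Simulate an age-spanning cohort and recover k and the deamination slope.

    With ``workdir`` given, the cohort goes through the full file pipeline
    (FASTA + SAM written, loaded back, deduplicated); otherwise reads are
    profiled in memory, sample by sample.
    """
    ages = np.linspace(age_range[0], age_range[1], n_samples)
    cfg = SimulationConfig(
        ages=[float(a) for a in ages],
        n_reads=n_reads,
        reference_length=reference_length,
        k_true=k_true,
        deam_rate_per_year=deam_rate_per_year,
        seed=seed,
    )
    rows = []
    if workdir is not None:
        manifest = simulate_cohort(cfg, workdir)
        reference = alignments_io.load_reference(manifest.fasta)
        for truth in manifest.truths:
            reads = list(
                alignments_io.load_alignments(
                    manifest.alignments[truth.sample_id], reference
                )
            )
            reads = alignments_io.deduplicate(reads)
            rows.append(_damage_row(reads, truth))
    else:
        reference = generate_reference(cfg)
        for sid, age in zip((f"S{i + 1:02d}" for i in range(n_samples)), ages):
            truth = make_truth(cfg, sid, float(age))
            reads = simulate_sample(reference, truth, cfg)
            rows.append(_damage_row(reads, truth))
    table = pd.DataFrame(rows)
    decay = kinetics.estimate_decay_rate(list(zip(table["age"], table["lambda_hat"])))
    deam = regress(table["age"], table["ct_first_pct"])
    return CohortRecovery(
        table=table,
        decay=decay,
        k_true=k_true,
        deam_regression=deam,
        deam_slope_true_pct=100.0
        * deam_rate_per_year
        * (1.0 - cfg.seq_error),
    )


def _damage_row(reads, truth) -> dict:
    fit = fit_decay(length_distribution(reads))
    ct = first_base_ct(misincorporation_profile(reads))
    return {
        "sample_id": truth.sample_id,
        "age": truth.age,
        "lambda_true": truth.lambda_true,
        "lambda_hat": fit.lambda_hat,
        "ct_first_pct": ct.ct_first_pct,
    }


@dataclass
class ModernBaseline:
    ct_first_pct: float
    expected_pct: float
    binomial_sd_pct: float
    denominator: int


def modern_baseline(
    seed: int, age: float = 1.0, n_reads: int = 60_000,
    deam_rate_per_year: float = 2.0e-4, seq_error: float = 1.0e-3,
) -> ModernBaseline:
    """First-base C->T of a freshly collected sample: sequencing error only.

    The expectation for a read with reference C at position 1 is
    P(T) = d1*(1-e) + (1-d1)*e/3 with d1 = age * deamination rate; for a
    modern-age sample this sits at the error baseline e/3.
    """
    cfg = SimulationConfig(
        ages=[age],
        n_reads=n_reads,
        reference_length=100_000,
        deam_rate_per_year=deam_rate_per_year,
        seq_error=seq_error,
        seed=seed,
    )
    ref = generate_reference(cfg)
    reads = simulate_sample(ref, make_truth(cfg, "M1", age), cfg)
    stat = first_base_ct(misincorporation_profile(reads))
    d1 = age * deam_rate_per_year
    p = d1 * (1 - seq_error) + (1 - d1) * seq_error / 3
    return ModernBaseline(
        ct_first_pct=stat.ct_first_pct,
        expected_pct=100.0 * p,
        binomial_sd_pct=100.0 * float(np.sqrt(p * (1 - p) / stat.denominator)),
        denominator=stat.denominator,
    )


def purine_fold_oracle(
    reference: Reference,
    w_pur: float,
    seed: int,
    n_draws: int = 400_000,
    fragment_length: int = 60,
) -> dict[str, float]:
    """Brute-force rejection-sampling expectation of the -1/-5 fold ratios.

    Independent of the simulator: places fragments uniformly on the given
    reference, accepts each with probability proportional to the product of
    the break-point weights of the two flanking bases (purine weight w_pur,
    pyrimidine 1; the right flank assessed on the complementary strand),
    picks a strand at random, and tallies the reference base at positions
    -1 and -5 of the resulting 5' end.
    """
    rng = np.random.default_rng([seed, 0x0AC1E])
    genome = np.concatenate([reference.codes(c) for c in reference.contig_names])
    L = fragment_length
    w_max = max(w_pur, 1.0)
    start = rng.integers(5, genome.size - L - 5, size=n_draws)
    left = genome[start - 1]
    right = genome[start + L]
    w_left = np.where((left == A) | (left == G), w_pur, 1.0)
    w_right = np.where((right == C) | (right == T), w_pur, 1.0)
    keep = rng.random(n_draws) < (w_left * w_right) / (w_max * w_max)
    start = start[keep]
    minus = rng.random(start.size) < 0.5
    pos1 = np.where(minus, start + L, start - 1)
    pos5 = np.where(minus, start + L + 4, start - 5)
    b1 = genome[pos1]
    b5 = genome[pos5]
    b1 = np.where(minus, 3 - b1.astype(np.int16), b1)
    b5 = np.where(minus, 3 - b5.astype(np.int16), b5)
    out = {}
    for base, code in (("A", A), ("G", G)):
        f1 = np.mean(b1 == code)
        f5 = np.mean(b5 == code)
        out[base] = float(f1 / f5)
    return out


def purine_enrichment_experiment(
    seed: int, w_pur: float = 2.0, n_reads: int = 100_000,
    reference_length: int = 100_000,
) -> dict[str, dict[str, float]]:
    """Measured fold enrichment vs the rejection-sampling oracle."""
    cfg = SimulationConfig(
        ages=[100.0],
        n_reads=n_reads,
        reference_length=reference_length,
        gc_content=0.5,
        purine_break_weight=w_pur,
        seed=seed,
    )
    ref = generate_reference(cfg)
    reads = simulate_sample(ref, make_truth(cfg, "P1", 100.0), cfg)
    enr = purine_enrichment(composition_profile(reads))
    oracle = purine_fold_oracle(ref, w_pur, seed)
    return {
        "measured": {b: enr[b].fold for b in "AG"},
        "oracle": oracle,
    }


def purine_null_slope_experiment(
    seed: int,
    n_replicates: int = 100,
    n_samples: int = 8,
    n_reads: int = 2_500,
    alpha: float = 0.05,
) -> float:
    """Fraction of null cohorts whose fold-vs-year slope is non-significant.

    Each replicate simulates a cohort with a constant purine break weight
    (the null: depurination-driven breakage does not change through time),
    regresses fold(A) on collection year and tests the slope at ``alpha``.
    """
    ages = np.linspace(40.0, 260.0, n_samples)
    non_significant = 0
    for rep in range(n_replicates):
        cfg = SimulationConfig(
            ages=[float(a) for a in ages],
            n_reads=n_reads,
            reference_length=20_000,
            gc_content=0.5,
            seed=(seed * 1_000 + rep) % (2**31),
        )
        ref = generate_reference(cfg)
        folds, years = [], []
        for i, age in enumerate(ages):
            truth = make_truth(cfg, f"R{rep}S{i}", float(age))
            reads = simulate_sample(ref, truth, cfg)
            enr = purine_enrichment(composition_profile(reads))
            folds.append(enr["A"].fold)
            years.append(cfg.reference_year - age)
        r = regress(years, folds)
        non_significant += r.p_value >= alpha
    return non_significant / n_replicates


def _ancova_tables(rng, n_per_group: int, slope_b: float, shift_sd: float,
                   noise_sd: float = 1.0) -> pd.DataFrame:
    x = np.tile(np.linspace(20.0, 278.0, n_per_group), 2)
    g = np.repeat(["nuclear", "organelle"], n_per_group)
    slope = np.where(g == "nuclear", 0.02, slope_b)
    shift = np.where(g == "nuclear", 0.0, shift_sd * noise_sd)
    y = slope * x + shift + rng.normal(0.0, noise_sd, x.size)
    return pd.DataFrame({"y": y, "x": x, "g": g})


def ancova_type1_experiment(
    seed: int, n_replicates: int = 200, n_per_group: int = 15, alpha: float = 0.05
) -> float:
    """Interaction-test type-I error rate when both groups share one line."""
    rng = np.random.default_rng([seed, 0xA1])
    rejections = 0
    for _ in range(n_replicates):
        df = _ancova_tables(rng, n_per_group, slope_b=0.02, shift_sd=0.0)
        res = ancova(df, "y", "x", "g", alpha=alpha)
        rejections += res.interaction_p < alpha
    return rejections / n_replicates


def ancova_power_experiment(
    seed: int, n_replicates: int = 200, n_per_group: int = 15,
    shift_sd: float = 5.0, alpha: float = 0.05,
) -> dict[str, float]:
    """Detection of an intercept-only group shift (same slope in both groups).

    Returns the rate at which the additive-model factor effect is detected
    (power), the rate at which the interaction is *not* flagged, and the
    joint rate reproducing the expected pattern (factor significant,
    interaction not).
    """
    rng = np.random.default_rng([seed, 0xA2])
    factor_sig = interaction_ns = joint = 0
    for _ in range(n_replicates):
        df = _ancova_tables(rng, n_per_group, slope_b=0.02, shift_sd=shift_sd)
        res = ancova(df, "y", "x", "g", alpha=alpha)
        f = res.factor_p_additive < alpha
        ns = res.interaction_p >= alpha
        factor_sig += f
        interaction_ns += ns
        joint += f and ns
    n = n_replicates
    return {
        "power_factor": factor_sig / n,
        "interaction_not_significant": interaction_ns / n,
        "pattern_rate": joint / n,
    }
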