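"""Self-contained calibration and recovery experiments.

These run the pipeline's own code paths on synthetic data with known
truth and measure operating characteristics: the outlier rate of the
diploid-reference expression classifier, the false-discovery proportion
of the CNA caller, and end-to-end driver recovery through the
cross-species discrimination route.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import gene_cna as gc
from . import segmentation as seg
from . import synthetic as syn
from .driver_passenger import discriminate, project_region
from .expression import classify_value, prediction_interval
from .model import CnaTruth, SegmentCall


def expression_classifier_calibration(
    n_ref: int = 8,
    n_replicates: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    mu: float = 5.0,
    sd: float = 1.0,
) -> float:
    """Fraction (%) of held-out diploid draws classified 'normal'.

    Each replicate draws a fresh set of ``n_ref`` Gaussian reference
    values on the log scale, builds the classifier interval exactly as
    the expression module does, and classifies one held-out draw from
    the same distribution.  Averaging over replicates measures the
    marginal coverage of the rule; a correctly calibrated prediction
    interval gives close to ``100 * (1 - alpha)``.
    """
    rng = np.random.default_rng(seed)
    n_normal = 0
    for _ in range(n_replicates):
        ref = rng.normal(mu, sd, size=n_ref)
        lo, hi = prediction_interval(ref, alpha=alpha)
        if classify_value(float(rng.normal(mu, sd)), lo, hi) == "normal":
            n_normal += 1
    return 100.0 * n_normal / n_replicates


def _overlaps_truth(call: SegmentCall, truth: CnaTruth) -> bool:
    return any(
        s.chrom == call.chrom and call.start < s.end and s.start < call.end
        for s in truth.segments
    )


@dataclass
class FdrExperimentResult:
    mean_fdp: float
    per_replicate_fdp: list[float]
    total_called: int
    total_false: int


def cna_caller_fdr_experiment(
    n_replicates: int = 20,
    seed: int = 0,
    n_chrom: int = 5,
    chrom_len: int = 10_000_000,
    probe_spacing: float = 5_500.0,
    noise_sd: float = 0.2,
    target_probe_fraction: float = 0.05,
    fdr: float = seg.DEFAULT_FDR,
    min_probes: int = seg.DEFAULT_MIN_PROBES,
    mean_cutoff: float = seg.DEFAULT_MEAN_CUTOFF,
) -> FdrExperimentResult:
    """Mean false-discovery proportion among called CNA segments.

    Each replicate builds a synthetic genome, implants amp/del segments
    at |log2| >= 0.6 covering ~5% of probes, adds Gaussian probe noise,
    runs segmentation and calling with the standard parameters, and
    counts called segments that overlap no implanted segment as false
    discoveries.  Replicates without calls contribute FDP 0.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3 * n_replicates)]
    fdps: list[float] = []
    total_called = total_false = 0
    for rep in range(n_replicates):
        s_genome, s_truth, s_noise = child_seeds[3 * rep : 3 * rep + 3]
        genome = syn.make_genome(
            n_chrom=n_chrom, chrom_len=chrom_len, gene_count=1,
            probe_spacing=probe_spacing, seed=s_genome,
        )
        truth = syn.implant_random_truth(
            genome, f"rep{rep}", target_probe_fraction=target_probe_fraction,
            amp_range=(0.6, 1.5), seed=s_truth,
        )
        profiles = syn.simulate_acgh(genome, truth, noise_sd=noise_sd, seed=s_noise)
        segments = seg.segment_genome(profiles)
        calls = seg.call_cnas(
            segments, fdr=fdr, min_probes=min_probes, mean_cutoff=mean_cutoff
        )
        called = [c for c in calls if c.call != "neutral"]
        false = [c for c in called if not _overlaps_truth(c, truth)]
        fdps.append(len(false) / len(called) if called else 0.0)
        total_called += len(called)
        total_false += len(false)
    return FdrExperimentResult(
        mean_fdp=float(np.mean(fdps)) if fdps else 0.0,
        per_replicate_fdp=fdps,
        total_called=total_called,
        total_false=total_false,
    )


@dataclass
class DriverRecoveryResult:
    recall: float
    pcg_contamination: float
    n_dcg: int
    n_pcg: int
    p_value: float
    status: str


def driver_recovery_experiment(
    seed: int = 0,
    human_region_len: int = 8_000_000,
    n_genes: int = 80,
    driver_fraction: float = 0.5,
    n_samples: int = 8,
    noise_sd: float = 0.2,
    n_perm: int = 500,
    recurrence_fdr: float = 0.2,
) -> DriverRecoveryResult:
    """End-to-end synthetic driver recovery through the full pipeline.

    Simulates a human-amplicon-split scenario, runs aCGH simulation per
    dog tumor, segmentation, CNA calling, gene assignment, permutation
    recurrence, synteny projection and discrimination, then compares the
    DCG set against the implanted driver set.  ``pcg_contamination`` is
    the fraction of region-B genes wrongly absent from the PCG set
    because they were called amplified.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3 + n_samples)]
    scenario = syn.make_synteny_scenario(
        human_region_len=human_region_len, n_genes=n_genes,
        driver_fraction=driver_fraction, seed=seeds[0],
    )
    genome = syn.scenario_genome(scenario, seed=seeds[1])
    all_calls: list[SegmentCall] = []
    for i in range(n_samples):
        truth = CnaTruth(f"tumor{i + 1}", scenario.truth.segments)
        profiles = syn.simulate_acgh(genome, truth, noise_sd=noise_sd, seed=seeds[3 + i])
        segments = seg.segment_genome(profiles)
        all_calls.extend(seg.call_cnas(segments))
    matrix = gc.assign_gene_status(all_calls, genome.genes)
    gc.recurrence_test(matrix, n_perm=n_perm, fdr=recurrence_fdr, seed=seeds[2])
    human_region = (
        scenario.human_chrom,
        int(scenario.human_genes["start"].min()),
        int(scenario.human_genes["end"].max()),
    )
    regions, _ = project_region(human_region, scenario.blocks)
    result = discriminate(
        scenario.human_genes, matrix, regions, recurrence_fdr=recurrence_fdr
    )
    drivers = set(scenario.driver_ids)
    dcg = set(result.dcg)
    recall = len(dcg & drivers) / len(drivers) if drivers else 0.0
    b_ids = {g.id for g in scenario.dog_genes if g.chrom == "chr29"}
    amp_in_b = b_ids - set(result.pcg) - set(result.deleted)
    contamination = len(amp_in_b) / len(b_ids) if b_ids else 0.0
    return DriverRecoveryResult(
        recall=recall,
        pcg_contamination=contamination,
        n_dcg=len(result.dcg),
        n_pcg=len(result.pcg),
        p_value=result.p_value,
        status=result.status,
    )
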