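"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline (segmentation, gene recurrence,
expression integration, mutation spectra, driver/passenger
discrimination) can be exercised end-to-end on data produced here, with
the implanted truth available for recovery checks.  Defaults emulate the
study conditions the pipeline was built for: probe spacing of one probe
per 5-6 kb, Gaussian probe noise around implanted segments, log-normal
expression coupled to copy number for driver genes, substitution spectra
dominated by C:G>T:A transitions with a configurable CpG-transversion
odds multiplier, and a single "human" region split across two "dog"
chromosomes by a synteny break.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    SUBSTITUTION_CLASSES,
    TRANSITION_CLASSES,
    CnaTruth,
    Gene,
    GenomeModel,
    GeneCnaMatrix,
    ProbeProfile,
    SpectrumProfile,
    SyntenyBlock,
    TruthSegment,
    VariantRecord,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = 0, 1, 2, 3
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}

#: Default substitution spectrum: transitions at C:G sites dominate, as
#: observed in squamous-cell tumors of both species.
DEFAULT_CLASS_PROBS = {
    "C>A": 0.08, "C>G": 0.06, "C>T": 0.50,
    "T>A": 0.06, "T>C": 0.24, "T>G": 0.06,
}


def make_genome(
    n_chrom: int = 5,
    chrom_len: int = 10_000_000,
    gene_count: int = 50,
    probe_spacing: float = 5_500.0,
    seed: int = 0,
    gene_length: int = 20_000,
    jitter: float = 0.4,
) -> GenomeModel:
    """Build a miniature genome with a jittered probe grid and uniform genes.

    ``gene_count`` genes of length ``gene_length`` are placed uniformly
    and non-overlapping on **each** chromosome.  Probe positions sit on a
    grid with mean spacing ``probe_spacing`` jittered uniformly by
    ``+-jitter`` (fraction of the nominal spacing) to avoid grid
    artifacts.
    """
    if n_chrom < 1 or gene_count < 1 or chrom_len < 1:
        raise ValueError("all counts must be >= 1")
    if probe_spacing >= chrom_len:
        raise ValueError("probe spacing must be smaller than the chromosome length")
    if gene_count * gene_length > chrom_len:
        raise ValueError(
            f"impossible packing: {gene_count} genes x {gene_length} bp "
            f"exceed chromosome length {chrom_len}"
        )
    rng = np.random.default_rng(seed)
    chromosomes = [(f"chr{i + 1}", int(chrom_len)) for i in range(n_chrom)]
    probes: dict[str, np.ndarray] = {}
    genes: list[Gene] = []
    for chrom, length in chromosomes:
        m = int(length / (probe_spacing * (1 - jitter))) + 2
        gaps = rng.uniform(1 - jitter, 1 + jitter, size=m) * probe_spacing
        pos = np.cumsum(gaps).astype(np.int64)
        pos = pos[pos < length]
        pos = pos[np.concatenate(([True], np.diff(pos) > 0))]
        probes[chrom] = pos
        free = length - gene_count * gene_length
        offsets = np.sort(rng.uniform(0, free, size=gene_count))
        starts = (offsets + np.arange(gene_count) * gene_length).astype(np.int64)
        for i, s in enumerate(starts):
            genes.append(Gene(f"{chrom}_g{i:04d}", chrom, int(s), int(s) + gene_length))
    return GenomeModel(chromosomes, float(probe_spacing), probes, genes)


def implant_random_truth(
    genome: GenomeModel,
    sample_id: str,
    target_probe_fraction: float = 0.05,
    min_len: int = 150_000,
    max_len: int = 500_000,
    amp_range: tuple[float, float] = (0.6, 1.5),
    seed: int = 0,
) -> CnaTruth:
    """Implant non-overlapping amp/del segments covering about
    ``target_probe_fraction`` of all probes, alternating sign, with
    |log2| drawn uniformly from ``amp_range``."""
    rng = np.random.default_rng(seed)
    total_probes = sum(len(p) for p in genome.probes.values())
    budget = int(round(target_probe_fraction * total_probes))
    sizes = genome.chrom_sizes
    chrom_names = [c for c, _ in genome.chromosomes]
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    segments: list[TruthSegment] = []
    covered = 0
    sign = 1
    attempts = 0
    while covered < budget and attempts < 10_000:
        attempts += 1
        chrom = chrom_names[rng.integers(len(chrom_names))]
        length = int(rng.integers(min_len, max_len + 1))
        if length >= sizes[chrom]:
            continue
        start = int(rng.integers(0, sizes[chrom] - length))
        end = start + length
        if any(start < e and s < end for s, e in placed[chrom]):
            continue
        amp = float(rng.uniform(*amp_range)) * sign
        kind = "amp" if sign > 0 else "del"
        placed[chrom].append((start, end))
        segments.append(TruthSegment(chrom, start, end, amp, kind))
        pos = genome.probes[chrom]
        covered += int(np.sum((pos >= start) & (pos < end)))
        sign = -sign
    return CnaTruth(sample_id, segments)


def simulate_acgh(
    genome: GenomeModel,
    truth: CnaTruth,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> list[ProbeProfile]:
    """Probe log2 ratios: true segment amplitude plus Gaussian noise.

    Probes outside every truth segment have mean zero.  Returns one
    profile per chromosome of the genome.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    sizes = genome.chrom_sizes
    for seg in truth.segments:
        if seg.chrom not in sizes:
            raise ValueError(f"truth segment on unknown chromosome {seg.chrom}")
        if seg.start < 0 or seg.end > sizes[seg.chrom]:
            raise ValueError(f"truth segment {seg.chrom}:{seg.start}-{seg.end} outside genome")
    rng = np.random.default_rng(seed)
    profiles = []
    for chrom, _ in genome.chromosomes:
        pos = genome.probes[chrom]
        vals = np.zeros(len(pos))
        for seg in truth.segments:
            if seg.chrom == chrom:
                vals[(pos >= seg.start) & (pos < seg.end)] += seg.log2
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, size=len(pos))
        profiles.append(ProbeProfile(truth.sample_id, chrom, pos.copy(), vals))
    return profiles


def simulate_expression(
    genome: GenomeModel,
    gene_cna: "GeneCnaMatrix | pd.DataFrame",
    driver_ids: set[str] | Sequence[str],
    base_log2_mean: float = 5.0,
    sd: float = 0.5,
    coupling: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """FPKM-scale expression coupled to copy number for driver genes.

    ``log2(expr) = base + coupling * copy_log2 + N(0, sd)`` for drivers;
    the coupling term is omitted for all other genes.  ``gene_cna`` may
    be a :class:`GeneCnaMatrix` (its ``amplitude`` is used as the copy
    log2) or a gene x sample DataFrame of true copy log2 values.
    Returned values are ``2 ** log2`` (FPKM scale).
    """
    if coupling < 0:
        raise ValueError("coupling must be >= 0")
    copy_log2 = gene_cna.amplitude if isinstance(gene_cna, GeneCnaMatrix) else gene_cna
    driver_ids = set(driver_ids)
    unknown = driver_ids - set(copy_log2.index)
    if unknown:
        raise ValueError(f"unknown driver gene ids: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    log2e = pd.DataFrame(
        base_log2_mean + rng.normal(0.0, sd, size=copy_log2.shape),
        index=copy_log2.index,
        columns=copy_log2.columns,
    )
    drivers = copy_log2.index.isin(driver_ids)
    log2e.values[drivers, :] += coupling * copy_log2.values[drivers, :]
    return 2.0 ** log2e


def random_sequences(genome: GenomeModel, seed: int = 0) -> dict[str, np.ndarray]:
    """Uniform-random chromosome sequences as uint8 codes (0..3 = ACGT)."""
    rng = np.random.default_rng(seed)
    return {c: rng.integers(0, 4, size=n, dtype=np.uint8) for c, n in genome.chromosomes}


def sequences_to_str(seqs: Mapping[str, np.ndarray]) -> dict[str, str]:
    return {c: _BASES[s].tobytes().decode() for c, s in seqs.items()}


def _site_catalog(seqs: Mapping[str, np.ndarray]):
    """Candidate substitution sites, collapsed to the pyrimidine strand.

    Returns for each pyrimidine ref ('C' or 'T') a global catalog of
    (chrom index, position) sites; C sites carry (is_cpg, is_tpc) flags.
    """
    chroms = list(seqs)
    c_pos, c_chrom, c_cpg, c_tpc = [], [], [], []
    t_pos, t_chrom = [], []
    for ci, chrom in enumerate(chroms):
        s = seqs[chrom]
        if len(s) < 3:
            continue
        mid = s[1:-1]
        left = s[:-2]
        right = s[2:]
        idx = np.arange(1, len(s) - 1)
        is_c = mid == _C
        is_g = mid == _G
        sel = is_c | is_g
        pos = idx[sel]
        # CpG on either strand: C with 3' G, or G with 5' C
        cpg = np.where(mid[sel] == _C, right[sel] == _G, left[sel] == _C)
        # strand-collapsed TpC: 5' T on the strand where the ref reads C
        tpc = np.where(mid[sel] == _C, left[sel] == _T, right[sel] == _A)
        c_pos.append(pos)
        c_chrom.append(np.full(len(pos), ci))
        c_cpg.append(cpg)
        c_tpc.append(tpc)
        sel_t = (mid == _T) | (mid == _A)
        pos_t = idx[sel_t]
        t_pos.append(pos_t)
        t_chrom.append(np.full(len(pos_t), ci))
    cat = {
        "chroms": chroms,
        "C": {
            "pos": np.concatenate(c_pos) if c_pos else np.empty(0, int),
            "chrom": np.concatenate(c_chrom) if c_chrom else np.empty(0, int),
            "cpg": np.concatenate(c_cpg) if c_cpg else np.empty(0, bool),
            "tpc": np.concatenate(c_tpc) if c_tpc else np.empty(0, bool),
        },
        "T": {
            "pos": np.concatenate(t_pos) if t_pos else np.empty(0, int),
            "chrom": np.concatenate(t_chrom) if t_chrom else np.empty(0, int),
        },
    }
    return cat


def simulate_variants(
    genome: GenomeModel,
    profiles: Mapping[str, SpectrumProfile],
    n_variants: int = 1000,
    coverage_range: tuple[int, int] = (30, 300),
    seed: int = 0,
    sequences: Mapping[str, np.ndarray] | None = None,
    out_of_range_rate: float = 0.10,
) -> tuple[list[VariantRecord], dict[str, np.ndarray]]:
    """Draw base substitutions from per-sample spectrum profiles.

    Substitution classes are drawn from each profile's marginal class
    probabilities (so observed class fractions follow the profile
    exactly, up to multinomial noise).  Sites are then drawn among
    reference positions whose base matches the class; for C-class
    variants, CpG sites receive extra weight ``cpg_transversion_mult``
    when the class is a transversion, and TpC sites extra weight
    ``tpc_mult``, realising the configured context odds ratios.  A fixed
    ``out_of_range_rate`` of records get read depths outside
    ``coverage_range`` (half below, half above) so the coverage filter
    is exercised.  Records on purine reference bases are emitted in
    forward-strand (uncollapsed) representation.
    """
    if n_variants < 0:
        raise ValueError("n_variants must be >= 0")
    lo, hi = coverage_range
    if lo > hi:
        raise ValueError("coverage_range min must be <= max")
    rng = np.random.default_rng(seed)
    if sequences is None:
        sequences = random_sequences(genome, seed=int(rng.integers(2**31)))
    cat = _site_catalog(sequences)
    chroms = cat["chroms"]
    # stratify C sites by (cpg, tpc)
    c_strata = {}
    for cpg in (False, True):
        for tpc in (False, True):
            m = (cat["C"]["cpg"] == cpg) & (cat["C"]["tpc"] == tpc)
            c_strata[(cpg, tpc)] = np.nonzero(m)[0]
    records: list[VariantRecord] = []
    for sample_id in profiles:
        prof = profiles[sample_id]
        pvec = prof.prob_vector()
        classes = rng.choice(len(SUBSTITUTION_CLASSES), size=n_variants, p=pvec)
        for k in classes:
            cls = SUBSTITUTION_CLASSES[k]
            pyr_ref, pyr_alt = cls[0], cls[2]
            if pyr_ref == "C":
                is_tv = cls not in TRANSITION_CLASSES
                weights = np.array(
                    [
                        len(c_strata[(cpg, tpc)])
                        * (prof.cpg_transversion_mult if (cpg and is_tv) else 1.0)
                        * (prof.tpc_mult if tpc else 1.0)
                        for cpg in (False, True)
                        for tpc in (False, True)
                    ],
                    float,
                )
                keys = [(cpg, tpc) for cpg in (False, True) for tpc in (False, True)]
                if weights.sum() == 0:
                    raise ValueError("no candidate C sites in sequences")
                stratum = keys[rng.choice(4, p=weights / weights.sum())]
                sites = c_strata[stratum]
                j = sites[rng.integers(len(sites))]
                ci = cat["C"]["chrom"][j]
                pos = int(cat["C"]["pos"][j])
            else:
                sites = cat["T"]["pos"]
                if len(sites) == 0:
                    raise ValueError("no candidate T sites in sequences")
                j = rng.integers(len(sites))
                ci = cat["T"]["chrom"][j]
                pos = int(cat["T"]["pos"][j])
            chrom = chroms[ci]
            seq = sequences[chrom]
            base = int(seq[pos])
            pyr_code = {"C": _C, "T": _T}[pyr_ref]
            if base == pyr_code:  # forward strand carries the pyrimidine
                ref, alt = pyr_ref, pyr_alt
            else:  # purine strand: emit the complement representation
                ref = "ACGT"[_COMP[pyr_code]]
                alt = "ACGT"[_COMP["ACGT".index(pyr_alt)]]
            # depth: mostly in range, a fixed share outside
            u = rng.uniform()
            if u < out_of_range_rate / 2 and lo > 0:
                depth = int(rng.integers(0, lo))
            elif u < out_of_range_rate:
                depth = int(rng.integers(hi + 1, 2 * hi + 2))
            else:
                depth = int(rng.integers(lo, hi + 1))
            records.append(
                VariantRecord(
                    sample_id=sample_id,
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    depth=depth,
                    five_prime="ACGT"[int(seq[pos - 1])],
                    three_prime="ACGT"[int(seq[pos + 1])],
                )
            )
    return records, dict(sequences)


@dataclass
class SyntenyScenario:
    """A human-amplicon-split-into-two-dog-regions scenario with truth."""

    blocks: list[SyntenyBlock]
    human_genes: pd.DataFrame  # index gene_id; chrom, start, end, status (+1)
    dog_genes: list[Gene]
    truth: CnaTruth
    driver_ids: list[str]
    dog_chrom_sizes: dict[str, int]
    human_chrom: str
    n_region_a: int
    n_region_b: int


def make_synteny_scenario(
    human_region_len: int = 48_000_000,
    n_genes: int = 398,
    driver_fraction: float = 125 / 210,
    seed: int = 0,
    gene_length: int = 20_000,
    region_a_gene_share: float = 210 / 398,
    amp_log2: float = 1.0,
    sample_id: str = "dog_tumor",
) -> SyntenyScenario:
    """One "human" amplified region split across two "dog" chromosomes.

    All ``n_genes`` human genes are flagged amplified (the scenario
    mirrors a recurrently amplified human arm).  The human region is
    split so that ``region_a_gene_share`` of its genes land in dog
    region A (one dog chromosome, '+' orientation) and the rest in dog
    region B (a second dog chromosome, '-' orientation).  A
    ``driver_fraction`` of region-A genes are designated drivers and
    covered by implanted amplification segments in the dog truth; region
    B carries no implanted changes.
    """
    if not 0 <= driver_fraction <= 1:
        raise ValueError("driver_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    L = int(human_region_len)
    if n_genes * gene_length > L:
        raise ValueError("impossible packing: too many genes for region length")
    free = L - n_genes * gene_length
    offsets = np.sort(rng.uniform(0, free, size=n_genes))
    starts = (offsets + np.arange(n_genes) * gene_length).astype(np.int64)
    human_chrom = "hsa8q"
    ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    n_a = int(round(region_a_gene_share * n_genes))
    n_a = min(max(n_a, 0), n_genes)
    # split coordinate between the last region-A gene and the first region-B gene
    if 0 < n_a < n_genes:
        split = int((starts[n_a - 1] + gene_length + starts[n_a]) // 2)
    elif n_a == n_genes:
        split = L - 1  # keep a non-empty region B block
    else:
        split = 1
    blocks = [
        SyntenyBlock(human_chrom, 0, split, "chr13", 0, split, "+"),
        SyntenyBlock(human_chrom, split, L, "chr29", 0, L - split, "-"),
    ]
    human_genes = pd.DataFrame(
        {
            "chrom": human_chrom,
            "start": starts,
            "end": starts + gene_length,
            "status": 1,
        },
        index=pd.Index(ids, name="gene_id"),
    )
    dog_genes: list[Gene] = []
    for gid, s in zip(ids, starts):
        e = int(s) + gene_length
        if e <= split:
            dog_genes.append(Gene(gid, "chr13", int(s), e))
        else:
            # '-' orientation: human offset x maps to dog (block_len - 1 - x)...
            # as intervals: [s,e) within [split,L) -> [(L - e), (L - s))
            dog_genes.append(Gene(gid, "chr29", L - e, L - int(s)))
    a_ids = ids[:n_a]
    n_drivers = int(round(driver_fraction * n_a))
    driver_ids = sorted(rng.choice(a_ids, size=n_drivers, replace=False)) if n_drivers else []
    driver_set = set(driver_ids)
    pad = 1_000
    intervals = sorted(
        (g.start - pad, g.end + pad) for g in dog_genes if g.id in driver_set
    )
    merged: list[list[int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([max(s, 0), e])
    segments = [
        TruthSegment("chr13", s, min(e, split), amp_log2, "amp") for s, e in merged
    ]
    return SyntenyScenario(
        blocks=blocks,
        human_genes=human_genes,
        dog_genes=dog_genes,
        truth=CnaTruth(sample_id, segments),
        driver_ids=list(driver_ids),
        dog_chrom_sizes={"chr13": split, "chr29": L - split},
        human_chrom=human_chrom,
        n_region_a=n_a,
        n_region_b=n_genes - n_a,
    )


def scenario_genome(
    scenario: SyntenyScenario,
    probe_spacing: float = 5_500.0,
    seed: int = 0,
    jitter: float = 0.4,
) -> GenomeModel:
    """A dog GenomeModel (probe grid + genes) for a synteny scenario."""
    rng = np.random.default_rng(seed)
    chromosomes = [(c, n) for c, n in scenario.dog_chrom_sizes.items()]
    probes = {}
    for chrom, length in chromosomes:
        m = int(length / (probe_spacing * (1 - jitter))) + 2
        gaps = rng.uniform(1 - jitter, 1 + jitter, size=m) * probe_spacing
        pos = np.cumsum(gaps).astype(np.int64)
        pos = pos[pos < length]
        probes[chrom] = pos[np.concatenate(([True], np.diff(pos) > 0))]
    return GenomeModel(chromosomes, float(probe_spacing), probes, list(scenario.dog_genes))
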