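"""Cross-species driver/passenger discrimination on a recurrent amplicon.

A recurrently amplified region in one genome ("human") is projected
through a synteny block map into the other genome ("dog").  Because
interspecies rearrangements break the region into multiple dog regions,
the dog recurrence status of the projected genes can differ between
regions: if one projected region is recurrently amplified in dog tumors
while another is copy-neutral, the amplified region's genes are driver
candidates (DCGs) and the neutral region's genes passenger candidates
(PCGs).  The tally difference is assessed with a two-sided Fisher's
exact test.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import DriverPassengerResult, Gene, GeneCnaMatrix, SyntenyBlock, norm_chrom


@dataclass(frozen=True)
class ProjectedRegion:
    chrom: str
    start: int
    end: int
    orientation: str
    source_start: int  # interval in the query genome this piece maps
    source_end: int


def project_region(
    region: tuple[str, int, int],
    blocks: Sequence[SyntenyBlock],
    direction: str = "human_to_dog",
) -> tuple[list[ProjectedRegion], list[tuple[int, int]]]:
    """Piecewise-linear projection of a region through a synteny map.

    Returns (projected pieces, unmapped gaps in the query interval).
    For '-' blocks within-block offsets are reversed, so the query start
    maps to the target end.  The projection is invertible on mapped
    bases; call with ``direction='dog_to_human'`` to go back.
    """
    chrom, start, end = region
    if end <= start:
        raise ValueError("empty region")
    if direction not in ("human_to_dog", "dog_to_human"):
        raise ValueError(f"bad direction {direction!r}")
    pieces: list[ProjectedRegion] = []
    covered: list[tuple[int, int]] = []
    for b in blocks:
        if direction == "human_to_dog":
            src = (b.human_chrom, b.human_start, b.human_end)
            dst = (b.dog_chrom, b.dog_start, b.dog_end)
        else:
            src = (b.dog_chrom, b.dog_start, b.dog_end)
            dst = (b.human_chrom, b.human_start, b.human_end)
        if norm_chrom(src[0]) != norm_chrom(chrom):
            continue
        lo = max(start, src[1])
        hi = min(end, src[2])
        if hi <= lo:
            continue
        off_lo, off_hi = lo - src[1], hi - src[1]
        block_len = src[2] - src[1]
        if b.orientation == "+":
            t_lo = dst[1] + off_lo
            t_hi = dst[1] + off_hi
        else:
            t_lo = dst[1] + (block_len - off_hi)
            t_hi = dst[1] + (block_len - off_lo)
        pieces.append(ProjectedRegion(dst[0], t_lo, t_hi, b.orientation, lo, hi))
        covered.append((lo, hi))
    covered.sort()
    gaps: list[tuple[int, int]] = []
    cursor = start
    for lo, hi in covered:
        if lo > cursor:
            gaps.append((cursor, lo))
        cursor = max(cursor, hi)
    if cursor < end:
        gaps.append((cursor, end))
    if not pieces:
        warnings.warn(f"region {chrom}:{start}-{end} is entirely unmapped", stacklevel=2)
    return pieces, gaps


def _region_of(gene_chrom: str, midpoint: int, regions: Sequence[ProjectedRegion]) -> int | None:
    hits = [
        i
        for i, r in enumerate(regions)
        if norm_chrom(r.chrom) == norm_chrom(gene_chrom) and r.start <= midpoint < r.end
    ]
    if len(hits) > 1:
        raise ValueError("gene midpoint falls in more than one projected region")
    return hits[0] if hits else None


def discriminate(
    human_genes: pd.DataFrame,
    dog_gene_cna: GeneCnaMatrix,
    regions: Sequence[ProjectedRegion],
    recurrence_fdr: float = 0.2,
    alpha: float = 0.05,
) -> DriverPassengerResult:
    """Partition a projected amplicon's genes into DCGs and PCGs.

    ``human_genes`` must list the amplicon's genes, all flagged amplified
    (column ``status`` == 1): the method addresses regions that are
    recurrently amplified in the first species.  Dog genes (rows of
    ``dog_gene_cna`` sharing ids with ``human_genes``) are assigned to
    exactly one projected region by midpoint, and classified amplified
    (``q_amp <= recurrence_fdr``), deleted (``q_del <= recurrence_fdr``,
    excluded from both candidate sets) or unchanged.  With two regions a
    single two-sided Fisher's exact test on the amplified/unchanged 2x2
    decides discrimination; with more, one-vs-rest tests are BH-corrected.
    """
    if "status" not in human_genes.columns or not (human_genes["status"] == 1).all():
        raise ValueError("every human gene in the region must be flagged amplified (status 1)")
    if len(regions) < 2:
        raise ValueError(
            "discrimination needs at least 2 projected regions: the method relies on "
            "a synteny break separating the amplicon's genes"
        )
    shared = human_genes.index.intersection(dog_gene_cna.gene_ids)
    if len(shared) == 0:
        raise ValueError("no shared gene ids between human table and dog matrix")
    q_amp = dog_gene_cna.q_amp
    q_del = dog_gene_cna.q_del
    meta = dog_gene_cna.genes
    names = [f"{r.chrom}:{r.start}-{r.end}" for r in regions]
    assign: dict[str, int] = {}
    state: dict[str, str] = {}
    for g in shared:
        mid = (int(meta.loc[g, "start"]) + int(meta.loc[g, "end"])) // 2
        ri = _region_of(str(meta.loc[g, "chrom"]), mid, regions)
        if ri is None:
            continue
        assign[g] = ri
        if not np.isnan(q_amp.loc[g]) and q_amp.loc[g] <= recurrence_fdr:
            state[g] = "amplified"
        elif not np.isnan(q_del.loc[g]) and q_del.loc[g] <= recurrence_fdr:
            state[g] = "deleted"
        else:
            state[g] = "unchanged"
    counts = pd.DataFrame(
        0, index=names, columns=["n_amplified", "n_unchanged", "n_deleted"]
    )
    for g, ri in assign.items():
        counts.loc[names[ri], f"n_{state[g]}"] += 1
    amp = counts["n_amplified"].to_numpy()
    unch = counts["n_unchanged"].to_numpy()
    if len(regions) == 2:
        table = np.array([[amp[0], unch[0]], [amp[1], unch[1]]], dtype=int)
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        region_p = np.array([p, p])
    else:
        pvals = []
        for i in range(len(regions)):
            t = np.array(
                [[amp[i], unch[i]], [amp.sum() - amp[i], unch.sum() - unch[i]]], int
            )
            pvals.append(stats.fisher_exact(t, alternative="two-sided")[1])
        _, region_p, _, _ = multipletests(pvals, method="fdr_bh")
        i_best = int(np.argmax(np.divide(amp, np.maximum(amp + unch, 1))))
        table = np.array(
            [[amp[i_best], unch[i_best]],
             [amp.sum() - amp[i_best], unch.sum() - unch[i_best]]],
            int,
        )
        odds, p = stats.fisher_exact(table, alternative="two-sided")
    frac = np.divide(amp, np.maximum(amp + unch, 1), dtype=float)
    significant = (np.asarray(region_p) <= alpha) if len(regions) > 2 else (p <= alpha)
    if (len(regions) == 2 and p <= alpha) or (len(regions) > 2 and np.any(significant)):
        if len(regions) == 2:
            amp_regions = {int(np.argmax(frac))}
        else:
            amp_regions = {
                i for i in range(len(regions)) if region_p[i] <= alpha and frac[i] > frac.mean()
            }
        dcg = sorted(
            g for g, ri in assign.items() if ri in amp_regions and state[g] == "amplified"
        )
        pcg = sorted(
            g for g, ri in assign.items() if ri not in amp_regions and state[g] == "unchanged"
        )
        status = "discriminated"
    else:
        dcg, pcg = [], []
        status = "no_discrimination"
    deleted = sorted(g for g in assign if state[g] == "deleted")
    return DriverPassengerResult(
        region_counts=counts,
        table=table,
        odds_ratio=float(odds),
        p_value=float(p),
        dcg=dcg,
        pcg=pcg,
        deleted=deleted,
        status=status,
    )


def validate_mutation_enrichment(
    dcg: Sequence[str], pcg: Sequence[str], mutated: set[str] | Sequence[str]
) -> tuple[np.ndarray, float, float]:
    """Fisher test of mutation prevalence among DCGs vs PCGs.

    Returns (2x2 table [(mutated, not) x (DCG, PCG)], odds ratio, p).
    """
    dcg, pcg = set(dcg), set(pcg)
    if dcg & pcg:
        raise ValueError("DCG and PCG sets must be disjoint")
    mutated = set(mutated)
    table = np.array(
        [
            [len(dcg & mutated), len(dcg - mutated)],
            [len(pcg & mutated), len(pcg - mutated)],
        ],
        dtype=int,
    )
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(odds), float(p)


def validate_concordance(
    dcg_features: np.ndarray, pcg_features: np.ndarray
):
    """Hotelling T-squared comparison of (copy, expression) gene features."""
    from .expression import hotelling_concordance

    return hotelling_concordance(dcg_features, pcg_features)
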