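"""Gene-level copy-number status and recurrence scoring.

A gene takes the call of the segment containing its midpoint (nearest
segment if the midpoint falls in a probe gap).  Recurrence across
samples is scored with a permutation analog of a G-score: per-gene
amplification score = sum over samples of max(0, amplitude), with a null
built from within-sample cyclic shifts of the gene-level amplitude
vectors along the genomic gene order.  The shift null preserves each
sample's total CNA burden and the spatial correlation of amplitudes
exactly, so it measures recurrence above sample-specific background.
"""
from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .model import Gene, GeneCnaMatrix, SegmentCall, norm_chrom


def assign_gene_status(
    calls: Sequence[SegmentCall],
    genes: Sequence[Gene],
    exclude_chroms: set[str] | frozenset[str] = frozenset(),
) -> GeneCnaMatrix:
    """Map segment calls onto genes by the midpoint rule, per sample."""
    excl = {norm_chrom(c) for c in exclude_chroms}
    samples = sorted({c.sample_id for c in calls})
    by_sample_chrom: dict[tuple[str, str], list[SegmentCall]] = {}
    call_chroms: set[str] = set()
    for c in calls:
        by_sample_chrom.setdefault((c.sample_id, norm_chrom(c.chrom)), []).append(c)
        call_chroms.add(norm_chrom(c.chrom))
    order = sorted(range(len(genes)), key=lambda i: (genes[i].chrom, genes[i].start))
    genes = [genes[i] for i in order]
    gene_ids = [g.id for g in genes]
    status = pd.DataFrame(0, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    amplitude = pd.DataFrame(0.0, index=status.index, columns=samples)
    excluded = pd.Series(False, index=status.index)
    for g in genes:
        gchrom = norm_chrom(g.chrom)
        if gchrom in excl:
            excluded.loc[g.id] = True
            continue
        if gchrom not in call_chroms:
            raise ValueError(f"gene {g.id}: no segments on chromosome {g.chrom}")
        mid = g.midpoint
        for s in samples:
            segs = by_sample_chrom.get((s, gchrom))
            if not segs:
                raise ValueError(f"gene {g.id}: sample {s} has no segments on {g.chrom}")
            seg = _segment_for_point(segs, mid)
            amplitude.loc[g.id, s] = seg.mean_log2
            status.loc[g.id, s] = {"amp": 1, "del": -1, "neutral": 0}[seg.call]
    meta = pd.DataFrame(
        {"chrom": [g.chrom for g in genes],
         "start": [g.start for g in genes],
         "end": [g.end for g in genes]},
        index=status.index,
    )
    return GeneCnaMatrix(status, amplitude, meta, excluded)


def _segment_for_point(segs: list[SegmentCall], point: int) -> SegmentCall:
    """Containing segment, else the nearer flanking segment (probe gaps)."""
    segs = sorted(segs, key=lambda s: s.start)
    best = None
    best_dist = None
    for seg in segs:
        if seg.start <= point < seg.end:
            return seg
        dist = seg.start - point if point < seg.start else point - (seg.end - 1)
        if best_dist is None or dist < best_dist:
            best, best_dist = seg, dist
    assert best is not None
    return best


def recurrence_test(
    matrix: GeneCnaMatrix,
    n_perm: int = 1000,
    fdr: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation recurrence q-values for amplification and deletion.

    The observed per-gene score is compared against the pooled null of
    per-gene scores from ``n_perm`` rounds of independent per-sample
    cyclic shifts.  Empirical p-values use the add-one estimator;
    Benjamini-Hochberg is applied separately to the amp and del arms.
    Fills ``matrix.q_amp`` / ``matrix.q_del`` and returns a summary
    frame (score_amp, q_amp, score_del, q_del).
    """
    if matrix.status.shape[1] < 2:
        raise ValueError("recurrence_test needs at least 2 samples")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if n_perm < 10 / max(fdr, 1e-9):
        warnings.warn(
            f"n_perm={n_perm} gives coarse p-value resolution for fdr={fdr}",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    keep = ~matrix.excluded.values
    amp = np.asarray(matrix.amplitude.values[keep], float)  # genes x samples, genomic order
    n_genes, n_samples = amp.shape
    # deterministic function of the (unordered) sample set: sort columns by id
    col_order = np.argsort(matrix.amplitude.columns.values.astype(str))
    amp = amp[:, col_order]
    obs_amp = np.maximum(amp, 0.0).sum(axis=1)
    obs_del = np.maximum(-amp, 0.0).sum(axis=1)
    null_ge_amp = np.zeros(n_genes, dtype=np.int64)
    null_ge_del = np.zeros(n_genes, dtype=np.int64)
    pos = np.maximum(amp, 0.0)
    neg = np.maximum(-amp, 0.0)
    for _ in range(n_perm):
        shifts = rng.integers(0, n_genes, size=n_samples)
        perm_amp = np.zeros(n_genes)
        perm_del = np.zeros(n_genes)
        for s in range(n_samples):
            perm_amp += np.roll(pos[:, s], shifts[s])
            perm_del += np.roll(neg[:, s], shifts[s])
        # pooled null: compare every observed score against all permuted scores
        perm_amp.sort()
        perm_del.sort()
        null_ge_amp += n_genes - np.searchsorted(perm_amp, obs_amp, side="left")
        null_ge_del += n_genes - np.searchsorted(perm_del, obs_del, side="left")
    total = n_perm * n_genes
    p_amp = (1.0 + null_ge_amp) / (1.0 + total)
    p_del = (1.0 + null_ge_del) / (1.0 + total)
    _, q_amp, _, _ = multipletests(p_amp, method="fdr_bh")
    _, q_del, _, _ = multipletests(p_del, method="fdr_bh")
    idx = matrix.gene_ids[keep]
    matrix.q_amp.loc[:] = np.nan
    matrix.q_del.loc[:] = np.nan
    matrix.q_amp.loc[idx] = q_amp
    matrix.q_del.loc[idx] = q_del
    return pd.DataFrame(
        {"score_amp": obs_amp, "p_amp": p_amp, "q_amp": q_amp,
         "score_del": obs_del, "p_del": p_del, "q_del": q_del},
        index=idx,
    )


def gene_cna_to_frame(matrix: GeneCnaMatrix) -> pd.DataFrame:
    """Flat per-gene table (status/amplitude per sample plus q-values)."""
    out = matrix.genes.copy()
    out["excluded"] = matrix.excluded
    for s in matrix.sample_ids:
        out[f"status_{s}"] = matrix.status[s]
        out[f"amplitude_{s}"] = matrix.amplitude[s]
    out["q_amp"] = matrix.q_amp
    out["q_del"] = matrix.q_del
    return out
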