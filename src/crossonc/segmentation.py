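"""Copy-number segmentation and FDR-controlled CNA calling.

Per chromosome, change-points are placed by exact dynamic programming
minimising the Gaussian residual sum of squares over all placements of
``k`` change-points (O(k n^2)); the number of change-points is chosen by
a modified-BIC rule, penalising each change-point by ``2 * sigma^2 * log n``
with ``sigma`` estimated robustly from the median absolute first
difference of the probe ratios.  Calling then applies, genome-wide, a
one-sample t-test of each segment's probe ratios against zero,
Benjamini-Hochberg control of the false discovery rate, a minimum probe
count, and an absolute segment-mean cutoff.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import ProbeProfile, SegmentCall, norm_chrom

#: Default calling parameters.
DEFAULT_FDR = 0.01
DEFAULT_MIN_PROBES = 3
DEFAULT_MEAN_CUTOFF = 0.4
DEFAULT_EXCLUDE_CHROMS = frozenset({"X"})


def robust_noise_sd(x: np.ndarray) -> float:
    """Noise SD estimate from the median absolute first difference.

    For i.i.d. Gaussian noise, successive differences have SD
    ``sigma * sqrt(2)``; the median absolute value of a centred Gaussian
    is ``0.6745 * SD``.  Change-points only affect a handful of
    differences, so the median is insensitive to them.
    """
    x = np.asarray(x, float)
    if len(x) < 2:
        return 0.0
    mad = float(np.median(np.abs(np.diff(x))))
    return mad / (0.6744897501960817 * math.sqrt(2.0))


def _segment_cost_matrix(x: np.ndarray) -> np.ndarray:
    """C[i, j] = RSS of probes i..j-1 around their own mean (i < j), else +inf."""
    n = len(x)
    s1 = np.concatenate(([0.0], np.cumsum(x)))
    s2 = np.concatenate(([0.0], np.cumsum(x * x)))
    i = np.arange(n + 1)
    li = i[:, None]
    lj = i[None, :]
    length = (lj - li).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cost = (s2[None, :] - s2[:, None]) - (s1[None, :] - s1[:, None]) ** 2 / length
    cost[length <= 0] = np.inf
    # guard tiny negative round-off
    np.clip(cost, 0.0, None, out=cost)
    cost[length <= 0] = np.inf
    return cost


def optimal_breakpoints(x: np.ndarray, k: int) -> tuple[list[int], float]:
    """Exact DP: the RSS-minimising placement of exactly ``k`` change-points.

    Returns (breakpoint indices, RSS).  A breakpoint at index ``b`` splits
    probes into ``[..b)`` and ``[b..)``.  Ties resolve to the leftmost
    placement for determinism.
    """
    x = np.asarray(x, float)
    n = len(x)
    if n < 1:
        raise ValueError("empty profile")
    if k < 0 or k >= n:
        raise ValueError(f"k={k} must satisfy 0 <= k < n={n}")
    cost = _segment_cost_matrix(x)
    bps, rss = _dp_all_k(cost, n, k)
    return bps[k], rss[k]


def _dp_all_k(cost: np.ndarray, n: int, max_k: int) -> tuple[list[list[int]], np.ndarray]:
    """DP over all k in 0..max_k.  Returns per-k breakpoints and RSS."""
    # D[k][j] = min RSS of covering probes [0, j) with k change-points,
    # i.e. k+1 segments.  back[k][j] = argmin split point.
    D = np.full((max_k + 1, n + 1), np.inf)
    D[0] = cost[0]
    D[0, 0] = 0.0
    back = np.zeros((max_k + 1, n + 1), dtype=np.int64)
    for k in range(1, max_k + 1):
        # candidate split i: last segment [i, j); i ranges over 0..n
        tot = D[k - 1][:, None] + cost  # (n+1, n+1): tot[i, j]
        # leftmost argmin for deterministic ties
        back[k] = np.argmin(tot, axis=0)
        D[k] = tot[back[k], np.arange(n + 1)]
    rss = D[:, n].copy()
    breakpoints: list[list[int]] = []
    for k in range(max_k + 1):
        bps = []
        j = n
        for kk in range(k, 0, -1):
            j = int(back[kk, j])
            bps.append(j)
        breakpoints.append(sorted(bps))
    return breakpoints, rss


def segment_chromosome(
    profile: ProbeProfile,
    max_k: int | None = None,
    penalty_per_changepoint: float | None = None,
) -> list[int]:
    """Segment one chromosome; returns the chosen breakpoint index list.

    For each candidate ``k <= max_k`` the exact RSS-optimal placement is
    computed; the returned ``k`` minimises ``RSS(k) + penalty * k``.
    Ties (equal total cost) resolve to the smallest ``k`` and then the
    leftmost placement.
    """
    x = np.asarray(profile.log2ratio, float)
    n = len(x)
    if n < 1:
        raise ValueError("empty profile")
    if max_k is None:
        # enough budget for many focal events on a dense chromosome
        max_k = min(n - 1, max(20, -(-n // 20)))
    if max_k >= n:
        raise ValueError(f"max_k={max_k} must be < probe count {n}")
    if penalty_per_changepoint is None:
        sigma = robust_noise_sd(x)
        penalty_per_changepoint = 2.0 * sigma**2 * math.log(max(n, 2))
    cost = _segment_cost_matrix(x)
    bps, rss = _dp_all_k(cost, n, max_k)
    total = rss[: max_k + 1] + penalty_per_changepoint * np.arange(max_k + 1)
    # smallest k achieving the minimum (within float slack) wins
    best = float(np.min(total))
    k_star = int(np.nonzero(total <= best + 1e-10)[0][0])
    return bps[k_star]


def segments_from_breakpoints(profile: ProbeProfile, breakpoints: list[int]) -> list[SegmentCall]:
    """Materialise SegmentCalls (no p/q yet) from probe-index breakpoints."""
    n = len(profile)
    bounds = [0] + sorted(breakpoints) + [n]
    out = []
    for a, b in zip(bounds, bounds[1:]):
        if b <= a:
            continue
        out.append(
            SegmentCall(
                sample_id=profile.sample_id,
                chrom=profile.chrom,
                start=int(profile.positions[a]),
                end=int(profile.positions[b - 1]) + 1,
                probe_count=b - a,
                mean_log2=float(np.mean(profile.log2ratio[a:b])),
            )
        )
    return out


@dataclass
class _SegWithProbes:
    call: SegmentCall
    values: np.ndarray


def segment_genome(
    profiles: list[ProbeProfile],
    max_k: int | None = None,
    penalty_per_changepoint: float | None = None,
) -> list[tuple[SegmentCall, np.ndarray]]:
    """Segment every chromosome profile; returns (segment, probe values) pairs."""
    out: list[tuple[SegmentCall, np.ndarray]] = []
    for prof in profiles:
        bps = segment_chromosome(prof, max_k=max_k, penalty_per_changepoint=penalty_per_changepoint)
        bounds = [0] + list(bps) + [len(prof)]
        for seg, (a, b) in zip(
            segments_from_breakpoints(prof, list(bps)), zip(bounds, bounds[1:])
        ):
            out.append((seg, prof.log2ratio[a:b]))
    return out


def call_cnas(
    segments: list[tuple[SegmentCall, np.ndarray]],
    fdr: float = DEFAULT_FDR,
    min_probes: int = DEFAULT_MIN_PROBES,
    mean_cutoff: float = DEFAULT_MEAN_CUTOFF,
    exclude_chroms: frozenset[str] | set[str] = DEFAULT_EXCLUDE_CHROMS,
) -> list[SegmentCall]:
    """Genome-wide CNA calling over pre-computed segments.

    Each segment's probe ratios are tested against zero with a one-sample
    t-test; Benjamini-Hochberg across all testable segments yields q.  A
    segment is called amplified when ``q <= fdr``, ``probe_count >=
    min_probes`` and ``mean_log2 >= mean_cutoff`` (mirrored for
    deletions).  Chromosomes in ``exclude_chroms`` (compared after
    stripping a ``chr`` prefix) receive no calls and no test.
    """
    excl = {norm_chrom(c) for c in exclude_chroms}
    if not segments:
        return []
    kept: list[tuple[SegmentCall, np.ndarray]] = []
    out: list[SegmentCall] = []
    for seg, vals in segments:
        if norm_chrom(seg.chrom) in excl:
            out.append(seg)  # stays neutral, untested
            continue
        kept.append((seg, vals))
    if kept:
        pvals = np.ones(len(kept))
        for idx, (seg, vals) in enumerate(kept):
            if len(vals) >= 2 and np.std(vals) > 0:
                pvals[idx] = stats.ttest_1samp(vals, 0.0).pvalue
            else:
                # single probe or zero variance: no valid t-test
                pvals[idx] = 0.0 if (len(vals) >= 2 and abs(np.mean(vals)) > 0) else 1.0
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for (seg, vals), p, q in zip(kept, pvals, qvals):
            seg.p_value = float(p)
            seg.q_value = float(q)
            if q <= fdr and seg.probe_count >= min_probes:
                if seg.mean_log2 >= mean_cutoff:
                    seg.call = "amp"
                elif seg.mean_log2 <= -mean_cutoff:
                    seg.call = "del"
            out.append(seg)
    return out


def genome_cna_summary(calls: list[SegmentCall]) -> pd.DataFrame:
    """Per-sample amplified/deleted totals and segment-size summaries."""
    rows: dict[str, dict[str, float]] = {}
    for seg in calls:
        r = rows.setdefault(
            seg.sample_id,
            {"amplified_bp": 0, "deleted_bp": 0, "n_amp": 0, "n_del": 0,
             "mean_amp_size": 0.0, "mean_del_size": 0.0},
        )
        size = seg.end - seg.start
        if seg.call == "amp":
            r["amplified_bp"] += size
            r["n_amp"] += 1
        elif seg.call == "del":
            r["deleted_bp"] += size
            r["n_del"] += 1
    for r in rows.values():
        r["mean_amp_size"] = r["amplified_bp"] / r["n_amp"] if r["n_amp"] else 0.0
        r["mean_del_size"] = r["deleted_bp"] / r["n_del"] if r["n_del"] else 0.0
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df
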