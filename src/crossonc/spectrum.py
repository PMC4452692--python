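"""Substitution-spectrum analysis: coverage filtering, strand-collapsed
class fractions, CpG/TpC context, virus-status group comparison, and
coding-consequence classification.

The twelve ordered base substitutions collapse onto six classes by
reverse-complementing purine-reference pairs onto the pyrimidine strand
(e.g. G>A becomes C>T).  Transitions are C>T and T>C; the other four
classes are transversions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .model import SUBSTITUTION_CLASSES, TRANSITION_CLASSES, VariantRecord

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def filter_by_coverage(
    records: Iterable[VariantRecord], min_depth: int = 30, max_depth: int = 300
) -> list[VariantRecord]:
    """Keep records with min_depth <= depth <= max_depth (both inclusive)."""
    return [r for r in records if min_depth <= r.depth <= max_depth]


def collapse_class(ref: str, alt: str) -> tuple[str, bool]:
    """Strand-collapsed substitution class and its transition flag."""
    if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    cls = f"{ref}>{alt}"
    return cls, cls in TRANSITION_CLASSES


def annotate_context(record: VariantRecord) -> dict[str, bool | None]:
    """CpG / TpC flags for one record; None when a needed flank is N.

    CpG: the mutated base is a C with 3' G, or a G with 5' C (the same
    dinucleotide read from the other strand).  TpC: after collapsing to
    the pyrimidine strand, the mutated C has a 5' T.
    """
    if record.ref in "CT":
        five, three = record.five_prime, record.three_prime
    else:  # collapse: complement and swap the flanks
        five, three = _COMPLEMENT[record.three_prime], _COMPLEMENT[record.five_prime]
    pyr_ref = record.ref if record.ref in "CT" else _COMPLEMENT[record.ref]
    is_cpg: bool | None
    is_tpc: bool | None
    if pyr_ref == "C":
        is_cpg = None if three == "N" else three == "G"
        is_tpc = None if five == "N" else five == "T"
    else:
        is_cpg = False
        is_tpc = False
    return {"is_CpG": is_cpg, "is_TpC": is_tpc}


@dataclass
class SpectrumSummary:
    """Per-sample substitution class counts and derived fractions."""

    counts: pd.DataFrame  # samples x 6 classes
    fractions: pd.DataFrame  # samples x 6 classes (NaN for empty samples)
    transition_fraction: pd.Series
    transversion_fraction: pd.Series
    cpg_counts: pd.DataFrame
    cpg_fractions: pd.DataFrame
    cpg_transversion_fraction: pd.Series
    tpc_fraction: pd.Series  # fraction of C-class mutations in TpC context


def spectrum(records: Sequence[VariantRecord]) -> SpectrumSummary:
    """Summarise class counts/fractions per sample, with CpG-restricted views."""
    samples = sorted({r.sample_id for r in records})
    zero = pd.DataFrame(0, index=pd.Index(samples, name="sample_id"),
                        columns=list(SUBSTITUTION_CLASSES))
    counts = zero.copy()
    cpg_counts = zero.copy()
    tpc_hits = pd.Series(0, index=zero.index)
    c_class_known_tpc = pd.Series(0, index=zero.index)
    for r in records:
        cls, _ = collapse_class(r.ref, r.alt)
        counts.loc[r.sample_id, cls] += 1
        ctx = annotate_context(r)
        if ctx["is_CpG"]:
            cpg_counts.loc[r.sample_id, cls] += 1
        if cls.startswith("C") and ctx["is_TpC"] is not None:
            c_class_known_tpc.loc[r.sample_id] += 1
            if ctx["is_TpC"]:
                tpc_hits.loc[r.sample_id] += 1
    def _fractions(c: pd.DataFrame) -> pd.DataFrame:
        tot = c.sum(axis=1)
        with np.errstate(invalid="ignore"):
            f = c.div(tot.replace(0, np.nan), axis=0)
        return f
    fractions = _fractions(counts)
    cpg_fractions = _fractions(cpg_counts)
    ti_cols = sorted(TRANSITION_CLASSES)
    tv_cols = [c for c in SUBSTITUTION_CLASSES if c not in TRANSITION_CLASSES]
    transition_fraction = fractions[ti_cols].sum(axis=1, min_count=1)
    transversion_fraction = fractions[tv_cols].sum(axis=1, min_count=1)
    cpg_tv = cpg_fractions[tv_cols].sum(axis=1, min_count=1)
    tpc_fraction = tpc_hits / c_class_known_tpc.replace(0, np.nan)
    return SpectrumSummary(
        counts=counts,
        fractions=fractions,
        transition_fraction=transition_fraction,
        transversion_fraction=transversion_fraction,
        cpg_counts=cpg_counts,
        cpg_fractions=cpg_fractions,
        cpg_transversion_fraction=cpg_tv,
        tpc_fraction=tpc_fraction,
    )


@dataclass(frozen=True)
class CpgComparison:
    """2x2 CpG-site transversion/transition counts by group, with Fisher stats."""

    table: np.ndarray  # rows: (group_pos, group_neg); cols: (transversion, transition)
    odds_ratio: float
    p_value: float


def compare_cpg_transversions(
    group_pos: Sequence[VariantRecord], group_neg: Sequence[VariantRecord]
) -> CpgComparison:
    """Pooled two-sided Fisher test of transversion prevalence at CpG sites.

    Counts are pooled across samples within each group (per-sample
    fractions are available from :func:`spectrum` for transparency).
    Records whose CpG status is unknown (N flank) are excluded.
    """
    def _tv_ti(records: Sequence[VariantRecord]) -> tuple[int, int]:
        tv = ti = 0
        for r in records:
            if not annotate_context(r)["is_CpG"]:
                continue
            _, is_transition = collapse_class(r.ref, r.alt)
            if is_transition:
                ti += 1
            else:
                tv += 1
        return tv, ti

    table = np.array([_tv_ti(group_pos), _tv_ti(group_neg)], dtype=int)
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        warnings.warn("empty margin in CpG comparison; p set to 1", stacklevel=2)
        return CpgComparison(table=table, odds_ratio=np.nan, p_value=1.0)
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return CpgComparison(table=table, odds_ratio=float(odds), p_value=float(p))


_AA3TO1 = None  # translation handled by Bio.Seq


def classify_coding_effect(
    codon: str,
    pos_in_codon: int,
    ref: str,
    alt: str,
    residue_index: int | None = None,
    strand: str = "+",
) -> tuple[str, str]:
    """Classify a substitution inside a codon and format the change label.

    ``codon`` is given in coding orientation; ``ref``/``alt`` are genomic
    bases — for a '-'-strand codon they are complemented before use.
    Returns (kind, label) with kind in {synonymous, missense, nonsense}
    and a label like ``E233K`` (nonsense uses ``*``).
    """
    codon = codon.upper()
    ref, alt = ref.upper(), alt.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"bad codon {codon!r}")
    if pos_in_codon not in (0, 1, 2):
        raise ValueError("pos_in_codon must be 0, 1, or 2")
    if strand == "-":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    elif strand != "+":
        raise ValueError(f"bad strand {strand!r}")
    if codon[pos_in_codon] != ref:
        raise ValueError(
            f"codon {codon} position {pos_in_codon} is {codon[pos_in_codon]}, not ref {ref}"
        )
    mutated = codon[:pos_in_codon] + alt + codon[pos_in_codon + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    idx = residue_index if residue_index is not None else ""
    label = f"{aa_ref}{idx}{aa_alt}"
    if aa_alt == "*":
        return "nonsense", label
    if aa_alt == aa_ref:
        return "synonymous", label
    return "missense", label
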