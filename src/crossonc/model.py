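"""Core in-memory containers shared across the pipeline.

All genomic intervals are 0-based half-open; conversions to 1-based
conventions (VCF, SEG) happen only in :mod:`crossonc.io`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The six strand-collapsed (pyrimidine-reference) substitution classes.
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Classes that are transitions (purine<->purine / pyrimidine<->pyrimidine).
TRANSITION_CLASSES = frozenset({"C>T", "T>C"})


def norm_chrom(name: str) -> str:
    """Normalise a chromosome name: strip an optional ``chr`` prefix.

    Matching elsewhere is exact string comparison on the normalised name,
    which prevents silent cross-naming between e.g. ``chr13`` and ``13``.
    """
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


@dataclass(frozen=True)
class Gene:
    """A gene interval (0-based half-open) on a named chromosome."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.id}: empty interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: bad strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GenomeModel:
    """A miniature genome: chromosome sizes, probe grid, and gene set.

    ``probes`` maps chromosome name to a strictly increasing array of
    probe positions (bp).  Gene intervals must lie within their chromosome.
    """

    chromosomes: list[tuple[str, int]]
    probe_spacing_bp: float
    probes: dict[str, np.ndarray]
    genes: list[Gene]

    def __post_init__(self) -> None:
        sizes = dict(self.chromosomes)
        for chrom, pos in self.probes.items():
            if chrom not in sizes:
                raise ValueError(f"probes on unknown chromosome {chrom}")
            if len(pos) and not np.all(np.diff(pos) > 0):
                raise ValueError(f"probe positions not strictly increasing on {chrom}")
        for g in self.genes:
            if g.chrom not in sizes:
                raise ValueError(f"gene {g.id} on unknown chromosome {g.chrom}")
            if g.start < 0 or g.end > sizes[g.chrom]:
                raise ValueError(f"gene {g.id} outside chromosome bounds")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def genes_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g.id, g.chrom, g.start, g.end, g.strand) for g in self.genes],
            columns=["gene_id", "chrom", "start", "end", "strand"],
        ).set_index("gene_id")


@dataclass(frozen=True)
class TruthSegment:
    """One implanted copy-number segment with its true log2 amplitude."""

    chrom: str
    start: int
    end: int
    log2: float
    kind: str  # "amp" | "del"

    def __post_init__(self) -> None:
        if self.kind not in ("amp", "del"):
            raise ValueError(f"bad truth kind {self.kind!r}")
        if self.kind == "amp" and self.log2 <= 0:
            raise ValueError("amp segment must have positive amplitude")
        if self.kind == "del" and self.log2 >= 0:
            raise ValueError("del segment must have negative amplitude")
        if self.end <= self.start:
            raise ValueError("empty truth segment")


@dataclass
class CnaTruth:
    """Ground-truth copy-number segments for one simulated sample."""

    sample_id: str
    segments: list[TruthSegment]

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[TruthSegment]] = {}
        for seg in self.segments:
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping truth segments on {chrom}")


@dataclass
class SpectrumProfile:
    """A per-sample substitution spectrum with context modifiers.

    ``class_probs`` are the marginal probabilities of the six
    strand-collapsed substitution classes.  ``cpg_transversion_mult``
    multiplies the odds of a transversion (relative to a transition)
    conditional on the mutated cytosine sitting in a CpG dinucleotide.
    ``tpc_mult`` inflates the propensity of C-class mutations to occur
    with a 5' thymine (TpC, the APOBEC-associated context).
    """

    class_probs: Mapping[str, float]
    cpg_transversion_mult: float = 1.0
    tpc_mult: float = 1.0
    virus_status: str = "negative"

    def __post_init__(self) -> None:
        missing = set(SUBSTITUTION_CLASSES) - set(self.class_probs)
        if missing:
            raise ValueError(f"class_probs missing classes: {sorted(missing)}")
        total = float(sum(self.class_probs[c] for c in SUBSTITUTION_CLASSES))
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ValueError(f"class probabilities sum to {total}, not 1")
        if self.cpg_transversion_mult <= 0 or self.tpc_mult <= 0:
            raise ValueError("context multipliers must be > 0")
        if self.virus_status not in ("positive", "negative"):
            raise ValueError(f"bad virus_status {self.virus_status!r}")

    def prob_vector(self) -> np.ndarray:
        return np.array([self.class_probs[c] for c in SUBSTITUTION_CLASSES], float)


@dataclass
class ProbeProfile:
    """Ordered probes with log2 tumor/normal ratios for one sample on one chromosome."""

    sample_id: str
    chrom: str
    positions: np.ndarray
    log2ratio: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.log2ratio = np.asarray(self.log2ratio, dtype=float)
        if self.positions.shape != self.log2ratio.shape:
            raise ValueError("positions and log2ratio must have equal length")
        if len(self.positions) and not np.all(np.diff(self.positions) > 0):
            raise ValueError(f"probe positions not strictly increasing on {self.chrom}")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class SegmentCall:
    """A contiguous probe run with its summary statistics and CNA call.

    bp extent is [first probe position, last probe position + 1).
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    probe_count: int
    mean_log2: float
    p_value: float = float("nan")
    q_value: float = float("nan")
    call: str = "neutral"  # "amp" | "del" | "neutral"

    def __post_init__(self) -> None:
        if self.probe_count < 1:
            raise ValueError("segment must contain at least one probe")
        if self.call not in ("amp", "del", "neutral"):
            raise ValueError(f"bad call {self.call!r}")


@dataclass(frozen=True)
class VariantRecord:
    """One base substitution with read depth and flanking reference bases."""

    sample_id: str
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    depth: int
    five_prime: str = "N"
    three_prime: str = "N"
    codon: str | None = None
    pos_in_codon: int | None = None
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.ref not in "ACGT" or self.alt not in "ACGT":
            raise ValueError(f"ref/alt must be single bases, got {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError("ref == alt is not a substitution")
        if self.depth < 0:
            raise ValueError("negative depth")
        for b in (self.five_prime, self.three_prime):
            if b not in "ACGTN":
                raise ValueError(f"bad flanking base {b!r}")


@dataclass(frozen=True)
class SyntenyBlock:
    """A length-preserving aligned interval pair between two genomes.

    Orientation '-' means the start of the human interval aligns to the
    end of the dog interval.
    """

    human_chrom: str
    human_start: int
    human_end: int
    dog_chrom: str
    dog_start: int
    dog_end: int
    orientation: str = "+"

    def __post_init__(self) -> None:
        if self.human_end <= self.human_start or self.dog_end <= self.dog_start:
            raise ValueError("empty synteny interval")
        if self.orientation not in ("+", "-"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if (self.human_end - self.human_start) != (self.dog_end - self.dog_start):
            raise ValueError("synteny block sides differ in length; projection must be length-preserving")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    role: str  # "tumor" | "normal"
    site: str = ""
    virus_status: str = "unknown"  # "positive" | "negative" | "unknown"
    case_id: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("tumor", "normal"):
            raise ValueError(f"bad role {self.role!r}")
        if self.virus_status not in ("positive", "negative", "unknown"):
            raise ValueError(f"bad virus_status {self.virus_status!r}")


class GeneCnaMatrix:
    """Gene x sample copy-number status with amplitudes and recurrence q-values.

    ``status`` holds -1/0/+1 per gene and sample; ``amplitude`` the mean
    log2 ratio of the segment assigned to the gene.  ``q_amp``/``q_del``
    are filled by :func:`crossonc.gene_cna.recurrence_test` and are NaN
    until then.  ``excluded`` flags genes on chromosomes left out of CNA
    calling (they keep status 0).
    """

    def __init__(
        self,
        status: pd.DataFrame,
        amplitude: pd.DataFrame,
        genes: pd.DataFrame,
        excluded: pd.Series | None = None,
    ) -> None:
        if not status.index.equals(amplitude.index) or not status.columns.equals(amplitude.columns):
            raise ValueError("status and amplitude must be aligned")
        if not status.index.equals(genes.index):
            raise ValueError("gene metadata must be aligned with the matrix")
        if status.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        self.status = status.astype(int)
        self.amplitude = amplitude.astype(float)
        self.genes = genes  # columns: chrom, start, end
        self.excluded = (
            excluded.astype(bool)
            if excluded is not None
            else pd.Series(False, index=status.index)
        )
        self.q_amp = pd.Series(np.nan, index=status.index)
        self.q_del = pd.Series(np.nan, index=status.index)

    @property
    def gene_ids(self) -> pd.Index:
        return self.status.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.status.columns

    def recurrent_genes(self, fdr: float = 0.2, kind: str = "amp") -> list[str]:
        q = self.q_amp if kind == "amp" else self.q_del
        return list(q.index[q <= fdr])


@dataclass
class DriverPassengerResult:
    """DCG/PCG partition of a projected amplicon with its Fisher statistics."""

    region_counts: pd.DataFrame  # index: region name; columns: n_amplified, n_unchanged, n_deleted
    table: np.ndarray  # 2x2 used for the headline test
    odds_ratio: float
    p_value: float
    dcg: list[str]
    pcg: list[str]
    deleted: list[str]
    status: str  # "discriminated" | "no_discrimination"

    def __post_init__(self) -> None:
        if set(self.dcg) & set(self.pcg):
            raise ValueError("DCG and PCG sets overlap")
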