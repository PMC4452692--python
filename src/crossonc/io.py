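"""Readers and writers for the on-disk formats the pipeline touches.

Conventions: internal coordinates are 0-based half-open everywhere.
BED is 0-based half-open on disk; VCF and SEG are 1-based (SEG end
inclusive); the synteny TSV uses 0-based half-open coordinates on both
sides.  Gzipped variants of the text formats are accepted transparently.
Indel and multi-nucleotide VCF records are dropped with a logged count:
the analyses downstream are substitution-only.
"""
from __future__ import annotations

import gzip
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    CnaTruth,
    Gene,
    ProbeProfile,
    SampleMeta,
    SegmentCall,
    SyntenyBlock,
    TruthSegment,
    VariantRecord,
)

logger = logging.getLogger(__name__)


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# probe TSV
# ---------------------------------------------------------------------------

def read_probe_tsv(path) -> dict[str, list[ProbeProfile]]:
    """Read a probe table (chrom, pos, one log2-ratio column per sample).

    Returns ``{sample_id: [ProbeProfile per chromosome]}``.  Probes must
    be sorted by (chrom, pos) within each chromosome with no duplicate
    positions; violations raise with the offending line number.
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "chrom" or df.columns[1] != "pos":
        raise ValueError(f"{path}: first two columns must be 'chrom' and 'pos'")
    samples = list(df.columns[2:])
    if not samples:
        raise ValueError(f"{path}: no sample columns")
    for col in samples:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(np.nonzero(bad.values)[0][0]) + 2  # header is line 1
            raise ValueError(f"{path}: non-numeric ratio in column {col} at line {line}")
        df[col] = pd.to_numeric(df[col])
    out: dict[str, list[ProbeProfile]] = {s: [] for s in samples}
    for chrom, grp in df.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(np.int64)
        diffs = np.diff(pos)
        if np.any(diffs <= 0):
            i = int(np.nonzero(diffs <= 0)[0][0])
            line = int(grp.index[i + 1]) + 2
            kind = "duplicate" if diffs[i] == 0 else "unsorted"
            raise ValueError(f"{path}: {kind} position on {chrom} at line {line}")
        for s in samples:
            out[s].append(ProbeProfile(s, str(chrom), pos, grp[s].to_numpy(float)))
    return out


def write_probe_tsv(profiles: Mapping[str, Sequence[ProbeProfile]], path) -> None:
    """Write per-sample probe profiles sharing one probe grid."""
    samples = list(profiles)
    if not samples:
        raise ValueError("no samples to write")
    first = profiles[samples[0]]
    frames = []
    for ci, prof in enumerate(first):
        data = {"chrom": prof.chrom, "pos": prof.positions}
        for s in samples:
            other = profiles[s][ci]
            if other.chrom != prof.chrom or not np.array_equal(other.positions, prof.positions):
                raise ValueError("all samples must share the same probe grid")
            data[s] = np.round(other.log2ratio, 6)
        frames.append(pd.DataFrame(data))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SEG (IGV dialect)
# ---------------------------------------------------------------------------

_SEG_COLS = ["Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean",
             "P_Value", "Q_Value", "Call"]


def write_seg(calls: Sequence[SegmentCall], path) -> None:
    """Write segment calls as IGV-style SEG (1-based inclusive on disk)."""
    by_key: dict[tuple[str, str], list[SegmentCall]] = {}
    for c in calls:
        by_key.setdefault((c.sample_id, c.chrom), []).append(c)
    for (sample, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping segments for {sample} on {chrom}")
    rows = [
        (c.sample_id, c.chrom, c.start + 1, c.end, c.probe_count,
         round(c.mean_log2, 6), c.p_value, c.q_value, c.call)
        for c in calls
    ]
    pd.DataFrame(rows, columns=_SEG_COLS).to_csv(path, sep="\t", index=False)


def read_seg(path) -> list[SegmentCall]:
    df = pd.read_csv(path, sep="\t")
    need = _SEG_COLS[:6]
    if list(df.columns[:6]) != need:
        raise ValueError(f"{path}: expected SEG columns {need}")
    out = []
    for _, r in df.iterrows():
        out.append(
            SegmentCall(
                sample_id=str(r["Sample"]),
                chrom=str(r["Chromosome"]),
                start=int(r["Start"]) - 1,
                end=int(r["End"]),
                probe_count=int(r["Num_Probes"]),
                mean_log2=float(r["Segment_Mean"]),
                p_value=float(r.get("P_Value", np.nan)),
                q_value=float(r.get("Q_Value", np.nan)),
                call=str(r.get("Call", "neutral")),
            )
        )
    return out


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> list[Gene]:
    """Read genes from BED (0-based half-open); BED3 gets synthetic ids."""
    genes = []
    with _open_text(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {i}: fewer than 3 BED fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"feature_{i}"
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "+"
            genes.append(Gene(name, chrom, start, end, strand))
    return genes


def write_bed(genes: Iterable[Gene], path) -> None:
    with _open_text(path, "wt") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(seqs: Mapping[str, str], path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(records: Sequence[VariantRecord], path, contigs: Mapping[str, int]) -> None:
    """Write substitutions as a multi-sample VCF v4.2 with DP per sample.

    Flanking context is carried in INFO (F5/F3) so it is recoverable
    without the FASTA; a reference FASTA may restore it as well.
    """
    samples = sorted({r.sample_id for r in records})
    by_site: dict[tuple[str, int, str, str], dict[str, VariantRecord]] = {}
    for r in records:
        by_site.setdefault((r.chrom, r.pos, r.ref, r.alt), {})[r.sample_id] = r
    chrom_order = list(contigs)
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, n in contigs.items():
            fh.write(f"##contig=<ID={c},length={n}>\n")
        fh.write('##INFO=<ID=F5,Number=1,Type=String,Description="5-prime flanking reference base">\n')
        fh.write('##INFO=<ID=F3,Number=1,Type=String,Description="3-prime flanking reference base">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        def key(site):
            chrom, pos, ref, alt = site
            ci = chrom_order.index(chrom) if chrom in chrom_order else len(chrom_order)
            return (ci, pos, ref, alt)
        for site in sorted(by_site, key=key):
            chrom, pos, ref, alt = site
            carriers = by_site[site]
            any_rec = next(iter(carriers.values()))
            info = f"F5={any_rec.five_prime};F3={any_rec.three_prime}"
            cols = [chrom, str(pos + 1), ".", ref, alt, ".", "PASS", info, "GT:DP"]
            for s in samples:
                if s in carriers:
                    cols.append(f"0/1:{carriers[s].depth}")
                else:
                    cols.append("./.:.")
            fh.write("\t".join(cols) + "\n")


def read_vcf(path, fasta=None) -> list[VariantRecord]:
    """Read substitutions from a VCF; one record per carrying sample.

    Multi-allelic rows are split; indels/MNVs are skipped with a logged
    count.  Flanking bases come from INFO F5/F3 when present, else from
    the reference ``fasta`` (a path, opened with pyfaidx), else 'N'.
    """
    from cyvcf2 import VCF

    fa = None
    if fasta is not None:
        from pyfaidx import Fasta

        fa = Fasta(str(fasta))
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    n_skipped = 0
    for v in vcf:
        depths = None
        try:
            depths = v.format("DP")
        except Exception:
            depths = None
        for alt in v.ALT:
            if len(v.REF) != 1 or len(alt) != 1 or v.REF not in "ACGT" or alt not in "ACGT":
                n_skipped += 1
                continue
            pos0 = v.POS - 1
            f5 = v.INFO.get("F5")
            f3 = v.INFO.get("F3")
            if (f5 is None or f3 is None) and fa is not None and v.CHROM in fa:
                seq = fa[v.CHROM]
                f5 = str(seq[pos0 - 1]).upper() if pos0 >= 1 else "N"
                f3 = str(seq[pos0 + 1]).upper() if pos0 + 1 < len(seq) else "N"
            f5 = f5 if f5 in ("A", "C", "G", "T") else "N"
            f3 = f3 if f3 in ("A", "C", "G", "T") else "N"
            if not samples:
                continue
            for si, s in enumerate(samples):
                dp = int(depths[si][0]) if depths is not None else -1
                if dp < 0:
                    continue
                records.append(
                    VariantRecord(
                        sample_id=s, chrom=v.CHROM, pos=pos0, ref=v.REF, alt=alt,
                        depth=dp, five_prime=f5, three_prime=f3,
                    )
                )
    if n_skipped:
        logger.info("read_vcf: skipped %d non-substitution allele(s)", n_skipped)
    return records


# ---------------------------------------------------------------------------
# expression / synteny / metadata / truth
# ---------------------------------------------------------------------------

def read_expression_tsv(path) -> pd.DataFrame:
    """Gene x sample FPKM matrix; first column is the gene id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene ids")
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative expression values")
    return df


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


_SYNTENY_COLS = ["human_chrom", "human_start", "human_end",
                 "dog_chrom", "dog_start", "dog_end", "orientation"]


def read_synteny_tsv(path) -> list[SyntenyBlock]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_SYNTENY_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing synteny columns {sorted(missing)}")
    blocks = [
        SyntenyBlock(
            str(r.human_chrom), int(r.human_start), int(r.human_end),
            str(r.dog_chrom), int(r.dog_start), int(r.dog_end), str(r.orientation),
        )
        for r in df.itertuples()
    ]
    by_chrom: dict[str, list[SyntenyBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.human_chrom, []).append(b)
    for chrom, bs in by_chrom.items():
        bs = sorted(bs, key=lambda b: b.human_start)
        for a, b in zip(bs, bs[1:]):
            if b.human_start < a.human_end:
                raise ValueError(f"{path}: overlapping human intervals on {chrom}")
    return blocks


def write_synteny_tsv(blocks: Sequence[SyntenyBlock], path) -> None:
    rows = [
        (b.human_chrom, b.human_start, b.human_end,
         b.dog_chrom, b.dog_start, b.dog_end, b.orientation)
        for b in blocks
    ]
    pd.DataFrame(rows, columns=_SYNTENY_COLS).to_csv(path, sep="\t", index=False)


def read_sample_meta(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t").fillna("")
    if "sample_id" not in df.columns or "role" not in df.columns:
        raise ValueError(f"{path}: need at least sample_id and role columns")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return [
        SampleMeta(
            sample_id=str(r["sample_id"]),
            role=str(r["role"]),
            site=str(r.get("site", "")),
            virus_status=str(r.get("virus_status", "unknown") or "unknown"),
            case_id=str(r.get("case_id", "")),
        )
        for _, r in df.iterrows()
    ]


def write_sample_meta(metas: Sequence[SampleMeta], path) -> None:
    pd.DataFrame(
        [(m.sample_id, m.role, m.site, m.virus_status, m.case_id) for m in metas],
        columns=["sample_id", "role", "site", "virus_status", "case_id"],
    ).to_csv(path, sep="\t", index=False)


def write_truth_json(truth: CnaTruth, path) -> None:
    payload = {
        "sample_id": truth.sample_id,
        "segments": [
            {"chrom": s.chrom, "start": s.start, "end": s.end,
             "log2": s.log2, "kind": s.kind}
            for s in truth.segments
        ],
    }
    with _open_text(path, "wt") as fh:
        json.dump(payload, fh, indent=1)


def read_truth_json(path) -> CnaTruth:
    with _open_text(path) as fh:
        payload = json.load(fh)
    return CnaTruth(
        payload["sample_id"],
        [TruthSegment(s["chrom"], s["start"], s["end"], s["log2"], s["kind"])
         for s in payload["segments"]],
    )
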