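"""End-to-end orchestration: config, stage ordering, and the run report.

Stages run in dependency order (segment -> gene-cna -> integrate /
spectrum -> discriminate); each stage's outputs are written before the
next starts, so a failing stage leaves earlier outputs intact and aborts
the rest.  All randomness flows from one root seed via named substreams.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expression as ex
from . import gene_cna as gc
from . import io as cio
from . import segmentation as seg
from . import spectrum as sp
from .driver_passenger import discriminate, project_region
from .model import norm_chrom

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative inputs, thresholds and seed for a pipeline run."""

    out_dir: str
    probes: str | None = None
    genes_bed: str | None = None
    expression: str | None = None
    vcf: str | None = None
    fasta: str | None = None
    synteny: str | None = None
    human_genes_bed: str | None = None
    sample_meta: str | None = None
    fdr_cna: float = 0.01
    min_probes: int = 3
    mean_cutoff: float = 0.4
    recurrence_fdr: float = 0.2
    n_perm: int = 1000
    expr_alpha: float = 0.05
    de_fdr: float = 0.1
    min_depth: int = 30
    max_depth: int = 300
    exclude_chroms: list[str] = field(default_factory=lambda: ["X"])
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fdr_cna", "recurrence_fdr", "expr_alpha", "de_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name}={v} must be in (0, 1)")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")
        if self.mean_cutoff < 0:
            raise ValueError("mean_cutoff must be >= 0")
        if not 0 <= self.min_depth <= self.max_depth:
            raise ValueError("need 0 <= min_depth <= max_depth")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


REPORT_REQUIRED_KEYS = {"seed", "parameters", "stages", "status"}
STAGE_REQUIRED_KEYS = {"name", "status", "counts", "outputs"}


def validate_report(report: dict) -> None:
    """Schema check for the run report; raises on violation."""
    missing = REPORT_REQUIRED_KEYS - set(report)
    if missing:
        raise ValueError(f"report missing keys: {sorted(missing)}")
    if report["status"] not in ("ok", "failed"):
        raise ValueError(f"bad report status {report['status']!r}")
    for st in report["stages"]:
        miss = STAGE_REQUIRED_KEYS - set(st)
        if miss:
            raise ValueError(f"stage entry missing keys: {sorted(miss)}")
        if st["status"] not in ("ok", "failed", "skipped", "aborted"):
            raise ValueError(f"bad stage status {st['status']!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute all configured stages; returns the run report (also written).

    Stages whose inputs are not configured are skipped; a stage failure
    aborts every downstream stage while retaining earlier outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    substreams = {
        name: int(s.generate_state(1)[0] % 2**31)
        for name, s in zip(["recurrence"], ss.spawn(1))
    }
    report: dict = {
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "stages": [],
        "status": "ok",
    }
    state: dict = {}
    stages = [
        ("segment", _stage_segment),
        ("gene_cna", _stage_gene_cna),
        ("integrate", _stage_integrate),
        ("de", _stage_de),
        ("spectrum", _stage_spectrum),
        ("discriminate", _stage_discriminate),
    ]
    aborted = False
    for name, fn in stages:
        entry = {"name": name, "status": "skipped", "counts": {}, "outputs": []}
        if aborted:
            entry["status"] = "aborted"
            report["stages"].append(entry)
            continue
        t0 = time.time()
        try:
            ran = fn(config, state, out, entry, substreams)
            if ran:
                entry["status"] = "ok"
                entry["wall_seconds"] = round(time.time() - t0, 3)
        except Exception as err:  # noqa: BLE001 - report and abort downstream
            logger.error("stage %s failed: %s", name, err)
            entry["status"] = "failed"
            entry["error"] = str(err)
            report["status"] = "failed"
            aborted = True
        report["stages"].append(entry)
    manifest = {
        "seed": config.seed,
        "files": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name not in ("MANIFEST.json", "report.json")
        },
    }
    with open(out / "MANIFEST.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    validate_report(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def _stage_segment(config, state, out, entry, substreams) -> bool:
    if config.probes is None:
        return False
    profiles = cio.read_probe_tsv(config.probes)
    all_calls = []
    for sample, profs in profiles.items():
        segments = seg.segment_genome(profs)
        all_calls.extend(
            seg.call_cnas(
                segments,
                fdr=config.fdr_cna,
                min_probes=config.min_probes,
                mean_cutoff=config.mean_cutoff,
                exclude_chroms=set(config.exclude_chroms),
            )
        )
    path = out / "calls.seg"
    cio.write_seg(all_calls, path)
    summary = seg.genome_cna_summary(all_calls)
    spath = out / "cna_summary.tsv"
    summary.to_csv(spath, sep="\t")
    state["calls"] = all_calls
    entry["counts"] = {
        "samples": len(profiles),
        "segments": len(all_calls),
        "called": sum(1 for c in all_calls if c.call != "neutral"),
    }
    entry["outputs"] = [path.name, spath.name]
    return True


def _stage_gene_cna(config, state, out, entry, substreams) -> bool:
    if config.genes_bed is None or "calls" not in state:
        return False
    genes = cio.read_bed(config.genes_bed)
    matrix = gc.assign_gene_status(
        state["calls"], genes, exclude_chroms=set(config.exclude_chroms)
    )
    if len(matrix.sample_ids) >= 2:
        gc.recurrence_test(
            matrix,
            n_perm=config.n_perm,
            fdr=config.recurrence_fdr,
            seed=substreams["recurrence"],
        )
    path = out / "gene_cna.tsv"
    gc.gene_cna_to_frame(matrix).to_csv(path, sep="\t")
    state["gene_cna"] = matrix
    entry["counts"] = {
        "genes": len(matrix.gene_ids),
        "recurrent_amp": len(matrix.recurrent_genes(config.recurrence_fdr, "amp")),
        "recurrent_del": len(matrix.recurrent_genes(config.recurrence_fdr, "del")),
    }
    entry["outputs"] = [path.name]
    return True


def _stage_integrate(config, state, out, entry, substreams) -> bool:
    if config.expression is None or "gene_cna" not in state:
        return False
    matrix = cio.read_expression_tsv(config.expression)
    matrix = ex.filter_expressed(matrix)
    calls = ex.classify_expression(matrix, state["gene_cna"], alpha=config.expr_alpha)
    path = out / "expression_calls.tsv"
    calls.to_csv(path, sep="\t", index=False)
    table = ex.concordance_table(calls, state["gene_cna"])
    cpath = out / "concordance.tsv"
    table.to_csv(cpath, sep="\t")
    state["expression"] = matrix
    entry["counts"] = {
        "genes_expressed": matrix.shape[0],
        "calls": len(calls),
        "high": int((calls["level"] == "high").sum()),
        "low": int((calls["level"] == "low").sum()),
    }
    entry["outputs"] = [path.name, cpath.name]
    return True


def _stage_de(config, state, out, entry, substreams) -> bool:
    if config.expression is None or config.sample_meta is None:
        return False
    matrix = state.get("expression")
    if matrix is None:
        matrix = ex.filter_expressed(cio.read_expression_tsv(config.expression))
    metas = cio.read_sample_meta(config.sample_meta)
    tumors = [m.sample_id for m in metas if m.role == "tumor" and m.sample_id in matrix.columns]
    normals = [m.sample_id for m in metas if m.role == "normal" and m.sample_id in matrix.columns]
    if len(tumors) < 2 or len(normals) < 2:
        return False
    de = ex.differential_expression_ttest(matrix, tumors, normals, fdr=config.de_fdr)
    path = out / "differential_expression.tsv"
    de.to_csv(path, sep="\t", index_label="gene_id")
    entry["counts"] = {"genes": len(de), "significant": int(de["significant"].sum())}
    entry["outputs"] = [path.name]
    return True


def _stage_spectrum(config, state, out, entry, substreams) -> bool:
    if config.vcf is None:
        return False
    records = cio.read_vcf(config.vcf, fasta=config.fasta)
    kept = sp.filter_by_coverage(records, config.min_depth, config.max_depth)
    summary = sp.spectrum(kept)
    path = out / "spectrum.tsv"
    table = summary.fractions.copy()
    table["transition_fraction"] = summary.transition_fraction
    table["transversion_fraction"] = summary.transversion_fraction
    table["cpg_transversion_fraction"] = summary.cpg_transversion_fraction
    table["tpc_fraction"] = summary.tpc_fraction
    table.to_csv(path, sep="\t")
    outputs = [path.name]
    counts = {"records": len(records), "coverage_filtered": len(kept)}
    if config.sample_meta is not None:
        metas = cio.read_sample_meta(config.sample_meta)
        pos_ids = {m.sample_id for m in metas if m.virus_status == "positive"}
        neg_ids = {m.sample_id for m in metas if m.virus_status == "negative"}
        group_pos = [r for r in kept if r.sample_id in pos_ids]
        group_neg = [r for r in kept if r.sample_id in neg_ids]
        if group_pos and group_neg:
            cmp_res = sp.compare_cpg_transversions(group_pos, group_neg)
            jpath = out / "cpg_comparison.json"
            with open(jpath, "w") as fh:
                json.dump(
                    {
                        "table": cmp_res.table.tolist(),
                        "odds_ratio": None if np.isnan(cmp_res.odds_ratio) else cmp_res.odds_ratio,
                        "p_value": cmp_res.p_value,
                        "rows": ["virus_positive", "virus_negative"],
                        "cols": ["transversion", "transition"],
                    },
                    fh,
                    indent=1,
                )
            outputs.append(jpath.name)
            counts["cpg_p_value"] = cmp_res.p_value
    entry["counts"] = counts
    entry["outputs"] = outputs
    return True


def _stage_discriminate(config, state, out, entry, substreams) -> bool:
    if config.synteny is None or config.human_genes_bed is None or "gene_cna" not in state:
        return False
    blocks = cio.read_synteny_tsv(config.synteny)
    human_genes_list = cio.read_bed(config.human_genes_bed)
    human_genes = pd.DataFrame(
        {
            "chrom": [g.chrom for g in human_genes_list],
            "start": [g.start for g in human_genes_list],
            "end": [g.end for g in human_genes_list],
            "status": 1,
        },
        index=pd.Index([g.id for g in human_genes_list], name="gene_id"),
    )
    chroms = {norm_chrom(g.chrom) for g in human_genes_list}
    if len(chroms) != 1:
        raise ValueError("human amplicon genes must lie on one chromosome")
    region = (
        human_genes_list[0].chrom,
        int(human_genes["start"].min()),
        int(human_genes["end"].max()),
    )
    regions, gaps = project_region(region, blocks)
    result = discriminate(
        human_genes, state["gene_cna"], regions, recurrence_fdr=config.recurrence_fdr
    )
    path = out / "dp_result.json"
    with open(path, "w") as fh:
        json.dump(
            {
                "status": result.status,
                "table": result.table.tolist(),
                "odds_ratio": None if np.isinf(result.odds_ratio) else result.odds_ratio,
                "p_value": result.p_value,
                "region_counts": result.region_counts.to_dict(orient="index"),
                "dcg": result.dcg,
                "pcg": result.pcg,
                "deleted": result.deleted,
                "unmapped_gaps": gaps,
            },
            fh,
            indent=1,
        )
    entry["counts"] = {
        "regions": len(regions),
        "dcg": len(result.dcg),
        "pcg": len(result.pcg),
        "p_value": result.p_value,
    }
    entry["outputs"] = [path.name]
    return True
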