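"""File formats, reports and the batch driver.

FASTA output uses 70-character lines; circular topology is recorded in
the header as ``topology=circular`` (FASTA has no standard field for it —
this is a documented dialect of this package). Candidate reports are
written as TSV (fixed column schema) and JSON (same rows plus the
sequences). Config files are simple ``key: value`` YAML mappings that
override built-in defaults and are themselves overridden by CLI flags.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .design import AnnotatedSequence, DesignCandidate, DesignParams, EditTask, design
from .seqcore import GeneLocus, InputError, PipoError, parse_goi, read_fasta_single, validate_locus

logger = logging.getLogger("pipo")

FASTA_WIDTH = 70

TSV_COLUMNS = [
    "gene", "task", "enzyme", "pop_in_region", "cut_pos", "d_junction",
    "pop_in_len", "pop_out_len", "achieved_ratio", "truncated", "tag_sites",
    "mcs_left", "mcs_right", "insert_len", "status", "reason", "optimal",
]


def write_fasta(path: str | Path, name: str, seq: str, circular: bool = False) -> None:
    header = f">{name} topology=circular" if circular else f">{name}"
    lines = [header] + [seq[i : i + FASTA_WIDTH] for i in range(0, len(seq), FASTA_WIDTH)]
    Path(path).write_text("\n".join(lines) + "\n")


def candidate_rows(gene: str, task: EditTask, candidates: list[DesignCandidate]) -> list[dict]:
    rows = []
    for c in candidates:
        rows.append(
            {
                "gene": gene,
                "task": task.value,
                "enzyme": c.cut.enzyme,
                "pop_in_region": c.cut.pop_in_region.value,
                "cut_pos": c.cut.cut_pos,
                "d_junction": c.cut.d_junction,
                "pop_in_len": c.arms.pop_in_len if c.arms else None,
                "pop_out_len": c.arms.pop_out_len if c.arms else None,
                "achieved_ratio": round(c.arms.achieved_ratio, 4) if c.arms else None,
                "truncated": c.arms.truncated if c.arms else None,
                "tag_sites": ",".join(c.tag_flank_assignment),
                "mcs_left": c.mcs_pair[0] if c.mcs_pair else None,
                "mcs_right": c.mcs_pair[1] if c.mcs_pair else None,
                "insert_len": c.insert_len if c.status == "valid" else None,
                "status": c.status,
                "reason": c.reject_reason or "",
                "optimal": c.optimal,
            }
        )
    return rows


def write_reports(
    candidates: list[DesignCandidate],
    out_dir: str | Path,
    gene: str,
    task: EditTask,
    formats: tuple[str, ...] = ("tsv", "json"),
    genbank: bool = False,
) -> dict[str, Path]:
    """Write candidate reports and the optimal plasmid/insert FASTA files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    rows = candidate_rows(gene, task, candidates)
    stem = f"{gene}_{task.value}"

    if "tsv" in formats:
        path = out / f"{stem}_report.tsv"
        pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)
        written["tsv"] = path
    if "json" in formats:
        path = out / f"{stem}_report.json"
        payload = []
        for row, cand in zip(rows, candidates):
            entry = dict(row)
            entry["insert_seq"] = cand.insert.seq if cand.insert else None
            entry["plasmid_seq"] = cand.plasmid.seq if cand.plasmid else None
            payload.append(entry)
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
        written["json"] = path

    best = next((c for c in candidates if c.optimal), None)
    if best is not None:
        ppath = out / f"{stem}_plasmid.fasta"
        write_fasta(ppath, f"{stem}_plasmid", best.plasmid.seq, circular=True)
        written["plasmid"] = ppath
        ipath = out / f"{stem}_insert.fasta"
        write_fasta(ipath, f"{stem}_insert", best.insert.seq)
        written["insert"] = ipath
        if genbank:
            gpath = out / f"{stem}_plasmid.gb"
            write_genbank(gpath, f"{stem}_plasmid", best.plasmid)
            written["genbank"] = gpath
    return written


def write_genbank(path: str | Path, name: str, annotated: AnnotatedSequence) -> None:
    """Annotated plasmid map in GenBank format (origin-wrapping features
    are written as joined locations)."""
    L = len(annotated.seq)
    features = []
    for f in annotated.features:
        if f.end == f.start:
            continue
        strand = 1 if f.strand == "+" else -1
        start, end = f.start % L, f.end
        if start + (f.end - f.start) <= L:
            loc = FeatureLocation(start, start + (f.end - f.start), strand=strand)
        else:
            split = L - start
            loc = CompoundLocation(
                [
                    FeatureLocation(start, L, strand=strand),
                    FeatureLocation(0, (f.end - f.start) - split, strand=strand),
                ]
            )
        features.append(SeqFeature(loc, type="misc_feature", qualifiers={"label": [f.label]}))
    record = SeqRecord(
        Seq(annotated.seq),
        id=name[:16],
        name=name[:16],
        description="",
        features=features,
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if annotated.circular else "linear",
        },
    )
    SeqIO.write([record], str(path), "genbank")


def load_config(path: str | Path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise InputError(f"{path}: config must be a key: value mapping")
    return data


# ---------------------------------------------------------------------------
# Batch driver
# ---------------------------------------------------------------------------

@dataclass
class BatchSummary:
    """Per-gene-per-task design outcomes plus the headline aggregate."""

    rows: pd.DataFrame  # gene, task, n_candidates, n_valid, optimal_insert_len, reasons

    @property
    def designable_fraction(self) -> float:
        if len(self.rows) == 0:
            return float("nan")
        return float((self.rows["n_valid"] >= 1).sum() / len(self.rows))

    @property
    def insert_lengths(self) -> pd.Series:
        return self.rows.loc[self.rows["n_valid"] >= 1, "optimal_insert_len"]


def run_batch(
    genes_dir: str | Path,
    tasks: list[EditTask],
    params: DesignParams,
    backbone: str,
    mcs_interval: tuple[int, int],
    out_dir: str | Path | None = None,
    report_formats: tuple[str, ...] = (),
) -> BatchSummary:
    """Design every ``<GENE>.fasta`` in a directory for the selected tasks.

    Malformed gene files are skipped with a logged warning and counted as
    failures (one row per task), not crashes.
    """
    from .design import summarize_reasons

    records: list[dict] = []
    gene_files = sorted(Path(genes_dir).glob("*.fasta"))
    if not gene_files:
        raise InputError(f"{genes_dir}: no .fasta gene files found")
    for path in gene_files:
        gene = path.stem
        try:
            name, raw = read_fasta_single(path, what="gene locus")
            locus = parse_goi(raw, params.flank_len, name=name or gene)
            validate_locus(locus)
        except PipoError as exc:
            logger.warning("skipping %s: %s", path.name, exc)
            for task in tasks:
                records.append(
                    {
                        "gene": gene, "task": task.value, "n_candidates": 0,
                        "n_valid": 0, "optimal_insert_len": None,
                        "reasons": f"INPUT_ERROR: {exc}",
                    }
                )
            continue
        for task in tasks:
            candidates = design(locus, task, params, backbone, mcs_interval)
            valid = [c for c in candidates if c.status == "valid"]
            best = next((c for c in candidates if c.optimal), None)
            records.append(
                {
                    "gene": gene,
                    "task": task.value,
                    "n_candidates": len(candidates),
                    "n_valid": len(valid),
                    "optimal_insert_len": best.insert_len if best else None,
                    "reasons": ";".join(
                        f"{k}={v}" for k, v in sorted(summarize_reasons(candidates).items())
                    ),
                }
            )
            if out_dir is not None and report_formats:
                write_reports(candidates, out_dir, gene, task, formats=report_formats)
    summary = BatchSummary(rows=pd.DataFrame.from_records(records))
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        summary.rows.to_csv(Path(out_dir) / "batch_summary.tsv", sep="\t", index=False)
    return summary
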