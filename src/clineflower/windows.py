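"""Candidate-gene windows around significant SNPs.

Each significant SNP defines a window [pos - W, pos + W] (default W = 10 kbp,
clipped at 1 and at the chromosome end when lengths are known); any gene body
overlapping the window by >= 1 bp is a candidate.  All coordinates are
1-based inclusive.  A per-gene view aggregates SNPs sharing a gene, keeping
the best (minimum) p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GeneAnnotation


@dataclass
class CandidateReport:
    per_snp: pd.DataFrame   # snp_id chrom pos win_start win_end gene_ids neglog10p
    per_gene: pd.DataFrame  # gene_id chrom start end best_neglog10p snp_ids description
    window_bp: int
    label: str = "scan"

    def gene_set(self) -> set[str]:
        return set(self.per_gene["gene_id"])


def genes_near_snps(
    sig: pd.DataFrame,
    ann: GeneAnnotation,
    window_bp: int = 10_000,
    chrom_lengths: dict[str, int] | None = None,
    label: str = "scan",
) -> CandidateReport:
    """Genes overlapping +/- ``window_bp`` windows around significant SNPs.

    ``sig`` needs columns snp_id, chrom, pos, neglog10p (as produced by
    :func:`clineflower.permthresh.call_significant`).  Overlap is inclusive:
    a gene is kept unless it ends before the window starts or starts after
    the window ends.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    t = ann.table
    ann_chroms = set(t["chrom"])
    snp_rows, hits = [], []
    for _, r in sig.iterrows():
        chrom = str(r["chrom"])
        pos = int(r["pos"])
        w_start = max(1, pos - window_bp)
        w_end = pos + window_bp
        if chrom_lengths and chrom in chrom_lengths:
            w_end = min(w_end, int(chrom_lengths[chrom]))
        if chrom not in ann_chroms:
            warnings.warn(f"SNP {r['snp_id']}: chromosome {chrom!r} absent from "
                          "annotation; empty gene list", stacklevel=2)
            genes = t.iloc[0:0]
        else:
            tc = t[t["chrom"] == chrom]
            genes = tc[~((tc["end"] < w_start) | (tc["start"] > w_end))]
        snp_rows.append({
            "snp_id": r["snp_id"], "chrom": chrom, "pos": pos,
            "win_start": w_start, "win_end": w_end,
            "gene_ids": list(genes["gene_id"]),
            "neglog10p": float(r["neglog10p"]),
        })
        for _, gr in genes.iterrows():
            hits.append({
                "gene_id": gr["gene_id"], "chrom": chrom,
                "start": gr["start"], "end": gr["end"],
                "description": gr.get("description", ""),
                "snp_id": r["snp_id"], "neglog10p": float(r["neglog10p"]),
            })
    per_snp = pd.DataFrame(
        snp_rows, columns=["snp_id", "chrom", "pos", "win_start", "win_end",
                           "gene_ids", "neglog10p"])
    if hits:
        h = pd.DataFrame(hits)
        per_gene = (
            h.groupby(["gene_id", "chrom", "start", "end", "description"],
                      as_index=False)
            .agg(best_neglog10p=("neglog10p", "max"),
                 snp_ids=("snp_id", list))
            .sort_values(["chrom", "start"], kind="stable")
            .reset_index(drop=True)
        )
    else:
        per_gene = pd.DataFrame(columns=["gene_id", "chrom", "start", "end",
                                         "description", "best_neglog10p", "snp_ids"])
    return CandidateReport(per_snp=per_snp, per_gene=per_gene,
                           window_bp=window_bp, label=label)


def cross_scan_overlap(a: CandidateReport, b: CandidateReport) -> pd.DataFrame:
    """Genes reported by both scans, with each scan's best -log10 p."""
    shared = sorted(a.gene_set() & b.gene_set())
    if not shared:
        return pd.DataFrame(columns=["gene_id", "chrom", "start", "end",
                                     f"best_neglog10p_{a.label}",
                                     f"best_neglog10p_{b.label}"])
    ga = a.per_gene.set_index("gene_id")
    gb = b.per_gene.set_index("gene_id")
    rows = [{
        "gene_id": gid,
        "chrom": ga.loc[gid, "chrom"],
        "start": ga.loc[gid, "start"],
        "end": ga.loc[gid, "end"],
        f"best_neglog10p_{a.label}": ga.loc[gid, "best_neglog10p"],
        f"best_neglog10p_{b.label}": gb.loc[gid, "best_neglog10p"],
    } for gid in shared]
    return pd.DataFrame(rows)
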