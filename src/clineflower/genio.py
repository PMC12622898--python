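"""Genotype, phenotype and annotation I/O plus marker-level filters.

Genotypes live in a :class:`GenotypeMatrix`: an accessions x SNPs dosage
matrix (alt-allele counts in {0, 1, 2}, NaN for missing) with per-SNP
chromosome / position / allele metadata.  Coordinates are 1-based inclusive
everywhere a user can see them, matching VCF and BED-derived annotation
conventions.

The filters implement the marker handling used ahead of association scans on
inbred accession panels: a minor-allele-frequency cutoff, removal of the
unanchored "chromosome 0" contig group, and a naive per-SNP imputation
(mean dosage for association, modal dosage where an integer domain is needed,
e.g. for minor-allele counts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class GenioError(ValueError):
    """Base class for genotype/annotation I/O and filter errors."""


class EmptyPanelError(GenioError):
    """Raised when a source yields zero usable SNPs."""


class InvalidParameterError(GenioError):
    """Raised for out-of-domain filter parameters."""


def _as_str_array(x: Iterable) -> np.ndarray:
    return np.asarray(list(x), dtype=object)


@dataclass
class GenotypeMatrix:
    """Accessions x SNPs dosage matrix with SNP metadata.

    dosage[i, j] is the alt-allele count of accession i at SNP j; NaN marks
    missing calls.  After mean imputation dosages may be real-valued in
    [0, 2]; operations needing an integer domain must check
    :meth:`is_integer_dosage`.
    """

    accession_ids: list[str]
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = _as_str_array(self.snp_ids)
        self.chrom = _as_str_array(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = _as_str_array(self.ref)
        self.alt = _as_str_array(self.alt)
        self.dosage = np.asarray(self.dosage, dtype=float)
        n_acc, n_snp = self.dosage.shape
        if len(self.accession_ids) != n_acc:
            raise GenioError("accession_ids length does not match dosage rows")
        for name, arr in (("snp_ids", self.snp_ids), ("chrom", self.chrom),
                          ("pos", self.pos), ("ref", self.ref), ("alt", self.alt)):
            if len(arr) != n_snp:
                raise GenioError(f"{name} length does not match dosage columns")
        if len(set(self.snp_ids)) != n_snp:
            raise GenioError("snp_ids must be unique")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosage < 0) | (self.dosage > 2))
        if bad:
            raise GenioError("dosage values must lie in [0, 2] or be NaN")
        # positions strictly increasing within each chromosome block
        for c in dict.fromkeys(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise GenioError(f"positions not strictly increasing on chromosome {c}")

    @property
    def n_accessions(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def is_integer_dosage(self) -> bool:
        d = self.dosage[~np.isnan(self.dosage)]
        return bool(np.all(d == np.round(d)))

    def alt_frequency(self) -> np.ndarray:
        """Per-SNP alt-allele frequency p over non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_frequency()
        return np.minimum(p, 1.0 - p)

    def mac(self) -> np.ndarray:
        """Per-SNP minor-allele count over non-missing accessions.

        Requires an integer dosage domain (use major-mode imputation first).
        """
        if not self.is_integer_dosage():
            raise InvalidParameterError(
                "MAC needs integer dosages; impute with mode='major' first")
        alt = np.nansum(self.dosage, axis=0)
        total = 2 * np.sum(~np.isnan(self.dosage), axis=0)
        return np.minimum(alt, total - alt).astype(np.int64)

    def snp_index(self, snp_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snp_ids)}
        try:
            return np.array([lookup[s] for s in snp_ids], dtype=np.int64)
        except KeyError as exc:
            raise GenioError(f"unknown SNP id {exc.args[0]!r}") from None

    def take_snps(self, mask_or_index: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            accession_ids=list(self.accession_ids),
            snp_ids=self.snp_ids[idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            dosage=self.dosage[:, idx],
        )

    def take_accessions(self, accessions: Sequence[str]) -> "GenotypeMatrix":
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        rows = [lookup[a] for a in accessions]
        return GenotypeMatrix(
            accession_ids=list(accessions),
            snp_ids=self.snp_ids,
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            dosage=self.dosage[rows, :],
        )

    def snp_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": self.snp_ids,
            "chrom": self.chrom,
            "pos": self.pos,
            "ref": self.ref,
            "alt": self.alt,
        })


@dataclass
class GeneAnnotation:
    """Gene records with 1-based inclusive [start, end] coordinates."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("gene_id", "chrom", "start", "end")

    def __post_init__(self) -> None:
        if len(self.table) == 0 and not set(self.REQUIRED) <= set(self.table.columns):
            self.table = pd.DataFrame(
                columns=["gene_id", "chrom", "start", "end", "strand", "description"])
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise GenioError(f"annotation missing columns: {sorted(missing)}")
        t = self.table.copy()
        t["chrom"] = t["chrom"].astype(str)
        t["start"] = t["start"].astype(np.int64)
        t["end"] = t["end"].astype(np.int64)
        if "strand" not in t.columns:
            t["strand"] = "."
        if "description" not in t.columns:
            t["description"] = ""
        if (t["start"] > t["end"]).any():
            raise GenioError("gene start must be <= end")
        if (t["start"] < 1).any():
            raise GenioError("gene coordinates are 1-based; start must be >= 1")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load biallelic SNP records from a VCF 4.x file with GT calls.

    Multiallelic sites and non-SNP alleles are skipped (count logged).
    Dosage is the alt-allele count; "./." is kept as NaN.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path, gts012=True)
    accessions = list(vcf.samples)
    snp_ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        # gts012: 0/1/2 = alt count, 3 = unknown
        gt = v.gt_types.astype(float)
        gt[gt == 3] = np.nan
        snp_ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}")
        chroms.append(str(v.CHROM))
        poss.append(int(v.POS))
        refs.append(v.REF)
        alts.append(v.ALT[0])
        rows.append(gt)
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    if not rows:
        raise EmptyPanelError(f"no usable biallelic SNPs in {path}")
    return GenotypeMatrix(
        accession_ids=accessions,
        snp_ids=snp_ids,
        chrom=chroms,
        pos=poss,
        ref=refs,
        alt=alts,
        dosage=np.column_stack(rows) if len(rows) > 1 else np.asarray(rows).T,
    )


_GT_CODES = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(g: GenotypeMatrix, path: str | Path,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a minimal VCF 4.2 file (GT only) for a genotype matrix.

    Requires integer dosages (imputed real-valued matrices cannot round-trip
    through GT calls).
    """
    if not g.is_integer_dosage():
        raise InvalidParameterError("write_vcf needs integer dosages in {0,1,2}")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(g.chrom):
            if contig_lengths and c in contig_lengths:
                fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.accession_ids) + "\n")
        for j in range(g.n_snps):
            calls = [
                "./." if np.isnan(d) else _GT_CODES[float(d)]
                for d in g.dosage[:, j]
            ]
            fh.write(f"{g.chrom[j]}\t{g.pos[j]}\t{g.snp_ids[j]}\t{g.ref[j]}\t"
                     f"{g.alt[j]}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


# ---------------------------------------------------------------------------
# Annotation formats
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> GeneAnnotation:
    """Read BED3+name(+score+strand); half-open 0-based -> 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise GenioError("need BED3+name (>=4 columns) for gene annotations")
    out = pd.DataFrame({
        "gene_id": df[3],
        "chrom": df[0],
        "start": df[1].astype(np.int64) + 1,
        "end": df[2].astype(np.int64),
    })
    if df.shape[1] >= 6:
        out["strand"] = df[5]
    return GeneAnnotation(out)


def write_bed(ann: GeneAnnotation, path: str | Path) -> None:
    t = ann.table
    with Path(path).open("w") as fh:
        for _, r in t.iterrows():
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.gene_id}\t0\t{r.strand}\n")


def read_gff3_genes(path: str | Path) -> GeneAnnotation:
    """Read gene features from a GFF3 file (1-based inclusive, as stored)."""
    rows = []
    with Path(path).open() as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            rows.append({
                "gene_id": attrs.get("ID", attrs.get("Name", f"{f[0]}:{f[3]}-{f[4]}")),
                "chrom": f[0],
                "start": int(f[3]),
                "end": int(f[4]),
                "strand": f[6],
                "description": attrs.get("description", ""),
            })
    return GeneAnnotation(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_maf(g: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Keep SNPs with minor-allele frequency >= min_maf.

    MAF is min(p, 1-p) with p the mean non-missing dosage / 2.
    """
    if not 0.0 <= min_maf <= 0.5:
        raise InvalidParameterError(f"min_maf must be in [0, 0.5], got {min_maf}")
    return g.take_snps(g.maf() >= min_maf)


def impute_naive(g: GenotypeMatrix, mode: str = "mean") -> GenotypeMatrix:
    """Fill missing dosages per SNP: 'mean' dosage or 'major' (modal) dosage.

    SNPs missing in every accession are removed with a warning.
    """
    if mode not in ("mean", "major"):
        raise InvalidParameterError(f"mode must be 'mean' or 'major', got {mode!r}")
    d = g.dosage.copy()
    n_obs = np.sum(~np.isnan(d), axis=0)
    all_missing = n_obs == 0
    if all_missing.any():
        logger.warning("impute_naive: removing %d all-missing SNPs", all_missing.sum())
        g = g.take_snps(~all_missing)
        d = d[:, ~all_missing]
    miss = np.isnan(d)
    if not miss.any():
        return g
    if mode == "mean":
        fill = np.nanmean(d, axis=0)
    else:
        fill = np.empty(d.shape[1])
        for j in range(d.shape[1]):
            col = d[:, j]
            vals, counts = np.unique(col[~np.isnan(col)], return_counts=True)
            fill[j] = vals[np.argmax(counts)]  # ties -> smallest dosage
    d[miss] = np.broadcast_to(fill, d.shape)[miss]
    return replace(g, dosage=d)


def drop_chromosome(g: GenotypeMatrix, label: str) -> GenotypeMatrix:
    """Remove all SNPs on the given chromosome label, preserving order."""
    return g.take_snps(g.chrom != str(label))
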