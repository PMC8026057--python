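"""Readers and writers for the interchange formats.

TSV dialects (allele counts, pair counts, genotypes, metadata, labels) are
plain pandas tables.  Gene annotation round-trips through GFF3 (1-based
inclusive on disk, 0-based half-open in memory); allele counts optionally
round-trip through VCF with one sample per population carrying AD/DP.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GFF3 gene annotation

def write_gff3(genes: pd.DataFrame, path: str | Path) -> Path:
    """Write gene intervals as GFF3; in-memory coordinates are 0-based
    half-open and become 1-based inclusive on disk."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            fh.write("\t".join([
                str(g["scaffold"]), "driftld", "gene",
                str(int(g["start"]) + 1), str(int(g["end"])),
                ".", "+", ".", f"ID={g['gene_id']}",
            ]) + "\n")
    return path


def read_gff3(path: str | Path, feature: str = "gene") -> pd.DataFrame:
    """Gene intervals from GFF3, converted to 0-based half-open."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: malformed GFF3 record")
            if parts[2] != feature:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            rows.append((parts[0], int(parts[3]) - 1, int(parts[4]),
                         attrs.get("ID", f"{feature}_{lineno}")))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "gene_id"])


# ---------------------------------------------------------------------------
# VCF allele counts

VCF_HEADER = """##fileformat=VCFv4.2
##source=driftld
##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of samples">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_vcf_counts(counts: pd.DataFrame, path: str | Path) -> Path:
    """Allele-count table as a VCF with one sample per population."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pops = sorted(counts["pop"].unique())
    wide = counts.pivot_table(
        index=["scaffold", "pos", "ref", "alt"], columns="pop",
        values=["ref_count", "alt_count", "depth"], aggfunc="first")
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for scaffold in counts["scaffold"].unique():
            fh.write(f"##contig=<ID={scaffold}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(pops) + "\n")
        for (scaffold, pos, ref, alt), row in wide.sort_index().iterrows():
            cells = []
            for p in pops:
                rc = row.get(("ref_count", p))
                ac = row.get(("alt_count", p))
                dp = row.get(("depth", p))
                if pd.isna(rc):
                    cells.append("./.")
                else:
                    cells.append(f"{int(rc)},{int(ac)}:{int(dp)}")
            fh.write(f"{scaffold}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t"
                     f"NS={len(pops)}\tAD:DP\t" + "\t".join(cells) + "\n")
    return path


def read_vcf_counts(path: str | Path) -> pd.DataFrame:
    """Allele counts from a VCF written by :func:`write_vcf_counts` or any
    VCF with per-sample AD.  Keeps biallelic SNPs only; multi-allelic
    records and indels are skipped and counted."""
    rows = []
    skipped = 0
    pops: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("##") or not line.strip():
                continue
            if line.startswith("#CHROM"):
                pops = line.rstrip("\n").split("\t")[9:]
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 10:
                raise ValueError(f"{path}:{lineno}: malformed VCF record")
            scaffold, pos, _, ref, alt = parts[:5]
            if "," in alt or len(ref) != 1 or len(alt) != 1 or alt == ".":
                skipped += 1
                continue
            fmt = parts[8].split(":")
            try:
                i_ad = fmt.index("AD")
            except ValueError:
                raise ValueError(f"{path}:{lineno}: no AD field")
            i_dp = fmt.index("DP") if "DP" in fmt else None
            for pop, cell in zip(pops, parts[9:]):
                if cell.startswith("./."):
                    continue
                vals = cell.split(":")
                rc, ac = (int(x) for x in vals[i_ad].split(",")[:2])
                dp = int(vals[i_dp]) if i_dp is not None else rc + ac
                rows.append((scaffold, int(pos), ref, alt, pop, rc, ac, dp))
    if skipped:
        log.info("read_vcf_counts: skipped %d non-biallelic/indel records",
                 skipped)
    return pd.DataFrame(rows, columns=[
        "scaffold", "pos", "ref", "alt", "pop",
        "ref_count", "alt_count", "depth"])


# ---------------------------------------------------------------------------
# manifest helpers

def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(manifest: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
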