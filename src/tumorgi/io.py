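"""Plain-text fixtures: bedGraph coverage, BED intervals, VCF variants.

All interval files are 0-based half-open (BED convention); VCF positions are
1-based.  ``write_fixture_set`` emits a complete simulated run that
round-trips losslessly through the readers here.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .sim import GenomeModel, LineageTruth

__all__ = [
    "write_fixture_set",
    "write_coverage",
    "read_coverage",
    "write_bed",
    "read_bed",
    "write_snp_vcf",
    "read_snp_vcf",
    "read_samplesheet",
]


def write_coverage(path, model: GenomeModel, values: np.ndarray) -> None:
    df = pd.DataFrame(
        {
            "chrom": model.bin_chrom,
            "start": model.bin_start,
            "end": model.bin_end,
            "mean_coverage": values,
        }
    )
    df.to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")


def read_coverage(path, model: GenomeModel) -> np.ndarray:
    """Read a 4-column bedGraph-like TSV back onto the model's bin grid."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "mean_coverage"],
            dtype={"chrom": str},
        )
    except OSError as exc:
        raise OSError(f"cannot read coverage file {path}: {exc}") from exc
    values = np.full(model.n_bins_total, np.nan)
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in model.chrom_lengths:
            raise ValueError(f"{path}: unknown chromosome {chrom!r}")
        sl = model.arm_slice(chrom)
        idx = sub["start"].to_numpy() // model.bin_size
        values[sl.start + idx] = sub["mean_coverage"].to_numpy()
    if np.isnan(values).any():
        raise ValueError(f"{path}: coverage does not cover the full bin grid")
    return values


def write_bed(path, intervals: pd.DataFrame, name_col: str | None = "id") -> None:
    cols = intervals[["chrom", "start", "end"]].copy()
    if name_col and name_col in intervals:
        cols["name"] = intervals[name_col]
    cols.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = ["chrom", "start", "end", "id"][: df.shape[1]]
    return df


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AAF,Number=1,Type=Float,Description="Alternative allele fraction">
##INFO=<ID=F1R2,Number=1,Type=Integer,Description="Alt-supporting reads, F1R2 orientation">
##INFO=<ID=F2R1,Number=1,Type=Integer,Description="Alt-supporting reads, F2R1 orientation">
##INFO=<ID=CLASS,Number=1,Type=String,Description="Region class annotation">
"""


def write_snp_vcf(path, snps: pd.DataFrame, contigs: dict | None = None) -> None:
    """Write somatic SNVs as VCF v4.2 with AAF/F1R2/F2R1/CLASS INFO keys."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in snps.sort_values(["chrom", "pos"]).itertuples(index=False):
            info = (
                f"AAF={row.aaf:.4f};F1R2={int(row.f1r2)};F2R1={int(row.f2r1)}"
                f";CLASS={row.region_class}"
            )
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t{info}\n"
            )


def read_snp_vcf(path) -> pd.DataFrame:
    rows = []
    for rec in VCF(str(path)):
        rows.append(
            (
                rec.CHROM,
                rec.POS,
                rec.REF,
                rec.ALT[0] if rec.ALT else ".",
                float(rec.INFO.get("AAF", np.nan)),
                int(rec.INFO.get("F1R2", 0)),
                int(rec.INFO.get("F2R1", 0)),
                rec.INFO.get("CLASS", "unknown"),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "aaf", "f1r2", "f2r1", "region_class"],
    )


def read_samplesheet(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"timepoint": int})


def write_fixture_set(outdir, model: GenomeModel, truth: LineageTruth,
                      coverages: dict) -> dict:
    """Emit a full simulated run as plain-text files under ``outdir``.

    Returns a manifest of paths.  Layout: genome tracks + annotation BEDs at
    the top level, coverage bedGraphs under coverage/, per-sample truth under
    truth/.
    """
    out = Path(outdir)
    for sub in ("coverage", "truth"):
        os.makedirs(out / sub, exist_ok=True)
    manifest = {}

    sizes = pd.DataFrame(
        {"chrom": list(model.chrom_lengths), "length": list(model.chrom_lengths.values())}
    )
    sizes.to_csv(out / "chrom_sizes.tsv", sep="\t", index=False)
    tracks = pd.DataFrame(
        {
            "chrom": model.bin_chrom,
            "start": model.bin_start,
            "end": model.bin_end,
            "gc": model.gc,
            "mappability": model.mappability,
        }
    )
    tracks.to_csv(out / "tracks.tsv", sep="\t", index=False, float_format="%.6f")
    manifest["chrom_sizes"] = out / "chrom_sizes.tsv"
    manifest["tracks"] = out / "tracks.tsv"

    for name, df in (
        ("ur", model.ur_intervals),
        ("repeats", model.repeat_intervals),
        ("genes", model.gene_intervals),
        ("exome", model.exome_intervals),
    ):
        write_bed(out / f"{name}.bed", df)
        manifest[name] = out / f"{name}.bed"

    sheet = pd.DataFrame(
        [
            (s.sample_id, s.line, s.timepoint, s.role, s.donor_id)
            for s in truth.samples
        ],
        columns=["sample_id", "line", "timepoint", "role", "donor_id"],
    )
    sheet.to_csv(out / "samples.tsv", sep="\t", index=False)
    manifest["samples"] = out / "samples.tsv"

    contigs = model.chrom_lengths
    for s in truth.samples:
        cov_path = out / "coverage" / f"{s.sample_id}.bedgraph"
        write_coverage(cov_path, model, coverages[s.sample_id])
        manifest[f"coverage/{s.sample_id}"] = cov_path
        if s.role == "tumor":
            cnvs = truth.cnvs_for(s.sample_id)
            bed = cnvs.rename(columns={"state": "id"})
            write_bed(out / "truth" / f"{s.sample_id}.cnv.bed", bed)
            write_snp_vcf(
                out / "truth" / f"{s.sample_id}.snp.vcf",
                truth.snps_for(s.sample_id),
                contigs=contigs,
            )
            manifest[f"truth_cnv/{s.sample_id}"] = out / "truth" / f"{s.sample_id}.cnv.bed"
            manifest[f"truth_snp/{s.sample_id}"] = out / "truth" / f"{s.sample_id}.snp.vcf"
    return manifest
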