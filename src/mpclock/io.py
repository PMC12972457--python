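"""Readers and writers for the package's on-disk formats.

Conventions: internal coordinates are 0-based; VCF is written/read as
1-based and converted once at this boundary; BED is 0-based half-open.
Tables are tab-separated with header rows.  All writers round-trip with
the readers in this module.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import ClockConfig, SimConfig, VafLaw
from .containers import PILEUP_COLUMNS, BetaMatrix, TruthState, VariantRecord
from .errors import InputError

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def write_vcf(records: list[VariantRecord], path: str | Path) -> None:
    """Write variant records as a minimal uncompressed VCF (1-based POS)."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            info = "." if np.isnan(r.vaf) else f"VAF={r.vaf:.6g}"
            fh.write(f"{r.chrom}\t{r.pos + 1}\t.\t{r.ref}\t{r.alt}\t.\t.\t{info}\n")


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read variant records from a VCF via cyvcf2 (positions to 0-based)."""
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises opaque errors on bad input
        raise InputError(f"cannot parse VCF {path}: {exc}") from exc
    out = []
    for v in vcf:
        alt = v.ALT[0] if v.ALT else "."
        vaf = v.INFO.get("VAF")
        out.append(
            VariantRecord(
                v.CHROM, v.POS - 1, v.REF, alt, float(vaf) if vaf is not None else float("nan")
            )
        )
    return out


def write_bed(
    intervals: list[tuple[str, int, int]], path: str | Path, names: list[str] | None = None
) -> None:
    """Write (chrom, start, end) 0-based half-open intervals as BED."""
    with open(path, "w") as fh:
        for i, (chrom, start, end) in enumerate(intervals):
            if start >= end:
                raise InputError(f"BED interval must satisfy start < end: {chrom}:{start}-{end}")
            name = names[i] if names is not None else f"iv{i}"
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file into a DataFrame with chrom/start/end[/name]."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"][:4], usecols=[0, 1, 2, 3],
        dtype={0: str}, engine="python",
    )
    if (df["start"] >= df["end"]).any():
        raise InputError(f"BED file {path} has intervals with start >= end")
    return df


def write_loci_bed(truth: TruthState, path: str | Path) -> None:
    """Write the truth loci as 1-bp BED intervals named by locus index."""
    rows = [
        (str(r.chrom), int(r.pos), int(r.pos) + 1)
        for r in truth.loci.itertuples(index=False)
    ]
    write_bed(rows, path, names=[f"L{i:05d}" for i in range(len(rows))])


def write_pileup(pileup: pd.DataFrame, path: str | Path) -> None:
    pileup[PILEUP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_pileup(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"pileup table {path} lacks columns {sorted(missing)}")
    return df[PILEUP_COLUMNS]


def write_beta_matrix(bm: BetaMatrix, values_path: str | Path, ages_path: str | Path) -> None:
    bm.values.to_csv(values_path, sep="\t", index_label="locus")
    bm.ages.rename("age_months").to_frame().to_csv(ages_path, sep="\t", index_label="sample")


def read_beta_matrix(
    values_path: str | Path, ages_path: str | Path, channel: str
) -> BetaMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="locus")
    ages_df = pd.read_csv(ages_path, sep="\t", index_col="sample")
    if "age_months" not in ages_df.columns:
        raise InputError(f"ages table {ages_path} lacks an age_months column")
    ages = ages_df["age_months"]
    if set(values.columns) != set(ages.index):
        raise InputError("sample ids differ between values and ages tables")
    return BetaMatrix(values=values[list(ages.index)], ages=ages, channel=channel)


def save_config(sim: SimConfig, path: str | Path, clock: ClockConfig | None = None) -> None:
    doc: dict = {"sim": dataclasses.asdict(sim)}
    doc["sim"]["age_range"] = list(sim.age_range)
    if clock is not None:
        doc["clock"] = dataclasses.asdict(clock)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_config(path: str | Path) -> tuple[SimConfig, ClockConfig | None]:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    sim_kw = dict(doc.get("sim", {}))
    if "age_range" in sim_kw:
        sim_kw["age_range"] = tuple(sim_kw["age_range"])
    if "vaf_law" in sim_kw and isinstance(sim_kw["vaf_law"], dict):
        law = dict(sim_kw["vaf_law"])
        if "clonal_vafs" in law:
            law["clonal_vafs"] = tuple(law["clonal_vafs"])
        sim_kw["vaf_law"] = VafLaw(**law)
    for key in ("variant_type_probs",):
        if key in sim_kw:
            sim_kw[key] = tuple(sim_kw[key])
    sim = SimConfig(**sim_kw)
    clock = None
    if "clock" in doc:
        clock_kw = dict(doc["clock"])
        if "l1_ratios" in clock_kw:
            clock_kw["l1_ratios"] = tuple(clock_kw["l1_ratios"])
        clock = ClockConfig(**clock_kw)
    return sim, clock
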