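"""Variant-table IO and the pre-scan site filters.

A variant table is a pandas DataFrame with one row per biallelic site and the
columns ``chrom, pos, ref, alt, site_type`` plus ``<pool>_ref / <pool>_alt``
read depths for the four pools ``gp05, pp05, green, purple`` (the two parents
and the two extreme bulks). Coordinates are 1-based inclusive everywhere;
BED exports are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .simdata import POOLS

__all__ = [
    "DEFAULT_SAMPLES",
    "read_variants",
    "write_variants",
    "orient_pp05_allele",
    "filter_informative",
    "FilterReport",
    "window_density",
]

# VCF sample name for each internal pool key
DEFAULT_SAMPLES = {
    "gp05": "GP05",
    "pp05": "PP05",
    "green": "BULK_GREEN",
    "purple": "BULK_PURPLE",
}

_DEPTH_COLS = [f"{pool}_{al}" for pool in POOLS for al in ("ref", "alt")]
_COLS = ["chrom", "pos", "ref", "alt", "site_type"] + _DEPTH_COLS


def _site_type(ref: str, alt: str) -> str:
    return "SNP" if len(ref) == 1 and len(alt) == 1 else "InDel"


def read_variants(path, format: str = "vcf", samples: dict | None = None) -> pd.DataFrame:
    """Read a variant table from VCF 4.x (with per-sample AD) or TSV.

    Multiallelic VCF records are dropped. Missing samples or AD fields raise
    with the offending record's coordinates.
    """
    if format == "tsv":
        table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        missing = [c for c in _COLS if c not in table.columns]
        if missing:
            raise ValueError(f"TSV variant table missing columns: {missing}")
        return table[_COLS]
    if format != "vcf":
        raise ValueError(f"unknown format: {format!r}")

    samples = DEFAULT_SAMPLES if samples is None else samples
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        present = list(vcf.header.samples)
        absent = [s for s in samples.values() if s not in present]
        if absent:
            raise ValueError(f"VCF is missing sample(s) {absent}; found {present}")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue  # multiallelic / ref-only records dropped
            row = {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0],
                "site_type": _site_type(rec.ref, rec.alts[0]),
            }
            for pool, sample in samples.items():
                ad = rec.samples[sample].get("AD")
                if ad is None or len(ad) < 2 or ad[0] is None:
                    raise ValueError(f"missing AD for {sample} at {rec.chrom}:{rec.pos}")
                row[f"{pool}_ref"] = int(ad[0])
                row[f"{pool}_alt"] = int(ad[1])
            rows.append(row)
    return pd.DataFrame(rows, columns=_COLS)


def write_variants(
    table: pd.DataFrame,
    path,
    format: str = "vcf",
    contig_lengths: dict[str, int] | None = None,
    samples: dict | None = None,
) -> None:
    """Write a variant table as uncompressed VCF 4.2 (GT + AD) or TSV."""
    if format == "tsv":
        table[_COLS].to_csv(path, sep="\t", index=False)
        return
    if format != "vcf":
        raise ValueError(f"unknown format: {format!r}")

    samples = DEFAULT_SAMPLES if samples is None else samples
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">'
    )
    if contig_lengths is None:
        contig_lengths = {
            c: int(table.loc[table["chrom"] == c, "pos"].max())
            for c in pd.unique(table["chrom"])
        }
    for chrom, length in contig_lengths.items():
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    for sample in samples.values():
        header.add_sample(sample)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in table.itertuples(index=False):
            rec = out.new_record(
                contig=row.chrom, start=row.pos - 1, alleles=(row.ref, row.alt)
            )
            for pool, sample in samples.items():
                ref_n = int(getattr(row, f"{pool}_ref"))
                alt_n = int(getattr(row, f"{pool}_alt"))
                rec.samples[sample]["AD"] = (ref_n, alt_n)
                if pool == "gp05":
                    rec.samples[sample]["GT"] = (0, 0)
                elif pool == "pp05":
                    rec.samples[sample]["GT"] = (1, 1)
                else:
                    rec.samples[sample]["GT"] = (None,)
            out.write(rec)


def orient_pp05_allele(table: pd.DataFrame, e_max: float = 0.1) -> pd.Series:
    """Which allele ("ref"/"alt") the PP05 parent carries, from parental depths.

    A parent is called homozygous when its minor-allele read fraction is
    <= ``e_max``. Sites where either parent is ambiguous or the parents agree
    get ``None``.
    """
    out = np.full(len(table), None, dtype=object)
    calls = {}
    for pool in ("gp05", "pp05"):
        ref_n = table[f"{pool}_ref"].to_numpy(dtype=float)
        alt_n = table[f"{pool}_alt"].to_numpy(dtype=float)
        depth = ref_n + alt_n
        with np.errstate(invalid="ignore", divide="ignore"):
            alt_frac = np.where(depth > 0, alt_n / depth, np.nan)
        hom_ref = alt_frac <= e_max
        hom_alt = alt_frac >= 1.0 - e_max
        call = np.full(len(table), -1)
        call[hom_ref] = 0
        call[hom_alt] = 1
        calls[pool] = call
    opposite = (calls["gp05"] >= 0) & (calls["pp05"] >= 0) & (calls["gp05"] != calls["pp05"])
    out[opposite & (calls["pp05"] == 1)] = "alt"
    out[opposite & (calls["pp05"] == 0)] = "ref"
    return pd.Series(out, index=table.index, name="pp05_allele")


@dataclass
class FilterReport:
    """Per-rule counts of sites removed by :func:`filter_informative`."""

    n_input: int
    parent_not_informative: int
    bulk_depth_out_of_range: int
    n_kept: int

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def filter_informative(
    table: pd.DataFrame,
    min_depth: int = 10,
    max_depth: float | None = None,
    e_max: float = 0.1,
) -> tuple[pd.DataFrame, FilterReport]:
    """Keep sites informative for bulk comparison.

    Rules, applied in order: (1) parents must be confidently opposite
    homozygotes (minor-allele read fraction <= e_max in each parent);
    (2) both bulk depths within [min_depth, max_depth] (max_depth defaults to
    3x the mean bulk depth of the input). Adds the ``pp05_allele`` orientation
    column. Idempotent by construction.
    """
    depth_g = (table["green_ref"] + table["green_alt"]).to_numpy(dtype=float)
    depth_p = (table["purple_ref"] + table["purple_alt"]).to_numpy(dtype=float)
    if max_depth is None:
        max_depth = 3.0 * float(np.mean(np.concatenate([depth_g, depth_p]))) if len(table) else np.inf

    orient = orient_pp05_allele(table, e_max=e_max)
    informative = orient.notna().to_numpy()
    depth_ok = (
        (depth_g >= min_depth) & (depth_g <= max_depth)
        & (depth_p >= min_depth) & (depth_p <= max_depth)
    )
    keep = informative & depth_ok
    out = table.loc[keep].copy()
    out["pp05_allele"] = orient[keep]
    report = FilterReport(
        n_input=len(table),
        parent_not_informative=int((~informative).sum()),
        bulk_depth_out_of_range=int((informative & ~depth_ok).sum()),
        n_kept=int(keep.sum()),
    )
    return out.reset_index(drop=True), report


def window_density(
    sites: pd.DataFrame,
    chrom_lengths: dict[str, int] | None = None,
    window: int = 1_000_000,
    step: int = 100_000,
) -> pd.DataFrame:
    """Sliding-window site counts (window 1 Mb, step 100 kb by default).

    Windows start on the 1-based grid 1, 1+step, 1+2*step, ... and span
    [start, start+window-1]; a site at position p is counted in every window
    whose span covers p.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if chrom_lengths is None:
        chrom_lengths = {
            c: int(sites.loc[sites["chrom"] == c, "pos"].max())
            for c in pd.unique(sites["chrom"])
        }
    frames = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(1, max(length - window + 1, 1) + 1, step, dtype=np.int64)
        pos = np.sort(sites.loc[sites["chrom"] == chrom, "pos"].to_numpy())
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window - 1, side="right")
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "window_start": starts,
                    "window_end": starts + window - 1,
                    "n_sites": hi - lo,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
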