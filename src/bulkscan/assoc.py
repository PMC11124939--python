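"""Bulked-segregant association statistics and the genome scan model.

Two statistics are computed per informative site from the pooled read depths
of the two extreme bulks:

* the SNP-index of each bulk (fraction of reads carrying the PP05 parental
  allele) and their difference Δ(SNP-index) = index_purple − index_green,
  compared against simulation-based two-sided confidence thresholds of the
  null (no selection) F2 pooling model, computed per sequencing depth;
* the Euclidean distance ED between the bulk allele-frequency vectors,
  de-noised by raising to a power k (default 5) and thresholded at
  median + 3·SD of the smoothed values genome-wide.

Both raw tracks are smoothed along each chromosome by distance-weighted
local regression (tricube kernel, fixed physical bandwidth). Regions are
maximal marker runs whose smoothed statistic exceeds the threshold; the two
methods' regions are intersected to give the final candidate interval(s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .intervals import Region, intersect_regions, merge_regions, union_regions, regions_to_frame

__all__ = [
    "snp_index",
    "ed",
    "ed_power",
    "fit_distance",
    "simulate_ci",
    "DeltaCI",
    "ed_threshold",
    "call_regions",
    "intersect_regions",
    "ScanTrack",
    "BulkSegregantScan",
    "BulkScanResults",
]


def _oriented_pp05_counts(sites: pd.DataFrame, pool: str) -> tuple[np.ndarray, np.ndarray]:
    """(PP05-allele reads, total depth) for one bulk, using the orientation
    column written by the informative-site filter."""
    if "pp05_allele" not in sites.columns or sites["pp05_allele"].isna().any():
        raise ValueError(
            "sites are not oriented: run filter_informative first "
            "(parents must be opposite homozygotes)"
        )
    ref_n = sites[f"{pool}_ref"].to_numpy(dtype=float)
    alt_n = sites[f"{pool}_alt"].to_numpy(dtype=float)
    pp_is_alt = (sites["pp05_allele"] == "alt").to_numpy()
    pp = np.where(pp_is_alt, alt_n, ref_n)
    return pp, ref_n + alt_n


def snp_index(sites: pd.DataFrame) -> pd.DataFrame:
    """Per-site SNP-index of each bulk and Δ(SNP-index) = purple − green.

    Zero-depth pools yield NaN indices flagged ``ok=False``; those records
    are excluded from smoothing.
    """
    pp_g, depth_g = _oriented_pp05_counts(sites, "green")
    pp_p, depth_p = _oriented_pp05_counts(sites, "purple")
    with np.errstate(invalid="ignore", divide="ignore"):
        idx_g = np.where(depth_g > 0, pp_g / depth_g, np.nan)
        idx_p = np.where(depth_p > 0, pp_p / depth_p, np.nan)
    out = sites[["chrom", "pos", "site_type"]].copy()
    out["index_green"] = idx_g
    out["index_purple"] = idx_p
    out["delta"] = idx_p - idx_g
    out["depth_green"] = depth_g.astype(int)
    out["depth_purple"] = depth_p.astype(int)
    out["ok"] = (depth_g > 0) & (depth_p > 0)
    return out


def ed(sites: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance between the bulk allele-frequency vectors.

    For a biallelic site ED = sqrt((f_ref_g−f_ref_p)² + (f_alt_g−f_alt_p)²)
    = sqrt(2)·|Δf_alt|, bounded by sqrt(2). Zero-depth pools flagged NaN.
    """
    ref_g = sites["green_ref"].to_numpy(dtype=float)
    alt_g = sites["green_alt"].to_numpy(dtype=float)
    ref_p = sites["purple_ref"].to_numpy(dtype=float)
    alt_p = sites["purple_alt"].to_numpy(dtype=float)
    depth_g = ref_g + alt_g
    depth_p = ref_p + alt_p
    with np.errstate(invalid="ignore", divide="ignore"):
        fg = np.where(depth_g > 0, alt_g / depth_g, np.nan)
        fp = np.where(depth_p > 0, alt_p / depth_p, np.nan)
    out = sites[["chrom", "pos", "site_type"]].copy()
    out["ed"] = np.sqrt(np.square(fg - fp) + np.square((1 - fg) - (1 - fp)))
    out["ok"] = (depth_g > 0) & (depth_p > 0)
    return out


def ed_power(records: pd.DataFrame, k: float = 5.0) -> pd.DataFrame:
    """Raise ED to the power k (background-noise suppression; k=1 is identity)."""
    if k < 1:
        raise ValueError("power k must be >= 1")
    out = records.copy()
    out["ed_k"] = np.power(out["ed"].to_numpy(dtype=float), k)
    return out


def fit_distance(
    positions: np.ndarray,
    values: np.ndarray,
    bandwidth_bp: float = 2_000_000.0,
    degree: int = 0,
) -> np.ndarray:
    """Distance-weighted local regression along one chromosome.

    Tricube kernel w = (1−(d/h)³)³ on physical distance d within bandwidth h,
    local-constant (degree 0, default) or local-linear (degree 1), evaluated
    at every input position. Missing (NaN) values are excluded from the
    support but still receive a fitted value from their neighbours.
    """
    if bandwidth_bp <= 0:
        raise ValueError("bandwidth must be positive")
    if degree not in (0, 1):
        raise ValueError("degree must be 0 or 1")
    pos = np.asarray(positions, dtype=float)
    val = np.asarray(values, dtype=float)
    ok = np.isfinite(val)
    if ok.sum() < 2:
        raise ValueError("need >= 2 non-missing values per chromosome")
    sp = pos[ok]
    sv = val[ok]
    order = np.argsort(sp, kind="mergesort")
    sp, sv = sp[order], sv[order]

    fitted = np.empty(pos.size)
    lo = np.searchsorted(sp, pos - bandwidth_bp, side="left")
    hi = np.searchsorted(sp, pos + bandwidth_bp, side="right")
    for i in range(pos.size):
        a, b = lo[i], hi[i]
        if a == b:  # no support in the window: fall back to nearest neighbour
            j = np.clip(np.searchsorted(sp, pos[i]), 0, sp.size - 1)
            if j > 0 and abs(sp[j - 1] - pos[i]) <= abs(sp[j] - pos[i]):
                j -= 1
            fitted[i] = sv[j]
            continue
        d = (sp[a:b] - pos[i]) / bandwidth_bp
        w = (1.0 - np.abs(d) ** 3) ** 3
        sw = w.sum()
        if sw <= 0:
            fitted[i] = sv[np.argmin(np.abs(sp - pos[i]))]
        elif degree == 0:
            fitted[i] = w @ sv[a:b] / sw
        else:
            x = sp[a:b] - pos[i]
            xbar = w @ x / sw
            ybar = w @ sv[a:b] / sw
            sxx = w @ np.square(x - xbar)
            if sxx <= 0:
                fitted[i] = ybar
            else:
                slope = w @ ((x - xbar) * (sv[a:b] - ybar)) / sxx
                fitted[i] = ybar - slope * xbar
    return fitted


@dataclass
class DeltaCI:
    """Simulated null thresholds for |Δ(SNP-index)| on a depth grid."""

    depths: np.ndarray
    levels: tuple[float, ...]
    thresholds: np.ndarray  # (n_depths, n_levels)
    n_bulk: int
    reps: int

    def at(self, depth, level: float) -> np.ndarray:
        """Threshold for |delta| at the given depth(s), linearly interpolated
        between grid depths (clamped at the grid ends)."""
        if level not in self.levels:
            raise ValueError(f"level {level} not simulated (have {self.levels})")
        col = self.thresholds[:, self.levels.index(level)]
        return np.interp(np.asarray(depth, dtype=float), self.depths, col)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"depth": self.depths})
        for j, level in enumerate(self.levels):
            out[f"q{level}"] = self.thresholds[:, j]
        return out


def simulate_ci(
    depths,
    n_bulk: int,
    reps: int = 10_000,
    levels: tuple[float, ...] = (0.95, 0.99),
    seed=None,
) -> DeltaCI:
    """Monte-Carlo null distribution of Δ(SNP-index) under no selection.

    Per replicate, each bulk's ``n_bulk`` F2 genotypes are drawn from the
    Mendelian 1:2:1, the bulk allele frequency is the mean dosage, reads are
    Binomial(depth, frequency), and delta is the read-fraction difference.
    The threshold at each level is the symmetric two-sided quantile of
    |delta| at that depth.
    """
    for level in levels:
        if not (0.0 < level <= 1.0):
            raise ValueError(f"invalid confidence level {level}")
    if reps < 1000:
        raise ValueError("reps must be >= 1000 for stable quantiles")
    depths = np.unique(np.asarray(depths, dtype=int))
    if depths.size == 0 or depths.min() < 1:
        raise ValueError("depths must be >= 1")
    rng = np.random.default_rng(seed)
    # genotype sampling is depth-independent: draw bulk frequencies once
    dosage = rng.choice([0.0, 0.5, 1.0], p=[0.25, 0.5, 0.25], size=(reps, 2, n_bulk))
    freq = dosage.mean(axis=2)  # (reps, 2)
    thresholds = np.empty((depths.size, len(levels)))
    for i, d in enumerate(depths):
        reads = rng.binomial(d, freq)
        delta = (reads[:, 1] - reads[:, 0]) / d
        thresholds[i] = np.quantile(np.abs(delta), levels)
    return DeltaCI(
        depths=depths.astype(float),
        levels=tuple(levels),
        thresholds=thresholds,
        n_bulk=n_bulk,
        reps=reps,
    )


def ed_threshold(fitted_values) -> float:
    """Association threshold: median + 3·sample SD (n−1) of the fitted values."""
    vals = np.asarray(fitted_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need >= 2 fitted values")
    return float(np.median(vals) + 3.0 * np.std(vals, ddof=1))


@dataclass
class ScanTrack:
    """Per-chromosome raw and fitted statistic values plus threshold metadata."""

    chrom: str
    positions: np.ndarray
    raw: np.ndarray
    fitted: np.ndarray
    statistic: str  # "delta_snp_index" | "ed_k"
    site_type: str
    params: dict = dc_field(default_factory=dict)
    threshold: float | np.ndarray | None = None
    threshold_rule: str = ""

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.positions,
                "raw": self.raw,
                "fitted": self.fitted,
                "statistic": self.statistic,
                "site_type": self.site_type,
            }
        )
        thr = self.threshold
        out["threshold"] = np.broadcast_to(
            np.asarray(thr if thr is not None else np.nan, dtype=float), (len(out),)
        )
        return out


def call_regions(
    track: ScanTrack,
    threshold=None,
    gap_bp: int = 1_000_000,
    min_sites: int = 10,
    two_sided: bool = False,
) -> list[Region]:
    """Maximal runs of consecutive markers whose fitted value exceeds the
    threshold (``|fitted|`` when two_sided); runs separated by < gap_bp are
    merged, runs with fewer than min_sites markers dropped. Region endpoints
    are the first/last marker positions of the run."""
    thr = track.threshold if threshold is None else threshold
    if thr is None:
        raise ValueError("no threshold on track and none supplied")
    fitted = np.asarray(track.fitted, dtype=float)
    stat = np.abs(fitted) if two_sided else fitted
    above = np.zeros(fitted.size, dtype=bool)
    finite = np.isfinite(stat)
    above[finite] = stat[finite] > np.broadcast_to(np.asarray(thr, dtype=float), stat.shape)[finite]

    regions: list[Region] = []
    pos = np.asarray(track.positions)
    i = 0
    while i < above.size:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < above.size and above[j + 1]:
            j += 1
        regions.append(
            Region(
                chrom=track.chrom,
                start=int(pos[i]),
                end=int(pos[j]),
                method=track.statistic,
                n_sites=int(j - i + 1),
                peak=float(np.nanmax(stat[i : j + 1])),
            )
        )
        i = j + 1
    regions = merge_regions(regions, gap_bp=gap_bp)
    return [r for r in regions if r.n_sites >= min_sites]


# ---------------------------------------------------------------------------
# model / results surface


class BulkSegregantScan:
    """Genome-wide bulked-segregant association scan on a variant table.

    Parameters
    ----------
    sites : DataFrame
        Informative, oriented variant table (output of
        :func:`bulkscan.variant_io.filter_informative`).
    n_bulk : int
        Number of F2 plants per bulk (used by the null-model simulation).
    """

    def __init__(self, sites: pd.DataFrame, n_bulk: int = 30):
        if "pp05_allele" not in sites.columns:
            raise ValueError("sites must carry the pp05_allele orientation column")
        self.sites = sites.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        self.n_bulk = int(n_bulk)

    def fit(
        self,
        method: str = "both",
        k: float = 5.0,
        bandwidth_bp: float = 2_000_000.0,
        ci_levels: tuple[float, ...] = (0.95, 0.99),
        call_level: float = 0.99,
        reps: int = 10_000,
        gap_bp: int = 1_000_000,
        min_sites: int = 10,
        degree: int = 0,
        seed=None,
    ) -> "BulkScanResults":
        """Run the scan and return fitted tracks, thresholds and regions.

        method : "ed", "snpindex" or "both". SNP and InDel sites are scanned
        separately and their regions union-merged within each method before
        the two methods are intersected.
        """
        if method not in ("ed", "snpindex", "both"):
            raise ValueError(f"unknown method {method!r}")
        if call_level not in ci_levels:
            ci_levels = tuple(sorted(set(ci_levels) | {call_level}))

        idx_table = snp_index(self.sites)
        ed_table = ed_power(ed(self.sites), k=k)
        tracks: list[ScanTrack] = []
        regions_delta: list[Region] = []
        regions_ed: list[Region] = []

        ci = None
        if method in ("snpindex", "both"):
            min_depth = np.minimum(
                idx_table["depth_green"].to_numpy(), idx_table["depth_purple"].to_numpy()
            )
            grid = np.unique(min_depth[min_depth >= 1])
            ci = simulate_ci(grid, n_bulk=self.n_bulk, reps=reps, levels=ci_levels, seed=seed)

        for site_type in pd.unique(self.sites["site_type"]):
            for chrom in pd.unique(self.sites["chrom"]):
                sel_idx = idx_table[
                    (idx_table["chrom"] == chrom) & (idx_table["site_type"] == site_type)
                ]
                if len(sel_idx) < 2:
                    continue
                pos = sel_idx["pos"].to_numpy()
                if method in ("snpindex", "both"):
                    fitted = fit_distance(pos, sel_idx["delta"].to_numpy(), bandwidth_bp, degree)
                    depth = np.minimum(
                        sel_idx["depth_green"].to_numpy(), sel_idx["depth_purple"].to_numpy()
                    ).clip(min=1)
                    thr = ci.at(depth, call_level)
                    track = ScanTrack(
                        chrom=chrom,
                        positions=pos,
                        raw=sel_idx["delta"].to_numpy(),
                        fitted=fitted,
                        statistic="delta_snp_index",
                        site_type=site_type,
                        params={"bandwidth_bp": bandwidth_bp, "degree": degree},
                        threshold=thr,
                        threshold_rule=f"simulated {call_level:g} two-sided CI per depth",
                    )
                    tracks.append(track)
                    regions_delta += call_regions(
                        track, gap_bp=gap_bp, min_sites=min_sites, two_sided=True
                    )
                if method in ("ed", "both"):
                    sel_ed = ed_table[
                        (ed_table["chrom"] == chrom) & (ed_table["site_type"] == site_type)
                    ]
                    fitted = fit_distance(pos, sel_ed["ed_k"].to_numpy(), bandwidth_bp, degree)
                    tracks.append(
                        ScanTrack(
                            chrom=chrom,
                            positions=pos,
                            raw=sel_ed["ed_k"].to_numpy(),
                            fitted=fitted,
                            statistic="ed_k",
                            site_type=site_type,
                            params={"bandwidth_bp": bandwidth_bp, "degree": degree, "k": k},
                        )
                    )

        # one genome-wide threshold per marker type: the InDel scan is the
        # same method run in parallel, judged against its own fitted values
        ed_thr: dict[str, float] = {}
        if method in ("ed", "both"):
            for site_type in pd.unique(self.sites["site_type"]):
                type_tracks = [
                    t for t in tracks if t.statistic == "ed_k" and t.site_type == site_type
                ]
                if not type_tracks:
                    continue
                thr = ed_threshold(np.concatenate([t.fitted for t in type_tracks]))
                ed_thr[site_type] = thr
                for t in type_tracks:
                    t.threshold = thr
                    t.threshold_rule = "median + 3*SD of fitted values, genome-wide"
                    regions_ed += call_regions(t, gap_bp=gap_bp, min_sites=min_sites)

        regions_delta = union_regions(regions_delta, method="snp_index")
        regions_ed = union_regions(regions_ed, method="ed")
        if method == "both":
            intersection, total_mb = intersect_regions(regions_ed, regions_delta)
        elif method == "ed":
            intersection, total_mb = regions_ed, round(
                sum(r.length_bp for r in regions_ed) / 1e6, 2
            )
        else:
            intersection, total_mb = regions_delta, round(
                sum(r.length_bp for r in regions_delta) / 1e6, 2
            )
        return BulkScanResults(
            model=self,
            method=method,
            tracks=tracks,
            delta_ci=ci,
            ed_thresholds=ed_thr,
            regions_ed=regions_ed,
            regions_delta=regions_delta,
            intersection=intersection,
            intersection_mb=total_mb,
            snp_index_table=idx_table,
            ed_table=ed_table,
            params={
                "method": method,
                "k": k,
                "bandwidth_bp": bandwidth_bp,
                "ci_levels": list(ci_levels),
                "call_level": call_level,
                "reps": reps,
                "gap_bp": gap_bp,
                "min_sites": min_sites,
                "degree": degree,
                "n_bulk": self.n_bulk,
                "seed": seed,
            },
        )


@dataclass
class BulkScanResults:
    """Fitted tracks, thresholds and called regions of a bulk-segregant scan."""

    model: BulkSegregantScan
    method: str
    tracks: list[ScanTrack]
    delta_ci: DeltaCI | None
    ed_thresholds: dict[str, float]
    regions_ed: list[Region]
    regions_delta: list[Region]
    intersection: list[Region]
    intersection_mb: float
    snp_index_table: pd.DataFrame
    ed_table: pd.DataFrame
    params: dict

    def tracks_frame(self) -> pd.DataFrame:
        return pd.concat([t.to_frame() for t in self.tracks], ignore_index=True)

    def summary(self) -> str:
        lines = [
            "Bulked-segregant association scan",
            "=================================",
            f"sites:                 {len(self.model.sites)}"
            f" ({(self.model.sites['site_type'] == 'SNP').sum()} SNP,"
            f" {(self.model.sites['site_type'] == 'InDel').sum()} InDel)",
            f"method:                {self.method}",
            f"smoother:              tricube local regression,"
            f" bandwidth {self.params['bandwidth_bp'] / 1e6:g} Mb",
        ]
        if self.ed_thresholds:
            thr_txt = ", ".join(f"{st}: {v:.4g}" for st, v in self.ed_thresholds.items())
            lines.append(
                f"ED^{self.params['k']:g} threshold:      {thr_txt} (median + 3*SD of fitted)"
            )
            lines.append(f"ED regions:            {_fmt_regions(self.regions_ed)}")
        if self.delta_ci is not None:
            lines.append(
                f"delta threshold:       simulated {self.params['call_level']:g}"
                f" CI, {self.params['reps']} reps, per depth"
            )
            lines.append(f"delta regions:         {_fmt_regions(self.regions_delta)}")
        lines.append(
            f"intersection:          {_fmt_regions(self.intersection)}"
            f" (total {self.intersection_mb:.2f} Mb)"
        )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Simple per-chromosome tracks figure (fitted statistic vs position)."""
        import matplotlib.pyplot as plt

        stats = sorted({t.statistic for t in self.tracks})
        fig, axes = plt.subplots(len(stats), 1, figsize=(9, 2.8 * len(stats)), squeeze=False)
        for ax_, stat in zip(axes[:, 0], stats):
            for t in self.tracks:
                if t.statistic != stat:
                    continue
                ax_.plot(t.positions / 1e6, t.fitted, lw=0.8, label=f"{t.chrom} {t.site_type}")
                if t.threshold is not None:
                    thr = np.broadcast_to(np.asarray(t.threshold, float), t.positions.shape)
                    ax_.plot(t.positions / 1e6, thr, lw=0.6, ls="--", color="grey")
            ax_.set_ylabel(stat)
            ax_.set_xlabel("position (Mb)")
            ax_.legend(fontsize=7)
        fig.tight_layout()
        return fig

    def to_dir(self, outdir) -> None:
        """Write per-site statistics, tracks and regions (TSV + BED)."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.snp_index_table.to_csv(outdir / "snp_index.tsv", sep="\t", index=False)
        self.ed_table.to_csv(outdir / "ed.tsv", sep="\t", index=False)
        self.tracks_frame().to_csv(outdir / "tracks.tsv", sep="\t", index=False)
        for name, regs in (
            ("regions_ed", self.regions_ed),
            ("regions_snp_index", self.regions_delta),
            ("regions_intersection", self.intersection),
        ):
            regions_to_frame(regs).to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
            with open(outdir / f"{name}.bed", "w") as fh:
                for r in regs:
                    chrom, start, end = r.to_bed_fields()
                    fh.write(f"{chrom}\t{start}\t{end}\t{r.method}\n")


def _fmt_regions(regions: list[Region]) -> str:
    if not regions:
        return "none"
    return "; ".join(f"{r.chrom}:{r.start}-{r.end} ({r.length_mb:.2f} Mb)" for r in regions)
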