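"""Marker co-segregation screening and candidate-interval refinement.

The wet-lab step this models: PCR markers (SSR/CAPS) inside the association
interval are genotyped on the bulked extreme F2 plants; a marker that never
recombines with the phenotype among the scored plants ("co-segregating")
must lie at or very near the causal locus, and the outermost co-segregating
markers bound the refined interval.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import Region

__all__ = ["score_cosegregation", "refine_interval", "FineMapError"]

_META_COLS = ["marker_id", "chrom", "pos", "marker_type"]


class FineMapError(ValueError):
    """Raised when the marker screen cannot refine the interval."""


def _genotype_matrix(markers: pd.DataFrame, individuals: list) -> np.ndarray:
    cols = [c for c in individuals]
    missing = [c for c in cols if c not in markers.columns]
    if missing:
        raise ValueError(f"individuals not genotyped in marker table: {missing[:5]}")
    g = markers[cols].to_numpy(dtype=float)
    g[g < 0] = np.nan  # -1 also accepted as missing
    bad = ~(np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0)))
    if bad.any():
        raise ValueError("genotype codes must be 0/1/2 or missing")
    return g


def score_cosegregation(
    markers: pd.DataFrame,
    bulk_low: list,
    bulk_high: list,
    model: str = "additive",
) -> pd.DataFrame:
    """Count recombinants per marker among the bulked extreme plants.

    Expected genotypes: green extremes (bulk_low) carry code 0; purple
    extremes (bulk_high) carry code 2 under the additive model, or {1, 2}
    under the dominant model. Missing calls are excluded from ``n_scored``;
    a marker is co-segregating iff it has zero recombinants. Markers with
    < 80% of the bulked plants scored are flagged low-confidence.
    """
    if model not in ("additive", "dominant"):
        raise ValueError(f"unknown model {model!r}")
    missing_meta = [c for c in _META_COLS if c not in markers.columns]
    if missing_meta:
        raise ValueError(f"marker table missing columns: {missing_meta}")
    g_low = _genotype_matrix(markers, list(bulk_low))
    g_high = _genotype_matrix(markers, list(bulk_high))

    ok_low = ~np.isnan(g_low)
    ok_high = ~np.isnan(g_high)
    n_scored = ok_low.sum(axis=1) + ok_high.sum(axis=1)
    if (n_scored == 0).any():
        bad = markers.loc[n_scored == 0, "marker_id"].tolist()
        raise FineMapError(f"marker(s) with all genotypes missing: {bad}")

    viol_low = ok_low & (g_low != 0.0)
    if model == "additive":
        viol_high = ok_high & (g_high != 2.0)
    else:
        viol_high = ok_high & (g_high == 0.0)
    n_rec = viol_low.sum(axis=1) + viol_high.sum(axis=1)

    n_total = len(list(bulk_low)) + len(list(bulk_high))
    out = markers[_META_COLS].copy()
    out["n_scored"] = n_scored.astype(int)
    out["n_recombinants"] = n_rec.astype(int)
    out["cosegregating"] = n_rec == 0
    out["low_confidence"] = n_scored < 0.8 * n_total
    return out.reset_index(drop=True)


def refine_interval(results: pd.DataFrame, region: Region) -> Region:
    """Bound the candidate region by the outermost co-segregating markers.

    Requires at least one co-segregating marker inside ``region``. The
    refined interval is [min pos, max pos] of all co-segregating markers on
    the region's chromosome (inclusive); a single marker gives a zero-length
    region.
    """
    coseg = results[(results["cosegregating"]) & (results["chrom"] == region.chrom)]
    inside = coseg[(coseg["pos"] >= region.start) & (coseg["pos"] <= region.end)]
    if inside.empty:
        raise FineMapError(
            "no co-segregating marker inside the region; "
            "design denser markers within the interval"
        )
    return Region(
        chrom=region.chrom,
        start=int(coseg["pos"].min()),
        end=int(coseg["pos"].max()),
        method="finemap",
        n_sites=int(len(coseg)),
        peak=float("nan"),
    )
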