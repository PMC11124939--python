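"""Desk-scale RNA-seq stage: FPKM, low-expression filtering, a lightweight
two-group negative-binomial DEG caller, replicate QC and term enrichment.

The DEG caller deliberately does not reproduce DESeq2. It keeps the parts of
that workflow that matter at this scale — median-of-ratios library-size
normalisation, a per-gene negative-binomial Wald test with method-of-moments
dispersion, Benjamini–Hochberg correction — and applies the standard
significance rule FDR < 0.01 and |log2FC| > 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "fpkm",
    "filter_low_expression",
    "size_factors",
    "call_degs",
    "replicate_correlation",
    "overlap_counts",
    "term_enrichment",
    "DifferentialExpression",
    "DiffExpressionResults",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples fragment counts with gene lengths and group labels.

    counts: integer DataFrame indexed by gene id, columns are sample ids.
    lengths: bp length per gene (aligned with counts.index).
    groups: group label per sample (aligned with counts.columns).
    """

    counts: pd.DataFrame
    lengths: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        self.lengths = self.lengths.reindex(self.counts.index)
        self.groups = self.groups.reindex(self.counts.columns)
        if self.lengths.isna().any():
            raise ValueError("every gene needs a length")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def samples_of(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def to_tsv(self, counts_path, groups_path) -> None:
        out = self.counts.copy()
        out.insert(0, "length", self.lengths)
        out.to_csv(counts_path, sep="\t", index_label="gene_id")
        self.groups.rename("group").to_csv(groups_path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, counts_path, groups_path) -> "ExpressionMatrix":
        tab = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
        groups = pd.read_csv(groups_path, sep="\t", index_col="sample")["group"]
        lengths = tab.pop("length")
        return cls(counts=tab, lengths=lengths, groups=groups)


def fpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM[g, s] = counts[g, s] * 1e9 / (length[g] * total[s]).
    """
    lengths = lengths.reindex(counts.index)
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero library size in sample(s): {bad}")
    return counts.mul(1e9, axis=0).div(lengths, axis=0).div(totals, axis=1)


def filter_low_expression(fpkm_table: pd.DataFrame, min_fpkm: float = 1.0) -> pd.Index:
    """Genes with FPKM >= min_fpkm in at least one sample (FPKM-below-threshold
    in *all* samples is the exclusion rule; the boundary value is kept)."""
    keep = (fpkm_table >= min_fpkm).any(axis=1)
    return fpkm_table.index[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors; total-count ratio fallback when
    no gene is expressed in every sample."""
    arr = counts.to_numpy(dtype=float)
    pos = (arr > 0).all(axis=1)
    if pos.sum() >= 1:
        loggeo = np.log(arr[pos]).mean(axis=1)
        s = np.exp(np.median(np.log(arr[pos]) - loggeo[:, None], axis=0))
    else:
        totals = arr.sum(axis=0)
        s = totals / np.exp(np.mean(np.log(totals)))
    return pd.Series(s, index=counts.columns, name="size_factor")


def _mom_dispersion(q: np.ndarray, groups: list[np.ndarray], min_disp: float) -> np.ndarray:
    """Pooled within-group method-of-moments NB dispersion per gene.

    For NB, var = mu + alpha * mu^2, so alpha = (var - mu) / mu^2 estimated
    within each group and averaged; floored at ``min_disp``.
    """
    alphas = np.zeros(q.shape[0])
    weight = 0.0
    for idx in groups:
        sub = q[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / np.square(m)
        a = np.where(np.isfinite(a), a, 0.0)
        w = len(idx) - 1
        alphas += w * a
        weight += w
    alphas /= max(weight, 1.0)
    return np.maximum(alphas, min_disp)


def call_degs(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    fdr_max: float = 0.01,
    lfc_min: float = 1.0,
    pseudocount: float = 0.5,
    min_disp: float = 1e-8,
) -> pd.DataFrame:
    """Two-group NB Wald differential-expression test (b vs a).

    log2fc = log2((mean_b + pseudocount) / (mean_a + pseudocount)) on
    size-factor-normalised counts; Wald SE from the delta method with the
    method-of-moments dispersion; BH-corrected p values; direction "up" iff
    log2fc > lfc_min and FDR < fdr_max ("down" symmetric, else "ns").
    """
    cols_a = matrix.samples_of(group_a)
    cols_b = matrix.samples_of(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    counts = matrix.counts[cols_a + cols_b]
    s = size_factors(counts)
    q = counts.div(s, axis=1).to_numpy(dtype=float)
    ia = np.arange(len(cols_a))
    ib = np.arange(len(cols_a), len(cols_a) + len(cols_b))

    m_a = q[:, ia].mean(axis=1)
    m_b = q[:, ib].mean(axis=1)
    alpha = _mom_dispersion(q, [ia, ib], min_disp)

    log2fc = np.log2((m_b + pseudocount) / (m_a + pseudocount))
    # delta method: var(log mean) ~= (1/mu + alpha)/n per group
    se2 = (1.0 / (m_a + pseudocount) + alpha) / len(ia) + (
        1.0 / (m_b + pseudocount) + alpha
    ) / len(ib)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.log((m_b + pseudocount) / (m_a + pseudocount)) / np.sqrt(se2)
    pvals = 2.0 * stats.norm.sf(np.abs(wald))
    fdr = multipletests(pvals, method="fdr_bh")[1]

    direction = np.where(
        (fdr < fdr_max) & (log2fc > lfc_min),
        "up",
        np.where((fdr < fdr_max) & (log2fc < -lfc_min), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "base_mean_a": m_a,
            "base_mean_b": m_b,
            "log2fc": log2fc,
            "dispersion": alpha,
            "stat": wald,
            "pvalue": pvals,
            "fdr": fdr,
            "direction": direction,
        },
        index=counts.index.rename("gene_id"),
    )


def replicate_correlation(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Pairwise Pearson r on log2(FPKM + 1); constant samples give NaN."""
    values = np.log2(fpkm(matrix.counts, matrix.lengths) + 1.0)
    if values.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    return values.corr(method="pearson")


def overlap_counts(set_a, set_b) -> tuple[int, int, int]:
    """Venn partition counts: (only in a, only in b, in both)."""
    a, b = set(set_a), set(set_b)
    return len(a - b), len(b - a), len(a & b)


def term_enrichment(
    selected,
    term_genes: dict[str, set],
    universe,
    p_max: float = 1e-4,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in ``selected``.

    p is the upper tail P(X >= k) of drawing k term members in a sample of
    len(selected) from the universe; Q is BH across terms. Significance flags
    at the configured p (GO convention) and Q (KEGG convention) thresholds.
    """
    universe = set(universe)
    selected = set(selected)
    missing = selected - universe
    if missing:
        raise ValueError(f"selected gene(s) absent from universe: {sorted(missing)[:5]}")
    if not term_genes:
        raise ValueError("no terms supplied")
    rows = []
    n_sel = len(selected)
    n_uni = len(universe)
    for term, genes in sorted(term_genes.items()):
        members = set(genes) & universe
        k = len(members & selected)
        p = stats.hypergeom.sf(k - 1, n_uni, len(members), n_sel)
        rows.append((term, len(members), k, p))
    out = pd.DataFrame(rows, columns=["term", "n_term", "n_hit", "pvalue"]).set_index("term")
    out["qvalue"] = multipletests(out["pvalue"].to_numpy(), method="fdr_bh")[1]
    out["significant_p"] = out["pvalue"] <= p_max
    out["significant_q"] = out["qvalue"] <= q_max
    return out


# ---------------------------------------------------------------------------
# model / results surface


class DifferentialExpression:
    """Two-group differential-expression model on a fragment-count matrix.

    Parameters
    ----------
    matrix : ExpressionMatrix
    group_a, group_b : str, optional
        Group labels to contrast (b vs a). Defaults to the two labels in
        ``matrix.groups`` in sorted order.
    """

    def __init__(self, matrix: ExpressionMatrix, group_a: str | None = None, group_b: str | None = None):
        self.matrix = matrix
        labels = sorted(matrix.groups.unique())
        if group_a is None or group_b is None:
            if len(labels) != 2:
                raise ValueError("specify group_a/group_b when there are not exactly 2 groups")
            group_a, group_b = labels
        self.group_a = group_a
        self.group_b = group_b

    def fit(
        self,
        fdr_max: float = 0.01,
        lfc_min: float = 1.0,
        min_fpkm: float = 1.0,
        **kwargs,
    ) -> "DiffExpressionResults":
        """Filter low-expression genes, test the remainder, return results."""
        fpkm_table = fpkm(self.matrix.counts, self.matrix.lengths)
        kept = filter_low_expression(fpkm_table, min_fpkm=min_fpkm)
        sub = ExpressionMatrix(
            counts=self.matrix.counts.loc[kept],
            lengths=self.matrix.lengths.loc[kept],
            groups=self.matrix.groups,
        )
        table = call_degs(sub, self.group_a, self.group_b, fdr_max=fdr_max, lfc_min=lfc_min, **kwargs)
        return DiffExpressionResults(
            model=self,
            table=table,
            fpkm=fpkm_table,
            n_filtered=len(self.matrix.counts) - len(kept),
            fdr_max=fdr_max,
            lfc_min=lfc_min,
        )


@dataclass
class DiffExpressionResults:
    """DEG table plus the filtering context that produced it."""

    model: DifferentialExpression
    table: pd.DataFrame
    fpkm: pd.DataFrame
    n_filtered: int
    fdr_max: float
    lfc_min: float
    _corr: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def up(self) -> pd.Index:
        return self.table.index[self.table["direction"] == "up"]

    @property
    def down(self) -> pd.Index:
        return self.table.index[self.table["direction"] == "down"]

    @property
    def degs(self) -> pd.Index:
        return self.table.index[self.table["direction"] != "ns"]

    def replicate_correlation(self) -> pd.DataFrame:
        if self._corr is None:
            self._corr = replicate_correlation(self.model.matrix)
        return self._corr

    def summary(self) -> str:
        lines = [
            "Differential expression (NB Wald)",
            "=================================",
            f"contrast:          {self.model.group_b} vs {self.model.group_a}",
            f"genes tested:      {len(self.table)}",
            f"low-FPKM excluded: {self.n_filtered}",
            f"thresholds:        FDR < {self.fdr_max}, |log2FC| > {self.lfc_min}",
            f"up-regulated:      {len(self.up)}",
            f"down-regulated:    {len(self.down)}",
        ]
        return "\n".join(lines)
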