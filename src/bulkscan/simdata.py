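"""Simulation of an F2 bulked-segregant experiment for sepal-color-style traits.

The generator emulates the standard design for mapping an ordinal color trait
in an F2 population: two inbred parents fixed for opposite alleles at every
marker (a green-sepal line, "GP05", and a purple-sepal line, "PP05"), an F2
produced by selfing the F1, a five-class ordinal phenotype driven by a latent
liability with a single major QTL (additive effect ``a``, dominance ``d``,
Gaussian residual), bulks of the 30 most extreme plants per color class,
pooled short-read allele depths for the two parents and two bulks, marker
genotype tables for fine mapping, a gene annotation, and a 3-vs-3 replicated
RNA-seq count matrix with differentially expressed genes concentrated in the
causal region.

Every operation is a pure function of (inputs, seed): the per-stage RNG is
derived from ``config.seed`` plus a fixed stage tag, so re-running any stage
with the same config reproduces its output byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .expression import ExpressionMatrix
from .intervals import Region

__all__ = [
    "SimulationConfig",
    "Population",
    "simulate_f2",
    "build_bulks",
    "simulate_pool_reads",
    "make_gene_annotation",
    "simulate_expression",
    "marker_table_from_population",
]

# stage tags mixed into the seed so stages draw from independent streams
_STAGE_F2 = 0
_STAGE_POOL = 1
_STAGE_EXPR = 2
_STAGE_ANNOT = 3
_STAGE_MARKERS = 4

POOLS = ("gp05", "pp05", "green", "purple")


@dataclass
class SimulationConfig:
    """Parameters of the simulated mapping experiment.

    Defaults describe a single 100-Mb chromosome (the geometry of the real
    chromosome-10 target) carrying one major QTL at 78 Mb with additive
    effect a=3, no dominance and residual sd 0.5 — a nearly Mendelianised
    major gene, which is the regime in which extreme-class bulking works.
    """

    n_chromosomes: int = 1
    chrom_length_bp: int = 100_000_000
    n_markers: int = 10_000
    n_f2: int = 240
    qtl_position: tuple[str, int] = ("chr1", 78_000_000)
    qtl_effect: float = 3.0
    qtl_dominance: float = 0.0
    residual_sd: float = 0.5
    n_bulk: int = 30
    mean_depth: float = 30.0
    seq_error: float = 0.001
    cm_per_mb: float = 1.0
    indel_fraction: float = 0.11
    # optional second QTL: (chrom, bp, additive effect, dominance)
    qtl2: tuple[str, int, float, float] | None = None
    # liability cut points between the 5 ordinal classes; None = quintiles
    # of the no-QTL liability distribution N(0, residual_sd^2)
    class_thresholds: Sequence[float] | None = None
    seed: int = 0

    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def thresholds(self) -> np.ndarray:
        if self.class_thresholds is not None:
            t = np.asarray(self.class_thresholds, dtype=float)
            if t.shape != (4,) or not np.all(np.diff(t) > 0):
                raise ValueError("class_thresholds must be 4 strictly increasing cut points")
            return t
        return norm.ppf([0.2, 0.4, 0.6, 0.8], loc=0.0, scale=self.residual_sd)

    def _qtl_components(self) -> list[tuple[float, float]]:
        comps = [(self.qtl_effect, self.qtl_dominance)]
        if self.qtl2 is not None:
            comps.append((self.qtl2[2], self.qtl2[3]))
        return comps

    def class_probabilities(self) -> np.ndarray:
        """Expected fraction of the F2 in each ordinal class under the model."""
        t = self.thresholds()
        # mixture over QTL genotype combinations, 1:2:1 per locus
        means = np.array([0.0])
        weights = np.array([1.0])
        for a, d in self._qtl_components():
            mu = np.array([-a, d, a])
            w = np.array([0.25, 0.5, 0.25])
            means = (means[:, None] + mu[None, :]).ravel()
            weights = (weights[:, None] * w[None, :]).ravel()
        cdf = np.zeros(5)
        edges = np.concatenate([t, [np.inf]])
        for mu, w in zip(means, weights):
            cdf += w * norm.cdf(edges, loc=mu, scale=self.residual_sd)
        return np.diff(np.concatenate([[0.0], cdf]))

    def validate(self) -> None:
        if min(self.n_chromosomes, self.n_markers, self.n_f2, self.n_bulk) <= 0:
            raise ValueError("all counts must be positive")
        if self.chrom_length_bp <= 0 or self.mean_depth <= 0:
            raise ValueError("chromosome length and mean depth must be positive")
        if not (0.0 <= self.seq_error < 0.5):
            raise ValueError("seq_error must be in [0, 0.5)")
        if 2 * self.n_bulk > self.n_f2:
            raise ValueError("2 * n_bulk must not exceed n_f2")
        chroms = self.chromosomes()
        for chrom, pos in [self.qtl_position] + (
            [self.qtl2[:2]] if self.qtl2 is not None else []
        ):
            if chrom not in chroms or not (1 <= pos <= self.chrom_length_bp):
                raise ValueError(f"QTL position {chrom}:{pos} outside the simulated genome")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        probs = self.class_probabilities()
        for cls in (0, 4):
            if probs[cls] * self.n_f2 < 1.0:
                raise ValueError(
                    f"extreme class {cls + 1} is empty in expectation "
                    f"(expected {probs[cls] * self.n_f2:.2f} plants)"
                )


@dataclass
class Population:
    """Simulated F2: genotype codes 0 (GP05 hom) / 1 (het) / 2 (PP05 hom),
    continuous liability, and ordinal class 1 (green) ... 5 (purple)."""

    config: SimulationConfig
    markers: pd.DataFrame  # chrom, pos, site_type
    genotypes: np.ndarray  # (n_f2, n_markers) int8
    qtl_genotype: np.ndarray  # (n_f2,) int8, genotype at the causal locus
    liability: np.ndarray  # (n_f2,) float
    phenotype_class: np.ndarray  # (n_f2,) int, 1..5

    @property
    def n_f2(self) -> int:
        return self.genotypes.shape[0]

    @property
    def individual_ids(self) -> np.ndarray:
        return np.arange(self.n_f2)


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


def _marker_positions(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Roughly evenly spaced marker positions with uniform jitter."""
    chroms = config.chromosomes()
    per = np.full(len(chroms), config.n_markers // len(chroms))
    per[: config.n_markers % len(chroms)] += 1
    frames = []
    for chrom, m in zip(chroms, per):
        spacing = config.chrom_length_bp / m
        base = (np.arange(m) + 0.5) * spacing
        jitter = rng.uniform(-0.45, 0.45, size=m) * spacing
        pos = np.clip(np.round(base + jitter), 1, config.chrom_length_bp).astype(np.int64)
        # enforce strictly increasing positions (jitter can locally reorder)
        idx = np.arange(m)
        pos = np.maximum.accumulate(pos - idx) + idx
        pos = np.clip(pos, 1, config.chrom_length_bp)
        site_type = np.where(rng.random(m) < config.indel_fraction, "InDel", "SNP")
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos, "site_type": site_type}))
    return pd.concat(frames, ignore_index=True)


def _simulate_gametes(
    rng: np.random.Generator, n: int, positions: np.ndarray, cm_per_mb: float
) -> np.ndarray:
    """One recombinant gamete per row along one chromosome (Haldane map)."""
    d_morgan = np.diff(positions) * cm_per_mb / 1e6 / 100.0
    r = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
    alleles = np.empty((n, positions.size), dtype=np.int8)
    start = rng.integers(0, 2, size=n).astype(np.int8)
    if positions.size > 1:
        rec = rng.random((n, positions.size - 1)) < r[None, :]
        flips = np.cumsum(rec, axis=1).astype(np.int8) & 1
        alleles[:, 0] = start
        alleles[:, 1:] = (start[:, None] + flips) & 1
    else:
        alleles[:, 0] = start
    return alleles


def simulate_f2(config: SimulationConfig) -> Population:
    """Simulate F2 genotypes (1:2:1 segregation, Haldane recombination along
    each chromosome) and the liability/class phenotype."""
    config.validate()
    rng = _rng(config, _STAGE_F2)
    markers = _marker_positions(config, rng)

    qtl_loci = [(config.qtl_position[0], int(config.qtl_position[1]))]
    if config.qtl2 is not None:
        qtl_loci.append((config.qtl2[0], int(config.qtl2[1])))

    geno_cols = []
    qtl_geno: dict[tuple[str, int], np.ndarray] = {}
    for chrom in config.chromosomes():
        sel = markers["chrom"] == chrom
        pos = markers.loc[sel, "pos"].to_numpy()
        latent = sorted(p for c, p in qtl_loci if c == chrom)
        ext = np.sort(np.concatenate([pos, np.asarray(latent, dtype=np.int64)]))
        ins = np.searchsorted(ext, latent)  # latent loci positions in ext
        g = (
            _simulate_gametes(rng, config.n_f2, ext.astype(float), config.cm_per_mb)
            + _simulate_gametes(rng, config.n_f2, ext.astype(float), config.cm_per_mb)
        ).astype(np.int8)
        for p in latent:
            i = int(np.searchsorted(ext, p))
            qtl_geno[(chrom, p)] = g[:, i]
        keep = np.ones(ext.size, dtype=bool)
        # drop the inserted latent copies (first match per latent position)
        for p in latent:
            i = int(np.searchsorted(ext, p))
            keep[i] = False
        geno_cols.append(g[:, keep][:, : sel.sum()])
    genotypes = np.concatenate(geno_cols, axis=1)

    qg = qtl_geno[(config.qtl_position[0], int(config.qtl_position[1]))]
    liability = (
        config.qtl_effect * (qg.astype(float) - 1.0)
        + config.qtl_dominance * (qg == 1)
        + rng.normal(0.0, config.residual_sd, size=config.n_f2)
    )
    if config.qtl2 is not None:
        g2 = qtl_geno[(config.qtl2[0], int(config.qtl2[1]))]
        liability += config.qtl2[2] * (g2.astype(float) - 1.0) + config.qtl2[3] * (g2 == 1)

    classes = np.searchsorted(config.thresholds(), liability) + 1
    return Population(
        config=config,
        markers=markers,
        genotypes=genotypes,
        qtl_genotype=qg,
        liability=liability,
        phenotype_class=classes.astype(int),
    )


def build_bulks(pop: Population, n_bulk: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Pick the extreme bulks: class-1 (green) and class-5 (purple) plants.

    Within the eligible class, ties are broken by most-extreme liability then
    individual id, so the selection is deterministic given the seed.
    """
    n_bulk = pop.config.n_bulk if n_bulk is None else int(n_bulk)
    ids = pop.individual_ids
    out = []
    for cls, sign, name in ((1, 1.0, "green (class 1)"), (5, -1.0, "purple (class 5)")):
        member = ids[pop.phenotype_class == cls]
        if member.size < n_bulk:
            raise ValueError(
                f"cannot build {name} bulk: {member.size} plants available, {n_bulk} needed"
            )
        order = np.lexsort((member, sign * pop.liability[member]))
        out.append(np.sort(member[order[:n_bulk]]))
    return out[0], out[1]


def _read_counts(
    rng: np.random.Generator, p_pp05: np.ndarray, mean_depth: float, seq_error: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (pp05-allele reads, other-allele reads) at Poisson depth."""
    depth = rng.poisson(mean_depth, size=p_pp05.size)
    p_obs = p_pp05 * (1.0 - seq_error) + (1.0 - p_pp05) * seq_error
    alt = rng.binomial(depth, p_obs)
    return alt, depth - alt


def simulate_pool_reads(
    pop: Population, bulks: tuple[np.ndarray, np.ndarray], config: SimulationConfig | None = None
) -> pd.DataFrame:
    """Pooled allele depths for the four pools (GP05, PP05, green, purple).

    The true PP05-allele frequency in a bulk is the mean genotype dosage of
    its members; parent pools are fixed at 0 and 1. Depths are Poisson and
    reads binomial with a symmetric per-read error. The PP05 allele is the
    ALT allele at a random half of the sites so that downstream orientation
    from parental depths is exercised.
    """
    config = pop.config if config is None else config
    rng = _rng(config, _STAGE_POOL)
    bulk_green, bulk_purple = bulks
    n_sites = len(pop.markers)

    p_true = {
        "gp05": np.zeros(n_sites),
        "pp05": np.ones(n_sites),
        "green": pop.genotypes[bulk_green].mean(axis=0) / 2.0,
        "purple": pop.genotypes[bulk_purple].mean(axis=0) / 2.0,
    }

    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=n_sites)
    ref = bases[ref_idx]
    alt = bases[(ref_idx + rng.integers(1, 4, size=n_sites)) % 4]
    # indel alleles: extend the alt string
    is_indel = (pop.markers["site_type"] == "InDel").to_numpy()
    alt = np.where(is_indel, np.char.add(alt.astype("U8"), "A"), alt)
    pp05_is_alt = rng.random(n_sites) < 0.5

    table = pop.markers[["chrom", "pos", "site_type"]].copy()
    table["ref"] = ref
    table["alt"] = alt
    for pool in POOLS:
        pp, other = _read_counts(rng, p_true[pool], config.mean_depth, config.seq_error)
        table[f"{pool}_ref"] = np.where(pp05_is_alt, other, pp)
        table[f"{pool}_alt"] = np.where(pp05_is_alt, pp, other)
    cols = ["chrom", "pos", "ref", "alt", "site_type"] + [
        f"{pool}_{al}" for pool in POOLS for al in ("ref", "alt")
    ]
    return table[cols].reset_index(drop=True)


def make_gene_annotation(
    config: SimulationConfig,
    n_genes: int = 2000,
    mean_length_bp: float = 3000.0,
    length_log_sd: float = 0.5,
) -> pd.DataFrame:
    """Gene models laid uniformly over the genome (sorted by chrom, start)."""
    rng = _rng(config, _STAGE_ANNOT)
    chroms = np.sort(rng.integers(0, config.n_chromosomes, size=n_genes))
    lengths = np.round(
        np.exp(rng.normal(math.log(mean_length_bp), length_log_sd, size=n_genes))
    ).astype(np.int64)
    starts = rng.integers(1, config.chrom_length_bp, size=n_genes)
    ends = np.minimum(starts + lengths - 1, config.chrom_length_bp)
    names = [f"chr{c + 1}" for c in chroms]
    ann = pd.DataFrame(
        {
            "gene_id": [f"gene{i:05d}" for i in range(n_genes)],
            "chrom": names,
            "start": starts,
            "end": ends,
            "annotation": "hypothetical protein",
        }
    )
    ann = ann.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return ann


def simulate_expression(
    config: SimulationConfig,
    region: Region,
    n_de: int = 100,
    log2fc: float = 2.0,
    annotation: pd.DataFrame | None = None,
    n_reps: int = 3,
    dispersion: float = 0.05,
    base_mean_log_mu: float = math.log(100.0),
    base_mean_log_sd: float = 1.3,
    in_region_fraction: float = 0.8,
    causal_gene: str | None = None,
    causal_log2fc: float = 3.5,
    group_names: tuple[str, str] = ("gc", "pc"),
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Negative-binomial 3-vs-3 counts with DE genes concentrated in ``region``.

    Returns the matrix and a ground-truth table (gene_id, is_de, true_log2fc).
    ``causal_gene`` (if named) is forced differentially expressed at
    ``causal_log2fc`` — the strong cis effect expected of an on/off regulator.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if not np.isfinite(log2fc):
        raise ValueError("log2fc must be finite")
    if annotation is None:
        annotation = make_gene_annotation(config)
    if n_de > len(annotation):
        raise ValueError("n_de exceeds the number of genes")
    rng = _rng(config, _STAGE_EXPR)

    genes = annotation["gene_id"].to_numpy()
    in_region = (
        (annotation["chrom"] == region.chrom)
        & (annotation["start"] <= region.end)
        & (annotation["end"] >= region.start)
    ).to_numpy()

    true_lfc = np.zeros(len(genes))
    n_in = min(int(round(n_de * in_region_fraction)), int(in_region.sum()))
    pick_in = rng.choice(np.flatnonzero(in_region), size=n_in, replace=False)
    pool_out = np.flatnonzero(~in_region)
    pick_out = rng.choice(pool_out, size=min(n_de - n_in, pool_out.size), replace=False)
    de_idx = np.concatenate([pick_in, pick_out])
    true_lfc[de_idx] = np.abs(log2fc) * rng.choice([-1.0, 1.0], size=de_idx.size)
    if causal_gene is not None:
        ci = int(np.flatnonzero(genes == causal_gene)[0])
        true_lfc[ci] = causal_log2fc

    base = np.exp(rng.normal(base_mean_log_mu, base_mean_log_sd, size=len(genes)))
    mu_a = base
    mu_b = base * np.power(2.0, true_lfc)
    r = 1.0 / dispersion
    counts = {}
    for grp, mu in zip(group_names, (mu_a, mu_b)):
        for rep in range(1, n_reps + 1):
            p = r / (r + mu)
            counts[f"{grp}_{rep}"] = rng.negative_binomial(r, p)
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"))
    lengths = pd.Series(
        (annotation["end"] - annotation["start"] + 1).to_numpy(),
        index=counts_df.index,
        name="length",
    )
    groups = pd.Series(
        {col: col.rsplit("_", 1)[0] for col in counts_df.columns}, name="group"
    )
    truth = pd.DataFrame(
        {"gene_id": genes, "is_de": true_lfc != 0.0, "true_log2fc": true_lfc}
    ).set_index("gene_id")
    return ExpressionMatrix(counts=counts_df, lengths=lengths, groups=groups), truth


def marker_table_from_population(
    pop: Population,
    individuals: Sequence[int],
    region: Region | None = None,
    n_markers: int = 100,
    missing_rate: float = 0.02,
    marker_prefix: str = "M",
) -> pd.DataFrame:
    """Wide genotype table (rows = markers, columns = F2 individuals) for the
    co-segregation screen, emulating SSR/CAPS genotyping of the bulked plants.

    Markers are drawn evenly across ``region`` (or the whole genome); a small
    fraction of calls is set missing. Individual columns are named f2_<id>.
    """
    rng = _rng(pop.config, _STAGE_MARKERS)
    markers = pop.markers
    idx = np.arange(len(markers))
    if region is not None:
        mask = (
            (markers["chrom"] == region.chrom).to_numpy()
            & (markers["pos"].to_numpy() >= region.start)
            & (markers["pos"].to_numpy() <= region.end)
        )
        idx = idx[mask]
    if idx.size == 0:
        raise ValueError("no simulated markers available in the requested region")
    take = idx[np.unique(np.linspace(0, idx.size - 1, min(n_markers, idx.size)).astype(int))]
    individuals = np.asarray(list(individuals), dtype=int)

    geno = pop.genotypes[np.ix_(individuals, take)].astype(float).T
    geno[rng.random(geno.shape) < missing_rate] = np.nan
    marker_type = np.where(rng.random(take.size) < 0.15, "CAPS", "SSR")
    out = pd.DataFrame(
        {
            "marker_id": [f"{marker_prefix}{i + 1:03d}" for i in range(take.size)],
            "chrom": markers["chrom"].to_numpy()[take],
            "pos": markers["pos"].to_numpy()[take],
            "marker_type": marker_type,
        }
    )
    for j, ind in enumerate(individuals):
        out[f"f2_{ind}"] = geno[:, j]
    return out
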