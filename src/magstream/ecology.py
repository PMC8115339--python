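"""Ecological distribution: dereplication, recruitment normalization,
environmental pairing and constrained ordination.

Read-recruitment counts are normalized two ways: the *relative fraction*
(reads recruited to a genome over total reads in the sample — the genome's
share of the community sequence) and *RPKM*, reads per kbp of genome per
Mbp of metagenome,

    RPKM = (reads / (genome_length_bp / 1000)) / (sample_bp / 1e6),

which is comparable across genomes of different size and samples of
different depth of sequencing.

Genomes are dereplicated at an average-nucleotide-identity threshold
(default 98.5%) by single-linkage clustering of above-threshold pairs; the
representative of each cluster is the highest-completeness member, ties
broken by lower contamination, larger assembly, then lexicographic id.

Environmental casts are paired to a metagenome only when taken at the same
station within a depth tolerance (default 1 m); a parameter measured by
several qualifying casts contributes its mean.

The ordination is canonical correspondence analysis (CCA, ter Braak):
chi-square-standardized abundances are projected onto the row-weighted
environmental predictors and the fitted matrix decomposed by SVD.
Abundances are log(n+1)-transformed first (natural log by default);
environmental variables measured in fewer than 90% of samples are dropped,
then samples with any remaining missing value are dropped listwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputError, NumericalError

ANI_THRESHOLD = 98.5       # percent, species/strain-cluster boundary
DEPTH_TOLERANCE_M = 1.0    # max |depth difference| for env pairing
MIN_ENV_COVERAGE = 0.90    # fraction of samples a variable must cover


@dataclass(frozen=True)
class AniPair:
    genome_a: str
    genome_b: str
    ani_ab: float
    ani_ba: float | None = None

    def __post_init__(self) -> None:
        for v in (self.ani_ab, self.ani_ba):
            if v is not None and not 0 <= v <= 100:
                raise InputError(f"ANI out of [0, 100]: {v}")

    @property
    def mean_ani(self) -> float:
        if self.ani_ba is None:
            return self.ani_ab
        return (self.ani_ab + self.ani_ba) / 2


@dataclass(frozen=True)
class GenomeQuality:
    completeness: float
    contamination: float
    assembly_length: int


@dataclass
class CcaResult:
    """Constrained-ordination result, scaling type 2.

    ``site_scores`` are linear-combination scores (rows standardized in the
    chi-square metric); ``species_scores`` are scaled by the singular
    values; ``biplot_scores`` are weighted correlations of each surviving
    environmental variable with the site axes.
    """

    eigenvalues: np.ndarray
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame
    total_inertia: float
    env_variables: list[str] = field(default_factory=list)


def dereplicate_by_ani(
    pairs: Iterable[AniPair],
    quality: Mapping[str, GenomeQuality] | pd.DataFrame,
    threshold: float = ANI_THRESHOLD,
) -> tuple[list[frozenset[str]], dict[frozenset[str], str]]:
    """Single-linkage ANI clusters and one representative per cluster.

    Every genome named in ``pairs`` must appear in ``quality``; genomes in
    ``quality`` without qualifying pairs become singletons.
    """
    if not 0 < threshold <= 100:
        raise InputError(f"threshold must be in (0, 100], got {threshold}")
    if isinstance(quality, pd.DataFrame):
        quality = {
            g: GenomeQuality(
                float(row["completeness"]),
                float(row["contamination"]),
                int(row["assembly_length"]),
            )
            for g, row in quality.iterrows()
        }
    g = nx.Graph()
    g.add_nodes_from(quality)
    for p in pairs:
        for gid in (p.genome_a, p.genome_b):
            if gid not in quality:
                raise InputError(f"genome {gid!r} missing from quality map")
        if p.mean_ani >= threshold:
            g.add_edge(p.genome_a, p.genome_b)
    clusters = sorted(
        (frozenset(c) for c in nx.connected_components(g)),
        key=lambda c: sorted(c)[0],
    )
    reps = {}
    for cluster in clusters:
        reps[cluster] = sorted(
            cluster,
            key=lambda gid: (
                -quality[gid].completeness,
                quality[gid].contamination,
                -quality[gid].assembly_length,
                gid,
            ),
        )[0]
    return clusters, reps


def relative_fraction(reads_recruited: int, sample_total_reads: int) -> float:
    """Reads recruited to a genome over total reads in the sample."""
    if sample_total_reads <= 0:
        raise InputError("sample_total_reads must be > 0")
    if reads_recruited > sample_total_reads:
        raise InputError(
            f"recruited reads ({reads_recruited}) exceed sample total "
            f"({sample_total_reads})"
        )
    return reads_recruited / sample_total_reads


def rpkm(reads_recruited: int, genome_length: int, sample_total_bp: int) -> float:
    """Reads per kbp of genome per Mbp of metagenome."""
    if genome_length <= 0:
        raise InputError("genome_length must be > 0")
    if sample_total_bp <= 0:
        raise InputError("sample_total_bp must be > 0")
    return (reads_recruited / (genome_length / 1000)) / (sample_total_bp / 1e6)


def abundance_table(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    genome_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Long-form abundance table with relative fraction and RPKM.

    ``counts`` columns: genome_id, sample_id, reads.  ``samples`` is indexed
    by sample_id with columns total_reads and total_bp.
    """
    rows = []
    for rec in counts.itertuples(index=False):
        if rec.sample_id not in samples.index:
            raise InputError(f"unknown sample {rec.sample_id!r} in count table")
        if rec.genome_id not in genome_lengths:
            raise InputError(f"unknown genome {rec.genome_id!r} in count table")
        s = samples.loc[rec.sample_id]
        rows.append({
            "genome_id": rec.genome_id,
            "sample_id": rec.sample_id,
            "reads_recruited": int(rec.reads),
            "relative_fraction": relative_fraction(
                int(rec.reads), int(s["total_reads"])
            ),
            "rpkm": rpkm(
                int(rec.reads), genome_lengths[rec.genome_id], int(s["total_bp"])
            ),
        })
    return pd.DataFrame(rows)


def pair_environment(
    metagenomes: pd.DataFrame,
    env: pd.DataFrame,
    tolerance: float = DEPTH_TOLERANCE_M,
) -> pd.DataFrame:
    """Environmental parameters per metagenome (station + depth matching).

    ``metagenomes``: indexed by sample_id with columns station, depth.
    ``env``: one row per cast with columns station, depth plus parameter
    columns (missing values allowed).  For each metagenome, casts at the
    same station within ``tolerance`` metres qualify; each parameter is the
    mean over the qualifying non-missing values.  Metagenomes without any
    qualifying cast get an all-missing row and a warning.
    """
    if tolerance < 0:
        raise InputError("tolerance must be >= 0")
    params = [c for c in env.columns if c not in ("station", "depth", "sample_id")]
    rows = {}
    for sid, meta in metagenomes.iterrows():
        cand = env[
            (env["station"] == meta["station"])
            & ((env["depth"] - meta["depth"]).abs() <= tolerance)
        ]
        if cand.empty:
            warnings.warn(
                f"metagenome {sid!r}: no environmental cast within "
                f"{tolerance} m at station {meta['station']!r}",
                stacklevel=2,
            )
        rows[sid] = cand[params].mean(skipna=True) if not cand.empty else (
            pd.Series(np.nan, index=params)
        )
    out = pd.DataFrame(rows).T
    out.index.name = "sample_id"
    return out


def _chi_square_residuals(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    total = y.sum()
    if total <= 0:
        raise InputError("abundance matrix sums to zero")
    p = y / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    expected = np.outer(r, c)
    return (p - expected) / np.sqrt(expected), r, c


def cca(
    abundance: pd.DataFrame,
    env: pd.DataFrame,
    min_coverage: float = MIN_ENV_COVERAGE,
    log_base: str = "e",
    transform: bool = True,
) -> CcaResult:
    """Canonical correspondence analysis of samples x genomes on env data.

    ``abundance``: samples x genomes (RPKM or counts, non-negative),
    ``env``: samples x variables, aligned on the sample index.  Variables
    covering fewer than ``min_coverage`` of the samples are dropped, then
    samples with remaining missing values are dropped listwise.  Abundances
    are log(n+1)-transformed (``log_base``: "e" or "10"); pass
    ``transform=False`` for pre-transformed input.  Constant or collinear
    predictors are pruned with a warning.
    """
    if abundance.shape[0] < 3 or abundance.shape[1] < 2:
        raise InputError("need >= 3 samples and >= 2 genomes")
    env = env.loc[abundance.index]
    coverage = env.notna().mean(axis=0)
    kept = [v for v in env.columns if coverage[v] >= min_coverage]
    if not kept:
        raise InputError(
            f"no environmental variable covers >= {min_coverage:.0%} of samples"
        )
    env = env[kept].astype(float)
    complete = env.notna().all(axis=1)
    env = env.loc[complete]
    y_df = abundance.loc[complete].astype(float)

    y = y_df.to_numpy()
    if transform:
        y = np.log1p(y) if log_base == "e" else np.log1p(y) / np.log(10)
    zero_rows = np.flatnonzero(y.sum(axis=1) == 0)
    if zero_rows.size:
        raise InputError(
            f"all-zero sample after transform: {y_df.index[zero_rows[0]]!r}"
        )
    zero_cols = np.flatnonzero(y.sum(axis=0) == 0)
    if zero_cols.size:
        raise InputError(
            f"all-zero genome after transform: {y_df.columns[zero_cols[0]]!r}"
        )

    qbar, r, c = _chi_square_residuals(y)
    total_inertia = float((qbar ** 2).sum())

    x = env.to_numpy()
    x = x - r @ x  # weighted centering (weights sum to 1)
    xw = x * np.sqrt(r)[:, None]
    # prune constant/collinear predictors via pivoted QR
    qmat, rmat, piv = _pivoted_qr(xw)
    diag = np.abs(np.diag(rmat))
    rank = int((diag > 1e-10 * max(diag[0], 1e-300)).sum()) if diag.size else 0
    if rank < xw.shape[1]:
        dropped = [kept[i] for i in piv[rank:]]
        warnings.warn(
            f"rank-deficient environmental matrix; pruned: {dropped}",
            stacklevel=2,
        )
        keep_idx = sorted(piv[:rank])
        kept = [kept[i] for i in keep_idx]
        xw = xw[:, keep_idx]
    if xw.shape[1] == 0:
        raise NumericalError("no informative environmental variable remains")

    proj = xw @ np.linalg.solve(xw.T @ xw, xw.T @ qbar)
    u, s, vt = np.linalg.svd(proj, full_matrices=False)
    n_axes = min(xw.shape[1], y.shape[1] - 1, y.shape[0] - 1)
    pos = s[:n_axes] > 1e-12
    u, s, vt = u[:, :n_axes][:, pos], s[:n_axes][pos], vt[:n_axes][pos]
    axes = [f"CCA{i + 1}" for i in range(len(s))]

    site = u / np.sqrt(r)[:, None]
    species = (vt.T / np.sqrt(c)[:, None]) * s[None, :]
    xn = xw / np.linalg.norm(xw, axis=0, keepdims=True)
    biplot = xn.T @ u

    return CcaResult(
        eigenvalues=s ** 2,
        site_scores=pd.DataFrame(site, index=y_df.index, columns=axes),
        species_scores=pd.DataFrame(species, index=y_df.columns, columns=axes),
        biplot_scores=pd.DataFrame(biplot, index=kept, columns=axes),
        total_inertia=total_inertia,
        env_variables=list(kept),
    )


def _pivoted_qr(a: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(a, mode="economic", pivoting=True)
    return q, r, piv
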