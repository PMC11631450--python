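"""Orthogroup-based comparative QC.

Given per-genome gene -> orthogroup assignment tables (one orthogroup per
gene, PlantTribes2-style two-column text), this module builds the core
orthogroup (CROG) gene-count matrix (rows = orthogroups, columns =
genomes), z-scores each row across genomes (population SD; zero-SD rows
are uninformative and dropped), derives deterministic clustermap leaf
orders (average linkage, Euclidean distance), summarises per-genome
z-score distributions, and computes UpSet-style exact membership-pattern
counts and unique-orthogroup queries.

The row z-score (x - mean) / sd turns raw per-genome gene counts into a
departure-from-expectation panel: a genome whose count in an orthogroup
sits far above (below) the cross-genome mean shows up as a warm (cold)
cell, independent of orthogroup size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .annotation_io import UsageError


@dataclass
class OrthogroupAssignment:
    """One genome's gene -> orthogroup map (unassigned genes absent)."""

    genome: str
    gene_to_orthogroup: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path, genome: str | None = None) -> "OrthogroupAssignment":
        """Read a two-column (gene_id, orthogroup_id) table."""
        path = Path(path)
        mapping: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                gene, og = line.split("\t")[:2]
                mapping[gene] = og
        return cls(genome=genome or path.stem, gene_to_orthogroup=mapping)

    def orthogroups(self) -> set[str]:
        return set(self.gene_to_orthogroup.values())


def build_crog_matrix(
    assignments: Sequence[OrthogroupAssignment],
    orthogroup_universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Orthogroup x genome integer gene-count matrix.

    Orthogroups in the universe that no genome populates are kept as
    all-zero rows; column sums equal the number of assigned genes per
    genome.
    """
    if not assignments:
        raise UsageError("at least one genome assignment is required")
    labels = [a.genome for a in assignments]
    if len(set(labels)) != len(labels):
        raise UsageError(f"duplicate genome labels: {labels}")
    rows = set(orthogroup_universe) if orthogroup_universe is not None else set()
    for a in assignments:
        rows |= a.orthogroups()
    index = sorted(rows)
    mat = pd.DataFrame(0, index=index, columns=labels, dtype=int)
    for a in assignments:
        counts = pd.Series(list(a.gene_to_orthogroup.values())).value_counts()
        mat.loc[counts.index, a.genome] = counts.astype(int)
    return mat


def zscore_normalize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Row-wise z-score with population SD; zero-SD rows dropped.

    Returns the z-matrix and the dropped row ids (includes all-zero rows,
    which necessarily have zero SD).
    """
    if matrix.shape[1] < 2:
        raise UsageError("z-scores need >= 2 genome columns")
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=0)
    keep = sd > 0
    dropped = [str(i) for i in matrix.index[~keep]]
    kept = values[keep]
    z = (kept - kept.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return pd.DataFrame(z, index=matrix.index[keep], columns=matrix.columns), dropped


def cluster_order(zmatrix: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Deterministic clustermap leaf orders for rows and columns.

    Hierarchical agglomerative clustering, average linkage on Euclidean
    distances; scipy's tie-breaking by input index keeps the result
    reproducible for a fixed input ordering.
    """
    if zmatrix.shape[0] < 2 or zmatrix.shape[1] < 2:
        raise UsageError("clustering needs at least a 2x2 matrix")
    values = zmatrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise UsageError("z-matrix contains non-finite entries")
    row_order = leaves_list(linkage(pdist(values), method="average"))
    col_order = leaves_list(linkage(pdist(values.T), method="average"))
    return (
        [str(zmatrix.index[i]) for i in row_order],
        [str(zmatrix.columns[i]) for i in col_order],
    )


def zscore_summary(zmatrix: pd.DataFrame) -> pd.DataFrame:
    """Boxplot-style per-genome summary of the z-score distribution.

    Columns: mean, median, q1, q3, whisker_low, whisker_high (Tukey 1.5xIQR
    whiskers clipped to observed values).
    """
    out = {}
    for col in zmatrix.columns:
        x = zmatrix[col].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        iqr = q3 - q1
        lo = x[x >= q1 - 1.5 * iqr].min()
        hi = x[x <= q3 + 1.5 * iqr].max()
        out[col] = {
            "mean": x.mean(), "median": med, "q1": q1, "q3": q3,
            "whisker_low": lo, "whisker_high": hi,
        }
    return pd.DataFrame(out).T[
        ["mean", "median", "q1", "q3", "whisker_low", "whisker_high"]
    ]


def upset_counts(
    sets_by_genome: Mapping[str, set[str]]
) -> dict[frozenset[str], int]:
    """Exact membership-pattern counts over the orthogroup union.

    Every orthogroup is counted in exactly one category — the frozenset of
    genomes that contain it — so the category counts partition the union.
    """
    if not sets_by_genome:
        raise UsageError("at least one genome set is required")
    pattern_counts: dict[frozenset[str], int] = {}
    universe = set().union(*sets_by_genome.values())
    for og in universe:
        pattern = frozenset(g for g, s in sets_by_genome.items() if og in s)
        pattern_counts[pattern] = pattern_counts.get(pattern, 0) + 1
    return pattern_counts


def unique_orthogroups(
    sets_by_genome: Mapping[str, set[str]], focal: Iterable[str]
) -> set[str]:
    """Orthogroups present in every focal genome and absent from the rest."""
    focal = set(focal)
    unknown = focal - set(sets_by_genome)
    if unknown:
        raise UsageError(f"unknown focal genome label(s): {sorted(unknown)}")
    others = set(sets_by_genome) - focal
    shared = set.intersection(*(sets_by_genome[g] for g in focal))
    for g in others:
        shared -= sets_by_genome[g]
    return shared


def write_upset_tsv(pattern_counts: dict[frozenset[str], int], path) -> None:
    lines = ["genomes\tcount"]
    ordered = sorted(
        pattern_counts.items(), key=lambda kv: (-kv[1], ",".join(sorted(kv[0])))
    )
    for pattern, count in ordered:
        lines.append(",".join(sorted(pattern)) + f"\t{count}")
    Path(path).write_text("\n".join(lines) + "\n")


def plot_clustermap(zmatrix: pd.DataFrame, path) -> None:
    """Render the clustered z-score heatmap (thin seaborn wrapper)."""
    import seaborn as sns

    g = sns.clustermap(zmatrix, method="average", metric="euclidean", cmap="vlag",
                       center=0)
    g.savefig(path)
    import matplotlib.pyplot as plt

    plt.close("all")


def plot_zscore_boxplot(zmatrix: pd.DataFrame, path) -> None:
    import matplotlib.pyplot as plt
    import seaborn as sns

    long = zmatrix.melt(var_name="genome", value_name="zscore")
    ax = sns.boxplot(data=long, x="genome", y="zscore")
    ax.tick_params(axis="x", rotation=90)
    ax.figure.tight_layout()
    ax.figure.savefig(path)
    plt.close("all")
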