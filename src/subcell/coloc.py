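"""Compartment-specific RNA colocalization via the colocation quotient.

The colocation quotient (CLQ) for an ordered gene pair A->B within one
compartment of one cell is the odds ratio of the observed to the expected
proportion of B transcripts among the neighbors of A at radius r:

    CLQ(A->B) = (C_{A->B} / N_A) / (N'_B / (N - 1))

where C_{A->B} = sum over A transcripts of the proportion of B transcripts
among that transcript's neighbors within r (so C_{A->B}/N_A is the mean
observed B proportion; an A transcript with no neighbors contributes 0),
N_A and N_B are the transcript counts of A and B, N is the compartment
total, and N'_B = N_B - 1 for the self-pair A = B (a transcript is never
its own neighbor).  The expected proportion under complete spatial
randomness is N'_B/(N-1), so E[CLQ] = 1 for a CSR compartment regardless
of edge effects.  Genes with fewer than ``min_count`` transcripts in the
compartment are not scored (the entry is missing).

CLQ values over (ordered gene pair) x (cell) x (compartment) form a
three-way tensor with a missing-entry mask; masked non-negative PARAFAC
with elbow rank selection over ranks 2-12 extracts compartment-, cell- and
pair-specific colocalization programs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import false_discovery_control, mannwhitneyu

from ._tensor import CPResult, cp_nonneg_masked
from ._util import elbow_index
from .core import CYTOPLASM, NUCLEUS, UNASSIGNED, CellDataset

DEFAULT_RADIUS = 20.0
DEFAULT_MIN_COUNT = 10


def neighbor_counts(points: pd.DataFrame, gene_a: str, gene_b: str, r: float) -> int:
    """C_{A->B}: number of A transcripts with >= 1 B transcript within r.

    Distance is boundary-inclusive (d <= r); a transcript is not its own
    neighbor.  Matches the O(N^2) brute force exactly.
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    a_xy = points.loc[points["gene"] == gene_a, ["x", "y"]].to_numpy(float)
    b_xy = points.loc[points["gene"] == gene_b, ["x", "y"]].to_numpy(float)
    if not len(a_xy) or not len(b_xy):
        return 0
    tree = cKDTree(b_xy)
    counts = tree.query_ball_point(a_xy, r, return_length=True)
    if gene_a == gene_b:
        counts = counts - 1  # each A point finds itself at distance 0
    return int((counts > 0).sum())


def neighbor_proportions(
    points: pd.DataFrame, gene_a: str, gene_b: str, r: float
) -> float:
    """C_{A->B}: summed proportion of B among each A transcript's neighbors.

    Neighbors are all transcripts (any gene) within r, self excluded,
    boundary inclusive; an A transcript with no neighbors contributes 0.
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    xy = points[["x", "y"]].to_numpy(float)
    genes = points["gene"].to_numpy()
    a_idx = np.flatnonzero(genes == gene_a)
    if not len(a_idx):
        return 0.0
    tree = cKDTree(xy)
    total = 0.0
    for i, nbrs in zip(a_idx, tree.query_ball_point(xy[a_idx], r)):
        nbrs = [j for j in nbrs if j != i]
        if not nbrs:
            continue
        n_b = sum(genes[j] == gene_b for j in nbrs)
        total += n_b / len(nbrs)
    return total


def clq_pair(
    points: pd.DataFrame,
    gene_a: str,
    gene_b: str,
    r: float,
    min_count: int = DEFAULT_MIN_COUNT,
) -> float:
    """CLQ(A->B) for one compartment point set; NaN when not scoreable.

    Missing when the compartment has <= 1 transcript or either gene falls
    below ``min_count`` transcripts.
    """
    n = len(points)
    if n <= 1:
        return np.nan
    n_a = int((points["gene"] == gene_a).sum())
    n_b = int((points["gene"] == gene_b).sum())
    if n_a < min_count or n_b < min_count:
        return np.nan
    nb_prime = n_b - 1 if gene_a == gene_b else n_b
    if nb_prime == 0:
        return np.nan
    c_ab = neighbor_proportions(points, gene_a, gene_b, r)
    return (c_ab / n_a) / (nb_prime / (n - 1))


@dataclass
class ClqTensor:
    """CLQ values over (ordered gene pair) x cell x compartment.

    ``mask`` is True where the value is missing (min-count filter failed or
    the compartment was empty).  Axis labels are lexicographically stable.
    """

    values: np.ndarray  # (P, C, K)
    mask: np.ndarray  # True = missing
    pairs: list[tuple[str, str]]
    cells: list[str]
    compartments: list[str]
    radius: float = DEFAULT_RADIUS
    min_count: int = DEFAULT_MIN_COUNT

    def to_frame(self) -> pd.DataFrame:
        """Long-format table of present entries."""
        p, c, k = np.nonzero(~self.mask)
        return pd.DataFrame(
            {
                "gene_a": [self.pairs[i][0] for i in p],
                "gene_b": [self.pairs[i][1] for i in p],
                "cell_id": [self.cells[i] for i in c],
                "compartment": [self.compartments[i] for i in k],
                "clq": self.values[p, c, k],
            }
        )


def build_tensor(
    dataset: CellDataset,
    compartments: tuple[str, ...] = (NUCLEUS, CYTOPLASM),
    r: float | None = None,
    min_count: int = DEFAULT_MIN_COUNT,
    include_self_pairs: bool = True,
    max_missing_fraction: float = 0.95,
) -> ClqTensor:
    """CLQ for every ordered gene pair per cell per compartment.

    Pairs missing in more than ``max_missing_fraction`` of the
    (cell, compartment) slabs are dropped from the pair axis.  The
    neighborhood radius is in data units; when not given, a default of
    20 is used with a warning (real data should set it explicitly).
    """
    if r is None:
        warnings.warn(
            f"no neighborhood radius given; defaulting to r={DEFAULT_RADIUS} data units",
            stacklevel=2,
        )
        r = DEFAULT_RADIUS
    genes = sorted(dataset.counts.index)
    cells = sorted(dataset.counts.columns)
    pairs = [
        (a, b) for a in genes for b in genes if include_self_pairs or a != b
    ]
    n_p, n_c, n_k = len(pairs), len(cells), len(compartments)
    values = np.zeros((n_p, n_c, n_k))
    mask = np.ones((n_p, n_c, n_k), dtype=bool)

    assigned = dataset.points[dataset.points["cell_id"] != UNASSIGNED]
    for ci, cell_id in enumerate(cells):
        cell_pts = assigned[assigned["cell_id"] == cell_id]
        for ki, comp in enumerate(compartments):
            pts = cell_pts[cell_pts["compartment"] == comp]
            n = len(pts)
            if n <= 1:
                continue
            counts = pts["gene"].value_counts()
            eligible = sorted(g for g in counts.index if counts[g] >= min_count)
            if not eligible:
                continue
            xy = pts[["x", "y"]].to_numpy(float)
            gene_arr = pts["gene"].to_numpy()
            tree = cKDTree(xy)
            neighbor_lists = tree.query_ball_point(xy, r)
            gene_to_col = {g: i for i, g in enumerate(eligible)}
            # per point: neighbor count per eligible gene and total neighbors
            nb_count = np.zeros((n, len(eligible)))
            nb_total = np.zeros(n)
            for i, nbrs in enumerate(neighbor_lists):
                for j in nbrs:
                    if j != i:
                        nb_total[i] += 1
                        col = gene_to_col.get(gene_arr[j])
                        if col is not None:
                            nb_count[i, col] += 1
            with np.errstate(divide="ignore", invalid="ignore"):
                nb_frac = np.where(nb_total[:, None] > 0, nb_count / nb_total[:, None], 0.0)
            for pi, (a, b) in enumerate(pairs):
                if a not in gene_to_col or b not in gene_to_col:
                    continue
                rows_a = gene_arr == a
                c_ab = float(nb_frac[rows_a, gene_to_col[b]].sum())
                n_a = int(counts[a])
                nb_prime = int(counts[b]) - (1 if a == b else 0)
                if nb_prime == 0:
                    continue
                values[pi, ci, ki] = (c_ab / n_a) / (nb_prime / (n - 1))
                mask[pi, ci, ki] = False

    keep = mask.reshape(n_p, -1).mean(axis=1) <= max_missing_fraction
    if not keep.any():
        raise ValueError("all tensor entries are masked; no pair passes the filters")
    return ClqTensor(
        values=values[keep],
        mask=mask[keep],
        pairs=[p for p, k in zip(pairs, keep) if k],
        cells=cells,
        compartments=list(compartments),
        radius=float(r),
        min_count=min_count,
    )


@dataclass
class FactorModel:
    """Masked non-negative PARAFAC fit of a CLQ tensor."""

    rank: int
    gene_pair_loadings: np.ndarray  # (P, R)
    cell_loadings: np.ndarray  # (C, R)
    compartment_loadings: np.ndarray  # (K, R)
    rmse: float
    converged: bool
    rank_curve: pd.DataFrame  # columns rank, rmse
    degenerate: bool = False
    tensor: ClqTensor | None = field(default=None, repr=False)


def decompose(
    tensor: ClqTensor,
    rank_range: range = range(2, 13),
    seed: int = 0,
    n_restarts: int = 3,
    tol: float = 1e-7,
    max_iter: int = 500,
) -> FactorModel:
    """Fit masked non-negative PARAFAC at each rank and pick the elbow.

    The rank-selection curve is observed-entry RMSE vs rank; the selected
    rank maximizes the perpendicular distance to the chord joining the
    curve endpoints.  A flat curve (e.g. an all-constant tensor) is flagged
    degenerate and the minimum rank returned.
    """
    ranks = list(rank_range)
    fits: dict[int, CPResult] = {}
    rmses = []
    for rank in ranks:
        fit = cp_nonneg_masked(
            tensor.values,
            tensor.mask,
            rank,
            seed=seed,
            n_restarts=n_restarts,
            tol=tol,
            max_iter=max_iter,
        )
        fits[rank] = fit
        rmses.append(fit.rmse)
    idx, degenerate = elbow_index(np.array(ranks, float), np.array(rmses))
    scale = float(np.sqrt((tensor.values[~tensor.mask] ** 2).mean()))
    if max(rmses) <= 1e-8 * max(scale, 1.0):
        # already perfectly reconstructed at the minimum rank (e.g. an
        # all-constant tensor): no meaningful elbow exists
        idx, degenerate = 0, True
    best_rank = ranks[idx]
    best = fits[best_rank]
    return FactorModel(
        rank=best_rank,
        gene_pair_loadings=best.factors[0],
        cell_loadings=best.factors[1],
        compartment_loadings=best.factors[2],
        rmse=best.rmse,
        converged=best.converged,
        rank_curve=pd.DataFrame({"rank": ranks, "rmse": rmses}),
        degenerate=degenerate,
        tensor=tensor,
    )


def self_vs_cross_summary(tensor: ClqTensor) -> dict:
    """log-CLQ distributions for {self, cross} x compartment, with tests.

    Groups positive CLQ values by self-pair vs cross-pair and compartment,
    compares every group pair with the two-sided Mann-Whitney U test, and
    adjusts p-values with Benjamini-Hochberg.  Empty groups are skipped
    with a warning.
    """
    frame = tensor.to_frame()
    frame = frame[frame["clq"] > 0]
    frame["kind"] = np.where(frame["gene_a"] == frame["gene_b"], "self", "cross")
    frame["log_clq"] = np.log(frame["clq"])
    groups: dict[tuple[str, str], np.ndarray] = {}
    for (kind, comp), sub in frame.groupby(["kind", "compartment"], observed=True):
        if len(sub) == 0:
            continue
        groups[(kind, comp)] = sub["log_clq"].to_numpy()
    for kind in ("self", "cross"):
        for comp in tensor.compartments:
            if (kind, comp) not in groups:
                warnings.warn(f"group ({kind}, {comp}) is empty; skipped", stacklevel=2)

    keys = sorted(groups)
    rows = []
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            u, p = mannwhitneyu(groups[keys[i]], groups[keys[j]], alternative="two-sided")
            rows.append(
                {
                    "group_a": "|".join(keys[i]),
                    "group_b": "|".join(keys[j]),
                    "median_a": float(np.median(groups[keys[i]])),
                    "median_b": float(np.median(groups[keys[j]])),
                    "u_statistic": float(u),
                    "p_value": float(p),
                }
            )
    tests = pd.DataFrame(rows)
    if len(tests):
        tests["p_adjusted"] = false_discovery_control(tests["p_value"], method="bh")
    return {"groups": groups, "tests": tests}
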