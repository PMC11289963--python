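"""Gene-set enrichment of embeddings, domains, and pattern frequencies.

Locale weight tables assign each gene a log fold-change for a subcellular
locale (nucleus, nucleolus, nuclear pore, nuclear lamina, cytosol, ER
lumen, ER membrane, outer mitochondrial membrane, ...), as measured by
proximity-labeling RNA-seq.  The raw enrichment of a flux-embedding pixel
for a locale is the weighted sum of its embedding over the genes shared
between the panel and the weight table; scores are z-scaled per cell
against a permutation null that shuffles the gene labels of the weight
vector, which holds the embedding geometry fixed.  Domain-level summaries
are the mean z-score and the fraction of positive pixels per domain.
Localization shifts between conditions are quantified with the 1D
Wasserstein (earth mover) distance over the canonically ordered domains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .core import UNASSIGNED, CellDataset
from .flux import FluxEmbedding, FluxmapResult


def load_locale_weights(path) -> pd.DataFrame:
    """Read a locale weight CSV with columns gene, locale, logFC."""
    table = pd.read_csv(path)
    required = {"gene", "locale", "logFC"}
    if not required <= set(table.columns):
        raise ValueError(f"weights table must have columns {sorted(required)}")
    return table


def _weights_matrix(
    weights: pd.DataFrame, genes: list[str]
) -> tuple[np.ndarray, list[str], dict[str, int]]:
    """Align a long weight table to the dataset gene panel.

    Returns (W, locales, overlap) with W of shape (n_locales, n_genes);
    genes absent from a locale's set get weight 0.  Locales with no overlap
    are dropped with a warning; overlap sizes are reported.
    """
    locales, mats, overlap = [], [], {}
    for locale, sub in weights.groupby("locale", sort=True):
        w = pd.Series(sub["logFC"].to_numpy(), index=sub["gene"]).reindex(genes)
        n_overlap = int(w.notna().sum())
        if n_overlap == 0:
            warnings.warn(f"locale {locale!r}: no overlap with gene panel; skipped", stacklevel=3)
            continue
        locales.append(locale)
        overlap[locale] = n_overlap
        mats.append(w.fillna(0.0).to_numpy())
    if not locales:
        raise ValueError("no locale overlaps the dataset gene panel")
    return np.vstack(mats), locales, overlap


@dataclass
class EnrichmentScores:
    """Per-query locale enrichment with permutation z-scaling."""

    raw: pd.DataFrame  # (n_q, locales)
    z: pd.DataFrame  # (n_q, locales)
    grid: pd.DataFrame  # cell_id, x, y aligned with rows
    overlap: dict[str, int]
    n_perm: int
    seed: int
    degenerate: list[str]


def flux_enrichment(
    embedding: FluxEmbedding,
    weights: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentScores:
    """Weighted-sum locale scores per pixel, z-scaled per cell.

    raw(q, locale) = sum_g r_q[g] * w_locale[g] over the panel/locale gene
    overlap.  The null permutes the gene labels of the weight vector
    ``n_perm`` times within each cell; z = (raw - mean_null) / sd_null.
    All-zero weight vectors produce z = 0 and are flagged degenerate.
    """
    w_mat, locales, overlap = _weights_matrix(weights, embedding.genes)
    r = embedding.embedding
    raw = r @ w_mat.T  # (n_q, L)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xE12]))
    z = np.zeros_like(raw)
    degenerate = [loc for loc, w in zip(locales, w_mat) if not np.any(w)]

    table = embedding.grid.table
    n_genes = r.shape[1]
    for _, rows in table.groupby("cell_id", sort=True).groups.items():
        rows = np.asarray(rows)
        r_cell = r[rows]
        perms = np.stack([rng.permutation(n_genes) for _ in range(n_perm)])
        # null_scores[p, q, l] for this cell
        null = np.einsum("qg,pgl->pql", r_cell, w_mat.T[perms])
        mean = null.mean(axis=0)
        sd = null.std(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            z_cell = (raw[rows] - mean) / sd
        z_cell[~np.isfinite(z_cell)] = 0.0
        z[rows] = z_cell
    return EnrichmentScores(
        raw=pd.DataFrame(raw, columns=locales),
        z=pd.DataFrame(z, columns=locales),
        grid=table.copy(),
        overlap=overlap,
        n_perm=n_perm,
        seed=int(seed),
        degenerate=degenerate,
    )


def domain_enrichment(scores: EnrichmentScores, fluxmaps: FluxmapResult) -> pd.DataFrame:
    """Per-(domain, locale) mean z-score and positive-pixel fraction."""
    rows = []
    labels = fluxmaps.labels
    for d in sorted(np.unique(labels)):
        m = labels == d
        for locale in scores.z.columns:
            vals = scores.z.loc[m, locale]
            rows.append(
                {
                    "domain": int(d),
                    "locale": locale,
                    "mean_z": float(vals.mean()) if m.any() else np.nan,
                    "positive_fraction": float((vals > 0).mean()) if m.any() else 0.0,
                    "n_pixels": int(m.sum()),
                }
            )
    return pd.DataFrame(rows).sort_values(["domain", "locale"]).reset_index(drop=True)


def pattern_enrichment(
    pattern_freqs: pd.DataFrame,
    weights: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Locale enrichment of per-label gene pattern frequencies.

    ``pattern_freqs`` is gene x label with each row the fraction of a
    gene's cells assigned each localization label (rows sum to <= 1).
    score(label, locale) = sum_g freq[g, label] * w_locale[g]; the
    permutation p-value shuffles gene labels of the weight vector; BH
    adjusts across the full (label x locale) family.
    """
    if (pattern_freqs.sum(axis=1) > 1 + 1e-9).any():
        raise ValueError("pattern frequency rows must sum to <= 1")
    genes = list(pattern_freqs.index)
    w_mat, locales, overlap = _weights_matrix(weights, genes)
    f = pattern_freqs.to_numpy(float)  # (G, L_labels)
    scores = f.T @ w_mat.T  # (labels, locales)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xE13]))
    n_genes = len(genes)
    perms = np.stack([rng.permutation(n_genes) for _ in range(n_perm)])
    null = np.einsum("gl,pgk->plk", f, w_mat.T[perms])  # (p, labels, locales)
    # two-sided permutation p-value with the +1 correction
    extreme = (np.abs(null) >= np.abs(scores)[None]).sum(axis=0)
    pvals = (extreme + 1) / (n_perm + 1)
    rows = []
    for li, label in enumerate(pattern_freqs.columns):
        for ki, locale in enumerate(locales):
            rows.append(
                {
                    "label": label,
                    "locale": locale,
                    "score": float(scores[li, ki]),
                    "p_value": float(pvals[li, ki]),
                    "n_overlap": overlap[locale],
                }
            )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = false_discovery_control(out["p_value"], method="bh")
    return out


def composition_shift(comp_a: np.ndarray, comp_b: np.ndarray) -> float:
    """1D Wasserstein distance between two domain-composition distributions.

    Both inputs are non-negative vectors summing to one over the same
    canonically ordered domain axis (nucleus first); with unit spacing the
    distance equals the summed absolute difference of the CDFs.
    """
    a = np.asarray(comp_a, dtype=float)
    b = np.asarray(comp_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("domain axes differ in length")
    for v, name in ((a, "comp_a"), (b, "comp_b")):
        if (v < -1e-12).any() or abs(v.sum() - 1) > 1e-6:
            raise ValueError(f"{name} must be a non-negative distribution summing to 1")
    return float(np.abs(np.cumsum(a - b)[:-1]).sum())


def gene_domain_composition(
    dataset: CellDataset, fluxmaps: FluxmapResult, embedding: FluxEmbedding
) -> pd.DataFrame:
    """Fraction of each gene's molecules per fluxmap domain (rows sum to 1).

    Molecules are assigned the domain of the nearest grid query within
    their cell (the grid tiles partition the cell at step resolution).
    Genes with no in-cell molecules are dropped with a note.
    """
    from scipy.spatial import cKDTree

    table = embedding.grid.table
    assigned = dataset.points[dataset.points["cell_id"] != UNASSIGNED]
    domains = sorted(np.unique(fluxmaps.labels))
    counts = pd.DataFrame(
        0.0, index=sorted(assigned["gene"].unique()), columns=domains
    )
    for cell_id, sub in table.groupby("cell_id", sort=True):
        pts = assigned[assigned["cell_id"] == cell_id]
        if not len(pts):
            continue
        tree = cKDTree(sub[["x", "y"]].to_numpy(float))
        _, nearest = tree.query(pts[["x", "y"]].to_numpy(float))
        labs = fluxmaps.labels[sub.index.to_numpy()][nearest]
        for gene, lab in zip(pts["gene"], labs):
            counts.loc[gene, lab] += 1
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} gene(s) with no in-cell molecules dropped", stacklevel=2
        )
        counts = counts[~zero]
        totals = totals[~zero]
    frac = counts.div(totals, axis=0)
    frac.index.name = "gene"
    frac.columns = [f"domain_{d}" for d in domains]
    return frac


__all__ = [
    "EnrichmentScores",
    "composition_shift",
    "domain_enrichment",
    "flux_enrichment",
    "gene_domain_composition",
    "load_locale_weights",
    "pattern_enrichment",
]
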