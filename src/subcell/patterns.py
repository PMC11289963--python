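"""Multilabel RNA localization-pattern classification.

Each gene-in-cell sample (a 2D point set plus the cell and nucleus
polygons) is summarized by 13 spatial features in three groups —
compartment proximity, symmetry about the center of mass, and
dispersion/point density — each normalized to the cell's morphology so
that every feature is translation- and scale-invariant.  An ensemble of
five one-vs-rest binary random-forest classifiers assigns one or more of
the labels {cell_edge, cytoplasmic, nuclear, nuclear_edge, none}; a sample
whose five probabilities all fall below 0.5 gets the fallback label
``none``.

A 64x64 grayscale rasterization of each sample is also provided
(background 0, cytoplasm 20, nucleus 40, molecule bins 40 + 20n, all
divided by 255 and capped at 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial.distance import pdist, squareform
from shapely.geometry import Polygon
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score, precision_score, recall_score
from sklearn.model_selection import cross_val_score

from ._geometry import (
    boundary_distance_fn,
    boundary_distance_quantile,
    contains_fn,
    polygon_normalized_second_moment,
)
from .simulate import LABELS, SimSample

FEATURE_NAMES = (
    # group A: proximity to compartments
    "cell_boundary_distance",  # f1 mean distance to cell membrane / R_eq
    "nucleus_boundary_distance",  # f2 mean distance to nuclear membrane / R_eq
    "nuclear_fraction",  # f3 fraction of molecules inside the nucleus
    # group B: symmetry about the center of mass
    "polarization",  # f4 |point centroid - cell centroid| / R_eq
    "moment_asymmetry",  # f5 (l1-l2)/(l1+l2) of the point covariance
    "angular_dispersion",  # f6 circular variance of angles around the cell centroid
    # group C: dispersion and point density
    "dispersion_index",  # f7 mean sq. dist to point centroid / cell second moment
    "ripley_l_max",  # f8 max_t (L(t)-t) / R_eq
    "ripley_l_argmax",  # f9 argmax_t (L(t)-t) / R_eq
    "ripley_l_half",  # f10 (L(R_eq/2) - R_eq/2) / R_eq
    "nn_distance",  # f11 Clark-Evans ratio: mean NN dist / (0.5 sqrt(A/n))
    "local_density_ratio",  # f12 neighbor density within R_eq/4 vs CSR expectation
    "inner_quartile_fraction",  # f13 fraction beyond the 75th pct of boundary distance
)


class InsufficientPointsError(ValueError):
    """Fewer than two molecules: the spatial features are undefined."""


def _ripley_l(dist_matrix: np.ndarray, area: float, t: np.ndarray) -> np.ndarray:
    """Ripley's L function, L(t) = sqrt(K(t)/pi), without edge correction."""
    n = dist_matrix.shape[0]
    d = dist_matrix[np.triu_indices(n, k=1)]
    counts = 2.0 * np.searchsorted(np.sort(d), t, side="right")
    k = area * counts / (n * (n - 1))
    return np.sqrt(k / np.pi)


def compute_features(
    points: np.ndarray, cell: Polygon, nucleus: Polygon | None
) -> np.ndarray:
    """The 13-feature spatial summary of one gene-in-cell sample.

    All features are dimensionless: distances are normalized by the cell
    equivalent radius R_eq = sqrt(area/pi) and densities by the cell's
    overall density, so translating or uniformly rescaling the sample
    leaves the vector unchanged.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or len(points) < 2:
        raise InsufficientPointsError("at least 2 molecules are required")
    if nucleus is None:
        raise ValueError("nucleus polygon is required (features f2, f3)")
    area = cell.area
    r_eq = float(np.sqrt(area / np.pi))

    d_cell = boundary_distance_fn(cell)(points)
    d_nuc = boundary_distance_fn(nucleus)(points)
    in_nuc = contains_fn(nucleus)(points)

    f1 = float(d_cell.mean()) / r_eq
    f2 = float(d_nuc.mean()) / r_eq
    f3 = float(in_nuc.mean())

    centroid = points.mean(axis=0)
    cell_centroid = np.array([cell.centroid.x, cell.centroid.y])
    f4 = float(np.linalg.norm(centroid - cell_centroid)) / r_eq

    cov = np.cov(points.T, bias=True)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    tot = eig.sum()
    f5 = float((eig[0] - eig[1]) / tot) if tot > 0 else 0.0

    rel = points - cell_centroid
    rho = np.hypot(rel[:, 0], rel[:, 1])
    ok = rho > 1e-12 * r_eq
    if ok.any():
        unit = rel[ok] / rho[ok, None]
        f6 = float(1.0 - np.linalg.norm(unit.mean(axis=0)))
    else:
        f6 = 0.0

    second_moment = polygon_normalized_second_moment(cell)
    f7 = float(((points - centroid) ** 2).sum(axis=1).mean()) / second_moment

    dmat = squareform(pdist(points))
    t = np.linspace(0.0, r_eq, 32)[1:]
    l_minus_t = _ripley_l(dmat, area, t) - t
    imax = int(np.argmax(l_minus_t))
    f8 = float(l_minus_t[imax]) / r_eq
    f9 = float(t[imax]) / r_eq
    l_half = _ripley_l(dmat, area, np.array([r_eq / 2.0]))[0]
    f10 = float(l_half - r_eq / 2.0) / r_eq

    n = len(points)
    np.fill_diagonal(dmat, np.inf)
    nn = dmat.min(axis=1)
    f11 = float(nn.mean()) / (0.5 * np.sqrt(area / n))

    r_local = r_eq / 4.0
    neighbor_frac = (dmat <= r_local).sum(axis=1) / (n - 1)
    expected_frac = min(np.pi * r_local**2 / area, 1.0)
    f12 = float(neighbor_frac.mean()) / expected_frac

    d75 = boundary_distance_quantile(cell, 0.75)
    f13 = float((d_cell > d75).mean())

    vec = np.array([f1, f2, f3, f4, f5, f6, f7, f8, f9, f10, f11, f12, f13])
    if not np.all(np.isfinite(vec)):  # pragma: no cover - contract guard
        raise FloatingPointError("non-finite feature value")
    return vec


def features_from_samples(samples: list[SimSample]) -> pd.DataFrame:
    """Feature matrix (samples x 13) for simulated samples."""
    rows = [compute_features(s.points, s.cell.cell, s.cell.nucleus) for s in samples]
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES))


def rasterize(
    points: np.ndarray, cell: Polygon, nucleus: Polygon | None, size: int = 64
) -> np.ndarray:
    """Grayscale raster encoding of a sample on a ``size`` x ``size`` grid.

    The cell bounding box, padded to square, is tiled into bins.  Raw
    values: background 0, cytoplasm 20, nucleus 40, and 40 + 20n for a bin
    holding n molecules; the raster is then divided by 255 and capped at 1.
    Output is row 0 = lowest y, value = img[row, col].
    """
    points = np.asarray(points, dtype=float)
    minx, miny, maxx, maxy = cell.bounds
    extent = max(maxx - minx, maxy - miny)
    cx, cy = (minx + maxx) / 2.0, (miny + maxy) / 2.0
    x0, y0 = cx - extent / 2.0, cy - extent / 2.0

    centers = (np.arange(size) + 0.5) * extent / size
    xx, yy = np.meshgrid(x0 + centers, y0 + centers)
    grid = np.column_stack([xx.ravel(), yy.ravel()])
    raw = np.zeros(size * size)
    in_cell = contains_fn(cell)(grid)
    raw[in_cell] = 20.0
    if nucleus is not None:
        in_nuc = contains_fn(nucleus)(grid)
        raw[in_nuc] = 40.0
    raw = raw.reshape(size, size)

    if len(points):
        col = np.clip((points[:, 0] - x0) / extent * size, 0, size - 1).astype(int)
        row = np.clip((points[:, 1] - y0) / extent * size, 0, size - 1).astype(int)
        occupancy = np.zeros((size, size), dtype=int)
        np.add.at(occupancy, (row, col), 1)
        occupied = occupancy > 0
        raw[occupied] = 40.0 + 20.0 * occupancy[occupied]
    return np.minimum(raw / 255.0, 1.0)


@dataclass
class PatternPrediction:
    """Per-label probabilities and the assigned multilabel set."""

    probabilities: dict[str, float]
    assigned: tuple[str, ...]


@dataclass
class PatternModel:
    """Five one-vs-rest binary random forests, one per localization label."""

    classifiers: dict[str, RandomForestClassifier]
    labels: tuple[str, ...] = LABELS
    threshold: float = 0.5
    cv_table: pd.DataFrame | None = None
    version: str = "1"

    def predict_proba(self, features: pd.DataFrame | np.ndarray) -> pd.DataFrame:
        x = np.asarray(features, dtype=float)
        cols = {}
        for label in self.labels:
            clf = self.classifiers[label]
            pos = list(clf.classes_).index(True)
            cols[label] = clf.predict_proba(x)[:, pos]
        return pd.DataFrame(cols)

    def predict(self, features: pd.DataFrame | np.ndarray) -> list[PatternPrediction]:
        proba = self.predict_proba(features)
        out = []
        for _, row in proba.iterrows():
            assigned = tuple(l for l in self.labels if row[l] >= self.threshold)
            if not assigned:
                assigned = ("none",)
            out.append(PatternPrediction(probabilities=row.to_dict(), assigned=assigned))
        return out


def train(
    features: pd.DataFrame,
    labels: np.ndarray,
    n_estimators: int = 200,
    seed: int = 0,
    run_cv: bool = False,
    cv_folds: int = 5,
) -> PatternModel:
    """Fit the five-binary-classifier ensemble on single-label training data.

    ``labels`` holds one class name per row; each binary forest is trained
    one-vs-rest with balanced class weights and a fixed seed.  With
    ``run_cv`` a 5-fold cross-validated F1 per label is recorded.
    """
    labels = np.asarray(labels)
    missing = set(LABELS) - set(labels)
    if missing:
        raise ValueError(f"training data lacks label(s) {sorted(missing)}")
    x = np.asarray(features, dtype=float)
    classifiers: dict[str, RandomForestClassifier] = {}
    cv_rows = []
    for label in LABELS:
        y = labels == label
        clf = RandomForestClassifier(
            n_estimators=n_estimators,
            class_weight="balanced",
            random_state=seed,
            n_jobs=1,
        )
        if run_cv:
            scores = cross_val_score(clf, x, y, cv=cv_folds, scoring="f1")
            cv_rows.append({"label": label, "cv_f1_mean": scores.mean(), "cv_f1_std": scores.std()})
        clf.fit(x, y)
        classifiers[label] = clf
    cv_table = pd.DataFrame(cv_rows) if cv_rows else None
    return PatternModel(classifiers=classifiers, cv_table=cv_table)


def predict(model: PatternModel, features: pd.DataFrame) -> list[PatternPrediction]:
    return model.predict(features)


def evaluate(
    model: PatternModel, features: pd.DataFrame, labels: np.ndarray
) -> pd.DataFrame:
    """Per-label precision/recall/F1 plus a macro row.

    Ground truth is single-label; a prediction counts as positive for a
    label when that label is in the assigned set.
    """
    labels = np.asarray(labels)
    preds = model.predict(features)
    rows = []
    f1s = []
    for label in LABELS:
        y_true = labels == label
        y_pred = np.array([label in p.assigned for p in preds])
        p = precision_score(y_true, y_pred, zero_division=0)
        r = recall_score(y_true, y_pred, zero_division=0)
        f = f1_score(y_true, y_pred, zero_division=0)
        rows.append(
            {
                "label": label,
                "precision": p,
                "recall": r,
                "f1": f,
                "tp": int((y_true & y_pred).sum()),
                "fp": int((~y_true & y_pred).sum()),
                "fn": int((y_true & ~y_pred).sum()),
                "tn": int((~y_true & ~y_pred).sum()),
            }
        )
        f1s.append(f)
    rows.append(
        {
            "label": "macro",
            "precision": np.mean([r["precision"] for r in rows]),
            "recall": np.mean([r["recall"] for r in rows]),
            "f1": float(np.mean(f1s)),
            "tp": sum(r["tp"] for r in rows),
            "fp": sum(r["fp"] for r in rows),
            "fn": sum(r["fn"] for r in rows),
            "tn": sum(r["tn"] for r in rows),
        }
    )
    return pd.DataFrame(rows).set_index("label")


def save_model(model: PatternModel, path) -> None:
    """Serialize a fitted ensemble (joblib with a version tag)."""
    import joblib

    joblib.dump({"version": model.version, "model": model}, path)


def load_model(path) -> PatternModel:
    import joblib

    payload = joblib.load(path)
    return payload["model"]
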