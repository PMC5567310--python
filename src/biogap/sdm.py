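"""Species distribution models and protected-area representativeness.

The environmental stack (19 climate-like + 2 terrain-like layers by default)
is reduced to its first four correlation-matrix PCA axes; suitability models
are fitted on those axes at presence points:

* bioclim — percentile envelope: per axis 1 - 2|ECDF - 0.5| (midpoint ECDF),
  0 outside the training envelope; suitability = min over axes;
* domain — Gower similarity to the closest training point;
* mahalanobis — exp(-D^2/2) to the training mean/covariance;
* glm — logistic regression of presences vs pseudo-absences.

Suitability is binarised at the lowest training-point suitability — the most
conservative threshold supported by the data, which forces zero training
omission — and models are kept only when their pseudo-absence AUC exceeds
0.7. Representativeness is the percentage of the binary range (restricted to
remaining native vegetation) that falls inside protected areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.stats import kruskal, mannwhitneyu, rankdata
from shapely.geometry.base import BaseGeometry
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

from .geoio import points_array, read_ascii_grid, write_ascii_grid

AUC_KEEP_THRESHOLD = 0.7
MIN_PRESENCES = 15
ALGORITHMS = ("bioclim", "domain", "mahalanobis", "glm")


class SDMError(ValueError):
    pass


@dataclass
class EnvStack:
    """Aligned raster layers on a regular grid; row 0 is the northern edge."""

    data: np.ndarray  # (n_layers, nrows, ncols)
    names: list[str]
    xmin: float
    ymin: float
    cellsize: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        nr, nc = self.shape
        return (
            self.xmin,
            self.ymin,
            self.xmin + nc * self.cellsize,
            self.ymin + nr * self.cellsize,
        )

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        nr, nc = self.shape
        col = np.clip(((x - self.xmin) / self.cellsize).astype(int), 0, nc - 1)
        row = np.clip(
            (nr - 1 - (y - self.ymin) / self.cellsize).astype(int), 0, nr - 1
        )
        return row, col

    def values_at(self, x, y) -> np.ndarray:
        """(n_points, n_layers) layer values at point coordinates."""
        row, col = self.cell_index(x, y)
        return self.data[:, row, col].T

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nr, nc = self.shape
        xs = self.xmin + (np.arange(nc) + 0.5) * self.cellsize
        ys = self.ymin + (nr - 1 - np.arange(nr) + 0.5) * self.cellsize
        return np.meshgrid(xs, ys)

    def write(self, directory, prefix: str = "env") -> list[str]:
        paths = []
        for i, name in enumerate(self.names):
            p = f"{directory}/{prefix}_{name}.asc"
            write_ascii_grid(self.data[i], p, self.xmin, self.ymin, self.cellsize)
            paths.append(p)
        return paths

    @classmethod
    def read(cls, paths: Sequence[str], names: Sequence[str] | None = None):
        arrays, header = [], None
        for p in paths:
            arr, h = read_ascii_grid(p)
            arrays.append(arr)
            header = h
        return cls(
            data=np.stack(arrays),
            names=list(names) if names else [f"layer{i}" for i in range(len(paths))],
            xmin=header["xllcorner"],
            ymin=header["yllcorner"],
            cellsize=header["cellsize"],
        )


@dataclass
class PCAResult:
    axes: EnvStack  # first n component-score rasters
    loadings: np.ndarray  # (n_layers, n_axes)
    explained_variance_ratio: np.ndarray


def pca_env(stack: EnvStack, n_axes: int = 4) -> PCAResult:
    """Correlation-matrix PCA of the stack; returns component-score rasters."""
    n_layers, nr, nc = stack.data.shape
    if n_layers < n_axes:
        raise SDMError(f"need at least {n_axes} layers")
    flat = stack.data.reshape(n_layers, -1).T  # (cells, layers)
    sd = flat.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise SDMError("constant environmental layer; correlation PCA undefined")
    z = (flat - flat.mean(axis=0)) / sd
    pca = PCA(n_components=n_axes, svd_solver="full")
    scores = pca.fit_transform(z)
    axes = EnvStack(
        data=scores.T.reshape(n_axes, nr, nc),
        names=[f"pc{i + 1}" for i in range(n_axes)],
        xmin=stack.xmin,
        ymin=stack.ymin,
        cellsize=stack.cellsize,
    )
    return PCAResult(
        axes=axes,
        loadings=pca.components_.T,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


# ---------------------------------------------------------------------------
# Suitability models


@dataclass
class SDMFit:
    algorithm: str
    suitability: np.ndarray  # raster in [0, 1]
    predict: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    threshold: float | None = None
    auc: float | None = None
    kept: bool | None = None
    binary_range: np.ndarray | None = None  # bool raster


def _env_at(axes: EnvStack, xy: np.ndarray) -> np.ndarray:
    return axes.values_at(xy[:, 0], xy[:, 1])


def fit_bioclim(presences_xy: np.ndarray, axes: EnvStack) -> SDMFit:
    train = _env_at(axes, _check_presences(presences_xy))
    sorted_cols = [np.sort(train[:, j]) for j in range(train.shape[1])]
    n = train.shape[0]

    def predict(vals: np.ndarray) -> np.ndarray:
        suit = np.ones(vals.shape[0])
        for j, col in enumerate(sorted_cols):
            v = vals[:, j]
            lo = np.searchsorted(col, v, side="left")
            hi = np.searchsorted(col, v, side="right")
            f = (lo + 0.5 * (hi - lo)) / n  # midpoint ECDF
            s = 2.0 * np.minimum(f, 1.0 - f)
            s[(v < col[0]) | (v > col[-1])] = 0.0
            suit = np.minimum(suit, s)
        return np.clip(suit, 0.0, 1.0)

    return _finish("bioclim", predict, axes)


def fit_domain(presences_xy: np.ndarray, axes: EnvStack) -> SDMFit:
    train = _env_at(axes, _check_presences(presences_xy))
    rng_ = train.max(axis=0) - train.min(axis=0)
    rng_[rng_ == 0] = 1.0

    def predict(vals: np.ndarray) -> np.ndarray:
        # Gower similarity to the closest training point, chunked
        out = np.empty(vals.shape[0])
        for start in range(0, vals.shape[0], 4096):
            chunk = vals[start : start + 4096]
            d = np.abs(chunk[:, None, :] - train[None, :, :]) / rng_
            out[start : start + 4096] = 1.0 - d.mean(axis=2).min(axis=1)
        return np.clip(out, 0.0, 1.0)

    return _finish("domain", predict, axes)


def fit_mahalanobis(presences_xy: np.ndarray, axes: EnvStack) -> SDMFit:
    train = _env_at(axes, _check_presences(presences_xy))
    mean = train.mean(axis=0)
    cov = np.cov(train, rowvar=False)
    if np.linalg.cond(cov) > 1e12:
        raise SDMError("singular training covariance; mahalanobis model unavailable")
    inv = np.linalg.inv(cov)

    def predict(vals: np.ndarray) -> np.ndarray:
        d = vals - mean
        d2 = np.einsum("ij,jk,ik->i", d, inv, d)
        return np.exp(-0.5 * d2)

    return _finish("mahalanobis", predict, axes)


def fit_glm(
    presences_xy: np.ndarray, axes: EnvStack, pseudo_absences_xy: np.ndarray
) -> SDMFit:
    xp = _env_at(axes, _check_presences(presences_xy))
    xa = _env_at(axes, np.asarray(pseudo_absences_xy, float))
    X = np.vstack([xp, xa])
    y = np.r_[np.ones(len(xp)), np.zeros(len(xa))]
    model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)  # unpenalised
    model.fit(X, y)

    def predict(vals: np.ndarray) -> np.ndarray:
        return model.predict_proba(vals)[:, 1]

    return _finish("glm", predict, axes)


def _check_presences(presences_xy) -> np.ndarray:
    xy = np.asarray(presences_xy, float)
    if len(xy) <= MIN_PRESENCES:
        raise SDMError(
            f"needs more than {MIN_PRESENCES} presences, got {len(xy)}"
        )
    return xy


def _finish(name: str, predict, axes: EnvStack) -> SDMFit:
    nr, nc = axes.shape
    vals = axes.data.reshape(axes.data.shape[0], -1).T
    suit = predict(vals).reshape(nr, nc)
    return SDMFit(algorithm=name, suitability=suit, predict=predict)


def fit_sdm(
    algorithm: str,
    presences_xy: np.ndarray,
    axes: EnvStack,
    pseudo_absences_xy: np.ndarray | None = None,
) -> SDMFit:
    if algorithm == "glm":
        if pseudo_absences_xy is None:
            raise SDMError("glm requires pseudo-absences")
        return fit_glm(presences_xy, axes, pseudo_absences_xy)
    fitter = {
        "bioclim": fit_bioclim,
        "domain": fit_domain,
        "mahalanobis": fit_mahalanobis,
    }.get(algorithm)
    if fitter is None:
        raise SDMError(f"unknown SDM algorithm {algorithm!r}")
    return fitter(presences_xy, axes)


def sample_pseudo_absences(
    axes: EnvStack,
    presences_xy: np.ndarray,
    seed: int,
    n: int | None = None,
    exclusion_cells: int = 1,
) -> np.ndarray:
    """Uniform random background cell centres, excluding cells within
    ``exclusion_cells`` of any presence; count defaults to 10x presences."""
    rng = np.random.default_rng(seed)
    xy = np.asarray(presences_xy, float)
    n = n if n is not None else 10 * len(xy)
    nr, nc = axes.shape
    prow, pcol = axes.cell_index(xy[:, 0], xy[:, 1])
    forbidden = np.zeros((nr, nc), dtype=bool)
    k = exclusion_cells
    for r, c in zip(prow, pcol):
        forbidden[max(0, r - k) : r + k + 1, max(0, c - k) : c + k + 1] = True
    free = np.flatnonzero(~forbidden.ravel())
    if len(free) == 0:
        raise SDMError("no background cells left after presence exclusion")
    pick = rng.choice(free, size=min(n, len(free)), replace=len(free) < n)
    rows, cols = np.unravel_index(pick, (nr, nc))
    x = axes.xmin + (cols + 0.5) * axes.cellsize
    y = axes.ymin + (nr - 1 - rows + 0.5) * axes.cellsize
    return np.column_stack([x, y])


def apply_threshold(fit: SDMFit, presences_xy: np.ndarray, axes: EnvStack) -> SDMFit:
    """Binarise at the minimum training-point suitability (zero omission)."""
    xy = np.asarray(presences_xy, float)
    train_suit = fit.predict(_env_at(axes, xy))
    fit.threshold = float(train_suit.min())
    fit.binary_range = fit.suitability >= fit.threshold - 1e-12
    return fit


def rank_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Mann-Whitney AUC with half credit for ties."""
    pos = np.asarray(pos_scores, float)
    neg = np.asarray(neg_scores, float)
    if len(pos) == 0 or len(neg) == 0:
        raise SDMError("AUC needs nonempty presence and absence score sets")
    ranks = rankdata(np.r_[pos, neg])
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def auc_pseudoabsence(
    fit: SDMFit,
    presences_xy: np.ndarray,
    pseudo_absences_xy: np.ndarray,
    axes: EnvStack,
) -> SDMFit:
    pos = fit.predict(_env_at(axes, np.asarray(presences_xy, float)))
    neg = fit.predict(_env_at(axes, np.asarray(pseudo_absences_xy, float)))
    fit.auc = rank_auc(pos, neg)
    fit.kept = fit.auc > AUC_KEEP_THRESHOLD
    return fit


# ---------------------------------------------------------------------------
# Representativeness


def rasterize(geometries: Sequence[BaseGeometry], stack: EnvStack) -> np.ndarray:
    """Boolean mask of cells whose centre lies inside any geometry."""
    gx, gy = stack.cell_centers()
    pts = points_array(gx.ravel(), gy.ravel())
    union = shapely.union_all(list(geometries)) if len(geometries) else None
    if union is None or union.is_empty:
        return np.zeros(stack.shape, dtype=bool)
    return shapely.covers(union, pts).reshape(stack.shape)


def representativeness(
    binary_range: np.ndarray,
    pa_mask: np.ndarray,
    native_veg_mask: np.ndarray | None = None,
) -> float | None:
    """Percentage of the (native-vegetation) range inside protected areas.

    Returns None when the range retains no native vegetation (flagged
    undefined rather than 0)."""
    rng = binary_range.astype(bool)
    if native_veg_mask is not None:
        rng = rng & native_veg_mask.astype(bool)
    denom = rng.sum()
    if denom == 0:
        return None
    return float(100.0 * (rng & pa_mask.astype(bool)).sum() / denom)


def sdm_summary(results: pd.DataFrame) -> dict:
    """Medians and quartiles of %-inside-PA per algorithm x group, with a
    Kruskal-Wallis comparison across groups within each algorithm.

    ``results`` columns: species_id, algorithm, group, pct_inside_pa.
    """
    kept = results.dropna(subset=["pct_inside_pa"])
    summary = (
        kept.groupby(["algorithm", "group"])["pct_inside_pa"]
        .agg(median="median", q25=lambda s: s.quantile(0.25),
             q75=lambda s: s.quantile(0.75), n="count")
        .reset_index()
    )
    tests = {}
    for alg, grp in kept.groupby("algorithm"):
        samples = [g["pct_inside_pa"].to_numpy() for _, g in grp.groupby("group")]
        labels = sorted(grp["group"].unique())
        if len(samples) >= 2 and all(len(s) >= 2 for s in samples):
            if np.ptp(np.concatenate(samples)) == 0:
                h, p = 0.0, 1.0  # scipy rejects all-identical samples
            else:
                h, p = kruskal(*samples)
            pairwise = {}
            for i in range(len(samples)):
                for j in range(i + 1, len(samples)):
                    u, pu = mannwhitneyu(
                        samples[i], samples[j], alternative="two-sided"
                    )
                    pairwise[f"{labels[i]}|{labels[j]}"] = {
                        "U": float(u), "p": float(pu)
                    }
            tests[alg] = {"H": float(h), "p": float(p), "pairwise": pairwise}
    return {"summary": summary, "tests": tests}
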