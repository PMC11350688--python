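"""Maximum-entropy habitat suitability on 1-km^2 grids.

A minimal maximum-entropy (Gibbs) species distribution model: given presence
cells and standardized environmental layers f_j, the occurrence distribution
over non-masked cells is

    p(cell) = exp(sum_j lambda_j f_j(cell)) / Z(lambda)

with the weights lambda fitted by L2-penalized maximum likelihood, so that
model feature expectations match presence-sample means up to a slack
proportional to the penalty. Suitability per cell is reported on [0, 1]
either as the complementary log-log transform (the convention of recent
MaxEnt releases) or as the raw probability rescaled by its maximum.

Downstream, the paper-style habitat accounting thresholds the suitability
index (potential habitat 0.5-0.7, highly suitable 0.7-1.0, distribution
range >= 0.5), converts qualifying cells to area, and measures the
between-species overlap of thresholded ranges.

Rasters are exchanged as ESRI ASCII grids (.asc) with a NODATA value.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "SuitabilityGrid",
    "MaxentFit",
    "SUITABILITY_CLASSES",
    "read_ascii_grid",
    "write_ascii_grid",
    "standardize_layers",
    "fit_maxent",
    "classify_suitability",
    "habitat_area",
    "overlap_ratio",
]

#: Suitability classes, half-open lower-inclusive except the closed top.
SUITABILITY_CLASSES: tuple[tuple[str, float, float], ...] = (
    ("unsuitable", 0.0, 0.5),
    ("potential", 0.5, 0.7),
    ("high", 0.7, 1.0 + 1e-12),  # include index == 1.0
)


@dataclass
class SuitabilityGrid:
    """Per-cell habitat index in [0, 1] on a regular grid with a nodata mask."""

    index: np.ndarray  # (rows, cols) float
    mask: np.ndarray | None = None  # True where valid; None = all valid
    cell_resolution: float = 1.0  # km^2 per cell

    def __post_init__(self) -> None:
        self.index = np.asarray(self.index, dtype=float)
        if self.mask is None:
            self.mask = np.ones_like(self.index, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.index.shape:
            raise ValueError("mask shape must match index shape")
        if self.cell_resolution <= 0:
            raise ValueError("cell_resolution must be > 0")
        vals = self.index[self.mask]
        if vals.size and (vals.min() < 0.0 or vals.max() > 1.0):
            raise ValueError("suitability indices must lie in [0, 1]")

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())


@dataclass
class MaxentFit:
    """Fitted Gibbs model: feature weights, penalty, convergence and loss trace."""

    weights: np.ndarray  # one lambda per layer
    regularization: float
    converged: bool
    trace: list[float] = field(default_factory=list)  # penalized NLL per iterate
    probability: np.ndarray | None = None  # p(cell), sums to 1 over valid cells


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; returns (array with NaN at nodata, header dict)."""
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = text.strip().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    if "ncols" not in header or "nrows" not in header:
        raise ValueError("ASCII grid header missing ncols/nrows")
    data = np.loadtxt(io.StringIO("\n".join(lines[i:])), ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (nrows, ncols):
        raise ValueError(f"grid body {data.shape} does not match header ({nrows}, {ncols})")
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    return data, header


def write_ascii_grid(
    array: np.ndarray,
    path,
    cellsize: float = 1.0,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    nodata: float = -9999.0,
) -> None:
    """Write a 2-D array as an ESRI ASCII grid (NaN -> NODATA_value)."""
    a = np.asarray(array, dtype=float)
    body = np.where(np.isnan(a), nodata, a)
    header = (
        f"ncols {a.shape[1]}\nnrows {a.shape[0]}\n"
        f"xllcorner {xllcorner}\nyllcorner {yllcorner}\n"
        f"cellsize {cellsize}\nNODATA_value {nodata}\n"
    )
    lines = "\n".join(" ".join(f"{v:.6g}" for v in row) for row in body)
    if hasattr(path, "write"):
        path.write(header + lines + "\n")
    else:
        with open(path, "w") as fh:
            fh.write(header + lines + "\n")


def standardize_layers(layers: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero-mean unit-variance scaling over valid cells; constant layers -> 0."""
    out = np.zeros_like(layers, dtype=float)
    for j, layer in enumerate(layers):
        vals = layer[mask]
        sd = vals.std()
        if sd > 0:
            out[j][mask] = (layer[mask] - vals.mean()) / sd
    return out


def maxent_objective(
    lam: np.ndarray, features: np.ndarray, presence_idx: np.ndarray, alpha: float
) -> tuple[float, np.ndarray]:
    """Penalized negative mean log-likelihood of the Gibbs model and its gradient.

    features : (n_features, n_valid_cells) standardized layer values
    presence_idx : indices into the valid-cell axis, one per presence
    """
    scores = lam @ features
    shift = scores.max()  # log-sum-exp stabilisation
    logz = shift + np.log(np.exp(scores - shift).sum())
    emp = features[:, presence_idx].mean(axis=1)
    nll = -(lam @ emp) + logz  # mean over presences
    p = np.exp(scores - logz)
    grad = features @ p - emp + alpha * lam
    return float(nll + 0.5 * alpha * (lam @ lam)), grad


def fit_maxent(
    presences: np.ndarray,
    layers: np.ndarray,
    regularization: float = 0.1,
    mask: np.ndarray | None = None,
    transform: str = "cloglog",
    cell_resolution: float = 1.0,
) -> tuple[MaxentFit, SuitabilityGrid]:
    """Fit the penalized Gibbs model and map suitability on [0, 1].

    presences : (n, 2) integer (row, col) presence cells (>= 5 of them)
    layers : (n_layers, rows, cols) environmental rasters (standardized
        internally over non-masked cells)
    regularization : L2 penalty strength alpha (> 0 keeps the fit proper when
        features separate the presences)
    transform : 'cloglog' (default) maps p to 1 - exp(-exp(H) * p) with H the
        entropy of p, so a uniform model scores ~0.63 everywhere; 'raw' uses
        p / max(p).

    Presences on masked cells raise; divergence is reported through the
    ``converged`` flag, never silently.
    """
    layers = np.asarray(layers, dtype=float)
    if layers.ndim != 3 or layers.shape[0] < 1:
        raise ValueError("layers must be (n_layers, rows, cols) with >= 1 layer")
    rows, cols = layers.shape[1:]
    if mask is None:
        mask = ~np.any(np.isnan(layers), axis=0)
    pres = np.asarray(presences, dtype=int)
    if pres.ndim != 2 or pres.shape[1] != 2:
        raise ValueError("presences must be (n, 2) row/col pairs")
    if pres.shape[0] < 5:
        raise ValueError("need >= 5 presence points")
    if (pres[:, 0].min() < 0 or pres[:, 0].max() >= rows
            or pres[:, 1].min() < 0 or pres[:, 1].max() >= cols):
        raise ValueError("presence outside layer extent")
    if not mask[pres[:, 0], pres[:, 1]].all():
        raise ValueError("presence falls on a masked (nodata) cell")

    std = standardize_layers(layers, mask)
    features = std[:, mask]  # (n_features, n_valid)
    flat_valid = np.flatnonzero(mask.ravel())
    lookup = {c: i for i, c in enumerate(flat_valid)}
    presence_idx = np.array([lookup[r * cols + c] for r, c in pres])

    trace: list[float] = []

    def fun(lam):
        val, grad = maxent_objective(lam, features, presence_idx, regularization)
        return val, grad

    res = optimize.minimize(
        fun,
        x0=np.zeros(layers.shape[0]),
        jac=True,
        method="L-BFGS-B",
        callback=lambda lam: trace.append(
            maxent_objective(lam, features, presence_idx, regularization)[0]
        ),
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10},
    )
    lam = res.x
    scores = lam @ features
    scores -= scores.max()
    p = np.exp(scores)
    p /= p.sum()

    if transform == "cloglog":
        entropy = -np.sum(p * np.log(np.maximum(p, 1e-300)))
        suit_valid = 1.0 - np.exp(-np.exp(entropy) * p)
    elif transform == "raw":
        suit_valid = p / p.max()
    else:
        raise ValueError(f"unknown transform {transform!r}")

    index = np.zeros((rows, cols))
    index[mask] = np.clip(suit_valid, 0.0, 1.0)
    fit = MaxentFit(
        weights=lam,
        regularization=regularization,
        converged=bool(res.success) and np.all(np.isfinite(lam)),
        trace=trace,
        probability=p,
    )
    return fit, SuitabilityGrid(index=index, mask=mask, cell_resolution=cell_resolution)


def classify_suitability(grid: SuitabilityGrid) -> np.ndarray:
    """Label each valid cell 'unsuitable' / 'potential' / 'high' (else 'nodata')."""
    labels = np.full(grid.index.shape, "nodata", dtype=object)
    for name, lo, hi in SUITABILITY_CLASSES:
        sel = grid.mask & (grid.index >= lo) & (grid.index < hi)
        labels[sel] = name
    return labels


def habitat_area(grid: SuitabilityGrid, class_or_threshold) -> float:
    """Area (km^2) of cells in a suitability class or at/above a numeric threshold.

    A string selects one class ('potential', 'high', 'unsuitable') or the
    union 'distribution' (index >= 0.5, the actual distribution range); a
    number counts valid cells with index >= threshold.
    """
    if isinstance(class_or_threshold, str):
        if class_or_threshold == "distribution":
            qualifying = grid.mask & (grid.index >= 0.5)
        else:
            names = [c[0] for c in SUITABILITY_CLASSES]
            if class_or_threshold not in names:
                raise ValueError(f"unknown class {class_or_threshold!r}")
            qualifying = classify_suitability(grid) == class_or_threshold
    else:
        qualifying = grid.mask & (grid.index >= float(class_or_threshold))
    return float(qualifying.sum()) * grid.cell_resolution


def overlap_ratio(
    grid_a: SuitabilityGrid,
    grid_b: SuitabilityGrid,
    threshold: float = 0.5,
    report: bool = False,
) -> tuple[float, float]:
    """Shared-range overlap between two species' thresholded suitability maps.

    Both grids are thresholded at ``threshold``; with O the overlap area the
    return is (O / area_A, O / area_B) — each species' share of its own range
    that it shares with the other. ``report=True`` rounds to 1 dp, the
    precision of a printed ratio like '0.4:0.3'. Empty ranges yield 0 shares.
    """
    if grid_a.index.shape != grid_b.index.shape:
        raise ValueError("grids must share a common extent")
    if grid_a.cell_resolution != grid_b.cell_resolution:
        raise ValueError("grids must share a common resolution")
    in_a = grid_a.mask & (grid_a.index >= threshold)
    in_b = grid_b.mask & (grid_b.index >= threshold)
    area_a, area_b = in_a.sum(), in_b.sum()
    overlap = (in_a & in_b).sum()
    share_a = float(overlap / area_a) if area_a else 0.0
    share_b = float(overlap / area_b) if area_b else 0.0
    if report:
        share_a, share_b = round(share_a, 1), round(share_b, 1)
    return share_a, share_b
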