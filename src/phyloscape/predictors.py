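"""Predictor derivation and screening: terrain indices from a DEM,
climatic-instability statistics from multi-period climate layers, and
collinearity screening (correlation clustering + stepwise VIF removal).

Climatic instability follows the refugium-detection idea: standardize the
CURRENT climate over cells, fit a PCA on it, project every historical
period (standardized with the current means/sds so that climate change —
not re-normalization — drives the geometry) onto PC1-PC2, and measure the
per-cell Euclidean distance travelled between consecutive periods,
oldest to present.  Cells with small aggregated distances are putative
climatic refugia.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .grid import Grid, GridLayer

__all__ = [
    "terrain_indices",
    "pca_instability",
    "lig_instability",
    "lgm_instability",
    "panel_from_layers",
    "scale_panel",
    "correlation_cluster",
    "vif_stepwise",
]


# ---------------------------------------------------------------------------
# terrain


def _neighbor_stack(z: np.ndarray) -> np.ndarray:
    """(8, ny, nx) stack of the 8-neighborhood, NaN where off-grid."""
    p = np.pad(z, 1, constant_values=np.nan)
    offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    return np.stack([p[1 + dr : 1 + dr + z.shape[0], 1 + dc : 1 + dc + z.shape[1]]
                     for dr, dc in offs])


def terrain_indices(dem: GridLayer) -> tuple[GridLayer, GridLayer, GridLayer]:
    """Slope (degrees, Horn's 3x3 method), Topographic Position Index and
    Terrain Ruggedness Index from an elevation layer.

    TPI(c) = z_c - mean(neighbors); TRI(c) = mean |z_n - z_c|; both use
    the 8-neighbor window, restricted to neighbors that exist at edges.
    Slope uses Horn's finite differences on an edge-replicated pad.
    """
    grid = dem.grid
    if grid.shape is None or min(grid.shape) < 2:
        raise ValueError("terrain indices need a regular grid with >= 2 rows/cols")
    z = grid.to_array(dem.values)
    nb = _neighbor_stack(z)

    with np.errstate(invalid="ignore"):
        tpi = z - np.nanmean(nb, axis=0)
        tri = np.nanmean(np.abs(nb - z[None]), axis=0)

    # Horn slope; rows run north -> south so +row is -y
    zp = np.pad(z, 1, mode="edge")
    a, b, c = zp[:-2, :-2], zp[:-2, 1:-1], zp[:-2, 2:]
    d, f = zp[1:-1, :-2], zp[1:-1, 2:]
    g, h, i = zp[2:, :-2], zp[2:, 1:-1], zp[2:, 2:]
    cs = grid.cell_size
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cs)
    dzdy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * cs)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))

    mk = lambda arr, nm: GridLayer(grid, grid.from_array(arr), nm)
    return mk(slope, "slope"), mk(tpi, "tpi"), mk(tri, "tri")


# ---------------------------------------------------------------------------
# climatic instability


def _layers_matrix(layers: list[GridLayer]) -> np.ndarray:
    return np.column_stack([l.values for l in layers])


def pca_instability(
    current: list[GridLayer],
    past: dict[str, list[GridLayer]],
    aggregate: str = "mean",
) -> GridLayer:
    """Aggregated per-cell PC-space step distance over a climate sequence.

    ``past`` maps period label -> layers, ordered OLDEST -> most recent;
    the sequence analysed is ``list(past) + [current]``.  ``aggregate`` is
    one of ``mean`` / ``sum`` / ``sd`` over the consecutive-step distances.
    """
    out = _instability_aggregates(current, past, (aggregate,))
    return out[aggregate]


def _instability_aggregates(
    current: list[GridLayer],
    past: dict[str, list[GridLayer]],
    aggregates: tuple[str, ...],
) -> dict[str, GridLayer]:
    if len(past) < 1:
        raise ValueError("need >= 2 periods including current")
    n_vars = len(current)
    names = [l.name for l in current]
    for label, layers in past.items():
        if len(layers) != n_vars:
            raise ValueError(
                f"period {label!r} has {len(layers)} variables, expected {n_vars}"
            )
    grid = current[0].grid

    X_cur = _layers_matrix(current)
    mu = X_cur.mean(axis=0)
    sd = X_cur.std(axis=0)
    for j, s in enumerate(sd):
        if s == 0:
            raise ValueError(f"variable {names[j]!r} is constant (zero variance)")

    pca = PCA(n_components=min(2, n_vars), svd_solver="full")
    pca.fit((X_cur - mu) / sd)

    seq = list(past.values()) + [current]
    scores = [pca.transform((_layers_matrix(layers) - mu) / sd) for layers in seq]
    steps = np.stack(
        [np.linalg.norm(scores[t + 1] - scores[t], axis=1)
         for t in range(len(scores) - 1)]
    )  # (n_steps, n_cells)

    out = {}
    for agg in aggregates:
        if agg == "mean":
            vals = steps.mean(axis=0)
        elif agg == "sum":
            vals = steps.sum(axis=0)
        elif agg == "sd":
            vals = steps.std(axis=0, ddof=0)
        else:
            raise ValueError(f"unknown aggregate {agg!r}")
        out[agg] = GridLayer(grid, vals, f"instability_{agg}", "PC units")
    return out


def lig_instability(
    current: list[GridLayer],
    layers_6ky: list[GridLayer],
    layers_21ky: list[GridLayer],
    layers_120ky: list[GridLayer],
) -> GridLayer:
    """Mean instability since the Last Inter-Glacial: the 4-period
    sequence 120 ky -> 21 ky -> 6 ky -> present (3 steps), aggregate =
    mean, on the full variable panel."""
    layer = pca_instability(
        current,
        {"120ky": layers_120ky, "21ky": layers_21ky, "6ky": layers_6ky},
        aggregate="mean",
    )
    layer.name = "lig_instability"
    return layer


def lgm_instability(series: list[list[GridLayer]]) -> dict[str, GridLayer]:
    """Mean / sum / sd instability since the Last Glacial Maximum over a
    dense (e.g. 500-year) series ordered oldest -> present; the last entry
    is the current climate the PCA is fitted on.  Uses the restricted
    variable panel passed in (precipitation / max and min temperature
    stand-ins)."""
    if len(series) < 2:
        raise ValueError("need >= 2 periods")
    current = series[-1]
    past = {f"p{k:03d}": layers for k, layers in enumerate(series[:-1])}
    out = _instability_aggregates(current, past, ("mean", "sum", "sd"))
    for agg, layer in out.items():
        layer.name = f"lgm_{agg}"
    return out


# ---------------------------------------------------------------------------
# predictor panel + collinearity screening


def panel_from_layers(layers: list[GridLayer]) -> pd.DataFrame:
    """Cells x predictors table (indexed by cell id, NaN = missing)."""
    grid = layers[0].grid
    return pd.DataFrame(
        {l.name: l.values for l in layers},
        index=pd.Index(list(grid.cell_ids), name="cell_id"),
    )


def scale_panel(panel: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize each column to mean 0 / sd 1 over non-missing rows;
    returns the scaled panel and the (mean, sd) scaling record."""
    mu = panel.mean()
    sd = panel.std(ddof=0)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant predictors cannot be scaled: {bad}")
    record = pd.DataFrame({"mean": mu, "sd": sd})
    return (panel - mu) / sd, record


def correlation_cluster(panel: pd.DataFrame, cut: float = 0.7) -> pd.DataFrame:
    """Advisory collinearity report: complete-linkage hierarchical
    clustering of predictors on distance 1 - |Pearson r|; predictors more
    correlated than ``cut`` (in absolute value) share a cluster."""
    cc = panel.dropna()
    r = np.corrcoef(cc.to_numpy(), rowvar=False)
    dist = 1.0 - np.abs(r)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2  # exact symmetry for squareform
    if panel.shape[1] < 2:
        labels = np.ones(panel.shape[1], dtype=int)
    else:
        Z = linkage(squareform(dist, checks=False), method="complete")
        labels = fcluster(Z, t=1.0 - cut, criterion="distance")
    return pd.DataFrame({"predictor": panel.columns, "cluster": labels}).sort_values(
        ["cluster", "predictor"]
    ).reset_index(drop=True)


def _vif(X: np.ndarray, j: int) -> float:
    """VIF of column j regressed on the others (with intercept)."""
    others = np.delete(X, j, axis=1)
    A = np.column_stack([np.ones(len(X)), others])
    y = X[:, j]
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        return np.inf
    r2 = 1.0 - (resid**2).sum() / ss_tot
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def vif_stepwise(
    panel: pd.DataFrame, threshold: float = 2.5
) -> tuple[list[str], pd.DataFrame]:
    """Stepwise collinearity removal: repeatedly drop the predictor with
    the largest variance inflation factor until all VIFs are <= threshold.
    Ties break alphabetically.  Returns the retained names and a per-step
    log (step, dropped, vif)."""
    cols = list(panel.columns)
    if len(cols) < 2:
        return cols, pd.DataFrame(columns=["step", "dropped", "vif"])
    cc = panel.dropna()
    log = []
    step = 0
    while len(cols) >= 2:
        X = cc[cols].to_numpy(dtype=float)
        vifs = np.array([_vif(X, j) for j in range(len(cols))])
        worst = vifs.max()
        if worst <= threshold:
            break
        # largest VIF; alphabetical tie-break
        cand = sorted(
            (cols[j] for j in range(len(cols)) if vifs[j] == worst)
        )[0]
        step += 1
        log.append({"step": step, "dropped": cand, "vif": float(worst)})
        cols = [c for c in cols if c != cand]
    return cols, pd.DataFrame(log, columns=["step", "dropped", "vif"])
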