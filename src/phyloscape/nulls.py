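"""Permutation null models for gridded PD and PE.

Two randomization schemes are provided:

* **tip shuffle** — permute species labels across tree tips, keeping the
  topology, branch lengths and the community matrix fixed.  Under this
  null a cell's PD distribution depends only on its richness.
* **independent swap** (fixed-fixed) — randomize the community matrix by
  repeated 2x2 checkerboard submatrix swaps, preserving each species'
  range size and each cell's richness exactly.

Each replicate draws ONE shuffled tree (or swapped matrix) for the whole
map, then recomputes the metric in every cell, mirroring a whole-map
randomization rather than per-cell resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import branch_ranges
from .grid import OccurrenceMatrix
from .tree import Phylogeny

__all__ = [
    "tip_shuffle",
    "independent_swap",
    "null_distribution",
    "classify_significant",
]


def tip_shuffle(tree: Phylogeny, seed) -> Phylogeny:
    """Return a copy of ``tree`` with tip labels permuted uniformly at
    random; topology and branch lengths untouched."""
    rng = np.random.default_rng(seed)
    labels = tree.tip_labels
    perm = rng.permutation(len(labels))
    return tree.relabel({labels[i]: labels[perm[i]] for i in range(len(labels))})


def independent_swap(
    occ: OccurrenceMatrix, n_iterations: int | None = None, seed=None
) -> OccurrenceMatrix:
    """Fixed-fixed matrix randomization via sequential checkerboard swaps.

    At each step, two cells and two species are drawn at random; if the
    2x2 submatrix is a checkerboard ([[1,0],[0,1]] or [[0,1],[1,0]]) it is
    flipped.  Both margins — per-cell richness and per-species range size —
    are invariant.  Default iteration count is 10x the number of presences
    (a common burn-in heuristic).  A matrix with no swappable submatrix is
    returned unchanged with a warning."""
    M = occ.matrix.copy()
    n_cells, n_sp = M.shape
    if n_iterations is None:
        n_iterations = 10 * int(M.sum())
    rng = np.random.default_rng(seed)
    if n_cells < 2 or n_sp < 2:
        warnings.warn("matrix too small to swap; returned unchanged", stacklevel=2)
        return OccurrenceMatrix(occ.grid, list(occ.species), M)

    rows = rng.integers(0, n_cells, size=(n_iterations, 2))
    cols = rng.integers(0, n_sp, size=(n_iterations, 2))
    swapped = 0
    for k in range(n_iterations):
        r1, r2 = rows[k]
        c1, c2 = cols[k]
        if r1 == r2 or c1 == c2:
            continue
        a, b, c, d = M[r1, c1], M[r1, c2], M[r2, c1], M[r2, c2]
        if a == d and b == c and a != b:  # checkerboard
            M[r1, c1], M[r1, c2] = b, a
            M[r2, c1], M[r2, c2] = d, c
            swapped += 1
    if swapped == 0:
        warnings.warn(
            "no checkerboard submatrix found; matrix returned unchanged",
            stacklevel=2,
        )
    return OccurrenceMatrix(occ.grid, list(occ.species), M)


def _metric_all_cells(metric: str, tree: Phylogeny, occ: OccurrenceMatrix,
                      perm: np.ndarray, inc: np.ndarray) -> np.ndarray:
    """PD or PE for every cell given a tip permutation of the incidence
    columns (tip shuffle acts on the community side as a column relabel)."""
    pres = inc[:, perm] @ occ.matrix.T.astype(np.float64) > 0
    if metric == "PD":
        return pres.T @ tree.length
    rng_size = pres.sum(axis=1)
    w = np.divide(tree.length, rng_size, out=np.zeros_like(tree.length),
                  where=rng_size > 0)
    return pres.T @ w


@dataclass
class NullSummary:
    """Observed metric vs. its permutation null, per cell."""

    table: pd.DataFrame  # cell_id, observed, null_mean, null_sd, ses, p, degenerate
    metric: str
    null: str
    n_reps: int

    def __getitem__(self, col):
        return self.table[col]


def null_distribution(
    metric: str,
    tree: Phylogeny,
    occ: OccurrenceMatrix,
    null: str = "tip_shuffle",
    n_reps: int = 999,
    seed=None,
    return_replicates: bool = False,
):
    """Observed PD/PE per cell with null mean, sd, SES and rank p-value.

    p(cell) = (#{null < obs} + 0.5 * #{null == obs} + 1) / (n_reps + 1):
    a half-tie rule, so a cell whose null distribution is degenerate at
    the observed value (e.g. a cell holding every species under tip
    shuffle) lands at ~0.5.  Cells with null sd 0 get SES 0 and a
    ``degenerate`` flag instead of NaN so the null mean stays usable as a
    regression covariate downstream.
    """
    if metric not in {"PD", "PE"}:
        raise ValueError("metric must be 'PD' or 'PE'")
    if null not in {"tip_shuffle", "independent_swap"}:
        raise ValueError("null must be 'tip_shuffle' or 'independent_swap'")
    rng = np.random.default_rng(seed)
    perm0 = _occ_perm(tree, occ)
    inc = tree.incidence().astype(np.float64)
    observed = _metric_all_cells(metric, tree, occ, perm0, inc)

    reps = np.empty((n_reps, occ.grid.n_cells))
    if null == "tip_shuffle":
        # permuting tip labels == composing a uniform permutation of tip
        # positions with the species -> tip map
        for r in range(n_reps):
            sigma = rng.permutation(tree.n_tips)
            reps[r] = _metric_all_cells(metric, tree, occ, sigma[perm0], inc)
    else:
        for r in range(n_reps):
            occ_r = independent_swap(occ, seed=rng)
            pres = inc[:, perm0] @ occ_r.matrix.T.astype(np.float64) > 0
            if metric == "PD":
                reps[r] = pres.T @ tree.length
            else:
                rs = pres.sum(axis=1)
                w = np.divide(tree.length, rs, out=np.zeros_like(tree.length),
                              where=rs > 0)
                reps[r] = pres.T @ w

    mean = reps.mean(axis=0)
    sd = reps.std(axis=0, ddof=0)
    degenerate = sd == 0
    ses = np.zeros_like(mean)
    np.divide(observed - mean, sd, out=ses, where=~degenerate)
    less = (reps < observed[None, :] - 1e-12).sum(axis=0)
    ties = (np.abs(reps - observed[None, :]) <= 1e-12).sum(axis=0)
    p = (less + 0.5 * ties + 1) / (n_reps + 1)

    table = pd.DataFrame(
        {
            "observed": observed,
            "null_mean": mean,
            "null_sd": sd,
            "ses": ses,
            "p": p,
            "degenerate": degenerate,
        },
        index=pd.Index(list(occ.grid.cell_ids), name="cell_id"),
    )
    summary = NullSummary(table, metric, null, n_reps)
    if return_replicates:
        return summary, reps
    return summary


def _occ_perm(tree: Phylogeny, occ: OccurrenceMatrix) -> np.ndarray:
    tip_pos = {lab: k for k, lab in enumerate(tree.tip_labels)}
    missing = [s for s in occ.species if s not in tip_pos]
    if missing:
        raise KeyError(f"species not in tree: {missing}")
    return np.array([tip_pos[s] for s in occ.species], dtype=np.intp)


def classify_significant(summary: NullSummary, threshold: float = 0.95) -> pd.Series:
    """One-sided high-tail flag: True where p is STRICTLY above the
    threshold (observed diversity higher than the null expectation)."""
    return (summary.table["p"] > threshold).rename("significant")
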