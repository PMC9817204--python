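"""Per-cell phylogenetic diversity (PD), phylogenetic endemism (PE),
weighted endemism (WE) and richness on a gridded community.

PD of a cell is the total branch length of the union of root-to-tip paths
of the species present (rooted Faith PD: a single-species cell has the
length of its path to the root).  PE divides each branch length by the
branch's geographic range — the number of cells holding at least one
descendant tip — before summing, so every branch's length is apportioned
exactly once across the map and the per-cell values sum to the length of
the tree pruned to occurring species.  WE is the taxon-level analogue:
the sum of inverse species range sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import OccurrenceMatrix
from .tree import Phylogeny

__all__ = [
    "BranchRangeTable",
    "branch_ranges",
    "compute_pd",
    "compute_pd_cells",
    "compute_pe",
    "compute_we",
    "diversity_table",
    "filter_restricted_species",
]


@dataclass
class BranchRangeTable:
    """Per-branch geographic ranges for one (tree, occurrence) pairing.

    ``presence[b, c]`` — branch b has >= 1 descendant tip in cell c;
    ``range_size[b]`` — number of such cells;  ``length[b]`` — branch
    length.  Branches with empty range (no descendant occurs anywhere)
    keep range 0 and are skipped by PE.  Computed once and reused by the
    diversity and null-model stages."""

    length: np.ndarray
    presence: np.ndarray  # (n_branches, n_cells) bool
    range_size: np.ndarray
    species_cols: np.ndarray  # (n_branches, n_species) incidence in occ order


def _occ_tip_permutation(tree: Phylogeny, occ: OccurrenceMatrix) -> np.ndarray:
    """Column j of the occurrence matrix corresponds to tip perm[j]."""
    tip_pos = {lab: k for k, lab in enumerate(tree.tip_labels)}
    missing = [s for s in occ.species if s not in tip_pos]
    if missing:
        raise KeyError(f"species not in tree: {missing}")
    return np.array([tip_pos[s] for s in occ.species], dtype=np.intp)


def branch_ranges(tree: Phylogeny, occ: OccurrenceMatrix) -> BranchRangeTable:
    perm = _occ_tip_permutation(tree, occ)
    inc = tree.incidence()[:, perm]  # (branches, occ species)
    presence = (
        inc.astype(np.float64) @ occ.matrix.T.astype(np.float64) > 0
    )  # branch has a descendant tip in cell?
    return BranchRangeTable(
        length=tree.length.copy(),
        presence=presence,
        range_size=presence.sum(axis=1).astype(int),
        species_cols=inc,
    )


def compute_pd(tree: Phylogeny, present) -> float:
    """Rooted PD of one species set (empty set -> 0)."""
    present = set(present)
    if not present:
        return 0.0
    tip_pos = {lab: k for k, lab in enumerate(tree.tip_labels)}
    unknown = present - set(tip_pos)
    if unknown:
        raise KeyError(f"species not in tree: {sorted(unknown)}")
    mask = np.zeros(tree.n_tips, dtype=bool)
    for s in present:
        mask[tip_pos[s]] = True
    on_path = tree.incidence()[:, mask].any(axis=1)
    return float(tree.length[on_path].sum())


def compute_pd_cells(tree: Phylogeny, occ: OccurrenceMatrix,
                     brt: BranchRangeTable | None = None) -> np.ndarray:
    """PD of every cell at once (vectorized over the branch x cell table)."""
    brt = brt if brt is not None else branch_ranges(tree, occ)
    return brt.presence.T @ brt.length


def compute_pe(tree: Phylogeny, occ: OccurrenceMatrix,
               brt: BranchRangeTable | None = None) -> np.ndarray:
    """Range-weighted PD per cell (Rosauer phylogenetic endemism)."""
    brt = brt if brt is not None else branch_ranges(tree, occ)
    w = np.zeros_like(brt.length)
    occupied = brt.range_size > 0
    w[occupied] = brt.length[occupied] / brt.range_size[occupied]
    return brt.presence.T @ w


def compute_we(occ: OccurrenceMatrix) -> np.ndarray:
    """Weighted endemism: per-cell sum of inverse species range sizes."""
    ranges = occ.matrix.sum(axis=0).astype(float)
    inv = np.divide(1.0, ranges, out=np.zeros_like(ranges), where=ranges > 0)
    return occ.matrix @ inv


def diversity_table(tree: Phylogeny, occ: OccurrenceMatrix) -> pd.DataFrame:
    """Per-cell ``richness, PD, PE, WE`` DataFrame indexed by cell id."""
    brt = branch_ranges(tree, occ)
    return pd.DataFrame(
        {
            "richness": occ.richness,
            "PD": compute_pd_cells(tree, occ, brt),
            "PE": compute_pe(tree, occ, brt),
            "WE": compute_we(occ),
        },
        index=pd.Index(list(occ.grid.cell_ids), name="cell_id"),
    )


def filter_restricted_species(
    occ: OccurrenceMatrix, min_range_cells: int = 3
) -> tuple[OccurrenceMatrix, pd.DataFrame]:
    """Drop species occupying fewer than ``min_range_cells`` cells.

    Extreme micro-endemics inflate PE in the handful of cells they occupy
    and destabilise downstream regression; the default threshold of 3
    removes species confined to <= 2 cells.  Returns the filtered matrix
    and a report of removals."""
    ranges = occ.range_sizes
    removed = ranges[ranges < min_range_cells]
    report = pd.DataFrame(
        {"species": removed.index, "range_cells": removed.to_numpy()}
    )
    if len(removed):
        warnings.warn(
            f"removed {len(removed)} range-restricted species "
            f"(< {min_range_cells} cells): {list(removed.index)}",
            stacklevel=2,
        )
    return occ.drop_species(set(removed.index)), report
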