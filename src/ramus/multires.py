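"""Random nested multiresolution decompositions of the source space.

A decomposition is an ordered set of resolution levels.  Level ``l``
(1 = coarsest) keeps ``K_l = round(K * s**(l - L))`` center positions; the
remaining positions are attached to their nearest center, partitioning the
source space into subsets on which the unknown is assumed constant.  The
actual source count is assumed unchanged regardless of the resolution, so
a coarse lead-field column is the SUM of its member fine columns, while a
fine estimate is carried down to a coarse level by the subset MEAN (the
adjoint-consistent restriction that preserves constant fields).

Levels are nested top-down: the finest level is the full space and each
coarser center set is drawn uniformly without replacement from the next
finer one; a flag disables nesting for sensitivity checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .errors import DimensionError, ParameterError
from .forward_spherical import SourceSpace

__all__ = [
    "ResolutionLevel",
    "MultiresolutionDecomposition",
    "partition_nearest",
    "build_decomposition",
    "restrict_leadfield",
    "prolongate",
    "restrict_estimate",
]


@dataclass
class ResolutionLevel:
    """One resolution level: chosen centers and the induced partition."""

    level_index: int  # 1 = coarsest
    center_indices: np.ndarray  # (K_l,) indices into the source positions
    assignment: np.ndarray  # (K,) subset label of every fine position
    _P: sparse.csr_matrix | None = field(default=None, repr=False, compare=False)

    @property
    def n_centers(self) -> int:
        return self.center_indices.size

    @property
    def n_fine(self) -> int:
        return self.assignment.size

    @property
    def is_identity(self) -> bool:
        return self.n_centers == self.n_fine and np.array_equal(
            self.assignment, np.arange(self.n_fine)
        )

    def subset_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.n_centers)

    def prolongation(self) -> sparse.csr_matrix:
        """Sparse (3K, 3K_l) map copying each subset value to its members."""
        if self._P is None:
            K, Kl = self.n_fine, self.n_centers
            rows = np.repeat(3 * np.arange(K), 3) + np.tile([0, 1, 2], K)
            cols = np.repeat(3 * self.assignment, 3) + np.tile([0, 1, 2], K)
            self._P = sparse.csr_matrix(
                (np.ones(3 * K), (rows, cols)), shape=(3 * K, 3 * Kl)
            )
        return self._P


@dataclass
class MultiresolutionDecomposition:
    levels: list[ResolutionLevel]  # coarsest first
    sparsity: float
    seed: object = None

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def to_json(self, path=None):
        data = {
            "sparsity": self.sparsity,
            "n_levels": self.n_levels,
            "seed": repr(self.seed),
            "center_indices": [lvl.center_indices.tolist() for lvl in self.levels],
        }
        if path is None:
            return json.dumps(data)
        with open(path, "w") as fh:
            json.dump(data, fh)

    @classmethod
    def from_json(cls, src, space: SourceSpace) -> "MultiresolutionDecomposition":
        data = json.loads(src) if isinstance(src, str) else json.load(src)
        levels = []
        for li, centers in enumerate(data["center_indices"]):
            centers = np.asarray(centers, dtype=np.intp)
            assignment = partition_nearest(space.positions, space.positions[centers])
            levels.append(
                ResolutionLevel(
                    level_index=li + 1, center_indices=centers, assignment=assignment
                )
            )
        return cls(levels=levels, sparsity=data["sparsity"], seed=data.get("seed"))


def partition_nearest(positions: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Label each position with the index of its nearest center.

    Euclidean distance, ties broken deterministically by the lowest center
    index (argmin keeps the first minimizer).  Distances are compared via
    ``|c|^2 - 2 p.c``, dropping the per-position constant.
    """
    positions = np.atleast_2d(np.asarray(positions, float))
    centers = np.atleast_2d(np.asarray(centers, float))
    if centers.shape[0] == 0:
        raise ParameterError("centers must be non-empty")
    if positions.shape[0] * centers.shape[0] > 200_000:
        # large products go through a KD-tree; exact ties between distinct
        # centers have probability zero for continuous positions
        from scipy.spatial import cKDTree

        return cKDTree(centers).query(positions, k=1)[1].astype(np.intp)
    c2 = np.einsum("ij,ij->i", centers, centers)
    labels = np.empty(positions.shape[0], dtype=np.intp)
    chunk = max(1, int(4e6 // max(centers.shape[0], 1)))
    for a in range(0, positions.shape[0], chunk):
        block = positions[a : a + chunk]
        d = c2[None, :] - 2.0 * (block @ centers.T)
        labels[a : a + block.shape[0]] = np.argmin(d, axis=1)
    return labels


def build_decomposition(
    space: SourceSpace,
    n_levels: int,
    sparsity: float,
    seed=None,
    nested: bool = True,
) -> MultiresolutionDecomposition:
    """Draw one random multiresolution decomposition.

    ``K_l = round(K * sparsity**(l - n_levels))`` (round-half-to-even, at
    least 3 centers) and the finest level is the full space with singleton
    subsets.  ``sparsity = 1`` degenerates to identical full-space levels.
    """
    if n_levels < 1:
        raise ParameterError("n_levels must be >= 1")
    if sparsity < 1:
        raise ParameterError("sparsity must be >= 1")
    K = space.n_positions
    rng = np.random.default_rng(seed)
    counts = []
    for l in range(1, n_levels + 1):
        k = int(round(K * sparsity ** (l - n_levels)))
        if k < 1:
            raise ParameterError(
                f"level {l} rounds to {k} centers; decrease sparsity or levels"
            )
        counts.append(min(max(k, 3), K))
    levels: list[ResolutionLevel] = [None] * n_levels  # type: ignore[list-item]
    finer = np.arange(K)
    for l in range(n_levels, 0, -1):
        k = counts[l - 1]
        if k >= finer.size:
            centers = finer
        elif nested:
            centers = np.sort(rng.choice(finer, size=k, replace=False))
        else:
            centers = np.sort(rng.choice(K, size=k, replace=False))
        if centers.size == K:
            assignment = np.arange(K)
        else:
            assignment = partition_nearest(space.positions, space.positions[centers])
        levels[l - 1] = ResolutionLevel(
            level_index=l, center_indices=centers, assignment=assignment
        )
        if nested:
            finer = centers
    return MultiresolutionDecomposition(levels=levels, sparsity=sparsity, seed=seed)


def restrict_leadfield(
    L_fine: np.ndarray, level: ResolutionLevel, mode: str = "mean"
) -> np.ndarray:
    """Coarse lead field: per subset and component, combine the member columns.

    With ``mode="mean"`` (default) a coarse column is the average of its
    member columns, so a coarse coefficient carries the amplitude of the
    underlying local current density: estimates keep the same scale on
    every resolution level, which is what lets one hyperprior scale serve
    all levels and what the normalized level mean assumes when it divides
    the summed prolongations by the multiplied source count.
    ``mode="sum"`` (coefficient = per-member value of a subset whose total
    forward contribution is the summed columns) is kept for diagnostics.
    """
    L_fine = np.asarray(L_fine, dtype=float)
    if L_fine.shape[1] != 3 * level.n_fine:
        raise DimensionError("lead-field columns do not match the level layout")
    if level.is_identity:
        return L_fine
    out = L_fine @ level.prolongation()
    if mode == "mean":
        out /= np.repeat(level.subset_sizes(), 3)[None, :]
    elif mode != "sum":
        raise ParameterError(f"unknown restriction mode {mode!r}")
    return out


def prolongate(x_coarse: np.ndarray, level: ResolutionLevel) -> np.ndarray:
    """Copy each subset value to all members (per Cartesian component)."""
    x_coarse = np.asarray(x_coarse, dtype=float)
    if x_coarse.size != 3 * level.n_centers:
        raise DimensionError("coarse vector does not match the level layout")
    if level.is_identity:
        return x_coarse.copy()
    return x_coarse.reshape(level.n_centers, 3)[level.assignment].ravel()


def restrict_estimate(x_fine: np.ndarray, level: ResolutionLevel) -> np.ndarray:
    """Subset mean per component: the left inverse of ``prolongate``."""
    x_fine = np.asarray(x_fine, dtype=float)
    if x_fine.size != 3 * level.n_fine:
        raise DimensionError("fine vector does not match the level layout")
    if level.is_identity:
        return x_fine.copy()
    sums = np.zeros((level.n_centers, 3))
    np.add.at(sums, level.assignment, x_fine.reshape(level.n_fine, 3))
    return (sums / level.subset_sizes()[:, None]).ravel()
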