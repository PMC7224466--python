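"""GGE biplot analytics: environment-centered SVD, which-won-where sectors,
and average-environment-coordination (AEC) mean/stability statistics.

A GGE analysis starts from a complete genotype x condition table of
adjusted means or BLUPs (conditions are environments, traits, or
trait-by-environment composites).  Column centering removes the condition
main effect, keeping genotype main effect plus genotype-by-condition
interaction; the SVD of the centered table yields genotype scores
``u_i d_i^f`` and condition scores ``v_i d_i^(1-f)`` for a singular-value
partitioning exponent ``f`` (0.5 symmetric by default, 1 genotype-focused,
0 condition-focused).

The which-won-where view takes the convex hull of the genotype (PC1, PC2)
scores; rays from the origin perpendicular to the hull edges cut the plane
into sectors and each condition's winner is the vertex genotype of the
sector containing its score vector -- equivalently, the genotype maximising
the inner product with the condition score, which on a rank-2 table is the
per-condition argmax of the centered data itself.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .errors import CompletenessError, DegenerateError, GeometryError

__all__ = [
    "center_table",
    "decompose",
    "fit_gge",
    "BiplotModel",
    "WhichWonWhere",
    "which_won_where",
    "aec_analysis",
    "stability_ranking",
]


def center_table(t: pd.DataFrame) -> pd.DataFrame:
    """Column-center a complete two-way table (condition means removed)."""
    if t.isna().to_numpy().any():
        raise CompletenessError("two-way table has missing cells; impute or "
                                "complete it before the biplot")
    return t - t.mean(axis=0)


@dataclass
class BiplotModel:
    """SVD of a centered two-way table with scores under partitioning f."""

    centered: pd.DataFrame
    svals: np.ndarray
    row_scores: pd.DataFrame      # genotypes x PCs
    col_scores: pd.DataFrame      # conditions x PCs
    var_fraction: pd.Series       # percent per PC, sums to 100
    f: float

    @property
    def genotypes(self) -> list:
        return list(self.row_scores.index)

    @property
    def conditions(self) -> list:
        return list(self.col_scores.index)

    def reconstruct(self, rank: int = 2) -> pd.DataFrame:
        """Rank-k reconstruction from the score matrices (exact at full rank
        since the partitioning exponents sum to one)."""
        g = self.row_scores.to_numpy()[:, :rank]
        c = self.col_scores.to_numpy()[:, :rank]
        return pd.DataFrame(g @ c.T, index=self.centered.index,
                            columns=self.centered.columns)


def decompose(centered: pd.DataFrame, f: float = 0.5) -> BiplotModel:
    """Singular value decomposition of a centered table into biplot scores."""
    M = centered.to_numpy(dtype=float)
    if not np.any(M):
        raise DegenerateError("centered table is identically zero")
    U, dvals, Vt = np.linalg.svd(M, full_matrices=False)
    dvals = np.where(dvals < 1e-12 * dvals[0], 0.0, dvals)  # exact low rank
    total = float((dvals ** 2).sum())
    frac = 100.0 * dvals ** 2 / total
    pcs = [f"PC{i + 1}" for i in range(len(dvals))]
    row = U * dvals ** f
    col = Vt.T * dvals ** (1.0 - f)
    return BiplotModel(
        centered=centered,
        svals=dvals,
        row_scores=pd.DataFrame(row, index=centered.index, columns=pcs),
        col_scores=pd.DataFrame(col, index=centered.columns, columns=pcs),
        var_fraction=pd.Series(frac, index=pcs),
        f=f,
    )


def fit_gge(table: pd.DataFrame, f: float = 0.5, scale: bool = False
            ) -> BiplotModel:
    """Center (optionally per-column standardise) a two-way table and
    decompose it.  ``scale=True`` divides each centered column by its
    standard deviation -- useful for multi-trait tables on different units."""
    centered = center_table(table)
    if scale:
        sd = centered.std(axis=0, ddof=1).replace(0.0, np.nan)
        if sd.isna().any():
            raise DegenerateError("cannot standardise a constant column")
        centered = centered / sd
    return decompose(centered, f=f)


@dataclass
class WhichWonWhere:
    """Convex hull, sector boundaries and per-condition winners."""

    hull_vertices: list                 # genotype labels, counter-clockwise
    boundary_angles: list               # sector-boundary ray angles (radians)
    winners: dict                       # condition -> vertex genotype
    sector_of: dict = field(default_factory=dict)  # condition -> vertex index


def _scores2d(b: BiplotModel, what: str) -> np.ndarray:
    tab = b.row_scores if what == "row" else b.col_scores
    if tab.shape[1] < 2:
        raise GeometryError("need at least two principal components")
    return tab.to_numpy()[:, :2]


def which_won_where(b: BiplotModel) -> WhichWonWhere:
    """Polygon (convex hull) view of the biplot with condition winners.

    Raises :class:`GeometryError` when the genotype scores are collinear
    (no two-dimensional hull exists); with fewer than three distinct score
    points there is nothing to sectorise.
    """
    pts = _scores2d(b, "row")
    try:
        hull = ConvexHull(pts)
    except (QhullError, ValueError) as exc:
        raise GeometryError(
            "genotype scores are collinear or degenerate; a which-won-where "
            "polygon needs >= 3 genotypes spanning the PC1-PC2 plane"
        ) from exc
    verts = list(hull.vertices)  # counter-clockwise
    labels = [b.genotypes[i] for i in verts]
    V = pts[verts]

    # boundary between adjacent vertices u, w: ray where <u,d> = <w,d>,
    # i.e. perpendicular to the edge u - w
    nv = len(verts)
    angles = []
    for i in range(nv):
        u, w = V[i], V[(i + 1) % nv]
        edge = w - u
        d = np.array([-edge[1], edge[0]])  # perpendicular
        if np.dot(d, u) < 0:               # orient outward
            d = -d
        angles.append(float(np.arctan2(d[1], d[0])))

    winners = {}
    sector_of = {}
    cond = _scores2d(b, "col")
    for j, name in enumerate(b.conditions):
        proj = V @ cond[j]
        idx = int(np.argmax(proj))
        winners[name] = labels[idx]
        sector_of[name] = idx
    return WhichWonWhere(labels, angles, winners, sector_of)


def aec_analysis(b: BiplotModel) -> pd.DataFrame:
    """Average-environment-coordination statistics per genotype.

    The average-environment axis (abscissa) runs through the mean of the
    condition score vectors; a genotype's projection on it measures mean
    performance, the absolute perpendicular projection measures instability,
    and the distance to the ideal point (on the abscissa, at the maximal
    projection) ranks genotypes for overall merit.
    """
    cond = _scores2d(b, "col")
    if cond.shape[0] < 2:
        raise DegenerateError("AEC needs at least two conditions")
    avg = cond.mean(axis=0)
    norm = float(np.linalg.norm(avg))
    if norm < 1e-12:
        raise DegenerateError("average-environment vector has zero length")
    a = avg / norm
    aperp = np.array([-a[1], a[0]])
    pts = _scores2d(b, "row")
    mean_perf = pts @ a
    stability = np.abs(pts @ aperp)
    ideal = a * mean_perf.max()
    dist = np.linalg.norm(pts - ideal, axis=1)
    out = pd.DataFrame(
        {"mean_performance": mean_perf, "stability": stability,
         "ideal_distance": dist},
        index=pd.Index(b.genotypes, name="genotype"),
    )
    out["ideal_rank"] = out["ideal_distance"].rank(method="first").astype(int)
    return out


def stability_ranking(b: BiplotModel) -> pd.DataFrame:
    """AEC table sorted by mean performance (ties broken by genotype label)."""
    aec = aec_analysis(b)
    aec = aec.sort_values(["mean_performance"], ascending=False,
                          kind="mergesort")
    # deterministic tie-break on the label
    aec = aec.loc[
        sorted(aec.index, key=lambda g: (-aec.loc[g, "mean_performance"], str(g)))
    ]
    aec.insert(0, "rank", np.arange(1, len(aec) + 1))
    return aec
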