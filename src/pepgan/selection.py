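"""Representative-peptide selection pipeline.

Generated and training peptides are placed on a UPGMA tree of raw
Hamming differences, the tree is cut at a branch-length threshold into
clades, and each clade is tested for *physiochemical* overlap between
the two sources: classical MDS embeds the clade members' scaled
descriptors in 2-D and 95% confidence ellipses are fitted per source.
From each overlapping clade, the generated peptide closest to the
clade's PAM medoid enters the representative library.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import chi2

from .descriptors import descriptor_frame, robust_scale
from .io import PeptideDataset
from .phylo import PhyloTree, cut_tree, hamming_matrix, upgma

__all__ = [
    "clade_similarity",
    "mds_embed",
    "Ellipse",
    "confidence_ellipse",
    "ellipses_overlap",
    "pam_medoid",
    "MedoidSet",
    "select_library",
]

CHI2_95_DF2 = float(chi2.ppf(0.95, df=2))  # 5.991...


def clade_similarity(
    clades: Sequence[Sequence[str]], dist: np.ndarray, ids: Sequence[str]
) -> pd.DataFrame:
    """Average pairwise distance within each clade versus across clades.

    ``within`` is the mean over unordered member pairs (NaN for
    singleton clades); ``across`` is the mean over pairs with exactly
    one member inside the clade.
    """
    if len(clades) < 2:
        raise ValueError("need at least 2 clades")
    index = {pid: i for i, pid in enumerate(ids)}
    rows = []
    all_idx = np.arange(len(ids))
    for c, members in enumerate(clades):
        inside = np.array([index[m] for m in members])
        outside = np.setdiff1d(all_idx, inside)
        if len(inside) > 1:
            sub = dist[np.ix_(inside, inside)]
            within = float(sub[np.triu_indices_from(sub, k=1)].mean())
        else:
            within = float("nan")
        across = float(dist[np.ix_(inside, outside)].mean()) if len(outside) else float("nan")
        rows.append({"clade": c, "size": len(inside), "within": within, "across": across})
    return pd.DataFrame(rows)


def mds_embed(x: np.ndarray, dims: int = 2, is_distance: bool | None = None) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling.

    Accepts either a square distance matrix or a feature matrix (in
    which case Euclidean distances are used).  Double-centers the
    squared distances and embeds on the top eigenvectors; the sign of
    each axis is fixed so its first nonzero loading is positive.
    """
    x = np.asarray(x, dtype=float)
    if is_distance is None:
        is_distance = x.shape[0] == x.shape[1] and np.allclose(x, x.T) and np.allclose(
            np.diag(x), 0.0
        )
    d = x if is_distance else cdist(x, x)
    n = d.shape[0]
    if dims >= n:
        raise ValueError(f"dims={dims} must be smaller than n={n}")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    lam, vec = np.linalg.eigh(b)
    order = np.argsort(lam)[::-1][:dims]
    lam_top = np.clip(lam[order], 0.0, None)
    coords = vec[:, order] * np.sqrt(lam_top)
    for k in range(dims):
        col = coords[:, k]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if len(nz) and col[nz[0]] < 0:
            coords[:, k] = -col
    return coords


@dataclasses.dataclass(frozen=True)
class Ellipse:
    """95% confidence ellipse: {x : (x-mean)' cov^-1 (x-mean) <= chi2_2(0.95)}."""

    mean: np.ndarray
    cov: np.ndarray
    scale: float = CHI2_95_DF2

    def mahalanobis_sq(self, points: np.ndarray) -> np.ndarray:
        diff = np.atleast_2d(points) - self.mean
        return np.einsum("ij,jk,ik->i", diff, np.linalg.inv(self.cov), diff)

    def contains(self, points: np.ndarray, rtol: float = 1e-9) -> np.ndarray:
        return self.mahalanobis_sq(points) <= self.scale * (1.0 + rtol)

    def boundary(self, n: int = 720) -> np.ndarray:
        theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        circle = np.column_stack([np.cos(theta), np.sin(theta)])
        chol = np.linalg.cholesky(self.cov)
        return self.mean + np.sqrt(self.scale) * circle @ chol.T


def confidence_ellipse(points: np.ndarray, level: float = 0.95) -> Ellipse:
    """Fit the 95% (by default) confidence ellipse of 2-D points.

    The orientation comes from the sample covariance; the radius from
    the chi-square quantile with 2 degrees of freedom.  Raises on fewer
    than 3 points or a singular (collinear) covariance.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an (n, 2) array")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points to fit an ellipse")
    cov = np.cov(pts, rowvar=False)
    if np.linalg.det(cov) <= 1e-300:
        raise ValueError("singular covariance (collinear points)")
    return Ellipse(mean=pts.mean(axis=0), cov=cov, scale=float(chi2.ppf(level, df=2)))


def ellipses_overlap(a: Ellipse, b: Ellipse, n_boundary: int = 2048, rtol: float = 1e-6) -> bool:
    """True iff the ellipse boundaries intersect or one contains the other.

    Tested by dense boundary sampling plus mutual center containment.
    """
    if a.contains(b.mean[None, :], rtol=rtol)[0] or b.contains(a.mean[None, :], rtol=rtol)[0]:
        return True
    if a.contains(b.boundary(n_boundary), rtol=rtol).any():
        return True
    return bool(b.contains(a.boundary(n_boundary), rtol=rtol).any())


def pam_medoid(dist: np.ndarray, members: Sequence[str], ids: Sequence[str]) -> str:
    """Partition-around-medoids representative of a member set.

    Returns the member minimizing the total distance to the other
    members; ties break on id order.
    """
    if len(members) == 0:
        raise ValueError("empty member set")
    index = {pid: i for i, pid in enumerate(ids)}
    midx = [index[m] for m in members]
    sub = dist[np.ix_(midx, midx)]
    costs = sub.sum(axis=1)
    best = min(range(len(members)), key=lambda i: (costs[i], members[i]))
    return members[best]


@dataclasses.dataclass
class MedoidSet:
    """Per-clade representatives with provenance."""

    table: pd.DataFrame  # clade, size, n_real, n_generated, overlap, representative, sequence
    clades: list[list[str]]
    tree: PhyloTree
    cut_height: float

    @property
    def representatives(self) -> list[str]:
        sel = self.table[self.table["representative"].notna()]
        return sel["representative"].tolist()

    @property
    def sequences(self) -> list[str]:
        sel = self.table[self.table["sequence"].notna()]
        return sel["sequence"].tolist()


def select_library(
    real: PeptideDataset,
    generated: PeptideDataset,
    cut_height: float = 4.10,
    min_group: int = 3,
) -> MedoidSet:
    """End-to-end representative selection.

    Pipeline: Hamming distances over the pooled peptides -> UPGMA tree
    -> clades below ``cut_height`` -> per-clade MDS of robust-scaled
    physiochemical descriptors with 95% ellipses per source -> for each
    clade where the real and generated ellipses overlap, the generated
    member closest to the clade's PAM medoid.  Clades lacking
    ``min_group`` members of either source cannot support an ellipse and
    are reported as non-overlapping.
    """
    if len(real) == 0 or len(generated) == 0:
        raise ValueError("both datasets must be non-empty")
    ids = real.ids + generated.ids
    if len(set(ids)) != len(ids):
        raise ValueError("real and generated ids overlap; use distinct id prefixes")
    seqs = real.sequences + generated.sequences
    source = np.array(["real"] * len(real) + ["generated"] * len(generated))
    id_to_pos = {pid: i for i, pid in enumerate(ids)}

    dist = hamming_matrix(seqs)
    tree = upgma(dist, ids)
    clades = cut_tree(tree, height=cut_height)

    scaled = robust_scale(descriptor_frame(seqs, ids=ids)).array

    rows = []
    for c, members in enumerate(clades):
        pos = np.array([id_to_pos[m] for m in members])
        src = source[pos]
        n_real = int((src == "real").sum())
        n_gen = int((src == "generated").sum())
        overlap = False
        rep = seq = None
        if n_real >= min_group and n_gen >= min_group:
            coords = mds_embed(scaled[pos], dims=2)
            try:
                e_real = confidence_ellipse(coords[src == "real"])
                e_gen = confidence_ellipse(coords[src == "generated"])
                overlap = ellipses_overlap(e_real, e_gen)
            except ValueError:
                overlap = False  # degenerate clade geometry
        if overlap:
            medoid = pam_medoid(dist, members, ids)
            gen_members = [m for m in members if source[id_to_pos[m]] == "generated"]
            mpos = id_to_pos[medoid]
            rep = min(gen_members, key=lambda m: (dist[mpos, id_to_pos[m]], m))
            seq = seqs[id_to_pos[rep]]
        rows.append(
            {
                "clade": c,
                "size": len(members),
                "n_real": n_real,
                "n_generated": n_gen,
                "overlap": overlap,
                "representative": rep,
                "sequence": seq,
            }
        )
    return MedoidSet(table=pd.DataFrame(rows), clades=clades, tree=tree, cut_height=cut_height)
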