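"""Alpha diversity, between-sample distances, principal-coordinate
embedding, PERMANOVA, and the dispersion-homogeneity (betadisper-style) test.

Beta diversity is tree-free: Bray-Curtis (default) or the square-root
Jensen-Shannon divergence, which is a metric on the simplex.  Output headers
state the metric used.  Permutation p-values use the ``(1 + hits) /
(1 + n_perm)`` convention so p is never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .tables import CountTable, RelAbundanceTable

METRICS = ("bray_curtis", "jsd")
DEFAULT_PSEUDOCOUNT = 1e-6


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative matrix with zero diagonal over samples."""

    sample_ids: list
    values: np.ndarray
    metric: str = "unknown"

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.abs(np.diag(v)).max() > 1e-12:
            raise ValueError("distance matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)
        df.rename_axis(f"sample_id(metric={self.metric})").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        metric = "unknown"
        name = str(df.index.name or "")
        if "metric=" in name:
            metric = name.split("metric=")[1].rstrip(")")
        return cls(list(df.columns), df.to_numpy(), metric)

    def to_skbio(self):
        import skbio

        return skbio.DistanceMatrix(self.values, ids=[str(s) for s in self.sample_ids])


def alpha(table: CountTable) -> pd.DataFrame:
    """Observed richness and Shannon index (nats) per sample.

    Expects rarefied (equal-depth) counts; unequal depths trigger a warning
    but are tolerated since callers may intend them.
    """
    sums = table.sample_sums()
    if sums.nunique() > 1:
        warnings.warn(
            "alpha diversity on unequal sequencing depths "
            f"(min {int(sums.min())}, max {int(sums.max())})",
            stacklevel=2,
        )
    counts = table.counts
    richness = (counts > 0).sum(axis=1)
    p = counts / np.where(sums.to_numpy() == 0, 1, sums.to_numpy())[:, None]
    logp = np.zeros_like(p, dtype=float)
    np.log(p, out=logp, where=p > 0)
    shannon = -(p * logp).sum(axis=1)
    return pd.DataFrame(
        {"richness": richness, "shannon": shannon}, index=table.data.index
    )


def distance(
    rel: RelAbundanceTable,
    metric: str = "bray_curtis",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> DistanceMatrix:
    """Pairwise distances between row-normalized samples.

    ``jsd`` is sqrt(Jensen-Shannon divergence) with natural logarithms; zero
    proportions are replaced by ``pseudocount`` and rows renormalized first.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    X = rel.data.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("negative entries in relative-abundance table")
    if metric == "jsd":
        if pseudocount > 0:
            X = np.where(X <= 0, pseudocount, X)
            X = X / X.sum(axis=1, keepdims=True)
        d = pdist(X, metric="jensenshannon")  # sqrt-JSD, natural log
    else:
        d = pdist(X, metric="braycurtis")
    return DistanceMatrix(list(rel.data.index), squareform(np.nan_to_num(d)), metric)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame     # samples x axes, ordered by eigenvalue
    eigenvalues: np.ndarray
    negative_axes: np.ndarray     # boolean flags per axis


def pcoa(dist: DistanceMatrix) -> PCoAResult:
    """Classical scaling of the double-centered squared-distance matrix."""
    D2 = dist.values**2
    n = dist.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    coords = eigvecs * np.sqrt(np.abs(eigvals))[None, :]
    cols = [f"PCo{i + 1}" for i in range(n)]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=dist.sample_ids, columns=cols),
        eigenvalues=eigvals,
        negative_axes=eigvals < 0,
    )


def _group_indices(labels: pd.Series | np.ndarray, sample_ids) -> list[np.ndarray]:
    lab = pd.Series(np.asarray(labels), index=sample_ids) if not isinstance(labels, pd.Series) else labels.reindex(sample_ids)
    if lab.isna().any():
        raise ValueError("labels missing for some samples")
    codes, _ = pd.factorize(lab.to_numpy())
    return [np.flatnonzero(codes == g) for g in range(codes.max() + 1)]


def _pseudo_f(D2: np.ndarray, groups: list[np.ndarray]) -> float:
    n = D2.shape[0]
    total = D2.sum() / (2 * n)
    within = sum(D2[np.ix_(g, g)].sum() / (2 * len(g)) for g in groups)
    k = len(groups)
    between = total - within
    if within <= 0:
        return np.inf
    return (between / (k - 1)) / (within / (n - k))


def permanova(
    dist: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int | None = None,
) -> dict:
    """One-way PERMANOVA on a distance matrix.

    Pseudo-F from the distance-based sums-of-squares decomposition; p-value
    from seeded label permutations, ``p = (1 + #{F_perm >= F_obs}) /
    (1 + n_perm)``.
    """
    groups = _group_indices(labels, dist.sample_ids)
    if len(groups) < 2:
        raise ValueError("permanova requires at least two groups")
    if min(len(g) for g in groups) < 2:
        raise ValueError("each group needs at least two samples")
    D2 = dist.values**2
    f_obs = _pseudo_f(D2, groups)
    rng = np.random.default_rng(seed)
    sizes = [len(g) for g in groups]
    idx = np.arange(dist.n)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        start, pg = 0, []
        for s in sizes:
            pg.append(perm[start:start + s])
            start += s
        if _pseudo_f(D2, pg) >= f_obs - 1e-12 * (1 + abs(f_obs)):
            hits += 1
    return {"F": f_obs, "p": (1 + hits) / (1 + n_perm), "n_perm": n_perm}


def dispersion_test(
    dist: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int | None = None,
) -> dict:
    """Homogeneity of group dispersions (betadisper-style).

    Samples are embedded by PCoA restricted to non-negative-eigenvalue axes;
    each sample's Euclidean distance to its own group centroid is the
    dispersion score; F is the one-way ANOVA F on these scores and p comes
    from permuting group labels of the fixed scores.
    """
    groups = _group_indices(labels, dist.sample_ids)
    if len(groups) < 2:
        raise ValueError("dispersion test requires at least two groups")
    res = pcoa(dist)
    keep = ~res.negative_axes & (res.eigenvalues > 1e-12)
    X = res.coordinates.to_numpy()[:, keep]
    scores = np.empty(dist.n)
    for g in groups:
        centroid = X[g].mean(axis=0)
        scores[g] = np.linalg.norm(X[g] - centroid, axis=1)

    def anova_f(groups_idx) -> float:
        grand = scores.mean()
        ssb = sum(len(g) * (scores[g].mean() - grand) ** 2 for g in groups_idx)
        ssw = sum(((scores[g] - scores[g].mean()) ** 2).sum() for g in groups_idx)
        k, n = len(groups_idx), len(scores)
        if ssw <= 0:
            return np.inf
        return (ssb / (k - 1)) / (ssw / (n - k))

    f_obs = anova_f(groups)
    rng = np.random.default_rng(seed)
    sizes = [len(g) for g in groups]
    idx = np.arange(dist.n)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        start, pg = 0, []
        for s in sizes:
            pg.append(perm[start:start + s])
            start += s
        if anova_f(pg) >= f_obs - 1e-12 * (1 + abs(f_obs)):
            hits += 1
    dist_to_centroid = pd.Series(scores, index=dist.sample_ids, name="dist_to_centroid")
    return {
        "F": f_obs,
        "p": (1 + hits) / (1 + n_perm),
        "dist_to_centroid": dist_to_centroid,
        "n_perm": n_perm,
    }
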