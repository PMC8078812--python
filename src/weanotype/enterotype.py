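"""Enterotype discovery on genus-level relative abundances.

The clustering substrate is the square-root Jensen-Shannon divergence;
clusters come from a deterministic Partitioning Around Medoids (BUILD +
steepest-descent SWAP, ties broken by lowest sample index), the cluster count
from the distance-based Calinski-Harabasz index over a K range, and the
solution is validated by comparing its mean silhouette against re-clustered
random subsets.  Longitudinal dynamics are summarized by the d26->d35
transition matrix over pigs with both samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_samples

from .diversity import DEFAULT_PSEUDOCOUNT, DistanceMatrix, distance
from .tables import RelAbundanceTable, SampleMetadata

#: genera whose combined mean orders clusters along the maturational gradient
MATURITY_GENERA = ("Prevotella", "Faecalibacterium")


def pam(dist: DistanceMatrix | np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic k-medoids (BUILD + SWAP) on a distance matrix.

    Returns ``(labels, medoids)`` with labels in 0..k-1 numbered by medoid
    order (medoids sorted by sample index).  The total cost (sum of distances
    to the assigned medoid) never increases across SWAP iterations.
    """
    D = dist.values if isinstance(dist, DistanceMatrix) else np.asarray(dist)
    n = D.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of samples {n}")

    # BUILD: start from the 1-medoid minimizer, then greedily add the point
    # giving the largest cost reduction (lowest index on ties).
    medoids = [int(np.argmin(D.sum(axis=0)))]
    d_near = D[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.minimum(D, d_near[None, :]).sum(axis=1)
        gains[medoids] = np.inf
        new = int(np.argmin(gains))
        medoids.append(new)
        d_near = np.minimum(d_near, D[new])

    medoids = sorted(medoids)
    cost = _assign(D, medoids)[1]
    while True:
        best = None  # (delta, m_pos, h)
        med_arr = np.array(medoids)
        labels, _, d_near, d_second = _assign_full(D, med_arr)
        is_med = np.zeros(n, bool)
        is_med[med_arr] = True
        for m_pos, m in enumerate(med_arr):
            owned = labels == m_pos
            # delta[h, i]: change in i's cost if m is replaced by candidate h
            alt = np.where(owned[None, :], np.minimum(D, d_second[None, :]),
                           np.minimum(D, d_near[None, :]))
            deltas = (alt - d_near[None, :]).sum(axis=1)
            deltas[is_med] = np.inf
            h = int(np.argmin(deltas))
            if best is None or deltas[h] < best[0] - 1e-12:
                best = (float(deltas[h]), m_pos, h)
        if best is None or best[0] >= -1e-10:
            break
        _, m_pos, h = best
        medoids[m_pos] = h
        medoids = sorted(medoids)
        new_cost = _assign(D, medoids)[1]
        if new_cost > cost + 1e-9:
            raise AssertionError("PAM swap increased total cost")
        cost = new_cost

    labels, _ = _assign(D, medoids)
    return labels, np.array(medoids)


def _assign(D: np.ndarray, medoids) -> tuple[np.ndarray, float]:
    sub = D[np.asarray(medoids)]
    labels = np.argmin(sub, axis=0)
    return labels, float(sub.min(axis=0).sum())


def _assign_full(D: np.ndarray, medoids: np.ndarray):
    sub = D[medoids]
    order = np.argsort(sub, axis=0)
    labels = order[0]
    d_near = sub[order[0], np.arange(D.shape[0])]
    d_second = sub[order[1], np.arange(D.shape[0])]
    return labels, None, d_near, d_second


def ch_index(dist: DistanceMatrix | np.ndarray, labels: np.ndarray) -> float:
    """Distance-based Calinski-Harabasz index.

    ``W = sum_k (1/n_k) sum_{i<j in k} d_ij^2``, ``B = T - W`` with
    ``T = (1/n) sum_{i<j} d_ij^2``; ``CH = (B/(K-1)) / (W/(n-K))``.
    Degenerate zero-within-dispersion clusterings return ``inf``.
    """
    D = dist.values if isinstance(dist, DistanceMatrix) else np.asarray(dist)
    labels = np.asarray(labels)
    n = D.shape[0]
    groups = np.unique(labels)
    k = len(groups)
    if k < 2:
        raise ValueError("CH index requires at least two clusters")
    D2 = D**2
    total = D2.sum() / (2 * n)
    within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        within += D2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    between = total - within
    if within <= 1e-15:
        return np.inf
    return (between / (k - 1)) / (within / (n - k))


@dataclass
class EnterotypeSolution:
    k: int
    labels: pd.Series                 # sample -> enterotype name ("E1"..)
    medoids: list                     # medoid sample ids
    ch_curve: pd.Series               # K -> CH value
    mean_silhouette: float
    profiles: pd.DataFrame            # enterotype x genus mean composition
    weak_structure: bool = False
    silhouette_null: np.ndarray | None = None
    silhouette_percentile: float | None = None


def _canonical_order(rel: pd.DataFrame, labels: np.ndarray) -> list[int]:
    """Order raw cluster ids by ascending maturity score (mean of the
    maturity genera when present, else by descending cluster size)."""
    present = [g for g in MATURITY_GENERA if g in rel.columns]
    ids = list(np.unique(labels))
    if present:
        score = {g: rel.loc[labels == g, present].to_numpy().sum(axis=1).mean() for g in ids}
        return sorted(ids, key=lambda g: score[g])
    size = {g: (labels == g).sum() for g in ids}
    return sorted(ids, key=lambda g: -size[g])


def choose_k(
    rel_genus: RelAbundanceTable,
    k_range: tuple[int, int] = (2, 8),
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    weak_ratio: float = 1.2,
) -> EnterotypeSolution:
    """Cluster genus profiles with JSD + PAM over a K range and select the K
    maximizing the distance-based CH index."""
    dist = distance(rel_genus, metric="jsd", pseudocount=pseudocount)
    n = dist.n
    k_lo, k_hi = k_range
    if k_hi >= n:
        warnings.warn(f"shrinking K range: only {n} samples", stacklevel=2)
        k_hi = n - 1
    ch = {}
    partitions = {}
    for k in range(k_lo, k_hi + 1):
        labels, medoids = pam(dist, k)
        ch[k] = ch_index(dist, labels)
        partitions[k] = (labels, medoids)
    ch_curve = pd.Series(ch).sort_index()
    best_k = int(ch_curve.idxmax())
    labels, medoids = partitions[best_k]
    return _finalize_solution(rel_genus, dist, labels, medoids, best_k, ch_curve, weak_ratio)


def cluster_at_k(
    rel_genus: RelAbundanceTable,
    k: int,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> EnterotypeSolution:
    """Cluster at a fixed K (canonically renamed), no K selection."""
    dist = distance(rel_genus, metric="jsd", pseudocount=pseudocount)
    labels, medoids = pam(dist, k)
    ch_curve = pd.Series({k: ch_index(dist, labels)})
    return _finalize_solution(rel_genus, dist, labels, medoids, k, ch_curve, weak_ratio=np.inf)


def _finalize_solution(rel_genus, dist, labels, medoids, k, ch_curve, weak_ratio):
    rel = rel_genus.data
    order = _canonical_order(rel, labels)
    rename = {old: f"E{i + 1}" for i, old in enumerate(order)}
    named = pd.Series([rename[l] for l in labels], index=rel.index, name="enterotype")
    sil = silhouette_samples(dist.values, labels, metric="precomputed")
    profiles = rel.groupby(named.to_numpy()).mean().sort_index()
    medoid_ids = [rel.index[m] for m in medoids]
    weak = bool(np.isfinite(ch_curve.max()) and len(ch_curve) > 1
                and ch_curve.max() < weak_ratio * ch_curve.median())
    return EnterotypeSolution(
        k=k,
        labels=named,
        medoids=medoid_ids,
        ch_curve=ch_curve,
        mean_silhouette=float(sil.mean()),
        profiles=profiles,
        weak_structure=weak,
    )


def silhouette_validation(
    rel_genus: RelAbundanceTable,
    solution: EnterotypeSolution,
    n_subsets: int = 100,
    subsample_frac: float = 0.8,
    seed: int | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> EnterotypeSolution:
    """Compare the solution's mean silhouette with re-clustered random
    subsets (without replacement) at the same K; records the null
    distribution and the observed value's percentile."""
    rng = np.random.default_rng(seed)
    n = len(rel_genus.data)
    k = solution.k
    null = []
    attempts = 0
    while len(null) < n_subsets and attempts < 10 * n_subsets:
        attempts += 1
        m = max(int(round(subsample_frac * n)), k + 1)
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sub = RelAbundanceTable(rel_genus.data.iloc[idx])
        dist = distance(sub, metric="jsd", pseudocount=pseudocount)
        labels, _ = pam(dist, k)
        if len(np.unique(labels)) < k:
            continue  # degenerate subset; resample
        null.append(float(silhouette_samples(dist.values, labels, metric="precomputed").mean()))
    null = np.array(null)
    solution.silhouette_null = null
    solution.silhouette_percentile = float(100.0 * (null <= solution.mean_silhouette).mean())
    return solution


@dataclass
class TransitionMatrix:
    counts: pd.DataFrame          # d26 state x d35 state
    probabilities: pd.DataFrame   # rows sum to 1
    shift_fraction: float
    n_pigs: int


def transitions(labels: pd.Series, metadata: SampleMetadata) -> TransitionMatrix:
    """d26->d35 enterotype transition counts over pigs with both samples."""
    meta = metadata.data
    df = pd.DataFrame({
        "enterotype": labels,
        "pig_id": meta.loc[labels.index, "pig_id"],
        "age_point": meta.loc[labels.index, "age_point"],
    })
    wide = df.pivot(index="pig_id", columns="age_point", values="enterotype")
    if "d26" not in wide.columns or "d35" not in wide.columns:
        raise ValueError("labels must cover both age points")
    wide = wide.dropna()
    if len(wide) == 0:
        raise ValueError("no pig has samples at both age points")
    states = sorted(set(labels))
    counts = pd.crosstab(wide["d26"], wide["d35"]).reindex(
        index=states, columns=states, fill_value=0
    )
    row_sums = counts.sum(axis=1).replace(0, 1)
    probs = counts.div(row_sums, axis=0)
    total = counts.to_numpy().sum()
    shift = 1.0 - np.trace(counts.to_numpy()) / total
    return TransitionMatrix(counts, probs, float(shift), int(total))
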