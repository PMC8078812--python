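"""Best-subset linear prediction of continuous rADG from microbiota
features, with leave-one-farm-out validation and a weight-only baseline.

Features are per-pig: family and genus relative abundances at each age, an
optional univariate preselection of OTUs, and optionally the weaning weight.
The subset search maximizes adjusted R^2 of the OLS fit — exhaustively when
feasible, by forward stepwise selection otherwise.  Validation refits the
coefficients of the fixed selected subset on all-but-one farm and scores the
held-out farm with an adjusted R_i^2; the headline number is the arithmetic
mean of the per-farm values (negative folds are kept, not floored).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables import CountTable, RelAbundanceTable, SampleMetadata

log = logging.getLogger(__name__)

EXHAUSTIVE_LIMIT = 20        # max candidate count for exhaustive search
EXHAUSTIVE_MODELS_CAP = 200_000  # max number of candidate subsets to enumerate


def build_feature_matrix(
    tables_by_age: dict[str, RelAbundanceTable | pd.DataFrame],
    metadata: SampleMetadata,
    extra: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per pig with both time points; columns ``<taxon>@<age>``.

    ``tables_by_age`` maps age point to a per-sample abundance table (any
    taxonomic level); pigs lacking either age are dropped and logged.
    ``extra`` (indexed by pig) appends covariates such as weight_d26.
    """
    meta = metadata.data
    blocks = []
    pig_sets = []
    for age, rel in tables_by_age.items():
        sub = (rel.data if isinstance(rel, RelAbundanceTable) else rel).copy()
        m = meta.loc[sub.index]
        sub = sub[m["age_point"] == age]
        sub.index = meta.loc[sub.index, "pig_id"]
        sub.columns = [f"{c}@{age}" for c in sub.columns]
        blocks.append(sub)
        pig_sets.append(set(sub.index))
    pigs = sorted(set.intersection(*pig_sets))
    dropped = sorted(set.union(*pig_sets) - set(pigs))
    if dropped:
        log.info("build_feature_matrix: dropped %d pigs lacking both ages", len(dropped))
    X = pd.concat([b.loc[pigs] for b in blocks], axis=1)
    if extra is not None:
        X = X.join(extra.loc[pigs])
    if X.isna().any().any():
        bad = X.columns[X.isna().any()][0]
        raise ValueError(f"missing entries in feature {bad!r}")
    return X.rename_axis("pig_id")


def preselect_otus(
    table: CountTable | RelAbundanceTable,
    metadata: SampleMetadata,
    growth_records: pd.DataFrame,
    m: int = 10,
) -> dict[str, list]:
    """Top-``m`` OTUs per age by |rank-sum z| between growth classes."""
    data = table.data
    meta = metadata.data.loc[data.index]
    cls = meta["pig_id"].map(growth_records["growth_class"])
    out = {}
    for age in ("d26", "d35"):
        mask = (meta["age_point"] == age) & cls.isin(["rADG+", "rADG-"])
        y = data[mask]
        is_pos = (cls[mask] == "rADG+").to_numpy()
        if m == 0 or not mask.any():
            out[age] = []
            continue
        scores = {}
        n1, n2 = int(is_pos.sum()), int((~is_pos).sum())
        mu = n1 * n2 / 2.0
        sigma = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        for otu in y.columns:
            u = stats.mannwhitneyu(
                y[otu].to_numpy()[is_pos], y[otu].to_numpy()[~is_pos],
                alternative="two-sided",
            ).statistic
            scores[otu] = abs((u - mu) / sigma) if sigma > 0 else 0.0
        ranked = sorted(scores, key=lambda o: (-scores[o], o))
        out[age] = ranked[:m]
    return out


def _adjusted_r2(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        return -np.inf
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


@dataclass
class SubsetModel:
    features: list
    coefficients: pd.Series          # includes "(intercept)"
    adjusted_r2: float
    n: int
    search: str                      # "exhaustive" | "forward"
    cv_r2_by_farm: pd.Series | None = None
    cv_r2_mean: float | None = None


def _fit_subset(G: np.ndarray, gy: np.ndarray, yty: float, idx: tuple) -> float | None:
    """R^2 of OLS on the (centered) subset via the Gram matrix; None if the
    design is rank-deficient."""
    sel = np.array(idx)
    Gs = G[np.ix_(sel, sel)]
    if np.linalg.cond(Gs) > 1e12:
        return None
    beta = np.linalg.solve(Gs, gy[sel])
    if not np.all(np.isfinite(beta)):
        return None
    rss = yty - gy[sel] @ beta
    if yty <= 0:
        return None
    return 1.0 - rss / yty


def best_subset(
    features: pd.DataFrame,
    radg: pd.Series,
    p_max: int = 10,
) -> SubsetModel:
    """Select the feature subset (size <= ``p_max``) maximizing adjusted R^2.

    Exhaustive over all subsets when the candidate count is at most
    ``EXHAUSTIVE_LIMIT`` (and the model count is tractable); otherwise
    forward stepwise.  Ties break lexicographically on feature names.
    """
    y = radg.reindex(features.index).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("rADG missing for some pigs in the feature matrix")
    n, p_all = features.shape
    if n <= p_max + 2:
        raise ValueError(f"need n > p_max + 2 (n={n}, p_max={p_max})")
    names = list(features.columns)
    Xc = features.to_numpy(dtype=float)
    Xc = Xc - Xc.mean(axis=0)
    yc = y - y.mean()
    G = Xc.T @ Xc
    gy = Xc.T @ yc
    yty = float(yc @ yc)

    best: tuple[float, tuple] | None = None

    def consider(idx: tuple) -> float | None:
        r2 = _fit_subset(G, gy, yty, idx)
        if r2 is None:
            return None
        return _adjusted_r2(r2, n, len(idx))

    from math import comb

    n_models = sum(comb(p_all, k) for k in range(1, min(p_max, p_all) + 1))
    def better(adj, idx):
        """Higher adjusted R^2 wins; ties go to fewer features, then to the
        lexicographically smallest name tuple."""
        if best is None:
            return True
        if adj > best[0] + 1e-12:
            return True
        if adj < best[0] - 1e-12:
            return False
        key_new = (len(idx), tuple(names[i] for i in idx))
        key_old = (len(best[1]), tuple(names[i] for i in best[1]))
        return key_new < key_old

    if p_all <= EXHAUSTIVE_LIMIT and n_models <= EXHAUSTIVE_MODELS_CAP:
        search = "exhaustive"
        for k in range(1, min(p_max, p_all) + 1):
            for idx in itertools.combinations(range(p_all), k):
                adj = consider(idx)
                if adj is None:
                    continue
                if better(adj, idx):
                    best = (adj, idx)
    else:
        search = "forward"
        current: list[int] = []
        current_adj = -np.inf
        while len(current) < min(p_max, p_all):
            step_best = None
            for j in range(p_all):
                if j in current:
                    continue
                adj = consider(tuple(sorted(current + [j])))
                if adj is None:
                    continue
                if step_best is None or adj > step_best[0] + 1e-12 or (
                    abs(adj - step_best[0]) <= 1e-12 and names[j] < names[step_best[1]]
                ):
                    step_best = (adj, j)
            if step_best is None or step_best[0] <= current_adj:
                break
            current.append(step_best[1])
            current_adj = step_best[0]
            if best is None or current_adj > best[0]:
                best = (current_adj, tuple(sorted(current)))

    if best is None:
        raise ValueError("no admissible subset found (all designs rank-deficient)")
    adj, idx = best
    sel = [names[i] for i in idx]
    X = np.column_stack([np.ones(n), features[sel].to_numpy(dtype=float)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    coef = pd.Series(beta, index=["(intercept)"] + sel)
    return SubsetModel(features=sel, coefficients=coef, adjusted_r2=float(adj),
                       n=n, search=search)


def leave_one_farm_out(
    features: pd.DataFrame,
    radg: pd.Series,
    farm_ids: pd.Series,
    selected: list,
) -> tuple[pd.Series, float]:
    """Refit the fixed subset on all-but-one farm; score each held-out farm.

    R_i^2 = 1 - SSE/SST on farm i, adjusted by
    ``1 - (1 - R^2)(n_i - 1)/(n_i - p - 1)``.  Farms with too few pigs for
    the adjustment are skipped with a warning.  Returns (per-farm adjusted
    R_i^2, their arithmetic mean).
    """
    farms = farm_ids.reindex(features.index)
    uniq = sorted(farms.unique())
    if len(uniq) < 3:
        raise ValueError("leave-one-farm-out needs at least three farms")
    y = radg.reindex(features.index).to_numpy(dtype=float)
    X = features[selected].to_numpy(dtype=float)
    p = len(selected)
    out = {}
    for farm in uniq:
        test = (farms == farm).to_numpy()
        n_i = int(test.sum())
        if n_i <= p + 1:
            log.warning("leave_one_farm_out: farm %s has %d pigs <= p+1=%d, skipped",
                        farm, n_i, p + 1)
            continue
        Xtr = np.column_stack([np.ones((~test).sum()), X[~test]])
        beta, *_ = np.linalg.lstsq(Xtr, y[~test], rcond=None)
        pred = np.column_stack([np.ones(n_i), X[test]]) @ beta
        resid = y[test] - pred
        sst = ((y[test] - y[test].mean()) ** 2).sum()
        if sst <= 0:
            continue
        r2 = 1.0 - (resid @ resid) / sst
        out[farm] = _adjusted_r2(r2, n_i, p)
    if not out:
        raise ValueError("no farm could be scored")
    per_farm = pd.Series(out, name="adjusted_r2").rename_axis("farm_id")
    return per_farm, float(per_farm.mean())
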