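"""Factor-effect tests on taxa: Kruskal-Wallis + Dunn post-hoc,
Benjamini-Hochberg FDR control, pooled weaning percent-change summaries, and
the two-step growth-class association procedure.

The two-step procedure first prescreens taxa with rank-sum tests of the
growth class at each age separately (BH-adjusted p < 0.1 at either age keeps
a taxon), then, on pigs with data at both ages, tests class, age, and the
class x age interaction with OLS F-statistics referenced to a permutation
distribution in which pig-level class labels are permuted within farm (both
of a pig's samples move together, preserving exchangeability under the
null).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import RelAbundanceTable, SampleMetadata

log = logging.getLogger(__name__)


def bh_adjust(p: np.ndarray | list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _tie_correction(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    return float((counts**3 - counts).sum())


def _dunn_pairwise(values: np.ndarray, codes: np.ndarray, levels: list) -> pd.DataFrame:
    """Dunn z-tests on mean ranks with tie correction; BH across pairs."""
    n = len(values)
    ranks = stats.rankdata(values)
    mean_rank = {g: ranks[codes == i].mean() for i, g in enumerate(levels)}
    n_g = {g: int((codes == i).sum()) for i, g in enumerate(levels)}
    tie = _tie_correction(values)
    var_base = n * (n + 1) / 12.0 - tie / (12.0 * (n - 1))
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a, b = levels[i], levels[j]
            se = np.sqrt(var_base * (1.0 / n_g[a] + 1.0 / n_g[b]))
            z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
            rows.append((a, b, z, 2 * stats.norm.sf(abs(z))))
    df = pd.DataFrame(rows, columns=["level_a", "level_b", "z", "p"])
    df["p_adj"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df


@dataclass
class KruskalDunnResult:
    table: pd.DataFrame                 # per taxon: H, p, p_adj
    dunn: dict[str, pd.DataFrame]       # taxon -> pairwise table (when KW p<0.05)


def kruskal_dunn(
    rel: RelAbundanceTable,
    factor: pd.Series,
    alpha: float = 0.05,
    min_level_size: int = 2,
) -> KruskalDunnResult:
    """Per-taxon Kruskal-Wallis across factor levels (ties-corrected), BH
    across taxa, and Dunn pairwise z-tests where the omnibus test rejects."""
    data = rel.data
    fac = factor.reindex(data.index)
    if fac.isna().any():
        raise ValueError("factor missing for some samples")
    sizes = fac.value_counts()
    dropped = sizes.index[sizes < min_level_size]
    if len(dropped):
        log.warning("kruskal_dunn: dropping levels with <%d samples: %s",
                    min_level_size, list(dropped))
        keep = ~fac.isin(dropped)
        data, fac = data.loc[keep], fac[keep]
    levels = sorted(fac.unique())
    if len(levels) < 2:
        raise ValueError("factor needs at least two usable levels")
    codes = fac.map({g: i for i, g in enumerate(levels)}).to_numpy()
    rows, dunn = [], {}
    for taxon in data.columns:
        v = data[taxon].to_numpy()
        if np.ptp(v) == 0:
            rows.append((taxon, 0.0, 1.0))
            continue
        groups = [v[codes == i] for i in range(len(levels))]
        h, p = stats.kruskal(*groups)
        rows.append((taxon, h, p))
    table = pd.DataFrame(rows, columns=["taxon", "H", "p"]).set_index("taxon")
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    for taxon in table.index[table["p"] < alpha]:
        dunn[taxon] = _dunn_pairwise(data[taxon].to_numpy(), codes, levels)
    return KruskalDunnResult(table, dunn)


def percent_change(
    rel: RelAbundanceTable,
    metadata: SampleMetadata,
) -> pd.DataFrame:
    """Pooled d26->d35 percent change per taxon with a paired signed-rank
    test over pigs sampled at both ages.

    change = 100 * (mean_d35 - mean_d26) / mean_d26 over cross-sample
    arithmetic means.  Taxa absent at d26 get NaN change and a flag.
    """
    meta = metadata.data.loc[rel.data.index]
    by_age = rel.data.groupby(meta["age_point"].to_numpy()).mean()
    if not {"d26", "d35"}.issubset(by_age.index):
        raise ValueError("both age points required for percent change")
    m26, m35 = by_age.loc["d26"], by_age.loc["d35"]
    with np.errstate(divide="ignore", invalid="ignore"):
        change = 100.0 * (m35 - m26) / m26.replace(0, np.nan)

    # paired test on pigs with both samples
    wide = {}
    for age in ("d26", "d35"):
        sub = rel.data[meta["age_point"] == age]
        sub.index = meta.loc[sub.index, "pig_id"]
        wide[age] = sub
    common = wide["d26"].index.intersection(wide["d35"].index)
    pvals = []
    for taxon in rel.data.columns:
        a = wide["d26"].loc[common, taxon].to_numpy()
        b = wide["d35"].loc[common, taxon].to_numpy()
        diff = b - a
        if np.allclose(diff, 0):
            pvals.append(1.0)
        else:
            pvals.append(stats.wilcoxon(a, b, zero_method="wilcox").pvalue)
    out = pd.DataFrame({
        "mean_d26": m26,
        "mean_d35": m35,
        "percent_change": change,
        "p": pvals,
    })
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["undefined_baseline"] = m26 == 0
    return out.rename_axis("taxon")


# ---------------------------------------------------------------------------
# two-step growth-class association

def _ols_f_stats(y: np.ndarray, cls: np.ndarray, age: np.ndarray) -> np.ndarray:
    """Type-III F statistics for class, age, and class x age.

    Factors are centered, so in a balanced design (every pig at both ages)
    the three effect columns are mutually orthogonal and each term's effect
    sum of squares is invariant to reshuffling the other factors."""
    n = len(y)
    cls_c = cls - cls.mean()
    age_c = age - age.mean()
    inter = cls_c * age_c
    X_full = np.column_stack([np.ones(n), cls_c, age_c, inter - inter.mean()])

    def rss(X):
        beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if res.size and rank == X.shape[1]:
            return float(res[0])
        r = y - X @ beta
        return float(r @ r)

    rss_full = rss(X_full)
    df_resid = n - X_full.shape[1]
    out = np.empty(3)
    for t, drop in enumerate((1, 2, 3)):  # class / age / interaction
        keep = [c for c in range(4) if c != drop]
        out[t] = (rss(X_full[:, keep]) - rss_full) / max(rss_full / df_resid, 1e-300)
    return out


@dataclass
class TwoStepResult:
    step1: pd.DataFrame    # per taxon: p at d26/d35 (raw + BH), retained flag
    step2: pd.DataFrame    # per retained taxon: permutation p for class/age/interaction
    n_perm: int
    n_pigs: int


def two_step_radg(
    rel: RelAbundanceTable,
    growth_records: pd.DataFrame,
    metadata: SampleMetadata,
    alpha_pre: float = 0.1,
    n_perm: int = 5000,
    seed: int | None = None,
    adjust_step1: bool = True,
) -> TwoStepResult:
    """Two-step test of the growth-class effect on taxa.

    Step 1: per age, rank-sum test of rADG+ vs rADG- on all samples of that
    age; keep taxa with (BH-adjusted, or raw if ``adjust_step1=False``)
    p < ``alpha_pre`` at either age.  Step 2: on pigs with both samples, OLS
    F tests of class, age, class x age with p-values from within-farm
    pig-level permutations of the class labels.
    """
    meta = metadata.data.loc[rel.data.index]
    cls_of_pig = growth_records["growth_class"]
    cls = meta["pig_id"].map(cls_of_pig)
    usable = cls.isin(["rADG+", "rADG-"])

    # step 1
    rows = {}
    for age in ("d26", "d35"):
        mask = usable & (meta["age_point"] == age)
        y = rel.data[mask]
        is_pos = (cls[mask] == "rADG+").to_numpy()
        pv = []
        for taxon in y.columns:
            a, b = y[taxon].to_numpy()[is_pos], y[taxon].to_numpy()[~is_pos]
            if np.ptp(np.concatenate([a, b])) == 0:
                pv.append(1.0)
            else:
                pv.append(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows[f"p_{age}"] = np.array(pv)
        rows[f"p_adj_{age}"] = bh_adjust(np.array(pv))
    step1 = pd.DataFrame(rows, index=rel.data.columns)
    key = ("p_adj_d26", "p_adj_d35") if adjust_step1 else ("p_d26", "p_d35")
    step1["retained"] = (step1[key[0]] < alpha_pre) | (step1[key[1]] < alpha_pre)

    # step 2: complete pigs only
    pig_age = meta[usable].rename_axis("sample_id").reset_index().pivot(
        index="pig_id", columns="age_point", values="sample_id")
    if "d26" not in pig_age.columns or "d35" not in pig_age.columns:
        raise ValueError("both age points required")
    complete = pig_age.dropna()
    n_pigs = len(complete)
    per_class = cls_of_pig.reindex(complete.index).value_counts()
    if per_class.min() < 2 or len(per_class) < 2:
        raise ValueError("need at least two complete pigs per growth class")

    sample_ids = list(complete["d26"]) + list(complete["d35"])
    age_vec = np.r_[np.zeros(n_pigs), np.ones(n_pigs)]
    pig_cls = (cls_of_pig.reindex(complete.index) == "rADG+").to_numpy().astype(float)
    farms = growth_records["farm_id"].reindex(complete.index).to_numpy()
    farm_groups = [np.flatnonzero(farms == f) for f in np.unique(farms)]

    rng = np.random.default_rng(seed)
    retained = list(step1.index[step1["retained"]])
    step2_rows = []
    for taxon in retained:
        y = rel.data.loc[sample_ids, taxon].to_numpy()
        cls_vec = np.r_[pig_cls, pig_cls]
        f_obs = _ols_f_stats(y, cls_vec, age_vec)
        hits = np.zeros(3)
        for _ in range(n_perm):
            perm_cls = pig_cls.copy()
            for g in farm_groups:
                perm_cls[g] = perm_cls[rng.permutation(g)]
            f_perm = _ols_f_stats(y, np.r_[perm_cls, perm_cls], age_vec)
            hits += f_perm >= f_obs
        p = (1 + hits) / (1 + n_perm)
        step2_rows.append((taxon, *f_obs, *p))
    step2 = pd.DataFrame(
        step2_rows,
        columns=["taxon", "F_class", "F_age", "F_interaction",
                 "p_class", "p_age", "p_interaction"],
    ).set_index("taxon") if step2_rows else pd.DataFrame(
        columns=["F_class", "F_age", "F_interaction",
                 "p_class", "p_age", "p_interaction"]
    )
    return TwoStepResult(step1, step2, n_perm, n_pigs)
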