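"""Community-wide screen for directed, possibly non-monotonic associations.

Stages, in pipeline order: CSS normalization of count variables, variable
pruning (>= 16 unique values), pairwise co-occurrence filtering (>= 16
joint-presence plots), directed dependence q in both orientations with a
999-step permutation test, Spearman's rho, and classification of every
significant directed association as positive monotonic, negative
monotonic, or non-monotonic.  Each unordered variable pair yields two
directed records, one per orientation, labelled with the ordered
constituent-group pair ("association type").
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceTable, assoc_type
from .copula import _m_batch, _overlap_matrix, _pair_q_batch, rank_transform, resolution

logger = logging.getLogger(__name__)

EDGE_COLUMNS = [
    "source", "target", "assoc_type", "n_used",
    "q", "p_q", "m", "a", "rho", "p_rho", "klass",
]

CLASSES = ("positive", "negative", "non-monotonic")


@dataclass
class ScreenConfig:
    """Tunable parameters of the association screen (defaults as published)."""

    min_unique: int = 16
    min_co_occurrence: int = 16
    n_perm: int = 999
    alpha: float = 0.05
    seed: int = 0
    css_quantile: float = 0.5
    #: compute the dependence on all plots instead of co-occurrence plots
    use_all_plots: bool = False
    #: optional Benjamini-Hochberg FDR on permutation p-values (non-default)
    fdr: bool = False


def css_normalize(counts: pd.DataFrame, quantile_level: float = 0.5,
                  scale: float = 1000.0) -> pd.DataFrame:
    """Cumulative sum scaling of a plot x variable count matrix.

    For each sample (row), counts are divided by the sum of counts not
    exceeding the ``quantile_level`` quantile of the sample's positive
    counts, then multiplied by ``scale``.  Corrects for unequal
    sequencing depth while damping the influence of dominant taxa.
    All-zero samples are left unscaled with a warning.
    """
    if not 0 < quantile_level < 1:
        raise ValueError("quantile_level must be in (0, 1)")
    arr = counts.to_numpy(dtype=float)
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    out = arr.copy()
    flagged = []
    for i in range(arr.shape[0]):
        row = arr[i]
        positive = row[row > 0]
        if positive.size == 0:
            flagged.append(counts.index[i])
            continue
        q = np.quantile(positive, quantile_level)
        s = row[row <= q].sum()
        if s == 0:
            flagged.append(counts.index[i])
            continue
        out[i] = row / s * scale
    if flagged:
        warnings.warn(f"CSS: {len(flagged)} all-zero sample(s) left unscaled: {flagged}")
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def normalize_table(tbl: AbundanceTable, quantile_level: float = 0.5) -> AbundanceTable:
    """Apply CSS normalization to the count variables of a table."""
    count_cols = tbl.kind.index[tbl.kind == "count"]
    values = tbl.values.copy()
    if len(count_cols):
        values[count_cols] = css_normalize(values[count_cols], quantile_level)
    return AbundanceTable(values=values, groups=tbl.groups,
                          gradient=tbl.gradient, kind=tbl.kind)


def prune_variables(tbl: AbundanceTable, min_unique: int = 16) -> list[str]:
    """Variables with at least ``min_unique`` distinct observed values.

    Screens out sparse or near-constant variables for which a
    checkerboard of resolution >= 4 is not meaningful.
    """
    nunique = tbl.values.nunique()
    return nunique.index[nunique >= min_unique].tolist()


def co_occurrence_plots(x: str, y: str, tbl: AbundanceTable,
                        min_plots: int = 16) -> pd.Index | None:
    """Plots on which both variables are present, or None if fewer than
    ``min_plots`` (the pair is then rejected as a spurious co-occurrence)."""
    present = tbl.presence()
    mask = present[x] & present[y]
    if int(mask.sum()) < min_plots:
        return None
    return tbl.values.index[mask]


def _permutations(n: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    return rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)


def permutation_pvalue(x, y, n_perm: int = 999,
                       seed: int | np.random.Generator | None = 0
                       ) -> tuple[float, float]:
    """Permutation p-values of q(X,Y) and q(Y,X).

    The target y is permuted relative to x ``n_perm`` times on one shared
    permutation stream; each direction's p-value uses the add-one
    estimator p = (1 + #{q_perm >= q_obs}) / (n_perm + 1), so the
    smallest attainable p with 999 permutations is 0.001.
    """
    stats_ = _pair_statistics(np.asarray(x, float), np.asarray(y, float),
                              n_perm=n_perm, rng=np.random.default_rng(seed))
    return stats_["p_xy"], stats_["p_yx"]


def _pair_statistics(x: np.ndarray, y: np.ndarray, n_perm: int,
                     rng: np.random.Generator) -> dict:
    """All per-pair statistics: q, m (both orientations), permutation p's,
    Spearman rho.  One batched permutation stream serves both directions."""
    rp = rank_transform(x, y)
    N = resolution(rp.n)
    U = _overlap_matrix(rp.u_lo, rp.u_hi, N)
    V = _overlap_matrix(rp.v_lo, rp.v_hi, N)
    q_xy, q_yx = _pair_q_batch(U, V)
    q_xy, q_yx = float(q_xy), float(q_yx)
    mass = U.T @ V / rp.n
    m_xy = float(_m_batch(mass))
    m_yx = float(_m_batch(mass.T))
    if n_perm >= 1:
        perms = _permutations(rp.n, n_perm, rng)
        qp_xy, qp_yx = _pair_q_batch(U, V, perms)
        p_xy = (1 + int(np.sum(qp_xy >= q_xy))) / (n_perm + 1)
        p_yx = (1 + int(np.sum(qp_yx >= q_yx))) / (n_perm + 1)
    else:
        p_xy = p_yx = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant input -> nan rho
        rho, p_rho = stats.spearmanr(x, y)
    return dict(n=rp.n, N=N, q_xy=q_xy, q_yx=q_yx, a=q_xy - q_yx,
                m_xy=m_xy, m_yx=m_yx, p_xy=p_xy, p_yx=p_yx,
                rho=float(rho), p_rho=float(p_rho))


def classify_association(p_q: float, m: float, rho: float, p_rho: float,
                         alpha: float = 0.05) -> str:
    """Assign one directed association to its class.

    not-significant if the permutation test fails (p_q > alpha);
    otherwise positive/negative by a significant Spearman trend (sign of
    rho), or non-monotonic when no significant monotone trend exists.
    Sign conflicts between m and rho are resolved by rho and logged.
    """
    for name, v in (("p_q", p_q), ("m", m), ("rho", rho), ("p_rho", p_rho)):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError(f"missing input: {name}")
    if p_q > alpha:
        return "not-significant"
    if p_rho <= alpha:
        klass = "positive" if rho > 0 else "negative"
        if m * rho < 0:
            logger.info("m/rho sign conflict (m=%.3f, rho=%.3f): classified by rho", m, rho)
        return klass
    return "non-monotonic"


def screen_all(tbl: AbundanceTable, config: ScreenConfig | None = None) -> pd.DataFrame:
    """Screen every retained variable pair; two directed records per pair.

    Returns a table with columns source, target, assoc_type, n_used, q,
    p_q, m, a, rho, p_rho, klass — deterministic under a fixed seed.
    """
    config = config or ScreenConfig()
    kept = prune_variables(tbl, config.min_unique)
    if not kept:
        raise ValueError("no variables retained after pruning")
    present = tbl.presence()
    pairs = list(itertools.combinations(kept, 2))
    children = np.random.SeedSequence(config.seed).spawn(len(pairs))
    records = []
    n_rejected = 0
    for (vx, vy), child in zip(pairs, children):
        if config.use_all_plots:
            plots = tbl.values.index
        else:
            mask = present[vx] & present[vy]
            if int(mask.sum()) < config.min_co_occurrence:
                n_rejected += 1
                continue
            plots = tbl.values.index[mask]
        x = tbl.values.loc[plots, vx].to_numpy(float)
        y = tbl.values.loc[plots, vy].to_numpy(float)
        st = _pair_statistics(x, y, config.n_perm, np.random.default_rng(child))
        for src, tgt, q, p_q, m, a in (
            (vx, vy, st["q_xy"], st["p_xy"], st["m_xy"], st["a"]),
            (vy, vx, st["q_yx"], st["p_yx"], st["m_yx"], -st["a"]),
        ):
            records.append({
                "source": src, "target": tgt,
                "assoc_type": assoc_type(tbl.groups[src], tbl.groups[tgt]),
                "n_used": st["n"], "q": q, "p_q": p_q, "m": m, "a": a,
                "rho": st["rho"], "p_rho": st["p_rho"],
            })
    logger.info("screen: %d pairs tested, %d rejected by co-occurrence",
                len(pairs) - n_rejected, n_rejected)
    assocs = pd.DataFrame.from_records(records, columns=EDGE_COLUMNS[:-1])
    if config.fdr:
        assocs["p_q"] = _bh_adjust(assocs["p_q"].to_numpy())
    assocs["klass"] = [
        classify_association(r.p_q, r.m, r.rho, r.p_rho, config.alpha)
        for r in assocs.itertuples()
    ]
    return assocs


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


def significant(assocs: pd.DataFrame) -> pd.DataFrame:
    """Drop not-significant records (the published screens do so downstream)."""
    return assocs[assocs["klass"] != "not-significant"].copy()


def proportions_by_type(assocs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class proportions per association type, with pairwise G-tests.

    Returns (proportions, gtests).  proportions: counts and proportions
    of positive/negative/non-monotonic per type (non-significant records
    excluded).  gtests: for each pair of types, the G-statistic
    2 * sum O ln(O/E) of the 2 x K contingency table (classes with zero
    total dropped), with chi-square p-values and Bonferroni correction.
    """
    sig = significant(assocs)
    counts = (
        sig.groupby(["assoc_type", "klass"]).size()
        .unstack(fill_value=0)
        .reindex(columns=list(CLASSES), fill_value=0)
    )
    props = counts.div(counts.sum(axis=1), axis=0)
    props.columns = [f"prop_{c}" for c in props.columns]
    report = pd.concat([counts, props], axis=1)
    report["n_significant"] = counts.sum(axis=1)

    types = counts.index[counts.sum(axis=1) > 0].tolist()
    rows = []
    for ta, tb in itertools.combinations(types, 2):
        table = counts.loc[[ta, tb]].to_numpy()
        table = table[:, table.sum(axis=0) > 0]
        if table.shape[1] < 2:
            g, df, p = 0.0, 0, 1.0
        else:
            g, p, df, _ = stats.chi2_contingency(
                table, correction=False, lambda_="log-likelihood")
        rows.append({"type_a": ta, "type_b": tb, "G": float(g), "df": int(df),
                     "p": float(p)})
    gtests = pd.DataFrame(rows, columns=["type_a", "type_b", "G", "df", "p"])
    if len(gtests):
        gtests["p_bonferroni"] = np.minimum(gtests["p"] * len(gtests), 1.0)
    else:
        gtests["p_bonferroni"] = pd.Series(dtype=float)
    return report, gtests


def split_stages(tbl: AbundanceTable) -> tuple[AbundanceTable, AbundanceTable]:
    """Split plots into early and late successional stages by gradient rank.

    The first ceil(n/2) plots along the gradient form the early stage
    (a 135-plot gradient splits 68/67).
    """
    order = tbl.gradient.sort_values(kind="stable").index
    n_early = math.ceil(len(order) / 2)
    return tbl.subset_plots(order[:n_early]), tbl.subset_plots(order[n_early:])


def compare_stages(assocs_early: pd.DataFrame,
                   assocs_late: pd.DataFrame) -> pd.DataFrame:
    """Paired Wilcoxon tests of class proportions between two stages.

    The pairing unit is the association type: for each class, the per-type
    proportion in the early screen is paired with the same type's
    proportion in the late screen.  Types with no significant association
    in either stage are dropped.
    """
    prop_e, _ = proportions_by_type(assocs_early)
    prop_l, _ = proportions_by_type(assocs_late)
    shared = prop_e.index.intersection(prop_l.index)
    if len(shared) < 2:
        raise ValueError("fewer than 2 paired association types")
    rows = []
    for klass in CLASSES:
        e = prop_e.loc[shared, f"prop_{klass}"].to_numpy()
        l = prop_l.loc[shared, f"prop_{klass}"].to_numpy()
        diff = l - e
        if np.allclose(diff, 0):
            p = 1.0  # no signed ranks to test
        else:
            p = float(stats.wilcoxon(e, l).pvalue)
        rows.append({"klass": klass, "n_types": len(shared),
                     "median_diff_late_minus_early": float(np.median(diff)),
                     "p": p})
    return pd.DataFrame(rows)
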