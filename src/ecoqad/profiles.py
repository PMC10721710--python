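"""Association profiles in (q, m) space: overlap, clustering, per-type tests.

Every significant directed association is a point in the two-dimensional
"association space" with coordinates (q, m).  The point cloud of one
association type is its association profile.  Profile overlap is
quantified with dynamic range boxes (dynRB): at each quantile level
gamma, each profile spans a box [Q(gamma), Q(1-gamma)] per dimension;
port(A, B) is the portion of B's box covered by A's, multiplied over
dimensions and averaged over gamma levels.  1 - port, symmetrized,
yields a dissimilarity used for average-linkage hierarchical clustering
with ordinary bootstrap support on the nodes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .screening import significant

DEFAULT_GAMMA_GRID = tuple(np.round(np.arange(0.0, 0.50, 0.05), 2))


@dataclass(frozen=True)
class AssociationProfile:
    """(q, m) point cloud of one association type."""

    assoc_type: str
    points: np.ndarray  # (k, 2) columns q, m

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be a (k, 2) array of (q, m) pairs")
        if pts.shape[0] == 0:
            raise ValueError(f"empty profile for {self.assoc_type}")
        if np.any(pts[:, 0] < 0) or np.any(pts[:, 0] > 1) or np.any(np.abs(pts[:, 1]) > 1):
            raise ValueError("q must lie in [0,1] and m in [-1,1]")
        object.__setattr__(self, "points", pts)


def build_profiles(assocs: pd.DataFrame, min_points: int = 1) -> list[AssociationProfile]:
    """Profiles of all association types with at least ``min_points``
    significant directed associations."""
    sig = significant(assocs)
    profiles = []
    for atype, sub in sig.groupby("assoc_type", sort=True):
        if len(sub) >= min_points:
            profiles.append(AssociationProfile(atype, sub[["q", "m"]].to_numpy()))
    return profiles


def dynrb_port(A: AssociationProfile, B: AssociationProfile,
               gamma_grid=DEFAULT_GAMMA_GRID) -> float:
    """Portion of B's dynamic range boxes covered by A's, in [0, 1].

    Asymmetric: port(A, B) answers "how much of B's occupied region does
    A reach into"; per gamma level the per-dimension overlaps are
    multiplied, then averaged over the grid.  Degenerate B intervals
    contribute 0.
    """
    gammas = np.asarray(gamma_grid, dtype=float)
    if gammas.size == 0 or np.any(gammas < 0) or np.any(gammas >= 0.5):
        raise ValueError("gamma grid must be non-empty and lie in [0, 0.5)")
    ports = np.empty(gammas.size)
    for g_i, g in enumerate(gammas):
        per_dim = np.empty(2)
        for d in range(2):
            lo_a, hi_a = np.quantile(A.points[:, d], [g, 1 - g])
            lo_b, hi_b = np.quantile(B.points[:, d], [g, 1 - g])
            width_b = hi_b - lo_b
            if width_b <= 0:
                per_dim[d] = 0.0
            else:
                inter = min(hi_a, hi_b) - max(lo_a, lo_b)
                per_dim[d] = max(inter, 0.0) / width_b
        ports[g_i] = per_dim.prod()
    return float(ports.mean())


def profile_dissimilarity(profiles: list[AssociationProfile],
                          gamma_grid=DEFAULT_GAMMA_GRID) -> pd.DataFrame:
    """Symmetric dissimilarity matrix d(A,B) = 1 - (port(A,B)+port(B,A))/2."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    names = [p.assoc_type for p in profiles]
    d = np.zeros((len(profiles), len(profiles)))
    for i, j in itertools.combinations(range(len(profiles)), 2):
        pij = dynrb_port(profiles[i], profiles[j], gamma_grid)
        pji = dynrb_port(profiles[j], profiles[i], gamma_grid)
        d[i, j] = d[j, i] = 1.0 - 0.5 * (pij + pji)
    return pd.DataFrame(np.clip(d, 0.0, 1.0), index=names, columns=names)


@dataclass
class ClusterResult:
    """Average-linkage dendrogram of association profiles with bootstrap support."""

    labels: list[str]
    linkage: np.ndarray
    #: frozenset of leaf labels -> bootstrap support in [0, 1]
    supports: dict = field(default_factory=dict)
    newick: str = ""


def _clades(Z: np.ndarray, labels: list[str]) -> list[frozenset]:
    n = len(labels)
    sets: list[frozenset] = [frozenset([lab]) for lab in labels]
    for a, b, _, _ in Z:
        sets.append(sets[int(a)] | sets[int(b)])
    return sets[n:]


def _to_newick(node, labels: list[str], supports: dict) -> str:
    if node.is_leaf():
        return f"{labels[node.id]}:{node.dist:.6g}"
    left = _to_newick(node.left, labels, supports)
    right = _to_newick(node.right, labels, supports)
    leaves = frozenset(labels[i] for i in node.pre_order(lambda x: x.id))
    sup = supports.get(leaves)
    label = f"{sup:.3f}" if sup is not None else ""
    return f"({left},{right}){label}:{node.dist:.6g}"


def cluster_profiles(profiles: list[AssociationProfile], n_boot: int = 1000,
                     seed: int | None = 0,
                     gamma_grid=DEFAULT_GAMMA_GRID) -> ClusterResult:
    """Cluster association profiles and attach ordinary bootstrap supports.

    Each bootstrap replicate resamples every profile's points with
    replacement, recomputes the dissimilarity matrix and the
    average-linkage tree; a node's support is the fraction of replicate
    trees containing the same leaf set.
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles for a non-trivial tree")
    labels = [p.assoc_type for p in profiles]
    d = profile_dissimilarity(profiles, gamma_grid)
    Z = hierarchy.linkage(d.to_numpy()[np.triu_indices(len(labels), 1)],
                          method="average")
    observed = _clades(Z, labels)
    counts = dict.fromkeys(observed, 0)
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        res = [
            AssociationProfile(
                p.assoc_type,
                p.points[rng.integers(0, len(p.points), len(p.points))])
            for p in profiles
        ]
        db = profile_dissimilarity(res, gamma_grid)
        Zb = hierarchy.linkage(db.to_numpy()[np.triu_indices(len(labels), 1)],
                               method="average")
        for clade in _clades(Zb, labels):
            if clade in counts:
                counts[clade] += 1
    supports = {clade: c / n_boot for clade, c in counts.items()} if n_boot else {}
    tree = hierarchy.to_tree(Z)
    newick = f"{_to_newick(tree, labels, supports)};"
    return ClusterResult(labels=labels, linkage=Z, supports=supports, newick=newick)


def _compact_letters(types: list[str], different: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display: types sharing a letter are
    not significantly different."""
    groups: list[set[str]] = [set(types)]
    for a, b in different:
        for g in list(groups):
            if a in g and b in g:
                groups.remove(g)
                for drop in (a, b):
                    ng = g - {drop}
                    if ng and not any(ng <= other for other in groups):
                        groups.append(ng)
    groups.sort(key=lambda g: sorted(types.index(t) for t in g))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {t: "" for t in types}
    for letter, g in zip(alphabet, groups):
        for t in g:
            out[t] += letter
    return out


def per_type_tests(assocs: pd.DataFrame, min_records: int = 2,
                   method: str = "ranksum", alpha: float = 0.05
                   ) -> tuple[pd.DataFrame, dict[str, dict[str, str]]]:
    """Pairwise per-type comparisons of q and of m with Bonferroni correction.

    For every pair of association types, compares the distributions of q
    and of m with a two-sample Wilcoxon rank-sum test (the default;
    ``method='signed-rank'`` pairs records positionally after truncation
    to the shorter type and is only meaningful for matched designs).
    Returns the test table and compact-letter groupings per metric.
    """
    sig = significant(assocs)
    sizes = sig.groupby("assoc_type").size()
    small = sizes.index[sizes < min_records].tolist()
    if small:
        warnings.warn(f"types with < {min_records} records skipped: {small}")
    types = sizes.index[sizes >= min_records].tolist()
    if len(types) < 2:
        raise ValueError("need at least 2 association types with enough records")
    pairs = list(itertools.combinations(types, 2))
    n_tests = len(pairs) * 2
    rows = []
    for ta, tb in pairs:
        for metric in ("q", "m"):
            va = sig.loc[sig.assoc_type == ta, metric].to_numpy()
            vb = sig.loc[sig.assoc_type == tb, metric].to_numpy()
            if method == "ranksum":
                p = float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
            elif method == "signed-rank":
                k = min(len(va), len(vb))
                diff = va[:k] - vb[:k]
                p = 1.0 if np.allclose(diff, 0) else float(stats.wilcoxon(diff).pvalue)
            else:
                raise ValueError(f"unknown method: {method!r}")
            rows.append({"type_a": ta, "type_b": tb, "metric": metric,
                         "p": p, "p_bonferroni": min(p * n_tests, 1.0)})
    report = pd.DataFrame(rows)
    letters = {}
    for metric in ("q", "m"):
        sub = report[report.metric == metric]
        different = {(r.type_a, r.type_b) for r in sub.itertuples()
                     if r.p_bonferroni <= alpha}
        letters[metric] = _compact_letters(types, different)
    return report, letters
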