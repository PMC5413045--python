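"""Expression statistics: normalization, differential calls, screens, ddCt.

The microarray side follows the study's recipe: per-array 2%-trimmed-mean
scaling to a common target of 2,500; differential expression as a mean fold
change >= 3 (or <= 1/3) combined with an equal-variance two-sided Student
t-test and Benjamini-Hochberg control at FDR 5%; Pearson correlations of
per-probe intensity differences between contrasts; and average-linkage
(UPGMA) hierarchical clustering on 1 - Pearson correlation of log2
fold-change profiles.

The small-RNA side implements the responsiveness screen: per-library CPM
normalization with a pseudocount, per-genotype low/normal-temperature
response ratios, and selection of miRNAs whose response ratio differs
between genotypes by more than 3-fold (the scatter-plot threshold of 2-fold
is a separate parameter).  qPCR quantification uses the standard 2^-ddCt
form against an internal control gene and a calibrator sample.

The t-test runs on log2(normalized + 1) for variance stabilization (a
``log_scale=False`` flag reverts to the raw scale), and the fold change is
the ratio of group means on the normalized linear scale (``mean_of_ratios``
gives the per-replicate-pair alternative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "normalize_trimmed_mean",
    "trimmed_mean",
    "call_de",
    "bh_adjust",
    "venn",
    "contrast_correlation",
    "cluster_features",
    "screen_responsive",
    "ddct",
    "ContrastResult",
]


def trimmed_mean(values: np.ndarray, trim: float = 0.02) -> float:
    """Mean after dropping the ceil(trim*n) largest and smallest values."""
    x = np.sort(np.asarray(values, dtype=float))
    k = math.ceil(trim * x.size)
    if 2 * k >= x.size:
        raise ValueError("trim removes all values")
    return float(x[k: x.size - k].mean())


def normalize_trimmed_mean(matrix: pd.DataFrame, trim: float = 0.02,
                           target: float = 2500.0) -> pd.DataFrame:
    """Scale each array (column) so its trimmed mean equals ``target``."""
    if (matrix.values < 0).any():
        raise ValueError("intensities must be nonnegative")
    out = {}
    for col in matrix.columns:
        tm = trimmed_mean(matrix[col].values, trim)
        if tm == 0:
            raise ValueError(f"array {col!r} has zero trimmed mean")
        out[col] = matrix[col] * (target / tm)
    return pd.DataFrame(out, index=matrix.index)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class ContrastResult:
    """Per-feature differential-expression calls for one comparison."""

    table: pd.DataFrame  # fold_change, log2_ratio, p, q, call
    group_a: tuple
    group_b: tuple

    @property
    def up(self) -> set:
        return set(self.table.index[self.table["call"] == "up"])

    @property
    def down(self) -> set:
        return set(self.table.index[self.table["call"] == "down"])


def call_de(matrix: pd.DataFrame, group_a, group_b, fold: float = 3.0,
            alpha: float = 0.05, log_scale: bool = True,
            mean_of_ratios: bool = False) -> ContrastResult:
    """Fold-change + Student t + BH differential calls (B relative to A).

    ``matrix`` holds normalized linear intensities; groups are column lists
    with >= 2 replicates each.  ``up``: mean fold >= ``fold`` and q < alpha;
    ``down``: mean fold <= 1/``fold`` and q < alpha; otherwise ``ns``.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    a = matrix[group_a].values.astype(float)
    b = matrix[group_b].values.astype(float)
    if mean_of_ratios:
        fc = (b[:, :, None] / np.maximum(a[:, None, :], 1e-300)).mean(axis=(1, 2))
    else:
        fc = b.mean(axis=1) / np.maximum(a.mean(axis=1), 1e-300)
    if log_scale:
        a_t, b_t = np.log2(a + 1), np.log2(b + 1)
    else:
        a_t, b_t = a, b
    t, p = stats.ttest_ind(b_t, a_t, axis=1, equal_var=True)
    p = np.where(np.isnan(p), 1.0, p)  # zero variance in both groups, equal means
    q = bh_adjust(p)
    call = np.where((fc >= fold) & (q < alpha), "up",
                    np.where((fc <= 1 / fold) & (q < alpha), "down", "ns"))
    table = pd.DataFrame({
        "fold_change": fc,
        "log2_ratio": np.log2(np.maximum(fc, 1e-300)),
        "p": p,
        "q": q,
        "call": call,
    }, index=matrix.index)
    return ContrastResult(table, tuple(group_a), tuple(group_b))


def venn(sets: dict[str, set]) -> dict[str, int]:
    """Exclusive-region and intersection counts for 2 or 3 named sets."""
    names = list(sets)
    if len(names) not in (2, 3):
        raise ValueError("venn supports 2 or 3 sets")
    out = {}
    universe = set().union(*sets.values())
    from itertools import combinations
    # exclusive regions
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo)) \
                if len(combo) < len(names) else set()
            out["&".join(combo) + "_only"] = len(inside - outside)
    for r in (2, 3):
        for combo in combinations(names, r):
            if r <= len(names):
                out["&".join(combo)] = len(set.intersection(*(sets[n] for n in combo)))
    out["union"] = len(universe)
    return out


def contrast_correlation(delta1, delta2) -> tuple[float, float]:
    """Pearson r (and two-sided p) between per-probe difference vectors."""
    d1 = np.asarray(delta1, dtype=float)
    d2 = np.asarray(delta2, dtype=float)
    if d1.shape != d2.shape:
        raise ValueError("difference vectors must cover the same probes")
    if np.std(d1) == 0 or np.std(d2) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    r, p = stats.pearsonr(d1, d2)
    return float(r), float(p)


def cluster_features(log2fc: pd.DataFrame, k: int = 6
                     ) -> tuple[np.ndarray, pd.Series, list]:
    """UPGMA clustering of feature log2 fold-change profiles.

    Distance is 1 - Pearson correlation between feature rows; constant rows
    are dropped with a warning entry.  Returns ``(linkage, labels, dropped)``
    with labels cut to ``k`` clusters (scipy maxclust numbering).
    """
    import warnings

    values = log2fc.values.astype(float)
    sd = values.std(axis=1)
    dropped = list(log2fc.index[sd == 0])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant feature(s): "
                      f"correlation undefined", stacklevel=2)
    keep = log2fc.loc[sd > 0]
    if len(keep) < k:
        raise ValueError(f"need >= {k} non-constant features")
    corr = np.corrcoef(keep.values)
    dist = 1.0 - corr
    condensed = dist[np.triu_indices_from(dist, k=1)]
    condensed = np.maximum(condensed, 0.0)
    link = hierarchy.average(condensed)
    labels = pd.Series(hierarchy.fcluster(link, t=k, criterion="maxclust"),
                       index=keep.index, name="cluster")
    return link, labels, dropped


def linkage_to_newick(link: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(link)

    def walk(node):
        if node.is_leaf():
            return leaf_names[node.id]
        left, right = walk(node.left), walk(node.right)
        return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

    return walk(tree) + ";"


def screen_responsive(counts: pd.DataFrame, line_wt: str, line_mut: str,
                      threshold: float = 3.0, pseudocount: float = 1.0,
                      plot_threshold: float = 2.0) -> pd.DataFrame:
    """Differential temperature-responsiveness screen over miRNA counts.

    ``counts`` columns must be the four libraries named ``{line}_{temp}C``
    with temps 24 and 4.  Counts are CPM-normalized per library; each line's
    response ratio is R = (CPM at 4C + c) / (CPM at 24C + c) and the screen
    statistic is S = R_wt / R_mut.  Selected iff S > threshold or
    S < 1/threshold; the scatter-plot flag uses ``plot_threshold`` the same
    way.
    """
    cols = [f"{line_wt}_24C", f"{line_wt}_4C", f"{line_mut}_24C", f"{line_mut}_4C"]
    missing = [c for c in cols if c not in counts.columns]
    if missing:
        raise ValueError(f"missing libraries: {missing}")
    cpm = counts[cols].astype(float)
    totals = cpm.sum(axis=0)
    cpm = cpm * 1e6 / totals.replace(0, np.nan)
    c = pseudocount
    r_wt = (cpm[f"{line_wt}_4C"] + c) / (cpm[f"{line_wt}_24C"] + c)
    r_mut = (cpm[f"{line_mut}_4C"] + c) / (cpm[f"{line_mut}_24C"] + c)
    s = r_wt / r_mut
    table = pd.DataFrame({
        "r_wt": r_wt,
        "r_mut": r_mut,
        "screen_statistic": s,
        "log2_screen": np.log2(s),
        "selected": (s > threshold) | (s < 1 / threshold),
        "plot_flagged": (s >= plot_threshold) | (s <= 1 / plot_threshold),
    }, index=counts.index)
    return table


def ddct(ct_table: pd.DataFrame, target_gene: str, control_gene: str,
         sample: str, calibrator: str) -> float:
    """Relative expression 2^-ddCt of a target gene vs an internal control.

    ``ct_table`` is long-format with columns gene, sample, ct (technical
    replicates averaged).  dCt = Ct_target - Ct_control per sample;
    ddCt = dCt_sample - dCt_calibrator.
    """
    means = ct_table.groupby(["gene", "sample"])["ct"].mean()

    def dct(s):
        try:
            return means[(target_gene, s)] - means[(control_gene, s)]
        except KeyError as exc:
            raise ValueError(f"missing Ct value for {exc.args[0]}") from exc

    return float(2.0 ** -(dct(sample) - dct(calibrator)))
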