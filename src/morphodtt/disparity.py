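"""Time binning, sum-of-variances disparity, and permutation tests.

Disparity is measured as the sum of per-PC sample variances (SoV) of a
group's scores within a time bin, computed on the first m PCs (8 by
default, the broken-stick-significant block in the motivating dataset).
Bins with fewer than ``min_taxa`` members (3 by default) are recorded but
carry no SoV.  Differences in disparity between two groups are tested by
pooling the scores and reshuffling taxa between the groups at the original
sample sizes; positional differences in morphospace are tested with
NPMANOVA on Euclidean distances.  All permutation p-values use the add-one
estimator p = (1 + exceedances) / (1 + replicates), so p is always positive
and exactly reproducible for a given seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "assign_bins",
    "sum_of_variances",
    "group_membership_sets",
    "disparity_curve",
    "permutation_disparity_test",
    "npmanova",
    "NpmanovaResult",
    "bonferroni",
    "disparity_size_correlation",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def assign_bins(ages: Mapping[str, float] | pd.Series, bins: pd.DataFrame) -> pd.Series:
    """Assign each age to its time bin (older edge inclusive).

    Age ``a`` falls in bin B iff ``B.older >= a > B.younger``.  Ages outside
    every bin come back as NaN with a warning naming them.
    """
    ages = pd.Series(dict(ages) if not isinstance(ages, pd.Series) else ages, dtype=float)
    out = pd.Series(pd.NA, index=ages.index, dtype=object)
    for _, row in bins.iterrows():
        mask = (ages <= row["older"]) & (ages > row["younger"])
        out[mask] = row["name"]
    unassigned = out[out.isna()].index.tolist()
    if unassigned:
        warnings.warn(
            f"{len(unassigned)} age(s) fall outside every bin: {unassigned}",
            stacklevel=2,
        )
    return out


def sum_of_variances(scores: np.ndarray) -> float:
    """Sum over columns of the (n-1)-divisor sample variance."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 2:
        raise ValueError("need a 2D score matrix with at least 2 rows")
    return float(scores.var(axis=0, ddof=1).sum())


def group_membership_sets(
    tip_groups: Mapping[str, str],
    tree=None,
) -> dict[str, frozenset[str]]:
    """Base-group set carried by each terminal and (optionally) ancestor.

    A terminal carries the singleton of its own group; an internal node of
    ``tree`` carries the union of its descendants' groups.  A node then
    belongs to a named (possibly composite) group iff its carried set is a
    subset of that group's base groups — so a crown subclade's ancestors
    count for the subclade and for the crown, while backbone ancestors with
    mixed descendants count only for groupings that span all their
    descendants.
    """
    sets: dict[str, frozenset[str]] = {
        taxon: frozenset([g]) for taxon, g in tip_groups.items()
    }
    if tree is not None:
        from .chronophylo import _label

        for node in tree.postorder_node_iter():
            if node.is_leaf():
                continue
            carried: set[str] = set()
            for child in node.child_nodes():
                if child.is_leaf():
                    carried |= sets[child.taxon.label]
                else:
                    carried |= sets[_label(child)]
            sets[_label(node)] = frozenset(carried)
    return sets


def disparity_curve(
    scores: pd.DataFrame,
    bin_assignment: pd.Series,
    membership: Mapping[str, frozenset[str] | str],
    group_sets: Mapping[str, Iterable[str]],
    bin_order: Sequence[str],
    m_pcs: int = 8,
    min_taxa: int = 3,
) -> pd.DataFrame:
    """Per (group, bin) sample size and sum-of-variances table.

    ``membership`` maps each label (terminal or ancestor) to its carried
    base-group set (see :func:`group_membership_sets`); ``group_sets`` maps
    each named group — composites included — to the base groups it spans.
    SoV is NaN wherever n < ``min_taxa``; n is always recorded.
    """
    m_pcs = min(m_pcs, scores.shape[1])
    use = scores.iloc[:, :m_pcs]
    rows = []
    for gname, bases in group_sets.items():
        bases = frozenset(bases)
        unknown = bases - {b for s in membership.values() for b in (frozenset([s]) if isinstance(s, str) else s)}
        if unknown:
            raise ValueError(f"group {gname!r} references unknown base groups: {sorted(unknown)}")
        members = [
            lab
            for lab in use.index
            if lab in membership
            and (
                frozenset([membership[lab]]) if isinstance(membership[lab], str) else frozenset(membership[lab])
            )
            <= bases
        ]
        for bname in bin_order:
            in_bin = [lab for lab in members if bin_assignment.get(lab) == bname]
            n = len(in_bin)
            sov = (
                sum_of_variances(use.loc[in_bin].to_numpy())
                if n >= max(min_taxa, 2)
                else np.nan
            )
            rows.append({"group": gname, "bin": bname, "n": n, "sov": sov})
    return pd.DataFrame(rows)


def permutation_disparity_test(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    n_permutations: int = 10_000,
    seed=None,
    min_taxa: int = 3,
) -> tuple[float, float]:
    """Two-sided permutation test for a difference in sum-of-variances.

    The statistic is |SoV(A) - SoV(B)|.  Group sizes are held fixed; each
    replicate reshuffles the pooled taxa between the groups without
    replacement.  Returns (observed statistic, add-one p-value).
    """
    A = np.atleast_2d(np.asarray(scores_a, dtype=float))
    B = np.atleast_2d(np.asarray(scores_b, dtype=float))
    if A.shape[0] < min_taxa or B.shape[0] < min_taxa:
        raise ValueError(
            f"both groups need >= {min_taxa} members; got {A.shape[0]} and {B.shape[0]}"
        )
    rng = _rng(seed)
    observed = abs(sum_of_variances(A) - sum_of_variances(B))
    pool = np.vstack([A, B])
    n_a = A.shape[0]
    # ties count as exceedances; the tolerance absorbs float summation-order
    # noise so a re-drawn identity split is not dropped
    threshold = observed - 1e-12 * (1.0 + observed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pool.shape[0])
        stat = abs(
            sum_of_variances(pool[perm[:n_a]]) - sum_of_variances(pool[perm[n_a:]])
        )
        if stat >= threshold:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return observed, p


@dataclass
class NpmanovaResult:
    """Nonparametric MANOVA outcome on a Euclidean distance matrix."""

    f_statistic: float
    p_value: float
    group_sizes: dict[str, int]
    n_permutations: int


def _permanova_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F from squared distances via the within/total decomposition."""
    N = d2.shape[0]
    groups = np.unique(labels)
    g = groups.size
    iu = np.triu_indices(N, k=1)
    ss_total = d2[iu].sum() / N
    ss_within = 0.0
    for grp in groups:
        idx = np.flatnonzero(labels == grp)
        sub = d2[np.ix_(idx, idx)]
        ss_within += np.triu(sub, k=1).sum() / idx.size
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        return np.inf if ss_among > 0 else 0.0
    return (ss_among / (g - 1)) / (ss_within / (N - g))


def npmanova(
    scores: np.ndarray,
    labels: Sequence[str],
    n_permutations: int = 10_000,
    seed=None,
) -> NpmanovaResult:
    """NPMANOVA (PERMANOVA) on Euclidean distances between score rows.

    F = (SS_among/(g-1)) / (SS_within/(N-g)) with sums of squares obtained
    from the pairwise squared-distance decomposition; the p-value permutes
    group labels with the add-one rule.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels length mismatch")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < 2:
        small = uniq[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 members: {small}")
    rng = _rng(seed)
    diff = scores[:, None, :] - scores[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    observed = _permanova_f(d2, labels)
    threshold = observed - 1e-12 * (1.0 + abs(observed))  # count ties
    count = 0
    for _ in range(n_permutations):
        if _permanova_f(d2, rng.permutation(labels)) >= threshold:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return NpmanovaResult(
        f_statistic=float(observed),
        p_value=p,
        group_sizes={str(u): int(c) for u, c in zip(uniq, counts)},
        n_permutations=n_permutations,
    )


def bonferroni(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    return np.minimum(1.0, m * p)


def disparity_size_correlation(
    sov: Sequence[float], n_taxa: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation between a disparity curve and sample size.

    Bins with undefined SoV are dropped pairwise; at least 4 defined pairs
    are required.  Returns (rho, p).
    """
    sov = np.asarray(sov, dtype=float)
    n_taxa = np.asarray(n_taxa, dtype=float)
    keep = np.isfinite(sov) & np.isfinite(n_taxa)
    if keep.sum() < 4:
        raise ValueError(f"need >= 4 defined (SoV, n) pairs; got {int(keep.sum())}")
    x, y = sov[keep], n_taxa[keep]
    rho = float(stats.spearmanr(x, y).statistic)
    n = int(keep.sum())
    if n <= 7:
        # few bins: exact two-sided permutation distribution of rho
        from itertools import permutations

        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        perms = np.array(list(permutations(ry)))
        cx = rx - rx.mean()
        cy = perms - ry.mean()
        rhos = cy @ cx / np.sqrt((cx @ cx) * (cy * cy).sum(axis=1))
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return rho, p
    return rho, float(stats.spearmanr(x, y).pvalue)
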