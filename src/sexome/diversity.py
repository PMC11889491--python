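"""Alpha and beta diversity: Shannon, rank-sum test, Bray-Curtis, PCoA,
one-factor PERMANOVA.

These are the community-level statistics used to compare penile-skin and
vaginal microbiomes across sexes, couples and before/after-intercourse
timepoints.  All are implemented directly from their defining formulas so
that every numeric choice (log base, tie handling, permutation scheme,
eigenvalue treatment) is explicit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from sexome.cohort import AsvCountTable, CohortDataset
from sexome.errors import EmptySampleError

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "PermanovaResult",
    "shannon_index",
    "rank_sum_test",
    "bray_curtis",
    "bray_curtis_matrix",
    "pcoa",
    "permanova",
    "alpha_table",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with sample labels."""

    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        ids = tuple(self.sample_ids)
        object.__setattr__(self, "sample_ids", ids)
        m = np.asarray(self.values, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(ids):
            raise ValueError("distance matrix must be square and match ids")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(m)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix must have a zero diagonal")
        if (m < 0).any():
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", m)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class OrdinationResult:
    """Principal-coordinates embedding.

    ``coordinates`` is samples x axes (axes ordered by non-increasing
    eigenvalue, positive eigenvalues only); ``eigenvalues`` keeps the full
    spectrum including any negative values for reporting;
    ``proportion_explained`` covers the retained (positive) axes.
    """

    sample_ids: tuple[str, ...]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    def coordinates_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(
            self.coordinates, index=list(self.sample_ids), columns=cols
        )


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int | None


def shannon_index(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i in nats.

    Proportions are counts over the sample total; zero-count taxa
    contribute nothing.
    """
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total == 0:
        raise EmptySampleError("Shannon index undefined for an all-zero vector")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def _rank_with_ties(pooled: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midranks of the pooled sample and the tie-group sizes."""
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled), dtype=float)
    sorted_vals = pooled[order]
    i = 0
    tie_sizes = []
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        tie_sizes.append(j - i + 1)
        i = j + 1
    return ranks, np.asarray(tie_sizes)


def _exact_rank_sum_p(w: float, n1: int, n2: int) -> float:
    """Two-sided exact p for the rank-sum W of the smaller-indexed group.

    Counts, by dynamic programming over subset rank sums, how many of the
    C(n1+n2, n1) equally likely rank assignments give a sum at least / at
    most as extreme as ``w``; two-sided p doubles the smaller tail.
    """
    n = n1 + n2
    max_sum = n1 * n - n1 * (n1 - 1) // 2
    # ways[k][s] = number of k-subsets of {1..n} with rank sum s
    ways = np.zeros((n1 + 1, max_sum + 1), dtype=object)
    ways[0][0] = 1
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            for s in range(max_sum, r - 1, -1):
                if ways[k - 1][s - r]:
                    ways[k][s] += ways[k - 1][s - r]
    dist = ways[n1]
    total = math.comb(n, n1)
    w_int = int(round(w))
    lower = sum(dist[: w_int + 1])
    upper = sum(dist[w_int:])
    return min(1.0, 2.0 * min(lower, upper) / total)


def rank_sum_test(group_a, group_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact by enumeration of the rank-sum distribution when both groups
    have <= 10 observations and no ties occur; otherwise the normal
    approximation with tie correction (no continuity correction).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank_sum_test requires non-empty groups")
    pooled = np.concatenate([a, b])
    ranks, tie_sizes = _rank_with_ties(pooled)
    w = float(ranks[: a.size].sum())
    n1, n2, n = a.size, b.size, a.size + b.size

    has_ties = (tie_sizes > 1).any()
    if n1 <= 10 and n2 <= 10 and not has_ties:
        return _exact_rank_sum_p(w, n1, n2)

    mean_w = n1 * (n + 1) / 2.0
    tie_term = ((tie_sizes**3 - tie_sizes).sum()) / (n * (n - 1))
    var_w = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_w == 0:
        return 1.0
    z = (w - mean_w) / math.sqrt(var_w)
    return float(math.erfc(abs(z) / math.sqrt(2.0)))


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity BC = sum|x_i - y_i| / sum(x_i + y_i)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = (x + y).sum()
    if denom == 0:
        raise EmptySampleError("Bray-Curtis undefined when both vectors are zero")
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(table: AsvCountTable) -> DistanceMatrix:
    """All-pairs Bray-Curtis distances between the table's samples."""
    m = table.counts.to_numpy(dtype=float)
    totals = m.sum(axis=0)
    if (totals == 0).any():
        bad = table.sample_ids[int(np.argmax(totals == 0))]
        raise EmptySampleError(f"all-zero sample column: {bad!r}")
    n = m.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(m[:, i : i + 1] - m[:, i + 1 :]).sum(axis=0)
        sums = totals[i] + totals[i + 1 :]
        d[i, i + 1 :] = diff / sums
    d = d + d.T
    return DistanceMatrix(tuple(table.sample_ids), d)


def pcoa(d: DistanceMatrix, eig_tol: float = 1e-10) -> OrdinationResult:
    """Principal coordinates analysis by Gower double-centering.

    B = -1/2 J D^2 J with J the centering matrix; coordinates are the
    eigenvectors of B scaled by the square root of their (positive)
    eigenvalues.  Negative eigenvalues -- expected for non-Euclidean
    dissimilarities such as Bray-Curtis -- are reported in ``eigenvalues``
    but excluded from coordinates and from the proportion-explained
    denominator.  Axis signs follow the convention that the largest-
    magnitude loading on each axis is positive.
    """
    n = d.n
    if n < 3:
        raise ValueError("PCoA requires at least 3 samples")
    d2 = d.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    positive = eigvals > eig_tol * max(abs(eigvals[0]), 1.0)
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    for k in range(coords.shape[1]):
        if coords[np.abs(coords[:, k]).argmax(), k] < 0:
            coords[:, k] *= -1
    pos_sum = eigvals[positive].sum()
    prop = eigvals[positive] / pos_sum if pos_sum > 0 else eigvals[positive]
    return OrdinationResult(
        sample_ids=d.sample_ids,
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


def _permanova_ss(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and group labels."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(
    d: DistanceMatrix,
    labels,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-factor permutational multivariate analysis of variance.

    Partitions the total sum of squared dissimilarities between and within
    the label groups; significance comes from unrestricted label
    permutations, p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations).
    """
    labels = np.asarray(labels)
    if labels.shape[0] != d.n:
        raise ValueError("labels must cover every sample")
    groups, counts = np.unique(labels, return_counts=True)
    a = len(groups)
    if a < 2:
        raise ValueError("PERMANOVA requires >= 2 groups")
    if (counts < 2).any():
        small = groups[counts < 2]
        raise ValueError(f"every group needs >= 2 members; too small: {small}")
    n = d.n
    d2 = d.values**2
    ss_total, ss_within = _permanova_ss(d2, labels)
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        warnings.warn(
            "SS_within = 0: groups are internally identical; reporting the "
            "smallest attainable p-value",
            RuntimeWarning,
            stacklevel=2,
        )
        return PermanovaResult(
            pseudo_f=float("inf"),
            r_squared=1.0 if ss_total > 0 else 0.0,
            p_value=1.0 / (1 + n_permutations),
            n_permutations=n_permutations,
            seed=seed,
        )
    f_obs = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    geq = 0
    labels_codes = np.searchsorted(groups, labels)
    # vectorized within-group sums over permutations: for indicator m of a
    # group, sum of within-group squared distances = (m^T D2 m) / 2
    perms = np.array(
        [rng.permutation(labels_codes) for _ in range(n_permutations)]
    )
    for g, n_g in zip(range(a), counts):
        mask = (perms == g).astype(float)  # (n_perm, n)
        quad = np.einsum("pi,ij,pj->p", mask, d2, mask) / 2.0
        if g == 0:
            ss_w_perm = quad / n_g
        else:
            ss_w_perm += quad / n_g
    ss_b_perm = ss_total - ss_w_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (ss_b_perm / (a - 1)) / (ss_w_perm / (n - a))
    f_perm = np.where(ss_w_perm <= 0, np.inf, f_perm)
    geq = int((f_perm >= f_obs - 1e-12).sum())
    p = (1 + geq) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r_squared=float(r2),
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )


def exhaustive_permanova_p(d: DistanceMatrix, labels) -> float:
    """Exact permutation p-value by enumerating all distinct label
    assignments (feasible for small two-group designs)."""
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) != 2:
        raise ValueError("exhaustive enumeration implemented for 2 groups")
    n = d.n
    a = 2
    d2 = d.values**2
    ss_total, ss_within = _permanova_ss(d2, labels)
    f_obs = ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))
    n_g0 = counts[0]
    geq = total = 0
    for idx in combinations(range(n), n_g0):
        perm = np.full(n, groups[1], dtype=labels.dtype)
        perm[list(idx)] = groups[0]
        _, ss_w = _permanova_ss(d2, perm)
        f = ((ss_total - ss_w) / (a - 1)) / (ss_w / (n - a)) if ss_w > 0 else np.inf
        total += 1
        if f >= f_obs - 1e-12:
            geq += 1
    return geq / total


def alpha_table(
    dataset: CohortDataset, grouping: str = "sex", paired: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-specimen richness and Shannon diversity with group comparisons.

    Parameters
    ----------
    dataset
        Cohort to summarize; controls are excluded.
    grouping
        Metadata field to group by (``sex``, ``timepoint``, ``couple_id``
        or ``participant_id``).
    paired
        Reserved switch for couple-paired comparisons; the default
        (unpaired rank-sum) matches a two-group Wilcoxon comparison.

    Returns
    -------
    (alpha, comparisons)
        ``alpha``: one row per specimen with richness, Shannon and group
        label.  ``comparisons``: one row per unordered pair of group
        levels with the two-sided rank-sum p-value (empty with one level).
    """
    valid = {"sex", "timepoint", "couple_id", "participant_id"}
    if grouping not in valid:
        raise KeyError(f"unknown grouping field {grouping!r}; one of {valid}")
    if paired:
        raise NotImplementedError("paired comparisons are not implemented")
    rows = []
    for r in dataset.specimen_records:
        col = dataset.counts.sample(r.sample_id)
        rows.append(
            {
                "sample_id": r.sample_id,
                "group": getattr(r, grouping),
                "richness": int((col > 0).sum()),
                "shannon": shannon_index(col.to_numpy()),
            }
        )
    alpha = pd.DataFrame(rows).set_index("sample_id")
    comps = []
    levels = sorted(alpha["group"].unique())
    for g1, g2 in combinations(levels, 2):
        comps.append(
            {
                "group_a": g1,
                "group_b": g2,
                "metric": "shannon",
                "p_value": rank_sum_test(
                    alpha.loc[alpha["group"] == g1, "shannon"],
                    alpha.loc[alpha["group"] == g2, "shannon"],
                ),
            }
        )
    comparisons = pd.DataFrame(
        comps, columns=["group_a", "group_b", "metric", "p_value"]
    )
    return alpha, comparisons
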