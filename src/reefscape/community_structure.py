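"""Community composition by reef morphology.

Works on a replicate x family abundance matrix (square-root transformed for
distance-based analyses).  Provides Bray-Curtis dissimilarities, a
permutational MANOVA (pseudo-F with significance from label permutations),
nonmetric multidimensional scaling (SMACOF with isotonic regression,
minimizing Kruskal stress-1, with Shepard diagnostics), an indicator-value
analysis over morphology groups and their combinations, and one-way ANOVA
with post-hoc pairwise t-tests for univariate metrics.

All permutation P-values use the (1 + count) / (1 + n_perm) convention;
designs small enough can be enumerated exhaustively instead.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# dissimilarity

def bray_curtis(matrix) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y).

    Rows are samples, columns taxa; values must be non-negative and no row may
    be entirely zero (the dissimilarity is undefined for empty samples).
    """
    X = np.asarray(matrix, dtype=float)
    if np.any(X < 0):
        raise ValueError("abundances must be non-negative")
    zero_rows = np.flatnonzero(X.sum(axis=1) == 0)
    if len(zero_rows):
        raise ValueError(f"all-zero sample row(s) {zero_rows.tolist()}")
    return squareform(pdist(X, metric="braycurtis"))


# ---------------------------------------------------------------------------
# PERMANOVA

@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    df_between: int
    df_within: int
    n_permutations: int
    exhaustive: bool


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Pseudo-F from squared dissimilarities and integer group codes."""
    n = len(codes)
    ss_total = d2.sum() / (2.0 * n)          # sum over i<j of d^2 / N
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ss_between = ss_total - ss_within
    a = n_groups
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def _distinct_relabelings(codes: np.ndarray):
    """All distinct arrangements of a label multiset (identity included)."""
    seen = set()
    for perm in itertools.permutations(codes.tolist()):
        if perm not in seen:
            seen.add(perm)
            yield np.asarray(perm)


def n_distinct_relabelings(groups) -> int:
    _, counts = np.unique(np.asarray(groups), return_counts=True)
    return math.factorial(int(counts.sum())) // math.prod(
        math.factorial(int(c)) for c in counts)


def permanova(D: np.ndarray, groups, n_perm: int = 1000,
              seed: int | None = None, exhaustive: bool = False) -> PermanovaResult:
    """One-way permutational MANOVA on a dissimilarity matrix.

    pseudo-F = (SS_between/(a-1)) / (SS_within/(N-a)) with sums of squared
    dissimilarities; P from free relabeling of samples.  With
    ``exhaustive=True`` every distinct relabeling is enumerated and
    P = #{F_perm >= F_obs} / n_relabelings (identity included).
    """
    D = np.asarray(D, dtype=float)
    groups = np.asarray(groups)
    labels, codes = np.unique(groups, return_inverse=True)
    a = len(labels)
    if a < 2:
        raise ValueError("need at least 2 groups")
    _, counts = np.unique(codes, return_counts=True)
    if np.any(counts < 2):
        raise ValueError("every group needs at least 2 samples")
    d2 = D * D
    f_obs = _pseudo_f(d2, codes, a)
    if exhaustive:
        count = total = 0
        for perm in _distinct_relabelings(codes):
            total += 1
            if _pseudo_f(d2, perm, a) >= f_obs - 1e-12:
                count += 1
        return PermanovaResult(pseudo_f=f_obs, p_value=count / total,
                               df_between=a - 1, df_within=len(codes) - a,
                               n_permutations=total, exhaustive=True)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _pseudo_f(d2, rng.permutation(codes), a) >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(pseudo_f=f_obs, p_value=p, df_between=a - 1,
                           df_within=len(codes) - a, n_permutations=n_perm,
                           exhaustive=False)


# ---------------------------------------------------------------------------
# nMDS

@dataclass
class OrdinationResult:
    coordinates: np.ndarray     # (n, k), centered at the origin
    stress: float               # Kruskal stress-1
    shepard: pd.DataFrame       # dissimilarity, ordination distance, disparity
    k: int
    n_restarts: int


def _kruskal_stress1(dhat: np.ndarray, disp: np.ndarray) -> float:
    return float(np.sqrt(np.sum((dhat - disp) ** 2) / np.sum(dhat ** 2)))


def _smacof_single(Dvec: np.ndarray, X0: np.ndarray, max_iter: int,
                   tol: float) -> tuple[np.ndarray, float]:
    n = X0.shape[0]
    X = X0 - X0.mean(axis=0)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    order = np.argsort(Dvec, kind="stable")
    last = np.inf
    for _ in range(max_iter):
        dhat = pdist(X)
        # monotone regression of configuration distances on dissimilarity rank
        disp = np.empty_like(dhat)
        disp[order] = iso.fit_transform(np.arange(len(Dvec)), dhat[order])
        stress = _kruskal_stress1(dhat, disp)
        if last - stress < tol:
            last = stress
            break
        last = stress
        # Guttman transform toward the disparities
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dhat > 0, disp / dhat, 0.0)
        B = -squareform(ratio)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = (B @ X) / n
        X -= X.mean(axis=0)
    return X, last


def nmds(D: np.ndarray, k: int = 2, n_restarts: int = 20, max_iter: int = 300,
         seed: int | None = None, tol: float = 1e-7) -> OrdinationResult:
    """Nonmetric MDS minimizing Kruskal stress-1 over rank-ordered distances.

    Runs SMACOF with isotonic (monotone) regression from ``n_restarts`` random
    starts plus a classical-scaling start, returning the best configuration
    with its Shepard (dissimilarity vs ordination distance) pairs.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValueError("D must be a symmetric dissimilarity matrix")
    Dvec = squareform(D, checks=False)
    rng = np.random.default_rng(seed)

    # classical-scaling (PCoA) start
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:k]
    pcoa = V[:, idx] * np.sqrt(np.clip(w[idx], 0, None))

    best_X, best_stress = None, np.inf
    starts = [pcoa] + [rng.normal(size=(n, k)) for _ in range(n_restarts)]
    for X0 in starts:
        X, s = _smacof_single(Dvec, X0, max_iter, tol)
        if s < best_stress:
            best_X, best_stress = X, s
    if best_X is None or not np.isfinite(best_stress):
        raise RuntimeError(f"nMDS failed to converge; best stress {best_stress}")
    dhat = pdist(best_X)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    order = np.argsort(Dvec, kind="stable")
    disp = np.empty_like(dhat)
    disp[order] = iso.fit_transform(np.arange(len(Dvec)), dhat[order])
    shepard = pd.DataFrame({"dissimilarity": Dvec, "distance": dhat,
                            "disparity": disp}).sort_values("dissimilarity")
    return OrdinationResult(coordinates=best_X - best_X.mean(axis=0),
                            stress=best_stress, shepard=shepard, k=k,
                            n_restarts=n_restarts)


# ---------------------------------------------------------------------------
# indicator-value analysis

def _indval_stat(X: np.ndarray, codes: np.ndarray, n_groups: int,
                 combos: list[tuple[int, ...]]) -> np.ndarray:
    """sqrt(A * B) per taxon x group combination, group-size corrected.

    A (specificity) uses per-group MEAN abundance so unequal group sizes do
    not bias the statistic; for a combination c, A = sum of the member-group
    means over the sum across all groups.  B (fidelity) is the occurrence
    frequency within the combination's samples.
    """
    n, p = X.shape
    group_means = np.stack([X[codes == g].mean(axis=0) for g in range(n_groups)])
    present = X > 0
    total_mean = group_means.sum(axis=0)
    out = np.zeros((len(combos), p))
    for ci, combo in enumerate(combos):
        in_combo = np.isin(codes, combo)
        with np.errstate(invalid="ignore", divide="ignore"):
            A = np.where(total_mean > 0,
                         group_means[list(combo)].sum(axis=0) / total_mean, 0.0)
        B = present[in_combo].mean(axis=0)
        out[ci] = np.sqrt(A * B)
    return out


def indicator_analysis(matrix: pd.DataFrame, groups, n_perm: int = 999,
                       seed: int | None = None, max_combo_size: int | None = None,
                       exhaustive: bool = False) -> pd.DataFrame:
    """Indicator-value analysis of taxa for groups and group combinations.

    For each taxon and each combination of morphology groups (singletons up to
    ``max_combo_size``, default all proper subsets — so e.g. an "artificial
    reefs regardless of topography" indicator is the concrete+ship
    combination), the statistic sqrt(A x B) combines group-size-corrected
    abundance specificity A and occurrence fidelity B.  Significance is by
    permutation of sample labels (or exhaustive enumeration).

    Taxa absent everywhere are excluded with a warning.  Returns a tidy frame
    (taxon, group combination, stat, p, best-combination flag) using
    untransformed abundances.
    """
    X = np.asarray(matrix, dtype=float)
    taxa = list(matrix.columns) if isinstance(matrix, pd.DataFrame) else [
        f"taxon_{j}" for j in range(X.shape[1])]
    groups = np.asarray(groups)
    labels, codes = np.unique(groups, return_inverse=True)
    a = len(labels)
    if a < 2:
        raise ValueError("need at least 2 groups")
    absent = np.flatnonzero(X.sum(axis=0) == 0)
    if len(absent):
        warnings.warn(f"excluding taxa absent everywhere: "
                      f"{[taxa[j] for j in absent]}", stacklevel=2)
        keep = np.setdiff1d(np.arange(X.shape[1]), absent)
        X, taxa = X[:, keep], [taxa[j] for j in keep]
    max_size = max_combo_size if max_combo_size is not None else a - 1
    combos = [c for r in range(1, max_size + 1)
              for c in itertools.combinations(range(a), r)]
    obs = _indval_stat(X, codes, a, combos)

    if exhaustive:
        count = np.zeros_like(obs)
        total = 0
        for perm in _distinct_relabelings(codes):
            total += 1
            count += _indval_stat(X, perm, a, combos) >= obs - 1e-12
        pmat = count / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros_like(obs)
        for _ in range(n_perm):
            count += _indval_stat(X, rng.permutation(codes), a, combos) >= obs - 1e-12
        pmat = (1 + count) / (1 + n_perm)
        n_used = n_perm
    rows = []
    best_ci = obs.argmax(axis=0)
    for ci, combo in enumerate(combos):
        name = "+".join(str(labels[g]) for g in combo)
        for j, taxon in enumerate(taxa):
            rows.append({"taxon": taxon, "group": name, "stat": obs[ci, j],
                         "p": pmat[ci, j], "best": ci == best_ci[j],
                         "n_permutations": n_used})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# univariate ANOVA by morphology

@dataclass
class AnovaResult:
    f: float
    df: tuple[int, int]
    p_value: float
    posthoc: pd.DataFrame
    transform: str


def morphology_anova(values, groups, transform: str = "log",
                     adjust: str = "holm") -> AnovaResult:
    """One-way ANOVA of a community metric across reef morphologies.

    Abundance and biomass are log transformed to meet homogeneity-of-variance
    assumptions (log(x+1) fallback with a warning when zeros are present);
    richness is analysed untransformed.  Post-hoc: pairwise pooled-variance
    t-tests with Holm adjustment (``adjust='none'`` to disable).
    """
    y = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if transform not in ("log", "none"):
        raise ValueError("transform must be 'log' or 'none'")
    if transform == "log":
        if np.any(y <= 0):
            warnings.warn("zeros under log transform; using log(x+1)", stacklevel=2)
            y = np.log1p(y)
        else:
            y = np.log(y)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [y[groups == lab] for lab in labels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least 2 samples")
    f, p = stats.f_oneway(*samples)
    df1 = len(labels) - 1
    df2 = len(y) - len(labels)
    pairs, raw_p, tvals = [], [], []
    for i, j in itertools.combinations(range(len(labels)), 2):
        t, pt = stats.ttest_ind(samples[i], samples[j], equal_var=True)
        pairs.append((labels[i], labels[j]))
        tvals.append(t)
        raw_p.append(pt)
    if adjust == "holm":
        adj = multipletests(raw_p, method="holm")[1]
    elif adjust == "none":
        adj = np.asarray(raw_p)
    else:
        raise ValueError("adjust must be 'holm' or 'none'")
    posthoc = pd.DataFrame({
        "group_a": [p[0] for p in pairs], "group_b": [p[1] for p in pairs],
        "t": tvals, "p_raw": raw_p, "p_adj": adj,
    })
    return AnovaResult(f=float(f), df=(df1, df2), p_value=float(p),
                       posthoc=posthoc, transform=transform)
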