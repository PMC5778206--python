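"""Statistical layer: Duncan multiple-range grouping, correlation-matrix
PCA, and the visible-vs-chemical fat regression.

Duncan's multiple range test compares each pair of (sorted) group means
against a range-dependent critical value

    R_r = q(1 - (1-alpha)^(r-1); r, df) * sqrt(MS_within / n_h)

where ``r`` is the number of means spanned, ``q`` the studentized-range
quantile and ``n_h`` the harmonic mean group size.  Testing proceeds from
the widest range inward; any range found non-significant shields all the
ranges nested inside it.  The whole procedure is protected by the
omnibus one-way ANOVA: when F fails to reject at ``alpha``, every group
shares one letter, which keeps the familywise false-separation rate of
the letters near the nominal level.  Results are reported as the usual
compact letter display (groups sharing any letter are not separable).
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupingResult:
    sample_ids: tuple[str, ...]
    group_letters: tuple[str, ...]  # aligned with sample_ids
    means: tuple[float, ...]
    alpha: float
    f_statistic: float
    p_value: float

    def letters(self) -> dict[str, str]:
        return dict(zip(self.sample_ids, self.group_letters))

    def share_letter(self, a: str, b: str) -> bool:
        la = self.group_letters[self.sample_ids.index(a)]
        lb = self.group_letters[self.sample_ids.index(b)]
        return bool(set(la) & set(lb))


@dataclass(frozen=True)
class PCAResult:
    variable_names: tuple[str, ...]
    loadings: np.ndarray  # variables x components, orthonormal columns
    scores: np.ndarray  # samples x components
    eigenvalues: np.ndarray  # of the correlation matrix, non-increasing
    explained_variance_pct: np.ndarray


@dataclass(frozen=True)
class CorrelationResult:
    slope: float
    intercept: float
    r2: float
    n_points: int


@lru_cache(maxsize=4096)
def _range_quantile(alpha: float, r: int, df: int) -> float:
    # studentized-range quantile at Duncan's per-range level 1-(1-alpha)^(r-1);
    # cached because ppf is expensive and (alpha, r, df) recur across calls
    return float(sps.studentized_range.ppf((1 - alpha) ** (r - 1), r, df))


def _letter(i: int) -> str:
    letters = string.ascii_lowercase
    if i < len(letters):
        return letters[i]
    return letters[i // len(letters) - 1] + letters[i % len(letters)]


def anova_duncan(values: Mapping[str, Sequence[float]], alpha: float = 0.05) -> GroupingResult:
    """One-way ANOVA followed by Duncan's multiple range letter display.

    Parameters
    ----------
    values : mapping of group id -> replicate values (each group >= 2).
    alpha : significance level of both the omnibus test and the ranges.

    Groups with identical letters (sharing at least one character) are
    not significantly separated; letters are assigned sweeping the means
    in ascending order.  Zero within-group variance degenerates to exact
    comparison of the means.
    """
    ids = tuple(values.keys())
    groups = [np.asarray(values[g], dtype=float) for g in ids]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for gid, g in zip(ids, groups):
        if len(g) < 2:
            raise ValueError(f"group {gid!r} has fewer than 2 replicates")
    means = np.array([g.mean() for g in groups])
    sizes = np.array([len(g) for g in groups])
    k, n_total = len(groups), int(sizes.sum())
    df_within = n_total - k
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    mse = ss_within / df_within
    if mse > 0:
        f_stat, p_val = sps.f_oneway(*groups)
        f_stat, p_val = float(f_stat), float(p_val)
    else:
        distinct = len(np.unique(means)) > 1
        f_stat, p_val = (np.inf, 0.0) if distinct else (0.0, 1.0)

    order = np.argsort(means, kind="stable")
    sorted_means = means[order]
    nonsig = np.zeros((k, k), dtype=bool)  # over sorted indices, i < j

    if mse == 0.0:
        for i in range(k):
            for j in range(i + 1, k):
                nonsig[i, j] = sorted_means[j] == sorted_means[i]
    elif p_val > alpha:
        nonsig[np.triu_indices(k, 1)] = True  # omnibus not significant: no separation claimed
    else:
        n_h = k / np.sum(1.0 / sizes)  # harmonic mean size for unequal n
        crit = {
            r: _range_quantile(alpha, r, df_within) * np.sqrt(mse / n_h)
            for r in range(2, k + 1)
        }
        seen: set[tuple[int, int]] = set()

        def sweep(i: int, j: int) -> None:
            if j <= i or (i, j) in seen:
                return
            seen.add((i, j))
            if sorted_means[j] - sorted_means[i] <= crit[j - i + 1]:
                # a non-significant range shields everything nested in it
                for a in range(i, j + 1):
                    for b in range(a + 1, j + 1):
                        nonsig[a, b] = True
            else:
                sweep(i, j - 1)
                sweep(i + 1, j)

        sweep(0, k - 1)

    # Maximal intervals of mutually non-separated sorted means -> letters.
    intervals: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and all(nonsig[a, j + 1] for a in range(i, j + 1)):
            j += 1
        intervals.append((i, j))
    maximal = [iv for iv in intervals if not any(o[0] <= iv[0] and iv[1] <= o[1] and o != iv for o in intervals)]
    maximal = sorted(set(maximal))
    letters_sorted = ["" for _ in range(k)]
    for li, (a, b) in enumerate(maximal):
        for i in range(a, b + 1):
            letters_sorted[i] += _letter(li)
    group_letters = [""] * k
    for pos, orig in enumerate(order):
        group_letters[orig] = letters_sorted[pos]
    return GroupingResult(
        sample_ids=ids,
        group_letters=tuple(group_letters),
        means=tuple(float(m) for m in means),
        alpha=alpha,
        f_statistic=f_stat,
        p_value=p_val,
    )


def pca_correlation(table: pd.DataFrame) -> PCAResult:
    """PCA on the correlation matrix of a samples x variables table.

    Variables are standardized to zero mean and unit (n-1) variance, so
    each contributes equally regardless of its units; the eigenvalues of
    the correlation matrix give the percentage of variance explained by
    each component (they sum to the number of variables).
    """
    table = pd.DataFrame(table)
    if table.shape[0] < 3:
        raise ValueError("PCA needs at least 3 samples")
    if table.shape[1] < 2:
        raise ValueError("PCA needs at least 2 variables")
    X = table.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("PCA input contains missing values")
    sd = X.std(axis=0, ddof=1)
    for name, s in zip(table.columns, sd):
        if s == 0:
            raise ValueError(f"variable {name!r} is constant; correlation undefined")
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (X.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    loadings = eigvecs[:, order]
    # deterministic sign: the largest-magnitude loading of each component is positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = Z @ loadings
    explained = eigvals / eigvals.sum() * 100.0
    return PCAResult(
        variable_names=tuple(str(c) for c in table.columns),
        loadings=loadings,
        scores=scores,
        eigenvalues=eigvals,
        explained_variance_pct=explained,
    )


def correlate_vfc_chemical(vfc: Sequence[float], chemical: Sequence[float]) -> CorrelationResult:
    """Ordinary least-squares line (chemical ~ vfc) and its R^2.

    Both inputs are per-sample fat percentages; R^2 = 1 - SS_res/SS_tot
    measures how well image-derived visible fat predicts chemically
    extracted fat.
    """
    x = np.asarray(vfc, dtype=float)
    y = np.asarray(chemical, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("visible fat values are constant; fit undefined")
    fit = sps.linregress(x, y)
    return CorrelationResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue ** 2),
        n_points=int(x.size),
    )
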