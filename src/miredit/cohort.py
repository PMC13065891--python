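"""Cohort-level editing-profile analysis.

Builds the sites x samples editing-level matrix, imputes missing values with
per-condition regression trees, selects sites whose healthy-vs-cancer
comparison reaches p < 0.1, runs PCA on the imputed levels of the selected
sites, and compares editing levels between condition pairs with a two-sided
Wilcoxon rank-sum test (exact enumeration for small groups, tie-aware
normal approximation otherwise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.tree import DecisionTreeRegressor

logger = logging.getLogger(__name__)

SELECTION_P = 0.1
EXACT_MAX_N = 10


@dataclass
class EditingMatrix:
    """Editing levels (sites x samples, NaN = missing) plus condition labels."""

    levels: pd.DataFrame
    conditions: pd.Series

    def __post_init__(self) -> None:
        self.conditions = pd.Series(self.conditions)
        if self.levels.index.has_duplicates or self.levels.columns.has_duplicates:
            raise ValueError("site and sample ids must be unique")
        missing = [s for s in self.levels.columns if s not in self.conditions.index]
        if missing:
            raise ValueError(f"samples without condition labels: {missing}")
        vals = self.levels.to_numpy(dtype=float)
        observed = vals[~np.isnan(vals)]
        if observed.size and (observed.min() < 0 or observed.max() > 1):
            raise ValueError("editing levels must lie in [0, 1]")

    @property
    def sites(self) -> list[str]:
        return list(self.levels.index)

    @property
    def samples(self) -> list[str]:
        return list(self.levels.columns)

    def condition_samples(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.conditions[s] == condition]

    def copy(self) -> "EditingMatrix":
        return EditingMatrix(levels=self.levels.copy(), conditions=self.conditions.copy())


@dataclass(frozen=True)
class GroupComparison:
    site_id: str
    condition_a: str
    condition_b: str
    p_value: float
    direction: str  # "up" | "down": condition_b relative to condition_a
    significance_tier: str  # "none" | "*" | "**"


def matrix_from_calls(calls, conditions: Mapping[str, str]) -> EditingMatrix:
    """Assemble an EditingMatrix from per-sample editing calls."""
    rows = [(c.site_id, c.sample_id, c.level) for c in calls]
    df = pd.DataFrame(rows, columns=["site_id", "sample_id", "level"])
    levels = df.pivot_table(index="site_id", columns="sample_id", values="level")
    levels = levels.sort_index().sort_index(axis=1)
    return EditingMatrix(levels=levels, conditions=pd.Series(dict(conditions)))


def impute_missing(m: EditingMatrix, seed: int) -> EditingMatrix:
    """Impute missing levels with per-condition decision-tree regression.

    Within each condition, each site with missing values is predicted from
    the other sites' levels (predictor gaps mean-filled within condition)
    using a DecisionTreeRegressor with default parameters, trained on the
    condition's samples where the target site is observed. Sites missing in
    every sample of a condition fall back to the global site mean. Imputed
    values are clipped to [0, 1]; observed cells are never altered.
    """
    out = m.levels.copy()
    global_means = m.levels.mean(axis=1)
    for condition in sorted(m.conditions.unique()):
        samples = m.condition_samples(condition)
        if len(samples) < 2:
            logger.warning("condition %r has < 2 samples: skipped in imputation", condition)
            continue
        block = m.levels[samples]
        for site in m.sites:
            target = block.loc[site]
            missing_samples = target[target.isna()].index
            if len(missing_samples) == 0:
                continue
            observed_samples = target[target.notna()].index
            if len(observed_samples) == 0:
                fallback = global_means[site]
                if np.isnan(fallback):
                    logger.warning("site %r missing in every sample: imputed 0.0", site)
                    fallback = 0.0
                else:
                    logger.warning(
                        "site %r missing in all of condition %r: global mean used",
                        site,
                        condition,
                    )
                out.loc[site, missing_samples] = np.clip(fallback, 0.0, 1.0)
                continue
            predictors = block.drop(index=site)
            if predictors.empty:
                out.loc[site, missing_samples] = np.clip(
                    float(target[observed_samples].mean()), 0.0, 1.0
                )
                continue
            filled = predictors.apply(
                lambda row: row.fillna(0.0 if np.isnan(row.mean()) else row.mean()), axis=1
            )
            x_train = filled[observed_samples].to_numpy().T
            y_train = target[observed_samples].to_numpy(dtype=float)
            x_pred = filled[missing_samples].to_numpy().T
            tree = DecisionTreeRegressor(random_state=seed)
            tree.fit(x_train, y_train)
            out.loc[site, missing_samples] = np.clip(tree.predict(x_pred), 0.0, 1.0)
    return EditingMatrix(levels=out, conditions=m.conditions.copy())


def rank_sum_test(x: Iterable[float], y: Iterable[float], *, exact_max_n: int = EXACT_MAX_N) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration of the permutation null of the (midrank) rank-sum
    statistic when both groups have at most ``exact_max_n`` observations;
    tie-corrected normal approximation otherwise. Degenerate comparisons
    (all values identical) return p = 1.0.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return 1.0
    ranks = rankdata(combined)
    n1, n = x.size, combined.size
    mu = n1 * (n + 1) / 2.0
    obs = float(ranks[:n1].sum())
    dev = abs(obs - mu)
    if n1 <= exact_max_n and (n - n1) <= exact_max_n:
        count = 0
        for idx in combinations(range(n), n1):
            if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9:
                count += 1
        return count / comb(n, n1)
    n2 = n - n1
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = dev / sqrt(var)
    return float(max(0.0, min(1.0, 2.0 * (1.0 - 0.5 * (1.0 + erf(z / sqrt(2.0)))))))


def select_sites(
    m: EditingMatrix, healthy_label: str, *, p_threshold: float = SELECTION_P
) -> list[str]:
    """Sites whose healthy-vs-any-other-condition comparison reaches p < 0.1.

    Tests use raw (non-imputed) levels, unadjusted, per site and condition;
    conditions with fewer than 2 non-missing samples for a site are skipped.
    No missingness-based exclusion is applied.
    """
    if healthy_label not in set(m.conditions):
        raise ValueError(f"healthy condition {healthy_label!r} not present")
    healthy_samples = m.condition_samples(healthy_label)
    other_conditions = sorted(set(m.conditions.unique()) - {healthy_label})
    selected: list[str] = []
    for site in m.sites:
        row = m.levels.loc[site]
        hx = row[healthy_samples].dropna().to_numpy()
        if hx.size < 2:
            continue
        best = np.inf
        for condition in other_conditions:
            cx = row[m.condition_samples(condition)].dropna().to_numpy()
            if cx.size < 2:
                logger.warning(
                    "site %r, condition %r: < 2 non-missing samples, skipped", site, condition
                )
                continue
            best = min(best, rank_sum_test(hx, cx))
        if best < p_threshold:
            selected.append(site)
    return selected


def run_pca(
    m: EditingMatrix,
    selected_sites: Iterable[str] | None = None,
    *,
    n_components: int | None = None,
    scale: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of samples in editing-level space (matrix must be imputed).

    Columns (sites) are centered; optional unit-variance scaling. Sign
    convention: the largest-magnitude loading of each component is positive.
    Returns (scores: samples x PCs, loadings: sites x PCs, explained-variance
    fractions).
    """
    sites = list(selected_sites) if selected_sites is not None else m.sites
    if len(sites) < 2:
        raise ValueError("PCA requires at least 2 sites")
    data = m.levels.loc[sites].to_numpy(dtype=float).T  # samples x sites
    if data.shape[0] < 3:
        raise ValueError("PCA requires at least 3 samples")
    if np.isnan(data).any():
        raise ValueError("matrix contains missing values: impute first")
    centered = data - data.mean(axis=0)
    if scale:
        sd = data.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        centered = centered / sd
    if np.allclose(centered, 0):
        raise ValueError("matrix has zero variance")
    n_comp = n_components or min(centered.shape[0] - 1, centered.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(centered)
    loadings = pca.components_.T  # sites x PCs
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    pc_names = [f"PC{i + 1}" for i in range(n_comp)]
    return (
        pd.DataFrame(scores, index=m.samples, columns=pc_names),
        pd.DataFrame(loadings, index=sites, columns=pc_names),
        pca.explained_variance_ratio_.copy(),
    )


def compare_groups(
    m: EditingMatrix, site: str, cond_a: str, cond_b: str
) -> GroupComparison:
    """Two-sided rank-sum comparison of one site between two conditions.

    Uses raw (non-imputed) levels; direction is that of condition_b relative
    to condition_a by median difference (mean difference when medians tie).
    Tiers: ** for p < 0.01, * for p < 0.05, none otherwise.
    """
    row = m.levels.loc[site]
    a = row[m.condition_samples(cond_a)].dropna().to_numpy()
    b = row[m.condition_samples(cond_b)].dropna().to_numpy()
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"site {site!r}: need >= 2 non-missing samples per group "
            f"({cond_a}: {a.size}, {cond_b}: {b.size})"
        )
    p = rank_sum_test(a, b)
    diff = float(np.median(b) - np.median(a))
    if diff == 0.0:
        diff = float(np.mean(b) - np.mean(a))
    direction = "up" if diff > 0 else "down"
    tier = "**" if p < 0.01 else "*" if p < 0.05 else "none"
    return GroupComparison(
        site_id=site,
        condition_a=cond_a,
        condition_b=cond_b,
        p_value=p,
        direction=direction,
        significance_tier=tier,
    )
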