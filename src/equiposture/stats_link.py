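"""Statistical linkage of shape scores to welfare indicators.

The central test is a mixed-model ANOVA: per-photo principal-component
scores regressed on a horse-level factor with a per-horse random
intercept (photographs of the same individual are repeated measures).
The fixed factor is tested with a Wald F whose denominator degrees of
freedom follow the containment rule for between-subject factors,
``df_den = n_individuals - n_levels``.

Also provided, behind one module surface: Kruskal-Wallis for a
quantitative-vs-qualitative association, a Pearson correlation test, and
the chi-square test with a fixed-margins Monte Carlo option for sparse
tables. The study-wide significance level is 5%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


class SpecificationError(ValueError):
    """Raised when the data violate the model's design assumptions."""


@dataclass
class AnovaResult:
    factor: str
    component: int
    F: float
    p: float
    df_num: int
    df_den: int
    n_individuals: int
    n_photos: int

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def mixed_anova_pc(
    scores: np.ndarray,
    factor: np.ndarray,
    individual: np.ndarray,
    factor_name: str = "factor",
    component: int = 0,
) -> AnovaResult:
    """Random-intercept mixed-model ANOVA of per-photo scores on a
    horse-level factor.

    The model ``score = fixed factor effect + individual effect +
    residual`` is fit by restricted maximum likelihood; the factor is
    tested with a Wald F on its coefficients, with denominator df
    ``n_individuals - n_levels`` and numerator df ``n_levels - 1``.
    A quantitative factor (many numeric values) is treated as a single
    continuous fixed effect with ``df_num = 1`` and
    ``df_den = n_individuals - 2``.

    Raises :class:`SpecificationError` when the factor varies within an
    individual; warns (and proceeds, df unchanged by the containment
    formula) when a level holds a single individual.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    scores = np.asarray(scores, dtype=float)
    factor = np.asarray(factor)
    individual = np.asarray(individual)
    if not (len(scores) == len(factor) == len(individual)):
        raise ValueError("scores, factor and individual must have equal length")

    df = pd.DataFrame({"y": scores, "f": factor, "ind": individual})
    per_ind = df.groupby("ind")["f"].nunique()
    varying = per_ind[per_ind > 1]
    if len(varying):
        raise SpecificationError(
            f"factor varies within individuals {list(varying.index)[:5]}"
        )
    n_ind = df["ind"].nunique()
    n_photos = len(df)

    continuous = np.issubdtype(factor.dtype, np.number) and len(np.unique(factor)) > 6
    if continuous:
        X = np.column_stack([np.ones(n_photos), df["f"].astype(float)])
        q = 1
        df_den = n_ind - 2
    else:
        levels = pd.unique(df["f"])
        if len(levels) < 2:
            raise SpecificationError("factor needs at least 2 levels")
        ind_level = df.groupby("ind")["f"].first()
        singletons = ind_level.value_counts()
        if (singletons < 2).any():
            warnings.warn(
                f"factor level(s) {list(singletons[singletons < 2].index)} hold a "
                "single individual; the F test is weakly identified",
                stacklevel=2,
            )
        dummies = pd.get_dummies(df["f"], drop_first=True, dtype=float)
        X = np.column_stack([np.ones(n_photos), dummies.to_numpy()])
        q = len(levels) - 1
        df_den = n_ind - len(levels)
    if df_den < 1:
        raise SpecificationError("not enough individuals for the denominator df")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(df["y"].to_numpy(), X, groups=df["ind"].to_numpy())
        fit = model.fit(reml=True)
    # Wald chi-square on the factor coefficients -> F with containment df
    beta = np.asarray(fit.fe_params)[1 : 1 + q]
    cov = np.asarray(fit.cov_params())[1 : 1 + q, 1 : 1 + q]
    chi2 = float(beta @ np.linalg.solve(cov, beta))
    F = chi2 / q
    p = float(stats.f.sf(F, q, df_den))
    return AnovaResult(factor_name, component, F, p, q, df_den, n_ind, n_photos)


@dataclass
class TestResult:
    statistic: float
    p: float
    df: int | None = None
    monte_carlo: bool = False
    degenerate: bool = False


def kruskal_wallis(*groups: np.ndarray) -> TestResult:
    """Rank-based Kruskal-Wallis H with tie correction, chi-square
    reference distribution. All-constant data (H undefined: the tie
    correction divides by zero) returns a flagged degenerate result."""
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if sum(len(a) for a in arrays) < 2 or any(len(a) == 0 for a in arrays):
        raise ValueError("each group must be non-empty with >= 2 total observations")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult(float("nan"), float("nan"), len(arrays) - 1, degenerate=True)
    h, p = stats.kruskal(*arrays)
    return TestResult(float(h), float(p), len(arrays) - 1)


def chi_square(
    table: np.ndarray,
    monte_carlo: bool = False,
    reps: int = 2000,
    seed: int | None = None,
) -> TestResult:
    """Pearson chi-square on a contingency table.

    With ``monte_carlo`` set and any observed or expected count below 5,
    the p-value is instead estimated from ``reps`` random tables drawn
    conditional on both margins (Patefield algorithm), as
    ``(1 + #{X2* >= X2}) / (reps + 1)``; reproducible under a fixed seed.
    """
    tab = np.asarray(table)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(tab < 0) or not np.allclose(tab, np.round(tab)):
        raise ValueError("counts must be non-negative integers")
    tab = np.round(tab).astype(int)
    row, col = tab.sum(axis=1), tab.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero row or column margin")
    res = stats.chi2_contingency(tab, correction=False)
    x2, df = float(res.statistic), int(res.dof)
    expected = res.expected_freq
    sparse = bool(np.any(expected < 5) or np.any(tab < 5))
    if monte_carlo and sparse:
        rng = np.random.default_rng(seed)
        sim = stats.random_table(row, col).rvs(reps, random_state=rng)
        with np.errstate(invalid="ignore"):
            x2_sim = np.sum((sim - expected) ** 2 / expected, axis=(1, 2))
        p = (1.0 + float(np.sum(x2_sim >= x2 - 1e-12))) / (reps + 1.0)
        return TestResult(x2, p, df, monte_carlo=True)
    return TestResult(x2, float(res.pvalue), df)


def pearson_cor(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Pearson product-moment correlation with its t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples of at least 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return TestResult(float(r), float(p))


def holm_adjust(pvalues: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional; the default reporting
    follows the per-test 5% level without multiplicity correction)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()
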