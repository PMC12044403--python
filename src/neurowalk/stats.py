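"""The statistical layer of the factorial design.

Provides the Kolmogorov-Smirnov normality screen (with Monte-Carlo
Lilliefors correction, since the reference normal's parameters are
estimated from the sample), the 2 x 2 fully-within repeated-measures ANOVA
with partial eta squared, Bonferroni-corrected paired post hocs, and
Spearman rank correlations.

With both factors at two levels, each ANOVA effect is exactly the squared
paired t statistic of its within-subject contrast: the main effect of a
factor is the paired comparison of per-subject means across its levels,
and the interaction is the paired test on the double difference. This
closed form is algebraically identical to the classical sums-of-squares
decomposition (no sphericity issue arises with two levels), and every F
has (1, n - 1) degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "AnovaEffect",
    "AnovaResult",
    "PosthocResult",
    "ks_normality",
    "rm_anova_2x2",
    "partial_eta_squared",
    "bonferroni_pairwise",
    "spearman_correlation",
]

EFFECTS = ("condition", "task", "condition x task")


@dataclass
class AnovaEffect:
    """One tested effect of the factorial model."""

    name: str
    F: float
    df_num: int
    df_den: int
    p: float
    eta_p_sq: float


@dataclass
class AnovaResult:
    """The three effects of the 2 x 2 within-subject ANOVA."""

    effects: dict[str, AnovaEffect]
    n_subjects: int

    def __getitem__(self, name: str) -> AnovaEffect:
        return self.effects[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.name, e.F, e.df_num, e.df_den, e.p, e.eta_p_sq)
             for e in self.effects.values()],
            columns=["effect", "F", "df_num", "df_den", "p", "eta_p_sq"],
        )


@dataclass
class PosthocResult:
    """Pairwise contrasts with raw and Bonferroni-adjusted p values."""

    comparisons: pd.DataFrame  # columns: contrast, t, df, p_raw, p_adj
    m: int


def partial_eta_squared(F: float, df_num: int, df_den: int) -> float:
    """Partial eta squared from an F ratio:
    ``eta_p^2 = F * df_num / (F * df_num + df_den)``."""
    if F < 0:
        raise ValueError("F must be nonnegative")
    if df_num < 1 or df_den < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(F * df_num / (F * df_num + df_den))


def ks_normality(values, n_reps: int = 10_000, seed: int = 0
                 ) -> tuple[float, float]:
    """One-sample KS test against a normal fitted to the sample.

    The statistic is the two-sided sup-gap between the empirical CDF and
    the normal CDF with the sample's own mean and SD. Because the
    parameters are estimated, the classical KS p value is anti-conservative;
    the p value is therefore calibrated by Monte Carlo over ``n_reps``
    standard-normal samples of the same size (the Lilliefors construction),
    seeded for reproducibility.

    Returns (statistic, p).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance sample")

    def stat(sample_sorted: np.ndarray) -> np.ndarray:
        """Vectorized two-sided KS distance of standardized sorted rows."""
        m = sample_sorted.shape[-1]
        mu = sample_sorted.mean(axis=-1, keepdims=True)
        s = sample_sorted.std(axis=-1, ddof=1, keepdims=True)
        cdf = sps.norm.cdf((sample_sorted - mu) / s)
        grid = np.arange(1, m + 1) / m
        d_plus = (grid - cdf).max(axis=-1)
        d_minus = (cdf - (np.arange(m) / m)).max(axis=-1)
        return np.maximum(d_plus, d_minus)

    d_obs = float(stat(np.sort(x)))
    rng = np.random.default_rng(seed)
    sims = np.sort(rng.standard_normal((n_reps, n)), axis=-1)
    d_null = stat(sims)
    p = (1 + np.count_nonzero(d_null >= d_obs)) / (n_reps + 1)
    return d_obs, float(p)


def _cell_matrix(table: pd.DataFrame, dv: str = "value") -> tuple[np.ndarray, int]:
    """(n_subjects, 4) matrix of cell values in the fixed order
    (neutral, elevator), (neutral, plank), (negative, elevator),
    (negative, plank); raises naming the subject and cell on missing data."""
    cells = [("neutral", "elevator"), ("neutral", "plank"),
             ("negative", "elevator"), ("negative", "plank")]
    subjects = sorted(table["subject"].unique())
    M = np.empty((len(subjects), 4))
    grouped = table.set_index(["subject", "condition", "task"])[dv]
    for si, subj in enumerate(subjects):
        for ci, (cond, task) in enumerate(cells):
            try:
                v = grouped.loc[(subj, cond, task)]
            except KeyError:
                raise ValueError(
                    f"subject {subj!r} missing cell "
                    f"(condition={cond}, task={task})") from None
            if np.ndim(v) > 0:
                if len(v) != 1:
                    raise ValueError(
                        f"subject {subj!r} has {len(v)} rows for cell "
                        f"(condition={cond}, task={task}); expected 1")
                v = v.iloc[0]
            M[si, ci] = v
    return M, len(subjects)


def _paired_contrast_f(d: np.ndarray) -> tuple[float, float]:
    """F = t^2 and p of the one-sample t on contrast scores d."""
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        # zero error variance: degenerate input, reported as no evidence
        logger.warning("rm_anova_2x2: zero-variance contrast; F=0, p=1")
        return 0.0, 1.0
    t = d.mean() / (sd / np.sqrt(n))
    F = t * t
    p = float(sps.f.sf(F, 1, n - 1))
    return float(F), p


def rm_anova_2x2(table: pd.DataFrame, dv: str = "value") -> AnovaResult:
    """2 (condition) x 2 (task) fully-within repeated-measures ANOVA.

    ``table`` must hold one value per subject per cell in long format with
    columns subject, condition, task and the dependent variable ``dv``.
    Each effect is the squared paired t of its within-subject contrast,
    with (1, n - 1) degrees of freedom; partial eta squared follows as
    ``F / (F + df_den)``.
    """
    M, n = _cell_matrix(table, dv)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    # columns: 0=(neu,elev) 1=(neu,plank) 2=(neg,elev) 3=(neg,plank)
    contrasts = {
        "condition": (M[:, 2] + M[:, 3] - M[:, 0] - M[:, 1]) / 2.0,
        "task": (M[:, 1] + M[:, 3] - M[:, 0] - M[:, 2]) / 2.0,
        "condition x task": (M[:, 3] - M[:, 2]) - (M[:, 1] - M[:, 0]),
    }
    effects = {}
    for name, d in contrasts.items():
        F, p = _paired_contrast_f(d)
        effects[name] = AnovaEffect(
            name=name, F=F, df_num=1, df_den=n - 1, p=p,
            eta_p_sq=partial_eta_squared(F, 1, n - 1),
        )
    return AnovaResult(effects=effects, n_subjects=n)


def bonferroni_pairwise(table: pd.DataFrame, comparisons,
                        dv: str = "value") -> PosthocResult:
    """Paired t tests for explicitly enumerated cell contrasts, with
    Bonferroni adjustment ``p_adj = min(1, m * p)``.

    Each comparison is a pair of (condition, task) cells; values are paired
    within subject.
    """
    comparisons = list(comparisons)
    m = len(comparisons)
    M, _ = _cell_matrix(table, dv)
    order = {("neutral", "elevator"): 0, ("neutral", "plank"): 1,
             ("negative", "elevator"): 2, ("negative", "plank"): 3}
    rows = []
    for cell_a, cell_b in comparisons:
        a, b = M[:, order[tuple(cell_a)]], M[:, order[tuple(cell_b)]]
        d = a - b
        n = d.size
        sd = d.std(ddof=1)
        if sd == 0:
            t, p = 0.0, 1.0
        else:
            t = d.mean() / (sd / np.sqrt(n))
            p = float(2 * sps.t.sf(abs(t), n - 1))
        rows.append((f"{cell_a} vs {cell_b}", float(t), n - 1, p,
                     min(1.0, m * p)))
    return PosthocResult(
        comparisons=pd.DataFrame(
            rows, columns=["contrast", "t", "df", "p_raw", "p_adj"]),
        m=m,
    )


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank-order correlation: Pearson correlation of mid-ranks
    (ties get average ranks), p from the t approximation on n - 2 df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input has no rank correlation")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
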