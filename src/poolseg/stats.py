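"""Statistical readout: chi-square tests and the two-sample t-test.

The test statistics are computed from their defining formulas; tail
probabilities come from the regularized incomplete gamma function
(chi-square) and the t distribution. Conventions follow the usual
condensation-assay readout: chi-square on matched/total mass counts,
two-tailed t-test on per-field matched percentages, alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy import stats as sps

__all__ = [
    "TestResult",
    "chi_square_gof",
    "chi_square_independence",
    "t_two_sample",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    test_name: str
    statistic: float
    df: float
    p_value: float
    alpha: float = 0.05
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")
        if self.df <= 0:
            raise ValueError("df must be > 0")

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "significant": self.significant,
        }


def _chi2_sf(statistic: float, df: float) -> float:
    """Upper-tail chi-square probability via Q(df/2, x/2)."""
    return float(special.gammaincc(df / 2.0, statistic / 2.0))


def chi_square_gof(
    observed: "np.typing.ArrayLike",
    expected_proportions: "np.typing.ArrayLike",
    alpha: float = 0.05,
) -> TestResult:
    """Chi-square goodness of fit of counts against fixed proportions.

    ``statistic = sum (O - E)^2 / E`` with ``E = N * proportion`` and
    ``df = categories - 1``.
    """
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.ndim != 1 or obs.size < 2:
        raise ValueError("observed must be a 1-D array of >= 2 category counts")
    if props.shape != obs.shape:
        raise ValueError("expected_proportions must match observed in length")
    if not np.isclose(props.sum(), 1.0, atol=1e-8):
        raise ValueError("expected proportions must sum to 1")
    expected = obs.sum() * props
    if np.any(expected <= 0):
        raise ValueError("every expected count must be > 0")
    statistic = float(np.sum((obs - expected) ** 2 / expected))
    df = obs.size - 1
    return TestResult(
        test_name="chi_square_gof",
        statistic=statistic,
        df=float(df),
        p_value=_chi2_sf(statistic, df),
        alpha=alpha,
    )


def chi_square_independence(
    table: "np.typing.ArrayLike", alpha: float = 0.05
) -> TestResult:
    """Chi-square test of independence on an r x c count table.

    ``E_ij = row_i * col_j / N``, ``df = (r - 1)(c - 1)``; no continuity
    correction.
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or min(tab.shape) < 2:
        raise ValueError("table must be 2-D with at least 2 rows and 2 columns")
    rows, cols = tab.sum(axis=1), tab.sum(axis=0)
    if np.any(rows <= 0) or np.any(cols <= 0):
        raise ValueError("all row and column sums must be > 0")
    expected = np.outer(rows, cols) / tab.sum()
    statistic = float(np.sum((tab - expected) ** 2 / expected))
    df = (tab.shape[0] - 1) * (tab.shape[1] - 1)
    return TestResult(
        test_name="chi_square_independence",
        statistic=statistic,
        df=float(df),
        p_value=_chi2_sf(statistic, df),
        alpha=alpha,
    )


def t_two_sample(
    a: "np.typing.ArrayLike",
    b: "np.typing.ArrayLike",
    variant: str = "student",
    alpha: float = 0.05,
) -> TestResult:
    """Two-tailed two-sample t-test on per-field percentages.

    ``student`` pools the variance (df = n_a + n_b - 2); ``welch`` uses
    the Welch-Satterthwaite df. When both samples have zero variance the
    test degenerates: p = 1 for equal means, p = 0 (flagged) otherwise.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    na, nb = xa.size, xb.size
    ma, mb = xa.mean(), xb.mean()
    va, vb = xa.var(ddof=1), xb.var(ddof=1)

    if va == 0.0 and vb == 0.0:
        if ma == mb:
            return TestResult("t_two_sample", 0.0, float(na + nb - 2), 1.0,
                              alpha, degenerate=True)
        return TestResult("t_two_sample", float("inf"), float(na + nb - 2),
                          0.0, alpha, degenerate=True)

    if variant == "student":
        df = na + nb - 2
        pooled = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    else:
        se = np.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    statistic = float((ma - mb) / se)
    p = float(2.0 * sps.t.sf(abs(statistic), df))
    return TestResult("t_two_sample", statistic, float(df), min(p, 1.0), alpha)
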