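"""Paired-binary test statistics for test-phase responses.

The test phase yields, for each ant, a 0/1 MaLER response to each of the
four test odours: a subjects x conditions binary matrix. Differences across
odours within a training group are assessed with Cochran's Q; pairwise
follow-ups use McNemar's chi-square on the discordant pairs with sequential
(Holm) Bonferroni correction; between-group comparisons of a single odour
use Fisher's exact test.

Cochran's Q and McNemar are computed from their closed forms here;
Fisher's exact test and the Holm step-down delegate to scipy/statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairedBinaryMatrix",
    "CochranQResult",
    "McNemarResult",
    "cochran_q",
    "mcnemar",
    "holm_bonferroni",
    "fisher_exact",
    "pairwise_mcnemar",
]


@dataclass(frozen=True)
class PairedBinaryMatrix:
    """Subjects x conditions matrix of 0/1 responses, no missing cells.

    ``n_excluded`` records how many subjects were dropped upstream for
    incomplete test batteries (listwise exclusion).
    """

    data: np.ndarray
    condition_labels: tuple
    n_excluded: int = 0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=int)
        if data.ndim != 2:
            raise ValueError("data must be 2-D (subjects x conditions)")
        if not np.isin(data, (0, 1)).all():
            raise ValueError("all cells must be 0 or 1")
        if len(self.condition_labels) != data.shape[1]:
            raise ValueError("one label per condition column required")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "condition_labels", tuple(self.condition_labels))

    @classmethod
    def from_per_ant(cls, frame: pd.DataFrame, experiment_id=None, protocol=None):
        """Build the matrix from per-ant long-format test rows.

        Ants lacking a response to every condition are excluded listwise and
        counted in ``n_excluded``.
        """
        rows = frame[frame["phase"] == "test"]
        if experiment_id is not None:
            rows = rows[rows["experiment_id"] == experiment_id]
        if protocol is not None:
            rows = rows[rows["protocol"] == protocol]
        if rows.empty:
            raise ValueError("no test-phase rows for the requested group")
        wide = rows.pivot_table(index="ant_id", columns="test_carbon",
                                values="response", aggfunc="first")
        complete = wide.dropna()
        return cls(
            data=complete.to_numpy(dtype=int),
            condition_labels=tuple(int(c) for c in wide.columns),
            n_excluded=int(len(wide) - len(complete)),
        )


@dataclass(frozen=True)
class CochranQResult:
    statistic: float
    df: int
    pvalue: float
    undefined: bool = False


def cochran_q(matrix: PairedBinaryMatrix) -> CochranQResult:
    """Cochran's Q across k paired binary conditions.

    Q = k(k-1) * sum_j (C_j - N/k)^2 / (k * sum_i R_i - sum_i R_i^2), with
    column totals C_j, row totals R_i and grand total N; the p-value comes
    from chi-square with k-1 degrees of freedom. Subjects whose responses are
    identical across conditions contribute nothing but are retained. If every
    row is constant the denominator vanishes; since the numerator is then
    also zero (constant rows imply identical columns), the statistic is
    reported as 0 with p = 1 and the ``undefined`` flag set.
    """
    data = matrix.data
    n_subjects, k = data.shape
    if k < 2 or n_subjects < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    col_totals = data.sum(axis=0)
    row_totals = data.sum(axis=1)
    grand = data.sum()
    denom = k * row_totals.sum() - np.sum(row_totals**2)
    df = k - 1
    if denom == 0:
        return CochranQResult(statistic=0.0, df=df, pvalue=1.0, undefined=True)
    q = k * (k - 1) * np.sum((col_totals - grand / k) ** 2) / denom
    p = float(sps.chi2.sf(q, df))
    return CochranQResult(statistic=float(q), df=df, pvalue=p)


@dataclass(frozen=True)
class McNemarResult:
    statistic: float
    pvalue: float
    corrected: bool


def mcnemar(b: int, c: int, correction: bool = False) -> McNemarResult:
    """McNemar's chi-square from the discordant-pair counts b and c.

    Uncorrected: (b-c)^2 / (b+c); with continuity correction:
    (|b-c|-1)^2 / (b+c). p from chi-square with 1 df. With no discordant
    pairs (b+c = 0) the statistic is defined as 0 with p = 1.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    if b + c == 0:
        return McNemarResult(statistic=0.0, pvalue=1.0, corrected=correction)
    if correction:
        stat = (abs(b - c) - 1) ** 2 / (b + c)
    else:
        stat = (b - c) ** 2 / (b + c)
    return McNemarResult(statistic=float(stat), pvalue=float(sps.chi2.sf(stat, 1)),
                         corrected=correction)


def holm_bonferroni(p_values, alpha: float = 0.05, method: str = "holm"):
    """Sequential-Bonferroni (Holm step-down) adjusted p-values and decisions.

    Sort ascending, multiply the i-th smallest by (m - i + 1), enforce
    monotonicity, cap at 1. ``method="bonferroni"`` gives the plain
    single-step correction instead. Returns ``(adjusted, reject)`` arrays in
    the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("holm", "bonferroni"):
        raise ValueError(f"unknown method {method!r}")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method=method)
    return adjusted, reject


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 count table.

    Sums the hypergeometric probabilities of all tables with the observed
    margins that are no more probable than the observed one.
    """
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    _, p = sps.fisher_exact(table, alternative="two-sided")
    return float(p)


def pairwise_mcnemar(matrix: PairedBinaryMatrix, correction: bool = False,
                     alpha: float = 0.05, method: str = "holm") -> pd.DataFrame:
    """All pairwise McNemar tests between conditions, Holm-adjusted.

    One row per condition pair with the discordant counts, the chi-square
    statistic, raw and adjusted p-values and the rejection decision at
    ``alpha``. The report names the McNemar variant used (``corrected``
    column) because the continuity-correction choice changes the statistic.
    """
    data = matrix.data
    rows = []
    for i, j in combinations(range(data.shape[1]), 2):
        b = int(np.sum((data[:, i] == 1) & (data[:, j] == 0)))
        c = int(np.sum((data[:, i] == 0) & (data[:, j] == 1)))
        res = mcnemar(b, c, correction=correction)
        rows.append(
            {
                "condition_a": matrix.condition_labels[i],
                "condition_b": matrix.condition_labels[j],
                "b": b,
                "c": c,
                "statistic": res.statistic,
                "pvalue": res.pvalue,
                "corrected": correction,
            }
        )
    frame = pd.DataFrame(rows)
    adjusted, reject = holm_bonferroni(frame["pvalue"].to_numpy(), alpha=alpha, method=method)
    frame["pvalue_adjusted"] = adjusted
    frame["reject"] = reject
    return frame
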