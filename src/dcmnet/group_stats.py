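"""Group-level tests on subject-wise coupling estimates.

One-sample and paired t tests per directed connection, with
Benjamini-Hochberg FDR correction applied across all enabled connections of
one table (one table per factor: baseline, Execution modulation, Hand
modulation, and the Execution-minus-Hand paired contrast).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TTestResult",
    "ConnectionTable",
    "one_sample_t",
    "paired_t",
    "t_to_p",
    "bh_fdr",
    "connection_tests",
    "modulator_contrast",
]

DEFAULT_FDR_Q = 0.05


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean: float
    se: float
    degenerate: bool = False


def one_sample_t(values) -> TTestResult:
    """Two-tailed one-sample t test of mean 0: t = mean / (SD / sqrt(N))."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D sample with N >= 2")
    n = len(x)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return TTestResult(t=np.nan, df=n - 1, p=np.nan, mean=mean, se=0.0, degenerate=True)
    se = sd / np.sqrt(n)
    t = mean / se
    return TTestResult(t=t, df=n - 1, p=t_to_p(t, n - 1), mean=mean, se=se)


def paired_t(x, y) -> TTestResult:
    """Paired t test: one-sample test on the differences x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"paired samples must match in length ({x.shape} vs {y.shape})")
    return one_sample_t(x - y)


def t_to_p(t: float, df: int) -> float:
    """Two-tailed p-value: 2 * P(T_df > |t|)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(2.0 * stats.t.sf(abs(t), df))


def bh_fdr(pvals, q: float = DEFAULT_FDR_Q):
    """Benjamini-Hochberg step-up.

    Returns (reject flags, adjusted p-values).  NaN p-values (degenerate
    tests) are never rejected and keep NaN adjusted values.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie in (0, 1)")
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")

    reject = np.zeros(p.shape, dtype=bool)
    p_adj = np.full(p.shape, np.nan)
    idx = np.flatnonzero(finite)
    m = len(idx)
    if m:
        order = idx[np.argsort(p[idx], kind="stable")]
        ranked = p[order]
        # step-up: largest k with p_(k) <= k q / m; reject all smaller ranks
        thresh = (np.arange(1, m + 1) / m) * q
        passing = np.flatnonzero(ranked <= thresh)
        if passing.size:
            reject[order[: passing[-1] + 1]] = True
        adj = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
        p_adj[order] = np.minimum(adj, 1.0)
    return reject, p_adj


@dataclass(frozen=True)
class ConnectionTable:
    """Per-connection group statistics for one factor's table."""

    factor: str
    table: pd.DataFrame  # columns: from, to, mean, se, t, df, p, p_adj, significant
    q: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def _build_table(factor, connections, results, q) -> ConnectionTable:
    p = np.array([r.p for r in results])
    reject, p_adj = bh_fdr(p, q=q)
    rows = []
    for (frm, to), r, rej, pa in zip(connections, results, reject, p_adj):
        rows.append(
            {
                "from": frm, "to": to, "mean": r.mean, "se": r.se,
                "t": r.t, "df": r.df, "p": r.p, "p_adj": pa,
                "significant": bool(rej),
            }
        )
    return ConnectionTable(factor=factor, table=pd.DataFrame(rows), q=q)


def connection_tests(
    estimates: np.ndarray,
    connections,
    factor: str = "baseline",
    q: float = DEFAULT_FDR_Q,
) -> ConnectionTable:
    """One-sample t per connection with FDR across the table.

    ``estimates`` is (n_subjects, n_connections); ``connections`` lists the
    matching (from, to) region pairs.
    """
    est = np.asarray(estimates, dtype=float)
    connections = list(connections)
    if est.ndim != 2 or est.shape[1] != len(connections):
        raise ValueError("estimates must be (n_subjects, n_connections)")
    if est.shape[0] < 2:
        raise ValueError("need at least two subjects")
    results = [one_sample_t(est[:, j]) for j in range(est.shape[1])]
    return _build_table(factor, connections, results, q)


def modulator_contrast(
    b_exec: np.ndarray,
    b_hand: np.ndarray,
    connections,
    q: float = DEFAULT_FDR_Q,
) -> ConnectionTable:
    """Paired t (Execution minus Hand modulation) per connection, with FDR."""
    x = np.asarray(b_exec, dtype=float)
    y = np.asarray(b_hand, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    connections = list(connections)
    if x.ndim != 2 or x.shape[1] != len(connections):
        raise ValueError("estimates must be (n_subjects, n_connections)")
    results = [paired_t(x[:, j], y[:, j]) for j in range(x.shape[1])]
    return _build_table("contrast", connections, results, q)
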