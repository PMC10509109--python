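"""Agreement and reclassification statistics for paired CAC measurements.

Ordinal risk-class agreement between two scoring conditions (e.g. an 80 kVp
scan vs the 120 kVp reference) is summarized by Cohen's kappa and Kendall's
tau-b on the 5x5 contingency table, plus the reclassification count and its
direction.  Continuous score agreement uses Bland-Altman bias / limits of
agreement and the single-measure absolute-agreement intraclass correlation
ICC(A,1) from the two-way (subjects x raters) mean squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .scoring import RiskClass
from .study_data import RISK_CLASS_LABELS

N_CLASSES = len(RISK_CLASS_LABELS)


@dataclass
class RiskContingencyTable:
    """5x5 cross-tabulation of ordinal risk classes between two conditions.

    ``counts[i, j]`` is the number of subjects placed in class ``i`` by the
    comparison condition (rows) and class ``j`` by the reference condition
    (columns); classes are ordered 0 < 1-10 < 11-100 < 101-400 < >400.
    """

    counts: np.ndarray
    row_condition: str = "comparison"
    col_condition: str = "reference"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (N_CLASSES, N_CLASSES):
            raise ValueError(f"counts must be {N_CLASSES}x{N_CLASSES}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Expand to per-subject (comparison, reference) class index arrays."""
        rows, cols = np.nonzero(self.counts)
        reps = self.counts[rows, cols]
        return np.repeat(rows, reps), np.repeat(cols, reps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(RISK_CLASS_LABELS), columns=list(RISK_CLASS_LABELS))

    def to_csv(self, path: str | Path) -> None:
        """Write as labeled CSV (rows = comparison classes, cols = reference)."""
        self.to_frame().to_csv(path, index_label=f"{self.row_condition} \\ {self.col_condition}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "RiskContingencyTable":
        df = pd.read_csv(path, index_col=0)
        row_cond, _, col_cond = df.index.name.partition(" \\ ")
        return cls(df.to_numpy(), row_cond or "comparison", col_cond or "reference")


@dataclass
class AgreementReport:
    """Summary of ordinal agreement between two scoring conditions."""

    kappa: float
    tau_b: float
    n_reclassified: int
    rate: float
    n_upward: int
    n_downward: int


def _as_class_indices(values) -> np.ndarray:
    out = np.empty(len(values), dtype=int)
    for i, v in enumerate(values):
        if isinstance(v, RiskClass):
            out[i] = int(v)
        elif isinstance(v, str):
            out[i] = int(RiskClass.from_label(v))
        elif isinstance(v, (int, np.integer)) and 0 <= int(v) < N_CLASSES:
            out[i] = int(v)
        else:
            raise ValueError(f"unknown risk class label {v!r}")
    return out


def cross_tabulate(
    comparison_classes,
    reference_classes,
    row_condition: str = "comparison",
    col_condition: str = "reference",
) -> RiskContingencyTable:
    """Cross-tabulate paired risk classes (comparison rows x reference cols)."""
    a = _as_class_indices(comparison_classes)
    b = _as_class_indices(reference_classes)
    if a.size != b.size:
        raise ValueError("paired class sequences must have equal length")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(counts, (a, b), 1)
    return RiskContingencyTable(counts, row_condition, col_condition)


def cohen_kappa(table: RiskContingencyTable, weights: str | None = None) -> float:
    """Cohen's kappa for a contingency table.

    ``weights=None`` gives the unweighted kappa used for the study's
    agreement figures; ``weights='linear'`` is offered for sensitivity
    analyses only.
    """
    n = table.total
    if n == 0:
        raise ValueError("empty table")
    p = table.counts / n
    r = table.row_margins / n
    c = table.col_margins / n
    if weights is None:
        w = 1.0 - np.eye(N_CLASSES)
    elif weights == "linear":
        idx = np.arange(N_CLASSES)
        w = np.abs(idx[:, None] - idx[None, :]) / (N_CLASSES - 1)
    else:
        raise ValueError(f"unknown weights {weights!r}; use None or 'linear'")
    disagree_o = float((w * p).sum())
    disagree_e = float((w * np.outer(r, c)).sum())
    if disagree_e == 0:
        if disagree_o == 0:
            return 1.0
        raise ValueError("kappa undefined: degenerate marginals with observed disagreement")
    return 1.0 - disagree_o / disagree_e


def _concordance_counts(counts: np.ndarray) -> tuple[float, float]:
    """Concordant and discordant pair counts over an ordinal table."""
    P = Q = 0.0
    nr, nc = counts.shape
    for i in range(nr):
        for j in range(nc):
            nij = counts[i, j]
            if nij == 0:
                continue
            P += nij * counts[i + 1 :, j + 1 :].sum()
            Q += nij * counts[i + 1 :, :j].sum()
    return P, Q


def kendall_tau_b(table: RiskContingencyTable) -> float:
    """Kendall's tau-b (tie-corrected) for an ordinal contingency table."""
    n = table.total
    if n < 2:
        raise ValueError("tau-b needs at least 2 subjects")
    counts = table.counts
    P, Q = _concordance_counts(counts)
    n0 = n * (n - 1) / 2.0
    ties_r = float(sum(m * (m - 1) / 2.0 for m in table.row_margins))
    ties_c = float(sum(m * (m - 1) / 2.0 for m in table.col_margins))
    denom = math.sqrt((n0 - ties_r) * (n0 - ties_c))
    if denom == 0:
        raise ValueError("tau-b undefined: all mass in a single row or column")
    return (P - Q) / denom


def reclassification_summary(table: RiskContingencyTable) -> tuple[int, float, int, int]:
    """(n_reclassified, rate, n_upward, n_downward) for a contingency table.

    Upward means the comparison condition assigned a higher risk class than
    the reference (rows below the diagonal are downward moves).
    """
    n = table.total
    if n == 0:
        raise ValueError("empty table")
    n_re = n - table.trace
    upper = int(np.triu(table.counts, k=1).sum())  # row < col: comparison lower
    lower = int(np.tril(table.counts, k=-1).sum())  # row > col: comparison higher
    n_up = lower
    n_down = upper
    return n_re, n_re / n, n_up, n_down


def agreement_report(table: RiskContingencyTable) -> AgreementReport:
    """Kappa, tau-b, and the reclassification summary in one report."""
    n_re, rate, n_up, n_down = reclassification_summary(table)
    return AgreementReport(
        kappa=cohen_kappa(table),
        tau_b=kendall_tau_b(table),
        n_reclassified=n_re,
        rate=rate,
        n_upward=n_up,
        n_downward=n_down,
    )


def agreement_p_values(table: RiskContingencyTable) -> dict[str, float]:
    """Large-sample normal-approximation p-values for kappa and tau-b.

    Informational only (the study reports both simply as p < 0.001).
    """
    from scipy import stats

    n = table.total
    p0 = table.trace / n
    r = table.row_margins / n
    c = table.col_margins / n
    pe = float(r @ c)
    # null SE of unweighted kappa (Fleiss)
    se0 = math.sqrt((pe + pe**2 - float(((r * c) * (r + c)).sum())) / (n * (1 - pe) ** 2))
    z_kappa = cohen_kappa(table) / se0
    a, b = table.to_pairs()
    tau_res = stats.kendalltau(a, b, variant="b")
    return {
        "kappa_p": float(2 * stats.norm.sf(abs(z_kappa))),
        "tau_b_p": float(tau_res.pvalue),
    }


@dataclass
class PairedScores:
    """Paired continuous CAC scores (reference vs comparison) per subject."""

    reference: np.ndarray
    comparison: np.ndarray
    bmi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        self.comparison = np.asarray(self.comparison, dtype=float)
        if self.reference.shape != self.comparison.shape or self.reference.ndim != 1:
            raise ValueError("reference and comparison must be equal-length 1D arrays")
        if (self.reference < 0).any() or (self.comparison < 0).any():
            raise ValueError("CAC scores must be non-negative")
        if self.bmi is not None:
            self.bmi = np.asarray(self.bmi, dtype=float)
            if self.bmi.shape != self.reference.shape:
                raise ValueError("bmi must match the score arrays in length")

    @property
    def n(self) -> int:
        return self.reference.size

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"reference": self.reference, "comparison": self.comparison})
        if self.bmi is not None:
            df["bmi"] = self.bmi
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PairedScores":
        df = pd.read_csv(path)
        return cls(
            df["reference"].to_numpy(),
            df["comparison"].to_numpy(),
            df["bmi"].to_numpy() if "bmi" in df else None,
        )


@dataclass(frozen=True)
class BlandAltman:
    """Mean difference (bias) and 95% limits of agreement."""

    bias: float
    loa_low: float
    loa_high: float
    sd: float


def bland_altman(pairs: PairedScores) -> BlandAltman:
    """Bland-Altman bias and limits: mean(d) +/- 1.96 sd(d), d = comparison - reference."""
    if pairs.n < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = pairs.comparison - pairs.reference
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, sd=sd)


def icc_absolute(pairs: PairedScores) -> float:
    """Single-measure absolute-agreement intraclass correlation ICC(A,1).

    Two-way (subjects x raters) mean squares with k = 2 raters:

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))
    """
    n = pairs.n
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    data = np.stack([pairs.reference, pairs.comparison], axis=1)  # n x k
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom == 0:
        if np.allclose(data, data[0, 0]):
            return 1.0
        raise ValueError("ICC undefined: zero total variance with unequal values")
    return float((ms_r - ms_e) / denom)
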