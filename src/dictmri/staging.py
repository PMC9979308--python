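"""Diagnostic concordance of imaging T staging against pathological T staging.

A staging study yields a K x K contingency table: rows are the stage called
from imaging before surgery, columns the histopathological ground truth
established after surgery.  This module computes the standard evaluation
quantities of such a table:

* per-stage **sensitivity** — among cases whose true (pathological) stage is
  k, the fraction the imaging call also placed in k;
* per-stage **specificity** — among cases whose true stage is not k, the
  fraction imaging did *not* place in k (one-vs-rest);
* **diagnostic coincidence rate** — trace over grand total, i.e. the overall
  fraction of exact stage agreement;
* Pearson **chi-square** test of row/column independence;
* **Cohen's kappa**, the chance-corrected agreement coefficient.

Published staging reports sometimes print specificity and coincidence
denominators that cannot be re-derived from their own contingency counts;
``evaluate_cohort`` therefore always recomputes every metric from the raw
table and renders the fractions it actually used.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: sentinel for metrics whose denominator is empty
UNDEFINED = float("nan")


@dataclass(frozen=True)
class StagingTable:
    """K x K contingency counts: rows = imaging stage, columns = pathology."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if counts.sum() == 0:
            raise ValueError("table is empty (grand total 0)")
        if len(self.labels) != counts.shape[0]:
            raise ValueError("label count must equal table dimension")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def imaging_totals(self) -> np.ndarray:
        """Row margins: number of cases assigned each stage by imaging."""
        return self.counts.sum(axis=1)

    @property
    def pathology_totals(self) -> np.ndarray:
        """Column margins: number of cases in each true stage."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


def load_staging_csv(source) -> StagingTable:
    """Read a staging table CSV with a header row/column of stage labels."""
    df = pd.read_csv(source, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(
            "row labels (imaging) and column labels (pathology) must match: "
            f"{list(df.index)} vs {list(df.columns)}"
        )
    return StagingTable(df.to_numpy(dtype=np.int64), tuple(df.columns))


def save_staging_csv(table: StagingTable, path) -> None:
    table.to_frame().to_csv(path)


def bundled_table(name: str) -> StagingTable:
    """Load one of the shipped staging fixtures (``mr_cohort``/``ct_cohort``)."""
    fname = {"mr_cohort": "table_mr_staging.csv", "ct_cohort": "table_ct_staging.csv"}[name]
    text = resources.files("dictmri.data").joinpath(fname).read_text()
    return load_staging_csv(io.StringIO(text))


def bundled_demographics() -> pd.DataFrame:
    """Per-stage demographics of the MR cohort (counts by sex)."""
    text = resources.files("dictmri.data").joinpath("cohort_demographics.csv").read_text()
    return pd.read_csv(io.StringIO(text), index_col=0)


# ---------------------------------------------------------------------------
# metrics

def sensitivity(table: StagingTable, stage: int | str) -> float:
    """Fraction of true-stage-k cases that imaging also called k."""
    k = _stage_index(table, stage)
    col = table.pathology_totals[k]
    if col == 0:
        return UNDEFINED
    return float(table.counts[k, k] / col)


def specificity(table: StagingTable, stage: int | str) -> float:
    """Among cases whose true stage is not k, fraction not called k (one-vs-rest)."""
    k = _stage_index(table, stage)
    non_k = table.n - table.pathology_totals[k]
    if non_k == 0:
        return UNDEFINED
    false_pos = table.imaging_totals[k] - table.counts[k, k]
    return float(1.0 - false_pos / non_k)


def coincidence_rate(table: StagingTable) -> float:
    """Overall diagnostic coincidence: trace over grand total."""
    return float(np.trace(table.counts) / table.n)


def chi_square_test(table: StagingTable) -> tuple[float, float]:
    """Pearson chi-square of independence with (K-1)^2 degrees of freedom.

    Returns ``(statistic, p_value)``.  Yates continuity correction is never
    applied (K x K with K >= 2 analysed as a general contingency table); a
    low-expected-count condition is the caller's to inspect via
    ``expected_counts``.
    """
    if (table.imaging_totals == 0).any() or (table.pathology_totals == 0).any():
        raise ValueError("chi-square undefined with a zero row or column margin")
    chi2, p, _, _ = stats.chi2_contingency(table.counts, correction=False)
    return float(chi2), float(p)


def expected_counts(table: StagingTable) -> np.ndarray:
    """Expected counts under independence (outer product of margins / n)."""
    return np.outer(table.imaging_totals, table.pathology_totals) / table.n


def agreement_kappa(table: StagingTable) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e), chance-corrected agreement."""
    n = table.n
    p_o = np.trace(table.counts) / n
    p_e = float(table.imaging_totals @ table.pathology_totals) / n**2
    if p_e >= 1.0:
        return UNDEFINED
    return float((p_o - p_e) / (1.0 - p_e))


def _stage_index(table: StagingTable, stage: int | str) -> int:
    if isinstance(stage, str):
        return table.labels.index(stage)
    return int(stage)


def _round_half_up(x: float, decimals: int) -> float:
    # np.round is banker's rounding; printed clinical tables round half up
    factor = 10.0**decimals
    return float(np.floor(x * factor + 0.5) / factor)


@dataclass(frozen=True)
class StageMetrics:
    """All evaluation quantities of one staging cohort."""

    labels: tuple[str, ...]
    sensitivity: tuple[float, ...]
    specificity: tuple[float, ...]
    coincidence_rate: float
    chi_square: float
    chi_square_p: float
    agreement_kappa: float
    n: int
    footnotes: tuple[str, ...] = field(default=())


def evaluate_cohort(table: StagingTable, rounding: int = 2) -> tuple[StageMetrics, pd.DataFrame]:
    """Compute every staging metric and render a per-stage report table.

    Percentages in the report are rounded half-up to ``rounding`` decimals,
    matching how clinical staging tables are printed.  The report carries the
    raw fractions alongside so every percentage is auditable.
    """
    sens = tuple(sensitivity(table, k) for k in range(table.k))
    spec = tuple(specificity(table, k) for k in range(table.k))
    chi2, p = chi_square_test(table)
    metrics = StageMetrics(
        labels=table.labels,
        sensitivity=sens,
        specificity=spec,
        coincidence_rate=coincidence_rate(table),
        chi_square=chi2,
        chi_square_p=p,
        agreement_kappa=agreement_kappa(table),
        n=table.n,
        footnotes=(
            "sensitivity_k = diag_k / pathology column total_k",
            "specificity_k = 1 - (row_k off-diagonal) / (n - pathology column total_k); "
            "one-vs-rest definition recomputed from the table (printed reports may use "
            "non-derivable denominators)",
            "coincidence rate = trace / n",
        ),
    )
    col_tot = table.pathology_totals
    rows = []
    for k, label in enumerate(table.labels):
        non_k = table.n - col_tot[k]
        fp = table.imaging_totals[k] - table.counts[k, k]
        rows.append(
            {
                "stage": label,
                "sensitivity_pct": _round_half_up(100 * sens[k], rounding),
                "sensitivity_fraction": f"{table.counts[k, k]}/{col_tot[k]}",
                "specificity_pct": _round_half_up(100 * spec[k], rounding),
                "specificity_fraction": f"{non_k - fp}/{non_k}",
                "coincidence_pct": _round_half_up(100 * metrics.coincidence_rate, rounding),
                "coincidence_fraction": f"{int(np.trace(table.counts))}/{table.n}",
                "p": _round_half_up(p, 3),
                "chi_square": _round_half_up(chi2, rounding),
                "kappa": _round_half_up(metrics.agreement_kappa, rounding + 2),
            }
        )
    return metrics, pd.DataFrame(rows)
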