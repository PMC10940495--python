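"""Per-site differential editing between control and silenced libraries.

The test is Welch's two-sample t-test (unequal variances, Satterthwaite
degrees of freedom), one-tailed by default in the 'less' direction: silenced
editing lower than control.  Saturated sites (both groups at fraction 1.0)
make both sample variances zero; the degenerate convention is p = 0.5 for
equal means and p = 0 / 1 when the alternative direction holds / fails
strictly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .editing_quant import EditingMeasurement

ALTERNATIVES = ("less", "greater", "two_sided")
CONDITIONS = ("control", "test")


class DesignError(ValueError):
    pass


class UntestableError(ValueError):
    """Fewer than two usable values in a group."""


@dataclass(frozen=True)
class TestResult:
    t_stat: float
    df: float
    pvalue: float
    alternative: str
    n_ctrl: int
    n_test: int


@dataclass(frozen=True)
class DifferentialRecord:
    site_label: str
    mean_ctrl: float
    mean_test: float
    delta: float  # mean_test − mean_ctrl
    test: TestResult | None
    significant: bool
    adjusted_pvalue: float | None = None
    untestable: bool = False


def welch_one_tailed(
    ctrl: Sequence[float], test: Sequence[float], alternative: str = "less"
) -> TestResult:
    """Welch's t-test of ``test`` against ``ctrl``.

    The statistic is computed on (test − ctrl), so ``alternative='less'``
    asks whether the test group's mean is below the control's.  NA values
    are dropped; fewer than two remaining values in either group raises
    :class:`UntestableError`.
    """
    if alternative not in ALTERNATIVES:
        raise DesignError(f"unknown alternative {alternative!r}")
    a = np.asarray([x for x in ctrl if not math.isnan(x)], dtype=float)
    b = np.asarray([x for x in test if not math.isnan(x)], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise UntestableError(
            f"untestable: need >= 2 values per group, got {len(a)} vs {len(b)}"
        )
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = b.mean() - a.mean()
    if va == 0.0 and vb == 0.0:
        # degenerate: both groups constant
        if diff == 0:
            p = 0.5
        elif alternative == "less":
            p = 0.0 if diff < 0 else 1.0
        elif alternative == "greater":
            p = 0.0 if diff > 0 else 1.0
        else:
            p = 0.0
        t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
        return TestResult(t, math.nan, p, alternative, len(a), len(b))
    sa, sb = va / len(a), vb / len(b)
    se = math.sqrt(sa + sb)
    t = diff / se
    df = (sa + sb) ** 2 / (
        sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1)
    )
    if alternative == "less":
        p = stats.t.cdf(t, df)
    elif alternative == "greater":
        p = stats.t.sf(t, df)
    else:
        p = 2 * stats.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), alternative, len(a), len(b))


def welch_pvalues_vectorised(
    ctrl: np.ndarray, test: np.ndarray, alternative: str = "less"
) -> np.ndarray:
    """One p-value per row of two (m, n) matrices; non-degenerate rows only.

    Used for large simulation batches (calibration studies); semantics match
    :func:`welch_one_tailed` away from the zero-variance degenerate case.
    """
    va = ctrl.var(axis=1, ddof=1) / ctrl.shape[1]
    vb = test.var(axis=1, ddof=1) / test.shape[1]
    diff = test.mean(axis=1) - ctrl.mean(axis=1)
    se = np.sqrt(va + vb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
        df = (va + vb) ** 2 / (
            va**2 / (ctrl.shape[1] - 1) + vb**2 / (test.shape[1] - 1)
        )
    if alternative == "less":
        return stats.t.cdf(t, df)
    if alternative == "greater":
        return stats.t.sf(t, df)
    return 2 * stats.t.sf(np.abs(t), df)


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up FDR)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def differential_table(
    measurements: Iterable[EditingMeasurement],
    design: dict[str, str],
    *,
    alpha: float = 0.05,
    alternative: str = "less",
    adjust: str = "none",
) -> list[DifferentialRecord]:
    """One differential record per site.

    ``design`` maps each library to 'control' or 'test'.  Sites with fewer
    than two usable measurements in either group are flagged untestable and
    retained.  Adjustment 'BH' applies Benjamini–Hochberg across testable
    sites; significance is then judged on the adjusted p-value.  Output is
    sorted by p-value then site label, untestable sites last.
    """
    if adjust not in ("none", "BH"):
        raise DesignError(f"unknown adjustment {adjust!r}")
    for cond in set(design.values()):
        if cond not in CONDITIONS:
            raise DesignError(f"condition {cond!r} not in {CONDITIONS}")

    by_site: dict[str, dict[str, list[float]]] = {}
    for m in measurements:
        if m.library_id not in design:
            raise DesignError(f"library {m.library_id!r} absent from design")
        cond = design[m.library_id]
        by_site.setdefault(m.site.label, {"control": [], "test": []})[cond].append(
            m.fraction
        )

    records: list[DifferentialRecord] = []
    for label, groups in by_site.items():
        ctrl = [x for x in groups["control"] if not math.isnan(x)]
        test = [x for x in groups["test"] if not math.isnan(x)]
        mean_ctrl = float(np.mean(ctrl)) if ctrl else math.nan
        mean_test = float(np.mean(test)) if test else math.nan
        try:
            result = welch_one_tailed(ctrl, test, alternative)
        except UntestableError:
            records.append(
                DifferentialRecord(
                    site_label=label,
                    mean_ctrl=mean_ctrl,
                    mean_test=mean_test,
                    delta=mean_test - mean_ctrl,
                    test=None,
                    significant=False,
                    untestable=True,
                )
            )
            continue
        records.append(
            DifferentialRecord(
                site_label=label,
                mean_ctrl=mean_ctrl,
                mean_test=mean_test,
                delta=mean_test - mean_ctrl,
                test=result,
                significant=result.pvalue < alpha,
            )
        )

    if adjust == "BH":
        testable = [r for r in records if not r.untestable]
        if testable:
            adj = benjamini_hochberg(np.array([r.test.pvalue for r in testable]))
            adjusted = {
                r.site_label: float(q) for r, q in zip(testable, adj)
            }
            records = [
                r
                if r.untestable
                else DifferentialRecord(
                    site_label=r.site_label,
                    mean_ctrl=r.mean_ctrl,
                    mean_test=r.mean_test,
                    delta=r.delta,
                    test=r.test,
                    significant=adjusted[r.site_label] < alpha,
                    adjusted_pvalue=adjusted[r.site_label],
                )
                for r in records
            ]

    records.sort(
        key=lambda r: (
            r.untestable,
            r.test.pvalue if r.test is not None else math.inf,
            r.site_label,
        )
    )
    return records


def read_design(path: str | Path) -> dict[str, str]:
    """Read a design TSV (``library_id  condition``)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"library_id", "condition"} <= set(df.columns):
        raise DesignError("design file needs columns library_id, condition")
    return dict(zip(df["library_id"], df["condition"]))


def records_to_frame(records: Sequence[DifferentialRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        t = r.test
        rows.append(
            {
                "site_label": r.site_label,
                "mean_ctrl": r.mean_ctrl,
                "mean_test": r.mean_test,
                "delta": r.delta,
                "t": t.t_stat if t else math.nan,
                "df": t.df if t else math.nan,
                "pvalue": t.pvalue if t else math.nan,
                "adjusted_pvalue": (
                    r.adjusted_pvalue if r.adjusted_pvalue is not None else math.nan
                ),
                "significant": int(r.significant),
                "n_ctrl": t.n_ctrl if t else 0,
                "n_test": t.n_test if t else 0,
                "untestable": int(r.untestable),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "site_label", "mean_ctrl", "mean_test", "delta", "t", "df",
            "pvalue", "adjusted_pvalue", "significant",
            "n_ctrl", "n_test", "untestable",
        ],
    )
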