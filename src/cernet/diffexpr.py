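"""Differential expression: paired t-test, BH adjustment, FC/p thresholds.

Features are called differentially expressed (DE) between patient (A) and
control (H) groups when |log2FC| >= 1 and p < 0.05, with the Benjamini-
Hochberg q-value reported alongside (and usable as the gate instead of the
raw p via :attr:`ThresholdConfig.use_fdr_for_call`). The t-test runs on
log2(x + c) so that multiplicative noise becomes additive; the fold change
is the ratio of group means of the normalized values themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateTestError, DesignError, UndefinedRatioError, ValidationError
from .matrix import GROUP_A, GROUP_H, ExpressionMatrix

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"
DIRECTION_NULL = "null"

DE_COLUMNS = ["feature", "rna_class", "log2fc", "t", "p", "q", "direction", "passes", "degenerate"]


@dataclass
class ThresholdConfig:
    """DE calling thresholds.

    ``lfc_threshold`` is on the log2 scale (1.0 means fold change >= 2 or
    <= 0.5); ``pseudocount`` guards fold changes of zero means; when
    ``use_fdr_for_call`` is set the BH q-value replaces the raw p in the
    pass condition. ``method`` selects the paired t-test (the default,
    aligned on the sample pair ids) or an unpaired Welch test.
    """

    lfc_threshold: float = 1.0
    p_threshold: float = 0.05
    pseudocount: float = 0.01
    use_fdr_for_call: bool = False
    method: str = "paired"  # or "welch"

    def __post_init__(self):
        if self.lfc_threshold <= 0 or self.p_threshold <= 0:
            raise ValidationError("thresholds must be positive")
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be >= 0")
        if self.method not in ("paired", "welch"):
            raise ValidationError(f"unknown test method {self.method!r}")


def log2_fold_change(mean_a: float, mean_h: float, pseudocount: float = 0.01) -> float:
    """log2((mean_A + c) / (mean_H + c)) of two nonnegative group means."""
    if mean_a < 0 or mean_h < 0 or pseudocount < 0:
        raise ValidationError("means and pseudocount must be nonnegative")
    num, den = mean_a + pseudocount, mean_h + pseudocount
    if num == 0 or den == 0:
        raise UndefinedRatioError("zero mean with zero pseudocount; fold change undefined")
    return float(np.log2(num / den))


def paired_t(x, y) -> tuple[float, float]:
    """Two-sided paired t-test of ``x`` against ``y``.

    The statistic is computed on the differences ``x - y`` with n-1
    degrees of freedom. A zero-variance difference vector (including
    ``x == y`` elementwise) has no defined t statistic and raises
    :class:`DegenerateTestError`; callers record such features as
    degenerate and exclude them from BH adjustment.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("paired_t requires two equal-length vectors")
    if len(x) < 2:
        raise DesignError("paired t-test needs at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateTestError("zero variance of paired differences")
    t = d.mean() / (sd / np.sqrt(len(d)))
    p = 2.0 * stats.t.sf(abs(t), len(d) - 1)
    return float(t), float(p)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing values (NaN) pass through untouched and do not count toward
    the number of tests; output positions match input positions.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust expects a 1-D vector")
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def call_de(matrix: ExpressionMatrix, thresholds: ThresholdConfig | None = None) -> pd.DataFrame:
    """Call DE features of one RNA class.

    Returns one row per feature with columns ``feature, rna_class, log2fc,
    t, p, q, direction, passes, degenerate``. Degenerate features (zero
    variance of the paired differences) carry NaN statistics, never pass,
    and are excluded from the BH adjustment.
    """
    thresholds = thresholds or ThresholdConfig()
    c = thresholds.pseudocount

    if thresholds.method == "paired":
        cols_a, cols_h = matrix.paired_columns()
    else:
        cols_a = matrix.group_columns(GROUP_A)
        cols_h = matrix.group_columns(GROUP_H)
        if not cols_a or not cols_h:
            raise DesignError("both groups A and H must be present")

    raw_a = matrix.values[cols_a].to_numpy(dtype=float)
    raw_h = matrix.values[cols_h].to_numpy(dtype=float)
    la = np.log2(raw_a + c)
    lh = np.log2(raw_h + c)

    n_feat = raw_a.shape[0]
    t_stat = np.full(n_feat, np.nan)
    p_val = np.full(n_feat, np.nan)

    if thresholds.method == "paired":
        d = la - lh
        n = d.shape[1]
        sd = d.std(axis=1, ddof=1)
        ok = sd > 0
        t_stat[ok] = d[ok].mean(axis=1) / (sd[ok] / np.sqrt(n))
        p_val[ok] = 2.0 * stats.t.sf(np.abs(t_stat[ok]), n - 1)
    else:
        t_arr, p_arr = stats.ttest_ind(la, lh, axis=1, equal_var=False)
        t_stat, p_val = np.asarray(t_arr), np.asarray(p_arr)
        ok = ~np.isnan(p_val)

    lfc = np.log2((raw_a.mean(axis=1) + c) / (raw_h.mean(axis=1) + c))
    q = bh_adjust(p_val)

    gate = q if thresholds.use_fdr_for_call else p_val
    with np.errstate(invalid="ignore"):
        passes = ok & (np.abs(lfc) >= thresholds.lfc_threshold) & (gate < thresholds.p_threshold)
    direction = np.where(passes & (lfc > 0), DIRECTION_UP,
                         np.where(passes & (lfc < 0), DIRECTION_DOWN, DIRECTION_NULL))

    return pd.DataFrame(
        {
            "feature": matrix.features,
            "rna_class": matrix.rna_class,
            "log2fc": lfc,
            "t": t_stat,
            "p": p_val,
            "q": q,
            "direction": direction,
            "passes": passes,
            "degenerate": ~ok,
        }
    ).reset_index(drop=True)


def de_counts(table: pd.DataFrame) -> dict:
    """Tally of a DE table: total passing, up, down."""
    passing = table[table["passes"]]
    return {
        "total": int(len(passing)),
        "up": int((passing["direction"] == DIRECTION_UP).sum()),
        "down": int((passing["direction"] == DIRECTION_DOWN).sum()),
    }
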