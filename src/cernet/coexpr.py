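"""Pearson coexpression of DE ncRNAs with DE mRNAs.

The correlation-test p-value uses the exact t-transform:

    t = |r| * sqrt((n - 2) / (1 - r^2)),   p = 2 * P(T_{n-2} > t)

evaluated with the exact Student-t survival function, not a normal
approximation — at n = 6 (df = 4) the two differ by orders of magnitude
in the far tail where strongly coexpressed pairs live.

Pairs are selected at |r| >= r_threshold and p < p_threshold; the sign of
r is kept per pair so downstream ceRNA assembly can restrict to
positively coupled sponge-mRNA pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, UndefinedCorrelationError, ValidationError
from .matrix import ExpressionMatrix

PAIR_COLUMNS = ["ncrna", "ncrna_class", "mrna", "r", "p", "n", "mrna_log2fc"]


def pearson_r(x, y) -> float:
    """Sample Pearson correlation of two vectors of length >= 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson_r requires two equal-length vectors")
    if len(x) < 3:
        raise ValidationError("pearson_r requires at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    return max(-1.0, min(1.0, r))


def correlation_p(r: float, n: int) -> float:
    """Two-sided p-value of the Pearson correlation test at sample size n.

    df = n - 2. |r| = 1 returns 0.0; r = 0 returns 1.0.
    """
    if n < 3:
        raise ValidationError("correlation test needs n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValidationError("correlation must lie in [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, n - 2))


def coexpression_pairs(
    de_mrna: pd.DataFrame,
    de_ncrna: pd.DataFrame,
    mrna_matrix: ExpressionMatrix,
    ncrna_matrix: ExpressionMatrix,
    r_threshold: float = 0.8,
    p_threshold: float = 0.05,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """All (DE ncRNA, DE mRNA) pairs passing |r| >= r_threshold and p < p_threshold.

    Correlations are computed across every sample of both groups on
    log2(x + pseudocount). The result is sorted by p ascending with ties
    broken by (ncRNA id, mRNA id); columns are ``ncrna, ncrna_class,
    mrna, r, p, n, mrna_log2fc``. Features that are constant across all
    samples are skipped (their correlation is undefined).
    """
    if list(mrna_matrix.values.columns) != list(ncrna_matrix.values.columns):
        raise DesignError("mRNA and ncRNA matrices must cover the same samples, in order")

    mrna_ids = list(de_mrna.loc[de_mrna["passes"], "feature"])
    nc_ids = list(de_ncrna.loc[de_ncrna["passes"], "feature"])
    lfc = de_mrna.set_index("feature")["log2fc"]
    n = mrna_matrix.n_samples

    rows = []
    if mrna_ids and nc_ids:
        gm = np.log2(mrna_matrix.values.loc[mrna_ids].to_numpy(dtype=float) + pseudocount)
        gn = np.log2(ncrna_matrix.values.loc[nc_ids].to_numpy(dtype=float) + pseudocount)
        ok_m = np.ptp(gm, axis=1) > 0
        ok_n = np.ptp(gn, axis=1) > 0
        # row-standardize, then r is a dot product / (n-1)
        zm = (gm - gm.mean(axis=1, keepdims=True))
        zn = (gn - gn.mean(axis=1, keepdims=True))
        with np.errstate(invalid="ignore", divide="ignore"):
            zm /= zm.std(axis=1, ddof=1, keepdims=True)
            zn /= zn.std(axis=1, ddof=1, keepdims=True)
        rmat = np.clip(zn @ zm.T / (n - 1), -1.0, 1.0)
        for i, nc in enumerate(nc_ids):
            if not ok_n[i]:
                continue
            for j, m in enumerate(mrna_ids):
                if not ok_m[j]:
                    continue
                r = float(rmat[i, j])
                if abs(r) < r_threshold:
                    continue
                p = correlation_p(r, n)
                if p < p_threshold:
                    rows.append((nc, ncrna_matrix.rna_class, m, r, p, n, float(lfc[m])))

    out = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return out.sort_values(["p", "ncrna", "mrna"], kind="mergesort").reset_index(drop=True)
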