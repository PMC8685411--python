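"""qPCR relative expression (2^-dCt) and group comparison.

Each sample's relative expression of a target gene is 2^-(dCt) with
dCt = mean Ct(target) - mean Ct(reference); technical replicates are
averaged on the Ct scale before the transform. Groups are compared on
the 2^-dCt values with a two-tailed Student's t-test (equal variances,
per the validation design; Welch available via ``equal_var=False``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTestError, DesignError, MissingReferenceError, ValidationError
from .matrix import GROUP_A, GROUP_H

CT_COLUMNS = ["sample", "group", "gene", "replicate", "ct"]


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"Ct table lacks columns: {missing}")
    if (table["ct"] <= 0).any():
        raise ValidationError("Ct values must be positive cycle counts")
    return table


def relative_expression(table: pd.DataFrame, target: str, reference: str = "ACTB") -> pd.DataFrame:
    """Per-sample 2^-dCt of ``target`` normalized to ``reference``.

    Returns a DataFrame with columns ``sample, group, dct, rel_expr``.
    """
    validate_ct_table(table)
    sub = table[table["gene"].isin([target, reference])]
    mean_ct = sub.groupby(["sample", "group", "gene"])["ct"].mean().unstack("gene")
    if target not in mean_ct.columns:
        raise ValidationError(f"target gene {target!r} not measured")
    if reference not in mean_ct.columns or mean_ct[reference].isna().any():
        bad = [] if reference not in mean_ct.columns else \
            list(mean_ct.index[mean_ct[reference].isna()].get_level_values("sample"))
        raise MissingReferenceError(
            f"reference gene {reference!r} missing for samples {bad or 'all'}"
        )
    mean_ct = mean_ct.dropna(subset=[target])
    dct = mean_ct[target] - mean_ct[reference]
    out = dct.reset_index()
    out.columns = ["sample", "group", "dct"]
    out["rel_expr"] = 2.0 ** (-out["dct"])
    return out


@dataclass
class GroupComparison:
    t: float
    p: float
    mean_a: float
    sd_a: float
    mean_h: float
    sd_h: float
    n_a: int
    n_h: int


def group_compare(values_a, values_h, equal_var: bool = True) -> GroupComparison:
    """Two-sided two-sample t-test on 2^-dCt values with group summaries."""
    a = np.asarray(values_a, dtype=float)
    h = np.asarray(values_h, dtype=float)
    if len(a) < 2 or len(h) < 2:
        raise DesignError("need at least 2 values per group")
    if a.std(ddof=1) == 0 and h.std(ddof=1) == 0:
        if a.mean() == h.mean():
            t, p = 0.0, 1.0  # identical constant groups: no evidence either way
        else:
            raise DegenerateTestError("zero variance in both groups with unequal means")
    else:
        t, p = stats.ttest_ind(a, h, equal_var=equal_var)
    return GroupComparison(
        t=float(t), p=float(p),
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_h=float(h.mean()), sd_h=float(h.std(ddof=1)),
        n_a=len(a), n_h=len(h),
    )


def qpcr_report(table: pd.DataFrame, targets, reference: str = "ACTB",
                equal_var: bool = True) -> pd.DataFrame:
    """Group comparison of 2^-dCt for each target gene.

    Columns: gene, t, p, mean_a, sd_a, mean_h, sd_h, n_a, n_h, direction.
    """
    rows = []
    for gene in targets:
        rel = relative_expression(table, gene, reference)
        cmp = group_compare(
            rel.loc[rel["group"] == GROUP_A, "rel_expr"],
            rel.loc[rel["group"] == GROUP_H, "rel_expr"],
            equal_var=equal_var,
        )
        direction = "up" if cmp.mean_a > cmp.mean_h else ("down" if cmp.mean_a < cmp.mean_h else "null")
        rows.append((gene, cmp.t, cmp.p, cmp.mean_a, cmp.sd_a, cmp.mean_h, cmp.sd_h,
                     cmp.n_a, cmp.n_h, direction))
    return pd.DataFrame(rows, columns=[
        "gene", "t", "p", "mean_a", "sd_a", "mean_h", "sd_h", "n_a", "n_h", "direction",
    ])
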