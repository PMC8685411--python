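"""Expression-matrix container shared by all pipeline stages.

An :class:`ExpressionMatrix` holds one RNA class (mRNA, lncRNA, circRNA or
miRNA) as a nonnegative features x samples table of normalized expression,
plus per-sample metadata: a group label (``"A"`` for patients, ``"H"`` for
healthy controls) and an optional pair id linking one A sample to one H
sample for paired testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError, ValidationError

RNA_CLASSES = ("mRNA", "lncRNA", "circRNA", "miRNA")
GROUP_A = "A"
GROUP_H = "H"


@dataclass
class ExpressionMatrix:
    """Normalized expression for one RNA class.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample;
        entries are nonnegative normalized expression (unitless).
    rna_class
        One of ``mRNA``, ``lncRNA``, ``circRNA``, ``miRNA``.
    samples
        DataFrame indexed by sample id with a ``group`` column
        (values ``A``/``H``) and an optional ``pair`` column. If
        ``pair`` is present it must be a bijection between groups.
    """

    values: pd.DataFrame
    rna_class: str
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        if self.rna_class not in RNA_CLASSES:
            raise ValidationError(
                f"unknown RNA class {self.rna_class!r}; expected one of {RNA_CLASSES}"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups[:5]}")
        if "group" not in self.samples.columns:
            raise DesignError("sample metadata lacks a 'group' column")
        missing = [s for s in self.values.columns if s not in self.samples.index]
        if missing:
            raise DesignError(f"samples without metadata: {missing}")
        groups = set(self.samples.loc[list(self.values.columns), "group"])
        if not groups <= {GROUP_A, GROUP_H}:
            raise DesignError(f"unknown group labels: {sorted(groups - {GROUP_A, GROUP_H})}")
        vals = self.values.to_numpy(dtype=float)
        if vals.size and (np.isnan(vals).any() or (vals < 0).any()):
            raise ValidationError("expression values must be nonnegative and non-missing")
        if "pair" in self.samples.columns:
            self._check_pairing()

    def _check_pairing(self):
        meta = self.samples.loc[list(self.values.columns)]
        a = meta[meta["group"] == GROUP_A]
        h = meta[meta["group"] == GROUP_H]
        if sorted(a["pair"]) != sorted(h["pair"]) or a["pair"].duplicated().any():
            raise DesignError("pair ids are not a bijection between groups A and H")

    # -- convenience accessors -------------------------------------------------

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_columns(self, group: str) -> list[str]:
        meta = self.samples.loc[list(self.values.columns)]
        return list(meta.index[meta["group"] == group])

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values[self.group_columns(group)]

    def group_means(self) -> pd.DataFrame:
        """Per-feature mean expression in each group (columns ``A`` and ``H``)."""
        return pd.DataFrame(
            {
                GROUP_A: self.group_values(GROUP_A).mean(axis=1),
                GROUP_H: self.group_values(GROUP_H).mean(axis=1),
            }
        )

    def paired_columns(self) -> tuple[list[str], list[str]]:
        """Sample columns of group A and group H aligned by pair id.

        Raises :class:`DesignError` when no ``pair`` metadata is present.
        """
        if "pair" not in self.samples.columns:
            raise DesignError("paired analysis requested but no 'pair' metadata present")
        meta = self.samples.loc[list(self.values.columns)]
        a = meta[meta["group"] == GROUP_A].sort_values("pair")
        h = meta[meta["group"] == GROUP_H].sort_values("pair")
        if len(a) == 0 or len(h) == 0:
            raise DesignError("both groups A and H must be present")
        return list(a.index), list(h.index)
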