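"""Protein-by-sample abundance container used across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ProteinMatrix:
    """Proteins x samples log2 abundances with an explicit missing mask.

    ``values`` holds log2 abundances with NaN marking missing entries;
    ``groups`` maps sample ids to response-group labels; ``flags`` carries
    boolean annotation layers (``below_lod``, ``imputed``) aligned to
    ``values``.
    """

    values: pd.DataFrame
    groups: pd.Series | None = None
    flags: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.groups is not None:
            missing = [s for s in self.values.columns if s not in self.groups.index]
            if missing:
                raise ValueError(f"samples without group labels: {missing[:5]}")
            self.groups = self.groups.reindex(self.values.columns)
        for name, flag in self.flags.items():
            if flag.shape != self.values.shape:
                raise ValueError(f"flag layer {name!r} misaligned with values")
        finite = self.values.to_numpy(dtype=float)
        if np.isinf(finite).any():
            raise ValueError("non-finite (inf) abundances present")

    @property
    def present(self) -> pd.DataFrame:
        return self.values.notna()

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def copy(self) -> "ProteinMatrix":
        return ProteinMatrix(
            values=self.values.copy(),
            groups=None if self.groups is None else self.groups.copy(),
            flags={k: v.copy() for k, v in self.flags.items()},
        )

    def subset(self, proteins=None, samples=None) -> "ProteinMatrix":
        values = self.values
        if proteins is not None:
            values = values.loc[list(proteins)]
        if samples is not None:
            values = values[list(samples)]
        groups = None
        if self.groups is not None:
            groups = self.groups.reindex(values.columns)
        flags = {k: v.reindex(index=values.index, columns=values.columns)
                 for k, v in self.flags.items()}
        return ProteinMatrix(values=values, groups=groups, flags=flags)

    def group_columns(self, group: str) -> pd.Index:
        if self.groups is None:
            raise ValueError("matrix carries no group labels")
        return self.values.columns[(self.groups == group).to_numpy()]
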