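"""Shared in-memory containers for the screening pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("Bacteria", "Fungi", "Plants", "Environment")
KINDS = ("count", "cover", "measurement")

#: separator used in association-type labels, e.g. "Fungi->Bacteria"
TYPE_SEP = "->"


@dataclass
class AbundanceTable:
    """Plot x variable community table with metadata.

    values: numeric matrix, rows = sampling plots, columns = variables.
    groups: variable -> constituent group (Bacteria/Fungi/Plants/Environment).
    gradient: plot -> ordinal gradient position / successional stage.
    kind: variable -> measurement kind (count, cover, measurement).
    """

    values: pd.DataFrame
    groups: pd.Series
    gradient: pd.Series
    kind: pd.Series

    def __post_init__(self) -> None:
        cols = self.values.columns
        if cols.duplicated().any():
            dupes = cols[cols.duplicated()].tolist()
            raise ValueError(f"duplicated variable names: {dupes}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicated plot names")
        for name, meta in (("groups", self.groups), ("kind", self.kind)):
            missing = cols.difference(meta.index)
            if len(missing):
                raise ValueError(f"{name} metadata missing for variables: {missing.tolist()}")
        missing = self.values.index.difference(self.gradient.index)
        if len(missing):
            raise ValueError(f"gradient position missing for plots: {missing.tolist()}")
        bad_group = set(self.groups.loc[cols]) - set(GROUPS)
        if bad_group:
            raise ValueError(f"unknown constituent groups: {sorted(bad_group)}")
        bad_kind = set(self.kind.loc[cols]) - set(KINDS)
        if bad_kind:
            raise ValueError(f"unknown variable kinds: {sorted(bad_kind)}")
        self.groups = self.groups.loc[cols]
        self.kind = self.kind.loc[cols]
        self.gradient = self.gradient.loc[self.values.index]
        count_cols = self.kind.index[self.kind == "count"]
        if len(count_cols):
            counts = self.values[count_cols].to_numpy()
            if np.any(counts < 0):
                raise ValueError("count variables must be nonnegative")

    @property
    def n_plots(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def presence(self) -> pd.DataFrame:
        """Boolean plot x variable presence mask.

        Taxon variables (count/cover) are present where abundance > 0;
        environment measurements are present on every plot.
        """
        present = self.values > 0
        env = self.kind.index[self.kind == "measurement"]
        present[env] = True
        return present

    def subset_plots(self, plots) -> "AbundanceTable":
        return AbundanceTable(
            values=self.values.loc[plots],
            groups=self.groups,
            gradient=self.gradient.loc[plots],
            kind=self.kind,
        )


def assoc_type(group_source: str, group_target: str) -> str:
    """Ordered association-type label for a directed source -> target pair."""
    return f"{group_source}{TYPE_SEP}{group_target}"


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset.

    links: one row per planted pairwise link (source, target, klass,
    effect, noise_sd).  variables: one row per generated variable
    (variable, group, kind, response).
    """

    links: pd.DataFrame
    variables: pd.DataFrame = field(default_factory=pd.DataFrame)
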