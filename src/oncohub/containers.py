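"""In-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd


@dataclass
class ExpressionCompendium:
    """Gene x sample expression matrix with per-sample annotations.

    ``values`` holds log-scale expression with genes in rows and samples in
    columns; ``sample_meta`` is indexed by sample id and carries at least a
    ``dataset`` label plus any phenotype/trait columns.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(index=self.values.columns)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        if not self.values.columns.equals(self.sample_meta.index):
            self.sample_meta = self.sample_meta.loc[self.values.columns]
        if self.values.isna().any().any():
            raise ValueError("missing values in expression matrix")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionCompendium":
        ids = list(sample_ids)
        return ExpressionCompendium(self.values[ids], self.sample_meta.loc[ids])

    def copy(self) -> "ExpressionCompendium":
        return ExpressionCompendium(self.values.copy(), self.sample_meta.copy())


def make_trait_table(sample_meta: pd.DataFrame, phenotypes: Sequence[str]) -> pd.DataFrame:
    """Per-sample trait table: ordinal phenotype rank plus binary indicators.

    The phenotype order encodes disease progression (e.g. normal < benign <
    HGPIN < cancer < CRPC < metastasis); the integer rank is the trait used
    for module-trait correlation, and each phenotype also gets a 0/1
    indicator column.
    """
    if "phenotype" not in sample_meta.columns:
        raise ValueError("sample_meta must contain a 'phenotype' column")
    ranks = {p: i for i, p in enumerate(phenotypes)}
    unknown = set(sample_meta["phenotype"]) - set(ranks)
    if unknown:
        raise ValueError(f"unknown phenotypes: {sorted(unknown)}")
    traits = pd.DataFrame(index=sample_meta.index)
    traits["phenotype_rank"] = sample_meta["phenotype"].map(ranks).astype(int)
    for p in phenotypes:
        traits[p] = (sample_meta["phenotype"] == p).astype(int)
    return traits
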