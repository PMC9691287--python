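"""Core in-memory containers shared across the analysis stages.

The central object is :class:`CountMatrix`, a genes x samples integer count
table with a condition label per sample (cell type for the B-cell panel,
tissue name for the tissue panel). It is a thin, validated wrapper around a
pandas DataFrame so every stage speaks the same dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class BspliceError(Exception):
    """Base class for errors raised by this package."""


class SizingError(BspliceError, ValueError):
    """Invalid dimensions or sizes for a simulation or computation."""


class NormalizationError(BspliceError, ValueError):
    """Normalization is undefined for the given matrix."""


class LookupError_(BspliceError, KeyError):
    """A referenced condition, gene, sample or gene set does not exist."""


@dataclass
class CountMatrix:
    """Genes x samples non-negative integer counts with condition labels.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample id.
    condition_of
        Mapping sample id -> condition label; must cover every sample.
    """

    counts: pd.DataFrame
    condition_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        missing = [s for s in self.counts.columns if s not in self.condition_of]
        if missing:
            raise ValueError(f"samples without a condition label: {missing}")
        if self.counts.size:
            vals = self.counts.to_numpy()
            if not np.issubdtype(vals.dtype, np.integer):
                if not np.allclose(vals, np.round(vals)):
                    raise ValueError("counts must be integers")
                self.counts = self.counts.astype(np.int64)
            if (self.counts.to_numpy() < 0).any():
                raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def conditions(self) -> list[str]:
        """Distinct condition labels in sample order."""
        seen: list[str] = []
        for s in self.sample_ids:
            c = self.condition_of[s]
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        """Sample ids belonging to one condition, in column order."""
        out = [s for s in self.sample_ids if self.condition_of[s] == condition]
        if not out:
            raise LookupError_(f"unknown condition label: {condition!r}")
        return out

    def subset_samples(self, samples: list[str]) -> "CountMatrix":
        return CountMatrix(
            self.counts[samples].copy(),
            {s: self.condition_of[s] for s in samples},
        )
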