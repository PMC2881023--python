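"""Core data containers shared across the pipeline.

The central object is :class:`ExpressionMatrix`: a genes × samples table of
normalized log2 intensities together with a sample sheet assigning each array
to a (strain, treatment) condition. Everything downstream — per-strain
contrasts, tri-state scoring, clustering — consumes this container.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field

import pandas as pd

CONTROL = "control"
EXPOSED = "exposed"
TREATMENTS = (CONTROL, EXPOSED)

RESISTANT = "resistant"
SENSITIVE = "sensitive"


class CrossDiffError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CrossDiffError):
    """An invalid configuration value; the message names the offending field."""


class DesignError(CrossDiffError):
    """The sample design cannot support the requested model."""


class InsufficientDataError(CrossDiffError):
    """Too few observations for the requested computation."""


class DegenerateDataError(CrossDiffError):
    """Input data are degenerate (e.g. all variances identically zero)."""


class InputError(CrossDiffError):
    """Malformed or inconsistent user input."""


@dataclass
class ExpressionMatrix:
    """Genes × samples log2 expression with per-sample condition labels.

    Parameters
    ----------
    values : DataFrame
        Rows indexed by unique gene IDs, columns by sample IDs; log2
        intensities (dimensionless).
    samples : DataFrame
        Indexed by sample ID with columns ``strain`` and ``treatment``
        (``control``/``exposed``); an optional ``replicate`` column is kept
        if present.
    collectives : dict, optional
        Strain label → ``"resistant"`` or ``"sensitive"``. Required by the
        cross-strain scoring layer, not by the linear model itself.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    collectives: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise InputError(f"duplicate gene IDs: {list(dupes[:5])}")
        missing = [s for s in self.values.columns if s not in self.samples.index]
        if missing:
            raise InputError(f"samples missing from sample sheet: {missing[:5]}")
        bad = set(self.samples["treatment"]) - set(TREATMENTS)
        if bad:
            raise InputError(f"unknown treatment labels: {sorted(bad)}")
        # keep the sheet aligned to the matrix columns
        self.samples = self.samples.loc[self.values.columns]
        if self.collectives is not None:
            bad = set(self.collectives.values()) - {RESISTANT, SENSITIVE}
            if bad:
                raise InputError(f"unknown collective labels: {sorted(bad)}")

    # ------------------------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def strains(self) -> list[str]:
        return list(pd.unique(self.samples["strain"]))

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def condition_labels(self) -> pd.Series:
        """Per-sample '(strain, treatment)' condition key."""
        return self.samples["strain"].astype(str) + ":" + self.samples["treatment"].astype(str)

    def subset_strain(self, strain: str) -> "ExpressionMatrix":
        keep = self.samples.index[self.samples["strain"] == strain]
        if len(keep) == 0:
            raise DesignError(f"no samples for strain {strain!r}")
        return ExpressionMatrix(
            self.values[keep], self.samples.loc[keep].copy(), self.collectives
        )

    def validate_for_testing(self, min_replicates: int = 2) -> None:
        """Check every present condition has enough samples for testing."""
        counts = self.condition_labels().value_counts()
        thin = counts[counts < min_replicates]
        if len(thin):
            raise DesignError(
                f"conditions with fewer than {min_replicates} samples: "
                f"{sorted(thin.index)}"
            )

    # ------------------------------------------------------------------ io
    def to_tsv(self, matrix_path, samples_path) -> None:
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(matrix_path, sep="\t")
        sheet = self.samples.copy()
        sheet.index.name = "sample"
        sheet.to_csv(samples_path, sep="\t")

    @classmethod
    def from_tsv(cls, matrix_path, samples_path,
                 collectives: dict[str, str] | None = None) -> "ExpressionMatrix":
        values = pd.read_csv(pathlib.Path(matrix_path), sep="\t", index_col=0)
        samples = pd.read_csv(pathlib.Path(samples_path), sep="\t", index_col=0)
        return cls(values, samples, collectives)
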