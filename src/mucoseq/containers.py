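"""In-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Gene x sample integer counts with sample factors and gene annotation.

    Parameters
    ----------
    counts
        Non-negative integer matrix, genes as rows (index = gene ids),
        samples as columns.
    samples
        One row per sample (index = sample ids), one column per factor
        (e.g. ``group`` with levels ``UC.I`` / ``UC.nI`` / ``Cntrl`` and
        ``gender`` with levels ``male`` / ``female``).
    annotation
        One row per gene; expected columns ``chromosome``, ``full_name``,
        ``entrez`` (any cross-reference id) and ``pseudogene`` (bool).
        Optional — pass ``None`` when annotation-dependent steps are not
        used.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.isna().any().any():
            raise ValueError("count matrix contains missing values")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("count matrix contains negative values")
        if not self.counts.index.is_unique:
            raise ValueError("gene ids are not unique")
        if not self.counts.columns.equals(self.samples.index):
            missing = self.counts.columns.difference(self.samples.index)
            if len(missing):
                raise ValueError(f"samples without metadata: {list(missing)[:5]}")
            self.samples = self.samples.loc[self.counts.columns]
        if self.samples.isna().any().any():
            raise ValueError("sample factor table contains missing levels")
        if self.annotation is not None:
            self.annotation = self.annotation.reindex(self.counts.index)
        # canonical dtype/layout and axis names so downstream arithmetic and
        # written files are bit-reproducible regardless of whether the matrix
        # came from memory or from disk
        self.counts = pd.DataFrame(
            np.ascontiguousarray(self.counts.to_numpy(dtype=np.int64)),
            index=self.counts.index,
            columns=self.counts.columns,
        )
        self.counts.index.name = "gene"
        self.counts.columns.name = "sample"
        self.samples.index.name = "sample"
        if self.annotation is not None:
            self.annotation.index.name = "gene"

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_genes(self, genes) -> "CountMatrix":
        ann = self.annotation.loc[genes] if self.annotation is not None else None
        return CountMatrix(self.counts.loc[genes], self.samples.copy(), ann)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(
            self.counts[sample_ids], self.samples.loc[sample_ids], self.annotation
        )


@dataclass
class DesignSpec:
    """Model design for the per-gene NB GLM.

    ``factor`` is the primary factor (possibly a combined interaction
    factor such as disease x inflammation collapsed to one ``group``
    variable), ``covariate`` an optional controlled factor (e.g.
    ``gender``), ``contrast`` the ordered pair of ``factor`` levels
    (numerator, denominator): a positive log2 fold change means higher
    expression in the first level.
    """

    factor: str
    contrast: tuple[str, str]
    covariate: str | None = None
    reference: str | None = None  # treatment-coding reference level

    def __post_init__(self) -> None:
        if self.covariate == self.factor:
            raise ValueError("covariate must differ from the primary factor")
        if len(self.contrast) != 2 or self.contrast[0] == self.contrast[1]:
            raise ValueError("contrast must be two distinct levels")


@dataclass
class DEResult:
    """Per-gene differential expression results for one contrast.

    ``table`` columns: ``baseMean``, ``log2FC``, ``SE``, ``stat``, ``p``,
    ``q``, ``passed_filter``, ``converged``. Genes that failed the count
    filter carry NaN test results and ``passed_filter = False``.
    """

    table: pd.DataFrame
    size_factors: pd.Series
    dispersions: pd.Series
    design: DesignSpec | None = None
    dispersion_trend: tuple[float, float] | None = None

    def significant(self, q_threshold: float = 0.05) -> pd.DataFrame:
        t = self.table
        return t[t["passed_filter"] & (t["q"] <= q_threshold)]


@dataclass
class PCAResult:
    """Principal components of standardised expression values.

    ``scores`` is samples x components, ``loadings`` genes x components,
    ``variance_fraction`` the eigenvalue share of each component.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fraction: np.ndarray
    selected_gene_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        vf = np.asarray(self.variance_fraction, dtype=float)
        if (vf < -1e-12).any():
            raise ValueError("negative variance fraction")
        if vf.sum() > 1 + 1e-8:
            raise ValueError("variance fractions sum above 1")
        self.variance_fraction = vf
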