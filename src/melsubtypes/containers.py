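"""Core in-memory containers shared across the pipeline.

All omic assays are held as features x samples :class:`pandas.DataFrame`
objects wrapped in a light :class:`OmicsMatrix` that records the assay kind.
Missing values are NaN; methylation values, where observed, are beta
fractions in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ASSAYS = ("CNV", "MET", "EXPR")

#: vocabulary of categorical state calls per assay (see :mod:`melsubtypes.states`)
CNV_STATES = ("Loss", "Normal", "Gain")
MET_STATES = ("Hypo", "Normal", "Hyper")

CPG_REGIONS = ("Island", "Shore", "Shelf", "OpenSea")
GENE_REGIONS = ("Promoter", "5'UTR", "FirstExon", "Body", "Intergenic")

ANNOTATION_COLUMNS = (
    "probe_id",
    "chromosome",
    "arm",
    "position",
    "gene",
    "cpg_region",
    "gene_region",
    "strand",
)

SEX_CHROMOSOMES = frozenset({"X", "Y", "chrX", "chrY"})


@dataclass
class OmicsMatrix:
    """Features x samples numeric matrix with an assay tag.

    Parameters
    ----------
    values
        DataFrame with feature identifiers as the index and sample
        identifiers as columns. NaN marks missing entries.
    assay
        One of ``"CNV"`` (log-ratio vs normal), ``"MET"`` (beta values) or
        ``"EXPR"`` (counts or normalized expression).
    """

    values: pd.DataFrame
    assay: str

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature identifiers")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        if self.assay == "MET":
            vals = self.values.to_numpy(dtype=float)
            observed = vals[~np.isnan(vals)]
            if observed.size and (observed.min() < -1e-9 or observed.max() > 1 + 1e-9):
                raise ValueError("MET beta values must lie in [0, 1]")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def copy_with(self, values: pd.DataFrame) -> "OmicsMatrix":
        return OmicsMatrix(values=values, assay=self.assay)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"OmicsMatrix(assay={self.assay}, features={self.values.shape[0]}, "
            f"samples={self.values.shape[1]})"
        )


@dataclass
class StateMatrix:
    """Categorical per-feature, per-sample abnormality calls.

    ``values`` holds string labels from ``vocabulary`` (NaN where the source
    value was missing); ``thresholds`` records the cutoffs used, for
    provenance.
    """

    values: pd.DataFrame
    vocabulary: tuple
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        observed = pd.unique(self.values.to_numpy().ravel())
        allowed = set(self.vocabulary)
        for v in observed:
            if isinstance(v, float) and np.isnan(v):
                continue
            if v not in allowed:
                raise ValueError(f"state {v!r} outside vocabulary {self.vocabulary}")


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Check a probe-annotation table for the required columns and vocabularies."""
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    if not ann["cpg_region"].isin(CPG_REGIONS).all():
        raise ValueError("cpg_region outside vocabulary")
    if not ann["gene_region"].isin(GENE_REGIONS).all():
        raise ValueError("gene_region outside vocabulary")
    if (ann["position"] < 1).any():
        raise ValueError("probe positions must be >= 1")
    return ann


def validate_survival(clinical: pd.DataFrame) -> pd.DataFrame:
    """Check a survival table (columns sample, os_time, os_event)."""
    for c in ("sample", "os_time", "os_event"):
        if c not in clinical.columns:
            raise ValueError(f"survival table missing column {c!r}")
    if (clinical["os_time"] <= 0).any() or not np.isfinite(clinical["os_time"]).all():
        raise ValueError("os_time must be positive and finite")
    if not clinical["os_event"].isin([0, 1]).all():
        raise ValueError("os_event must be 0 (censored) or 1 (death)")
    return clinical


def align_samples(*frames: pd.DataFrame) -> list[pd.DataFrame]:
    """Restrict a set of features x samples frames to their shared samples."""
    shared = frames[0].columns
    for f in frames[1:]:
        shared = shared.intersection(f.columns)
    if len(shared) == 0:
        raise ValueError("no shared samples between matrices")
    return [f.loc[:, shared] for f in frames]
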