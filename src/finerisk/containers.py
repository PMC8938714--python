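"""Core in-memory containers shared across pipeline stages.

Tabular data lives in pandas DataFrames with fixed schemas; the thin
dataclasses here bundle those tables with the arrays and metadata that
belong to them (dosage matrices, LD matrices, panel provenance).

Schemas
-------
Cohort table (``pd.DataFrame`` indexed by individual id)
    ``status`` (0/1), ``study``, ``age``, ``bmi``, ``whr``, ``menopause``,
    ``age_menarche``, ``age_first_birth``, ``family_history``,
    ``benign_breast_disease`` and, after :func:`finerisk.synthio.split_cohort`,
    ``partition``.  Missing values (the two age-at-event fields only) are NaN.

Score set (``pd.DataFrame`` indexed by individual id)
    ``raw``, optionally ``standardized``, plus ``status`` and ``partition``.

Summary statistics (``SummaryStatSet.table`` indexed by SNV id)
    ``a1`` (effect allele), ``a2``, ``freq`` (effect-allele frequency),
    ``b`` (log-OR or linear beta per dosage unit), ``se``, ``p``, ``n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COHORT_COVARIATES = (
    "bmi",
    "whr",
    "menopause",
    "age_menarche",
    "age_first_birth",
    "family_history",
    "benign_breast_disease",
)
#: covariate fields allowed to contain missing values
MISSABLE_COVARIATES = ("age_menarche", "age_first_birth")

SUMSTAT_COLUMNS = ("a1", "a2", "freq", "b", "se", "p", "n")


@dataclass
class DosageMatrix:
    """Individuals x SNVs allelic-dosage matrix with SNV metadata.

    ``dosages[i, j]`` is the expected count of ``snvs.effect_allele[j]``
    carried by ``samples[i]``; every value lies in [0, 2].  ``snvs`` is
    indexed by unique SNV id with columns ``chrom``, ``pos``,
    ``effect_allele``, ``other_allele`` (and ``locus`` when simulated).
    """

    samples: pd.Index
    snvs: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        self.samples = pd.Index(self.samples)
        if self.dosages.shape != (len(self.samples), len(self.snvs)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.snvs)} SNVs"
            )
        if not self.snvs.index.is_unique:
            raise ValueError("SNV ids must be unique")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snvs(self) -> int:
        return len(self.snvs)

    def snv_column(self, snv_id: str) -> np.ndarray:
        return self.dosages[:, self.snvs.index.get_loc(snv_id)]

    def subset_samples(self, sample_ids) -> "DosageMatrix":
        idx = self.samples.get_indexer(sample_ids)
        if (idx < 0).any():
            missing = [s for s, i in zip(sample_ids, idx) if i < 0]
            raise KeyError(f"samples not in panel: {missing[:5]}")
        return DosageMatrix(pd.Index(sample_ids), self.snvs, self.dosages[idx])

    def subset_snvs(self, snv_ids) -> "DosageMatrix":
        idx = self.snvs.index.get_indexer(snv_ids)
        if (idx < 0).any():
            missing = [s for s, i in zip(snv_ids, idx) if i < 0]
            raise KeyError(f"SNVs not in panel: {missing[:5]}")
        return DosageMatrix(self.samples, self.snvs.iloc[idx], self.dosages[:, idx])

    def frequencies(self) -> pd.Series:
        return pd.Series(self.dosages.mean(axis=0) / 2.0, index=self.snvs.index)


@dataclass
class SummaryStatSet:
    """Per-study (or meta-analysed) marginal association results.

    ``table`` is indexed by SNV id with columns :data:`SUMSTAT_COLUMNS`.
    The effect allele convention follows the COJO ``.ma`` format: ``a1``
    is the allele whose per-dosage-unit effect ``b`` refers to.
    """

    study: str
    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in SUMSTAT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns {missing}")
        if not self.table.index.is_unique:
            raise ValueError("SNV ids must be unique within a summary-stat set")

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, snv_ids) -> "SummaryStatSet":
        present = [s for s in snv_ids if s in self.table.index]
        return SummaryStatSet(self.study, self.table.loc[present])


@dataclass
class LDReference:
    """Dosage correlation matrix plus per-SNV frequencies and variances
    estimated from a reference genotype panel."""

    snvs: pd.DataFrame  # indexed by SNV id: freq, var (+ metadata passthrough)
    corr: np.ndarray
    n_ref: int

    def __post_init__(self):
        k = len(self.snvs)
        if self.corr.shape != (k, k):
            raise ValueError("correlation matrix shape inconsistent with SNV metadata")

    def submatrix(self, snv_ids) -> np.ndarray:
        idx = self.snvs.index.get_indexer(snv_ids)
        if (idx < 0).any():
            missing = [s for s, i in zip(snv_ids, idx) if i < 0]
            raise KeyError(f"SNVs not in LD reference: {missing[:5]}")
        return self.corr[np.ix_(idx, idx)]


@dataclass
class Locus:
    """A susceptibility-locus window anchored on an index SNV.

    Coordinates are 0-based half-open internally.
    """

    locus_id: str
    index_snv: str
    chrom: str
    start: int
    end: int
    members: list = field(default_factory=list)

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class SelectionResult:
    """Outcome of stepwise conditional selection within one locus.

    ``joint`` is indexed by selected SNV id with columns ``b``, ``se``,
    ``p``, ``order``.  Ineligible loci (no SNV below the threshold) keep
    an empty selection but still record the lead SNV and its marginal
    statistics so downstream tier-3 panel construction can use them.
    """

    locus_id: str
    eligible: bool
    selected: list
    joint: pd.DataFrame
    threshold: float
    members: list
    lead_snv: str | None = None
    lead_b: float = float("nan")
    lead_p: float = float("nan")


@dataclass
class WeightPanel:
    """A PRS definition: per-SNV effect allele and weight, with provenance.

    ``table`` is indexed by SNV id with columns ``effect_allele`` and
    ``weight`` (optionally ``freq`` to enable frequency imputation of
    missing dosages).
    """

    table: pd.DataFrame
    tier: str
    threshold: float | None = None
    source: str | None = None
    label: str | None = None

    def __post_init__(self):
        if not self.table.index.is_unique:
            raise ValueError("panel SNV ids must be unique")
        if not np.isfinite(self.table["weight"].to_numpy(dtype=float)).all():
            raise ValueError("panel weights must be finite")
        if self.label is None:
            self.label = self.tier

    @property
    def n(self) -> int:
        return len(self.table)


@dataclass
class NGRSWeights:
    """Fitted nongenetic-risk-score weights.

    ``weights`` covers the seven factors plus the ``bmi_x_menopause``
    interaction; ``intercept`` is stored for the record but never enters
    the score.
    """

    weights: pd.Series
    intercept: float
    se: pd.Series | None = None


@dataclass
class EvalReport:
    """Discrimination summary for one score on one partition."""

    label: str
    partition: str
    or_per_sd: float
    or_ci: tuple
    p: float
    auc: float
    auc_ci: tuple
    n_cases: int
    n_controls: int
    panel_n: int | None = None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "partition": self.partition,
            "or_per_sd": self.or_per_sd,
            "or_ci_low": self.or_ci[0],
            "or_ci_high": self.or_ci[1],
            "p": self.p,
            "auc": self.auc,
            "auc_ci_low": self.auc_ci[0],
            "auc_ci_high": self.auc_ci[1],
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "panel_n": self.panel_n,
        }
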