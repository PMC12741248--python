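"""Domain containers and I/O for long-format longitudinal proteomic data.

The central container is :class:`LongitudinalDataset`: a long table of
log2-transformed protein abundances observed at up to three visits per
subject, at irregular ages. Companion tables hold survival follow-up
(time origin at the last visit), covariates, and per-protein QC results.

Measurements are sparse by construction: a missing (subject, visit,
protein) cell is the absence of a row, never a sentinel value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical long-format column order
LONG_COLUMNS = ["subject_id", "visit", "age", "protein_id", "value"]

#: number of visits a subject must complete to be retained
N_VISITS = 3

SURVIVAL_CAUSES = frozenset({"all_cause", "cvd", "cancer", "other", "none"})

QC_FAIL_REASONS = ("low_variance", "high_cv", "nonspecific_binding_flag")


class SchemaError(ValueError):
    """Input table does not match the declared column schema."""


@dataclass
class LongitudinalDataset:
    """Sparse per-subject, per-protein longitudinal observations.

    Parameters
    ----------
    observations : pandas.DataFrame
        Long table with columns ``subject_id, visit, age, protein_id,
        value``. ``visit`` is an integer 1..3, ``age`` is in years and
        ``value`` is a log2-transformed abundance.

    Attributes
    ----------
    proteins : list
        Ordered unique protein identifiers.
    subjects : list
        Ordered unique subject identifiers.
    age_domain : tuple of float
        (min age, max age) over all observations.
    """

    observations: pd.DataFrame
    proteins: list = field(init=False)
    subjects: list = field(init=False)
    age_domain: tuple = field(init=False)

    def __post_init__(self) -> None:
        df = self.observations
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        df = df[LONG_COLUMNS].copy()
        df["visit"] = df["visit"].astype(int)
        df["age"] = pd.to_numeric(df["age"], errors="raise").astype(float)
        df["value"] = pd.to_numeric(df["value"], errors="raise").astype(float)
        if len(df) == 0:
            raise ValueError("dataset has no observations")
        if not df["visit"].between(1, N_VISITS).all():
            bad = df.loc[~df["visit"].between(1, N_VISITS), "visit"].unique()
            raise ValueError(f"visit index outside 1..{N_VISITS}: {sorted(bad)}")
        if not np.isfinite(df["age"]).all() or (df["age"] <= 0).any():
            raise ValueError("ages must be finite and positive")
        dup = df.duplicated(subset=["subject_id", "visit", "protein_id"])
        if dup.any():
            key = df.loc[dup, ["subject_id", "visit", "protein_id"]].iloc[0]
            raise ValueError(
                "duplicate observation for (subject, visit, protein) = "
                f"({key['subject_id']}, {key['visit']}, {key['protein_id']})"
            )
        # age must increase strictly with visit index within a subject
        ages = df.drop_duplicates(["subject_id", "visit"]).sort_values(
            ["subject_id", "visit"]
        )
        diffs = ages.groupby("subject_id")["age"].diff().dropna()
        if (diffs <= 0).any():
            raise ValueError("age must strictly increase with visit within a subject")
        # a subject must have a single age per visit
        per_visit = df.groupby(["subject_id", "visit"])["age"].nunique()
        if (per_visit > 1).any():
            raise ValueError("conflicting ages for the same (subject, visit)")
        self.observations = df.reset_index(drop=True)
        self.proteins = sorted(df["protein_id"].unique().tolist())
        self.subjects = sorted(df["subject_id"].unique().tolist())
        self.age_domain = (float(df["age"].min()), float(df["age"].max()))

    # -- convenience accessors -------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    def protein_frame(self, protein_id) -> pd.DataFrame:
        """All observations of one protein, sorted by subject then visit."""
        if protein_id not in set(self.proteins):
            raise KeyError(f"unknown protein {protein_id!r}")
        sub = self.observations[self.observations["protein_id"] == protein_id]
        return sub.sort_values(["subject_id", "visit"]).reset_index(drop=True)

    def subset_subjects(self, subject_ids) -> "LongitudinalDataset":
        keep = set(subject_ids)
        df = self.observations[self.observations["subject_id"].isin(keep)]
        return LongitudinalDataset(df.copy())

    def subset_proteins(self, protein_ids) -> "LongitudinalDataset":
        keep = set(protein_ids)
        df = self.observations[self.observations["protein_id"].isin(keep)]
        return LongitudinalDataset(df.copy())

    def visit_matrix(self, protein_id) -> pd.DataFrame:
        """Wide subject x visit value matrix for one protein."""
        sub = self.protein_frame(protein_id)
        return sub.pivot(index="subject_id", columns="visit", values="value")

    def to_csv(self, path) -> None:
        self.observations.to_csv(path, index=False)


@dataclass
class SurvivalTable:
    """Follow-up time (years from last visit), event indicator and cause."""

    table: pd.DataFrame  # subject_id, time, event, cause

    def __post_init__(self) -> None:
        df = self.table
        required = ["subject_id", "time", "event", "cause"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"survival table missing columns: {missing}")
        df = df[required].copy()
        df["time"] = pd.to_numeric(df["time"]).astype(float)
        df["event"] = df["event"].astype(int)
        if (df["time"] < 0).any():
            raise ValueError("negative follow-up time")
        if not df["event"].isin([0, 1]).all():
            raise ValueError("event must be 0/1")
        unknown = set(df["cause"]) - SURVIVAL_CAUSES
        if unknown:
            raise ValueError(f"unknown causes: {sorted(unknown)}")
        if ((df["event"] == 0) & (df["cause"] != "none")).any():
            raise ValueError("censored subjects must have cause 'none'")
        if df["subject_id"].duplicated().any():
            raise ValueError("duplicate subject in survival table")
        self.table = df.reset_index(drop=True)

    def subset(self, subject_ids) -> "SurvivalTable":
        keep = set(subject_ids)
        return SurvivalTable(self.table[self.table["subject_id"].isin(keep)].copy())

    def aligned(self, subject_ids) -> pd.DataFrame:
        """Rows reindexed to the given subject order; missing subjects raise."""
        idx = self.table.set_index("subject_id")
        missing = [s for s in subject_ids if s not in idx.index]
        if missing:
            raise KeyError(f"survival table missing subjects: {missing[:5]}")
        return idx.loc[list(subject_ids)].reset_index()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class CovariateTable:
    """One row of per-subject covariates measured at the last visit."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        if "subject_id" not in df.columns:
            raise SchemaError("covariate table needs a subject_id column")
        if df["subject_id"].duplicated().any():
            raise ValueError("duplicate subject in covariate table")
        self.table = df.reset_index(drop=True)

    def aligned(self, subject_ids) -> pd.DataFrame:
        idx = self.table.set_index("subject_id")
        missing = [s for s in subject_ids if s not in idx.index]
        if missing:
            raise KeyError(f"covariate table missing subjects: {missing[:5]}")
        return idx.loc[list(subject_ids)].reset_index()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class QcReport:
    """Per-protein QC statistics and pass/fail flags."""

    table: pd.DataFrame  # protein_id, variance, cv, passed, reason

    @property
    def failed(self) -> pd.DataFrame:
        return self.table[~self.table["passed"]]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# -----------------------------------------------------------------------------
# loading


def load_long_dataset(path, schema: dict | None = None) -> LongitudinalDataset:
    """Read a delimited long-format table into a :class:`LongitudinalDataset`.

    Parameters
    ----------
    path : str or pathlib.Path
        CSV/TSV file (delimiter sniffed from the extension; ``.tsv`` ->
        tab, otherwise comma).
    schema : dict, optional
        Mapping from canonical column names (``subject_id, visit, age,
        protein_id, value``) to the column names used in the file.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if schema:
        rename = {v: k for k, v in schema.items()}
        df = df.rename(columns=rename)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"file {path} missing columns {missing} after schema mapping")
    for col in ("age", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"non-numeric {col} at row {row}: {df[col].iloc[row]!r}")
        df[col] = coerced
    return LongitudinalDataset(df)


def load_survival_table(path) -> SurvivalTable:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if "time_years" in df.columns and "time" not in df.columns:
        df = df.rename(columns={"time_years": "time"})
    return SurvivalTable(df)


def load_covariate_table(path) -> CovariateTable:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return CovariateTable(pd.read_csv(path, sep=sep))


# -----------------------------------------------------------------------------
# QC filtering


def apply_protein_qc(
    dataset: LongitudinalDataset,
    var_min: float = 0.01,
    cv_max: float = 50.0,
    cv_values: dict | pd.Series | None = None,
    nonspecific: set | None = None,
) -> tuple[LongitudinalDataset, QcReport]:
    """Drop proteins failing variance / CV / binding-specificity filters.

    A protein is removed when its pooled log-scale variance falls below
    ``var_min`` (default 0.01), when its assay coefficient of variation
    exceeds ``cv_max`` percent (default 50), or when it is flagged for
    non-specific binding. The CV statistic requires replicate assay data
    so it is supplied externally via ``cv_values``; proteins without a
    supplied CV are not CV-filtered.
    """
    if var_min <= 0 or cv_max <= 0:
        raise ValueError("QC thresholds must be positive")
    if cv_values is not None:
        cv_values = pd.Series(dict(cv_values))
    nonspecific = set(nonspecific or ())

    variances = dataset.observations.groupby("protein_id")["value"].var(ddof=1)
    rows = []
    for protein in dataset.proteins:
        var = float(variances.get(protein, 0.0))
        cv = float(cv_values[protein]) if cv_values is not None and protein in cv_values else np.nan
        reason = ""
        if protein in nonspecific:
            reason = "nonspecific_binding_flag"
        elif var < var_min:
            reason = "low_variance"
        elif np.isfinite(cv) and cv > cv_max:
            reason = "high_cv"
        rows.append(
            {"protein_id": protein, "variance": var, "cv": cv,
             "passed": reason == "", "reason": reason}
        )
    report = QcReport(pd.DataFrame(rows))
    passed = report.table.loc[report.table["passed"], "protein_id"].tolist()
    if not passed:
        raise ValueError("all proteins removed by QC filters")
    if len(passed) == len(dataset.proteins):
        return dataset, report
    return dataset.subset_proteins(passed), report


def validate_complete_visits(dataset: LongitudinalDataset) -> LongitudinalDataset:
    """Retain only subjects observed for every protein at all visits.

    Returns a dataset in which every subject has a value for each
    (protein, visit) pair; drops the rest and logs the count.
    """
    expected = dataset.n_proteins * N_VISITS
    counts = dataset.observations.groupby("subject_id").size()
    complete = counts[counts == expected].index.tolist()
    dropped = dataset.n_subjects - len(complete)
    if not complete:
        raise ValueError("no subject has complete visit data")
    if dropped:
        logger.info("dropped %d subjects lacking complete visit data", dropped)
        return dataset.subset_subjects(complete)
    return dataset
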