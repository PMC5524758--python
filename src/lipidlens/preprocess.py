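"""Feature-table container and the preprocessing pipeline.

Pipeline order follows the reference workflow: relative-mass-defect
filter, >20% missingness filter, split of internal-standard channels,
mean imputation, internal-standard normalization, Pareto scaling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nomenclature import parse_primary_id

__all__ = [
    "FeatureTable",
    "ProcessingReport",
    "relative_mass_defect",
    "rmd_filter",
    "missingness_filter",
    "mean_impute",
    "is_normalize",
    "pareto_scale",
    "qc_cv",
    "preprocess",
    "DEFAULT_IS_NAME",
]

DEFAULT_IS_NAME = "PC(8:0/8:0)"


@dataclass
class FeatureTable:
    """Sample x ion abundance matrix with ion and sample metadata.

    ``abundances``: DataFrame (samples x ions), NaN marks missing values.
    ``ion_meta``: DataFrame indexed by ion name with columns
    ``retention_time``, ``mz``, ``is_internal_standard``.
    ``sample_meta``: DataFrame indexed by sample id with columns
    ``injection_order``, ``is_qc``.
    """

    abundances: pd.DataFrame
    ion_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.abundances.columns.has_duplicates:
            dupes = self.abundances.columns[self.abundances.columns.duplicated()].tolist()
            raise ValueError(f"duplicate ion names: {dupes[:5]}")
        if not self.abundances.columns.equals(self.ion_meta.index):
            raise ValueError("abundance columns and ion_meta index differ")
        if not self.abundances.index.equals(self.sample_meta.index):
            raise ValueError("abundance rows and sample_meta index differ")
        analyte = ~self.ion_meta["is_internal_standard"].to_numpy(dtype=bool)
        if (self.ion_meta.loc[analyte, "retention_time"] < 0).any():
            raise ValueError("negative retention time")
        if (self.ion_meta.loc[analyte, "mz"] <= 0).any():
            raise ValueError("non-positive m/z")
        is_cols = self.ion_meta.index[~analyte]
        if len(is_cols) and self.abundances[is_cols].isna().any().any():
            raise ValueError("internal-standard channels must have no missing values")

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.abundances.shape[0]

    @property
    def n_ions(self) -> int:
        return self.abundances.shape[1]

    @property
    def is_names(self) -> list[str]:
        flags = self.ion_meta["is_internal_standard"].to_numpy(dtype=bool)
        return list(self.ion_meta.index[flags])

    def analyte_matrix(self) -> pd.DataFrame:
        """Abundances restricted to non-IS ions and non-QC samples."""
        keep_rows = ~self.sample_meta["is_qc"].to_numpy(dtype=bool)
        flags = self.ion_meta["is_internal_standard"].to_numpy(dtype=bool)
        return self.abundances.loc[keep_rows, self.ion_meta.index[~flags]]

    def subset_ions(self, names) -> "FeatureTable":
        names = pd.Index(names)
        return FeatureTable(self.abundances[names], self.ion_meta.loc[names], self.sample_meta)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.abundances.copy(), self.ion_meta.copy(), self.sample_meta.copy())

    # -- I/O --------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """One CSV: sample metadata columns first, then ion columns."""
        out = pd.concat([self.sample_meta, self.abundances], axis=1)
        out.to_csv(path, index=True)

    @classmethod
    def from_csv(cls, path: str | Path, ion_meta: pd.DataFrame | None = None) -> "FeatureTable":
        """Read the CSV written by :meth:`to_csv`.

        Without a sidecar ``ion_meta``, analyte metadata is parsed from the
        ``X<rt>_<mz>`` column names and unparsable columns are flagged as
        internal standards.
        """
        raw = pd.read_csv(path, index_col=0)
        meta_cols = [c for c in ("injection_order", "is_qc") if c in raw.columns]
        sample_meta = raw[meta_cols].copy()
        if "injection_order" not in sample_meta:
            sample_meta["injection_order"] = np.arange(len(raw))
        if "is_qc" not in sample_meta:
            sample_meta["is_qc"] = False
        sample_meta["is_qc"] = sample_meta["is_qc"].astype(bool)
        abundances = raw.drop(columns=meta_cols)
        if ion_meta is None:
            rows = []
            for name in abundances.columns:
                try:
                    rt, mz = parse_primary_id(name)
                    rows.append((rt, mz, False))
                except ValueError:
                    rows.append((0.0, np.nan, True))
            ion_meta = pd.DataFrame(
                rows, columns=["retention_time", "mz", "is_internal_standard"],
                index=abundances.columns,
            )
        return cls(abundances, ion_meta, sample_meta)


@dataclass
class ProcessingReport:
    """Accounting of the preprocessing pipeline; the identity
    ``n_input_ions = n_rmd_excluded + n_missing_excluded + n_is_split + n_retained``
    must always hold."""

    n_input_ions: int = 0
    n_rmd_excluded: int = 0
    n_missing_excluded: int = 0
    n_is_split: int = 0
    n_retained: int = 0
    qc_cv_per_ion: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def check_identity(self) -> None:
        total = self.n_rmd_excluded + self.n_missing_excluded + self.n_is_split + self.n_retained
        if total != self.n_input_ions:
            raise AssertionError(
                f"pipeline accounting broken: {self.n_input_ions} != "
                f"{self.n_rmd_excluded}+{self.n_missing_excluded}+{self.n_is_split}+{self.n_retained}"
            )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_input_ions": self.n_input_ions,
            "n_rmd_excluded": self.n_rmd_excluded,
            "n_missing_excluded": self.n_missing_excluded,
            "n_is_split": self.n_is_split,
            "n_retained": self.n_retained,
            "qc_cv_per_ion": self.qc_cv_per_ion,
            "notes": self.notes,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def relative_mass_defect(mz: float | np.ndarray) -> float | np.ndarray:
    """Relative mass defect in ppm: (mz - floor(mz)) / mz * 1e6."""
    arr = np.asarray(mz, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("m/z must be positive")
    out = (arr - np.floor(arr)) / arr * 1e6
    return float(out) if np.isscalar(mz) or arr.ndim == 0 else out


def rmd_filter(
    table: FeatureTable, low: float = 350.0, high: float = 950.0
) -> tuple[FeatureTable, list[str]]:
    """Retain ions with RMD in the closed interval [low, high] ppm.

    Internal-standard channels are exempt; they are separated later.
    """
    if low >= high:
        raise ValueError(f"low bound {low} must be below high bound {high}")
    is_flag = table.ion_meta["is_internal_standard"].to_numpy(dtype=bool)
    rmd = relative_mass_defect(table.ion_meta["mz"].to_numpy(dtype=float)[~is_flag])
    analyte_names = table.ion_meta.index[~is_flag]
    keep_analytes = analyte_names[(rmd >= low) & (rmd <= high)]
    excluded = [n for n in analyte_names if n not in set(keep_analytes)]
    keep = [n for n in table.ion_meta.index if n in set(keep_analytes) or n in set(table.is_names)]
    return table.subset_ions(keep), excluded


def missingness_filter(
    table: FeatureTable, max_missing: float = 0.20
) -> tuple[FeatureTable, list[str]]:
    """Drop ions whose missing fraction strictly exceeds ``max_missing``."""
    frac = table.abundances.isna().mean(axis=0)
    excluded = list(frac.index[frac > max_missing])
    keep = [n for n in table.ion_meta.index if n not in set(excluded)]
    return table.subset_ions(keep), excluded


def split_internal_standards(table: FeatureTable) -> tuple[FeatureTable, FeatureTable]:
    """Separate IS channels from the analyte table; returns (analytes, standards)."""
    is_names = set(table.is_names)
    analyte = [n for n in table.ion_meta.index if n not in is_names]
    return table.subset_ions(analyte), table.subset_ions(sorted(is_names))


def mean_impute(table: FeatureTable) -> FeatureTable:
    """Replace each missing cell by the ion's observed mean."""
    values = table.abundances
    all_missing = values.isna().all(axis=0)
    if all_missing.any():
        raise ValueError(
            f"ions with no observed values (filter first): {list(values.columns[all_missing])[:5]}"
        )
    filled = values.fillna(values.mean(axis=0))
    return FeatureTable(filled, table.ion_meta.copy(), table.sample_meta.copy())


def is_normalize(
    table: FeatureTable,
    standards: FeatureTable | None = None,
    is_name: str = DEFAULT_IS_NAME,
) -> FeatureTable:
    """Divide every abundance by the sample's named IS signal.

    The IS channel may live in ``table`` itself or in the ``standards``
    table split off earlier; IS channels are removed from the result.
    """
    source = None
    if is_name in table.abundances.columns:
        source = table.abundances[is_name]
    elif standards is not None and is_name in standards.abundances.columns:
        source = standards.abundances[is_name]
    if source is None:
        raise ValueError(f"internal standard {is_name!r} not found")
    source = source.reindex(table.abundances.index)
    bad = source.index[(source.isna()) | (source <= 0)]
    if len(bad):
        raise ValueError(
            f"IS {is_name!r} missing or non-positive in samples: {list(bad)[:5]}"
        )
    normalized = table.abundances.div(source, axis=0)
    keep = [c for c in normalized.columns if c not in set(table.is_names)]
    return FeatureTable(
        normalized[keep], table.ion_meta.loc[keep].copy(), table.sample_meta.copy()
    )


def pareto_scale(table: FeatureTable) -> FeatureTable:
    """Center each ion and divide by the square root of its standard deviation."""
    values = table.abundances
    if values.isna().any().any():
        raise ValueError("Pareto scaling requires a complete matrix (impute first)")
    sd = values.std(axis=0, ddof=1)
    zero = list(sd.index[sd == 0])
    if zero:
        raise ValueError(f"zero-variance ions cannot be Pareto scaled: {zero[:5]}")
    scaled = (values - values.mean(axis=0)) / np.sqrt(sd)
    return FeatureTable(scaled, table.ion_meta.copy(), table.sample_meta.copy())


def qc_cv(table: FeatureTable) -> pd.Series:
    """Per-ion coefficient of variation (%) over QC injections."""
    qc_rows = table.sample_meta["is_qc"].to_numpy(dtype=bool)
    if qc_rows.sum() < 2:
        raise ValueError("need at least 2 QC samples to compute CV")
    qc = table.abundances.loc[qc_rows]
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    return (sd / mean * 100.0).rename("qc_cv_percent")


def preprocess(
    table: FeatureTable,
    is_name: str = DEFAULT_IS_NAME,
    rmd_low: float = 350.0,
    rmd_high: float = 950.0,
    max_missing: float = 0.20,
    pareto: bool = True,
) -> tuple[FeatureTable, ProcessingReport]:
    """Full pipeline: RMD filter, missingness filter, IS split, mean
    imputation, IS normalization, optional Pareto scaling."""
    report = ProcessingReport(n_input_ions=table.n_ions)

    table, rmd_excluded = rmd_filter(table, rmd_low, rmd_high)
    report.n_rmd_excluded = len(rmd_excluded)

    table, miss_excluded = missingness_filter(table, max_missing)
    report.n_missing_excluded = len(miss_excluded)

    analytes, standards = split_internal_standards(table)
    report.n_is_split = standards.n_ions
    report.n_retained = analytes.n_ions

    analytes = mean_impute(analytes)
    analytes = is_normalize(analytes, standards, is_name=is_name)

    try:
        report.qc_cv_per_ion = qc_cv(analytes).to_dict()
    except ValueError:
        report.notes.append("fewer than 2 QC samples; QC CV not computed")

    if pareto:
        # Pareto scaling is meaningful on subject rows; QC rows are dropped here
        subjects = ~analytes.sample_meta["is_qc"].to_numpy(dtype=bool)
        analytes = FeatureTable(
            analytes.abundances.loc[subjects],
            analytes.ion_meta.copy(),
            analytes.sample_meta.loc[subjects],
        )
        analytes = pareto_scale(analytes)

    report.check_identity()
    return analytes, report
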