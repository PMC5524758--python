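"""Synthetic cohorts, feature tables, traits, and MS/MS spectra with known truth.

Everything here is deterministic under a fixed seed. Abundances are
log-normal per ion; injection-order drift is multiplicative and shared
exactly between internal-standard (IS) channels and analytes so that IS
normalization is exactly corrective; missingness is MCAR with per-ion
counts assigned exactly so downstream filter accounting is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import masses
from .nomenclature import parse_lipid_name, primary_id
from .preprocess import FeatureTable
from .spectra import MsmsSpectrum

__all__ = [
    "CohortSpec",
    "FeaturePanelSpec",
    "TraitGenSpec",
    "generate_cohort",
    "generate_feature_table",
    "generate_traits",
    "generate_msms_spectrum",
]


@dataclass
class CohortSpec:
    """Cohort of middle-aged male subjects with age and smoking covariates."""

    n_subjects: int = 126
    age_mean: float = 56.9
    age_sd: float = 4.7
    age_range: tuple[float, float] = (48.0, 65.0)
    smoking_probs: tuple[float, float, float] = (0.2540, 0.5714, 0.1746)  # ever, never, unknown
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")
        if abs(sum(self.smoking_probs) - 1.0) > 1e-9 or any(p < 0 for p in self.smoking_probs):
            raise ValueError(f"smoking_probs must be non-negative and sum to 1, got {self.smoking_probs}")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("invalid age range")


SMOKING_LEVELS = ("ever", "never", "unknown")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Covariate table: one row per subject with truncated-normal age and smoking."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    from scipy.stats import truncnorm

    lo, hi = spec.age_range
    a, b = (lo - spec.age_mean) / spec.age_sd, (hi - spec.age_mean) / spec.age_sd
    ages = truncnorm.rvs(a, b, loc=spec.age_mean, scale=spec.age_sd,
                         size=spec.n_subjects, random_state=rng)
    smoking = rng.choice(SMOKING_LEVELS, size=spec.n_subjects, p=spec.smoking_probs)
    index = pd.Index([f"S{i + 1:03d}" for i in range(spec.n_subjects)], name="subject")
    return pd.DataFrame({"age": ages, "smoking": pd.Categorical(smoking, categories=SMOKING_LEVELS)},
                        index=index)


@dataclass
class FeaturePanelSpec:
    """Shape and noise structure of the simulated ion panel."""

    n_ions: int = 4802
    n_internal_standards: int = 10
    # fraction of analyte ions with relative mass defect inside [350, 950] ppm;
    # default mirrors the reference pipeline accounting (2871 of 4792 in range)
    rmd_in_range_fraction: float = 2871 / 4792
    # fraction of all ions assigned >20% missingness (default: 1126 of 4802)
    missing_fraction_high: float = 1126 / 4802
    high_missing_rate: float = 0.35
    max_low_missing_rate: float = 0.15
    drift_magnitude: float = 0.3
    abundance_log_sd: float = 0.5
    # latent subject-level factors induce the strong inter-ion correlation seen
    # in real lipid panels (and give the similarity kernel its structure)
    n_latent_factors: int = 8
    factor_sd: float = 1.0
    n_qc: int = 13
    qc_noise_cv: float = 0.04
    seed: int = 0

    def validate(self) -> None:
        if self.n_internal_standards >= self.n_ions:
            raise ValueError("n_internal_standards must be < n_ions")
        for name in ("rmd_in_range_fraction", "missing_fraction_high",
                     "high_missing_rate", "max_low_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.high_missing_rate <= 0.20 and self.missing_fraction_high > 0:
            raise ValueError("high_missing_rate must exceed the 20% cut")
        if self.max_low_missing_rate > 0.20:
            raise ValueError("max_low_missing_rate must not exceed the 20% cut")
        n_high = round(self.missing_fraction_high * self.n_ions)
        n_analytes = self.n_ions - self.n_internal_standards
        n_in_range = round(self.rmd_in_range_fraction * n_analytes)
        if n_high > n_in_range:
            raise ValueError("more high-missingness ions requested than RMD-in-range analytes")


def _draw_mz(rng: np.random.Generator, n: int, in_range: bool) -> np.ndarray:
    """m/z values whose relative mass defect is inside (or outside) [350, 950] ppm.

    The integer part stays below 1000 so the fractional part implied by the
    target RMD never reaches 1.
    """
    base = rng.integers(150, 1000, size=n).astype(float)
    if in_range:
        rmd = rng.uniform(360.0, 940.0, size=n)
    else:
        rmd = rng.uniform(20.0, 300.0, size=n)
    return base / (1.0 - rmd * 1e-6)


def generate_feature_table(spec: FeaturePanelSpec, cohort: pd.DataFrame) -> FeatureTable:
    """Sample x ion abundance table with drift, exact missingness, IS channels, QC rows."""
    spec.validate()
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    rng = np.random.default_rng(spec.seed)

    n_is = spec.n_internal_standards
    n_analytes = spec.n_ions - n_is
    n_in_range = round(spec.rmd_in_range_fraction * n_analytes)
    n_high = round(spec.missing_fraction_high * spec.n_ions)

    # ion metadata: analytes named by rt/mz; first IS is the normalization channel
    while True:
        mz = np.concatenate([
            _draw_mz(rng, n_in_range, True),
            _draw_mz(rng, n_analytes - n_in_range, False),
        ])
        rt = rng.uniform(0.5, 15.0, size=n_analytes)
        names = [primary_id(r, m) for r, m in zip(rt, mz)]
        if len(set(names)) == n_analytes:
            break
    is_names = ["PC(8:0/8:0)"] + [f"IS_{k:02d}" for k in range(2, n_is + 1)]
    is_mz = _draw_mz(rng, n_is, True)
    is_rt = rng.uniform(0.5, 15.0, size=n_is)

    ion_meta = pd.DataFrame(
        {
            "retention_time": np.concatenate([rt, is_rt]),
            "mz": np.concatenate([mz, is_mz]),
            "is_internal_standard": [False] * n_analytes + [True] * n_is,
        },
        index=pd.Index(names + is_names, name="ion"),
    )

    # samples: subjects with QC injections appended, injection order interleaved
    n_sub = len(cohort)
    n_rows = n_sub + spec.n_qc
    sample_ids = list(cohort.index) + [f"QC{k + 1:02d}" for k in range(spec.n_qc)]
    order = rng.permutation(n_rows)
    sample_meta = pd.DataFrame(
        {"injection_order": order, "is_qc": [False] * n_sub + [True] * spec.n_qc},
        index=pd.Index(sample_ids, name="sample"),
    )

    # multiplicative injection-order drift, shared by all channels
    if spec.drift_magnitude != 0.0 and n_rows > 1:
        drift = np.exp(spec.drift_magnitude * (order / (n_rows - 1) - 0.5))
    else:
        drift = np.ones(n_rows)

    base = np.exp(rng.normal(np.log(1e5), 1.2, size=n_analytes))
    log_noise = rng.normal(0.0, spec.abundance_log_sd, size=(n_sub, n_analytes))
    if spec.n_latent_factors > 0 and spec.factor_sd > 0:
        loadings = rng.normal(0.0, 1.0, size=(spec.n_latent_factors, n_analytes))
        factors = rng.normal(0.0, spec.factor_sd, size=(n_sub, spec.n_latent_factors))
        log_noise += factors @ loadings / np.sqrt(spec.n_latent_factors)
    noise = np.exp(log_noise)
    qc_noise = np.exp(rng.normal(0.0, spec.qc_noise_cv, size=(spec.n_qc, n_analytes)))
    analyte = base[None, :] * np.vstack([noise, qc_noise]) * drift[:, None]

    is_base = np.exp(rng.normal(np.log(5e5), 0.3, size=n_is))
    is_values = is_base[None, :] * drift[:, None]  # noise-free: exactly corrective

    values = np.hstack([analyte, is_values])

    # exact per-ion MCAR missingness; high-missingness ions are RMD-in-range
    # analytes so they survive the RMD filter and hit the >20% rule
    high_idx = rng.choice(n_in_range, size=n_high, replace=False)
    max_low = int(np.floor(spec.max_low_missing_rate * n_rows))
    n_high_cells = int(np.floor(spec.high_missing_rate * n_rows))
    if n_high_cells <= 0.20 * n_rows:
        n_high_cells = int(np.floor(0.20 * n_rows)) + 1
    for j in range(n_analytes):
        if j in set(high_idx):
            k = n_high_cells
        else:
            k = int(rng.integers(0, max_low + 1))
        if k:
            rows = rng.choice(n_rows, size=k, replace=False)
            values[rows, j] = np.nan

    abundances = pd.DataFrame(values, index=sample_meta.index, columns=ion_meta.index)
    return FeatureTable(abundances, ion_meta, sample_meta)


@dataclass
class TraitGenSpec:
    """Trait generated as covariate effects + lipidome effect + noise."""

    variance_fraction: float = 0.5
    n_causal_lipids: int = 0  # 0 -> diffuse effects on every lipid
    effect_size: float = 1.0
    age_slope: float = 0.0
    smoking_offsets: Mapping[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    trait_name: str = "trait"
    seed: int = 0

    def validate(self, n_ions: int) -> None:
        if not 0.0 <= self.variance_fraction < 1.0:
            raise ValueError(f"variance_fraction must be in [0, 1), got {self.variance_fraction}")
        if self.n_causal_lipids > n_ions:
            raise ValueError("n_causal_lipids exceeds the number of lipids")


def generate_traits(
    spec: TraitGenSpec, features: FeatureTable, cohort: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Simulate one trait over the cohort subjects.

    Returns ``(trait_frame, truth)`` where ``trait_frame`` contains the
    covariates plus the simulated trait column, and ``truth`` holds the
    per-lipid effects ``alpha``, the lipidome effect ``u``, the residuals
    ``eps`` and the realized variance fraction var(u)/(var(u)+var(eps)).
    """
    X = features.analyte_matrix().loc[cohort.index]
    spec.validate(X.shape[1])
    rng = np.random.default_rng(spec.seed)

    # standardize lipids for effect generation (missing -> column mean)
    Z = X.to_numpy(dtype=float).copy()
    col_mean = np.nanmean(Z, axis=0)
    nan_r, nan_c = np.where(np.isnan(Z))
    Z[nan_r, nan_c] = col_mean[nan_c]
    Z = Z - Z.mean(axis=0)
    sd = Z.std(axis=0)
    keep = sd > 0
    Z[:, keep] = Z[:, keep] / sd[keep]

    m = Z.shape[1]
    alpha = np.zeros(m)
    if spec.variance_fraction > 0.0:
        if spec.n_causal_lipids > 0:
            causal = rng.choice(np.flatnonzero(keep), size=spec.n_causal_lipids, replace=False)
            alpha[causal] = spec.effect_size * np.where(rng.random(spec.n_causal_lipids) < 0.5, -1, 1)
            background = rng.normal(0.0, spec.effect_size / 50.0, size=m)
            background[causal] = 0.0
            alpha += np.where(keep, background, 0.0)
        else:
            alpha = np.where(keep, rng.normal(0.0, 1.0, size=m), 0.0)

    u = Z @ alpha
    var_u = float(np.var(u))
    if spec.variance_fraction > 0.0 and var_u > 0:
        sigma2_eps = var_u * (1.0 - spec.variance_fraction) / spec.variance_fraction
    else:
        sigma2_eps = 1.0
    eps = rng.normal(0.0, np.sqrt(sigma2_eps), size=len(u))

    age = cohort["age"].to_numpy(dtype=float)
    smoke_shift = np.array(
        [spec.smoking_offsets.get(str(s), 0.0) for s in cohort["smoking"]]
    )
    y = spec.intercept + spec.age_slope * (age - age.mean()) + smoke_shift + u + eps

    frame = cohort.copy()
    frame[spec.trait_name] = y
    realized = float(np.var(u) / (np.var(u) + np.var(eps))) if np.var(u) + np.var(eps) > 0 else 0.0
    truth = {
        "alpha": pd.Series(alpha, index=X.columns, name="alpha"),
        "u": pd.Series(u, index=cohort.index, name="u"),
        "eps": pd.Series(eps, index=cohort.index, name="eps"),
        "sigma2_eps": sigma2_eps,
        "target_fraction": spec.variance_fraction,
        "realized_fraction": realized,
    }
    return frame, truth


# ---------------------------------------------------------------------------
# Synthetic MS/MS spectra
# ---------------------------------------------------------------------------

# m/z windows the noise generator must avoid so diagnostics stay unambiguous
_NOISE_GUARD = 0.08


def _protected_mz(precursor: float) -> np.ndarray:
    vals = [precursor, precursor - 60.0211, precursor - 87.0320, 140.0118, 241.0119]
    vals += [masses.fa_anion_mz(c, d) for c in range(12, 27) for d in range(0, 7)]
    vals += list(masses.ETHER_FRAGMENT_MZ.values())
    return np.asarray(vals)


def generate_msms_spectrum(
    lipid_name: str,
    adduct: str = masses.ADDUCT_M_MINUS_H,
    noise_peaks: int = 0,
    seed: int = 0,
    retention_time: float = 1.0,
) -> MsmsSpectrum:
    """Theoretical negative-mode spectrum for a supported lipid name.

    Contains the precursor, the head-group diagnostic peak/loss, one
    carboxylate anion per acyl chain (the ether diagnostic for O- chains),
    and ``noise_peaks`` random peaks kept away from every diagnostic window.
    """
    name = parse_lipid_name(lipid_name)
    neutral = masses.lipid_neutral_mass(name.head_group, name.chain_tuples)
    precursor = masses.adduct_mz(neutral, adduct)

    rng = np.random.default_rng(seed)
    peaks: list[tuple[float, float]] = [(precursor, 100.0)]

    root = name.head_group[-2:] if name.head_group.startswith("L") else name.head_group
    if root != "FA":
        rule = masses.headgroup_diagnostics()[root]
        diag = precursor - float(rule["mass"]) if rule["kind"] == "loss" else float(rule["mass"])
        peaks.append((diag, 50.0))

    for chain in name.chains:
        if chain.linkage == "ether":
            peaks.append((masses.ether_fragment_mz(chain.carbons, chain.double_bonds), 60.0))
        elif root != "FA":
            peaks.append((masses.fa_anion_mz(chain.carbons, chain.double_bonds), 80.0))

    protected = _protected_mz(precursor)
    added = 0
    while added < noise_peaks:
        cand = rng.uniform(80.0, max(precursor - 2.0, 120.0))
        if np.min(np.abs(protected - cand)) > _NOISE_GUARD:
            peaks.append((cand, float(rng.uniform(1.0, 30.0))))
            added += 1

    return MsmsSpectrum(
        precursor_mz=precursor,
        peaks=np.array(peaks),
        polarity="negative",
        retention_time=retention_time,
        title=str(name),
        metadata={"adduct": adduct},
    )
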