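"""Single-lipid trait regressions with multiplicity control, plus the
cohort summary, significance-overlap sets, and the targeted FA
cross-reference regression.

Each lipid is tested in its own ordinary least squares model
``trait ~ age + smoking + lipid``; per trait, p-values for the lipid
effect are adjusted by Benjamini-Hochberg and Bonferroni over all lipids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import FeatureTable

__all__ = [
    "TRAIT_TRANSFORMS",
    "transform_trait",
    "smoking_design",
    "fit_single_lipid",
    "run_all_regressions",
    "bh_fdr",
    "bonferroni",
    "venn_overlaps",
    "cohort_summary",
    "fame_crossref",
    "RegressionRecord",
]

# trait -> transform flag; log for the serum markers, identity otherwise
TRAIT_TRANSFORMS: Mapping[str, str] = {
    "bmi": "identity",
    "wc": "identity",
    "leptin": "log",
    "adiponectin": "log",
    "c_peptide": "log",
    "il6": "log",
    "tnf_alpha": "log",
    "ip10": "log",
    "mcp1": "identity",
}


def transform_trait(values: pd.Series, transform: str) -> pd.Series:
    """Apply the declared transform; log uses an offset of the smallest
    positive observed value when zeros are present (keeps the map total)."""
    if transform == "identity":
        return values.astype(float)
    if transform != "log":
        raise ValueError(f"unknown transform {transform!r}")
    v = values.astype(float)
    if (v < 0).any():
        raise ValueError(f"negative values in {values.name!r} cannot be log transformed")
    if (v == 0).any():
        positive = v[v > 0]
        if positive.empty:
            raise ValueError(f"trait {values.name!r} is all zero")
        v = v + positive.min()
    return np.log(v)


def smoking_design(smoking: pd.Series) -> np.ndarray:
    """Dummy columns for smoking with 'never' as the reference level.

    Levels absent from the data contribute no column (keeps the design
    full rank on small subsets).
    """
    s = smoking.astype(str)
    cols = [(s == level).to_numpy(dtype=float) for level in ("ever", "unknown")
            if (s == level).any()]
    if not cols:
        return np.empty((len(s), 0))
    return np.column_stack(cols)


@dataclass
class RegressionRecord:
    ion: str
    trait: str
    effect: float
    se: float
    p_raw: float
    df_resid: int
    p_bh: float = np.nan
    p_bonferroni: float = np.nan
    ok: bool = True


def _covariate_matrix(covariates: pd.DataFrame) -> np.ndarray:
    cols = [np.ones(len(covariates)), covariates["age"].to_numpy(dtype=float)]
    W = np.column_stack(cols + [smoking_design(covariates["smoking"])])
    return W


def fit_single_lipid(
    trait: pd.Series, covariates: pd.DataFrame, lipid: pd.Series, ion: str = "", trait_name: str = ""
) -> RegressionRecord:
    """OLS of the (transformed) trait on age + smoking + one lipid.

    The reported effect and two-sided t-test concern the lipid coefficient.
    Rank-deficient fits (e.g. a constant lipid) yield a flagged record with
    NaN statistics rather than an exception.
    """
    y = trait.to_numpy(dtype=float)
    W = _covariate_matrix(covariates)
    x = lipid.to_numpy(dtype=float)
    if np.isnan(y).any() or np.isnan(x).any():
        raise ValueError("missing values in trait or lipid")
    X = np.column_stack([W, x])
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} observations, got {n}")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    df_resid = n - p
    record = RegressionRecord(ion or lipid.name, trait_name or str(trait.name),
                              np.nan, np.nan, np.nan, df_resid, ok=False)
    if rank < p:
        return record
    resid = y - X @ beta
    sigma2 = resid @ resid / df_resid
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
    effect = float(beta[-1])
    t = effect / se
    p_raw = float(2.0 * stats.t.sf(abs(t), df_resid))
    record.effect, record.se, record.p_raw, record.ok = effect, se, p_raw, True
    return record


def _batch_lipid_stats(
    y: np.ndarray, W: np.ndarray, L: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Vectorized per-lipid OLS via Frisch-Waugh-Lovell residualization.

    Returns (effects, ses, raw p-values, residual df); columns of ``L``
    that are collinear with the covariates come back NaN.
    """
    n, p_w = W.shape
    H = W @ np.linalg.solve(W.T @ W, W.T)
    y_t = y - H @ y
    L_t = L - H @ L
    ltl = np.einsum("ij,ij->j", L_t, L_t)
    df_resid = n - p_w - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (L_t.T @ y_t) / ltl
        ssr = y_t @ y_t - beta**2 * ltl
        sigma2 = ssr / df_resid
        se = np.sqrt(sigma2 / ltl)
        tstat = beta / se
    bad = ltl <= max(1e-12, 1e-10 * n)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df_resid)
    beta[bad] = np.nan
    se[bad] = np.nan
    pvals[bad] = np.nan
    return beta, se, pvals, df_resid


def run_all_regressions(
    traits: pd.DataFrame,
    table: FeatureTable,
    trait_names: Sequence[str] | None = None,
    transforms: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All lipids x all traits single-lipid regressions.

    Returns ``(records, effect_matrix)``: a long DataFrame with one row per
    (ion, trait) carrying effect, raw/BH/Bonferroni p-values, and the
    lipids x traits matrix of effects feeding the SVD biplot.
    """
    transforms = dict(TRAIT_TRANSFORMS) if transforms is None else dict(transforms)
    if trait_names is None:
        trait_names = [c for c in traits.columns if c not in ("age", "smoking")]
    missing = [t for t in trait_names if t not in traits.columns]
    if missing:
        raise ValueError(f"traits not found: {missing}")

    L_frame = table.analyte_matrix().loc[traits.index]
    if L_frame.isna().any().any():
        raise ValueError("feature table has missing values; preprocess first")
    L = L_frame.to_numpy(dtype=float)
    W = _covariate_matrix(traits)

    rows = []
    effects = {}
    for trait in trait_names:
        y = transform_trait(traits[trait], transforms.get(trait, "identity")).to_numpy(dtype=float)
        beta, se, pvals, df_resid = _batch_lipid_stats(y, W, L)
        finite = ~np.isnan(pvals)
        p_bh = np.full_like(pvals, np.nan)
        p_bonf = np.full_like(pvals, np.nan)
        p_bh[finite] = bh_fdr(pvals[finite])
        p_bonf[finite] = bonferroni(pvals[finite])
        effects[trait] = beta
        rows.append(
            pd.DataFrame(
                {
                    "ion": L_frame.columns,
                    "trait": trait,
                    "effect": beta,
                    "se": se,
                    "p_raw": pvals,
                    "p_bh": p_bh,
                    "p_bonferroni": p_bonf,
                    "df_resid": df_resid,
                }
            )
        )
    records = pd.concat(rows, ignore_index=True)
    effect_matrix = pd.DataFrame(effects, index=L_frame.columns)
    return records, effect_matrix


def bh_fdr(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (with monotonicity)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def bonferroni(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(p * p.size, 1.0)


@dataclass
class OverlapResult:
    significant: dict[str, set] = field(default_factory=dict)
    intersections: dict[tuple, int] = field(default_factory=dict)
    exclusive_regions: dict[tuple, int] = field(default_factory=dict)


def venn_overlaps(
    records: pd.DataFrame,
    traits: Sequence[str],
    threshold: str = "p_bh",
    alpha: float = 0.05,
) -> OverlapResult:
    """Significant-ion sets per trait and every intersection region count.

    ``intersections`` maps each non-empty trait subset to the size of the
    plain intersection of its sets; ``exclusive_regions`` to the size of the
    Venn region belonging to exactly that subset.
    """
    if threshold not in ("p_raw", "p_bh", "p_bonferroni"):
        raise ValueError(f"unknown threshold column {threshold!r}")
    unknown = [t for t in traits if t not in set(records["trait"])]
    if unknown:
        raise ValueError(f"traits not present in records: {unknown}")
    sets = {
        t: set(records.loc[(records["trait"] == t) & (records[threshold] < alpha), "ion"])
        for t in traits
    }
    result = OverlapResult(significant=sets)
    universe = set().union(*sets.values()) if sets else set()
    for r in range(1, len(traits) + 1):
        for subset in combinations(traits, r):
            inter = set.intersection(*(sets[t] for t in subset))
            result.intersections[subset] = len(inter)
            others = universe - set().union(*(sets[t] for t in traits if t not in subset)) \
                if len(subset) < len(traits) else universe
            exclusive = inter & others if len(subset) < len(traits) else inter
            result.exclusive_regions[subset] = len(exclusive)
    return result


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise z-tests with tie correction."""
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g in labels:
        k = len(groups[g])
        mean_ranks[g] = ranks[start:start + k].mean()
        sizes[g] = k
        start += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for a, b in combinations(labels, 2):
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": 2.0 * stats.norm.sf(abs(z))})
    out = pd.DataFrame(rows)
    out["p_bh"] = bh_fdr(out["p_raw"].to_numpy())
    return out


def _compact_letters(labels: Sequence[str], significant_pairs: set[frozenset]) -> dict[str, str]:
    """Compact letter display: groups share a letter iff not significantly different."""
    letter_sets: list[set] = []
    for g in labels:
        placed = False
        for s in letter_sets:
            if all(frozenset((g, other)) not in significant_pairs for other in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    alphabet = "ABCDEFGHIJ"
    letters = {g: "" for g in labels}
    for i, s in enumerate(letter_sets):
        for g in s:
            letters[g] += alphabet[i]
    return letters


def cohort_summary(
    traits: pd.DataFrame,
    parameters: Sequence[str] | None = None,
    bmi_column: str = "bmi",
    bins: tuple[float, float] = (25.0, 30.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median [range] by BMI category with Kruskal-Wallis and Dunn tests.

    Categories: lean (BMI < bins[0]), overweight (bins[0] <= BMI < bins[1]),
    obese (BMI >= bins[1]). Kruskal-Wallis p-values are BH adjusted across
    parameters; Dunn pairwise p-values are BH adjusted within parameter and
    summarized as a compact letter display.
    """
    if bmi_column not in traits.columns:
        raise ValueError(f"no {bmi_column!r} column")
    if parameters is None:
        parameters = [c for c in traits.columns if c != "smoking"]
    bmi = traits[bmi_column].to_numpy(dtype=float)
    cat = np.where(bmi < bins[0], "lean", np.where(bmi < bins[1], "overweight", "obese"))
    order = ["lean", "overweight", "obese"]

    summary_rows, pairwise_rows, kw_pvals = [], [], []
    for param in parameters:
        values = traits[param].to_numpy(dtype=float)
        groups = {g: values[cat == g] for g in order if (cat == g).sum() >= 2}
        row: dict = {"parameter": param}
        row["overall"] = f"{np.median(values):g} [{values.min():g}-{values.max():g}]"
        for g in order:
            gv = values[cat == g]
            row[g] = f"{np.median(gv):g} [{gv.min():g}-{gv.max():g}]" if len(gv) else ""
        if len(groups) >= 2 and all(np.ptp(v) > 0 for v in groups.values()):
            kw_stat, kw_p = stats.kruskal(*groups.values())
            dunn = _dunn_pairwise(groups)
            sig = {
                frozenset((a, b))
                for a, b, p in zip(dunn["group_a"], dunn["group_b"], dunn["p_bh"])
                if p < 0.05
            }
            letters = _compact_letters(list(groups), sig)
            for g, letter in letters.items():
                row[f"{g}_letter"] = letter
            dunn.insert(0, "parameter", param)
            pairwise_rows.append(dunn)
        else:
            kw_stat, kw_p = np.nan, np.nan
        row["kw_statistic"] = kw_stat
        row["kw_p_raw"] = kw_p
        kw_pvals.append(kw_p)
        summary_rows.append(row)

    summary = pd.DataFrame(summary_rows)
    finite = ~pd.isna(summary["kw_p_raw"])
    summary["kw_p_bh"] = np.nan
    if finite.any():
        summary.loc[finite, "kw_p_bh"] = bh_fdr(summary.loc[finite, "kw_p_raw"].to_numpy())
    pairwise = pd.concat(pairwise_rows, ignore_index=True) if pairwise_rows else pd.DataFrame()
    return summary, pairwise


def fame_crossref(
    pl_abundance: pd.Series, fa_percent: pd.Series, bmi: pd.Series
) -> dict:
    """log(plasma PL) ~ log(% FA isomer) + BMI, plus the Spearman correlation.

    Returns effect/se/p for the log(%FA) term and the companion rho.
    """
    pl = pl_abundance.to_numpy(dtype=float)
    fa = fa_percent.to_numpy(dtype=float)
    b = bmi.to_numpy(dtype=float)
    if not (len(pl) == len(fa) == len(b)):
        raise ValueError("inputs must have equal length")
    if np.any(pl <= 0) or np.any(fa <= 0):
        raise ValueError("log transform requires strictly positive PL and FA values")
    X = np.column_stack([np.ones(len(pl)), np.log(fa), b])
    y = np.log(pl)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("design is rank deficient")
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = float(np.sqrt(cov[1, 1]))
    t = beta[1] / se
    rho, rho_p = stats.spearmanr(fa, pl)
    return {
        "effect": float(beta[1]),
        "se": se,
        "p": float(2.0 * stats.t.sf(abs(t), df)),
        "spearman_rho": float(rho),
        "spearman_p": float(rho_p),
        "df_resid": df,
    }
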