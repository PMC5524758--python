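"""Cross-product PCA of the lipid abundance matrix and the SVD biplot of
the lipids x traits effect matrix."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import FeatureTable
from .regression import _covariate_matrix

__all__ = [
    "PcaResult",
    "BiplotResult",
    "crossproduct_pca",
    "regress_trait_on_pc",
    "regress_pc_on_lipids",
    "effect_biplot",
]


@dataclass
class PcaResult:
    eigenvalues: np.ndarray  # descending, length n
    percent_total_variation: np.ndarray
    scores: pd.DataFrame  # samples x components, columns Pc1..Pcn

    def score(self, k: int) -> pd.Series:
        """1-based component score vector (Pc1 is the leading component)."""
        return self.scores[f"Pc{k}"]


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each column positive (reproducible signs)."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def crossproduct_pca(table: FeatureTable | pd.DataFrame) -> PcaResult:
    """Eigen-decomposition of the n x n sample cross-product of the
    (processed) lipid matrix; scores equal U*D of the matrix SVD up to sign."""
    X_frame = table.analyte_matrix() if isinstance(table, FeatureTable) else table
    if X_frame.isna().any().any():
        raise ValueError("matrix has missing values; preprocess first")
    X = X_frame.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    G = X @ X.T
    eigenvalues, vectors = np.linalg.eigh(G)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = np.clip(eigenvalues[order], 0.0, None)
    vectors = vectors[:, order]
    scores = _fix_signs(vectors * np.sqrt(eigenvalues)[None, :])
    percent = eigenvalues / eigenvalues.sum() * 100.0
    return PcaResult(
        eigenvalues=eigenvalues,
        percent_total_variation=percent,
        scores=pd.DataFrame(
            scores, index=X_frame.index, columns=[f"Pc{k}" for k in range(1, n + 1)]
        ),
    )


def regress_trait_on_pc(
    trait: pd.Series,
    covariates: pd.DataFrame,
    pca: PcaResult,
    k: int,
    n_tested: int = 10,
) -> dict:
    """OLS of the trait on age + smoking + the k-th Pc score, Bonferroni
    corrected over the ``n_tested`` components examined."""
    if not 1 <= k <= pca.scores.shape[1]:
        raise ValueError(f"component {k} out of range")
    score = pca.score(k).loc[trait.index].to_numpy(dtype=float)
    y = trait.to_numpy(dtype=float)
    W = _covariate_matrix(covariates.loc[trait.index])
    X = np.column_stack([W, score])
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise ValueError("rank-deficient design (constant score?)")
    resid = y - X @ beta
    df = n - p
    sigma2 = resid @ resid / df
    se = float(np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[-1, -1]))
    t = beta[-1] / se
    p_raw = float(2.0 * stats.t.sf(abs(t), df))
    return {
        "component": k,
        "effect": float(beta[-1]),
        "se": se,
        "p_raw": p_raw,
        "p_bonferroni": min(1.0, p_raw * n_tested),
        "df_resid": df,
    }


def regress_pc_on_lipids(
    score: pd.Series, table: FeatureTable | pd.DataFrame, top: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-lipid simple OLS ``Pc_i = b0 + l_ij b1``, Bonferroni over lipids.

    Returns (all effects, top positive, top negative), the top lists ranked
    by signed effect.
    """
    L_frame = table.analyte_matrix() if isinstance(table, FeatureTable) else table
    L_frame = L_frame.loc[score.index]
    y = score.to_numpy(dtype=float)
    L = L_frame.to_numpy(dtype=float)
    n, m = L.shape
    yc = y - y.mean()
    Lc = L - L.mean(axis=0)
    ll = np.einsum("ij,ij->j", Lc, Lc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (Lc.T @ yc) / ll
        ssr = yc @ yc - beta**2 * ll
        df = n - 2
        sigma2 = ssr / df
        se = np.sqrt(sigma2 / ll)
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    bad = ll <= 1e-12
    beta[bad] = np.nan
    pvals[bad] = np.nan
    out = pd.DataFrame(
        {
            "effect": beta,
            "se": se,
            "p_raw": pvals,
            "p_bonferroni": np.minimum(pvals * m, 1.0),
        },
        index=L_frame.columns,
    )
    ranked = out.dropna(subset=["effect"]).sort_values("effect")
    return out, ranked.tail(top).iloc[::-1], ranked.head(top)


@dataclass
class BiplotResult:
    lipid_coords: pd.DataFrame  # lipids x (v1, v2), points = U * D
    trait_coords: pd.DataFrame  # traits x (v1, v2), arrows = V
    percent_variance_12: float
    radius_raw: pd.Series
    radius_normalized: pd.Series
    highlighted: pd.Series  # normalized radius > threshold
    singular_values: np.ndarray = field(default_factory=lambda: np.array([]))
    display_coords: pd.DataFrame | None = None


def effect_biplot(
    effects: pd.DataFrame,
    highlight_radius: float = 0.15,
    display_scale: dict[str, float] | None = None,
) -> BiplotResult:
    """SVD biplot of the lipids x traits effect matrix.

    Lipid points are the first two left singular vectors scaled by their
    singular values; trait arrows are the right singular vectors. Radii and
    highlight flags are computed before any display scaling; per-trait
    ``display_scale`` factors touch only ``display_coords``.
    """
    if effects.shape[1] < 2:
        raise ValueError("need at least 2 traits for a biplot")
    B = effects.to_numpy(dtype=float)
    if np.isnan(B).any():
        warnings.warn("NaN effects replaced by 0 in the biplot matrix", stacklevel=2)
        B = np.nan_to_num(B, nan=0.0)
    U, D, Vt = np.linalg.svd(B, full_matrices=False)
    # reproducible signs: largest-|.| loading of each right vector positive
    sign_idx = np.argmax(np.abs(Vt), axis=1)
    signs = np.sign(Vt[np.arange(Vt.shape[0]), sign_idx])
    signs[signs == 0] = 1.0
    U = U * signs[None, :]
    Vt = Vt * signs[:, None]

    points = U[:, :2] * D[:2][None, :]
    arrows = Vt[:2].T
    lipid_coords = pd.DataFrame(points, index=effects.index, columns=["v1", "v2"])
    trait_coords = pd.DataFrame(arrows, index=effects.columns, columns=["v1", "v2"])
    total = float((D**2).sum())
    pct12 = float((D[:2] ** 2).sum() / total * 100.0) if total > 0 else 100.0

    radius_raw = pd.Series(np.linalg.norm(points, axis=1), index=effects.index, name="radius")
    max_r = radius_raw.max()
    radius_norm = radius_raw / max_r if max_r > 0 else radius_raw
    highlighted = radius_norm > highlight_radius

    display = lipid_coords.copy()
    trait_display = trait_coords.copy()
    if display_scale:
        for trait, factor in display_scale.items():
            if trait not in trait_coords.index:
                raise ValueError(f"unknown trait {trait!r} in display_scale")
            trait_display.loc[trait] = trait_display.loc[trait] / factor

    return BiplotResult(
        lipid_coords=lipid_coords,
        trait_coords=trait_coords,
        percent_variance_12=pct12,
        radius_raw=radius_raw,
        radius_normalized=radius_norm.rename("radius_normalized"),
        highlighted=highlighted.rename("highlighted"),
        singular_values=D,
        display_coords=display if display_scale else None,
    )
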