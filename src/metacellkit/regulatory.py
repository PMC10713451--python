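"""Transcription-factor activity inference.

Gene expression trends along a supplied pseudotime (cubic-spline additive
model), a TF-target matrix from motif scores weighted by peak-gene
correlations, lasso regression of metacell expression on that matrix, and
signed leave-one-out TF activities.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from .types import TFActivityResult, TFTargetMatrix

DEFAULT_SPLINE_DF = 6
DEFAULT_FOLDS = 10
QUALIFY_P = 0.1
QUALIFY_R = 0.1


def fit_gene_trends(
    tau: np.ndarray,
    expression: np.ndarray,
    gene_ids: np.ndarray,
    spline_df: int = DEFAULT_SPLINE_DF,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Fit smooth expression trends along pseudotime and z-score them.

    Per gene, an additive model ``y = beta_0 + f(tau)`` with a penalized
    cubic B-spline smoother is fit across the lineage metacells; fitted
    values are z-scored across metacells. The spline's wiggliness penalty
    leaves linear trends unpenalized, so linear signals are recovered
    exactly. Constant genes return all-zero trends.

    Returns a metacells x genes DataFrame of z-scored fitted expression.
    """
    tau = np.asarray(tau, dtype=float)
    Y = np.asarray(expression, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = tau.shape[0]
    if n < 8:
        raise ValueError(f"need at least 8 metacells on the lineage; have {n}")
    if Y.shape[0] != n:
        raise ValueError("expression rows must align with pseudotime entries")
    df = spline_df
    if df >= n - 1:
        df = max(4, n - 2)
        warnings.warn(f"spline basis reduced to df={df} for {n} metacells")
    X, Omega = _cubic_spline_basis(tau, df)
    # normalize the curvature penalty so alpha is a dimensionless knob;
    # linear trends have zero curvature and are never penalized
    scale = np.trace(X.T @ X) / max(np.trace(Omega), 1e-300)
    H = X.T @ X + alpha * scale * Omega + 1e-10 * np.eye(X.shape[1])
    coef = np.linalg.solve(H, X.T @ Y)
    fitted = X @ coef
    const = Y.std(axis=0, ddof=0) == 0
    fitted[:, const] = Y[:, const]
    mu = fitted.mean(axis=0)
    sd = fitted.std(axis=0, ddof=0)
    z = np.where(sd > 0, (fitted - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, columns=np.asarray(gene_ids))


def _cubic_spline_basis(tau: np.ndarray, df: int):
    """Clamped cubic B-spline design matrix plus the exact curvature penalty
    ``Omega_ij = integral B_i'' B_j''`` (2-point Gauss quadrature per knot
    interval, exact for the piecewise-linear second derivatives)."""
    k = 3
    lo, hi = float(tau.min()), float(tau.max())
    if hi <= lo:
        hi = lo + 1.0
    n_interior = max(df - k - 1, 0)
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    t = np.concatenate([[lo] * (k + 1), interior, [hi] * (k + 1)])
    n_basis = len(t) - k - 1
    X = BSpline.design_matrix(np.clip(tau, lo, hi), t, k).toarray()
    d2 = BSpline(t, np.eye(n_basis), k, extrapolate=True).derivative(2)
    Omega = np.zeros((n_basis, n_basis))
    breaks = np.unique(t)
    gauss = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    for a, b in zip(breaks[:-1], breaks[1:]):
        mid, half = (a + b) / 2.0, (b - a) / 2.0
        vals = d2(mid + half * gauss)  # (2, n_basis)
        Omega += half * (vals.T @ vals)
    return X, Omega


def build_tf_target_matrix(
    links: pd.DataFrame,
    motif_scores: pd.DataFrame,
    p_threshold: float = QUALIFY_P,
    r_threshold: float = QUALIFY_R,
) -> TFTargetMatrix:
    """Correlation-weighted motif scores per (gene, TF).

    For each gene g the qualifying peak set S_g holds peaks whose
    accessibility correlates with g's expression (p < 0.1 and r > 0.1);
    the entry for TF t is ``sum_{k in S_g} c_kg * F_kt / sum_{k in S_g} c_kg``
    where F is the peaks x TFs motif-score matrix. Genes with empty S_g get
    zero rows.
    """
    req = {"gene", "peak", "r", "p"}
    if not req.issubset(links.columns):
        raise ValueError(f"links must have columns {sorted(req)}")
    qual = links[(links["p"] < p_threshold) & (links["r"] > r_threshold)]
    genes = sorted(links["gene"].unique())
    tfs = list(motif_scores.columns)
    F = motif_scores
    G = np.zeros((len(genes), len(tfs)))
    S_g: dict[str, list] = {g: [] for g in genes}
    for gi, gene in enumerate(genes):
        sub = qual[qual["gene"] == gene]
        sub = sub[sub["peak"].isin(F.index)]
        if len(sub) == 0:
            continue
        c = sub["r"].to_numpy()
        Fk = F.loc[sub["peak"]].to_numpy()
        denom = c.sum()
        if denom <= 0:  # cannot occur under r > 0.1, but guard the division
            continue
        G[gi] = (c[:, None] * Fk).sum(axis=0) / denom
        S_g[gene] = list(sub["peak"])
    return TFTargetMatrix(
        G=pd.DataFrame(G, index=genes, columns=tfs),
        qualifying_peaks=S_g,
        p_threshold=p_threshold,
        r_threshold=r_threshold,
    )


def infer_tf_activities(
    tf_targets: TFTargetMatrix,
    trends: pd.DataFrame,
    n_folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    ranking: str = "signed",
) -> TFActivityResult:
    """Lasso TF-activity inference per metacell.

    For each metacell s, the gene trend column y_s is regressed on the
    standardized TF-target matrix G with an L1 penalty chosen by
    ``n_folds``-fold cross-validation. The activity of TF t is the increase
    in squared prediction error when t's term is removed from the fitted
    predictor, signed by its coefficient:
    ``M_ts = (SSE_without_t - SSE_full) * sign(w_st)``; TFs with zero
    coefficients have zero activity. TFs are ranked by total activity
    across metacells (``ranking="absolute"`` ranks by total |activity|).
    """
    G_df = tf_targets.G
    shared = [g for g in trends.columns if g in G_df.index]
    if len(shared) == 0:
        raise ValueError("no genes shared between the TF-target matrix and trends")
    G = G_df.loc[shared].to_numpy()
    nonzero_cols = np.flatnonzero((G != 0).any(axis=0))
    if nonzero_cols.size < 2:
        raise ValueError("need at least 2 TFs with non-zero target columns")
    if not (G != 0).any():
        raise ValueError("TF-target matrix is all zero")
    tfs = np.asarray(G_df.columns)
    # standardize columns; all-zero columns stay zero
    mu, sd = G.mean(axis=0), G.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Gz = (G - mu) / sd_safe
    Gz[:, sd == 0] = 0.0

    n_genes = len(shared)
    folds = n_folds
    if n_genes < folds:
        folds = max(2, n_genes)
        warnings.warn(f"reduced CV folds to {folds} for {n_genes} genes")
    Y = trends[shared].to_numpy()  # metacells x genes
    n_mc = Y.shape[0]
    acts = np.zeros((len(tfs), n_mc))
    coefs = np.zeros((len(tfs), n_mc))
    alphas = np.zeros(n_mc)
    for s_i in range(n_mc):
        y = Y[s_i]
        cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
        model = LassoCV(cv=cv, random_state=seed, max_iter=5000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Gz, y)
        w = model.coef_
        coefs[:, s_i] = w
        alphas[s_i] = model.alpha_
        pred = Gz @ w + model.intercept_
        sse_full = float(((y - pred) ** 2).sum())
        active = np.flatnonzero(w != 0)
        for t in active:
            pred_wo = pred - Gz[:, t] * w[t]
            sse_wo = float(((y - pred_wo) ** 2).sum())
            acts[t, s_i] = (sse_wo - sse_full) * np.sign(w[t])
    mc_ids = [str(c) for c in trends.index]
    activities = pd.DataFrame(acts, index=tfs, columns=mc_ids)
    total = activities.abs().sum(axis=1) if ranking == "absolute" else activities.sum(axis=1)
    return TFActivityResult(
        activities=activities,
        coefficients=pd.DataFrame(coefs, index=tfs, columns=mc_ids),
        alphas=alphas,
        ranking=total.sort_values(ascending=False),
    )
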