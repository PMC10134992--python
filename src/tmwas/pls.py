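"""Pairwise PLS integration and signed association scoring.

Two preprocessed blocks sharing the same ordered conditions are fit with a
deterministic NIPALS partial least squares in regression mode (optionally
sparse via soft-thresholded weight vectors). Feature-feature association
scores on the correlation scale are then read off the latent components:

    r_ij = sum_h cor(x_i, xi_h) * cor(y_j, xi_h)

where xi_h is the h-th X latent score and features are standardized. In
regression mode both blocks are projected onto the X scores, which makes
the score collapse exactly to the Pearson correlation when either block is
univariate — the property the paired |r|/p thresholds rely on. An
averaged-score variant z_h = (xi_h + omega_h)/2 is available as
``score_mode="average"``.

Significance uses the correlation t-test with n - 2 degrees of freedom,
n being the number of conditions entering the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import AssociationEdge, Block, OmicsBlock

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 1000


def _standardize(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardize (mean 0, sd 1); returns (standardized, keep mask)."""
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    keep = sd > 0
    out = (matrix[:, keep] - mean[keep]) / sd[keep]
    return out, keep


def _soft_threshold(w: np.ndarray, keep: int | None) -> np.ndarray:
    """Shrink all but the ``keep`` largest |w| to zero (lasso-style)."""
    if keep is None or keep >= w.size:
        return w
    if keep < 1:
        raise ValueError("keep budget must be >= 1")
    absw = np.abs(w)
    lam = np.sort(absw)[::-1][keep]
    return np.sign(w) * np.maximum(absw - lam, 0.0)


@dataclass
class PLSModel:
    """Fitted sparse-PLS decomposition of one block pair."""

    n_components: int
    x_scores: np.ndarray  # n_samples x H  (xi)
    y_scores: np.ndarray  # n_samples x H  (omega)
    x_weights: np.ndarray
    y_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_features: list[str]
    y_features: list[str]
    sample_ids: list[str]
    keep_x: int | None
    keep_y: int | None

    @property
    def n_samples(self) -> int:
        return self.x_scores.shape[0]


def fit_pls(x_block: OmicsBlock, y_block: OmicsBlock, n_components: int = 2,
            keep_x: int | None = None, keep_y: int | None = None) -> PLSModel:
    """Deterministic NIPALS sparse PLS in regression mode.

    Per component the Y-weight iteration starts from the Y column of
    maximal variance (no random initialization), X is deflated by its
    score-loading outer product and Y by the regression of Y on the X
    score. Features are standardized internally; zero-variance features
    are dropped with a warning.
    """
    if x_block.sample_ids != y_block.sample_ids:
        raise ValueError("blocks must share identical, identically ordered samples")
    n = len(x_block.sample_ids)
    if n_components > n - 1:
        raise ValueError(f"n_components={n_components} exceeds n_samples-1={n - 1}")

    def prepare(block: OmicsBlock) -> tuple[np.ndarray, list[str]]:
        mat = block.matrix().T  # samples x features
        std, keep = _standardize(mat)
        if std.shape[1] == 0:
            raise ValueError(f"block {block.block_id.value} has no variable features")
        if not keep.all():
            dropped = int((~keep).sum())
            warnings.warn(
                f"dropped {dropped} zero-variance features from "
                f"{block.block_id.value}", stacklevel=3)
        feats = [f for f, k in zip(block.feature_ids, keep) if k]
        return std, feats

    xc, x_features = prepare(x_block)
    yc, y_features = prepare(y_block)

    h_dim = n_components
    xi_all = np.zeros((n, h_dim))
    omega_all = np.zeros((n, h_dim))
    w_all = np.zeros((xc.shape[1], h_dim))
    c_all = np.zeros((yc.shape[1], h_dim))
    p_all = np.zeros((xc.shape[1], h_dim))
    q_all = np.zeros((yc.shape[1], h_dim))

    x_work = xc.copy()
    y_work = yc.copy()
    for h in range(h_dim):
        u = y_work[:, int(np.argmax(y_work.var(axis=0, ddof=1)))].copy()
        if not np.any(u):
            break  # Y residual exhausted; remaining components stay zero
        w = np.zeros(xc.shape[1])
        for _ in range(_NIPALS_MAX_ITER):
            w_new = x_work.T @ u
            denom = float(u @ u)
            if denom == 0:
                break
            w_new = _soft_threshold(w_new / denom, keep_x)
            norm = np.linalg.norm(w_new)
            if norm == 0:
                break
            w_new /= norm
            xi = x_work @ w_new
            c = y_work.T @ xi / float(xi @ xi)
            c = _soft_threshold(c, keep_y)
            c_norm = np.linalg.norm(c)
            if c_norm == 0:
                break
            c /= c_norm
            u = y_work @ c
            if np.linalg.norm(w_new - w) < _NIPALS_TOL:
                w = w_new
                break
            w = w_new
        xi = x_work @ w
        ss = float(xi @ xi)
        if ss == 0:
            break
        p = x_work.T @ xi / ss
        q = y_work.T @ xi / ss  # regression-mode Y loadings
        xi_all[:, h] = xi
        omega_all[:, h] = u
        w_all[:, h], c_all[:, h] = w, c
        p_all[:, h], q_all[:, h] = p, q
        x_work = x_work - np.outer(xi, p)
        y_work = y_work - np.outer(xi, q)

    return PLSModel(
        n_components=h_dim,
        x_scores=xi_all, y_scores=omega_all,
        x_weights=w_all, y_weights=c_all,
        x_loadings=p_all, y_loadings=q_all,
        x_features=x_features, y_features=y_features,
        sample_ids=list(x_block.sample_ids),
        keep_x=keep_x, keep_y=keep_y)


def _cor_with_scores(std: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Correlation of each standardized feature column with each score."""
    n = std.shape[0]
    out = np.zeros((std.shape[1], scores.shape[1]))
    for h in range(scores.shape[1]):
        z = scores[:, h]
        sd = z.std(ddof=1)
        if sd == 0:
            continue
        zc = (z - z.mean()) / sd
        out[:, h] = std.T @ zc / (n - 1)
    return out


def association_matrix(model: PLSModel, x_block: OmicsBlock, y_block: OmicsBlock,
                       score_mode: str = "regression") -> pd.DataFrame:
    """Cross-block association scores on the correlation scale.

    ``score_mode="regression"`` correlates both blocks' features against
    the X latent scores (Pearson-exact in the univariate limit);
    ``"average"`` uses the averaged latent scores (xi_h + omega_h) / 2.
    Result is a features_X x features_Y DataFrame clipped to [-1, 1].
    """
    if score_mode == "regression":
        scores = model.x_scores
    elif score_mode == "average":
        scores = (model.x_scores + model.y_scores) / 2.0
    else:
        raise ValueError(f"unknown score_mode {score_mode!r}")

    x_std, _ = _standardize(
        x_block.values.loc[model.x_features].to_numpy(dtype=float).T)
    y_std, _ = _standardize(
        y_block.values.loc[model.y_features].to_numpy(dtype=float).T)
    a = _cor_with_scores(x_std, scores)
    b = _cor_with_scores(y_std, scores)
    r = np.clip(a @ b.T, -1.0, 1.0)
    return pd.DataFrame(r, index=model.x_features, columns=model.y_features)


def edge_p_value(r: float, n: int) -> float:
    """Two-sided p for a correlation-scale score via the t-test, n-2 df."""
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation test")
    r = float(r)
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(t, df=n - 2))


def select_edges(r_matrix: pd.DataFrame, n: int,
                 source_block: Block, target_block: Block,
                 r_threshold: float = 0.8,
                 p_threshold: float = 0.05) -> list[AssociationEdge]:
    """Threshold the association matrix into a sorted edge list.

    Both cuts are strict: |r| > r_threshold AND p < p_threshold. Edges are
    sorted by |r| descending, ties broken by (source_id, target_id).
    """
    if not (0 < r_threshold < 1 and 0 < p_threshold < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    rows, cols = np.where(np.abs(r_matrix.to_numpy()) > r_threshold)
    edges = []
    for i, j in zip(rows, cols):
        r = float(r_matrix.iat[i, j])
        p = edge_p_value(r, n)
        if p < p_threshold:
            edges.append(AssociationEdge(
                source_id=str(r_matrix.index[i]),
                target_id=str(r_matrix.columns[j]),
                source_block=source_block, target_block=target_block,
                r=r, p=p, n=n))
    edges.sort(key=lambda e: (-abs(e.r), e.source_id, e.target_id))
    return edges


def integrate(x_block: OmicsBlock, y_block: OmicsBlock,
              n_components: int = 2,
              keep_x: int | None = None, keep_y: int | None = None,
              r_threshold: float = 0.8, p_threshold: float = 0.05,
              score_mode: str = "regression",
              ) -> tuple[pd.DataFrame, list[AssociationEdge]]:
    """Fit, score and threshold one block pair in a single call."""
    model = fit_pls(x_block, y_block, n_components, keep_x, keep_y)
    r_matrix = association_matrix(model, x_block, y_block, score_mode)
    edges = select_edges(r_matrix, model.n_samples,
                         x_block.block_id, y_block.block_id,
                         r_threshold, p_threshold)
    return r_matrix, edges
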