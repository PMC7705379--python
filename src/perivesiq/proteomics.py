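"""Multivariate statistics for label-free quantification (LFQ) matrices.

Implements the proteomics analysis chain used to characterise EV protein
cargo across patient groups: a control-normalised log2-ratio heatmap with
a 1.2-fold-change filter, pairwise volcano records (one-way ANOVA p
against fold-change boundaries), PLS-DA via NIPALS with VIP and sMC
variable-importance indices and per-group 95% confidence ellipses on the
score plane, and neighbor-joining clustering of Euclidean distances
between log2-ratio profiles.

Zeros in an LFQ matrix are treated as missing values throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# Heatmap and volcano


def log2_ratio_matrix(
    lfq: pd.DataFrame,
    groups: pd.Series,
    reference: str = "CNT",
    fc_filter: float = 1.2,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample log2 ratios to the reference-group mean, fold-change filtered.

    Each entry is ``log2(abundance / mean reference abundance)`` for its
    protein. A protein is retained when the mean of at least one group
    differs from the reference mean by the fold-change threshold (ratio
    ≥ ``fc_filter`` or ≤ 1/``fc_filter``). Proteins whose reference mean
    is unobserved (all missing) are dropped.

    Returns the filtered log2-ratio matrix and the retained protein list.
    """
    if reference not in set(groups):
        raise ValueError(f"reference group {reference!r} not in labels")
    if fc_filter <= 0:
        raise ValueError("fc_filter must be positive")
    vals = lfq.replace(0, np.nan)
    ref_cols = groups.index[groups == reference]
    ref_mean = vals[ref_cols].mean(axis=1)
    keep = []
    for pid in lfq.index:
        rm = ref_mean[pid]
        if not np.isfinite(rm) or rm <= 0:
            continue
        for g in groups.unique():
            gm = vals.loc[pid, groups.index[groups == g]].mean()
            if np.isfinite(gm) and gm > 0:
                ratio = gm / rm
                if ratio >= fc_filter or ratio <= 1.0 / fc_filter:
                    keep.append(pid)
                    break
    mat = np.log2(vals.loc[keep].div(ref_mean[keep], axis=0))
    return mat, list(keep)


@dataclass(frozen=True)
class VolcanoRecord:
    """One protein's two-group comparison: effect size and significance."""

    protein_id: str
    log2_fc: float
    p_value: float
    significant: bool  # p < p_boundary and |fold change| >= fc_boundary
    labelled: bool  # |log2 FC| > 1 — name shown on the plot

    @property
    def is_na(self) -> bool:
        return not np.isfinite(self.log2_fc)


def volcano(
    lfq: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    p_boundary: float = 0.05,
    fc_boundary: float = 2.0,
) -> list[VolcanoRecord]:
    """Pairwise volcano: log2 fold change of group means vs one-way ANOVA p.

    The fold change is ``log2(mean_A / mean_B)``; p comes from a one-way
    ANOVA on the two groups (algebraically a two-sample equal-variance
    t-test). A protein with fewer than two observed values in either
    group yields an NA record rather than an exception.
    """
    cols_a = groups.index[groups == group_a]
    cols_b = groups.index[groups == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("both groups need at least two samples")
    vals = lfq.replace(0, np.nan)
    out = []
    for pid in lfq.index:
        a = vals.loc[pid, cols_a].dropna().to_numpy(float)
        b = vals.loc[pid, cols_b].dropna().to_numpy(float)
        if len(a) < 2 or len(b) < 2 or a.mean() <= 0 or b.mean() <= 0:
            out.append(VolcanoRecord(pid, np.nan, np.nan, False, False))
            continue
        log2fc = float(np.log2(a.mean() / b.mean()))
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0
        else:
            _, p = stats.f_oneway(a, b)
            p = float(p) if np.isfinite(p) else 1.0
        sig = p < p_boundary and abs(log2fc) >= np.log2(fc_boundary)
        out.append(VolcanoRecord(pid, log2fc, p, sig, abs(log2fc) > 1.0))
    return out


def volcano_frame(records: list[VolcanoRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "log2_fc": r.log2_fc,
                "p_value": r.p_value,
                "significant": r.significant,
                "labelled": r.labelled,
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# PLS-DA


@dataclass
class PLSDAResult:
    """Fitted PLS-DA model (NIPALS PLS2 on autoscaled X, one-hot Y).

    Arrays follow chemometrics conventions: scores ``T`` (n×A), X-weights
    ``W`` (p×A, unit norm per component), X-loadings ``P``, Y-loadings
    ``Q``, regression coefficients ``beta`` (p×g) on the scaled data.
    """

    n_components: int
    protein_ids: list[str]
    sample_ids: list[str]
    group_names: list[str]
    y_labels: list[str]
    T: np.ndarray
    W: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    beta: np.ndarray
    ssy_explained: np.ndarray  # per-component explained Y sum of squares
    X_scaled: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    dropped_constant: list[str] = field(default_factory=list)

    def scores_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.T,
            index=self.sample_ids,
            columns=[f"LV{a + 1}" for a in range(self.n_components)],
        )
        df.insert(0, "group", self.y_labels)
        return df


def fit_plsda(
    lfq: pd.DataFrame,
    groups: pd.Series,
    n_components: int = 3,
    scale: bool = True,
) -> PLSDAResult:
    """Fit PLS-DA: NIPALS PLS2 of autoscaled X against one-hot group Y.

    Rows of ``lfq`` are proteins (variables), columns are samples.
    Missing values (zeros) are imputed per protein with the protein mean
    of observed values. Constant variables are dropped under autoscaling.
    """
    group_names = sorted(set(groups))
    if len(lfq.columns) < len(group_names) + 1:
        raise ValueError("need more samples than groups")
    X = lfq.replace(0, np.nan).T.to_numpy(float)  # n samples × p proteins
    col_mean = np.nanmean(X, axis=0)
    nan_idx = np.where(np.isnan(X))
    X[nan_idx] = np.take(col_mean, nan_idx[1])

    protein_ids = list(lfq.index)
    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0, ddof=1) if scale else np.ones(X.shape[1])
    keep = x_std > 0 if scale else ~np.all(X == X[0], axis=0) | np.ones(X.shape[1], bool)
    dropped = [protein_ids[j] for j in np.where(~keep)[0]]
    X = X[:, keep]
    protein_ids = [protein_ids[j] for j in np.where(keep)[0]]
    x_mean, x_std = x_mean[keep], x_std[keep]
    Xs = (X - x_mean) / (x_std if scale else 1.0)

    y_labels = [groups[s] for s in lfq.columns]
    Y = np.array([[1.0 if g == gn else 0.0 for gn in group_names] for g in y_labels])
    Yc = Y - Y.mean(axis=0)

    n, p = Xs.shape
    A = min(n_components, n - 1, p)
    T = np.zeros((n, A))
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    Q = np.zeros((Y.shape[1], A))
    ssy = np.zeros(A)
    Xd, Yd = Xs.copy(), Yc.copy()
    ssy_prev = (Yd**2).sum()
    for a in range(A):
        u = Yd[:, np.argmax((Yd**2).sum(axis=0))].copy()
        t_old = np.zeros(n)
        for _ in range(500):
            w = Xd.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t = Xd @ w
            q = Yd.T @ t / (t @ t)
            nq = np.linalg.norm(q)
            u = Yd @ q / (q @ q) if nq > 0 else t
            if np.linalg.norm(t - t_old) <= 1e-12 * max(1.0, np.linalg.norm(t)):
                break
            t_old = t
        if np.linalg.norm(w) == 0 or t @ t == 0:
            A = a
            break
        pl = Xd.T @ t / (t @ t)
        Xd = Xd - np.outer(t, pl)
        Yd = Yd - np.outer(t, q)
        ssy_now = (Yd**2).sum()
        T[:, a], W[:, a], P[:, a], Q[:, a] = t, w, pl, q
        ssy[a] = ssy_prev - ssy_now
        ssy_prev = ssy_now
    T, W, P, Q, ssy = T[:, :A], W[:, :A], P[:, :A], Q[:, :A], ssy[:A]
    if A == 0:
        raise ValueError("no usable PLS components (degenerate X)")
    Wstar = W @ np.linalg.pinv(P.T @ W)
    beta = Wstar @ Q.T
    return PLSDAResult(
        n_components=A,
        protein_ids=protein_ids,
        sample_ids=list(lfq.columns),
        group_names=group_names,
        y_labels=y_labels,
        T=T,
        W=W,
        P=P,
        Q=Q,
        beta=beta,
        ssy_explained=ssy,
        X_scaled=Xs,
        x_mean=x_mean,
        x_std=x_std,
        dropped_constant=dropped,
    )


def predict_groups(model: PLSDAResult, lfq_new: pd.DataFrame) -> list[str]:
    """Assign new samples (columns) to the group with the highest predicted
    one-hot response."""
    X = lfq_new.replace(0, np.nan).T.reindex(columns=model.protein_ids).to_numpy(float)
    col_mean = np.where(np.isfinite(model.x_mean), model.x_mean, 0.0)
    nan_idx = np.where(np.isnan(X))
    X[nan_idx] = np.take(col_mean, nan_idx[1])
    Xs = (X - model.x_mean) / model.x_std
    Yhat = Xs @ model.beta
    return [model.group_names[i] for i in np.argmax(Yhat, axis=1)]


def vip(model: PLSDAResult) -> np.ndarray:
    """Variable importance in projection.

    ``VIP_j = sqrt( p * Σ_a SSY_a (w_ja / ||w_a||)² / Σ_a SSY_a )`` where
    ``SSY_a`` is the Y sum of squares explained by component ``a``. The
    mean of VIP² over variables is exactly 1.
    """
    ssy = model.ssy_explained
    total = ssy.sum()
    if total <= 0:
        raise ValueError("model explains no Y variance; VIP undefined")
    p = model.W.shape[0]
    wnorm2 = (model.W**2).sum(axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    contrib = (model.W**2 / wnorm2) @ ssy
    return np.sqrt(p * contrib / total)


def smc(model: PLSDAResult, response: int | None = None) -> np.ndarray:
    """Significance multivariate correlation (sMC) per variable.

    Target projection: ``t_TP = X β/||β||``; variable loadings
    ``p_TP = Xᵀ t_TP / (t_TPᵀ t_TP)``. The index is the F-like ratio of
    the variance of each variable explained by the target component to
    its residual variance:

    ``sMC_j = ||x̂_j||² / ( ||x_j − x̂_j||² / (n − 2) )``, x̂_j = t_TP p_TP,j.

    With multiple groups the regression vector is taken per one-vs-rest
    response column; ``response=None`` returns the element-wise maximum
    over responses. Variables with (numerically) zero residual are
    reported as ``inf``.
    """
    n = model.T.shape[0]
    if n <= 2:
        raise ValueError("sMC needs n > 2 samples")
    X = model.X_scaled

    def one(beta_col: np.ndarray) -> np.ndarray:
        nb = np.linalg.norm(beta_col)
        if nb == 0:
            raise ValueError("zero regression vector; sMC undefined")
        t = X @ (beta_col / nb)
        tt = t @ t
        p_tp = X.T @ t / tt
        xhat = np.outer(t, p_tp)
        ss_fit = (xhat**2).sum(axis=0)
        ss_res = ((X - xhat) ** 2).sum(axis=0)
        with np.errstate(divide="ignore"):
            return np.where(ss_res > 1e-12 * ss_fit.clip(min=1.0), ss_fit / (ss_res / (n - 2)), np.inf)

    if response is not None:
        return one(model.beta[:, response])
    vals = np.stack([one(model.beta[:, r]) for r in range(model.beta.shape[1])])
    return vals.max(axis=0)


def group_ellipses(model: PLSDAResult, confidence: float = 0.95) -> dict[str, dict]:
    """95% confidence ellipses per group on the first two score components.

    Each ellipse is parameterised by its centre, semi-axis lengths and
    rotation (radians), from the per-group 2D score covariance and the
    χ²(2) quantile.
    """
    if model.n_components < 2:
        raise ValueError("ellipses need at least two components")
    chi2 = stats.chi2.ppf(confidence, df=2)
    out = {}
    scores = model.T[:, :2]
    labels = np.array(model.y_labels)
    for g in model.group_names:
        pts = scores[labels == g]
        if len(pts) < 3:
            continue
        centre = pts.mean(axis=0)
        cov = np.cov(pts.T)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        out[g] = {
            "center": centre.tolist(),
            "semi_axes": np.sqrt(np.clip(evals, 0, None) * chi2).tolist(),
            "angle_rad": float(np.arctan2(evecs[1, 0], evecs[0, 0])),
            "n": int(len(pts)),
        }
    return out


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_cluster(
    dist: np.ndarray | pd.DataFrame, names: list[str] | None = None
) -> str:
    """Neighbor-joining (Saitou–Nei) tree from a distance matrix, as Newick.

    Deterministic: among minimal Q entries the lowest-index pair is
    joined. Exact on additive distance matrices — leaf-to-leaf path
    lengths in the returned tree reproduce the input distances.
    """
    if isinstance(dist, pd.DataFrame):
        names = list(dist.index)
        d = dist.to_numpy(float).copy()
    else:
        d = np.asarray(dist, dtype=float).copy()
        if names is None:
            names = [f"item{i}" for i in range(d.shape[0])]
    n = d.shape[0]
    if d.shape != (n, n) or n != len(names):
        raise ValueError("distance matrix must be square and match names")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 items")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")

    nodes = [str(nm) for nm in names]  # Newick fragments
    active = list(range(n))
    D = d
    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(q), q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = sub[i_loc, j_loc]
        bi = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        bj = dij - bi
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(new_row)] = new_row
        D[: len(new_row), -1] = new_row
        D[-1, -1] = 0.0
        nodes.append(f"({nodes[i]}:{bi:.10g},{nodes[j]}:{bj:.10g})")
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]
    i, j = active
    bij = D[i, j]
    return f"({nodes[i]}:{bij / 2.0:.10g},{nodes[j]}:{bij / 2.0:.10g});"


def nj_from_profiles(profiles: pd.DataFrame, axis: str = "samples") -> str:
    """NJ tree over Euclidean distances between log2-ratio profiles.

    ``axis='samples'`` clusters the columns, ``axis='proteins'`` the rows.
    Missing entries are ignored pairwise (complete pairs only).
    """
    mat = profiles if axis == "proteins" else profiles.T
    X = mat.to_numpy(float)
    names = list(mat.index)
    k = X.shape[0]
    if k < 3:
        raise ValueError("need at least 3 profiles")
    d = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            ok = np.isfinite(X[a]) & np.isfinite(X[b])
            if not ok.any():
                raise ValueError(f"no shared observations between {names[a]} and {names[b]}")
            d[a, b] = d[b, a] = float(np.sqrt(((X[a, ok] - X[b, ok]) ** 2).sum()))
    return nj_cluster(d, names)
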