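"""Single-cell phenotype analysis: intensity transforms, percentile
normalization, t-SNE embedding and Gaussian-mixture (EMGM) clustering.

Imaging-cytometry intensities are approximately lognormal, so features are
variance-stabilized (log1p or asinh with a cofactor) and rescaled per channel
to the 1st–99th percentile range before embedding or clustering. Clustering
uses expectation–maximization on a full-covariance Gaussian mixture with
k-means++ restarts; the number of phenotypes is chosen from the elbow of the
best negative log-likelihood across k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import kmeans_plusplus
from sklearn.manifold import TSNE

__all__ = [
    "FeatureMatrix",
    "PhenotypeModel",
    "transform_intensities",
    "normalize_channels",
    "embed_tsne",
    "select_k",
    "fit_emgm",
    "cluster_composition",
]


@dataclass
class FeatureMatrix:
    """Transformed, normalized cells × features matrix with provenance metadata."""

    values: np.ndarray
    feature_names: list[str]
    cell_ids: np.ndarray
    transform: dict = field(default_factory=dict)


@dataclass
class PhenotypeModel:
    """Fitted Gaussian mixture over single-cell features."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray  # (k, d, d), full
    assignments: np.ndarray  # hard argmax labels, 0-based
    responsibilities: np.ndarray  # (n, k), rows sum to 1
    nll: float  # best negative log-likelihood (total, nats)
    nll_trace: np.ndarray  # per-iteration NLL of the best restart
    selection_curve: pd.DataFrame | None = None


def _marker_columns(celltable: pd.DataFrame, compartment: str = "cell") -> list[str]:
    """Marker-channel mean-intensity columns (nuclear channel ch0 excluded)."""
    return [
        c
        for c in celltable.columns
        if c.endswith(f"_{compartment}_mean") and "_ch0_" not in c
    ]


def transform_intensities(
    celltable: pd.DataFrame,
    method: str = "asinh",
    cofactor: float = 5.0,
    columns: list[str] | None = None,
    include_area: bool = False,
    include_nuclear: bool = False,
) -> FeatureMatrix:
    """Variance-stabilize per-cell intensities into a feature matrix.

    ``log`` applies x -> log(x + 1); ``asinh`` applies x -> asinh(x / cofactor)
    (default cofactor 5). Rows flagged ``valid=False`` are dropped. Cell area
    and nuclear-stain intensity can optionally be appended as extra features
    for clustering.
    """
    if columns is None:
        columns = _marker_columns(celltable)
    if not columns:
        raise ValueError("no marker columns found")
    tab = celltable
    if "valid" in tab.columns:
        tab = tab[tab["valid"].astype(bool)]
    x = tab[columns].to_numpy(float)
    if np.nanmin(x) < 0:
        raise ValueError("intensities must be non-negative")
    names = list(columns)
    extra = []
    if include_area:
        extra.append(tab["cell_area"].to_numpy(float)[:, None])
        names.append("cell_area")
    if include_nuclear:
        nuc_cols = [c for c in tab.columns if "_ch0_nuc_mean" in c]
        if nuc_cols:
            extra.append(tab[[nuc_cols[0]]].to_numpy(float))
            names.append(nuc_cols[0])
    if extra:
        x = np.hstack([x] + extra)
    if method == "log":
        v = np.log(x + 1.0)
    elif method == "asinh":
        v = np.arcsinh(x / cofactor)
    else:
        raise ValueError("method must be 'log' or 'asinh'")
    keep = ~np.isnan(v).any(axis=1)
    return FeatureMatrix(
        values=v[keep],
        feature_names=names,
        cell_ids=tab["cell_id"].to_numpy()[keep] if "cell_id" in tab else np.nonzero(keep)[0],
        transform={"method": method, "cofactor": cofactor},
    )


def normalize_channels(
    fm: FeatureMatrix, p_low: float = 1.0, p_high: float = 99.0
) -> FeatureMatrix:
    """Rescale each channel to its [p_low, p_high] percentile range, clipped to [0, 1].

    Constant channels (P_high == P_low) cannot be rescaled; they are excluded
    with a warning.
    """
    if fm.values.shape[0] < 100:
        raise ValueError("percentile normalization needs at least 100 cells")
    lo = np.percentile(fm.values, p_low, axis=0)
    hi = np.percentile(fm.values, p_high, axis=0)
    keep = hi > lo
    if not keep.all():
        dropped = [n for n, k in zip(fm.feature_names, keep) if not k]
        warnings.warn(f"constant channels excluded from normalization: {dropped}")
    v = (fm.values[:, keep] - lo[keep]) / (hi[keep] - lo[keep])
    return FeatureMatrix(
        values=np.clip(v, 0.0, 1.0),
        feature_names=[n for n, k in zip(fm.feature_names, keep) if k],
        cell_ids=fm.cell_ids,
        transform={**fm.transform, "p_low": p_low, "p_high": p_high},
    )


def embed_tsne(
    fm: FeatureMatrix | np.ndarray,
    perplexity: float = 30.0,
    seed: int = 0,
    learning_rate: float = 500.0,
    early_exaggeration: float = 4.0,
) -> np.ndarray:
    """2-D t-SNE embedding; deterministic for a fixed seed.

    Defaults mirror the classic cytometry settings: perplexity 30, learning
    rate (epsilon) 500 and early exaggeration 4 applied during the initial
    optimization phase.
    """
    x = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, float)
    if len(x) < 3 * perplexity:
        raise ValueError(f"need at least {int(3 * perplexity)} cells for perplexity {perplexity}")
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        learning_rate=learning_rate,
        early_exaggeration=early_exaggeration,
        init="pca",
        random_state=seed,
        n_jobs=1,
    )
    return tsne.fit_transform(x)


def _em_single(
    x: np.ndarray,
    k: int,
    rng: np.random.Generator,
    reg: float,
    tol: float,
    max_iter: int,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One EM run from a k-means++ start; returns (nll, w, mu, cov, resp, trace)."""
    n, d = x.shape
    mu, _ = kmeans_plusplus(x, n_clusters=k, random_state=int(rng.integers(2**31 - 1)))
    cov = np.tile(np.cov(x.T).reshape(d, d) + reg * np.eye(d), (k, 1, 1))
    w = np.full(k, 1.0 / k)
    trace = []
    prev = None
    resp = np.full((n, k), 1.0 / k)
    eye = reg * np.eye(d)
    const = d * np.log(2 * np.pi)
    for _ in range(max_iter):
        # E step, vectorized over components
        try:
            chol = np.linalg.cholesky(cov)  # (k, d, d)
        except np.linalg.LinAlgError:
            raise FloatingPointError("singular covariance")
        logdet = 2.0 * np.log(np.diagonal(chol, axis1=1, axis2=2)).sum(1)
        prec = np.linalg.inv(cov)  # (k, d, d)
        diff = x[None, :, :] - mu[:, None, :]  # (k, n, d)
        maha = ((diff @ prec) * diff).sum(-1)  # (k, n)
        log_prob = (-0.5 * (const + logdet[:, None] + maha) + np.log(w)[:, None]).T
        mx = log_prob.max(axis=1)
        norm = mx + np.log(np.exp(log_prob - mx[:, None]).sum(axis=1))
        nll = -float(norm.sum())
        trace.append(nll)
        resp = np.exp(log_prob - norm[:, None])
        if prev is not None and abs(prev - nll) <= tol * max(abs(prev), 1.0):
            break
        prev = nll
        # M step
        nk = resp.sum(axis=0) + 10 * np.finfo(float).eps
        w = nk / n
        mu = (resp.T @ x) / nk[:, None]
        diff = x[None, :, :] - mu[:, None, :]
        cov = (
            np.einsum("nk,kni,knj->kij", resp, diff, diff) / nk[:, None, None] + eye
        )
    return trace[-1], w, mu, cov, resp, np.asarray(trace)


def fit_emgm(
    fm: FeatureMatrix | np.ndarray,
    k: int,
    restarts: int = 30,
    seed: int = 0,
    reg: float = 1e-6,
    tol: float = 1e-7,
    max_iter: int = 500,
) -> PhenotypeModel:
    """Fit a full-covariance Gaussian mixture by EM with k-means++ restarts.

    The best (lowest negative log-likelihood) of ``restarts`` runs is
    returned; covariances carry a diagonal regularization of ``reg``.
    Restarts whose covariance degenerates despite regularization are
    discarded; if every restart degenerates an error is raised.
    """
    x = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, float)
    n = len(x)
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= 10 * k:
        raise ValueError(f"need more than {10 * k} cells to fit k={k}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        try:
            result = _em_single(x, k, rng, reg, tol, max_iter)
        except FloatingPointError:
            continue
        if best is None or result[0] < best[0]:
            best = result
    if best is None:
        raise RuntimeError("all EM restarts degenerated")
    nll, w, mu, cov, resp, trace = best
    return PhenotypeModel(
        k=k,
        weights=w,
        means=mu,
        covariances=cov,
        assignments=np.argmax(resp, axis=1),
        responsibilities=resp,
        nll=nll,
        nll_trace=trace,
    )


def select_k(
    fm: FeatureMatrix | np.ndarray,
    k_range: list[int],
    restarts: int = 30,
    seed: int = 0,
    **em_kwargs,
) -> tuple[pd.DataFrame, int]:
    """Scan mixture sizes and pick the elbow of the best-NLL curve.

    For every k the mixture is fitted ``restarts`` times and the lowest
    negative log-likelihood kept; the curve reports NLL(k) and the improvement
    Δ(k) = NLL(k−1) − NLL(k). The chosen k is the knee of the NLL curve — the
    point of maximum deviation below the chord joining its endpoints, i.e. the
    inflection where extra components stop paying for themselves. When the
    whole curve is flat (total drop below 1% of the k_min NLL magnitude)
    there is no mixture structure and the smallest k is returned. The full
    curve is exposed so the choice can be overridden manually.
    """
    ks = sorted(k_range)
    if ks[0] < 1:
        raise ValueError("k_range entries must be >= 1")
    rows = []
    for i, k in enumerate(ks):
        try:
            model = fit_emgm(fm, k, restarts=restarts, seed=seed + i, **em_kwargs)
        except RuntimeError:
            continue
        rows.append({"k": k, "nll": model.nll})
    curve = pd.DataFrame(rows)
    if curve.empty:
        raise RuntimeError("no mixture size converged")
    nll = curve["nll"].to_numpy()
    kvals = curve["k"].to_numpy()
    curve["delta"] = np.concatenate([[np.nan], nll[:-1] - nll[1:]])
    if len(nll) < 3:
        return curve, int(kvals[int(np.argmin(nll))])
    if nll[0] - nll[-1] < 0.01 * abs(nll[0]):
        return curve, int(kvals[0])
    t = (kvals - kvals[0]) / (kvals[-1] - kvals[0])
    chord = nll[0] + t * (nll[-1] - nll[0])
    chosen = int(kvals[int(np.argmax(chord - nll))])
    return curve, chosen


def cluster_composition(
    assignments: np.ndarray, group_labels: np.ndarray
) -> pd.DataFrame:
    """Within-group cluster proportions: rows = groups, columns = clusters, rows sum to 1."""
    df = pd.DataFrame({"group": group_labels, "cluster": assignments})
    counts = df.groupby(["group", "cluster"]).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)
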