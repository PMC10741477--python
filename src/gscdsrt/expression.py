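"""Expression-dispersion classification of genes.

Starting from a genes × samples TPM matrix, genes failing QC, expressed at
zero in all samples, or lowly expressed (mean TPM < 1) are removed; each
remaining gene's cross-sample dispersion is summarised as the log of its
standard deviation; a two-component Gaussian mixture is fitted to the
log-SD values by expectation–maximisation; and genes whose posterior
probability of one component reaches a high threshold (default 99.8%) are
classified as homogeneously (low dispersion) or heterogeneously (high
dispersion) expressed. A generic signature scorer aggregates z-scored
expression over user-supplied gene sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

LABELS = ("homogeneous", "heterogeneous", "unclassified", "filtered")


# ---------------------------------------------------------------------------
# Gene filtering
# ---------------------------------------------------------------------------

def filter_genes(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Apply the QC filters in order, recording one reason per removed gene.

    Order: qc_flag == 'failed' → all-zero TPM → mean TPM < 1 (strict).
    The ``qc_flag`` column is optional; when absent all genes count as ok.
    Returns the filtered matrix (values only, flag column dropped) and a
    per-gene ``filter_reason`` Series ('ok' for retained genes).
    """
    if matrix.index.duplicated().any():
        raise ValueError("duplicate gene ids")
    flags = matrix["qc_flag"] if "qc_flag" in matrix.columns else pd.Series(
        "ok", index=matrix.index)
    values = matrix.drop(columns=["qc_flag"], errors="ignore").astype(float)
    if (values.to_numpy() < 0).any():
        raise ValueError("TPM values must be non-negative")

    reason = pd.Series("ok", index=matrix.index, name="filter_reason")
    reason[flags == "failed"] = "qc_failed"
    allzero = (values == 0).all(axis=1) & (reason == "ok")
    reason[allzero] = "all_zero"
    low = (values.mean(axis=1) < 1.0) & (reason == "ok")
    reason[low] = "low_expression"

    kept = values.loc[reason == "ok"]
    if kept.empty:
        counts = reason.value_counts().to_dict()
        raise ValueError(f"no genes pass filtering: {counts}")
    return kept, reason


# ---------------------------------------------------------------------------
# Dispersion
# ---------------------------------------------------------------------------

def dispersion(matrix: pd.DataFrame, log_base: float = math.e) -> pd.Series:
    """Per-gene log standard deviation of TPM across samples.

    SD uses the n−1 denominator; the log is natural by default (the base
    shifts component parameters but not the classification). Genes constant
    across samples get −inf and are excluded from mixture fitting.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples for a dispersion estimate")
    sd = matrix.std(axis=1, ddof=1)
    with np.errstate(divide="ignore"):
        log_sd = np.log(sd.to_numpy(dtype=float))
    if log_base != math.e:
        log_sd = log_sd / math.log(log_base)
    out = pd.Series(log_sd, index=matrix.index, name="log_sd")
    n_zero = int(np.isneginf(log_sd).sum())
    if n_zero:
        warnings.warn(f"{n_zero} genes have zero SD; excluded from mixture fitting")
    return out


# ---------------------------------------------------------------------------
# Two-component Gaussian mixture by EM
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    """Univariate Gaussian mixture on the log-SD scale, components ordered
    by ascending mean (component 0 = low dispersion = homogeneous)."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    n_iter: int
    converged: bool
    posterior_low: pd.Series  # per-gene P(low-dispersion component | x)
    ll_trace: np.ndarray | None = None  # log-likelihood per EM iteration

    def posterior_for(self, x: np.ndarray) -> np.ndarray:
        """P(component 0 | x) for new points."""
        x = np.asarray(x, dtype=float)
        logp = (np.log(self.weights)[None, :]
                + norm.logpdf(x[:, None], self.means[None, :], self.sds[None, :]))
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p[:, 0] / p.sum(axis=1)


def _em_once(x: np.ndarray, means, sds, weights, tol: float, max_iter: int):
    k = len(means)
    means, sds, weights = (np.array(means, float), np.array(sds, float),
                           np.array(weights, float))
    ll_old = -np.inf
    n_iter = 0
    converged = False
    trace: list[float] = []
    resp = np.full((x.size, k), 1.0 / k)
    for n_iter in range(1, max_iter + 1):
        # E step
        logp = np.log(weights)[None, :] + norm.logpdf(x[:, None], means[None, :],
                                                      sds[None, :])
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(lse.sum())
        trace.append(ll)
        resp = np.exp(logp - lse[:, None])
        # M step
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):
            raise FloatingPointError("component collapsed to zero weight")
        weights = nk / x.size
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        if np.any(var < 1e-12):
            raise FloatingPointError("component variance collapsed")
        sds = np.sqrt(var)
        if ll - ll_old < tol and n_iter > 1:
            converged = True
            break
        ll_old = ll
    return means, sds, weights, ll, n_iter, converged, resp, np.asarray(trace)


def fit_mixture(
    log_sd: pd.Series | np.ndarray,
    k: int = 2,
    tol: float = 1e-8,
    max_iter: int = 1000,
    n_restarts: int = 5,
    seed: int = 0,
) -> MixtureFit:
    """EM fit of a k-component univariate Gaussian mixture to finite log-SD
    values.

    Initialisation is deterministic: component means at the k interior
    quantiles of the data, pooled SD, equal weights. If a component
    degenerates (variance → 0) the fit restarts from jittered initial means
    using a seeded generator, up to ``n_restarts`` times. Components are
    reported in ascending mean order for identifiability.
    """
    if isinstance(log_sd, pd.Series):
        index = log_sd.index
        x_all = log_sd.to_numpy(dtype=float)
    else:
        x_all = np.asarray(log_sd, dtype=float)
        index = pd.RangeIndex(x_all.size)
    finite = np.isfinite(x_all)
    x = x_all[finite]
    if x.size < 10 * k:
        raise ValueError(f"need at least {10 * k} finite values, got {x.size}")

    q = (np.arange(k) + 0.5) / k
    means0 = np.quantile(x, q)
    sd0 = np.full(k, max(x.std(ddof=1), 1e-6))
    w0 = np.full(k, 1.0 / k)

    rng = np.random.default_rng(seed)
    last_err: Exception | None = None
    for attempt in range(n_restarts + 1):
        m_init = means0 if attempt == 0 else means0 + rng.normal(0, sd0[0], k)
        try:
            means, sds, weights, ll, n_iter, converged, resp, trace = _em_once(
                x, m_init, sd0, w0, tol, max_iter)
            break
        except FloatingPointError as err:
            last_err = err
    else:
        raise RuntimeError(f"EM failed after {n_restarts} restarts: {last_err}")

    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    resp = resp[:, order]
    post = pd.Series(np.nan, index=index, name="posterior_low", dtype=float)
    post.iloc[np.flatnonzero(finite)] = resp[:, 0]
    return MixtureFit(means=means, sds=sds, weights=weights,
                      log_likelihood=ll, n_iter=n_iter, converged=converged,
                      posterior_low=post, ll_trace=trace)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify(
    fit: MixtureFit,
    threshold: float = 0.998,
    filter_reason: pd.Series | None = None,
) -> pd.DataFrame:
    """Label genes by mixture posterior at a high-credibility threshold.

    homogeneous when P(low-dispersion) ≥ threshold, heterogeneous when
    P(high-dispersion) ≥ threshold (both inclusive), otherwise unclassified.
    Genes removed upstream can be merged in via ``filter_reason`` so that
    homogeneous + heterogeneous + unclassified + filtered = total genes.
    """
    if threshold <= 0.5:
        raise ValueError("threshold must exceed 0.5 or labels would overlap")
    post = fit.posterior_low
    label = pd.Series("unclassified", index=post.index, name="label")
    label[post >= threshold] = "homogeneous"
    label[(1.0 - post) >= threshold] = "heterogeneous"
    reason = pd.Series("", index=post.index)
    reason[post.isna()] = "zero_sd"

    out = pd.DataFrame({"label": label, "posterior_low": post,
                        "filter_reason": reason})
    if filter_reason is not None:
        full = pd.DataFrame({
            "label": "filtered",
            "posterior_low": np.nan,
            "filter_reason": filter_reason.astype(str),
        }, index=filter_reason.index)
        full.loc[out.index, "label"] = out["label"]
        full.loc[out.index, "posterior_low"] = out["posterior_low"]
        full.loc[out.index, "filter_reason"] = out["filter_reason"]
        out = full
    out.index.name = "gene"
    out.attrs["counts"] = out["label"].value_counts().to_dict()
    return out


# ---------------------------------------------------------------------------
# Signature scoring
# ---------------------------------------------------------------------------

def signature_score(
    matrix: pd.DataFrame,
    gene_set,
    log_transform: bool = True,
    pseudo: float = 0.01,
    ddof: int = 1,
) -> pd.Series:
    """Mean per-gene z-score of (log-transformed) expression over a gene set.

    Expression is transformed to log2(value + pseudo), z-scored per gene
    across samples (sample SD, ddof=1 by default; constant genes get z = 0
    with a warning), then averaged over the genes of the set per sample.
    Reports coverage of the set in the matrix via ``attrs``.
    """
    gene_set = list(gene_set)
    present = [g for g in gene_set if g in matrix.index]
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    vals = matrix.loc[present].astype(float)
    if log_transform:
        vals = np.log2(vals + pseudo)
    mu = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=ddof)
    zero_sd = sd == 0
    if zero_sd.any():
        warnings.warn(f"{int(zero_sd.sum())} constant genes in set scored as z=0")
    z = vals.sub(mu, axis=0).div(sd.where(~zero_sd, 1.0), axis=0)
    z[zero_sd] = 0.0
    score = z.mean(axis=0)
    score.name = "signature_score"
    score.attrs["coverage"] = len(present) / len(gene_set)
    return score
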