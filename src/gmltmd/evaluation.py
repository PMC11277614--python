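"""Model-checking battery: predictive checks, fit indices and comparison.

Implements the standard Bayesian workflow for these models: prior predictive
checks of the implied item-success distributions, posterior predictive checks
of per-item marginal success proportions with central 2.5–97.5% intervals,
the discordance rate (share of items whose observed proportion falls outside
its interval), an interval-bias summary, a binary-data SRMR over marginal
proportions and inter-item correlations, pointwise WAIC, model comparison,
and component-wise item characteristic curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .inference import FitResult
from .kernels import log_logistic
from .structures import ComposedItemParameters

logger = logging.getLogger(__name__)

__all__ = [
    "PredictiveSummary",
    "ComparisonTable",
    "prior_predictive_check",
    "posterior_predictive_marginals",
    "discordance_rate",
    "interval_bias",
    "srmr",
    "srmr_from_stats",
    "waic",
    "compare_models",
    "icc_curve",
]


@dataclass(frozen=True)
class PredictiveSummary:
    """Per-item posterior predictive marginal summary (the check table).

    ``table`` columns: item, lower (2.5%), eap, upper (97.5%), dobs,
    outside. ``n_replicates`` is the number of replicated datasets.
    """

    table: pd.DataFrame
    n_replicates: int


@dataclass(frozen=True)
class ComparisonTable:
    """Model-comparison metrics, ranked by WAIC ascending (ties by name)."""

    table: pd.DataFrame

    @property
    def ranking(self) -> list[str]:
        return list(self.table["model"])


def _draw_probabilities(fit: FitResult, s_chain: int, s_draw: int) -> np.ndarray:
    """(N, J) success probabilities implied by one posterior draw."""
    ms = fit.structure
    theta = fit.draws["theta"][s_chain, s_draw]
    b = ms.eta_to_b(fit.draws["eta"][s_chain, s_draw])
    if ms.has_alpha:
        A = ms.alpha_matrix(np.log(fit.draws["alpha"][s_chain, s_draw]))
    else:
        A = ms.c_matrix
    z = A[None, :, :] * (theta[:, None, :] - b[None, :, :])
    log_pi = np.einsum("njm,jm->nj", log_logistic(z), ms.c_matrix)
    pi = np.exp(log_pi)
    if ms.has_guessing:
        c = fit.draws["guessing"][s_chain, s_draw]
        return c[None, :] + (1 - c[None, :]) * pi
    return pi


def _replicate_indices(fit: FitResult, n_rep: int, rng: np.random.Generator):
    n_chains, n_draws = fit.draws["theta"].shape[:2]
    total = n_chains * n_draws
    if n_rep >= total:
        flat = np.arange(total)
    else:
        flat = rng.choice(total, size=n_rep, replace=False)
    return [(s // n_draws, s % n_draws) for s in flat]


def prior_predictive_check(
    priors,
    q,
    cs,
    model_kind: str,
    n_sim: int = 500,
    seed: int = 0,
    n_persons: int = 383,
    fixed_params=None,
) -> pd.DataFrame:
    """Distribution of simulated item marginal proportions under the priors.

    Each simulation draws a parameter set from the priors (or uses
    ``fixed_params`` as a point mass, with only θ drawn standard normal)
    and one response matrix, then records per-item success proportions.
    Returns a per-item table of the 2.5/50/97.5% quantiles and the mean,
    suitable for plotting.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100 for stable quantiles")
    from .inference import build_model_structure

    rng = np.random.default_rng(seed)
    ms = build_model_structure(q, cs, model_kind)
    if fixed_params is not None:
        eta_fix = np.array([fixed_params.eta[p] for p in ms.eta_pairs])
        alpha_fix = (np.array([fixed_params.alpha[g] for g in range(ms.n_groups)])
                     if ms.has_alpha and fixed_params.alpha is not None else None)
        guess_fix = (np.asarray(fixed_params.guessing, dtype=float)
                     if ms.has_guessing and fixed_params.guessing is not None
                     else None)
    props = np.empty((n_sim, q.n_items))
    for s in range(n_sim):
        theta = priors.theta_mean + priors.theta_sd * rng.standard_normal(
            (n_persons, ms.n_components))
        if fixed_params is not None:
            eta_v, alpha_v, guess_v = eta_fix, alpha_fix, guess_fix
        else:
            eta_v = priors.eta_mean + priors.eta_sd * rng.standard_normal(ms.n_eta)
            alpha_v = (np.abs(priors.alpha_sd * rng.standard_normal(ms.n_groups))
                       if ms.has_alpha else None)
            guess_v = (rng.beta(priors.guessing_a, priors.guessing_b,
                                size=q.n_items)
                       if ms.has_guessing else None)
        b = ms.eta_to_b(eta_v)
        A = ms.alpha_matrix(np.log(np.maximum(alpha_v, 1e-300))
                            if alpha_v is not None else None) \
            if ms.has_alpha else ms.c_matrix
        z = A[None, :, :] * (theta[:, None, :] - b[None, :, :])
        log_pi = np.einsum("njm,jm->nj", log_logistic(z), ms.c_matrix)
        p = np.exp(log_pi)
        if ms.has_guessing and guess_v is not None:
            p = guess_v[None, :] + (1 - guess_v[None, :]) * p
        rep = rng.random(p.shape) < p
        props[s] = rep.mean(axis=0)
    return pd.DataFrame({
        "item": list(q.item_ids),
        "q2.5": np.quantile(props, 0.025, axis=0),
        "median": np.quantile(props, 0.5, axis=0),
        "mean": props.mean(axis=0),
        "q97.5": np.quantile(props, 0.975, axis=0),
    })


def posterior_predictive_marginals(
    fit: FitResult,
    y,
    n_replicates: int = 1000,
    seed: int = 0,
) -> PredictiveSummary:
    """Posterior predictive check of per-item marginal success proportions.

    For each selected posterior draw, a full replicate response matrix is
    simulated (abilities taken from that draw, so parameter uncertainty
    propagates) and its item proportions recorded; the observed proportions
    (Dobs) are attached with an outside-interval flag.
    """
    rng = np.random.default_rng(seed)
    idx = _replicate_indices(fit, n_replicates, rng)
    obs_mask = np.asarray(y.observed, dtype=bool)
    props = np.empty((len(idx), fit.structure.n_items))
    n_obs = np.maximum(obs_mask.sum(axis=0), 1)
    for r, (ci, di) in enumerate(idx):
        p = _draw_probabilities(fit, ci, di)
        rep = rng.random(p.shape) < p
        props[r] = (rep & obs_mask).sum(axis=0) / n_obs
    lower = np.quantile(props, 0.025, axis=0)
    upper = np.quantile(props, 0.975, axis=0)
    eap = props.mean(axis=0)
    dobs = y.item_proportions()
    table = pd.DataFrame({
        "item": list(y.item_ids),
        "lower": lower,
        "eap": eap,
        "upper": upper,
        "dobs": dobs,
        "outside": (dobs < lower) | (dobs > upper),
    })
    return PredictiveSummary(table=table, n_replicates=len(idx))


def discordance_rate(ps: PredictiveSummary) -> float:
    """Fraction of items whose observed proportion lies strictly outside
    its posterior predictive interval."""
    t = ps.table
    return float(np.mean((t["dobs"] < t["lower"]) | (t["dobs"] > t["upper"])))


def interval_bias(ps: PredictiveSummary) -> float:
    """Mean exceedance of observed proportions beyond their intervals.

    Items inside their interval contribute 0; outside items contribute the
    distance from the observed proportion to the nearest interval endpoint.
    """
    t = ps.table
    below = np.maximum(t["lower"] - t["dobs"], 0.0)
    above = np.maximum(t["dobs"] - t["upper"], 0.0)
    return float(np.mean(below + above))


def _summary_stats(entries: np.ndarray, observed: np.ndarray):
    """Item proportions and pairwise inter-item Pearson correlations."""
    df = pd.DataFrame(np.where(observed, entries.astype(float), np.nan))
    props = df.mean(axis=0).to_numpy()
    corr = df.corr().to_numpy()
    return props, corr


def srmr_from_stats(obs_props, obs_corr, implied_props, implied_corr) -> float:
    """Pooled RMS of proportion and correlation residuals.

    Residuals over the J marginal proportions and the J(J−1)/2 distinct
    inter-item correlations are pooled into one root mean square. Items
    with undefined correlations (zero variance) are excluded, with a
    logged warning.
    """
    obs_props = np.asarray(obs_props, dtype=float)
    implied_props = np.asarray(implied_props, dtype=float)
    J = obs_props.size
    resid = list(obs_props - implied_props)
    iu = np.triu_indices(J, k=1)
    oc = np.asarray(obs_corr, dtype=float)[iu]
    ic = np.asarray(implied_corr, dtype=float)[iu]
    defined = np.isfinite(oc) & np.isfinite(ic)
    if not defined.all():
        logger.warning(
            "excluding %d undefined inter-item correlations (zero variance)",
            int((~defined).sum()),
        )
    resid += list(oc[defined] - ic[defined])
    return float(np.sqrt(np.mean(np.square(resid))))


def srmr(y, fit: FitResult, n_replicates: int = 200, seed: int = 0) -> float:
    """Standardized root mean square residual for a fitted model.

    Compares observed item proportions and inter-item correlations with
    their posterior-predictive means over replicated datasets.
    """
    entries = np.asarray(y.entries)
    observed = np.asarray(y.observed, dtype=bool)
    if entries.shape[1] < 2:
        raise ValueError("SRMR requires at least 2 items")
    obs_props, obs_corr = _summary_stats(entries, observed)
    rng = np.random.default_rng(seed)
    idx = _replicate_indices(fit, n_replicates, rng)
    props_acc = np.zeros(entries.shape[1])
    corr_acc = np.zeros((entries.shape[1], entries.shape[1]))
    corr_n = np.zeros_like(corr_acc)
    for ci, di in idx:
        p = _draw_probabilities(fit, ci, di)
        rep = (rng.random(p.shape) < p).astype(np.int8)
        rp, rc = _summary_stats(rep, observed)
        props_acc += rp
        ok = np.isfinite(rc)
        corr_acc[ok] += rc[ok]
        corr_n += ok
    implied_props = props_acc / len(idx)
    with np.errstate(invalid="ignore"):
        implied_corr = np.where(corr_n > 0, corr_acc / np.maximum(corr_n, 1), np.nan)
    return srmr_from_stats(obs_props, obs_corr, implied_props, implied_corr)


def waic(pointwise_loglik: np.ndarray):
    """WAIC on the deviance scale from an (S, N, J) pointwise array.

    lppd = Σ_cells log mean_s exp(ll); p_waic = Σ_cells var_s(ll) (sample
    variance); waic = −2 (lppd − p_waic). Cells that are NaN across all
    draws are treated as missing; any other non-finite value is an error.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim == 2:
        ll = ll[:, :, None]
    S = ll.shape[0]
    if S < 2:
        raise ValueError("WAIC needs >= 2 draws for the variance term")
    missing = np.isnan(ll).all(axis=0)
    bad = ~np.isfinite(ll) & ~np.isnan(ll)
    bad |= np.isnan(ll) & ~missing[None, :, :]
    if bad.any():
        s, n, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-finite pointwise log-likelihood at draw {s}, cell ({n}, {j})"
        )
    obs = ~missing
    ll_obs = ll[:, obs]                              # (S, n_cells)
    lppd = float(np.sum(logsumexp(ll_obs, axis=0) - np.log(S)))
    p_waic = float(np.sum(np.var(ll_obs, axis=0, ddof=1)))
    return -2.0 * (lppd - p_waic), lppd, p_waic


def compare_models(
    fits: list[FitResult],
    y,
    n_replicates: int = 500,
    seed: int = 0,
) -> ComparisonTable:
    """WAIC/SRMR/discordance/bias comparison across fitted models.

    All fits must be on the same response matrix; rows are ordered by WAIC
    ascending with ties broken by model name.
    """
    shapes = {f.y.shape for f in fits}
    if len(shapes) != 1 or next(iter(shapes)) != np.asarray(y.entries).shape:
        raise ValueError("all fits must be on the same response matrix as y")
    rows = []
    for fit in fits:
        w, lppd, p_w = waic(fit.pointwise_loglik)
        ps = posterior_predictive_marginals(fit, y, n_replicates=n_replicates,
                                            seed=seed)
        rows.append({
            "model": fit.model_kind,
            "waic": w,
            "lppd": lppd,
            "p_waic": p_w,
            "srmr": srmr(y, fit, n_replicates=min(n_replicates, 200), seed=seed),
            "discordance": discordance_rate(ps),
            "interval_bias": interval_bias(ps),
        })
    table = pd.DataFrame(rows).sort_values(
        ["waic", "model"], kind="mergesort").reset_index(drop=True)
    table.index = pd.RangeIndex(1, len(table) + 1, name="rank")
    return ComparisonTable(table=table.reset_index())


def icc_curve(item: int, composed: ComposedItemParameters, theta_grid) -> pd.DataFrame:
    """Component-wise and joint item characteristic curves for one item.

    For each active component m the marginal curve σ(α_jm (θ − b_jm)) is
    evaluated over the grid; the joint curve c_j + (1 − c_j) Π_m σ(·) is
    evaluated along the diagonal where every active ability equals the grid
    value. Each component curve crosses 0.5 at θ = b_jm, and the joint
    curve's left asymptote is the guessing floor c_j.
    """
    grid = np.asarray(theta_grid, dtype=float)
    if not np.isfinite(grid).all():
        raise ValueError("theta grid must be finite")
    b = composed.difficulty[item]
    active = composed.active[item]
    A = (composed.discrimination[item] if composed.discrimination is not None
         else np.where(active, 1.0, 0.0))
    c = float(composed.guessing[item]) if composed.guessing is not None else 0.0
    out = {"theta": grid}
    log_joint = np.zeros_like(grid)
    comp_ids = (composed.component_ids
                or tuple(str(m + 1) for m in range(b.size)))
    for m in range(b.size):
        if not active[m]:
            continue
        lz = log_logistic(A[m] * (grid - b[m]))
        out[f"component_{comp_ids[m]}"] = np.exp(lz)
        log_joint += lz
    out["joint"] = c + (1 - c) * np.exp(log_joint)
    return pd.DataFrame(out)
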