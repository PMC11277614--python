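"""Bayesian estimation of the four nested latent trait models.

The posterior is sampled with the package's NUTS implementation on an
unconstrained parameter vector:

* θ (person × component abilities) and η (feature difficulties) live on the
  real line under standard-normal priors;
* discriminations α carry a half-normal(0, 1) prior and are sampled as
  log α with the Jacobian correction;
* guessing parameters c carry a Beta(3, 20) prior and are sampled as
  logit c with the Jacobian correction.

Model kinds:

``lltm``
    Rasch-type with β = Qη; unidimensional (the component structure is
    collapsed to a single column of ones).
``c2pl``
    Constrained 2PL: unidimensional with one slope per item.
``mltmd``
    Non-compensatory multicomponent model; slopes fixed at 1, no guessing.
``gmltmd``
    The generalized model: slopes shared within discrimination groups
    (items with identical feature patterns inside a component), plus
    per-item guessing.

The likelihood unit is a single person-item response; missing responses are
dropped from the likelihood (ignorable missingness).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from functools import cached_property

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import sampler as _sampler
from .structures import (
    ComponentStructure,
    DiscriminationPartition,
    FeatureMatrix,
    discrimination_partition,
)

logger = logging.getLogger(__name__)

MODEL_KINDS = ("lltm", "c2pl", "mltmd", "gmltmd")

__all__ = [
    "PriorSpec",
    "SamplerConfig",
    "FitResult",
    "ModelStructure",
    "build_model_structure",
    "fit_model",
    "check_convergence",
    "eap_abilities",
    "MODEL_KINDS",
]


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters; defaults follow the models' standard setup.

    θ_im ~ Normal(0, 1), η_mk ~ Normal(0, 1), α ~ Normal(0, 1) truncated to
    [0, ∞) (half-normal), c_j ~ Beta(3, 20).
    """

    theta_mean: float = 0.0
    theta_sd: float = 1.0
    eta_mean: float = 0.0
    eta_sd: float = 1.0
    alpha_sd: float = 1.0
    guessing_a: float = 3.0
    guessing_b: float = 20.0


@dataclass(frozen=True)
class SamplerConfig:
    """Sampler settings; the seed fully determines the draws."""

    chains: int = 4
    warmup: int = 1000
    samples: int = 1000
    seed: int = 1
    target_accept: float = 0.8
    max_treedepth: int = 10


@dataclass(frozen=True)
class ModelStructure:
    """Index bookkeeping mapping a flat unconstrained vector to parameters."""

    model_kind: str
    n_persons: int
    n_items: int
    n_components: int
    q: np.ndarray                       # (J, K) float
    c_matrix: np.ndarray                # (J, M) float
    incidence: np.ndarray               # (K, M) int
    eta_pairs: tuple[tuple[int, int], ...]
    group_of: np.ndarray | None         # (J, M) int or None when slopes fixed
    n_groups: int
    has_alpha: bool
    has_guessing: bool
    partition: DiscriminationPartition | None = None

    @property
    def n_eta(self) -> int:
        return len(self.eta_pairs)

    @property
    def dim(self) -> int:
        d = self.n_persons * self.n_components + self.n_eta
        if self.has_alpha:
            d += self.n_groups
        if self.has_guessing:
            d += self.n_items
        return d

    def unpack(self, x: np.ndarray):
        N, M, J = self.n_persons, self.n_components, self.n_items
        i = N * M
        theta = x[:i].reshape(N, M)
        eta = x[i:i + self.n_eta]
        i += self.n_eta
        if self.has_alpha:
            log_alpha = x[i:i + self.n_groups]
            i += self.n_groups
        else:
            log_alpha = None
        logit_c = x[i:i + J] if self.has_guessing else None
        return theta, eta, log_alpha, logit_c

    def eta_to_b(self, eta: np.ndarray) -> np.ndarray:
        """Composed difficulties b (J, M) from the active η vector."""
        K, M = self.incidence.shape
        full = np.zeros((K, M))
        for (m, k), v in zip(self.eta_pairs, eta):
            full[k, m] = v
        return self.q @ full

    def alpha_matrix(self, log_alpha) -> np.ndarray:
        """Per-item (J, M) slopes; 1 where slopes are fixed, 0 on inactive cells."""
        if not self.has_alpha:
            return self.c_matrix.copy()
        alpha = np.exp(np.clip(log_alpha, -40.0, 40.0))
        A = np.zeros((self.n_items, self.n_components))
        active = self.group_of >= 0
        A[active] = alpha[self.group_of[active]]
        return A


def _collapse_unidimensional(q: FeatureMatrix) -> ComponentStructure:
    inc = np.ones((q.n_features, 1), dtype=np.int8)
    C = np.ones((q.n_items, 1), dtype=np.int8)
    return ComponentStructure(
        incidence=inc, component_matrix=C, component_ids=("1",), derived_flag=True
    )


def build_model_structure(
    q: FeatureMatrix, cs: ComponentStructure, model_kind: str
) -> ModelStructure:
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}; expected one of {MODEL_KINDS}")
    if model_kind in ("lltm", "c2pl"):
        cs = _collapse_unidimensional(q)
    J, K = q.entries.shape
    M = cs.n_components
    partition = None
    if model_kind == "gmltmd":
        partition = discrimination_partition(q, cs)
        group_of = np.asarray(partition.group_of)
        n_groups = partition.n_groups
        has_alpha, has_guessing = True, True
    elif model_kind == "c2pl":
        group_of = np.arange(J, dtype=int).reshape(J, 1)
        n_groups = J
        has_alpha, has_guessing = True, False
    else:
        group_of, n_groups = None, 0
        has_alpha, has_guessing = False, False
    return ModelStructure(
        model_kind=model_kind,
        n_persons=0,  # filled at fit time
        n_items=J,
        n_components=M,
        q=q.entries.astype(float),
        c_matrix=cs.component_matrix.astype(float),
        incidence=np.asarray(cs.incidence),
        eta_pairs=tuple(cs.active_eta()),
        group_of=group_of,
        n_groups=n_groups,
        has_alpha=has_alpha,
        has_guessing=has_guessing,
        partition=partition,
    )


_TINY = 1e-300


def _loglik_terms(ms: ModelStructure, theta, b, A, logit_c, y, obs):
    """Per-cell log-likelihood pieces shared by value and gradient.

    Returns (ll, aux) where ll is the summed log likelihood over observed
    cells and aux carries the arrays the gradient needs. The product over
    components is accumulated in log space; intermediate probabilities are
    floored at the smallest normal float so ratios stay finite.
    """
    C = ms.c_matrix                                    # (J, M)
    z = A[None, :, :] * (theta[:, None, :] - b[None, :, :])   # (N, J, M)
    sig = expit(z)
    with np.errstate(divide="ignore"):
        logsig = np.log(np.maximum(sig, _TINY))
    log_pi = np.einsum("njm,jm->nj", logsig, C)
    pi = np.exp(log_pi)
    one_m_pi = np.maximum(-np.expm1(log_pi), _TINY)
    log_1m_pi = np.log(one_m_pi)
    if ms.has_guessing:
        lc = np.clip(logit_c, -40.0, 40.0)
        c = expit(lc)
        one_m_c = expit(-lc)
        log_c = np.log(c)
        log_1m_c = np.log(one_m_c)
        p1 = c[None, :] + one_m_c[None, :] * pi
        ll1 = np.log(p1)
        ll0 = log_1m_c[None, :] + log_1m_pi
    else:
        c = one_m_c = log_c = log_1m_c = p1 = None
        ll1 = log_pi
        ll0 = log_1m_pi
    ll_cells = np.where(y == 1, ll1, ll0)
    ll = float(np.sum(ll_cells, where=obs))
    return ll, (z, sig, pi, one_m_pi, c, one_m_c, log_c, log_1m_c, p1,
                ll1, ll0)


def make_logpost(ms: ModelStructure, y: np.ndarray, obs: np.ndarray,
                 priors: PriorSpec):
    """Return f(x) -> (log posterior, gradient) on the unconstrained vector."""
    C = ms.c_matrix
    obs_f = obs.astype(float)
    y1 = (y == 1) & obs
    y0 = (y == 0) & obs

    def logpost(x: np.ndarray):
        theta, eta, log_alpha, logit_c = ms.unpack(x)
        b = ms.eta_to_b(eta)
        A = ms.alpha_matrix(log_alpha)
        ll, aux = _loglik_terms(ms, theta, b, A, logit_c, y, obs)
        (z, sig, pi, one_m_pi, c, one_m_c, log_c, log_1m_c, p1,
         ll1, ll0) = aux

        # priors (log densities up to constants)
        lp = ll
        lp += -0.5 * float(np.sum(((theta - priors.theta_mean) / priors.theta_sd) ** 2))
        lp += -0.5 * float(np.sum(((eta - priors.eta_mean) / priors.eta_sd) ** 2))
        if ms.has_alpha:
            la = np.clip(log_alpha, -40.0, 40.0)
            alpha = np.exp(la)
            lp += float(np.sum(-0.5 * (alpha / priors.alpha_sd) ** 2 + la))
        if ms.has_guessing:
            # Beta(a, b) on c with logit transform: a·log c + b·log(1 − c)
            lp += float(np.sum(priors.guessing_a * log_c
                               + priors.guessing_b * log_1m_c))

        # likelihood gradient through z; dΠ/dz_m = Π σ(−z_m) on active cells
        dfac = np.zeros_like(pi)
        if ms.has_guessing:
            dfac[y1] = (one_m_c[None, :] * pi / p1)[y1]
        else:
            dfac[y1] = 1.0
        dfac[y0] = -(pi / one_m_pi)[y0]
        gz = dfac[:, :, None] * (1.0 - sig) * C[None, :, :]

        grad = np.empty_like(x)
        N, M = ms.n_persons, ms.n_components
        dtheta = np.einsum("njm,jm->nm", gz, A) - (theta - priors.theta_mean) / priors.theta_sd ** 2
        grad[: N * M] = dtheta.ravel()
        db = -np.einsum("njm->jm", gz * A[None, :, :])   # ∂ll/∂b
        i = N * M
        for idx, (m, k) in enumerate(ms.eta_pairs):
            grad[i + idx] = float(np.dot(db[:, m], ms.q[:, k]))
        grad[i:i + ms.n_eta] -= (eta - priors.eta_mean) / priors.eta_sd ** 2
        i += ms.n_eta
        if ms.has_alpha:
            dA = np.einsum("njm,njm->jm", gz, theta[:, None, :] - b[None, :, :])
            dalpha = np.zeros(ms.n_groups)
            active = ms.group_of >= 0
            np.add.at(dalpha, ms.group_of[active], dA[active])
            grad[i:i + ms.n_groups] = alpha * dalpha - alpha ** 2 / priors.alpha_sd ** 2 + 1.0
            i += ms.n_groups
        if ms.has_guessing:
            dc_like = np.zeros_like(pi)
            dc_like[y1] = (one_m_pi / p1)[y1]                   # (1 − Π)/p
            dc_like[y0] = (-1.0 / one_m_c)[np.nonzero(y0)[1]]   # −1/(1 − c)
            dll_dc = np.sum(dc_like * obs_f, axis=0)
            grad[i:i + ms.n_items] = (
                c * one_m_c * dll_dc
                + priors.guessing_a * one_m_c
                - priors.guessing_b * c
            )
        return lp, grad

    return logpost


def pointwise_loglik(ms: ModelStructure, draws: dict, y: np.ndarray,
                     obs: np.ndarray) -> np.ndarray:
    """(S, N, J) log p(y_ij | draw s) over all chains' draws; NaN where missing."""
    theta_d = draws["theta"]                   # (chains, n, N, M)
    n_chains, n_draws = theta_d.shape[:2]
    S = n_chains * n_draws
    N, J = y.shape
    out = np.full((S, N, J), np.nan)
    s = 0
    for ch in range(n_chains):
        for d in range(n_draws):
            theta = theta_d[ch, d]
            b = ms.eta_to_b(draws["eta"][ch, d])
            if ms.has_alpha:
                A = ms.alpha_matrix(np.log(draws["alpha"][ch, d]))
            else:
                A = ms.c_matrix
            lc = logit(np.clip(draws["guessing"][ch, d], 1e-12, 1 - 1e-12)) \
                if ms.has_guessing else None
            _, aux = _loglik_terms(ms, theta, b, A, lc, y, obs)
            ll1, ll0 = aux[9], aux[10]
            cell = np.where(y == 1, ll1, ll0)
            cell[~obs] = np.nan
            out[s] = cell
            s += 1
    return out


@dataclass
class FitResult:
    """Posterior draws, diagnostics and summaries for one fitted model.

    ``draws`` maps parameter block name → array with leading (chain, draw)
    axes, on the natural scale (α positive, c in (0, 1)).
    """

    model_kind: str
    structure: ModelStructure
    draws: dict
    y: np.ndarray
    obs_mask: np.ndarray
    config: SamplerConfig
    priors: PriorSpec
    divergences: tuple[int, ...]
    person_ids: tuple[str, ...]
    item_ids: tuple[str, ...]

    @cached_property
    def diagnostics(self) -> pd.DataFrame:
        """Per-parameter split R-hat and bulk ESS (via arviz).

        R-hat is the classic split Gelman–Rubin statistic (each chain halved,
        between/within variance ratio); bulk ESS uses the rank-normalized
        estimator.
        """
        import arviz as az

        rows = []
        for name, arr in self.draws.items():
            ds = az.convert_to_dataset({name: arr})
            rhat = np.asarray(az.rhat(ds, method="split")[name])
            ess = np.asarray(az.ess(ds)[name])
            flat_r = np.ravel(rhat)
            flat_e = np.ravel(ess)
            labels = self._labels(name, np.shape(rhat))
            for lab, r, e in zip(labels, flat_r, flat_e):
                rows.append({"parameter": lab, "rhat": float(r), "ess_bulk": float(e)})
        return pd.DataFrame(rows)

    def _labels(self, name, shape):
        if shape == ():
            return [name]
        return [name + "[" + ",".join(str(i) for i in idx) + "]"
                for idx in np.ndindex(*shape)]

    @cached_property
    def summaries(self) -> pd.DataFrame:
        """EAP and central 2.5/97.5% quantiles per parameter."""
        rows = []
        for name, arr in self.draws.items():
            flat = arr.reshape(-1, *arr.shape[2:])
            eap = flat.mean(axis=0)
            lo = np.quantile(flat, 0.025, axis=0)
            hi = np.quantile(flat, 0.975, axis=0)
            labels = self._labels(name, np.shape(eap))
            for lab, e, l, h in zip(labels, np.ravel(eap), np.ravel(lo), np.ravel(hi)):
                rows.append({"parameter": lab, "eap": float(e),
                             "q2.5": float(l), "q97.5": float(h)})
        return pd.DataFrame(rows)

    @cached_property
    def pointwise_loglik(self) -> np.ndarray:
        """(S, N, J) pointwise log-likelihood; computed lazily from the draws."""
        return pointwise_loglik(self.structure, self.draws, self.y, self.obs_mask)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]


def _pack_draws(ms: ModelStructure, raw: np.ndarray) -> dict:
    """Split (chains, draws, dim) unconstrained draws into natural-scale blocks."""
    n_chains, n_draws, _ = raw.shape
    N, M, J = ms.n_persons, ms.n_components, ms.n_items
    i = N * M
    out = {"theta": raw[:, :, :i].reshape(n_chains, n_draws, N, M)}
    out["eta"] = raw[:, :, i:i + ms.n_eta].copy()
    i += ms.n_eta
    if ms.has_alpha:
        out["alpha"] = np.exp(raw[:, :, i:i + ms.n_groups])
        i += ms.n_groups
    if ms.has_guessing:
        out["guessing"] = expit(raw[:, :, i:i + J])
    return out


def fit_model(
    y,
    q: FeatureMatrix,
    cs: ComponentStructure,
    model_kind: str,
    priors: PriorSpec | None = None,
    cfg: SamplerConfig | None = None,
) -> FitResult:
    """Fit one of the four models by NUTS and return a FitResult.

    ``y`` is a ResponseMatrix (see the simulation module) or anything with
    ``entries`` (N, J in {0,1}), ``observed`` mask, ``person_ids`` and
    ``item_ids``. Item labels must match the Q matrix.
    """
    priors = priors or PriorSpec()
    cfg = cfg or SamplerConfig()
    if tuple(y.item_ids) != tuple(q.item_ids):
        raise ValueError(
            "response-matrix item labels do not match the Q matrix "
            f"({list(y.item_ids)[:3]}... vs {list(q.item_ids)[:3]}...)"
        )
    ms = build_model_structure(q, cs, model_kind)
    entries = np.asarray(y.entries)
    obs = np.asarray(y.observed, dtype=bool)
    ms = replace(ms, n_persons=entries.shape[0])
    logpost = make_logpost(ms, entries, obs, priors)

    ss = np.random.SeedSequence(cfg.seed)
    child_seeds = ss.spawn(cfg.chains)
    raw = np.empty((cfg.chains, cfg.samples, ms.dim))
    divergences = []
    for ch in range(cfg.chains):
        rng = np.random.default_rng(child_seeds[ch])
        x0 = 0.1 * rng.standard_normal(ms.dim)
        if ms.has_guessing:
            # start c near its prior mean rather than 0.5
            a, bb = priors.guessing_a, priors.guessing_b
            x0[-ms.n_items:] += logit(a / (a + bb))
        try:
            res = _sampler.nuts_chain(
                logpost, x0, cfg.warmup, cfg.samples, rng,
                target_accept=cfg.target_accept,
                max_treedepth=cfg.max_treedepth,
            )
        except Exception as err:  # surface the config with the backend error
            raise RuntimeError(
                f"sampler failed on chain {ch} for model {model_kind!r} "
                f"with config {cfg}: {err}"
            ) from err
        raw[ch] = res.draws
        divergences.append(res.divergences)
        logger.info(
            "chain %d/%d done: step_size=%.3g accept=%.2f divergences=%d",
            ch + 1, cfg.chains, res.step_size, res.accept_stat, res.divergences,
        )
    return FitResult(
        model_kind=model_kind,
        structure=ms,
        draws=_pack_draws(ms, raw),
        y=entries,
        obs_mask=obs,
        config=cfg,
        priors=priors,
        divergences=tuple(divergences),
        person_ids=tuple(y.person_ids),
        item_ids=tuple(y.item_ids),
    )


def check_convergence(fit: FitResult, rhat_max: float = 1.01) -> pd.DataFrame:
    """Pass/fail convergence report per parameter block.

    Requires at least two chains (split R-hat over one chain is not
    configured here). Returns a table with the worst R-hat, the smallest
    ESS, divergence counts and a boolean ``passed`` per block.
    """
    if fit.n_chains < 2:
        raise ValueError("convergence check requires >= 2 chains")
    diag = fit.diagnostics
    diag = diag.assign(block=diag["parameter"].str.replace(r"\[.*", "", regex=True))
    rows = []
    for block, sub in diag.groupby("block", sort=False):
        worst = sub.loc[sub["rhat"].idxmax()]
        failed = sub[sub["rhat"] > rhat_max]
        rows.append({
            "block": block,
            "max_rhat": float(worst["rhat"]),
            "worst_parameter": worst["parameter"],
            "min_ess_bulk": float(sub["ess_bulk"].min()),
            "n_failing": int(len(failed)),
            "failing_parameters": ",".join(failed["parameter"].head(10)),
            "passed": bool(len(failed) == 0),
        })
    report = pd.DataFrame(rows)
    report.attrs["divergences"] = fit.divergences
    report.attrs["passed"] = bool(report["passed"].all())
    return report


def eap_abilities(fit: FitResult) -> pd.DataFrame:
    """Person × component EAP ability table with central 95% intervals."""
    theta = fit.draws["theta"]
    flat = theta.reshape(-1, *theta.shape[2:])     # (S, N, M)
    eap = flat.mean(axis=0)
    lo = np.quantile(flat, 0.025, axis=0)
    hi = np.quantile(flat, 0.975, axis=0)
    N, M = eap.shape
    comp_ids = (fit.structure.partition.component_ids
                if fit.structure.partition is not None
                else tuple(str(m + 1) for m in range(M)))
    rows = []
    for i in range(N):
        for m in range(M):
            rows.append({
                "person": fit.person_ids[i],
                "component": comp_ids[m] if m < len(comp_ids) else str(m + 1),
                "eap": eap[i, m],
                "q2.5": lo[i, m],
                "q97.5": hi[i, m],
            })
    return pd.DataFrame(rows)
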