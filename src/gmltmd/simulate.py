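"""Generative simulation for all four models and the recovery harness.

Includes the canonical study-emulating fixture: the 27-item figural
analogies test built from five composition rules (principal-figure
rotation, trapezium rotation, whole-figure reflection, line subtraction,
point movement), its published Q matrix, the global/local two-component
assignment (rules 1–3 → component 1, rules 4–5 → component 2), and the
generalized-model point estimates used as ground-truth parameters for
parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .inference import PriorSpec, SamplerConfig, fit_model
from .structures import (
    ComponentStructure,
    FeatureMatrix,
    ParameterSet,
    derive_component_matrix,
    discrimination_partition,
    expand_composed,
    validate_feature_matrix,
)
from .kernels import log_logistic

__all__ = [
    "ResponseMatrix",
    "RecoveryReport",
    "simulate_responses",
    "study_fixture",
    "recovery_study",
    "analogy_q_matrix",
    "analogy_component_structure",
    "analogy_true_parameters",
]

# 27 × 5 Q matrix of the figural analogies test (items × composition rules).
ANALOGY_Q = np.array([
    [0, 1, 0, 0, 0],
    [0, 0, 1, 0, 0],
    [1, 0, 0, 0, 0],
    [0, 0, 0, 0, 1],
    [1, 0, 0, 0, 0],
    [0, 1, 0, 0, 0],
    [1, 1, 0, 0, 0],
    [0, 1, 1, 0, 1],
    [1, 1, 0, 1, 1],
    [1, 1, 0, 0, 0],
    [0, 1, 1, 1, 1],
    [1, 0, 0, 0, 1],
    [1, 1, 0, 0, 1],
    [1, 1, 0, 1, 1],
    [0, 1, 0, 0, 1],
    [1, 1, 0, 0, 1],
    [1, 1, 0, 1, 1],
    [1, 1, 0, 0, 0],
    [0, 1, 1, 0, 1],
    [1, 1, 0, 1, 1],
    [0, 1, 1, 0, 0],
    [1, 1, 0, 0, 1],
    [0, 1, 1, 1, 1],
    [0, 0, 1, 0, 1],
    [1, 1, 0, 0, 1],
    [0, 1, 1, 0, 0],
    [1, 1, 0, 0, 1],
], dtype=np.int8)

RULE_IDS = ("rule1", "rule2", "rule3", "rule4", "rule5")

# rules 1-3 measure the global component, rules 4-5 the local component
ANALOGY_INCIDENCE = np.array([
    [1, 0],
    [1, 0],
    [1, 0],
    [0, 1],
    [0, 1],
], dtype=np.int8)

# Published EAP point estimates of the generalized model on the 383-person
# dataset: rule difficulties per component, group-shared discriminations and
# per-item guessing. Used as the canonical ground truth for simulation.
ANALOGY_ETA = {
    (0, 0): 0.29,   # rule 1, global
    (0, 1): 0.77,   # rule 2, global
    (0, 2): 0.39,   # rule 3, global
    (1, 3): 0.87,   # rule 4, local
    (1, 4): -0.79,  # rule 5, local
}

# discrimination per (component, restricted feature pattern); patterns are in
# Q column order over all five rules
ANALOGY_ALPHA_BY_PATTERN = {
    (0, (0, 0, 1, 0, 0)): 2.42,  # reflection only
    (0, (0, 1, 0, 0, 0)): 1.42,  # trapezium rotation only
    (0, (0, 1, 1, 0, 0)): 1.66,  # trapezium rotation + reflection
    (0, (1, 0, 0, 0, 0)): 1.65,  # principal rotation only
    (0, (1, 1, 0, 0, 0)): 2.19,  # principal + trapezium rotation
    (1, (0, 0, 0, 0, 1)): 2.66,  # point movement only
    (1, (0, 0, 0, 1, 1)): 1.78,  # line subtraction + point movement
}

ANALOGY_GUESSING = np.array([
    0.27, 0.57, 0.07, 0.07, 0.08, 0.11, 0.20, 0.09, 0.09, 0.20, 0.08,
    0.07, 0.12, 0.08, 0.27, 0.23, 0.04, 0.03, 0.12, 0.07, 0.13, 0.19,
    0.02, 0.18, 0.08, 0.03, 0.03,
])


def analogy_q_matrix() -> FeatureMatrix:
    """The 27 × 5 Q matrix of the figural analogies test."""
    return validate_feature_matrix(
        ANALOGY_Q,
        item_ids=[str(j) for j in range(1, 28)],
        feature_ids=RULE_IDS,
    )


def analogy_component_structure(q: FeatureMatrix | None = None) -> ComponentStructure:
    """Global/local two-component assignment: rules 1–3 vs rules 4–5."""
    q = q or analogy_q_matrix()
    return derive_component_matrix(q, ANALOGY_INCIDENCE,
                                   component_ids=("global", "local"))


def analogy_true_parameters(q=None, cs=None, n_persons: int = 383,
                            rng: np.random.Generator | None = None) -> ParameterSet:
    """Canonical ground-truth ParameterSet (θ drawn standard normal)."""
    q = q or analogy_q_matrix()
    cs = cs or analogy_component_structure(q)
    part = discrimination_partition(q, cs)
    alpha = {}
    for gi, (m, pattern, _members) in enumerate(part.groups):
        alpha[gi] = ANALOGY_ALPHA_BY_PATTERN[(m, pattern)]
    rng = rng or np.random.default_rng(0)
    theta = rng.standard_normal((n_persons, cs.n_components))
    return ParameterSet(theta=theta, eta=dict(ANALOGY_ETA), alpha=alpha,
                        guessing=ANALOGY_GUESSING.copy())


@dataclass(frozen=True)
class ResponseMatrix:
    """Binary person × item responses with a missingness mask."""

    entries: np.ndarray          # (N, J) int, 0 where missing
    observed: np.ndarray         # (N, J) bool
    person_ids: tuple[str, ...]
    item_ids: tuple[str, ...]

    @property
    def n_persons(self) -> int:
        return self.entries.shape[0]

    @property
    def n_items(self) -> int:
        return self.entries.shape[1]

    def item_proportions(self) -> np.ndarray:
        """Observed marginal success proportion per item."""
        obs = self.observed
        with np.errstate(invalid="ignore"):
            return np.where(
                obs.sum(axis=0) > 0,
                (self.entries * obs).sum(axis=0) / np.maximum(obs.sum(axis=0), 1),
                np.nan,
            )

    def to_frame(self) -> pd.DataFrame:
        data = self.entries.astype(object)
        data = np.where(self.observed, data, pd.NA)
        return pd.DataFrame(data, index=list(self.person_ids),
                            columns=list(self.item_ids))


def success_probabilities(model_kind: str, q: FeatureMatrix,
                          cs: ComponentStructure, params: ParameterSet,
                          theta: np.ndarray) -> np.ndarray:
    """(N, J) success probabilities under the chosen kernel, vectorized."""
    composed = expand_composed(q, cs, params)
    b, active = composed.difficulty, composed.active
    if model_kind in ("lltm", "mltmd"):
        A = np.where(active, 1.0, 0.0)
    else:
        A = composed.discrimination
    z = A[None, :, :] * (theta[:, None, :] - b[None, :, :])
    log_pi = np.sum(np.where(active[None, :, :], log_logistic(z), 0.0), axis=2)
    pi = np.exp(log_pi)
    if model_kind == "gmltmd":
        c = composed.guessing
        return c[None, :] + (1.0 - c[None, :]) * pi
    return pi


def simulate_responses(
    model_kind: str,
    q: FeatureMatrix,
    cs: ComponentStructure,
    params: ParameterSet,
    n_persons: int | None = None,
    seed: int | np.random.SeedSequence = 0,
    theta_source: str = "given",
) -> ResponseMatrix:
    """Draw y_ij ~ Bernoulli(p_ij) under the chosen model kernel.

    ``theta_source='given'`` uses ``params.theta``; ``'prior'`` draws
    abilities standard normal for ``n_persons`` people.
    """
    rng = np.random.default_rng(seed)
    M = cs.n_components
    if theta_source == "prior":
        if n_persons is None:
            raise ValueError("n_persons required when theta_source='prior'")
        theta = rng.standard_normal((n_persons, M))
    elif theta_source == "given":
        theta = np.asarray(params.theta, dtype=float)
        if theta.ndim != 2 or theta.shape[1] != M:
            raise ValueError(
                f"params.theta must be (N, {M}), got shape {theta.shape}"
            )
        if n_persons is not None and n_persons != theta.shape[0]:
            raise ValueError("n_persons conflicts with the given theta")
    else:
        raise ValueError(f"unknown theta_source {theta_source!r}")
    p = success_probabilities(model_kind, q, cs, params, theta)
    entries = (rng.random(p.shape) < p).astype(np.int8)
    N, J = entries.shape
    return ResponseMatrix(
        entries=entries,
        observed=np.ones((N, J), dtype=bool),
        person_ids=tuple(f"p{i + 1}" for i in range(N)),
        item_ids=tuple(q.item_ids),
    )


def study_fixture(seed: int | np.random.SeedSequence = 0, n_persons: int = 383):
    """Study-emulating fixture: structure, canonical truth and simulated data.

    Returns (FeatureMatrix, ComponentStructure, ParameterSet, ResponseMatrix),
    with responses generated from the generalized model at the canonical
    point estimates and θ ~ N(0, 1).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    theta_ss, resp_ss = ss.spawn(2)
    q = analogy_q_matrix()
    cs = analogy_component_structure(q)
    params = analogy_true_parameters(
        q, cs, n_persons=n_persons, rng=np.random.default_rng(theta_ss)
    )
    y = simulate_responses("gmltmd", q, cs, params, seed=resp_ss)
    return q, cs, params, y


@dataclass
class RecoveryReport:
    """Aggregated parameter-recovery metrics over replications.

    ``blocks`` rows: per parameter block (eta, alpha, guessing, theta) the
    pooled bias, RMSE, 95%-interval coverage and EAP-truth correlation.
    """

    blocks: pd.DataFrame
    per_replication: pd.DataFrame
    theta_rank_corr: np.ndarray   # (n_reps, M) Spearman correlations

    def block(self, name: str) -> pd.Series:
        return self.blocks.set_index("block").loc[name]


def _truth_vector(params: ParameterSet, block: str, structure) -> np.ndarray:
    if block == "eta":
        pairs = [(m, k) for m in range(structure.incidence.shape[1])
                 for k in range(structure.incidence.shape[0])
                 if structure.incidence[k, m]]
        return np.array([params.eta[p] for p in pairs])
    if block == "alpha":
        return np.array([params.alpha[g] for g in sorted(params.alpha)])
    if block == "guessing":
        return np.asarray(params.guessing, dtype=float)
    raise KeyError(block)


def recovery_study(
    model_kind: str,
    q: FeatureMatrix,
    cs: ComponentStructure,
    true_params: ParameterSet,
    n_persons: int = 500,
    n_reps: int = 5,
    cfg: SamplerConfig | None = None,
    priors: PriorSpec | None = None,
    seed: int = 0,
    redraw_theta: bool = True,
) -> RecoveryReport:
    """Simulate → fit → score, replicated; the validation-harness pattern.

    Each replication draws fresh abilities (θ ~ N(0,1)) and responses from
    ``true_params``, fits ``model_kind``, and scores EAP estimates and 95%
    intervals against the truth. One master seed spawns independent
    substreams per replication.
    """
    cfg = cfg or SamplerConfig(chains=2, warmup=400, samples=400)
    master = np.random.SeedSequence(seed)
    rep_seeds = master.spawn(n_reps)
    blocks = ["eta"]
    if true_params.alpha is not None and model_kind in ("gmltmd", "c2pl"):
        blocks.append("alpha")
    if true_params.guessing is not None and model_kind == "gmltmd":
        blocks.append("guessing")

    rep_rows, corr_rows = [], []
    pooled: dict[str, dict[str, list]] = {
        b: {"err": [], "cover": [], "eap": [], "truth": []} for b in blocks + ["theta"]
    }
    for rep in range(n_reps):
        theta_ss, resp_ss, fit_ss = rep_seeds[rep].spawn(3)
        if redraw_theta:
            theta = np.random.default_rng(theta_ss).standard_normal(
                (n_persons, cs.n_components))
            params = ParameterSet(theta=theta, eta=true_params.eta,
                                  alpha=true_params.alpha,
                                  guessing=true_params.guessing)
        else:
            params = true_params
        y = simulate_responses(model_kind, q, cs, params, seed=resp_ss)
        fit_seed = int(fit_ss.generate_state(1)[0] % (2 ** 31))
        try:
            fit = fit_model(y, q, cs, model_kind, priors=priors,
                            cfg=SamplerConfig(
                                chains=cfg.chains, warmup=cfg.warmup,
                                samples=cfg.samples, seed=fit_seed,
                                target_accept=cfg.target_accept,
                                max_treedepth=cfg.max_treedepth))
        except Exception as err:
            raise RuntimeError(f"replication {rep} failed: {err}") from err

        row = {"replication": rep}
        for b in blocks:
            arr = fit.draws[b]
            flat = arr.reshape(-1, *arr.shape[2:])
            eap = flat.mean(axis=0)
            lo = np.quantile(flat, 0.025, axis=0)
            hi = np.quantile(flat, 0.975, axis=0)
            truth = _truth_vector(params, b, fit.structure)
            err_v = eap - truth
            cover = (truth >= lo) & (truth <= hi)
            pooled[b]["err"] += list(err_v)
            pooled[b]["cover"] += list(cover)
            pooled[b]["eap"] += list(eap)
            pooled[b]["truth"] += list(truth)
            row[f"{b}_rmse"] = float(np.sqrt(np.mean(err_v ** 2)))
            row[f"{b}_coverage"] = float(np.mean(cover))
        # theta: EAP vs simulated truth
        tdraws = fit.draws["theta"]
        tflat = tdraws.reshape(-1, *tdraws.shape[2:])
        teap = tflat.mean(axis=0)
        tlo = np.quantile(tflat, 0.025, axis=0)
        thi = np.quantile(tflat, 0.975, axis=0)
        terr = teap - params.theta
        pooled["theta"]["err"] += list(terr.ravel())
        pooled["theta"]["cover"] += list(
            ((params.theta >= tlo) & (params.theta <= thi)).ravel())
        pooled["theta"]["eap"] += list(teap.ravel())
        pooled["theta"]["truth"] += list(params.theta.ravel())
        corrs = [spearmanr(teap[:, m], params.theta[:, m]).statistic
                 for m in range(teap.shape[1])]
        corr_rows.append(corrs)
        row["theta_rank_corr_min"] = float(np.min(corrs))
        row["max_rhat"] = float(fit.diagnostics["rhat"].max())
        row["divergences"] = int(sum(fit.divergences))
        rep_rows.append(row)

    block_rows = []
    for b, acc in pooled.items():
        err_arr = np.asarray(acc["err"])
        eap_arr = np.asarray(acc["eap"])
        truth_arr = np.asarray(acc["truth"])
        corr = (float(np.corrcoef(eap_arr, truth_arr)[0, 1])
                if np.std(truth_arr) > 0 else np.nan)
        block_rows.append({
            "block": b,
            "bias": float(np.mean(err_arr)),
            "rmse": float(np.sqrt(np.mean(err_arr ** 2))),
            "coverage": float(np.mean(acc["cover"])),
            "corr_eap_truth": corr,
        })
    return RecoveryReport(
        blocks=pd.DataFrame(block_rows),
        per_replication=pd.DataFrame(rep_rows),
        theta_rank_corr=np.asarray(corr_rows),
    )
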