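"""File formats and run configuration: the reproducible outer shell.

All tables are comma-delimited text with a header row; the run
configuration is YAML. Responses are persons × items with a leading
person-id column; empty cells or NA tokens mark missing responses. The Q
matrix is items × features; the component assignment is a two-column
feature → component table (a feature may repeat under several components).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inference import FitResult, PriorSpec, SamplerConfig
from .simulate import ResponseMatrix
from .structures import (
    ComponentStructure,
    FeatureMatrix,
    derive_component_matrix,
    validate_feature_matrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_response_matrix",
    "write_response_matrix",
    "read_feature_structure",
    "write_feature_structure",
    "write_outputs",
]

_NA_TOKENS = {"", "NA", "NaN", "nan", "na", "."}


def read_response_matrix(path) -> ResponseMatrix:
    """Read a persons × items CSV (first column person id, header item ids)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    person_ids = tuple(df.iloc[:, 0].astype(str))
    if len(set(person_ids)) != len(person_ids):
        raise ValueError(f"duplicate person ids in {path}")
    item_ids = tuple(str(c) for c in df.columns[1:])
    if len(set(item_ids)) != len(item_ids):
        raise ValueError(f"duplicate item ids in {path}")
    raw = df.iloc[:, 1:].to_numpy(dtype=object)
    N, J = raw.shape
    entries = np.zeros((N, J), dtype=np.int8)
    observed = np.ones((N, J), dtype=bool)
    for i in range(N):
        for j in range(J):
            cell = str(raw[i, j]).strip()
            if cell in _NA_TOKENS:
                observed[i, j] = False
            elif cell in ("0", "1"):
                entries[i, j] = int(cell)
            else:
                raise ValueError(
                    f"non-binary response {cell!r} at person {person_ids[i]!r}, "
                    f"item {item_ids[j]!r}"
                )
    miss = 1.0 - observed.mean()
    logger.info("read responses: N=%d, J=%d, missing=%.1f%%", N, J, 100 * miss)
    return ResponseMatrix(entries=entries, observed=observed,
                          person_ids=person_ids, item_ids=item_ids)


def write_response_matrix(y: ResponseMatrix, path) -> None:
    df = y.to_frame()
    df.index.name = "person"
    df.to_csv(path, na_rep="")


def read_feature_structure(q_path, assignment_path, override_path=None):
    """Read the Q matrix and feature → component assignment; derive C.

    Returns (FeatureMatrix, ComponentStructure). The assignment file has
    columns feature, component; repeated feature rows put a feature in
    several components (cross-loading, so η exists in each). An optional
    override table (item, component) adds C entries additively.
    """
    qdf = pd.read_csv(q_path, index_col=0)
    q = validate_feature_matrix(
        qdf.to_numpy(), item_ids=qdf.index, feature_ids=qdf.columns
    )
    adf = pd.read_csv(assignment_path, dtype=str)
    if adf.shape[1] < 2:
        raise ValueError("assignment file needs columns: feature, component")
    feats = [str(v) for v in adf.iloc[:, 0]]
    comps = [str(v) for v in adf.iloc[:, 1]]
    unknown = set(feats) - set(q.feature_ids)
    if unknown:
        raise ValueError(f"assignment lists features not in Q: {sorted(unknown)}")
    missing = set(q.feature_ids) - set(feats)
    if missing:
        raise ValueError(f"features in Q missing from assignment: {sorted(missing)}")
    component_ids = tuple(dict.fromkeys(comps))      # first-appearance order
    inc = np.zeros((q.n_features, len(component_ids)), dtype=np.int8)
    for f, c in zip(feats, comps):
        inc[q.feature_ids.index(f), component_ids.index(c)] = 1
    override = None
    if override_path is not None:
        odf = pd.read_csv(override_path, dtype=str)
        derived = (q.entries @ inc > 0).astype(np.int8)
        override = derived.copy()
        for _, row in odf.iterrows():
            j = q.item_ids.index(str(row.iloc[0]))
            m = component_ids.index(str(row.iloc[1]))
            override[j, m] = 1
    cs = derive_component_matrix(q, inc, component_ids=component_ids,
                                 override=override)
    logger.info("read structure: J=%d, K=%d, M=%d", q.n_items, q.n_features,
                cs.n_components)
    return q, cs


def write_feature_structure(q: FeatureMatrix, cs: ComponentStructure,
                            q_path, assignment_path) -> None:
    qdf = q.to_frame()
    qdf.index.name = "item"
    qdf.to_csv(q_path)
    rows = [
        {"feature": q.feature_ids[k], "component": cs.component_ids[m]}
        for k in range(q.n_features)
        for m in range(cs.n_components)
        if cs.incidence[k, m]
    ]
    pd.DataFrame(rows).to_csv(assignment_path, index=False)


@dataclass
class RunConfig:
    """Structured run configuration; round-trips losslessly through YAML."""

    responses: str = ""
    q_matrix: str = ""
    assignment: str = ""
    override: str | None = None
    out_dir: str = "out"
    model: str = "gmltmd"
    seed: int = 1
    ppc_replicates: int = 1000
    priors: PriorSpec = field(default_factory=PriorSpec)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for sub, typ in (("priors", PriorSpec), ("sampler", SamplerConfig)):
            if sub in d and isinstance(d[sub], dict):
                subknown = {f.name for f in dataclasses.fields(typ)}
                bad = set(d[sub]) - subknown
                if bad:
                    raise ValueError(f"unknown {sub} keys: {sorted(bad)}")
                d[sub] = typ(**d[sub])
        return cls(**d)


def _draws_long_frame(fit: FitResult) -> pd.DataFrame:
    frames = []
    for name, arr in fit.draws.items():
        n_chains, n_draws = arr.shape[:2]
        flat = arr.reshape(n_chains, n_draws, -1)
        labels = fit._labels(name, arr.shape[2:]) if arr.ndim > 2 else [name]
        for li, lab in enumerate(labels):
            vals = flat[:, :, li]
            frames.append(pd.DataFrame({
                "chain": np.repeat(np.arange(n_chains), n_draws),
                "draw": np.tile(np.arange(n_draws), n_chains),
                "parameter": lab,
                "value": vals.ravel(),
            }))
    return pd.concat(frames, ignore_index=True)


def write_outputs(fit: FitResult, out_dir, ppc_summary=None,
                  comparison=None, config: RunConfig | None = None) -> dict:
    """Write parameter summaries, checks, draws and a run manifest as CSV/JSON.

    Returns a dict of written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}

    summ = fit.summaries
    written["parameters"] = out / "parameter_summary.csv"
    summ.to_csv(written["parameters"], index=False)

    diag = fit.diagnostics
    written["diagnostics"] = out / "diagnostics.csv"
    diag.to_csv(written["diagnostics"], index=False)

    if fit.structure.partition is not None:
        written["groups"] = out / "discrimination_groups.csv"
        fit.structure.partition.describe().to_csv(written["groups"], index=False)

    if ppc_summary is not None:
        written["ppc"] = out / "ppc_marginals.csv"
        ppc_summary.table.to_csv(written["ppc"], index=False)

    if comparison is not None:
        written["comparison"] = out / "model_comparison.csv"
        comparison.table.to_csv(written["comparison"], index=False)

    written["draws"] = out / "draws.csv"
    _draws_long_frame(fit).to_csv(written["draws"], index=False)

    manifest = {
        "model": fit.model_kind,
        "seed": fit.config.seed,
        "chains": fit.config.chains,
        "warmup": fit.config.warmup,
        "samples": fit.config.samples,
        "divergences": list(fit.divergences),
        "n_persons": fit.structure.n_persons,
        "n_items": fit.structure.n_items,
        "n_components": fit.structure.n_components,
        "python": platform.python_version(),
        "numpy": np.__version__,
    }
    if config is not None:
        manifest["config"] = dataclasses.asdict(config)
    written["manifest"] = out / "manifest.json"
    written["manifest"].write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("wrote %d output files to %s", len(written), out)
    return {k: str(v) for k, v in written.items()}
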