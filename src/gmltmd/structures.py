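"""Q-matrix data structures for multicomponent latent trait models.

The central objects are the binary item × feature incidence matrix (the Q
matrix), the feature → component assignment from which the item × component
C matrix is derived, the composed item difficulties b = Q η restricted to
each component's features, and the partition of items into discrimination
groups (items whose feature pattern within a component is identical share a
single discrimination parameter).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "ComponentStructure",
    "DiscriminationPartition",
    "ComposedItemParameters",
    "ParameterSet",
    "validate_feature_matrix",
    "derive_component_matrix",
    "compose_item_difficulties",
    "discrimination_partition",
]


@dataclass(frozen=True)
class FeatureMatrix:
    """Binary item × feature incidence matrix.

    Attributes
    ----------
    entries : (J, K) int array of {0, 1}; entry (j, k) = 1 when item j
        contains feature k.
    item_ids, feature_ids : row / column labels, preserved verbatim.
    """

    entries: np.ndarray
    item_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]

    @property
    def n_items(self) -> int:
        return self.entries.shape[0]

    @property
    def n_features(self) -> int:
        return self.entries.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, index=list(self.item_ids), columns=list(self.feature_ids)
        )


def validate_feature_matrix(raw, item_ids=None, feature_ids=None) -> FeatureMatrix:
    """Validate a raw integer matrix as a feature (Q) matrix.

    Every entry must be 0 or 1; every item must contain at least one feature
    (an all-zero item row would make the non-compensatory success probability
    degenerate), and every feature must appear in at least one item.
    """
    entries = np.asarray(raw)
    if entries.ndim != 2:
        raise ValueError(f"Q matrix must be 2-dimensional, got shape {entries.shape}")
    J, K = entries.shape
    item_ids = tuple(str(i) for i in (item_ids if item_ids is not None else range(1, J + 1)))
    feature_ids = tuple(
        str(k) for k in (feature_ids if feature_ids is not None else range(1, K + 1))
    )
    if len(item_ids) != J or len(set(item_ids)) != J:
        raise ValueError("item_ids must be unique and match the number of rows")
    if len(feature_ids) != K or len(set(feature_ids)) != K:
        raise ValueError("feature_ids must be unique and match the number of columns")
    bad = (entries != 0) & (entries != 1)
    if bad.any():
        j, k = np.argwhere(bad)[0]
        raise ValueError(
            f"non-binary Q entry {entries[j, k]!r} at item {item_ids[j]!r}, "
            f"feature {feature_ids[k]!r}"
        )
    entries = entries.astype(np.int8)
    zero_rows = np.flatnonzero(entries.sum(axis=1) == 0)
    if zero_rows.size:
        raise ValueError(
            f"item {item_ids[zero_rows[0]]!r} has no features; an all-zero Q row "
            "gives a degenerate (always-correct) item and is rejected"
        )
    zero_cols = np.flatnonzero(entries.sum(axis=0) == 0)
    if zero_cols.size:
        raise ValueError(
            f"feature {feature_ids[zero_cols[0]]!r} appears in no item"
        )
    entries.setflags(write=False)
    return FeatureMatrix(entries=entries, item_ids=item_ids, feature_ids=feature_ids)


@dataclass(frozen=True)
class ComponentStructure:
    """Feature → component incidence plus the derived item × component C matrix.

    ``incidence`` is (K, M): entry (k, m) = 1 when feature k loads on
    component m, i.e. the difficulty parameter η_mk exists. ``component_matrix``
    is the (J, M) C matrix: C_jm = 1 exactly when some feature of item j loads
    on component m (unless overridden additively).
    """

    incidence: np.ndarray
    component_matrix: np.ndarray
    component_ids: tuple[str, ...]
    derived_flag: bool = True

    @property
    def n_components(self) -> int:
        return self.incidence.shape[1]

    def active_eta(self) -> list[tuple[int, int]]:
        """Ordered (component, feature) index pairs where η exists."""
        K, M = self.incidence.shape
        return [(m, k) for m in range(M) for k in range(K) if self.incidence[k, m]]


def derive_component_matrix(
    q: FeatureMatrix,
    incidence,
    component_ids=None,
    override=None,
) -> ComponentStructure:
    """Derive the item × component C matrix from Q and the feature assignment.

    C_jm = 1 iff item j contains some feature k with incidence[k, m] = 1.
    An optional ``override`` (J, M) binary matrix may only ADD active cells,
    and only where the item shares at least one feature with the target
    component; a derived 1 can never be removed.
    """
    inc = np.asarray(incidence)
    if inc.ndim != 2 or inc.shape[0] != q.n_features:
        raise ValueError(
            f"incidence must be ({q.n_features}, M), got shape {inc.shape}"
        )
    if ((inc != 0) & (inc != 1)).any():
        raise ValueError("incidence entries must be 0 or 1")
    if (inc.sum(axis=1) == 0).any():
        k = int(np.flatnonzero(inc.sum(axis=1) == 0)[0])
        raise ValueError(f"feature {q.feature_ids[k]!r} maps to no component")
    inc = inc.astype(np.int8)
    M = inc.shape[1]
    component_ids = tuple(
        str(m) for m in (component_ids if component_ids is not None else range(1, M + 1))
    )
    derived = (q.entries @ inc > 0).astype(np.int8)
    derived_flag = True
    if override is not None:
        ov = np.asarray(override).astype(np.int8)
        if ov.shape != derived.shape:
            raise ValueError(f"override must have shape {derived.shape}")
        if ((derived == 1) & (ov == 0)).any():
            j, m = np.argwhere((derived == 1) & (ov == 0))[0]
            raise ValueError(
                f"override removes derived C entry (item {q.item_ids[j]!r}, "
                f"component {component_ids[m]!r}); overrides are additive-only"
            )
        added = (ov == 1) & (derived == 0)
        for j, m in np.argwhere(added):
            if not (q.entries[j] & inc[:, m]).any():
                raise ValueError(
                    f"override adds component {component_ids[m]!r} to item "
                    f"{q.item_ids[j]!r}, but no feature of that item is assigned "
                    "to the component; extend the feature assignment instead"
                )
        if added.any():
            derived = derived | added.astype(np.int8)
            derived_flag = False
    derived.setflags(write=False)
    inc.setflags(write=False)
    return ComponentStructure(
        incidence=inc,
        component_matrix=derived,
        component_ids=component_ids,
        derived_flag=derived_flag,
    )


@dataclass(frozen=True)
class ComposedItemParameters:
    """Item-level parameters on the component scale.

    ``difficulty`` (J, M) holds b_jm = Σ_k q_jk η_mk over the features of
    component m; cells with C_jm = 0 are inactive (flagged in ``active``)
    and reported as 0. ``discrimination`` expands group-level slopes to
    items; ``guessing`` is the per-item lower asymptote.
    """

    difficulty: np.ndarray
    active: np.ndarray
    discrimination: np.ndarray | None = None
    guessing: np.ndarray | None = None
    item_ids: tuple[str, ...] | None = None
    component_ids: tuple[str, ...] | None = None


def _eta_full(q: FeatureMatrix, cs: ComponentStructure, eta) -> np.ndarray:
    """Expand an η mapping to a dense (M, K) array, zeros where no parameter exists."""
    K, M = cs.incidence.shape
    full = np.zeros((M, K))
    if isinstance(eta, dict):
        required = set(cs.active_eta())
        given = set()
        for key, value in eta.items():
            m, k = key
            if isinstance(m, str):
                m = cs.component_ids.index(m)
            if isinstance(k, str):
                k = q.feature_ids.index(k)
            if not cs.incidence[k, m]:
                raise ValueError(
                    f"eta given for feature {q.feature_ids[k]!r} in component "
                    f"{cs.component_ids[m]!r}, where no parameter exists "
                    "(non-compensatory structure)"
                )
            full[m, k] = value
            given.add((m, k))
        missing = required - given
        if missing:
            m, k = sorted(missing)[0]
            raise ValueError(
                f"eta missing required value for component {cs.component_ids[m]!r}, "
                f"feature {q.feature_ids[k]!r}"
            )
    else:
        values = np.asarray(eta, dtype=float)
        pairs = cs.active_eta()
        if values.shape != (len(pairs),):
            raise ValueError(
                f"expected {len(pairs)} eta values (active incidence cells), "
                f"got shape {values.shape}"
            )
        for (m, k), v in zip(pairs, values):
            full[m, k] = v
    return full


def compose_item_difficulties(
    q: FeatureMatrix, cs: ComponentStructure, eta
) -> ComposedItemParameters:
    """Compose item difficulties b = Q η within each component.

    ``eta`` is either a dict keyed by (component, feature) — labels or
    indices — defined exactly on the incidence support, or a flat vector in
    ``cs.active_eta()`` order. Composition is linear in η.
    """
    full = _eta_full(q, cs, eta)
    active = cs.component_matrix.astype(bool)
    b = q.entries.astype(float) @ (full.T * cs.incidence)
    b[~active] = 0.0
    return ComposedItemParameters(
        difficulty=b,
        active=active,
        item_ids=q.item_ids,
        component_ids=cs.component_ids,
    )


@dataclass(frozen=True)
class DiscriminationPartition:
    """Partition of each component's items into equal-discrimination groups.

    Two items with C_jm = 1 fall in the same component-m group exactly when
    their feature patterns restricted to component-m features are equal:
    discrimination is a property of the feature combination, not the item.
    Groups are ordered canonically by component, then by the restricted
    pattern read as a bit string in Q column order.
    """

    groups: tuple[tuple[int, tuple[int, ...], tuple[int, ...]], ...]
    group_of: np.ndarray  # (J, M) int, group index or -1 where C_jm = 0
    item_ids: tuple[str, ...]
    component_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def groups_in_component(self, m: int):
        return [g for g in self.groups if g[0] == m]

    def describe(self) -> pd.DataFrame:
        rows = []
        for gi, (m, pattern, members) in enumerate(self.groups):
            feats = [self.feature_ids[k] for k in np.flatnonzero(pattern)]
            rows.append(
                {
                    "group": gi,
                    "component": self.component_ids[m],
                    "pattern": "".join(str(int(v)) for v in pattern),
                    "features": "+".join(feats),
                    "items": ",".join(self.item_ids[j] for j in members),
                    "n_items": len(members),
                }
            )
        return pd.DataFrame(rows)


def discrimination_partition(
    q: FeatureMatrix, cs: ComponentStructure
) -> DiscriminationPartition:
    """Group items by identical feature patterns within each component."""
    J, K = q.entries.shape
    M = cs.n_components
    group_of = np.full((J, M), -1, dtype=int)
    groups: list[tuple[int, tuple[int, ...], tuple[int, ...]]] = []
    for m in range(M):
        mask = cs.incidence[:, m].astype(bool)
        patterns: dict[tuple[int, ...], list[int]] = {}
        for j in range(J):
            if not cs.component_matrix[j, m]:
                continue
            restricted = tuple(int(v) for v in (q.entries[j] * mask))
            patterns.setdefault(restricted, []).append(j)
        for pattern in sorted(patterns):
            gi = len(groups)
            members = tuple(patterns[pattern])
            groups.append((m, pattern, members))
            for j in members:
                group_of[j, m] = gi
    group_of.setflags(write=False)
    return DiscriminationPartition(
        groups=tuple(groups),
        group_of=group_of,
        item_ids=q.item_ids,
        component_ids=cs.component_ids,
        feature_ids=q.feature_ids,
    )


@dataclass(frozen=True)
class ParameterSet:
    """A full parameter point for the generalized multicomponent model.

    theta : (N, M) person abilities on the logit scale.
    eta : dict (component index, feature index) → feature difficulty, defined
        exactly on the incidence support.
    alpha : dict group index → slope (≥ 0), keyed by discrimination-partition
        group; None means all slopes fixed at 1.
    guessing : (J,) lower asymptotes in [0, 1); None means 0.
    """

    theta: np.ndarray
    eta: dict
    alpha: dict | None = None
    guessing: np.ndarray | None = None

    def __post_init__(self):
        if self.alpha is not None and any(v < 0 for v in self.alpha.values()):
            raise ValueError("discrimination (alpha) values must be >= 0")
        if self.guessing is not None:
            g = np.asarray(self.guessing, dtype=float)
            if ((g < 0) | (g >= 1)).any():
                raise ValueError("guessing values must lie in [0, 1)")


def expand_composed(
    q: FeatureMatrix,
    cs: ComponentStructure,
    params: ParameterSet,
    partition: DiscriminationPartition | None = None,
) -> ComposedItemParameters:
    """Expand a ParameterSet to per-item composed difficulties/slopes/guessing."""
    composed = compose_item_difficulties(q, cs, params.eta)
    J, M = composed.difficulty.shape
    if params.alpha is not None:
        if partition is None:
            partition = discrimination_partition(q, cs)
        A = np.zeros((J, M))
        for j in range(J):
            for m in range(M):
                gi = partition.group_of[j, m]
                if gi >= 0:
                    A[j, m] = params.alpha[gi]
    else:
        A = np.where(composed.active, 1.0, 0.0)
    g = (
        np.zeros(J)
        if params.guessing is None
        else np.asarray(params.guessing, dtype=float)
    )
    return ComposedItemParameters(
        difficulty=composed.difficulty,
        active=composed.active,
        discrimination=A,
        guessing=g,
        item_ids=composed.item_ids,
        component_ids=composed.component_ids,
    )
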