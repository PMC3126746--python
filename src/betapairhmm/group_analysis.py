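"""Group-level methylation-state summaries and differential testing.

A group's *overall state* for a probe pair is the modal decoded (Viterbi)
joint state across the group's samples.  Differentially methylated pairs
between two groups are those whose overall states differ *and* whose
per-sample joint posterior proportion vectors separate the groups
significantly under Fisher's linear discriminant criterion, calibrated by
label permutation (10,000 permutations and a 1% level by default).
State changes are then counted per probe (a pair changing LL -> MM counts
two L -> M probe changes) and broken down by genomic region (I/S/O).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import state_sort_key

#: Directed probe-level change types between two groups.
CHANGE_TYPES: tuple[str, ...] = ("L->M", "M->L", "M->H", "H->M", "L->H", "H->L")


@dataclass
class GroupStateTable:
    """Overall (modal) decoded states per probe pair and group.

    ``pair_states``: DataFrame indexed by pair_id, one column per group,
    values are joint-state strings like "LM".  ``pair_class``: Series
    mapping pair_id to its pair class.  ``probe_states``: per-probe modal
    marginal states, MultiIndex (pair_id, slot) with slot 1 or 2.
    """

    pair_states: pd.DataFrame
    pair_class: pd.Series
    probe_states: pd.DataFrame


@dataclass(frozen=True)
class ChangeRecord:
    """One probe's state change between two groups."""

    probe_id: str
    location_class: str
    group_a_state: str
    group_b_state: str

    @property
    def change_type(self) -> str:
        return f"{self.group_a_state}->{self.group_b_state}"


def _joint_key(state: str) -> tuple[int, int]:
    return state_sort_key(state[0]), state_sort_key(state[1])


def _modal(values: list[str], key) -> str:
    counts: dict[str, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    best = max(counts.values())
    return min((v for v, c in counts.items() if c == best), key=key)


def group_overall_states(
    decoded: dict[str, pd.DataFrame], groups: dict[str, str]
) -> GroupStateTable:
    """Modal decoded joint state per probe pair and group.

    ``decoded`` maps sample_id to its decoding table (as produced by
    :func:`betapairhmm.inference.decode_pairs`: columns pair_id, pair_class,
    viterbi_k1, viterbi_k2).  Every sample must be decoded under its own
    fitted model.  Ties break toward the smaller state under the
    componentwise L < M < H order.
    """
    by_group: dict[str, list[str]] = {}
    for s, g in groups.items():
        if s in decoded:
            by_group.setdefault(g, []).append(s)
    for g, members in by_group.items():
        if not members:
            raise ValueError(f"group {g!r} has no decoded samples")
    if not by_group:
        raise ValueError("no decoded samples matched the group labels")

    tables = {
        s: df.assign(joint=df["viterbi_k1"] + df["viterbi_k2"]).set_index("pair_id")
        for s, df in decoded.items()
    }
    common = None
    for s in tables:
        ids = set(tables[s].index)
        common = ids if common is None else (common & ids)
    pair_ids = sorted(common)
    first = tables[next(iter(tables))]
    pair_class = first.loc[pair_ids, "pair_class"]

    pair_states = {}
    probe1 = {}
    probe2 = {}
    for g, members in sorted(by_group.items()):
        joint = pd.DataFrame({s: tables[s].loc[pair_ids, "joint"] for s in members})
        pair_states[g] = joint.apply(
            lambda row: _modal(list(row), _joint_key), axis=1
        )
        probe1[g] = joint.apply(
            lambda row: _modal([v[0] for v in row], state_sort_key), axis=1
        )
        probe2[g] = joint.apply(
            lambda row: _modal([v[1] for v in row], state_sort_key), axis=1
        )
    ps = pd.DataFrame(pair_states)
    p1 = pd.DataFrame(probe1)
    p1.index = pd.MultiIndex.from_product([pair_ids, [1]]).set_names(
        ["pair_id", "slot"]
    )
    p2 = pd.DataFrame(probe2)
    p2.index = pd.MultiIndex.from_product([pair_ids, [2]]).set_names(
        ["pair_id", "slot"]
    )
    probe_states = pd.concat([p1, p2]).sort_index()
    return GroupStateTable(ps, pair_class, probe_states)


def change_records_for_pair(
    pair_id: str, pair_class: str, state_a: str, state_b: str
) -> list[ChangeRecord]:
    """Per-probe change records for one pair whose group states differ."""
    records = []
    for slot in (0, 1):
        if state_a[slot] != state_b[slot]:
            records.append(
                ChangeRecord(
                    probe_id=f"{pair_id}:{slot + 1}",
                    location_class=pair_class[slot],
                    group_a_state=state_a[slot],
                    group_b_state=state_b[slot],
                )
            )
    return records


def tabulate_state_changes(
    table: GroupStateTable,
    group_a: str,
    group_b: str,
    significant=None,
) -> pd.Series:
    """Per-probe counts of each directed state change between two groups.

    Counts probes, not pairs: a pair going LL -> MM contributes 2 to L->M.
    ``significant`` optionally restricts to a set of pair IDs (e.g. those
    passing the permutation test); None means all pairs.
    """
    for g in (group_a, group_b):
        if g not in table.pair_states.columns:
            raise KeyError(f"unknown group {g!r}")
    counts = {t: 0 for t in CHANGE_TYPES}
    for pair_id, row in table.pair_states.iterrows():
        if significant is not None and pair_id not in significant:
            continue
        for rec in change_records_for_pair(
            str(pair_id), table.pair_class.loc[pair_id], row[group_a], row[group_b]
        ):
            counts[rec.change_type] += 1
    return pd.Series(counts, name=f"{group_a} vs {group_b}")


def tabulate_changes_by_region(records: list[ChangeRecord]) -> pd.DataFrame:
    """Counts and percentages of probe changes per genomic region (I/S/O)."""
    counts = {a: 0 for a in ("I", "S", "O")}
    for rec in records:
        counts[rec.location_class] += 1
    total = sum(counts.values())
    out = pd.DataFrame({"count": pd.Series(counts)})
    out["percent"] = 100.0 * out["count"] / total if total else 0.0
    return out


# ---------------------------------------------------------------------------
# Fisher discriminant permutation test


def _fisher_stat_batched(X: np.ndarray, members1: np.ndarray, ridge: float) -> np.ndarray:
    """Fisher criterion for many group-1 membership vectors at once.

    ``members1`` is (n_perm, n) boolean; the statistic is
    d' (Sw + lambda I)^{-1} d with d the group-mean difference and Sw the
    within-group scatter, ridge-regularized because small groups make Sw
    singular.
    """
    n, d = X.shape
    n1 = members1.sum(axis=1)
    n2 = n - n1
    sums1 = members1.astype(float) @ X  # (P, d)
    total = X.sum(axis=0)
    m1 = sums1 / n1[:, None]
    m2 = (total - sums1) / n2[:, None]
    xtx = X.T @ X
    sw = (
        xtx[None, :, :]
        - n1[:, None, None] * (m1[:, :, None] * m1[:, None, :])
        - n2[:, None, None] * (m2[:, :, None] * m2[:, None, :])
    )
    tr = np.trace(sw, axis1=1, axis2=2)
    lam = np.maximum(ridge * tr / d, 1e-12)
    sw = sw + lam[:, None, None] * np.eye(d)[None, :, :]
    diff = m1 - m2
    sol = np.linalg.solve(sw, diff[:, :, None])[:, :, 0]
    return np.einsum("pd,pd->p", diff, sol)


def fisher_statistic(X, labels, ridge: float = 1e-6) -> float:
    """Fisher linear discriminant criterion for a two-group comparison.

    The maximized between/within scatter ratio along the optimal
    discriminant direction, which for two groups equals
    d' Sw^{-1} d (up to the constant n1 n2 / n); the within scatter is
    ridge-regularized by ``ridge * trace(Sw)/dim``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    uniq = sorted(pd.unique(y))
    if len(uniq) != 2:
        raise ValueError("fisher_statistic requires exactly two groups")
    members1 = (y == uniq[0])[None, :]
    if members1.sum() == 0 or members1.sum() == len(y):
        raise ValueError("one group is empty")
    return float(_fisher_stat_batched(X, members1, ridge)[0])


def fisher_permutation_test(
    features,
    labels,
    n_perm: int = 10000,
    seed: int = 0,
    ridge: float = 1e-6,
) -> tuple[float, float]:
    """Permutation-calibrated Fisher discriminant test for two groups.

    Returns (statistic, p) with the add-one estimator
    p = (1 + #{permuted >= observed}) / (1 + n_perm); group labels are
    permuted uniformly at random, preserving group sizes.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    uniq = sorted(pd.unique(y))
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    n1 = int(np.sum(y == uniq[0]))
    n2 = len(y) - n1
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 samples")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-value resolution is coarse")

    obs = fisher_statistic(X, y, ridge)
    rng = np.random.default_rng(seed)
    n = len(y)
    members = np.zeros((n_perm, n), dtype=bool)
    for r in range(n_perm):
        members[r, rng.permutation(n)[:n1]] = True
    stats = _fisher_stat_batched(X, members, ridge)
    p = (1.0 + float(np.sum(stats >= obs))) / (1.0 + n_perm)
    return obs, p


def select_differential_pairs(
    decoded: dict[str, pd.DataFrame],
    groups: dict[str, str],
    group_a: str,
    group_b: str,
    alpha: float = 0.01,
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple[list[ChangeRecord], pd.DataFrame]:
    """Differentially methylated probe pairs between two groups.

    A pair is selected when (a) the groups' overall decoded states differ
    and (b) the per-sample joint posterior proportion vectors differ
    significantly under the Fisher permutation test at level ``alpha``
    (no multiple-testing correction; pass the returned p-values through
    statsmodels' multipletests for a Benjamini-Hochberg variant).

    Returns per-probe :class:`ChangeRecord`s for the selected pairs and a
    table of candidate pairs with their statistics and p-values.
    """
    table = group_overall_states(decoded, groups)
    samples = [s for s in groups if s in decoded and groups[s] in (group_a, group_b)]
    labels = np.array([groups[s] for s in samples])
    if alpha < 0 or alpha > 1:
        raise ValueError("alpha must be in [0, 1]")

    indexed = {s: decoded[s].set_index("pair_id") for s in samples}
    post_cols = [c for c in next(iter(indexed.values())).columns if c.startswith("p_")]

    candidates = table.pair_states.index[
        table.pair_states[group_a] != table.pair_states[group_b]
    ]
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(max(len(candidates), 1)) % (2**31)

    rows = []
    records: list[ChangeRecord] = []
    for i, pair_id in enumerate(candidates):
        X = np.stack([indexed[s].loc[pair_id, post_cols].to_numpy(float) for s in samples])
        stat, p = fisher_permutation_test(
            X, labels, n_perm=n_perm, seed=int(child_seeds[i])
        )
        significant = p < alpha
        rows.append(
            {
                "pair_id": pair_id,
                "pair_class": table.pair_class.loc[pair_id],
                "state_a": table.pair_states.loc[pair_id, group_a],
                "state_b": table.pair_states.loc[pair_id, group_b],
                "statistic": stat,
                "p_value": p,
                "significant": significant,
            }
        )
        if significant:
            records.extend(
                change_records_for_pair(
                    str(pair_id),
                    table.pair_class.loc[pair_id],
                    table.pair_states.loc[pair_id, group_a],
                    table.pair_states.loc[pair_id, group_b],
                )
            )
    cols = [
        "pair_id", "pair_class", "state_a", "state_b",
        "statistic", "p_value", "significant",
    ]
    return records, pd.DataFrame(rows, columns=cols)
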