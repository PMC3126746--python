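"""State decoding and annotation uncertainty.

For a length-2 chain the joint posterior over at most nine joint states is
computed by exact enumeration (equivalent to forward-backward, and for the
MAP state to Viterbi, on a 2-step chain).  The false annotation rate (FAR)
is the mean posterior probability that the modal joint-state assignment is
wrong: FAR = mean over pairs of (1 - max posterior).  It is the expected
error rate of the MAP rule under the fitted model — e.g. FAR = 0.125 means
about one pair in eight carries a wrong state annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .model_core import (
    ProbePair,
    SampleModel,
    allowed_states,
    pair_joint_log_density,
    state_sort_key,
)


@dataclass
class PairPosterior:
    """Joint-state posterior of one probe pair."""

    pair_id: str
    pair_class: str
    probs: dict[tuple[str, str], float]
    viterbi: tuple[str, str]
    max_prob: float


def _decode_arrays(
    x1: np.ndarray, x2: np.ndarray, pair_class: str, sm: SampleModel
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    """(posteriors (n, n_joint), viterbi index (n,), joint state labels)."""
    logj = pair_joint_log_density(x1, x2, pair_class, sm)  # (n, n1, n2)
    n, n1, n2 = logj.shape
    flat = logj.reshape(n, n1 * n2)
    lse = logsumexp(flat, axis=1)
    post = np.exp(flat - lse[:, None])
    # argmax on the flattened array breaks exact ties toward the first
    # (lexicographically smallest under L<M<H) joint state.
    vit = np.argmax(post, axis=1)
    s1 = allowed_states(pair_class[0])
    s2 = allowed_states(pair_class[1])
    labels = [(k1, k2) for k1 in s1 for k2 in s2]
    return post, vit, labels


def pair_posteriors(pair: ProbePair, sm: SampleModel) -> PairPosterior:
    """Exact joint posterior of one probe pair under the fitted model.

    probs[(k1,k2)] = omega[k1] T[k1,k2] f(x1;k1) f(x2;k2), normalized over
    the pair class's allowed joint states.
    """
    post, vit, labels = _decode_arrays(
        np.array([pair.x1]), np.array([pair.x2]), pair.pair_class, sm
    )
    probs = dict(zip(labels, post[0]))
    v = labels[int(vit[0])]
    return PairPosterior(
        pair_id=pair.gene_id,
        pair_class=pair.pair_class,
        probs=probs,
        viterbi=v,
        max_prob=float(post[0, int(vit[0])]),
    )


def viterbi_pair(pair: ProbePair, sm: SampleModel) -> tuple[str, str]:
    """MAP joint state of a probe pair (= Viterbi path on the 2-step chain).

    Exact ties are broken toward the lexicographically smallest joint state
    under the canonical L < M < H order.
    """
    return pair_posteriors(pair, sm).viterbi


def far(posteriors) -> float:
    """False annotation rate of a set of decoded probe pairs.

    Accepts a list of :class:`PairPosterior` or an array of modal posterior
    probabilities; returns mean(1 - max_prob) in [0, 1].
    """
    if isinstance(posteriors, (list, tuple)) and posteriors and isinstance(
        posteriors[0], PairPosterior
    ):
        mp = np.array([p.max_prob for p in posteriors])
    else:
        mp = np.asarray(posteriors, dtype=float)
    if mp.size == 0:
        raise ValueError("FAR undefined for an empty set of pairs")
    return float(np.mean(1.0 - mp))


def marginal_probe_posteriors(pp: PairPosterior) -> tuple[dict[str, float], dict[str, float]]:
    """Per-probe marginal state posteriors, by summing the joint posterior."""
    m1: dict[str, float] = {}
    m2: dict[str, float] = {}
    for (k1, k2), p in pp.probs.items():
        m1[k1] = m1.get(k1, 0.0) + p
        m2[k2] = m2.get(k2, 0.0) + p
    return m1, m2


def decode_pairs(pairs: list[ProbePair], sm: SampleModel) -> pd.DataFrame:
    """Decode a list of probe pairs into a tidy table.

    Columns: pair_id, pair_class, x1, x2, viterbi_k1, viterbi_k2, max_prob,
    and one ``p_k1k2`` column per joint state (absent states are 0 for pair
    classes that do not reach them).  Row order follows the input.
    """
    all_joint = [
        (k1, k2)
        for k1 in sorted("LMH", key=state_sort_key)
        for k2 in sorted("LMH", key=state_sort_key)
    ]
    cols = {f"p_{k1}{k2}": np.zeros(len(pairs)) for k1, k2 in all_joint}
    rec = {
        "pair_id": [p.gene_id for p in pairs],
        "pair_class": [p.pair_class for p in pairs],
        "x1": [p.x1 for p in pairs],
        "x2": [p.x2 for p in pairs],
        "viterbi_k1": [""] * len(pairs),
        "viterbi_k2": [""] * len(pairs),
        "max_prob": np.zeros(len(pairs)),
    }
    idx = np.arange(len(pairs))
    classes = np.array([p.pair_class for p in pairs])
    x1 = np.array([p.x1 for p in pairs])
    x2 = np.array([p.x2 for p in pairs])
    for pc in np.unique(classes):
        sel = idx[classes == pc]
        post, vit, labels = _decode_arrays(x1[sel], x2[sel], pc, sm)
        for j, (k1, k2) in enumerate(labels):
            cols[f"p_{k1}{k2}"][sel] = post[:, j]
        rec["max_prob"][sel] = post[np.arange(len(sel)), vit]
        for i, v in zip(sel, vit):
            rec["viterbi_k1"][i] = labels[int(v)][0]
            rec["viterbi_k2"][i] = labels[int(v)][1]
    rec.update(cols)
    return pd.DataFrame(rec)
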