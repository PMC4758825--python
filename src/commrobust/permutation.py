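"""Data-stream permutation null for modularity.

The null model randomizes the observation stream itself rather than the
network: each swap exchanges one individual in one group with another
individual in another group, subject to neither already belonging to the
target group.  Swaps preserve every individual's number of observations
and every group's size, so the null retains the sampling structure of the
data while destroying any genuine social preference.  Swaps accumulate
serially, increasingly randomizing the stream; after each step the SRI
network is rebuilt, communities re-detected and Q recorded, giving the
null distribution Q_rand against which the empirical Q is tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .network import build_sri_network, detect_communities
from .robustness import _as_rng
from .streams import ObservationStream

__all__ = ["PermutationResult", "stream_swap", "permutation_test_Q"]


@dataclass
class PermutationResult:
    Q_emp: float
    Q_rand: list
    p_value: float
    n_perm: int
    seed: object = None

    def to_dict(self) -> dict:
        return {
            "Q": self.Q_emp,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "Q_rand_quantiles": {
                "2.5%": float(np.percentile(self.Q_rand, 2.5)),
                "50%": float(np.percentile(self.Q_rand, 50)),
                "97.5%": float(np.percentile(self.Q_rand, 97.5)),
            },
        }


def _swap_once(groups: list, rng: np.random.Generator, max_tries: int = 200) -> bool:
    """Attempt one in-place swap between two groups; True on success.

    Picks two distinct groups, then one member of each not present in the
    other, and exchanges them.  Group sizes and per-individual observation
    counts are conserved by construction.
    """
    n_groups = len(groups)
    if n_groups < 2:
        return False
    for _ in range(max_tries):
        g1, g2 = rng.choice(n_groups, size=2, replace=False)
        only1 = list(groups[g1] - groups[g2])
        only2 = list(groups[g2] - groups[g1])
        if not only1 or not only2:
            continue
        only1.sort()
        only2.sort()
        a = only1[rng.integers(len(only1))]
        b = only2[rng.integers(len(only2))]
        groups[g1].discard(a)
        groups[g1].add(b)
        groups[g2].discard(b)
        groups[g2].add(a)
        return True
    return False


def stream_swap(stream: ObservationStream, rng) -> ObservationStream:
    """Return a copy of the stream with one individual swap applied.

    If no valid swap exists (e.g. a single group, or all groups share the
    same membership) the stream is returned unchanged with a warning.
    """
    if stream.mode != "group":
        raise ValueError("stream_swap requires a group-mode stream")
    rng = _as_rng(rng)
    groups = [set(u) for u in stream.units]
    if not _swap_once(groups, rng):
        warnings.warn("no valid swap found; stream returned unchanged", stacklevel=2)
        return stream
    return ObservationStream([frozenset(g) for g in groups], stream.roster, "group")


def permutation_test_Q(
    stream: ObservationStream,
    n_perm: int = 1000,
    swaps_per_step: int = 1,
    rng=None,
    burn_in: int = 0,
) -> PermutationResult:
    """One-sided data-stream permutation test of modularity.

    Q_emp is computed once from the unpermuted stream.  The chain then
    applies ``swaps_per_step`` swaps per recorded step (after ``burn_in``
    unrecorded swaps), rebuilding the network and re-detecting communities
    each step.  The p value uses the standard add-one correction:
    (1 + #{Q_rand >= Q_emp}) / (1 + n_perm), testing whether the stream is
    more modular than its sampling structure alone can explain.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if stream.mode != "group":
        raise ValueError("permutation_test_Q requires a group-mode stream")
    rng = _as_rng(rng)
    q_emp = detect_communities(build_sri_network(stream)).Q
    groups = [set(u) for u in stream.units]
    for _ in range(burn_in):
        _swap_once(groups, rng)
    q_rand = []
    warned = False
    for _ in range(n_perm):
        for _ in range(swaps_per_step):
            if not _swap_once(groups, rng) and not warned:
                warnings.warn("no valid swap found at some steps; chain may mix slowly", stacklevel=2)
                warned = True
        permuted = ObservationStream([frozenset(g) for g in groups], stream.roster, "group")
        q_rand.append(detect_communities(build_sri_network(permuted)).Q)
    p = (1 + sum(q >= q_emp for q in q_rand)) / (1 + n_perm)
    return PermutationResult(q_emp, q_rand, p, n_perm)
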