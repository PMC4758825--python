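"""Bootstrap robustness of community assignment: the r_com pipeline.

Modularity Q measures how much community structure a network shows, but
says nothing about how reproducible the *assignment* of individuals to
communities is under resampling of the observation effort.  Community
assortativity r_com fills that gap:

1. Resample the observation stream (units drawn with replacement, same
   sample size) many times; re-infer the network and its communities for
   each replicate.
2. For every dyad, accumulate M (replicates in which both were present and
   co-assigned) and C (replicates in which both were present), and form
   the co-membership proportion P_ij = ΣM_ij / ΣC_ij.
3. Treat P as a weighted network and compute its assortativity with
   respect to the *empirical* community labels:

       r_com = (Σ_x e_xx − Σ_x a_x b_x) / (1 − Σ_x a_x b_x)

   where e is the community mixing matrix of P and a, b its marginals
   (equal here, the network being undirected).

r_com = 1 when every replicate reproduces the empirical assignment
exactly; values near the ~0.2 floor indicate assignments no more stable
than chance; negative values indicate systematic reassignment across
empirical community boundaries.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .network import CommunityPartition, build_sri_network, detect_communities
from .streams import AssociationNetwork, ObservationStream

__all__ = [
    "CoMembershipSummary",
    "RcomResult",
    "bootstrap_replicate",
    "comembership_proportions",
    "assortativity_rcom",
    "run_rcom",
]


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass
class CoMembershipSummary:
    """Accumulated co-assignment evidence across bootstrap replicates.

    ``P[i, j]`` is the proportion of replicates in which individuals i and
    j landed in the same detected community, conditional on both having
    been sampled; dyads never co-sampled carry P = 0 and are flagged in
    ``never_co_sampled``.
    """

    roster: tuple
    M_sum: np.ndarray
    C_sum: np.ndarray
    P: np.ndarray
    replicate_Q: list
    replicate_c: list
    n_boot: int
    seed: object = None
    never_co_sampled: np.ndarray = field(default=None)

    def community_count_histogram(self) -> dict:
        return dict(sorted(Counter(self.replicate_c).items()))


@dataclass
class RcomResult:
    """Full output of the r_com pipeline on one observation stream."""

    r_com: float
    Q_emp: float
    Q_ci: tuple
    empirical_partition: CommunityPartition
    network: AssociationNetwork
    summary: CoMembershipSummary

    def to_dict(self) -> dict:
        return {
            "r_com": self.r_com,
            "Q": self.Q_emp,
            "Q_ci": list(self.Q_ci),
            "n_boot": self.summary.n_boot,
            "seed": self.summary.seed,
            "c": self.empirical_partition.c,
            "communities": {k: int(v) for k, v in self.empirical_partition.labels.items()},
            "replicate_c_histogram": {str(k): v for k, v in self.summary.community_count_histogram().items()},
        }


def bootstrap_replicate(stream: ObservationStream, rng) -> ObservationStream:
    """One bootstrap resample of the observation stream.

    Draws ``n_units`` units uniformly with replacement and restricts the
    roster to individuals observed in the drawn units — a dyad can be
    absent from a replicate purely through sampling, which is exactly what
    the co-presence matrix C accounts for.
    """
    if stream.n_units == 0:
        raise ValueError("cannot bootstrap an empty stream")
    rng = _as_rng(rng)
    idx = rng.integers(0, stream.n_units, size=stream.n_units)
    return stream.subset_units(idx.tolist(), restrict_roster=True)


def comembership_proportions(
    stream: ObservationStream,
    n_boot: int = 100,
    rng=None,
    seed_label=None,
) -> CoMembershipSummary:
    """Bootstrap the stream ``n_boot`` times and accumulate M, C and P.

    Each replicate is rebuilt from scratch: SRI network, fast-greedy
    communities, then per-dyad increments of co-assignment (M) and
    co-presence (C).  Replicate modularity and community counts are kept
    for the Q confidence interval and the community-count histogram.
    Replicates with fewer than two sampled individuals contribute nothing
    to M and C but are recorded with Q = 0.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = _as_rng(rng)
    roster = stream.roster
    index = {r: k for k, r in enumerate(roster)}
    n = len(roster)
    M = np.zeros((n, n), dtype=np.int64)
    C = np.zeros((n, n), dtype=np.int64)
    rep_Q, rep_c = [], []
    for _ in range(n_boot):
        rep = bootstrap_replicate(stream, rng)
        if rep.n_individuals < 2:
            rep_Q.append(0.0)
            rep_c.append(rep.n_individuals)
            continue
        part = detect_communities(build_sri_network(rep))
        rep_Q.append(part.Q)
        rep_c.append(part.c)
        idx = np.array([index[r] for r in rep.roster])
        lab = part.label_vector(rep.roster)
        same = lab[:, None] == lab[None, :]
        np.fill_diagonal(same, False)
        C[np.ix_(idx, idx)] += 1
        M[np.ix_(idx, idx)] += same
    np.fill_diagonal(C, 0)
    np.fill_diagonal(M, 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(C > 0, M / np.where(C > 0, C, 1), 0.0)
    flagged = (C == 0)
    np.fill_diagonal(flagged, False)
    return CoMembershipSummary(roster, M, C, P, rep_Q, rep_c, n_boot, seed_label, flagged)


def assortativity_rcom(P: np.ndarray, labels) -> float:
    """Community assortativity of a co-membership proportion matrix.

    ``labels`` may be a sequence of community indices aligned with P's
    rows or a dict keyed like a roster ordering of P.  The diagonal of P
    is ignored.  Returns NaN (with a warning) when P has no weight at all
    or when a single community absorbs everything, which makes the
    denominator 1 − Σ a_x b_x vanish.
    """
    P = np.asarray(P, dtype=float)
    if isinstance(labels, dict):
        raise TypeError("pass labels aligned with P's rows (sequence of community ids)")
    lab = np.asarray(labels)
    if lab.shape[0] != P.shape[0]:
        raise ValueError("labels length must match P")
    if not np.allclose(P, P.T):
        raise ValueError("P must be symmetric")
    _, lab = np.unique(lab, return_inverse=True)
    W = P.copy()
    np.fill_diagonal(W, 0.0)
    total = W.sum()
    if total == 0:
        warnings.warn("P has no weight; r_com undefined", stacklevel=2)
        return float("nan")
    c = lab.max() + 1
    ind = np.zeros((P.shape[0], c))
    ind[np.arange(P.shape[0]), lab] = 1.0
    e = ind.T @ W @ ind / total
    a = e.sum(axis=1)  # = b: undirected, symmetric ordered convention
    ab = float(a @ a)
    if abs(1.0 - ab) < 1e-12:
        warnings.warn("degenerate partition (sum a_x b_x = 1); r_com undefined", stacklevel=2)
        return float("nan")
    return float((np.trace(e) - ab) / (1.0 - ab))


def run_rcom(
    stream: ObservationStream,
    n_boot: int = 100,
    rng=None,
    ci: tuple = (2.5, 97.5),
) -> RcomResult:
    """End-to-end pipeline: empirical network and partition, bootstrap
    co-membership, r_com, and the percentile confidence interval of Q."""
    rng = _as_rng(rng)
    net = build_sri_network(stream)
    part = detect_communities(net)
    summary = comembership_proportions(stream, n_boot=n_boot, rng=rng)
    r = assortativity_rcom(summary.P, part.label_vector(stream.roster))
    lo, hi = np.percentile(summary.replicate_Q, ci)
    return RcomResult(r, part.Q, (float(lo), float(hi)), part, net, summary)
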