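"""How Q and r_com respond to the number of observations.

Random subsets of increasing size are drawn from an observation stream
(without replacement, so the largest size recovers the full stream up to
unit order) and the full r_com pipeline is run on each.  When community
structure is strong, r_com is high even at modest sample size; at
intermediate structure r_com climbs with sample size while Q stays flat;
with weak structure more data does not rescue the assignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .robustness import _as_rng, run_rcom
from .streams import ObservationStream

__all__ = ["SubsampleCurve", "subsample_curve"]


@dataclass
class SubsampleCurve:
    sizes: list
    mean_Q: list
    mean_rcom: list
    reps: int
    seed: object = None

    def to_rows(self):
        return list(zip(self.sizes, self.mean_Q, self.mean_rcom))


def subsample_curve(
    stream: ObservationStream,
    start: int = 50,
    step: int = 10,
    reps: int = 50,
    n_boot: int = 100,
    rng=None,
) -> SubsampleCurve:
    """Mean Q and r_com over random subsamples of increasing size.

    Sizes run from ``start`` in increments of ``step`` up to and including
    the total unit count.  At each size, ``reps`` subsamples are drawn
    uniformly without replacement and the bootstrap pipeline is run on
    each; r_com values that are undefined (degenerate partitions) are
    excluded from the mean.
    """
    total = stream.n_units
    if start > total:
        raise ValueError(f"start = {start} exceeds the {total} available units")
    if step < 1 or reps < 1:
        raise ValueError("step and reps must be >= 1")
    rng = _as_rng(rng)
    sizes = list(range(start, total + 1, step))
    if sizes[-1] != total:
        sizes.append(total)
    mean_q, mean_r = [], []
    for size in sizes:
        qs, rs = [], []
        for _ in range(reps):
            idx = rng.choice(total, size=size, replace=False)
            sub = stream.subset_units(idx.tolist(), restrict_roster=True)
            res = run_rcom(sub, n_boot=n_boot, rng=rng)
            qs.append(res.Q_emp)
            rs.append(res.r_com)
        mean_q.append(float(np.mean(qs)))
        mean_r.append(float(np.nanmean(rs)) if np.any(~np.isnan(rs)) else float("nan"))
    return SubsampleCurve(sizes, mean_q, mean_r, reps)
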