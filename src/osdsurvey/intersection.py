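"""Randomization null for the overlap of strong-rejector groups.

Respondents scoring -2 on any of the three attitude questions form the
strong-negative sets.  Whether the observed overlap between the sets (the
Venn intersections) exceeds chance is judged against a null in which sets
of the observed sizes are drawn uniformly without replacement from the
respondent pool, independently of each other; the empirical P is the share
of replicates whose intersection is at least the observed one, and
Z = (observed - null mean) / null SD summarises the deviation.

Under this null the pairwise intersection is hypergeometric with mean
``n1*n2/N`` (three-way: ``n1*n2*n3/N^2``), which the tests use as an
analytic cross-check of the simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._exceptions import ParameterError, ValidationError

__all__ = ["IntersectionTestResult", "intersection_null_test",
           "strong_negative_sets"]


@dataclass
class IntersectionTestResult:
    """Outcome of the set-intersection randomization test."""

    pool_n: int
    sizes: tuple
    observed: int
    null_mean: float
    null_sd: float
    z: float | None       #: None when the null is degenerate (SD = 0)
    p_empirical: float
    replicates: int
    seed: int | None

    @property
    def p_label(self) -> str:
        """Empirical P, reported as a bound when no replicate reached the
        observed overlap."""
        if self.p_empirical == 0.0:
            return f"< {1.0 / self.replicates:g}"
        return f"{self.p_empirical:g}"


def _random_memberships(rng, pool_n, size, reps):
    """Boolean (reps, pool_n) matrix; each row a uniform size-subset."""
    out = np.zeros((reps, pool_n), dtype=bool)
    keys = rng.random((reps, pool_n))
    take = np.argpartition(keys, size - 1, axis=1)[:, :size]
    np.put_along_axis(out, take, True, axis=1)
    return out


def intersection_null_test(pool_n: int, sizes: Sequence[int], observed: int,
                           replicates: int = 100_000,
                           seed: int | np.random.Generator | None = None,
                           chunk: int = 4_000) -> IntersectionTestResult:
    """Randomization test for the overlap of 2 or 3 sets.

    Each replicate draws every group uniformly without replacement from a
    pool of ``pool_n`` respondents, independently, and records the size of
    the common intersection (pairwise, or common to all three).  The pool
    size is an explicit argument, not inferred from the sets.

    ``p_empirical`` is ``#{replicates with intersection >= observed} /
    replicates``; a value of 0 is reported as "< 1/replicates" by
    :attr:`IntersectionTestResult.p_label`.  When the null is degenerate
    (SD = 0, e.g. groups as large as the pool), ``z`` is ``None``.
    """
    sizes = tuple(int(s) for s in sizes)
    if len(sizes) not in (2, 3):
        raise ParameterError("sizes must list 2 or 3 group sizes")
    if any(s < 0 for s in sizes) or observed < 0:
        raise ParameterError("sizes and observed must be non-negative")
    if any(s > pool_n for s in sizes):
        raise ParameterError(f"group size exceeds pool ({sizes} > {pool_n})")
    if observed > min(sizes):
        raise ParameterError("observed intersection exceeds smallest group")
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")

    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    counts = np.empty(replicates, dtype=np.int64)
    done = 0
    while done < replicates:
        r = min(chunk, replicates - done)
        inter = _random_memberships(rng, pool_n, sizes[0], r)
        for s in sizes[1:]:
            inter &= _random_memberships(rng, pool_n, s, r)
        counts[done:done + r] = inter.sum(axis=1)
        done += r

    mean = float(counts.mean())
    sd = float(counts.std(ddof=0))
    z = None if sd == 0 else float((observed - mean) / sd)
    p = float(np.mean(counts >= observed))
    return IntersectionTestResult(
        pool_n=int(pool_n), sizes=sizes, observed=int(observed),
        null_mean=mean, null_sd=sd, z=z, p_empirical=p,
        replicates=int(replicates),
        seed=seed if isinstance(seed, (int, np.integer)) else None)


def strong_negative_sets(scored: pd.DataFrame, threshold: float = -2,
                         questions: Sequence[str] = ("trust", "hype", "gm"),
                         ) -> dict:
    """Membership sets of strong rejectors per attitude question.

    Returns a dict with the index set per question, every pairwise
    intersection count, the three-way count, and per-question counts that
    belong to *no* other strong-negative set (the Venn-exclusive counts).
    """
    for q in questions:
        if q not in scored.columns:
            raise ValidationError(f"column {q!r} missing from scored table")
    sets = {q: set(scored.index[scored[q] == threshold]) for q in questions}
    out = {"sets": sets,
           "sizes": {q: len(s) for q, s in sets.items()},
           "pairwise": {}, "exclusive": {}}
    qs = list(questions)
    for i in range(len(qs)):
        for j in range(i + 1, len(qs)):
            out["pairwise"][(qs[i], qs[j])] = len(sets[qs[i]] & sets[qs[j]])
    if len(qs) == 3:
        out["three_way"] = len(sets[qs[0]] & sets[qs[1]] & sets[qs[2]])
    for q in qs:
        others = set().union(*(sets[o] for o in qs if o != q))
        out["exclusive"][q] = len(sets[q] - others)
    return out
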