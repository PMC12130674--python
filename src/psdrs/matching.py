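"""Greedy 1:1 nearest-neighbor caliper matching on the logit score scale.

Treated units are processed in descending logit-score order (ties by
ascending index); each takes its nearest still-unmatched control by
absolute logit distance, provided the distance is within the caliper —
by default 0.2 sample standard deviations of the logit of the score over
the whole cohort.  Matching is without replacement and fully
deterministic given its inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cohort import NonEstimableError
from .scores import ScoreVector

logger = logging.getLogger(__name__)


def logit(p):
    """ln(p / (1 - p)) for p strictly inside (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("logit requires values strictly in (0, 1)")
    out = np.log(p / (1.0 - p))
    return float(out) if out.ndim == 0 else out


@dataclass
class MatchedSet:
    """1:1 matched pairs of (treated_index, control_index) row positions."""

    pairs: list[tuple[int, int]]
    caliper_width: float
    score_kind: str
    unmatched_treated: int

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def to_csv(self, path) -> None:
        """Write the pairs as a two-column CSV of 0-based row indices."""
        with open(path, "w") as fh:
            fh.write("treated_index,control_index\n")
            for t, c in self.pairs:
                fh.write(f"{t},{c}\n")

    def matched_rows(self) -> np.ndarray:
        """Row indices of all matched subjects (treated then controls, pair order)."""
        if not self.pairs:
            return np.empty(0, dtype=int)
        arr = np.asarray(self.pairs, dtype=int)
        return np.concatenate([arr[:, 0], arr[:, 1]])


def greedy_match(
    scores,
    T: np.ndarray,
    caliper_multiplier: float = 0.2,
    *,
    order: str = "descending",
    sd_population: str = "all",
    rng_seed: int | None = None,
) -> MatchedSet:
    """Greedy nearest-neighbor matching without replacement on logit(score).

    Parameters
    ----------
    scores
        A :class:`~psdrs.scores.ScoreVector` or plain array of probabilities
        strictly in (0, 1).
    T
        Binary treatment vector aligned with ``scores``.
    caliper_multiplier
        Caliper as a multiple of the sample SD of the logit scores
        (0.2 by default).
    order
        Treated processing order: ``descending`` (default), ``ascending``
        or ``random`` (requires ``rng_seed``).
    sd_population
        Which subjects define the caliper SD: ``all`` (default) or
        ``treated``.
    """
    kind = "PS"
    if isinstance(scores, ScoreVector):
        kind = scores.kind
        scores = scores.values
    scores = np.asarray(scores, dtype=float)
    T = np.asarray(T)
    logits = logit(scores)

    treated_idx = np.flatnonzero(T == 1)
    control_idx = np.flatnonzero(T == 0)
    if treated_idx.size == 0 or control_idx.size == 0:
        raise NonEstimableError("matching requires at least one treated and one control")

    sd_pool = logits[treated_idx] if sd_population == "treated" else logits
    sd = float(np.std(sd_pool, ddof=1)) if sd_pool.size > 1 else 0.0
    if sd < 1e-12:  # identical scores up to float noise
        sd = 0.0
    caliper = caliper_multiplier * sd
    if sd == 0.0:
        logger.warning("logit-score SD is 0; caliper collapses to exact-score matching")

    t_logits = logits[treated_idx]
    if order == "descending":
        proc = np.argsort(-t_logits, kind="stable")
    elif order == "ascending":
        proc = np.argsort(t_logits, kind="stable")
    elif order == "random":
        if rng_seed is None:
            raise ValueError("order='random' requires rng_seed")
        proc = np.random.default_rng(rng_seed).permutation(treated_idx.size)
    else:
        raise ValueError(f"unknown order {order!r}")

    c_logits = logits[control_idx]
    available = np.ones(control_idx.size, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for k in proc:
        if not available.any():
            break
        dist = np.abs(c_logits - t_logits[k])
        dist[~available] = np.inf
        j = int(np.argmin(dist))  # argmin keeps the lowest control index on ties
        if dist[j] <= caliper:
            pairs.append((int(treated_idx[k]), int(control_idx[j])))
            available[j] = False

    return MatchedSet(
        pairs=pairs,
        caliper_width=float(caliper),
        score_kind=kind,
        unmatched_treated=int(treated_idx.size - len(pairs)),
    )
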