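"""Score trimming and greedy 1:1 caliper matching on the logit scale.

Patients outside the region where both groups' score distributions overlap
are trimmed; high-potency patients are then matched without replacement to
the nearest lower-potency patient by logit score, accepting a pair only if
the distance is within 0.2 times the pooled sample SD of the logit scores.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .propensity import ScoreSet

__all__ = [
    "MatchedPairs",
    "trim_nonoverlap",
    "GreedyCaliperMatcher",
    "greedy_caliper_match",
    "match_scores",
]


@dataclass
class MatchedPairs:
    """1:1 matching output.

    ``pairs`` has columns ``high_id``, ``lower_id``, ``distance`` (logit
    units). Every id appears in at most one pair and all distances are
    within the caliper.
    """

    pairs: pd.DataFrame
    caliper: float
    sd_logit: float
    n_trimmed_high: int = 0
    n_trimmed_lower: int = 0
    unmatched_high: list = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _split(scores: ScoreSet | pd.DataFrame, exposure=None):
    if isinstance(scores, ScoreSet):
        frame = scores.to_frame()
    else:
        frame = pd.DataFrame(scores)
    if exposure is None:
        raise ValueError("exposure vector required")
    exposure = np.asarray(exposure)
    if exposure.dtype.kind in "UOS":
        exposure = exposure == "high"
    return frame, exposure.astype(bool)


def trim_nonoverlap(scores: ScoreSet | pd.DataFrame, exposure
                    ) -> tuple[np.ndarray, int, int]:
    """Retain patients inside the common support of the score distributions.

    The overlap interval is [max of group minima, min of group maxima],
    boundary inclusive. Returns the retained patient ids and the number
    trimmed per group (high, lower). Disjoint distributions are an error.
    """
    frame, high = _split(scores, exposure)
    s = frame["score"].to_numpy()
    if high.all() or not high.any():
        raise ValueError("both exposure groups must be non-empty")
    lo = max(s[high].min(), s[~high].min())
    hi = min(s[high].max(), s[~high].max())
    if lo > hi:
        raise ValueError(
            "score distributions are disjoint; no overlap region to retain")
    keep = (s >= lo) & (s <= hi)
    ids = frame["patient_id"].to_numpy()
    n_trim_high = int((~keep & high).sum())
    n_trim_lower = int((~keep & ~high).sum())
    return ids[keep], n_trim_high, n_trim_lower


class GreedyCaliperMatcher(BaseEstimator):
    """Greedy nearest-neighbor 1:1 matching within a logit caliper.

    The caliper is ``caliper_mult`` times the pooled sample SD (n-1
    denominator) of the logit scores over both groups as supplied (i.e.
    post-trim when trimming has been applied). High-potency patients are
    processed in descending logit order (ties by id); each is paired
    without replacement to the nearest remaining lower-potency logit, and
    the pair is kept only if the distance is within the caliper. Equidistant
    controls tie-break on the lower patient id.

    Parameters
    ----------
    caliper_mult:
        Caliper width as a multiple of the pooled logit SD (default 0.2).
    order:
        ``"descending"`` (default) or ``"random"`` processing order of the
        high-potency group; random order uses ``random_state``.

    Attributes
    ----------
    pairs_ : pd.DataFrame with columns high_id, lower_id, distance
    sd_logit_ : float
    caliper_ : float
    unmatched_high_ : list of high-potency ids left unmatched
    """

    def __init__(self, caliper_mult: float = 0.2, order: str = "descending",
                 random_state: int | None = None):
        self.caliper_mult = caliper_mult
        self.order = order
        self.random_state = random_state

    def fit(self, logit_scores, exposure, patient_id=None) -> "GreedyCaliperMatcher":
        logits = np.asarray(logit_scores, dtype=float)
        high = np.asarray(exposure)
        if high.dtype.kind in "UOS":
            high = high == "high"
        high = high.astype(bool)
        if patient_id is None:
            patient_id = np.arange(len(logits))
        ids = np.asarray(patient_id)
        if high.all() or not high.any():
            raise ValueError("both exposure groups must be non-empty")

        self.sd_logit_ = float(np.std(logits, ddof=1))
        if np.ptp(logits) == 0.0:
            self.sd_logit_ = 0.0  # guard against rounding in the mean
        if self.sd_logit_ == 0.0:
            warnings.warn("all logit scores identical; caliper degenerates to "
                          "exact-score matching", stacklevel=2)
        self.caliper_ = self.caliper_mult * self.sd_logit_

        t_logit, t_ids = logits[high], ids[high]
        c_logit, c_ids = logits[~high], ids[~high]
        if self.order == "descending":
            t_order = np.lexsort((t_ids, -t_logit))
        elif self.order == "random":
            t_order = np.random.default_rng(self.random_state).permutation(len(t_ids))
        else:
            raise ValueError(f"unknown order {self.order!r}")
        c_order = np.lexsort((c_ids, c_logit))
        pool_logit = list(c_logit[c_order])
        pool_ids = list(c_ids[c_order])

        pairs, unmatched = [], []
        for i in t_order:
            t = t_logit[i]
            if not pool_logit:
                unmatched.append(t_ids[i])
                continue
            pos = bisect.bisect_left(pool_logit, t)
            best = None  # (distance, control_id, index)
            if pos < len(pool_logit):
                best = (pool_logit[pos] - t, pool_ids[pos], pos)
            if pos > 0:
                left = (t - pool_logit[pos - 1], pool_ids[pos - 1], pos - 1)
                if best is None or left[0] < best[0] \
                        or (left[0] == best[0] and left[1] < best[1]):
                    best = left
            dist, cid, j = best
            if dist <= self.caliper_:
                pairs.append((t_ids[i], cid, dist))
                pool_logit.pop(j)
                pool_ids.pop(j)
            else:
                unmatched.append(t_ids[i])

        self.pairs_ = pd.DataFrame(pairs, columns=["high_id", "lower_id", "distance"])
        self.unmatched_high_ = unmatched
        self.n_matched_ = len(self.pairs_)
        return self

    def to_matched_pairs(self, n_trimmed_high: int = 0,
                         n_trimmed_lower: int = 0) -> MatchedPairs:
        return MatchedPairs(
            pairs=self.pairs_.copy(), caliper=self.caliper_,
            sd_logit=self.sd_logit_, n_trimmed_high=n_trimmed_high,
            n_trimmed_lower=n_trimmed_lower,
            unmatched_high=list(self.unmatched_high_),
        )


def greedy_caliper_match(scores: ScoreSet | pd.DataFrame, exposure,
                         caliper_mult: float = 0.2) -> MatchedPairs:
    """Greedy caliper matching of an (already trimmed) score set."""
    frame, high = _split(scores, exposure)
    matcher = GreedyCaliperMatcher(caliper_mult=caliper_mult)
    matcher.fit(frame["logit_score"].to_numpy(), high,
                frame["patient_id"].to_numpy())
    return matcher.to_matched_pairs()


def match_scores(scores: ScoreSet, exposure, caliper_mult: float = 0.2
                 ) -> MatchedPairs:
    """Trim non-overlapping score regions, then match within the caliper."""
    frame, high = _split(scores, exposure)
    kept_ids, n_trim_high, n_trim_lower = trim_nonoverlap(frame, high)
    keep = frame["patient_id"].isin(kept_ids).to_numpy()
    matcher = GreedyCaliperMatcher(caliper_mult=caliper_mult)
    matcher.fit(frame.loc[keep, "logit_score"].to_numpy(), high[keep],
                frame.loc[keep, "patient_id"].to_numpy())
    return matcher.to_matched_pairs(n_trim_high, n_trim_lower)
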