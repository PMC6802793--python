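"""Optimal cut-off dichotomisation of grip apertures (the OC% statistic).

The key question is whether grasping discriminates the two object sizes
better than the perceptual report does. The perceptual measure is already
dichotomous (proportion of correct verbal judgements), so the continuous
MGA is made comparable by dichotomising it at the threshold that maximises
classification accuracy: any MGA above the cut-off is called "big object",
any MGA at or below it "small object". The achieved proportion correct at
the best threshold is the optimal cut-off proportion, OC%. Because the
threshold is optimised on the very trials it classifies, OC% is biased
upward (in-sample optimism) — i.e. it *favours* the motor measure; the
leave-one-out variant quantifies that optimism.

The direction of the rule is fixed (above -> big): a participant whose
apertures scale inversely with size legitimately scores near the chance
floor rather than being re-scored with a flipped rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .trial_data import ParticipantSet, TrialRecord, _ordered_participants

logger = logging.getLogger(__name__)


@dataclass
class CutoffResult:
    """Optimal cut-off for one participant in one condition.

    ``oc_proportion`` is never below max(n_small, n_big)/(n_small+n_big):
    the degenerate all-small / all-big thresholds are always candidates.
    """

    participant_id: str
    condition_label: str
    cutoff_mm: float
    oc_proportion: float
    n_small: int
    n_big: int
    candidate_count: int


def optimal_cutoff(
    mga_small: Sequence[float],
    mga_big: Sequence[float],
    participant_id: str = "",
    condition_label: str = "",
) -> CutoffResult:
    """Accuracy-maximising threshold for one participant's MGAs.

    Candidate thresholds are the midpoints between consecutive distinct
    pooled values plus the two degenerate extremes (every real threshold is
    equivalent to one of these). A value strictly above the cut-off is
    classified "big", a value at or below it "small". Ties among equally
    good candidates break to the smallest (the proportion, which is the
    reported quantity, is tie-invariant). The degenerate extremes are
    reported as pooled min - 1 / max + 1 so results serialise.
    """
    small = np.asarray(mga_small, dtype=float)
    big = np.asarray(mga_big, dtype=float)
    if small.size == 0 or big.size == 0:
        raise ValueError("both size classes must be non-empty")
    if not (np.isfinite(small).all() and np.isfinite(big).all()):
        raise ValueError("MGA values must be finite")

    pooled = np.sort(np.concatenate([small, big]))
    distinct = np.unique(pooled)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    candidates = np.concatenate([[pooled[0] - 1.0], mids, [pooled[-1] + 1.0]])

    n = small.size + big.size
    # correct = small values <= c  plus  big values > c
    n_small_le = np.searchsorted(np.sort(small), candidates, side="right")
    n_big_gt = big.size - np.searchsorted(np.sort(big), candidates, side="right")
    correct = n_small_le + n_big_gt
    best = int(np.argmax(correct))  # argmax takes the first (smallest) maximiser
    return CutoffResult(
        participant_id=participant_id,
        condition_label=condition_label,
        cutoff_mm=float(candidates[best]),
        oc_proportion=float(correct[best]) / n,
        n_small=int(small.size),
        n_big=int(big.size),
        candidate_count=int(candidates.size),
    )


def crossvalidated_cutoff(
    mga_small: Sequence[float], mga_big: Sequence[float], seed: int = 0
) -> float:
    """Leave-one-out accuracy of the optimal cut-off.

    Each trial is classified by the threshold optimised on the remaining
    trials; the held-out proportion correct strips the in-sample optimism
    of OC%. Deterministic; ``seed`` is reserved for alternative tie-break
    policies and currently unused.
    """
    small = np.asarray(mga_small, dtype=float)
    big = np.asarray(mga_big, dtype=float)
    if small.size < 2 or big.size < 2:
        raise ValueError("each class needs >= 2 values for leave-one-out")
    correct = 0
    for i in range(small.size):
        rest = np.delete(small, i)
        c = optimal_cutoff(rest, big).cutoff_mm
        correct += small[i] <= c
    for i in range(big.size):
        rest = np.delete(big, i)
        c = optimal_cutoff(small, rest).cutoff_mm
        correct += big[i] > c
    return correct / (small.size + big.size)


def expected_optimal_accuracy(delta: float, sigma: float) -> float:
    """Ideal-threshold accuracy for two equal-variance Gaussian classes.

    With class means ``delta`` apart, common SD ``sigma`` and balanced
    priors, the best threshold sits midway and achieves
    Phi(delta / (2 sigma)). This is the analytic target that empirical OC%
    values (in-sample from above, cross-validated from below) bracket.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if delta < 0:
        raise ValueError("delta must be non-negative")
    return float(norm.cdf(delta / (2.0 * sigma)))


def _condition_labels(experiment: str) -> list[str]:
    if experiment == "E3":
        return ["closed_loop", "open_loop"]
    return ["none"]


def _mga_trials(records: Sequence[TrialRecord], vision: str) -> list[TrialRecord]:
    return [
        r
        for r in records
        if r.valid and r.mga_mm is not None and (vision == "none" or r.vision == vision)
    ]


def occ_by_participant(
    pset: ParticipantSet, pooling: str = "pooled"
) -> list[CutoffResult]:
    """One :class:`CutoffResult` per OC%-eligible participant (and vision condition).

    Trials are pooled across experimental blocks within a vision condition
    (``pooling="pooled"``, the default reading: a single OC% per participant
    per condition is reported). ``pooling="per_block"`` instead computes a
    per-block cut-off and averages the proportions. Participants without at
    least one MGA per size in a condition get a logged missing result (no
    row), never a crash.
    """
    if pooling not in ("pooled", "per_block"):
        raise ValueError(f"unknown pooling {pooling!r}")
    valid = [r for r in pset.records if r.valid]
    experiment = valid[0].experiment
    sizes = sorted({r.target_size_mm for r in valid})
    small_mm, big_mm = sizes[0], sizes[-1]
    out: list[CutoffResult] = []
    for pid in _ordered_participants(valid):
        if pid not in pset.occ_eligible:
            continue
        precs = [r for r in valid if r.participant_id == pid]
        for vision in _condition_labels(experiment):
            trials = _mga_trials(precs, vision)
            label = experiment if vision == "none" else f"{experiment}/{vision}"
            if pooling == "pooled":
                small = [r.mga_mm for r in trials if r.target_size_mm == small_mm]
                big = [r.mga_mm for r in trials if r.target_size_mm == big_mm]
                if not small or not big:
                    logger.info("participant %s: no OC%% in %s (empty class)", pid, label)
                    continue
                res = optimal_cutoff(small, big, pid, label)
            else:
                blocks = sorted({r.block for r in trials})
                per_block = []
                for b in blocks:
                    small = [
                        r.mga_mm for r in trials
                        if r.block == b and r.target_size_mm == small_mm
                    ]
                    big = [
                        r.mga_mm for r in trials
                        if r.block == b and r.target_size_mm == big_mm
                    ]
                    if small and big:
                        per_block.append(optimal_cutoff(small, big, pid, label))
                if not per_block:
                    logger.info("participant %s: no OC%% in %s (empty class)", pid, label)
                    continue
                res = CutoffResult(
                    participant_id=pid,
                    condition_label=label,
                    cutoff_mm=float(np.mean([r.cutoff_mm for r in per_block])),
                    oc_proportion=float(np.mean([r.oc_proportion for r in per_block])),
                    n_small=sum(r.n_small for r in per_block),
                    n_big=sum(r.n_big for r in per_block),
                    candidate_count=sum(r.candidate_count for r in per_block),
                )
            out.append(res)
    return out


def verbal_accuracy(
    records: Sequence[TrialRecord], by_vision: bool = False
) -> pd.DataFrame:
    """Per-participant proportion of correct verbal judgements.

    Counts all valid trials with a response, including those whose MGA is
    missing (the verbal measure does not depend on the kinematics). Returns
    a tidy frame with columns participant_id, condition_label, n_trials,
    accuracy; participants with zero countable trials are logged and
    omitted.
    """
    valid = [r for r in records if r.valid]
    rows = []
    for pid in _ordered_participants(valid):
        precs = [r for r in valid if r.participant_id == pid]
        groups = (
            sorted({r.vision for r in precs}) if by_vision else ["all"]
        )
        for g in groups:
            trials = [r for r in precs if not by_vision or r.vision == g]
            if not trials:
                logger.info("participant %s: no trials in %s", pid, g)
                continue
            rows.append(
                {
                    "participant_id": pid,
                    "condition_label": g,
                    "n_trials": len(trials),
                    "accuracy": float(np.mean([r.verbal_correct for r in trials])),
                }
            )
    return pd.DataFrame(rows, columns=["participant_id", "condition_label", "n_trials", "accuracy"])
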