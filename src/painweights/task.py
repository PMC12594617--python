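"""Cued pain task: trial construction, stimulation delivery and cue statistics.

The paradigm presents two cue pairs per trial. The *target* pair shows two
integer stimulation levels (on the 0-10 psychophysics scale, anchored at the
pain threshold and the highest tolerable level) differing by at least
``min_gap`` units; each level is equally likely to be delivered. The *lure*
pair repeats one target card and replaces the other with a strictly higher
level, so its expected worst case always exceeds the target's. Participants
are instructed to pick the target; picking the lure on more than 25% of
trials marks inattention and excludes the participant.

Stimulation levels and cue means are rescaled to the 0-100 rating scale
before modelling so that stimulus, cue and rating share one scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "TrialSpec",
    "AttentionResult",
    "rescale",
    "admissible_target_pairs",
    "make_target_pair",
    "make_lure_pair",
    "deliver_stimulation",
    "cue_stats",
    "attention_filter",
    "simulate_trials",
    "trials_to_frame",
    "frame_to_trials",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = [
    "participant_id",
    "trial_index",
    "target_a",
    "target_b",
    "lure_a",
    "lure_b",
    "chosen_is_target",
    "delivered_level",
    "X",
    "q",
    "SD",
    "rating",
]


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the cued pain task.

    ``level_lo``/``level_hi`` are the psychophysics anchors (pain threshold
    and highest tolerable pain). ``sd_convention`` selects how the two-card
    cue spread is summarised: ``"population"`` gives |a-b|/2 on the rescaled
    scale, ``"sample"`` gives |a-b|/sqrt(2).
    """

    n_trials: int = 60
    level_lo: int = 3
    level_hi: int = 7
    min_gap: int = 2
    p_high: float = 0.5
    rescale_lo: float = 0.0
    rescale_hi: float = 100.0
    seed: Optional[int] = None
    sd_convention: str = "population"

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for name in ("level_lo", "level_hi", "min_gap"):
            v = getattr(self, name)
            if int(v) != v:
                raise ValueError(f"{name} must be an integer, got {v!r}")
        if self.level_hi - self.level_lo < self.min_gap:
            raise ValueError(
                "level range narrower than min_gap: no admissible target pair"
            )
        if not 0.0 <= self.p_high <= 1.0:
            raise ValueError("p_high must lie in [0, 1]")
        if self.rescale_hi <= self.rescale_lo:
            raise ValueError("rescale_hi must exceed rescale_lo")
        if self.sd_convention not in ("population", "sample"):
            raise ValueError("sd_convention must be 'population' or 'sample'")


class AttentionResult(NamedTuple):
    passed: bool
    lure_fraction: float


@dataclass(frozen=True)
class TrialSpec:
    """One cued-pain trial with its rescaled model inputs.

    ``X`` is the rescaled delivered intensity, ``q`` the rescaled cue mean of
    the *chosen* pair and ``SD`` its spread; ``rating`` is filled in by the
    rating model (None until then).
    """

    target: tuple[int, int]
    lure: tuple[int, int]
    chosen_is_target: bool
    delivered_level: int
    X: float
    q: float
    SD: float
    rating: Optional[float] = None

    def validate(self, cfg: TaskConfig) -> None:
        a, b = self.target
        if not a < b:
            raise ValueError("target pair must be ordered a < b")
        if b - a < cfg.min_gap:
            raise ValueError("target cards closer than min_gap")
        if not (cfg.level_lo <= a and b <= cfg.level_hi):
            raise ValueError("target outside anchor range")
        la, lb = self.lure
        matched = set(self.lure) & set(self.target)
        if not matched:
            raise ValueError("no lure card matches a target card")
        # the non-matched lure card must strictly exceed the non-matched
        # target card
        if not _lure_admissible(self.target, self.lure, cfg):
            raise ValueError("lure does not dominate the alternative target card")
        chosen = self.target if self.chosen_is_target else self.lure
        if self.delivered_level not in chosen:
            raise ValueError("delivered level not on the chosen pair")
        lo, hi = cfg.rescale_lo, cfg.rescale_hi
        if not (lo <= self.X <= hi and lo <= self.q <= hi):
            raise ValueError("X and q must lie on the rating scale")
        if self.SD < 0:
            raise ValueError("SD must be non-negative")


def rescale(level: float, cfg: TaskConfig) -> float:
    """Affine map from the psychophysics anchors onto the rating scale."""
    if not cfg.level_lo <= level <= cfg.level_hi:
        raise ValueError(
            f"level {level} outside anchors [{cfg.level_lo}, {cfg.level_hi}]"
        )
    frac = (level - cfg.level_lo) / (cfg.level_hi - cfg.level_lo)
    return frac * (cfg.rescale_hi - cfg.rescale_lo) + cfg.rescale_lo


def admissible_target_pairs(cfg: TaskConfig) -> list[tuple[int, int]]:
    """All ordered integer pairs (a, b) with b - a >= min_gap inside the anchors."""
    levels = range(int(cfg.level_lo), int(cfg.level_hi) + 1)
    return [
        (a, b) for a, b in itertools.combinations(levels, 2) if b - a >= cfg.min_gap
    ]


def make_target_pair(cfg: TaskConfig, rng: np.random.Generator) -> tuple[int, int]:
    """Sample a target pair uniformly over all admissible pairs."""
    pairs = admissible_target_pairs(cfg)
    if not pairs:
        raise ValueError("no admissible target pair for this configuration")
    return pairs[rng.integers(len(pairs))]


def _lure_candidates(
    target: tuple[int, int], cfg: TaskConfig
) -> list[tuple[int, list[int]]]:
    """Matched-card choices and the admissible 'higher' cards for each."""
    a, b = target
    out = []
    for matched, other in ((a, b), (b, a)):
        higher = [lv for lv in range(other + 1, int(cfg.level_hi) + 1)]
        if higher:
            out.append((matched, higher))
    return out


def _lure_admissible(
    target: tuple[int, int], lure: tuple[int, int], cfg: TaskConfig
) -> bool:
    a, b = target
    for matched, other in ((a, b), (b, a)):
        rest = list(lure)
        if matched in rest:
            rest.remove(matched)
            if other < rest[0] <= cfg.level_hi:
                return True
    return False


def make_lure_pair(
    target: tuple[int, int], cfg: TaskConfig, rng: np.random.Generator
) -> tuple[int, int]:
    """Construct a lure: one target card repeated, the other strictly higher.

    The card to repeat is chosen uniformly among target cards for which a
    strictly-higher alternative (to the *other* target card) exists within
    the anchors; the higher card is then sampled uniformly.
    """
    cands = _lure_candidates(target, cfg)
    if not cands:
        raise ValueError(f"no admissible lure for target {target}")
    matched, higher = cands[rng.integers(len(cands))]
    other = higher[rng.integers(len(higher))]
    return (matched, other) if matched <= other else (other, matched)


def deliver_stimulation(
    pair: tuple[int, int], cfg: TaskConfig, rng: np.random.Generator
) -> int:
    """Deliver the higher card with probability p_high, else the lower."""
    lo, hi = min(pair), max(pair)
    return hi if rng.random() < cfg.p_high else lo


def cue_stats(pair: tuple[int, int], cfg: TaskConfig) -> tuple[float, float]:
    """Rescaled cue mean and spread of a two-card cue.

    q is the mean of the two rescaled card values. SD follows the configured
    convention: population SD |r(a)-r(b)|/2 (default) or sample SD
    |r(a)-r(b)|/sqrt(2).
    """
    ra, rb = rescale(pair[0], cfg), rescale(pair[1], cfg)
    q = 0.5 * (ra + rb)
    half_range = 0.5 * abs(ra - rb)
    if cfg.sd_convention == "population":
        sd = half_range
    else:
        sd = abs(ra - rb) / np.sqrt(2.0)
    return q, sd


def attention_filter(trials: Sequence[TrialSpec] | pd.DataFrame) -> AttentionResult:
    """Exclusion rule: fail when lure picks exceed 25% of trials (strict)."""
    if isinstance(trials, pd.DataFrame):
        chosen = trials["chosen_is_target"].to_numpy(dtype=bool)
    else:
        chosen = np.array([t.chosen_is_target for t in trials], dtype=bool)
    if chosen.size == 0:
        raise ValueError("attention_filter requires at least one trial")
    lure_fraction = float(np.mean(~chosen))
    return AttentionResult(passed=lure_fraction <= 0.25, lure_fraction=lure_fraction)


def simulate_trials(
    cfg: TaskConfig,
    rng: np.random.Generator,
    choice_accuracy: float = 0.95,
) -> list[TrialSpec]:
    """Simulate one participant's sequence of cued-pain trials.

    Synthetic participants pick the target with probability
    ``choice_accuracy``; on lure-pick trials the stimulation is delivered
    from the chosen (lure) pair and the trial is flagged via
    ``chosen_is_target``. The model inputs X, q, SD always describe the
    chosen pair, i.e. the cue the participant actually saw.
    """
    if not 0.0 <= choice_accuracy <= 1.0:
        raise ValueError("choice_accuracy must lie in [0, 1]")
    trials = []
    for _ in range(cfg.n_trials):
        target = make_target_pair(cfg, rng)
        lure = make_lure_pair(target, cfg, rng)
        chose_target = bool(rng.random() < choice_accuracy)
        chosen = target if chose_target else lure
        delivered = deliver_stimulation(chosen, cfg, rng)
        q, sd = cue_stats(chosen, cfg)
        trials.append(
            TrialSpec(
                target=target,
                lure=lure,
                chosen_is_target=chose_target,
                delivered_level=delivered,
                X=rescale(delivered, cfg),
                q=q,
                SD=sd,
            )
        )
    return trials


def trials_to_frame(
    trials: Iterable[TrialSpec], participant_id: str
) -> pd.DataFrame:
    """Flatten trials into the canonical delimited-text trial table."""
    rows = []
    for i, t in enumerate(trials):
        rows.append(
            {
                "participant_id": participant_id,
                "trial_index": i,
                "target_a": t.target[0],
                "target_b": t.target[1],
                "lure_a": t.lure[0],
                "lure_b": t.lure[1],
                "chosen_is_target": t.chosen_is_target,
                "delivered_level": t.delivered_level,
                "X": t.X,
                "q": t.q,
                "SD": t.SD,
                "rating": t.rating if t.rating is not None else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_trials(frame: pd.DataFrame) -> list[TrialSpec]:
    """Inverse of :func:`trials_to_frame` for a single participant's rows."""
    trials = []
    for row in frame.itertuples(index=False):
        rating = getattr(row, "rating", np.nan)
        trials.append(
            TrialSpec(
                target=(int(row.target_a), int(row.target_b)),
                lure=(int(row.lure_a), int(row.lure_b)),
                chosen_is_target=bool(row.chosen_is_target),
                delivered_level=int(row.delivered_level),
                X=float(row.X),
                q=float(row.q),
                SD=float(row.SD),
                rating=None if pd.isna(rating) else float(rating),
            )
        )
    return trials
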