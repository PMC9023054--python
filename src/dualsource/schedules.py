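"""Probabilistic reward schedules with stable and volatile phases.

Two independent information sources are tracked on every trial of a
120-trial session: a *primary* source (the option directly indicated by
reward feedback) and a *secondary* source (advice whose correctness must
be inferred from feedback).  Each source follows its own pseudo-random
schedule composed of stable blocks, in which the reward probability is
constant for more than 30 trials, and volatile blocks, in which the
probability reverses between ``q`` and ``1 - q`` every 10-20 trials.

Conventions
-----------
``r(t)``
    Binary outcome for the primary-congruent option (1 = that option was
    rewarded).
``advice(t)``
    Secondary-source advice coded relative to the primary-congruent
    option: 0 = the advice endorses the primary-congruent option,
    1 = it endorses the alternative.  The advice is *correct* on trial
    ``t`` exactly when it endorses the rewarded option, i.e. the
    correctness indicator is ``r(t) XOR advice(t)``.
``y(t)``
    Choice (1 = primary-congruent option), possibly missing (NaN).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

STABLE = "stable"
VOLATILE = "volatile"

#: column order of the trial-level CSV format
TRIAL_COLUMNS = [
    "trial", "p_primary", "p_secondary", "phase_primary", "phase_secondary",
    "r", "advice", "y", "subject", "group", "drug", "session",
]


@dataclass(frozen=True)
class Block:
    """One schedule block: a phase type, its length and its high probability."""

    phase: Literal["stable", "volatile"]
    length: int
    p_high: float = 0.8

    def __post_init__(self) -> None:
        if self.phase not in (STABLE, VOLATILE):
            raise ValueError(f"unknown phase type {self.phase!r}")
        if not 0.5 < self.p_high < 1.0:
            raise ValueError("p_high must lie in (0.5, 1)")
        if self.length <= 0:
            raise ValueError("block length must be positive")


def default_blocks(n_trials: int = 120, p_high: float = 0.8,
                   stable_first: bool = True) -> tuple[Block, ...]:
    """Half stable / half volatile split of a session.

    The default primary schedule opens with the stable block and the
    default secondary schedule with the volatile block, so the phases of
    the two sources are not aligned.
    """
    half = n_trials // 2
    blocks = [Block(STABLE, n_trials - half, p_high), Block(VOLATILE, half, p_high)]
    if not stable_first:
        blocks.reverse()
    return tuple(blocks)


def counterbalanced_configs(n_trials: int = 120, p_high: float = 0.8,
                            volatile_switch_range: tuple[int, int] = (10, 20),
                            seed: int = 0) -> list["ScheduleConfig"]:
    """The four counterbalanced block orders (stable/volatile first for each
    source), emulating random assignment to pseudo-randomised schedules."""
    configs = []
    for i, (pri_first, sec_first) in enumerate(
            [(True, False), (False, True), (True, True), (False, False)]):
        configs.append(ScheduleConfig(
            n_trials=n_trials,
            blocks_primary=default_blocks(n_trials, p_high, pri_first),
            blocks_secondary=default_blocks(n_trials, p_high, sec_first),
            volatile_switch_range=volatile_switch_range,
            seed=seed + i))
    return configs


@dataclass(frozen=True)
class ScheduleConfig:
    """Configuration of the two independent source schedules.

    Parameters
    ----------
    n_trials
        Session length (default 120 trials).
    blocks_primary, blocks_secondary
        Ordered block lists per source; lengths must sum to ``n_trials``
        and stable blocks must be longer than 30 trials.
    volatile_switch_range
        Inclusive bounds on the number of trials between reversals
        inside a volatile block (default 10-20).
    seed
        Seed for reversal placement.
    """

    n_trials: int = 120
    blocks_primary: tuple[Block, ...] = field(default_factory=default_blocks)
    blocks_secondary: tuple[Block, ...] = field(
        default_factory=lambda: default_blocks(stable_first=False))
    volatile_switch_range: tuple[int, int] = (10, 20)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.volatile_switch_range
        if not (0 < lo <= hi):
            raise ValueError("volatile_switch_range must satisfy 0 < min <= max")
        for name, blocks in (("primary", self.blocks_primary),
                             ("secondary", self.blocks_secondary)):
            total = sum(b.length for b in blocks)
            if total != self.n_trials:
                raise ValueError(
                    f"{name} block lengths sum to {total}, expected {self.n_trials}")
            for b in blocks:
                if b.phase == STABLE and b.length <= 30:
                    raise ValueError(
                        f"stable blocks must exceed 30 trials (got {b.length})")
                if b.phase == VOLATILE and b.length < lo:
                    raise ValueError("volatile block shorter than the minimum "
                                     "reversal interval")

    # -- JSON round trip ------------------------------------------------
    def to_json(self) -> str:
        def enc(blocks: Sequence[Block]):
            return [[b.phase, b.length, b.p_high] for b in blocks]
        return json.dumps({
            "n_trials": self.n_trials,
            "blocks_primary": enc(self.blocks_primary),
            "blocks_secondary": enc(self.blocks_secondary),
            "volatile_switch_range": list(self.volatile_switch_range),
            "seed": self.seed,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ScheduleConfig":
        d = json.loads(text)
        def dec(items):
            return tuple(Block(p, int(n), float(q)) for p, n, q in items)
        return cls(
            n_trials=int(d.get("n_trials", 120)),
            blocks_primary=dec(d["blocks_primary"]) if "blocks_primary" in d
            else default_blocks(int(d.get("n_trials", 120))),
            blocks_secondary=dec(d["blocks_secondary"]) if "blocks_secondary" in d
            else default_blocks(int(d.get("n_trials", 120)), stable_first=False),
            volatile_switch_range=tuple(d.get("volatile_switch_range", (10, 20))),
            seed=int(d.get("seed", 0)),
        )

    def with_seed(self, seed: int) -> "ScheduleConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class TaskSchedule:
    """Per-trial reward probabilities and phase labels for both sources."""

    p_primary: np.ndarray
    p_secondary: np.ndarray
    phase_primary: np.ndarray   # array of {"stable", "volatile"}
    phase_secondary: np.ndarray

    @property
    def n_trials(self) -> int:
        return len(self.p_primary)

    def __post_init__(self) -> None:
        n = len(self.p_primary)
        for arr in (self.p_secondary, self.phase_primary, self.phase_secondary):
            if len(arr) != n:
                raise ValueError("schedule arrays must have equal length")
        for p in (self.p_primary, self.p_secondary):
            if np.any((p <= 0) | (p >= 1)):
                raise ValueError("schedule probabilities must lie in (0, 1)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trial": np.arange(1, self.n_trials + 1),
            "p_primary": self.p_primary,
            "p_secondary": self.p_secondary,
            "phase_primary": self.phase_primary,
            "phase_secondary": self.phase_secondary,
        })


@dataclass
class TrialSequence:
    """Realised outcomes, advice and (optionally) choices for one session."""

    r: np.ndarray                 # outcome for the primary-congruent option
    advice: np.ndarray            # 0 = advice endorses primary-congruent option
    phase_primary: np.ndarray
    phase_secondary: np.ndarray
    y: np.ndarray | None = None   # choices, NaN = missing
    p_primary: np.ndarray | None = None
    p_secondary: np.ndarray | None = None
    subject: str = ""
    group: str = ""               # individual-primary | social-primary
    drug: str = ""                # HAL | PLA
    session: int = 1

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=int)
        self.advice = np.asarray(self.advice, dtype=int)
        n = len(self.r)
        if len(self.advice) != n:
            raise ValueError("r and advice must have equal length")
        if not set(np.unique(self.r)) <= {0, 1}:
            raise ValueError("outcomes must be binary")
        if not set(np.unique(self.advice)) <= {0, 1}:
            raise ValueError("advice must be binary")
        if self.y is None:
            self.y = np.full(n, np.nan)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.y) != n:
            raise ValueError("y must match the trial count")

    @property
    def n_trials(self) -> int:
        return len(self.r)

    @property
    def secondary_correct(self) -> np.ndarray:
        """Correctness of the advice, inferred from feedback (r XOR advice)."""
        return self.r ^ self.advice

    def to_frame(self) -> pd.DataFrame:
        n = self.n_trials
        def col(a, fill=np.nan):
            return a if a is not None else np.full(n, fill)
        return pd.DataFrame({
            "trial": np.arange(1, n + 1),
            "p_primary": col(self.p_primary),
            "p_secondary": col(self.p_secondary),
            "phase_primary": self.phase_primary,
            "phase_secondary": self.phase_secondary,
            "r": self.r,
            "advice": self.advice,
            "y": self.y,
            "subject": self.subject,
            "group": self.group,
            "drug": self.drug,
            "session": self.session,
        })[TRIAL_COLUMNS]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialSequence":
        df = df.sort_values("trial") if "trial" in df else df
        meta = {}
        for key in ("subject", "group", "drug"):
            meta[key] = str(df[key].iloc[0]) if key in df and df[key].notna().any() else ""
        session = int(df["session"].iloc[0]) if "session" in df and df["session"].notna().any() else 1
        return cls(
            r=df["r"].to_numpy(dtype=int),
            advice=df["advice"].to_numpy(dtype=int),
            phase_primary=df["phase_primary"].to_numpy(),
            phase_secondary=df["phase_secondary"].to_numpy(),
            y=df["y"].to_numpy(dtype=float) if "y" in df else None,
            p_primary=df["p_primary"].to_numpy(dtype=float) if "p_primary" in df else None,
            p_secondary=df["p_secondary"].to_numpy(dtype=float) if "p_secondary" in df else None,
            session=session,
            **meta,
        )


def _volatile_runs(length: int, lo: int, hi: int, rng: np.random.Generator) -> list[int]:
    """Partition a volatile block into reversal intervals, each in [lo, hi].

    Intervals are drawn uniformly; the admissible range of each draw is
    narrowed so the remainder can always be completed, keeping every run
    (including the last) inside the bounds whenever ``length >= lo``.
    """
    if length < lo:
        raise ValueError("volatile block shorter than the minimum interval")
    runs: list[int] = []
    remaining = length
    while remaining > 0:
        if remaining <= hi:
            runs.append(remaining)
            break
        upper = min(hi, remaining - lo)
        runs.append(int(rng.integers(lo, upper + 1)))
        remaining -= runs[-1]
    return runs


def _source_schedule(blocks: Sequence[Block], lo: int, hi: int,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    p_parts: list[np.ndarray] = []
    phase_parts: list[np.ndarray] = []
    for block in blocks:
        if block.phase == STABLE:
            p_parts.append(np.full(block.length, block.p_high))
        else:
            high_first = bool(rng.integers(2))
            segs = []
            for i, run in enumerate(_volatile_runs(block.length, lo, hi, rng)):
                level = block.p_high if (i % 2 == 0) == high_first else 1 - block.p_high
                segs.append(np.full(run, level))
            p_parts.append(np.concatenate(segs))
        phase_parts.append(np.full(block.length, block.phase, dtype=object))
    return np.concatenate(p_parts), np.concatenate(phase_parts)


def generate_schedule(config: ScheduleConfig) -> TaskSchedule:
    """Build the two uncorrelated source schedules from a configuration.

    Deterministic given ``config.seed``; the two sources use the same
    stream but are constructed independently of each other's draws.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.volatile_switch_range
    p_pri, ph_pri = _source_schedule(config.blocks_primary, lo, hi, rng)
    p_sec, ph_sec = _source_schedule(config.blocks_secondary, lo, hi, rng)
    return TaskSchedule(p_pri, p_sec, ph_pri, ph_sec)


def sample_trials(schedule: TaskSchedule, seed: int, **metadata) -> TrialSequence:
    """Realise Bernoulli outcomes and advice from a schedule.

    ``r(t) ~ Bernoulli(p_primary(t))`` and the advice-correctness draw
    ``c(t) ~ Bernoulli(p_secondary(t))`` are independent; the advice is
    then coded so that it endorses the rewarded option exactly when
    ``c(t) = 1``.  Choices are left missing.
    """
    rng = np.random.default_rng(seed)
    r = (rng.random(schedule.n_trials) < schedule.p_primary).astype(int)
    correct = (rng.random(schedule.n_trials) < schedule.p_secondary).astype(int)
    # advice endorses the rewarded option iff the correctness draw is 1:
    # correct & r=1 -> 0, correct & r=0 -> 1, incorrect flips each case
    advice = r ^ correct
    return TrialSequence(
        r=r, advice=advice,
        phase_primary=schedule.phase_primary,
        phase_secondary=schedule.phase_secondary,
        p_primary=schedule.p_primary,
        p_secondary=schedule.p_secondary,
        **metadata,
    )


def write_trials(sequences: Sequence[TrialSequence], path) -> None:
    """Write trial sequences to a single CSV, one row per trial."""
    pd.concat([s.to_frame() for s in sequences], ignore_index=True).to_csv(
        path, index=False)


def read_trials(path) -> list[TrialSequence]:
    """Read a trial CSV back into one TrialSequence per (subject, drug, session)."""
    df = pd.read_csv(path, keep_default_na=True)
    keys = [k for k in ("subject", "drug", "session") if k in df.columns]
    if not keys:
        return [TrialSequence.from_frame(df)]
    out = []
    for _, g in df.groupby(keys, dropna=False, sort=True):
        out.append(TrialSequence.from_frame(g))
    return out
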