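"""Volatile binary trial sequences.

The task presents a stream of ball bounces that are either "normal"
(``u = 1``) or unexpectedly bouncy (``u = 0``).  Volatility is created by
shifting the generating probability p(normal) among 0.5, 0.67 and 0.83 in
segments; the default plans cycle 12-trial segments through those levels
over 2 blocks of 72 trials, in two counterbalanced orders (A and its
reverse, B).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TrialSchedule",
    "default_segment_plan",
    "generate_schedule",
    "empirical_rates",
]

DEFAULT_BLOCK_LENGTH = 72
DEFAULT_N_BLOCKS = 2
_CYCLE_A = (0.5, 0.83, 0.67, 0.83, 0.5, 0.67)
DEFAULT_SEGMENT_LENGTH = 12


@dataclass
class TrialSchedule:
    """Per-trial ball types with their generating probabilities.

    ``trials`` columns: trial (1-based), block, u, p_normal, segment.
    """

    trials: pd.DataFrame
    order_id: str
    seed: int
    block_length: int = DEFAULT_BLOCK_LENGTH

    def __post_init__(self):
        self.validate()

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def u(self) -> np.ndarray:
        return self.trials["u"].to_numpy(dtype=float)

    @property
    def p_normal(self) -> np.ndarray:
        return self.trials["p_normal"].to_numpy(dtype=float)

    def validate(self) -> None:
        t = self.trials
        if not np.isin(t["u"].to_numpy(), (0, 1)).all():
            raise ValueError("u values must be binary")
        if not ((t["p_normal"] >= 0) & (t["p_normal"] <= 1)).all():
            raise ValueError("p_normal outside [0, 1]")
        counts = t.groupby("block").size()
        if not (counts == self.block_length).all():
            raise ValueError(
                f"every block must hold {self.block_length} trials, got {dict(counts)}"
            )
        # constant p within segment
        per_seg = t.groupby("segment")["p_normal"].nunique()
        if not (per_seg == 1).all():
            raise ValueError("p_normal must be constant within a segment")

    def to_csv(self, path) -> None:
        out = self.trials[["trial", "block", "u", "p_normal"]].copy()
        out["order_id"] = self.order_id
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, seed: int = -1, block_length: int | None = None) -> "TrialSchedule":
        df = pd.read_csv(path)
        required = {"trial", "block", "u", "p_normal"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"schedule file missing columns {sorted(missing)}")
        order_id = str(df["order_id"].iloc[0]) if "order_id" in df else "unknown"
        df = df.sort_values("trial").reset_index(drop=True)
        seg = (df["p_normal"].diff().fillna(0) != 0).cumsum()
        df["segment"] = seg.astype(int)
        if block_length is None:
            block_length = int(df.groupby("block").size().iloc[0])
        return cls(df[["trial", "block", "u", "p_normal", "segment"]],
                   order_id=order_id, seed=seed, block_length=block_length)


def default_segment_plan(
    order_id: str = "A",
    n_blocks: int = DEFAULT_N_BLOCKS,
    block_length: int = DEFAULT_BLOCK_LENGTH,
    segment_length: int = DEFAULT_SEGMENT_LENGTH,
) -> list[tuple[float, int]]:
    """Built-in counterbalanced plans: 12-trial segments cycling
    0.5 -> 0.83 -> 0.67 -> 0.83 -> 0.5 -> 0.67 per block (order A) or the
    reversed cycle (order B)."""
    cycle = _CYCLE_A if order_id == "A" else tuple(reversed(_CYCLE_A))
    if order_id not in ("A", "B"):
        raise ValueError("order_id must be 'A' or 'B'")
    per_block = block_length // segment_length
    plan = []
    for _ in range(n_blocks):
        for i in range(per_block):
            plan.append((cycle[i % len(cycle)], segment_length))
    return plan


def generate_schedule(
    segment_plan: list[tuple[float, int]] | None = None,
    n_blocks: int = DEFAULT_N_BLOCKS,
    block_length: int = DEFAULT_BLOCK_LENGTH,
    order_id: str = "A",
    seed: int = 0,
    fixed_ratio: bool = False,
) -> TrialSchedule:
    """Draw a volatile binary trial sequence.

    Within each segment, ball types are independent Bernoulli(p_normal)
    draws (``fixed_ratio=True`` instead shuffles the closest fixed count of
    normals). Reproducible from ``seed``.
    """
    if segment_plan is None:
        segment_plan = default_segment_plan(order_id, n_blocks, block_length)
    total = n_blocks * block_length
    lengths = [int(l) for _, l in segment_plan]
    if sum(lengths) != total:
        raise ValueError(
            f"segment lengths sum to {sum(lengths)}, expected {total} "
            f"({n_blocks} blocks x {block_length})"
        )
    for p, _ in segment_plan:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"segment probability {p} outside [0, 1]")
    rng = np.random.default_rng(seed)
    u = np.empty(total, dtype=int)
    p_col = np.empty(total)
    seg_col = np.empty(total, dtype=int)
    pos = 0
    for si, (p, length) in enumerate(segment_plan):
        if fixed_ratio:
            n_one = int(round(p * length))
            seg = np.concatenate([np.ones(n_one, dtype=int), np.zeros(length - n_one, dtype=int)])
            rng.shuffle(seg)
        else:
            seg = (rng.random(length) < p).astype(int)
        u[pos:pos + length] = seg
        p_col[pos:pos + length] = p
        seg_col[pos:pos + length] = si
        pos += length
    trials = pd.DataFrame(
        {
            "trial": np.arange(1, total + 1),
            "block": np.repeat(np.arange(1, n_blocks + 1), block_length),
            "u": u,
            "p_normal": p_col,
            "segment": seg_col,
        }
    )
    return TrialSchedule(trials, order_id=order_id, seed=seed, block_length=block_length)


def empirical_rates(schedule: TrialSchedule) -> pd.DataFrame:
    """Observed fraction of u=1 per segment (generation sanity check)."""
    if len(schedule) == 0:
        raise ValueError("empty schedule")
    g = schedule.trials.groupby("segment")
    out = g.agg(p_normal=("p_normal", "first"), n=("u", "size"), rate=("u", "mean"))
    return out.reset_index()


def plan_to_json(segment_plan: list[tuple[float, int]], path) -> None:
    with open(path, "w") as fh:
        json.dump([{"p_normal": p, "length": l} for p, l in segment_plan], fh, indent=2)


def plan_from_json(path) -> list[tuple[float, int]]:
    with open(path) as fh:
        raw = json.load(fh)
    return [(float(d["p_normal"]), int(d["length"])) for d in raw]
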