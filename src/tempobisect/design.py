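"""Trial-schedule construction for the auditory temporal bisection task.

The task presents sounds of seven durations (2–5 s in 0.5 s steps) drawn
from a 2x2 stimulus design: semantic category (environmental vs human
vocal) crossed with affective valence (pleasant vs unpleasant), two sound
exemplars per condition.  A training phase teaches the 2 s ("short") and
5 s ("long") reference durations; the experimental phase presents every
duration x condition combination once per block, in an order constrained
so that no two consecutive trials share a condition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

from ._rng import substream

#: The seven stimulus durations, seconds.
DURATIONS: tuple[float, ...] = (2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0)
#: Short and long reference durations learned in training, seconds.
SHORT_REF: float = 2.0
LONG_REF: float = 5.0
#: Arithmetic mean of the two references — the veridical bisection point.
REFERENCE_MEAN: float = (SHORT_REF + LONG_REF) / 2.0

CATEGORIES: tuple[str, str] = ("environmental", "human")
VALENCES: tuple[str, str] = ("pleasant", "unpleasant")

ITI_RANGE: tuple[float, float] = (1.0, 3.0)

#: Proportion correct that must be exceeded (strictly) to pass training.
TRAINING_PASS_FRACTION: float = 0.80
TRAINING_N_TRIALS: int = 16


class DesignError(ValueError):
    """Raised for structurally invalid design inputs (e.g. exemplar sets)."""


class SchedulingError(RuntimeError):
    """Raised when the adjacency constraint cannot be satisfied."""


@dataclass(frozen=True, order=True)
class Condition:
    """One cell of the 2x2 semantic-category x valence stimulus design."""

    semantic_category: str
    valence: str

    def __post_init__(self) -> None:
        if self.semantic_category not in CATEGORIES:
            raise DesignError(f"unknown semantic category {self.semantic_category!r}")
        if self.valence not in VALENCES:
            raise DesignError(f"unknown valence {self.valence!r}")

    @property
    def key(self) -> str:
        return f"{self.semantic_category}-{self.valence}"


#: The four conditions, in a fixed canonical order.
ALL_CONDITIONS: tuple[Condition, ...] = tuple(
    Condition(c, v) for c in CATEGORIES for v in VALENCES
)


def condition_from_key(key: str) -> Condition:
    cat, _, val = key.partition("-")
    return Condition(cat, val)


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled stimulus presentation."""

    phase: str  # "training" | "experimental"
    block_index: int
    condition: Condition
    exemplar_id: str
    duration: float
    iti: float


@dataclass
class Schedule:
    """An ordered trial list plus the seed that generated it."""

    trials: list[TrialSpec]
    seed: int
    phase: str = "experimental"

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_blocks(self) -> int:
        if not self.trials:
            return 0
        return max(t.block_index for t in self.trials) + 1


#: The eight sound exemplars of the published stimulus set, two per condition.
DEFAULT_EXEMPLARS: dict[Condition, tuple[str, str]] = {
    Condition("environmental", "pleasant"): ("brook", "river"),
    Condition("environmental", "unpleasant"): ("angle_grinder", "car_horn"),
    Condition("human", "pleasant"): ("laughter_female", "laughter_male"),
    Condition("human", "unpleasant"): ("crying_female", "crying_male"),
}


def _check_exemplars(exemplars: dict[Condition, tuple[str, str]]) -> None:
    if set(exemplars) != set(ALL_CONDITIONS):
        raise DesignError(
            "exemplar mapping must cover exactly the four conditions; got "
            f"{sorted(c.key for c in exemplars)}"
        )
    ids: list[str] = []
    for cond, pair in exemplars.items():
        if len(pair) != 2:
            raise DesignError(f"condition {cond.key} needs exactly 2 exemplars")
        ids.extend(pair)
    if len(set(ids)) != 8:
        raise DesignError("the 8 exemplar identifiers must be distinct")


def passes_training(n_correct: int, n_trials: int = TRAINING_N_TRIALS) -> bool:
    """Training-phase pass rule: strictly more than 80% correct.

    With the standard 16 training trials this means at least 13 correct.
    """
    if not 0 <= n_correct <= n_trials:
        raise ValueError(f"n_correct={n_correct} outside [0, {n_trials}]")
    return n_correct / n_trials > TRAINING_PASS_FRACTION


def build_training_schedule(
    exemplars: dict[Condition, tuple[str, str]] | None = None,
    seed: int = 0,
) -> Schedule:
    """16 training trials: each of the 8 exemplars once at 2 s and once at 5 s.

    Order is a seeded permutation; ITIs are drawn uniformly on [1, 3] s.
    """
    exemplars = DEFAULT_EXEMPLARS if exemplars is None else exemplars
    _check_exemplars(exemplars)
    rng = substream(seed, "training")
    cells = [
        (cond, ex, dur)
        for cond, pair in sorted(exemplars.items())
        for ex in pair
        for dur in (SHORT_REF, LONG_REF)
    ]
    order = rng.permutation(len(cells))
    itis = rng.uniform(*ITI_RANGE, size=len(cells))
    trials = [
        TrialSpec("training", 0, cells[j][0], cells[j][1], cells[j][2], float(itis[i]))
        for i, j in enumerate(order)
    ]
    return Schedule(trials, seed, phase="training")


def _block_cells(
    exemplars: dict[Condition, tuple[str, str]], offset_rng: np.random.Generator
) -> list[tuple[Condition, str, float]]:
    """The 28 duration x condition cells of one block with exemplars assigned.

    Within a block each condition's seven duration cells alternate between its
    two exemplars round-robin, starting from a seeded offset, so exemplars are
    balanced (4/3 split) without specifying more than the design does.
    """
    cells = []
    for cond in ALL_CONDITIONS:
        pair = exemplars[cond]
        start = int(offset_rng.integers(2))
        for i, dur in enumerate(DURATIONS):
            cells.append((cond, pair[(start + i) % 2], dur))
    return cells


def _no_adjacent_repeat(conds: list[Condition], prev: Condition | None) -> bool:
    if prev is not None and conds and conds[0] == prev:
        return False
    return all(a != b for a, b in zip(conds, conds[1:]))


def _backtrack_order(
    items: list[tuple[Condition, str, float]],
    prev: Condition | None,
    rng: np.random.Generator,
) -> list[tuple[Condition, str, float]] | None:
    """Randomized depth-first search for a no-adjacent-repeat ordering.

    Most-constrained-first: always place an item from the condition with the
    most remaining trials (ties broken at random), which for this balanced
    7-per-condition multiset always succeeds.
    """
    remaining: dict[Condition, list[tuple[Condition, str, float]]] = {}
    for it in items:
        remaining.setdefault(it[0], []).append(it)
    for lst in remaining.values():
        rng.shuffle(lst)  # type: ignore[arg-type]
    out: list[tuple[Condition, str, float]] = []

    def step(last: Condition | None) -> bool:
        if all(not lst for lst in remaining.values()):
            return True
        counts = sorted(
            ((len(lst), rng.random(), c) for c, lst in remaining.items() if lst),
            reverse=True,
        )
        for _, _, cond in counts:
            if cond == last:
                continue
            out.append(remaining[cond].pop())
            if step(cond):
                return True
            remaining[cond].append(out.pop())
        return False

    return out if step(prev) else None


def build_experiment_schedule(
    exemplars: dict[Condition, tuple[str, str]] | None = None,
    n_blocks: int = 8,
    seed: int = 0,
    cross_block_constraint: bool = False,
    max_retries: int = 10_000,
) -> Schedule:
    """Experimental-phase schedule: ``n_blocks`` blocks of all 28 cells.

    Each block contains every duration x condition combination exactly once,
    pseudo-randomized so that no two consecutive trials share a condition.
    The constraint is enforced within blocks; with
    ``cross_block_constraint=True`` it also spans block boundaries (for
    back-to-back presentation without breaks).  Primary strategy is
    shuffle-and-check with ``max_retries`` attempts per block, falling back to
    constructive backtracking; both are deterministic given ``seed``.
    """
    exemplars = DEFAULT_EXEMPLARS if exemplars is None else exemplars
    _check_exemplars(exemplars)
    if n_blocks < 1:
        raise DesignError("n_blocks must be >= 1")
    rng = substream(seed, "experiment")
    trials: list[TrialSpec] = []
    prev_cond: Condition | None = None
    for b in range(n_blocks):
        cells = _block_cells(exemplars, rng)
        anchor = prev_cond if cross_block_constraint else None
        ordered = None
        for _ in range(max_retries):
            perm = [cells[i] for i in rng.permutation(len(cells))]
            if _no_adjacent_repeat([c for c, _, _ in perm], anchor):
                ordered = perm
                break
        if ordered is None:
            ordered = _backtrack_order(cells, anchor, rng)
        if ordered is None:  # pragma: no cover - balanced design always solvable
            raise SchedulingError(
                f"could not order block {b} without adjacent repeats (seed={seed})"
            )
        itis = rng.uniform(*ITI_RANGE, size=len(ordered))
        trials.extend(
            TrialSpec("experimental", b, cond, ex, dur, float(iti))
            for (cond, ex, dur), iti in zip(ordered, itis)
        )
        prev_cond = trials[-1].condition
    return Schedule(trials, seed, phase="experimental")


def participant_block_order(
    n_blocks: int, participant_id: str | int, seed: int
) -> list[int]:
    """Per-participant block permutation (block order is randomized across
    participants); seeded jointly from the root seed and the participant id."""
    rng = substream(seed, f"block-order/{participant_id}")
    return [int(i) for i in rng.permutation(n_blocks)]


def reorder_blocks(schedule: Schedule, order: list[int]) -> Schedule:
    """Return a schedule whose blocks are presented in ``order``."""
    if sorted(order) != list(range(schedule.n_blocks)):
        raise DesignError("order must be a permutation of the block indices")
    by_block: dict[int, list[TrialSpec]] = {}
    for t in schedule.trials:
        by_block.setdefault(t.block_index, []).append(t)
    trials = [
        replace(t, block_index=new_b)
        for new_b, old_b in enumerate(order)
        for t in by_block[old_b]
    ]
    return Schedule(trials, schedule.seed, phase=schedule.phase)


def validate_schedule(schedule: Schedule) -> list[str]:
    """Check the schedule invariants; return human-readable violations.

    Empty list iff the schedule is valid.  Experimental blocks are checked
    for per-block completeness of the 7x4 grid and the no-adjacent-condition
    constraint; training schedules for the 8 exemplars x 2 references grid.
    """
    violations: list[str] = []
    if schedule.phase == "training":
        if len(schedule.trials) != TRAINING_N_TRIALS:
            violations.append(
                f"training schedule has {len(schedule.trials)} trials, expected 16"
            )
        seen = [(t.exemplar_id, t.duration) for t in schedule.trials]
        if len(set(seen)) != len(seen):
            violations.append("duplicate (exemplar, duration) training cell")
        bad = [
            i
            for i, t in enumerate(schedule.trials)
            if t.duration not in (SHORT_REF, LONG_REF)
        ]
        if bad:
            violations.append(f"non-reference durations at training trials {bad}")
        return violations

    expected = set(itertools.product(DURATIONS, ALL_CONDITIONS))
    by_block: dict[int, list[tuple[int, TrialSpec]]] = {}
    for i, t in enumerate(schedule.trials):
        by_block.setdefault(t.block_index, []).append((i, t))
    for b in sorted(by_block):
        block = by_block[b]
        got = [(t.duration, t.condition) for _, t in block]
        missing = expected - set(got)
        if len(got) != len(expected) or missing:
            desc = ", ".join(f"{d:.1f}s/{c.key}" for d, c in sorted(missing)[:4])
            violations.append(
                f"block {b} does not cover the 28 duration x condition cells "
                f"(has {len(got)} trials; missing e.g. {desc or 'none'})"
            )
        for (i1, t1), (i2, t2) in zip(block, block[1:]):
            if t1.condition == t2.condition:
                violations.append(
                    f"trials {i1} and {i2} (block {b}) share condition {t1.condition.key}"
                )
    for t in schedule.trials:
        if not (ITI_RANGE[0] <= t.iti <= ITI_RANGE[1]):
            violations.append(f"iti {t.iti} outside [1, 3] s")
            break
    return violations
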