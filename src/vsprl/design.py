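"""Constrained pseudorandom trial sequences for the reciprocal evaluation task.

The task presents 75 trials: every combination of 3 feedback valences
(negative / neutral / positive) and 5 objective-creativity (OC) levels
appears exactly ``n_per_cell`` (default 5) times.  Two ordering constraints
are enforced during generation:

* no more than ``max_run_length`` consecutive trials share the same
  (valence, oc_level) condition, and
* the running sum of valence codes (-1/0/+1) never leaves
  ``[-accfb_bound, +accfb_bound]`` — this keeps the accumulated-feedback
  regressor inside its nominal [-1, 1] range after rescaling.

Neutral trials are split into two cover-story subtypes ("not yet evaluated"
vs "no response", 20/5 with defaults); the split has no analytic role.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field

import numpy as np

VALENCES = ("negative", "neutral", "positive")
VALENCE_CODE = {"negative": -1, "neutral": 0, "positive": 1}

NEUTRAL_SUBTYPES = ("not_yet_evaluated", "no_response")


class InfeasibleDesignError(RuntimeError):
    """No valid trial sequence was found within the restart budget."""


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of the trial-sequence generator.

    With the defaults the design reproduces the published task structure:
    75 trials, 25 per valence, 5 per valence x OC cell, runs of at most 2,
    running feedback sum bounded by +/-3.
    """

    n_per_cell: int = 5
    valences: tuple[str, ...] = VALENCES
    oc_levels: tuple[int, ...] = (1, 2, 3, 4, 5)
    max_run_length: int = 2
    accfb_bound: int = 3
    seed: int = 0
    n_neutral_no_response: int = 5
    restart_budget: int = 10_000
    # Optional explicit sequence of (valence, oc_level) pairs overriding
    # random construction, for loading a published fixed order.
    fixed_sequence: tuple[tuple[str, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        if self.max_run_length < 1:
            raise ValueError("max_run_length must be >= 1")
        if self.accfb_bound < 1:
            raise ValueError("accfb_bound must be >= 1")
        unknown = set(self.valences) - set(VALENCES)
        if unknown:
            raise ValueError(f"unknown valences: {sorted(unknown)}")

    @property
    def n_trials(self) -> int:
        return self.n_per_cell * len(self.valences) * len(self.oc_levels)


@dataclass(frozen=True)
class Trial:
    trial: int  # 1-based
    valence: str
    oc_level: int
    neutral_subtype: str = "none"


@dataclass
class TaskDesign:
    """An ordered 75-trial (by default) condition sequence."""

    trials: list[Trial] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def valences(self) -> list[str]:
        return [t.valence for t in self.trials]

    @property
    def oc_levels(self) -> list[int]:
        return [t.oc_level for t in self.trials]

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["trial", "valence", "oc_level", "neutral_subtype"])
            for t in self.trials:
                w.writerow([t.trial, t.valence, t.oc_level, t.neutral_subtype])

    @classmethod
    def from_csv(cls, path) -> "TaskDesign":
        trials = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                trials.append(
                    Trial(
                        trial=int(row["trial"]),
                        valence=row["valence"],
                        oc_level=int(row["oc_level"]),
                        neutral_subtype=row.get("neutral_subtype", "none"),
                    )
                )
        return cls(trials=trials)


def _attempt_sequence(
    cells: list[tuple[str, int]],
    counts: dict[tuple[str, int], int],
    spec: DesignSpec,
    rng: np.random.Generator,
) -> list[tuple[str, int]] | None:
    """One randomized greedy construction pass; None on dead end."""
    n_total = sum(counts.values())
    counts = dict(counts)
    seq: list[tuple[str, int]] = []
    running = 0
    for _ in range(n_total):
        candidates = []
        for cell in cells:
            if counts[cell] == 0:
                continue
            # run-length constraint on the full (valence, oc) condition
            run = 0
            for prev in reversed(seq):
                if prev == cell:
                    run += 1
                else:
                    break
            if run >= spec.max_run_length:
                continue
            code = VALENCE_CODE[cell[0]]
            if abs(running + code) > spec.accfb_bound:
                continue
            candidates.append(cell)
        if not candidates:
            return None
        pick = candidates[rng.integers(len(candidates))]
        counts[pick] -= 1
        running += VALENCE_CODE[pick[0]]
        seq.append(pick)
    return seq


def generate_design(spec: DesignSpec | None = None) -> TaskDesign:
    """Generate a task design satisfying all ordering constraints.

    Uses randomized sequential construction with restarts; deterministic for
    a fixed ``spec.seed``.  Raises :class:`InfeasibleDesignError` if no valid
    sequence is found within ``spec.restart_budget`` restarts.
    """
    if spec is None:
        spec = DesignSpec()
    rng = np.random.default_rng(spec.seed)

    if spec.fixed_sequence is not None:
        seq = list(spec.fixed_sequence)
    else:
        cells = list(itertools.product(spec.valences, spec.oc_levels))
        counts = {cell: spec.n_per_cell for cell in cells}
        seq = None
        for _ in range(spec.restart_budget):
            seq = _attempt_sequence(cells, counts, spec, rng)
            if seq is not None:
                break
        if seq is None:
            raise InfeasibleDesignError(
                f"no valid sequence found in {spec.restart_budget} restarts; "
                "the spec constraints may be contradictory"
            )

    # assign cover-story subtypes among neutral trials, at random
    neutral_idx = [i for i, (v, _) in enumerate(seq) if v == "neutral"]
    n_nr = min(spec.n_neutral_no_response, len(neutral_idx))
    no_resp = set(
        rng.choice(neutral_idx, size=n_nr, replace=False).tolist()
    ) if neutral_idx else set()

    trials = []
    for i, (valence, oc) in enumerate(seq):
        if valence == "neutral":
            subtype = "no_response" if i in no_resp else "not_yet_evaluated"
        else:
            subtype = "none"
        trials.append(Trial(trial=i + 1, valence=valence, oc_level=oc, neutral_subtype=subtype))
    design = TaskDesign(trials=trials)

    violations = validate_design(design, spec)
    if violations:
        raise InfeasibleDesignError(
            "generated design violates constraints: " + "; ".join(violations)
        )
    return design


def validate_design(design: TaskDesign, spec: DesignSpec | None = None) -> list[str]:
    """Check a design against the spec invariants.

    Returns a list of human-readable violation descriptions (empty if the
    design is valid).  Never raises.
    """
    if spec is None:
        spec = DesignSpec()
    violations: list[str] = []

    # cell counts
    counts: dict[tuple[str, int], int] = {}
    for t in design.trials:
        counts[(t.valence, t.oc_level)] = counts.get((t.valence, t.oc_level), 0) + 1
    for cell in itertools.product(spec.valences, spec.oc_levels):
        got = counts.pop(cell, 0)
        if got != spec.n_per_cell:
            violations.append(
                f"cell {cell}: expected {spec.n_per_cell} trials, found {got}"
            )
    for cell, got in counts.items():
        violations.append(f"unexpected cell {cell} with {got} trials")

    # run length on the (valence, oc_level) condition
    run = 0
    prev = None
    for t in design.trials:
        cond = (t.valence, t.oc_level)
        run = run + 1 if cond == prev else 1
        prev = cond
        if run == spec.max_run_length + 1:
            violations.append(
                f"trial {t.trial}: more than {spec.max_run_length} consecutive "
                f"trials of condition {cond}"
            )

    # running valence-sum bound
    running = 0
    for t in design.trials:
        code = VALENCE_CODE.get(t.valence)
        if code is None:
            violations.append(f"trial {t.trial}: unknown valence {t.valence!r}")
            continue
        running += code
        if abs(running) > spec.accfb_bound:
            violations.append(
                f"trial {t.trial}: running feedback sum {running} exceeds "
                f"bound +/-{spec.accfb_bound}"
            )

    # neutral subtype split
    n_nr = sum(1 for t in design.trials if t.neutral_subtype == "no_response")
    n_neutral = sum(1 for t in design.trials if t.valence == "neutral")
    expected_nr = min(spec.n_neutral_no_response, n_neutral)
    if n_nr != expected_nr:
        violations.append(
            f"neutral subtype split: expected {expected_nr} no_response trials, found {n_nr}"
        )
    for t in design.trials:
        if t.valence != "neutral" and t.neutral_subtype != "none":
            violations.append(
                f"trial {t.trial}: non-neutral trial has subtype {t.neutral_subtype!r}"
            )

    return violations
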