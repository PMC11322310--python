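"""Choice problems for risky choice between a safe and a risky option.

A choice problem pairs two options, each a small lottery over non-negative
monetary outcomes. In the experimental design this package targets, the safe
option pays one outcome for sure and the risky option pays one non-zero
outcome with probability ``p`` (zero otherwise). Problems are classified by
which option offers the higher expected value (EV): ``risky.better`` or
``safe.better``. Problems where both EVs tie, or where both options are safe,
carry no decision-quality signal and are excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Option",
    "ChoiceProblem",
    "ProblemType",
    "InvalidOptionError",
    "expected_value",
    "classify_problem",
    "filter_problems",
    "problems_to_frame",
    "problems_from_frame",
    "read_problems_csv",
    "write_problems_csv",
]

EV_TOL = 1e-9
"""Absolute tolerance for EV ties; outcomes are integers or simple fractions,
so exact ties are intended ties."""


class InvalidOptionError(ValueError):
    """Raised when an option's outcome probabilities are inconsistent."""


class ProblemType:
    """Problem-type labels determined by option structure and EVs."""

    RISKY_BETTER = "risky.better"
    SAFE_BETTER = "safe.better"
    EQUAL_EV = "equal.ev"
    TRIVIAL_SAFE_SAFE = "trivial.safe.safe"

    ALL = (RISKY_BETTER, SAFE_BETTER, EQUAL_EV, TRIVIAL_SAFE_SAFE)


@dataclass(frozen=True)
class Option:
    """A lottery: list of (outcome, probability) pairs.

    Probabilities must sum to 1 (within ``EV_TOL``). A *safe* option has a
    single outcome with probability 1.
    """

    outcomes: tuple[tuple[float, float], ...]

    def __init__(self, outcomes: Iterable[tuple[float, float]]):
        object.__setattr__(self, "outcomes", tuple((float(x), float(p)) for x, p in outcomes))
        self._validate()

    def _validate(self) -> None:
        if not self.outcomes:
            raise InvalidOptionError("option needs at least one outcome")
        if len(self.outcomes) > 2:
            raise InvalidOptionError("at most 2 outcomes supported in this design")
        total = sum(p for _, p in self.outcomes)
        if abs(total - 1.0) > EV_TOL:
            raise InvalidOptionError(f"outcome probabilities sum to {total}, not 1")
        if any(p < 0 for _, p in self.outcomes):
            raise InvalidOptionError("negative probability")
        if any(x < 0 for x, _ in self.outcomes):
            raise InvalidOptionError("negative outcome not supported")

    @property
    def is_safe(self) -> bool:
        return len(self.outcomes) == 1 and abs(self.outcomes[0][1] - 1.0) <= EV_TOL

    @staticmethod
    def safe(outcome: float) -> "Option":
        return Option([(outcome, 1.0)])

    @staticmethod
    def risky(outcome: float, probability: float) -> "Option":
        """Risky option paying ``outcome`` with ``probability``, else 0."""
        return Option([(outcome, probability), (0.0, 1.0 - probability)])


def expected_value(option: Option) -> float:
    """Probability-weighted sum of an option's outcomes."""
    return float(sum(p * x for x, p in option.outcomes))


@dataclass(frozen=True)
class ChoiceProblem:
    """Two options plus layout metadata (layout never affects analysis)."""

    id: str
    option_a: Option
    option_b: Option
    layout: dict = field(default_factory=dict, compare=False)

    @property
    def ev_a(self) -> float:
        return expected_value(self.option_a)

    @property
    def ev_b(self) -> float:
        return expected_value(self.option_b)

    def higher_ev_option(self) -> str:
        """Label ('option_a'/'option_b') of the higher-EV option.

        Raises on EV ties, where the measure is undefined.
        """
        ptype = classify_problem(self)
        if ptype == ProblemType.EQUAL_EV:
            raise ValueError(f"problem {self.id}: EVs tie, no higher-EV option")
        return "option_a" if self.ev_a > self.ev_b else "option_b"


def classify_problem(problem: ChoiceProblem) -> str:
    """Classify by option structure and EVs.

    ``trivial.safe.safe`` if both options are safe; otherwise ``equal.ev`` on
    an EV tie, else ``risky.better`` / ``safe.better`` according to whether
    the risky or the safe option has the higher EV. For two risky options
    (not part of this design) the labels reduce to which EV is higher with
    option order ignored; such problems are labelled by the larger EV's
    option being treated as 'risky' only if exactly one option is safe.
    """
    a, b = problem.option_a, problem.option_b
    if a.is_safe and b.is_safe:
        return ProblemType.TRIVIAL_SAFE_SAFE
    ev_a, ev_b = expected_value(a), expected_value(b)
    if abs(ev_a - ev_b) <= EV_TOL:
        return ProblemType.EQUAL_EV
    # orient by safe vs risky role, not by a/b position
    if a.is_safe:
        safe_ev, risky_ev = ev_a, ev_b
    elif b.is_safe:
        safe_ev, risky_ev = ev_b, ev_a
    else:
        # two risky options: fall back to magnitude ordering with option_a in
        # the 'risky' role; not produced by the generator
        safe_ev, risky_ev = ev_b, ev_a
    return ProblemType.RISKY_BETTER if risky_ev > safe_ev else ProblemType.SAFE_BETTER


def filter_problems(
    problems: Sequence[ChoiceProblem],
) -> tuple[list[ChoiceProblem], pd.DataFrame]:
    """Drop equal-EV and safe-safe problems, preserving order.

    Returns (kept, exclusion_log); the log has one row per excluded problem
    with columns ``problem_id`` and ``reason``.
    """
    kept: list[ChoiceProblem] = []
    log_rows: list[dict] = []
    for p in problems:
        ptype = classify_problem(p)
        if ptype in (ProblemType.EQUAL_EV, ProblemType.TRIVIAL_SAFE_SAFE):
            log_rows.append({"problem_id": p.id, "reason": ptype})
        else:
            kept.append(p)
    log = pd.DataFrame(log_rows, columns=["problem_id", "reason"])
    return kept, log


# ---------------------------------------------------------------------------
# I/O: flat CSV for the safe-vs-risky design, one row per problem.

_CSV_COLS = ["problem_id", "safe_outcome", "risky_outcome", "risky_probability"]


def problems_to_frame(problems: Sequence[ChoiceProblem]) -> pd.DataFrame:
    rows = []
    for p in problems:
        if p.option_a.is_safe and not p.option_b.is_safe:
            safe, risky = p.option_a, p.option_b
        elif p.option_b.is_safe and not p.option_a.is_safe:
            safe, risky = p.option_b, p.option_a
        else:
            raise ValueError(
                f"problem {p.id}: CSV dialect needs exactly one safe and one "
                "risky option; use JSON round-trip for general problems"
            )
        nonzero = max(risky.outcomes, key=lambda xp: xp[0])
        row = {
            "problem_id": p.id,
            "safe_outcome": safe.outcomes[0][0],
            "risky_outcome": nonzero[0],
            "risky_probability": nonzero[1],
        }
        row.update({f"layout_{k}": v for k, v in p.layout.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def problems_from_frame(frame: pd.DataFrame) -> list[ChoiceProblem]:
    problems = []
    layout_cols = [c for c in frame.columns if c.startswith("layout_")]
    for _, row in frame.iterrows():
        layout = {c[len("layout_"):]: row[c] for c in layout_cols}
        problems.append(
            ChoiceProblem(
                id=str(row["problem_id"]),
                option_a=Option.safe(row["safe_outcome"]),
                option_b=Option.risky(row["risky_outcome"], row["risky_probability"]),
                layout=layout,
            )
        )
    return problems


def write_problems_csv(problems: Sequence[ChoiceProblem], path) -> None:
    problems_to_frame(problems).to_csv(path, index=False)


def read_problems_csv(path) -> list[ChoiceProblem]:
    return problems_from_frame(pd.read_csv(path))
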