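"""Paired evaluation: scoring, confabulation rate, exact Cochran Q.

Each exam question is answered under k >= 2 matched conditions (here
typically native vs retrieval-augmented), giving a complete blocks x
conditions binary outcome table (1 = correct). Because question
difficulty varies, condition effects are tested with the Cochran Q
statistic over question blocks; at k = 2 this is McNemar's statistic
(b - c)^2 / (b + c) over the discordant blocks. Significance comes from
the exact conditional permutation distribution: outcomes are permuted
within each block, enumerated in full when feasible and sampled by
seeded Monte Carlo otherwise.

Confabulation is the error metric for generative answerers: a *wrong
nonnull* answer. A model that stays silent on a question it cannot
answer does not confabulate; one that asserts a wrong letter does.
Silent answers score as incorrect throughout.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .backend import AnswerRecord

__all__ = [
    "PairedOutcomeTable",
    "ConditionStats",
    "EvalReport",
    "score_responses",
    "confabulation_rate",
    "cochran_q",
    "exact_p_value",
    "compare_conditions",
    "discordant_table",
    "percent",
]

_ENUMERATION_LIMIT = 200_000  # max within-block assignments for full enumeration


def percent(count: int, n: int) -> float:
    """count / n as a percentage, one decimal, half-up (table typography)."""
    if n <= 0:
        raise ValueError("cannot compute a percentage of zero records")
    return float(
        (Decimal(count) / Decimal(n) * 100).quantize(Decimal("0.1"), ROUND_HALF_UP)
    )


@dataclass
class PairedOutcomeTable:
    """Complete blocks x conditions binary outcome matrix.

    ``outcomes[i, j]`` is 1 when block (question) ``blocks[i]`` was
    answered correctly under ``conditions[j]``.
    """

    blocks: list[str]
    conditions: list[str]
    outcomes: np.ndarray

    def __post_init__(self) -> None:
        self.outcomes = np.asarray(self.outcomes, dtype=int)
        if len(self.conditions) < 2:
            raise ValueError("need k >= 2 conditions")
        if self.outcomes.shape != (len(self.blocks), len(self.conditions)):
            raise ValueError(
                f"outcome matrix shape {self.outcomes.shape} does not match "
                f"{len(self.blocks)} blocks x {len(self.conditions)} conditions"
            )
        if not np.isin(self.outcomes, (0, 1)).all():
            raise ValueError("outcomes must be binary (0/1)")

    @property
    def k(self) -> int:
        return len(self.conditions)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def discordant_counts(self) -> tuple[int, int]:
        """(b, c) for k = 2: blocks correct only under condition 2 / only 1."""
        if self.k != 2:
            raise ValueError("discordant counts are defined for k = 2 only")
        b = int(np.sum((self.outcomes[:, 1] == 1) & (self.outcomes[:, 0] == 0)))
        c = int(np.sum((self.outcomes[:, 0] == 1) & (self.outcomes[:, 1] == 0)))
        return b, c


def discordant_table(
    n_blocks: int, correct_first: int, only_second: int, only_first: int,
    conditions: Sequence[str] = ("native", "rag"),
) -> PairedOutcomeTable:
    """Build a two-condition table from its marginal + discordant counts.

    ``correct_first`` blocks are correct under the first condition, of
    which ``only_first`` fail under the second; ``only_second`` blocks are
    correct under the second condition only. Used to reconstruct outcome
    tables that published reports summarize by marginals alone.
    """
    both = correct_first - only_first
    neither = n_blocks - both - only_first - only_second
    if min(both, neither, only_first, only_second) < 0:
        raise ValueError("infeasible marginal/discordant combination")
    rows = (
        [(1, 1)] * both + [(1, 0)] * only_first + [(0, 1)] * only_second + [(0, 0)] * neither
    )
    return PairedOutcomeTable(
        blocks=[f"q{i:04d}" for i in range(n_blocks)],
        conditions=list(conditions),
        outcomes=np.array(rows),
    )


def score_responses(
    records: Sequence[AnswerRecord], key: Mapping[str, str]
) -> list[AnswerRecord]:
    """Mark each record correct iff its parsed letter equals the keyed letter.

    Null (silent) letters are incorrect. Unknown question ids are a
    validation error.
    """
    unknown = sorted({r.question_id for r in records} - set(key))
    if unknown:
        raise ValueError(f"records reference question ids not in key: {unknown}")
    scored = []
    for r in records:
        scored.append(
            AnswerRecord(
                r.question_id, r.condition, r.raw_response, r.letter,
                correct=(r.letter == key[r.question_id]), error=r.error,
            )
        )
    return scored


def confabulation_rate(records: Sequence[AnswerRecord]) -> tuple[int, float]:
    """Count and percent of wrong *nonnull* answers among all records."""
    if not records:
        raise ValueError("confabulation rate undefined for zero records")
    if any(r.correct is None for r in records):
        raise ValueError("records must be scored before computing confabulation")
    count = sum(1 for r in records if not r.correct and r.letter is not None)
    return count, percent(count, len(records))


def cochran_q(table: PairedOutcomeTable) -> float:
    """Cochran's Q over k matched binary conditions with question blocks.

    Q = (k-1) * [k * sum G_j^2 - (sum G_j)^2] / (k * sum L_i - sum L_i^2)
    with column totals G_j and block totals L_i. Blocks answered equally
    under every condition contribute nothing. For k = 2 this reduces to
    McNemar's (b-c)^2/(b+c). All-concordant tables give Q = 0 by
    convention (and p = 1).
    """
    x = table.outcomes
    k = table.k
    G = x.sum(axis=0)
    L = x.sum(axis=1)
    denom = k * L.sum() - int((L**2).sum())
    if denom == 0:
        return 0.0
    num = (k - 1) * (k * int((G**2).sum()) - int(G.sum()) ** 2)
    return num / denom


def _exact_p(
    table: PairedOutcomeTable, n_permutations: int, seed: int,
    method: str = "auto",
) -> tuple[float, str]:
    """Conditional within-block permutation p-value for Cochran's Q.

    Returns (p, method) with method "enumeration" or "monte-carlo". The
    p-value is the proportion of within-block outcome assignments whose Q
    is >= the observed Q (the observed assignment included). ``method``
    forces a strategy; "auto" enumerates whenever feasible.
    """
    if method not in ("auto", "enumeration", "monte-carlo"):
        raise ValueError(f"unknown p-value method {method!r}")
    q_obs = cochran_q(table)
    if q_obs == 0.0:
        return 1.0, "enumeration"
    x = table.outcomes
    k = table.k

    if k == 2 and method != "monte-carlo":
        # Only discordant blocks vary under permutation; each flips
        # independently with probability 1/2, so Q' = (2X - d)^2 / d with
        # X ~ Binomial(d, 1/2). Exact integer tail sums.
        b, c = table.discordant_counts()
        d = b + c
        if d == 0:
            return 1.0, "enumeration"
        diff2 = (b - c) ** 2
        favorable = sum(
            math.comb(d, x_) for x_ in range(d + 1) if (2 * x_ - d) ** 2 >= diff2
        )
        return float(Fraction(favorable, 2**d)), "enumeration"

    # k > 2: permute each non-constant block's row. Constant rows are
    # invariant, so only the others enter the assignment count.
    variable = [i for i in range(x.shape[0]) if 0 < x[i].sum() < k]
    L = x.sum(axis=1)
    denom = k * int(L.sum()) - int((L**2).sum())
    base_G = x[[i for i in range(x.shape[0]) if i not in variable]].sum(axis=0)
    rows = [x[i] for i in variable]

    def q_from_G(G: np.ndarray) -> float:
        num = (k - 1) * (k * int((G**2).sum()) - int(G.sum()) ** 2)
        return num / denom

    perms_per_row = [
        np.unique(list(itertools.permutations(row)), axis=0) for row in rows
    ]
    total_assignments = 1.0
    for p_ in perms_per_row:
        total_assignments *= len(p_)
        if total_assignments > _ENUMERATION_LIMIT:
            break
    if method == "enumeration" and total_assignments > _ENUMERATION_LIMIT:
        raise ValueError("table too large for full enumeration")
    if method != "monte-carlo" and total_assignments <= _ENUMERATION_LIMIT:
        count = 0
        total = 0
        for combo in itertools.product(*perms_per_row):
            G = base_G + (np.sum(combo, axis=0) if combo else 0)
            total += 1
            if q_from_G(G) >= q_obs - 1e-12:
                count += 1
        return count / total, "enumeration"

    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100 for Monte-Carlo estimation")
    rng = np.random.default_rng(seed)
    count = 0
    row_mat = np.stack(rows)
    for _ in range(n_permutations):
        G = base_G.astype(int).copy()
        for row in row_mat:
            G += row[rng.permutation(k)]
        if q_from_G(G) >= q_obs - 1e-12:
            count += 1
    # observed assignment included per the exact-test convention
    return (count + 1) / (n_permutations + 1), "monte-carlo"


def exact_p_value(
    table: PairedOutcomeTable, n_permutations: int = 100_000, seed: int = 0,
    method: str = "auto",
) -> float:
    """Two-sided exact Cochran Q p-value by within-block permutation.

    Full enumeration whenever feasible (always at k = 2, where the
    permutation distribution collapses to binomial tail sums over the
    discordant blocks and equals the exact two-sided McNemar p); seeded
    Monte-Carlo with ``n_permutations`` draws otherwise. ``method`` can
    force "enumeration" or "monte-carlo".
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    p, _ = _exact_p(table, n_permutations, seed, method)
    return p


@dataclass
class ConditionStats:
    """Per-condition score summary; correct + confabulation + silent = n."""

    condition: str
    n: int
    correct: int
    correct_pct: float
    confabulation: int
    confabulation_pct: float
    silent: int

    def __post_init__(self) -> None:
        if self.correct + self.confabulation + self.silent != self.n:
            raise ValueError("correct + confabulation + silent must equal n")


@dataclass
class EvalReport:
    """Condition comparison: per-condition stats plus the exact Q test."""

    conditions: list[ConditionStats]
    q_statistic: float
    p_value: float
    method: str
    n_permutations: int
    seed: int
    table: Optional[PairedOutcomeTable] = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "conditions": [
                {
                    "condition": c.condition,
                    "n": c.n,
                    "correct": c.correct,
                    "correct_pct": c.correct_pct,
                    "confabulation": c.confabulation,
                    "confabulation_pct": c.confabulation_pct,
                    "silent": c.silent,
                }
                for c in self.conditions
            ],
            "q_statistic": self.q_statistic,
            "p_value": self.p_value,
            "method": self.method,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def to_text(self) -> str:
        """Plain-text summary table: correct n (%), confabulation n (%), Q, p."""
        lines = [
            f"{'condition':<10} {'correct, n (%)':>18} {'confabulation, n (%)':>22} {'silent':>7}"
        ]
        for c in self.conditions:
            lines.append(
                f"{c.condition:<10} {f'{c.correct} ({c.correct_pct}%)':>18} "
                f"{f'{c.confabulation} ({c.confabulation_pct}%)':>22} {c.silent:>7}"
            )
        p = f"{self.p_value:.3f}" if self.p_value >= 0.001 else "<.001"
        lines.append(f"Cochran Q = {self.q_statistic:.2f}, exact p = {p} ({self.method})")
        return "\n".join(lines)


def _condition_stats(records: Sequence[AnswerRecord], label: str) -> ConditionStats:
    n = len(records)
    correct = sum(1 for r in records if r.correct)
    confab, confab_pct = confabulation_rate(records)
    silent = sum(1 for r in records if r.letter is None)
    return ConditionStats(
        label, n, correct, percent(correct, n), confab, confab_pct, silent
    )


def compare_conditions(
    native_records: Sequence[AnswerRecord],
    rag_records: Sequence[AnswerRecord],
    key: Mapping[str, str],
    n_permutations: int = 100_000,
    seed: int = 0,
) -> EvalReport:
    """Score both record sets against the key and run the paired Q test.

    The two record sets must cover the same question ids (each exactly
    once); a mismatch raises with the differing ids listed.
    """
    native_ids = {r.question_id for r in native_records}
    rag_ids = {r.question_id for r in rag_records}
    if native_ids != rag_ids or len(native_records) != len(native_ids) or len(
        rag_records
    ) != len(rag_ids):
        diff = sorted(native_ids ^ rag_ids)
        raise ValueError(f"condition record sets differ on question ids: {diff}")
    native = score_responses(native_records, key)
    rag = score_responses(rag_records, key)
    by_id_native = {r.question_id: r for r in native}
    by_id_rag = {r.question_id: r for r in rag}
    blocks = sorted(native_ids)
    outcomes = np.array(
        [
            [int(bool(by_id_native[q].correct)), int(bool(by_id_rag[q].correct))]
            for q in blocks
        ]
    )
    table = PairedOutcomeTable(blocks, ["native", "rag"], outcomes)
    q = cochran_q(table)
    p, method = _exact_p(table, n_permutations, seed)
    return EvalReport(
        conditions=[
            _condition_stats(native, "native"),
            _condition_stats(rag, "rag"),
        ],
        q_statistic=q,
        p_value=p,
        method=method,
        n_permutations=n_permutations,
        seed=seed,
        table=table,
    )
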