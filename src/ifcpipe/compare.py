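"""Exact paired binomial comparison of classifier outcome vectors.

Two feature families classified on the same subjects are compared through
their discordant pairs: subjects correct under one family and wrong under
the other. Under the null of equal performance the number W of wins of
the first family among the N discordant subjects is Binomial(N, 1/2); the
exact tail probability is the p-value (a paired sign test, the exact form
of McNemar's test).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .classify import OutcomeVector


@dataclass
class ComparisonStat:
    """Result of one pairwise exact binomial test."""

    family_a: str
    family_b: str
    W: int  # subjects correct under a, wrong under b
    N: int  # discordant subjects
    p_value: float
    sidedness: str  # "one-sided" or "two-sided"

    def __post_init__(self):
        if not (0 <= self.W <= self.N):
            raise ValueError("need 0 <= W <= N")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value must lie in (0, 1]")


def binomial_tail(W: int, N: int) -> float:
    """P(Bin(N, 1/2) >= W), exactly from binomial coefficients.

    The numerator is an integer and the denominator a power of two, so
    the float result is exact for any N a test will ever see.
    """
    if N == 0:
        return 1.0
    num = sum(comb(N, k) for k in range(W, N + 1))
    return num / (1 << N)


def paired_binomial(
    a: OutcomeVector, b: OutcomeVector, sidedness: str = "one-sided"
) -> ComparisonStat:
    """Exact test of family a against family b on paired outcomes.

    W counts subjects with ``a_i = 1, b_i = 0``; N counts all subjects
    where the two families disagree. One-sided:
    ``p = P(Bin(N, 1/2) >= W)``. Two-sided: twice the smaller tail,
    capped at 1. ``N = 0`` (identical outcomes) returns p = 1 by
    convention -- no discordance is no evidence.
    """
    if a.subject_ids != b.subject_ids:
        raise ValueError("outcome vectors cover different subjects (or orders)")
    xa, xb = a.correct, b.correct
    W = int(np.sum((xa == 1) & (xb == 0)))
    N = int(np.sum(xa != xb))
    if sidedness == "one-sided":
        p = binomial_tail(W, N)
    elif sidedness == "two-sided":
        p = min(1.0, 2.0 * min(binomial_tail(W, N), 1.0 - binomial_tail(W + 1, N)))
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    return ComparisonStat(
        family_a=a.family, family_b=b.family, W=W, N=N, p_value=p, sidedness=sidedness
    )


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def compare_all_families(
    outcomes: dict[str, OutcomeVector],
    sidedness: str = "one-sided",
    correction: str | None = None,
) -> pd.DataFrame:
    """Upper-triangular table of pairwise exact tests.

    Each pair is oriented so that W counts wins of the family with the
    numerically higher accuracy (ties keep the given order), matching the
    one-sided question "is the better family significantly better?".
    ``correction="holm"`` appends a ``p_adjusted`` column; by default the
    raw exact p-values stand alone.
    """
    names = list(outcomes)
    subj0 = outcomes[names[0]].subject_ids
    for nm in names[1:]:
        if outcomes[nm].subject_ids != subj0:
            raise ValueError(f"family {nm!r} classified on a different subject set")
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = outcomes[names[i]], outcomes[names[j]]
            if b.correct.mean() > a.correct.mean():
                a, b = b, a
            st = paired_binomial(a, b, sidedness)
            rows.append(
                {
                    "better_family": st.family_a,
                    "other_family": st.family_b,
                    "W": st.W,
                    "N": st.N,
                    "p_value": st.p_value,
                    "sidedness": st.sidedness,
                }
            )
    table = pd.DataFrame(rows)
    if correction == "holm" and len(table):
        table["p_adjusted"] = holm_adjust(table["p_value"].to_numpy())
    elif correction not in (None, "holm"):
        raise ValueError(f"unknown correction {correction!r}")
    return table


def comparison_report(table: pd.DataFrame, families: list[str]) -> str:
    """Markdown matrix of p-values for a subset of families (table layout:
    upper triangle, rows/columns in the given family order)."""
    lookup = {}
    for _, r in table.iterrows():
        key = frozenset((r["better_family"], r["other_family"]))
        lookup[key] = r["p_value"]
    lines = ["| | " + " | ".join(families[1:]) + " |",
             "|---" * len(families) + "|"]
    for i, fa in enumerate(families[:-1]):
        cells = []
        for fb in families[1:]:
            if families.index(fb) <= i:
                cells.append("")
            else:
                p = lookup.get(frozenset((fa, fb)))
                cells.append(f"{p:.4f}" if p is not None else "-")
        lines.append("| " + fa + " | " + " | ".join(cells) + " |")
    return "\n".join(lines)
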