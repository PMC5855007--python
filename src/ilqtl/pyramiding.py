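"""QTL validation by flanking-marker interval genotypes, pyramiding-group
enumeration, background recovery, and multiple-range group comparison.

A target QTL is scored in a segregating population through the *interval
genotype*: the shared call of the two flanking markers, with recombinant or
missing intervals excluded.  Validation splits the lines into the two
homozygous interval classes (AA = recurrent, BB = donor) and compares trait
means with Welch's t-test — Welch rather than the pooled-variance form
because homozygous classes in small F2 samples routinely show strongly
unequal spreads.  Pyramiding enumerates lines by their favorable-homozygote
signature over several targets, and group means across pyramids, parents and
checks are separated with Duncan's multiple range test plus a compact letter
display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    CODE_A,
    CODE_B,
    CODE_H,
    CODE_MISSING,
    Population,
    interval_genotype,
)

__all__ = [
    "QtlTarget",
    "PyramidGroup",
    "assign_interval_groups",
    "two_group_test",
    "percent_change",
    "enumerate_pyramids",
    "background_recovery",
    "multiple_range_groups",
]


@dataclass(frozen=True)
class QtlTarget:
    """A validated/target QTL with its flanking marker pair.

    ``favorable_code`` is the interval genotype carrying the favorable
    allele as a homozygote: ``CODE_B`` when the favorable allele comes from
    the donor, ``CODE_A`` when it comes from the recurrent parent.
    """

    name: str
    chrom: int
    left_marker: str
    right_marker: str
    favorable_founder: str
    favorable_code: int = CODE_B
    trait: str = "GY"
    environment: str = "drought"


@dataclass
class PyramidGroup:
    """Lines sharing one favorable-homozygote signature over the targets."""

    signature: tuple[str, ...]  # "+"/"-" per target, in target order
    line_ids: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.line_ids)


def _interval_calls(population: Population, target: QtlTarget) -> np.ndarray:
    left = population.markers.index_of(target.left_marker)
    right = population.markers.index_of(target.right_marker)
    gl = population.genotypes[:, left]
    gr = population.genotypes[:, right]
    out = np.full(population.n_lines, CODE_MISSING, dtype=np.int8)
    agree = (gl == gr) & (gl != CODE_MISSING)
    out[agree] = gl[agree]
    return out


def assign_interval_groups(
    population: Population, target: QtlTarget
) -> tuple[list[str], list[str], list[str]]:
    """Split lines into homozygous interval classes at one target QTL.

    Returns ``(AA_group, BB_group, excluded)`` line ids; heterozygous,
    recombinant (discordant flanking calls) and missing intervals are
    excluded.
    """
    calls = _interval_calls(population, target)
    ids = np.asarray(population.line_ids)
    aa = ids[calls == CODE_A].tolist()
    bb = ids[calls == CODE_B].tolist()
    excluded = ids[(calls != CODE_A) & (calls != CODE_B)].tolist()
    return aa, bb, excluded


def two_group_test(
    values_aa: np.ndarray, values_bb: np.ndarray
) -> tuple[float, float, float, float, float]:
    """Welch's unequal-variance t-test between the two homozygous classes.

    Returns ``(mean_AA, mean_BB, difference AA - BB, t, p)``.  The
    difference is reported recurrent-minus-donor, so a negative value means
    the donor homozygote outperforms.
    """
    a = np.asarray(values_aa, dtype=float)
    b = np.asarray(values_bb, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if a.var() == 0 and b.var() == 0:
        if mean_a == mean_b:
            return mean_a, mean_b, 0.0, 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return mean_a, mean_b, mean_a - mean_b, float(t), float(p)


def percent_change(reference_mean: float, other_mean: float) -> float:
    """Relative change of ``other`` vs ``reference`` in percent, one decimal."""
    if reference_mean == 0:
        raise ValueError("reference mean must be non-zero")
    return round(100.0 * (other_mean - reference_mean) / reference_mean, 1)


def enumerate_pyramids(
    population: Population, targets: list[QtlTarget]
) -> list[PyramidGroup]:
    """Partition lines by their favorable-homozygote signature over targets.

    A line is scorable when its interval genotype at *every* target is one
    of the two homozygous classes; scorable lines fall into exactly one
    group.  Lines heterozygous, recombinant or missing at any target are
    dropped.
    """
    if not targets:
        raise ValueError("at least one target QTL required")
    calls = np.stack([_interval_calls(population, t) for t in targets], axis=1)
    homozygous = np.isin(calls, (CODE_A, CODE_B)).all(axis=1)
    if not homozygous.any():
        raise ValueError("no line is scorable at all targets")
    groups: dict[tuple[str, ...], PyramidGroup] = {}
    fav = np.array([t.favorable_code for t in targets])
    for i in np.flatnonzero(homozygous):
        sig = tuple("+" if calls[i, j] == fav[j] else "-" for j in range(len(targets)))
        groups.setdefault(sig, PyramidGroup(signature=sig)).line_ids.append(
            population.line_ids[i]
        )
    # most-stacked groups first, then lexicographic for determinism
    return sorted(
        groups.values(), key=lambda g: (-g.signature.count("+"), g.signature)
    )


def background_recovery(calls: np.ndarray) -> float:
    """Fraction of the recurrent-parent genome recovered in one line.

    Marker-count based: ``(n_A + 0.5 n_H) / (n_A + n_H + n_B)`` with missing
    calls excluded.  Heterozygous markers count half because only one of the
    two alleles is recurrent.
    """
    calls = np.asarray(calls)
    n_a = int(np.sum(calls == CODE_A))
    n_h = int(np.sum(calls == CODE_H))
    n_b = int(np.sum(calls == CODE_B))
    total = n_a + n_h + n_b
    if total == 0:
        raise ValueError("all calls missing")
    return (n_a + 0.5 * n_h) / total


@lru_cache(maxsize=4096)
def _duncan_critical(p_span: int, df: int, alpha: float) -> float:
    """Duncan critical studentized range for a span of ``p_span`` means.

    Uses the stage-dependent protection level 1 - (1 - alpha)^(p - 1).
    """
    alpha_p = 1.0 - (1.0 - alpha) ** (p_span - 1)
    return float(stats.studentized_range.ppf(1.0 - alpha_p, p_span, df))


def multiple_range_groups(
    means: np.ndarray,
    ns: np.ndarray,
    mse: float,
    df_error: int,
    alpha: float = 0.05,
) -> list[str]:
    """Duncan's multiple range test with a compact letter display.

    Means are ranked and every span of ``p`` consecutive ranked means is
    compared against the Duncan critical range ``q(alpha_p, p, df) * SE``,
    where ``alpha_p = 1 - (1-alpha)^(p-1)`` and the standard error uses the
    harmonic mean of the two compared group sizes.  A span whose range does
    not exceed its critical value is declared homogeneous, and no pair
    inside it is tested further.  The letter display is built by
    insert-and-absorb; groups sharing a letter are not significantly
    different.  Returns one letter string per input group, in input order.
    """
    means = np.asarray(means, dtype=float)
    ns = np.asarray(ns, dtype=float)
    k = len(means)
    if k < 2:
        raise ValueError("need at least two groups")
    if mse <= 0:
        raise ValueError("error variance must be positive")
    if df_error < 1:
        raise ValueError("error degrees of freedom must be >= 1")

    order = np.argsort(-means, kind="mergesort")  # descending
    sorted_means = means[order]
    sorted_ns = ns[order]

    nonsig = np.zeros((k, k), dtype=bool)  # in sorted coordinates, i < j
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if nonsig[i, j]:
                continue
            n_h = 2.0 / (1.0 / sorted_ns[i] + 1.0 / sorted_ns[j])
            crit = _duncan_critical(span, df_error, alpha) * np.sqrt(mse / n_h)
            if sorted_means[i] - sorted_means[j] <= crit:
                for a in range(i, j + 1):
                    for b in range(a + 1, j + 1):
                        nonsig[a, b] = True

    # insert-and-absorb compact letter display
    columns: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if nonsig[i, j]:
                continue
            new_cols: list[set[int]] = []
            for col in columns:
                if i in col and j in col:
                    new_cols.extend((col - {i}, col - {j}))
                else:
                    new_cols.append(col)
            # absorb: drop empty columns, proper subsets and duplicates
            columns = []
            for c in new_cols:
                if not c or any(c < o for o in new_cols):
                    continue
                if c not in columns:
                    columns.append(c)
    # letters ordered by the best mean each column contains
    columns.sort(key=lambda col: min(col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters_sorted = ["" for _ in range(k)]
    for letter, col in zip(alphabet, columns):
        for g in col:
            letters_sorted[g] += letter
    out = ["" for _ in range(k)]
    for sorted_pos, original in enumerate(order):
        out[original] = letters_sorted[sorted_pos]
    return out


def validate_targets(
    population: Population,
    phenotypes: pd.DataFrame,
    targets: list[QtlTarget],
) -> pd.DataFrame:
    """Two-group validation of each target QTL (one row per target).

    For each target, lines are split by interval genotype and the target's
    trait is compared between the homozygous classes under the target's
    environment with Welch's t-test.  The table mirrors the usual
    validation layout: group sizes, means, SDs, AA-BB difference, t, p and
    the relative change of the donor class vs the recurrent class.
    """
    rows = []
    for t in targets:
        aa, bb, _ = assign_interval_groups(population, t)
        sub = phenotypes[phenotypes["environment"] == t.environment]
        means = sub.groupby("line_id")[t.trait].mean()
        va = means.reindex(aa).dropna().to_numpy()
        vb = means.reindex(bb).dropna().to_numpy()
        mean_a, mean_b, diff, tstat, p = two_group_test(va, vb)
        rows.append(
            {
                "qtl": t.name,
                "trait": t.trait,
                "environment": t.environment,
                "favorable_founder": t.favorable_founder,
                "n_AA": len(va),
                "mean_AA": mean_a,
                "sd_AA": float(np.std(va, ddof=1)),
                "n_BB": len(vb),
                "mean_BB": mean_b,
                "sd_BB": float(np.std(vb, ddof=1)),
                "diff_AA_minus_BB": diff,
                "t": tstat,
                "p_value": p,
                "percent_change_BB_vs_AA": percent_change(mean_a, mean_b),
            }
        )
    return pd.DataFrame(rows)
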