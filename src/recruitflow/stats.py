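"""Inferential battery: Kruskal-Wallis with Dunn post hoc and a compact
letter display, and sample-vs-census chi-square with Cohen's w.

The Dunn test is implemented here on pooled midranks with the standard tie
correction,

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)),

with T = sum over tie groups of (t^3 - t); p-values are two-sided normal and
adjusted for multiple comparisons (Holm by default).  Letters are assigned
with the insert-and-absorb algorithm: two groups share a letter exactly when
their adjusted p-value is above the significance level.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .types import CensusMarginals, InputError

__all__ = [
    "GroupedValues",
    "KruskalResult",
    "DunnResult",
    "ChiSquareResult",
    "kruskal_wallis",
    "dunn_posthoc",
    "census_comparison",
]


@dataclass
class GroupedValues:
    """Parallel arrays of values (e.g. questionnaires per participant) and
    group labels (e.g. city)."""

    values: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.values.shape != self.groups.shape:
            raise InputError("values and groups must have equal length")
        labels, counts = np.unique(self.groups, return_counts=True)
        if labels.size < 2:
            raise InputError("need at least 2 groups")
        if np.any(counts < 1):
            raise InputError("every group needs at least one observation")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, value: str, group: str) -> "GroupedValues":
        sub = df[[value, group]].dropna()
        return cls(values=sub[value].to_numpy(), groups=sub[group].to_numpy())

    def split(self) -> dict[str, np.ndarray]:
        return {
            str(lbl): self.values[self.groups == lbl]
            for lbl in np.unique(self.groups)
        }


@dataclass(frozen=True)
class KruskalResult:
    H: float
    df: int
    p: float


@dataclass
class DunnResult:
    pairwise: pd.DataFrame  # group1, group2, z, p_unadjusted, p_adjusted, significant
    letters: dict[str, str]
    mean_ranks: pd.Series
    adjust: str
    alpha: float


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    effect_size: float  # Cohen's w = sqrt(chi2 / n)
    n: int


def kruskal_wallis(data: GroupedValues) -> KruskalResult:
    """Kruskal-Wallis rank-sum test on midranks with tie correction;
    p-value from the chi-square approximation with df = groups - 1."""
    samples = list(data.split().values())
    if all(np.all(s == samples[0][0]) for s in samples):
        # all values identical: H = 0 by convention (scipy raises)
        return KruskalResult(H=0.0, df=len(samples) - 1, p=1.0)
    H, p = sps.kruskal(*samples)
    return KruskalResult(H=float(H), df=len(samples) - 1, p=float(p))


def _tie_term(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts**3 - counts))


def dunn_posthoc(
    data: GroupedValues, adjust: str = "holm", alpha: float = 0.05
) -> DunnResult:
    """Dunn's pairwise post hoc test with a compact letter display.

    ``adjust`` is any method statsmodels' ``multipletests`` understands
    (``holm``, ``bonferroni``, ``fdr_bh``, ...) or ``none``.  Two groups
    share a letter iff their adjusted p-value is >= ``alpha``; group order
    for letter assignment is by mean rank, ties broken lexicographically by
    label, so the display is deterministic.
    """
    values, groups = data.values, data.groups
    N = values.size
    ranks = sps.rankdata(values)
    labels = sorted(np.unique(groups).astype(str))
    mean_ranks = pd.Series(
        {lbl: float(ranks[groups.astype(str) == lbl].mean()) for lbl in labels}
    )
    n_per = {lbl: int(np.sum(groups.astype(str) == lbl)) for lbl in labels}
    var_term = N * (N + 1) / 12.0 - _tie_term(values) / (12.0 * (N - 1))

    pairs = list(combinations(labels, 2))
    z = np.empty(len(pairs))
    for k, (g1, g2) in enumerate(pairs):
        se = np.sqrt(var_term * (1.0 / n_per[g1] + 1.0 / n_per[g2]))
        z[k] = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
    p_raw = 2.0 * sps.norm.sf(np.abs(z))
    if adjust == "none":
        p_adj = p_raw.copy()
    else:
        p_adj = multipletests(p_raw, method=adjust)[1]
    significant = p_adj < alpha

    pairwise = pd.DataFrame(
        {
            "group1": [p[0] for p in pairs],
            "group2": [p[1] for p in pairs],
            "z": z,
            "p_unadjusted": p_raw,
            "p_adjusted": p_adj,
            "significant": significant,
        }
    )
    order = sorted(labels, key=lambda lbl: (mean_ranks[lbl], lbl))
    sig_pairs = {
        frozenset((r.group1, r.group2))
        for r in pairwise.itertuples()
        if r.significant
    }
    letters = _compact_letters(order, sig_pairs)
    return DunnResult(
        pairwise=pairwise,
        letters=letters,
        mean_ranks=mean_ranks,
        adjust=adjust,
        alpha=alpha,
    )


def _compact_letters(
    order: Sequence[str], sig_pairs: set[frozenset]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Starts from one column containing every group; for each significantly
    different pair, every column containing both is split into two columns
    (one without each member); columns that become subsets of another are
    absorbed.  The result is a clique cover of the "not significantly
    different" graph: groups share a letter iff they do not differ.
    """
    columns: list[set[str]] = [set(order)]
    for pair in sorted(sig_pairs, key=lambda p: tuple(sorted(p))):
        a, b = sorted(pair)
        new_columns: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_columns.extend((col - {a}, col - {b}))
            else:
                new_columns.append(col)
        # absorb: drop empties, duplicates and strict subsets
        uniq: list[set[str]] = []
        for col in new_columns:
            if col and col not in uniq:
                uniq.append(col)
        columns = [c for c in uniq if not any(c < other for other in uniq)]
    # order columns by the first group (in mean-rank order) they contain
    pos = {g: i for i, g in enumerate(order)}
    columns.sort(key=lambda col: min(pos[g] for g in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {g: [] for g in order}
    for i, col in enumerate(columns):
        letter = alphabet[i % len(alphabet)] * (1 + i // len(alphabet))
        for g in order:
            if g in col:
                letters[g].append(letter)
    return {g: "".join(ls) for g, ls in letters.items()}


def census_comparison(
    sample: Mapping[str, int] | pd.Series,
    census: CensusMarginals,
    margin: str,
) -> ChiSquareResult:
    """Goodness-of-fit chi-square of sample demographic counts against
    census shares, with Cohen's w = sqrt(chi2 / n) as the effect size.

    Expected counts are n times the census share per class; df = classes - 1.
    """
    sample = dict(sample)
    shares = census.margin_shares(margin)
    n = int(sum(sample.values()))
    if n < 1:
        raise InputError("sample must contain at least one observation")
    classes = sorted(sample)
    missing = [c for c in classes if c not in shares]
    if missing:
        raise InputError(f"census shares missing for classes: {missing}")
    for c in classes:
        if shares[c] == 0 and sample[c] > 0:
            raise InputError(
                f"class {c!r} observed in the sample but has zero census share"
            )
    observed = np.array([sample[c] for c in classes], dtype=float)
    share_vec = np.array([shares[c] for c in classes])
    expected = n * share_vec / share_vec.sum()
    chi2, p = sps.chisquare(observed, f_exp=expected)
    return ChiSquareResult(
        chi2=float(chi2),
        df=len(classes) - 1,
        p=float(p),
        effect_size=float(np.sqrt(chi2 / n)),
        n=n,
    )
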