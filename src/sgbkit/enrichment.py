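"""Prevalence contrasts with Fisher's exact test and multiplicity control.

Features (species-level genome bins, or KEGG Orthology families) are scored
as present/absent per sample; two sample groups (e.g. Westernized vs
non-Westernized hosts) are contrasted feature-by-feature with a two-sided
Fisher's exact test on the 2x2 presence-by-group table, followed by
Bonferroni or Benjamini-Hochberg adjustment over the features that pass the
presence gates.

The two-sided p-value uses the point-probability method: the sum of all
hypergeometric point probabilities not exceeding that of the observed
table.  It is computed with exact big-integer binomial coefficients, so tie
decisions are exact rather than float-rounded; the conversion to float
happens once, on the final rational number.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import comb
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ArgumentError

ADJUST_METHODS = ("bonferroni", "bh")


@dataclass(frozen=True)
class PresenceMatrix:
    """Binary feature-by-sample matrix with a two-group sample labeling."""

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    presence: np.ndarray  # shape (features, samples), values {0, 1}
    group_of: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.presence.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ArgumentError("presence matrix shape does not match labels")
        if not np.isin(self.presence, (0, 1)).all():
            raise ArgumentError("presence entries must be 0 or 1")
        missing = [s for s in self.sample_ids if s not in self.group_of]
        if missing:
            raise ArgumentError(f"samples without a group: {missing[:5]}")

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted({self.group_of[s] for s in self.sample_ids}))

    def group_mask(self, group: str) -> np.ndarray:
        return np.array([self.group_of[s] == group for s in self.sample_ids])

    def overall_prevalence(self) -> np.ndarray:
        return self.presence.mean(axis=1)


@dataclass(frozen=True)
class EnrichmentResult:
    """One feature's prevalence contrast between the two groups."""

    feature_id: str
    prevalence_a: float
    prevalence_b: float
    table: tuple[int, int, int, int]  # (present_a, present_b, absent_a, absent_b)
    p_value: float
    p_adjusted: float
    enriched_group: str | None


def prevalence(feature_row: np.ndarray, group_mask: np.ndarray) -> float:
    """Fraction of the group's samples in which the feature is present."""
    n = int(group_mask.sum())
    if n == 0:
        raise ArgumentError("prevalence of an empty group is undefined")
    return float(feature_row[group_mask].sum()) / n


@lru_cache(maxsize=100_000)
def _fisher_cached(a: int, b: int, c: int, d: int) -> float:
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    observed = comb(r1, a) * comb(r2, c1 - a)
    total = comb(n, c1)
    acc = 0
    for k in range(lo, hi + 1):
        w = comb(r1, k) * comb(r2, c1 - k)
        if w <= observed:
            acc += w
    return float(Fraction(acc, total))


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 table, point-probability method."""
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ArgumentError(f"table counts must be non-negative integers: {table}")
    return _fisher_cached(int(a), int(b), int(c), int(d))


def adjust_pvalues(p: Sequence[float], method: str) -> list[float]:
    """Bonferroni or Benjamini-Hochberg adjusted p-values, input order kept."""
    if method not in ADJUST_METHODS:
        raise ArgumentError(f"unknown adjustment method {method!r}")
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ArgumentError("p-values must lie in [0, 1]")
    sm_method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[method]
    _, adjusted, _, _ = multipletests(arr, method=sm_method)
    return [float(x) for x in adjusted]


def enrichment_scan(
    pm: PresenceMatrix,
    alpha: float = 0.05,
    method: str = "bonferroni",
    min_presence_per_group: int = 0,
    min_total_presence: int = 1,
) -> list[EnrichmentResult]:
    """Fisher-test every feature passing the presence gates.

    Gates are applied before testing, so the multiplicity burden ``m``
    counts only tested features.  ``min_presence_per_group`` requires at
    least that many present samples in each group; ``min_total_presence``
    bounds the overall count.  Results are sorted by adjusted p, then
    feature id; ``enriched_group`` names the higher-prevalence group for
    features with adjusted p below ``alpha``.
    """
    groups = pm.groups
    if len(groups) != 2:
        raise ArgumentError(f"need exactly 2 groups, got {groups}")
    ga, gb = groups
    mask_a, mask_b = pm.group_mask(ga), pm.group_mask(gb)
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    if na == 0 or nb == 0:
        raise ArgumentError("both groups must be non-empty")

    tested: list[tuple[str, int, int]] = []
    for fid, row in zip(pm.feature_ids, pm.presence):
        pa = int(row[mask_a].sum())
        pb = int(row[mask_b].sum())
        if pa + pb < min_total_presence:
            continue
        if pa < min_presence_per_group or pb < min_presence_per_group:
            continue
        tested.append((fid, pa, pb))

    pvals = [
        fisher_exact_two_sided([[pa, pb], [na - pa, nb - pb]])
        for _, pa, pb in tested
    ]
    adjusted = adjust_pvalues(pvals, method)
    results = []
    for (fid, pa, pb), p, p_adj in zip(tested, pvals, adjusted):
        prev_a, prev_b = pa / na, pb / nb
        if p_adj < alpha and prev_a != prev_b:
            enriched = ga if prev_a > prev_b else gb
        else:
            enriched = None
        results.append(
            EnrichmentResult(
                feature_id=fid,
                prevalence_a=prev_a,
                prevalence_b=prev_b,
                table=(pa, pb, na - pa, nb - pb),
                p_value=p,
                p_adjusted=p_adj,
                enriched_group=enriched,
            )
        )
    return sorted(results, key=lambda r: (r.p_adjusted, r.feature_id))


def ko_filter(pm: PresenceMatrix, low: float = 0.20, high: float = 0.80) -> PresenceMatrix:
    """Keep features with overall prevalence in [low, high).

    The default band (present in at least 20% and less than 80% of samples)
    drops core and rare gene families before presence/absence comparisons.
    """
    if not 0.0 <= low < high <= 1.0:
        raise ArgumentError(f"invalid prevalence band [{low}, {high})")
    prev = pm.overall_prevalence()
    keep = (prev >= low) & (prev < high)
    return PresenceMatrix(
        feature_ids=tuple(np.array(pm.feature_ids)[keep]),
        sample_ids=pm.sample_ids,
        presence=pm.presence[keep],
        group_of=pm.group_of,
    )


def results_to_tsv(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    rows = [
        {
            "feature_id": r.feature_id,
            "prev_a": r.prevalence_a,
            "prev_b": r.prevalence_b,
            "a": r.table[0],
            "b": r.table[1],
            "c": r.table[2],
            "d": r.table[3],
            "p": r.p_value,
            "p_adj": r.p_adjusted,
            "enriched_group": r.enriched_group or "",
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_presence_matrix(
    matrix_path: str | Path, groups_path: str | Path
) -> PresenceMatrix:
    """Features-by-samples 0/1 TSV plus a two-column sample->group TSV."""
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    gdf = pd.read_csv(groups_path, sep="\t", dtype=str)
    group_of = dict(zip(gdf.iloc[:, 0], gdf.iloc[:, 1]))
    return PresenceMatrix(
        feature_ids=tuple(df.index.astype(str)),
        sample_ids=tuple(df.columns.astype(str)),
        presence=df.to_numpy(dtype=int),
        group_of=group_of,
    )


def write_presence_matrix(
    pm: PresenceMatrix, matrix_path: str | Path, groups_path: str | Path
) -> None:
    pd.DataFrame(pm.presence, index=list(pm.feature_ids), columns=list(pm.sample_ids)).to_csv(
        matrix_path, sep="\t"
    )
    pd.DataFrame(
        {"sample_id": list(pm.sample_ids), "group": [pm.group_of[s] for s in pm.sample_ids]}
    ).to_csv(groups_path, sep="\t", index=False)
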