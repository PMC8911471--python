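"""Contour agreement metrics: Dice similarity, pairwise observer tables,
and the one-way ANOVA used to compare comparison groups.

The Dice similarity index between two binary structure masks A and B is

    DSI = 2 |A ∩ B| / (|A| + |B|)

computed on voxel counts of masks sampled on one shared grid.  Two empty
masks have an undefined DSI and raise, rather than silently scoring 1 (a
silent 1.0 would mask a missing contour pair).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grid import StructureMask


def dice(ref: StructureMask, test: StructureMask) -> float:
    """Dice similarity index 2|A∩B|/(|A|+|B|) of two masks on one grid."""
    ref.grid.require_compatible(test.grid)
    a = ref.voxel_count
    b = test.voxel_count
    if a == 0 and b == 0:
        raise ValueError(
            f"Dice of two empty masks ('{ref.name}' vs '{test.name}') is "
            "undefined"
        )
    inter = int(np.logical_and(ref.data, test.data).sum())
    return 2.0 * inter / (a + b)


@dataclass
class PairwiseDSITable:
    """Mean/SD Dice per comparison pair and structure, over fractions.

    ``values`` holds the underlying per-fraction Dice values in long form
    (pair, structure, patient, fraction, dsi); ``table`` is the wide
    mean/SD/n summary with one row per pair.  SDs are sample (n-1)
    standard deviations.
    """

    table: pd.DataFrame
    values: pd.DataFrame
    benchmark_pair: str | None = None


def pairwise_dsi(
    masks: Mapping[str, Mapping[tuple[str, str], Mapping[str, StructureMask]]],
    reference: str,
    structures: Sequence[str],
    benchmark: str | None = None,
) -> PairwiseDSITable:
    """Pairwise Dice of every observer against one reference observer.

    Parameters
    ----------
    masks
        ``masks[observer][(patient_id, fraction_id)][structure]`` ->
        :class:`StructureMask`.  Every observer must cover every
        (fraction, structure) cell the reference covers; gaps raise with a
        list of the missing triples.
    reference
        Observer id whose contours anchor every comparison pair.
    structures
        Structure names to compare (e.g. bladder and the cranially limited
        bowel).
    benchmark
        Observer id forming the benchmark pair with the reference (the
        second physician); that pair is flagged on the returned table.
    """
    if reference not in masks:
        raise KeyError(f"reference observer '{reference}' not in mask set")
    fractions = sorted(masks[reference])
    gaps = [
        (obs, frac, s)
        for obs, per_frac in masks.items()
        for frac in fractions
        for s in structures
        if frac not in per_frac or s not in per_frac[frac]
    ]
    if gaps:
        raise ValueError(f"missing (observer, fraction, structure) triples: {gaps}")

    records = []
    for obs in masks:
        if obs == reference:
            continue
        pair = f"{reference} v {obs}"
        for frac in fractions:
            for s in structures:
                records.append(
                    {
                        "pair": pair,
                        "structure": s,
                        "patient": frac[0],
                        "fraction": frac[1],
                        "dsi": dice(masks[reference][frac][s], masks[obs][frac][s]),
                    }
                )
    values = pd.DataFrame.from_records(records)
    table = (
        values.groupby(["pair", "structure"])["dsi"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count")
        .unstack("structure")
        .swaplevel(axis=1)
        .sort_index(axis=1)
    )
    benchmark_pair = f"{reference} v {benchmark}" if benchmark else None
    if benchmark_pair is not None and benchmark_pair not in table.index:
        raise ValueError(f"benchmark pair '{benchmark_pair}' not present")
    return PairwiseDSITable(table=table, values=values, benchmark_pair=benchmark_pair)


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def anova_oneway(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA across >= 2 groups.

    Raises on groups with fewer than 2 values, non-finite values, and the
    fully degenerate case of zero variance both within and between groups
    (where the F ratio is 0/0).
    """
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
        if not np.all(np.isfinite(g)):
            raise ValueError(f"group {i} contains non-finite values")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise ValueError(
            "degenerate ANOVA: zero within-group and between-group variance"
        )
    f_stat, p = stats.f_oneway(*arrays)
    return AnovaResult(float(f_stat), float(p), alpha)
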