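"""Cross-linking percentage (%XL) quantitation and two-condition
comparison with outlier calling.

The core statistic for a cross-linked residue pair is its cross-linking
percentage,

    %XL = 100 * PH(pair) / [ sum of PH over all cross-linked species
          containing either linked residue
          + PH(dead-end at residue_i) + PH(dead-end at residue_j) ]

computed within one protein, condition and replicate from XIC apex peak
heights (PH).  Normalizing by every species that consumed either lysine
cancels residue-reactivity differences, so the percentage mainly
reflects the spatial proximity of the two residues.  Dead-end species
are cross-linker-modified peptides whose second linker arm hydrolyzed.

Replicate %XL values are compared between two conditions with a pooled
two-sample t-test; a pair is an outlier when its residues are at least
``min_separation`` amino acids apart in sequence, the mean difference
is at least ``sd_multiplier`` pooled replicate standard deviations, and
the t-test p-value is at or below ``alpha``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from epiconform.io import CrosslinkSpeciesRecord


@dataclass(frozen=True, order=True)
class PairKey:
    """A cross-linked residue pair, 1-based, residue_i < residue_j."""

    protein_id: str
    residue_i: int
    residue_j: int

    def __post_init__(self) -> None:
        if not self.residue_i < self.residue_j:
            raise ValueError("residue_i must be < residue_j")

    @property
    def seq_separation(self) -> int:
        return self.residue_j - self.residue_i


@dataclass(frozen=True)
class XLMeasurement:
    """One replicate %XL value for a pair under one condition."""

    pair: PairKey
    condition: str
    replicate: int
    percent: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent <= 100.0 + 1e-9:
            raise ValueError(f"percent out of [0, 100]: {self.percent}")


@dataclass
class PairComparison:
    """Per-pair replicate statistics across two conditions.

    ``delta = mean_a - mean_b``; ``pooled_sd`` is the pooled replicate
    standard deviation; test fields are None when either condition has
    fewer than two replicates or zero pooled variance (no fabricated
    significance).  The three outlier criteria are recorded separately
    so the verdict is auditable.
    """

    pair: PairKey
    condition_a: str
    condition_b: str
    mean_a: float | None = None
    sd_a: float | None = None
    n_a: int = 0
    mean_b: float | None = None
    sd_b: float | None = None
    n_b: int = 0
    delta: float | None = None
    pooled_sd: float | None = None
    t_stat: float | None = None
    p_value: float | None = None
    crit_separation: bool = False
    crit_effect: bool = False
    crit_significant: bool = False
    outlier: bool = False

    @property
    def seq_separation(self) -> int:
        return self.pair.seq_separation


def _pair_of(record: CrosslinkSpeciesRecord) -> PairKey:
    assert record.species_type == "crosslink" and record.residue_j is not None
    return PairKey(record.protein_id, record.residue_i, record.residue_j)


def crosslink_percentage(pair: PairKey,
                         records: Sequence[CrosslinkSpeciesRecord],
                         condition: str, replicate: int,
                         denominator: str = "residue") -> float:
    """%XL for one pair in one condition/replicate (module docstring formula).

    ``denominator="residue"`` (default) includes every cross-linked
    species sharing either residue of the pair; ``"pair"`` restricts the
    cross-link term to the pair itself.  Multiple species rows mapping
    to the same residue pair (charge states, miscleavage forms) are
    summed before the ratio.
    """
    if denominator not in ("residue", "pair"):
        raise ValueError("denominator must be 'residue' or 'pair'")
    sub = [r for r in records
           if r.protein_id == pair.protein_id
           and r.condition == condition and r.replicate == replicate]
    ph_pair = sum(r.peak_height for r in sub
                  if r.species_type == "crosslink"
                  and r.residue_i == pair.residue_i
                  and r.residue_j == pair.residue_j)
    has_pair = any(r.species_type == "crosslink"
                   and r.residue_i == pair.residue_i
                   and r.residue_j == pair.residue_j for r in sub)
    if not has_pair:
        raise ValueError(
            f"no crosslink record for {pair} in condition={condition!r} "
            f"replicate={replicate}"
        )
    if denominator == "residue":
        xl_term = sum(
            r.peak_height for r in sub if r.species_type == "crosslink"
            and {pair.residue_i, pair.residue_j} & {r.residue_i, r.residue_j}
        )
    else:
        xl_term = ph_pair
    de_i = sum(r.peak_height for r in sub
               if r.species_type == "deadend" and r.residue_i == pair.residue_i)
    de_j = sum(r.peak_height for r in sub
               if r.species_type == "deadend" and r.residue_i == pair.residue_j)
    denom = xl_term + de_i + de_j
    if denom <= 0:
        raise ValueError(f"zero denominator for {pair} ({condition}, rep {replicate})")
    # numerator is part of the denominator, so the ratio is <= 1 up to
    # floating-point roundoff; clamp to keep the [0, 100] contract
    return min(100.0, 100.0 * ph_pair / denom)


def percentages_from_records(records: Sequence[CrosslinkSpeciesRecord],
                             denominator: str = "residue") -> list[XLMeasurement]:
    """%XL for every (pair, condition, replicate) present in a species table."""
    groups: dict[tuple[str, str, int], list[CrosslinkSpeciesRecord]] = {}
    for r in records:
        groups.setdefault((r.protein_id, r.condition, r.replicate), []).append(r)
    keys = sorted({
        (_pair_of(r), r.condition, r.replicate)
        for r in records if r.species_type == "crosslink"
    }, key=lambda k: (k[0], k[1], k[2]))
    return [
        XLMeasurement(
            pair=pair, condition=cond, replicate=rep,
            percent=crosslink_percentage(
                pair, groups[(pair.protein_id, cond, rep)], cond, rep,
                denominator))
        for pair, cond, rep in keys
    ]


def summarize_pair(measurements: Sequence[XLMeasurement]
                   ) -> tuple[float, float | None, int]:
    """Mean, sample SD (n-1 denominator; None when n = 1) and n of
    replicate %XL values for one pair and condition."""
    if not measurements:
        raise ValueError("no measurements")
    pairs = {(m.pair, m.condition) for m in measurements}
    if len(pairs) > 1:
        raise ValueError("measurements span multiple pairs/conditions")
    values = np.array([m.percent for m in measurements], dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else None
    return mean, sd, len(values)


def compare_conditions(measurements: Sequence[XLMeasurement],
                       condition_a: str, condition_b: str,
                       require_test: bool = False) -> list[PairComparison]:
    """Per-pair two-condition comparison with pooled two-sample t-test.

    Pairs observed in only one condition, or with fewer than two
    replicates in either, are reported with the test fields absent
    (error instead when ``require_test``).  Zero pooled variance also
    leaves the p-value absent rather than fabricating 0 or 1.
    """
    by_pair: dict[PairKey, dict[str, list[float]]] = {}
    for m in measurements:
        by_pair.setdefault(m.pair, {}).setdefault(m.condition, []).append(m.percent)
    out = []
    for pair in sorted(by_pair):
        groups = by_pair[pair]
        a = np.array(groups.get(condition_a, []), dtype=float)
        b = np.array(groups.get(condition_b, []), dtype=float)
        cmp = PairComparison(pair=pair, condition_a=condition_a,
                             condition_b=condition_b,
                             n_a=len(a), n_b=len(b))
        if len(a):
            cmp.mean_a = float(a.mean())
            cmp.sd_a = float(a.std(ddof=1)) if len(a) > 1 else None
        if len(b):
            cmp.mean_b = float(b.mean())
            cmp.sd_b = float(b.std(ddof=1)) if len(b) > 1 else None
        if len(a) and len(b):
            cmp.delta = cmp.mean_a - cmp.mean_b
        if len(a) >= 2 and len(b) >= 2:
            sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) \
                / (len(a) + len(b) - 2)
            cmp.pooled_sd = float(math.sqrt(sp2))
            if sp2 > 0:
                t, p = stats.ttest_ind(a, b, equal_var=True)
                cmp.t_stat = float(t)
                cmp.p_value = float(p)
        elif require_test:
            raise ValueError(
                f"pair {pair}: fewer than 2 replicates in a condition "
                f"(n_a={len(a)}, n_b={len(b)}) but a t-test was requested"
            )
        out.append(cmp)
    return out


def flag_outliers(comparisons: Iterable[PairComparison],
                  sd_multiplier: float = 1.5,
                  min_separation: int = 8,
                  alpha: float = 0.05) -> list[PairComparison]:
    """Apply the three-part outlier rule, recording each criterion.

    outlier = (sequence separation >= min_separation)
              and (|delta| >= sd_multiplier * pooled_sd)
              and (p_value <= alpha)

    Pairs lacking the test fields are never outliers and are returned
    with every criterion False.
    """
    out = []
    for c in comparisons:
        c = replace(c)
        c.crit_separation = c.seq_separation >= min_separation
        if c.delta is not None and c.pooled_sd is not None:
            c.crit_effect = abs(c.delta) >= sd_multiplier * c.pooled_sd
        else:
            c.crit_effect = False
        c.crit_significant = c.p_value is not None and c.p_value <= alpha
        c.outlier = c.crit_separation and c.crit_effect and c.crit_significant
        out.append(c)
    return out


class ConditionComparison:
    """Two-condition %XL comparison over a whole species table.

    Thin results container: computes per-replicate percentages, the
    per-pair statistics and the outlier verdicts in one pass, and
    exposes them as records and as a DataFrame.
    """

    def __init__(self, records: Sequence[CrosslinkSpeciesRecord],
                 condition_a: str, condition_b: str,
                 sd_multiplier: float = 1.5, min_separation: int = 8,
                 alpha: float = 0.05, denominator: str = "residue"):
        self.condition_a = condition_a
        self.condition_b = condition_b
        self.measurements = percentages_from_records(records, denominator)
        comparisons = compare_conditions(self.measurements,
                                         condition_a, condition_b)
        self.comparisons = flag_outliers(comparisons, sd_multiplier,
                                         min_separation, alpha)

    @property
    def outliers(self) -> list[PairComparison]:
        return [c for c in self.comparisons if c.outlier]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.comparisons:
            rows.append({
                "protein_id": c.pair.protein_id,
                "residue_i": c.pair.residue_i,
                "residue_j": c.pair.residue_j,
                "seq_separation": c.seq_separation,
                "mean_a": c.mean_a, "sd_a": c.sd_a, "n_a": c.n_a,
                "mean_b": c.mean_b, "sd_b": c.sd_b, "n_b": c.n_b,
                "delta": c.delta, "pooled_sd": c.pooled_sd,
                "t_stat": c.t_stat, "p_value": c.p_value,
                "crit_separation": c.crit_separation,
                "crit_effect": c.crit_effect,
                "crit_significant": c.crit_significant,
                "outlier": c.outlier,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        n_tested = int(df["p_value"].notna().sum()) if len(df) else 0
        lines = [
            f"Cross-linking percentage comparison: "
            f"{self.condition_a} vs {self.condition_b}",
            f"pairs: {len(df)}   with t-test: {n_tested}   "
            f"outliers: {int(df['outlier'].sum()) if len(df) else 0}",
            "",
        ]
        if len(df):
            with pd.option_context("display.width", 120):
                lines.append(df.to_string(
                    index=False, float_format=lambda v: f"{v:.3f}",
                    columns=["protein_id", "residue_i", "residue_j",
                             "mean_a", "mean_b", "delta", "pooled_sd",
                             "p_value", "outlier"]))
        return "\n".join(lines)
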