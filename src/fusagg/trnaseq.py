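"""tRNA-seq count-table accounting: pooling of identical gene copies,
total-count normalization, differential abundance and pool fractions.

Count tables are tidy DataFrames with metadata columns ``transcript_id``,
``mapping_class`` (``unique`` for transcripts with a distinguishing
sequence, ``multi`` for reads shared among identical gene copies) and
optionally ``family``, plus one integer column per sample named
``{condition}_{replicate}`` (e.g. ``AAA_2``). Reads from identical gene
copies cannot be assigned to an individual gene, so multi-mapped
transcripts are summed into per-family pools before any comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import welch_t_test

logger = logging.getLogger(__name__)

__all__ = [
    "DiffAbundanceResult",
    "PoolFractions",
    "sample_columns",
    "condition_columns",
    "pool_counts",
    "normalize_counts",
    "differential_abundance",
    "pool_fractions",
]

META_COLUMNS = ("transcript_id", "mapping_class", "family")


@dataclass(frozen=True)
class DiffAbundanceResult:
    transcript_id: str
    mean_a: float
    mean_b: float
    fold_change: float  # b / a, on pseudocount-stabilised means
    p_value: float
    flag_1_5x: bool
    flag_2x: bool
    q_value: float | None = None


@dataclass(frozen=True)
class PoolFractions:
    """The mutant transcript's share of successively narrower tRNA pools,
    and the share adjusted for incomplete transfection (fraction divided by
    the transfection efficiency; values > 1 are reported and flagged,
    never clamped)."""

    fraction_of_ser_pool: float
    fraction_of_aga_pool: float
    fraction_of_phe_decoders: float
    transfection_adjusted_fraction: float
    adjusted_exceeds_one: bool


def sample_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def condition_columns(table: pd.DataFrame, condition: str) -> list[str]:
    cols = [c for c in sample_columns(table) if c.rsplit("_", 1)[0] == condition]
    if not cols:
        raise ValueError(f"no sample columns for condition {condition!r}")
    return cols


def pool_counts(
    table: pd.DataFrame, family_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Sum multi-mapped transcripts into pools; unique transcripts pass
    through unpooled.

    ``family_map`` assigns each multi-mapped transcript to a pool id; by
    default the table's ``family`` column is used. A multi-mapped transcript
    missing from the map is retained as its own pool (with a log warning).
    Pooling is linear in the counts, so it commutes with total-count
    normalization.
    """
    samples = sample_columns(table)
    rows = []
    pooled: dict[str, np.ndarray] = {}
    for rec in table.to_dict("records"):
        if rec["mapping_class"] != "multi":
            rows.append(rec)
            continue
        tid = rec["transcript_id"]
        if family_map is not None:
            pool = family_map.get(tid)
            if pool is None:
                logger.warning("transcript %s missing from family_map; kept as own pool", tid)
                pool = tid
        else:
            pool = rec.get("family") or tid
        counts = np.array([rec[c] for c in samples], dtype=float)
        if pool in pooled:
            pooled[pool] = pooled[pool] + counts
        else:
            pooled[pool] = counts
    for pool, counts in pooled.items():
        rec = {"transcript_id": pool, "mapping_class": "multi", "family": pool}
        rec.update(dict(zip(samples, counts)))
        rows.append(rec)
    out = pd.DataFrame(rows)
    keep = [c for c in table.columns if c in out.columns]
    extra = [c for c in out.columns if c not in keep]
    return out[keep + extra].reset_index(drop=True)


def normalize_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample by its total read count and rescale by the mean
    total across samples, keeping magnitudes comparable to raw counts.
    Column sums are equal across samples afterwards."""
    samples = sample_columns(table)
    totals = table[samples].sum(axis=0).to_numpy(dtype=float)
    if np.any(totals == 0):
        raise ValueError("sample with zero total reads cannot be normalized")
    out = table.copy()
    out[samples] = table[samples].to_numpy(dtype=float) / totals * totals.mean()
    return out


def differential_abundance(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    pseudocount: float = 0.5,
    fc_flags: tuple[float, float] = (1.5, 2.0),
    bh_correction: bool = False,
) -> list[DiffAbundanceResult]:
    """Per-transcript fold change (group-b over group-a means, with a
    pseudocount added to both means to stabilise zero counts) and a Welch
    two-sample t-test on the counts.

    Transcripts with all-zero counts in both groups are excluded (logged).
    The stabilisation floors each group mean at the pseudocount
    (``max(mean, pseudocount)``), so fold changes between well-measured
    transcripts are exact mean ratios while zero-count groups stay finite.
    Flags mark |log2 FC| beyond the 1.5x and 2x thresholds in either
    direction. ``bh_correction`` optionally appends Benjamini-Hochberg
    q-values (off by default: raw pairwise p-values are reported).
    """
    cols_a = condition_columns(table, group_a)
    cols_b = condition_columns(table, group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    lo, hi = sorted(fc_flags)
    results = []
    for rec in table.to_dict("records"):
        a = np.array([rec[c] for c in cols_a], dtype=float)
        b = np.array([rec[c] for c in cols_b], dtype=float)
        if not a.any() and not b.any():
            logger.info("transcript %s all-zero in both groups; excluded", rec["transcript_id"])
            continue
        mean_a = float(a.mean())
        mean_b = float(b.mean())
        fc = max(mean_b, pseudocount) / max(mean_a, pseudocount)
        p = welch_t_test(a, b).p_value
        ratio = max(fc, 1.0 / fc)
        results.append(
            DiffAbundanceResult(
                transcript_id=rec["transcript_id"],
                mean_a=mean_a,
                mean_b=mean_b,
                fold_change=fc,
                p_value=p,
                flag_1_5x=ratio >= lo,
                flag_2x=ratio >= hi,
            )
        )
    if bh_correction and results:
        from statsmodels.stats.multitest import multipletests

        q = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        results = [
            DiffAbundanceResult(
                r.transcript_id, r.mean_a, r.mean_b, r.fold_change, r.p_value,
                r.flag_1_5x, r.flag_2x, q_value=float(qv),
            )
            for r, qv in zip(results, q)
        ]
    return results


def volcano_table(results: list[DiffAbundanceResult]) -> pd.DataFrame:
    """log2 fold change vs -log10 p, ready for a volcano plot export."""
    return pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in results],
            "log2_fc": [math.log2(r.fold_change) for r in results],
            "neg_log10_p": [-math.log10(r.p_value) for r in results],
            "flag_1_5x": [r.flag_1_5x for r in results],
            "flag_2x": [r.flag_2x for r in results],
        }
    )


def pool_fractions(
    table: pd.DataFrame,
    mutant_id: str,
    ser_pool_ids: list[str],
    aga_pool_id: str,
    phe_pool_ids: list[str],
    condition: str,
    transfection_efficiency: float = 0.60,
) -> PoolFractions:
    """The mutant transcript's share of the total Ser pool, of the wild-type
    isodecoder pool it arose from, and of the Phe-decoding pool it competes
    with — computed on raw mean counts within one condition (pools are
    compared within samples, so no cross-sample normalization applies).

    Pool denominators include the mutant itself where the pool definition
    covers it (the Ser and Phe-decoder pools; the wild-type AGA pool does
    not). The transfection-adjusted fraction divides the Phe-decoder share
    by the transfection efficiency, extrapolating from the bulk population
    to the transfected subpopulation.
    """
    if not (0.0 < transfection_efficiency <= 1.0):
        raise ValueError("transfection_efficiency must be in (0, 1]")
    cols = condition_columns(table, condition)
    means = table.set_index("transcript_id")[cols].mean(axis=1)

    def pool_mean(ids: list[str]) -> float:
        missing = [i for i in ids if i not in means.index]
        if missing:
            raise KeyError(f"pool transcripts missing from table: {missing}")
        return float(means.loc[ids].sum())

    mutant = pool_mean([mutant_id])

    def frac(denom: float) -> float:
        return mutant / denom if denom > 0 else math.nan

    ser = frac(pool_mean(ser_pool_ids) + (0.0 if mutant_id in ser_pool_ids else mutant))
    aga = frac(pool_mean([aga_pool_id]))
    phe = frac(pool_mean(phe_pool_ids) + (0.0 if mutant_id in phe_pool_ids else mutant))
    adjusted = phe / transfection_efficiency
    return PoolFractions(
        fraction_of_ser_pool=ser,
        fraction_of_aga_pool=aga,
        fraction_of_phe_decoders=phe,
        transfection_adjusted_fraction=adjusted,
        adjusted_exceeds_one=bool(adjusted > 1.0),
    )
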