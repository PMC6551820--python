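"""Dimerization assay statistics: normalization, relative fluorescence,
merged-homodimer fold change, Student's t tests and Benjamini-Hochberg FDR.

Input tables are long-format records with columns (construct_n, construct_c,
replicate, batch, raw_fluorescence, normalizer); the normalizer is the
culture absorbance (OD600) or co-transfected luciferase counts.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DimerizationResult",
    "REQUIRED_COLUMNS",
    "normalize",
    "relative_to_control",
    "hetero_fold_change",
    "bh_adjust",
    "classify_pairs",
    "analyze_table",
]

REQUIRED_COLUMNS = ("construct_n", "construct_c", "replicate", "batch",
                    "raw_fluorescence", "normalizer")


@dataclass
class DimerizationResult:
    pair: tuple[str, str]
    mean_relative: float
    std_relative: float
    n: int
    fold_change: float | None = None
    p_vs_homo: float | None = None
    q_vs_homo: float | None = None
    p_vs_negative: float | None = None
    q_vs_negative: float | None = None
    call: str | None = None


def _validate(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"table missing columns: {missing}")
    bad = table.index[(table["raw_fluorescence"] <= 0)]
    if len(bad):
        raise ValueError(f"non-positive raw_fluorescence in records {list(bad[:5])}")
    bad = table.index[(table["normalizer"] <= 0)]
    if len(bad):
        raise ValueError(f"non-positive normalizer in records {list(bad[:5])}")
    keys = table[["construct_n", "construct_c", "replicate", "batch"]]
    if keys.duplicated().any():
        raise ValueError("duplicate (construct_n, construct_c, replicate, batch) records")


def normalize(table: pd.DataFrame) -> pd.Series:
    """Per-record normalized fluorescence = raw / normalizer."""
    _validate(table)
    return table["raw_fluorescence"] / table["normalizer"]


def _pair_mask(table: pd.DataFrame, pair: tuple[str, str],
               symmetric: bool = True) -> pd.Series:
    x, y = pair
    m = (table["construct_n"] == x) & (table["construct_c"] == y)
    if symmetric and x != y:
        m = m | ((table["construct_n"] == y) & (table["construct_c"] == x))
    return m


def relative_to_control(table: pd.DataFrame, positive_control: tuple[str, str],
                        batchwise: bool = False) -> pd.Series:
    """Normalized fluorescence relative to the mean of the positive control.

    With *batchwise* the control mean is computed per batch and records are
    matched to their own batch's control.
    """
    normalized = normalize(table)
    ctrl_mask = _pair_mask(table, positive_control)
    if not ctrl_mask.any():
        raise ValueError(f"positive control {positive_control} absent from table")
    if not batchwise:
        return normalized / normalized[ctrl_mask].mean()
    out = pd.Series(np.nan, index=table.index)
    missing = []
    for batch, idx in table.groupby("batch").groups.items():
        cmask = ctrl_mask.loc[idx]
        if not cmask.any():
            missing.append(batch)
            continue
        out.loc[idx] = normalized.loc[idx] / normalized.loc[idx][cmask].mean()
    if missing:
        raise ValueError(f"positive control missing in batches: {missing}")
    return out


def _ttest(a: np.ndarray, b: np.ndarray, welch: bool = False) -> float:
    if len(a) < 2 or len(b) < 2:
        raise ValueError("t-test needs at least 2 values per group")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def hetero_fold_change(table: pd.DataFrame, relative: pd.Series,
                       pair: tuple[str, str], welch: bool = False
                       ) -> tuple[float, float]:
    """Fold change and p-value of a hetero pair vs its merged homo references.

    The reference set is the concatenation of the X/X and Y/Y relative values;
    fold change = mean(X/Y) / mean(reference); p from a two-sided two-sample
    Student's t test of the X/Y values against the reference set.
    """
    x, y = pair
    hetero = relative[_pair_mask(table, (x, y))].to_numpy()
    homo_x = relative[_pair_mask(table, (x, x))].to_numpy()
    homo_y = relative[_pair_mask(table, (y, y))].to_numpy()
    if len(homo_x) == 0 or len(homo_y) == 0:
        raise ValueError(f"missing homo-dimer records for {x!r} or {y!r}")
    if len(hetero) == 0:
        raise ValueError(f"no records for pair {pair}")
    reference = np.concatenate([homo_x, homo_y])
    fold = float(hetero.mean() / reference.mean())
    p = _ttest(hetero, reference, welch=welch)
    return fold, p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} (m * p_(j) / j) on the sorted p-values, mapped back
    to the input order and clipped to [p, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return np.maximum(q, p)


def classify_pairs(results: list[DimerizationResult],
                   alpha: float = 0.05) -> list[str]:
    """Assign dimer/reduced/background calls from the two q-value comparisons.

    dimer: above the negative control and indistinguishable from the homo
    reference; reduced: above the negative control but significantly below the
    homo reference; background: indistinguishable from the negative control.
    """
    calls = []
    for r in results:
        if r.q_vs_negative is None or r.q_vs_homo is None:
            raise ValueError(f"pair {r.pair}: missing q-value comparisons")
        if r.q_vs_negative >= alpha:
            call = "background"
        elif r.q_vs_homo < alpha:
            call = "reduced"
        else:
            call = "dimer"
        r.call = call
        calls.append(call)
    return calls


def analyze_table(table: pd.DataFrame, positive_control: tuple[str, str],
                  negative_control: tuple[str, str], pairs=None,
                  alpha: float = 0.05, welch: bool = False,
                  batchwise: bool = False) -> list[DimerizationResult]:
    """Full assay pipeline: normalize, scale to the positive control, compare
    each tested pair against its merged homo references and the negative
    control, BH-adjust all p-values as one family, and classify."""
    relative = relative_to_control(table, positive_control, batchwise=batchwise)
    if pairs is None:
        seen = {}
        for cn, cc in zip(table["construct_n"], table["construct_c"]):
            key = (cn, cc)
            if key not in seen and key != negative_control:
                seen[key] = None
        pairs = list(seen)
    neg = relative[_pair_mask(table, negative_control)].to_numpy()
    if len(neg) < 2:
        raise ValueError("negative control needs at least 2 records")
    results = []
    for pair in pairs:
        vals = relative[_pair_mask(table, pair)].to_numpy()
        if len(vals) < 2:
            raise ValueError(f"pair {pair}: need at least 2 replicates")
        fold, p_homo = hetero_fold_change(table, relative, pair, welch=welch)
        p_neg = _ttest(vals, neg, welch=welch)
        results.append(DimerizationResult(
            pair=pair, mean_relative=float(vals.mean()),
            std_relative=float(vals.std(ddof=1)), n=len(vals),
            fold_change=fold, p_vs_homo=p_homo, p_vs_negative=p_neg,
        ))
    qs = bh_adjust([r.p_vs_homo for r in results] + [r.p_vs_negative for r in results])
    k = len(results)
    for i, r in enumerate(results):
        r.q_vs_homo = float(qs[i])
        r.q_vs_negative = float(qs[k + i])
    classify_pairs(results, alpha=alpha)
    return results
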