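"""Scoring of inferred migration graphs against the true graphs.

Edges of the inferred graph G are compared with the true graph G* per
ordered site pair, by default as multisets (polyclonal seeding of the
same site from the same source counts with its multiplicity):

    TP = sum min(mult_G, mult_G*),   FP = |G| - TP,   FN = |G*| - TP

and summarized per dataset by precision TP/(TP+FP), recall TP/(TP+FN)
and their harmonic mean, the F1-score. Errors are further decomposed by
migration path type — primary to metastasis (P→M), metastasis to
metastasis (M→M), metastasis back to primary (M→P) — and aggregated over
scenario / tumor-count groups with two-sample Z and Welch t tests on
mean F1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .graphs import MigrationGraph

__all__ = [
    "compare_graphs",
    "f1_score",
    "path_type",
    "path_type_rates",
    "evaluate_graph",
    "aggregate_benchmark",
    "EvalReport",
    "PATH_TYPES",
]

PATH_TYPES = ("P→M", "M→M", "M→P")


def compare_graphs(
    g: MigrationGraph, g_star: MigrationGraph, semantics: str = "multiset"
) -> tuple[int, int, int]:
    """(TP, FP, FN) between inferred and true migration graphs.

    ``semantics="multiset"`` respects edge multiplicity; ``"set"`` reduces
    every positive multiplicity to 1 first.
    """
    if semantics not in ("multiset", "set"):
        raise ValueError(f"unknown semantics {semantics!r}")
    keys = set(g.edges) | set(g_star.edges)
    alphabet = g_star.sites | g.sites
    for s, t in keys:
        if alphabet and (s not in alphabet or t not in alphabet):
            raise ValueError(f"site {s!r} or {t!r} outside the site alphabet")
    tp = fp = fn = 0
    for key in keys:
        a = g.edges.get(key, 0)
        b = g_star.edges.get(key, 0)
        if semantics == "set":
            a, b = min(a, 1), min(b, 1)
        tp += min(a, b)
        fp += max(0, a - b)
        fn += max(0, b - a)
    return tp, fp, fn


def f1_score(tp: int, fp: int, fn: int) -> tuple[float | None, ...]:
    """(precision, recall, F1) from edge counts.

    All-zero counts leave every quantity undefined: returns
    ``(None, None, None)`` with a warning. A defined-but-zero
    precision+recall yields F1 = 0.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp + fn == 0:
        warnings.warn(
            "no edges in either graph: precision/recall/F1 undefined",
            stacklevel=2,
        )
        return (None, None, None)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    if precision + recall == 0:
        return (precision, recall, 0.0)
    return (precision, recall, 2 * precision * recall / (precision + recall))


def path_type(source: str, target: str, primary: str) -> str:
    if source == primary:
        return "P→M"
    if target == primary:
        return "M→P"
    return "M→M"


def path_type_counts(
    g: MigrationGraph, g_star: MigrationGraph, primary: str, semantics: str = "multiset"
) -> pd.DataFrame:
    """Per path type: TP/FP/FN plus inferred and true edge totals."""
    rows = {t: dict.fromkeys(("tp", "fp", "fn", "inferred", "true"), 0)
            for t in PATH_TYPES}
    keys = set(g.edges) | set(g_star.edges)
    for key in keys:
        a = g.edges.get(key, 0)
        b = g_star.edges.get(key, 0)
        if semantics == "set":
            a, b = min(a, 1), min(b, 1)
        t = path_type(*key, primary)
        rows[t]["tp"] += min(a, b)
        rows[t]["fp"] += max(0, a - b)
        rows[t]["fn"] += max(0, b - a)
        rows[t]["inferred"] += a
        rows[t]["true"] += b
    return pd.DataFrame(rows).T


def path_type_rates(
    g: MigrationGraph,
    g_star: MigrationGraph,
    primary: str | None = None,
    semantics: str = "multiset",
) -> pd.DataFrame:
    """FP and FN rates per path type for one dataset.

    FN rate = missed true edges / true edges of that type; FP rate =
    spurious inferred edges / inferred edges of that type. Types with no
    edges in the relevant denominator get NaN.
    """
    primary = primary or g_star.primary
    counts = path_type_counts(g, g_star, primary, semantics)
    with np.errstate(invalid="ignore", divide="ignore"):
        counts["fn_rate"] = counts["fn"] / counts["true"].replace(0, np.nan)
        counts["fp_rate"] = counts["fp"] / counts["inferred"].replace(0, np.nan)
    return counts


def pooled_path_type_rates(counts_frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Micro-averaged path-type rates: pool counts across datasets first."""
    total = sum(f[["tp", "fp", "fn", "inferred", "true"]] for f in counts_frames)
    with np.errstate(invalid="ignore", divide="ignore"):
        total["fn_rate"] = total["fn"] / total["true"].replace(0, np.nan)
        total["fp_rate"] = total["fp"] / total["inferred"].replace(0, np.nan)
    return total


@dataclass
class EvalReport:
    """Scores of one inferred graph against one true graph."""

    tp: int
    fp: int
    fn: int
    precision: float | None
    recall: float | None
    f1: float | None
    entirely_correct: bool
    path_counts: pd.DataFrame = field(repr=False)

    def as_row(self) -> dict:
        row = {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "entirely_correct": self.entirely_correct,
        }
        for t in PATH_TYPES:
            for col in ("tp", "fp", "fn", "inferred", "true"):
                row[f"{t}:{col}"] = int(self.path_counts.loc[t, col])
        return row


def evaluate_graph(
    g: MigrationGraph, g_star: MigrationGraph, semantics: str = "multiset"
) -> EvalReport:
    tp, fp, fn = compare_graphs(g, g_star, semantics)
    precision, recall, f1 = f1_score(tp, fp, fn) if tp + fp + fn else (None,) * 3
    return EvalReport(
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f1=f1,
        entirely_correct=(fp == 0 and fn == 0),
        path_counts=path_type_counts(g, g_star, g_star.primary, semantics),
    )


# ---------------------------------------------------------------------------
# aggregation and significance tests

def _ztest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample Z-test on means with unpooled sample variances."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    if se == 0:
        z = 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
    else:
        z = (a.mean() - b.mean()) / se
    p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
    return float(z), float(p)


def aggregate_benchmark(
    reports: pd.DataFrame,
    group_keys: tuple[str, ...] = ("method", "scenario"),
    value: str = "f1",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group means plus pairwise tests between groups of the last key.

    ``reports`` must hold one row per (dataset x method) with at least the
    ``group_keys`` columns and the ``value`` column. Returns
    ``(summary, tests)``: per-group mean/sd/n, and for each slice of the
    leading keys, a two-sample Z-test and a Welch t-test between every
    pair of levels of the final grouping key. Groups with fewer than two
    observations are skipped with a notice column.
    """
    df = reports.dropna(subset=[value])
    summary = (
        df.groupby(list(group_keys))[value]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    lead, last = list(group_keys[:-1]), group_keys[-1]
    rows = []
    slices = df.groupby(lead) if lead else [((), df)]
    for lead_vals, sub in slices:
        if not isinstance(lead_vals, tuple):
            lead_vals = (lead_vals,)
        levels = sorted(sub[last].unique())
        for x, y in combinations(levels, 2):
            a = sub.loc[sub[last] == x, value].to_numpy(float)
            b = sub.loc[sub[last] == y, value].to_numpy(float)
            row = dict(zip(lead, lead_vals))
            row.update({f"{last}_a": x, f"{last}_b": y, "n_a": len(a), "n_b": len(b)})
            if len(a) < 2 or len(b) < 2:
                row.update(z=np.nan, p_z=np.nan, t=np.nan, p_t=np.nan,
                           note="skipped: <2 observations in a group")
            else:
                z, pz = _ztest(a, b)
                with warnings.catch_warnings():
                    # zero-variance groups make scipy warn about precision
                    # loss; the degenerate t is still reported as-is
                    warnings.simplefilter("ignore", RuntimeWarning)
                    t, pt = stats.ttest_ind(a, b, equal_var=False)
                row.update(z=z, p_z=pz, t=float(t), p_t=float(pt), note="")
            rows.append(row)
    tests = pd.DataFrame(rows)
    return summary, tests
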