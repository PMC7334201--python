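"""fSNP-calling statistics for the Reel-seq screen.

For every SNP the screen computes, per replicate library, the raw read-count
ratio of the risk allele over a non-risk allele.  A functional SNP binds a
regulatory protein allele-imbalancedly, so selection changes this ratio in
the nuclear-extract samples but not in the buffer controls.  Two filters
are applied, in the order the screen defines them:

1. a two-tailed pooled-variance Student's t-test comparing the five
   control ratios with the five sample ratios at the final sequenced cycle
   (df = 8), with no multiple-testing correction by default;
2. the *slope*: the ordinary least-squares slope, over sequenced cycles
   (x = 1, 4, 7, 10), of the normalized ratio — the mean sample ratio
   divided by the mean control ratio at each cycle.

Classification: *candidate* fSNP if p < 0.05 and |slope| > 0.05 (strict);
*putative* fSNP if p < 0.05 but |slope| ≤ 0.05; *non-fSNP* otherwise.
Multi-allelic SNPs are analysed as risk allele versus each non-risk allele
separately; the SNP-level class is the strongest per-pair call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .counting import CountMatrix, qc_complete
from .library import LibraryDefinition

__all__ = [
    "SnpScreenResult",
    "ScreenReport",
    "ScreenError",
    "CLASSES",
    "allele_ratio",
    "ttest_cycle10",
    "normalized_trajectory",
    "fit_slope",
    "classify",
    "replicate_correlation",
    "run_screen",
]

CLASSES = ("candidate", "putative", "non_fSNP")
_CLASS_PRIORITY = {"candidate": 0, "putative": 1, "non_fSNP": 2}


class ScreenError(ValueError):
    """Invalid input to the screen statistics."""


@dataclass
class SnpScreenResult:
    """Per-(SNP, allele-pair) screen outcome."""

    snp_id: str
    risk_allele: str
    nonrisk_allele: str
    control_ratios_c10: np.ndarray
    sample_ratios_c10: np.ndarray
    p_value: float
    norm_ratio: np.ndarray  # one per sequenced cycle
    slope: float
    classification: str


@dataclass
class ScreenReport:
    """Full screen output: per-pair results, per-SNP classes, QC, and the
    replicate-correlation diagnostics."""

    results: pd.DataFrame
    snp_classes: pd.Series
    class_counts: dict[str, int]
    replicate_r2: dict[str, float]
    dropped: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def n_analyzed(self) -> int:
        return len(self.snp_classes)


def allele_ratio(count_risk: float, count_nonrisk: float) -> float:
    """Raw risk/non-risk count ratio; the denominator must be positive
    (guaranteed for QC-passing SNPs)."""
    if count_nonrisk <= 0:
        raise ScreenError(
            "non-risk allele count is zero; SNP should have been removed by QC"
        )
    return count_risk / count_nonrisk


def ttest_cycle10(
    control_ratios: Sequence[float], sample_ratios: Sequence[float]
) -> float:
    """Two-tailed pooled-variance (classic Student's) two-sample t-test.

    df = n1 + n2 − 2.  Degenerate zero-variance inputs: p = 1 when the
    group means are equal, else 0.0 (underflow sentinel for an infinite
    t statistic).
    """
    a = np.asarray(control_ratios, dtype=float)
    b = np.asarray(sample_ratios, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ScreenError("each group needs at least two replicates")
    df = a.size + b.size - 2
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if pooled == 0:
        return 1.0 if diff == 0 else 0.0
    t = diff / math.sqrt(pooled * (1 / a.size + 1 / b.size))
    return 2.0 * float(stats.t.sf(abs(t), df))


def normalized_trajectory(
    cm: CountMatrix,
    snp_id: str,
    allele_pair: tuple[str, str],
    cycles: Sequence[int] = (1, 4, 7, 10),
) -> np.ndarray:
    """Normalized ratio per cycle: mean(sample risk/non-risk ratios) ÷
    mean(control ratios), over the replicate libraries of that cycle."""
    risk, nonrisk = allele_pair
    out = np.empty(len(cycles))
    for k, cyc in enumerate(cycles):
        try:
            sample = cm.counts(cyc, "sample")
            control = cm.counts(cyc, "control")
        except KeyError as exc:
            raise ScreenError(f"cycle {cyc} missing from count matrix") from exc
        s = (
            sample.loc[(snp_id, risk)].to_numpy(dtype=float)
            / sample.loc[(snp_id, nonrisk)].to_numpy(dtype=float)
        )
        c = (
            control.loc[(snp_id, risk)].to_numpy(dtype=float)
            / control.loc[(snp_id, nonrisk)].to_numpy(dtype=float)
        )
        out[k] = s.mean() / c.mean()
    return out


def fit_slope(
    norm_ratio: Sequence[float], cycles: Sequence[int] = (1, 4, 7, 10)
) -> float:
    """OLS slope of the normalized ratio against cycle number
    (units: normalized ratio per cycle)."""
    y = np.asarray(norm_ratio, dtype=float)
    x = np.asarray(cycles, dtype=float)
    if not np.isfinite(y).all():
        raise ScreenError("non-finite normalized ratios")
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


def classify(
    p_value: float, slope: float, alpha: float = 0.05, slope_cut: float = 0.05
) -> str:
    """Three-way call from the two empirical cutoffs (strict inequalities)."""
    if p_value < alpha:
        return "candidate" if abs(slope) > slope_cut else "putative"
    return "non_fSNP"


def replicate_correlation(
    cm: CountMatrix,
    lib: LibraryDefinition,
    cycle: int = 10,
) -> dict[str, float]:
    """Technical-replicate agreement: squared Pearson correlation, between
    consecutive replicate pairs, of the per-SNP sample/control ratio
    vectors at one cycle."""
    ratios = _pair_ratio_matrix(cm, lib)
    try:
        sample = ratios.xs((cycle, "sample"), axis=1, level=("cycle", "condition"))
        control = ratios.xs((cycle, "control"), axis=1, level=("cycle", "condition"))
    except KeyError as exc:
        raise ScreenError(f"cycle {cycle} missing from count matrix") from exc
    if len(ratios) < 2:
        raise ScreenError("replicate correlation needs at least two SNPs")
    norm = sample.to_numpy() / control.to_numpy()
    out = {}
    reps = sorted(sample.columns)
    for i, j in zip(reps, reps[1:]):
        r = np.corrcoef(norm[:, reps.index(i)], norm[:, reps.index(j)])[0, 1]
        out[f"{i}/{j}"] = float(r**2)
    return out


def _build_pairs(
    lib: LibraryDefinition, snp_ids: Sequence[str]
) -> list[tuple[str, str, str]]:
    present = set(snp_ids)
    pairs = []
    for rec in lib.records:
        if rec.snp_id in present:
            for other in rec.nonrisk_alleles:
                pairs.append((rec.snp_id, rec.risk_allele, other))
    return pairs


def _pair_ratio_matrix(cm: CountMatrix, lib: LibraryDefinition) -> pd.DataFrame:
    """Risk/non-risk ratio per (snp, pair) row × library column."""
    pairs = _build_pairs(lib, cm.snp_ids)
    if not pairs:
        return pd.DataFrame(
            index=pd.MultiIndex.from_arrays([[], [], []],
                                            names=["snp_id", "risk", "nonrisk"]),
            columns=cm.df.columns,
            dtype=float,
        )
    risk_rows = cm.df.loc[[(s, r) for s, r, _ in pairs]].to_numpy(dtype=float)
    non_rows = cm.df.loc[[(s, n) for s, _, n in pairs]].to_numpy(dtype=float)
    if (non_rows <= 0).any():
        raise ScreenError("zero non-risk counts; run qc_complete first")
    idx = pd.MultiIndex.from_tuples(pairs, names=["snp_id", "risk", "nonrisk"])
    return pd.DataFrame(risk_rows / non_rows, index=idx, columns=cm.df.columns)


def run_screen(
    cm: CountMatrix,
    lib: LibraryDefinition,
    alpha: float = 0.05,
    slope_cut: float = 0.05,
    min_count: int = 1,
    test_cycle: int = 10,
    cycles: Sequence[int] = (1, 4, 7, 10),
    slope_x: str = "cycle",
    welch: bool = False,
    log_ratios: bool = False,
    bh_correction: bool = False,
) -> ScreenReport:
    """Run the full screen pipeline on a count matrix.

    qc_complete → per-pair ratios → t-test at ``test_cycle`` →
    normalized trajectory over ``cycles`` → slope → classification.
    ``slope_x="rank"`` regresses against cycle rank (1..k) instead of
    cycle number; ``welch`` switches to the unequal-variance t-test;
    ``log_ratios`` log-transforms the per-replicate ratios before the
    t-test; ``bh_correction`` adds a Benjamini–Hochberg q-value column
    (classification still uses the raw p, as the screen defines it).
    """
    retained, dropped = qc_complete(cm, min_count=min_count)
    ratios = _pair_ratio_matrix(retained, lib)
    n_pairs = len(ratios)
    cyc_arr = np.asarray(cycles, dtype=float)

    if n_pairs == 0:
        results = pd.DataFrame(
            columns=[
                "snp_id", "risk_allele", "nonrisk_allele", "p_value",
                *[f"norm_ratio_c{int(c)}" for c in cycles], "slope",
                "classification",
            ]
        )
        return ScreenReport(
            results=results,
            snp_classes=pd.Series(dtype=object),
            class_counts={c: 0 for c in CLASSES},
            replicate_r2={},
            dropped=dropped,
            params={"alpha": alpha, "slope_cut": slope_cut},
        )

    try:
        ctrl = ratios.xs((test_cycle, "control"), axis=1,
                         level=("cycle", "condition")).to_numpy()
        samp = ratios.xs((test_cycle, "sample"), axis=1,
                         level=("cycle", "condition")).to_numpy()
    except KeyError as exc:
        raise ScreenError(f"cycle {test_cycle} missing from count matrix") from exc
    if log_ratios:
        ctrl, samp = np.log(ctrl), np.log(samp)
    p_values = _ttest_rows(ctrl, samp, welch=welch)

    traj = np.empty((n_pairs, len(cycles)))
    for k, cyc in enumerate(cycles):
        try:
            s = ratios.xs((cyc, "sample"), axis=1, level=("cycle", "condition"))
            c = ratios.xs((cyc, "control"), axis=1, level=("cycle", "condition"))
        except KeyError as exc:
            raise ScreenError(f"cycle {cyc} missing from count matrix") from exc
        traj[:, k] = s.mean(axis=1).to_numpy() / c.mean(axis=1).to_numpy()

    x = cyc_arr if slope_x == "cycle" else np.arange(1, len(cycles) + 1, dtype=float)
    xc = x - x.mean()
    slopes = (traj - traj.mean(axis=1, keepdims=True)) @ xc / (xc @ xc)

    cls = np.where(
        p_values < alpha,
        np.where(np.abs(slopes) > slope_cut, "candidate", "putative"),
        "non_fSNP",
    )

    results = pd.DataFrame(
        {
            "snp_id": ratios.index.get_level_values("snp_id"),
            "risk_allele": ratios.index.get_level_values("risk"),
            "nonrisk_allele": ratios.index.get_level_values("nonrisk"),
            "p_value": p_values,
        }
    )
    for k, cyc in enumerate(cycles):
        results[f"norm_ratio_c{int(cyc)}"] = traj[:, k]
    results["slope"] = slopes
    results["classification"] = cls
    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        results["q_value"] = multipletests(p_values, method="fdr_bh")[1]

    # SNP-level class = strongest per-pair call
    prio = results["classification"].map(_CLASS_PRIORITY)
    best = results.assign(_prio=prio).groupby("snp_id", sort=False)["_prio"].min()
    inv = {v: k for k, v in _CLASS_PRIORITY.items()}
    snp_classes = best.map(inv)
    class_counts = {c: int((snp_classes == c).sum()) for c in CLASSES}

    try:
        rep_r2 = replicate_correlation(retained, lib, cycle=test_cycle)
    except ScreenError:
        rep_r2 = {}

    return ScreenReport(
        results=results,
        snp_classes=snp_classes,
        class_counts=class_counts,
        replicate_r2=rep_r2,
        dropped=dropped,
        params={
            "alpha": alpha,
            "slope_cut": slope_cut,
            "min_count": min_count,
            "test_cycle": test_cycle,
            "cycles": list(cycles),
            "slope_x": slope_x,
            "welch": welch,
            "log_ratios": log_ratios,
        },
    )


def _ttest_rows(a: np.ndarray, b: np.ndarray, welch: bool = False) -> np.ndarray:
    """Row-wise two-sample two-tailed t-test (pooled or Welch)."""
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    diff = m1 - m2
    if welch:
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = pooled * (1 / n1 + 1 / n2)
        df = np.full(a.shape[0], n1 + n2 - 2, dtype=float)
    p = np.empty(a.shape[0])
    zero = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    p[~zero] = 2.0 * stats.t.sf(np.abs(t[~zero]), df[~zero])
    p[zero] = np.where(diff[zero] == 0, 1.0, 0.0)
    return p
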