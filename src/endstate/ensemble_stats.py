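"""Replica aggregation, ranking metrics, outlier flagging, and bootstrap
replica-sufficiency analysis.

The sampling protocol follows the ensemble-of-short-replicas design: many
independent replicas, an equilibration span discarded from each, and frames
taken at a fixed stride (defaults: 25 replicas × 4 ns, last 3 ns, 10 ps →
300 frames/replica, 7500 frames/complex). Per-variant uncertainty is the
standard deviation over per-replica means, and bootstrap resampling is done
at the replica level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import FrameSchedule


def select_frames(
    replica_length_ns: float = 4.0,
    discard_ns: float = 1.0,
    stride_ps: float = 10.0,
) -> np.ndarray:
    """Snapshot times (ps) retained from one replica.

    Frames fall every ``stride_ps`` across the post-discard span, ending at
    the replica end; the defaults give 300 frames per replica.
    """
    if discard_ns >= replica_length_ns:
        raise ValueError("discard must be shorter than the replica")
    span_ps = (replica_length_ns - discard_ns) * 1000.0
    if stride_ps > span_ps:
        raise ValueError("stride exceeds the retained span: empty schedule")
    n = int(round(span_ps / stride_ps))
    return discard_ns * 1000.0 + stride_ps * np.arange(1, n + 1)


@dataclass
class ReplicaEnergyMatrix:
    """Per-frame total ΔG_bind, shaped replica × frame, for one variant."""

    variant_id: str
    values: np.ndarray  # (n_replicas, n_frames)
    schedule: FrameSchedule = field(default_factory=FrameSchedule)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.size == 0:
            raise ValueError("empty energy matrix")


def aggregate_variant(
    matrix: ReplicaEnergyMatrix,
) -> tuple[float, np.ndarray, float]:
    """(grand mean ΔG, per-replica means, SD over replica means).

    The SD uses the n−1 denominator over replica means; with a single
    replica it is NaN (flagged, not zero).
    """
    per_replica = matrix.values.mean(axis=1)
    mean = float(per_replica.mean())
    sd = float(per_replica.std(ddof=1)) if per_replica.size > 1 else float("nan")
    return mean, per_replica, sd


def delta_delta_g(
    dg: dict[str, float], reference_id: str
) -> dict[str, float]:
    """ΔΔG_v = ΔG_v − ΔG_ref; the reference maps to exactly 0."""
    if reference_id not in dg:
        raise KeyError(f"reference variant {reference_id!r} missing")
    ref = dg[reference_id]
    return {v: g - ref for v, g in dg.items()}


@dataclass
class RankingMetrics:
    r_pearson: float
    r_spearman: float
    mad: float
    slope: float
    intercept: float


def ranking_metrics(
    ddg_calc: np.ndarray, ddg_exp: np.ndarray
) -> RankingMetrics:
    """Pearson r, Spearman ρ (average ranks on ties), and the mean absolute
    deviation of residuals about the OLS line of calc vs exp."""
    calc = np.asarray(ddg_calc, dtype=np.float64)
    exp = np.asarray(ddg_exp, dtype=np.float64)
    if calc.size != exp.size or calc.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.isclose(calc.std(), 0.0) or np.isclose(exp.std(), 0.0):
        raise ValueError("zero variance: correlation undefined")
    r_p = float(stats.pearsonr(calc, exp).statistic)
    r_s = float(stats.spearmanr(calc, exp).statistic)
    slope, intercept = np.polyfit(exp, calc, 1)
    residuals = calc - (slope * exp + intercept)
    return RankingMetrics(
        r_pearson=r_p,
        r_spearman=r_s,
        mad=float(np.mean(np.abs(residuals))),
        slope=float(slope),
        intercept=float(intercept),
    )


def flag_outliers(
    ddg_calc: np.ndarray,
    ddg_exp: np.ndarray,
    variant_ids: list[str] | None = None,
    z_threshold: float = 2.0,
) -> tuple[list[str], np.ndarray]:
    """Outliers by standardized residuals from the calc-vs-exp OLS line.

    Returns the flagged ids (or stringified indices) and all standardized
    residuals. Points with |z| > ``z_threshold`` are flagged.
    """
    calc = np.asarray(ddg_calc, dtype=np.float64)
    exp = np.asarray(ddg_exp, dtype=np.float64)
    if calc.size < 4:
        raise ValueError("need >= 4 points for outlier analysis")
    ids = variant_ids or [str(i) for i in range(calc.size)]
    slope, intercept = np.polyfit(exp, calc, 1)
    residuals = calc - (slope * exp + intercept)
    sd = residuals.std(ddof=2)  # two params fitted
    # collinear data: residuals are fp noise, nothing is an outlier
    scale = max(np.abs(calc).max(), np.abs(exp).max(), 1.0)
    if sd <= 1e-10 * scale:
        z = np.zeros_like(residuals)
    else:
        z = residuals / sd
    flagged = [ids[i] for i in np.where(np.abs(z) > z_threshold)[0]]
    return flagged, z


@dataclass
class RankingReport:
    """Per-variant ΔΔG statistics, quality metrics, outliers, bootstrap CIs."""

    table: pd.DataFrame  # variant_id, ddg_calc, sd, ddg_exp, z, outlier
    metrics: RankingMetrics
    metrics_without_outliers: RankingMetrics | None = None
    bootstrap: pd.DataFrame | None = None


def build_ranking_report(
    per_replica_dg: dict[str, np.ndarray],
    ddg_exp: dict[str, float],
    reference_id: str,
    z_threshold: float = 2.0,
) -> RankingReport:
    """Aggregate replica means into a ΔΔG ranking report with outlier flags.

    ``per_replica_dg`` maps variant id → per-replica mean ΔG. Metrics are
    reported both with and without the flagged outliers when at least three
    points remain.
    """
    variants = sorted(per_replica_dg)
    dg = {v: float(np.mean(per_replica_dg[v])) for v in variants}
    ddg = delta_delta_g(dg, reference_id)
    sds = {
        v: float(np.std(per_replica_dg[v], ddof=1))
        if len(per_replica_dg[v]) > 1
        else float("nan")
        for v in variants
    }
    others = [v for v in variants if v != reference_id]
    calc = np.array([ddg[v] for v in others])
    exp = np.array([ddg_exp[v] for v in others])
    metrics = ranking_metrics(calc, exp)
    flagged, z = flag_outliers(calc, exp, others, z_threshold)
    metrics_wo = None
    keep = [i for i, v in enumerate(others) if v not in flagged]
    if flagged and len(keep) >= 3:
        metrics_wo = ranking_metrics(calc[keep], exp[keep])
    zmap = dict(zip(others, z))
    table = pd.DataFrame(
        {
            "variant_id": variants,
            "ddg_calc": [ddg[v] for v in variants],
            "sd": [sds[v] for v in variants],
            "ddg_exp": [
                0.0 if v == reference_id else ddg_exp[v] for v in variants
            ],
            "z_residual": [zmap.get(v, 0.0) for v in variants],
            "outlier": [v in flagged for v in variants],
        }
    )
    return RankingReport(table=table, metrics=metrics, metrics_without_outliers=metrics_wo)


def _pearson_rows(calc: np.ndarray, exp: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r of a (B, V) matrix against one length-V vector."""
    cm = calc - calc.mean(axis=1, keepdims=True)
    em = exp - exp.mean()
    denom = np.sqrt((cm**2).sum(axis=1) * (em**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (cm @ em) / denom


def bootstrap_replica_sweep(
    per_replica_dg: dict[str, np.ndarray],
    ddg_exp: dict[str, float],
    reference_id: str,
    replica_counts: list[int] | None = None,
    n_resamples: int = 1_000_000,
    seed: int = 0,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Bootstrap mean and percentile CI of r_s/r_p versus replica count.

    For each count k, replicas are resampled with replacement independently
    per variant, per-variant ΔG is the mean of the k sampled replica means,
    ΔΔG is taken against the reference, and both correlations against
    experiment are recorded. Resamples where the calculated ΔΔG vector is
    degenerate (zero variance) are skipped and counted.

    Deterministic for a fixed ``seed``.
    """
    variants = sorted(per_replica_dg)
    others = [v for v in variants if v != reference_id]
    if reference_id not in variants:
        raise KeyError(f"reference {reference_id!r} missing")
    exp = np.array([ddg_exp[v] for v in others])
    arrays = {v: np.asarray(per_replica_dg[v], dtype=np.float64) for v in variants}
    n_rep = min(len(a) for a in arrays.values())
    if replica_counts is None:
        replica_counts = [k for k in (1, 2, 5, 10, 15, 20, 25) if k <= n_rep]
    rng = np.random.default_rng(seed)
    rows = []
    alpha = (1.0 - confidence) / 2.0
    for k in replica_counts:
        if k < 1 or k > n_rep:
            raise ValueError(f"replica count {k} out of range [1, {n_rep}]")
        # independent resampling per variant, including the reference
        dg = np.empty((n_resamples, len(others)))
        idx_ref = rng.integers(0, len(arrays[reference_id]), size=(n_resamples, k))
        dg_ref = arrays[reference_id][idx_ref].mean(axis=1)
        for j, v in enumerate(others):
            idx = rng.integers(0, len(arrays[v]), size=(n_resamples, k))
            dg[:, j] = arrays[v][idx].mean(axis=1)
        ddg = dg - dg_ref[:, None]
        valid = ddg.std(axis=1) > 0
        n_skipped = int((~valid).sum())
        ddg_v = ddg[valid]
        r_p = _pearson_rows(ddg_v, exp)
        ranks_calc = stats.rankdata(ddg_v, axis=1)
        ranks_exp = stats.rankdata(exp)
        r_s = _pearson_rows(ranks_calc, ranks_exp)
        for name, vals in (("r_s", r_s), ("r_p", r_p)):
            vals = vals[np.isfinite(vals)]
            rows.append(
                {
                    "n_replicas": k,
                    "metric": name,
                    "mean": float(vals.mean()) if vals.size else float("nan"),
                    "ci_lo": float(np.percentile(vals, 100 * alpha))
                    if vals.size
                    else float("nan"),
                    "ci_hi": float(np.percentile(vals, 100 * (1 - alpha)))
                    if vals.size
                    else float("nan"),
                    "n_skipped": n_skipped,
                }
            )
    return pd.DataFrame(rows)
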