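"""Structure-similarity scores and QA-evaluation statistics.

GDT-TS and TM-score use an LGA-style iterative superposition search (seed
fragments, superpose, keep residues within the distance cutoff, repeat to a
fixed point, take the best over seeds). Evaluation statistics follow the
conventions of blind QA assessment: per-target Pearson correlation between
predicted and real scores, per-target loss of the top-ranked model, best-of-
top-k selection, pool-standardized Z-score sums and Wilcoxon signed-rank
significance between paired per-target metrics.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from modelqa.geometry import Superposition, kabsch_superpose
from modelqa.structure_model import ProteinModel

GDT_THRESHOLDS = (1.0, 2.0, 4.0, 8.0)
TM_D0_FLOOR = 0.5  # Å, keeps d0 positive for chains of <= ~24 residues
LOCAL_GLOBAL_D0 = 5.0  # Å, distance scale of the local->global conversion


@dataclass
class QualityRecord:
    """Predicted and (optionally) true quality of one model."""

    model_id: str
    predicted: float
    gdt_ts: Optional[float] = None
    tm_score: Optional[float] = None
    rmsd: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.predicted <= 1.0:
            raise ValueError(f"{self.model_id}: predicted {self.predicted} outside [0, 1]")
        if self.gdt_ts is not None and not 0.0 <= self.gdt_ts <= 1.0:
            raise ValueError(f"{self.model_id}: GDT-TS {self.gdt_ts} outside [0, 1]")
        if self.tm_score is not None and not 0.0 < self.tm_score <= 1.0:
            raise ValueError(f"{self.model_id}: TM-score {self.tm_score} outside (0, 1]")
        if self.rmsd is not None and self.rmsd < 0:
            raise ValueError(f"{self.model_id}: negative RMSD")


def _check_compatible(model: ProteinModel, native: ProteinModel) -> None:
    if model.length != native.length:
        raise ValueError(
            f"length mismatch: model {model.model_id} has {model.length} residues, "
            f"native {native.length}"
        )


def _iterative_superpositions(
    ca_model: np.ndarray, ca_native: np.ndarray, cutoffs: Sequence[float],
    max_iter: int = 30,
) -> List[Superposition]:
    """LGA-style seed-and-extend search for near-optimal superpositions.

    Seeds are the full chain plus every 3-residue window. For each seed and
    cutoff the superposition is iterated: superpose on the current subset,
    keep all residues within the cutoff, repeat until the subset stabilizes.
    All fixed-point superpositions are returned for scoring.
    """
    L = len(ca_model)
    seeds = [np.arange(L)]
    if L <= 12:
        # Short chains: every 3-residue combination is affordable and makes
        # the search near-exhaustive.
        seeds.extend(np.array(c) for c in itertools.combinations(range(L), 3))
    else:
        for start in range(L - 2):
            seeds.append(np.arange(start, start + 3))
    out: List[Superposition] = []
    seen = set()

    def record(sup: Superposition) -> None:
        key = (round(float(sup.rotation[0, 0]), 6), round(float(sup.translation[0]), 4),
               round(float(sup.rotation[2, 1]), 6))
        if key not in seen:
            seen.add(key)
            out.append(sup)

    for seed in seeds:
        # Progressive extension: superpose on the n best-fitting residues,
        # growing n one residue at a time and re-superposing at each step.
        sup = kabsch_superpose(ca_native[seed], ca_model[seed])
        record(sup)
        for n in range(3, L + 1):
            dev = np.linalg.norm(sup.apply(ca_model) - ca_native, axis=1)
            subset = np.argsort(dev, kind="stable")[:n]
            sup = kabsch_superpose(ca_native[subset], ca_model[subset])
            record(sup)
        # Cutoff-driven fixed-point iteration, one run per distance cutoff.
        for d in cutoffs:
            subset = seed
            for _ in range(max_iter):
                sup = kabsch_superpose(ca_native[subset], ca_model[subset])
                record(sup)
                dev = np.linalg.norm(sup.apply(ca_model) - ca_native, axis=1)
                new_subset = np.where(dev <= d)[0]
                if len(new_subset) < 3:
                    break
                if len(new_subset) == len(subset) and np.array_equal(new_subset, subset):
                    break
                subset = new_subset
    return out


def gdt_ts(model: ProteinModel, native: ProteinModel) -> float:
    """Global Distance Test Total Score in [0, 1].

    For each cutoff d in {1, 2, 4, 8} Å the search looks for the largest
    residue subset that superposes with all CA deviations <= d; GDT-TS is
    the mean of the four largest fractions. The search is a deterministic
    heuristic (seeded iterative extension), so values are a lower bound on
    the exhaustive optimum.
    """
    _check_compatible(model, native)
    ca_m = model.ca_coords()
    ca_n = native.ca_coords()
    L = model.length
    sups = _iterative_superpositions(ca_m, ca_n, GDT_THRESHOLDS)
    best = {d: 0.0 for d in GDT_THRESHOLDS}
    for sup in sups:
        dev = np.linalg.norm(sup.apply(ca_m) - ca_n, axis=1)
        for d in GDT_THRESHOLDS:
            frac = float((dev <= d).mean())
            if frac > best[d]:
                best[d] = frac
    return float(np.mean([best[d] for d in GDT_THRESHOLDS]))


def tm_d0(L: int) -> float:
    """TM-score distance scale d0 = 1.24 (L-15)^(1/3) - 1.8, floored at 0.5 Å."""
    if L > 15:
        d0 = 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8
    else:
        d0 = TM_D0_FLOOR
    return max(d0, TM_D0_FLOOR)


def tm_score(model: ProteinModel, native: ProteinModel) -> float:
    """Template-modeling score in (0, 1], length-normalized by the native length.

    Maximizes (1/L) sum 1/(1 + (d_i/d0)^2) over the superpositions found by
    the same seed-and-extend search as GDT-TS (with d0 added to the cutoff
    list), which recovers 1.0 for identical structures.
    """
    _check_compatible(model, native)
    ca_m = model.ca_coords()
    ca_n = native.ca_coords()
    L = model.length
    d0 = tm_d0(L)
    cutoffs = tuple(GDT_THRESHOLDS) + (d0,)
    best = 0.0
    for sup in _iterative_superpositions(ca_m, ca_n, cutoffs):
        dev = np.linalg.norm(sup.apply(ca_m) - ca_n, axis=1)
        score = float(np.mean(1.0 / (1.0 + (dev / d0) ** 2)))
        if score > best:
            best = score
    return best


def rmsd(model: ProteinModel, native: ProteinModel) -> float:
    """CA RMSD (Å) after optimal superposition on all residues."""
    _check_compatible(model, native)
    return kabsch_superpose(native.ca_coords(), model.ca_coords()).rmsd


def per_target_correlation(records: Sequence[QualityRecord]) -> Optional[float]:
    """Pearson correlation between predicted and true GDT-TS over one pool.

    Returns None (excluded from averages) when fewer than 3 scored models
    exist or either side has zero variance.
    """
    pairs = [(r.predicted, r.gdt_ts) for r in records if r.gdt_ts is not None]
    if len(pairs) < 3:
        return None
    pred, true = map(np.array, zip(*pairs))
    if pred.std() == 0.0 or true.std() == 0.0:
        return None
    return float(stats.pearsonr(pred, true).statistic)


def _rank_by_prediction(records: Sequence[QualityRecord]) -> List[QualityRecord]:
    """Descending by predicted score; ties broken by model id for reproducibility."""
    return sorted(records, key=lambda r: (-r.predicted, r.model_id))


def per_target_loss(records: Sequence[QualityRecord]) -> float:
    """True GDT-TS of the pool best minus that of the top-ranked model."""
    scored = [r for r in records if r.gdt_ts is not None]
    if not scored:
        raise ValueError("no records with true GDT-TS")
    best_true = max(r.gdt_ts for r in scored)
    top = _rank_by_prediction(scored)[0]
    return float(best_true - top.gdt_ts)


def top_k_selection(records: Sequence[QualityRecord], k: int = 5):
    """Best true TM-score and RMSD among the k highest-predicted models.

    Returns ``(best_tm, best_rmsd)``; either is None when the corresponding
    truth is absent. k larger than the pool uses the whole pool (warns).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(records):
        warnings.warn(f"k={k} exceeds pool size {len(records)}; using full pool", stacklevel=2)
        k = len(records)
    top = _rank_by_prediction(records)[:k]
    tms = [r.tm_score for r in top if r.tm_score is not None]
    rms = [r.rmsd for r in top if r.rmsd is not None]
    best_tm = max(tms) if tms else None
    best_rmsd = min(rms) if rms else None
    return best_tm, best_rmsd


def zscore_sum(selected: Sequence[float], pools: Sequence[Sequence[float]]) -> float:
    """Sum over targets of the selected model's pool-standardized Z-score.

    Standardization uses the population standard deviation of the pool's
    true scores; degenerate pools (zero spread) contribute 0. For TM-score
    good selections push the sum positive, for RMSD negative.
    """
    if len(selected) != len(pools):
        raise ValueError("one selected value per pool required")
    total = 0.0
    for sel, pool in zip(selected, pools):
        arr = np.asarray(pool, dtype=float)
        std = float(arr.std())  # population std
        if std > 0.0:
            total += (float(sel) - float(arr.mean())) / std
    return total


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float]) -> Tuple[float, bool]:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped; tied absolute differences get mid-ranks.
    With n <= 12 non-zero pairs the exact null distribution is enumerated
    over all 2^n sign assignments; larger n uses the normal approximation
    with continuity and tie corrections. Returns ``(p, degenerate)`` where
    degenerate flags the all-zero-differences case (p reported as 1.0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return 1.0, True
    ranks = stats.rankdata(np.abs(d))
    t_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    if n <= 12:
        # Exact two-sided tail by enumeration of every sign assignment.
        observed_dev = abs(t_plus - mu)
        count = 0
        for signs in itertools.product((0.0, 1.0), repeat=n):
            t = float(np.dot(signs, ranks))
            if abs(t - mu) >= observed_dev - 1e-12:
                count += 1
        return count / 2.0 ** n, False
    # Normal approximation with tie correction and continuity correction.
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts) / 48.0).sum())
    sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    if sigma == 0.0:
        return 1.0, True
    z = (abs(t_plus - mu) - 0.5) / sigma
    p = 2.0 * stats.norm.sf(z)
    return min(1.0, p), False


def local_to_global(local_distances: Sequence[float], L: Optional[int] = None) -> float:
    """Convert per-residue local error estimates (Å) to one global score.

    Global = (1/L) sum 1 / (1 + (local_i / 5)^2); 1.0 when every local
    error is zero, 0.5 when every local error equals 5 Å.
    """
    local = np.asarray(local_distances, dtype=float)
    if L is None:
        L = len(local)
    if L != len(local):
        raise ValueError(f"L={L} but {len(local)} local scores given")
    if (local < 0).any():
        raise ValueError("local distances must be non-negative")
    return float(np.mean(1.0 / (1.0 + (local / LOCAL_GLOBAL_D0) ** 2)))


@dataclass
class EvaluationReport:
    """Aggregated QA evaluation across targets."""

    per_target_r: Dict[str, Optional[float]] = field(default_factory=dict)
    per_target_loss: Dict[str, float] = field(default_factory=dict)
    top1_tm: Dict[str, Optional[float]] = field(default_factory=dict)
    top1_rmsd: Dict[str, Optional[float]] = field(default_factory=dict)
    top5_tm: Dict[str, Optional[float]] = field(default_factory=dict)
    top5_rmsd: Dict[str, Optional[float]] = field(default_factory=dict)
    zscore_sum_tm: Optional[float] = None
    zscore_sum_rmsd: Optional[float] = None

    @property
    def average_r(self) -> Optional[float]:
        vals = [v for v in self.per_target_r.values() if v is not None]
        return float(np.mean(vals)) if vals else None

    @property
    def average_loss(self) -> Optional[float]:
        vals = list(self.per_target_loss.values())
        return float(np.mean(vals)) if vals else None

    def summary(self) -> Dict[str, Optional[float]]:
        def _mean(d):
            vals = [v for v in d.values() if v is not None]
            return float(np.mean(vals)) if vals else None

        return {
            "n_targets": len(self.per_target_loss),
            "average_r": self.average_r,
            "average_loss": self.average_loss,
            "mean_top1_tm": _mean(self.top1_tm),
            "mean_top1_rmsd": _mean(self.top1_rmsd),
            "mean_top5_tm": _mean(self.top5_tm),
            "mean_top5_rmsd": _mean(self.top5_rmsd),
            "zscore_sum_tm": self.zscore_sum_tm,
            "zscore_sum_rmsd": self.zscore_sum_rmsd,
        }


def evaluate_targets(records_by_target: Dict[str, Sequence[QualityRecord]],
                     k: int = 5) -> EvaluationReport:
    """Full evaluation of one QA method over a set of per-target pools."""
    report = EvaluationReport()
    tm_selected, tm_pools = [], []
    rmsd_selected, rmsd_pools = [], []
    for target, records in records_by_target.items():
        records = list(records)
        report.per_target_r[target] = per_target_correlation(records)
        report.per_target_loss[target] = per_target_loss(records)
        t1_tm, t1_rmsd = top_k_selection(records, k=1)
        t5_tm, t5_rmsd = top_k_selection(records, k=min(k, len(records)))
        report.top1_tm[target] = t1_tm
        report.top1_rmsd[target] = t1_rmsd
        report.top5_tm[target] = t5_tm
        report.top5_rmsd[target] = t5_rmsd
        tms = [r.tm_score for r in records if r.tm_score is not None]
        if t1_tm is not None and len(tms) == len(records):
            tm_selected.append(_selected_true(records, "tm_score"))
            tm_pools.append(tms)
        rms = [r.rmsd for r in records if r.rmsd is not None]
        if t1_rmsd is not None and len(rms) == len(records):
            rmsd_selected.append(_selected_true(records, "rmsd"))
            rmsd_pools.append(rms)
    if tm_pools:
        report.zscore_sum_tm = zscore_sum(tm_selected, tm_pools)
    if rmsd_pools:
        report.zscore_sum_rmsd = zscore_sum(rmsd_selected, rmsd_pools)
    return report


def _selected_true(records: Sequence[QualityRecord], attr: str) -> float:
    return getattr(_rank_by_prediction(records)[0], attr)
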