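"""Window aggregation and stratified dataset partitioning.

Per-pulse features are reduced to per-feature medians over consecutive
non-overlapping 60-s windows of session wall-clock time, paired with the mean
of the retained invasive ICP samples in the same window. Windows with too few
pulses or with mean ICP outside the 5-40 mmHg inclusion range are dropped.
Because ICP in sedated patients is heavily skewed toward normal values, the
train/validation/test partition is stratified over 5-mmHg ICP bins so every
pressure level is represented in every split.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .core import FEATURE_NAMES, Dataset, WindowObservation
from .preprocessing import CleanSegment

__all__ = ["build_windows", "stratified_split", "bin_index"]

logger = logging.getLogger(__name__)


def build_windows(
    records: list[tuple[float, dict[str, float]]],
    segments: list[CleanSegment],
    cfg: AnalysisConfig,
    patient_id: str,
) -> list[WindowObservation]:
    """Aggregate pulse records and retained ICP into window observations.

    ``records`` are ``(absolute_foot_time_s, features)`` pairs as produced by
    :func:`nicp.pulses.pulse_records`; ``segments`` carry the synchronously
    retained ICP. A window keeps consecutive-interval semantics even across
    removed gaps: window k covers wall-clock ``[k*window_s, (k+1)*window_s)``.
    """
    if not records:
        return []
    w = cfg.window_s

    df = pd.DataFrame([feats for _, feats in records], columns=list(FEATURE_NAMES))
    df["window"] = (np.array([t for t, _ in records]) // w).astype(np.int64)
    grouped = df.groupby("window")
    medians = grouped.median()
    counts = grouped.size()

    # mean retained ICP per window, accumulated across segments
    icp_sum: dict[int, float] = defaultdict(float)
    icp_n: dict[int, int] = defaultdict(int)
    for seg in segments:
        rate = seg.icp.rate
        idx = seg.start_index + np.arange(len(seg.icp))
        win = (idx / rate // w).astype(np.int64)
        uniq, start = np.unique(win, return_index=True)
        bounds = np.append(start, len(win))
        sums = np.add.reduceat(seg.icp.values, start)
        for u, s, n in zip(uniq, sums, np.diff(bounds)):
            icp_sum[int(u)] += float(s)
            icp_n[int(u)] += int(n)

    out: list[WindowObservation] = []
    for win in medians.index:
        n_pulses = int(counts.loc[win])
        if n_pulses < cfg.min_pulses_per_window or icp_n.get(int(win), 0) == 0:
            continue
        mean_icp = icp_sum[int(win)] / icp_n[int(win)]
        if not (cfg.icp_min_mmhg <= mean_icp <= cfg.icp_max_mmhg):
            continue
        out.append(
            WindowObservation(
                patient_id=patient_id,
                window_index=int(win),
                features={name: float(medians.loc[win, name]) for name in FEATURE_NAMES},
                mean_icp_mmhg=float(mean_icp),
                n_pulses=n_pulses,
            )
        )
    return out


def bin_index(icp: float, cfg: AnalysisConfig) -> int:
    """Stratification bin of an ICP value; the top edge folds into the last bin."""
    b = int((icp - cfg.icp_min_mmhg) // cfg.bin_width_mmhg)
    return min(max(b, 0), cfg.n_bins - 1)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(
    obs: list[WindowObservation],
    cfg: AnalysisConfig,
    seed: int | None = None,
    by_patient: bool = False,
) -> Dataset:
    """Partition observations into train/val/test, stratified by ICP bin.

    Within each 5-mmHg bin the observations are shuffled with the seeded
    generator; round(test_fraction*n) go to test (only when the bin holds at
    least 3 observations), then round(val_fraction*remaining) to validation
    and the rest to train, so every non-empty bin contributes to training.

    With ``by_patient`` the same stratified draw is applied to whole patients
    (binned by their median window ICP) instead of single windows — the
    leakage-free alternative, not the default.
    """
    if not obs:
        raise ValueError("cannot split an empty observation list")
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    labels = np.empty(len(obs), dtype=object)

    if by_patient:
        by_pid: dict[str, list[int]] = defaultdict(list)
        for i, o in enumerate(obs):
            by_pid[o.patient_id].append(i)
        units = sorted(by_pid)
        unit_icp = {pid: float(np.median([obs[i].mean_icp_mmhg for i in idx])) for pid, idx in by_pid.items()}
        unit_bins = {pid: bin_index(unit_icp[pid], cfg) for pid in units}
        member = lambda pid: by_pid[pid]
        keys, bins = units, unit_bins
    else:
        keys = list(range(len(obs)))
        bins = {i: bin_index(obs[i].mean_icp_mmhg, cfg) for i in keys}
        member = lambda i: [i]

    per_bin: dict[int, list] = defaultdict(list)
    for k in keys:
        per_bin[bins[k]].append(k)

    for b in sorted(per_bin):
        members = per_bin[b]
        order = rng.permutation(len(members))
        shuffled = [members[i] for i in order]
        n = len(shuffled)
        n_test = _round_half_up(cfg.test_fraction * n) if n >= 3 else 0
        rem = n - n_test
        n_val = _round_half_up(cfg.val_fraction_of_train * rem)
        for j, k in enumerate(shuffled):
            if j < n_test:
                lab = "test"
            elif j < n_test + n_val:
                lab = "val"
            else:
                lab = "train"
            for i in member(k):
                labels[i] = lab

    split = [str(s) for s in labels]
    counts = {lab: split.count(lab) for lab in ("train", "val", "test")}
    logger.info("split: %s", counts)
    return Dataset(list(obs), split)
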