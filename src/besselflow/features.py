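"""Waveform features, gating, and sort-quality metrics.

Sorting decisions are taken directly from the temporal waveform, without
image reconstruction:

* ``T1`` -- duration between the first and last negative envelope peaks of
  an event; ``T1 * v_flow`` is the object length along the flow axis.
* ``T2`` -- within-scan duration of the contiguous below-threshold region
  around the scan minimum; ``max_n T2_n * v_scan`` is the object width
  along the scan axis (the widest section is the diameter).
* ``N`` -- number of positive (above-baseline) peaks during the transit;
  a proxy for intracellular granularity.
* ``v`` -- per-object flow speed from the two-slit LED velocimeter.

Multiplying time features by the per-object speed removes the distortion
caused by the 10-25 cm/s speed spread, so gates act on geometric rather
than temporal quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .forward import WaveformRecord
from .reconstruct import EventWindow, _clean_scan_mask

__all__ = [
    "GateSpec",
    "SortReport",
    "estimate_noise_sigma",
    "estimate_speed",
    "compute_T1",
    "compute_T2_profile",
    "count_positive_peaks",
    "extract_features",
    "apply_gate_and_score",
    "valley_threshold",
    "otsu_threshold",
]


@dataclass(frozen=True)
class GateSpec:
    """Axis-aligned gate: closed interval per feature axis (1D or 2D)."""

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if not self.bounds:
            raise ValueError("gate needs at least one axis")
        for axis, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"degenerate gate on {axis!r}: [{lo}, {hi}]")

    def contains(self, features: pd.DataFrame) -> pd.Series:
        missing = [a for a in self.bounds if a not in features.columns]
        if missing:
            raise KeyError(
                f"gate axes {missing} absent; available: {list(features.columns)}"
            )
        mask = pd.Series(True, index=features.index)
        for axis, (lo, hi) in self.bounds.items():
            mask &= features[axis].between(lo, hi)
        return mask


@dataclass
class SortReport:
    """Mixture-level outcome of a gated sort against ground truth."""

    target_label: str
    true_positive: int
    false_positive: int
    false_negative: int
    true_negative: int
    n_target_before: int
    n_background_before: int
    class_counts_sorted: dict[str, int] = field(default_factory=dict)

    @property
    def purity_percent(self) -> float:
        sorted_n = self.true_positive + self.false_positive
        return 100.0 * self.true_positive / sorted_n if sorted_n else float("nan")

    @property
    def yield_percent(self) -> float:
        n = self.true_positive + self.false_negative
        return 100.0 * self.true_positive / n if n else float("nan")

    @property
    def enrichment(self) -> float:
        """Target:background odds after sorting over odds before."""
        if self.n_target_before == 0 or self.n_background_before == 0:
            return float("nan")
        before = self.n_target_before / self.n_background_before
        if self.false_positive == 0:
            return float("inf") if self.true_positive else float("nan")
        return (self.true_positive / self.false_positive) / before

    def to_dict(self) -> dict:
        e = self.enrichment
        return {
            "target_label": self.target_label,
            "true_positive": self.true_positive,
            "false_positive": self.false_positive,
            "false_negative": self.false_negative,
            "true_negative": self.true_negative,
            "purity_percent": self.purity_percent,
            "yield_percent": self.yield_percent,
            "enrichment": None if not math.isfinite(e) else e,
            "class_counts_sorted": self.class_counts_sorted,
        }


def estimate_noise_sigma(record: WaveformRecord, threshold: float = 0.05) -> float:
    """Noise sd of the transmission baseline, from object-free scans."""
    clean = _clean_scan_mask(record, threshold)
    if not clean.any():
        clean = np.ones(record.n_scans, dtype=bool)
    samples = record.scans[clean].ravel()
    return float(samples.std())


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Sub-sample minimum location by a parabola through (i-1, i, i+1)."""
    if i <= 0 or i >= len(y) - 1:
        return float(i)
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom <= 0:
        return float(i)
    return i + 0.5 * (y[i - 1] - y[i + 1]) / denom


def _two_dip_delta_t(
    trace: np.ndarray, dt: float, min_depth: float, exclusion: float
) -> tuple[float, float] | None:
    """Locate the two deepest, well-separated dips in a velocimeter trace;
    returns their (sub-sample) times or None if fewer than two qualify."""
    i1 = int(np.argmin(trace))
    if 1.0 - trace[i1] < min_depth:
        return None
    excl = int(round(exclusion / dt))
    masked = trace.copy()
    masked[max(0, i1 - excl) : i1 + excl + 1] = 1.0
    i2 = int(np.argmin(masked))
    if 1.0 - masked[i2] < min_depth:
        return None
    t1 = _parabolic_refine(trace, i1) * dt
    t2 = _parabolic_refine(trace, i2) * dt
    return (t1, t2) if t1 < t2 else (t2, t1)


def estimate_speed(
    record: WaveformRecord,
    event: EventWindow,
    min_depth: float = 0.1,
    exclusion_us: float = 35.0,
    search_half_us: float = 220.0,
) -> float | None:
    """Per-event flow speed (cm/s) from the LED channel.

    v = slit separation at the object plane / time between the two dip
    minima (parabolic sub-sample refinement).  Returns None when fewer
    than two qualifying dips are found; such events are excluded from
    sorting.
    """
    params = record.params
    t_center = (event.first_scan + event.last_scan + 1) / 2.0 * params.scan_period
    i0 = max(0, int((t_center - search_half_us) / params.dt))
    i1 = min(len(record.speed_channel), int((t_center + search_half_us) / params.dt))
    dips = _two_dip_delta_t(
        record.speed_channel[i0:i1], params.dt, min_depth, exclusion_us
    )
    if dips is None:
        return None
    delta_t = dips[1] - dips[0]
    if delta_t <= 0:
        return None
    return params.led_separation_object / delta_t * 100.0  # um/us -> cm/s


def _crossing(times: np.ndarray, depth: np.ndarray, i_in: int, i_out: int, thr: float) -> float:
    """Linear-interpolated time where the depth profile crosses ``thr``
    between an outside point ``i_out`` and an inside point ``i_in``."""
    if i_out < 0 or i_out >= len(depth) or depth[i_out] >= thr:
        return float(times[i_in])
    d0, d1 = depth[i_out], depth[i_in]
    frac = (thr - d0) / (d1 - d0) if d1 != d0 else 1.0
    return float(times[i_out] + frac * (times[i_in] - times[i_out]))


def compute_T1(
    record: WaveformRecord,
    event: EventWindow,
    sigma: float,
    k: float = 4.0,
    floor: float = 0.005,
    envelope_fraction: float = 0.1,
) -> tuple[float | None, tuple[int, int] | None]:
    """Envelope duration of an event.

    Scans whose minimum dips below threshold carry negative peaks; T1
    spans from the first to the last such scan, with the endpoints refined
    by linear interpolation of the per-scan dip depth across the
    threshold.  The threshold is ``max(k * sigma, floor,
    envelope_fraction * peak depth)``: anchoring it to the envelope's own
    peak depth keeps the endpoint crossings on the steep flank of the
    envelope, where interpolation between adjacent scans is meaningful,
    instead of in its vanishing tail.  Returns (T1 in us, qualifying scan
    span) or (None, None) when no scan qualifies.
    """
    scans = record.scans[event.first_scan : event.last_scan + 1]
    depth = 1.0 - scans.min(axis=1)
    thr = max(k * sigma, floor, envelope_fraction * depth.max(initial=0.0))
    qual = np.flatnonzero(depth > thr)
    if qual.size == 0:
        return None, None
    times = record.scan_times()[event.first_scan : event.last_scan + 1]
    t_first = _crossing(times, depth, qual[0], qual[0] - 1, thr)
    t_last = _crossing(times, depth, qual[-1], qual[-1] + 1, thr)
    span = (event.first_scan + int(qual[0]), event.first_scan + int(qual[-1]))
    return t_last - t_first, span


def compute_T2_profile(
    record: WaveformRecord,
    event: EventWindow,
    sigma: float,
    k: float = 4.0,
    floor: float = 0.005,
    depth_fraction: float = 0.2,
) -> tuple[np.ndarray, float]:
    """Per-scan below-threshold widths (us) and their maximum.

    For each scan, T2 is the duration of the contiguous region below a
    threshold that contains the scan minimum, with the region edges
    refined by linear interpolation; scans without a qualifying dip
    contribute 0.  The maximum over scans tracks the widest section of the
    object.

    The threshold sits ``max(k * sigma, floor, depth_fraction * depth)``
    below baseline, where ``depth`` is the scan's own dip depth: the
    depth-scaled term keeps the shallow sidelobe echo of a dark object
    (a few percent of baseline, regardless of noise) outside the region,
    so T2 tracks the main-lobe crossing of the object rather than the
    comb-broadened footprint.
    """
    dt = record.params.dt
    scans = record.scans[event.first_scan : event.last_scan + 1]
    widths = np.zeros(scans.shape[0])
    for i, row in enumerate(scans):
        j = int(np.argmin(row))
        depth = 1.0 - row[j]
        thr_val = 1.0 - max(k * sigma, floor, depth_fraction * depth)
        if row[j] >= thr_val:
            continue
        lo = j
        while lo > 0 and row[lo - 1] < thr_val:
            lo -= 1
        hi = j
        while hi < len(row) - 1 and row[hi + 1] < thr_val:
            hi += 1
        # sub-sample edges
        left = lo - (thr_val - row[lo]) / (row[lo - 1] - row[lo]) if lo > 0 and row[lo - 1] != row[lo] else float(lo)
        right = hi + (thr_val - row[hi]) / (row[hi + 1] - row[hi]) if hi < len(row) - 1 and row[hi + 1] != row[hi] else float(hi)
        widths[i] = (right - left) * dt
    return widths, float(widths.max(initial=0.0))


def count_positive_peaks(
    record: WaveformRecord,
    event: EventWindow,
    sigma: float,
    prominence_k: float = 4.0,
    floor: float = 0.02,
    min_separation: int = 2,
    scan_span: tuple[int, int] | None = None,
) -> int:
    """Count above-baseline peaks during the transit.

    Local maxima exceeding ``1 + max(prominence_k * sigma, floor)`` with at
    least ``min_separation`` samples between peaks, summed over the scans
    of the transit (restricted to the T1 span when given, so baseline noise
    outside the object contributes nothing).
    """
    thr = 1.0 + max(prominence_k * sigma, floor)
    first, last = scan_span if scan_span is not None else (event.first_scan, event.last_scan)
    n = 0
    for row in record.scans[first : last + 1]:
        peaks, _ = signal.find_peaks(row, height=thr, distance=min_separation)
        n += len(peaks)
    return n


def extract_features(
    record: WaveformRecord,
    events: list[EventWindow],
    sigma: float | None = None,
    peak_k: float = 4.0,
) -> pd.DataFrame:
    """One feature row per event.

    Columns: T1_us, T2_max_us, n_pos_peaks, speed_cm_s, L_um (= T1 * v),
    W_um (= T2_max * v_scan), size_product_um2 (= L * W), Nv (= N * v),
    truth_label / truth_index (matched by arrival time when the record
    carries ground truth), and an exclusion ``reason`` ('' when valid).
    Events with a missing speed or empty envelope are reason-coded and
    excluded from gating.
    """
    params = record.params
    if sigma is None:
        sigma = estimate_noise_sigma(record)
    truth_times = np.array([t["arrival_time_us"] for t in record.truth])
    rows = []
    for ev in events:
        reason = ""
        v = estimate_speed(record, ev)
        t1, span = compute_T1(record, ev, sigma, k=peak_k)
        if t1 is None:
            reason = "no_negative_peaks"
        elif v is None:
            reason = "speed_unavailable"
        _, t2max = compute_T2_profile(record, ev, sigma, k=peak_k)
        npk = count_positive_peaks(record, ev, sigma, prominence_k=peak_k, scan_span=span)
        v_um_us = (v / 100.0) if v is not None else np.nan
        L = t1 * v_um_us if t1 is not None else np.nan
        W = t2max * params.scan_speed
        t_center = (ev.first_scan + ev.last_scan + 1) / 2.0 * params.scan_period
        if truth_times.size:
            ti = int(np.argmin(np.abs(truth_times - t_center)))
            label = record.truth[ti]["label"]
            tidx = record.truth[ti]["index"]
            if abs(truth_times[ti] - t_center) > 250.0:
                label, tidx = "", -1
        else:
            label, tidx = "", -1
        rows.append(
            {
                "first_scan": ev.first_scan,
                "last_scan": ev.last_scan,
                "T1_us": t1 if t1 is not None else np.nan,
                "T2_max_us": t2max,
                "n_pos_peaks": npk,
                "speed_cm_s": v if v is not None else np.nan,
                "L_um": L,
                "W_um": W,
                "size_product_um2": L * W,
                "Nv": npk * v if v is not None else np.nan,
                "truth_label": label,
                "truth_index": tidx,
                "reason": reason,
            }
        )
    return pd.DataFrame(rows)


def apply_gate_and_score(
    features: pd.DataFrame, gate: GateSpec, target_label: str
) -> SortReport:
    """Sort decision = event inside the gate; score against truth labels.

    Reason-coded (invalid) events never sort; they count against yield but
    not purity.  Purity = 100 * TP / (TP + FP); enrichment compares
    target:background odds after vs. before sorting.
    """
    valid = features["reason"] == ""
    inside = gate.contains(features) & valid
    is_target = features["truth_label"] == target_label
    tp = int((inside & is_target).sum())
    fp = int((inside & ~is_target).sum())
    fn = int((~inside & is_target).sum())
    tn = int((~inside & ~is_target).sum())
    counts = features.loc[inside, "truth_label"].value_counts().to_dict()
    return SortReport(
        target_label=target_label,
        true_positive=tp,
        false_positive=fp,
        false_negative=fn,
        true_negative=tn,
        n_target_before=int(is_target.sum()),
        n_background_before=int((~is_target).sum()),
        class_counts_sorted={str(k): int(v) for k, v in counts.items()},
    )


def valley_threshold(values: np.ndarray, grid_points: int = 512) -> float:
    """Histogram-valley gate helper: Gaussian-KDE density of a bimodal
    feature, threshold at the density minimum between the two most
    prominent modes."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 4:
        raise ValueError("need at least 4 finite values")
    kde = stats.gaussian_kde(values)
    grid = np.linspace(values.min(), values.max(), grid_points)
    dens = kde(grid)
    peaks, props = signal.find_peaks(dens, prominence=0.0)
    if len(peaks) < 2:
        raise ValueError("feature distribution is not bimodal")
    top2 = peaks[np.argsort(props["prominences"])[-2:]]
    lo, hi = np.sort(top2)
    return float(grid[lo + int(np.argmin(dens[lo:hi + 1]))])


def otsu_threshold(values: np.ndarray, bins: int = 128) -> float:
    """1D Otsu threshold (between-class variance maximization) as a
    convenience alternative to the KDE valley."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    hist, edges = np.histogram(values, bins=bins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    w = hist.astype(float)
    p = w / w.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_t * omega - mu) ** 2 / (omega * (1 - omega))
    between[~np.isfinite(between)] = -1
    # empty gaps between modes give a flat maximum: take the plateau midpoint
    best = np.flatnonzero(between >= between.max() - 1e-12 * abs(between.max()))
    return float(centers[best[(len(best) - 1) // 2]])
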