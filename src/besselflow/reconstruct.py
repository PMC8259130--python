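"""Transfer-matrix construction, background subtraction, event detection,
per-scan inversion, and speed-corrected 2D image assembly.

The per-scan signal is a linear mixture of the transmission line with the
sidelobe comb; on the extended scan grid (in-FOV points plus sidelobe
padding on each side) the mixture is a symmetric, unit-diagonal, banded
Toeplitz operator.  Because the transmission outside the field of view is
known to be background (objects are confined to the FOV), the inversion
solves the in-FOV block exactly with the off-FOV contribution moved to the
right-hand side, which makes the forward->inverse round trip exact to
machine precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, ndimage

from .beam import BesselComb
from .forward import AcquisitionParams, WaveformRecord, grid_comb

__all__ = [
    "TransferMatrix",
    "ReconstructedImage",
    "build_transfer_matrix",
    "subtract_background",
    "detect_events",
    "invert_scan",
    "reconstruct_image",
    "EventWindow",
]


@dataclass
class TransferMatrix:
    """Discrete sidelobe-mixing operator on the extended scan grid."""

    values: np.ndarray
    grid_pitch: float
    index_range: tuple[int, int]  # inclusive extended-grid index bounds
    n_fov: int  # in-FOV points (rows/cols [pad, pad+n_fov))
    conditioning: float
    regularized: bool = False
    _lu: tuple | None = field(default=None, repr=False)

    @property
    def side(self) -> int:
        return self.values.shape[0]

    @property
    def pad(self) -> int:
        return (self.side - self.n_fov) // 2

    @property
    def total_weight(self) -> float:
        """Row sum (baseline response for f == 1); constant by symmetry
        away from the band edges."""
        return float(self.values[self.side // 2].sum())

    def fov_block(self) -> np.ndarray:
        p = self.pad
        return self.values[p : p + self.n_fov, p : p + self.n_fov]

    def offfov_row_sums(self) -> np.ndarray:
        """Per in-FOV row, the summed coupling into off-FOV columns."""
        p = self.pad
        rows = self.values[p : p + self.n_fov]
        return rows.sum(axis=1) - self.fov_block().sum(axis=1)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.values, delimiter=",", fmt="%.10g")


@dataclass
class EventWindow:
    """Contiguous run of scans containing one object transit."""

    first_scan: int
    last_scan: int  # inclusive
    min_value: float

    @property
    def n_scans(self) -> int:
        return self.last_scan - self.first_scan + 1


@dataclass
class ReconstructedImage:
    """Restored transmission image for one event: rows are scans (flow
    axis, pitch ``speed * scan_period``), columns the scan axis."""

    values: np.ndarray
    pitch_y: float
    pitch_z: float
    speed_cm_s: float
    event: EventWindow


def build_transfer_matrix(
    comb: BesselComb, params: AcquisitionParams
) -> TransferMatrix:
    """Build the T-matrix on the extended grid.

    The diagonal is 1; entry (i, j) carries the comb weight whose sidelobe
    offset nearest-matches the grid offset ``|i - j| * pitch``; sidelobes
    snapping to the same grid point have their weights added.  At default
    beam and acquisition settings the matrix is 251 x 251, symmetric and
    strictly diagonally dominant.
    """
    offsets, weights = grid_comb(comb, params.pitch)
    if np.max(np.abs(offsets)) > params.pad:
        raise ValueError("comb sidelobes exceed the grid padding: pitch mismatch")
    side = params.extended_size
    col = np.zeros(side)
    col[np.abs(offsets)] = weights  # symmetric: +/-o carry equal weight
    col[0] = 1.0
    values = linalg.toeplitz(col)
    off_sum = float(col[1:].sum() * 2)
    regularized = off_sum >= 1.0
    if regularized:
        warnings.warn(
            "transfer matrix is not diagonally dominant "
            f"(off-diagonal row sum {off_sum:.3f} >= 1); "
            "inversion falls back to a ridge-regularized solve",
            stacklevel=2,
        )
    cond = float(np.linalg.cond(values))
    return TransferMatrix(
        values=values,
        grid_pitch=params.pitch,
        index_range=(-params.pad, side - params.pad - 1),
        n_fov=params.samples_per_scan,
        conditioning=cond,
        regularized=regularized,
    )


def _clean_scan_mask(record: WaveformRecord, threshold: float) -> np.ndarray:
    mins = record.scans.min(axis=1)
    return mins > 1.0 - threshold


def subtract_background(
    record: WaveformRecord, threshold: float = 0.05
) -> WaveformRecord:
    """Remove the fixed per-scan ripple.

    Two passes: a median over all scans gives a provisional pattern robust
    to sparse objects; object scans are then flagged (minimum below
    ``1 - threshold`` after provisional division) and the pattern is
    re-estimated from object-free scans only, divided out, and the
    baseline renormalized to 1.
    """
    scans = record.scans
    if scans.shape[0] < 3:
        raise ValueError("need at least 3 scans to estimate the background")
    provisional = np.median(scans, axis=0)
    provisional[provisional <= 0] = 1.0
    rough = scans / provisional[None, :]
    clean = rough.min(axis=1) > 1.0 - threshold
    if not clean.any():
        raise ValueError("no object-free scans found for background estimation")
    pattern = np.median(scans[clean], axis=0)
    pattern[pattern <= 0] = 1.0
    out = scans / pattern[None, :]
    out /= np.median(out[clean])  # renormalize baseline to 1
    return WaveformRecord(
        transmission=out.reshape(-1),
        speed_channel=record.speed_channel,
        params=record.params,
        truth=record.truth,
    )


def detect_events(
    record: WaveformRecord,
    threshold: float = 0.08,
    min_scans: int = 2,
    pad_scans: int = 2,
) -> list[EventWindow]:
    """Find object transits in a background-subtracted record.

    An event is a maximal run of >= ``min_scans`` consecutive scans whose
    minimum dips below ``1 - threshold``, padded by ``pad_scans`` clean
    scans on each side (so shallow envelope tails stay inside the window);
    overlapping padded windows are merged.
    """
    mins = record.scans.min(axis=1)
    dipped = mins < 1.0 - threshold
    events: list[EventWindow] = []
    n = len(mins)
    i = 0
    while i < n:
        if dipped[i]:
            j = i
            while j + 1 < n and dipped[j + 1]:
                j += 1
            if j - i + 1 >= min_scans:
                first = max(0, i - pad_scans)
                last = min(n - 1, j + pad_scans)
                if events and first <= events[-1].last_scan:
                    prev = events.pop()
                    first = prev.first_scan
                    mv = min(prev.min_value, float(mins[i : j + 1].min()))
                else:
                    mv = float(mins[i : j + 1].min())
                events.append(EventWindow(first, last, mv))
            i = j + 1
        else:
            i += 1
    return events


def _solve_fov(tm: TransferMatrix, rhs: np.ndarray) -> np.ndarray:
    """Solve the in-FOV block system T_ff x = rhs (LU cached); ridge
    fallback when the dominance flag is set."""
    block = tm.fov_block()
    if tm.regularized:
        lam = 1e-3 * np.trace(block) / block.shape[0]
        return np.linalg.solve(block.T @ block + lam * np.eye(block.shape[0]), block.T @ rhs)
    if tm._lu is None:
        tm._lu = linalg.lu_factor(block)
    return linalg.lu_solve(tm._lu, rhs)


def invert_scan(tm: TransferMatrix, scan_samples: np.ndarray) -> np.ndarray:
    """Restore the in-FOV transmission line from one background-subtracted,
    baseline-normalized scan.

    The scan is scaled back to the raw comb response, the off-FOV grid is
    closed with the known background (f = 1, contributing the off-FOV
    column sums to each row), and the in-FOV block is solved directly.
    """
    scan_samples = np.asarray(scan_samples, dtype=float)
    if scan_samples.shape != (tm.n_fov,):
        raise ValueError(f"expected {tm.n_fov} samples, got {scan_samples.shape}")
    rhs = scan_samples * tm.total_weight - tm.offfov_row_sums()
    return _solve_fov(tm, rhs)


def reconstruct_image(
    record: WaveformRecord,
    event: EventWindow,
    speed_cm_s: float,
    tm: TransferMatrix,
    square_pixels: bool = False,
) -> ReconstructedImage:
    """Invert every scan of an event and stack the restored lines at the
    flow-axis pitch ``speed * scan_period``.  Optional bilinear resampling
    to square pixels (presentation only; features always use the raw
    grid)."""
    if speed_cm_s is None or not np.isfinite(speed_cm_s) or speed_cm_s <= 0:
        raise ValueError("a positive event speed is required to scale the flow axis")
    scans = record.scans[event.first_scan : event.last_scan + 1]
    rows = np.vstack([invert_scan(tm, s) for s in scans])
    pitch_z = (speed_cm_s / 100.0) * record.params.scan_period  # um per scan
    pitch_y = record.params.pitch
    if square_pixels:
        rows = ndimage.zoom(rows, (pitch_z / pitch_y, 1.0), order=1, mode="nearest")
        pitch_z = pitch_y
    return ReconstructedImage(
        values=rows,
        pitch_y=pitch_y,
        pitch_z=pitch_z,
        speed_cm_s=speed_cm_s,
        event=event,
    )
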