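"""Forward model: synthesize the two-channel temporal waveform.

The scanning beam sweeps the 40 um field of view once per 5 us scan while
the object drifts along the flow axis at 10-25 cm/s -- a factor >= 30
slower than the 8 m/s scan speed, so each scan sees the object at an
essentially fixed flow position.  The temporal-to-spatial mapping is

    y' = (FOV_y / T) * t_in_scan        (scan axis)
    z' = v_flow * t                     (flow axis)

Per scan, the transmitted power is the comb-weighted shift sum

    J(y') = sum_l a_l^2 * f(y' - u_l / k_r)

evaluated on a grid of 125 in-FOV points padded by the sidelobe span on
each side (251 points total); a 1.5 um slit at the object plane integrates
f along the flow axis before the sum.  A fixed per-scan multiplicative
background (chip imperfections, periodic in every scan) and additive
Gaussian noise complete the signal; a separate LED channel carries two
transmission dips per object from the two-slit velocimeter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .beam import BesselComb
from .phantom import ObjectSpec, ScenePlan, TransmissionMap, render_object

__all__ = [
    "AcquisitionParams",
    "WaveformRecord",
    "temporal_mapping",
    "grid_comb",
    "scan_response",
    "synthesize_waveform",
    "synthesize_speed_channel",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition geometry and signal-chain settings.

    Times in microseconds, lengths in object-plane micrometres unless noted.
    ``led_slit_separation`` is at the mask plane; divide by ``magnification``
    for the object-plane separation used in velocimetry.
    """

    scan_period: float = 5.0  # us per AOD scan
    fov_y: float = 40.0  # um scanned per period
    sample_rate: float = 25e6  # Hz
    slit_height: float = 1.5  # um along flow at the object plane
    magnification: float = 10.0
    led_slit_separation: float = 200.0  # um at the mask plane
    led_slit_width: float = 1.0  # um along flow at the object plane
    noise_sigma: float = 0.01  # additive Gaussian, fraction of baseline
    background_amplitude: float = 0.02  # per-scan fixed ripple amplitude
    sidelobe_span: float = 20.0  # um of padding on each side of the FOV

    def __post_init__(self) -> None:
        n = self.sample_rate * self.scan_period * 1e-6
        if abs(n - round(n)) > 1e-9:
            raise ValueError("sample_rate * scan_period must be an integer")
        if self.fov_y <= 0 or self.scan_period <= 0:
            raise ValueError("fov_y and scan_period must be positive")

    @property
    def samples_per_scan(self) -> int:
        return int(round(self.sample_rate * self.scan_period * 1e-6))

    @property
    def pitch(self) -> float:
        """Scan-grid pitch in um (0.32 at defaults)."""
        return self.fov_y / self.samples_per_scan

    @property
    def pad(self) -> int:
        """Grid points of sidelobe padding on each side of the FOV."""
        return int(np.ceil(self.sidelobe_span / self.pitch))

    @property
    def extended_size(self) -> int:
        """Side of the extended scan grid (251 at defaults)."""
        return self.samples_per_scan + 2 * self.pad

    @property
    def scan_speed(self) -> float:
        """Beam scan speed in um/us (== m/s); 8 at defaults."""
        return self.fov_y / self.scan_period

    @property
    def dt(self) -> float:
        """Sample period in us."""
        return 1e6 / self.sample_rate

    @property
    def led_separation_object(self) -> float:
        """Velocimeter slit separation at the object plane (um)."""
        return self.led_slit_separation / self.magnification


def temporal_mapping(
    t_in_scan: float, scan_index: int, speed_cm_s: float, params: AcquisitionParams
) -> tuple[float, float]:
    """Map a time within scan ``scan_index`` to object-plane coordinates
    (y', z') in um.  ``speed_cm_s`` is the object flow speed."""
    if not 0 <= t_in_scan < params.scan_period:
        raise ValueError("t_in_scan must lie in [0, scan_period)")
    y = params.scan_speed * t_in_scan
    v_um_us = speed_cm_s / 100.0
    z = v_um_us * (scan_index * params.scan_period + t_in_scan)
    return y, z


def grid_comb(comb: BesselComb, pitch: float) -> tuple[np.ndarray, np.ndarray]:
    """Snap the comb to the scan grid: nearest-grid-point assignment of
    each sidelobe offset ``u_l / k_r``; offsets that collide on one grid
    point have their weights added.  Returns (integer offsets, weights)."""
    idx = np.rint(comb.offsets_um / pitch).astype(int)
    offsets, inverse = np.unique(idx, return_inverse=True)
    weights = np.zeros(offsets.size)
    np.add.at(weights, inverse, comb.weights)
    return offsets, weights


def scan_response(
    f_line: np.ndarray, comb: BesselComb, params: AcquisitionParams
) -> np.ndarray:
    """Comb-weighted shift sum over one extended f-line.

    ``f_line`` must cover the extended grid (``params.extended_size``
    points).  Returns the raw (unnormalized) in-FOV response of
    ``samples_per_scan`` points; divide by the total grid weight for a
    baseline of 1.
    """
    f_line = np.asarray(f_line, dtype=float)
    if f_line.shape != (params.extended_size,):
        raise ValueError(
            f"f_line must have {params.extended_size} points, got {f_line.shape}"
        )
    offsets, weights = grid_comb(comb, params.pitch)
    if np.max(np.abs(offsets)) > params.pad:
        raise ValueError("comb sidelobes exceed the grid padding: pitch mismatch")
    n, pad = params.samples_per_scan, params.pad
    out = np.zeros(n)
    for o, w in zip(offsets, weights):
        out += w * f_line[pad - o : pad - o + n]
    return out


@dataclass
class WaveformRecord:
    """Two-channel acquisition record.

    ``transmission`` and ``speed_channel`` are baseline-normalized time
    series of equal length (an integer number of scans); ``truth`` holds
    per-object ground-truth metadata for synthetic records.
    """

    transmission: np.ndarray
    speed_channel: np.ndarray
    params: AcquisitionParams
    truth: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.params.samples_per_scan
        if len(self.transmission) % n:
            raise ValueError("record length must be a whole number of scans")

    @property
    def n_scans(self) -> int:
        return len(self.transmission) // self.params.samples_per_scan

    @property
    def scan_boundaries(self) -> np.ndarray:
        return np.arange(self.n_scans) * self.params.samples_per_scan

    @property
    def scans(self) -> np.ndarray:
        """Transmission reshaped to (n_scans, samples_per_scan)."""
        return self.transmission.reshape(self.n_scans, self.params.samples_per_scan)

    def scan_times(self) -> np.ndarray:
        """Centre time of each scan in us."""
        return (np.arange(self.n_scans) + 0.5) * self.params.scan_period

    def sample_times(self) -> np.ndarray:
        return (np.arange(len(self.transmission)) + 0.5) * self.params.dt

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("transmission", data=self.transmission)
            fh.create_dataset("speed_channel", data=self.speed_channel)
            fh.create_dataset("scan_boundaries", data=self.scan_boundaries)
            fh.attrs["truth"] = json.dumps(self.truth)
            fh.attrs["sample_rate"] = self.params.sample_rate
            fh.attrs["scan_period"] = self.params.scan_period
            fh.attrs["fov_y"] = self.params.fov_y
            fh.attrs["params"] = json.dumps(vars(self.params) | {})

    @classmethod
    def from_hdf5(cls, path) -> "WaveformRecord":
        import h5py

        with h5py.File(path, "r") as fh:
            params = AcquisitionParams(**json.loads(fh.attrs["params"]))
            return cls(
                transmission=fh["transmission"][:],
                speed_channel=fh["speed_channel"][:],
                params=params,
                truth=json.loads(fh.attrs["truth"]),
            )

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "time_us": self.sample_times(),
                "transmission": self.transmission,
                "speed_channel": self.speed_channel,
            }
        ).to_csv(path, index=False)


def _slit_averaged_line(
    tmap: TransmissionMap, z_obj: float, slit_height: float, n_quad: int = 9
) -> np.ndarray:
    """Average the map along z over the slit window centred at ``z_obj``
    (object coordinates, um), by linear interpolation between rows at
    ``n_quad`` equally spaced z samples.  Rows outside the map contribute
    background (1)."""
    zq = z_obj + (np.arange(n_quad) + 0.5) / n_quad * slit_height - slit_height / 2.0
    rpos = zq / tmap.pitch_z + tmap.origin[0]
    nrow = tmap.values.shape[0]
    lo = np.floor(rpos).astype(int)
    frac = rpos - lo
    out = np.zeros(tmap.values.shape[1])
    for k in range(n_quad):
        for j, wgt in ((lo[k], 1 - frac[k]), (lo[k] + 1, frac[k])):
            if 0 <= j < nrow:
                out += wgt * tmap.values[j]
            else:
                out += wgt  # background row
    return out / n_quad


def _paste_line(
    base: np.ndarray, profile: np.ndarray, center_um: float, origin_col: float,
    pitch: float, pad: int,
) -> None:
    """Overwrite ``base`` (extended f-line of ones) with an object profile
    whose centre column maps to object-plane position ``center_um``."""
    start = pad + int(round(center_um / pitch - origin_col))
    s0 = max(0, start)
    s1 = min(len(base), start + len(profile))
    if s1 > s0:
        base[s0:s1] = profile[s0 - start : s1 - start]


def synthesize_speed_channel(
    scene: ScenePlan,
    params: AcquisitionParams,
    seed: int,
    n_samples: int,
    dip_depth: float = 0.4,
) -> np.ndarray:
    """Two-slit LED velocimeter channel: per object, two smooth transmission
    dips separated by ``(led_slit_separation / M) / v`` and centred on the
    object's arrival time, each of duration
    ``(object length + slit width) / v``."""
    rng = np.random.default_rng(seed)
    t = (np.arange(n_samples) + 0.5) * params.dt
    signal = np.ones(n_samples)
    sep = params.led_separation_object
    for obj in scene.objects:
        v = obj.speed / 100.0  # um/us
        dt_dips = sep / v
        width = (obj.diameter + params.led_slit_width) / v
        sigma = width / 4.0
        for tc in (obj.arrival_time - dt_dips / 2.0, obj.arrival_time + dt_dips / 2.0):
            i0 = np.searchsorted(t, tc - 4 * sigma)
            i1 = np.searchsorted(t, tc + 4 * sigma)
            signal[i0:i1] -= dip_depth * np.exp(-0.5 * ((t[i0:i1] - tc) / sigma) ** 2)
    if params.noise_sigma > 0:
        signal = signal + rng.normal(0, params.noise_sigma, n_samples)
    return signal


def _background_pattern(params: AcquisitionParams, rng: np.random.Generator) -> np.ndarray:
    """Fixed per-scan multiplicative ripple: a smooth low-order Fourier
    profile of the configured amplitude, drawn once per run."""
    n = params.samples_per_scan
    y = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pattern = np.zeros(n)
    for h in range(1, 5):
        pattern += rng.normal() * np.cos(h * y) + rng.normal() * np.sin(h * y)
    if np.ptp(pattern) > 0:
        pattern = pattern / np.max(np.abs(pattern))
    return 1.0 + params.background_amplitude * pattern


def synthesize_waveform(
    scene: ScenePlan,
    comb: BesselComb,
    params: AcquisitionParams,
    seed: int,
    maps: Sequence[TransmissionMap] | None = None,
    duration_margin_us: float = 400.0,
) -> WaveformRecord:
    """Render a full two-channel record for a scene.

    For every scan that overlaps an object (within the slit window), the
    object's map is slit-averaged at the current flow position, embedded in
    a background f-line, and passed through the comb shift sum; the result
    is normalized so the empty-channel baseline is 1.  The fixed per-scan
    background ripple multiplies every scan and Gaussian noise is added to
    both channels.
    """
    if maps is not None and len(maps) != len(scene.objects):
        raise ValueError("need one map per scene object")
    ss = np.random.SeedSequence(seed)
    rng_noise, rng_bg, rng_led = (np.random.default_rng(s) for s in ss.spawn(3))

    last = scene.objects[-1].arrival_time if scene.objects else 0.0
    n_scans = int(np.ceil((last + duration_margin_us) / params.scan_period))
    n_scans = max(n_scans, 10)
    nspc = params.samples_per_scan
    scans = np.ones((n_scans, nspc))
    offsets, weights = grid_comb(comb, params.pitch)
    total_w = weights.sum()
    scan_t = (np.arange(n_scans) + 0.5) * params.scan_period

    truth = []
    for k, obj in enumerate(scene.objects):
        tmap = maps[k] if maps is not None else render_object(obj, pitch=params.pitch)
        v = obj.speed / 100.0  # um/us
        half_z = tmap.origin[0] * tmap.pitch_z + params.slit_height / 2.0 + 0.5
        j0 = np.searchsorted(scan_t, obj.arrival_time - half_z / v)
        j1 = np.searchsorted(scan_t, obj.arrival_time + half_z / v)
        j1 = min(j1, n_scans)
        if j0 >= j1:
            continue
        center = params.fov_y / 2.0 + obj.lateral_offset
        prev = scene.objects[k - 1].arrival_time if k else None
        if prev is not None and obj.arrival_time - prev < 2 * half_z / v:
            raise ValueError("objects overlap in time within one interrogation window")
        for j in range(j0, j1):
            z_obj = (scan_t[j] - obj.arrival_time) * v
            profile = _slit_averaged_line(tmap, z_obj, params.slit_height)
            line = np.ones(params.extended_size)
            _paste_line(line, profile, center, tmap.origin[1], params.pitch, params.pad)
            scans[j] = scan_response(line, comb, params) / total_w
        truth.append(
            {
                "index": k,
                "label": obj.label,
                "kind": obj.kind,
                "diameter_um": obj.diameter,
                "speed_cm_s": obj.speed,
                "arrival_time_us": obj.arrival_time,
                "n_granules": obj.n_granules,
                "scan_window": [int(j0), int(j1)],
            }
        )

    pattern = _background_pattern(params, rng_bg)
    scans *= pattern[None, :]
    transmission = scans.reshape(-1)
    if params.noise_sigma > 0:
        transmission = transmission + rng_noise.normal(0, params.noise_sigma, transmission.size)

    speed = synthesize_speed_channel(
        scene, params, int(rng_led.integers(2**31 - 1)), transmission.size
    )
    return WaveformRecord(
        transmission=transmission, speed_channel=speed, params=params, truth=truth
    )
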