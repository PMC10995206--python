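"""Super-resolved outputs from tracks: accumulation density maps,
axial-direction-signed flow maps, per-pixel microbubble-count time
series, and functional activation maps.

Track coordinates are fine-grid pixels; maps are accumulated on a
reconstruction grid of ``lambda/5`` pixels by default, after first
rounding each localization to ``lambda/10``.  Functional activation is
the Pearson correlation between a pixel's per-second distinct-track
count and the stimulation pattern, evaluated over stimulation seconds
and stable-rest seconds only (transition seconds are excluded); pixels
with r > 0.2 count as activated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ImagingConfig
from .tracking import Track

ACTIVATION_THRESHOLD = 0.2


@dataclass
class UlmImage:
    density: np.ndarray
    pixel_um: float
    direction: np.ndarray | None = None


@dataclass
class StimulationPattern:
    """Block design: per cycle, stim_s seconds of stimulation, then
    transition_s seconds (excluded from analysis), then rest_s seconds
    of stable rest."""

    n_cycles: int = 15
    stim_s: int = 30
    transition_s: int = 10
    rest_s: int = 30

    @property
    def cycle_s(self) -> int:
        return self.stim_s + self.transition_s + self.rest_s

    @property
    def total_s(self) -> int:
        return self.n_cycles * self.cycle_s

    def series(self) -> np.ndarray:
        """A(t) per second: 1 during stimulation, 0 otherwise."""
        a = np.zeros(self.total_s, dtype=float)
        for c in range(self.n_cycles):
            a[c * self.cycle_s: c * self.cycle_s + self.stim_s] = 1.0
        return a

    def analysis_mask(self) -> np.ndarray:
        """True for stimulation and stable-rest seconds."""
        m = np.zeros(self.total_s, dtype=bool)
        for c in range(self.n_cycles):
            t0 = c * self.cycle_s
            m[t0: t0 + self.stim_s] = True
            m[t0 + self.stim_s + self.transition_s: t0 + self.cycle_s] = True
        return m


@dataclass
class ActivationMap:
    r: np.ndarray
    activated: np.ndarray = field(init=False)
    flagged: np.ndarray | None = None      # zero-variance pixels forced to 0

    def __post_init__(self):
        self.activated = self.r > ACTIVATION_THRESHOLD


# ---------------------------------------------------------------------

def _grid_shape(cfg: ImagingConfig, pixel_um: float) -> tuple[int, int]:
    h, w = cfg.fov_fine
    return (int(np.ceil(h * cfg.fine_pixel_um / pixel_um)),
            int(np.ceil(w * cfg.fine_pixel_um / pixel_um)))


def _to_bins(rows_um: np.ndarray, cols_um: np.ndarray, cfg: ImagingConfig,
             pixel_um: float, round_um: float | None) -> tuple[np.ndarray, np.ndarray]:
    """Round coordinates (in microns) to ``round_um`` then bin to the
    reconstruction grid."""
    if round_um is not None:
        rows_um = np.round(rows_um / round_um) * round_um
        cols_um = np.round(cols_um / round_um) * round_um
    shape = _grid_shape(cfg, pixel_um)
    ri = np.clip((rows_um / pixel_um).astype(int), 0, shape[0] - 1)
    ci = np.clip((cols_um / pixel_um).astype(int), 0, shape[1] - 1)
    return ri, ci


def accumulate_density(tracks: list[Track], cfg: ImagingConfig,
                       pixel_um: float | None = None,
                       round_um: float | None = None) -> UlmImage:
    """Count accumulated track points per reconstruction pixel.

    Defaults follow the reconstruction convention: localizations rounded
    to lambda/10, maps binned at lambda/5.
    """
    lam = cfg.wavelength_um
    pixel_um = pixel_um if pixel_um is not None else lam / 5
    round_um = round_um if round_um is not None else lam / 10
    shape = _grid_shape(cfg, pixel_um)
    density = np.zeros(shape)
    for tr in tracks:
        c = tr.coords() * cfg.fine_pixel_um
        ri, ci = _to_bins(c[:, 0], c[:, 1], cfg, pixel_um, round_um)
        np.add.at(density, (ri, ci), 1)
    return UlmImage(density, pixel_um)


def directional_map(tracks: list[Track], cfg: ImagingConfig,
                    pixel_um: float | None = None,
                    round_um: float | None = None) -> np.ndarray:
    """Accumulation signed by the axial component of the local track
    velocity: +1 toward the transducer (decreasing row), -1 away."""
    lam = cfg.wavelength_um
    pixel_um = pixel_um if pixel_um is not None else lam / 5
    round_um = round_um if round_um is not None else lam / 10
    out = np.zeros(_grid_shape(cfg, pixel_um))
    for tr in tracks:
        if len(tr.points) < 2:
            continue
        c = tr.coords()
        vel_r = np.gradient(c[:, 0])
        sign = np.where(vel_r < 0, 1.0, -1.0)
        cu = c * cfg.fine_pixel_um
        ri, ci = _to_bins(cu[:, 0], cu[:, 1], cfg, pixel_um, round_um)
        np.add.at(out, (ri, ci), sign)
    return out


def mb_count_series(tracks: list[Track], cfg: ImagingConfig,
                    pixel_um: float | None = None, window_s: float = 1.0,
                    n_windows: int | None = None) -> np.ndarray:
    """s_MB(t): per reconstruction pixel, the number of *distinct* tracks
    touching it in each time window."""
    lam = cfg.wavelength_um
    pixel_um = pixel_um if pixel_um is not None else lam / 5
    frames_per_window = max(1, int(round(window_s * cfg.frame_rate_hz)))
    if n_windows is None:
        last = max((tr.points[-1].frame for tr in tracks), default=0)
        n_windows = last // frames_per_window + 1
    shape = _grid_shape(cfg, pixel_um)
    series = np.zeros((n_windows,) + shape)
    for tr in tracks:
        frames = np.array([p.frame for p in tr.points])
        cu = tr.coords() * cfg.fine_pixel_um
        ri, ci = _to_bins(cu[:, 0], cu[:, 1], cfg, pixel_um, None)
        wi = frames // frames_per_window
        seen = set()
        for wdx, r, c in zip(wi, ri, ci):
            if wdx >= n_windows:
                continue
            key = (int(wdx), int(r), int(c))
            if key not in seen:     # a lingering track still counts once
                seen.add(key)
                series[key] += 1
    return series


def simulate_vessel_counts(pattern: StimulationPattern,
                           rng: np.random.Generator,
                           n_modulated: int = 50, n_null: int = 50,
                           base_rate_per_s: float = 3.0,
                           stim_gain: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic per-second bubble counts for activation-map validation.

    Modulated "vessel" pixels draw Poisson counts whose rate multiplies by
    ``stim_gain`` during stimulation seconds (the hemodynamic response of
    a perfused vessel); null pixels keep the base rate throughout.
    Returns (series, is_modulated) with series shaped (seconds, pixels, 1).
    """
    a = pattern.series()
    rates = np.where(a[:, None] > 0, base_rate_per_s * stim_gain,
                     base_rate_per_s)
    mod = rng.poisson(np.repeat(rates, n_modulated, axis=1))
    null = rng.poisson(np.full((pattern.total_s, n_null), base_rate_per_s))
    series = np.concatenate([mod, null], axis=1)[:, :, None].astype(float)
    flags = np.concatenate([np.ones(n_modulated, bool), np.zeros(n_null, bool)])
    return series, flags


def activation_map(series: np.ndarray, pattern: StimulationPattern) -> ActivationMap:
    """Pearson correlation of each pixel's count series with the
    stimulation pattern over the analysis mask."""
    mask = pattern.analysis_mask()
    a = pattern.series()
    if series.shape[0] != a.shape[0]:
        raise ValueError(f"series length {series.shape[0]} != pattern "
                         f"length {a.shape[0]}")
    am = a[mask]
    if am.std() == 0:
        raise ValueError("stimulation pattern constant on the analysis mask")
    s = series[mask].reshape(mask.sum(), -1)
    s_c = s - s.mean(axis=0)
    a_c = am - am.mean()
    denom = np.sqrt((s_c ** 2).sum(axis=0)) * np.sqrt((a_c ** 2).sum())
    flagged = denom == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (s_c * a_c[:, None]).sum(axis=0) / denom
    r = np.where(flagged, 0.0, r).reshape(series.shape[1:])
    return ActivationMap(np.clip(r, -1.0, 1.0),
                         flagged=flagged.reshape(series.shape[1:]))


def activated_pixel_count(amap: ActivationMap,
                          roi: np.ndarray | None = None,
                          threshold: float = ACTIVATION_THRESHOLD) -> int:
    """Number of pixels with r strictly above the threshold inside the ROI."""
    act = amap.r > threshold
    if roi is not None:
        if roi.shape != act.shape:
            raise ValueError("roi shape mismatch")
        act = act & roi.astype(bool)
    return int(act.sum())
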