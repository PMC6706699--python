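"""Synthetic data generation with full ground truth.

This module produces the four kinds of input the analysis pipeline consumes:

* multi-channel TIRF-like movies of diffraction-limited spots (clathrin-coated
  pits, CCPs) on a noisy background,
* fixed-cell-like multi-channel still images,
* pre-linked two-channel track tables (bypassing imaging, for isolated tests
  of track statistics and colocalization),
* binding titrations (fluorescence anisotropy, SPR dissociation, ITC).

Every generator returns the planted ground truth alongside the data, so
downstream recovery can be scored exactly.

The movie model: each CCP is a stationary, isotropic 2D Gaussian of width
``psf_sigma`` whose amplitude follows a category-dependent temporal profile —
bona fide pits rise linearly over the first 30% of their lifetime, plateau,
and fall over the last 20%; transient assemblies sit at a low flat level;
persistent (stalled) structures hold a constant amplitude for the whole
acquisition.  Noise is Poisson shot noise on the noiseless image plus
additive Gaussian read noise, the usual sCMOS approximation.  A second
("slave") channel renders only the events flagged slave-positive, at
``slave_amplitude_ratio`` times the master amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from . import bindingfit

__all__ = [
    "LifetimeMixture",
    "MovieSpec",
    "FrameStack",
    "SpotEvent",
    "GroundTruth",
    "CrowdingError",
    "generate_movie",
    "generate_track_table",
    "generate_if_image",
    "generate_titration",
    "write_movie",
    "read_movie",
]

# flat amplitude of a transient assembly relative to its drawn peak amplitude
TRANSIENT_AMPLITUDE_SCALE = 0.5


class CrowdingError(ValueError):
    """Requested spot density too high for non-overlapping placement."""


@dataclass
class LifetimeMixture:
    """Two-population CCP lifetime model.

    Transient coat assemblies are short-lived; bona fide CCPs live longer.
    Lifetimes are exponential with the given means, floored at two frames.
    """

    transient_fraction: float = 0.4
    transient_mean_s: float = 8.0
    bona_fide_mean_s: float = 40.0

    def validate(self) -> None:
        if not 0.0 <= self.transient_fraction <= 1.0:
            raise ValueError("transient_fraction must be in [0, 1]")
        if self.transient_mean_s <= 0 or self.bona_fide_mean_s <= 0:
            raise ValueError("lifetime means must be positive")


@dataclass
class MovieSpec:
    """Parameters of a synthetic dual-channel movie.

    Defaults emulate the acquisition conditions of the live-cell data the
    pipeline targets: 0.5 frames/s (2 s interval) for 10 min (300 frames),
    a 100x/1.49 NA TIRF objective with ~6.45 um camera pixels (PSF sigma
    ~1.1 px), photon background with Poisson shot noise plus Gaussian read
    noise.
    """

    width: int = 128
    height: int = 128
    n_frames: int = 300
    frame_interval: float = 2.0
    psf_sigma: float = 1.1
    background_level: float = 100.0
    read_noise_sd: float = 4.0
    spot_amplitude_range: tuple[float, float] = (80.0, 250.0)
    nucleation_rate: float = 0.2
    lifetime_model: LifetimeMixture = field(default_factory=LifetimeMixture)
    persistent_count: int = 2
    slave_positive_fraction: float = 0.65
    slave_amplitude_ratio: float = 0.7
    poisson_noise: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.width < 8 or self.height < 8 or self.n_frames < 1:
            raise ValueError("movie dimensions too small")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if self.read_noise_sd < 0 or self.background_level < 0:
            raise ValueError("noise levels must be non-negative")
        if self.nucleation_rate < 0 or self.persistent_count < 0:
            raise ValueError("rates/counts must be non-negative")
        if not 0.0 <= self.slave_positive_fraction <= 1.0:
            raise ValueError("slave_positive_fraction must be in [0, 1]")
        lo, hi = self.spot_amplitude_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid spot_amplitude_range")
        self.lifetime_model.validate()

    @property
    def noise_sd(self) -> float:
        """Approximate per-pixel noise SD at background level."""
        return math.sqrt(self.background_level + self.read_noise_sd**2)


@dataclass
class FrameStack:
    """Time-ordered pixel grid for one channel."""

    data: np.ndarray  # (n_frames, height, width), float
    frame_interval: float
    channel: str = "master"

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass
class SpotEvent:
    """Ground truth for one planted spot event."""

    event_id: int
    x: float
    y: float
    birth: int
    death: int  # inclusive
    category: str  # transient | bona_fide | persistent
    peak_amplitude: float
    slave_positive: bool
    master_trace: np.ndarray  # amplitude per frame birth..death

    @property
    def lifetime_frames(self) -> int:
        return self.death - self.birth + 1


@dataclass
class GroundTruth:
    """Ledger of all planted events in one synthetic dataset."""

    events: list[SpotEvent]
    n_frames: int
    frame_interval: float

    def __len__(self) -> int:
        return len(self.events)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "event_id": e.event_id,
                "x": e.x,
                "y": e.y,
                "birth": e.birth,
                "death": e.death,
                "category": e.category,
                "peak_amplitude": e.peak_amplitude,
                "slave_positive": e.slave_positive,
                "lifetime_s": e.lifetime_frames * self.frame_interval,
            }
            for e in self.events
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "event_id", "x", "y", "birth", "death", "category",
                "peak_amplitude", "slave_positive", "lifetime_s",
            ],
        )


def amplitude_profile(category: str, peak: float, n: int) -> np.ndarray:
    """Temporal amplitude profile for one event of ``n`` frames.

    bona fide: linear rise over the first 30% of the lifetime, plateau, linear
    fall over the last 20%; transient: flat at half the drawn peak; persistent:
    constant at the peak.
    """
    if category == "transient":
        return np.full(n, TRANSIENT_AMPLITUDE_SCALE * peak)
    if category == "persistent":
        return np.full(n, peak)
    # midpoint sampling of the normalized lifetime keeps short traces off
    # the zero endpoints of the rise/fall ramps
    f = (np.arange(n) + 0.5) / n
    trace = np.full(n, peak)
    rise = f < 0.3
    trace[rise] = peak * f[rise] / 0.3
    fall = f > 0.8
    trace[fall] = peak * (1.0 - f[fall]) / 0.2
    return trace


def _draw_lifetime_frames(rng: np.random.Generator, model: LifetimeMixture,
                          frame_interval: float) -> tuple[str, int]:
    if rng.random() < model.transient_fraction:
        cat, mean = "transient", model.transient_mean_s
    else:
        cat, mean = "bona_fide", model.bona_fide_mean_s
    life_s = rng.exponential(mean)
    return cat, max(2, int(round(life_s / frame_interval)))


def _place_positions(rng: np.random.Generator, n: int, width: int, height: int,
                     min_spacing: float, margin: float,
                     max_tries: int = 2000) -> np.ndarray:
    """Uniform placement with pairwise minimum-spacing rejection."""
    if n == 0:
        return np.empty((0, 2))
    # quick density sanity check: expected mean NN spacing of a Poisson
    # process of this intensity is 0.5 / sqrt(density)
    usable = max(width - 2 * margin, 1.0) * max(height - 2 * margin, 1.0)
    if 0.5 / math.sqrt(n / usable) <= min_spacing:
        raise CrowdingError(
            f"{n} spots in {usable:.0f} px^2 gives mean nearest-neighbour "
            f"spacing <= {min_spacing:.2f} px; reduce density"
        )
    pos = np.empty((n, 2))
    placed = 0
    tries = 0
    while placed < n:
        if tries > max_tries * n:
            raise CrowdingError("could not place spots at requested spacing")
        tries += 1
        x = rng.uniform(margin, width - 1 - margin)
        y = rng.uniform(margin, height - 1 - margin)
        if placed:
            d2 = (pos[:placed, 0] - x) ** 2 + (pos[:placed, 1] - y) ** 2
            if d2.min() < min_spacing**2:
                continue
        pos[placed] = (x, y)
        placed += 1
    return pos


def _render_gaussian(image: np.ndarray, x: float, y: float, amp: float,
                     sigma: float) -> None:
    """Add one isotropic 2D Gaussian to ``image`` in place (local patch)."""
    h, w = image.shape
    r = int(math.ceil(5 * sigma))
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1)
    ys = np.arange(y0, y1)[:, None]
    image[y0:y1, x0:x1] += amp * np.exp(
        -((xs - x) ** 2 + (ys - y) ** 2) / (2.0 * sigma**2)
    )


def generate_movie(spec: MovieSpec) -> tuple[dict[str, FrameStack], GroundTruth]:
    """Render a dual-channel synthetic movie with planted CCP events.

    Returns ``{"master": FrameStack, "slave": FrameStack}`` and the ground
    truth.  Identical spec (including seed) gives bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.spot_amplitude_range
    margin = 4.0 * spec.psf_sigma + 2.0

    # draw the event schedule first, then place all events at once so the
    # pairwise spacing rule covers every event in the movie
    events: list[SpotEvent] = []
    eid = 0
    for _ in range(spec.persistent_count):
        amp = rng.uniform(lo, hi)
        events.append(SpotEvent(eid, 0.0, 0.0, 0, spec.n_frames - 1,
                                "persistent", amp,
                                bool(rng.random() < spec.slave_positive_fraction),
                                np.empty(0)))
        eid += 1
    for f in range(spec.n_frames):
        for _ in range(rng.poisson(spec.nucleation_rate)):
            cat, nfr = _draw_lifetime_frames(rng, spec.lifetime_model,
                                             spec.frame_interval)
            death = min(f + nfr - 1, spec.n_frames - 1)
            if f == 0 and death == spec.n_frames - 1:
                death -= 1  # nucleated events never count as persistent
            amp = rng.uniform(lo, hi)
            events.append(SpotEvent(eid, 0.0, 0.0, f, death, cat, amp,
                                    bool(rng.random() < spec.slave_positive_fraction),
                                    np.empty(0)))
            eid += 1

    positions = _place_positions(rng, len(events), spec.width, spec.height,
                                 min_spacing=4.0 * spec.psf_sigma, margin=margin)
    for ev, (x, y) in zip(events, positions):
        ev.x, ev.y = float(x), float(y)
        ev.master_trace = amplitude_profile(ev.category, ev.peak_amplitude,
                                            ev.lifetime_frames)

    shape = (spec.n_frames, spec.height, spec.width)
    master = np.full(shape, float(spec.background_level))
    slave = np.full(shape, float(spec.background_level))
    for ev in events:
        for i, f in enumerate(range(ev.birth, ev.death + 1)):
            a = ev.master_trace[i]
            _render_gaussian(master[f], ev.x, ev.y, a, spec.psf_sigma)
            if ev.slave_positive:
                _render_gaussian(slave[f], ev.x, ev.y,
                                 spec.slave_amplitude_ratio * a, spec.psf_sigma)

    for stack in (master, slave):
        if spec.poisson_noise:
            stack[:] = rng.poisson(np.clip(stack, 0, None)).astype(float)
        if spec.read_noise_sd > 0:
            stack += rng.normal(0.0, spec.read_noise_sd, size=stack.shape)

    gt = GroundTruth(events, spec.n_frames, spec.frame_interval)
    stacks = {
        "master": FrameStack(master, spec.frame_interval, "master"),
        "slave": FrameStack(slave, spec.frame_interval, "slave"),
    }
    return stacks, gt


def generate_track_table(
    n_tracks: int,
    lifetime_model: LifetimeMixture | None = None,
    slave_positive_fraction: float = 0.65,
    noise_sd: float = 1.0,
    frame_interval: float = 2.0,
    peak_amplitude: float = 10.0,
    slave_amplitude_ratio: float = 0.7,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample pre-linked two-channel intensity tracks, bypassing imaging.

    Master traces follow the category profiles of :func:`generate_movie`;
    slave traces are ``slave_amplitude_ratio`` times the master trace for
    tracks drawn slave-positive (Bernoulli with the given fraction) and zero
    otherwise; both channels get additive Gaussian noise of SD ``noise_sd``.

    Returns a long-format table (track_id, frame, channel, amplitude) and a
    per-track ground-truth table (track_id, category, slave_positive,
    lifetime_s, peak_amplitude).
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    model = lifetime_model or LifetimeMixture()
    model.validate()
    rng = np.random.default_rng(seed)

    rows = []
    truth = []
    for tid in range(n_tracks):
        cat, nfr = _draw_lifetime_frames(rng, model, frame_interval)
        positive = bool(rng.random() < slave_positive_fraction)
        m = amplitude_profile(cat, peak_amplitude, nfr)
        s = slave_amplitude_ratio * m if positive else np.zeros(nfr)
        m_obs = m + rng.normal(0, noise_sd, nfr) if noise_sd else m.copy()
        s_obs = s + rng.normal(0, noise_sd, nfr) if noise_sd else s.copy()
        for f in range(nfr):
            rows.append((tid, f, "master", m_obs[f]))
            rows.append((tid, f, "slave", s_obs[f]))
        truth.append((tid, cat, positive, nfr * frame_interval, peak_amplitude))

    table = pd.DataFrame(rows, columns=["track_id", "frame", "channel", "amplitude"])
    gt = pd.DataFrame(
        truth,
        columns=["track_id", "category", "slave_positive", "lifetime_s",
                 "peak_amplitude"],
    )
    return table, gt


def generate_if_image(
    n_spots: int,
    co_occurrence: dict[str, float] | float = 0.7,
    width: int = 512,
    height: int = 512,
    psf_sigma: float = 1.1,
    background_level: float = 100.0,
    read_noise_sd: float = 4.0,
    spot_amplitude_range: tuple[float, float] = (80.0, 250.0),
    secondary_amplitude_ratio: float = 0.7,
    amplitude_correlation: float = 0.5,
    poisson_noise: bool = True,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Render a fixed-cell-like multi-channel still image.

    The master channel carries ``n_spots`` spots placed uniformly with
    minimum-spacing rejection.  Each secondary channel (key of
    ``co_occurrence``; a bare float means one channel named ``"secondary"``)
    is populated per spot with its co-occurrence probability; secondary
    amplitudes mix the master amplitude with an independent draw according to
    ``amplitude_correlation`` (1 → exactly proportional to the master).

    Returns channel images and a ground-truth table with one row per spot
    and a boolean ``<channel>_positive`` column per secondary channel.
    """
    if isinstance(co_occurrence, float | int):
        co_occurrence = {"secondary": float(co_occurrence)}
    for name, p in co_occurrence.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"co-occurrence probability for {name!r} not in [0,1]")
    rng = np.random.default_rng(seed)
    margin = 4.0 * psf_sigma + 2.0  # keep spots clear of the fit-window border
    pos = _place_positions(rng, n_spots, width, height,
                           min_spacing=4.0 * psf_sigma, margin=margin)
    lo, hi = spot_amplitude_range
    amps = rng.uniform(lo, hi, n_spots)

    images = {"master": np.full((height, width), float(background_level))}
    for i in range(n_spots):
        _render_gaussian(images["master"], pos[i, 0], pos[i, 1], amps[i], psf_sigma)

    gt = pd.DataFrame({"x": pos[:, 0], "y": pos[:, 1], "amplitude": amps})
    for name, p in co_occurrence.items():
        positive = rng.random(n_spots) < p
        indep = rng.uniform(lo, hi, n_spots)
        sec_amp = secondary_amplitude_ratio * (
            amplitude_correlation * amps + (1.0 - amplitude_correlation) * indep
        )
        img = np.full((height, width), float(background_level))
        for i in range(n_spots):
            if positive[i]:
                _render_gaussian(img, pos[i, 0], pos[i, 1], sec_amp[i], psf_sigma)
        images[name] = img
        gt[f"{name}_positive"] = positive
        gt[f"{name}_amplitude"] = np.where(positive, sec_amp, 0.0)

    for name in images:
        if poisson_noise:
            images[name] = rng.poisson(np.clip(images[name], 0, None)).astype(float)
        if read_noise_sd > 0:
            images[name] = images[name] + rng.normal(
                0.0, read_noise_sd, size=images[name].shape)
    return images, gt


# ---------------------------------------------------------------------------
# binding titrations


def generate_titration(kind: str, true_params: dict, design: dict | None = None,
                       noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Forward-simulate one binding titration.

    kind:
      * ``"anisotropy"`` — single-site anisotropy vs ligand concentration;
        params F_f, F_b, Kd_uM; design ``ligand_uM`` (default 12 points,
        0.1–200 uM log-spaced).
      * ``"spr_dissociation"`` — biexponential decay; params A_fast, k_fast,
        A_slow, k_slow (per second); design ``time_s`` (default 0–510 s at
        1 s).
      * ``"itc"`` — single-site isotherm heats per injection; params Kd_M,
        n, dH_J_per_mol; design cell/syringe concentrations (molar), cell
        volume (litres) and injection volumes (default 20 x 2.43 ul).

    Gaussian noise of SD ``noise_sd`` (same units as the y column) is added.
    """
    rng = np.random.default_rng(seed)
    design = dict(design or {})
    if kind == "anisotropy":
        conc = np.asarray(design.get("ligand_uM",
                                     np.geomspace(0.1, 200.0, 12)), float)
        y = bindingfit.anisotropy_model(conc, true_params["F_f"],
                                        true_params["F_b"],
                                        true_params["Kd_uM"])
        out = pd.DataFrame({"ligand_uM": conc, "anisotropy": y})
        ycol = "anisotropy"
    elif kind == "spr_dissociation":
        t = np.asarray(design.get("time_s", np.arange(0.0, 510.0 + 1)), float)
        y = bindingfit.biexponential(t, true_params["A_fast"],
                                     true_params["k_fast"],
                                     true_params["A_slow"],
                                     true_params["k_slow"])
        out = pd.DataFrame({"time_s": t, "response_RU": y})
        ycol = "response_RU"
    elif kind == "itc":
        exp = bindingfit.ITCExperiment(
            cell_conc_M=design.get("cell_conc_M", 125e-6),
            syringe_conc_M=design.get("syringe_conc_M", 2.5e-3),
            cell_volume_L=design.get("cell_volume_L", 170e-6),
            injection_volumes_L=np.asarray(
                design.get("injection_volumes_L",
                           np.full(20, 2.43e-6)), float),
        )
        heats = bindingfit.itc_predicted_heats(
            exp, true_params["Kd_M"], true_params["n"],
            true_params["dH_J_per_mol"])
        out = pd.DataFrame({
            "injection_index": np.arange(1, len(heats) + 1),
            "heat_uJ": heats * 1e6,
        })
        ycol = "heat_uJ"
    else:
        raise ValueError(f"unknown titration kind {kind!r}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd:
        out[ycol] = out[ycol] + rng.normal(0.0, noise_sd, len(out))
    return out


# ---------------------------------------------------------------------------
# I/O


def write_movie(stack: FrameStack, path) -> None:
    """Write one channel as a 16-bit multi-page TIFF."""
    data = np.clip(np.round(stack.data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)


def read_movie(path, frame_interval: float, channel: str = "master") -> FrameStack:
    data = tifffile.imread(path).astype(float)
    if data.ndim == 2:
        data = data[None]
    return FrameStack(data, frame_interval, channel)
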