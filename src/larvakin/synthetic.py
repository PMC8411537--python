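"""Synthetic data with known ground truth for every pipeline stage.

Three generators mirror the study's inputs:

* **tracks** -- a run-and-bend model of larval crawling.  Bend events
  arrive as a Poisson process; each event deflects the body angle as a
  half-sine pulse peaking at a sampled amplitude, slows the centroid,
  and turns the heading.  Between events the body is nearly straight
  (|angle| < 5 deg) and the centroid advances at a per-run sampled speed
  while the heading diffuses.  Output matches the tracker's table:
  5 frames/s, 0.13 mm/pixel, centroid and head/tail coordinates and the
  bend angle per frame.
* **climate rasters** -- min/mean/max temperature layers with habitat
  masks, optionally planting a bimodal minimum-temperature histogram
  (a tall cold mode plus a warmer secondary peak at known locations).
* **traits** -- multivariate Brownian evolution on a fixed tree with
  known branch rates, per-trait rates and trait correlations.

A species *panel* links behaviour to an assigned habitat Tmin: bend rate
falls and run speed rises linearly in Tmin, planting the correlations
the downstream analysis is expected to recover.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .habitat import ClimateRaster
from .kinematics import TrackTable, DEFAULT_FPS, DEFAULT_PX_SCALE
from .phylo import Phylogeny, phylo_covariance


class InvalidParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# behaviour parameters and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SpeciesBehaviorParams:
    """Generative behaviour parameters of one synthetic species."""

    species_id: str = "species"
    tmin_assigned: float = 10.0  # degC
    bend_rate: float = 0.2  # bend events / s
    bend_amplitude_mean: float = 45.0  # deg
    bend_duration_mean: float = 1.0  # s
    run_speed_mean: float = 1.0  # mm/s
    run_speed_sd: float = 0.1  # mm/s
    heading_diffusion: float = 0.05  # rad^2 / s
    backward_bout_prob: float = 0.0
    n_larvae: int = 12
    n_frames: int = 900  # 3 min at 5 fps
    fps: float = DEFAULT_FPS
    px_scale: float = DEFAULT_PX_SCALE
    body_length_mm: float = 4.0
    bend_slowdown: float = 0.3  # speed multiplier during a bend event
    backward_window_frames: int = 10

    def validate(self) -> None:
        if self.n_larvae < 1 or self.n_frames < 1:
            raise InvalidParameterError(
                f"n_larvae and n_frames must be positive "
                f"(got {self.n_larvae}, {self.n_frames})"
            )
        if not (0 <= self.backward_bout_prob <= 1):
            raise InvalidParameterError("backward_bout_prob must be in [0, 1]")
        if self.bend_rate < 0 or self.run_speed_mean <= 0 or self.run_speed_sd < 0:
            raise InvalidParameterError("rates and speeds must be non-negative")
        if self.bend_amplitude_mean <= 0 or self.bend_duration_mean <= 0:
            raise InvalidParameterError("bend amplitude and duration must be positive")
        if self.fps <= 0 or self.px_scale <= 0:
            raise InvalidParameterError("fps and px_scale must be positive")

    def expected_bend_probability(self, threshold_deg: float = 20.0) -> float:
        """Fraction of time the half-sine pulses exceed the threshold.

        For a pulse of amplitude A the angle is above the threshold for a
        fraction 1 - (2/pi) asin(th/A) of its duration; the expected bend
        probability is that fraction (at the mean amplitude) times the
        expected fraction of time spent inside events.
        """
        A = self.bend_amplitude_mean
        if A <= threshold_deg:
            return 0.0
        frac_above = 1.0 - (2.0 / math.pi) * math.asin(threshold_deg / A)
        occupancy = min(1.0, self.bend_rate * self.bend_duration_mean)
        return frac_above * occupancy


@dataclass
class GroundTruth:
    """Simulation-side record of what the pipeline should recover."""

    species: list[dict] = field(default_factory=list)
    expected_bend_probability: dict = field(default_factory=dict)
    expected_crawling_speed: dict = field(default_factory=dict)
    tmin: dict = field(default_factory=dict)
    branch_rates: list | None = None
    trait_rates: list | None = None
    correlation: list | None = None
    root_state: list | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


# ---------------------------------------------------------------------------
# track simulation
# ---------------------------------------------------------------------------

def _simulate_one_larva(params: SpeciesBehaviorParams, rng) -> dict:
    p = params
    n = p.n_frames
    dt = 1.0 / p.fps
    t_total = n * dt

    # Poisson bend events: starts, durations, signed amplitudes
    n_events = rng.poisson(p.bend_rate * t_total) if p.bend_rate > 0 else 0
    starts = np.sort(rng.uniform(0, t_total, size=n_events))
    durations = rng.gamma(2.0, p.bend_duration_mean / 2.0, size=n_events)
    amplitudes = np.maximum(
        rng.normal(p.bend_amplitude_mean, 0.15 * p.bend_amplitude_mean, n_events),
        0.3 * p.bend_amplitude_mean,
    )
    signs = rng.choice([-1.0, 1.0], size=n_events)

    t = np.arange(n) * dt
    angle = rng.uniform(-3.0, 3.0, size=n)  # straight-body jitter, < 5 deg
    in_event = np.zeros(n, dtype=bool)
    for s, d, a, sg in zip(starts, durations, amplitudes, signs):
        sel = (t >= s) & (t < s + d)
        tau = (t[sel] - s) / d
        angle[sel] = sg * a * np.sin(np.pi * tau)
        in_event |= sel

    # per-run speeds: resampled after each event
    speed = np.empty(n)
    boundaries = np.searchsorted(t, starts)
    seg_edges = np.unique(np.concatenate(([0], boundaries, [n])))
    for lo, hi in zip(seg_edges[:-1], seg_edges[1:]):
        speed[lo:hi] = max(rng.normal(p.run_speed_mean, p.run_speed_sd), 0.0)
    speed = np.where(in_event, speed * p.bend_slowdown, speed)

    # heading: Gaussian diffusion plus a turn at each event start
    dtheta = rng.normal(0.0, math.sqrt(p.heading_diffusion * dt), size=n)
    for s, a, sg in zip(starts, amplitudes, signs):
        idx = int(np.searchsorted(t, s))
        if idx < n:
            dtheta[idx] += sg * math.radians(a) * 0.5
    theta = np.cumsum(dtheta) + rng.uniform(0, 2 * np.pi)

    # one backward bout: centroid moves anti-parallel to the body axis
    direction = np.ones(n)
    if p.backward_bout_prob > 0 and rng.random() < p.backward_bout_prob:
        w = min(p.backward_window_frames, n)
        start = rng.integers(0, n - w + 1)
        direction[start : start + w] = -1.0

    step_mm = speed * dt * direction
    x_mm = np.concatenate(([0.0], np.cumsum(step_mm * np.cos(theta))[:-1]))
    y_mm = np.concatenate(([0.0], np.cumsum(step_mm * np.sin(theta))[:-1]))
    x_mm += rng.uniform(20.0, 100.0)
    y_mm += rng.uniform(20.0, 100.0)

    half = p.body_length_mm / 2.0
    head_x = x_mm + half * np.cos(theta)
    head_y = y_mm + half * np.sin(theta)
    tail_x = x_mm - half * np.cos(theta)
    tail_y = y_mm - half * np.sin(theta)

    scale = p.px_scale
    return {
        "frame": np.arange(n),
        "x_px": x_mm / scale,
        "y_px": y_mm / scale,
        "bend_angle_deg": angle,
        "head_x_px": head_x / scale,
        "head_y_px": head_y / scale,
        "tail_x_px": tail_x / scale,
        "tail_y_px": tail_y / scale,
    }


def simulate_larva_track(params: SpeciesBehaviorParams, seed: int) -> TrackTable:
    """Simulate per-frame tracks for ``params.n_larvae`` larvae.

    Deterministic for a given (params, seed).  The output table carries
    centroid and head/tail pixel coordinates and the bend angle, in the
    same long format the track reader produces.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(params.n_larvae):
        rec = _simulate_one_larva(params, rng)
        df = pd.DataFrame(rec)
        df.insert(0, "larva_id", f"{params.species_id}_L{i:03d}")
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    return TrackTable(data, fps=params.fps, px_scale=params.px_scale)


# ---------------------------------------------------------------------------
# species panel with Tmin-linked behaviour
# ---------------------------------------------------------------------------

@dataclass
class SlopeSpec:
    """Linear linkage of behaviour parameters to assigned habitat Tmin.

    Defaults plant the study-scale trends: bend rate falls from ~0.6 /s
    at Tmin = 0 degC to near zero at Tmin = 25 degC (bend probabilities
    spanning roughly 0.36 to ~0.01), and run speed rises from 0.95 to
    ~1.45 mm/s over the same range.
    """

    bend_rate_intercept: float = 0.60  # events/s at Tmin = 0
    bend_rate_slope: float = -0.022  # events/s per degC
    speed_intercept: float = 0.95  # mm/s at Tmin = 0
    speed_slope: float = 0.020  # mm/s per degC
    noise_frac: float = 0.05  # lognormal sd of multiplicative noise


def make_species_panel(
    n_species: int,
    tmin_range: tuple[float, float] = (0.0, 25.0),
    slope_spec: SlopeSpec | None = None,
    seed: int = 0,
    n_larvae: int = 12,
    n_frames: int = 900,
) -> tuple[list[SpeciesBehaviorParams], GroundTruth]:
    """Assign each species a habitat Tmin and linked behaviour parameters."""
    if n_species < 3:
        raise InvalidParameterError("panel needs at least 3 species")
    lo, hi = tmin_range
    if not hi > lo:
        raise InvalidParameterError("tmin_range must have positive width")
    spec = slope_spec or SlopeSpec()
    rng = np.random.default_rng(seed)
    tmins = np.sort(rng.uniform(lo, hi, size=n_species))
    panel = []
    truth = GroundTruth()
    for i, tmin in enumerate(tmins):
        noise_b = math.exp(spec.noise_frac * rng.standard_normal()) \
            if spec.noise_frac > 0 else 1.0
        noise_s = math.exp(spec.noise_frac * rng.standard_normal()) \
            if spec.noise_frac > 0 else 1.0
        bend_rate = max(
            (spec.bend_rate_intercept + spec.bend_rate_slope * tmin) * noise_b, 0.01
        )
        run_speed = max(
            (spec.speed_intercept + spec.speed_slope * tmin) * noise_s, 0.05
        )
        params = SpeciesBehaviorParams(
            species_id=f"sp{i:02d}",
            tmin_assigned=float(tmin),
            bend_rate=float(bend_rate),
            run_speed_mean=float(run_speed),
            n_larvae=n_larvae,
            n_frames=n_frames,
        )
        panel.append(params)
        truth.species.append(asdict(params))
        truth.tmin[params.species_id] = float(tmin)
        truth.expected_bend_probability[params.species_id] = (
            params.expected_bend_probability()
        )
        truth.expected_crawling_speed[params.species_id] = float(run_speed)
    return panel, truth


# ---------------------------------------------------------------------------
# Brownian traits on a tree
# ---------------------------------------------------------------------------

def _psd_sqrt(mat: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(mat)
    vals = np.clip(vals, 0.0, None)
    return vecs @ (np.sqrt(vals)[:, None] * vecs.T)


def simulate_brownian_traits(
    tree: Phylogeny,
    branch_rates: np.ndarray,
    trait_rates: np.ndarray,
    correlation: np.ndarray,
    root: np.ndarray,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw tip traits from the matrix normal implied by the model.

    Row covariance is the rate-scaled phylogenetic covariance C; column
    covariance is diag(s) R diag(s) with s = sqrt(trait_rates).  With all
    rate-scaled branch lengths zero, every tip equals the root exactly.
    """
    branch_rates = np.asarray(branch_rates, dtype=float)
    trait_rates = np.asarray(trait_rates, dtype=float)
    correlation = np.asarray(correlation, dtype=float)
    root = np.asarray(root, dtype=float)
    k = trait_rates.size
    if np.any(branch_rates < 0) or np.any(trait_rates <= 0):
        raise InvalidParameterError("branch rates must be >= 0, trait rates > 0")
    if correlation.shape != (k, k) or not np.allclose(correlation, correlation.T):
        raise InvalidParameterError("correlation must be a symmetric k x k matrix")
    if not np.allclose(np.diag(correlation), 1.0):
        raise InvalidParameterError("correlation must have a unit diagonal")
    eigmin = float(np.linalg.eigvalsh(correlation).min())
    if eigmin <= 0:
        raise InvalidParameterError(
            f"correlation matrix is not positive definite "
            f"(smallest eigenvalue {eigmin:.3e})"
        )
    C = phylo_covariance(tree, branch_rates)
    s = np.sqrt(trait_rates)
    Sigma = s[:, None] * correlation * s[None, :]
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((tree.n_tips, k))
    X = root[None, :] + _psd_sqrt(C) @ G @ np.linalg.cholesky(Sigma).T
    return pd.DataFrame(
        X, index=tree.tip_labels, columns=[f"trait_{j}" for j in range(k)]
    )


# ---------------------------------------------------------------------------
# climate rasters and habitat masks
# ---------------------------------------------------------------------------

@dataclass
class FieldSpec:
    """Planted structure of the synthetic minimum-temperature field.

    The base min layer is a north-south gradient from ``t_north`` to
    ``t_south``.  ``bimodal_mask`` (name of one of ``masks``) plants,
    inside that mask, a mixture of a cold mode at ``cold_mode`` degC and
    a warmer secondary peak at ``warm_peak`` degC (``warm_frac`` of the
    cells), each with ``mode_sd`` degC of spread.  Mean and max layers
    sit ``mean_offset`` and ``max_offset`` degC above the min layer.
    """

    t_north: float = -10.0
    t_south: float = 25.0
    mean_offset: float = 8.0
    max_offset: float = 18.0
    masks: dict = field(default_factory=dict)  # name -> (r0, r1, c0, c1)
    bimodal_mask: str | None = None
    cold_mode: float = -5.0
    warm_peak: float = 12.0
    warm_frac: float = 0.35
    mode_sd: float = 0.3


def generate_climate_raster(
    shape: tuple[int, int],
    field_spec: FieldSpec | None = None,
    seed: int = 0,
) -> tuple[dict[str, ClimateRaster], dict[str, np.ndarray]]:
    """Generate min/mean/max temperature layers and boolean habitat masks."""
    nrows, ncols = shape
    if nrows < 1 or ncols < 1:
        raise InvalidParameterError("raster shape must be positive")
    spec = field_spec or FieldSpec()
    rng = np.random.default_rng(seed)
    rows = np.linspace(spec.t_north, spec.t_south, nrows)[:, None]
    tmin = rows + np.zeros((1, ncols)) + rng.normal(0.0, 0.2, size=shape)
    masks: dict[str, np.ndarray] = {}
    for name, (r0, r1, c0, c1) in spec.masks.items():
        if r0 < 0 or c0 < 0 or r1 > nrows or c1 > ncols or r1 <= r0 or c1 <= c0:
            raise InvalidParameterError(
                f"mask {name!r} window {(r0, r1, c0, c1)} outside raster "
                f"bounds {shape}"
            )
        m = np.zeros(shape, dtype=bool)
        m[r0:r1, c0:c1] = True
        masks[name] = m
    if spec.bimodal_mask is not None:
        if spec.bimodal_mask not in masks:
            raise InvalidParameterError(
                f"bimodal_mask {spec.bimodal_mask!r} is not one of the masks"
            )
        sel = masks[spec.bimodal_mask]
        n_cells = int(sel.sum())
        warm = rng.random(n_cells) < spec.warm_frac
        vals = np.where(
            warm,
            rng.normal(spec.warm_peak, spec.mode_sd, n_cells),
            rng.normal(spec.cold_mode, spec.mode_sd, n_cells),
        )
        tmin[sel] = vals
    layers = {
        "min": ClimateRaster(values=tmin),
        "mean": ClimateRaster(values=tmin + spec.mean_offset),
        "max": ClimateRaster(values=tmin + spec.max_offset),
    }
    return layers, masks
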