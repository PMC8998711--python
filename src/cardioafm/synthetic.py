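"""Synthetic AFM and histology data with known ground truth.

Every generator returns its artifact together with a :class:`GroundTruth`
record holding the exact parameters used, so that each downstream
analysis stage can be validated by parameter recovery.  All generators
are deterministic: the same seed and parameters give bit-identical
output.

The tissue-cohort generator emulates the four-group infarct study design
(sham/infarct heart x section close to / far from the infarct).  Its
default parameters encode a *hidden fibrosis* scenario: the far-infarct
sections carry an elevated stiff-ECM area fraction on the stiffness maps
while their collagen-stain fractions stay at sham level, so only the
AFM-side metric separates far-infarct tissue from sham.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .curves import Cantilever, ForceCurve, Segment
from .elasticity import contact_model_force
from .maps import LabeledImage, StiffnessMap
from .relaxation import RelaxationTrace, maxwell_model
from .wlc import wlc_force

__all__ = [
    "GroundTruth",
    "gen_indentation_curve",
    "gen_relaxation_trace",
    "gen_sawtooth_curve",
    "gen_retract_with_adhesion",
    "gen_beat_trace",
    "gen_stiffness_map",
    "gen_psr_image",
    "gen_shg_image",
    "gen_tissue_maps_and_images",
    "TissueSample",
    "HIDDEN_FIBROSIS_SCENARIO",
]


@dataclass(frozen=True)
class GroundTruth:
    """Exact generating parameters attached to a synthetic artifact."""

    kind: str
    params: dict
    rng_seed: int | None = None

    def __getitem__(self, key):
        return self.params[key]


# ---------------------------------------------------------------- force curves

def gen_indentation_curve(
    e_true: float,
    cantilever: Cantilever,
    *,
    noise_sd: float = 0.0,
    noise_fraction: float | None = None,
    z_range: float = 2e-6,
    contact_fraction: float = 0.5,
    speed: float = 1e-6,
    n_samples: int = 1000,
    baseline_tilt: float = 0.0,
    seed: int | None = None,
) -> tuple[ForceCurve, GroundTruth]:
    """Synthetic approach curve: baseline, contact-model indentation, noise.

    The piezo extends by ``z_range`` at ``speed`` (m/s; usual indentation
    speeds run from 50 nm/s to 10 um/s); contact occurs at
    ``contact_fraction`` of the travel.  Past contact the cantilever
    bending d satisfies F(delta) = k d with delta = travel - d, solved
    exactly per sample, so refitting the curve recovers ``e_true``.
    Gaussian noise of standard deviation ``noise_sd`` newtons (or
    ``noise_fraction`` of the peak force) is added to the deflection.
    ``baseline_tilt`` adds a linear optical-artifact slope (N per m of
    piezo travel) across the whole record.
    """
    if not e_true > 0:
        raise ValueError("e_true must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 50e-9 / 20 <= speed <= 10e-6 * 20:
        raise ValueError("speed far outside the plausible indentation range")
    rng = np.random.default_rng(seed)
    k = cantilever.spring_constant
    z0 = contact_fraction * z_range
    in_contact = z0 < z_range

    if in_contact:
        # depth reached when the piezo is fully extended:
        #   z_range - z0 = delta + F(delta)/k
        travel = z_range - z0

        def gap(delta):
            return delta + contact_model_force(cantilever, e_true, delta) / k - travel

        delta_max = brentq(gap, 0.0, travel)
        n_pre = max(int(round(n_samples * z0 / z_range)), 10)
        n_post = n_samples - n_pre
        z_pre = np.linspace(0.0, z0, n_pre, endpoint=False)
        delta = np.linspace(0.0, delta_max, n_post)
        f_post = contact_model_force(cantilever, e_true, delta)
        z_post = z0 + delta + f_post / k
        z = np.concatenate([z_pre, z_post])
        d = np.concatenate([np.zeros(n_pre), f_post / k])
    else:
        z = np.linspace(0.0, z_range, n_samples)
        d = np.zeros(n_samples)
        delta_max = 0.0

    d = d + baseline_tilt * z / k
    f_peak = k * float(np.max(np.abs(d))) if np.any(d) else 0.0
    sd = noise_sd if noise_fraction is None else noise_fraction * f_peak
    d = d + rng.normal(0.0, sd / k, d.size) if sd > 0 else d
    time = np.concatenate([[0.0], np.cumsum(np.abs(np.diff(z)))]) / speed
    time += np.arange(z.size) * 1e-12  # keep time strictly increasing pre-contact
    curve = ForceCurve(
        time=time, piezo_position=z,
        segment=np.full(z.size, Segment.APPROACH.value, dtype=object),
        deflection=d, force=k * d, calibrated=True,
    )
    truth = GroundTruth("indentation", {
        "e_true": e_true, "contact_position": z0 if in_contact else None,
        "delta_max": delta_max, "noise_sd": sd, "geometry": cantilever.tip_geometry.value,
    }, seed)
    return curve, truth


def gen_relaxation_trace(
    g0: float, g1: float, g2: float, tau1: float, tau2: float,
    *,
    duration: float = 60.0,
    n_samples: int = 600,
    noise_sd: float = 0.0,
    normalize_weights: bool = False,
    seed: int | None = None,
) -> tuple[RelaxationTrace, GroundTruth]:
    """Two-element generalized-Maxwell decay sampled on a uniform grid.

    Weights must satisfy g0 + g1 + g2 = 1 (the normalized model has
    G(0) = 1) unless ``normalize_weights`` rescales them.  Gaussian noise
    is added and, as with measured dwell data, the trace is renormalized
    by its maximum so the container invariant max(g) = 1 holds.
    """
    if not tau1 < tau2:
        raise ValueError("tau1 must be < tau2")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    total = g0 + g1 + g2
    if normalize_weights:
        g0, g1, g2 = g0 / total, g1 / total, g2 / total
    elif not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError("weights must sum to 1 (or pass normalize_weights=True)")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration, n_samples)
    g = maxwell_model(t, g0, (g1, g2), (tau1, tau2))
    if noise_sd > 0:
        g = g + rng.normal(0.0, noise_sd, g.size)
        g = g / np.max(g)
    trace = RelaxationTrace(time=t, g=g, dwell_duration=duration)
    truth = GroundTruth("relaxation", {
        "g0": g0, "g1": g1, "g2": g2, "tau1": tau1, "tau2": tau2,
        "noise_sd": noise_sd, "percent_relaxation_true":
            float((1.0 - maxwell_model(np.array([duration]), g0, (g1, g2), (tau1, tau2))[0]) * 100.0),
    }, seed)
    return trace, truth


def gen_sawtooth_curve(
    n_domains: int,
    delta_lc: float = 28e-9,
    *,
    lc_first: float = 60e-9,
    persistence: float = 0.4e-9,
    unfold_force: float = 200e-12,
    temperature: float = 298.0,
    n_samples: int = 4000,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[ForceCurve, GroundTruth]:
    """Multi-domain unfolding sawtooth built from worm-like-chain branches.

    Domain i has contour length ``lc_first + i * delta_lc``; each branch
    follows the worm-like chain up to ``unfold_force`` and then drops to
    the next branch (one domain unfolds, releasing ``delta_lc`` of
    contour).  ``n_domains = 0`` gives a featureless zero-force retract.
    """
    if persistence <= 0:
        raise ValueError("persistence must be > 0")
    if delta_lc <= 0:
        raise ValueError("delta_lc must be > 0")
    rng = np.random.default_rng(seed)
    lcs = lc_first + delta_lc * np.arange(max(n_domains, 0))
    ruptures = []
    for lc in lcs:
        x_r = brentq(lambda x: wlc_force(x, lc, persistence, temperature) - unfold_force,
                     1e-12, lc * (1 - 1e-9))
        ruptures.append(x_r)
    x_end = (ruptures[-1] * 1.15) if ruptures else 200e-9
    x = np.linspace(0.0, x_end, n_samples)
    f = np.zeros_like(x)
    prev = 0.0
    for lc, x_r in zip(lcs, ruptures):
        sel = (x > prev) & (x <= x_r)
        f[sel] = wlc_force(x[sel], lc, persistence, temperature)
        prev = x_r
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, f.size)
    time = np.arange(x.size) * 1e-3
    time[0] = 0.0
    curve = ForceCurve(
        time=time, piezo_position=x,
        segment=np.full(x.size, Segment.RETRACT.value, dtype=object),
        force=f, calibrated=True,
    )
    truth = GroundTruth("sawtooth", {
        "n_domains": n_domains, "delta_lc": delta_lc, "lc_first": lc_first,
        "persistence": persistence, "unfold_force": unfold_force,
        "rupture_extensions": ruptures, "contour_lengths": list(map(float, lcs)),
        "temperature": temperature, "noise_sd": noise_sd,
    }, seed)
    return curve, truth


def gen_retract_with_adhesion(
    peak_force: float = -1e-9,
    peak_distance: float = 0.3e-6,
    detach_distance: float = 1e-6,
    *,
    total_distance: float | None = None,
    event_kinds: tuple[str, ...] = (),
    n_samples: int = 2000,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[ForceCurve, GroundTruth]:
    """Retract curve with an adhesion dip and optional discrete events.

    Without events the dip is a triangle: force falls linearly from 0 to
    ``peak_force`` (negative) at ``peak_distance``, then returns to 0 at
    ``detach_distance``; its work of adhesion is the triangle area
    ``|peak_force| * detach_distance / 2``.  ``event_kinds`` inserts
    upward force steps on the return flank, each preceded by a loading
    ramp (``"rupture"``) or a force plateau (``"tether"``).
    """
    if peak_force > 0:
        raise ValueError("peak_force must be on the adhesion (negative) side")
    if total_distance is None:
        total_distance = 1.5 * detach_distance
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, total_distance, n_samples)
    f = np.zeros_like(x)
    rise = x <= peak_distance
    f[rise] = peak_force * x[rise] / peak_distance
    events: list[dict] = []
    if not event_kinds:
        fall = (x > peak_distance) & (x < detach_distance)
        f[fall] = peak_force * (detach_distance - x[fall]) / (detach_distance - peak_distance)
    else:
        k = len(event_kinds)
        # return flank split into k sub-branches, each ending in a step
        xs = np.linspace(peak_distance, detach_distance, k + 1)
        levels = np.linspace(peak_force, 0.0, k + 1)
        for i, kind in enumerate(event_kinds):
            lo, hi = xs[i], xs[i + 1]
            sel = (x > lo) & (x <= hi)
            if kind == "tether":
                f[sel] = levels[i]            # plateau, then jump to next level
                pre_level = levels[i]
            else:
                # load further downward by half the step, then jump
                depth = levels[i] - 0.5 * (levels[i + 1] - levels[i])
                f[sel] = levels[i] + (depth - levels[i]) * (x[sel] - lo) / (hi - lo)
                pre_level = depth
            events.append({"kind": kind, "position": float(hi),
                           "force_step": float(levels[i + 1] - pre_level)})
        f[x > detach_distance] = 0.0
    work_true = 0.5 * abs(peak_force) * detach_distance if not event_kinds else float(
        abs(np.trapezoid(np.minimum(f, 0.0), x)))
    i_min = int(np.argmin(f))
    truth = GroundTruth("adhesion_retract", {
        "max_adhesion_force": float(-f[i_min]), "distance_at_max": float(x[i_min]),
        "work_of_adhesion": work_true, "events": events, "noise_sd": noise_sd,
    }, seed)
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, f.size)
    time = np.arange(x.size) * 1e-3
    curve = ForceCurve(
        time=time, piezo_position=x,
        segment=np.full(x.size, Segment.RETRACT.value, dtype=object),
        force=f, calibrated=True,
    )
    return curve, truth


# ---------------------------------------------------------------- beat traces

def gen_beat_trace(
    rate_hz: float = 1.0,
    force_amp: float = 2e-9,
    *,
    amp_jitter: float = 0.0,
    interval_model: str = "iid_gaussian",
    interval_sd: float = 0.0,
    alternating_delta: float = 0.2,
    ar1_phi: float = 0.5,
    duration: float = 10.0,
    sampling_hz: float = 500.0,
    rise_time: float = 0.08,
    fall_time: float = 0.12,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Beating force trace: asymmetric triangular pulses on a flat baseline.

    Beat intervals follow one of three models around the mean 1/rate:
    ``iid_gaussian`` (sd ``interval_sd`` seconds), ``alternating``
    (``mean * (1 +/- alternating_delta)``), or ``ar1`` (lag-1
    autoregressive with coefficient ``ar1_phi`` and innovation sd
    ``interval_sd``).  Each pulse rises linearly for ``rise_time`` and
    falls for ``fall_time``, so its FWHM is (rise + fall)/2.  Returns
    ``(time, force, truth)``.
    """
    if rate_hz <= 0:
        raise ValueError("rate_hz must be > 0")
    mean = 1.0 / rate_hz
    if duration < 3 * mean:
        raise ValueError("duration must cover at least 3 beats")
    rng = np.random.default_rng(seed)
    n_beats = int(np.floor((duration - 0.5 * mean) / mean)) + 1
    if interval_model == "iid_gaussian":
        intervals = rng.normal(mean, interval_sd, n_beats - 1)
    elif interval_model == "alternating":
        signs = np.where(np.arange(n_beats - 1) % 2 == 0, 1.0, -1.0)
        intervals = mean * (1.0 + alternating_delta * signs)
    elif interval_model == "ar1":
        eps = rng.normal(0.0, interval_sd, n_beats - 1)
        intervals = np.empty(n_beats - 1)
        prev = 0.0
        for i in range(n_beats - 1):
            prev = ar1_phi * prev + eps[i]
            intervals[i] = mean + prev
    else:
        raise ValueError(f"unknown interval model {interval_model!r}")
    intervals = np.clip(intervals, 0.3 * mean, 1.7 * mean)
    peak_times = 0.5 * mean + np.concatenate([[0.0], np.cumsum(intervals)])
    peak_times = peak_times[peak_times < duration - fall_time]
    amps = force_amp * (1.0 + amp_jitter * rng.standard_normal(peak_times.size))
    t = np.arange(0.0, duration, 1.0 / sampling_hz)
    f = np.zeros_like(t)
    for tp, a in zip(peak_times, amps):
        lo = np.searchsorted(t, tp - rise_time)
        hi = np.searchsorted(t, tp + fall_time, side="right")
        seg = t[lo:hi]
        pulse = np.where(seg < tp,
                         a * (seg - (tp - rise_time)) / rise_time,
                         a * (tp + fall_time - seg) / fall_time)
        f[lo:hi] += np.clip(pulse, 0.0, None)
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, f.size)
    truth = GroundTruth("beat_trace", {
        "peak_times": peak_times, "intervals": np.diff(peak_times),
        "amplitudes": amps, "fwhm": (rise_time + fall_time) / 2.0,
        "rate_hz": rate_hz, "interval_model": interval_model,
        "interval_sd": interval_sd, "noise_sd": noise_sd,
    }, seed)
    return t, f, truth


# ------------------------------------------------------------- tissue cohorts

def _blob_mask(shape: tuple[int, int], fraction: float, rng,
               correlation_px: float = 8.0) -> np.ndarray:
    """Connected scar-like patch mask hitting ``fraction`` exactly.

    A smoothed Gaussian random field is thresholded at the quantile that
    leaves ``fraction`` of the pixels above it, giving blob-shaped
    connected regions with the requested area fraction (to within one
    pixel).
    """
    if fraction <= 0:
        return np.zeros(shape, bool)
    if fraction >= 1:
        return np.ones(shape, bool)
    field_ = gaussian_filter(rng.standard_normal(shape), correlation_px)
    thresh = np.quantile(field_, 1.0 - fraction)
    return field_ > thresh


def gen_stiffness_map(
    ecm_fraction: float,
    *,
    e_cell: float = 5e3,
    e_ecm: float = 25e3,
    sigma_log: float = 0.2,
    shape: tuple[int, int] = (256, 256),
    pixel_size_um: float = 0.390625,   # 100 um / 256 px -> 10,000 um^2 scan
    correlation_px: float = 8.0,
    missing_fraction: float = 0.0,
    seed: int | None = None,
) -> tuple[StiffnessMap, GroundTruth]:
    """Stiffness map with stiff-ECM patches on a softer myocyte background.

    Moduli are lognormal around the class medians (biological stiffness
    distributions are right-skewed); the ECM patch mask is blob-shaped
    and occupies ``ecm_fraction`` of the pixels exactly.  A fraction of
    pixels can be knocked out to emulate discarded force curves.
    """
    if not 0 <= ecm_fraction <= 1:
        raise ValueError("ecm_fraction must be in [0, 1]")
    if e_ecm <= e_cell:
        raise ValueError("e_ecm must exceed e_cell")
    rng = np.random.default_rng(seed)
    ecm = _blob_mask(shape, ecm_fraction, rng, correlation_px)
    e = np.where(
        ecm,
        e_ecm * np.exp(sigma_log * rng.standard_normal(shape)),
        e_cell * np.exp(sigma_log * rng.standard_normal(shape)),
    )
    if missing_fraction > 0:
        e[rng.random(shape) < missing_fraction] = np.nan
    x = (np.arange(shape[1]) + 0.5) * pixel_size_um
    y = (np.arange(shape[0]) + 0.5) * pixel_size_um
    smap = StiffnessMap(x=x, y=y, modulus=e)
    truth = GroundTruth("stiffness_map", {
        "ecm_mask": ecm, "ecm_fraction": float(ecm.mean()),
        "e_cell": e_cell, "e_ecm": e_ecm, "sigma_log": sigma_log,
    }, seed)
    return smap, truth


def gen_psr_image(
    collagen_fraction: float,
    *,
    shape: tuple[int, int] = (256, 256),
    seed: int | None = None,
) -> tuple[LabeledImage, GroundTruth]:
    """Picrosirius-red micrograph with an exact positive-pixel fraction.

    Positive pixels are deep red (R in 150--220, G = B = 40): red
    dominant, hue exactly 0, saturation >= 0.6, green far below the
    pale-gray background (140--200 in every channel), which itself fails
    the rule on saturation, red dominance and the green threshold.  The
    positive green level is single-valued so that an automatic (Otsu)
    green threshold -- which settles just above the lower histogram mode
    -- still classifies every constructed pixel correctly.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    n = h * w
    n_pos = int(round(collagen_fraction * n))
    v = rng.integers(140, 201, size=(h, w)).astype(np.uint8)
    rgb = np.stack([v, v, v], axis=-1)
    pos_idx = rng.choice(n, size=n_pos, replace=False)
    rows, cols = np.unravel_index(pos_idx, shape)
    r = rng.integers(150, 221, size=n_pos).astype(np.uint8)
    rgb[rows, cols, 0] = r
    rgb[rows, cols, 1] = 40
    rgb[rows, cols, 2] = 40
    label = np.zeros(shape, bool)
    label[rows, cols] = True
    truth = GroundTruth("psr_image", {
        "positive_mask": label, "collagen_fraction": n_pos / n}, seed)
    return LabeledImage(rgb=rgb), truth


def gen_shg_image(
    collagen_fraction: float,
    *,
    shape: tuple[int, int] = (256, 256),
    seed: int | None = None,
) -> tuple[LabeledImage, GroundTruth]:
    """SHG micrograph: bright red-channel pixels at an exact fraction.

    The dark background is single-valued on the red channel (with
    residual autofluorescence kept in green/blue) so that an automatic
    (Otsu) red threshold classifies every constructed pixel correctly.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    n = h * w
    n_pos = int(round(collagen_fraction * n))
    red = np.full((h, w), 20, dtype=np.uint8)
    pos_idx = rng.choice(n, size=n_pos, replace=False)
    rows, cols = np.unravel_index(pos_idx, shape)
    red[rows, cols] = rng.integers(180, 251, size=n_pos).astype(np.uint8)
    rgb = np.stack([red, rng.integers(0, 31, size=(h, w)).astype(np.uint8),
                    rng.integers(0, 31, size=(h, w)).astype(np.uint8)], axis=-1)
    label = np.zeros(shape, bool)
    label[rows, cols] = True
    truth = GroundTruth("shg_image", {
        "positive_mask": label, "collagen_fraction": n_pos / n}, seed)
    return LabeledImage(rgb=rgb), truth


# Default hidden-fibrosis study conditions.  Far-infarct sections are
# stiff-ECM rich on the maps but sham-level on both collagen stains; the
# infarct scar itself (close section) is elevated everywhere.
HIDDEN_FIBROSIS_SCENARIO: dict = {
    "groups": ("sham_close", "sham_far", "mi_close", "mi_far"),
    "ecm_fraction": {"sham_close": 0.05, "sham_far": 0.05,
                     "mi_close": 0.40, "mi_far": 0.35},
    "psr_fraction": {"sham_close": 0.025, "sham_far": 0.025,
                     "mi_close": 0.12, "mi_far": 0.025},
    "shg_fraction": {"sham_close": 0.03, "sham_far": 0.03,
                     "mi_close": 0.10, "mi_far": 0.03},
    "e_cell": 5e3,
    "e_ecm": 25e3,
    "sigma_log": 0.2,
    # between-sample biological variability
    "sample_modulus_sigma": 0.03,      # lognormal sd of per-sample modulus scale
    "ecm_fraction_jitter": 0.01,       # sd of per-sample ECM area fraction
    "collagen_fraction_jitter": 0.003, # sd of the per-sample collagen level
    "stain_noise": 0.0005,             # stain-specific measurement noise (fraction)
    "map_shape": (256, 256),
    "image_shape": (256, 256),
}


@dataclass
class TissueSample:
    sample_id: str
    group: str
    stiffness_map: StiffnessMap
    psr: LabeledImage
    shg: LabeledImage
    truth: GroundTruth


def gen_tissue_maps_and_images(
    group: str,
    n_samples: int,
    seed: int | None = None,
    **overrides,
) -> list[TissueSample]:
    """Synthetic tissue samples (stiffness map + PSR + SHG images) for a group.

    Per-sample biology is drawn around the group-level scenario
    parameters: the modulus scale gets a lognormal factor, the ECM area
    fraction a Gaussian jitter, and both stain fractions derive from one
    shared per-sample collagen level (the same tissue is sectioned for
    both stains) plus stain-specific noise.
    """
    scenario = {**HIDDEN_FIBROSIS_SCENARIO, **overrides}
    for key in ("ecm_fraction", "psr_fraction", "shg_fraction"):
        if group not in scenario[key]:
            raise ValueError(f"group {group!r} not in scenario {key} table")
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n_samples):
        sub = rng.integers(0, 2**31 - 1, size=4)
        scale = float(np.exp(scenario["sample_modulus_sigma"] * rng.standard_normal()))
        ecm_frac = float(np.clip(
            scenario["ecm_fraction"][group] + scenario["ecm_fraction_jitter"] * rng.standard_normal(),
            0.0, 0.9))
        collagen_shift = scenario["collagen_fraction_jitter"] * rng.standard_normal()
        psr_frac = float(np.clip(
            scenario["psr_fraction"][group] + collagen_shift
            + scenario["stain_noise"] * rng.standard_normal(), 0.0, 1.0))
        shg_frac = float(np.clip(
            scenario["shg_fraction"][group] + collagen_shift
            + scenario["stain_noise"] * rng.standard_normal(), 0.0, 1.0))
        smap, map_truth = gen_stiffness_map(
            ecm_frac, e_cell=scenario["e_cell"] * scale,
            e_ecm=scenario["e_ecm"] * scale, sigma_log=scenario["sigma_log"],
            shape=tuple(scenario["map_shape"]), seed=int(sub[0]))
        psr, psr_truth = gen_psr_image(psr_frac, shape=tuple(scenario["image_shape"]),
                                       seed=int(sub[1]))
        shg, shg_truth = gen_shg_image(shg_frac, shape=tuple(scenario["image_shape"]),
                                       seed=int(sub[2]))
        truth = GroundTruth("tissue_sample", {
            "group": group, "modulus_scale": scale, "ecm_fraction": ecm_frac,
            "psr_fraction": psr_truth["collagen_fraction"],
            "shg_fraction": shg_truth["collagen_fraction"],
            "map": map_truth, "psr": psr_truth, "shg": shg_truth,
        }, seed)
        samples.append(TissueSample(
            sample_id=f"{group}_{i:02d}", group=group, stiffness_map=smap,
            psr=psr, shg=shg, truth=truth))
    return samples
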