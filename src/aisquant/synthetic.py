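"""Synthetic microscopy and electrophysiology data with known ground truth.

Everything the measurement modules consume can be generated here with the
true answer known by construction:

* AIS-like fluorescence profiles and images: a unit-height plateau between
  the true start and end positions, blurred by a Gaussian point-spread
  function and corrupted by additive Gaussian noise.
* AIS length cohorts: truncated-Normal length populations whose location
  and scale are calibrated to published distribution summaries (medians
  and full widths at half maximum) for the P15/P21 deprivation conditions
  and the enriched-environment (EE) paradigm.
* Current-clamp step families: stylized, piecewise-analytic action
  potentials whose voltage threshold, amplitude, half-width and
  phase-plane peak rates equal the requested parameters exactly, plus
  exponential subthreshold charging; spike counts for long steps follow a
  monotone frequency-vs-current lookup, so I-f ground truth is exact.
* Spontaneous PSC traces: homogeneous Poisson events with biexponential
  kernels and Gaussian noise.

All generators are deterministic given their integer seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .ephys import Sweep, SweepSet
from .morphometry import IntensityProfile

__all__ = [
    "AISGroundTruth", "CohortPreset", "SpikeModelParams", "PSCModelParams",
    "COHORT_PRESETS", "FWHM_FACTOR", "CFOS_SHIFT_UM",
    "gen_ais_profile", "gen_ais_image", "gen_cohort",
    "gen_profiles_for_lengths", "gen_paired_ee_cohort",
    "gen_step_protocol_traces", "gen_psc_trace",
    "rheobase_from_length",
]

#: FWHM of a Gaussian in units of its sigma: 2*sqrt(2*ln 2)
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))
#: mean AIS shortening of recently active (c-Fos+) neurons (um)
CFOS_SHIFT_UM = -3.0


# ---------------------------------------------------------------------------
# ground-truth containers


@dataclass(frozen=True)
class AISGroundTruth:
    """True geometry and imaging conditions of one synthetic AIS."""

    start_um: float
    end_um: float
    psf_sigma_um: float = 0.0
    noise_sd: float = 0.0
    background: float = 0.0

    def __post_init__(self):
        if not (self.end_um > self.start_um >= 0):
            raise ValueError("need end_um > start_um >= 0")
        if self.psf_sigma_um < 0 or self.noise_sd < 0:
            raise ValueError("psf_sigma_um and noise_sd must be >= 0")

    @property
    def length_um(self) -> float:
        return self.end_um - self.start_um

    @property
    def onset_um(self) -> float:
        """Distance from the path origin (soma edge) to the AIS start."""
        return self.start_um


@dataclass(frozen=True)
class CohortPreset:
    """Truncated-Normal AIS length population for one condition."""

    name: str
    mu_um: float
    sigma_um: float
    truncation: tuple = (5.0, 70.0)
    n_per_animal: int = 100
    n_animals: int = 6

    def __post_init__(self):
        if self.sigma_um < 0:
            raise ValueError("sigma_um must be >= 0")
        lo, hi = self.truncation
        if not (lo <= self.mu_um <= hi):
            raise ValueError("truncation interval must contain mu_um")

    @property
    def fwhm_um(self) -> float:
        return FWHM_FACTOR * self.sigma_um


def _preset(name, mu, fwhm=None, sigma=None):
    if sigma is None:
        sigma = fwhm / FWHM_FACTOR
    return CohortPreset(name=name, mu_um=mu, sigma_um=sigma)


#: named length-population presets.  P15/P21 locations are the published
#: medians and scales derive from the published FWHMs via sigma = FWHM/2.3548;
#: the EE pair encodes the ~3 um shortening of the stimulated hemisphere.
COHORT_PRESETS = {
    "P15-Ctrl": _preset("P15-Ctrl", 30.8, fwhm=11.9),
    "P15-Dep": _preset("P15-Dep", 35.8, fwhm=25.3),
    "P21-Ctrl": _preset("P21-Ctrl", 25.6, fwhm=9.79),
    "P21-Dep": _preset("P21-Dep", 31.0, fwhm=10.86),
    "EE-Ctrl-3h": _preset("EE-Ctrl-3h", 24.0, sigma=4.0),
    "EE-Stim-3h": _preset("EE-Stim-3h", 21.0, sigma=4.0),
}


@dataclass(frozen=True)
class SpikeModelParams:
    """Ground-truth AP and protocol parameters for the stylized neuron.

    ``rise_rates_Vps`` are the two phase-plane peak magnitudes (axonal
    component first in time, then the larger somatic component).  The
    linear AIS-length coupling used for simulated cells lives in
    :func:`rheobase_from_length`.
    """

    rheobase_pA: float = 150.0
    v_rest_mV: float = -80.0
    tau_ms: float = 5.0
    v_thr_true_mV: float = -48.0
    ap_peak_mV: float = 35.0
    rise_rates_Vps: tuple = (150.0, 400.0)
    half_width_true_ms: float = 1.2
    sample_rate_Hz: float = 50_000.0
    r_n_MOhm: float = 300.0

    def __post_init__(self):
        if not (self.ap_peak_mV > self.v_thr_true_mV > self.v_rest_mV):
            raise ValueError("need ap_peak > v_thr > v_rest")
        if self.sample_rate_Hz <= 0 or self.tau_ms <= 0 or self.r_n_MOhm <= 0:
            raise ValueError("sample_rate_Hz, tau_ms, r_n_MOhm must be > 0")
        r1, r2 = self.rise_rates_Vps
        if not (0 < r1 < r2):
            raise ValueError("rise_rates must satisfy 0 < first < second")
        if self.half_width_true_ms <= 0:
            raise ValueError("half_width_true_ms must be > 0")


@dataclass(frozen=True)
class PSCModelParams:
    """Poisson PSC train parameters (2-minute voltage-clamp recordings)."""

    rate_Hz: float = 0.2
    amplitude_mean_pA: float = 20.0
    rise_ms: float = 0.5
    decay_ms: float = 5.0
    noise_sd_pA: float = 2.0
    duration_s: float = 120.0
    sample_rate_Hz: float = 50_000.0

    def __post_init__(self):
        if min(self.rate_Hz, self.amplitude_mean_pA, self.rise_ms,
               self.decay_ms, self.duration_s, self.sample_rate_Hz) < 0:
            raise ValueError("all PSC parameters must be non-negative")
        if self.noise_sd_pA < 0:
            raise ValueError("noise_sd_pA must be >= 0")
        if self.decay_ms <= self.rise_ms:
            raise ValueError("decay_ms must exceed rise_ms")


# ---------------------------------------------------------------------------
# intensity profiles and images


def _plateau(x_um, truth: AISGroundTruth):
    """Unit plateau on [start, end], Gaussian-blurred when psf_sigma > 0.

    The blurred form is the exact convolution of the rectangle with a
    Gaussian: 0.5*(erf((x-a)/(s*sqrt2)) - erf((x-b)/(s*sqrt2))).  With no
    blur the edges are inclusive, so on-grid edge samples read 1.0.
    """
    x = np.asarray(x_um, float)
    if truth.psf_sigma_um == 0:
        return ((x >= truth.start_um - 1e-12) &
                (x <= truth.end_um + 1e-12)).astype(float)
    s = truth.psf_sigma_um * math.sqrt(2.0)
    return 0.5 * (special.erf((x - truth.start_um) / s)
                  - special.erf((x - truth.end_um) / s))


def gen_ais_profile(truth: AISGroundTruth, pixel_size_um: float = 0.21,
                    seed: int = 0, span_um: float | None = None,
                    source_id: str = ""):
    """Synthesize a 1D AIS intensity profile.

    Returns ``(IntensityProfile, truth)``.  The profile is
    ``background + plateau + noise`` sampled every ``pixel_size_um`` from
    the path origin; negative noisy samples are clipped to zero (photon
    counts cannot be negative).  Plateaus shorter than 3 pixels are
    rejected as unresolvable.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    if truth.length_um < 3 * pixel_size_um:
        raise ValueError("plateau shorter than 3 pixels is unresolvable")
    if span_um is None:
        span_um = truth.end_um + max(5.0, 6.0 * truth.psf_sigma_um)
    n = int(np.floor(span_um / pixel_size_um)) + 1
    x = np.arange(n) * pixel_size_um
    y = truth.background + _plateau(x, truth)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, truth.noise_sd, size=n)
    profile = IntensityProfile(positions_um=x, intensities=np.maximum(y, 0.0),
                               pixel_size_um=pixel_size_um,
                               source_id=source_id)
    return profile, truth


def _dist_and_arc_to_polyline(px_xy, path):
    """Exact perpendicular distance and arc position to a polyline (pixels)."""
    p = np.asarray(px_xy, float)[:, None, :]           # (M, 1, 2)
    a = np.asarray(path, float)[None, :-1, :]          # (1, S, 2)
    b = np.asarray(path, float)[None, 1:, :]
    ab = b - a
    ab2 = (ab * ab).sum(-1)
    t = np.clip(((p - a) * ab).sum(-1) / np.where(ab2 > 0, ab2, 1.0), 0.0, 1.0)
    proj = a + t[..., None] * ab
    d = np.linalg.norm(p - proj, axis=-1)              # (M, S)
    seglen = np.sqrt(ab2[0])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    k = d.argmin(axis=1)
    rows = np.arange(len(p))
    return d[rows, k], cum[k] + t[rows, k] * seglen[k]


def gen_ais_image(truth: AISGroundTruth, path_px, image_shape,
                  pixel_size_um: float = 0.21, seed: int = 0,
                  cross_sigma_um: float = 0.4, n_slices: int = 1):
    """Render an AIS as a Gaussian-cross-section line structure in an image.

    The longitudinal intensity along the path equals the 1D profile of
    :func:`gen_ais_profile`, so extracting along the true path recovers
    the 1D generator's output up to interpolation error.  With
    ``n_slices > 1`` a thin stack is returned with the structure in the
    middle slice (emulating the in-focus plane before max projection).
    Returns ``(image, path_px)``.
    """
    path = np.atleast_2d(np.asarray(path_px, float))
    if path.shape[0] < 2:
        raise ValueError("path needs at least 2 vertices")
    h, w = image_shape[-2], image_shape[-1]
    if (path[:, 0].min() < 0 or path[:, 0].max() > w - 1
            or path[:, 1].min() < 0 or path[:, 1].max() > h - 1):
        raise ValueError("path leaves image bounds")
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    d_px, s_px = _dist_and_arc_to_polyline(pts, path)
    d_um = d_px * pixel_size_um
    s_um = s_px * pixel_size_um
    plane = (_plateau(s_um, truth)
             * np.exp(-0.5 * (d_um / cross_sigma_um) ** 2)).reshape(h, w)
    rng = np.random.default_rng(seed)
    if n_slices <= 1:
        img = truth.background + plane
        if truth.noise_sd > 0:
            img = img + rng.normal(0.0, truth.noise_sd, size=img.shape)
        return np.maximum(img, 0.0), path
    stack = np.full((n_slices, h, w), truth.background, dtype=float)
    stack[n_slices // 2] += plane
    if truth.noise_sd > 0:
        stack = stack + rng.normal(0.0, truth.noise_sd, size=stack.shape)
    return np.maximum(stack, 0.0), path


# ---------------------------------------------------------------------------
# length cohorts


def _draw_lengths(rng, mu, sigma, truncation, n):
    lo, hi = truncation
    if sigma == 0:
        return np.full(n, float(mu))
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n,
                               random_state=rng)


def gen_cohort(preset, seed: int = 0, n_animals: int | None = None,
               n_per_animal: int | None = None, condition: str | None = None,
               layer: str = "II/III", hemisphere: str = "ctrl",
               cfos_fraction: float | None = None,
               cfos_shift_um: float = CFOS_SHIFT_UM,
               animal_offset_sd_um: float = 0.0,
               animal_prefix: str = "") -> pd.DataFrame:
    """Draw an annotated AIS-length cohort from a preset.

    Lengths are truncated-Normal per animal.  ``animal_offset_sd_um`` adds
    a shared per-animal location offset (biological animal-to-animal
    variation); ``cfos_fraction`` labels that fraction of cells c-Fos+ and
    shifts their population mean by ``cfos_shift_um`` (recently active
    neurons carry shorter AIS).  Fewer than 100 AIS per animal triggers a
    warning (the cohort-statistics sampling rule), not an error.
    """
    if isinstance(preset, str):
        preset = COHORT_PRESETS[preset]
    n_animals = preset.n_animals if n_animals is None else n_animals
    n_per_animal = preset.n_per_animal if n_per_animal is None else n_per_animal
    condition = preset.name if condition is None else condition
    if n_per_animal < 100:
        warnings.warn(f"n_per_animal={n_per_animal} violates the >=100 AIS "
                      "per animal sampling rule", stacklevel=2)
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_animals):
        offset = rng.normal(0.0, animal_offset_sd_um) if animal_offset_sd_um else 0.0
        labels = np.full(n_per_animal, "unknown", dtype=object)
        if cfos_fraction is not None:
            labels = np.where(rng.random(n_per_animal) < cfos_fraction,
                              "+", "-")
        lengths = np.empty(n_per_animal)
        for lab in np.unique(labels):
            m = labels == lab
            mu = preset.mu_um + offset + (cfos_shift_um if lab == "+" else 0.0)
            lengths[m] = _draw_lengths(rng, mu, preset.sigma_um,
                                       preset.truncation, int(m.sum()))
        onsets = np.clip(rng.normal(2.5, 0.8, n_per_animal), 0.5, None)
        for j in range(n_per_animal):
            rows.append(dict(
                ais_id=f"{animal_prefix}a{a:02d}_{j:04d}",
                animal_id=f"{animal_prefix}animal{a:02d}",
                condition=condition, layer=layer, hemisphere=hemisphere,
                cfos=labels[j], length_um=lengths[j], onset_um=onsets[j],
            ))
    return pd.DataFrame(rows)


def gen_paired_ee_cohort(seed: int = 0, n_animals: int = 6,
                         n_per_hemisphere: int = 100,
                         ctrl_preset: str = "EE-Ctrl-3h",
                         stim_preset: str = "EE-Stim-3h",
                         animal_offset_sd_um: float = 1.0) -> pd.DataFrame:
    """Paired two-hemisphere EE design: per animal, a control hemisphere and
    a stimulated hemisphere whose population mean is shifted by the preset
    pair (~3 um shortening).  The per-animal offset is shared across both
    hemispheres, so the paired analysis removes it.
    """
    ctrl = COHORT_PRESETS[ctrl_preset]
    stim = COHORT_PRESETS[stim_preset]
    rng = np.random.default_rng(seed)
    frames = []
    for a in range(n_animals):
        offset = rng.normal(0.0, animal_offset_sd_um)
        for preset, hemi in ((ctrl, "ctrl"), (stim, "treated")):
            lengths = _draw_lengths(
                rng, preset.mu_um + offset, preset.sigma_um,
                preset.truncation, n_per_hemisphere)
            frames.append(pd.DataFrame(dict(
                ais_id=[f"ee_a{a:02d}_{hemi}_{j:04d}"
                        for j in range(n_per_hemisphere)],
                animal_id=f"animal{a:02d}", condition="EE-3h",
                layer="II/III", hemisphere=hemi, cfos="unknown",
                length_um=lengths,
                onset_um=np.clip(rng.normal(2.5, 0.8, n_per_hemisphere),
                                 0.5, None),
            )))
    return pd.concat(frames, ignore_index=True)


def gen_profiles_for_lengths(lengths_um, seed: int = 0, onset_um: float = 3.0,
                             psf_sigma_um: float = 0.5, noise_sd: float = 0.1,
                             background: float = 0.0,
                             pixel_size_um: float = 0.21):
    """Profiles whose plateau lengths equal the given cohort lengths.

    Yields ``(IntensityProfile, AISGroundTruth)`` pairs; per-profile seeds
    are derived from ``seed`` so the batch is reproducible.
    """
    seeds = np.random.SeedSequence(seed).generate_state(len(lengths_um))
    out = []
    for k, length in enumerate(np.asarray(lengths_um, float)):
        truth = AISGroundTruth(start_um=onset_um, end_um=onset_um + length,
                               psf_sigma_um=psf_sigma_um, noise_sd=noise_sd,
                               background=background)
        prof, _ = gen_ais_profile(truth, pixel_size_um=pixel_size_um,
                                  seed=int(seeds[k] % (2 ** 31)),
                                  source_id=f"prof{k:05d}")
        out.append((prof, truth))
    return out


# ---------------------------------------------------------------------------
# stylized action-potential sweeps


def rheobase_from_length(length_um, a_pA: float = 400.0,
                         b_pA_per_um: float = 5.0):
    """Linear AIS-length -> rheobase coupling for simulated cells.

    ``rheobase = a - b * length``: a longer AIS clusters more sodium
    channels and lowers the current threshold (defaults give ~50 pA per
    10 um, the scale of the published deprivation effect).
    """
    return a_pA - b_pA_per_um * np.asarray(length_um, float)


class _APWaveform:
    """Piecewise-analytic AP with exact feature ground truth.

    dV/dt over the upstroke is piecewise linear in time with short
    plateaus at the two requested rise rates (so centered differences on
    the sample grid reproduce them exactly); the decay is linear at the
    rate that makes the half-width exact.  All pre-peak knots sit on the
    sample grid, which pins the 50 V/s threshold crossing to a sample at
    the true threshold voltage.
    """

    def __init__(self, params: SpikeModelParams, v_base_gap_mV: float = 10.0):
        p = params
        dt = 1e3 / p.sample_rate_Hz                    # ms
        r1, r2 = p.rise_rates_Vps                      # mV/ms
        amp = p.ap_peak_mV - p.v_thr_true_mV
        self.v_base = p.v_thr_true_mV - v_base_gap_mV
        self.v_thr = p.v_thr_true_mV
        self.v_peak = p.ap_peak_mV
        gap = v_base_gap_mV

        # lead-in: dV/dt ramps s0 -> 50 over d0 (grid multiple), area = gap
        d0 = max(2, int(np.floor(gap / 25.0 / dt))) * dt
        s0 = 2.0 * gap / d0 - 50.0
        if not (0 <= s0 < 50.0):
            raise ValueError("baseline gap incompatible with the 50 V/s "
                             "threshold criterion")
        seg = 2 * dt                                   # ramp/plateau length
        dip = 0.55 * r1
        knots_t = [0.0, d0, d0 + seg, d0 + 2 * seg, d0 + 3 * seg,
                   d0 + 4 * seg, d0 + 5 * seg]
        knots_s = [s0, 50.0, r1, r1, dip, r2, r2]
        area = 0.0
        for i in range(1, len(knots_t)):
            if knots_t[i] > d0:  # area above threshold only
                lo = max(knots_t[i - 1], d0)
                # knots are at or after d0 except the first segment
                area += 0.5 * (knots_s[i - 1] + knots_s[i]) * (knots_t[i] - knots_t[i - 1])
        d_final = 2.0 * (amp - area) / r2
        if d_final < 2 * dt:
            raise ValueError(
                "AP amplitude too small for the requested rise rates")
        knots_t.append(knots_t[-1] + d_final)
        knots_s.append(0.0)
        self.t_thr = d0
        self.t_peak = knots_t[-1]
        self.knots_t = np.array(knots_t)
        self.knots_s = np.array(knots_s)
        # cumulative voltage at knots
        v = [self.v_base]
        for i in range(1, len(knots_t)):
            h = knots_t[i] - knots_t[i - 1]
            v.append(v[-1] + 0.5 * (knots_s[i - 1] + knots_s[i]) * h)
        self.knots_v = np.array(v)

        # decay rate pinned by the true half-width
        v_mid = 0.5 * (self.v_thr + self.v_peak)
        t_mid_rise = self._solve_rise_time(v_mid)
        t_fall_mid = t_mid_rise + p.half_width_true_ms
        if t_fall_mid <= self.t_peak:
            raise ValueError("half-width shorter than the AP upstroke")
        self.q = (self.v_peak - v_mid) / (t_fall_mid - self.t_peak)
        self.t_end = self.t_peak + (self.v_peak - self.v_base) / self.q
        self.duration_ms = self.t_end

    def _eval_rise(self, t):
        """Exact V(t) on the upstroke (piecewise quadratic)."""
        t = np.asarray(t, float)
        i = np.clip(np.searchsorted(self.knots_t, t, side="right") - 1,
                    0, len(self.knots_t) - 2)
        tau = t - self.knots_t[i]
        h = self.knots_t[i + 1] - self.knots_t[i]
        slope = (self.knots_s[i + 1] - self.knots_s[i]) / h
        return self.knots_v[i] + self.knots_s[i] * tau + 0.5 * slope * tau * tau

    def _solve_rise_time(self, v_target):
        lo, hi = self.t_thr, self.t_peak
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if self._eval_rise(mid) < v_target:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def sample(self, t_ms):
        """Evaluate the waveform at times (ms) relative to the lead-in start."""
        t = np.asarray(t_ms, float)
        v = np.empty_like(t)
        rise = t <= self.t_peak
        v[rise] = self._eval_rise(t[rise])
        fall = ~rise
        v[fall] = np.maximum(self.v_peak - self.q * (t[fall] - self.t_peak),
                             self.v_base)
        return v


def _default_f_of_i(amps, rheobase):
    """Monotone saturating frequency lookup (max ~20 Hz)."""
    f = {}
    for a in amps:
        f[a] = 0.0 if a < rheobase else min(20.0, 2.0 + 0.06 * (a - rheobase))
    return f


def gen_step_protocol_traces(params: SpikeModelParams, protocol=None,
                             seed: int = 0, f_of_i: dict | None = None,
                             noise_sd_mV: float = 0.0):
    """Render a current-clamp step family with exact feature ground truth.

    ``protocol`` is a dict with keys ``kind`` ('short' -> 20 ms / 10 pA,
    'long' -> 500 ms / 50 pA), ``step_pA``, ``duration_ms``, ``n_steps``,
    ``start_pA``.  Sub-rheobase steps show exponential charging toward
    ``v_rest + I * R_N``; steps at/above rheobase carry stylized APs.  For
    long steps the spike count per sweep is ``round(f(I) * duration)``
    with a supplied (or default) monotone lookup.

    Returns ``(SweepSet, truth)`` where ``truth`` holds the AP feature
    ground truth, the grid rheobase, per-sweep spike counts/times and the
    frequency lookup.
    """
    protocol = dict(protocol or {})
    kind = protocol.setdefault("kind", "short")
    if kind == "short":
        protocol.setdefault("step_pA", 10.0)
        protocol.setdefault("duration_ms", 20.0)
        protocol.setdefault("n_steps", 30)
    else:
        protocol.setdefault("step_pA", 50.0)
        protocol.setdefault("duration_ms", 500.0)
        protocol.setdefault("n_steps", 8)
    protocol.setdefault("start_pA", 0.0)
    if protocol["step_pA"] <= 0:
        raise ValueError("step increment must be positive")

    p = params
    dt = 1e3 / p.sample_rate_Hz                        # ms
    pre_ms, post_ms, ramp_ms = 50.0, 30.0, 3.0
    dur = protocol["duration_ms"]
    n_t = int(round((pre_ms + dur + post_ms) / dt)) + 1
    t_ms = np.arange(n_t) * dt
    onset_i = int(round(pre_ms / dt))
    offset_i = int(round((pre_ms + dur) / dt))

    ap = _APWaveform(p)
    amps = protocol["start_pA"] + protocol["step_pA"] * np.arange(
        protocol["n_steps"], dtype=float)
    grid_rheo = amps[amps >= p.rheobase_pA]
    rheo_on_grid = float(grid_rheo[0]) if len(grid_rheo) else np.nan
    if kind == "long" and f_of_i is None:
        f_of_i = _default_f_of_i(amps, p.rheobase_pA)

    rng = np.random.default_rng(seed)
    sweeps, spike_times, spike_counts = [], [], []
    for amp_pA in amps:
        v = np.full(n_t, p.v_rest_mV)
        spiking = amp_pA >= p.rheobase_pA
        if kind == "long" and f_of_i is not None:
            n_spikes = int(np.floor(
                f_of_i.get(float(amp_pA), 0.0) * dur * 1e-3 + 0.5))
            spiking = n_spikes > 0
        else:
            n_spikes = 1 if spiking else 0
        if not spiking:
            dv = amp_pA * p.r_n_MOhm / 1000.0          # pA * MOhm -> mV
            tt = t_ms[onset_i:offset_i] - t_ms[onset_i]
            v[onset_i:offset_i] = p.v_rest_mV + dv * (1 - np.exp(-tt / p.tau_ms))
            tail = t_ms[offset_i:] - t_ms[offset_i]
            v[offset_i:] = p.v_rest_mV + (v[offset_i - 1] - p.v_rest_mV) * \
                np.exp(-tail / p.tau_ms)
        else:
            nr = int(round(ramp_ms / dt))
            v[onset_i:onset_i + nr] = np.linspace(
                p.v_rest_mV, ap.v_base, nr, endpoint=False)
            v[onset_i + nr:offset_i] = ap.v_base
            # evenly spaced spike onsets, snapped to the sample grid
            first = pre_ms + ramp_ms + 2.0
            avail = dur - ramp_ms - 4.0
            if n_spikes * ap.duration_ms > avail:
                raise ValueError("requested spike count does not fit the step")
            starts = first + np.arange(n_spikes) * (avail / n_spikes)
            starts_i = np.round(starts / dt).astype(int)
            n_ap = int(np.floor(ap.duration_ms / dt)) + 1
            wave = ap.sample(np.arange(n_ap) * dt)
            times = []
            for si in starts_i:
                v[si:si + n_ap] = wave[:max(0, min(n_ap, n_t - si))]
                times.append((si * dt + ap.t_peak) * 1e-3)
            v[offset_i:offset_i + nr] = np.linspace(
                ap.v_base, p.v_rest_mV, nr, endpoint=False)
            v[offset_i + nr:] = p.v_rest_mV
            spike_times.append(np.array(times))
        if not spiking:
            spike_times.append(np.empty(0))
        spike_counts.append(n_spikes)
        if noise_sd_mV > 0:
            v = v + rng.normal(0.0, noise_sd_mV, size=n_t)
        sweeps.append(Sweep(signal=v, step_pA=float(amp_pA),
                            step_onset_s=pre_ms * 1e-3,
                            step_duration_s=dur * 1e-3))
    sweepset = SweepSet(time_s=t_ms * 1e-3, sweeps=sweeps)
    truth = dict(
        v_threshold_mV=p.v_thr_true_mV,
        amplitude_mV=p.ap_peak_mV - p.v_thr_true_mV,
        half_width_ms=p.half_width_true_ms,
        rise_rates_Vps=p.rise_rates_Vps,
        rheobase_pA=p.rheobase_pA,
        rheobase_on_grid_pA=rheo_on_grid,
        spike_counts=np.array(spike_counts),
        spike_times_s=spike_times,
        f_of_i=f_of_i,
        step_amplitudes_pA=amps,
    )
    return sweepset, truth


# ---------------------------------------------------------------------------
# PSC traces


def gen_psc_trace(params: PSCModelParams, seed: int = 0):
    """Poisson train of biexponential PSCs in Gaussian noise.

    Events are negative-going (inward currents at -90 mV); amplitudes are
    Normal(mean, 0.2*mean) floored at 0.25*mean; overlapping events sum.
    Returns ``(time_s, current_pA, events)`` with the ground-truth event
    table (onset time and drawn amplitude, both positive magnitudes).
    """
    p = params
    rng = np.random.default_rng(seed)
    n_t = int(round(p.duration_s * p.sample_rate_Hz))
    t = np.arange(n_t) / p.sample_rate_Hz
    i_pA = np.zeros(n_t)
    n_ev = rng.poisson(p.rate_Hz * p.duration_s)
    times = np.sort(rng.uniform(0.0, p.duration_s, size=n_ev))
    amps = rng.normal(p.amplitude_mean_pA, 0.2 * p.amplitude_mean_pA,
                      size=n_ev)
    amps = np.maximum(amps, 0.25 * p.amplitude_mean_pA)
    dt = 1.0 / p.sample_rate_Hz
    n_k = int(round((p.rise_ms + 8 * p.decay_ms) * 1e-3 / dt))
    tk = np.arange(n_k) * dt * 1e3
    kern = np.exp(-tk / p.decay_ms) - np.exp(-tk / p.rise_ms)
    kern /= kern.max()
    for t0, a in zip(times, amps):
        i0 = int(round(t0 * p.sample_rate_Hz))
        seg = min(n_k, n_t - i0)
        if seg > 0:
            i_pA[i0:i0 + seg] -= a * kern[:seg]
    if p.noise_sd_pA > 0:
        i_pA = i_pA + rng.normal(0.0, p.noise_sd_pA, size=n_t)
    events = pd.DataFrame({"time_s": times, "amplitude_pA": amps})
    return t, i_pA, events
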