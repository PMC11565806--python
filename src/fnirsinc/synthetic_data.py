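"""Synthetic cohorts, probes, task designs and CW-fNIRS recordings.

The generator emulates the structure of a hair/skin inclusivity study:

* participants with trichoscopy metrics (per side/back scalp region),
  categorical hair scales, Melanin-Index skin pigmentation, head
  measurements and demographics, drawn from the study population's
  means/SDs with configurable dependence between pigmentation and hair
  color;
* a bilateral probe with forehead/side/back regions (4+10+4 long and
  1+2+1 short channels per hemisphere, ~30/~8 mm separations, 760/850 nm,
  10.2 Hz);
* a ball-squeezing design (two conditions, 5 s stimuli, 5-15 s ISI);
* a forward intensity model: baseline attenuated on the log10 scale
  linearly in the normalized pigment/color/thickness/type factors, a
  shared cardiac pulsation whose channel coupling is degraded by hair
  factors, smooth superficial (systemic) physiology shared within a
  hemisphere, evoked responses injected in OD space through the same
  Beer-Lambert forward model the analysis inverts, and white noise at a
  configurable raw-unit floor.

The model is a statistical emulator, not photon transport: it reproduces
the *directions* and rough scales of the factor effects, which is what the
downstream statistics are tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal, stats

from ._types import (
    Channel, IntensityRecording, Optode, Probe, StimDesign,
    LONG_SEPARATION_MM, SHORT_SEPARATION_MM, ROIS, HEMISPHERES, WAVELENGTHS_NM,
)
from . import hrf_glm
from .participant_metrics import CombinedMetricSpec, normalize_metric

__all__ = [
    "TrichoscopyBlock",
    "ParticipantProfile",
    "SimulationConfig",
    "Probe", "Channel", "Optode", "StimDesign", "IntensityRecording",
    "TRICHOSCOPY_POPULATION", "WHOLE_HEAD_POPULATION",
    "generate_participants",
    "generate_probe",
    "generate_events",
    "attenuation_exponent",
    "cardiac_coupling",
    "generate_recording",
    "generate_capping_pair",
]


@dataclass
class TrichoscopyBlock:
    """Dermatoscopy-derived scalp hair metrics for one region."""

    avg_num_hairs: float           # N/cm^2
    avg_shaft_thickness: float     # um
    thin_pct: float
    middle_pct: float
    thick_pct: float
    single_fu_pct: float
    double_fu_pct: float
    triple_fu_pct: float
    n_follicular_units: float
    sinclair_scale: float

    @property
    def cumulative_thickness(self) -> float:
        """mm/cm^2: density times mean shaft diameter (um -> mm)."""
        return self.avg_num_hairs * self.avg_shaft_thickness * 1e-3


@dataclass
class ParticipantProfile:
    id: str
    age: float
    sex: str                        # "male" | "female"
    head_circumference_cm: float
    nasion_inion_cm: float
    ear_to_ear_cm: float
    skin_pigmentation: float        # Melanin Index, 0-99
    skin_type: int                  # Fitzpatrick regrouped 1-3
    hair_color: int                 # 0-4
    hair_type: int                  # 0-4
    hair_texture: int               # 0-3
    trichoscopy: dict[str, TrichoscopyBlock]   # keys: "side", "back"

    def __post_init__(self):
        if not 0 <= self.hair_color <= 4:
            raise ValueError("hair_color outside 0-4")
        if not 0 <= self.hair_type <= 4:
            raise ValueError("hair_type outside 0-4")
        if not 0 <= self.hair_texture <= 3:
            raise ValueError("hair_texture outside 0-3")
        if self.skin_type not in (1, 2, 3):
            raise ValueError("skin_type must be 1, 2 or 3")
        codes = (self.hair_color, self.hair_type, self.hair_texture)
        if any(c == 0 for c in codes) and any(c != 0 for c in codes):
            raise ValueError('"no hair" must set all three hair codes to 0')


# Population means/SDs of the trichoscopy metrics per region.
TRICHOSCOPY_POPULATION = {
    "side": {
        "avg_num_hairs": (160.7, 41.3),
        "avg_shaft_thickness": (62.2, 8.0),
        "thin_pct": (6.5, 5.5),
        "middle_pct": (20.9, 10.7),
        "thick_pct": (72.7, 13.3),
        "single_fu_pct": (31.1, 12.1),
        "double_fu_pct": (43.3, 10.2),
        "triple_fu_pct": (25.6, 12.4),
        "n_follicular_units": (80.6, 18.2),
        "sinclair_scale": (2.5, 0.4),
    },
    "back": {
        "avg_num_hairs": (217.4, 47.2),
        "avg_shaft_thickness": (62.0, 7.9),
        "thin_pct": (5.1, 4.6),
        "middle_pct": (22.3, 10.6),
        "thick_pct": (72.7, 13.5),
        "single_fu_pct": (23.1, 9.6),
        "double_fu_pct": (38.5, 9.5),
        "triple_fu_pct": (38.4, 13.6),
        "n_follicular_units": (93.9, 17.3),
        "sinclair_scale": (1.9, 0.4),
    },
}

# Whole-head factors: mean, SD and (optionally) hard truncation bounds.
WHOLE_HEAD_POPULATION = {
    "skin_pigmentation": (25.3, 18.1, (4.7, 90.0)),
    "head_circumference_cm": (57.1, 2.3, None),
    "nasion_inion_cm": (35.4, 2.4, None),
    "ear_to_ear_cm": (35.8, 2.7, None),
    "age": (26.4, 10.3, (18.0, 89.0)),
}

# Shaft thickness uses the observed study range as truncation bounds.
THICKNESS_BOUNDS_UM = (42.0, 88.0)

# Categorical priors solved once to match the whole-head means/SDs
# (color 3.2/1.0 on 0-4; type 1.8/1.1 on 0-4; texture 1.7/0.8 on 0-3).
HAIR_COLOR_PRIOR = (0.02, 0.06, 0.12, 0.30, 0.50)
HAIR_TYPE_PRIOR_GIVEN_HAIR = (0.46, 0.29, 0.16, 0.09)      # over 1..4
HAIR_TEXTURE_PRIOR_GIVEN_HAIR = (0.40, 0.47, 0.13)          # over 1..3
FEMALE_PROB = 0.55

# Fitzpatrick regrouping thresholds on the Melanin Index.
_SKIN_TYPE_EDGES = (20.0, 45.0)


def _default_attenuation_weights() -> dict:
    # log10 units per normalized factor; anchored to the observed
    # per-region effect directions (and rough magnitudes) of the study.
    return {
        "forehead": {"pigment": 0.85, "color": 0.0, "thickness": 0.0, "type": 0.0},
        "side": {"pigment": 1.6, "color": 1.2, "thickness": 0.6, "type": 0.5},
        "back": {"pigment": 1.2, "color": 1.6, "thickness": 1.2, "type": 0.4},
    }


def _default_coupling_weights() -> dict:
    # fraction of cardiac coupling lost per normalized hair factor
    return {"color": 0.15, "thickness": 0.25, "type": 0.30}


def _default_evoked_betas() -> dict:
    # mol/L effective (no pathlength correction), per condition
    return {
        "left": {"hbo": 1.0e-6, "hbr": -0.3e-6},
        "right": {"hbo": 1.0e-6, "hbr": -0.3e-6},
    }


@dataclass
class SimulationConfig:
    """Forward-model knobs.  Defaults are the emulated study's conditions."""

    seed: int = 0
    baseline_intensity: float = 0.33          # raw units at zero attenuation
    attenuation_weights: dict = field(default_factory=_default_attenuation_weights)
    channel_log10_sd: float = 0.25            # per-channel attenuation jitter
    cardiac_freq_hz: float = 1.1
    cardiac_rel_amplitude: float = 0.01
    coupling_weights: dict = field(default_factory=_default_coupling_weights)
    systemic_rel_amplitude: float = 0.005
    noise_floor_raw: float = 6.8e-6
    wavelength_gains: tuple[float, float] = (1.0, 0.9)
    short_channel_gain: float = 3.0           # less tissue path at ~8 mm
    source_power_policy: str = "fixed"        # or "auto-scaled"
    auto_power_base_pct: float = 5.0
    evoked_betas: dict = field(default_factory=_default_evoked_betas)
    pigment_color_dependence: float = 0.5     # latent Gaussian correlation
    # fast- vs proper-capping degradation (applied to hair regions only)
    fast_capping_attenuation: float = 0.10    # extra log10 loss per hair-factor sum
    fast_capping_coupling_penalty: float = 0.20
    sex_baseline_modifier: dict | None = None   # optional {"female": gain}
    sex_evoked_modifier: dict | None = None

    def __post_init__(self):
        if self.baseline_intensity <= 0:
            raise ValueError("baseline_intensity must be positive")
        if self.noise_floor_raw < 0:
            raise ValueError("noise_floor_raw must be non-negative")
        for region, w in self.attenuation_weights.items():
            if any(v < 0 for v in w.values()):
                raise ValueError(f"negative attenuation weight in {region}")
        if any(v < 0 for v in self.coupling_weights.values()):
            raise ValueError("coupling weights must be non-negative")
        if self.source_power_policy not in ("fixed", "auto-scaled"):
            raise ValueError("source_power_policy must be fixed|auto-scaled")


# ---------------------------------------------------------------------------
# participants


def _truncnorm(rng, mean, sd, lo=None, hi=None, size=None):
    a = -np.inf if lo is None else (lo - mean) / sd
    b = np.inf if hi is None else (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _categorical_from_latent(z: float, prior, values) -> int:
    """Map a standard-normal latent through the categorical inverse CDF."""
    u = stats.norm.cdf(z)
    cum = np.cumsum(prior)
    return int(values[np.searchsorted(cum, u, side="right").clip(0, len(values) - 1)])


def _validate_prior(prior, name):
    prior = np.asarray(prior, dtype=float)
    if np.any(prior < 0) or abs(prior.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} prior must be non-negative and sum to 1")
    return prior


def generate_participants(n: int, config: SimulationConfig | None = None,
                          hair_color_prior=HAIR_COLOR_PRIOR,
                          hair_type_prior=HAIR_TYPE_PRIOR_GIVEN_HAIR,
                          hair_texture_prior=HAIR_TEXTURE_PRIOR_GIVEN_HAIR,
                          ) -> list[ParticipantProfile]:
    """Draw ``n`` participants with the study population's factor structure.

    Continuous factors are truncated normals (observed-range bounds where
    known, otherwise mean ± 3 SD floored at 0); percent triples are
    renormalized to sum to 100; skin pigmentation and hair color share a
    Gaussian copula with latent correlation
    ``config.pigment_color_dependence``; skin type is the Fitzpatrick
    regrouping of the pigment value.  Deterministic under a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or SimulationConfig()
    color_prior = _validate_prior(hair_color_prior, "hair color")
    type_prior = _validate_prior(hair_type_prior, "hair type")
    texture_prior = _validate_prior(hair_texture_prior, "hair texture")
    rng = np.random.default_rng(config.seed)
    rho = float(np.clip(config.pigment_color_dependence, -1.0, 1.0))

    out = []
    for i in range(n):
        # pigment & hair color through a shared latent Gaussian
        z_pig = rng.standard_normal()
        z_col = rho * z_pig + np.sqrt(1.0 - rho ** 2) * rng.standard_normal()
        mean, sd, bounds = WHOLE_HEAD_POPULATION["skin_pigmentation"]
        lo, hi = bounds
        a, b = (lo - mean) / sd, (hi - mean) / sd
        pigment = float(stats.truncnorm.ppf(stats.norm.cdf(z_pig), a, b,
                                            loc=mean, scale=sd))
        hair_color = _categorical_from_latent(z_col, color_prior, range(5))
        if hair_color == 0:
            hair_type = hair_texture = 0
        else:
            hair_type = int(rng.choice(np.arange(1, 5), p=type_prior))
            hair_texture = int(rng.choice(np.arange(1, 4), p=texture_prior))
        skin_type = 1 + int(np.searchsorted(_SKIN_TYPE_EDGES, pigment,
                                            side="right"))

        def head_factor(key):
            mean, sd, bounds = WHOLE_HEAD_POPULATION[key]
            lo, hi = bounds if bounds else (max(0.0, mean - 3 * sd), mean + 3 * sd)
            return float(_truncnorm(rng, mean, sd, lo, hi))

        trich = {}
        for region in ("side", "back"):
            pop = TRICHOSCOPY_POPULATION[region]

            def draw(key, lo=None, hi=None):
                mean, sd = pop[key]
                if lo is None:
                    lo, hi = max(0.0, mean - 3 * sd), mean + 3 * sd
                return float(_truncnorm(rng, mean, sd, lo, hi))

            thin, mid, thick = (draw("thin_pct"), draw("middle_pct"),
                                draw("thick_pct"))
            tot = thin + mid + thick
            thin, mid, thick = (100 * thin / tot, 100 * mid / tot,
                                100 * thick / tot)
            sgl, dbl, trp = (draw("single_fu_pct"), draw("double_fu_pct"),
                             draw("triple_fu_pct"))
            tot = sgl + dbl + trp
            sgl, dbl, trp = 100 * sgl / tot, 100 * dbl / tot, 100 * trp / tot
            trich[region] = TrichoscopyBlock(
                avg_num_hairs=draw("avg_num_hairs"),
                avg_shaft_thickness=draw("avg_shaft_thickness",
                                         *THICKNESS_BOUNDS_UM),
                thin_pct=thin, middle_pct=mid, thick_pct=thick,
                single_fu_pct=sgl, double_fu_pct=dbl, triple_fu_pct=trp,
                n_follicular_units=draw("n_follicular_units"),
                sinclair_scale=draw("sinclair_scale"),
            )

        out.append(ParticipantProfile(
            id=f"sub-{i + 1:04d}",
            age=head_factor("age"),
            sex="female" if rng.random() < FEMALE_PROB else "male",
            head_circumference_cm=head_factor("head_circumference_cm"),
            nasion_inion_cm=head_factor("nasion_inion_cm"),
            ear_to_ear_cm=head_factor("ear_to_ear_cm"),
            skin_pigmentation=pigment,
            skin_type=skin_type,
            hair_color=hair_color,
            hair_type=hair_type,
            hair_texture=hair_texture,
            trichoscopy=trich,
        ))
    return out


# ---------------------------------------------------------------------------
# probe & events

_ROI_LAYOUT = {"forehead": (4, 1), "side": (10, 2), "back": (4, 1)}
_ROI_X = {"forehead": 80.0, "side": 0.0, "back": -80.0}


def generate_probe() -> Probe:
    """Bilateral montage: per hemisphere 4+1 forehead, 10+2 side, 4+1 back
    (long+short) channels at ~30/~8 mm, wavelengths 760/850 nm."""
    sources, detectors, channels = [], [], []
    s_idx = d_idx = 0
    for hemi in HEMISPHERES:
        y = -60.0 if hemi == "left" else 60.0
        for roi in ROIS:
            n_long, n_short = _ROI_LAYOUT[roi]
            x0 = _ROI_X[roi]
            # one source per long channel; detectors shared per pair of
            # long channels; dedicated short-separation detectors
            roi_sources = []
            for k in range(n_long):
                s_idx += 1
                src = Optode(f"S{s_idx}", roi, hemi, (x0 + 5.0 * k, y, 0.0))
                sources.append(src)
                roi_sources.append(src)
                if k % 2 == 0:
                    d_idx += 1
                    det = Optode(f"D{d_idx}", roi, hemi,
                                 (x0 + 5.0 * k + 30.0, y, 0.0))
                    detectors.append(det)
                channels.append(Channel(src.label, detectors[-1].label,
                                        LONG_SEPARATION_MM, "long", roi, hemi))
            for k in range(n_short):
                d_idx += 1
                det = Optode(f"D{d_idx}", roi, hemi,
                             (x0 + 5.0 * k + 8.0, y, 1.0))
                detectors.append(det)
                # short channel re-uses the k-th source of the ROI
                channels.append(Channel(roi_sources[k].label, det.label,
                                        SHORT_SEPARATION_MM, "short", roi, hemi))
    return Probe(sources=sources, detectors=detectors, channels=channels)


def generate_events(n_trials: int = 15, seed: int = 0,
                    conditions: tuple[str, str] = ("left", "right"),
                    stim_duration: float = 5.0,
                    isi_range: tuple[float, float] = (5.0, 15.0)) -> StimDesign:
    """Randomized two-condition design: ``n_trials`` per condition, 5 s
    stimuli, uniform 5-15 s inter-stimulus intervals, no overlap."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    order = np.array(list(conditions) * n_trials)
    rng.shuffle(order)
    events = []
    t = float(rng.uniform(*isi_range))
    for cond in order:
        events.append((t, stim_duration, str(cond)))
        t += stim_duration + float(rng.uniform(*isi_range))
    return StimDesign(events=events, run_duration=float(t + isi_range[0]))


# ---------------------------------------------------------------------------
# forward model

_METRIC_SPEC = CombinedMetricSpec()


def _normalized_factors(profile: ParticipantProfile, region: str) -> dict:
    thickness = (profile.trichoscopy[region].avg_shaft_thickness
                 if region in profile.trichoscopy else 0.0)
    return {
        "pigment": normalize_metric(profile.skin_pigmentation,
                                    *_METRIC_SPEC.pigmentation_range),
        "color": normalize_metric(profile.hair_color,
                                  *_METRIC_SPEC.hair_color_range),
        "thickness": normalize_metric(thickness,
                                      *_METRIC_SPEC.thickness_range),
        "type": normalize_metric(profile.hair_type,
                                 *_METRIC_SPEC.hair_type_range),
    }


def attenuation_exponent(profile: ParticipantProfile, region: str,
                         config: SimulationConfig | None = None) -> float:
    """log10 intensity attenuation for one region of one participant.

    Linear in the normalized factors; the (hairless) forehead responds to
    skin pigmentation only.  Non-decreasing in every factor.
    """
    config = config or SimulationConfig()
    if region not in ROIS:
        raise ValueError(f"unknown region {region!r}")
    weights = config.attenuation_weights[region]
    factors = _normalized_factors(profile, region if region != "forehead"
                                  else "side")
    if region == "forehead":
        return weights["pigment"] * factors["pigment"]
    return sum(weights[k] * factors[k] for k in ("pigment", "color",
                                                 "thickness", "type"))


def cardiac_coupling(profile: ParticipantProfile, region: str,
                     config: SimulationConfig | None = None) -> float:
    """Cardiac-to-optical coupling in [0, 1]: 1 minus the weighted
    normalized hair-factor sum.  Hairless forehead couples fully."""
    config = config or SimulationConfig()
    if region == "forehead":
        return 1.0
    factors = _normalized_factors(profile, region)
    loss = sum(config.coupling_weights.get(k, 0.0) * factors[k]
               for k in ("color", "thickness", "type"))
    return float(np.clip(1.0 - loss, 0.0, 1.0))


def _smooth_noise(rng, n: int, fs: float, cutoff: float = 0.25) -> np.ndarray:
    """Unit-SD low-frequency random process (superficial physiology)."""
    x = rng.standard_normal(n)
    sos = signal.butter(2, cutoff / (fs / 2.0), btype="lowpass", output="sos")
    y = signal.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def generate_recording(profile: ParticipantProfile, probe: Probe,
                       duration_s: float = 180.0, fs: float = 10.2,
                       stim: StimDesign | None = None,
                       config: SimulationConfig | None = None,
                       seed: int | None = None,
                       run_label: str | None = None,
                       channel_seed: int | None = None,
                       _capping_attenuation: float = 0.0,
                       _capping_coupling: float = 0.0) -> IntensityRecording:
    """Simulate one CW intensity recording for a participant on a probe.

    intensity = baseline x 10^(-attenuation) x (1 + coupled cardiac +
    systemic) x exp(-evoked OD) + white noise at the raw-unit floor.
    The cardiac term is shared across wavelengths (that is what the SCI
    detects); evoked responses are injected in OD space through the same
    forward MBLL the analysis inverts, on long channels of the hemisphere
    contralateral to the squeezing hand.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    config = config or SimulationConfig()
    if fs <= 2 * config.cardiac_freq_hz:
        raise ValueError("fs must exceed twice the cardiac frequency")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    # channel-specific effects (placement, local hair/skin under the optode)
    # belong to the cap fit, not to the run: a capping pair shares them
    rng_ch = np.random.default_rng(seed if channel_seed is None else channel_seed)

    n_t = int(round(duration_s * fs))
    t = np.arange(n_t) / fs
    n_ch = probe.n_channels
    n_wl = len(probe.wavelengths)

    # cardiac waveform (fundamental + one harmonic), shared across channels
    phase = rng.uniform(0, 2 * np.pi)
    f0 = config.cardiac_freq_hz
    cardiac = np.sin(2 * np.pi * f0 * t + phase) \
        + 0.3 * np.sin(4 * np.pi * f0 * t + 2 * phase)

    # superficial physiology, shared within hemisphere
    systemic = {h: _smooth_noise(rng, n_t, fs) for h in HEMISPHERES}

    baseline = config.baseline_intensity
    if config.sex_baseline_modifier:
        baseline *= config.sex_baseline_modifier.get(profile.sex, 1.0)
    wl_gain = np.asarray(config.wavelength_gains, dtype=float)[:n_wl]

    # per-condition evoked OD (wavelength x time), reused across channels
    evoked_od = None
    if stim is not None:
        evoked_od = {}
        sex_gain = 1.0
        if config.sex_evoked_modifier:
            sex_gain = config.sex_evoked_modifier.get(profile.sex, 1.0)
        for cond in stim.conditions:
            betas = config.evoked_betas.get(cond, {"hbo": 0.0, "hbr": 0.0})
            reg_hbo = hrf_glm.hrf_regressor(hrf_glm.HRF_SPEC_HBO, fs, n_t,
                                            stim.onsets(cond))
            reg_hbr = hrf_glm.hrf_regressor(hrf_glm.HRF_SPEC_HBR, fs, n_t,
                                            stim.onsets(cond))
            conc = np.vstack([betas["hbo"] * sex_gain * reg_hbo,
                              betas["hbr"] * sex_gain * reg_hbr])
            evoked_od[cond] = hrf_glm.EXTINCTION_CM_PER_M @ conc  # per cm

    data = np.empty((n_ch, n_wl, n_t))
    power = np.full((n_ch, n_wl), 100.0)
    hair_sum = {roi: sum(_normalized_factors(profile, roi).values())
                - _normalized_factors(profile, roi)["pigment"]
                for roi in ("side", "back")}
    for i, ch in enumerate(probe.channels):
        att = attenuation_exponent(profile, ch.roi, config)
        if ch.roi != "forehead":
            att += _capping_attenuation * hair_sum[ch.roi]
        att += rng_ch.normal(0.0, config.channel_log10_sd)
        att = max(att, 0.0)
        coupling = cardiac_coupling(profile, ch.roi, config)
        if ch.roi != "forehead":
            coupling = max(0.0, coupling - _capping_coupling)
        base_i = baseline * 10.0 ** (-att)
        if ch.kind == "short":
            # shorter tissue path: short channels detect more light
            base_i *= config.short_channel_gain
        sys_gain = rng_ch.uniform(0.5, 1.5)
        clean = base_i * (1.0
                          + config.cardiac_rel_amplitude * coupling * cardiac
                          + config.systemic_rel_amplitude * sys_gain
                          * systemic[ch.hemisphere])
        od_task = 0.0
        if evoked_od is not None and ch.kind == "long" and ch.roi == "side":
            # contralateral response: left hand drives the right hemisphere
            cond = "left" if ch.hemisphere == "right" else "right"
            if cond in evoked_od:
                od_task = evoked_od[cond] * (ch.separation_mm / 10.0)
        for w in range(n_wl):
            od_w = od_task[w] if isinstance(od_task, np.ndarray) else 0.0
            trace = clean * wl_gain[w] * np.exp(-od_w)
            if config.source_power_policy == "auto-scaled":
                p = float(np.clip(config.auto_power_base_pct * 10.0 ** att,
                                  config.auto_power_base_pct, 100.0))
                power[i, w] = p
                trace = trace * (p / 100.0)
            noise = rng.normal(0.0, config.noise_floor_raw, size=n_t)
            data[i, w] = trace + noise

    if run_label is None:
        run_label = "task" if stim is not None else "rest_proper_cap"
    return IntensityRecording(data=data, fs=fs, channels=list(probe.channels),
                              wavelengths=tuple(probe.wavelengths),
                              source_power_pct=power, run_label=run_label)


def generate_capping_pair(profile: ParticipantProfile, probe: Probe,
                          config: SimulationConfig | None = None,
                          duration_s: float = 180.0, fs: float = 10.2,
                          seed: int | None = None,
                          ) -> tuple[IntensityRecording, IntensityRecording]:
    """Two 3-minute resting runs: run 1 after fast capping (hair-dependent
    extra attenuation and coupling loss on side/back), run 2 after proper
    capping.  The forehead is unaffected by the hair degradation."""
    config = config or SimulationConfig()
    seed = config.seed if seed is None else seed
    hair_pen = {roi: sum(v for k, v in _normalized_factors(profile, roi).items()
                         if k != "pigment") for roi in ("side", "back")}
    max_pen = max(hair_pen.values()) if hair_pen else 0.0
    run1 = generate_recording(
        profile, probe, duration_s, fs, stim=None, config=config,
        seed=seed, channel_seed=seed + 10_000, run_label="rest_fast_cap",
        _capping_attenuation=config.fast_capping_attenuation,
        _capping_coupling=config.fast_capping_coupling_penalty
        * min(1.0, max_pen),
    )
    run2 = generate_recording(
        profile, probe, duration_s, fs, stim=None, config=config,
        seed=seed + 1, channel_seed=seed + 10_000,
        run_label="rest_proper_cap",
    )
    return run1, run2
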