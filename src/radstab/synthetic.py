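"""Synthetic multi-b-value DWI cohorts with known ground truth.

This module builds digital phantoms of a pelvic slab containing one tumor
lesion, forward-models the diffusion signal (IVIM bi-exponential, diffusion
kurtosis, or a combined perfusion+kurtosis model), applies the acquisition
effects of simultaneous-multislice (SMS) acceleration (T1-saturation scaling
from the shortened TR, plus an acceleration-dependent noise scale), and adds
Rician magnitude noise with per-b-value signal averaging.

Every operation is a pure function of its inputs and an explicit seed, so the
whole downstream pipeline (model fitting, feature extraction, stability and
staging statistics) is testable without any acquired data.

Units: b-values in s/mm^2, diffusivities (D, D*, MD) in mm^2/s, TR/T1 in ms,
signal in arbitrary consistent units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PARAM_NAMES",
    "BValueScheme",
    "HeterogeneityModel",
    "PhantomSpec",
    "AfProfile",
    "PhantomTruth",
    "DwiSeries",
    "Cohort",
    "default_scheme",
    "default_af_profiles",
    "default_phantom_spec",
    "make_phantom",
    "simulate_signal",
    "emulate_af",
    "add_rician_noise",
    "make_cohort",
    "reference_tissue_mask",
]

#: Parameter fields carried by a phantom: baseline signal, IVIM tissue
#: diffusivity D, pseudo-diffusivity D*, perfusion fraction f, and the
#: kurtosis-model mean diffusivity MD and mean kurtosis MK.
PARAM_NAMES = ("S0", "D", "Dstar", "f", "MD", "MK")

#: Default Rician noise scale (same units as S0), calibrated once so that the
#: default cohort reproduces the qualitative image-quality ordering
#: S1 ~ S2 > S3 (see docs/methods.md); never tuned per run.
DEFAULT_SIGMA = 5.0


@dataclass(frozen=True)
class BValueScheme:
    """Ordered acquisition scheme: (b, number of averages) per diffusion weighting."""

    entries: tuple[tuple[float, int], ...]

    def __post_init__(self):
        b = [e[0] for e in self.entries]
        n = [e[1] for e in self.entries]
        if len(b) == 0:
            raise ValueError("scheme must contain at least one b-value")
        if b[0] != 0:
            raise ValueError("first b-value must be 0")
        if any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ValueError("b-values must be strictly increasing")
        if any(int(k) != k or k < 1 for k in n):
            raise ValueError("n_averages must be positive integers")

    @property
    def b_values(self) -> np.ndarray:
        return np.array([e[0] for e in self.entries], dtype=float)

    @property
    def n_averages(self) -> np.ndarray:
        return np.array([e[1] for e in self.entries], dtype=int)

    def __len__(self) -> int:
        return len(self.entries)

    def restrict(self, b_values: Sequence[float]) -> "BValueScheme":
        """Sub-scheme containing exactly the requested b-values (order kept)."""
        wanted = set(float(b) for b in b_values)
        entries = tuple(e for e in self.entries if float(e[0]) in wanted)
        if len(entries) != len(wanted):
            missing = wanted - {e[0] for e in entries}
            raise ValueError(f"b-values not in scheme: {sorted(missing)}")
        return BValueScheme(entries)

    def indices_of(self, b_values: Sequence[float]) -> np.ndarray:
        lookup = {float(e[0]): i for i, e in enumerate(self.entries)}
        return np.array([lookup[float(b)] for b in b_values], dtype=int)


def default_scheme() -> BValueScheme:
    """The 11-b-value pelvic protocol: 0-2000 s/mm^2 with per-b averages."""
    return BValueScheme(
        (
            (0, 1), (10, 1), (20, 1), (40, 1), (80, 1), (150, 1),
            (200, 2), (400, 2), (800, 2), (1500, 4), (2000, 6),
        )
    )


@dataclass(frozen=True)
class HeterogeneityModel:
    """Within-lesion texture: smoothed Gaussian-blob multiplicative field.

    ``amplitude`` is the maximum fractional deviation of a parameter from its
    lesion mean; ``correlation_length`` is the blob standard deviation in
    voxels, i.e. the spatial scale of the texture.
    """

    n_blobs: int = 40
    amplitude: float = 0.12
    correlation_length: float = 3.0

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be > 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to generate one subject's ground truth.

    ``background_params`` / ``lesion_params`` map parameter names from
    :data:`PARAM_NAMES` to either a scalar or a (lo, hi) sampling range.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 24)
    voxel_spacing: tuple[float, float, float] = (3.0, 2.8, 4.4)
    lesion_center: tuple[float, float, float] = (32.0, 32.0, 12.0)
    lesion_radii: tuple[float, float, float] = (9.0, 9.0, 4.5)
    background_params: dict = field(default_factory=dict)
    lesion_params: dict = field(default_factory=dict)
    heterogeneity: HeterogeneityModel = field(default_factory=HeterogeneityModel)
    stage_amp_multiplier: float = 1.6
    stage_label: str = "low"
    signal_model: str = "combined"
    seed: int = 0

    def __post_init__(self):
        if self.stage_label not in ("low", "high"):
            raise ValueError("stage_label must be 'low' or 'high'")
        if self.signal_model not in ("ivim", "dki", "combined"):
            raise ValueError("signal_model must be one of ivim/dki/combined")
        if min(self.lesion_radii) < 2:
            raise ValueError("lesion radii must be >= 2 voxels")
        for c, r, n in zip(self.lesion_center, self.lesion_radii, self.grid_shape):
            if c - r < 0 or c + r > n - 1:
                raise ValueError(
                    f"lesion (center {self.lesion_center}, radii {self.lesion_radii}) "
                    f"extends outside grid {self.grid_shape}"
                )


def _default_background_params() -> dict:
    # Pelvic soft tissue: higher diffusivity, little perfusion, mild kurtosis.
    return {"S0": 170.0, "D": 1.6e-3, "Dstar": 6.0e-3, "f": 0.05,
            "MD": 1.7e-3, "MK": 0.4}


def _default_lesion_params() -> dict:
    # Cervical-tumor scales: restricted diffusion (~0.9e-3 mm^2/s), moderate
    # perfusion fraction, D* an order of magnitude above D, MK near 0.85.
    return {"S0": (190.0, 230.0), "D": (0.7e-3, 1.1e-3),
            "Dstar": (7.0e-3, 15.0e-3), "f": (0.08, 0.18),
            "MD": (1.0e-3, 1.5e-3), "MK": (0.7, 1.0)}


def default_phantom_spec(**overrides) -> PhantomSpec:
    """Spec with the package's documented default tissue values."""
    base = dict(
        background_params=_default_background_params(),
        lesion_params=_default_lesion_params(),
    )
    base.update(overrides)
    return PhantomSpec(**base)


@dataclass(frozen=True)
class AfProfile:
    """Acquisition effects of one SMS acceleration factor.

    T1 saturation: with repetition time ``tr_ms`` and tissue ``t1_ms``, the
    steady-state magnetization is scaled by 1 - exp(-TR/T1); shorter TR at
    higher AF therefore loses signal. ``sigma_scale`` multiplies the Rician
    noise scale relative to AF = 1 (parallel-imaging g-factor-like penalty).
    """

    af: int = 1
    tr_ms: float = 4700.0
    t1_ms: float = 1500.0
    sigma_scale: float = 1.0

    def __post_init__(self):
        if self.af not in (1, 2, 3):
            raise ValueError("af must be 1, 2 or 3")
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be > 0")
        if self.af == 1 and self.sigma_scale != 1.0:
            raise ValueError("af = 1 is the reference: sigma_scale must be 1")
        if self.af > 1 and self.sigma_scale < 1.0:
            raise ValueError("sigma_scale must be >= 1 for af > 1")

    @property
    def saturation_factor(self) -> float:
        if self.t1_ms <= 0:
            return 1.0
        return 1.0 - float(np.exp(-self.tr_ms / self.t1_ms))


def default_af_profiles() -> dict[str, AfProfile]:
    """S1-S3 protocols: AF 1/2/3 with the protocol TRs and default noise scales."""
    return {
        "S1": AfProfile(af=1, tr_ms=4700.0, sigma_scale=1.0),
        "S2": AfProfile(af=2, tr_ms=2500.0, sigma_scale=1.1),
        "S3": AfProfile(af=3, tr_ms=2000.0, sigma_scale=1.3),
    }


@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth parameter fields and lesion mask for one subject."""

    spec: PhantomSpec
    param_fields: dict
    lesion_mask: np.ndarray

    def __post_init__(self):
        if not self.lesion_mask.any():
            raise ValueError("lesion mask is empty")
        for name in PARAM_NAMES:
            if name not in self.param_fields:
                raise ValueError(f"missing parameter field {name}")


@dataclass(frozen=True)
class DwiSeries:
    """One subject/sequence 4D magnitude stack with its b-value scheme."""

    volumes: np.ndarray  # (x, y, z, b-index)
    scheme: BValueScheme
    sequence_label: str = "S1"
    af_profile: AfProfile | None = None
    subject_id: str = "sub-000"
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.volumes.ndim != 4:
            raise ValueError("volumes must be 4D (x, y, z, b)")
        if self.volumes.shape[3] != len(self.scheme):
            raise ValueError("volume count must equal scheme length")
        if np.any(self.volumes < 0):
            raise ValueError("magnitude data must be non-negative")


def _derive_rng(*keys: int) -> np.random.Generator:
    """Deterministic RNG from a tuple of integer keys (master seed first)."""
    return np.random.default_rng(np.random.SeedSequence([int(k) for k in keys]))


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return r2 <= 1.0


def _blob_texture(spec: PhantomSpec, rng: np.random.Generator,
                  lesion_mask: np.ndarray):
    """Zero-mean texture field in [-1, 1] over the lesion bounding box."""
    het = spec.heterogeneity
    c = np.asarray(spec.lesion_center)
    r = np.asarray(spec.lesion_radii)
    lo = np.maximum(np.floor(c - r).astype(int), 0)
    hi = np.minimum(np.ceil(c + r).astype(int) + 1, np.asarray(spec.grid_shape))
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    grids = np.ogrid[box]
    centers = rng.uniform(c - r, c + r, size=(het.n_blobs, 3))
    amps = rng.uniform(-1.0, 1.0, size=het.n_blobs)
    w2 = 2.0 * het.correlation_length**2
    tex = np.zeros([b - a for a, b in zip(lo, hi)])
    for k in range(het.n_blobs):
        d2 = sum((g - ck) ** 2 for g, ck in zip(grids, centers[k]))
        tex += amps[k] * np.exp(-d2 / w2)
    # center over the lesion so the lesion-mean parameter equals the nominal
    # value, then normalize the in-lesion peak to 1 (centering is preserved)
    lesion_in_box = lesion_mask[box]
    if lesion_in_box.any():
        tex -= tex[lesion_in_box].mean()
        peak = np.abs(tex[lesion_in_box]).max()
    else:  # pragma: no cover - lesion always intersects its bounding box
        peak = np.abs(tex).max()
    if peak > 0:
        tex /= peak
    return box, tex


def _resolve(value, rng: np.random.Generator) -> float:
    if np.isscalar(value):
        return float(value)
    lo, hi = value
    return float(rng.uniform(lo, hi))


def make_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Generate ground-truth parameter fields for one subject.

    Background voxels take the (possibly sampled) background value; lesion
    voxels take the lesion value modulated by the multiplicative blob texture,
    clipped to +/- amplitude. High-stage lesions use a larger texture
    amplitude (``stage_amp_multiplier``) so that gray-level-nonuniformity-type
    features genuinely separate the stage groups.
    """
    rng = _derive_rng(spec.seed)
    mask = _ellipsoid_mask(spec.grid_shape, spec.lesion_center, spec.lesion_radii)
    if not mask.any():
        raise ValueError("lesion mask is empty for the given geometry")

    amp = spec.heterogeneity.amplitude
    if spec.stage_label == "high":
        amp *= spec.stage_amp_multiplier

    bg = dict(_default_background_params())
    bg.update(spec.background_params)
    les = dict(_default_lesion_params())
    les.update(spec.lesion_params)

    fields = {}
    box, base_tex = _blob_texture(spec, rng, mask)
    for name in PARAM_NAMES:
        bg_val = _resolve(bg[name], rng)
        les_val = _resolve(les[name], rng)
        fld = np.full(spec.grid_shape, bg_val, dtype=float)
        if amp > 0:
            # Independent texture per parameter: fresh blob field, same model.
            _, tex = _blob_texture(spec, rng, mask)
            factor = np.clip(1.0 + amp * tex, 1.0 - amp, 1.0 + amp)
        else:
            factor = np.ones_like(base_tex)
        lesion_box = np.full(factor.shape, les_val) * factor
        region = fld[box]
        region[mask[box]] = lesion_box[mask[box]]
        fld[box] = region
        fields[name] = fld

    # Voxelwise physical constraints.
    fields["f"] = np.clip(fields["f"], 0.0, 1.0)
    fields["MK"] = np.maximum(fields["MK"], 0.0)
    fields["D"] = np.maximum(fields["D"], 1e-6)
    fields["MD"] = np.maximum(fields["MD"], 1e-6)
    fields["Dstar"] = np.maximum(fields["Dstar"], fields["D"] * (1.0 + 1e-6))
    return PhantomTruth(spec=spec, param_fields=fields, lesion_mask=mask)


def _decay(truth: PhantomTruth, b: float) -> np.ndarray:
    """Noiseless S(b)/S0 for one b-value under the spec's signal model."""
    p = truth.param_fields
    model = truth.spec.signal_model
    if model == "ivim":
        return (1.0 - p["f"]) * np.exp(-b * p["D"]) + p["f"] * np.exp(
            -b * (p["D"] + p["Dstar"])
        )
    kurt = np.exp(-b * p["MD"] + (b**2) * p["MD"] ** 2 * p["MK"] / 6.0)
    if model == "dki":
        return kurt
    # combined: perfusion compartment + kurtosis tissue compartment
    return p["f"] * np.exp(-b * p["Dstar"]) + (1.0 - p["f"]) * kurt


def simulate_signal(truth: PhantomTruth, scheme: BValueScheme | None = None) -> DwiSeries:
    """Forward-model the noiseless multi-b-value signal for one subject.

    S(b=0) equals S0 exactly in every model. If the quadratic kurtosis term
    makes the modelled decay exceed 1 at any b > 0 (MK too large for the
    maximum b), the decay is clipped to 1 and a ``signal_clipped`` flag is
    recorded on the returned series.
    """
    scheme = scheme or default_scheme()
    s0 = truth.param_fields["S0"]
    vols = np.empty(truth.spec.grid_shape + (len(scheme),), dtype=float)
    clipped = False
    for i, b in enumerate(scheme.b_values):
        if b == 0:
            vols[..., i] = s0
            continue
        dec = _decay(truth, b)
        if np.any(dec > 1.0):
            clipped = True
            dec = np.minimum(dec, 1.0)
        vols[..., i] = s0 * dec
    flags = {}
    if clipped:
        warnings.warn("kurtosis term produced signal above S0; clipped", stacklevel=2)
        flags["signal_clipped"] = True
    return DwiSeries(volumes=vols, scheme=scheme, flags=flags)


def emulate_af(series: DwiSeries, profile: AfProfile) -> DwiSeries:
    """Apply SMS acquisition effects to a noiseless series.

    Scales every volume by the T1-saturation factor 1 - exp(-TR/T1) and
    attaches the profile so that :func:`add_rician_noise` applies its
    ``sigma_scale``. Slice-leakage and reconstruction artifacts are out of
    scope of this model.
    """
    factor = profile.saturation_factor
    return replace(
        series,
        volumes=series.volumes * factor,
        af_profile=profile,
        sequence_label=f"S{profile.af}",
    )


def add_rician_noise(series: DwiSeries, sigma: float, seed: int = 0) -> DwiSeries:
    """Rician magnitude noise with per-b signal averaging.

    For each b entry, ``n_averages`` independent magnitude images
    sqrt((S + n_r)^2 + n_i^2), with n_r, n_i ~ N(0, sigma_eff), are averaged;
    sigma_eff = sigma * af_profile.sigma_scale. Averaging magnitudes (rather
    than scaling noise down) preserves the low-SNR Rician bias that drives
    D*/f instability. ``sigma = 0`` returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return series
    scale = sigma * (series.af_profile.sigma_scale if series.af_profile else 1.0)
    rng = _derive_rng(seed)
    out = np.empty_like(series.volumes)
    navg = series.scheme.n_averages
    for i in range(len(series.scheme)):
        s = series.volumes[..., i]
        acc = np.zeros_like(s)
        for _ in range(navg[i]):
            # float32 draws: noise precision is irrelevant at these SNRs and
            # generation dominates the simulation cost
            nr = rng.standard_normal(s.shape, dtype=np.float32)
            ni = rng.standard_normal(s.shape, dtype=np.float32)
            acc += np.sqrt((s + scale * nr) ** 2 + (scale * ni) ** 2)
        out[..., i] = acc / navg[i]
    return replace(series, volumes=out)


@dataclass(frozen=True)
class Cohort:
    """A simulated two-group cohort: per subject one truth + three series."""

    subjects: tuple  # of (subject_id, stage, PhantomTruth, dict[label, DwiSeries])
    metadata: pd.DataFrame

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self):
        return len(self.subjects)


def make_cohort(
    n_low: int,
    n_high: int,
    base_spec: PhantomSpec | None = None,
    af_profiles: dict[str, AfProfile] | None = None,
    seed: int = 0,
    sigma: float = DEFAULT_SIGMA,
    stage_radius_multiplier: float = 1.3,
    radius_jitter: float = 0.2,
) -> Cohort:
    """Simulate a low/high-stage cohort, three SMS sequences per subject.

    Per subject, lesion parameters are resampled from the spec's ranges and
    the lesion radii jittered (uniformly +/- ``radius_jitter`` fractional);
    high-stage subjects get radii scaled by ``stage_radius_multiplier`` and
    the texture-amplitude multiplier from the spec. The three series share one
    :class:`PhantomTruth` and differ only in AF emulation and noise
    realization. Sub-seeds are derived deterministically from ``seed``.
    """
    if n_low < 1 or n_high < 1:
        raise ValueError("group sizes must be >= 1")
    base_spec = base_spec or default_phantom_spec()
    af_profiles = af_profiles or default_af_profiles()

    subjects = []
    rows = []
    stages = ["low"] * n_low + ["high"] * n_high
    for idx, stage in enumerate(stages):
        sub_rng = _derive_rng(seed, idx)
        sub_seed = int(sub_rng.integers(0, 2**31 - 1))
        radii = np.asarray(base_spec.lesion_radii) * sub_rng.uniform(
            1.0 - radius_jitter, 1.0 + radius_jitter
        )
        if stage == "high":
            radii = radii * stage_radius_multiplier
        spec = replace(
            base_spec,
            lesion_radii=tuple(float(r) for r in radii),
            stage_label=stage,
            seed=sub_seed,
        )
        truth = make_phantom(spec)
        clean = simulate_signal(truth)
        subject_id = f"sub-{idx:03d}"
        series_by_label = {}
        for s_idx, (label, profile) in enumerate(sorted(af_profiles.items())):
            noise_rng = _derive_rng(seed, idx, s_idx)
            noise_seed = int(noise_rng.integers(0, 2**31 - 1))
            ser = emulate_af(clean, profile)
            ser = add_rician_noise(ser, sigma, seed=noise_seed)
            ser = replace(ser, subject_id=subject_id)
            series_by_label[label] = ser
            rows.append({"subject_id": subject_id, "stage": stage, "sequence": label})
        subjects.append((subject_id, stage, truth, series_by_label))
    return Cohort(subjects=tuple(subjects), metadata=pd.DataFrame(rows))


def reference_tissue_mask(
    truth: PhantomTruth,
    radii: tuple[float, float, float] = (5.0, 5.0, 2.5),
) -> np.ndarray:
    """Background-tissue reference ROI (muscle analog) for CNR measurements.

    An ellipsoid placed laterally of the lesion in homogeneous background,
    guaranteed not to intersect the lesion. The in-plane direction with the
    most room is used and the in-plane radii shrink to fit when the grid is
    small.
    """
    spec = truth.spec
    gap = 2.0
    best = None
    for axis, sign in ((0, +1), (0, -1), (1, +1), (1, -1)):
        # room between lesion edge and grid border along this direction
        edge = spec.lesion_center[axis] + sign * spec.lesion_radii[axis]
        room = (spec.grid_shape[axis] - 1 - edge) if sign > 0 else edge
        r_fit = min(radii[axis], (room - gap) / 2.0)
        if best is None or r_fit > best[3]:
            best = (axis, sign, room, r_fit)
    axis, sign, room, r_fit = best
    if r_fit < 1.0:
        raise ValueError("reference ROI extends outside grid")
    ref_radii = list(radii)
    ref_radii[axis] = r_fit
    ref_radii[1 - axis] = min(ref_radii[1 - axis], r_fit)
    center = list(spec.lesion_center)
    center[axis] += sign * (spec.lesion_radii[axis] + gap + r_fit)
    ref_radii[2] = min(radii[2], center[2], spec.grid_shape[2] - 1 - center[2])
    mask = _ellipsoid_mask(spec.grid_shape, tuple(center), tuple(ref_radii))
    if (mask & truth.lesion_mask).any():
        raise ValueError("reference ROI overlaps lesion")
    if not mask.any():
        raise ValueError("reference ROI is empty")
    return mask
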