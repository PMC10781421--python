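"""Ground-truth-labelled synthetic inputs for every analysis stage.

Each generator emulates the statistical structure its paired analysis
assumes — not the full optics or physics of the instruments:

* relaxation curves: the two-branch piecewise exponential itself, plus
  additive Gaussian noise;
* fiber-orientation images: depth-layered oriented noise textures whose
  angular spectrum follows a von Mises law around the layer's modal angle,
  with a brightness dip marking the superficial/middle border;
* trabecular volumes: periodic rod lattices, parallel plates, or thresholded
  Gaussian random fields, optionally topped by a dense subchondral band;
* allometric tables: y = b * M**a with multiplicative lognormal noise.

Every generator takes a seed and is bit-reproducible; every generator
returns its ground truth alongside the artifact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq

from .relaxation import LoadingProtocol, RelaxationCurve

__all__ = [
    "LoadingProtocol",
    "RelaxationTruth", "gen_relaxation_curve", "relaxation_preset",
    "OrientationTruth", "gen_orientation_image", "orientation_preset",
    "VolumeTruth", "gen_trabecular_volume", "volume_preset",
    "AllometryTruth", "gen_allometric_table",
    "DEFAULT_PROTOCOL",
]

#: Table-2-style default geometry with the standard loading protocol.
DEFAULT_PROTOCOL = LoadingProtocol(sample_diameter_mm=6.4, sample_thickness_mm=1.7)

_T_SPLIT = 100.0


# ---------------------------------------------------------------------------
# stress-relaxation curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RelaxationTruth:
    """Generating parameters of a two-branch relaxation curve (kPa, s)."""

    A1: float
    tau1: float
    B1: float
    A2: float
    tau2: float
    B2: float
    t_split: float = _T_SPLIT

    def __post_init__(self):
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("time constants must be positive")
        fast = self.A1 * math.exp(-self.t_split / self.tau1) + self.B1
        slow = self.A2 * math.exp(-self.t_split / self.tau2) + self.B2
        scale = max(abs(fast), abs(slow), 1e-12)
        if abs(fast - slow) > 1e-6 * scale:
            raise ValueError(
                f"branches disagree at t={self.t_split:g} s "
                f"(fast={fast:.6g}, slow={slow:.6g} kPa); solve A2 or B2 for "
                "continuity, e.g. via RelaxationTruth.from_fast_phase"
            )

    @classmethod
    def from_fast_phase(cls, A1: float, tau1: float, B1: float, tau2: float,
                        B2: float) -> "RelaxationTruth":
        """Solve A2 so the slow branch meets the fast branch at t_split."""
        sigma_split = A1 * math.exp(-_T_SPLIT / tau1) + B1
        A2 = (sigma_split - B2) / math.exp(-_T_SPLIT / tau2)
        return cls(A1=A1, tau1=tau1, B1=B1, A2=A2, tau2=tau2, B2=B2)

    def evaluate(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        fast = self.A1 * np.exp(-t / self.tau1) + self.B1
        slow = self.A2 * np.exp(-t / self.tau2) + self.B2
        return np.where(t < self.t_split, fast, slow)


def gen_relaxation_curve(
    protocol: LoadingProtocol = DEFAULT_PROTOCOL,
    truth: RelaxationTruth | None = None,
    noise_sd_kPa: float = 0.0,
    sampling_rate_hz: float = 1.0,
    seed: int = 0,
) -> tuple[RelaxationCurve, RelaxationTruth]:
    """Sample a noisy relaxation hold from known piecewise parameters."""
    if truth is None:
        truth = relaxation_preset("terrestrial")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, protocol.hold_duration_s + 0.5 / sampling_rate_hz,
                  1.0 / sampling_rate_hz)
    stress = truth.evaluate(t)
    if noise_sd_kPa > 0:
        stress = stress + rng.normal(0.0, noise_sd_kPa, size=t.shape)
    curve = RelaxationCurve(
        time_s=t, stress_kPa=stress,
        applied_strain=protocol.target_strain, protocol=protocol,
    )
    return curve, truth


def relaxation_preset(habitat: Literal["terrestrial", "aquatic"]) -> RelaxationTruth:
    """Habitat-style presets: fast initial relaxation with a higher peak for
    terrestrial-like cartilage, slow shallow relaxation for aquatic-like;
    identical slow-phase time constant in both."""
    if habitat == "terrestrial":
        return RelaxationTruth.from_fast_phase(A1=2.0, tau1=8.0, B1=1.5,
                                               tau2=300.0, B2=1.0)
    if habitat == "aquatic":
        return RelaxationTruth.from_fast_phase(A1=1.0, tau1=40.0, B1=0.8,
                                               tau2=300.0, B2=0.6)
    raise ValueError(f"unknown habitat {habitat!r}")


# ---------------------------------------------------------------------------
# fiber-orientation images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrientationTruth:
    """Layer fractions (%), per-layer modal angles (deg), von Mises
    concentration of the angular spectrum, and the dip position."""

    layer_fractions: tuple[float, float, float]
    modal_angles_deg: tuple[float, float, float]
    concentration: float
    seed: int
    dip_depth: float | None = None  # superficial/middle border (fraction)


def _oriented_texture(h: int, w: int, angle_deg: float, concentration: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Zero-mean noise texture whose orientation spectrum is von Mises around
    ``angle_deg``; concentration 0 gives isotropic noise."""
    noise = rng.standard_normal((h, w))
    if concentration <= 0:
        return noise
    F = np.fft.fft2(noise)
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    # structure orientation carried by a frequency sample (see orientation.py)
    theta = np.degrees(np.arctan2(-fy, fx)) + 90.0
    delta = np.radians(2.0 * (theta - angle_deg))
    weight = np.exp(concentration * (np.cos(delta) - 1.0))
    weight[0, 0] = 0.0
    tex = np.fft.ifft2(F * weight).real
    sd = tex.std()
    return tex / sd if sd > 0 else tex


def gen_orientation_image(
    layer_fractions: tuple[float, float, float] = (10.0, 35.0, 55.0),
    modal_angles_deg: tuple[float, float, float] = (0.0, 45.0, 90.0),
    concentration: float = 8.0,
    size: int = 512,
    seed: int = 0,
    dip_strength: float = 0.6,
) -> tuple[np.ndarray, OrientationTruth]:
    """Depth-layered oriented texture standing in for a PLM micrograph.

    Rows run surface to deep.  Each layer band carries an oriented noise
    texture at its modal angle; per-row brightness encodes a synthetic
    birefringence signal with a V-shaped dip of ``dip_strength`` at the
    superficial/middle border (only when that border exists).
    """
    fr = np.asarray(layer_fractions, dtype=float)
    if abs(fr.sum() - 100.0) > 1e-6:
        raise ValueError("layer fractions must sum to 100")
    if fr.min() < 0:
        raise ValueError("layer fractions must be non-negative")
    for a in modal_angles_deg:
        if not (-90.0 < a <= 90.0):
            raise ValueError("modal angles must lie in (-90, 90]")
    rng = np.random.default_rng(seed)

    edges = np.concatenate([[0.0], np.cumsum(fr) / 100.0])
    rows = np.round(edges * size).astype(int)
    tex = np.zeros((size, size))
    for i in range(3):
        h = rows[i + 1] - rows[i]
        if h <= 0:
            continue
        tex[rows[i]:rows[i + 1]] = _oriented_texture(
            h, size, modal_angles_deg[i], concentration, rng)

    # map texture to [0, 1]
    o = np.clip(tex, -3.0, 3.0) / 6.0 + 0.5

    dip = None
    brightness = np.ones(size)
    if fr[0] > 0 and fr[0] < 100:
        dip = edges[1]
        y = np.arange(size) / size
        width = 0.06
        v = 1.0 - dip_strength * np.clip(1.0 - np.abs(y - dip) / width, 0.0, 1.0)
        brightness = v
    img = np.round(255.0 * brightness[:, None] * o).astype(np.uint8)
    truth = OrientationTruth(tuple(fr), tuple(modal_angles_deg),
                             concentration, seed, dip_depth=dip)
    return img, truth


def orientation_preset(kind: str, seed: int = 0, size: int = 512,
                       fraction_jitter_pct: float = 2.0):
    """Layered phantoms mimicking the two habitat archetypes.

    ``terrestrial``: arcade-like stratification with a relatively thick deep
    zone (mean fractions 10/35/55 %).  ``aquatic``: weak stratification with
    a thick middle and thin deep zone (12/58/30 %).  ``aquatic_isotropic``:
    fully random fiber texture (concentration 0) that should segment as
    "unstratified".  Per-specimen biological variation is emulated by
    jittering the superficial and deep fractions by N(0, ``fraction_jitter_pct``)
    points (middle absorbs the difference), so different seeds yield
    different true layer geometries.
    """
    if kind == "terrestrial":
        base, conc = (10.0, 35.0, 55.0), 8.0
    elif kind == "aquatic":
        base, conc = (12.0, 58.0, 30.0), 4.0
    elif kind == "aquatic_isotropic":
        return gen_orientation_image((10.0, 35.0, 55.0), (0.0, 45.0, 90.0),
                                     concentration=0.0, size=size, seed=seed)
    else:
        raise ValueError(f"unknown preset {kind!r}")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x0F1B)))
    sup = float(np.clip(base[0] + fraction_jitter_pct * rng.standard_normal(),
                        4.0, 25.0))
    deep = float(np.clip(base[2] + fraction_jitter_pct * rng.standard_normal(),
                         15.0, 80.0))
    fractions = (sup, 100.0 - sup - deep, deep)
    return gen_orientation_image(fractions, (0.0, 45.0, 90.0),
                                 concentration=conc, size=size, seed=seed)


# ---------------------------------------------------------------------------
# trabecular volumes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VolumeTruth:
    """Ground truth of a trabecular phantom."""

    kind: str
    target_bvtv_pct: float
    analytic_bvtv_pct: float | None
    strut_thickness_vox: float | None
    voxel_size_um: float
    subchondral_depth: float | None
    subchondral_bvtv_pct: float | None
    seed: int


def _rod_lattice_fraction(r: float, p: float) -> float:
    """Solid fraction of three orthogonal rod arrays (radius r, pitch p)
    intersecting at common nodes, by inclusion-exclusion."""
    return 3 * math.pi * r**2 / p**2 - 8 * math.sqrt(2.0) * r**3 / p**3


def _rod_lattice(shape, r: float, p: float) -> np.ndarray:
    idx = [np.arange(n, dtype=float) for n in shape]

    def axdist(x):  # distance to nearest lattice line coordinate (offset p/2)
        return np.abs(((x - p / 2.0) % p) - p / 2.0)

    dz, dy, dx = (axdist(idx[0])[:, None, None], axdist(idx[1])[None, :, None],
                  axdist(idx[2])[None, None, :])
    rods_z = (dy**2 + dx**2) <= r**2
    rods_y = (dz**2 + dx**2) <= r**2
    rods_x = (dz**2 + dy**2) <= r**2
    return (rods_z | rods_y | rods_x).astype(np.uint8)


def _gaussian_field(shape, corr_vox: float, frac: float,
                    rng: np.random.Generator) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.standard_normal(shape), corr_vox)
    thr = np.quantile(field, 1.0 - frac)
    return (field > thr).astype(np.uint8)


def gen_trabecular_volume(
    shape: tuple[int, int, int] = (128, 128, 128),
    voxel_size_um: float = 20.0,
    kind: Literal["rods", "plates", "gaussian_field"] = "rods",
    strut_thickness_vox: float = 6.0,
    target_bvtv_pct: float = 30.0,
    subchondral_band: tuple[float, float] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, VolumeTruth]:
    """Binary trabecular phantom with known volume fraction and strut size.

    ``subchondral_band=(depth_fraction, band_bvtv_pct)`` replaces the top
    slices along axis 0 (the cartilage interface) with a denser band, standing
    in for a subchondral bone plate.
    """
    if not (0.0 < target_bvtv_pct <= 100.0):
        raise ValueError("target BV/TV must be in (0, 100]")
    if strut_thickness_vox < 2:
        raise ValueError("strut thickness must be >= 2 voxels")
    rng = np.random.default_rng(seed)
    frac = target_bvtv_pct / 100.0
    analytic = None
    strut_truth: float | None = float(strut_thickness_vox)

    if target_bvtv_pct == 100.0:
        vol = np.ones(shape, dtype=np.uint8)
        analytic = 100.0
    elif kind == "rods":
        r = strut_thickness_vox / 2.0
        pmax = 20.0 * strut_thickness_vox
        lo_frac = _rod_lattice_fraction(r, pmax)
        if frac < lo_frac:
            raise ValueError("target BV/TV too low for this strut thickness")
        # densest sensible lattice: rods touching at pitch 2r gives the cap
        if _rod_lattice_fraction(r, 2.0 * r + 1.0) < frac:
            raise ValueError(
                f"target BV/TV {target_bvtv_pct}% infeasible for strut "
                f"thickness {strut_thickness_vox} voxels"
            )
        pitch = brentq(lambda p: _rod_lattice_fraction(r, p) - frac,
                       2.0 * r + 1.0, pmax)
        vol = _rod_lattice(shape, r, pitch)
        analytic = 100.0 * _rod_lattice_fraction(r, pitch)
    elif kind == "plates":
        t = int(round(strut_thickness_vox))
        nz = shape[0]
        n_plates = max(1, int(round(frac * nz / t)))
        if n_plates * t >= nz:
            raise ValueError("plate thickness incompatible with target fraction")
        pitch = nz / n_plates
        plate = np.zeros(nz, dtype=bool)
        for i in range(n_plates):  # centered in each period: no border contact
            start = int(round(i * pitch + (pitch - t) / 2.0))
            plate[start:start + t] = True
        vol = np.broadcast_to(plate[:, None, None], shape).astype(np.uint8).copy()
        analytic = 100.0 * n_plates * t / nz
    elif kind == "gaussian_field":
        vol = _gaussian_field(shape, strut_thickness_vox / 2.0, frac, rng)
        analytic = None        # thickness/geometry truth is empirical here
        strut_truth = None
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")

    band_depth = band_bvtv = None
    if subchondral_band is not None:
        band_depth, band_bvtv = subchondral_band
        if not (0.0 < band_depth < 1.0) or not (0.0 < band_bvtv <= 100.0):
            raise ValueError("invalid subchondral band specification")
        nb = max(1, int(round(band_depth * shape[0])))
        if band_bvtv == 100.0:
            vol[:nb] = 1
        else:
            vol[:nb] = _gaussian_field((nb,) + tuple(shape[1:]), 1.5,
                                       band_bvtv / 100.0, rng)

    truth = VolumeTruth(
        kind=kind, target_bvtv_pct=target_bvtv_pct, analytic_bvtv_pct=analytic,
        strut_thickness_vox=strut_truth, voxel_size_um=voxel_size_um,
        subchondral_depth=band_depth, subchondral_bvtv_pct=band_bvtv, seed=seed,
    )
    return vol, truth


def volume_preset(habitat: Literal["terrestrial", "aquatic"],
                  shape=(128, 128, 128), seed: int = 0):
    """Habitat-style bone phantoms: a dense subchondral plate over ~34.5 %
    trabecular bone for terrestrial, plate-free ~29.4 % bone for aquatic
    (group-mean fractions of the comparative study)."""
    if habitat == "terrestrial":
        return gen_trabecular_volume(shape=shape, kind="gaussian_field",
                                     strut_thickness_vox=6.0,
                                     target_bvtv_pct=34.5,
                                     subchondral_band=(0.05, 98.5), seed=seed)
    if habitat == "aquatic":
        return gen_trabecular_volume(shape=shape, kind="gaussian_field",
                                     strut_thickness_vox=4.0,
                                     target_bvtv_pct=29.4, seed=seed)
    raise ValueError(f"unknown habitat {habitat!r}")


# ---------------------------------------------------------------------------
# allometric tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AllometryTruth:
    a: float
    b: float
    noise_cv: float
    n: int
    mass_range_kg: tuple[float, float]
    seed: int


def gen_allometric_table(
    a: float = 0.28,
    b: float = 0.3,
    noise_cv: float = 0.2,
    n: int = 60,
    mass_range_kg: tuple[float, float] = (0.25, 50000.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, AllometryTruth]:
    """Power-law table y = b * M**a with multiplicative lognormal noise.

    Masses are log-uniform over ``mass_range_kg``; the lognormal sigma is
    chosen so the multiplicative noise has coefficient of variation
    ``noise_cv``.
    """
    if n < 3:
        raise ValueError("need at least 3 rows for a power fit")
    lo, hi = mass_range_kg
    if lo <= 0 or hi <= lo:
        raise ValueError("mass range must be positive and increasing")
    rng = np.random.default_rng(seed)
    mass = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    y = b * mass**a
    if noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        y = y * rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=n)
    df = pd.DataFrame({"body_mass_kg": mass, "response": y})
    truth = AllometryTruth(a=a, b=b, noise_cv=noise_cv, n=n,
                           mass_range_kg=(lo, hi), seed=seed)
    return df, truth


def truth_to_dict(truth) -> dict:
    """JSON-ready dict of any phantom truth dataclass."""
    return asdict(truth)
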