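"""Synthetic osteochondral cohort generator with known ground truth.

The generator emulates a cadaver-knee study: ~48 osteochondral samples from
13 donors across four anatomical locations (femoral groove FG, femoral
lateral condyle FLC, tibial lateral and medial plateau TLP/TMP), each with

* a diffuse-reflectance NIR absorbance spectrum on a 650-1870 nm grid,
* a binary micro-CT-like voxel volume of the subchondral bone, and
* morphometric ground truth (Sb.Th, Tb.Th, BV/TV, SMI) plus a Mankin
  cartilage-degeneration score.

By construction only the first tissue optical window (650-950 nm) carries a
morphometry signal: four Gaussian absorption bands there have amplitudes
linear in the standardised morphometric parameters, while bands in the
second and third windows vary independently of morphometry.  Per-sample
multiplicative scatter (slope and offset) and per-window additive noise are
applied on top, so the full pre-processing chain (MSC, derivatives) has
something real to remove.

All distributional defaults are order-of-magnitude emulation choices in
physiological ranges; no deposited dataset exists to fit them to.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .datasets import DEFAULT_WINDOWS, LOCATIONS, OpticalWindow, SpectralDataset
from .morphometry import BoneVolume

__all__ = [
    "CohortConfig",
    "draw_morphometry",
    "synthesize_spectrum",
    "synthesize_volume",
    "generate_cohort",
    "validate_ground_truth",
]

MORPH_PARAMS = ("sb_th_mm", "tb_th_mm", "bvtv_fraction", "smi")

#: Per-location morphometry means; TMP strictly highest in Sb.Th, Tb.Th and
#: BV/TV (the medial plateau carries the most load).  Units: mm, mm,
#: fraction, unitless.
DEFAULT_MORPH_MEANS = {
    "FG": {"sb_th_mm": 0.26, "tb_th_mm": 0.15, "bvtv_fraction": 0.20, "smi": 1.9},
    "FLC": {"sb_th_mm": 0.28, "tb_th_mm": 0.16, "bvtv_fraction": 0.23, "smi": 1.7},
    "TLP": {"sb_th_mm": 0.31, "tb_th_mm": 0.18, "bvtv_fraction": 0.27, "smi": 1.5},
    "TMP": {"sb_th_mm": 0.40, "tb_th_mm": 0.23, "bvtv_fraction": 0.38, "smi": 1.2},
}

DEFAULT_MORPH_SDS = {
    "sb_th_mm": 0.06,
    "tb_th_mm": 0.035,
    "bvtv_fraction": 0.07,
    "smi": 0.5,
}

#: Hard physical truncation bounds for the truncated-normal draws.
MORPH_BOUNDS = {
    "sb_th_mm": (0.08, 0.8),
    "tb_th_mm": (0.05, 0.45),
    "bvtv_fraction": (0.02, 0.98),
    "smi": (0.0, 3.0),
}

#: Centre (nm), width (nm) of the morphometry-coding Gaussian bands in OW1,
#: one per parameter, on disjoint supports.
OW1_BAND_CENTERS = {
    "sb_th_mm": 720.0,
    "tb_th_mm": 780.0,
    "bvtv_fraction": 845.0,
    "smi": 905.0,
}
OW1_BAND_WIDTH_NM = 18.0

#: Morphometry-independent distractor bands in OW2/OW3 (centre, width, mean
#: amplitude); their amplitudes jitter per sample.
DISTRACTOR_BANDS = (
    (1180.0, 25.0, 0.10),
    (1250.0, 25.0, 0.07),
    (1320.0, 25.0, 0.05),
    (1650.0, 22.0, 0.12),
    (1720.0, 22.0, 0.08),
    (1790.0, 22.0, 0.06),
)

#: Fixed per-parameter base amplitude of the OW1 bands (absorbance units).
OW1_BASE_AMPLITUDE = 0.05


def _default_samples() -> dict[str, int]:
    # 48 analysed samples: two of the original 50 excluded for cartilage loss
    return {"FG": 11, "FLC": 11, "TLP": 13, "TMP": 13}


def _default_coeffs() -> dict[str, float]:
    # Amplitude per unit standardised parameter.
    return {p: 0.0021 for p in MORPH_PARAMS}


def _default_noise() -> dict[str, float]:
    # Additive channel noise after co-added scans and repetition averaging;
    # grows toward longer wavelengths (InGaAs detector tail).
    return {"OW1": 0.0005, "OW2": 0.002, "OW3": 0.003}


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions.

    ``mankin_link_strength`` is the slope of the logistic link between the
    within-location standardised plate thickness and the probability of a
    high (> 4) Mankin score; the default 3.0 separates the class means by
    roughly one cohort standard deviation of Sb.Th.  Setting it to 0 makes
    Mankin independent of morphometry.
    """

    n_donors: int = 13
    locations: tuple[str, ...] = LOCATIONS
    samples_per_location: dict[str, int] = field(default_factory=_default_samples)
    wavelength_start_nm: float = 650.0
    wavelength_stop_nm: float = 1870.0
    wavelength_step_nm: float = 1.0
    window_defs: tuple[OpticalWindow, ...] = DEFAULT_WINDOWS
    morph_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MORPH_MEANS.items()}
    )
    morph_sds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MORPH_SDS))
    ow1_signal_coefficients: dict[str, float] = field(default_factory=_default_coeffs)
    ow1_amplitude_noise_sd: float = 0.0007
    noise_sd_by_window: dict[str, float] = field(default_factory=_default_noise)
    distractor_amplitude_sd: float = 0.005
    scatter_slope_sd: float = 0.05
    scatter_offset_sd: float = 0.02
    mankin_link_strength: float = 3.0
    mankin_class2_rate: float = 0.30
    voxel_um: float = 12.5
    voi_mm: tuple[float, float, float] = (1.8, 1.0, 1.1)  # (z, y, x)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.samples_per_location.values()):
            raise ValueError("samples_per_location entries must be positive")
        if self.n_donors <= 0:
            raise ValueError("n_donors must be positive")
        if set(self.samples_per_location) - set(self.locations):
            raise ValueError("samples_per_location keys must be known locations")
        for loc in self.locations:
            means = self.morph_means[loc]
            if any(means[p] <= 0 for p in ("sb_th_mm", "tb_th_mm")):
                raise ValueError(f"{loc}: thickness means must be positive")
            if not 0.0 < means["bvtv_fraction"] < 1.0:
                raise ValueError(f"{loc}: BV/TV mean must lie in (0, 1)")
        if any(sd < 0 for sd in self.morph_sds.values()):
            raise ValueError("morph_sds must be non-negative")
        wl = self.wavelength_grid
        lo, hi = wl[0], wl[-1]
        spans = sorted((w.lo_nm, w.hi_nm) for w in self.window_defs)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 <= a1:
                raise ValueError("window_defs must be disjoint")
        if spans[0][0] < lo or spans[-1][1] > hi:
            raise ValueError("window_defs must lie inside the wavelength grid span")

    @property
    def wavelength_grid(self) -> np.ndarray:
        n = int(round((self.wavelength_stop_nm - self.wavelength_start_nm) / self.wavelength_step_nm)) + 1
        return self.wavelength_start_nm + self.wavelength_step_nm * np.arange(n)

    @property
    def n_samples(self) -> int:
        return sum(self.samples_per_location[loc] for loc in self.locations)

    def population_stats(self, param: str) -> tuple[float, float]:
        """Deterministic cohort-level mean and sd of a parameter implied by
        the per-location mixture (weights = configured sample counts)."""
        w = np.array([self.samples_per_location[loc] for loc in self.locations], float)
        w /= w.sum()
        mu = np.array([self.morph_means[loc][param] for loc in self.locations])
        sd = self.morph_sds[param]
        mean = float(w @ mu)
        var = sd**2 + float(w @ (mu - mean) ** 2)
        return mean, float(np.sqrt(var))


# --------------------------------------------------------------------------
# ground-truth morphometry + Mankin
# --------------------------------------------------------------------------

def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    """Truncated normal by resampling (the truncation tails are far out for
    the default parameters, so this terminates almost immediately)."""
    if sd == 0:
        return np.full(size, mean, dtype=float)
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def draw_morphometry(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-sample ground-truth morphometry, donor ids and Mankin scores.

    Morphometric parameters are truncated-normal per location.  The Mankin
    score is linked to plate thickness: the probability of a score above 4
    is logistic in the *within-location* standardised Sb.Th, with slope
    ``mankin_link_strength`` and intercept solved so the expected high-score
    rate equals ``mankin_class2_rate``.  Conditioning within location keeps
    the link from aliasing the anatomical-location differences into the
    other parameters.
    """
    rows = []
    donor_cycle = np.arange(config.n_donors)
    for loc in config.locations:
        n = config.samples_per_location[loc]
        draws = {}
        for param in MORPH_PARAMS:
            lo, hi = MORPH_BOUNDS[param]
            draws[param] = _truncnorm(
                rng, config.morph_means[loc][param], config.morph_sds[param], lo, hi, n
            )
        donors = donor_cycle[np.arange(n) % config.n_donors]
        for i in range(n):
            rows.append(
                {
                    "location": loc,
                    "donor_id": f"D{donors[i]:02d}",
                    **{p: draws[p][i] for p in MORPH_PARAMS},
                }
            )
    truth = pd.DataFrame(rows)
    truth.insert(0, "sample_id", [f"S{i:03d}" for i in range(len(truth))])

    # within-location standardised Sb.Th drives the degeneration link
    z = np.empty(len(truth))
    for loc in config.locations:
        m = truth["location"] == loc
        sd = config.morph_sds["sb_th_mm"]
        if sd == 0:
            z[m.to_numpy()] = 0.0
        else:
            z[m.to_numpy()] = (truth.loc[m, "sb_th_mm"] - config.morph_means[loc]["sb_th_mm"]) / sd

    b = config.mankin_link_strength
    target = config.mankin_class2_rate

    def rate(a: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(a + b * z))))) - target

    a = optimize.brentq(rate, -30.0, 30.0)
    p_high = 1.0 / (1.0 + np.exp(-(a + b * z)))
    high = rng.random(len(truth)) < p_high
    # low scores 1-4 (normal / early), high scores 5-9 (mild to advanced)
    low_scores = rng.choice([1, 2, 3, 4], size=len(truth), p=[0.35, 0.30, 0.25, 0.10])
    high_scores = rng.choice([5, 6, 7, 8, 9], size=len(truth), p=[0.35, 0.25, 0.20, 0.12, 0.08])
    truth["mankin"] = np.where(high, high_scores, low_scores)
    return truth


def validate_ground_truth(truth: pd.DataFrame) -> None:
    """Invariant checks: one row per sample, Mankin in [1, 9], positive sizes."""
    required = {"sample_id", "location", "donor_id", "mankin", *MORPH_PARAMS}
    missing = required - set(truth.columns)
    if missing:
        raise ValueError(f"ground truth missing columns {sorted(missing)}")
    if truth["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in ground truth")
    if not truth["mankin"].between(1, 9).all():
        raise ValueError("Mankin scores must lie in [1, 9]")
    if (truth[["sb_th_mm", "tb_th_mm"]] <= 0).any().any():
        raise ValueError("thickness ground truth must be positive")
    if not truth["bvtv_fraction"].between(0, 1).all():
        raise ValueError("BV/TV ground truth must lie in [0, 1]")


# --------------------------------------------------------------------------
# spectra
# --------------------------------------------------------------------------

def _gaussian_band(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    """Gaussian absorption band, truncated to compact support at 5 sigma
    (tail < 4e-6 of peak) so band effects are strictly local in wavelength."""
    g = np.exp(-0.5 * ((wl - center) / width) ** 2)
    g[np.abs(wl - center) > 5.0 * width] = 0.0
    return g


def _noise_sd_profile(config: CohortConfig, wl: np.ndarray) -> np.ndarray:
    """Per-channel additive noise sd: each channel uses the sd of the nearest
    optical window (by centre), so out-of-window channels are covered too."""
    centers = {w.name: 0.5 * (w.lo_nm + w.hi_nm) for w in config.window_defs}
    names = list(centers)
    cvals = np.array([centers[n] for n in names])
    nearest = np.abs(wl[:, None] - cvals[None, :]).argmin(axis=1)
    sds = np.array([config.noise_sd_by_window[n] for n in names])
    return sds[nearest]


def synthesize_spectrum(
    truth_row: pd.Series,
    config: CohortConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One absorbance spectrum for a sample with known morphometry.

    Structure: smooth quadratic baseline + four OW1 bands whose amplitudes
    are linear in the standardised morphometric parameters + fixed-position
    distractor bands in OW2/OW3 with morphometry-independent amplitude
    jitter; then per-sample multiplicative scatter and additive noise.
    """
    wl = config.wavelength_grid
    u = (wl - wl[0]) / (wl[-1] - wl[0])
    spectrum = 0.55 + 0.25 * u + 0.18 * u**2

    for param in MORPH_PARAMS:
        mean, sd = config.population_stats(param)
        z = (float(truth_row[param]) - mean) / sd if sd > 0 else 0.0
        # band-amplitude jitter: compositional variation the morphometric
        # parameters do not explain; it bounds the attainable (population)
        # R^2 at coeff^2 / (coeff^2 + jitter^2) ~ 0.9 with the defaults
        amp = (
            OW1_BASE_AMPLITUDE
            + config.ow1_signal_coefficients[param] * z
            + rng.normal(0.0, config.ow1_amplitude_noise_sd)
        )
        spectrum = spectrum + amp * _gaussian_band(wl, OW1_BAND_CENTERS[param], OW1_BAND_WIDTH_NM)

    for center, width, base_amp in DISTRACTOR_BANDS:
        amp = base_amp + rng.normal(0.0, config.distractor_amplitude_sd)
        spectrum = spectrum + amp * _gaussian_band(wl, center, width)

    slope = rng.normal(0.0, config.scatter_slope_sd)
    offset = rng.normal(0.0, config.scatter_offset_sd)
    spectrum = (1.0 + slope) * spectrum + offset

    spectrum = spectrum + rng.normal(0.0, 1.0, wl.size) * _noise_sd_profile(config, wl)
    return spectrum


# --------------------------------------------------------------------------
# volumes
# --------------------------------------------------------------------------

def synthesize_volume(
    truth_row: pd.Series,
    voxel_um: float | None = None,
    rng: np.random.Generator | None = None,
    config: CohortConfig | None = None,
) -> BoneVolume:
    """Binary bone phantom: plate slab over a jittered rod lattice.

    Geometry (z down from the cartilage-facing surface):

    * a solid plate slab of thickness Sb.Th containing sparse spherical
      pores of two size classes (for exercising the pore rule);
    * a marrow gap of ~100 um separating plate from lattice, so the
      endocortical boundary is well defined in every column;
    * a three-axis rod lattice with strut radius Tb.Th / 2 and grid spacing
      chosen so the lattice-band occupancy matches BV/TV; the final radius
      is the exact occupancy quantile of the distance-to-axes field, which
      pins BV/TV while keeping strut thickness within ~10 % of Tb.Th.

    Ground-truth compartment labels (plate / trabecular) are attached, and
    the true boundary slice index is stored as attribute ``truth_boundary``.
    """
    cfg = config if config is not None else CohortConfig()
    if voxel_um is None:
        voxel_um = cfg.voxel_um
    if rng is None:
        rng = np.random.default_rng(0)
    vox_mm = voxel_um / 1000.0
    nz, ny, nx = (int(round(e / vox_mm)) for e in cfg.voi_mm)
    if min(nz, ny, nx) < 40:
        raise ValueError(
            f"voxel size {voxel_um} um gives VOI shape {(nz, ny, nx)}; "
            "need >= 40 voxels per axis"
        )

    sb_th = float(truth_row["sb_th_mm"])
    tb_th = float(truth_row["tb_th_mm"])
    bvtv_target = float(truth_row["bvtv_fraction"])

    plate_vox = int(round(sb_th / vox_mm))
    gap_vox = max(8, int(round(0.1 / vox_mm)))  # ~100 um marrow gap
    if plate_vox + gap_vox + 16 > nz:
        raise ValueError(
            f"plate thickness {sb_th} mm plus lattice does not fit a "
            f"{cfg.voi_mm[0]} mm deep volume"
        )

    vol = np.zeros((nz, ny, nx), dtype=bool)
    vol[:plate_vox] = True

    # sparse intracortical pores, two size classes, kept off the faces;
    # sizes are physical so pores never exceed the marrow-gap threshold,
    # and sub-voxel pores are simply unresolved at coarse voxel sizes
    if plate_vox >= 8:
        small_r = 0.015 / vox_mm   # 30 um diameter
        large_r = 0.030 / vox_mm   # 60 um diameter
        n_small, n_large = 6, 2
        zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx]
        for r, count in ((small_r, n_small), (large_r, n_large)):
            if r < 1.0:
                continue
            for _ in range(count):
                cz = rng.integers(int(r) + 1, max(int(r) + 2, plate_vox - int(r) - 1))
                cy = rng.integers(int(r) + 1, ny - int(r) - 1)
                cx = rng.integers(int(r) + 1, nx - int(r) - 1)
                pore = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
                vol[pore] = False

    # rod lattice in the trabecular band
    z0 = plate_vox + gap_vox
    band = np.s_[z0:nz]
    rod_r = max(1.0, tb_th / 2.0 / vox_mm)
    # per-family occupancy f with overlap correction: 1 - (1-f)^3 = BV/TV
    f = 1.0 - (1.0 - min(bvtv_target, 0.999)) ** (1.0 / 3.0)
    spacing = rod_r * np.sqrt(np.pi / max(f, 1e-4))
    spacing = max(spacing, 2.5 * rod_r)
    # every dimension must hold a few lattice cells or the occupancy
    # quantile would fatten the struts to reach the target fraction; cap
    # the spacing and thin the rod population instead
    cap = max(min(nz - z0, ny, nx) / 2.5, 2.5 * rod_r)
    keep_prob = 1.0
    if spacing > cap:
        keep_prob = (cap / spacing) ** 2
        spacing = cap
    dist = _rod_lattice_distance(nz - z0, ny, nx, spacing, rng, keep_prob)
    # exact-occupancy radius: the BV/TV quantile of the distance field
    r_star = float(np.quantile(dist, min(bvtv_target, 1.0)))
    lattice = dist <= r_star
    vol[band] = lattice

    labels = np.zeros_like(vol, dtype=np.uint8)
    labels[:plate_vox][vol[:plate_vox]] = 1
    labels[band][vol[band]] = 2
    out = BoneVolume(voxels=vol, voxel_um=voxel_um, labels=labels)
    out.truth_boundary = plate_vox
    return out


def _rod_lattice_distance(
    nz: int,
    ny: int,
    nx: int,
    spacing: float,
    rng: np.random.Generator,
    keep_prob: float = 1.0,
) -> np.ndarray:
    """Distance (voxels) to the nearest rod axis of a jittered three-axis
    rod lattice filling an (nz, ny, nx) band; ``keep_prob`` randomly thins
    the rod population (at least one rod per family survives)."""

    def axis_points(n1: int, n2: int) -> np.ndarray:
        g1 = np.arange(spacing / 2, n1, spacing)
        g2 = np.arange(spacing / 2, n2, spacing)
        pts = np.stack(np.meshgrid(g1, g2, indexing="ij"), axis=-1).reshape(-1, 2)
        pts += rng.uniform(-0.15 * spacing, 0.15 * spacing, pts.shape)
        if keep_prob < 1.0:
            keep = rng.random(len(pts)) < keep_prob
            if not keep.any():
                keep[rng.integers(len(pts))] = True
            pts = pts[keep]
        return pts

    def plane_distance(n1: int, n2: int) -> np.ndarray:
        pts = axis_points(n1, n2)
        ii, jj = np.mgrid[0:n1, 0:n2]
        grid = np.stack([ii.ravel(), jj.ravel()], axis=1).astype(float)
        d2 = ((grid[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2).min(axis=1)
        return np.sqrt(d2).reshape(n1, n2)

    d_z = plane_distance(ny, nx)[None, :, :]          # rods along z
    d_y = plane_distance(nz, nx)[:, None, :]          # rods along y
    d_x = plane_distance(nz, ny)[:, :, None]          # rods along x
    return np.minimum(np.minimum(
        np.broadcast_to(d_z, (nz, ny, nx)),
        np.broadcast_to(d_y, (nz, ny, nx))),
        np.broadcast_to(d_x, (nz, ny, nx)),
    )


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------

def generate_cohort(
    config: CohortConfig,
    out_dir=None,
    with_volumes: bool = True,
) -> tuple[SpectralDataset, list[BoneVolume] | None, pd.DataFrame]:
    """Compose the generators into a full cohort, deterministically.

    With ``out_dir`` set, writes ``spectra.csv``, ``metadata.csv``,
    ``truth.csv`` and (if generated) per-sample multi-page TIFF volumes with
    JSON sidecars.
    """
    rng = np.random.default_rng(config.seed)
    truth = draw_morphometry(config, rng)
    validate_ground_truth(truth)

    spectra = np.stack(
        [synthesize_spectrum(row, config, rng) for _, row in truth.iterrows()]
    )
    metadata = truth[["sample_id", "donor_id", "location", "mankin"]].set_index("sample_id")
    ds = SpectralDataset(
        wavelengths=config.wavelength_grid,
        absorbance=spectra,
        sample_ids=list(truth["sample_id"]),
        metadata=metadata,
    )

    volumes = None
    if with_volumes:
        volumes = [
            synthesize_volume(row, config.voxel_um, rng, config)
            for _, row in truth.iterrows()
        ]

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        try:
            ds.to_csv(out_dir / "spectra.csv")
            metadata.to_csv(out_dir / "metadata.csv")
            truth.to_csv(out_dir / "truth.csv", index=False, float_format="%.8f")
            if volumes is not None:
                vol_dir = out_dir / "volumes"
                vol_dir.mkdir(exist_ok=True)
                for sid, vol in zip(truth["sample_id"], volumes):
                    vol.to_tiff(vol_dir / f"{sid}.tiff")
        except OSError as exc:
            raise OSError(f"failed writing cohort to {out_dir}: {exc}") from exc

    return ds, volumes, truth
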