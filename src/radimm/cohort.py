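"""Seeded synthetic cohort: lesion MR phantoms plus immune frequencies.

The generator produces the statistical structure the downstream analysis
assumes, without any patient data:

* **Imaging** — per subject, a nested-ellipsoid lesion (necrosis ⊂ CET ⊂
  nCET ⊂ edema shells) inside an ellipsoidal intracranial mask, rendered
  into five MR contrasts with per-compartment mean intensities. Within the
  lesion, a subject-specific texture field is added: voxelwise Gaussian
  noise smoothed with a kernel whose width shrinks as the subject's latent
  ``texture_roughness`` (in [0, 1]) grows, so rough subjects have
  fine-grained, high-variance lesion texture and smooth subjects a blurred,
  low-variance one. Fractality and SD features respond monotonically to
  the latent.

* **Immune samples** — per subject and sampling site (necrosis / core /
  margin, each present with a site-specific probability), logit-normal
  leukocyte and myeloid frequencies around the configured medians, and the
  two macrophage subsets constructed as a total macrophage share ``t`` of
  myeloid times a BMDM-vs-MG split ``s``: BMDM = 100·t·s, MG = 100·t·(1−s).
  The gating bound BMDM+MG ≤ 100 holds by construction and the BMDM/MG
  ratio equals s/(1−s), exactly log-normal with median
  ``bmdm_median/mg_median``.

* **Coupling** — a Gaussian copula ties the *core*-site ratio to the
  texture latent: the normal score of the core log-ratio has correlation
  ``coupling_rho`` with the normal score of the roughness latent; the
  other sites stay uncoupled, so site specificity is a recoverable ground
  truth.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit
from scipy.stats import norm

from .constants import LABEL_CODES, SEQUENCES, SITES, TISSUES
from .imaging import ImageVolume, LabelMap, MRIStudy, save_study
from .immune import FREQ_COLUMNS, ImmunoSample, samples_to_frame


class ConfigurationError(ValueError):
    """Raised when a SyntheticConfig field violates its invariants."""


class EmptyDataError(ValueError):
    """Raised when a summary is requested over zero samples."""


@dataclass(frozen=True)
class SiteImmuneParams:
    """Per-site medians (percent) and logit/log-scale dispersions."""

    leukocytes_median: float
    myeloid_median: float
    bmdm_median: float
    mg_median: float
    sigma_leukocytes: float = 0.5
    sigma_myeloid: float = 0.4
    sigma_total: float = 0.3  # dispersion of the macrophage share of myeloid
    sigma_split: float = 0.6  # dispersion of logit(BMDM vs MG split) = log-ratio SD


# Site medians: leukocyte and myeloid medians follow the reported central
# (41.5%) vs marginal (29.2%) leukocyte infiltration and ~92-94% myeloid
# fractions; BMDM/MG medians encode the central-to-marginal gradient
# (BMDM-dominated core, MG-dominated margin) with ratio medians 2.5/2.0/0.8.
DEFAULT_SITE_PARAMS: dict[str, SiteImmuneParams] = {
    "necrosis": SiteImmuneParams(41.5, 94.3, 60.0, 24.0),
    "core": SiteImmuneParams(41.5, 92.3, 56.7, 28.3),
    "margin": SiteImmuneParams(29.2, 92.8, 37.8, 47.2),
}

# Specimen availability: 58/62 core, 37/62 necrosis, 31/62 margin.
DEFAULT_MISSING_SITE_PROB = {
    "necrosis": 1.0 - 37 / 62,
    "core": 1.0 - 58 / 62,
    "margin": 1.0 - 31 / 62,
}

# Mean intensity per (sequence, region) in arbitrary units, normal tissue = 1.
# Qualitative contrasts: dark necrosis on T1w, avid rim enhancement on GdT1w,
# bright fluid/edema on T2w/FLAIR, elevated diffusion in necrosis and edema.
DEFAULT_SEQUENCE_CONTRASTS: dict[str, dict[str, float]] = {
    "T1w": {"normal": 1.00, "necrosis": 0.45, "CET": 0.80, "nCET": 0.70, "edema": 0.60},
    "GdT1w": {"normal": 1.00, "necrosis": 0.50, "CET": 1.80, "nCET": 0.80, "edema": 0.70},
    "T2w": {"normal": 1.00, "necrosis": 1.80, "CET": 1.30, "nCET": 1.50, "edema": 1.60},
    "FLAIR": {"normal": 1.00, "necrosis": 0.90, "CET": 1.40, "nCET": 1.50, "edema": 1.80},
    "ADC": {"normal": 1.00, "necrosis": 1.90, "CET": 0.80, "nCET": 0.90, "edema": 1.40},
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic cohort. Seed fixes everything."""

    n_subjects: int = 62
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    roi_radii_mm: tuple[float, float, float, float] = (10.0, 20.0, 28.0, 40.0)
    icv_radius_mm: float = 66.0
    sequence_contrasts: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SEQUENCE_CONTRASTS.items()}
    )
    base_noise_sd: float = 0.02  # flat background noise, all tissue
    texture_noise_sd: float = 0.25  # white-noise SD before lesion smoothing
    smooth_sigma_range: tuple[float, float] = (0.5, 2.0)  # voxels; rough -> low
    radius_jitter_sd: float = 0.15  # log-scale common scale factor per subject
    shell_jitter_sd: float = 0.05  # per-shell multiplicative jitter
    site_immune_params: dict[str, SiteImmuneParams] = field(
        default_factory=lambda: dict(DEFAULT_SITE_PARAMS)
    )
    coupling_rho: float = -0.4
    missing_site_prob: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_SITE_PROB)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError(f"n_subjects must be >= 1, got {self.n_subjects}")
        radii = self.roi_radii_mm
        if len(radii) != 4 or any(b <= a for a, b in zip(radii, radii[1:])):
            raise ConfigurationError(f"roi_radii_mm must be 4 strictly increasing radii, got {radii}")
        if radii[-1] >= self.icv_radius_mm:
            raise ConfigurationError(
                f"outer lesion radius {radii[-1]} must lie inside icv_radius_mm={self.icv_radius_mm}"
            )
        if not -1.0 <= self.coupling_rho <= 1.0:
            raise ConfigurationError(f"coupling_rho must be in [-1, 1], got {self.coupling_rho}")
        for site in SITES:
            if site not in self.site_immune_params:
                raise ConfigurationError(f"site_immune_params missing site {site!r}")
            p = self.site_immune_params[site]
            for name in ("leukocytes_median", "myeloid_median", "bmdm_median", "mg_median"):
                v = getattr(p, name)
                if not 0.0 < v < 100.0:
                    raise ConfigurationError(f"site_immune_params[{site!r}].{name}={v} outside (0, 100)")
            if p.bmdm_median + p.mg_median >= 100.0:
                raise ConfigurationError(
                    f"site_immune_params[{site!r}]: bmdm_median + mg_median must be < 100"
                )
            prob = self.missing_site_prob.get(site)
            if prob is None or not 0.0 <= prob <= 1.0:
                raise ConfigurationError(f"missing_site_prob[{site!r}]={prob} outside [0, 1]")
        lo, hi = self.smooth_sigma_range
        if not 0 < lo < hi:
            raise ConfigurationError(f"smooth_sigma_range must be increasing positive, got {self.smooth_sigma_range}")

    @property
    def ratio_median(self) -> dict[str, float]:
        """Planted per-site BMDM/MG ratio medians (exact by construction)."""
        return {s: p.bmdm_median / p.mg_median for s, p in self.site_immune_params.items()}


@dataclass
class SyntheticCohort:
    """Generated studies, immune samples, and the latent ground truth.

    ``latent`` has one row per subject: texture_roughness and the true
    (noise-free score) core BMDM/MG ratio, kept for recovery tests.
    """

    config: SyntheticConfig
    studies: list[MRIStudy]
    immuno: list[ImmunoSample]
    latent: pd.DataFrame

    def checksum(self) -> str:
        """SHA-256 over a canonical serialization (determinism contract)."""
        h = hashlib.sha256()
        for study in self.studies:
            h.update(study.subject_id.encode())
            for seq in SEQUENCES:
                h.update(np.ascontiguousarray(study.volumes[seq].data).tobytes())
            h.update(np.ascontiguousarray(study.label_map.labels).tobytes())
            h.update(np.ascontiguousarray(study.icv_mask).tobytes())
        for frame in (samples_to_frame(self.immuno), self.latent):
            buf = io.StringIO()
            frame.to_csv(buf, index=False, float_format="%.12g")
            h.update(buf.getvalue().encode())
        return h.hexdigest()


_RADIUS_GRID_CACHE: dict[tuple, np.ndarray] = {}


def _radius_grid(shape: tuple[int, int, int], voxel: tuple[float, float, float]) -> np.ndarray:
    """Distance (mm) of each voxel center from the grid center, cached."""
    key = (tuple(shape), tuple(voxel))
    if key not in _RADIUS_GRID_CACHE:
        axes = [((np.arange(n) - (n - 1) / 2.0) * v) ** 2 for n, v in zip(shape, voxel)]
        d2 = axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :]
        _RADIUS_GRID_CACHE[key] = np.sqrt(d2)
    return _RADIUS_GRID_CACHE[key]


def _ellipsoid_mask(shape: tuple[int, int, int], voxel: tuple[float, float, float], radius_mm: float) -> np.ndarray:
    return _radius_grid(shape, voxel) <= radius_mm


def _subject_label_map(config: SyntheticConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Nested shells with per-subject radius jitter; returns (labels, icv)."""
    scale = float(np.exp(rng.normal(0.0, config.radius_jitter_sd)))
    radii = np.array(config.roi_radii_mm) * scale * (1.0 + rng.normal(0.0, config.shell_jitter_sd, size=4))
    radii = np.sort(np.abs(radii))
    # keep the lesion inside the ICV and the shells strictly nested
    radii = np.minimum(radii, config.icv_radius_mm * 0.95)
    for i in range(1, 4):
        radii[i] = max(radii[i], radii[i - 1] * 1.05 + 0.5)
    icv = _ellipsoid_mask(config.grid_shape, config.voxel_size_mm, config.icv_radius_mm)
    labels = np.zeros(config.grid_shape, dtype=np.int16)
    for tissue, r in zip(reversed(TISSUES), reversed(radii)):
        inside = _ellipsoid_mask(config.grid_shape, config.voxel_size_mm, float(r))
        labels[inside] = LABEL_CODES[tissue]
    labels[~icv] = 0
    return labels, icv


def _render_volumes(
    config: SyntheticConfig,
    labels: np.ndarray,
    icv: np.ndarray,
    roughness: float,
    rng: np.random.Generator,
) -> dict[str, ImageVolume]:
    lo, hi = config.smooth_sigma_range
    sigma = hi - roughness * (hi - lo)  # rough subject -> narrow kernel
    lesion = labels > 0
    volumes = {}
    for seq in SEQUENCES:
        means = config.sequence_contrasts[seq]
        vol = np.zeros(config.grid_shape, dtype=np.float64)
        vol[icv] = means["normal"]
        for tissue in TISSUES:
            vol[labels == LABEL_CODES[tissue]] = means[tissue]
        vol += rng.normal(0.0, config.base_noise_sd, size=config.grid_shape) * icv
        texture = gaussian_filter(rng.standard_normal(config.grid_shape), sigma=sigma)
        vol[lesion] += config.texture_noise_sd * texture[lesion]
        volumes[seq] = ImageVolume(data=vol, voxel_size_mm=config.voxel_size_mm, sequence=seq)
    return volumes


def _immune_sample(
    config: SyntheticConfig,
    subject_id: str,
    site: str,
    split_score: float,
    rng: np.random.Generator,
) -> ImmunoSample:
    p = config.site_immune_params[site]
    leuk = 100.0 * expit(logit(p.leukocytes_median / 100.0) + p.sigma_leukocytes * rng.standard_normal())
    myel = 100.0 * expit(logit(p.myeloid_median / 100.0) + p.sigma_myeloid * rng.standard_normal())
    t_med = (p.bmdm_median + p.mg_median) / 100.0
    s_med = p.bmdm_median / (p.bmdm_median + p.mg_median)
    t = expit(logit(t_med) + p.sigma_total * rng.standard_normal())
    s = expit(logit(s_med) + p.sigma_split * split_score)
    return ImmunoSample(
        subject_id=subject_id,
        site=site,
        pct_leukocytes=float(leuk),
        pct_myeloid=float(myel),
        pct_bmdm=float(100.0 * t * s),
        pct_mg=float(100.0 * t * (1.0 - s)),
    )


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate a full cohort from a single seed.

    Every source of randomness (geometry jitter, image noise, immune
    frequencies, missing specimens) descends from ``config.seed``; equal
    (seed, config) pairs produce bit-identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    studies: list[MRIStudy] = []
    immuno: list[ImmunoSample] = []
    latent_rows = []
    rho = config.coupling_rho
    core_params = config.site_immune_params["core"]
    s_med_core = core_params.bmdm_median / (core_params.bmdm_median + core_params.mg_median)
    for i in range(config.n_subjects):
        subject_id = f"sub-{i + 1:03d}"
        z1 = rng.standard_normal()  # roughness normal score
        z2 = rho * z1 + np.sqrt(1.0 - rho**2) * rng.standard_normal()  # core ratio score
        roughness = float(norm.cdf(z1))
        labels, icv = _subject_label_map(config, rng)
        volumes = _render_volumes(config, labels, icv, roughness, rng)
        studies.append(
            MRIStudy(
                subject_id=subject_id,
                volumes=volumes,
                label_map=LabelMap(labels=labels),
                icv_mask=icv,
                voxel_size_mm=config.voxel_size_mm,
            )
        )
        s_true = expit(logit(s_med_core) + core_params.sigma_split * z2)
        latent_rows.append(
            {
                "subject_id": subject_id,
                "texture_roughness": roughness,
                "true_core_ratio": float(s_true / (1.0 - s_true)),
            }
        )
        for site in SITES:
            present = rng.random() >= config.missing_site_prob[site]
            split_score = z2 if site == "core" else rng.standard_normal()
            if present:
                immuno.append(_immune_sample(config, subject_id, site, split_score, rng))
    return SyntheticCohort(
        config=config,
        studies=studies,
        immuno=immuno,
        latent=pd.DataFrame(latent_rows),
    )


def generate_immune_samples(config: SyntheticConfig) -> tuple[list[ImmunoSample], pd.DataFrame]:
    """Generate only the immune arm (same model as ``generate_cohort``).

    Useful for calibration studies of the frequency distributions where
    the imaging volumes are irrelevant. The latent frame carries the
    coupled core ratio scores exactly as in the full generator.
    """
    rng = np.random.default_rng(config.seed)
    rho = config.coupling_rho
    core_params = config.site_immune_params["core"]
    s_med_core = core_params.bmdm_median / (core_params.bmdm_median + core_params.mg_median)
    immuno: list[ImmunoSample] = []
    latent_rows = []
    for i in range(config.n_subjects):
        subject_id = f"sub-{i + 1:03d}"
        z1 = rng.standard_normal()
        z2 = rho * z1 + np.sqrt(1.0 - rho**2) * rng.standard_normal()
        s_true = expit(logit(s_med_core) + core_params.sigma_split * z2)
        latent_rows.append(
            {
                "subject_id": subject_id,
                "texture_roughness": float(norm.cdf(z1)),
                "true_core_ratio": float(s_true / (1.0 - s_true)),
            }
        )
        for site in SITES:
            present = rng.random() >= config.missing_site_prob[site]
            split_score = z2 if site == "core" else rng.standard_normal()
            if present:
                immuno.append(_immune_sample(config, subject_id, site, split_score, rng))
    return immuno, pd.DataFrame(latent_rows)


def site_frequency_summary(cohort: SyntheticCohort, population: str, site: str) -> float:
    """Median frequency of one gated population at one sampling site."""
    col = {
        "leukocytes": "pct_leukocytes",
        "myeloid": "pct_myeloid",
        "BMDM": "pct_bmdm",
        "MG": "pct_mg",
    }.get(population)
    if col is None:
        raise ValueError(f"unknown population {population!r}")
    if site not in SITES:
        raise ValueError(f"unknown site {site!r}")
    vals = [getattr(s, col) for s in cohort.immuno if s.site == site]
    if not vals:
        raise EmptyDataError(f"no samples at site {site!r}")
    return float(np.median(vals))


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Serialize a cohort: NIfTI volumes per subject, CSV tables, YAML config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for study in cohort.studies:
        save_study(study, out / study.subject_id)
    samples_to_frame(cohort.immuno).to_csv(out / "immune_samples.csv", index=False)
    cohort.latent.to_csv(out / "latent_truth.csv", index=False)
    cfg = cohort.config
    config_dict = {
        "n_subjects": cfg.n_subjects,
        "grid_shape": list(cfg.grid_shape),
        "voxel_size_mm": list(cfg.voxel_size_mm),
        "roi_radii_mm": list(cfg.roi_radii_mm),
        "icv_radius_mm": cfg.icv_radius_mm,
        "sequence_contrasts": cfg.sequence_contrasts,
        "base_noise_sd": cfg.base_noise_sd,
        "texture_noise_sd": cfg.texture_noise_sd,
        "smooth_sigma_range": list(cfg.smooth_sigma_range),
        "coupling_rho": cfg.coupling_rho,
        "missing_site_prob": cfg.missing_site_prob,
        "site_immune_params": {
            s: {
                "leukocytes_median": p.leukocytes_median,
                "myeloid_median": p.myeloid_median,
                "bmdm_median": p.bmdm_median,
                "mg_median": p.mg_median,
                "sigma_leukocytes": p.sigma_leukocytes,
                "sigma_myeloid": p.sigma_myeloid,
                "sigma_total": p.sigma_total,
                "sigma_split": p.sigma_split,
            }
            for s, p in cfg.site_immune_params.items()
        },
        "seed": cfg.seed,
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config_dict, fh, sort_keys=True)
    return out


def load_config_yaml(path: str | Path) -> SyntheticConfig:
    """Build a SyntheticConfig from a YAML file (missing keys use defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "site_immune_params" in raw:
        raw["site_immune_params"] = {
            s: SiteImmuneParams(**p) for s, p in raw["site_immune_params"].items()
        }
    for key in ("grid_shape", "voxel_size_mm", "roi_radii_mm", "smooth_sigma_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SyntheticConfig(**raw)
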