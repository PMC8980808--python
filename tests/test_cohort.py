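"""Synthetic cohort generator: determinism, geometry, calibration, coupling."""

import hashlib

import numpy as np
import pytest
from scipy.stats import pearsonr

from radimm.cohort import (
    ConfigurationError,
    EmptyDataError,
    SiteImmuneParams,
    SyntheticConfig,
    generate_cohort,
    generate_immune_samples,
    load_config_yaml,
    site_frequency_summary,
    write_cohort,
)
from radimm.constants import LABEL_CODES, SITES, TISSUES
from radimm.immune import aggregate_subject_site

from conftest import small_config


def test_counting_contract():
    cfg = small_config(
        n_subjects=10,
        seed=1,
        missing_site_prob={s: 0.0 for s in SITES},
    )
    cohort = generate_cohort(cfg)
    assert len(cohort.studies) == 10
    assert len(cohort.immuno) == 30
    assert len(cohort.latent) == 10
    ids = {s.subject_id for s in cohort.studies}
    assert {s.subject_id for s in cohort.immuno} <= ids
    assert set(cohort.latent["subject_id"]) == ids


def test_determinism_same_seed_bit_identical(tmp_path):
    cfg = small_config(n_subjects=3, seed=42)
    c1, c2 = generate_cohort(cfg), generate_cohort(cfg)
    assert c1.checksum() == c2.checksum()

    d1, d2 = tmp_path / "a", tmp_path / "b"
    write_cohort(c1, d1)
    write_cohort(c2, d2)
    for p1 in sorted(d1.rglob("*")):
        if p1.is_file():
            p2 = d2 / p1.relative_to(d1)
            h = lambda p: hashlib.sha256(p.read_bytes()).hexdigest()
            assert h(p1) == h(p2), p1.name


def test_different_seed_differs():
    cfg = small_config(n_subjects=2, seed=0)
    other = small_config(n_subjects=2, seed=1)
    assert generate_cohort(cfg).checksum() != generate_cohort(other).checksum()


def test_config_roundtrip_through_yaml(tmp_path):
    cfg = small_config(n_subjects=2, seed=9)
    cohort = generate_cohort(cfg)
    out = write_cohort(cohort, tmp_path / "c")
    loaded = load_config_yaml(out / "config.yaml")
    assert loaded == cfg


def test_shells_nested_disjoint_nonempty(small_cohort):
    for study in small_cohort.studies[:4]:
        labels = study.label_map.labels
        masks = {t: labels == LABEL_CODES[t] for t in TISSUES}
        for t in TISSUES:
            assert masks[t].any(), f"{t} empty"
        # voxel labels partition the lesion: one label per voxel by construction;
        # nesting: necrosis bbox inside CET-hull bbox inside ... inside edema hull
        hull = np.zeros_like(labels, dtype=bool)
        for t in reversed(TISSUES):  # edema outward -> necrosis inward
            hull = hull | masks[t]
        centers = {}
        for t in TISSUES:
            idx = np.argwhere(masks[t])
            centers[t] = idx.mean(axis=0)
        for a, b in zip(TISSUES, TISSUES[1:]):
            assert np.allclose(centers[a], centers[b], atol=3.0)


class TestConfigValidation:
    def test_non_nested_radii(self):
        with pytest.raises(ConfigurationError, match="roi_radii_mm"):
            small_config(roi_radii_mm=(20.0, 10.0, 28.0, 40.0))

    def test_frequency_out_of_range(self):
        params = dict(small_config().site_immune_params)
        params["core"] = SiteImmuneParams(150.0, 90.0, 50.0, 25.0)
        with pytest.raises(ConfigurationError, match="leukocytes_median"):
            small_config(site_immune_params=params)

    def test_coupling_rho_out_of_range(self):
        with pytest.raises(ConfigurationError, match="coupling_rho"):
            small_config(coupling_rho=-1.5)

    def test_missing_prob_out_of_range(self):
        with pytest.raises(ConfigurationError, match="missing_site_prob"):
            small_config(missing_site_prob={"necrosis": 0.5, "core": 1.2, "margin": 0.5})

    def test_gating_bound_on_medians(self):
        params = dict(small_config().site_immune_params)
        params["margin"] = SiteImmuneParams(30.0, 90.0, 60.0, 45.0)
        with pytest.raises(ConfigurationError, match="< 100"):
            small_config(site_immune_params=params)


def test_copula_coupling_recovered_at_n200():
    cfg = small_config(
        n_subjects=200,
        seed=77,
        coupling_rho=-0.4,
        missing_site_prob={s: 0.0 for s in SITES},
    )
    immuno, latent = generate_immune_samples(cfg)
    agg = aggregate_subject_site(immuno)
    core = agg[agg["site"] == "core"].set_index("subject_id")["ratio"]
    merged = latent.set_index("subject_id").join(core).dropna()
    r, _ = pearsonr(merged["texture_roughness"], merged["ratio"])
    assert -0.55 <= r <= -0.25
    # the latent frame also stores the noise-free planted ratio
    r_true, _ = pearsonr(merged["texture_roughness"], merged["true_core_ratio"])
    assert r_true < r + 0.1


def test_uncoupled_sites_stay_uncoupled():
    cfg = small_config(
        n_subjects=300,
        seed=78,
        coupling_rho=-0.5,
        missing_site_prob={s: 0.0 for s in SITES},
    )
    immuno, latent = generate_immune_samples(cfg)
    agg = aggregate_subject_site(immuno)
    for site in ("necrosis", "margin"):
        vals = agg[agg["site"] == site].set_index("subject_id")["ratio"]
        merged = latent.set_index("subject_id").join(vals).dropna()
        r, p = pearsonr(merged["texture_roughness"], merged["ratio"])
        assert abs(r) < 0.15


class TestSiteFrequencySummary:
    def test_degenerate_dispersion_returns_parameter(self):
        params = {
            site: SiteImmuneParams(40.0, 90.0, 50.0, 25.0, 0.0, 0.0, 0.0, 0.0)
            for site in SITES
        }
        cfg = small_config(
            n_subjects=5,
            seed=3,
            site_immune_params=params,
            missing_site_prob={s: 0.0 for s in SITES},
        )
        cohort = generate_cohort(cfg)
        assert site_frequency_summary(cohort, "leukocytes", "core") == pytest.approx(40.0)
        assert site_frequency_summary(cohort, "myeloid", "margin") == pytest.approx(90.0)

    def test_empty_site_is_error(self):
        cfg = small_config(
            n_subjects=3,
            seed=4,
            missing_site_prob={"necrosis": 0.0, "core": 0.0, "margin": 1.0},
        )
        cohort = generate_cohort(cfg)
        with pytest.raises(EmptyDataError, match="margin"):
            site_frequency_summary(cohort, "MG", "margin")

    def test_unknown_population_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="population"):
            site_frequency_summary(small_cohort, "neutrophils", "core")


def test_site_gradient_direction_matches_parameters():
    cfg = small_config(n_subjects=200, seed=5, missing_site_prob={s: 0.0 for s in SITES})
    immuno, _ = generate_immune_samples(cfg)

    class _C:  # site_frequency_summary only needs .immuno
        pass

    c = _C()
    c.immuno = immuno
    bmdm = [site_frequency_summary(c, "BMDM", s) for s in ("necrosis", "core", "margin")]
    mg = [site_frequency_summary(c, "MG", s) for s in ("necrosis", "core", "margin")]
    assert bmdm[0] > bmdm[1] > bmdm[2]
    assert mg[0] < mg[1] < mg[2]
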