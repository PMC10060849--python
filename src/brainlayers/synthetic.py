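"""Synthetic multi-site cohorts of ROI time series.

Real resting-state MDD cohorts (e.g. the multi-site consortium data this
pipeline targets) are access-restricted, so every downstream stage is
exercised on simulated cohorts with a known ground truth:

* a sparse latent correlation matrix shared by controls, projected to the
  nearest symmetric positive-definite (SPD) correlation matrix;
* a patient matrix obtained by shifting the latent correlation by +δ on a
  chosen set of effect edges, then re-projecting to SPD — so the *realized*
  group difference (post-projection) is what tests compare against;
* per-site acquisition effects: a per-ROI multiplicative gain and additive
  offset (scanner gain/baseline), a site-specific sensor-noise level and a
  site-specific global-signal amplitude.  Gain and offset alone leave
  Pearson correlations untouched; the site-varying noise floor *attenuates*
  observed correlations while the shared global signal *inflates* them, so
  every site leaves its own fingerprint on the connectivity features — the
  nuisance structure domain-adversarial training is meant to fight.

Subject time series are i.i.d. multivariate-normal draws from the group's
correlation matrix — no hemodynamics, temporal autocorrelation or motion
artifacts are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import RoiTimeSeries, pair_to_edge

__all__ = [
    "SiteSpec",
    "CohortConfig",
    "generate_cohort",
    "ground_truth_edges",
    "realized_effects",
    "group_correlations",
]

#: eigenvalue floor used when projecting to the nearest SPD correlation matrix
_EIG_FLOOR = 1e-4


@dataclass(frozen=True)
class SiteSpec:
    site_id: str
    n_patients: int
    n_controls: int


def _default_sites() -> list[SiteSpec]:
    # ten sites, 597 patients / 563 controls in total
    pats = [60] * 7 + [59] * 3
    ctrs = [56] * 7 + [57] * 3
    return [SiteSpec(f"site{k + 1:02d}", p, c) for k, (p, c) in enumerate(zip(pats, ctrs))]


@dataclass
class CohortConfig:
    """Parameters of a simulated multi-site case/control cohort.

    ``effect_size`` is the shift δ added to the latent correlation on each
    effect edge for patients (before SPD projection), ``site_shift_sd`` the
    log-scale spread of the per-site gain/noise perturbations, and
    ``base_density`` the fraction of nonzero off-diagonal latent correlations.
    """

    n_rois: int = 116
    n_timepoints: int = 230
    sites: list[SiteSpec] = field(default_factory=_default_sites)
    effect_edges: frozenset[tuple[int, int]] = frozenset()
    effect_size: float = 0.0
    site_shift_sd: float = 0.0
    base_density: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.sites = [SiteSpec(*s) if not isinstance(s, SiteSpec) else s for s in self.sites]
        self.effect_edges = frozenset(tuple(e) for e in self.effect_edges)
        if self.n_rois < 3:
            raise ValueError("n_rois must be >= 3")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        if not self.sites:
            raise ValueError("at least one site is required")
        for s in self.sites:
            if s.n_patients < 0 or s.n_controls < 0 or s.n_patients + s.n_controls == 0:
                raise ValueError(f"site {s.site_id}: invalid group sizes")
        for i, j in self.effect_edges:
            if not (0 <= i < j < self.n_rois):
                raise ValueError(
                    f"effect edge ({i}, {j}) is not a strict upper-triangle pair "
                    f"within n_rois={self.n_rois}"
                )
        if not 0.0 <= self.effect_size < 1.0:
            raise ValueError("effect_size must lie in [0, 1)")
        if self.site_shift_sd < 0.0:
            raise ValueError("site_shift_sd must be nonnegative")
        if not 0.0 <= self.base_density <= 1.0:
            raise ValueError("base_density must lie in [0, 1]")


def _project_to_correlation(m: np.ndarray, floor: float = _EIG_FLOOR) -> np.ndarray:
    """Nearest-ish SPD correlation matrix: eigenvalue clipping + renormalization."""
    sym = (m + m.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    spd = (vecs * np.clip(vals, floor, None)) @ vecs.T
    d = np.sqrt(np.diag(spd))
    corr = spd / np.outer(d, d)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    if np.linalg.eigvalsh(corr).min() <= 0.0:
        raise RuntimeError("SPD projection failed to produce a positive-definite matrix")
    return corr


def _group_correlations(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n = config.n_rois
    latent = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.size) < config.base_density
    vals = rng.uniform(-0.6, 0.8, size=iu.size) * mask
    latent[iu, ju] = vals
    latent[ju, iu] = vals
    np.fill_diagonal(latent, 1.0)
    control = _project_to_correlation(latent)

    shifted = control.copy()
    for i, j in sorted(config.effect_edges):
        shifted[i, j] = shifted[j, i] = np.clip(
            shifted[i, j] + config.effect_size, -0.99, 0.99
        )
    patient = _project_to_correlation(shifted) if config.effect_edges else control
    return control, patient


def group_correlations(config: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """(control, patient) latent correlation matrices implied by the config.

    Both are valid SPD correlation matrices; the patient matrix carries the
    +δ shift on the effect edges, re-projected to SPD.  Deterministic given
    ``config.seed`` and independent of the site structure.
    """
    return _group_correlations(config, np.random.default_rng(config.seed))


def realized_effects(config: CohortConfig) -> dict[tuple[int, int], float]:
    """Post-projection correlation difference (patient − control) per effect edge.

    The SPD projection can shrink the nominal +δ shift, so recovery tests
    compare against these realized differences, not the nominal effect size.
    """
    control, patient = group_correlations(config)
    return {
        (i, j): float(patient[i, j] - control[i, j])
        for (i, j) in sorted(config.effect_edges)
    }


def ground_truth_edges(config: CohortConfig) -> set[int]:
    """Effect edges mapped into vectorized (row-major upper-triangle) coordinates."""
    return {pair_to_edge(i, j, config.n_rois) for (i, j) in config.effect_edges}


def generate_cohort(config: CohortConfig) -> list[RoiTimeSeries]:
    """Draw the full multi-site cohort described by ``config``.

    Returns Σ(n_patients + n_controls) subjects in site order, patients before
    controls within a site.  Bit-identical for identical configs (one seeded
    generator stream drives latent structure, site parameters and subject
    noise in a fixed order).
    """
    rng = np.random.default_rng(config.seed)
    control_corr, patient_corr = _group_correlations(config, rng)
    n = config.n_rois
    chol = {
        "control": np.linalg.cholesky(control_corr),
        "patient": np.linalg.cholesky(patient_corr),
    }
    t = config.n_timepoints
    cohort: list[RoiTimeSeries] = []
    for site in config.sites:
        gain = np.exp(rng.normal(0.0, config.site_shift_sd, size=n))
        offset = rng.normal(0.0, config.site_shift_sd, size=n)
        if config.site_shift_sd > 0.0:
            noise_scale = float(np.exp(rng.normal(np.log(config.site_shift_sd), 0.5)))
            common_amp = float(np.exp(rng.normal(np.log(config.site_shift_sd), 0.5)))
        else:
            noise_scale = common_amp = 0.0
        members = [("patient", k) for k in range(site.n_patients)] + [
            ("control", k) for k in range(site.n_controls)
        ]
        for label, k in members:
            latent = rng.standard_normal((t, n)) @ chol[label].T
            noise = noise_scale * rng.standard_normal((t, n)) if noise_scale else 0.0
            shared = (
                common_amp * rng.standard_normal((t, 1)) if common_amp else 0.0
            )
            data = latent * gain + offset + noise + shared
            cohort.append(
                RoiTimeSeries(
                    subject_id=f"{site.site_id}-{'p' if label == 'patient' else 'c'}{k:03d}",
                    site_id=site.site_id,
                    label=label,  # type: ignore[arg-type]
                    data=data,
                )
            )
    return cohort
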