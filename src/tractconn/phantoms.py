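"""Synthetic inputs: tensor phantoms and matrix-level simulated cohorts.

Two stand-ins for the clinical MRI data the pipeline was designed for:

* **Tensor phantoms** — small NIfTI-sized tensor volumes whose
  white-matter voxels carry an axially symmetric tensor (eigenvalues
  (λ1, λ2, λ2)) oriented along a known geometry (straight slab, quarter
  arc, or a 90° crossing interface), with grey-matter caps at the
  bundle endpoints.  λ2 is solved in closed form from the requested FA,
  so the phantom's FA is exact and the tractography oracle (the
  geometry) is analytic.

* **Simulated cohorts** — per-subject 70x70 connection matrices for a
  patient and a control group.  Per-edge fiber counts are negative
  binomial around edge-specific rates, scaled by a lognormal
  subject-level factor (inter-subject total-count variability), with a
  global patient/control multiplier (default 0.90, the study-scale 10%
  reduction) and optional lobe-pair-specific multipliers on top.
  Per-edge FA is bimodal: near-diagonal (short-range) edges draw from a
  low-FA mode, the rest from a high-FA mode.  Age and sex covariates
  are drawn to match the study cohort's structure (ages ~7-25, roughly
  balanced sex), independent of group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .atlas import LOBES, Parcellation, connectome_atlas
from .connectome import ConnectionMatrix
from .tracking import TensorVolume

__all__ = [
    "PhantomSpec",
    "CohortConfig",
    "make_tensor_phantom",
    "simulate_cohort",
    "axially_symmetric_eigenvalues",
    "study_cohort_config",
]

GEOMETRIES = ("straight_slab", "quarter_arc", "crossing_interface")


@dataclass
class PhantomSpec:
    """Specification of a tensor phantom.

    geometry_params by geometry:
      straight_slab: thickness (mm, along x), half_width (mm, y/z extent)
      quarter_arc: radius (mm), tube_radius (mm); arc in the x-y plane
        centred on the grid centre, from angle 0 to 90 degrees
      crossing_interface: thickness (mm); x-oriented fibers meet a
        y-oriented field at the mid-plane
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    geometry: str = "straight_slab"
    geometry_params: dict = dc_field(default_factory=dict)
    fa_target: float = 0.7
    lambda1: float = 1.0  # largest eigenvalue (arbitrary diffusivity units)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape):
            raise ValueError("shape must be positive")
        if not (0.0 <= self.fa_target < 1.0):
            raise ValueError("fa_target must lie in [0, 1)")
        if self.geometry not in GEOMETRIES:
            raise ValueError(
                f"unknown geometry {self.geometry!r}; expected one of {GEOMETRIES}"
            )


def axially_symmetric_eigenvalues(fa: float, lambda1: float = 1.0) -> tuple[float, float, float]:
    """Eigenvalues (λ1, λ2, λ2) with exactly the requested FA.

    For the axially symmetric tensor FA = (λ1-λ2)/sqrt(λ1²+2λ2²)
    (λ1 ≥ λ2 ≥ 0), which gives the quadratic
    (1-2FA²)λ2² - 2λ1 λ2 + (1-FA²)λ1² = 0; the root in (0, λ1] is the
    physically meaningful one.  FA=0 returns the isotropic tensor.
    """
    if not (0.0 <= fa < 1.0):
        raise ValueError("fa must lie in [0, 1)")
    if fa == 0.0:
        return (lambda1, lambda1, lambda1)
    f2 = fa * fa
    a = 1.0 - 2.0 * f2
    if abs(a) < 1e-12:  # FA = 1/sqrt(2): the quadratic degenerates to linear
        lam2 = lambda1 * (1.0 - f2) / 2.0
    else:
        disc = 1.0 - a * (1.0 - f2)
        lam2 = lambda1 * (1.0 - math.sqrt(disc)) / a
    return (lambda1, lam2 * 1.0, lam2 * 1.0)


def _tensor_from_direction(direction: np.ndarray, lam1: float, lam2: float) -> np.ndarray:
    d = direction / np.linalg.norm(direction)
    return lam2 * np.eye(3) + (lam1 - lam2) * np.outer(d, d)


def make_tensor_phantom(spec: PhantomSpec, seed: int = 0) -> TensorVolume:
    """Build a tensor phantom volume from a geometry specification.

    White voxels carry a tensor whose principal eigenvector is the
    geometry's local tangent and whose FA equals ``spec.fa_target``
    exactly; grey caps sit at the bundle endpoints; everything else is
    isotropic background (FA 0) outside both masks.  ``seed`` is
    accepted for interface uniformity; the construction is
    deterministic.
    """
    del seed  # construction is fully deterministic
    nx, ny, nz = spec.shape
    vs = np.asarray(spec.voxel_size, dtype=float)
    lam1, lam2, _ = axially_symmetric_eigenvalues(spec.fa_target, spec.lambda1)
    iso = spec.lambda1 * np.eye(3) * 0.5

    tensors = np.tile(iso, (nx, ny, nz, 1, 1))
    white = np.zeros(spec.shape, dtype=bool)
    grey = np.zeros(spec.shape, dtype=bool)

    centers = (
        np.moveaxis(np.indices(spec.shape), 0, -1).astype(float) + 0.5
    ) * vs  # (nx,ny,nz,3) voxel centres in mm
    extent = np.asarray(spec.shape) * vs
    p = spec.geometry_params

    if spec.geometry == "straight_slab":
        thickness = float(p.get("thickness", extent[0] / 2))
        half_width = float(p.get("half_width", min(extent[1], extent[2]) / 4))
        cap = float(p.get("cap_thickness", 2.0 * vs[0]))
        x0 = (extent[0] - thickness) / 2.0
        mid = extent[1:] / 2.0
        lateral = (np.abs(centers[..., 1] - mid[0]) <= half_width) & (
            np.abs(centers[..., 2] - mid[1]) <= half_width
        )
        x = centers[..., 0]
        white = lateral & (x >= x0) & (x < x0 + thickness)
        grey = lateral & (
            ((x >= x0 - cap) & (x < x0)) | ((x >= x0 + thickness) & (x < x0 + thickness + cap))
        )
        tensors[white] = _tensor_from_direction(np.array([1.0, 0.0, 0.0]), lam1, lam2)

    elif spec.geometry == "quarter_arc":
        radius = float(p.get("radius", extent[0] / 2 - 2 * vs[0]))
        tube = float(p.get("tube_radius", 3.0 * float(vs.min())))
        cap_deg = float(p.get("cap_degrees", 6.0))
        origin = np.array([extent[0] / 2 - radius / 2, extent[1] / 2 - radius / 2, extent[2] / 2])
        rel = centers - origin
        r_xy = np.hypot(rel[..., 0], rel[..., 1])
        dist = np.sqrt((r_xy - radius) ** 2 + rel[..., 2] ** 2)  # distance to arc circle
        theta = np.degrees(np.arctan2(rel[..., 1], rel[..., 0]))
        in_tube = dist <= tube
        white = in_tube & (theta >= 0.0) & (theta <= 90.0)
        grey = in_tube & (
            ((theta < 0.0) & (theta >= -cap_deg)) | ((theta > 90.0) & (theta <= 90.0 + cap_deg))
        )
        wi = np.argwhere(white)
        for i, j, k in wi:
            t = math.atan2(rel[i, j, k, 1], rel[i, j, k, 0])
            tangent = np.array([-math.sin(t), math.cos(t), 0.0])
            tensors[i, j, k] = _tensor_from_direction(tangent, lam1, lam2)

    elif spec.geometry == "crossing_interface":
        thickness = float(p.get("thickness", extent[0] / 2))
        half_width = float(p.get("half_width", min(extent[1], extent[2]) / 4))
        x0 = (extent[0] - thickness) / 2.0
        mid = extent[1:] / 2.0
        lateral = (np.abs(centers[..., 1] - mid[0]) <= half_width) & (
            np.abs(centers[..., 2] - mid[1]) <= half_width
        )
        x = centers[..., 0]
        white = lateral & (x >= x0) & (x < x0 + thickness)
        left = white & (x < x0 + thickness / 2.0)
        right = white & ~left
        tensors[left] = _tensor_from_direction(np.array([1.0, 0.0, 0.0]), lam1, lam2)
        tensors[right] = _tensor_from_direction(np.array([0.0, 1.0, 0.0]), lam1, lam2)

    return TensorVolume(
        tensors=tensors, white_mask=white, grey_mask=grey, voxel_size=tuple(vs)
    )


# ----------------------------------------------------------------------
# matrix-level cohort simulation


@dataclass
class CohortConfig:
    """Generative settings for a two-group connectome cohort.

    ``global_ratio`` multiplies every patient edge rate (0.90 = the 10%
    global fiber reduction); ``edge_effects`` maps lobe-pair keys such
    as ``("frontal-L", "temporal-L")`` to extra patient multipliers.
    ``count_model`` is ``poisson`` or ``negative_binomial`` (dispersion
    ``nb_theta``); ``subject_scale_sd`` is the sd of the lognormal
    subject-level scale factor.  FA modes: near-diagonal edges
    (|i-j| <= ``low_fa_band``) draw from the low mode, others from the
    high mode.
    """

    n_per_group: int = 30
    n_regions: int = 70
    global_ratio: float = 0.90
    edge_effects: Mapping[tuple[str, str], float] = dc_field(default_factory=dict)
    total_fibers_mean: float = 47423.0
    count_model: str = "negative_binomial"
    nb_theta: float = 50.0
    subject_scale_sd: float = 0.115
    edge_noise_sd: float = 0.25
    edge_rate_sigma: float = 1.0
    low_fa_band: int = 1
    preserve_global: bool = True
    fa_low_mean: float = 0.22
    fa_low_sd: float = 0.05
    fa_high_mean: float = 0.60
    fa_high_sd: float = 0.10
    age_range: tuple[float, float] = (7.0, 25.0)
    age_mean: float = 14.85
    age_sd: float = 3.85
    female_fraction: float = 0.45
    wm_volume_age_r: float = 0.42
    fa_age_r_control: float = 0.32
    fa_age_r_patient: float = 0.22
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2 (covaried models unfittable)")
        if self.global_ratio <= 0:
            raise ValueError("global_ratio must be positive")
        if self.count_model not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown count_model {self.count_model!r}")
        for v in (self.nb_theta, self.fa_low_sd, self.fa_high_sd):
            if v <= 0:
                raise ValueError("dispersions and sds must be positive")


def study_cohort_config(seed: int = 0, n_per_group: int = 30) -> CohortConfig:
    """The demo cohort: study-scale conditions with the reported lobar effects.

    Patient multipliers per lobe pair are the reported absolute
    percentages divided by the 90% global ratio, so the planted absolute
    ratios reproduce the study-scale effect structure.
    """
    from .reference import GLOBAL_PCT, LOBAR_ABSOLUTE_PCT

    effects = {k: v / GLOBAL_PCT for k, v in LOBAR_ABSOLUTE_PCT.items()}
    return CohortConfig(
        n_per_group=n_per_group, edge_effects=effects, seed=seed
    )


def _unit_key(lobe: str, hemi: str) -> str:
    return f"{lobe}-{hemi}"


def _edge_multiplier_matrix(
    config: CohortConfig, parcellation: Parcellation
) -> np.ndarray:
    """Per-edge patient multiplier = global_ratio x lobe-pair effect."""
    n = parcellation.n_nodes
    mult = np.full((n, n), config.global_ratio)
    if not config.edge_effects:
        return mult
    units = [
        _unit_key(lobe, hemi)
        for lobe, hemi in zip(
            parcellation.roi_table["lobe"], parcellation.roi_table["hemisphere"]
        )
    ]
    effects = {frozenset(k): float(v) for k, v in config.edge_effects.items()}
    for i in range(n):
        for j in range(n):
            key = frozenset((units[i], units[j]))
            if key in effects:
                mult[i, j] *= effects[key]
    return mult


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, config: CohortConfig) -> np.ndarray:
    mean = np.clip(mean, 1e-12, None)
    if config.count_model == "poisson":
        return rng.poisson(mean)
    shape = config.nb_theta
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def simulate_cohort(
    config: CohortConfig, parcellation: Optional[Parcellation] = None
) -> tuple[pd.DataFrame, dict[str, ConnectionMatrix]]:
    """Simulate a two-group cohort of symmetric connection matrices.

    Returns ``(subjects, matrices)``: a subject table (id, group, age,
    sex, white_matter_volume, mean_fa, total_fibers) and a mapping from
    subject id to its :class:`ConnectionMatrix`.  Fully reproducible
    from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    if parcellation is None:
        parc = connectome_atlas()
        if parc.n_nodes != config.n_regions:
            parc = _generic_parcellation(config.n_regions)
    else:
        parc = parcellation
    n = parc.n_nodes

    # symmetric baseline edge rates, scaled to the control total mean
    iu = np.triu_indices(n)
    base = rng.lognormal(mean=0.0, sigma=config.edge_rate_sigma, size=len(iu[0]))
    base *= config.total_fibers_mean / base.sum()
    rate = np.zeros((n, n))
    rate[iu] = base
    rate = rate + np.triu(rate, 1).T

    mult = _edge_multiplier_matrix(config, parc)
    if config.preserve_global and config.edge_effects:
        # rescale non-planted edges so the expected patient/control total
        # stays at global_ratio: lobar deviations net out against the rest,
        # as they must when the global ratio already includes them
        planted = ~np.isclose(mult, config.global_ratio)
        w_all = rate[iu].sum()
        w_planted = (rate * mult / config.global_ratio)[iu][planted[iu]].sum()
        w_rest = rate[iu][~planted[iu]].sum()
        if w_rest > 0:
            c = (w_all - w_planted) / w_rest
            mult = np.where(planted, mult, mult * c)

    # FA mode assignment: near-diagonal edges are the short-fiber low mode
    ij = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    low_mode = ij <= config.low_fa_band

    ids, groups = [], []
    for g, gname in enumerate(("control", "patient")):
        for k in range(config.n_per_group):
            ids.append(f"{'hc' if g == 0 else 'pt'}{k + 1:03d}")
            groups.append(gname)
    n_sub = len(ids)
    ages = np.clip(
        rng.normal(config.age_mean, config.age_sd, size=n_sub),
        config.age_range[0],
        config.age_range[1],
    )
    sex = (rng.random(n_sub) >= config.female_fraction).astype(int)  # 0=F, 1=M

    matrices: dict[str, ConnectionMatrix] = {}
    totals = np.zeros(n_sub)
    for s, sid in enumerate(ids):
        # unit-mean lognormal subject scale and per-edge biological noise
        scale = rng.lognormal(
            mean=-0.5 * config.subject_scale_sd**2, sigma=config.subject_scale_sd
        )
        lam = rate * scale
        if config.edge_noise_sd > 0:
            noise = np.zeros((n, n))
            noise[iu] = rng.lognormal(
                mean=-0.5 * config.edge_noise_sd**2,
                sigma=config.edge_noise_sd,
                size=len(iu[0]),
            )
            lam = lam * (noise + np.triu(noise, 1).T)
        if groups[s] == "patient":
            lam = lam * mult
        draw = np.zeros((n, n), dtype=np.int64)
        draw[iu] = _draw_counts(rng, lam[iu], config)
        counts = draw + np.triu(draw, 1).T

        fa = np.zeros((n, n))
        fa_draw = np.where(
            low_mode[iu],
            rng.normal(config.fa_low_mean, config.fa_low_sd, size=len(iu[0])),
            rng.normal(config.fa_high_mean, config.fa_high_sd, size=len(iu[0])),
        )
        fa_vals = np.clip(fa_draw, 0.01, 0.99)
        fa[iu] = np.where(draw[iu] > 0, fa_vals, 0.0)
        fa = fa + np.triu(fa, 1).T

        # mean fiber length per edge ~ inter-regional distance proxy; density = count/len
        mean_len = 10.0 + 2.0 * ij
        with np.errstate(divide="ignore", invalid="ignore"):
            density = np.where(counts > 0, counts / mean_len, 0.0)

        matrices[sid] = ConnectionMatrix(
            subject_id=sid, count=counts, density=density, fa_mean=fa
        )
        totals[s] = matrices[sid].total_fibers()

    # age-linked nuisance measures for the age-regression analyses
    z_age = (ages - ages.mean()) / ages.std()
    noise = rng.normal(size=n_sub)
    r_wm = config.wm_volume_age_r
    wm = 4.0e5 * (1.0 + 0.08 * (r_wm * z_age + math.sqrt(1 - r_wm**2) * noise))
    mean_fa = np.empty(n_sub)
    for gname, r in (
        ("control", config.fa_age_r_control),
        ("patient", config.fa_age_r_patient),
    ):
        m = np.array(groups) == gname
        eps = rng.normal(size=m.sum())
        mean_fa[m] = 0.45 + 0.02 * (r * z_age[m] + math.sqrt(1 - r**2) * eps)

    subjects = pd.DataFrame(
        dict(
            id=ids,
            group=groups,
            age=np.round(ages, 2),
            sex=sex,
            white_matter_volume=np.round(wm, 1),
            mean_fa=np.round(mean_fa, 4),
            total_fibers=totals.astype(int),
        )
    )
    return subjects, matrices


def _generic_parcellation(n_regions: int) -> Parcellation:
    """Evenly split n_regions over the 10 lobe-hemisphere units."""
    rows = []
    units = [(lobe, hemi) for hemi in ("L", "R") for lobe in LOBES]
    per = max(1, n_regions // len(units))
    for i in range(n_regions):
        lobe, hemi = units[min(i // per, len(units) - 1)]
        rows.append(
            dict(
                id=i + 1,
                name=f"r{i + 1}",
                hemisphere=hemi,
                lobe=lobe,
                cls="cortical",
                excluded=False,
            )
        )
    return Parcellation(roi_table=pd.DataFrame(rows), name=f"generic{n_regions}")
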