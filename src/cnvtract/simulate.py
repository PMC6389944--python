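"""Synthetic cohort generator emulating the CNV-carrier study design.

Generates, from one master seed: (i) a 36-subject cohort (21 carriers
across the twelve study CNV classes with their real per-CNV counts, 15
controls) with age / gender / total-brain-volume / head-motion nuisance
covariates and penetrance scores; (ii) parametric 3-D streamline bundles
— a cingulum-like sagittal arc whose anterior–posterior curvature
amplitude increases with penetrance, plus corpus-callosum
splenium / body / genu arches and an uncinate-like hook; and (iii)
scalar microstructure maps whose bundle-interior values shift linearly
with penetrance (default: ICVF decreases). The outputs use the same
containers and file formats the real pipeline reads, so the simulator is
a drop-in data source for every downstream stage.

The generator produces the *statistical structure* the analysis assumes
(dose–response effects, nuisance structure, measurement noise); it makes
no attempt at MRI physics, realistic anatomy beyond bundle topology, or
scanner artefacts.

Seeding: one master seed; per-subject, per-stage streams are derived by
hashing ``(seed, subject id, stage, template)`` into a
``numpy.random.SeedSequence``, so any part of a cohort can be
regenerated independently and bit-exactly.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation

from cnvtract.penetrance import (CONTROL_LABEL, PenetranceTable, assign_scores,
                                 load_penetrance_table)
from cnvtract.streamlines import Streamline
from cnvtract.tractometry import METRIC_RANGES, ScalarVolume, traversed_voxels

__all__ = [
    "SimulationDesign",
    "BUNDLE_TEMPLATES",
    "build_cohort",
    "simulate_bundle",
    "simulate_scalar_map",
    "simulate_subject_maps",
    "simulate_cohort_dataset",
    "simulate_feature_table",
    "SimulatedCohort",
    "bundle_mask",
    "make_grid",
]

_STAGE = {"cohort": 0, "bundle": 1, "map": 2, "features": 3}


def _rng_for(seed: int, subject_id: str = "", stage: str = "cohort",
             extra: int = 0) -> np.random.Generator:
    """Deterministic per-(seed, subject, stage) random stream."""
    key = [int(seed), _STAGE[stage], zlib.crc32(subject_id.encode()), int(extra)]
    return np.random.default_rng(np.random.SeedSequence(key))


# ---------------------------------------------------------------------------
# Parametric bundle templates (mm, MNI-like axes: x right, y anterior,
# z superior). Each maps (t in [0,1], amplitude) -> (n, 3) points; the
# amplitude parameter controls the template's characteristic deflection.

def _cingulum(side: float) -> Callable[[np.ndarray, float], np.ndarray]:
    def f(t: np.ndarray, amplitude: float) -> np.ndarray:
        # sagittal arc wrapping dorsally: long A-P extent, superior
        # deflection = amplitude
        return np.column_stack([
            np.full_like(t, 12.0 * side),
            -40.0 + 80.0 * t,
            25.0 + amplitude * np.sin(np.pi * t)])
    return f


def _cc_arch(y_centre: float, y_sign: float, z_level: float,
             ) -> Callable[[np.ndarray, float], np.ndarray]:
    def f(t: np.ndarray, amplitude: float) -> np.ndarray:
        th = np.pi * t
        return np.column_stack([
            -25.0 * np.cos(th),
            y_centre + y_sign * amplitude * np.sin(th),
            np.full_like(t, z_level) + (amplitude * np.sin(th)
                                        if y_sign == 0.0 else 0.0)])
    return f


def _uncinate(side: float) -> Callable[[np.ndarray, float], np.ndarray]:
    def f(t: np.ndarray, amplitude: float) -> np.ndarray:
        th = np.pi * (t - 0.5)
        return np.column_stack([
            np.full_like(t, 32.0 * side),
            10.0 + 1.7 * amplitude * np.sin(th),
            -5.0 - amplitude * np.cos(th)])
    return f


#: Named parametric bundle templates. ``cc_genu`` arches anteriorly,
#: ``cc_splenium`` posteriorly, ``cc_body`` superiorly; the cingulum is a
#: long sagittal arc; the uncinate a ventral hook.
BUNDLE_TEMPLATES: dict[str, Callable[[np.ndarray, float], np.ndarray]] = {
    "cingulum_dorsal_L": _cingulum(-1.0),
    "cingulum_dorsal_R": _cingulum(+1.0),
    "cc_genu": _cc_arch(22.0, +1.0, 20.0),
    "cc_splenium": _cc_arch(-32.0, -1.0, 18.0),
    "cc_body": _cc_arch(0.0, 0.0, 25.0),
    "uncinate_L": _uncinate(-1.0),
    "uncinate_R": _uncinate(+1.0),
}


@dataclass
class SimulationDesign:
    """All knobs of the synthetic study, with the study conditions as defaults.

    Effects are linear in the configured penetrance score (percent):
    the cingulum arc amplitude grows by ``curvature_effect`` mm per
    penetrance-percent and bundle-interior metric values shift by
    ``microstructure_effects[metric]`` per percent.
    """

    #: CNV label -> carrier count; default = the real per-CNV study counts.
    cnv_counts: dict[str, int] | None = None
    bundle_templates: tuple[str, ...] = (
        "cingulum_dorsal_L", "cc_splenium", "cc_body", "cc_genu")
    #: templates whose amplitude carries the penetrance effect
    effect_bundles: tuple[str, ...] = ("cingulum_dorsal_L",)
    effect_score: str = "P_DD"
    n_streamlines: int = 50
    n_points: int = 60
    amplitude_base: float = 15.0          # mm, a0
    curvature_effect: float = 0.05        # mm per penetrance-percent, beta_a
    amplitude_subject_sd: float = 1.0     # mm, between-subject amplitude noise
    point_jitter_sd: float = 1.0          # mm, per-point isotropic jitter
    microstructure_effects: dict[str, float] = field(
        default_factory=lambda: {"ICVF": -0.002})  # per penetrance-percent
    metric_base: dict[str, float] = field(default_factory=lambda: {
        "FA": 0.45, "MD": 0.8e-3, "AD": 1.3e-3, "RD": 0.6e-3,
        "R1": 1.0, "T1": 1.0, "ICVF": 0.6, "ISOF": 0.1, "ODI": 0.2})
    map_noise_sd: float = 0.01            # per-voxel map noise (metric units)
    voxel_size: float = 2.0               # mm, isotropic map grid
    # covariate model
    age_mean: float = 38.0
    age_sd: float = 12.0
    age_range: tuple[float, float] = (18.0, 65.0)
    male_fraction_carriers: float = 14.0 / 21.0
    male_fraction_controls: float = 6.0 / 15.0
    tbv_mean: float = 1.1e6               # mm^3
    tbv_sd: float = 1.0e5
    motion_scale: float = 1.0             # half-normal scale, unitless index
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cnv_counts is None:
            table = load_penetrance_table().table
            self.cnv_counts = {l: int(n) for l, n in table["n"].items()}
        if any(n < 0 for n in self.cnv_counts.values()):
            raise ValueError("cnv_counts must be non-negative")
        for name in self.bundle_templates:
            if name not in BUNDLE_TEMPLATES:
                raise ValueError(f"unknown bundle template {name!r}; "
                                 f"available: {sorted(BUNDLE_TEMPLATES)}")
        if self.point_jitter_sd < 0 or self.map_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.n_streamlines < 1 or self.n_points < 4:
            raise ValueError("need >= 1 streamline and >= 4 points")


def build_cohort(design: SimulationDesign,
                 table: PenetranceTable | None = None) -> pd.DataFrame:
    """Build the cohort table: one row per subject, scores populated.

    Subjects are ordered carriers-first by CNV label (table order), then
    controls; covariates are drawn from the design's distributions
    (age truncated-normal, gender Bernoulli per group, TBV normal,
    motion half-normal). Deterministic per seed.
    """
    if table is None:
        table = load_penetrance_table()
    known = set(table.labels)
    bad = sorted(set(design.cnv_counts) - known)
    if bad:
        raise ValueError(f"unknown CNV labels in counts: {bad}")
    rng = _rng_for(design.seed, stage="cohort")
    rows = []
    order = [l for l in table.labels if l != CONTROL_LABEL] + [CONTROL_LABEL]
    idx = 0
    for label in order:
        for _ in range(design.cnv_counts.get(label, 0)):
            idx += 1
            carrier = label != CONTROL_LABEL
            p_male = (design.male_fraction_carriers if carrier
                      else design.male_fraction_controls)
            lo, hi = design.age_range
            age = float(rng.normal(design.age_mean, design.age_sd))
            while not lo <= age <= hi:
                age = float(rng.normal(design.age_mean, design.age_sd))
            rows.append({
                "subject": f"sub-{idx:03d}",
                "cnv_label": label,
                "age": age,
                "gender": "M" if rng.random() < p_male else "F",
                "total_brain_volume": float(rng.normal(design.tbv_mean,
                                                       design.tbv_sd)),
                "motion_index": float(abs(rng.normal(0.0, design.motion_scale))),
            })
    cohort = pd.DataFrame(rows).set_index("subject")
    return assign_scores(cohort, table)


def simulate_bundle(template: str, subject: pd.Series, design: SimulationDesign,
                    subject_id: str | None = None) -> list[Streamline]:
    """Simulate one subject's streamline bundle from a named template.

    The arc amplitude is ``a0 + beta_a * P + N(0, sd_subject^2)`` for
    effect bundles (``a0 + N(0, sd_subject^2)`` otherwise), with
    independent isotropic N(0, sigma^2) jitter on every point of every
    streamline copy. Streamlines are tagged with the true bundle label.
    """
    if template not in BUNDLE_TEMPLATES:
        raise ValueError(f"unknown bundle template {template!r}")
    sid = subject_id if subject_id is not None else str(subject.name)
    t_idx = sorted(BUNDLE_TEMPLATES).index(template)
    rng = _rng_for(design.seed, sid, "bundle", extra=t_idx)
    amplitude = design.amplitude_base
    if template in design.effect_bundles:
        amplitude += design.curvature_effect * float(subject[design.effect_score])
    amplitude += float(rng.normal(0.0, design.amplitude_subject_sd)) \
        if design.amplitude_subject_sd > 0 else 0.0
    t = np.linspace(0.0, 1.0, design.n_points)
    base = BUNDLE_TEMPLATES[template](t, amplitude)
    out = []
    for _ in range(design.n_streamlines):
        jitter = (rng.normal(0.0, design.point_jitter_sd, size=base.shape)
                  if design.point_jitter_sd > 0 else 0.0)
        out.append(Streamline(points=base + jitter, bundle_label=template))
    return out


def make_grid(points: np.ndarray, voxel_size: float,
              margin: float = 6.0) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Isotropic voxel-centre affine + shape covering a point cloud."""
    lo = np.floor(points.min(axis=0) - margin)
    hi = np.ceil(points.max(axis=0) + margin)
    shape = tuple(int(np.ceil((hi[k] - lo[k]) / voxel_size)) + 1 for k in range(3))
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size
    affine[:3, 3] = lo
    return affine, shape


def bundle_mask(streamlines: Sequence[Streamline], affine: np.ndarray,
                shape: Sequence[int], dilate: int = 1) -> np.ndarray:
    """Boolean voxel mask of the bundle (traversed voxels, dilated)."""
    vox = traversed_voxels(streamlines, affine, shape)
    mask = np.zeros(tuple(shape), dtype=bool)
    if vox.size:
        mask[tuple(vox.T)] = True
    if dilate:
        mask = binary_dilation(mask, iterations=dilate)
    return mask


def simulate_scalar_map(metric: str, subject: pd.Series, mask: np.ndarray,
                        affine: np.ndarray, design: SimulationDesign,
                        subject_id: str | None = None,
                        effect_mask: np.ndarray | None = None,
                        extra_seed: int = 0) -> ScalarVolume:
    """Simulate one scalar parameter map for one subject.

    The whole grid sits at the metric's base value; inside the bundle
    mask the value is ``base + slope * P + N(0, sigma_map^2)`` per voxel,
    truncated to the metric's physical range (with a warning if the
    *mean* itself falls outside the range). When ``effect_mask`` is
    given, the penetrance slope applies only there while the rest of
    ``mask`` receives base + noise — this localises the dose effect to
    the effect bundles.
    """
    if metric not in design.metric_base:
        raise ValueError(f"no base value configured for metric {metric!r}")
    sid = subject_id if subject_id is not None else str(subject.name)
    rng = _rng_for(design.seed, sid, "map", extra=extra_seed)
    base = design.metric_base[metric]
    slope = design.microstructure_effects.get(metric, 0.0)
    p = float(subject[design.effect_score])
    mean_in = base + slope * p
    lo, hi = METRIC_RANGES.get(metric, (-np.inf, np.inf))
    if not lo <= mean_in <= hi:
        warnings.warn(f"{metric}: effect drives mean to {mean_in:g}, outside "
                      f"[{lo:g}, {hi:g}]; values will be truncated", stacklevel=2)
    if effect_mask is None:
        effect_mask = mask
    grid = np.full(mask.shape, float(np.clip(base, lo, hi)))
    n_in = int(mask.sum())
    if n_in:
        vals = base + rng.normal(0.0, design.map_noise_sd, size=n_in) \
            if design.map_noise_sd > 0 else np.full(n_in, float(base))
        vals = vals + slope * p * effect_mask[mask]
        grid[mask] = np.clip(vals, lo, hi)
    return ScalarVolume(grid=grid, affine=affine, metric_name=metric)


def simulate_subject_maps(subject: pd.Series,
                          bundles: Mapping[str, Sequence[Streamline]],
                          design: SimulationDesign,
                          metrics: Sequence[str] | None = None,
                          ) -> tuple[dict[str, ScalarVolume], np.ndarray]:
    """All scalar maps for one subject on a grid covering their bundles.

    Returns ``(metric -> ScalarVolume, affine)``; the effect applies
    inside the union mask of the subject's bundles.
    """
    if metrics is None:
        metrics = tuple(design.metric_base)
    pts = np.vstack([s.points for sls in bundles.values() for s in sls])
    affine, shape = make_grid(pts, design.voxel_size)
    mask = np.zeros(shape, dtype=bool)
    effect_mask = np.zeros(shape, dtype=bool)
    for name, sls in bundles.items():
        bm = bundle_mask(sls, affine, shape)
        mask |= bm
        if name in design.effect_bundles:
            effect_mask |= bm
    maps = {m: simulate_scalar_map(m, subject, mask, affine, design,
                                   effect_mask=effect_mask, extra_seed=k)
            for k, m in enumerate(metrics)}
    return maps, affine


@dataclass
class SimulatedCohort:
    """A fully simulated study: cohort table + per-subject labelled bundles."""

    design: SimulationDesign
    cohort: pd.DataFrame
    bundles: dict[str, dict[str, list[Streamline]]]  # subject -> bundle -> sls


def simulate_cohort_dataset(design: SimulationDesign) -> SimulatedCohort:
    """Simulate the cohort table and every subject's streamline bundles.

    Scalar maps are intentionally not materialised here (they dominate
    memory); generate them per subject with :func:`simulate_subject_maps`.
    """
    cohort = build_cohort(design)
    bundles = {
        sid: {tpl: simulate_bundle(tpl, row, design, subject_id=sid)
              for tpl in design.bundle_templates}
        for sid, row in cohort.iterrows()}
    return SimulatedCohort(design=design, cohort=cohort, bundles=bundles)


def simulate_feature_table(cohort: pd.DataFrame, n_features: int,
                           effect_slope: float = 0.0, score: str = "P_DD",
                           noise_sd: float = 1.0,
                           nuisance: Mapping[str, float] | None = None,
                           seed: int = 0) -> pd.DataFrame:
    """Directly simulate an imaging-feature table on an existing cohort.

    Every feature is ``slope * score + nuisance structure + N(0, sd^2)``:
    a cheap generator for statistical calibration studies (null designs,
    power curves) that exercises the covariate policy without the
    streamline machinery. Default nuisance coefficients give age, gender,
    TBV and motion each a modest share of variance.
    """
    if nuisance is None:
        nuisance = {"age": 0.02, "gender": 0.3, "tbv": 0.2, "motion": 0.3}
    rng = np.random.default_rng(np.random.SeedSequence([seed, _STAGE["features"]]))
    n = len(cohort)
    male = (cohort["gender"] == "M").to_numpy(float)
    base = (nuisance.get("age", 0.0) * (cohort["age"].to_numpy(float) - cohort["age"].mean())
            + nuisance.get("gender", 0.0) * male
            + nuisance.get("tbv", 0.0)
            * (cohort["total_brain_volume"].to_numpy(float)
               - cohort["total_brain_volume"].mean()) / 1e5
            + nuisance.get("motion", 0.0) * cohort["motion_index"].to_numpy(float)
            + effect_slope * cohort[score].to_numpy(float))
    Y = base[:, None] + rng.normal(0.0, noise_sd, size=(n, n_features))
    return pd.DataFrame(Y, index=cohort.index,
                        columns=[f"feat{j + 1}" for j in range(n_features)])
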