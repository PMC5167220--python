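"""Synthetic atlas, subjects and cohorts for end-to-end pipeline testing.

The generator emulates the study design the analysis pipeline targets:
21 named bundles with the registry's template fiber counts, three
diagnostic groups (33 controls, 20 bvFTD, 23 EOAD by default) with
group-matched age distributions, sex ratios and MMSE scores, and
along-tract scalar profiles built as

    value = bundle/point baseline
          + group effect            (where an EffectSpec applies)
          + covariate slopes . covariates
          + independent Gaussian noise

Bundle geometry is a smooth randomized spline centerline per bundle with
jittered parallel copies as fibers; bundles are spaced far apart relative
to the matching threshold so extraction has an unambiguous ground truth.
Effects are additive on the scalar metrics directly, giving exact control
of effect sizes for power and recovery experiments; a tensor-level mode
(shift eigenvalues, recompute scalars) supports integration tests of the
tensor stage.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .extraction import AtlasBundle, SubjectTractProfile
from .registry import DEFAULT_K, load_registry, registry_order
from .stats import GROUPS, expected_direction
from .tensor import METRICS

__all__ = [
    "EffectSpec",
    "CohortSpec",
    "Cohort",
    "DEFAULT_NOISE_SD",
    "DEFAULT_BASELINE_RANGES",
    "generate_atlas",
    "generate_baselines",
    "generate_subject",
    "generate_cohort",
    "effect_from_d",
]

#: Per-metric additive noise SD at a single sample point.  FA is
#: dimensionless; diffusivities are mm^2/s.  Chosen to mimic the
#: point-level variability of along-tract profiles in clinical DTI.
DEFAULT_NOISE_SD = {"FA": 0.04, "MD": 6e-5, "RD": 6e-5, "AX": 8e-5}

#: Plausible per-bundle baseline ranges (not fitted to any dataset):
#: FA of coherent white matter, diffusivities around 0.7-0.8e-3 mm^2/s.
DEFAULT_BASELINE_RANGES = {
    "FA": (0.30, 0.70),
    "MD": (0.70e-3, 0.80e-3),
    "RD": (0.45e-3, 0.60e-3),
    "AX": (1.05e-3, 1.30e-3),
}

#: Default covariate slopes per metric: mild age-related FA decline and
#: diffusivity increase, small sex offsets, negligible brain-volume slope.
DEFAULT_COVARIATE_SLOPES = {
    "FA": {"age": -1.0e-3, "sex": 5.0e-3, "brain_volume": 0.0},
    "MD": {"age": 1.5e-6, "sex": -5.0e-6, "brain_volume": 0.0},
    "RD": {"age": 1.5e-6, "sex": -5.0e-6, "brain_volume": 0.0},
    "AX": {"age": 1.0e-6, "sex": -5.0e-6, "brain_volume": 0.0},
}


@dataclass(frozen=True)
class EffectSpec:
    """A planted group effect: additive shifts on chosen metrics over a
    contiguous range of sample points of one bundle.

    ``points`` are 1-based inclusive indices into 1..K; ``deltas`` maps
    metric name to the additive shift applied to subjects of ``group``.
    """

    bundle: str
    points: tuple[int, int]
    group: str
    deltas: dict[str, float]

    def __post_init__(self) -> None:
        lo, hi = self.points
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid point range {self.points}")
        bad = set(self.deltas) - set(METRICS)
        if bad:
            raise ValueError(f"unknown metrics in effect: {sorted(bad)}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")

    def point_mask(self, k: int) -> np.ndarray:
        lo, hi = self.points
        if hi > k:
            raise ValueError(f"point range {self.points} exceeds K={k}")
        mask = np.zeros(k, dtype=bool)
        mask[lo - 1 : hi] = True
        return mask


def effect_from_d(
    bundle: str,
    points: tuple[int, int],
    group: str,
    d: float,
    metrics: tuple[str, ...] = METRICS,
    noise_sd: dict[str, float] | None = None,
) -> EffectSpec:
    """An EffectSpec whose shifts equal ``d`` noise standard deviations,
    signed in the hypothesized disease direction of each metric."""
    sd = noise_sd or DEFAULT_NOISE_SD
    deltas = {m: expected_direction(m) * d * sd[m] for m in metrics}
    return EffectSpec(bundle=bundle, points=points, group=group, deltas=deltas)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generator parameters.

    Defaults reproduce the emulated study's design: 33/20/23 subjects,
    group age distributions 59.4+-9.6, 60.7+-10.7, 59.0+-5.0 years, sex
    ratios 14M/19F, 8M/12F, 10M/13F and MMSE 29.1+-0.9, 24.1+-4.7,
    23.4+-4.2 for controls, bvFTD and EOAD respectively.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"control": 33, "bvFTD": 20, "EOAD": 23}
    )
    age_mean: dict[str, float] = field(
        default_factory=lambda: {"control": 59.4, "bvFTD": 60.7, "EOAD": 59.0}
    )
    age_sd: dict[str, float] = field(
        default_factory=lambda: {"control": 9.6, "bvFTD": 10.7, "EOAD": 5.0}
    )
    n_male: dict[str, int] = field(
        default_factory=lambda: {"control": 14, "bvFTD": 8, "EOAD": 10}
    )
    mmse_mean: dict[str, float] = field(
        default_factory=lambda: {"control": 29.1, "bvFTD": 24.1, "EOAD": 23.4}
    )
    mmse_sd: dict[str, float] = field(
        default_factory=lambda: {"control": 0.9, "bvFTD": 4.7, "EOAD": 4.2}
    )
    brain_volume_mean: float = 1.10e6  # mm^3
    brain_volume_sd: float = 0.10e6
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    covariate_slopes: dict[str, dict[str, float]] = field(
        default_factory=lambda: {m: dict(s) for m, s in DEFAULT_COVARIATE_SLOPES.items()}
    )
    #: MMSE points lost per cohort-SD increase of a subject's global mean MD.
    mmse_coupling: float = 1.0
    dropout: float = 0.0
    k: int = DEFAULT_K
    metrics: tuple[str, ...] = METRICS
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs >= 2 subjects, got {n}")
        for m, sd in self.noise_sd.items():
            if sd <= 0:
                raise ValueError(f"noise SD for {m} must be > 0")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class Cohort:
    """A generated cohort: profiles, design table and planted-effect truth."""

    profiles: dict[str, SubjectTractProfile]
    design: pd.DataFrame
    truth_mask: dict[str, np.ndarray]  # bundle -> (K,) bool, any planted effect
    atlas: dict[str, list[AtlasBundle]]
    baselines: dict[str, np.ndarray]  # bundle -> (K, 4) metric baselines
    spec: CohortSpec


# ---------------------------------------------------------------------------
# Atlas geometry


def _bundle_centerline(rng: np.random.Generator, center: np.ndarray, n_dense: int = 60) -> np.ndarray:
    """A smooth random spline through jittered control points, ~80 mm long."""
    n_ctrl = 5
    t = np.linspace(0.0, 1.0, n_ctrl)
    ctrl = np.empty((n_ctrl, 3))
    ctrl[:, 0] = np.linspace(-40.0, 40.0, n_ctrl) + rng.normal(0, 2.0, n_ctrl)
    ctrl[:, 1] = rng.normal(0, 10.0, n_ctrl)
    ctrl[:, 2] = rng.normal(0, 10.0, n_ctrl)
    spline = CubicSpline(t, ctrl, axis=0)
    dense = spline(np.linspace(0.0, 1.0, n_dense))
    return dense + center


def _resample_many(curves: np.ndarray, k: int) -> np.ndarray:
    from .streamlines import resample_polyline

    return np.stack([resample_polyline(c, k) for c in curves])


def generate_atlas(
    registry: pd.DataFrame | None = None,
    k: int = DEFAULT_K,
    seed: int = 0,
    n_atlases: int = 1,
    fiber_scale: float = 1.0,
    fiber_spread: float = 1.5,
    bundle_spacing: float = 100.0,
) -> dict[str, list[AtlasBundle]]:
    """Generate template bundles for every registry entry.

    Each bundle is a randomized smooth centerline with its registered
    number of fibers as jittered parallel copies resampled to ``k``
    points.  Bundles sit on a widely spaced grid so that inter-bundle
    distances dwarf the matching threshold.  ``fiber_scale`` < 1 shrinks
    fiber counts proportionally (minimum 1) for reduced-size runs;
    ``n_atlases`` > 1 emits additional lightly perturbed atlas subjects
    for multi-atlas fusion.
    """
    reg = registry if registry is not None else load_registry()
    if (reg["n_fibers"] <= 0).any():
        raise ValueError("fiber counts must be positive")
    atlas: dict[str, list[AtlasBundle]] = {}
    n_cols = int(math.ceil(math.sqrt(len(reg))))
    for b_idx, row in reg.reset_index(drop=True).iterrows():
        name = row["abbreviation"]
        n_fibers = max(1, int(round(row["n_fibers"] * fiber_scale)))
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence([seed, 0xA71A5, b_idx]))
        )
        center = np.array(
            [
                (b_idx % n_cols) * bundle_spacing,
                (b_idx // n_cols) * bundle_spacing,
                0.0,
            ]
        )
        centerline = _bundle_centerline(rng, center)
        offsets = rng.normal(0.0, fiber_spread, size=(n_fibers, 1, 3))
        if n_fibers == 1:
            offsets[:] = 0.0  # a single-fiber bundle is its centerline
        fibers = centerline[None, :, :] + offsets
        prototypes = _resample_many(fibers, k)
        bundles = [AtlasBundle(name=name, prototypes=prototypes, atlas_id=0)]
        for a in range(1, n_atlases):
            jitter = rng.normal(0.0, 0.2, size=prototypes.shape)
            bundles.append(
                AtlasBundle(name=name, prototypes=prototypes + jitter, atlas_id=a)
            )
        atlas[name] = bundles
    return atlas


# ---------------------------------------------------------------------------
# Scalar baselines and subjects


def generate_baselines(
    bundle_names: list[str],
    k: int = DEFAULT_K,
    seed: int = 0,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> dict[str, np.ndarray]:
    """Per-bundle (K, 4) baseline profiles: a bundle-level mean drawn from
    the plausible range plus a smooth low-amplitude along-tract
    modulation."""
    ranges = ranges or DEFAULT_BASELINE_RANGES
    baselines = {}
    for b_idx, name in enumerate(bundle_names):
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence([seed, 0xBA5E, b_idx]))
        )
        arr = np.empty((k, len(METRICS)))
        x = np.linspace(0.0, 1.0, k)
        for mi, metric in enumerate(METRICS):
            lo, hi = ranges[metric]
            level = rng.uniform(lo, hi)
            amp = 0.05 * (hi - lo)
            phase = rng.uniform(0, 2 * np.pi)
            arr[:, mi] = level + amp * np.sin(2 * np.pi * x + phase)
        baselines[name] = arr
    return baselines


def _covariate_offset(
    metric: str, slopes: dict[str, dict[str, float]], covariates: dict
) -> float:
    s = slopes.get(metric, {})
    sex_ind = 1.0 if covariates["sex"] == "M" else 0.0
    return (
        s.get("age", 0.0) * covariates["age"]
        + s.get("sex", 0.0) * sex_ind
        + s.get("brain_volume", 0.0) * covariates["brain_volume"]
    )


def generate_subject(
    atlas: dict[str, list[AtlasBundle]],
    covariates: dict,
    effects: tuple[EffectSpec, ...] = (),
    noise_sd: dict[str, float] | None = None,
    covariate_slopes: dict[str, dict[str, float]] | None = None,
    dropout: float = 0.0,
    seed: int = 0,
    baselines: dict[str, np.ndarray] | None = None,
    with_streamlines: bool = False,
    fiber_jitter: float = 0.3,
) -> tuple[SubjectTractProfile, dict[str, list[np.ndarray]]]:
    """One subject's profile (and optionally streamlines) from the atlas.

    ``covariates`` must hold group, age, sex and brain_volume.  Dropped
    fiber slots (fraction ``dropout``, seeded) are flagged as map
    fallback; their scalar values follow the same generative model, as
    sampling a registered map at the prototype's points would.  Returned
    streamlines cover only the surviving slots, as jittered copies of the
    atlas prototypes.
    """
    if not (0 <= dropout < 1):
        raise ValueError("dropout must be in [0, 1)")
    noise_sd = noise_sd or DEFAULT_NOISE_SD
    slopes = covariate_slopes if covariate_slopes is not None else DEFAULT_COVARIATE_SLOPES
    names = list(atlas.keys())
    for eff in effects:
        if eff.bundle not in names:
            raise ValueError(f"effect references unknown bundle {eff.bundle!r}")
    k = atlas[names[0]][0].k
    if baselines is None:
        baselines = generate_baselines(names, k=k)
    rng = np.random.Generator(np.random.PCG64(seed))
    profile = SubjectTractProfile(subject_id=str(covariates.get("id", "subject")))
    streamlines: dict[str, list[np.ndarray]] = {}
    group = covariates["group"]
    for name in names:
        protos = atlas[name][0].prototypes
        n_slots = protos.shape[0]
        base = baselines[name]  # (K, 4)
        values = np.broadcast_to(base, (n_slots, k, len(METRICS))).copy()
        for mi, metric in enumerate(METRICS):
            values[:, :, mi] += _covariate_offset(metric, slopes, covariates)
            for eff in effects:
                if eff.bundle == name and eff.group == group and metric in eff.deltas:
                    values[:, eff.point_mask(k), mi] += eff.deltas[metric]
            values[:, :, mi] += rng.normal(0.0, noise_sd[metric], size=(n_slots, k))
        dropped = rng.random(n_slots) < dropout
        profile.values[name] = values
        profile.fallback[name] = np.repeat(dropped[:, None], k, axis=1)
        if with_streamlines:
            keep = np.flatnonzero(~dropped)
            jitter = rng.normal(0.0, fiber_jitter, size=(keep.size, k, 3))
            streamlines[name] = [protos[j] + jitter[i] for i, j in enumerate(keep)]
    profile.validate()
    return profile, streamlines


def _group_design(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for group in spec.group_sizes:
        n = spec.group_sizes[group]
        n_male = spec.n_male.get(group, n // 2)
        ages = rng.normal(spec.age_mean[group], spec.age_sd[group], size=n)
        sexes = np.array(["M"] * n_male + ["F"] * (n - n_male))
        rng.shuffle(sexes)
        volumes = rng.normal(spec.brain_volume_mean, spec.brain_volume_sd, size=n)
        for i in range(n):
            rows.append(
                {
                    "id": f"{group.lower()}{i + 1:03d}",
                    "group": group,
                    "age": round(float(ages[i]), 1),
                    "sex": sexes[i],
                    "brain_volume": round(float(volumes[i]), 0),
                }
            )
    return pd.DataFrame(rows)


def generate_cohort(
    spec: CohortSpec,
    effects: tuple[EffectSpec, ...] = (),
    atlas: dict[str, list[AtlasBundle]] | None = None,
    registry: pd.DataFrame | None = None,
    fiber_scale: float = 1.0,
    with_streamlines: bool = False,
) -> Cohort:
    """Generate a full cohort: atlas, per-subject profiles, design table
    with MMSE, and the ground-truth mask of planted (bundle, point)
    effects.

    MMSE is drawn from the group's distribution with a planted negative
    dependence (``spec.mmse_coupling`` points per cohort SD) on the
    subject's global mean MD, then clipped to 0..30 integers.
    """
    ss = np.random.SeedSequence([spec.seed, 0xC0407])
    design_rng = np.random.Generator(np.random.PCG64(ss.spawn(1)[0]))
    if atlas is None:
        atlas = generate_atlas(
            registry=registry, k=spec.k, seed=spec.seed, fiber_scale=fiber_scale
        )
    names = list(atlas.keys())
    for eff in effects:
        if eff.bundle not in names:
            raise ValueError(f"effect references unknown bundle {eff.bundle!r}")
        if eff.group not in spec.group_sizes:
            raise ValueError(f"effect group {eff.group!r} absent from cohort")
    baselines = generate_baselines(names, k=spec.k, seed=spec.seed)
    design = _group_design(spec, design_rng)
    subject_seeds = ss.spawn(len(design))
    profiles = {}
    for (_, row), sub_ss in zip(design.iterrows(), subject_seeds):
        profile, _ = generate_subject(
            atlas,
            covariates=row.to_dict(),
            effects=effects,
            noise_sd=spec.noise_sd,
            covariate_slopes=spec.covariate_slopes,
            dropout=spec.dropout,
            seed=sub_ss,
            baselines=baselines,
            with_streamlines=with_streamlines,
        )
        profile.subject_id = row["id"]
        profiles[row["id"]] = profile

    # MMSE: group distribution plus planted coupling to global mean MD.
    md_idx = METRICS.index("MD")
    mean_md = np.array(
        [
            np.mean([profiles[sid].values[n][:, :, md_idx].mean() for n in names])
            for sid in design["id"]
        ]
    )
    z = (mean_md - mean_md.mean()) / (mean_md.std() if mean_md.std() > 0 else 1.0)
    mmse_rng = np.random.Generator(np.random.PCG64(ss.spawn(1)[0]))
    mmse = np.empty(len(design))
    for i, group in enumerate(design["group"]):
        mmse[i] = (
            mmse_rng.normal(spec.mmse_mean[group], spec.mmse_sd[group])
            - spec.mmse_coupling * z[i]
        )
    design["mmse"] = np.clip(np.round(mmse), 0, 30).astype(int)

    truth_mask = {name: np.zeros(spec.k, dtype=bool) for name in names}
    for eff in effects:
        truth_mask[eff.bundle] |= eff.point_mask(spec.k)
    return Cohort(
        profiles=profiles,
        design=design,
        truth_mask=truth_mask,
        atlas=atlas,
        baselines=baselines,
        spec=spec,
    )
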