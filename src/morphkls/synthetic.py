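"""Synthetic cohorts with the statistical structure the analysis assumes.

Two groups of subjects (controls and patients) are generated; each subject
is a set of 90 regional bags of positive "grey-matter volume" voxel values.
Per-region value distributions are two-component Gaussian mixtures truncated
at zero.  Regions are organised into modules that share mixture parameters,
so that within-module pairs have similar distribution shapes and therefore
high KLS edges — giving the networks the modular, small-world-like structure
the downstream graph analysis expects.

Group differences are planted in two ways:

``mean_shift``
    Affected regions' mixture means are shifted in patients, scaled by a
    per-patient severity factor — detectable by nodal and edge-level tests.
``module_tighten``
    Affected regions' within-module parameter jitter shrinks in patients,
    strengthening within-module similarity — raising network segregation
    (clustering coefficient, local efficiency).

Patients' UPDRS-III motor scores are generated from the same severity factor
(plus noise), so clinical correlations with network metrics have known sign.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np

from .network import N_REGIONS, RegionalVoxelSet

N_MODULES = 9
SUBTYPES = ("tremor", "akinetic_rigid", "mixed")


@dataclass
class SubjectMeta:
    """Demographic and clinical record for one subject."""

    subject_id: str
    group: str  # control | patient
    subtype: str  # tremor | akinetic_rigid | mixed | none
    age: float
    gender: int  # 0 female, 1 male
    education: float
    updrs3: float
    hoehn_yahr: float
    mmse: float

    def __post_init__(self) -> None:
        if self.group not in ("control", "patient"):
            raise ValueError(f"invalid group {self.group!r}")
        if (self.subtype == "none") != (self.group == "control"):
            raise ValueError("subtype must be 'none' iff group is 'control'")
        if self.group == "patient" and self.subtype not in SUBTYPES:
            raise ValueError(f"invalid subtype {self.subtype!r}")
        if not 0 <= self.updrs3 <= 108:
            raise ValueError("updrs3 out of range 0-108")
        if not 0 <= self.hoehn_yahr <= 5 or (self.hoehn_yahr * 2) % 1 != 0:
            raise ValueError("hoehn_yahr must be in 0-5 in half steps")
        if not 0 <= self.mmse <= 30:
            raise ValueError("mmse out of range 0-30")
        if self.gender not in (0, 1):
            raise ValueError("gender must be coded 0/1")


@dataclass
class PlantedEffect:
    """Group difference planted into patient subjects."""

    regions: tuple[int, ...] = ()  # 0-based region indices
    magnitude: float = 0.0
    kind: str = "mean_shift"  # mean_shift | module_tighten

    def __post_init__(self) -> None:
        self.regions = tuple(int(r) for r in self.regions)
        if any(r < 0 or r >= N_REGIONS for r in self.regions):
            raise ValueError("affected regions must be within 1..90 (0-based 0..89)")
        if self.kind not in ("mean_shift", "module_tighten"):
            raise ValueError(f"unknown effect kind {self.kind!r}")


@dataclass
class ClinicalLink:
    """Couples patients' UPDRS-III scores to the planted severity factor."""

    region: int = 0
    metric: str = "degree"
    slope: float = 20.0
    noise_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise SD must be > 0")


@dataclass
class SimulationDesign:
    """Full description of a synthetic two-group cohort."""

    n_per_group: int = 20
    voxels_per_region: int = 300
    planted_effect: PlantedEffect = field(default_factory=PlantedEffect)
    clinical_link: ClinicalLink = field(default_factory=ClinicalLink)
    seed: int = 0
    # base-distribution shape parameters (per-module mixtures)
    component_gap: float = 0.25
    component_sd: float = 0.08
    mixture_weight: float = 0.6
    region_jitter_sd: float = 0.03
    subject_sd: float = 0.012

    def __post_init__(self) -> None:
        if self.n_per_group <= 0 or self.voxels_per_region <= 0:
            raise ValueError("invalid design: counts must be positive")
        if self.voxels_per_region < 30:
            raise ValueError("invalid design: need >= 30 voxels per region")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationDesign":
        raw = json.loads(Path(path).read_text())
        raw["planted_effect"] = PlantedEffect(**raw.get("planted_effect", {}))
        raw["clinical_link"] = ClinicalLink(**raw.get("clinical_link", {}))
        return cls(**raw)


def module_of(region: int) -> int:
    """Module index (0..8) of a 0-based region index."""
    return region % N_MODULES


def _base_parameters(design: SimulationDesign) -> tuple[np.ndarray, np.ndarray]:
    """Fixed per-region mixture means: module base + deterministic jitter.

    Returns (mean1, mean2) arrays of length 90.  The jitter is drawn from a
    dedicated RNG seeded only by the design seed, so it is a property of the
    design, shared by every subject.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 17]))
    modules = np.arange(N_REGIONS) % N_MODULES
    base = 0.30 + 0.05 * modules
    jitter = rng.normal(0.0, design.region_jitter_sd, N_REGIONS)
    mean1 = base + jitter
    return mean1, mean1 + design.component_gap


def _draw_region_values(
    rng: np.random.Generator,
    n: int,
    mean1: float,
    mean2: float,
    sd: float,
    w: float,
) -> np.ndarray:
    comp = rng.random(n) < w
    vals = np.where(comp, rng.normal(mean1, sd, n), rng.normal(mean2, sd, n))
    return np.clip(vals, 0.0, None)  # truncate the mixture at zero


def simulate_cohort(
    design: SimulationDesign,
    return_severity: bool = False,
):
    """Generate a two-group cohort of regional voxel-value sets plus metadata.

    Deterministic for a fixed design seed.  With ``planted_effect.magnitude``
    zero the two groups are statistically exchangeable.  With
    ``return_severity=True`` also returns the latent per-subject severity
    factors (ground truth for recovery tests), in cohort order.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 29]))
    mean1, mean2 = _base_parameters(design)
    effect = design.planted_effect
    affected = np.zeros(N_REGIONS, dtype=bool)
    affected[list(effect.regions)] = True

    subjects: list[RegionalVoxelSet] = []
    metas: list[SubjectMeta] = []
    severities: list[float] = []
    for group, prefix in (("control", "hc"), ("patient", "pd")):
        for i in range(design.n_per_group):
            sid = f"{prefix}{i + 1:03d}"
            severity = rng.uniform(0.5, 1.5)
            severities.append(severity)
            subj_noise = rng.normal(0.0, design.subject_sd, N_REGIONS)
            m1 = mean1 + subj_noise
            m2 = mean2 + subj_noise
            if group == "patient" and effect.magnitude > 0:
                if effect.kind == "mean_shift":
                    shift = effect.magnitude * severity
                    m1 = np.where(affected, m1 + shift, m1)
                    m2 = np.where(affected, m2 + shift, m2)
                else:  # module_tighten: pull affected regions onto module base
                    frac = np.clip(effect.magnitude * severity, 0.0, 1.0)
                    modules = np.arange(N_REGIONS) % N_MODULES
                    base1 = 0.30 + 0.05 * modules
                    base2 = base1 + design.component_gap
                    m1 = np.where(affected, m1 + frac * (base1 - m1), m1)
                    m2 = np.where(affected, m2 + frac * (base2 - m2), m2)
            bags = [
                _draw_region_values(
                    rng,
                    design.voxels_per_region,
                    m1[r],
                    m2[r],
                    design.component_sd,
                    design.mixture_weight,
                )
                for r in range(N_REGIONS)
            ]
            subjects.append(RegionalVoxelSet(sid, bags))
            metas.append(_draw_meta(rng, sid, group, severity, design))
    if return_severity:
        return subjects, metas, np.asarray(severities)
    return subjects, metas


def _draw_meta(
    rng: np.random.Generator,
    sid: str,
    group: str,
    severity: float,
    design: SimulationDesign,
) -> SubjectMeta:
    age = float(np.clip(rng.normal(56.0, 7.0), 30, 85))
    gender = int(rng.random() < 0.35)
    education = float(np.clip(rng.normal(9.0, 3.4), 0, 22))
    if group == "control":
        return SubjectMeta(sid, "control", "none", age, gender, education,
                           updrs3=0.0, hoehn_yahr=0.0,
                           mmse=float(np.clip(rng.normal(28.5, 1.2), 24, 30)))
    link = design.clinical_link
    updrs = float(np.clip(
        5.0 + link.slope * severity + rng.normal(0.0, link.noise_sd), 0, 108))
    hy = float(np.clip(np.round(2 * (0.5 + severity)) / 2, 1.0, 2.5))
    mmse = float(np.clip(rng.normal(27.9, 1.9), 24, 30))
    subtype = SUBTYPES[rng.choice(3, p=[0.46, 0.32, 0.22])]
    return SubjectMeta(sid, "patient", subtype, age, gender, education,
                       updrs3=updrs, hoehn_yahr=hy, mmse=mmse)


def build_block_atlas(shape: tuple[int, int, int], voxels_per_region: int) -> np.ndarray:
    """Integer atlas assigning each region a contiguous block of voxels."""
    total = int(np.prod(shape))
    if N_REGIONS * voxels_per_region > total:
        raise ValueError(
            f"volume {shape} too small for {N_REGIONS} parcels of "
            f"{voxels_per_region} voxels"
        )
    flat = np.zeros(total, dtype=np.int16)
    for k in range(N_REGIONS):
        flat[k * voxels_per_region:(k + 1) * voxels_per_region] = k + 1
    return flat.reshape(shape)


def write_cohort_nifti(
    cohort: list[RegionalVoxelSet],
    out_dir: str | Path,
    atlas_shape: tuple[int, int, int] = (30, 30, 30),
) -> tuple[list[Path], Path]:
    """Write one grey-matter-value NIfTI per subject plus a shared atlas.

    Voxel values are placed in the atlas parcels so that re-extraction
    recovers each subject's regional bags exactly (as multisets).
    Returns (subject map paths, atlas path).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vpr = {len(bag) for subj in cohort for bag in subj.region_values}
    if len(vpr) != 1:
        raise ValueError("all regions must have the same voxel count for NIfTI export")
    atlas = build_block_atlas(atlas_shape, vpr.pop())
    affine = np.eye(4)
    atlas_path = out_dir / "atlas.nii"
    nib.save(nib.Nifti1Image(atlas, affine), atlas_path)
    paths = []
    flat_idx = [np.flatnonzero(atlas.ravel() == k + 1) for k in range(N_REGIONS)]
    for subj in cohort:
        vol = np.zeros(atlas.size, dtype=np.float64)
        for k, bag in enumerate(subj.region_values):
            vol[flat_idx[k]] = bag
        p = out_dir / f"{subj.subject_id}_gm.nii"
        nib.save(nib.Nifti1Image(vol.reshape(atlas_shape), affine), p)
        paths.append(p)
    return paths, atlas_path
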