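"""Synthetic cohorts of levodopa-challenge-test subjects with ROI intensity samples.

The generator emulates the statistical structure the downstream analysis
assumes: two responsiveness groups defined by percent improvement of the
UPDRS-III motor score under a levodopa challenge (low responders at or below
33%, high responders above), and per-region gray-matter voxel-intensity
samples whose distributions differ between groups in a designated subset of
region pairs.  Group membership is never assigned directly: UPDRS scores are
drawn so that the responsiveness formula and threshold reproduce the intended
group sizes exactly, which keeps the labeling logic on the tested path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

GROUP_LOW = "LCT_L"
GROUP_HIGH = "LCT_H"
LR_THRESHOLD = 33.0


def compute_lr(updrs_off: float, updrs_on_peak: float) -> float:
    """Percent levodopa responsiveness: 100 * (off - peak on) / off.

    Both scores are UPDRS-III points (higher = worse).  The "off" score must
    be positive for the ratio to be defined.
    """
    if not math.isfinite(updrs_off) or not math.isfinite(updrs_on_peak):
        raise ValueError("UPDRS scores must be finite")
    if updrs_off <= 0:
        raise ValueError(f"levodopa responsiveness undefined for off score {updrs_off!r}")
    if updrs_on_peak < 0:
        raise ValueError("UPDRS scores must be nonnegative")
    return (updrs_off - updrs_on_peak) / updrs_off * 100.0


def assign_group(lr_percent: float, threshold: float = LR_THRESHOLD) -> str:
    """Dichotomize responsiveness: ``LCT_L`` if lr <= threshold else ``LCT_H``."""
    if not (0.0 <= lr_percent <= 100.0):
        raise ValueError(f"lr_percent must lie in [0, 100], got {lr_percent!r}")
    return GROUP_LOW if lr_percent <= threshold else GROUP_HIGH


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    updrs_off: float
    updrs_on_peak: float
    lr_percent: float
    group: str

    def __post_init__(self) -> None:
        if self.group not in (GROUP_LOW, GROUP_HIGH):
            raise ValueError(f"unknown group {self.group!r}")


@dataclass(frozen=True)
class ROIIntensitySamples:
    """Per-region vectors of gray-matter voxel intensities for one subject."""

    subject_id: str
    samples: dict[int, np.ndarray]

    def validate(self) -> None:
        for roi, vec in self.samples.items():
            vec = np.asarray(vec)
            if vec.size < 2:
                raise ValueError(f"ROI {roi} has fewer than 2 samples")
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"ROI {roi} has non-finite intensities")
            if vec.min() < 0.0 or vec.max() > 1.0:
                raise ValueError(f"ROI {roi} has intensities outside [0, 1]")

    @property
    def n_rois(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters for a synthetic cohort.

    Defaults mirror the analysis conditions the pipeline is built for: 13 low
    responders versus 25 high responders, 90 atlas regions, a couple hundred
    voxels per region, and gray-matter-probability-like intensities from a
    truncated normal on [0, 1].  ``effect_size`` is expressed in units of the
    within-region standard deviation: for each pair (a, b) in
    ``effect_pairs``, high responders have region b's distribution altered
    (mean shift by default, variance inflation with
    ``effect_mode="variance"``), which makes the a-b divergence differ
    between groups.
    """

    n_low: int = 13
    n_high: int = 25
    n_rois: int = 90
    voxels_per_roi: int = 200
    effect_pairs: tuple[tuple[int, int], ...] = ()
    effect_size: float = 0.0
    effect_mode: str = "mean_shift"
    base_mean: float = 0.4
    base_sd: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_low < 1 or self.n_high < 1:
            raise ValueError("both groups need at least one subject")
        if self.n_rois < 2:
            raise ValueError("need at least 2 ROIs")
        if self.voxels_per_roi < 2:
            raise ValueError("need at least 2 voxels per ROI")
        if not (0.0 < self.base_mean < 1.0):
            raise ValueError("base_mean must lie in (0, 1)")
        if self.base_sd <= 0:
            raise ValueError("base_sd must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if self.effect_mode not in ("mean_shift", "variance"):
            raise ValueError(f"unknown effect_mode {self.effect_mode!r}")
        if self.effect_size > 0 and not self.effect_pairs:
            raise ValueError("effect_size > 0 requires effect_pairs")
        seen: set[tuple[int, int]] = set()
        for a, b in self.effect_pairs:
            if not (0 <= a < self.n_rois and 0 <= b < self.n_rois) or a == b:
                raise ValueError(f"invalid ROI pair ({a}, {b})")
            key = (min(a, b), max(a, b))
            if key in seen:
                raise ValueError(f"duplicate ROI pair ({a}, {b})")
            seen.add(key)

    @property
    def n_subjects(self) -> int:
        return self.n_low + self.n_high

    def with_(self, **kwargs) -> "CohortSpec":
        return replace(self, **kwargs)


def _truncnorm_samples(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _shifted_rois(spec: CohortSpec) -> set[int]:
    # The second member of each designated pair carries the group effect.
    return {b for _, b in spec.effect_pairs}


def generate_cohort(spec: CohortSpec) -> list[tuple[SubjectRecord, ROIIntensitySamples]]:
    """Draw a full cohort: metadata plus per-region intensity samples.

    One master seed; each subject consumes an independent, deterministically
    derived substream, so the cohort is reproducible and subjects can be
    regenerated in any order.  Low responders come first in the returned
    list; group sizes match the spec exactly for every seed.
    """
    master = np.random.SeedSequence(spec.seed)
    children = master.spawn(spec.n_subjects)
    shifted = _shifted_rois(spec)
    out: list[tuple[SubjectRecord, ROIIntensitySamples]] = []
    for idx in range(spec.n_subjects):
        is_high = idx >= spec.n_low
        rng = np.random.default_rng(children[idx])
        off = float(rng.integers(30, 71))
        # Target responsiveness inside the group's band; the open lower edge
        # of the high band is safe because a continuous draw never hits 33.
        lr = float(rng.uniform(33.0, 80.0)) if is_high else float(rng.uniform(10.0, 33.0))
        on = off * (1.0 - lr / 100.0)
        lr_check = compute_lr(off, on)
        record = SubjectRecord(
            subject_id=f"sub-{idx + 1:03d}",
            updrs_off=off,
            updrs_on_peak=on,
            lr_percent=lr_check,
            group=assign_group(lr_check),
        )
        samples: dict[int, np.ndarray] = {}
        for roi in range(spec.n_rois):
            mean, sd = spec.base_mean, spec.base_sd
            if is_high and roi in shifted and spec.effect_size > 0:
                if spec.effect_mode == "mean_shift":
                    mean = mean + spec.effect_size * spec.base_sd
                else:
                    sd = sd * (1.0 + spec.effect_size)
            samples[roi] = _truncnorm_samples(rng, mean, sd, spec.voxels_per_roi)
        roi_samples = ROIIntensitySamples(subject_id=record.subject_id, samples=samples)
        roi_samples.validate()
        out.append((record, roi_samples))
    n_low = sum(1 for rec, _ in out if rec.group == GROUP_LOW)
    assert n_low == spec.n_low, "group construction must reproduce spec sizes"
    return out


# ---------------------------------------------------------------------------
# volumetric fixture


def _near_cube_factors(v: int) -> tuple[int, int, int]:
    """Factor v into three integers as close to a cube as possible."""
    best = (v, 1, 1)
    best_score = float(v)
    for a in range(1, v + 1):
        if v % a:
            continue
        va = v // a
        for b in range(1, va + 1):
            if va % b:
                continue
            c = va // b
            dims = sorted((a, b, c))
            score = dims[2] / dims[0]
            if score < best_score:
                best_score = score
                best = (a, b, c)
    return best


def default_label_table(n_rois: int = 90) -> pd.DataFrame:
    """Region label table: integer label, name, hemisphere.

    Follows the customary atlas convention of alternating left/right
    homologues (odd labels left, even labels right), giving 45 regions per
    hemisphere for the default 90-region parcellation.
    """
    rows = []
    for i in range(1, n_rois + 1):
        hemi = "L" if i % 2 == 1 else "R"
        rows.append({"index": i, "name": f"ROI_{i:03d}_{hemi}", "hemisphere": hemi})
    return pd.DataFrame(rows)


def generate_volume_fixture(spec: CohortSpec):
    """Emit the volumetric form of a cohort: GM maps, parcellation, labels.

    Each region occupies a disjoint cuboid parcel on a regular lattice with a
    one-voxel background gap; the parcel's voxels are exactly that subject's
    ROI samples laid out in row-major order, so extraction round-trips the
    generating samples.  Returns ``(gm_volumes, parcellation, label_table,
    cohort)`` where ``gm_volumes`` maps subject_id to a gm-map
    :class:`~jssenet.roi.LabeledVolume` and ``cohort`` is the underlying
    sample cohort.
    """
    from jssenet.roi import LabeledVolume

    cohort = generate_cohort(spec)
    block = _near_cube_factors(spec.voxels_per_roi)
    k1 = int(math.ceil(spec.n_rois ** (1 / 3)))
    k2 = int(math.ceil(math.sqrt(spec.n_rois / k1)))
    k3 = int(math.ceil(spec.n_rois / (k1 * k2)))
    shape = tuple(k * (d + 1) + 1 for k, d in zip((k1, k2, k3), block))
    affine = np.diag([1.5, 1.5, 1.5, 1.0])

    parcel_data = np.zeros(shape, dtype=np.int32)
    slots: list[tuple[slice, slice, slice]] = []
    label = 0
    for i in range(k1):
        for j in range(k2):
            for k in range(k3):
                if label >= spec.n_rois:
                    break
                label += 1
                sl = tuple(
                    slice(1 + idx * (d + 1), 1 + idx * (d + 1) + d)
                    for idx, d in zip((i, j, k), block)
                )
                if np.any(parcel_data[sl]):
                    raise RuntimeError("parcel layout produced overlapping blocks")
                parcel_data[sl] = label
                slots.append(sl)
    parcellation = LabeledVolume(data=parcel_data, affine=affine, kind="parcellation")
    label_table = default_label_table(spec.n_rois)

    gm_volumes: dict[str, LabeledVolume] = {}
    for record, roi_samples in cohort:
        gm = np.zeros(shape, dtype=np.float64)
        for roi, sl in enumerate(slots):
            gm[sl] = roi_samples.samples[roi].reshape(block)
        gm_volumes[record.subject_id] = LabeledVolume(data=gm, affine=affine, kind="gm_map")
    return gm_volumes, parcellation, label_table, cohort


# ---------------------------------------------------------------------------
# on-disk form


def write_cohort(cohort, outdir) -> None:
    """Write subject metadata TSV plus one long-format sample TSV per subject."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = pd.DataFrame(
        [
            {
                "subject_id": rec.subject_id,
                "updrs_off": rec.updrs_off,
                "updrs_on_peak": rec.updrs_on_peak,
                "lr_percent": rec.lr_percent,
                "group": rec.group,
            }
            for rec, _ in cohort
        ]
    )
    meta.to_csv(outdir / "subjects.tsv", sep="\t", index=False)
    for rec, roi_samples in cohort:
        rows = [
            {"roi_index": roi, "intensity": float(v)}
            for roi in sorted(roi_samples.samples)
            for v in roi_samples.samples[roi]
        ]
        pd.DataFrame(rows).to_csv(outdir / f"{rec.subject_id}_samples.tsv", sep="\t", index=False)


def read_cohort(indir) -> list[tuple[SubjectRecord, ROIIntensitySamples]]:
    from pathlib import Path

    indir = Path(indir)
    meta = pd.read_csv(indir / "subjects.tsv", sep="\t")
    cohort = []
    for _, row in meta.iterrows():
        rec = SubjectRecord(
            subject_id=str(row["subject_id"]),
            updrs_off=float(row["updrs_off"]),
            updrs_on_peak=float(row["updrs_on_peak"]),
            lr_percent=float(row["lr_percent"]),
            group=str(row["group"]),
        )
        df = pd.read_csv(indir / f"{rec.subject_id}_samples.tsv", sep="\t")
        samples = {
            int(roi): np.asarray(sub["intensity"], dtype=np.float64)
            for roi, sub in df.groupby("roi_index")
        }
        cohort.append((rec, ROIIntensitySamples(subject_id=rec.subject_id, samples=samples)))
    return cohort
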