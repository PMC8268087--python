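"""Synthetic ground-truth data generators.

Every downstream stage (contact detection, SLS fitting, orientation
analysis, group statistics) is exercised against data produced here, with
the generating parameters carried along as provenance so tests can close
the loop.

The generators emulate the study conditions: trapezoidal
displacement-controlled indentation (2 um/s to 2 um, 10 s hold, 2 um/s
unload) with a pre-contact baseline, organised as >= 6 indents per structure
per specimen and 3 specimens per group; and fibrous images with a known
axial angular distribution, optionally different per quadrant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .indentation import forward_hereditary_numeric, forward_ramp_hold
from .models import (
    IndentProfile,
    IndentationRecord,
    InvalidSpecError,
    SLSParams,
)

__all__ = [
    "SyntheticIndentSpec",
    "CohortCell",
    "CohortSpec",
    "FiberImageSpec",
    "generate_indent_curve",
    "generate_cohort",
    "generate_fiber_image",
    "ts24_cohort_spec",
]

QUADRANT_LABELS = (
    "cranial-dorsal",
    "cranial-ventral",
    "caudal-dorsal",
    "caudal-ventral",
)


@dataclass(frozen=True)
class SyntheticIndentSpec:
    """Specification for one synthetic indentation curve.

    Noise model: additive i.i.d. Gaussian force noise plus a linear baseline
    drift — the simplest model that exercises contact detection.
    """

    params: SLSParams
    profile: IndentProfile = field(default_factory=IndentProfile)
    tip_radius: float = 42.0
    poisson_ratio: float = 0.5
    baseline_duration: float = 1.0
    noise_sd: float = 0.0
    drift_rate: float = 0.0
    sample_rate: float = 100.0
    include_unload: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise InvalidSpecError("sample_rate must be strictly positive")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be non-negative")
        if self.baseline_duration < 0:
            raise InvalidSpecError("baseline_duration must be non-negative")
        if self.tip_radius <= 0:
            raise InvalidSpecError("tip_radius must be positive")


def generate_indent_curve(spec: SyntheticIndentSpec) -> IndentationRecord:
    """Simulate one ramp-hold indentation curve with known ground truth.

    The record starts with a pre-contact approach segment of
    ``baseline_duration`` seconds (displacement below the surface, force =
    drift + noise), followed by the trapezoidal ramp/hold/unload with force
    from the hereditary-integral SLS model.  Ramp and hold use the
    closed-form solution; the unload segment uses a trapezoid-rule
    hereditary integral over the full depth history.

    The true contact index, generating parameters and profile are stored in
    ``record.metadata["ground_truth"]``.
    """
    profile, params = spec.profile, spec.params
    dt = 1.0 / spec.sample_rate
    n_base = int(round(spec.baseline_duration * spec.sample_rate))
    t_post = profile.t_total if spec.include_unload else profile.t_ramp + profile.t_hold
    n_post = int(np.floor(t_post * spec.sample_rate)) + 1
    t = np.arange(n_base + n_post) * dt
    t_rel = t - n_base * dt  # time since contact

    # displacement command: approach at the ramp speed, then the trapezoid
    h = np.where(t_rel < 0, profile.v_load * t_rel, profile.displacement(t_rel))

    P = np.zeros_like(t)
    post = t_rel >= 0
    t_mh = np.minimum(t_rel[post], profile.t_ramp + profile.t_hold)
    P[post] = forward_ramp_hold(
        profile, params, spec.tip_radius, spec.poisson_ratio, t_mh
    )
    unload = post & (t_rel > profile.t_ramp + profile.t_hold)
    if unload.any():
        P_num = forward_hereditary_numeric(
            t_rel[post], h[post], params, spec.tip_radius, spec.poisson_ratio
        )
        P[unload] = P_num[t_rel[post] > profile.t_ramp + profile.t_hold]

    rng = np.random.default_rng(spec.seed)
    P = P + spec.drift_rate * t
    if spec.noise_sd > 0:
        P = P + spec.noise_sd * rng.standard_normal(t.size)

    return IndentationRecord(
        t=t,
        h=h,
        P=P,
        tip_radius=spec.tip_radius,
        poisson_ratio=spec.poisson_ratio,
        metadata={
            "ground_truth": {
                "contact_index": n_base,
                "E0": params.E0,
                "E1": params.E1,
                "tau1": params.tau1,
                "E_ins": params.E_ins,
                "f": params.f if params.E_ins > 0 else float("nan"),
                "seed": spec.seed,
            }
        },
    )


@dataclass(frozen=True)
class CohortCell:
    """Population parameters for one group x structure cell.

    Means and SDs describe the distribution of per-indent viscoelastic
    properties, split into a between-specimen and a within-specimen
    component (specimen means are drawn first, indent values around them).
    Moduli in kPa; ``tau1`` in seconds is shared (the summary tables print
    no relaxation time, so it is a free simulation choice).
    """

    group: str
    structure: str
    level: str
    mean_E_ins: float
    mean_f: float
    between_sd_E_ins: float = 0.0
    within_sd_E_ins: float = 0.0
    between_sd_f: float = 0.0
    within_sd_f: float = 0.0
    tau1: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "between_sd_E_ins",
            "within_sd_E_ins",
            "between_sd_f",
            "within_sd_f",
        ):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be non-negative")
        if self.mean_E_ins <= 0:
            raise InvalidSpecError("mean_E_ins must be positive")
        if not 0.0 < self.mean_f <= 1.0:
            raise InvalidSpecError("mean_f must lie in (0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Nested design: groups x structures x specimens x indents.

    Defaults follow the study design: 3 specimens per group with at least 6
    indents per structure per specimen.
    """

    cells: tuple[CohortCell, ...]
    stage: str = "TS24"
    n_specimens: int = 3
    n_indents_per_structure: int = 6
    profile: IndentProfile = field(default_factory=IndentProfile)
    tip_radius: float = 42.0
    poisson_ratio: float = 0.5
    baseline_duration: float = 0.5
    noise_sd: float = 0.0
    sample_rate: float = 100.0
    include_unload: bool = False

    def __post_init__(self) -> None:
        if self.n_specimens < 1:
            raise InvalidSpecError("n_specimens must be >= 1")
        if self.n_indents_per_structure < 1:
            raise InvalidSpecError("n_indents_per_structure must be >= 1")


def ts24_cohort_spec(**overrides) -> CohortSpec:
    """Cohort spec with the TS24 summary-table group means and SDs.

    The printed per-cell SDs pool specimen and indent variability; here two
    thirds of the variance is assigned between specimens and one third
    within, a typical split for technical replicates nested in biological
    ones.
    """
    table = [
        # group, structure, level, E_ins, sd_E, f, sd_f
        ("control", "VB", "C5", 29.0, 7.3, 0.78, 0.046),
        ("mdg", "VB", "C5", 30.0, 15.0, 0.74, 0.055),
        ("control", "VB", "C6", 29.0, 14.0, 0.78, 0.024),
        ("mdg", "VB", "C6", 27.0, 9.5, 0.77, 0.069),
        ("control", "AF", "C5-C6", 24.0, 4.9, 0.74, 0.042),
        ("mdg", "AF", "C5-C6", 37.0, 21.0, 0.67, 0.076),
    ]
    cells = tuple(
        CohortCell(
            group=g,
            structure=s,
            level=lv,
            mean_E_ins=e,
            mean_f=f,
            between_sd_E_ins=np.sqrt(2.0 / 3.0) * sd_e,
            within_sd_E_ins=np.sqrt(1.0 / 3.0) * sd_e,
            between_sd_f=np.sqrt(2.0 / 3.0) * sd_f,
            within_sd_f=np.sqrt(1.0 / 3.0) * sd_f,
        )
        for g, s, lv, e, sd_e, f, sd_f in table
    )
    return CohortSpec(cells=cells, stage="TS24", **overrides)


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> list[IndentationRecord]:
    """Simulate a nested cohort of indentation records.

    Specimen-level (E_ins, f) pairs are drawn from the between-specimen
    distribution, indent-level values around each specimen mean from the
    within-specimen distribution; E_ins is truncated to stay positive and f
    clipped to (0, 1].  Every record's metadata carries group, specimen ID,
    structure, level and stage, so the nested structure is conserved.
    """
    rng = np.random.default_rng(seed)
    records: list[IndentationRecord] = []
    for cell in spec.cells:
        for i_spec in range(spec.n_specimens):
            specimen_id = f"{cell.group}-{spec.stage}-{i_spec + 1}"
            spec_E = max(
                rng.normal(cell.mean_E_ins, cell.between_sd_E_ins), 0.1 * cell.mean_E_ins
            )
            spec_f = float(np.clip(rng.normal(cell.mean_f, cell.between_sd_f), 0.01, 1.0))
            for i_ind in range(spec.n_indents_per_structure):
                E_ins = max(
                    rng.normal(spec_E, cell.within_sd_E_ins), 0.05 * cell.mean_E_ins
                )
                f = float(np.clip(rng.normal(spec_f, cell.within_sd_f), 0.01, 1.0))
                params = SLSParams.from_moduli(E_ins, f, cell.tau1)
                curve_seed = int(rng.integers(0, 2**31 - 1))
                record = generate_indent_curve(
                    SyntheticIndentSpec(
                        params=params,
                        profile=spec.profile,
                        tip_radius=spec.tip_radius,
                        poisson_ratio=spec.poisson_ratio,
                        baseline_duration=spec.baseline_duration,
                        noise_sd=spec.noise_sd,
                        sample_rate=spec.sample_rate,
                        include_unload=spec.include_unload,
                        seed=curve_seed,
                    )
                )
                record.metadata.update(
                    group=cell.group,
                    specimen=specimen_id,
                    structure=cell.structure,
                    level=cell.level,
                    stage=spec.stage,
                    indent=i_ind + 1,
                )
                records.append(record)
    return records


@dataclass(frozen=True)
class FiberImageSpec:
    """Specification for a fibrous phantom image.

    Angles are axial (defined modulo 180 deg) and measured counter-clockwise
    from the image x-axis (the dorsoventral axis in the study's framing).
    Per-quadrant overrides confine fibre centres to each quadrant with that
    quadrant's angular distribution.
    """

    width: int = 512
    height: int = 512
    n_fibers: int = 200
    angle_mean: float = 90.0
    angle_sd: float = 5.0
    fiber_width: float = 3.0
    fiber_length: float | None = None
    fiber_intensity: float = 1.0
    background_intensity: float = 0.0
    noise_sd: float = 0.0
    quadrant_angles: dict[str, tuple[float, float]] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 64:
            raise InvalidSpecError("image dimensions must be >= 64 px")
        if self.n_fibers < 0 or self.noise_sd < 0 or self.fiber_width <= 0:
            raise InvalidSpecError("invalid fibre image parameters")
        if self.quadrant_angles is not None:
            unknown = set(self.quadrant_angles) - set(QUADRANT_LABELS)
            if unknown:
                raise InvalidSpecError(f"unknown quadrant labels: {sorted(unknown)}")


def _draw_axial_angles(
    rng: np.random.Generator, n: int, mean: float, sd: float
) -> np.ndarray:
    """Wrapped normal on the axial scale: double, wrap to 360, halve."""
    doubled = rng.normal(2.0 * mean, 2.0 * sd, size=n) % 360.0
    return doubled / 2.0


def _render_fiber(
    image: np.ndarray,
    cy: float,
    cx: float,
    angle_deg: float,
    length: float,
    sigma: float,
    intensity: float,
) -> None:
    """Add one anti-aliased fibre with Gaussian cross-section in place.

    Angle is CCW from the x-axis with y pointing up, so the direction in
    array (row, col) coordinates is (-sin a, cos a).
    """
    a = np.radians(angle_deg)
    d = np.array([-np.sin(a), np.cos(a)])  # (row, col)
    half = 0.5 * length
    p0 = np.array([cy, cx]) - half * d
    p1 = np.array([cy, cx]) + half * d
    margin = 3.0 * sigma + 1.0
    r0 = int(max(np.floor(min(p0[0], p1[0]) - margin), 0))
    r1 = int(min(np.ceil(max(p0[0], p1[0]) + margin), image.shape[0] - 1))
    c0 = int(max(np.floor(min(p0[1], p1[1]) - margin), 0))
    c1 = int(min(np.ceil(max(p0[1], p1[1]) + margin), image.shape[1] - 1))
    if r1 < r0 or c1 < c0:
        return
    rr, cc = np.meshgrid(
        np.arange(r0, r1 + 1, dtype=float),
        np.arange(c0, c1 + 1, dtype=float),
        indexing="ij",
    )
    # point-to-segment distance
    seg = p1 - p0
    seg_len2 = float(seg @ seg)
    wr, wc = rr - p0[0], cc - p0[1]
    tproj = np.clip((wr * seg[0] + wc * seg[1]) / seg_len2, 0.0, 1.0)
    dr = wr - tproj * seg[0]
    dc = wc - tproj * seg[1]
    dist2 = dr**2 + dc**2
    image[r0 : r1 + 1, c0 : c1 + 1] += intensity * np.exp(-dist2 / (2.0 * sigma**2))


@dataclass
class FiberPhantom:
    """A rendered phantom image plus its ground-truth fibre angles."""

    image: np.ndarray
    angles: np.ndarray
    angles_by_quadrant: dict[str, np.ndarray] | None = None


def generate_fiber_image(spec: FiberImageSpec) -> FiberPhantom:
    """Render a grayscale fibrous phantom with known axial orientations.

    Fibres are straight anti-aliased segments with a Gaussian cross-section
    (sigma = fiber_width / 2), centres uniform over the image (or over each
    quadrant when per-quadrant distributions are given), angles drawn from a
    wrapped normal on the axial scale.  Gaussian background noise is added
    last.  Returns the image together with the drawn angles.
    """
    rng = np.random.default_rng(spec.seed)
    image = np.full((spec.height, spec.width), spec.background_intensity, dtype=float)
    sigma = spec.fiber_width / 2.0

    if spec.n_fibers == 0 and spec.fiber_intensity > 0:
        warnings.warn("n_fibers=0: returning a pure-background image", stacklevel=2)

    def _fill(region_rows, region_cols, n, mean, sd):
        length = spec.fiber_length or 0.5 * min(
            region_rows[1] - region_rows[0], region_cols[1] - region_cols[0]
        )
        angles = _draw_axial_angles(rng, n, mean, sd)
        cy = rng.uniform(region_rows[0], region_rows[1], size=n)
        cx = rng.uniform(region_cols[0], region_cols[1], size=n)
        for yy, xx, aa in zip(cy, cx, angles):
            _render_fiber(image, yy, xx, aa, length, sigma, spec.fiber_intensity)
        return angles

    if spec.quadrant_angles is None:
        angles = _fill((0, spec.height), (0, spec.width), spec.n_fibers,
                       spec.angle_mean, spec.angle_sd)
        by_quadrant = None
    else:
        # cranial = top rows, dorsal = left columns (default axis convention)
        rmid, cmid = spec.height // 2, spec.width // 2
        regions = {
            "cranial-dorsal": ((0, rmid), (0, cmid)),
            "cranial-ventral": ((0, rmid), (cmid, spec.width)),
            "caudal-dorsal": ((rmid, spec.height), (0, cmid)),
            "caudal-ventral": ((rmid, spec.height), (cmid, spec.width)),
        }
        n_per = spec.n_fibers // 4
        by_quadrant = {}
        for label, (rows, cols) in regions.items():
            mean, sd = spec.quadrant_angles.get(label, (spec.angle_mean, spec.angle_sd))
            by_quadrant[label] = _fill(rows, cols, n_per, mean, sd)
        angles = np.concatenate(list(by_quadrant.values()))

    if spec.noise_sd > 0:
        image = image + spec.noise_sd * rng.standard_normal(image.shape)
        image = np.clip(image, 0.0, None)

    return FiberPhantom(image=image, angles=angles, angles_by_quadrant=by_quadrant)
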