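"""Synthetic phantom plans emulating a three-group boost-comparison cohort.

No patient data ship with the package; this module generates idealised but
dosimetrically faithful stand-ins:

* an ellipsoidal pelvic phantom with boost target (CTV + 5 mm margin for the
  intracavitary boost, CTV + 7-10 mm for the external-beam boost), pelvic
  PTV, rectum wall, bladder wall, bowel, femoral heads and spinal cord;
* a four-field-box pelvic dose (near-uniform inside the field intersection,
  erf penumbra, bony-landmark field borders that cover the whole rectum);
* an intracavitary boost dose from an inverse-square source kernel on a
  tandem-plus-ovoids source arrangement, normalised at a point-A-like
  prescription point 20 mm lateral of the tandem;
* a conformal external-beam boost dose (homogeneous inside the target,
  exponential lateral falloff).

Geometry is deliberately simple — only DVH-level statistics feed the
downstream comparisons — but target/OAR volumes are sampled to land in the
ranges of the emulated cohort (intracavitary boost ~12-88 cm^3, external-beam
boost larger by construction of its margin).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .fractionation import (
    PDR_HDR_EQUIVALENTS,
    TUMOUR,
    FractionationScheme,
    bed_fractionated,
    isoeffective_fractions,
)
from .grids import DoseGrid, StructureMask

__all__ = [
    "PhantomSpec",
    "SourceSet",
    "Phantom",
    "PatientPlan",
    "Cohort",
    "generate_phantom",
    "dose_box_ebrt",
    "dose_brachy",
    "dose_conformal_imrt",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic patient geometry.

    Distances in mm.  The intracavitary boost margin is fixed at 5 mm; the
    external-beam boost margin is sampled uniformly from ``margin_imrt``.
    Identical seeds produce identical phantoms.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (5.0, 5.0, 5.0)
    seed: int = 0
    ctv_radii_mean: tuple[float, float, float] = (16.0, 18.5, 13.0)
    ctv_radii_rel_sd: float = 0.12
    margin_icbrt: float = 5.0
    margin_imrt: tuple[float, float] = (7.0, 10.0)
    pelvis_radii_mean: tuple[float, float, float] = (75.0, 56.0, 66.0)
    pelvis_radii_rel_sd: float = 0.05
    rectum_outer_radius: float = 15.0
    rectum_wall_thickness: float = 4.0
    rectum_length: float = 80.0
    rectum_gap: tuple[float, float] = (1.0, 6.0)
    bladder_outer_radius: float = 28.0
    bladder_wall_thickness: float = 3.5
    bladder_gap: tuple[float, float] = (2.0, 5.0)
    packing_displacement: tuple[float, ...] = (5.0, 10.0)
    tandem_length: float = 60.0
    tandem_step: float = 5.0
    ovoid_offset: float = 18.0
    ovoid_weight: float = 3.0


@dataclass(frozen=True)
class SourceSet:
    """Point sources with an inverse-square kernel.

    ``positions`` are (N, 3) mm coordinates, ``weights`` relative strengths.
    ``attenuation_per_mm`` optionally multiplies the kernel by
    ``exp(-mu_att r)``.
    """

    positions: np.ndarray
    weights: np.ndarray
    attenuation_per_mm: float | None = None

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        w = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if pos.shape[0] < 1 or pos.shape[1] != 3 or w.shape[0] != pos.shape[0]:
            raise ValueError("need >= 1 source position with one weight each")
        if np.any(w <= 0):
            raise ValueError("source weights must be > 0")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "weights", w)

    def dose_at(self, points: np.ndarray) -> np.ndarray:
        """Unnormalised kernel sum(w / r^2) at arbitrary points (shape (..., 3))."""
        pts = np.asarray(points, dtype=float)
        flat = pts.reshape(-1, 3)
        out = np.zeros(flat.shape[0])
        for p, w in zip(self.positions, self.weights):
            r2 = np.sum((flat - p) ** 2, axis=1)
            r2 = np.maximum(r2, 1e-12)
            term = w / r2
            if self.attenuation_per_mm is not None:
                term = term * np.exp(-self.attenuation_per_mm * np.sqrt(r2))
            out += term
        return out.reshape(pts.shape[:-1])


@dataclass(frozen=True)
class Phantom:
    """A generated geometry: masks, source arrangement and reference points.

    ``brachy_masks`` holds the rectum/bladder walls as they sit during the
    intracavitary session, displaced away from the sources by vaginal packing
    and the Foley balloon; displacements are whole-voxel so each displaced
    structure keeps exactly its natural volume.
    """

    spec: PhantomSpec
    masks: dict[str, StructureMask]
    brachy_masks: dict[str, StructureMask]
    sources: SourceSet
    prescription_point: tuple[float, float, float]
    sampled: dict[str, float] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.spec.shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.spec.spacing

    def voxel_centres(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        axes = [
            (np.arange(n) + 0.5) * s - n * s / 2.0
            for n, s in zip(self.spec.shape, self.spec.spacing)
        ]
        return np.meshgrid(*axes, indexing="ij")

    def empty_grid(self, values: np.ndarray) -> DoseGrid:
        return DoseGrid(values, self.spec.spacing)


def _axes(spec: PhantomSpec):
    return [
        (np.arange(n) + 0.5) * s - n * s / 2.0
        for n, s in zip(spec.shape, spec.spacing)
    ]


def _ellipsoid(coords, centre, radii) -> np.ndarray:
    x, y, z = coords
    cx, cy, cz = centre
    rx, ry, rz = radii
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


def _tube_z(coords, centre, outer_r, inner_r, length) -> np.ndarray:
    x, y, z = coords
    cx, cy, cz = centre
    r2 = (x - cx) ** 2 + (y - cy) ** 2
    in_len = np.abs(z - cz) <= length / 2.0
    return (r2 <= outer_r**2) & (r2 > inner_r**2) & in_len


def _shell(coords, centre, outer_r, inner_r) -> np.ndarray:
    x, y, z = coords
    cx, cy, cz = centre
    r2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
    return (r2 <= outer_r**2) & (r2 > inner_r**2)


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Build one seeded phantom geometry.

    Axis convention: +y is posterior (rectum side), -y anterior (bladder),
    +z superior.  The boost CTV is centred at the origin; the tandem runs
    superiorly from the vault (inferior CTV pole).
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    extent = [n * s / 2.0 for n, s in zip(spec.shape, spec.spacing)]

    def jitter(mean, rel_sd):
        z = float(np.clip(rng.normal(), -2.0, 2.0))
        return mean * (1.0 + rel_sd * z)

    ctv = tuple(jitter(m, spec.ctv_radii_rel_sd) for m in spec.ctv_radii_mean)
    m_imrt = float(rng.uniform(*spec.margin_imrt))
    icbrt_radii = tuple(r + spec.margin_icbrt for r in ctv)
    imrt_radii = tuple(r + m_imrt for r in ctv)

    gap_r = float(rng.uniform(*spec.rectum_gap))
    rect_outer = jitter(spec.rectum_outer_radius, 0.1)
    rect_front = imrt_radii[1] + gap_r
    rect_centre_y = rect_front + rect_outer

    gap_b = float(rng.uniform(*spec.bladder_gap))
    bl_outer = jitter(spec.bladder_outer_radius, 0.1)
    bl_centre_y = -(imrt_radii[1] + gap_b + bl_outer)

    # packing/Foley displacement during the intracavitary session, snapped to
    # whole voxels so the displaced masks keep exactly their natural volumes
    dy = spec.spacing[1]
    disp_r = dy * round(float(rng.choice(spec.packing_displacement)) / dy)
    disp_b = dy * round(float(rng.choice(spec.packing_displacement)) / dy)

    pelvis_radii = tuple(jitter(m, spec.pelvis_radii_rel_sd) for m in spec.pelvis_radii_mean)
    # posterior PTV border just reaches the anterior rectal wall (2 mm overlap)
    pelvis_centre_y = (rect_front + 2.0) - pelvis_radii[1]

    for label, reach in [
        ("pelvis-x", pelvis_radii[0]),
        ("pelvis-y", abs(pelvis_centre_y) + pelvis_radii[1]),
        ("pelvis-z", pelvis_radii[2]),
        ("rectum-y", rect_centre_y + disp_r + rect_outer),
        ("bladder-y", abs(bl_centre_y) + disp_b + bl_outer),
    ]:
        axis = {"x": 0, "y": 1, "z": 2}[label.split("-")[1]]
        if reach > extent[axis]:
            raise GeometryError(
                f"structure extent {label} = {reach:.1f} mm exceeds half-grid "
                f"{extent[axis]:.1f} mm; enlarge the grid"
            )

    coords = np.meshgrid(*_axes(spec), indexing="ij")
    masks = {
        "PTV_pelvis": _ellipsoid(coords, (0.0, pelvis_centre_y, 0.0), pelvis_radii),
        "BOOST_ICBRT": _ellipsoid(coords, (0.0, 0.0, 0.0), icbrt_radii),
        "BOOST_IMRT": _ellipsoid(coords, (0.0, 0.0, 0.0), imrt_radii),
        "rectum_wall": _tube_z(
            coords,
            (0.0, rect_centre_y, 0.0),
            rect_outer,
            rect_outer - spec.rectum_wall_thickness,
            spec.rectum_length,
        ),
        "bladder_wall": _shell(
            coords, (0.0, bl_centre_y, -5.0), bl_outer, bl_outer - spec.bladder_wall_thickness
        ),
        # bowel loops sit superiorly, clear of the tandem tip
        "bowel": _ellipsoid(coords, (0.0, -15.0, 95.0), (70.0, 45.0, 20.0)),
        "femoral_heads": (
            _ellipsoid(coords, (78.0, 0.0, -10.0), (21.0, 21.0, 21.0))
            | _ellipsoid(coords, (-78.0, 0.0, -10.0), (21.0, 21.0, 21.0))
        ),
        "spinal_cord": _tube_z(coords, (0.0, 70.0, 70.0), 6.0, 0.0, 95.0),
    }
    brachy_masks = {
        "rectum_wall": _tube_z(
            coords,
            (0.0, rect_centre_y + disp_r, 0.0),
            rect_outer,
            rect_outer - spec.rectum_wall_thickness,
            spec.rectum_length,
        ),
        "bladder_wall": _shell(
            coords,
            (0.0, bl_centre_y - disp_b, -5.0),
            bl_outer,
            bl_outer - spec.bladder_wall_thickness,
        ),
    }
    for name, arr in {**masks, **brachy_masks}.items():
        if not arr.any():
            raise GeometryError(f"structure {name!r} is empty on this grid")
    for name in brachy_masks:
        if brachy_masks[name].sum() != masks[name].sum():
            raise GeometryError(
                f"displaced {name!r} was clipped by the grid; enlarge the grid"
            )

    vault_z = -ctv[2]
    n_dwell = int(spec.tandem_length / spec.tandem_step) + 1
    dwell_z = vault_z + np.arange(n_dwell) * spec.tandem_step
    tandem = np.column_stack([np.zeros(n_dwell), np.zeros(n_dwell), dwell_z])
    ovoids = np.array(
        [[spec.ovoid_offset, 0.0, vault_z], [-spec.ovoid_offset, 0.0, vault_z]]
    )
    sources = SourceSet(
        positions=np.vstack([tandem, ovoids]),
        weights=np.concatenate([np.ones(n_dwell), np.full(2, spec.ovoid_weight)]),
    )
    prescription_point = (20.0, 0.0, vault_z + 20.0)

    return Phantom(
        spec=spec,
        masks={name: StructureMask(name, arr) for name, arr in masks.items()},
        brachy_masks={name: StructureMask(name, arr) for name, arr in brachy_masks.items()},
        sources=sources,
        prescription_point=prescription_point,
        sampled={
            "ctv_rx": ctv[0],
            "ctv_ry": ctv[1],
            "ctv_rz": ctv[2],
            "margin_imrt": m_imrt,
            "rectum_gap": gap_r,
            "bladder_gap": gap_b,
            "packing_rectum": disp_r,
            "packing_bladder": disp_b,
        },
    )


def _smooth_ripple(shape, spacing, rng, amplitude, wavelength_mm=80.0) -> np.ndarray:
    """Deterministic low-frequency multiplicative ripple in [1-a, 1+a]."""
    axes = [
        (np.arange(n) + 0.5) * s - n * s / 2.0 for n, s in zip(shape, spacing)
    ]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    k = 2.0 * np.pi / wavelength_mm
    p = rng.uniform(0, 2 * np.pi, size=3)
    return 1.0 + amplitude * np.cos(k * x + p[0]) * np.cos(k * y + p[1]) * np.cos(k * z + p[2])


def dose_box_ebrt(
    phantom: Phantom,
    prescription: float = 45.0,
    ripple: float = 0.025,
    penumbra_mm: float = 6.0,
    field_margin_mm: tuple[tuple[float, float], ...] = ((18.0, 18.0), (18.0, 35.0), (18.0, 18.0)),
) -> DoseGrid:
    """Four-field-box pelvic dose: flat inside the field intersection.

    Field borders follow the pelvic PTV bounding box plus bony-landmark
    margins (larger posteriorly so the whole rectum sits in-field, as a box
    technique does); each axis profile has an erf penumbra of width
    ``penumbra_mm`` (sigma).
    """
    from scipy.special import erf

    spec = phantom.spec
    ptv = phantom.masks["PTV_pelvis"].voxels
    coords = phantom.voxel_centres()
    profiles = np.ones(spec.shape)
    for axis in range(3):
        c = coords[axis]
        proj = np.any(ptv, axis=tuple(a for a in range(3) if a != axis))
        ax_coords = _axes(spec)[axis]
        lo = ax_coords[proj].min() - field_margin_mm[axis][0]
        hi = ax_coords[proj].max() + field_margin_mm[axis][1]
        s = penumbra_mm * np.sqrt(2.0)
        profiles = profiles * 0.5 * (erf((c - lo) / s) - erf((c - hi) / s))
    profiles /= profiles.max()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    dose = prescription * profiles * _smooth_ripple(spec.shape, spec.spacing, rng, ripple)
    return phantom.empty_grid(np.clip(dose, 0.0, None))


def dose_brachy(
    phantom: Phantom,
    prescription: float,
    sources: SourceSet | None = None,
    cap_factor: float = 10.0,
) -> DoseGrid:
    """Inverse-square source-kernel boost dose.

    Normalised so the phantom's prescription point (20 mm lateral of the
    tandem at the point-A level) receives ``prescription`` Gy; voxels at the
    sources are capped at ``cap_factor`` x prescription.
    """
    if prescription <= 0:
        raise ValueError(f"prescription must be > 0, got {prescription}")
    src = sources if sources is not None else phantom.sources
    x, y, z = phantom.voxel_centres()
    pts = np.stack([x, y, z], axis=-1)
    raw = src.dose_at(pts)
    ref = float(src.dose_at(np.asarray(phantom.prescription_point)))
    dose = prescription * raw / ref
    return phantom.empty_grid(np.clip(dose, 0.0, cap_factor * prescription))


def dose_conformal_imrt(
    phantom: Phantom,
    target: StructureMask | str,
    prescription: float,
    falloff_mm: float = 8.0,
    homogeneity: float = 0.03,
    penumbra_offset_mm: float = 2.5,
) -> DoseGrid:
    """Conformal external-beam boost dose.

    Inside the target the dose sits in ``[prescription,
    prescription (1 + homogeneity)]`` with a smooth seeded ripple; outside it
    decays exponentially with distance to the target surface, the prescription
    isodose sitting ``penumbra_offset_mm`` outside the target (the small
    block margin a planning system produces).  ``falloff_mm -> 0`` with zero
    offset makes the prescription isodose coincide with the target.
    """
    from scipy.ndimage import distance_transform_edt

    if isinstance(target, str):
        target = phantom.masks[target]
    target.check_congruent(phantom.empty_grid(np.zeros(phantom.shape)))
    spec = phantom.spec
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 202, target.voxel_count()]))
    ripple = _smooth_ripple(spec.shape, spec.spacing, rng, 1.0)  # in [0, 2]
    inside = prescription * (1.0 + homogeneity * 0.5 * ripple)
    # centre-to-centre EDT overestimates distance to the target *surface* by
    # about half a voxel; correct the bias so the falloff is grid-independent
    half_voxel = 0.5 * float(np.mean(spec.spacing))
    dist = distance_transform_edt(~target.voxels, sampling=spec.spacing)
    dist = np.maximum(dist - half_voxel, 0.0)
    decay = np.exp(-np.maximum(dist - penumbra_offset_mm, 0.0) / max(falloff_mm, 1e-9))
    dose = np.where(target.voxels, inside, prescription * decay)
    return phantom.empty_grid(dose)


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class PatientPlan:
    """One synthetic patient: geometry, dose grids and assigned regimens."""

    patient_id: int
    group: str  # "I" (postop HDR), "II" (postop PDR), "III" (radical PDR)
    seed: int
    phantom: Phantom
    grids: dict[str, DoseGrid]
    schemes: dict[str, FractionationScheme]
    clonogen_density: float


@dataclass(frozen=True)
class Cohort:
    seed: int
    patients: list[PatientPlan]

    def __len__(self) -> int:
        return len(self.patients)


def _assign_groups(n_patients: int, group_mix: tuple[float, float, float]) -> list[str]:
    mix = np.asarray(group_mix, dtype=float)
    mix = mix / mix.sum()
    counts = np.floor(mix * n_patients).astype(int)
    order = np.argsort(-(mix * n_patients - counts))
    for i in range(n_patients - counts.sum()):
        counts[order[i % 3]] += 1
    labels = ["I", "II", "III"]
    out: list[str] = []
    for label, c in zip(labels, counts):
        out.extend([label] * int(c))
    return out


def generate_cohort(
    n_patients: int = 15,
    seed: int = 0,
    group_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    pelvis_prescription: float = 45.0,
    pelvis_fractions: int = 25,
    spec_kwargs: dict | None = None,
) -> Cohort:
    """Generate a reproducible cohort of phantom plans.

    Groups: I = postoperative HDR boost 5 Gy x 3; II = postoperative PDR
    15 Gy (0.5 Gy pulses, hourly); III = radical PDR 15 or 30 Gy
    (alternating).  Clonogen density is 1e5 /cm^3 for postoperative and
    1e7 /cm^3 for radical patients.  The external-beam boost regimen is the
    smallest 1.8 Gy/fraction schedule matching the intracavitary boost BED
    (tumour alpha/beta = 10 Gy).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    groups = _assign_groups(n_patients, group_mix)
    child_seeds = [int(s) for s in np.random.SeedSequence(seed).generate_state(n_patients) % (2**31)]
    pelvis_scheme = FractionationScheme.ebrt(pelvis_prescription / pelvis_fractions, pelvis_fractions)

    patients: list[PatientPlan] = []
    n_group3 = 0
    for pid, (group, pseed) in enumerate(zip(groups, child_seeds)):
        phantom = generate_phantom(PhantomSpec(seed=pseed, **(spec_kwargs or {})))
        if group == "I":
            icbrt = FractionationScheme.hdr(5.0, 3)
            icbrt_eq = icbrt
            density = 1e5
        elif group == "II":
            icbrt = FractionationScheme.pdr(0.5, 30, 1.0)
            icbrt_eq = PDR_HDR_EQUIVALENTS[15.0]
            density = 1e5
        else:
            total = 15.0 if n_group3 % 2 == 0 else 30.0
            n_group3 += 1
            icbrt = FractionationScheme.pdr(0.5, int(total / 0.5), 1.0)
            icbrt_eq = PDR_HDR_EQUIVALENTS[total]
            density = 1e7
        target_bed = bed_fractionated(icbrt_eq, TUMOUR)
        n_fx = isoeffective_fractions(target_bed, 1.8, TUMOUR).n_fractions
        imrt_boost_scheme = FractionationScheme.ebrt(1.8, n_fx)

        grids = {
            "pelvis_3dcrt": dose_box_ebrt(phantom, pelvis_prescription),
            "pelvis_imrt": dose_conformal_imrt(
                phantom, "PTV_pelvis", pelvis_prescription, falloff_mm=10.0
            ),
            "boost_icbrt": dose_brachy(phantom, icbrt.total_dose),
            "boost_imrt": dose_conformal_imrt(
                phantom, "BOOST_IMRT", imrt_boost_scheme.total_dose
            ),
        }
        patients.append(
            PatientPlan(
                patient_id=pid,
                group=group,
                seed=pseed,
                phantom=phantom,
                grids=grids,
                schemes={
                    "pelvis": pelvis_scheme,
                    "icbrt": icbrt,
                    "icbrt_eq": icbrt_eq,
                    "imrt_boost": imrt_boost_scheme,
                },
                clonogen_density=density,
            )
        )
    return Cohort(seed=seed, patients=patients)


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write a cohort manifest (YAML) and per-structure DVH CSVs."""
    from pathlib import Path

    import yaml

    from .dvh import compute_dvh, write_dvh_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"cohort_seed": cohort.seed, "patients": []}
    for p in cohort.patients:
        entry = {
            "patient_id": p.patient_id,
            "group": p.group,
            "seed": p.seed,
            "clonogen_density_per_cm3": p.clonogen_density,
            "regimens": {k: s.describe() for k, s in p.schemes.items()},
        }
        manifest["patients"].append(entry)
        pdir = out / f"patient_{p.patient_id:02d}"
        pdir.mkdir(exist_ok=True)
        for plan_name, grid in p.grids.items():
            for struct_name, mask in p.phantom.masks.items():
                dvh = compute_dvh(grid, mask)
                write_dvh_csv(dvh, pdir / f"{plan_name}__{struct_name}.csv")
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
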