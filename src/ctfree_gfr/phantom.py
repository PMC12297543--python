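"""Digital torso phantom for quantitative kidney SPECT.

Generates clinical-like cases — attenuation map, DTPA activity distribution,
kidney labels and two-energy-window SPECT surrogates — so the whole
u-map-generation / segmentation / quantification pipeline can be exercised and
validated without patient data.

The torso is an ellipsoidal cylinder of soft tissue containing partial lung
bases, a spine column, and two bean-shaped kidneys wrapped in a perirenal fat
capsule; attenuation values come from a configurable narrow-beam tissue table
at 140 keV.  Case categories mirror a renal SPECT/CT referral population:
normal (kidney donor), renal tumor (cold nodule), urinary stone (dense calculus),
post partial nephrectomy (truncated pole) and post total nephrectomy (absent
kidney).  Image degradation is a deliberately simple post-reconstruction model:
depth-dependent attenuation along a fixed anterior axis, Gaussian system blur,
and Poisson counting noise in two windows, plus an idealized quantitative
volume calibrated in MBq/mL.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import LEFT_KIDNEY, RIGHT_KIDNEY, LabelMap, Volume3D

__all__ = [
    "TissueTable",
    "PhantomSpec",
    "PhantomCase",
    "REFERRAL_POPULATION_MIX",
    "generate_case",
    "degrade_to_spect",
    "sample_population",
]

CATEGORIES = (
    "normal",
    "renal_tumor",
    "urinary_stone",
    "post_partial_nephrectomy",
    "post_total_nephrectomy",
)

#: Referral mix of the 1000-case development population (Others excluded):
#: normal 10, renal tumor 307, urinary stone 151, post partial 516, post total 8.
REFERRAL_POPULATION_MIX = {
    "normal": 10 / 992,
    "renal_tumor": 307 / 992,
    "urinary_stone": 151 / 992,
    "post_partial_nephrectomy": 516 / 992,
    "post_total_nephrectomy": 8 / 992,
}

#: Right : Left : Both side counts per category from the same population.
_SIDE_COUNTS = {
    "normal": {"both": 1.0},
    "renal_tumor": {"right": 151, "left": 151, "both": 5},
    "urinary_stone": {"right": 47, "left": 55, "both": 49},
    "post_partial_nephrectomy": {"right": 261, "left": 244, "both": 11},
    "post_total_nephrectomy": {"right": 6, "left": 2},
}


@dataclass(frozen=True)
class TissueTable:
    """Linear attenuation coefficients (cm^-1) at 140 keV, narrow beam.

    Kidney parenchyma sits slightly above generic soft tissue (denser, blood
    rich) and the perirenal fat capsule below it — the contrast a CT-derived
    u-map actually shows at the kidney boundary, and what makes the organ
    segmentable from attenuation alone.
    """

    air: float = 0.0
    lung: float = 0.04
    fat: float = 0.135
    soft_tissue: float = 0.15
    kidney: float = 0.162
    spine: float = 0.25
    stone: float = 0.45  # calcified calculus; stays under the 0.5 windowing ceiling

    def values(self) -> tuple[float, ...]:
        return tuple(getattr(self, f.name) for f in dataclasses.fields(self))


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic case; identical spec + seed => identical case.

    Fractions are of the injected activity: each kidney's uptake fraction is
    drawn from ``kidney_uptake_fraction_range`` (0.04 = 4 %ID, a normal single
    kidney 2-3 min after Tc-99m DTPA injection) and
    ``background_uptake_fraction`` is spread over non-renal soft tissue
    (circulating tracer).  ``counts_scale`` converts MBq/mL to expected counts
    per voxel and thereby sets the Poisson noise level.
    """

    grid_shape: tuple[int, int, int] = (64, 128, 128)
    voxel_size_mm: float = 3.45
    category: str = "normal"
    side: str = "both"
    kidney_volume_ml_range: tuple[float, float] = (120.0, 200.0)
    injected_activity_MBq: float = 370.0
    kidney_uptake_fraction_range: tuple[float, float] = (0.025, 0.05)
    background_uptake_fraction: float = 0.25
    psf_fwhm_mm: float = 12.0
    counts_scale: float = 2000.0
    seed: int = 0
    mu_table: TissueTable = field(default_factory=TissueTable)
    smoothing_sigma_vox: float = 0.6

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.side not in ("right", "left", "both"):
            raise ValueError(f"unknown side {self.side!r}")
        if self.category == "post_total_nephrectomy" and self.side == "both":
            raise ValueError("post total nephrectomy requires side 'right' or 'left'")
        if any(n < 16 for n in self.grid_shape):
            raise ValueError("grid_shape axes must all be >= 16")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        lo, hi = self.kidney_uptake_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("kidney uptake fractions must lie in [0, 1]")
        if not 0 <= self.background_uptake_fraction <= 1:
            raise ValueError("background_uptake_fraction must lie in [0, 1]")
        if 2 * hi + self.background_uptake_fraction > 1:
            raise ValueError("uptake fractions must sum to at most 1")
        if self.counts_scale < 0:
            raise ValueError("counts_scale must be >= 0")
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be >= 0")

    @classmethod
    def desk(cls, **overrides) -> "PhantomSpec":
        """Small-grid profile: 32x48x48 at 6.9 mm voxels (same torso coverage)."""
        defaults = dict(grid_shape=(32, 48, 48), voxel_size_mm=6.9)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class PhantomCase:
    """One generated case with its ground truth.

    ``true_pct_id`` maps kidney class (1 right, 2 left) to the ground-truth
    %ID recorded from the activity map before any degradation; absent kidneys
    are missing from the dict.
    """

    mu_map: Volume3D
    activity: Volume3D
    labels: LabelMap
    primary_spect: Volume3D
    scatter_spect: Volume3D
    quantitative_spect: Volume3D
    injected_activity_MBq: float
    true_pct_id: dict[int, float]
    category: str
    side: str
    seed: int


def _ellipsoid(zz, yy, xx, center, semi) -> np.ndarray:
    cz, cy, cx = center
    az, ay, ax = semi
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _kidney_mask(zz, yy, xx, center, semi, medial_sign: float) -> np.ndarray:
    """Bean shape: two overlapping lobes minus a medial hilum notch."""
    az, ay, ax = semi
    cz, cy, cx = center
    upper = _ellipsoid(zz, yy, xx, (cz - 0.30 * az, cy, cx), (0.80 * az, ay, ax))
    lower = _ellipsoid(zz, yy, xx, (cz + 0.30 * az, cy, cx), (0.80 * az, ay, ax))
    mask = upper | lower
    notch = _ellipsoid(
        zz, yy, xx,
        (cz, cy, cx + medial_sign * 0.95 * ax),
        (0.45 * az, 0.55 * ay, 0.55 * ax),
    )
    return mask & ~notch


def generate_case(spec: PhantomSpec) -> PhantomCase:
    """Generate one synthetic case from a validated spec.

    Raises if the grid is too small for the requested kidneys to materialize.
    """
    ss = np.random.SeedSequence(spec.seed)
    geom_ss, noise_ss = ss.spawn(2)
    rng = np.random.default_rng(geom_ss)
    noise_seed = int(noise_ss.generate_state(1)[0])

    d, h, w = spec.grid_shape
    vs = spec.voxel_size_mm
    zz, yy, xx = np.meshgrid(
        np.arange(d, dtype=np.float64),
        np.arange(h, dtype=np.float64),
        np.arange(w, dtype=np.float64),
        indexing="ij", sparse=True,
    )
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0

    # torso: elliptical cylinder spanning all slices; ~300 x 230 mm or what fits
    torso_ax = min(150.0, 0.46 * w * vs) / vs * rng.uniform(0.92, 1.05)
    torso_ay = min(115.0, 0.40 * h * vs) / vs * rng.uniform(0.92, 1.05)
    body = ((yy - cy) / torso_ay) ** 2 + ((xx - cx) / torso_ax) ** 2 <= 1.0
    body = np.broadcast_to(body, (d, h, w)).copy()

    # partial lung bases in the superior slices (low z)
    lung_top = int(0.22 * d)
    lungs = np.zeros((d, h, w), dtype=bool)
    for sign in (-1.0, 1.0):
        lung = _ellipsoid(
            zz, yy, xx,
            (0.0, cy - 0.15 * torso_ay, cx + sign * 0.45 * torso_ax),
            (max(lung_top, 2) * 1.6, 0.45 * torso_ay, 0.35 * torso_ax),
        )
        lungs |= lung
    lungs &= body

    # spine: posterior midline column (posterior = high y)
    spine_r = 16.0 / vs
    spine = ((yy - (cy + 0.62 * torso_ay)) ** 2 + (xx - cx) ** 2) <= spine_r**2
    spine = np.broadcast_to(spine, (d, h, w)) & body

    # kidneys: class 1 = patient right (-x side), class 2 = patient left (+x)
    want = {"right": spec.side in ("right", "both"),
            "left": spec.side in ("left", "both")}
    sides_present = {
        "right": spec.category != "post_total_nephrectomy" or not want["right"],
        "left": spec.category != "post_total_nephrectomy" or not want["left"],
    }
    kid_masks: dict[int, np.ndarray] = {}
    cold_masks: dict[int, np.ndarray] = {}
    stone_mask = np.zeros((d, h, w), dtype=bool)
    for name, cls, xsign in (("right", RIGHT_KIDNEY, -1.0), ("left", LEFT_KIDNEY, +1.0)):
        if not sides_present[name]:
            continue
        vol_ml = rng.uniform(*spec.kidney_volume_ml_range)
        # semi-axis ratio (z:y:x) = 2 : 1 : 0.8 for a 110 x 55 x 44 mm organ
        s = (vol_ml * 1000.0 * 3.0 / (4.0 * np.pi * 2.0 * 1.0 * 0.8)) ** (1.0 / 3.0)
        semi_mm = (2.0 * s, 1.0 * s, 0.8 * s)
        semi = tuple(a / vs for a in semi_mm)
        center = (
            0.62 * (d - 1) + rng.uniform(-0.05, 0.05) * d,
            cy + 0.28 * torso_ay + rng.uniform(-0.08, 0.08) * torso_ay,
            cx + xsign * (0.50 * torso_ax + rng.uniform(-0.06, 0.06) * torso_ax),
        )
        # the whole organ (lobes extend 1.1 x the z semi-axis) must fit the grid
        extents = (1.1 * semi[0], semi[1], semi[2])
        for c, e, dim in zip(center, extents, (d, h, w)):
            if c - e < 0 or c + e > dim - 1:
                raise ValueError(
                    f"grid {spec.grid_shape} at {vs} mm is too small to contain "
                    f"the {name} kidney"
                )
        mask = _kidney_mask(zz, yy, xx, center, semi, medial_sign=-xsign) & body

        affected = want[name]
        if affected and spec.category == "post_partial_nephrectomy":
            cut = center[0] - 0.45 * semi[0]
            mask &= np.broadcast_to(zz >= cut, mask.shape)
        if mask.sum() < 8:
            raise ValueError(
                f"grid {spec.grid_shape} at {vs} mm is too small to contain the "
                f"{name} kidney"
            )
        kid_masks[cls] = mask

        if affected and spec.category == "renal_tumor":
            nod = _ellipsoid(
                zz, yy, xx,
                (center[0] - 0.45 * semi[0], center[1], center[2]),
                tuple(max(0.35 * a, 1.0) for a in semi),
            )
            cold_masks[cls] = nod & mask
        if affected and spec.category == "urinary_stone":
            r = max(6.0 / vs, 1.0)
            st = _ellipsoid(zz, yy, xx, center, (r, r, r)) & mask
            stone_mask |= st
            cold_masks[cls] = st

    # perirenal fat capsule: ~1 voxel shell around each kidney
    all_kid = np.zeros((d, h, w), dtype=bool)
    for m in kid_masks.values():
        all_kid |= m
    fat = ndimage.binary_dilation(all_kid, iterations=1) & body & ~all_kid

    t = spec.mu_table
    mu = np.zeros((d, h, w), dtype=np.float64)
    mu[body] = t.soft_tissue
    mu[lungs] = t.lung
    mu[spine] = t.spine
    mu[fat] = t.fat
    mu[all_kid] = t.kidney
    mu[stone_mask] = t.stone
    if spec.smoothing_sigma_vox > 0:
        mu = ndimage.gaussian_filter(mu, spec.smoothing_sigma_vox)
    mu = np.clip(mu, 0.0, 0.5)

    labels = np.zeros((d, h, w), dtype=np.int16)
    for cls, m in kid_masks.items():
        labels[m] = cls

    # activity: uniform renal uptake over functioning parenchyma, uniform
    # soft-tissue background elsewhere in the body (lungs excluded)
    vox_ml = vs**3 / 1000.0
    activity = np.zeros((d, h, w), dtype=np.float64)
    bg_region = body & ~all_kid & ~lungs
    n_bg = int(bg_region.sum())
    if spec.background_uptake_fraction > 0 and n_bg > 0:
        activity[bg_region] = (
            spec.background_uptake_fraction * spec.injected_activity_MBq
            / (n_bg * vox_ml)
        )
    true_pct_id: dict[int, float] = {}
    for cls, m in kid_masks.items():
        frac = rng.uniform(*spec.kidney_uptake_fraction_range)
        active = m & ~cold_masks.get(cls, np.zeros_like(m))
        n_active = int(active.sum())
        if n_active == 0:
            active, n_active = m, int(m.sum())
        activity[m] = 0.0
        activity[active] = frac * spec.injected_activity_MBq / (n_active * vox_ml)
        true_pct_id[cls] = 100.0 * frac

    spacing = (vs, vs, vs)
    mu_vol = Volume3D(mu, spacing)
    act_vol = Volume3D(activity, spacing)
    primary, scatter, quant = degrade_to_spect(
        act_vol, mu_vol, spec.psf_fwhm_mm, spec.counts_scale, noise_seed
    )
    return PhantomCase(
        mu_map=mu_vol,
        activity=act_vol,
        labels=LabelMap(labels, spacing),
        primary_spect=primary,
        scatter_spect=scatter,
        quantitative_spect=quant,
        injected_activity_MBq=spec.injected_activity_MBq,
        true_pct_id=true_pct_id,
        category=spec.category,
        side=spec.side,
        seed=spec.seed,
    )


def degrade_to_spect(
    activity: Volume3D,
    mu_map: Volume3D,
    psf_fwhm_mm: float,
    counts_scale: float,
    seed: int,
    noise: bool = True,
) -> tuple[Volume3D, Volume3D, Volume3D]:
    """Degrade a true activity map into two-window SPECT surrogates.

    A post-reconstruction image model: each voxel's emission is attenuated by
    exp(-integral of mu) along a single fixed anterior axis (a one-projection
    simplification), blurred with the Gaussian system PSF, scaled to expected
    counts and Poisson-sampled.  The scatter window is a wider-blurred,
    down-weighted copy; the quantitative volume is the blurred activity with
    calibrated Poisson noise, i.e. an idealized fully corrected image in
    MBq/mL.
    """
    if counts_scale < 0:
        raise ValueError("counts_scale must be >= 0")
    if not activity.same_grid(mu_map):
        raise ValueError("activity and attenuation map must share the grid")
    voxel_cm = activity.require_isotropic() / 10.0
    rng = np.random.default_rng(seed)

    mu = np.asarray(mu_map.data, dtype=np.float64)
    act = np.asarray(activity.data, dtype=np.float64)
    # path integral from each voxel to the anterior face (y index 0),
    # excluding the emitting voxel itself
    path = (np.cumsum(mu, axis=1) - mu) * voxel_cm
    attenuated = act * np.exp(-path)

    sigma_vox = psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / (voxel_cm * 10.0)

    def blur(img: np.ndarray, scale: float = 1.0) -> np.ndarray:
        s = sigma_vox * scale
        return ndimage.gaussian_filter(img, s) if s > 0 else img

    primary_exp = counts_scale * blur(attenuated)
    scatter_exp = 0.35 * counts_scale * blur(attenuated, 1.8)
    quant_exp = blur(act)

    if noise:
        primary = rng.poisson(primary_exp).astype(np.float64)
        scatter = rng.poisson(scatter_exp).astype(np.float64)
        if counts_scale > 0:
            quant = rng.poisson(counts_scale * quant_exp) / counts_scale
        else:
            quant = quant_exp
    else:
        primary, scatter, quant = primary_exp, scatter_exp, quant_exp

    sp = activity.spacing_mm
    return Volume3D(primary, sp), Volume3D(scatter, sp), Volume3D(quant, sp)


def sample_population(
    n: int,
    mix: dict[str, float] | None = None,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> list[PhantomCase]:
    """Draw ``n`` cases with categories from ``mix`` (default: the referral mix).

    Category and affected side are drawn per case; each case receives its own
    child seed, so the list is deterministic under ``seed`` and cases are
    mutually independent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = dict(mix or REFERRAL_POPULATION_MIX)
    if abs(sum(mix.values()) - 1.0) > 1e-6:
        raise ValueError("category proportions must sum to 1")
    for cat in mix:
        if cat not in CATEGORIES:
            raise ValueError(f"unknown category {cat!r}")
    base = base_spec or PhantomSpec()

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    cats = list(mix.keys())
    probs = np.array([mix[c] for c in cats], dtype=float)
    probs = probs / probs.sum()

    cases = []
    child_seeds = np.random.SeedSequence(seed).spawn(n + 1)[1:]
    for i in range(n):
        cat = cats[int(rng.choice(len(cats), p=probs))]
        side_counts = _SIDE_COUNTS[cat]
        sides = list(side_counts.keys())
        sp = np.array([side_counts[s] for s in sides], dtype=float)
        side = sides[int(rng.choice(len(sides), p=sp / sp.sum()))]
        case_seed = int(child_seeds[i].generate_state(1)[0] % (2**31 - 1))
        spec = dataclasses.replace(base, category=cat, side=side, seed=case_seed)
        cases.append(generate_case(spec))
    return cases
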