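"""Synthetic cauliflower cohorts with known ground truth.

The generator emulates the acquisition design of a 47-germplasm x 3-replicate
greenhouse trial: imaging every 3 days from day 1 after transplanting,
switching to daily acquisition once the first curd appears in the cohort,
and raising the camera from 1.5 m to 2.2 m after day 70.  Leaf-area
trajectories follow the generalized Richards sigmoid; curd-area trajectories
follow a rising sine half-period starting at the plant's curd-appearance
day.  Measurement noise is multiplicative Gaussian with a fixed coefficient
of variation, since trait magnitudes span two orders over the season and
additive noise would distort the early points.

Germplasms belong to one of four archetypes whose parameter means encode
the qualitative contrasts seen among cauliflower germplasm groups: a
comprehensively coordinated type, a mid-maturity compact type (smallest,
earliest), a large high-yield type (largest leaf asymptote, latest), and a
curd-dominant type (short, intense curd expansion).  Every generating
parameter is recorded in a truth table so downstream fitting, kinetics,
classification and clustering can be validated by recovery.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import ellipse as _ellipse

from .calibration import CalibrationProfile
from .masks import BoundingBox, CURD_CODE, PLANT_CODE
from .models import evaluate_model
from .series import GrowthSeries

__all__ = [
    "PlantTruth",
    "ArchetypeSpec",
    "AcquisitionSchedule",
    "CohortResult",
    "DEFAULT_ARCHETYPES",
    "simulate_leaf_series",
    "simulate_curd_series",
    "simulate_cohort",
    "render_label_mask",
    "richards_rate_inflections",
    "sine_params_from_landmarks",
    "plant_rng",
]

#: floor curd area (cm^2) at the sine minimum; a just-visible curd
_CURD_FLOOR = 2.0


def plant_rng(seed: int, plant_id: str, stream: str = "") -> np.random.Generator:
    """Per-plant RNG substream by stable hashing, reproducible under reordering."""
    digest = hashlib.sha256(f"{seed}:{plant_id}:{stream}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Imaging calendar: sparse 3-day cadence, daily after first curd."""

    transplant_date: _dt.date = _dt.date(2024, 10, 1)
    base_interval: int = 3
    dense_interval: int = 1
    densify_after_first_curd: bool = True
    height_switch_day: float = 70.0
    heights: tuple[float, float] = (1.5, 2.2)

    def __post_init__(self):
        if not self.base_interval >= self.dense_interval >= 1:
            raise ValueError("need base_interval >= dense_interval >= 1")
        if self.height_switch_day <= 0:
            raise ValueError("height_switch_day must be positive")

    def sampling_days(self, end_day: float, first_curd_day: float | None = None) -> np.ndarray:
        """Acquisition days 1, 1+base, ... then every dense_interval days.

        Densification starts at ``first_curd_day`` (the cohort's first curd
        appearance) when enabled.
        """
        end = int(math.floor(end_day))
        if end < 1:
            raise ValueError("end_day must be >= 1")
        if self.densify_after_first_curd and first_curd_day is not None:
            dense_from = int(math.floor(first_curd_day))
        else:
            dense_from = end + 1
        days = list(range(1, min(dense_from, end + 1), self.base_interval))
        if dense_from <= end:
            days.extend(range(dense_from, end + 1, self.dense_interval))
        return np.array(sorted(set(days)), dtype=float)

    def camera_height(self, day: float) -> float:
        return self.heights[0] if day <= self.height_switch_day else self.heights[1]


@dataclass(frozen=True)
class PlantTruth:
    """Generating parameters of one plant."""

    plant_id: str
    germplasm_id: str
    replicate: int
    leaf_params: dict  # Richards: a (cm^2), k (1/day), tc (day), d (shape)
    curd_params: dict  # sine: y0 (cm^2), A (cm^2), tc (day), w (day)
    tca_true: float  # curd appearance day
    harvest_day: float
    noise_cv: float = 0.02
    archetype: str | None = None

    def __post_init__(self):
        lp, cp = self.leaf_params, self.curd_params
        for name, val in [*lp.items(), *cp.items()]:
            if not np.isfinite(val):
                raise ValueError(f"non-finite parameter {name}={val}")
        if lp["a"] <= 0 or lp["k"] <= 0 or lp["d"] <= 1.0:
            raise ValueError("Richards parameters require a>0, k>0, d>1")
        if cp["A"] <= 0 or cp["w"] <= 0:
            raise ValueError("sine parameters require A>0, w>0")
        if not 1 <= self.tca_true < self.harvest_day:
            raise ValueError("need 1 <= tca_true < harvest_day")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")


def richards_rate_inflections(a: float, k: float, tc: float, d: float) -> tuple[float, float]:
    """The two inflection points of the Richards growth-rate curve.

    Roots of the third time derivative; for the logistic limit (d = 2) they
    reduce to ``tc -/+ ln(2 + sqrt(3)) / k``.
    """
    if d <= 1.0:
        raise ValueError("Richards shape d must exceed 1")
    m = 1.0 / (1.0 - d)
    c2 = 1.0 + 3.0 * (m - 1.0) + (m - 1.0) * (m - 2.0)
    c1 = 2.0 + 3.0 * (m - 1.0)
    c0 = 1.0
    disc = c1 * c1 - 4.0 * c2 * c0
    roots = np.roots([c2, c1, c0]) if disc >= 0 else np.array([])
    s_roots = sorted(float(r) for r in roots if np.isreal(r) and r > 0)
    if len(s_roots) != 2:
        raise ValueError("no real rapid-growth window for these parameters")
    ts = [tc - math.log(s / (d - 1.0)) / k for s in s_roots]
    return (min(ts), max(ts))


def _apply_noise(values: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    if cv == 0:
        return values.copy()
    noisy = values * (1.0 + cv * rng.standard_normal(values.size))
    return np.clip(noisy, 0.0, None)


def simulate_leaf_series(
    truth: PlantTruth,
    schedule: AcquisitionSchedule,
    seed: int = 0,
    first_curd_day: float | None = None,
) -> GrowthSeries:
    """Richards leaf-area trajectory on the acquisition calendar.

    ``first_curd_day`` is the cohort-level densification trigger; it
    defaults to the plant's own curd appearance day.
    """
    if first_curd_day is None:
        first_curd_day = truth.tca_true
    days = schedule.sampling_days(truth.harvest_day, first_curd_day)
    if days.size < 8:
        raise ValueError(
            f"schedule yields only {days.size} sampling days before harvest; need >= 8"
        )
    clean = evaluate_model("richards", truth.leaf_params, days)
    rng = plant_rng(seed, truth.plant_id, "leaf")
    return GrowthSeries(truth.plant_id, "LA", days, _apply_noise(clean, truth.noise_cv, rng))


def simulate_curd_series(
    truth: PlantTruth,
    schedule: AcquisitionSchedule,
    seed: int = 0,
    first_curd_day: float | None = None,
) -> GrowthSeries:
    """Sine curd-area trajectory from appearance day to harvest."""
    cp = truth.curd_params
    half_lo, half_hi = cp["tc"] - cp["w"] / 2.0, cp["tc"] + cp["w"] / 2.0
    if not (half_lo - 1e-9 <= truth.tca_true and truth.harvest_day <= half_hi + 1e-9):
        raise ValueError(
            "observation window extends beyond the monotone-increasing sine "
            f"half-period [{half_lo:.2f}, {half_hi:.2f}]"
        )
    if first_curd_day is None:
        first_curd_day = truth.tca_true
    days = schedule.sampling_days(truth.harvest_day, first_curd_day)
    days = days[days >= truth.tca_true]
    clean = evaluate_model("sine", cp, days)
    rng = plant_rng(seed, truth.plant_id, "curd")
    return GrowthSeries(truth.plant_id, "CA", days, _apply_noise(clean, truth.noise_cv, rng))


def sine_params_from_landmarks(
    tca: float,
    harvest_day: float,
    ca_start: float,
    ca_final: float,
    harvest_phase: float,
    floor: float = _CURD_FLOOR,
) -> dict:
    """Construct valid sine parameters from biological landmarks.

    ``harvest_phase`` is the sine phase at harvest as a fraction of a
    quarter period (-1 < phase <= 1): negative = harvested pre-peak-rate,
    0 = at the rate peak, positive = post-peak.  The curve passes through
    ``ca_start`` at appearance and ``ca_final`` at harvest, with minimum
    value ``floor`` so the whole observed arc stays inside the
    monotone-increasing half-period.
    """
    if not (floor < ca_start < ca_final):
        raise ValueError("need floor < ca_start < ca_final")
    if not (-1.0 < harvest_phase <= 1.0):
        raise ValueError("harvest_phase must lie in (-1, 1]")
    if not tca < harvest_day:
        raise ValueError("tca must precede harvest")
    phi_h = harvest_phase * math.pi / 2.0
    b = ca_start - floor
    f = ca_final - floor
    s = (b / f) * (1.0 + math.sin(phi_h)) - 1.0
    phi_s = math.asin(s)
    amp = f / (1.0 + math.sin(phi_h))
    w = math.pi * (harvest_day - tca) / (phi_h - phi_s)
    tc = tca - phi_s * w / math.pi
    return {"y0": amp + floor, "A": amp, "tc": tc, "w": w}


@dataclass(frozen=True)
class ArchetypeSpec:
    """Germplasm-archetype parameter distributions.

    ``params`` maps each generative quantity to a (mean, sd) pair drawn at
    the germplasm level; replicates within a germplasm jitter around the
    germplasm value with sd ``replicate_sd_frac * sd``.  Quantities:

    - ``leaf_a``, ``leaf_k``, ``leaf_tc``, ``leaf_d``: Richards leaf parameters
    - ``tca_lag``: days from the leaf rate-curve's second inflection point to
      visible curd appearance
    - ``ecep``: effective curd expansion period, appearance to harvest (days)
    - ``ca_start`` / ``ca_final``: curd area at appearance / harvest (cm^2)
    - ``harvest_phase``: sine phase at harvest (fraction of a quarter period)
    - ``noise_cv``: measurement coefficient of variation
    """

    name: str
    n_germplasms: int
    params: dict
    replicate_sd_frac: float = 0.25

    def __post_init__(self):
        if self.n_germplasms < 1:
            raise ValueError("n_germplasms must be >= 1")
        for key, (mean, sd) in self.params.items():
            if sd < 0:
                raise ValueError(f"negative sd for {key}")


def _archetype(name, n, **kw) -> ArchetypeSpec:
    return ArchetypeSpec(name=name, n_germplasms=n, params=kw)


#: the four cohort archetypes; means encode the qualitative group contrasts
#: (largest leaf asymptote for the large high-yield type, shortest season for
#: the mid-maturity compact type, shortest curd expansion for the
#: curd-dominant type), counts sum to 47 germplasms
DEFAULT_ARCHETYPES: tuple[ArchetypeSpec, ...] = (
    _archetype(
        "comprehensive_coordinated", 14,
        leaf_a=(9000.0, 700.0), leaf_k=(0.10, 0.008), leaf_tc=(72.0, 4.0),
        leaf_d=(1.5, 0.10), tca_lag=(5.71, 1.5), ecep=(16.0, 2.0),
        ca_start=(8.0, 1.5), ca_final=(425.0, 35.0),
        harvest_phase=(-0.30, 0.25), noise_cv=(0.02, 0.0),
    ),
    _archetype(
        "midmaturity_compact", 12,
        leaf_a=(5600.0, 450.0), leaf_k=(0.12, 0.010), leaf_tc=(58.0, 3.0),
        leaf_d=(1.5, 0.10), tca_lag=(5.71, 1.5), ecep=(14.0, 2.0),
        ca_start=(7.0, 1.5), ca_final=(264.0, 25.0),
        harvest_phase=(-0.30, 0.25), noise_cv=(0.02, 0.0),
    ),
    _archetype(
        "large_highyield", 11,
        leaf_a=(15400.0, 1100.0), leaf_k=(0.09, 0.007), leaf_tc=(82.0, 4.0),
        leaf_d=(1.6, 0.10), tca_lag=(5.71, 1.5), ecep=(18.0, 2.0),
        ca_start=(9.0, 1.5), ca_final=(467.0, 35.0),
        harvest_phase=(-0.30, 0.25), noise_cv=(0.02, 0.0),
    ),
    _archetype(
        "curd_dominant", 10,
        leaf_a=(9500.0, 700.0), leaf_k=(0.11, 0.008), leaf_tc=(64.0, 3.0),
        leaf_d=(1.4, 0.10), tca_lag=(5.71, 1.5), ecep=(11.5, 1.5),
        ca_start=(8.0, 1.5), ca_final=(355.0, 30.0),
        harvest_phase=(-0.20, 0.25), noise_cv=(0.02, 0.0),
    ),
)

# hard plausibility clips applied after Gaussian draws
_CLIPS = {
    "leaf_a": (500.0, 40000.0),
    "leaf_k": (0.03, 0.35),
    "leaf_tc": (25.0, 110.0),
    "leaf_d": (1.05, 5.0),
    "tca_lag": (0.5, 15.0),
    "ecep": (5.0, 30.0),
    "ca_start": (3.0, 25.0),
    "ca_final": (60.0, 900.0),
    "harvest_phase": (-0.90, 0.95),
    "noise_cv": (0.0, 0.5),
}


def _draw(rng, mean, sd, key):
    lo, hi = _CLIPS[key]
    return float(np.clip(mean + sd * rng.standard_normal(), lo, hi))


def make_plant_truth(
    archetype: ArchetypeSpec,
    germplasm_id: str,
    replicate: int,
    seed: int = 0,
) -> PlantTruth:
    """Draw one plant: germplasm-level means, replicate-level jitter."""
    g_rng = plant_rng(seed, germplasm_id, "germplasm")
    g_vals = {
        key: _draw(g_rng, mean, sd, key) for key, (mean, sd) in archetype.params.items()
    }
    plant_id = f"{germplasm_id}-r{replicate}"
    p_rng = plant_rng(seed, plant_id, "plant")
    vals = {
        key: _draw(p_rng, g_vals[key], archetype.replicate_sd_frac * sd, key)
        for key, (mean, sd) in archetype.params.items()
    }
    # enforce the landmark ordering after independent clipped draws
    vals["ca_final"] = max(vals["ca_final"], vals["ca_start"] + 30.0)
    leaf = {"a": vals["leaf_a"], "k": vals["leaf_k"], "tc": vals["leaf_tc"],
            "d": vals["leaf_d"]}
    _, t_infl2 = richards_rate_inflections(**leaf)
    tca = max(1.0, round(t_infl2 + vals["tca_lag"]))
    harvest = tca + max(3.0, round(vals["ecep"]))
    curd = sine_params_from_landmarks(
        tca, harvest, vals["ca_start"], vals["ca_final"], vals["harvest_phase"]
    )
    return PlantTruth(
        plant_id=plant_id,
        germplasm_id=germplasm_id,
        replicate=replicate,
        leaf_params=leaf,
        curd_params=curd,
        tca_true=tca,
        harvest_day=harvest,
        noise_cv=vals["noise_cv"],
        archetype=archetype.name,
    )


@dataclass(frozen=True)
class CohortResult:
    """All plant series plus the generating-truth table."""

    leaf_series: dict
    curd_series: dict
    truth: pd.DataFrame
    schedule: AcquisitionSchedule

    @property
    def plant_ids(self) -> list[str]:
        return list(self.truth["plant_id"])

    def series_frame(self) -> pd.DataFrame:
        """Long-format (plant_id, germplasm_id, replicate, day, trait, value)."""
        meta = self.truth.set_index("plant_id")
        rows = []
        for trait, store in (("LA", self.leaf_series), ("CA", self.curd_series)):
            for pid, s in store.items():
                g = meta.loc[pid, "germplasm_id"]
                r = meta.loc[pid, "replicate"]
                for d, v in zip(s.days, s.values):
                    rows.append((pid, g, int(r), float(d), trait, float(v)))
        return pd.DataFrame(
            rows, columns=["plant_id", "germplasm_id", "replicate", "day", "trait", "value"]
        )


def simulate_cohort(
    archetypes=DEFAULT_ARCHETYPES,
    replicates: int = 3,
    schedule: AcquisitionSchedule | None = None,
    seed: int = 0,
) -> CohortResult:
    """Generate a full cohort (default 47 germplasms x 3 replicates = 141 plants)."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    schedule = schedule or AcquisitionSchedule()
    truths: list[PlantTruth] = []
    g_index = 0
    for arch in archetypes:
        for _ in range(arch.n_germplasms):
            g_index += 1
            gid = f"G{g_index:02d}"
            for rep in range(1, replicates + 1):
                truths.append(make_plant_truth(arch, gid, rep, seed=seed))
    first_curd = min(t.tca_true for t in truths)
    leaf = {}
    curd = {}
    for t in truths:
        leaf[t.plant_id] = simulate_leaf_series(t, schedule, seed=seed,
                                                first_curd_day=first_curd)
        curd[t.plant_id] = simulate_curd_series(t, schedule, seed=seed,
                                                first_curd_day=first_curd)
    truth_rows = [
        {
            "plant_id": t.plant_id,
            "germplasm_id": t.germplasm_id,
            "replicate": t.replicate,
            "archetype": t.archetype,
            "leaf_a": t.leaf_params["a"],
            "leaf_k": t.leaf_params["k"],
            "leaf_tc": t.leaf_params["tc"],
            "leaf_d": t.leaf_params["d"],
            "curd_y0": t.curd_params["y0"],
            "curd_A": t.curd_params["A"],
            "curd_tc": t.curd_params["tc"],
            "curd_w": t.curd_params["w"],
            "tca_true": t.tca_true,
            "harvest_day": t.harvest_day,
            "noise_cv": t.noise_cv,
        }
        for t in truths
    ]
    truth = pd.DataFrame(truth_rows).sort_values("plant_id", kind="stable")
    truth = truth.reset_index(drop=True)
    return CohortResult(leaf, curd, truth, schedule)


def render_label_mask(
    leaf_area: float,
    curd_area: float,
    calibration: CalibrationProfile,
    canvas: tuple[int, int] = (600, 600),
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Rasterize a synthetic label mask with known ground truth.

    The plant is an ellipse whose code-1 pixel count targets
    ``leaf_area / pixel_to_area``; the curd is a concentric code-2 ellipse
    nested inside it.  Returns the uint8 mask and the true (raster) bounding
    boxes per class.  This is fixture plumbing for the measurement loop, not
    a photorealistic renderer.
    """
    if leaf_area <= 0:
        raise ValueError("leaf_area must be positive")
    if curd_area < 0:
        raise ValueError("curd_area cannot be negative")
    if curd_area >= leaf_area:
        raise ValueError("curd must be smaller than the plant")
    rng = np.random.default_rng(seed)
    pta = calibration.pixel_to_area
    leaf_px = leaf_area / pta
    curd_px = curd_area / pta
    total_px = leaf_px + curd_px  # curd overwrites plant pixels

    h, w = canvas
    aspect = rng.uniform(0.75, 1.3)
    r_r = math.sqrt(total_px * aspect / math.pi)
    r_c = total_px / (math.pi * r_r)
    if 2 * r_r + 4 > h or 2 * r_c + 4 > w:
        raise ValueError(
            f"requested area needs an ellipse of {2*r_r:.0f}x{2*r_c:.0f} px; "
            f"canvas is only {h}x{w}"
        )
    max_jr = (h - 2 * r_r - 4) / 2
    max_jc = (w - 2 * r_c - 4) / 2
    cr = h / 2 + rng.uniform(-1, 1) * min(max_jr, h * 0.05)
    cc = w / 2 + rng.uniform(-1, 1) * min(max_jc, w * 0.05)

    mask = np.zeros((h, w), dtype=np.uint8)
    rr, cc_ix = _ellipse(cr, cc, r_r, r_c, shape=(h, w))
    mask[rr, cc_ix] = PLANT_CODE

    bboxes: dict[str, BoundingBox | None] = {"curd": None}
    if curd_px > 0:
        cr_r = math.sqrt(curd_px * aspect / math.pi)
        cr_c = curd_px / (math.pi * cr_r)
        rr2, cc2 = _ellipse(cr, cc, cr_r, cr_c, shape=(h, w))
        mask[rr2, cc2] = CURD_CODE
        bboxes["curd"] = BoundingBox(
            int(cc2.min()), int(rr2.min()),
            int(cc2.max() - cc2.min() + 1), int(rr2.max() - rr2.min() + 1),
        )
    bboxes["plant"] = BoundingBox(
        int(cc_ix.min()), int(rr.min()),
        int(cc_ix.max() - cc_ix.min() + 1), int(rr.max() - rr.min() + 1),
    )
    return mask, bboxes
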