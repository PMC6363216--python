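"""Synthetic dorsal-outline populations and behaviour streams.

No photographs ship with the analysis, so this module generates
30-point dorsal profiles (croup at point 1 to the medial canthus of the
eye at point 30, withers at point 15) with the statistical structure the
pipeline assumes:

* a fixed smooth template — a gentle sinusoid plus localized Gaussian
  bumps in height over arc length — parameterized by interpretable
  posture features (withers prominence, neck and croup roundness,
  head/neck angle, relative head size);
* per-individual random effects on those features, a binary group label
  shifting withers prominence up and neck roundness and head size down
  (the posture signature reported for horses with stereotypic/abnormal
  repetitive behaviour);
* per-photograph landmark jitter and a random rigid "balance" swing of
  the neck chain about the withers — the nuisance that articulation-angle
  stabilization removes;
* behaviour observation streams constructed to satisfy (or violate) the
  SB/ARB scoring rule according to each horse's label.

All randomness flows from a single seed through ``numpy``'s
``SeedSequence`` spawning, so each stage draws from an independent,
reproducible stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .gm_core import articulation_angle
from .landmark_io import (
    N_OUTLINE_POINTS,
    WITHERS_INDEX,
    LandmarkConfiguration,
    MethodScheme,
    ShapeSample,
    ssl_scheme,
)
from .welfare import EAR_CATEGORIES, ObservationStream, WelfareRecord

_HEAD_START = 27  # 1-based index where the head segment (facial crest..eye) begins


@dataclass
class ProfileParams:
    """Interpretable features of one dorsal profile.

    Amplitudes are in the same units as ``baseline_length`` (arbitrary
    image units; the default template uses a 100-unit croup-to-eye
    extent). ``head_neck_angle`` is the interior angle (degrees) formed
    at the withers by the croup point, the withers and the eye; an open
    (large) angle is a flat/low neck, a closed one a raised, rounder
    neck carriage.
    """

    withers_prominence: float = 5.0
    neck_roundness: float = 6.0
    croup_roundness: float = 5.0
    head_neck_angle: float = 160.0
    head_size: float = 1.0
    baseline_length: float = 100.0

    def validate(self) -> None:
        if self.baseline_length <= 0:
            raise ValueError("baseline_length must be positive")
        if not 90.0 < self.head_neck_angle < 270.0:
            raise ValueError("head_neck_angle must lie in (90, 270) degrees")
        if self.head_size <= 0:
            raise ValueError("head_size must be positive")


def _gauss(u: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((u - center) / width) ** 2)


def generate_profile(params: ProfileParams) -> np.ndarray:
    """Deterministic 30-point outline for one parameter set.

    Points sit at fixed arc-length fractions of the baseline; the head
    segment's x-extent scales with ``head_size``; the neck-and-head chain
    (points 16..30) is rigidly rotated about the withers to realize the
    requested croup-withers-eye angle. x is strictly increasing
    croup -> head.
    """
    params.validate()
    L = params.baseline_length
    u = np.linspace(0.0, 1.0, N_OUTLINE_POINTS)
    h0 = _HEAD_START - 1
    u = u.copy()
    u[h0:] = u[h0] + params.head_size * (u[h0:] - u[h0])
    u15 = u[WITHERS_INDEX - 1]

    y = 0.02 * L * np.sin(np.pi * u)
    y += params.croup_roundness * _gauss(u, 0.12, 0.07)
    y += params.withers_prominence * _gauss(u, u15, 0.04)
    y += params.neck_roundness * _gauss(u, 0.76, 0.10)
    pts = np.column_stack([u * L, y])

    # realize the head/neck angle: rotate the chain beyond the withers
    target = -np.deg2rad(params.head_neck_angle)  # signed, neck above the back
    current = articulation_angle(pts)
    phi = target - current
    pivot = pts[WITHERS_INDEX - 1]
    c, s = np.cos(phi), np.sin(phi)
    rot = np.array([[c, -s], [s, c]])
    pts[WITHERS_INDEX:] = (pts[WITHERS_INDEX:] - pivot) @ rot.T + pivot

    if np.any(np.diff(pts[:, 0]) <= 0):
        raise ValueError(
            "parameters produce a non-monotone outline (x must increase croup->head)"
        )
    return pts


#: Profile parameters receiving the group effect and its sign: horses in
#: the affected group get more prominent withers, a flatter neck and a
#: relatively smaller head.
GROUP_EFFECT_SIGNS = {
    "withers_prominence": +1.0,
    "neck_roundness": -1.0,
    "head_size": -1.0,
}

#: Between-individual SDs per profile parameter. Chosen so that
#: between-horse posture variation realistically dominates the 2-unit
#: per-photo landmark jitter: repeated photographs of one standing horse
#: scatter far less than postures differ between horses.
DEFAULT_BETWEEN_SD = {
    "withers_prominence": 2.0,
    "neck_roundness": 2.5,
    "croup_roundness": 2.0,
    "head_neck_angle": 6.0,
    "head_size": 0.12,
    "baseline_length": 5.0,
}


@dataclass
class PopulationSpec:
    """Study-design parameters of a synthetic population.

    Defaults follow the study design: 10 standing and 20 walking
    photographs per individual, a group effect of 1.5 between-individual
    SD on the affected parameters, landmark jitter of 2% of the baseline
    length, and a 5-degree SD random neck swing per photograph.
    """

    n_individuals: int = 40
    photos_standing: int = 10
    photos_walking: int = 20
    group_delta: float = 1.5
    between_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETWEEN_SD))
    photo_noise_sd: float = 2.0
    neck_swing_sd_deg: float = 5.0
    depressed_prevalence: float = 0.18
    ear_probs: tuple[float, float, float] = (0.4, 0.3, 0.3)  # forward, backward, neutral
    base_params: ProfileParams = field(default_factory=ProfileParams)
    seed: int = 0

    def validate(self) -> None:
        self.base_params.validate()
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        if any(sd < 0 for sd in self.between_sd.values()):
            raise ValueError("between-individual SDs must be non-negative")
        if self.photo_noise_sd < 0 or self.neck_swing_sd_deg < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.photos_standing + self.photos_walking < 1:
            raise ValueError("each individual needs at least one photograph")


def _neck_swing(pts: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rigid rotation of the neck-and-head chain about the withers."""
    out = pts.copy()
    pivot = pts[WITHERS_INDEX - 1]
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    rot = np.array([[c, -s], [s, c]])
    out[WITHERS_INDEX:] = (pts[WITHERS_INDEX:] - pivot) @ rot.T + pivot
    return out


def generate_population(
    spec: PopulationSpec, scheme: MethodScheme | None = None
) -> tuple[ShapeSample, list[WelfareRecord]]:
    """Draw a population of repeated dorsal photographs plus welfare records.

    Individual ``i`` belongs to group ``i % 2`` (balanced design); its
    profile parameters are the group mean (base parameters shifted by
    ``group_delta`` between-individual SDs on the affected features) plus
    an individual random deviation. Every photograph adds isotropic
    landmark jitter and an independent rigid neck swing. The group label
    is written to ``WelfareRecord.sb_arb``.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    rng_ind, rng_photo, rng_welf = (
        np.random.default_rng(s) for s in root.spawn(3)
    )

    configs: list[LandmarkConfiguration] = []
    records: list[WelfareRecord] = []
    base = spec.base_params
    param_names = (
        "withers_prominence", "neck_roundness", "croup_roundness",
        "head_neck_angle", "head_size", "baseline_length",
    )
    for i in range(spec.n_individuals):
        group = i % 2
        # rejection sampling: individual deviations are redrawn until they
        # yield a geometrically valid (x-monotone) outline, i.e. the
        # parameter distribution is truncated to the valid envelope
        for attempt in range(50):
            dev = {k: rng_ind.normal(0.0, sd) for k, sd in spec.between_sd.items()}
            values = {k: getattr(base, k) + dev.get(k, 0.0) for k in param_names}
            if group == 1:
                for k, sign in GROUP_EFFECT_SIGNS.items():
                    values[k] += sign * spec.group_delta * spec.between_sd.get(k, 0.0)
            values["head_size"] = max(values["head_size"], 0.2)
            values["baseline_length"] = max(values["baseline_length"], 10.0)
            values["head_neck_angle"] = float(np.clip(values["head_neck_angle"], 95.0, 265.0))
            params = replace(base, **values)
            try:
                clean = generate_profile(params)
                break
            except ValueError:
                continue
        else:
            raise ValueError(
                "could not draw a valid profile in 50 attempts; "
                "between-individual SDs are too large for the template"
            )

        hid = f"H{i:03d}"
        for condition, n_photos in (
            ("standing", spec.photos_standing),
            ("walking", spec.photos_walking),
        ):
            for j in range(n_photos):
                swing = rng_photo.normal(0.0, np.deg2rad(spec.neck_swing_sd_deg))
                pts = _neck_swing(clean, swing)
                pts = pts + rng_photo.normal(0.0, spec.photo_noise_sd, pts.shape)
                configs.append(
                    LandmarkConfiguration(
                        pts, horse_id=hid, condition=condition,
                        photo_id=f"{hid}_{condition}_{j:02d}",
                    )
                )

        records.append(
            WelfareRecord(
                horse_id=hid,
                sb_arb=group,
                depressed=int(rng_welf.random() < spec.depressed_prevalence),
                ear_category=str(rng_welf.choice(EAR_CATEGORIES, p=spec.ear_probs)),
                type_of_equid=str(rng_welf.choice(["pony", "horse"])),
                proportion=str(
                    rng_welf.choice(["dolicho", "meso", "brachy"], p=[0.13, 0.72, 0.15])
                ),
                hay_meals=int(rng_welf.integers(1, 4)),
                paddock_time=float(np.round(rng_welf.uniform(0, 95), 1)),
                paddock_social=str(rng_welf.choice(["alone", "group"], p=[0.3, 0.7])),
                visible_conspecifics=int(rng_welf.integers(0, 12)),
                work_hours=float(np.round(rng_welf.uniform(3, 14), 1)),
            )
        )
    return ShapeSample(configs, scheme if scheme is not None else ssl_scheme()), records


#: Pool of behaviour labels used when constructing observation streams.
SB_ARB_LABELS = (
    "weaving", "cribbing", "head_tossing", "stall_walking", "repetitive_licking",
    "repetitive_biting", "head_movements", "mouth_open", "teeth_rubbing",
    "teeth_chattering", "tongue_movements",
)


def generate_observation_streams(
    records: list[WelfareRecord], seed: int = 0
) -> list[ObservationStream]:
    """Construct behaviour streams consistent with each record's labels.

    Horses scored 1 for SB/ARB receive at least 5 bouts of one behaviour
    with >= 3 successive repeats each; horses scored 0 receive streams
    that break the rule (too few qualifying bouts and/or short runs).
    Ear scans (10 per horse) are drawn to realize the record's favourite
    ear category; depressed sightings respect the binary flag.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    streams: list[ObservationStream] = []
    for rec in records:
        events: list[tuple[str, int]] = []
        if rec.sb_arb:
            label = str(rng.choice(SB_ARB_LABELS))
            n_bouts = int(rng.integers(5, 9))
            events += [(label, int(rng.integers(3, 7))) for _ in range(n_bouts)]
            # occasional sub-threshold noise from other behaviours
            for _ in range(int(rng.integers(0, 3))):
                events.append((str(rng.choice(SB_ARB_LABELS)), int(rng.integers(1, 3))))
        else:
            # rule violated: either long runs but < 5 bouts, or >= 5 short runs
            label = str(rng.choice(SB_ARB_LABELS))
            if rng.random() < 0.5:
                events += [(label, int(rng.integers(3, 6))) for _ in range(int(rng.integers(1, 5)))]
            else:
                events += [(label, int(rng.integers(1, 3))) for _ in range(int(rng.integers(5, 9)))]
        order = rng.permutation(len(events))
        events = [events[o] for o in order]

        cat = rec.ear_category
        if cat in ("forward", "backward"):
            n_major = int(rng.integers(6, 11))
            others = [c for c in EAR_CATEGORIES if c != cat]
            scans = [cat] * n_major + [
                str(rng.choice(others)) for _ in range(10 - n_major)
            ]
        else:
            n_fwd = int(rng.integers(0, 6))
            n_bwd = int(rng.integers(0, min(6, 11 - n_fwd)))
            scans = ["forward"] * n_fwd + ["backward"] * n_bwd
            scans += ["neutral"] * (10 - len(scans))
        scans = [scans[i] for i in rng.permutation(10)]

        depressed_seen = int(rng.integers(1, 5)) if rec.depressed else 0
        streams.append(
            ObservationStream(
                horse_id=rec.horse_id,
                events=events,
                ear_scans=scans,
                depressed_seen=depressed_seen,
            )
        )
    return streams
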