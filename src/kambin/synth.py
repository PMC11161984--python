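"""Synthetic L4-L5 anatomy generation.

Two modes:

* ``parametric`` — landmark sets sampled from configurable distributions,
  for unconstrained simulation studies.
* ``paper_fixture`` — a 40-case cohort inverse-constructed so that the
  forward measurement pipeline reproduces the published reference-cohort
  summaries: per-case d, L1 and L2 targets are quantile-matched to the
  published five-number summaries, and beta values are drawn and then
  affinely standardized to the published mean and SD.

The inverse constructor is deliberately an independent implementation of
the forward geometry (closed-form triangle and trig instead of the generic
projection machinery), so forward-inverse round-trip agreement is a real
cross-check rather than a tautology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import truncnorm

from .errors import ConfigurationError, NoSolutionError
from .geometry import PlanePatch, Segment3, line_segment_distance
from .measure import LumbarCase

# --- reference cohort calibration (published L4-L5 morphometry, n = 40) ---
REFERENCE_N = 40
D_SUMMARY_MM = (9.46, 11.35, 11.62, 12.04, 12.54)
L1_SUMMARY_MM = (0.88, 1.34, 1.40, 1.43, 1.48)
L2_SUMMARY_MM = (1.99, 2.14, 2.30, 2.34, 3.43)
BETA_MEAN_DEG = 32.02
BETA_SD_DEG = 0.90
BETA_RANGE_DEG = (30.32, 34.56)
# reference covariates (20 patients: age/BMI mean +/- SD, 12 of 20 female)
AGE_MEAN, AGE_SD = 48.45, 7.97
BMI_MEAN, BMI_SD = 25.12, 2.13
FEMALE_FRACTION = 0.6


@dataclass(frozen=True)
class FiveNumberSummary:
    """min, q1, median, q3, max in the variable's units."""

    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float

    def __post_init__(self) -> None:
        vals = self.as_tuple()
        if any(not math.isfinite(v) for v in vals):
            raise ConfigurationError("non-finite five-number summary")
        if any(a > b for a, b in zip(vals, vals[1:])):
            raise ConfigurationError(f"five-number summary not ordered: {vals}")

    def as_tuple(self) -> Tuple[float, float, float, float, float]:
        return (self.minimum, self.q1, self.median, self.q3, self.maximum)


@dataclass(frozen=True)
class TargetQuadruple:
    """Per-case calibration targets for the inverse constructor."""

    d: float  # mm
    beta: float  # degrees
    L1: float  # mm
    L2: float  # mm

    def __post_init__(self) -> None:
        if not (self.d > 0):
            raise ConfigurationError(f"d target must be > 0, got {self.d}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything the generators need; all lengths mm, angles degrees."""

    n: int = REFERENCE_N
    seed: int = 0
    mode: str = "paper_fixture"  # or "parametric"
    # geometry layout
    leg_aspect: float = 0.75  # base : height of the working triangle
    od_distance: float = 30.0  # projected |OD|
    o_height: float = 6.0  # O above the transverse plane through D
    e_distance: float = 60.0  # D -> E along the midline
    disc_width: float = 44.0  # tangent rectangle, lateral extent
    disc_depth: float = 34.0  # tangent rectangle, antero-posterior extent
    facet_offset: float = 15.0  # patch plane posterior of the triangle plane
    facet_patch_size: float = 20.0  # square patch side
    trephine_diameter: float = 8.0
    # parametric mode distributions
    height_mean: float = 23.24
    height_sd: float = 1.6
    base_mean: float = 17.43
    base_sd: float = 1.2
    beta_mean: float = BETA_MEAN_DEG
    beta_sd: float = BETA_SD_DEG
    vertex_jitter: float = 0.0  # isotropic landmark noise on A, B, C
    # covariates
    age_mean: float = AGE_MEAN
    age_sd: float = AGE_SD
    bmi_mean: float = BMI_MEAN
    bmi_sd: float = BMI_SD
    female_fraction: float = FEMALE_FRACTION
    # fixture pairing: permute beta against the sorted (d, L1, L2) targets
    shuffle_pairing: bool = False
    # solver
    solver_tol: float = 1e-8
    solver_max_iter: int = 500

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")
        if self.mode not in ("paper_fixture", "parametric"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        for name in ("height_sd", "base_sd", "beta_sd", "age_sd", "bmi_sd",
                     "vertex_jitter"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not (0.0 <= self.female_fraction <= 1.0):
            raise ConfigurationError("female_fraction must be in [0, 1]")
        if not (self.leg_aspect > 0):
            raise ConfigurationError("leg_aspect must be > 0")


# ---------------------------------------------------------------------------
# quantile matching
# ---------------------------------------------------------------------------


def quantile_match(
    summary: FiveNumberSummary, n: int, seed: int = 0
) -> np.ndarray:
    """n sorted values whose empirical five-number summary equals ``summary``.

    Intermediate values come from monotone piecewise-linear interpolation of
    the summary at evenly spaced plotting positions i/(n-1); the order
    statistics entering the empirical quartiles (linear interpolation of
    order statistics, numpy's default) are then pinned so the recomputed
    min, q1, median, q3 and max are exact.  Deterministic; ``seed`` is
    accepted for interface symmetry with the samplers.
    """
    if n < 5:
        raise ConfigurationError(f"quantile matching needs n >= 5, got {n}")
    anchors_p = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    anchors_v = np.array(summary.as_tuple())
    pos = np.linspace(0.0, 1.0, n)
    x = np.interp(pos, anchors_p, anchors_v)
    x[0], x[-1] = summary.minimum, summary.maximum

    if n == 6:
        # the only n where q1, median and q3 share order statistics; the
        # greedy chain below can overshoot, so place x[3] inside its
        # feasible interval [median, q3] and cascade the rest exactly
        q1, med, q3 = summary.q1, summary.median, summary.q3
        x[3] = (med + q3) / 2.0
        x[2] = 2.0 * med - x[3]
        x[1] = (q1 - 0.25 * x[2]) / 0.75
        x[4] = (q3 - 0.25 * x[3]) / 0.75
        return _verify_match(x, anchors_p, anchors_v)

    pinned = {0: summary.minimum, n - 1: summary.maximum}
    for p, q in ((0.25, summary.q1), (0.5, summary.median), (0.75, summary.q3)):
        h = (n - 1) * p
        i = int(math.floor(h))
        f = h - i
        if f < 1e-12:
            x[i] = q
            pinned[i] = q
        elif i in pinned:
            # order statistic shared with the previous constraint: solve
            x[i + 1] = (q - (1.0 - f) * x[i]) / f
            pinned[i + 1] = x[i + 1]
        else:
            lo_gap = max(q - x[i - 1], 0.0) if i - 1 >= 0 else 0.0
            hi_gap = max(x[i + 2] - q, 0.0) if i + 2 <= n - 1 else 0.0
            eps = 0.25 * min(lo_gap, hi_gap)
            x[i] = q - f * eps
            x[i + 1] = q + (1.0 - f) * eps
            pinned[i] = x[i]
            pinned[i + 1] = x[i + 1]

    return _verify_match(x, anchors_p, anchors_v)


def _verify_match(x: np.ndarray, anchors_p: np.ndarray, anchors_v: np.ndarray) -> np.ndarray:
    scale = max(abs(anchors_v).max(), 1.0)
    if np.any(np.diff(x) < -1e-12 * scale):
        raise ConfigurationError(
            "quantile matching produced a non-monotone sequence for this summary"
        )
    x = np.maximum.accumulate(x)  # remove fp-level inversions only
    got = np.quantile(x, anchors_p)
    if not np.allclose(got, anchors_v, rtol=0.0, atol=1e-9 * scale):
        raise ConfigurationError(
            f"quantile matching failed verification: {got} vs {anchors_v}"
        )
    return x


# ---------------------------------------------------------------------------
# inverse construction
# ---------------------------------------------------------------------------


def _triangle_legs(d: float, aspect: float) -> Tuple[float, float]:
    """Closed-form legs (base, height) of a right triangle with incircle
    diameter d and base:height ratio ``aspect``."""
    k = aspect + 1.0 - math.hypot(aspect, 1.0)
    height = d / k
    return aspect * height, height


def _layout(targets: TargetQuadruple, config: GeneratorConfig):
    """Deterministic part of the inverse construction (no solving)."""
    d, beta = targets.d, math.radians(targets.beta)
    r = d / 2.0
    base, height = _triangle_legs(d, config.leg_aspect)
    sb, cb = math.sin(beta), math.cos(beta)
    O = np.array([config.od_distance * sb, config.od_distance * cb, config.o_height])
    tip = np.array([-sb, -cb, 0.0])  # anterior axis direction
    e_lat = np.array([cb, -sb, 0.0])  # z x tip, toward the measured side
    e_sup = np.array([0.0, 0.0, 1.0])
    C = O + np.array([-r, 0.0, -r])
    B = C + np.array([base, 0.0, 0.0])
    A = C + np.array([0.0, 0.0, height])
    return O, tip, e_lat, e_sup, A, B, C


def _clearance_residual(
    offset: np.ndarray,
    O: np.ndarray,
    tip: np.ndarray,
    e_lat: np.ndarray,
    e_sup: np.ndarray,
    seg_ab: Segment3,
    seg_ac: Segment3,
    target_dists: np.ndarray,
) -> np.ndarray:
    anchor = O + offset[0] * e_lat + offset[1] * e_sup
    return np.array(
        [
            line_segment_distance(anchor, tip, seg_ab),
            line_segment_distance(anchor, tip, seg_ac),
        ]
    ) - target_dists


_STARTS = (
    (0.0, 0.0), (1.5, -2.5), (1.0, -1.0), (2.0, -5.0), (-1.0, -1.0),
    (1.5, 2.0), (-2.0, 2.0), (3.0, -7.0), (4.0, -3.0), (-3.0, -4.0),
)


def invert_case(
    targets: TargetQuadruple,
    config: Optional[GeneratorConfig] = None,
    *,
    case_id: str = "case",
    side: str = "right",
    sex: str = "F",
    age: float = AGE_MEAN,
    bmi: float = BMI_MEAN,
) -> LumbarCase:
    """Construct a landmark set the forward pipeline measures as ``targets``.

    Triangle legs and the O/D/E layout are closed-form in d and beta; the
    two wire-offset components are solved numerically (bounded least
    squares, multi-start) so the trephine clearances hit L1 and L2.  With
    beta = 0 and L1 = L2 = d/2 - radius the perpendicular configuration is
    returned directly without solving.
    """
    cfg = config or GeneratorConfig()
    rt = cfg.trephine_diameter / 2.0
    O, tip, e_lat, e_sup, A, B, C = _layout(targets, cfg)
    seg_ab, seg_ac = Segment3(A, B), Segment3(A, C)
    target_dists = np.array([targets.L1 + rt, targets.L2 + rt])
    if np.any(target_dists < 0):
        raise NoSolutionError(
            f"clearance targets below -radius are unreachable: {targets}",
            residual=float("inf"),
        )

    perp_limit = targets.d / 2.0 - rt
    if (
        abs(targets.beta) < 1e-12
        and abs(targets.L1 - perp_limit) < 1e-9
        and abs(targets.L2 - perp_limit) < 1e-9
    ):
        offset = np.zeros(2)
        best_res = 0.0
    else:
        args = (O, tip, e_lat, e_sup, seg_ab, seg_ac, target_dists)
        best = None
        for x0 in _STARTS:
            sol = least_squares(
                _clearance_residual,
                x0,
                args=args,
                bounds=([-40.0, -40.0], [40.0, 40.0]),
                xtol=3e-16,
                ftol=3e-16,
                gtol=3e-16,
                max_nfev=cfg.solver_max_iter,
            )
            res = float(np.linalg.norm(sol.fun, np.inf))
            if best is None or res < best[0]:
                best = (res, sol.x)
            if res < cfg.solver_tol:
                break
        best_res, offset = best
        if best_res > cfg.solver_tol:
            raise NoSolutionError(
                f"inverse construction did not converge for {targets} "
                f"(best residual {best_res:.3g} mm)",
                residual=best_res,
            )

    # disc tangent rectangle centred on D = origin, in the transverse plane
    hw, hd = cfg.disc_width / 2.0, cfg.disc_depth / 2.0
    disc_corners = np.array(
        [[-hw, -hd, 0.0], [hw, -hd, 0.0], [hw, hd, 0.0], [-hw, hd, 0.0]]
    )
    E = np.array([0.0, cfg.e_distance, 0.0])

    # facet patch 15 mm posterior of the triangle plane; J sits in the
    # upper-outer quadrant, 3 mm up and out from the patch center
    anchor = O + offset[0] * e_lat + offset[1] * e_sup
    posterior = -tip
    y_patch = O[1] + cfg.facet_offset
    s = (y_patch - anchor[1]) / posterior[1]
    J = anchor + s * posterior
    half = cfg.facet_patch_size / 2.0
    in_quadrant = min(3.0, half / 2.0)
    center = J - in_quadrant * np.array([1.0, 0.0, 0.0]) - in_quadrant * e_sup
    patch = PlanePatch(
        origin=center,
        u_axis=np.array([1.0, 0.0, 0.0]),
        v_axis=np.array([0.0, 0.0, 1.0]),
        u_range=(-half, half),
        v_range=(-half, half),
    )
    facet_landmarks = {
        "upper_vertex_L5": patch.from_uv(0.0, half),
        "lower_edge_L4": patch.from_uv(0.0, -half),
        "lateral_edge_facet": patch.from_uv(half, 0.0),
        "lateral_edge_exiting_root": patch.from_uv(-half, 0.0),
    }
    return LumbarCase(
        case_id=case_id,
        side=side,
        A=A,
        B=B,
        C=C,
        disc_corners=disc_corners,
        E=E,
        facet_landmarks=facet_landmarks,
        facet_patch=patch,
        sex=sex,
        age=float(age),
        bmi=float(bmi),
        wire_offset=(float(offset[0]), float(offset[1])),
    )


# ---------------------------------------------------------------------------
# cohort builders
# ---------------------------------------------------------------------------


def standardized_beta_sample(
    n: int,
    rng: np.random.Generator,
    mean: float = BETA_MEAN_DEG,
    sd: float = BETA_SD_DEG,
    value_range: Tuple[float, float] = BETA_RANGE_DEG,
    max_rounds: int = 200,
) -> np.ndarray:
    """Draw n values, then affinely standardize to the exact mean and SD.

    The draw is a truncated normal; clipping to ``value_range`` and
    re-standardization alternate until the standardized sample lies inside
    the range (re-checked after the final affine step).  Sample SD uses
    ddof = 1.
    """
    if n < 2:
        raise ConfigurationError("need n >= 2 to standardize")
    lo, hi = value_range
    zlo, zhi = (lo - mean) / sd, (hi - mean) / sd
    # start comfortably inside the admissible z-range
    a = max(zlo * 0.75, zlo + 0.35)
    b = min(zhi * 0.85, zhi - 0.35)
    z = truncnorm.rvs(a, b, size=n, random_state=rng)
    for _ in range(max_rounds):
        z = (z - z.mean()) / z.std(ddof=1)
        vals = mean + sd * z
        if vals.min() >= lo - 1e-12 and vals.max() <= hi + 1e-12:
            return vals
        z = np.clip(vals, lo, hi)
        z = (z - mean) / sd
    raise ConfigurationError(
        "beta standardization did not settle inside the printed range"
    )


def _sample_covariates(n_cases: int, cfg: GeneratorConfig, rng: np.random.Generator):
    """Patient-level covariates; two cases (left + right) per patient."""
    n_patients = (n_cases + 1) // 2
    n_female = int(round(cfg.female_fraction * n_patients))
    sexes = np.array(["F"] * n_female + ["M"] * (n_patients - n_female))
    rng.shuffle(sexes)
    ages = rng.normal(cfg.age_mean, cfg.age_sd, size=n_patients)
    bmis = rng.normal(cfg.bmi_mean, cfg.bmi_sd, size=n_patients)
    rows = []
    for i in range(n_patients):
        for side in ("left", "right"):
            if len(rows) < n_cases:
                rows.append(
                    dict(
                        patient=i + 1,
                        side=side,
                        sex=str(sexes[i]),
                        age=float(ages[i]),
                        bmi=float(bmis[i]),
                    )
                )
    return rows


def build_paper_fixture(config: Optional[GeneratorConfig] = None) -> List[LumbarCase]:
    """The 40-case calibrated cohort (or config.n cases of it).

    Per-case d, L1, L2 targets are quantile-matched to the published
    five-number summaries and paired comonotonically (which also plants the
    published positive d-L1 association); beta is standardized to the
    published mean/SD and paired anti-monotonically with L1 (planting the
    published negative beta-L1 association).  Covariates and the
    case-to-target assignment are seeded draws.  The marginals are
    calibrated; the joint structure is an artifact of this pairing and can
    be broken with ``shuffle_pairing``.
    """
    cfg = config or GeneratorConfig()
    if cfg.mode != "paper_fixture":
        raise ConfigurationError("build_paper_fixture requires mode='paper_fixture'")
    n = cfg.n
    rng = np.random.default_rng(cfg.seed)
    d_vals = quantile_match(FiveNumberSummary(*D_SUMMARY_MM), n, cfg.seed)
    l1_vals = quantile_match(FiveNumberSummary(*L1_SUMMARY_MM), n, cfg.seed)
    l2_vals = quantile_match(FiveNumberSummary(*L2_SUMMARY_MM), n, cfg.seed)
    betas = standardized_beta_sample(n, rng)
    if cfg.shuffle_pairing:
        betas = rng.permutation(betas)
    else:
        betas = np.sort(betas)[::-1]  # anti-monotone with the sorted L1 targets

    covs = _sample_covariates(n, cfg, rng)
    order = rng.permutation(n)  # which target quadruple each case receives
    cases = []
    for idx, cov in enumerate(covs):
        k = order[idx]
        targets = TargetQuadruple(
            d=float(d_vals[k]), beta=float(betas[k]),
            L1=float(l1_vals[k]), L2=float(l2_vals[k]),
        )
        case_id = f"P{cov['patient']:02d}-{cov['side'][0].upper()}"
        cases.append(
            invert_case(
                targets,
                cfg,
                case_id=case_id,
                side=cov["side"],
                sex=cov["sex"],
                age=cov["age"],
                bmi=cov["bmi"],
            )
        )
    return cases


def sample_parametric_cohort(config: Optional[GeneratorConfig] = None) -> List[LumbarCase]:
    """Unconstrained simulation cohort.

    Triangle legs and beta are drawn from the configured normals; optional
    isotropic jitter perturbs the triangle vertices, with rejection keeping
    the right angle within tolerance.
    """
    cfg = config or GeneratorConfig(mode="parametric")
    if cfg.mode != "parametric":
        raise ConfigurationError("sample_parametric_cohort requires mode='parametric'")
    rng = np.random.default_rng(cfg.seed)
    covs = _sample_covariates(cfg.n, cfg, rng)
    cases: List[LumbarCase] = []
    attempts = 0
    while len(cases) < cfg.n:
        attempts += 1
        if attempts > max(100, 100 * cfg.n):
            raise ConfigurationError(
                f"rejection rate too high: {len(cases)} cases in {attempts} attempts"
            )
        height = rng.normal(cfg.height_mean, cfg.height_sd)
        base = rng.normal(cfg.base_mean, cfg.base_sd)
        beta = rng.normal(cfg.beta_mean, cfg.beta_sd)
        if height <= 1.0 or base <= 1.0 or not (0.0 < beta < 80.0):
            continue
        hyp = math.hypot(base, height)
        d = base + height - hyp
        aspect = base / height
        targets = TargetQuadruple(d=d, beta=beta, L1=0.0, L2=0.0)
        layout_cfg = replace(cfg, leg_aspect=aspect)
        O, tip, e_lat, e_sup, A, B, C = _layout(targets, layout_cfg)
        if cfg.vertex_jitter > 0:
            A = A + rng.normal(0.0, cfg.vertex_jitter, 3)
            B = B + rng.normal(0.0, cfg.vertex_jitter, 3)
            C = C + rng.normal(0.0, cfg.vertex_jitter, 3)
            va, vb = A - C, B - C
            ang = math.degrees(
                math.atan2(np.linalg.norm(np.cross(va, vb)), float(np.dot(va, vb)))
            )
            if abs(ang - 90.0) > 2.0:
                continue
        cov = covs[len(cases)]
        # direct assembly (no solver): wire offset zero, jittered vertices
        case = _assemble_case(
            A, B, C, O, tip, e_lat, e_sup, layout_cfg,
            case_id=f"S{cov['patient']:03d}-{cov['side'][0].upper()}",
            side=cov["side"], sex=cov["sex"], age=cov["age"], bmi=cov["bmi"],
        )
        cases.append(case)
    return cases


def _assemble_case(A, B, C, O, tip, e_lat, e_sup, cfg: GeneratorConfig, **meta):
    """Shared landmark assembly for the parametric sampler (offset zero)."""
    hw, hd = cfg.disc_width / 2.0, cfg.disc_depth / 2.0
    disc_corners = np.array(
        [[-hw, -hd, 0.0], [hw, -hd, 0.0], [hw, hd, 0.0], [-hw, hd, 0.0]]
    )
    E = np.array([0.0, cfg.e_distance, 0.0])
    posterior = -tip
    y_patch = O[1] + cfg.facet_offset
    s = (y_patch - O[1]) / posterior[1]
    J = O + s * posterior
    half = cfg.facet_patch_size / 2.0
    in_quadrant = min(3.0, half / 2.0)
    center = J - in_quadrant * np.array([1.0, 0.0, 0.0]) - in_quadrant * e_sup
    patch = PlanePatch(
        origin=center,
        u_axis=np.array([1.0, 0.0, 0.0]),
        v_axis=np.array([0.0, 0.0, 1.0]),
        u_range=(-half, half),
        v_range=(-half, half),
    )
    facet_landmarks = {
        "upper_vertex_L5": patch.from_uv(0.0, half),
        "lower_edge_L4": patch.from_uv(0.0, -half),
        "lateral_edge_facet": patch.from_uv(half, 0.0),
        "lateral_edge_exiting_root": patch.from_uv(-half, 0.0),
    }
    return LumbarCase(
        A=A, B=B, C=C, disc_corners=disc_corners, E=E,
        facet_landmarks=facet_landmarks, facet_patch=patch,
        wire_offset=(0.0, 0.0), **meta,
    )
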