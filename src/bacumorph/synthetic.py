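"""Synthetic bone phantoms and simulated RIL panels.

The phantom emulates the gross geometry of a mouse baculum: an elongate,
slightly dorsally bowed bone, broad at the proximal base and tapering
distally, with a hollow medullary core.  It is built from superellipse
cross-sections swept along a circular-arc centerline, filled with interior
points (micro-CT segmentation keeps internal structure, not just the
surface), jittered with Gaussian noise and returned in a random rigid pose
so that the alignment stage is always exercised.  Superellipse sections have
closed-form extremes, which gives independent oracles for the leftmost /
rightmost / dorsal / ventral semilandmarks.

RIL panels are simulated as two-state Markov chains along the marker map
with sib-mating-expanded recombination fractions r* = 4r/(1+6r), planted
additive QTL, Gaussian residuals and masked missing genotypes.

Every generator is a pure function of (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .pointcloud import PointCloud
from .qtl import Marker, RILPanel, haldane_r, ril_expansion

# ---------------------------------------------------------------------------
# bone phantoms


@dataclass(frozen=True)
class BonePhantomParams:
    """Geometry and sampling parameters of one synthetic bone.

    Lengths are in millimetres (a mouse baculum is ~5-8 mm long).  The
    default point count (2e4) keeps phantoms fast; raise it toward the
    ~1.75e5 points of a real micro-CT segmentation where realism matters.
    """

    length: float = 7.0
    base_width: float = 1.0
    base_height: float = 0.7
    tip_width_frac: float = 0.45  # width multiplier at the distal tip
    tip_height_frac: float = 0.55
    curvature: float = 0.25  # sagitta of the dorsal bow of the centerline
    cavity_frac: float = 0.35  # relative size of the hollow medullary core
    superellipse_exponent: float = 2.0
    n_points: int = 20_000
    noise_sd: float = 0.008
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("length", "base_width", "base_height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.cavity_frac < 1:
            raise ValueError("cavity_frac must be in [0, 1)")
        if self.n_points < 100:
            raise ValueError("n_points must be >= 100")


def _arc_offset(z: np.ndarray, length: float, sagitta: float) -> np.ndarray:
    """Dorsal (y) offset of a circular-arc centerline with the given sagitta."""
    if sagitta == 0:
        return np.zeros_like(z)
    half = length / 2.0
    radius = (half**2 + sagitta**2) / (2.0 * sagitta)
    return np.sqrt(radius**2 - (z - half) ** 2) - (radius - sagitta)


def generate_bone(
    params: BonePhantomParams,
    random_pose: bool = True,
    rng: np.random.Generator | None = None,
    specimen_id: str = "phantom",
    meta: dict | None = None,
) -> PointCloud:
    """Sample one bone phantom as a point cloud.

    Cross-sections are superellipses |2u/w|^p + |2v/h|^p <= 1 whose width w
    and height h taper linearly from base to tip; points inside the scaled
    cavity superellipse (factor ``cavity_frac``) are excluded, leaving a
    hollow core.  The section is offset dorsally by a circular arc of
    sagitta ``curvature`` and jittered by isotropic Gaussian noise.
    """
    rng = rng or np.random.default_rng(params.seed)
    p = params.superellipse_exponent
    pts: list[np.ndarray] = []
    need = params.n_points
    while need > 0:
        m = max(2 * need, 1000)
        s = rng.uniform(0.0, 1.0, m)
        u = rng.uniform(-0.5, 0.5, m)
        v = rng.uniform(-0.5, 0.5, m)
        rho = (np.abs(2 * u) ** p + np.abs(2 * v) ** p) ** (1.0 / p)
        keep = (rho <= 1.0) & (rho >= params.cavity_frac)
        s, u, v = s[keep], u[keep], v[keep]
        w = params.base_width * (1.0 - (1.0 - params.tip_width_frac) * s)
        h = params.base_height * (1.0 - (1.0 - params.tip_height_frac) * s)
        z = s * params.length
        x = u * w
        y = v * h + _arc_offset(z, params.length, params.curvature)
        batch = np.column_stack([x, y, z])
        pts.append(batch[:need])
        need -= len(batch)
    points = np.vstack(pts)
    if params.noise_sd > 0:
        points = points + rng.normal(0.0, params.noise_sd, points.shape)
    if random_pose:
        # uniform random proper rotation via QR of a Gaussian matrix
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        t = rng.uniform(-params.length, params.length, 3)
        points = points @ q.T + t
    return PointCloud(points=points, specimen_id=specimen_id, meta=dict(meta or {}))


def b6_like_params(n_points: int = 20_000, seed: int = 0) -> BonePhantomParams:
    """Parental preset: a shorter, broader bone with a pronounced
    dorsoventral bow (the curved parental extreme)."""
    return BonePhantomParams(
        length=7.0, base_width=1.05, tip_width_frac=0.50, curvature=0.30,
        n_points=n_points, seed=seed,
    )


def d2_like_params(n_points: int = 20_000, seed: int = 0) -> BonePhantomParams:
    """Parental preset: a longer, slimmer, nearly straight bone (the
    straight parental extreme)."""
    return BonePhantomParams(
        length=7.6, base_width=0.90, tip_width_frac=0.38, curvature=0.10,
        n_points=n_points, seed=seed,
    )


def interpolate_params(
    p1: BonePhantomParams, p2: BonePhantomParams, t: float
) -> BonePhantomParams:
    """Field-wise linear interpolation of two phantom parameter sets."""
    kwargs = {}
    for f in fields(BonePhantomParams):
        a, b = getattr(p1, f.name), getattr(p2, f.name)
        if f.name == "seed":
            kwargs[f.name] = p1.seed
        elif f.name == "n_points":
            kwargs[f.name] = int(round((1 - t) * a + t * b))
        else:
            kwargs[f.name] = (1 - t) * a + t * b
    return BonePhantomParams(**kwargs)


def generate_morph_continuum(
    p1: BonePhantomParams,
    p2: BonePhantomParams,
    t_values: list[float],
    seed: int = 0,
) -> list[PointCloud]:
    """Phantoms interpolated between two parental parameter sets.

    t = 0 reproduces the first parent's distribution, t = 1 the second's;
    intermediate t mixes every numeric parameter linearly.
    """
    rng = np.random.default_rng(seed)
    clouds = []
    for i, t in enumerate(t_values):
        if not 0 <= t <= 1:
            raise ValueError(f"t values must lie in [0, 1], got {t}")
        params = interpolate_params(p1, p2, t)
        child = np.random.default_rng(rng.integers(2**31))
        clouds.append(
            generate_bone(
                params,
                rng=child,
                specimen_id=f"morph_{i}_t{t:.3f}",
                meta={"t": t},
            )
        )
    return clouds


@dataclass(frozen=True)
class ReplicateJitter:
    """Scan-replicate jitter: the specimen is removed and reloaded, so each
    scan sees a slightly different pose and point noise."""

    rotation_sd: float = 0.05  # radians
    translation_sd: float = 0.2
    noise_sd: float = 0.005


def generate_replicates(
    cloud: PointCloud,
    n: int,
    jitter: ReplicateJitter = ReplicateJitter(),
    seed: int = 0,
) -> list[PointCloud]:
    """n repeat "scans" of one bone under independent small rigid motions
    plus per-point Gaussian noise."""
    if n < 2:
        raise ValueError("need n >= 2 replicates")
    rng = np.random.default_rng(seed)
    out = []
    for r in range(n):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.normal(0.0, jitter.rotation_sd)
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        t = rng.normal(0.0, jitter.translation_sd, 3)
        pts = cloud.points @ R.T + t
        if jitter.noise_sd > 0:
            pts = pts + rng.normal(0.0, jitter.noise_sd, pts.shape)
        out.append(
            PointCloud(
                points=pts,
                voxel_size=cloud.voxel_size,
                specimen_id=f"{cloud.specimen_id}_rep{r}",
                meta={**cloud.meta, "replicate_group": cloud.specimen_id},
            )
        )
    return out


# ---------------------------------------------------------------------------
# RIL panels


@dataclass(frozen=True)
class PlantedQTL:
    marker: str
    effect: float  # half the difference between homozygous classes
    trait: str = "CS"


@dataclass(frozen=True)
class PanelSimParams:
    """Simulated RIL panel dimensions and planted genetic architecture."""

    n_strains: int = 70
    n_chromosomes: int = 5
    markers_per_chromosome: int = 20
    chromosome_length_cm: float = 95.0
    qtl: tuple[PlantedQTL, ...] = ()
    residual_sd: float = 1.0
    missing_rate: float = 0.022
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate <= 0.5:
            raise ValueError("missing_rate must be in [0, 0.5]")
        for q in self.qtl:
            if not np.isfinite(q.effect):
                raise ValueError("QTL effects must be finite")


def effect_for_h2(h2: float, residual_sd: float = 1.0) -> float:
    """Additive effect giving a planted QTL the target fraction of
    strain-mean variance (genetic variance of a +/-a biallelic QTL is a^2)."""
    if not 0 < h2 < 1:
        raise ValueError("h2 must be in (0, 1)")
    return residual_sd * np.sqrt(h2 / (1.0 - h2))


@dataclass
class PanelTruth:
    qtl: tuple[PlantedQTL, ...]
    qtl_chromosomes: dict
    residual_sd: float
    marker_spacing_cm: float


def generate_panel(params: PanelSimParams) -> tuple[RILPanel, PanelTruth]:
    """Simulate a RIL panel with planted additive QTL.

    Genotypes follow a two-state Markov chain along each chromosome with
    transition probability equal to the RIL-expanded recombination fraction
    between adjacent markers; each chromosome starts from a fair coin, so
    the genome-wide second-parent allele fraction is 0.5 in expectation.
    Phenotypes are the sum of planted effects (+a for the second parent's
    allele, -a for the first's, using the true unmasked genotypes) plus
    Gaussian residuals; genotypes are then masked at ``missing_rate``.
    """
    rng = np.random.default_rng(params.seed)
    markers: list[Marker] = []
    for c in range(params.n_chromosomes):
        pos = np.linspace(0.0, params.chromosome_length_cm, params.markers_per_chromosome)
        markers.extend(
            Marker(f"m{c + 1}_{j + 1}", f"chr{c + 1}", float(p))
            for j, p in enumerate(pos)
        )
    spacing = params.chromosome_length_cm / max(params.markers_per_chromosome - 1, 1)
    r_star = float(ril_expansion(haldane_r(spacing)))

    n, m = params.n_strains, len(markers)
    geno = np.empty((n, m))
    col = 0
    for _ in range(params.n_chromosomes):
        g = rng.random(n) < 0.5
        for j in range(params.markers_per_chromosome):
            if j > 0:
                g = g ^ (rng.random(n) < r_star)
            geno[:, col] = g
            col += 1

    marker_col = {mk.name: i for i, mk in enumerate(markers)}
    traits = sorted({q.trait for q in params.qtl}) or ["CS"]
    phenotypes = {}
    for trait in traits:
        y = rng.normal(0.0, params.residual_sd, n)
        for q in params.qtl:
            if q.trait != trait:
                continue
            if q.marker not in marker_col:
                raise KeyError(f"planted QTL marker {q.marker!r} not in map")
            y = y + q.effect * (2.0 * geno[:, marker_col[q.marker]] - 1.0)
        phenotypes[trait] = y

    masked = geno.copy()
    if params.missing_rate > 0:
        masked[rng.random(geno.shape) < params.missing_rate] = np.nan

    panel = RILPanel(
        strains=[f"BXD{i + 1:03d}" for i in range(n)],
        markers=markers,
        genotypes=masked,
        phenotypes=phenotypes,
    )
    truth = PanelTruth(
        qtl=params.qtl,
        qtl_chromosomes={
            q.marker: markers[marker_col[q.marker]].chromosome for q in params.qtl
        },
        residual_sd=params.residual_sd,
        marker_spacing_cm=spacing,
    )
    return panel, truth


# ---------------------------------------------------------------------------
# strain phenotype tables for estimator checks


def generate_strain_phenotypes(
    n_strains: int,
    n_per_strain: int,
    h2: float,
    seed: int = 0,
    trait: str = "CS",
    mode: str = "exact",
    baseline: float = 0.0,
) -> pd.DataFrame:
    """Tidy per-individual phenotype table with a planted strain-variance
    fraction.

    mode='exact' standardises the realized strain effects and within-strain
    residuals so that the realized between-strain fraction of the total sum
    of squares equals ``h2`` exactly — the natural oracle for an estimator
    that is *defined* as that SS fraction.  mode='sampled' draws strain
    effects ~ N(0, h2) and residuals ~ N(0, 1 - h2) instead, so the
    realized fraction varies (and the SS-fraction estimator exceeds h2 in
    expectation, since between-strain SS absorbs within-strain noise).
    """
    if not 0 < h2 < 1:
        raise ValueError("h2 must be in (0, 1)")
    rng = np.random.default_rng(seed)
    strains = np.repeat([f"S{i:03d}" for i in range(n_strains)], n_per_strain)
    if mode == "sampled":
        g = rng.normal(0.0, np.sqrt(h2), n_strains)
        e = rng.normal(0.0, np.sqrt(1.0 - h2), n_strains * n_per_strain)
        y = np.repeat(g, n_per_strain) + e
    elif mode == "exact":
        e = rng.normal(size=(n_strains, n_per_strain))
        e = e - e.mean(axis=1, keepdims=True)  # kill within-group mean noise
        ssw = np.sum(e**2)
        u = rng.normal(size=n_strains)
        u = u - u.mean()
        ssb = n_per_strain * np.sum(u**2)
        u *= np.sqrt((ssw * h2 / (1.0 - h2)) / ssb)
        y = (np.repeat(u, n_per_strain) + e.ravel())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame({"strain": strains, trait: baseline + y})


def strain_params_from_genotype(
    base: BonePhantomParams,
    genotype: float,
    length_effect_frac: float = 0.05,
    curvature_effect_frac: float = 0.0,
) -> BonePhantomParams:
    """Strain-specific phantom parameters from a biallelic genotype.

    The second parent's allele (genotype 1) lengthens the bone by
    ``length_effect_frac`` and the first shortens it, scaling size; a
    curvature effect can likewise plant a shape difference.
    """
    sign = 2.0 * genotype - 1.0
    return replace(
        base,
        length=base.length * (1.0 + sign * length_effect_frac),
        curvature=base.curvature * (1.0 + sign * curvature_effect_frac),
    )
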