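"""Synthetic cumulus–oocyte-complex images and radial profiles with ground truth.

Every downstream stage of the pipeline (segmentation, radial profiling,
breakpoint regression, intensity statistics, body counting) is exercised on
scenes generated here, where the truth is known by construction:

* a large spherical oocyte (default diameter 115 µm) whose organelle puncta
  follow a stage-dependent radial density — a perinuclear cluster in GV-like
  cells that leaves an organelle-free zone below the cortex, a broader or
  central cluster in MII-like cells;
* a ring of small (~10 µm) cumulus cells attached outside the oocyte, with
  independently controlled intensity;
* optional bright refractile-body inclusions;
* an isotropic-in-xy Gaussian PSF (3x wider axially), Poisson shot noise and
  Gaussian read noise, and per-donor multiplicative intensity effects.

Radial densities are mixtures of a uniform component, a central uniform ball
("cluster") and a Gaussian shell, so the resulting mean-versus-distance curve
has a known change point; 1D profiles with an exactly planted two-segment
breakpoint are generated separately by :func:`simulate_profile`.

All generators are deterministic: the same truth object (including its seed)
yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry_io import ImageStack

__all__ = [
    "ProfileTruth",
    "ChannelSpec",
    "BodyTruth",
    "SceneTruth",
    "EffectSpec",
    "simulate_profile",
    "simulate_oocyte_stack",
    "simulate_coc_dataset",
    "gv_like_scene",
    "mii_like_scene",
    "with_gains",
]


# ---------------------------------------------------------------------------
# 1D profiles with a planted breakpoint


@dataclass(frozen=True)
class ProfileTruth:
    """Ground truth for a two-segment radial profile.

    The noiseless curve is ``intercept + slope_left * x`` up to the
    breakpoint ``psi_true`` and continues with ``slope_right`` beyond it;
    i.i.d. Gaussian noise of SD ``noise_sd`` is added on top.
    """

    psi_true: float
    slope_left: float = -0.01
    slope_right: float = -0.03
    intercept: float = 1.0
    noise_sd: float = 0.0
    n_points: int = 300
    x_max: float = 57.5
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.psi_true < self.x_max):
            raise ValueError(
                f"psi_true={self.psi_true} must lie strictly inside (0, {self.x_max})"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_points < 5:
            raise ValueError("n_points must be at least 5")


def piecewise_line(x: np.ndarray, truth: ProfileTruth) -> np.ndarray:
    """Noiseless continuous two-segment line described by ``truth``."""
    x = np.asarray(x, dtype=float)
    return (
        truth.intercept
        + truth.slope_left * np.minimum(x, truth.psi_true)
        + truth.slope_right * np.clip(x - truth.psi_true, 0.0, None)
    )


def simulate_profile(truth: ProfileTruth) -> tuple[np.ndarray, np.ndarray]:
    """Sample a noisy two-segment profile on an even distance grid.

    Returns ``(distances, intensities)``; identical truth (same seed) gives
    bit-identical arrays.
    """
    x = np.linspace(0.0, truth.x_max, truth.n_points)
    y = piecewise_line(x, truth)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        y = y + rng.normal(0.0, truth.noise_sd, size=x.shape)
    return x, y


# ---------------------------------------------------------------------------
# 3D scenes


@dataclass(frozen=True)
class ChannelSpec:
    """Radial organelle density and brightness for one probe channel.

    The density over the cell is a mixture: ``cluster_weight`` of puncta fall
    uniformly inside a central ball of radius ``cluster_radius_um``,
    ``shell_weight`` in a Gaussian shell at ``shell_radius_um`` (SD
    ``shell_sigma_um``), and the remainder uniformly in the whole cell.
    ``punctum_amplitude`` is the PSF peak intensity of one punctum (a.u.).
    """

    name: str
    n_puncta: int = 1500
    punctum_amplitude: float = 2000.0
    cluster_radius_um: float = 30.0
    cluster_weight: float = 0.9
    shell_radius_um: float | None = None
    shell_weight: float = 0.0
    shell_sigma_um: float = 2.0

    def __post_init__(self):
        if self.n_puncta < 0 or self.punctum_amplitude < 0:
            raise ValueError("puncta count and amplitude must be non-negative")
        w = (self.cluster_weight, self.shell_weight)
        if any(v < 0 for v in w) or sum(w) > 1 + 1e-9:
            raise ValueError("component weights must be non-negative and sum to <= 1")
        if self.shell_weight > 0 and self.shell_radius_um is None:
            raise ValueError("shell_weight > 0 requires shell_radius_um")
        if self.cluster_radius_um <= 0:
            raise ValueError("cluster_radius_um must be positive")


@dataclass(frozen=True)
class BodyTruth:
    """A planted refractile body: bright sphere inside the oocyte."""

    centre_um: tuple[float, float, float]  # (x, y, z) relative to cell centre
    diameter_um: float
    intensity: dict  # channel name -> added level (a.u.)

    def __post_init__(self):
        if self.diameter_um <= 0:
            raise ValueError("body diameter must be positive")


@dataclass(frozen=True)
class SceneTruth:
    """Full ground truth of one synthetic cumulus–oocyte-complex stack."""

    stage_label: str = "GV-like"
    cell_radius_um: float = 57.5
    nucleus_radius_um: float = 12.0
    nucleus_offset_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    channels: tuple[ChannelSpec, ...] = ()
    psf_sigma_um: float = 0.3
    psf_z_factor: float = 3.0
    background: float = 500.0  # cytoplasmic baseline inside the cell (a.u.)
    outside_level: float = 5.0  # medium level outside all cells
    donor_multiplier: float = 1.0
    oocyte_gain: float = 1.0  # stage / treatment multiplier on oocyte signal
    cumulus_gain: float = 1.0
    n_cumulus: int = 10
    cumulus_radius_um: float = 5.0
    zona_gap_um: float = 10.0  # oocyte-to-cumulus gap (zona pellucida width)
    cumulus_intensity: float | dict | None = None
    oocyte_to_cumulus_ratio: float | None = None
    n_dead_cumulus: int = 0
    dead_channel: str = "tmre"
    bodies: tuple[BodyTruth, ...] = ()
    pixel_size_um: float = 0.4
    z_step_um: float = 2.0
    margin_um: float = 25.0
    read_noise_sd: float = 3.0
    poisson: bool = True
    seed: int = 0
    noise_seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if min(self.cell_radius_um, self.nucleus_radius_um) <= 0:
            raise ValueError("all radii must be positive")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("voxel calibration must be positive")
        off = np.linalg.norm(self.nucleus_offset_um)
        if off + self.nucleus_radius_um > self.cell_radius_um:
            raise ValueError("nucleus must lie fully inside the cell")
        if self.n_dead_cumulus > self.n_cumulus:
            raise ValueError("n_dead_cumulus cannot exceed n_cumulus")
        for body in self.bodies:
            r = np.linalg.norm(body.centre_um) + body.diameter_um / 2
            if r > self.cell_radius_um:
                raise ValueError("bodies must lie fully inside the cell")
        if self.oocyte_to_cumulus_ratio is not None and self.oocyte_to_cumulus_ratio <= 0:
            raise ValueError("oocyte_to_cumulus_ratio must be positive")


def _sample_radii(spec: ChannelSpec, cell_r: float, rng) -> np.ndarray:
    """Sample punctum distances from the mixture radial density."""
    n = spec.n_puncta
    w_uniform = max(1.0 - spec.cluster_weight - spec.shell_weight, 0.0)
    comp = rng.choice(
        3, size=n, p=np.array([spec.cluster_weight, spec.shell_weight, w_uniform])
    )
    r = np.empty(n)
    u = rng.uniform(size=n)
    ball = comp == 0
    r[ball] = spec.cluster_radius_um * np.cbrt(u[ball])
    shell = comp == 1
    if shell.any():
        # The shell is a Gaussian ridge in *volume* (intensity) density, so
        # the per-radius density carries an r^2 factor: sample by rejection.
        n_shell = int(shell.sum())
        mu, sg = spec.shell_radius_um, spec.shell_sigma_um
        r_ref = min(mu + 4 * sg, cell_r * 0.999)
        out = np.empty(0)
        for _ in range(200):
            if out.size >= n_shell:
                break
            prop = rng.normal(mu, sg, size=2 * n_shell)
            prop = prop[(prop > 0) & (prop <= cell_r * 0.999)]
            accept = rng.uniform(size=prop.size) <= (prop / r_ref) ** 2
            out = np.concatenate([out, prop[accept]])
        if out.size < n_shell:
            raise RuntimeError("shell radius sampling failed to converge")
        r[shell] = out[:n_shell]
    uni = comp == 2
    r[uni] = cell_r * 0.999 * np.cbrt(u[uni])
    return r


def sample_puncta(truth: SceneTruth, spec: ChannelSpec, rng) -> np.ndarray:
    """Sample punctum centres (x, y, z in µm, relative to the cell centre).

    Positions are drawn from the channel's radial density with isotropic
    direction, and redrawn if they land inside the nucleus.
    """
    pts = np.empty((0, 3))
    nuc = np.asarray(truth.nucleus_offset_um)
    need = spec.n_puncta
    for _ in range(100):
        if need == 0:
            break
        sub = replace(spec, n_puncta=need)
        r = _sample_radii(sub, truth.cell_radius_um, rng)
        direction = rng.normal(size=(need, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        cand = direction * r[:, None]
        ok = np.linalg.norm(cand - nuc, axis=1) >= truth.nucleus_radius_um
        pts = np.vstack([pts, cand[ok]])
        need = spec.n_puncta - len(pts)
    if need > 0:
        raise RuntimeError("puncta rejection sampling failed to converge")
    return pts


def _render_puncta(expect, pts_um, amplitude, coords, truth):
    """Add Gaussian PSF spots at sub-voxel positions (in place)."""
    zs_um, ys_um, xs_um = coords
    sx = truth.psf_sigma_um
    sz = truth.psf_sigma_um * truth.psf_z_factor
    hx = max(int(np.ceil(3 * sx / truth.pixel_size_um)), 1)
    hz = max(int(np.ceil(3 * sz / truth.z_step_um)), 1)
    nz, ny, nx = expect.shape
    cz0 = (nz - 1) / 2
    cy0 = (ny - 1) / 2
    cx0 = (nx - 1) / 2
    for x, y, z in pts_um:
        iz = int(round(cz0 + z / truth.z_step_um))
        iy = int(round(cy0 + y / truth.pixel_size_um))
        ix = int(round(cx0 + x / truth.pixel_size_um))
        zsl = slice(max(iz - hz, 0), min(iz + hz + 1, nz))
        ysl = slice(max(iy - hx, 0), min(iy + hx + 1, ny))
        xsl = slice(max(ix - hx, 0), min(ix + hx + 1, nx))
        dz = (zs_um[zsl] - z) / sz
        dy = (ys_um[ysl] - y) / sx
        dx = (xs_um[xsl] - x) / sx
        g = np.exp(
            -0.5
            * (
                dz[:, None, None] ** 2
                + dy[None, :, None] ** 2
                + dx[None, None, :] ** 2
            )
        )
        expect[zsl, ysl, xsl] += amplitude * g


def simulate_oocyte_stack(truth: SceneTruth) -> tuple[ImageStack, SceneTruth]:
    """Render one cumulus–oocyte-complex stack from its ground truth.

    Returns the noisy calibrated :class:`~ooquant.geometry_io.ImageStack`
    together with a resolved copy of the truth (cumulus intensity levels and
    punctum centres filled in, under ``metadata['puncta_um']``).
    """
    if not truth.channels:
        raise ValueError("scene needs at least one channel")
    rng = np.random.default_rng([truth.seed, 11])
    noise_seed = truth.seed if truth.noise_seed is None else truth.noise_seed
    rng_noise = np.random.default_rng([noise_seed, 23])

    px, pz = truth.pixel_size_um, truth.z_step_um
    half_xy = truth.cell_radius_um + truth.margin_um
    half_z = truth.cell_radius_um + 2 * pz
    nx = ny = 2 * int(round(half_xy / px)) + 1
    nz = 2 * int(round(half_z / pz)) + 1
    xs_um = (np.arange(nx) - (nx - 1) / 2) * px
    ys_um = (np.arange(ny) - (ny - 1) / 2) * px
    zs_um = (np.arange(nz) - (nz - 1) / 2) * pz
    r2 = (
        zs_um[:, None, None] ** 2
        + ys_um[None, :, None] ** 2
        + xs_um[None, None, :] ** 2
    )
    cell = r2 <= truth.cell_radius_um**2

    # Cumulus cells: evenly spaced on an equatorial ring outside the zona.
    ring_r = truth.cell_radius_um + truth.zona_gap_um + truth.cumulus_radius_um
    angles = 2 * np.pi * (np.arange(truth.n_cumulus) + rng.uniform(0, 1)) / max(
        truth.n_cumulus, 1
    )
    cum_centres = [
        (ring_r * np.cos(a), ring_r * np.sin(a), 0.0) for a in angles
    ]
    cum_masks = []
    for cx_um, cy_um, cz_um in cum_centres:
        d2 = (
            (zs_um[:, None, None] - cz_um) ** 2
            + (ys_um[None, :, None] - cy_um) ** 2
            + (xs_um[None, None, :] - cx_um) ** 2
        )
        cum_masks.append(d2 <= truth.cumulus_radius_um**2)
    cum_z_slices = np.abs(zs_um) <= truth.cumulus_radius_um

    puncta_record: dict[str, np.ndarray] = {}
    expectations = []
    resolved_levels: dict[str, float] = {}
    for spec in truth.channels:
        expect = np.full((nz, ny, nx), float(truth.outside_level))
        expect[cell] = truth.background * truth.oocyte_gain
        pts = sample_puncta(truth, spec, rng)
        puncta_record[spec.name] = pts
        if spec.n_puncta and spec.punctum_amplitude > 0:
            _render_puncta(
                expect,
                pts,
                spec.punctum_amplitude * truth.oocyte_gain,
                (zs_um, ys_um, xs_um),
                truth,
            )
        for body in truth.bodies:
            level = body.intensity.get(spec.name, 0.0)
            if level:
                bx, by, bz = body.centre_um
                d2 = (
                    (zs_um[:, None, None] - bz) ** 2
                    + (ys_um[None, :, None] - by) ** 2
                    + (xs_um[None, None, :] - bx) ** 2
                )
                expect[d2 <= (body.diameter_um / 2) ** 2] += level * truth.oocyte_gain

        # Cumulus intensity: explicit level, or derived from the planted
        # oocyte:cumulus mean-intensity ratio over the slices both occupy.
        if isinstance(truth.cumulus_intensity, dict):
            level = float(truth.cumulus_intensity.get(spec.name, 0.0))
        elif truth.cumulus_intensity is not None:
            level = float(truth.cumulus_intensity)
        elif truth.oocyte_to_cumulus_ratio is not None:
            band = expect[cum_z_slices][cell[cum_z_slices]]
            level = float(band.mean()) / truth.oocyte_to_cumulus_ratio
        else:
            level = truth.background
        resolved_levels[spec.name] = level
        for i, m in enumerate(cum_masks):
            dead = i < truth.n_dead_cumulus and spec.name == truth.dead_channel
            expect[m] = 0.0 if dead else level * truth.cumulus_gain
        expectations.append(expect)

    vol = np.stack(expectations, axis=-1) * truth.donor_multiplier
    if truth.poisson:
        vol = rng_noise.poisson(vol).astype(np.float64)
    if truth.read_noise_sd > 0:
        vol = vol + rng_noise.normal(0.0, truth.read_noise_sd, size=vol.shape)
    vol = np.clip(vol, 0.0, None).astype(np.float32)

    meta = dict(truth.metadata)
    meta.setdefault("stage", "GV" if truth.stage_label.startswith("GV") else "MII")
    stack = ImageStack(
        vol, px, pz, [c.name for c in truth.channels], metadata=meta
    )
    resolved = replace(
        truth,
        cumulus_intensity=resolved_levels,
        metadata={**meta, "puncta_um": puncta_record},
    )
    return stack, resolved


def with_gains(
    truth: SceneTruth, oocyte_factor: float, cumulus_factor: float, noise_seed: int
) -> SceneTruth:
    """Paired re-imaging of the same scene with scaled compartment signal.

    Organelle positions are preserved (same scene seed); only the oocyte and
    cumulus intensity gains and the noise realisation change — e.g. probe
    retention after an efflux-blocker (verapamil) treatment.  Use on a
    resolved truth so the cumulus level is fixed rather than re-derived.
    """
    return replace(
        truth,
        oocyte_gain=truth.oocyte_gain * oocyte_factor,
        cumulus_gain=truth.cumulus_gain * cumulus_factor,
        noise_seed=noise_seed,
        metadata={k: v for k, v in truth.metadata.items() if k != "puncta_um"},
    )


# ---------------------------------------------------------------------------
# Stage presets and cohort datasets


def _default_channels(stage: str, cluster_radius: float | None, **ch_kwargs):
    ch_kwargs.setdefault("cluster_weight", 0.95)
    if stage == "GV-like":
        cr = 30.0 if cluster_radius is None else cluster_radius
        return (
            ChannelSpec("lysotracker", cluster_radius_um=cr, **ch_kwargs),
            ChannelSpec("tmre", cluster_radius_um=cr, **ch_kwargs),
        )
    cr = 50.0 if cluster_radius is None else cluster_radius
    return (
        ChannelSpec("lysotracker", cluster_radius_um=min(cr, 20.0), **ch_kwargs),
        ChannelSpec("tmre", cluster_radius_um=cr, **ch_kwargs),
    )


def gv_like_scene(
    seed: int = 0, cluster_radius: float | None = None, **overrides
) -> SceneTruth:
    """GV-stage preset: perinuclear organelle cluster (default radius 30 µm)."""
    channels = overrides.pop(
        "channels", _default_channels("GV-like", cluster_radius)
    )
    return SceneTruth(stage_label="GV-like", channels=channels, seed=seed, **overrides)


def mii_like_scene(
    seed: int = 0, cluster_radius: float | None = None, **overrides
) -> SceneTruth:
    """MII-stage preset: dispersed mitochondria, centrally clustered lysosomes.

    The germinal vesicle has broken down by MII, so no nuclear exclusion
    zone remains (token 1 µm nucleus keeps the geometry well-defined).
    """
    channels = overrides.pop(
        "channels", _default_channels("MII-like", cluster_radius)
    )
    overrides.setdefault("nucleus_radius_um", 1.0)
    return SceneTruth(stage_label="MII-like", channels=channels, seed=seed, **overrides)


@dataclass(frozen=True)
class EffectSpec:
    """Planted effect sizes for a cohort dataset.

    ``gv_mii_ratio`` scales MII oocyte signal relative to GV; the
    ``oocyte_cumulus_ratio`` is the planted in-slice mean-intensity ratio;
    donor multipliers are lognormal with log-SD ``donor_sigma``.
    """

    gv_mii_ratio: float = 0.6
    oocyte_cumulus_ratio: float = 0.5
    donor_sigma: float = 0.2


def simulate_coc_dataset(
    n_donors: int,
    oocytes_per_stage: int,
    effect_spec: EffectSpec | None = None,
    seed: int = 0,
    scene_kwargs: dict | None = None,
    match_distributions: bool = True,
) -> tuple[list[tuple[ImageStack, SceneTruth]], pd.DataFrame]:
    """Simulate a donor-structured cohort of GV and MII complexes.

    Every donor contributes ``oocytes_per_stage`` GV-like and as many
    MII-like scenes (so each donor has at least one of each, as required for
    per-donor normalization).  Returns the rendered stacks with their
    resolved truths and a manifest table carrying donor, stage, treatment and
    the planted multipliers.

    With ``match_distributions`` (default) both stages share the GV spatial
    organelle pattern, so the planted stage effect is a pure intensity ratio
    and projection readouts estimate it without spatial confounding; set it
    to False to combine the intensity effect with the stage-dependent
    redistribution of the presets.
    """
    if n_donors < 1:
        raise ValueError("n_donors must be at least 1")
    if oocytes_per_stage < 1:
        raise ValueError("oocytes_per_stage must be at least 1")
    effect = effect_spec or EffectSpec()
    scene_kwargs = dict(scene_kwargs or {})
    if match_distributions and "channels" not in scene_kwargs:
        scene_kwargs["channels"] = _default_channels(
            "GV-like", scene_kwargs.pop("cluster_radius", None)
        )
    rng = np.random.default_rng([seed, 5])
    out: list[tuple[ImageStack, SceneTruth]] = []
    rows = []
    for d in range(n_donors):
        donor = f"donor{d + 1:02d}"
        mult = float(np.exp(rng.normal(0.0, effect.donor_sigma)))
        for stage, maker, gain in (
            ("GV", gv_like_scene, 1.0),
            ("MII", mii_like_scene, effect.gv_mii_ratio),
        ):
            for i in range(oocytes_per_stage):
                scene_seed = int(rng.integers(2**31))
                cell_id = f"{donor}_{stage.lower()}{i + 1}"
                truth = maker(
                    seed=scene_seed,
                    donor_multiplier=mult,
                    oocyte_gain=gain,
                    oocyte_to_cumulus_ratio=effect.oocyte_cumulus_ratio,
                    metadata={
                        "donor": donor,
                        "stage": stage,
                        "cell_id": cell_id,
                        "treatment": "none",
                    },
                    **scene_kwargs,
                )
                stack, resolved = simulate_oocyte_stack(truth)
                out.append((stack, resolved))
                rows.append(
                    {
                        "donor": donor,
                        "cell_id": cell_id,
                        "stage": stage,
                        "treatment": "none",
                        "donor_multiplier": mult,
                        "oocyte_gain": gain,
                        "seed": scene_seed,
                    }
                )
    return out, pd.DataFrame(rows)
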