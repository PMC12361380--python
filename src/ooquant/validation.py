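"""Self-validation experiments: recover planted truths through the pipeline.

Each function runs one desk-scale experiment on synthetic ground truth and
returns the measured quantities as a plain dict, so the same computations
back both the test suite and the reproduction script.  Experiments use
coarse 1.0–1.5 µm voxels (against the 0.4 µm acquisition default) to keep
run times in seconds; planted geometry and intensity truths are unchanged
by the voxel size.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import (
    breakpoint_model,
    geometry_io,
    intensity_stats,
    membrane_aggregates,
    radial_profiling,
    synthetic_cocs,
)

__all__ = [
    "breakpoint_exact_recovery",
    "oracle_equivalence",
    "ci_coverage",
    "profiling_checks",
    "distribution_contrast",
    "effect_recovery",
    "welch_calibration",
    "body_counting",
]

COARSE = dict(pixel_size_um=1.5, psf_sigma_um=1.2)


def _subseeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng([int(seed), 97])
    return [int(s) for s in rng.integers(0, 2**31, size=n)]


def breakpoint_exact_recovery(psis=(10.0, 30.0, 50.0), x_max=60.0) -> dict:
    """Noiseless two-segment profiles must be recovered exactly."""
    errs, rsses, widths = [], [], []
    for psi in psis:
        truth = synthetic_cocs.ProfileTruth(psi_true=psi, x_max=x_max, n_points=200)
        x, y = synthetic_cocs.simulate_profile(truth)
        fit = breakpoint_model.fit_segmented(x, y)
        errs.append(abs(fit.psi - psi))
        rsses.append(fit.rss)
        widths.append(fit.ci95[1] - fit.ci95[0])
    return {
        "max_abs_error_um": float(max(errs)),
        "max_rss": float(max(rsses)),
        "max_ci_width_um": float(max(widths)),
        "n": len(psis),
    }


def oracle_equivalence(seed: int, n_instances: int = 50) -> dict:
    """Iterative fit vs exhaustive 0.01 µm grid search on noisy instances."""
    psi_diffs, rss_excess = [], []
    for s in _subseeds(seed, n_instances):
        truth = synthetic_cocs.ProfileTruth(
            psi_true=30.0, x_max=60.0, n_points=300, noise_sd=0.05, seed=s
        )
        x, y = synthetic_cocs.simulate_profile(truth)
        fit = breakpoint_model.fit_segmented(x, y)
        psi_g, rss_g = breakpoint_model.grid_search_oracle(x, y, resolution=0.01)
        psi_diffs.append(abs(fit.psi - psi_g))
        rss_excess.append(fit.rss - rss_g)
    return {
        "max_psi_diff_um": float(max(psi_diffs)),
        "max_rss_excess": float(max(rss_excess)),
        "n": n_instances,
    }


def ci_coverage(
    seed: int, n_replicates: int = 500, n_points: int = 300, noise_sd: float = 0.05
) -> dict:
    """Empirical coverage of the 95% Wald interval for the breakpoint."""
    psi_true = 30.0
    hits = 0
    for s in _subseeds(seed, n_replicates):
        truth = synthetic_cocs.ProfileTruth(
            psi_true=psi_true, x_max=60.0, n_points=n_points, noise_sd=noise_sd, seed=s
        )
        x, y = synthetic_cocs.simulate_profile(truth)
        fit = breakpoint_model.fit_segmented(x, y)
        lo, hi = fit.ci95
        hits += lo <= psi_true <= hi
    return {"coverage": hits / n_replicates, "n": n_replicates}


def _oocyte_of(stack, channel):
    regions = geometry_io.segment_cells(stack, channel)
    return next(r for r in regions if r.cell_type == "oocyte"), regions


def profiling_checks(seed: int) -> dict:
    """Flat-disc flatness, planted-shell peak location, rotation invariance."""
    # 1) uniform disc -> flat interior profile
    size, radius = 201, 80.0
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2
    disc = (np.hypot(yy - c, xx - c) < radius).astype(float) * 7.0
    vol = np.repeat(disc[None], 5, axis=0)
    resliced, radii = radial_profiling.radial_reslice(vol, (c, c), 1.0)
    prof = resliced[2]
    interior = prof[(radii >= 5.0) & (radii <= 45.0)]
    disc_cv = float(interior.std() / interior.mean())

    # 2) Gaussian intensity shell planted at 40 µm
    ch = synthetic_cocs.ChannelSpec(
        "shell", n_puncta=20_000, cluster_weight=0.0, shell_weight=1.0,
        shell_radius_um=40.0, shell_sigma_um=2.0, punctum_amplitude=300,
    )
    truth = synthetic_cocs.gv_like_scene(
        seed=seed, channels=(ch,), pixel_size_um=1.0, psf_sigma_um=0.8,
        n_cumulus=0, nucleus_radius_um=1.0,
    )
    stack, _ = synthetic_cocs.simulate_oocyte_stack(truth)
    oocyte, _ = _oocyte_of(stack, "shell")
    shell_prof = radial_profiling.extract_radial_profile(stack, oocyte, "shell")
    argmax_um = float(shell_prof.distances[np.argmax(shell_prof.raw)])

    # 3) rotating the stack by 90 degrees
    svol = stack.channel("shell")
    cx, cy = oocyte.centre_px
    ref, _ = radial_profiling.radial_reslice(svol, (cx, cy), 1.0)
    rot = np.rot90(svol, k=1, axes=(1, 2)).copy()
    # rot90 maps (row y, col x) -> (row nx-1-x, col y)
    res, _ = radial_profiling.radial_reslice(rot, (cy, svol.shape[2] - 1 - cx), 1.0)
    rot_change = float(np.max(np.abs(ref - res)) / (ref.max() - ref.min()))
    return {
        "disc_cv": disc_cv,
        "shell_argmax_um": argmax_um,
        "rotation_change_fraction": rot_change,
        "n": int(shell_prof.distances.size),
    }


def _cohort_fit(maker, cluster_radius, seeds, channel="tmre"):
    profiles = []
    for s in seeds:
        truth = maker(seed=s, cluster_radius=cluster_radius, **COARSE)
        stack, _ = synthetic_cocs.simulate_oocyte_stack(truth)
        oocyte, _ = _oocyte_of(stack, channel)
        prof = radial_profiling.extract_radial_profile(stack, oocyte, channel)
        profiles.append(radial_profiling.normalize_profile(prof))
    cohort = radial_profiling.average_profiles(profiles)
    return breakpoint_model.fit_segmented(cohort.distances, cohort.mean)


def distribution_contrast(seed: int, n_per_group: int = 8) -> dict:
    """GV-like (30 µm cluster) vs MII-like (50 µm) cohort breakpoints."""
    seeds = _subseeds(seed, 2 * n_per_group)
    fit_gv = _cohort_fit(synthetic_cocs.gv_like_scene, 30.0, seeds[:n_per_group])
    fit_mii = _cohort_fit(synthetic_cocs.mii_like_scene, 50.0, seeds[n_per_group:])
    cmp = breakpoint_model.compare_conditions(fit_gv, fit_mii)
    return {
        "gv_psi_um": fit_gv.psi,
        "gv_ci": list(fit_gv.ci95),
        "mii_psi_um": fit_mii.psi,
        "mii_ci": list(fit_mii.ci95),
        "overlap": cmp["overlap"],
        "gap_um": cmp["gap"],
        "ordered_as_planted": fit_gv.psi < fit_mii.psi,
        "n": 2 * n_per_group,
    }


def effect_recovery(seed: int, n_donors: int = 3, per_stage: int = 2) -> dict:
    """Recover planted oocyte:cumulus (0.5) and GV:MII (0.6) intensity ratios."""
    effect = synthetic_cocs.EffectSpec(
        gv_mii_ratio=0.6, oocyte_cumulus_ratio=0.5, donor_sigma=0.2
    )
    dataset, _ = synthetic_cocs.simulate_coc_dataset(
        n_donors, per_stage, effect_spec=effect, seed=seed, scene_kwargs=COARSE
    )
    records = intensity_stats.measure_dataset(dataset, "lysotracker")

    # stage effect: whole-oocyte max-Z means, normalized to the donor GV median
    oocytes = records[records.compartment == "oocyte"]
    by_stage = intensity_stats.per_donor_normalize(oocytes, {"stage": "GV"})
    gv_mii = float(by_stage.loc[by_stage.stage == "MII", "normalized"].median())

    # compartment effect: per-slice means, normalized to the donor cumulus median
    slice_recs = records.copy()
    oo_rows = slice_recs.compartment == "oocyte"
    slice_recs.loc[oo_rows, "readout"] = slice_recs.loc[oo_rows, "slice_mean_oocyte"]
    by_comp = intensity_stats.per_donor_normalize(
        slice_recs, {"compartment": "cumulus"}
    )
    oo_cc = float(
        by_comp.loc[by_comp.compartment == "oocyte", "normalized"].median()
    )
    return {
        "gv_mii_ratio": gv_mii,
        "oocyte_cumulus_ratio": oo_cc,
        "planted": {"gv_mii": 0.6, "oocyte_cumulus": 0.5},
        "n": len(dataset),
    }


def welch_calibration(seed: int, n_replicates: int = 1000, n_per_group: int = 10) -> dict:
    """Type-I error at alpha = 0.05 under the null, plus a closed-form check."""
    rng = np.random.default_rng([int(seed), 31])
    a = rng.normal(0.0, 1.0, size=(n_replicates, n_per_group))
    b = rng.normal(0.0, 1.0, size=(n_replicates, n_per_group))
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    type1 = float(np.mean(res.pvalue < 0.05))

    # worked example against the textbook Welch/Satterthwaite formulas
    ga = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    gb = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
    out = intensity_stats.welch_t_test(ga, gb)
    va, vb = ga.var(ddof=1) / ga.size, gb.var(ddof=1) / gb.size
    t = (ga.mean() - gb.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (ga.size - 1) + vb**2 / (gb.size - 1))
    p = 2 * stats.t.sf(abs(t), df)
    example_diff = max(abs(out.t - t), abs(out.df - df), abs(out.p_value - p))
    return {
        "type1_error": type1,
        "example_max_abs_diff": float(example_diff),
        "n": n_replicates,
    }


def body_counting(seed: int) -> dict:
    """Plant 5 detectable bodies plus one sub-threshold; count and match them."""
    positions = [(20, 0, 0), (-20, 10, 4), (0, -25, -4), (15, 20, 0), (-10, -15, 6)]
    bodies = [
        synthetic_cocs.BodyTruth(p, 4.0, {"lamp1": 4000.0, "proteostat": 4000.0})
        for p in positions
    ]
    bodies.append(
        synthetic_cocs.BodyTruth((0, 30, 0), 1.0, {"lamp1": 4000.0, "proteostat": 4000.0})
    )
    channels = (
        synthetic_cocs.ChannelSpec(
            "lamp1", n_puncta=300, cluster_weight=0.0, punctum_amplitude=800
        ),
        synthetic_cocs.ChannelSpec("proteostat", n_puncta=0, punctum_amplitude=0),
    )
    truth = synthetic_cocs.mii_like_scene(
        seed=seed, channels=channels, bodies=tuple(bodies),
        pixel_size_um=1.0, psf_sigma_um=0.8, n_cumulus=0,
    )
    stack, _ = synthetic_cocs.simulate_oocyte_stack(truth)
    oocyte, _ = _oocyte_of(stack, "lamp1")
    det = membrane_aggregates.detect_refractile_bodies(
        stack, oocyte, "proteostat", ("lamp1", "proteostat"), min_diameter_um=2.0
    )
    planted = np.array([b.centre_um for b in bodies if b.diameter_um >= 2.0])
    found = np.array([b.centroid_um for b in det.bodies]).reshape(-1, 3)
    matched = 0
    if found.size:
        d = np.linalg.norm(planted[:, None, :] - found[None, :, :], axis=2)
        matched = int(np.sum(d.min(axis=1) < 2.0))
    precision = matched / len(found) if len(found) else 0.0
    recall = matched / len(planted)
    return {
        "count": det.count,
        "precision": float(precision),
        "recall": float(recall),
        "n": len(bodies),
    }
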