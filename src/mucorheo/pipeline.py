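"""End-to-end workflow: QC -> pooling -> PTMR -> bulk sweeps -> scaling -> stats.

Runs the full analysis on either a user-supplied sample table or a
synthetic cohort, with synthetic bead trajectories and matched sweep
tables standing in for undeposited raw measurements.  Everything is a
pure function of (config, master seed): per-stage seeds are derived by
hashing stage names against the master seed, so each stage is
independently reproducible, and the report is deterministic JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from mucorheo import __version__
from mucorheo.errors import InfeasibleMixtureError, MucorheoError
from mucorheo.io import read_sample_table
from mucorheo.macrorheology import (
    FrequencySweep,
    StrainSweep,
    cross_scale_compare,
    find_lvr,
    tan_delta,
)
from mucorheo.microrheology import GserConfig, per_bead_eta_distribution
from mucorheo.sample_qc import (
    TonicityReference,
    classify_tonicity,
    apply_inclusion_filters,
    cohort_summary,
    optimize_mixture,
    salt_addition_plan,
)
from mucorheo.scaling_stats import fit_power_law, kruskal_wallis, rank_sum_test
from mucorheo.synthetic_data import (
    ConcentrationLaw,
    TrajectoryParams,
    fluid_for_concentration,
    simulate_fbm_tracks,
    simulate_macro_sweep,
    simulate_population_mixture,
    simulate_sample_table,
)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    With ``sample_table`` unset a synthetic cohort is generated.  The
    measurement chain simulates bead trajectories at each concentration
    in ``concentrations_pct`` (the lowest one as a 50/50 bimodal mixture
    when ``bimodal_lowest`` is set, mirroring behavior near the
    entanglement concentration), inverts them via GSER, generates
    matched bulk sweeps, and fits the concentration power law.
    Simulation sizes default to a demonstration scale.
    """

    sample_table: str | None = None
    n_synthetic_samples: int = 12
    tonicity_mix: tuple[float, float, float] = (0.4, 0.4, 0.2)
    reference: TonicityReference = field(default_factory=TonicityReference)
    gser: GserConfig = field(default_factory=GserConfig)
    law: ConcentrationLaw = field(default_factory=ConcentrationLaw)
    concentrations_pct: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0)
    bimodal_lowest: bool = True
    alpha: float = 0.1856  # critical-gel exponent, tan delta ~ 0.3
    n_beads: int = 40
    n_frames: int = 300
    frame_rate_hz: float = 60.0
    localization_sigma_um: float = 0.01
    comparison_f_hz: float = 1.0
    seed: int = 0


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _qc_stage(cfg: PipelineConfig) -> tuple[dict, list]:
    if cfg.sample_table:
        samples = read_sample_table(cfg.sample_table)
    else:
        samples = simulate_sample_table(
            cfg.n_synthetic_samples, cfg.tonicity_mix, stage_seed(cfg.seed, "samples")
        )
    included, excluded = apply_inclusion_filters(samples, cfg.reference)
    summary = cohort_summary(included, cfg.reference) if included else None
    report = {
        "n_samples": len(samples),
        "n_included": len(included),
        "excluded": [
            {"sample_id": s.sample_id, "reason": r} for s, r in excluded
        ],
        "tonicity": {
            s.sample_id: classify_tonicity(s, cfg.reference) for s in samples
        },
        "summary": asdict(summary) if summary else None,
    }
    return report, included


def _pool_stage(cfg: PipelineConfig, included: list) -> dict:
    if not included:
        return {"error": "no samples passed QC"}
    try:
        recipe = optimize_mixture(included, cfg.reference)
    except InfeasibleMixtureError as exc:
        return {"error": str(exc)}
    out = {
        "entries": [
            {"sample_id": sid, "aliquot_volume_ul": round(v, 3)}
            for sid, v in recipe.entries
        ],
        "expected_na_mM": round(recipe.expected_na_mM, 4),
        "expected_k_mM": round(recipe.expected_k_mM, 4),
    }
    if recipe.expected_na_mM < cfg.reference.na_ref:
        target_k = max(recipe.expected_k_mM, cfg.reference.k_ref)
        nacl, kcl = salt_addition_plan(
            recipe.total_volume_ul,
            (recipe.expected_na_mM, recipe.expected_k_mM),
            (cfg.reference.na_ref, target_k),
        )
        out["salt_addition"] = {"nacl_mg": round(nacl, 4), "kcl_mg": round(kcl, 4)}
    return out


def _ptmr_stage(cfg: PipelineConfig) -> tuple[dict, dict]:
    report = {}
    distributions = {}
    for i, c in enumerate(cfg.concentrations_pct):
        fluid = fluid_for_concentration(
            c,
            cfg.law,
            alpha=cfg.alpha,
            temperature_k=cfg.gser.temperature_k,
            bead_radius_um=cfg.gser.bead_radius_um,
        )
        seed = stage_seed(cfg.seed, f"tracks-{c}")
        bimodal_here = cfg.bimodal_lowest and i == 0
        if bimodal_here:
            # 50/50 low/high-viscosity phases one decade apart, centered on
            # the concentration law (entanglement-transition heterogeneity)
            half_decade = 10.0**0.5
            lo = replace(fluid, eta_1hz=fluid.eta_1hz / half_decade)
            hi = replace(fluid, eta_1hz=fluid.eta_1hz * half_decade)
            params = TrajectoryParams(
                n_beads=cfg.n_beads,
                n_frames=cfg.n_frames,
                frame_rate_hz=cfg.frame_rate_hz,
                localization_sigma_um=cfg.localization_sigma_um,
                mixture=((0.5, lo), (0.5, hi)),
            )
            ts = simulate_population_mixture(params, seed)
        else:
            params = TrajectoryParams(
                n_beads=cfg.n_beads,
                n_frames=cfg.n_frames,
                frame_rate_hz=cfg.frame_rate_hz,
                localization_sigma_um=cfg.localization_sigma_um,
            )
            ts = simulate_fbm_tracks(fluid, params, seed)
        gser_cfg = GserConfig(
            cfg.gser.temperature_k,
            cfg.gser.bead_radius_um,
            static_error_sigma_um=cfg.localization_sigma_um,
        )
        dist = per_bead_eta_distribution(ts, gser_cfg, cfg.comparison_f_hz)
        distributions[c] = dist
        report[str(c)] = {
            "true_eta_1hz": fluid.eta_1hz,
            "median_eta": dist.median,
            "q25": dist.q25,
            "q75": dist.q75,
            "n_beads": len(dist.values),
            "bimodal": dist.bimodal,
            "separation_decades": dist.separation_decades,
        }
    return report, distributions


def _macro_stage(cfg: PipelineConfig, distributions: dict) -> dict:
    out = {}
    omega = np.geomspace(0.1, 10.0, 15)
    strain = np.geomspace(0.1, 10.0, 15)
    for i, c in enumerate(cfg.concentrations_pct):
        fluid = fluid_for_concentration(
            c,
            cfg.law,
            alpha=cfg.alpha,
            temperature_k=cfg.gser.temperature_k,
            bead_radius_um=cfg.gser.bead_radius_um,
        )
        freq_df = simulate_macro_sweep(fluid, omega_rad_s=omega)
        strain_df = simulate_macro_sweep(fluid, strain_pct=strain)
        fsweep = FrequencySweep(
            freq_df["omega_rad_s"].to_numpy(),
            freq_df["Gp_Pa"].to_numpy(),
            freq_df["Gpp_Pa"].to_numpy(),
        )
        ssweep = StrainSweep(
            strain_df["strain_pct"].to_numpy(),
            strain_df["Gp_Pa"].to_numpy(),
            strain_df["Gpp_Pa"].to_numpy(),
        )
        lvr = find_lvr(ssweep)
        td, verdict = tan_delta(fsweep.g_prime, fsweep.g_dprime)
        compare = cross_scale_compare(
            fsweep, distributions[c], cfg.comparison_f_hz
        )
        out[str(c)] = {
            "lvr_strain_pct": list(lvr) if lvr else None,
            "tan_delta_max": float(np.max(td)),
            "gel_verdict": verdict,
            "bulk_eta_1hz": compare.bulk_eta,
            "micro_eta_1hz": compare.micro_eta,
            "cross_scale_ratio": round(compare.ratio, 4),
            "within_factor_2": compare.within_bound,
        }
    return out


def _scaling_stage(cfg: PipelineConfig, distributions: dict) -> dict:
    points = [(c, d.median) for c, d in distributions.items()]
    fit = fit_power_law(points)
    cs = sorted(distributions)
    rs = rank_sum_test(
        np.log10(distributions[cs[0]].values), np.log10(distributions[cs[-1]].values)
    )
    kw = kruskal_wallis([np.log10(distributions[c].values) for c in cs])
    return {
        "gamma": round(fit.gamma, 4),
        "ci95": [round(v, 4) for v in fit.ci95],
        "r_squared": round(fit.r_squared, 4),
        "rank_sum_low_vs_high": {
            "statistic": rs.statistic,
            "p": rs.p_two_sided,
            "method": rs.method,
        },
        "kruskal_wallis": {"h": round(kw.h, 4), "p": kw.p, "df": kw.df},
    }


def estimate_static_error(
    render_params,
    tracking_diameter_px: int,
    min_mass: float,
    seed: int,
    n_frames: int = 40,
    n_beads: int = 9,
    frame_rate_hz: float = 60.0,
) -> float:
    """Per-axis localization noise (um) from a static-bead control video.

    Renders immobilized beads with the given imaging parameters, tracks
    them, and reads the noise off the flat MSD plateau (MSD = 4 sigma^2
    at every lag for a static bead) — the standard fixed-bead
    calibration used to correct live MSDs.
    """
    import pandas as pd

    from mucorheo.microrheology import msd_ensemble, msd_track
    from mucorheo.synthetic_data import render_image_stack
    from mucorheo.tracking import (
        bandpass_filter,
        filter_tracks,
        link_trajectories,
        locate_beads,
    )
    from mucorheo.trajectories import TrajectorySet

    px = render_params.pixel_size_um
    side = int(np.ceil(np.sqrt(n_beads)))
    spacing = 15.0 * px  # keep PSFs well separated
    coords = [
        ((i % side) * spacing + 5 * px, (i // side) * spacing + 5 * px)
        for i in range(n_beads)
    ]
    rows = [
        (b, t, x, y)
        for b, (x, y) in enumerate(coords)
        for t in range(n_frames)
    ]
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um"])
    ts = TrajectorySet(df, 1.0 / frame_rate_hz)
    stack = render_image_stack(ts, render_params, seed)
    bp = bandpass_filter(stack, 1.0, tracking_diameter_px)
    det = locate_beads(bp, tracking_diameter_px, min_mass)
    tracked = link_trajectories(det, px, frame_rate_hz, search_radius_px=3.0)
    tracked = filter_tracks(tracked, n_frames // 2)
    curves = [
        msd_track(fr, xy, tracked.frame_interval_s, max_lag_fraction=0.5)
        for _, fr, xy in tracked.iter_tracks()
    ]
    ens = msd_ensemble(curves)
    return float(np.sqrt(np.mean(ens.msd) / 4.0))


def measure_eta_from_video(
    fluid,
    seed: int,
    n_beads: int = 20,
    n_frames: int = 300,
    frame_rate_hz: float = 60.0,
    f_hz: float = 1.0,
    peak_counts: float = 8000.0,
    box_um: float = 40.0,
    diameter_px: int = 7,
    min_mass: float = 2000.0,
    min_track_frames: int = 100,
):
    """Full measurement chain on one synthetic sample.

    simulate beads -> render video -> band-pass -> localize -> link ->
    drift-correct -> per-bead MSD -> static-error correction (sigma from
    a matched fixed-bead control) -> GSER -> per-bead |eta*|(f).
    Returns the :class:`EtaDistribution`.
    """
    from mucorheo.microrheology import GserConfig, per_bead_eta_distribution
    from mucorheo.synthetic_data import (
        RenderParams,
        TrajectoryParams,
        render_image_stack,
        simulate_fbm_tracks,
    )
    from mucorheo.tracking import (
        bandpass_filter,
        drift_correct,
        filter_tracks,
        link_trajectories,
        locate_beads,
    )

    render = RenderParams(peak_counts=peak_counts)
    px = render.pixel_size_um
    margin_um = 4.0 * px * 3
    params = TrajectoryParams(
        n_beads=n_beads,
        n_frames=n_frames,
        frame_rate_hz=frame_rate_hz,
        localization_sigma_um=0.0,  # noise enters through the imaging model
        start_box=((margin_um, box_um - margin_um), (margin_um, box_um - margin_um)),
    )
    truth = simulate_fbm_tracks(fluid, params, seed)
    field_px = int(np.ceil(box_um / px)) + 20
    render = RenderParams(peak_counts=peak_counts, shape_yx=(field_px, field_px))
    stack = render_image_stack(truth, render, seed + 1)
    bp = bandpass_filter(stack, 1.0, diameter_px)
    det = locate_beads(bp, diameter_px, min_mass)
    ts = link_trajectories(
        det, px, frame_rate_hz, search_radius_px=5.0, memory=2
    )
    ts = drift_correct(filter_tracks(ts, min_track_frames))
    sigma = estimate_static_error(
        RenderParams(peak_counts=peak_counts), diameter_px, min_mass, seed + 2
    )
    cfg = GserConfig(
        bead_radius_um=fluid.bead_radius_um,
        temperature_k=fluid.temperature_k,
        static_error_sigma_um=sigma,
    )
    return per_bead_eta_distribution(ts, cfg, f_hz)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the report dict (JSON-serializable).

    Any stage failure is re-raised with the stage name attached.
    """
    report = {
        "provenance": {
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": hashlib.sha256(
                repr(cfg).encode()
            ).hexdigest()[:16],
            "schema": "mucorheo-report v1",
        }
    }
    stage = "qc"
    try:
        report["qc"], included = _qc_stage(cfg)
        stage = "pool"
        report["pool"] = _pool_stage(cfg, included)
        stage = "ptmr"
        report["ptmr"], distributions = _ptmr_stage(cfg)
        stage = "macro"
        report["macro"] = _macro_stage(cfg, distributions)
        stage = "scaling"
        report["scaling"] = _scaling_stage(cfg, distributions)
    except MucorheoError as exc:
        raise MucorheoError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
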