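"""End-to-end pipeline driver: chain stages, write CSVs, record a manifest.

Two pipelines are expressible through :class:`~threephoton.config.RunConfig`:
tissue-optics characterization (synthetic damage curves -> threshold fits ->
attenuation model; synthetic THG profile -> segment fits) and functional
tuning analysis (synthetic tuned traces -> per-neuron feature table), plus
the safety-envelope table and a photon-transport run. Every file written is
listed in the JSON manifest together with the seeds used; re-running an
identical config reproduces identical summary CSVs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

import threephoton
from threephoton import calcium, photophysics, synth, tissue_optics, transport
from threephoton.config import RunConfig


class DependencyError(RuntimeError):
    """A stage's upstream artifact is missing."""


KNOWN_STAGES = ("safety", "ablation", "thg", "tuning", "transport")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the manifest (also written to ``manifest.json`` in the output
    directory): package version, config echo, seeds, and every output file.
    """
    unknown = set(config.stages) - set(KNOWN_STAGES)
    if unknown:
        raise DependencyError(f"unknown stages {sorted(unknown)}; known: {KNOWN_STAGES}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": threephoton.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "outputs": [],
    }

    def _write(df: pd.DataFrame, name: str) -> Path:
        path = outdir / name
        df.to_csv(path, index=False, float_format="%.10g")
        manifest["outputs"].append(str(path))
        return path

    if "safety" in config.stages:
        c = config.safety
        envelope = photophysics.SafetyEnvelope(
            heating_power_bound=c.heating_power_bound_w,
            breakdown_energy_at_surface=c.breakdown_energy_at_surface_j,
            imaging_anchor=(c.anchor_energy_j, c.anchor_rate_hz, c.anchor_width_s),
        )
        grid = np.geomspace(c.r_min_hz, c.r_max_hz, c.n_points)
        _write(photophysics.safety_envelope_curves(grid, envelope, c.mode), "safety_envelope.csv")

    if "ablation" in config.stages:
        c = config.optics
        spec = synth.SyntheticOpticsSpec(
            ablation_extinction_length=c.ablation_extinction_length_um,
            threshold_fluence=c.threshold_fluence_j_cm2,
            fwhm_3p=c.fwhm_3p_um,
            seed=config.seed,
        )
        curves = synth.make_damage_dataset(spec, depths=c.depths_um)
        fits = [(cv.depth, tissue_optics.fit_damage_threshold(cv).e_th_surface) for cv in curves]
        model = tissue_optics.fit_attenuation(fits, w0=spec.w0)
        _write(
            pd.DataFrame(fits, columns=["depth_um", "e_th_surface_nj"]), "ablation_thresholds.csv"
        )
        _write(
            pd.DataFrame(
                [
                    {
                        "extinction_length_um": model.extinction_length,
                        "threshold_fluence_j_cm2": model.threshold_fluence,
                        "w0_um": model.w0,
                        "stderr_extinction_um": model.stderr_extinction,
                        "stderr_fluence_j_cm2": model.stderr_fluence,
                    }
                ]
            ),
            "attenuation_model.csv",
        )

    if "thg" in config.stages:
        c = config.optics
        spec = synth.SyntheticOpticsSpec(
            extinction_lengths=c.thg_extinction_lengths_um,
            segment_breaks=c.thg_segment_breaks_um,
            seed=config.seed,
        )
        profile = synth.make_thg_profile(spec)
        fits = tissue_optics.fit_thg_attenuation(profile)
        _write(
            pd.DataFrame(
                [
                    {
                        "z_start_um": f.z_start,
                        "z_stop_um": f.z_stop,
                        "extinction_length_um": f.extinction_length,
                        "stderr_um": f.stderr,
                    }
                    for f in fits
                ]
            ),
            "thg_fits.csv",
        )

    if "tuning" in config.stages:
        c = config.tuning
        protocol = calcium.StimulusProtocol.generate(seed=config.seed)
        spec = synth.SyntheticPopulationSpec(
            n_neurons=c.n_neurons,
            fraction_responsive=c.fraction_responsive,
            noise_sd=c.noise_sd,
            seed=config.seed,
        )
        traces, truth = synth.make_tuned_traces(spec, protocol)
        table = calcium.analyze_traces(traces, protocol, alpha=c.alpha)
        _write(table, "tuning_features.csv")
        _write(truth, "tuning_ground_truth.csv")

    if "transport" in config.stages:
        c = config.transport
        medium = transport.OpticalMedium(
            scattering_length=c.scattering_length_um,
            absorption_length=c.absorption_length_um,
            anisotropy_g=c.anisotropy_g,
            thickness=c.thickness_um,
        )
        geometry = transport.CollectionGeometry(
            aperture_radius=c.aperture_radius_mm,
            aperture_distance_above_surface=c.aperture_distance_mm,
            acceptance_half_angle=c.acceptance_half_angle_deg,
        )
        res = transport.simulate_collection(
            c.n_photons, c.depth_um, medium, geometry, seed=config.seed
        )
        _write(
            pd.DataFrame(
                [
                    {
                        "n_launched": res.n_launched,
                        "n_collected": res.n_collected,
                        "n_absorbed": res.n_absorbed,
                        "n_escaped_uncollected": res.n_escaped_uncollected,
                        "collected_fraction": res.collected_fraction,
                        "seed": res.seed,
                    }
                ]
            ),
            "transport_result.csv",
        )

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
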