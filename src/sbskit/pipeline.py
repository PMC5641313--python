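"""End-to-end analysis pipeline.

Contact matrix in -> P(s) mixture decomposition -> binding-domain inference
-> Langevin ensemble of the inferred polymer model -> simulated contact map,
P(s), phase label, 3D conformations and (optionally) track correlations out.
Every artifact is stamped with the package version, a configuration hash and
the master seed; non-simulation outputs are bitwise reproducible for a given
configuration, simulation outputs are statistically reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from ._version import __version__ as _version
from .contacts import contact_curve, map_pearson, read_contact_matrix, write_contact_matrix
from .inference import BindingDomainAnnealer
from .mixture import estimate_pure_curves, fit_mixture
from .observables import classify_phase, contact_map_from_ensemble, rg_series
from .profiles import write_profile_tsv
from .simulate import BinderSpec, SimulationParams, run_ensemble, write_xyz
from .tracks import correlate_profile_tracks, read_bedgraph

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("sbskit.pipeline")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage. Artifacts
    written by earlier stages are left in place."""


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    The region metadata must be consistent with the matrix: the matrix is
    ``n_beads x n_beads`` and the modelled region spans
    ``n_beads * bin_size_bp`` base pairs from ``genomic_start``.
    """

    matrix_path: str
    out_dir: str
    n_types: int
    matrix_format: str = "auto"
    chrom: str = "chrS"
    genomic_start: int = 0
    bin_size_bp: int = 50_000
    track_paths: list[str] = field(default_factory=list)
    seed: int = 0
    # forward model / annealing
    decay_exponent: float = 1.0
    enrichment: float = 1.0
    saturation: float = 1.0
    n_sweeps: int = 200
    n_restarts: int = 2
    lambda_reg: float = 0.002
    # mixture fit
    pure_n_beads: int = 64
    mixture_s_min: float = 2.0
    # simulation of the inferred model
    n_replicas: int = 2
    sim_tau: float = 400.0
    sim_timestep: float = 0.01
    binder_affinity: float = 8.0
    binders_per_site: float = 0.5
    contact_threshold: float = 3.5
    # misc
    cache_dir: str | None = None
    skip_simulation: bool = False
    skip_mixture: bool = False

    def validate(self) -> None:
        if not os.path.exists(self.matrix_path):
            raise PipelineError(f"config: matrix file not found: {self.matrix_path}")
        for t in self.track_paths:
            if not os.path.exists(t):
                raise PipelineError(f"config: track file not found: {t}")
        if self.n_types < 1:
            raise PipelineError("config: n_types must be >= 1")
        if self.bin_size_bp <= 0:
            raise PipelineError("config: bin_size_bp must be positive")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _provenance(config: PipelineConfig) -> list[str]:
    return [
        f"sbskit v{_version}",
        f"config_hash={config.config_hash()}",
        f"seed={config.seed}",
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the report dict (also written as JSON).

    Stages: read matrix; mixture-decompose its P(s); infer the binding-domain
    profile by simulated annealing; simulate a 3D ensemble of the inferred
    model and compute its contact map and phase; correlate the inferred
    domains with any provided tracks.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    prov = _provenance(config)
    report: dict = {
        "version": _version,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    def _out(name: str) -> str:
        return os.path.join(config.out_dir, name)

    def _stage(name):
        logger.info("pipeline stage %s starting", name)
        t0 = time.time()

        def _done(**kv):
            report["stages"][name] = {"seconds": round(time.time() - t0, 3), **kv}
            logger.info("pipeline stage %s done in %.2fs", name, time.time() - t0)

        return _done

    # ---- stage: read matrix -------------------------------------------------
    done = _stage("read_matrix")
    try:
        data_map = read_contact_matrix(
            config.matrix_path,
            config.matrix_format,
            chrom=config.chrom,
            genomic_start=config.genomic_start,
            bin_size_bp=config.bin_size_bp,
        )
    except Exception as e:
        raise PipelineError(f"read_matrix: {e}") from e
    done(n_bins=data_map.n_beads)

    # ---- stage: mixture decomposition of P(s) ------------------------------
    if not config.skip_mixture:
        done = _stage("mixture_fit")
        try:
            pure = estimate_pure_curves(
                n_beads=config.pure_n_beads, cache_dir=config.cache_dir
            )
            observed = contact_curve(data_map)
            mix = fit_mixture(observed, pure, fit_range=(config.mixture_s_min, data_map.n_beads / 2))
            with open(_out("mixture.tsv"), "w") as fh:
                for line in prov:
                    fh.write(f"# {line}\n")
                fh.write("state\tfraction\n")
                for name, frac in zip(
                    ("coil", "disordered_globule", "ordered_globule"), mix.fractions
                ):
                    fh.write(f"{name}\t{frac:.6f}\n")
                fh.write(f"# chi_squared\t{mix.chi_squared:.6g}\n")
        except Exception as e:
            raise PipelineError(f"mixture_fit: {e}") from e
        report["mixture"] = {
            "f_coil": mix.f_coil,
            "f_disordered": mix.f_disordered,
            "f_ordered": mix.f_ordered,
            "chi_squared": mix.chi_squared,
        }
        done()

    # ---- stage: binding-domain inference -----------------------------------
    done = _stage("inference")
    try:
        annealer = BindingDomainAnnealer(
            n_types=config.n_types,
            decay_exponent=config.decay_exponent,
            enrichment=config.enrichment,
            saturation=config.saturation,
            n_sweeps=config.n_sweeps,
            n_restarts=config.n_restarts,
            lambda_reg=config.lambda_reg,
            random_state=config.seed,
        )
        annealer.fit(data_map)
        profile = annealer.profile_
        write_profile_tsv(profile, _out("profile.tsv"), header_lines=prov)
        write_contact_matrix(annealer.model_map_, _out("inferred_map.tsv"), header_lines=prov)
    except Exception as e:
        raise PipelineError(f"inference: {e}") from e
    report["inference"] = {
        "pearson_r": annealer.pearson_r_,
        "final_cost": annealer.final_cost_,
        "n_sites": int(profile.abundance.sum()),
    }
    done(pearson_r=round(annealer.pearson_r_, 4))

    # ---- stage: 3D ensemble of the inferred model --------------------------
    if not config.skip_simulation:
        done = _stage("simulation")
        try:
            sites_per_type = profile.abundance.sum(axis=1)
            counts = np.maximum(1, np.round(config.binders_per_site * sites_per_type)).astype(int)
            counts[sites_per_type == 0] = 0
            binders = BinderSpec(counts, np.full(config.n_types, config.binder_affinity))
            params = SimulationParams(
                timestep=config.sim_timestep,
                n_steps=int(round(config.sim_tau / config.sim_timestep)),
                seed=config.seed,
                save_stride=max(1, int(round(5.0 / config.sim_timestep))),
            )
            seeds = [config.seed + 1000 * (r + 1) for r in range(config.n_replicas)]
            ensemble = run_ensemble(profile, binders, params, config.n_replicas, seeds)
            sim_map = contact_map_from_ensemble(ensemble, threshold=config.contact_threshold)
            write_contact_matrix(sim_map, _out("simulated_map.tsv"), header_lines=prov)
            ps = contact_curve(sim_map)
            with open(_out("simulated_ps.tsv"), "w") as fh:
                for line in prov:
                    fh.write(f"# {line}\n")
                fh.write("separation\tprobability\n")
                for s, p in zip(ps.separations, ps.probabilities):
                    fh.write(f"{s:.0f}\t{p:.6g}\n")
            for r, tr in enumerate(ensemble):
                write_xyz(tr, _out(f"replica_{r}.xyz"), comment_extra=" ".join(prov))
                rg_series(tr).write_tsv(_out(f"replica_{r}_rg.tsv"), header_lines=prov)
            phase = classify_phase(ensemble[0], binders, require_equilibrated=False)
            sim_pearson = map_pearson(sim_map, data_map)
        except Exception as e:
            raise PipelineError(f"simulation: {e}") from e
        report["simulation"] = {
            "phase": phase.label,
            "nu_estimate": phase.nu_estimate,
            "binder_order_parameter": phase.binder_order_parameter,
            "map_pearson_vs_input": sim_pearson,
            "replicas": config.n_replicas,
        }
        done(phase=phase.label, map_pearson=round(sim_pearson, 4))

    # ---- stage: track correlations -----------------------------------------
    if config.track_paths:
        done = _stage("tracks")
        try:
            tracks = [read_bedgraph(p) for p in config.track_paths]
            corr = correlate_profile_tracks(profile, tracks)
            with open(_out("track_correlations.tsv"), "w") as fh:
                for line in prov:
                    fh.write(f"# {line}\n")
                corr.to_frame().to_csv(fh, sep="\t")
        except Exception as e:
            raise PipelineError(f"tracks: {e}") from e
        report["tracks"] = {
            "names": corr.track_names,
            "max_abs_r": float(np.nanmax(np.abs(corr.matrix))),
        }
        done()

    with open(_out("report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
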