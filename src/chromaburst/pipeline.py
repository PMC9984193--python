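"""End-to-end orchestration: synthetic data → spatial statistics →
co-expression → allele dynamics → distance model → co-bursting fit.

A single YAML/dict configuration drives all stages; every stage draws its
randomness from a sub-seed derived by hashing (global seed, stage name), so
each stage is reproducible independently of execution order.  The run
writes a manifest recording versions, seeds, a parameter hash and the
outputs of each stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cobursting, coexpression, dynamics, spatial_stats, synthetic
from . import distance_process as dp
from . import tracing_io as tio
from .datatypes import ConfigurationError, CouplingFunction

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "DependencyError", "run_pipeline", "stage_seed"]

STAGES = ("simulate", "spatial", "coexpr", "msd", "distance_model", "coburst")


class DependencyError(RuntimeError):
    """A stage needs outputs of an earlier stage that did not run."""


def stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    outdir: str
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    synthetic: dict = field(default_factory=dict)
    allele: dict = field(
        default_factory=lambda: {"n_cells": 20, "duration": 3000.0, "dt": 10.0}
    )
    spatial: dict = field(default_factory=lambda: {"window_mb": 0.5, "metagene_k": 5})
    coexpr: dict = field(default_factory=dict)
    coburst: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)
        # validate every stage's parameters before any stage runs
        self.synthetic_config()
        if self.allele["duration"] <= self.allele["dt"]:
            raise ConfigurationError("allele duration must exceed dt")
        search_kwargs = {
            k: v for k, v in self.coburst.items() if k != "omega_bins"
        }
        cobursting.OmegaSearchConfig(**search_kwargs)

    def synthetic_config(self) -> synthetic.SyntheticConfig:
        params = dict(self.synthetic)
        omega = params.pop("omega_true", None)
        if isinstance(omega, dict):
            params["omega_true"] = CouplingFunction(
                np.asarray(omega["values"], dtype=float),
                bin_width=float(omega.get("bin_width", 200.0)),
            )
        elif omega is not None:
            params["omega_true"] = omega
        params.setdefault("n_chromosomes", 200)
        params.setdefault("rng_seed", stage_seed(self.seed, "simulate"))
        if "gene_promoter_loci" not in params:
            # small demo study: two co-burst pairs plus loci to spare
            params.setdefault("n_loci", 14)
            params["gene_promoter_loci"] = [2, 3, 6, 8]
            params["gene_ptot"] = [m / 800.0 for m in (0.4, 0.6, 0.5, 0.6)]
            params.setdefault("coburst_pairs", [(0, 1), (2, 3)])
            params.setdefault("missing_rate", 0.05)
        params["coburst_pairs"] = [tuple(p) for p in params.get("coburst_pairs", [])]
        return synthetic.SyntheticConfig(**params)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def parameter_hash(self) -> str:
        blob = yaml.safe_dump(
            {
                "outdir": "",  # location does not change the science
                "seed": self.seed,
                "stages": self.stages,
                "synthetic": _jsonable(self.synthetic),
                "allele": self.allele,
                "spatial": self.spatial,
                "coexpr": self.coexpr,
                "coburst": self.coburst,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, CouplingFunction):
        return {"values": obj.values.tolist(), "bin_width": obj.bin_width}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _require(paths: dict, stage: str) -> None:
    missing = [str(p) for p in paths.values() if not Path(p).exists()]
    if missing:
        raise DependencyError(
            f"stage {stage!r} requires outputs that are missing: {missing}"
        )


def _write_json(path, payload) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(payload), fh, indent=1, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "parameter_hash": config.parameter_hash(),
        "stages": {},
    }
    traces_path = out / "traces_observed.tsv"
    truth_path = out / "traces_true.tsv"
    states_path = out / "gene_states.tsv"
    alleles_path = out / "allele_tracks.tsv"

    syn_cfg = config.synthetic_config()

    try:
        if config.stages["simulate"]:
            truth = synthetic.generate_polymer_traces(syn_cfg)
            activity = synthetic.generate_gene_activity(truth, syn_cfg)
            observed = synthetic.add_localization_noise(
                truth,
                syn_cfg.localization_sigma,
                seed=stage_seed(config.seed, "simulate") + 1,
            )
            trajs = synthetic.generate_allele_trajectories(
                syn_cfg,
                n_cells=config.allele["n_cells"],
                duration=config.allele["duration"],
                dt=config.allele["dt"],
            )
            tio.write_chromatin_traces(truth, truth_path)
            tio.write_chromatin_traces(observed, traces_path)
            tio.write_gene_states(activity, observed.chromosome_ids, states_path)
            tio.write_allele_trajectories(trajs, alleles_path)
            manifest["stages"]["simulate"] = {
                "outputs": [
                    str(p)
                    for p in (truth_path, traces_path, states_path, alleles_path)
                ]
            }

        if config.stages["spatial"]:
            _require({"traces": traces_path, "states": states_path}, "spatial")
            traces, activity = tio.read_chromatin_traces(
                traces_path, states_path=states_path
            )
            mpd = spatial_stats.distance_summary_matrix(traces, "median")
            seps, means = spatial_stats.expected_mpd(mpd, traces.bin_size)
            rows = []
            for g in range(activity.n_genes):
                entry = {"gene": activity.gene_ids[g]}
                for state in (0, 1):
                    try:
                        entry[f"centroid_nm_state{state}"] = (
                            spatial_stats.centroid_distance(
                                traces,
                                activity,
                                g,
                                config.spatial["window_mb"],
                                state,
                            )
                        )
                    except ValueError:
                        entry[f"centroid_nm_state{state}"] = np.nan
                rows.append(entry)
            mpd_path = out / "mpd_matrix.tsv"
            pd.DataFrame(mpd.values).to_csv(mpd_path, sep="\t", index=False)
            exp_path = out / "expected_mpd.tsv"
            pd.DataFrame(
                {"genomic_distance_bp": seps, "mean_mpd_nm": means}
            ).to_csv(exp_path, sep="\t", index=False)
            centroid_path = out / "centroid_distances.tsv"
            pd.DataFrame(rows).to_csv(centroid_path, sep="\t", index=False)
            manifest["stages"]["spatial"] = {
                "outputs": [str(mpd_path), str(exp_path), str(centroid_path)]
            }

        if config.stages["coexpr"]:
            _require({"traces": traces_path, "states": states_path}, "coexpr")
            traces, activity = tio.read_chromatin_traces(
                traces_path, states_path=states_path
            )
            seed = stage_seed(config.seed, "coexpr")
            min_chrom = config.coexpr.get("min_chrom", 100)
            curves = {}
            for cov in ("genomic_distance", "mpd"):
                c = coexpression.correlation_vs_covariate(
                    traces, activity, cov, n_boot=200, seed=seed
                )
                curves[cov] = {
                    "bin_edges": c.bin_edges,
                    "mean_phi": c.mean_phi,
                    "sem": c.sem,
                    "n": c.n,
                }
            sc = coexpression.correlation_vs_single_chrom_distance(
                traces, activity, min_chrom=min_chrom, n_boot=200, seed=seed
            )
            curves["single_chromosome_distance"] = {
                "bin_edges": sc.bin_edges,
                "mean_phi": sc.mean_phi,
                "sem": sc.sem,
                "n": sc.n,
            }
            coexpr_path = out / "coexpression_curves.json"
            _write_json(coexpr_path, curves)
            manifest["stages"]["coexpr"] = {"outputs": [str(coexpr_path)]}

        if config.stages["msd"]:
            _require({"alleles": alleles_path}, "msd")
            trajs = tio.read_allele_trajectories(alleles_path)
            rel = dynamics.relative_positions(trajs)
            curve = dynamics.msd(rel, seed=stage_seed(config.seed, "msd"))
            d_coeff = dynamics.fit_diffusion(curve, n_dims=2, relative=True)
            msd_path = out / "msd.tsv"
            pd.DataFrame(
                {
                    "lag_s": curve.lags,
                    "msd_um2": curve.msd,
                    "ci_lo": curve.ci95[0],
                    "ci_hi": curve.ci95[1],
                    "n": curve.n_observations,
                }
            ).to_csv(msd_path, sep="\t", index=False)
            d_path = out / "diffusion.json"
            _write_json(
                d_path,
                {"diffusion_um2_per_s": d_coeff, "n_tracks": len(rel)},
            )
            manifest["stages"]["msd"] = {"outputs": [str(msd_path), str(d_path)]}

        pair_data = None
        if config.stages["distance_model"] or config.stages["coburst"]:
            pass  # shared inputs are built below when needed

        if config.stages["distance_model"]:
            _require({"traces": traces_path, "states": states_path}, "distance_model")
            traces, activity = tio.read_chromatin_traces(
                traces_path, states_path=states_path
            )
            rows = []
            for gi, gj in syn_cfg.coburst_pairs:
                pi = int(activity.promoter_locus[gi])
                pj = int(activity.promoter_locus[gj])
                d = traces.pair_distances(pi, pj)
                obs = dp.DistanceDistribution.from_samples(d[~np.isnan(d)])
                dec = dp.deconvolve_distance_distribution(
                    obs, syn_cfg.localization_sigma
                )
                drift = dp.drift_from_distribution(
                    dec, 2.0 * syn_cfg.diffusion_coeff * 1e6
                )
                for c, po, pdec, mu in zip(
                    obs.bin_centers, obs.pmf, dec.pmf, drift.values
                ):
                    rows.append(
                        {
                            "pair": f"{activity.gene_ids[gi]}-{activity.gene_ids[gj]}",
                            "r_nm": c,
                            "p_observed": po,
                            "p_deconvolved": pdec,
                            "drift_nm_per_s": mu,
                        }
                    )
            dist_path = out / "distance_model.tsv"
            pd.DataFrame(rows).to_csv(dist_path, sep="\t", index=False)
            manifest["stages"]["distance_model"] = {"outputs": [str(dist_path)]}

        if config.stages["coburst"]:
            _require({"traces": traces_path, "states": states_path}, "coburst")
            traces, activity = tio.read_chromatin_traces(
                traces_path, states_path=states_path
            )
            seed = stage_seed(config.seed, "coburst")
            search_kwargs = {
                k: v for k, v in config.coburst.items() if k != "omega_bins"
            }
            search_kwargs.setdefault("seed", seed)
            search = cobursting.OmegaSearchConfig(**search_kwargs)
            lookup = cobursting.build_ptot_lookup(
                pd=syn_cfg.pd, n_traj=500, T=syn_cfg.burst_T, seed=seed + 1
            )
            pair_data = []
            for gi, gj in syn_cfg.coburst_pairs:
                pi = int(activity.promoter_locus[gi])
                pj = int(activity.promoter_locus[gj])
                d = traces.pair_distances(pi, pj)
                ok = ~np.isnan(d)
                pair_data.append(
                    cobursting.pair_data_from_observations(
                        activity.states[ok, gi],
                        activity.states[ok, gj],
                        d[ok],
                        lookup,
                        sigma=syn_cfg.localization_sigma,
                        n_bins=search.n_bins,
                        min_chrom=search.min_chrom,
                        label=f"{activity.gene_ids[gi]}-{activity.gene_ids[gj]}",
                    )
                )
            if not pair_data:
                raise DependencyError(
                    "stage 'coburst' requires synthetic co-burst pairs in the config"
                )
            fit = cobursting.fit_omega(pair_data, search)
            noise = cobursting.noise_removal_experiments(
                fit.omega, pair_data, search, seed=seed + 2
            )
            coburst_path = out / "coburst_fit.json"
            _write_json(
                coburst_path,
                {
                    "omega_values": fit.omega.values,
                    "omega_bin_width": fit.omega.bin_width,
                    "error": fit.error,
                    "n_evaluated": fit.n_evaluated,
                    "noise_removal": {
                        k: v["mean_phi"] for k, v in noise.items()
                    },
                },
            )
            manifest["stages"]["coburst"] = {"outputs": [str(coburst_path)]}
    except DependencyError:
        _write_json(out / "manifest.json", manifest)  # partial outputs retained
        raise
    except Exception as exc:  # abort with the stage named
        running = [s for s in STAGES if config.stages[s] and s not in manifest["stages"]]
        stage = running[0] if running else "unknown"
        _write_json(out / "manifest.json", manifest)
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    _write_json(out / "manifest.json", manifest)
    return manifest
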