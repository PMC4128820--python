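"""End-to-end analysis pipeline.

Mirrors the study workflow on one dataset: per-clade summary statistics with
coalescent-null p-values, multi-chain calibrated MCMC dating (pooled after
burnin, ESS-checked), MCC tree export, node-time table, demographic model
comparison by power-posterior marginal likelihoods, and a skyline
reconstruction.  Every stage's outputs land in the output directory as they
are produced; a manifest records seeds and configurations sufficient to
re-run bit-identically.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import Alignment
from .demography import DemographicModel
from .errors import InvalidInputError, LandbridgeError, UndefinedStatisticError
from .io import config_from_json, read_clades, read_fasta
from .mcmc import ModelConfig
from .model import CalibratedClockModel
from .model_selection import log_bayes_factor
from .popgen import coalescent_null_test, nucleotide_diversity
from .priors import land_bridge_clade_calibration, root_age_calibration
from .simulate import StudyConfig, generate_study_like_dataset
from .skyline import export_skyline
from .substitution import ClockModel, SubstitutionModel

__all__ = ["run_pipeline", "default_study_model", "stats_table"]

log = logging.getLogger("landbridge")

_DEFAULTS = {
    "seed": 1,
    "data": {"simulate": {}},
    "clades": None,
    "model": None,
    "calibrated_clade": "Scandinavia",
    "stats": {"alpha": 0.1705, "n_boot": 1000, "n_sims": 2000},
    "mcmc": {"n_chains": 2, "n_generations": 20_000, "thin": 50,
             "burnin_fraction": 0.1},
    "model_selection": {"enabled": True, "n_steps": 12,
                        "generations_per_step": 1_200,
                        "models": ["expansion", "constant"]},
    "skyline": {"enabled": True, "groups": 8, "grid": 100,
                "n_generations": 20_000},
}


def default_study_model(
    clades: dict[str, list[str]],
    demography: str = "expansion",
    calibrated_clade: str = "Scandinavia",
    n_tips: int | None = None,
    skyline_groups: int = 8,
) -> ModelConfig:
    """The study-style model: partitioned HKY+Gamma, strict clock, land-bridge
    clade calibration plus offset-gamma root calibration."""
    calibrations = []
    if calibrated_clade in clades:
        calibrations.append(
            land_bridge_clade_calibration(calibrated_clade,
                                          clades[calibrated_clade])
        )
    calibrations.append(root_age_calibration())
    if demography == "skyline":
        if n_tips is None:
            raise InvalidInputError("skyline model needs the tip count")
        m = min(skyline_groups, n_tips - 1)
        sizes = np.full(m, (n_tips - 1) // m)
        sizes[: (n_tips - 1) % m] += 1
        demog = DemographicModel(kind="skyline", group_sizes=sizes,
                                 group_thetas=np.full(m, 30_000.0))
    elif demography == "expansion":
        demog = DemographicModel(kind="expansion", theta0=30_000.0,
                                 growth_rate=2e-4)
    else:
        demog = DemographicModel(kind="constant", theta0=30_000.0)
    return ModelConfig(
        subst=SubstitutionModel(),
        clock=ClockModel(kind="strict", mean_rate=4.5e-7),
        demography=demog,
        calibrations=tuple(calibrations),
        clades=clades,
    )


def stats_table(aln: Alignment, clades: dict[str, list[str]],
                alpha: float = 0.1705, n_boot: int = 1000,
                n_sims: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Per-lineage diversity and neutrality table (Table-1 shape):
    lineage, n, pi, se_pi, tajima_D, D_p_coal, fu_FS, FS_p_coal."""
    rows = []
    rng = np.random.default_rng(seed)
    for name, taxa in clades.items():
        sub = aln.take_sequences(taxa)
        div = nucleotide_diversity(sub, alpha=alpha, n_boot=n_boot,
                                   seed=int(rng.integers(2**31 - 1)))
        row = {"lineage": name, "n": sub.n_sequences,
               "pi": round(div.pi, 5), "se_pi": round(div.se_pi, 5)}
        for stat, prefix in (("tajima_d", "D"), ("fu_fs", "FS")):
            try:
                res = coalescent_null_test(sub, stat, n_sims=n_sims,
                                           seed=int(rng.integers(2**31 - 1)))
                row[f"{prefix}"] = round(res.observed, 5)
                row[f"{prefix}_p_coal"] = round(res.p_coal, 5)
            except UndefinedStatisticError:
                row[f"{prefix}"] = np.nan
                row[f"{prefix}_p_coal"] = np.nan
        rows.append(row)
    cols = ["lineage", "n", "pi", "se_pi", "D", "D_p_coal", "FS", "FS_p_coal"]
    return pd.DataFrame(rows)[cols]


def _load_config(source) -> dict:
    if isinstance(source, dict):
        doc = source
    else:
        doc = json.loads(Path(source).read_text())
    cfg = json.loads(json.dumps(_DEFAULTS))  # deep copy
    for k, v in doc.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def run_pipeline(config, out_dir) -> Path:
    """Run the full pipeline; returns the output directory.

    ``config`` is a master-config path or dict (see ``_DEFAULTS`` for the
    schema and desk-scale defaults).  Any stage failure raises with the
    stage name; outputs already written are retained.
    """
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master_seed = int(cfg["seed"])
    seeds = {name: int(s.generate_state(1)[0] % (2**31 - 1))
             for name, s in zip(
                 ["simulate", "stats", "mcmc", "mlestimate", "skyline"],
                 np.random.SeedSequence(master_seed).spawn(5))}
    manifest = {"master_seed": master_seed, "stage_seeds": seeds,
                "config": cfg, "stages": {}}
    t_start = time.time()

    def finish_stage(name, **info):
        manifest["stages"][name] = {"elapsed_s": round(time.time() - t_start, 2),
                                    **info}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    stage = "data"
    try:
        truth = None
        if "fasta" in cfg["data"]:
            aln = read_fasta(cfg["data"]["fasta"])
        else:
            sim_kwargs = dict(cfg["data"].get("simulate", {}))
            study = StudyConfig(**sim_kwargs)
            aln, true_tree, truth = generate_study_like_dataset(
                study, seeds["simulate"])
            aln.to_fasta(out / "alignment.fasta")
            (out / "true_tree.nwk").write_text(true_tree.to_newick() + "\n")
            truth.to_json(out / "truth.json")
        if cfg["clades"] is None:
            if truth is None:
                raise InvalidInputError(
                    "clade definitions are required with external data"
                )
            clades = truth.clades
        elif isinstance(cfg["clades"], dict):
            clades = cfg["clades"]
        else:
            clades = read_clades(cfg["clades"])
        finish_stage(stage, n_sequences=aln.n_sequences, n_sites=aln.n_sites)

        stage = "stats"
        s = cfg["stats"]
        table1 = stats_table(aln, clades, alpha=s["alpha"], n_boot=s["n_boot"],
                             n_sims=s["n_sims"], seed=seeds["stats"])
        table1.to_csv(out / "table1.tsv", sep="\t", index=False)
        finish_stage(stage, rows=len(table1))

        stage = "mcmc"
        if cfg["model"] is not None:
            model_cfg = config_from_json(cfg["model"])
        else:
            model_cfg = default_study_model(
                clades, demography="expansion",
                calibrated_clade=cfg["calibrated_clade"])
        m = cfg["mcmc"]
        model = CalibratedClockModel(aln, model_cfg)
        results = model.fit(
            n_generations=m["n_generations"], thin=m["thin"],
            burnin_fraction=m["burnin_fraction"], n_chains=m["n_chains"],
            seed=seeds["mcmc"],
        )
        ess_table = results.ess_by_chain(min_ess=200.0)
        ess_table.to_csv(out / "ess.tsv", sep="\t", index=False)
        results.summary().to_csv(out / "parameters.tsv", sep="\t")
        results.node_times_frame().to_csv(out / "table2.tsv", sep="\t",
                                          index=False)
        results.mcc_tree().to_nexus(out / "mcc.nex")
        finish_stage(stage,
                     n_chains=m["n_chains"],
                     pooled_samples=int(results.trace.n_samples),
                     low_ess_parameters=int(ess_table["below_target"].sum()))

        stage = "model_selection"
        if cfg["model_selection"]["enabled"]:
            ms = cfg["model_selection"]
            mls = {}
            for kind in ms["models"]:
                mc = default_study_model(clades, demography=kind,
                                         calibrated_clade=cfg["calibrated_clade"],
                                         n_tips=aln.n_sequences)
                ml = CalibratedClockModel(aln, mc).marginal_likelihood(
                    n_steps=ms["n_steps"],
                    generations_per_step=ms["generations_per_step"],
                    seed=seeds["mlestimate"],
                )
                mls[kind] = ml
            a, b = ms["models"][:2]
            comp = log_bayes_factor(mls[a].log_ml_path, mls[b].log_ml_path)
            doc = {
                "models": {
                    k: {"log_ml_path": v.log_ml_path,
                        "log_ml_stepping_stone": v.log_ml_stepping_stone,
                        "ps_ss_discrepancy": v.discrepancy}
                    for k, v in mls.items()
                },
                "comparison": {
                    "a": a, "b": b,
                    "log_bayes_factor": comp.log_bayes_factor,
                    "interpretation": comp.interpretation,
                    "favoured": {None: None, "a": a, "b": b}[comp.favoured],
                },
            }
            (out / "model_comparison.json").write_text(json.dumps(doc, indent=2))
            finish_stage(stage, log_bf=comp.log_bayes_factor)

        stage = "skyline"
        if cfg["skyline"]["enabled"]:
            sk = cfg["skyline"]
            sk_cfg = default_study_model(
                clades, demography="skyline",
                calibrated_clade=cfg["calibrated_clade"],
                n_tips=aln.n_sequences, skyline_groups=sk["groups"])
            sk_results = CalibratedClockModel(aln, sk_cfg).fit(
                n_generations=sk["n_generations"],
                thin=cfg["mcmc"]["thin"],
                burnin_fraction=cfg["mcmc"]["burnin_fraction"],
                seed=seeds["skyline"],
            )
            curve = sk_results.skyline(grid_size=sk["grid"])
            export_skyline(curve, out / "skyline.tsv",
                           plot_path=(out / "skyline.png") if sk.get("plot")
                           else None)
            finish_stage(stage, truncation_age=curve.truncation_age)
    except LandbridgeError:
        raise
    except Exception as exc:
        raise LandbridgeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
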