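"""File formats: FASTA alignments, Newick/NEXUS trees, clade definitions,
and JSON (de)serialization of model configurations."""

from __future__ import annotations

import json
from pathlib import Path

import dendropy
import numpy as np

from .alignment import Alignment
from .demography import DemographicModel
from .errors import InvalidInputError
from .mcmc import ModelConfig
from .priors import (
    CalibrationPrior,
    ExponentialPrior,
    LogNormalPrior,
    OffsetGammaCalibration,
    TruncatedNormalCalibration,
)
from .substitution import ClockModel, SubstitutionModel
from .trees import TimeTree

__all__ = [
    "read_fasta", "read_clades", "write_clades",
    "read_trees", "write_trees",
    "config_to_json", "config_from_json",
]


def read_fasta(path) -> Alignment:
    """Read an aligned FASTA file (order preserved, uppercased, lengths
    validated; the offending record is named on a ragged alignment)."""
    return Alignment.from_fasta(path)


# ------------------------------------------------------------------- clades
def read_clades(path, allow_overlap: bool = False) -> dict[str, list[str]]:
    doc = json.loads(Path(path).read_text())
    if not isinstance(doc, dict) or not doc:
        raise InvalidInputError("clade file must be a non-empty JSON object")
    seen: dict[str, str] = {}
    for name, taxa in doc.items():
        if not isinstance(taxa, list) or not taxa:
            raise InvalidInputError(f"clade {name!r} must list at least one taxon")
        for t in taxa:
            if t in seen and not allow_overlap:
                raise InvalidInputError(
                    f"taxon {t!r} appears in both {seen[t]!r} and {name!r}"
                )
            seen[t] = name
    return {name: list(taxa) for name, taxa in doc.items()}


def write_clades(clades: dict[str, list[str]], path) -> None:
    Path(path).write_text(json.dumps(clades, indent=2))


# -------------------------------------------------------------------- trees
def read_trees(path, schema: str = "newick") -> list[TimeTree]:
    """Read time trees (branch lengths in years are required)."""
    if schema not in ("newick", "nexus"):
        raise InvalidInputError("schema must be 'newick' or 'nexus'")
    try:
        trees = dendropy.TreeList.get(path=str(path), schema=schema)
    except Exception as exc:
        raise InvalidInputError(f"unparseable tree file {path}: {exc}") from exc
    if not trees:
        raise InvalidInputError(f"no trees in {path}")
    return [TimeTree.from_dendropy(t) for t in trees]


def write_trees(trees: list[TimeTree], path, schema: str = "newick") -> None:
    if schema not in ("newick", "nexus"):
        raise InvalidInputError("schema must be 'newick' or 'nexus'")
    tns = dendropy.TaxonNamespace()
    tl = dendropy.TreeList(taxon_namespace=tns)
    for t in trees:
        d = t.to_dendropy(taxon_namespace=tns)
        d.taxon_namespace = tns
        tl.append(d)
    tl.write(path=str(path), schema=schema)


# ------------------------------------------------------------------- config
def _prior_to_dict(p):
    if isinstance(p, LogNormalPrior):
        return {"kind": "lognormal", "meanlog": p.meanlog, "sdlog": p.sdlog}
    if isinstance(p, ExponentialPrior):
        return {"kind": "exponential", "mean": p.mean}
    raise InvalidInputError(f"unserializable prior {type(p).__name__}")


def _prior_from_dict(d):
    if d["kind"] == "lognormal":
        return LogNormalPrior(d["meanlog"], d["sdlog"])
    if d["kind"] == "exponential":
        return ExponentialPrior(d["mean"])
    raise InvalidInputError(f"unknown prior kind {d['kind']!r}")


def _calibration_to_dict(c: CalibrationPrior):
    dens = c.density
    if isinstance(dens, TruncatedNormalCalibration):
        dd = {"kind": "truncated_normal", "mean": dens.mean, "sd": dens.sd,
              "lower": dens.lower, "upper": dens.upper}
    elif isinstance(dens, OffsetGammaCalibration):
        dd = {"kind": "offset_gamma", "offset": dens.offset, "peak": dens.peak,
              "shape": dens.shape}
    else:
        raise InvalidInputError("unserializable calibration density")
    return {"target": c.target, "taxa": list(c.taxa) if c.taxa else None,
            "monophyly_enforced": c.monophyly_enforced, "density": dd}


def _calibration_from_dict(d):
    dd = d["density"]
    if dd["kind"] == "truncated_normal":
        dens = TruncatedNormalCalibration(dd["mean"], dd["sd"], dd["lower"],
                                          dd["upper"])
    elif dd["kind"] == "offset_gamma":
        dens = OffsetGammaCalibration(dd["offset"], dd["peak"],
                                      dd.get("shape", 2.0))
    else:
        raise InvalidInputError(f"unknown calibration kind {dd['kind']!r}")
    taxa = d.get("taxa")
    return CalibrationPrior(target=d["target"],
                            taxa=tuple(taxa) if taxa else None,
                            monophyly_enforced=d.get("monophyly_enforced", True),
                            density=dens)


def config_to_json(config: ModelConfig, path=None) -> str:
    demog = config.demography
    doc = {
        "units": "years BP",
        "substitution": {
            "kappa": config.subst.kappa.tolist(),
            "base_freqs": config.subst.base_freqs.tolist(),
            "gamma_alpha": config.subst.gamma_alpha.tolist(),
            "n_categories": config.subst.n_categories,
            "rate_ratio": config.subst.rate_ratio,
        },
        "clock": {
            "kind": config.clock.kind,
            "mean_rate": config.clock.mean_rate,
            "ucln_sigma": config.clock.ucln_sigma,
        },
        "demography": {
            "kind": demog.kind,
            "theta0": demog.theta0,
            "growth_rate": demog.growth_rate,
            "ancestral_fraction": demog.ancestral_fraction,
            "group_sizes": None if demog.group_sizes is None
            else demog.group_sizes.tolist(),
            "group_thetas": None if demog.group_thetas is None
            else demog.group_thetas.tolist(),
        },
        "calibrations": [_calibration_to_dict(c) for c in config.calibrations],
        "clades": config.clades,
        "fixed_topology": config.fixed_topology,
        "estimate": {
            k: getattr(config, f"estimate_{k}")
            for k in ("rate", "kappa", "alpha", "freqs", "rate_ratio",
                      "demography", "ucln_sigma")
        },
        "priors": {
            "rate": _prior_to_dict(config.rate_prior),
            "kappa": _prior_to_dict(config.kappa_prior),
            "alpha": _prior_to_dict(config.alpha_prior),
            "rate_ratio": _prior_to_dict(config.rate_ratio_prior),
            "theta": _prior_to_dict(config.theta_prior),
            "growth": _prior_to_dict(config.growth_prior),
            "ucln_sigma": _prior_to_dict(config.ucln_sigma_prior),
        },
    }
    text = json.dumps(doc, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_from_json(source) -> ModelConfig:
    """Rebuild a :class:`ModelConfig` from a JSON string or file path."""
    text = Path(source).read_text() if isinstance(source, (str, Path)) \
        and "{" not in str(source) else str(source)
    doc = json.loads(text)
    sub = doc["substitution"]
    demog = doc["demography"]
    kwargs = {
        "subst": SubstitutionModel(
            kappa=np.asarray(sub["kappa"]),
            base_freqs=np.asarray(sub["base_freqs"]),
            gamma_alpha=np.asarray(sub["gamma_alpha"]),
            n_categories=sub["n_categories"],
            rate_ratio=sub["rate_ratio"],
        ),
        "clock": ClockModel(kind=doc["clock"]["kind"],
                            mean_rate=doc["clock"]["mean_rate"],
                            ucln_sigma=doc["clock"]["ucln_sigma"]),
        "demography": DemographicModel(
            kind=demog["kind"], theta0=demog["theta0"],
            growth_rate=demog.get("growth_rate", 0.0),
            ancestral_fraction=demog.get("ancestral_fraction", 0.0),
            group_sizes=demog.get("group_sizes"),
            group_thetas=demog.get("group_thetas"),
        ),
        "calibrations": tuple(_calibration_from_dict(c)
                              for c in doc.get("calibrations", [])),
        "clades": doc.get("clades", {}),
        "fixed_topology": doc.get("fixed_topology", False),
    }
    for k, v in doc.get("estimate", {}).items():
        kwargs[f"estimate_{k}"] = v
    for k, v in doc.get("priors", {}).items():
        kwargs[f"{k}_prior"] = _prior_from_dict(v)
    return ModelConfig(**kwargs)
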