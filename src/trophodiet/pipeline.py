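"""One-config orchestration of simulate → filter → selectivity → community.

The pipeline is driven by a single YAML file with optional blocks::

    seed: 1
    out_dir: results
    simulate: { n_estuaries: 6, ... }     # or
    inputs:   { counts: ..., taxonomy: ..., metadata: ... }
    filter:   { min_sample_depth: 1000, ... }
    selectivity: { report_threshold: 0.005, phylum: true }
    community:
      mantel: true
      permanova: [estuary]          # or [estuary, site] for nested
      n_perm: 999
      rarefy_depth: 1000

Any block may be omitted; stages run in the fixed order above.  A
:class:`RunManifest` records config and file digests so that re-running
with identical inputs and seed reproduces identical output digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import community as comm
from . import filtering, io, selectivity, simulate
from .table import MotuTable, ValidationError


class ConfigError(ValueError):
    """Pipeline configuration violates the schema; message names the field."""


@dataclass
class RunManifest:
    config_hash: str
    seed: int | None
    input_digests: dict[str, str] = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)
    output_digests: dict[str, str] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def _digest_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _digest_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


_KNOWN_BLOCKS = {"seed", "out_dir", "simulate", "inputs", "filter",
                 "selectivity", "community"}


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(cfg) - _KNOWN_BLOCKS
    if unknown:
        raise ConfigError(f"unknown config blocks {sorted(unknown)}")
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ConfigError("config needs a 'simulate' or 'inputs' block")
    if "inputs" in cfg:
        inputs = cfg["inputs"]
        for key in ("counts", "taxonomy", "metadata"):
            if key not in inputs:
                raise ConfigError(f"inputs.{key}: required field missing")
        for key in ("counts", "taxonomy", "metadata"):
            if not Path(inputs[key]).exists():
                raise ConfigError(f"inputs.{key}: file not found: {inputs[key]}")
    return cfg


def run_all(config_path, out_dir=None, seed: int | None = None) -> RunManifest:
    """Execute all configured stages; write outputs plus manifest.json.

    Returns the manifest.  Raises (and writes nothing further) on the
    first stage error; partial outputs keep their stage-specific names
    so an aborted run is recognizable.
    """
    cfg = load_config(config_path)
    if seed is None:
        seed = cfg.get("seed")
    out = Path(out_dir or cfg.get("out_dir") or "trophodiet_out")
    out.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(
        config_hash=_digest_obj(cfg), seed=seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    outputs: dict[str, Path] = {}

    # --- obtain the raw table --------------------------------------------
    if "simulate" in cfg:
        sim_cfg = simulate.SimConfig.from_dict(cfg.get("simulate") or {})
        table, truth = simulate.simulate_dataset(sim_cfg, seed=seed)
        paths = io.write_motu_table(table, out / "simulated")
        outputs.update({f"simulated_{k}": p for k, p in paths.items()})
        truth_path = out / "truth.json"
        truth_path.write_text(
            json.dumps(truth.to_json_dict(), indent=2), encoding="utf-8"
        )
        outputs["truth"] = truth_path
        manifest.stages.append({"name": "simulate", "seed": seed})
    else:
        inputs = cfg["inputs"]
        table = io.read_motu_table(
            inputs["counts"], inputs["taxonomy"], inputs["metadata"]
        )
        manifest.input_digests = {
            k: _digest_file(Path(v)) for k, v in inputs.items()
        }
        manifest.stages.append({"name": "load_inputs"})

    # --- filter cascade ---------------------------------------------------
    filtered = table
    if "filter" in cfg:
        fcfg = filtering.FilterConfig.from_dict(cfg.get("filter") or {})
        filtered, report = filtering.run_cascade(table, fcfg)
        paths = io.write_motu_table(filtered, out / "filtered")
        outputs.update({f"filtered_{k}": p for k, p in paths.items()})
        rp = out / "filter_report.json"
        report.to_json(rp)
        outputs["filter_report"] = rp
        manifest.stages.append(
            {"name": "filter", "stage_order": list(fcfg.stage_order)}
        )

    diet = filtered.subset(sample_types={"stomach"}) \
        if (filtered.samples["sample_type"] == "stomach").any() else None
    env = filtered.subset(sample_types={"sediment"}) \
        if (filtered.samples["sample_type"] == "sediment").any() else None

    # --- selectivity ------------------------------------------------------
    if "selectivity" in cfg:
        scfg = dict(cfg.get("selectivity") or {})
        unknown = set(scfg) - {"report_threshold", "phylum", "high", "low"}
        if unknown:
            raise ConfigError(f"selectivity: unknown fields {sorted(unknown)}")
        if diet is None or env is None:
            raise ConfigError(
                "selectivity: filtered table lacks stomach or sediment samples"
            )
        pairing = selectivity.pair_by_site(diet, env)
        summary = selectivity.diet_summary(
            diet, env, pairing,
            report_threshold=float(scfg.get("report_threshold", 0.005)),
            high=float(scfg.get("high", 0.10)),
            low=float(scfg.get("low", 0.01)),
        )
        sp = out / "diet_summary.tsv"
        summary.to_csv(sp, sep="\t")
        outputs["diet_summary"] = sp
        if scfg.get("phylum", False):
            ph = selectivity.phylum_summary(diet, env, pairing)
            pp = out / "phylum_summary.tsv"
            ph.to_csv(pp, sep="\t")
            outputs["phylum_summary"] = pp
        manifest.stages.append({"name": "selectivity"})

    # --- community statistics --------------------------------------------
    if "community" in cfg:
        ccfg = dict(cfg.get("community") or {})
        unknown = set(ccfg) - {"mantel", "permanova", "n_perm", "rarefy_depth",
                               "transform"}
        if unknown:
            raise ConfigError(f"community: unknown fields {sorted(unknown)}")
        n_perm = int(ccfg.get("n_perm", 999))
        results: dict[str, dict] = {}
        if ccfg.get("mantel", False):
            if diet is None or env is None:
                raise ConfigError("community.mantel needs stomach and sediment")
            pairing = selectivity.pair_by_site(diet, env)
            # mean stomach composition per site against its sediment sample
            by_site: dict[str, list[str]] = {}
            for st, sed in pairing:
                by_site.setdefault(sed, []).append(st)
            sed_ids = sorted(by_site)
            diet_rel = pd.DataFrame({
                sed: pd.concat(
                    [diet.relative_abundance(s) for s in by_site[sed]], axis=1
                ).mean(axis=1)
                for sed in sed_ids
            })
            env_rel = pd.DataFrame(
                {sed: env.relative_abundance(sed) for sed in sed_ids}
            ).reindex(diet_rel.index).fillna(0.0)
            from scipy.spatial.distance import pdist, squareform
            from skbio import DistanceMatrix
            d1 = DistanceMatrix(
                squareform(pdist(diet_rel.T, metric="braycurtis")), ids=sed_ids
            )
            d2 = DistanceMatrix(
                squareform(pdist(env_rel.T, metric="braycurtis")), ids=sed_ids
            )
            res = comm.mantel(d1, d2, n_perm=n_perm, seed=seed)
            results["mantel_diet_vs_environment"] = dataclasses.asdict(res)
        groups = ccfg.get("permanova")
        if groups:
            if isinstance(groups, str):
                groups = [groups]
            dm = comm.bray_curtis(
                filtered.subset(sample_types={"stomach", "sediment"}),
                transform=ccfg.get("transform", "sqrt"),
            )
            meta = filtered.samples
            factors = []
            for g in groups:
                if g == "sample_type":
                    factors.append(meta["sample_type"])
                elif g in ("estuary", "site"):
                    factors.append(meta[g])
                else:
                    raise ConfigError(f"community.permanova: unknown factor {g!r}")
            grouping = factors[0] if len(factors) == 1 else tuple(factors)
            res = comm.permanova(dm, grouping, n_perm=n_perm, seed=seed)
            if isinstance(res, dict):
                results["permanova"] = {
                    k: dataclasses.asdict(v) for k, v in res.items()
                }
            else:
                results["permanova"] = dataclasses.asdict(res)
        if "rarefy_depth" in ccfg and diet is not None:
            depth = int(ccfg["rarefy_depth"])
            rich = {
                s: comm.rarefy_richness(diet.counts[s].to_numpy(), depth)
                for s in diet.sample_ids
                if diet.sample_depths()[s] >= depth
            }
            results["rarefied_richness"] = rich
        cp = out / "community_stats.json"
        cp.write_text(json.dumps(results, indent=2, default=str),
                      encoding="utf-8")
        outputs["community_stats"] = cp
        manifest.stages.append({"name": "community", "n_perm": n_perm,
                                "seed": seed})

    manifest.output_digests = {k: _digest_file(p) for k, p in outputs.items()}
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.to_json(out / "manifest.json")
    return manifest
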