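"""Synthetic paired stomach/sediment metabarcoding datasets with ground truth.

The generator emulates the sampling design of a multi-estuary diet
survey of a benthic consumer: several estuaries, several sites per
estuary, one pooled sediment eDNA sample per site and three pooled
stomach samples per site (batches of up to eight stomachs), plus pooled
visually-empty stomachs and PCR-negative controls.

Generative model
----------------
* Each estuary draws a base prey community from a log-normal abundance
  profile; each site perturbs it with a Dirichlet draw (between-site
  heterogeneity).
* Consumption acts multiplicatively on availability: the expected diet
  composition at a site is r ∝ p · w, where p is the site community and
  w ≥ 0 a per-taxon preference weight.  Under this model Jacobs' D is a
  monotone function of w, which is what makes parameter-recovery tests
  meaningful.
* Stomach reads are dominated by the consumer's own DNA (default 28% of
  reads) and a ubiquitous fungal taxon (default 36%), as seen in real
  stomach libraries; sediment carries traces of both.
* Bacterial and human contaminant MOTUs are spiked at a small fraction;
  one lab-contaminant MOTU concentrates in the negative controls.
* Tag switching moves a configurable fraction of each sample's reads to
  uniformly chosen other samples (controls included), conserving totals.
* Optionally, one prey species is emitted as two MOTU records to
  exercise same-species merging.

Every stochastic choice flows from a single seed; identical
(config, seed) pairs give bit-identical tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .table import MotuTable, ValidationError

_PHYLA = (
    "Arthropoda", "Annelida", "Chordata", "Mollusca", "Bacillariophyta",
    "Dinoflagellata", "Nematoda", "Cnidaria", "Rhodophyta", "Echinodermata",
)

FOCAL_SPECIES = "Crangon crangon"
FUNGAL_SPECIES = "Purpureocillium lilacinum"


class SimulationError(ValueError):
    pass


def default_preference_weights(n_taxa: int) -> np.ndarray:
    """Geometric preference ladder from strong selection to strong avoidance.

    Weights are log-spaced from 50 down to 0.02 across the taxa, so
    every taxon has a distinct preference rank — rank-order recovery is
    then well defined (heavy ties would cap any rank correlation well
    below 1 regardless of estimator quality).
    """
    return np.geomspace(50.0, 0.02, n_taxa)


@dataclass
class SimConfig:
    """Study design and generative parameters for one synthetic dataset."""

    n_estuaries: int = 6
    sites_per_estuary: int = 4
    stomach_pools_per_site: int = 3
    pool_size: int = 8
    n_taxa: int = 30
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.5
    site_dirichlet_concentration: float = 200.0
    preference_weights: np.ndarray | None = None
    focal_read_fraction: float = 0.28
    fungal_read_fraction: float = 0.36
    sediment_focal_fraction: float = 0.01
    sediment_fungal_fraction: float = 0.001
    contaminant_read_fraction: float = 0.002
    stomach_depth: int = 50_000
    sediment_depth: int = 20_000
    empty_stomach_depth: int = 200
    n_empty_stomach: int = 3
    n_negative_controls: int = 3
    tag_switch_rate: float = 0.002
    negctrl_contam_rate: float = 0.002
    split_species_motus: int = 1
    per_gut: bool = False
    gut_dirichlet_concentration: float = 5.0
    seed: int | None = None

    def __post_init__(self) -> None:
        fracs = (
            self.focal_read_fraction, self.fungal_read_fraction,
            self.sediment_focal_fraction, self.sediment_fungal_fraction,
            self.contaminant_read_fraction, self.tag_switch_rate,
            self.negctrl_contam_rate,
        )
        if any(not (0 <= f <= 1) for f in fracs):
            raise SimulationError("all fractions must lie in [0,1]")
        if self.focal_read_fraction + self.fungal_read_fraction >= 1:
            raise SimulationError("focal + fungal fractions must leave diet reads")
        for d in (self.stomach_depth, self.sediment_depth, self.empty_stomach_depth):
            if d < 1:
                raise SimulationError("depths must be positive integers")
        if self.n_taxa < 2:
            raise SimulationError("need at least 2 prey taxa")
        if not (1 <= self.pool_size <= 8):
            raise SimulationError("pool_size must be in [1,8]")
        if self.preference_weights is not None:
            w = np.asarray(self.preference_weights, dtype=float)
            if len(w) != self.n_taxa:
                raise SimulationError("preference_weights length != n_taxa")
            if np.any(w < 0):
                raise SimulationError("preference weights must be >= 0")
            if not np.any(w > 0):
                raise SimulationError("all preference weights are zero")
            object.__setattr__(self, "preference_weights", w)

    def weights(self) -> np.ndarray:
        if self.preference_weights is None:
            return default_preference_weights(self.n_taxa)
        return np.asarray(self.preference_weights, dtype=float)

    @classmethod
    def from_dict(cls, d) -> "SimConfig":
        d = dict(d)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise SimulationError(f"unknown simulate config fields {sorted(unknown)}")
        if d.get("preference_weights") is not None:
            d["preference_weights"] = np.asarray(d["preference_weights"], float)
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated dataset."""

    site_community: pd.DataFrame       # taxa x sites: availability p
    diet_proportions: pd.DataFrame     # taxa x sites: expected diet r ∝ p·w
    preference_weights: pd.Series      # per prey taxon
    taxon_motus: dict[str, list[str]]  # prey taxon -> emitted MOTU id(s)
    tag_jump_events: list[dict]        # {motu, source, dest, reads}
    contaminant_motus: list[str]
    focal_counts: pd.Series            # per sample, pre-jump
    fungal_counts: pd.Series

    def to_json_dict(self) -> dict:
        return {
            "site_community": self.site_community.to_dict(),
            "diet_proportions": self.diet_proportions.to_dict(),
            "preference_weights": self.preference_weights.to_dict(),
            "taxon_motus": self.taxon_motus,
            "tag_jump_events": self.tag_jump_events,
            "contaminant_motus": self.contaminant_motus,
            "focal_counts": {k: int(v) for k, v in self.focal_counts.items()},
            "fungal_counts": {k: int(v) for k, v in self.fungal_counts.items()},
        }


def _prey_taxonomy(i: int, n_split: int) -> list[tuple[str, dict]]:
    phylum = _PHYLA[i % len(_PHYLA)]
    genus = f"Simulatus"
    species = f"Simulatus taxon{i:03d}"
    base = {
        "rank": "species", "kingdom": "Eukaryota", "phylum": phylum,
        "class": pd.NA, "order": f"Order{i % 7}", "family": f"Family{i % 11}",
        "genus": genus, "species": species, "best_identity": 0.99,
    }
    rows = [(f"motu_prey_{i:03d}", base)]
    if i < n_split:
        dup = dict(base, best_identity=0.93)
        rows.append((f"motu_prey_{i:03d}b", dup))
    return rows


def _fixed_taxonomy() -> dict[str, dict]:
    return {
        "motu_crangon": {
            "rank": "species", "kingdom": "Eukaryota", "phylum": "Arthropoda",
            "class": "Malacostraca", "order": "Decapoda", "family": "Crangonidae",
            "genus": "Crangon", "species": FOCAL_SPECIES, "best_identity": 1.0,
        },
        "motu_fungus": {
            "rank": "species", "kingdom": "Fungi", "phylum": "Ascomycota",
            "class": pd.NA, "order": "Hypocreales", "family": "Ophiocordycipitaceae",
            "genus": "Purpureocillium", "species": FUNGAL_SPECIES,
            "best_identity": 1.0,
        },
        "motu_bacteria": {
            "rank": "phylum", "kingdom": "Bacteria", "phylum": "Proteobacteria",
            "class": pd.NA, "order": pd.NA, "family": pd.NA,
            "genus": pd.NA, "species": pd.NA, "best_identity": 0.85,
        },
        "motu_human": {
            "rank": "species", "kingdom": "Eukaryota", "phylum": "Chordata",
            "class": "Mammalia", "order": "Primates", "family": "Hominidae",
            "genus": "Homo", "species": "Homo sapiens", "best_identity": 1.0,
        },
        "motu_labcontam": {
            "rank": "unassigned", "kingdom": pd.NA, "phylum": pd.NA,
            "class": pd.NA, "order": pd.NA, "family": pd.NA,
            "genus": pd.NA, "species": pd.NA, "best_identity": 0.4,
        },
    }


def simulate_dataset(
    config: SimConfig | None = None, seed: int | None = None
) -> tuple[MotuTable, SimTruth]:
    """Generate one paired stomach/sediment dataset plus its ground truth.

    ``seed`` overrides ``config.seed`` when given.  The emitted table
    passes full validation and is ready for the filter cascade.
    """
    config = config or SimConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    n_taxa = config.n_taxa
    w = config.weights()
    taxa = [f"taxon{i:03d}" for i in range(n_taxa)]

    # --- taxonomy ---------------------------------------------------------
    tax_rows: dict[str, dict] = {}
    taxon_motus: dict[str, list[str]] = {}
    for i, t in enumerate(taxa):
        rows = _prey_taxonomy(i, config.split_species_motus)
        taxon_motus[t] = [mid for mid, _ in rows]
        for mid, row in rows:
            tax_rows[mid] = row
    tax_rows.update(_fixed_taxonomy())
    taxonomy = pd.DataFrame.from_dict(tax_rows, orient="index")

    # --- site structure ---------------------------------------------------
    samples: dict[str, dict] = {}
    site_p: dict[str, np.ndarray] = {}
    site_r: dict[str, np.ndarray] = {}
    site_of: dict[str, str] = {}
    stomach_ids: list[str] = []
    sediment_ids: list[str] = []
    for e in range(config.n_estuaries):
        estuary = f"estuary{e:02d}"
        base = rng.lognormal(config.lognormal_mu, config.lognormal_sigma, n_taxa)
        base /= base.sum()
        for s in range(config.sites_per_estuary):
            site = f"{estuary}_site{s:02d}"
            p = rng.dirichlet(config.site_dirichlet_concentration * base)
            # Dirichlet can underflow tiny categories to exactly 0
            p = np.clip(p, 1e-12, None)
            p /= p.sum()
            r = p * w
            if r.sum() == 0:
                raise SimulationError("diet proportions vanish (all-zero p·w)")
            r /= r.sum()
            site_p[site] = p
            site_r[site] = r
            sed_id = f"sed_{site}"
            samples[sed_id] = {
                "sample_type": "sediment", "site": site, "estuary": estuary,
                "country": "SIM", "pool_size": pd.NA,
            }
            sediment_ids.append(sed_id)
            site_of[sed_id] = site
            for k in range(config.stomach_pools_per_site):
                st_id = f"sto_{site}_p{k}"
                samples[st_id] = {
                    "sample_type": "stomach", "site": site, "estuary": estuary,
                    "country": "SIM", "pool_size": config.pool_size,
                }
                stomach_ids.append(st_id)
                site_of[st_id] = site

    empty_ids = [f"empty_{i}" for i in range(config.n_empty_stomach)]
    for i, eid in enumerate(empty_ids):
        site = list(site_p)[i % len(site_p)]
        samples[eid] = {
            "sample_type": "empty_stomach", "site": site,
            "estuary": site.split("_site")[0], "country": "SIM",
            "pool_size": config.pool_size,
        }
    ctrl_ids = [f"negctrl_{i}" for i in range(config.n_negative_controls)]
    for cid in ctrl_ids:
        samples[cid] = {
            "sample_type": "negative_control", "site": pd.NA,
            "estuary": pd.NA, "country": "SIM", "pool_size": pd.NA,
        }

    motu_ids = list(taxonomy.index)
    sample_ids = stomach_ids + sediment_ids + empty_ids + ctrl_ids
    counts = pd.DataFrame(0, index=motu_ids, columns=sample_ids, dtype=np.int64)
    idx = {m: i for i, m in enumerate(motu_ids)}

    c_frac = config.contaminant_read_fraction

    def place_prey(col: np.ndarray, prey_counts: np.ndarray) -> None:
        for t, cnt in zip(taxa, prey_counts):
            mids = taxon_motus[t]
            if cnt == 0:
                continue
            if len(mids) == 1:
                col[idx[mids[0]]] += cnt
            else:  # split one species over its duplicate MOTUs
                parts = rng.multinomial(cnt, np.full(len(mids), 1 / len(mids)))
                for mid, part in zip(mids, parts):
                    col[idx[mid]] += part

    focal_counts = pd.Series(0, index=sample_ids, dtype=np.int64)
    fungal_counts = pd.Series(0, index=sample_ids, dtype=np.int64)

    # --- sediment ---------------------------------------------------------
    for sid in sediment_ids:
        p = site_p[site_of[sid]]
        extras = config.sediment_focal_fraction + config.sediment_fungal_fraction + 2 * c_frac
        q = np.concatenate([
            p * (1 - extras),
            [config.sediment_focal_fraction, config.sediment_fungal_fraction,
             c_frac, c_frac],
        ])
        draw = rng.multinomial(config.sediment_depth, q / q.sum())
        col = counts[sid].to_numpy()
        place_prey(col, draw[:n_taxa])
        col[idx["motu_crangon"]] += draw[n_taxa]
        col[idx["motu_fungus"]] += draw[n_taxa + 1]
        col[idx["motu_bacteria"]] += draw[n_taxa + 2]
        col[idx["motu_human"]] += draw[n_taxa + 3]
        counts[sid] = col
        focal_counts[sid] = draw[n_taxa]
        fungal_counts[sid] = draw[n_taxa + 1]

    # --- stomach pools ----------------------------------------------------
    diet_share = 1 - config.focal_read_fraction - config.fungal_read_fraction - 2 * c_frac
    for sid in stomach_ids:
        r = site_r[site_of[sid]]
        if config.per_gut:
            # each gut perturbs the site diet; the pool sums gut draws
            per_gut_depth = rng.multinomial(
                config.stomach_depth,
                np.full(config.pool_size, 1 / config.pool_size),
            )
            prey = np.zeros(n_taxa, dtype=np.int64)
            foc = fun = bac = hum = 0
            for d in per_gut_depth:
                rg = rng.dirichlet(config.gut_dirichlet_concentration * r)
                q = np.concatenate([
                    rg * diet_share,
                    [config.focal_read_fraction, config.fungal_read_fraction,
                     c_frac, c_frac],
                ])
                draw = rng.multinomial(d, q / q.sum())
                prey += draw[:n_taxa]
                foc += draw[n_taxa]; fun += draw[n_taxa + 1]
                bac += draw[n_taxa + 2]; hum += draw[n_taxa + 3]
        else:
            q = np.concatenate([
                r * diet_share,
                [config.focal_read_fraction, config.fungal_read_fraction,
                 c_frac, c_frac],
            ])
            draw = rng.multinomial(config.stomach_depth, q / q.sum())
            prey = draw[:n_taxa]
            foc, fun = draw[n_taxa], draw[n_taxa + 1]
            bac, hum = draw[n_taxa + 2], draw[n_taxa + 3]
        col = counts[sid].to_numpy()
        place_prey(col, prey)
        col[idx["motu_crangon"]] += foc
        col[idx["motu_fungus"]] += fun
        col[idx["motu_bacteria"]] += bac
        col[idx["motu_human"]] += hum
        counts[sid] = col
        focal_counts[sid] = foc
        fungal_counts[sid] = fun

    # --- empty stomachs: almost entirely consumer + fungus ----------------
    for eid in empty_ids:
        r = site_r[samples[eid]["site"]]
        q = np.concatenate([r * 0.05, [0.55, 0.40]])
        draw = rng.multinomial(config.empty_stomach_depth, q / q.sum())
        col = counts[eid].to_numpy()
        place_prey(col, draw[:n_taxa])
        col[idx["motu_crangon"]] += draw[n_taxa]
        col[idx["motu_fungus"]] += draw[n_taxa + 1]
        counts[eid] = col
        focal_counts[eid] = draw[n_taxa]
        fungal_counts[eid] = draw[n_taxa + 1]

    # --- lab contamination (concentrates in negative controls) ------------
    ctrl_mean = config.negctrl_contam_rate * config.stomach_depth
    for cid in ctrl_ids:
        counts.loc["motu_labcontam", cid] = rng.poisson(ctrl_mean)
    for sid in stomach_ids + sediment_ids:
        counts.loc["motu_labcontam", sid] = rng.poisson(0.05 * ctrl_mean)

    # --- tag switching: move reads to uniformly chosen other samples ------
    events: list[dict] = []
    if config.tag_switch_rate > 0 and len(sample_ids) > 1:
        mat = counts.to_numpy()
        moves = np.zeros_like(mat)
        arrivals = np.zeros_like(mat)
        n_s = len(sample_ids)
        for j, sid in enumerate(sample_ids):
            col = mat[:, j]
            total = int(col.sum())
            if total == 0:
                continue
            n_jump = rng.binomial(total, config.tag_switch_rate)
            if n_jump == 0:
                continue
            moved = rng.multivariate_hypergeometric(col, n_jump)
            others = [k for k in range(n_s) if k != j]
            for i_m in np.flatnonzero(moved):
                dest = rng.multinomial(
                    int(moved[i_m]), np.full(len(others), 1 / len(others))
                )
                for k, cnt in zip(others, dest):
                    if cnt:
                        arrivals[i_m, k] += cnt
                        events.append({
                            "motu": motu_ids[i_m],
                            "source": sid,
                            "dest": sample_ids[k],
                            "reads": int(cnt),
                        })
            moves[:, j] = moved
        mat = mat - moves + arrivals
        counts = pd.DataFrame(mat, index=motu_ids, columns=sample_ids)

    metadata = pd.DataFrame.from_dict(samples, orient="index")
    table = MotuTable(counts, taxonomy, metadata)

    truth = SimTruth(
        site_community=pd.DataFrame(site_p, index=taxa),
        diet_proportions=pd.DataFrame(site_r, index=taxa),
        preference_weights=pd.Series(w, index=taxa),
        taxon_motus=taxon_motus,
        tag_jump_events=events,
        contaminant_motus=["motu_bacteria", "motu_human", "motu_labcontam"],
        focal_counts=focal_counts,
        fungal_counts=fungal_counts,
    )
    return table, truth


def expected_diet_counts(config: SimConfig, truth: SimTruth) -> pd.Series:
    """Expected per-taxon diet reads in one stomach pool (mean over sites)."""
    diet_share = (
        1 - config.focal_read_fraction - config.fungal_read_fraction
        - 2 * config.contaminant_read_fraction
    )
    mean_r = truth.diet_proportions.mean(axis=1)
    return mean_r * diet_share * config.stomach_depth


def recovery_report(
    estimates: pd.DataFrame,
    truth: SimTruth,
    config: SimConfig,
    min_expected_count: float = 50.0,
) -> dict:
    """Compare estimated selectivity with the generator's ground truth.

    ``estimates`` is a diet-summary frame indexed by motu_id with a
    ``jacobs_D`` column (e.g. the output of
    :func:`trophodiet.selectivity.diet_summary` at threshold 0).
    Reports the Spearman rank correlation between the preference weights
    w and estimated mean D (over taxa whose expected diet count reaches
    ``min_expected_count``), the bias of D for neutral (w = 1) taxa, and
    any truth taxa filtered out of the estimates (listed, not dropped).
    """
    from scipy.stats import spearmanr

    exp_counts = expected_diet_counts(config, truth)
    w = truth.preference_weights
    rows = []
    missing = []
    for taxon, mids in truth.taxon_motus.items():
        est = [m for m in mids if m in estimates.index]
        if not est:
            missing.append(taxon)
            continue
        d = float(estimates.loc[est, "jacobs_D"].mean())
        rows.append({
            "taxon": taxon,
            "true_w": float(w[taxon]),
            "estimated_D": d,
            "expected_diet_count": float(exp_counts[taxon]),
        })
    per_taxon = pd.DataFrame(rows).set_index("taxon")
    well = per_taxon[per_taxon["expected_diet_count"] >= min_expected_count]
    well = well.dropna(subset=["estimated_D"])
    if len(well) >= 3 and well["true_w"].nunique() > 1:
        rho = float(spearmanr(well["true_w"], well["estimated_D"]).statistic)
    else:
        rho = float("nan")
    neutral = well[np.isclose(well["true_w"], 1.0)]
    bias = float(neutral["estimated_D"].mean()) if len(neutral) else float("nan")
    return {
        "per_taxon": per_taxon,
        "spearman_rho": rho,
        "neutral_bias": bias,
        "n_taxa_compared": int(len(well)),
        "filtered_out_taxa": missing,
    }
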