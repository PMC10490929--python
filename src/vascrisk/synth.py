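"""Synthetic drug-response database with planted cardiovascular-risk structure.

The real reference database (111 compounds profiled in a hemodynamic
endothelial/smooth-muscle co-culture) is proprietary, so this module generates
a stand-in with the same shape and a *known* ground truth, making every
downstream stage testable without any download.

Generative model
----------------
1.  Genes are partitioned into disjoint pathways (sizes drawn uniformly from
    ``pathway_size_range``; leftover genes are pathway-free background).
2.  Every pathway ``p`` carries a fixed gene **loading vector**
    ``L_p ~ N(0, sigma_L^2)`` shared by all compounds.  ``sigma_L`` is chosen
    in closed form so that a fully activated pathway has mean absolute gene
    log fold change equal to ``effect_size``:
    ``sigma_L^2 = max(effect_size^2 * pi/2 - noise_sd^2, 0)``.
3.  Each compound ``c`` activates pathway ``p`` with a scalar ``a_cp``.
    Risk-flagged compounds share the planted signature on the
    ``n_risk_pathways`` risk pathways: ``a_cp = +1`` with probability
    ``(1 + signature_corr)/2`` and ``-1`` otherwise, so the expected pairwise
    activation agreement rises with ``signature_corr``.  All other
    (compound, pathway) activations are independent ``N(0, 1)`` draws —
    every drug perturbs biology, but only risk drugs do so *coherently* on
    the risk pathways.
4.  Gene-level true log2 fold change: ``a_cp * L_pg + eps``, with independent
    per-compound gene noise ``eps ~ N(0, noise_sd^2)``.  The endothelial (EC)
    compartment carries the same activations attenuated by ``ec_attenuation``
    (the planted risk structure is a smooth-muscle phenomenon); gene noise is
    not attenuated.
5.  Per-replicate counts are negative-binomial around
    ``depth * q_g * 2^logFC`` where ``q_g`` is a log-normal baseline
    abundance profile, with constant dispersion; treatments are contrasted
    against a shared vehicle-control replicate group through the
    differential-expression stage, so the emitted tables carry realistic
    estimation noise.
6.  Binary side-effect labels are a thresholded linear function of the
    smooth-muscle pathway activations, flipped with probability
    ``label_noise``; the first side effect (``arteriosclerosis``) loads on
    the risk pathways, so it is learnable from the transcriptomic features.
7.  A disease baseline (atheroprone vehicle vs atheroprotective control) is
    generated per cell type with its own dense-ish effect vector, stronger in
    EC than SMC.

All randomness flows from ``SyntheticConfig.seed`` through named
``numpy.random.SeedSequence`` child streams, so identical configs give
identical databases and independently reproducible sub-streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    CellType,
    CompoundRecord,
    ContrastResult,
    DataError,
    Database,
    Pathway,
    PathwayCollection,
    treatment_id,
    write_database,
    write_gmt,
)
from .de import CountMatrix, de_contrast

__all__ = [
    "ConfigError",
    "SyntheticConfig",
    "PlantedTruth",
    "generate_database",
    "make_query_compound",
    "generate_fixture",
    "QUERY_PROFILES",
]

QUERY_PROFILES = ("risk_like", "neutral")

_DRUG_CLASSES = (
    "statin", "xanthine oxidase inhibitor", "NSAID", "beta blocker", "ACE inhibitor",
    "PPAR agonist", "kinase inhibitor", "SGLT2 inhibitor", "corticosteroid",
    "antihistamine", "PDE inhibitor", "calcium channel blocker",
)

_SIDE_EFFECT_BASE = ("arteriosclerosis", "nausea", "dizziness", "rash", "headache",
                     "arrhythmia", "insomnia", "fatigue")


class ConfigError(DataError):
    """A configuration is internally inconsistent or infeasible."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for the synthetic database; defaults mirror the reference screen
    (111 compounds, 33 risk-flagged, 4 replicates per treatment, two cell
    types with the risk signature planted in SMC)."""

    n_compounds: int = 111
    n_risk: int = 33
    n_clinical: int | None = None       # default: n_compounds - 4 (>= n_risk)
    n_genes: int = 2000
    n_pathways: int = 100
    pathway_size_range: tuple[int, int] = (8, 24)
    n_risk_pathways: int = 10
    effect_size: float = 1.0            # mean |log2FC| of a fully activated pathway gene
    signature_corr: float = 0.9         # within-risk-class activation agreement
    noise_sd: float = 0.3               # per-compound idiosyncratic gene noise (log2FC)
    n_replicates: int = 4
    count_depth: int = 5_000_000        # library size for the count layer
    dispersion: float = 0.05            # NB dispersion (1/size)
    n_side_effects: int = 5
    label_noise: float = 0.05           # label flip probability
    ec_attenuation: float = 0.25        # EC signal scale relative to SMC
    neutral_effect_scale: float = 0.15  # activation sd of the neutral query profile
    low_dose_attenuation: float = 0.1   # signal scale at the low concentration
    include_low_dose: bool = False      # also emit low-concentration contrasts
    seed: int = 42

    def resolved_n_clinical(self) -> int:
        if self.n_clinical is not None:
            return self.n_clinical
        return max(self.n_compounds - 4, self.n_risk)

    def violations(self) -> list[str]:
        v: list[str] = []
        lo, hi = self.pathway_size_range
        if self.n_compounds < 1:
            v.append("n_compounds must be >= 1")
        if not (0 <= self.n_risk <= self.n_compounds):
            v.append("n_risk must satisfy 0 <= n_risk <= n_compounds")
        if not (self.n_risk <= self.resolved_n_clinical() <= self.n_compounds):
            v.append("n_clinical must satisfy n_risk <= n_clinical <= n_compounds")
        if not (0 <= self.n_risk_pathways <= self.n_pathways):
            v.append("n_risk_pathways must satisfy 0 <= n_risk_pathways <= n_pathways")
        if lo < 3 or hi < lo:
            v.append("pathway_size_range must satisfy 3 <= min <= max")
        if self.n_pathways * lo > self.n_genes:
            v.append(
                f"infeasible: {self.n_pathways} pathways x min size {lo} "
                f"exceeds n_genes={self.n_genes}"
            )
        if self.effect_size < 0:
            v.append("effect_size must be >= 0")
        if not (0 <= self.signature_corr <= 1):
            v.append("signature_corr must be in [0, 1]")
        if self.noise_sd <= 0:
            v.append("noise_sd must be > 0")
        if self.n_replicates < 2:
            v.append("n_replicates must be >= 2")
        if self.count_depth < 1:
            v.append("count_depth must be >= 1")
        if self.dispersion <= 0:
            v.append("dispersion must be > 0")
        if not (0 <= self.label_noise <= 0.5):
            v.append("label_noise must be in [0, 0.5]")
        if self.n_side_effects < 0:
            v.append("n_side_effects must be >= 0")
        return v

    def validate(self) -> "SyntheticConfig":
        problems = self.violations()
        if problems:
            raise ConfigError("; ".join(problems))
        return self

    @property
    def loading_sd(self) -> float:
        """Pathway gene-loading sd such that mean |logFC| of an activated
        pathway gene equals ``effect_size`` (E|N(0,s^2)| = s*sqrt(2/pi))."""
        return math.sqrt(max(self.effect_size**2 * math.pi / 2 - self.noise_sd**2, 0.0))


@dataclass
class PlantedTruth:
    """Ground truth of a generated database — the acceptance oracle."""

    risk_compound_ids: frozenset[str]
    risk_pathway_ids: frozenset[str]
    activations: dict[str, pd.DataFrame]        # cell type -> compounds x pathways
    gene_loadings: pd.Series                    # gene -> loading within its pathway (0 = background)
    gene_pathway: pd.Series                     # gene -> pathway_id ("" = background)
    baseline_abundance: pd.Series               # gene -> relative abundance (sums to 1)
    true_log_fc: dict[str, pd.DataFrame]        # cell type -> genes x compounds true log2FC
    side_effect_coefs: pd.DataFrame             # side effect x pathway coefficients
    side_effect_scores: pd.DataFrame            # compound x side effect latent scores


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    size = 1.0 / dispersion
    mean = np.maximum(mean, 1e-12)
    return rng.negative_binomial(size, size / (size + mean))


def _pathway_sizes(rng: np.random.Generator, cfg: SyntheticConfig) -> np.ndarray:
    lo, hi = cfg.pathway_size_range
    sizes = rng.integers(lo, hi + 1, size=cfg.n_pathways)
    while sizes.sum() > cfg.n_genes:  # feasible because n_pathways * lo <= n_genes
        sizes[int(np.argmax(sizes))] -= 1
    return sizes


def _true_log_fc(
    activations: np.ndarray,          # compounds x pathways
    loading_matrix: np.ndarray,       # pathways x genes (sparse pattern, dense array)
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """compounds x genes matrix of true log2 fold changes."""
    signal = activations @ loading_matrix
    return signal + rng.normal(0.0, noise_sd, size=signal.shape)


def _contrast_from_truth(
    tid: str,
    cell_type: CellType,
    true_lfc: np.ndarray,
    gene_ids: list[str],
    baseline: np.ndarray,
    vehicle_counts: np.ndarray,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> ContrastResult:
    """Simulate treatment replicates and contrast them against the vehicle group."""
    n_rep = cfg.n_replicates
    mean = cfg.count_depth * baseline * np.exp2(true_lfc)
    treated = _nb_draw(rng, np.tile(mean[:, None], (1, n_rep)), cfg.dispersion)
    counts = np.hstack([treated, vehicle_counts])
    cm = CountMatrix(
        gene_ids=gene_ids,
        sample_ids=[f"trt_{i+1}" for i in range(n_rep)] + [f"veh_{i+1}" for i in range(vehicle_counts.shape[1])],
        conditions=["trt"] * n_rep + ["veh"] * vehicle_counts.shape[1],
        counts=counts,
    )
    return de_contrast(cm, "trt", "veh", treatment=tid, cell_type=cell_type)


def generate_database(
    config: SyntheticConfig,
) -> tuple[Database, PathwayCollection, PlantedTruth]:
    """Generate the full synthetic database, pathway collection and ground truth."""
    cfg = config.validate()
    streams = np.random.SeedSequence(cfg.seed).spawn(5)
    rng_struct, rng_act, rng_noise, rng_counts, rng_labels = map(np.random.default_rng, streams)

    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    pathway_ids = [f"PW{i:04d}" for i in range(cfg.n_pathways)]

    # --- pathway structure & loadings -----------------------------------
    sizes = _pathway_sizes(rng_struct, cfg)
    order = rng_struct.permutation(cfg.n_genes)
    gene_pathway = np.full(cfg.n_genes, "", dtype=object)
    loading = np.zeros(cfg.n_genes)
    loading_matrix = np.zeros((cfg.n_pathways, cfg.n_genes))
    pathways = []
    cursor = 0
    for p, size in enumerate(sizes):
        members = order[cursor:cursor + size]
        cursor += size
        gene_pathway[members] = pathway_ids[p]
        load = rng_struct.normal(0.0, cfg.loading_sd, size=size)
        loading[members] = load
        loading_matrix[p, members] = load
        pathways.append(
            Pathway(pathway_ids[p], f"synthetic pathway {p}", frozenset(gene_ids[g] for g in members))
        )
    collection = PathwayCollection(pathways)
    risk_pw_idx = np.sort(rng_struct.choice(cfg.n_pathways, cfg.n_risk_pathways, replace=False))
    risk_pathway_ids = frozenset(pathway_ids[i] for i in risk_pw_idx)

    # --- compounds -------------------------------------------------------
    compound_ids = [f"C{i:03d}" for i in range(cfg.n_compounds)]
    risk_idx = np.sort(rng_struct.choice(cfg.n_compounds, cfg.n_risk, replace=False))
    risk_set = set(risk_idx.tolist())
    non_risk = [i for i in range(cfg.n_compounds) if i not in risk_set]
    n_nonclinical = cfg.n_compounds - cfg.resolved_n_clinical()
    nonclinical = set(rng_struct.choice(non_risk, n_nonclinical, replace=False).tolist()) if n_nonclinical else set()
    base_conc = 10.0 ** rng_struct.uniform(-8, -5, size=cfg.n_compounds)
    base_conc = np.array([float(f"{c:.6g}") for c in base_conc])  # match the treatment-id format
    classes = rng_struct.choice(len(_DRUG_CLASSES), size=cfg.n_compounds)

    # --- activations (SMC carries the signature, EC attenuated) ---------
    act_smc = rng_act.normal(0.0, 1.0, size=(cfg.n_compounds, cfg.n_pathways))
    if cfg.n_risk and cfg.n_risk_pathways:
        agree = rng_act.random(size=(cfg.n_risk, cfg.n_risk_pathways)) < (1 + cfg.signature_corr) / 2
        act_smc[np.ix_(risk_idx, risk_pw_idx)] = np.where(agree, 1.0, -1.0)
    act = {"SMC": act_smc, "EC": cfg.ec_attenuation * act_smc}

    true_lfc = {
        ct: _true_log_fc(act[ct], loading_matrix, cfg.noise_sd, rng_noise) for ct in ("EC", "SMC")
    }

    # --- side-effect labels ----------------------------------------------
    se_names = [
        _SIDE_EFFECT_BASE[k] if k < len(_SIDE_EFFECT_BASE) else f"side_effect_{k:02d}"
        for k in range(cfg.n_side_effects)
    ]
    coefs = np.zeros((cfg.n_side_effects, cfg.n_pathways))
    for k in range(cfg.n_side_effects):
        if k == 0 and cfg.n_risk_pathways:
            coefs[k, risk_pw_idx] = 1.0  # cardiovascular-flavoured side effect
        else:
            chosen = rng_labels.choice(cfg.n_pathways, size=min(5, cfg.n_pathways), replace=False)
            coefs[k, chosen] = rng_labels.choice([-1.0, 1.0], size=chosen.size)
    scores = act_smc @ coefs.T  # compounds x side effects
    labels = scores > np.median(scores, axis=0, keepdims=True)
    flips = rng_labels.random(size=labels.shape) < cfg.label_noise
    labels = labels ^ flips

    # --- baseline abundance, disease effect, vehicle counts -------------
    weights = rng_struct.lognormal(0.0, 1.2, size=cfg.n_genes)
    baseline = weights / weights.sum()
    disease = {}
    for ct, frac in (("EC", 0.15), ("SMC", 0.05)):
        mask = rng_struct.random(cfg.n_genes) < frac
        eff = np.zeros(cfg.n_genes)
        eff[mask] = rng_struct.normal(0.0, max(cfg.effect_size, 0.5), size=int(mask.sum()))
        disease[ct] = eff
    vehicle_counts = {
        ct: _nb_draw(
            rng_counts,
            np.tile(cfg.count_depth * baseline[:, None], (1, cfg.n_replicates)),
            cfg.dispersion,
        )
        for ct in ("EC", "SMC")
    }

    # --- compound records and contrasts ----------------------------------
    compounds: list[CompoundRecord] = []
    contrasts: dict[tuple[str, str], ContrastResult] = {}
    for i, cid in enumerate(compound_ids):
        side_effects = {
            se_names[k]: ("positive" if labels[i, k] else "negative") for k in range(cfg.n_side_effects)
        }
        compounds.append(
            CompoundRecord(
                compound_id=cid,
                name=f"compound-{i:03d}",
                drug_class=_DRUG_CLASSES[classes[i]],
                clinical_stage=i not in nonclinical,
                cv_risk=i in risk_set,
                side_effects=side_effects,
                concentrations=(base_conc[i], 10 * base_conc[i]),
            )
        )
        for ct in ("EC", "SMC"):
            tid = treatment_id(cid, 10 * base_conc[i])
            contrasts[(tid, ct)] = _contrast_from_truth(
                tid, CellType(ct), true_lfc[ct][i], gene_ids, baseline,
                vehicle_counts[ct], cfg, rng_counts,
            )
            if cfg.include_low_dose:
                tid_lo = treatment_id(cid, base_conc[i])
                contrasts[(tid_lo, ct)] = _contrast_from_truth(
                    tid_lo, CellType(ct), cfg.low_dose_attenuation * true_lfc[ct][i],
                    gene_ids, baseline, vehicle_counts[ct], cfg, rng_counts,
                )

    control_contrasts = {}
    for ct in ("EC", "SMC"):
        protective_mean = cfg.count_depth * baseline * np.exp2(-disease[ct])
        protective = _nb_draw(
            rng_counts, np.tile(protective_mean[:, None], (1, cfg.n_replicates)), cfg.dispersion
        )
        counts = np.hstack([vehicle_counts[ct], protective])
        cm = CountMatrix(
            gene_ids=gene_ids,
            sample_ids=[f"prone_{i+1}" for i in range(cfg.n_replicates)]
            + [f"protect_{i+1}" for i in range(cfg.n_replicates)],
            conditions=["prone"] * cfg.n_replicates + ["protect"] * cfg.n_replicates,
            counts=counts,
        )
        control_contrasts[ct] = de_contrast(cm, "prone", "protect", treatment="control", cell_type=ct)

    database = Database(compounds=compounds, contrasts=contrasts, control_contrasts=control_contrasts)
    truth = PlantedTruth(
        risk_compound_ids=frozenset(compound_ids[i] for i in risk_idx),
        risk_pathway_ids=risk_pathway_ids,
        activations={ct: pd.DataFrame(act[ct], index=compound_ids, columns=pathway_ids) for ct in act},
        gene_loadings=pd.Series(loading, index=gene_ids, name="loading"),
        gene_pathway=pd.Series(gene_pathway, index=gene_ids, name="pathway_id"),
        baseline_abundance=pd.Series(baseline, index=gene_ids, name="abundance"),
        true_log_fc={ct: pd.DataFrame(true_lfc[ct].T, index=gene_ids, columns=compound_ids) for ct in true_lfc},
        side_effect_coefs=pd.DataFrame(coefs, index=se_names, columns=pathway_ids),
        side_effect_scores=pd.DataFrame(scores, index=compound_ids, columns=se_names),
    )
    return database, collection, truth


def make_query_compound(
    config: SyntheticConfig,
    truth: PlantedTruth,
    profile: str,
    seed: int | None = None,
    cell_types: tuple[str, ...] = ("EC", "SMC"),
) -> dict[str, ContrastResult]:
    """Simulate a fresh query compound (not in the database) and return its
    DE contrasts keyed by cell type.

    ``risk_like`` activates every planted risk pathway exactly as the shared
    signature does (a febuxostat-like compound); ``neutral`` draws small
    independent activations everywhere (an oxypurinol-like compound).  The
    query is profiled against its own fresh vehicle-control replicates.
    """
    cfg = config.validate()
    if profile not in QUERY_PROFILES:
        raise ConfigError(f"unknown query profile {profile!r}; expected one of {QUERY_PROFILES}")
    entropy = [cfg.seed, 7_001 if profile == "risk_like" else 7_002, 0 if seed is None else int(seed)]
    rng = np.random.default_rng(np.random.SeedSequence(entropy))

    pathway_ids = list(truth.side_effect_coefs.columns)
    gene_ids = list(truth.gene_loadings.index)
    n_pathways = len(pathway_ids)
    loading_matrix = np.zeros((n_pathways, len(gene_ids)))
    pw_index = {pw: i for i, pw in enumerate(pathway_ids)}
    member = truth.gene_pathway.to_numpy()
    gene_pos = np.flatnonzero(member != "")
    for g in gene_pos:
        loading_matrix[pw_index[member[g]], g] = truth.gene_loadings.iloc[g]

    if profile == "risk_like":
        act = rng.normal(0.0, 1.0, size=n_pathways)
        for pw in truth.risk_pathway_ids:
            act[pw_index[pw]] = 1.0
    else:
        act = rng.normal(0.0, cfg.neutral_effect_scale, size=n_pathways)

    baseline = truth.baseline_abundance.to_numpy()
    qname = f"QRY-{profile}" if seed is None else f"QRY-{profile}-{seed}"
    out: dict[str, ContrastResult] = {}
    for ct in cell_types:
        scale = cfg.ec_attenuation if ct == "EC" else 1.0
        true_lfc = (scale * act) @ loading_matrix + rng.normal(0.0, cfg.noise_sd, size=len(gene_ids))
        vehicle = _nb_draw(
            rng, np.tile(cfg.count_depth * baseline[:, None], (1, cfg.n_replicates)), cfg.dispersion
        )
        tid = treatment_id(qname, 1e-4)
        out[ct] = _contrast_from_truth(
            tid, CellType(ct), true_lfc, gene_ids, baseline, vehicle, cfg, rng
        )
    return out


def generate_fixture(config: SyntheticConfig, directory: str | Path) -> Path:
    """Generate a database and write it (metadata + contrasts + GMT) to disk."""
    directory = Path(directory)
    database, pathways, truth = generate_database(config)
    write_database(database, directory)
    write_gmt(pathways, directory / "pathways.gmt")
    summary = pd.DataFrame(
        {
            "risk_compound": sorted(truth.risk_compound_ids),
        }
    )
    summary.to_csv(directory / "planted_risk_compounds.tsv", sep="\t", index=False)
    pd.DataFrame({"risk_pathway": sorted(truth.risk_pathway_ids)}).to_csv(
        directory / "planted_risk_pathways.tsv", sep="\t", index=False
    )
    return directory
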