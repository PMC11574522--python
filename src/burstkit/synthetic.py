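"""Synthetic two-condition single-cell study with full ground truth.

Generates "cluster 1"-style count matrices for a treated and an untreated
condition in which every gene's counts follow multi-allele telegraph-model
statistics with known rates.  A signature subset has its production rate
(hence burst size, with k_off fixed) amplified in the treated condition, and
— in the treated condition only — shares a per-cell log-normal extrinsic
factor multiplying the production rate, which couples the signature genes'
expression and creates the co-expression block the downstream analysis is
designed to detect.  Mitochondrial-flagged decoy genes make the per-cell
mitochondrial fraction computable, and a configurable fraction of planted
"aberrant" cells each violates exactly one quality-control threshold.

Counts are drawn with the exact stationary Beta-Poisson sampler per allele;
trajectory (Gillespie) simulation is kept in :mod:`burstkit.simulate` for
cross-validation.  A fixed seed yields a bit-identical study.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmwrite

from .core import LN2, decay_from_halflife, telegraph_moments
from .preprocess import MAX_COUNTS, compute_qc_metrics
from .simulate import betapoisson_sample

__all__ = [
    "DEFAULT_SIGNATURE",
    "StudyConfig",
    "GroundTruth",
    "Study",
    "generate_study",
    "write_study",
    "GROUND_TRUTH_SCHEMA",
    "validate_ground_truth",
]

#: interferon-signature gene ids used by default for the amplified subset
DEFAULT_SIGNATURE = (
    "DDX58", "DDX60", "EPSTI1", "HERC5", "HERC6", "IFI27",
    "IFI35", "IFIH1", "IRF7", "OASL", "PLSCR1", "STAT1",
)

CONDITIONS = ("treated", "control")


@dataclass
class StudyConfig:
    """Ground-truth design of the synthetic study.

    Rates are per minute.  Background kinetics are drawn log-uniformly:
    activation rate in ``k_on_range``, inactivation rate in ``k_off_range``
    (ON periods of a few minutes to ~20 min), burst size in ``burst_range``;
    half-lives are log-normal with the given median.  Signature genes share
    background kinetics in the control condition; in the treated condition
    their production rate is multiplied by ``burst_size_multiplier`` (k_off
    fixed, so burst size scales by the same factor) and further modulated per
    cell by a mean-one log-normal extrinsic factor with log-scale sigma
    ``coupling_strength``.  The factor models cell-level variability in the
    signature genes' production rate and is present in both conditions with
    the same magnitude; in the treated condition one factor per cell is
    *shared* by all signature genes (coordinated regulation, creating the
    co-expression block), whereas in the control condition each signature
    gene draws an independent factor (uncoordinated noise, no correlation).
    Keeping the marginal overdispersion identical in the two conditions means
    any bias it induces in the per-gene kinetic fits cancels in the
    treated-over-control fold changes.
    """

    n_background: int = 300
    n_signature: int = 12
    signature_ids: tuple = DEFAULT_SIGNATURE
    n_cells: int = 3000
    burst_size_multiplier: float = 3.0
    coupling_strength: float = 0.5
    dropout_rate: float = 0.0
    halflife_median_min: float = 300.0
    halflife_sigma: float = 0.5
    ploidy: int = 2
    aberrant_fraction: float = 0.05
    n_mito_genes: int = 10
    mito_fraction_target: float = 0.02
    k_on_range: tuple = (0.003, 0.3)
    k_off_range: tuple = (0.05, 0.5)
    burst_range: tuple = (1.0, 20.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_background < 0 or self.n_signature < 0 or self.n_mito_genes < 1:
            raise ValueError("gene counts must be nonnegative (>=1 mito decoy)")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0 <= self.aberrant_fraction < 0.5:
            raise ValueError("aberrant_fraction must be in [0, 0.5)")
        if self.burst_size_multiplier <= 0 or self.coupling_strength < 0:
            raise ValueError("burst_size_multiplier must be > 0 and coupling_strength >= 0")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        for name in ("k_on_range", "k_off_range", "burst_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"infeasible {name}: {(lo, hi)}")
        if self.n_signature > len(self.signature_ids):
            extra = tuple(
                f"SIG{i:02d}" for i in range(len(self.signature_ids) + 1, self.n_signature + 1)
            )
            self.signature_ids = tuple(self.signature_ids) + extra
        self.signature_ids = tuple(self.signature_ids)[: self.n_signature]


GROUND_TRUTH_SCHEMA = {
    "type": "object",
    "required": ["config", "genes", "extrinsic_factor", "aberrant_cells"],
    "properties": {
        "config": {"type": "object"},
        "genes": {
            "type": "object",
            "values": {
                "required": ["signature", "is_mito", "half_life_min", "rates"],
                "rates_conditions": list(CONDITIONS),
                "rate_keys": ["k_on", "k_off", "k_eject", "k_decay"],
            },
        },
        "extrinsic_factor": {"type": "object", "conditions": list(CONDITIONS)},
        "aberrant_cells": {"type": "object", "conditions": list(CONDITIONS)},
    },
}


def validate_ground_truth(obj: dict) -> None:
    """Check a ground-truth JSON object against :data:`GROUND_TRUTH_SCHEMA`."""
    for key in GROUND_TRUTH_SCHEMA["required"]:
        if key not in obj:
            raise ValueError(f"ground truth missing key {key!r}")
    for gene, entry in obj["genes"].items():
        for key in ("signature", "is_mito", "half_life_min", "rates"):
            if key not in entry:
                raise ValueError(f"gene {gene} missing {key!r}")
        for cond in CONDITIONS:
            rates = entry["rates"].get(cond)
            if rates is None:
                raise ValueError(f"gene {gene} missing rates for condition {cond!r}")
            for rk in ("k_on", "k_off", "k_eject", "k_decay"):
                if not (isinstance(rates.get(rk), (int, float)) and rates[rk] > 0):
                    raise ValueError(f"gene {gene} condition {cond}: bad rate {rk!r}")
    for cond in CONDITIONS:
        if cond not in obj["extrinsic_factor"] or cond not in obj["aberrant_cells"]:
            raise ValueError(f"missing per-condition entry for {cond!r}")
        ef = obj["extrinsic_factor"][cond]
        for key in ("shared", "sigma"):
            if key not in ef:
                raise ValueError(f"extrinsic_factor[{cond!r}] missing {key!r}")
        if ef["shared"] and not isinstance(ef.get("factors"), list):
            raise ValueError(f"extrinsic_factor[{cond!r}] must list the shared per-cell factors")


@dataclass
class GroundTruth:
    """Everything needed to recompute every expected pipeline result."""

    config: dict
    genes: dict            # gene -> {signature, is_mito, half_life_min, rates{cond -> 4 rates}}
    extrinsic_factor: dict  # condition -> {shared, sigma, factors (per-cell list when shared)}
    aberrant_cells: dict    # condition -> {barcode: "high_count" | "high_mito"}

    def to_json(self, path) -> None:
        obj = asdict(self)
        validate_ground_truth(obj)
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            obj = json.load(fh)
        validate_ground_truth(obj)
        return cls(**obj)

    def signature_genes(self) -> list[str]:
        return [g for g, e in self.genes.items() if e["signature"]]

    def rates_frame(self) -> pd.DataFrame:
        rows = []
        for gene, entry in self.genes.items():
            for cond, r in entry["rates"].items():
                rows.append(
                    {"gene_id": gene, "condition": cond, "signature": entry["signature"],
                     "is_mito": entry["is_mito"], "half_life_min": entry["half_life_min"], **r}
                )
        return pd.DataFrame(rows)


@dataclass
class Study:
    conditions: dict      # condition -> AnnData (cells x genes)
    truth: GroundTruth
    half_lives: pd.Series
    config: StudyConfig

    def write(self, out_dir) -> Path:
        return write_study(self, out_dir)


def _loguniform(rng, lo, hi, size):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def generate_study(config: StudyConfig | None = None) -> Study:
    """Draw the full two-condition study; deterministic given ``config.seed``."""
    cfg = config or StudyConfig()
    rng_rates = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    rng_factor = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    rng_counts = {
        cond: np.random.default_rng(np.random.SeedSequence([cfg.seed, 2 + i]))
        for i, cond in enumerate(CONDITIONS)
    }
    rng_aberrant = np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))

    sig = list(cfg.signature_ids)
    background = [f"BG{i + 1:04d}" for i in range(cfg.n_background)]
    mito = [f"MT-DECOY{i + 1:02d}" for i in range(cfg.n_mito_genes)]
    genes = sig + background + mito
    n_main = len(sig) + len(background)

    k_on = _loguniform(rng_rates, *cfg.k_on_range, size=n_main)
    k_off = _loguniform(rng_rates, *cfg.k_off_range, size=n_main)
    burst = _loguniform(rng_rates, *cfg.burst_range, size=n_main)
    t_half = rng_rates.lognormal(np.log(cfg.halflife_median_min), cfg.halflife_sigma, size=len(genes))
    k_decay = LN2 / t_half
    k_eject = burst * k_off

    # mitochondrial decoys: near-constitutive, sized to a small share of the
    # expected per-cell total so percent_mito of normal cells sits ~2 %
    a_main = k_on / k_decay[:n_main]
    b_main = k_off / k_decay[:n_main]
    lam_main = k_eject / k_decay[:n_main]
    mean_main = cfg.ploidy * lam_main * a_main / (a_main + b_main)
    mito_budget = max(cfg.mito_fraction_target * float(mean_main.sum()), 1.0)
    mito_mean_each = mito_budget / cfg.n_mito_genes
    k_on_mito = np.full(cfg.n_mito_genes, 0.1)
    k_off_mito = np.full(cfg.n_mito_genes, 0.1)
    k_decay_mito = k_decay[n_main:]
    # mean = ploidy * (k_eject/k_decay) * a/(a+b) with a = b  ->  solve for k_eject
    k_eject_mito = mito_mean_each * k_decay_mito * 2.0 / cfg.ploidy

    k_on = np.concatenate([k_on, k_on_mito])
    k_off = np.concatenate([k_off, k_off_mito])
    k_eject = np.concatenate([k_eject, k_eject_mito])
    is_sig = np.array([g in set(sig) for g in genes])
    is_mito = np.array([g.startswith("MT-DECOY") for g in genes])

    def _lognormal_factor(size):
        return np.exp(
            cfg.coupling_strength * rng_factor.standard_normal(size)
            - 0.5 * cfg.coupling_strength**2
        )

    # treated: one factor per cell shared by every signature gene;
    # control: an independent factor per signature gene (drawn in gene order)
    shared_factor = _lognormal_factor(cfg.n_cells)
    control_factors = {g: _lognormal_factor(cfg.n_cells) for g in sig}

    truth_genes = {}
    matrices = {}
    aberrant = {}
    for cond in CONDITIONS:
        rng = rng_counts[cond]
        X = np.zeros((len(genes), cfg.n_cells), dtype=np.int64)
        for j, gene in enumerate(genes):
            ke = k_eject[j]
            if is_sig[j] and cond == "treated":
                ke = ke * cfg.burst_size_multiplier
            a = k_on[j] / k_decay[j]
            b = k_off[j] / k_decay[j]
            lam = ke / k_decay[j]
            if is_sig[j]:
                lam_cells = lam * (shared_factor if cond == "treated" else control_factors[gene])
            else:
                lam_cells = lam
            counts = betapoisson_sample(a, b, lam_cells, cfg.ploidy, cfg.n_cells, rng)
            if cfg.dropout_rate > 0:
                counts = rng.binomial(counts, 1.0 - cfg.dropout_rate)
            X[j] = counts
            truth_genes.setdefault(
                gene,
                {
                    "signature": bool(is_sig[j]),
                    "is_mito": bool(is_mito[j]),
                    "half_life_min": float(t_half[j]),
                    "rates": {},
                },
            )["rates"][cond] = {
                "k_on": float(k_on[j]),
                "k_off": float(k_off[j]),
                "k_eject": float(ke),
                "k_decay": float(k_decay[j]),
            }
        barcodes = [f"{cond}_{i + 1:05d}" for i in range(cfg.n_cells)]
        aberrant[cond] = _plant_aberrant_cells(X, barcodes, is_mito, cfg, rng_aberrant)
        matrices[cond] = (X, barcodes)

    conditions = {}
    for cond, (X, barcodes) in matrices.items():
        adata = ad.AnnData(X=sparse.csr_matrix(X.T))
        adata.obs_names = barcodes
        adata.var_names = genes
        adata.obs["condition"] = cond
        adata.obs["cluster"] = "1"
        adata.obs["aberrant"] = [aberrant[cond].get(bc, "") for bc in barcodes]
        adata.var["is_mito"] = is_mito
        adata.var["half_life"] = t_half
        adata.var["signature"] = is_sig
        compute_qc_metrics(adata)
        conditions[cond] = adata

    truth = GroundTruth(
        config={k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        genes=truth_genes,
        extrinsic_factor={
            "treated": {"shared": True, "sigma": cfg.coupling_strength,
                        "factors": [float(x) for x in shared_factor]},
            "control": {"shared": False, "sigma": cfg.coupling_strength, "factors": None},
        },
        aberrant_cells=aberrant,
    )
    half_lives = pd.Series(t_half, index=genes, name="half_life_min")
    return Study(conditions=conditions, truth=truth, half_lives=half_lives, config=cfg)


def _plant_aberrant_cells(X, barcodes, is_mito, cfg: StudyConfig, rng) -> dict:
    """Modify planted cells in place so each violates exactly one QC threshold."""
    n_ab = int(round(cfg.aberrant_fraction * cfg.n_cells))
    if n_ab == 0:
        return {}
    chosen = rng.choice(cfg.n_cells, size=n_ab, replace=False)
    labels = {}
    n_high_count = (n_ab + 1) // 2
    for rank, i in enumerate(chosen):
        total = int(X[:, i].sum())
        if rank < n_high_count:
            mult = int(np.ceil(1.2 * MAX_COUNTS / max(total, 1)))
            X[:, i] *= mult
            labels[barcodes[i]] = "high_count"
        else:
            # raise the mitochondrial share to ~20 % (threshold is 8 %)
            nonmito_total = int(X[~is_mito, i].sum())
            add = max(int(np.ceil(nonmito_total / 3.0)) - int(X[is_mito, i].sum()), 1)
            extra = rng.multinomial(add, np.full(is_mito.sum(), 1.0 / is_mito.sum()))
            X[np.where(is_mito)[0], i] += extra
            labels[barcodes[i]] = "high_mito"
    return labels


def write_study(study: Study, out_dir) -> Path:
    """Write the study as Matrix Market + TSV companions + ground-truth JSON.

    Layout: ``<out>/<condition>/{matrix.mtx,features.tsv,barcodes.tsv}``,
    ``cell_metadata.tsv``, ``half_lives.tsv``, ``ground_truth.json``.  Counts
    round-trip losslessly through :func:`burstkit.preprocess.read_study`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta_frames = []
    for cond, adata in study.conditions.items():
        cdir = out / cond
        cdir.mkdir(exist_ok=True)
        mat = sparse.csr_matrix(adata.X).T.tocoo()   # genes x cells
        mmwrite(str(cdir / "matrix.mtx"), mat, field="integer")
        (cdir / "features.tsv").write_text("\n".join(adata.var_names) + "\n")
        (cdir / "barcodes.tsv").write_text("\n".join(adata.obs_names) + "\n")
        meta = adata.obs.copy()
        meta.index.name = "barcode"
        meta_frames.append(meta.reset_index())
    pd.concat(meta_frames, ignore_index=True).to_csv(
        out / "cell_metadata.tsv", sep="\t", index=False
    )
    hl = study.half_lives.rename_axis("gene_id").reset_index()
    hl.to_csv(out / "half_lives.tsv", sep="\t", index=False)
    study.truth.to_json(out / "ground_truth.json")
    return out
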