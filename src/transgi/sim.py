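"""Synthetic cohort generator with known ground truth.

Produces aligned genotype dosages, gene expression, DNA methylation, and
covariates for a configurable number of samples, together with truth tables
(true regulators, true effect sizes, scenario labels) that downstream stages
never see.

Genotypes are drawn from a latent multivariate Gaussian per LD block and
thresholded at Hardy-Weinberg quantiles into {0, 1, 2}. The latent
correlation of each block is calibrated numerically so the *dosage*
correlation matches the requested block target.

Expression is ``sum(beta_s * std_dosage_s) + covariate effects + noise`` with
noise scaled so the total variance is 1. Methylation is
``sum(phi_g * std_expression_g) + covariate effects + scenario terms + noise``
with unit-variance noise (total variance is free; the analysis pipeline
rank-INT-transforms methylation regardless).

Three confounding scenarios can be injected:

``shared_eqtl``
    two genes driven by a shared cis SNP (configured through the gene map),
    so their genetic instruments are correlated; only one truly affects the
    target probe.
``direct_snp_to_cpg``
    a SNP affects a probe directly, bypassing expression.
``cell_composition_confounder``
    a SNP drives an unmeasured confounder that feeds both a gene's expression
    and a probe's methylation (the synthetic analogue of residual cell
    composition effects; removable by conditioning on the SNP).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats
from scipy.special import expit

__all__ = [
    "SnpSpec",
    "GeneSpec",
    "TransEffect",
    "ScenarioSpec",
    "SimConfig",
    "CohortDataset",
    "simulate",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_expression",
    "simulate_methylation",
    "shared_eqtl_config",
    "cell_confounder_config",
    "write_dataset",
    "write_vcf",
]

CIS_WINDOW = 100_000
TRANS_DISTANCE = 10_000_000

SCENARIO_KINDS = ("shared_eqtl", "direct_snp_to_cpg", "cell_composition_confounder")


@dataclass(frozen=True)
class SnpSpec:
    snp: str
    chrom: str
    pos: int
    maf: float
    ld_block: str | None = None


@dataclass(frozen=True)
class GeneSpec:
    gene: str
    chrom: str
    tss: int
    tes: int
    cis_snps: tuple[str, ...] = ()
    cis_effects: tuple[float, ...] = ()
    h2_cis: float | None = None


@dataclass(frozen=True)
class TransEffect:
    gene: str
    probe: str
    phi: float


@dataclass(frozen=True)
class ScenarioSpec:
    """One injected confounding scenario; required fields depend on ``kind``."""

    kind: str
    snp: str | None = None
    gene: str | None = None
    gene_b: str | None = None
    probe: str | None = None
    expr_effect: float = 0.0
    meth_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "shared_eqtl" and (self.gene is None or self.gene_b is None):
            raise ValueError("shared_eqtl requires gene and gene_b")
        if self.kind == "direct_snp_to_cpg" and (self.snp is None or self.probe is None):
            raise ValueError("direct_snp_to_cpg requires snp and probe")
        if self.kind == "cell_composition_confounder" and (
            self.snp is None or self.gene is None or self.probe is None
        ):
            raise ValueError("cell_composition_confounder requires snp, gene and probe")


@dataclass
class SimConfig:
    n_samples: int
    snps: list[SnpSpec]
    genes: list[GeneSpec]
    probes: list[tuple[str, str, int]]  # (probe id, chrom, pos)
    trans_effects: list[TransEffect] = field(default_factory=list)
    n_cohorts: int = 1
    ld_block_r: dict[str, float] = field(default_factory=dict)
    covariate_effects: dict[str, tuple[float, float]] = field(default_factory=dict)
    scenarios: list[ScenarioSpec] = field(default_factory=list)
    n_cell_types: int = 3
    meth_noise_sd: float = 1.0
    beta_scale: bool = False
    make_counts: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        snp_ids = {s.snp for s in self.snps}
        snp_pos = {s.snp: (s.chrom, s.pos) for s in self.snps}
        probe_ids = {p[0] for p in self.probes}
        probe_pos = {p[0]: (p[1], p[2]) for p in self.probes}
        gene_ids = {g.gene for g in self.genes}
        for s in self.snps:
            if not (0.01 <= s.maf <= 0.5):
                raise ValueError(f"MAF out of [0.01, 0.5] for {s.snp}")
        for b, r in self.ld_block_r.items():
            if not (0.0 <= r < 1.0):
                raise ValueError(f"LD block {b!r} correlation must be in [0, 1)")
        for g in self.genes:
            if g.h2_cis is not None and not (0.0 <= g.h2_cis < 1.0):
                raise ValueError(f"h2_cis out of [0, 1) for gene {g.gene}")
            if len(g.cis_snps) != len(g.cis_effects):
                raise ValueError(f"cis_snps/cis_effects length mismatch for {g.gene}")
            lo = min(g.tss, g.tes) - CIS_WINDOW
            hi = max(g.tss, g.tes) + CIS_WINDOW
            for sid in g.cis_snps:
                if sid not in snp_ids:
                    raise ValueError(f"unknown cis SNP {sid} for gene {g.gene}")
                chrom, pos = snp_pos[sid]
                if chrom != g.chrom or not (lo <= pos <= hi):
                    raise ValueError(
                        f"SNP {sid} outside cis window of gene {g.gene}"
                    )
        gene_by_id = {g.gene: g for g in self.genes}
        for te in self.trans_effects:
            if te.gene not in gene_ids:
                raise ValueError(f"unknown regulator gene {te.gene}")
            if te.probe not in probe_ids:
                raise ValueError(f"unknown target probe {te.probe}")
            g = gene_by_id[te.gene]
            chrom, pos = probe_pos[te.probe]
            if chrom == g.chrom:
                d = min(abs(pos - g.tss), abs(pos - g.tes))
                inside = min(g.tss, g.tes) <= pos <= max(g.tss, g.tes)
                if inside or d <= TRANS_DISTANCE:
                    raise ValueError(
                        f"trans effect {te.gene}->{te.probe} violates the "
                        f"trans criterion (> {TRANS_DISTANCE} bp or another chromosome)"
                    )
        for sc in self.scenarios:
            for sid in (sc.snp,):
                if sid is not None and sid not in snp_ids:
                    raise ValueError(f"scenario references unknown SNP {sid}")
            for gid in (sc.gene, sc.gene_b):
                if gid is not None and gid not in gene_ids:
                    raise ValueError(f"scenario references unknown gene {gid}")
            if sc.probe is not None and sc.probe not in probe_ids:
                raise ValueError(f"scenario references unknown probe {sc.probe}")
            if sc.kind == "shared_eqtl":
                a = set(gene_by_id[sc.gene].cis_snps)
                b = set(gene_by_id[sc.gene_b].cis_snps)
                if not a & b:
                    raise ValueError(
                        "shared_eqtl scenario requires the two genes to share a cis SNP"
                    )

    # -- YAML round trip ----------------------------------------------------
    def to_yaml(self, path: str) -> None:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.floating):
                return float(obj)
            if isinstance(obj, np.integer):
                return int(obj)
            return obj

        data = plain(dataclasses.asdict(self))
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["snps"] = [SnpSpec(**s) for s in data.get("snps", [])]
        data["genes"] = [
            GeneSpec(
                **{
                    **g,
                    "cis_snps": tuple(g.get("cis_snps", ())),
                    "cis_effects": tuple(g.get("cis_effects", ())),
                }
            )
            for g in data.get("genes", [])
        ]
        data["probes"] = [tuple(p) for p in data.get("probes", [])]
        data["trans_effects"] = [TransEffect(**t) for t in data.get("trans_effects", [])]
        data["scenarios"] = [ScenarioSpec(**s) for s in data.get("scenarios", [])]
        data["covariate_effects"] = {
            k: tuple(v) for k, v in (data.get("covariate_effects") or {}).items()
        }
        return cls(**data)


@dataclass
class CohortDataset:
    """Aligned sample-indexed matrices plus annotations and truth tables."""

    dosages: pd.DataFrame
    expression: pd.DataFrame
    methylation: pd.DataFrame
    covariates: pd.DataFrame
    snps: pd.DataFrame
    genes: pd.DataFrame
    probes: pd.DataFrame
    expression_counts: pd.DataFrame | None = None
    truth: dict[str, pd.DataFrame] = field(default_factory=dict)
    methylation_scale: str = "latent"
    expression_scale: str = "latent"

    def check_alignment(self) -> None:
        idx = self.dosages.index
        for name in ("expression", "methylation", "covariates"):
            m = getattr(self, name)
            if not m.index.equals(idx):
                raise ValueError(f"{name} sample index differs from dosages")
            if m.isna().any().any():
                raise ValueError(f"{name} contains missing values")


# ---------------------------------------------------------------------------
# genotype generation
# ---------------------------------------------------------------------------

def _hw_thresholds(maf: float) -> tuple[float, float]:
    q = 1.0 - maf
    return stats.norm.ppf(q * q), stats.norm.ppf(1.0 - maf * maf)


@lru_cache(maxsize=4096)
def _dosage_corr_given_latent(latent_r: float, maf: float) -> float:
    """Dosage correlation implied by latent correlation under HWE thresholds."""
    t1, t2 = _hw_thresholds(maf)
    cov = [[1.0, latent_r], [latent_r, 1.0]]
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov, allow_singular=True)

    def joint_sf(a: float, b: float) -> float:
        return 1.0 - stats.norm.cdf(a) - stats.norm.cdf(b) + mvn.cdf([a, b])

    exy = sum(joint_sf(a, b) for a in (t1, t2) for b in (t1, t2))
    ex = 2.0 * maf
    ex2 = (1.0 - (1.0 - maf) ** 2) + 3.0 * maf * maf
    var = ex2 - ex * ex
    return (exy - ex * ex) / var


@lru_cache(maxsize=4096)
def latent_corr_for_dosage_corr(target_r: float, maf: float) -> float:
    """Invert the threshold map: latent correlation giving dosage corr ``target_r``."""
    if target_r == 0.0:
        return 0.0
    if not (0.0 <= target_r < 1.0):
        raise ValueError("correlation target must be in [0, 1)")
    maf = round(float(maf), 6)

    def f(r: float) -> float:
        return _dosage_corr_given_latent(r, maf) - target_r

    return float(optimize.brentq(f, 0.0, 0.999999, xtol=1e-6))


def simulate_genotypes(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate dosages in {0, 1, 2} and return (dosages, SNP annotation)."""
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_samples
    samples = pd.Index([f"S{i:05d}" for i in range(n)], name="sample")
    cols: dict[str, np.ndarray] = {}
    blocks: dict[str, list[SnpSpec]] = {}
    singles: list[SnpSpec] = []
    for s in config.snps:
        if s.ld_block is None:
            singles.append(s)
        else:
            blocks.setdefault(s.ld_block, []).append(s)
    for s in singles:
        t1, t2 = _hw_thresholds(s.maf)
        z = rng.standard_normal(n)
        cols[s.snp] = (z > t1).astype(float) + (z > t2)
    for block_id in sorted(blocks):
        members = blocks[block_id]
        target = config.ld_block_r.get(block_id, 0.0)
        mean_maf = float(np.mean([m.maf for m in members]))
        lat = latent_corr_for_dosage_corr(target, mean_maf) if len(members) > 1 else 0.0
        shared = rng.standard_normal(n)
        for s in members:
            z = np.sqrt(lat) * shared + np.sqrt(1.0 - lat) * rng.standard_normal(n)
            t1, t2 = _hw_thresholds(s.maf)
            cols[s.snp] = (z > t1).astype(float) + (z > t2)
    order = [s.snp for s in config.snps]
    dosages = pd.DataFrame({sid: cols[sid] for sid in order}, index=samples)
    snp_ann = pd.DataFrame(
        {
            "chrom": [s.chrom for s in config.snps],
            "pos": [s.pos for s in config.snps],
            "maf": [s.maf for s in config.snps],
            "ld_block": [s.ld_block for s in config.snps],
        },
        index=pd.Index(order, name="snp"),
    )
    return dosages, snp_ann


# ---------------------------------------------------------------------------
# covariates / expression / methylation
# ---------------------------------------------------------------------------

def simulate_covariates(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_samples
    samples = pd.Index([f"S{i:05d}" for i in range(n)], name="sample")
    cohort = np.arange(n) % config.n_cohorts
    age = rng.normal(50.0, 10.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    alphas = np.linspace(6.0, 1.0, config.n_cell_types)
    cf = rng.dirichlet(alphas, size=n)
    cov = pd.DataFrame({"age": age, "sex": sex, "cohort": cohort}, index=samples)
    for j in range(config.n_cell_types):
        cov[f"cf_{j + 1}"] = cf[:, j]
    return cov


def _std(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _covariate_component(
    covariates: pd.DataFrame, effects: dict[str, tuple[float, float]], which: int
) -> np.ndarray:
    comp = np.zeros(len(covariates))
    for name, eff in effects.items():
        e = eff[which]
        if e == 0:
            continue
        if name not in covariates.columns:
            raise ValueError(f"covariate_effects references unknown covariate {name!r}")
        comp += e * _std(covariates[name].to_numpy(float))
    return comp


def simulate_expression(
    dosages: pd.DataFrame,
    covariates: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate unit-variance expression; returns (expression, truth table).

    When ``h2_cis`` is set for a gene, the provided cis effect sizes are
    rescaled so the realized (sample) variance of the genetic component is
    exactly ``h2_cis``.
    """
    n = config.n_samples
    cov_comp = _covariate_component(covariates, config.covariate_effects, 0)
    confounders: dict[str, np.ndarray] = {}
    for sc in config.scenarios:
        if sc.kind == "cell_composition_confounder":
            confounders[sc.gene] = confounders.get(sc.gene, 0.0) + sc.expr_effect * _std(
                dosages[sc.snp].to_numpy(float)
            )
    expr = {}
    rows = []
    for g in config.genes:
        genetic = np.zeros(n)
        if g.cis_snps:
            d_std = np.column_stack(
                [_std(dosages[sid].to_numpy(float)) for sid in g.cis_snps]
            )
            genetic = d_std @ np.asarray(g.cis_effects, dtype=float)
        realized = float(genetic.var())
        h2 = g.h2_cis
        if h2 is not None and realized > 0:
            genetic = genetic * np.sqrt(h2 / realized)
            realized = h2
        elif h2 == 0.0:
            genetic = np.zeros(n)
            realized = 0.0
        conf = confounders.get(g.gene, np.zeros(n))
        systematic = genetic + cov_comp + conf
        noise_var = 1.0 - float(np.var(systematic))
        if noise_var <= 0:
            warnings.warn(
                f"systematic variance >= 1 for gene {g.gene}; flooring noise at 0.02"
            )
            noise_var = 0.02
        e = systematic + rng.normal(0.0, np.sqrt(noise_var), size=n)
        expr[g.gene] = e
        rows.append(
            {
                "gene": g.gene,
                "h2_cis": realized,
                "cis_snps": ",".join(g.cis_snps),
                "noise_var": noise_var,
            }
        )
    frame = pd.DataFrame(expr, index=dosages.index)
    truth = pd.DataFrame(rows).set_index("gene")
    return frame, truth


def _counts_from_latent(
    expression: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Map latent-normal expression onto a pseudo-CPM count scale.

    Each gene gets a log-scale baseline so that median CPM spans roughly
    0.1-100; a handful of genes land below the median-CPM filter cutoff.
    """
    n_genes = expression.shape[1]
    base = rng.uniform(-1.0, 2.0, size=n_genes)  # log10 relative abundance
    lam = 10 ** (base[None, :] + 0.15 * expression.to_numpy(float)) * 50.0
    counts = rng.poisson(lam).astype(float)
    # all-zero libraries break the CPM filter contract; nudge the most
    # abundant gene (vanishingly rare except for very small gene panels)
    zero_lib = counts.sum(axis=1) == 0
    if zero_lib.any():
        counts[zero_lib, np.argmax(lam[zero_lib], axis=1)] = 1.0
    return pd.DataFrame(counts, index=expression.index, columns=expression.columns)


def simulate_methylation(
    expression: pd.DataFrame,
    dosages: pd.DataFrame,
    covariates: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate methylation; returns (methylation, truth table).

    The trans criterion for every (regulator, probe) pair is enforced by
    :meth:`SimConfig.validate`. Noise is ``N(0, meth_noise_sd^2)``; optional
    inverse-logit squashing to the beta scale is applied when
    ``config.beta_scale`` is set (flagged in the dataset).
    """
    n = config.n_samples
    cov_comp = _covariate_component(covariates, config.covariate_effects, 1)
    probe_ids = [p[0] for p in config.probes]
    meth = {pid: cov_comp.copy() for pid in probe_ids}
    rows = []
    for te in config.trans_effects:
        meth[te.probe] = meth[te.probe] + te.phi * _std(
            expression[te.gene].to_numpy(float)
        )
        rows.append(
            {"kind": "trans", "gene": te.gene, "probe": te.probe, "effect": te.phi,
             "snp": ""}
        )
    for sc in config.scenarios:
        if sc.kind == "direct_snp_to_cpg":
            meth[sc.probe] = meth[sc.probe] + sc.meth_effect * _std(
                dosages[sc.snp].to_numpy(float)
            )
            rows.append(
                {"kind": sc.kind, "gene": "", "probe": sc.probe,
                 "effect": sc.meth_effect, "snp": sc.snp}
            )
        elif sc.kind == "cell_composition_confounder":
            meth[sc.probe] = meth[sc.probe] + sc.meth_effect * _std(
                dosages[sc.snp].to_numpy(float)
            )
            rows.append(
                {"kind": sc.kind, "gene": sc.gene or "", "probe": sc.probe,
                 "effect": sc.meth_effect, "snp": sc.snp}
            )
        elif sc.kind == "shared_eqtl":
            rows.append(
                {"kind": sc.kind, "gene": f"{sc.gene};{sc.gene_b}",
                 "probe": sc.probe or "", "effect": np.nan, "snp": ""}
            )
    noise = rng.normal(0.0, config.meth_noise_sd, size=(n, len(probe_ids)))
    frame = pd.DataFrame(
        {pid: meth[pid] + noise[:, j] for j, pid in enumerate(probe_ids)},
        index=expression.index,
    )
    if config.beta_scale:
        frame = pd.DataFrame(
            expit(frame.to_numpy(float)), index=frame.index, columns=frame.columns
        )
    truth = pd.DataFrame(
        rows, columns=["kind", "gene", "probe", "effect", "snp"]
    )
    return frame, truth


def simulate(config: SimConfig) -> CohortDataset:
    """Generate a full :class:`CohortDataset` from a :class:`SimConfig`.

    Deterministic: the same config (including seed) yields identical data.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    dosages, snp_ann = simulate_genotypes(config, rng)
    covariates = simulate_covariates(config, rng)
    expression, expr_truth = simulate_expression(dosages, covariates, config, rng)
    methylation, meth_truth = simulate_methylation(
        expression, dosages, covariates, config, rng
    )
    counts = _counts_from_latent(expression, rng) if config.make_counts else None
    genes = pd.DataFrame(
        {
            "chrom": [g.chrom for g in config.genes],
            "tss": [g.tss for g in config.genes],
            "tes": [g.tes for g in config.genes],
        },
        index=pd.Index([g.gene for g in config.genes], name="gene"),
    )
    probes = pd.DataFrame(
        {
            "chrom": [p[1] for p in config.probes],
            "pos": [p[2] for p in config.probes],
        },
        index=pd.Index([p[0] for p in config.probes], name="probe"),
    )
    ds = CohortDataset(
        dosages=dosages,
        expression=expression,
        methylation=methylation,
        covariates=covariates,
        snps=snp_ann,
        genes=genes,
        probes=probes,
        expression_counts=counts,
        truth={"expression": expr_truth, "effects": meth_truth},
        methylation_scale="beta" if config.beta_scale else "latent",
        expression_scale="latent",
    )
    ds.check_alignment()
    return ds


# ---------------------------------------------------------------------------
# canned scenario configs
# ---------------------------------------------------------------------------

def shared_eqtl_config(
    n_samples: int = 1500,
    h2: float = 0.15,
    shared_fraction: float = 0.64,
    phi: float = 1.0,
    n_cohorts: int = 1,
    seed: int = 0,
) -> SimConfig:
    """Two neighboring genes sharing a cis SNP; only gene A drives the probe.

    ``shared_fraction`` is the share of each gene's genetic variance coming
    from the shared SNP, hence also the approximate correlation of the two
    true genetic instruments.
    """
    snps = [
        SnpSpec("rs_shared", "1", 1_000_000, 0.3, "blkA"),
        SnpSpec("rs_a", "1", 1_010_000, 0.3, None),
        SnpSpec("rs_b", "1", 1_060_000, 0.3, None),
    ]
    w_shared = np.sqrt(shared_fraction)
    w_priv = np.sqrt(1.0 - shared_fraction)
    genes = [
        GeneSpec("geneA", "1", 1_000_500, 1_005_000,
                 ("rs_shared", "rs_a"), (w_shared, w_priv), h2),
        GeneSpec("geneB", "1", 1_050_000, 1_055_000,
                 ("rs_shared", "rs_b"), (w_shared, w_priv), h2),
    ]
    probes = [("cpg_t", "2", 5_000_000), ("cpg_null", "3", 9_000_000)]
    return SimConfig(
        n_samples=n_samples,
        snps=snps,
        genes=genes,
        probes=probes,
        trans_effects=[TransEffect("geneA", "cpg_t", phi)],
        scenarios=[ScenarioSpec("shared_eqtl", gene="geneA", gene_b="geneB",
                                probe="cpg_t")],
        n_cohorts=n_cohorts,
        seed=seed,
    )


def cell_confounder_config(
    n_samples: int = 1500,
    h2: float = 0.15,
    confound_meth: float = 0.6,
    n_cohorts: int = 1,
    seed: int = 0,
) -> SimConfig:
    """A SNP drives a gene's expression and, via an unmeasured confounder,
    a distant probe. There is no true expression -> methylation effect."""
    snps = [
        SnpSpec("rs_drv", "1", 2_000_000, 0.3, None),
        SnpSpec("rs_extra", "1", 2_020_000, 0.3, None),
    ]
    genes = [
        GeneSpec("geneC", "1", 2_005_000, 2_010_000,
                 ("rs_drv", "rs_extra"), (np.sqrt(0.7), np.sqrt(0.3)), h2),
    ]
    probes = [("cpg_c", "5", 3_000_000)]
    return SimConfig(
        n_samples=n_samples,
        snps=snps,
        genes=genes,
        probes=probes,
        trans_effects=[],
        scenarios=[
            ScenarioSpec(
                "cell_composition_confounder",
                snp="rs_drv",
                gene="geneC",
                probe="cpg_c",
                expr_effect=0.0,
                meth_effect=confound_meth,
            )
        ],
        n_cohorts=n_cohorts,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# writers (text formats only)
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"


def write_dataset(ds: CohortDataset, outdir: str, vcf: bool = False) -> None:
    """Write the dataset as TSV/BED files under ``outdir``.

    Truth tables go to a ``truth/`` subdirectory so pipeline stages cannot
    accidentally consume them.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    kw = dict(sep="\t", float_format=_FLOAT_FMT)
    ds.dosages.to_csv(os.path.join(outdir, "dosages.tsv"), index_label="sample", **kw)
    ds.expression.to_csv(
        os.path.join(outdir, "expression.tsv"), index_label="sample", **kw
    )
    if ds.expression_counts is not None:
        ds.expression_counts.to_csv(
            os.path.join(outdir, "expression_counts.tsv"), index_label="sample", **kw
        )
    ds.methylation.to_csv(
        os.path.join(outdir, "methylation.tsv"), index_label="sample", **kw
    )
    ds.covariates.to_csv(
        os.path.join(outdir, "covariates.tsv"), index_label="sample", **kw
    )
    ds.snps.to_csv(os.path.join(outdir, "snps.tsv"), **kw)
    genes_bed = pd.DataFrame(
        {
            "chrom": ds.genes["chrom"],
            "start": np.minimum(ds.genes["tss"], ds.genes["tes"]),
            "end": np.maximum(ds.genes["tss"], ds.genes["tes"]) + 1,
            "gene": ds.genes.index,
            "tss": ds.genes["tss"],
            "tes": ds.genes["tes"],
        }
    )
    genes_bed.to_csv(os.path.join(outdir, "genes.tsv"), index=False, **kw)
    probes_bed = pd.DataFrame(
        {
            "chrom": ds.probes["chrom"],
            "start": ds.probes["pos"],
            "end": ds.probes["pos"] + 1,
            "probe": ds.probes.index,
        }
    )
    probes_bed.to_csv(
        os.path.join(outdir, "probes.bed"), index=False, header=False, **kw
    )
    truth_dir = os.path.join(outdir, "truth")
    os.makedirs(truth_dir, exist_ok=True)
    for name, table in ds.truth.items():
        table.to_csv(os.path.join(truth_dir, f"{name}.tsv"), **kw)
    if vcf:
        write_vcf(ds, os.path.join(outdir, "dosages.vcf"))


def write_vcf(ds: CohortDataset, path: str) -> None:
    """Write dosages as an uncompressed VCF with a DS FORMAT field."""
    samples = list(ds.dosages.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        order = ds.snps.sort_values(["chrom", "pos"]).index
        for sid in order:
            row = ds.snps.loc[sid]
            ds_vals = ds.dosages[sid].to_numpy(float)
            vals = "\t".join(f"{v:.3f}" for v in ds_vals)
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{sid}\tA\tG\t.\tPASS\t.\tDS\t{vals}\n"
            )
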