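"""Synthetic genotype/phenotype generator with half-sib family structure.

The generator emulates the statistical structure of an AI (artificial
insemination) bull population: paternal half-sib families (each sire leaves
``offspring_per_sire`` genotyped sons; the sons are the study individuals),
biallelic SNPs with allele frequencies drawn uniformly from a MAF band,
planted QTLs acting additively, dominantly, recessively or overdominantly,
a polygenic term u ~ N(0, G·σu²) built from the realised genomic
relationship matrix, and an i.i.d. residual. Setting
``offspring_per_sire = 1`` gives an unrelated panel for calibration work.

Every output is a pure function of the configuration (including its seed);
a :class:`TruthTable` records the planted effects for power and calibration
studies downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coding import CodingModel, encode_genotypes
from .grm import compute_grm
from .io import GenotypeMatrix, MarkerInfo


@dataclass(frozen=True)
class QtlSpec:
    """A planted causal marker: which SNP, which gene action, what effect.

    ``effect`` is the phenotype-unit effect of one coded unit — the
    generative analogue of the per-SNP regression coefficient.
    """

    snp_index: int
    model: CodingModel
    effect: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "model", CodingModel(self.model))
        if not np.isfinite(self.effect):
            raise ValueError(f"QTL effect must be finite, got {self.effect}")
        if self.snp_index < 0:
            raise ValueError(f"snp_index must be non-negative, got {self.snp_index}")


class SimulationConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Defaults mirror a mid-size paternal half-sib study: 50 sires × 10 sons
    (n = 500), 2,000 SNPs with MAF in [0.05, 0.5], heritability
    σu²/(σu²+σe²) = 0.3 on a residual of unit-variance scale, no QTLs.
    """

    n_sires: int = 50
    offspring_per_sire: int = 10
    n_snps: int = 2000
    maf_low: float = 0.05
    maf_high: float = 0.5
    qtl_specs: tuple[QtlSpec, ...] = ()
    sigma_u2: float = 3.0
    sigma_e2: float = 7.0
    mu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "qtl_specs", tuple(self.qtl_specs))
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise SimulationConfigError(
                f"require 0 < maf_low <= maf_high <= 0.5; got [{self.maf_low}, {self.maf_high}]"
            )
        if self.n_sires < 1 or self.offspring_per_sire < 1 or self.n_snps < 1:
            raise SimulationConfigError("counts must be positive")
        if self.sigma_u2 < 0 or self.sigma_e2 <= 0:
            raise SimulationConfigError(
                f"require sigma_u2 >= 0 and sigma_e2 > 0; got {self.sigma_u2}, {self.sigma_e2}"
            )
        for q in self.qtl_specs:
            if q.snp_index >= self.n_snps:
                raise SimulationConfigError(
                    f"QTL index {q.snp_index} out of range for {self.n_snps} SNPs"
                )

    @property
    def n_individuals(self) -> int:
        return self.n_sires * self.offspring_per_sire

    @property
    def h2(self) -> float:
        return self.sigma_u2 / (self.sigma_u2 + self.sigma_e2)


@dataclass
class TruthTable:
    """Ground truth of the planted QTLs plus realised variance shares."""

    qtls: pd.DataFrame  # snp_id, snp_index, model, effect, freq_AA, freq_AB, freq_BB
    sigma_u2: float
    sigma_e2: float

    def write_tsv(self, path) -> None:
        self.qtls.to_csv(path, sep="\t", index=False)


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw a half-sib genotype panel.

    Per SNP, allele-B frequency p_j ~ U[maf_low, maf_high]. Each sire is an
    HWE draw; each son receives one random sire gamete (so paternal half sibs
    share alleles identically by descent) and one dam gamete drawn from the
    population frequency (dams unobserved and unrelated).

    RNG contract: the frequency vector is the *first* draw from
    ``default_rng(config.seed)``, so callers can reproduce the drawn
    frequencies independently of the genotype draws.
    """
    rng = np.random.default_rng(config.seed)
    m, s, k = config.n_snps, config.n_sires, config.offspring_per_sire
    p = rng.uniform(config.maf_low, config.maf_high, size=m)

    sire_haps = rng.random((s, m, 2)) < p[None, :, None]  # two gametes per sire
    # each offspring samples which of the sire's two gametes it inherits
    which = rng.integers(0, 2, size=(s, k, m))
    paternal = np.empty((s, k, m), dtype=bool)
    for i in range(s):
        paternal[i] = np.where(which[i] == 0, sire_haps[i, :, 0], sire_haps[i, :, 1])
    maternal = rng.random((s, k, m)) < p[None, None, :]
    dosages = (paternal.astype(int) + maternal.astype(int)).reshape(s * k, m).astype(float)

    ids = [f"S{i + 1:03d}_O{j + 1:03d}" for i in range(s) for j in range(k)]
    # spread markers over 29 autosome labels, 1 Mb apart within a chromosome
    markers = [
        MarkerInfo(
            snp_id=f"snp{j + 1:05d}",
            chromosome=str(j % 29 + 1),
            position=(j // 29 + 1) * 1_000_000,
        )
        for j in range(m)
    ]
    return GenotypeMatrix(dosages=dosages, individual_ids=ids, markers=markers)


def plant_qtls(gm: GenotypeMatrix, specs: list[QtlSpec] | tuple[QtlSpec, ...]) -> np.ndarray:
    """Genetic value per individual: Σ_q effect_q · code(dosage_q, model_q)."""
    g = np.zeros(gm.n_individuals)
    for q in specs:
        if not 0 <= q.snp_index < gm.n_markers:
            raise IndexError(f"QTL index {q.snp_index} out of range for {gm.n_markers} markers")
        g += q.effect * encode_genotypes(gm.dosages[:, q.snp_index], q.model)
    return g


def simulate_phenotypes(
    gm: GenotypeMatrix,
    specs: list[QtlSpec] | tuple[QtlSpec, ...],
    sigma_u2: float,
    sigma_e2: float,
    seed: int,
    mu: float = 0.0,
) -> tuple[np.ndarray, TruthTable]:
    """Phenotype = μ + planted QTL values + polygenic term + residual.

    The polygenic term is u = L·ζ·σu with G = L·Lᵀ the Cholesky factor of
    the realised VanRaden GRM of ``gm`` (so the simulated covariance is the
    matrix the analysis will estimate) and ζ i.i.d. standard normal. The
    residual is i.i.d. N(0, σe²).
    """
    if gm.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    if sigma_u2 < 0 or sigma_e2 <= 0:
        raise ValueError("require sigma_u2 >= 0 and sigma_e2 > 0")
    rng = np.random.default_rng(seed)
    n = gm.n_individuals

    u = np.zeros(n)
    if sigma_u2 > 0:
        grm = compute_grm(gm)
        try:
            L = np.linalg.cholesky(grm.g)
        except np.linalg.LinAlgError as exc:
            cond = np.linalg.cond(grm.g)
            raise np.linalg.LinAlgError(
                f"GRM not positive definite even after ridge (condition number {cond:.3e})"
            ) from exc
        u = np.sqrt(sigma_u2) * (L @ rng.standard_normal(n))
    e = np.sqrt(sigma_e2) * rng.standard_normal(n)
    y = mu + plant_qtls(gm, specs) + u + e

    rows = []
    for q in specs:
        d = gm.dosages[:, q.snp_index]
        obs = d[~np.isnan(d)]
        total = max(obs.size, 1)
        rows.append(
            {
                "snp_id": gm.markers[q.snp_index].snp_id,
                "snp_index": q.snp_index,
                "model": q.model.value,
                "effect": q.effect,
                "freq_AA": float((obs == 0).sum()) / total,
                "freq_AB": float((obs == 1).sum()) / total,
                "freq_BB": float((obs == 2).sum()) / total,
            }
        )
    truth = TruthTable(
        qtls=pd.DataFrame(
            rows,
            columns=["snp_id", "snp_index", "model", "effect", "freq_AA", "freq_AB", "freq_BB"],
        ),
        sigma_u2=sigma_u2,
        sigma_e2=sigma_e2,
    )
    return y, truth


def simulate_dataset(config: SimulationConfig) -> tuple[GenotypeMatrix, np.ndarray, TruthTable]:
    """Genotypes and phenotypes in one call, both driven by ``config.seed``."""
    gm = simulate_genotypes(config)
    # derive an independent phenotype stream from the same seed
    pheno_seed = int(np.random.SeedSequence(config.seed).spawn(1)[0].generate_state(1)[0] % (2**31))
    y, truth = simulate_phenotypes(
        gm, config.qtl_specs, config.sigma_u2, config.sigma_e2, seed=pheno_seed, mu=config.mu
    )
    return gm, y, truth
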