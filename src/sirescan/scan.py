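"""Step 2 of the two-step scan: per-SNP association tests.

With the null covariance V₀ = G·σ̂u² + I·σ̂e² and the fixed-effect solutions
β̂ frozen from step 1, each coded SNP vector x is tested with the score-type
statistic

    z = xᵀ V₀⁻¹ (y − X·β̂) / sqrt(xᵀ V₀⁻¹ x),

which approximates the per-SNP Wald test and is asymptotically standard
normal. The implied effect estimate is β = xᵀV₀⁻¹r / xᵀV₀⁻¹x with standard
error (xᵀV₀⁻¹x)^(−1/2), so z = β/se. Before testing, each coded vector is
residualized against the fixed-effect design in the V₀⁻¹ inner product (for
an intercept-only design this is GLS centering, absorbing the coding's
baseline). This leaves the numerator of the printed statistic unchanged —
XᵀV₀⁻¹(y − Xβ̂) = 0 at the GLS solution — while making the denominator the
exact conditional variance of the numerator, so z coincides with the Wald
statistic of a joint GLS fit of y on [X, x] at the frozen V₀.

The whole-panel scan evaluates every marker under every requested coding
(the additive coding is always computed alongside, so each marker reports
both a non-additive and an additive p-value), applies genomic control per
coding, and flags markers whose coded vector is constant (e.g. the recessive
coding of a marker with no BB individuals) as untestable rather than
reporting z = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coding import CodingModel, encode_genotypes, genotype_counts, compute_maf
from .correction import GcEstimate, bonferroni_threshold, estimate_lambda, gc_adjust
from .io import GenotypeMatrix
from .reml import NullFit

#: numerical floor on xᵀV₀⁻¹x below which a marker is untestable
_DEN_FLOOR = 1e-12


def _residualize_against_fixed(M: np.ndarray, nf: NullFit) -> np.ndarray:
    """Project coded columns onto the V₀⁻¹-orthocomplement of the fixed
    design: M − X·(XᵀV₀⁻¹X)⁻¹·XᵀV₀⁻¹M."""
    vix_X = nf.v0_solve(nf.X)
    A = nf.X.T @ vix_X
    coef = np.linalg.solve(A, vix_X.T @ M)
    return M - nf.X @ coef


@dataclass(frozen=True)
class SnpTestResult:
    """One marker tested under one coding model."""

    snp_id: str
    model: CodingModel
    beta: float
    se: float
    z: float
    p_raw: float
    p_gc: float
    maf: float
    n_AA: int
    n_AB: int
    n_BB: int

    @property
    def testable(self) -> bool:
        return np.isfinite(self.z)


def snp_test(x_coded: np.ndarray, nf: NullFit) -> tuple[float, float, float, float]:
    """Score-type test of one coded SNP vector against the frozen null.

    Returns (beta, se, z, p_raw); all-nan when the centered coded vector is
    numerically constant (untestable marker).
    """
    x = np.asarray(x_coded, dtype=float).ravel()
    if x.size != nf.y.size:
        raise ValueError(f"coded vector length {x.size} != {nf.y.size} records")
    x = _residualize_against_fixed(x[:, None], nf).ravel()
    vix = nf.v0_solve(x)
    den = float(x @ vix)
    if den <= _DEN_FLOOR:
        return (np.nan, np.nan, np.nan, np.nan)
    num = float(vix @ nf.residuals)
    beta = num / den
    se = den**-0.5
    z = num / np.sqrt(den)
    return (beta, se, z, float(2.0 * stats.norm.sf(abs(z))))


@dataclass
class ScanResult:
    """Full per-marker, per-model scan table plus per-model inflation factors."""

    table: pd.DataFrame  # snp_id, chr, pos, model, maf, counts, beta, se, z, p_raw, p_gc
    lambda_gc: dict[CodingModel, GcEstimate]
    n_tested: dict[CodingModel, int]
    alpha: float
    threshold: float

    def results_for(self, model: CodingModel) -> pd.DataFrame:
        return self.table[self.table["model"] == CodingModel(model).value]

    def significant(self, model: CodingModel | None = None) -> pd.DataFrame:
        t = self.table if model is None else self.results_for(model)
        return t[t["significant"]]

    def manhattan_frame(self) -> pd.DataFrame:
        """Plot-ready data: chromosome, position and −log10(p_gc) per model."""
        out = self.table[["snp_id", "chr", "pos", "model", "p_gc"]].copy()
        with np.errstate(divide="ignore"):
            out["neg_log10_p_gc"] = -np.log10(out["p_gc"])
        return out


def genome_scan(
    gm: GenotypeMatrix,
    y: np.ndarray,
    nf: NullFit,
    models: tuple[CodingModel, ...] | list[CodingModel] = (
        CodingModel.DOMINANCE,
        CodingModel.RECESSIVE,
        CodingModel.OVERDOMINANCE,
    ),
    alpha: float = 0.01,
    gc_method: str = "median",
) -> ScanResult:
    """Scan every marker under every requested coding (plus additive).

    ``gm`` must be the QC'd panel whose individuals match the null fit in
    identity *and order*; any mismatch is a hard error, never a silent
    reorder. Genomic control is estimated per coding from that coding's own
    z statistics. The significance column uses the Bonferroni threshold
    alpha / n_markers applied to p_gc.
    """
    if list(gm.individual_ids) != list(nf.ids):
        extra = [i for i in gm.individual_ids if i not in set(nf.ids)][:5]
        raise ValueError(
            "genotype individuals do not match the null fit (same ids, same order, "
            f"required); first offenders: {extra or 'order mismatch'}"
        )
    y = np.asarray(y, dtype=float).ravel()
    if not np.allclose(y, nf.y):
        raise ValueError("phenotype vector differs from the one the null model was fitted to")

    wanted = [CodingModel(m) for m in models]
    all_models = list(dict.fromkeys(wanted + [CodingModel.ADDITIVE]))

    d_imp = gm.imputed_dosages()
    vr = nf.v0_solve(nf.residuals)  # V₀⁻¹ (y − Xβ̂), shared across markers
    lam_inv = 1.0 / nf.v0_eigenvalues

    per_marker = [
        (mk.snp_id, mk.chromosome, mk.position) + genotype_counts(gm.dosages[:, j])
        for j, mk in enumerate(gm.markers)
    ]
    maf = np.array([compute_maf(nAA, nAB, nBB) for (_, _, _, nAA, nAB, nBB) in per_marker])

    frames = []
    lambdas: dict[CodingModel, GcEstimate] = {}
    n_tested: dict[CodingModel, int] = {}
    threshold = bonferroni_threshold(alpha, gm.n_markers)

    for model in all_models:
        M = encode_genotypes(d_imp, model)
        M = _residualize_against_fixed(M, nf)
        # spectral inner products: xᵀV₀⁻¹x = Σᵢ (Uᵀx)ᵢ² / λᵢ per column
        B = nf.eigenvectors.T @ M
        den = np.einsum("ij,ij->j", B, B * lam_inv[:, None])
        num = M.T @ vr
        testable = den > _DEN_FLOOR
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(testable, num / den, np.nan)
            se = np.where(testable, den**-0.5, np.nan)
            z = np.where(testable, num / np.sqrt(den), np.nan)
        p_raw = 2.0 * stats.norm.sf(np.abs(z))
        gc = estimate_lambda(z, method=gc_method)
        p_gc = gc_adjust(z, gc)
        lambdas[model] = gc
        n_tested[model] = int(testable.sum())
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": [p[0] for p in per_marker],
                    "chr": [p[1] for p in per_marker],
                    "pos": [p[2] for p in per_marker],
                    "model": model.value,
                    "maf": maf,
                    "n_AA": [p[3] for p in per_marker],
                    "n_AB": [p[4] for p in per_marker],
                    "n_BB": [p[5] for p in per_marker],
                    "beta": beta,
                    "se": se,
                    "z": z,
                    "p_raw": p_raw,
                    "p_gc": p_gc,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table["significant"] = table["p_gc"] < threshold
    return ScanResult(
        table=table,
        lambda_gc=lambdas,
        n_tested=n_tested,
        alpha=alpha,
        threshold=threshold,
    )
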