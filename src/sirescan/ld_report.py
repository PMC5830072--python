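"""Post-scan reporting: pairwise LD, top-marker tables and genotype-class
phenotype summaries.

LD between unphased markers is measured as composite r² — the squared
Pearson correlation of genotype dosages over individuals with complete calls
at both markers — since haplotype phase is not available from array data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coding import NON_ADDITIVE_MODELS, CodingModel
from .io import GenotypeMatrix
from .scan import ScanResult


@dataclass
class LdMatrix:
    """Symmetric matrix of pairwise composite-LD r² values."""

    marker_ids: list[str]
    r2: np.ndarray  # entries in [0,1]; nan rows for zero-variance markers

    def __post_init__(self) -> None:
        k = len(self.marker_ids)
        if self.r2.shape != (k, k):
            raise ValueError("r2 matrix shape does not match marker count")
        finite = self.r2[np.isfinite(self.r2)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("r2 entries must lie in [0, 1]")
        if not np.allclose(
            np.nan_to_num(self.r2), np.nan_to_num(self.r2.T), atol=1e-12
        ):
            raise ValueError("r2 matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r2, index=self.marker_ids, columns=self.marker_ids)


def pairwise_r2(gm: GenotypeMatrix, marker_ids: list[str]) -> LdMatrix:
    """Composite LD r² between every pair of the named markers.

    Each pair is correlated over the individuals with observed calls at both
    markers. A marker with zero dosage variance gets a nan row/column (its
    diagonal stays 1 by convention).
    """
    if len(marker_ids) < 2:
        raise ValueError("need at least 2 markers for an LD matrix")
    idx = [gm.marker_index(s) for s in marker_ids]
    k = len(idx)
    cols = [gm.dosages[:, j] for j in idx]
    r2 = np.full((k, k), np.nan)
    np.fill_diagonal(r2, 1.0)
    for a in range(k):
        for b in range(a + 1, k):
            both = ~np.isnan(cols[a]) & ~np.isnan(cols[b])
            xa, xb = cols[a][both], cols[b][both]
            if both.sum() < 2 or xa.std() == 0 or xb.std() == 0:
                continue
            r = np.corrcoef(xa, xb)[0, 1]
            r2[a, b] = r2[b, a] = min(r * r, 1.0)
    return LdMatrix(marker_ids=list(marker_ids), r2=r2)


@dataclass
class GenotypeClassSummary:
    """Phenotype distribution within each genotype class of one marker."""

    snp_id: str
    summary: pd.DataFrame  # index AA/AB/BB: n, mean, median, q1, q3

    def to_frame(self) -> pd.DataFrame:
        return self.summary


def genotype_phenotype_summary(
    gm: GenotypeMatrix, y: np.ndarray, marker_id: str
) -> GenotypeClassSummary:
    """Per-genotype-class n, mean, median and quartiles of the raw phenotype.

    An empty class is reported with n = 0 and nan statistics; class ns sum
    to the number of individuals with an observed genotype call.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size != gm.n_individuals:
        raise ValueError("phenotype length does not match genotype rows")
    d = gm.dosages[:, gm.marker_index(marker_id)]
    rows = {}
    for label, dosage in (("AA", 0.0), ("AB", 1.0), ("BB", 2.0)):
        vals = y[d == dosage]
        rows[label] = {
            "n": int(vals.size),
            "mean": float(np.mean(vals)) if vals.size else np.nan,
            "median": float(np.median(vals)) if vals.size else np.nan,
            "q1": float(np.percentile(vals, 25)) if vals.size else np.nan,
            "q3": float(np.percentile(vals, 75)) if vals.size else np.nan,
        }
    return GenotypeClassSummary(snp_id=marker_id, summary=pd.DataFrame(rows).T)


def results_table(
    scan: ScanResult,
    gm: GenotypeMatrix,
    y: np.ndarray,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Top-marker table: one row per marker passing the threshold under a
    non-additive coding, pairing the non-additive test with the additive test
    of the same marker (so a purely non-additive mode of action shows as a
    small non-additive p next to a large additive p).

    Columns: marker, chr, pos, model, maf, n_AA, n_AB, n_BB, beta, se,
    p_nonadd (GC-adjusted), p_raw, p_add; sorted by model then chr/pos.
    """
    threshold = scan.threshold if threshold is None else threshold
    add = (
        scan.results_for(CodingModel.ADDITIVE)
        .set_index("snp_id")["p_gc"]
        .rename("p_add")
    )
    rows = []
    for model in NON_ADDITIVE_MODELS:
        sub = scan.results_for(model)
        hits = sub[sub["p_gc"] < threshold]
        for _, r in hits.iterrows():
            rows.append(
                {
                    "marker": r["snp_id"],
                    "chr": r["chr"],
                    "pos": r["pos"],
                    "model": model.value,
                    "maf": r["maf"],
                    "n_AA": r["n_AA"],
                    "n_AB": r["n_AB"],
                    "n_BB": r["n_BB"],
                    "beta": r["beta"],
                    "se": r["se"],
                    "p_nonadd": r["p_gc"],
                    "p_raw": r["p_raw"],
                    "p_add": add.get(r["snp_id"], np.nan),
                }
            )
    columns = [
        "marker", "chr", "pos", "model", "maf", "n_AA", "n_AB", "n_BB",
        "beta", "se", "p_nonadd", "p_raw", "p_add",
    ]
    out = pd.DataFrame(rows, columns=columns)
    if len(out):
        model_order = {m.value: i for i, m in enumerate(NON_ADDITIVE_MODELS)}
        out = (
            out.assign(_m=out["model"].map(model_order))
            .sort_values(["_m", "chr", "pos"], kind="stable")
            .drop(columns="_m")
            .reset_index(drop=True)
        )
    return out
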