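"""Genomic relationship matrix (VanRaden method 1).

G = W·Wᵀ / (2·Σⱼ pⱼ(1−pⱼ)), where W is the dosage matrix with each column
centered at twice its sample allele frequency. Under Hardy–Weinberg
equilibrium with unrelated individuals the diagonal has expectation 1 and
paternal half sibs have expected off-diagonal 0.25. A small ridge is added to
the diagonal so G is always invertible (the null covariance V₀ built from it
is inverted downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix


@dataclass
class GRM:
    """Symmetric genomic relationship matrix with its individual ids."""

    g: np.ndarray
    ids: list[str]
    ridge: float = 0.0

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        n = len(self.ids)
        if self.g.shape != (n, n):
            raise ValueError(f"GRM shape {self.g.shape} does not match {n} ids")
        if not np.allclose(self.g, self.g.T, atol=1e-10):
            raise ValueError("GRM must be symmetric to 1e-10")

    @property
    def n(self) -> int:
        return self.g.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.g, index=self.ids, columns=self.ids)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def read_csv(cls, path) -> "GRM":
        df = pd.read_csv(path, index_col=0)
        return cls(g=df.to_numpy(dtype=float), ids=[str(i) for i in df.index])


def compute_grm(gm: GenotypeMatrix, ridge: float = 1e-6) -> GRM:
    """VanRaden method-1 GRM from a QC'd genotype matrix.

    Missing dosages are mean-imputed per marker before centering (an imputed
    cell contributes exactly zero to W). Allele frequencies are the sample
    frequencies of the imputed matrix. Raises if the scaling denominator
    2Σp(1−p) vanishes (an all-monomorphic panel: run QC first).
    """
    if gm.n_markers < 2:
        raise ValueError("need >= 2 markers to build a GRM; run QC first")
    x = gm.imputed_dosages()
    p = x.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError(
            "GRM denominator 2*sum(p(1-p)) is zero: all markers monomorphic; run QC first"
        )
    w = x - 2.0 * p
    g = (w @ w.T) / denom
    g = (g + g.T) / 2.0  # enforce exact symmetry against FP noise
    if ridge:
        g[np.diag_indices_from(g)] += ridge
    return GRM(g=g, ids=list(gm.individual_ids), ridge=ridge)
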