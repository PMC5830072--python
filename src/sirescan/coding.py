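"""Marker QC and the four genotype codings.

A biallelic SNP with alleles A and B can act on a phenotype in four simple
ways, each expressible as a single numeric regressor built from the B-allele
dosage (0 = AA, 1 = AB, 2 = BB):

========== =================== ====================================
model       code(0,1,2)         interpretation
========== =================== ====================================
additive    (0, 1, 2)           linear in allele count
dominance   (0, 1, 1)           one B copy acts like two
recessive   (0, 0, 1)           only the BB homozygote deviates
overdominance (0, 1, 0)         only the heterozygote deviates
========== =================== ====================================

Note the algebraic identity code_dom − code_rec = code_overdom.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .io import GenotypeMatrix


class CodingModel(str, enum.Enum):
    """The four single-regressor genetic-effect codings."""

    ADDITIVE = "additive"
    DOMINANCE = "dominance"
    RECESSIVE = "recessive"
    OVERDOMINANCE = "overdominance"

    @property
    def code_map(self) -> tuple[float, float, float]:
        """Codes assigned to dosages (0, 1, 2)."""
        return _CODE_MAPS[self]


_CODE_MAPS = {
    CodingModel.ADDITIVE: (0.0, 1.0, 2.0),
    CodingModel.DOMINANCE: (0.0, 1.0, 1.0),
    CodingModel.RECESSIVE: (0.0, 0.0, 1.0),
    CodingModel.OVERDOMINANCE: (0.0, 1.0, 0.0),
}

NON_ADDITIVE_MODELS = (
    CodingModel.DOMINANCE,
    CodingModel.RECESSIVE,
    CodingModel.OVERDOMINANCE,
)


def encode_genotypes(dosages: np.ndarray, model: CodingModel) -> np.ndarray:
    """Map dosage values {0,1,2,nan} through a coding model.

    Missing dosages are first mean-imputed on the dosage scale, then mapped by
    treating the coding as piecewise-linear in dosage (preserves the column
    mean under the additive coding and keeps fractional imputed values
    meaningful under the others).
    """
    model = CodingModel(model)
    d = np.asarray(dosages, dtype=float)
    observed = ~np.isnan(d)
    if not observed.all():
        if d.ndim == 1:
            fill = np.nanmean(d) if observed.any() else 0.0
            d = np.where(observed, d, fill)
        else:
            col_mean = np.where(
                observed.any(axis=0), np.nanmean(np.where(observed, d, np.nan), axis=0), 0.0
            )
            d = np.where(observed, d, np.broadcast_to(col_mean, d.shape))
    bad = (d < 0) | (d > 2)
    if bad.any():
        raise ValueError(f"dosage outside [0, 2]: {np.asarray(d)[bad][:5]}")
    c0, c1, c2 = model.code_map
    # piecewise-linear interpolation of the code map in dosage
    return np.interp(d, [0.0, 1.0, 2.0], [c0, c1, c2])


def compute_maf(n_AA: int, n_AB: int, n_BB: int) -> float:
    """Minor allele frequency from genotype counts.

    f_B = (2·n_BB + n_AB) / (2·total); returns min(f_B, 1 − f_B).
    """
    if min(n_AA, n_AB, n_BB) < 0:
        raise ValueError("genotype counts must be non-negative")
    total = n_AA + n_AB + n_BB
    if total == 0:
        raise ValueError("cannot compute MAF with zero genotyped individuals")
    f_b = (2 * n_BB + n_AB) / (2 * total)
    return min(f_b, 1.0 - f_b)


def genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """(n_AA, n_AB, n_BB) over observed calls of one marker."""
    d = np.asarray(dosages, dtype=float)
    return (
        int(np.nansum(d == 0)),
        int(np.nansum(d == 1)),
        int(np.nansum(d == 2)),
    )


@dataclass
class QcReport:
    """Counts of markers removed per rule, in application order."""

    n_input: int
    n_sex_chromosome: int
    n_monomorphic: int
    n_low_maf: int
    n_retained: int
    maf_min: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "rule": ["sex_chromosome", "monomorphic", f"maf<{self.maf_min}", "retained"],
                "n_removed": [self.n_sex_chromosome, self.n_monomorphic, self.n_low_maf, 0],
                "n_retained": [
                    self.n_input - self.n_sex_chromosome,
                    self.n_input - self.n_sex_chromosome - self.n_monomorphic,
                    self.n_retained,
                    self.n_retained,
                ],
            }
        )


class EmptyPanelError(ValueError):
    """All markers were removed by QC."""


def qc_filter(
    gm: GenotypeMatrix,
    maf_min: float = 0.01,
    drop_sex_chromosomes: bool = True,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the marker QC filters, in order: sex-chromosome labels,
    monomorphic markers, then MAF < ``maf_min``.

    MAF is computed on observed (non-missing) calls, so imputation can never
    rescue a monomorphic marker. The MAF boundary is inclusive: a marker at
    exactly ``maf_min`` is retained (markers with MAF *less than* the
    threshold are removed).
    """
    d = gm.dosages
    n_input = gm.n_markers

    sex = np.array(
        [mk.is_sex_chromosome if drop_sex_chromosomes else False for mk in gm.markers]
    )
    n_obs = (~np.isnan(d)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        f_b = np.where(n_obs > 0, np.nansum(d, axis=0) / (2 * np.maximum(n_obs, 1)), np.nan)
    maf = np.minimum(f_b, 1.0 - f_b)
    mono = (maf == 0) | (n_obs == 0)
    low = maf < maf_min

    n_sex = int(sex.sum())
    n_mono = int((mono & ~sex).sum())
    n_low = int((low & ~mono & ~sex).sum())
    keep = ~sex & ~mono & ~low
    if not keep.any():
        raise EmptyPanelError(
            "QC removed every marker; check MAF threshold and chromosome labels"
        )
    report = QcReport(
        n_input=n_input,
        n_sex_chromosome=n_sex,
        n_monomorphic=n_mono,
        n_low_maf=n_low,
        n_retained=int(keep.sum()),
        maf_min=maf_min,
    )
    return gm.subset_markers(keep), report


def orient_minor(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Flip dosages so the B allele is the minor allele at every marker.

    Under opposite orientations the dominance and recessive codings are
    mirror images of each other, so orientation affects labelling of the two
    non-additive homozygote models, not which markers can be discovered.
    """
    from dataclasses import replace

    d = gm.dosages.copy()
    n_obs = (~np.isnan(d)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        f_b = np.nansum(d, axis=0) / (2 * np.maximum(n_obs, 1))
    flip = f_b > 0.5
    d[:, flip] = 2.0 - d[:, flip]
    markers = [
        replace(mk, allele_a=mk.allele_b, allele_b=mk.allele_a) if fl else mk
        for mk, fl in zip(gm.markers, flip)
    ]
    return GenotypeMatrix(dosages=d, individual_ids=list(gm.individual_ids), markers=markers)
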