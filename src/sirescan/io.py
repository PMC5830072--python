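"""Readers and writers for the file formats the pipeline touches.

Genotypes travel as a :class:`GenotypeMatrix` — an individuals × SNPs dosage
matrix (0/1/2 copies of the B allele, ``nan`` for missing) with ordered
individual ids and per-marker metadata.  Supported on-disk dialects:

* PLINK 1.x text ``.ped``/``.map`` pairs (the only genotype format the
  upstream panels are distributed in as text),
* a simple dosage-matrix CSV (rows = individuals, header = SNP ids),
* a phenotype TSV/CSV with columns ``id``, ``phenotype`` and an optional
  ``n_breedings`` column used to resolve duplicate records.

Readers never reorder individuals or markers; order is the file's order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: labels treated as sex chromosomes / non-autosomal for QC purposes
#: ("30" is a legacy synonym for the bovine X)
SEX_CHROMOSOME_LABELS = frozenset({"X", "Y", "XY", "MT", "30"})


class PlinkFormatError(ValueError):
    """Raised on malformed .ped/.map input (carries the offending line number)."""


class PhenotypeFormatError(ValueError):
    """Raised on malformed phenotype tables."""


@dataclass(frozen=True)
class MarkerInfo:
    """Metadata for one SNP marker.

    ``allele_a``/``allele_b`` are the two allele symbols seen in the source
    file; dosage counts copies of ``allele_b``.
    """

    snp_id: str
    chromosome: str
    position: int
    allele_a: str = "A"
    allele_b: str = "B"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(
                f"marker {self.snp_id}: position must be >= 1 (1-based), got {self.position}"
            )

    @property
    def is_sex_chromosome(self) -> bool:
        return self.chromosome.upper() in SEX_CHROMOSOME_LABELS


@dataclass
class GenotypeMatrix:
    """Individuals × SNPs dosage matrix with marker metadata.

    ``dosages`` is a float array with entries in {0, 1, 2} and ``nan`` for
    missing genotypes. Rows follow ``individual_ids``, columns ``markers``.
    """

    dosages: np.ndarray
    individual_ids: list[str]
    markers: list[MarkerInfo] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        n, m = self.dosages.shape
        if n != len(self.individual_ids):
            raise ValueError(
                f"{len(self.individual_ids)} ids but {n} dosage rows"
            )
        if m != len(self.markers):
            raise ValueError(f"{len(self.markers)} markers but {m} dosage columns")
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            bad = observed[~np.isin(observed, (0.0, 1.0, 2.0))]
            raise ValueError(f"dosages must lie in {{0,1,2,missing}}; found {bad[:5]}")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("individual ids must be unique")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [m.snp_id for m in self.markers]

    def marker_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"marker {snp_id!r} not in panel") from None

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to marker columns selected by ``keep``
        (boolean mask or integer index array); individual order unchanged."""
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return GenotypeMatrix(
            dosages=self.dosages[:, idx].copy(),
            individual_ids=list(self.individual_ids),
            markers=[self.markers[i] for i in idx],
        )

    def imputed_dosages(self) -> np.ndarray:
        """Dosages with missing cells replaced by the per-marker mean of
        observed calls (a fully missing column imputes to 0)."""
        d = self.dosages.copy()
        if np.isnan(d).any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-nan columns
                col_means = np.nanmean(d, axis=0)
            col_means = np.where(np.isnan(col_means), 0.0, col_means)
            nan_r, nan_c = np.nonzero(np.isnan(d))
            d[nan_r, nan_c] = col_means[nan_c]
        return d


@dataclass
class PhenotypeTable:
    """One continuous phenotype record per individual id."""

    values: pd.Series  # index = id (str), values = float

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("phenotype ids must be unique")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("phenotypes must be finite")

    @property
    def ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    def aligned_to(self, ids: list[str]) -> np.ndarray:
        """Phenotype vector in the order of ``ids``; KeyError if any id is
        missing (never silently drops or reorders)."""
        missing = [i for i in ids if i not in self.values.index]
        if missing:
            raise KeyError(f"no phenotype for ids: {missing[:10]}")
        return self.values.loc[ids].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# PLINK 1.x text .ped / .map


def _read_map(map_path) -> list[MarkerInfo]:
    markers: list[MarkerInfo] = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 4:
                raise PlinkFormatError(f"{map_path}:{ln}: expected 4 fields, got {len(fields)}")
            chrom, snp_id, _cm, pos = fields[:4]
            markers.append(MarkerInfo(snp_id=snp_id, chromosome=chrom, position=int(pos)))
    return markers


def read_plink_text(ped_path, map_path) -> GenotypeMatrix:
    """Read a PLINK 1.x text ``.ped``/``.map`` pair as B-allele dosages.

    The B allele of each marker is the *second distinct* allele symbol
    encountered in file order (stable and file-defined); ``0 0`` is missing.
    A third allele symbol at any marker is a format error.
    """
    markers = _read_map(map_path)
    m = len(markers)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    # allele registry per marker: [first-seen symbol, second-seen symbol]
    seen: list[list[str]] = [[] for _ in range(m)]
    raw_pairs: list[list[tuple[str, str]]] = []

    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise PlinkFormatError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} fields "
                    f"(6 + 2×{m} markers), got {len(fields)}"
                )
            ids.append(fields[1])
            pairs = []
            for j in range(m):
                a1, a2 = fields[6 + 2 * j], fields[7 + 2 * j]
                pairs.append((a1, a2))
                for a in (a1, a2):
                    if a != "0" and a not in seen[j]:
                        seen[j].append(a)
                        if len(seen[j]) > 2:
                            raise PlinkFormatError(
                                f"{ped_path}:{ln}: marker {markers[j].snp_id} "
                                f"has >2 alleles: {seen[j]}"
                            )
            raw_pairs.append(pairs)

    out_markers = []
    for j, mk in enumerate(markers):
        alleles = seen[j]
        allele_a = alleles[0] if alleles else "0"
        allele_b = alleles[1] if len(alleles) > 1 else allele_a
        out_markers.append(replace(mk, allele_a=allele_a, allele_b=allele_b))

    dosages = np.full((len(ids), m), np.nan)
    for i, pairs in enumerate(raw_pairs):
        for j, (a1, a2) in enumerate(pairs):
            if a1 == "0" or a2 == "0":
                continue
            b = out_markers[j].allele_b
            dosages[i, j] = (a1 == b) + (a2 == b)
    return GenotypeMatrix(dosages=dosages, individual_ids=ids, markers=out_markers)


def write_plink_text(gm: GenotypeMatrix, out_prefix) -> tuple[str, str]:
    """Write ``gm`` as ``<out_prefix>.ped`` / ``<out_prefix>.map``.

    Dosage 0 → A/A, 1 → A/B, 2 → B/B, missing → ``0 0``. Returns the two
    paths written. Round-trips through :func:`read_plink_text`.
    """
    ped_path, map_path = f"{out_prefix}.ped", f"{out_prefix}.map"
    with open(map_path, "w") as fh:
        for mk in gm.markers:
            fh.write(f"{mk.chromosome}\t{mk.snp_id}\t0\t{mk.position}\n")
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(gm.individual_ids):
            fields = ["FAM", ind, "0", "0", "0", "-9"]
            for j, mk in enumerate(gm.markers):
                d = gm.dosages[i, j]
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [mk.allele_a, mk.allele_a]
                elif d == 1:
                    fields += [mk.allele_a, mk.allele_b]
                else:
                    fields += [mk.allele_b, mk.allele_b]
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# dosage-matrix CSV


def read_dosage_csv(path) -> GenotypeMatrix:
    """Dosage CSV: first column = individual id, remaining columns = SNP ids,
    cells in {0,1,2} or empty/NA for missing. Chromosome/position metadata is
    not carried by this dialect and defaults to chromosome "0", position j+1."""
    df = pd.read_csv(path, index_col=0)
    markers = [
        MarkerInfo(snp_id=str(c), chromosome="0", position=j + 1)
        for j, c in enumerate(df.columns)
    ]
    return GenotypeMatrix(
        dosages=df.to_numpy(dtype=float),
        individual_ids=[str(i) for i in df.index],
        markers=markers,
    )


def write_dosage_csv(gm: GenotypeMatrix, path) -> None:
    pd.DataFrame(gm.dosages, index=gm.individual_ids, columns=gm.snp_ids).to_csv(path)


# ---------------------------------------------------------------------------
# phenotypes


def read_phenotypes(path) -> PhenotypeTable:
    """Read a phenotype table (TSV or CSV sniffed from the header line).

    Columns: ``id``, ``phenotype``, optional ``n_breedings``. Duplicate ids
    are resolved by keeping the record with the largest ``n_breedings`` (the
    record based on most breedings is the most reliable one); without that
    column the last record wins and a warning is logged.
    """
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    required = {"id", "phenotype"}
    if not required.issubset(df.columns):
        raise PhenotypeFormatError(
            f"{path}: header must contain {sorted(required)}, got {list(df.columns)}"
        )
    pheno = pd.to_numeric(df["phenotype"], errors="coerce")
    if pheno.isna().any():
        row = int(pheno.index[pheno.isna()][0]) + 2  # header + 1-based
        raise PhenotypeFormatError(f"{path}:{row}: non-numeric phenotype value")
    df = df.assign(phenotype=pheno)

    if df["id"].duplicated().any():
        first_seen = df["id"].drop_duplicates().tolist()
        if "n_breedings" in df.columns:
            # stable sort keeps file order among ties; last (max) record wins
            df = df.sort_values("n_breedings", kind="stable")
        else:
            logger.warning(
                "%s: duplicate ids without n_breedings column; keeping last record", path
            )
        df = df.drop_duplicates("id", keep="last")
        # restore first-occurrence id order
        df = df.set_index("id").loc[first_seen].reset_index()
    return PhenotypeTable(values=pd.Series(df["phenotype"].to_numpy(), index=df["id"].astype(str)))


def write_phenotypes(values: pd.Series, path, n_breedings: pd.Series | None = None) -> None:
    """Write a phenotype TSV with columns id, phenotype[, n_breedings]."""
    df = pd.DataFrame({"id": values.index.astype(str), "phenotype": values.to_numpy()})
    if n_breedings is not None:
        df["n_breedings"] = n_breedings.to_numpy()
    df.to_csv(path, sep="\t", index=False)
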