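"""Genotype, genetic-map and phenotype input/output.

Genotypes are biallelic SNP states per subject coded as integers:
0 = homozygous dominant, 1 = heterozygous, 2 = homozygous recessive,
3 = missing.  Files are delimited text (comma or tab, sniffed) with a
header row; genotype rows are markers, columns are subjects.  The map
file carries one row per marker with columns ``marker_id, chromosome,
cm, mb`` (centiMorgan and megabase positions).  Phenotypes are one
quantitative value per subject, reconciled against the genotype header
by subject id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALID_STATES = frozenset({0, 1, 2, 3})
MISSING = 3

MAP_COLUMNS = ["marker_id", "chromosome", "cm", "mb"]


class GenotypeParseError(ValueError):
    """Raised when a genotype or map file violates the format contract."""


@dataclass(frozen=True)
class GeneticMap:
    """Per-marker genetic map for a single chromosome.

    Markers are stored sorted by increasing cM position (stable with
    respect to input order for ties).
    """

    marker_id: np.ndarray  # (S,) str
    chromosome: str
    cm: np.ndarray  # (S,) float, centiMorgans
    mb: np.ndarray  # (S,) float, megabases

    def __post_init__(self) -> None:
        if len(set(self.marker_id)) != len(self.marker_id):
            raise GenotypeParseError("duplicate marker ids in genetic map")
        if np.any(self.cm < 0) or np.any(self.mb < 0):
            raise GenotypeParseError("cM and Mb positions must be non-negative")
        if np.any(np.diff(self.cm) < 0):
            raise GenotypeParseError("map markers must be sorted by increasing cM")

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chromosome": self.chromosome,
                "cm": self.cm,
                "mb": self.mb,
            }
        )


@dataclass(frozen=True)
class GenotypeMatrix:
    """S x N state matrix for one chromosome, rows in map order."""

    states: np.ndarray  # (S, N) int8
    gmap: GeneticMap
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        s, n = self.states.shape
        if s != self.gmap.n_markers:
            raise ValueError("state rows do not match map length")
        if s < 1 or n < 2:
            raise ValueError("need at least 1 marker and 2 subjects")
        bad = ~np.isin(self.states, list(VALID_STATES))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeParseError(
                f"invalid state {self.states[i, j]} at marker "
                f"'{self.gmap.marker_id[i]}', subject '{self.subject_ids[j]}'"
            )

    @property
    def n_markers(self) -> int:
        return self.states.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.states.shape[1]

    @property
    def chromosome(self) -> str:
        return self.gmap.chromosome


@dataclass(frozen=True)
class PhenotypeVector:
    """A quantitative phenotype in raw (log), positive, and normalized form.

    ``positive`` is exp(raw); ``rho`` is positive / sum(positive) and sums
    to one, the weight vector used by the phenotype-weighted mutual
    information.
    """

    raw: np.ndarray
    positive: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.positive <= 0):
            raise ValueError("positive phenotype values must be > 0")
        if not math.isclose(float(self.rho.sum()), 1.0, abs_tol=1e-12):
            raise ValueError("rho must sum to 1")

    @property
    def n_subjects(self) -> int:
        return len(self.raw)


def normalize_phenotype(y, already_positive: bool = False) -> PhenotypeVector:
    """Exponentiate and normalize a phenotype to weights summing to one.

    Parameters
    ----------
    y
        N raw phenotype values.  By default these are taken on the raw
        (possibly signed) scale and exponentiated; with
        ``already_positive=True`` they are treated as the positive values
        w directly (and the raw scale is their log).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) < 2:
        raise ValueError("phenotype must be a 1-D vector with N >= 2")
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    if already_positive:
        if np.any(y <= 0):
            raise ValueError("already_positive=True requires strictly positive values")
        positive = y
        raw = np.log(y)
    else:
        raw = y
        positive = np.exp(y)
    rho = positive / positive.sum()
    return PhenotypeVector(raw=raw, positive=positive, rho=rho)


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str)


def read_genetic_map(path) -> pd.DataFrame:
    """Read a map file into a DataFrame with marker_id, chromosome, cm, mb."""
    df = _read_table(path)
    missing = [c for c in MAP_COLUMNS if c not in df.columns]
    if missing:
        raise GenotypeParseError(f"map file {path} lacks columns {missing}")
    df = df[MAP_COLUMNS].copy()
    df["cm"] = df["cm"].astype(float)
    df["mb"] = df["mb"].astype(float)
    return df


def load_genotypes(genotype_path, map_path) -> dict[str, GenotypeMatrix]:
    """Load genotype and map files into per-chromosome matrices.

    Returns a dict keyed by chromosome label; within each chromosome
    rows are sorted by increasing cM (stable for ties).
    """
    geno = _read_table(genotype_path)
    if geno.shape[1] < 3:
        raise GenotypeParseError("genotype file needs marker_id plus >= 2 subjects")
    marker_col = geno.columns[0]
    subject_ids = tuple(geno.columns[1:])
    markers = geno[marker_col].to_numpy(dtype=str)

    raw = geno.iloc[:, 1:].to_numpy()
    states = np.empty(raw.shape, dtype=np.int8)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            try:
                v = int(raw[i, j])
            except (TypeError, ValueError):
                v = -1
            if v not in VALID_STATES:
                raise GenotypeParseError(
                    f"invalid state {raw[i, j]!r} at marker '{markers[i]}', "
                    f"subject '{subject_ids[j]}'"
                )
            states[i, j] = v

    gmap_df = read_genetic_map(map_path)
    gmap_df = gmap_df.set_index("marker_id", drop=False)
    absent = [m for m in markers if m not in gmap_df.index]
    if absent:
        raise GenotypeParseError(f"markers missing from map: {absent[:5]}")

    row_of = {m: i for i, m in enumerate(markers)}
    if len(row_of) != len(markers):
        raise GenotypeParseError("duplicate marker ids in genotype file")
    rows = gmap_df.loc[list(markers)]
    out: dict[str, GenotypeMatrix] = {}
    for chrom, sub in rows.groupby("chromosome", sort=True):
        idx = np.array([row_of[m] for m in sub["marker_id"]])
        order = np.argsort(sub["cm"].to_numpy(), kind="stable")
        idx = idx[order]
        gmap = GeneticMap(
            marker_id=sub["marker_id"].to_numpy(dtype=str)[order],
            chromosome=str(chrom),
            cm=sub["cm"].to_numpy()[order],
            mb=sub["mb"].to_numpy()[order],
        )
        out[str(chrom)] = GenotypeMatrix(
            states=states[idx], gmap=gmap, subject_ids=subject_ids
        )
    return out


def write_genotypes(genotypes: dict[str, GenotypeMatrix], genotype_path, map_path) -> None:
    """Write per-chromosome matrices back to the two delimited files."""
    geno_frames = []
    map_frames = []
    for chrom in genotypes:
        g = genotypes[chrom]
        gf = pd.DataFrame(g.states, columns=list(g.subject_ids))
        gf.insert(0, "marker_id", g.gmap.marker_id)
        geno_frames.append(gf)
        map_frames.append(g.gmap.to_frame())
    pd.concat(geno_frames).to_csv(genotype_path, index=False)
    pd.concat(map_frames).to_csv(map_path, index=False)


def load_phenotypes(path, subject_ids) -> np.ndarray:
    """Read a subject_id,value phenotype file aligned to a subject order."""
    df = _read_table(path)
    if df.shape[1] < 2:
        raise GenotypeParseError("phenotype file needs subject_id and value columns")
    table = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    missing = [s for s in subject_ids if s not in table]
    if missing:
        raise GenotypeParseError(f"phenotype missing for subjects: {missing[:5]}")
    return np.array([float(table[s]) for s in subject_ids])


def write_phenotypes(path, subject_ids, values) -> None:
    pd.DataFrame({"subject_id": list(subject_ids), "value": values}).to_csv(
        path, index=False
    )


def filter_missing(g: GenotypeMatrix, max_missing_fraction: float = 0.5) -> GenotypeMatrix:
    """Drop SNPs with missing entries on more than a fraction of subjects.

    A SNP survives when its count of missing (state 3) entries is at most
    ``max_missing_fraction * N``; exactly half-missing markers are kept
    under the default threshold.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    n = g.n_subjects
    miss = (g.states == MISSING).sum(axis=1)
    keep = miss <= max_missing_fraction * n
    if not keep.any():
        raise ValueError("no markers survive missingness filter")
    if keep.all():
        return g
    gmap = GeneticMap(
        marker_id=g.gmap.marker_id[keep],
        chromosome=g.gmap.chromosome,
        cm=g.gmap.cm[keep],
        mb=g.gmap.mb[keep],
    )
    return GenotypeMatrix(states=g.states[keep], gmap=gmap, subject_ids=g.subject_ids)
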