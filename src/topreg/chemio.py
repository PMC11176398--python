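"""Reading, cleaning and fingerprinting of activity tables.

Molecules arrive as delimited text with (identifier, SMILES, activity)
columns; pChEMBL-like real activities are the response.  Chemistry is
delegated to RDKit: canonicalization, ECFP4 (Morgan radius-2) fingerprints
folded to a fixed bit size, and Bemis–Murcko scaffolds.  Similarity between
binary fingerprints is the Tanimoto coefficient TC = |a∩b|/|a∪b|; the
distance handed to the regression layer is 1−TC, optionally squared (the
default) to mimic a squared-Euclidean design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .exceptions import ConfigurationError, EmptyDatasetError, SmilesParseError

logger = logging.getLogger(__name__)

DEFAULT_NBITS = 1024
DEFAULT_RADIUS = 2


@dataclass(frozen=True)
class MoleculeRecord:
    """One compound: identifier, SMILES, fingerprint bit-set, activity.

    ``smiles`` may be None for synthetic records whose fingerprints were
    injected directly (no chemistry toolkit involved).
    """

    id: str
    smiles: str | None
    fingerprint: frozenset[int]
    activity: float


@dataclass
class Dataset:
    """Ordered collection of molecules sharing one fingerprint universe."""

    records: list[MoleculeRecord]
    nbits: int = DEFAULT_NBITS
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def activities(self) -> np.ndarray:
        return np.array([r.activity for r in self.records], dtype=float)

    def fingerprint_matrix(self) -> np.ndarray:
        """Dense 0/1 matrix, one row per molecule."""
        m = np.zeros((len(self.records), self.nbits), dtype=np.uint8)
        for i, r in enumerate(self.records):
            m[i, sorted(r.fingerprint)] = 1
        return m


@dataclass
class SimilarityMatrix:
    """Square symmetric Tanimoto similarity matrix with row/column ids."""

    values: np.ndarray
    ids: list[str] = field(default_factory=list)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), [str(c) for c in df.columns])


def canonical_smiles(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return Chem.MolToSmiles(mol)


def compute_ecfp4(
    smiles: str, nbits: int = DEFAULT_NBITS, radius: int = DEFAULT_RADIUS
) -> frozenset[int]:
    """Folded ECFP4 fingerprint (Morgan radius 2, 1024 bits by default).

    Returns the set of set-bit indices; deterministic for a given SMILES
    (RDKit canonicalizes internally, so "CCO" and "OCC" agree).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    fp = gen.GetFingerprint(mol)
    return frozenset(fp.GetOnBits())


def tanimoto_similarity(a: frozenset[int], b: frozenset[int]) -> float:
    """TC = |a∩b|/|a∪b|; two empty fingerprints count as identical (TC=1)."""
    union = len(a | b)
    if union == 0:
        return 1.0
    return len(a & b) / union


def tanimoto_distance(a: frozenset[int], b: frozenset[int]) -> float:
    """1 − TC; a metric on binary sets (0 for the empty/empty pair)."""
    return 1.0 - tanimoto_similarity(a, b)


def read_activity_table(
    path,
    id_col: str = "id",
    smiles_col: str = "smiles",
    activity_col: str = "activity",
    nbits: int = DEFAULT_NBITS,
    radius: int = DEFAULT_RADIUS,
    sep: str | None = None,
) -> Dataset:
    """Read and clean a delimited activity table into a :class:`Dataset`.

    Cleaning: rows whose SMILES RDKit cannot parse are dropped; rows whose
    canonical SMILES duplicates an earlier row are collapsed (first
    occurrence kept).  The number of rows dropped for each reason is logged.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    for col in (id_col, smiles_col, activity_col):
        if col not in df.columns:
            raise ConfigurationError(
                f"column {col!r} not found in {path} (have {list(df.columns)})"
            )
    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    n_invalid = n_dup = 0
    for row in df.itertuples(index=False):
        smiles = str(getattr(row, smiles_col))
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            n_invalid += 1
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            n_dup += 1
            continue
        seen.add(canon)
        activity = float(getattr(row, activity_col))
        if not np.isfinite(activity):
            n_invalid += 1
            continue
        records.append(
            MoleculeRecord(
                id=str(getattr(row, id_col)),
                smiles=canon,
                fingerprint=compute_ecfp4(canon, nbits=nbits, radius=radius),
                activity=activity,
            )
        )
    logger.info(
        "read %d rows from %s: kept %d, dropped %d invalid, %d duplicate",
        len(df), path, len(records), n_invalid, n_dup,
    )
    if not records:
        raise EmptyDatasetError(f"no valid records in {path}")
    return Dataset(records=records, nbits=nbits, provenance=str(path))


def read_fingerprint_table(
    path,
    id_col: str = "id",
    fingerprint_col: str = "fingerprint",
    activity_col: str = "activity",
    nbits: int = DEFAULT_NBITS,
    sep: str | None = None,
) -> Dataset:
    """Read a table whose fingerprints are given directly (no SMILES).

    The fingerprint column holds semicolon-separated set-bit indices, the
    schema the synthetic landscape generator writes.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    for col in (id_col, fingerprint_col, activity_col):
        if col not in df.columns:
            raise ConfigurationError(f"column {col!r} not found in {path}")
    records = []
    for row in df.itertuples(index=False):
        raw = str(getattr(row, fingerprint_col))
        bits = frozenset(int(tok) for tok in raw.split(";") if tok != "")
        if bits and max(bits) >= nbits:
            raise ConfigurationError(
                f"fingerprint bit {max(bits)} out of range for nbits={nbits}"
            )
        records.append(
            MoleculeRecord(
                id=str(getattr(row, id_col)),
                smiles=None,
                fingerprint=bits,
                activity=float(getattr(row, activity_col)),
            )
        )
    if not records:
        raise EmptyDatasetError(f"no records in {path}")
    return Dataset(records=records, nbits=nbits, provenance=str(path))


def pairwise_similarity_matrix(ds: Dataset) -> SimilarityMatrix:
    """N×N Tanimoto similarity; unit diagonal, exactly symmetric."""
    m = ds.fingerprint_matrix().astype(np.int64)
    inter = m @ m.T
    card = m.sum(axis=1)
    union = card[:, None] + card[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(values=sim, ids=ds.ids)


def pairwise_distance_matrix(ds: Dataset) -> np.ndarray:
    """N×N matrix of 1−TC; zero diagonal, symmetric."""
    d = 1.0 - pairwise_similarity_matrix(ds).values
    np.fill_diagonal(d, 0.0)
    return d


def design_distances(distances: np.ndarray, distance_power: int = 2) -> np.ndarray:
    """Distances as fed to the regression design.

    ``distance_power=2`` (default) squares the Tanimoto distance so the
    design plays the role of a squared-Euclidean distance matrix;
    ``distance_power=1`` uses 1−TC as-is.
    """
    if distance_power not in (1, 2):
        raise ConfigurationError(f"distance_power must be 1 or 2, got {distance_power}")
    return distances if distance_power == 1 else distances**2
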